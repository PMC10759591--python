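import numpy as np
import pandas as pd
import pytest

from orchardblup.kinship import build_A, build_A_selfing, build_G
from orchardblup.qc import MISSING
from orchardblup.simulate import (ConfigError, SimConfig, SiteLayout,
                                  SiteVariance, inject_missing,
                                  realized_pedigree, simulate_genotypes,
                                  simulate_orchard, simulate_pedigree,
                                  simulate_trials)

from conftest import small_sim_config


def one_site_config(**kw):
    base = dict(
        n_provenances=3, families_per_provenance=2,
        trees_per_family_per_site=4, n_bulk_lots=2,
        trees_per_bulk_lot_per_site=3, n_snps=50,
        site_layouts={"S": SiteLayout(10, 10, 2)},
        variance_truth={"S": SiteVariance(2.0, 1.0, 1.5, 5.0)},
        site_means={"S": 12.0}, seed=1)
    base.update(kw)
    return SimConfig(**base)


def test_pedigree_counts_and_selfing_flags():
    cfg = one_site_config(selfing_rate=0.0)
    ped, par = simulate_pedigree(cfg)
    trees = par[par["site"].notna()]
    assert len(ped.founders()) == 6 + 6  # 6 dams + 6 bulk trees
    fam_trees = trees[trees.index.str.contains("-F")]
    assert len(fam_trees) == 3 * 2 * 4
    assert not par["selfed"].any()

    cfg1 = one_site_config(selfing_rate=1.0)
    _, par1 = simulate_pedigree(cfg1)
    offspring = par1[par1["realized_father"].notna()]
    assert offspring["selfed"].all()


def test_selfed_fraction_binomial_bound():
    cfg = small_sim_config(selfing_rate=0.3, families_per_provenance=21,
                           trees_per_family_per_site=14,
                           site_layouts={s: SiteLayout(34, 34, 4)
                                         for s in ("ILRI", "SM", "Suba")})
    _, par = simulate_pedigree(cfg, seed=123)
    off = par[par["realized_father"].notna()]
    n = len(off)
    assert n > 2000
    frac = off["selfed"].mean()
    assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)


def test_capacity_error_names_site():
    with pytest.raises(ConfigError, match="S"):
        one_site_config(site_layouts={"S": SiteLayout(3, 3, 1)})


def test_genotypes_fixed_allele_and_homozygote_selfing():
    cfg = one_site_config(selfing_rate=1.0, n_snps=1,
                          founder_maf_distribution=(1e6, 1e-6))
    # Beta(1e6, 1e-6) concentrates at frequency 1 -> every call 2
    ped, par = simulate_pedigree(cfg)
    geno, freqs = simulate_genotypes(ped, cfg, parentage=par)
    assert freqs[0] > 0.999
    assert (geno.calls == 2).all()


def test_selfed_offspring_of_homozygous_mother_is_homozygous():
    cfg = one_site_config(selfing_rate=1.0, n_snps=200)
    ped, par = simulate_pedigree(cfg)
    geno, _ = simulate_genotypes(ped, cfg, parentage=par)
    pos = {i: k for k, i in enumerate(geno.ids)}
    moms = dict(zip(ped.ids, ped.table["mother"]))
    for tid, row in par.iterrows():
        if not row["selfed"]:
            continue
        mom = moms[tid]
        m_calls = geno.calls[pos[mom]]
        o_calls = geno.calls[pos[tid]]
        hom = m_calls != 1
        assert np.array_equal(o_calls[hom], m_calls[hom])
        break


def test_halfsib_vanraden_relatedness_near_quarter():
    # outcrossing only: mean within-family G off-diagonal ~ 0.25
    cfg = SimConfig(
        n_provenances=2, families_per_provenance=10,
        trees_per_family_per_site=10, n_bulk_lots=0,
        trees_per_bulk_lot_per_site=0, n_snps=5000, selfing_rate=0.0,
        provenance_fst=0.0,  # pedigree-scale expectation needs one gene pool
        site_layouts={"S": SiteLayout(20, 12, 2)},
        variance_truth={"S": SiteVariance()}, site_means={"S": 10.0}, seed=2)
    ped, par = simulate_pedigree(cfg)
    geno, freqs = simulate_genotypes(ped, cfg, parentage=par)
    trees = [i for i in ped.ids if not i.endswith("dam")]
    panel = geno.select_individuals(trees)
    # centre on true founder frequencies for an unbiased pedigree-scale check
    W = panel.calls.astype(float) - 2 * freqs
    G = W @ W.T / (2 * np.sum(freqs * (1 - freqs)))
    fam = dict(zip(ped.ids, ped.family))
    vals = []
    for a in range(len(trees)):
        for b in range(a + 1, len(trees)):
            if fam[trees[a]] == fam[trees[b]]:
                vals.append(G[a, b])
    assert np.mean(vals) == pytest.approx(0.25, abs=0.02)


def test_realized_A2_equals_A_at_zero_selfing():
    cfg = one_site_config(selfing_rate=0.0)
    ped, par = simulate_pedigree(cfg)
    real = realized_pedigree(ped, par)
    assert np.array_equal(build_A(real).values,
                          build_A_selfing(real, 0.0).values)


def test_trials_zero_variance_is_pure_fixed_structure():
    cfg = one_site_config(
        variance_truth={"S": SiteVariance(0.0, 0.0, 0.0, 0.0)},
        block_effect_sd=0.0, bv_mechanism="pedigree")
    ped, par = simulate_pedigree(cfg)
    trial, truth = simulate_trials(ped, cfg, parentage=par)
    expect = 12.0 + trial["provenance"].map(cfg.provenance_effects).fillna(0.0)
    assert np.allclose(trial["height"], expect, atol=1e-9)


def test_spatial_surface_ar1_lag_decay():
    cfg = one_site_config(
        site_layouts={"S": SiteLayout(60, 60, 2)},
        trees_per_family_per_site=4,
        variance_truth={"S": SiteVariance(0.0, 0.0, 4.0, 0.0)},
        rho_col=0.9, rho_row=0.9, bv_mechanism="pedigree", seed=4)
    ped, par = simulate_pedigree(cfg)
    _, truth = simulate_trials(ped, cfg, parentage=par)
    surf = truth.spatial_surfaces["S"]

    def lag_corr(lag):
        return np.corrcoef(surf[:, :-lag].ravel(), surf[:, lag:].ravel())[0, 1]

    assert lag_corr(1) > lag_corr(5)
    assert lag_corr(1) == pytest.approx(0.9, abs=0.08)


def test_realized_heritability_close_to_truth():
    # outcrossing only, no bulk lots: var(true BV) / var(height - fixed part)
    # should sit at sigma2_a / (sigma2_a + sigma2_xi + sigma2_eta)
    cfg = SimConfig(
        n_provenances=2, families_per_provenance=10,
        trees_per_family_per_site=25, n_bulk_lots=0,
        trees_per_bulk_lot_per_site=0, n_snps=2000, selfing_rate=0.0,
        site_layouts={"S": SiteLayout(25, 25, 5)},
        variance_truth={"S": SiteVariance(2.5, 0.0, 2.0, 6.0)},
        site_means={"S": 12.0}, seed=6)
    data = simulate_orchard(cfg)
    trial, truth = data.trial, data.truth
    tb = truth.true_breeding_values.loc[trial["id"], "S"].to_numpy()
    fixed = (12.0
             + trial["provenance"].map(cfg.provenance_effects).fillna(0.0)
             + trial["block"].map(truth.block_effects["S"]))
    resid = trial["height"].to_numpy() - fixed.to_numpy()
    want = 2.5 / (2.5 + 2.0 + 6.0)
    assert tb.var() / resid.var() == pytest.approx(want, abs=0.05)


def test_inject_missing_rates_and_extremes():
    cfg = one_site_config(missing_locus_rate=0.0,
                          missing_individual_rate=0.0,
                          bad_locus_fraction=0.0, bad_individual_fraction=0.0,
                          low_het_locus_fraction=0.0)
    ped, par = simulate_pedigree(cfg)
    geno, _ = simulate_genotypes(ped, cfg, parentage=par)
    same = inject_missing(geno, cfg)
    assert np.array_equal(same.calls, geno.calls)

    cfg_all = one_site_config(missing_locus_rate=1.0,
                              bad_locus_fraction=0.0,
                              low_het_locus_fraction=0.0)
    gone = inject_missing(geno, cfg_all)
    assert (gone.calls == MISSING).all()


def test_inject_missing_binomial_bound():
    cfg = SimConfig(
        n_provenances=2, families_per_provenance=10,
        trees_per_family_per_site=25, n_bulk_lots=0,
        trees_per_bulk_lot_per_site=0, n_snps=2000,
        site_layouts={"S": SiteLayout(25, 20, 2)},
        variance_truth={"S": SiteVariance()}, site_means={"S": 10.0},
        missing_locus_rate=0.1, missing_individual_rate=0.0,
        bad_locus_fraction=0.0, bad_individual_fraction=0.0,
        low_het_locus_fraction=0.0, seed=7)
    ped, par = simulate_pedigree(cfg)
    geno, _ = simulate_genotypes(ped, cfg, parentage=par)
    out = inject_missing(geno, cfg)
    n_calls = out.calls.size
    assert n_calls >= 1_000_000
    frac = (out.calls == MISSING).mean()
    assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n_calls)


def test_orchard_determinism_and_genotyped_panel():
    cfg = small_sim_config(seed=8)
    d1 = simulate_orchard(cfg)
    d2 = simulate_orchard(cfg)
    assert d1.genotyped_ids == d2.genotyped_ids
    assert np.array_equal(d1.genotypes.calls, d2.genotypes.calls)
    pd.testing.assert_frame_equal(d1.trial, d2.trial)
    gsite = cfg.site_names[0]
    site_of = dict(zip(d1.trial["id"], d1.trial["site"]))
    assert all(site_of[i] == gsite for i in d1.genotyped_ids)
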