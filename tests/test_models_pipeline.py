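import numpy as np
import pandas as pd
import pytest

from orchardblup.kinship import build_A, RelationshipMatrix
from orchardblup.mme import IidResidual, MixedModel, MixedModelError, RandomTerm
from orchardblup.models import fit_gblup, fit_multi_site, fit_single_site
from orchardblup.pipeline import adjust_phenotypes, run_pipeline
from orchardblup.simulate import (SimConfig, SiteLayout, SiteVariance,
                                  simulate_orchard)

from conftest import make_pedigree, small_sim_config

FAST = {"max_iter": 25, "use_simplex_fallback": False}


def founder_trial(n=120, seed=0):
    """Trial of unrelated founders (A = I) on one site."""
    rng = np.random.default_rng(seed)
    ids = [f"t{i}" for i in range(n)]
    rows = [(i, None, None, "P30", None, None) for i in ids]
    ped = make_pedigree(rows)
    u = rng.normal(0, np.sqrt(2.0), n)
    trial = pd.DataFrame({
        "id": ids, "site": "S", "block": np.repeat(["B1", "B2"], n // 2),
        "row": np.repeat(np.arange(1, n // 10 + 1), 10),
        "col": np.tile(np.arange(1, 11), n // 10),
        "provenance": "P30", "family": None, "bulk_lot": None,
        "height": 10 + u + rng.normal(0, 1.0, n),
    })
    return ped, trial, u


def test_single_site_founder_pedigree_equals_iid_animal_model():
    ped, trial, _ = founder_trial()
    A = build_A(ped)
    fit = fit_single_site(trial, A, spatial=False, reml_options=FAST)
    # same data fitted with an explicit iid random effect
    obs = trial
    X = np.column_stack([np.ones(len(obs)),
                         (obs["block"] == "B2").astype(float)])
    term = RandomTerm("u", np.arange(len(obs)), None, len(obs))
    ref = MixedModel(obs["height"].to_numpy(), X, {"u": term},
                     IidResidual(len(obs))).reml(**FAST)
    assert fit.varcomp["additive"]["variances"][0] == pytest.approx(
        ref.varcomp["u"]["variances"][0], rel=1e-5)
    assert fit.loglik == pytest.approx(ref.loglik, abs=1e-5)


def test_single_site_requires_one_site_and_known_trees():
    ped, trial, _ = founder_trial()
    A = build_A(ped)
    two = pd.concat([trial, trial.assign(site="T")])
    with pytest.raises(MixedModelError, match="one site"):
        fit_single_site(two, A)
    stranger = trial.copy()
    stranger.loc[0, "id"] = "ghost"
    with pytest.raises(MixedModelError, match="absent"):
        fit_single_site(stranger, A, spatial=False)


@pytest.fixture(scope="module")
def orchard():
    cfg = small_sim_config(seed=31)
    return simulate_orchard(cfg)


@pytest.fixture(scope="module")
def stage1_spatial(orchard):
    A = build_A(orchard.pedigree)
    out = {}
    for site, sub in orchard.trial.groupby("site"):
        out[site] = fit_single_site(sub, A, spatial=True)
    return A, out


def test_adjustment_contract_rejects_design_fit(orchard):
    A = build_A(orchard.pedigree)
    sub = orchard.trial[orchard.trial["site"] == "ILRI"]
    design = fit_single_site(sub, A, spatial=False, reml_options=FAST)
    with pytest.raises(MixedModelError, match="spatial"):
        adjust_phenotypes(sub, design)


def test_adjustment_near_identity_without_spatial_or_block_signal():
    cfg = small_sim_config(seed=32)
    cfg.variance_truth = {s: SiteVariance(2.5, 1.5, 0.0, 6.0)
                          for s in cfg.site_names}
    cfg.block_effect_sd = 0.0
    data = simulate_orchard(cfg)
    A = build_A(data.pedigree)
    sub = data.trial[data.trial["site"] == "ILRI"]
    fit = fit_single_site(sub, A, spatial=True)
    adj = adjust_phenotypes(sub, fit)
    merged = adj.merge(sub[["id", "height"]], on="id")
    diff = merged["y_adj"] - merged["height"]
    # estimation noise only: the subtracted block + spatial component is a
    # small fraction of the residual scale and leaves y essentially intact
    assert np.var(diff) < 0.2 * 6.0
    assert np.corrcoef(merged["y_adj"], merged["height"])[0, 1] > 0.95


def test_adjustment_invariant_to_block_level_shift(orchard, stage1_spatial):
    A, fits = stage1_spatial
    sub = orchard.trial[orchard.trial["site"] == "SM"].copy()
    adj0 = adjust_phenotypes(sub, fits["SM"])
    shifted = sub.copy()
    block = sorted(shifted["block"].unique())[1]
    shifted.loc[shifted["block"] == block, "height"] += 7.0
    fit2 = fit_single_site(shifted, A, spatial=True)
    adj1 = adjust_phenotypes(shifted, fit2)
    m = adj0.merge(adj1, on="id", suffixes=("_0", "_1"))
    diff = m["y_adj_1"] - m["y_adj_0"]
    # constant added to one block is soaked by that block's estimate:
    # adjusted values agree up to the fit's own estimation wobble
    assert np.std(diff[~m["id"].isin(shifted[shifted['block'] == block]['id'])]) \
        == pytest.approx(np.std(diff), abs=0.35)
    assert np.abs(np.median(diff)) < 0.35


def test_multi_site_k1_reduces_to_single_site_design(orchard, stage1_spatial):
    A, fits = stage1_spatial
    sub = orchard.trial[orchard.trial["site"] == "Suba"]
    adj = adjust_phenotypes(sub, fits["Suba"])
    multi = fit_multi_site(adj, A, reml_options=FAST)
    # same adjusted data through the single-site design path (one block level)
    single_df = adj.rename(columns={"y_adj": "height"}).copy()
    single_df["block"] = "B1"
    single_df["row"] = np.arange(len(single_df)) + 1
    single_df["col"] = 1
    single = fit_single_site(single_df, A, spatial=False, reml_options=FAST)
    assert multi.varcomp["additive"]["variances"][0] == pytest.approx(
        single.varcomp["additive"]["variances"][0], rel=1e-4, abs=1e-6)
    assert multi.varcomp["residual"]["variances"][0] == pytest.approx(
        single.varcomp["residual"]["variances"][0], rel=1e-4, abs=1e-6)
    b1 = multi.meta["blup"].set_index("id")["blup"]
    b2 = single.meta["blup"].set_index("id")["blup"]
    assert np.allclose(b1, b2.reindex(b1.index), atol=1e-5)


def test_pipeline_emits_all_five_models_and_is_deterministic(orchard):
    run1 = run_pipeline(orchard, reml_options=FAST, seed=5, cv_folds=2,
                        cv_schemes=("random",))
    assert set(run1.stage2) == {"ABLUP-1", "ABLUP-2", "ssGBLUP-1",
                                "ssGBLUP-2", "GBLUP"}
    assert run1.s_estimate is not None
    assert run1.qc_report.n_loci_out > 0
    for model, fit in run1.stage2.items():
        blup = fit.meta["blup"]
        assert blup["pev"].ge(0).all()
        assert np.isfinite(blup["blup"]).all()
    # self-consistency of the report
    for m, h in run1.report["h2"].items():
        assert ((h > 0) & (h < 1)).all()
    for pair, ov in run1.report["overlap_top"].items():
        assert 0.0 <= ov <= 1.0
    assert run1.cv is not None and not run1.cv.empty

    run2 = run_pipeline(orchard, reml_options=FAST, seed=5, cv_folds=2,
                        cv_schemes=("random",))
    pd.testing.assert_frame_equal(run1.adjusted, run2.adjusted)
    for m in run1.stage2:
        pd.testing.assert_frame_equal(run1.stage2[m].meta["blup"],
                                      run2.stage2[m].meta["blup"])
    pd.testing.assert_frame_equal(run1.cv, run2.cv)


def test_pipeline_without_genotypes_runs_pedigree_models_only(orchard):
    with pytest.warns(UserWarning, match="skipping"):
        run = run_pipeline(orchard.pedigree, orchard.trial, None,
                           selfing_rate=0.30, reml_options=FAST, seed=1)
    assert set(run.stage2) == {"ABLUP-1", "ABLUP-2"}
    assert run.s_used == 0.30
    assert run.qc_report is None


def test_gblup_panel_self_consistency(orchard):
    run = run_pipeline(orchard, reml_options=FAST, seed=2,
                       models=("ssGBLUP-1", "GBLUP"), keep_matrices=True)
    g_fit = run.stage2["GBLUP"]
    assert set(g_fit.meta["blup"]["id"]) == set(run.genotyped_ids)
    # cross-validation predictions at full data reproduce the fit's BLUPs
    adj = run.adjusted
    gw = run.matrices["Gw"]
    pred = adj.loc[adj["id"].isin(run.genotyped_ids), ["id", "site"]]
    refit = fit_gblup(adj, gw, reml_options=FAST)
    b1 = g_fit.meta["blup"].set_index("id")["blup"]
    b2 = refit.meta["blup"].set_index("id")["blup"].reindex(b1.index)
    assert np.allclose(b1, b2, atol=1e-8)
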