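"""Synthetic breeding-seedling-orchard generator with known truth.

The generator emulates the structure of a first-generation, open-pollinated
tropical-tree breeding trial: a few provenances each contributing ~20 or so
open-pollinated families, bulk seed lots of unknown parentage, partial
selfing at a configurable rate, biallelic SNP genotypes gene-dropped through
the realized pedigree, and field trials on rectangular grids with a
separable AR1 x AR1 spatial trend plus nugget noise.

Mating model: each offspring of a family is selfed with probability s
(father = mother); otherwise it receives pollen from a fresh, unique,
unrelated male founder of the same provenance (infinite pollen pool), which
keeps the expected relatedness of outcross maternal half-sibs at exactly
0.25.  The wild-stand mating structure behind real orchards is unknown; this
pollen-pool model is an explicit assumption.

Trait model: by default breeding values are genic - each simulated SNP
carries a per-site effect, with effects correlated across sites at the
configured genetic correlation and scaled so founder breeding-value variance
matches the configured additive variance.  A purely pedigree-driven
alternative (recursive Mendelian-sampling draws, marker-independent) is
available via ``bv_mechanism="pedigree"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .qc import GenotypeMatrix, MISSING


class ConfigError(ValueError):
    pass


@dataclass
class SiteLayout:
    rows: int
    cols: int
    blocks: int

    @property
    def capacity(self) -> int:
        return self.rows * self.cols


@dataclass
class SiteVariance:
    """Per-site truth: additive, bulk-lot, spatial and nugget variances (dm^2)."""

    sigma2_a: float = 2.7
    sigma2_b: float = 1.5
    sigma2_xi: float = 2.0
    sigma2_eta: float = 6.5


def _default_layouts() -> dict:
    return {
        "ILRI": SiteLayout(44, 60, 22),
        "SM": SiteLayout(60, 60, 30),
        "Suba": SiteLayout(40, 51, 17),
    }


def _default_variances() -> dict:
    return {
        "ILRI": SiteVariance(2.7, 1.4, 2.0, 6.5),
        "SM": SiteVariance(2.3, 2.9, 2.0, 6.9),
        "Suba": SiteVariance(3.2, 1.6, 2.0, 5.3),
    }


def _default_site_means() -> dict:
    return {"ILRI": 16.0, "SM": 9.0, "Suba": 12.0}


def _default_prov_effects() -> dict:
    return {"P30": 0.0, "P31": -1.5, "P34": 1.5, "BULK": 0.0}


@dataclass
class SimConfig:
    """Study conditions for one synthetic orchard; defaults mirror a
    three-site, three-provenance open-pollinated trial with partial selfing."""

    n_provenances: int = 3
    families_per_provenance: int = 21
    trees_per_family_per_site: int = 30
    n_bulk_lots: int = 25
    trees_per_bulk_lot_per_site: int = 30
    selfing_rate: float = 0.30
    n_snps: int = 4000
    founder_maf_distribution: tuple[float, float] = (1.0, 1.0)
    provenance_fst: float = 0.10  # Balding-Nichols differentiation of provenances
    site_layouts: dict = field(default_factory=_default_layouts)
    variance_truth: dict = field(default_factory=_default_variances)
    rho_col: float = 0.6
    rho_row: float = 0.6
    genetic_correlation: float = 0.5
    bulk_correlation: float = 0.5
    site_means: dict = field(default_factory=_default_site_means)
    provenance_effects: dict = field(default_factory=_default_prov_effects)
    block_effect_sd: float = 1.0
    missing_locus_rate: float = 0.03
    missing_individual_rate: float = 0.02
    bad_locus_fraction: float = 0.05
    bad_individual_fraction: float = 0.02
    low_het_locus_fraction: float = 0.03
    genotyped_site: str | None = None  # default: first site
    genotyped_families_fraction: float = 0.34  # share of families with any genotyping
    genotyped_fraction: float = 0.80  # share of trees genotyped within those families
    bv_mechanism: str = "marker"  # "marker" | "pedigree"
    seed: int = 20240102

    def __post_init__(self):
        self.validate()

    @property
    def site_names(self) -> list[str]:
        return list(self.site_layouts)

    def validate(self) -> None:
        probs = {
            "selfing_rate": self.selfing_rate,
            "missing_locus_rate": self.missing_locus_rate,
            "missing_individual_rate": self.missing_individual_rate,
            "bad_locus_fraction": self.bad_locus_fraction,
            "bad_individual_fraction": self.bad_individual_fraction,
            "low_het_locus_fraction": self.low_het_locus_fraction,
            "genotyped_fraction": self.genotyped_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 <= self.genotyped_families_fraction <= 1.0:
            raise ConfigError("genotyped_families_fraction must be in [0, 1]")
        if not 0.0 <= self.provenance_fst < 1.0:
            raise ConfigError("provenance_fst must be in [0, 1)")
        for rho in (self.rho_col, self.rho_row):
            if not -1.0 < rho < 1.0:
                raise ConfigError("spatial correlations must be in (-1, 1)")
        if not -1.0 < self.genetic_correlation < 1.0:
            raise ConfigError("genetic correlation must be in (-1, 1)")
        if self.bv_mechanism not in ("marker", "pedigree"):
            raise ConfigError("bv_mechanism must be 'marker' or 'pedigree'")
        if set(self.variance_truth) != set(self.site_layouts) or \
                set(self.site_means) != set(self.site_layouts):
            raise ConfigError("site_layouts, variance_truth and site_means "
                              "must name the same sites")
        n_fam_trees = self.n_provenances * self.families_per_provenance \
            * self.trees_per_family_per_site
        n_bulk_trees = self.n_bulk_lots * self.trees_per_bulk_lot_per_site
        for site, lay in self.site_layouts.items():
            vc = self.variance_truth[site]
            for v in (vc.sigma2_a, vc.sigma2_b, vc.sigma2_xi, vc.sigma2_eta):
                if v < 0:
                    raise ConfigError(f"negative variance at site {site}")
            if n_fam_trees + n_bulk_trees > lay.capacity:
                raise ConfigError(
                    f"site {site}: grid capacity {lay.capacity} < "
                    f"{n_fam_trees + n_bulk_trees} trees assigned")

    def provenances(self) -> list[str]:
        return [f"P{30 + i}" for i in range(self.n_provenances)]

    def sigma_a(self) -> np.ndarray:
        """Across-site additive covariance implied by the per-site variances
        and the common genetic correlation."""
        sd = np.sqrt([self.variance_truth[s].sigma2_a for s in self.site_names])
        k = len(sd)
        S = self.genetic_correlation * np.outer(sd, sd)
        S[np.diag_indices(k)] = sd ** 2
        if np.linalg.eigvalsh(S).min() < -1e-10:
            raise ConfigError("implied across-site additive covariance is "
                              "not positive semidefinite")
        return S

    def sigma_b(self) -> np.ndarray:
        sd = np.sqrt([self.variance_truth[s].sigma2_b for s in self.site_names])
        k = len(sd)
        S = self.bulk_correlation * np.outer(sd, sd)
        S[np.diag_indices(k)] = sd ** 2
        return S


@dataclass
class SimTruth:
    """Ground truth for one simulated orchard."""

    true_breeding_values: pd.DataFrame  # index id, one column per site (dm)
    spatial_surfaces: dict  # site -> 2D array (rows x cols)
    realized_pedigree: Pedigree  # includes realized sires / selfing events
    founder_allele_frequencies: np.ndarray
    parentage: pd.DataFrame  # id, realized_father, selfed, site
    block_effects: dict  # site -> {block: effect}
    lot_effects: pd.DataFrame | None = None  # lot x site truth


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig, seed=None
                      ) -> tuple[Pedigree, pd.DataFrame]:
    """Observed pedigree plus realized-parentage truth.

    The observed pedigree records mothers only (open pollination); the truth
    frame carries the realized father (the mother herself for selfed
    offspring, a unique male founder otherwise), the selfed flag and the
    site each tree is planted at.  Output is topologically ordered.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed)
    s = config.selfing_rate
    rows = []
    truth_rows = []

    def founder(i, prov, fam, lot=None, site=None):
        rows.append((i, None, None, prov, fam, lot))
        truth_rows.append((i, None, False, site))

    # family founders (mothers)
    fam_ids = []
    for prov in config.provenances():
        for j in range(config.families_per_provenance):
            fam = f"{prov}-F{j + 1:02d}"
            dam = f"{fam}-dam"
            founder(dam, prov, fam)
            fam_ids.append((prov, fam, dam))

    sire_count = 0
    for site in config.site_names:
        for prov, fam, dam in fam_ids:
            for t in range(config.trees_per_family_per_site):
                tid = f"{fam}-{site}-{t + 1:03d}"
                selfed = bool(rng.random() < s)
                if selfed:
                    father = dam
                else:
                    # realized sire: unique unrelated male founder, recorded
                    # in the truth only (open pollination hides him)
                    sire_count += 1
                    father = f"{prov}-sire{sire_count:05d}"
                rows.append((tid, dam, None, prov, fam, None))
                truth_rows.append((tid, father, selfed, site))
        for lot in range(config.n_bulk_lots):
            lot_name = f"lot{lot + 1:02d}"
            for t in range(config.trees_per_bulk_lot_per_site):
                tid = f"{lot_name}-{site}-{t + 1:03d}"
                founder(tid, "BULK", None, lot=lot_name, site=site)

    table = pd.DataFrame(rows, columns=["id", "mother", "father",
                                        "provenance", "family", "bulk_lot"])
    parentage = pd.DataFrame(truth_rows, columns=["id", "realized_father",
                                                  "selfed", "site"])
    return Pedigree(table), parentage.set_index("id")


def realized_pedigree(pedigree: Pedigree, parentage: pd.DataFrame) -> Pedigree:
    """Pedigree with realized fathers filled in (truth view).

    Sires that exist only in the parentage truth are materialised as
    unrelated founder records of their provenance.
    """
    t = pedigree.table.copy()
    fathers = parentage["realized_father"]
    known = set(t["id"])
    prov_of = dict(zip(t["id"], t["provenance"]))
    t["father"] = [fathers.get(i) for i in t["id"]]
    sire_rows = []
    seen = set()
    for child, father in zip(t["id"], t["father"]):
        if father is not None and father not in known and father not in seen:
            seen.add(father)
            sire_rows.append((father, None, None, prov_of.get(child),
                              None, None))
    if sire_rows:
        sires = pd.DataFrame(sire_rows, columns=list(t.columns))
        t = pd.concat([sires, t], ignore_index=True)
    return Pedigree(t)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(pedigree: Pedigree, config: SimConfig, seed=None,
                       parentage: pd.DataFrame | None = None
                       ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Gene-drop biallelic genotypes through the (realized) pedigree.

    Founder genotypes are Hardy-Weinberg draws at Beta-sampled allele
    frequencies; provenances are differentiated by Balding-Nichols drift at
    the configured F_st, so genotyped provenances cluster the way real seed
    sources do.  Each offspring receives one maternal gamete and one paternal
    gamete (maternal again when selfed).  Returns the 0/1/2 genotype matrix
    over every pedigree id plus the ancestral founder allele frequencies.
    """
    rng = _rng(config.seed + 1 if seed is None else seed)
    m = config.n_snps
    a, b = config.founder_maf_distribution
    freqs = rng.beta(a, b, size=m)

    fst = config.provenance_fst
    prov_freqs: dict[str, np.ndarray] = {}

    def freq_of(provenance: str | None) -> np.ndarray:
        if provenance is None or fst <= 0.0:
            return freqs
        if provenance not in prov_freqs:
            p = np.clip(freqs, 1e-6, 1.0 - 1e-6)
            shape = (1.0 - fst) / fst
            prov_freqs[provenance] = rng.beta(p * shape, (1.0 - p) * shape)
        return prov_freqs[provenance]

    ids = pedigree.ids
    prov_of = dict(zip(ids, pedigree.provenance))
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    hapA = np.zeros((n, m), dtype=np.uint8)
    hapB = np.zeros((n, m), dtype=np.uint8)
    m_idx, _ = pedigree.parent_indices()
    # realized fathers: id -> haplotype source (lazily created sires get
    # fresh founder haplotypes)
    father_of: dict[int, str | None] = {}
    selfed_of = np.zeros(n, dtype=bool)
    if parentage is not None:
        rf = parentage["realized_father"]
        sf = parentage["selfed"]
        for i, k in pos.items():
            father_of[k] = rf.get(i)
            selfed_of[k] = bool(sf.get(i, False))
    sire_haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    lot_of = dict(zip(ids, pedigree.bulk_lot))
    for k in range(n):
        mo = m_idx[k]
        if mo < 0:
            # bulk lots drift independently (distinct seed sources); family
            # founders drift with their provenance
            key = lot_of.get(ids[k]) or prov_of.get(ids[k])
            fk = freq_of(key)
            hapA[k] = rng.random(m) < fk
            hapB[k] = rng.random(m) < fk
            continue
        pick = rng.integers(0, 2, size=m).astype(bool)
        maternal = np.where(pick, hapA[mo], hapB[mo])
        father = father_of.get(k)
        selfed = selfed_of[k] if parentage is not None \
            else bool(rng.random() < config.selfing_rate)
        pick2 = rng.integers(0, 2, size=m).astype(bool)
        if selfed or father == ids[mo]:
            paternal = np.where(pick2, hapA[mo], hapB[mo])
        elif father is not None and father in pos:
            fa = pos[father]
            paternal = np.where(pick2, hapA[fa], hapB[fa])
        else:
            # unique unrelated sire from the same provenance's pollen pool
            key = father if father is not None else f"_anon{k}"
            if key not in sire_haps:
                fk = freq_of(prov_of.get(ids[k]))
                sire_haps[key] = (
                    (rng.random(m) < fk).astype(np.uint8),
                    (rng.random(m) < fk).astype(np.uint8),
                )
            sa, sb = sire_haps[key]
            paternal = np.where(pick2, sa, sb)
        hapA[k] = maternal
        hapB[k] = paternal

    calls = (hapA.astype(np.int16) + hapB.astype(np.int16)).astype(np.int8)
    snp_ids = [f"snp{j + 1:05d}" for j in range(m)]
    return GenotypeMatrix(list(ids), snp_ids, calls), freqs


def _marker_breeding_values(calls: np.ndarray, freqs: np.ndarray,
                            sigma_a: np.ndarray, rng: np.random.Generator,
                            pedigree: Pedigree | None = None) -> np.ndarray:
    """Genic breeding values: per-site SNP effects correlated across sites,
    scaled so the within-provenance founder BV variance equals the
    configured additive variance (the variance the mixed model estimates
    once provenance means are in the fixed part)."""
    m = calls.shape[1]
    k = sigma_a.shape[0]
    denom = 2.0 * float(np.sum(freqs * (1.0 - freqs)))
    if pedigree is not None:
        # realized within-provenance heterozygosity of the family founders
        t = pedigree.table
        dams = t["mother"].isna() & t["father"].isna() & t["family"].notna()
        pos = {i: j for j, i in enumerate(pedigree.ids)}
        cs = []
        for _, grp in t[dams].groupby("provenance"):
            if len(grp) < 5:
                continue
            rows = [pos[i] for i in grp["id"]]
            p_hat = calls[rows].mean(axis=0) / 2.0
            cs.append(2.0 * float(np.sum(p_hat * (1.0 - p_hat))))
        if cs:
            denom = float(np.mean(cs))
    if denom <= 0:
        raise ConfigError("founder allele frequencies are degenerate")
    L = np.linalg.cholesky(sigma_a / denom + 1e-12 * np.eye(k))
    effects = rng.standard_normal((m, k)) @ L.T
    W = calls.astype(float) - 2.0 * freqs
    return W @ effects  # n x k


def _pedigree_breeding_values(pedigree: Pedigree, parentage: pd.DataFrame,
                              sigma_a: np.ndarray, rng: np.random.Generator
                              ) -> np.ndarray:
    """Recursive Mendelian-sampling breeding values from the realized pedigree."""
    ids = pedigree.ids
    pos = {i: k for k, i in enumerate(ids)}
    n, k = len(ids), sigma_a.shape[0]
    L = np.linalg.cholesky(sigma_a + 1e-12 * np.eye(k))
    bv = np.zeros((n, k))
    F = np.zeros(n)
    m_idx, _ = pedigree.parent_indices()
    rf = parentage["realized_father"]
    sires: dict[str, tuple[np.ndarray, float]] = {}
    for i in range(n):
        mo = m_idx[i]
        if mo < 0:
            bv[i] = L @ rng.standard_normal(k)
            continue
        father = rf.get(ids[i])
        if father == ids[mo]:  # selfed
            mean = bv[mo]
            ms_scale = 0.5 * (1.0 - F[mo])
            F[i] = 0.5 * (1.0 + F[mo])
        else:
            key = father if father is not None else f"_anon{i}"
            if key not in sires:
                sires[key] = (L @ rng.standard_normal(k), 0.0)
            bv_f, F_f = sires[key]
            mean = 0.5 * (bv[mo] + bv_f)
            ms_scale = 0.25 * (2.0 - F[mo] - F_f)
            F[i] = 0.0
        bv[i] = mean + np.sqrt(max(ms_scale, 0.0)) * (L @ rng.standard_normal(k))
    return bv


# ---------------------------------------------------------------------------
# Trials
# ---------------------------------------------------------------------------

def simulate_trials(pedigree: Pedigree, config: SimConfig, seed=None,
                    parentage: pd.DataFrame | None = None,
                    breeding_values: np.ndarray | None = None,
                    founder_freqs: np.ndarray | None = None,
                    genotypes: GenotypeMatrix | None = None,
                    ) -> tuple[pd.DataFrame, SimTruth]:
    """Phenotype the orchard on its grids.

    phenotype = site mean + provenance shift + block effect + breeding value
    + bulk-lot effect (bulk trees) + AR1xAR1 spatial field + nugget noise,
    in decimetres.  Breeding values follow the configured mechanism unless
    supplied.
    """
    config.validate()
    rng = _rng(config.seed + 2 if seed is None else seed)
    if parentage is None:
        raise ConfigError("simulate_trials needs the parentage truth from "
                          "simulate_pedigree")
    sigma_a = config.sigma_a()
    sites = config.site_names
    k = len(sites)

    if breeding_values is None:
        if config.bv_mechanism == "marker":
            if genotypes is None or founder_freqs is None:
                raise ConfigError("marker breeding values need genotypes and "
                                  "founder frequencies")
            breeding_values = _marker_breeding_values(
                genotypes.calls, founder_freqs, sigma_a, rng,
                pedigree=pedigree)
        else:
            breeding_values = _pedigree_breeding_values(
                pedigree, parentage, sigma_a, rng)
    bv = pd.DataFrame(breeding_values, index=pedigree.ids, columns=sites)

    # bulk-lot effects, correlated across sites
    lots = sorted(set(pedigree.bulk_lot.dropna()))
    lot_fx = None
    if lots:
        Lb = np.linalg.cholesky(config.sigma_b() + 1e-12 * np.eye(k))
        lot_fx = pd.DataFrame(
            rng.standard_normal((len(lots), k)) @ Lb.T, index=lots,
            columns=sites)

    site_of = parentage["site"]
    prov = dict(zip(pedigree.ids, pedigree.provenance))
    lot_of = dict(zip(pedigree.ids, pedigree.bulk_lot))
    fam_of = dict(zip(pedigree.ids, pedigree.family))

    records = []
    surfaces = {}
    block_truth = {}
    for si, site in enumerate(sites):
        lay = config.site_layouts[site]
        vc = config.variance_truth[site]
        tree_ids = [i for i in pedigree.ids if site_of.get(i) == site]
        # spatial field on the full grid
        Lr = np.linalg.cholesky(_ar1(config.rho_row, lay.rows)
                                + 1e-10 * np.eye(lay.rows))
        Lc = np.linalg.cholesky(_ar1(config.rho_col, lay.cols)
                                + 1e-10 * np.eye(lay.cols))
        field_z = rng.standard_normal((lay.rows, lay.cols))
        surface = np.sqrt(vc.sigma2_xi) * (Lr @ field_z @ Lc.T)
        surfaces[site] = surface
        # blocks: contiguous row-major bands of cells
        cells = [(r + 1, c + 1) for r in range(lay.rows) for c in range(lay.cols)]
        chunks = np.array_split(np.arange(len(cells)), lay.blocks)
        block_of_cell = np.empty(len(cells), dtype=int)
        for bi, ch in enumerate(chunks):
            block_of_cell[ch] = bi
        b_fx = rng.normal(0.0, config.block_effect_sd, size=lay.blocks)
        block_truth[site] = {f"B{bi + 1:02d}": b_fx[bi] for bi in range(lay.blocks)}
        chosen = rng.permutation(len(cells))[: len(tree_ids)]
        nugget = rng.normal(0.0, np.sqrt(vc.sigma2_eta), size=len(tree_ids))
        for t, (tid, cell_idx) in enumerate(zip(tree_ids, chosen)):
            r, c = cells[cell_idx]
            bi = block_of_cell[cell_idx]
            p = prov[tid]
            lot = lot_of[tid]
            y = (config.site_means[site]
                 + config.provenance_effects.get(p, 0.0)
                 + b_fx[bi]
                 + bv.at[tid, site]
                 + (lot_fx.at[lot, site] if lot is not None else 0.0)
                 + surface[r - 1, c - 1]
                 + nugget[t])
            records.append((tid, site, f"B{bi + 1:02d}", r, c, p,
                            fam_of[tid], lot, y))
    trial = pd.DataFrame(records, columns=["id", "site", "block", "row",
                                           "col", "provenance", "family",
                                           "bulk_lot", "height"])
    truth = SimTruth(
        true_breeding_values=bv,
        spatial_surfaces=surfaces,
        realized_pedigree=realized_pedigree(pedigree, parentage),
        founder_allele_frequencies=founder_freqs
        if founder_freqs is not None else np.array([]),
        parentage=parentage,
        block_effects=block_truth,
        lot_effects=lot_fx,
    )
    return trial, truth


def _ar1(rho: float, n: int) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :]).astype(float)


# ---------------------------------------------------------------------------
# Missingness / QC fodder
# ---------------------------------------------------------------------------

def inject_missing(genotypes: GenotypeMatrix, config: SimConfig, seed=None
                   ) -> GenotypeMatrix:
    """Apply per-locus and per-individual missingness and force a subset of
    loci near-monomorphic (to exercise the heterozygosity filter)."""
    rng = _rng(config.seed + 3 if seed is None else seed)
    n, m = genotypes.calls.shape
    calls = genotypes.calls.copy()

    locus_rate = np.full(m, config.missing_locus_rate)
    n_bad_loci = int(round(config.bad_locus_fraction * m))
    if n_bad_loci:
        bad = rng.choice(m, size=n_bad_loci, replace=False)
        locus_rate[bad] = rng.uniform(0.2, 0.5, size=n_bad_loci)
    ind_rate = np.full(n, config.missing_individual_rate)
    n_bad_ind = int(round(config.bad_individual_fraction * n))
    if n_bad_ind:
        bad = rng.choice(n, size=n_bad_ind, replace=False)
        ind_rate[bad] = rng.uniform(0.2, 0.5, size=n_bad_ind)

    miss = rng.random((n, m)) < locus_rate[None, :]
    miss |= rng.random((n, m)) < ind_rate[:, None]

    n_low = int(round(config.low_het_locus_fraction * m))
    if n_low:
        low = rng.choice(m, size=n_low, replace=False)
        calls[:, low] = 0
        if n >= 2:  # leave a single heterozygote so the locus is not trivially fixed
            het_row = rng.integers(0, n, size=n_low)
            calls[het_row, low] = 1
    calls = np.where(miss, MISSING, calls).astype(genotypes.calls.dtype)
    return GenotypeMatrix(list(genotypes.ids), list(genotypes.snp_ids), calls)


# ---------------------------------------------------------------------------
# Planted pedigree errors and the one-call orchard
# ---------------------------------------------------------------------------

def plant_pedigree_errors(pedigree: Pedigree, genotypes: GenotypeMatrix,
                          genotyped_ids: list[str], founder_freqs: np.ndarray,
                          n_swaps: int = 0, n_intruders: int = 0, seed=0
                          ) -> tuple[Pedigree, GenotypeMatrix, dict]:
    """Plant maternity-record swaps and unrelated intruders among genotyped trees.

    Swapped trees keep their true genotypes but are recorded under a wrong
    family that itself has genotyped members (a record error invisible to
    the genotyped panel cannot be detected, let alone corrected); intruders
    keep their records but get fresh unrelated genotypes.  Returns the
    corrupted pedigree, corrupted genotypes, and the truth.
    """
    rng = _rng(seed)
    fam = dict(zip(pedigree.ids, pedigree.family))
    candidates = [i for i in genotyped_ids if fam.get(i) is not None]
    if n_swaps + n_intruders > len(candidates):
        raise ConfigError("not enough genotyped family trees to corrupt")
    chosen = rng.choice(len(candidates), size=n_swaps + n_intruders,
                        replace=False)
    swap_ids = [candidates[i] for i in chosen[:n_swaps]]
    intruder_ids = [candidates[i] for i in chosen[n_swaps:]]

    counts: dict[str, int] = {}
    for i in candidates:
        counts[fam[i]] = counts.get(fam[i], 0) + 1
    families = sorted(f for f, c in counts.items() if c >= 2)
    t = pedigree.table.copy().set_index("id", drop=False)
    dams = {f: t.loc[t["family"] == f].query("mother.isna()")["id"].iloc[0]
            for f in families}
    swaps = []
    for i in swap_ids:
        true_fam = fam[i]
        others = [f for f in families if f != true_fam]
        wrong = others[int(rng.integers(0, len(others)))]
        t.at[i, "family"] = wrong
        t.at[i, "mother"] = dams[wrong]
        swaps.append({"id": i, "true_family": true_fam,
                      "recorded_family": wrong})

    calls = genotypes.calls.copy()
    gpos = {gid: k for k, gid in enumerate(genotypes.ids)}
    m = calls.shape[1]
    for i in intruder_ids:
        hap1 = rng.random(m) < founder_freqs
        hap2 = rng.random(m) < founder_freqs
        calls[gpos[i]] = (hap1.astype(np.int16)
                          + hap2.astype(np.int16)).astype(calls.dtype)

    corrupted = Pedigree(t.reset_index(drop=True))
    return corrupted, GenotypeMatrix(list(genotypes.ids),
                                     list(genotypes.snp_ids), calls), \
        {"swaps": swaps, "intruders": intruder_ids}


@dataclass
class OrchardData:
    """One simulated orchard: inputs as the analysis would see them, plus truth."""

    config: SimConfig
    pedigree: Pedigree  # observed (mothers only)
    trial: pd.DataFrame
    genotypes: GenotypeMatrix  # genotyped subset, with injected missingness
    genotyped_ids: list[str]
    truth: SimTruth


def simulate_orchard(config: SimConfig, seed=None) -> OrchardData:
    """Simulate pedigree, genotypes, trials and the genotyped panel in one call.

    Genotyping mirrors partial genotyping of one site's material: a random
    subset of families (``genotyped_families_fraction``) contributes
    genotypes, and within each selected family a random
    ``genotyped_fraction`` of its trees at the genotyped site is typed.
    Bulk trees are never genotyped.
    """
    base = config.seed if seed is None else seed
    rng = _rng(base)
    ped, parentage = simulate_pedigree(config, seed=rng.integers(2 ** 31))
    geno_all, freqs = simulate_genotypes(ped, config,
                                         seed=rng.integers(2 ** 31),
                                         parentage=parentage)
    trial, truth = simulate_trials(ped, config, seed=rng.integers(2 ** 31),
                                   parentage=parentage, founder_freqs=freqs,
                                   genotypes=geno_all)
    gsite = config.genotyped_site or config.site_names[0]
    fam_trees = trial[(trial["site"] == gsite) & trial["family"].notna()]
    families = sorted(fam_trees["family"].unique())
    n_fam = max(1, int(round(config.genotyped_families_fraction
                             * len(families))))
    sel_fams = set(np.array(families)[
        rng.choice(len(families), size=n_fam, replace=False)])
    chosen: list[str] = []
    for fam, grp in fam_trees.groupby("family"):
        if fam not in sel_fams:
            continue
        ids = list(grp["id"])
        n_take = int(round(config.genotyped_fraction * len(ids)))
        if n_take:
            take = rng.choice(len(ids), size=n_take, replace=False)
            chosen.extend(ids[j] for j in take)
    chosen = sorted(chosen)
    panel = geno_all.select_individuals(chosen)
    panel = inject_missing(panel, config, seed=rng.integers(2 ** 31))
    return OrchardData(config=config, pedigree=ped, trial=trial,
                       genotypes=panel, genotyped_ids=chosen, truth=truth)
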