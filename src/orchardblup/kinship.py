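"""Relationship matrices: pedigree A, partial-selfing A2, VanRaden G, blended Gw, single-step H.

The numerator relationship matrix A is twice the coancestry matrix, built by
the tabular method.  The partial-selfing variant A2 treats every
open-pollinated record (known mother d, unknown father) as selfed with
probability s, giving the mixture recursion

    a_ij = 0.5 * (1 + s) * a_dj        (j preceding i)
    a_ii = 1 + 0.5 * s * a_dd

which reduces to the ordinary single-parent rule at s = 0.  The genomic
matrix follows VanRaden: W = M - 2p, G = W W' / (2 * sum_i p_i (1 - p_i)),
with missing calls mean-imputed as 2 p_i from the current (post-QC) allele
frequencies.  The single-step H matrix merges A (or A2) for non-genotyped
individuals with the blended Gw = w G + (1-w) A22 for genotyped ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

from .pedigree import Pedigree, PedigreeError
from .qc import GenotypeMatrix, MISSING


class KinshipError(ValueError):
    pass


@dataclass
class RelationshipMatrix:
    """Symmetric additive relationship matrix over an ordered id set."""

    ids: list[str]
    values: np.ndarray
    flavour: str  # one of A, A2, G, Gw, H, H2

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise KinshipError(f"matrix shape {self.values.shape} != ({n},{n})")
        if len(set(self.ids)) != n:
            raise KinshipError("duplicate ids in relationship matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise KinshipError("relationship matrix is not symmetric")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def index_of(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[i] for i in ids], dtype=int)
        except KeyError as e:  # pragma: no cover
            raise KinshipError(f"id {e.args[0]!r} absent from matrix") from e

    def subset(self, ids) -> "RelationshipMatrix":
        pos = self.index_of(ids)
        return RelationshipMatrix(list(ids), self.values[np.ix_(pos, pos)],
                                  self.flavour)

    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.values), index=self.ids)

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_triplet_frame(self, lower: bool = True) -> pd.DataFrame:
        r, c = np.tril_indices(len(self.ids)) if lower else \
            np.unravel_index(np.arange(len(self.ids) ** 2),
                             self.values.shape)
        return pd.DataFrame({
            "id1": [self.ids[i] for i in r],
            "id2": [self.ids[j] for j in c],
            "value": self.values[r, c],
        })


@dataclass
class PedigreeCorrectionReport:
    """Outcome of genomic validation of recorded maternity."""

    min_within: float
    min_reassign: float
    reassigned: list[tuple[str, str, str]] = field(default_factory=list)  # id, old fam, new fam
    removed: list[tuple[str, str]] = field(default_factory=list)  # id, reason
    skipped_singletons: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (f"pedigree correction: {len(self.reassigned)} reassigned, "
                f"{len(self.removed)} removed, "
                f"{len(self.skipped_singletons)} singletons skipped "
                f"(min_within={self.min_within}, min_reassign={self.min_reassign})")


# ---------------------------------------------------------------------------
# Pedigree-based matrices (tabular method)
# ---------------------------------------------------------------------------

def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method."""
    return _tabular(pedigree, selfing_rate=0.0, flavour="A")


def build_A_selfing(pedigree: Pedigree, s: float) -> RelationshipMatrix:
    """Numerator relationship matrix assuming unknown-sire offspring are
    selfed with probability `s` (partial-selfing mixture recursion)."""
    if not 0.0 <= s <= 1.0:
        raise KinshipError("selfing rate must be in [0, 1]")
    return _tabular(pedigree, selfing_rate=s, flavour="A2" if s > 0 else "A")


def _tabular(pedigree: Pedigree, selfing_rate: float, flavour: str) -> RelationshipMatrix:
    n = len(pedigree)
    m_idx, f_idx = pedigree.parent_indices()
    A = np.zeros((n, n))
    s = selfing_rate
    for i in range(n):
        m, f = m_idx[i], f_idx[i]
        if m >= 0 and f >= 0:
            if m >= i or f >= i:  # defensive: Pedigree guarantees topo order
                raise PedigreeError(f"record {pedigree.ids[i]!r} precedes a parent")
            row = 0.5 * (A[m, :i] + A[f, :i])
            diag = 1.0 + 0.5 * A[m, f]
        elif m >= 0 or f >= 0:
            p = m if m >= 0 else f
            row = 0.5 * (1.0 + s) * A[p, :i]
            diag = 1.0 + 0.5 * s * A[p, p]
        else:
            row = None
            diag = 1.0
        if row is not None:
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = diag
    return RelationshipMatrix(pedigree.ids, A, flavour)


# ---------------------------------------------------------------------------
# Genomic matrices
# ---------------------------------------------------------------------------

def build_G(g: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from 0/1/2 dosages.

    Allele frequencies are taken from the supplied (post-QC) genotypes;
    missing calls are imputed as twice the allele frequency, so they carry
    zero weight after centering.  Monomorphic loci contribute nothing to
    numerator or denominator.
    """
    calls = g.calls.astype(float)
    miss = g.missing_mask()
    calls[miss] = np.nan
    p = np.nanmean(calls, axis=0) / 2.0
    if np.isnan(p).any():
        # loci with no calls at all: treat as monomorphic, zero weight
        p = np.where(np.isnan(p), 0.0, p)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise KinshipError("all loci monomorphic: G undefined")
    W = calls - 2.0 * p
    W[miss.nonzero()] = 0.0  # imputed call 2p centres to zero
    W[:, (p <= 0.0) | (p >= 1.0)] = 0.0
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(list(g.ids), G, "G")


def blend_G(g_mat: RelationshipMatrix, a22: RelationshipMatrix,
            weight: float = 0.90) -> RelationshipMatrix:
    """Gw = weight * G + (1 - weight) * A22 (elementwise, same id order)."""
    if not 0.0 <= weight <= 1.0:
        raise KinshipError("blend weight must be in [0, 1]")
    if list(g_mat.ids) != list(a22.ids):
        raise KinshipError("blend_G: id order of G and A22 differ")
    vals = weight * g_mat.values + (1.0 - weight) * a22.values
    return RelationshipMatrix(list(g_mat.ids), vals, "Gw")


def build_H(a: RelationshipMatrix, gw: RelationshipMatrix,
            genotyped_ids) -> RelationshipMatrix:
    """Single-step H matrix combining pedigree A (or A2) with blended Gw.

    H11 = A11 + A12 A22^-1 (Gw - A22) A22^-1 A21,  H12 = A12 A22^-1 Gw,
    H22 = Gw.  Output keeps the id order of `a`.  Flavour is H when `a` is
    the plain A matrix and H2 when it is the selfing-adjusted A2.
    """
    genotyped_ids = list(genotyped_ids)
    flavour = "H2" if a.flavour == "A2" else "H"
    if len(genotyped_ids) == 0:
        return RelationshipMatrix(list(a.ids), a.values.copy(), flavour)
    if list(gw.ids) != genotyped_ids:
        raise KinshipError("build_H: gw must be ordered exactly as genotyped_ids")
    gpos = a.index_of(genotyped_ids)
    all_pos = np.arange(len(a.ids))
    npos = np.setdiff1d(all_pos, gpos)
    if len(npos) == 0:
        return RelationshipMatrix(genotyped_ids, gw.values.copy(), flavour)

    A = a.values
    A11 = A[np.ix_(npos, npos)]
    A12 = A[np.ix_(npos, gpos)]
    A22 = A[np.ix_(gpos, gpos)]
    try:
        c = cho_factor(A22)
    except np.linalg.LinAlgError as e:
        cond = np.linalg.cond(A22)
        raise KinshipError(
            f"A22 not positive definite (condition number {cond:.3g}); "
            "cannot form H"
        ) from e
    # T = A12 A22^-1  (solve on the right)
    T = cho_solve(c, A12.T).T
    Gw = gw.values
    H11 = A11 + T @ (Gw - A22) @ T.T
    H12 = T @ Gw

    n = len(a.ids)
    H = np.zeros((n, n))
    H[np.ix_(npos, npos)] = H11
    H[np.ix_(npos, gpos)] = H12
    H[np.ix_(gpos, npos)] = H12.T
    H[np.ix_(gpos, gpos)] = Gw
    return RelationshipMatrix(list(a.ids), 0.5 * (H + H.T), flavour)


def inbreeding_coefficients(m: RelationshipMatrix) -> pd.Series:
    """F_i = diagonal - 1, for every id."""
    return pd.Series(np.diag(m.values) - 1.0, index=m.ids, name="F")


# ---------------------------------------------------------------------------
# Selfing-rate estimation and pedigree correction
# ---------------------------------------------------------------------------

def pairwise_relatedness(g: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden-style relatedness with pairwise-complete normalisation.

    Each pair (i, j) is scaled by 2 sum p_l (1-p_l) over the loci observed in
    BOTH individuals, so missing calls do not deflate relatedness the way
    mean imputation does.  Used for estimation of mating-system parameters;
    `build_G` remains the covariance matrix for model fitting.
    """
    calls = g.calls.astype(float)
    miss = g.missing_mask()
    calls[miss] = np.nan
    p = np.nanmean(calls, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    q = 2.0 * p * (1.0 - p)
    W = calls - 2.0 * p
    W[miss.nonzero()] = 0.0
    M = (~miss).astype(float)
    num = W @ W.T
    den = (M * q) @ M.T
    if not np.any(den > 0):
        raise KinshipError("no co-observed polymorphic loci")
    R = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return RelationshipMatrix(list(g.ids), 0.5 * (R + R.T), "G")


def pedigree_scale_relatedness(g: GenotypeMatrix,
                               pedigree: Pedigree) -> RelationshipMatrix:
    """Pairwise-complete relatedness re-anchored to the pedigree scale.

    Panel-frequency centring shifts relatedness baselines: with
    differentiated provenances, 'unrelated' same-provenance pairs sit above
    zero and cross-provenance pairs below.  For expected-vs-observed
    pedigree validation we subtract, per provenance pair, the mean
    relatedness of pairs the pedigree calls unrelated (different families),
    so family thresholds retain their textbook meaning (half sib ~0.25).
    """
    R = pairwise_relatedness(g)
    fam = dict(zip(pedigree.ids, pedigree.family))
    prov = dict(zip(pedigree.ids, pedigree.provenance))
    fams = [fam.get(i) for i in R.ids]
    provs = [prov.get(i) for i in R.ids]
    n = len(R.ids)
    V = R.values.copy()
    sums: dict[tuple, list] = {}
    for a in range(n):
        for b in range(a + 1, n):
            key = tuple(sorted((str(provs[a]), str(provs[b]))))
            if fams[a] is None or fams[b] is None or fams[a] != fams[b]:
                sums.setdefault(key, []).append(V[a, b])
    base = {k: float(np.mean(v)) for k, v in sums.items() if v}
    for a in range(n):
        for b in range(a + 1, n):
            key = tuple(sorted((str(provs[a]), str(provs[b]))))
            shift = base.get(key, 0.0)
            V[a, b] -= shift
            V[b, a] -= shift
    return RelationshipMatrix(list(R.ids), V, "G")


def estimate_selfing_rate(g_mat: RelationshipMatrix | GenotypeMatrix,
                          pedigree: Pedigree) -> float:
    """Estimate the selfing rate from within-family genomic relatedness.

    Under partial selfing at rate s, the expected relatedness of two
    maternal half-sibs is 0.25 (1 + s)^2.  Because marker relatedness is
    centred on the genotyped panel's own allele frequencies, the raw
    within-family mean is shifted when the panel is structured; the shift is
    removed by subtracting the mean relatedness of same-provenance,
    different-family pairs (expected 0 on the pedigree scale).
    s_hat = 2 sqrt(within - baseline) - 1, clamped to [0, 1].
    """
    if isinstance(g_mat, GenotypeMatrix):
        g_mat = pairwise_relatedness(g_mat)
    fam = dict(zip(pedigree.ids, pedigree.family))
    prov = dict(zip(pedigree.ids, pedigree.provenance))
    has_mother = dict(zip(pedigree.ids, pedigree.table["mother"].notna()))
    # only open-pollinated offspring count as family members (a genotyped
    # dam is not her own half-sib)
    idx_fam: list = [fam.get(i) if has_mother.get(i, False) else None
                     for i in g_mat.ids]
    idx_prov: list = [prov.get(i) for i in g_mat.ids]
    n = len(g_mat.ids)
    within, between = [], []
    V = g_mat.values
    for a in range(n):
        if idx_fam[a] is None:
            continue
        for b in range(a + 1, n):
            if idx_fam[b] is None:
                continue
            if idx_fam[a] == idx_fam[b]:
                within.append(V[a, b])
            elif idx_prov[a] == idx_prov[b]:
                between.append(V[a, b])
    if not within:
        raise KinshipError("no within-family genotyped pairs: cannot estimate s")
    baseline = float(np.mean(between)) if between else 0.0
    mean_rel = float(np.mean(within)) - baseline
    if mean_rel <= 0.0:
        return 0.0
    s = 2.0 * np.sqrt(mean_rel) - 1.0
    return float(min(max(s, 0.0), 1.0))


def correct_pedigree(
    pedigree: Pedigree,
    g_mat: RelationshipMatrix,
    min_within: float = 0.15,
    min_reassign: float = 0.20,
    drop_removed: bool = True,
) -> tuple[Pedigree, PedigreeCorrectionReport]:
    """Validate recorded maternity against genomic relatedness.

    A genotyped tree whose mean relatedness to its recorded maternal sibs
    falls below `min_within` is flagged; it is reassigned to the family (any
    provenance) maximising its mean relatedness if that maximum reaches
    `min_reassign` (both the family label and the maternal link are
    rewritten), otherwise removed.  Bulk-lot trees (no family) and trees
    with no genotyped sibs are skipped.  With ``drop_removed=False`` the
    conflicting trees stay in the returned pedigree (callers typically drop
    them from the genotyped panel instead).
    """
    report = PedigreeCorrectionReport(min_within=min_within,
                                      min_reassign=min_reassign)
    fam = dict(zip(pedigree.ids, pedigree.family))
    gids = list(g_mat.ids)
    gset = {i: k for k, i in enumerate(gids)}
    fam_members: dict[str, list[int]] = {}
    for i, k in gset.items():
        f = fam.get(i)
        if f is not None:
            fam_members.setdefault(f, []).append(k)

    V = g_mat.values
    reassign_ids: list[str] = []
    reassign_fams: list[str] = []
    remove_ids: list[str] = []
    for i, k in gset.items():
        f = fam.get(i)
        if f is None:
            continue  # bulk tree, no recorded family to check
        sibs = [j for j in fam_members.get(f, []) if j != k]
        if not sibs:
            report.skipped_singletons.append(i)
            continue
        mean_within = float(np.mean(V[k, sibs]))
        if mean_within >= min_within:
            continue
        best_fam, best_val = None, -np.inf
        for other, members in fam_members.items():
            others = [j for j in members if j != k]
            if not others:
                continue
            val = float(np.mean(V[k, others]))
            if val > best_val:
                best_fam, best_val = other, val
        if best_fam is not None and best_val >= min_reassign:
            reassign_ids.append(i)
            reassign_fams.append(best_fam)
            report.reassigned.append((i, f, best_fam))
        else:
            remove_ids.append(i)
            report.removed.append((i, f"max mean family relatedness "
                                      f"{best_val:.3f} < {min_reassign}"))
    corrected = pedigree
    if reassign_ids:
        # maternal link follows the family: the new mother is the dam shared
        # by the target family's recorded members
        t = pedigree.table
        dam_of_family: dict[str, str] = {}
        for f in set(reassign_fams):
            mothers = t.loc[t["family"] == f, "mother"].dropna()
            if len(mothers):
                dam_of_family[f] = mothers.mode().iloc[0]
        new_mothers = [dam_of_family.get(f) for f in reassign_fams]
        corrected = corrected.with_family(reassign_ids, reassign_fams,
                                          new_mothers)
    if remove_ids and drop_removed:
        corrected = corrected.drop(remove_ids)
    return corrected, report


def pca_of_G(g_mat: RelationshipMatrix, n_components: int = 2) -> pd.DataFrame:
    """Principal component scores of a relationship matrix.

    Eigendecomposition in descending eigenvalue order; scores are
    eigenvectors scaled by sqrt(eigenvalue), with a deterministic sign
    convention (the largest-magnitude loading of each component is positive).
    """
    if g_mat.values.shape[0] < 1:
        raise KinshipError("empty matrix")
    w, v = eigh(g_mat.values)
    order = np.argsort(w)[::-1][:n_components]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    for j in range(v.shape[1]):
        k = np.argmax(np.abs(v[:, j]))
        if v[k, j] < 0:
            v[:, j] = -v[:, j]
    scores = v * np.sqrt(w)
    cols = [f"PC{j + 1}" for j in range(scores.shape[1])]
    out = pd.DataFrame(scores, index=g_mat.ids, columns=cols)
    out.attrs["eigenvalues"] = w
    return out
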