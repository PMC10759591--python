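"""Derived genetic-evaluation statistics from fitted models.

Heritability, across-site genetic correlations, theoretical accuracy of
predicted breeding values, ssGBLUP efficiency, net breeding values and
expected genetic gain, candidate-ranking overlap and provenance composition,
the family-level inbreeding-height correlation, and k-fold cross-validated
predictive accuracy (PA) and prediction bias (PB).
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix
from .mme import FitResult, MixedModelError


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Variance-component statistics
# ---------------------------------------------------------------------------

def heritability(vc, sites: Optional[list[str]] = None) -> pd.Series:
    """Narrow-sense individual heritability h2 = s2_a / (s2_a + s2_e + s2_b).

    `vc` is either a FitResult from a multi-site fit or a dict with keys
    sigma2_a, sigma2_e and optionally sigma2_b (scalars or per-site arrays).
    """
    if isinstance(vc, FitResult):
        add = vc.varcomp["additive"]["variances"]
        res = vc.varcomp["residual"]["variances"]
        blk = vc.varcomp.get("bulk", {}).get("variances", np.zeros_like(add))
        sites = sites or vc.meta.get("sites") or vc.model.terms["additive"].group_names
    else:
        add = np.atleast_1d(np.asarray(vc["sigma2_a"], dtype=float))
        res = np.atleast_1d(np.asarray(vc["sigma2_e"], dtype=float))
        blk = np.atleast_1d(np.asarray(vc.get("sigma2_b", 0.0), dtype=float))
        blk = np.broadcast_to(blk, add.shape)
        sites = sites or [str(i) for i in range(len(add))]
    res = np.broadcast_to(np.atleast_1d(res), np.shape(add))
    denom = add + res + blk
    if np.any(denom <= 0):
        raise EvaluationError("zero phenotypic variance: heritability undefined")
    return pd.Series(add / denom, index=list(sites), name="h2")


def derived_se(fit: FitResult, func, n_draws: int = 2000,
               seed: int = 0) -> float:
    """Monte-Carlo delta-method SE of a derived variance-component statistic.

    Draws transformed parameters from the REML fit's average-information
    normal approximation, maps each draw through `func(varcomp_dict)` and
    returns the SD of the resulting values.
    """
    cov = fit.meta.get("vc_cov_trans")
    if cov is None:
        raise EvaluationError("fit carries no variance-component covariance")
    rng = np.random.default_rng(seed)
    cov = 0.5 * (cov + cov.T)
    w, V = np.linalg.eigh(cov)
    half = V * np.sqrt(np.clip(w, 0, None))
    draws = fit.theta + rng.standard_normal((n_draws, len(fit.theta))) @ half.T
    vals = []
    for t in draws:
        try:
            vals.append(func(fit.model._natural_all(t)))
        except Exception:
            continue
    if len(vals) < n_draws // 2:
        raise EvaluationError("derived statistic undefined on most draws")
    return float(np.nanstd(np.asarray(vals, dtype=float), ddof=1))


def genetic_correlations(sigma_a: np.ndarray,
                         sites: Optional[list[str]] = None) -> pd.DataFrame:
    """Additive genetic correlations r_a(i,j) = s_aij / sqrt(s2_aii * s2_ajj)."""
    S = np.asarray(sigma_a, dtype=float)
    d = np.diag(S)
    if np.any(d <= 0):
        raise EvaluationError("zero additive variance: correlation undefined")
    denom = np.sqrt(np.outer(d, d))
    R = S / denom
    sites = sites or [str(i) for i in range(len(d))]
    return pd.DataFrame(R, index=sites, columns=sites)


def theoretical_accuracy(pev, F, sigma2_a, tol: float = 1e-6) -> np.ndarray:
    """Acc_i = sqrt(1 - PEV_i / ((1 + F_i) * s2_a)), clipped to [0, 1].

    PEV above the additive variance bound beyond `tol` (relative) signals an
    inconsistent model/PEV pairing and raises.
    """
    pev = np.atleast_1d(np.asarray(pev, dtype=float))
    F = np.broadcast_to(np.atleast_1d(np.asarray(F, dtype=float)), pev.shape)
    bound = (1.0 + F) * float(sigma2_a) if np.isscalar(sigma2_a) else \
        (1.0 + F) * np.broadcast_to(np.atleast_1d(sigma2_a), pev.shape)
    if np.any(pev < -tol * np.maximum(bound, 1e-12)):
        raise EvaluationError("negative PEV supplied")
    if np.any(pev > bound * (1.0 + tol) + 1e-12):
        worst = float(np.max(pev / np.maximum(bound, 1e-300)))
        raise EvaluationError(
            f"PEV exceeds (1+F) sigma2_a by more than tolerance "
            f"(max ratio {worst:.6f})")
    ratio = np.clip(pev / np.maximum(bound, 1e-300), 0.0, 1.0)
    return np.sqrt(1.0 - ratio)


def accuracy_by_site(fit: FitResult, relmatrix: RelationshipMatrix
                     ) -> pd.DataFrame:
    """Per-site mean and SD of theoretical accuracy for the fit's predicted trees."""
    blup = fit.meta["blup"]
    sites = fit.meta.get("sites") or fit.model.terms["additive"].group_names
    sigma = fit.varcomp["additive"]["variances"]
    Fdiag = relmatrix.diagonal() - 1.0
    rows = []
    for g, site in enumerate(sites):
        sub = blup[blup["group"] == g] if "group" in blup else blup
        if sub.empty:
            continue
        F = Fdiag.reindex(sub["id"]).to_numpy()
        acc = theoretical_accuracy(sub["pev"].to_numpy(), F, sigma[g])
        rows.append({"site": site, "mean": float(np.mean(acc)),
                     "sd": float(np.std(acc, ddof=1)) if len(acc) > 1 else 0.0,
                     "n": len(acc)})
    return pd.DataFrame(rows).set_index("site")


def efficiency(acc_ablup: float, acc_ssgblup: float, acc_gblup: float) -> float:
    """Proportion of GBLUP's accuracy benefit over ABLUP captured by ssGBLUP:
    E = (ssGBLUP - ABLUP) / (GBLUP - ABLUP)."""
    denom = acc_gblup - acc_ablup
    if denom == 0:
        raise EvaluationError("GBLUP and ABLUP accuracies equal: E undefined")
    return (acc_ssgblup - acc_ablup) / denom


# ---------------------------------------------------------------------------
# Net breeding values, gain, rankings
# ---------------------------------------------------------------------------

def net_breeding_values(fit: FitResult) -> pd.DataFrame:
    """Net breeding value = provenance(-within-site) BLUE + predicted BV.

    Bulk trees add their lot-effect BLUP on top of their (bulk) cell estimate
    since the lot, not the provenance, is their group-mean term.
    """
    data = fit.meta.get("data")
    blup = fit.meta["blup"]
    if data is None:
        raise EvaluationError("fit carries no data frame; "
                              "use the fit_multi_site wrapper")
    cells = dict(zip(fit.fixed_names, fit.beta))
    merged = blup.merge(
        data[["id", "site", "provenance", "bulk_lot"]], on="id", how="left",
        suffixes=("", "_d"))
    if "site" not in merged or merged["site"].isna().any():
        raise EvaluationError("prediction frame and data frame do not align")
    key = merged["site"].astype(str) + ":" + merged["provenance"].astype(str)
    blue = key.map(cells)
    if blue.isna().any():
        raise EvaluationError("missing provenance BLUE for some cells")
    net = blue.to_numpy(dtype=float) + merged["blup"].to_numpy(dtype=float)
    bulk_blup = fit.meta.get("bulk_blup")
    if bulk_blup is not None and merged["bulk_lot"].notna().any():
        site_names = fit.meta.get("sites", [])
        code = {s: i for i, s in enumerate(site_names)}
        if "group" in bulk_blup:
            lot_val = {(r["bulk_lot"], r["group"]): r["blup"]
                       for _, r in bulk_blup.iterrows()}
            add = [lot_val.get((l, code.get(str(s), 0)), 0.0)
                   if pd.notna(l) else 0.0
                   for l, s in zip(merged["bulk_lot"], merged["site"])]
        else:
            lot_val = dict(zip(bulk_blup["bulk_lot"], bulk_blup["blup"]))
            add = [lot_val.get(l, 0.0) if pd.notna(l) else 0.0
                   for l in merged["bulk_lot"]]
        net = net + np.asarray(add)
    out = merged[["id", "site", "provenance", "bulk_lot"]].copy()
    out["net_bv"] = net
    return out


def _top_ids(values: pd.Series, fraction: float, end: str = "top") -> list:
    if not 0.0 < fraction <= 1.0:
        raise EvaluationError("selection fraction must be in (0, 1]")
    n_sel = max(1, int(round(fraction * len(values))))
    df = pd.DataFrame({"v": values.to_numpy(), "id": values.index})
    asc = end == "bottom"
    df = df.sort_values(["v", "id"], ascending=[asc, True], kind="mergesort")
    return list(df["id"].iloc[:n_sel])


def expected_gain(net: pd.Series, fraction: float = 0.10) -> float:
    """Percent increase of mean net breeding value in the selected top
    fraction over the whole population."""
    pop_mean = float(net.mean())
    if pop_mean <= 0:
        warnings.warn("population mean net value is not positive; "
                      "percent gain changes sign meaning")
    top = _top_ids(net, fraction, "top")
    return 100.0 * (float(net.loc[top].mean()) - pop_mean) / pop_mean


def ranking_overlap(bv1: pd.Series, bv2: pd.Series, fraction: float = 0.10,
                    end: str = "top") -> float:
    """Proportion of shared candidates in the selected fraction of two rankings."""
    common = bv1.index.intersection(bv2.index)
    if len(common) != len(bv1) or len(common) != len(bv2):
        raise EvaluationError("rankings must share the same id universe")
    s1 = set(_top_ids(bv1, fraction, end))
    s2 = set(_top_ids(bv2, fraction, end))
    return len(s1 & s2) / len(s1)


def provenance_composition(net: pd.DataFrame, fraction: float = 0.10,
                           end: str = "top") -> pd.Series:
    """Share of each provenance (bulk trees under their 'provenance' label)
    among the selected fraction; shares sum to 1."""
    values = pd.Series(net["net_bv"].to_numpy(), index=net["id"])
    sel = _top_ids(values, fraction, end)
    prov = pd.Series(net["provenance"].to_numpy(), index=net["id"])
    counts = prov.loc[sel].value_counts()
    return counts / counts.sum()


def family_inbreeding_height_correlation(F: pd.Series, heights: pd.Series,
                                         families: pd.Series) -> float:
    """Pearson correlation of family-mean inbreeding vs family-mean height."""
    df = pd.DataFrame({"F": F, "h": heights, "fam": families}).dropna()
    means = df.groupby("fam").mean()
    if len(means) < 3:
        raise EvaluationError("need at least 3 families with both quantities")
    tol_F = 1e-9 * (abs(means["F"].mean()) + 1.0)
    tol_h = 1e-9 * (abs(means["h"].mean()) + 1.0)
    if means["F"].std(ddof=0) <= tol_F or means["h"].std(ddof=0) <= tol_h:
        warnings.warn("degenerate family means; correlation undefined")
        return float("nan")
    return float(np.corrcoef(means["F"], means["h"])[0, 1])


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def make_folds(ids: list[str], k: int, scheme: str, rng,
               provenance: Optional[pd.Series] = None) -> list[list[str]]:
    """Partition `ids` into k validation folds (random, or stratified random
    within provenance)."""
    if scheme not in ("random", "within_provenance"):
        raise EvaluationError(f"unknown CV scheme {scheme!r}")
    if len(ids) < k:
        raise EvaluationError("fewer genotyped trees than folds")
    folds: list[list[str]] = [[] for _ in range(k)]
    if scheme == "random":
        perm = list(np.array(ids)[rng.permutation(len(ids))])
        for j, i in enumerate(perm):
            folds[j % k].append(i)
    else:
        if provenance is None:
            raise EvaluationError("within_provenance scheme needs provenance labels")
        for _, grp in pd.Series(ids).groupby(
                provenance.reindex(ids).to_numpy()):
            sub = list(grp)
            perm = list(np.array(sub)[rng.permutation(len(sub))])
            for j, i in enumerate(perm):
                folds[j % k].append(i)
    return [sorted(f) for f in folds if f]


def cross_validate(adjusted: pd.DataFrame,
                   model_specs: dict[str, tuple[RelationshipMatrix, np.ndarray]],
                   genotyped_ids: list[str],
                   reference_bv: pd.Series,
                   k: int = 10,
                   scheme: str = "random",
                   provenance: Optional[pd.Series] = None,
                   seed: int = 0) -> pd.DataFrame:
    """k-fold cross-validated predictive accuracy and bias per model.

    Folds partition the genotyped trees; per fold the validation trees'
    phenotypes are masked, each model's BLUP system is re-solved at its
    full-data variance components, and the validation breeding values are
    predicted.  PA is the fold's Pearson correlation between the reference
    (full-data ssGBLUP) breeding values and the predictions; PB is the slope
    of regressing the reference on the predictions (1 = unbiased).
    """
    from .models import fit_multi_site  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    folds = make_folds(list(genotyped_ids), k, scheme, rng, provenance)
    rows = []
    for fold_no, val_ids in enumerate(folds):
        val = set(val_ids)
        for name, (relmat, theta) in model_specs.items():
            known = set(relmat.ids)
            usable_val = [i for i in val_ids if i in known]
            if len(usable_val) < 3:
                warnings.warn(f"fold {fold_no}: <3 validation trees for {name}")
                continue
            data = adjusted[adjusted["id"].isin(known)].copy()
            data.loc[data["id"].isin(val), "y_adj"] = np.nan
            pred_frame = adjusted.loc[adjusted["id"].isin(usable_val),
                                      ["id", "site"]]
            try:
                fit = fit_multi_site(data, relmat, predict_for=pred_frame,
                                     fixed_theta=theta)
            except MixedModelError as e:
                warnings.warn(f"fold {fold_no}, model {name} skipped: {e}")
                continue
            pred = pd.Series(fit.meta["blup"]["blup"].to_numpy(),
                             index=fit.meta["blup"]["id"])
            ref = reference_bv.reindex(pred.index)
            ok = ref.notna() & pred.notna()
            ref, pred = ref[ok], pred[ok]
            if pred.std(ddof=0) == 0 or ref.std(ddof=0) == 0:
                warnings.warn(f"fold {fold_no}, model {name}: zero validation "
                              "variance; skipped")
                continue
            pa = float(np.corrcoef(ref, pred)[0, 1])
            pb = float(np.cov(ref, pred, ddof=1)[0, 1] / np.var(pred, ddof=1))
            rows.append({"fold": fold_no, "model": name, "scheme": scheme,
                         "pa": pa, "pb": pb, "n_val": int(ok.sum())})
    return pd.DataFrame(rows)


def summarize_cv(cv: pd.DataFrame) -> pd.DataFrame:
    """Per-model mean +- SD of PA and PB over folds."""
    return cv.groupby(["model", "scheme"]).agg(
        pa_mean=("pa", "mean"), pa_sd=("pa", "std"),
        pb_mean=("pb", "mean"), pb_sd=("pb", "std"),
        n_folds=("fold", "nunique"),
    ).reset_index()
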