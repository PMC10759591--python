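"""Trial-level model specifications: single-site spatial/design fits, multi-site fits, GBLUP.

`fit_single_site` fits the individual-tree model

    height = blocks + provenances (fixed) + additive (relmatrix-scaled)
             + bulk-lot effect (iid over lots, bulk trees only) + residual

with an iid residual (the a-priori design model) or a separable AR1(col) x
AR1(row) spatially dependent residual plus nugget (the a-posteriori spatial
model).

`fit_multi_site` fits the across-site model on stage-1 adjusted phenotypes:
fixed provenance-within-site cell means, additive effects with an
unstructured across-site covariance Sigma_a Kronecker the relationship
matrix, bulk-lot effects with unstructured Sigma_b, and site-wise
heterogeneous diagonal residuals.  Every tree grows at exactly one site, so
cross-site residual covariances are not identifiable from this layout and
are not parameterised.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix
from .mme import (
    Ar1Residual,
    IidResidual,
    MixedModel,
    MixedModelError,
    RandomTerm,
    SitewiseResidual,
    FitResult,
)

TRIAL_COLUMNS = ["id", "site", "block", "row", "col", "provenance",
                 "family", "bulk_lot", "height"]


def _dummies(labels: pd.Series, prefix: str, drop_first: bool) -> pd.DataFrame:
    cats = pd.Categorical(labels.astype(str))
    d = pd.get_dummies(cats, prefix=prefix, drop_first=drop_first, dtype=float)
    return d.set_axis(labels.index)


def _single_site_design(obs: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + block + provenance with first-level reference constraints."""
    parts = [pd.DataFrame({"intercept": np.ones(len(obs))}, index=obs.index)]
    if obs["block"].nunique() > 1:
        parts.append(_dummies(obs["block"], "block", drop_first=True))
    if obs["provenance"].nunique() > 1:
        parts.append(_dummies(obs["provenance"], "prov", drop_first=True))
    X = pd.concat(parts, axis=1)
    return X.to_numpy(dtype=float), list(X.columns)


def _cell_means_design(obs: pd.DataFrame, cols: list[str]) -> tuple[np.ndarray, list[str]]:
    key = obs[cols].astype(str).agg(":".join, axis=1)
    d = _dummies(key, "cell", drop_first=False)
    return d.to_numpy(dtype=float), [c.removeprefix("cell_") for c in d.columns]


def _bulk_term(obs: pd.DataFrame, groups=None, n_groups=1,
               group_names=None) -> Optional[RandomTerm]:
    lots = sorted(obs["bulk_lot"].dropna().unique())
    if not lots:
        return None
    lot_idx = {l: i for i, l in enumerate(lots)}
    levels = np.array([lot_idx.get(l, -1) if pd.notna(l) else -1
                       for l in obs["bulk_lot"]], dtype=int)
    term = RandomTerm("bulk", levels, K=None, n_levels=len(lots),
                      groups=groups, n_groups=n_groups,
                      level_ids=lots, group_names=group_names)
    return term


def _additive_term(obs: pd.DataFrame, relmatrix: RelationshipMatrix,
                   groups=None, n_groups=1, group_names=None) -> RandomTerm:
    missing = [i for i in obs["id"] if i not in relmatrix._index]
    if missing:
        raise MixedModelError(
            f"{len(missing)} phenotyped trees absent from the relationship "
            f"matrix (first: {missing[:3]})")
    levels = relmatrix.index_of(obs["id"])
    return RandomTerm("additive", levels, relmatrix.values,
                      n_levels=len(relmatrix.ids), groups=groups,
                      n_groups=n_groups, level_ids=list(relmatrix.ids),
                      group_names=group_names)


def _attach_blups(fit: FitResult, model: MixedModel,
                  relmatrix: RelationshipMatrix,
                  pred: pd.DataFrame, drop_cache: bool) -> None:
    """Predict additive BLUP/PEV for the (id, group) pairs in `pred`."""
    levels = relmatrix.index_of(pred["id"])
    groups = pred["group"].to_numpy(dtype=int) if "group" in pred else None
    bv, pev = model.predict_random(fit, "additive", levels, groups)
    out = pred.copy()
    out["blup"] = bv
    out["pev"] = pev
    fit.meta["blup"] = out
    if "bulk" in model.terms:
        t = model.terms["bulk"]
        glev = np.arange(t.n_levels)
        if t.k > 1:
            rows = []
            for g in range(t.k):
                u, p = model.predict_random(fit, "bulk", glev,
                                            np.full(t.n_levels, g))
                rows.append(pd.DataFrame({"bulk_lot": t.level_ids,
                                          "group": g, "blup": u, "pev": p}))
            fit.meta["bulk_blup"] = pd.concat(rows, ignore_index=True)
        else:
            u, p = model.predict_random(fit, "bulk", glev)
            fit.meta["bulk_blup"] = pd.DataFrame(
                {"bulk_lot": t.level_ids, "blup": u, "pev": p})
    if drop_cache:
        fit.meta.pop("pieces", None)


def fit_single_site(trial: pd.DataFrame, relmatrix: RelationshipMatrix,
                    spatial: bool = True, reml_options: Optional[dict] = None,
                    drop_cache: bool = True) -> FitResult:
    """Stage-1 single-site fit (design or AR1xAR1 spatial residual)."""
    sites = trial["site"].unique()
    if len(sites) != 1:
        raise MixedModelError(f"fit_single_site expects one site, got {list(sites)}")
    obs = trial[trial["height"].notna()].reset_index(drop=True)
    if obs.empty:
        raise MixedModelError("no phenotyped trees at this site")
    X, names = _single_site_design(obs)
    terms = {"additive": _additive_term(obs, relmatrix)}
    bulk = _bulk_term(obs)
    if bulk is not None:
        terms["bulk"] = bulk
    if spatial:
        residual = Ar1Residual(obs["row"].to_numpy(), obs["col"].to_numpy())
    else:
        residual = IidResidual(len(obs))
    model = MixedModel(obs["height"].to_numpy(dtype=float), X, terms,
                       residual, fixed_names=names)
    fit = model.reml(**(reml_options or {}))
    fit.meta["site"] = sites[0]
    fit.meta["spatial"] = spatial
    fit.meta["obs"] = obs
    pred = pd.DataFrame({"id": relmatrix.ids})
    _attach_blups(fit, model, relmatrix, pred, drop_cache=not spatial and drop_cache)
    # spatial fits keep their cache: phenotype adjustment needs Py
    return fit


def fit_multi_site(adjusted: pd.DataFrame, relmatrix: RelationshipMatrix,
                   reml_options: Optional[dict] = None,
                   predict_for: Optional[pd.DataFrame] = None,
                   start: Optional[dict] = None,
                   fixed_theta: Optional[np.ndarray] = None,
                   drop_cache: bool = True) -> FitResult:
    """Stage-2 multi-site fit on adjusted phenotypes.

    `adjusted` needs columns id, site, provenance, bulk_lot, y_adj.
    `predict_for` optionally lists (id, site) pairs to predict breeding
    values for; defaults to every record of `adjusted` (including records
    whose y_adj is missing, e.g. masked cross-validation trees).
    """
    site_names = sorted(adjusted["site"].astype(str).unique())
    k = len(site_names)
    site_code = {s: i for i, s in enumerate(site_names)}
    data = adjusted.copy()
    data["_site_code"] = data["site"].astype(str).map(site_code)
    obs = data[data["y_adj"].notna()].reset_index(drop=True)
    if obs.empty:
        raise MixedModelError("no adjusted phenotypes supplied")
    X, names = _cell_means_design(obs, ["site", "provenance"])
    groups = obs["_site_code"].to_numpy(dtype=int)
    terms = {"additive": _additive_term(obs, relmatrix, groups=groups,
                                        n_groups=k, group_names=site_names)}
    bulk = _bulk_term(obs, groups=groups, n_groups=k, group_names=site_names)
    if bulk is not None:
        terms["bulk"] = bulk
    residual = SitewiseResidual(groups, k, site_names)
    model = MixedModel(obs["y_adj"].to_numpy(dtype=float), X, terms,
                       residual, fixed_names=names)
    if fixed_theta is not None:
        # re-solve the BLUP system at known variance components (the
        # transformed parameter layout does not depend on which
        # observations are present)
        fit = model.solve(np.asarray(fixed_theta, dtype=float))
    else:
        fit = model.reml(start=start, **(reml_options or {}))
    fit.meta["sites"] = site_names
    fit.meta["obs"] = obs
    fit.meta["data"] = data.drop(columns=["_site_code"])
    if predict_for is None:
        predict_for = data[["id", "_site_code"]].rename(
            columns={"_site_code": "group"})
        predict_for["site"] = data["site"].astype(str).to_numpy()
    else:
        predict_for = predict_for.copy()
        predict_for["group"] = predict_for["site"].astype(str).map(site_code)
    _attach_blups(fit, model, relmatrix, predict_for.reset_index(drop=True),
                  drop_cache=drop_cache)
    return fit


def fit_gblup(adjusted: pd.DataFrame, gw: RelationshipMatrix,
              reml_options: Optional[dict] = None,
              drop_cache: bool = True) -> FitResult:
    """GBLUP on the genotyped subset (single site, blended G matrix).

    Restricted to trees present in `gw`; bulk trees (no family) are not part
    of the genotyped panel, so no bulk term is fitted.
    """
    sub = adjusted[adjusted["id"].isin(set(gw.ids))].copy()
    if sub.empty:
        raise MixedModelError("no genotyped trees among adjusted phenotypes")
    sub["bulk_lot"] = None
    return fit_multi_site(sub, gw, reml_options=reml_options,
                          drop_cache=drop_cache)
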