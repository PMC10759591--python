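"""Two-stage evaluation pipeline.

Stage 1 fits each site separately with the pedigree A matrix, both as an
a-priori design model (iid residual) and an a-posteriori spatial model
(AR1 x AR1 + nugget); adjusted phenotypes are the raw heights minus the
estimated block effects and the spatially dependent residual BLUP from the
spatial fit.  Stage 2 fits the across-site model on the adjusted phenotypes
once per relationship-matrix flavour:

    ABLUP-1: A        ABLUP-2: A2 (partial selfing)
    ssGBLUP-1: H      ssGBLUP-2: H2
    GBLUP: Gw, genotyped trees at the genotyped site only

and the evaluation layer derives heritabilities, genetic correlations,
accuracies, efficiency, gains, rankings and cross-validated predictive
accuracy from the fits.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import evaluation as ev
from .kinship import (
    PedigreeCorrectionReport,
    pedigree_scale_relatedness,
    RelationshipMatrix,
    blend_G,
    build_A,
    build_A_selfing,
    build_G,
    build_H,
    correct_pedigree,
    estimate_selfing_rate,
    inbreeding_coefficients,
)
from .mme import FitResult, MixedModelError
from .models import fit_gblup, fit_multi_site, fit_single_site
from .pedigree import Pedigree
from .qc import GenotypeMatrix, QCReport, run_qc
from .simulate import OrchardData

MODEL_MATRIX = {"ABLUP-1": "A", "ABLUP-2": "A2", "ssGBLUP-1": "H",
                "ssGBLUP-2": "H2", "GBLUP": "Gw"}
DEFAULT_MODELS = tuple(MODEL_MATRIX)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class EvaluationRun:
    """All artifacts of one pipeline execution."""

    config: dict
    s_estimate: Optional[float]
    s_used: float
    qc_report: Optional[QCReport]
    correction_report: Optional[PedigreeCorrectionReport]
    pedigree: Pedigree
    genotyped_ids: list[str]
    stage1: dict  # site -> {"design": FitResult, "spatial": FitResult}
    stage2: dict  # model -> FitResult
    adjusted: pd.DataFrame
    report: dict
    cv: Optional[pd.DataFrame] = None
    matrices: Optional[dict] = None
    stage_log: list = field(default_factory=list)


def adjust_phenotypes(trial: pd.DataFrame, stage1: FitResult) -> pd.DataFrame:
    """Adjusted phenotypes: raw height minus estimated block effect and
    spatially dependent residual BLUP (genetic effects and nugget untouched)."""
    if not stage1.meta.get("spatial", False):
        raise MixedModelError(
            "phenotype adjustment needs the spatial stage-1 fit "
            "(design-variant fit supplied)")
    obs = stage1.meta["obs"]
    xi = stage1.model.spatial_blup(stage1)
    beta = dict(zip(stage1.fixed_names, stage1.beta))
    block_eff = np.array([beta.get(f"block_{b}", 0.0) for b in obs["block"]])
    out = obs[["id", "site", "provenance", "family", "bulk_lot"]].copy()
    out["y_adj"] = obs["height"].to_numpy(dtype=float) - block_eff - xi
    return out


def _timed(log, stage, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as e:
        raise PipelineError(stage, e) from e
    log.append((stage, round(time.perf_counter() - t0, 3)))
    return result


def run_pipeline(
    pedigree: Pedigree | OrchardData,
    trial: Optional[pd.DataFrame] = None,
    genotypes: Optional[GenotypeMatrix] = None,
    *,
    selfing_rate: Optional[float] = None,
    qc_thresholds: Optional[dict] = None,
    blend_weight: float = 0.90,
    correction_thresholds: tuple[float, float] = (0.15, 0.20),
    models: tuple[str, ...] = DEFAULT_MODELS,
    selection_fraction: float = 0.10,
    cv_folds: int = 0,
    cv_schemes: tuple[str, ...] = ("random", "within_provenance"),
    reml_options: Optional[dict] = None,
    keep_matrices: bool = False,
    seed: int = 0,
) -> EvaluationRun:
    """Run QC, pedigree correction, matrix construction, both stages, and
    the evaluation statistics; returns every artifact in an EvaluationRun."""
    if isinstance(pedigree, OrchardData):
        data = pedigree
        pedigree, trial, genotypes = data.pedigree, data.trial, data.genotypes
    if trial is None:
        raise ValueError("run_pipeline needs a field-trial table")
    log: list = []
    config = {
        "selfing_rate": selfing_rate, "qc_thresholds": qc_thresholds or {},
        "blend_weight": blend_weight,
        "correction_thresholds": correction_thresholds, "models": list(models),
        "selection_fraction": selection_fraction, "cv_folds": cv_folds,
        "cv_schemes": list(cv_schemes), "seed": seed,
    }

    qc_report = None
    correction_report = None
    s_estimate = None
    panel_ids: list[str] = []
    matrices: dict[str, RelationshipMatrix] = {}
    ped = pedigree

    if genotypes is not None:
        g_qc, qc_report = _timed(log, "qc", run_qc, genotypes,
                                 **(qc_thresholds or {}))
        G = _timed(log, "G-matrix", build_G, g_qc)
        # validation of recorded maternity uses relatedness re-anchored to
        # the pedigree scale, so the thresholds keep their half-sib meaning
        R_ped = _timed(log, "relatedness", pedigree_scale_relatedness, g_qc,
                       pedigree)
        ped, correction_report = _timed(
            log, "pedigree-correction", correct_pedigree, pedigree, R_ped,
            correction_thresholds[0], correction_thresholds[1],
            drop_removed=False)
        removed = {i for i, _ in correction_report.removed}
        panel_ids = [i for i in g_qc.ids if i not in removed]
        G_panel = G.subset(panel_ids)
        matrices["G"] = G_panel
        try:
            s_estimate = _timed(log, "selfing-rate", estimate_selfing_rate,
                                g_qc.select_individuals(panel_ids), ped)
        except Exception:
            s_estimate = None
    requested = [m for m in models if m in MODEL_MATRIX]
    if genotypes is None:
        skipped = [m for m in requested if m not in ("ABLUP-1", "ABLUP-2")]
        if skipped:
            warnings.warn(f"no genotypes supplied; skipping {skipped}")
        requested = [m for m in requested if m in ("ABLUP-1", "ABLUP-2")]

    if selfing_rate is not None:
        s_used = float(selfing_rate)
    elif s_estimate is not None:
        s_used = float(s_estimate)
    else:
        warnings.warn("no genotypes and no selfing rate supplied; using 0.30")
        s_used = 0.30

    A = _timed(log, "A-matrix", build_A, ped)
    matrices["A"] = A
    need_a2 = any(m in requested for m in ("ABLUP-2", "ssGBLUP-2"))
    if need_a2:
        matrices["A2"] = _timed(log, "A2-matrix", build_A_selfing, ped, s_used)
    if genotypes is not None and panel_ids:
        A22 = A.subset(panel_ids)
        matrices["Gw"] = _timed(log, "Gw", blend_G, matrices["G"], A22,
                                blend_weight)
        if any(m in requested for m in ("ssGBLUP-1",)):
            matrices["H"] = _timed(log, "H-matrix", build_H, A,
                                   matrices["Gw"], panel_ids)
        if "ssGBLUP-2" in requested:
            A2_22 = matrices["A2"].subset(panel_ids)
            gw2 = blend_G(matrices["G"], A2_22, blend_weight)
            matrices["Gw2"] = gw2
            matrices["H2"] = _timed(log, "H2-matrix", build_H, matrices["A2"],
                                    gw2, panel_ids)

    # ---- stage 1 --------------------------------------------------------
    stage1: dict = {}
    adjusted_parts = []
    for site in sorted(trial["site"].astype(str).unique()):
        sub = trial[trial["site"].astype(str) == site]
        design = _timed(log, f"stage1-design-{site}", fit_single_site,
                        sub, A, spatial=False, reml_options=reml_options)
        spatial = _timed(log, f"stage1-spatial-{site}", fit_single_site,
                         sub, A, spatial=True, reml_options=reml_options)
        adjusted_parts.append(
            _timed(log, f"adjust-{site}", adjust_phenotypes, sub, spatial))
        spatial.meta.pop("pieces", None)
        stage1[site] = {"design": design, "spatial": spatial}
    adjusted = pd.concat(adjusted_parts, ignore_index=True)

    # ---- stage 2 --------------------------------------------------------
    # start values informed by the stage-1 spatial fits: additive and bulk
    # variances per site, nugget as residual, moderate across-site
    # correlation (cuts AI iterations substantially on large fits)
    sites = sorted(stage1)
    k = len(sites)
    floor = 1e-3 * float(np.var(adjusted["y_adj"].dropna()))
    s1_add = [max(stage1[s]["spatial"].varcomp["additive"]["variances"][0],
                  floor) for s in sites]
    s1_eta = [max(stage1[s]["spatial"].varcomp["residual"]["sigma2_eta"],
                  floor) for s in sites]
    corr0 = np.full((k, k), 0.4) + 0.6 * np.eye(k)
    start2: dict = {"additive": {"variances": s1_add, "correlations": corr0},
                    "residual": {"variances": s1_eta}}
    has_bulk = any("bulk" in stage1[s]["spatial"].varcomp for s in sites)
    if has_bulk:
        s1_bulk = [max(stage1[s]["spatial"].varcomp
                       .get("bulk", {"variances": [floor]})["variances"][0],
                       floor) for s in sites]
        start2["bulk"] = {"variances": s1_bulk, "correlations": corr0}

    stage2: dict = {}
    for model in requested:
        flavour = MODEL_MATRIX[model]
        if flavour == "Gw":
            fit = _timed(log, f"stage2-{model}", fit_gblup, adjusted,
                         matrices["Gw"], reml_options=reml_options)
        else:
            fit = _timed(log, f"stage2-{model}", fit_multi_site, adjusted,
                         matrices[flavour], reml_options=reml_options,
                         start=start2)
        stage2[model] = fit

    # ---- evaluation ------------------------------------------------------
    report = _timed(log, "evaluation", _build_report, stage2, matrices,
                    ped, panel_ids, trial, selection_fraction)

    cv = None
    if cv_folds and panel_ids and stage2:
        cv = _timed(log, "cross-validation", _run_cv, adjusted, stage2,
                    matrices, panel_ids, ped, cv_folds, cv_schemes, seed)

    run = EvaluationRun(
        config=config, s_estimate=s_estimate, s_used=s_used,
        qc_report=qc_report, correction_report=correction_report,
        pedigree=ped, genotyped_ids=panel_ids, stage1=stage1, stage2=stage2,
        adjusted=adjusted, report=report, cv=cv,
        matrices=matrices if keep_matrices else None, stage_log=log,
    )
    return run


def _build_report(stage2, matrices, ped, panel_ids, trial,
                  selection_fraction) -> dict:
    report: dict = {}
    h2 = {}
    ra = {}
    acc = {}
    net = {}
    gain = {}
    for model, fit in stage2.items():
        flavour = MODEL_MATRIX[model]
        relmat = matrices[flavour]
        h2[model] = ev.heritability(fit)
        sigma = fit.varcomp["additive"]["Sigma"]
        if sigma.shape[0] > 1:
            ra[model] = ev.genetic_correlations(sigma, fit.meta.get("sites"))
        acc[model] = ev.accuracy_by_site(fit, relmat)
        nbv = ev.net_breeding_values(fit)
        net[model] = nbv
        gain[model] = ev.expected_gain(
            pd.Series(nbv["net_bv"].to_numpy(), index=nbv["id"]),
            selection_fraction)
    report["h2"] = h2
    report["genetic_correlations"] = ra
    report["accuracy"] = acc
    report["gain_percent"] = gain

    # efficiency at the genotyped site, per inbreeding scenario
    if "GBLUP" in stage2:
        gsite = stage2["GBLUP"].meta["sites"][0]
        acc_g = acc["GBLUP"].loc[gsite, "mean"]
        eff = {}
        for suffix in ("1", "2"):
            a, ss = f"ABLUP-{suffix}", f"ssGBLUP-{suffix}"
            if a in acc and ss in acc and gsite in acc[a].index:
                try:
                    eff[f"scenario-{suffix}"] = ev.efficiency(
                        acc[a].loc[gsite, "mean"], acc[ss].loc[gsite, "mean"],
                        acc_g)
                except ev.EvaluationError:
                    eff[f"scenario-{suffix}"] = float("nan")
        report["efficiency"] = eff

    # ranking overlap (pairwise, top fraction); GBLUP compared on its own panel
    overlap = {}
    names = list(net)
    for i, m1 in enumerate(names):
        for m2 in names[i + 1:]:
            s1 = pd.Series(net[m1]["net_bv"].to_numpy(), index=net[m1]["id"])
            s2 = pd.Series(net[m2]["net_bv"].to_numpy(), index=net[m2]["id"])
            common = s1.index.intersection(s2.index)
            overlap[(m1, m2)] = ev.ranking_overlap(
                s1.loc[common], s2.loc[common], selection_fraction)
    report["overlap_top"] = overlap

    comp = {}
    for model, nbv in net.items():
        comp[model] = {
            "top": ev.provenance_composition(nbv, selection_fraction, "top"),
            "bottom": ev.provenance_composition(nbv, selection_fraction,
                                                "bottom"),
        }
    report["provenance_composition"] = comp

    # family-level inbreeding vs height (genotyped trees)
    if panel_ids and "G" in matrices:
        F = inbreeding_coefficients(matrices["G"])
        heights = trial.set_index("id")["height"]
        fams = pd.Series(dict(zip(ped.ids, ped.family)))
        try:
            report["family_F_height_r"] = ev.family_inbreeding_height_correlation(
                F, heights.reindex(F.index), fams.reindex(F.index))
        except ev.EvaluationError:
            report["family_F_height_r"] = float("nan")
        report["mean_inbreeding"] = {
            "overall": float(F.mean()),
            "by_provenance": F.groupby(
                pd.Series(dict(zip(ped.ids, ped.provenance))).reindex(F.index)
            ).mean().to_dict(),
        }
    report["net_bv"] = net
    return report


def _run_cv(adjusted, stage2, matrices, panel_ids, ped, k, schemes, seed):
    """Scenario-matched cross-validation: models without the selfing
    adjustment are scored against the full-data ssGBLUP-1 reference, models
    with it against ssGBLUP-2."""
    prov = pd.Series(dict(zip(ped.ids, ped.provenance)))
    frames = []
    ref_map = {"ABLUP-1": "ssGBLUP-1", "ssGBLUP-1": "ssGBLUP-1",
               "GBLUP": "ssGBLUP-1", "ABLUP-2": "ssGBLUP-2",
               "ssGBLUP-2": "ssGBLUP-2"}
    for scheme in schemes:
        by_ref: dict[str, dict] = {}
        for model, fit in stage2.items():
            ref = ref_map.get(model, "ssGBLUP-1")
            if ref not in stage2:
                ref = next(iter(stage2))
            by_ref.setdefault(ref, {})[model] = (
                matrices[MODEL_MATRIX[model]], fit.theta)
        for ref, specs in by_ref.items():
            blup = stage2[ref].meta["blup"]
            ref_bv = pd.Series(blup["blup"].to_numpy(), index=blup["id"])
            ref_bv = ref_bv[ref_bv.index.isin(panel_ids)]
            cvf = ev.cross_validate(adjusted, specs, panel_ids, ref_bv,
                                    k=k, scheme=scheme, provenance=prov,
                                    seed=seed)
            cvf["reference"] = ref
            frames.append(cvf)
    return pd.concat(frames, ignore_index=True) if frames else None
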