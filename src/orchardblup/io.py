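"""Readers and writers for pedigree, genotype, trial and matrix tables, plus run configs.

All tabular formats are delimited text (comma written; comma or tab read).
Unknown parents and missing values are written as "NA"; empty strings are
accepted on read.  Grid coordinates are 1-based (row, column) following
field-book convention.  Heights are decimetres end-to-end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinship import RelationshipMatrix
from .pedigree import COLUMNS as PED_COLUMNS
from .pedigree import Pedigree
from .qc import MISSING, GenotypeMatrix

NA = "NA"


class FormatError(ValueError):
    pass


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       keep_default_na=False)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def read_pedigree(path) -> Pedigree:
    t = _read_table(path)
    missing = [c for c in PED_COLUMNS if c not in t.columns]
    if missing:
        raise FormatError(f"pedigree file {path} lacks columns {missing}")
    t = t.replace({NA: None, "": None})
    return Pedigree(t)


def write_pedigree(pedigree: Pedigree, path) -> None:
    t = pedigree.table.copy()
    for c in PED_COLUMNS:
        t[c] = [NA if v is None else v for v in t[c]]
    t.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "matrix") -> GenotypeMatrix:
    """Genotype matrix from delimited text (individuals x loci) or VCF.

    Matrix dialect: first column `id`, remaining columns one per locus with
    values in {0,1,2} or NA/empty for missing.  VCF: biallelic records map to
    alt-allele dosage; multiallelic records are skipped (count reported via
    the returned object's `.skipped` attribute is not kept - a warning is
    raised instead).
    """
    if format == "vcf":
        return _read_vcf(path)
    if format != "matrix":
        raise FormatError(f"unknown genotype format {format!r}")
    t = _read_table(path)
    if "id" not in t.columns:
        raise FormatError(f"genotype matrix {path} lacks an 'id' column")
    ids = list(t["id"])
    snps = [c for c in t.columns if c != "id"]
    vals = t[snps].replace({NA: str(MISSING), "": str(MISSING)})
    calls = vals.to_numpy(dtype=np.int16).astype(np.int8)
    return GenotypeMatrix(ids, snps, calls)


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise FormatError("VCF support needs the optional cyvcf2 dependency") from e
    import warnings
    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 dosage, 3 unknown
    ids = list(vcf.samples)
    snp_ids, cols = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        name = var.ID or f"{var.CHROM}:{var.POS}"
        snp_ids.append(name)
        # gt_types: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        g = var.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        cols.append(g)
    if not snp_ids:
        raise FormatError(f"no usable biallelic records in {path}")
    if skipped:
        warnings.warn(f"skipped {skipped} multiallelic VCF records")
    calls = np.column_stack(cols).astype(np.int8)
    return GenotypeMatrix(ids, snp_ids, calls)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    t = pd.DataFrame(g.calls.astype(object), columns=g.snp_ids)
    t = t.mask(g.calls == MISSING, NA)
    t.insert(0, "id", g.ids)
    t.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Field trial
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = ["id", "site", "block", "row", "col", "provenance", "family",
                 "bulk_lot", "height"]


def read_trial(path) -> pd.DataFrame:
    t = _read_table(path)
    missing = [c for c in TRIAL_COLUMNS if c not in t.columns]
    if missing:
        raise FormatError(f"trial file {path} lacks columns {missing}")
    t = t.replace({NA: None, "": None})
    t["row"] = t["row"].astype(int)
    t["col"] = t["col"].astype(int)
    t["height"] = pd.to_numeric(t["height"], errors="coerce")
    if (t["height"].dropna() < 0).any():
        bad = t.loc[t["height"] < 0, "id"].iloc[0]
        raise FormatError(f"negative height for tree {bad!r}")
    dup = t.duplicated(subset=["site", "row", "col"])
    if dup.any():
        r = t[dup].iloc[0]
        raise FormatError(
            f"duplicate grid cell (site={r['site']}, row={r['row']}, "
            f"col={r['col']})")
    if t["id"].duplicated().any():
        raise FormatError("duplicate tree ids in trial file")
    return t[TRIAL_COLUMNS]


def write_trial(trial: pd.DataFrame, path) -> None:
    t = trial[TRIAL_COLUMNS].copy()
    t = t.where(pd.notna(t), NA)
    t.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------

def write_matrix(m: RelationshipMatrix, path, dialect: str = "square") -> None:
    if dialect == "square":
        m.to_square_frame().to_csv(path, index_label="id")
    elif dialect == "triplet":
        m.to_triplet_frame(lower=True).to_csv(path, index=False)
    else:
        raise FormatError(f"unknown matrix dialect {dialect!r}")


def read_matrix(path, dialect: str = "square",
                flavour: str = "A") -> RelationshipMatrix:
    if dialect == "square":
        t = pd.read_csv(path, index_col="id")
        ids = [str(i) for i in t.index]
        return RelationshipMatrix(ids, t.to_numpy(dtype=float), flavour)
    if dialect != "triplet":
        raise FormatError(f"unknown matrix dialect {dialect!r}")
    t = pd.read_csv(path, dtype={"id1": str, "id2": str})
    ids = list(dict.fromkeys(list(t["id1"]) + list(t["id2"])))
    pos = {i: k for k, i in enumerate(ids)}
    vals = np.zeros((len(ids), len(ids)))
    for i1, i2, v in zip(t["id1"], t["id2"], t["value"]):
        vals[pos[i1], pos[i2]] = v
        vals[pos[i2], pos[i1]] = v
    return RelationshipMatrix(ids, vals, flavour)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every threshold, weight, rate and seed of a pipeline run."""

    pedigree: str | None = None
    trial: str | None = None
    genotypes: str | None = None
    genotype_format: str = "matrix"
    selfing_rate: float | None = None
    max_locus_missing: float = 0.15
    min_het: float = 0.05
    max_ind_missing: float = 0.15
    blend_weight: float = 0.90
    correction_min_within: float = 0.15
    correction_min_reassign: float = 0.20
    models: list = field(default_factory=lambda: list(
        ("ABLUP-1", "ABLUP-2", "ssGBLUP-1", "ssGBLUP-2", "GBLUP")))
    selection_fraction: float = 0.10
    cv_folds: int = 0
    cv_schemes: list = field(default_factory=lambda: ["random",
                                                      "within_provenance"])
    seed: int = 0

    def validate(self) -> None:
        for name in ("max_locus_missing", "min_het", "max_ind_missing",
                     "blend_weight", "selection_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"config {name} must be in [0, 1], got {v}")
        if self.selfing_rate is not None and not 0 <= self.selfing_rate <= 1:
            raise FormatError("config selfing_rate must be in [0, 1]")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Run artifacts
# ---------------------------------------------------------------------------

def write_run(run, out_dir) -> None:
    """Write an EvaluationRun's tables and a manifest under `out_dir`.

    Deterministic output: the manifest echoes configuration and stage names
    but no wall-clock times.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run.adjusted.to_csv(out / "adjusted_phenotypes.csv", index=False)
    write_pedigree(run.pedigree, out / "pedigree_corrected.csv")
    h2 = pd.DataFrame({m: s for m, s in run.report["h2"].items()})
    h2.to_csv(out / "heritability.csv", index_label="site")
    for model, fit in run.stage2.items():
        fit.meta["blup"].to_csv(out / f"blup_{model}.csv", index=False)
        nbv = run.report["net_bv"].get(model)
        if nbv is not None:
            nbv.to_csv(out / f"net_bv_{model}.csv", index=False)
    if run.cv is not None:
        run.cv.to_csv(out / "cross_validation.csv", index=False)
    summary = {
        "s_estimate": run.s_estimate,
        "s_used": run.s_used,
        "qc": run.qc_report.to_dict() if run.qc_report else None,
        "pedigree_correction": {
            "reassigned": run.correction_report.reassigned,
            "removed": run.correction_report.removed,
        } if run.correction_report else None,
        "gain_percent": run.report.get("gain_percent"),
        "efficiency": run.report.get("efficiency"),
        "overlap_top": {f"{a}|{b}": v for (a, b), v
                        in run.report.get("overlap_top", {}).items()},
        "family_F_height_r": run.report.get("family_F_height_r"),
        "mean_inbreeding": run.report.get("mean_inbreeding"),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    manifest = {
        "config": run.config,
        "stages": [name for name, _ in run.stage_log],
        "models": list(run.stage2),
        "n_genotyped": len(run.genotyped_ids),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
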