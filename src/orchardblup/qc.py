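"""SNP quality control: locus missingness, locus heterozygosity, individual missingness.

Genotypes are biallelic alt-allele dosages in {0, 1, 2}; missing calls are
stored as -1.  The QC stage mirrors routine filtering of
genotyping-by-sequencing data before relationship-matrix construction:

1. drop loci whose missing-call proportion is >= `max_locus_missing`,
2. drop loci whose observed heterozygosity is <= `min_het`,
3. drop individuals whose missing-call proportion is >= `max_ind_missing`,

each filter applied to the output of the previous one.  The thresholds are
exposed because the strict/inclusive reading of "missing data in 15%" is a
convention, not a law; heterozygosity removal is inclusive (<= threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING: int = -1

DEFAULT_MAX_LOCUS_MISSING = 0.15
DEFAULT_MIN_HET = 0.05
DEFAULT_MAX_IND_MISSING = 0.15


class QCError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Individuals x loci matrix of calls in {0, 1, 2, MISSING(-1)}."""

    ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray  # int8/int16, shape (n_individuals, n_loci)

    def __post_init__(self):
        self.calls = np.asarray(self.calls)
        if self.calls.shape != (len(self.ids), len(self.snp_ids)):
            raise QCError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.ids)} ids x {len(self.snp_ids)} loci"
            )
        if len(set(self.ids)) != len(self.ids):
            raise QCError("duplicate individual ids in genotype matrix")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise QCError("duplicate snp ids in genotype matrix")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise QCError(f"calls contain values outside {{0,1,2,{MISSING}}}")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.snp_ids)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset(self, rows: np.ndarray | None = None,
               cols: np.ndarray | None = None) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_loci) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            [self.ids[i] for i in rows],
            [self.snp_ids[j] for j in cols],
            self.calls[np.ix_(rows, cols)].copy(),
        )

    def select_individuals(self, ids) -> "GenotypeMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        return self.subset(rows=np.array([pos[i] for i in ids], dtype=int))


@dataclass
class QCReport:
    """Counts and removed-id lists for each filter, in application order."""

    thresholds: dict
    n_loci_in: int = 0
    n_individuals_in: int = 0
    removed_loci_missing: list[str] = field(default_factory=list)
    removed_loci_het: list[str] = field(default_factory=list)
    removed_individuals: list[str] = field(default_factory=list)
    n_loci_out: int = 0
    n_individuals_out: int = 0

    def summary(self) -> str:
        return (
            f"QC: loci {self.n_loci_in} -> {self.n_loci_out} "
            f"(missingness removed {len(self.removed_loci_missing)}, "
            f"heterozygosity removed {len(self.removed_loci_het)}); "
            f"individuals {self.n_individuals_in} -> {self.n_individuals_out} "
            f"(removed {len(self.removed_individuals)}); "
            f"thresholds {self.thresholds}"
        )

    def to_dict(self) -> dict:
        return {
            "thresholds": dict(self.thresholds),
            "n_loci_in": self.n_loci_in,
            "n_loci_out": self.n_loci_out,
            "n_individuals_in": self.n_individuals_in,
            "n_individuals_out": self.n_individuals_out,
            "removed_loci_missing": list(self.removed_loci_missing),
            "removed_loci_het": list(self.removed_loci_het),
            "removed_individuals": list(self.removed_individuals),
        }


def _require_nonempty(g: GenotypeMatrix) -> None:
    if g.n_individuals == 0 or g.n_loci == 0:
        raise QCError("empty genotype matrix")


def filter_loci_missingness(
    g: GenotypeMatrix, max_missing: float = DEFAULT_MAX_LOCUS_MISSING
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep loci with missing proportion strictly below `max_missing`."""
    if not 0.0 <= max_missing <= 1.0:
        raise QCError("max_missing must be in [0, 1]")
    _require_nonempty(g)
    prop = g.missing_mask().mean(axis=0)
    keep = prop < max_missing
    removed = [s for s, k in zip(g.snp_ids, keep) if not k]
    return g.subset(cols=np.flatnonzero(keep)), removed


def filter_loci_heterozygosity(
    g: GenotypeMatrix, min_het: float = DEFAULT_MIN_HET
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep loci with observed heterozygosity strictly above `min_het`.

    Observed heterozygosity is (# calls == 1) / (# non-missing calls).  A
    locus with zero non-missing calls is removed.
    """
    if not 0.0 <= min_het <= 1.0:
        raise QCError("min_het must be in [0, 1]")
    _require_nonempty(g)
    nonmiss = (~g.missing_mask()).sum(axis=0)
    het_count = (g.calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(nonmiss > 0, het_count / np.maximum(nonmiss, 1), 0.0)
    keep = (nonmiss > 0) & (het > min_het)
    removed = [s for s, k in zip(g.snp_ids, keep) if not k]
    return g.subset(cols=np.flatnonzero(keep)), removed


def filter_individuals_missingness(
    g: GenotypeMatrix, max_missing: float = DEFAULT_MAX_IND_MISSING
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep individuals with missing proportion strictly below `max_missing`."""
    if not 0.0 <= max_missing <= 1.0:
        raise QCError("max_missing must be in [0, 1]")
    _require_nonempty(g)
    prop = g.missing_mask().mean(axis=1)
    keep = prop < max_missing
    removed = [s for s, k in zip(g.ids, keep) if not k]
    return g.subset(rows=np.flatnonzero(keep)), removed


def run_qc(
    g: GenotypeMatrix,
    max_locus_missing: float = DEFAULT_MAX_LOCUS_MISSING,
    min_het: float = DEFAULT_MIN_HET,
    max_ind_missing: float = DEFAULT_MAX_IND_MISSING,
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the three filters in order, each on the previous filter's output."""
    report = QCReport(
        thresholds={
            "max_locus_missing": max_locus_missing,
            "min_het": min_het,
            "max_ind_missing": max_ind_missing,
        },
        n_loci_in=g.n_loci,
        n_individuals_in=g.n_individuals,
    )
    g1, report.removed_loci_missing = filter_loci_missingness(g, max_locus_missing)
    if g1.n_loci == 0:
        raise QCError(f"all loci removed by missingness filter; {report.summary()}")
    g2, report.removed_loci_het = filter_loci_heterozygosity(g1, min_het)
    if g2.n_loci == 0:
        raise QCError(f"all loci removed by heterozygosity filter; {report.summary()}")
    g3, report.removed_individuals = filter_individuals_missingness(g2, max_ind_missing)
    if g3.n_individuals == 0:
        raise QCError(f"all individuals removed; {report.summary()}")
    report.n_loci_out = g3.n_loci
    report.n_individuals_out = g3.n_individuals
    return g3, report
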