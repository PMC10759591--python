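import numpy as np
import pandas as pd
import pytest

from orchardblup.pedigree import Pedigree
from orchardblup.simulate import SimConfig, SiteLayout, SiteVariance


def make_pedigree(rows):
    """rows: (id, mother, father, provenance, family, bulk_lot) tuples."""
    return Pedigree(pd.DataFrame(
        rows, columns=["id", "mother", "father", "provenance", "family",
                       "bulk_lot"]))


@pytest.fixture
def op_family_pedigree():
    """One dam with two open-pollinated offspring."""
    return make_pedigree([
        ("dam", None, None, "P30", "F1", None),
        ("o1", "dam", None, "P30", "F1", None),
        ("o2", "dam", None, "P30", "F1", None),
    ])


def small_sim_config(**overrides):
    """Tiny three-site orchard for fast end-to-end tests."""
    sites = ("ILRI", "SM", "Suba")
    base = dict(
        n_provenances=3,
        families_per_provenance=7,
        trees_per_family_per_site=8,
        n_bulk_lots=4,
        trees_per_bulk_lot_per_site=6,
        selfing_rate=0.30,
        n_snps=500,
        site_layouts={s: SiteLayout(15, 15, 5) for s in sites},
        variance_truth={s: SiteVariance(2.5, 1.5, 2.0, 6.0) for s in sites},
        rho_col=0.6,
        rho_row=0.6,
        genetic_correlation=0.5,
        site_means={"ILRI": 16.0, "SM": 9.0, "Suba": 12.0},
        genotyped_families_fraction=0.5,
        genotyped_fraction=0.8,
        seed=20240102,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture
def small_config():
    return small_sim_config()


# ---------------------------------------------------------------------------
# Independent gene-dropping kinship oracle (used to validate the tabular A)
# ---------------------------------------------------------------------------

def gene_drop_relationship(mothers, fathers, n_rep=10_000, selfing=0.0,
                           seed=0):
    """Monte-Carlo additive relationship matrix by dropping labelled alleles.

    mothers/fathers: integer parent indices per individual in topological
    order, -1 for unknown.  An individual with a known mother and unknown
    father is treated as selfed with probability `selfing`, otherwise sired
    by a fresh unrelated founder.  Returns 2x the estimated kinship matrix
    (diagonal 1 + F).
    """
    rng = np.random.default_rng(seed)
    n = len(mothers)
    label = 0
    # allele labels per individual: (n, n_rep) arrays for the two slots
    A1 = np.zeros((n, n_rep), dtype=np.int64)
    A2 = np.zeros((n, n_rep), dtype=np.int64)
    next_label = [0]

    def fresh(shape):
        lab = next_label[0]
        next_label[0] += shape if np.isscalar(shape) else 0
        return lab

    for i in range(n):
        m, f = mothers[i], fathers[i]
        if m < 0 and f < 0:
            A1[i] = next_label[0]
            A2[i] = next_label[0] + 1
            next_label[0] += 2
            continue
        pick = rng.random(n_rep) < 0.5
        maternal = np.where(pick, A1[m], A2[m])
        if f >= 0:
            pick2 = rng.random(n_rep) < 0.5
            paternal = np.where(pick2, A1[f], A2[f])
        else:
            selfed = rng.random(n_rep) < selfing
            pick2 = rng.random(n_rep) < 0.5
            self_gamete = np.where(pick2, A1[m], A2[m])
            # unrelated sire alleles: unique labels per replicate
            sire = next_label[0] + np.arange(n_rep)
            next_label[0] += n_rep
            paternal = np.where(selfed, self_gamete, sire)
        A1[i], A2[i] = maternal, paternal

    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            share = ((A1[i] == A1[j]).astype(float) + (A1[i] == A2[j])
                     + (A2[i] == A1[j]) + (A2[i] == A2[j]))
            if i == j:
                # f_ii = 0.5 (1 + F); F = P(the two own alleles are IBD)
                F = (A1[i] == A2[i]).mean()
                A[i, i] = 1.0 + F
            else:
                A[i, j] = A[j, i] = 0.5 * share.mean()
    return A
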