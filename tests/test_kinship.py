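import numpy as np
import pandas as pd
import pytest

from orchardblup.kinship import (KinshipError, RelationshipMatrix, blend_G,
                                 build_A, build_A_selfing, build_G, build_H,
                                 correct_pedigree, estimate_selfing_rate,
                                 inbreeding_coefficients, pairwise_relatedness,
                                 pca_of_G)
from orchardblup.qc import GenotypeMatrix, MISSING
from orchardblup.simulate import (SimConfig, SiteLayout, SiteVariance,
                                  simulate_genotypes, simulate_pedigree)

from conftest import gene_drop_relationship, make_pedigree


# ---------------------------------------------------------------------------
# Pedigree numerator matrices
# ---------------------------------------------------------------------------

def test_A_textbook_identities(op_family_pedigree):
    A = build_A(op_family_pedigree)
    assert A.values[0, 0] == 1.0          # founder diagonal
    assert A.values[0, 1] == 0.5          # parent-offspring
    assert A.values[1, 2] == 0.25         # outcross half sibs
    assert np.allclose(A.values, A.values.T)


def test_A_full_sib_mating_inbreeding():
    ped = make_pedigree([
        ("s", None, None, "P", None, None),
        ("d", None, None, "P", None, None),
        ("c1", "d", "s", "P", "F", None),
        ("c2", "d", "s", "P", "F", None),
        ("x", "c1", "c2", "P", "F", None),  # offspring of full sibs
    ])
    A = build_A(ped)
    assert A.values[2, 3] == pytest.approx(0.5)       # full sibs
    assert A.values[4, 4] == pytest.approx(1.25)      # 1 + 0.5 * 0.5


def test_A_selfing_identities(op_family_pedigree):
    A2 = build_A_selfing(op_family_pedigree, 0.3)
    assert A2.values[1, 1] == pytest.approx(1.15)
    assert A2.values[0, 1] == pytest.approx(0.65)
    assert A2.values[1, 2] == pytest.approx(0.4225)
    full = build_A_selfing(op_family_pedigree, 1.0)
    assert full.values[1, 1] == pytest.approx(1.5)
    assert full.values[0, 1] == pytest.approx(1.0)


def test_A_selfing_zero_is_bitwise_A():
    rng = np.random.default_rng(0)
    rows = [("f0", None, None, "P", None, None),
            ("f1", None, None, "P", None, None)]
    ids = ["f0", "f1"]
    for k in range(2, 12):
        m = ids[rng.integers(0, len(ids))]
        f = ids[rng.integers(0, len(ids))] if rng.random() < 0.5 else None
        rows.append((f"i{k}", m, f if f != m else None, "P", "F", None))
        ids.append(f"i{k}")
    ped = make_pedigree(rows)
    assert np.array_equal(build_A(ped).values,
                          build_A_selfing(ped, 0.0).values)


PEDIGREE_LIBRARY = [
    # (rows, selfing rate) - all <= 12 individuals, checked against the
    # gene-dropping Monte-Carlo oracle
    ([("d", None, None, "P", "F", None),
      ("a", "d", None, "P", "F", None),
      ("b", "d", None, "P", "F", None)], 0.0),
    ([("d", None, None, "P", "F", None),
      ("a", "d", None, "P", "F", None),
      ("b", "d", None, "P", "F", None),
      ("c", "a", None, "P", "F", None)], 0.3),
    # selfing chain: three generations of unknown-sire descent
    ([("d", None, None, "P", "F", None),
      ("g1", "d", None, "P", "F", None),
      ("g2", "g1", None, "P", "F", None),
      ("g3", "g2", None, "P", "F", None)], 1.0),
    # mixed known/unknown sires
    ([("s", None, None, "P", None, None),
      ("d1", None, None, "P", None, None),
      ("d2", None, None, "P", None, None),
      ("k1", "d1", "s", "P", "F1", None),
      ("k2", "d2", "s", "P", "F2", None),
      ("o1", "k1", None, "P", "F1", None),
      ("o2", "k2", None, "P", "F2", None)], 0.5),
]


@pytest.mark.parametrize("rows,s", PEDIGREE_LIBRARY)
def test_tabular_A_matches_gene_dropping_oracle(rows, s):
    ped = make_pedigree(rows)
    m_idx, f_idx = ped.parent_indices()
    oracle = gene_drop_relationship(m_idx, f_idx, n_rep=40_000, selfing=s,
                                    seed=42)
    ours = build_A_selfing(ped, s).values if s > 0 else build_A(ped).values
    assert np.max(np.abs(ours - oracle)) < 0.01


# ---------------------------------------------------------------------------
# Genomic matrices
# ---------------------------------------------------------------------------

def test_G_two_individual_hand_example():
    g = GenotypeMatrix(["a", "b"], ["s1"], np.array([[0], [2]], dtype=np.int8))
    G = build_G(g)
    assert np.allclose(G.values, [[2, -2], [-2, 2]])


def test_G_duplicate_rows_and_centering():
    rng = np.random.default_rng(1)
    calls = rng.integers(0, 3, size=(12, 300)).astype(np.int8)
    calls[5] = calls[3]
    G = build_G(GenotypeMatrix([f"i{k}" for k in range(12)],
                               [f"s{k}" for k in range(300)], calls))
    assert np.allclose(G.values[3], G.values[5])
    # column means of G are ~0 when frequencies come from the panel itself
    assert abs(G.values.mean()) < 1e-10


def test_G_monomorphic_only_raises():
    calls = np.zeros((4, 3), dtype=np.int8)
    with pytest.raises(KinshipError, match="monomorphic"):
        build_G(GenotypeMatrix(["a", "b", "c", "d"], ["s0", "s1", "s2"], calls))


def test_blend_weights():
    G = RelationshipMatrix(["a", "b"], np.array([[2., -2.], [-2., 2.]]), "G")
    A22 = RelationshipMatrix(["a", "b"], np.eye(2), "A")
    assert np.allclose(blend_G(G, A22, 1.0).values, G.values)
    assert np.allclose(blend_G(G, A22, 0.0).values, A22.values)
    assert np.allclose(blend_G(G, A22, 0.9).values,
                       [[1.9, -1.8], [-1.8, 1.9]])


def test_H_hand_example_and_limits(op_family_pedigree):
    ped = make_pedigree([
        ("1", None, None, "P", "F", None),
        ("2", "1", None, "P", "F", None),
        ("3", "1", None, "P", "F", None),
    ])
    A = build_A(ped)
    gw = RelationshipMatrix(["2", "3"], np.array([[1.0, 0.5], [0.5, 1.0]]),
                            "Gw")
    H = build_H(A, gw, ["2", "3"])
    assert H.values[0, 0] == pytest.approx(1.08, abs=1e-12)
    assert np.allclose(H.values[0, 1:], [0.6, 0.6], atol=1e-12)
    # genotyped block equals Gw exactly
    assert np.allclose(H.values[1:, 1:], gw.values, atol=1e-14)
    # limits: no genotyped ids -> A; all genotyped -> Gw
    assert np.allclose(build_H(A, gw, []).values, A.values)
    gw_all = RelationshipMatrix(ped.ids, build_A(ped).values, "Gw")
    assert np.allclose(build_H(A, gw_all, ped.ids).values, gw_all.values)


def test_H_equals_A_when_Gw_equals_A22():
    ped = make_pedigree([
        ("d", None, None, "P", "F", None),
        ("a", "d", None, "P", "F", None),
        ("b", "d", None, "P", "F", None),
        ("c", "a", None, "P", "F", None),
    ])
    A = build_A(ped)
    a22 = A.subset(["b", "c"])
    a22.flavour = "Gw"
    H = build_H(A, a22, ["b", "c"])
    assert np.allclose(H.values, A.values, atol=1e-12)


def test_blended_G_is_positive_semidefinite():
    rng = np.random.default_rng(2)
    cfg = SimConfig(
        n_provenances=2, families_per_provenance=4, trees_per_family_per_site=6,
        n_bulk_lots=0, trees_per_bulk_lot_per_site=0, n_snps=400,
        site_layouts={"S": SiteLayout(10, 10, 2)},
        variance_truth={"S": SiteVariance()}, site_means={"S": 10.0}, seed=3)
    ped, par = simulate_pedigree(cfg)
    geno, _ = simulate_genotypes(ped, cfg, parentage=par)
    trees = [i for i in ped.ids if not i.endswith("dam")]
    G = build_G(geno.select_individuals(trees))
    A22 = build_A(ped).subset(trees)
    Gw = blend_G(G, A22, 0.90)
    assert np.linalg.eigvalsh(Gw.values).min() > -1e-8


def test_inbreeding_coefficients():
    m = RelationshipMatrix(["a", "b"], np.array([[1.0, 0.2], [0.2, 1.5]]), "G")
    F = inbreeding_coefficients(m)
    assert F["a"] == 0.0 and F["b"] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# Selfing rate
# ---------------------------------------------------------------------------

def test_selfing_rate_exact_inversions(op_family_pedigree):
    def mat(rel):
        v = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, rel], [0.0, rel, 1.0]])
        return RelationshipMatrix(["dam", "o1", "o2"], v, "G")
    assert estimate_selfing_rate(mat(0.25), op_family_pedigree) == \
        pytest.approx(0.0)
    assert estimate_selfing_rate(mat(0.4225), op_family_pedigree) == \
        pytest.approx(0.3)
    # negative relatedness clamps at 0
    assert estimate_selfing_rate(mat(-0.1), op_family_pedigree) == 0.0


def test_selfing_rate_no_pairs_raises():
    ped = make_pedigree([("d", None, None, "P", "F", None),
                         ("o", "d", None, "P", "F", None)])
    m = RelationshipMatrix(["o"], np.array([[1.0]]), "G")
    with pytest.raises(KinshipError):
        estimate_selfing_rate(m, ped)


def test_selfing_rate_simulation_recovery():
    cfg = SimConfig(
        n_provenances=2, families_per_provenance=10,
        trees_per_family_per_site=10, n_bulk_lots=0,
        trees_per_bulk_lot_per_site=0, n_snps=3000, selfing_rate=0.3,
        site_layouts={"S": SiteLayout(20, 12, 2)},
        variance_truth={"S": SiteVariance()}, site_means={"S": 10.0}, seed=5)
    ped, par = simulate_pedigree(cfg)
    geno, _ = simulate_genotypes(ped, cfg, parentage=par)
    trees = [i for i in ped.ids if not i.endswith("dam")]
    s_hat = estimate_selfing_rate(geno.select_individuals(trees), ped)
    assert abs(s_hat - 0.3) < 0.05


# ---------------------------------------------------------------------------
# Pedigree correction and PCA
# ---------------------------------------------------------------------------

def _panel_with_errors(n_swaps, n_intruders, seed=9):
    from orchardblup.simulate import plant_pedigree_errors
    cfg = SimConfig(
        n_provenances=2, families_per_provenance=8,
        trees_per_family_per_site=8, n_bulk_lots=0,
        trees_per_bulk_lot_per_site=0, n_snps=1500, selfing_rate=0.3,
        site_layouts={"S": SiteLayout(16, 8, 2)},
        variance_truth={"S": SiteVariance()}, site_means={"S": 10.0},
        seed=seed)
    ped, par = simulate_pedigree(cfg)
    geno, freqs = simulate_genotypes(ped, cfg, parentage=par)
    trees = [i for i in ped.ids if not i.endswith("dam")]
    panel = geno.select_individuals(trees)
    bad_ped, bad_panel, truth = plant_pedigree_errors(
        ped, panel, trees, freqs, n_swaps=n_swaps, n_intruders=n_intruders,
        seed=seed + 1)
    return bad_ped, bad_panel, truth


def test_correct_pedigree_clean_data_no_flags():
    ped, panel, _ = _panel_with_errors(0, 0)
    G = build_G(panel)
    _, report = correct_pedigree(ped, G)
    assert not report.reassigned and not report.removed


def test_correct_pedigree_recovers_planted_swaps():
    ped, panel, truth = _panel_with_errors(6, 0)
    G = build_G(panel)
    corrected, report = correct_pedigree(ped, G)
    got = {i: new for i, _, new in report.reassigned}
    hits = sum(1 for sw in truth["swaps"]
               if got.get(sw["id"]) == sw["true_family"])
    assert hits >= len(truth["swaps"]) - 1
    # corrected pedigree records the true mother again
    tab = corrected.table.set_index("id")
    for sw in truth["swaps"]:
        if got.get(sw["id"]) == sw["true_family"]:
            assert tab.at[sw["id"], "family"] == sw["true_family"]


def test_correct_pedigree_removes_planted_intruders():
    ped, panel, truth = _panel_with_errors(0, 5)
    G = build_G(panel)
    _, report = correct_pedigree(ped, G)
    removed = {i for i, _ in report.removed}
    assert set(truth["intruders"]) <= removed


def test_pca_separates_block_structure():
    blocks = [np.full((8, 8), 0.45) + 0.55 * np.eye(8) for _ in range(3)]
    from scipy.linalg import block_diag
    V = block_diag(*blocks)
    ids = [f"i{k}" for k in range(24)]
    scores = pca_of_G(RelationshipMatrix(ids, V, "G"), n_components=2)
    labels = np.repeat([0, 1, 2], 8)
    from sklearn.metrics import silhouette_score
    assert silhouette_score(scores.to_numpy(), labels) > 0.8


def test_pca_rank_one_and_sign_convention():
    v = np.array([1.0, 2.0, -1.0])
    m = RelationshipMatrix(["a", "b", "c"], np.outer(v, v), "G")
    scores = pca_of_G(m, n_components=3)
    ev = scores.attrs["eigenvalues"]
    assert ev[0] == pytest.approx(6.0) and np.allclose(ev[1:], 0.0, atol=1e-9)
    # largest-magnitude loading positive -> component aligned with (1,2,-1)
    assert scores["PC1"].iloc[1] > 0
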