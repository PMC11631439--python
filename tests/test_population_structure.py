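"""Marker pruning, IBS distances, neighbor joining, admixture EM, and the
strict 60%-ancestry clade rule."""

import numpy as np
import pandas as pd
import pytest

from popsaturate.population_structure import (
    AncestryMatrix,
    CladeAssignment,
    DistanceMatrix,
    _pairwise_r2,
    admixture_em,
    align_components,
    assign_clades,
    filter_biallelic_maf,
    group_superclades,
    ibs_distance,
    ld_prune,
    neighbor_joining,
)
from tests.conftest import make_matrix

M = -1


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------


def test_maf_threshold_is_strict():
    # 10 diploids, 20 copies; 1 alt copy -> MAF 0.05 exactly -> dropped;
    # 2 copies -> 0.10 -> kept; monomorphic -> dropped
    col_5pct = [1] + [0] * 9
    col_10pct = [1, 1] + [0] * 8
    col_mono = [0] * 10
    mat = make_matrix(np.array([col_5pct, col_10pct, col_mono]).T)
    kept = filter_biallelic_maf(mat, maf_min=0.05)
    assert kept.n_loci == 1
    assert kept.loci["pos"].iloc[0] == mat.loci["pos"].iloc[1]


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def test_duplicated_column_pruned_once():
    rng = np.random.default_rng(0)
    base = rng.integers(0, 3, 40)
    mat = make_matrix(np.stack([base, base, rng.integers(0, 3, 40)], axis=1))
    pruned = ld_prune(mat)
    assert pruned.n_loci == 2
    # the EARLIER of the duplicated pair survives
    assert mat.loci["pos"].iloc[0] in set(pruned.loci["pos"])
    assert mat.loci["pos"].iloc[1] not in set(pruned.loci["pos"])


def test_independent_loci_not_pruned():
    rng = np.random.default_rng(1)
    freqs = rng.uniform(0.2, 0.8, 60)
    mat = make_matrix(rng.binomial(2, freqs[None, :], (500, 60)).astype(np.int16))
    pruned = ld_prune(mat)
    assert pruned.n_loci == 60


def test_no_surviving_pair_violates_r2_in_any_window():
    """Brute-force windowed check of the plink indep-pairwise postcondition."""
    rng = np.random.default_rng(2)
    n, L = 80, 120
    base = rng.binomial(2, 0.5, (n, L)).astype(np.int16)
    # inject LD: copy blocks with noise
    for j in range(0, L - 3, 7):
        flip = rng.random(n) < 0.05
        base[:, j + 1] = np.where(flip, rng.integers(0, 3, n), base[:, j])
    pruned = ld_prune(make_matrix(base), window=20, r2_max=0.5)
    d = pruned.dosage
    for start in range(0, max(d.shape[1] - 1, 0)):
        idx = range(start, min(start + 20, d.shape[1]))
        for a in idx:
            for b in idx:
                if a < b:
                    assert _pairwise_r2(d[:, a], d[:, b]) <= 0.5 + 1e-12


# ---------------------------------------------------------------------------
# IBS distance
# ---------------------------------------------------------------------------


def test_ibs_identity_and_opposite():
    mat = make_matrix([[0, 1, 2, 0], [0, 1, 2, 0], [2, M, 0, 2]])
    dm = ibs_distance(mat)
    assert dm.values[0, 1] == 0
    assert dm.values[0, 2] == 1.0  # 0 vs 2 at every comparable locus
    assert np.allclose(dm.values, dm.values.T)


def test_ibs_hand_computed():
    # s0 = (0,1,2,1), s1 = (2,1,0,2): per-locus sharing 0, 1, 0, 1/2
    mat = make_matrix([[0, 1, 2, 1], [2, 1, 0, 2]])
    dm = ibs_distance(mat)
    assert dm.values[0, 1] == pytest.approx(1 - (0 + 1 + 0 + 0.5) / 4)


def test_ibs_no_comparable_loci_flagged():
    mat = make_matrix([[0, M, M], [M, 1, 1], [0, 1, 1]])
    dm = ibs_distance(mat)
    assert np.isnan(dm.values[0, 1])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def additive_distance_from_tree(branch):
    """4-taxon tree ((A,B),(C,D)) with given branch lengths -> distance matrix."""
    a, b, c, d, internal = branch
    ids = ["A", "B", "C", "D"]
    D = np.zeros((4, 4))
    D[0, 1] = D[1, 0] = a + b
    D[0, 2] = D[2, 0] = a + internal + c
    D[0, 3] = D[3, 0] = a + internal + d
    D[1, 2] = D[2, 1] = b + internal + c
    D[1, 3] = D[3, 1] = b + internal + d
    D[2, 3] = D[3, 2] = c + d
    return DistanceMatrix(ids, D, metric="additive")


def test_nj_recovers_additive_four_taxon_tree():
    dm = additive_distance_from_tree([2.0, 3.0, 1.5, 2.5, 4.0])
    tree = neighbor_joining(dm)
    paths = tree.path_lengths()
    for i, a in enumerate(dm.ids):
        for j, b in enumerate(dm.ids):
            assert paths.loc[a, b] == pytest.approx(dm.values[i, j], abs=1e-10)


def test_nj_recovers_additive_eight_taxon_tree():
    """Random additive 8-taxon tree: patristic distances match exactly."""
    rng = np.random.default_rng(4)
    # build a random binary tree by sequential attachment, tracking distances
    n = 8
    D = np.zeros((1, 1))
    for k in range(1, n):
        attach = rng.integers(k)
        new_edge = rng.uniform(0.5, 2.0)
        stretch = rng.uniform(0.5, 2.0)
        newD = np.zeros((k + 1, k + 1))
        newD[:k, :k] = D
        for i in range(k):
            newD[i, k] = newD[k, i] = D[i, attach] + new_edge + (stretch if i != attach else stretch)
        D = newD
    ids = [f"t{i}" for i in range(n)]
    dm = DistanceMatrix(ids, (D + D.T) / 2, metric="additive")
    tree = neighbor_joining(dm)
    paths = tree.path_lengths()
    for i in range(n):
        for j in range(n):
            if i != j:
                assert paths.iloc[i, j] == pytest.approx(dm.values[i, j], abs=1e-8)


def test_nj_three_taxa_star():
    D = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
    tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], D))
    paths = tree.path_lengths()
    assert paths.loc["a", "b"] == pytest.approx(3.0)
    assert paths.loc["a", "c"] == pytest.approx(4.0)
    assert paths.loc["b", "c"] == pytest.approx(5.0)


def test_nj_invariant_to_taxon_order():
    dm = additive_distance_from_tree([2.0, 3.0, 1.5, 2.5, 4.0])
    perm = [2, 0, 3, 1]
    dmp = DistanceMatrix([dm.ids[i] for i in perm], dm.values[np.ix_(perm, perm)])
    p1 = neighbor_joining(dm).path_lengths()
    p2 = neighbor_joining(dmp).path_lengths()
    for a in dm.ids:
        for b in dm.ids:
            if a != b:
                assert p1.loc[a, b] == pytest.approx(p2.loc[a, b], abs=1e-10)


def test_nj_newick_serializes():
    dm = additive_distance_from_tree([1, 1, 1, 1, 1])
    nwk = neighbor_joining(dm).to_newick()
    assert nwk.endswith(";") and set("ABCD") <= set(nwk)


def test_nj_requires_complete_matrix():
    D = np.zeros((3, 3))
    D[0, 1] = D[1, 0] = np.nan
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["a", "b", "c"], np.nan_to_num(D) * np.nan))


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------


def test_admixture_k1_closed_form():
    mat = make_matrix([[0, 1, 2], [2, 1, 0], [1, 1, 1]])
    anc = admixture_em(mat, K=1)
    assert np.allclose(anc.Q, 1.0)
    assert np.allclose(anc.F[0], [0.5, 0.5, 0.5])


def test_admixture_recovers_fixed_populations():
    """Two populations fixed for opposite alleles: Q recovers membership."""
    d = np.vstack([np.full((10, 50), 2), np.zeros((10, 50))]).astype(np.int16)
    anc = admixture_em(make_matrix(d), K=2, seed=0)
    Qt = np.zeros((20, 2))
    Qt[:10, 0] = 1
    Qt[10:, 1] = 1
    Qe = align_components(anc.Q, Qt)
    assert np.abs(Qe - Qt).max() < 1e-3


def test_admixture_balding_nichols_recovery():
    """K=3, F=0.2, 5,000 loci, 150 samples: Q mean absolute error < 0.05."""
    from popsaturate.synthetic_population import SimConfig, simulate_genotypes

    cfg = SimConfig(
        seed=11, n_clades=3, samples_per_clade=50, n_admixed=0, n_loci=5000,
        divergence_f=0.2, homozygous_fraction=0.0, ploidy_weights={2: 1.0},
        missing_rate=0.0,
    )
    mat, truth = simulate_genotypes(cfg)
    anc = admixture_em(mat, K=3, seed=5)
    Qt = truth.samples[["q_0", "q_1", "q_2"]].to_numpy()
    Qe = align_components(anc.Q, Qt)
    assert np.abs(Qe - Qt).mean() < 0.05


def test_admixture_rejects_bad_k():
    mat = make_matrix([[0, 1], [1, 0]])
    with pytest.raises(ValueError):
        admixture_em(mat, K=3)
    with pytest.raises(ValueError):
        admixture_em(mat, K=0)


# ---------------------------------------------------------------------------
# clade assignment
# ---------------------------------------------------------------------------


def ancestry_from_rows(rows):
    Q = np.asarray(rows, dtype=float)
    n, K = Q.shape
    return AncestryMatrix(
        samples=[f"s{i}" for i in range(n)], Q=Q,
        F=np.full((K, 3), 0.5), K=K, loglik=0.0, n_iter=1, converged=True,
    )


def test_assignment_threshold_is_strict():
    anc = ancestry_from_rows([[0.61, 0.39], [0.60, 0.40], [1.0, 0.0]])
    a = assign_clades(anc)
    assert a[0].component == 0
    assert a[1].component is None  # exactly 60% stays admixed
    assert a[2].component == 0


def test_superclade_grouping():
    anc = ancestry_from_rows([[0.9, 0.1, 0], [0.1, 0.8, 0.1], [0, 0, 1.0], [0.4, 0.3, 0.3]])
    assignments = assign_clades(anc)
    labeled = group_superclades(assignments, {"A": [0, 1], "B": [2]})
    assert [a.superclade for a in labeled] == ["A", "A", "B", None]


def test_superclade_empty_config():
    anc = ancestry_from_rows([[0.9, 0.1]])
    labeled = group_superclades(assign_clades(anc), {})
    assert labeled[0].superclade is None


def test_superclade_unknown_component_warns():
    anc = ancestry_from_rows([[0.9, 0.1]])
    with pytest.warns(UserWarning):
        group_superclades(assign_clades(anc), {"X": [7]})
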