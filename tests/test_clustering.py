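"""UPGMA, z-scoring and two-way identity-matrix clustering."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import average as scipy_average
from scipy.spatial.distance import squareform

from akfam.clustering import (
    cluster_identity_matrix,
    upgma_linkage,
    zscore_rows,
)
from akfam.io_formats import IdentityMatrix
from akfam.simulate import make_identity_fixture


def test_upgma_three_leaves_hand_computed():
    """d(A,B)=2, d(A,C)=d(B,C)=4 -> merge (A,B) at height 1, then C at 2."""
    d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree = upgma_linkage(d, ["A", "B", "C"])
    assert [(m.a, m.b, m.height) for m in tree.merges] == [(0, 1, 1.0), (3, 2, 2.0)]


def test_upgma_four_leaves_hand_computed():
    """Classic worked example: after merging (A,B)@d=2, average distances
    pull C in at (2+6)/2... checked by hand:
    d(AB,C) = (4+6)/2 = 5, d(AB,D) = (6+8)/2 = 7, d(C,D) = 8
    -> second merge (AB,C)@2.5; d(ABC,D) = (7*2 + 8)/3 = 22/3 -> 11/3."""
    d = np.array(
        [
            [0, 2, 4, 6],
            [2, 0, 6, 8],
            [4, 6, 0, 8],
            [6, 8, 8, 0],
        ],
        dtype=float,
    )
    tree = upgma_linkage(d, ["A", "B", "C", "D"])
    heights = [m.height for m in tree.merges]
    assert heights == pytest.approx([1.0, 2.5, 22.0 / 6.0])
    assert (tree.merges[0].a, tree.merges[0].b) == (0, 1)
    assert (tree.merges[1].a, tree.merges[1].b) == (4, 2)


def test_upgma_tie_break_lexicographic():
    """All distances equal: first merge is (A,B) by label order, both at
    the same height."""
    d = np.full((3, 3), 2.0)
    np.fill_diagonal(d, 0.0)
    tree = upgma_linkage(d, ["C", "A", "B"])
    first = tree.merges[0]
    labels = {tree.leaf_ids[first.a], tree.leaf_ids[first.b]}
    assert labels == {"A", "B"}
    assert [m.height for m in tree.merges] == [1.0, 1.0]


def test_upgma_two_leaves():
    tree = upgma_linkage(np.array([[0.0, 3.0], [3.0, 0.0]]), ["x", "y"])
    assert len(tree.merges) == 1 and tree.merges[0].height == 1.5


def test_upgma_rejects_bad_input():
    with pytest.raises(ValueError, match="symmetric"):
        upgma_linkage(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="non-negative"):
        upgma_linkage(np.array([[0.0, -1.0], [-1.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        upgma_linkage(np.array([[1.0, 2.0], [2.0, 1.0]]))


def test_upgma_matches_scipy_average_linkage(rng):
    """On distinct distances (no ties) the merge heights must equal scipy's
    average linkage heights halved."""
    for _ in range(20):
        n = int(rng.integers(3, 10))
        condensed = rng.uniform(1.0, 100.0, size=n * (n - 1) // 2)
        d = squareform(condensed)
        tree = upgma_linkage(d)
        ours = sorted(m.height for m in tree.merges)
        scipys = sorted(scipy_average(condensed)[:, 2] / 2.0)
        assert ours == pytest.approx(scipys, abs=1e-9)


def test_upgma_ultrametric_and_monotone(rng):
    """Cophenetic distances satisfy the ultrametric inequality and merge
    heights never decrease, on random matrices."""
    for _ in range(20):
        n = int(rng.integers(3, 12))
        d = squareform(rng.uniform(0.5, 50.0, size=n * (n - 1) // 2))
        tree = upgma_linkage(d)
        heights = [m.height for m in tree.merges]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))
        coph = tree.cophenetic()
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if len({i, j, k}) == 3:
                        assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-9


def test_zscore_rows_hand_checked():
    out = zscore_rows(np.array([[40.0, 50.0, 60.0]]))
    np.testing.assert_allclose(out, [[-1.0, 0.0, 1.0]])


def test_zscore_constant_row_warns_and_zeroes():
    with pytest.warns(UserWarning, match="constant"):
        out = zscore_rows(np.array([[50.0, 50.0, 50.0], [1.0, 2.0, 3.0]]))
    np.testing.assert_allclose(out[0], 0.0)
    assert out[1].mean() == pytest.approx(0.0, abs=1e-12)
    assert out[1].std(ddof=1) == pytest.approx(1.0)


def test_zscore_rows_mean_zero_sd_one(rng):
    x = rng.uniform(0, 100, size=(10, 8))
    out = zscore_rows(x)
    np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0)


def test_identical_rows_merge_first():
    # rows a and b identical (query/subject asymmetry makes this legal)
    values = np.array(
        [
            [100.0, 100.0, 20.0],
            [100.0, 100.0, 20.0],
            [20.0, 20.0, 100.0],
        ]
    )
    m = IdentityMatrix(["a", "b", "c"], values)
    res = cluster_identity_matrix(m)
    assert res.row_tree.merges[0].height == 0.0
    assert {res.row_tree.leaf_ids[res.row_tree.merges[0].a],
            res.row_tree.leaf_ids[res.row_tree.merges[0].b]} == {"a", "b"}


def test_block_matrix_separates_blocks():
    m, labels = make_identity_fixture(5, 2, within=90.0, between=50.0, noise_sd=0.0, seed=1)
    res = cluster_identity_matrix(m)
    order = res.row_tree.leaf_order()
    block_of = dict(zip(m.ids, labels))
    seq = [block_of[i] for i in order]
    # each block forms a contiguous clade in the leaf order
    assert seq == sorted(seq) or seq == sorted(seq, reverse=True)
    # and the deepest split separates them: last merge joins the two blocks
    coph = res.row_tree.cophenetic()
    ids = res.row_tree.leaf_ids
    within_max = max(
        coph[i, j]
        for i in range(10) for j in range(10)
        if i != j and block_of[ids[i]] == block_of[ids[j]]
    )
    between_min = min(
        coph[i, j]
        for i in range(10) for j in range(10)
        if block_of[ids[i]] != block_of[ids[j]]
    )
    assert within_max < between_min


def test_clustering_invariant_under_row_permutation(rng):
    m, _ = make_identity_fixture(4, 2, within=85.0, between=40.0, noise_sd=3.0, seed=7)
    res1 = cluster_identity_matrix(m)
    perm = rng.permutation(m.n)
    m2 = IdentityMatrix([m.ids[i] for i in perm], m.values[np.ix_(perm, perm)])
    res2 = cluster_identity_matrix(m2)
    assert res1.row_tree.leaf_order() in (res2.row_tree.leaf_order(),
                                          res2.row_tree.leaf_order()[::-1]) or \
        sorted(res1.row_tree.cophenetic().ravel()) == pytest.approx(
            sorted(res2.row_tree.cophenetic().ravel()))
    # cophenetic distances between the same ids must agree exactly
    c1 = res1.row_tree.cophenetic()
    c2 = res2.row_tree.cophenetic()
    idx1 = {i: k for k, i in enumerate(m.ids)}
    idx2 = {i: k for k, i in enumerate(m2.ids)}
    for a in m.ids:
        for b in m.ids:
            assert c1[idx1[a], idx1[b]] == pytest.approx(c2[idx2[a], idx2[b]], abs=1e-9)


def test_cluster_requires_two_rows():
    m = IdentityMatrix(["only"], np.array([[100.0]]))
    with pytest.raises(ValueError):
        cluster_identity_matrix(m)


def test_newick_export_parses_and_is_ultrametric():
    import io

    from Bio import Phylo

    d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree = upgma_linkage(d, ["A", "B", "C"])
    newick = tree.to_newick()
    parsed = Phylo.read(io.StringIO(newick), "newick")
    depths = parsed.depths()
    leaf_depths = {t.name: depth for t, depth in depths.items() if t.name}
    assert leaf_depths == pytest.approx({"A": 2.0, "B": 2.0, "C": 2.0})
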