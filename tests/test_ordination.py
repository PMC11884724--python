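import numpy as np
import pytest

from ssrpopgen import (
    DistanceMatrix,
    GenotypeMatrix,
    pcoa,
    shared_allele_distance,
    upgma,
)


def _dm(values, labels=None, kind="generic"):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"t{i}" for i in range(values.shape[0])]
    return DistanceMatrix(labels, values, kind=kind)


# --- PCoA ------------------------------------------------------------------


def test_two_points_single_axis():
    res = pcoa(_dm([[0, 3], [3, 0]]))
    assert res.n_axes == 1
    assert res.percent_variation[0] == pytest.approx(100.0)
    coords = res.coordinates.values[:, 0]
    assert abs(coords[0] - coords[1]) == pytest.approx(3.0)


def test_collinear_points_single_axis():
    res = pcoa(_dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]]))
    assert res.percent_variation[0] == pytest.approx(100.0)
    x = np.sort(res.coordinates.values[:, 0])
    assert np.diff(x) == pytest.approx([1.0, 1.0])


def test_euclidean_reconstruction():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(12, 4))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    res = pcoa(_dm(d))
    rec = res.coordinates.values
    d_rec = np.linalg.norm(rec[:, None] - rec[None, :], axis=2)
    assert np.allclose(d_rec, d, atol=1e-8)
    assert np.all(np.diff(res.cumulative_percent) >= -1e-12)


def test_pcoa_matches_scikit_bio():
    skbio_ord = pytest.importorskip("skbio.stats.ordination")
    from skbio import DistanceMatrix as SkbioDM

    rng = np.random.default_rng(11)
    pts = rng.normal(size=(10, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    ours = pcoa(_dm(d))
    theirs = skbio_ord.pcoa(SkbioDM(d), method="eigh", number_of_dimensions=3)
    # axis directions are sign-arbitrary; compare absolute coordinates
    assert np.allclose(
        np.abs(ours.coordinates.values[:, :3]),
        np.abs(theirs.samples.values[:, :3]),
        atol=1e-6,
    )


def test_pcoa_rejects_non_finite_entries():
    dm = DistanceMatrix(["a", "b"], np.array([[0.0, np.inf], [np.inf, 0.0]]))
    with pytest.raises(ValueError):
        pcoa(dm)


# --- UPGMA -----------------------------------------------------------------


def test_textbook_three_taxon_tree():
    d = _dm([[0, 2, 6], [2, 0, 6], [6, 6, 0]], labels=["A", "B", "C"])
    tree = upgma(d)
    assert tree.root.height == pytest.approx(3.0)
    inner = [c for c in tree.root.children if not c.is_leaf()][0]
    assert inner.height == pytest.approx(1.0)
    assert sorted(inner.leaves()) == ["A", "B"]
    assert tree.to_newick().count("(") == 2


def test_upgma_matches_scipy_average_linkage():
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(5)
    for trial in range(5):
        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = _dm(d)
        tree = upgma(dm)
        ours = tree.cophenetic()
        z = linkage(squareform(d), method="average")
        theirs = squareform(cophenet(z))
        labels = ours.labels
        order = [dm.labels.index(l) for l in labels]
        assert np.allclose(ours.values, theirs[np.ix_(order, order)], atol=1e-9)


def test_upgma_ultrametric_and_cophenetic_fixed_point(study_like):
    matrix, _ = study_like
    sub = matrix.subset(matrix.individuals[:20])
    tree = upgma(shared_allele_distance(sub))
    # all leaves equidistant from the root
    def depth(node, acc, out):
        if node.is_leaf():
            out.append(acc)
        for c in node.children:
            depth(c, acc + (node.height - c.height), out)

    depths: list[float] = []
    depth(tree.root, 0.0, depths)
    assert np.allclose(depths, depths[0], atol=1e-9)
    # an ultrametric input is reproduced exactly by its own cophenetic matrix
    coph = tree.cophenetic()
    tree2 = upgma(coph)
    assert np.allclose(tree2.cophenetic().values, coph.values, atol=1e-9)


def test_upgma_deterministic_under_ties():
    d = np.ones((4, 4)) - np.eye(4)
    t1 = upgma(_dm(d, labels=["d", "c", "b", "a"]))
    t2 = upgma(_dm(d, labels=["d", "c", "b", "a"]))
    assert t1.to_newick() == t2.to_newick()
    # lexicographically smallest pair merges first
    assert "(a:0.5,b:0.5)" in t1.to_newick().replace("(b:0.5,a:0.5)", "(a:0.5,b:0.5)")


def test_upgma_rejects_single_item():
    with pytest.raises(ValueError):
        upgma(_dm([[0.0]]))


def test_newick_round_trips_through_dendropy(study_like):
    dendropy = pytest.importorskip("dendropy")
    matrix, _ = study_like
    sub = matrix.subset(matrix.individuals[:15])
    tree = upgma(shared_allele_distance(sub))
    parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(
        sub.individuals
    )


# --- shared-allele distance ------------------------------------------------


def _matrix(calls, pops):
    calls = np.asarray(calls)
    return GenotypeMatrix(
        [f"i{k}" for k in range(calls.shape[0])],
        [f"L{j}" for j in range(calls.shape[1])],
        calls,
        pops,
    )


def test_shared_allele_identical_zero():
    m = _matrix([[[1, 2], [3, 3]], [[1, 2], [3, 3]]], ["A", "A"])
    assert shared_allele_distance(m).values[0, 1] == pytest.approx(0.0)


def test_shared_allele_disjoint_one():
    m = _matrix([[[1, 2], [5, 5]], [[3, 4], [6, 6]]], ["A", "A"])
    assert shared_allele_distance(m).values[0, 1] == pytest.approx(1.0)


def test_shared_allele_hand_worked():
    # locus 1: (1,2) vs (1,3) share 1 allele -> d = 1 - 1/2 = 0.5
    # locus 2: (4,4) vs (4,5) share 1 allele -> d = 0.5; mean = 0.5
    m = _matrix([[[1, 2], [4, 4]], [[1, 3], [4, 5]]], ["A", "A"])
    assert shared_allele_distance(m).values[0, 1] == pytest.approx(0.5)
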