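"""PCA, classical MDS and hierarchical clustering against closed-form
and cross-implementation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform

from imglia import (
    DistanceMatrix,
    NormalizedMatrix,
    classical_mds,
    cluster_purity,
    hierarchical_cluster,
    nearest_centroid,
    pca,
    sample_distances,
)


def _normalized(values, samples=None):
    values = np.asarray(values, dtype=float)
    genes = [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame(
        {"cell_type": "x", "study": "a"}, index=pd.Index(samples, name="sample_id")
    )
    return NormalizedMatrix(
        pd.DataFrame(values, index=genes, columns=samples), meta, [{"name": "test"}]
    )


def _distance(points, samples=None):
    d = squareform(pdist(np.asarray(points, dtype=float)))
    samples = samples or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(pd.DataFrame(d, index=samples, columns=samples))


def procrustes_residual(a, b):
    """Max abs deviation after optimally rotating b onto a (no scaling)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    R, _ = orthogonal_procrustes(b, a)
    return np.abs(b @ R - a).max()


class TestPca:
    def test_rank_one_variation(self):
        vals = np.ones((5, 4))
        vals[0] = [1.0, 2.0, 3.0, 4.0]
        emb = pca(_normalized(vals), k=2)
        assert emb.explained[0] == pytest.approx(1.0)
        assert emb.explained[1] == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_sample_identical_scores(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(20, 5))
        vals[:, 4] = vals[:, 3]
        emb = pca(_normalized(vals), k=3)
        assert np.allclose(
            emb.coordinates.iloc[3].to_numpy(), emb.coordinates.iloc[4].to_numpy()
        )

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(30, 12))
        emb = pca(_normalized(vals), k=5)
        X = vals.T - vals.T.mean(axis=0)
        eigval, eigvec = np.linalg.eigh(np.cov(X.T, bias=False))
        order = np.argsort(eigval)[::-1]
        scores = X @ eigvec[:, order[:5]]
        for j in range(5):
            ours = emb.coordinates.iloc[:, j].to_numpy()
            ref = scores[:, j]
            assert min(np.abs(ours - ref).max(), np.abs(ours + ref).max()) < 1e-8

    def test_explained_shares_bounded(self):
        rng = np.random.default_rng(2)
        emb = pca(_normalized(rng.normal(size=(10, 6))), k=5)
        assert emb.explained.sum() <= 1 + 1e-12
        assert np.all(np.diff(emb.explained) <= 1e-12)
        full = pca(_normalized(rng.normal(size=(10, 6))), k=5)
        assert full.explained.sum() == pytest.approx(1.0)

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError, match="k"):
            pca(_normalized(np.ones((5, 3))), k=3)


class TestClassicalMds:
    def test_two_points_closed_form(self):
        emb = classical_mds(_distance([[0.0], [4.0]]), k=1)
        coords = np.sort(emb.coordinates["axis1"].to_numpy())
        assert coords == pytest.approx([-2.0, 2.0])

    def test_all_zero_distances(self):
        d = DistanceMatrix(pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc")))
        emb = classical_mds(d, k=2)
        assert np.allclose(emb.coordinates.to_numpy(), 0.0)

    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(3)
        points = rng.normal(size=(15, 2))
        emb = classical_mds(_distance(points), k=2)
        assert procrustes_residual(points, emb.coordinates.to_numpy()) < 1e-8

    def test_agrees_with_pca_on_euclidean_distances(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(200, 20))
        emb_pca = pca(_normalized(vals), k=5)
        emb_mds = classical_mds(
            _distance(vals.T, samples=emb_pca.sample_ids), k=5
        )
        assert (
            procrustes_residual(
                emb_pca.coordinates.to_numpy(), emb_mds.coordinates.to_numpy()
            )
            < 1e-8
        )

    def test_agrees_with_skbio_pcoa(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        points = rng.normal(size=(10, 3))
        dist = _distance(points)
        ours = classical_mds(dist, k=3)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dist.d.to_numpy(), ids=dist.sample_ids)
        )
        assert (
            procrustes_residual(
                ref.samples.iloc[:, :3].to_numpy(), ours.coordinates.to_numpy()
            )
            < 1e-8
        )

    def test_non_euclidean_geometry_reported(self):
        # triangle-inequality-violating distances: negative eigenvalues
        # must be surfaced on the embedding, not silently used
        d = np.array([[0.0, 10.0, 0.1], [10.0, 0.0, 0.1], [0.1, 0.1, 0.0]])
        dm = DistanceMatrix(pd.DataFrame(d, index=list("abc"), columns=list("abc")))
        emb = classical_mds(dm, k=2)
        assert len(emb.negative_eigenvalues) > 0


class TestHierarchicalCluster:
    def test_identical_pair_merges_first_at_zero(self):
        points = [[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [9.0, 0.0]]
        dendro = hierarchical_cluster(_distance(points), "average")
        assert dendro.merges[0, 2] == pytest.approx(0.0)
        assert set(dendro.merges[0, :2].astype(int)) == {0, 1}

    @pytest.mark.parametrize("linkage", ["complete", "average", "single"])
    def test_separated_pairs_merge_within_pair(self, linkage):
        points = [[0.0], [0.1], [100.0], [100.1]]
        dendro = hierarchical_cluster(_distance(points), linkage)
        first_two = {frozenset(dendro.merges[i, :2].astype(int)) for i in range(2)}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_complete_linkage_heights_monotone(self):
        rng = np.random.default_rng(6)
        dendro = hierarchical_cluster(_distance(rng.normal(size=(12, 3))), "complete")
        assert np.all(np.diff(dendro.heights) >= -1e-12)

    def test_single_sample_errors(self):
        with pytest.raises(ValueError, match="two samples"):
            hierarchical_cluster(_distance([[0.0]]), "average")


class TestClusterPurity:
    def test_perfect_separation(self):
        points = [[0.0], [0.1], [50.0], [50.1], [100.0], [100.2]]
        labels = pd.Series(
            ["a", "a", "b", "b", "c", "c"], index=[f"s{i}" for i in range(6)]
        )
        dendro = hierarchical_cluster(_distance(points), "average")
        assert cluster_purity(dendro, labels, k=3) == 1.0

    def test_single_class_always_pure(self):
        rng = np.random.default_rng(8)
        dendro = hierarchical_cluster(_distance(rng.normal(size=(8, 2))), "average")
        labels = pd.Series(["a"] * 8, index=dendro.leaf_ids)
        for k in (1, 3, 8):
            assert cluster_purity(dendro, labels, k=k) == 1.0

    def test_matches_brute_force_majority_count(self):
        rng = np.random.default_rng(9)
        points = rng.normal(size=(10, 2)) * 5
        dendro = hierarchical_cluster(_distance(points), "average")
        labels = pd.Series(
            rng.choice(["a", "b"], size=10), index=dendro.leaf_ids
        )
        k = 4
        assignment = dendro.cut(k)
        brute = sum(
            labels.loc[assignment.index[assignment == c]].value_counts().max()
            for c in assignment.unique()
        )
        assert cluster_purity(dendro, labels, k=k) == pytest.approx(brute / 10)

    def test_k_exceeding_samples_errors(self):
        dendro = hierarchical_cluster(_distance([[0.0], [1.0]]), "average")
        with pytest.raises(ValueError, match="cut"):
            cluster_purity(dendro, pd.Series(["a", "b"], index=dendro.leaf_ids), k=3)


def test_nearest_centroid_prefers_cocluster():
    vals = np.array(
        [
            [0.0, 0.1, 5.0, 5.1, 0.2],
        ]
    )
    m = _normalized(vals, samples=["q1", "q2", "far1", "far2", "near1"])
    emb = pca(m, k=1)
    winner = nearest_centroid(
        emb, ["q1", "q2"], {"far": ["far1", "far2"], "near": ["near1"]}
    )
    assert winner == "near"
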