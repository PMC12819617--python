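import numpy as np
import pandas as pd
import pytest

from metaconcord import (
    build_views,
    cluster_agreement,
    factorize,
    kmeans_cluster,
    permanova_r2,
    select_k,
)
from metaconcord.endotype import ViewMatrix


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    return df.sub(df.mean(axis=1), axis=0).div(df.std(axis=1, ddof=0), axis=0)


def _blobs(n_per: int, centers, sd: float, seed: int, dims: int = 3) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows, names = [], []
    for ci, c in enumerate(centers):
        for i in range(n_per):
            rows.append(rng.normal(c, sd, size=dims))
            names.append(f"S{ci}_{i}")
    return pd.DataFrame(rows, index=names)


class TestBuildViews:
    def test_prevalence_filter_and_zscore(self):
        samples = [f"S{i}" for i in range(10)]
        df = pd.DataFrame(0.0, index=["common", "rare"], columns=samples)
        df.loc["common"] = np.arange(10, dtype=float) + 1
        df.loc["rare", "S0"] = 5.0          # 10% prevalence < 30%
        df.loc["extra"] = np.arange(10, dtype=float) * 2 + 1
        views = build_views({"bacterial": df})
        v = views[0]
        assert "rare" not in v.matrix.index
        assert v.dropped_low_prevalence == 1
        z = v.matrix.loc["common"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0)

    def test_host_threshold_differs(self):
        samples = [f"S{i}" for i in range(10)]
        df = pd.DataFrame(0.0, index=["g1", "g2", "g3"], columns=samples)
        df.loc["g1", samples[:4]] = [1.0, 2.0, 3.0, 4.0]   # 40% prevalence
        df.loc["g2"] = np.arange(10, dtype=float) + 1
        df.loc["g3"] = np.arange(10, dtype=float) * 3 + 2
        host = build_views({"host": df})[0]        # host threshold 50%
        microbe = build_views({"x": df})[0]        # microbe threshold 30%
        assert "g1" not in host.matrix.index
        assert "g1" in microbe.matrix.index

    def test_explicit_presence_mask(self):
        # ALR-like view: undetected cells carry the finite floor -5
        samples = [f"S{i}" for i in range(10)]
        df = pd.DataFrame(-5.0, index=["fam1", "fam2", "fam3"], columns=samples)
        df.loc["fam1"] = np.linspace(-2, 2, 10)
        df.loc["fam3"] = np.linspace(1, -1, 10)
        df.loc["fam2", "S0"] = 1.0
        pres = df > -5.0 + 1e-12
        views = build_views({"viral": df}, presence={"viral": pres})
        assert "fam2" not in views[0].matrix.index   # 10% true presence
        assert {"fam1", "fam3"} <= set(views[0].matrix.index)

    def test_zero_variance_dropped(self):
        samples = [f"S{i}" for i in range(4)]
        df = pd.DataFrame({"S0": [1.0, 1.0, 0.5], "S1": [1.0, 2.0, 1.5],
                           "S2": [1.0, 3.0, 2.0], "S3": [1.0, 4.0, 0.1]},
                          index=["const", "a", "b"])
        v = build_views({"x": df})[0]
        assert "const" not in v.matrix.index
        assert v.dropped_zero_variance == 1

    def test_mismatched_samples_raise(self):
        a = pd.DataFrame(np.ones((2, 3)), index=["x", "y"], columns=["S1", "S2", "S3"])
        b = pd.DataFrame(np.ones((2, 2)), index=["x", "y"], columns=["S1", "S2"])
        with pytest.raises(ValueError, match="same samples"):
            build_views({"a": a, "b": b})

    def test_too_few_features_raise(self):
        df = pd.DataFrame(np.zeros((2, 4)),
                          index=["r1", "r2"], columns=[f"S{i}" for i in range(4)])
        with pytest.raises(ValueError, match="fewer than 2"):
            build_views({"x": df})


class TestFactorize:
    def _view(self, seed=0, n_feat=8, n_samp=6, name="v"):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(n_feat, n_samp)),
                          index=[f"f{i}" for i in range(n_feat)],
                          columns=[f"S{i}" for i in range(n_samp)])
        return ViewMatrix(name, _zscore_rows(df), 0.3)

    def test_single_view_is_pca(self):
        v = self._view()
        model = factorize([v], n_factors=3)
        # oracle: PCA scores = U*S of the centered samples x features matrix
        X = (v.matrix.to_numpy() / np.linalg.norm(v.matrix.to_numpy())).T
        X = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        scores = U[:, :3] * S[:3]
        got = model.factors.to_numpy()
        for j in range(3):
            assert np.allclose(np.abs(got[:, j]), np.abs(scores[:, j]), atol=1e-10)
        # singular values decrease -> factor scores have decreasing norm
        norms = np.linalg.norm(got, axis=0)
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_full_rank_reconstruction_exact(self):
        v = self._view(seed=1)
        model = factorize([v], n_factors=5)     # n_samples - 1 = full rank
        rec = model.reconstruct("v")
        assert np.allclose(rec.to_numpy(), v.matrix.to_numpy(), atol=1e-8)

    def test_multi_view_shared_factors_and_variance(self):
        va, vb = self._view(seed=2, name="a"), self._view(seed=3, n_feat=5, name="b")
        model = factorize([va, vb], n_factors=5)
        assert list(model.factors.index) == list(va.matrix.columns)
        assert set(model.loadings) == {"a", "b"}
        ve = model.variance_explained
        assert ((ve.sum(axis=1) <= 1.0 + 1e-9).all())
        # full rank -> all variance of each view is explained
        assert np.allclose(ve.sum(axis=1), 1.0, atol=1e-9)

    def test_deterministic_sign_convention(self):
        v = self._view(seed=4)
        m1 = factorize([v], 3)
        m2 = factorize([v], 3)
        pd.testing.assert_frame_equal(m1.factors, m2.factors)

    def test_too_many_factors_raise(self):
        with pytest.raises(ValueError, match="exceeds"):
            factorize([self._view()], n_factors=6)


class TestKMeans:
    def test_recovers_separated_blobs(self):
        pts = _blobs(10, centers=[(0, 0, 0), (10, 10, 10)], sd=0.5, seed=0)
        res = kmeans_cluster(pts, k=2, seed=1)
        labels = pd.Series(res.labels)
        first = labels[[s for s in labels.index if s.startswith("S0_")]]
        second = labels[[s for s in labels.index if s.startswith("S1_")]]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_labels_canonicalized_by_size(self):
        pts = _blobs(12, centers=[(0, 0, 0)], sd=0.3, seed=0)
        small = _blobs(4, centers=[(30, 30, 30)], sd=0.3, seed=1)
        small.index = [f"T{i}" for i in range(len(small))]
        res = kmeans_cluster(pd.concat([pts, small]), k=2, seed=0)
        # cluster 0 must be the larger one
        sizes = pd.Series(res.labels).value_counts()
        assert sizes[0] > sizes[1]

    def test_k_exceeds_n_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(np.zeros((3, 2)), k=4)

    def test_deterministic(self):
        pts = _blobs(8, centers=[(0, 0, 0), (5, 5, 5)], sd=1.0, seed=5)
        assert kmeans_cluster(pts, 2, seed=7).labels == kmeans_cluster(pts, 2, seed=7).labels


class TestSelectK:
    def test_three_blobs(self):
        pts = _blobs(8, centers=[(0, 0, 0), (12, 0, 0), (0, 12, 0)], sd=0.6, seed=2)
        k, diag = select_k(pts, (2, 6), seed=0)
        assert k == 3
        assert set(diag.columns) >= {"k", "within_ss", "silhouette", "gap", "vote"}

    def test_within_ss_non_increasing(self):
        pts = _blobs(6, centers=[(0, 0, 0), (8, 8, 8)], sd=1.5, seed=3)
        _, diag = select_k(pts, (2, 6), seed=0)
        w = diag["within_ss"].to_numpy()
        assert all(a >= b - 1e-9 for a, b in zip(w, w[1:]))

    def test_needs_four_samples(self):
        with pytest.raises(ValueError, match="4"):
            select_k(np.zeros((3, 2)))


class TestClusterAgreement:
    def test_identical_is_one(self):
        labels = {f"S{i}": i % 3 for i in range(9)}
        frac, mapping = cluster_agreement(labels, labels)
        assert frac == 1.0
        assert mapping == {0: 0, 1: 1, 2: 2}

    def test_invariant_to_label_permutation(self):
        a = {f"S{i}": i % 2 for i in range(10)}
        b = {s: 1 - c for s, c in a.items()}
        frac, mapping = cluster_agreement(a, b)
        assert frac == 1.0
        assert mapping == {0: 1, 1: 0}

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        a = {f"S{i}": int(rng.integers(3)) for i in range(20)}
        b = {f"S{i}": int(rng.integers(3)) for i in range(20)}
        assert cluster_agreement(a, b)[0] == pytest.approx(cluster_agreement(b, a)[0])

    def test_different_sample_sets_raise(self):
        with pytest.raises(ValueError, match="sample sets"):
            cluster_agreement({"S1": 0}, {"S2": 0})

    def test_different_k(self):
        a = {"S1": 0, "S2": 0, "S3": 1, "S4": 1}
        b = {"S1": 0, "S2": 1, "S3": 2, "S4": 2}
        frac, _ = cluster_agreement(a, b)
        assert frac == 0.75


class TestPermanova:
    def test_separated_groups_large_r2_small_p(self):
        pts = _blobs(6, centers=[(0, 0, 0), (10, 10, 10)], sd=0.5, seed=4)
        labels = {s: (0 if s.startswith("S0_") else 1) for s in pts.index}
        es = permanova_r2(pts, labels, n_permutations=199, seed=0)
        assert es.r_squared > 0.8
        assert es.p <= 0.01

    def test_distance_matrix_input_matches_feature_input(self):
        from scipy.spatial.distance import pdist, squareform
        pts = _blobs(5, centers=[(0, 0, 0), (3, 3, 3)], sd=1.0, seed=5)
        labels = [0] * 5 + [1] * 5
        d = squareform(pdist(pts.to_numpy()))
        e1 = permanova_r2(pts.to_numpy(), labels, 99, seed=1)
        e2 = permanova_r2(d, labels, 99, seed=1, is_distance=True)
        assert e1.r_squared == pytest.approx(e2.r_squared, abs=1e-12)
        assert e1.p == e2.p

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="2 groups"):
            permanova_r2(np.zeros((4, 2)), [0, 0, 0, 0])
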