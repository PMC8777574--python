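"""PCA contracts, ellipse geometry and replicate-distance diagnostics."""

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from woodvar.anova import per_lot_decomposition
from woodvar.errors import DegenerateDataError
from woodvar.pca import (
    fit_pca,
    lot_ellipses,
    msq_pca,
    replicate_distance,
    subsample_mean_pca,
)
from woodvar.preprocess import msc
from woodvar.simulate import generate_dataset


class TestFitPCA:
    def test_rank_one_matrix_fully_explained_by_pc1(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([0.5, -1.0, 2.0])
        with pytest.warns(UserWarning, match="rank"):
            res = fit_pca(np.outer(u, v), n_components=2)
        assert res.n_components == 1
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(5)
        X = rng.random((8, 4))
        res = fit_pca(X, n_components=3)
        evals, evecs = np.linalg.eigh(np.cov(X.T, ddof=1))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(3):
            v = evecs[:, j]
            # compare up to sign
            dot = abs(float(v @ res.loadings[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-10)
            # score variance along the component equals the eigenvalue
            assert res.scores[:, j].var(ddof=1) == pytest.approx(evals[j], rel=1e-10)

    def test_matches_sklearn_reference(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(9)
        X = rng.random((20, 6))
        res = fit_pca(X, n_components=4)
        sk = sklearn_pca(n_components=4).fit(X)
        np.testing.assert_allclose(
            np.abs(res.loadings.T), np.abs(sk.components_), atol=1e-9
        )
        np.testing.assert_allclose(
            res.explained_variance_ratio, sk.explained_variance_ratio_, atol=1e-10
        )

    def test_centered_scores_have_zero_column_means(self):
        X = np.random.default_rng(1).random((12, 5))
        res = fit_pca(X, n_components=3)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_loadings_orthonormal(self):
        X = np.random.default_rng(2).random((10, 6))
        res = fit_pca(X, n_components=4)
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(4), atol=1e-10
        )

    def test_full_rank_reconstruction(self):
        X = np.random.default_rng(3).random((7, 4))
        res = fit_pca(X)
        np.testing.assert_allclose(
            res.scores @ res.loadings.T + res.center, X, atol=1e-8
        )

    def test_explained_variance_sums_to_total(self):
        X = np.random.default_rng(4).random((9, 5))
        res = fit_pca(X)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, rel=1e-8)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-15)

    def test_deterministic_sign_convention(self):
        X = np.random.default_rng(6).random((10, 5))
        a, b = fit_pca(X, 3), fit_pca(X.copy(), 3)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        for j in range(3):
            i = np.argmax(np.abs(a.loadings[:, j]))
            assert a.loadings[i, j] > 0

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_pca(np.ones((5, 3)))


class TestMSQPCA:
    def test_identical_lots_score_at_origin(self, flat_bundle):
        ds, _, _ = flat_bundle
        per_lot = per_lot_decomposition(ds)
        with pytest.raises(DegenerateDataError):
            msq_pca(per_lot, "replicate")

    def test_inflated_lot_deviates_most(self):
        cfg = small_config(
            bwc_sd_subsample=0.3,
            bwc_lot_sd_scale={"L02": 8.0},
            variance_components={"lot": 0.0, "subsample": 0.0,
                                 "replicate": 1e-5, "scan": 1e-5},
            scatter_slope_sd=0.0, scatter_offset_sd=0.0,
        )
        ds, _, _ = generate_dataset(cfg)
        res = msq_pca(per_lot_decomposition(ds), "subsample", n_components=2)
        dist = np.linalg.norm(res.scores[:, :2], axis=1)
        lots = res.row_labels["lot"].to_numpy()
        assert lots[np.argmax(dist)] == "L02"

    def test_water_driven_loadings_peak_at_water_bands(self):
        # when subsample-level variability is purely water-driven, the PC1
        # loading magnitude must peak near the O-H bands (~6,950 / ~5,150)
        cfg = small_config(
            bwc_sd_subsample=0.5,
            variance_components={"lot": 0.0, "subsample": 0.0,
                                 "replicate": 0.0, "scan": 0.0},
            scatter_slope_sd=0.0, scatter_offset_sd=0.0, additive_noise_sd=1e-5,
        )
        ds, _, _ = generate_dataset(cfg)
        res = msq_pca(per_lot_decomposition(ds), "subsample", n_components=2)
        peak_wn = ds.axis[np.argmax(np.abs(res.loadings[:, 0]))]
        assert min(abs(peak_wn - 5189.0), abs(peak_wn - 6950.0)) < 150.0


class TestSubsampleMeanPCA:
    def test_study_shape_gives_16x8_rows(self):
        ds, _, _ = generate_dataset(small_config(n_lots=16, n_scans_per_replicate=3))
        res = subsample_mean_pca(ds)
        assert res.scores.shape[0] == 16 * 8

    def test_degenerate_on_identical_spectra(self, flat_bundle):
        ds, _, _ = flat_bundle
        with pytest.raises(DegenerateDataError):
            subsample_mean_pca(ds)

    def test_composes_with_fit_pca_on_mean_matrix(self, small_bundle):
        ds, _, _ = small_bundle
        corrected, _ = msc(ds)
        res = subsample_mean_pca(corrected, n_components=2)
        means = (
            pd.DataFrame(corrected.absorbance)
            .groupby(
                [corrected.labels["lot"], corrected.labels["subsample"],
                 corrected.labels["replicate"]],
                sort=True,
            )
            .mean()
            .to_numpy()
        )
        direct = fit_pca(means, n_components=2)
        np.testing.assert_allclose(res.scores, direct.scores, atol=1e-10)


class TestEllipses:
    def test_identical_points_give_zero_radii(self):
        res = fit_pca(np.random.default_rng(0).random((8, 4)), 2)
        pts = np.zeros((8, 2))
        pts[:, 0] = 1.5
        res.scores = pts
        ell = lot_ellipses(res, lots=np.array(["x"] * 8))
        assert len(ell) == 1
        np.testing.assert_allclose(ell[0].radii, 0.0, atol=1e-12)
        np.testing.assert_allclose(ell[0].center, [1.5, 0.0])

    def test_gaussian_cloud_recovers_axes_and_standard_errors(self):
        rng = np.random.default_rng(12)
        n = 400
        pts = np.column_stack([rng.normal(0, 3.0, n), rng.normal(0, 1.0, n)])
        res = fit_pca(np.random.default_rng(0).random((n, 4)), 2)
        res.scores = pts
        (e,) = lot_ellipses(res, lots=np.array(["g"] * n))
        angle = np.degrees(np.arctan2(e.directions[0, 1], e.directions[0, 0]))
        assert min(abs(angle), abs(180 - abs(angle))) < 5.0
        assert abs(e.radii[0] - 3.0 / np.sqrt(n)) / (3.0 / np.sqrt(n)) < 0.15
        assert abs(e.radii[1] - 1.0 / np.sqrt(n)) / (1.0 / np.sqrt(n)) < 0.15

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(13)
        pts = np.column_stack([rng.normal(0, 2.0, 50), rng.normal(0, 0.5, 50)])
        res = fit_pca(rng.random((50, 4)), 2)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        res.scores = pts
        (e1,) = lot_ellipses(res, lots=np.array(["g"] * 50))
        res.scores = pts @ R.T
        (e2,) = lot_ellipses(res, lots=np.array(["g"] * 50))
        np.testing.assert_allclose(e2.radii, e1.radii, atol=1e-8)
        for j in range(2):
            rotated = R @ e1.directions[j]
            assert abs(abs(rotated @ e2.directions[j]) - 1.0) < 1e-8

    def test_single_point_lot_skipped_with_warning(self):
        res = fit_pca(np.random.default_rng(0).random((3, 4)), 2)
        with pytest.warns(UserWarning, match="single point"):
            ell = lot_ellipses(res, lots=np.array(["a", "a", "b"]))
        assert [e.lot for e in ell] == ["a"]


class TestReplicateDistance:
    def test_identical_replicates_give_zero_distance(self):
        res = fit_pca(np.random.default_rng(0).random((4, 5)), 2)
        res.scores = np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0], [3.0, 4.0]])
        labels = pd.DataFrame(
            {"lot": ["A"] * 4, "subsample": ["s1", "s1", "s2", "s2"],
             "replicate": ["t1", "t2", "t1", "t2"]}
        )
        d = replicate_distance(res, labels)
        assert d.set_index("subsample")["distance"]["s1"] == pytest.approx(0.0)
        assert d.set_index("subsample")["distance"]["s2"] == pytest.approx(5.0)

    def test_doubling_spectra_doubles_distances(self, small_bundle):
        ds, _, _ = small_bundle
        r1 = replicate_distance(subsample_mean_pca(ds, 2))
        doubled = ds.copy()
        doubled.absorbance *= 2.0
        r2 = replicate_distance(subsample_mean_pca(doubled, 2))
        np.testing.assert_allclose(r2["distance"], 2.0 * r1["distance"], rtol=1e-8)

    def test_odd_replicate_counts_skipped(self):
        res = fit_pca(np.random.default_rng(0).random((3, 5)), 2)
        labels = pd.DataFrame(
            {"lot": ["A"] * 3, "subsample": ["s1", "s1", "s2"],
             "replicate": ["t1", "t2", "t1"]}
        )
        with pytest.warns(UserWarning, match="skipped"):
            d = replicate_distance(res, labels)
        assert list(d["subsample"]) == ["s1"]
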