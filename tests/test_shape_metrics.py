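"""Distances, within-lake variation and ordinations."""

import numpy as np
import pytest
from conftest import brute_force_mahalanobis, make_shape_data

import craterlakes as cl
from craterlakes import shape_metrics as sm


class TestProcrustesDistance:
    def test_same_group_zero(self):
        sh = make_shape_data({"a": None, "b": None}, seed=1)
        assert sm.procrustes_distance(sh, "a", "a") == 0.0

    def test_single_coordinate_offset(self):
        off = np.zeros(24)
        off[5] = 0.7
        sh = make_shape_data({"a": None, "b": off}, noise=0.0)
        assert sm.procrustes_distance(sh, "a", "b") == pytest.approx(0.7, abs=1e-12)

    def test_planted_offset_recovered_through_pipeline(self, unit_base):
        d = cl.elongation_offset(1e-4, unit_base)
        spec = cl.SyntheticLandmarkSpec(
            base_shape=unit_base,
            groups=[
                cl.GroupSpec("crater", 10, d),
                cl.GroupSpec("source", 10, -d),
            ],
            landmark_noise_sd=0.0,
        )
        ds = cl.generate_landmark_dataset(spec, seed=5)
        aligned = cl.gpa(ds)
        sh = aligned.as_shape_data()
        assert sm.procrustes_distance(sh, "crater", "source") == pytest.approx(
            2e-4, abs=1e-6
        )

    def test_unknown_group(self):
        sh = make_shape_data({"a": None, "b": None})
        with pytest.raises(KeyError):
            sm.procrustes_distance(sh, "a", "zzz")


class TestMahalanobis:
    def test_identical_groups_zero(self):
        sh = make_shape_data({"a": None}, n=30, seed=3)
        sh2 = cl.ShapeData(
            np.vstack([sh.coords, sh.coords]),
            np.array(["a"] * 30 + ["b"] * 30, dtype=object),
        )
        assert sm.mahalanobis_distance(sh2, "a", "b") == pytest.approx(0.0, abs=1e-10)

    def test_two_variable_closed_form(self):
        # isotropic unit covariance, mean gap (3, 4) -> distance 5
        rng = np.random.default_rng(0)
        base = rng.normal(size=(2000, 2))
        base = (base - base.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(base.T)).T)
        sh = cl.ShapeData(
            np.vstack([base, base + [3.0, 4.0]]),
            np.array(["a"] * 2000 + ["b"] * 2000, dtype=object),
        )
        d = sm.mahalanobis_distance(sh, "a", "b")
        assert d == pytest.approx(5.0, rel=1e-6)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        xa = rng.normal(size=(5, 6))
        xb = rng.normal(0.5, 1.0, size=(5, 6))
        sh = cl.ShapeData(
            np.vstack([xa, xb]), np.array(["a"] * 5 + ["b"] * 5, dtype=object)
        )
        r = min(6, 10 - 2)
        assert sm.mahalanobis_distance(sh, "a", "b") == pytest.approx(
            brute_force_mahalanobis(xa, xb, r), abs=1e-9
        )

    def test_symmetry_and_nonnegativity(self):
        sh = make_shape_data({"a": None, "b": np.ones(24) * 0.2}, seed=4)
        d1 = sm.mahalanobis_distance(sh, "a", "b")
        d2 = sm.mahalanobis_distance(sh, "b", "a")
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert d1 >= 0


class TestShapeVariance:
    def make_lakes(self, unit_base, sds, n=25, seed=0):
        groups = [
            cl.GroupSpec(f"lake{i}", n, np.zeros(24))
            for i in range(len(sds))
        ]
        configs = []
        for i, sd in enumerate(sds):
            spec = cl.SyntheticLandmarkSpec(
                base_shape=unit_base,
                groups=[groups[i]],
                landmark_noise_sd=sd,
            )
            configs += cl.generate_landmark_dataset(spec, seed=seed + i).configurations
        return cl.LandmarkDataset(configs)

    def test_identical_specimens_zero(self, unit_base):
        cfg = [
            cl.LandmarkConfiguration(f"s{i}", unit_base, lake="L", group="L")
            for i in range(5)
        ]
        assert sm.shape_variance(cl.LandmarkDataset(cfg), "L") == pytest.approx(
            0.0, abs=1e-16
        )

    def test_scales_with_noise_variance(self, unit_base):
        sds = [0.005, 0.01, 0.02, 0.04, 0.06]
        ds = self.make_lakes(unit_base, sds, n=60)
        est = [sm.shape_variance(ds, f"lake{i}") for i in range(5)]
        x = np.array(sds) ** 2
        r = np.corrcoef(x, est)[0, 1]
        assert r**2 > 0.99

    def test_independent_of_other_lakes(self, unit_base):
        ds = self.make_lakes(unit_base, [0.01, 0.05])
        solo = cl.LandmarkDataset(
            [c for c in ds.configurations if c.lake == "lake0"]
        )
        assert sm.shape_variance(ds, "lake0") == pytest.approx(
            sm.shape_variance(solo, "lake0"), abs=1e-12
        )

    def test_unknown_lake(self, unit_base):
        ds = self.make_lakes(unit_base, [0.01])
        with pytest.raises(KeyError):
            sm.shape_variance(ds, "atlantis")


class TestElongationCV:
    def make_with_ei(self, eis, unit_base):
        # stretch x by factor so that dist(0,6)/dist(3,9) hits target EI
        configs = []
        base_sl = np.linalg.norm(unit_base[0] - unit_base[6])
        base_bh = np.linalg.norm((unit_base[3] - unit_base[9])[1])
        for i, ei in enumerate(eis):
            c = unit_base.copy()
            c[:, 0] *= ei / (base_sl / np.linalg.norm(unit_base[3] - unit_base[9]))
            configs.append(
                cl.LandmarkConfiguration(f"s{i}", c, lake="L", group="L")
            )
        return cl.LandmarkDataset(configs)

    def test_constant_ei_zero(self, unit_base):
        cfg = [
            cl.LandmarkConfiguration(f"s{i}", unit_base * (1 + 0.1 * i), lake="L")
            for i in range(4)
        ]
        assert cl.elongation_cv(cl.LandmarkDataset(cfg), "L") == pytest.approx(
            0.0, abs=1e-9
        )

    def test_hand_computed_cv(self):
        # EI values {1.8, 2.0, 2.2}: sample sd 0.2, mean 2.0 -> CV = 10.0
        configs = []
        for i, ei in enumerate([1.8, 2.0, 2.2]):
            coords = np.zeros((12, 2))
            coords[0] = [0.0, 0.0]
            coords[6] = [ei, 0.0]
            coords[3] = [0.5, 0.5]
            coords[9] = [0.5, -0.5]
            coords[1] = [0.1, 0.2]  # break coincidence of unused landmarks
            for j in (2, 4, 5, 7, 8, 10, 11):
                coords[j] = [0.01 * j, -0.01 * j]
            configs.append(cl.LandmarkConfiguration(f"s{i}", coords, lake="L"))
        cv = cl.elongation_cv(cl.LandmarkDataset(configs), "L")
        assert cv == pytest.approx(10.0, abs=1e-9)

    def test_scale_invariance(self, unit_base):
        rng = np.random.default_rng(2)
        cfg1 = [
            cl.LandmarkConfiguration(
                f"s{i}", unit_base + rng.normal(0, 0.01, (12, 2)), lake="L"
            )
            for i in range(6)
        ]
        cfg2 = [
            cl.LandmarkConfiguration(c.specimen_id, c.coords * (i + 1.0), lake="L")
            for i, c in enumerate(cfg1)
        ]
        cv1 = cl.elongation_cv(cl.LandmarkDataset(cfg1), "L")
        cv2 = cl.elongation_cv(cl.LandmarkDataset(cfg2), "L")
        assert cv1 == pytest.approx(cv2, rel=1e-12)

    def test_zero_body_height_names_specimen(self):
        coords = np.zeros((12, 2))
        coords[0] = [0, 0]
        coords[6] = [2, 0]
        for j in range(1, 12):
            if j not in (3, 9):
                coords[j] = [0.1 * j, 0.1]
        coords[3] = coords[9] = [1.0, 0.0]
        ds = cl.LandmarkDataset(
            [cl.LandmarkConfiguration("flatfish", coords, lake="L")]
        )
        with pytest.raises(ValueError, match="flatfish"):
            cl.elongation_cv(ds, "L")


class TestPCA:
    def test_single_axis_of_variation(self):
        t = np.linspace(-1, 1, 20)
        direction = np.zeros(24)
        direction[[0, 5]] = [3.0, 4.0]
        coords = np.outer(t, direction)
        sh = cl.ShapeData(coords, np.array(["g"] * 20, dtype=object))
        res = sm.pca(sh)
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_identity(self):
        sh = make_shape_data({"a": None, "b": np.ones(24) * 0.3}, n=15, seed=8)
        res = sm.pca(sh)
        np.testing.assert_allclose(res.reconstruct(), sh.coords, atol=1e-9)

    def test_axes_orthonormal_variance_sums_to_one(self):
        sh = make_shape_data({"a": None}, n=40, seed=9)
        res = sm.pca(sh)
        np.testing.assert_allclose(res.axes.T @ res.axes, np.eye(24), atol=1e-9)
        assert res.variance_explained.sum() <= 1 + 1e-9

    def test_sign_convention(self):
        sh = make_shape_data({"a": None}, n=40, seed=10)
        res = sm.pca(sh)
        for j in range(res.axes.shape[1]):
            col = res.axes[:, j]
            assert col[np.argmax(np.abs(col))] >= 0


class TestBetweenGroupPCA:
    def test_collinear_group_means(self):
        d = np.zeros(24)
        d[2] = 1.0
        sh = make_shape_data(
            {"a": 0 * d, "b": 1 * d, "c": 2 * d}, n=10, noise=0.0, seed=11
        )
        res = sm.between_group_pca(sh)
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_pca_when_every_specimen_its_own_group(self):
        rng = np.random.default_rng(12)
        coords = rng.normal(size=(10, 6))
        groups = np.array([f"s{i}" for i in range(10)], dtype=object)
        sh = cl.ShapeData(coords, groups)
        bg = sm.between_group_pca(sh)
        p = sm.pca(sh)
        k = min(bg.axes.shape[1], 9)
        np.testing.assert_allclose(
            np.abs(bg.axes[:, :k]), np.abs(p.axes[:, :k]), atol=1e-9
        )
        np.testing.assert_allclose(
            bg.variance_explained[:k],
            p.variance_explained[:k] / p.variance_explained[:k].sum()
            * bg.variance_explained[:k].sum(),
            atol=1e-9,
        )

    def test_needs_three_groups(self):
        sh = make_shape_data({"a": None, "b": None})
        with pytest.raises(ValueError):
            sm.between_group_pca(sh)

    def test_group_mean_scores_shape(self):
        sh = make_shape_data({"a": None, "b": None, "c": None}, n=8, seed=13)
        res = sm.between_group_pca(sh)
        assert list(res.group_mean_scores.index) == ["a", "b", "c"]
        assert res.scores.shape == (24, res.axes.shape[1])
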