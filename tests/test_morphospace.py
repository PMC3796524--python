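"""Morphospace statistics: PCA, distances, BCa bootstrap, ellipses, overlap."""

import numpy as np
import pytest

from murimorph.morphospace import (
    bca_bootstrap_ci,
    concentration_ellipse,
    distance_between_means,
    distance_from_basal,
    ellipse_overlap,
    ellipse_polygon,
    pca_covariance,
    rule_of_eye,
    select_pcs,
    ConcentrationEllipse,
)


class TestPCA:
    def test_trace_conservation_and_distance_preservation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 6)) @ np.diag([3, 2, 1, 1, 0.5, 0.1])
        pca = pca_covariance(x)
        total = np.var(x, axis=0, ddof=1).sum()
        assert np.isclose(pca.eigenvalues.sum(), total, atol=1e-8)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(pca.scores), pdist(x), atol=1e-8)

    def test_spherical_noise_spreads_variance(self):
        rng = np.random.default_rng(1)
        pca = pca_covariance(rng.normal(size=(2000, 8)))
        prop = pca.proportion_variance
        assert prop.max() / prop.min() < 1.3

    def test_planted_direction_recovered(self):
        rng = np.random.default_rng(2)
        direction = np.array([3.0, 4.0, 0.0, 0.0]) / 5.0
        shift = np.where(rng.random(500) < 0.5, -1.0, 1.0)
        x = rng.normal(0, 0.2, size=(500, 4)) + np.outer(shift, direction)
        pca = pca_covariance(x)
        assert abs(pca.loadings[:, 0] @ direction) > 0.95

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            pca_covariance(np.zeros((2, 3)))


class TestSelectPCs:
    @pytest.mark.parametrize(
        "threshold,expected", [(0.7, 1), (0.75, 2), (1.0, 2)]
    )
    def test_three_one_eigenvalues(self, threshold, expected):
        from murimorph.morphospace import PCAResult

        pca = PCAResult(
            eigenvalues=np.array([3.0, 1.0]),
            loadings=np.eye(2),
            scores=np.zeros((4, 2)),
            proportion_variance=np.array([0.75, 0.25]),
        )
        assert select_pcs(pca, threshold) == expected


class TestDistances:
    def test_same_group_zero_and_345(self):
        scores = np.array([[0.0, 0], [0, 0], [3, 4], [3, 4]])
        labels = np.array(["a", "a", "b", "b"])
        assert distance_between_means(scores, labels, "a", "a", 2) == 0.0
        assert distance_between_means(scores, labels, "a", "b", 2) == pytest.approx(5.0)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(60, 5))
        labels = np.repeat(["a", "b", "c"], 20)
        dab = distance_between_means(scores, labels, "a", "b", 5)
        dba = distance_between_means(scores, labels, "b", "a", 5)
        dac = distance_between_means(scores, labels, "a", "c", 5)
        dcb = distance_between_means(scores, labels, "c", "b", 5)
        assert dab == pytest.approx(dba)
        assert dab <= dac + dcb + 1e-12

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            distance_between_means(np.zeros((4, 2)), np.array(["a"] * 4), "a", "zz", 2)

    def test_basal_table_anchors(self):
        rng = np.random.default_rng(4)
        scores = np.vstack(
            [rng.normal(0, 0.01, (10, 3)) + off for off in ([0, 0, 0], [1, 0, 0], [2, 0, 0])]
        )
        labels = np.repeat(["basal", "mid", "far"], 10)
        table = distance_from_basal(scores, labels, "basal", 3, reference_group="far")
        by = table.set_index("group")
        assert by.loc["basal", "distance"] == 0.0
        assert by.loc["basal", "percent_change"] == 0.0
        assert by.loc["far", "percent_change"] == pytest.approx(100.0)
        assert 0 < by.loc["mid", "percent_change"] < 100


class TestBCa:
    def test_constant_data_degenerate(self):
        with pytest.warns(UserWarning):
            lo, hi = bca_bootstrap_ci(np.full(20, 3.3), np.mean, n_boot=200, seed=0)
        assert lo == hi == pytest.approx(3.3)

    def test_matches_scipy_bca(self):
        """Independent oracle: scipy.stats.bootstrap with method='BCa'."""
        from scipy.stats import bootstrap

        rng = np.random.default_rng(5)
        data = rng.normal(1.0, 2.0, size=60)
        lo, hi = bca_bootstrap_ci(data, np.mean, n_boot=4999, seed=10, vectorized=True)
        ref = bootstrap(
            (data,), np.mean, n_resamples=4999, method="BCa",
            confidence_level=0.95, random_state=np.random.default_rng(10),
        ).confidence_interval
        assert lo == pytest.approx(ref.low, abs=0.08)
        assert hi == pytest.approx(ref.high, abs=0.08)

    def test_stratified_distance_statistic(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.1, size=(25, 3))
        b = rng.normal(0, 0.1, size=(25, 3)) + [1.0, 0, 0]

        def stat(xa, xb):
            return float(np.linalg.norm(xa.mean(axis=0) - xb.mean(axis=0)))

        lo, hi = bca_bootstrap_ci((a, b), stat, n_boot=999, seed=7)
        assert lo < stat(a, b) < hi
        assert 0.8 < lo and hi < 1.2

    def test_small_nboot_warns(self):
        with pytest.warns(UserWarning):
            bca_bootstrap_ci(np.arange(10.0), np.mean, n_boot=50, seed=1)


class TestRuleOfEye:
    @pytest.mark.parametrize(
        "ci_a,ci_b,expected",
        [
            ((0, 1), (2, 3), True),  # disjoint
            ((0, 2), (0, 2), False),  # identical
            ((0, 2), (1.6, 3.6), True),  # overlap 0.4 < half-width mean 1 * 0.5
            ((0, 2), (1.4, 3.4), False),  # overlap 0.6 > 0.5
        ],
    )
    def test_cases(self, ci_a, ci_b, expected):
        assert rule_of_eye(ci_a, ci_b) is expected


class TestEllipses:
    def test_containment_calibration(self):
        rng = np.random.default_rng(8)
        pts = rng.multivariate_normal([0, 0], [[2.0, 0.7], [0.7, 1.0]], size=20000)
        ell = concentration_ellipse(pts, 0.55)
        poly = ellipse_polygon(ell)
        from shapely.geometry import Point

        inside = np.fromiter(
            (poly.contains(Point(p)) for p in pts[:5000]), bool, count=5000
        )
        assert inside.mean() == pytest.approx(0.55, abs=0.03)

    def test_isotropy_and_homogeneity(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(5000, 2))
        ell = concentration_ellipse(pts, 0.55)
        assert ell.axes[0] / ell.axes[1] < 1.1
        ell2 = concentration_ellipse(2 * pts, 0.55)
        assert np.allclose(ell2.axes, 2 * ell.axes)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        with pytest.raises(ValueError):
            concentration_ellipse(pts)

    def test_overlap_identical_and_disjoint(self):
        e1 = ConcentrationEllipse(center=np.zeros(2), axes=np.array([1.0, 0.5]), orientation=0.3)
        e2 = ConcentrationEllipse(center=np.array([10.0, 0]), axes=np.array([1.0, 0.5]), orientation=0.0)
        assert ellipse_overlap([e1, e1]) == pytest.approx(1.0, abs=1e-6)
        assert ellipse_overlap([e1, e2]) == 0.0

    def test_circle_lens_closed_form(self):
        """Two unit circles one radius apart: IoU from the analytic lens area."""
        c1 = ConcentrationEllipse(center=np.zeros(2), axes=np.ones(2), orientation=0.0)
        c2 = ConcentrationEllipse(center=np.array([1.0, 0]), axes=np.ones(2), orientation=0.0)
        lens = 2 * np.arccos(0.5) - 0.5 * np.sqrt(3)
        expected = lens / (2 * np.pi - lens)
        assert ellipse_overlap([c1, c2]) == pytest.approx(expected, abs=1e-3)

    def test_overlap_rigid_motion_invariant(self):
        e1 = ConcentrationEllipse(center=np.zeros(2), axes=np.array([1.0, 0.6]), orientation=0.2)
        e2 = ConcentrationEllipse(center=np.array([0.8, 0.3]), axes=np.array([0.9, 0.5]), orientation=1.0)
        base = ellipse_overlap([e1, e2])
        theta = 0.77
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = [
            ConcentrationEllipse(
                center=rot @ e.center + [5, -2], axes=e.axes, orientation=e.orientation + theta
            )
            for e in (e1, e2)
        ]
        assert ellipse_overlap(moved) == pytest.approx(base, abs=1e-6)
        assert ellipse_overlap([e2, e1]) == pytest.approx(base, abs=1e-12)

    def test_three_ellipse_overlap(self):
        mk = lambda x: ConcentrationEllipse(center=np.array([x, 0.0]), axes=np.ones(2), orientation=0.0)
        # only the first pair overlaps; the third is far away
        prop = ellipse_overlap([mk(0.0), mk(1.0), mk(10.0)])
        lens = 2 * np.arccos(0.5) - 0.5 * np.sqrt(3)
        union = 3 * np.pi - lens
        assert prop == pytest.approx(lens / union, abs=1e-3)
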