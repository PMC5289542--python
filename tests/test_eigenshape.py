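import math

import numpy as np
import pytest

from eigenvault.eigenshape import (
    PhiFunction,
    eigenshape_decompose,
    inverse_phi,
    outline_from_angles,
    phi_transform,
    project,
    segment_layout,
    segment_submodel,
    shape_model,
    tangent_angles,
    ternary_coordinates,
)


def random_smooth_curve(rng, n=30):
    """A non-self-overlapping open curve with gentle turning angles."""
    turn = rng.uniform(-0.4, 0.4, size=n - 2)
    steps = rng.uniform(0.5, 1.5, size=n - 1)
    ang = np.concatenate([[rng.uniform(-math.pi, math.pi)], turn]).cumsum()
    pts = np.vstack([[0, 0], np.cumsum(
        steps[:, None] * np.column_stack([np.cos(ang), np.sin(ang)]), axis=0)])
    return pts + rng.normal(size=2)


class TestPhiTransform:
    def test_collinear_points_have_zero_phi(self):
        pts = [(i, 2.0 * i) for i in range(6)]
        phi = phi_transform(pts)
        np.testing.assert_allclose(phi.values, 0.0, atol=1e-12)

    def test_closed_convex_polygon_turns_two_pi(self):
        theta = np.linspace(0, 2 * math.pi, 101)  # anti-clockwise, closed
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        phi = phi_transform(pts, open=False)
        # total turning = last cumulative value + the closing turn
        total = phi.values[-1]
        closing = 2 * math.pi / 100  # one more equal exterior angle
        assert total + closing == pytest.approx(2 * math.pi, abs=1e-9)

    def test_quarter_circle_total_curvature(self):
        # the open polyline's accumulated turning omits the two endpoint
        # tangents, so the discretization error is (pi/2)/n_arcs
        theta = np.linspace(0, math.pi / 2, 2001)
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        phi = phi_transform(pts)
        assert phi.values[-1] == pytest.approx(math.pi / 2, abs=1e-3)

    def test_coincident_consecutive_points_error(self):
        with pytest.raises(ValueError, match="index 1"):
            phi_transform([(0, 0), (1, 0), (1, 0), (2, 0)])

    def test_invariant_to_rigid_motion(self, rng):
        pts = random_smooth_curve(rng)
        ang = 0.7
        R = np.array([[math.cos(ang), -math.sin(ang)],
                      [math.sin(ang), math.cos(ang)]])
        moved = pts @ R.T + [5, -3]
        np.testing.assert_allclose(
            phi_transform(moved).values, phi_transform(pts).values, atol=1e-10
        )


class TestInversePhi:
    def test_zero_phi_unit_steps_is_straight_line(self):
        phi = PhiFunction(values=np.zeros(3), step_lengths=np.ones(4),
                          start_point=(0, 0), start_angle=0.0)
        pts = inverse_phi(phi)
        np.testing.assert_allclose(pts, [(i, 0) for i in range(5)], atol=1e-12)

    def test_roundtrip_on_seeded_random_curves(self, rng):
        for _ in range(50):
            pts = random_smooth_curve(rng)
            back = inverse_phi(phi_transform(pts))
            np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_phi_of_reconstruction_matches(self, rng):
        pts = random_smooth_curve(rng)
        phi = phi_transform(pts)
        phi2 = phi_transform(inverse_phi(phi))
        np.testing.assert_allclose(phi2.values, phi.values, atol=1e-9)

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            PhiFunction(values=np.zeros(3), step_lengths=np.ones(3),
                        start_point=(0, 0), start_angle=0.0)

    def test_tangent_angle_roundtrip(self, rng):
        pts = random_smooth_curve(rng)
        theta = tangent_angles(pts)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        back = outline_from_angles(theta, steps, start_point=tuple(pts[0]))
        np.testing.assert_allclose(back, pts, atol=1e-9)


class TestDecompose:
    def test_variance_fractions_sum_to_one(self, rng):
        X = rng.normal(size=(8, 15))
        model = eigenshape_decompose(X)
        assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(model.variance_fractions) <= 1e-12)

    def test_eigenshapes_orthonormal_and_scores_centered(self, rng):
        model = eigenshape_decompose(rng.normal(size=(10, 12)))
        gram = model.eigenshapes @ model.eigenshapes.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0.0, atol=1e-8)

    def test_duplicated_specimen_set_same_axes(self, rng):
        X = rng.normal(size=(6, 10))
        m1 = eigenshape_decompose(X)
        m2 = eigenshape_decompose(np.vstack([X, X]))
        k = min(len(m1.eigenvalues), 5)
        np.testing.assert_allclose(
            np.abs(m2.eigenshapes[:k]), np.abs(m1.eigenshapes[:k]), atol=1e-8
        )
        np.testing.assert_allclose(
            m2.variance_fractions[:k], m1.variance_fractions[:k], atol=1e-8
        )

    def test_two_generating_modes_recovered(self, rng):
        # data = mean + a*v1 + b*v2 with orthonormal v1, v2
        p = 20
        v1 = np.zeros(p); v1[:10] = 1 / math.sqrt(10)
        v2 = np.zeros(p); v2[10:] = 1 / math.sqrt(10)
        a = rng.normal(0, 3, size=9)
        b = rng.normal(0, 1, size=9)
        X = 5.0 + np.outer(a, v1) + np.outer(b, v2)
        model = eigenshape_decompose(X)
        assert np.sum(model.eigenvalues > 1e-20) == 2
        # oracle: brute-force covariance eigendecomposition
        cov = np.cov(X, rowvar=False)
        ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(model.eigenvalues, ev[: len(model.eigenvalues)],
                                   atol=1e-8)
        for axis in model.eigenshapes[:2]:
            proj = abs(axis @ v1) ** 2 + abs(axis @ v2) ** 2
            assert proj == pytest.approx(1.0, abs=1e-8)

    def test_constant_data_flagged_as_zero_variance(self):
        X = np.ones((5, 7))
        model = eigenshape_decompose(X)
        np.testing.assert_allclose(model.eigenvalues, 0.0, atol=1e-20)
        assert model.variance_fractions.sum() == 0.0


class TestProjectAndShapes:
    def test_mean_projects_to_zero(self, rng):
        model = eigenshape_decompose(rng.normal(size=(7, 9)))
        np.testing.assert_allclose(project(model, model.mean_phi), 0.0, atol=1e-12)

    def test_training_scores_reproduced(self, rng):
        X = rng.normal(size=(7, 9))
        model = eigenshape_decompose(X)
        for i in range(len(X)):
            np.testing.assert_allclose(project(model, X[i]), model.scores[i],
                                       atol=1e-10)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(8, 5))  # full rank: k = p = 5
        model = eigenshape_decompose(X)
        for i in range(len(X)):
            s = project(model, X[i])
            back = model.mean_phi + s @ model.eigenshapes
            np.testing.assert_allclose(back, X[i], atol=1e-8)

    def test_shape_model_score_zero_is_mean(self, rng):
        pts = random_smooth_curve(rng, n=12)
        phis = np.array([tangent_angles(pts + 0.01 * rng.normal(size=pts.shape))
                         for _ in range(5)])
        model = eigenshape_decompose(phis)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        mean_curve = shape_model(model, 0, 0.0, steps)
        oracle = outline_from_angles(model.mean_phi, steps)
        np.testing.assert_allclose(mean_curve, oracle, atol=1e-12)

    def test_symmetric_displacements_about_mean(self, rng):
        model = eigenshape_decompose(rng.normal(size=(6, 8)))
        plus = model.mean_phi + 2.0 * model.eigenshapes[0]
        minus = model.mean_phi - 2.0 * model.eigenshapes[0]
        np.testing.assert_allclose(plus + minus, 2 * model.mean_phi, atol=1e-12)

    def test_axis_out_of_range(self, rng):
        model = eigenshape_decompose(rng.normal(size=(5, 6)))
        with pytest.raises(ValueError):
            shape_model(model, 99, 1.0, np.ones(7))


class TestSegments:
    def test_layout_partitions_chords(self):
        counts = {"occipital": 61, "parietal": 71, "frontal": 70}
        layout = segment_layout(counts, ("occipital", "parietal", "frontal"))
        assert layout["occipital"] == (0, 60)
        assert layout["parietal"] == (60, 130)
        assert layout["frontal"] == (130, 199)

    def test_single_segment_layout_equals_whole_decomposition(self, rng):
        X = rng.normal(size=(6, 14))
        whole = eigenshape_decompose(X)
        sub = segment_submodel(X, {"all": (0, 14)}, "all")
        np.testing.assert_allclose(sub.eigenvalues, whole.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(sub.scores, whole.scores, atol=1e-8)

    def test_submodel_fractions_sum_to_one(self, rng):
        X = rng.normal(size=(6, 20))
        layout = {"frontal": (0, 8), "parietal": (8, 20)}
        for name in layout:
            sub = segment_submodel(X, layout, name)
            assert sub.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_unknown_segment_error(self, rng):
        with pytest.raises(ValueError, match="unknown segment"):
            segment_submodel(rng.normal(size=(5, 6)), {"frontal": (0, 6)}, "nasal")

    def test_variation_localizes_to_deformed_segment(self, rng):
        # deform only columns of the "parietal" block beyond a common noise floor
        n, p = 12, 30
        layout = {"frontal": (0, 10), "parietal": (10, 20), "occipital": (20, 30)}
        X = 0.01 * rng.normal(size=(n, p))
        mode = rng.normal(size=10)
        X[:, 10:20] += np.outer(rng.normal(0, 2, size=n), mode / np.linalg.norm(mode))
        par = segment_submodel(X, layout, "parietal")
        fro = segment_submodel(X, layout, "frontal")
        assert par.variance_fractions[0] > fro.variance_fractions[0]


def test_ternary_coordinates_are_barycentric(rng):
    scores = rng.normal(size=(10, 5))
    coords = ternary_coordinates(scores)
    assert coords.shape == (10, 3)
    np.testing.assert_allclose(coords.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(coords >= 0)
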