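"""Marker extraction, landmark transforms, end-to-end channel localisation."""
import numpy as np
import pytest

import phonomap as pm
from phonomap.errors import RegistrationError
from phonomap.fixtures import default_landmarks, similarity_map
from phonomap.registration import (assign_channel_ids, invert_points,
                                   label_landmarks)


def _square_landmarks(source="chest"):
    # joint (top), 10th rib (bottom), right/left 6th ribs (middle)
    return pm.LandmarkSet(points=np.array(
        [[100.0, 20.0], [90.0, 220.0], [30.0, 120.0], [180.0, 120.0]]),
        source=source)


class TestExtractMarkers:
    def test_blank_image_gives_nothing(self):
        img = pm.render_marker_image(80, 60, [])
        assert pm.extract_markers(img, pm.RED_DISC).shape == (0, 2)

    def test_four_red_discs_recovered_within_1px(self):
        truth = [(30.2, 25.7), (150.8, 30.1), (40.5, 160.3), (170.0, 150.9)]
        img = pm.render_marker_image(220, 200,
                                     [(c, 9.0, "red") for c in truth])
        got = pm.extract_markers(img, pm.RED_DISC)
        assert got.shape == (4, 2)
        for c in truth:
            err = np.min(np.linalg.norm(got - np.asarray(c), axis=1))
            assert err < 1.0

    def test_green_spec_ignores_red_discs(self, registration_scene):
        img = registration_scene["chest_image"]
        green = pm.extract_markers(img, pm.GREEN_DISC)
        red = pm.extract_markers(img, pm.RED_DISC)
        assert green.shape == (72, 2)
        assert red.shape == (4, 2)


class TestLabelLandmarks:
    def test_geometric_role_assignment(self):
        pts = np.array([[30.0, 120.0], [180.0, 120.0],
                        [100.0, 20.0], [90.0, 220.0]])
        lm = label_landmarks(pts)
        assert np.allclose(lm.points[0], [100.0, 20.0])   # joint topmost
        assert np.allclose(lm.points[1], [90.0, 220.0])   # 10th rib bottommost
        assert np.allclose(lm.points[2], [30.0, 120.0])   # right 6th: image left
        assert np.allclose(lm.points[3], [180.0, 120.0])

    def test_wrong_count_raises(self):
        with pytest.raises(RegistrationError):
            label_landmarks(np.zeros((3, 2)), source="chest")


class TestEstimateTransform:
    def test_identical_landmarks_give_identity(self):
        chest = _square_landmarks("chest")
        skel = _square_landmarks("skeleton")
        T = pm.estimate_transform(chest, skel)
        assert T.theta2 - T.theta1 == pytest.approx(0.0)
        assert (T.eta_x, T.eta_y) == (pytest.approx(1.0), pytest.approx(1.0))
        assert (T.phi_x, T.phi_y) == (pytest.approx(0.0), pytest.approx(0.0))
        pts = np.array([[12.3, 45.6], [99.0, 140.0]])
        assert np.allclose(pm.transform_points(pts, T), pts)

    def test_pure_doubling_recovered(self):
        chest = _square_landmarks("chest")
        skel = pm.LandmarkSet(points=2.0 * chest.points, source="skeleton")
        T = pm.estimate_transform(chest, skel)
        assert T.theta2 - T.theta1 == pytest.approx(0.0)
        assert T.eta_x == pytest.approx(2.0) and T.eta_y == pytest.approx(2.0)

    def test_rotation_translation_recovered_exactly(self):
        chest = _square_landmarks("chest")
        skel_pts = similarity_map(chest.points, 10.0, 1.0, (30.0, -20.0))
        skel = pm.LandmarkSet(points=skel_pts, source="skeleton")
        T = pm.estimate_transform(chest, skel)
        assert (T.theta2 - T.theta1) == pytest.approx(np.deg2rad(10.0), abs=1e-9)
        assert np.allclose(pm.transform_points(chest.points, T), skel_pts,
                           atol=1e-6)

    def test_degenerate_baseline_raises(self):
        pts = _square_landmarks().points.copy()
        pts[3] = pts[2]
        with pytest.raises(RegistrationError):
            pm.LandmarkSet(points=pts)

    def test_landmark_axis_consistency(self):
        # each equation's own axis must be matched exactly by the estimate
        chest = _square_landmarks("chest")
        skel_pts = similarity_map(chest.points, -6.0, 1.4, (12.0, 80.0))
        skel = pm.LandmarkSet(points=skel_pts, source="skeleton")
        T = pm.estimate_transform(chest, skel)
        mapped = pm.transform_points(chest.points, T)
        assert mapped[2, 0] == pytest.approx(skel_pts[2, 0], abs=1e-9)  # x of lm3
        assert mapped[0, 1] == pytest.approx(skel_pts[0, 1], abs=1e-9)  # y of lm1
        assert (mapped[3, 0] - mapped[2, 0]) == pytest.approx(
            skel_pts[3, 0] - skel_pts[2, 0], abs=1e-9)
        assert (mapped[1, 1] - mapped[0, 1]) == pytest.approx(
            skel_pts[1, 1] - skel_pts[0, 1], abs=1e-9)


class TestTransformPoints:
    def test_grid_round_trip_under_known_similarity(self, grid72):
        chest = pm.LandmarkSet(points=default_landmarks(grid72), source="chest")
        skel = pm.LandmarkSet(points=similarity_map(chest.points, 7.0, 1.3,
                                                    (25.0, 40.0)),
                              source="skeleton")
        T = pm.estimate_transform(chest, skel)
        mapped = pm.transform_points(grid72.coords, T)
        truth = similarity_map(grid72.coords, 7.0, 1.3, (25.0, 40.0))
        assert np.max(np.linalg.norm(mapped - truth, axis=1)) < 0.5

    def test_analytic_inverse_is_exact(self):
        chest = _square_landmarks("chest")
        skel = pm.LandmarkSet(points=similarity_map(chest.points, 13.0, 0.8,
                                                    (-5.0, 60.0)),
                              source="skeleton")
        T = pm.estimate_transform(chest, skel)
        pts = np.array([[7.0, 9.0], [200.0, 111.0], [50.5, 60.5]])
        back = invert_points(pm.transform_points(pts, T), T)
        assert np.max(np.abs(back - pts)) < 1e-9

    def test_literal_mode_matches_printed_arithmetic(self):
        # with theta1 == theta2 == theta the literal step gives
        # w * cos^2(theta) and h * sin^2(theta)
        theta = np.deg2rad(25.0)
        T = pm.SimilarityTransform(theta1=theta, theta2=theta, eta_x=1.0,
                                   eta_y=1.0, phi_x=0.0, phi_y=0.0,
                                   mode="paper_literal")
        pts = np.array([[10.0, 20.0], [-3.0, 7.5]])
        out = pm.transform_points(pts, T)
        assert np.allclose(out[:, 0], pts[:, 0] * np.cos(theta) ** 2)
        assert np.allclose(out[:, 1], pts[:, 1] * np.sin(theta) ** 2)

    def test_literal_mode_is_not_identity_at_zero_angles(self):
        T = pm.SimilarityTransform(theta1=0.0, theta2=0.0, eta_x=1.0,
                                   eta_y=1.0, phi_x=0.0, phi_y=0.0,
                                   mode="paper_literal")
        out = pm.transform_points(np.array([[10.0, 20.0]]), T)
        assert np.allclose(out, [[10.0, 0.0]])  # the y coordinate collapses


class TestLocateChannels:
    def test_end_to_end_recovery_within_1px(self, grid72, registration_scene):
        scene = registration_scene
        layout = pm.locate_channels(scene["chest_image"],
                                    scene["skeleton_image"])
        assert len(layout) == 72
        order = assign_channel_ids(scene["chest_sensors"])
        truth = scene["skeleton_sensors"][order]
        err = np.linalg.norm(layout.coords - truth, axis=1)
        assert err.max() < 1.0

    def test_jittered_landmarks_degrade_gracefully(self, grid72,
                                                   registration_scene):
        scene = registration_scene
        chest_lm = label_landmarks(scene["chest_landmarks"], "chest")
        rng = np.random.default_rng(12)
        jitter = rng.uniform(-1.0, 1.0, (4, 2))
        jitter /= np.maximum(np.linalg.norm(jitter, axis=1, keepdims=True), 1.0)
        skel_lm = label_landmarks(scene["skeleton_landmarks"] + jitter,
                                  "skeleton")
        T = pm.estimate_transform(chest_lm, skel_lm)
        order = assign_channel_ids(scene["chest_sensors"])
        mapped = pm.transform_points(scene["chest_sensors"][order], T)
        truth = scene["skeleton_sensors"][order]
        # landmark radius is 10 px; <= 1 px jitter must stay within radius/2
        assert np.linalg.norm(mapped - truth, axis=1).max() <= 5.0

    def test_missing_landmark_named_in_error(self, registration_scene):
        blank = pm.render_marker_image(100, 100, [])
        with pytest.raises(RegistrationError, match="skeleton image"):
            pm.locate_channels(registration_scene["chest_image"], blank)

    def test_no_sensor_markers_is_an_error(self, registration_scene):
        truth = [(30.0, 25.0), (150.0, 30.0), (40.0, 160.0), (170.0, 150.0)]
        lm_only = pm.render_marker_image(220, 200,
                                         [(c, 9.0, "red") for c in truth])
        with pytest.raises(RegistrationError, match="no sensor markers"):
            pm.locate_channels(lm_only, registration_scene["skeleton_image"])

    def test_row_major_channel_assignment(self):
        pts = np.array([[10.0, 10.2], [50.0, 9.8], [90.0, 10.1],
                        [10.0, 50.0], [50.0, 50.3], [90.0, 49.9]])
        order = assign_channel_ids(pts)
        assert list(order) == [0, 1, 2, 3, 4, 5]
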