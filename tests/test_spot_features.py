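"""Spot numbering, Feret geometry, Procrustes alignment and derived features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from spotmorph.segmentation import LabeledSpots, SpotComponent
from spotmorph.spot_features import (
    CentroidConfiguration,
    QCError,
    SpecimenSpots,
    SpotRecord,
    build_feature_table,
    classify_and_number,
    fold_angle,
    gpa,
    max_feret,
    min_feret,
    spot_metrics,
    sum_central_lateral_distances,
)

# ---------------------------------------------------------------------------
# independent geometric oracles


def brute_force_max_feret(points: np.ndarray) -> float:
    """All-pairs maximum distance over every input point (no hull)."""
    best = 0.0
    pts = np.asarray(points, float)
    for i in range(len(pts)):
        dx = pts[i + 1 :, 0] - pts[i, 0]
        dy = pts[i + 1 :, 1] - pts[i, 1]
        d2 = dx * dx + dy * dy
        if len(d2):
            best = max(best, float(d2.max()))
    return math.sqrt(best)


def rotation_scan_min_feret(points: np.ndarray, coarse_step_deg: float = 0.01) -> float:
    """Projection-width scan over orientations, refined around the best angle."""
    pts = np.asarray(points, float)

    def width(theta_deg: np.ndarray) -> np.ndarray:
        t = np.radians(theta_deg)
        proj = pts[:, 0][:, None] * np.cos(t)[None, :] + pts[:, 1][:, None] * np.sin(t)[None, :]
        return proj.max(axis=0) - proj.min(axis=0)

    coarse = np.arange(0.0, 180.0, coarse_step_deg)
    w = width(coarse)
    j = int(np.argmin(w))
    fine = np.linspace(coarse[j] - coarse_step_deg, coarse[j] + coarse_step_deg, 4001)
    return float(min(w[j], width(fine).min()))


def _random_polygons(n_poly: int, n_vertices: int, seed: int):
    rng = np.random.default_rng(seed)
    return [rng.uniform(0, 10, size=(n_vertices, 2)) for _ in range(n_poly)]


# ---------------------------------------------------------------------------


def _components(centroids):
    return [
        SpotComponent(label=i + 1, pixel_count=100, contour=np.array([[x, y]] * 3, float), centroid=(x, y))
        for i, (x, y) in enumerate(centroids)
    ]


class TestNumbering:
    CENTROIDS = [(500, 200), (500, 400), (100, 150), (900, 160), (110, 300), (890, 310)]

    def _number(self, centroids):
        spots = LabeledSpots(labels=np.zeros((1, 1), int), components=_components(centroids), Ta=1)
        recs = classify_and_number(spots, midline=500.0, body_width=1000.0)
        return {r.centroid: r for r in recs}

    def test_central_then_left_odd_right_even(self):
        by_pos = self._number(self.CENTROIDS)
        expected = dict(zip(self.CENTROIDS, [1, 2, 3, 4, 5, 6]))
        for pos, num in expected.items():
            assert by_pos[(float(pos[0]), float(pos[1]))].number == num

    def test_mirrored_layout_swaps_parities(self):
        mirrored = [(1000 - x, y) for x, y in self.CENTROIDS]
        by_pos = self._number(mirrored)
        expected = dict(zip(mirrored, [1, 2, 4, 3, 6, 5]))
        for pos, num in expected.items():
            assert by_pos[(float(pos[0]), float(pos[1]))].number == num

    def test_y_tie_broken_by_x(self):
        by_pos = self._number([(500, 200), (500, 400), (100, 300), (200, 300)])
        assert by_pos[(100.0, 300.0)].number == 3
        assert by_pos[(200.0, 300.0)].number == 5

    def test_too_many_central_candidates_is_qc_error(self):
        with pytest.raises(QCError, match="ambiguous central"):
            self._number([(490, 100), (500, 200), (510, 300)])

    def test_classes_and_sides(self):
        by_pos = self._number(self.CENTROIDS)
        assert by_pos[(500.0, 200.0)].cls == "central"
        assert by_pos[(100.0, 150.0)].side == "left"
        assert by_pos[(900.0, 160.0)].side == "right"


class TestMaxFeret:
    def test_unit_square_diagonal_with_tie_break(self):
        length, angle = max_feret(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        assert length == pytest.approx(math.sqrt(2), abs=1e-12)
        assert angle == pytest.approx(45.0, abs=1e-9)

    def test_collinear_points(self):
        length, angle = max_feret(np.array([[0, 0], [2, 0], [4, 0]], float))
        assert length == 4.0
        assert angle == 0.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            max_feret(np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_matches_brute_force_on_random_polygons(self):
        for pts in _random_polygons(200, 25, seed=1):
            length, _ = max_feret(pts)
            assert length == brute_force_max_feret(pts)


class TestMinFeret:
    def test_unit_square(self):
        assert min_feret(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)) == pytest.approx(1.0)

    def test_equilateral_triangle_height(self):
        tri = np.array([[0, 0], [2, 0], [1, math.sqrt(3)]], float)
        assert min_feret(tri) == pytest.approx(math.sqrt(3), abs=1e-12)

    def test_collinear_returns_zero(self):
        assert min_feret(np.array([[0, 0], [1, 1], [2, 2]], float)) == 0.0

    def test_matches_rotation_scan_oracle(self):
        for pts in _random_polygons(50, 25, seed=2):
            assert min_feret(pts) == pytest.approx(rotation_scan_min_feret(pts), abs=1e-6)


class TestFoldAngle:
    @pytest.mark.parametrize("theta,expected", [(135, 45), (90, 90), (179, 1), (0, 0), (45, 45)])
    def test_fold(self, theta, expected):
        assert fold_angle(theta) == pytest.approx(expected)

    def test_out_of_range_normalized_first(self):
        assert fold_angle(315.0) == pytest.approx(45.0)
        assert fold_angle(-45.0) == pytest.approx(45.0)


class TestSpotMetrics:
    def _record(self, contour, area):
        return SpotRecord(number=1, cls="central", side="center", area_px=area, centroid=(0, 0), contour=contour)

    def test_relative_area_and_feret(self):
        # 30-px-long segment-ish triangle in a Ta of 900 -> MaxFd relative 1.0
        contour = np.array([[0, 0], [30, 0], [15, 1]], float)
        rec = spot_metrics(self._record(contour, area=50), Ta=1000)
        assert rec.Ra == pytest.approx(5.0)
        rec = spot_metrics(self._record(contour, area=50), Ta=900)
        assert rec.MaxFd == pytest.approx(1.0, abs=1e-6)

    def test_rasterized_circle_is_nearly_round(self):
        yy, xx = np.mgrid[:50, :50]
        disk = ((yy - 25) ** 2 + (xx - 25) ** 2) <= 20**2
        from spotmorph.segmentation import BinaryMask, SegmentationParams, label_spots

        spots = label_spots(BinaryMask(disk, np.ones_like(disk)), SegmentationParams())
        rec = self._record(spots.components[0].contour, spots.components[0].pixel_count)
        spot_metrics(rec, Ta=2500)
        assert rec.Ar >= 0.95
        assert rec.MinFd <= rec.MaxFd

    def test_rotation_equivariance_on_exact_contour(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 2 * math.pi, 80, endpoint=False)
        ellipse = np.column_stack([10 * np.cos(t), 4 * np.sin(t)])
        base_len, base_angle = max_feret(ellipse)
        base_min = min_feret(ellipse)
        for rot_deg in rng.uniform(0, 180, 8):
            c, s = math.cos(math.radians(rot_deg)), math.sin(math.radians(rot_deg))
            # y-down image coordinates: a +rot_deg visual rotation flips sign
            rotated = ellipse @ np.array([[c, s], [-s, c]]).T
            length, angle = max_feret(rotated)
            assert length == pytest.approx(base_len, rel=1e-9)
            assert min_feret(rotated) == pytest.approx(base_min, rel=1e-9)
            assert (angle - base_angle) % 180.0 == pytest.approx(rot_deg, abs=1e-6)


class TestFeretProperties:
    point_sets = arrays(
        np.float64,
        st.tuples(st.integers(4, 20), st.just(2)),
        elements=st.floats(-100, 100, allow_nan=False),
    )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(point_sets)
    def test_min_never_exceeds_max(self, pts):
        distinct = np.unique(pts, axis=0)
        if len(distinct) < 3:
            return
        length, angle = max_feret(distinct)
        width = min_feret(distinct)
        assert width <= length + 1e-9
        assert 0.0 <= angle < 180.0

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.floats(-1e6, 1e6, allow_nan=False))
    def test_fold_angle_range_and_idempotence(self, theta):
        folded = fold_angle(theta)
        assert 0.0 <= folded <= 90.0
        assert fold_angle(folded) == pytest.approx(folded, abs=1e-9)


class TestGPA:
    def _config(self, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(-1, 1, size=(14, 2))

    def test_similarity_transformed_copy_aligns_exactly(self):
        base = self._config()
        psi = math.radians(57.0)
        rot = np.array([[math.cos(psi), -math.sin(psi)], [math.sin(psi), math.cos(psi)]])
        moved = 3.0 * base @ rot.T + np.array([5.0, -2.0])
        result = gpa([CentroidConfiguration(base, "a"), CentroidConfiguration(moved, "b")])
        rms = np.sqrt(np.mean(np.sum((result.aligned[0].points - result.aligned[1].points) ** 2, axis=1)))
        assert rms < 1e-8

    def test_duplicated_configuration_consensus(self):
        base = self._config(1)
        result = gpa([CentroidConfiguration(base, str(i)) for i in range(5)])
        norm = base - base.mean(axis=0)
        norm /= np.linalg.norm(norm)
        # consensus equals the normalized configuration up to rotation
        u, _, vt = np.linalg.svd(result.mean_shape.T @ norm)
        r = u @ vt
        assert np.allclose(result.mean_shape @ r, norm, atol=1e-10)

    def test_noisy_copies_recover_consensus(self):
        rng = np.random.default_rng(7)
        truth = self._config(2)
        truth -= truth.mean(axis=0)
        truth /= np.linalg.norm(truth)
        configs = [
            CentroidConfiguration(truth + rng.normal(0, 0.01, truth.shape), str(i))
            for i in range(50)
        ]
        result = gpa(configs)
        u, _, vt = np.linalg.svd(result.mean_shape.T @ truth)
        aligned_mean = result.mean_shape @ (u @ vt)
        rms = np.sqrt(np.mean(np.sum((aligned_mean - truth) ** 2, axis=1)))
        assert rms < 0.005

    def test_mismatched_point_counts_reported(self):
        with pytest.raises(ValueError, match="odd_one"):
            gpa(
                [
                    CentroidConfiguration(self._config(0), "a"),
                    CentroidConfiguration(self._config(1), "b"),
                    CentroidConfiguration(self._config(2)[:10], "odd_one"),
                ]
            )


class TestCentralLateralDistances:
    def test_three_four_five(self):
        pts = np.array([[0, 0], [3, 4], [0, 5]], float)
        assert sum_central_lateral_distances(pts, ["central", "lateral", "lateral"]) == pytest.approx(10.0)

    def test_coincident_points_give_zero(self):
        pts = np.zeros((4, 2))
        classes = ["central", "central", "lateral", "lateral"]
        assert sum_central_lateral_distances(pts, classes) == 0.0

    def test_symmetric_configuration_balanced(self):
        pts = np.array([[0, 0], [-2, 1], [2, 1]], float)
        total = sum_central_lateral_distances(pts, ["central", "lateral", "lateral"])
        assert total == pytest.approx(2 * math.hypot(2, 1))

    def test_missing_central_raises(self):
        with pytest.raises(ValueError, match="central"):
            sum_central_lateral_distances(np.zeros((2, 2)), ["lateral", "lateral"])


class TestFeatureTable:
    def _specimen(self, sid="s1", ras_central=(2, 3), ras_lateral=(1, 1, 1, 1)):
        records = []
        n = 1
        for ra in ras_central:
            records.append(
                SpotRecord(number=n, cls="central", side="center", area_px=1, centroid=(0, n), Ra=float(ra),
                           MaxFd=1.0, MinFd=0.5, Fa=10.0, Fa_folded=10.0, Ar=0.5)
            )
            n += 1
        for ra in ras_lateral:
            records.append(
                SpotRecord(number=n, cls="lateral", side="left" if n % 2 else "right", area_px=1,
                           centroid=(n, n), Ra=float(ra), MaxFd=1.0, MinFd=0.5, Fa=20.0, Fa_folded=20.0, Ar=0.5)
            )
            n += 1
        return SpecimenSpots(specimen_id=sid, group="G", Ta=1000, records=records)

    def test_derived_arithmetic(self):
        table = build_feature_table([self._specimen()], run_gpa=False)
        row = table.loc["s1"]
        assert row["total_Ra"] == pytest.approx(9.0)
        assert row["mean_Ra_central"] == pytest.approx(2.5)
        assert row["mean_Ra_lateral"] == pytest.approx(1.0)
        assert row["central_lateral_ratio"] == pytest.approx(2.5)
        assert row["n_central"] == 2 and row["n_lateral"] == 4

    def test_total_ra_is_exact_sum(self):
        spec = self._specimen(ras_central=(0.1, 0.2), ras_lateral=(0.3, 0.4, 0.5, 0.7))
        table = build_feature_table([spec], run_gpa=False)
        assert table.loc["s1", "total_Ra"] == pytest.approx(
            sum(r.Ra for r in spec.records), abs=1e-9
        )

    def test_empty_specimen_set_refused(self):
        with pytest.raises(ValueError, match="empty"):
            build_feature_table([])

    def test_duplicate_ids_refused(self):
        with pytest.raises(ValueError, match="duplicated"):
            build_feature_table([self._specimen("a"), self._specimen("a")])

    def test_gpa_distance_filled_for_modal_count(self):
        specs = [self._specimen(f"s{i}") for i in range(3)]
        table = build_feature_table(specs, run_gpa=True)
        assert table["sum_central_lateral_dist"].notna().all()
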