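"""Geometry operators: exact values, invariances, and an independent
line-polyline intersection oracle (shapely)."""

import numpy as np
import pytest
from shapely.geometry import LineString

from parityquant.geometry import (
    INDEX_NAMES,
    DegenerateGeometryError,
    DirectedLine,
    MeasurementConfig,
    SagittalGeometry,
    length_along_axis,
    measure_indices,
    read_annotations,
    width_at_level,
    write_annotations,
)

from .conftest import random_polyline_geometry


def shapely_axis_crossing_t(line: DirectedLine, polyline: np.ndarray, span: float = 1e3):
    """Independent oracle: intersect a long segment along the axis with the polyline."""
    seg = LineString([line.at(-span), line.at(span)])
    inter = seg.intersection(LineString(polyline))
    if inter.is_empty:
        return []
    pts = [inter] if inter.geom_type == "Point" else list(inter.geoms)
    return sorted(line.project_t((p.x, p.y)) for p in pts)


class TestLengthAlongAxis:
    def test_axis_aligned_values(self, axis_aligned_geometry):
        g = axis_aligned_geometry
        assert length_along_axis(g, g.tooth_axis, g.crest_point) == pytest.approx(21.0)
        assert length_along_axis(g, g.tooth_axis, g.apex_point) == pytest.approx(8.0)

    def test_rigid_motion_invariance(self, axis_aligned_geometry):
        g = axis_aligned_geometry
        g2 = g.transformed(rotation_deg=30.0, translation=(4.2, -1.7))
        a = length_along_axis(g, g.tooth_axis, g.apex_point)
        b = length_along_axis(g2, g2.tooth_axis, g2.apex_point)
        assert b == pytest.approx(a, abs=1e-9)

    def test_no_intersection_raises(self, axis_aligned_geometry):
        g = axis_aligned_geometry
        away = DirectedLine((100.0, 0.0), (0.0, 1.0))
        with pytest.raises(DegenerateGeometryError):
            length_along_axis(g, away, (100.0, 0.0))


class TestWidthAtLevel:
    def test_axis_aligned_both_and_single(self, axis_aligned_geometry):
        g = axis_aligned_geometry
        for level in (0.0, 5.0, 15.0):
            assert width_at_level(g, g.tooth_axis, level, "both") == pytest.approx(10.0)
            assert width_at_level(g, g.tooth_axis, level, "buccal") == pytest.approx(5.0)
            assert width_at_level(g, g.tooth_axis, level, "palatal") == pytest.approx(5.0)

    def test_zero_width_tangent_contours(self, axis_aligned_geometry):
        g = axis_aligned_geometry
        tangent = SagittalGeometry(
            crest_point=g.crest_point,
            apex_point=g.apex_point,
            tooth_axis=g.tooth_axis,
            bone_axis=g.bone_axis,
            basal_boundary=g.basal_boundary,
            buccal_contour=np.array([[0.0, -1.0], [0.0, 25.0]]),
            palatal_contour=np.array([[0.0, -1.0], [0.0, 25.0]]),
        )
        assert width_at_level(tangent, g.tooth_axis, 5.0, "both") == pytest.approx(0.0)

    def test_missing_contour_raises_with_level(self, axis_aligned_geometry):
        g = axis_aligned_geometry
        with pytest.raises(DegenerateGeometryError, match="50.0"):
            width_at_level(g, g.tooth_axis, 50.0, "both")


class TestMeasureIndices:
    def test_axis_aligned_fixture_all_nine(self, axis_aligned_geometry):
        iv = measure_indices(axis_aligned_geometry)
        expected = dict(
            LTAcb=21.0, LTAab=8.0, LBAcb=21.0, LBAab=8.0,
            apical2mm=10.0, WTAB=5.0, WTAP=5.0, WBAB=5.0, WBAP=5.0,
        )
        for name, val in expected.items():
            assert iv[name] == pytest.approx(val), name

    def test_apex_on_basal_boundary_gives_zero_length(self, axis_aligned_geometry):
        g = axis_aligned_geometry
        g2 = SagittalGeometry(
            crest_point=g.crest_point,
            apex_point=(0.0, 21.0),
            tooth_axis=g.tooth_axis,
            bone_axis=g.bone_axis,
            basal_boundary=g.basal_boundary,
            buccal_contour=g.buccal_contour,
            palatal_contour=g.palatal_contour,
        )
        assert measure_indices(g2)["LTAab"] == pytest.approx(0.0)

    def test_tilted_bone_axis_against_closed_form(self, axis_aligned_geometry):
        # bone axis tilted 10 deg from the tooth axis, through the crest
        g = axis_aligned_geometry
        th = np.deg2rad(10.0)
        bone = DirectedLine((0.0, 0.0), (np.sin(th), np.cos(th)))
        g2 = SagittalGeometry(
            crest_point=g.crest_point,
            apex_point=g.apex_point,
            tooth_axis=g.tooth_axis,
            bone_axis=bone,
            basal_boundary=g.basal_boundary,
            buccal_contour=g.buccal_contour,
            palatal_contour=g.palatal_contour,
        )
        iv = measure_indices(g2)
        # closed form: basal y=21 crossed at t = 21/cos(th); crest projects to t=0
        assert iv["LBAcb"] == pytest.approx(21.0 / np.cos(th))
        # apex (0,13) projects onto the tilted axis at t = 13 cos(th)
        assert iv["LBAab"] == pytest.approx(21.0 / np.cos(th) - 13.0 * np.cos(th))
        # widths at the basal crossing: perpendicular hits vertical contours x=+-5
        # crossing point (21 tan th, 21); distance to x=+-5 along the perpendicular
        xc = 21.0 * np.tan(th)
        assert iv["WBAB"] == pytest.approx((xc + 5.0) / np.cos(th))
        assert iv["WBAP"] == pytest.approx((5.0 - xc) / np.cos(th))

    @pytest.mark.parametrize("seed", range(6))
    def test_rigid_motion_invariance_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        geom = random_polyline_geometry(rng)
        base = measure_indices(geom).values
        rot = rng.uniform(-180, 180)
        tr = rng.uniform(-30, 30, size=2)
        moved = measure_indices(geom.transformed(rotation_deg=rot, translation=tr)).values
        np.testing.assert_allclose(moved, base, atol=1e-9)

    @pytest.mark.parametrize("scale", [0.5, 2.0, 3.7])
    def test_scale_equivariance(self, scale):
        # scaling coordinates by s scales every index by s, provided the
        # fixed measurement offsets (the 2 mm apical level) scale along
        rng = np.random.default_rng(7)
        geom = random_polyline_geometry(rng)
        base = measure_indices(geom).values
        cfg = MeasurementConfig(apical_offset_mm=2.0 * scale)
        scaled = measure_indices(geom.transformed(scale=scale), cfg).values
        np.testing.assert_allclose(scaled, scale * base, rtol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_shapely_intersection_oracle(self, seed):
        """All nine indices recomputed from shapely crossings on <=20-segment fixtures."""
        rng = np.random.default_rng(100 + seed)
        g = random_polyline_geometry(rng, n_seg=rng.integers(5, 20))
        iv = measure_indices(g)

        def oracle_length(axis, from_point):
            ts = shapely_axis_crossing_t(axis, g.basal_boundary)
            assert len(ts) == 1
            return abs(ts[0] - axis.project_t(from_point))

        def oracle_width(axis, level, side):
            perp = axis.perpendicular_at(level)
            tb = min(shapely_axis_crossing_t(perp, g.buccal_contour), key=abs)
            tp = min(shapely_axis_crossing_t(perp, g.palatal_contour), key=abs)
            if side == "both":
                return abs(tb - tp)
            return abs(tb) if side == "buccal" else abs(tp)

        assert iv["LTAcb"] == pytest.approx(oracle_length(g.tooth_axis, g.crest_point), abs=1e-8)
        assert iv["LTAab"] == pytest.approx(oracle_length(g.tooth_axis, g.apex_point), abs=1e-8)
        assert iv["LBAcb"] == pytest.approx(oracle_length(g.bone_axis, g.crest_point), abs=1e-8)
        assert iv["LBAab"] == pytest.approx(oracle_length(g.bone_axis, g.apex_point), abs=1e-8)
        t_apex = g.tooth_axis.project_t(g.apex_point)
        assert iv["apical2mm"] == pytest.approx(oracle_width(g.tooth_axis, t_apex + 2.0, "both"), abs=1e-8)
        t_basal_t = shapely_axis_crossing_t(g.tooth_axis, g.basal_boundary)[0]
        t_basal_b = shapely_axis_crossing_t(g.bone_axis, g.basal_boundary)[0]
        assert iv["WTAB"] == pytest.approx(oracle_width(g.tooth_axis, t_basal_t, "buccal"), abs=1e-8)
        assert iv["WTAP"] == pytest.approx(oracle_width(g.tooth_axis, t_basal_t, "palatal"), abs=1e-8)
        assert iv["WBAB"] == pytest.approx(oracle_width(g.bone_axis, t_basal_b, "buccal"), abs=1e-8)
        assert iv["WBAP"] == pytest.approx(oracle_width(g.bone_axis, t_basal_b, "palatal"), abs=1e-8)

    def test_crest_not_shallower_than_apex_along_tooth_axis(self):
        # crest and apex on the same side of the basal boundary => LTAcb >= LTAab
        for seed in range(5):
            iv = measure_indices(random_polyline_geometry(np.random.default_rng(200 + seed)))
            assert iv["LTAcb"] >= iv["LTAab"]

    def test_error_names_failed_index(self, axis_aligned_geometry):
        g = axis_aligned_geometry
        bad = SagittalGeometry(
            crest_point=g.crest_point,
            apex_point=g.apex_point,
            tooth_axis=g.tooth_axis,
            bone_axis=g.bone_axis,
            basal_boundary=g.basal_boundary,
            buccal_contour=np.array([[-5.0, -1.0], [-5.0, 10.0]]),  # too short for basal level
            palatal_contour=g.palatal_contour,
        )
        with pytest.raises(DegenerateGeometryError, match="WTAB|apical2mm"):
            measure_indices(bad)


class TestValidation:
    def test_apex_off_axis_rejected(self, axis_aligned_geometry):
        g = axis_aligned_geometry
        bad = SagittalGeometry(
            crest_point=g.crest_point,
            apex_point=(1.0, 13.0),
            tooth_axis=g.tooth_axis,
            bone_axis=g.bone_axis,
            basal_boundary=g.basal_boundary,
            buccal_contour=g.buccal_contour,
            palatal_contour=g.palatal_contour,
        )
        with pytest.raises(ValueError, match="apex"):
            bad.validate()

    def test_contours_same_side_rejected(self, axis_aligned_geometry):
        g = axis_aligned_geometry
        bad = SagittalGeometry(
            crest_point=g.crest_point,
            apex_point=g.apex_point,
            tooth_axis=g.tooth_axis,
            bone_axis=g.bone_axis,
            basal_boundary=g.basal_boundary,
            buccal_contour=np.array([[3.0, -1.0], [3.0, 25.0]]),
            palatal_contour=g.palatal_contour,
        )
        with pytest.raises(ValueError, match="opposite"):
            bad.validate()


class TestAnnotationIO:
    def test_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        annotations = {f"img{i:02d}": random_polyline_geometry(rng) for i in range(3)}
        path = tmp_path / "annotations.csv"
        write_annotations(path, annotations)
        back = read_annotations(path)
        assert set(back) == set(annotations)
        for key, orig in annotations.items():
            got = back[key]
            np.testing.assert_array_equal(got.basal_boundary, orig.basal_boundary)
            np.testing.assert_array_equal(got.buccal_contour, orig.buccal_contour)
            np.testing.assert_array_equal(got.crest_point, orig.crest_point)
            np.testing.assert_array_equal(got.tooth_axis.direction, orig.tooth_axis.direction)
            assert got.pixel_spacing == orig.pixel_spacing
            np.testing.assert_allclose(measure_indices(got).values, measure_indices(orig).values, atol=1e-12)
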