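"""Sagittal-section geometry model and the nine basal-bone index operators.

A mid-facial sagittal section through an anterior maxillary tooth is represented
as a small set of landmarks and polylines in continuous millimetre coordinates
(y increasing apically):

* the alveolar crest reference point and the root apex,
* the tooth axis and the bone axis (directed lines),
* the basal-bone boundary toward the nasal floor (polyline),
* the buccal and palatal bone contours (polylines).

From this representation the four length indices (LTAcb, LTAab, LBAcb, LBAab:
crest/apex to the basal boundary along the tooth/bone axis) and five width
indices (apical2mm, WTAB, WTAP, WBAB, WBAP) are pure line–polyline intersection
problems, so every index has an exact analytic value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: canonical ordering of the nine basal-bone indices
INDEX_NAMES = (
    "LTAcb",
    "LTAab",
    "LBAcb",
    "LBAab",
    "apical2mm",
    "WTAB",
    "WTAP",
    "WBAB",
    "WBAP",
)

_EPS = 1e-12


class DegenerateGeometryError(ValueError):
    """An axis/level misses the structure it is supposed to intersect."""


@dataclass(frozen=True)
class DirectedLine:
    """An infinite directed line ``point + t * direction`` (direction unit-norm)."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(2)
        d = np.asarray(self.direction, dtype=float).reshape(2)
        n = np.linalg.norm(d)
        if n < _EPS:
            raise ValueError("direction must be non-zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / n)

    def at(self, t: float) -> np.ndarray:
        return self.point + t * self.direction

    def project_t(self, p) -> float:
        """Signed arc-length parameter of the orthogonal projection of ``p``."""
        return float(np.dot(np.asarray(p, dtype=float) - self.point, self.direction))

    def normal(self) -> np.ndarray:
        """Unit normal obtained by a +90 deg rotation of the direction."""
        dx, dy = self.direction
        return np.array([-dy, dx])

    def perpendicular_at(self, t: float) -> "DirectedLine":
        return DirectedLine(self.at(t), self.normal())

    def signed_offset(self, p) -> float:
        """Signed perpendicular distance of ``p`` from the line."""
        return float(np.dot(np.asarray(p, dtype=float) - self.point, self.normal()))


def line_polyline_intersections(line: DirectedLine, polyline: np.ndarray) -> np.ndarray:
    """All parameters ``t`` where the infinite line crosses the polyline.

    Each segment is solved as a 2x2 linear system; segment parameters are taken
    half-open in [0, 1) except for the terminal vertex of the last segment, so a
    crossing at a shared vertex is reported once.  Parallel segments lying off
    the line are skipped; near-duplicate parameters (within 1e-9) are merged.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be an (n>=2, 2) array")
    ts: list[float] = []
    n_seg = pts.shape[0] - 1
    for i in range(n_seg):
        a, b = pts[i], pts[i + 1]
        seg = b - a
        # [d, -seg] [t, s]^T = a - p0
        det = -line.direction[0] * seg[1] + line.direction[1] * seg[0]
        if abs(det) < _EPS * max(1.0, float(np.linalg.norm(seg))):
            continue
        rhs = a - line.point
        t = (-rhs[0] * seg[1] + rhs[1] * seg[0]) / det
        s = (line.direction[0] * rhs[1] - line.direction[1] * rhs[0]) / det
        hi_closed = i == n_seg - 1
        if -1e-12 <= s < 1.0 or (hi_closed and abs(s - 1.0) <= 1e-12):
            ts.append(float(t))
    ts.sort()
    out: list[float] = []
    for t in ts:
        if not out or abs(t - out[-1]) > 1e-9:
            out.append(t)
    return np.asarray(out)


@dataclass(frozen=True)
class SagittalGeometry:
    """One tooth + alveolar/basal bone cross-section in mm coordinates."""

    crest_point: np.ndarray
    apex_point: np.ndarray
    tooth_axis: DirectedLine
    bone_axis: DirectedLine
    basal_boundary: np.ndarray
    buccal_contour: np.ndarray
    palatal_contour: np.ndarray
    pixel_spacing: float = 0.25

    def __post_init__(self):
        for name in ("crest_point", "apex_point"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(2))
        for name in ("basal_boundary", "buccal_contour", "palatal_contour"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    # -- invariants ---------------------------------------------------------
    def validate(self, atol: float = 1e-6) -> None:
        """Raise ``ValueError`` if a structural invariant is violated."""
        if abs(np.linalg.norm(self.tooth_axis.direction) - 1.0) > 1e-9:
            raise ValueError("tooth_axis direction must be unit-norm")
        if abs(self.tooth_axis.signed_offset(self.apex_point)) > atol:
            raise ValueError("apex_point must lie on tooth_axis")
        b = np.array([self.tooth_axis.signed_offset(p) for p in self.buccal_contour])
        p = np.array([self.tooth_axis.signed_offset(p) for p in self.palatal_contour])
        if not ((np.all(b <= atol) and np.all(p >= -atol)) or (np.all(b >= -atol) and np.all(p <= atol))):
            raise ValueError("buccal and palatal contours must lie on opposite sides of tooth_axis")
        for axis, name in ((self.tooth_axis, "tooth_axis"), (self.bone_axis, "bone_axis")):
            k = len(line_polyline_intersections(axis, self.basal_boundary))
            if k != 1:
                raise ValueError(f"basal_boundary must intersect {name} exactly once (got {k})")

    def transformed(self, rotation_deg: float = 0.0, translation=(0.0, 0.0), scale: float = 1.0) -> "SagittalGeometry":
        """Rigid motion (plus optional uniform scale) of the whole geometry."""
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        tr = np.asarray(translation, dtype=float)

        def tp(pts):
            return (scale * np.asarray(pts, dtype=float)) @ rot.T + tr

        def tl(line: DirectedLine) -> DirectedLine:
            return DirectedLine(tp(line.point.reshape(1, 2))[0], rot @ line.direction)

        return replace(
            self,
            crest_point=tp(self.crest_point.reshape(1, 2))[0],
            apex_point=tp(self.apex_point.reshape(1, 2))[0],
            tooth_axis=tl(self.tooth_axis),
            bone_axis=tl(self.bone_axis),
            basal_boundary=tp(self.basal_boundary),
            buccal_contour=tp(self.buccal_contour),
            palatal_contour=tp(self.palatal_contour),
        )


@dataclass(frozen=True)
class IndexVector:
    """The nine basal-bone measurements in mm, in canonical order."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).reshape(len(INDEX_NAMES))
        object.__setattr__(self, "values", v)

    @classmethod
    def from_dict(cls, d) -> "IndexVector":
        return cls(np.array([d[k] for k in INDEX_NAMES], dtype=float))

    def to_dict(self) -> dict:
        return dict(zip(INDEX_NAMES, (float(v) for v in self.values)))

    def __getitem__(self, name: str) -> float:
        return float(self.values[INDEX_NAMES.index(name)])

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all indices must be finite")
        if np.any(self.values < 0):
            raise ValueError("all indices must be non-negative")


@dataclass(frozen=True)
class MeasurementConfig:
    """Conventions for the width operators.

    width_level_offset_mm
        Offset along each axis, relative to its basal-boundary intersection, at
        which the four axis widths (WTAB/WTAP/WBAB/WBAP) are taken.  0 means the
        basal level itself.
    apical_offset_mm
        Distance beyond the apex (away from the crown) for apical2mm.
    """

    width_level_offset_mm: float = 0.0
    apical_offset_mm: float = 2.0


def length_along_axis(geometry: SagittalGeometry, axis: DirectedLine, from_point) -> float:
    """Distance along ``axis`` from the projection of ``from_point`` to the basal boundary.

    The axis must cross the basal boundary exactly once; otherwise a
    :class:`DegenerateGeometryError` is raised.
    """
    ts = line_polyline_intersections(axis, geometry.basal_boundary)
    if len(ts) != 1:
        raise DegenerateGeometryError(
            f"axis through {axis.point.tolist()} crosses basal_boundary {len(ts)} times (expected 1)"
        )
    return abs(float(ts[0]) - axis.project_t(from_point))


def _nearest_crossing(perp: DirectedLine, contour: np.ndarray):
    ts = line_polyline_intersections(perp, contour)
    if len(ts) == 0:
        return None
    return float(ts[np.argmin(np.abs(ts))])


def width_at_level(geometry: SagittalGeometry, axis: DirectedLine, level_mm: float, side: str = "both") -> float:
    """Bone width on the perpendicular to ``axis`` at parameter ``level_mm``.

    ``side='both'`` is the buccal-to-palatal contour distance; ``'buccal'`` /
    ``'palatal'`` the respective contour-to-axis distance.  If a perpendicular
    crosses a contour more than once the crossing nearest the axis is used.
    """
    if side not in ("both", "buccal", "palatal"):
        raise ValueError(f"side must be 'both', 'buccal' or 'palatal', got {side!r}")
    perp = axis.perpendicular_at(level_mm)
    tb = _nearest_crossing(perp, geometry.buccal_contour)
    tp = _nearest_crossing(perp, geometry.palatal_contour)
    if side in ("both", "buccal") and tb is None:
        raise DegenerateGeometryError(f"perpendicular at level {level_mm:.3f} mm misses the buccal contour")
    if side in ("both", "palatal") and tp is None:
        raise DegenerateGeometryError(f"perpendicular at level {level_mm:.3f} mm misses the palatal contour")
    if side == "both":
        return abs(tb - tp)
    if side == "buccal":
        return abs(tb)
    return abs(tp)


def measure_indices(geometry: SagittalGeometry, config: MeasurementConfig | None = None) -> IndexVector:
    """Measure all nine basal-bone indices on one sagittal geometry.

    Lengths are axis/basal-boundary intersections; axis widths are taken at the
    basal level (plus the configured offset) perpendicular to the respective
    axis, and apical2mm is the full bucco-palatal width 2 mm beyond the apex.
    """
    cfg = config or MeasurementConfig()
    out = {}

    def run(name, fn, *args, **kw):
        try:
            out[name] = fn(*args, **kw)
        except DegenerateGeometryError as e:
            raise DegenerateGeometryError(f"{name}: {e}") from e

    run("LTAcb", length_along_axis, geometry, geometry.tooth_axis, geometry.crest_point)
    run("LTAab", length_along_axis, geometry, geometry.tooth_axis, geometry.apex_point)
    run("LBAcb", length_along_axis, geometry, geometry.bone_axis, geometry.crest_point)
    run("LBAab", length_along_axis, geometry, geometry.bone_axis, geometry.apex_point)

    t_apex = geometry.tooth_axis.project_t(geometry.apex_point)
    t_crest = geometry.tooth_axis.project_t(geometry.crest_point)
    apical_dir = 1.0 if t_apex >= t_crest else -1.0
    run(
        "apical2mm",
        width_at_level,
        geometry,
        geometry.tooth_axis,
        t_apex + apical_dir * cfg.apical_offset_mm,
        "both",
    )

    for axis, prefix in ((geometry.tooth_axis, "WTA"), (geometry.bone_axis, "WBA")):
        ts = line_polyline_intersections(axis, geometry.basal_boundary)
        if len(ts) != 1:
            raise DegenerateGeometryError(
                f"{prefix}B/{prefix}P: axis crosses basal_boundary {len(ts)} times (expected 1)"
            )
        level = float(ts[0]) + cfg.width_level_offset_mm
        run(prefix + "B", width_at_level, geometry, axis, level, "buccal")
        run(prefix + "P", width_at_level, geometry, axis, level, "palatal")

    iv = IndexVector.from_dict(out)
    iv.validate()
    return iv


# -- annotation I/O ---------------------------------------------------------

def _fmt_pts(pts: np.ndarray) -> str:
    return ";".join(f"{float(x)!r},{float(y)!r}" for x, y in np.asarray(pts, dtype=float))


def _parse_pts(s: str) -> np.ndarray:
    return np.array([[float(v) for v in pair.split(",")] for pair in s.split(";")])


def geometry_to_record(image_id: str, geom: SagittalGeometry) -> dict:
    """Flatten a geometry to one CSV row (pixel coordinates, exact round-trip)."""
    sp = geom.pixel_spacing

    def px(pts):
        return np.asarray(pts, dtype=float) / sp

    return {
        "image_id": image_id,
        "pixel_spacing": repr(float(sp)),
        "crest": _fmt_pts(px(geom.crest_point).reshape(1, 2)),
        "apex": _fmt_pts(px(geom.apex_point).reshape(1, 2)),
        "tooth_axis_point": _fmt_pts(px(geom.tooth_axis.point).reshape(1, 2)),
        "tooth_axis_dir": _fmt_pts(geom.tooth_axis.direction.reshape(1, 2)),
        "bone_axis_point": _fmt_pts(px(geom.bone_axis.point).reshape(1, 2)),
        "bone_axis_dir": _fmt_pts(geom.bone_axis.direction.reshape(1, 2)),
        "basal_boundary": _fmt_pts(px(geom.basal_boundary)),
        "buccal_contour": _fmt_pts(px(geom.buccal_contour)),
        "palatal_contour": _fmt_pts(px(geom.palatal_contour)),
    }


def record_to_geometry(rec) -> tuple[str, SagittalGeometry]:
    sp = float(rec["pixel_spacing"])

    def mm(s):
        return _parse_pts(s) * sp

    geom = SagittalGeometry(
        crest_point=mm(rec["crest"])[0],
        apex_point=mm(rec["apex"])[0],
        tooth_axis=DirectedLine(mm(rec["tooth_axis_point"])[0], _parse_pts(rec["tooth_axis_dir"])[0]),
        bone_axis=DirectedLine(mm(rec["bone_axis_point"])[0], _parse_pts(rec["bone_axis_dir"])[0]),
        basal_boundary=mm(rec["basal_boundary"]),
        buccal_contour=mm(rec["buccal_contour"]),
        palatal_contour=mm(rec["palatal_contour"]),
        pixel_spacing=sp,
    )
    return str(rec["image_id"]), geom


def write_annotations(path, annotations: dict) -> None:
    """Write ``{image_id: SagittalGeometry}`` as an annotation CSV."""
    rows = [geometry_to_record(i, g) for i, g in annotations.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annotations(path) -> dict:
    df = pd.read_csv(path, dtype=str)
    return dict(record_to_geometry(rec) for _, rec in df.iterrows())
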