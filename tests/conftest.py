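import numpy as np
import pytest

from parityquant.geometry import DirectedLine, SagittalGeometry


@pytest.fixture
def axis_aligned_geometry() -> SagittalGeometry:
    """Crest y=0, apex y=13, basal y=21, contours x=±5, coincident vertical axes."""
    axis = DirectedLine((0.0, 0.0), (0.0, 1.0))
    return SagittalGeometry(
        crest_point=(0.0, 0.0),
        apex_point=(0.0, 13.0),
        tooth_axis=axis,
        bone_axis=axis,
        basal_boundary=np.array([[-8.0, 21.0], [8.0, 21.0]]),
        buccal_contour=np.array([[-5.0, -1.0], [-5.0, 25.0]]),
        palatal_contour=np.array([[5.0, -1.0], [5.0, 25.0]]),
    )


def random_polyline_geometry(rng: np.random.Generator, n_seg: int = 12) -> SagittalGeometry:
    """Irregular but valid geometry with wiggly polyline contours/boundary."""
    tilt = rng.uniform(-0.06, 0.06)
    tooth_dir = np.array([np.sin(tilt), np.cos(tilt)])
    crest = np.array([rng.uniform(-4.0, -2.0), 0.0])
    apex = crest + rng.uniform(8.0, 12.0) * tooth_dir
    d0 = rng.uniform(17.0, 22.0)
    xs = np.linspace(-10.0, 10.0, n_seg + 1)
    basal = np.column_stack([xs, d0 + 0.2 * xs + rng.normal(0, 0.15, xs.size)])
    ys = np.linspace(-1.5, 27.0, n_seg + 1)
    buccal = np.column_stack([-6.5 + rng.normal(0, 0.2, ys.size), ys])
    palatal = np.column_stack([5.0 + rng.normal(0, 0.2, ys.size), ys])
    geom = SagittalGeometry(
        crest_point=crest,
        apex_point=apex,
        tooth_axis=DirectedLine(crest, tooth_dir),
        bone_axis=DirectedLine((0.0, 0.0), (0.02, 1.0)),
        basal_boundary=basal,
        buccal_contour=buccal,
        palatal_contour=palatal,
    )
    geom.validate()
    return geom
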