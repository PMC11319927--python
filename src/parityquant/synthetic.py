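"""Synthetic sagittal-section generator with analytic ground truth.

Emulates the study population the pipeline is designed for: ~1,000 adults with
a female-skewed sex ratio (388:612), age 36.15 +/- 13.09 y truncated at 18, four
anterior tooth sites per patient (#11, #12, #21, #22), and sex-conditional bone
morphology (male bone widths larger by a configurable multiplicative factor).
Each tooth yields a parametric 2D cross-section — tooth axis, bone axis, basal
boundary, buccal/palatal contours — whose nine indices are measured analytically
by :mod:`parityquant.geometry`, so every rendered image carries exact labels.

The default morphology brackets published clinical ranges for the nine indices
(e.g. LTAcb ~ 17.6 mm, apical2mm ~ 9.7 mm, WTAB ~ 1.7 mm).  By default only sex
has a morphological effect; age and tooth site are demographic labels without
anatomical consequence, so the expected audit verdict on synthetic data is
unambiguous.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import stats
from scipy.ndimage import gaussian_filter

from .geometry import (
    INDEX_NAMES,
    DirectedLine,
    SagittalGeometry,
    line_polyline_intersections,
    measure_indices,
)

TOOTH_SITES = ("#11", "#12", "#21", "#22")
AGE_GROUPS = ("18-29", "30-49", ">=50")
SPLITS = ("train", "validation", "test")


def age_group_of(age: float) -> str:
    if age < 30:
        return AGE_GROUPS[0]
    if age < 50:
        return AGE_GROUPS[1]
    return AGE_GROUPS[2]


@dataclass(frozen=True)
class DemographicRecord:
    patient_id: str
    sex: str  # "male" | "female"
    age: float
    age_group: str
    tooth_site: str

    def validate(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.age < 18:
            raise ValueError("age must be >= 18")
        if self.age_group != age_group_of(self.age):
            raise ValueError("age_group inconsistent with age")
        if self.tooth_site not in TOOTH_SITES:
            raise ValueError(f"unknown tooth site {self.tooth_site!r}")


@dataclass(frozen=True)
class ImageConfig:
    """Rendering parameters for the grayscale sagittal section."""

    size: int = 128
    pixel_spacing: float = 0.25  # mm / pixel
    background: float = 0.08
    bone_level: float = 0.45
    tooth_level: float = 0.85
    blur_sigma_px: float = 0.7
    noise_sd: float = 0.02
    file_format: str = "tiff"  # "tiff" | "png" on disk
    render_jitter_mm: float = 0.4  # bucco-palatal ambiguity of contours/tooth
    basal_jitter_mm: float = 0.25  # apico-coronal ambiguity of the basal boundary
    dtype: str = "float32"  # "float32" | "uint8" on disk


@dataclass(frozen=True)
class PopulationConfig:
    """Study-population and morphology parameters.

    Morphology means/SDs are the female reference; ``sex_effect`` multiplies the
    width-governing parameters (buccal/palatal half-widths) for males.
    """

    n_patients: int = 1000
    male_fraction: float = 0.388
    age_mean: float = 36.15
    age_sd: float = 13.09
    age_min: float = 18.0
    sex_effect: float = 1.0

    # morphology, mm (mean, sd)
    buccal_half_mm: tuple = (4.85, 1.15)
    palatal_half_mm: tuple = (4.85, 1.15)
    crest_buccal_frac: tuple = (0.65, 0.05)  # tooth-axis offset as fraction of buccal half-width
    crest_apex_mm: tuple = (9.7, 1.2)
    crest_basal_mm: tuple = (19.0, 3.5)  # basal-boundary height on the bone axis
    basal_slope: tuple = (0.25, 0.08)
    tooth_tilt_deg: tuple = (0.0, 2.5)
    contour_taper: tuple = (0.05, 0.03)
    placement_rotation_deg: tuple = (0.0, 3.0)
    # imaging dimorphism: male cortical boundaries render shifted toward the
    # axis by this scale times (sex_effect - 1) mm per side, so the image-to-
    # measurement relationship differs by sex whenever the morphology does
    render_sex_offset_scale: float = 3.0
    # share of morphological variance carried at the patient level
    # (0 = the four tooth sites are independent draws)
    patient_correlation: float = 0.0

    image: ImageConfig = field(default_factory=ImageConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        if self.sex_effect <= 0:
            raise ValueError("sex_effect must be > 0")
        for name in (
            "buccal_half_mm",
            "palatal_half_mm",
            "crest_buccal_frac",
            "crest_apex_mm",
            "crest_basal_mm",
            "basal_slope",
            "tooth_tilt_deg",
            "contour_taper",
            "placement_rotation_deg",
        ):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be >= 0")
        if self.age_sd < 0:
            raise ValueError("age_sd must be >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "PopulationConfig":
        d = json.loads(s)
        d["image"] = ImageConfig(**d["image"])
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


# -- demographics -----------------------------------------------------------

def sample_population(config: PopulationConfig, rng: np.random.Generator | None = None) -> list[DemographicRecord]:
    """Draw patients (4 tooth-site records each) from the configured population."""
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_patients
    sexes = np.where(rng.random(n) < config.male_fraction, "male", "female")
    if config.age_sd > 0:
        a = (config.age_min - config.age_mean) / config.age_sd
        ages = stats.truncnorm.rvs(
            a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
        )
    else:
        ages = np.full(n, max(config.age_mean, config.age_min))
    records = []
    width = len(str(n))
    for i in range(n):
        pid = f"P{i:0{width}d}"
        for site in TOOTH_SITES:
            rec = DemographicRecord(pid, str(sexes[i]), float(ages[i]), age_group_of(float(ages[i])), site)
            rec.validate()
            records.append(rec)
    return records


# -- per-tooth geometry -----------------------------------------------------

def _truncated_normal(rng, mean, sd, low, high):
    for _ in range(100):
        v = rng.normal(mean, sd)
        if low <= v <= high:
            return v
    return float(np.clip(mean, low, high))


_PATIENT_PARAMS = (
    "buccal_half",
    "palatal_half",
    "crest_frac",
    "crest_apex",
    "crest_basal",
    "slope",
    "tilt",
    "taper_b",
    "taper_p",
)


def draw_patient_effects(rng: np.random.Generator) -> dict:
    """Per-patient standard-normal morphology effects (one per parameter)."""
    return {k: float(rng.normal()) for k in _PATIENT_PARAMS}


def sample_geometry(
    record: DemographicRecord,
    config: PopulationConfig,
    rng: np.random.Generator,
    patient_effects: dict | None = None,
    max_retries: int = 20,
) -> SagittalGeometry:
    """Draw one valid sagittal geometry for a demographic record.

    The section is built in a local frame with the bone axis vertical (y
    apical), then rigidly rotated/translated into the rendering field of view.
    Morphology combines a patient-level effect (``patient_correlation`` of the
    variance, shared by the patient's four tooth sites) with a per-site draw.
    Geometries violating the structural invariants are re-drawn up to
    ``max_retries`` times.
    """
    record.validate()
    config.validate()
    sex_factor = config.sex_effect if record.sex == "male" else 1.0
    if patient_effects is None:
        patient_effects = draw_patient_effects(rng)
    rho = config.patient_correlation
    a_pat, a_site = np.sqrt(rho), np.sqrt(1.0 - rho)

    def draw(name, mean_sd, low=None, high=None):
        mean, sd = mean_sd
        v = mean + sd * (a_pat * patient_effects[name.split(":")[0]] + a_site * rng.normal())
        return float(np.clip(v, low if low is not None else -np.inf, high if high is not None else np.inf))

    last_err: Exception | None = None
    for _ in range(max_retries):
        wb = draw("buccal_half", config.buccal_half_mm, 1.5, 12.0) * sex_factor
        wp = draw("palatal_half", config.palatal_half_mm, 1.5, 12.0) * sex_factor
        frac = draw("crest_frac", config.crest_buccal_frac, 0.25, 0.8)
        l_ca = draw("crest_apex", config.crest_apex_mm, 5.0, 15.0)
        d0 = draw("crest_basal", config.crest_basal_mm, l_ca + 4.0, 28.0)
        slope = draw("slope", config.basal_slope)
        tilt = np.deg2rad(draw("tilt", config.tooth_tilt_deg, -4.5, 4.5))
        taper_b = draw("taper_b", config.contour_taper)
        taper_p = draw("taper_p", config.contour_taper)

        # local frame: bone axis is x=0 pointing +y; buccal side x<0
        tooth_x0 = -frac * wb
        tooth_dir = np.array([np.sin(tilt), np.cos(tilt)])
        crest = np.array([tooth_x0, 0.0])
        apex = crest + l_ca * tooth_dir

        y_top = d0 + abs(slope) * (max(wb, wp) + 2.0) + 2.0
        ys = np.linspace(-1.5, y_top, 8)
        buccal = np.column_stack([-(wb * (1.0 + taper_b * ys / 20.0)), ys])
        palatal = np.column_stack([wp * (1.0 + taper_p * ys / 20.0), ys])
        xs = np.linspace(-(wb + 2.5), wp + 2.5, 7)
        basal = np.column_stack([xs, d0 + slope * xs])

        geom = SagittalGeometry(
            crest_point=crest,
            apex_point=apex,
            tooth_axis=DirectedLine(crest, tooth_dir),
            bone_axis=DirectedLine(np.zeros(2), np.array([0.0, 1.0])),
            basal_boundary=basal,
            buccal_contour=buccal,
            palatal_contour=palatal,
            pixel_spacing=config.image.pixel_spacing,
        )
        fov = config.image.size * config.image.pixel_spacing
        rot = rng.normal(*config.placement_rotation_deg)
        geom = geom.transformed(rotation_deg=rot, translation=(fov / 2.0, fov / 2.0 - (y_top - 2.0) / 2.0))
        try:
            geom.validate()
        except ValueError as e:
            last_err = e
            continue
        return geom
    raise RuntimeError(f"could not draw a valid geometry after {max_retries} retries: {last_err}")


# -- rendering --------------------------------------------------------------

def _pixel_grid(cfg: ImageConfig):
    # pixel centers at integer coordinates, mm = px * pixel_spacing
    c = np.arange(cfg.size) * cfg.pixel_spacing
    xx, yy = np.meshgrid(c, c)
    return np.column_stack([xx.ravel(), yy.ravel()])


def _contour_basal_crossing(contour: np.ndarray, basal: np.ndarray) -> int:
    """Index of the last contour vertex before the basal boundary (crude clip)."""
    # walk vertices; the basal boundary separates bone from background
    for i in range(len(contour) - 1):
        seg_line = DirectedLine(contour[i], contour[i + 1] - contour[i])
        ts = line_polyline_intersections(seg_line, basal)
        seg_len = np.linalg.norm(contour[i + 1] - contour[i])
        hit = [t for t in ts if -1e-9 <= t <= seg_len + 1e-9]
        if hit:
            return i
    return len(contour) - 2


def _clip_contour(contour: np.ndarray, basal: np.ndarray) -> np.ndarray:
    i = _contour_basal_crossing(contour, basal)
    seg_line = DirectedLine(contour[i], contour[i + 1] - contour[i])
    ts = line_polyline_intersections(seg_line, basal)
    seg_len = np.linalg.norm(contour[i + 1] - contour[i])
    hit = [t for t in ts if -1e-9 <= t <= seg_len + 1e-9]
    end = seg_line.at(min(hit)) if hit else contour[i + 1]
    return np.vstack([contour[: i + 1], end])


def bone_polygon(geometry: SagittalGeometry) -> np.ndarray:
    """Closed polygon of the bone region (contours capped by the basal boundary)."""
    b = _clip_contour(geometry.buccal_contour, geometry.basal_boundary)
    p = _clip_contour(geometry.palatal_contour, geometry.basal_boundary)
    return np.vstack([b, p[::-1]])


def tooth_polygon(geometry: SagittalGeometry, crest_halfwidth: float = 1.2, crown_mm: float = 2.0) -> np.ndarray:
    """Tapered root polygon around the tooth axis, crest to apex plus a crown stub."""
    ax = geometry.tooth_axis
    n = ax.normal()
    t_crest = ax.project_t(geometry.crest_point)
    t_apex = ax.project_t(geometry.apex_point)
    sgn = 1.0 if t_apex >= t_crest else -1.0
    base = ax.at(t_crest - sgn * crown_mm)
    crest = ax.at(t_crest)
    apex = ax.at(t_apex)
    return np.vstack(
        [
            base - crest_halfwidth * n,
            crest - crest_halfwidth * n,
            apex - 0.5 * n,
            apex + 0.5 * n,
            crest + crest_halfwidth * n,
            base + crest_halfwidth * n,
        ]
    )


def render_image(
    geometry: SagittalGeometry,
    image_config: ImageConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Rasterize a sagittal geometry to a grayscale image in [0, 1].

    Bone renders brighter than background and the tooth brighter than bone;
    Gaussian blur and additive Gaussian noise are applied per the config.
    Raises ``ValueError`` if the geometry extends beyond the field of view.
    """
    cfg = image_config or ImageConfig()
    fov = cfg.size * cfg.pixel_spacing
    bone = bone_polygon(geometry)
    tooth = tooth_polygon(geometry)
    allpts = np.vstack([bone, tooth])
    lo, hi = allpts.min(axis=0), allpts.max(axis=0)
    if lo.min() < -cfg.pixel_spacing or hi.max() > fov + cfg.pixel_spacing:
        raise ValueError(
            f"geometry extent [{lo.tolist()}, {hi.tolist()}] mm exceeds field of view {fov:.1f} mm"
        )
    grid = _pixel_grid(cfg)
    img = np.full(cfg.size * cfg.size, cfg.background, dtype=np.float64)
    img[MplPath(bone).contains_points(grid)] = cfg.bone_level
    img[MplPath(tooth).contains_points(grid)] = cfg.tooth_level
    img = img.reshape(cfg.size, cfg.size)
    if cfg.blur_sigma_px > 0:
        img = gaussian_filter(img, cfg.blur_sigma_px)
    if cfg.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def bone_mask(geometry: SagittalGeometry, image_config: ImageConfig | None = None) -> np.ndarray:
    """Boolean mask of the (tooth + bone) region at pixel centers."""
    cfg = image_config or ImageConfig()
    grid = _pixel_grid(cfg)
    m = MplPath(bone_polygon(geometry)).contains_points(grid)
    m |= MplPath(tooth_polygon(geometry)).contains_points(grid)
    return m.reshape(cfg.size, cfg.size)


def jitter_geometry(
    geometry: SagittalGeometry,
    sd_mm: float,
    rng: np.random.Generator,
    basal_sd_mm: float | None = None,
) -> SagittalGeometry:
    """Displace the drawn structures by small random offsets (imaging ambiguity).

    Emulates the irreducible mismatch between what a sagittal image shows and
    what the reference annotation measures (slice placement, boundary blur,
    annotation convention): the buccal/palatal contours and the tooth shift
    independently along the bucco-palatal direction, the basal boundary along
    the bone axis.  Ground truth stays on the unjittered geometry, so the
    rendered image carries only degraded information about the true indices.
    """
    basal_sd = sd_mm if basal_sd_mm is None else basal_sd_mm
    if sd_mm <= 0 and basal_sd <= 0:
        return geometry
    n = geometry.bone_axis.normal()
    d = geometry.bone_axis.direction
    tooth_shift = rng.normal(0.0, sd_mm) * n
    return replace(
        geometry,
        buccal_contour=geometry.buccal_contour + rng.normal(0.0, sd_mm) * n,
        palatal_contour=geometry.palatal_contour + rng.normal(0.0, sd_mm) * n,
        basal_boundary=geometry.basal_boundary + rng.normal(0.0, basal_sd) * d,
        crest_point=geometry.crest_point + tooth_shift,
        apex_point=geometry.apex_point + tooth_shift,
        tooth_axis=DirectedLine(geometry.tooth_axis.point + tooth_shift, geometry.tooth_axis.direction),
    )


# -- dataset assembly -------------------------------------------------------

def apportion(n: int, ratio=(6, 2, 2)) -> tuple[int, ...]:
    """Largest-remainder apportionment of ``n`` into parts by ``ratio``.

    Remainder ties are broken in listed order (train > validation > test).
    """
    ratio = np.asarray(ratio, dtype=float)
    quota = n * ratio / ratio.sum()
    base = np.floor(quota).astype(int)
    rem = quota - base
    for i in np.lexsort((np.arange(len(ratio)), -rem))[: n - base.sum()]:
        base[i] += 1
    return tuple(int(b) for b in base)


def assign_splits(patient_ids: list[str], ratio=(6, 2, 2), rng: np.random.Generator | None = None) -> dict:
    """Patient-wise split assignment: shuffle patients, apportion, fill in order."""
    rng = rng or np.random.default_rng(0)
    ids = list(patient_ids)
    order = rng.permutation(len(ids))
    counts = apportion(len(ids), ratio)
    out = {}
    k = 0
    for split, c in zip(SPLITS, counts):
        for j in range(c):
            out[ids[order[k]]] = split
            k += 1
    return out


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset: manifest + geometries (+ rendered images)."""

    manifest: pd.DataFrame
    geometries: list[SagittalGeometry]
    images: np.ndarray | None
    config: PopulationConfig

    def gt_array(self) -> np.ndarray:
        return self.manifest[[f"gt_{n}" for n in INDEX_NAMES]].to_numpy(dtype=float)

    def rows(self, split: str | None = None) -> np.ndarray:
        idx = np.arange(len(self.manifest))
        if split is None:
            return idx
        return idx[(self.manifest["split"] == split).to_numpy()]

    def save(self, outdir) -> None:
        """Write manifest CSV + config JSON sidecar (+ TIFF images if rendered)."""
        import tifffile
        from matplotlib.image import imsave

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        fmt = self.config.image.file_format
        if fmt not in ("tiff", "png"):
            raise ValueError(f"file_format must be 'tiff' or 'png', got {fmt!r}")
        if self.images is not None:
            imgdir = outdir / "images"
            imgdir.mkdir(exist_ok=True)
            paths = []
            for i, img in enumerate(self.images):
                p = imgdir / f"{manifest['image_id'].iloc[i]}.{fmt}"
                if fmt == "png":
                    imsave(p, img, cmap="gray", vmin=0.0, vmax=1.0)
                elif self.config.image.dtype == "uint8":
                    tifffile.imwrite(p, (img * 255).round().astype(np.uint8))
                else:
                    tifffile.imwrite(p, img.astype(np.float32))
                paths.append(str(p.relative_to(outdir)))
            manifest["image_path"] = paths
        manifest.to_csv(outdir / "manifest.csv", index=False)
        (outdir / "config.json").write_text(self.config.to_json())


def build_dataset(
    config: PopulationConfig,
    split_ratio=(6, 2, 2),
    render: bool = True,
) -> SyntheticDataset:
    """Generate the full synthetic dataset.

    One image + exact ground-truth index vector per (patient, tooth site);
    ground truth is measured by :func:`parityquant.geometry.measure_indices` on
    the noiseless geometry; the split is patient-wise with largest-remainder
    ratios.  Fully deterministic given ``(config, config.seed)``.
    """
    config.validate()
    if config.n_patients < 5:
        raise ValueError("n_patients must be >= 5 so every split is non-empty")
    rng = np.random.default_rng(config.seed)
    records = sample_population(config, rng)
    patient_ids = sorted({r.patient_id for r in records})
    split_of = assign_splits(patient_ids, split_ratio, rng)

    rows = []
    geoms = []
    images = [] if render else None
    effects_of: dict = {}
    for rec in records:
        if rec.patient_id not in effects_of:
            effects_of[rec.patient_id] = draw_patient_effects(rng)
        try:
            for _ in range(20):
                geom = sample_geometry(rec, config, rng, effects_of[rec.patient_id])
                try:
                    if render:
                        shown = jitter_geometry(
                            geom, config.image.render_jitter_mm, rng, config.image.basal_jitter_mm
                        )
                        if rec.sex == "male":
                            off = config.render_sex_offset_scale * (config.sex_effect - 1.0)
                            n_hat = shown.bone_axis.normal()
                            shown = replace(
                                shown,
                                buccal_contour=shown.buccal_contour + off * n_hat,
                                palatal_contour=shown.palatal_contour - off * n_hat,
                            )
                        img = render_image(shown, config.image, rng)
                    else:
                        img = None
                except ValueError:
                    continue  # field-of-view overflow: redraw
                break
            else:
                raise RuntimeError("geometry did not fit the field of view after 20 redraws")
        except Exception as e:
            raise RuntimeError(f"generation failed for {rec.patient_id}/{rec.tooth_site}: {e}") from e
        gt = measure_indices(geom)
        row = {
            "image_id": f"{rec.patient_id}_{rec.tooth_site.replace('#', 'T')}",
            "patient_id": rec.patient_id,
            "sex": rec.sex,
            "age": rec.age,
            "age_group": rec.age_group,
            "tooth_site": rec.tooth_site,
            "split": split_of[rec.patient_id],
        }
        row.update({f"gt_{k}": v for k, v in gt.to_dict().items()})
        rows.append(row)
        geoms.append(geom)
        if render:
            images.append(img)
    manifest = pd.DataFrame(rows)
    return SyntheticDataset(
        manifest=manifest,
        geometries=geoms,
        images=np.stack(images) if render else None,
        config=config,
    )
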