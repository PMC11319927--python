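"""Synthetic population/geometry/rendering: determinism, demographics,
split bookkeeping, exact ground truth, and image-content sanity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from parityquant.geometry import INDEX_NAMES, measure_indices
from parityquant.synthetic import (
    AGE_GROUPS,
    TOOTH_SITES,
    DemographicRecord,
    ImageConfig,
    PopulationConfig,
    apportion,
    assign_splits,
    bone_mask,
    build_dataset,
    render_image,
    sample_geometry,
    sample_population,
)

DESK_IMAGE = ImageConfig(size=64, pixel_spacing=0.5)


def desk_config(**kw) -> PopulationConfig:
    kw.setdefault("image", DESK_IMAGE)
    return PopulationConfig(**kw)


class TestSamplePopulation:
    def test_single_patient_has_four_tooth_sites(self):
        recs = sample_population(desk_config(n_patients=1, seed=3))
        assert len(recs) == 4
        assert {r.tooth_site for r in recs} == set(TOOTH_SITES)

    def test_sex_ratio_within_binomial_bounds(self):
        recs = sample_population(desk_config(n_patients=1000, seed=11))
        males = sum(1 for r in recs if r.sex == "male") / 4
        sd = np.sqrt(1000 * 0.388 * 0.612)
        assert abs(males - 388) <= 3 * sd

    def test_age_truncated_and_group_consistent(self):
        recs = sample_population(desk_config(n_patients=300, seed=2))
        ages = np.array([r.age for r in recs])
        assert ages.min() >= 18.0
        for r in recs:
            r.validate()
        # rough location check of the truncated normal
        assert 33.0 < ages.mean() < 40.0

    def test_deterministic_given_seed(self):
        a = sample_population(desk_config(n_patients=40, seed=9))
        b = sample_population(desk_config(n_patients=40, seed=9))
        assert a == b

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            desk_config(n_patients=0).validate()
        with pytest.raises(ValueError):
            desk_config(male_fraction=1.5).validate()
        with pytest.raises(ValueError):
            desk_config(sex_effect=0.0).validate()


class TestSampleGeometry:
    def test_deterministic_given_rng_state(self):
        cfg = desk_config(seed=0)
        rec = DemographicRecord("P0", "female", 30.0, "30-49", "#11")
        g1 = sample_geometry(rec, cfg, np.random.default_rng(5))
        g2 = sample_geometry(rec, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(g1.buccal_contour, g2.buccal_contour)
        np.testing.assert_array_equal(g1.crest_point, g2.crest_point)

    def test_geometries_satisfy_invariants(self):
        cfg = desk_config(seed=1)
        rng = np.random.default_rng(0)
        for i in range(20):
            rec = DemographicRecord(f"P{i}", "male" if i % 2 else "female", 25.0, "18-29", "#12")
            sample_geometry(rec, cfg, rng).validate()

    def test_null_sex_effect_gives_equal_width_distributions(self):
        cfg = desk_config(sex_effect=1.0, seed=21)
        rng = np.random.default_rng(21)
        widths = {"male": [], "female": []}
        for sex in widths:
            for i in range(150):
                rec = DemographicRecord(f"P{i}", sex, 30.0, "30-49", "#11")
                widths[sex].append(measure_indices(sample_geometry(rec, cfg, rng))["apical2mm"])
        m, f = np.mean(widths["male"]), np.mean(widths["female"])
        se = np.sqrt(np.var(widths["male"]) / 150 + np.var(widths["female"]) / 150)
        assert abs(m - f) < 3 * se

    def test_sex_effect_scales_mean_width_ratio(self):
        cfg = desk_config(sex_effect=1.3, seed=22)
        rng = np.random.default_rng(22)
        widths = {"male": [], "female": []}
        for sex in widths:
            for i in range(500):
                rec = DemographicRecord(f"P{i}", sex, 30.0, "30-49", "#11")
                widths[sex].append(measure_indices(sample_geometry(rec, cfg, rng))["apical2mm"])
        ratio = np.mean(widths["male"]) / np.mean(widths["female"])
        se = ratio * np.sqrt(
            np.var(widths["male"]) / (500 * np.mean(widths["male"]) ** 2)
            + np.var(widths["female"]) / (500 * np.mean(widths["female"]) ** 2)
        )
        assert abs(ratio - 1.3) < 3 * se


class TestRenderImage:
    def _one_geometry(self, seed=4):
        cfg = desk_config(seed=seed)
        rec = DemographicRecord("P0", "female", 40.0, "30-49", "#21")
        return sample_geometry(rec, cfg, np.random.default_rng(seed)), cfg

    def test_intensity_ordering_tooth_bone_background(self):
        geom, cfg = self._one_geometry()
        img_cfg = ImageConfig(size=64, pixel_spacing=0.5, blur_sigma_px=0.0, noise_sd=0.0)
        img = render_image(geom, img_cfg)
        mid = geom.tooth_axis.at(geom.tooth_axis.project_t(geom.apex_point) / 2)
        px = (mid / img_cfg.pixel_spacing).round().astype(int)
        tooth_val = img[px[1], px[0]]
        corner_val = img[1, 1]
        bone_pt = (geom.crest_point + np.array([2.5, 6.0]))  # palatal side, mid-height
        bpx = (bone_pt / img_cfg.pixel_spacing).round().astype(int)
        bone_val = img[bpx[1], bpx[0]]
        assert tooth_val > bone_val > corner_val

    def test_noiseless_render_deterministic(self):
        geom, cfg = self._one_geometry()
        img_cfg = ImageConfig(size=64, pixel_spacing=0.5, noise_sd=0.0)
        np.testing.assert_array_equal(render_image(geom, img_cfg), render_image(geom, img_cfg))

    def test_geometry_outside_fov_raises(self):
        geom, cfg = self._one_geometry()
        tiny = ImageConfig(size=16, pixel_spacing=0.5)
        with pytest.raises(ValueError, match="field of view"):
            render_image(geom, tiny)

    def test_length_recovered_from_noiseless_image(self):
        """Boundary crossings along the tooth axis on the rendered array
        reproduce LTAcb within two pixels (sub-pixel rendering oracle)."""
        geom, cfg = self._one_geometry(seed=6)
        img_cfg = ImageConfig(size=128, pixel_spacing=0.25, blur_sigma_px=0.0, noise_sd=0.0)
        img = render_image(geom, img_cfg)
        axis = geom.tooth_axis
        t0 = axis.project_t(geom.crest_point)
        ts = np.arange(t0, t0 + 30.0, 0.05)
        pts = np.array([axis.at(t) for t in ts]) / img_cfg.pixel_spacing
        ij = np.clip(pts.round().astype(int), 0, img_cfg.size - 1)
        vals = img[ij[:, 1], ij[:, 0]]
        inside = vals > (img_cfg.background + img_cfg.bone_level) / 2
        last_inside = np.max(np.where(inside))
        lta_cb_est = ts[last_inside] - t0
        true = measure_indices(geom)["LTAcb"]
        assert abs(lta_cb_est - true) <= 2 * img_cfg.pixel_spacing

    def test_bone_mask_covers_crest_to_basal(self):
        geom, cfg = self._one_geometry(seed=8)
        mask = bone_mask(geom, DESK_IMAGE)
        assert mask.shape == (64, 64)
        assert 0.05 < mask.mean() < 0.7


class TestApportionment:
    def test_five_patients_three_one_one(self):
        assert apportion(5) == (3, 1, 1)

    def test_ten_patients_exact_ratio(self):
        assert apportion(10) == (6, 2, 2)

    def test_thirty_eight_patients_largest_remainder(self):
        assert apportion(38) == (23, 8, 7)

    @given(st.integers(min_value=1, max_value=5000))
    @settings(max_examples=100, deadline=None)
    def test_parts_sum_and_order(self, n):
        parts = apportion(n)
        assert sum(parts) == n
        # train quota dominates at the 6:2:2 ratio
        assert parts[0] >= parts[1] >= 0 and parts[0] >= parts[2] >= 0


class TestBuildDataset:
    def test_bookkeeping_counts(self):
        ds = build_dataset(desk_config(n_patients=25, seed=1), render=False)
        assert len(ds.manifest) == 100
        assert ds.gt_array().size == 900

    def test_manifest_gt_equals_remeasurement(self):
        ds = build_dataset(desk_config(n_patients=10, seed=5), render=False)
        remeasured = np.array([measure_indices(g).values for g in ds.geometries])
        np.testing.assert_allclose(ds.gt_array(), remeasured, atol=1e-6)

    def test_patient_wise_split_disjoint(self):
        ds = build_dataset(desk_config(n_patients=10, seed=7), render=False)
        by_split = ds.manifest.groupby("split")["patient_id"].apply(set)
        assert len(by_split["train"] & by_split["validation"]) == 0
        assert len(by_split["train"] & by_split["test"]) == 0
        assert len(by_split["validation"] & by_split["test"]) == 0
        counts = ds.manifest.drop_duplicates("patient_id")["split"].value_counts()
        assert counts["train"] == 6 and counts["validation"] == 2 and counts["test"] == 2

    @given(st.integers(min_value=5, max_value=400), st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=100, deadline=None)
    def test_split_disjointness_property(self, n, seed):
        ids = [f"P{i}" for i in range(n)]
        split_of = assign_splits(ids, rng=np.random.default_rng(seed))
        assert set(split_of) == set(ids)
        counts = pd.Series(list(split_of.values())).value_counts()
        assert counts.get("train", 0) + counts.get("validation", 0) + counts.get("test", 0) == n

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="n_patients"):
            build_dataset(desk_config(n_patients=3, seed=0), render=False)

    def test_full_determinism_manifest_and_images(self):
        cfg = desk_config(n_patients=6, seed=13)
        a = build_dataset(cfg)
        b = build_dataset(cfg)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        np.testing.assert_array_equal(a.images, b.images)

    def test_save_png_format(self, tmp_path):
        import dataclasses

        cfg = desk_config(n_patients=5, seed=4)
        cfg = dataclasses.replace(cfg, image=dataclasses.replace(cfg.image, file_format="png"))
        ds = build_dataset(cfg)
        ds.save(tmp_path / "png_out")
        manifest = pd.read_csv(tmp_path / "png_out" / "manifest.csv")
        assert manifest["image_path"].str.endswith(".png").all()
        assert (tmp_path / "png_out" / manifest["image_path"].iloc[0]).exists()

    def test_save_round_trip(self, tmp_path):
        ds = build_dataset(desk_config(n_patients=5, seed=2))
        ds.save(tmp_path / "out")
        import tifffile

        manifest = pd.read_csv(tmp_path / "out" / "manifest.csv")
        assert len(manifest) == 20
        img = tifffile.imread(tmp_path / "out" / manifest["image_path"].iloc[0])
        np.testing.assert_allclose(img, ds.images[0], atol=1e-6)
        cfg2 = PopulationConfig.from_json((tmp_path / "out" / "config.json").read_text())
        assert cfg2 == ds.config
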