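"""End-to-end demographic-parity workflow.

Primary fit on the pooled dataset -> subgroup audit -> subdivision by the
sensitive attribute -> per-level submodels -> routed ensemble (each test record
scored by its own level's submodel) -> final evaluation, mirroring the
audit/subdivide/retrain/pool strategy.  The ensemble is a routing pool, not a
prediction average: demographic parity is realized by letting every stratum be
served by the model trained on its own population.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audit import AuditConfig, subgroup_audit
from .geometry import INDEX_NAMES
from .model import MultiQuantRegressor
from .stats import (
    PairedMeasurements,
    agreement_metrics,
    bland_altman,
    count_significant,
    wilcoxon_signed_rank,
)
from .synthetic import (
    PopulationConfig,
    SyntheticDataset,
    apportion,
    assign_splits,
    build_dataset,
)


# -- evaluation tables ------------------------------------------------------

def eval_table(gt: np.ndarray, pred: np.ndarray, model_label: str = "") -> pd.DataFrame:
    """Per-index evaluation table (means, difference, MAE, p, r, ICC).

    One row per index in canonical order; the difference column is pred - gt.
    """
    rows = []
    for j, name in enumerate(INDEX_NAMES):
        pairs = PairedMeasurements(gt[:, j], pred[:, j], name)
        m = agreement_metrics(pairs)
        _, p = wilcoxon_signed_rank(pairs)
        rows.append(
            {
                "index": name,
                "model": model_label,
                "n": gt.shape[0],
                "gt_mean": float(gt[:, j].mean()),
                "gt_sd": float(gt[:, j].std(ddof=1)),
                "pred_mean": float(pred[:, j].mean()),
                "pred_sd": float(pred[:, j].std(ddof=1)),
                "diff_mean": m["mean_diff"],
                "diff_sd": m["sd_diff"],
                "mae": m["mae"],
                "p": p,
                "r": m["pearson_r"],
                "icc": m["icc"],
            }
        )
    return pd.DataFrame(rows)


# -- configuration ----------------------------------------------------------

@dataclass
class PipelineConfig:
    """Nested configuration of the full workflow."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    model: dict = field(default_factory=dict)  # MultiQuantRegressor overrides
    audit: AuditConfig = field(default_factory=AuditConfig)
    subdivision_attribute: str | None = None  # override the audited verdict
    seed: int = 0

    def __post_init__(self):
        if self.subdivision_attribute is not None and self.subdivision_attribute not in self.audit.attributes:
            raise ValueError(
                f"subdivision override {self.subdivision_attribute!r} not among audit attributes {self.audit.attributes}"
            )

    @classmethod
    def desk_scale(cls, seed: int = 0, n_patients: int = 200, sex_effect: float = 1.0, **pop_kw) -> "PipelineConfig":
        """CPU-scale configuration: 64 px images, small backbone, short training."""
        from .synthetic import ImageConfig

        pop = PopulationConfig(
            n_patients=n_patients,
            sex_effect=sex_effect,
            image=ImageConfig(size=64, pixel_spacing=0.5),
            seed=seed,
            **pop_kw,
        )
        model = dict(
            backbone="small-resnet",
            learning_rate=2e-3,
            batch_size=32,
            epochs=30,
            val_every=10,
            random_state=seed,
        )
        return cls(population=pop, model=model, seed=seed)


def _make_model(config: PipelineConfig, seed: int) -> MultiQuantRegressor:
    params = dict(config.model)
    params["random_state"] = int(seed)
    return MultiQuantRegressor(**params)


def _split_arrays(ds: SyntheticDataset, manifest: pd.DataFrame | None = None):
    manifest = ds.manifest if manifest is None else manifest
    out = {}
    gt_cols = [f"gt_{n}" for n in INDEX_NAMES]
    for split in ("train", "validation", "test"):
        rows = manifest.index[manifest["split"] == split].to_numpy()
        out[split] = (ds.images[rows], manifest.loc[rows, gt_cols].to_numpy(dtype=float), rows)
    return out


# -- stages -----------------------------------------------------------------

def run_primary(config: PipelineConfig):
    """Build the dataset, train the pooled model, evaluate and audit it.

    Returns ``(dataset, model, eval_table, audit_report, test_predictions)``.
    """
    ds = build_dataset(config.population)
    parts = _split_arrays(ds)
    model = _make_model(config, config.seed)
    model.fit(parts["train"][0], parts["train"][1], X_val=parts["validation"][0], y_val=parts["validation"][1])
    X_test, y_test, test_rows = parts["test"]
    pred = model.predict(X_test)
    table = eval_table(y_test, pred, "primary")
    report = subgroup_audit(ds.manifest.loc[test_rows].reset_index(drop=True), pred, config.audit)
    return ds, model, table, report, pred


def subdivide(
    manifest: pd.DataFrame,
    attribute: str,
    seed: int = 0,
    ratio=(6, 2, 2),
    min_patients: int = 5,
    resplit: bool = False,
) -> dict:
    """Split the manifest into per-level manifests along one attribute.

    With ``resplit=False`` (default) each level keeps the original patient-wise
    split restricted to that level, so the union of the level test sets is the
    original test set and before/after comparisons share their test records.
    ``resplit=True`` draws a fresh patient-wise 6:2:2 split within each level
    (largest-remainder apportionment, level-derived seed).
    """
    if attribute not in manifest.columns:
        raise ValueError(f"attribute {attribute!r} missing from manifest")
    out = {}
    for level in sorted(manifest[attribute].astype(str).unique()):
        sub = manifest[manifest[attribute].astype(str) == level].copy()
        patients = sorted(sub["patient_id"].unique())
        if len(patients) < min_patients:
            raise ValueError(f"level {level!r} has only {len(patients)} patients (need >= {min_patients})")
        if resplit:
            rng = np.random.default_rng((seed + zlib.crc32(level.encode())) % (2**31))
            split_of = assign_splits(patients, ratio, rng)
            sub["split"] = sub["patient_id"].map(split_of)
        out[level] = sub
    return out


def train_submodels(ds: SyntheticDataset, subsets: dict, config: PipelineConfig) -> dict:
    """Train one submodel per level with identical architecture/hyperparameters.

    Per-level seeds are derived deterministically from the global seed and the
    level name.
    """
    models = {}
    for level, sub in subsets.items():
        parts = _split_arrays(ds, sub)
        seed = (config.seed * 1000 + zlib.crc32(str(level).encode())) % (2**31)
        model = _make_model(config, seed)
        x_val, y_val = parts["validation"][0], parts["validation"][1]
        if len(x_val) == 0:
            x_val = y_val = None
        try:
            model.fit(parts["train"][0], parts["train"][1], X_val=x_val, y_val=y_val)
        except Exception as e:
            raise RuntimeError(f"submodel training failed for level {level!r}: {e}") from e
        models[level] = model
    return models


def ensemble_pool(per_level: dict, label: str = "ensemble"):
    """Pool per-level test predictions into the routed-ensemble evaluation.

    ``per_level`` maps level -> dict with keys ``ids`` (test record ids),
    ``gt`` (n, 9) and ``pred`` (n, 9).  Levels must have disjoint test sets;
    each record is scored by its own level's submodel.  Returns
    ``(pooled_frame, eval_table)``.
    """
    ids: list = []
    gts, preds, levels = [], [], []
    for level, d in per_level.items():
        if len(d["ids"]) == 0:
            continue
        overlap = set(ids) & set(d["ids"])
        if overlap:
            raise ValueError(f"overlapping test ids across levels: {sorted(overlap)[:5]}")
        ids.extend(d["ids"])
        gts.append(np.asarray(d["gt"], float))
        preds.append(np.asarray(d["pred"], float))
        levels.extend([level] * len(d["ids"]))
    gt = np.vstack(gts)
    pred = np.vstack(preds)
    pooled = pd.DataFrame({"image_id": ids, "level": levels})
    for j, name in enumerate(INDEX_NAMES):
        pooled[f"gt_{name}"] = gt[:, j]
        pooled[f"pred_{name}"] = pred[:, j]
    return pooled, eval_table(gt, pred, label)


def rater_comparison(raters: dict, subsample_fraction: float = 0.10, seed: int = 0) -> dict:
    """Pairwise ICC(2,1) per index over a common random image subsample.

    ``raters`` maps a rater label (junior | senior | GT | AI) to a DataFrame
    indexed by image id with the nine index columns.  Returns
    ``{index: DataFrame}`` of symmetric rater-by-rater ICC matrices.
    """
    from .stats import icc_2_1

    if len(raters) < 2:
        raise ValueError("need at least two raters")
    common = None
    for df in raters.values():
        common = set(df.index) if common is None else common & set(df.index)
    if not common:
        raise ValueError("raters share no common image ids")
    common = sorted(common)
    rng = np.random.default_rng(seed)
    k = max(2, int(round(subsample_fraction * len(common))))
    chosen = sorted(rng.choice(len(common), size=min(k, len(common)), replace=False))
    sample_ids = [common[i] for i in chosen]
    labels = list(raters)
    out = {}
    for name in INDEX_NAMES:
        mat = np.ones((len(labels), len(labels)))
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                va = raters[labels[a]].loc[sample_ids, name].to_numpy(dtype=float)
                vb = raters[labels[b]].loc[sample_ids, name].to_numpy(dtype=float)
                mat[a, b] = mat[b, a] = icc_2_1(va, vb)
        out[name] = pd.DataFrame(mat, index=labels, columns=labels)
    return out


def simulate_raters(gt: pd.DataFrame, noise_sd: dict | float, bias: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Synthetic clinician: ground truth + Gaussian noise (+ constant bias)."""
    rng = np.random.default_rng(seed)
    out = gt.copy()
    for name in INDEX_NAMES:
        sd = noise_sd[name] if isinstance(noise_sd, dict) else noise_sd
        out[name] = gt[name] + bias + rng.normal(0.0, sd, len(gt))
    return out


def run_full(config: PipelineConfig, outdir=None, n_gradcam: int = 8) -> dict:
    """The whole workflow; returns a report bundle dict (and writes artifacts).

    Stages: primary fit -> audit -> subdivide by the sensitive attribute (or
    the configured override) -> submodels -> routed ensemble -> final tables,
    Bland–Altman data and Grad-CAM maps, plus the before/after comparison of
    significant-bias counts.
    """
    ds, primary, primary_table, report, primary_pred = run_primary(config)
    attribute = config.subdivision_attribute or report.sensitive_attribute

    subsets = subdivide(ds.manifest, attribute, seed=config.seed)
    submodels = train_submodels(ds, subsets, config)

    per_level = {}
    gt_cols = [f"gt_{n}" for n in INDEX_NAMES]
    for level, sub in subsets.items():
        rows = sub.index[sub["split"] == "test"].to_numpy()
        per_level[level] = {
            "ids": sub.loc[rows, "image_id"].tolist(),
            "gt": sub.loc[rows, gt_cols].to_numpy(dtype=float),
            "pred": submodels[level].predict(ds.images[rows]),
        }
    pooled, ensemble_table = ensemble_pool(per_level)

    n_sig_primary = count_significant(primary_table["p"], config.audit.alpha)
    n_sig_ensemble = count_significant(ensemble_table["p"], config.audit.alpha)

    # stratum-resolved bias counts over the subdivision attribute: the sum of
    # per-level significant indices before (pooled model, from the audit) and
    # after (each level scored by its own submodel) — the per-stratum panels
    bias_count_primary = sum(report.significant_counts[attribute].values())
    bias_count_ensemble = 0
    for level, d in per_level.items():
        if len(d["ids"]) == 0:
            continue
        ps = [
            wilcoxon_signed_rank(PairedMeasurements(d["gt"][:, j], d["pred"][:, j], name))[1]
            for j, name in enumerate(INDEX_NAMES)
        ]
        bias_count_ensemble += count_significant(ps, config.audit.alpha)

    ba = {
        name: bland_altman(
            PairedMeasurements(pooled[f"gt_{name}"], pooled[f"pred_{name}"], name)
        )
        for name in INDEX_NAMES
    }

    rng = np.random.default_rng(config.seed)
    test_rows = ds.manifest.index[ds.manifest["split"] == "test"].to_numpy()
    cam_rows = rng.choice(test_rows, size=min(n_gradcam, len(test_rows)), replace=False)
    gradcams = {
        str(ds.manifest.loc[i, "image_id"]): primary.grad_cam(ds.images[i], 0) for i in cam_rows
    }

    bundle = {
        "dataset": ds,
        "primary_model": primary,
        "primary_table": primary_table,
        "audit_report": report,
        "attribute": attribute,
        "submodels": submodels,
        "pooled": pooled,
        "ensemble_table": ensemble_table,
        "n_significant_primary": n_sig_primary,
        "n_significant_ensemble": n_sig_ensemble,
        "bias_count_primary": bias_count_primary,
        "bias_count_ensemble": bias_count_ensemble,
        "bland_altman": ba,
        "gradcams": gradcams,
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir), config)
    return bundle


def _write_bundle(bundle: dict, outdir: Path, config: PipelineConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    bundle["primary_table"].to_csv(outdir / "primary_eval.csv", index=False)
    bundle["ensemble_table"].to_csv(outdir / "ensemble_eval.csv", index=False)
    bundle["audit_report"].to_json(outdir / "audit_report.json")
    bundle["pooled"].to_csv(outdir / "ensemble_pairs.csv", index=False)
    ba_rows = [
        {"index": k, "bias": v["bias"], "lower_loa": v["lower_loa"], "upper_loa": v["upper_loa"]}
        for k, v in bundle["bland_altman"].items()
    ]
    pd.DataFrame(ba_rows).to_csv(outdir / "bland_altman.csv", index=False)
    camdir = outdir / "gradcam"
    camdir.mkdir(exist_ok=True)
    for image_id, cam in bundle["gradcams"].items():
        fig, ax = plt.subplots(figsize=(3, 3))
        ax.imshow(cam, cmap="jet")
        ax.axis("off")
        fig.savefig(camdir / f"{image_id}.png", dpi=72, bbox_inches="tight")
        plt.close(fig)
    lines = [
        "# Demographic-parity multi-quantification report",
        "",
        f"- sensitive attribute: **{bundle['audit_report'].sensitive_attribute}** (subdivided by: {bundle['attribute']})",
        f"- per-attribute disparity: {bundle['audit_report'].disparity}",
        f"- significant-bias indices, primary model: {bundle['n_significant_primary']}/9",
        f"- significant-bias indices, parity ensemble: {bundle['n_significant_ensemble']}/9",
        f"- per-stratum significant-bias count, primary: {bundle['bias_count_primary']}",
        f"- per-stratum significant-bias count, ensemble: {bundle['bias_count_ensemble']}",
        "",
        "See primary_eval.csv / ensemble_eval.csv for the per-index tables.",
    ]
    (outdir / "report.md").write_text("\n".join(lines))


# -- Monte-Carlo fairness harness -------------------------------------------

def derive_seed(base_seed: int, index: int) -> int:
    """Deterministic, well-spread per-replicate seed below 2**31."""
    return int(np.random.SeedSequence([int(base_seed), int(index)]).generate_state(1)[0] % (2**31))


def fairness_monte_carlo(
    n_seeds: int = 10,
    sex_effect: float = 1.3,
    male_fraction: float = 0.388,
    base_seed: int = 0,
    n_patients: int = 200,
    full: bool = True,
) -> pd.DataFrame:
    """Replicate the parity workflow over independent seeds at desk scale.

    One row per replicate with the audit verdict, per-attribute disparities and
    the before/after significant-bias counts.  ``full=False`` runs only the
    primary fit + audit (the null-calibration harness).
    """
    rows = []
    for i in range(n_seeds):
        seed = derive_seed(base_seed, i)
        config = PipelineConfig.desk_scale(
            seed=seed, n_patients=n_patients, sex_effect=sex_effect, male_fraction=male_fraction
        )
        if full:
            b = run_full(config)
            report = b["audit_report"]
            row = {
                "seed": seed,
                "sensitive_attribute": report.sensitive_attribute,
                "n_significant_primary": b["n_significant_primary"],
                "n_significant_ensemble": b["n_significant_ensemble"],
                "bias_count_primary": b["bias_count_primary"],
                "bias_count_ensemble": b["bias_count_ensemble"],
                "ensemble_mean_mae": float(b["ensemble_table"]["mae"].mean()),
            }
        else:
            _, _, table, report, _ = run_primary(config)
            row = {
                "seed": seed,
                "sensitive_attribute": report.sensitive_attribute,
                "n_significant_primary": count_significant(table["p"], config.audit.alpha),
            }
        for attr, d in report.disparity.items():
            row[f"disparity_{attr}"] = d
        row["max_disparity"] = max(report.disparity.values())
        rows.append(row)
    return pd.DataFrame(rows)
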