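"""Subgroup bias audit: which demographic attribute is "sensitive"?

For every demographic attribute (sex, age group, tooth site), every level of
that attribute, and every index, the audit runs a paired Wilcoxon signed-rank
test between predictions and ground truth within the stratum.  The per-level
count of significantly biased indices summarizes how unevenly the model serves
the strata; the attribute's *disparity* is the max-minus-min of those counts
over its (sufficiently populated) levels, and the sensitive attribute is the
argmax of disparity — ties broken by larger total significant count, then by
attribute order.  Strata with fewer than ``min_stratum_n`` pairs are flagged as
underpowered and excluded from the disparity.

No multiple-testing correction is applied across indices or strata: each test
is read at the configured per-test alpha, mirroring common clinical-audit
practice (a questionable but deliberate convention, see the methods note).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import INDEX_NAMES
from .stats import PairedMeasurements, count_significant, wilcoxon_signed_rank

DEFAULT_ATTRIBUTES = ("sex", "age_group", "tooth_site")


@dataclass(frozen=True)
class AuditConfig:
    alpha: float = 0.05
    attributes: tuple = DEFAULT_ATTRIBUTES
    min_stratum_n: int = 5
    disparity_threshold: int = 1  # disparity >= threshold flags an attribute

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class AuditReport:
    """Per-attribute/level/index p-values and the sensitive-attribute verdict."""

    p_matrix: dict  # attribute -> level -> index -> p
    stratum_sizes: dict  # attribute -> level -> n pairs
    underpowered: list  # (attribute, level) excluded from disparity
    significant_counts: dict  # attribute -> level -> count at alpha
    disparity: dict  # attribute -> max-min significant count over powered levels
    sensitive_attribute: str
    any_flagged: bool
    alpha: float
    note: str = ""

    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.alpha,
            "sensitive_attribute": self.sensitive_attribute,
            "any_flagged": self.any_flagged,
            "disparity": self.disparity,
            "significant_counts": self.significant_counts,
            "stratum_sizes": self.stratum_sizes,
            "underpowered": [list(u) for u in self.underpowered],
            "p_matrix": self.p_matrix,
            "note": self.note,
        }
        s = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def p_frame(self) -> pd.DataFrame:
        rows = []
        for attr, levels in self.p_matrix.items():
            for level, ps in levels.items():
                rows.append({"attribute": attr, "level": level, **ps})
        return pd.DataFrame(rows)


def subgroup_audit(
    test_manifest: pd.DataFrame,
    predictions: np.ndarray,
    config: AuditConfig | None = None,
) -> AuditReport:
    """Audit aligned test-set predictions across demographic strata.

    ``test_manifest`` must contain the attribute columns plus the nine
    ``gt_<index>`` columns; ``predictions`` is the aligned (n, 9) array.
    """
    cfg = config or AuditConfig()
    pred = np.asarray(predictions, dtype=float)
    if pred.shape != (len(test_manifest), len(INDEX_NAMES)):
        raise ValueError(f"predictions must be ({len(test_manifest)}, {len(INDEX_NAMES)}), got {pred.shape}")
    gt = test_manifest[[f"gt_{n}" for n in INDEX_NAMES]].to_numpy(dtype=float)

    p_matrix: dict = {}
    sizes: dict = {}
    counts: dict = {}
    underpowered: list = []
    disparity: dict = {}
    for attr in cfg.attributes:
        if attr not in test_manifest.columns:
            raise ValueError(f"attribute {attr!r} missing from manifest")
        p_matrix[attr] = {}
        sizes[attr] = {}
        counts[attr] = {}
        powered_counts = []
        for level in sorted(test_manifest[attr].astype(str).unique()):
            mask = (test_manifest[attr].astype(str) == level).to_numpy()
            n = int(mask.sum())
            sizes[attr][level] = n
            ps = {}
            for j, name in enumerate(INDEX_NAMES):
                pairs = PairedMeasurements(gt[mask, j], pred[mask, j], name)
                ps[name] = wilcoxon_signed_rank(pairs)[1]
            p_matrix[attr][level] = ps
            c = count_significant(ps.values(), cfg.alpha)
            counts[attr][level] = c
            if n < cfg.min_stratum_n:
                underpowered.append((attr, level))
            else:
                powered_counts.append(c)
        disparity[attr] = int(max(powered_counts) - min(powered_counts)) if len(powered_counts) >= 2 else 0

    def rank_key(attr):
        total = sum(
            counts[attr][lv]
            for lv in counts[attr]
            if (attr, lv) not in underpowered
        )
        return (disparity[attr], total, -list(cfg.attributes).index(attr))

    sensitive = max(cfg.attributes, key=rank_key)
    any_flagged = any(d >= cfg.disparity_threshold for d in disparity.values())
    note = "" if any_flagged else "no attribute exceeds disparity threshold"
    return AuditReport(
        p_matrix=p_matrix,
        stratum_sizes=sizes,
        underpowered=underpowered,
        significant_counts=counts,
        disparity=disparity,
        sensitive_attribute=sensitive,
        any_flagged=any_flagged,
        alpha=cfg.alpha,
        note=note,
    )
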