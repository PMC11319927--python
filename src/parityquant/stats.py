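"""Agreement statistics: Wilcoxon signed-rank, MAE/MSE, Pearson r, ICC(2,1),
Bland–Altman.

The Wilcoxon signed-rank test follows the classical convention: zero
differences are dropped, tied absolute differences receive mid-ranks, the null
distribution is enumerated exactly for effective n <= 25 (generating-function
convolution over the 2^n sign assignments), and a tie- and continuity-corrected
normal approximation is used beyond that.

The intraclass correlation is the two-way random-effects, absolute-agreement,
single-measure form — ICC(2,1) — computed from the two-way ANOVA mean squares;
it is the standard choice for agreement between two measurement methods and is
deliberately sensitive to systematic offsets (unlike Pearson r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class PairedMeasurements:
    """Ground-truth and predicted values (mm) for one index."""

    gt: np.ndarray
    pred: np.ndarray
    index_name: str = ""

    def __post_init__(self):
        g = np.asarray(self.gt, dtype=float).ravel()
        p = np.asarray(self.pred, dtype=float).ravel()
        if g.shape != p.shape:
            raise ValueError(f"gt and pred lengths differ: {g.shape} vs {p.shape}")
        if g.size < 1:
            raise ValueError("need at least one pair")
        if not (np.all(np.isfinite(g)) and np.all(np.isfinite(p))):
            raise ValueError("all values must be finite")
        object.__setattr__(self, "gt", g)
        object.__setattr__(self, "pred", p)


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact p over all 2^n sign assignments via polynomial convolution.

    Mid-ranks are doubled so all rank sums are integers.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(round(2 * w_plus))
    cdf = float(pmf[: w2 + 1].sum())
    sf = float(pmf[w2:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_signed_rank(pairs: PairedMeasurements, exact_max_n: int = 25) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test on pred - gt.

    Returns ``(W_plus, p_two_sided)``; if all differences are zero the test is
    degenerate and ``(0.0, 1.0)`` is returned.
    """
    d = pairs.pred - pairs.gt
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return w_plus, _exact_two_sided_p(ranks, w_plus)
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        return w_plus, 1.0
    # continuity correction toward the mean
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sigma if w_plus != mu else 0.0
    return w_plus, float(2.0 * sps.norm.sf(abs(z)))


def icc_2_1(gt, pred) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares for n targets x k=2 raters:
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``.
    Returns NaN when either list has zero variance together with the other
    (degenerate ANOVA).
    """
    data = np.column_stack([np.asarray(gt, float), np.asarray(pred, float)])
    n, k = data.shape
    if n < 2:
        return float("nan")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return float("nan")
    return float((msr - mse) / denom)


def agreement_metrics(pairs: PairedMeasurements) -> dict:
    """Mean difference (pred - gt), SD of differences, MAE, MSE, Pearson r, ICC(2,1).

    ``r`` and ``icc`` are NaN (not exceptions) when a list has zero variance.
    """
    d = pairs.pred - pairs.gt
    out = {
        "mean_diff": float(d.mean()),
        "sd_diff": float(d.std(ddof=1)) if d.size > 1 else 0.0,
        "mae": float(np.abs(d).mean()),
        "mse": float((d**2).mean()),
    }
    if pairs.gt.size >= 2 and pairs.gt.std() > 0 and pairs.pred.std() > 0:
        out["pearson_r"] = float(sps.pearsonr(pairs.gt, pairs.pred)[0])
    else:
        out["pearson_r"] = float("nan")
    out["icc"] = icc_2_1(pairs.gt, pairs.pred) if pairs.gt.size >= 2 else float("nan")
    return out


def bland_altman(pairs: PairedMeasurements) -> dict:
    """Bland–Altman bias and 95% limits of agreement (bias ± 1.96 SD)."""
    if pairs.gt.size < 2:
        raise ValueError("need at least two pairs")
    d = pairs.pred - pairs.gt
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "lower_loa": bias - 1.96 * sd,
        "upper_loa": bias + 1.96 * sd,
        "means": (pairs.pred + pairs.gt) / 2.0,
        "differences": d,
    }


def count_significant(p_values, alpha: float = 0.05) -> int:
    """Number of p-values strictly below alpha."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return int(np.sum(p < alpha))
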