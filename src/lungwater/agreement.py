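"""Method-agreement and study-design statistics.

Bland–Altman bias/limits of agreement with their sampling precision
(Var(LoA) ≈ 3σ²/n), precision-based and power-based paired sample sizes
(normal-approximation z quantiles throughout — the convention that matches
precision-based design tables), a Shapiro–Wilk-gated paired comparison, and
Spearman rank correlation.

Sign convention: paired differences are always reference - test and this is
deliberately NOT configurable, so a bias sign can never silently flip between
runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .errors import NumericError, ValidationError

__all__ = [
    "BlandAltmanResult",
    "bland_altman",
    "loa_ci_halfwidth",
    "min_n_for_loa_precision",
    "paired_n",
    "detectable_delta",
    "paired_compare",
    "spearman_corr",
    "summarize",
    "round_half_up",
]

#: LoA multiplier, exactly 1.96 by convention.
LOA_MULTIPLIER = 1.96


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for reported precisions)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _paired(reference, test) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.ndim != 1 or tst.ndim != 1:
        raise ValidationError("paired series must be 1-D")
    if ref.size != tst.size:
        raise ValidationError(f"paired series length mismatch: {ref.size} vs {tst.size}")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(tst))):
        raise ValidationError("paired series contain non-finite values")
    return ref, tst


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias, SD of differences, 95% limits of agreement and their precision.

    All quantities in the units of the input series (ml/kg here); differences
    are reference - test.
    """

    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    loa_ci_halfwidth: float
    n: int


def loa_ci_halfwidth(sd_diff: float, n: int, alpha: float = 0.05) -> float:
    """95% CI half-width of each limit of agreement: z * sd * sqrt(3/n)."""
    if sd_diff < 0:
        raise ValidationError("sd_diff must be >= 0")
    if n < 1:
        raise ValidationError("n must be >= 1")
    z = stats.norm.ppf(1 - alpha / 2)
    return float(z * sd_diff * math.sqrt(3.0 / n))


def bland_altman(reference, test) -> BlandAltmanResult:
    """Bland–Altman agreement between a reference and a test method.

    Differences are reference - test; bias is their mean, LoA are
    bias ± 1.96 * SD (sample SD, n-1).
    """
    ref, tst = _paired(reference, test)
    n = ref.size
    if n < 2:
        raise ValidationError(f"Bland–Altman requires n >= 2, got {n}")
    d = ref - tst
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        loa_ci_halfwidth=loa_ci_halfwidth(sd, n),
        n=int(n),
    )


def _ceil(x: float) -> int:
    # guard against ceil(45.000000001) when the exact answer is 45
    return max(1, int(math.ceil(round(x, 9))))


def min_n_for_loa_precision(sd_diff: float, halfwidth_target: float, alpha: float = 0.05) -> int:
    """Smallest n with z * sd_diff * sqrt(3/n) <= halfwidth_target.

    Precision-based Bland–Altman sample size using Var(LoA) ≈ 3σ²/n.
    """
    if sd_diff <= 0 or halfwidth_target <= 0:
        raise ValidationError("sd_diff and halfwidth_target must be > 0")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if math.isinf(halfwidth_target):
        return 1
    z = stats.norm.ppf(1 - alpha / 2)
    return _ceil(3.0 * (z * sd_diff / halfwidth_target) ** 2)


def paired_n(delta: float, sd_diff: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Paired-comparison sample size, normal approximation, rounded up.

    n = ceil((z_{1-α/2} + z_{power})² * sd² / δ²), clamped to at least 1.
    """
    if delta <= 0:
        raise ValidationError("delta must be > 0")
    if sd_diff <= 0:
        raise ValidationError("sd_diff must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must be in (0, 1)")
    if math.isinf(delta):
        return 1
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    return _ceil((z_a + z_b) ** 2 * sd_diff**2 / delta**2)


def detectable_delta(n: int, sd_diff: float, alpha: float = 0.05, power: float = 0.80) -> float:
    """Smallest detectable mean paired difference at a given n (continuous inverse
    of :func:`paired_n`): (z_{1-α/2} + z_{power}) * sd / sqrt(n)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if sd_diff < 0:
        raise ValidationError("sd_diff must be >= 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must be in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    return float((z_a + z_b) * sd_diff / math.sqrt(n))


def paired_compare(reference, test, normality_alpha: float = 0.05) -> dict:
    """Shapiro–Wilk-gated paired comparison.

    Tests normality of the paired differences; if p >= ``normality_alpha``
    runs a paired t-test, otherwise a Wilcoxon signed-rank test (exact p for
    n <= 25 without ties/zeros, normal approximation with continuity
    correction otherwise).  Returns which branch ran.
    """
    ref, tst = _paired(reference, test)
    n = ref.size
    if n < 3:
        raise ValidationError(f"paired_compare requires n >= 3, got {n}")
    d = ref - tst
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; comparison is degenerate", stacklevel=2)
        return {"test_name": "degenerate", "statistic": 0.0, "p_value": 1.0, "shapiro_p": None}
    sw_stat, sw_p = stats.shapiro(d)
    if sw_p >= normality_alpha:
        t_stat, p = stats.ttest_1samp(d, 0.0)
        return {
            "test_name": "paired_t",
            "statistic": float(t_stat),
            "p_value": float(p),
            "shapiro_p": float(sw_p),
        }
    nz = d[d != 0]
    exact_ok = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size and nz.size == d.size
    method = "exact" if exact_ok else "approx"
    w_stat, p = stats.wilcoxon(d, method=method, correction=(method == "approx"))
    return {
        "test_name": "wilcoxon",
        "statistic": float(w_stat),
        "p_value": float(p),
        "shapiro_p": float(sw_p),
    }


def spearman_corr(reference, test) -> dict:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    ref, tst = _paired(reference, test)
    if ref.size < 3:
        raise ValidationError(f"spearman_corr requires n >= 3, got {ref.size}")
    if np.ptp(ref) == 0 or np.ptp(tst) == 0:
        raise NumericError("Spearman correlation undefined for a constant series")
    rho, p = stats.spearmanr(ref, tst)
    return {"rho": float(rho), "p_value": float(p)}


def summarize(values, normality_alpha: float = 0.05) -> dict:
    """Normality-gated descriptive summary.

    Shapiro–Wilk p >= alpha -> {"kind": "mean_sd", ...}; otherwise median with
    linear-interpolation (median-inclusive) quartiles.
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 3:
        raise ValidationError("summarize requires a 1-D sample with n >= 3")
    if np.ptp(vals) == 0:
        return {"kind": "mean_sd", "mean": float(vals[0]), "sd": 0.0}
    _, sw_p = stats.shapiro(vals)
    if sw_p >= normality_alpha:
        return {"kind": "mean_sd", "mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {"kind": "median_iqr", "median": float(med), "q1": float(q1), "q3": float(q3)}
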