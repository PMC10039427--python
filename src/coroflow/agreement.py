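"""Method-comparison statistics: Pearson, Passing–Bablok, Bland–Altman.

Conventions used throughout:

* differences are **test minus reference** (computed minus invasive);
* the reference method sits on the independent axis of the Passing–Bablok
  regression;
* standard deviations use the population (divisor-``n``) convention;
* the interquartile range uses Tukey hinges (median of each half, the
  overall median excluded from both halves when ``n`` is odd);
* Pearson p-values are two-sided (t distribution, ``n - 2`` df).

Passing–Bablok regression follows the original rank procedure: the slope is
the shifted median of all pairwise slopes (slopes equal to −1 discarded, the
median offset by the count of slopes below −1 so the estimate is invariant
to swapping the axes), with rank-based confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PairedSample:
    """Paired measurements of one quantity by a reference and a test method."""

    reference: np.ndarray
    test: np.ndarray
    unit: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        tst = np.asarray(self.test, dtype=float)
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "test", tst)
        if ref.shape != tst.shape or ref.ndim != 1:
            raise ValueError("reference and test must be 1-D arrays of equal length")
        if ref.size < 3:
            raise ValueError(f"paired sample needs n >= 3, got {ref.size}")
        if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(tst))):
            raise ValueError("paired sample contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.reference.size)

    @property
    def delta(self) -> np.ndarray:
        """Pairwise differences, test minus reference."""
        return self.test - self.reference

    def log_transformed(self) -> "PairedSample":
        """Natural-log transform of both methods (requires positive values)."""
        if np.any(self.reference <= 0) or np.any(self.test <= 0):
            raise ValueError("log transform requires strictly positive values")
        return PairedSample(
            np.log(self.reference), np.log(self.test),
            unit=f"ln({self.unit})" if self.unit else "ln",
            label=self.label,
        )


@dataclass(frozen=True)
class AgreementReport:
    """Full comparison of a test method against a reference on paired data."""

    n: int
    r: float
    p: float
    pb_slope: float
    pb_intercept: float
    pb_slope_ci: tuple[float, float]
    pb_intercept_ci: tuple[float, float]
    ba_mean_delta: float
    ba_loa_low: float
    ba_loa_high: float
    unit: str = ""
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "unit": self.unit,
            "n": self.n,
            "pearson_r": self.r,
            "pearson_p": self.p,
            "pb_slope": self.pb_slope,
            "pb_slope_ci": list(self.pb_slope_ci),
            "pb_intercept": self.pb_intercept,
            "pb_intercept_ci": list(self.pb_intercept_ci),
            "ba_mean_delta": self.ba_mean_delta,
            "ba_limits": [self.ba_loa_low, self.ba_loa_high],
        }


def tukey_hinges(values) -> tuple[float, float]:
    """Lower and upper Tukey hinges (median of each half; odd n excludes the median)."""
    v = np.sort(np.asarray(values, dtype=float))
    half = v.size // 2
    return float(np.median(v[:half])), float(np.median(v[-half:]))


def summary_stats(values, skewed: bool = False) -> dict:
    """Location/spread summary: mean & population SD, or median & hinge IQR.

    Returns ``{"mean": ..., "sd": ...}`` for ``skewed=False`` and
    ``{"median": ..., "iqr": (lo, hi)}`` otherwise.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need at least 2 values, got {v.size}")
    if skewed:
        return {"median": float(np.median(v)), "iqr": tukey_hinges(v)}
    return {"mean": float(v.mean()), "sd": float(v.std(ddof=0))}


def pearson(sample: PairedSample) -> tuple[float, float]:
    """Product-moment correlation with two-sided p (t distribution, n-2 df)."""
    x, y = sample.reference, sample.test
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a zero-variance variable")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bland_altman(
    sample: PairedSample, multiplier: float = 1.96
) -> tuple[float, float, float]:
    """Mean difference and limits of agreement (mean ± multiplier · pop-SD).

    Differences are test − reference; the SD uses divisor n.
    """
    d = sample.delta
    mean = float(d.mean())
    half = multiplier * float(d.std(ddof=0))
    return mean, mean - half, mean + half


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = x.size
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = dy / dx
    # vertical pairs count as infinite slope of the sign of dy; 0/0 is dropped
    s[(dx == 0) & (dy > 0)] = np.inf
    s[(dx == 0) & (dy < 0)] = -np.inf
    s = s[~np.isnan(s)]
    return s[s != -1.0]


def passing_bablok(
    sample: PairedSample, alpha: float = 0.05
) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """Passing–Bablok rank regression of test on reference.

    Returns ``(slope, intercept, slope_ci, intercept_ci)``.  The slope is
    the median of all pairwise slopes shifted by ``K``, the number of slopes
    below −1 (slopes equal to −1 are excluded); the intercept is
    ``median(y - slope * x)``.  Confidence bounds come from the rank offsets
    ``C = z * sqrt(n(n-1)(2n+5)/18)`` around the shifted median; intercept
    bounds re-use the slope bounds.
    """
    x, y = sample.reference, sample.test
    if np.ptp(x) == 0:
        raise ValueError("Passing-Bablok undefined when all reference values are equal")
    S = np.sort(_pairwise_slopes(x, y))
    N = S.size
    if N == 0:
        raise ValueError("no valid pairwise slopes")
    K = int(np.sum(S < -1.0))

    def shifted_median(offset_lo: int, offset_hi: int | None = None) -> float:
        if offset_hi is None:
            return float(S[offset_lo])
        return float(0.5 * (S[offset_lo] + S[offset_hi]))

    if N % 2:
        slope = shifted_median((N + 1) // 2 + K - 1)
    else:
        slope = shifted_median(N // 2 + K - 1, N // 2 + K)
    intercept = float(np.median(y - slope * x))

    n = sample.n
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    C = z * math.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    M1 = int(round((N - C) / 2.0))
    M2 = N - M1 + 1
    lo_i = max(M1 + K - 1, 0)
    hi_i = min(M2 + K - 1, N - 1)
    slope_ci = (float(S[lo_i]), float(S[hi_i]))
    intercept_ci = (
        float(np.median(y - slope_ci[1] * x)),
        float(np.median(y - slope_ci[0] * x)),
    )
    return slope, intercept, slope_ci, intercept_ci


def mvd_diagnostics(
    reference_rmicro, test_rmicro, threshold: float = 460.0
) -> dict:
    """Threshold diagnostics for microvascular disease classification.

    A value strictly above ``threshold`` (mmHg·min/L) is positive.  Returns
    the 2×2 counts and sensitivity/specificity/PPV/NPV of the test method
    against the reference; degenerate proportions (zero denominator) are NaN
    with a warning.
    """
    ref = np.asarray(reference_rmicro, dtype=float)
    tst = np.asarray(test_rmicro, dtype=float)
    if ref.size == 0:
        raise ValueError("empty input")
    if ref.shape != tst.shape:
        raise ValueError("reference and test must have equal length")
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    rpos = ref > threshold
    tpos = tst > threshold
    tp = int(np.sum(rpos & tpos))
    fn = int(np.sum(rpos & ~tpos))
    fp = int(np.sum(~rpos & tpos))
    tn = int(np.sum(~rpos & ~tpos))

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    return {
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "n_ref_positive": tp + fn,
        "n_test_positive": tp + fp,
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "ppv": ratio(tp, tp + fp, "PPV"),
        "npv": ratio(tn, tn + fn, "NPV"),
    }


def compare(sample: PairedSample, multiplier: float = 1.96) -> AgreementReport:
    """Full agreement workup of a paired sample: r, Passing–Bablok, Bland–Altman."""
    r, p = pearson(sample)
    slope, intercept, s_ci, i_ci = passing_bablok(sample)
    mean_d, lo, hi = bland_altman(sample, multiplier)
    return AgreementReport(
        n=sample.n, r=r, p=p,
        pb_slope=slope, pb_intercept=intercept,
        pb_slope_ci=s_ci, pb_intercept_ci=i_ci,
        ba_mean_delta=mean_d, ba_loa_low=lo, ba_loa_high=hi,
        unit=sample.unit, label=sample.label,
    )
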