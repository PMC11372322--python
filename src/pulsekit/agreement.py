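"""HRV summaries and the method-agreement battery.

For two measurement methods of the same beat series (ECG R-R vs
camera-PPG pulse intervals) the battery computes Pearson correlation,
the single-rater two-way random-effects absolute-agreement intraclass
correlation ICC(A,1), and a Bland-Altman analysis: mean difference
(fixed bias, paired two-tailed t test), 1.96-SD limits of agreement,
and proportional bias as the OLS slope of the difference on the mean.
The difference direction is ECG minus PPG throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment import BeatPairing
from .types import IntervalSeries, InvalidInputError

__all__ = [
    "HRVSummary",
    "BlandAltmanResult",
    "AgreementResult",
    "AgreementReport",
    "LOA_MULTIPLIER",
    "hrv_summary",
    "pearson",
    "icc_two_way_random_absolute",
    "bland_altman",
    "compare_methods",
]

#: Limits-of-agreement multiplier (95% coverage under normal differences).
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class HRVSummary:
    n_beats: int
    mean_pi: float      # ms
    sdnn: float         # ms


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    fixed_bias_t: float
    fixed_bias_p: float
    prop_slope_b: float
    prop_slope_se: float
    prop_p: float
    prop_r2: float


@dataclass(frozen=True)
class AgreementResult:
    pearson_r: float
    pearson_p: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_degenerate: bool = False


@dataclass(frozen=True)
class AgreementReport:
    """Full per-comparison report: agreement stats plus per-method HRV."""

    level: str
    agreement: AgreementResult
    bland_altman: BlandAltmanResult
    hrv_ecg: HRVSummary | None = None
    hrv_ppg: HRVSummary | None = None
    n: int = 0
    extra: dict = field(default_factory=dict)


def hrv_summary(series: IntervalSeries) -> HRVSummary:
    """Mean pulse interval and SDNN (sample SD) over the valid intervals."""
    vals = series.valid_intervals
    if len(vals) < 2:
        raise InvalidInputError("HRV summary needs at least 2 valid intervals")
    return HRVSummary(n_beats=len(vals), mean_pi=float(vals.mean()),
                      sdnn=float(vals.std(ddof=1)))


def _summary_from_values(values: np.ndarray) -> HRVSummary:
    return HRVSummary(n_beats=len(values), mean_pi=float(np.mean(values)),
                      sdnn=float(np.std(values, ddof=1)))


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-tailed p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("pearson needs >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidInputError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def icc_two_way_random_absolute(x, y, alpha: float = 0.05) -> AgreementResult:
    """ICC(A,1): single-rater absolute agreement, two-way random effects.

    From the two-way ANOVA of an ``n x 2`` table (subjects x methods)::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    with ``k = 2``. The 95% CI follows the standard F-based interval
    for this form. Degenerate tables with no between-subject variance
    report ICC 0 with ``icc_degenerate=True``. Pearson r and its p are
    filled in alongside for convenience when both inputs vary.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("ICC needs >= 3 subjects with both methods")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    try:
        r, p = pearson(x, y)
    except InvalidInputError:
        r, p = float("nan"), float("nan")

    scale = max(ss_total / (n * k), 1e-300)
    if msr <= 1e-12 * scale:
        return AgreementResult(r, p, 0.0, float("nan"), float("nan"),
                               icc_degenerate=True)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    if mse <= 1e-15 * scale and msc <= 1e-15 * scale:
        # methods agree exactly: ICC and both CI bounds are 1
        return AgreementResult(r, p, 1.0, 1.0, 1.0)

    # F-based CI (two-way random absolute agreement, single rater), with
    # the Satterthwaite df combining MS_C (df k-1) and MS_E (df (n-1)(k-1))
    fj = msc / mse if mse > 0 else np.inf
    a = k * icc
    b = n * (1 + (k - 1) * icc) - k * icc
    if np.isfinite(fj):
        v_num = (n - 1) * (k - 1) * (a * fj + b) ** 2
        v_den = (n - 1) * a ** 2 * fj ** 2 + b ** 2
        v = v_num / v_den
    else:
        v = k - 1
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (msr - f1 * mse)
             / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr))
    upper = (n * (f2 * msr - mse)
             / (k * msc + (k * n - k - n) * mse + n * f2 * msr))
    return AgreementResult(r, p, float(icc),
                           float(min(lower, upper)), float(max(lower, upper)))


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman comparison of method A (x) minus method B (y).

    Differences ``d = x - y`` are summarized by their mean (fixed
    bias), sample SD, and ``mean +/- 1.96 SD`` limits of agreement; the
    fixed bias is tested with a paired two-tailed t test, and
    proportional bias is the OLS regression of ``d`` on the pairwise
    means ``(x + y)/2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("bland_altman needs >= 3 pairs")
    d = x - y
    m = (x + y) / 2.0
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if sd_diff > 0:
        t_stat, t_p = stats.ttest_rel(x, y)
    else:
        t_stat, t_p = (0.0, 1.0) if mean_diff == 0 else (np.inf, 0.0)
    if np.std(m) > 0 and sd_diff > 0:
        reg = stats.linregress(m, d)
        slope, se, p_slope, r2 = reg.slope, reg.stderr, reg.pvalue, reg.rvalue ** 2
    else:
        slope, se, p_slope, r2 = 0.0, 0.0, 1.0, 0.0
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_lower=mean_diff - LOA_MULTIPLIER * sd_diff,
        loa_upper=mean_diff + LOA_MULTIPLIER * sd_diff,
        fixed_bias_t=float(t_stat),
        fixed_bias_p=float(t_p),
        prop_slope_b=float(slope),
        prop_slope_se=float(se),
        prop_p=float(p_slope),
        prop_r2=float(r2),
    )


def _battery(x: np.ndarray, y: np.ndarray, level: str, n: int,
             hrv_ecg=None, hrv_ppg=None, **extra) -> AgreementReport:
    return AgreementReport(
        level=level,
        agreement=icc_two_way_random_absolute(x, y),
        bland_altman=bland_altman(x, y),
        hrv_ecg=hrv_ecg,
        hrv_ppg=hrv_ppg,
        n=n,
        extra=extra,
    )


def compare_methods(pairing, level: str = "beat_by_beat",
                    metric: str = "mean_pi") -> AgreementReport:
    """Run the full agreement battery at one of two levels.

    ``beat_by_beat`` takes one subject's :class:`BeatPairing` and
    compares paired intervals directly. ``subject_means`` takes a
    sequence of pairings (one per subject) and compares the per-subject
    summaries — ``metric='mean_pi'`` for the mean pulse interval or
    ``'sdnn'`` for HRV. Difference direction is ECG minus PPG.
    """
    if level == "beat_by_beat":
        if not isinstance(pairing, BeatPairing):
            raise InvalidInputError("beat_by_beat level expects a single BeatPairing")
        x, y = pairing.ecg_intervals, pairing.ppg_intervals
        return _battery(x, y, level, n=len(pairing),
                        hrv_ecg=_summary_from_values(x),
                        hrv_ppg=_summary_from_values(y))
    if level == "subject_means":
        pairings = list(pairing)
        if len(pairings) < 3:
            raise InvalidInputError("subject_means level needs >= 3 subjects")
        attr = {"mean_pi": "mean_pi", "sdnn": "sdnn"}[metric]
        x = np.array([getattr(_summary_from_values(p.ecg_intervals), attr)
                      for p in pairings])
        y = np.array([getattr(_summary_from_values(p.ppg_intervals), attr)
                      for p in pairings])
        return _battery(x, y, level, n=len(pairings), metric=metric)
    raise InvalidInputError(f"unknown level {level!r}")
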