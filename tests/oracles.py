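"""Independent brute-force reference implementations used only by tests.

Every function here is written directly from the mathematical
definition, with no shared code with the package, so it can serve as an
oracle for the optimized implementations.
"""

from __future__ import annotations

import numpy as np


def brute_local_maxima(values: np.ndarray) -> list[int]:
    """Indices i with v[i-1] < v[i] >= v[i+1] (first sample of a plateau)."""
    out = []
    for i in range(1, len(values) - 1):
        if values[i - 1] < values[i] and values[i] >= values[i + 1]:
            out.append(i)
    return out


def brute_prominence(values: np.ndarray, peak: int) -> float:
    """Topographic prominence: height above the higher of the two lowest
    descents toward a strictly higher sample (or the signal edge)."""
    v = values
    left_min = v[peak]
    j = peak - 1
    while j >= 0 and v[j] <= v[peak]:
        left_min = min(left_min, v[j])
        j -= 1
    right_min = v[peak]
    j = peak + 1
    while j < len(v) and v[j] <= v[peak]:
        right_min = min(right_min, v[j])
        j += 1
    return v[peak] - max(left_min, right_min)


def brute_global_filter(prominences: np.ndarray, fraction: float) -> list[int]:
    threshold = fraction * np.mean(prominences)
    return [i for i, p in enumerate(prominences) if p > threshold]


def brute_window_filter(prominences: np.ndarray, fraction: float, win: int) -> list[int]:
    n = len(prominences)
    half = win // 2
    kept = []
    for i in range(n):
        lo = min(max(0, i - half), max(0, n - win))
        hi = min(n, lo + win)
        if prominences[i] >= fraction * np.mean(prominences[lo:hi]):
            kept.append(i)
    return kept


def brute_quantile(sorted_vals, q: float) -> float:
    """Linear interpolation between order statistics (exclusive of method tricks)."""
    x = sorted(sorted_vals)
    pos = q * (len(x) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return x[lo] + (pos - lo) * (x[hi] - x[lo])


def brute_quartile_reject(intervals, valid, window: int, m: float) -> set[int]:
    """Indices rejected by the windowed quartile-fence rule."""
    idx = [i for i in range(len(intervals)) if valid[i]]
    rejected = set()
    for start in range(0, len(idx), window):
        block = idx[start:start + window]
        vals = [intervals[i] for i in block]
        q1 = brute_quantile(vals, 0.25)
        q3 = brute_quantile(vals, 0.75)
        iqr = q3 - q1
        for i in block:
            if intervals[i] < q1 - m * iqr or intervals[i] > q3 + m * iqr:
                rejected.add(i)
    return rejected


def brute_successive_reject(intervals, valid, fraction: float) -> set[int]:
    rejected = set()
    ref = None
    for i in range(len(intervals)):
        if not valid[i]:
            continue
        if ref is None:
            ref = intervals[i]
        elif abs(intervals[i] - ref) / ref > fraction:
            rejected.add(i)
        else:
            ref = intervals[i]
    return rejected


def brute_rate_reject(intervals, valid, min_bpm: float, max_bpm: float) -> set[int]:
    rejected = set()
    for i in range(len(intervals)):
        if valid[i]:
            bpm = 60000.0 / intervals[i]
            if bpm < min_bpm or bpm > max_bpm:
                rejected.add(i)
    return rejected


def brute_pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = np.sum((x - mx) * (y - my))
    return cov / np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2))


def brute_icc_a1(x, y) -> float:
    """ICC(A,1) by explicit two-way ANOVA sums of squares, k=2 raters."""
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    grand = data.mean()
    ss_rows = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((data[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def brute_nearest_one_to_one(a, b, tol: float) -> dict[int, int]:
    """Globally greedy nearest-neighbour one-to-one assignment by distance."""
    cand = sorted(
        (abs(ta - tb), i, j)
        for i, ta in enumerate(a)
        for j, tb in enumerate(b)
        if abs(ta - tb) <= tol
    )
    used_a, used_b, match = set(), set(), {}
    for _, i, j in cand:
        if i not in used_a and j not in used_b:
            match[i] = j
            used_a.add(i)
            used_b.add(j)
    return match
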