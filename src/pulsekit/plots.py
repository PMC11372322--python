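"""Method-comparison figures: identity scatter and Bland-Altman plots.

Conventions: dashed line of identity, solid regression line, solid
mean-difference line with dashed limits of agreement.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from scipy import stats  # noqa: E402

from .agreement import bland_altman  # noqa: E402

__all__ = ["scatter_plot", "bland_altman_plot"]


def scatter_plot(x, y, path, xlabel="ECG interval (ms)",
                 ylabel="PPG interval (ms)") -> None:
    """Scatter of method B against method A with identity and regression lines."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(x, y, "o", ms=3, alpha=0.6)
    span = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax.plot(span, span, "k--", lw=1, label="identity")
    reg = stats.linregress(x, y)
    xs = np.linspace(*span, 50)
    ax.plot(xs, reg.intercept + reg.slope * xs, "r-", lw=1.2,
            label=f"fit (r={reg.rvalue:.2f})")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(x, y, path, units="ms") -> None:
    """Difference (A−B) against the pairwise mean with bias and LoA lines."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = bland_altman(x, y)
    d = x - y
    m = (x + y) / 2.0
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.plot(m, d, "o", ms=3, alpha=0.6)
    ax.axhline(res.mean_diff, color="k", lw=1.2)
    ax.axhline(res.loa_lower, color="k", lw=1, ls="--")
    ax.axhline(res.loa_upper, color="k", lw=1, ls="--")
    if np.std(m) > 0 and res.sd_diff > 0:
        xs = np.linspace(m.min(), m.max(), 50)
        reg = stats.linregress(m, d)
        ax.plot(xs, reg.intercept + reg.slope * xs, "r-", lw=1.2,
                label=f"b={res.prop_slope_b:.3f}, R²={res.prop_r2:.3f}")
        ax.legend(frameon=False)
    ax.set_xlabel(f"Mean of methods ({units})")
    ax.set_ylabel(f"Difference A−B ({units})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
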