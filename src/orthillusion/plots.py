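"""Optional figures mirroring the count-null histograms and CDF comparison."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .resampling import CdfComparison, CountNull

__all__ = ["plot_count_null", "plot_cdf_comparison"]


def plot_count_null(null: CountNull, title: str = "", marks: dict | None = None, ax=None):
    """Histogram of the bootstrap error-count null with mean and 5/95 percentiles.

    ``marks`` maps label -> count for extra vertical reference lines (e.g.
    the other condition's observed count).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    lo, hi = int(null.counts.min()), int(null.counts.max())
    bins = np.arange(lo - 0.5, hi + 1.5)
    ax.hist(null.counts, bins=bins, color="0.75", edgecolor="0.4", density=True)
    ax.axvline(null.mean_count, color="crimson", lw=2, label=f"mean = {null.mean_count:.1f}")
    for pct, val in (("5th", null.pct5), ("95th", null.pct95)):
        ax.axvline(val, color="purple", lw=1.2, ls="--", label=f"{pct} pct = {val:g}")
    for label, count in (marks or {}).items():
        ax.axvline(count, color="k", lw=1.2, ls=":", label=f"{label} = {count}")
    ax.set_xlabel("error count")
    ax.set_ylabel("probability")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8, frameon=False)
    return ax


def plot_cdf_comparison(cmp_res: CdfComparison, title: str = "", ax=None):
    """Error CDF against the control reference CDF with the 5-95% envelope."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.fill_between(
        cmp_res.grid, cmp_res.band5, cmp_res.band95, color="0.85",
        label="5th-95th pct of resamples",
    )
    ax.plot(cmp_res.grid, cmp_res.reference_cdf, color="goldenrod", lw=2, label="reference (controls)")
    # reconstruct the observed error CDF from the stored distance inputs is
    # not possible; callers overlay it themselves if needed
    ax.set_xlabel("centered offset (deg)")
    ax.set_ylabel("cumulative probability")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(f"{title} (p = {cmp_res.p_value:.3f}, n = {cmp_res.n_cases})")
    ax.legend(fontsize=8, frameon=False)
    return ax
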