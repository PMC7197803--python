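"""The three resampling procedures of the analysis.

* :func:`bootstrap_error_counts` -- resample the 240 adapted-probe trials of
  one condition with replacement (by trial or by participant), reclassify
  against the fixed control reference, and build the null distribution of
  error counts with its mean and 5th/95th percentiles.
* :func:`shuffle_orientation_test` -- permutation test for clustering of
  error trials at the adapted probe orientations: probe labels are shuffled
  within each condition-by-grating panel while each trial keeps its error
  flag, and the count of errors sitting at adapted labels is re-computed.
* :func:`cdf_distance_test` -- compares the empirical CDF of centered
  near-orthogonal error offsets with CDFs of same-size resamples of the
  centered control offsets via mean absolute vertical distance.

Empirical p-values are reported both as plain frequencies and with the
add-one convention (1 + #extreme) / (1 + n), which bounds p away from zero
(p >= 1/(1+n), the floor behind a "p < 1e-6 at 1e6 shuffles" statement).

All procedures are reproducible under a fixed seed and invariant to the row
order of their inputs (rows are sorted on a stable key before sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ControlReference, classify_errors
from .exceptions import InsufficientDataError

__all__ = [
    "CountNull",
    "bootstrap_error_counts",
    "ShuffleTestResult",
    "shuffle_orientation_test",
    "CdfComparison",
    "cdf_distance_test",
]

_SORT_KEY = ["participant", "condition", "probe_deg", "repeat"]


def _sorted_copy(trials: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in _SORT_KEY if c in trials.columns]
    return trials.sort_values(cols, kind="mergesort").reset_index(drop=True)


def add_one_p(n_extreme: int, n_iterations: int) -> float:
    return (1.0 + n_extreme) / (1.0 + n_iterations)


@dataclass
class CountNull:
    """Bootstrap null distribution of error counts."""

    counts: np.ndarray = field(repr=False)
    n_iterations: int
    observed_count: int
    unit: str
    mean_count: float = 0.0
    pct5: float = 0.0
    pct95: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.mean_count = float(np.mean(self.counts))
        self.pct5 = float(np.percentile(self.counts, 5))
        self.pct95 = float(np.percentile(self.counts, 95))

    def _tail(self, mask: np.ndarray, convention: str) -> float:
        k = int(mask.sum())
        if convention == "add_one":
            return add_one_p(k, self.n_iterations)
        if convention == "raw":
            return k / self.n_iterations
        raise ValueError(f"unknown convention {convention!r}")

    def p_exact(self, k: int, convention: str = "add_one") -> float:
        """Empirical probability of observing exactly ``k`` errors."""
        return self._tail(self.counts == k, convention)

    def p_le(self, k: int, convention: str = "add_one") -> float:
        """Empirical probability of ``k`` errors or fewer."""
        return self._tail(self.counts <= k, convention)

    def p_ge(self, k: int, convention: str = "add_one") -> float:
        """Empirical probability of ``k`` errors or more."""
        return self._tail(self.counts >= k, convention)

    @property
    def mc_se_of_mean(self) -> float:
        return float(np.std(self.counts, ddof=1) / np.sqrt(self.n_iterations))


def bootstrap_error_counts(
    adapted_trials: pd.DataFrame,
    reference: ControlReference,
    n_iterations: int = 100_000,
    unit: str = "trial",
    seed=None,
    chunk: int = 10_000,
) -> CountNull:
    """Bootstrap the error count of the adapted-probe trials of one condition.

    ``unit='trial'`` resamples individual trials with replacement (the count
    is then exactly Binomial(n, k/n) distributed); ``unit='participant'``
    resamples whole participants with all their adapted trials, which
    respects the clustering of errors within observers.  Classification
    uses the *fixed* reference fit on the original control data.
    """
    if len(adapted_trials) == 0:
        raise ValueError("adapted_trials must be non-empty")
    if unit not in ("trial", "participant"):
        raise ValueError(f"unknown resampling unit {unit!r}")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")

    trials = _sorted_copy(adapted_trials)
    labeled = classify_errors(trials, reference)
    err = labeled["is_error"].to_numpy()
    observed = int(err.sum())
    rng = np.random.default_rng(seed)

    counts = np.empty(n_iterations, dtype=np.int64)
    if unit == "trial":
        n = len(err)
        done = 0
        while done < n_iterations:
            m = min(chunk, n_iterations - done)
            idx = rng.integers(0, n, size=(m, n))
            counts[done : done + m] = err[idx].sum(axis=1)
            done += m
    else:
        per_participant = (
            labeled.groupby("participant", sort=True)["is_error"].sum().to_numpy()
        )
        n_p = len(per_participant)
        done = 0
        while done < n_iterations:
            m = min(chunk, n_iterations - done)
            idx = rng.integers(0, n_p, size=(m, n_p))
            counts[done : done + m] = per_participant[idx].sum(axis=1)
            done += m

    return CountNull(
        counts=counts,
        n_iterations=n_iterations,
        observed_count=observed,
        unit=unit,
    )


@dataclass
class ShuffleTestResult:
    observed_statistic: int
    n_shuffles: int
    n_extreme: int
    shuffled_mean: float
    panel_sizes: list

    @property
    def p_value(self) -> float:
        """Add-one convention; never exactly zero."""
        return add_one_p(self.n_extreme, self.n_shuffles)

    @property
    def p_value_raw(self) -> float:
        return self.n_extreme / self.n_shuffles


def shuffle_orientation_test(
    panels,
    n_shuffles: int = 100_000,
    seed=None,
    adapted_labels=(-45, 45),
    chunk: int = 5_000,
) -> ShuffleTestResult:
    """Permutation test for the concentration of errors at adapted orientations.

    ``panels`` is a sequence of labeled trial tables (one per condition x
    sustained-grating combination) carrying ``probe_deg`` and ``is_error``
    columns.  The observed statistic is the total number of error trials
    whose probe label lies on the adapted orientations, summed over panels.
    Each shuffle permutes the probe labels uniformly within every panel
    (responses, and hence each trial's error status, stay fixed) and
    recomputes the statistic.  p = (1 + #{shuffled >= observed}) / (1 + n).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    adapted = set(int(a) for a in adapted_labels)
    masks = []
    for panel in panels:
        panel = _sorted_copy(panel)
        err = panel["is_error"].to_numpy(dtype=bool)
        at_adapted = panel["probe_deg"].astype(int).isin(adapted).to_numpy()
        if len(err):
            masks.append((err, at_adapted))
    observed = int(sum((e & a).sum() for e, a in masks))

    rng = np.random.default_rng(seed)
    stats_arr = np.zeros(n_shuffles, dtype=np.int64)
    for err, at_adapted in masks:
        if not err.any() or at_adapted.all() or not at_adapted.any():
            # permuting labels cannot change this panel's contribution spread
            stats_arr += int((err & at_adapted).sum()) if at_adapted.all() else 0
            continue
        err_f = err.astype(np.float64)
        done = 0
        while done < n_shuffles:
            m = min(chunk, n_shuffles - done)
            tiled = np.tile(at_adapted.astype(np.float64), (m, 1))
            perm = rng.permuted(tiled, axis=1)
            stats_arr[done : done + m] += (perm @ err_f).astype(np.int64)
            done += m

    n_extreme = int((stats_arr >= observed).sum())
    return ShuffleTestResult(
        observed_statistic=observed,
        n_shuffles=n_shuffles,
        n_extreme=n_extreme,
        shuffled_mean=float(stats_arr.mean()),
        panel_sizes=[len(e) for e, _ in masks],
    )


@dataclass
class CdfComparison:
    """Result of the centered-CDF mean-absolute-distance comparison."""

    grid: np.ndarray = field(repr=False)
    reference_cdf: np.ndarray = field(repr=False)
    resample_distances: np.ndarray = field(repr=False)
    observed_distance: float = 0.0
    n_cases: int = 0
    n_resamples: int = 0
    band5: np.ndarray = field(default=None, repr=False)
    band95: np.ndarray = field(default=None, repr=False)

    @property
    def p_value(self) -> float:
        """Fraction of resamples at least as distant as the error CDF."""
        return float(np.mean(self.resample_distances >= self.observed_distance))

    @property
    def p_value_add_one(self) -> float:
        return add_one_p(
            int((self.resample_distances >= self.observed_distance).sum()),
            self.n_resamples,
        )


def _ecdf_on_grid(sorted_rows: np.ndarray, grid: np.ndarray, chunk: int = 2_000) -> np.ndarray:
    """Row-wise empirical CDF values on a fixed grid (rows pre-sorted)."""
    n_rows, n_cases = sorted_rows.shape
    out = np.empty((n_rows, grid.size))
    for start in range(0, n_rows, chunk):
        block = sorted_rows[start : start + chunk]
        out[start : start + chunk] = (
            (block[:, :, None] <= grid[None, None, :]).sum(axis=1) / n_cases
        )
    return out


def cdf_distance_test(
    error_offsets,
    control_offsets,
    n_resamples: int = 10_000,
    grid: np.ndarray | None = None,
    seed=None,
    recenter_per_resample: bool = True,
) -> CdfComparison:
    """Do near-orthogonal errors scatter like veridical judgments?

    ``error_offsets`` are the raw offsets of the near-orthogonal error
    cases; they are centered by (circularly) subtracting 90 degrees.
    ``control_offsets`` are all control-trial offsets, centered at 0 by
    subtracting their mean.  The reference CDF is the empirical CDF of all
    centered control offsets.  Each resample draws ``n_cases`` control
    offsets with replacement, re-centers them at 0 (default), and its mean
    absolute vertical distance to the reference CDF over a fixed grid
    (default 201 points spanning +/-4 control SD) forms the null
    distribution against which the error CDF's distance is compared.
    """
    from .orientation import canonicalize_orientation

    err = np.asarray(canonicalize_orientation(np.asarray(error_offsets, float) - 90.0))
    if err.size < 2:
        raise InsufficientDataError(
            f"need at least 2 near-orthogonal error cases, got {err.size}"
        )
    ctrl = np.asarray(control_offsets, dtype=float)
    if ctrl.size < 2:
        raise InsufficientDataError("need at least 2 control offsets")
    ctrl = ctrl - ctrl.mean()
    sd = float(np.std(ctrl, ddof=1))
    if grid is None:
        grid = np.linspace(-4.0 * sd, 4.0 * sd, 201)
    grid = np.asarray(grid, dtype=float)

    ctrl_sorted = np.sort(ctrl)
    reference_cdf = np.searchsorted(ctrl_sorted, grid, side="right") / ctrl.size

    n_cases = err.size
    rng = np.random.default_rng(seed)
    samples = rng.choice(ctrl, size=(n_resamples, n_cases), replace=True)
    if recenter_per_resample:
        samples = samples - samples.mean(axis=1, keepdims=True)
        err = err - err.mean()
    samples.sort(axis=1)
    cdfs = _ecdf_on_grid(samples, grid)
    distances = np.abs(cdfs - reference_cdf[None, :]).mean(axis=1)

    err_sorted = np.sort(err)
    err_cdf = np.searchsorted(err_sorted, grid, side="right") / n_cases
    observed = float(np.abs(err_cdf - reference_cdf).mean())

    band5, band95 = np.percentile(cdfs, [5, 95], axis=0)
    return CdfComparison(
        grid=grid,
        reference_cdf=reference_cdf,
        resample_distances=distances,
        observed_distance=observed,
        n_cases=n_cases,
        n_resamples=n_resamples,
        band5=band5,
        band95=band95,
    )
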