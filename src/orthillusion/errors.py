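"""Error classification against the control-condition offset distribution.

The study defines an illusory-percept "error" as a judgment whose offset
from the true probe orientation lies more than 4 SD from the mean of the
offset distribution of the control conditions.  This module fits that
control reference (pooled, or after per-orientation centering to remove the
oblique bias), classifies trials, and counts errors at the adapted probe
orientations of the test conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONTROL_CONDITIONS, TEST_CONDITIONS, Condition, StudyDesign
from .exceptions import DegenerateReferenceError
from .orientation import canonicalize_orientation, circular_offset

#: The study's outlier criterion: 4 standard deviations.
SD_MULTIPLIER = 4.0

__all__ = [
    "SD_MULTIPLIER",
    "ControlReference",
    "compute_offsets",
    "fit_control_reference",
    "classify_errors",
    "count_errors_at_adapted",
    "AdaptedErrorCount",
]


def compute_offsets(trials: pd.DataFrame) -> np.ndarray:
    """Signed circular offset of each response from its (physical) probe."""
    probe_physical = canonicalize_orientation(trials["probe_deg"].to_numpy(dtype=float))
    return circular_offset(trials["response_deg"].to_numpy(dtype=float), probe_physical)


@dataclass
class ControlReference:
    """Summary of the pooled control offset distribution.

    ``threshold`` is always ``multiplier * sd_offset``.  In
    ``per_orientation`` mode the per-probe-label mean offsets used for
    centering are retained so test trials can be centered identically.
    """

    mean_offset: float
    sd_offset: float
    n_control: int
    centering_mode: str = "pooled"
    multiplier: float = SD_MULTIPLIER
    label_means: dict | None = field(default=None, repr=False)

    @property
    def threshold(self) -> float:
        return self.multiplier * self.sd_offset

    def center(self, offsets: np.ndarray, probe_labels: np.ndarray) -> np.ndarray:
        """Apply the reference's centering to arbitrary trial offsets."""
        if self.centering_mode == "pooled" or not self.label_means:
            return np.asarray(offsets, dtype=float)
        shift = np.array(
            [self.label_means.get(int(l), 0.0) for l in np.asarray(probe_labels)]
        )
        return np.asarray(offsets, dtype=float) - shift


def fit_control_reference(
    trials: pd.DataFrame,
    centering_mode: str = "pooled",
    multiplier: float = SD_MULTIPLIER,
) -> ControlReference:
    """Fit mean/SD of control offsets; threshold = multiplier * SD.

    ``centering_mode='pooled'`` uses raw offsets of all control trials;
    ``'per_orientation'`` first subtracts each probe label's mean offset
    (removing the oblique bias component) before pooling, which can only
    shrink the SD.
    """
    if centering_mode not in ("pooled", "per_orientation"):
        raise ValueError(f"unknown centering_mode {centering_mode!r}")
    control_values = {c.value for c in CONTROL_CONDITIONS}
    controls = trials[trials["condition"].isin(control_values)]
    if len(controls) < 2:
        raise ValueError("need at least 2 control trials to fit a reference")

    offsets = compute_offsets(controls)
    label_means = None
    if centering_mode == "per_orientation":
        labels = controls["probe_deg"].to_numpy()
        means = pd.Series(offsets).groupby(labels).mean()
        label_means = {int(k): float(v) for k, v in means.items()}
        offsets = offsets - means.loc[labels].to_numpy()

    sd = float(np.std(offsets, ddof=1))
    if sd == 0.0:
        raise DegenerateReferenceError(
            "control offsets are constant; the SD criterion is undefined"
        )
    return ControlReference(
        mean_offset=float(np.mean(offsets)),
        sd_offset=sd,
        n_control=len(controls),
        centering_mode=centering_mode,
        multiplier=multiplier,
        label_means=label_means,
    )


def classify_errors(trials: pd.DataFrame, reference: ControlReference) -> pd.DataFrame:
    """Label every trial with its offset and the error flags.

    ``is_error``: circular distance of the (centered) offset from the
    reference mean exceeds the threshold.  ``is_near_orthogonal``: circular
    distance of the raw offset from 90 degrees is within the threshold --
    the selection used for the error-CDF comparison.  Deterministic, and
    invariant under adding 180 degrees to any response.
    """
    labeled = trials.copy()
    offsets = compute_offsets(trials)
    centered = reference.center(offsets, trials["probe_deg"].to_numpy())
    deviation = np.abs(canonicalize_orientation(centered - reference.mean_offset))
    labeled["offset_deg"] = offsets
    labeled["is_error"] = deviation > reference.threshold
    labeled["is_near_orthogonal"] = (
        np.abs(canonicalize_orientation(offsets - 90.0)) <= reference.threshold
    )
    return labeled


@dataclass(frozen=True)
class AdaptedErrorCount:
    condition: str
    count: int
    n_trials: int

    @property
    def fraction(self) -> float:
        return self.count / self.n_trials

    @property
    def percent(self) -> float:
        """Fraction as a percentage rounded to one decimal (presentation)."""
        return round(100.0 * self.fraction, 1)


def count_errors_at_adapted(
    labeled: pd.DataFrame,
    condition,
    design: StudyDesign | None = None,
) -> AdaptedErrorCount:
    """Count error trials at the adapted (+/-45) probe labels of one test condition.

    The denominator is the design's adapted-trial capacity
    (participants x repeats x 2 orientations = 240), not the observed row
    count, so fractions match the study's reporting even on subsets.
    """
    design = design or StudyDesign()
    cond = Condition(condition)
    if cond not in TEST_CONDITIONS:
        raise ValueError(f"{cond.value} is not a test condition")
    sub = labeled[
        (labeled["condition"] == cond.value)
        & labeled["probe_deg"].isin(set(design.adapted_labels))
    ]
    return AdaptedErrorCount(
        condition=cond.value,
        count=int(sub["is_error"].sum()),
        n_trials=design.n_adapted_trials_per_test_condition,
    )
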