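"""Study-design constants for the orientation-adjustment experiment.

The experiment has five conditions: a probe-only control, two controls in
which a superposition of two orthogonal oblique gratings (-45 and +45
degrees) is shown for 33 or 200 ms, and two test conditions in which the
superposition is followed by a single grating at one of the two oblique
orientations before the probe appears.  Thirteen probe orientations
(-90 to +90 in 15-degree steps; the two endpoints label the same physical
orientation) are each judged 8 times per condition, i.e. 104 adjustment
judgments per condition per participant, by 15 participants.

Everything downstream (expected trial counts, the 240 adapted-probe trials
per test condition, the 4680 control trials) is derived from
:class:`StudyDesign`, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Condition(str, Enum):
    CONTROL_PROBE_ONLY = "control_probe_only"
    CONTROL_SUPER_33 = "control_super_33"
    CONTROL_SUPER_200 = "control_super_200"
    TEST_33 = "test_33"
    TEST_200 = "test_200"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CONTROL_CONDITIONS = (
    Condition.CONTROL_PROBE_ONLY,
    Condition.CONTROL_SUPER_33,
    Condition.CONTROL_SUPER_200,
)
TEST_CONDITIONS = (Condition.TEST_33, Condition.TEST_200)

#: Superposition duration in ms implied by each condition (0 = no superposition).
CONDITION_DURATION_MS = {
    Condition.CONTROL_PROBE_ONLY: 0,
    Condition.CONTROL_SUPER_33: 33,
    Condition.CONTROL_SUPER_200: 200,
    Condition.TEST_33: 33,
    Condition.TEST_200: 200,
}


@dataclass(frozen=True)
class StudyDesign:
    """Factorial layout of the adjustment experiment."""

    n_participants: int = 15
    probe_labels: tuple = tuple(range(-90, 91, 15))
    n_repeats: int = 8
    #: Probe labels parallel to the gratings of the superposition; in test
    #: conditions one of these remains on screen ("adapted" orientations).
    adapted_labels: tuple = (-45, 45)
    conditions: tuple = field(default=tuple(Condition))

    def __post_init__(self) -> None:
        if not set(self.adapted_labels) <= set(self.probe_labels):
            raise ValueError("adapted_labels must be a subset of probe_labels")

    # -- derived counts -------------------------------------------------
    @property
    def trials_per_condition_per_participant(self) -> int:
        """13 probe labels x 8 repeats = 104 judgments."""
        return len(self.probe_labels) * self.n_repeats

    @property
    def control_conditions(self) -> tuple:
        return tuple(c for c in self.conditions if c in CONTROL_CONDITIONS)

    @property
    def test_conditions(self) -> tuple:
        return tuple(c for c in self.conditions if c in TEST_CONDITIONS)

    @property
    def n_adapted_trials_per_test_condition(self) -> int:
        """Trials at the two adapted probe labels in one test condition (240)."""
        return self.n_participants * self.n_repeats * len(self.adapted_labels)

    @property
    def n_control_cases_at_adapted(self) -> int:
        """Control trials at the adapted probe labels across all controls (720)."""
        return (
            self.n_participants
            * self.n_repeats
            * len(self.adapted_labels)
            * len(self.control_conditions)
        )

    @property
    def n_control_trials(self) -> int:
        """All trials of all control conditions (4680)."""
        return (
            self.n_participants
            * self.trials_per_condition_per_participant
            * len(self.control_conditions)
        )

    @property
    def n_trials_total(self) -> int:
        """Full cohort size (7800)."""
        return (
            self.n_participants
            * self.trials_per_condition_per_participant
            * len(self.conditions)
        )

    def participant_ids(self) -> list:
        return [f"P{i + 1:02d}" for i in range(self.n_participants)]
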