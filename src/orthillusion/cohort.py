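"""Phenomenological synthetic-cohort generator.

Emulates the statistical structure of the adjustment-task data: Gaussian
response scatter around the true probe orientation, a smooth oblique bias
pushing judgments away from the cardinal axes, participant-level bias
heterogeneity, and a rare mixture component of responses orthogonal to the
probe that occurs almost exclusively at the adapted (+/-45 degree) probe
orientations of the test conditions, more often after a 200 ms than a 33 ms
superposition, and only in a susceptible subset of participants.

Two entry points:

``generate_cohort``
    Bernoulli-mixture cohort with configurable rates; the defaults are the
    rates observed in the study (8.3% / 3.3% of adapted-probe trials,
    7 of 15 susceptible participants, ~2 orthogonal responses per 4680
    control trials).

``reconstruct_reported_counts``
    A cohort built to contain an *exact* number of orthogonal error trials
    per test condition, used to reproduce summary statistics that depend
    only on the reported counts (e.g. bootstrap error-count means).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    CONDITION_DURATION_MS,
    TEST_CONDITIONS,
    Condition,
    StudyDesign,
)
from .exceptions import ConfigurationError
from .orientation import canonicalize_orientation

__all__ = ["GeneratorParams", "bias_function", "generate_cohort", "reconstruct_reported_counts"]


@dataclass
class GeneratorParams:
    """Parameters of the phenomenological generator.

    All angles in degrees, rates are per-trial probabilities.  The illusion
    rates are *marginal* rates over all adapted-probe trials of a test
    condition; internally the per-trial probability among susceptible
    participants is ``rate / susceptible_fraction`` so that the marginal
    matches the parameter.
    """

    response_noise_sd: float = 5.0
    bias_amplitude: float = 6.8
    bias_heterogeneity_sd: float = 6.2
    illusion_rate_200: float = 0.083
    illusion_rate_33: float = 0.033
    control_illusion_rate: float = 2.0 / 4680.0
    susceptible_fraction: float = 7.0 / 15.0
    orthogonal_jitter_sd: float | None = None  # None -> response_noise_sd
    seed: int | None = None
    # Optional truncation (in SD units) of the Gaussian components; used by
    # reconstruction cohorts to bound veridical offsets away from the 4-SD
    # error threshold.  None means untruncated.
    noise_truncation_sd: float | None = None
    heterogeneity_truncation_sd: float | None = None
    jitter_truncation_sd: float | None = None

    def validate(self) -> None:
        rates = {
            "illusion_rate_200": self.illusion_rate_200,
            "illusion_rate_33": self.illusion_rate_33,
            "control_illusion_rate": self.control_illusion_rate,
            "susceptible_fraction": self.susceptible_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name in ("response_noise_sd", "bias_heterogeneity_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.bias_amplitude < 0:
            raise ConfigurationError("bias_amplitude must be >= 0")
        if self.orthogonal_jitter_sd is not None and self.orthogonal_jitter_sd <= 0:
            raise ConfigurationError("orthogonal_jitter_sd must be > 0")

    @property
    def jitter_sd(self) -> float:
        return (
            self.response_noise_sd
            if self.orthogonal_jitter_sd is None
            else self.orthogonal_jitter_sd
        )

    def to_dict(self) -> dict:
        return asdict(self)


def bias_function(probe_deg, amplitude: float):
    """Oblique bias: judgments repelled from the cardinal axes.

    ``amplitude * sin(4 * theta)`` -- zero at 0, +/-45 and +/-90 degrees,
    positive just above 0 (pushes up, away from horizontal), negative just
    below 90 (pushes down, away from vertical), bounded by ``amplitude``.
    """
    if amplitude < 0:
        raise ConfigurationError("amplitude must be >= 0")
    theta = np.deg2rad(np.asarray(probe_deg, dtype=float))
    out = amplitude * np.sin(4.0 * theta)
    if np.ndim(probe_deg) == 0:
        return float(out)
    return out


def _draw_centered(rng, size, sd, truncation_sd):
    """Gaussian or symmetric truncated-Gaussian draws with mean 0."""
    if sd == 0:
        return np.zeros(size)
    if truncation_sd is None:
        return rng.normal(0.0, sd, size=size)
    return stats.truncnorm.rvs(
        -truncation_sd, truncation_sd, loc=0.0, scale=sd, size=size, random_state=rng
    )


_ILLUSION_RATE_BY_CONDITION = {
    Condition.TEST_200: "illusion_rate_200",
    Condition.TEST_33: "illusion_rate_33",
}


def generate_cohort(
    design: StudyDesign | None = None,
    params: GeneratorParams | None = None,
    seed: int | None = None,
    return_info: bool = False,
):
    """Simulate a full cohort (participants x conditions x probes x repeats).

    Each trial draws either a veridical response (probe + oblique bias +
    participant bias + Gaussian noise) or, with a small probability, an
    orthogonal "illusory" response (probe + 90 + jitter).  The orthogonal
    branch is available at the marginal illusion rate of the trial's
    condition when the probe sits at an adapted orientation of a test
    condition and the participant belongs to the susceptible subset, and at
    ``control_illusion_rate`` everywhere else.  Same seed, same cohort.

    Returns the canonical trial table; with ``return_info=True`` also a dict
    with the susceptible participant ids and per-participant bias offsets.
    """
    design = design or StudyDesign()
    params = params or GeneratorParams()
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    n_p = design.n_participants
    labels = np.asarray(design.probe_labels, dtype=float)
    n_l = len(labels)
    n_r = design.n_repeats
    conditions = list(design.conditions)
    per_cond = n_p * n_l * n_r
    n = per_cond * len(conditions)

    # participant-level structure
    n_susceptible = int(round(params.susceptible_fraction * n_p))
    susceptible_idx = rng.choice(n_p, size=n_susceptible, replace=False)
    susceptible = np.zeros(n_p, dtype=bool)
    susceptible[susceptible_idx] = True
    participant_bias = _draw_centered(
        rng, n_p, params.bias_heterogeneity_sd, params.heterogeneity_truncation_sd
    )

    cond_idx = np.repeat(np.arange(len(conditions)), per_cond)
    pid = np.tile(np.repeat(np.arange(n_p), n_l * n_r), len(conditions))
    probe = np.tile(np.repeat(labels, n_r), n_p * len(conditions))
    rep = np.tile(np.arange(1, n_r + 1), n_p * n_l * len(conditions))

    is_test = np.isin(
        cond_idx, [conditions.index(c) for c in TEST_CONDITIONS if c in conditions]
    )
    at_adapted = np.isin(probe, np.asarray(design.adapted_labels, dtype=float))

    # marginal -> within-susceptible per-trial probability
    realized_fraction = n_susceptible / n_p
    p_trial = np.full(n, params.control_illusion_rate)
    for cond, attr in _ILLUSION_RATE_BY_CONDITION.items():
        if cond not in conditions:
            continue
        rate = getattr(params, attr)
        if rate > 0 and realized_fraction == 0:
            raise ConfigurationError(
                "illusion rates > 0 require a non-empty susceptible subset"
            )
        within = 0.0 if rate == 0 else rate / realized_fraction
        if within > 1.0:
            raise ConfigurationError(
                f"{attr}={rate} not reachable with susceptible_fraction="
                f"{realized_fraction:.3f} (per-trial probability {within:.3f} > 1)"
            )
        eligible = (
            (cond_idx == conditions.index(cond)) & at_adapted & susceptible[pid]
        )
        p_trial[eligible] = within

    illusory = rng.random(n) < p_trial

    # single grating only exists in test conditions; random +/-45 per trial
    single = np.full(n, np.nan)
    single[is_test] = rng.choice(
        np.asarray(design.adapted_labels, dtype=float), size=int(is_test.sum())
    )
    # illusions occur in the context of a sustained grating parallel to the probe
    match = illusory & is_test & at_adapted
    single[match] = probe[match]

    noise = _draw_centered(rng, n, params.response_noise_sd, params.noise_truncation_sd)
    jitter = _draw_centered(rng, n, params.jitter_sd, params.jitter_truncation_sd)
    veridical = probe + bias_function(probe, params.bias_amplitude) + participant_bias[pid] + noise
    orthogonal = probe + 90.0 + jitter
    response = canonicalize_orientation(np.where(illusory, orthogonal, veridical))

    participant_ids = np.asarray(design.participant_ids())
    trials = pd.DataFrame(
        {
            "participant": participant_ids[pid],
            "condition": np.asarray([c.value for c in conditions])[cond_idx],
            "superposition_duration_ms": np.asarray(
                [CONDITION_DURATION_MS[c] for c in conditions]
            )[cond_idx],
            "single_grating_deg": single,
            "probe_deg": probe.astype(int),
            "response_deg": response,
            "repeat": rep,
        }
    )
    if not return_info:
        return trials
    info = {
        "susceptible_participants": sorted(participant_ids[susceptible_idx].tolist()),
        "participant_bias": dict(zip(participant_ids.tolist(), participant_bias.tolist())),
        "illusory_mask": illusory,
        "seed": seed,
    }
    return trials, info


def reconstruct_reported_counts(
    design: StudyDesign | None = None,
    counts_per_condition: dict | None = None,
    seed: int | None = None,
    params: GeneratorParams | None = None,
) -> pd.DataFrame:
    """Cohort containing an exact number of orthogonal errors per test condition.

    ``counts_per_condition`` maps a test condition (``Condition`` or its
    string value) to the integer number of error trials to plant at the
    adapted probe orientations of that condition.  The veridical background
    uses truncated noise components so that, by construction, the 4-SD
    classifier fit on the cohort's own control trials finds exactly the
    requested counts; planted trials carry a sustained grating parallel to
    the probe and are concentrated in the susceptible participants.
    """
    design = design or StudyDesign()
    if counts_per_condition is None:
        raise ConfigurationError("counts_per_condition is required")
    counts: dict[Condition, int] = {}
    for key, value in counts_per_condition.items():
        cond = Condition(key)
        if cond not in TEST_CONDITIONS:
            raise ConfigurationError(f"{cond.value} is not a test condition")
        k = int(value)
        cap = design.n_adapted_trials_per_test_condition
        if not 0 <= k <= cap:
            raise ValueError(
                f"requested {k} errors for {cond.value}, capacity is {cap}"
            )
        counts[cond] = k

    base = params or GeneratorParams()
    base = replace(
        base,
        illusion_rate_200=0.0,
        illusion_rate_33=0.0,
        control_illusion_rate=0.0,
        noise_truncation_sd=3.0,
        heterogeneity_truncation_sd=2.0,
        jitter_truncation_sd=3.0,
    )
    base.validate()
    if isinstance(seed, np.random.Generator):
        gen_rng, rng = seed.spawn(2)
    else:
        gen_seed, plant_seed = np.random.SeedSequence(seed).spawn(2)
        gen_rng, rng = np.random.default_rng(gen_seed), np.random.default_rng(plant_seed)
    trials, info = generate_cohort(design, base, seed=gen_rng, return_info=True)

    susceptible = set(info["susceptible_participants"])
    adapted = set(design.adapted_labels)
    for cond, k in counts.items():
        if k == 0:
            continue
        pool = trials.index[
            (trials["condition"] == cond.value)
            & trials["probe_deg"].isin(adapted)
            & trials["participant"].isin(susceptible)
        ].to_numpy()
        if len(pool) < k:  # fall back to all adapted trials of the condition
            pool = trials.index[
                (trials["condition"] == cond.value)
                & trials["probe_deg"].isin(adapted)
            ].to_numpy()
        chosen = rng.choice(pool, size=k, replace=False)
        probe = trials.loc[chosen, "probe_deg"].to_numpy(dtype=float)
        jitter = _draw_centered(rng, k, base.jitter_sd, base.jitter_truncation_sd)
        trials.loc[chosen, "response_deg"] = canonicalize_orientation(
            probe + 90.0 + jitter
        )
        trials.loc[chosen, "single_grating_deg"] = probe

    _repair_spurious_errors(trials, design, base, counts, info)
    return trials


def _repair_spurious_errors(trials, design, params, counts, info) -> None:
    """Zero out the noise of veridical adapted-probe trials that would be
    classified as errors, so planted counts are exact.

    With truncated components the veridical offsets sit below the fitted
    4-SD threshold with overwhelming margin; this pass deterministically
    removes the (expected << 1) residual exceedances without touching the
    control trials that define the reference.
    """
    from .errors import classify_errors, fit_control_reference  # local: avoid cycle

    reference = fit_control_reference(trials, centering_mode="pooled")
    labeled = classify_errors(trials, reference)
    adapted = set(design.adapted_labels)
    for cond in counts:
        sub = labeled[
            (labeled["condition"] == cond.value)
            & labeled["probe_deg"].isin(adapted)
            & labeled["is_error"]
        ]
        n_excess = len(sub) - counts[cond]
        if n_excess <= 0:
            continue
        # spurious = error trials that are not near-orthogonal (planted ones are)
        spurious = sub.index[~sub["is_near_orthogonal"]][:n_excess]
        probe = trials.loc[spurious, "probe_deg"].to_numpy(dtype=float)
        pbias = trials.loc[spurious, "participant"].map(info["participant_bias"])
        trials.loc[spurious, "response_deg"] = canonicalize_orientation(
            probe + bias_function(probe, params.bias_amplitude) + pbias.to_numpy()
        )
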