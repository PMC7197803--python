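"""Toy predictive-coding decision model for the orthogonal illusion.

A deliberately minimal, phenomenological competition model -- not a
biophysical simulation.  After the switch from a superposition of two
orthogonal gratings to a single sustained grating of duration ``d`` ms:

* the representation signal of the sustained orientation has adapted:
  ``R(d) = exp(-d / adaptation_timescale)``;
* removal of the other orientation evokes an orientation-tuned "off"
  response that builds up with duration and is partially explained away by
  top-down feedback: ``E(d) = feedback_attenuation * (1 - exp(-d /
  off_buildup_timescale))`` (``feedback_attenuation`` is the fraction of
  the error signal that survives feedback; 0 means fully explained away).
  Alternatively the error signal can be read out as the amplitude
  difference between off response and adapted representation
  (``error_signal='difference'``).

Independent Gaussian noise is added to both amplitudes and the larger one,
if it clears ``decision_threshold``, determines the percept: an error-unit
win reports the removed (orthogonal) orientation, otherwise the sustained
orientation is reported (also when neither signal clears the threshold).

The default parameters were calibrated by Monte-Carlo so that the illusion
rate is ~3.3% at 33 ms and ~8.3% at 200 ms, the rates observed in the
adjustment experiment; only the qualitative increase with duration is a
structural property of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .orientation import canonicalize_orientation

__all__ = ["DecisionModelParams", "signal_amplitudes", "simulate_trial", "rate_sweep"]


@dataclass
class DecisionModelParams:
    """Parameters of the competition model (amplitudes normalized to 1)."""

    tuning_width: float = 30.0  # deg; width of the orientation-tuned peaks
    adaptation_timescale: float = 800.0  # ms
    off_buildup_timescale: float = 300.0  # ms
    feedback_attenuation: float = 0.159  # surviving error fraction in [0, 1]
    decision_noise_sd: float = 0.367  # amplitude units
    decision_threshold: float = 0.10  # amplitude units
    response_scatter_sd: float = 5.0  # deg; motor/readout scatter of the report
    error_signal: str = "off_response"  # or "difference"
    seed: int | None = None

    def validate(self) -> None:
        if self.adaptation_timescale <= 0 or self.off_buildup_timescale <= 0:
            raise ConfigurationError("timescales must be > 0")
        if not 0.0 <= self.feedback_attenuation <= 1.0:
            raise ConfigurationError("feedback_attenuation must be in [0, 1]")
        if self.decision_noise_sd < 0 or self.response_scatter_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if self.tuning_width <= 0:
            raise ConfigurationError("tuning_width must be > 0")
        if self.error_signal not in ("off_response", "difference"):
            raise ConfigurationError(f"unknown error_signal {self.error_signal!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def signal_amplitudes(duration_ms, params: DecisionModelParams):
    """Deterministic amplitudes (R, E) entering the competition."""
    d = np.asarray(duration_ms, dtype=float)
    if np.any(d < 0):
        raise ConfigurationError("duration_ms must be >= 0")
    r = np.exp(-d / params.adaptation_timescale)
    off = 1.0 - np.exp(-d / params.off_buildup_timescale)
    if params.error_signal == "difference":
        off = np.maximum(off - r, 0.0)
    e = params.feedback_attenuation * off
    return r, e


def _compete(r, e, noise_r, noise_e, params: DecisionModelParams):
    """Vectorized one-shot noisy max with threshold; True = illusory report.

    A fully explained-away error signal (amplitude exactly 0) carries no
    activity and cannot win on decision noise alone.
    """
    rn = r + noise_r
    en = e + noise_e
    return (e > 0) & (en > rn) & (en > params.decision_threshold)


def simulate_trial(
    duration_ms: float,
    params: DecisionModelParams | None = None,
    seed=None,
    sustained_deg: float = 45.0,
):
    """Simulate one perceptual decision; returns (reported_deg, diagnostics).

    The report is the sustained orientation, or the removed (orthogonal)
    orientation on an error-unit win, plus Gaussian readout scatter
    (doubled when neither signal clears the threshold, modeling a guess
    anchored on the sustained orientation).
    """
    params = params or DecisionModelParams()
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    r, e = signal_amplitudes(duration_ms, params)
    noise_r, noise_e = rng.normal(0.0, params.decision_noise_sd, size=2)
    rn, en = r + noise_r, e + noise_e
    winner_amp = max(rn, en)
    illusory = bool(e > 0 and en > rn and en > params.decision_threshold)
    subthreshold = bool(winner_amp <= params.decision_threshold)
    scatter_sd = params.response_scatter_sd * (2.0 if subthreshold else 1.0)
    base = sustained_deg + (90.0 if illusory else 0.0)
    reported = canonicalize_orientation(base + rng.normal(0.0, scatter_sd))
    diagnostics = {
        "representation_amplitude": float(r),
        "error_amplitude": float(e),
        "noisy_representation": float(rn),
        "noisy_error": float(en),
        "winner": "error" if illusory else "representation",
        "subthreshold": subthreshold,
    }
    return reported, diagnostics


def rate_sweep(
    durations,
    params: DecisionModelParams | None = None,
    n_trials: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Monte-Carlo illusion-rate estimate per superposition duration.

    Returns a DataFrame with columns duration_ms, illusion_rate, se
    (binomial standard error), n_trials.  The same noise draws are used at
    every duration (common random numbers), so monotonicity in duration
    holds pathwise under the default monotone amplitude curves.
    """
    params = params or DecisionModelParams()
    params.validate()
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    durations = list(durations)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    noise_r = rng.normal(0.0, params.decision_noise_sd, size=n_trials)
    noise_e = rng.normal(0.0, params.decision_noise_sd, size=n_trials)

    rows = []
    for d in durations:
        r, e = signal_amplitudes(d, params)
        illusory = _compete(r, e, noise_r, noise_e, params)
        p = float(illusory.mean())
        rows.append(
            {
                "duration_ms": float(d),
                "illusion_rate": p,
                "se": float(np.sqrt(p * (1.0 - p) / n_trials)),
                "n_trials": n_trials,
            }
        )
    return pd.DataFrame(rows, columns=["duration_ms", "illusion_rate", "se", "n_trials"])
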