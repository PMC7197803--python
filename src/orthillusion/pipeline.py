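"""End-to-end analysis: trial table in, structured JSON report out.

Chains the full procedure: design validation, control-reference fit
(pooled and per-orientation side by side), 4-SD error classification,
error counts at the adapted probe orientations, bootstrap error-count
nulls, the orientation-shuffle permutation test, and the centered-CDF
distance test.  Stages that cannot run on the given data (degenerate
reference, too few near-orthogonal cases) are recorded as skipped, not
fatal.  Every report embeds its configuration, seed and package version;
timestamps live in a separate field so re-runs are comparable.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .design import CONTROL_CONDITIONS, StudyDesign
from .errors import (
    SD_MULTIPLIER,
    classify_errors,
    count_errors_at_adapted,
    fit_control_reference,
)
from .exceptions import ConfigurationError, DegenerateReferenceError, InsufficientDataError
from .resampling import bootstrap_error_counts, cdf_distance_test, shuffle_orientation_test

__all__ = ["AnalysisConfig", "analyze", "validate_report", "report_schema"]


@dataclass
class AnalysisConfig:
    """Knobs of the end-to-end run."""

    centering_mode: str = "pooled"
    sd_multiplier: float = SD_MULTIPLIER
    n_bootstrap: int = 100_000
    n_shuffles: int = 100_000
    n_cdf_resamples: int = 10_000
    unit: str = "trial"  # bootstrap resampling unit: trial | participant
    adapted_labels: tuple = (-45, 45)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_bootstrap", "n_shuffles", "n_cdf_resamples"):
            if getattr(self, name) < 100:
                raise ConfigurationError(f"{name} must be >= 100 for reported p-values")
        if self.centering_mode not in ("pooled", "per_orientation"):
            raise ConfigurationError(f"unknown centering_mode {self.centering_mode!r}")
        if self.unit not in ("trial", "participant"):
            raise ConfigurationError(f"unknown unit {self.unit!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["adapted_labels"] = list(self.adapted_labels)
        return d


def _reference_summary(ref) -> dict:
    return {
        "mean_offset_deg": ref.mean_offset,
        "sd_offset_deg": ref.sd_offset,
        "threshold_deg": ref.threshold,
        "multiplier": ref.multiplier,
        "n_control": ref.n_control,
        "centering_mode": ref.centering_mode,
    }


def _count_null_summary(null, eval_counts) -> dict:
    out = {
        "unit": null.unit,
        "n_iterations": null.n_iterations,
        "observed_count": null.observed_count,
        "mean_count": null.mean_count,
        "pct5": null.pct5,
        "pct95": null.pct95,
        "p_at": {},
    }
    for k in sorted(set(int(c) for c in eval_counts)):
        out["p_at"][str(k)] = {
            "exact": {"add_one": null.p_exact(k), "raw": null.p_exact(k, "raw")},
            "le": {"add_one": null.p_le(k), "raw": null.p_le(k, "raw")},
            "ge": {"add_one": null.p_ge(k), "raw": null.p_ge(k, "raw")},
        }
    return out


def analyze(
    trials: pd.DataFrame,
    config: AnalysisConfig | None = None,
    design: StudyDesign | None = None,
) -> dict:
    """Run the whole analysis on a canonical trial table; returns the report."""
    from . import __version__
    from .io import validate_design

    config = config or AnalysisConfig()
    config.validate()
    design = design or StudyDesign()
    t0 = time.perf_counter()
    seq = np.random.SeedSequence(config.seed)
    seeds = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["bootstrap_200", "bootstrap_33", "bootstrap_control", "shuffle", "cdf_200", "cdf_33"],
            seq.spawn(6),
        )
    }

    report: dict = {
        "provenance": {
            "package_version": __version__,
            "config": config.to_dict(),
            "seed": config.seed,
            "n_trials": int(len(trials)),
        },
        "timestamps": {"started_unix": time.time()},
        "skipped_stages": [],
    }

    design_report = validate_design(trials, design)
    report["design_check"] = {
        "expected_per_cell": design_report.expected,
        "n_flagged_cells": len(design_report.flags),
        "flags": [list(f) for f in design_report.flags[:50]],
    }

    # --- control reference (both centering modes reported side by side) ----
    references = {}
    for mode in ("pooled", "per_orientation"):
        try:
            references[mode] = fit_control_reference(
                trials, centering_mode=mode, multiplier=config.sd_multiplier
            )
        except (ValueError, DegenerateReferenceError) as exc:
            report["skipped_stages"].append({"stage": f"reference_{mode}", "reason": str(exc)})
    report["control_reference"] = {
        mode: _reference_summary(ref) for mode, ref in references.items()
    }
    if config.centering_mode not in references:
        report["timestamps"]["finished_unix"] = time.time()
        report["elapsed_s"] = time.perf_counter() - t0
        return report
    reference = references[config.centering_mode]

    labeled = classify_errors(trials, reference)

    # --- error counts at adapted orientations ------------------------------
    observed_counts = {}
    report["error_counts"] = {}
    for cond in design.test_conditions:
        res = count_errors_at_adapted(labeled, cond, design)
        observed_counts[cond.value] = res.count
        report["error_counts"][cond.value] = {
            "count": res.count,
            "n_trials": res.n_trials,
            "fraction": res.fraction,
            "percent": res.percent,
        }
    adapted_set = set(design.adapted_labels)
    control_values = {c.value for c in CONTROL_CONDITIONS}
    control_adapted = labeled[
        labeled["condition"].isin(control_values) & labeled["probe_deg"].isin(adapted_set)
    ]
    report["error_counts"]["controls_at_adapted"] = {
        "count": int(control_adapted["is_error"].sum()),
        "n_trials": design.n_control_cases_at_adapted,
        "total_control_errors": int(
            labeled.loc[labeled["condition"].isin(control_values), "is_error"].sum()
        ),
        "n_control_trials": design.n_control_trials,
    }

    # --- bootstrap error-count nulls ---------------------------------------
    eval_counts = sorted(set(observed_counts.values()) | {1})
    report["bootstrap"] = {}
    for cond, rng_name in (("test_200", "bootstrap_200"), ("test_33", "bootstrap_33")):
        if cond not in observed_counts:
            continue
        sub = trials[
            (trials["condition"] == cond) & trials["probe_deg"].isin(adapted_set)
        ]
        null = bootstrap_error_counts(
            sub,
            reference,
            n_iterations=config.n_bootstrap,
            unit=config.unit,
            seed=seeds[rng_name],
        )
        report["bootstrap"][cond] = _count_null_summary(null, eval_counts)
    if len(control_adapted):
        null = bootstrap_error_counts(
            control_adapted,
            reference,
            n_iterations=config.n_bootstrap,
            unit=config.unit,
            seed=seeds["bootstrap_control"],
        )
        report["bootstrap"]["controls_at_adapted"] = _count_null_summary(null, eval_counts)

    # --- orientation-shuffle permutation test ------------------------------
    panels = [
        panel
        for (_, _), panel in labeled[
            labeled["condition"].isin({c.value for c in design.test_conditions})
            & labeled["single_grating_deg"].notna()
        ].groupby(["condition", "single_grating_deg"], sort=True)
    ]
    if panels:
        shuffle = shuffle_orientation_test(
            panels,
            n_shuffles=config.n_shuffles,
            seed=seeds["shuffle"],
            adapted_labels=config.adapted_labels,
        )
        report["shuffle_test"] = {
            "observed_statistic": shuffle.observed_statistic,
            "n_shuffles": shuffle.n_shuffles,
            "shuffled_mean": shuffle.shuffled_mean,
            "p_value": {"add_one": shuffle.p_value, "raw": shuffle.p_value_raw},
            "n_panels": len(shuffle.panel_sizes),
        }
    else:
        report["skipped_stages"].append(
            {"stage": "shuffle_test", "reason": "no test trials with a single grating"}
        )

    # --- centered-CDF distance test ----------------------------------------
    control_offsets = labeled.loc[labeled["condition"].isin(control_values), "offset_deg"]
    report["cdf_test"] = {}
    for cond, rng_name in (("test_200", "cdf_200"), ("test_33", "cdf_33")):
        cases = labeled[
            (labeled["condition"] == cond)
            & labeled["probe_deg"].isin(adapted_set)
            & labeled["is_near_orthogonal"]
        ]
        try:
            cmp_res = cdf_distance_test(
                cases["offset_deg"].to_numpy(),
                control_offsets.to_numpy(),
                n_resamples=config.n_cdf_resamples,
                seed=seeds[rng_name],
            )
        except InsufficientDataError as exc:
            report["skipped_stages"].append(
                {"stage": f"cdf_test_{cond}", "reason": str(exc)}
            )
            continue
        report["cdf_test"][cond] = {
            "n_near_orthogonal": cmp_res.n_cases,
            "n_resamples": cmp_res.n_resamples,
            "observed_distance": cmp_res.observed_distance,
            "p_value": {"add_one": cmp_res.p_value_add_one, "raw": cmp_res.p_value},
        }

    report["timestamps"]["finished_unix"] = time.time()
    report["elapsed_s"] = time.perf_counter() - t0
    return report


# --------------------------------------------------------------------------
# report schema


def report_schema() -> dict:
    """The JSON schema shipped with the package."""
    with resources.files("orthillusion").joinpath("schema/report.schema.json").open() as fh:
        return json.load(fh)


_REQUIRED_TOP = {
    "provenance": dict,
    "timestamps": dict,
    "skipped_stages": list,
    "design_check": dict,
    "control_reference": dict,
}


def validate_report(report: dict) -> list:
    """Structural check of a report against the shipped schema.

    Returns a list of problem strings (empty = valid).  Intentionally a
    small structural validator (required keys and types), mirroring the
    shipped JSON schema file.
    """
    problems = []
    if not isinstance(report, dict):
        return ["report is not an object"]
    for key, typ in _REQUIRED_TOP.items():
        if key not in report:
            problems.append(f"missing key {key!r}")
        elif not isinstance(report[key], typ):
            problems.append(f"key {key!r} has type {type(report[key]).__name__}")
    prov = report.get("provenance", {})
    for key in ("package_version", "config", "seed"):
        if key not in prov:
            problems.append(f"provenance missing {key!r}")
    for section in ("error_counts", "bootstrap", "shuffle_test", "cdf_test"):
        if section in report and not isinstance(report[section], dict):
            problems.append(f"section {section!r} is not an object")
    return problems
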