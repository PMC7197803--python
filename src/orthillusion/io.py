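"""Trial-table I/O: canonical CSV schema, column-map adapter, validation.

The in-memory trial container is a :class:`pandas.DataFrame` with the
canonical columns below.  Deposited data sets with arbitrary headers are
adapted through a ``column_map`` (canonical field -> source header), which
may be given as a dict or a YAML file.

Canonical columns
-----------------
participant : str            observer identifier
condition : str              one of the five :class:`~orthillusion.design.Condition` values
superposition_duration_ms : int   0, 33 or 200, redundant with condition
single_grating_deg : float   -45/+45 in test conditions, empty otherwise
probe_deg : int              probe label on the 13-value design grid
response_deg : float         adjusted bar orientation, degrees
repeat : int                 1..n_repeats
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import CONDITION_DURATION_MS, TEST_CONDITIONS, Condition, StudyDesign
from .exceptions import ConfigurationError, RowValidationError

CANONICAL_COLUMNS = [
    "participant",
    "condition",
    "superposition_duration_ms",
    "single_grating_deg",
    "probe_deg",
    "response_deg",
    "repeat",
]

__all__ = [
    "CANONICAL_COLUMNS",
    "read_trials",
    "write_trials",
    "load_column_map",
    "validate_trial_frame",
    "validate_design",
    "DesignReport",
]


def load_column_map(source) -> dict:
    """Load a column map from a dict, a YAML file path, or None."""
    if source is None:
        return {}
    if isinstance(source, dict):
        return dict(source)
    with open(source, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"column map file {source!r} must contain a mapping")
    return data


def _to_float(series: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Coerce to float; second return marks values that failed to parse."""
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & (series.astype(str).str.strip() != "")
    return out.astype(float), bad


def validate_trial_frame(df: pd.DataFrame, design: StudyDesign | None = None) -> list:
    """Check trial invariants row by row.

    Returns a list of ``(row_index, message)`` pairs (0-based positional
    index into ``df``).  Checks: known condition, duration consistent with
    the condition, probe label on the design grid, finite response, repeat
    in range, and the single-grating field present exactly for test
    conditions (with value on the adapted grid).
    """
    design = design or StudyDesign()
    errors: list[tuple[int, str]] = []
    valid_conditions = {c.value for c in Condition}
    test_values = {c.value for c in TEST_CONDITIONS}
    grid = set(design.probe_labels)

    cond = df["condition"].astype(str)
    bad_cond = ~cond.isin(valid_conditions)

    dur, bad_dur_parse = _to_float(df["superposition_duration_ms"])
    expected_dur = cond.map(
        {c.value: CONDITION_DURATION_MS[c] for c in Condition}
    )
    bad_dur = (~bad_cond) & (bad_dur_parse | (dur != expected_dur))

    probe, bad_probe_parse = _to_float(df["probe_deg"])
    bad_probe = bad_probe_parse | ~probe.isin(grid)

    resp, bad_resp_parse = _to_float(df["response_deg"])
    bad_resp = bad_resp_parse | ~np.isfinite(resp.to_numpy())

    rep, bad_rep_parse = _to_float(df["repeat"])
    bad_rep = bad_rep_parse | ~rep.isin(range(1, design.n_repeats + 1))

    single, bad_single_parse = _to_float(df["single_grating_deg"])
    is_test = cond.isin(test_values)
    single_missing = single.isna()
    bad_single = (
        bad_single_parse
        | (is_test & (single_missing | ~single.isin(set(design.adapted_labels))))
        | (~is_test & ~bad_cond & ~single_missing)
    )

    checks = [
        (bad_cond, "unknown condition"),
        (bad_dur, "superposition_duration_ms inconsistent with condition"),
        (bad_probe, "probe label off the design grid"),
        (bad_resp, "unparseable or non-finite response angle"),
        (bad_rep, "repeat index out of range"),
        (bad_single, "single_grating_deg violates condition rule"),
    ]
    for mask, msg in checks:
        for idx in np.flatnonzero(mask.to_numpy()):
            errors.append((int(idx), msg))
    errors.sort()
    return errors


def read_trials(
    path,
    column_map=None,
    design: StudyDesign | None = None,
    drop_invalid: bool = False,
) -> pd.DataFrame:
    """Read a trial CSV into the canonical schema.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    column_map : dict | path | None
        Maps canonical field names to source headers for files that do not
        already use the canonical schema.
    drop_invalid : bool
        If True, rows violating trial invariants are dropped with a warning
        listing their file line numbers; if False (default) a
        :class:`RowValidationError` is raised.
    """
    design = design or StudyDesign()
    cmap = load_column_map(column_map)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)

    df = pd.DataFrame()
    for col in CANONICAL_COLUMNS:
        source = cmap.get(col, col)
        if source not in raw.columns:
            raise ConfigurationError(
                f"mapped column {source!r} for field {col!r} not found in {path}"
            )
        df[col] = raw[source]

    errors = validate_trial_frame(df, design)
    if errors:
        # +2: header line plus 1-based numbering.
        file_errors = [(idx + 2, msg) for idx, msg in errors]
        if not drop_invalid:
            raise RowValidationError(file_errors)
        warnings.warn(str(RowValidationError(file_errors)), stacklevel=2)
        bad_rows = sorted({idx for idx, _ in errors})
        df = df.drop(index=df.index[bad_rows]).reset_index(drop=True)

    out = pd.DataFrame(
        {
            "participant": df["participant"].astype(str),
            "condition": df["condition"].astype(str),
            "superposition_duration_ms": pd.to_numeric(
                df["superposition_duration_ms"]
            ).astype(int),
            "single_grating_deg": pd.to_numeric(
                df["single_grating_deg"], errors="coerce"
            ).astype(float),
            "probe_deg": pd.to_numeric(df["probe_deg"]).astype(int),
            "response_deg": pd.to_numeric(df["response_deg"]).astype(float),
            "repeat": pd.to_numeric(df["repeat"]).astype(int),
        }
    )
    return out


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a canonical trial table to CSV (UTF-8, comma-separated)."""
    missing = [c for c in CANONICAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ConfigurationError(f"trial table lacks canonical columns: {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials[CANONICAL_COLUMNS].to_csv(path, index=False)


@dataclass
class DesignReport:
    """Per participant-by-condition trial counts against the design grid."""

    counts: pd.DataFrame  # index participant, columns condition
    expected: int
    flags: list  # (participant, condition, observed_count)

    @property
    def ok(self) -> bool:
        return not self.flags


def validate_design(trials: pd.DataFrame, design: StudyDesign | None = None) -> DesignReport:
    """Compare observed trial counts to the expected probe x repeat grid.

    Purely reporting: never mutates or drops data.  A cell is flagged
    whenever a participant-condition pair does not hold exactly
    ``trials_per_condition_per_participant`` trials.
    """
    design = design or StudyDesign()
    expected = design.trials_per_condition_per_participant
    counts = (
        trials.groupby(["participant", "condition"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    # participants or conditions entirely absent still count as deviations
    for cond in (c.value for c in design.conditions):
        if cond not in counts.columns:
            counts[cond] = 0
    counts = counts[[c.value for c in design.conditions]]

    flags = [
        (participant, cond, int(counts.at[participant, cond]))
        for participant in counts.index
        for cond in counts.columns
        if counts.at[participant, cond] != expected
    ]
    return DesignReport(counts=counts, expected=expected, flags=flags)
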