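"""Exception types shared across the package."""


class OrthillusionError(Exception):
    """Base class for package errors."""


class ConfigurationError(OrthillusionError):
    """Invalid parameters, missing mapped columns, or inconsistent options."""


class RowValidationError(OrthillusionError):
    """One or more CSV rows violate the trial invariants.

    Attributes
    ----------
    errors : list of (int, str)
        1-based file line number and a message per offending row.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "; ".join(f"line {row}: {msg}" for row, msg in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {lines}{more}")


class DegenerateReferenceError(OrthillusionError):
    """Control offsets have zero spread; a 4-SD criterion is undefined."""


class InsufficientDataError(OrthillusionError):
    """Too few cases to run the requested procedure."""
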