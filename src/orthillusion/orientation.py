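"""Circular arithmetic on the 180-degree-periodic orientation domain.

Gratings have no direction, only orientation, so angles that differ by a
multiple of 180 degrees describe the same stimulus.  All arithmetic in the
package goes through the two functions here.  The canonical representative
of an orientation lies in the half-open interval (-90, +90]; -90 folds onto
+90.  Note that the *design labels* of the probe grid keep -90 and +90 as
distinct bookkeeping labels (the same physical orientation measured twice);
only the physical angle is canonicalized.
"""

from __future__ import annotations

import numpy as np

__all__ = ["canonicalize_orientation", "circular_offset", "circular_distance"]


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got non-finite value(s)")


def canonicalize_orientation(theta):
    """Map an angle in degrees to its canonical representative in (-90, +90].

    Accepts scalars or array-likes; returns the same shape.  Idempotent, and
    invariant under adding any multiple of 180 degrees.
    """
    arr = np.asarray(theta, dtype=float)
    _check_finite(arr, "theta")
    out = np.mod(arr, 180.0)
    # np.mod returns values in [0, 180); fold (90, 180) down by one period.
    out = np.where(out > 90.0, out - 180.0, out)
    if np.ndim(theta) == 0:
        return float(out)
    return out


def circular_offset(response, probe):
    """Signed offset (response minus probe) on the orientation circle.

    The result lies in (-90, +90]; it is 0 when the two orientations agree
    and +90 exactly when they are orthogonal (the unique maximal-distance
    case, mapped to the positive endpoint).
    """
    r = np.asarray(response, dtype=float)
    p = np.asarray(probe, dtype=float)
    _check_finite(r, "response")
    _check_finite(p, "probe")
    out = canonicalize_orientation(r - p)
    return out


def circular_distance(a, b):
    """Absolute circular distance between two orientations, in [0, 90]."""
    return np.abs(circular_offset(a, b))
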