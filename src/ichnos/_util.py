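"""Small shared helpers: rounding conventions and argument checks."""

from __future__ import annotations

import math

import numpy as np


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class InsufficientLandmarksError(ValueError):
    """A required named landmark is absent from a footprint."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (report convention; Python's round() banks)."""
    if not math.isfinite(x):
        return x
    factor = 10.0 ** ndigits
    scaled = x * factor
    # nudge by one ulp-ish epsilon so values that are exactly *.5 after a
    # clean decimal computation do not fall on the wrong side of fp error
    rounded = math.floor(abs(scaled) + 0.5 + 1e-9)
    out = math.copysign(rounded, x) / factor
    return out if ndigits > 0 else float(out)


def as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise InvalidArgumentError(f"expected a 2-D point, got shape {a.shape}")
    return a


def unit(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    n = np.linalg.norm(a)
    if n == 0:
        raise InvalidArgumentError("zero-length vector cannot be normalized")
    return a / n
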