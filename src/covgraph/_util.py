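"""Small shared helpers."""
from __future__ import annotations

import math

import numpy as np

__all__ = ["ValidationError", "round_half_up", "trapezoid_auc", "as_rng"]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up.

    Deterministic across platforms (unlike banker's rounding).  A tiny
    epsilon absorbs binary representation error in products such as
    ``0.30 * 45`` which should be an exact half.
    """
    return int(math.floor(x + 0.5 + 1e-9))


def trapezoid_auc(values, x) -> float:
    """Trapezoidal integral of ``values`` over grid ``x`` (0.0 for a single point)."""
    values = np.asarray(values, dtype=float)
    x = np.asarray(x, dtype=float)
    if values.shape[-1] != x.shape[0]:
        raise ValidationError("curve values and grid have different lengths")
    if x.shape[0] < 2:
        return 0.0
    return float(np.trapezoid(values, x))


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
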