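"""Small numeric helpers used across modules."""

from __future__ import annotations

import numpy as np


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` rounds halves to even; point tables need a
    deterministic, sign-symmetric half-case rule.
    """
    if x >= 0:
        return int(np.floor(x + 0.5))
    return int(np.ceil(x - 0.5))


def as_binary(y) -> np.ndarray:
    """Coerce an outcome vector to a float {0,1} array; reject other values."""
    arr = np.asarray(y, dtype=float)
    if arr.ndim != 1:
        raise ValueError("outcome must be one-dimensional")
    if not np.all(np.isin(arr, (0.0, 1.0))):
        raise ValueError("outcome vector must be binary (0/1)")
    return arr
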