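"""Shared numerical helpers: standardization and seed derivation."""

from __future__ import annotations

import numpy as np

__all__ = ["standardize", "spawn_seeds", "check_in_open_unit_interval"]


def standardize(x: np.ndarray, axis: int = 0, ddof: int = 0) -> np.ndarray:
    """Center to mean 0 and scale to variance 1 along ``axis``.

    Uses the population variance (``ddof=0``) so that the sample variance of
    the result is exactly 1, which downstream variance bookkeeping relies on.
    Raises if any slice has (near-)zero variance.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, ddof=ddof, keepdims=True)
    if np.any(sd < 1e-12):
        raise ValueError("cannot standardize a (near-)constant vector")
    return (x - mu) / sd


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one user seed.

    All randomness in a run flows from a single user-facing seed through this
    splitter, so that any component can be re-run in isolation.
    """
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def check_in_open_unit_interval(value: float, name: str) -> float:
    value = float(value)
    if not (0.0 < value < 1.0):
        raise ValueError(f"{name} must lie strictly inside (0, 1); got {value}")
    return value
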