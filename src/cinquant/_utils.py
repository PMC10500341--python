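"""Shared numerical helpers: robust statistics and seed plumbing."""

from __future__ import annotations

import numpy as np

# Consistency constant making the MAD an unbiased scale estimate for a Gaussian.
MAD_SCALE = 1.4826


def robust_location_scale(x: np.ndarray) -> tuple[float, float]:
    """Median and scaled-MAD of ``x`` (robust mean/SD pair).

    Returns ``(median, 1.4826 * MAD)``; the scale is 0 for constant input.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute robust statistics of an empty array")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med, MAD_SCALE * mad


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent substreams from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def child_seed(seed: int, label: str) -> int:
    """Deterministic 31-bit child seed for a named pipeline stage."""
    h = np.uint64(seed & 0x7FFFFFFF)
    for ch in label:
        h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**61 - 1))
    return int(h % np.uint64(2**31 - 1))


def round_half_up(x):
    """Round to nearest integer, halves away from zero (unlike banker's rounding)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)
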