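"""Random-number plumbing shared across modules."""

from __future__ import annotations

import numpy as np

RngLike = "np.random.Generator | int | None"


def as_rng(rng: "np.random.Generator | int | None") -> np.random.Generator:
    """Coerce a Generator, an integer seed, or None into a Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def round_half_away(x):
    """Round to the nearest integer with ties away from zero (vectorized)."""
    x = np.asarray(x)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)
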