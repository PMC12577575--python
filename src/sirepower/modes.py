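"""Paternal contribution modes.

A *paternal contribution mode* describes how the eggs of a single clutch are
apportioned among the males that sired it.  Six modes are supported, each
producing a weight vector ``w_1 >= w_2 >= ... >= w_F`` over the ``F`` fathers
of a clutch (position 1 is the dominant, or top-of-hierarchy, father):

``random``
    every father fertilizes an equal expected share, ``1/F``.
``exponential``
    a strict hierarchy: shares halve down the hierarchy (1/2, 1/4, 1/8, ...)
    with the last father repeating the share of the father above him so the
    vector sums to one.
``dominant50`` / ``dominant70`` / ``dominant90``
    one dominant father fertilizes 50%, 70% or 90% of the eggs and the
    remaining share is split evenly among the other fathers.
``mixed_dominant``
    a meta-mode: each clutch independently behaves like one of the three
    dominant modes, chosen uniformly at random.

The smallest entry of the weight vector -- the *marginal paternal
contribution* -- is the expected egg share of the least dominant father and
is the main driver of how hard it is to detect every father in a finite
offspring sample.

Father counts are capped at five, reflecting the absence of field evidence
for more than five sires in a single clutch.
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = [
    "MAX_FATHERS",
    "ContributionMode",
    "CONCRETE_MODES",
    "DOMINANT_MODES",
    "contribution_weights",
    "marginal_contribution",
    "resolve_mode",
]

#: Maximum number of fathers allowed per clutch (and mates per individual).
MAX_FATHERS = 5


class ContributionMode(str, enum.Enum):
    """The six admissible paternal contribution modes."""

    RANDOM = "random"
    EXPONENTIAL = "exponential"
    DOMINANT50 = "dominant50"
    DOMINANT70 = "dominant70"
    DOMINANT90 = "dominant90"
    MIXED_DOMINANT = "mixed_dominant"

    @classmethod
    def parse(cls, name: "str | ContributionMode") -> "ContributionMode":
        """Parse a case-insensitive mode name (``'Dominant 90'``, ``'dominant90'``...)."""
        if isinstance(name, cls):
            return name
        key = str(name).strip().lower().replace(" ", "_").replace("-", "_")
        # accept both 'dominant_50' and 'dominant50'
        for mode in cls:
            if key in (mode.value, mode.value.replace("dominant", "dominant_")):
                return mode
        raise ValueError(
            f"unknown contribution mode {name!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


#: Concrete (directly simulable) modes, i.e. everything but the meta-mode.
CONCRETE_MODES: tuple[ContributionMode, ...] = (
    ContributionMode.RANDOM,
    ContributionMode.EXPONENTIAL,
    ContributionMode.DOMINANT50,
    ContributionMode.DOMINANT70,
    ContributionMode.DOMINANT90,
)

#: The three modes the meta-mode resolves to, each with probability 1/3.
DOMINANT_MODES: tuple[ContributionMode, ...] = (
    ContributionMode.DOMINANT50,
    ContributionMode.DOMINANT70,
    ContributionMode.DOMINANT90,
)

_DOMINANT_SHARE = {
    ContributionMode.DOMINANT50: 0.5,
    ContributionMode.DOMINANT70: 0.7,
    ContributionMode.DOMINANT90: 0.9,
}


def _validate_n_fathers(n_fathers: int) -> int:
    n = int(n_fathers)
    if n != n_fathers or not (1 <= n <= MAX_FATHERS):
        raise ValueError(
            f"number of fathers must be an integer in 1..{MAX_FATHERS}, got {n_fathers!r}"
        )
    return n


def resolve_mode(
    mode: "str | ContributionMode", rng: np.random.Generator
) -> ContributionMode:
    """Resolve a (possibly meta-) mode to a concrete mode for one clutch.

    ``mixed_dominant`` returns one of the three dominant modes with equal
    probability; every concrete mode is returned unchanged.
    """
    mode = ContributionMode.parse(mode)
    if mode is ContributionMode.MIXED_DOMINANT:
        return DOMINANT_MODES[rng.integers(len(DOMINANT_MODES))]
    return mode


def contribution_weights(mode: "str | ContributionMode", n_fathers: int) -> np.ndarray:
    """Per-father egg-fertilization probabilities for a clutch.

    Parameters
    ----------
    mode
        A *concrete* contribution mode (resolve ``mixed_dominant`` first with
        :func:`resolve_mode`).
    n_fathers
        Total number of fathers ``F`` siring the clutch, 1..5.

    Returns
    -------
    numpy.ndarray
        Length-``F`` probability vector, position 0 being the dominant
        father.  Sums to one; every entry is positive.
    """
    mode = ContributionMode.parse(mode)
    n = _validate_n_fathers(n_fathers)
    if mode is ContributionMode.MIXED_DOMINANT:
        raise ValueError(
            "mixed_dominant is a meta-mode; resolve it to a concrete mode "
            "per clutch with resolve_mode() before requesting weights"
        )
    if n == 1:
        return np.ones(1)
    if mode is ContributionMode.RANDOM:
        return np.full(n, 1.0 / n)
    if mode is ContributionMode.EXPONENTIAL:
        w = 0.5 ** np.arange(1, n + 1, dtype=float)
        w[-1] = w[-2]  # last father repeats the previous hierarchy level
        return w
    share = _DOMINANT_SHARE[mode]
    w = np.full(n, (1.0 - share) / (n - 1))
    w[0] = share
    return w


def marginal_contribution(mode: "str | ContributionMode", n_fathers: int) -> float:
    """Expected egg share of the least dominant father (min of the weights)."""
    return float(contribution_weights(mode, n_fathers).min())
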