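"""Bayes posterior on the true father count given the identified count.

Field studies observe only ``Y``, the number of fathers identified in an
offspring sample, while inference targets ``X``, the number that actually
sired the clutch.  Given an identification matrix ``P(Y | X)`` estimated by
simulation and a prior ``P(X)`` over 1..5 fathers, Bayes' theorem yields

    P(X | Y) = P(Y | X) P(X) / sum_X' P(Y | X') P(X').

Rows are reported for Y = 1..4 only: observing five identified fathers
logically implies five contributed (five is the cap), so that row is a point
mass and carries no information.

The prior defaults to uniform over 1..5 contributing fathers; the empirical
"decreasing" mating-number distribution can be substituted (or any custom
vector) when population-specific rates of multiple paternity are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clutch import IdentificationMatrix
from .modes import MAX_FATHERS, ContributionMode

__all__ = [
    "UNIFORM_PRIOR",
    "UndefinedPosteriorError",
    "PosteriorTable",
    "father_count_posterior",
    "min_diagonal",
]

#: Uniform prior over 1..5 contributing fathers.
UNIFORM_PRIOR = np.full(MAX_FATHERS, 1.0 / MAX_FATHERS)


class UndefinedPosteriorError(ValueError):
    """Raised when a posterior row conditions on an event of probability zero."""


def _validate_prior(prior) -> np.ndarray:
    p = np.asarray(prior, dtype=float)
    if p.shape != (MAX_FATHERS,):
        raise ValueError(f"prior must have length {MAX_FATHERS}, got shape {p.shape}")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
        raise ValueError("prior must be non-negative and sum to 1")
    return p


@dataclass
class PosteriorTable:
    """``P(X contributed | Y identified)`` for Y = 1..4, X = 1..5.

    ``Q[Y-1, X-1]`` holds the posterior mass; rows sum to one over their
    support ``X >= Y``.  A row whose conditioning event ``Y`` had zero
    estimated marginal probability is flagged in ``defined`` and filled with
    NaN instead of being silently normalized.
    """

    mode: ContributionMode
    sample_size: int
    Q: np.ndarray = field(repr=False)
    defined: np.ndarray = field(repr=False)

    def prob(self, y: int, x: int) -> float:
        """``P(X = x | Y = y)`` with 1-based counts, y in 1..4."""
        if not self.defined[y - 1]:
            raise UndefinedPosteriorError(
                f"P(X | Y={y}) is undefined: Y={y} was never observed"
            )
        return float(self.Q[y - 1, x - 1])


def father_count_posterior(
    M: IdentificationMatrix, prior=None
) -> PosteriorTable:
    """Invert an identification matrix through Bayes' theorem.

    Parameters
    ----------
    M
        Estimated ``P(Y | X)`` from :func:`sirepower.clutch.identification_matrix`.
    prior
        ``P(X)`` over 1..5 fathers; defaults to uniform.
    """
    prior = _validate_prior(UNIFORM_PRIOR if prior is None else prior)
    n_rows = MAX_FATHERS - 1  # Y = 5 implies X = 5 logically; row omitted
    Q = np.full((n_rows, MAX_FATHERS), np.nan)
    defined = np.zeros(n_rows, dtype=bool)
    for y in range(1, n_rows + 1):
        joint = M.P[:, y - 1] * prior
        marginal = joint.sum()
        if marginal > 0:
            Q[y - 1] = joint / marginal
            defined[y - 1] = True
    return PosteriorTable(mode=M.mode, sample_size=M.sample_size, Q=Q, defined=defined)


def min_diagonal(table: PosteriorTable) -> float:
    """Smallest ``P(X = Y | Y)`` over Y = 1..4.

    This is the headline accuracy statistic: across all observable
    identified counts, the worst-case probability that the identified count
    equals the true count.
    """
    if not table.defined.all():
        missing = [y + 1 for y in np.flatnonzero(~table.defined)]
        raise UndefinedPosteriorError(
            f"posterior undefined for identified counts {missing}"
        )
    return float(min(table.Q[y, y] for y in range(table.Q.shape[0])))
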