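"""Within-clutch simulation: fertilization, offspring sampling, identification.

A clutch is simulated in three steps: draw an egg count from a (rounded,
positive) normal distribution; assign each egg independently to one of the
``F`` fathers with probabilities given by the contribution mode; sample ``n``
offspring without replacement and record the distinct fathers observed.  The
number of fathers identified, ``Y``, is compared to the number contributing,
``X``, across many replicate clutches to estimate ``P(Y | X)``.

Because the eggs carry i.i.d. father labels, a uniform without-replacement
subsample of ``m = min(n, clutch size)`` eggs carries i.i.d. labels as well;
the distinct-father count of a sample is therefore distributed exactly as the
number of non-empty categories of a single multinomial(m, w) draw.  The
Monte-Carlo drivers below use that identity to vectorize over replicates,
while :func:`assign_paternity` / :func:`sample_offspring` expose the explicit
egg-level path (the two are checked against each other in the test suite).

:func:`analytic_identify_all_probability` gives the exact
inclusion-exclusion probability of observing every father, which serves as
an independent check on the simulations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._rng import as_rng, round_half_away
from .modes import (
    MAX_FATHERS,
    ContributionMode,
    contribution_weights,
    resolve_mode,
)

__all__ = [
    "ClutchDemography",
    "Clutch",
    "draw_clutch_size",
    "assign_paternity",
    "sample_offspring",
    "analytic_identify_all_probability",
    "expected_identify_all_probability",
    "clutch_size_pmf",
    "identification_distribution",
    "IdentificationMatrix",
    "identification_matrix",
    "clutch_confidence_curve",
]


@dataclass(frozen=True)
class ClutchDemography:
    """Normal model for the number of eggs per clutch.

    Defaults are the field estimates for a green sea turtle nesting
    population (mean 100.58 eggs, SD 22.61).  Draws are rounded to the
    nearest integer (ties away from zero) and redrawn while below one, so a
    clutch always holds at least one egg.
    """

    mu_eggs: float = 100.58
    sigma_eggs: float = 22.61

    def __post_init__(self) -> None:
        if self.mu_eggs <= 0:
            raise ValueError(f"mu_eggs must be > 0, got {self.mu_eggs}")
        if self.sigma_eggs < 0:
            raise ValueError(f"sigma_eggs must be >= 0, got {self.sigma_eggs}")


def draw_positive_rounded_normal(mu, sigma, rng, size=None):
    """Rounded normal draws, redrawn until >= 1.

    Used for both eggs per clutch and clutches per mother.  Rounding is to
    the nearest integer with ties away from zero; any draw below one is
    redrawn rather than clamped, which keeps the mean essentially unbiased
    when 1 is far in the lower tail.
    """
    scalar = size is None
    n = 1 if scalar else int(size)
    out = round_half_away(rng.normal(mu, sigma, size=n))
    bad = out < 1
    while bad.any():
        out[bad] = round_half_away(rng.normal(mu, sigma, size=int(bad.sum())))
        bad = out < 1
    return int(out[0]) if scalar else out


def draw_clutch_size(demog: ClutchDemography, rng, size=None):
    """Draw one (or ``size``) integer clutch sizes, always >= 1."""
    return draw_positive_rounded_normal(demog.mu_eggs, demog.sigma_eggs, as_rng(rng), size)


@dataclass
class Clutch:
    """One clutch of eggs with a father label per egg.

    Labels are 1..F when the clutch is simulated in isolation and actual
    male IDs when it is produced by the season model; either way
    ``father_of_egg`` has one entry per egg.
    """

    size: int
    father_of_egg: np.ndarray

    def __post_init__(self) -> None:
        self.father_of_egg = np.asarray(self.father_of_egg)
        if self.size < 1 or len(self.father_of_egg) != self.size:
            raise ValueError("father_of_egg must hold one label per egg (size >= 1)")

    def fathers_present(self) -> set:
        """Fathers with at least one egg in the clutch."""
        return set(np.unique(self.father_of_egg).tolist())


def _sample_labels(cumw: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. 1-based category draws given cumulative weights."""
    labels = np.searchsorted(cumw, rng.random(n), side="right")
    return np.minimum(labels, len(cumw) - 1) + 1


def assign_paternity(clutch_size: int, weights: np.ndarray, rng) -> Clutch:
    """Assign each egg independently to a father by weighted draw.

    Eggs are i.i.d. multinomial, so a father may end up with zero eggs --
    which is exactly why whole-clutch censuses can still miss fathers under
    strongly skewed contribution modes.
    """
    if clutch_size < 1:
        raise ValueError("clutch_size must be >= 1")
    rng = as_rng(rng)
    w = np.asarray(weights, dtype=float)
    cumw = np.cumsum(w / w.sum())
    return Clutch(int(clutch_size), _sample_labels(cumw, int(clutch_size), rng))


def sample_offspring(clutch: Clutch, n: int, rng) -> set:
    """Sample ``min(n, clutch.size)`` eggs without replacement; return the
    distinct father labels observed."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    rng = as_rng(rng)
    m = min(int(n), clutch.size)
    idx = rng.choice(clutch.size, size=m, replace=False)
    return set(np.unique(clutch.father_of_egg[idx]).tolist())


def analytic_identify_all_probability(weights, n: int, clutch_size: int) -> float:
    """Exact probability that a sample contains every father label.

    Inclusion-exclusion over the set of missed fathers: with ``m = min(n,
    clutch_size)`` i.i.d.-labelled eggs in the sample,

        P(all F observed) = sum over S of (-1)^|S| (1 - sum_{i in S} w_i)^m

    where S ranges over all subsets of fathers.  Exact for the egg-level
    model because a uniform without-replacement subsample of i.i.d. labels
    is itself i.i.d.
    """
    if n < 1 or clutch_size < 1:
        raise ValueError("n and clutch_size must be >= 1")
    w = np.asarray(weights, dtype=float)
    m = min(int(n), int(clutch_size))
    total = 0.0
    for k in range(len(w) + 1):
        for subset in itertools.combinations(range(len(w)), k):
            total += (-1.0) ** k * (1.0 - w[list(subset)].sum()) ** m
    return float(total)


def clutch_size_pmf(demog: ClutchDemography, upper: "int | None" = None):
    """Discretized clutch-size distribution implied by round-and-redraw.

    Returns ``(sizes, probs)`` with ``P(K = k)`` proportional to the normal
    mass of the rounding interval ``[k - 0.5, k + 0.5)`` (the ``k = 1`` bin
    absorbs everything below 1.5 that survives redrawing), renormalized over
    ``k >= 1``.
    """
    if demog.sigma_eggs == 0:
        k = int(round_half_away(np.array(demog.mu_eggs)))
        return np.array([max(k, 1)]), np.array([1.0])
    if upper is None:
        upper = int(np.ceil(demog.mu_eggs + 8 * demog.sigma_eggs))
    k = np.arange(1, upper + 1)
    hi = stats.norm.cdf(k + 0.5, demog.mu_eggs, demog.sigma_eggs)
    lo = stats.norm.cdf(k - 0.5, demog.mu_eggs, demog.sigma_eggs)
    lo[0] = stats.norm.cdf(0.5, demog.mu_eggs, demog.sigma_eggs)
    p = hi - lo
    return k, p / p.sum()


def expected_identify_all_probability(
    weights, n: int, demog: "ClutchDemography | None" = None
) -> float:
    """:func:`analytic_identify_all_probability` averaged over clutch size."""
    demog = demog or ClutchDemography()
    sizes, probs = clutch_size_pmf(demog)
    # the probability only depends on min(n, k); collapse the k >= n tail
    small = sizes < n
    total = sum(
        p * analytic_identify_all_probability(weights, n, int(k))
        for k, p in zip(sizes[small], probs[small])
    )
    tail = probs[~small].sum()
    if tail > 0:
        total += tail * analytic_identify_all_probability(weights, n, int(n))
    return float(total)


def _resolved_mode_groups(mode: ContributionMode, reps: int, rng: np.random.Generator):
    """Split replicate indices by the concrete mode each clutch resolves to."""
    mode = ContributionMode.parse(mode)
    if mode is not ContributionMode.MIXED_DOMINANT:
        return [(mode, np.arange(reps))]
    from .modes import DOMINANT_MODES

    picks = rng.integers(len(DOMINANT_MODES), size=reps)
    return [
        (m, np.flatnonzero(picks == i))
        for i, m in enumerate(DOMINANT_MODES)
        if (picks == i).any()
    ]


def identification_distribution(
    mode,
    n_fathers: int,
    sample_size: int,
    demog: "ClutchDemography | None" = None,
    reps: int = 10_000,
    rng=None,
) -> np.ndarray:
    """Monte-Carlo distribution of the number of fathers identified.

    Simulates ``reps`` independent clutches with ``n_fathers`` contributing
    fathers (resolving ``mixed_dominant`` per clutch), samples
    ``sample_size`` offspring from each, and returns the estimated
    probability vector ``P(Y = 1), ..., P(Y = n_fathers)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    demog = demog or ClutchDemography()
    rng = as_rng(rng)
    sizes = draw_clutch_size(demog, rng, size=reps)
    m = np.minimum(int(sample_size), sizes)
    n_distinct = np.empty(reps, dtype=np.int64)
    for concrete, idx in _resolved_mode_groups(mode, reps, rng):
        w = contribution_weights(concrete, n_fathers)
        draws = rng.multinomial(m[idx], w / w.sum())
        n_distinct[idx] = (draws > 0).sum(axis=-1)
    return np.bincount(n_distinct, minlength=n_fathers + 1)[1:] / reps


@dataclass
class IdentificationMatrix:
    """Estimated ``P(Y identified | X contributed)`` for X, Y in 1..5.

    ``P[X-1, Y-1]`` holds the estimate; rows sum to one and every entry with
    ``Y > X`` is structurally zero (one cannot identify more fathers than
    contributed).
    """

    mode: ContributionMode
    sample_size: int
    reps: int
    P: np.ndarray = field(repr=False)

    def prob(self, x: int, y: int) -> float:
        """``P(Y = y | X = x)`` with 1-based father counts."""
        return float(self.P[x - 1, y - 1])


def identification_matrix(
    mode,
    sample_size: int,
    demog: "ClutchDemography | None" = None,
    reps: int = 10_000,
    rng=None,
) -> IdentificationMatrix:
    """Stack :func:`identification_distribution` for X = 1..5."""
    mode = ContributionMode.parse(mode)
    rng = as_rng(rng)
    P = np.zeros((MAX_FATHERS, MAX_FATHERS))
    for x in range(1, MAX_FATHERS + 1):
        P[x - 1, :x] = identification_distribution(
            mode, x, sample_size, demog=demog, reps=reps, rng=rng
        )
    return IdentificationMatrix(mode=mode, sample_size=sample_size, reps=reps, P=P)


def clutch_confidence_curve(
    mode,
    n_fathers: int,
    sample_sizes,
    demog: "ClutchDemography | None" = None,
    reps: int = 10_000,
    rng=None,
) -> np.ndarray:
    """Probability of identifying *all* fathers versus offspring sample size.

    For each replicate clutch the same simulated eggs are reused across all
    sample sizes (the size-``n`` sample is a prefix of a single random
    ordering of the eggs), so the returned curve is non-decreasing in ``n``
    by construction.
    """
    ns = np.asarray(sample_sizes, dtype=int)
    if ns.ndim == 0:
        ns = ns[None]
    if (ns < 1).any() or (ns > 96).any():
        raise ValueError("sample sizes must lie in 1..96")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    demog = demog or ClutchDemography()
    rng = as_rng(rng)
    mode = ContributionMode.parse(mode)

    cumw_cache: dict[ContributionMode, np.ndarray] = {}
    hits = np.zeros(len(ns))
    for _ in range(reps):
        concrete = resolve_mode(mode, rng)
        cumw = cumw_cache.get(concrete)
        if cumw is None:
            w = contribution_weights(concrete, n_fathers)
            cumw = np.cumsum(w / w.sum())
            cumw_cache[concrete] = cumw
        size = draw_clutch_size(demog, rng)
        labels = _sample_labels(cumw, size, rng)
        # eggs arrive i.i.d., hence already exchangeable: the first m eggs
        # are a uniform without-replacement sample of size m
        if n_fathers == 1:
            first_all = 1
        else:
            firsts = np.empty(n_fathers, dtype=np.int64)
            complete = True
            for f in range(1, n_fathers + 1):
                match = labels == f
                if not match.any():
                    complete = False
                    break
                firsts[f - 1] = np.argmax(match)
            first_all = int(firsts.max()) + 1 if complete else size + 1
        hits += np.minimum(ns, size) >= first_all
    return hits / reps
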