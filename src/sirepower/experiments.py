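"""Batch experiment sweeps with seeded reproducibility and CSV-ready output.

Each ``run_*`` function consumes a flat configuration mapping (mirroring the
CLI flags; YAML files parse straight into it), runs the corresponding sweep,
and returns a tidy :class:`pandas.DataFrame` in which every row carries the
full parameter tuple, the replicate count, the seed, and the package
version, so a result file is self-describing and a rerun with the same
configuration is byte-identical.

Replicate streams are spawned per grid cell from a single root seed, so the
results of one cell do not depend on which other cells are in the grid.
"""

from __future__ import annotations

import logging
import time
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .clutch import ClutchDemography, clutch_confidence_curve, identification_matrix
from .modes import MAX_FATHERS, ContributionMode
from .posterior import UNIFORM_PRIOR, father_count_posterior
from .season import (
    DECREASING_MATING,
    SeasonConfig,
    mating_numbers,
    season_confidence_curve,
)

__all__ = ["run_clutch_sweep", "run_posterior_tables", "run_season_grid"]

logger = logging.getLogger(__name__)


def _get(cfg: Mapping, key: str, default):
    value = cfg.get(key, default)
    if value is None:
        value = default
    return value


def _modes(cfg: Mapping) -> list[ContributionMode]:
    raw = _get(cfg, "modes", [m.value for m in ContributionMode])
    if isinstance(raw, (str, ContributionMode)):
        raw = [raw]
    return [ContributionMode.parse(m) for m in raw]


def _as_list(value) -> list:
    if np.isscalar(value):
        return [value]
    return list(value)


def _demog(cfg: Mapping) -> ClutchDemography:
    return ClutchDemography(
        mu_eggs=float(_get(cfg, "mu_eggs", 100.58)),
        sigma_eggs=float(_get(cfg, "sigma_eggs", 22.61)),
    )


def _spawned(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_clutch_sweep(cfg: Mapping) -> pd.DataFrame:
    """Within-clutch confidence versus sample size, per mode and father count.

    Config keys: ``modes``, ``fathers``, ``sample_sizes``, ``mu_eggs``,
    ``sigma_eggs``, ``reps``, ``seed``.
    """
    modes = _modes(cfg)
    fathers = [int(f) for f in _as_list(_get(cfg, "fathers", range(1, MAX_FATHERS + 1)))]
    sample_sizes = np.asarray(_as_list(_get(cfg, "sample_sizes", range(1, 97))), int)
    reps = int(_get(cfg, "reps", 10_000))
    seed = int(_get(cfg, "seed", 0))
    demog = _demog(cfg)
    if any(not 1 <= f <= MAX_FATHERS for f in fathers):
        raise ValueError(f"father counts must lie in 1..{MAX_FATHERS}")
    if (sample_sizes < 1).any() or (sample_sizes > 96).any():
        raise ValueError("sample sizes must lie in 1..96")

    cells = [(m, f) for m in modes for f in fathers]
    rows = []
    for (mode, f), rng in zip(cells, _spawned(seed, len(cells))):
        t0 = time.perf_counter()
        conf = clutch_confidence_curve(
            mode, f, sample_sizes, demog=demog, reps=reps, rng=rng
        )
        logger.info(
            "clutch sweep %s F=%d: %d sample sizes x %d reps in %.1fs",
            mode.value, f, len(sample_sizes), reps, time.perf_counter() - t0,
        )
        for n, c in zip(sample_sizes, conf):
            rows.append(
                {
                    "mode": mode.value,
                    "F": f,
                    "sample_size": int(n),
                    "reps": reps,
                    "confidence": c,
                    "mc_se": float(np.sqrt(c * (1 - c) / reps)),
                    "seed": seed,
                    "version": __version__,
                }
            )
    return pd.DataFrame(rows)


def _prior(cfg: Mapping) -> np.ndarray:
    raw = _get(cfg, "prior", "uniform")
    if isinstance(raw, str):
        key = raw.strip().lower()
        if key == "uniform":
            return UNIFORM_PRIOR
        if key in ("decreasing", "polyandry-decreasing", "polyandry_decreasing"):
            return DECREASING_MATING
        raise ValueError(f"unknown prior {raw!r}")
    return np.asarray(raw, dtype=float)


def run_posterior_tables(cfg: Mapping) -> pd.DataFrame:
    """Posterior P(X contributed | Y identified) per mode and sample size.

    Config keys: ``modes``, ``sample_sizes`` (default 32 and 96), ``prior``
    (``uniform``, ``decreasing``, or a length-5 vector), ``mu_eggs``,
    ``sigma_eggs``, ``reps``, ``seed``.
    """
    modes = _modes(cfg)
    sample_sizes = [int(n) for n in _as_list(_get(cfg, "sample_sizes", [32, 96]))]
    reps = int(_get(cfg, "reps", 10_000))
    seed = int(_get(cfg, "seed", 0))
    prior = _prior(cfg)
    demog = _demog(cfg)

    cells = [(m, n) for m in modes for n in sample_sizes]
    rows = []
    for (mode, n), rng in zip(cells, _spawned(seed, len(cells))):
        M = identification_matrix(mode, n, demog=demog, reps=reps, rng=rng)
        table = father_count_posterior(M, prior)
        for y in range(1, MAX_FATHERS):
            if not table.defined[y - 1]:
                logger.warning(
                    "posterior %s n=%d: Y=%d never observed", mode.value, n, y
                )
                continue
            for x in range(y, MAX_FATHERS + 1):
                rows.append(
                    {
                        "mode": mode.value,
                        "sample_size": n,
                        "Y": y,
                        "X": x,
                        "probability": table.prob(y, x),
                        "reps": reps,
                        "seed": seed,
                        "version": __version__,
                    }
                )
    return pd.DataFrame(rows)


def run_season_grid(cfg: Mapping) -> pd.DataFrame:
    """Season-level confidence over an OSR x clutch-fraction grid.

    Config keys: ``pop_size``, ``osr`` (list), ``clutch_fractions`` (list),
    ``n_per_clutch``, ``modes``, ``polyandry``, ``polygyny``, ``threshold``,
    ``mu_eggs``, ``sigma_eggs``, ``reps``, ``seed``.  Within one (mode, OSR)
    cell all clutch fractions share common random seasons, so confidence is
    monotone along the fraction axis.
    """
    modes = _modes(cfg)
    pop_size = int(_get(cfg, "pop_size", 100))
    osrs = [float(v) for v in _as_list(_get(cfg, "osr", [0.5]))]
    fractions = np.asarray(
        _as_list(_get(cfg, "clutch_fractions", np.round(np.arange(1, 21) * 0.05, 2))),
        float,
    )
    n_per_clutch = int(_get(cfg, "n_per_clutch", 32))
    polyandry = _get(cfg, "polyandry", "decreasing")
    polygyny = _get(cfg, "polygyny", "decreasing")
    threshold = float(_get(cfg, "threshold", 1.0))
    reps = int(_get(cfg, "reps", 10_000))
    seed = int(_get(cfg, "seed", 0))
    demog = _demog(cfg)
    polyandry_name = polyandry if isinstance(polyandry, str) else "custom"
    polygyny_name = polygyny if isinstance(polygyny, str) else "custom"

    cells = [(m, o) for m in modes for o in osrs]
    rows = []
    for (mode, osr), rng in zip(cells, _spawned(seed, len(cells))):
        config = SeasonConfig(
            osr=osr,
            pop_size=pop_size,
            polyandry=mating_numbers(polyandry),
            polygyny=mating_numbers(polygyny),
            mode=mode,
            demog=demog,
        )
        t0 = time.perf_counter()
        curve = season_confidence_curve(
            config,
            n_per_clutch=n_per_clutch,
            success_threshold=threshold,
            fractions=fractions,
            reps=reps,
            rng=rng,
        )
        logger.info(
            "season grid %s osr=%.2f: %d fractions x %d reps in %.1fs",
            mode.value, osr, len(fractions), reps, time.perf_counter() - t0,
        )
        for frac, c, se in zip(curve.fractions, curve.confidence, curve.mc_se):
            rows.append(
                {
                    "pop_size": pop_size,
                    "osr": osr,
                    "clutch_fraction": float(frac),
                    "n_per_clutch": n_per_clutch,
                    "mode": mode.value,
                    "polyandry": polyandry_name,
                    "polygyny": polygyny_name,
                    "threshold": threshold,
                    "reps": reps,
                    "confidence": float(c),
                    "mc_se": float(se),
                    "mean_breeding_fathers": curve.mean_breeding_fathers,
                    "mean_clutches": curve.mean_clutches,
                    "seed": seed,
                    "version": __version__,
                }
            )
    return pd.DataFrame(rows)
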