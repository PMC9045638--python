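"""Bayesian block bootstrap errors for weighted estimates.

Each free-energy window is one block.  A replicate draws one flat Dirichlet
weight vector over blocks (the Bayesian bootstrap), scales it by the number
of blocks so the expected per-block factor is one, multiplies each window's
effective frame count by its factor, and re-solves the full self-consistent
reweighting before re-evaluating the statistic — errors therefore propagate
through the window-offset estimation, not just through the final binning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE
from .reweight import ensemble_from_runs

__all__ = ["BootstrapSpec", "BootstrapResult", "bayesian_block_weights",
           "bootstrap_estimate"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapSpec:
    """Replicate count (100 in the production analysis) and seed."""

    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("need at least 2 bootstrap replicates")


@dataclass
class BootstrapResult:
    point: object
    error: object
    replicates: np.ndarray
    n_failed: int = 0


def bayesian_block_weights(n_blocks: int, n_replicates: int, seed) -> np.ndarray:
    """(n_replicates, n_blocks) Dirichlet block factors, each row summing to
    n_blocks so the expected factor per block is 1."""
    if n_blocks < 1:
        raise ValueError("need at least one block")
    if n_blocks == 1:
        return np.ones((n_replicates, 1))
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(n_blocks), size=n_replicates)
    return w * n_blocks


def bootstrap_estimate(statistic, runs, spec: BootstrapSpec | None = None,
                       temperature: float = DEFAULT_TEMPERATURE,
                       equilibration: float = 0.1, subsample: int = 10,
                       max_failure_fraction: float = 0.2):
    """Point value, standard error and replicate values of a statistic.

    ``statistic(ensemble, views)`` maps a reweighted ensemble (plus the
    per-window frame views aligned with it) to a float or array.  The point
    value uses unit block factors; each replicate re-solves the reweighting
    under its Dirichlet factors (warm-started from the point solution, with
    the bias matrix reused).
    """
    spec = spec or BootstrapSpec()
    ens, g0, views, bias = ensemble_from_runs(
        runs, temperature, equilibration, subsample)
    point = statistic(ens, views)
    factors = bayesian_block_weights(len(runs), spec.n_replicates, spec.seed)
    replicates = []
    n_failed = 0
    for r in range(spec.n_replicates):
        try:
            ens_r, _, _, _ = ensemble_from_runs(
                runs, temperature, equilibration, subsample,
                window_factors=factors[r], g0=g0, bias=bias)
            replicates.append(np.asarray(statistic(ens_r, views), dtype=float))
        except Exception as exc:  # noqa: BLE001 - replicate-level containment
            n_failed += 1
            warnings.warn(f"bootstrap replicate {r} failed and was excluded: {exc}")
    if n_failed > max_failure_fraction * spec.n_replicates:
        raise RuntimeError(
            f"{n_failed}/{spec.n_replicates} bootstrap replicates failed")
    replicates = np.stack(replicates)
    return BootstrapResult(point, replicates.std(axis=0, ddof=1),
                           replicates, n_failed)
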