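"""Exact match probabilities and weighted moments for the rejection estimator.

Because a simulated experiment's per-context expert count is binomial under
the choice model, the probability that one simulation matches the observed
table has a closed form: a product over conditions (and, in the eight-cell
layout, order strata) of binomial mass on the tolerated count window.  The
match-weighted parameter moments of an infinite-simulation grid run follow
by normalizing these probabilities over the lattice.  This module is the
non-stochastic oracle the Monte-Carlo estimator is verified against.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

from .choice_model import (
    BiasParameters,
    Order,
    expert_production_probability,
)
from .estimator import GridSpec
from .simulator import CONTEXTS, CountTable, ExperimentDesign, TableLayout

__all__ = [
    "UnsupportedModelError",
    "AllZeroMatchProbabilityError",
    "match_probability",
    "grid_match_probabilities",
    "exact_weighted_moments",
]


class UnsupportedModelError(ValueError):
    """The requested layout/parameter combination has no implemented closed form."""


class AllZeroMatchProbabilityError(RuntimeError):
    """Every lattice cell has zero match probability; moments are undefined."""


def _window_mass(n, p, center: int, tolerance: int):
    """Binomial(n, p) mass on {center-tol, ..., center+tol} clipped to [0, n]."""
    lo = max(0, center - tolerance)
    hi = min(n, center + tolerance)
    if lo > hi:
        return np.zeros(np.shape(p)) if np.ndim(p) else 0.0
    upper = binom.cdf(hi, n, p)
    lower = binom.cdf(lo - 1, n, p) if lo > 0 else 0.0
    return upper - lower


def _interval_mass(n, p, lo: int, hi: int):
    """Binomial(n, p) mass on the integer interval [lo, hi] (may be empty)."""
    lo = max(0, lo)
    hi = min(n, hi)
    if lo > hi:
        return np.zeros(np.shape(p)) if np.ndim(p) else 0.0
    upper = binom.cdf(hi, n, p)
    lower = binom.cdf(lo - 1, n, p) if lo > 0 else 0.0
    return upper - lower


def _four_cell_probability(eb, cb, observed: CountTable, design: ExperimentDesign, tolerance: int):
    prob = 1.0
    for context in CONTEXTS:
        p = expert_production_probability(eb, cb, context=context)
        prob = prob * _window_mass(
            design.n(context), p, observed.expert_count(context), tolerance
        )
    return prob


def _eight_cell_probability(
    eb, cb, pb, observed: CountTable, design: ExperimentDesign, tolerance: int
):
    """Product over contexts and order strata of constrained binomial mass.

    In the expert-first stratum (size ``nf``) the expert count ``k`` fills
    the (expert, first) cell and ``nf - k`` fills (peer, last); matching
    both cells within the tolerance confines ``k`` to the intersection of
    two windows.  Likewise for the expert-last stratum.
    """
    prob = 1.0
    for ci, context in enumerate(CONTEXTS):
        nf, nl = design.order_split(context)
        obs = observed.cells[ci]
        p_first = expert_production_probability(
            eb, cb, pb, context=context, expert_order=Order.FIRST
        )
        p_last = expert_production_probability(
            eb, cb, pb, context=context, expert_order=Order.LAST
        )
        # expert-first stratum: k -> (expert, first); nf - k -> (peer, last)
        lo_f = max(obs[0, 0] - tolerance, nf - obs[1, 1] - tolerance)
        hi_f = min(obs[0, 0] + tolerance, nf - obs[1, 1] + tolerance)
        prob = prob * _interval_mass(nf, p_first, lo_f, hi_f)
        # expert-last stratum: k -> (expert, last); nl - k -> (peer, first)
        lo_l = max(obs[0, 1] - tolerance, nl - obs[1, 0] - tolerance)
        hi_l = min(obs[0, 1] + tolerance, nl - obs[1, 0] + tolerance)
        prob = prob * _interval_mass(nl, p_last, lo_l, hi_l)
    return prob


def match_probability(
    params: BiasParameters,
    observed: CountTable,
    design: ExperimentDesign,
    tolerance: int = 0,
) -> float:
    """Exact probability that one simulated experiment matches ``observed``.

    Supported model/layout combinations: the four-cell layout with a neutral
    primacy bias, and the eight-cell layout with the simulator's balanced
    order counterbalancing (any primacy bias).

    Raises
    ------
    UnsupportedModelError
        Four-cell layout with a non-zero primacy bias (the expert count is
        then a binomial convolution across order strata, not handled here).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if observed.layout is TableLayout.FOUR_CELL:
        if params.primacy_bias != 0.0:
            raise UnsupportedModelError(
                "four-cell match probability requires primacy_bias == 0"
            )
        return float(
            _four_cell_probability(
                params.expert_bias, params.congruent_bias, observed, design, tolerance
            )
        )
    return float(
        _eight_cell_probability(
            params.expert_bias,
            params.congruent_bias,
            params.primacy_bias,
            observed,
            design,
            tolerance,
        )
    )


def grid_match_probabilities(
    observed: CountTable, design: ExperimentDesign, grid: GridSpec
) -> np.ndarray:
    """Exact per-cell match probabilities over a whole lattice (vectorized)."""
    meshes = grid.param_meshes()
    eb = np.clip(meshes["expert_bias"], -1, 1)
    cb = np.clip(meshes["congruent_bias"], -1, 1)
    if observed.layout is TableLayout.FOUR_CELL:
        if grid.primacy_axis is not None:
            raise UnsupportedModelError(
                "four-cell probabilities require a primacy-free grid"
            )
        return np.asarray(
            _four_cell_probability(eb, cb, observed, design, grid.match_tolerance)
        )
    pb = (
        np.clip(meshes["primacy_bias"], -1, 1)
        if grid.primacy_axis is not None
        else np.zeros_like(eb)
    )
    return np.asarray(
        _eight_cell_probability(eb, cb, pb, observed, design, grid.match_tolerance)
    )


def exact_weighted_moments(
    observed: CountTable, design: ExperimentDesign, grid: GridSpec
) -> dict:
    """Infinite-simulation limit of the grid estimator's summary.

    Returns ``{"parameters": {name: {"mean", "sd"}}, "total_probability"}``
    where each mean/SD weights the lattice by its exact match probability —
    the almost-sure limit of the Monte-Carlo match-weighted summary as the
    per-cell simulation count grows.

    Raises
    ------
    AllZeroMatchProbabilityError
        No lattice cell can produce the observed table.
    """
    probs = grid_match_probabilities(observed, design, grid)
    total = float(probs.sum())
    if total <= 0.0:
        raise AllZeroMatchProbabilityError(
            "match probability is zero over the entire grid"
        )
    meshes = grid.param_meshes()
    out: dict = {"parameters": {}, "total_probability": total}
    for name in grid.param_names:
        values = meshes[name]
        mean = float((values * probs).sum() / total)
        var = float((probs * (values - mean) ** 2).sum() / total)
        out["parameters"][name] = {"mean": mean, "sd": float(np.sqrt(var))}
    return out
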