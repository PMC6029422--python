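"""Local IDA: causal-effect multisets and lower bounds from a CPDAG.

A CPDAG identifies the true DAG only up to its Markov equivalence class,
so the causal effect of a covariate X on the outcome Y is a *multiset*
Theta_i of adjusted estimates, one per locally valid parent set of X.  The
reported quantity is the lower bound

    beta_i = min_j |theta_ij|,

the minimum absolute effect over the class, and the *ambiguity* a-hat, the
number of distinct effect values in the multiset (a-hat = 1 means the
effect is unambiguous).

Adjusted effects on the binary endpoint come from Firth-penalized logistic
regression of Y on X and the adjustment set, either as the log-odds
coefficient of X (default) or as a g-formula risk difference for a one-unit
increase of X from its mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .firth_glm import firth_logistic_fit
from .graph_core import MixedGraph
from scipy.special import expit

logger = logging.getLogger(__name__)

_THETA_TOL = 1e-8

SCALES = ("log-odds", "risk-difference")


@dataclass
class EffectMultiset:
    """Per-covariate multiset of adjusted effects with its lower bound.

    entries: (adjustment set, theta) per locally valid parent set;
    lower_bound = min |theta|; ambiguity = number of distinct theta values
    at tolerance 1e-8.
    """

    covariate: str
    entries: list[tuple[frozenset, float]]
    lower_bound: float
    ambiguity: int


def locally_valid_parent_sets(cpdag: MixedGraph, x: str) -> list[frozenset]:
    """Candidate parent sets of x extracted locally from the CPDAG.

    For each subset S of x's undirected neighbors, pa(x) ∪ S is locally
    valid iff orienting every s in S towards x creates no new collider at
    x, i.e. every s in S is adjacent to every other member of S and to
    every directed parent of x.  Returned in deterministic order (by size,
    then lexicographically).
    """
    if x not in cpdag.variables.names:
        raise ValueError(f"{x!r} not in graph")
    pa = sorted(cpdag.parents(x))
    sibs = sorted(cpdag.undirected_neighbors(x))
    out: list[frozenset] = []
    for size in range(len(sibs) + 1):
        for S in combinations(sibs, size):
            ok = True
            for s in S:
                for other in S:
                    if other != s and not cpdag.is_adjacent(s, other):
                        ok = False
                        break
                if not ok:
                    break
                for p in pa:
                    if not cpdag.is_adjacent(s, p):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                out.append(frozenset(pa) | frozenset(S))
    # orienting different sibling subsets can yield the same parent set
    seen: set[frozenset] = set()
    dedup = []
    for s in out:
        if s not in seen:
            seen.add(s)
            dedup.append(s)
    return dedup


def estimate_effect(
    data: pd.DataFrame,
    x: str,
    outcome: str,
    adjust,
    scale: str = "log-odds",
) -> float:
    """Adjusted effect of continuous x on the binary outcome.

    log-odds: Firth coefficient of x in outcome ~ 1 + x + adjust.
    risk-difference: g-formula standardization with the same fit — the mean
    over observed adjustment rows of p(x_bar + 1, row) - p(x_bar, row),
    x_bar the sample mean of x.
    """
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {SCALES}")
    adjust = sorted(set(adjust) - {x, outcome})
    y = data[outcome].to_numpy(dtype=float)
    xcol = data[x].to_numpy(dtype=float)
    z = data[adjust].to_numpy(dtype=float) if adjust else np.empty((len(y), 0))
    X = np.column_stack([np.ones(len(y)), xcol, z])
    fit = firth_logistic_fit(X, y)
    if scale == "log-odds":
        return float(fit.coefficients[1])
    b0, bx = fit.coefficients[0], fit.coefficients[1]
    bz = fit.coefficients[2:]
    xbar = xcol.mean()
    base = b0 + z @ bz
    return float(np.mean(expit(base + bx * (xbar + 1)) - expit(base + bx * xbar)))


def ida_multiset(
    cpdag: MixedGraph,
    data: pd.DataFrame,
    x: str,
    outcome: str,
    scale: str = "log-odds",
) -> EffectMultiset:
    """Effect multiset Theta_x of covariate x on the outcome.

    One entry per locally valid parent set (the outcome itself never
    enters an adjustment set); lower bound and ambiguity per the type
    invariants.
    """
    sets = locally_valid_parent_sets(cpdag, x)
    entries: list[tuple[frozenset, float]] = []
    for S in sets:
        adj = frozenset(S - {outcome})
        theta = estimate_effect(data, x, outcome, adj, scale=scale)
        entries.append((adj, theta))
    thetas = np.array([t for _, t in entries])
    lower = float(np.min(np.abs(thetas)))
    distinct = _count_distinct(thetas)
    return EffectMultiset(
        covariate=x, entries=entries, lower_bound=lower, ambiguity=distinct
    )


def _count_distinct(values: np.ndarray, tol: float = _THETA_TOL) -> int:
    vals = np.sort(np.asarray(values, dtype=float))
    if len(vals) == 0:
        raise ValueError("empty multiset")
    return int(1 + np.sum(np.diff(vals) > tol))


def rank_effects(bounds: dict[str, float]) -> list[str]:
    """Covariates sorted by lower bound, largest first; ties broken by
    name for determinism."""
    return sorted(bounds, key=lambda v: (-bounds[v], v))


def ida_all_covariates(
    cpdag: MixedGraph,
    data: pd.DataFrame,
    outcome: str,
    scale: str = "log-odds",
    covariates=None,
) -> dict[str, EffectMultiset]:
    """IDA multiset for every covariate (or the given subset)."""
    covs = list(covariates) if covariates is not None else [
        v for v in cpdag.variables.names if v != outcome
    ]
    return {
        x: ida_multiset(cpdag, data, x, outcome, scale=scale) for x in covs
    }
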