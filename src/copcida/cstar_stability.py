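"""CStaR: causal stability ranking with per-comparison error rate control.

Structure learning plus IDA is repeated on B random subsamples (drawn
without replacement).  In each run covariates are ranked by their IDA
lower bound; across runs the relative frequency Pi-hat of landing in the
top q defines the stable ranking, and for each covariate a bound on the
per-comparison error rate (PCER, a false-positive rate) is

    PCER_j = 1 / (2 Pi-hat_j - 1) * q^2 / p^2        (Pi-hat_j > 1/2),

infinite otherwise.  Biomarkers are selected at a PCER threshold (0.5% in
the melanoma application).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph_core import MixedGraph, TieredVariableSet
from .ida_effects import ida_all_covariates, rank_effects
from .structure_learning import LearnConfig, copc_stable, pc_stable

logger = logging.getLogger(__name__)


@dataclass
class StabilityRanking:
    """Per-covariate stability-selection summary over B subsample runs.

    table columns: covariate, pi_hat, pcer, median_effect, rank — sorted by
    pi_hat descending (ties by name).  ``graphs`` keeps the per-run CPDAGs
    so they can be aggregated into a summary graph downstream.
    """

    q: int
    B: int
    effective_B: int
    subsample_size: int
    table: pd.DataFrame
    graphs: list[MixedGraph] = field(default_factory=list)


def pcer(pi_hat: float, q: int, p: int) -> float:
    """Per-comparison error-rate bound q^2 / (p^2 (2 pi_hat - 1));
    +inf when pi_hat <= 1/2 (the bound is uninformative there)."""
    if not (0 <= pi_hat <= 1):
        raise ValueError("pi_hat must be in [0, 1]")
    if q > p:
        raise ValueError("q cannot exceed p")
    if pi_hat <= 0.5:
        return math.inf
    return (q * q) / (p * p * (2.0 * pi_hat - 1.0))


def default_q(p: int) -> int:
    """Default top-list size: 10% of the covariates, at least 1."""
    return max(1, math.ceil(0.1 * p))


def subsample_runs(
    data: pd.DataFrame,
    variables: TieredVariableSet,
    cfg: LearnConfig | None = None,
    B: int = 100,
    m: int | None = None,
    q: int | None = None,
    seed: int = 0,
    scale: str = "log-odds",
    keep_graphs: bool = True,
) -> StabilityRanking:
    """Run the learner + IDA over B seeded subsamples of size m.

    Each subsample is drawn without replacement (default m = n//2); the
    learner is COPC-stable when ``cfg.tiered`` (default) else PC-stable.
    A run that fails is logged and excluded; frequencies use the effective
    number of successful runs.
    """
    cfg = cfg or LearnConfig(tiered=True)
    n = len(data)
    outcome = variables.outcome
    if outcome is None:
        raise ValueError("stability selection needs an outcome variable")
    m = m if m is not None else n // 2
    if m > n:
        raise ValueError(f"subsample size {m} exceeds n={n}")
    covs = [v for v in variables.names if v != outcome]
    p = len(covs)
    q = q if q is not None else default_q(p)
    if q > p:
        raise ValueError("q cannot exceed the number of covariates")

    data = data[list(variables.names)]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B)
    top_counts = {v: 0 for v in covs}
    bounds_acc: dict[str, list[float]] = {v: [] for v in covs}
    graphs: list[MixedGraph] = []
    effective = 0
    for b in range(B):
        rng = np.random.default_rng(children[b])
        idx = rng.choice(n, size=m, replace=False)
        sub = data.iloc[np.sort(idx)].reset_index(drop=True)
        try:
            if cfg.tiered:
                cpdag = copc_stable(sub.to_numpy(float), variables, cfg)
            else:
                cpdag = pc_stable(sub.to_numpy(float), cfg, variables=variables)
            effects = ida_all_covariates(cpdag, sub, outcome, scale=scale)
        except Exception as exc:  # noqa: BLE001 - a failing run is excluded
            logger.warning("subsample run %d failed: %s", b, exc)
            continue
        effective += 1
        if keep_graphs:
            graphs.append(cpdag)
        bounds = {v: em.lower_bound for v, em in effects.items()}
        ranked = rank_effects(bounds)
        for v in ranked[:q]:
            top_counts[v] += 1
        for v in covs:
            bounds_acc[v].append(bounds[v])
    if effective == 0:
        raise RuntimeError("every subsample run failed")
    rows = []
    for v in covs:
        pi = top_counts[v] / effective
        rows.append(
            {
                "covariate": v,
                "pi_hat": pi,
                "pcer": pcer(pi, q, p),
                "median_effect": float(np.median(bounds_acc[v])),
            }
        )
    tab = pd.DataFrame(rows).sort_values(
        ["pi_hat", "covariate"], ascending=[False, True], kind="stable"
    )
    tab["rank"] = np.arange(1, len(tab) + 1)
    tab = tab.reset_index(drop=True)
    return StabilityRanking(
        q=q,
        B=B,
        effective_B=effective,
        subsample_size=m,
        table=tab,
        graphs=graphs,
    )


def select_biomarkers(
    ranking: StabilityRanking, threshold: float = 0.005
) -> list[str]:
    """Covariates whose PCER bound is at or below the threshold, sorted by
    PCER ascending then median effect descending."""
    tab = ranking.table
    sel = tab[tab["pcer"] <= threshold].sort_values(
        ["pcer", "median_effect", "covariate"],
        ascending=[True, False, True],
        kind="stable",
    )
    return sel["covariate"].tolist()
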