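"""Synthetic tiered-DAG benchmark: data generator and scenario runner.

The generator emulates panels of repeated biomarker measurements: p
biomarkers measured at each of several visits plus one binary endpoint in
the final tier.  A random tier-respecting weighted DAG drives linear
structural equations whose noise reproduces the autoregressive dependence
of repeated measures — for one biomarker the noise across visits is
multivariate normal with

    Sigma_st = rho^|s-t| * sigma^2        (mu = 0, sigma^2 = 1 by default),

independent across distinct biomarkers.  The endpoint follows a logistic
model on its parents with the intercept calibrated to ~50% prevalence.

``run_scenario`` replays the benchmark: per replicate both PC-stable and
COPC-stable are fit and compared with the true CPDAG via sensitivity,
specificity and SHD over adjacencies, and (optionally) the accuracy of the
IDA lower bounds via mean squared error against large-sample true effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .graph_core import (
    MixedGraph,
    TieredVariableSet,
    WeightedDAG,
    dag_to_cpdag,
    structure_metrics,
)
from .ida_effects import ida_all_covariates
from .structure_learning import LearnConfig, copc_stable, pc_stable

logger = logging.getLogger(__name__)

OUTCOME_NAME = "Y"


@dataclass(frozen=True)
class SimScenario:
    """One simulation condition.

    Defaults are the stated benchmark world: correlation rho = 0.6 (the
    middle of the studied 0.5-0.7 range), unit variance, alpha = 0.02,
    sparse random DAGs (edge probability 0.1, weights of magnitude 0.5-1.5
    with random sign, same-biomarker consecutive-visit chain edges always
    present) and 9 biomarkers per visit — the scale of the smallest
    application panel (36 covariates over 4 visits plus the endpoint).
    """

    p_per_visit: int = 9
    n_visits: int = 4
    n_obs: int = 1000
    rho: float = 0.6
    sigma2: float = 1.0
    alpha: float = 0.02
    edge_prob: float = 0.1
    weight_range: tuple[float, float] = (0.5, 1.5)
    n_replicates: int = 50
    seed: int = 0
    fixed_dag: bool = False
    scale: str = "log-odds"

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        for name in ("p_per_visit", "n_visits", "n_obs", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not (0 <= self.edge_prob <= 1):
            raise ValueError("edge_prob must be a proportion")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class SimReport:
    """Aggregated benchmark results.

    structure: per-method mean/sd/se of sensitivity, specificity, SHD.
    mse: per-covariate, per-method mean squared error of the IDA lower
    bound against the large-sample true effect (when computed).
    """

    scenario: SimScenario
    structure: pd.DataFrame
    mse: pd.DataFrame | None
    n_requested: int
    n_ok: int
    per_replicate: pd.DataFrame | None = None


def scenario_variables(scn: SimScenario) -> TieredVariableSet:
    """Variable set bm<i>@V<t> for t = 1..n_visits plus the outcome."""
    names = [
        f"bm{i}@V{t}"
        for t in range(1, scn.n_visits + 1)
        for i in range(1, scn.p_per_visit + 1)
    ]
    tiers = {v: int(v.rsplit("@V", 1)[1]) for v in names}
    names.append(OUTCOME_NAME)
    tiers[OUTCOME_NAME] = scn.n_visits + 1
    return TieredVariableSet.from_names(names, tier=tiers, outcome=OUTCOME_NAME)


def generate_tiered_dag(
    scn: SimScenario, rng: np.random.Generator | None = None
) -> WeightedDAG:
    """Random tier-respecting weighted DAG.

    Every ordered pair with tier(tail) <= tier(head) is a candidate
    (within-tier candidates run from the lower to the higher biomarker
    index, which keeps the graph acyclic by construction); candidates
    enter independently with ``edge_prob`` except same-biomarker
    consecutive-visit chain edges, which are always included.  Weights
    are uniform on ``weight_range`` in magnitude with random sign.
    """
    rng = rng if rng is not None else np.random.default_rng(scn.seed)
    variables = scenario_variables(scn)
    tier = variables.tier
    names = list(variables.names)
    g = MixedGraph(variables)
    weights: dict[tuple[str, str], float] = {}

    def bm_index(v: str) -> int:
        return int(v.split("@V", 1)[0][2:])

    def is_chain(a: str, b: str) -> bool:
        if OUTCOME_NAME in (a, b):
            return False
        return bm_index(a) == bm_index(b) and tier[b] - tier[a] == 1

    lo, hi = scn.weight_range
    for a in names:
        for b in names:
            if a == b:
                continue
            if tier[a] > tier[b]:
                continue
            if tier[a] == tier[b] and bm_index(a) >= bm_index(b):
                continue
            include = is_chain(a, b) or rng.random() < scn.edge_prob
            if include:
                w = rng.uniform(lo, hi) * (1.0 if rng.random() < 0.5 else -1.0)
                g.add_directed(a, b)
                weights[(a, b)] = w
    return WeightedDAG(graph=g, weight=weights)


def _noise_matrix(scn: SimScenario, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """AR(1) noise per biomarker series: columns V1..Vn_visits."""
    k = scn.n_visits
    lag = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
    sigma = (scn.rho ** lag) * scn.sigma2
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("autoregressive covariance not positive definite") from exc
    out: dict[str, np.ndarray] = {}
    for i in range(1, scn.p_per_visit + 1):
        z = rng.standard_normal((n, k))
        eps = z @ chol.T
        for t in range(1, k + 1):
            out[f"bm{i}@V{t}"] = eps[:, t - 1]
    return out


def simulate_dataset(
    dag: WeightedDAG,
    scn: SimScenario,
    rng: np.random.Generator | None = None,
    n_obs: int | None = None,
) -> pd.DataFrame:
    """Draw a dataset from the structural equations of ``dag``.

    Covariates: X_v = sum_{u in pa(v)} w_uv X_u + eps_v with the AR(1)
    noise above.  Outcome: Bernoulli(expit(c + sum w X_pa)) with c set to
    the negative empirical mean of the linear predictor, giving ~50%
    prevalence.
    """
    rng = rng if rng is not None else np.random.default_rng(scn.seed)
    n = n_obs if n_obs is not None else scn.n_obs
    variables = dag.graph.variables
    eps = _noise_matrix(scn, n, rng)
    cols: dict[str, np.ndarray] = {}
    for v in dag.topological_order():
        if v == OUTCOME_NAME:
            continue
        x = eps[v].copy()
        for u in sorted(dag.graph.parents(v)):
            x += dag.weight[(u, v)] * cols[u]
        cols[v] = x
    linpred = np.zeros(n)
    for u in sorted(dag.graph.parents(OUTCOME_NAME)):
        linpred += dag.weight[(u, OUTCOME_NAME)] * cols[u]
    intercept = -float(np.mean(linpred))
    prob = expit(intercept + linpred)
    cols[OUTCOME_NAME] = rng.binomial(1, prob).astype(float)
    frame = pd.DataFrame({v: cols[v] for v in variables.names})
    return frame


def true_effects(
    dag: WeightedDAG,
    scn: SimScenario,
    scale: str = "log-odds",
    n_mc: int = 200_000,
    seed: int = 12345,
) -> dict[str, float]:
    """Large-sample adjusted effect of each covariate on the outcome.

    One seeded Monte-Carlo draw of size n_mc from the generating model;
    per covariate the effect is estimated with adjustment on the true
    parents, on the same scale as the IDA estimates.
    """
    rng = np.random.default_rng(seed)
    frame = simulate_dataset(dag, scn, rng=rng, n_obs=n_mc)
    from .ida_effects import estimate_effect

    out: dict[str, float] = {}
    for x in dag.graph.variables.covariates:
        pa = frozenset(dag.graph.parents(x)) - {OUTCOME_NAME}
        out[x] = estimate_effect(frame, x, OUTCOME_NAME, pa, scale=scale)
    return out


def run_scenario(
    scn: SimScenario,
    compute_mse: bool = True,
    n_mc_true: int = 200_000,
) -> SimReport:
    """Replay the benchmark for one scenario.

    Per replicate: draw a DAG (or reuse one fixed DAG), simulate a
    dataset, learn with PC-stable and COPC-stable at ``scn.alpha``, and
    score both against the true CPDAG — dag_to_cpdag of the covariate
    sub-DAG plus the (chronologically forced) outcome edges.  Replicates
    that fail are logged, skipped and counted.
    """
    ss = np.random.SeedSequence(scn.seed)
    master = np.random.default_rng(ss)
    fixed = generate_tiered_dag(scn, master) if scn.fixed_dag else None
    fixed_truth = _true_cpdag(fixed) if fixed is not None else None
    fixed_fx = (
        true_effects(fixed, scn, scale=scn.scale, n_mc=n_mc_true,
                     seed=int(ss.generate_state(1)[0] % (2**31)))
        if (fixed is not None and compute_mse)
        else None
    )
    rows = []
    sq_err: dict[str, dict[str, list[float]]] = {"pc": {}, "copc": {}}
    n_ok = 0
    children = ss.spawn(scn.n_replicates)
    for rep in range(scn.n_replicates):
        rng = np.random.default_rng(children[rep])
        try:
            dag = fixed if fixed is not None else generate_tiered_dag(scn, rng)
            truth = fixed_truth if fixed is not None else _true_cpdag(dag)
            frame = simulate_dataset(dag, scn, rng=rng)
            variables = dag.graph.variables
            arr = frame.to_numpy(float)
            cfg_pc = LearnConfig(alpha=scn.alpha, tiered=False)
            cfg_co = LearnConfig(alpha=scn.alpha, tiered=True)
            est_pc = pc_stable(arr, cfg_pc, variables=variables)
            est_co = copc_stable(arr, variables, cfg_co)
            met_pc = structure_metrics(est_pc, truth, variables)
            met_co = structure_metrics(est_co, truth, variables)
            if compute_mse:
                fx = fixed_fx if fixed_fx is not None else true_effects(
                    dag, scn, scale=scn.scale, n_mc=n_mc_true,
                    seed=int(children[rep].generate_state(1)[0] % (2**31)),
                )
                for method, est in (("pc", est_pc), ("copc", est_co)):
                    effects = ida_all_covariates(
                        est, frame, OUTCOME_NAME, scale=scn.scale
                    )
                    for v, em in effects.items():
                        sq_err[method].setdefault(v, []).append(
                            (em.lower_bound - abs(fx[v])) ** 2
                        )
        except Exception as exc:  # noqa: BLE001 - replicate skipped
            logger.warning("replicate %d failed: %s", rep, exc)
            continue
        n_ok += 1
        for method, met in (("pc", met_pc), ("copc", met_co)):
            rows.append(
                {
                    "replicate": rep,
                    "method": method,
                    "sensitivity": met.sensitivity,
                    "specificity": met.specificity,
                    "shd": met.shd,
                    "n_directed": met.n_directed,
                    "n_undirected": met.n_undirected,
                    "n_nonchronological": met.n_nonchronological,
                }
            )
    if n_ok == 0:
        raise RuntimeError("every replicate failed")
    raw = pd.DataFrame(rows)
    metrics = ["sensitivity", "specificity", "shd", "n_nonchronological"]
    agg = raw.groupby("method")[metrics].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    for m in metrics:
        agg[f"{m}_se"] = agg[f"{m}_std"] / np.sqrt(n_ok)
    agg = agg.reset_index()
    mse_df = None
    if compute_mse:
        mse_rows = []
        for method in ("pc", "copc"):
            for v, errs in sorted(sq_err[method].items()):
                mse_rows.append(
                    {"method": method, "covariate": v, "mse": float(np.mean(errs))}
                )
        mse_df = pd.DataFrame(mse_rows)
    return SimReport(
        scenario=scn,
        structure=agg,
        mse=mse_df,
        n_requested=scn.n_replicates,
        n_ok=n_ok,
        per_replicate=raw,
    )


def _true_cpdag(dag: WeightedDAG) -> MixedGraph:
    """True comparison graph: CPDAG of the covariate sub-DAG, with the
    outcome edges appended as directed (the endpoint is measured last, so
    its edges are chronologically identified)."""
    variables = dag.graph.variables
    cov_vars = TieredVariableSet.from_names(
        variables.covariates,
        tier={v: variables.tier[v] for v in variables.covariates},
    )
    sub = MixedGraph(cov_vars)
    for a, b, _ in dag.graph.edges():
        if OUTCOME_NAME not in (a, b):
            sub.add_directed(a, b)
    cp_cov = dag_to_cpdag(sub)
    out = MixedGraph(variables)
    for a, b, mark in cp_cov.edges():
        if mark == "directed":
            out.add_directed(a, b)
        else:
            out.add_undirected(a, b)
    for u in sorted(dag.graph.parents(OUTCOME_NAME)):
        out.add_directed(u, OUTCOME_NAME)
    return out
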