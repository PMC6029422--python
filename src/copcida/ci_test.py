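"""Gaussian conditional-independence testing.

Both PC variants decide edge removal with the classical partial-correlation
test: under joint normality of the covariates, X_i ⟂ X_j | S iff the
partial correlation ρ_{ij·S} vanishes.  The sample partial correlation is
mapped through Fisher's z transform and compared with a standard normal at
two-sided level α.

The binary endpoint is, by default, included in the testing as a 0/1
numeric column — a pragmatic Gaussian approximation.  A likelihood-ratio
test from a logistic fit can be substituted for pairs involving the
outcome (``outcome_test="logistic-lrt"``).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class CITestError(ValueError):
    """Invalid input to a conditional-independence test."""


class SingularCorrelationError(CITestError):
    """The correlation submatrix over a conditioning set is singular —
    usually a collinearity signal among the conditioning variables."""


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one conditional-independence test at level alpha."""

    pair: frozenset
    cond_set: frozenset
    partial_corr: float
    statistic: float
    p_value: float
    independent: bool


def partial_correlation(corr: np.ndarray, i: int, j: int, S) -> float:
    """Partial correlation of variables i and j given the index set S.

    Computed from the inverse of the (i, j, S) submatrix of the
    correlation matrix: ρ_{ij·S} = -P_ij / sqrt(P_ii P_jj) with P the
    precision of the submatrix.
    """
    S = tuple(S)
    if i == j:
        raise CITestError("i and j must differ")
    if i in S or j in S:
        raise CITestError("conditioning set must not contain i or j")
    if not S:
        return float(corr[i, j])
    if len(S) == 1:
        # first-order closed form avoids a matrix inversion
        k = S[0]
        rij, rik, rjk = corr[i, j], corr[i, k], corr[j, k]
        denom = (1.0 - rik * rik) * (1.0 - rjk * rjk)
        if denom <= 0:
            raise SingularCorrelationError(
                f"singular correlation submatrix for pair ({i}, {j}) given {S}"
            )
        r = (rij - rik * rjk) / math.sqrt(denom)
        return float(min(1.0, max(-1.0, r)))
    idx = np.array((i, j) + S)
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError as exc:
        raise SingularCorrelationError(
            f"singular correlation submatrix for pair ({i}, {j}) given {S}"
        ) from exc
    denom = prec[0, 0] * prec[1, 1]
    if not np.isfinite(prec).all() or denom <= 0:
        raise SingularCorrelationError(
            f"degenerate precision matrix for pair ({i}, {j}) given {S}"
        )
    r = -prec[0, 1] / math.sqrt(denom)
    return float(min(1.0, max(-1.0, r)))


def fisher_z_test(
    r: float, n: int, s_size: int, alpha: float
) -> tuple[float, float, bool]:
    """Fisher z test of a (partial) correlation.

    Returns ``(statistic, p_value, independent)`` where
    statistic = sqrt(n - s_size - 3) * |arctanh(r)| and the p-value is the
    two-sided standard-normal tail.  ``independent`` iff p > alpha.
    """
    dof = n - s_size - 3
    if dof < 1:
        raise CITestError(
            f"sample size {n} too small for conditioning-set size {s_size}"
        )
    if abs(r) > 1:
        raise CITestError(f"correlation {r} outside [-1, 1]")
    if abs(r) >= 1.0:
        warnings.warn("|partial correlation| = 1; declaring dependence (p = 0)")
        return math.inf, 0.0, False
    z = math.atanh(r)
    stat = math.sqrt(dof) * abs(z)
    # two-sided standard-normal tail, 2*(1 - Phi(stat)) = erfc(stat/sqrt(2))
    p = math.erfc(stat / math.sqrt(2.0))
    return stat, float(p), bool(p > alpha)


class GaussianCITester:
    """Fisher-z tester bound to one dataset.

    The correlation matrix is computed once per dataset (or per subsample)
    and reused for every test — this makes runs deterministic and cheap.
    ``n_tests`` counts the tests actually performed.
    """

    def __init__(self, data: np.ndarray, names, alpha: float):
        data = np.asarray(data, dtype=float)
        if data.ndim != 2:
            raise CITestError("data must be an n x p matrix")
        if not np.isfinite(data).all():
            raise CITestError(
                "data contains missing or non-finite cells; impute upstream "
                "(e.g. MICE) before structure learning"
            )
        if not (0 < alpha < 1):
            raise CITestError("alpha must be in (0, 1)")
        self.names = list(names)
        if len(self.names) != data.shape[1]:
            raise CITestError("names do not match the number of columns")
        self._index = {v: k for k, v in enumerate(self.names)}
        self.n = data.shape[0]
        self.alpha = alpha
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(data, rowvar=False)
        corr = np.atleast_2d(corr)
        if not np.isfinite(corr).all():
            bad = [self.names[k] for k in np.where(~np.isfinite(np.diag(corr)))[0]]
            raise CITestError(f"constant columns yield undefined correlations: {bad}")
        self.corr = corr
        self.n_tests = 0

    @property
    def max_cond_size(self) -> int:
        """Largest conditioning-set size with positive degrees of freedom."""
        return self.n - 4

    def test(self, a: str, b: str, S) -> CITestResult:
        S = tuple(S)
        i, j = self._index[a], self._index[b]
        idx = tuple(self._index[s] for s in S)
        r = partial_correlation(self.corr, i, j, idx)
        stat, p, indep = fisher_z_test(r, self.n, len(S), self.alpha)
        self.n_tests += 1
        return CITestResult(
            pair=frozenset((a, b)),
            cond_set=frozenset(S),
            partial_corr=r,
            statistic=stat,
            p_value=p,
            independent=indep,
        )


class LogisticOutcomeCITester(GaussianCITester):
    """Gaussian tester that swaps in a logistic likelihood-ratio test for
    pairs involving the binary outcome.

    For the pair (X, Y) given S the statistic is 2·(ll(Y ~ S + X) - ll(Y ~ S)),
    referred to a chi-square with 1 degree of freedom.
    """

    def __init__(self, data: np.ndarray, names, alpha: float, outcome: str):
        super().__init__(data, names, alpha)
        if outcome not in self._index:
            raise CITestError(f"outcome {outcome!r} not among columns")
        self.outcome = outcome
        self._data = np.asarray(data, dtype=float)
        y = self._data[:, self._index[outcome]]
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise CITestError("outcome column must be binary 0/1")

    def test(self, a: str, b: str, S) -> CITestResult:
        if self.outcome not in (a, b):
            return super().test(a, b, S)
        from .firth_glm import logistic_loglik_fit

        x_name = a if b == self.outcome else b
        S = tuple(S)
        y = self._data[:, self._index[self.outcome]]
        zcols = [self._index[s] for s in S]
        z = self._data[:, zcols]
        x = self._data[:, [self._index[x_name]]]
        n = len(y)
        ones = np.ones((n, 1))
        ll_null = logistic_loglik_fit(np.hstack([ones, z]), y)
        ll_full = logistic_loglik_fit(np.hstack([ones, z, x]), y)
        lr = max(0.0, 2.0 * (ll_full - ll_null))
        p = float(stats.chi2.sf(lr, df=1))
        self.n_tests += 1
        return CITestResult(
            pair=frozenset((a, b)),
            cond_set=frozenset(S),
            partial_corr=math.nan,
            statistic=lr,
            p_value=p,
            independent=bool(p > self.alpha),
        )


class DSeparationOracle:
    """Oracle tester answering with d-separation in a known DAG.

    Used in place of data-driven tests to check algorithm consistency:
    p-value is 1 when the pair is d-separated given S, 0 otherwise.
    """

    def __init__(self, dag, alpha: float = 0.05):
        # `dag` is a fully directed MixedGraph
        self._g = dag.directed_view()
        self.names = list(dag.variables.names)
        self.alpha = alpha
        self.n_tests = 0
        self.max_cond_size = None

    def test(self, a: str, b: str, S) -> CITestResult:
        self.n_tests += 1
        sep = nx.is_d_separator(self._g, {a}, {b}, set(S))
        return CITestResult(
            pair=frozenset((a, b)),
            cond_set=frozenset(S),
            partial_corr=0.0 if sep else 1.0,
            statistic=0.0 if sep else math.inf,
            p_value=1.0 if sep else 0.0,
            independent=sep,
        )
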