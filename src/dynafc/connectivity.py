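"""Static and dynamic functional connectivity.

Static FC (sFC) is the Fisher z-transformed Pearson correlation between two
node timeseries.  Dynamic FC (dFC) summarizes an edge's moment-to-moment
correlation path: each node series is fitted with a univariate GARCH(1,1)
model by Gaussian quasi-maximum likelihood, the standardized residuals of a
node pair are passed to a bivariate DCC(1,1) stage-2 fit, and the edge's dFC
value is the sample variance of the fitted conditional-correlation path
rho_t.  High dFC therefore means an edge whose coupling fluctuates strongly
over the scan, independent of its average strength.

Model recursions (t = 2..T):

    GARCH(1,1):  sigma2_t = omega + alpha * eps_{t-1}^2 + beta * sigma2_{t-1}
    DCC(1,1):    Q_t = (1 - a - b) * S + a * z_{t-1} z_{t-1}' + b * Q_{t-1}
                 rho_t = Q_t[0,1] / sqrt(Q_t[0,0] * Q_t[1,1])

with sigma2_1 initialized at the sample variance and Q_1 = S, the sample
correlation matrix of the standardized residuals.  Both stages maximize the
Gaussian quasi-likelihood under the stationarity constraints alpha + beta < 1
and a + b < 1, by constrained local search from a small set of fixed starting
points (fully deterministic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import lfilter

__all__ = [
    "GarchFit",
    "DccFit",
    "ConnectivityMatrix",
    "static_fc",
    "garch11_fit",
    "dcc_fit_edge",
    "dynamic_fc",
    "edge_vectorize",
    "edge_devectorize",
    "edge_index",
    "n_edges",
]

_STATIONARITY_SLACK = 1e-6
_R_CAP = 0.999999
_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GarchFit:
    """Result of a univariate GARCH(1,1) quasi-ML fit."""

    omega: float
    alpha: float
    beta: float
    sigma2: np.ndarray          # conditional variances, length T
    std_resid: np.ndarray       # eps_t / sigma_t
    loglik: float
    converged: bool
    mean: float = 0.0           # removed before fitting

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.omega, self.alpha, self.beta)


@dataclass
class DccFit:
    """Result of a bivariate DCC(1,1) stage-2 quasi-ML fit."""

    a: float
    b: float
    s_bar: float                # unconditional residual correlation
    rho: np.ndarray             # conditional correlation path, length T
    loglik: float
    converged: bool
    degenerate: bool = False    # |s_bar| at cap: constant path, variance 0

    @property
    def dfc_variance(self) -> float:
        if self.degenerate:
            return 0.0
        return float(np.var(self.rho, ddof=1))


@dataclass
class ConnectivityMatrix:
    """N x N symmetric edge summary with a masked diagonal.

    ``kind`` is ``"sfc_z"`` (Fisher z of Pearson r) or ``"dfc_var"``
    (variance of the DCC correlation path).
    """

    values: np.ndarray
    kind: str
    node_labels: list[str] = field(default_factory=list)
    scan_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and np.nanmax(np.abs(v - v.T)) > 1e-12:
            raise ValueError("connectivity matrix must be symmetric")
        if self.kind not in ("sfc_z", "dfc_var"):
            raise ValueError(f"unknown connectivity kind {self.kind!r}")
        np.fill_diagonal(v, np.nan)
        self.values = v
        if not self.node_labels:
            self.node_labels = [f"n{i}" for i in range(v.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_vector(self) -> np.ndarray:
        return edge_vectorize(self.values)


# ---------------------------------------------------------------------------
# edge vectorization
# ---------------------------------------------------------------------------

def n_edges(n_nodes: int) -> int:
    """Number of unordered node pairs: N(N-1)/2 (89 nodes -> 3916)."""
    return n_nodes * (n_nodes - 1) // 2


def edge_vectorize(matrix: np.ndarray) -> np.ndarray:
    """Upper triangle in canonical row-major order (0,1),(0,2),...,(1,2),..."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("edge_vectorize requires a square matrix")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def edge_devectorize(vector: np.ndarray, n_nodes: int) -> np.ndarray:
    vec = np.asarray(vector, dtype=float)
    if vec.size != n_edges(n_nodes):
        raise ValueError(
            f"vector length {vec.size} does not match {n_nodes} nodes "
            f"({n_edges(n_nodes)} edges expected)"
        )
    out = np.full((n_nodes, n_nodes), np.nan)
    iu = np.triu_indices(n_nodes, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def edge_index(i: int, j: int, n_nodes: int) -> int:
    """Position of edge (i, j) in the canonical vectorization."""
    if i == j:
        raise ValueError("diagonal entries are not edges")
    if not (0 <= i < n_nodes and 0 <= j < n_nodes):
        raise ValueError("node index out of range")
    if i > j:
        i, j = j, i
    return i * (2 * n_nodes - i - 1) // 2 + (j - i - 1)


def edge_nodes(position: int, n_nodes: int) -> tuple[int, int]:
    """Inverse of :func:`edge_index`."""
    iu = np.triu_indices(n_nodes, k=1)
    return int(iu[0][position]), int(iu[1][position])


# ---------------------------------------------------------------------------
# static FC
# ---------------------------------------------------------------------------

def static_fc(data: np.ndarray, node_labels: list[str] | None = None,
              scan_id: str = "") -> ConnectivityMatrix:
    """Fisher z-transformed Pearson correlation matrix of a T x N array.

    Perfect correlations (duplicated nodes) are capped at atanh(0.999999)
    with a warning rather than returned as inf.
    """
    y = np.asarray(getattr(data, "values", data), dtype=float)
    if node_labels is None:
        node_labels = list(getattr(data, "node_labels", []) or [])
    if y.ndim != 2:
        raise ValueError("expected a T x N array")
    t, n = y.shape
    if t < 3:
        raise ValueError("static FC needs at least 3 timepoints")
    sd = y.std(axis=0)
    if np.any(sd == 0):
        bad = [node_labels[k] if node_labels else str(k)
               for k in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant node timeseries: {bad}")
    r = np.corrcoef(y, rowvar=False)
    off = ~np.eye(n, dtype=bool)
    if np.any(np.abs(r[off]) >= _R_CAP):
        warnings.warn("|r| = 1 edges capped at atanh(0.999999)", stacklevel=2)
    r = np.clip(r, -_R_CAP, _R_CAP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # symmetrize away float noise
    return ConnectivityMatrix(z, kind="sfc_z", node_labels=node_labels,
                              scan_id=scan_id)


# ---------------------------------------------------------------------------
# GARCH(1,1) stage
# ---------------------------------------------------------------------------

def _garch_sigma2(eps: np.ndarray, omega: float, alpha: float,
                  beta: float) -> np.ndarray:
    """Conditional-variance recursion, sigma2_1 = sample variance of eps.

    Implemented as a first-order IIR filter: sigma2_t - beta*sigma2_{t-1}
    = omega + alpha*eps_{t-1}^2, which scipy.signal.lfilter evaluates exactly.
    """
    t = eps.size
    sigma2 = np.empty(t)
    sigma2[0] = np.var(eps)
    x = omega + alpha * eps[:-1] ** 2
    sigma2[1:], _ = lfilter([1.0], [1.0, -beta], x, zi=[beta * sigma2[0]])
    return sigma2

_PARSIMONY_NLL_BAND = 2.0  # ~AIC penalty for the two persistence parameters


def _select_candidate(candidates):
    """Best-likelihood candidate with a parsimony tie-break.

    When the likelihood is flat in the persistence direction (white noise
    leaves beta, and constant correlation leaves b, unidentified), all
    near-optimal candidates sit within a couple of log-likelihood units of
    each other; among those we return the one with the smallest persistence
    sum, which collapses unidentified fits onto the constant-variance /
    constant-correlation solution.
    """
    best_nll = min(c[0] for c in candidates)
    near = [c for c in candidates if c[0] <= best_nll + _PARSIMONY_NLL_BAND]
    return min(near, key=lambda c: (float(np.sum(c[1][-2:])), c[0]))


def _garch_nll(theta: np.ndarray, eps: np.ndarray) -> float:
    omega, alpha, beta = theta
    if omega <= 0 or alpha < 0 or beta < 0 or alpha + beta >= 1.0:
        return np.inf
    sigma2 = _garch_sigma2(eps, omega, alpha, beta)
    if np.any(sigma2 <= 0) or not np.all(np.isfinite(sigma2)):
        return np.inf
    return 0.5 * float(np.sum(_LOG_2PI + np.log(sigma2) + eps ** 2 / sigma2))


def garch11_fit(series: np.ndarray) -> GarchFit:
    """Gaussian quasi-ML GARCH(1,1) fit of a demeaned series.

    Constrained local search (SLSQP) from three fixed starting points; the
    best of all converged candidates and the constant-variance fallback is
    returned, so the reported likelihood never falls below the fallback's.
    Non-convergence from every start degrades to the constant-variance
    solution with ``converged=False`` instead of raising.
    """
    y = np.asarray(series, dtype=float).ravel()
    if y.size < 100:
        raise ValueError("GARCH fit needs at least 100 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant series cannot be fitted")
    mean = float(np.mean(y))
    eps = y - mean
    var = float(np.var(eps))

    starts = [(0.05, 0.90), (0.10, 0.80), (0.20, 0.50)]
    constraints = [{"type": "ineq",
                    "fun": lambda th: 1.0 - _STATIONARITY_SLACK - th[1] - th[2]}]
    bounds = [(1e-12, None), (0.0, 1.0), (0.0, 1.0)]

    candidates: list[tuple[float, np.ndarray, bool]] = []
    for alpha0, beta0 in starts:
        theta0 = np.array([var * (1.0 - alpha0 - beta0), alpha0, beta0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = minimize(_garch_nll, theta0, args=(eps,), method="SLSQP",
                               bounds=bounds, constraints=constraints,
                               options={"maxiter": 200, "ftol": 1e-10})
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if np.isfinite(res.fun):
            candidates.append((float(res.fun), res.x, bool(res.success)))

    # constant-variance fallback is always a candidate
    fallback = np.array([var, 0.0, 0.0])
    candidates.append((_garch_nll(fallback, eps), fallback, False))

    nll, theta, ok = _select_candidate(candidates)
    converged = ok or any(c[2] and abs(c[0] - nll) < 1e-8 for c in candidates)
    omega, alpha, beta = (float(v) for v in theta)
    sigma2 = _garch_sigma2(eps, omega, alpha, beta)
    std_resid = eps / np.sqrt(sigma2)
    return GarchFit(omega=omega, alpha=alpha, beta=beta, sigma2=sigma2,
                    std_resid=std_resid, loglik=-nll, converged=converged,
                    mean=mean)


# ---------------------------------------------------------------------------
# DCC(1,1) stage
# ---------------------------------------------------------------------------

def _dcc_rho(z1: np.ndarray, z2: np.ndarray, a: float, b: float,
             s_bar: float) -> np.ndarray:
    """Conditional-correlation path of the DCC recursion with Q_1 = S.

    The three distinct entries of Q_t each follow a scalar AR(1)-type
    recursion driven by the lagged residual products, evaluated with lfilter.
    """
    t = z1.size
    c = 1.0 - a - b

    def _filt(drive: np.ndarray, q1: float, intercept: float) -> np.ndarray:
        out = np.empty(t)
        out[0] = q1
        x = intercept + a * drive[:-1]
        out[1:], _ = lfilter([1.0], [1.0, -b], x, zi=[b * q1])
        return out

    q11 = _filt(z1 * z1, 1.0, c * 1.0)
    q22 = _filt(z2 * z2, 1.0, c * 1.0)
    q12 = _filt(z1 * z2, s_bar, c * s_bar)
    rho = q12 / np.sqrt(q11 * q22)
    return np.clip(rho, -_R_CAP, _R_CAP)


def _dcc_nll(theta: np.ndarray, z1: np.ndarray, z2: np.ndarray,
             s_bar: float) -> float:
    a, b = theta
    if a < 0 or b < 0 or a + b >= 1.0:
        return np.inf
    rho = _dcc_rho(z1, z2, a, b, s_bar)
    one_m = 1.0 - rho ** 2
    ll_terms = (np.log(one_m)
                + (z1 ** 2 + z2 ** 2 - 2.0 * rho * z1 * z2) / one_m
                - z1 ** 2 - z2 ** 2)
    val = 0.5 * float(np.sum(ll_terms))
    return val if np.isfinite(val) else np.inf


def dcc_fit_edge(z1: np.ndarray, z2: np.ndarray) -> DccFit:
    """Stage-2 DCC(1,1) fit on a pair of standardized residual series.

    Near-identical residuals (|S| at the correlation cap) are flagged as a
    degenerate edge: the correlation path is held constant at S and the dFC
    variance is 0, so duplicated nodes cannot crash a full-connectome run.
    """
    z1 = np.asarray(z1, dtype=float).ravel()
    z2 = np.asarray(z2, dtype=float).ravel()
    if z1.size != z2.size:
        raise ValueError("residual series lengths differ")
    if z1.size < 100:
        raise ValueError("DCC fit needs at least 100 observations")
    s_bar = float(np.corrcoef(z1, z2)[0, 1])
    if abs(s_bar) >= _R_CAP:
        s_bar = float(np.clip(s_bar, -_R_CAP, _R_CAP))
        rho = np.full(z1.size, s_bar)
        return DccFit(a=0.0, b=0.0, s_bar=s_bar, rho=rho,
                      loglik=-_dcc_nll(np.zeros(2), z1, z2, s_bar),
                      converged=True, degenerate=True)

    starts = [(0.05, 0.90), (0.02, 0.95), (0.10, 0.70)]
    constraints = [{"type": "ineq",
                    "fun": lambda th: 1.0 - _STATIONARITY_SLACK - th[0] - th[1]}]
    bounds = [(0.0, 1.0), (0.0, 1.0)]
    candidates: list[tuple[float, np.ndarray, bool]] = []
    for a0, b0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = minimize(_dcc_nll, np.array([a0, b0]), args=(z1, z2, s_bar),
                               method="SLSQP", bounds=bounds,
                               constraints=constraints,
                               options={"maxiter": 200, "ftol": 1e-10})
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if np.isfinite(res.fun):
            candidates.append((float(res.fun), res.x, bool(res.success)))
    candidates.append((_dcc_nll(np.zeros(2), z1, z2, s_bar),
                       np.zeros(2), False))

    nll, theta, ok = _select_candidate(candidates)
    converged = ok or any(c[2] and abs(c[0] - nll) < 1e-8 for c in candidates)
    a, b = (float(v) for v in theta)
    rho = _dcc_rho(z1, z2, a, b, s_bar)
    return DccFit(a=a, b=b, s_bar=s_bar, rho=rho, loglik=-nll,
                  converged=converged)


# ---------------------------------------------------------------------------
# dynamic FC
# ---------------------------------------------------------------------------

def dynamic_fc(data: np.ndarray, node_labels: list[str] | None = None,
               scan_id: str = "") -> tuple[ConnectivityMatrix, pd.DataFrame]:
    """Per-edge dFC matrix: variance of each edge's DCC correlation path.

    The GARCH stage is fitted once per node and its standardized residuals
    reused across all of that node's edges.  Returns the matrix and a QC
    table recording convergence/degeneracy per edge.
    """
    y = np.asarray(getattr(data, "values", data), dtype=float)
    if node_labels is None:
        node_labels = list(getattr(data, "node_labels", []) or [])
    t, n = y.shape
    labels = node_labels or [f"n{i}" for i in range(n)]
    fits = [garch11_fit(y[:, k]) for k in range(n)]
    z = np.column_stack([f.std_resid for f in fits])

    values = np.zeros((n, n))
    qc_rows = []
    for i in range(n):
        for j in range(i + 1, n):
            fit = dcc_fit_edge(z[:, i], z[:, j])
            values[i, j] = values[j, i] = fit.dfc_variance
            qc_rows.append({
                "node_i": labels[i], "node_j": labels[j],
                "a": fit.a, "b": fit.b, "s_bar": fit.s_bar,
                "converged": fit.converged, "degenerate": fit.degenerate,
            })
    qc = pd.DataFrame(qc_rows)
    return (ConnectivityMatrix(values, kind="dfc_var", node_labels=labels,
                               scan_id=scan_id), qc)
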