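"""Model definition: spatial grid topology, parameters and likelihoods.

Latent community states ``mu_s`` sit on a K x 1 chain or a K x 2 grid and
form a linear-Gaussian Bayesian network.  Along the chain each state is the
previous state plus a shared longitudinal step ``Delta`` with deviation
covariance ``Q``; on a grid the second row additionally shifts by a radial
step ``Delta_perp`` orthogonal to ``Delta``, and interior second-row states
are centred on the average of their two neighbours plus the average step.
Observations from a state are Gaussian around its mean, and each barcode's
state is categorical with weights ``pi``.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

__all__ = [
    "GridSpec",
    "DirectionalGmmParams",
    "prior_log_density",
    "observation_log_density",
    "log_observation_matrix",
    "log_mixture_density",
    "complete_log_likelihood",
    "canonicalize",
]


@dataclass(frozen=True)
class GridSpec:
    """Latent cluster index set: ``K`` columns by ``rows`` (1 or 2) rows.

    Clusters are enumerated row-major: row 1 columns 1..K, then row 2.
    ``labels[i]`` is ``col`` for 1-D models and ``(row, col)`` for 2-D.
    """

    K: int
    rows: int = 1

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.rows not in (1, 2):
            raise ValueError("rows must be 1 or 2")

    @property
    def n_clusters(self) -> int:
        return self.K * self.rows

    @property
    def labels(self) -> list:
        if self.rows == 1:
            return list(range(1, self.K + 1))
        return [(r, i) for r in (1, 2) for i in range(1, self.K + 1)]

    def index(self, label) -> int:
        """Row-major index of a cluster label."""
        if self.rows == 1:
            return int(label) - 1
        r, i = label
        return (r - 1) * self.K + (i - 1)

    def edges(self) -> list:
        """Non-root factors of the spatial prior.

        Each entry is ``(child, [(coef, parent), ...], (a, b))`` meaning the
        child mean is Gaussian around ``sum coef * mu_parent + a*Delta +
        b*Delta_perp`` with covariance Q.  The root (index 0) has no entry;
        it is Gaussian around the hyperprior mean ``mu0`` with covariance Q0.
        """
        out = []
        if self.rows == 1:
            for i in range(1, self.K):
                out.append((i, [(1.0, i - 1)], (1.0, 0.0)))
            return out
        idx = self.index
        for i in range(2, self.K + 1):
            out.append((idx((1, i)), [(1.0, idx((1, i - 1)))], (1.0, 0.0)))
        out.append((idx((2, 1)), [(1.0, idx((1, 1)))], (0.0, 1.0)))
        for i in range(2, self.K + 1):
            out.append(
                (
                    idx((2, i)),
                    [(0.5, idx((1, i))), (0.5, idx((2, i - 1)))],
                    (0.5, 0.5),
                )
            )
        return out

    @property
    def name(self) -> str:
        return f"{self.K}x{self.rows}"

    @classmethod
    def from_name(cls, name: str) -> "GridSpec":
        k, r = name.lower().split("x")
        return cls(int(k), int(r))


def _check_spd(M: np.ndarray, what: str):
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError(f"{what} is not symmetric")
    try:
        return cho_factor(M, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{what} is not positive definite") from exc


@dataclass
class DirectionalGmmParams:
    """All model parameters plus the cluster means.

    ``mu`` are the |S| community states (ILR space), ``Sigma`` their full
    observation covariances, ``pi`` the mixture weights, ``Delta`` /
    ``Delta_perp`` the longitudinal and radial steps (``Delta_perp`` is None
    for 1-D grids and orthogonal to ``Delta`` otherwise), ``Q`` the spatial
    deviation covariance and ``mu0``/``Q0`` the root hyperprior.
    """

    mu: np.ndarray
    Sigma: np.ndarray
    pi: np.ndarray
    Delta: np.ndarray
    Q: np.ndarray
    Q0: np.ndarray
    mu0: np.ndarray
    Delta_perp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.Delta = np.asarray(self.Delta, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.Q0 = np.asarray(self.Q0, dtype=float)
        self.mu0 = np.asarray(self.mu0, dtype=float)
        if self.Delta_perp is not None:
            self.Delta_perp = np.asarray(self.Delta_perp, dtype=float)

    @property
    def n_clusters(self) -> int:
        return self.mu.shape[0]

    @property
    def d(self) -> int:
        return self.mu.shape[1]

    def validate(self) -> None:
        if self.pi.min() < -1e-12 or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a probability vector")
        for s in range(self.n_clusters):
            _check_spd(self.Sigma[s], f"Sigma[{s}]")
        _check_spd(self.Q, "Q")
        _check_spd(self.Q0, "Q0")
        if self.Delta_perp is not None:
            dp = float(abs(self.Delta @ self.Delta_perp))
            bound = 1e-8 * np.linalg.norm(self.Delta) * np.linalg.norm(self.Delta_perp)
            if dp > max(bound, 1e-12):
                raise ValueError("Delta_perp is not orthogonal to Delta")

    def to_dict(self) -> dict:
        out = {
            "mu": self.mu.tolist(),
            "Sigma": self.Sigma.tolist(),
            "pi": self.pi.tolist(),
            "Delta": self.Delta.tolist(),
            "Q": self.Q.tolist(),
            "Q0": self.Q0.tolist(),
            "mu0": self.mu0.tolist(),
            "Delta_perp": None if self.Delta_perp is None else self.Delta_perp.tolist(),
        }
        return out

    @classmethod
    def from_dict(cls, doc: dict) -> "DirectionalGmmParams":
        dp = doc.get("Delta_perp")
        return cls(
            mu=np.array(doc["mu"], dtype=float),
            Sigma=np.array(doc["Sigma"], dtype=float),
            pi=np.array(doc["pi"], dtype=float),
            Delta=np.array(doc["Delta"], dtype=float),
            Q=np.array(doc["Q"], dtype=float),
            Q0=np.array(doc["Q0"], dtype=float),
            mu0=np.array(doc["mu0"], dtype=float),
            Delta_perp=None if dp is None else np.array(dp, dtype=float),
        )


def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, chol, logdet: float) -> float:
    diff = np.atleast_2d(x - mean)
    sol = cho_solve(chol, diff.T)
    quad = np.einsum("ij,ji->i", diff, sol)
    d = diff.shape[1]
    val = -0.5 * (d * np.log(2.0 * np.pi) + logdet + quad)
    return val if val.size > 1 else float(val[0])


def _chol_logdet(M: np.ndarray, what: str):
    chol = _check_spd(M, what)
    logdet = 2.0 * np.log(np.diag(chol[0])).sum()
    return chol, logdet


def prior_log_density(mu, grid: GridSpec, params: DirectionalGmmParams) -> float:
    """Log density of the spatial prior, sum over root and edge factors."""
    mu = np.asarray(mu, dtype=float)
    if (params.Delta_perp is not None) != (grid.rows == 2):
        raise ValueError("Delta_perp must be present exactly for 2-row grids")
    chol0, logdet0 = _chol_logdet(params.Q0, "Q0")
    total = _mvn_logpdf(mu[0], params.mu0, chol0, logdet0)
    edges = grid.edges()
    if edges:
        cholq, logdetq = _chol_logdet(params.Q, "Q")
        dperp = params.Delta_perp if params.Delta_perp is not None else 0.0
        for child, parents, (a, b) in edges:
            center = a * params.Delta + b * dperp
            for coef, p in parents:
                center = center + coef * mu[p]
            total += _mvn_logpdf(mu[child], center, cholq, logdetq)
    return float(total)


def gaussian_logpdf_matrix(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(n, k) matrix of log N(x_i | means_j, covs_j), batched cholesky."""
    from scipy.linalg import solve_triangular

    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    k = means.shape[0]
    out = np.empty((n, k))
    const = d * np.log(2.0 * np.pi)
    try:
        L = np.linalg.cholesky(covs)  # batched over components
    except np.linalg.LinAlgError:
        for j in range(k):  # re-run singly for a precise error message
            _chol_logdet(covs[j], f"covariance[{j}]")
        raise
    logdet = 2.0 * np.log(np.einsum("sii->si", L)).sum(axis=1)
    for j in range(k):
        sol = solve_triangular(L[j], (X - means[j]).T, lower=True, check_finite=False)
        out[:, j] = -0.5 * (const + logdet[j] + np.einsum("ji,ji->i", sol, sol))
    return out


def log_observation_matrix(X: np.ndarray, params: DirectionalGmmParams) -> np.ndarray:
    """(n, |S|) matrix of log N(x_b | mu_s, Sigma_s)."""
    return gaussian_logpdf_matrix(X, params.mu, params.Sigma)


def observation_log_density(x_b: np.ndarray, s: int, params: DirectionalGmmParams) -> float:
    """log N(x_b | mu_s, Sigma_s) for a single barcode."""
    return float(log_observation_matrix(np.atleast_2d(x_b), params)[0, s])


def log_mixture_density(x_b: np.ndarray, params: DirectionalGmmParams) -> float:
    """log sum_s pi_s N(x_b | mu_s, Sigma_s), computed via log-sum-exp."""
    logobs = log_observation_matrix(np.atleast_2d(x_b), params)[0]
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
    return float(logsumexp(logobs + logpi))


def _as_responsibilities(assignments, n: int, S: int) -> np.ndarray:
    w = np.asarray(assignments)
    if w.ndim == 1:
        if w.shape[0] != n:
            raise ValueError("one hard label per barcode required")
        out = np.zeros((n, S))
        out[np.arange(n), w.astype(int)] = 1.0
        return out
    if w.shape != (n, S):
        raise ValueError("responsibility matrix has the wrong shape")
    if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("responsibility rows must sum to 1")
    return w.astype(float)


def complete_log_likelihood(
    data, mu, assignments, params: DirectionalGmmParams, grid: GridSpec
) -> float:
    """log p(mu_S, z_B, x_B): spatial prior plus (expected) data terms.

    ``assignments`` may be hard labels (ints indexing clusters) or a
    row-stochastic responsibility matrix; with responsibilities this is the
    expected complete log-likelihood used as the EM surrogate objective.
    """
    X = data.x if hasattr(data, "x") else np.atleast_2d(np.asarray(data, dtype=float))
    mu = np.asarray(mu, dtype=float)
    S = mu.shape[0]
    w = _as_responsibilities(assignments, X.shape[0], S)
    work = DirectionalGmmParams(
        mu=mu,
        Sigma=params.Sigma,
        pi=params.pi,
        Delta=params.Delta,
        Q=params.Q,
        Q0=params.Q0,
        mu0=params.mu0,
        Delta_perp=params.Delta_perp,
    )
    logobs = log_observation_matrix(X, work)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
    # 0 * -inf from empty clusters contributes nothing
    terms = np.where(w > 0, w * (logobs + logpi[None, :]), 0.0)
    return prior_log_density(mu, grid, work) + float(terms.sum())


def _reversal_permutation(grid: GridSpec) -> np.ndarray:
    """Index permutation reading the chain (each row) right to left."""
    if grid.rows == 1:
        return np.arange(grid.K)[::-1].copy()
    cols = np.arange(grid.K)[::-1]
    return np.concatenate([cols, cols + grid.K])


def canonicalize(params: DirectionalGmmParams, grid: GridSpec, responsibilities=None):
    """Fix the chain-reversal gauge: first coordinate of Delta >= 0.

    The chain read backwards with ``-Delta`` describes the same joint law
    (up to the root factor, whose prior is effectively uninformative), so
    fits are reported with ``Delta[0] >= 0``.  Returns ``(params,
    responsibilities)`` with cluster order, weights and responsibility
    columns permuted consistently.
    """
    if params.Delta[0] >= 0:
        return params, responsibilities
    perm = _reversal_permutation(grid)
    flipped = DirectionalGmmParams(
        mu=params.mu[perm],
        Sigma=params.Sigma[perm],
        pi=params.pi[perm],
        Delta=-params.Delta,
        Q=params.Q,
        Q0=params.Q0,
        mu0=params.mu0,
        Delta_perp=params.Delta_perp,
    )
    if responsibilities is not None:
        responsibilities = np.asarray(responsibilities)[:, perm]
    return flipped, responsibilities
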