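"""Synthetic data generator with the model's exact statistical structure.

Cluster-mean anchors come from heavy-tailed Pareto(alpha = 1) abundance
draws closed to the simplex and sorted in decreasing order before the ILR
transform, so the longitudinal step concentrates its mass on balances
involving abundant taxa -- larger dynamics are visible on abundant taxa, as
in real gut data.  The step Delta is the ILR difference of two such draws
rescaled to the requested magnitude; for grids, Delta_perp is a standard
normal draw orthogonalized against Delta.  The remaining means are laid out
exactly on the chain/grid from the first anchor.  Cluster covariances are
inverse-Wishart(nu = D+1, Psi = I/(D-1)) draws, optionally rescaled to a
target within-cluster standard deviation, and samples are drawn evenly and
independently from each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import invwishart

from dirgmm.compositional import IlrBasis, TransformedData, build_ilr_basis
from dirgmm.model import DirectionalGmmParams, GridSpec

__all__ = ["SimulationConfig", "GroundTruth", "sample_true_means", "sample_covariances", "generate_dataset"]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the reference simulation regime: D = 47 taxa, 360
    samples, step magnitudes 5, within-cluster standard deviation 1 (the
    ``sd_scale`` rescaling of raw inverse-Wishart draws; ``sd_scale=None``
    keeps the raw draws, whose mean diagonal is 1/(D-1)).
    """

    grid: GridSpec
    D: int = 47
    delta_mag: float = 5.0
    delta_perp_mag: float = 5.0
    wishart_nu: float | None = None  # default D + 1
    n_samples: int = 360
    sd_scale: float | None = 1.0
    seed: int = 0
    pareto_alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.D < 3:
            raise ValueError("need at least 3 taxa")
        if self.n_samples < self.grid.n_clusters:
            raise ValueError("need at least one sample per cluster")
        if self.delta_mag <= 0 and self.grid.n_clusters > 1:
            raise ValueError("delta_mag = 0 gives a degenerate multi-cluster truth")

    @property
    def nu(self) -> float:
        return self.D + 1 if self.wishart_nu is None else self.wishart_nu


@dataclass
class GroundTruth:
    """True parameters, per-sample cluster labels and the ILR basis used."""

    params: DirectionalGmmParams
    labels: np.ndarray
    basis: IlrBasis


def _pareto_composition_ilr(rng: np.random.Generator, D: int, alpha: float, basis: IlrBasis):
    raw = 1.0 + rng.pareto(alpha, size=D)  # standard Pareto, scale 1
    comp = np.sort(raw)[::-1]
    comp = comp / comp.sum()
    return basis.V @ np.log(comp)


def sample_true_means(config: SimulationConfig, rng: np.random.Generator):
    """Draw the anchor means and step vectors; lay the grid out exactly.

    Returns ``(mu_S, Delta, Delta_perp, basis)`` with ``|Delta|`` equal to
    ``config.delta_mag`` and, for grids, ``Delta_perp`` orthogonal to
    ``Delta`` with magnitude ``config.delta_perp_mag``.
    """
    basis = build_ilr_basis(D=config.D)
    x1 = _pareto_composition_ilr(rng, config.D, config.pareto_alpha, basis)
    x2 = _pareto_composition_ilr(rng, config.D, config.pareto_alpha, basis)
    delta = x2 - x1
    delta *= config.delta_mag / np.linalg.norm(delta)

    grid = config.grid
    dperp = None
    if grid.rows == 2:
        dperp = rng.standard_normal(config.D - 1)
        dperp -= (dperp @ delta) / (delta @ delta) * delta
        dperp *= config.delta_perp_mag / np.linalg.norm(dperp)

    anchor = x1
    mu = np.empty((grid.n_clusters, config.D - 1))
    for idx, label in enumerate(grid.labels):
        if grid.rows == 1:
            mu[idx] = anchor + (label - 1) * delta
        else:
            r, i = label
            mu[idx] = anchor + (i - 1) * delta + (r - 1) * dperp
    return mu, delta, dperp, basis


def sample_covariances(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """One inverse-Wishart draw per cluster, optionally rescaled.

    Raw draws use nu = D + 1 and Psi = I/(D-1), whose mean is Psi itself;
    with ``sd_scale`` set, each draw is rescaled so its mean diagonal equals
    ``sd_scale**2`` (a target within-cluster standard deviation).
    """
    d = config.D - 1
    if config.nu <= d - 1:
        raise ValueError("inverse-Wishart needs nu > d - 1")
    Psi = np.eye(d) / d
    out = np.empty((config.grid.n_clusters, d, d))
    for s in range(config.grid.n_clusters):
        draw = invwishart.rvs(df=config.nu, scale=Psi, random_state=rng)
        if config.sd_scale is not None:
            draw *= config.sd_scale**2 / np.diag(draw).mean()
        out[s] = draw
    return out


def generate_dataset(config: SimulationConfig) -> tuple[TransformedData, GroundTruth]:
    """Simulate one dataset: ILR observations plus the generating truth.

    ``floor(n/|S|)`` samples per cluster, the remainder assigned round-robin
    starting from cluster 1; sample b in cluster s is N(mu_s, Sigma_s).
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mu, delta, dperp, basis = sample_true_means(config, rng)
    Sigma = sample_covariances(config, rng)

    S = config.grid.n_clusters
    n = config.n_samples
    counts = np.full(S, n // S)
    counts[: n % S] += 1

    d = config.D - 1
    X = np.empty((n, d))
    labels = np.empty(n, dtype=int)
    pos = 0
    for s in range(S):
        L = np.linalg.cholesky(Sigma[s])
        X[pos : pos + counts[s]] = mu[s] + rng.standard_normal((counts[s], d)) @ L.T
        labels[pos : pos + counts[s]] = s
        pos += counts[s]

    # the truth lies exactly on the grid: spatial deviations are nil, so Q
    # is a token small matrix; the root prior is centred on the anchor.
    params = DirectionalGmmParams(
        mu=mu,
        Sigma=Sigma,
        pi=counts / n,
        Delta=delta,
        Q=np.eye(d) * 1e-6,
        Q0=np.eye(d),
        mu0=mu[0],
        Delta_perp=dperp,
    )
    data = TransformedData(X, [f"b{i}" for i in range(n)])
    return data, GroundTruth(params=params, labels=labels, basis=basis)
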