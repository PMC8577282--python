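"""Quantitative assessment of fitted models.

Covers label-matched RMSE of learned cluster means (grid-matched for the
directional model, best-over-all-label-permutations for a naive GMM), the
paired one-sided Wilcoxon comparison of the two, projections of data and
means onto the unit Delta / Delta_perp axes, KL divergence between observed
and model-proposed cluster compositions with a coordinate-permutation test,
and the assigned-versus-best-other-cluster paired t-test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from dirgmm.compositional import CompositionMatrix, IlrBasis, ilr_inverse
from dirgmm.model import DirectionalGmmParams, GridSpec, log_observation_matrix

__all__ = [
    "EvaluationResult",
    "matched_rmse",
    "rmse_comparison_test",
    "project_onto_axes",
    "kl_divergence",
    "kl_permutation_test",
    "assigned_vs_best_other_test",
    "cluster_composition_summary",
]


@dataclass
class EvaluationResult:
    """Bundle of the quantitative assessments of one fit.

    Simulation mode fills the RMSE/Wilcoxon fields; data mode fills the
    per-cluster KL divergences, their permutation p-values, and the
    assigned-versus-best-other t-test p-value.
    """

    rmse_directional: float | None = None
    rmse_naive_best_perm: float | None = None
    wilcoxon_stat: float | None = None
    wilcoxon_p: float | None = None
    kl_by_cluster: list = field(default_factory=list)
    kl_perm_p: list = field(default_factory=list)
    ttest_stat: float | None = None
    ttest_p: float | None = None

    def __post_init__(self) -> None:
        for v in (self.rmse_directional, self.rmse_naive_best_perm):
            if v is not None and v < 0:
                raise ValueError("RMSE must be nonnegative")
        for v in [self.wilcoxon_p, self.ttest_p, *self.kl_perm_p]:
            if v is not None and not 0 <= v <= 1:
                raise ValueError("p-values must lie in [0, 1]")
        if any(k < 0 for k in self.kl_by_cluster):
            raise ValueError("KL divergences must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "rmse_directional": self.rmse_directional,
            "rmse_naive_best_perm": self.rmse_naive_best_perm,
            "wilcoxon_stat": self.wilcoxon_stat,
            "wilcoxon_p": self.wilcoxon_p,
            "kl_by_cluster": list(self.kl_by_cluster),
            "kl_perm_p": list(self.kl_perm_p),
            "ttest_stat": self.ttest_stat,
            "ttest_p": self.ttest_p,
        }


def _avg_rmse(true_means: np.ndarray, learned: np.ndarray) -> float:
    """Mean over clusters of per-cluster coordinate RMSE."""
    sq = (true_means - learned) ** 2
    return float(np.sqrt(sq.mean(axis=1)).mean())


def _grid_symmetries(grid: GridSpec) -> list[np.ndarray]:
    """Index permutations under which the arrangement is equivalent."""
    K, rows = grid.K, grid.rows
    base = np.arange(grid.n_clusters)
    perms = [base]
    if rows == 1:
        perms.append(base[::-1].copy())
        return perms
    cols = np.arange(K)
    rev = cols[::-1]
    col_rev = np.concatenate([rev, rev + K])
    row_swap = np.concatenate([cols + K, cols])
    both = np.concatenate([rev + K, rev])
    perms += [col_rev, row_swap, both]
    return perms


def matched_rmse(
    true_means: np.ndarray,
    learned_means: np.ndarray,
    mode: str = "grid",
    grid: GridSpec | None = None,
) -> float:
    """Average per-cluster RMSE of learned means against the truth.

    ``grid`` mode keeps the model's spatial labeling but minimizes over its
    order-reversal symmetries (a chain read backwards is the same model).
    ``permutation`` mode -- for label-free baselines like a naive GMM --
    minimizes over all |S|! label permutations (exhaustive, |S| <= 8).
    """
    true_means = np.asarray(true_means, dtype=float)
    learned_means = np.asarray(learned_means, dtype=float)
    if true_means.shape != learned_means.shape:
        raise ValueError("true and learned means have mismatched shapes")
    S = true_means.shape[0]
    if mode == "grid":
        if grid is None:
            raise ValueError("grid mode needs the GridSpec")
        return min(_avg_rmse(true_means, learned_means[p]) for p in _grid_symmetries(grid))
    if mode == "permutation":
        if S > 8:
            raise ValueError("exhaustive permutation matching is limited to |S| <= 8")
        return min(
            _avg_rmse(true_means, learned_means[list(p)])
            for p in itertools.permutations(range(S))
        )
    raise ValueError(f"unknown mode {mode!r}")


def rmse_comparison_test(paired_rmse) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test that directional RMSE < naive RMSE.

    ``paired_rmse`` is a sequence of (directional, naive) values, one pair
    per simulated dataset.
    """
    pairs = np.asarray(paired_rmse, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("paired_rmse must be a sequence of (directional, naive) pairs")
    if pairs.shape[0] < 6:
        raise ValueError("need at least 6 pairs for a meaningful signed-rank test")
    diff = pairs[:, 0] - pairs[:, 1]
    if np.all(diff == 0):
        warnings.warn("all paired differences are zero; returning degenerate p = 1")
        return 0.0, 1.0
    res = stats.wilcoxon(pairs[:, 0], pairs[:, 1], alternative="less")
    return float(res.statistic), float(res.pvalue)


def project_onto_axes(points, params: DirectionalGmmParams) -> np.ndarray:
    """Scalar projections of points (data or means) onto the unit step axes.

    Returns an (n, 1) array of coordinates along Delta/|Delta|, or (n, 2)
    with the Delta_perp axis appended when the model is two-dimensional.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    nd = np.linalg.norm(params.Delta)
    if nd == 0:
        raise ValueError("Delta is the zero vector; projection axis undefined")
    cols = [X @ (params.Delta / nd)]
    if params.Delta_perp is not None:
        np_ = np.linalg.norm(params.Delta_perp)
        if np_ == 0:
            raise ValueError("Delta_perp is the zero vector; projection axis undefined")
        cols.append(X @ (params.Delta_perp / np_))
    return np.column_stack(cols)


def kl_divergence(observed, proposed) -> float:
    """Relative entropy KL(observed || proposed), natural log."""
    p = np.asarray(observed, dtype=float)
    q = np.asarray(proposed, dtype=float)
    if p.shape != q.shape:
        raise ValueError("compositions have different lengths")
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("compositions must be strictly positive; run replace_zeros first")
    if abs(p.sum() - 1) > 1e-6 or abs(q.sum() - 1) > 1e-6:
        raise ValueError("compositions must sum to 1")
    return float(np.sum(p * np.log(p / q)))


def kl_permutation_test(
    observed,
    proposed,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation test of whether KL(observed || proposed) is small.

    The null distribution is the KL of coordinate-permuted observed vectors
    against the fixed proposed vector; ``p = (1 + #{KL_perm <= KL_obs}) /
    (n_perm + 1)``, so small p means the two compositions are closer than
    random coordinate matching would produce.
    """
    p = np.asarray(observed, dtype=float)
    if p.size < 3:
        warnings.warn("fewer than 3 parts: the permutation space is trivial")
    if rng is None:
        rng = np.random.default_rng()
    obs = kl_divergence(p, proposed)
    hits = 0
    for _ in range(n_perm):
        hits += kl_divergence(rng.permutation(p), proposed) <= obs + 1e-15
    return (1 + hits) / (n_perm + 1)


def assigned_vs_best_other_test(data, params: DirectionalGmmParams, assignments) -> tuple[float, float]:
    """Paired one-sided t-test: assigned-cluster log-likelihood > best other.

    For each barcode the pair is (log N under its assigned cluster, max log
    N over the remaining clusters), using the same fitted covariances.
    Returns (t statistic, p-value); small p supports the assignments.
    """
    X = data.x if hasattr(data, "x") else np.atleast_2d(np.asarray(data, dtype=float))
    labels = np.asarray(assignments)
    if labels.ndim == 2:
        labels = np.argmax(labels, axis=1)
    if params.n_clusters < 2:
        raise ValueError("need at least two clusters to compare against")
    logobs = log_observation_matrix(X, params)
    n = X.shape[0]
    assigned = logobs[np.arange(n), labels]
    masked = logobs.copy()
    masked[np.arange(n), labels] = -np.inf
    best_other = masked.max(axis=1)
    res = stats.ttest_rel(assigned, best_other, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def cluster_composition_summary(
    mu: np.ndarray,
    basis: IlrBasis,
    assignments=None,
    compositions: CompositionMatrix | None = None,
    taxon_groups: dict | None = None,
):
    """Proposed vs observed average composition of each latent cluster.

    Proposed compositions are the inverse-ILR of the cluster means;
    observed compositions are the mean relative abundance of the barcodes
    hard-assigned to each cluster (requires ``assignments`` and the
    pre-transform ``compositions``).  ``taxon_groups`` optionally aggregates
    taxa into named groups (e.g. phyla) for reporting.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    proposed = ilr_inverse(mu, basis).values
    observed = None
    empty = []
    if assignments is not None and compositions is not None:
        labels = np.asarray(assignments)
        if labels.ndim == 2:
            labels = np.argmax(labels, axis=1)
        observed = np.full((mu.shape[0], basis.n_taxa), np.nan)
        for s in range(mu.shape[0]):
            members = labels == s
            if not members.any():
                empty.append(s)
                continue
            observed[s] = compositions.values[members].mean(axis=0)
    if taxon_groups is not None:
        taxa = compositions.taxon_ids if compositions is not None else [
            f"t{i}" for i in range(basis.n_taxa)
        ]
        cols = {g: [i for i, t in enumerate(taxa) if t in members] for g, members in taxon_groups.items()}
        proposed = np.column_stack([proposed[:, idx].sum(axis=1) for idx in cols.values()])
        if observed is not None:
            observed = np.column_stack([observed[:, idx].sum(axis=1) for idx in cols.values()])
    return {"proposed": proposed, "observed": observed, "empty_clusters": empty}
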