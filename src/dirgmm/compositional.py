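"""Compositional preprocessing: counts to ILR coordinates.

Sequencing read counts carry no information about absolute community size,
only about proportions, so the model operates on relative abundances mapped
to Euclidean space with an isometric log-ratio (ILR) transform.  The ILR
basis is a sequential binary partition: each coordinate is a "balance"
contrasting two groups of taxa, and when a rooted binary phylogeny is
supplied the groups are its clades (the PhILR construction).  The pipeline
is: normalize counts, keep the most abundant taxa covering a target share of
total abundance, renormalize, impute zeros by multiplicative replacement,
then transform.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CountTable",
    "CompositionMatrix",
    "IlrBasis",
    "TransformedData",
    "normalize_counts",
    "filter_top_taxa",
    "replace_zeros",
    "build_ilr_basis",
    "ilr_transform",
    "ilr_inverse",
]


@dataclass
class CountTable:
    """Barcode x taxon read counts.

    ``counts`` is a nonnegative (n_barcodes, n_taxa) array; every row must
    have a positive total so it can be closed to a composition.
    """

    barcode_ids: list
    taxon_ids: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape != (len(self.barcode_ids), len(self.taxon_ids)):
            raise ValueError("counts shape does not match id lists")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")


@dataclass
class CompositionMatrix:
    """Barcode x taxon relative abundances; each row sums to one."""

    values: np.ndarray
    taxon_ids: list
    barcode_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if np.any(self.values < 0):
            raise ValueError("compositions must be nonnegative")
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("composition rows must sum to 1 within 1e-9")
        if not self.barcode_ids:
            self.barcode_ids = [f"b{i}" for i in range(self.values.shape[0])]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]


@dataclass
class IlrBasis:
    """Orthonormal clr contrast matrix, one balance row per binary split.

    ``V`` has shape (D-1, D); rows are orthonormal and sum to zero, so
    ``x = V @ log(p)`` equals ``V @ clr(p)`` for any composition ``p``.
    """

    V: np.ndarray
    node_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        d, D = self.V.shape
        if d != D - 1:
            raise ValueError("contrast matrix must be (D-1) x D")
        if not np.allclose(self.V @ self.V.T, np.eye(d), atol=1e-8):
            raise ValueError("basis rows are not orthonormal")
        if not np.allclose(self.V.sum(axis=1), 0.0, atol=1e-8):
            raise ValueError("basis rows must sum to zero")
        if not self.node_labels:
            self.node_labels = [f"balance{i}" for i in range(d)]

    @property
    def n_taxa(self) -> int:
        return self.V.shape[1]


@dataclass
class TransformedData:
    """ILR coordinates, one row per barcode; columns are balances."""

    x: np.ndarray
    barcode_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("x must be a 2-D array")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("transformed data must be finite")
        if not self.barcode_ids:
            self.barcode_ids = [f"b{i}" for i in range(self.x.shape[0])]

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def d(self) -> int:
        return self.x.shape[1]


def normalize_counts(table: CountTable) -> CompositionMatrix:
    """Close each count row to the unit simplex (relative abundances)."""
    totals = table.counts.sum(axis=1)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        raise ValueError(
            f"barcode(s) with zero total count: {[table.barcode_ids[i] for i in bad]}"
        )
    values = table.counts / totals[:, None]
    return CompositionMatrix(values, list(table.taxon_ids), list(table.barcode_ids))


def filter_top_taxa(
    tables: list[CompositionMatrix], coverage: float = 0.95
) -> tuple[list[CompositionMatrix], list]:
    """Keep the most abundant taxa jointly covering ``coverage`` of abundance.

    Taxa are ranked by relative abundance summed over every row of every
    table; the shortest prefix whose cumulative share reaches ``coverage``
    is retained (ties broken by input order) and rows are renormalized.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if not tables:
        raise ValueError("no tables given")
    shared = [t for t in tables[0].taxon_ids if all(t in tb.taxon_ids for tb in tables[1:])]
    if not shared:
        raise ValueError("tables have an empty taxon intersection")
    totals = np.zeros(len(shared))
    for tb in tables:
        idx = [tb.taxon_ids.index(t) for t in shared]
        totals += tb.values[:, idx].sum(axis=0)
    # stable sort keeps input order among ties
    order = np.argsort(-totals, kind="stable")
    cum = np.cumsum(totals[order]) / totals.sum()
    n_keep = int(np.searchsorted(cum, coverage - 1e-12) + 1)
    kept_set = sorted(order[:n_keep])
    kept = [shared[i] for i in kept_set]

    out = []
    for tb in tables:
        idx = [tb.taxon_ids.index(t) for t in kept]
        vals = tb.values[:, idx]
        rowsum = vals.sum(axis=1)
        if np.any(rowsum <= 0):
            raise ValueError("a barcode lost all abundance under the taxon filter")
        out.append(CompositionMatrix(vals / rowsum[:, None], kept, list(tb.barcode_ids)))
    return out, kept


def replace_zeros(comp: CompositionMatrix, delta: float | None = None) -> CompositionMatrix:
    """Multiplicative zero replacement: zeros -> delta, nonzeros rescaled.

    The default ``delta`` is 1/D^2 for D taxa.  Each zero becomes ``delta``
    and every nonzero entry in that row is scaled by ``1 - z*delta`` (z =
    number of zeros in the row), preserving the unit sum and the ratios
    among nonzero parts.
    """
    D = comp.n_taxa
    if delta is None:
        delta = 1.0 / D**2
    values = comp.values.copy()
    zero = values == 0
    z = zero.sum(axis=1)
    scale = 1.0 - z * delta
    if np.any(scale <= 0):
        raise ValueError("too many zeros for this delta: replacement mass >= 1")
    values = values * scale[:, None]
    values[zero] = delta
    return CompositionMatrix(values, list(comp.taxon_ids), list(comp.barcode_ids))


def _balance_row(D: int, left: list[int], right: list[int]) -> np.ndarray:
    r, s = len(left), len(right)
    row = np.zeros(D)
    row[left] = np.sqrt(s / (r * (r + s)))
    row[right] = -np.sqrt(r / (s * (r + s)))
    return row


def _bisect_partition(indices: list[int], rows: list, labels: list, D: int) -> None:
    if len(indices) < 2:
        return
    half = (len(indices) + 1) // 2
    left, right = indices[:half], indices[half:]
    labels.append(f"balance{len(rows)}")
    rows.append(_balance_row(D, left, right))
    _bisect_partition(left, rows, labels, D)
    _bisect_partition(right, rows, labels, D)


def _binarize(node):
    """Resolve polytomies by left-to-right caterpillar expansion.

    Returns a nested tuple tree whose leaves are taxon names.
    """
    children = list(node.children)
    if not children:
        return node.name
    sub = [_binarize(c) for c in children]
    tree = sub[0]
    for nxt in sub[1:]:
        tree = (tree, nxt)
    return tree


def build_ilr_basis(tree=None, D: int | None = None, taxon_ids: list | None = None) -> IlrBasis:
    """Construct the sequential-binary-partition ILR basis.

    With a rooted phylogeny (newick string or ``skbio.TreeNode``) each
    internal node contributes one balance: ``+sqrt(s/(r(r+s)))`` on the r
    taxa of its first subtree and ``-sqrt(r/(s(r+s)))`` on the s taxa of its
    second.  Non-binary nodes are resolved deterministically by caterpillar
    expansion of their children left to right.  Without a tree, a balanced
    bisection of the taxon order is used.
    """
    if tree is None:
        if D is None:
            raise ValueError("give either a tree or the number of taxa D")
        if D < 2:
            raise ValueError("need at least two taxa")
        rows: list = []
        labels: list = []
        _bisect_partition(list(range(D)), rows, labels, D)
        return IlrBasis(np.array(rows), labels)

    from skbio import TreeNode

    if isinstance(tree, str):
        tree = TreeNode.read(io.StringIO(tree))
    leaves = [t.name for t in tree.tips()]
    if taxon_ids is None:
        taxon_ids = leaves
    if set(leaves) != set(taxon_ids) or len(leaves) != len(taxon_ids):
        missing = set(taxon_ids) ^ set(leaves)
        raise ValueError(f"tree leaves and taxa differ: {sorted(map(str, missing))}")
    index = {t: i for i, t in enumerate(taxon_ids)}
    D = len(taxon_ids)

    rows, labels = [], []

    def visit(sub, label_hint: str) -> list[int]:
        if isinstance(sub, tuple):
            li = visit(sub[0], label_hint + "L")
            ri = visit(sub[1], label_hint + "R")
            labels.append(label_hint)
            rows.append(_balance_row(D, li, ri))
            return li + ri
        return [index[sub]]

    visit(_binarize(tree), "n")
    # visit() appends postorder; report root-first for readability
    rows.reverse()
    labels.reverse()
    return IlrBasis(np.array(rows), labels)


def ilr_transform(comp: CompositionMatrix, basis: IlrBasis) -> TransformedData:
    """Map strictly positive compositions to ILR coordinates x = V log p."""
    if comp.n_taxa != basis.n_taxa:
        raise ValueError("composition and basis disagree on taxon count")
    if np.any(comp.values <= 0):
        raise ValueError("compositions contain zeros; run replace_zeros first")
    x = np.log(comp.values) @ basis.V.T
    return TransformedData(x, list(comp.barcode_ids))


def ilr_inverse(x, basis: IlrBasis, barcode_ids: list | None = None) -> CompositionMatrix:
    """Invert the ILR transform: closure of exp(V^T x)."""
    arr = x.x if isinstance(x, TransformedData) else np.atleast_2d(np.asarray(x, dtype=float))
    if barcode_ids is None and isinstance(x, TransformedData):
        barcode_ids = list(x.barcode_ids)
    logp = arr @ basis.V
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    return CompositionMatrix(p, [f"t{i}" for i in range(basis.n_taxa)], barcode_ids or [])
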