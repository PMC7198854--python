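"""Construction of the cancer-specific network.

The cancer-related network is the intersection of two sources of evidence:

1. a *differential coexpression* network — gene pairs whose Pearson
   correlation is significant (two-sided p < 0.05) in exactly one of the
   tumor/normal conditions — which supplies the edge candidates, and
2. a directed reference interaction network, which supplies edge direction
   and restricts the candidates to known interactions.

Correlation significance uses the standard t transform
``t = r * sqrt((m - 2) / (1 - r^2))`` with ``m - 2`` degrees of freedom,
where ``m`` is the sample count. Zero-variance genes produce undefined
correlations, which are flagged and treated as non-significant. No
multiple-testing correction is applied: the selection rule is the raw
p < 0.05 threshold, strict on both sides of the XOR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.stats

from .data_io import ExpressionMatrix, ValidationError
from .network import DirectedNetwork

logger = logging.getLogger(__name__)


@dataclass
class CorrelationNetwork:
    """All-pairs Pearson r and two-sided p for one condition.

    ``defined[i, j]`` is False where either gene has zero variance; such
    pairs carry no coexpression evidence and are never significant.
    """

    genes: list[str]
    r: np.ndarray
    p: np.ndarray
    defined: np.ndarray  # bool mask of pairs with a defined correlation
    condition: str

    def __post_init__(self) -> None:
        n = len(self.genes)
        for name, mat in (("r", self.r), ("p", self.p), ("defined", self.defined)):
            if mat.shape != (n, n):
                raise ValidationError(f"{name} matrix shape mismatch")
        if (np.abs(self.r[self.defined]) > 1 + 1e-12).any():
            raise ValidationError("|r| > 1 on a defined pair")


@dataclass
class SignificanceMask:
    """Symmetric 0-1 matrix: 1 iff the pair's p-value clears the threshold."""

    genes: list[str]
    mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if (self.mask != self.mask.T).any():
            raise ValidationError("significance mask not symmetric")
        if self.mask.diagonal().any():
            raise ValidationError("significance mask has nonzero diagonal")


@dataclass
class DifferentialEdgeSet:
    """Unordered gene pairs significant in exactly one condition."""

    genes: list[str]  # the expression gene universe the pairs were drawn from
    pairs: set[tuple[str, str]]  # each pair stored sorted

    def __post_init__(self) -> None:
        self.pairs = {tuple(sorted(p)) for p in self.pairs}
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"degenerate pair ({a}, {b})")

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(sorted(pair)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def pearson_with_pvalues(expr: ExpressionMatrix) -> CorrelationNetwork:
    """All-pairs Pearson correlation with two-sided p-values.

    Requires at least 3 samples (the t test has ``m - 2`` degrees of
    freedom). Computed vectorized from standardized rows; agrees with the
    per-pair textbook formula to ~1e-13.
    """
    m = expr.n_samples
    if m < 3:
        raise ValidationError(f"need >= 3 samples for correlation p-values, got {m}")
    X = expr.values
    sd = X.std(axis=1, ddof=1)
    nonconstant = sd > 0
    Z = np.zeros_like(X)
    Z[nonconstant] = (X[nonconstant] - X[nonconstant].mean(axis=1, keepdims=True)) / (
        sd[nonconstant, None] * np.sqrt(m - 1)
    )
    r = Z @ Z.T
    np.clip(r, -1.0, 1.0, out=r)
    defined = np.outer(nonconstant, nonconstant)
    np.fill_diagonal(defined, False)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((m - 2) / (1.0 - r**2))
    # |r| = 1 gives an infinite t statistic: p is exactly 0
    p = np.where(
        np.isfinite(t), 2.0 * scipy.stats.t.sf(np.abs(t), df=m - 2), 0.0
    )
    p[~defined] = np.nan
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, np.nan)
    return CorrelationNetwork(
        genes=list(expr.genes), r=r, p=p, defined=defined, condition=expr.condition
    )


def significance_mask(
    corr: CorrelationNetwork, threshold: float = 0.05
) -> SignificanceMask:
    """1 iff p strictly below the threshold; undefined pairs are 0."""
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must lie in (0, 1), got {threshold}")
    with np.errstate(invalid="ignore"):
        mask = (corr.p < threshold) & corr.defined
    np.fill_diagonal(mask, False)
    return SignificanceMask(
        genes=list(corr.genes), mask=mask.astype(np.int8), threshold=threshold
    )


def differential_edges(
    tumor_mask: SignificanceMask, normal_mask: SignificanceMask
) -> DifferentialEdgeSet:
    """Pairs significant in exactly one condition (XOR of the masks).

    Pairs significant in both ("consistent edges") or neither are removed.
    """
    if tumor_mask.genes != normal_mask.genes:
        raise ValidationError("tumor/normal masks cover different gene universes")
    xor = tumor_mask.mask ^ normal_mask.mask
    genes = tumor_mask.genes
    ii, jj = np.nonzero(np.triu(xor, k=1))
    pairs = {(genes[i], genes[j]) for i, j in zip(ii, jj)}
    return DifferentialEdgeSet(genes=list(genes), pairs=pairs)


def intersect_with_reference(
    diff: DifferentialEdgeSet, reference: DirectedNetwork
) -> DirectedNetwork:
    """Keep common nodes, and reference edges whose pair is differential.

    The node set is the intersection of the reference nodes with the
    expression gene universe; a directed edge ``i -> j`` survives iff it is
    in the reference and the unordered pair {i, j} is a differential edge.
    Direction comes solely from the reference. Nodes left with no edges are
    kept (they become dangling rows in the walk).
    """
    expr_genes = set(diff.genes)
    nodes = [g for g in reference.genes if g in expr_genes]
    node_set = set(nodes)
    kept = [
        (src, dst)
        for src, dst in reference.edges()
        if src in node_set and dst in node_set and (src, dst) in diff
    ]
    if not kept:
        logger.warning("cancer-specific network has no edges; walk rows fall back to uniform")
    return DirectedNetwork.from_edges(nodes, kept)


def build_cancer_network(
    tumor_expr: ExpressionMatrix,
    normal_expr: ExpressionMatrix,
    reference: DirectedNetwork,
    threshold: float = 0.05,
) -> DirectedNetwork:
    """Full construction: per-condition correlation -> XOR -> intersection.

    Correlations are computed only on genes shared by both expression
    matrices and the reference network (an efficiency choice: genes outside
    the reference can never contribute an edge to the intersection).
    """
    common = [
        g
        for g in tumor_expr.genes
        if g in set(normal_expr.genes) and g in set(reference.genes)
    ]
    t_sub = _subset_expression(tumor_expr, common)
    n_sub = _subset_expression(normal_expr, common)
    tm = significance_mask(pearson_with_pvalues(t_sub), threshold)
    nm = significance_mask(pearson_with_pvalues(n_sub), threshold)
    diff = differential_edges(tm, nm)
    return intersect_with_reference(diff, reference)


def _subset_expression(expr: ExpressionMatrix, genes: list[str]) -> ExpressionMatrix:
    pos = {g: i for i, g in enumerate(expr.genes)}
    idx = [pos[g] for g in genes]
    return ExpressionMatrix(
        genes=list(genes),
        samples=list(expr.samples),
        values=expr.values[idx, :],
        condition=expr.condition,
    )
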