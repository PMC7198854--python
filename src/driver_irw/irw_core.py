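"""The degree-biased random walk with restart.

The walk iterates

    r(t+1) = d * P^T r(t) + (1 - d) * prior_p

where ``P`` is the degree-biased transition matrix: from node i, transition
probability to j is proportional to j's *out*-degree among i's out-neighbors,
mixed with a uniform teleport term,

    P[i, j] = alpha * DC+_j * A[i, j] / sum_{v in N+(i)} DC+_v + (1 - alpha)/n

whenever the neighbor out-degree sum is positive, and uniform 1/n otherwise
(dangling nodes, and nodes all of whose out-neighbors are sinks). The
restart prior places mass on seed genes in proportion to the mean of their
normalized betweenness and Katz centralities. Iteration stops when the
squared score change ``sum_i (r_i(t+1) - r_i(t))^2`` falls below eps, or
after max_iter sweeps. Defaults: alpha = 0.85, d = 0.85, eps = 1e-8,
max_iter = 1000.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .centrality import CentralityVector
from .data_io import ExpressionMatrix, GeneSet, ValidationError
from .network import DirectedNetwork

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-12


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix, stored in factored form.

    ``P = alpha_mix * W + (1 - alpha_mix)/n`` on live rows (W holds the
    degree-biased neighbor weights, each live row of W summing to 1) and a
    uniform 1/n on dangling rows. The factored form keeps ``P^T r``
    products sparse; ``to_dense()`` materializes P for inspection.
    """

    genes: list[str]
    W: sp.csr_matrix  # neighbor-weight part; zero rows where dangling
    dangling: np.ndarray  # bool mask of uniform rows
    alpha_mix: float

    @property
    def n(self) -> int:
        return len(self.genes)

    def to_dense(self) -> np.ndarray:
        n = self.n
        P = self.alpha_mix * self.W.toarray() + (1.0 - self.alpha_mix) / n
        P[self.dangling, :] = 1.0 / n
        return P

    def row_sums(self) -> np.ndarray:
        live = ~self.dangling
        sums = np.full(self.n, 1.0)
        w_sums = np.asarray(self.W.sum(axis=1)).ravel()
        sums[live] = self.alpha_mix * w_sums[live] + (1.0 - self.alpha_mix)
        return sums

    def transpose_apply(self, r: np.ndarray) -> np.ndarray:
        """Compute ``P^T r`` without materializing the dense matrix."""
        r = np.asarray(r, dtype=float)
        live = ~self.dangling
        mass_live = r[live].sum()
        mass_dang = r[self.dangling].sum()
        out = self.alpha_mix * (self.W.T @ r)
        out += ((1.0 - self.alpha_mix) * mass_live + mass_dang) / self.n
        return out

    def validate(self) -> None:
        sums = self.row_sums()
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValidationError("transition matrix rows do not sum to 1")


@dataclass
class PriorVector:
    genes: list[str]
    prior_p: np.ndarray
    seed_genes: GeneSet  # seeds actually used (intersection with the network)

    def __post_init__(self) -> None:
        self.prior_p = np.asarray(self.prior_p, dtype=float)
        if (self.prior_p < -1e-15).any():
            raise ValidationError("prior has negative entries")
        if abs(self.prior_p.sum() - 1.0) > 1e-9:
            raise ValidationError("prior does not sum to 1")


@dataclass
class ScoreVector:
    genes: list[str]
    r: np.ndarray
    iterations: int = 0
    converged: bool = True
    final_diff: float = 0.0

    def as_series(self):
        import pandas as pd

        return pd.Series(self.r, index=self.genes, name="score")


def _degree_biased_weights(net: DirectedNetwork) -> tuple[sp.csr_matrix, np.ndarray]:
    """Neighbor weights proportional to the neighbor's out-degree.

    Returns (W, dangling): W row i holds DC+_j / S_i on i's out-neighbors
    where S_i = sum of neighbor out-degrees; dangling marks rows with
    S_i = 0 (no out-neighbors, or all out-neighbors are sinks).
    """
    deg = net.out_degrees().astype(float)
    A = net.A.astype(float)
    weighted = A.multiply(deg[None, :]).tocsr()  # entry (i,j) = DC+_j * A_ij
    S = np.asarray(weighted.sum(axis=1)).ravel()
    dangling = S == 0
    inv = np.zeros_like(S)
    inv[~dangling] = 1.0 / S[~dangling]
    W = sp.diags(inv) @ weighted
    W.eliminate_zeros()
    return W.tocsr(), dangling


def build_transition_matrix(
    net: DirectedNetwork, alpha_mix: float = 0.85
) -> TransitionMatrix:
    """Degree-biased transition matrix with uniform teleport mixing."""
    if not (0.0 <= alpha_mix <= 1.0):
        raise ValidationError(f"alpha_mix must lie in [0, 1], got {alpha_mix}")
    W, dangling = _degree_biased_weights(net)
    return TransitionMatrix(list(net.genes), W, dangling, alpha_mix)


def build_uniform_transition(
    net: DirectedNetwork, alpha_mix: float = 0.85
) -> TransitionMatrix:
    """Ablation variant: every out-neighbor weighted equally (RW_UniTr)."""
    if not (0.0 <= alpha_mix <= 1.0):
        raise ValidationError(f"alpha_mix must lie in [0, 1], got {alpha_mix}")
    A = net.A.astype(float)
    deg_out = np.asarray(A.sum(axis=1)).ravel()
    dangling = deg_out == 0
    inv = np.zeros_like(deg_out)
    inv[~dangling] = 1.0 / deg_out[~dangling]
    W = (sp.diags(inv) @ A).tocsr()
    W.eliminate_zeros()
    return TransitionMatrix(list(net.genes), W, dangling, alpha_mix)


def _normalize_to_sum_one(values: np.ndarray) -> np.ndarray:
    total = values.sum()
    if total <= 0:
        return np.zeros_like(values)
    return values / total


def build_prior(
    seeds: GeneSet,
    bc: CentralityVector,
    kc: CentralityVector,
    net: DirectedNetwork,
) -> PriorVector:
    """Seed restart prior from normalized betweenness and Katz centrality.

    Each centrality is first normalized to sum 1 over all network genes
    (an all-zero vector stays zero); each seed then scores the mean of its
    two normalized values; non-seeds score 0; the result is renormalized to
    sum 1. Seeds absent from the network are dropped with a warning. If no
    usable seed remains, or every usable seed has zero centrality, the
    prior falls back to uniform 1/n.
    """
    if bc.genes != net.genes or kc.genes != net.genes:
        raise ValidationError("centrality vectors must cover the network genes in order")
    n = net.n
    usable = sorted(seeds.genes & set(net.genes))
    dropped = seeds.genes - set(usable)
    if dropped:
        logger.warning(
            "%d seed(s) absent from the network were dropped: %s",
            len(dropped),
            sorted(dropped)[:10],
        )
    bc_norm = _normalize_to_sum_one(bc.values)
    kc_norm = _normalize_to_sum_one(kc.values)
    prior = np.zeros(n)
    for g in usable:
        i = net.index_of(g)
        prior[i] = 0.5 * (bc_norm[i] + kc_norm[i])
    total = prior.sum()
    if not usable or total <= 0:
        logger.warning("no usable seed mass; falling back to the uniform prior")
        return PriorVector(list(net.genes), np.full(n, 1.0 / n), GeneSet(seeds.name, set()))
    return PriorVector(
        list(net.genes), prior / total, GeneSet(seeds.name, set(usable))
    )


def uniform_prior(net: DirectedNetwork) -> PriorVector:
    """Seedless restart: equal jump probability 1/n to every node."""
    n = net.n
    return PriorVector(list(net.genes), np.full(n, 1.0 / n), GeneSet("uniform", set()))


def initial_scores(tumor_expr: ExpressionMatrix, net: DirectedNetwork) -> ScoreVector:
    """r(0): per-gene tumor mean expression, normalized to sum 1.

    Every network gene must be present in the tumor expression matrix;
    abundance must be non-negative. If all means are zero the initial
    vector falls back to uniform with a warning.
    """
    if (tumor_expr.values < 0).any():
        raise ValidationError("expression abundance must be non-negative")
    means = tumor_expr.mean_per_gene()
    missing = [g for g in net.genes if g not in means.index]
    if missing:
        raise ValidationError(
            f"network gene(s) missing from tumor expression: {missing[:10]}"
        )
    r0 = means.reindex(net.genes).to_numpy(dtype=float)
    total = r0.sum()
    if total <= 0:
        logger.warning("all tumor means are zero; using uniform initial scores")
        r0 = np.full(net.n, 1.0 / net.n)
    else:
        r0 = r0 / total
    return ScoreVector(list(net.genes), r0)


def random_walk(
    P: TransitionMatrix,
    prior: PriorVector,
    r0: ScoreVector,
    d: float = 0.85,
    eps: float = 1e-8,
    max_iter: int = 1000,
    *,
    check_mass: bool = False,
) -> ScoreVector:
    """Iterate ``r <- d P^T r + (1 - d) prior`` to the stationary scores.

    Stops when the squared change ``sum_i (r_i(t+1) - r_i(t))^2 < eps`` or
    after ``max_iter`` iterations. With d = 0 the walk returns the prior
    after one iteration. When r(0) and the prior both sum to 1 every
    iterate sums to 1 (P^T has unit column sums); ``check_mass`` asserts
    this at each step.
    """
    if not (0.0 <= d < 1.0):
        raise ValidationError(f"damping d must lie in [0, 1), got {d}")
    P.validate()
    r = np.asarray(r0.r, dtype=float)
    p = prior.prior_p
    diff = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        r_next = d * P.transpose_apply(r) + (1.0 - d) * p
        if np.isnan(r_next).any():
            raise ValidationError("NaN encountered during walk iteration")
        if check_mass and abs(r_next.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"score mass drifted to {r_next.sum():.12f} at iteration {it}"
            )
        diff = float(((r_next - r) ** 2).sum())
        r = r_next
        if diff < eps:
            break
    converged = diff < eps
    if not converged:
        logger.warning("walk did not converge in %d iterations (diff=%.3g)", max_iter, diff)
    return ScoreVector(list(P.genes), r, iterations=it, converged=converged, final_diff=diff)


def stationary_solve(P: TransitionMatrix, prior: PriorVector, d: float = 0.85) -> np.ndarray:
    """Closed-form stationary scores ``(1 - d)(I - d P^T)^{-1} prior``.

    Independent of the iteration path; used as a cross-check of the walk.
    """
    n = P.n
    dense = P.to_dense()
    M = np.eye(n) - d * dense.T
    return (1.0 - d) * np.linalg.solve(M, prior.prior_p)
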