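"""Mutation post-filter, ranking, top-N evaluation and experiment runners.

The walk scores every network gene; only mutated genes (an SNV, or a
GISTIC +2/-2 call, in at least one sample) are retained in the final
ranking — mutation status is the posterior filter, not part of the walk.
Performance against a benchmark gene set is summarized by top-N precision
and recall:

    precision(N) = |top-N  intersect  benchmark| / N
    recall(N)    = |top-N  intersect  benchmark| / |benchmark|

The module also hosts the two ablations (uniform-neighbor transition;
seedless uniform restart) and the seed-subsampling robustness experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import centrality as _centrality
from . import irw_core, network_builder
from .data_io import ExpressionMatrix, GeneSet, MutationStatus, ValidationError
from .network import DirectedNetwork

logger = logging.getLogger(__name__)

MODES = ("full", "uniform_transition", "no_seeds")


@dataclass
class RankedList:
    """Mutation-filtered genes ordered by walk score.

    Entries are (rank, gene, score, mutated_sample_count); ranks start at
    1, scores are non-increasing, ties break by gene identifier ascending.
    """

    entries: list[tuple[int, str, float, int]]

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, n: int) -> list[str]:
        return [gene for _, gene, _, _ in self.entries[:n]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["rank", "gene", "score", "mutated_sample_count"]
        )


@dataclass
class PRCurve:
    top_n: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    benchmark_name: str
    benchmark_size: int

    def at(self, n: int) -> tuple[float, float]:
        idx = int(np.searchsorted(self.top_n, n))
        if idx >= len(self.top_n) or self.top_n[idx] != n:
            raise ValidationError(f"top-{n} outside the computed curve")
        return float(self.precision[idx]), float(self.recall[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"N": self.top_n, "precision": self.precision, "recall": self.recall}
        )


def filter_and_rank(scores: irw_core.ScoreVector, mutation: MutationStatus) -> RankedList:
    """Keep mutated genes, sort by score desc then gene id asc."""
    counts = mutation.per_sample_counts
    rows = [
        (gene, float(score), int(counts[gene]))
        for gene, score in zip(scores.genes, scores.r)
        if gene in counts.index and counts[gene] >= 1
    ]
    if not rows:
        logger.warning("no mutated genes among the scored genes; empty ranking")
        return RankedList(entries=[])
    rows.sort(key=lambda t: (-t[1], t[0]))
    return RankedList(
        entries=[(i + 1, g, s, c) for i, (g, s, c) in enumerate(rows)]
    )


def precision_recall_at(
    ranked: RankedList, benchmark: GeneSet, n_max: int = 100
) -> PRCurve:
    """Top-N precision/recall for N = 1 .. min(n_max, len(ranked)).

    Benchmark genes absent from the ranking still count in the recall
    denominator (the benchmark size as given). A ranking shorter than
    n_max yields a curve that simply ends early.
    """
    if not benchmark.genes:
        raise ValidationError("benchmark gene set is empty")
    upper = min(n_max, len(ranked))
    hits = np.zeros(upper, dtype=int)
    running = 0
    for i, (_, gene, _, _) in enumerate(ranked.entries[:upper]):
        running += gene in benchmark.genes
        hits[i] = running
    top_n = np.arange(1, upper + 1)
    return PRCurve(
        top_n=top_n,
        precision=hits / top_n if upper else np.array([]),
        recall=hits / len(benchmark.genes) if upper else np.array([]),
        benchmark_name=benchmark.name,
        benchmark_size=len(benchmark.genes),
    )


def mutation_frequency_ranking(mutation: MutationStatus) -> RankedList:
    """Naive baseline: rank mutated genes by mutated-sample count."""
    counts = mutation.per_sample_counts
    rows = [(g, float(c), int(c)) for g, c in counts.items() if c >= 1]
    rows.sort(key=lambda t: (-t[1], t[0]))
    return RankedList(entries=[(i + 1, g, s, c) for i, (g, s, c) in enumerate(rows)])


@dataclass
class RunParams:
    """All tunable parameters of one pipeline run."""

    alpha_mix: float = 0.85  # teleport mixing of the transition matrix
    d: float = 0.85  # restart damping of the walk
    eps: float = 1e-8  # squared-change convergence threshold
    max_iter: int = 1000
    katz_fraction: float = 0.85  # Katz damping as a fraction of 1/lambda_1
    p_threshold: float = 0.05  # coexpression significance cutoff
    bc_undirected: bool = False  # betweenness on the undirected projection

    def as_dict(self) -> dict:
        return {
            "alpha_mix": self.alpha_mix,
            "d": self.d,
            "eps": self.eps,
            "max_iter": self.max_iter,
            "katz_fraction": self.katz_fraction,
            "p_threshold": self.p_threshold,
            "bc_undirected": self.bc_undirected,
        }


@dataclass
class PipelineInputs:
    tumor_expr: ExpressionMatrix
    normal_expr: ExpressionMatrix
    reference: DirectedNetwork
    seeds: GeneSet
    mutation: MutationStatus


@dataclass
class PreparedRun:
    """Network, centralities, transition matrices and r(0), computed once.

    Seed-dependent pieces (prior, walk, ranking) are cheap to rerun from
    here, which is what the subsampling experiment does.
    """

    net: DirectedNetwork
    bc: _centrality.CentralityVector
    kc: _centrality.CentralityVector
    katz_alpha: float
    P_biased: irw_core.TransitionMatrix
    P_uniform: irw_core.TransitionMatrix
    r0: irw_core.ScoreVector
    params: RunParams
    mutation: MutationStatus


def prepare(inputs: PipelineInputs, params: RunParams | None = None) -> PreparedRun:
    """Build the cancer network and every seed-independent artifact."""
    params = params or RunParams()
    net = network_builder.build_cancer_network(
        inputs.tumor_expr, inputs.normal_expr, inputs.reference, params.p_threshold
    )
    bc = _centrality.betweenness(net, directed=not params.bc_undirected)
    kc, katz_alpha = _centrality.katz(net, params.katz_fraction, return_alpha=True)
    return PreparedRun(
        net=net,
        bc=bc,
        kc=kc,
        katz_alpha=katz_alpha,
        P_biased=irw_core.build_transition_matrix(net, params.alpha_mix),
        P_uniform=irw_core.build_uniform_transition(net, params.alpha_mix),
        r0=irw_core.initial_scores(inputs.tumor_expr, net),
        params=params,
        mutation=inputs.mutation,
    )


def rank_from_prepared(
    prep: PreparedRun, seeds: GeneSet, mode: str = "full"
) -> tuple[RankedList, irw_core.ScoreVector]:
    """Run prior + walk + mutation filter for one mode and seed set."""
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode == "no_seeds":
        prior = irw_core.uniform_prior(prep.net)
    else:
        prior = irw_core.build_prior(seeds, prep.bc, prep.kc, prep.net)
    P = prep.P_uniform if mode == "uniform_transition" else prep.P_biased
    scores = irw_core.random_walk(
        P,
        prior,
        prep.r0,
        d=prep.params.d,
        eps=prep.params.eps,
        max_iter=prep.params.max_iter,
    )
    return filter_and_rank(scores, prep.mutation), scores


def run_pipeline(
    inputs: PipelineInputs,
    params: RunParams | None = None,
    mode: str = "full",
) -> tuple[RankedList, irw_core.ScoreVector, PreparedRun]:
    """End-to-end: network construction through the mutation-filtered ranking."""
    prep = prepare(inputs, params)
    ranked, scores = rank_from_prepared(prep, inputs.seeds, mode)
    return ranked, scores, prep


def run_ablation(
    inputs: PipelineInputs,
    benchmark: GeneSet,
    params: RunParams | None = None,
    mode: str = "full",
    n_max: int = 100,
) -> tuple[RankedList, PRCurve]:
    """One pipeline run in the given mode, evaluated against a benchmark.

    Modes: ``full`` (degree-biased transition + seed prior),
    ``uniform_transition`` (RW_UniTr: equal-neighbor transition, same seed
    prior), ``no_seeds`` (degree-biased transition, uniform 1/n restart).
    """
    ranked, _, _ = run_pipeline(inputs, params, mode)
    return ranked, precision_recall_at(ranked, benchmark, n_max)


def seed_subsampling(
    inputs: PipelineInputs,
    benchmark: GeneSet,
    fractions: tuple[float, ...] = (0.9, 0.7, 0.5),
    repeats: int = 10,
    rng_seed: int = 0,
    params: RunParams | None = None,
    n_eval: int = 100,
) -> pd.DataFrame:
    """Robustness to seed loss: delete seeds at random and re-rank.

    For each retention fraction f, draws ``repeats`` uniform random subsets
    of ceil(f * |seeds|) seeds (without replacement), reruns the
    seed-dependent half of the pipeline, and reports mean and sd of top-N
    precision ("accuracy") and recall, next to the full-seed run (fraction
    1.0). A subset that empties the usable seed set falls back to the
    uniform prior and is flagged in the ``uniform_fallbacks`` column.
    """
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValidationError(f"retention fraction {f} outside (0, 1]")
    prep = prepare(inputs, params)
    rng = np.random.default_rng(rng_seed)
    seed_list = sorted(inputs.seeds.genes)

    def _evaluate(seed_genes: set[str]) -> tuple[float, float, bool]:
        gs = GeneSet(inputs.seeds.name, seed_genes)
        ranked, _ = rank_from_prepared(prep, gs, mode="full")
        curve = precision_recall_at(ranked, benchmark, n_eval)
        n_at = min(n_eval, len(ranked))
        if n_at == 0:
            return 0.0, 0.0, False
        prec, rec = curve.at(n_at)
        fallback = not (seed_genes & set(prep.net.genes))
        return prec, rec, fallback

    rows = []
    full_prec, full_rec, _ = _evaluate(set(seed_list))
    rows.append(
        {
            "fraction": 1.0,
            "mean_precision": full_prec,
            "mean_recall": full_rec,
            "sd_precision": 0.0,
            "sd_recall": 0.0,
            "uniform_fallbacks": 0,
        }
    )
    for f in fractions:
        if f == 1.0:
            continue
        k = int(np.ceil(f * len(seed_list)))
        precs, recs, fallbacks = [], [], 0
        for _ in range(repeats):
            subset = set(rng.choice(seed_list, size=k, replace=False))
            p_, r_, fb = _evaluate(subset)
            precs.append(p_)
            recs.append(r_)
            fallbacks += fb
        rows.append(
            {
                "fraction": f,
                "mean_precision": float(np.mean(precs)),
                "mean_recall": float(np.mean(recs)),
                "sd_precision": float(np.std(precs, ddof=1)) if repeats > 1 else 0.0,
                "sd_recall": float(np.std(recs, ddof=1)) if repeats > 1 else 0.0,
                "uniform_fallbacks": fallbacks,
            }
        )
    return pd.DataFrame(rows)
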