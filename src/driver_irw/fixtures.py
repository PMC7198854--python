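"""Synthetic inputs with the statistical structure the method assumes.

The generator plants a known truth so every pipeline stage carries signal:

* a directed reference network with heavy-tailed out-degree (preferential
  attachment) plus guaranteed edges inside each planted driver block;
* expression where block genes are pairwise correlated (shared-factor
  construction ``x = sqrt(rho) * factor + sqrt(1 - rho) * noise``) in the
  tumor condition only, shifted to non-negative abundance;
* mutation tables where planted drivers are mutated at an elevated
  per-sample rate, with a configurable fraction of driver events emitted
  as GISTIC +-2 copy-number calls instead of SNVs;
* seed and benchmark sets: the benchmark is the planted-driver identity,
  the seed set covers a configurable fraction of the drivers plus decoys.

Everything is a pure function of the config (byte-identical per rng_seed).
The generator does not imitate real tumor marginals (library-size effects,
count noise); it targets the method's assumptions, not the data's realism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import ExpressionMatrix, GeneSet
from .network import DirectedNetwork


@dataclass(frozen=True)
class FixtureConfig:
    n_genes: int = 300
    n_tumor: int = 150
    n_normal: int = 150
    n_modules: int = 3  # planted tumor-only correlated blocks
    block_size: int = 10  # planted drivers per block
    within_block_correlation: float = 0.7
    pa_out_edges: int = 3  # preferential-attachment out-edges per node
    seed_overlap: float = 0.5  # fraction of drivers included in the seed set
    n_decoy_seeds: int = 10
    mutation_base_rate: float = 0.02  # per-sample mutation prob, passengers
    driver_mutation_rate: float = 0.3  # per-sample mutation prob, drivers
    cnv_event_fraction: float = 0.3  # driver events emitted as +-2 CNV calls
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tumor, self.n_normal, self.n_modules,
               self.block_size) <= 0:
            raise ValueError("all counts must be positive")
        if self.block_size * self.n_modules > self.n_genes:
            raise ValueError("planted blocks exceed the gene universe")
        for rate in (self.within_block_correlation, self.seed_overlap,
                     self.mutation_base_rate, self.driver_mutation_rate,
                     self.cnv_event_fraction):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate {rate} outside [0, 1]")

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def blocks(self) -> list[list[str]]:
        names = self.gene_names
        return [
            names[b * self.block_size : (b + 1) * self.block_size]
            for b in range(self.n_modules)
        ]

    def driver_genes(self) -> GeneSet:
        return GeneSet("planted_drivers", {g for blk in self.blocks() for g in blk})


def make_reference_network(cfg: FixtureConfig) -> DirectedNetwork:
    """Directed preferential-attachment graph plus intra-block edges.

    Each node beyond a small core emits ``pa_out_edges`` directed edges to
    targets drawn with probability proportional to in-degree + 1, giving a
    heavy-tailed degree profile. Every planted block is internally
    connected by a directed cycle plus chords, guaranteeing the block's
    edges exist in the reference for the intersection step to recover.
    """
    if cfg.pa_out_edges >= cfg.n_genes:
        raise ValueError("out-edges per node must be below the gene count")
    rng = np.random.default_rng(cfg.rng_seed)
    names = cfg.gene_names
    n = cfg.n_genes
    edges: set[tuple[int, int]] = set()
    in_deg = np.zeros(n)
    core = cfg.pa_out_edges + 1
    for i in range(1, core):
        for j in range(i):
            edges.add((i, j))
            in_deg[j] += 1
    for i in range(core, n):
        weights = in_deg[:i] + 1.0
        targets = rng.choice(i, size=min(cfg.pa_out_edges, i), replace=False,
                             p=weights / weights.sum())
        for j in targets:
            edges.add((i, int(j)))
            in_deg[j] += 1
    # guaranteed internal wiring per planted block: cycle plus skip chords
    name_to_idx = {g: i for i, g in enumerate(names)}
    for block in cfg.blocks():
        idx = [name_to_idx[g] for g in block]
        k = len(idx)
        for t in range(k):
            edges.add((idx[t], idx[(t + 1) % k]))
            if k > 2:
                edges.add((idx[t], idx[(t + 2) % k]))
    edge_list = [(names[i], names[j]) for i, j in sorted(edges) if i != j]
    return DirectedNetwork.from_edges(names, edge_list)


def _shifted_nonnegative(X: np.ndarray) -> np.ndarray:
    """Affine shift to non-negative abundance, preserving correlations."""
    return X - X.min() + 0.01


def make_expression(
    cfg: FixtureConfig, net: DirectedNetwork | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Tumor and normal expression; blocks correlate in tumor only.

    Tumor block genes follow ``x = sqrt(rho) * f + sqrt(1 - rho) * e`` with
    a per-block shared factor f, so each within-block pair has population
    correlation rho. All other genes, and all genes in the normal
    condition, are independent standard normals before the non-negativity
    shift (which is affine and leaves correlations untouched).
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    names = cfg.gene_names
    rho = cfg.within_block_correlation
    tumor = rng.standard_normal((cfg.n_genes, cfg.n_tumor))
    normal = rng.standard_normal((cfg.n_genes, cfg.n_normal))
    name_to_idx = {g: i for i, g in enumerate(names)}
    for block in cfg.blocks():
        factor = rng.standard_normal(cfg.n_tumor)
        for g in block:
            i = name_to_idx[g]
            tumor[i] = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * tumor[i]
    t_samples = [f"t{j:03d}" for j in range(cfg.n_tumor)]
    n_samples = [f"n{j:03d}" for j in range(cfg.n_normal)]
    return (
        ExpressionMatrix(names, t_samples, _shifted_nonnegative(tumor), "tumor"),
        ExpressionMatrix(names, n_samples, _shifted_nonnegative(normal), "normal"),
    )


def make_mutation_data(
    cfg: FixtureConfig, drivers: GeneSet | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bernoulli SNV and GISTIC CNV tables over the tumor samples.

    Drivers mutate per sample at ``driver_mutation_rate``, passengers at
    ``mutation_base_rate``. A ``cnv_event_fraction`` of driver events is
    emitted as a +-2 copy-number call instead of an SNV (exercising the
    high-level-amplification / homozygous-deletion rule downstream).
    """
    drivers = drivers or cfg.driver_genes()
    rng = np.random.default_rng(cfg.rng_seed + 2)
    names = cfg.gene_names
    samples = [f"t{j:03d}" for j in range(cfg.n_tumor)]
    is_driver = np.array([g in drivers.genes for g in names])
    rates = np.where(is_driver, cfg.driver_mutation_rate, cfg.mutation_base_rate)
    events = rng.random((cfg.n_genes, cfg.n_tumor)) < rates[:, None]
    as_cnv = events & is_driver[:, None] & (
        rng.random((cfg.n_genes, cfg.n_tumor)) < cfg.cnv_event_fraction
    )
    snv = (events & ~as_cnv).astype(int)
    sign = np.where(rng.random((cfg.n_genes, cfg.n_tumor)) < 0.5, 2, -2)
    cnv = np.where(as_cnv, sign, 0)
    snv_df = pd.DataFrame(snv, index=names, columns=samples)
    cnv_df = pd.DataFrame(cnv, index=names, columns=samples)
    return snv_df, cnv_df


def make_gene_sets(
    cfg: FixtureConfig, drivers: GeneSet | None = None
) -> tuple[GeneSet, GeneSet]:
    """Seeds (partial driver coverage plus decoys) and benchmark (drivers)."""
    drivers = drivers or cfg.driver_genes()
    rng = np.random.default_rng(cfg.rng_seed + 3)
    driver_list = sorted(drivers.genes)
    k = int(round(cfg.seed_overlap * len(driver_list)))
    chosen = set(rng.choice(driver_list, size=k, replace=False)) if k else set()
    non_drivers = sorted(set(cfg.gene_names) - drivers.genes)
    n_decoys = min(cfg.n_decoy_seeds, len(non_drivers))
    decoys = set(rng.choice(non_drivers, size=n_decoys, replace=False)) if n_decoys else set()
    seeds = GeneSet("seeds", chosen | decoys)
    benchmark = GeneSet("benchmark", set(driver_list))
    return seeds, benchmark


def make_inputs(cfg: FixtureConfig):
    """Assemble the full pipeline input bundle for one config."""
    from .data_io import build_mutation_status
    from .rank_eval import PipelineInputs

    net = make_reference_network(cfg)
    tumor, normal = make_expression(cfg, net)
    drivers = cfg.driver_genes()
    snv, cnv = make_mutation_data(cfg, drivers)
    seeds, benchmark = make_gene_sets(cfg, drivers)
    mutation = build_mutation_status(snv, cnv)
    inputs = PipelineInputs(
        tumor_expr=tumor,
        normal_expr=normal,
        reference=net,
        seeds=seeds,
        mutation=mutation,
    )
    return inputs, benchmark


def write_bundle(cfg: FixtureConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the complete input bundle in the dialects the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = make_reference_network(cfg)
    tumor, normal = make_expression(cfg, net)
    drivers = cfg.driver_genes()
    snv, cnv = make_mutation_data(cfg, drivers)
    seeds, benchmark = make_gene_sets(cfg, drivers)

    paths = {
        "tumor_expr": outdir / "tumor_expression.tsv",
        "normal_expr": outdir / "normal_expression.tsv",
        "network": outdir / "reference_network.tsv",
        "snv": outdir / "snv_matrix.tsv",
        "cnv": outdir / "cnv_gistic.tsv",
        "seeds": outdir / "seed_genes.txt",
        "benchmark": outdir / "benchmark_genes.txt",
        "config": outdir / "fixture_config.yaml",
    }
    tumor.to_frame().to_csv(paths["tumor_expr"], sep="\t", float_format="%.6f")
    normal.to_frame().to_csv(paths["normal_expr"], sep="\t", float_format="%.6f")
    with open(paths["network"], "w") as fh:
        for src, dst in net.edges():
            fh.write(f"{src}\t{dst}\n")
    snv.to_csv(paths["snv"], sep="\t")
    cnv.to_csv(paths["cnv"], sep="\t")
    for key, gs in (("seeds", seeds), ("benchmark", benchmark)):
        with open(paths[key], "w") as fh:
            for g in sorted(gs.genes):
                fh.write(g + "\n")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
    return paths
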