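"""Readers and writers for the pipeline's standard tabular inputs.

Formats handled here:

* expression — TSV, genes in rows, samples in columns, header row present;
* directed network — two-column TSV edge list (source TAB target);
* gene sets — plain text, one symbol per line;
* SNV — binary gene x sample TSV matrix, or a two-column (gene, sample)
  pair list (the reduction of a MAF);
* CNV — integer gene x sample TSV in the GISTIC thresholded convention
  {-2, -1, 0, 1, 2};
* rankings — TSV with rank, gene, score, mutated_sample_count.

Gene identifiers are opaque case-sensitive strings: no aliasing, no ID
mapping. Missing expression values are a hard error, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import DirectedNetwork

logger = logging.getLogger(__name__)

GISTIC_VALUES = frozenset({-2, -1, 0, 1, 2})


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Well-formed input that violates a contract."""


@dataclass
class ExpressionMatrix:
    """Normalized abundance per gene per sample for one condition."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # (n_genes, n_samples), non-negative
    condition: str  # "tumor" or "normal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError("expression shape does not match gene/sample labels")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene identifiers in expression matrix")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample identifiers in expression matrix")
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def mean_per_gene(self) -> pd.Series:
        return pd.Series(self.values.mean(axis=1), index=self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class MutationStatus:
    """Cohort-level mutation flag per gene.

    A gene counts as mutated in a sample if it carries an SNV there or a
    GISTIC call of +2 (high-level amplification) or -2 (homozygous
    deletion); it is mutated overall if mutated in at least one sample.
    """

    genes: list[str]
    per_sample_counts: pd.Series  # int count of mutated samples, indexed by gene

    def __post_init__(self) -> None:
        self.per_sample_counts = self.per_sample_counts.reindex(self.genes).fillna(0)
        if (self.per_sample_counts < 0).any():
            raise ValidationError("negative mutated-sample count")
        self.per_sample_counts = self.per_sample_counts.astype(int)

    def is_mutated(self, gene: str) -> bool:
        return gene in self.per_sample_counts.index and bool(
            self.per_sample_counts[gene] >= 1
        )

    @property
    def mutated_genes(self) -> set[str]:
        return set(self.per_sample_counts.index[self.per_sample_counts >= 1])


@dataclass
class GeneSet:
    name: str
    genes: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def read_expression(path: str | Path, condition: str) -> ExpressionMatrix:
    """Read a genes-in-rows expression TSV with a sample header row."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty expression file")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse expression TSV: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: expression file has no data rows")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene rows {dups}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        if bad.isna().any() and not df[col].isna().any():
            row = df.index[bad.isna()][0]
            raise ParseError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"{path}: missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=values,
        condition=condition,
    )


def read_network(path: str | Path, directed: bool = True) -> DirectedNetwork:
    """Read a two-column edge list into a directed 0-1 adjacency.

    Self-loops are dropped with a warning; duplicate edges collapse to one.
    With ``directed=False`` every edge is mirrored.
    """
    path = Path(path)
    genes: list[str] = []
    seen: set[str] = set()
    edges: list[tuple[str, str]] = []
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            src, dst = fields[0].strip(), fields[1].strip()
            for g in (src, dst):
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
            if src == dst:
                n_loops += 1
                continue
            edges.append((src, dst))
            if not directed:
                edges.append((dst, src))
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    return DirectedNetwork.from_edges(genes, edges)


def _read_gene_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TSV with a header row, returning a numeric frame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValidationError(f"{path}: duplicate gene rows")
    return df


def read_snv(path: str | Path) -> pd.DataFrame:
    """Read SNV calls in either supported dialect.

    A header starting with ``gene<TAB>sample`` marks the pair-list dialect
    (one mutated gene/sample pair per line, the reduction of a MAF);
    anything else is treated as a binary gene x sample matrix.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if [h.strip().lower() for h in header[:2]] == ["gene", "sample"]:
        pairs = pd.read_csv(path, sep="\t")
        pairs.columns = [c.strip().lower() for c in pairs.columns]
        mat = pd.crosstab(pairs["gene"], pairs["sample"]).clip(upper=1)
        mat.index.name = None
        mat.columns.name = None
        return mat
    df = _read_gene_sample_table(path)
    if not df.isin([0, 1]).all().all():
        raise ValidationError(f"{path}: SNV matrix entries must be 0 or 1")
    return df.astype(int)


def read_cnv(path: str | Path) -> pd.DataFrame:
    """Read a GISTIC-thresholded CNV matrix; values must lie in {-2..2}."""
    df = _read_gene_sample_table(path)
    if not df.isin(GISTIC_VALUES).all().all():
        bad = sorted(set(df.to_numpy().ravel()) - GISTIC_VALUES)
        raise ValidationError(f"{path}: CNV values outside GISTIC range: {bad}")
    return df.astype(int)


def build_mutation_status(
    snv_table: pd.DataFrame | None, cnv_table: pd.DataFrame | None
) -> MutationStatus:
    """Combine SNV and CNV evidence into per-gene mutated-sample counts.

    Gene g is mutated in sample s iff ``snv[g, s] == 1`` or
    ``cnv[g, s] in {-2, +2}`` (high-level amplification or homozygous
    deletion only; low-level gains and losses do not count). Gene and
    sample universes are the outer union; absent cells count as 0.
    """
    if snv_table is None and cnv_table is None:
        raise ValidationError("at least one of SNV/CNV tables is required")
    frames = []
    if snv_table is not None:
        if not snv_table.isin([0, 1]).all().all():
            raise ValidationError("SNV table entries must be 0 or 1")
        frames.append(snv_table.astype(bool))
    if cnv_table is not None:
        if not cnv_table.isin(GISTIC_VALUES).all().all():
            raise ValidationError("CNV values outside the GISTIC range {-2..2}")
        frames.append(cnv_table.abs() == 2)
    genes = sorted(set().union(*(f.index for f in frames)))
    samples = sorted(set().union(*(f.columns for f in frames)))
    hit = pd.DataFrame(False, index=genes, columns=samples)
    for f in frames:
        aligned = f.reindex(index=genes, columns=samples, fill_value=False)
        hit |= aligned
    counts = hit.sum(axis=1)
    return MutationStatus(genes=genes, per_sample_counts=counts)


def read_gene_set(path: str | Path, name: str) -> GeneSet:
    """Read a one-symbol-per-line gene list; blank lines ignored."""
    path = Path(path)
    genes = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g:
                genes.add(g)
    logger.info("%s: read %d unique genes for set %r", path, len(genes), name)
    return GeneSet(name=name, genes=genes)


def require_nonempty_seeds(seeds: GeneSet) -> GeneSet:
    if not seeds.genes:
        raise ValidationError(f"seed set {seeds.name!r} is empty")
    return seeds


SCORE_PRECISION = 12


def write_ranking(ranked, path: str | Path) -> None:
    """Write a ranking as TSV: rank, gene, score, mutated_sample_count."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("rank\tgene\tscore\tmutated_sample_count\n")
        for rank, gene, score, count in ranked.entries:
            fh.write(f"{rank}\t{gene}\t{score:.{SCORE_PRECISION}f}\t{count}\n")


def read_ranking(path: str | Path):
    """Read back a ranking written by :func:`write_ranking`."""
    from .rank_eval import RankedList

    df = pd.read_csv(path, sep="\t")
    entries = [
        (int(r), str(g), float(s), int(c))
        for r, g, s, c in zip(
            df["rank"], df["gene"], df["score"], df["mutated_sample_count"]
        )
    ]
    return RankedList(entries=entries)
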