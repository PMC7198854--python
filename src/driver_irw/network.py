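"""Directed network container shared across the pipeline.

The walk, the centralities, and the network construction all operate on the
same object: an ordered list of gene identifiers plus a 0-1 adjacency matrix
``A`` with ``A[i, j] = 1`` iff there is a directed edge ``i -> j``. Self-loops
are disallowed by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


@dataclass
class DirectedNetwork:
    """A directed graph over named genes with 0-1 adjacency.

    Parameters
    ----------
    genes
        Ordered node identifiers (unique).
    A
        ``n x n`` sparse 0-1 adjacency, ``A[i, j] = 1`` iff edge ``i -> j``.
        The diagonal must be empty.
    """

    genes: list[str]
    A: sp.csr_matrix
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers in network")
        self.A = sp.csr_matrix(self.A, dtype=np.int8)
        if self.A.shape != (len(self.genes), len(self.genes)):
            raise ValueError(
                f"adjacency shape {self.A.shape} does not match {len(self.genes)} genes"
            )
        if self.A.diagonal().any():
            raise ValueError("adjacency has self-loops")
        if self.A.nnz and not np.isin(self.A.data, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.A.sum())

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def out_degrees(self) -> np.ndarray:
        """Row sums of A: out-degree per node, integer valued."""
        return np.asarray(self.A.sum(axis=1)).ravel().astype(np.int64)

    def edges(self) -> list[tuple[str, str]]:
        rows, cols = self.A.nonzero()
        return [(self.genes[i], self.genes[j]) for i, j in zip(rows, cols)]

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_edges(
        cls, genes: list[str], edges: list[tuple[str, str]]
    ) -> "DirectedNetwork":
        """Build from an explicit node list and directed edge list.

        Duplicate edges collapse to one; self-loops are rejected here (the
        I/O layer drops them with a warning before reaching this point).
        """
        index = {g: i for i, g in enumerate(genes)}
        rows, cols = [], []
        seen: set[tuple[int, int]] = set()
        for src, dst in edges:
            i, j = index[src], index[dst]
            if i == j:
                raise ValueError(f"self-loop on {src!r}")
            if (i, j) not in seen:
                seen.add((i, j))
                rows.append(i)
                cols.append(j)
        n = len(genes)
        A = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
        )
        return cls(genes, A)
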