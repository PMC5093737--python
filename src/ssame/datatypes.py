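"""Core domain types shared by all ssame modules.

Gene and sample identifiers are case-sensitive opaque strings; no symbol
normalization is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneNetwork",
    "AlterationMatrix",
    "SmallSubnetwork",
    "SSAMEParams",
    "RankedEntry",
    "RankedGeneList",
]


class GeneNetwork:
    """Undirected interaction network over gene identifiers.

    Invariants: no self-loops, no duplicate edges, symmetric adjacency,
    every edge endpoint is a node.  Isolated nodes are allowed (e.g. genes
    that only appeared in self-loop records).
    """

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        self._adj: dict[str, set[str]] = {}
        for n in nodes:
            self._adj.setdefault(n, set())
        for u, v in edges:
            self.add_edge(u, v)
        self._index_cache: "IndexedNetwork | None" = None

    # -- construction -----------------------------------------------------
    def add_node(self, n: str) -> None:
        self._adj.setdefault(n, set())
        self._index_cache = None

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop not allowed: {u!r}")
        self._adj.setdefault(u, set()).add(v)
        self._adj.setdefault(v, set()).add(u)
        self._index_cache = None

    def remove_edge(self, u: str, v: str) -> None:
        self._adj[u].discard(v)
        self._adj[v].discard(u)
        self._index_cache = None

    # -- queries ----------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        """Nodes in sorted order."""
        return sorted(self._adj)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edges as sorted (u, v) tuples with u < v."""
        out = set()
        for u, nbrs in self._adj.items():
            for v in nbrs:
                if u < v:
                    out.add((u, v))
        return out

    def neighbors(self, n: str) -> set[str]:
        return set(self._adj[n])

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    def degree(self, n: str) -> int:
        return len(self._adj[n])

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self._adj.values()) // 2

    def __contains__(self, n: str) -> bool:
        return n in self._adj

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        return self._adj == other._adj

    def __repr__(self) -> str:
        return f"GeneNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def copy(self) -> "GeneNetwork":
        g = GeneNetwork()
        g._adj = {n: set(s) for n, s in self._adj.items()}
        return g

    def subgraph_is_connected(self, genes: Sequence[str]) -> bool:
        gs = set(genes)
        if not gs:
            return True
        start = next(iter(gs))
        seen = {start}
        stack = [start]
        while stack:
            for nb in self._adj[stack.pop()] & gs:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen == gs

    def indexed(self) -> "IndexedNetwork":
        """Integer-indexed view (cached) used by the hot sampling loops."""
        if self._index_cache is None:
            self._index_cache = IndexedNetwork(self)
        return self._index_cache


class IndexedNetwork:
    """Array-backed view of a :class:`GeneNetwork` for fast sampling.

    Gene index = position in the sorted node list, so lexicographic
    tie-breaks reduce to integer comparisons.
    """

    def __init__(self, net: GeneNetwork):
        self.genes: list[str] = net.nodes
        self.index: dict[str, int] = {g: i for i, g in enumerate(self.genes)}
        # plain python int lists: fastest to iterate in the grow loop
        self.neighbors: list[list[int]] = [
            sorted(self.index[v] for v in net.neighbors(g)) for g in self.genes
        ]

    @property
    def n_genes(self) -> int:
        return len(self.genes)


class AlterationMatrix:
    """Binary gene x sample indicator of genomic alterations."""

    def __init__(self, genes: Sequence[str], samples: Sequence[str], values):
        genes = list(genes)
        samples = list(samples)
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene identifiers")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers")
        arr = np.asarray(values)
        if arr.shape != (len(genes), len(samples)):
            raise ValueError(
                f"values shape {arr.shape} != ({len(genes)}, {len(samples)})"
            )
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("indicator values must be exactly 0 or 1")
        self.genes = genes
        self.samples = samples
        self.values = arr.astype(np.uint8)
        self.gene_index = {g: i for i, g in enumerate(genes)}
        self.sample_index = {s: i for i, s in enumerate(samples)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def altered(self, gene: str, sample: str) -> int:
        return int(self.values[self.gene_index[gene], self.sample_index[sample]])

    def gene_counts(self) -> pd.Series:
        """Number of altered samples per gene."""
        return pd.Series(self.values.sum(axis=1), index=self.genes)

    def sample_counts(self) -> pd.Series:
        """Number of altered genes per sample (column sums)."""
        return pd.Series(self.values.sum(axis=0), index=self.samples)

    def altered_genes(self) -> list[str]:
        """Genes altered in at least one sample, sorted."""
        mask = self.values.sum(axis=1) > 0
        return sorted(g for g, m in zip(self.genes, mask) if m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlterationMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.samples == other.samples
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"AlterationMatrix({self.n_genes} genes x {self.n_samples} samples)"


@dataclass
class SmallSubnetwork:
    """A connected gene set grown around a seed, with its exclusivity scores.

    ``genes`` is ordered by descending alteration count (ties broken
    lexicographically) once scored; ``mes``/``rmes`` are ``None`` until set.
    """

    genes: tuple[str, ...]
    seed: str
    mes: float | None = None
    rmes: float | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def key(self) -> tuple[str, ...]:
        """Identity of the gene set, order-independent."""
        return tuple(sorted(self.genes))


@dataclass
class SSAMEParams:
    """Run parameters.

    Defaults follow the published settings: forgetfulness 0.995,
    reinforcement 0.005, 5000 iterations, subnetwork sizes cycling 3-6.
    Early stopping halts the run once the top-``early_stop_k`` gene set by
    current score has been unchanged for ``early_stop_patience`` consecutive
    iterations; it is skipped when the network has <= ``early_stop_k`` genes
    (the set could never change).
    """

    forgetfulness: float = 0.995
    reinforcement: float = 0.005
    iterations: int = 5000
    sizes: tuple[int, ...] = (3, 4, 5, 6)
    rng_seed: int = 0
    bootstrap_B: int = 1000
    bootstrap_support: float = 0.95
    early_stop: bool = True
    early_stop_k: int = 100
    early_stop_patience: int = 500

    def __post_init__(self) -> None:
        if not (0.0 < self.reinforcement < 1.0):
            raise ValueError("reinforcement must be in (0, 1)")
        if not (0.0 < self.forgetfulness <= 1.0):
            raise ValueError("forgetfulness must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        self.sizes = tuple(int(s) for s in self.sizes)
        if not self.sizes or any(s < 2 for s in self.sizes):
            raise ValueError("every subnetwork size must be >= 2")
        if self.bootstrap_B < 0:
            raise ValueError("bootstrap_B must be >= 0")


@dataclass
class RankedEntry:
    gene: str
    rank: int
    max_score: float
    convergence_iter: int
    bootstrap_threshold: int | None = None
    bootstrap_support: float | None = None


@dataclass
class RankedGeneList:
    """Final prioritization, best gene first."""

    entries: list[RankedEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[RankedEntry]:
        return iter(self.entries)

    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def rank_of(self) -> Mapping[str, int]:
        return {e.gene: e.rank for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [e.gene for e in self.entries],
                "rank": [e.rank for e in self.entries],
                "max_score": [e.max_score for e in self.entries],
                "convergence_iter": [e.convergence_iter for e in self.entries],
                "bootstrap_threshold": [e.bootstrap_threshold for e in self.entries],
                "bootstrap_support": [e.bootstrap_support for e in self.entries],
            }
        )
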