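"""Synthetic-data generation: test networks, network perturbations,
walker-selected target gene sets and alteration matrices with a planted
mutually exclusive module.

A simulated study plants a connected "target" set of up to 20 genes, picked
by a random walk with restart from a random start gene, and mutates it in an
(almost) mutually exclusive fashion across a configurable fraction of
samples, on top of per-sample background alterations.  The analysis can then
be run against the original network or an edge-perturbed version of it.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .datatypes import AlterationMatrix, GeneNetwork
from .io import write_alterations, write_network

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "StudyBundle",
    "generate_test_network",
    "perturb_network",
    "sample_target_set",
    "generate_alterations",
    "simulate_study",
]

# Stand-in background density: roughly 50 altered genes per tumor sample over
# a ~15k-gene reference network.  Desk-scale networks auto-scale the mean so
# the per-gene background alteration rate matches that setting instead of
# swamping a small gene universe.
BACKGROUND_MEAN_FULL_SCALE = 50.0
REFERENCE_NETWORK_GENES = 15000
BACKGROUND_DISPERSION = 5.0


@dataclass
class SimulationConfig:
    """Knobs of the simulated-study generator.

    ``background_counts`` is either an explicit per-sample alteration count
    list, a ``("nbinom", mean, dispersion)`` tuple, or ``None`` for the
    auto-scaled negative-binomial stand-in (mean proportional to the number
    of background genes; see module constants).
    """

    n_samples: int = 300
    target_fraction: float = 0.30
    co_mutation_prob: float = 0.05
    restart_prob: float = 0.05
    max_target_edges: int = 20
    max_target_genes: int = 20
    background_counts: Sequence[int] | tuple | None = None
    perturbation: tuple[str, float] = ("none", 0.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fraction <= 1.0):
            raise ValueError("target_fraction must be in [0, 1]")
        if not (0.0 <= self.co_mutation_prob <= 1.0):
            raise ValueError("co_mutation_prob must be in [0, 1]")
        if not (0.0 < self.restart_prob <= 1.0):
            raise ValueError("restart_prob must be in (0, 1]")
        mode = self.perturbation[0]
        if mode not in ("none", "delete", "add"):
            raise ValueError(f"unknown perturbation mode {mode!r}")


@dataclass
class StudyBundle:
    network: GeneNetwork
    perturbed_network: GeneNetwork
    matrix: AlterationMatrix
    truth: set[str] = field(default_factory=set)
    config: SimulationConfig | None = None


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def generate_test_network(
    n_nodes: int, mean_degree: float, rng: np.random.Generator
) -> GeneNetwork:
    """Connected scale-free-like network with exactly round(n*k/2) edges.

    Built by preferential attachment, then topped up with uniform random
    extra edges to hit the exact edge count.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    target_edges = round(n_nodes * mean_degree / 2.0)
    max_edges = n_nodes * (n_nodes - 1) // 2
    m = max(1, int(mean_degree // 2))
    if m >= n_nodes or target_edges > max_edges or target_edges < n_nodes - 1:
        raise ValueError(
            f"infeasible mean degree {mean_degree} for {n_nodes} nodes"
        )
    g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
    width = len(str(n_nodes - 1))
    net = GeneNetwork(nodes=(_gene_name(i, width) for i in range(n_nodes)))
    for u, v in g.edges():
        net.add_edge(_gene_name(u, width), _gene_name(v, width))
    deficit = target_edges - net.n_edges
    if deficit < 0:
        raise ValueError("preferential attachment overshot the edge budget")
    _add_random_edges(net, deficit, rng)
    return net


def _add_random_edges(net: GeneNetwork, k: int, rng: np.random.Generator) -> None:
    """Insert k new edges uniformly over non-adjacent node pairs."""
    nodes = net.nodes
    n = len(nodes)
    free = n * (n - 1) // 2 - net.n_edges
    if k > free:
        raise ValueError(f"cannot add {k} edges: only {free} node pairs free")
    added = 0
    attempts = 0
    max_attempts = 200 * max(k, 1) + 10000
    while added < k and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(n, size=2)
        if i == j:
            continue
        u, v = nodes[int(i)], nodes[int(j)]
        if net.has_edge(u, v):
            continue
        net.add_edge(u, v)
        added += 1
    if added < k:  # dense graph: fall back to explicit enumeration
        candidates = [
            (nodes[a], nodes[b])
            for a in range(n)
            for b in range(a + 1, n)
            if not net.has_edge(nodes[a], nodes[b])
        ]
        picks = rng.choice(len(candidates), size=k - added, replace=False)
        for p in picks:
            net.add_edge(*candidates[int(p)])


def perturb_network(
    net: GeneNetwork, mode: str, fraction: float, rng: np.random.Generator
) -> GeneNetwork:
    """Delete or add ``round(fraction * |E|)`` edges; the node set is kept."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    k = round(fraction * net.n_edges)
    out = net.copy()
    if mode == "delete":
        edges = sorted(net.edges)
        picks = rng.choice(len(edges), size=k, replace=False)
        for p in picks:
            out.remove_edge(*edges[int(p)])
    elif mode == "add":
        _add_random_edges(out, k, rng)
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    return out


def sample_target_set(
    net: GeneNetwork,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    step_cap: int = 100_000,
) -> list[str]:
    """Select a connected target gene set by random walk with restart.

    Starts at a uniform random node; each step restarts to the start node
    with probability ``cfg.restart_prob``, else moves to a uniform random
    neighbor, accumulating distinct traversed edges until
    ``cfg.max_target_edges`` have been visited or ``step_cap`` steps have
    been taken.  The distinct endpoint genes are returned in visit order,
    truncated to ``cfg.max_target_genes``.
    """
    nodes = net.nodes
    if not nodes:
        raise ValueError("empty network")
    start = nodes[int(rng.integers(len(nodes)))]
    tries = 0
    while net.degree(start) == 0:
        tries += 1
        if tries > 1000:
            raise ValueError("could not find a non-isolated start node")
        start = nodes[int(rng.integers(len(nodes)))]

    visited_edges: set[tuple[str, str]] = set()
    genes: list[str] = [start]
    gene_set = {start}
    current = start
    neigh = {g: sorted(net.neighbors(g)) for g in nodes}
    for _ in range(step_cap):
        if len(visited_edges) >= cfg.max_target_edges:
            break
        if rng.random() < cfg.restart_prob:
            current = start
            continue
        nbrs = neigh[current]
        nxt = nbrs[int(rng.integers(len(nbrs)))]
        edge = (current, nxt) if current < nxt else (nxt, current)
        visited_edges.add(edge)
        if nxt not in gene_set:
            gene_set.add(nxt)
            genes.append(nxt)
        current = nxt
    return genes[: cfg.max_target_genes]


def _background_counts(
    cfg: SimulationConfig, n_background_genes: int, rng: np.random.Generator
) -> np.ndarray:
    bc = cfg.background_counts
    if bc is None:
        mean = max(
            1.0,
            BACKGROUND_MEAN_FULL_SCALE * n_background_genes / REFERENCE_NETWORK_GENES,
        )
        bc = ("nbinom", mean, BACKGROUND_DISPERSION)
    if isinstance(bc, tuple) and len(bc) == 3 and bc[0] == "nbinom":
        _, mean, disp = bc
        p = disp / (disp + mean)
        return rng.negative_binomial(disp, p, size=cfg.n_samples)
    counts = np.asarray(list(bc), dtype=np.int64)
    if len(counts) != cfg.n_samples:
        raise ValueError(
            f"explicit background_counts length {len(counts)} != "
            f"n_samples {cfg.n_samples}"
        )
    if (counts < 0).any():
        raise ValueError("background counts must be non-negative")
    return counts


def generate_alterations(
    net: GeneNetwork,
    target: Sequence[str],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[AlterationMatrix, set[str]]:
    """Simulated gene x sample matrix with a planted exclusive target module.

    Background: each sample receives its drawn count of alterations at
    distinct uniformly chosen non-target genes.  Signal: exactly
    ``round(target_fraction * n_samples)`` samples each get one alteration in
    one target gene, assigned round-robin over a random permutation of the
    targets so per-gene counts are near-uniform.  Noise: each signal sample
    independently gains one extra alteration in a different target gene with
    probability ``co_mutation_prob``.
    """
    target = list(target)
    missing = [g for g in target if g not in net]
    if missing:
        raise ValueError(f"target genes not in network: {missing}")
    genes = net.nodes
    gi = {g: i for i, g in enumerate(genes)}
    target_set = set(target)
    background_genes = [g for g in genes if g not in target_set]
    n = cfg.n_samples
    width = len(str(max(n - 1, 1)))
    samples = [f"S{i:0{width}d}" for i in range(n)]
    values = np.zeros((len(genes), n), dtype=np.uint8)

    counts = _background_counts(cfg, len(background_genes), rng)
    bg_idx = np.array([gi[g] for g in background_genes])
    for s, k in enumerate(counts):
        k = int(min(k, len(bg_idx)))
        if k:
            picks = rng.choice(len(bg_idx), size=k, replace=False)
            values[bg_idx[picks], s] = 1

    n_signal = round(cfg.target_fraction * n)
    if target and n_signal < len(target):
        warnings.warn(
            f"only {n_signal} signal samples for {len(target)} target genes: "
            "some target genes stay unmutated", stacklevel=2,
        )
    signal_samples = rng.choice(n, size=n_signal, replace=False)
    perm = rng.permutation(len(target))
    for j, s in enumerate(signal_samples):
        g = target[int(perm[j % len(target)])]
        values[gi[g], s] = 1
        if len(target) > 1 and rng.random() < cfg.co_mutation_prob:
            others = [t for t in target if t != g]
            extra = others[int(rng.integers(len(others)))]
            values[gi[extra], s] = 1

    mat = AlterationMatrix(genes, samples, values)
    return mat, set(target)


def simulate_study(
    cfg: SimulationConfig,
    net: GeneNetwork,
    out_dir: str | Path | None = None,
) -> StudyBundle:
    """Compose target selection, alteration generation and perturbation.

    One master seed (``cfg.rng_seed``) drives everything.  When ``out_dir``
    is given the bundle is serialized as network.tsv,
    network_perturbed.tsv, matrix.tsv, truth.txt and config.json.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    target = sample_target_set(net, cfg, rng)
    mat, truth = generate_alterations(net, target, cfg, rng)
    mode, fraction = cfg.perturbation
    if mode == "none" or fraction == 0.0:
        perturbed = net.copy()
    else:
        perturbed = perturb_network(net, mode, fraction, rng)
    bundle = StudyBundle(
        network=net, perturbed_network=perturbed, matrix=mat,
        truth=truth, config=cfg,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_network(net, out / "network.tsv")
        write_network(perturbed, out / "network_perturbed.tsv")
        write_alterations(mat, out / "matrix.tsv")
        with open(out / "truth.txt", "w", encoding="utf-8", newline="\n") as fh:
            for g in sorted(truth):
                fh.write(g + "\n")
        cfg_dict = {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in vars(cfg).items()
        }
        with open(out / "config.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(cfg_dict, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return bundle
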