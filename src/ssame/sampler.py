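"""Stochastic growth of small subnetworks around seed genes.

One subnetwork is grown per seed gene per iteration.  Growth starts at the
seed and repeatedly draws one frontier gene (a non-member neighbor of the
current members) with probability proportional to its current gene score;
a zero-mass frontier falls back to a uniform draw so growth cannot deadlock
when scores have decayed to zero.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .datatypes import AlterationMatrix, GeneNetwork, SmallSubnetwork

logger = logging.getLogger(__name__)

__all__ = ["eligible_seeds", "grow_subnetwork", "iteration_size"]


def eligible_seeds(net: GeneNetwork, mat: AlterationMatrix) -> list[str]:
    """Seed genes: altered in >= 1 sample and present in the network, sorted.

    Raises if no gene qualifies.
    """
    altered = mat.altered_genes()
    seeds = [g for g in altered if g in net]
    excluded = len(altered) - len(seeds)
    if excluded:
        logger.warning(
            "%d altered gene(s) absent from the network cannot seed or join "
            "subnetworks", excluded,
        )
    if not seeds:
        raise ValueError("no usable seed genes (no altered gene is in the network)")
    return seeds


def iteration_size(iteration: int, sizes: Sequence[int]) -> int:
    """Subnetwork size for an iteration: a fixed cycle over ``sizes``."""
    if not sizes:
        raise ValueError("sizes must be non-empty")
    return sizes[iteration % len(sizes)]


def _grow_indexed(
    seed_i: int,
    scores: np.ndarray,
    neighbors: list[list[int]],
    size: int,
    rng: np.random.Generator,
) -> list[int] | None:
    """Index-based growth core.  Returns member indices or None if stalled
    below two genes (isolated seed)."""
    members = [seed_i]
    member_set = {seed_i}
    frontier = list(neighbors[seed_i])
    seen = set(frontier)
    while len(members) < size and frontier:
        w = scores[frontier]
        total = w.sum()
        if total > 0.0:
            cut = rng.random() * total
            c = int(np.searchsorted(np.cumsum(w), cut, side="right"))
            if c >= len(frontier):  # guard against fp edge at cut == total
                c = len(frontier) - 1
        else:
            c = int(rng.integers(len(frontier)))
        g = frontier[c]
        frontier[c] = frontier[-1]
        frontier.pop()
        members.append(g)
        member_set.add(g)
        for nb in neighbors[g]:
            if nb not in member_set and nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    if len(members) < 2:
        return None
    return members


def grow_subnetwork(
    seed: str,
    scores,
    net: GeneNetwork,
    size: int,
    rng: np.random.Generator,
) -> SmallSubnetwork | None:
    """Grow one subnetwork from ``seed``.

    ``scores`` is either a :class:`~ssame.reinforce.GeneScoreState` or a
    mapping from gene id to score; genes without a score count as 0.
    Returns ``None`` for an isolated seed (which then receives the
    no-subnetwork score update).  Under-size subnetworks (growth stalled
    with 2 <= |V| < size) are returned and scored normally.
    """
    if seed not in net:
        raise KeyError(f"seed {seed!r} not in network")
    if size < 2:
        raise ValueError("size must be >= 2")
    idx = net.indexed()
    score_of = scores.score_of if hasattr(scores, "score_of") else (
        lambda g: float(scores.get(g, 0.0))
    )
    vec = np.array([score_of(g) for g in idx.genes], dtype=np.float64)
    members = _grow_indexed(idx.index[seed], vec, idx.neighbors, size, rng)
    if members is None:
        return None
    return SmallSubnetwork(
        genes=tuple(idx.genes[i] for i in members), seed=seed
    )
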