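"""Sample-level bootstrap of the full run and the minimal-rank-threshold
support ranking.

Each bootstrap replicate resamples the tumor samples with replacement
(keeping the sample count), reruns the full algorithm and records every
gene's rank.  A gene's final key is the smallest rank threshold t at which
it was ranked <= t in at least a ``support`` fraction of replicates; genes
attaining support at a stricter (smaller) threshold rank higher.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    AlterationMatrix,
    GeneNetwork,
    RankedEntry,
    RankedGeneList,
    SSAMEParams,
)
from .reinforce import run_ssa_me

logger = logging.getLogger(__name__)

__all__ = ["resample_samples", "bootstrap_rank", "support_table"]


def resample_samples(
    mat: AlterationMatrix, rng: np.random.Generator
) -> AlterationMatrix:
    """Draw an equal number of samples i.i.d. with replacement.

    Duplicated samples get ``#k`` suffixes so identifiers stay unique.
    """
    if mat.n_samples < 1:
        raise ValueError("matrix has no samples")
    picks = rng.integers(mat.n_samples, size=mat.n_samples)
    seen: dict[str, int] = {}
    names = []
    for i in picks:
        base = mat.samples[i]
        k = seen.get(base, 0)
        seen[base] = k + 1
        names.append(base if k == 0 else f"{base}#{k}")
    return AlterationMatrix(list(mat.genes), names, mat.values[:, picks])


def support_table(
    rank_lists: list[dict[str, int]], genes: list[str], max_rank: int
) -> pd.DataFrame:
    """support(g, t) = fraction of runs with rank(g) <= t, for t = 1..max_rank.

    A gene absent from a run's ranking counts as rank +inf in that run.
    """
    B = len(rank_lists)
    ranks = np.full((len(genes), B), np.inf)
    gi = {g: i for i, g in enumerate(genes)}
    for b, rl in enumerate(rank_lists):
        for g, rk in rl.items():
            if g in gi:
                ranks[gi[g], b] = rk
    thresholds = np.arange(1, max_rank + 1)
    sup = (ranks[:, :, None] <= thresholds[None, None, :]).mean(axis=1)
    return pd.DataFrame(sup, index=genes, columns=thresholds)


def bootstrap_rank(
    net: GeneNetwork,
    mat: AlterationMatrix,
    params: SSAMEParams | None = None,
    B: int | None = None,
    support: float | None = None,
) -> RankedGeneList:
    """Bootstrap-supported ranking.

    Runs the full algorithm on ``B`` resampled matrices (child seeds spawned
    deterministically from ``params.rng_seed``); each gene's key is the
    smallest rank threshold t with support(g, t) >= ``support``, ties broken
    by higher support at that t, then gene id.  Genes never reaching support
    are left out of the returned list.
    """
    params = params or SSAMEParams()
    B = params.bootstrap_B if B is None else B
    support_level = params.bootstrap_support if support is None else support
    if B < 1:
        raise ValueError("B must be >= 1")

    master = np.random.SeedSequence(params.rng_seed)
    children = master.spawn(B)
    rank_lists: list[dict[str, int]] = []
    for b in range(B):
        child_params = SSAMEParams(
            forgetfulness=params.forgetfulness,
            reinforcement=params.reinforcement,
            iterations=params.iterations,
            sizes=params.sizes,
            rng_seed=int(children[b].generate_state(1)[0]),
            bootstrap_B=0,
            bootstrap_support=support_level,
            early_stop=params.early_stop,
            early_stop_k=params.early_stop_k,
            early_stop_patience=params.early_stop_patience,
        )
        boot_mat = resample_samples(mat, np.random.default_rng(children[b]))
        _, ranked = run_ssa_me(net, boot_mat, child_params)
        rank_lists.append(ranked.rank_of())
        logger.debug("bootstrap replicate %d/%d done", b + 1, B)

    genes = net.nodes
    sup = support_table(rank_lists, genes, max_rank=len(genes))
    entries: list[RankedEntry] = []
    for g in genes:
        row = sup.loc[g].to_numpy()
        hit = np.nonzero(row >= support_level)[0]
        if hit.size == 0:
            continue
        t = int(hit[0]) + 1
        entries.append(
            RankedEntry(
                gene=g,
                rank=0,  # assigned after sorting
                max_score=np.nan,
                convergence_iter=-1,
                bootstrap_threshold=t,
                bootstrap_support=float(row[t - 1]),
            )
        )
    entries.sort(key=lambda e: (e.bootstrap_threshold, -e.bootstrap_support, e.gene))
    for i, e in enumerate(entries):
        e.rank = i + 1
    return RankedGeneList(entries)
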