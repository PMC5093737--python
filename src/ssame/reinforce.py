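"""The main SSA-ME loop: reinforced gene-score updates from rMES, convergence
tracking, final ranking and mutual-exclusivity pattern extraction.

Per iteration the score update for every network gene g is

    score'(g) = min(1, f * score(g) + r * best(g))

where ``f`` is the forgetfulness, ``r`` the reinforcement and ``best(g)`` the
highest rMES over this iteration's subnetworks containing g (0 when g is in
none).  All network genes start at 0.5.  Genes are finally ranked by the
maximal score they ever reached, ties broken by how early the score
converged, then lexicographically.
"""

from __future__ import annotations

import logging
import math
from bisect import insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    AlterationMatrix,
    GeneNetwork,
    RankedEntry,
    RankedGeneList,
    SmallSubnetwork,
    SSAMEParams,
)
from . import _kernel
from .sampler import _grow_indexed, eligible_seeds, iteration_size
from .scoring import _mes_from_rows, rmes_values

logger = logging.getLogger(__name__)

__all__ = [
    "GeneScoreState",
    "update_scores",
    "run_ssa_me",
    "rank_genes",
    "extract_pattern",
]

TOP_SUBNETWORKS = 5  # best-MES subnetworks retained per gene


class GeneScoreState:
    """Per-gene reinforced score with convergence bookkeeping.

    ``convergence_iter(g)`` is the first iteration at which the score reached
    0.99 x its running maximum and never dropped below that level again;
    genes whose score never stabilizes get the sentinel ``iterations + 1``.
    """

    def __init__(self, net: GeneNetwork, mat: AlterationMatrix | None = None):
        self.network = net
        self.matrix = mat
        self.genes: list[str] = net.nodes
        self.index = {g: i for i, g in enumerate(self.genes)}
        n = len(self.genes)
        self.scores = np.full(n, 0.5)
        self.max_score = np.full(n, 0.5)
        self.iteration = 0
        # convergence tracking: candidate start iteration (-1 = none) and the
        # minimum score seen since the candidate
        self._cand = np.zeros(n, dtype=np.int64)
        self._min_since = np.full(n, 0.5)
        # per-gene bounded best-of list of (-mes, key, subnetwork)
        self._tops: list[list[tuple[float, tuple[str, ...], SmallSubnetwork]]] = [
            [] for _ in range(n)
        ]
        self._top_thr = np.full(n, -np.inf)  # mes needed to enter a full list
        self.mes_evaluations: list[int] = []  # per-iteration scored-subnetwork count

    # -- accessors --------------------------------------------------------
    def score_of(self, gene: str) -> float:
        return float(self.scores[self.index[gene]])

    def max_score_of(self, gene: str) -> float:
        return float(self.max_score[self.index[gene]])

    def convergence_iter_of(self, gene: str) -> int:
        i = self.index[gene]
        return int(self._cand[i]) if self._cand[i] >= 0 else self.iteration + 1

    def top_subnetworks(self, gene: str) -> list[SmallSubnetwork]:
        """The <= 5 highest-MES subnetworks containing ``gene``, best first."""
        return [sn for _, _, sn in self._tops[self.index[gene]]]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "score": self.scores,
                "max_score": self.max_score,
                "convergence_iter": [
                    self.convergence_iter_of(g) for g in self.genes
                ],
            }
        )

    # -- mutation ---------------------------------------------------------
    def _apply_best(self, best: np.ndarray, params: SSAMEParams) -> None:
        """One score update plus convergence bookkeeping."""
        f, r = params.forgetfulness, params.reinforcement
        self.scores = np.minimum(1.0, f * self.scores + r * best)
        self.iteration += 1
        s = self.scores
        new_max = np.maximum(self.max_score, s)
        thr = 0.99 * new_max
        rising = new_max > self.max_score
        # rising genes: keep the candidate only if every score since it (and
        # the new one) clears the raised threshold; else restart here
        keep = rising & (np.minimum(self._min_since, s) >= thr) & (self._cand >= 0)
        restart = rising & ~keep
        self._cand = np.where(restart, self.iteration, self._cand)
        self._min_since = np.where(
            restart, s, np.minimum(self._min_since, s)
        )
        # flat genes: drop the candidate on a dip below threshold, open a new
        # one on recovery
        flat = ~rising
        dip = flat & (s < thr)
        self._cand = np.where(dip, -1, self._cand)
        self._min_since = np.where(dip, np.inf, self._min_since)
        opens = flat & (s >= thr) & (self._cand == -1)
        self._cand = np.where(opens, self.iteration, self._cand)
        self._min_since = np.where(opens, s, self._min_since)
        self.max_score = new_max

    def _push_top(self, gi: int, sn: SmallSubnetwork) -> None:
        lst = self._tops[gi]
        key = sn.key()
        item = (-sn.mes, key, sn)
        for it in lst:
            if it[1] == key:
                return  # identical gene set already retained
        # comparison never reaches the SmallSubnetwork element: equal
        # (-mes, key) pairs are excluded by the dedupe check above
        insort(lst, item)
        if len(lst) > TOP_SUBNETWORKS:
            lst.pop()
        self._top_thr[gi] = (
            -lst[-1][0] if len(lst) == TOP_SUBNETWORKS else -np.inf
        )


def update_scores(
    state: GeneScoreState,
    batch: list[SmallSubnetwork],
    params: SSAMEParams,
) -> GeneScoreState:
    """Apply one iteration's score update from a scored, rMES-ranked batch.

    ``best(g)`` is the maximum rmes over the batch subnetworks containing g;
    genes in no subnetwork get 0.  Also merges the per-gene top-5 retained
    subnetworks.  Mutates and returns ``state``.
    """
    best = np.zeros(len(state.genes))
    for sn in batch:
        if sn.rmes is None:
            raise ValueError("subnetwork missing rmes; call rank_mes first")
        idxs = [state.index[g] for g in sn.genes]
        np.maximum.at(best, idxs, sn.rmes)
        for gi in idxs:
            if sn.mes > state._top_thr[gi]:
                state._push_top(gi, sn)
    state._apply_best(best, params)
    return state


def run_ssa_me(
    net: GeneNetwork,
    mat: AlterationMatrix,
    params: SSAMEParams | None = None,
) -> tuple[GeneScoreState, RankedGeneList]:
    """Run the full algorithm and return (final state, ranking).

    Fully reproducible given ``params.rng_seed``.  Stops early when the
    top-``early_stop_k`` gene set by current score has been unchanged for
    ``early_stop_patience`` consecutive iterations (only meaningful when the
    network has more genes than ``early_stop_k``).

    Uses a numba-compiled kernel for subnetwork growth and scoring when
    numba is importable, else a pure numpy path with identical semantics
    (the two paths consume different random streams, so results are
    reproducible per path, not across paths).
    """
    params = params or SSAMEParams()
    idx = net.indexed()
    n = idx.n_genes
    state = GeneScoreState(net, mat)

    seeds = eligible_seeds(net, mat)
    seed_idx = np.array([idx.index[g] for g in seeds], dtype=np.int64)
    # alteration rows aligned to network gene order; genes missing from the
    # matrix are all-zero
    alt = np.zeros((n, mat.n_samples), dtype=np.uint8)
    for g, gi in idx.index.items():
        mi = mat.gene_index.get(g)
        if mi is not None:
            alt[gi] = mat.values[mi]
    gene_counts = alt.sum(axis=1, dtype=np.int64)
    alt_f = alt.astype(np.float64)

    use_kernel = _kernel.HAVE_NUMBA
    if use_kernel:
        indptr = np.zeros(n + 1, dtype=np.int64)
        for gi in range(n):
            indptr[gi + 1] = indptr[gi] + len(idx.neighbors[gi])
        indices = np.fromiter(
            (nb for nbrs in idx.neighbors for nb in nbrs),
            dtype=np.int32,
            count=int(indptr[-1]),
        )
        rng_state = _kernel.seed_state(params.rng_seed)
        max_size = max(params.sizes)
        members_out = np.empty((len(seed_idx), max_size), dtype=np.int32)
        mes_out = np.empty(len(seed_idx), dtype=np.float64)
        seed_out = np.empty(len(seed_idx), dtype=np.int32)
    else:
        rng = np.random.default_rng(params.rng_seed)

    check_stop = (
        params.early_stop and 0 < params.early_stop_k < n
    )
    stable_iters = 0
    prev_top: frozenset[int] | None = None

    for it in range(params.iterations):
        size = iteration_size(it, params.sizes)
        if use_kernel:
            n_sub = _kernel.iteration_kernel(
                indptr, indices, state.scores, alt, gene_counts,
                seed_idx, size, rng_state, members_out, mes_out, seed_out,
            )
            members_batch = [
                [int(g) for g in row if g >= 0] for row in members_out[:n_sub]
            ]
            mes_vals = [float(v) for v in mes_out[:n_sub]]
            seed_batch = [int(s) for s in seed_out[:n_sub]]
        else:
            members_batch = []
            mes_vals = []
            seed_batch = []
            for si in seed_idx:
                members = _grow_indexed(
                    int(si), state.scores, idx.neighbors, size, rng
                )
                if members is None:
                    continue
                # order by descending alteration count, ties by gene index
                # (= lexicographic, since genes are index-sorted by name)
                members.sort(key=lambda gi: (-gene_counts[gi], gi))
                mes_vals.append(_mes_from_rows(alt_f[members]))
                members_batch.append(members)
                seed_batch.append(int(si))
        state.mes_evaluations.append(len(members_batch))
        if members_batch:
            rmes = rmes_values(np.asarray(mes_vals))
            best = np.zeros(n)
            thr = state._top_thr
            for members, mv, rv, sd in zip(
                members_batch, mes_vals, rmes, seed_batch
            ):
                np.maximum.at(best, members, rv)
                for gi in members:
                    if mv > thr[gi]:
                        sn = SmallSubnetwork(
                            genes=tuple(idx.genes[i] for i in members),
                            seed=idx.genes[sd],
                            mes=mv,
                            rmes=float(rv),
                        )
                        state._push_top(gi, sn)
        else:
            best = np.zeros(n)
        state._apply_best(best, params)

        if (it + 1) % 100 == 0:
            logger.debug(
                "iteration %d: size=%d mean_score=%.4f n_high=%d",
                it + 1, size, float(state.scores.mean()),
                int((state.scores > 0.9).sum()),
            )
        if check_stop:
            top = frozenset(
                np.argpartition(-state.scores, params.early_stop_k)[
                    : params.early_stop_k
                ].tolist()
            )
            if top == prev_top:
                stable_iters += 1
                if stable_iters >= params.early_stop_patience:
                    logger.info(
                        "converged: top-%d set stable for %d iterations, "
                        "stopping after iteration %d",
                        params.early_stop_k, stable_iters, it + 1,
                    )
                    break
            else:
                stable_iters = 0
                prev_top = top

    return state, rank_genes(state)


def rank_genes(state: GeneScoreState) -> RankedGeneList:
    """Rank genes by (max score desc, convergence iteration asc, gene id)."""
    keyed = sorted(
        state.genes,
        key=lambda g: (-state.max_score_of(g), state.convergence_iter_of(g), g),
    )
    entries = [
        RankedEntry(
            gene=g,
            rank=i + 1,
            max_score=state.max_score_of(g),
            convergence_iter=state.convergence_iter_of(g),
        )
        for i, g in enumerate(keyed)
    ]
    return RankedGeneList(entries)


def extract_pattern(
    gene: str, state: GeneScoreState
) -> tuple[list[str], pd.DataFrame]:
    """Mutual exclusivity pattern of a prioritized gene.

    Returns the union of the gene's <= 5 retained best subnetworks (ordered
    by descending alteration count) and the alteration sub-matrix restricted
    to those genes.  There is no guarantee that all genes within the
    retrieved pattern are mutually exclusive with each other — the union of
    good small subnetworks need not itself be one exclusive set.
    """
    tops = state.top_subnetworks(gene)
    if not tops:
        logger.warning("gene %s has no retained subnetworks; singleton pattern", gene)
        union = {gene}
    else:
        union = set()
        for sn in tops:
            union |= set(sn.genes)
    mat = state.matrix
    if mat is None:
        raise ValueError("state has no alteration matrix attached")
    rows = {
        g: (mat.values[mat.gene_index[g]] if g in mat.gene_index
            else np.zeros(mat.n_samples, dtype=np.uint8))
        for g in union
    }
    ordered = sorted(union, key=lambda g: (-int(rows[g].sum()), g))
    tiles = pd.DataFrame(
        np.vstack([rows[g] for g in ordered]), index=ordered, columns=mat.samples
    )
    tiles.index.name = "gene"
    return ordered, tiles
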