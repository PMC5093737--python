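"""Mutual exclusivity scoring of small subnetworks.

The mutual exclusivity score (MES) of a gene set V is accumulated gene by
gene.  Genes are processed in order of descending alteration count (ties
broken lexicographically).  Every sample altered in at least one gene of V
starts out "pending"; when a gene is processed, each pending sample altered
in that gene contributes a weight of 1/m(s, V) — where m(s, V) is the number
of genes of V altered in s, computed once on the full V — to that gene's
bucket, and is then removed from the pending set so a sample contributes at
most once.  The MES is the sum over genes of the square root of each bucket;
the square root rewards subnetworks whose genes are altered in approximately
the same number of samples.

.. note::
   The exact printed formula for MES is not machine-readable in the source
   publication; the form implemented here is a reconstruction constrained by
   its textual description (single contribution per sample, inverse-overlap
   weight, per-gene square root).  The functional form is concentrated in
   :func:`_mes_from_rows` so an alternative normalization can be swapped in
   at one place.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .datatypes import AlterationMatrix, SmallSubnetwork

__all__ = [
    "count_mutated",
    "order_genes",
    "mes",
    "rank_mes",
    "mes_oracle",
]


def count_mutated(sample: str, V: Sequence[str], mat: AlterationMatrix) -> int:
    """m(s, V): number of genes of V altered in ``sample``.

    Computed on the full V regardless of any sample-removal state.
    """
    try:
        si = mat.sample_index[sample]
    except KeyError:
        raise KeyError(f"unknown sample {sample!r}") from None
    total = 0
    for g in V:
        try:
            gi = mat.gene_index[g]
        except KeyError:
            raise KeyError(f"unknown gene {g!r}") from None
        total += int(mat.values[gi, si])
    return total


def order_genes(V: Sequence[str], mat: AlterationMatrix) -> list[str]:
    """Order V by descending alteration count, ties lexicographically."""
    counts = {g: int(mat.values[mat.gene_index[g]].sum()) for g in V}
    return sorted(V, key=lambda g: (-counts[g], g))


def _mes_from_rows(rows: np.ndarray) -> float:
    """MES from an already-ordered (k, n_samples) 0/1 float array.

    Single swappable location for the MES functional form.
    """
    m = rows.sum(axis=0)
    with np.errstate(divide="ignore"):
        w = np.where(m > 0, 1.0 / np.maximum(m, 1.0), 0.0)
    total = 0.0
    for row in rows:
        bucket = float(row @ w)
        total += math.sqrt(bucket)
        w[row > 0] = 0.0  # consumed samples no longer pending
    return total


def mes(sn: SmallSubnetwork | Sequence[str], mat: AlterationMatrix) -> float:
    """Mutual exclusivity score of a small subnetwork.

    Accepts a :class:`SmallSubnetwork` (whose ``genes`` are re-ordered by the
    alteration-count rule and whose ``mes`` field is set) or a bare gene
    sequence.  Deterministic; requires ``|V| >= 2``.
    """
    V = list(sn.genes) if isinstance(sn, SmallSubnetwork) else list(sn)
    if len(V) < 2:
        raise ValueError(f"subnetwork must have >= 2 genes, got {len(V)}")
    if len(set(V)) != len(V):
        raise ValueError("duplicate genes in subnetwork")
    ordered = order_genes(V, mat)
    idx = [mat.gene_index[g] for g in ordered]
    rows = mat.values[idx].astype(np.float64)
    value = _mes_from_rows(rows)
    if isinstance(sn, SmallSubnetwork):
        sn.genes = tuple(ordered)
        sn.mes = value
    return value


def rank_mes(batch: list[SmallSubnetwork]) -> list[SmallSubnetwork]:
    """Set ``rmes`` on every subnetwork of a batch by rank-normalizing MES.

    The highest MES maps to 1 and the lowest to 0 via
    ``(ascending_rank - 1) / (N - 1)``; tied MES values share the mean of
    their ascending ranks.  A single-element batch gets rmes 1.
    """
    if not batch:
        raise ValueError("empty batch")
    if any(sn.mes is None for sn in batch):
        raise ValueError("every subnetwork must have mes set")
    values = np.array([sn.mes for sn in batch], dtype=np.float64)
    r = rmes_values(values)
    for sn, v in zip(batch, r):
        sn.rmes = float(v)
    return batch


def rmes_values(mes_values: np.ndarray) -> np.ndarray:
    """Vector form of the rMES mapping used by :func:`rank_mes`."""
    n = len(mes_values)
    if n == 1:
        return np.ones(1)
    return (rankdata(mes_values, method="average") - 1.0) / (n - 1.0)


def mes_oracle(V: Sequence[str], mat: AlterationMatrix) -> float:
    """Literal, unoptimized reference implementation of :func:`mes`.

    Transcribes the sample-accounting rules with explicit sets: S starts as
    every sample altered in >= 1 gene of V; genes are processed in
    descending-count order; each gene's bucket collects 1/m(s, V) over the
    pending samples altered in it, which are then removed from S.  Used by
    the test suite as the independent scoring route; kept free of any code
    shared with :func:`mes`.
    """
    V = list(V)
    if len(V) < 2:
        raise ValueError(f"subnetwork must have >= 2 genes, got {len(V)}")
    altered_in = {
        g: {s for s in mat.samples if mat.altered(g, s) == 1} for g in V
    }
    ordered = sorted(V, key=lambda g: (-len(altered_in[g]), g))
    S = set()
    for g in V:
        S |= altered_in[g]
    m = {s: sum(1 for g in V if s in altered_in[g]) for s in S}
    total = 0.0
    for g in ordered:
        contributors = S & altered_in[g]
        bucket = sum(1.0 / m[s] for s in contributors)
        total += math.sqrt(bucket)
        S -= contributors
    return total
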