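"""Readers and writers for networks, alteration matrices and result files.

All on-disk formats are plain TSV (UTF-8, LF). Parsers reject malformed
input rather than silently coercing it.
"""

from __future__ import annotations

import logging
import os
import warnings
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .datatypes import AlterationMatrix, GeneNetwork, RankedEntry, RankedGeneList

if TYPE_CHECKING:  # pragma: no cover
    from .reinforce import GeneScoreState

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_network",
    "write_network",
    "read_alterations",
    "write_alterations",
    "maf_to_matrix",
    "filter_hypermutators",
    "write_results",
    "read_ranked",
]


class ParseError(ValueError):
    """Malformed input file."""


def read_network(path: str | os.PathLike, fmt: str | None = None) -> GeneNetwork:
    """Read an undirected network from a 2-column edge TSV or a 3-column SIF.

    ``fmt`` is ``"edge_tsv"`` or ``"sif"``; when ``None`` it is inferred from
    the file extension (``.sif`` -> sif).  Comment lines start with ``#``.
    Self-loop rows contribute their gene as an isolated node but no edge;
    duplicate and reciprocal edges are collapsed.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sif" if path.suffix.lower() == ".sif" else "edge_tsv"
    if fmt not in ("edge_tsv", "sif"):
        raise ValueError(f"unknown network format {fmt!r}")
    want = 2 if fmt == "edge_tsv" else 3
    net = GeneNetwork()
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) != want:
                raise ParseError(
                    f"{path}:{lineno}: expected {want} columns, got {len(fields)}"
                )
            u = fields[0]
            v = fields[-1]  # SIF middle column (interaction type) is ignored
            if u == v:
                net.add_node(u)
                dropped += 1
                continue
            if net.has_edge(u, v):
                dropped += 1
                continue
            net.add_edge(u, v)
    if net.n_nodes == 0:
        raise ParseError(f"{path}: empty network")
    if dropped:
        logger.info("read_network: dropped %d self-loop/duplicate records", dropped)
    return net


def write_network(net: GeneNetwork, path: str | os.PathLike) -> None:
    """Write a 2-column edge TSV; isolated nodes appear as self-referential
    comment lines so a round-trip preserves the node set."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        connected = set()
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")
            connected.add(u)
            connected.add(v)
        for n in net.nodes:
            if n not in connected:
                fh.write(f"{n}\t{n}\n")  # read back as isolated node


def read_alterations(path: str | os.PathLike) -> AlterationMatrix:
    """Read a binary gene x sample TSV (header = sample ids, first column =
    gene ids).  Duplicate gene rows are OR-combined with a warning."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]  # pandas would mangle duplicates, so check raw
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample column(s): {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell: {exc}") from None
    if values.size and not np.isin(values, (0.0, 1.0)).all():
        bad = values[~np.isin(values, (0.0, 1.0))][0]
        raise ParseError(f"{path}: non-binary cell value {bad!r}")
    genes = df.index.to_list()
    if len(set(genes)) != len(genes):
        dups = sorted({g for g in genes if genes.count(g) > 1})
        warnings.warn(f"duplicate gene rows OR-combined: {dups}", stacklevel=2)
        df2 = pd.DataFrame(values, index=genes, columns=df.columns)
        df2 = df2.groupby(level=0, sort=False).max()
        genes = df2.index.to_list()
        values = df2.to_numpy()
    return AlterationMatrix(genes, df.columns.to_list(), values.astype(np.uint8))


def write_alterations(mat: AlterationMatrix, path: str | os.PathLike) -> None:
    mat.to_frame().to_csv(path, sep="\t", lineterminator="\n")


def maf_to_matrix(
    path: str | os.PathLike,
    gene_col: str = "Hugo_Symbol",
    sample_col: str = "Tumor_Sample_Barcode",
) -> AlterationMatrix:
    """Collapse a MAF-like variant table to a binary matrix: any (gene,
    sample) pair with >= 1 variant row becomes 1."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in (gene_col, sample_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    genes = sorted(df[gene_col].unique())
    samples = sorted(df[sample_col].unique())
    gi = {g: i for i, g in enumerate(genes)}
    si = {s: i for i, s in enumerate(samples)}
    values = np.zeros((len(genes), len(samples)), dtype=np.uint8)
    for g, s in zip(df[gene_col], df[sample_col]):
        values[gi[g], si[s]] = 1
    return AlterationMatrix(genes, samples, values)


def filter_hypermutators(
    mat: AlterationMatrix, max_alterations: int = 500
) -> AlterationMatrix:
    """Drop samples with strictly more than ``max_alterations`` altered genes.

    The gene set is unchanged; removed sample ids are logged.
    """
    if max_alterations < 0:
        raise ValueError("max_alterations must be >= 0")
    colsums = mat.values.sum(axis=0)
    keep = colsums <= max_alterations
    removed = [s for s, k in zip(mat.samples, keep) if not k]
    if removed:
        logger.info("filter_hypermutators: removed %d sample(s): %s",
                    len(removed), removed)
    if not keep.any():
        warnings.warn("all samples removed as hypermutators", stacklevel=2)
    samples = [s for s, k in zip(mat.samples, keep) if k]
    return AlterationMatrix(list(mat.genes), samples, mat.values[:, keep])


def write_results(
    ranked: RankedGeneList,
    state: "GeneScoreState",
    out_dir: str | os.PathLike,
    n_patterns: int = 20,
) -> dict[str, Path]:
    """Write ranked_genes.tsv, node_attributes.tsv and per-gene pattern TSVs.

    Pattern files are written for the ``n_patterns`` top-ranked genes.  Note
    that a pattern is the union of a gene's best subnetworks: there is no
    guarantee that all genes within the retrieved pattern are mutually
    exclusive with each other.
    """
    from .reinforce import extract_pattern

    if len(ranked) == 0:
        raise ValueError("ranked gene list is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    ranked_path = out_dir / "ranked_genes.tsv"
    ranked.to_frame().to_csv(ranked_path, sep="\t", index=False, lineterminator="\n")
    written["ranked_genes"] = ranked_path

    counts = state.matrix.gene_counts() if state.matrix is not None else None
    attr_path = out_dir / "node_attributes.tsv"
    with open(attr_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tscore\tn_samples_altered\n")
        for g in state.genes:
            n_alt = int(counts.get(g, 0)) if counts is not None else 0
            fh.write(f"{g}\t{state.score_of(g):.10g}\t{n_alt}\n")
    written["node_attributes"] = attr_path

    pat_dir = out_dir / "patterns"
    pat_dir.mkdir(exist_ok=True)
    for entry in ranked.entries[:n_patterns]:
        _, tiles = extract_pattern(entry.gene, state)
        p = pat_dir / f"{entry.gene}.tsv"
        tiles.to_csv(p, sep="\t", lineterminator="\n")
        written[f"pattern:{entry.gene}"] = p
    return written


def read_ranked(path: str | os.PathLike) -> RankedGeneList:
    """Read back a ranked_genes.tsv written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t")
    entries = []
    for row in df.itertuples(index=False):
        bt = None if pd.isna(row.bootstrap_threshold) else int(row.bootstrap_threshold)
        bs = None if pd.isna(row.bootstrap_support) else float(row.bootstrap_support)
        entries.append(
            RankedEntry(
                gene=str(row.gene),
                rank=int(row.rank),
                max_score=float(row.max_score),
                convergence_iter=int(row.convergence_iter),
                bootstrap_threshold=bt,
                bootstrap_support=bs,
            )
        )
    return RankedGeneList(entries)
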