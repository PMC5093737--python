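"""Evaluation of rankings against a planted truth set, and the three
simulation experiments (network robustness, parameter grid, seed scaling).

Sensitivity/specificity are computed against the full network gene universe;
genes absent from a ranking share the worst rank.
"""

from __future__ import annotations

import logging
import time
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .datatypes import AlterationMatrix, GeneNetwork, RankedGeneList, SSAMEParams
from .reinforce import run_ssa_me
from .simulate import SimulationConfig, generate_test_network, simulate_study

logger = logging.getLogger(__name__)

__all__ = [
    "roc_curve",
    "ppv_at_cutoff",
    "experiment_network_robustness",
    "experiment_parameter_grid",
    "experiment_seed_scaling",
]

ROBUSTNESS_CONDITIONS: list[tuple[str, float]] = [
    ("none", 0.0),
    ("delete", 0.10), ("delete", 0.25), ("delete", 0.50),
    ("add", 0.10), ("add", 0.25), ("add", 0.50),
]


def _rank_scores(
    ranked: RankedGeneList, universe: Sequence[str]
) -> tuple[np.ndarray, dict[str, int]]:
    """Per-gene score for ROC purposes: negated rank, with all unranked
    genes sharing the worst rank."""
    rank_of = ranked.rank_of()
    worst = len(ranked) + 1
    ranks = np.array([rank_of.get(g, worst) for g in universe], dtype=float)
    return -ranks, rank_of


def roc_curve(
    ranked: RankedGeneList, truth: set[str], universe: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, float]:
    """(1 - specificity, sensitivity) points and trapezoidal AUC.

    Sweeps the rank cut-off over the whole universe.  Returns
    ``(fpr, tpr, auc)``.
    """
    universe = list(universe)
    if not truth:
        raise ValueError("empty truth set")
    if not set(truth) <= set(universe):
        raise ValueError("truth genes must be a subset of the universe")
    extraneous = set(ranked.genes()) - set(universe)
    if extraneous:
        raise ValueError(f"ranked genes outside the universe: {sorted(extraneous)[:5]}")
    y_true = np.array([g in truth for g in universe], dtype=int)
    y_score, _ = _rank_scores(ranked, universe)
    if y_true.all():
        raise ValueError("truth equals the universe; specificity undefined")
    fpr, tpr, _ = _sk_roc_curve(y_true, y_score)
    auc = float(roc_auc_score(y_true, y_score))
    return fpr, tpr, auc


def ppv_at_cutoff(ranked: RankedGeneList, truth: set[str], k: int) -> float:
    """Positive predictive value at rank cut-off k: |top-k & truth| / k."""
    if not (1 <= k <= len(ranked)):
        raise ValueError(f"k must be in [1, {len(ranked)}]")
    top = ranked.genes()[:k]
    return sum(1 for g in top if g in truth) / k


def _run_and_score(
    bundle, params: SSAMEParams, use_perturbed: bool = True
) -> float:
    net = bundle.perturbed_network if use_perturbed else bundle.network
    _, ranked = run_ssa_me(net, bundle.matrix, params)
    # evaluate against the analysis network's gene universe
    truth = bundle.truth & set(net.nodes)
    _, _, auc = roc_curve(ranked, truth, net.nodes)
    return auc


def experiment_network_robustness(
    reps: int = 10,
    n_nodes: int = 500,
    mean_degree: float = 4.0,
    n_samples: int = 300,
    iterations: int = 1500,
    conditions: Sequence[tuple[str, float]] = tuple(ROBUSTNESS_CONDITIONS),
    seed: int = 0,
    params: SSAMEParams | None = None,
) -> pd.DataFrame:
    """AUC of target recovery per network-perturbation condition.

    For each rep a fresh network/target/matrix is simulated; each condition
    perturbs that rep's network and reruns the full analysis.  Returns one
    row per (condition, rep) with the achieved AUC.
    """
    base = params or SSAMEParams(iterations=iterations)
    rows = []
    master = np.random.SeedSequence(seed)
    rep_seeds = master.spawn(reps)
    for rep in range(reps):
        states = rep_seeds[rep].generate_state(2)
        net = generate_test_network(
            n_nodes, mean_degree, np.random.default_rng(states[0])
        )
        for mode, fraction in conditions:
            cfg = SimulationConfig(
                n_samples=n_samples,
                perturbation=(mode, fraction),
                rng_seed=int(states[1]),
            )
            bundle = simulate_study(cfg, net)
            run_params = SSAMEParams(
                forgetfulness=base.forgetfulness,
                reinforcement=base.reinforcement,
                iterations=iterations,
                sizes=base.sizes,
                rng_seed=int(states[1]) ^ 0x5EED,
                early_stop=base.early_stop,
                early_stop_k=base.early_stop_k,
                early_stop_patience=base.early_stop_patience,
            )
            auc = _run_and_score(bundle, run_params)
            rows.append(
                {"condition": f"{mode}:{fraction:g}", "rep": rep, "auc": auc}
            )
            logger.info("robustness %s rep %d: AUC=%.3f", mode, rep, auc)
    return pd.DataFrame(rows)


def experiment_parameter_grid(
    f_values: Sequence[float],
    r_values: Sequence[float],
    reps: int = 3,
    n_nodes: int = 300,
    mean_degree: float = 4.0,
    n_samples: int = 200,
    iterations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean target-recovery AUC per (forgetfulness, reinforcement) pair."""
    rows = []
    master = np.random.SeedSequence(seed)
    rep_seeds = master.spawn(reps)
    bundles = []
    for rep in range(reps):
        states = rep_seeds[rep].generate_state(2)
        net = generate_test_network(
            n_nodes, mean_degree, np.random.default_rng(states[0])
        )
        cfg = SimulationConfig(n_samples=n_samples, rng_seed=int(states[1]))
        bundles.append((simulate_study(cfg, net), int(states[1])))
    for f in f_values:
        for r in r_values:
            aucs = []
            for bundle, s in bundles:
                run_params = SSAMEParams(
                    forgetfulness=f, reinforcement=r,
                    iterations=iterations, rng_seed=s ^ 0x5EED,
                )
                aucs.append(_run_and_score(bundle, run_params))
            rows.append(
                {"forgetfulness": f, "reinforcement": r,
                 "mean_auc": float(np.mean(aucs)), "n_reps": reps}
            )
            logger.info("grid f=%g r=%g: mean AUC=%.3f", f, r, rows[-1]["mean_auc"])
    return pd.DataFrame(rows)


def experiment_seed_scaling(
    seed_counts: Sequence[int],
    reps: int = 1,
    iterations: int = 10,
    n_samples: int = 30,
    mean_degree: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Work (MES evaluations) and wall time as a function of seed count.

    Seed genes are added in order of decreasing alteration frequency.  The
    MES-evaluation count is the hardware-independent work unit: one
    evaluation per eligible seed per iteration.  Wall time is informational
    only and never asserted on.
    """
    n_nodes = int(max(seed_counts) * 1.2) + 10
    rows = []
    master = np.random.SeedSequence(seed)
    for rep, ss in enumerate(master.spawn(reps)):
        states = ss.generate_state(2)
        rng = np.random.default_rng(states[0])
        net = generate_test_network(n_nodes, mean_degree, rng)
        cfg = SimulationConfig(n_samples=n_samples, rng_seed=int(states[1]))
        bundle = simulate_study(cfg, net)
        freq = bundle.matrix.gene_counts().sort_values(ascending=False)
        altered = [g for g in freq.index if freq[g] > 0]
        genes = bundle.matrix.genes
        for n_seeds in seed_counts:
            chosen = set(altered[:n_seeds])
            if len(chosen) < n_seeds:
                # top up with unaltered network genes given one alteration
                extra = [g for g in genes if g not in chosen][: n_seeds - len(chosen)]
                chosen |= set(extra)
            values = bundle.matrix.values.copy()
            for i, g in enumerate(genes):
                if g not in chosen:
                    values[i, :] = 0
                elif values[i].sum() == 0:
                    values[i, i % bundle.matrix.n_samples] = 1
            mat = AlterationMatrix(list(genes), list(bundle.matrix.samples), values)
            run_params = SSAMEParams(
                iterations=iterations, rng_seed=int(states[1]), early_stop=False
            )
            t0 = time.perf_counter()
            state, _ = run_ssa_me(net, mat, run_params)
            elapsed = time.perf_counter() - t0
            evals = state.mes_evaluations
            rows.append(
                {
                    "n_seeds": n_seeds,
                    "rep": rep,
                    "iterations": len(evals),
                    "mes_evaluations": int(np.sum(evals)),
                    "evals_per_iteration": evals[0] if evals else 0,
                    "wall_time_s": elapsed,
                }
            )
    return pd.DataFrame(rows)
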