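# ssame

Prioritize candidate cancer driver genes by reinforced sampling of small
interaction subnetworks scored for **mutual exclusivity** of genomic
alterations across tumor samples.

The method takes (1) an undirected gene interaction network and (2) a binary
gene × sample alteration matrix. Every gene altered in at least one sample
seeds the growth of a small connected subnetwork (3–6 genes, size cycling
across iterations); neighbors join with probability proportional to their
current gene score. Each subnetwork gets a mutual exclusivity score (MES),
the per-iteration batch of MES values is rank-normalized to rMES ∈ [0, 1],
and every gene's score is updated as

```
score'(g) = min(1, f · score(g) + r · best_rmes(g))
```

with forgetfulness `f = 0.995`, reinforcement `r = 0.005` and 5000
iterations by default. Genes that consistently sit in mutually exclusive
neighborhoods converge to high scores; everything else decays. Genes are
finally ranked by the maximal score they reach (ties: faster convergence
first), optionally consolidated by a sample-level bootstrap that re-ranks
genes by the smallest rank threshold at which they attain 95% support.

The package also ships the full synthetic-data harness used to validate the
method: scale-free test networks, edge-perturbed variants (±10/25/50%
edges), random-walk-with-restart target-module selection (5% restart, 20
interactions), planted near-exclusive alterations (30% of samples, 5%
co-mutation noise), ROC/AUC evaluation and the robustness / parameter-grid /
seed-scaling experiment drivers.

## MES: reconstruction note

The printed MES equation in the source publication is an image and is not
machine-readable here. The implemented form is a reconstruction constrained
by the published textual description:

* every sample altered in ≥ 1 subnetwork gene starts out "pending";
* genes are processed in descending order of their alteration count
  (ties lexicographic);
* a pending sample altered in the current gene contributes weight
  `1 / m(s, V)` — the inverse of the number of subnetwork genes altered in
  it, computed once on the full gene set — and is then consumed, so each
  sample contributes at most once;
* MES is the sum over genes of the **square root** of each gene's
  accumulated weight, which rewards subnetworks whose genes are altered in
  approximately equally many samples.

The functional form is concentrated in a single swappable function
(`ssame.scoring._mes_from_rows`, mirrored in the accelerated kernel) and is
cross-checked against a literal brute-force oracle
(`ssame.scoring.mes_oracle`) in the test suite.

## CLI

```bash
# synthetic study bundle (network.tsv, matrix.tsv, truth.txt, config.json)
ssame simulate --n-nodes 500 --n-samples 300 --perturb delete:0.25 \
    --seed 7 --out sim1/

# full run (ranked_genes.tsv, node_attributes.tsv, patterns/<gene>.tsv)
ssame run --network sim1/network.tsv --alterations sim1/matrix.tsv \
    --iterations 5000 --forgetfulness 0.995 --reinforcement 0.005 \
    --sizes 3,4,5,6 --seed 42 --out results/

# bootstrap-supported ranking
ssame bootstrap --network sim1/network.tsv --alterations sim1/matrix.tsv \
    --B 1000 --support 0.95 --seed 42 --out boot.tsv

# evaluation against a truth gene list
ssame evaluate --ranked results/ranked_genes.tsv --truth sim1/truth.txt \
    --network sim1/network.tsv --out eval/

# experiment drivers
ssame exp robustness --reps 10 --seed 0 --out robustness.tsv
ssame exp grid --reps 3 --seed 0 --out grid.tsv
ssame exp scaling --seed-counts 10,100,1000 --out scaling.tsv

# debug: MES breakdown of a gene set
ssame score-subnetwork --alterations sim1/matrix.tsv TP53 PIK3CA GATA3
```

Network input is a 2-column edge TSV or 3-column SIF (`#` comments,
self-loops dropped to isolated nodes, duplicate edges collapsed). The
alteration matrix is a binary gene × sample TSV; a MAF-like variant table
can be collapsed with `ssame.maf_to_matrix`. Samples with more than 500
alterations (hypermutators) are removed before analysis by `ssame run`
(`--max-alterations`).

Patterns written per prioritized gene are the union of its five best
retained subnetworks; note there is no guarantee that all genes within a
retrieved pattern are mutually exclusive with each other.

## Layout

```
src/ssame/
  datatypes.py   core domain types (network, matrix, params, rankings)
  io.py          TSV/SIF/MAF readers, result writers, hypermutator filter
  scoring.py     MES, rMES rank normalization, brute-force oracle
  sampler.py     seed selection and score-proportional subnetwork growth
  reinforce.py   main loop, score updates, ranking, pattern extraction
  bootstrap.py   sample-level bootstrap and support ranking
  simulate.py    synthetic networks, perturbations, walker, generator
  evaluate.py    ROC/AUC, PPV, experiment drivers
  _kernel.py     optional numba-jitted iteration kernel
  cli.py         `ssame` command-line interface
```
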