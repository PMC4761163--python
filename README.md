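# phyloniche

Phyloclimatic analysis of niche evolution across a clade: fit ecological
niche models (ENMs) to species occurrence records over environmental grids,
quantify pairwise niche overlap, test for niche conservatism versus
divergence against randomization nulls, and trace niche change along a
time-calibrated phylogeny.

The package is aimed at comparative biologists asking the questions that
drive phyloclimatic studies of radiations (freshwater fishes, herps,
plants): do closely related species keep more similar climatic niches than
their surroundings would predict, or has speciation pushed them apart —
and when in the clade's history did niche disparity accumulate?

## What it computes

**Niche models.** For each species with at least 5 records, a maximum-entropy
model over grid cells: the Gibbs distribution p_λ(i) ∝ exp(λ·f(i)) with
standardized linear and quadratic features of each environmental variable,
fitted by minimizing the L1-penalized negative log-likelihood of the
presence cells (penalty β·s_j/√m per feature). Outputs are the raw
distribution (Σp = 1), the logistic surface (prevalence τ = 0.5), the
Minimum Training Presence threshold, and replicate train/test AUC
(10 × 59 %/41 % splits, 0.7 acceptance gate).

**Overlap and randomization tests.** Schoener's D = 1 − ½Σ|p − q| and
Warren's I = 1 − ½Σ(√p − √q)² between normalized suitability surfaces
(I ≥ D always). The *identity test* pools and repartitions the two species'
records to ask whether their niches are interchangeable; the *background
test* refits one species' model to random pseudolocalities from its
accessible background (buffered convex hull by default) to call
**conservatism** (observed overlap above the null's upper bound) or
**divergence** (below the lower bound). Both use 100 replicates and
order-statistic bounds at 95 % confidence.

**Niche evolution on the tree.** Predicted niche occupancy (PNO) profiles
(per-variable suitability mass over 50 bins, summing to 1) and their
weighted means; ancestral tolerances by maximum-likelihood Brownian-motion
reconstruction of 100 random PNO draws; age-range correlation (per-node
cross-clade overlap regressed on node age, permutation-tested);
disparity-through-time curves with the MDI statistic against 1000
Brownian simulations; phylogenetic PCA of the weighted means and a
phylogenetic MANOVA whose F null comes from 1000 Brownian simulations.

**Synthetic data.** `phyloniche.synthetic` generates the whole study from
scratch — spatially autocorrelated, inter-correlated environmental grids;
Yule trees; niche optima evolving by Brownian motion (divergence) or
Ornstein–Uhlenbeck pull to an ancestral optimum (conservatism); occurrences
sampled from the true Gaussian-response suitability — so every analysis is
testable end to end with known truth.

## Worked example

Simulate an 8-species clade whose niches diverge by Brownian motion on a
25×25 landscape, then run the full analysis:

```python
from phyloniche.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    simulate=True, seed=7,
    sim={"n_rows": 25, "n_cols": 25, "n_tips": 8, "n_occurrences": 30},
    clades={f"sp{i:02d}": ("A" if i <= 4 else "B") for i in range(1, 9)},
    group_labels={f"sp{i:02d}": ("N" if i <= 4 else "S") for i in range(1, 9)},
)
run_pipeline(cfg, "demo")
```

On this dataset the run prints/writes (seed 7):

* mean AUC per species 0.805–0.959 — every model clears the 0.7 gate;
* `arc.json`: slope **−0.410**, permutation p = 0.02 — niche overlap decays
  with node age, the signature of divergence accumulating over time;
* `background_summary.tsv`: 4/6 and 5/6 within-clade pairs called
  *divergence* (67 %, 83 %) — the background tests recover the simulated
  regime;
* `mdi.json`: MDI per variable −0.055…+0.121 — near the Brownian
  expectation, as simulated;
* `manova.json`: F = 0.11, p = 0.91 — no group effect, as none was built in.

The same stages are exposed as a CLI
(`phyloniche simulate | thin | filter-vars | fit-enm | overlap |
identity-test | background-test | pno | ancestral | arc | dtt | ppca |
manova | run`).

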