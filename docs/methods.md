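# Methods

This note records the models implemented, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
demonstrate.

## Maximum-entropy niche model

The model is the Gibbs distribution over valid grid cells,
p_λ(i) ∝ exp(λ·f(i)), with features f(i) the linear and quadratic terms of
each environmental variable after standardization by the *background*
(all-cell) mean and SD, so models fitted to different occurrence sets share
one feature space. The fit minimizes

    J(λ) = −(1/m) Σ_presences λ·f + log Z(λ) + Σ_j β_j |λ_j|,
    β_j = β·s_j/√m,

with s_j the feature SD over the m presence records and β = 1 by default
(configurable). The L1 problem is made smooth by splitting λ = λ⁺ − λ⁻ with
non-negativity bounds and solved by L-BFGS-B (objective tolerance 1e-6,
iteration cap 1000). The contract is the KKT property of the convex
program — |E_p[f_j] − mean_presence f_j| ≤ β_j at the optimum — not any
particular optimizer; tests check that property numerically and compare the
β = 0 fit against direct constrained-entropy maximization on a 16-cell grid.

Hinge, product and threshold features, and clamping, are deliberately
omitted: linear + quadratic features are exactly what a unimodal
(Gaussian-response) niche needs, and they keep the program small, convex
and fully specifiable. This is a documented simplification relative to the
full MAXENT feature set, so fitted surfaces are not expected to be
numerically identical to MAXENT output.

The logistic transform uses the standard prevalence form
c_i = τ·e^H·p_i / (1 − τ + τ·e^H·p_i) with τ = 0.5 and H the entropy of p.
It is monotone in the raw output, so threshold (MTP) and AUC orderings do
not depend on this choice; overlap values computed on renormalized
logistic surfaces do, which is why the surface ("logistic" vs "raw") is a
parameter of every overlap-based function (default: logistic, renormalized
to sum 1).

Species with fewer than 5 presence records are refused with an explicit
"excluded from niche analyses" error; the pipeline logs the exclusion and
prunes them from the tree before the phylogenetic stages. Model evaluation
subsamples 59 % of records for training over 10 replicates and reports the
rank (Mann–Whitney, ties = ½) AUC of held-out presences against all
background cells, gated at a mean of 0.7.

## Overlap tests

Schoener's D and Warren's I are computed between surfaces renormalized to
probability distributions on the shared support. Randomization bounds use
raw order statistics at rank ⌈q(n+1)⌉ with no interpolation, so the default
100 replicates attain a one-sided level of 5/101 ≈ 4.95 % — the measured
type-I error of the identity test (5.0 % over 200 null datasets in the
acceptance suite) matches this by construction, not by tuning.

The identity test is one-sided low (rejection = observed overlap below the
null's 5th-percentile order statistic). The background test is directional:
conservatism above the upper bound, divergence below the lower, each
direction of a species pair run separately; the pipeline calls a pair
conservative/divergent if either direction is. A species' accessible
background defaults to the convex hull of its occurrences buffered by
5 cells and intersected with the valid grid; any boolean cell mask can be
passed instead (the calibration suite uses the whole landscape as a "broad
background"). Failed null-replicate fits are redrawn, capped at 3× the
replicate count.

## PNO, ancestral tolerances, ARC

PNO profiles bin a species' normalized suitability over each variable's
global range (50 bins; bin edges shared across species so profiles are
comparable). Ancestral tolerance reconstruction draws, per sample, one bin
*midpoint* per tip with probability equal to the bin mass — midpoints
rather than uniform-within-bin draws keep the sample space finite and
reproducible — and reconstructs internal nodes by the GLS/ML Brownian
solution (weighted graph Laplacian; root equals (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x).
100 samples per variable by default.

Age-range correlation computes, per internal node, the weighted mean
overlap of tip pairs whose MRCA is that node; the default "ft" weighting
halves a pair's weight for every internal node on its path other than the
MRCA (cherries weigh 1), and an unweighted "mean" option is provided and
oracle-tested by enumeration. The slope of overlap on node age is tested by
permuting tip identities of the overlap matrix (two-sided on |slope|).
Per-node 95 % intervals default to *prediction* intervals, which flag
individual outlier nodes (more overlap than expected for their age =
candidate conservatism; less = candidate divergence); mean-response
confidence bands are available via `interval="confidence"` since the two
flag different node sets.

## Disparity through time and MDI

Disparity is the average squared pairwise distance (= 2× the sample
variance, which is how it is computed). The DTT curve evaluates, at each
internal-node height walking root → present, the mean relative subclade
disparity over the lineages alive just before that branching event; it is
1 at the root by construction and is invariant to affine transformation of
the traits. MDI integrates (trapezoid over relative time) the observed
curve minus the pointwise *mean* (median available) of Brownian simulations
whose rate is the REML phylogenetic variance of the observed tips. Negative
MDI ⇔ disparity held among subclades (early divergence, later
conservatism); positive ⇔ disparity within subclades.

Per node, the observed curve value is ranked within the simulated values at
that node's height; both the two-tailed rank p-value 2·min(r, S+1−r)/(S+1)
and the one-tailed low version are reported, since "significant divergence"
reads one-tailed for some questions. The root's p is meaningless (every
curve starts at exactly 1) and is excluded from calibration pooling; for
uniformity checks the discrete rank is smoothed to an exactly-uniform score
(r − U)/(S+1).

## Phylogenetic PCA and MANOVA

pPCA eigendecomposes the evolutionary covariance
R = (X − 1aᵀ)ᵀC⁻¹(X − 1aᵀ)/(N−1) with a the GLS phylogenetic mean; scores
are (X − 1aᵀ)V. Because niche variables mix units (°C, cm, unitless), each
variable is standardized to unit variance by default (`scale=False` gives
the pure covariance version, which on a star phylogeny reduces exactly to
ordinary PCA — the oracle test). Both pPCA and MANOVA also accept an
explicit tip-covariance matrix in place of a tree.

The MANOVA keeps the ordinary Wilks'-Λ statistic with Rao's F transform
(exact for two groups: df = (p, N−p−1)) but replaces the parametric
reference with a simulation null: traits are re-drawn under multivariate
Brownian motion with the GLS-estimated rate matrix, group labels held
fixed, and p = (1 + #{F_sim ≥ F_obs})/(n_sims + 1). We simulate the score
traits directly rather than simulating raw variables and re-projecting; on
a star phylogeny the simulation p converges to the parametric Wilks p
(tested). The number of components carried into the MANOVA is a config
parameter (default 4, capped at N − g − 1).

## Synthetic data generator

Environmental layers are Gaussian-kernel-smoothed white noise (bandwidth =
autocorrelation length in cells; 0 gives i.i.d. cells), standardized, mixed
by the Cholesky factor of a target inter-variable correlation matrix, and
affinely rescaled so each variable's stated range spans ±2 SD. Default
ranges use realistic magnitudes for temperature-seasonality-like,
minimum-temperature-like and precipitation-seasonality-like variables.
Trees are Yule (pure birth) and rescaled to depth 1, since ARC and DTT work
in relative time; absolute-time trees are accepted everywhere. Niche optima
evolve along the tree by exact BM or OU transitions (OU attracts to the
value at the regime's root — the whole-tree root by default, or a clade
MRCA via `clade_regimes`); breadths are inherited unchanged. Occurrences
are drawn cell-wise proportional to the true suitability — a product of
per-variable Gaussian responses — then jittered uniformly within the cell.
One global seed feeds per-stage substreams (stage name hashed into the
stream) so stages re-run independently yet reproducibly.

What the generator does *not* emulate: real topography or drainage
structure, spatial sampling bias in occurrence records, non-Gaussian or
multimodal niche responses, and observation error in the phylogeny.
Passing tests therefore demonstrate that the machinery is correct and
well-calibrated under its own assumptions, not that those assumptions hold
for any particular empirical system.

## Problem sizes and numerical choices

Calibration experiments run complete pipelines on deliberately small
worlds — 10–12-cell-square grids, two variables, 2–8 species, 20–25
records per species — chosen so hundreds of full datasets (each involving
~200 model refits for a randomization test) complete in minutes. The
statistical targets (type-I ≈ 5 %, power > 80 %, MDI null mean ≈ 0) do not
depend on these sizes; only Monte-Carlo noise does. Other defaults:
ultrametricity tolerance 1e-6 × depth; normalization guard 1e-6 on overlap
inputs; PNO mass tolerance 1e-9; optimizer objective tolerance 1e-6; BM
rate estimates use REML (divide by n−1). Degenerate inputs are handled
explicitly: constant variables produce a single-bin PNO with a warning and
are treated as uncorrelated (with a warning) in the decorrelation filter;
zero whole-clade disparity and zero-length internal branches are errors.

## Known limitations

* The niche model's feature set (linear + quadratic) cannot represent
  multimodal or threshold responses; overlap statistics inherit this.
* Backgrounds are geometric (buffered hulls), not mechanistic
  accessibility regions.
* ARC weighting and interval conventions change which nodes are flagged;
  both options are exposed because the field has not settled on one.
* The MANOVA null simulates PC scores directly; simulating raw variables
  and re-projecting is a defensible alternative that would differ slightly
  when the loadings are themselves noisy.
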