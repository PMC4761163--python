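"""Simulation studies that check the pipeline's statistical operating
characteristics on generator truth.

Each experiment builds complete synthetic datasets (landscape → niches →
occurrences → fitted models) and measures a frequentist property end to end:

* type-I error of the niche identity test when both samples come from one
  niche (and the uniformity of its null p-values);
* power of the background similarity test to call conservatism when sister
  niches are pulled to a shared optimum (OU), and divergence when optima sit
  at opposite environmental extremes;
* sign recovery of the age-range correlation slope under Brownian niche
  divergence;
* the MDI null distribution under Brownian motion traits;
* type-I error of the phylogenetic MANOVA with arbitrary group labels.

Problem sizes default to desk-scale settings (small grids, few species) so a
whole calibration runs in minutes; the statistical targets do not depend on
the sizes, only their Monte-Carlo noise does.
"""

from __future__ import annotations

import numpy as np

from phyloniche.disparity import mdi
from phyloniche.enm import fit_maxent
from phyloniche.evolution import node_overlaps
from phyloniche.multivariate import phylo_manova
from phyloniche.overlap import background_test, identity_test, overlap_matrix
from phyloniche.phylo import bm_simulate
from phyloniche.synthetic import (
    NicheSpec,
    SimConfig,
    evolve_niches,
    sample_occurrences,
    simulate_env_stack,
    simulate_tree,
    stage_rng,
)

_VARS = ("bio4", "bio6")
_RANGES = {"bio4": (13.7, 41.4), "bio6": (7.0, 18.9)}


def _scene(seed: int, grid: int = 10):
    cfg = SimConfig(n_rows=grid, n_cols=grid, variables=_VARS, ranges=_RANGES,
                    autocorr_length=2.0, seed=seed)
    stack = simulate_env_stack(cfg)
    root = NicheSpec(
        mu={v: float(np.mean(stack.values(v))) for v in _VARS},
        sigma={v: float(np.std(stack.values(v))) / 2 for v in _VARS},
    )
    return stack, root


def identity_null_calibration(
    n_datasets: int = 200,
    n_points: int = 25,
    n_replicates: int = 100,
    grid: int = 10,
    conf: float = 0.95,
    seed: int = 0,
) -> dict:
    """Type-I behaviour of the identity test with both samples from one niche.

    Returns the rejection rate at the configured confidence and the per-
    dataset null p-values (rank of the observed overlap in its null sample),
    which should be uniform.
    """
    rejections = 0
    p_values = []
    for d in range(n_datasets):
        stack, root = _scene(seed * 1000 + d, grid)
        rng = stage_rng(seed, f"identity-null:{d}")
        occA = sample_occurrences(stack, root, n_points, seed=rng, species="A")
        occB = sample_occurrences(stack, root, n_points, seed=rng, species="B")
        res = identity_test(stack, occA, occB, n_replicates=n_replicates,
                            conf=conf, rng=rng)
        rejections += res.verdict == "identity-rejected"
        p_values.append(
            (1.0 + np.sum(res.null <= res.observed[res.metric])) / (len(res.null) + 1.0)
        )
    return {
        "rejection_rate": rejections / n_datasets,
        "p_values": np.asarray(p_values),
        "n_datasets": n_datasets,
    }


def background_power(
    scenario: str,
    n_datasets: int = 50,
    n_points: int = 20,
    n_replicates: int = 100,
    grid: int = 12,
    conf: float = 0.95,
    seed: int = 0,
) -> dict:
    """Power of the background test against generator truth.

    ``scenario="conservatism"``: sister species evolved under strong OU pull
    toward a shared ancestral optimum, tested against a broad background.
    ``scenario="divergence"``: optima forced to opposite environmental
    extremes of the shared background.
    Returns the fraction of datasets receiving the expected verdict.
    """
    if scenario not in ("conservatism", "divergence"):
        raise ValueError("scenario must be 'conservatism' or 'divergence'")
    hits = 0
    for d in range(n_datasets):
        stack, root = _scene(seed * 1000 + 500 + d, grid)
        rng = stage_rng(seed, f"background:{scenario}:{d}")
        if scenario == "conservatism":
            # shared ancestral optimum at a random (off-centre) spot on the
            # landscape, with a niche clearly narrower than the background
            q = rng.uniform(0.2, 0.8, size=len(_VARS))
            shared = NicheSpec(
                mu={v: float(np.quantile(stack.values(v), qk))
                    for v, qk in zip(_VARS, q)},
                sigma={v: float(np.std(stack.values(v))) / 3 for v in _VARS},
            )
            pair = simulate_tree(2, seed=rng)
            rates = {v: (1.5 * np.std(stack.values(v))) ** 2 for v in _VARS}
            specs = evolve_niches(pair, shared, bm_rate=rates, regime="OU",
                                  ou_alpha=16.0, seed=rng)
            specA, specB = (specs[n] for n in pair.tip_names)
        else:
            lo = {v: float(np.quantile(stack.values(v), 0.10)) for v in _VARS}
            hi = {v: float(np.quantile(stack.values(v), 0.90)) for v in _VARS}
            sig = {v: float(np.std(stack.values(v))) / 3 for v in _VARS}
            specA, specB = NicheSpec(lo, sig), NicheSpec(hi, sig)
        occA = sample_occurrences(stack, specA, n_points, seed=rng, species="A")
        occB = sample_occurrences(stack, specB, n_points, seed=rng, species="B")
        broad = np.ones(stack.n_cells, dtype=bool)   # whole landscape accessible
        res = background_test(stack, occA, occB, background_B=broad,
                              n_replicates=n_replicates, conf=conf, rng=rng)
        hits += res.verdict == scenario
    return {"fraction": hits / n_datasets, "n_datasets": n_datasets}


def arc_slope_recovery(
    n_datasets: int = 50,
    n_tips: int = 8,
    n_points: int = 25,
    grid: int = 12,
    seed: int = 0,
) -> dict:
    """Fraction of BM-divergence datasets whose ARC slope is negative.

    Niches diverge by Brownian motion, so older nodes separate more and the
    per-node overlap regression on age should slope downward.
    """
    negative = 0
    for d in range(n_datasets):
        stack, root = _scene(seed * 1000 + 900 + d, grid)
        rng = stage_rng(seed, f"arc:{d}")
        tree = simulate_tree(n_tips, seed=rng)
        rates = {v: (1.5 * np.std(stack.values(v))) ** 2 for v in _VARS}
        specs = evolve_niches(tree, root, bm_rate=rates, seed=rng)
        models = {
            n: fit_maxent(stack, sample_occurrences(stack, specs[n], n_points,
                                                    seed=rng, species=n))
            for n in tree.tip_names
        }
        ov = overlap_matrix(models)
        df = node_overlaps(tree, ov)
        slope = np.polyfit(df["age"], df["overlap"], 1)[0]
        negative += slope < 0
    return {"fraction_negative": negative / n_datasets, "n_datasets": n_datasets}


def mdi_null_calibration(
    n_datasets: int = 200,
    n_tips: int = 12,
    n_sims: int = 100,
    seed: int = 0,
) -> dict:
    """MDI under its own null: Brownian traits on a Brownian reference.

    The mean MDI across datasets should sit near zero and the per-node rank
    p-values should be close to uniform.
    """
    values, pvals = [], []
    for d in range(n_datasets):
        rng = stage_rng(seed, f"mdi-null:{d}")
        tree = simulate_tree(n_tips, seed=rng)
        x = bm_simulate(tree, 0.0, 1.0, n_sims=1, rng=rng)[0]
        res = mdi(tree, x, n_sims=n_sims, rng=rng)
        values.append(res.mdi)
        # pool smoothed uniform scores: the rank is discrete-uniform on
        # 1..n_sims+1 under the null, so (rank − U)/(n_sims+1) is exactly
        # U(0,1); skip the root, whose curve value is 1 by construction
        ranks = res.table["rank"].to_numpy()[1:]
        u = (ranks - rng.uniform(size=len(ranks))) / (n_sims + 1.0)
        pvals.extend(u.tolist())
    return {
        "mean_mdi": float(np.mean(values)),
        "sd_mdi": float(np.std(values)),
        "p_values": np.asarray(pvals),
        "n_datasets": n_datasets,
    }


def manova_type_I(
    n_datasets: int = 200,
    n_tips: int = 16,
    n_traits: int = 2,
    n_sims: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the phylogenetic MANOVA with arbitrary group labels.

    Traits evolve by BM with no group effect; labels split the tips in half
    at random, so rejections at level alpha should occur at rate ~alpha.
    """
    rejections = 0
    p_values = []
    for d in range(n_datasets):
        rng = stage_rng(seed, f"manova-null:{d}")
        tree = simulate_tree(n_tips, seed=rng)
        Y = bm_simulate(tree, 0.0, 1.0, n_sims=n_traits, rng=rng).T
        labels = np.array(["a"] * (n_tips // 2) + ["b"] * (n_tips - n_tips // 2))
        rng.shuffle(labels)
        res = phylo_manova(tree, Y, labels, n_sims=n_sims, rng=rng)
        p_values.append(res.p_value)
        rejections += res.p_value <= alpha
    return {
        "rejection_rate": rejections / n_datasets,
        "p_values": np.asarray(p_values),
        "n_datasets": n_datasets,
    }
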