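"""Predicted niche occupancy and niche evolution on the phylogeny.

A PNO (predicted niche occupancy) profile converts a species' suitability
surface into a probability distribution over the values of one environmental
variable: the surface mass falling in each value bin, summing to 1.  The
profiles drive three analyses:

* **weighted means** (one number per species × variable) summarizing where
  on the gradient each species sits;
* **ancestral tolerances**: repeated random draws from the tip profiles,
  each reconstructed over the tree by maximum-likelihood Brownian motion,
  giving a distribution of ancestral niche values per internal node;
* **age-range correlation (ARC)**: per-node cross-clade mean overlap
  regressed on node age; a negative slope indicates niche differences
  accumulating with divergence time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from phyloniche.geodata import EnvStack
from phyloniche.enm import NicheModel
from phyloniche.overlap import OverlapMatrix
from phyloniche.phylo import Tree, bm_ancestral_states


@dataclass
class PNOProfile:
    """Binned probability of niche occupancy along one variable."""

    species: str
    variable: str
    edges: np.ndarray      # n_bins + 1, strictly increasing
    mass: np.ndarray       # n_bins, sums to 1

    def __post_init__(self) -> None:
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.mass < 0) or abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("mass must be non-negative and sum to 1")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def variable_bins(stack: EnvStack, variable: str, n_bins: int = 50) -> np.ndarray:
    """Common bin edges spanning a variable's range over valid cells."""
    vals = stack.values(variable)
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        warnings.warn(f"variable {variable!r} is constant; degenerate single-bin profile")
        return np.array([lo - 0.5, lo + 0.5])
    return np.linspace(lo, hi, n_bins + 1)


def compute_pno(
    model: NicheModel,
    stack: EnvStack,
    variable: str,
    n_bins: int = 50,
    edges: np.ndarray | None = None,
    surface: str = "logistic",
) -> PNOProfile:
    """PNO profile of one species along one variable.

    Bins span the variable's global min/max over valid cells (pass ``edges``
    to share exact bins across species); each bin receives the summed,
    normalized suitability of the cells whose value falls in it.
    """
    if variable not in stack.variables:
        raise KeyError(f"variable {variable!r} not in stack")
    if edges is None:
        edges = variable_bins(stack, variable, n_bins)
    p = model.normalized_logistic() if surface == "logistic" else model.raw
    vals = stack.values(variable)
    mass, _ = np.histogram(vals, bins=edges, weights=p)
    # np.histogram puts values == upper edge in the last bin already; guard
    # against mass lost to floating-point at the extremes
    mass = mass / mass.sum()
    return PNOProfile(model.species, variable, np.asarray(edges, float), mass)


def pno_weighted_mean(profile: PNOProfile) -> float:
    """Probability-weighted mean niche position: Σ midpoint × mass."""
    return float(profile.midpoints @ profile.mass)


@dataclass
class AncestralTolerance:
    """Sampled ancestral niche values per internal node for one variable."""

    variable: str
    node_samples: np.ndarray      # (n_samples, n_internal); root is last column
    summary: pd.DataFrame         # per node: mean, lower, upper
    n_samples: int


def ancestral_tolerance(
    tree: Tree,
    profiles: dict[str, PNOProfile],
    n_samples: int = 100,
    conf: float = 0.90,
    rng: np.random.Generator | int | None = None,
) -> AncestralTolerance:
    """Brownian-motion ancestral tolerance reconstruction from PNO profiles.

    Each of ``n_samples`` draws picks one value per tip (a bin midpoint with
    probability equal to the bin's mass) and reconstructs all internal nodes
    by ML under Brownian motion; node distributions aggregate the samples.
    """
    rng = np.random.default_rng(rng)
    missing = [n for n in tree.tip_names if n not in profiles]
    if missing:
        raise KeyError(f"no PNO profile for tips: {missing}")
    variable = profiles[tree.tip_names[0]].variable
    tips = np.empty((n_samples, tree.n_tips))
    for j, name in enumerate(tree.tip_names):
        prof = profiles[name]
        tips[:, j] = rng.choice(prof.midpoints, size=n_samples, p=prof.mass)
    nodes = bm_ancestral_states(tree, tips)   # (n_samples, n_internal)
    alpha = 1.0 - conf
    summary = pd.DataFrame(
        {
            "node": np.arange(tree.n_tips, tree.n_nodes),
            "age": tree.node_ages()[tree.n_tips :],
            "mean": nodes.mean(axis=0),
            "lower": np.quantile(nodes, alpha / 2, axis=0),
            "upper": np.quantile(nodes, 1 - alpha / 2, axis=0),
        }
    )
    return AncestralTolerance(variable, nodes, summary, n_samples)


@dataclass
class ARCResult:
    """Age-range correlation: per-node overlap vs node age."""

    table: pd.DataFrame           # node, age, overlap, fit, lower, upper, flag
    slope: float
    intercept: float
    p_value: float
    weighting: str
    conf: float
    n_permutations: int


def node_overlaps(tree: Tree, overlap: OverlapMatrix | pd.DataFrame,
                  metric: str = "D", weighting: str = "ft") -> pd.DataFrame:
    """Mean cross-clade overlap at each internal node.

    For node n, the contributing pairs are tips whose MRCA is n.  Weighting
    ``"ft"`` down-weights nested pairs by 0.5^k with k the number of internal
    nodes on the tip-to-tip path excluding n (cherries get weight 1);
    ``"mean"`` averages all cross-clade pairs equally.
    """
    M = overlap.D if isinstance(overlap, OverlapMatrix) else overlap
    M = M.loc[tree.tip_names, tree.tip_names] if isinstance(M, pd.DataFrame) else M
    if isinstance(overlap, OverlapMatrix) and metric == "I":
        M = overlap.I.loc[tree.tip_names, tree.tip_names]
    vals = np.asarray(M, dtype=float)
    mrca = tree.mrca_matrix()
    # number of internal ancestors of each tip strictly below each node
    depth_below = np.zeros((tree.n_tips, tree.n_nodes), dtype=int)
    for tip in range(tree.n_tips):
        count = 0
        node = tip
        while node != tree.root:
            par = tree.parent[node]
            if node >= tree.n_tips:
                count += 1
            # ancestors of tip above `node`: record count at parent
            depth_below[tip, par] = count
            node = par
    rows = []
    ages = tree.node_ages()
    for n in range(tree.n_tips, tree.n_nodes):
        ii, jj = np.nonzero(np.triu(mrca == n, k=1))
        if weighting == "ft":
            k = depth_below[ii, n] + depth_below[jj, n]
            w = 0.5 ** k.astype(float)
        elif weighting == "mean":
            w = np.ones(len(ii))
        else:
            raise ValueError("weighting must be 'ft' or 'mean'")
        rows.append(
            {"node": n, "age": ages[n], "overlap": float(np.average(vals[ii, jj], weights=w))}
        )
    return pd.DataFrame(rows)


def age_range_correlation(
    tree: Tree,
    overlap: OverlapMatrix | pd.DataFrame,
    metric: str = "D",
    weighting: str = "ft",
    n_permutations: int = 1000,
    conf: float = 0.95,
    interval: str = "prediction",
    rng: np.random.Generator | int | None = None,
) -> ARCResult:
    """Regress per-node niche overlap on node age.

    The significance of the slope comes from permuting tip identities of the
    overlap matrix (two-sided).  Per-node 95 % intervals (prediction by
    default, mean-response via ``interval="confidence"``) flag nodes with
    more overlap than expected for their age ("above", candidate
    conservatism) or less ("below", candidate divergence).
    """
    rng = np.random.default_rng(rng)
    if tree.n_tips - 1 < 3:
        raise ValueError("need at least 3 internal nodes for the ARC regression")
    df = node_overlaps(tree, overlap, metric, weighting)
    x, y = df["age"].to_numpy(), df["overlap"].to_numpy()
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    fit = intercept + slope * x
    resid = y - fit
    s2 = resid @ resid / (n - 2)
    sxx = ((x - x.mean()) ** 2).sum()
    lev = 1.0 / n + (x - x.mean()) ** 2 / sxx
    if interval == "prediction":
        se = np.sqrt(s2 * (1.0 + lev))
    elif interval == "confidence":
        se = np.sqrt(s2 * lev)
    else:
        raise ValueError("interval must be 'prediction' or 'confidence'")
    tcrit = stats.t.ppf(0.5 + conf / 2.0, n - 2)
    df["fit"] = fit
    df["lower"] = fit - tcrit * se
    df["upper"] = fit + tcrit * se
    df["flag"] = np.where(y > df["upper"], "above", np.where(y < df["lower"], "below", ""))
    # permutation test on the slope
    M = overlap.D if isinstance(overlap, OverlapMatrix) else overlap
    if isinstance(overlap, OverlapMatrix) and metric == "I":
        M = overlap.I
    if isinstance(M, pd.DataFrame):
        M = M.loc[tree.tip_names, tree.tip_names].to_numpy()
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(tree.n_tips)
        Mp = pd.DataFrame(M[np.ix_(perm, perm)], index=tree.tip_names, columns=tree.tip_names)
        dfp = node_overlaps(tree, Mp, "D", weighting)
        sp = np.polyfit(dfp["age"], dfp["overlap"], 1)[0]
        if abs(sp) >= abs(slope):
            count += 1
    p_value = (1.0 + count) / (n_permutations + 1.0)
    return ARCResult(df, float(slope), float(intercept), float(p_value),
                     weighting, conf, n_permutations)
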