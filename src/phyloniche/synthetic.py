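"""Synthetic landscapes, phylogenies, and tree-structured species niches.

Every downstream stage (niche models, overlap tests, ancestral tolerances,
disparity) is exercised on data from this module, so its constructions are
deliberately transparent:

* environmental layers are Gaussian-smoothed white noise mixed through the
  Cholesky factor of a target inter-variable correlation matrix and affinely
  rescaled to stated ranges — spatially autocorrelated and inter-correlated
  like bioclim layers, with known statistics;
* trees are pure-birth (Yule) and rescaled to depth 1 (relative time);
* per-species niche optima evolve along the tree under Brownian motion
  (divergence) or an Ornstein–Uhlenbeck pull back to the clade ancestor
  (conservatism), using exact transition distributions;
* occurrences are drawn from the true suitability surface, a product of
  per-variable Gaussian (bell) responses, so the data-generating niche is
  known analytically for parameter-recovery tests.

All four generators are deterministic given a seed; stages derive
independent substreams from one global seed by hashing the stage name.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from phyloniche.geodata import EnvStack, OccurrenceSet
from phyloniche.phylo import Tree


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible substream for a named pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(stage.encode())])
    )


@dataclass
class NicheSpec:
    """True niche of one species: per-variable optimum and breadth.

    Suitability at a cell with environment e is
    ``exp(-Σ_k (e_k − mu_k)² / (2 sigma_k²))`` — a product of independent
    Gaussian responses, the simplest unimodal niche whose tolerances are
    recoverable analytically.
    """

    mu: dict[str, float]
    sigma: dict[str, float]

    def __post_init__(self) -> None:
        for v, s in self.sigma.items():
            if s <= 0:
                raise ValueError(f"sigma[{v!r}] must be positive")

    def suitability(self, stack: EnvStack) -> np.ndarray:
        """True suitability over valid cells (flattened row-major order)."""
        s = np.zeros(stack.n_cells)
        for v in stack.variables:
            if v in self.mu:
                z = (stack.values(v) - self.mu[v]) / self.sigma[v]
                s += -0.5 * z * z
        return np.exp(s)


@dataclass
class SimConfig:
    """Study-scale defaults for a full synthetic dataset.

    The defaults describe a desk-scale analogue of a regional bioclim
    study: a 40×40 projected grid with ~1-km cells, three inter-correlated
    autocorrelated layers, an 8-species clade, and 30 records per species.
    """

    n_rows: int = 40
    n_cols: int = 40
    cellsize: float = 1.0
    variables: tuple[str, ...] = ("bio4", "bio6", "bio15")
    autocorr_length: float = 3.0
    correlation: np.ndarray | None = None  # target inter-variable correlation
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "bio4": (13.7, 41.4),   # temperature seasonality, °C
            "bio6": (7.0, 18.9),    # min temperature coldest month, °C
            "bio15": (5.1, 7.8),    # precipitation seasonality (CV)
        }
    )
    n_tips: int = 8
    birth_rate: float = 1.0
    regime: str = "BM"                # "BM" (divergence) or "OU" (conservatism)
    clade_regimes: dict[str, str] | None = None
    bm_rate_rel: float = 1.0          # optimum SD over unit depth, in background SDs
    ou_alpha: float = 8.0             # OU pull toward the clade-root optimum
    n_occurrences: int = 30
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        k = len(self.variables)
        if self.correlation is None:
            # mild positive dependence, like co-varying climate layers
            R = np.full((k, k), 0.4)
            np.fill_diagonal(R, 1.0)
            return R
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (k, k) or not np.allclose(R, R.T):
            raise ValueError("correlation must be a symmetric k×k matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation diagonal must be 1")
        return R


def simulate_env_stack(config: SimConfig) -> EnvStack:
    """Simulate inter-correlated, spatially autocorrelated layers.

    Per layer: white noise smoothed with a Gaussian kernel (bandwidth =
    ``autocorr_length`` cells, 0 = i.i.d. cells), standardized, then the
    layers are mixed by the Cholesky factor of the target correlation matrix
    and affinely rescaled to each variable's stated range (range endpoints
    map to ±2 SD).
    """
    rng = stage_rng(config.seed, "env")
    R = config.correlation_matrix()
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation matrix is not positive semidefinite") from exc
    k = len(config.variables)
    fields = rng.standard_normal((k, config.n_rows, config.n_cols))
    if config.autocorr_length > 0:
        fields = np.stack(
            [gaussian_filter(f, sigma=config.autocorr_length, mode="wrap") for f in fields]
        )
    flat = fields.reshape(k, -1)
    flat = (flat - flat.mean(axis=1, keepdims=True)) / flat.std(axis=1, keepdims=True)
    mixed = L @ flat
    grids = {}
    for i, v in enumerate(config.variables):
        lo, hi = config.ranges.get(v, (0.0, 1.0))
        mid, half = 0.5 * (lo + hi), 0.25 * (hi - lo)
        grids[v] = (mid + half * mixed[i]).reshape(config.n_rows, config.n_cols)
    mask = np.ones((config.n_rows, config.n_cols), dtype=bool)
    return EnvStack(list(config.variables), grids, 0.0, 0.0, config.cellsize, mask)


def simulate_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int | np.random.Generator = 0,
    rescale_depth: float | None = 1.0,
) -> Tree:
    """Pure-birth (Yule) tree, by default rescaled to depth 1 (relative time).

    Speciation events occur at total rate ``k·birth_rate`` for k extant
    lineages; all tips are sampled at the time of the (n_tips)th lineage's
    birth, giving an ultrametric tree.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else stage_rng(seed, "tree")
    # grow from the root's two children
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=int)
    birth_time = np.zeros(n_nodes)
    root = n_nodes - 1
    next_internal = n_nodes - 2
    next_tip = 0
    # active lineages as (provisional) slots; assign final indices at the end
    lineages: list[dict] = [
        {"parent": root, "t0": 0.0},
        {"parent": root, "t0": 0.0},
    ]
    t = 0.0
    while len(lineages) < n_tips:
        k = len(lineages)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        # lineage i speciates at time t: becomes an internal node
        node = next_internal
        next_internal -= 1
        parent[node] = lineages[i]["parent"]
        birth_time[node] = t
        lineages[i] = {"parent": node, "t0": t}
        lineages.append({"parent": node, "t0": t})
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    lengths = np.zeros(n_nodes)
    for node in range(n_tips, n_nodes - 1):
        lengths[node] = birth_time[node] - birth_time[parent[node]]
    names = []
    for lin in lineages:
        tip = next_tip
        next_tip += 1
        parent[tip] = lin["parent"]
        lengths[tip] = t_end - lin["t0"]
        names.append(f"sp{tip + 1:02d}")
    tree = Tree(parent, lengths, names)
    if rescale_depth is not None:
        tree = tree.rescale(rescale_depth)
    return tree


def evolve_niches(
    tree: Tree,
    root_spec: NicheSpec,
    bm_rate: float | dict[str, float],
    regime: str = "BM",
    ou_alpha: float = 0.0,
    clade_regimes: dict[frozenset[str], str] | None = None,
    seed: int | np.random.Generator = 0,
) -> dict[str, NicheSpec]:
    """Evolve niche optima along the tree; breadths are inherited unchanged.

    ``bm_rate`` is the increment variance per unit time, either one value for
    all variables or a per-variable dict (variables live on very different
    scales, so per-variable rates are the norm).

    Under ``"BM"`` each branch adds a Normal(0, bm_rate·t) increment to every
    optimum (niche divergence).  Under ``"OU"`` the exact Ornstein–Uhlenbeck
    transition pulls each optimum back toward the value at its regime's root
    with strength ``ou_alpha`` (niche conservatism): along a branch of length
    t, x' ~ Normal(θ + (x − θ)e^{−αt}, bm_rate·(1 − e^{−2αt})/(2α)).

    ``clade_regimes`` maps frozensets of tip names to a regime for that
    clade's subtree (the MRCA value is the OU attractor θ); elsewhere the
    global ``regime`` applies with the tree root as attractor.
    """
    if regime not in ("BM", "OU"):
        raise ValueError("regime must be 'BM' or 'OU'")
    rng = seed if isinstance(seed, np.random.Generator) else stage_rng(seed, "niches")
    variables = list(root_spec.mu)
    rates = bm_rate if isinstance(bm_rate, dict) else {v: bm_rate for v in variables}
    if ou_alpha < 0 or any(r < 0 for r in rates.values()):
        raise ValueError("rates must be non-negative")
    sets = tree.tip_sets()
    node_regime = np.array([regime] * tree.n_nodes, dtype=object)
    attractor_root = np.full(tree.n_nodes, tree.root, dtype=int)
    if clade_regimes:
        name_to_idx = {n: i for i, n in enumerate(tree.tip_names)}
        for tip_names, reg in clade_regimes.items():
            want = {name_to_idx[n] for n in tip_names}
            mrca = min(
                (n for n in range(tree.n_nodes) if sets[n] >= want),
                key=lambda n: len(sets[n]),
            )
            for n in range(tree.n_nodes):
                if sets[n] <= sets[mrca]:
                    node_regime[n] = reg
                    attractor_root[n] = mrca
    values = {v: np.empty(tree.n_nodes) for v in variables}
    for v in variables:
        values[v][tree.root] = root_spec.mu[v]
    for node in tree.preorder[1:]:
        par = tree.parent[node]
        t = tree.lengths[node]
        for v in variables:
            x = values[v][par]
            if node_regime[node] == "OU" and ou_alpha > 0:
                theta = values[v][attractor_root[node]]
                decay = np.exp(-ou_alpha * t)
                mean = theta + (x - theta) * decay
                var = rates[v] * (1.0 - decay**2) / (2.0 * ou_alpha)
            else:
                mean, var = x, rates[v] * t
            values[v][node] = rng.normal(mean, np.sqrt(var))
    return {
        name: NicheSpec(
            mu={v: float(values[v][i]) for v in variables},
            sigma=dict(root_spec.sigma),
        )
        for i, name in enumerate(tree.tip_names)
    }


def sample_occurrences(
    stack: EnvStack,
    spec: NicheSpec,
    n: int,
    seed: int | np.random.Generator = 0,
    species: str = "species",
) -> OccurrenceSet:
    """Draw presences from the true suitability surface.

    Cells are drawn (with replacement) with probability proportional to
    suitability; each point is then placed uniformly within its cell.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else stage_rng(seed, f"occ:{species}")
    s = spec.suitability(stack)
    total = s.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("suitability is zero everywhere; cannot sample")
    rows, cols = np.nonzero(stack.mask)
    idx = rng.choice(len(s), size=n, p=s / total)
    jitter = rng.random((n, 2))
    xs = stack.x0 + (cols[idx] + jitter[:, 0]) * stack.cellsize
    y_top = stack.y0 + stack.n_rows * stack.cellsize
    ys = y_top - (rows[idx] + jitter[:, 1]) * stack.cellsize
    return OccurrenceSet(species, np.column_stack([xs, ys]), source="synthetic")
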