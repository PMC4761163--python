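"""Niche overlap statistics and randomization tests.

Overlap between two species is measured on their suitability surfaces,
renormalized to probability distributions over the shared grid support:

* Schoener's D = 1 − ½ Σ_i |p_i − q_i|
* Warren's I   = 1 − ½ Σ_i (√p_i − √q_i)²   (one minus half the squared
  Hellinger distance)

Both range from 0 (no overlap) to 1 (identical surfaces) and I ≥ D always.

Two randomization tests give the overlap a null reference:

* the **niche identity test** pools the two species' occurrences and
  repeatedly repartitions them at random into pseudo-samples of the original
  sizes, refitting both models; identity is rejected when the observed
  overlap falls below the null's lower one-sided bound;
* the **background similarity test** refits one species' model to random
  "pseudolocality" cells drawn from that species' accessible background and
  compares the other species' real model against the resulting null:
  observed overlap above the upper bound indicates niche conservatism,
  below the lower bound niche divergence.

Percentile bounds use raw order statistics at rank ⌈q·(n+1)⌉, so the
default 100 replicates attain a one-sided level of 5/101 ≈ 4.95 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from phyloniche.geodata import EnvStack, OccurrenceSet
from phyloniche.enm import NicheModel, fit_maxent, presence_cells


def _check_normalized(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} is not normalized (sums to {p.sum()!r})")
    return p


def schoener_D(pX: np.ndarray, pY: np.ndarray) -> float:
    """Schoener's D between two normalized surfaces."""
    pX = _check_normalized(pX, "pX")
    pY = _check_normalized(pY, "pY")
    return float(1.0 - 0.5 * np.abs(pX - pY).sum())


def warren_I(pX: np.ndarray, pY: np.ndarray) -> float:
    """Warren's I (Hellinger-based) between two normalized surfaces."""
    pX = _check_normalized(pX, "pX")
    pY = _check_normalized(pY, "pY")
    return float(1.0 - 0.5 * ((np.sqrt(pX) - np.sqrt(pY)) ** 2).sum())


def model_overlap(a: NicheModel, b: NicheModel, surface: str = "logistic") -> dict[str, float]:
    """D and I between two fitted models on the same stack."""
    if surface == "logistic":
        p, q = a.normalized_logistic(), b.normalized_logistic()
    elif surface == "raw":
        p, q = a.raw, b.raw
    else:
        raise ValueError("surface must be 'logistic' or 'raw'")
    return {"D": schoener_D(p, q), "I": warren_I(p, q)}


@dataclass
class OverlapMatrix:
    species: list[str]
    D: pd.DataFrame
    I: pd.DataFrame


def overlap_matrix(models: dict[str, NicheModel], surface: str = "logistic") -> OverlapMatrix:
    """All pairwise D and I overlaps; symmetric with unit diagonal."""
    names = list(models)
    n = len(names)
    D = np.eye(n)
    Imat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ov = model_overlap(models[names[i]], models[names[j]], surface)
            D[i, j] = D[j, i] = ov["D"]
            Imat[i, j] = Imat[j, i] = ov["I"]
    return OverlapMatrix(
        species=names,
        D=pd.DataFrame(D, index=names, columns=names),
        I=pd.DataFrame(Imat, index=names, columns=names),
    )


def percentile_bound(null: np.ndarray, q: float) -> float:
    """Order-statistic percentile without interpolation: rank ⌈q(n+1)⌉, clipped."""
    s = np.sort(np.asarray(null, dtype=float))
    n = len(s)
    rank = int(np.ceil(q * (n + 1)))
    return float(s[min(max(rank, 1), n) - 1])


@dataclass
class RandomizationResult:
    """Outcome of an identity or background randomization test."""

    pair: tuple[str, str]
    direction: str
    observed: dict[str, float]           # D and I
    metric: str                          # metric the verdict is based on
    null: np.ndarray = field(repr=False)
    lower: float = 0.0
    upper: float = 1.0
    conf: float = 0.95
    verdict: str = "n.s."

    @property
    def rejected(self) -> bool:
        return self.verdict not in ("n.s.", "identity-not-rejected")


def _refit(stack, species, pres_idx, beta, max_iter):
    occ = OccurrenceSet(species, np.empty((0, 2)))
    return fit_maxent(
        stack, occ, beta=beta, max_iter=max_iter, min_occurrences=1, _presence_idx=pres_idx
    )


def identity_test(
    stack: EnvStack,
    occA: OccurrenceSet,
    occB: OccurrenceSet,
    metric: str = "D",
    n_replicates: int = 100,
    conf: float = 0.95,
    rng: np.random.Generator | int | None = None,
    beta: float = 1.0,
    max_iter: int = 1000,
    surface: str = "logistic",
) -> RandomizationResult:
    """Niche identity test for one species pair.

    Null replicates pool both species' occurrences and repartition them at
    random into pseudo-samples of the original sizes before refitting both
    models; identity is rejected when the observed overlap lies below the
    null's lower one-sided bound at the configured confidence.
    """
    rng = np.random.default_rng(rng)
    modelA = fit_maxent(stack, occA, beta=beta, max_iter=max_iter)
    modelB = fit_maxent(stack, occB, beta=beta, max_iter=max_iter)
    observed = model_overlap(modelA, modelB, surface)
    pool = np.concatenate([presence_cells(stack, occA), presence_cells(stack, occB)])
    nA = len(occA)
    null = []
    attempts = 0
    while len(null) < n_replicates:
        if attempts >= 3 * n_replicates:
            raise RuntimeError("too many failed null replicates in identity test")
        attempts += 1
        perm = rng.permutation(len(pool))
        try:
            mA = _refit(stack, occA.species, pool[perm[:nA]], beta, max_iter)
            mB = _refit(stack, occB.species, pool[perm[nA:]], beta, max_iter)
        except Exception:
            continue
        null.append(model_overlap(mA, mB, surface)[metric])
    null = np.asarray(null)
    lower = percentile_bound(null, 1.0 - conf)
    rejected = observed[metric] < lower
    return RandomizationResult(
        pair=(occA.species, occB.species),
        direction="pooled",
        observed=observed,
        metric=metric,
        null=null,
        lower=lower,
        upper=percentile_bound(null, conf),
        conf=conf,
        verdict="identity-rejected" if rejected else "identity-not-rejected",
    )


def background_mask(
    stack: EnvStack, occ: OccurrenceSet, buffer_cells: float = 5.0
) -> np.ndarray:
    """Accessible background of a species: buffered convex hull of its
    occurrences intersected with the valid grid.  Returns a boolean array
    over valid cells (flattened row-major)."""
    hull = shapely.MultiPoint(occ.points).convex_hull
    region = hull.buffer(buffer_cells * stack.cellsize)
    rows, cols = np.nonzero(stack.mask)
    xs = stack.x0 + (cols + 0.5) * stack.cellsize
    y_top = stack.y0 + stack.n_rows * stack.cellsize
    ys = y_top - (rows + 0.5) * stack.cellsize
    inside = shapely.contains_xy(region, xs, ys)
    if not inside.any():
        raise ValueError(f"background of {occ.species} is empty")
    return inside


def background_test(
    stack: EnvStack,
    occA: OccurrenceSet,
    occB: OccurrenceSet,
    background_B: np.ndarray | None = None,
    metric: str = "D",
    n_replicates: int = 100,
    conf: float = 0.95,
    rng: np.random.Generator | int | None = None,
    beta: float = 1.0,
    max_iter: int = 1000,
    surface: str = "logistic",
    buffer_cells: float = 5.0,
) -> RandomizationResult:
    """Background similarity test, direction A vs background of B.

    Null replicates draw |occB| distinct pseudolocality cells uniformly from
    species B's background, fit a model to them, and overlap it with species
    A's real model.  Observed overlap above the upper one-sided bound is
    called niche conservatism; below the lower bound, niche divergence.
    Run the swapped direction by exchanging the arguments.
    """
    rng = np.random.default_rng(rng)
    if background_B is None:
        background_B = background_mask(stack, occB, buffer_cells)
    bg_cells = np.nonzero(np.asarray(background_B, dtype=bool))[0]
    nB = len(occB)
    if len(bg_cells) < nB:
        raise ValueError(
            f"background of {occB.species} has {len(bg_cells)} cells < {nB} pseudolocalities"
        )
    modelA = fit_maxent(stack, occA, beta=beta, max_iter=max_iter)
    modelB = fit_maxent(stack, occB, beta=beta, max_iter=max_iter)
    observed = model_overlap(modelA, modelB, surface)
    null = []
    attempts = 0
    while len(null) < n_replicates:
        if attempts >= 3 * n_replicates:
            raise RuntimeError("too many failed null replicates in background test")
        attempts += 1
        cells = rng.choice(bg_cells, size=nB, replace=False)
        try:
            m_null = _refit(stack, f"{occB.species}:null", cells, beta, max_iter)
        except Exception:
            continue
        null.append(model_overlap(modelA, m_null, surface)[metric])
    null = np.asarray(null)
    lower = percentile_bound(null, 1.0 - conf)
    upper = percentile_bound(null, conf)
    if observed[metric] > upper:
        verdict = "conservatism"
    elif observed[metric] < lower:
        verdict = "divergence"
    else:
        verdict = "n.s."
    return RandomizationResult(
        pair=(occA.species, occB.species),
        direction=f"{occA.species} vs background({occB.species})",
        observed=observed,
        metric=metric,
        null=null,
        lower=lower,
        upper=upper,
        conf=conf,
        verdict=verdict,
    )


def within_clade_pairs(clades: dict[str, str]) -> dict[str, list[tuple[str, str]]]:
    """All unordered within-clade species pairs, per clade."""
    out: dict[str, list[tuple[str, str]]] = {}
    by_clade: dict[str, list[str]] = {}
    for sp, cl in clades.items():
        by_clade.setdefault(cl, []).append(sp)
    for cl, members in by_clade.items():
        out[cl] = [
            (members[i], members[j])
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
    return out


def summarize_within_clade(
    clades: dict[str, str],
    verdicts: dict[frozenset, str] | None = None,
) -> pd.DataFrame:
    """Within-clade pair counts, and verdict counts/percentages if given.

    Each modeled species must carry exactly one clade label.  Percentages are
    rounded to the nearest integer (k significant of n → round(100·k/n)).
    """
    pairs = within_clade_pairs(clades)
    rows = []
    for cl, plist in sorted(pairs.items()):
        row: dict = {"clade": cl, "n_pairs": len(plist)}
        if verdicts is not None:
            counts: dict[str, int] = {}
            for pair in plist:
                key = frozenset(pair)
                if key not in verdicts:
                    raise KeyError(f"no verdict recorded for pair {tuple(pair)}")
                v = verdicts[key]
                counts[v] = counts.get(v, 0) + 1
            for v, k in sorted(counts.items()):
                row[f"n_{v}"] = k
                row[f"pct_{v}"] = int(np.floor(100.0 * k / len(plist) + 0.5))
        rows.append(row)
    df = pd.DataFrame(rows).fillna(0)
    count_cols = [c for c in df.columns if c.startswith(("n_", "pct_"))]
    df[count_cols] = df[count_cols].astype(int)
    return df
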