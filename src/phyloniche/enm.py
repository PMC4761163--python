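"""Presence-only maximum-entropy niche models.

The model is the Gibbs distribution over grid cells

    p_λ(i) ∝ exp(λ · f(i)),

with features f the standardized linear and quadratic terms of each
environmental variable, fitted by minimizing the L1-penalized negative
log-likelihood of the presence cells

    J(λ) = −(1/m) Σ_presences λ·f + log Z(λ) + Σ_j β_j |λ_j|,
    β_j = β · s_j / √m,

where s_j is the feature's standard deviation over the presences and m the
number of presences.  This is the convex core of MAXENT restricted to
linear+quadratic features; hinge/product/threshold features and clamping are
deliberately omitted.  The L1 problem is solved smoothly by splitting
λ = λ⁺ − λ⁻ with non-negativity bounds (L-BFGS-B), so the objective is
monotone under the optimizer and the KKT condition
|E_p[f_j] − mean_presence f_j| ≤ β_j holds at the solution.

The logistic output follows MAXENT's definition with prevalence τ:
c_i = τ·e^H·p_i / (1 − τ + τ·e^H·p_i), H the entropy of p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from phyloniche.geodata import EnvStack, OccurrenceSet

MIN_OCCURRENCES = 5


class TooFewOccurrencesError(ValueError):
    """Species below the modeling minimum: excluded from niche analyses."""


def feature_matrix(stack: EnvStack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_cells × 2k) standardized linear+quadratic features, cached on the stack.

    Standardization uses the background (all valid cells) mean/SD so that
    models fitted to different occurrence sets share one feature space.
    Returns (features, background mean, background SD of the raw columns).
    """
    cache = getattr(stack, "_feature_cache", None)
    if cache is not None:
        return cache
    X = stack.table()
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd
    F = np.concatenate([Z, Z * Z], axis=1)
    stack._feature_cache = (F, mean, sd)  # type: ignore[attr-defined]
    return stack._feature_cache  # type: ignore[attr-defined]


def _cell_index_map(stack: EnvStack) -> np.ndarray:
    """Grid of flat valid-cell indices (−1 on masked cells), cached."""
    cached = getattr(stack, "_cell_index", None)
    if cached is not None:
        return cached
    idx = np.full(stack.mask.shape, -1, dtype=int)
    idx[stack.mask] = np.arange(stack.n_cells)
    stack._cell_index = idx  # type: ignore[attr-defined]
    return idx


def presence_cells(stack: EnvStack, occ: OccurrenceSet) -> np.ndarray:
    """Flat valid-cell index of each occurrence point (order preserved)."""
    idx = _cell_index_map(stack)
    out = np.empty(len(occ), dtype=int)
    for i, (x, y) in enumerate(occ.points):
        r, c = stack.cell_of(x, y)
        if idx[r, c] < 0:
            raise ValueError(f"occurrence ({x}, {y}) falls on a masked cell")
        out[i] = idx[r, c]
    return out


@dataclass
class NicheModel:
    """A fitted maximum-entropy niche model for one species."""

    species: str
    variables: list[str]
    feature_names: list[str]
    lambdas: np.ndarray            # one weight per feature
    beta: float
    raw: np.ndarray                # distribution over valid cells, sums to 1
    logistic: np.ndarray           # per valid cell, in [0, 1]
    entropy: float
    presence_idx: np.ndarray       # valid-cell index of each training presence
    mtp: float = field(init=False)
    converged: bool = True
    tau: float = 0.5

    def __post_init__(self) -> None:
        self.mtp = float(self.logistic[self.presence_idx].min()) if len(self.presence_idx) else 0.0

    def logistic_grid(self, stack: EnvStack) -> np.ndarray:
        """Logistic surface on the full grid (NaN outside the mask)."""
        g = np.full(stack.mask.shape, np.nan)
        g[stack.mask] = self.logistic
        return g

    def normalized_logistic(self) -> np.ndarray:
        """Logistic surface rescaled to a probability distribution over cells."""
        return self.logistic / self.logistic.sum()


def _fit_lambdas(
    F: np.ndarray,
    pres: np.ndarray,
    beta: float,
    max_iter: int,
    tol: float = 1e-6,
) -> tuple[np.ndarray, bool]:
    m, J = len(pres), F.shape[1]
    if J == 0:
        # no constraints: maximum entropy is the uniform distribution
        return np.zeros(0), True
    f_pres = F[pres]
    target = f_pres.mean(axis=0)
    s = f_pres.std(axis=0)
    b = beta * s / np.sqrt(m)

    def objective(uv: np.ndarray) -> tuple[float, np.ndarray]:
        lam = uv[:J] - uv[J:]
        eta = F @ lam
        logz = logsumexp(eta)
        p = np.exp(eta - logz)
        val = logz - target @ lam + b @ (uv[:J] + uv[J:])
        g = F.T @ p - target
        return val, np.concatenate([g + b, -g + b])

    res = minimize(
        objective,
        np.zeros(2 * J),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * J),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    lam = res.x[:J] - res.x[J:]
    return lam, bool(res.success) or res.status == 0


def fit_maxent(
    stack: EnvStack,
    occ: OccurrenceSet,
    beta: float = 1.0,
    max_iter: int = 1000,
    tau: float = 0.5,
    min_occurrences: int = MIN_OCCURRENCES,
    _presence_idx: np.ndarray | None = None,
) -> NicheModel:
    """Fit the penalized maximum-entropy model for one species.

    Raises :class:`TooFewOccurrencesError` below ``min_occurrences`` presences
    (such species are excluded from niche analyses).  Warns without failing
    if the optimizer hits ``max_iter``.
    """
    pres = presence_cells(stack, occ) if _presence_idx is None else _presence_idx
    if len(pres) < min_occurrences:
        raise TooFewOccurrencesError(
            f"{occ.species}: {len(pres)} occurrence(s) < {min_occurrences}; "
            "excluded from niche analyses"
        )
    F, _, _ = feature_matrix(stack)
    lam, ok = _fit_lambdas(F, pres, beta, max_iter)
    if not ok:
        warnings.warn(f"{occ.species}: optimizer did not converge in {max_iter} iterations")
    eta = F @ lam
    logz = logsumexp(eta)
    raw = np.exp(eta - logz)
    H = float(-(raw * (eta - logz)).sum())
    q = tau * np.exp(np.clip(np.log(raw) + H, -700, 700))
    logistic = q / (1.0 - tau + q)
    names = [f"{v}" for v in stack.variables] + [f"{v}^2" for v in stack.variables]
    return NicheModel(
        species=occ.species,
        variables=list(stack.variables),
        feature_names=names,
        lambdas=lam,
        beta=beta,
        raw=raw,
        logistic=logistic,
        entropy=H,
        presence_idx=pres,
        converged=ok,
        tau=tau,
    )


@dataclass
class AUCReport:
    species: str
    replicate_auc: list[float]
    mean_auc: float
    gate: float
    passed: bool
    train_frac: float
    splits: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list, repr=False)


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann–Whitney AUC with ties counted 0.5."""
    from scipy.stats import rankdata

    scores = np.concatenate([pos, neg])
    ranks = rankdata(scores)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def evaluate_auc(
    stack: EnvStack,
    occ: OccurrenceSet,
    n_replicates: int = 10,
    train_frac: float = 0.59,
    gate: float = 0.7,
    beta: float = 1.0,
    max_iter: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> AUCReport:
    """Replicate train/test AUC of the niche model.

    Each replicate holds out ``1 − train_frac`` of the presences, fits on the
    rest, and scores the held-out presences against all background cells by
    the rank (Mann–Whitney) AUC.
    """
    rng = np.random.default_rng(rng)
    pres = presence_cells(stack, occ)
    n = len(pres)
    n_train = int(round(train_frac * n))
    if n_train < 1 or n - n_train < 1:
        raise ValueError(f"{n} presences cannot be split {train_frac:.0%}/{1-train_frac:.0%}")
    aucs, splits = [], []
    for _ in range(n_replicates):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit_maxent(
            stack, occ, beta=beta, max_iter=max_iter,
            min_occurrences=1, _presence_idx=pres[tr],
        )
        aucs.append(_rank_auc(model.logistic[pres[te]], model.logistic))
        splits.append((tr, te))
    mean_auc = float(np.mean(aucs))
    return AUCReport(
        species=occ.species,
        replicate_auc=[float(a) for a in aucs],
        mean_auc=mean_auc,
        gate=gate,
        passed=mean_auc >= gate,
        train_frac=train_frac,
        splits=splits,
    )


def apply_mtp(model: NicheModel, stack: EnvStack) -> np.ndarray:
    """Binary suitability grid under the Minimum Training Presence threshold.

    A cell is suitable iff its logistic value is >= the lowest logistic value
    among the training presences; masked cells are False.
    """
    out = np.zeros(stack.mask.shape, dtype=bool)
    out[stack.mask] = model.logistic >= model.mtp
    return out


def cumulative_clade_map(models: list[NicheModel], stack: EnvStack) -> np.ndarray:
    """Per-cell sum of the clade members' logistic surfaces (raster-calculator
    style); NaN outside the mask.  All models must share the stack's grid."""
    if not models:
        raise ValueError("no models given")
    total = np.zeros(stack.n_cells)
    for m in models:
        if len(m.logistic) != stack.n_cells or m.variables != list(stack.variables):
            raise ValueError(f"model {m.species!r} was not fitted on this stack")
        total += m.logistic
    g = np.full(stack.mask.shape, np.nan)
    g[stack.mask] = total
    return g
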