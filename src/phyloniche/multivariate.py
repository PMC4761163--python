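"""Phylogenetic PCA and phylogenetic MANOVA on niche summaries.

The pPCA eigendecomposes the *evolutionary* covariance matrix

    R = (X − 1aᵀ)ᵀ C⁻¹ (X − 1aᵀ) / (N − 1),

where C is the Brownian-motion phylogenetic covariance of the tips and
a the GLS phylogenetic mean, so species are weighted by their independence
on the tree.  On a star phylogeny (C ∝ I) it reduces exactly to ordinary
covariance PCA.

The phylogenetic MANOVA keeps the ordinary Wilks'-Λ exact-F statistic for a
grouping factor but replaces its parametric reference by a simulation null:
traits are re-drawn under multivariate Brownian motion on the tree (rate
matrix estimated from the data) with the group labels held fixed, and the
p-value is the upper tail rank of the observed F among the simulated ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from phyloniche.phylo import Tree, phylo_covariance


@dataclass
class PPCAResult:
    variables: list[str]
    phylo_mean: np.ndarray        # a, one entry per variable
    evo_cov: np.ndarray           # R
    eigenvalues: np.ndarray       # non-negative, non-increasing
    eigenvectors: np.ndarray      # columns = components
    scores: pd.DataFrame          # species × PC
    explained: np.ndarray         # fractions summing to 1
    scaled: bool


def _as_cov(tree: Tree | np.ndarray) -> tuple[np.ndarray, list[str] | None]:
    """Accept either a tree or an explicit tip covariance matrix."""
    if isinstance(tree, Tree):
        return phylo_covariance(tree), tree.tip_names
    C = np.asarray(tree, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance must be a square matrix")
    return C, None


def phylo_pca(
    tree: Tree | np.ndarray,
    X: pd.DataFrame | np.ndarray,
    variables: list[str] | None = None,
    scale: bool = True,
) -> PPCAResult:
    """Phylogenetic PCA of a species × variables matrix.

    ``tree`` may also be an explicit tip covariance matrix (e.g. the identity
    for phylogenetically independent species).  Rows must match the tree's
    tips (a DataFrame is aligned by index).  With ``scale=True`` (default)
    each variable is first standardized to unit variance, since niche
    variables mix units (°C, cm, unitless).
    """
    C, tip_names = _as_cov(tree)
    if isinstance(X, pd.DataFrame):
        variables = list(X.columns)
        if tip_names is not None:
            X = X.loc[tip_names]
        tip_names = list(X.index)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if variables is None:
            variables = [f"var{i+1}" for i in range(X.shape[1])]
    n, p = X.shape
    if tip_names is None:
        tip_names = [f"t{i+1}" for i in range(n)]
    if n != C.shape[0]:
        raise ValueError("one row per tip required")
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance variable; exclude it before the pPCA")
        X = X / sd
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    denom = one @ Ci @ one
    a = (one @ Ci @ X) / denom
    Xc = X - a
    R = Xc.T @ Ci @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    scores = Xc @ evecs
    return PPCAResult(
        variables=variables,
        phylo_mean=a,
        evo_cov=R,
        eigenvalues=evals,
        eigenvectors=evecs,
        scores=pd.DataFrame(
            scores, index=tip_names, columns=[f"PC{i+1}" for i in range(p)]
        ),
        explained=evals / evals.sum(),
        scaled=scale,
    )


def wilks_F(Y: np.ndarray, groups: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    """Wilks' Λ and its exact/Rao F transform for a one-way MANOVA.

    Returns (Λ, F, (df1, df2)).  For two groups the transform is exact with
    df1 = p and df2 = N − p − 1.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    N, p = Y.shape
    labels = np.unique(groups)
    g = len(labels)
    grand = Y.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for lab in labels:
        sub = Y[groups == lab]
        mu = sub.mean(axis=0)
        d = sub - mu
        W += d.T @ d
        dm = (mu - grand)[:, None]
        B += len(sub) * (dm @ dm.T)
    lam = float(np.linalg.det(W) / np.linalg.det(W + B))
    q = g - 1
    denom = p * p + q * q - 5
    s = np.sqrt((p * p * q * q - 4.0) / denom) if denom > 0 else 1.0
    m = (N - g) - (p - q + 1) / 2.0
    df1 = p * q
    df2 = m * s - p * q / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    F = (1.0 - lam_s) / lam_s * df2 / df1
    return lam, float(F), (float(df1), float(df2))


@dataclass
class PhyloMANOVAResult:
    groups: pd.Series
    n_species: int
    n_variables: int
    n_groups: int
    wilks_lambda: float
    F: float
    df: tuple[float, float]
    null_F: np.ndarray
    p_value: float
    n_sims: int


def _mv_bm_null(C: np.ndarray, Y: np.ndarray, n_sims: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate tip trait matrices under multivariate BM with the rate matrix
    estimated (GLS) from the observed data; returns (n_sims, N, p)."""
    n, p = Y.shape
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    a = (one @ Ci @ Y) / (one @ Ci @ one)
    Yc = Y - a
    R = Yc.T @ Ci @ Yc / (n - 1)
    # Cholesky with an eigenvalue-clip fallback for near-singular R
    try:
        LR = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        ev, U = np.linalg.eigh(R)
        LR = U @ np.diag(np.sqrt(np.clip(ev, 0.0, None)))
    LC = np.linalg.cholesky(C)
    G = rng.standard_normal((n_sims, n, p))
    return LC @ G @ LR.T


def phylo_manova(
    tree: Tree | np.ndarray,
    scores: pd.DataFrame | np.ndarray,
    groups: dict[str, str] | pd.Series | np.ndarray,
    n_sims: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> PhyloMANOVAResult:
    """One-way phylogenetic MANOVA with a Brownian-simulation null.

    ``scores`` holds the response traits (e.g. the first few phylogenetic
    principal components) per species; ``groups`` assigns each species to a
    factor level (e.g. north/south of a biogeographic barrier).  The p-value
    is (1 + #{F_sim ≥ F_obs}) / (n_sims + 1).
    """
    rng = np.random.default_rng(rng)
    C, tip_names = _as_cov(tree)
    if isinstance(scores, pd.DataFrame):
        if tip_names is not None:
            scores = scores.loc[tip_names]
        tip_names = list(scores.index)
        Y = scores.to_numpy(dtype=float)
    else:
        Y = np.asarray(scores, dtype=float)
    if tip_names is None:
        tip_names = [f"t{i+1}" for i in range(len(Y))]
    if isinstance(groups, dict):
        lab = np.array([groups[n] for n in tip_names])
    elif isinstance(groups, pd.Series):
        lab = groups.loc[tip_names].to_numpy()
    else:
        lab = np.asarray(groups)
    N, p = Y.shape
    uniq, counts = np.unique(lab, return_counts=True)
    g = len(uniq)
    if np.any(counts < 2):
        small = uniq[counts < 2]
        raise ValueError(f"every group needs >= 2 species; too small: {list(small)}")
    if p >= N - g:
        raise ValueError(f"too many responses: need p < N - g ({p} >= {N - g})")
    lam, F_obs, df = wilks_F(Y, lab)
    sims = _mv_bm_null(C, Y, n_sims, rng)
    null_F = np.array([wilks_F(sims[k], lab)[1] for k in range(n_sims)])
    p_value = (1.0 + float((null_F >= F_obs).sum())) / (n_sims + 1.0)
    return PhyloMANOVAResult(
        groups=pd.Series(lab, index=tip_names),
        n_species=N,
        n_variables=p,
        n_groups=g,
        wilks_lambda=lam,
        F=F_obs,
        df=df,
        null_F=null_F,
        p_value=p_value,
        n_sims=n_sims,
    )
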