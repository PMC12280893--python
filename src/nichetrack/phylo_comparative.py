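"""Tree-aware statistics, implemented from first principles.

Trait vectors are plain ``{tip_label: value}`` mappings aligned to the tree.
The module provides Felsenstein's phylogenetically independent contrasts
(PIC), PIC correlations, Blomberg's K with both a tip-permutation test for
signal and a Brownian-motion simulation test for K > 1 (stronger-than-
Brownian similarity, the signature of niche conservatism), and generalized
least squares regression with a Brownian correlation structure (PGLS).

None of the operations assumes an ultrametric tree unless stated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import Tree

__all__ = [
    "TraitVector",
    "PicCorrelation",
    "KResult",
    "PGLSFit",
    "align_trait",
    "phylo_covariance",
    "pic",
    "pic_correlation",
    "blomberg_K",
    "K_tests",
    "simulate_bm",
    "pgls",
]

TraitVector = dict  # {tip_label: float}


def align_trait(tree: Tree, x: TraitVector) -> np.ndarray:
    """Trait values in tree tip order; keys must match tip labels exactly."""
    labels = tree.tip_labels
    missing = set(labels) - set(x)
    extra = set(x) - set(labels)
    if missing or extra:
        raise ValueError(
            f"trait keys do not match tree tips (missing {sorted(missing)}, "
            f"extra {sorted(extra)})")
    vals = np.array([float(x[lab]) for lab in labels])
    if np.any(~np.isfinite(vals)):
        raise ValueError("trait contains non-finite values")
    return vals


def phylo_covariance(tree: Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian covariance structure C (shared root-to-MRCA path lengths)."""
    return tree.vcv()


# ---------------------------------------------------------------------------
# independent contrasts

def pic(tree: Tree, x: TraitVector) -> np.ndarray:
    """Standardized independent contrasts by Felsenstein's pruning.

    At each internal node of a binary tree the contrast is
    ``(x_i - x_j) / sqrt(b_i + b_j)`` where the b are the (possibly
    extended) child branch lengths; the node's ancestral value is the
    1/b-weighted average of its children and its own branch is extended by
    ``b_i * b_j / (b_i + b_j)``.  Contrasts are returned in postorder.
    """
    if tree.has_polytomy():
        raise ValueError("tree has polytomies; resolve with "
                         "Tree.resolve_polytomies() before computing contrasts")
    vals = dict(zip(tree.tip_labels, align_trait(tree, x)))
    node_val: dict[int, float] = {}
    node_b: dict[int, float] = {}
    contrasts = []
    for node in tree.postorder():
        if node.is_tip:
            node_val[id(node)] = vals[node.label]
            node_b[id(node)] = node.length
        else:
            ci, cj = node.children
            bi, bj = node_b.pop(id(ci)), node_b.pop(id(cj))
            if bi + bj <= 0:
                raise ValueError("zero-length sister branch pair; contrast "
                                 "variance is 0")
            xi, xj = node_val.pop(id(ci)), node_val.pop(id(cj))
            contrasts.append((xi - xj) / np.sqrt(bi + bj))
            node_val[id(node)] = (xi / bi + xj / bj) / (1 / bi + 1 / bj) \
                if bi > 0 and bj > 0 else (xi if bj > 0 else xj)
            node_b[id(node)] = node.length + bi * bj / (bi + bj)
    return np.array(contrasts)


@dataclass(frozen=True)
class PicCorrelation:
    r: float
    ci95: tuple[float, float]
    p: float
    n_contrasts: int
    through_origin: bool


def pic_correlation(tree: Tree, x: TraitVector, y: TraitVector,
                    through_origin: bool = False) -> PicCorrelation:
    """Correlation of independent contrasts of two traits.

    Default is the ordinary Pearson correlation with a Fisher-z 95% CI and a
    t-test p-value (n-2 df).  ``through_origin=True`` gives the
    origin-constrained estimator (contrast signs are arbitrary, so the
    regression through the origin is the textbook-correct variant); its
    t-test uses n-1 df.
    """
    u = pic(tree, x)
    v = pic(tree, y)
    m = len(u)
    if m < 3:
        raise ValueError(f"need >= 3 contrasts, got {m}")
    if through_origin:
        denom = np.sqrt(np.sum(u * u) * np.sum(v * v))
        if denom == 0:
            raise ValueError("constant contrasts; correlation undefined")
        r = float(np.sum(u * v) / denom)
        df = m - 1
    else:
        if np.std(u) == 0 or np.std(v) == 0:
            raise ValueError("constant contrasts; correlation undefined")
        r = float(stats.pearsonr(u, v).statistic)
        df = m - 2
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
        ci = (r, r)
    else:
        t = r * np.sqrt(df / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
        z = np.arctanh(r)
        zse = 1 / np.sqrt(m - 3) if m > 3 else np.inf
        ci = (float(np.tanh(z - 1.959963984540054 * zse)),
              float(np.tanh(z + 1.959963984540054 * zse)))
    return PicCorrelation(r=r, ci95=ci, p=p, n_contrasts=m,
                          through_origin=through_origin)


# ---------------------------------------------------------------------------
# Blomberg's K

def _K_from_parts(C_inv: np.ndarray, ones_Cinv: np.ndarray, denom: float,
                  expected: float, n: int, X: np.ndarray) -> np.ndarray:
    """Vectorized K for columns of X (n x m)."""
    a_hat = (ones_Cinv @ X) / denom
    Xc = X - a_hat[None, :]
    mse0 = np.sum(Xc * Xc, axis=0)
    mse = np.sum(Xc * (C_inv @ Xc), axis=0)
    if np.any(mse <= 0) or np.any(mse0 <= 0):
        raise ValueError("constant trait; K undefined")
    return (mse0 / mse) / expected


def _K_setup(tree: Tree):
    C, labels = tree.vcv()
    n = C.shape[0]
    C_inv = np.linalg.inv(C)
    ones = np.ones(n)
    ones_Cinv = ones @ C_inv
    denom = float(ones_Cinv @ ones)
    expected = (np.trace(C) - n / denom) / (n - 1)
    return C, labels, C_inv, ones_Cinv, denom, expected, n


def blomberg_K(tree: Tree, x: TraitVector) -> float:
    """Blomberg's K: observed-to-Brownian-expected ratio of the variance of
    tip values around the phylogenetic mean versus the phylogenetically
    corrected variance.  K = 1 under Brownian motion; K > 1 means relatives
    are more similar than Brownian evolution predicts."""
    C, labels, C_inv, ones_Cinv, denom, expected, n = _K_setup(tree)
    vals = align_trait(tree, x)
    return float(_K_from_parts(C_inv, ones_Cinv, denom, expected, n,
                               vals[:, None])[0])


def simulate_bm(tree: Tree, n_traits: int, rng: np.random.Generator,
                sigma2: float = 1.0, z0: float = 0.0) -> np.ndarray:
    """Simulate ``n_traits`` independent Brownian traits on the tree;
    returns an (n_tips, n_traits) array in tip order."""
    C, _ = tree.vcv()
    L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    return z0 + np.sqrt(sigma2) * (L @ rng.standard_normal((C.shape[0], n_traits)))


@dataclass(frozen=True)
class KResult:
    K: float
    p_perm: float   # tip-permutation test of any phylogenetic signal
    p_gt1: float    # P(K_null >= K_obs) under Brownian motion
    n_perm: int
    n_sim: int


def K_tests(tree: Tree, x: TraitVector, n_perm: int = 1000, n_sim: int = 1000,
            seed: int | None = None) -> KResult:
    """Blomberg's K with two Monte-Carlo tests.

    ``p_perm``: proportion of random tip relabelings with K at least as
    large as observed (tests for any signal).  ``p_gt1``: proportion of
    Brownian-simulated traits with K at least as large as observed (one-
    sided test of stronger-than-Brownian constraint; the Brownian rate is
    irrelevant because K is scale-free).  Both use the (b+1)/(m+1)
    correction so p is never exactly 0.
    """
    if n_perm < 1 or n_sim < 1:
        raise ValueError("n_perm and n_sim must be >= 1")
    C, labels, C_inv, ones_Cinv, denom, expected, n = _K_setup(tree)
    vals = align_trait(tree, x)
    rng = np.random.default_rng(seed)
    K_obs = float(_K_from_parts(C_inv, ones_Cinv, denom, expected, n,
                                vals[:, None])[0])
    # tip permutations
    perms = np.empty((n, n_perm))
    for j in range(n_perm):
        perms[:, j] = vals[rng.permutation(n)]
    K_perm = _K_from_parts(C_inv, ones_Cinv, denom, expected, n, perms)
    p_perm = (np.sum(K_perm >= K_obs) + 1.0) / (n_perm + 1.0)
    # Brownian null
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    sims = L @ rng.standard_normal((n, n_sim))
    K_null = _K_from_parts(C_inv, ones_Cinv, denom, expected, n, sims)
    p_gt1 = (np.sum(K_null >= K_obs) + 1.0) / (n_sim + 1.0)
    return KResult(K=K_obs, p_perm=float(p_perm), p_gt1=float(p_gt1),
                   n_perm=n_perm, n_sim=n_sim)


# ---------------------------------------------------------------------------
# PGLS

@dataclass(frozen=True)
class PGLSFit:
    beta: np.ndarray       # (intercept, slopes...)
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2_hat: float      # residual scale, divisor n - p (REML convention)
    df_resid: int
    n: int
    coef_names: tuple


def pgls(tree: Tree, y: TraitVector, X: list[TraitVector] | TraitVector,
         coef_names: tuple | None = None) -> PGLSFit:
    """Generalized least squares with Brownian phylogenetic covariance.

    beta_hat = (X' C^-1 X)^-1 X' C^-1 y with an intercept column; the
    residual scale uses the n - p divisor and coefficient tests are
    two-sided t with n - p degrees of freedom.  beta_hat is identical under
    the ML and REML residual-scale conventions (the correlation structure is
    fixed), so only the scale convention matters for the standard errors.
    """
    if isinstance(X, dict):
        X = [X]
    yv = align_trait(tree, y)
    n = len(yv)
    cols = [np.ones(n)] + [align_trait(tree, xi) for xi in X]
    M = np.column_stack(cols)
    p = M.shape[1]
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 observations (n={n}, p={p})")
    C, _ = tree.vcv()
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    Mw = np.linalg.solve(L, M)
    yw = np.linalg.solve(L, yv)
    XtX = Mw.T @ Mw
    if np.linalg.cond(XtX) > 1e12:
        raise ValueError("collinear predictors: X' C^-1 X is singular")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Mw.T @ yw)
    resid = yw - Mw @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(t), df)
    names = coef_names or tuple(["intercept"] + [f"x{i}" for i in range(1, p)])
    return PGLSFit(beta=beta, se=se, t=t, p=pvals, sigma2_hat=sigma2,
                   df_resid=df, n=n, coef_names=names)
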