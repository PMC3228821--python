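"""Component-number selection and independent component analysis.

The standardized genes x samples matrix X is modelled as X ~ S A: sparse,
supergaussian gene signatures (columns of S) times per-individual activation
patterns (rows of A).  The number of components is chosen from a
permutation-corrected screeplot; ICA is the symmetric (parallel) fixed-point
algorithm maximizing the logcosh negentropy proxy, restarted several times
with the most non-Gaussian solution kept.  Components dominated by a single
individual, and signatures that are insufficiently peaked (low kurtosis),
are filtered out before any downstream use.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import integrate, stats

from .containers import Decomposition, ExpressionMatrix

__all__ = [
    "choose_num_components",
    "run_ica",
    "compute_kurtosis",
    "flag_individual_specific",
    "annotate_components",
    "filter_components",
]

def _logcosh(t: np.ndarray) -> np.ndarray:
    """Numerically stable log(cosh(t))."""
    a = np.abs(t)
    return a + np.log1p(np.exp(-2.0 * a)) - np.log(2.0)


# E[log cosh(Z)] for Z ~ N(0,1); reference point of the negentropy proxy
_EG_GAUSS = integrate.quad(
    lambda t: _logcosh(np.asarray(t)) * np.exp(-t * t / 2) / np.sqrt(2 * np.pi),
    -np.inf,
    np.inf,
)[0]


# ---------------------------------------------------------------------------
# number of components: permutation-corrected screeplot


def _perm_top_eigenvalue(
    X: np.ndarray, rng: np.random.Generator, n_perm: int
) -> float:
    """Average top eigenvalue over within-gene permutations of X."""
    G, N = X.shape
    tot = 0.0
    for _ in range(max(1, n_perm)):
        Xp = np.take_along_axis(
            X, np.argsort(rng.random((G, N)), axis=1), axis=1
        )
        tot += np.linalg.svd(Xp, compute_uv=False)[0] ** 2
    return tot / max(1, n_perm)


def choose_num_components(
    x: ExpressionMatrix,
    n_perm: int = 1,
    seed: int = 0,
    margin: float = 0.05,
    max_components: int | None = None,
) -> int:
    """Choose K by comparing the scree against a within-gene permutation null.

    Permuting every gene's values independently across samples destroys
    gene-gene covariance while keeping each gene's marginal distribution,
    giving the eigenvalue scree expected of pure noise.  The null for
    component s must be corrected for the variance already claimed by the
    s-1 accepted components; this is done by deflation: after a component
    is accepted, its rank-1 term is subtracted from the matrix, and the
    next observed eigenvalue and its permutation null are both computed on
    the residual.  (Permuting the residual, rather than rescaling the
    original null curve, keeps the null's per-gene variances equal to the
    residual's, which matters when a minority of genes carries most of the
    signal.)  A component is accepted while its observed eigenvalue exceeds
    the null by the relative ``margin``; the default 0.05 is about three
    standard deviations of the single-permutation top-eigenvalue
    fluctuation, so a structureless matrix yields K = 0.  ``n_perm > 1``
    averages null draws.
    """
    if x.transform_state != "standardized":
        raise ValueError("choose_num_components expects a standardized matrix")
    G, N = x.values.shape
    if G < 3 or N < 3:
        raise ValueError("need at least 3 genes and 3 samples")
    rng = np.random.default_rng(seed)
    limit = min(G, N) if max_components is None else min(max_components, G, N)
    R = x.values.copy()
    total = float((R**2).sum())
    K = 0
    for _ in range(limit):
        U, s, Vt = np.linalg.svd(R, full_matrices=False)
        lam_obs = s[0] ** 2
        # numerically exhausted residual (e.g. exact low rank)
        if lam_obs <= 1e-12 * total:
            break
        lam_null = _perm_top_eigenvalue(R, rng, n_perm)
        if lam_obs > lam_null * (1.0 + margin):
            K += 1
            R = R - s[0] * np.outer(U[:, 0], Vt[0])
        else:
            break
    return K


# ---------------------------------------------------------------------------
# FastICA (symmetric, logcosh) on the truncated-SVD subspace


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^{-1/2} W (symmetric decorrelation)."""
    evals, evecs = np.linalg.eigh(W @ W.T)
    return (evecs * (1.0 / np.sqrt(np.clip(evals, 1e-300, None)))) @ evecs.T @ W


def _fastica_symmetric(
    Z: np.ndarray, W0: np.ndarray, tol: float, max_iter: int, alpha: float = 1.0
) -> tuple[np.ndarray, bool, int]:
    """Fixed-point iteration on whitened data Z (observations x K).

    Returns the unmixing matrix W (K x K, rows unit norm), a convergence
    flag and the number of iterations used.  The contrast is
    G(u) = log cosh(alpha u) / alpha.
    """
    G = Z.shape[0]
    W = _sym_decorrelate(W0)
    for it in range(1, max_iter + 1):
        U = Z @ W.T  # sources, observations x K
        gU = np.tanh(alpha * U)
        g_prime = alpha * (1.0 - gU**2).mean(axis=0)
        W_new = (gU.T @ Z) / G - g_prime[:, None] * W
        W_new = _sym_decorrelate(W_new)
        # convergence: rows aligned with previous iterate up to sign
        lim = np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0))
        W = W_new
        if lim < tol:
            return W, True, it
    return W, False, max_iter


def _negentropy_proxy(U: np.ndarray, alpha: float = 1.0) -> float:
    """Sum over components of (E[G(u)] - E[G(nu)])^2, G = logcosh."""
    eg = _logcosh(alpha * U).mean(axis=0) / alpha
    return float(np.sum((eg - _EG_GAUSS / alpha) ** 2))


def run_ica(
    x: ExpressionMatrix,
    K: int,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> Decomposition:
    """Extract K independent components from the standardized matrix.

    The matrix is first reduced to its rank-K SVD subspace (whitening over
    genes, which play the role of observations); the symmetric fixed-point
    iteration then rotates the subspace to maximize logcosh negentropy with
    alpha = 1.  ``n_restarts`` runs are started from seeds seed+0 ...
    seed+n_restarts-1 and the converged run with the largest summed
    negentropy proxy is kept.  Each signature is oriented so its skewness is
    non-negative and scaled to unit variance over genes, A absorbing the
    magnitude, so S @ A equals the rank-K projection of X exactly.
    """
    if x.transform_state != "standardized":
        raise ValueError("run_ica expects a standardized matrix")
    G, N = x.values.shape
    if not 1 <= K <= min(G, N):
        raise ValueError(f"K={K} outside [1, min(genes, samples)={min(G, N)}]")
    X = x.values
    U_svd, s_svd, Vt_svd = np.linalg.svd(X, full_matrices=False)
    U_K, s_K, Vt_K = U_svd[:, :K], s_svd[:K], Vt_svd[:K]
    if s_K[-1] <= 1e-12 * s_K[0]:
        raise ValueError(f"matrix rank below requested K={K}")
    # whitened gene-space coordinates: Z^T Z / G = I
    Z = U_K * np.sqrt(G)

    best = None
    diagnostics = []
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        W0 = rng.standard_normal((K, K))
        W, converged, iters = _fastica_symmetric(Z, W0, tol=tol, max_iter=max_iter)
        neg = _negentropy_proxy(Z @ W.T)
        diagnostics.append((r, converged, iters, neg))
        if converged and (best is None or neg > best[1]):
            best = (W, neg, r)
    if best is None:
        raise RuntimeError(
            "no ICA restart converged; diagnostics (restart, converged, iters, "
            f"negentropy): {diagnostics}"
        )
    W, neg, winner = best

    S = Z @ W.T  # genes x K, unit population variance per column
    # A from the subspace coordinates: X = U_K diag(s) Vt_K, S = sqrt(G) U_K W^T
    # => A = W diag(s) Vt / sqrt(G); equivalently the LS solution of X ~ S A.
    A = (W * s_K[None, :]) @ Vt_K / np.sqrt(G)

    # orientation: non-negative signature skewness
    skew = stats.skew(S, axis=0, bias=True)
    flip = np.where(skew < 0, -1.0, 1.0)
    S = S * flip[None, :]
    A = A * flip[:, None]
    # unit sample variance (ddof=1) of signatures; A absorbs the scale
    sd = S.std(axis=0, ddof=1)
    S = S / sd[None, :]
    A = A * sd[:, None]

    return Decomposition(
        S=S,
        A=A,
        gene_ids=list(x.gene_ids),
        sample_ids=list(x.sample_ids),
        component_ids=[f"IC{k + 1}" for k in range(K)],
        negentropy=neg,
        winning_restart=winner,
    )


# ---------------------------------------------------------------------------
# component annotation and filtering


def compute_kurtosis(s_col: np.ndarray) -> float:
    """Excess kurtosis m4/m2^2 - 3 of a signature (moment form, no bias
    correction); 0 for a Gaussian, 3 for a Laplace, -2 for a +/-1 two-point
    distribution."""
    v = np.asarray(s_col, dtype=float)
    if v.size < 4:
        raise ValueError("kurtosis needs at least 4 values")
    c = v - v.mean()
    m2 = np.mean(c**2)
    if m2 == 0:
        raise ValueError("kurtosis undefined for zero-variance input")
    return float(np.mean(c**4) / m2**2 - 3.0)


def flag_individual_specific(
    a_row: np.ndarray, threshold: float = 0.10
) -> tuple[bool, float]:
    """Flag a pattern dominated by a single individual.

    share_j = (a_j - mean)^2 / sum of squared deviations; the component is
    flagged when the maximum share strictly exceeds ``threshold`` (a single
    individual explaining more than 10% of the pattern's variability).
    Returns (flag, max_share).
    """
    a = np.asarray(a_row, dtype=float)
    if a.size < 3:
        raise ValueError("individual-specific flag needs at least 3 samples")
    dev2 = (a - a.mean()) ** 2
    tot = dev2.sum()
    if tot == 0:
        raise ValueError("zero-variance pattern is invalid")
    max_share = float(dev2.max() / tot)
    return max_share > threshold, max_share


def annotate_components(
    d: Decomposition,
    individual_threshold: float = 0.10,
    kurtosis_min: float = 3.0,
    kurtosis_scale: str = "excess",
) -> Decomposition:
    """Fill per-component kurtosis and individual-specific flags in place.

    ``kurtosis_scale`` selects whether ``kurtosis_min`` is on the excess
    scale (Gaussian = 0, default) or the raw scale (Gaussian = 3).
    """
    if kurtosis_scale not in ("excess", "raw"):
        raise ValueError("kurtosis_scale must be 'excess' or 'raw'")
    kurt = np.array([compute_kurtosis(d.S[:, k]) for k in range(d.K)])
    ind = np.array(
        [flag_individual_specific(d.A[k], individual_threshold)[0] for k in range(d.K)]
    )
    effective = kurt if kurtosis_scale == "excess" else kurt + 3.0
    d.kurtosis = kurt
    d.individual_specific = ind
    d.kurtosis_pass = effective >= kurtosis_min
    return d


def filter_components(
    d: Decomposition,
    kurtosis_min: float = 3.0,
    individual_threshold: float = 0.10,
    kurtosis_scale: str = "excess",
) -> Decomposition:
    """Drop individual-specific components, then low-kurtosis signatures.

    Component order is preserved.  Flags are (re)computed if absent.
    """
    if d.kurtosis is None or d.individual_specific is None:
        d = annotate_components(
            d,
            individual_threshold=individual_threshold,
            kurtosis_min=kurtosis_min,
            kurtosis_scale=kurtosis_scale,
        )
    keep = (~d.individual_specific.astype(bool)) & d.kurtosis_pass.astype(bool)
    if not keep.any():
        warnings.warn("all components removed by filtering", stacklevel=2)
    return d.subset_components(keep)
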