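"""Sample outlier screening by classical multidimensional scaling.

Expression outliers are screened on 1 - |Pearson correlation| distances
between arrays; genotype outliers on 1 - IBS (identity-by-state) distances.
A robust-distance rule on the leading MDS axes replaces the by-eye
exclusion such screens are usually subjected to, so that the procedure is
deterministic and repeatable over rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import DistanceMatrix, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "expression_distance",
    "ibs_matrix",
    "classical_mds",
    "robust_outlier_flags",
    "flag_outliers",
    "OutlierReport",
]


def expression_distance(x: ExpressionMatrix) -> DistanceMatrix:
    """Pairwise array distance d_ij = 1 - |r(sample_i, sample_j)| over genes."""
    if x.n_genes < 2:
        raise ValueError("expression_distance needs at least 2 genes")
    sd = x.values.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"constant samples have undefined correlation: {[x.sample_ids[i] for i in bad[:10]]}"
        )
    r = np.corrcoef(x.values.T)
    d = 1.0 - np.abs(r)
    np.clip(d, 0.0, 1.0, out=d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d=d, sample_ids=list(x.sample_ids), kind="expression_abscorr")


def ibs_matrix(g: GenotypeMatrix) -> DistanceMatrix:
    """1 - IBS distances: sharing (2 - |g_i - g_j|) / 2 averaged over SNPs.

    Missing genotypes are excluded pairwise; a pair with no shared
    non-missing SNP is an error.
    """
    counts = g.counts
    n = g.n_samples
    obs = ~np.isnan(counts)
    filled = np.where(obs, counts, 0.0)
    sim = np.empty((n, n))
    for i in range(n):
        both = obs[:, i : i + 1] & obs[:, i:]
        diff = np.abs(filled[:, i : i + 1] - filled[:, i:])
        shared = both.sum(axis=0)
        if (shared == 0).any():
            j = i + int(np.flatnonzero(shared == 0)[0])
            raise ValueError(
                f"samples {g.sample_ids[i]!r} and {g.sample_ids[j]!r} share no called SNP"
            )
        s = ((2.0 - diff) / 2.0 * both).sum(axis=0) / shared
        sim[i, i:] = s
        sim[i:, i] = s
    d = 1.0 - sim
    np.clip(d, 0.0, None, out=d)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d, sample_ids=list(g.sample_ids), kind="genotype_ibs")


def classical_mds(d: DistanceMatrix, dims: int = 2) -> np.ndarray:
    """Torgerson scaling: coordinates from the double-centred Gram matrix.

    B = -1/2 J D^2 J is eigendecomposed; coordinates are the top
    eigenvectors scaled by sqrt(eigenvalue).  Axes with non-positive
    eigenvalues are excluded (with a warning if fewer than ``dims`` remain).
    Signs are fixed so each axis's largest-magnitude coordinate is positive.
    """
    D2 = d.d**2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-12 * abs(evals[0]) if evals.size else 0)
    n_pos = int(pos.sum())
    if n_pos < dims:
        if n_pos < dims and n_pos > 0:
            warnings.warn(
                f"only {n_pos} positive eigenvalues; returning {n_pos} MDS dimensions",
                stacklevel=2,
            )
        dims = n_pos
    coords = evecs[:, :dims] * np.sqrt(evals[:dims])
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def robust_outlier_flags(coords: np.ndarray, k_mad: float = 6.0) -> np.ndarray:
    """Boolean flags for points whose per-axis robust z-norm exceeds ``k_mad``.

    Each axis is centred by its median and scaled by 1.4826*MAD; axes with
    zero MAD are skipped with a warning.  The flag criterion is the
    Euclidean norm of the robust z-scores across retained axes.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] < 10:
        raise ValueError("outlier flagging needs at least 10 samples")
    z2 = np.zeros(coords.shape[0])
    used = 0
    for k in range(coords.shape[1]):
        col = coords[:, k]
        med = np.median(col)
        mad = np.median(np.abs(col - med))
        if mad == 0:
            warnings.warn(f"axis {k} has zero MAD; skipped", stacklevel=2)
            continue
        z2 += ((col - med) / (1.4826 * mad)) ** 2
        used += 1
    if used == 0:
        return np.zeros(coords.shape[0], dtype=bool)
    return np.sqrt(z2) > k_mad


@dataclass
class OutlierReport:
    """Per-round flags from iterative MDS screening."""

    rounds: list[list[str]] = field(default_factory=list)
    coords: list[np.ndarray] = field(default_factory=list)
    coord_ids: list[list[str]] = field(default_factory=list)

    @property
    def flagged(self) -> set[str]:
        return {s for rnd in self.rounds for s in rnd}


def flag_outliers(
    d: DistanceMatrix,
    dims: int = 2,
    k_mad: float = 6.0,
    max_rounds: int = 3,
) -> OutlierReport:
    """Iterative outlier exclusion: MDS, robust flags, re-run on survivors.

    Stops when a round flags nothing or after ``max_rounds`` rounds.  The
    survivor set shrinks weakly monotonically.
    """
    ids = list(d.sample_ids)
    dist = d.d.copy()
    report = OutlierReport()
    for _ in range(max_rounds):
        sub = DistanceMatrix(d=dist, sample_ids=ids, kind=d.kind)
        coords = classical_mds(sub, dims=dims)
        report.coords.append(coords)
        report.coord_ids.append(list(ids))
        flags = robust_outlier_flags(coords, k_mad=k_mad)
        if not flags.any():
            break
        report.rounds.append([ids[i] for i in np.flatnonzero(flags)])
        keep = np.flatnonzero(~flags)
        ids = [ids[i] for i in keep]
        dist = dist[np.ix_(keep, keep)]
    return report
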