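"""Gene-module definition from signature loadings and gene-set enrichment.

Each signature's loadings are modelled as a two-group mixture: a Gaussian
null for the bulk of weakly influenced genes, fitted robustly around the
median, plus an alternative in the tails.  Genes whose tail-area false
discovery rate under that empirical null is below a threshold (default
1e-3) form the component's "module".  Modules are compared by Jaccard
overlap and annotated by hypergeometric gene-set enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GeneModule, NullFit

__all__ = [
    "fit_empirical_null",
    "assign_module",
    "module_overlap",
    "geneset_enrichment",
    "hypergeom_tail",
]


def fit_empirical_null(
    loadings: np.ndarray, central_fraction: float = 0.75
) -> NullFit:
    """Fit the null Gaussian N(center, sigma0^2) to the central bulk.

    center is the median.  sigma0 is the maximum-likelihood scale of a
    Gaussian truncated to the central ``central_fraction`` quantile window
    around the median, using only the loadings inside that window — the
    tails, where the alternative lives, never enter the fit.  eta0, the
    null proportion, is the fraction of genes inside the window divided by
    the null mass of the window (Storey-type), clipped to (0, 1].
    """
    x = np.asarray(loadings, dtype=float)
    if x.size < 100:
        raise ValueError("empirical null needs at least 100 loadings")
    if not 0 < central_fraction < 1:
        raise ValueError("central_fraction must lie in (0, 1)")
    center = float(np.median(x))
    lo_q, hi_q = 0.5 - central_fraction / 2, 0.5 + central_fraction / 2
    a, b = np.quantile(x, [lo_q, hi_q])
    inside = x[(x >= a) & (x <= b)]
    spread = float(np.std(inside))
    if spread == 0 or b <= a:
        raise ValueError("degenerate loadings: no spread in the central window")

    za, zb = a - center, b - center

    def nll(log_sigma: float) -> float:
        sigma = np.exp(log_sigma)
        mass = stats.norm.cdf(zb / sigma) - stats.norm.cdf(za / sigma)
        if mass <= 0:
            return np.inf
        return -(
            np.sum(stats.norm.logpdf(inside - center, scale=sigma))
            - inside.size * np.log(mass)
        )

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(spread) - 4, np.log(spread) + 4), method="bounded"
    )
    sigma0 = float(np.exp(res.x))

    null_mass = stats.norm.cdf(zb / sigma0) - stats.norm.cdf(za / sigma0)
    eta0 = (inside.size / x.size) / max(null_mass, 1e-12)
    eta0 = float(min(max(eta0, 1e-12), 1.0))
    return NullFit(center=center, sigma0=sigma0, eta0=eta0)


def _tail_fdr(z_abs: np.ndarray, eta0: float) -> np.ndarray:
    """Monotone tail-area FDR (q-values) for two-sided z statistics.

    At threshold t, Fdr(t) = eta0 * G * P(|Z| >= t) / #{|z| >= t}; the
    q-value of gene i is the minimum Fdr over thresholds at or below |z_i|
    (step-up monotonization over the observed order statistics).
    """
    G = z_abs.size
    order = np.argsort(z_abs)[::-1]
    z_sorted = z_abs[order]
    k = np.arange(1, G + 1)
    fdr = eta0 * G * 2.0 * stats.norm.sf(z_sorted) / k
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(G)
    q[order] = q_sorted
    return q


def assign_module(
    loadings: np.ndarray,
    gene_ids: list[str],
    fit: NullFit,
    component_id: str = "IC",
    fdr_max: float = 1e-3,
    rule: str = "qvalue",
) -> GeneModule:
    """Select the module: genes significant under the empirical null.

    ``rule='qvalue'`` (primary) thresholds the monotone tail-area FDR;
    ``rule='null_p'`` thresholds the plain two-sided null tail probability
    instead.  Membership is two-sided and invariant to affine rescaling of
    the loadings (center and scale fold into the null fit).
    """
    x = np.asarray(loadings, dtype=float)
    if len(gene_ids) != x.size:
        raise ValueError("gene_ids length differs from loadings")
    z_abs = np.abs(x - fit.center) / fit.sigma0
    if rule == "qvalue":
        q = _tail_fdr(z_abs, fit.eta0)
    elif rule == "null_p":
        q = 2.0 * stats.norm.sf(z_abs)
    else:
        raise ValueError(f"unknown membership rule {rule!r}")
    member = q < fdr_max
    idx = np.flatnonzero(member)
    return GeneModule(
        component_id=component_id,
        gene_ids=[gene_ids[i] for i in idx],
        loadings=x[idx],
        qvalues=q[idx],
    )


def module_overlap(a: GeneModule | set, b: GeneModule | set) -> float:
    """Jaccard overlap |A∩B| / |A∪B|; 0 when both modules are empty."""
    sa = a.members if isinstance(a, GeneModule) else set(a)
    sb = b.members if isinstance(b, GeneModule) else set(b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    N: universe size, K: marked genes in the universe, n: draws (module
    size), k: marked genes drawn.
    """
    if min(N, K, n, k) < 0 or K > N or n > N:
        raise ValueError("invalid hypergeometric parameters")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def geneset_enrichment(
    m: GeneModule,
    sets: dict[str, set[str]],
    universe: set[str] | list[str],
    alpha_family: float = 0.05,
    min_set: int = 5,
) -> pd.DataFrame:
    """Hypergeometric enrichment of the module in each gene set.

    Sets are intersected with the universe first; sets smaller than
    ``min_set`` after intersection are not tested (and do not count toward
    the Bonferroni family).  Returns one row per tested set with counts,
    the exact upper-tail p-value, the Bonferroni threshold
    ``alpha_family / n_sets_tested`` and a significance flag.
    """
    universe = set(universe)
    members = m.members
    if not members <= universe:
        missing = sorted(members - universe)
        raise ValueError(f"module genes outside the universe: {missing[:10]}")
    tested = {
        name: genes & universe
        for name, genes in sets.items()
        if len(genes & universe) >= min_set
    }
    n_tested = len(tested)
    threshold = alpha_family / n_tested if n_tested else np.nan
    rows = []
    for name in sorted(tested):
        genes = tested[name]
        k = len(genes & members)
        p = hypergeom_tail(len(universe), len(genes), len(members), k)
        rows.append(
            {
                "set": name,
                "N_universe": len(universe),
                "K_set": len(genes),
                "n_module": len(members),
                "k_overlap": k,
                "p": p,
                "threshold": threshold,
                "significant": p < threshold,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "set",
            "N_universe",
            "K_set",
            "n_module",
            "k_overlap",
            "p",
            "threshold",
            "significant",
        ],
    )
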