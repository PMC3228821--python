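"""SNP quality control and the two-step pattern-SNP association scan.

Step 1 tests each pattern against each SNP by a one-way fixed-effects ANOVA
with genotype as a categorical factor (2 d.f. when all three genotype
classes are present); associations below a suggestive threshold (default
1e-7) continue to step 2, which asks whether the component's module is
enriched, against the whole analyzed transcriptome, in genes individually
associated with the SNP (default per-gene threshold 1e-5), using an exact
hypergeometric test at a Bonferroni study-wise threshold.  Mediation by cis
genes and pattern-phenotype correlation round out the toolbox.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import GeneModule, GenotypeMatrix
from .modules import hypergeom_tail

__all__ = [
    "hwe_exact_test",
    "snp_qc",
    "AssociationRecord",
    "anova_2df",
    "scan",
    "study_wise_threshold",
    "EnrichmentResult",
    "module_enrichment_step",
    "mediation_adjust",
    "pattern_phenotype_corr",
]


# ---------------------------------------------------------------------------
# genotype QC


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of matching parity, the probabilities of configurations no more
    probable than the observed one (two-sided exact test on the heterozygote
    count).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype counts")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # log P(n_het | n, n_rare) up to a constant:
    #   n! / (n_aa! n_ab! n_bb!) * 2^n_ab / [ (2n)! / (n_rare! n_common!) ]
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    homs_rare = (n_rare - hets) // 2
    homs_common = n - hets - homs_rare
    valid = homs_common >= 0
    hets, homs_rare, homs_common = hets[valid], homs_rare[valid], homs_common[valid]
    logp = (
        hets * math.log(2.0)
        - gammaln(homs_rare + 1)
        - gammaln(hets + 1)
        - gammaln(homs_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.flatnonzero(hets == n_het)
    if obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def snp_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-4,
    call_min: float = 0.95,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter SNPs on minor-allele frequency, HWE and call rate.

    A SNP is kept iff maf >= maf_min, exact HWE p >= hwe_alpha and
    call_rate >= call_min.  Returns the filtered matrix and a per-SNP report.
    """
    maf = g.maf
    call = g.call_rate
    hwe = np.ones(g.n_snps)
    for i in range(g.n_snps):
        row = g.counts[i]
        row = row[~np.isnan(row)]
        if row.size == 0:
            hwe[i] = np.nan
            continue
        hwe[i] = hwe_exact_test(
            int((row == 0).sum()), int((row == 1).sum()), int((row == 2).sum())
        )
    keep = (maf >= maf_min) & (call >= call_min) & (np.nan_to_num(hwe) >= hwe_alpha)
    report = pd.DataFrame(
        {
            "snp": g.snp_ids,
            "maf": maf,
            "call_rate": call,
            "hwe_p": hwe,
            "kept": keep,
        }
    )
    if not keep.any():
        warnings.warn("all SNPs removed by QC", stacklevel=2)
    return g.subset_snps(keep), report


# ---------------------------------------------------------------------------
# ANOVA


@dataclass
class AssociationRecord:
    snp_id: str
    target_id: str
    F: float
    df_between: int
    df_within: int
    p: float
    r2: float
    n_used: int
    testable: bool = True
    degenerate: bool = False


def anova_2df(
    y: np.ndarray,
    geno: np.ndarray,
    snp_id: str = "snp",
    target_id: str = "target",
) -> AssociationRecord:
    """One-way ANOVA of a quantitative trait on genotype classes.

    Genotype enters as a categorical factor, so the test has 2 d.f. when all
    three classes are present and fewer when a class is empty.  Pairs with a
    missing genotype or trait value are dropped.  r2 = SS_between/SS_total.
    """
    y = np.asarray(y, dtype=float)
    geno = np.asarray(geno, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(geno))
    y, geno = y[ok], geno[ok]
    n = y.size
    classes = np.unique(geno)
    if n == 0 or classes.size < 2:
        return AssociationRecord(
            snp_id, target_id, 0.0, 0, max(n - 1, 0), 1.0, 0.0, n, testable=False
        )
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())
    ssb = 0.0
    for c in classes:
        yc = y[geno == c]
        ssb += yc.size * (yc.mean() - grand) ** 2
    ssw = max(sst - ssb, 0.0)
    df_b = classes.size - 1
    df_w = n - classes.size
    if sst == 0:
        return AssociationRecord(
            snp_id, target_id, 0.0, df_b, df_w, 1.0, 0.0, n, testable=False
        )
    r2 = ssb / sst
    if ssw == 0:
        if ssb > 0:
            return AssociationRecord(
                snp_id, target_id, np.inf, df_b, df_w, 0.0, r2, n, degenerate=True
            )
        return AssociationRecord(snp_id, target_id, 0.0, df_b, df_w, 1.0, 0.0, n)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w)) if df_w > 0 else 1.0
    return AssociationRecord(snp_id, target_id, float(F), df_b, df_w, p, float(r2), n)


def _scan_one_snp(Y: np.ndarray, geno: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorized one-way ANOVA of every row of Y against one SNP.

    Y is targets x samples with no missing values; missing genotypes are
    dropped columnwise.  Returns (F, p, r2, df_b, df_w, n_used) arrays.
    """
    ok = ~np.isnan(geno)
    Yo, go = Y[:, ok], geno[ok]
    n = go.size
    T = Yo.shape[0]
    classes = np.unique(go)
    if n == 0 or classes.size < 2:
        z = np.zeros(T)
        return z, np.ones(T), z, 0, max(n - 1, 0), n
    grand = Yo.mean(axis=1)
    sst = ((Yo - grand[:, None]) ** 2).sum(axis=1)
    ssb = np.zeros(T)
    for c in classes:
        mask = go == c
        nc = int(mask.sum())
        ssb += nc * (Yo[:, mask].mean(axis=1) - grand) ** 2
    ssw = np.clip(sst - ssb, 0.0, None)
    df_b = classes.size - 1
    df_w = n - classes.size
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
        r2 = np.where(sst > 0, ssb / sst, 0.0)
    F = np.where(ssw > 0, F, np.where(ssb > 0, np.inf, 0.0))
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 1.0, F), df_b, df_w))
    p = np.where(sst > 0, p, 1.0)
    return F, p, r2, df_b, df_w, n


def scan(
    targets: np.ndarray,
    target_ids: list[str],
    g: GenotypeMatrix,
    sample_ids: list[str],
    p_max: float,
) -> tuple[list[AssociationRecord], int]:
    """Test every target x SNP pair; return records with p < ``p_max``.

    ``targets`` is targets x samples on the same sample universe as the
    genotypes; ``sample_ids`` are the targets' sample ids and must match the
    genotype matrix's ids exactly (order included).  Also returns the total
    number of tests performed.
    """
    if list(sample_ids) != list(g.sample_ids):
        offenders = [
            (a, b) for a, b in zip(sample_ids, g.sample_ids) if a != b
        ][:5]
        raise ValueError(
            f"target/genotype sample ids differ (first mismatches: {offenders}; "
            f"lengths {len(sample_ids)} vs {len(g.sample_ids)})"
        )
    Y = np.asarray(targets, dtype=float)
    if Y.shape != (len(target_ids), len(sample_ids)):
        raise ValueError("targets shape inconsistent with ids")
    records: list[AssociationRecord] = []
    n_tests = 0
    for i in range(g.n_snps):
        F, p, r2, df_b, df_w, n_used = _scan_one_snp(Y, g.counts[i])
        n_tests += len(target_ids)
        for t in np.flatnonzero(p < p_max):
            records.append(
                AssociationRecord(
                    snp_id=g.snp_ids[i],
                    target_id=target_ids[t],
                    F=float(F[t]),
                    df_between=int(df_b),
                    df_within=int(df_w),
                    p=float(p[t]),
                    r2=float(r2[t]),
                    n_used=int(n_used),
                )
            )
    return records, n_tests


# ---------------------------------------------------------------------------
# step-2 module enrichment


def study_wise_threshold(
    n_modules: int, n_snps: int, alpha: float = 0.05, sig_digits: int = 3
) -> float:
    """Bonferroni study-wise threshold alpha / (n_modules * n_snps).

    The mantissa is truncated (not rounded) to ``sig_digits`` significant
    digits, matching how such thresholds are conventionally reported;
    pass ``sig_digits=None`` for the exact value.
    """
    if n_modules <= 0 or n_snps <= 0:
        raise ValueError("module and SNP counts must be positive")
    t = alpha / (n_modules * n_snps)
    if sig_digits is None:
        return t
    exp = math.floor(math.log10(t))
    mant = t / 10**exp
    mant = math.floor(mant * 10 ** (sig_digits - 1)) / 10 ** (sig_digits - 1)
    return mant * 10**exp


@dataclass
class EnrichmentResult:
    module_id: str
    snp_id: str
    N: int
    K_assoc: int
    n_module: int
    k_hit: int
    p: float
    threshold: float
    passed: bool


def module_enrichment_step(
    m: GeneModule,
    snp_gene_hits: set[str] | list[str],
    universe: set[str] | list[str],
    threshold: float,
    snp_id: str = "snp",
) -> EnrichmentResult:
    """Is the module enriched in genes individually associated to the SNP?

    Hypergeometric upper tail with the whole analyzed transcriptome as the
    universe: N = |universe|, K = |hits|, n = |module|, k = |hits ∩ module|.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(snp_gene_hits)
    members = m.members
    if not members <= universe or not hits <= universe:
        raise ValueError("module or hit genes outside the universe")
    k = len(hits & members)
    p = hypergeom_tail(len(universe), len(hits), len(members), k)
    return EnrichmentResult(
        module_id=m.component_id,
        snp_id=snp_id,
        N=len(universe),
        K_assoc=len(hits),
        n_module=len(members),
        k_hit=k,
        p=p,
        threshold=threshold,
        passed=p < threshold,
    )


# ---------------------------------------------------------------------------
# mediation and phenotype correlation


def _residualize(v: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of v (columns) on [1, covariates] by least squares."""
    n = v.shape[0]
    design = np.column_stack([np.ones(n), covariates]) if covariates.size else np.ones((n, 1))
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def mediation_adjust(
    trans_expr: np.ndarray,
    geno: np.ndarray,
    mediators: list[np.ndarray] | np.ndarray,
) -> tuple[float, float]:
    """Variance explained by genotype before and after mediator adjustment.

    r2_unadjusted is SS_between/SS_total from the categorical ANOVA.
    r2_adjusted is the partial R^2 of the genotype-class indicators after
    both the trans expression and the indicators are residualized on the
    mediator expressions (e.g. the cis genes at the locus): if the trans
    association is mediated by the cis genes it collapses toward zero.
    """
    y = np.asarray(trans_expr, dtype=float)
    geno = np.asarray(geno, dtype=float)
    med = np.column_stack(mediators) if len(mediators) else np.empty((y.size, 0))
    ok = ~(np.isnan(y) | np.isnan(geno) | np.isnan(med).any(axis=1))
    y, geno, med = y[ok], geno[ok], med[ok]
    r2_un = anova_2df(y, geno).r2
    if med.shape[1] == 0:
        return r2_un, r2_un
    classes = np.unique(geno)
    if classes.size < 2:
        return r2_un, 0.0
    # genotype-class indicators (first class as reference)
    G = np.column_stack([(geno == c).astype(float) for c in classes[1:]])
    y_res = _residualize(y[:, None], med)[:, 0]
    G_res = _residualize(G, med)
    sst = float((y_res**2).sum())  # y_res is centred by the intercept
    if sst == 0:
        return r2_un, 0.0
    coef, *_ = np.linalg.lstsq(G_res, y_res, rcond=None)
    ss_model = float(((G_res @ coef) ** 2).sum())
    return r2_un, ss_model / sst


def pattern_phenotype_corr(
    a_row: np.ndarray, phenotype: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of a pattern with a phenotype, pairwise-complete.

    Returns (r, two-sided p) with p from the usual t transform.
    """
    a = np.asarray(a_row, dtype=float)
    ph = np.asarray(phenotype, dtype=float)
    if a.shape != ph.shape:
        raise ValueError("pattern and phenotype lengths differ")
    ok = ~(np.isnan(a) | np.isnan(ph))
    a, ph = a[ok], ph[ok]
    if a.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if a.std() == 0 or ph.std() == 0:
        raise ValueError("zero variance in pattern or phenotype")
    res = stats.pearsonr(a, ph)
    return float(res.statistic), float(res.pvalue)
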