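"""Module-level replication of a SNP-module association in an independent
cohort.

A module replicates when both of two criteria hold on the per-gene
association p-values computed in the replication data: (1) at least two
genes pass 0.05 Bonferroni-corrected for the number of genes in the module,
and (2) the fraction of genes nominally associated at 0.05 is significantly
above the 5% expected by chance, by a one-sided exact binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import GeneModule, GenotypeMatrix

__all__ = ["ReplicationDecision", "replicate_module", "module_gene_pvalues"]


@dataclass
class ReplicationDecision:
    module_id: str
    snp_id: str
    n_genes_tested: int
    n_bonferroni_hits: int
    n_nominal_hits: int
    binomial_p: float
    criterion1: bool
    criterion2: bool
    replicated: bool
    testable: bool = True


def replicate_module(
    gene_pvalues: np.ndarray,
    module_size: int,
    module_id: str = "module",
    snp_id: str = "snp",
    alpha: float = 0.05,
    null_rate: float = 0.05,
) -> ReplicationDecision:
    """Apply the two replication criteria to per-gene p-values.

    Bonferroni correction uses the module's full gene count (``module_size``)
    even when fewer genes were measurable in the replication data; the
    binomial test uses the number actually tested.
    """
    if module_size < 1:
        raise ValueError("module_size must be >= 1")
    p = np.asarray(gene_pvalues, dtype=float)
    p = p[~np.isnan(p)]
    n = p.size
    if n == 0:
        return ReplicationDecision(
            module_id, snp_id, 0, 0, 0, 1.0, False, False, False, testable=False
        )
    n_bonf = int((p < alpha / module_size).sum())
    n_nom = int((p < alpha).sum())
    binom_p = float(stats.binom.sf(n_nom - 1, n, null_rate))
    c1 = n_bonf >= 2
    c2 = binom_p < alpha
    return ReplicationDecision(
        module_id, snp_id, n, n_bonf, n_nom, binom_p, c1, c2, c1 and c2
    )


def module_gene_pvalues(
    m: GeneModule,
    expr_values: np.ndarray,
    expr_gene_ids: list[str],
    g: GenotypeMatrix,
    snp_id: str,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Per-gene ANOVA p-values for the module's genes in a replication set.

    Genes of the module absent from the replication expression matrix yield
    NaN.  Optional covariates (e.g. age, sex, centre) are residualized out
    of each expression trait before the genotype ANOVA.
    """
    from .association import anova_2df

    if snp_id not in g.snp_ids:
        raise ValueError(f"SNP {snp_id!r} not in genotype matrix")
    geno = g.counts[g.snp_ids.index(snp_id)]
    index = {gid: i for i, gid in enumerate(expr_gene_ids)}
    out = np.full(m.size, np.nan)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        design = np.column_stack([np.ones(covariates.shape[0]), covariates])
    for j, gid in enumerate(m.gene_ids):
        if gid not in index:
            continue
        y = np.asarray(expr_values[index[gid]], dtype=float)
        if covariates is not None:
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            y = y - design @ coef
        out[j] = anova_2df(y, geno).p
    return out
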