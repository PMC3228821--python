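"""Cell-type contamination surrogates and post-hoc association re-testing.

When the profiled cell population is imperfectly purified, admixed cell
types inject their own expression programs into the matrix and can create
artefactual SNP-pattern associations (e.g. through platelet- or T-cell-
specific loci).  Per-sample surrogate variables — the mean expression of
genes specific to each contaminating lineage — proxy the admixture level;
re-testing an association with the surrogates as covariates shows whether
it survives.  Expression is never pre-adjusted before ICA (that can induce
artefactual correlations of its own); adjustment is post hoc only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "derive_cell_specific_genes",
    "ContaminationSurrogates",
    "build_surrogates",
    "adjust_association",
]


def derive_cell_specific_genes(
    reference: pd.DataFrame, fold_change: float = 2.0
) -> dict[str, list[str]]:
    """Cell-type-specific gene lists from linear-scale mean profiles.

    A gene is specific to lineage t when its mean there exceeds the highest
    mean among all other lineages by strictly more than ``fold_change``
    (so a ratio of exactly 2 does not qualify).  A gene belongs to at most
    one list.  Genes whose best competing mean is zero are skipped with a
    warning (the fold change is undefined).
    """
    if reference.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    vals = reference.to_numpy(dtype=float)
    types = list(reference.columns.astype(str))
    lists: dict[str, list[str]] = {t: [] for t in types}
    skipped = []
    for gi, gene in enumerate(reference.index.astype(str)):
        row = vals[gi]
        t_best = int(np.argmax(row))
        others = np.delete(row, t_best)
        denom = others.max()
        if denom == 0:
            skipped.append(gene)
            continue
        if row[t_best] / denom > fold_change:
            lists[types[t_best]].append(gene)
    if skipped:
        warnings.warn(
            f"{len(skipped)} genes skipped (zero competing reference mean): "
            f"{skipped[:5]}",
            stacklevel=2,
        )
    return lists


@dataclass
class ContaminationSurrogates:
    """Samples x cell-types surrogate matrix plus the gene lists used."""

    values: np.ndarray
    sample_ids: list[str]
    cell_types: list[str]
    gene_lists: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.cell_types)):
            raise ValueError("surrogate matrix shape inconsistent with ids")


def build_surrogates(
    x: ExpressionMatrix, gene_lists: dict[str, list[str]]
) -> ContaminationSurrogates:
    """Average each cell type's specific genes per sample.

    ``x`` should be on the transformed (arcsinh) scale *before* gene
    standardization — standardizing each gene would erase exactly the
    between-sample level differences the surrogate must capture.  Listed
    genes absent from the matrix are logged; a type with no measured gene
    is dropped with a warning.  Duplicate gene ids within a list are used
    once.
    """
    index = {g: i for i, g in enumerate(x.gene_ids)}
    cols, types, used = [], [], {}
    for t, genes in gene_lists.items():
        idx = sorted({index[g] for g in genes if g in index})
        missing = sorted(set(genes) - set(index))
        if not idx:
            warnings.warn(f"cell type {t!r} has no measured genes; dropped", stacklevel=2)
            continue
        if missing:
            warnings.warn(
                f"cell type {t!r}: {len(missing)} listed genes not measured", stacklevel=2
            )
        cols.append(x.values[idx].mean(axis=0))
        types.append(t)
        used[t] = [x.gene_ids[i] for i in idx]
    values = np.column_stack(cols) if cols else np.empty((x.n_samples, 0))
    return ContaminationSurrogates(
        values=values, sample_ids=list(x.sample_ids), cell_types=types, gene_lists=used
    )


def adjust_association(
    pattern: np.ndarray,
    geno: np.ndarray,
    s: ContaminationSurrogates | np.ndarray,
    p_threshold: float = 1e-7,
) -> tuple[float, float, bool]:
    """Re-test a SNP-pattern association with contamination covariates.

    The unadjusted p is the plain genotype-class ANOVA; the adjusted p is
    the F-test for the genotype-class indicators in a linear model that
    also contains every surrogate column.  The association is called
    contamination-driven when it was significant at ``p_threshold``
    unadjusted but no longer is after adjustment.  The same
    pairwise-complete sample set is used for both tests.
    """
    from .association import anova_2df

    y = np.asarray(pattern, dtype=float)
    geno = np.asarray(geno, dtype=float)
    S = s.values if isinstance(s, ContaminationSurrogates) else np.asarray(s, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    ok = ~(np.isnan(y) | np.isnan(geno))
    if S.shape[1]:
        ok &= ~np.isnan(S).any(axis=1)
    y, geno, S = y[ok], geno[ok], S[ok]
    n = y.size
    keep = [j for j in range(S.shape[1]) if S[:, j].std() > 0]
    if len(keep) < S.shape[1]:
        warnings.warn("zero-variance surrogate columns dropped", stacklevel=2)
    S = S[:, keep]

    p_un = anova_2df(y, geno).p
    if S.shape[1] == 0:
        return p_un, p_un, False

    classes = np.unique(geno)
    if classes.size < 2:
        return p_un, 1.0, p_un < p_threshold
    G = np.column_stack([(geno == c).astype(float) for c in classes[1:]])
    base = np.column_stack([np.ones(n), S])
    full = np.column_stack([base, G])

    def rss_rank(design: np.ndarray) -> tuple[float, int]:
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        return float(((y - design @ coef) ** 2).sum()), int(rank)

    rss0, rank0 = rss_rank(base)
    rss1, rank1 = rss_rank(full)
    if rank1 < full.shape[1]:
        warnings.warn("rank-deficient adjusted design; least-norm fit used", stacklevel=2)
    df_num = rank1 - rank0
    df_den = n - rank1
    if df_num <= 0 or df_den <= 0:
        p_adj = 1.0
    elif rss1 == 0:
        p_adj = 0.0 if rss0 > rss1 else 1.0
    else:
        F = ((rss0 - rss1) / df_num) / (rss1 / df_den)
        p_adj = float(stats.f.sf(max(F, 0.0), df_num, df_den))
    driven = (p_un < p_threshold) and (p_adj >= p_threshold)
    return p_un, p_adj, driven
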