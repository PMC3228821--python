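"""Expression preprocessing: probe collapsing, detection and gene-name
filters, arcsinh variance stabilization and per-gene standardization.

The fixed pipeline order is collapse -> detection filter -> name filter ->
arcsinh -> standardize; :func:`preprocess_pipeline` enforces it.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "collapse_probes",
    "detection_filter",
    "gene_name_filter",
    "arcsinh_transform",
    "standardize_genes",
    "preprocess_pipeline",
    "DEFAULT_NAME_PATTERNS",
]

# Poorly characterized transcripts: KIAA/FLJ/MGC clone ids, HS. / LOC /
# NT_ / ENSG placeholder names and open-reading-frame (CxorfN) symbols.
DEFAULT_NAME_PATTERNS: tuple[str, ...] = (
    r"^KIAA",
    r"^FLJ",
    r"^HS\.",
    r"^C\d+orf\d+",
    r"^MGC",
    r"^LOC",
    r"^NT_",
    r"^ENSG",
)


def collapse_probes(
    probe_values: pd.DataFrame, probe_to_gene: dict[str, str]
) -> ExpressionMatrix:
    """Average probe-level intensities into one row per gene.

    Parameters
    ----------
    probe_values
        Probes x samples intensities, indexed by probe id.
    probe_to_gene
        Maps every probe id to exactly one gene id.

    The mean is taken on the raw scale, before any transformation.
    """
    unmapped = [p for p in probe_values.index if p not in probe_to_gene]
    if unmapped:
        raise ValueError(f"probes without gene mapping: {unmapped[:10]}")
    genes = probe_values.index.map(probe_to_gene)
    collapsed = probe_values.groupby(genes, sort=True).mean()
    return ExpressionMatrix(
        values=collapsed.to_numpy(dtype=float),
        gene_ids=list(collapsed.index.astype(str)),
        sample_ids=list(probe_values.columns.astype(str)),
        transform_state="raw",
    )


def detection_filter(
    x: ExpressionMatrix,
    null_rate: float = 0.05,
    alpha: float = 0.05,
    detection_threshold: float = 0.05,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Keep genes detected in significantly more than ``null_rate`` of samples.

    A sample counts as detected when its detection p-value is below
    ``detection_threshold``; the per-gene decision is the one-sided exact
    binomial test of H0: detection rate = ``null_rate`` against "greater".

    Returns the filtered matrix and a per-gene report with the detected
    count, the exact upper-tail probability and the keep decision.
    """
    if x.detection_p is None:
        raise ValueError("detection_filter requires detection p-values (detection_p is None)")
    n = x.n_samples
    k = (x.detection_p < detection_threshold).sum(axis=1)
    # P(X >= k) under Binomial(n, null_rate)
    tail = stats.binom.sf(k - 1, n, null_rate)
    keep = tail < alpha
    report = pd.DataFrame(
        {
            "gene": x.gene_ids,
            "n_samples": n,
            "n_detected": k,
            "tail_p": tail,
            "kept": keep,
        }
    )
    return x.subset_genes(keep), report


def gene_name_filter(
    x: ExpressionMatrix, patterns: tuple[str, ...] = DEFAULT_NAME_PATTERNS
) -> ExpressionMatrix:
    """Drop genes whose id matches any of the name patterns (regex search)."""
    compiled = [re.compile(p) for p in patterns]
    keep = np.array(
        [not any(c.search(g) for c in compiled) for g in x.gene_ids], dtype=bool
    )
    if not keep.any():
        warnings.warn("gene_name_filter removed every gene", stacklevel=2)
    return x.subset_genes(keep)


def arcsinh_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Variance-stabilizing transform ln(x + sqrt(x^2 + 1)), elementwise."""
    if x.transform_state != "raw":
        raise ValueError(
            f"arcsinh_transform expects raw data, got state {x.transform_state!r}"
        )
    out = x.copy()
    out.values = np.arcsinh(out.values)
    out.transform_state = "arcsinh"
    return out


def standardize_genes(x: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale every gene row to mean 0, unit variance (ddof=1)."""
    if x.transform_state not in ("arcsinh", "standardized"):
        raise ValueError(
            f"standardize_genes expects arcsinh data, got state {x.transform_state!r}"
        )
    mean = x.values.mean(axis=1, keepdims=True)
    sd = x.values.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd[:, 0] == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance genes cannot be standardized: {[x.gene_ids[i] for i in zero[:10]]}"
        )
    out = x.copy()
    out.values = (x.values - mean) / sd
    out.transform_state = "standardized"
    return out


def preprocess_pipeline(
    x: ExpressionMatrix | pd.DataFrame,
    probe_to_gene: dict[str, str] | None = None,
    null_rate: float = 0.05,
    alpha: float = 0.05,
    name_patterns: tuple[str, ...] = DEFAULT_NAME_PATTERNS,
    detection_p: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, dict]:
    """Run the full preprocessing chain in its fixed order.

    Accepts either an :class:`ExpressionMatrix` or a probe-level DataFrame
    together with ``probe_to_gene``.  The detection filter is skipped (with a
    log entry) when no detection p-values are available.  A matrix already in
    the ``arcsinh`` state skips the transform.
    """
    log: dict = {}
    if isinstance(x, pd.DataFrame):
        if probe_to_gene is None:
            raise ValueError("probe-level input requires a probe_to_gene map")
        x = collapse_probes(x, probe_to_gene)
        if detection_p is not None:
            x.detection_p = np.asarray(detection_p, dtype=float)
    elif probe_to_gene is not None:
        raise ValueError("probe_to_gene given but input is already gene-level")
    log["n_genes_in"] = x.n_genes

    if x.detection_p is not None:
        x, report = detection_filter(x, null_rate=null_rate, alpha=alpha)
        log["detection_report"] = report
        log["n_after_detection"] = x.n_genes
    else:
        log["detection_report"] = None

    x = gene_name_filter(x, patterns=name_patterns)
    log["n_after_name_filter"] = x.n_genes

    if x.transform_state == "raw":
        x = arcsinh_transform(x)
    # drop zero-variance genes before standardization (constant rows carry
    # no co-expression signal and would make the z-score undefined)
    sd = x.values.std(axis=1, ddof=1)
    if (sd == 0).any():
        log["n_zero_variance_dropped"] = int((sd == 0).sum())
        x = x.subset_genes(sd > 0)
    x = standardize_genes(x)
    log["n_genes_out"] = x.n_genes
    return x, log
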