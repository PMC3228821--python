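"""Core in-memory containers shared by all pipeline stages.

The central object is the gene x sample expression matrix ``X`` whose
decomposition ``X ~ S A`` into sparse gene "signatures" (columns of S) and
per-individual "patterns" (rows of A) drives the whole analysis.  Containers
are thin dataclasses around numpy arrays with explicit row/column identifiers
and light invariant checking; heavy numerics live in the stage modules.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "GenotypeMatrix",
    "DistanceMatrix",
    "Decomposition",
    "NullFit",
    "GeneModule",
    "SimulationConfig",
    "GroundTruth",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        from collections import Counter

        dup = sorted(i for i, c in Counter(ids).items() if c > 1)
        raise ValueError(f"duplicate {what}: {dup[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with optional detection p-values.

    ``transform_state`` tracks the preprocessing state machine:
    raw -> arcsinh -> standardized.  Standardization is per gene row
    (mean 0, unit variance with the n-1 denominator).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    detection_p: np.ndarray | None = None
    transform_state: str = "raw"

    _STATES = ("raw", "arcsinh", "standardized")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (genes x samples)")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        g, n = self.values.shape
        if (len(self.gene_ids), len(self.sample_ids)) != (g, n):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} gene ids / {len(self.sample_ids)} sample ids"
            )
        if self.detection_p is not None:
            self.detection_p = np.asarray(self.detection_p, dtype=float)
            if self.detection_p.shape != self.values.shape:
                raise ValueError("detection_p shape differs from values")
            if self.detection_p.size and (
                np.nanmin(self.detection_p) < 0 or np.nanmax(self.detection_p) > 1
            ):
                raise ValueError("detection p-values must lie in [0, 1]")
        if self.transform_state not in self._STATES:
            raise ValueError(f"unknown transform_state {self.transform_state!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            values=self.values[keep],
            gene_ids=[self.gene_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            detection_p=None if self.detection_p is None else self.detection_p[keep],
            transform_state=self.transform_state,
        )

    def subset_samples(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            values=self.values[:, keep],
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in keep],
            detection_p=None if self.detection_p is None else self.detection_p[:, keep],
            transform_state=self.transform_state,
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            detection_p=None if self.detection_p is None else self.detection_p.copy(),
            transform_state=self.transform_state,
        )


@dataclass
class GenotypeMatrix:
    """SNPs x samples minor-allele dose matrix (0/1/2, NaN = missing)."""

    counts: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    chrom: list[str] | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("genotype counts must be 2-D (SNPs x samples)")
        self.snp_ids = _check_unique(self.snp_ids, "SNP ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        s, n = self.counts.shape
        if (len(self.snp_ids), len(self.sample_ids)) != (s, n):
            raise ValueError("genotype shape inconsistent with ids")
        obs = self.counts[~np.isnan(self.counts)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise ValueError("genotypes must be coded 0/1/2 (NaN for missing)")
        if self.chrom is None:
            self.chrom = ["1"] * s
        if self.pos is None:
            self.pos = np.arange(1, s + 1)
        self.pos = np.asarray(self.pos, dtype=int)
        if len(self.chrom) != s or self.pos.shape != (s,):
            raise ValueError("variant map length differs from SNP count")

    @property
    def n_snps(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.counts).mean(axis=1)

    @property
    def maf(self) -> np.ndarray:
        """Allele frequency of the coded (nominally minor) allele."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.counts, axis=1) / 2.0

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            counts=self.counts[keep],
            snp_ids=[self.snp_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            chrom=[self.chrom[i] for i in keep],
            pos=self.pos[keep],
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            counts=self.counts[:, keep],
            snp_ids=list(self.snp_ids),
            sample_ids=[self.sample_ids[i] for i in keep],
            chrom=list(self.chrom),
            pos=self.pos.copy(),
        )


@dataclass
class DistanceMatrix:
    """Symmetric sample-sample distances used for MDS outlier screening."""

    d: np.ndarray
    sample_ids: list[str]
    kind: str  # "expression_abscorr" or "genotype_ibs"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with sample ids")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal not zero")
        if np.nanmin(self.d) < -1e-10:
            raise ValueError("negative distances")
        if self.kind not in ("expression_abscorr", "genotype_ibs"):
            raise ValueError(f"unknown distance kind {self.kind!r}")
        if self.kind == "expression_abscorr" and np.nanmax(self.d) > 1 + 1e-10:
            raise ValueError("1-|r| distances must lie in [0, 1]")


@dataclass
class Decomposition:
    """ICA result: signatures S (genes x K) and patterns A (K x samples).

    Signature columns are scaled to unit variance over genes; A absorbs the
    magnitude so that S @ A reconstructs the rank-K projection of the input.
    """

    S: np.ndarray
    A: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    component_ids: list[str]
    kurtosis: np.ndarray = field(default=None)  # type: ignore[assignment]
    individual_specific: np.ndarray = field(default=None)  # type: ignore[assignment]
    kurtosis_pass: np.ndarray = field(default=None)  # type: ignore[assignment]
    negentropy: float | None = None
    winning_restart: int | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        g, k = self.S.shape
        k2, n = self.A.shape
        if k != k2:
            raise ValueError("S and A disagree on component count")
        if len(self.gene_ids) != g or len(self.sample_ids) != n:
            raise ValueError("decomposition ids inconsistent with shapes")
        if len(self.component_ids) != k:
            raise ValueError("component_ids length != K")
        for name in ("kurtosis", "individual_specific", "kurtosis_pass"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (k,):
                    raise ValueError(f"{name} length != K")
                setattr(self, name, v)

    @property
    def K(self) -> int:
        return self.S.shape[1]

    def subset_components(self, keep: np.ndarray) -> "Decomposition":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        sub = {}
        for name in ("kurtosis", "individual_specific", "kurtosis_pass"):
            v = getattr(self, name)
            sub[name] = None if v is None else v[keep]
        return Decomposition(
            S=self.S[:, keep],
            A=self.A[keep],
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            component_ids=[self.component_ids[i] for i in keep],
            negentropy=self.negentropy,
            winning_restart=self.winning_restart,
            **sub,
        )


@dataclass
class NullFit:
    """Empirical null for signature loadings: Gaussian fitted to the bulk."""

    center: float
    sigma0: float
    eta0: float

    def __post_init__(self) -> None:
        if not self.sigma0 > 0:
            raise ValueError("sigma0 must be positive")
        if not 0 < self.eta0 <= 1:
            raise ValueError("eta0 must lie in (0, 1]")


@dataclass
class GeneModule:
    """FDR-selected gene set characterizing one signature."""

    component_id: str
    gene_ids: list[str]
    loadings: np.ndarray
    qvalues: np.ndarray

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.qvalues = np.asarray(self.qvalues, dtype=float)
        n = len(self.gene_ids)
        if self.loadings.shape != (n,) or self.qvalues.shape != (n,):
            raise ValueError("module arrays inconsistent with gene count")

    @property
    def size(self) -> int:
        return len(self.gene_ids)

    @property
    def members(self) -> set[str]:
        return set(self.gene_ids)


@dataclass
class SimulationConfig:
    """Parameters of the genotype-driven transcriptome generator.

    Defaults emulate a desk-scale cohort: a few thousand genes, a few
    hundred individuals, a handful of sparse latent components of which
    one is driven by a SNP explaining ~20% of its pattern variance
    (the upper-middle of the 2-25% range seen for real lead SNPs).
    ``background_sd`` (non-member loading noise) is kept well below
    ``noise_sd`` so that, as in real data, a non-member gene's variance is
    dominated by its own measurement noise and signatures stay sparse and
    supergaussian after per-gene standardization.
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_snps: int = 100
    K_true: int = 3
    module_sizes: list[int] = field(default_factory=lambda: [50, 50, 50])
    loading_effect: float = 3.0
    background_sd: float = 0.1
    pattern_snp_r2: list[float] = field(default_factory=lambda: [0.2, 0.0, 0.0])
    maf: list[float] = field(default_factory=lambda: [0.3])
    n_cis_per_component: int = 2
    noise_sd: float = 1.0
    contamination: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_true > min(self.n_genes, self.n_samples):
            raise ValueError("K_true exceeds min(n_genes, n_samples)")
        if len(self.module_sizes) != self.K_true:
            raise ValueError("module_sizes must have K_true entries")
        if any(m > self.n_genes for m in self.module_sizes):
            raise ValueError("module size exceeds n_genes")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed gene count (modules are disjoint)")
        if len(self.pattern_snp_r2) != self.K_true:
            raise ValueError("pattern_snp_r2 must have K_true entries")
        if any(not 0 <= r < 1 for r in self.pattern_snp_r2):
            raise ValueError("pattern_snp_r2 entries must lie in [0, 1)")
        if any(not 0 < m <= 0.5 for m in self.maf):
            raise ValueError("maf entries must lie in (0, 0.5]")
        for name in ("loading_effect", "background_sd", "noise_sd"):
            if getattr(self, name) < 0 or (name != "noise_sd" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.contamination is not None:
            unknown = set(self.contamination) - {"n_cell_types", "genes_per_type", "fraction_sd"}
            if unknown:
                raise ValueError(f"unknown contamination keys: {sorted(unknown)}")
            if self.contamination.get("fraction_sd", 0.1) <= 0:
                raise ValueError("contamination fraction_sd must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset, for recovery evaluation."""

    true_loadings: np.ndarray  # genes x K_true
    true_activations: np.ndarray  # K_true x samples
    driver_snp_index: list[int | None]
    module_membership: list[set[str]]
    cis_gene_indices: list[set[int]]
    contamination_fractions: np.ndarray | None = None  # samples x cell types
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
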