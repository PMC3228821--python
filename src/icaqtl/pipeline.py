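"""End-to-end pipeline driver: preprocess -> outlier QC -> component-number
selection -> ICA -> component filtering -> module extraction -> SNP QC ->
two-step SNP-pattern association -> optional contamination adjustment and
gene-set enrichment.  All stage parameters live in a single strict config;
every run writes the resolved config and a provenance block next to its
outputs, and is deterministic given the seeds it contains.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iomod
from .association import (
    module_enrichment_step,
    scan,
    snp_qc,
    study_wise_threshold,
)
from .containers import ExpressionMatrix, GenotypeMatrix
from .contamination import adjust_association, build_surrogates, derive_cell_specific_genes
from .decompose import annotate_components, choose_num_components, filter_components, run_ica
from .modules import assign_module, fit_empirical_null, geneset_enrichment
from .outliers import expression_distance, flag_outliers, ibs_matrix
from .preprocess import DEFAULT_NAME_PATTERNS, preprocess_pipeline

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

_VERSION = "0.1.0"


def _strict(cls, d: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
    return cls(**d)


@dataclass
class PreprocessParams:
    detection_null_rate: float = 0.05
    detection_alpha: float = 0.05
    name_patterns: list[str] = field(default_factory=lambda: list(DEFAULT_NAME_PATTERNS))


@dataclass
class OutlierParams:
    enabled: bool = True
    dims: int = 2
    k_mad: float = 6.0
    max_rounds: int = 3


@dataclass
class DecomposeParams:
    K: int | None = None  # None -> permutation screeplot
    n_perm: int = 1
    scree_margin: float = 0.05
    n_restarts: int = 10
    tol: float = 1.0e-4
    max_iter: int = 200
    kurtosis_min: float = 3.0
    kurtosis_scale: str = "excess"
    individual_threshold: float = 0.10
    seed: int = 0


@dataclass
class ModuleParams:
    central_fraction: float = 0.75
    fdr_max: float = 1.0e-3
    rule: str = "qvalue"
    enrichment_alpha: float = 0.05
    min_set: int = 5


@dataclass
class AssociationParams:
    maf_min: float = 0.01
    hwe_alpha: float = 1.0e-4
    call_min: float = 0.95
    p_step1: float = 1.0e-7
    p_gene: float = 1.0e-5
    alpha_study: float = 0.05


@dataclass
class ContaminationParams:
    fold_change: float = 2.0
    p_threshold: float = 1.0e-7


@dataclass
class PipelineConfig:
    """Strict, nested pipeline configuration (unknown keys rejected)."""

    expression: str | None = None
    detection: str | None = None
    probe_map: str | None = None
    genotypes: str | None = None
    genotype_format: str | None = None
    gmt: str | None = None
    cell_reference: str | None = None
    out_dir: str = "icaqtl_out"
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    outliers: OutlierParams = field(default_factory=OutlierParams)
    decompose: DecomposeParams = field(default_factory=DecomposeParams)
    modules: ModuleParams = field(default_factory=ModuleParams)
    association: AssociationParams = field(default_factory=AssociationParams)
    contamination: ContaminationParams = field(default_factory=ContaminationParams)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        nested = {
            "preprocess": PreprocessParams,
            "outliers": OutlierParams,
            "decompose": DecomposeParams,
            "modules": ModuleParams,
            "association": AssociationParams,
            "contamination": ContaminationParams,
        }
        for key, sub in nested.items():
            if key in d and isinstance(d[key], dict):
                d[key] = _strict(sub, d[key], key)
        return _strict(cls, d, "pipeline")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)


@dataclass
class PipelineResult:
    expression: ExpressionMatrix
    genotypes: GenotypeMatrix | None
    decomposition: object
    modules: list
    associations: pd.DataFrame
    enrichments: pd.DataFrame
    outliers_expression: set
    outliers_genotype: set
    K: int
    out_dir: Path | None


def run_pipeline(
    cfg: PipelineConfig,
    expression: ExpressionMatrix | None = None,
    genotypes: GenotypeMatrix | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute the full workflow; inputs come from ``cfg`` paths unless
    passed in memory.  Outputs and logs for every stage are persisted under
    ``cfg.out_dir``; a stage failure aborts with the stage name, keeping
    whatever earlier stages already wrote.
    """
    out = Path(cfg.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        resolved = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
        (out / "config.resolved.yaml").write_text(resolved)
        prov = {
            "tool": "icaqtl",
            "version": _VERSION,
            "config_sha256": hashlib.sha256(resolved.encode()).hexdigest(),
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))

    stage = "load"
    try:
        if expression is None:
            if cfg.expression is None:
                raise ValueError("no expression input (config path or in-memory)")
            path = Path(cfg.expression)
            if path.suffix.lower() == ".gct":
                expression = iomod.read_expression_gct(path)
            else:
                expression = iomod.read_expression_tsv(path, detection_path=cfg.detection)
        if genotypes is None and cfg.genotypes is not None:
            genotypes = iomod.read_genotypes(cfg.genotypes, fmt=cfg.genotype_format)

        stage = "preprocess"
        probe_map = None
        if cfg.probe_map is not None:
            pm = pd.read_csv(cfg.probe_map, sep="\t", header=None, names=["probe", "gene"])
            probe_map = dict(zip(pm["probe"].astype(str), pm["gene"].astype(str)))
            frame = pd.DataFrame(
                expression.values, index=expression.gene_ids, columns=expression.sample_ids
            )
            x_std, pre_log = preprocess_pipeline(
                frame,
                probe_to_gene=probe_map,
                null_rate=cfg.preprocess.detection_null_rate,
                alpha=cfg.preprocess.detection_alpha,
                name_patterns=tuple(cfg.preprocess.name_patterns),
                detection_p=expression.detection_p,
            )
        else:
            x_std, pre_log = preprocess_pipeline(
                expression,
                null_rate=cfg.preprocess.detection_null_rate,
                alpha=cfg.preprocess.detection_alpha,
                name_patterns=tuple(cfg.preprocess.name_patterns),
            )

        stage = "outlier_qc"
        out_expr: set = set()
        out_geno: set = set()
        if cfg.outliers.enabled:
            rep_e = flag_outliers(
                expression_distance(x_std),
                dims=cfg.outliers.dims,
                k_mad=cfg.outliers.k_mad,
                max_rounds=cfg.outliers.max_rounds,
            )
            out_expr = rep_e.flagged
            if genotypes is not None:
                rep_g = flag_outliers(
                    ibs_matrix(genotypes),
                    dims=cfg.outliers.dims,
                    k_mad=cfg.outliers.k_mad,
                    max_rounds=cfg.outliers.max_rounds,
                )
                out_geno = rep_g.flagged
            drop = out_expr | out_geno
            if drop:
                keep = [s not in drop for s in x_std.sample_ids]
                x_std = x_std.subset_samples(np.array(keep))
                # re-standardize on the surviving samples
                x_std.transform_state = "arcsinh"
                from .preprocess import standardize_genes

                sd = x_std.values.std(axis=1, ddof=1)
                if (sd == 0).any():
                    x_std = x_std.subset_genes(sd > 0)
                x_std = standardize_genes(x_std)
                if genotypes is not None:
                    gkeep = [s not in drop for s in genotypes.sample_ids]
                    genotypes = genotypes.subset_samples(np.array(gkeep))
            if write:
                pd.DataFrame({"sample": sorted(drop)}).to_csv(
                    out / "outliers.tsv", sep="\t", index=False
                )

        stage = "decompose"
        dp = cfg.decompose
        K = dp.K
        if K is None:
            K = choose_num_components(
                x_std, n_perm=dp.n_perm, seed=dp.seed, margin=dp.scree_margin
            )
        if K == 0:
            warnings.warn("no components above the permutation null; stopping", stacklevel=2)
            return PipelineResult(
                expression=x_std,
                genotypes=genotypes,
                decomposition=None,
                modules=[],
                associations=pd.DataFrame(),
                enrichments=pd.DataFrame(),
                outliers_expression=out_expr,
                outliers_genotype=out_geno,
                K=0,
                out_dir=out if write else None,
            )
        decomp = run_ica(
            x_std,
            K=K,
            n_restarts=dp.n_restarts,
            seed=dp.seed,
            tol=dp.tol,
            max_iter=dp.max_iter,
        )
        decomp = annotate_components(
            decomp,
            individual_threshold=dp.individual_threshold,
            kurtosis_min=dp.kurtosis_min,
            kurtosis_scale=dp.kurtosis_scale,
        )
        if write:
            pd.DataFrame(
                {
                    "component_id": decomp.component_ids,
                    "kurtosis": decomp.kurtosis,
                    "individual_specific": decomp.individual_specific,
                    "kurtosis_pass": decomp.kurtosis_pass,
                }
            ).to_csv(out / "components.tsv", sep="\t", index=False)
        decomp = filter_components(
            decomp,
            kurtosis_min=dp.kurtosis_min,
            individual_threshold=dp.individual_threshold,
            kurtosis_scale=dp.kurtosis_scale,
        )
        if write:
            pd.DataFrame(decomp.S, index=decomp.gene_ids, columns=decomp.component_ids).to_csv(
                out / "S.tsv", sep="\t", float_format="%.12g", index_label="gene"
            )
            pd.DataFrame(
                decomp.A, index=decomp.component_ids, columns=decomp.sample_ids
            ).to_csv(out / "A.tsv", sep="\t", float_format="%.12g", index_label="component")

        stage = "module_extraction"
        mp = cfg.modules
        modules = []
        for k, cid in enumerate(decomp.component_ids):
            fit = fit_empirical_null(decomp.S[:, k], central_fraction=mp.central_fraction)
            modules.append(
                assign_module(
                    decomp.S[:, k],
                    decomp.gene_ids,
                    fit,
                    component_id=cid,
                    fdr_max=mp.fdr_max,
                    rule=mp.rule,
                )
            )
        if write:
            iomod.write_modules_tsv(modules, out / "modules.tsv")
        enrich_frames = []
        if cfg.gmt is not None:
            sets = iomod.read_gmt(cfg.gmt)
            for m in modules:
                df = geneset_enrichment(
                    m,
                    sets,
                    universe=decomp.gene_ids,
                    alpha_family=mp.enrichment_alpha,
                    min_set=mp.min_set,
                )
                df.insert(0, "component_id", m.component_id)
                enrich_frames.append(df)
            if write and enrich_frames:
                pd.concat(enrich_frames).to_csv(
                    out / "geneset_enrichment.tsv", sep="\t", index=False
                )

        stage = "association"
        assoc_df = pd.DataFrame()
        enr_df = pd.DataFrame()
        if genotypes is not None and decomp.K > 0:
            ap = cfg.association
            genotypes_qc, qc_report = snp_qc(
                genotypes, maf_min=ap.maf_min, hwe_alpha=ap.hwe_alpha, call_min=ap.call_min
            )
            if write:
                qc_report.to_csv(out / "snp_qc.tsv", sep="\t", index=False)
            records, _ = scan(
                decomp.A,
                decomp.component_ids,
                genotypes_qc,
                decomp.sample_ids,
                p_max=ap.p_step1,
            )
            assoc_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
            threshold = study_wise_threshold(
                n_modules=decomp.K, n_snps=genotypes_qc.n_snps, alpha=ap.alpha_study
            )
            mod_by_id = {m.component_id: m for m in modules}
            enr_rows = []
            surrogates = None
            if cfg.cell_reference is not None:
                ref = pd.read_csv(cfg.cell_reference, sep="\t", index_col=0)
                lists = derive_cell_specific_genes(ref, fold_change=cfg.contamination.fold_change)
                # surrogates need the pre-standardization (arcsinh) values
                surrogate_source = expression
                if surrogate_source.transform_state == "raw":
                    from .preprocess import arcsinh_transform

                    surrogate_source = arcsinh_transform(surrogate_source)
                surrogates = build_surrogates(surrogate_source, lists)
            for rec in records:
                snp_i = genotypes_qc.snp_ids.index(rec.snp_id)
                gene_hits, _ = scan(
                    x_std.values,
                    x_std.gene_ids,
                    genotypes_qc.subset_snps(np.array([snp_i])),
                    x_std.sample_ids,
                    p_max=ap.p_gene,
                )
                hit_ids = {h.target_id for h in gene_hits}
                er = module_enrichment_step(
                    mod_by_id[rec.target_id],
                    hit_ids,
                    universe=x_std.gene_ids,
                    threshold=threshold,
                    snp_id=rec.snp_id,
                )
                row = dataclasses.asdict(er)
                if surrogates is not None:
                    comp_idx = decomp.component_ids.index(rec.target_id)
                    sample_index = {sid: i for i, sid in enumerate(surrogates.sample_ids)}
                    sel = [sample_index[sid] for sid in decomp.sample_ids]
                    p_un, p_adj, driven = adjust_association(
                        decomp.A[comp_idx],
                        genotypes_qc.counts[snp_i],
                        surrogates.values[sel],
                        p_threshold=cfg.contamination.p_threshold,
                    )
                    row.update(
                        {"p_unadjusted": p_un, "p_adjusted": p_adj, "contamination_driven": driven}
                    )
                enr_rows.append(row)
            enr_df = pd.DataFrame(enr_rows)
            if write:
                assoc_df.to_csv(out / "associations.tsv", sep="\t", index=False)
                enr_df.to_csv(out / "association_enrichment.tsv", sep="\t", index=False)

        if write:
            (out / "pipeline_log.json").write_text(
                json.dumps(
                    {
                        "n_genes_out": pre_log.get("n_genes_out"),
                        "n_outliers": len(out_expr | out_geno),
                        "K_selected": K,
                        "K_retained": decomp.K,
                        "n_modules": len(modules),
                        "n_step1_hits": int(len(assoc_df)),
                    },
                    indent=2,
                )
            )
        return PipelineResult(
            expression=x_std,
            genotypes=genotypes,
            decomposition=decomp,
            modules=modules,
            associations=assoc_df,
            enrichments=enr_df,
            outliers_expression=out_expr,
            outliers_genotype=out_geno,
            K=K,
            out_dir=out if write else None,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
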