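"""Readers and writers for the plain-text formats the pipeline touches.

Expression travels as TSV (genes in rows, header of sample ids) or GCT;
genotypes as 0/1/2 TSV (with chrom/pos columns) or VCFv4.2 (GT only);
gene sets as GMT; simulation truth as JSON.  All tabular output is written
with 12 significant digits so round-trips are lossless at that precision.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneModule, GenotypeMatrix, GroundTruth

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_expression_gct",
    "read_genotypes",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_gmt",
    "write_gmt",
    "write_truth_json",
    "read_truth_json",
    "write_modules_tsv",
    "read_modules_tsv",
]

_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# expression


def read_expression_tsv(
    path: str | Path,
    detection_path: str | Path | None = None,
    transform_state: str = "raw",
) -> ExpressionMatrix:
    """Genes x samples TSV, index = gene ids, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    det = None
    if detection_path is not None:
        dp = pd.read_csv(detection_path, sep="\t", index_col=0)
        if list(dp.index) != list(df.index) or list(dp.columns) != list(df.columns):
            raise ValueError("detection p-value table does not align with expression")
        det = dp.to_numpy(dtype=float)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        detection_p=det,
        transform_state=transform_state,
    )


def write_expression_tsv(x: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(x.values, index=x.gene_ids, columns=x.sample_ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="gene")


def read_expression_gct(path: str | Path) -> ExpressionMatrix:
    """GCT v1.2: two header lines, then Name/Description + sample columns."""
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ValueError(f"unsupported GCT version line: {version!r}")
        fh.readline()  # dimensions line (trusted to match the table)
        df = pd.read_csv(fh, sep="\t")
    if df.columns[0].lower() != "name":
        raise ValueError("GCT table must start with a Name column")
    sample_cols = list(df.columns[2:])
    return ExpressionMatrix(
        values=df[sample_cols].to_numpy(dtype=float),
        gene_ids=list(df.iloc[:, 0].astype(str)),
        sample_ids=[str(c) for c in sample_cols],
        transform_state="raw",
    )


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on format ('vcf' or 'tsv'; inferred from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in (".vcf", ".gz") else "tsv"
    if fmt == "vcf":
        return read_genotypes_vcf(path)
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """TSV with index snp id, columns chrom, pos, then 0/1/2 doses (NA ok)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns[:2]) != ["chrom", "pos"]:
        raise ValueError("genotype TSV must start with 'chrom' and 'pos' columns")
    sample_cols = list(df.columns[2:])
    return GenotypeMatrix(
        counts=df[sample_cols].to_numpy(dtype=float),
        snp_ids=list(df.index.astype(str)),
        sample_ids=[str(c) for c in sample_cols],
        chrom=list(df["chrom"].astype(str)),
        pos=df["pos"].to_numpy(dtype=int),
    )


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.counts, index=g.snp_ids, columns=g.sample_ids)
    df.insert(0, "pos", g.pos)
    df.insert(0, "chrom", g.chrom)
    df.to_csv(path, sep="\t", float_format="%g", index_label="snp", na_rep="NA")


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Parse a VCF's GT fields to minor-allele dose.

    Multi-allelic records are skipped with a warning; "./." becomes NaN;
    doses are flipped so the coded allele is the rarer one at each site.
    Non-diploid GT fields are an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    counts, snp_ids, chrom, pos = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic record {var.CHROM}:{var.POS}", stacklevel=2
            )
            continue
        dose = np.full(len(sample_ids), np.nan)
        for j, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid GT at {var.CHROM}:{var.POS} sample {sample_ids[j]}"
                )
            if -1 in alleles:
                continue
            dose[j] = sum(alleles)
        obs = dose[~np.isnan(dose)]
        if obs.size and obs.mean() / 2.0 > 0.5:
            dose = 2.0 - dose  # orient to the rarer allele
        counts.append(dose)
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        chrom.append(str(var.CHROM))
        pos.append(int(var.POS))
    return GenotypeMatrix(
        counts=np.array(counts) if counts else np.empty((0, len(sample_ids))),
        snp_ids=snp_ids,
        sample_ids=sample_ids,
        chrom=chrom,
        pos=np.array(pos, dtype=int) if pos else np.empty(0, dtype=int),
    )


def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCFv4.2 with GT fields only (coded allele written as ALT)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for i in range(g.n_snps):
            gts = "\t".join(
                "./." if np.isnan(v) else gt_map[v] for v in g.counts[i]
            )
            fh.write(
                f"{g.chrom[i]}\t{g.pos[i]}\t{g.snp_ids[i]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: name <TAB> description <TAB> gene1 <TAB> gene2 ...

    Duplicate genes within a set are deduplicated; empty sets are dropped
    with a warning; a line with fewer than 3 fields is an error.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not any(ln.strip() for ln in lines):
        warnings.warn(f"empty GMT file: {path}", stacklevel=2)
        return {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name = fields[0]
        genes = {f for f in fields[2:] if f}
        if not genes:
            warnings.warn(f"{path}:{lineno}: empty set {name!r} dropped", stacklevel=2)
            continue
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str] | list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = sorted(set(sets[name]))
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# truth, modules


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "true_loadings": np.asarray(truth.true_loadings).tolist(),
        "true_activations": np.asarray(truth.true_activations).tolist(),
        "driver_snp_index": truth.driver_snp_index,
        "module_membership": [sorted(m) for m in truth.module_membership],
        "cis_gene_indices": [sorted(c) for c in truth.cis_gene_indices],
        "contamination_fractions": (
            None
            if truth.contamination_fractions is None
            else np.asarray(truth.contamination_fractions).tolist()
        ),
        "gene_ids": truth.gene_ids,
        "sample_ids": truth.sample_ids,
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_json(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        true_loadings=np.array(d["true_loadings"]),
        true_activations=np.array(d["true_activations"]),
        driver_snp_index=[None if v is None else int(v) for v in d["driver_snp_index"]],
        module_membership=[set(m) for m in d["module_membership"]],
        cis_gene_indices=[set(c) for c in d["cis_gene_indices"]],
        contamination_fractions=(
            None
            if d["contamination_fractions"] is None
            else np.array(d["contamination_fractions"])
        ),
        gene_ids=list(d["gene_ids"]),
        sample_ids=list(d["sample_ids"]),
    )


def write_modules_tsv(modules: list[GeneModule], path: str | Path) -> None:
    rows = [
        {"component_id": m.component_id, "gene": gid, "loading": m.loadings[i], "q": m.qvalues[i]}
        for m in modules
        for i, gid in enumerate(m.gene_ids)
    ]
    pd.DataFrame(rows, columns=["component_id", "gene", "loading", "q"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_modules_tsv(path: str | Path) -> list[GeneModule]:
    df = pd.read_csv(path, sep="\t")
    modules = []
    for cid, grp in df.groupby("component_id", sort=False):
        modules.append(
            GeneModule(
                component_id=str(cid),
                gene_ids=list(grp["gene"].astype(str)),
                loadings=grp["loading"].to_numpy(dtype=float),
                qvalues=grp["q"].to_numpy(dtype=float),
            )
        )
    return modules
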