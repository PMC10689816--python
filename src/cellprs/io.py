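"""Readers and writers for the pipeline's on-disk formats.

Expression goes to MatrixMarket (.mtx) with row/column label sidecars or a
dense TSV; annotations and interval tracks to BED (0-based half-open on
disk, converted to the package's 1-based inclusive convention on read);
variant weights to the tab-separated CHR/SNP/BP/A1/A2/BETA dialect
(headerless by default, header auto-detected on read); genotypes to an
individuals x variants TSV; phenotypes and scores to TSV; ground truth to
JSON. Genotypes can also be read from an uncompressed VCF (GT collapsed to
a 0/1/2 dosage, DS rounded to the nearest integer).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .intervals import IntervalSet
from .scoring import WEIGHT_COLUMNS, GenotypeMatrix, ScoreTable
from .specificity import ExpressionMatrix, GeneAnnotation, normalize_chrom


# ------------------------------------------------------------- expression

def write_expression_mtx(expr: ExpressionMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    counts = expr.counts if sp.issparse(expr.counts) else sp.csr_matrix(expr.counts)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), counts)
    pd.Series(expr.gene_ids).to_csv(
        prefix.parent / (prefix.name + ".genes.tsv"), sep="\t",
        index=False, header=False,
    )
    pd.DataFrame({"cell_type": expr.cell_types}).to_csv(
        prefix.parent / (prefix.name + ".cells.tsv"), sep="\t", index=False,
    )


def read_expression_mtx(prefix: str | Path) -> ExpressionMatrix:
    prefix = Path(prefix)
    counts = scipy.io.mmread(str(prefix.with_suffix(".mtx"))).tocsr()
    genes = pd.read_csv(
        prefix.parent / (prefix.name + ".genes.tsv"), sep="\t", header=None
    )[0].to_numpy(dtype=object)
    cells = pd.read_csv(prefix.parent / (prefix.name + ".cells.tsv"), sep="\t")
    return ExpressionMatrix(
        counts=counts, gene_ids=genes,
        cell_types=cells["cell_type"].to_numpy(dtype=object),
    )


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    X = expr.counts
    if sp.issparse(X):
        X = np.asarray(X.todense())
    df = pd.DataFrame(X, columns=expr.gene_ids)
    df.insert(0, "cell_type", expr.cell_types)
    df.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    labels = df.pop("cell_type").to_numpy(dtype=object)
    return ExpressionMatrix(
        counts=df.to_numpy(), gene_ids=df.columns.to_numpy(dtype=object),
        cell_types=labels,
    )


# --------------------------------------------------------------------- BED

def write_annotation_bed(ann: GeneAnnotation, path: str | Path) -> None:
    t = ann.table
    bed = pd.DataFrame({
        "chrom": t["chrom"],
        "start": t["start"] - 1,      # 1-based inclusive -> 0-based half-open
        "end": t["end"],
        "name": t["gene_id"],
        "score": 0,
        "strand": ".",
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_annotation_bed(path: str | Path) -> GeneAnnotation:
    bed = pd.read_csv(path, sep="\t", header=None)
    return GeneAnnotation(pd.DataFrame({
        "gene_id": bed[3],
        "chrom": bed[0].map(normalize_chrom),
        "start": bed[1] + 1,
        "end": bed[2],
    }))


def write_intervals_bed(iset: IntervalSet, path: str | Path) -> None:
    rows = []
    for chrom in sorted(iset.intervals):
        for s, e in iset.intervals[chrom]:
            rows.append((chrom, int(s) - 1, int(e)))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


# ----------------------------------------------------------------- weights

def write_weights(weights: pd.DataFrame, path: str | Path, header: bool = False) -> None:
    weights[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False, header=header)


def read_weights(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    has_header = first.split("\t")[0].strip().upper() == "CHR"
    df = pd.read_csv(
        path, sep="\t",
        header=0 if has_header else None,
        names=None if has_header else WEIGHT_COLUMNS,
    )
    df.columns = WEIGHT_COLUMNS
    df["CHR"] = df["CHR"].astype(str)
    return df


# --------------------------------------------------------------- genotypes

def write_genotypes(geno: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    df = pd.DataFrame(geno.dosages, columns=geno.variant_meta["SNP"])
    df.insert(0, "IID", geno.individual_ids)
    df.to_csv(prefix.parent / (prefix.name + ".dosage.tsv"), sep="\t", index=False)
    geno.variant_meta.to_csv(
        prefix.parent / (prefix.name + ".variants.tsv"), sep="\t", index=False
    )


def read_genotypes(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.parent / (prefix.name + ".dosage.tsv"), sep="\t")
    iids = df.pop("IID").to_numpy(dtype=object)
    meta = pd.read_csv(prefix.parent / (prefix.name + ".variants.tsv"), sep="\t")
    return GenotypeMatrix(
        dosages=df.to_numpy(dtype=np.int64), individual_ids=iids,
        variant_meta=meta,
    )


def read_vcf_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read dosages from a VCF: DS rounded to the nearest integer where
    present, otherwise GT collapsed to an alt-allele count. The counted
    allele is ALT. Missing genotypes are mean-imputed per variant (rounded),
    with a log message."""
    import logging

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    rows, meta = [], []
    n_imputed = 0
    for var in vcf:
        if "DS" in (var.FORMAT or []):
            d = np.rint(np.asarray(var.format("DS"), dtype=float).ravel())
        else:
            gts = np.asarray(var.genotypes, dtype=object)
            d = np.array([
                sum(1 for a in g[:2] if a == 1) if -1 not in g[:2] else np.nan
                for g in gts
            ], dtype=float)
        miss = ~np.isfinite(d)
        if miss.any():
            n_imputed += int(miss.sum())
            fill = np.rint(np.nanmean(d)) if np.isfinite(d).any() else 0
            d[miss] = fill
        rows.append(np.clip(np.rint(d), 0, 2).astype(np.int64))
        meta.append({
            "SNP": var.ID or f"{var.CHROM}:{var.POS}",
            "CHR": normalize_chrom(var.CHROM),
            "BP": var.POS,
            "counted_allele": var.ALT[0] if var.ALT else "N",
            "other_allele": var.REF,
        })
    if n_imputed:
        logging.getLogger(__name__).info(
            "mean-imputed %d missing genotype(s)", n_imputed
        )
    return GenotypeMatrix(
        dosages=np.vstack(rows).T, individual_ids=samples,
        variant_meta=pd.DataFrame(meta),
    )


# ----------------------------------------------------------- tables / JSON

def write_scores(scores: ScoreTable, prefix: str | Path) -> None:
    prefix = Path(prefix)
    scores.raw.rename_axis("IID").to_csv(
        prefix.parent / (prefix.name + ".raw.tsv"), sep="\t"
    )
    scores.standardized.rename_axis("IID").to_csv(
        prefix.parent / (prefix.name + ".std.tsv"), sep="\t"
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
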