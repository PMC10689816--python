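"""Expression specificity (Sg) and cell-type-specific gene sets.

Given a cells x genes count matrix with one cell-type label per cell, this
module

1. keeps genes detected (count > 0) in more than a threshold fraction of the
   cells of at least one cell type,
2. removes genes overlapping an excluded genomic region (by default the
   extended *APOE* locus, whose ε4/ε2 haplotypes are modelled as covariates
   downstream instead of entering any score),
3. computes the specificity metric Sg_ij = E_ij / Σ_j E_ij, where E_ij is the
   mean (library-size-normalised) expression of gene i in cell type j, and
4. selects, per cell type, the top fraction of genes ranked by Sg as that
   type's specific gene set.

Sg rows sum to one across cell types, so a gene expressed in a single type
has Sg = 1 there and 0 elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import floor
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Extended APOE locus, GRCh38, 1-based inclusive: APOE +/- 1 Mb.
APOE_REGION = ("chr19", 43_905_781, 45_909_393)


def normalize_chrom(chrom: str) -> str:
    """Canonical chromosome name: '19' and 'chr19' both map to 'chr19'."""
    c = str(chrom)
    return c if c.lower().startswith("chr") else "chr" + c


@dataclass
class ExpressionMatrix:
    """Cells x genes counts with per-cell type labels.

    ``counts`` may be dense or scipy-sparse; it is kept as given. Gene IDs
    must be unique and at least two cell types must be present.
    """

    counts: "np.ndarray | sp.spmatrix"
    gene_ids: np.ndarray
    cell_types: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_types = np.asarray(self.cell_types, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts columns")
        if len(self.cell_types) != n_cells:
            raise ValueError("cell_types length does not match counts rows")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene IDs")
        if len(set(self.cell_types)) < 2:
            raise ValueError("need at least 2 cell types")

    @property
    def type_names(self) -> list[str]:
        return sorted(set(self.cell_types))

    def dense_counts(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)


@dataclass
class GeneAnnotation:
    """One genomic interval per gene, 1-based inclusive coordinates."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene_id", "chrom", "start", "end"}
        if not required.issubset(t.columns):
            raise ValueError(f"annotation must have columns {sorted(required)}")
        if t["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in annotation")
        if (t["start"] > t["end"]).any():
            raise ValueError("annotation has start > end")
        t = t.copy()
        t["chrom"] = t["chrom"].map(normalize_chrom)
        self.table = t.reset_index(drop=True)

    def subset(self, gene_ids: Sequence[str]) -> "GeneAnnotation":
        keep = self.table["gene_id"].isin(set(gene_ids))
        return GeneAnnotation(self.table.loc[keep])


@dataclass
class SpecificityTable:
    """Per-gene, per-cell-type specificity Sg and mean expression E."""

    Sg: pd.DataFrame  # genes x cell types, rows sum to 1
    E: pd.DataFrame   # genes x cell types, mean normalized expression


@dataclass
class CellTypeGeneSets:
    """Per-cell-type specific gene lists (Sg-ordered) with provenance."""

    sets: Mapping[str, pd.DataFrame]  # cell type -> DataFrame(gene_id, Sg)
    fraction: float
    n_retained: int
    excluded_regions: list = field(default_factory=list)

    def gene_ids(self, cell_type: str) -> list[str]:
        return list(self.sets[cell_type]["gene_id"])

    def shared_genes(self, a: str, b: str) -> list[str]:
        return sorted(set(self.gene_ids(a)) & set(self.gene_ids(b)))


def filter_expressed_genes(
    expr: ExpressionMatrix, min_fraction: float = 0.01
) -> list[str]:
    """Genes detected in strictly more than ``min_fraction`` of the cells of
    at least one cell type.

    The inequality is strict: a gene detected in exactly 1% of every type's
    cells is dropped.
    """
    if not 0 < min_fraction < 1:
        raise ValueError(f"min_fraction must be in (0,1), got {min_fraction}")
    counts = expr.counts
    detected = (counts > 0)
    if sp.issparse(detected):
        detected = np.asarray(detected.todense())
    keep = np.zeros(len(expr.gene_ids), dtype=bool)
    for ct in expr.type_names:
        mask = expr.cell_types == ct
        n_ct = int(mask.sum())
        if n_ct == 0:
            raise ValueError(f"cell type {ct!r} has zero cells")
        frac = detected[mask].sum(axis=0) / n_ct
        keep |= np.asarray(frac).ravel() > min_fraction
    return [g for g, k in zip(expr.gene_ids, keep) if k]


def compute_specificity(
    expr: ExpressionMatrix,
    retained: Sequence[str],
    normalization: str = "cp10k",
) -> SpecificityTable:
    """Compute E_ij and Sg_ij over the retained genes.

    ``normalization`` is ``"cp10k"`` (counts scaled per cell to 10,000 before
    averaging; the default, which removes sequencing-depth differences between
    cell types) or ``"raw"`` (plain mean counts). Genes with zero mean in
    every type cannot be normalised and are excluded with a warning.
    """
    retained = list(retained)
    if not retained:
        raise ValueError("retained gene list is empty")
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in retained if g not in idx]
    if missing:
        raise KeyError(f"retained genes not in matrix: {missing[:5]}")
    cols = np.array([idx[g] for g in retained])

    X = expr.dense_counts()
    if normalization == "cp10k":
        lib = X.sum(axis=1, keepdims=True)
        lib[lib == 0] = 1.0
        X = X / lib * 1e4
    elif normalization != "raw":
        raise ValueError(f"unknown normalization {normalization!r}")
    X = X[:, cols]

    types = expr.type_names
    E = np.vstack([X[expr.cell_types == ct].mean(axis=0) for ct in types]).T
    total = E.sum(axis=1)
    zero = total == 0
    if zero.any():
        dropped = [g for g, z in zip(retained, zero) if z]
        logger.warning(
            "excluding %d gene(s) with zero expression in all types: %s",
            len(dropped), dropped[:5],
        )
        E = E[~zero]
        retained = [g for g, z in zip(retained, zero) if not z]
        total = total[~zero]
    Sg = E / total[:, None]
    return SpecificityTable(
        Sg=pd.DataFrame(Sg, index=retained, columns=types),
        E=pd.DataFrame(E, index=retained, columns=types),
    )


def exclude_region(
    annotation: GeneAnnotation,
    region: tuple[str, int, int] = APOE_REGION,
) -> GeneAnnotation:
    """Drop genes overlapping ``region`` (chrom, start, end; 1-based
    inclusive) by one or more base pairs."""
    chrom, start, end = region
    if start > end:
        raise ValueError("malformed region: start > end")
    chrom = normalize_chrom(chrom)
    t = annotation.table
    overlap = (t["chrom"] == chrom) & (t["start"] <= end) & (t["end"] >= start)
    n = int(overlap.sum())
    if n:
        logger.info("excluded %d gene(s) overlapping %s:%d-%d", n, chrom, start, end)
    return GeneAnnotation(t.loc[~overlap])


def select_top_decile(
    spec: SpecificityTable,
    fraction: float = 0.10,
    excluded_regions: list | None = None,
) -> CellTypeGeneSets:
    """Per cell type, the floor(fraction * N_retained) genes with the largest
    Sg. Ties at the boundary break by ascending gene ID, so the selection is
    deterministic across platforms."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0,1], got {fraction}")
    n_retained = spec.Sg.shape[0]
    k = floor(fraction * n_retained)
    if k == 0:
        raise ValueError(
            f"floor({fraction} x {n_retained}) = 0 genes; provide a larger "
            "retained gene list or fraction"
        )
    sets = {}
    for ct in spec.Sg.columns:
        ordered = spec.Sg[ct].reset_index().rename(columns={"index": "gene_id", ct: "Sg"})
        ordered = ordered.sort_values(
            ["Sg", "gene_id"], ascending=[False, True], kind="mergesort"
        ).head(k)
        sets[ct] = ordered.reset_index(drop=True)
    return CellTypeGeneSets(
        sets=sets,
        fraction=fraction,
        n_retained=n_retained,
        excluded_regions=list(excluded_regions or []),
    )


def build_gene_sets(
    expr: ExpressionMatrix,
    annotation: GeneAnnotation,
    min_fraction: float = 0.01,
    fraction: float = 0.10,
    region: tuple[str, int, int] = APOE_REGION,
    normalization: str = "cp10k",
) -> tuple[CellTypeGeneSets, SpecificityTable]:
    """Full pipeline: expressed-gene filter -> region exclusion -> Sg ->
    top-fraction sets. Region exclusion runs before the specificity ranking,
    so excluded genes never enter the per-type rank pool."""
    expressed = filter_expressed_genes(expr, min_fraction=min_fraction)
    ann = exclude_region(annotation.subset(expressed), region)
    retained = [g for g in expressed if g in set(ann.table["gene_id"])]
    spec = compute_specificity(expr, retained, normalization=normalization)
    sets = select_top_decile(spec, fraction=fraction, excluded_regions=[region])
    return sets, spec
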