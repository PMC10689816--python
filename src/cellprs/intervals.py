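"""Variant-to-gene-set assignment via margined genomic intervals.

Each cell-type gene set is expanded into a set of merged genomic windows
(gene body plus a fixed margin up- and downstream, default 30 kb) and a
variant belongs to a cell type's score iff its position falls inside one of
that type's windows. Bounds are inclusive on both ends: a variant exactly at
``start - margin`` or ``end + margin`` is a member. Variants inside the
excluded APOE region are ineligible for every score, including the
all-autosome one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .specificity import APOE_REGION, GeneAnnotation, normalize_chrom

logger = logging.getLogger(__name__)


@dataclass
class IntervalSet:
    """Merged, sorted 1-based inclusive intervals per chromosome."""

    intervals: Mapping[str, np.ndarray]  # chrom -> (m, 2) array [start, end]
    margin_bp: int
    source: str = ""

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorised membership by binary search."""
        chrom = normalize_chrom(chrom)
        pos = np.asarray(pos)
        ivs = self.intervals.get(chrom)
        if ivs is None or len(ivs) == 0:
            return np.zeros(pos.shape, dtype=bool)
        starts, ends = ivs[:, 0], ivs[:, 1]
        i = np.searchsorted(starts, pos, side="right") - 1
        ok = i >= 0
        member = np.zeros(pos.shape, dtype=bool)
        member[ok] = pos[ok] <= ends[i[ok]]
        return member

    def total_bp(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0] + 1).sum() for iv in self.intervals.values()))


def merge_intervals(raw: np.ndarray) -> np.ndarray:
    """Merge overlapping or touching 1-based inclusive intervals."""
    if len(raw) == 0:
        return raw.reshape(0, 2)
    order = np.lexsort((raw[:, 1], raw[:, 0]))
    raw = raw[order]
    merged = [raw[0].tolist()]
    for s, e in raw[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def build_intervals(
    genes: GeneAnnotation, margin_bp: int = 30_000, source: str = ""
) -> IntervalSet:
    """Expand each gene to [max(1, start - margin), end + margin] and merge
    per chromosome."""
    if margin_bp < 0:
        raise ValueError(f"margin_bp must be >= 0, got {margin_bp}")
    out: dict[str, np.ndarray] = {}
    t = genes.table
    for chrom, sub in t.groupby("chrom", sort=True):
        raw = np.column_stack([
            np.maximum(1, sub["start"].to_numpy(np.int64) - margin_bp),
            sub["end"].to_numpy(np.int64) + margin_bp,
        ])
        out[str(chrom)] = merge_intervals(raw)
    return IntervalSet(intervals=out, margin_bp=margin_bp, source=source)


@dataclass
class VariantMembership:
    """Boolean membership per variant per cell type plus eligibility flags.

    ``table`` is indexed by variant ID with one boolean column per cell type,
    an ``All`` column (eligible for the all-autosome score: every variant not
    excluded by region), and the variant metadata columns CHR/BP.
    """

    table: pd.DataFrame
    margin_bp: int

    def members(self, partition: str) -> list[str]:
        return list(self.table.index[self.table[partition]])

    def counts(self) -> dict[str, int]:
        cols = [c for c in self.table.columns if c not in ("CHR", "BP")]
        return {c: int(self.table[c].sum()) for c in cols}


def assign_variants(
    variant_meta: pd.DataFrame,
    interval_sets: Mapping[str, IntervalSet],
    apoe_region: tuple[str, int, int] = APOE_REGION,
) -> VariantMembership:
    """Assign variants (DataFrame with SNP, CHR, BP columns) to each cell
    type's interval set; flag APOE-region variants as ineligible for all
    scores."""
    vm = variant_meta.reset_index(drop=True).copy()
    required = {"SNP", "CHR", "BP"}
    if not required.issubset(vm.columns):
        raise ValueError(f"variant metadata needs columns {sorted(required)}")
    vm["CHR"] = vm["CHR"].map(normalize_chrom)
    chrom_r, start_r, end_r = apoe_region
    chrom_r = normalize_chrom(chrom_r)
    excluded = (
        (vm["CHR"] == chrom_r)
        & (vm["BP"] >= start_r)
        & (vm["BP"] <= end_r)
    ).to_numpy()

    margins = {s.margin_bp for s in interval_sets.values()}
    margin_bp = margins.pop() if len(margins) == 1 else -1

    out = pd.DataFrame(index=pd.Index(vm["SNP"], name="SNP"))
    out["CHR"] = vm["CHR"].to_numpy()
    out["BP"] = vm["BP"].to_numpy()
    known_chroms = set().union(*(set(s.intervals) for s in interval_sets.values()))
    n_unmatched = int((~vm["CHR"].isin(known_chroms)).sum())
    if n_unmatched:
        logger.info("%d variant(s) on chromosomes absent from all interval sets", n_unmatched)
    for name, iset in interval_sets.items():
        member = np.zeros(len(vm), dtype=bool)
        for chrom, sub in vm.groupby("CHR", sort=False):
            member[sub.index.to_numpy()] = iset.contains(
                chrom, sub["BP"].to_numpy()
            )
        out[name] = member & ~excluded
    out["All"] = ~excluded
    return VariantMembership(table=out, margin_bp=margin_bp)
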