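"""Partitioned polygenic score computation.

A score for individual *i* over a variant partition *P* is the plain weighted
sum  score_i = Σ_{v in P} β_v d_iv  of integer allele dosages d ∈ {0, 1, 2}
counted on each variant's recorded allele, with β the posterior effect
weights oriented to the same allele. Scores are standardised (sample SD,
n − 1) before any downstream model, which makes the plain sum equivalent to
per-allele averaging for complete data.

Allele reconciliation: if the genotype's counted allele is the weight table's
other allele (A2), the dosage is reflected (d → 2 − d). Palindromic (A/T,
C/G) variants are dropped under strict mode, mirroring the usual pre-
imputation exclusion; mismatching allele pairs are always dropped, with a
logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import VariantMembership

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

WEIGHT_COLUMNS = ["CHR", "SNP", "BP", "A1", "A2", "BETA"]


def is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(str(a1).upper()) == str(a2).upper()


@dataclass
class AlignedWeights:
    """Per-variant weights oriented to the genotype's counted allele.

    ``sign`` is +1 where the counted allele equals A1 and −1 where it equals
    A2 (the weight applies to the reflected dosage 2 − d; the constant offset
    2β is tracked in ``offset`` so raw scores stay exact).
    """

    snp_ids: np.ndarray
    beta: np.ndarray
    sign: np.ndarray
    n_dropped_mismatch: int = 0
    n_dropped_palindromic: int = 0

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def offset(self) -> np.ndarray:
        return np.where(self.sign < 0, 2.0 * self.beta, 0.0)

    @property
    def effective_beta(self) -> np.ndarray:
        return self.sign * self.beta


def reconcile_alleles(
    weights: pd.DataFrame,
    geno_meta: pd.DataFrame,
    strict_palindromic: bool = True,
) -> AlignedWeights:
    """Orient weight-table betas to the genotype's counted allele.

    ``weights`` has columns CHR, SNP, BP, A1, A2, BETA (A1 = effect allele);
    ``geno_meta`` has columns SNP, counted_allele, other_allele.
    """
    w = weights.set_index("SNP")
    g = geno_meta.set_index("SNP")
    shared = g.index.intersection(w.index)
    if len(shared) == 0:
        raise ValueError("no overlapping variants between weights and genotypes")
    w = w.loc[shared]
    g = g.loc[shared]

    a1 = w["A1"].str.upper().to_numpy()
    a2 = w["A2"].str.upper().to_numpy()
    counted = g["counted_allele"].str.upper().to_numpy()
    other = g["other_allele"].str.upper().to_numpy()

    direct = (counted == a1) & (other == a2)
    flipped = (counted == a2) & (other == a1)
    palin = np.array([is_palindromic(x, y) for x, y in zip(a1, a2)])

    keep = direct | flipped
    n_mismatch = int((~keep).sum())
    if n_mismatch:
        logger.info("dropped %d variant(s) with mismatching allele pairs", n_mismatch)
    n_palin = 0
    if strict_palindromic:
        n_palin = int((keep & palin).sum())
        if n_palin:
            logger.info("dropped %d palindromic variant(s) (strict mode)", n_palin)
        keep &= ~palin
    if not keep.any():
        raise ValueError("no variants left after allele reconciliation")

    sign = np.where(flipped, -1.0, 1.0)[keep]
    return AlignedWeights(
        snp_ids=np.asarray(shared, dtype=object)[keep],
        beta=w["BETA"].to_numpy(float)[keep],
        sign=sign,
        n_dropped_mismatch=n_mismatch,
        n_dropped_palindromic=n_palin,
    )


@dataclass
class GenotypeMatrix:
    """Individuals x variants integer dosages in {0, 1, 2}."""

    dosages: np.ndarray
    individual_ids: np.ndarray
    variant_meta: pd.DataFrame  # SNP, CHR, BP, counted_allele, other_allele

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        d = self.dosages
        if not np.isin(d, (0, 1, 2)).all():
            raise ValueError("dosages must be integers in {0, 1, 2}")
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual IDs")
        if self.variant_meta["SNP"].duplicated().any():
            raise ValueError("duplicate variant IDs")
        if d.shape != (len(self.individual_ids), len(self.variant_meta)):
            raise ValueError("dosage shape does not match IDs/metadata")


def compute_score(
    geno: GenotypeMatrix,
    aligned: AlignedWeights,
    membership: VariantMembership | None = None,
    partition: str | None = None,
    mode: str = "sum",
) -> np.ndarray:
    """Raw partition score: Σ β_v d_iv over the partition's member variants.

    Summation runs in sorted-variant-ID order so the floating-point result is
    independent of input ordering. With ``membership``/``partition`` omitted,
    all aligned variants are used.
    """
    snp_order = {s: j for j, s in enumerate(geno.variant_meta["SNP"])}
    in_geno = np.array([s in snp_order for s in aligned.snp_ids])
    snps = aligned.snp_ids[in_geno]
    beta = aligned.effective_beta[in_geno]
    offset = aligned.offset[in_geno]

    if membership is not None:
        if partition is None:
            raise ValueError("partition name required with membership")
        if partition not in membership.table.columns:
            raise KeyError(f"unknown partition {partition!r}")
        member_ids = set(membership.members(partition))
        sel = np.array([s in member_ids for s in snps])
        if not sel.any():
            raise ValueError(f"partition {partition!r} has no member variants")
        snps, beta, offset = snps[sel], beta[sel], offset[sel]

    order = np.argsort(snps.astype(str), kind="mergesort")
    snps, beta, offset = snps[order], beta[order], offset[order]
    cols = np.array([snp_order[s] for s in snps])
    D = geno.dosages[:, cols].astype(float)
    score = D @ beta + offset.sum()
    if mode == "average":
        # mean per allele: divide by 2 x number of scored variants; with
        # complete dosages this is an affine rescaling of the plain sum
        score = score / (2.0 * len(cols))
    elif mode != "sum":
        raise ValueError(f"unknown scoring mode {mode!r}")
    return score


def standardize(raw: np.ndarray) -> np.ndarray:
    """(x − mean) / SD with the n − 1 sample SD."""
    raw = np.asarray(raw, dtype=float)
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance score vector (degenerate partition)")
    return (raw - raw.mean()) / sd


@dataclass
class ScoreTable:
    """Raw and standardised per-individual scores per partition."""

    raw: pd.DataFrame
    standardized: pd.DataFrame
    variant_counts: Mapping[str, int] = field(default_factory=dict)
    margin_bp: int | None = None


def score_partitions(
    geno: GenotypeMatrix,
    aligned: AlignedWeights,
    membership: VariantMembership,
    partitions: Sequence[str] | None = None,
    strict: bool = True,
) -> ScoreTable:
    """Compute and standardise scores for every partition (cell types plus
    the all-autosome ``All`` column).

    With ``strict=False``, partitions that are empty or degenerate (zero
    score variance) are skipped with a log message instead of raising.
    """
    if partitions is None:
        partitions = [
            c for c in membership.table.columns if c not in ("CHR", "BP")
        ]
    raw = {}
    for p in partitions:
        try:
            col = compute_score(geno, aligned, membership, p)
            if np.asarray(col).std(ddof=1) == 0:
                raise ValueError(f"partition {p!r} yields a constant score")
            raw[p] = col
        except ValueError:
            if strict:
                raise
            logger.warning("skipping degenerate partition %r", p)
    raw_df = pd.DataFrame(raw, index=geno.individual_ids)
    std_df = raw_df.apply(lambda c: standardize(c.to_numpy()), axis=0)
    counts = {p: len(set(membership.members(p)) & set(aligned.snp_ids)) for p in partitions}
    return ScoreTable(
        raw=raw_df,
        standardized=std_df,
        variant_counts=counts,
        margin_bp=membership.margin_bp,
    )


def score_correlation(scores: pd.DataFrame) -> pd.DataFrame:
    """J x J matrix of squared Pearson correlations between score columns."""
    if scores.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    sds = scores.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant score column(s): {constant}")
    r = np.corrcoef(scores.to_numpy().T)
    return pd.DataFrame(r**2, index=scores.columns, columns=scores.columns)
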