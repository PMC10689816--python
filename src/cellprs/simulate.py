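"""Synthetic study generator with known ground truth.

Emulates the statistical structure the analysis assumes — not the biology:

* a cells x genes negative-binomial count matrix over six cortical cell
  types (Ex, In, Ast, Mic, Oli, Opc) with lognormal library-size variation
  and planted marker genes whose mean is multiplied by ``fold_change`` in
  their home type;
* a gene annotation with non-overlapping GRCh38-style coordinates across
  several chromosomes, guaranteed to place at least one gene inside the
  excluded APOE-like region on chr19;
* independent Hardy–Weinberg genotypes (integer dosages 0/1/2) at MAFs drawn
  uniformly from ``maf_range``, with positions uniform over the annotation's
  chromosomes and non-palindromic allele pairs (A1 is always the counted
  effect allele);
* a sparse Gaussian variant-weight table whose variance is inflated inside
  designated causal cell-type gene windows;
* phenotypes from the causal chain DP → NP → NFT → cognitive decline driven
  by the astrocyte and microglia scores, plus covariates (age, sex,
  education, ε4/ε2 dosages, batch, three PCs) and Gaussian noise, and a
  Bernoulli dementia outcome from a logistic model.

Every generator is a pure function of the configuration: a fixed seed gives
byte-identical outputs. Per-stage RNG streams are derived from the single
seed, so stages can be rerun independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalSet, build_intervals
from .specificity import ExpressionMatrix, GeneAnnotation


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


CELL_TYPES = ("Ex", "In", "Ast", "Mic", "Oli", "Opc")

#: Standardized causal edges. Score -> pathology edges echo the relative
#: pattern of the astrocyte/microglia partitioned-score effects; the
#: pathology chain follows DP -> NP -> NFT -> CogDec.
DEFAULT_PATH_COEFFICIENTS: dict[str, float] = {
    "AstScore->DP": 0.15,
    "AstScore->NP": 0.10,
    "MicScore->NP": 0.10,
    "DP->NP": 0.55,
    "NP->NFT": 0.50,
    "MicScore->NFT": 0.15,
    "NFT->CogDec": -0.40,
    "NP->CogDec": -0.10,
    "MicScore->CogDec": -0.10,
    "DP->Abeta": 0.45,
    "NP->Abeta": 0.40,
    "NFT->PHFtau": 0.70,
}

REQUIRED_EDGES = (
    "AstScore->DP", "AstScore->NP", "MicScore->NP", "DP->NP", "NP->NFT",
    "MicScore->NFT", "NFT->CogDec", "NP->CogDec", "MicScore->CogDec",
)

#: Residual SDs chosen so each endophenotype has roughly unit marginal
#: variance under the default path coefficients.
DEFAULT_NOISE_SD: dict[str, float] = {
    "DP": 0.989, "NP": 0.81, "NFT": 0.853, "CogDec": 0.906,
    "Abeta": 0.80, "PHFtau": 0.71,
}

DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, float]] = {
    "DP": {"age": 0.10, "e4": 0.30, "e2": -0.15},
    "NP": {"age": 0.10, "e4": 0.30, "e2": -0.15},
    "NFT": {"age": 0.12, "e4": 0.25, "e2": -0.10},
    # the cognitive-decline slope is emitted already adjusted for age, sex
    # and education, so only the allele-dosage covariates act on it
    "CogDec": {"e4": -0.15, "e2": 0.08},
    "Abeta": {"age": 0.10, "e4": 0.35, "e2": -0.15},
    "PHFtau": {"age": 0.10, "e4": 0.20},
    "dementia": {"age": 0.30, "e4": 0.50, "sex": 0.10},
}

DEFAULT_DEMENTIA_COEFFICIENTS: dict[str, float] = {
    "intercept": -0.9, "NP": 0.6, "NFT": 0.8, "CogDec": -0.9,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    cell_types: Sequence[str] = CELL_TYPES
    n_cells_per_type: Mapping[str, int] = field(
        default_factory=lambda: {
            "Ex": 180, "In": 70, "Ast": 60, "Mic": 40, "Oli": 100, "Opc": 30,
        }
    )
    n_genes: int = 2000
    n_specific_per_type: int = 25
    fold_change: float = 20.0
    dispersion: float = 0.5
    library_size_sd: float = 0.3
    chromosomes: Sequence[str] = ("chr1", "chr2", "chr3", "chr19")
    n_individuals: int = 1457
    n_variants: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    weight_sparsity: float = 0.2
    weight_scale: float = 0.01
    causal_cell_types: Sequence[str] = ("Ast", "Mic")
    causal_inflation: float = 5.0
    ld_block_correlation: float = 0.0   # optional exchangeable within-window LD
    ld_block_size: int = 10
    path_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATH_COEFFICIENTS)
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD)
    )
    covariate_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()}
    )
    dementia_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEMENTIA_COEFFICIENTS)
    )

    def __post_init__(self) -> None:
        if len(self.cell_types) < 2:
            raise ConfigError("cell_types: need at least 2 cell types")
        missing = [t for t in self.cell_types if t not in self.n_cells_per_type]
        if missing:
            raise ConfigError(f"n_cells_per_type: missing counts for {missing}")
        if any(self.n_cells_per_type[t] < 1 for t in self.cell_types):
            raise ConfigError("n_cells_per_type: every type needs >= 1 cell")
        if self.n_genes < 1:
            raise ConfigError(f"n_genes: must be >= 1, got {self.n_genes}")
        if self.n_specific_per_type * len(self.cell_types) > self.n_genes:
            raise ConfigError(
                "n_specific_per_type: n_specific_per_type x n_types exceeds n_genes"
            )
        if self.fold_change <= 0:
            raise ConfigError(f"fold_change: must be positive, got {self.fold_change}")
        if self.dispersion <= 0:
            raise ConfigError(f"dispersion: must be positive, got {self.dispersion}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range: must lie within (0, 0.5], got {self.maf_range}")
        if not 0 <= self.weight_sparsity <= 1:
            raise ConfigError(f"weight_sparsity: must be in [0, 1], got {self.weight_sparsity}")
        if self.n_individuals < 1 or self.n_variants < 1:
            raise ConfigError("n_individuals/n_variants: must be >= 1")
        for pheno, sd in self.noise_sd.items():
            if sd < 0:
                raise ConfigError(f"noise_sd: negative SD for {pheno}")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class GroundTruth:
    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    true_variant_effects: pd.Series | None = None
    true_path_coefficients: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------- expression

def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GeneAnnotation, GroundTruth]:
    rng = config.rng(1)
    types = list(config.cell_types)
    n_genes = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)], dtype=object)

    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes) * 0.1
    fold = np.ones((len(types), n_genes))
    markers: dict[str, list[str]] = {}
    k = config.n_specific_per_type
    for t_idx, ct in enumerate(types):
        cols = slice(t_idx * k, (t_idx + 1) * k)
        fold[t_idx, cols] = config.fold_change
        markers[ct] = list(gene_ids[cols])

    blocks, labels = [], []
    size = 1.0 / config.dispersion  # NB: var = mu + dispersion * mu^2
    for t_idx, ct in enumerate(types):
        n_c = config.n_cells_per_type[ct]
        lib = rng.lognormal(mean=0.0, sigma=config.library_size_sd, size=n_c)
        mu = lib[:, None] * (base_mean * fold[t_idx])[None, :]
        lam = rng.gamma(shape=size, scale=mu / size)
        blocks.append(rng.poisson(lam))
        labels.extend([ct] * n_c)
    counts = np.vstack(blocks)

    annotation = _generate_annotation(gene_ids, config, rng)
    gt = GroundTruth(marker_genes=markers)
    expr = ExpressionMatrix(counts=counts, gene_ids=gene_ids,
                            cell_types=np.array(labels, dtype=object))
    return expr, annotation, gt


def _generate_annotation(
    gene_ids: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> GeneAnnotation:
    """Non-overlapping gene intervals, round-robin over chromosomes.

    chr19 placement starts just upstream of the APOE-like excluded region and
    the first chr19 gene is pinned inside it, so the region always contains
    at least one gene.
    """
    chroms = list(config.chromosomes)
    cursor = {c: 1_000_000 for c in chroms}
    if "chr19" in cursor:
        cursor["chr19"] = 43_000_000
    rows = []
    first_chr19 = True
    for i, g in enumerate(gene_ids):
        chrom = chroms[i % len(chroms)]
        length = int(rng.integers(2_000, 20_000))
        gap = int(rng.integers(5_000, 60_000))
        if chrom == "chr19" and first_chr19:
            start = 44_000_000  # inside the APOE-like region
            first_chr19 = False
            cursor[chrom] = max(cursor[chrom], start + length + gap)
        else:
            start = cursor[chrom] + gap
            cursor[chrom] = start + length + gap
        rows.append({"gene_id": g, "chrom": chrom, "start": start,
                     "end": start + length - 1})
    return GeneAnnotation(pd.DataFrame(rows))


# ----------------------------------------------------------------- genotypes

def generate_genotypes(
    config: SimulationConfig,
    annotation: GeneAnnotation | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Dosage matrix (individuals x variants) and variant metadata.

    Variants are independent by default; ``ld_block_correlation > 0``
    switches on an exchangeable-correlation block mode (for robustness
    experiments only) via a shared latent Gaussian per block.
    """
    rng = config.rng(2)
    n, m = config.n_individuals, config.n_variants
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)

    if annotation is not None and len(annotation.table):
        extents = annotation.table.groupby("chrom")["end"].max().to_dict()
        chrom_names = sorted(extents)
        chrom_lo = annotation.table.groupby("chrom")["start"].min().to_dict()
    else:
        chrom_names = list(config.chromosomes)
        extents = {c: 10_000_000 for c in chrom_names}
        chrom_lo = {c: 1 for c in chrom_names}
    chrom = rng.choice(chrom_names, size=m)
    pos = np.array([
        int(rng.integers(max(1, chrom_lo[c] - 50_000), extents[c] + 50_000))
        for c in chrom
    ])

    rho = config.ld_block_correlation
    if rho > 0:
        z_shared = rng.standard_normal((n, (m + config.ld_block_size - 1) // config.ld_block_size))
        z_own = rng.standard_normal((n, m, 2))
        dosage = np.empty((n, m), dtype=np.int64)
        from scipy.stats import norm
        for j in range(m):
            blk = j // config.ld_block_size
            for a in range(2):
                z = np.sqrt(rho) * z_shared[:, blk] + np.sqrt(1 - rho) * z_own[:, j, a]
                allele = (norm.cdf(z) < maf[j]).astype(np.int64)
                if a == 0:
                    dosage[:, j] = allele
                else:
                    dosage[:, j] += allele
    else:
        dosage = rng.binomial(2, maf[None, :], size=(n, m))

    pairs = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
             ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
    pick = rng.integers(0, len(pairs), size=m)
    a1 = np.array([pairs[p][0] for p in pick], dtype=object)
    a2 = np.array([pairs[p][1] for p in pick], dtype=object)

    meta = pd.DataFrame({
        "SNP": [f"v{j:06d}" for j in range(m)],
        "CHR": chrom,
        "BP": pos,
        "counted_allele": a1,
        "other_allele": a2,
        "MAF": maf,
    })
    return dosage, meta


# ------------------------------------------------------------------- weights

def generate_weights(
    variant_meta: pd.DataFrame,
    causal_intervals: Mapping[str, IntervalSet] | None,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Sparse Gaussian posterior-style weight table (CHR SNP BP A1 A2 BETA).

    A fraction ``weight_sparsity`` of variants get nonzero N(0, scale²)
    weights; variants inside any causal cell type's interval set have their
    weight SD multiplied by ``causal_inflation``. A1 is the effect allele and
    matches the genotype's counted allele.
    """
    if len(variant_meta) == 0:
        raise ValueError("empty variant set")
    variant_meta = variant_meta.reset_index(drop=True)
    rng = config.rng(3)
    m = len(variant_meta)
    nonzero = rng.random(m) < config.weight_sparsity
    beta = np.zeros(m)
    beta[nonzero] = rng.normal(0.0, config.weight_scale, size=int(nonzero.sum()))

    if causal_intervals:
        in_causal = np.zeros(m, dtype=bool)
        for iset in causal_intervals.values():
            for chrom, sub in variant_meta.groupby("CHR"):
                mask = iset.contains(chrom, sub["BP"].to_numpy())
                in_causal[sub.index.to_numpy()] |= mask
        beta[in_causal & nonzero] *= config.causal_inflation

    return pd.DataFrame({
        "CHR": variant_meta["CHR"].to_numpy(),
        "SNP": variant_meta["SNP"].to_numpy(),
        "BP": variant_meta["BP"].to_numpy(),
        "A1": variant_meta["counted_allele"].to_numpy(),
        "A2": variant_meta["other_allele"].to_numpy(),
        "BETA": beta,
    })


# ---------------------------------------------------------------- phenotypes

def _parse_edge(edge: str) -> tuple[str, str]:
    src, dst = edge.split("->")
    return src.strip(), dst.strip()


def generate_phenotypes(
    scores: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Phenotype/covariate table from standardised Ast/Mic score inputs.

    ``scores`` must have standardised ``AstScore`` and ``MicScore`` columns.
    Endophenotypes follow the configured causal chain; ``dementia`` is
    Bernoulli with a logistic linear predictor; covariates are stored
    alongside.
    """
    missing = [e for e in REQUIRED_EDGES if e not in config.path_coefficients]
    if missing:
        raise ConfigError(f"path_coefficients: missing required edge(s) {missing}")
    for col in ("AstScore", "MicScore"):
        if col not in scores.columns:
            raise ValueError(f"scores must contain column {col!r}")

    rng = config.rng(4)
    n = len(scores)
    cov = pd.DataFrame(index=scores.index)
    cov["age"] = rng.normal(85.0, 6.0, size=n)
    cov["sex"] = rng.binomial(1, 0.5, size=n)
    cov["education"] = rng.normal(16.0, 3.0, size=n)
    cov["e4"] = rng.binomial(2, 0.15, size=n)
    cov["e2"] = rng.binomial(2, 0.08, size=n)
    cov["batch"] = rng.integers(0, 3, size=n)
    for k in (1, 2, 3):
        cov[f"PC{k}"] = rng.normal(0.0, 1.0, size=n)

    # standardized versions used when applying covariate effects
    cov_std = {
        "age": (cov["age"] - 85.0) / 6.0,
        "sex": cov["sex"].astype(float),
        "education": (cov["education"] - 16.0) / 3.0,
        "e4": cov["e4"].astype(float),
        "e2": cov["e2"].astype(float),
        "batch": cov["batch"].astype(float),
        "PC1": cov["PC1"], "PC2": cov["PC2"], "PC3": cov["PC3"],
    }

    coeffs: dict[tuple[str, str], float] = {
        _parse_edge(e): v for e, v in config.path_coefficients.items()
    }
    values: dict[str, np.ndarray] = {
        "AstScore": scores["AstScore"].to_numpy(float),
        "MicScore": scores["MicScore"].to_numpy(float),
    }

    def build(pheno: str) -> np.ndarray:
        lin = np.zeros(n)
        for (src, dst), beta in coeffs.items():
            if dst == pheno:
                lin = lin + beta * values[src]
        for covname, beta in config.covariate_effects.get(pheno, {}).items():
            lin = lin + beta * cov_std[covname].to_numpy(float)
        sd = config.noise_sd.get(pheno, 1.0)
        if sd > 0:
            lin = lin + rng.normal(0.0, sd, size=n)
        return lin

    for pheno in ("DP", "NP", "NFT", "CogDec", "Abeta", "PHFtau"):
        values[pheno] = build(pheno)

    dem = config.dementia_coefficients
    eta = np.full(n, float(dem.get("intercept", 0.0)))
    for name, beta in dem.items():
        if name == "intercept":
            continue
        eta = eta + beta * values[name]
    for covname, beta in config.covariate_effects.get("dementia", {}).items():
        eta = eta + beta * cov_std[covname].to_numpy(float)
    p_dem = 1.0 / (1.0 + np.exp(-eta))
    dementia = rng.binomial(1, p_dem)

    pheno = pd.DataFrame({
        "Abeta": values["Abeta"], "DP": values["DP"], "NP": values["NP"],
        "PHFtau": values["PHFtau"], "NFT": values["NFT"],
        "CogDec": values["CogDec"], "dementia": dementia,
    }, index=scores.index)
    table = pd.concat([pheno, cov], axis=1)
    gt = GroundTruth(true_path_coefficients=dict(config.path_coefficients))
    return table, gt


# ------------------------------------------------------------- full study

@dataclass
class SyntheticStudy:
    """Everything the analysis consumes, plus the generating ground truth."""

    expression: ExpressionMatrix
    annotation: GeneAnnotation
    gene_sets: object            # CellTypeGeneSets
    specificity: object          # SpecificityTable
    genotypes: object            # GenotypeMatrix
    weights: pd.DataFrame
    membership: object           # VariantMembership
    scores: object               # ScoreTable
    phenotypes: pd.DataFrame
    truth: GroundTruth


def simulate_study(
    config: SimulationConfig,
    margin_bp: int = 30_000,
    fraction: float = 0.10,
) -> SyntheticStudy:
    """Generate a complete synthetic study.

    The data-generating process reuses the analysis primitives: the planted
    causal cell types' gene windows receive inflated variant weights, the
    resulting standardised Ast/Mic partition scores drive the phenotype
    causal chain, and the full input bundle (expression, annotation,
    genotypes, weight table, phenotypes) is returned for the pipeline to
    re-analyse from scratch.
    """
    from .scoring import GenotypeMatrix, reconcile_alleles, score_partitions
    from .specificity import build_gene_sets

    expr, ann, truth = generate_expression(config)
    gene_sets, spec_table = build_gene_sets(expr, ann, fraction=fraction)
    dosages, meta = generate_genotypes(config, ann)

    causal = {
        ct: build_intervals(ann.subset(gene_sets.gene_ids(ct)), margin_bp, source=ct)
        for ct in config.causal_cell_types
        if ct in gene_sets.sets
    }
    weights = generate_weights(meta, causal, config)
    truth.true_variant_effects = pd.Series(
        weights["BETA"].to_numpy(), index=weights["SNP"].to_numpy()
    )

    geno = GenotypeMatrix(
        dosages=dosages,
        individual_ids=np.array(
            [f"I{i:05d}" for i in range(config.n_individuals)], dtype=object
        ),
        variant_meta=meta,
    )
    aligned = reconcile_alleles(
        weights, meta[["SNP", "counted_allele", "other_allele"]]
    )
    interval_sets = {
        ct: build_intervals(ann.subset(gene_sets.gene_ids(ct)), margin_bp, source=ct)
        for ct in gene_sets.sets
    }
    from .intervals import assign_variants

    membership = assign_variants(meta, interval_sets)
    scores = score_partitions(geno, aligned, membership, strict=False)

    score_inputs = pd.DataFrame(index=scores.standardized.index)
    for ct, name in (("Ast", "AstScore"), ("Mic", "MicScore")):
        if ct not in scores.standardized.columns:
            raise ConfigError(
                f"causal_cell_types: partition {ct!r} produced no usable score"
            )
        score_inputs[name] = scores.standardized[ct]
    phenotypes, truth2 = generate_phenotypes(score_inputs, config)
    truth.true_path_coefficients = truth2.true_path_coefficients

    return SyntheticStudy(
        expression=expr,
        annotation=ann,
        gene_sets=gene_sets,
        specificity=spec_table,
        genotypes=geno,
        weights=weights,
        membership=membership,
        scores=scores,
        phenotypes=phenotypes,
        truth=truth,
    )
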