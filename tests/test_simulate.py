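"""Generator determinism, planted structure and moment checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from cellprs.intervals import build_intervals
from cellprs.simulate import (
    ConfigError,
    SimulationConfig,
    generate_expression,
    generate_genotypes,
    generate_phenotypes,
    generate_weights,
)
from cellprs.specificity import build_gene_sets, compute_specificity, filter_expressed_genes


def small_config(**kw):
    defaults = dict(seed=7, n_genes=200, n_specific_per_type=10,
                    n_individuals=200, n_variants=400)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value,match", [
        ("fold_change", 0.0, "fold_change"),
        ("maf_range", (0.0, 0.5), "maf_range"),
        ("maf_range", (0.1, 0.6), "maf_range"),
        ("weight_sparsity", 1.5, "weight_sparsity"),
        ("n_specific_per_type", 100, "n_specific_per_type"),
        ("dispersion", -1.0, "dispersion"),
    ])
    def test_invalid_field_named_in_error(self, field, value, match):
        with pytest.raises(ConfigError, match=match):
            small_config(**{field: value})


class TestGenerateExpression:
    def test_seed_determinism(self):
        cfg = SimulationConfig(
            seed=7, cell_types=("A", "B"),
            n_cells_per_type={"A": 50, "B": 50}, n_genes=100,
            n_specific_per_type=5,
        )
        e1, a1, _ = generate_expression(cfg)
        e2, a2, _ = generate_expression(cfg)
        np.testing.assert_array_equal(e1.counts, e2.counts)
        pd.testing.assert_frame_equal(a1.table, a2.table)

    def test_annotation_nonoverlapping_with_apoe_gene(self):
        _, ann, _ = generate_expression(small_config())
        t = ann.table
        assert t["chrom"].nunique() >= 2
        for _, sub in t.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] > sub["end"].to_numpy()[:-1]).all()
        in_region = (
            (t["chrom"] == "chr19")
            & (t["start"] <= 45_909_393) & (t["end"] >= 43_905_781)
        )
        assert in_region.sum() >= 1

    def test_unit_fold_change_markers_indistinguishable(self):
        """With fold_change=1 the 'markers' have the same Sg distribution as
        other genes (KS test on a 2000-gene matrix)."""
        cfg = SimulationConfig(seed=1, n_genes=2000, n_specific_per_type=50,
                               fold_change=1.0)
        expr, ann, gt = generate_expression(cfg)
        retained = filter_expressed_genes(expr)
        spec = compute_specificity(expr, retained)
        max_sg = spec.Sg.max(axis=1)
        markers = {g for genes in gt.marker_genes.values() for g in genes}
        is_marker = max_sg.index.isin(markers)
        stat = kstest(max_sg[is_marker], max_sg[~is_marker])
        assert stat.pvalue > 0.01

    def test_strong_markers_recovered_in_top_decile(self):
        cfg = SimulationConfig(seed=2, n_genes=1000, n_specific_per_type=20,
                               fold_change=50.0)
        expr, ann, gt = generate_expression(cfg)
        sets, _ = build_gene_sets(expr, ann)
        recovered = total = 0
        for ct, markers in gt.marker_genes.items():
            in_set = set(sets.gene_ids(ct))
            # markers lost to the APOE-region exclusion don't count against recovery
            present = [m for m in markers if m in sets_universe(sets)]
            total += len(present)
            recovered += sum(1 for m in present if m in in_set)
        assert total > 0
        assert recovered / total >= 0.90


def sets_universe(sets):
    # genes that survived filtering/exclusion (the selection pool)
    universe = set()
    for df in sets.sets.values():
        universe |= set(df["gene_id"])
    return universe


class TestGenerateGenotypes:
    def test_hardy_weinberg_at_half(self):
        cfg = small_config(n_individuals=10_000, n_variants=50,
                           maf_range=(0.5, 0.5))
        dosage, _ = generate_genotypes(cfg)
        freqs = [(dosage == k).mean() for k in (0, 1, 2)]
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)

    def test_degenerate_maf_gives_zeros(self):
        cfg = small_config(maf_range=(1e-6, 1e-6), n_individuals=100,
                           n_variants=100)
        dosage, _ = generate_genotypes(cfg)
        assert dosage.sum() == 0

    def test_seed_determinism(self):
        cfg = small_config()
        d1, m1 = generate_genotypes(cfg)
        d2, m2 = generate_genotypes(cfg)
        np.testing.assert_array_equal(d1, d2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_dosages_are_valid_and_maf_moments(self):
        cfg = small_config(n_individuals=2000, n_variants=200,
                           maf_range=(0.3, 0.3))
        dosage, meta = generate_genotypes(cfg)
        assert set(np.unique(dosage)) <= {0, 1, 2}
        # mean dosage 2*maf within 4/sqrt(n)
        assert abs(dosage.mean() - 0.6) < 4 / np.sqrt(dosage.size)

    def test_ld_block_mode_correlates_neighbours(self):
        cfg = small_config(n_individuals=3000, n_variants=20,
                           ld_block_correlation=0.8, ld_block_size=10,
                           maf_range=(0.3, 0.3))
        dosage, _ = generate_genotypes(cfg)
        within = np.corrcoef(dosage[:, 0], dosage[:, 1])[0, 1]
        across = np.corrcoef(dosage[:, 0], dosage[:, 15])[0, 1]
        assert within > 0.3
        assert abs(across) < 0.1


class TestGenerateWeights:
    def test_zero_sparsity_gives_null_weights(self):
        cfg = small_config(weight_sparsity=0.0)
        _, meta = generate_genotypes(cfg)
        w = generate_weights(meta, None, cfg)
        assert (w["BETA"] == 0).all()

    def test_empty_variant_set_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError, match="empty"):
            generate_weights(pd.DataFrame(columns=["SNP", "CHR", "BP"]), None, cfg)

    def test_causal_set_weights_inflated(self):
        cfg = small_config(weight_sparsity=1.0, causal_inflation=10.0,
                           n_variants=2000)
        expr, ann, _ = generate_expression(cfg)
        _, meta = generate_genotypes(cfg, ann)
        sets, _ = build_gene_sets(expr, ann)
        causal = {"Ast": build_intervals(ann.subset(sets.gene_ids("Ast")), 30_000)}
        w = generate_weights(meta, causal, cfg)
        inside = np.zeros(len(meta), dtype=bool)
        for chrom, sub in meta.groupby("CHR"):
            inside[sub.index] = causal["Ast"].contains(chrom, sub["BP"].to_numpy())
        assert inside.any() and (~inside).any()
        assert w.loc[inside, "BETA"].abs().mean() > 3 * w.loc[~inside, "BETA"].abs().mean()


class TestGeneratePhenotypes:
    def _scores(self, n, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(n)
        m = rng.standard_normal(n)
        z = lambda x: (x - x.mean()) / x.std(ddof=1)
        return pd.DataFrame({"AstScore": z(a), "MicScore": z(m)})

    def test_noise_free_cogdec_is_exact_linear_map(self):
        cfg = small_config(
            noise_sd={k: 0.0 for k in ("DP", "NP", "NFT", "CogDec", "Abeta", "PHFtau")},
            covariate_effects={},
        )
        scores = self._scores(500)
        pheno, _ = generate_phenotypes(scores, cfg)
        pc = {tuple(k.split("->")): v for k, v in cfg.path_coefficients.items()}
        ast = scores["AstScore"].to_numpy()
        mic = scores["MicScore"].to_numpy()
        dp = pc[("AstScore", "DP")] * ast
        np_ = pc[("AstScore", "NP")] * ast + pc[("MicScore", "NP")] * mic + pc[("DP", "NP")] * dp
        nft = pc[("NP", "NFT")] * np_ + pc[("MicScore", "NFT")] * mic
        cog = (pc[("NFT", "CogDec")] * nft + pc[("NP", "CogDec")] * np_
               + pc[("MicScore", "CogDec")] * mic)
        assert np.abs(pheno["CogDec"].to_numpy() - cog).max() < 1e-10

    def test_mediation_parameters_recovered(self):
        """a = Score->M, b = M->Y, c' = Score->Y planted; OLS on the
        generated data recovers ACME = a*b and ADE = c' within 3 SE."""
        cfg = small_config(
            path_coefficients={
                "AstScore->DP": 0.5, "DP->NP": 0.4, "AstScore->NP": 0.2,
                "MicScore->NP": 0.0, "NP->NFT": 0.0, "MicScore->NFT": 0.0,
                "NFT->CogDec": 0.0, "NP->CogDec": 0.0, "MicScore->CogDec": 0.0,
            },
            noise_sd={"DP": 1.0, "NP": 1.0, "NFT": 1.0, "CogDec": 1.0,
                      "Abeta": 1.0, "PHFtau": 1.0},
            covariate_effects={},
        )
        scores = self._scores(5000, seed=3)
        pheno, _ = generate_phenotypes(scores, cfg)
        import statsmodels.api as sm
        T = scores["AstScore"].to_numpy()
        X1 = sm.add_constant(T)
        m_fit = sm.OLS(pheno["DP"].to_numpy(), X1).fit()
        X2 = sm.add_constant(np.column_stack([T, pheno["DP"]]))
        y_fit = sm.OLS(pheno["NP"].to_numpy(), X2).fit()
        a, b, cp = m_fit.params[1], y_fit.params[2], y_fit.params[1]
        se_ab = np.sqrt((b * m_fit.bse[1]) ** 2 + (a * y_fit.bse[2]) ** 2)
        assert abs(a * b - 0.20) < 3 * se_ab
        assert abs(cp - 0.20) < 3 * y_fit.bse[1]

    def test_zero_linear_predictor_gives_half_prevalence(self):
        cfg = small_config(
            dementia_coefficients={"intercept": 0.0},
            covariate_effects={},
        )
        pheno, _ = generate_phenotypes(self._scores(10_000, seed=5), cfg)
        assert abs(pheno["dementia"].mean() - 0.5) < 0.02

    def test_missing_required_edge_is_config_error(self):
        pc = dict(SimulationConfig().path_coefficients)
        del pc["NP->NFT"]
        cfg = small_config(path_coefficients=pc)
        with pytest.raises(ConfigError, match="NP->NFT"):
            generate_phenotypes(self._scores(50), cfg)

    def test_seed_determinism(self):
        cfg = small_config()
        s = self._scores(100)
        p1, _ = generate_phenotypes(s, cfg)
        p2, _ = generate_phenotypes(s, cfg)
        pd.testing.assert_frame_equal(p1, p2)

    def test_covariate_moments(self):
        cfg = small_config(n_individuals=5000)
        pheno, _ = generate_phenotypes(self._scores(5000, seed=9), cfg)
        n = len(pheno)
        tol = 4 / np.sqrt(n)
        assert abs(pheno["sex"].mean() - 0.5) < tol
        assert abs(pheno["e4"].mean() - 0.3) < tol       # Binomial(2, .15)
        assert abs(pheno["PC1"].mean()) < tol
        assert abs(pheno["PC1"].std(ddof=1) - 1) < 4 * tol


class TestCausalScoreSeparation:
    def test_causal_cell_type_score_explains_more_variance(self):
        """Weights planted in astrocyte windows: the Ast score out-explains
        a non-causal type's score for DP in most seeded replicates."""
        from cellprs import fit_association, simulate_study

        wins = 0
        n_rep = 12
        for seed in range(n_rep):
            cfg = SimulationConfig(
                seed=seed, n_genes=300, n_specific_per_type=15,
                n_individuals=400, n_variants=1500,
                causal_cell_types=("Ast", "Mic"), causal_inflation=20.0,
            )
            st = simulate_study(cfg)
            dp = st.phenotypes["DP"]
            d_ast = fit_association(dp, st.scores.standardized["Ast"]).delta_r2
            d_ex = fit_association(dp, st.scores.standardized["Ex"]).delta_r2
            wins += d_ast > d_ex
        assert wins >= int(0.75 * n_rep)
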