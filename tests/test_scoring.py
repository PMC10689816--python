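"""Allele reconciliation, weighted-sum scoring and standardisation."""

import numpy as np
import pandas as pd
import pytest

from cellprs.intervals import VariantMembership
from cellprs.scoring import (
    GenotypeMatrix,
    compute_score,
    reconcile_alleles,
    score_correlation,
    standardize,
)


def weight_table(rows):
    return pd.DataFrame(rows, columns=["CHR", "SNP", "BP", "A1", "A2", "BETA"])


def geno_from(dosages, snps, counted, other):
    dosages = np.asarray(dosages)
    meta = pd.DataFrame({
        "SNP": snps,
        "CHR": ["chr1"] * len(snps),
        "BP": np.arange(1, len(snps) + 1) * 1000,
        "counted_allele": counted,
        "other_allele": other,
    })
    ids = np.array([f"I{i}" for i in range(dosages.shape[0])], dtype=object)
    return GenotypeMatrix(dosages=dosages, individual_ids=ids, variant_meta=meta)


class TestReconcileAlleles:
    def test_flipped_allele_reflects_dosage(self):
        w = weight_table([("chr1", "v1", 1000, "A", "G", 0.3)])
        geno = geno_from([[0], [1], [2]], ["v1"], ["G"], ["A"])
        aligned = reconcile_alleles(w, geno.variant_meta)
        scores = compute_score(geno, aligned)
        # counted allele is A2 -> contribution 0.3 * (2 - d)
        np.testing.assert_allclose(scores, [0.6, 0.3, 0.0])

    def test_palindromic_dropped_in_strict_mode(self):
        w = weight_table([
            ("chr1", "v1", 1000, "A", "T", 0.5),
            ("chr1", "v2", 2000, "C", "G", 0.5),
            ("chr1", "v3", 3000, "A", "G", 0.5),
        ])
        meta = geno_from(np.zeros((2, 3), int), ["v1", "v2", "v3"],
                         ["A", "C", "A"], ["T", "G", "G"]).variant_meta
        aligned = reconcile_alleles(w, meta)
        assert list(aligned.snp_ids) == ["v3"]
        assert aligned.n_dropped_palindromic == 2
        relaxed = reconcile_alleles(w, meta, strict_palindromic=False)
        assert len(relaxed) == 3

    def test_mismatching_pairs_dropped(self):
        w = weight_table([
            ("chr1", "v1", 1000, "A", "G", 0.5),
            ("chr1", "v2", 2000, "A", "G", 0.5),
        ])
        meta = geno_from(np.zeros((2, 2), int), ["v1", "v2"],
                         ["A", "T"], ["G", "C"]).variant_meta
        aligned = reconcile_alleles(w, meta)
        assert list(aligned.snp_ids) == ["v1"]
        assert aligned.n_dropped_mismatch == 1

    def test_no_overlap_is_an_error(self):
        w = weight_table([("chr1", "v9", 1000, "A", "G", 0.5)])
        meta = geno_from(np.zeros((1, 1), int), ["v1"], ["A"], ["G"]).variant_meta
        with pytest.raises(ValueError, match="overlap"):
            reconcile_alleles(w, meta)

    def test_shuffled_orientation_matches_prealigned_oracle(self):
        rng = np.random.default_rng(8)
        m, n = 20, 50
        dosage = rng.integers(0, 3, size=(n, m))
        beta = rng.normal(0, 0.1, size=m)
        snps = [f"v{j}" for j in range(m)]
        flip = rng.random(m) < 0.5
        counted = np.where(flip, "G", "A")
        other = np.where(flip, "A", "G")
        w = weight_table([
            ("chr1", snps[j], 1000 * j + 1, "A", "G", beta[j]) for j in range(m)
        ])
        geno = geno_from(dosage, snps, counted, other)
        aligned = reconcile_alleles(w, geno.variant_meta)
        scores = compute_score(geno, aligned)
        # oracle: orient dosages to the A1 allele first, then plain sum
        oriented = np.where(flip[None, :], 2 - dosage, dosage)
        np.testing.assert_allclose(scores, oriented @ beta, atol=1e-12)


class TestComputeScore:
    def test_single_variant_dosage_scaling(self):
        w = weight_table([("chr1", "v1", 1000, "A", "G", 0.5)])
        geno = geno_from([[0], [1], [2]], ["v1"], ["A"], ["G"])
        aligned = reconcile_alleles(w, geno.variant_meta)
        np.testing.assert_allclose(compute_score(geno, aligned), [0, 0.5, 1.0])

    def test_null_weights_give_zero_scores(self):
        w = weight_table([
            ("chr1", f"v{j}", 1000 * (j + 1), "A", "G", 0.0) for j in range(3)
        ])
        geno = geno_from(np.random.default_rng(0).integers(0, 3, (5, 3)),
                         [f"v{j}" for j in range(3)], ["A"] * 3, ["G"] * 3)
        aligned = reconcile_alleles(w, geno.variant_meta)
        np.testing.assert_array_equal(compute_score(geno, aligned), np.zeros(5))

    def test_five_by_three_hand_computed(self):
        dosage = np.array([[0, 1, 2], [1, 1, 1], [2, 0, 0], [0, 0, 0], [2, 2, 2]])
        beta = np.array([0.1, -0.2, 0.3])
        w = weight_table([
            ("chr1", f"v{j}", 1000 * (j + 1), "A", "G", beta[j]) for j in range(3)
        ])
        geno = geno_from(dosage, [f"v{j}" for j in range(3)], ["A"] * 3, ["G"] * 3)
        aligned = reconcile_alleles(w, geno.variant_meta)
        np.testing.assert_allclose(compute_score(geno, aligned), dosage @ beta)

    def test_partition_restriction_and_empty_partition_error(self):
        dosage = np.array([[1, 2], [0, 1]])
        w = weight_table([
            ("chr1", "v0", 1000, "A", "G", 1.0),
            ("chr1", "v1", 2000, "A", "G", 10.0),
        ])
        geno = geno_from(dosage, ["v0", "v1"], ["A", "A"], ["G", "G"])
        aligned = reconcile_alleles(w, geno.variant_meta)
        table = pd.DataFrame(
            {"CHR": ["chr1", "chr1"], "BP": [1000, 2000],
             "Ast": [True, False], "Mic": [False, False], "All": [True, True]},
            index=pd.Index(["v0", "v1"], name="SNP"),
        )
        mem = VariantMembership(table=table, margin_bp=0)
        np.testing.assert_allclose(
            compute_score(geno, aligned, mem, "Ast"), [1.0, 0.0]
        )
        with pytest.raises(ValueError, match="Mic"):
            compute_score(geno, aligned, mem, "Mic")

    def test_variant_order_invariance(self):
        rng = np.random.default_rng(1)
        m = 30
        snps = [f"v{j}" for j in range(m)]
        beta = rng.normal(size=m)
        dosage = rng.integers(0, 3, size=(10, m))
        w = weight_table([
            ("chr1", snps[j], 1000 * (j + 1), "A", "G", beta[j]) for j in range(m)
        ])
        geno = geno_from(dosage, snps, ["A"] * m, ["G"] * m)
        perm = rng.permutation(m)
        w_perm = w.iloc[perm].reset_index(drop=True)
        s1 = compute_score(geno, reconcile_alleles(w, geno.variant_meta))
        s2 = compute_score(geno, reconcile_alleles(w_perm, geno.variant_meta))
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_disjoint_partition_scores_sum_to_union(self, tiny_study):
        """With disjoint partitions, raw scores add to the union's score."""
        mem = tiny_study.membership
        t = mem.table.copy()
        only_a = t["Ast"] & ~t["Mic"]
        only_b = t["Mic"] & ~t["Ast"]
        t["onlyA"], t["onlyB"], t["union"] = only_a, only_b, only_a | only_b
        mem2 = VariantMembership(table=t, margin_bp=mem.margin_bp)
        from cellprs.scoring import reconcile_alleles as ra

        aligned = ra(
            tiny_study.weights,
            tiny_study.genotypes.variant_meta[["SNP", "counted_allele", "other_allele"]],
        )
        sa = compute_score(tiny_study.genotypes, aligned, mem2, "onlyA")
        sb = compute_score(tiny_study.genotypes, aligned, mem2, "onlyB")
        su = compute_score(tiny_study.genotypes, aligned, mem2, "union")
        np.testing.assert_allclose(sa + sb, su, atol=1e-9)

    def test_sum_vs_average_mode_identical_after_standardization(self, tiny_study):
        from cellprs.scoring import reconcile_alleles as ra

        aligned = ra(
            tiny_study.weights,
            tiny_study.genotypes.variant_meta[["SNP", "counted_allele", "other_allele"]],
        )
        mem = tiny_study.membership
        s_sum = compute_score(tiny_study.genotypes, aligned, mem, "Ast", mode="sum")
        s_avg = compute_score(tiny_study.genotypes, aligned, mem, "Ast", mode="average")
        np.testing.assert_allclose(
            standardize(s_sum), standardize(s_avg), atol=1e-9
        )


class TestStandardize:
    def test_closed_form(self):
        np.testing.assert_allclose(standardize(np.array([1., 2., 3.])), [-1, 0, 1])

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        np.testing.assert_allclose(standardize(3.2 * x + 7), standardize(x),
                                   atol=1e-12)

    def test_output_moments(self):
        x = np.random.default_rng(5).normal(3, 9, size=500)
        z = standardize(x)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            standardize(np.ones(10))


class TestScoreCorrelation:
    def test_duplicate_columns_give_unit_offdiagonal(self):
        x = np.random.default_rng(0).normal(size=50)
        df = pd.DataFrame({"a": x, "b": x.copy()})
        r2 = score_correlation(df)
        assert r2.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        assert score_correlation(df).loc["a", "b"] < 0.01

    def test_matches_bruteforce_covariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        r2 = score_correlation(df)
        for a in "abc":
            for b in "abc":
                num = np.cov(df[a], df[b])[0, 1]
                den = df[a].std(ddof=1) * df[b].std(ddof=1)
                assert r2.loc[a, b] == pytest.approx((num / den) ** 2)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1., 1., 1.], "b": [1., 2., 3.]})
        with pytest.raises(ValueError, match="constant"):
            score_correlation(df)


def test_score_table_standardized_moments(tiny_study):
    std = tiny_study.scores.standardized
    assert np.abs(std.mean()).max() < 1e-9
    assert np.abs(std.std(ddof=1) - 1).max() < 1e-9
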