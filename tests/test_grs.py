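"""Weighted risk score: scoring rule, imputation, normalization, binning."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hbmkit.config import SimulationConfig
from hbmkit.grs import (
    assign_bins,
    bin_correlation,
    bin_summary,
    default_bin_edges,
    global_score,
    impute_missing_scores,
    mean_effect_size,
    normalize_score,
    score_cohort,
    snp_score,
)
from hbmkit.simulate import simulate_cohort


class TestSnpScore:
    @pytest.mark.parametrize(
        "dosage,beta,expected", [(2, 0.05, 0.10), (1, 0.05, 0.05), (0, 0.05, 0.0)]
    )
    def test_dosage_times_effect(self, dosage, beta, expected):
        assert snp_score(dosage, beta) == pytest.approx(expected)

    def test_missing_dosage_rejected(self):
        with pytest.raises(ValueError, match="impute"):
            snp_score(np.nan, 0.05)

    def test_non_positive_beta_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            snp_score(1, 0.0)


class TestImputation:
    def test_equal_frequency_reference_mean(self, tiny_effects):
        genotypes = pd.DataFrame([[np.nan]], index=["X"], columns=["rs1"])
        reference = pd.DataFrame([[0.0], [1.0], [2.0]], index=list("abc"), columns=["rs1"])
        effects = tiny_effects.iloc[:1].assign(beta=[0.06])
        scores, n_imputed = impute_missing_scores(genotypes, effects, reference)
        assert scores.loc["X", "rs1"] == pytest.approx(0.06)  # mean of 0, .06, .12
        assert n_imputed["X"] == 1

    def test_no_missing_equals_direct_scoring(self, tiny_effects, tiny_reference):
        scores, n_imputed = impute_missing_scores(tiny_reference, tiny_effects, tiny_reference)
        expected = tiny_reference * tiny_effects.set_index("rsid")["beta"]
        pd.testing.assert_frame_equal(scores, expected)
        assert (n_imputed == 0).all()

    def test_snp_entirely_missing_in_reference_named(self, tiny_effects, tiny_genotypes):
        reference = tiny_genotypes.copy()
        reference["rs2"] = np.nan
        with pytest.raises(ValueError, match="rs2"):
            impute_missing_scores(tiny_genotypes, tiny_effects, reference)

    def test_mean_imputation_preserves_cohort_mean(self):
        cfg = SimulationConfig(n_subjects=1000, missing_rate=0.1, seed=30)
        bundle = simulate_cohort(cfg)
        beta = bundle.effects.set_index("rsid")["beta"]
        true_mean = (bundle.genotypes_true * beta).sum(axis=1).mean()
        scores, _ = impute_missing_scores(bundle.genotypes, bundle.effects, bundle.genotypes)
        imputed_mean = scores.sum(axis=1).mean()
        # mean imputation preserves the cohort mean up to Monte-Carlo error
        assert imputed_mean == pytest.approx(true_mean, rel=0.02)


class TestNormalization:
    def test_worked_example(self, tiny_effects):
        assert normalize_score(
            2.4, tiny_effects.assign(beta=[0.05, 0.05, 0.05])
        ) == pytest.approx(48.0)

    def test_all_heterozygous_equal_betas_gives_snp_count(self):
        n = 55
        effects = pd.DataFrame(
            {"rsid": [f"rs{i}" for i in range(n)], "beta": 0.05, "maf": 0.3,
             "effect_allele": "A", "other_allele": "G"}
        )
        raw = float(np.sum(np.ones(n) * 0.05))
        assert normalize_score(raw, effects) == pytest.approx(55.0)

    def test_homozygous_upper_bound(self, tiny_effects):
        equal = tiny_effects.assign(beta=[0.05, 0.05, 0.05])
        raw = float((2 * np.ones(3) * 0.05).sum())
        assert normalize_score(raw, equal) == pytest.approx(2 * 3)

    @given(st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance_in_betas(self, c, ):
        effects = pd.DataFrame(
            {"rsid": ["rs1", "rs2"], "beta": [0.04, 0.08], "maf": [0.2, 0.3],
             "effect_allele": "A", "other_allele": "G"}
        )
        genotypes = pd.DataFrame([[1.0, 2.0], [0.0, 1.0]], index=["a", "b"],
                                 columns=["rs1", "rs2"])
        base = score_cohort(genotypes, effects).table["normalized_score"]
        scaled = score_cohort(genotypes, effects.assign(beta=effects["beta"] * c)).table[
            "normalized_score"
        ]
        np.testing.assert_allclose(base, scaled, rtol=1e-9)

    def test_empty_effect_table_rejected(self):
        with pytest.raises(ValueError):
            mean_effect_size(pd.DataFrame({"beta": []}))


class TestBinning:
    def test_half_open_convention(self):
        assignment = assign_bins([44.0, 47.9, 48.0], edges=[44, 48, 52])
        assert list(assignment.index) == [1, 1, 2]
        assert assignment.labels == ["44-48", "48-52"]

    def test_last_bin_closed(self):
        assignment = assign_bins([52.0], edges=[44, 48, 52], warn_clamp=False)
        assert list(assignment.index) == [2]

    def test_partition_counts_sum(self):
        rng = np.random.default_rng(31)
        scores = rng.normal(50, 5, 400)
        assignment = assign_bins(scores, warn_clamp=False)
        counts = assignment.index.value_counts()
        assert counts.sum() == 400

    def test_default_edges_anchored_at_multiples_of_four(self):
        rng = np.random.default_rng(32)
        edges = default_bin_edges(rng.normal(50, 5, 500))
        assert np.allclose(edges % 4, 0)
        assert len(edges) == 6

    def test_median_bin_is_central(self):
        edges = default_bin_edges([49.0] * 11)
        assert edges[2] <= 49.0 < edges[3]

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assignment = assign_bins([30.0, 45.0, 60.0], edges=[44, 48, 52])
        assert list(assignment.index) == [1, 1, 2]
        assert assignment.n_clamped == 2

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            assign_bins([1.0], edges=[0, 5, 5, 10])


class TestBinSummary:
    def test_singleton_bins_have_undefined_se(self):
        assignment = assign_bins([45.0, 49.0], edges=[44, 48, 52])
        summary = bin_summary(assignment, [1.0, 2.0])
        assert summary["count"].tolist() == [1, 1]
        assert summary["se_phenotype"].isna().all()
        assert summary["mean_phenotype"].tolist() == [1.0, 2.0]

    def test_constant_phenotype(self):
        rng = np.random.default_rng(33)
        assignment = assign_bins(rng.uniform(44, 52, 100), edges=[44, 48, 52])
        summary = bin_summary(assignment, np.ones(100))
        assert (summary["mean_phenotype"] == 1.0).all()
        assert (summary["se_phenotype"] == 0.0).all()

    def test_empty_bin_marked(self):
        assignment = assign_bins([45.0, 45.5], edges=[44, 48, 52], warn_clamp=False)
        summary = bin_summary(assignment, [1.0, 2.0])
        assert summary.loc[1, "count"] == 0
        assert np.isnan(summary.loc[1, "mean_phenotype"])


class TestBinCorrelation:
    def _summary(self, means):
        return pd.DataFrame(
            {
                "midpoint": 4.0 * np.arange(len(means)),
                "count": [10] * len(means),
                "mean_phenotype": means,
            }
        )

    def test_exact_linear_decrease(self):
        corr = bin_correlation(self._summary([4.0, 3.0, 2.0, 1.0, 0.0]))
        assert corr.r == pytest.approx(-1.0)
        assert corr.r_squared == pytest.approx(1.0)

    def test_constant_means_nan_marked(self):
        corr = bin_correlation(self._summary([1.0, 1.0, 1.0]))
        assert np.isnan(corr.r)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="3"):
            bin_correlation(self._summary([1.0, 2.0]))


class TestScoreCohort:
    def test_brute_force_micro_oracle(self):
        """Exhaustive hand computation for 4 subjects x 4 SNPs."""
        effects = pd.DataFrame(
            {
                "rsid": ["rs1", "rs2", "rs3", "rs4"],
                "effect_allele": list("ACGT"),
                "other_allele": list("GTAC"),
                "beta": [0.02, 0.04, 0.06, 0.08],
                "maf": [0.1, 0.2, 0.3, 0.4],
            }
        )
        genotypes = pd.DataFrame(
            [
                [0.0, 1.0, 2.0, 1.0],
                [2.0, 2.0, 2.0, 2.0],
                [0.0, 0.0, 0.0, 0.0],
                [1.0, 1.0, 1.0, 1.0],
            ],
            index=list("wxyz"),
            columns=effects["rsid"],
        )
        scored = score_cohort(genotypes, effects, edges=[0, 2, 4, 6, 8])
        mean_beta = 0.05
        raw_expected = [0.0 * 0.02 + 1 * 0.04 + 2 * 0.06 + 1 * 0.08,
                        2 * (0.02 + 0.04 + 0.06 + 0.08), 0.0,
                        0.02 + 0.04 + 0.06 + 0.08]
        np.testing.assert_allclose(scored.table["raw_score"], raw_expected)
        np.testing.assert_allclose(
            scored.table["normalized_score"], np.array(raw_expected) / mean_beta
        )
        # normalized: 4.8, 8.0, 0.0, 4.0 -> bins [0,2),[2,4),[4,6),[6,8]
        assert scored.table["bin_index"].tolist() == [3, 4, 1, 3]

    def test_exclusion_recomputes_mean_beta(self, tiny_effects, tiny_reference):
        scored = score_cohort(tiny_reference, tiny_effects, exclude=("rs3",))
        assert list(scored.effects["rsid"]) == ["rs1", "rs2"]
        assert scored.mean_beta == pytest.approx((0.04 + 0.05) / 2)

    def test_scores_bounded_without_imputation(self):
        rng = np.random.default_rng(34)
        n_snps = 8
        effects = pd.DataFrame(
            {
                "rsid": [f"rs{i}" for i in range(n_snps)],
                "beta": rng.uniform(0.01, 0.1, n_snps),
                "maf": rng.uniform(0.05, 0.5, n_snps),
                "effect_allele": "A",
                "other_allele": "G",
            }
        )
        genotypes = pd.DataFrame(
            rng.integers(0, 3, size=(50, n_snps)).astype(float),
            index=[f"S{i}" for i in range(50)],
            columns=effects["rsid"],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scored = score_cohort(genotypes, effects)
        assert (scored.table["normalized_score"] >= 0).all()
        assert (scored.table["normalized_score"] <= 2 * n_snps).all()

    def test_rank_recovery_as_noise_vanishes(self):
        from scipy.stats import spearmanr

        cfg = SimulationConfig(n_subjects=500, noise_sd=1e-6, missing_rate=0.0, seed=35)
        bundle = simulate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scored = score_cohort(bundle.genotypes, bundle.effects)
        rho = spearmanr(
            scored.table["normalized_score"], -bundle.subjects["phenotype_raw"]
        ).statistic
        assert rho > 0.999

    def test_bin_means_decrease_with_risk(self):
        successes = 0
        for seed in range(10):
            bundle = simulate_cohort(SimulationConfig(seed=seed))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scored = score_cohort(bundle.genotypes, bundle.effects)
            summary = bin_summary(scored.assignment, bundle.subjects["ls_z"])
            means = summary.loc[summary["count"] > 0, "mean_phenotype"].to_numpy()
            successes += bool((np.diff(means) < 0).all())
        assert successes >= 8


class TestVcfRoundTrip:
    def test_dosages_and_missing_preserved(self, tmp_path, tiny_effects, tiny_genotypes):
        from hbmkit.io import read_vcf, write_vcf

        path = tmp_path / "cohort.vcf"
        write_vcf(tiny_genotypes, tiny_effects, path)
        back = read_vcf(path)
        pd.testing.assert_frame_equal(back, tiny_genotypes, check_names=False)
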