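"""Chromosome-level inference, ratio CIs, densities, bias classes, profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from zdosage.containers import make_mf_table
from zdosage.dosage import (
    ChromosomeDosageModel,
    bias_expression_anova,
    chromosome_mf_regression,
    classify_sex_bias,
    density_log2mf,
    mean_ratio_ci,
    positional_mf_profile,
    za_ratio,
)
from zdosage.errors import ConfigurationError, DegenerateDesignError, InputError
from zdosage.quantify import annotation_chromosomes, compute_rpkm
from zdosage.simulate import SimulationConfig, simulate_expression


def mf_frame(chroms, log2_mf):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(chroms))],
            "chromosome": chroms,
            "log2_mf": log2_mf,
        }
    )


class TestChromosomeRegression:
    def test_all_zero_response(self):
        mf = mf_frame(["1"] * 5 + ["2"] * 5, [0.0] * 10)
        res = chromosome_mf_regression(mf)
        assert np.allclose(res.chrom_table["mean_log2_mf"], 0.0)
        assert not (res.f_pvalue < 0.05)

    def test_exact_dose_signal(self):
        mf = mf_frame(["1"] * 4 + ["Z"] * 4, [0.0] * 4 + [1.0] * 4)
        res = chromosome_mf_regression(mf)
        assert res.ratio("Z") == pytest.approx(2.0)
        assert res.ratio("1") == pytest.approx(1.0)

    def test_equivalence_with_weighted_group_means(self, rng):
        """No-intercept indicator OLS equals the gene-count-weighted means."""
        chroms = rng.choice(["1", "2", "3", "Z"], size=400, p=[0.3, 0.3, 0.3, 0.1])
        vals = rng.normal(0.0, 1.0, 400) + (chroms == "Z") * 0.8
        mf = mf_frame(chroms, vals)
        res = chromosome_mf_regression(mf)
        oracle = mf.groupby("chromosome")["log2_mf"].mean()
        est = res.chrom_table.set_index("chromosome")["mean_log2_mf"]
        assert np.allclose(est, oracle.loc[est.index], atol=1e-10)

    def test_small_chromosomes_excluded_with_warning(self, caplog):
        mf = mf_frame(["1"] * 5 + ["2"] * 5 + ["tiny"], [0.1] * 11)
        with caplog.at_level("WARNING"):
            model = ChromosomeDosageModel(mf)
        assert "tiny" not in model.chromosomes
        assert "tiny" in caplog.text

    def test_needs_two_chromosomes(self):
        with pytest.raises(InputError, match="2 chromosomes"):
            chromosome_mf_regression(mf_frame(["1"] * 10, [0.0] * 10))

    def test_simulated_partial_compensation_flags_only_z(self):
        """Fig-2-style outcome: only the Z's Bonferroni CI excludes ratio 1."""
        cfg = SimulationConfig(compensation_degree=0.55, seed=17)
        ann, expr, _ = simulate_expression(cfg)
        rpkm = compute_rpkm(expr, ann)
        mf = make_mf_table(rpkm, annotation_chromosomes(ann))
        res = chromosome_mf_regression(mf)
        flagged = res.chrom_table.loc[res.chrom_table["deviates_from_zero"], "chromosome"]
        assert list(flagged) == ["Z"]
        assert res.f_pvalue < 0.001

    def test_summary_mentions_z(self):
        mf = mf_frame(["1"] * 4 + ["Z"] * 4, [0.0] * 4 + [1.0] * 4)
        text = chromosome_mf_regression(mf).summary()
        assert "Z" in text and "Bonferroni" in text


class TestMeanRatioCi:
    def test_constant_ratios_collapse(self):
        pt, lo, hi = mean_ratio_ci(np.full(20, 1.7), mode="mean_of_ratios", n_boot=500, seed=0)
        assert pt == lo == hi == pytest.approx(1.7)

    def test_two_values_finite(self):
        pt, lo, hi = mean_ratio_ci(np.array([1.0, 3.0]), mode="mean_of_ratios", n_boot=500, seed=0)
        assert np.isfinite([pt, lo, hi]).all()
        assert lo <= pt <= hi

    def test_ratio_of_means_point(self, rng):
        pairs = np.column_stack([rng.uniform(1, 5, 50), rng.uniform(1, 5, 50)])
        pt, lo, hi = mean_ratio_ci(pairs, n_boot=500, seed=1)
        assert pt == pytest.approx(pairs[:, 0].mean() / pairs[:, 1].mean())
        assert lo <= pt <= hi

    def test_nboot_floor(self):
        with pytest.raises(ConfigurationError, match="n_boot"):
            mean_ratio_ci(np.ones((10, 2)), n_boot=10)

    def test_ci_shrinks_with_n(self, rng):
        widths = []
        for n in (50, 200, 800):
            pairs = np.column_stack([2 * rng.uniform(1, 3, n), rng.uniform(1, 3, n)])
            _, lo, hi = mean_ratio_ci(pairs, n_boot=2000, seed=3)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        # roughly 1/sqrt(n): quadrupling n about halves the width
        assert widths[2] < widths[0] / 2.5


class TestZaRatio:
    def test_equal_expression_unity(self):
        cfg = SimulationConfig(n_autosomal_genes=50, autosome_labels=("1",), n_z_genes=20,
                               compensation_degree=1.0, dispersion=0.0,
                               baseline_log2_expression_sd=0.0, seed=1)
        ann, expr, _ = simulate_expression(cfg)
        pt, lo, hi = za_ratio(expr, annotation_chromosomes(ann), "M", n_boot=200, seed=0)
        assert pt == pytest.approx(1.0, abs=1e-9)

    def test_noise_free_dose_arithmetic(self):
        cfg = SimulationConfig(n_autosomal_genes=50, autosome_labels=("1",), n_z_genes=20,
                               compensation_degree=0.0, dispersion=0.0,
                               baseline_log2_expression_sd=0.0, seed=1)
        ann, expr, _ = simulate_expression(cfg)
        chroms = annotation_chromosomes(ann)
        m, _, _ = za_ratio(expr, chroms, "M", n_boot=200, seed=0)
        f, _, _ = za_ratio(expr, chroms, "F", n_boot=200, seed=0)
        assert m == pytest.approx(1.0, abs=1e-9)
        assert f == pytest.approx(0.5, abs=1e-9)

    def test_partial_compensation_female_za(self):
        """d = 0.64 yields a female Z:A near 2**(-0.36) ~ 0.78."""
        cfg = SimulationConfig(compensation_degree=0.64, dispersion=0.0,
                               baseline_log2_expression_sd=0.0, seed=2)
        ann, expr, _ = simulate_expression(cfg)
        f, _, _ = za_ratio(expr, annotation_chromosomes(ann), "F", n_boot=200, seed=0)
        assert f == pytest.approx(2.0 ** (0.64 - 1.0), abs=1e-9)

    def test_no_z_genes_rejected(self, tiny_counts, tiny_annotation):
        rpkm = compute_rpkm(tiny_counts, tiny_annotation)
        chroms = pd.Series("1", index=rpkm.gene_ids, name="chromosome")
        with pytest.raises(InputError, match="Z"):
            za_ratio(rpkm, chroms, "M", n_boot=200)


class TestDensity:
    def test_mode_near_zero(self, rng):
        grid, dens = density_log2mf(rng.normal(0, 1, 100_000))
        assert abs(grid[np.argmax(dens)]) < 0.1
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_mixture(self, rng):
        values = np.concatenate([rng.normal(0, 0.15, 3000), rng.normal(1, 0.15, 600)])
        grid, dens = density_log2mf(values)
        interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
        peaks = grid[1:-1][interior]
        assert any(abs(p) < 0.2 for p in peaks)
        assert any(abs(p - 1) < 0.25 for p in peaks)

    def test_degenerate_input(self):
        with pytest.raises(DegenerateDesignError):
            density_log2mf(np.ones(10))
        with pytest.raises(InputError):
            density_log2mf([0.5])


class TestBiasClasses:
    @pytest.mark.parametrize(
        "ratio,label",
        [
            (2.5, "male_biased"),
            (2.0, "unclassified"),
            (1.5, "unclassified"),
            (1.2, "unclassified"),
            (1.0, "unbiased"),
            (0.81, "unbiased"),
            (0.8, "unclassified"),
            (0.5, "unclassified"),
            (0.4, "female_biased"),
        ],
    )
    def test_thresholds_and_gaps(self, ratio, label):
        assert classify_sex_bias(ratio) == label

    def test_nonpositive_rejected(self):
        with pytest.raises(InputError):
            classify_sex_bias(0.0)

    @given(st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_classes_exhaustive_over_positive_ratios(self, ratio):
        assert classify_sex_bias(ratio) in {
            "male_biased", "unbiased", "female_biased", "unclassified",
        }


class TestBiasAnova:
    def test_identical_class_means(self, rng):
        level = np.concatenate([rng.normal(5, 1, 40), rng.normal(5, 1, 40), rng.normal(5, 1, 21)])
        classes = ["male_biased"] * 40 + ["unbiased"] * 40 + ["female_biased"] * 21
        res = bias_expression_anova(level, classes)
        assert res.p_value > 0.01
        assert all(p > 0.05 for p in res.posthoc.values())

    def test_shifted_male_biased_class(self, rng):
        level = np.concatenate([rng.normal(7, 1, 40), rng.normal(5, 1, 40), rng.normal(5, 1, 21)])
        classes = ["male_biased"] * 40 + ["unbiased"] * 40 + ["female_biased"] * 21
        res = bias_expression_anova(level, classes)
        assert res.p_value < 1e-6
        assert res.posthoc[("male_biased", "unbiased")] < 1e-4

    def test_degrees_of_freedom(self, rng):
        """Three classes over 101 genes give F with df (2, 98)."""
        level = rng.normal(0, 1, 101)
        classes = ["male_biased"] * 40 + ["unbiased"] * 40 + ["female_biased"] * 21
        res = bias_expression_anova(level, classes)
        assert (res.df_num, res.df_den) == (2, 98)

    def test_unclassified_excluded_and_single_class_rejected(self, rng):
        level = rng.normal(0, 1, 30)
        res = bias_expression_anova(
            level, ["male_biased"] * 10 + ["unbiased"] * 10 + ["unclassified"] * 10
        )
        assert sum(res.class_sizes.values()) == 20
        with pytest.raises(InputError, match="classes"):
            bias_expression_anova(level, ["male_biased"] * 30)


class TestPositionalProfile:
    @staticmethod
    def table(log2_vals):
        n = len(log2_vals)
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "chromosome": "Z",
                "log2_mf": log2_vals,
                "position_bp": (np.arange(n) + 1) * 1000,
            }
        )

    def test_constant_signal_flat_profile(self):
        prof = positional_mf_profile(self.table([1.0] * 30), window_genes=10)
        assert np.allclose(prof["mean_log2_mf"], 1.0)
        assert len(prof) == 21

    def test_step_detected_at_boundary(self):
        prof = positional_mf_profile(self.table([1.0] * 25 + [0.0] * 25), window_genes=5)
        assert prof["mean_log2_mf"].iloc[0] == pytest.approx(1.0)
        assert prof["mean_log2_mf"].iloc[-1] == pytest.approx(0.0)
        assert prof["mean_log2_mf"].is_monotonic_decreasing

    def test_window_larger_than_gene_count(self):
        with pytest.raises(InputError, match="window"):
            positional_mf_profile(self.table([1.0] * 5), window_genes=10)
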