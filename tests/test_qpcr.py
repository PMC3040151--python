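"""ΔCt arithmetic, sex-comparison tests, Z-linkage calls and QC statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from zdosage.errors import InputError
from zdosage.qpcr import (
    LocusResult,
    call_z_linkage,
    call_z_linkage_from_results,
    choose_control_gene,
    delta_ct_concentration,
    efficiency_from_dilution,
    hypergeom_fisher_oracle,
    intron_length_check,
    load_crow_qpcr_table,
    locus_mf_test,
    plate_locus_results,
    synteny_disruption_test,
)
from zdosage.containers import QpcrPlate
from zdosage.simulate import QpcrSimConfig, simulate_qpcr


class TestDeltaCt:
    @pytest.mark.parametrize("target,control,expected", [(20.0, 20.0, 1.0), (21.0, 20.0, 0.5)])
    def test_examples(self, target, control, expected):
        assert delta_ct_concentration(target, control) == pytest.approx(expected)

    @given(st.floats(10, 35), st.floats(10, 35))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_one_cycle_halves_concentration(self, target, control):
        c0 = delta_ct_concentration(target, control)
        c1 = delta_ct_concentration(target + 1.0, control)
        assert c1 == pytest.approx(c0 / 2.0, rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            delta_ct_concentration(np.nan, 20.0)


class TestLocusTest:
    def test_matches_one_sided_pooled_t(self, rng):
        m = rng.normal(1.0, 0.1, 4)
        f = rng.normal(0.5, 0.1, 4)
        res = locus_mf_test(m, f)
        t_ref, p_ref = stats.ttest_ind(m, f, equal_var=True, alternative="greater")
        assert res.t == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)
        assert res.df == 6

    def test_identical_samples_null_centre(self):
        res = locus_mf_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.t == 0.0 and res.p == 0.5

    def test_minimum_group_size(self):
        with pytest.raises(InputError, match="2 samples"):
            locus_mf_test([1.0], [1.0, 1.0])

    def test_null_p_values_uniform(self, rng):
        """One-sided p is U(0,1) for autosomal (no sex effect) loci at n=4+4."""
        ps = []
        for _ in range(2000):
            m = rng.normal(1.0, 0.1, 4)
            f = rng.normal(1.0, 0.1, 4)
            ps.append(locus_mf_test(m, f).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


def locus(ratio, p, gene="g"):
    return LocusResult(gene_id=gene, locus="x", mean_conc_f=1.0, mean_conc_m=ratio,
                       mf_ratio=ratio, t=1.0, df=6, p=p)


class TestCallZLinkage:
    def test_consistent_z_loci(self):
        call = call_z_linkage([locus(2.03, 0.001), locus(2.40, 0.003)])
        assert call.call == "Z_linked" and call.n_loci == 2

    def test_consistent_autosomal_loci(self):
        call = call_z_linkage([locus(r, p) for r, p in [(1.05, 0.35), (1.14, 0.14), (1.06, 0.27)]])
        assert call.call == "autosomal"

    def test_conflicting_loci_ambiguous(self):
        call = call_z_linkage([locus(2.0, 0.001), locus(1.0, 0.9)])
        assert call.call == "ambiguous"

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            call_z_linkage([])


class TestPublishedWorkedExample:
    def test_twenty_of_twentyone_z_linked(self):
        table = load_crow_qpcr_table()
        assert table["candidate"].nunique() == 21
        calls = call_z_linkage_from_results(
            table.rename(columns={"p_value": "p"}), group_col="candidate"
        )
        counts = calls["call"].value_counts()
        assert counts["Z_linked"] == 20
        autosomal = calls.loc[calls["call"] == "autosomal", "gene_id"]
        assert list(autosomal) == ["ENSTGUG00000017495"]


class TestControlGene:
    @staticmethod
    def plate_from_ct(gene_ct):
        rows = []
        for gid, ct_by_sample in gene_ct.items():
            for sid, ct in ct_by_sample.items():
                sex = "M" if sid.startswith("M") else "F"
                for rep in (1, 2):
                    rows.append((sid, sex, "x", gid, "exon1", 10.0, rep, ct))
        return QpcrPlate(pd.DataFrame(rows, columns=[
            "sample_id", "sex", "group", "gene_id", "locus", "template_ng", "replicate", "ct"]))

    def test_ratio_criterion_dominates(self):
        plate = self.plate_from_ct({
            "A": {"M1": 20.0, "M2": 20.4, "F1": 20.0, "F2": 20.4},   # m:f 1, sd 0.23
            "B": {"M1": 20.0, "M2": 20.0, "F1": 20.4, "F2": 20.4},   # m:f 1.3, sd 0.23
        })
        ranked = choose_control_gene(plate)
        assert list(ranked["gene_id"]) == ["A", "B"]

    def test_tie_broken_by_ct_sd(self):
        plate = self.plate_from_ct({
            "A": {"M1": 20.0, "M2": 20.6, "F1": 20.0, "F2": 20.6},
            "B": {"M1": 20.0, "M2": 20.2, "F1": 20.0, "F2": 20.2},
        })
        ranked = choose_control_gene(plate)
        assert list(ranked["gene_id"]) == ["B", "A"]

    def test_low_noise_autosomal_candidate_wins(self, rng):
        """Across seeds, the stable autosomal gene outranks a noisy one."""
        wins = 0
        for _ in range(50):
            plate = self.plate_from_ct({
                "stable": {s: 20.0 + rng.normal(0, 0.05) for s in ["M1", "M2", "F1", "F2"]},
                "noisy": {s: 20.0 + rng.normal(0, 0.8) for s in ["M1", "M2", "F1", "F2"]},
            })
            wins += choose_control_gene(plate)["gene_id"].iloc[0] == "stable"
        assert wins >= 48

    def test_needs_two_candidates(self):
        plate = self.plate_from_ct({"A": {"M1": 20.0, "F1": 20.0}})
        with pytest.raises(InputError, match="2 candidate"):
            choose_control_gene(plate)


class TestEfficiency:
    def test_perfect_doubling(self):
        template = [100.0, 10.0, 1.0, 0.1]
        ct = [20.0 + 3.321928 * i for i in range(4)]  # slope -3.3219 vs log10
        eff, slope = efficiency_from_dilution(template, ct)
        assert eff == pytest.approx(1.0, abs=1e-4)

    def test_suboptimal_slope(self):
        template = [100.0, 10.0, 1.0, 0.1]
        ct = [20.0 + 3.6 * i for i in range(4)]
        eff, _ = efficiency_from_dilution(template, ct)
        assert eff == pytest.approx(0.8957, abs=1e-3)

    def test_positive_slope_rejected(self):
        # Ct falling with dilution implies a positive slope: physically invalid
        with pytest.raises(InputError, match="slope"):
            efficiency_from_dilution([100.0, 10.0, 1.0], [23.0, 21.0, 20.0])

    def test_span_and_count_requirements(self):
        with pytest.raises(InputError, match="3 dilution"):
            efficiency_from_dilution([100.0, 10.0], [20.0, 23.3])
        with pytest.raises(InputError, match="2 log10"):
            efficiency_from_dilution([100.0, 80.0, 60.0], [20.0, 20.3, 20.7])


class TestSyntenyDisruption:
    def test_no_signal(self):
        p1, p2 = synteny_disruption_test(0, 21, 0, 745)
        assert p1 == pytest.approx(1.0)

    def test_single_moved_gene_unremarkable(self):
        p1, p2 = synteny_disruption_test(1, 21, 15, 745)
        assert 0.35 <= p1 <= 0.38

    def test_total_movement_extreme(self):
        p1, _ = synteny_disruption_test(21, 21, 0, 745)
        assert p1 < 1e-6

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            synteny_disruption_test(-1, 21, 15, 745)

    def test_matches_hypergeometric_oracle(self, rng):
        """scipy's Fisher p equals brute-force enumeration on random tables."""
        tables = [(1, 20, 15, 730)]
        for _ in range(100):
            a, b, c, d = rng.integers(0, 15, 4)
            tables.append((int(a), int(b), int(c), int(d)))
        for a, b, c, d in tables:
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            o1, o2 = hypergeom_fisher_oracle(a, b, c, d)
            p1 = stats.fisher_exact([[a, b], [c, d]], alternative="greater").pvalue
            p2 = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue
            assert o1 == pytest.approx(p1, abs=1e-12)
            assert o2 == pytest.approx(p2, abs=1e-12)


class TestIntronLengthCheck:
    def test_exact_agreement(self):
        exp = np.array([300.0, 500.0, 800.0, 1200.0])
        r2, p, slope = intron_length_check(exp, exp)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_noisy_junctions(self, rng):
        exp = rng.uniform(300, 2000, 7)
        obs = exp + rng.normal(0, 50, 7)
        r2, p, slope = intron_length_check(obs, exp)
        assert r2 > 0.9 and abs(slope - 1.0) < 0.2 and p < 0.001

    def test_uncorrelated(self, rng):
        r2, _, _ = intron_length_check(rng.uniform(0, 1, 50), rng.uniform(0, 1, 50))
        assert r2 < 0.1

    def test_too_few_points(self):
        with pytest.raises(InputError):
            intron_length_check([1.0, 2.0], [1.0, 2.0])


class TestEndToEnd:
    def test_simulated_plate_recovery(self):
        """Z genes always recovered; autosomal calls ambiguous at ~alpha rate."""
        perfect = z_perfect = 0
        n = 60
        for s in range(n):
            plate = simulate_qpcr(QpcrSimConfig(seed=s))
            lr = plate_locus_results(plate, "AUT01")
            calls = call_z_linkage_from_results(lr).set_index("gene_id")["call"]
            truth = plate.truth.set_index("gene_id")["truth_linkage"].drop("AUT01")
            want = truth.map({"Z": "Z_linked", "autosome": "autosomal"})
            match = calls.reindex(want.index) == want
            perfect += int(match.all())
            z_perfect += int(match[want == "Z_linked"].all())
        assert z_perfect == n
        # one-sided alpha=0.05 per called autosomal locus: expect ~0.95**2 plates perfect
        assert perfect / n >= 0.85

    def test_missing_control_names_gene(self):
        plate = simulate_qpcr(QpcrSimConfig(seed=0))
        with pytest.raises(InputError, match="NOPE"):
            plate_locus_results(plate, "NOPE")
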