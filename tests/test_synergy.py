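import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hormsynergy import Thresholds
from hormsynergy.de import call_de, treatment_stats
from hormsynergy.model import HormoneTreatmentModel
from hormsynergy.simulate import (
    DEFAULT_EFFECT_SIZES,
    ExpressionSimConfig,
    simulate_expression,
)
from hormsynergy.synergy import additive_expectation, call_synergy, welch_sum_test

from conftest import make_calls, make_stats_row


class TestAdditiveExpectation:
    def test_baseline_corrected(self):
        assert additive_expectation(300.0, 380.0, 100.0) == pytest.approx(580.0)

    def test_literal_sum(self):
        assert additive_expectation(
            300.0, 380.0, 100.0, mode="literal_sum"
        ) == pytest.approx(680.0)

    def test_no_effect_returns_vehicle(self):
        assert additive_expectation(100.0, 100.0, 100.0) == pytest.approx(100.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            additive_expectation(1.0, 1.0, 1.0, mode="quadratic")


class TestWelchSumTest:
    def test_exactly_additive_probe(self):
        frame = make_stats_row(100.0, 300.0, 380.0, 580.0, var_comb=25.0)
        wt = welch_sum_test(frame)
        assert wt.loc["p0", "welch_t"] == 0.0
        assert wt.loc["p0", "welch_p"] == pytest.approx(1.0)

    def test_reduces_to_two_sample_welch(self):
        """literal_sum with one non-zero single variance equals the
        textbook two-sample Welch test of (700 +/- 50, n=3) against a
        synthetic sum group (680 +/- 50, n=3)."""
        frame = make_stats_row(
            100.0, 680.0, 0.1, 700.0,
            var_t3=2500.0, var_cort=0.0, var_comb=2500.0,
        )
        # drop CORT's mean contribution: literal sum = 680 + 0.1
        frame["mean_CORT"] = 0.0
        wt = welch_sum_test(frame, mode="literal_sum")
        oracle = sps.ttest_ind_from_stats(700.0, 50.0, 3, 680.0, 50.0, 3, equal_var=False)
        assert wt.loc["p0", "welch_t"] == pytest.approx(oracle.statistic)
        assert wt.loc["p0", "welch_p"] == pytest.approx(oracle.pvalue)
        assert wt.loc["p0", "welch_df"] == pytest.approx(4.0)

    def test_sd_margin_is_summed_single_variances(self):
        frame = make_stats_row(
            100.0, 300.0, 380.0, 700.0, var_t3=900.0, var_cort=1600.0
        )
        wt = welch_sum_test(frame)
        assert wt.loc["p0", "sd_margin"] == pytest.approx(50.0)

    def test_planted_departure_power(self):
        """Monte-Carlo power of the variance-sum test on +6-margin
        departures (triplicates, 0.15 log2 noise): ~78%, as an
        independent from-scratch simulation of the same test confirms;
        the small Welch-Satterthwaite df caps it well below 1."""
        cfg = ExpressionSimConfig(
            n_probes=4_000,
            class_fractions={"synergy_induced": 1.0},
            rng_seed=31,
        )
        matrix, design, _ = simulate_expression(cfg)
        stats = treatment_stats(matrix, design)
        wt = welch_sum_test(stats)
        power = float((wt["welch_p"] < 0.02).mean())
        assert 0.70 < power < 0.85


class TestCallSynergy:
    def test_combined_only_criterion(self, thresholds):
        calls = make_calls("ns", "ns", "up")
        frame = make_stats_row(100.0, 102.0, 99.0, 180.0, var_comb=25.0)
        out = call_synergy(calls, frame, thresholds)
        assert out.loc["p0", "criterion"] == "combined_only"
        assert out.loc["p0", "direction"] == "induced"

    def test_cyb561_configuration(self, thresholds):
        """FC triple (2.61, 3.78, 10.52) with tight replicates fires the
        greater-than-additive criterion, induced."""
        frame = make_stats_row(
            100.0, 261.0, 378.0, 1052.0,
            var_veh=100.0, var_t3=100.0, var_cort=100.0, var_comb=900.0,
        )
        calls = make_calls("up", "up", "up")
        out = call_synergy(calls, frame, thresholds)
        assert out.loc["p0", "criterion"] == "greater_than_additive"
        assert out.loc["p0", "direction"] == "induced"
        assert out.loc["p0", "expectation"] == pytest.approx(539.0)

    def test_exactly_additive_probe_not_synergistic(self, thresholds):
        frame = make_stats_row(100.0, 300.0, 380.0, 580.0, var_comb=25.0)
        out = call_synergy(make_calls("up", "up", "up"), frame, thresholds)
        assert out.loc["p0", "criterion"] == "none"
        assert out.loc["p0", "direction"] == "none"

    def test_abolished_response_is_not_synergy(self, thresholds):
        """A CORT response wiped out by T3 (combined back at baseline)
        sits far below the additive expectation but on the wrong side:
        blunting is not synergy."""
        frame = make_stats_row(
            100.0, 101.0, 380.0, 100.0,
            var_veh=25.0, var_t3=25.0, var_cort=25.0, var_comb=25.0,
        )
        out = call_synergy(make_calls("ns", "up", "ns"), frame, thresholds)
        assert out.loc["p0", "criterion"] == "none"

    def test_synergistic_repression(self, thresholds):
        """Combined repression deeper than additive on repressing singles."""
        frame = make_stats_row(
            1000.0, 850.0, 700.0, 300.0,
            var_veh=400.0, var_t3=400.0, var_cort=400.0, var_comb=400.0,
        )
        # additive expectation 550; combined 300 is 250 below
        out = call_synergy(make_calls("ns", "down", "down"), frame, thresholds)
        assert out.loc["p0", "criterion"] == "greater_than_additive"
        assert out.loc["p0", "direction"] == "repressed"

    def test_induced_and_repressed_mutually_exclusive(self, sim_expression, thresholds):
        matrix, design, _ = sim_expression
        stats = treatment_stats(matrix, design)
        calls = call_de(stats, thresholds)
        out = call_synergy(calls, stats, thresholds)
        both = (out["direction"] == "induced") & (out["direction"] == "repressed")
        assert not both.any()
        assert set(out["direction"]) <= {"induced", "repressed", "none"}

    def test_criterion2_scale_invariance(self, sim_expression, thresholds):
        """Rescaling all signals leaves every synergy call unchanged."""
        from hormsynergy.io import ExpressionMatrix

        matrix, design, _ = sim_expression
        stats1 = treatment_stats(matrix, design)
        calls1 = call_de(stats1, thresholds)
        scaled = ExpressionMatrix(matrix.signals * 11.0, floor=matrix.floor)
        stats2 = treatment_stats(scaled, design)
        calls2 = call_de(stats2, thresholds)
        out1 = call_synergy(calls1, stats1, thresholds)
        out2 = call_synergy(calls2, stats2, thresholds)
        pd.testing.assert_series_equal(out1["criterion"], out2["criterion"])
        pd.testing.assert_series_equal(out1["direction"], out2["direction"])

    def test_synergy_set_identity(self, sim_expression, thresholds):
        """Synergy set = section-c probes plus intersection probes that
        pass the greater-than-additive criterion."""
        from hormsynergy.patterns import venn_partition

        matrix, design, _ = sim_expression
        stats = treatment_stats(matrix, design)
        calls = call_de(stats, thresholds)
        out = call_synergy(calls, stats, thresholds)
        sections = venn_partition(calls)
        called = set(out.index[out["criterion"] != "none"])
        section_c = set(sections.index[sections == "c"])
        crit2 = set(out.index[out["criterion"].isin(["greater_than_additive", "both"])])
        assert called == section_c | crit2
        assert crit2 <= set(sections.index[sections.isin(["d", "e", "f"])])

    def test_null_criterion2_rate(self):
        """Type-I rate of the unrestricted greater-than-additive rule on
        pure null data stays within the nominal 2% band."""
        cfg = ExpressionSimConfig(n_probes=10_000, class_fractions={}, rng_seed=77)
        matrix, design, _ = simulate_expression(cfg)
        stats = treatment_stats(matrix, design)
        calls = call_de(stats, Thresholds())
        out = call_synergy(
            calls, stats, Thresholds(), restrict_to_intersections=False
        )
        rate = float((out["criterion"] != "none").mean())
        se = np.sqrt(0.02 * 0.98 / 10_000)
        assert rate <= 0.02 + 3 * se
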