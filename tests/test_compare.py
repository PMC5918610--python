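"""Arm summaries, chi-square contrasts, policy arithmetic, sweeps and PSA."""

import numpy as np
import pytest
from scipy import stats

from eiolsim.cohort_sim import Arm, simulate_cohort
from eiolsim.compare import (
    ArmSummary,
    cesareans_averted_per_100k,
    chi_square_2x2,
    compare_arms,
    comparison_table,
    cost_savings,
    one_way_sensitivity,
    psa,
    summarize,
)
from eiolsim.params import realize_points
from eiolsim.preferences import PreferenceWeights

from conftest import pin_all, strip_curve


def _summary(arm, n, counts, utility=1.0):
    base = {
        "cesarean": 0, "cesarean_unfavorable": 0, "maternal_morbidity": 0,
        "maternal_death": 0, "stillbirth": 0, "neonatal_death": 0,
        "neonatal_severe_morbidity": 0, "neonatal_morbidity": 0,
    }
    base.update(counts)
    den = {k: n for k in base}
    den["cesarean_unfavorable"] = n // 2
    return ArmSummary(
        arm=arm, n=n, counts=base, denominators=den,
        mean_dyad_utility=utility, sd_dyad_utility=0.0,
    )


class TestSummarize:
    def test_healthy_cohort_rates_zero_and_utility_one(self, zero_risk_ps, paperlike_pw):
        df = simulate_cohort(Arm.EIOL_39, 10, zero_risk_ps, seed=1)
        s = summarize(df, paperlike_pw)
        assert s.n == 10
        assert s.rates["cesarean"] == 0.0
        assert s.rates["maternal_morbidity"] == 0.0
        assert s.mean_dyad_utility == 1.0

    def test_counting_cesareans(self, zero_risk_ps, paperlike_pw):
        ps = zero_risk_ps.with_points({"p_cs_eiol_fav": 0.4, "p_cs_eiol_unfav": 0.4})
        df = simulate_cohort(Arm.EIOL_39, 4000, ps, seed=2)
        s = summarize(df, paperlike_pw)
        assert s.counts["cesarean"] == (df["mode"] == "cesarean").sum()
        assert s.rates["cesarean"] == s.counts["cesarean"] / 4000

    def test_maternal_state_counts_conserve_n(self, paperlike, paperlike_pw):
        df = simulate_cohort(Arm.EM_41, 20_000, paperlike, seed=3)
        s = summarize(df, paperlike_pw)
        assert sum(s.maternal_state_counts.values()) == s.n
        assert sum(s.neonatal_state_counts.values()) == s.n

    def test_mixed_arms_rejected(self, paperlike, paperlike_pw):
        a = simulate_cohort(Arm.EIOL_39, 10, paperlike, seed=4)
        b = simulate_cohort(Arm.EM_41, 10, paperlike, seed=4)
        import pandas as pd

        with pytest.raises(ValueError, match="mixed"):
            summarize(pd.concat([a, b]), paperlike_pw)

    def test_empty_input_rejected(self, paperlike_pw):
        with pytest.raises(ValueError, match="empty"):
            summarize([], paperlike_pw)

    def test_accepts_dataclass_lists(self, paperlike, paperlike_pw):
        from eiolsim.cohort_sim import frame_to_trajectories

        df = simulate_cohort(Arm.EIOL_39, 200, paperlike, seed=5)
        s_frame = summarize(df, paperlike_pw)
        s_list = summarize(frame_to_trajectories(df), paperlike_pw)
        assert s_frame.counts == s_list.counts
        assert s_frame.mean_dyad_utility == pytest.approx(s_list.mean_dyad_utility)


class TestChiSquare:
    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 200, size=4)
            stat, p = chi_square_2x2(a, b, c, d)
            ref = stats.chi2_contingency([[a, b], [c, d]], correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_yates_matches_scipy(self):
        stat, p = chi_square_2x2(20, 80, 35, 65, yates=True)
        ref = stats.chi2_contingency([[20, 80], [35, 65]], correction=True)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)

    def test_identical_arms_give_p_one(self):
        a = _summary("eIOL_39", 1000, {"cesarean": 140})
        b = _summary("EM_41", 1000, {"cesarean": 140})
        r = compare_arms(a, b, "cesarean")
        assert r.chi_square == 0.0
        assert r.p_value == 1.0
        assert r.difference_per_100k == 0.0

    def test_single_event_against_none_reproduces_p_032(self):
        # 1 death in 100,000 vs 0 in 100,000: the uncorrected statistic is
        # ~1.00001 and p ~0.317
        a = _summary("eIOL_39", 100_000, {"maternal_death": 0})
        b = _summary("EM_41", 100_000, {"maternal_death": 1})
        r = compare_arms(a, b, "maternal_death")
        assert r.chi_square == pytest.approx(1.00001, abs=1e-4)
        assert r.p_value == pytest.approx(0.3173, abs=5e-4)
        assert r.p_value_exact == pytest.approx(1.0, abs=1e-9)  # Fisher, zero cell

    def test_large_rate_gap_is_overwhelmingly_significant(self):
        a = _summary("eIOL_39", 100_000, {"cesarean": 13_900})
        b = _summary("EM_41", 100_000, {"cesarean": 35_900})
        r = compare_arms(a, b, "cesarean")
        assert r.p_value < 0.01
        assert r.difference_per_100k == pytest.approx(22_000.0)

    def test_difference_scaling_is_exact(self):
        a = _summary("eIOL_39", 200, {"stillbirth": 1})
        b = _summary("EM_41", 400, {"stillbirth": 4})
        r = compare_arms(a, b, "stillbirth")
        assert r.difference_per_100k == pytest.approx((4 / 400 - 1 / 200) * 100_000)

    def test_unknown_outcome_rejected(self):
        a = _summary("eIOL_39", 100, {})
        b = _summary("EM_41", 100, {})
        with pytest.raises(KeyError):
            compare_arms(a, b, "nonexistent")

    def test_comparison_table_has_one_row_per_outcome(self, paperlike, paperlike_pw):
        s_e = summarize(simulate_cohort(Arm.EIOL_39, 5000, paperlike, seed=6), paperlike_pw)
        s_m = summarize(simulate_cohort(Arm.EM_41, 5000, paperlike, seed=6), paperlike_pw)
        table = comparison_table(s_e, s_m)
        assert len(table) == 8
        assert set(table["outcome"]) >= {"cesarean", "stillbirth", "maternal_morbidity"}


class TestPolicyArithmetic:
    def test_equal_rates_avert_nothing(self):
        a = _summary("eIOL_39", 1000, {"cesarean": 100})
        b = _summary("EM_41", 1000, {"cesarean": 100})
        assert cesareans_averted_per_100k(a, b) == 0

    def test_headline_rates_avert_22000(self):
        a = _summary("eIOL_39", 1000, {"cesarean": 139})
        b = _summary("EM_41", 1000, {"cesarean": 359})
        assert cesareans_averted_per_100k(a, b) == 22_000

    @pytest.mark.parametrize(
        "averted,delta,expected",
        [(0, 3900, 0.0), (1, 3900, 3900.0), (21_980, 3900, 85_722_000.0)],
    )
    def test_cost_savings_product(self, averted, delta, expected):
        assert cost_savings(averted, delta) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cost_savings(-1, 3900)


class TestOneWaySensitivity:
    def test_identical_arm_distributions_are_indifferent(self, zero_risk_ps):
        # EM collapses to certain spontaneous week-39 labor with the same
        # (zero) cesarean and complication risks as the elective arm, and
        # common random numbers make the arms element-wise identical
        ps = zero_risk_ps.with_points(
            {"p_spont_labor_39": 0.98, "p_indicated_iol_39": 0.02}
        )
        res = one_way_sensitivity("pref_x", [0.5, 1.0, 2.0], ps, n=2000, seed=7)
        assert res.verdicts == ["indifferent"] * 3

    def test_analytic_crossover_detected_within_one_grid_step(self, zero_risk_ps):
        # eIOL: all vaginal; mother has certain mild morbidity after vaginal
        # birth; infant perfect.  EM: all cesarean at week 39; mother
        # perfect; infant certain severe morbidity.  With
        # disutilities a = w_mild*yM*(1-0.6) = 0.08 and b = w_sev*yB = 0.16
        # the mean utilities cross exactly at x* = a/b = 0.5.
        ps = zero_risk_ps.with_points(
            {
                "p_spont_labor_39": 0.98,
                "p_indicated_iol_39": 0.02,
                "p_cs_spont_39_fav": 1.0,
                "p_cs_spont_39_unfav": 1.0,
                "p_cs_ind_39_fav": 1.0,
                "p_cs_ind_39_unfav": 1.0,
                "p_mat_morb_vaginal": 1.0,
                "p_mat_severe_given_morb": 0.0,
                "p_neo_severe_cesarean": 1.0,
                "mat_sev_weight_mild": 0.5,
                "pref_y_maternal": 0.4,
                "neo_sev_weight_severe": 0.64,
                "pref_y_neonatal": 0.25,
            }
        )
        grid = [0.3, 0.4, 0.45, 0.55, 0.6, 0.7]
        res = one_way_sensitivity("pref_x", grid, ps, n=400, seed=8)
        assert res.crossovers == [(0.45, 0.55)]
        assert res.verdicts[:3] == ["EM_41"] * 3
        assert res.verdicts[3:] == ["eIOL_39"] * 3

    def test_unknown_parameter_rejected(self, paperlike):
        with pytest.raises(KeyError, match="unknown sweep parameter"):
            one_way_sensitivity("p_cs_eiol_fav", [0.1], paperlike, n=10, seed=0)

    def test_empty_grid_rejected(self, paperlike):
        with pytest.raises(ValueError):
            one_way_sensitivity("pref_x", [], paperlike, n=10, seed=0)


class TestPsa:
    def test_frequencies_sum_to_one(self, paperlike):
        res = psa(paperlike, n_draws=10, n_per_draw=500, seed=9)
        assert sum(res.frequencies.values()) == pytest.approx(1.0)
        assert len(res.winners) == 10

    def test_same_seed_identical_frequencies(self, paperlike):
        a = psa(paperlike, n_draws=8, n_per_draw=400, seed=10)
        b = psa(paperlike, n_draws=8, n_per_draw=400, seed=10)
        assert a.frequencies == b.frequencies
        assert a.winners == b.winners

    def test_strictly_dominant_arm_always_wins(self, zero_risk_ps):
        # all risk confined to the expectant arm: certain severe neonatal
        # morbidity after the (certain) 41-week cesarean
        ps = pin_all(
            zero_risk_ps.with_points(
                {
                    "p_spont_labor_39": 0.0,
                    "p_indicated_iol_39": 0.0,
                    "p_spont_labor_40": 0.0,
                    "p_indicated_iol_40": 0.0,
                    "p_cs_ind_41_fav": 1.0,
                    "p_cs_ind_41_unfav": 1.0,
                    "p_neo_severe_cesarean": 1.0,
                }
            )
        )
        res = psa(ps, n_draws=6, n_per_draw=200, seed=11)
        assert res.frequencies["eIOL_39"] == 1.0
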