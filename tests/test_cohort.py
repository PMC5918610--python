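"""Trajectory engine: tree structure, determinism, conservation, oracles."""

import numpy as np
import pandas as pd
import pytest

from eiolsim.cohort_sim import (
    Arm,
    expected_arm_rates,
    frame_to_trajectories,
    run_to_saturation,
    simulate_cohort,
    simulate_patient,
)
from eiolsim.params import realize_points

from conftest import strip_curve, zero_risk


class TestDegenerateTrees:
    def test_zero_risk_cohort_is_uniformly_healthy(self, zero_risk_ps):
        df = simulate_cohort(Arm.EM_41, 10, zero_risk_ps, seed=1)
        assert (df["mode"] == "vaginal").all()
        assert (df["maternal_state"] == "no_complication").all()
        assert (df["fetal_survival"] == "live_birth").all()
        assert (df["neonatal_state"] == "no_complication").all()
        assert df["apgar5"].between(8, 10).all()

    def test_certain_cesarean_forces_mode(self, paperlike):
        ps = strip_curve(paperlike).with_points(
            {n: 1.0 for n in (
                "p_cs_eiol_fav", "p_cs_eiol_unfav", "p_cs_spont_39_fav",
                "p_cs_spont_39_unfav", "p_cs_ind_39_fav", "p_cs_ind_39_unfav",
                "p_cs_spont_40_fav", "p_cs_spont_40_unfav", "p_cs_ind_40_fav",
                "p_cs_ind_40_unfav", "p_cs_ind_41_fav", "p_cs_ind_41_unfav",
            )}
        )
        for arm in Arm:
            df = simulate_cohort(arm, 500, ps, seed=3)
            assert (df["mode"] == "cesarean").all()

    def test_eliminating_early_branches_forces_41_week_induction(self, zero_risk_ps):
        ps = zero_risk_ps.with_points(
            {
                "p_spont_labor_39": 0.0,
                "p_indicated_iol_39": 0.0,
                "p_spont_labor_40": 0.0,
                "p_indicated_iol_40": 0.0,
            }
        )
        df = simulate_cohort(Arm.EM_41, 200, ps, seed=5)
        assert (df["delivery_week"] == 41).all()
        assert (df["labor_onset"] == "scheduled_41wk_induction").all()


class TestTrajectoryInvariants:
    def test_eiol_arm_structure(self, paperlike):
        df = simulate_cohort(Arm.EIOL_39, 5000, paperlike, seed=2)
        assert (df["delivery_week"] == 39).all()
        assert (df["labor_onset"] == "elective_induction").all()
        assert (df["fetal_survival"] == "live_birth").all()

    def test_eiol_stillbirths_structurally_zero_even_at_high_demise_risk(self, paperlike):
        ps = paperlike.with_points(
            {"p_stillbirth_39_40": 0.5, "p_stillbirth_40_41": 0.5}
        )
        df = simulate_cohort(Arm.EIOL_39, 5000, ps, seed=4)
        assert (df["fetal_survival"] == "live_birth").all()

    def test_em_week41_onset_is_always_scheduled_or_indicated(self, paperlike):
        df = simulate_cohort(Arm.EM_41, 20_000, paperlike, seed=6)
        wk41 = df[df["delivery_week"] == 41]
        assert set(wk41["labor_onset"]) <= {
            "spontaneous", "indicated_induction", "scheduled_41wk_induction",
        }
        assert (df["labor_onset"] != "").all()

    def test_stillbirth_rows_have_no_neonatal_outcome(self, paperlike):
        ps = paperlike.with_points({"p_stillbirth_39_40": 0.2, "p_stillbirth_40_41": 0.2})
        df = simulate_cohort(Arm.EM_41, 20_000, ps, seed=7)
        sb = df[df["fetal_survival"] == "stillbirth"]
        assert len(sb) > 0
        assert (sb["neonatal_state"] == "not_applicable").all()
        assert sb["apgar5"].isna().all()

    def test_conservation_of_terminal_states(self, paperlike):
        for arm in Arm:
            df = simulate_cohort(arm, 30_000, paperlike, seed=8)
            assert df["maternal_state"].notna().all()
            assert len(df) == 30_000
            # stillbirths plus live-birth neonatal states partition the cohort
            sb = (df["fetal_survival"] == "stillbirth").sum()
            live_states = df.loc[df["fetal_survival"] == "live_birth", "neonatal_state"]
            assert (live_states != "not_applicable").all()
            assert sb + len(live_states) == 30_000

    def test_apgar_bands_match_neonatal_state(self, paperlike):
        df = simulate_cohort(Arm.EM_41, 30_000, paperlike, seed=9)
        live = df[df["fetal_survival"] == "live_birth"]
        assert live.loc[live["neonatal_state"] == "severe_morbidity", "apgar5"].between(1, 3).all()
        assert live.loc[live["neonatal_state"] == "morbidity", "apgar5"].between(4, 7).all()
        assert live.loc[live["neonatal_state"] == "no_complication", "apgar5"].between(8, 10).all()


class TestDeterminism:
    def test_identical_runs_are_elementwise_identical(self, paperlike):
        a = simulate_cohort(Arm.EM_41, 2000, paperlike, seed=10)
        b = simulate_cohort(Arm.EM_41, 2000, paperlike, seed=10)
        pd.testing.assert_frame_equal(a, b)

    def test_patient_rows_do_not_depend_on_cohort_size(self, paperlike):
        small = simulate_cohort(Arm.EM_41, 100, paperlike, seed=11)
        large = simulate_cohort(Arm.EM_41, 1000, paperlike, seed=11)
        pd.testing.assert_frame_equal(small, large.iloc[:100].reset_index(drop=True))

    def test_simulate_patient_deterministic_dataclass(self, paperlike):
        rp = realize_points(paperlike)
        a = simulate_patient(Arm.EIOL_39, rp, seed=12)
        b = simulate_patient(Arm.EIOL_39, rp, seed=12)
        assert a == b
        assert a.arm == "eIOL_39" and a.delivery_week == 39

    def test_frame_round_trips_to_dataclasses(self, paperlike):
        df = simulate_cohort(Arm.EM_41, 50, paperlike, seed=13)
        trajs = frame_to_trajectories(df)
        assert len(trajs) == 50
        assert trajs[0].arm == "EM_41"

    def test_psa_cohort_deterministic(self, paperlike):
        a = simulate_cohort(Arm.EM_41, 1000, paperlike, seed=14, psa=True)
        b = simulate_cohort(Arm.EM_41, 1000, paperlike, seed=14, psa=True)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_cohort_size_rejected(self, paperlike):
        with pytest.raises(ValueError):
            simulate_cohort(Arm.EM_41, 0, paperlike, seed=1)


class TestStatisticalAgreement:
    def test_binomial_recovery_of_flat_cesarean_rate(self, paperlike):
        ps = strip_curve(paperlike).with_points(
            {"p_cs_eiol_fav": 0.139, "p_cs_eiol_unfav": 0.139}
        )
        df = simulate_cohort(Arm.EIOL_39, 100_000, ps, seed=15)
        rate = (df["mode"] == "cesarean").mean()
        se = np.sqrt(0.139 * 0.861 / 100_000)
        assert abs(rate - 0.139) < 4 * se

    def test_simulation_matches_closed_form_expectations(self, paperlike):
        n = 100_000
        values = realize_points(paperlike).values
        import eiolsim.bishop as bishop

        curve = bishop.fit_cs_curve(paperlike.bishop_curve_points)
        expect = expected_arm_rates(values, curve)
        for arm in Arm:
            df = simulate_cohort(arm, n, paperlike, seed=16)
            for outcome, col in [
                ("cesarean", (df["mode"] == "cesarean")),
                ("stillbirth", (df["fetal_survival"] == "stillbirth")),
                ("neonatal_severe_morbidity", (df["neonatal_state"] == "severe_morbidity")),
            ]:
                p = expect[arm.value][outcome]
                se = np.sqrt(max(p * (1 - p), 1e-9) / n)
                assert abs(col.mean() - p) < 4 * se + 1e-9, (arm, outcome)

    def test_raising_a_cesarean_branch_never_lowers_cs_rate(self, paperlike):
        base = simulate_cohort(Arm.EM_41, 30_000, paperlike, seed=17)
        base_rate = (base["mode"] == "cesarean").mean()
        for var in ("p_cs_spont_39_unfav", "p_cs_ind_40_fav"):
            bumped = paperlike.with_points(
                {var: min(1.0, paperlike.entries[var].point + 0.2)}
            )
            rate = (
                simulate_cohort(Arm.EM_41, 30_000, bumped, seed=17)["mode"] == "cesarean"
            ).mean()
            assert rate >= base_rate  # common random numbers


class TestSaturation:
    def test_degenerate_parameters_saturate_immediately(self, zero_risk_ps):
        ps = zero_risk_ps.with_points({"p_spont_labor_39": 1.0, "p_indicated_iol_39": 0.0})
        (s_e, s_m), n_used = run_to_saturation(ps, seed=18, n_start=1000, n_max=8000)
        assert n_used == 1000
        assert s_e.rates["cesarean"] == 0.0 and s_m.rates["cesarean"] == 0.0

    def test_zero_tolerance_runs_to_the_cap(self, paperlike):
        _, n_used = run_to_saturation(paperlike, seed=19, tol=0.0, n_start=500, n_max=4000)
        assert n_used == 4000

    def test_cap_is_never_exceeded(self, paperlike):
        _, n_used = run_to_saturation(paperlike, seed=20, tol=0.5, n_start=500, n_max=4000)
        assert n_used <= 4000
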