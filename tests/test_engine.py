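"""Cohort engine: stratification, transition matrices, trace invariants."""

import numpy as np
import pytest

from preterm_bia import (
    Arm,
    build_time_grid,
    build_transition_matrix,
    default_fixture,
    extract_outcomes,
    run_cohort,
    stratify,
)
from preterm_bia.cohort import (
    DEAD,
    HOME,
    N_STATES,
    PRE,
    TRAIN,
    CohortTrace,
)
from preterm_bia.synthetic import random_paramset


def null_dynamics_ps():
    """No discharge, no death, no events: everyone sits in the NICU."""
    ps = default_fixture()
    for name, v in {
        "time_to_fof_soc": 400.0,
        "mort_hospital_daily": 0.0,
        "mort_home_annual_y1": 0.0,
        "mort_home_annual_later": 0.0,
        "p_infection_hosp_daily": 0.0,
    }.items():
        ps = ps.with_value(name, v)
    # disable home-event risks (no one reaches home anyway)
    for y in range(1, 6):
        ps = ps.with_value(f"home_infection_annual_y{y}", 0.0)
        ps = ps.with_value(f"rehosp_rate_24_27_y{y}", 0.0)
        ps = ps.with_value(f"rehosp_rate_28_31_y{y}", 0.0)
    return ps


def geometric_ps(p_daily, **extra):
    """Single-branch cohort discharged with a constant daily probability from day 0."""
    ps = null_dynamics_ps()
    for name, v in {
        "prop_nns_at_birth": 0.0,
        "prop_train_success_soc": 1.0,
        "training_start_day": 0.0,
        "prop_discharge_to_ward": 0.0,
        "time_to_fof_soc": 1.0 / p_daily,
        **extra,
    }.items():
        ps = ps.with_value(name, v)
    return ps


class TestStratify:
    def test_masses_proportional(self, fixture_ps):
        ps = fixture_ps.with_value("prop_nns_at_birth", 0.1)
        ps = ps.with_value("prop_train_success_soc", 8.0 / 9.0)
        split = stratify(ps, Arm.SOC)
        assert split.mass_nns_at_birth == pytest.approx(10.0)
        assert split.mass_train_success == pytest.approx(80.0)
        assert split.mass_train_failure == pytest.approx(10.0)
        assert split.total == pytest.approx(100.0)

    def test_all_mass_at_birth_empties_markov_2(self, fixture_ps):
        ps = fixture_ps.with_value("prop_nns_at_birth", 1.0)
        split = stratify(ps, Arm.SOC)
        assert split.markov_mass[1] == 0.0
        trace = run_cohort(ps, Arm.SOC)
        assert trace.occupancy[:, 1, :].sum() == 0.0
        assert trace.total("ngt_discharges") == 0.0

    def test_fixture_non_fof_share_near_six_per_hundred(self, base_traces):
        for arm, lo, hi in ((Arm.SOC, 5.3, 6.6), (Arm.PFOS, 5.8, 7.1)):
            assert lo < base_traces[arm].total("ngt_discharges") < hi


class TestTransitionMatrix:
    @pytest.mark.parametrize("markov_id", [0, 1])
    @pytest.mark.parametrize("cycle_index", [0, 30, 200, 289])
    def test_rows_stochastic(self, fixture_ps, markov_id, cycle_index):
        cyc = build_time_grid(1825).cycles[cycle_index]
        for arm in Arm:
            M = build_transition_matrix(fixture_ps, arm, markov_id, cyc)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert M.min() >= 0.0
            assert M[DEAD, DEAD] == 1.0 and M[DEAD].sum() == 1.0

    def test_null_dynamics_identity_rows(self):
        ps = null_dynamics_ps().with_value("time_to_fof_soc", 400.0)
        ps = ps.with_value("ttd", 1.0)
        cyc = build_time_grid(1825).cycles[0]
        M = build_transition_matrix(ps, Arm.SOC, 0, cyc)
        # only the tiny residual discharge hazard leaves the NICU row
        assert M[PRE, PRE] == 1.0
        assert M[TRAIN, TRAIN] == pytest.approx(1.0 - 1.0 / 400.0)

    def test_ttd_one_makes_markovs_identical(self, fixture_ps):
        ps = fixture_ps.with_value("ttd", 1.0)
        ps = ps.with_value("ngt_home_infection_or", 1.0)
        ps = ps.with_value("m2_rehosp_factor", 1.0)
        for cyc in (build_time_grid(1825).cycles[i] for i in (0, 185, 289)):
            M1 = build_transition_matrix(ps, Arm.SOC, 0, cyc)
            M2 = build_transition_matrix(ps, Arm.SOC, 1, cyc)
            np.testing.assert_allclose(M1, M2, atol=0)

    def test_daily_vs_half_monthly_consistent_hazard(self, fixture_ps):
        grid = build_time_grid(1825)
        daily = build_transition_matrix(fixture_ps, Arm.SOC, 0, grid.cycles[0])
        half = build_transition_matrix(fixture_ps, Arm.SOC, 0, grid.cycles[185])
        # staying probabilities compound: M15[s,s] == M1[s,s]**15 for NICU rows
        assert half[TRAIN, TRAIN] == pytest.approx(daily[TRAIN, TRAIN] ** 15, rel=1e-10)


class TestTraceInvariants:
    def test_mass_conservation_every_cycle(self, base_traces):
        for arm, trace in base_traces.items():
            totals = trace.occupancy.sum(axis=2)  # (cycles+1, markov)
            for m in (0, 1):
                np.testing.assert_allclose(
                    totals[:, m], trace.entering_mass[m], atol=1e-9
                )

    def test_tallies_nonnegative(self, base_traces):
        for trace in base_traces.values():
            for name, arr in trace.tallies.items():
                assert arr.min() >= -1e-12, name

    def test_matrix_power_oracle_on_homogeneous_subproblem(self):
        """Iterated occupancy equals the matrix power on a constant-matrix segment."""
        ps = geometric_ps(0.02)
        grid = build_time_grid(1825)
        M = build_transition_matrix(ps, Arm.SOC, 0, grid.cycles[0])
        trace = run_cohort(ps, Arm.SOC)
        v0 = trace.occupancy[0, 0]
        for k in (1, 5, 50, 120):
            expected = v0 @ np.linalg.matrix_power(M, k)
            np.testing.assert_allclose(trace.occupancy[k, 0], expected, atol=1e-10)

    def test_immortal_undischarged_cohort_accrues_full_horizon(self):
        """Vanishing discharge hazard, no death: NICU days -> patients x horizon."""
        ps = null_dynamics_ps().with_value("time_to_fof_soc", 1.0e9)
        trace = run_cohort(ps, Arm.SOC, horizon_days=400)
        assert trace.nicu_days == pytest.approx(100 * 400, abs=0.1)
        # no occupancy ever reaches home or dead states beyond the residual hazard
        assert trace.occupancy[-1, :, HOME:].sum() < 1e-3

    def test_geometric_mean_stay_closed_form(self):
        """Constant daily discharge p, no mortality -> mean NICU stay 1/p."""
        for p in (0.05, 1 / 65.8, 0.0125):
            trace = run_cohort(geometric_ps(p), Arm.SOC)
            assert trace.mean_nicu_los == pytest.approx(1.0 / p, abs=1e-6)

    def test_ttd_identity_traces(self, fixture_ps):
        """ttd = 1 with shared risks makes the two Markov dynamics identical."""
        ps = fixture_ps.with_value("ttd", 1.0)
        ps = ps.with_value("ngt_home_infection_or", 1.0)
        ps = ps.with_value("m2_rehosp_factor", 1.0)
        ps = ps.with_value("prop_nns_at_birth", 0.0)  # identical entry states
        trace = run_cohort(ps, Arm.SOC)
        m1, m2 = trace.entering_mass
        assert m1 > 0 and m2 > 0
        # per-unit-mass occupancy paths coincide once both enter the same state
        np.testing.assert_allclose(
            trace.occupancy[:, 0, :] / m1 - trace.occupancy[:, 1, :] / m2,
            0.0,
            atol=1e-9,
        )

    def test_monotonicity_in_discharge_and_ttd(self, fixture_ps):
        faster = fixture_ps.with_value("time_to_fof_soc", 30.0)
        slower = fixture_ps.with_value("time_to_fof_soc", 60.0)
        assert run_cohort(faster, Arm.SOC).nicu_days < run_cohort(slower, Arm.SOC).nicu_days
        lo = fixture_ps.with_value("ttd", 0.5)
        hi = fixture_ps.with_value("ttd", 1.2)
        assert (
            run_cohort(hi, Arm.SOC).total("nicu_train_days", markov_id=1)
            < run_cohort(lo, Arm.SOC).total("nicu_train_days", markov_id=1)
        )

    def test_monotonicity_in_rehosp_rate(self, fixture_ps):
        lo = fixture_ps
        hi = fixture_ps
        for y in range(1, 6):
            hi = hi.with_value(f"rehosp_rate_24_27_y{y}",
                               1.5 * fixture_ps.value(f"rehosp_rate_24_27_y{y}"))
        assert (
            run_cohort(hi, Arm.SOC).total("rehosp_events")
            > run_cohort(lo, Arm.SOC).total("rehosp_events")
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_parameter_sets_run_cleanly(self, seed):
        ps = random_paramset(seed, jitter=0.2)
        trace = run_cohort(ps, Arm.PFOS)
        assert trace.nicu_days > 0
        totals = trace.occupancy.sum(axis=2)
        np.testing.assert_allclose(totals[:, 0], trace.entering_mass[0], atol=1e-9)


class TestOutcomes:
    def test_single_trace_summary_keys(self, base_traces):
        out = extract_outcomes(base_traces[Arm.SOC])
        assert out["nicu_days"] == pytest.approx(base_traces[Arm.SOC].nicu_days)
        assert set(out) >= {"nicu_days", "ngt_discharges", "rehosp_events"}

    def test_difference_of_identical_traces_is_zero(self, base_traces):
        t = base_traces[Arm.SOC]
        out = extract_outcomes(t, t)
        assert all(v == 0.0 for v in out["difference"].values())

    def test_fixture_nicu_day_difference_near_reference(self, base_traces):
        out = extract_outcomes(base_traces[Arm.PFOS], base_traces[Arm.SOC])
        assert out["difference"]["nicu_days"] == pytest.approx(-577, abs=60)

    def test_trace_export_long_format(self, base_traces):
        from preterm_bia.cohort import trace_to_frame

        df = trace_to_frame(base_traces[Arm.SOC])
        assert list(df.columns) == ["cycle", "start_day", "arm", "markov", "state", "mass"]
        assert df["mass"].min() >= 0.0
        assert df[df.cycle == 0]["mass"].sum() == pytest.approx(100.0)
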