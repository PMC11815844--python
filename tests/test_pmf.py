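"""Jarzynski estimator, stage planning, replica selection and the staged
protocol: oracle equivalence, exact inequalities and recovery of known
free-energy profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cppkit import (
    GaussianComponent,
    LangevinConfig,
    ThermoParams,
    generate_work_ensemble,
    hysteresis,
    jarzynski_free_energy,
    jarzynski_profile,
    plan_experiment_matrix,
    plan_stages,
    protocol_accounting,
    run_asmd,
    select_representative_replica,
)

THERMO = ThermoParams(temperature=310.15)


def naive_jarzynski(works, thermo=THERMO):
    """Direct evaluation of -kT ln <exp(-beta W)> without shifting."""
    beta = thermo.beta
    return -math.log(np.mean(np.exp(-beta * np.asarray(works)))) / beta


class TestPlanStages:
    def test_forty_angstrom_span_gives_eight_stages_of_five(self):
        plan = plan_stages(0.0, 40.0, 5.0, 25, 1.0)
        assert plan.n_stages == 8
        assert plan.stages[0] == (0.0, 5.0)
        assert plan.stages[-1] == (35.0, 40.0)

    def test_single_stage_span(self):
        assert plan_stages(0.0, 5.0, 5.0, 25, 1.0).n_stages == 1

    def test_last_stage_truncated(self):
        plan = plan_stages(0.0, 12.0, 5.0, 25, 1.0)
        assert plan.stages == ((0.0, 5.0), (5.0, 10.0), (10.0, 12.0))

    def test_backward_plan(self):
        plan = plan_stages(40.0, 0.0, 5.0, 25, 1.0)
        assert plan.direction == "backward"
        assert plan.stages[0] == (40.0, 35.0)

    def test_zero_span_rejected(self):
        with pytest.raises(ValueError):
            plan_stages(3.0, 3.0, 5.0, 25, 1.0)


class TestJarzynskiFreeEnergy:
    def test_constant_works_return_that_constant(self):
        assert jarzynski_free_energy([3.0, 3.0, 3.0], THERMO) == pytest.approx(3.0)

    def test_matches_direct_evaluation_on_two_works(self):
        expected = naive_jarzynski([0.0, 10.0])
        assert jarzynski_free_energy([0.0, 10.0], THERMO) == pytest.approx(
            expected, abs=1e-12
        )

    def test_second_cumulant_limit_for_gaussian_works(self):
        # for W ~ N(mu, sigma^2): dF = mu - beta*sigma^2/2
        rng = np.random.default_rng(0)
        mu, sigma, n = 5.0, 0.5, 100_000
        works = rng.normal(mu, sigma, n)
        beta = THERMO.beta
        est = jarzynski_free_energy(works, THERMO)
        expected = mu - beta * sigma**2 / 2.0
        # delta-method standard error of the estimator
        ew = np.exp(-beta * works)
        se = ew.std(ddof=1) / (math.sqrt(n) * ew.mean() * beta)
        assert abs(est - expected) <= 3 * se

    def test_logsumexp_equals_naive_when_naive_is_finite(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            works = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 2), 40)
            assert jarzynski_free_energy(works, THERMO) == pytest.approx(
                naive_jarzynski(works), abs=1e-10
            )

    def test_handles_huge_works_without_overflow(self):
        est = jarzynski_free_energy([500.0, 510.0, 520.0], THERMO)
        assert np.isfinite(est)
        assert est < 510.0

    @given(
        works=st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_jensen_bound_holds_for_any_ensemble(self, works):
        est = jarzynski_free_energy(works, THERMO)
        assert est <= np.mean(works) + 1e-9
        assert est <= min(works) + THERMO.kt * math.log(len(works)) + 1e-9

    @given(
        works=st.lists(
            st.floats(min_value=-20, max_value=20, allow_nan=False), min_size=2,
            max_size=20,
        ),
        shift=st.floats(min_value=-30, max_value=30, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_translation_equivariance(self, works, shift):
        base = jarzynski_free_energy(works, THERMO)
        shifted = jarzynski_free_energy([w + shift for w in works], THERMO)
        assert shifted == pytest.approx(base + shift, abs=1e-8)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            jarzynski_free_energy([], THERMO)
        with pytest.raises(ValueError):
            jarzynski_free_energy([1.0, float("nan")], THERMO)


class TestJarzynskiProfile:
    def test_single_replica_profile_equals_its_work_curve(self):
        traces = generate_work_ensemble(LangevinConfig(), 0.0, 3.0, 1, seed=4)
        grid = np.linspace(0.0, 3.0, 31)
        prof = jarzynski_profile(traces, grid, THERMO)
        expected = np.interp(grid, traces[0].lam, traces[0].work)
        assert prof.free_energy == pytest.approx(expected - expected[0], abs=1e-9)

    def test_identical_replicas_collapse_to_common_curve(self):
        traces = generate_work_ensemble(
            LangevinConfig(temperature=0.0), 0.0, 3.0, 5, seed=4
        )
        grid = np.linspace(0.0, 3.0, 16)
        prof = jarzynski_profile(traces, grid, THERMO)
        single = jarzynski_profile(traces[:1], grid, THERMO)
        assert prof.free_energy == pytest.approx(single.free_energy, abs=1e-9)

    def test_flat_potential_profile_is_near_zero(self):
        traces = generate_work_ensemble(LangevinConfig(), 0.0, 5.0, 25, seed=6)
        grid = np.linspace(0.0, 5.0, 26)
        prof = jarzynski_profile(traces, grid, THERMO)
        mean_dissipated = np.mean([t.final_work for t in traces])
        assert np.abs(prof.free_energy).max() <= max(0.1 * mean_dissipated, 0.15)

    def test_grid_outside_stage_rejected(self):
        traces = generate_work_ensemble(LangevinConfig(), 0.0, 3.0, 2, seed=4)
        with pytest.raises(ValueError):
            jarzynski_profile(traces, np.array([0.0, 4.0]), THERMO)


class TestRepresentativeReplica:
    def test_single_replica_selected(self):
        traces = generate_work_ensemble(LangevinConfig(), 0.0, 2.0, 1, seed=3)
        assert select_representative_replica(traces, THERMO) == 0

    def test_tie_breaks_to_lowest_id(self):
        traces = generate_work_ensemble(
            LangevinConfig(temperature=0.0), 0.0, 2.0, 4, seed=3
        )
        assert select_representative_replica(traces, THERMO) == 0

    def test_matches_enumerated_argmin(self):
        traces = generate_work_ensemble(LangevinConfig(), 0.0, 2.0, 3, seed=8)
        finals = [t.final_work for t in traces]
        df = naive_jarzynski(finals)
        expected = int(np.argmin([abs(w - df) for w in finals]))
        assert select_representative_replica(traces, THERMO) == expected


class TestRunAsmd:
    def test_flat_potential_recovers_zero_free_energy(self):
        plan = plan_stages(0.0, 40.0, 5.0, 25, 1.0)
        prof = run_asmd(plan, LangevinConfig(seed=1), THERMO, seed=1)
        assert abs(prof.final_value) <= 1.0

    def test_gaussian_barrier_recovered_within_fifteen_percent(self):
        pot = (GaussianComponent(height=5.0, center=20.0, width=2.0),)
        plan = plan_stages(0.0, 40.0, 5.0, 25, 1.0)
        prof = run_asmd(plan, LangevinConfig(potential=pot, seed=2), THERMO, seed=2)
        assert prof.barrier == pytest.approx(5.0, rel=0.15)

    def test_profile_continuous_at_stage_boundaries(self):
        plan = plan_stages(0.0, 15.0, 5.0, 5, 1.0)
        prof = run_asmd(plan, LangevinConfig(seed=3), THERMO, seed=3)
        # boundary points are shared between stages: no jump by construction
        assert np.all(np.isfinite(prof.free_energy))
        assert np.all(np.diff(prof.grid) > 0)
        assert prof.free_energy[0] == 0.0
        assert len(prof.selected_replicas) == plan.n_stages

    def test_same_seed_reproduces_profile_exactly(self):
        plan = plan_stages(0.0, 10.0, 5.0, 5, 1.0)
        a = run_asmd(plan, LangevinConfig(seed=5), THERMO, seed=9)
        b = run_asmd(plan, LangevinConfig(seed=5), THERMO, seed=9)
        assert np.array_equal(a.free_energy, b.free_energy)
        assert a.selected_replicas == b.selected_replicas

    def test_error_shrinks_with_replica_count(self):
        # on a small barrier, more replicas reduce the mean |error| of the
        # end value (expectation over repeated seeds)
        pot = (GaussianComponent(height=2.0, center=2.5, width=1.0),)
        plan_for = lambda n: plan_stages(0.0, 5.0, 5.0, n, 1.0)
        errors = {}
        for n in (4, 64):
            errs = []
            for seed in range(6):
                prof = run_asmd(
                    plan_for(n), LangevinConfig(potential=pot, seed=seed),
                    THERMO, seed=seed,
                )
                truth = float(
                    LangevinConfig(potential=pot).potential_energy(5.0)
                    - LangevinConfig(potential=pot).potential_energy(0.0)
                )
                errs.append(abs(prof.final_value - truth))
            errors[n] = np.mean(errs)
        assert errors[64] < errors[4]


class TestHysteresis:
    def test_profile_against_itself_is_zero(self):
        plan = plan_stages(0.0, 10.0, 5.0, 4, 1.0)
        prof = run_asmd(plan, LangevinConfig(seed=2), THERMO, seed=2)
        mx, mean = hysteresis(prof, prof)
        assert mx == pytest.approx(0.0, abs=1e-12)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_forward_backward_agree_in_slow_pull_limit(self):
        pot = (GaussianComponent(height=5.0, center=10.0, width=2.0),)
        cfg = LangevinConfig(potential=pot, velocity=0.1, timestep=2e-3, seed=7)
        fwd = run_asmd(plan_stages(0, 20, 5, 25, 0.1), cfg, THERMO, seed=11)
        bwd = run_asmd(plan_stages(20, 0, 5, 25, 0.1), cfg, THERMO, seed=12)
        mx, _ = hysteresis(fwd, bwd)
        assert mx <= 0.05 * 5.0

    def test_disjoint_grids_rejected(self):
        from cppkit import PMFProfile

        a = PMFProfile(grid=np.array([0.0, 1.0]), free_energy=np.zeros(2))
        b = PMFProfile(grid=np.array([5.0, 6.0]), free_energy=np.zeros(2))
        with pytest.raises(ValueError):
            hysteresis(a, b)


class TestProtocolAccounting:
    def test_reference_protocol_totals(self):
        plan = plan_stages(0.0, 40.0, 5.0, 25, 1.0)
        totals = protocol_accounting(plan)
        assert totals.per_replica_ns == tuple([5.0] * 8)
        assert totals.per_stage_ns == tuple([125.0] * 8)
        assert totals.per_simulation_ns == 1000.0

    def test_campaign_of_three_peptides_three_membranes(self):
        plan = plan_stages(0.0, 40.0, 5.0, 25, 1.0)
        totals = protocol_accounting(plan, n_peptides=3, n_membranes=3)
        assert totals.campaign_ns == 9000.0  # 9 microseconds

    def test_single_stage_single_replica(self):
        plan = plan_stages(0.0, 7.0, 7.0, 1, 2.0)
        totals = protocol_accounting(plan)
        assert totals.per_simulation_ns == pytest.approx(3.5)


class TestExperimentMatrix:
    def test_three_by_three_with_controls_gives_twelve_systems(self):
        systems = plan_experiment_matrix(
            ["Arg9", "MAP", "TP2"], ["A", "B", "C"], include_controls=True
        )
        assert len(systems) == 12
        assert sum(1 for s in systems if s["control"]) == 3

    def test_controls_only(self):
        assert len(plan_experiment_matrix([], ["A", "B", "C"], True)) == 3

    def test_minimal_matrix(self):
        assert len(plan_experiment_matrix(["p"], ["m"], False)) == 1

    def test_empty_membranes_rejected(self):
        with pytest.raises(ValueError):
            plan_experiment_matrix(["p"], [], True)
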