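"""Tests of the stochastic lattice engine against exact solutions and the
independent oracles (pure-death law, M/M/inf occupancy, Gillespie SSA,
mean-field ODE)."""

import math

import numpy as np
import pytest

from afbiofilm import (
    EndReason,
    HabitatState,
    ModelParams,
    apply_transition,
    channel_rates,
    init_state,
    mean_field_trajectory,
    replicate_rng,
    run_replicates,
    run_simulation,
    seed_population,
    ssa_reference_run,
    step_tau_leap,
)


@pytest.fixture
def baseline():
    return ModelParams.create()


class TestInitState:
    def test_initial_configuration(self, baseline):
        state = init_state(baseline)
        assert state.L == 0
        assert state.t == 0.0
        assert state.total_population() == 0
        assert state.habitat_state(0) is HabitatState.PRE_BIOFILM
        assert state.conc[0] == pytest.approx(4.975062, abs=5e-7)

    def test_rejects_non_params(self):
        with pytest.raises(TypeError):
            init_state({"c_max": 5.0})


class TestChannelRates:
    def test_empty_state_only_immigration(self, baseline):
        state = init_state(baseline)
        rates = channel_rates(state, baseline)
        assert rates["immigration"] == baseline.r_imm
        for key in ("birth", "death", "migration", "detachment"):
            assert rates[key].size == 0

    def test_logistic_shutoff_at_capacity(self, baseline):
        state = init_state(baseline)
        seed_population(state, mic=1e9, count=int(baseline.K))
        rates = channel_rates(state, baseline)
        assert rates["birth"][0, 0] == 0.0
        assert rates["death"][0, 0] == pytest.approx(baseline.d_uniform)

    def test_susceptible_death_rate(self):
        # flat 5 ppm profile so c = 5 exactly; MIC 2.5 organism
        p = ModelParams.create(alpha=0.0)
        state = init_state(p)
        seed_population(state, mic=2.5, count=10)
        rates = channel_rates(state, p)
        assert rates["death"][0, 0] == pytest.approx(0.156333, abs=1e-6)
        assert rates["birth"][0, 0] == 0.0
        assert rates["detachment"][0, 0] == p.r_det
        assert rates["migration"][0, 0] == 0.0  # lone habitat: no neighbour


class TestTauLeap:
    def test_no_rates_only_time_advances(self):
        p = ModelParams.create(r_imm=0.0)
        state = init_state(p)
        seed_population(state, mic=1e9, count=50)
        p_frozen = p.evolve(r_imm=0.0, r_max=0.0, d_uniform=0.0, r_det=0.0)
        state2 = init_state(p_frozen)
        seed_population(state2, mic=1e9, count=50)
        rng = np.random.default_rng(0)
        step_tau_leap(state2, p_frozen, rng)
        assert state2.t == pytest.approx(p_frozen.tau)
        assert state2.total_population() == 50

    def test_pure_death_matches_binomial_law(self):
        # no births, no immigration: survivors of one leap ~ Binomial(n, e^{-d tau})
        d, tau, n0 = 0.05, 0.1, 1000
        p = ModelParams.create(
            r_imm=0.0, r_max=0.0, d_uniform=d, r_det=0.0, tau=tau,
            K=5000.0, N_star=5000.0,
        )
        rng = np.random.default_rng(3)
        survivors = []
        for _ in range(200):
            state = init_state(p)
            seed_population(state, mic=1e9, count=n0)
            step_tau_leap(state, p, rng)
            survivors.append(state.total_population())
        survivors = np.asarray(survivors)
        q = math.exp(-d * tau)
        se = math.sqrt(n0 * q * (1 - q) / len(survivors))
        assert survivors.mean() == pytest.approx(n0 * q, abs=3 * se)
        assert np.all(survivors >= 0)

    def test_counts_never_negative_and_migration_conserves(self):
        # high rates, coarse tau: the binomial-exit scheme must still never
        # overdraw a subpopulation
        p = ModelParams.create(
            r_max=0.5, d_uniform=0.4, r_det=0.3, r_mig=0.5, r_imm=10.0,
            tau=0.5, K=100.0, N_star=80.0, L_max=5, t_max=100.0,
        )
        traj = run_simulation(p, seed=11, record_snapshots=True)
        for snap in traj.snapshots:
            assert np.all(snap.count > 0)  # sparse records store live cells


class TestTransitions:
    def test_below_threshold_no_transition(self, baseline):
        state = init_state(baseline)
        seed_population(state, mic=1e9, count=412)
        assert apply_transition(state, baseline) is None
        assert state.L == 0

    def test_at_threshold_adds_empty_habitat(self, baseline):
        state = init_state(baseline)
        seed_population(state, mic=1e9, count=413)
        assert apply_transition(state, baseline) == "added"
        assert state.L == 1
        assert state.counts[:, 1].sum() == 0
        assert state.conc[1] == pytest.approx(baseline.concentration(1))
        assert state.habitat_state(0) is HabitatState.BIOFILM
        assert state.habitat_state(1) is HabitatState.PRE_BIOFILM

    def test_thickness_cap_stops_run(self):
        # aggressive growth, two-habitat cap: first transition adds the
        # second habitat, the second transition hits the cap
        p = ModelParams.create(
            c_max=0.01, N_star=30.0, K=40.0, r_imm=50.0, r_max=0.5,
            L_max=2, t_max=2000.0,
        )
        traj = run_simulation(p, seed=1, record_snapshots=False)
        assert traj.end_reason is EndReason.THICKNESS_CAP
        assert len(traj.addition_times) == 1
        assert traj.final_L == 1


class TestRunSimulation:
    def test_no_immigration_stays_empty(self):
        p = ModelParams.create(r_imm=0.0, t_max=50.0)
        traj = run_simulation(p, seed=5)
        assert traj.end_reason is EndReason.TIME_CAP
        assert traj.censored
        assert traj.establishment_time is None
        assert all(snap.count.sum() == 0 for snap in traj.snapshots)

    def test_same_seed_identical_trajectories(self):
        p = ModelParams.create(t_max=120.0, record_dt=20.0)
        a = run_simulation(p, seed=99)
        b = run_simulation(p, seed=99)
        assert a.addition_times == b.addition_times
        assert len(a.snapshots) == len(b.snapshots)
        for sa, sb in zip(a.snapshots, b.snapshots):
            assert sa.t == sb.t
            np.testing.assert_array_equal(sa.count, sb.count)
            np.testing.assert_array_equal(sa.ecotype_id, sb.ecotype_id)

    def test_establishment_is_first_addition(self):
        p = ModelParams.create(N_star=0.6 * 550, t_max=2000.0, record_dt=200.0)
        traj = run_simulation(p, seed=4, record_snapshots=True)
        assert not traj.censored
        assert traj.establishment_time == traj.addition_times[0]
        assert traj.addition_times == sorted(traj.addition_times)

    def test_concentrations_decrease_with_depth(self):
        p = ModelParams.create(N_star=0.6 * 550, t_max=2000.0, L_max=6)
        rng = np.random.default_rng(8)
        state = init_state(p)
        for _ in range(20000):
            step_tau_leap(state, p, rng)
            if apply_transition(state, p) == "cap":
                break
        assert state.L >= 1
        assert np.all(np.diff(state.conc) < 0)

    def test_replicates_reproducible_and_labelled(self):
        p = ModelParams.create(t_max=100.0)
        trajs = run_replicates(p, 3, base_seed=1, stop_at_establishment=True)
        again = run_replicates(p, 3, base_seed=1, stop_at_establishment=True)
        assert [t.replicate for t in trajs] == [0, 1, 2]
        assert [t.establishment_time for t in trajs] == [
            t.establishment_time for t in again
        ]
        with pytest.raises(ValueError):
            run_replicates(p, 0, base_seed=1)

    def test_fast_and_general_paths_agree_in_distribution(self):
        """The pre-sampled establishment kernel is a reformulation of the
        leap loop; establishment times from both must be exchangeable."""
        from scipy.stats import ks_2samp

        p = ModelParams.create(N_star=0.63 * 550, t_max=1200.0)
        fast = run_replicates(p, 80, base_seed=50, stop_at_establishment=True)
        slow = []
        for r in range(80):
            rng = replicate_rng(60_000 + r, 0)
            slow.append(
                run_simulation(
                    p, seed=0, rng=rng,
                    record_snapshots=True, stop_at_establishment=True,
                )
            )
        tf = [t.establishment_time for t in fast if not t.censored]
        ts = [t.establishment_time for t in slow if not t.censored]
        assert len(tf) > 40 and len(ts) > 40
        assert ks_2samp(tf, ts).pvalue > 0.01


class TestMeanField:
    def test_resistant_fixed_point(self, baseline):
        # biocide-free habitat: logistic balance K (1 - d_eff / r_max)
        _, n, ss = mean_field_trajectory(
            baseline.evolve(r_imm=0.0), mic=1e9, n0=50.0, t_end=2000.0
        )
        expected = 550 * (1 - (0.018 + 0.22 * 0.083) / 0.083)
        assert ss == pytest.approx(expected, rel=1e-9)
        assert ss == pytest.approx(309.7, abs=0.05)
        assert n[-1] == pytest.approx(ss, rel=1e-4)

    def test_no_growth_linear_balance(self, baseline):
        p = baseline.evolve(r_max=0.0)
        _, n, ss = mean_field_trajectory(p, mic=1e9, t_end=3000.0)
        assert ss == pytest.approx(p.r_imm / (p.d_uniform + p.r_det))
        assert n[-1] == pytest.approx(ss, rel=1e-3)

    def test_empty_stays_empty(self, baseline):
        _, n, _ = mean_field_trajectory(
            baseline.evolve(r_imm=0.0), mic=1e9, n0=0.0, t_end=500.0
        )
        assert np.all(n == 0.0)


class TestSSAOracle:
    def test_zero_rates_no_events(self):
        p = ModelParams.create(r_imm=0.0, t_max=10.0)
        traj = ssa_reference_run(p, seed=1, t_end=10.0)
        assert traj.end_reason is EndReason.TIME_CAP
        assert traj.censored

    def test_immigration_removal_occupancy_poisson(self):
        # r_max = 0: a pure immigration-removal system; the stationary
        # occupancy is Poisson with mean r_imm / (d_uniform + r_det)
        p = ModelParams.create(
            r_max=0.0, r_imm=5.0, t_max=300.0, record_dt=300.0
        )
        mean_expected = p.r_imm / (p.d_uniform + p.r_det)
        finals = []
        for s in range(40):
            traj = ssa_reference_run(p, seed=100 + s, record_snapshots=True)
            finals.append(traj.snapshots[-1].count.sum())
        finals = np.asarray(finals, dtype=float)
        se = math.sqrt(mean_expected / len(finals))
        assert finals.mean() == pytest.approx(mean_expected, abs=3 * se)
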