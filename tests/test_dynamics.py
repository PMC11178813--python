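"""Monte Carlo engine: acceptance law, phases, polarity, conservation."""

import numpy as np
import pytest

from chainpotts import (
    ModelParams,
    advance_phases,
    attempt_copy,
    metropolis_probability,
    monte_carlo_step,
    run_simulation,
    sample_phase_duration,
    sample_phase_durations,
    update_polarity,
)
from chainpotts.dynamics import prepare_run, run_cycles, seed_kernel_rng

from .conftest import make_random_state


class TestMetropolis:
    @pytest.mark.parametrize("dh", [-5.0, -0.1, 0.0])
    def test_downhill_and_neutral_moves_certain(self, defaults, dh):
        assert metropolis_probability(dh, defaults) == 1.0

    def test_uphill_probability_closed_form(self, defaults):
        # beta = 0.2, dH = 5 -> exp(-1)
        assert metropolis_probability(5.0, defaults) == pytest.approx(
            np.exp(-1.0), rel=1e-12
        )

    def test_nonfinite_delta_rejected(self, defaults):
        with pytest.raises(ValueError):
            metropolis_probability(float("nan"), defaults)

    def test_empirical_acceptance_matches_law(self, defaults):
        """Acceptance frequency at fixed dH = 5 within 3 s.e. of exp(-1)."""
        n = 10_000
        p = metropolis_probability(5.0, defaults)
        rng = np.random.default_rng(42)
        hits = int((rng.random(n) < p).sum())
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - np.exp(-1.0)) < 3 * se


class TestPhaseScheduler:
    def test_durations_at_least_one(self, defaults):
        rng = np.random.default_rng(0)
        draws = sample_phase_durations(10_000, defaults, rng)
        assert draws.min() >= 1

    def test_scalar_and_batch_samplers_share_distribution(self, defaults):
        rng = np.random.default_rng(5)
        scalar = np.array(
            [sample_phase_duration(defaults, rng) for _ in range(20_000)]
        )
        batch = sample_phase_durations(20_000, defaults, np.random.default_rng(6))
        assert abs(scalar.mean() - batch.mean()) < 1.5
        assert abs(scalar.std() - batch.std()) < 1.5

    def test_moments_match_truncated_normal(self, defaults):
        """Mean/sd of draws match the >= 1-truncated rounded normal oracle."""
        from scipy import stats

        # rounding to the nearest integer >= 1 truncates the underlying
        # normal at 0.5
        a = (0.5 - defaults.phase_mean) / defaults.phase_sd
        tn = stats.truncnorm(a, np.inf, loc=defaults.phase_mean,
                             scale=defaults.phase_sd)
        n = 100_000
        draws = sample_phase_durations(n, defaults, np.random.default_rng(11))
        se_mean = tn.std() / np.sqrt(n)
        assert draws.mean() == pytest.approx(tn.mean(), abs=3 * se_mean + 0.5)
        # rounding changes the sd by < 0.3 of a step
        assert draws.std() == pytest.approx(tn.std(), abs=3 * se_mean + 0.5)

    def test_phases_alternate_strictly(self, defaults):
        state, params = make_random_state(seed=1)
        state.phase_remaining[1:] = [1, 2, 3]
        start = state.migrating.copy()
        advance_phases(state, params)
        assert state.migrating[1] == 1 - start[1]
        assert (state.migrating[2:] == start[2:]).all()
        assert state.phase_remaining[1] >= 1

    def test_cells_evolve_independently(self, defaults):
        state, params = make_random_state(seed=2)
        state.phase_remaining[1:] = [5, 9, 13]
        history = {m: [] for m in (1, 2, 3)}
        for _ in range(40):
            advance_phases(state, params)
            for m in history:
                history[m].append(int(state.migrating[m]))
        flips = {m: sum(a != b for a, b in zip(h, h[1:]))
                 for m, h in history.items()}
        assert flips[1] >= 1  # the short-phase cell flipped at least once


class TestPolarityUpdate:
    def test_parallel_displacement_leaves_polarity(self, defaults):
        p = np.array([1.0, 0.0])
        out = update_polarity(p, np.array([0.7, 0.0]), defaults)
        np.testing.assert_allclose(out, p, atol=1e-15)

    def test_zero_displacement_leaves_polarity(self, defaults):
        p = np.array([0.6, 0.8])
        np.testing.assert_allclose(
            update_polarity(p, np.zeros(2), defaults), p, atol=1e-15
        )

    def test_orthogonal_displacement_rotates_by_closed_form(self, defaults):
        # p = (1,0), d = (0, 0.5), tau = 500 MCS -> rotation of 0.001 rad
        out = update_polarity(
            np.array([1.0, 0.0]), np.array([0.0, 0.5]), defaults
        )
        np.testing.assert_allclose(
            out, [np.cos(0.001), np.sin(0.001)], rtol=1e-12
        )

    def test_rotation_sign_follows_cross_product(self, defaults):
        out = update_polarity(
            np.array([1.0, 0.0]), np.array([0.0, -0.5]), defaults
        )
        assert out[1] < 0

    def test_norm_preserved_over_many_updates(self, defaults):
        """|p| drift stays below 1e-9 over 10^4 random updates."""
        rng = np.random.default_rng(3)
        p = np.array([1.0, 0.0])
        for _ in range(10_000):
            p = update_polarity(p, rng.normal(0, 2, size=2), defaults)
        assert abs(np.linalg.norm(p) - 1.0) < 1e-9


class TestStepInvariants:
    def test_all_resting_cells_freeze_the_field(self):
        state, params = make_random_state(seed=4, with_walls=True)
        state.migrating[:] = 0
        state.phase_remaining[1:] = 10_000  # no flips within the test
        seed_kernel_rng(9)
        before = state.field.labels.copy()
        for _ in range(3):
            rep = monte_carlo_step(state, params)
            assert rep.accepted == 0
        np.testing.assert_array_equal(state.field.labels, before)

    def test_step_report_accounts_every_attempt(self):
        state, params = make_random_state(seed=5, with_walls=True)
        seed_kernel_rng(10)
        rep = monte_carlo_step(state, params)
        assert rep.attempts == params.attempts_per_step
        assert rep.attempts == (
            rep.accepted + rep.rejected_resting + rep.rejected_illegal
            + rep.rejected_metropolis
        )

    def test_obstacles_and_label_count_survive_dynamics(self):
        params = ModelParams(
            L_x=14, L_y=40, N_cells=4, warmup_cycles=0, measure_cycles=1,
            Gamma_R=3.0,
        )
        state = prepare_run(params, seed=2)
        walls = state.field.obstacle_mask().copy()
        run_cycles(state, params, 3)
        np.testing.assert_array_equal(state.field.obstacle_mask(), walls)
        assert state.field.cell_labels().size == params.N_cells
        assert (state.field.volumes()[1:] >= 1).all()

    def test_polarities_stay_unit_after_dynamics(self):
        params = ModelParams(
            L_x=14, L_y=40, N_cells=4, warmup_cycles=0, measure_cycles=1,
            Gamma_R=3.0,
        )
        state = prepare_run(params, seed=3)
        run_cycles(state, params, 2)
        norms = np.linalg.norm(state.polarities[1:], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_attempt_copy_runs_and_conserves_labels(self):
        state, params = make_random_state(seed=6, with_walls=True)
        seed_kernel_rng(11)
        n_before = state.field.cell_labels().size
        outcomes = [attempt_copy(state, params) for _ in range(2000)]
        assert any(outcomes) and not all(outcomes)
        assert state.field.cell_labels().size == n_before


class TestConnectivityRule:
    @pytest.mark.parametrize(
        "b_offsets, disconnects",
        [
            ([(-1, 0)], False),                      # tail tip: one arc
            ([(-1, -1), (-1, 0), (-1, 1)], False),   # straight edge
            ([(0, -1), (1, -1), (1, 0)], False),     # rectangle corner
            ([(-1, 0), (1, 0)], True),               # bridge between two arcs
            ([(-1, -1), (1, 1)], True),              # opposite diagonals
        ],
    )
    def test_local_arc_detection(self, b_offsets, disconnects):
        from chainpotts._kernels import _locally_disconnects

        labels = np.zeros((7, 7), dtype=np.int32)
        labels[3, 3] = 1
        for dx, dy in b_offsets:
            labels[3 + dx, 3 + dy] = 1
        assert bool(_locally_disconnects(labels, 3, 3, 1)) == disconnects

    def test_rule_suppresses_fragmentation_at_strong_adhesion(self):
        """At adhesion beyond the tension scale, cells fray without the rule.

        The local arc test cannot forbid every global split, so the check
        is comparative: total fragment count with the rule must be well
        below the unconstrained run's.
        """
        from scipy import ndimage

        def total_components(connectivity: bool) -> int:
            params = ModelParams(
                L_x=14, L_y=40, N_cells=4, warmup_cycles=0, measure_cycles=1,
                Gamma_R=10.0, connectivity=connectivity,
            )
            state = prepare_run(params, seed=7)
            run_cycles(state, params, 10)
            labels = state.field.labels
            total = 0
            for m in range(1, 5):
                mask = np.concatenate([labels == m] * 2, axis=1)  # unwrap y
                _, n = ndimage.label(mask, structure=np.ones((3, 3)))
                total += max(1, n // 2)
            return total

        constrained = total_components(True)
        free = total_components(False)
        assert constrained <= 6          # near-whole: ~1 component per cell
        assert constrained < free / 2    # and far below the unconstrained run


class TestRunSimulation:
    def test_same_seed_gives_identical_trajectories(self):
        params = ModelParams(
            L_x=14, L_y=40, N_cells=4, warmup_cycles=2, measure_cycles=6,
            Gamma_R=3.0,
        )
        t1 = run_simulation(params, seed=8)
        t2 = run_simulation(params, seed=8)
        np.testing.assert_array_equal(t1.polarities, t2.polarities)
        np.testing.assert_array_equal(t1.centers, t2.centers)

    def test_trajectory_shapes_match_protocol(self):
        params = ModelParams(
            L_x=14, L_y=40, N_cells=4, warmup_cycles=1, measure_cycles=6,
            Gamma_R=3.0,
        )
        traj = run_simulation(params, seed=8)
        assert traj.polarities.shape == (6, 4, 2)
        assert traj.centers.shape == (7, 4, 2)
        assert traj.final_state.mcs_clock == 7 * params.mcs_per_cycle

    def test_mean_volume_relaxes_to_target(self):
        """After relaxation the mean cell volume sits within 10% of V_0."""
        params = ModelParams(
            L_x=16, L_y=32, N_cells=4, warmup_cycles=20, measure_cycles=10,
            Gamma_R=3.0,
        )
        log: list[dict] = []
        run_simulation(params, seed=1, log=log)
        mean_vol = np.mean([r["mean_volume"] for r in log])
        assert mean_vol == pytest.approx(params.V_0, rel=0.10)
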