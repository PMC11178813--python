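"""Monte Carlo dynamics: copy attempts, saltatory phases, polarity updates.

One Monte Carlo step (MCS) consists of ``16 L_x L_y`` single-site copy
attempts with Metropolis acceptance at inverse fluctuation scale ``beta``,
followed by the slow-variable updates: cell centers are recomputed from the
label field, each polarity is rotated toward its half-step displacement
(leap-frog persistent-random-walk update), and the saltatory phase clocks
advance by one step.  A cell in its resting phase cannot gain or lose sites:
any copy touching a resting cell is rejected, which pins the cell body while
the phase lasts.

Randomness: a run draws everything from one seed.  A ``SeedSequence``
spawns separate streams for (a) placement + phase scheduling (a numpy
``Generator``) and (b) the compiled copy-attempt loop (numba's internal
RNG), so either half can be exercised in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .lattice import SimulationState, initial_state
from .params import ModelParams


@dataclass(frozen=True)
class StepReport:
    """Outcome tally of the copy attempts of one Monte Carlo step."""

    attempts: int
    accepted: int
    rejected_resting: int
    rejected_illegal: int
    rejected_metropolis: int

    @property
    def acceptance_fraction(self) -> float:
        return self.accepted / self.attempts if self.attempts else 0.0


def metropolis_probability(delta_H: float, params: ModelParams) -> float:
    """Metropolis acceptance probability ``min[1, exp(-beta dH)]``."""
    if not np.isfinite(delta_H):
        raise ValueError(f"delta_H must be finite, got {delta_H}")
    return float(min(1.0, np.exp(-params.beta * delta_H)))


def sample_phase_duration(params: ModelParams, rng: np.random.Generator) -> int:
    """One saltatory phase duration, in Monte Carlo steps.

    Draws Normal(phase_mean, phase_sd), rounds to the nearest integer and
    resamples until the result is >= 1.  The >= 1 truncation shifts the
    realized mean above ``phase_mean`` (see docs/methods.md).
    """
    while True:
        d = round(rng.normal(params.phase_mean, params.phase_sd))
        if d >= 1:
            return int(d)


def sample_phase_durations(
    n: int, params: ModelParams, rng: np.random.Generator
) -> np.ndarray:
    """``n`` i.i.d. phase durations (vectorized batch form of the sampler)."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        batch = np.rint(
            rng.normal(params.phase_mean, params.phase_sd, size=n - filled)
        ).astype(np.int64)
        batch = batch[batch >= 1]
        out[filled:filled + batch.size] = batch
        filled += batch.size
    return out


def advance_phases(state: SimulationState, params: ModelParams) -> None:
    """Advance every cell's phase clock by one Monte Carlo step.

    On expiry the phase flips (phases alternate strictly) and a fresh
    duration is drawn.
    """
    rem = state.phase_remaining
    rem[1:] -= 1
    if (rem[1:] <= 0).any():
        for m in np.nonzero(rem[1:] <= 0)[0] + 1:
            state.migrating[m] ^= 1
            rem[m] = sample_phase_duration(params, state.rng)


def update_polarity(
    polarity: np.ndarray,
    half_step_displacement: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """Leap-frog polarity update toward a half-step displacement ``d``.

    ``dp = [d - (p.d) p] / (a tau)`` is orthogonal to ``p``; ``p`` is
    rotated in-plane by ``|dp|`` toward the side given by the sign of
    ``p x dp``, which preserves the unit norm exactly.  ``tau`` is the
    persistence time converted to Monte Carlo steps.
    """
    px, py = _kernels.rotate_polarity(
        float(polarity[0]), float(polarity[1]),
        float(half_step_displacement[0]), float(half_step_displacement[1]),
        1.0 / (params.a * params.tau_mcs),
    )
    return np.array([px, py])


def _kernel_args(state: SimulationState, params: ModelParams):
    n = state.n_cells
    vols = np.zeros(n + 2, dtype=np.int64)
    vols[: n + 1] = state.field.volumes()
    return vols


def seed_kernel_rng(seed: int) -> None:
    """Seed the compiled engine's internal RNG."""
    _kernels.seed_rng(np.uint32(seed & 0x7FFFFFFF))


def attempt_copy(state: SimulationState, params: ModelParams) -> bool:
    """One random copy attempt (the elementary move), mutating the state.

    Draws a uniform source site and neighbor direction from the state's
    generator (the Metropolis variate comes from the compiled engine's
    stream); returns True iff the copy was accepted.  The production loop
    runs the same compiled routine ``16 L_x L_y`` times per step.
    """
    rng = state.rng
    L_x, L_y = state.field.shape
    vols = _kernel_args(state, params)
    code = _kernels.try_copy(
        state.field.labels, vols,
        np.ascontiguousarray(state.centers[:, 0]),
        np.ascontiguousarray(state.centers[:, 1] % L_y),
        np.ascontiguousarray(state.polarities[:, 0]),
        np.ascontiguousarray(state.polarities[:, 1]),
        state.migrating ^ 1,
        int(rng.integers(L_x)), int(rng.integers(L_y)),
        int(rng.integers(8)),
        params.gamma_E, params.gamma_C, params.gamma_P, params.gamma_W,
        params.Gamma_R, params.lam,
        params.kappa_0, params.V_0, params.kappa_2, params.beta,
        state.field.obstacle_label, params.connectivity,
    )
    return code == _kernels.ACCEPTED


class _StepWorkspace:
    """Reusable arrays threaded through the per-step compiled calls."""

    def __init__(self, state: SimulationState):
        n = state.n_cells
        self.vols = np.zeros(n + 2, dtype=np.int64)
        self.vols[: n + 1] = state.field.volumes()
        self.cx = np.ascontiguousarray(state.centers[:, 0])
        self.cy = np.ascontiguousarray(state.centers[:, 1])
        self.px = np.ascontiguousarray(state.polarities[:, 0])
        self.py = np.ascontiguousarray(state.polarities[:, 1])
        self.new_x = np.zeros(n + 1)
        self.new_y = np.zeros(n + 1)
        self.new_v = np.zeros(n + 1, dtype=np.int64)
        self.counts = np.zeros(5, dtype=np.int64)

    def write_back(self, state: SimulationState) -> None:
        state.centers[:, 0] = self.cx
        state.centers[:, 1] = self.cy
        state.polarities[:, 0] = self.px
        state.polarities[:, 1] = self.py


def monte_carlo_step(
    state: SimulationState,
    params: ModelParams,
    _ws: _StepWorkspace | None = None,
) -> StepReport:
    """One full Monte Carlo step: copies, centers, polarities, phases."""
    ws = _ws or _StepWorkspace(state)
    ws.counts[:] = 0
    resting = state.migrating ^ 1
    L_y = state.field.shape[1]
    cyw = ws.cy % L_y  # centers are frozen for the whole step
    _kernels.sweep(
        state.field.labels, ws.vols, ws.cx, cyw, ws.px, ws.py, resting,
        params.attempts_per_step,
        params.gamma_E, params.gamma_C, params.gamma_P, params.gamma_W,
        params.Gamma_R, params.lam,
        params.kappa_0, params.V_0, params.kappa_2, params.beta,
        state.field.obstacle_label, params.connectivity, ws.counts,
    )
    _kernels.post_sweep_update(
        state.field.labels, state.n_cells,
        ws.cx, ws.cy, ws.px, ws.py,
        1.0 / (params.a * params.tau_mcs),
        ws.new_x, ws.new_y, ws.new_v,
    )
    ws.write_back(state)
    advance_phases(state, params)
    state.mcs_clock += 1
    c = ws.counts
    return StepReport(
        attempts=int(c.sum()),
        accepted=int(c[_kernels.ACCEPTED]),
        rejected_resting=int(c[_kernels.REJ_RESTING]),
        rejected_illegal=int(c[_kernels.REJ_SAME] + c[_kernels.REJ_ILLEGAL]),
        rejected_metropolis=int(c[_kernels.REJ_METROPOLIS]),
    )


def prepare_run(params: ModelParams, seed: int) -> SimulationState:
    """Build the channel, place cells, and seed both RNG streams."""
    ss = np.random.SeedSequence(seed)
    place_ss, mc_ss = ss.spawn(2)
    state = initial_state(params, np.random.default_rng(place_ss))
    seed_kernel_rng(int(mc_ss.generate_state(1, dtype=np.uint32)[0]))
    return state


def run_cycles(
    state: SimulationState,
    params: ModelParams,
    cycles: int,
    ws: _StepWorkspace | None = None,
    collect: list | None = None,
) -> _StepWorkspace:
    """Advance the state by whole saltatory cycles.

    If ``collect`` is given, append one per-cycle record: mean acceptance
    fraction over the cycle and the mean cell volume at cycle end.
    """
    ws = ws or _StepWorkspace(state)
    for _ in range(cycles):
        accepted = attempts = 0
        for _ in range(params.mcs_per_cycle):
            rep = monte_carlo_step(state, params, ws)
            accepted += rep.accepted
            attempts += rep.attempts
        if collect is not None:
            collect.append(
                dict(
                    cycle=state.mcs_clock // params.mcs_per_cycle,
                    acceptance=accepted / attempts,
                    mean_volume=float(
                        state.field.volumes()[1:].mean()
                    ),
                )
            )
    return ws


def run_simulation(
    params: ModelParams,
    seed: int,
    cycles: int | None = None,
    warmup: int | None = None,
    log: list | None = None,
    snapshot_every: int = 0,
):
    """Warm up, then record a trajectory over the measurement period.

    Parameters
    ----------
    params, seed
        Model parameters and the single seed all randomness derives from.
    cycles, warmup
        Measurement and warm-up periods in cycles; default to
        ``params.measure_cycles`` and ``params.warmup_cycles``.
    log
        Optional list collecting one diagnostic record per measured cycle.
    snapshot_every
        If positive, keep a copy of the label raster every that many
        measured cycles (stored on the returned trajectory).

    Returns
    -------
    Trajectory
        Per-cycle polarity snapshots and center positions (unwrapped y)
        for the measurement period.
    """
    from .observables import Trajectory

    cycles = params.measure_cycles if cycles is None else cycles
    warmup = params.warmup_cycles if warmup is None else warmup
    state = prepare_run(params, seed)
    ws = run_cycles(state, params, warmup)

    n = params.N_cells
    pol = np.empty((cycles, n, 2))
    cen = np.empty((cycles + 1, n, 2))
    cen[0] = state.centers[1:]
    snapshots: list[tuple[int, np.ndarray]] = []
    for t in range(cycles):
        run_cycles(state, params, 1, ws, collect=log)
        pol[t] = state.polarities[1:]
        cen[t + 1] = state.centers[1:]
        if snapshot_every > 0 and (t + 1) % snapshot_every == 0:
            snapshots.append((t + 1, state.field.labels.copy()))
    return Trajectory(
        polarities=pol,
        centers=cen,
        window_cycles=params.disp_window_cycles,
        final_state=state,
        snapshots=snapshots,
    )
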