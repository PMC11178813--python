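"""Shared fixtures: small deterministic states for unit tests."""

import numpy as np
import pytest

from chainpotts import ModelParams, PottsField, SimulationState


@pytest.fixture
def defaults() -> ModelParams:
    return ModelParams()


def make_random_state(
    seed: int,
    L_x: int = 12,
    L_y: int = 12,
    n_cells: int = 3,
    with_walls: bool = False,
) -> tuple[SimulationState, ModelParams]:
    """A small random state: blobby cells, random polarities, random centers.

    Cells are scattered site-by-site (possibly disconnected; the model
    imposes no connectivity), each guaranteed at least one site.  Centers
    are the true centroids (wrapped-y minimal image around the first site)
    and polarities are uniform unit vectors.
    """
    rng = np.random.default_rng(seed)
    params = ModelParams(
        L_x=L_x, L_y=L_y, N_cells=n_cells, V_0=16.0, kappa_0=4.0,
        Gamma_R=2.0, warmup_cycles=0, measure_cycles=1,
    )
    labels = np.zeros((L_x, L_y), dtype=np.int32)
    if with_walls:
        labels[0, :] = n_cells + 1
        labels[-1, :] = n_cells + 1
    interior = labels == 0
    sites = np.argwhere(interior)
    rng.shuffle(sites)
    per_cell = max(3, int(0.6 * len(sites) / n_cells / 2))
    k = 0
    for m in range(1, n_cells + 1):
        for _ in range(per_cell):
            x, y = sites[k]
            labels[x, y] = m
            k += 1

    centers = np.zeros((n_cells + 1, 2))
    for m in range(1, n_cells + 1):
        xs, ys = np.nonzero(labels == m)
        y0 = ys[0]
        dy = (ys - y0 + L_y / 2) % L_y - L_y / 2
        centers[m] = (xs.mean(), (y0 + dy.mean()) % L_y)
    ang = rng.uniform(0, 2 * np.pi, n_cells + 1)
    polarities = np.stack([np.cos(ang), np.sin(ang)], axis=1)

    state = SimulationState(
        field=PottsField(labels, n_cells),
        centers=centers,
        polarities=polarities,
        migrating=np.ones(n_cells + 1, dtype=np.uint8),
        phase_remaining=np.full(n_cells + 1, 50, dtype=np.int64),
        rng=rng,
    )
    return state, params


@pytest.fixture
def random_state():
    return make_random_state(seed=7)


def cells_dict(state: SimulationState) -> dict:
    """label -> (center, polarity) mapping for the test oracle."""
    return {
        m: (state.centers[m].copy(), state.polarities[m].copy())
        for m in range(1, state.n_cells + 1)
    }
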