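"""Deterministic fixtures, the adhesion-strength sweep, and frame rendering.

The fixtures are tiny hand-constructable states whose energies are known in
closed form or by direct enumeration; they anchor the unit tests.  The
adhesion sweep is the package's central experiment: hold every parameter at
its default, scan the cell–cell adhesion strength ``Gamma_R`` over a grid
spanning no adhesion to well past the cell–cell tension, and record the
ordering indicator ``P`` and mean velocity ``v`` per (Gamma_R, seed).
Efficient chain migration appears only at intermediate adhesion: too weak
and cells migrate individually in incoherent directions, too strong and the
population clumps and stalls.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .dynamics import run_simulation
from .lattice import (
    CellState,
    PottsField,
    SimulationState,
    build_channel,
    initial_state,
)
from .observables import mean_velocity, ordering_indicator, sweep_frame
from .params import ModelParams, reduced_params

FIXTURE_NAMES = (
    "single_cell_torus",
    "two_cell_contact",
    "packed_channel",
    "direction_sets",
)

#: Default adhesion grid: 0 (no adhesion) to 2 * gamma_C = 16 (adhesion far
#: exceeding the cell-cell tension), denser at the low end where the
#: dissociation-to-chain transition sits.
DEFAULT_GAMMA_R_GRID = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 10.0, 16.0)

#: A representative intermediate adhesion strength from the grid interior.
INTERMEDIATE_GAMMA_R = 4.0


@dataclass
class Fixture:
    """A named deterministic test state with optional extra payloads."""

    name: str
    field: PottsField | None = None
    cells: list[CellState] = dc_field(default_factory=list)
    state: SimulationState | None = None
    extras: dict = dc_field(default_factory=dict)


def _state_from(field: PottsField, cells: list[CellState], rng=None) -> SimulationState:
    n = field.n_cells
    centers = np.zeros((n + 1, 2))
    pol = np.zeros((n + 1, 2))
    pol[1:, 0] = 1.0
    for c in cells:
        centers[c.index] = c.center
        pol[c.index] = c.polarity
    return SimulationState(
        field=field,
        centers=centers,
        polarities=pol,
        migrating=np.ones(n + 1, dtype=np.uint8),
        phase_remaining=np.full(n + 1, 50, dtype=np.int64),
        rng=rng or np.random.default_rng(0),
    )


def make_fixture(name: str, params: ModelParams | None = None, seed: int = 0) -> Fixture:
    """Construct one of the named deterministic fixtures."""
    if name == "single_cell_torus":
        # one 1-site cell in an obstacle-free 12 x 12 lattice: its 8
        # neighboring pairs are all cell-ECM, so H_st = 8 * gamma_E
        p = (params or ModelParams()).replace(
            N_cells=1, L_x=12, L_y=12, V_0=1.0, kappa_0=64.0
        )
        labels = np.zeros((12, 12), dtype=np.int32)
        labels[6, 6] = 1
        field = PottsField(labels, n_cells=1)
        cells = [
            CellState(
                1, np.array([1.0, 0.0]), np.array([6.0, 6.0]), "migrating", 50
            )
        ]
        return Fixture(name, field, cells, _state_from(field, cells), {"params": p})

    if name == "two_cell_contact":
        # two 8 x 8 cells sharing a vertical face inside a 20 x 24 channel
        p = (params or ModelParams()).replace(
            N_cells=2, L_x=20, L_y=24, warmup_cycles=0, measure_cycles=1
        )
        field = build_channel(p)
        field.labels[2:10, 4:12] = 1
        field.labels[10:18, 4:12] = 2
        cells = [
            CellState(1, np.array([0.0, 1.0]), np.array([5.5, 7.5]), "migrating", 50),
            CellState(2, np.array([0.0, -1.0]), np.array([13.5, 7.5]), "migrating", 50),
        ]
        return Fixture(name, field, cells, _state_from(field, cells), {"params": p})

    if name == "packed_channel":
        p = params or ModelParams()
        state = initial_state(p, seed)
        return Fixture(name, state.field, state.cells, state, {"params": p})

    if name == "direction_sets":
        rng = np.random.default_rng(seed)
        n, t = 48, 100
        ordered = np.tile(np.array([0.0, 1.0]), (t, n, 1))
        ang4 = np.deg2rad([0.0, 90.0, 180.0, 270.0])
        symmetric = np.tile(
            np.stack([np.cos(ang4), np.sin(ang4)], axis=1), (t, n // 4, 1)
        )
        ang = rng.uniform(0, 2 * np.pi, size=(t, n))
        uniform = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        return Fixture(
            name,
            extras={"ordered": ordered, "symmetric": symmetric, "uniform": uniform},
        )

    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")


@dataclass(frozen=True)
class SweepPlan:
    """Grid, replication, and scale of an adhesion-strength sweep."""

    gamma_r_grid: tuple[float, ...] = DEFAULT_GAMMA_R_GRID
    seeds: tuple[int, ...] = (1, 2, 3)
    scale: str = "reduced"  # "full" | "reduced"

    def __post_init__(self):
        g = self.gamma_r_grid
        if list(g) != sorted(set(g)):
            raise ValueError("gamma_r_grid must be strictly increasing")
        if self.scale not in ("full", "reduced"):
            raise ValueError(f"scale must be 'full' or 'reduced', got {self.scale!r}")

    def resolve_params(self, base: ModelParams | None = None) -> ModelParams:
        """Parameters the sweep actually runs.

        ``scale="full"`` uses ``base`` exactly as given; ``"reduced"``
        overlays the reduced-channel geometry and protocol (including its
        warm-up and measurement lengths) on top of ``base``.
        """
        base = base or ModelParams()
        return base if self.scale == "full" else reduced_params(base)


def adhesion_sweep(
    plan: SweepPlan,
    params: ModelParams | None = None,
    out_path=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the sweep and tabulate (Gamma_R, seed, P, v, ...) rows.

    Every grid point re-runs the full warm-up + measurement protocol from
    its own seed; rows are flushed to ``out_path`` (TSV) as they complete
    so an aborted sweep leaves partial results behind.
    """
    base = plan.resolve_params(params)
    jobs = [(g, s) for g in plan.gamma_r_grid for s in plan.seeds]
    if progress:
        from tqdm import tqdm

        jobs = tqdm(jobs, desc="adhesion sweep")
    rows: list[dict] = []
    for gamma_r, seed in jobs:
        p = base.replace(Gamma_R=gamma_r)
        log: list[dict] = []
        traj = run_simulation(p, seed, log=log)
        rows.append(
            dict(
                Gamma_R=gamma_r,
                seed=seed,
                P=ordering_indicator(traj),
                v=mean_velocity(traj),
                mean_volume=float(np.mean([r["mean_volume"] for r in log])),
                acceptance_rate=float(np.mean([r["acceptance"] for r in log])),
            )
        )
        if out_path is not None:
            sweep_frame(rows).to_csv(out_path, sep="\t", index=False)
    return sweep_frame(rows)


def sweep_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Seed-averaged P and v per adhesion strength."""
    return (
        df.groupby("Gamma_R", as_index=False)[["P", "v"]]
        .mean()
        .sort_values("Gamma_R", ignore_index=True)
    )


# -- rendering ---------------------------------------------------------------

def render_frame(
    field: PottsField,
    polarities: np.ndarray | None = None,
    centers: np.ndarray | None = None,
    upscale: int = 4,
) -> np.ndarray:
    """One RGB frame of the label raster (ECM white, obstacles black).

    Cells get colors cycled from a qualitative map; if polarities and
    centers are given, leading-process arrows are drawn from each center.
    """
    import matplotlib

    labels = field.labels
    n = field.n_cells
    cmap = matplotlib.colormaps["tab20"]
    lut = np.empty((n + 2, 3))
    lut[0] = (1.0, 1.0, 1.0)                 # ECM: white
    lut[field.obstacle_label] = (0.0, 0.0, 0.0)  # obstacle: black
    for m in range(1, n + 1):
        lut[m] = cmap((m - 1) % 20)[:3]
    img = (lut[labels] * 255).astype(np.uint8)
    img = np.repeat(np.repeat(img, upscale, axis=0), upscale, axis=1)
    if polarities is not None and centers is not None:
        _draw_arrows(img, centers, polarities, upscale, labels.shape[1])
    return img


def _draw_arrows(img, centers, polarities, upscale, L_y, length=6.0):
    """Rasterize unit-length polarity arrows (simple line stamps)."""
    for (cx, cy), (px, py) in zip(centers, polarities):
        cy = cy % L_y
        for t in np.linspace(0.0, length, int(length * upscale)):
            ix = int(round((cx + t * px) * upscale))
            iy = int(round((cy + t * py) * upscale)) % img.shape[1]
            if 0 <= ix < img.shape[0]:
                img[ix, iy] = (40, 40, 40)


def render_frames(snapshots, upscale: int = 4) -> list[np.ndarray]:
    """Frames for a sequence of (field, centers, polarities) snapshots."""
    out = []
    for snap in snapshots:
        if isinstance(snap, PottsField):
            out.append(render_frame(snap, upscale=upscale))
        else:
            fld, cen, pol = snap
            out.append(render_frame(fld, pol, cen, upscale))
    return out


def write_movie(frames, path, fps: int = 10) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.stack(frames), fps=fps)
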