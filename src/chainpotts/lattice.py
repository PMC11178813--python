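"""Lattice geometry, Potts label field, and initial configurations.

The simulation domain is an ``L_x x L_y`` square lattice: a migration
channel whose two edge columns (``x = 0`` and ``x = L_x - 1``) are filled
with obstacles so cells cannot leave in x, while y is periodic so cells can
migrate over distances much longer than their own size.  Site labels are
0 for extracellular matrix (ECM), ``1..N`` for cells and ``N + 1`` for the
obstacle.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np

from .params import ModelParams

ECM = 0

Phase = Literal["resting", "migrating"]


class PlacementError(RuntimeError):
    """Initial cell placement could not be completed."""


@dataclass
class PottsField:
    """Integer label raster over the lattice."""

    labels: np.ndarray  # (L_x, L_y) int32
    n_cells: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def obstacle_label(self) -> int:
        return self.n_cells + 1

    def obstacle_mask(self) -> np.ndarray:
        return self.labels == self.obstacle_label

    def volumes(self) -> np.ndarray:
        """Site count per cell label, index 1..N (index 0 unused)."""
        return np.bincount(
            self.labels.ravel(), minlength=self.n_cells + 2
        )[: self.n_cells + 1]

    def cell_labels(self) -> np.ndarray:
        """Distinct cell labels present in the field."""
        present = np.unique(self.labels)
        return present[(present >= 1) & (present <= self.n_cells)]

    def copy(self) -> "PottsField":
        return PottsField(self.labels.copy(), self.n_cells)

    def to_text(self) -> str:
        """Tab-separated raster, one lattice row per line."""
        return "\n".join("\t".join(str(v) for v in row) for row in self.labels)

    @classmethod
    def from_text(cls, text: str, n_cells: int) -> "PottsField":
        rows = [
            [int(v) for v in line.split("\t")]
            for line in text.strip().splitlines()
        ]
        return cls(np.array(rows, dtype=np.int32), n_cells)


@dataclass
class CellState:
    """Slow per-cell variables: polarity, center, and saltatory phase."""

    index: int
    polarity: np.ndarray  # unit 2-vector
    center: np.ndarray    # continuous 2-vector, y unwrapped
    phase: Phase
    phase_remaining: int


@dataclass
class SimulationState:
    """Full mutable simulation state (field + slow variables + clocks).

    Per-cell quantities are stored as arrays of length ``N + 1`` whose row 0
    is unused, so cell labels index them directly.  ``centers[:, 1]`` is
    kept in unwrapped y so displacements across the periodic seam are real
    motion.
    """

    field: PottsField
    centers: np.ndarray      # (N+1, 2) float64
    polarities: np.ndarray   # (N+1, 2) float64, unit rows for 1..N
    migrating: np.ndarray    # (N+1,) uint8; 1 = migrating, 0 = resting
    phase_remaining: np.ndarray  # (N+1,) int64, >= 1 for cells
    mcs_clock: int = 0
    rng: np.random.Generator = dc_field(
        default_factory=lambda: np.random.default_rng(0)
    )

    @property
    def n_cells(self) -> int:
        return self.field.n_cells

    @property
    def cells(self) -> list[CellState]:
        """Per-cell view (copies) in the spec's cell-state vocabulary."""
        return [
            CellState(
                index=m,
                polarity=self.polarities[m].copy(),
                center=self.centers[m].copy(),
                phase="migrating" if self.migrating[m] else "resting",
                phase_remaining=int(self.phase_remaining[m]),
            )
            for m in range(1, self.n_cells + 1)
        ]

    def copy(self) -> "SimulationState":
        import copy as _copy

        return SimulationState(
            field=self.field.copy(),
            centers=self.centers.copy(),
            polarities=self.polarities.copy(),
            migrating=self.migrating.copy(),
            phase_remaining=self.phase_remaining.copy(),
            mcs_clock=self.mcs_clock,
            rng=_copy.deepcopy(self.rng),
        )


def neighbors(
    site: tuple[int, int], L_x: int, L_y: int
) -> list[tuple[int, int]]:
    """Nearest + next-nearest neighbors of ``site``; y wraps, x clips.

    The clipped edge columns are obstacles in every scenario, so clipping
    never removes a site that dynamics could reach.
    """
    x, y = site
    if not (0 <= x < L_x and 0 <= y < L_y):
        raise ValueError(f"site {site} outside {L_x} x {L_y} lattice")
    out = []
    for dx in (-1, 0, 1):
        nx = x + dx
        if nx < 0 or nx >= L_x:
            continue
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            out.append((nx, (y + dy) % L_y))
    return out


def forward_pairs(L_x: int, L_y: int):
    """Every unordered neighboring site pair exactly once.

    Yields ``((x, y), (nx, ny))`` using the forward half of the
    8-neighborhood; y wraps, x clips.
    """
    for x in range(L_x):
        for y in range(L_y):
            for dx, dy in ((0, 1), (1, -1), (1, 0), (1, 1)):
                nx = x + dx
                if nx >= L_x:
                    continue
                yield (x, y), (nx, (y + dy) % L_y)


def build_channel(params: ModelParams) -> PottsField:
    """The empty migration channel: obstacle walls at x = 0 and x = L_x - 1."""
    labels = np.zeros((params.L_x, params.L_y), dtype=np.int32)
    labels[0, :] = params.obstacle_label
    labels[-1, :] = params.obstacle_label
    return PottsField(labels, params.N_cells)


def random_phase_init(
    params: ModelParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random initial phase and a fresh duration for every cell."""
    from .dynamics import sample_phase_duration

    n = params.N_cells
    migrating = np.zeros(n + 1, dtype=np.uint8)
    remaining = np.ones(n + 1, dtype=np.int64)
    migrating[1:] = rng.integers(0, 2, size=n)
    for m in range(1, n + 1):
        remaining[m] = sample_phase_duration(params, rng)
    return migrating, remaining


def place_initial_cells(
    field: PottsField, params: ModelParams, seed
) -> SimulationState:
    """Seed the channel with N square cells of V_0 sites each.

    Cells are axis-aligned ``side x side`` squares dropped on randomly
    chosen non-overlapping slots of an aligned grid inside the channel
    (the channel packs cells densely enough that unconstrained random
    placement would stall).  Polarities are uniform on the unit circle;
    phases and durations come from the saltatory scheduler.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    side = params.cell_side
    n = params.N_cells
    x_slots = (params.L_x - 2) // side
    y_slots = params.L_y // side
    if x_slots * y_slots < n:
        raise PlacementError(
            f"channel interior holds only {x_slots * y_slots} cell slots "
            f"of side {side}, need {n}"
        )
    chosen = rng.choice(x_slots * y_slots, size=n, replace=False)

    labels = field.labels
    centers = np.zeros((n + 1, 2), dtype=np.float64)
    for m, slot in enumerate(chosen, start=1):
        x0 = 1 + (slot // y_slots) * side
        y0 = (slot % y_slots) * side
        if np.any(labels[x0:x0 + side, y0:y0 + side] != ECM):
            raise PlacementError(f"slot for cell {m} is occupied")
        labels[x0:x0 + side, y0:y0 + side] = m
        centers[m] = (x0 + (side - 1) / 2.0, y0 + (side - 1) / 2.0)

    angles = rng.uniform(0.0, 2.0 * np.pi, size=n)
    polarities = np.zeros((n + 1, 2), dtype=np.float64)
    polarities[1:, 0] = np.cos(angles)
    polarities[1:, 1] = np.sin(angles)

    migrating, remaining = random_phase_init(params, rng)
    return SimulationState(
        field=field,
        centers=centers,
        polarities=polarities,
        migrating=migrating,
        phase_remaining=remaining,
        rng=rng,
    )


def initial_state(params: ModelParams, seed) -> SimulationState:
    """Build the channel and place cells in one call."""
    return place_initial_cells(build_channel(params), params, seed)
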