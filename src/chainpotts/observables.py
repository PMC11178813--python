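"""Summary statistics of a run: polarity order and mean migration velocity.

The two headline observables are

* the ordering indicator ``P = | <p_m(t)>_{m,t} |`` — the norm of the
  polarity vector averaged over cells and measurement cycles.  ``P = 1``
  for perfectly aligned polarities and ``P -> 0`` for uniformly random
  ones, so ``P`` detects the emergence of a collectively ordered
  (chain-like) migration direction;
* the mean velocity ``v = | <d_m(w)>_{m,w} |`` — the norm of the windowed
  displacement averaged over cells and windows, in lattice units per
  window (a window is ``disp_window_cycles`` saltatory cycles).  ``v`` is
  finite only when the population is actually conveyed in a common
  direction; incoherent motion cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .lattice import SimulationState


@dataclass
class Trajectory:
    """Per-cycle polarity and center time series of one measurement period.

    ``polarities`` has shape (T, N, 2); ``centers`` has shape (T+1, N, 2)
    (the leading snapshot is the state at measurement start) with y in
    unwrapped coordinates, so displacement across the periodic seam counts
    as real motion.
    """

    polarities: np.ndarray
    centers: np.ndarray
    window_cycles: int = 5
    final_state: SimulationState | None = field(default=None, repr=False)
    #: optional (cycle, label raster) pairs kept during the run
    snapshots: list = field(default_factory=list, repr=False)

    @property
    def n_cycles(self) -> int:
        return self.polarities.shape[0]

    @property
    def n_cells(self) -> int:
        return self.polarities.shape[1]

    def window_displacements(self) -> np.ndarray:
        """Displacement per window, shape (n_windows, N, 2).

        Window k spans cycles ``[k w, (k+1) w)``; the displacement is the
        center change over the window.
        """
        w = self.window_cycles
        n_win = self.n_cycles // w
        if n_win < 1:
            raise ValueError(
                f"trajectory of {self.n_cycles} cycles has no full "
                f"{w}-cycle window"
            )
        marks = self.centers[: n_win * w + 1 : w]
        return np.diff(marks, axis=0)

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cycle, cell, px, py, cx, cy (cycle 0 = start)."""
        T, N = self.n_cycles, self.n_cells
        cyc = np.repeat(np.arange(T + 1), N)
        cell = np.tile(np.arange(1, N + 1), T + 1)
        pol = np.concatenate([np.full((1, N, 2), np.nan), self.polarities])
        return pd.DataFrame(
            dict(
                cycle=cyc,
                cell=cell,
                px=pol[:, :, 0].ravel(),
                py=pol[:, :, 1].ravel(),
                cx=self.centers[:, :, 0].ravel(),
                cy=self.centers[:, :, 1].ravel(),
            )
        )

    def write_tsv(self, path) -> None:
        df = self.to_frame()
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read_tsv(cls, path, window_cycles: int = 5) -> "Trajectory":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        T = int(df["cycle"].max())
        N = int(df["cell"].max())
        pol = np.ascontiguousarray(
            df[["px", "py"]].to_numpy().reshape(T + 1, N, 2)[1:]
        )
        cen = np.ascontiguousarray(
            df[["cx", "cy"]].to_numpy().reshape(T + 1, N, 2)
        )
        return cls(polarities=pol, centers=cen, window_cycles=window_cycles)


def ordering_indicator(traj: Trajectory) -> float:
    """Norm of the time- and population-averaged polarity vector, in [0, 1]."""
    if traj.n_cycles < 1 or traj.n_cells < 1:
        raise ValueError("empty trajectory")
    return float(np.linalg.norm(traj.polarities.mean(axis=(0, 1))))


def mean_velocity(traj: Trajectory) -> float:
    """Norm of the averaged windowed displacement, lattice units per window."""
    d = traj.window_displacements()
    return float(np.linalg.norm(d.mean(axis=(0, 1))))


def diagnostics(state: SimulationState, params=None) -> dict[str, float]:
    """Structural health check of a state: volumes, labels, contacts, energy."""
    vols = state.field.volumes()[1:]
    rec = dict(
        mean_volume=float(vols.mean()),
        n_cell_labels=int(state.field.cell_labels().size),
        contact_pairs=int(
            _kernels.contact_pairs(
                state.field.labels, state.field.obstacle_label
            )
        ),
    )
    if params is not None:
        from .energy import total_energy

        rec.update(total_energy(state, params).as_dict())
    return rec


def sweep_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble adhesion-sweep rows into the canonical sorted table."""
    df = pd.DataFrame(
        rows,
        columns=[
            "Gamma_R", "seed", "P", "v", "mean_volume", "acceptance_rate",
        ],
    )
    return df.sort_values(["Gamma_R", "seed"], ignore_index=True)
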