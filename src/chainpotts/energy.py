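"""The Hamiltonian of the chain-migration Potts model.

Five terms act on the label field and the slow per-cell variables:

* surface tension ``H_st`` — gamma_E per cell–ECM neighboring pair and
  gamma_C per pair of distinct-label cells;
* volume + shape ``H_v`` — ``kappa_0 V_0 (1 - V_m/V_0)^2`` per cell plus an
  elongation penalty ``kappa_2 (1 - xi^2)`` per cell site, where ``xi`` is
  the direction cosine of the site seen from the cell center along the
  polarity, so a cell pays least when stretched along its polarity;
* motility ``H_m`` — ``-gamma_P (xi + xi')`` on cell–cell contact pairs:
  a cell in contact with another lowers its energy by advancing boundary
  toward its polarity (contact-dependent motility);
* cell–cell adhesion ``H_cca`` — ``-Gamma_R (1 + lam xi)(1 + lam xi')`` on
  the same contact pairs; ``lam`` biases adhesion toward the cell front;
* wall ``H_w`` — gamma_W per cell–obstacle neighboring pair.

All pair sums run over unordered nearest + next-nearest neighboring pairs,
each counted once.  These functions are deliberately direct transcriptions
(plain loops) used as the reference path; the Monte Carlo engine uses the
compiled incremental form in :mod:`chainpotts._kernels`, whose exact
agreement with this module is a tested invariant.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .lattice import ECM, CellState, PottsField, SimulationState, forward_pairs
from .params import ModelParams


class IllegalProposalError(ValueError):
    """A copy proposal that the dynamics must never evaluate."""


@dataclass(frozen=True)
class EnergyBreakdown:
    """The five Hamiltonian terms and their sum, in model energy units."""

    H_st: float
    H_v: float
    H_m: float
    H_cca: float
    H_w: float

    @property
    def H_total(self) -> float:
        return self.H_st + self.H_v + self.H_m + self.H_cca + self.H_w

    def as_dict(self) -> dict[str, float]:
        d = asdict(self)
        d["H_total"] = self.H_total
        return d


def direction_cosine(
    site: tuple[float, float],
    center: np.ndarray,
    polarity: np.ndarray,
    L_y: int,
) -> float:
    """Direction cosine ``e_m(r) . p_m`` of a site seen from a cell center.

    ``e_m(r)`` is the unit vector from the center to the site, with the y
    displacement taken as the minimal periodic image.  Defined as 0 at the
    center itself, where the unit vector is undefined.
    """
    return float(
        _kernels.xi_site(
            float(site[0]), float(site[1]),
            float(center[0]), float(center[1]),
            float(polarity[0]), float(polarity[1]),
            L_y,
        )
    )


def _is_cell(label: int, obstacle: int) -> bool:
    return label != ECM and label != obstacle


def surface_tension_energy(field: PottsField, params: ModelParams) -> float:
    """gamma_E per cell–ECM pair plus gamma_C per distinct cell–cell pair."""
    labels = field.labels
    obst = field.obstacle_label
    e = 0.0
    for (x, y), (nx, ny) in forward_pairs(*labels.shape):
        m, n = int(labels[x, y]), int(labels[nx, ny])
        if m == n:
            continue
        mc, nc = _is_cell(m, obst), _is_cell(n, obst)
        if mc and nc:
            e += params.gamma_C
        elif (mc and n == ECM) or (nc and m == ECM):
            e += params.gamma_E
    return e


def wall_energy(field: PottsField, params: ModelParams) -> float:
    """gamma_W per cell–obstacle neighboring pair."""
    labels = field.labels
    obst = field.obstacle_label
    k = 0
    for (x, y), (nx, ny) in forward_pairs(*labels.shape):
        m, n = int(labels[x, y]), int(labels[nx, ny])
        if (m == obst and _is_cell(n, obst)) or (n == obst and _is_cell(m, obst)):
            k += 1
    return params.gamma_W * k


def volume_shape_energy(
    field: PottsField, cells: Sequence[CellState], params: ModelParams
) -> float:
    """Volume constriction plus the elongation-shape penalty.

    The elongation sum runs over every site of each cell (not only the
    boundary), as the per-site Kronecker delta dictates.
    """
    labels = field.labels
    L_y = labels.shape[1]
    vols = field.volumes()
    e = 0.0
    by_label = {c.index: c for c in cells}
    for m, cell in by_label.items():
        e += params.kappa_0 * params.V_0 * (1.0 - vols[m] / params.V_0) ** 2
        for x, y in zip(*np.nonzero(labels == m)):
            xi = direction_cosine((x, y), cell.center, cell.polarity, L_y)
            e += params.kappa_2 * (1.0 - xi * xi)
    return e


def _contact_pair_terms(
    field: PottsField, cells: Sequence[CellState], params: ModelParams
):
    """Yield (xi, xi') for every unordered distinct cell–cell contact pair."""
    labels = field.labels
    L_y = labels.shape[1]
    obst = field.obstacle_label
    by_label = {c.index: c for c in cells}
    for (x, y), (nx, ny) in forward_pairs(*labels.shape):
        m, n = int(labels[x, y]), int(labels[nx, ny])
        if m == n or not (_is_cell(m, obst) and _is_cell(n, obst)):
            continue
        cm, cn = by_label[m], by_label[n]
        yield (
            direction_cosine((x, y), cm.center, cm.polarity, L_y),
            direction_cosine((nx, ny), cn.center, cn.polarity, L_y),
        )


def motility_energy(
    field: PottsField, cells: Sequence[CellState], params: ModelParams
) -> float:
    """Contact-dependent motility: -gamma_P (xi + xi') per contact pair."""
    return -params.gamma_P * sum(
        xi + xin for xi, xin in _contact_pair_terms(field, cells, params)
    )


def adhesion_energy(
    field: PottsField, cells: Sequence[CellState], params: ModelParams
) -> float:
    """Front-biased adhesion: -Gamma_R (1 + lam xi)(1 + lam xi') per pair."""
    return -params.Gamma_R * sum(
        (1.0 + params.lam * xi) * (1.0 + params.lam * xin)
        for xi, xin in _contact_pair_terms(field, cells, params)
    )


def total_energy(state: SimulationState, params: ModelParams) -> EnergyBreakdown:
    """All five terms of the Hamiltonian for the current state."""
    cells = state.cells
    return EnergyBreakdown(
        H_st=surface_tension_energy(state.field, params),
        H_v=volume_shape_energy(state.field, cells, params),
        H_m=motility_energy(state.field, cells, params),
        H_cca=adhesion_energy(state.field, cells, params),
        H_w=wall_energy(state.field, params),
    )


def delta_energy_for_copy(
    state: SimulationState,
    source: tuple[int, int],
    target: tuple[int, int],
    params: ModelParams,
) -> float:
    """Energy change of copying the source site's label onto the target site.

    Centers and polarities are held fixed (slow variables, updated once per
    Monte Carlo step).  Raises :class:`IllegalProposalError` for proposals
    the dynamics must reject outright: an obstacle source or target, or a
    copy that would erase a cell's last site.
    """
    labels = state.field.labels
    obst = state.field.obstacle_label
    src = int(labels[source])
    tgt = int(labels[target])
    if src == obst or tgt == obst:
        raise IllegalProposalError("obstacle sites never change label")
    vols = state.field.volumes()
    if tgt != ECM and vols[tgt] <= 1:
        raise IllegalProposalError(
            f"copy would erase the last site of cell {tgt}"
        )
    if src == tgt:
        return 0.0
    vols_ext = np.zeros(state.n_cells + 2, dtype=np.int64)
    vols_ext[: state.n_cells + 1] = vols
    return float(
        _kernels.delta_H(
            labels, vols_ext,
            np.ascontiguousarray(state.centers[:, 0]),
            np.ascontiguousarray(state.centers[:, 1] % labels.shape[1]),
            np.ascontiguousarray(state.polarities[:, 0]),
            np.ascontiguousarray(state.polarities[:, 1]),
            int(target[0]), int(target[1]), src,
            params.gamma_E, params.gamma_C, params.gamma_P, params.gamma_W,
            params.Gamma_R, params.lam,
            params.kappa_0, params.V_0, params.kappa_2,
            obst,
        )
    )
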