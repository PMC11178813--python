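"""Model parameters for the chain-migration cellular Potts model.

Defaults are the reference parameterization of the migration study.  Energies are in model
units (the Metropolis acceptance uses ``exp(-beta * dH)``); lengths are in
lattice spacings; times are in Monte Carlo steps (MCS) unless a field name
says cycles, where one *cycle* is the typical saltatory period of
``mcs_per_cycle`` MCS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace


class ParameterError(ValueError):
    """A parameter set violates a model invariant."""


@dataclass(frozen=True)
class ModelParams:
    """Every tunable of the model, with the reference defaults.

    Attributes
    ----------
    gamma_E : float
        Cell–ECM interface tension (energy per neighboring site pair).
    gamma_C : float
        Cell–cell interface tension.  Together with ``gamma_E`` it must
        satisfy ``2*gamma_E < gamma_C`` for ECM to invade gaps between
        cells, which stabilizes separated cells (violations warn).
    gamma_P : float
        Motility strength; drives boundary sites of contacting cells in
        the polarity direction.
    gamma_W : float
        Cell–obstacle repulsion (set well above ``gamma_E``).
    kappa_0, V_0 : float
        Volume stiffness and target volume (lattice sites) of each cell.
    kappa_2 : float
        Strength of the elongation-shape constriction along the polarity.
    Gamma_R : float
        Cell–cell adhesion strength, the swept control parameter.  The
        default 0.0 means no extra adhesion; sweeps set it explicitly.
    lam : float
        Front/rear adhesion imbalance, ``0 <= lam < 1``.
    beta : float
        Inverse fluctuation scale of shape change in the Metropolis rule.
    a : float
        Lattice spacing.
    tau_cycles : float
        Polarity persistence time, in saltatory cycles.
    N_cells : int
        Number of cells; conserved during a run.
    L_x, L_y : int
        Lattice dimensions.  The two columns ``x = 0`` and ``x = L_x - 1``
        are obstacle walls; ``y`` is periodic.
    mcs_per_cycle : int
        Monte Carlo steps per typical saltatory cycle.
    phase_mean, phase_sd : float
        Normal-distribution parameters (MCS) of the resting/migrating
        phase durations; draws are rounded and resampled until >= 1.
    warmup_cycles, measure_cycles : int
        Discarded relaxation period and measurement period, in cycles.
    disp_window_cycles : int
        Cycles per displacement window for the mean-velocity statistic;
        must lie in 2..10.
    connectivity : bool
        If True, copies that would locally disconnect the losing cell are
        rejected (cells stay simply connected).  Off by default: the model's
        treadmilling motion proceeds largely through rough-boundary site
        exchange that a strict local-connectivity rule suppresses.
    """

    gamma_E: float = 3.0
    gamma_C: float = 8.0
    gamma_P: float = 1.0
    gamma_W: float = 13.0
    kappa_0: float = 64.0
    V_0: float = 64.0
    kappa_2: float = 5.0
    Gamma_R: float = 0.0
    lam: float = 0.3
    beta: float = 0.2
    a: float = 1.0
    tau_cycles: float = 5.0
    N_cells: int = 48
    L_x: int = 35
    L_y: int = 192
    mcs_per_cycle: int = 100
    phase_mean: float = 50.0
    phase_sd: float = 50.0
    warmup_cycles: int = 1000
    measure_cycles: int = 5000
    disp_window_cycles: int = 5
    connectivity: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def tau_mcs(self) -> float:
        """Polarity persistence time in Monte Carlo steps."""
        return self.tau_cycles * self.mcs_per_cycle

    @property
    def obstacle_label(self) -> int:
        return self.N_cells + 1

    @property
    def attempts_per_step(self) -> int:
        """Copy attempts per Monte Carlo step (16 per lattice site)."""
        return 16 * self.L_x * self.L_y

    @property
    def interior_sites(self) -> int:
        """Non-obstacle sites of the channel."""
        return (self.L_x - 2) * self.L_y

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ParameterError` on invariant violations.

        The ECM-stability condition ``2*gamma_E < gamma_C`` is emitted as a
        loud warning rather than an error, so the unstable regime remains
        explorable on purpose.
        """
        nonneg = (
            "gamma_E", "gamma_C", "gamma_P", "gamma_W",
            "kappa_0", "V_0", "kappa_2", "beta",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.lam < 1.0:
            raise ParameterError(f"lam must lie in [0, 1), got {self.lam}")
        if not 2 <= self.disp_window_cycles <= 10:
            raise ParameterError(
                f"disp_window_cycles must lie in 2..10, got {self.disp_window_cycles}"
            )
        if self.L_x < 3 or self.L_y < 1:
            raise ParameterError(f"lattice {self.L_x} x {self.L_y} too small")
        if self.N_cells < 1:
            raise ParameterError("N_cells must be >= 1")
        if self.mcs_per_cycle < 1 or self.tau_cycles <= 0:
            raise ParameterError("mcs_per_cycle and tau_cycles must be positive")
        if self.phase_mean <= 0 or self.phase_sd <= 0:
            raise ParameterError("phase_mean and phase_sd must be positive")
        if self.a <= 0:
            raise ParameterError("lattice spacing a must be positive")
        if self.warmup_cycles < 0 or self.measure_cycles < 1:
            raise ParameterError("warmup_cycles >= 0 and measure_cycles >= 1 required")
        if self.N_cells * self.V_0 > self.interior_sites:
            raise ParameterError(
                f"total target cell volume {self.N_cells * self.V_0:g} exceeds the "
                f"{self.interior_sites} non-obstacle sites of the channel"
            )
        if not 2 * self.gamma_E < self.gamma_C:
            warnings.warn(
                f"2*gamma_E = {2 * self.gamma_E:g} >= gamma_C = {self.gamma_C:g}: "
                "ECM will not invade gaps between cells, so separated cells are "
                "not stabilized (stability needs 2*gamma_E < gamma_C)",
                stacklevel=2,
            )

    @property
    def cell_side(self) -> int:
        """Side of the square initial cell footprint (V_0 must be square)."""
        side = round(math.sqrt(self.V_0))
        if side * side != self.V_0:
            raise ParameterError(
                f"initial placement needs a square target volume, got V_0 = {self.V_0}"
            )
        return side

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields changed (re-validated)."""
        return replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


#: reduced-scale variant used by desk-size experiments: same packing
#: fraction as the full channel (12*64 / (22*64) ~ 0.55 of interior) and the
#: same energetic parameters, on a 24 x 64 channel.
REDUCED_OVERRIDES = dict(
    L_x=24, L_y=64, N_cells=12, warmup_cycles=200, measure_cycles=500,
)


def reduced_params(base: ModelParams | None = None, **extra) -> ModelParams:
    """The reduced-scale parameter set (24 x 64, 12 cells)."""
    base = base or ModelParams()
    return base.replace(**{**REDUCED_OVERRIDES, **extra})
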