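"""1-D membrane-zone transport: convection, dispersion and binding coupling.

Each virtual membrane zone is a thin flat slab traversed at a constant
interstitial velocity.  The mobile-phase mass balance per zone is

    dc/dt = Da * d2c/dx2 - v * dc/dx - ((1 - eps)/eps) * dq_total/dt

with the bound-phase rates supplied by :mod:`zrm.kinetics`.  The factor
``(1 - eps)/eps`` converts bound concentrations, stored per unit volume
of solid membrane, to the mobile-phase (void) volume basis.

Discretization is method-of-lines on a cell-centred grid: first-order
upwind for convection, second-order central for dispersion, Dirichlet
inlet (the feeding tank's outlet concentration) and zero-gradient
outlet.  Dispersion in the membrane itself is physically negligible at
the operating Peclet numbers (the hold-up tanks carry the system
dispersion), so Da defaults to the molecular diffusion coefficient of
BSA; the first-order upwind scheme adds a controlled numerical
dispersion of ~v*dx/2 which the grid-convergence tests bound.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .kinetics import (
    BoundState,
    LangmuirParams,
    SpreadingParams,
    _langmuir_rhs,
    _spreading_rhs,
)

__all__ = [
    "MembraneGeometry",
    "MembraneZone",
    "ZoneState",
    "zone_rhs",
    "solid_membrane_volume",
]

#: molecular diffusion coefficient of BSA in aqueous buffer, cm^2/s
DEFAULT_DISPERSION = 6e-7

#: default number of grid cells per membrane zone
DEFAULT_GRID_CELLS = 60


@dataclass(frozen=True)
class MembraneGeometry:
    """Geometry of a whole membrane bed (before zonal partitioning).

    Parameters
    ----------
    L : float
        Bed height, cm (0.22 cm for the capsules studied).
    A : float
        Total frontal area, cm^2.
    eps : float
        Bed porosity (void fraction), default 0.70.
    Da : float
        Axial dispersion coefficient, cm^2/s.
    N : int
        Grid cells per zone.
    """

    L: float
    A: float
    eps: float = 0.70
    Da: float = DEFAULT_DISPERSION
    N: int = DEFAULT_GRID_CELLS

    def __post_init__(self) -> None:
        if self.L <= 0 or self.A <= 0:
            raise ValueError("bed height and frontal area must be positive")
        if not 0 < self.eps < 1:
            raise ValueError("porosity must lie in (0, 1)")

    @property
    def volume(self) -> float:
        """Total membrane bed volume, mL (= cm^3)."""
        return self.L * self.A


@dataclass(frozen=True)
class MembraneZone:
    """One virtual zone of the membrane bed: a flat slab at constant velocity.

    ``v`` is the interstitial linear velocity (cm/s); ``A`` the zone's
    frontal area (cm^2) used to convert between volumetric and linear
    flow (volumetric flow through the zone is ``eps * A * v``).
    """

    L: float
    v: float
    Da: float
    eps: float
    N: int
    A: float

    def __post_init__(self) -> None:
        if self.L <= 0 or self.v <= 0 or self.A <= 0:
            raise ValueError("L, v and A must be positive")
        if not 0 < self.eps < 1:
            raise ValueError("porosity must lie in (0, 1)")
        if self.N < 10:
            raise ValueError("at least 10 grid cells are required")

    @property
    def dx(self) -> float:
        return self.L / self.N

    @property
    def volume(self) -> float:
        """Zone bed volume, mL."""
        return self.L * self.A

    @property
    def flow(self) -> float:
        """Volumetric flow through the zone, mL/s."""
        return self.eps * self.A * self.v

    @property
    def residence_time(self) -> float:
        """Mobile-phase hold-up time L/v, s."""
        return self.L / self.v

    def with_cells(self, N: int) -> "MembraneZone":
        return replace(self, N=N)


@dataclass
class ZoneState:
    """Mobile (``c``) and bound (``bound``) state of one zone, per grid cell."""

    c: np.ndarray
    bound: BoundState | None = None


def _advection_dispersion(c: np.ndarray, c_in: float, zone: MembraneZone) -> np.ndarray:
    dx = zone.dx
    cm1 = np.empty_like(c)  # upstream neighbour
    cm1[0] = c_in
    cm1[1:] = c[:-1]
    dcdt = (zone.v / dx) * (cm1 - c)
    if zone.Da > 0:
        cp1 = np.empty_like(c)
        cp1[:-1] = c[1:]
        cp1[-1] = c[-1]  # zero-gradient outlet
        dcdt += (zone.Da / dx**2) * (cp1 - 2.0 * c + cm1)
    return dcdt


def zone_rhs(state: ZoneState, c_inlet: float, zone: MembraneZone, binding):
    """Time derivatives of a zone's state.

    Returns a ``ZoneState`` holding dc/dt and the bound-phase rates.
    ``binding`` is ``None`` (non-binding conditions), a ``LangmuirParams``
    or a ``SpreadingParams``.
    """
    if c_inlet < 0:
        raise ValueError("inlet concentration must be non-negative")
    c = np.asarray(state.c, dtype=float)
    dcdt = _advection_dispersion(c, float(c_inlet), zone)
    phase_ratio = (1.0 - zone.eps) / zone.eps
    if binding is None:
        return ZoneState(c=dcdt, bound=None)
    if isinstance(binding, LangmuirParams):
        dq = _langmuir_rhs(c, state.bound.q1, binding)
        return ZoneState(c=dcdt - phase_ratio * dq, bound=BoundState(q1=dq))
    if isinstance(binding, SpreadingParams):
        dq1, dq2 = _spreading_rhs(c, state.bound.q1, state.bound.q2, binding)
        return ZoneState(
            c=dcdt - phase_ratio * (dq1 + dq2),
            bound=BoundState(q1=dq1, q2=dq2),
        )
    raise TypeError(f"unsupported binding parameter type {type(binding)!r}")


def solid_membrane_volume(V_membrane: float, eps: float) -> float:
    """Solid (skeleton) volume of a membrane bed, mL: ``V * (1 - eps)``."""
    if not 0 < eps <= 1:
        raise ValueError("porosity must lie in (0, 1]")
    if V_membrane < 0:
        raise ValueError("membrane volume must be non-negative")
    return V_membrane * (1.0 - eps)
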