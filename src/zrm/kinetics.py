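"""Adsorption/desorption rate laws for ion-exchange membrane chromatography.

Two kinetic models are provided, evaluated pointwise in the stationary
phase of a membrane zone:

* **Langmuir** — single binding state, one site type, no adsorbate
  interaction::

      dq/dt = ka * c * (qm - q) - kd * q

* **Spreading** — two bound orientations of an ellipsoidal protein
  (end-on, state 1; sideways, state 2) competing for the same sites.
  A molecule bound sideways occupies ``beta`` times the area of an
  end-on molecule, so the free-site capacity seen by all fluxes is
  ``qm - q1 - beta*q2``.  Bound molecules may also reorient::

      dq1/dt = ka1*c*F - kd1*q1 - k12*q1*F + k21*q2
      dq2/dt = ka2*c*F - kd2*q2 + k12*q1*F - k21*q2
      F      = qm - q1 - beta*q2

  The reorientation flux 1->2 is proportional to the free capacity
  (a sideways molecule needs more room), which gives the transition
  rate constant ``k12`` concentration-like units, L/(g s), and an
  initial-loading reorientation time constant of ``1/(k12*qm)``.

All bound concentrations are expressed per unit volume of *solid*
membrane (g/L solid); conversion to bed volume happens at the
transport-coupling boundary using the porosity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LangmuirParams",
    "SpreadingParams",
    "BoundState",
    "langmuir_rate",
    "spreading_rates",
    "characteristic_times",
]


@dataclass(frozen=True)
class LangmuirParams:
    """Langmuir kinetic parameters.

    Parameters
    ----------
    ka : float
        Adsorption rate constant, L/(g s).
    kd : float
        Desorption rate constant, 1/s.
    qm : float
        Maximum binding capacity, g per L of solid membrane.
    """

    ka: float
    kd: float
    qm: float

    def __post_init__(self) -> None:
        if self.ka < 0 or self.kd < 0:
            raise ValueError("rate constants must be non-negative")
        if self.qm <= 0:
            raise ValueError("binding capacity qm must be positive")

    def equilibrium(self, c):
        """Equilibrium bound concentration ``qm*ka*c/(kd + ka*c)`` at mobile c."""
        c = np.asarray(c, dtype=float)
        denom = self.kd + self.ka * c
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.where(denom > 0, self.qm * self.ka * c / denom, 0.0)
        return q[()] if q.ndim == 0 else q


@dataclass(frozen=True)
class SpreadingParams:
    """Two-orientation spreading kinetic parameters.

    ``ka1/kd1`` govern end-on (state 1) adsorption/desorption, ``ka2/kd2``
    sideways (state 2); the reduced model used for BSA sets ``ka2 = kd2 = 0``
    (no direct sideways adsorption or desorption).  ``k12`` (L/(g s)) and
    ``k21`` (1/s) are the bound-state reorientation rate constants, ``qm``
    the shared site capacity (g/L solid) and ``beta`` the area a sideways
    molecule occupies relative to an end-on one.
    """

    ka1: float
    kd1: float
    k12: float
    k21: float
    qm: float
    beta: float
    ka2: float = 0.0
    kd2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ka1", "kd1", "k12", "k21", "ka2", "kd2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.qm <= 0:
            raise ValueError("binding capacity qm must be positive")
        if self.beta <= 0:
            raise ValueError("area ratio beta must be positive")

    def free_sites(self, q1, q2):
        """Free-site capacity ``qm - q1 - beta*q2`` (g/L solid)."""
        return self.qm - np.asarray(q1) - self.beta * np.asarray(q2)


@dataclass
class BoundState:
    """Bound-phase state of one membrane zone (or a single point).

    For Langmuir kinetics only ``q1`` is used (total bound ``q``); for the
    spreading model ``q1``/``q2`` hold the end-on and sideways bound
    concentrations, g/L solid.
    """

    q1: np.ndarray
    q2: np.ndarray | None = None

    @property
    def total(self):
        """Total bound concentration q1 + q2 (g/L solid)."""
        if self.q2 is None:
            return self.q1
        return self.q1 + self.q2

    def free_sites(self, params):
        if isinstance(params, LangmuirParams):
            return params.qm - self.total
        q2 = 0.0 if self.q2 is None else self.q2
        return params.free_sites(self.q1, q2)


# -- rate evaluations ---------------------------------------------------

def _langmuir_rhs(c, q, p: LangmuirParams):
    return p.ka * c * (p.qm - q) - p.kd * q


def _spreading_rhs(c, q1, q2, p: SpreadingParams):
    free = p.qm - q1 - p.beta * q2
    trans = p.k12 * q1 * free - p.k21 * q2
    dq1 = p.ka1 * c * free - p.kd1 * q1 - trans
    dq2 = p.ka2 * c * free - p.kd2 * q2 + trans
    return dq1, dq2


def langmuir_rate(c, q, p: LangmuirParams):
    """Langmuir net adsorption rate dq/dt, g/(L solid s).

    Raises ``ValueError`` on negative concentrations or bound amounts
    exceeding capacity.
    """
    c = np.asarray(c, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(c < 0) or np.any(q < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(q > p.qm * (1 + 1e-12)):
        raise ValueError("bound amount exceeds capacity qm")
    out = _langmuir_rhs(c, q, p)
    return out[()] if np.ndim(out) == 0 else out


def spreading_rates(c, q1, q2, p: SpreadingParams):
    """Spreading-model rates (dq1/dt, dq2/dt), g/(L solid s).

    The sum of the returned rates equals the net flux removed from the
    mobile phase; reorientation fluxes cancel in the sum.
    """
    c = np.asarray(c, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    if np.any(c < 0) or np.any(q1 < 0) or np.any(q2 < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(q1 + p.beta * q2 > p.qm * (1 + 1e-9)):
        raise ValueError("occupied area q1 + beta*q2 exceeds capacity qm")
    dq1, dq2 = _spreading_rhs(c, q1, q2, p)
    if np.ndim(dq1) == 0:
        return float(dq1), float(dq2)
    return dq1, dq2


def characteristic_times(p: SpreadingParams) -> dict:
    """Characteristic time scales (s) of the spreading model on a fresh membrane.

    * ``t_ads`` = 1/(ka1*qm) — initial end-on adsorption,
    * ``t_12``  = 1/(k12*qm) — initial end-on -> sideways reorientation,
    * ``t_21``  = 1/k21      — sideways -> end-on reorientation,
    * ``t_des`` = 1/kd1      — end-on desorption.

    Zero rate constants are reported as infinite times.
    """

    def inv(x):
        return 1.0 / x if x > 0 else math.inf

    return {
        "t_ads": inv(p.ka1 * p.qm),
        "t_12": inv(p.k12 * p.qm),
        "t_21": inv(p.k21),
        "t_des": inv(p.kd1),
    }
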