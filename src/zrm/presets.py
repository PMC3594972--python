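"""Named presets: capsule geometries, fitted flow topologies and kinetics.

The flow and binding parameter sets below are published calibrations of
the two Pall Mustang Q capsules (axial XT5, radial XT140) loaded with
BSA at 1 g/L and 12 CV/min; they serve as reference points for
simulation, fixture generation and recovery tests.
"""

from __future__ import annotations

from .datagen import CapsulePreset
from .kinetics import LangmuirParams, SpreadingParams
from .network import (
    CapsuleTopology,
    SectorDistribution,
    build_axial_topology,
    build_radial_topology,
)
from .transport import DEFAULT_DISPERSION, DEFAULT_GRID_CELLS

__all__ = [
    "CAPSULES",
    "BINDING_PRESETS",
    "TOPOLOGY_PRESETS",
    "get_capsule",
    "get_binding",
    "get_topology",
]

CAPSULES = {
    # 15 stacked flat sheets, 2.20 mm bed, 22.06 cm^2 frontal area, 5 mL bed
    "XT5": CapsulePreset(
        name="XT5", V_membrane=5.0, bed_height=0.22, frontal_area=22.06,
        eps=0.70, V_holdup_upstream=3.21, V_holdup_downstream=3.21,
    ),
    # pleated radial capsule, same 2.20 mm effective bed height, 140 mL bed
    "XT140": CapsulePreset(
        name="XT140", V_membrane=140.0, bed_height=0.22,
        frontal_area=140.0 / 0.22, eps=0.70,
        V_holdup_upstream=105.0, V_holdup_downstream=45.0,
    ),
}

BINDING_PRESETS = {
    # Langmuir fit of the XT5 binding breakthrough
    "XT5-langmuir": LangmuirParams(ka=6.4e-2, kd=6e-3, qm=284.04),
    # reduced spreading-model fit (no direct sideways adsorption/desorption)
    "XT5-spreading": SpreadingParams(
        ka1=8.08e-2, kd1=1.06e-5, k12=7.37e-4, k21=9.41e-3,
        qm=289.003, beta=1.144, ka2=0.0, kd2=0.0,
    ),
}

# fitted hold-up volumes (mL) and flow fractions
_XT5_1ZONE = {"V_pfr": 2.22, "V_inner": 3.64}
_XT5_2ZONE = {"V_pfr": 3.91, "V_inner": 1.24, "V_outer": 1.69, "phi2": 0.43}
_XT140_SYM = {"V_pfr": 259.0, "V_upstream": 55.16, "V_downstream": 55.16}
_XT140_ASYM = {"V_pfr": 269.93, "V_upstream": 82.88, "V_downstream": 19.32}
# discrete 4-sector fit of the XT140 binding curve: (flow fraction, relative velocity)
_XT140_4SECTOR = SectorDistribution(
    u=(1.04, 0.82, 0.72, 0.64),
    f=(0.86, 0.066, 0.035, 0.039),
    params={"source": "discrete 4-sector fit"},
)

TOPOLOGY_PRESETS = (
    "XT5-1zone", "XT5-2zone", "XT140-sym", "XT140-asym", "XT140-4sector",
)


def get_capsule(name: str) -> CapsulePreset:
    try:
        return CAPSULES[name]
    except KeyError:
        raise KeyError(
            f"unknown capsule preset {name!r}; available: {sorted(CAPSULES)}"
        ) from None


def get_binding(name: str):
    try:
        return BINDING_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown binding preset {name!r}; available: {sorted(BINDING_PRESETS)}"
        ) from None


def get_topology(
    name: str,
    N: int = DEFAULT_GRID_CELLS,
    Da: float = DEFAULT_DISPERSION,
) -> CapsuleTopology:
    """Build a named topology preset (optionally on a custom grid)."""
    if name == "XT5-1zone":
        cap = CAPSULES["XT5"]
        p = _XT5_1ZONE
        return build_axial_topology(
            n_zones=1, V_pfr=p["V_pfr"], tank_volumes=[p["V_inner"]],
            phi=[1.0], Q=cap.Q, membrane=cap.geometry(Da=Da, N=N),
        )
    if name == "XT5-2zone":
        cap = CAPSULES["XT5"]
        p = _XT5_2ZONE
        return build_axial_topology(
            n_zones=2, V_pfr=p["V_pfr"],
            tank_volumes=[p["V_inner"], p["V_outer"]],
            phi=[1.0 - p["phi2"], p["phi2"]],
            Q=cap.Q, membrane=cap.geometry(Da=Da, N=N),
        )
    if name in ("XT140-sym", "XT140-asym", "XT140-4sector"):
        cap = CAPSULES["XT140"]
        p = _XT140_SYM if name == "XT140-sym" else _XT140_ASYM
        sectors = _XT140_4SECTOR if name == "XT140-4sector" else None
        return build_radial_topology(
            n_zones=1, V_pfr=p["V_pfr"], V_upstream=p["V_upstream"],
            V_downstream=p["V_downstream"], Q=cap.Q,
            membrane=cap.geometry(Da=Da, N=N), sectors=sectors,
        )
    raise KeyError(
        f"unknown topology preset {name!r}; available: {TOPOLOGY_PRESETS}"
    )
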