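"""Virtual-zone network topology of a membrane chromatography capsule.

The zonal rate model partitions a capsule's hold-up volumes into a
directed network of ideally mixed tanks (CSTRs), the membrane bed into
parallel 1-D zones, and lumps streamlined dead volume into a plug-flow
region (PFR) in series with the network.

Two capsule families are supported:

* **axial** — flat membrane sheets stacked perpendicular to the flow.
  Hold-up zones are mirror-symmetric: solute crossing membrane zone k
  passes upstream tanks 1a..ka, the zone, then downstream tanks kb..1b
  (downstream tanks with k < n_zones receive two inlets).
* **radial** — membrane pleated around a core, fed from a peripheral
  distribution channel and collected in a central channel.  Upstream
  and downstream volumes are generally unequal, every flow path crosses
  the same number of tanks, and a single membrane zone may be split
  into angular *sectors* with different linear velocities to represent
  irregular pleat packing.

Tank inlets are stored as (source node, volumetric flow) pairs; node
names are ``"feed"``, tank names, or zone names (a zone's outlet
concentration is its last grid cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .transport import MembraneGeometry, MembraneZone

__all__ = [
    "PlugFlowRegion",
    "TankSpec",
    "FlowFractions",
    "SectorDistribution",
    "ZonePlacement",
    "CapsuleTopology",
    "cstr_rhs",
    "multi_inlet_cstr_rhs",
    "sector_distribution",
    "build_axial_topology",
    "build_radial_topology",
]

FEED = "feed"


# -- elementary compartments -------------------------------------------

@dataclass(frozen=True)
class PlugFlowRegion:
    """Pure transport delay of volume ``V`` (mL); lag time is V/Q."""

    V: float

    def __post_init__(self) -> None:
        if self.V < 0:
            raise ValueError("PFR volume must be non-negative")

    def t_lag(self, Q: float) -> float:
        return self.V / Q


@dataclass
class TankSpec:
    """One ideally mixed tank.

    ``inlets`` holds (source node name, volumetric flow mL/s) pairs; the
    through-flow is their sum and the mean residence time is V/Q_through.
    """

    name: str
    V: float
    inlets: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError(f"tank {self.name}: volume must be positive")
        if not self.inlets:
            raise ValueError(f"tank {self.name}: at least one inlet required")
        if any(q <= 0 for _, q in self.inlets):
            raise ValueError(f"tank {self.name}: inlet flows must be positive")

    @property
    def Q_through(self) -> float:
        return sum(q for _, q in self.inlets)

    @property
    def tau(self) -> float:
        """Mean residence time V/Q_through, s."""
        return self.V / self.Q_through

    @property
    def tau_j(self) -> list[float]:
        """Partial residence times V/Q_j per inlet; 1/tau = sum(1/tau_j)."""
        return [self.V / q for _, q in self.inlets]

    @property
    def inlet_fractions(self) -> list[float]:
        """Flow fractions of the inlets (tau/tau_j); sum to one."""
        return [q / self.Q_through for _, q in self.inlets]


def cstr_rhs(c_out: float, c_in: float, tau: float) -> float:
    """Single-inlet CSTR balance: dc/dt = (c_in - c_out)/tau."""
    if tau <= 0:
        raise ValueError("residence time must be positive")
    return (c_in - c_out) / tau


def multi_inlet_cstr_rhs(c_out: float, c_in, tau_j) -> float:
    """Multi-inlet CSTR balance: dc/dt = sum_j c_in_j/tau_j - c_out/tau.

    The partial residence times ``tau_j = V/Q_j`` combine harmonically,
    ``1/tau = sum_j 1/tau_j``.
    """
    c_in = list(np.atleast_1d(c_in))
    tau_j = list(np.atleast_1d(tau_j))
    if not c_in or len(c_in) != len(tau_j):
        raise ValueError("need one residence time per inlet (non-empty)")
    if any(t <= 0 for t in tau_j):
        raise ValueError("residence times must be positive")
    inv_tau = sum(1.0 / t for t in tau_j)
    return sum(c / t for c, t in zip(c_in, tau_j)) - c_out * inv_tau


@dataclass(frozen=True)
class FlowFractions:
    """Per-membrane-zone fractions of the total volumetric flow; sum to one."""

    phi: tuple

    def __init__(self, phi):
        phi = tuple(float(p) for p in np.atleast_1d(phi))
        if any(p <= 0 for p in phi):
            raise ValueError("flow fractions must be positive")
        if abs(sum(phi) - 1.0) > 1e-9:
            raise ValueError(f"flow fractions must sum to 1, got {sum(phi)}")
        object.__setattr__(self, "phi", phi)

    def __len__(self):
        return len(self.phi)

    def __iter__(self):
        return iter(self.phi)

    def __getitem__(self, i):
        return self.phi[i]


# -- angular sector velocity distribution ------------------------------

@dataclass(frozen=True)
class SectorDistribution:
    """Discrete distribution of flow over relative linear velocity.

    ``u[i]`` is the linear velocity of sector i relative to the average
    linear velocity; ``f[i]`` the fraction of the total volumetric flow
    through sector i (sums to one).
    """

    u: tuple
    f: tuple
    params: dict = field(default_factory=dict)

    def __init__(self, u, f, params=None):
        u = tuple(float(x) for x in np.atleast_1d(u))
        f = tuple(float(x) for x in np.atleast_1d(f))
        if len(u) != len(f) or not u:
            raise ValueError("u and f must be non-empty and of equal length")
        if any(x <= 0 for x in u):
            raise ValueError("relative velocities must be positive")
        if any(x < 0 for x in f):
            raise ValueError("flow fractions must be non-negative")
        s = sum(f)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"sector flow fractions must sum to 1, got {s}")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "params", dict(params or {}))

    @property
    def n_sectors(self) -> int:
        return len(self.u)


def sector_distribution(
    mu: float,
    sigma: float,
    slope: float,
    n_sectors: int = 16,
    u_range: tuple = (0.3, 1.3),
) -> SectorDistribution:
    """Three-parameter flow-over-velocity distribution on an equidistant grid.

    The weight at relative velocity u is a Gaussian peak ``exp(-(u-mu)^2 /
    (2 sigma^2))``; left of the peak (u <= mu) the maximum of the Gaussian
    and a linear ramp ``slope*u`` from the origin is taken.  Weights are
    rescaled to sum to one so the total volumetric flow is preserved.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if slope < 0:
        raise ValueError("slope must be non-negative")
    if n_sectors < 1:
        raise ValueError("need at least one sector")
    if n_sectors == 1:
        # degenerate: one sector carries all flow at the peak velocity
        return SectorDistribution(
            u=[mu], f=[1.0], params=dict(mu=mu, sigma=sigma, slope=slope)
        )
    u = np.linspace(u_range[0], u_range[1], n_sectors)
    gauss = np.exp(-0.5 * ((u - mu) / sigma) ** 2)
    ramp = slope * u
    w = np.where(u <= mu, np.maximum(gauss, ramp), gauss)
    total = w.sum()
    if total <= 0:
        raise ValueError("all sector weights are zero")
    return SectorDistribution(
        u=u, f=w / total, params=dict(mu=mu, sigma=sigma, slope=slope)
    )


# -- capsule topology --------------------------------------------------

@dataclass
class ZonePlacement:
    """A membrane zone instance wired into the tank network."""

    name: str
    zone: MembraneZone
    inlet: str
    flow: float  # volumetric flow through this zone, mL/s

    def __post_init__(self) -> None:
        if self.flow <= 0:
            raise ValueError(f"zone {self.name}: flow must be positive")


@dataclass
class CapsuleTopology:
    """Complete virtual-zone network of one capsule.

    ``outlet`` names the node whose concentration is recorded by the
    detector (after the PFR time shift).  ``build_info`` retains the
    constructor arguments so calibration stages can rebuild variants
    (e.g. insert a sector distribution) and so topologies serialize.
    """

    mode: str
    Q: float
    pfr: PlugFlowRegion
    tanks: list[TankSpec]
    zones: list[ZonePlacement]
    outlet: str
    sectors: SectorDistribution | None = None
    build_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # - consistency checks -
    def validate(self) -> None:
        if self.mode not in ("axial", "radial"):
            raise ValueError("mode must be 'axial' or 'radial'")
        if self.Q <= 0:
            raise ValueError("total volumetric flow must be positive")
        names = [FEED] + [t.name for t in self.tanks] + [z.name for z in self.zones]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names in topology")
        known = set(names)
        for t in self.tanks:
            for src, _ in t.inlets:
                if src not in known:
                    raise ValueError(f"tank {t.name}: unknown inlet node {src!r}")
        for z in self.zones:
            if z.inlet not in known:
                raise ValueError(f"zone {z.name}: unknown inlet node {z.inlet!r}")
        if self.outlet not in known:
            raise ValueError(f"unknown outlet node {self.outlet!r}")
        # flow conservation: zone flows sum to Q
        zone_flow = sum(z.flow for z in self.zones)
        if abs(zone_flow - self.Q) > 1e-6 * self.Q:
            raise ValueError(
                f"zone flows sum to {zone_flow}, expected total flow {self.Q}"
            )
        self._check_connected()

    def _check_connected(self) -> None:
        """Every node must be reachable from the feed, and reach the outlet."""
        succ: dict[str, set] = {}
        for t in self.tanks:
            for src, _ in t.inlets:
                succ.setdefault(src, set()).add(t.name)
        for z in self.zones:
            succ.setdefault(z.inlet, set()).add(z.name)
        seen = {FEED}
        stack = [FEED]
        while stack:
            for nxt in succ.get(stack.pop(), ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        missing = {t.name for t in self.tanks} | {z.name for z in self.zones}
        missing -= seen
        if missing:
            raise ValueError(f"nodes unreachable from feed: {sorted(missing)}")
        if self.outlet not in seen:
            raise ValueError("outlet not reachable from feed")

    # - derived quantities -
    @property
    def flow_fractions(self) -> list[float]:
        return [z.flow / self.Q for z in self.zones]

    @property
    def tank_volume(self) -> float:
        return sum(t.V for t in self.tanks)

    @property
    def membrane_bed_volume(self) -> float:
        return sum(z.zone.volume for z in self.zones)

    def holdup_volume(self) -> float:
        """Total mobile-phase hold-up: PFR + tanks + membrane void, mL."""
        void = sum(z.zone.eps * z.zone.volume for z in self.zones)
        return self.pfr.V + self.tank_volume + void

    def t_lag(self) -> float:
        return self.pfr.t_lag(self.Q)

    # - serialization -
    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "Q_mL_per_s": self.Q,
            "V_pfr_mL": self.pfr.V,
            "outlet": self.outlet,
            "tanks": [
                {"name": t.name, "V_mL": t.V,
                 "inlets": [{"source": s, "Q_mL_per_s": q} for s, q in t.inlets]}
                for t in self.tanks
            ],
            "zones": [
                {"name": z.name, "inlet": z.inlet, "Q_mL_per_s": z.flow,
                 "L_cm": z.zone.L, "v_cm_per_s": z.zone.v,
                 "Da_cm2_per_s": z.zone.Da, "eps": z.zone.eps,
                 "N": z.zone.N, "A_cm2": z.zone.A}
                for z in self.zones
            ],
        }
        if self.sectors is not None:
            d["sectors"] = {
                "u": list(self.sectors.u),
                "f": list(self.sectors.f),
                **{k: v for k, v in self.sectors.params.items()},
            }
        if self.build_info:
            d["build_info"] = dict(self.build_info)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CapsuleTopology":
        sectors = None
        if "sectors" in d:
            s = d["sectors"]
            params = {k: v for k, v in s.items() if k not in ("u", "f")}
            sectors = SectorDistribution(u=s["u"], f=s["f"], params=params)
        return cls(
            mode=d["mode"],
            Q=d["Q_mL_per_s"],
            pfr=PlugFlowRegion(d["V_pfr_mL"]),
            tanks=[
                TankSpec(
                    name=t["name"], V=t["V_mL"],
                    inlets=[(i["source"], i["Q_mL_per_s"]) for i in t["inlets"]],
                )
                for t in d["tanks"]
            ],
            zones=[
                ZonePlacement(
                    name=z["name"],
                    inlet=z["inlet"],
                    flow=z["Q_mL_per_s"],
                    zone=MembraneZone(
                        L=z["L_cm"], v=z["v_cm_per_s"], Da=z["Da_cm2_per_s"],
                        eps=z["eps"], N=z["N"], A=z["A_cm2"],
                    ),
                )
                for z in d["zones"]
            ],
            outlet=d["outlet"],
            sectors=sectors,
            build_info=d.get("build_info", {}),
        )


# -- builders ----------------------------------------------------------

def build_axial_topology(
    n_zones: int,
    V_pfr: float,
    tank_volumes,
    phi,
    Q: float,
    membrane: MembraneGeometry,
) -> CapsuleTopology:
    """Mirror-symmetric axial-flow topology with ``n_zones`` membrane zones.

    ``tank_volumes[k]`` is the physical volume (mL) of upstream tank
    (k+1)a; downstream tanks are mirrored with identical volumes.  Zone k
    takes the fraction ``phi[k]`` of the total flow and a proportional
    share of the frontal area, so the interstitial velocity is uniform
    across zones.  ``n_zones=1`` reduces to the Roper–Lightfoot
    PFR + CSTR + membrane + CSTR chain.
    """
    if n_zones < 1:
        raise ValueError("need at least one membrane zone")
    tank_volumes = [float(v) for v in np.atleast_1d(tank_volumes)]
    if len(tank_volumes) != n_zones:
        raise ValueError(
            f"expected {n_zones} upstream tank volumes, got {len(tank_volumes)}"
        )
    phi = phi if isinstance(phi, FlowFractions) else FlowFractions(phi)
    if len(phi) != n_zones:
        raise ValueError(f"expected {n_zones} flow fractions, got {len(phi)}")

    # cumulative flow carried by upstream tank k (zones k..n downstream of it)
    tail = [sum(phi[k:]) for k in range(n_zones)]  # tail[0] == 1
    v_bar = Q / (membrane.eps * membrane.A)

    tanks: list[TankSpec] = []
    zones: list[ZonePlacement] = []
    for k in range(n_zones):
        up_src = FEED if k == 0 else f"tank{k}a"
        tanks.append(
            TankSpec(name=f"tank{k + 1}a", V=tank_volumes[k],
                     inlets=[(up_src, tail[k] * Q)])
        )
        zones.append(
            ZonePlacement(
                name=f"zone{k + 1}",
                inlet=f"tank{k + 1}a",
                flow=phi[k] * Q,
                zone=MembraneZone(
                    L=membrane.L, v=v_bar, Da=membrane.Da, eps=membrane.eps,
                    N=membrane.N, A=phi[k] * membrane.A,
                ),
            )
        )
    for k in reversed(range(n_zones)):
        inlets = [(f"zone{k + 1}", phi[k] * Q)]
        if k + 1 < n_zones:
            inlets.append((f"tank{k + 2}b", tail[k + 1] * Q))
        tanks.append(TankSpec(name=f"tank{k + 1}b", V=tank_volumes[k], inlets=inlets))

    return CapsuleTopology(
        mode="axial",
        Q=Q,
        pfr=PlugFlowRegion(V_pfr),
        tanks=tanks,
        zones=zones,
        outlet="tank1b",
        build_info={
            "family": "axial",
            "n_zones": n_zones,
            "V_pfr_mL": V_pfr,
            "tank_volumes_mL": tank_volumes,
            "phi": list(phi),
            "Q_mL_per_s": Q,
            "membrane": {
                "L_cm": membrane.L, "A_cm2": membrane.A, "eps": membrane.eps,
                "Da_cm2_per_s": membrane.Da, "N": membrane.N,
            },
        },
    )


def build_radial_topology(
    n_zones: int,
    V_pfr: float,
    V_upstream: float,
    V_downstream: float,
    Q: float,
    membrane: MembraneGeometry,
    sectors: SectorDistribution | None = None,
) -> CapsuleTopology:
    """Radial-flow topology with asymmetric hold-up volumes.

    For ``n_zones = 1`` the distributor/collector tanks are merged into
    the upstream/downstream volumes (three flow parameters total).  With
    a :class:`SectorDistribution` the single axial membrane zone is
    split into parallel angular sectors sharing the same tanks, sector i
    carrying flow ``f[i]*Q`` at interstitial velocity ``u[i]*v_bar``.
    For ``n_zones >= 2`` the upstream (peripheral) and downstream
    (central) volumes are split equally over chains of n tanks wired so
    every flow path crosses the same number of tanks.
    """
    if n_zones < 1:
        raise ValueError("need at least one membrane zone")
    if V_upstream <= 0 or V_downstream <= 0:
        raise ValueError("tank volumes must be positive")
    if sectors is not None and n_zones != 1:
        raise ValueError("angular sectors require a single axial membrane zone")

    v_bar = Q / (membrane.eps * membrane.A)
    build_info = {
        "family": "radial",
        "n_zones": n_zones,
        "V_pfr_mL": V_pfr,
        "V_upstream_mL": V_upstream,
        "V_downstream_mL": V_downstream,
        "Q_mL_per_s": Q,
        "membrane": {
            "L_cm": membrane.L, "A_cm2": membrane.A, "eps": membrane.eps,
            "Da_cm2_per_s": membrane.Da, "N": membrane.N,
        },
    }

    if n_zones == 1:
        tanks = [TankSpec(name="upstream", V=V_upstream, inlets=[(FEED, Q)])]
        zones: list[ZonePlacement] = []
        if sectors is None or sectors.n_sectors == 1:
            zones.append(
                ZonePlacement(
                    name="zone1", inlet="upstream", flow=Q,
                    zone=MembraneZone(
                        L=membrane.L, v=v_bar, Da=membrane.Da,
                        eps=membrane.eps, N=membrane.N, A=membrane.A,
                    ),
                )
            )
        else:
            for i, (u_i, f_i) in enumerate(zip(sectors.u, sectors.f)):
                if f_i <= 0:
                    continue  # zero-flow sectors carry no solute
                zones.append(
                    ZonePlacement(
                        name=f"sector{i + 1}", inlet="upstream", flow=f_i * Q,
                        zone=MembraneZone(
                            L=membrane.L, v=u_i * v_bar, Da=membrane.Da,
                            eps=membrane.eps, N=membrane.N,
                            # area follows from flow and velocity: Q_i = eps*A_i*v_i
                            A=(f_i / u_i) * membrane.A,
                        ),
                    )
                )
        tanks.append(
            TankSpec(
                name="downstream", V=V_downstream,
                inlets=[(z.name, z.flow) for z in zones],
            )
        )
        return CapsuleTopology(
            mode="radial", Q=Q, pfr=PlugFlowRegion(V_pfr), tanks=tanks,
            zones=zones, outlet="downstream", sectors=sectors,
            build_info=build_info,
        )

    # n_zones >= 2: equal flow split, equal tank split, equal tank counts
    # on every path (peripheral chain outward, central chain inward).
    phi = 1.0 / n_zones
    v_up = V_upstream / n_zones
    v_down = V_downstream / n_zones
    tanks = []
    zones = []
    for k in range(n_zones):
        src = FEED if k == 0 else f"tank{k}a"
        carried = (n_zones - k) * phi * Q
        tanks.append(TankSpec(name=f"tank{k + 1}a", V=v_up, inlets=[(src, carried)]))
        zones.append(
            ZonePlacement(
                name=f"zone{k + 1}", inlet=f"tank{k + 1}a", flow=phi * Q,
                zone=MembraneZone(
                    L=membrane.L, v=v_bar, Da=membrane.Da, eps=membrane.eps,
                    N=membrane.N, A=phi * membrane.A,
                ),
            )
        )
    for k in range(n_zones):
        inlets = [(f"zone{k + 1}", phi * Q)]
        if k > 0:
            inlets.append((f"tank{k}b", k * phi * Q))
        tanks.append(TankSpec(name=f"tank{k + 1}b", V=v_down, inlets=inlets))
    return CapsuleTopology(
        mode="radial", Q=Q, pfr=PlugFlowRegion(V_pfr), tanks=tanks,
        zones=zones, outlet=f"tank{n_zones}b", build_info=build_info,
    )
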