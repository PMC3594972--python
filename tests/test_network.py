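"""Tank network topology: CSTR balances, builders, sector distributions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import zrm
from zrm import presets
from zrm.network import (
    CapsuleTopology,
    FlowFractions,
    PlugFlowRegion,
    TankSpec,
    build_axial_topology,
    build_radial_topology,
    cstr_rhs,
    multi_inlet_cstr_rhs,
    sector_distribution,
)


class TestCstr:
    def test_steady_state(self):
        assert cstr_rhs(0.7, 0.7, 5.0) == 0.0

    def test_step_response_closed_form(self):
        """First-order response 1 - exp(-t/tau) at t = tau."""
        tau = 5.0
        sol = solve_ivp(lambda t, y: [cstr_rhs(y[0], 1.0, tau)], (0, tau),
                        [0.0], rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(1 - np.exp(-1), rel=1e-6)

    def test_two_tanks_in_series_gamma_response(self):
        """Two equal tanks: response 1 - e^(-t/tau)(1 + t/tau) (gamma CDF)."""
        tau = 3.0

        def rhs(t, y):
            return [cstr_rhs(y[0], 1.0, tau), cstr_rhs(y[1], y[0], tau)]

        t_eval = np.linspace(0, 30, 61)
        sol = solve_ivp(rhs, (0, 30), [0.0, 0.0], t_eval=t_eval,
                        rtol=1e-10, atol=1e-12)
        x = t_eval / tau
        closed = 1 - np.exp(-x) * (1 + x)
        assert np.abs(sol.y[1] - closed).max() < 1e-7

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            cstr_rhs(0.0, 1.0, 0.0)


class TestMultiInletCstr:
    def test_identical_inlets_merge(self):
        # two identical feeds at partial tau 2T combine to one at tau T
        assert multi_inlet_cstr_rhs(0.3, [0.9, 0.9], [8.0, 8.0]) == pytest.approx(
            cstr_rhs(0.3, 0.9, 4.0)
        )

    def test_equal_flow_mixing_steady_state(self):
        """c_in = [1, 0] with equal flows settles at 0.5."""
        tau = 2.0
        sol = solve_ivp(
            lambda t, y: [multi_inlet_cstr_rhs(y[0], [1.0, 0.0],
                                               [2 * tau, 2 * tau])],
            (0, 40 * tau), [0.0], rtol=1e-10, atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(0.5, rel=1e-6)

    def test_empty_inlets_rejected(self):
        with pytest.raises(ValueError):
            multi_inlet_cstr_rhs(0.0, [], [])

    def test_downstream_flow_fraction_products(self):
        """The zone fractions follow from the per-tank inlet fractions:
        phi_2 = phi_1b,2 * phi_2b,1 in a three-zone axial network."""
        cap = presets.CAPSULES["XT5"]
        phi = [0.5, 0.3, 0.2]
        topo = build_axial_topology(3, 1.0, [1.0, 1.0, 1.0], phi, cap.Q,
                                    cap.geometry(N=10))
        tanks = {t.name: t for t in topo.tanks}
        f1b = dict(zip([s for s, _ in tanks["tank1b"].inlets],
                       tanks["tank1b"].inlet_fractions))
        f2b = dict(zip([s for s, _ in tanks["tank2b"].inlets],
                       tanks["tank2b"].inlet_fractions))
        assert f1b["zone1"] == pytest.approx(phi[0])
        assert f1b["tank2b"] * f2b["zone2"] == pytest.approx(phi[1])
        assert f1b["tank2b"] * f2b["tank3b"] == pytest.approx(phi[2])
        # partial residence times combine harmonically: 1/tau = sum 1/tau_j
        t1b = tanks["tank1b"]
        assert sum(1.0 / tj for tj in t1b.tau_j) == pytest.approx(1.0 / t1b.tau)


class TestAxialBuilder:
    def test_one_zone_is_roper_lightfoot_chain(self):
        """PFR -> CSTR -> membrane -> CSTR with the published 1-zone volumes."""
        cap = presets.CAPSULES["XT5"]
        topo = build_axial_topology(1, 2.22, [3.64], [1.0], cap.Q,
                                    cap.geometry())
        assert topo.pfr.V == 2.22
        assert [t.name for t in topo.tanks] == ["tank1a", "tank1b"]
        assert topo.tanks[0].inlets == [("feed", cap.Q)]
        assert topo.zones[0].inlet == "tank1a"
        assert topo.tanks[1].inlets == [("zone1", cap.Q)]
        assert topo.outlet == "tank1b"

    def test_two_zone_preset_central_flow_fraction(self):
        """57% of the flow passes the central region (phi2 = 0.43)."""
        topo = presets.get_topology("XT5-2zone")
        assert topo.flow_fractions[0] == pytest.approx(0.57)
        assert sum(topo.flow_fractions) == pytest.approx(1.0)

    def test_flow_fractions_sum_to_one_any_topology(self):
        cap = presets.CAPSULES["XT5"]
        topo = build_axial_topology(3, 1.0, [0.5, 0.7, 0.9], [0.5, 0.3, 0.2],
                                    cap.Q, cap.geometry(N=10))
        assert sum(topo.flow_fractions) == pytest.approx(1.0)
        for t in topo.tanks:
            assert sum(t.inlet_fractions) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        cap = presets.CAPSULES["XT5"]
        with pytest.raises(ValueError):
            build_axial_topology(2, 1.0, [1.0], [0.5, 0.5], cap.Q,
                                 cap.geometry())

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FlowFractions([0.5, 0.4])


class TestRadialBuilder:
    @pytest.mark.parametrize(
        "V_pfr,V_up,V_down",
        [(269.93, 82.88, 19.32), (259.0, 55.16, 55.16)],  # asym / sym fits
    )
    def test_published_presets_are_valid(self, V_pfr, V_up, V_down):
        cap = presets.CAPSULES["XT140"]
        topo = build_radial_topology(1, V_pfr, V_up, V_down, cap.Q,
                                     cap.geometry())
        assert topo.mode == "radial"
        assert topo.tank_volume == pytest.approx(V_up + V_down)

    def test_equal_tank_count_on_every_path(self):
        """All flow paths cross the same number of tanks in radial mode."""
        cap = presets.CAPSULES["XT140"]
        topo = build_radial_topology(3, 10.0, 60.0, 30.0, cap.Q,
                                     cap.geometry(N=10))
        succ = {}
        for t in topo.tanks:
            for s, _ in t.inlets:
                succ.setdefault(s, []).append(t.name)
        for z in topo.zones:
            succ.setdefault(z.inlet, []).append(z.name)

        def tank_counts(node, acc):
            is_tank = node.startswith("tank")
            acc = acc + (1 if is_tank else 0)
            outs = succ.get(node, [])
            if not outs:
                return [acc]
            res = []
            for nxt in outs:
                res += tank_counts(nxt, acc)
            return res

        counts = tank_counts("feed", 0)
        assert len(set(counts)) == 1

    def test_invalid_volumes_rejected(self):
        cap = presets.CAPSULES["XT140"]
        with pytest.raises(ValueError):
            build_radial_topology(1, 1.0, 0.0, 5.0, cap.Q, cap.geometry())


class TestSectorDistribution:
    def test_delta_limit_concentrates_flow(self):
        # narrow peak aimed at one node of the 1/15-spaced velocity grid
        mu = 0.3 + 10.0 / 15.0
        sd = sector_distribution(mu=mu, sigma=0.01, slope=0.0, n_sectors=16)
        i = int(np.argmax(sd.f))
        assert sd.f[i] > 0.999
        assert abs(sd.u[i] - mu) == min(abs(u - mu) for u in sd.u)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        mu=st.floats(0.8, 1.2),
        sigma=st.floats(0.01, 0.3),
        slope=st.floats(0.0, 3.0),
    )
    def test_normalization_property(self, mu, sigma, slope):
        sd = sector_distribution(mu, sigma, slope, n_sectors=16)
        assert sum(sd.f) == pytest.approx(1.0, abs=1e-12)
        assert all(f >= 0 for f in sd.f)
        assert np.all(np.diff(sd.u) > 0)

    def test_ramp_only_applies_left_of_peak(self):
        # with a huge slope the right flank must stay pure Gaussian
        sd = sector_distribution(mu=0.8, sigma=0.05, slope=10.0, n_sectors=16)
        u = np.array(sd.u)
        f = np.array(sd.f)
        right = f[u > 0.8]
        assert np.all(np.diff(right) < 0)  # decaying Gaussian flank

    def test_four_sector_preset_loadable(self):
        topo = presets.get_topology("XT140-4sector")
        assert topo.sectors.f == pytest.approx((0.86, 0.066, 0.035, 0.039))
        assert topo.sectors.u == pytest.approx((1.04, 0.82, 0.72, 0.64))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sector_distribution(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            sector_distribution(1.0, 0.1, -1.0)


class TestSerialization:
    def test_topology_dict_round_trip(self):
        topo = presets.get_topology("XT140-4sector")
        clone = CapsuleTopology.from_dict(topo.to_dict())
        assert clone.to_dict() == topo.to_dict()

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            CapsuleTopology(
                mode="axial", Q=1.0, pfr=PlugFlowRegion(1.0),
                tanks=[TankSpec("a", 1.0, [("feed", 1.0)]),
                       TankSpec("a", 1.0, [("feed", 1.0)])],
                zones=[], outlet="a",
            )
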