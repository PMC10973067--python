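"""Reduced-order solver: Poiseuille closed forms, Murray splitting, loop
handling, conservation, periodic convergence, an independent resistor-
network oracle, and the analytic Womersley profile."""

import numpy as np
import pytest

import cowflow as cf
from cowflow.hemodynamics import poiseuille_wall_shear
from cowflow.types import InvalidArgumentError, VesselNetwork


def _tube(radius_mm=1.6, length_mm=20.0):
    net = VesselNetwork()
    net.add_node("in", [0, 0, 0], kind="inlet", label="IN")
    net.add_node("out", [length_mm, 0, 0], kind="outlet", label="OUT")
    net.add_edge("in", "out", "t", radius=radius_mm)
    return net


class TestMurraySplit:
    def test_equal_areas_split_equally(self):
        assert np.allclose(cf.murray_split_fractions([2.0] * 4), 0.25)

    def test_n2_is_area_proportional(self):
        assert np.allclose(cf.murray_split_fractions([1.0, 3.0]), [0.25, 0.75])

    def test_n3_radius_cubed(self):
        assert np.allclose(cf.murray_split_fractions([1.0, 1.0], n=3),
                           [0.5, 0.5])
        assert np.allclose(cf.murray_split_fractions([1.0, 4.0], n=3),
                           [1.0 / 9.0, 8.0 / 9.0])

    def test_fractions_sum_exactly_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform(0.1, 9.0, size=rng.integers(2, 12))
            f = cf.murray_split_fractions(a, n=rng.uniform(1.0, 3.0))
            # the closing fraction makes the partial-sum grouping exact
            assert f[:-1].sum() + f[-1] == 1.0
            assert abs(f.sum() - 1.0) < 1e-15

    def test_invalid_areas(self):
        with pytest.raises(InvalidArgumentError):
            cf.murray_split_fractions([])
        with pytest.raises(InvalidArgumentError):
            cf.murray_split_fractions([1.0, -2.0])


class TestEdgeResistance:
    def test_closed_form_value(self):
        # 8 * 0.004 * 0.01 / (pi * 1e-12)
        assert cf.edge_resistance(1e-3, 10e-3) == pytest.approx(1.0186e8,
                                                                rel=1e-4)

    def test_radius_fourth_power(self):
        assert cf.edge_resistance(2e-3, 1e-2) == \
            pytest.approx(cf.edge_resistance(1e-3, 1e-2) / 16.0)

    def test_preconditions(self):
        with pytest.raises(InvalidArgumentError):
            cf.edge_resistance(1e-3, 0.0)
        with pytest.raises(InvalidArgumentError):
            cf.edge_resistance(-1e-3, 1e-2)


class TestSolver:
    def test_steady_tube_poiseuille_drop(self, steady_waveform):
        net = _tube()
        res = cf.solve_unsteady(net, {"IN": steady_waveform})
        q = 1e-6  # 1e-3 l/s
        expected = q * cf.edge_resistance(1.6e-3, 20e-3)
        drop = res.node_pressure("in") - res.node_pressure("out")
        assert np.allclose(drop, expected, rtol=1e-10)
        # wall shear matches the Poiseuille closed form
        assert np.allclose(res.edge_tau("t"),
                           4 * 0.004 * q / (np.pi * 1.6e-3 ** 3), rtol=1e-12)

    def test_symmetric_loop_splits_evenly(self, steady_waveform):
        net = VesselNetwork()
        net.add_node("in", [0, 0, 0], kind="inlet", label="IN")
        net.add_node("a", [10, 0, 0])
        net.add_node("b", [30, 0, 0])
        net.add_node("out", [40, 0, 0], kind="outlet")
        net.add_edge("in", "a", "e0", radius=2.0)
        net.add_edge("a", "b", "loop1", radius=1.5, length=25.0)
        net.add_edge("a", "b", "loop2", radius=1.5, length=25.0)
        net.add_edge("b", "out", "e3", radius=2.0)
        res = cf.solve_unsteady(net, {"IN": steady_waveform})
        assert np.allclose(res.edge_flow("loop1"), res.edge_flow("loop2"))
        assert np.allclose(res.edge_flow("loop1"), 0.5e-6)

    def test_y_tree_murray_outflow(self, steady_waveform):
        net = VesselNetwork()
        net.add_node("in", [0, 0, 0], kind="inlet", label="IN")
        net.add_node("j", [10, 0, 0])
        net.add_node("o1", [20, 5, 0], kind="outlet")
        net.add_node("o2", [20, -5, 0], kind="outlet")
        net.add_edge("in", "j", "t", radius=2.0)
        net.add_edge("j", "o1", "b1", radius=np.sqrt(1.0 / np.pi))  # 1 mm^2
        net.add_edge("j", "o2", "b2", radius=np.sqrt(3.0 / np.pi))  # 3 mm^2
        res = cf.solve_unsteady(net, {"IN": steady_waveform})
        assert np.allclose(res.edge_flow("b1"), 0.25e-6)
        assert np.allclose(res.edge_flow("b2"), 0.75e-6)

    def test_pulsatile_conservation_and_outlets(self, cow10):
        wfs = cf.default_inlet_waveforms()
        res = cf.solve_unsteady(cow10, wfs)
        assert res.conservation_residual < 1e-10
        q_in = sum(wf.at(res.times) * 1e-3 for wf in wfs.values())
        q_out = sum(res.edge_flow(k) for k, (u, v) in
                    res.edge_orientation.items()
                    if cow10.node_kind(v) == "outlet")
        assert np.allclose(q_out, q_in, rtol=1e-12)

    def test_periodic_steady_state(self, cow10):
        """The evaluated (third) cycle is converged: it differs from the
        second cycle by under 1% RMS."""
        edge_id = cow10.edges_with_branch("M1r")[0]
        spec = cf.make_aneurysm_spec(cow10, edge_id)
        net = cf.attach_aneurysm(cow10, spec)
        wfs = cf.default_inlet_waveforms()
        r2 = cf.solve_unsteady(net, wfs, config=cf.SolverConfig(cycles=2))
        r3 = cf.solve_unsteady(net, wfs, config=cf.SolverConfig(cycles=3))
        rms = np.sqrt(np.mean((r3.Q - r2.Q) ** 2))
        assert rms < 0.01 * np.abs(r3.Q).max()

    @pytest.mark.parametrize("seed", range(4))
    def test_random_network_matches_independent_solve(self, seed,
                                                      steady_waveform):
        """Brute-force nodal solve assembled from scratch (dense, reduced
        Laplacian) agrees with the solver on random <= 8-node graphs."""
        rng = np.random.default_rng(seed)
        n_mid = int(rng.integers(2, 6))
        net = VesselNetwork()
        net.add_node("in", [0, 0, 0], kind="inlet", label="IN")
        mids = []
        for i in range(n_mid):
            net.add_node(f"m{i}", [10.0 + 10 * i, float(rng.uniform(-5, 5)), 0])
            mids.append(f"m{i}")
        net.add_node("out", [100, 0, 0], kind="outlet")
        chain = ["in"] + mids + ["out"]
        eid = 0
        edges = []
        for a, b in zip(chain[:-1], chain[1:]):
            edges.append((a, b, f"e{eid}",
                          float(rng.uniform(0.8, 2.5)),
                          float(np.linalg.norm(net.position(a) -
                                               net.position(b)) + rng.uniform(0, 5))))
            eid += 1
        for _ in range(int(rng.integers(1, 4))):  # extra loop edges
            a, b = rng.choice(mids, size=2, replace=False)
            d = float(np.linalg.norm(net.position(a) - net.position(b)))
            edges.append((a, b, f"e{eid}", float(rng.uniform(0.8, 2.5)),
                          d + float(rng.uniform(0.1, 5))))
            eid += 1
        for a, b, k, r, ln in edges:
            net.add_edge(a, b, k, radius=r, length=ln)
        res = cf.solve_unsteady(net, {"IN": steady_waveform})

        # independent dense assembly
        nodes = sorted(net.graph.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        L = np.zeros((len(nodes), len(nodes)))
        for a, b, k, r, ln in edges:
            g = 1.0 / cf.edge_resistance(r * 1e-3, ln * 1e-3)
            i, j = idx[a], idx[b]
            L[i, i] += g
            L[j, j] += g
            L[i, j] -= g
            L[j, i] -= g
        rhs = np.zeros(len(nodes))
        rhs[idx["in"]] = 1e-6
        rhs[idx["out"]] = -1e-6
        iref = idx["out"]
        L[iref, :] = 0.0
        L[iref, iref] = 1.0
        rhs[iref] = 0.0
        p = np.linalg.solve(L, rhs)
        for a, b, k, r, ln in edges:
            g = 1.0 / cf.edge_resistance(r * 1e-3, ln * 1e-3)
            q_ref = g * (p[idx[a]] - p[idx[b]])
            u, v = res.edge_orientation[k]
            sign = 1.0 if (u, v) == (a, b) else -1.0
            assert res.edge_flow(k)[0] * sign == pytest.approx(q_ref, abs=1e-9 * 1e-6 + abs(q_ref) * 1e-9)

    def test_missing_waveform_and_period_mismatch(self, cow10):
        wfs = cf.default_inlet_waveforms()
        with pytest.raises(InvalidArgumentError, match="missing inflow"):
            cf.solve_unsteady(cow10, {"ICAl": wfs["ICAl"]})
        bad = dict(wfs)
        bad["BA"] = cf.generate_inflow_waveform(2.332e-3, period=0.8)
        with pytest.raises(InvalidArgumentError, match="period"):
            cf.solve_unsteady(cow10, bad)


class TestWomersley:
    def test_steady_limit_is_parabolic(self):
        q = np.full(128, 2e-6)
        ps = cf.womersley_profile(q, 2e-3, period=1.0)
        expected = 2.0 * 2e-6 / (np.pi * 4e-6) * (1 - (ps.radii / 2e-3) ** 2)
        assert np.allclose(ps.V[:, 0], expected, rtol=1e-3)
        assert np.allclose(ps.integrated_flow(), 2e-6, rtol=1e-3)

    def test_pulsatile_quadrature_recovers_flow(self):
        t = np.arange(256) / 256.0
        q = 2e-6 * (1 + 0.8 * np.sin(2 * np.pi * t) + 0.3 * np.cos(6 * np.pi * t))
        ps = cf.womersley_profile(q, 2.5e-3, period=1.0, n_harmonics=8)
        err = np.abs(ps.integrated_flow() - q) / np.abs(q).max()
        assert err.max() < 0.005

    def test_high_alpha_annular_overshoot(self):
        """A pure oscillatory harmonic at high Womersley number flattens
        the core: the instantaneous peak sits off the centre axis."""
        t = np.arange(256) / 256.0
        q = 1e-6 * np.sin(2 * np.pi * 4 * t)  # 4 Hz harmonic, alpha ~ 5
        ps = cf.womersley_profile(q, 3e-3, period=1.0, n_harmonics=8)
        j = int(np.argmax(np.abs(ps.Q)))
        profile = np.abs(ps.V[:, j])
        # radii are ascending: index 0 is the axis; the peak sits in the
        # outer half of the pipe (near-wall overshoot)
        assert np.argmax(profile) > len(profile) // 2
        assert np.abs(ps.integrated_flow() - ps.Q).max() < 0.005 * np.abs(q).max()

    def test_zero_flow_zero_profile(self):
        ps = cf.womersley_profile(np.zeros(64), 2e-3, period=1.0)
        assert np.allclose(ps.V, 0.0)

    def test_wall_shear_consistency_steady(self):
        """mu du/dr at the wall of the reconstructed steady profile equals
        4 mu Q / (pi r^3) within 0.5%."""
        q0, r0 = 3e-6, 2e-3
        ps = cf.womersley_profile(np.full(64, q0), r0, period=1.0, n_radial=64)
        coeff = np.polyfit(ps.radii ** 2, ps.V[:, 0], 1)  # v = a r^2 + b
        wall_shear = abs(0.004 * 2 * coeff[0] * r0)
        assert wall_shear == pytest.approx(
            abs(poiseuille_wall_shear(q0, r0)), rel=0.005)

    def test_harmonic_truncation_warns(self):
        with pytest.warns(UserWarning, match="Nyquist"):
            cf.womersley_profile(np.sin(np.arange(16) / 16 * 2 * np.pi) + 2,
                                 1e-3, n_harmonics=100)
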