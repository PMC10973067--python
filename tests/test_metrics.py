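"""Hemodynamic evaluation statistics: V_Norm, TAWSS, OSI, NIR, centerline
velocities, spatial-mean normalization and paired model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cowflow as cf
from cowflow.metrics import removed_offtake_arcs
from cowflow.network import extract_path
from cowflow.types import InvalidArgumentError, VesselNetwork


class TestVNorm:
    def test_uniform_profile_is_one(self):
        ps = cf.womersley_profile(np.full(64, 1e-6), 2e-3, period=1.0)
        ps.V[:] = ps.Q[0] / ps.area  # plug flow
        assert np.allclose(cf.v_norm(ps), 1.0)

    def test_parabolic_centerline_is_two(self):
        ps = cf.womersley_profile(np.full(64, 2e-6), 2e-3, period=1.0,
                                  n_radial=64)
        vn = cf.v_norm(ps, time_index=0)
        # radii ascend from the axis: station 0 approximates the centerline
        assert vn[0] == pytest.approx(2.0, abs=1e-3)

    def test_area_weighted_mean_is_one_for_womersley_planes(self):
        t = np.arange(128) / 128.0
        q = 2e-6 * (1 + 0.7 * np.sin(2 * np.pi * t))
        ps = cf.womersley_profile(q, 2e-3, period=1.0)
        vn = cf.v_norm(ps)
        weighted = ps.weights @ vn / ps.area
        assert np.allclose(weighted, 1.0, atol=1e-3)

    def test_zero_flow_plane_rejected(self):
        ps = cf.womersley_profile(np.full(64, 1e-6), 2e-3, period=1.0)
        ps.Q[:] = 0.0
        with pytest.raises(InvalidArgumentError):
            cf.v_norm(ps)


class TestTawssOsi:
    def test_constant_shear(self):
        assert cf.tawss(np.full(100, 2.0)) == pytest.approx(2.0)
        assert cf.tawss(np.zeros(100)) == 0.0

    def test_rectified_sine_average(self):
        t = np.linspace(0.0, 1.0, 4001)
        tau = np.sin(2 * np.pi * t)
        assert cf.tawss(tau, t) == pytest.approx(2 / np.pi, abs=1e-4)

    def test_osi_limits(self):
        t = np.linspace(0.0, 1.0, 4001)
        assert cf.osi(np.abs(np.sin(2 * np.pi * t)) + 0.1, t) == 0.0
        assert cf.osi(np.sin(2 * np.pi * t), t) == pytest.approx(0.5, abs=1e-6)
        assert cf.osi(1.0 + np.sin(2 * np.pi * t), t) == pytest.approx(0.0,
                                                                       abs=1e-9)

    def test_zero_series_warns(self):
        with pytest.warns(UserWarning):
            assert cf.osi(np.zeros(100)) == 0.0

    def test_empty_series_raises(self):
        with pytest.raises(InvalidArgumentError):
            cf.tawss(np.array([]))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_osi_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        tau = rng.normal(size=rng.integers(4, 200))
        if np.all(tau == 0):
            return
        val = cf.osi(tau)
        assert 0.0 <= val <= 0.5
        if np.all(tau > 0) or np.all(tau < 0):
            assert val == 0.0

    def test_phase_invariance(self):
        rng = np.random.default_rng(3)
        tau = rng.normal(size=128)  # open periodic grid
        q = np.abs(tau) * 1e-6
        for shift in (1, 17, 64):
            rolled = np.roll(tau, shift)
            assert cf.tawss(rolled) == pytest.approx(cf.tawss(tau), rel=1e-9)
            assert cf.osi(rolled) == pytest.approx(cf.osi(tau), abs=1e-9)
            assert cf.nir(np.roll(q, shift))[1] == \
                pytest.approx(cf.nir(q)[1], rel=1e-9)


class TestNir:
    def test_steady_inflow(self):
        series, mean = cf.nir(np.full(100, 1e-7))  # 0.1 ml/s into the sac
        assert mean == pytest.approx(0.1)
        assert np.allclose(series, 0.1)

    def test_zero_mean_sinusoid(self):
        t = np.arange(4000) / 4000.0
        q0 = 2.5e-7
        _, mean = cf.nir(q0 * np.sin(2 * np.pi * t))
        assert mean == pytest.approx(q0 * 1e6 / np.pi, abs=1e-4)

    def test_outward_flow_gives_zero(self):
        series, mean = cf.nir(-np.abs(np.random.default_rng(0).normal(size=50)))
        assert mean == 0.0 and np.all(series == 0.0)


class TestNormalize:
    def test_constant_field(self):
        assert np.allclose(cf.normalize_by_spatial_mean(np.full(7, 3.3)), 1.0)

    def test_two_values(self):
        assert np.allclose(cf.normalize_by_spatial_mean(np.array([1.0, 3.0])),
                           [0.5, 1.5])

    def test_random_field_mean_one(self):
        x = np.random.default_rng(1).uniform(0.5, 2.0, size=1000)
        assert cf.normalize_by_spatial_mean(x).mean() == pytest.approx(1.0,
                                                                       abs=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(InvalidArgumentError):
            cf.normalize_by_spatial_mean(np.array([1.0, -1.0]))


def _steady(label="IN", q=1e-3):
    return cf.generate_inflow_waveform(q, 1.0, 0.0, label=label)


class TestCenterlineVelocity:
    def test_uniform_tube_constant_curve(self):
        net = VesselNetwork()
        net.add_node("in", [0, 0, 0], kind="inlet", label="IN")
        net.add_node("out", [30, 0, 0], kind="outlet", label="OUT")
        net.add_edge("in", "out", "t", radius=2.0)
        res = cf.solve_unsteady(net, {"IN": _steady()})
        path = extract_path(net, "IN", "out")
        df = cf.centerline_velocity(res, net, path, 10)
        expected = 1e-6 / (np.pi * (2e-3) ** 2)
        assert np.allclose(df["v_m_s"], expected, rtol=1e-12)

    def test_side_outlet_reduces_distal_velocity(self):
        # side outlet takes 40% of the flow (areas 2:3), same trunk radius
        net = VesselNetwork()
        net.add_node("in", [0, 0, 0], kind="inlet", label="IN")
        net.add_node("j", [20, 0, 0])
        net.add_node("side", [22, 10, 0], kind="outlet", label="side")
        net.add_node("main", [40, 0, 0], kind="outlet", label="main")
        net.add_edge("in", "j", "e_prox", radius=2.0)
        net.add_edge("j", "side", "e_side", radius=np.sqrt(0.4) * 1.5)
        net.add_edge("j", "main", "e_dist", radius=2.0)
        a_side = np.pi * (np.sqrt(0.4) * 1.5) ** 2
        a_main = np.pi * 2.0 ** 2
        frac_main = a_main / (a_side + a_main)
        res = cf.solve_unsteady(net, {"IN": _steady()})
        path = extract_path(net, "IN", "main")
        df = cf.centerline_velocity(res, net, path, 20)
        prox = df[df.s_mm < 20]["v_m_s"].iloc[0]
        dist = df[df.s_mm > 20]["v_m_s"].iloc[-1]
        assert dist / prox == pytest.approx(frac_main, rel=1e-9)

    def test_requires_inlet_rooted_path(self):
        net = VesselNetwork()
        net.add_node("in", [0, 0, 0], kind="inlet", label="IN")
        net.add_node("out", [30, 0, 0], kind="outlet", label="OUT")
        net.add_edge("in", "out", "t", radius=2.0)
        res = cf.solve_unsteady(net, {"IN": _steady()})
        path = extract_path(net, "IN", "out")
        path.node_ids = path.node_ids[::-1]
        with pytest.raises(InvalidArgumentError):
            cf.centerline_velocity(res, net, path, 5)


def _run_pair(n_side=4, keep_main_only=True):
    """Complex vs trimmed run on the trunk-with-side-outlets template."""
    net_c = cf.generate_trunk_template(n_side, seed=0)
    main = net_c.node_by_label("main")
    net_t = cf.trim_network(net_c, [main])
    wf = {"IN": cf.generate_inflow_waveform(1e-3, 1.0, 0.5, label="IN")}
    res_c = cf.solve_unsteady(net_c, wf)
    res_t = cf.solve_unsteady(net_t, wf)
    path_c = extract_path(net_c, "IN", main)
    path_t = extract_path(net_t, "IN", main)
    mc = cf.compute_metrics(res_c, net_c, case_id="complex",
                            paths={"p": path_c}, n_points=40)
    mt = cf.compute_metrics(res_t, net_t, case_id="trimmed",
                            paths={"p": path_t},
                            shared_radii={"p": path_c}, n_points=40)
    removed = {"p": removed_offtake_arcs(net_c, net_t, path_c, path_t)}
    return cf.compare_models(mc, mt, removed_offtakes=removed)


class TestCompareModels:
    def test_identical_inputs_zero_deltas(self, cow10):
        wfs = cf.default_inlet_waveforms()
        res = cf.solve_unsteady(cow10, wfs)
        outlet = cf.outlet_prominence(cow10)[0][0]
        path = extract_path(cow10, "ICAr", outlet)
        m = cf.compute_metrics(res, cow10, case_id="a", paths={"p": path})
        rep = cf.compare_models(m, m)
        assert rep.summary["delta_spatial_mean_tawss_Pa"] == 0.0
        assert rep.summary["max_abs_delta_centerline_v_m_s"] == 0.0

    def test_trunk_overestimation_all_distal_stations(self):
        rep = _run_pair()
        cl = rep.centerline["p"]
        assert cl["distal_overestimation_fraction"] == 1.0
        distal = cl["s_mm"] > cl["first_removed_offtake_s_mm"]
        assert np.all(cl["delta_v_m_s"][distal] < 0.0)  # strict

    def test_delta_sign_convention(self):
        """delta = complex - trimmed: trimmed overestimates distal flow, so
        the centerline delta is negative there (the complex model shows the
        reduction)."""
        rep = _run_pair()
        assert rep.sign_convention == "complex_minus_trimmed"
        cl = rep.centerline["p"]
        assert cl["delta_v_m_s"][-1] < 0.0

    def test_unpaired_labels_rejected(self, cow10):
        wfs = cf.default_inlet_waveforms()
        res = cf.solve_unsteady(cow10, wfs)
        outlet = cf.outlet_prominence(cow10)[0][0]
        path = extract_path(cow10, "ICAr", outlet)
        m1 = cf.compute_metrics(res, cow10, case_id="a", paths={"p": path})
        m2 = cf.compute_metrics(res, cow10, case_id="b", paths={"q": path})
        with pytest.raises(InvalidArgumentError, match="unpaired"):
            cf.compare_models(m1, m2)
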