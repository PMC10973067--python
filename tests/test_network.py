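"""Centerline graph construction, outlet prominence, trimming and
aneurysm graph surgery."""

import networkx as nx
import numpy as np
import pytest

import cowflow as cf
from cowflow.network import merge_degree2_chains, offtake_arcs
from cowflow.types import InvalidArgumentError, VesselNetwork
from conftest import gt_mask_to_segmentation


class TestSkeletonize:
    def test_straight_tube_graph(self, tube_imaging):
        volume, gt = tube_imaging
        net = cf.skeletonize_and_build(gt_mask_to_segmentation(volume, gt),
                                       gt.openings)
        assert net.graph.number_of_nodes() == 2
        assert net.graph.number_of_edges() == 1
        (_, _, d), = net.graph.edges(data=True)
        assert abs(d["radius"] - 1.6) <= 0.5 * volume.spacing

    def test_y_bifurcation_topology(self, y_network):
        volume, gt = cf.rasterize_network(y_network, spacing=0.32)
        net = cf.skeletonize_and_build(gt_mask_to_segmentation(volume, gt),
                                       gt.openings)
        assert net.graph.number_of_nodes() == 4
        assert net.graph.number_of_edges() == 3
        kinds = sorted(net.node_kind(n) for n in net.graph.nodes)
        assert kinds == ["inlet", "junction", "outlet", "outlet"]

    def test_cow60_boundary_recovery(self, cow60):
        volume, gt = cf.rasterize_network(cow60, spacing=0.32, seed=0,
                                          voxel_budget=40_000_000)
        net = cf.skeletonize_and_build(gt_mask_to_segmentation(volume, gt),
                                       gt.openings)
        assert len(net.inlets) == 3
        assert len(net.outlets) == 60

    def test_requires_two_openings(self, tube_imaging):
        volume, gt = tube_imaging
        with pytest.raises(InvalidArgumentError):
            cf.skeletonize_and_build(gt_mask_to_segmentation(volume, gt),
                                     gt.openings[:1])


class TestProminence:
    def _net_with_outlets(self, radii, labels=None):
        net = VesselNetwork()
        net.add_node("in", [0, 0, 0], kind="inlet", label="IN")
        net.add_node("j", [10, 0, 0])
        net.add_edge("in", "j", "t", radius=max(radii) + 0.5)
        for i, r in enumerate(radii):
            lbl = labels[i] if labels else f"o{i}"
            net.add_node(f"o{i}", [15, 4 * i - 4, 0], kind="outlet", label=lbl)
            net.add_edge("j", f"o{i}", f"b{i}", radius=r)
        return net

    def test_area_descending_order(self):
        net = self._net_with_outlets([1.0, 2.0, 1.5])
        order = [o for o, _ in cf.outlet_prominence(net)]
        assert order == ["o1", "o2", "o0"]
        areas = [a for _, a in cf.outlet_prominence(net)]
        assert areas == sorted(areas, reverse=True)

    def test_ties_broken_by_label(self):
        net = self._net_with_outlets([1.0, 1.0, 1.0], labels=["c", "a", "b"])
        order = [o for o, _ in cf.outlet_prominence(net)]
        assert order == ["o1", "o2", "o0"]  # labels a, b, c

    def test_permutation_property(self, cow10):
        prom = cf.outlet_prominence(cow10)
        assert sorted(o for o, _ in prom) == cow10.outlets

    def test_branch_summary_bookkeeping(self, cow60):
        df = cf.branch_summary(cow60)
        assert int(df["n_outlets"].sum()) == 60
        assert set(df["inlet_branch"]) == {"ICAl", "ICAr", "BA"}
        assert (df["sum_area_mm2"] > 0).all()


class TestTrim:
    def test_keep_all_preserves_outlets(self, cow10):
        trimmed = cf.trim_network(cow10, len(cow10.outlets))
        assert sorted(trimmed.outlets) == sorted(cow10.outlets)

    def test_60_to_10(self, cow60):
        trimmed = cf.trim_network(cow60, 10)
        assert len(trimmed.outlets) == 10
        assert len(trimmed.inlets) == 3
        trimmed.validate(cow_template=True)
        top10 = {o for o, _ in cf.outlet_prominence(cow60)[:10]}
        assert set(trimmed.outlets) == top10

    def test_trunk_side_branch_pruning(self):
        net = cf.generate_trunk_template(3, seed=0)
        main = net.node_by_label("main")
        trimmed = cf.trim_network(net, [main], merge_chains=False)
        assert trimmed.outlets == [main]
        # single inlet-to-outlet path remains, no side stubs
        assert all(trimmed.graph.degree(n) <= 2 for n in trimmed.graph.nodes)

    def test_geometry_preserved_on_kept_paths(self, cow60):
        trimmed = cf.trim_network(cow60, 10, merge_chains=False)
        inlet = cow60.node_by_label("ICAl")
        for outlet in trimmed.outlets:
            try:
                pc = nx.shortest_path_length(cow60.graph, inlet, outlet,
                                             weight="length")
            except nx.NetworkXNoPath:
                continue
            pt = nx.shortest_path_length(trimmed.graph, inlet, outlet,
                                         weight="length")
            assert pt == pytest.approx(pc, rel=1e-12)
        # with merge_chains=False every surviving edge keeps its attributes
        for u, v, k, d in trimmed.graph.edges(keys=True, data=True):
            _, _, d0 = cow60.edge_by_id(k)
            assert d["radius"] == d0["radius"] and d["length"] == d0["length"]

    def test_disconnect_raises(self):
        net = cf.generate_trunk_template(2, seed=0)
        with pytest.raises(InvalidArgumentError):
            cf.trim_network(net, 0)
        with pytest.raises(InvalidArgumentError):
            cf.trim_network(net, ["nonexistent"])

    def test_reachability_oracle(self, cow10):
        """Trimmed node set equals the union of surviving paths plus loop
        segments: every node keeps a route to an inlet and a kept outlet."""
        kept = [o for o, _ in cf.outlet_prominence(cow10)[:4]]
        trimmed = cf.trim_network(cow10, kept, merge_chains=False)
        g = trimmed.graph
        targets = set(kept)
        inlets = set(trimmed.inlets)
        for n in g.nodes:
            reach = set(nx.node_connected_component(g, n))
            assert reach & targets and reach & inlets


class TestAneurysmSurgery:
    def test_mid_edge_attachment_arithmetic(self, cow10):
        edge_id = cow10.edges_with_branch("M1r")[0]
        spec = cf.make_aneurysm_spec(cow10, edge_id, arc_position=0.5)
        out = cf.attach_aneurysm(cow10, spec)
        assert out.graph.number_of_edges() == cow10.graph.number_of_edges() + 2
        assert out.graph.number_of_nodes() == cow10.graph.number_of_nodes() + 2
        assert len(out.sacs) == 1

    def test_snap_near_node_warns(self, cow10):
        edge_id = cow10.edges_with_branch("A1l")[0]
        u, v, d = cow10.edge_by_id(edge_id)
        spec = cf.make_aneurysm_spec(cow10, edge_id,
                                     arc_position=0.01 / d["length"])
        with pytest.warns(UserWarning, match="snapped"):
            out = cf.attach_aneurysm(cow10, spec)
        assert out.graph.number_of_nodes() == cow10.graph.number_of_nodes() + 1

    def test_attach_then_remove_restores_isomorphic_network(self, cow10):
        edge_id = cow10.edges_with_branch("M1l")[0]
        spec = cf.make_aneurysm_spec(cow10, edge_id, arc_position=0.4)
        attached = cf.attach_aneurysm(cow10, spec)
        restored = cf.remove_aneurysm(attached, "sac_IA")

        def nm(a, b):
            return a["kind"] == b["kind"]

        def em(a, b):
            da = sorted((round(x["radius"], 9), round(x["length"], 6))
                        for x in a.values())
            db = sorted((round(x["radius"], 9), round(x["length"], 6))
                        for x in b.values())
            return da == db

        assert nx.is_isomorphic(cow10.graph, restored.graph,
                                node_match=nm, edge_match=em)

    def test_sac_survives_trimming_elsewhere(self, cow10):
        edge_id = cow10.edges_with_branch("M1r")[0]
        spec = cf.make_aneurysm_spec(cow10, edge_id)
        attached = cf.attach_aneurysm(cow10, spec)
        trimmed = cf.trim_network(attached, 5)
        assert trimmed.sacs == ["sac_IA"]
        trimmed.validate()


class TestPaths:
    def test_extract_path_arc_monotone(self, cow10):
        outlet = cf.outlet_prominence(cow10)[0][0]
        path = cf.extract_path(cow10, "ICAr", outlet)
        assert np.all(np.diff(path.arc) > 0)
        assert path.node_ids[0] == cow10.node_by_label("ICAr")
        assert (path.seg_radii > 0).all()

    def test_offtake_arcs_shrink_after_trimming(self, cow60):
        trimmed = cf.trim_network(cow60, 10)
        outlet = trimmed.outlets[0]
        inlet_label = None
        for lbl in ("ICAl", "ICAr", "BA"):
            pc = cf.extract_path(cow60, lbl, outlet)
            inlet_label = lbl
            break
        pc = cf.extract_path(cow60, inlet_label, outlet)
        pt = cf.extract_path(trimmed, inlet_label, outlet)
        assert pt.length == pytest.approx(pc.length, rel=1e-9)
        assert len(offtake_arcs(trimmed, pt)) <= len(offtake_arcs(cow60, pc))

    def test_merge_degree2_preserves_resistance_order(self):
        net = VesselNetwork()
        net.add_node("a", [0, 0, 0], kind="inlet", label="IN")
        net.add_node("m", [10, 0, 0], kind="junction")
        net.add_node("b", [30, 0, 0], kind="outlet", label="OUT")
        net.add_edge("a", "m", "e1", radius=1.0)
        net.add_edge("m", "b", "e2", radius=2.0)
        merge_degree2_chains(net)
        assert net.graph.number_of_edges() == 1
        (_, _, d), = net.graph.edges(data=True)
        assert d["length"] == pytest.approx(30.0)
        assert d["radius"] == pytest.approx((1.0 * 10 + 2.0 * 20) / 30)
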