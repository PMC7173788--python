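import json

import numpy as np
import pytest

from mdflow.cluster_analysis import build_tracking_graph
from mdflow.graph_engine import (
    Graph,
    GraphSchemaError,
    GraphValidationError,
    NodeExecutionError,
    PortType,
    execute_trajectory,
    load_graph,
    node_kind,
    save_graph,
    topo_order,
    validate,
)


# --- test-only node kinds ---------------------------------------------------

@node_kind("t_const_int", outputs=[("value", "int")], param_defaults={"value": 1})
def _const_int(ctx, inputs):
    return {"value": int(ctx.param("value"))}


@node_kind("t_sink_int", inputs=[("value", "int")])
def _sink_int(ctx, inputs):
    return {}


@node_kind("t_sink_float", inputs=[("value", "float")])
def _sink_float(ctx, inputs):
    return {}


@node_kind("t_incr", inputs=[("values", "float[1]")],
           outputs=[("values", "float[1]")])
def _incr(ctx, inputs):
    return {"values": np.asarray(inputs["values"]) + 1.0}


@node_kind("t_boom", outputs=[("value", "int")], param_defaults={"at": -1})
def _boom(ctx, inputs):
    if ctx.frame_index == ctx.param("at"):
        raise RuntimeError("scripted failure")
    return {"value": 0}


class TestPortType:
    def test_parse_and_str_round_trip(self):
        t = PortType.parse("float[2]")
        assert (t.base, t.rank) == ("float", 2)
        assert PortType.parse(str(t)) == t

    @pytest.mark.parametrize(
        "src, dst, ok",
        [
            ("int", "float", True),      # promotion
            ("float", "int", False),     # no demotion
            ("int[1]", "float[1]", True),
            ("float", "float[1]", False),  # rank mismatch
            ("string", "string", True),
            ("string", "float", False),
        ],
    )
    def test_compatibility(self, src, dst, ok):
        assert PortType.parse(dst).accepts(PortType.parse(src)) is ok

    def test_unknown_base_rejected(self):
        with pytest.raises(ValueError):
            PortType("quaternion", 0)


class TestValidate:
    def test_float_to_int_is_a_type_mismatch(self):
        g = Graph()
        g.add_node("a", "positions")
        g.add_node("b", "t_sink_int")
        g.connect("a", "positions", "b", "value")
        codes = [d.code for d in validate(g)]
        assert "type-mismatch" in codes

    def test_int_to_float_promotes(self):
        g = Graph()
        g.add_node("a", "t_const_int")
        g.add_node("b", "t_sink_float")
        g.connect("a", "value", "b", "value")
        assert validate(g) == []

    def test_cycle_diagnostic_names_both_nodes(self):
        g = Graph()
        g.add_node("a", "t_incr")
        g.add_node("b", "t_incr")
        g.connect("a", "values", "b", "values")
        g.connect("b", "values", "a", "values")
        cyc = [d for d in validate(g) if d.code == "cycle"]
        assert cyc and {"a", "b"} <= set(cyc[0].nodes)

    def test_unknown_kind_and_dangling_port(self):
        g = Graph()
        g.add_node("a", "no_such_kind")
        g.add_node("b", "t_sink_int")
        g.connect("a", "out", "b", "nope")
        codes = {d.code for d in validate(g)}
        assert "unknown-kind" in codes and "dangling" in codes

    def test_unwired_required_input_flagged(self):
        g = Graph()
        g.add_node("b", "t_sink_int")
        codes = [d.code for d in validate(g)]
        assert codes == ["missing-input"]

    def test_double_wired_input_flagged(self):
        g = Graph()
        g.add_node("a", "t_const_int")
        g.add_node("b", "t_const_int")
        g.add_node("c", "t_sink_int")
        g.connect("a", "value", "c", "value")
        g.connect("b", "value", "c", "value")
        assert "multiple-inputs" in {d.code for d in validate(g)}


class TestTopoOrder:
    def test_chain_in_order(self):
        g = Graph()
        for nid in ("c", "a", "b"):
            g.add_node(nid, "t_incr")
        g.connect("c", "values", "a", "values")
        g.connect("a", "values", "b", "values")
        # wire roots so validation-independent topo still works
        assert topo_order(g) == ["c", "a", "b"]

    def test_independent_nodes_sort_lexicographically(self):
        g = Graph()
        g.add_node("zeta", "t_const_int")
        g.add_node("alpha", "t_const_int")
        assert topo_order(g) == ["alpha", "zeta"]

    def test_diamond_has_source_first_sink_last(self):
        g = Graph()
        for nid in ("d", "b", "c", "a"):
            g.add_node(nid, "t_incr")
        g.connect("a", "values", "b", "values")
        g.connect("a", "values", "c", "values")
        g.connect("b", "values", "d", "values")
        order = topo_order(g)
        assert order[0] == "a" and order[-1] == "d"

    def test_cycle_raises(self):
        g = Graph()
        g.add_node("a", "t_incr")
        g.connect("a", "values", "a", "values")
        with pytest.raises(GraphValidationError):
            topo_order(g)


class TestExecution:
    def test_reader_before_writer_sees_previous_frame_value(self, cage_pair):
        # node ids force the get before the set in topological order
        g = Graph()
        g.add_node("a_get", "get_attribute", {"name": "x"})
        g.add_node("b_incr", "t_incr")
        g.add_node("c_set", "set_attribute", {"name": "x"})
        g.connect("a_get", "values", "b_incr", "values")
        g.connect("b_incr", "values", "c_set", "values")
        res = execute_trajectory(g, cage_pair)
        np.testing.assert_array_equal(res.value(0, "a_get", "values"), 0.0)

    def test_reader_after_writer_sees_new_value(self, cage_pair):
        g = Graph()
        g.add_node("a_get", "get_attribute", {"name": "x"})
        g.add_node("b_incr", "t_incr")
        g.add_node("c_set", "set_attribute", {"name": "x"})
        g.add_node("d_get", "get_attribute", {"name": "x"})
        g.connect("a_get", "values", "b_incr", "values")
        g.connect("b_incr", "values", "c_set", "values")
        # d_get has no wire forcing order, but id sorts after c_set
        res = execute_trajectory(g, cage_pair)
        np.testing.assert_array_equal(res.value(0, "d_get", "values"), 1.0)

    @pytest.mark.parametrize("direction", ["forward", "backward"])
    def test_attribute_accumulates_across_frames_either_direction(
        self, droplet, direction
    ):
        traj, _ = droplet
        g = Graph()
        g.add_node("a_get", "get_attribute", {"name": "acc"})
        g.add_node("b_incr", "t_incr")
        g.add_node("c_set", "set_attribute", {"name": "acc"})
        g.connect("a_get", "values", "b_incr", "values")
        g.connect("b_incr", "values", "c_set", "values")
        g.declare_attribute("acc", init=0.0, record=True)
        g.direction = direction
        res = execute_trajectory(g, traj)
        last_visited = res.visit_order[-1]
        np.testing.assert_array_equal(
            res.attribute_history["acc"][last_visited], 20.0
        )

    def test_backward_visits_frames_in_descending_order(self, droplet):
        traj, _ = droplet
        g = Graph()
        g.add_node("a", "t_const_int")
        g.direction = "backward"
        res = execute_trajectory(g, traj)
        assert res.visit_order == list(range(19, -1, -1))

    def test_failure_reports_node_and_frame_and_keeps_prior_cache(self, droplet):
        traj, _ = droplet
        g = Graph()
        g.add_node("a", "t_boom", {"at": 3})
        with pytest.raises(NodeExecutionError) as err:
            execute_trajectory(g, traj)
        assert err.value.node_id == "a" and err.value.frame_index == 3
        cached = {f for (f, _, _) in err.value.partial_result.cache}
        assert cached == {0, 1, 2}

    def test_cache_is_complete(self, droplet):
        traj, _ = droplet
        g = Graph()
        g.add_node("a", "positions")
        g.add_node("b", "box")
        res = execute_trajectory(g, traj)
        # one entry per executed (frame, node, output port)
        assert len(res.cache) == traj.n_frames * 3

    def test_frame_range_limits_execution(self, droplet):
        traj, _ = droplet
        g = Graph()
        g.add_node("a", "t_const_int")
        g.frames = (5, 9)
        res = execute_trajectory(g, traj)
        assert res.visit_order == [5, 6, 7, 8]

    def test_identical_runs_serialize_byte_identically(self, droplet):
        traj, _ = droplet
        g = build_tracking_graph(cutoff=3.0)
        a = execute_trajectory(g, traj).to_json()
        b = execute_trajectory(g, traj).to_json()
        assert a.encode() == b.encode()


class TestGraphJson:
    def test_round_trip_preserves_structure(self, tmp_path):
        g = build_tracking_graph(cutoff=3.0)
        path = tmp_path / "g.json"
        save_graph(g, path)
        back = load_graph(path)
        assert back.to_dict() == g.to_dict()

    def test_unknown_kind_named_in_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(
            {"nodes": [{"id": "a", "kind": "warp_drive"}]}
        ))
        with pytest.raises(GraphSchemaError) as err:
            load_graph(path)
        assert "warp_drive" in str(err.value)

    def test_missing_direction_defaults_to_forward(self, tmp_path):
        path = tmp_path / "g.json"
        path.write_text(json.dumps({"nodes": [], "execution": {}}))
        assert load_graph(path).direction == "forward"

    def test_bad_frames_shape_rejected(self, tmp_path):
        path = tmp_path / "g.json"
        path.write_text(json.dumps({"execution": {"frames": [1, 2, 3]}}))
        with pytest.raises(GraphSchemaError) as err:
            load_graph(path)
        assert "execution.frames" in str(err.value)
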