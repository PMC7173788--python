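import numpy as np
import pytest

from mdflow.builtin_nodes import combine_attributes, export_plot_csv, mask_centroid
from mdflow.graph_engine import (
    Graph,
    NodeExecutionError,
    execute_trajectory,
    node_kind,
    validate,
)


@node_kind("t_emit_pairs", outputs=[("pairs", "int[2]")],
           param_defaults={"pairs": []})
def _emit_pairs(ctx, inputs):
    return {"pairs": np.asarray(ctx.param("pairs"), dtype=int).reshape(-1, 2)}


@node_kind("t_emit_vec", outputs=[("values", "float[1]")],
           param_defaults={"values": []})
def _emit_vec(ctx, inputs):
    return {"values": np.asarray(ctx.param("values"), dtype=float)}


@node_kind("t_emit_point", outputs=[("point", "float[1]")],
           param_defaults={"point": [0.0, 0.0, 0.0]})
def _emit_point(ctx, inputs):
    return {"point": np.asarray(ctx.param("point"), dtype=float)}


@node_kind("t_frame_scalar", outputs=[("y", "float")])
def _frame_scalar(ctx, inputs):
    return {"y": float(ctx.frame_index)}


def run_single(graph, traj):
    return execute_trajectory(graph, traj)


class TestInputNodes:
    def test_positions_are_copies(self, cage_pair):
        g = Graph()
        g.add_node("a", "positions")
        res = run_single(g, cage_pair)
        out = res.value(0, "a", "positions")
        out[0, 0] = 1e9
        assert cage_pair.frames[0].positions[0, 0] != 1e9

    def test_box_node_emits_lengths_and_flags(self, cage_pair):
        g = Graph()
        g.add_node("a", "box")
        res = run_single(g, cage_pair)
        assert res.value(0, "a", "lengths").shape == (3,)
        np.testing.assert_array_equal(res.value(0, "a", "periodic"), 0)

    def test_wired_velocities_without_data_fails_validation(self, cage_pair):
        g = Graph()
        g.add_node("a", "velocities")
        g.add_node("b", "list_neighbors", {"cutoff": 1.0})
        g.connect("a", "velocities", "b", "positions")
        assert any(d.code == "bad-params" for d in validate(g, cage_pair))

    def test_unwired_velocities_node_is_fine(self, cage_pair):
        g = Graph()
        g.add_node("a", "velocities")
        assert validate(g, cage_pair) == []


class TestCombine:
    @pytest.mark.parametrize(
        "mode, expected",
        [("max", [1, 1]), ("min", [0, 0]), ("sum", [1, 1]), ("mean", [0.5, 0.5])],
    )
    def test_modes(self, mode, expected):
        np.testing.assert_allclose(
            combine_attributes([0, 1], [1, 0], mode), expected
        )

    def test_max_is_idempotent(self):
        x = np.array([0.2, 0.8, 0.5])
        np.testing.assert_array_equal(combine_attributes(x, x, "max"), x)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_attributes([1], [1, 2])


class TestStateNodes:
    def test_extra_bonds_dedupe_and_replace(self, cage_pair):
        g = Graph()
        g.add_node("a", "t_emit_pairs", {"pairs": [[0, 1], [1, 0], [0, 1]]})
        g.add_node("b", "extra_bonds")
        g.connect("a", "pairs", "b", "pairs")
        res = run_single(g, cage_pair)
        assert res.viz_history[0].extra_bonds == [(0, 1)]

    def test_extra_bonds_out_of_range_fails(self, cage_pair):
        g = Graph()
        g.add_node("a", "t_emit_pairs", {"pairs": [[0, 999]]})
        g.add_node("b", "extra_bonds")
        g.connect("a", "pairs", "b", "pairs")
        with pytest.raises(NodeExecutionError):
            run_single(g, cage_pair)

    def test_show_range_closed_interval(self, cage_pair):
        n = cage_pair.n_atoms
        vals = np.arange(n, dtype=float)
        g = Graph()
        g.add_node("a", "t_emit_vec", {"values": vals.tolist()})
        g.add_node("b", "show_range", {"lo": 1.0, "hi": 2.0})
        g.connect("a", "values", "b", "values")
        res = run_single(g, cage_pair)
        vis = res.viz_history[0].visible
        assert not vis[0] and vis[1] and vis[2] and not vis[3]

    def test_show_range_lo_above_hi_fails_validation(self, cage_pair):
        g = Graph()
        g.add_node("a", "t_emit_vec", {"values": [0.0] * cage_pair.n_atoms})
        g.add_node("b", "show_range", {"lo": 2.0, "hi": 1.0})
        g.connect("a", "values", "b", "values")
        assert any(d.code == "bad-params" for d in validate(g))

    def test_radius_scale_scalar_broadcast_and_positive(self, cage_pair):
        g = Graph()
        g.add_node("b", "set_radius_scale", {"scale": 2.0})
        res = run_single(g, cage_pair)
        np.testing.assert_array_equal(res.viz_history[0].radius_scale, 2.0)
        g2 = Graph()
        g2.add_node("b", "set_radius_scale", {"scale": 0.0})
        with pytest.raises(NodeExecutionError):
            run_single(g2, cage_pair)

    def test_camera_center_rejects_non_finite(self, cage_pair):
        g = Graph()
        g.add_node("a", "t_emit_point", {"point": [np.nan, 0, 0]})
        g.add_node("b", "set_camera_center")
        g.connect("a", "point", "b", "point")
        with pytest.raises(NodeExecutionError):
            run_single(g, cage_pair)

    def test_camera_center_stores_upstream_centroid(self, cage_pair):
        mask = np.zeros(cage_pair.n_atoms)
        mask[:2] = 1  # the two guests
        g = Graph()
        g.add_node("a", "positions")
        g.add_node("b", "t_emit_vec", {"values": mask.tolist()})
        g.add_node("c", "mask_centroid")
        g.add_node("d", "set_camera_center")
        g.connect("a", "positions", "c", "positions")
        g.connect("b", "values", "c", "mask")
        g.connect("c", "center", "d", "point")
        res = run_single(g, cage_pair)
        expected = cage_pair.frames[0].positions[:2].mean(axis=0)
        np.testing.assert_allclose(res.viz_history[0].camera_center, expected)


class TestMaskCentroid:
    def test_mean_of_masked_positions(self):
        pos = np.array([[0, 0, 0], [2, 0, 0], [100, 100, 100]], dtype=float)
        np.testing.assert_allclose(
            mask_centroid(pos, [1, 1, 0]), [1, 0, 0]
        )

    def test_single_atom(self):
        pos = np.array([[5.0, 6.0, 7.0]])
        np.testing.assert_allclose(mask_centroid(pos, [1]), [5, 6, 7])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mask_centroid(np.zeros((3, 3)), [0, 0, 0])


class TestPlotData:
    def test_forward_series_accumulates_in_frame_order(self, droplet, tmp_path):
        traj, _ = droplet
        g = Graph()
        g.add_node("a", "t_frame_scalar")
        g.add_node("b", "plot_data")
        g.connect("a", "y", "b", "y")
        g.frames = (0, 5)
        res = execute_trajectory(g, traj)
        assert res.series("b") == [(i, float(i)) for i in range(5)]
        out = tmp_path / "p.csv"
        export_plot_csv(res, "b", out)
        assert out.read_text().splitlines()[0] == "frame,value"

    def test_backward_series_descends(self, droplet):
        traj, _ = droplet
        g = Graph()
        g.add_node("a", "t_frame_scalar")
        g.add_node("b", "plot_data")
        g.connect("a", "y", "b", "y")
        g.frames = (0, 5)
        g.direction = "backward"
        res = execute_trajectory(g, traj)
        assert [f for f, _ in res.series("b")] == [4, 3, 2, 1, 0]

    def test_unknown_mode_fails_validation(self, droplet):
        traj, _ = droplet
        g = Graph()
        g.add_node("a", "t_frame_scalar")
        g.add_node("b", "plot_data", {"mode": "scatter"})
        g.connect("a", "y", "b", "y")
        assert any(d.code == "bad-params" for d in validate(g, traj))
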