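"""Built-in operation nodes: trajectory inputs, attribute access,
visualization-state modification, and data plotting.

Visualization here is *data*, not pixels: nodes edit a per-frame
:class:`VisualizationState` (color scalar, radius scale, visibility mask,
extra bonds, camera center) that a renderer — or a test — consumes.  The
color channel is a single scalar in [0, 1], conventionally mapped
blue (0) to red (1).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .graph_engine import node_kind

__all__ = [
    "VisualizationState",
    "combine_attributes",
    "mask_centroid",
    "export_plot_csv",
    "export_viz_json",
]


@dataclass
class VisualizationState:
    """Per-frame, per-atom render state.

    Defaults: color 0 (blue), radius scale 1, all atoms visible, no extra
    bonds, camera at the origin.
    """

    color: np.ndarray
    radius_scale: np.ndarray
    visible: np.ndarray
    extra_bonds: list = field(default_factory=list)
    camera_center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @classmethod
    def create(cls, n_atoms: int) -> "VisualizationState":
        return cls(
            color=np.zeros(n_atoms),
            radius_scale=np.ones(n_atoms),
            visible=np.ones(n_atoms, dtype=bool),
        )

    @property
    def n_atoms(self) -> int:
        return len(self.color)

    def to_jsonable(self) -> dict:
        return {
            "color": self.color.tolist(),
            "radius_scale": self.radius_scale.tolist(),
            "visible": self.visible.astype(int).tolist(),
            "extra_bonds": [[int(i), int(j)] for i, j in self.extra_bonds],
            "camera_center": self.camera_center.tolist(),
        }


# ---------------------------------------------------------------------------
# Pure helpers (the node kinds below are thin wrappers over these)


def combine_attributes(a, b, mode: str = "max") -> np.ndarray:
    """Element-wise combination of two per-atom arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if mode == "max":
        return np.maximum(a, b)
    if mode == "min":
        return np.minimum(a, b)
    if mode == "sum":
        return a + b
    if mode == "mean":
        return (a + b) / 2.0
    raise ValueError(f"unknown combine mode {mode!r}; expected max/min/sum/mean")


def mask_centroid(positions, mask) -> np.ndarray:
    """Arithmetic mean of the masked positions (no periodic unwrapping).

    With periodic boxes the caller must keep the masked set whole; the mean
    of a cluster split across a boundary is not its physical center.
    """
    positions = np.asarray(positions, dtype=float)
    mask = np.asarray(mask, dtype=float)
    sel = mask != 0
    if not np.any(sel):
        raise ValueError("mask selects no atoms")
    return positions[sel].mean(axis=0)


# ---------------------------------------------------------------------------
# Node kinds


@node_kind("positions", outputs=[("positions", "float[2]")])
def _node_positions(ctx, inputs):
    return {"positions": ctx.frame.positions.copy()}


def _velocities_check(node, graph, traj):
    wired = graph is not None and any(
        c.from_node == node.id for c in graph.connections
    )
    if wired and traj is not None and any(
        fr.velocities is None for fr in traj.frames
    ):
        return ["trajectory has no velocities"]
    return []


@node_kind("velocities", outputs=[("velocities", "float[2]")],
           param_validator=_velocities_check)
def _node_velocities(ctx, inputs):
    if ctx.frame.velocities is None:
        raise RuntimeError("frame has no velocities")
    return {"velocities": ctx.frame.velocities.copy()}


@node_kind("box", outputs=[("lengths", "float[1]"), ("periodic", "int[1]")])
def _node_box(ctx, inputs):
    box = ctx.frame.box
    return {"lengths": box.lengths.copy(), "periodic": box.periodic.astype(int)}


@node_kind("get_attribute", outputs=[("values", "float[1]")],
           param_defaults={"name": ""})
def _node_get_attribute(ctx, inputs):
    return {"values": ctx.store.get(ctx.param("name"))}


@node_kind("set_attribute", inputs=[("values", "float[1]")],
           param_defaults={"name": ""})
def _node_set_attribute(ctx, inputs):
    ctx.store.set(ctx.param("name"), inputs["values"])
    return {}


@node_kind("combine_attributes",
           inputs=[("a", "float[1]"), ("b", "float[1]")],
           outputs=[("combined", "float[1]")],
           param_defaults={"mode": "max"})
def _node_combine(ctx, inputs):
    return {"combined": combine_attributes(inputs["a"], inputs["b"], ctx.param("mode"))}


@node_kind("extra_bonds", inputs=[("pairs", "int[2]")])
def _node_extra_bonds(ctx, inputs):
    n = ctx.viz.n_atoms
    bonds = set()
    for pair in np.asarray(inputs["pairs"], dtype=int).reshape(-1, 2):
        i, j = int(pair[0]), int(pair[1])
        if not (0 <= i < n and 0 <= j < n):
            raise RuntimeError(f"bond index out of range: ({i}, {j})")
        if i != j:
            bonds.add((min(i, j), max(i, j)))
    ctx.viz.extra_bonds = sorted(bonds)
    return {}


def _show_range_check(node, graph, traj):
    lo, hi = node.param("lo", -np.inf), node.param("hi", np.inf)
    if lo > hi:
        return [f"show_range requires lo <= hi, got [{lo}, {hi}]"]
    return []


@node_kind("show_range", inputs=[("values", "float[1]")],
           param_defaults={"lo": -np.inf, "hi": np.inf},
           param_validator=_show_range_check)
def _node_show_range(ctx, inputs):
    v = np.asarray(inputs["values"], dtype=float)
    lo, hi = ctx.param("lo"), ctx.param("hi")
    ctx.viz.visible = (v >= lo) & (v <= hi)  # closed interval; ties visible
    return {}


@node_kind("set_radius_scale", inputs=[("values", "float[1]", False)],
           param_defaults={"scale": 1.0})
def _node_set_radius_scale(ctx, inputs):
    if "values" in inputs:
        v = np.asarray(inputs["values"], dtype=float)
        if v.shape != (ctx.viz.n_atoms,):
            raise RuntimeError(f"radius array has wrong length {v.shape}")
    else:
        v = np.full(ctx.viz.n_atoms, float(ctx.param("scale")))
    if np.any(v <= 0):
        raise RuntimeError("radius scale must be positive")
    ctx.viz.radius_scale = v
    return {}


@node_kind("set_color", inputs=[("values", "float[1]")])
def _node_set_color(ctx, inputs):
    v = np.clip(np.asarray(inputs["values"], dtype=float), 0.0, 1.0)
    if v.shape != (ctx.viz.n_atoms,):
        raise RuntimeError(f"color array has wrong length {v.shape}")
    ctx.viz.color = v
    return {}


@node_kind("set_camera_center", inputs=[("point", "float[1]")])
def _node_set_camera_center(ctx, inputs):
    p = np.asarray(inputs["point"], dtype=float).reshape(3)
    if not np.all(np.isfinite(p)):
        raise RuntimeError("camera center must be finite")
    ctx.viz.camera_center = p
    return {}


def _plot_mode_check(node, graph, traj):
    mode = node.param("mode", "lines_accumulate")
    if mode != "lines_accumulate":
        return [f"unknown plot mode {mode!r}"]
    return []


@node_kind("plot_data", inputs=[("y", "float")],
           param_defaults={"mode": "lines_accumulate"},
           param_validator=_plot_mode_check)
def _node_plot_data(ctx, inputs):
    y = inputs["y"]
    if np.ndim(y) != 0:
        raise RuntimeError("plot_data needs a scalar input")
    series = ctx.result.plot_series.setdefault(ctx.node.id, {})
    series[ctx.frame_index] = float(y)
    return {}


@node_kind("mask_centroid",
           inputs=[("positions", "float[2]"), ("mask", "float[1]")],
           outputs=[("center", "float[1]")])
def _node_mask_centroid(ctx, inputs):
    return {"center": mask_centroid(inputs["positions"], inputs["mask"])}


# ---------------------------------------------------------------------------
# Exports


def export_plot_csv(result, node_id, path) -> None:
    """Write a plot node's series as CSV with header ``frame,value``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "value"])
        for frame, value in result.series(node_id):
            writer.writerow([frame, f"{value:.10g}"])


def export_viz_json(result, path) -> None:
    """Write the per-frame visualization states as one JSON object keyed by
    frame index."""
    import json

    payload = {str(f): v.to_jsonable() for f, v in sorted(result.viz_history.items())}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
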