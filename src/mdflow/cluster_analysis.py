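"""Nucleated-cluster analysis: neighbor lists, connected-component grouping,
largest-cluster masking, recurrent cluster tracking, and color graduation.

The tracking algorithm is recurrent: the binary label attribute written on
one frame is read back on the next, so running the same graph backward from
the final snapshot traces a cluster's history to its nucleation.  Per frame
the rule is

1. group atoms into clusters (connected components of the cutoff graph);
2. count, per cluster, the atoms that carried the label on the previously
   executed frame;
3. give the label to the cluster with the largest count (smallest group id
   on ties); if no cluster overlaps the old label, the tracked cluster has
   dissipated and all labels are cleared.

Isolated atoms are not clusters: groups below ``min_cluster_size``
(default 2) cannot inherit the label, which is what allows the label to
clear when a cluster disperses into free gas atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .datamodel import AttributeStore, Box, Trajectory, minimum_image
from .graph_engine import Graph, execute_trajectory, node_kind

__all__ = [
    "NeighborList",
    "list_neighbors",
    "group_list",
    "mode_mask",
    "track_cluster",
    "labels2colors",
    "build_largest_cluster_graph",
    "build_tracking_graph",
    "build_color_graph",
    "track_main_cluster",
]


@dataclass
class NeighborList:
    """Symmetric neighbor lists under a distance cutoff (closed: d <= cutoff)."""

    neighbors: list  # per-atom int arrays
    counts: np.ndarray
    cutoff: float

    @property
    def n_atoms(self) -> int:
        return len(self.neighbors)

    def edges(self) -> np.ndarray:
        """Unique (i < j) edge array, shape (m, 2)."""
        out = [
            (i, int(j))
            for i, nbrs in enumerate(self.neighbors)
            for j in nbrs
            if i < j
        ]
        return np.array(out, dtype=int).reshape(-1, 2)


def _check_cutoff(box: Box, cutoff: float) -> None:
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    per = box.periodic
    if np.any(per & (box.lengths / 2.0 < cutoff)):
        raise ValueError(
            f"cutoff {cutoff} exceeds half the box length on a periodic axis "
            f"(lengths {box.lengths.tolist()}); minimum image is ill-defined"
        )


def list_neighbors(positions, box: Box, cutoff: float) -> NeighborList:
    """All pairs within ``cutoff`` (minimum-image), via a cell list.

    Equivalent to the O(N^2) all-pairs search; the cell decomposition only
    changes the cost.  The criterion is closed: a pair at exactly the cutoff
    distance counts as neighbors.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    _check_cutoff(box, cutoff)
    if n == 0:
        return NeighborList([], np.zeros(0, dtype=int), cutoff)

    per = box.periodic
    ncells = np.ones(3, dtype=int)
    origin = np.zeros(3)
    width = np.ones(3)
    for ax in range(3):
        if per[ax]:
            L = box.lengths[ax]
            ncells[ax] = max(1, int(L // cutoff))
            origin[ax] = 0.0
            width[ax] = L / ncells[ax]
        else:
            lo = pos[:, ax].min()
            hi = pos[:, ax].max()
            ncells[ax] = max(1, int((hi - lo) // cutoff) + 1)
            origin[ax] = lo
            width[ax] = max((hi - lo) / ncells[ax], cutoff)

    coords = pos - origin
    for ax in range(3):
        if per[ax]:
            coords[:, ax] = coords[:, ax] % box.lengths[ax]
    idx = np.floor(coords / width).astype(int)
    idx = np.minimum(np.maximum(idx, 0), ncells - 1)

    cells: dict[tuple, list] = {}
    for i, key in enumerate(map(tuple, idx)):
        cells.setdefault(key, []).append(i)
    cells = {k: np.array(v, dtype=int) for k, v in cells.items()}

    def neighbor_cells(key):
        ranges = []
        for ax in range(3):
            c = key[ax]
            if per[ax]:
                ranges.append({(c + d) % ncells[ax] for d in (-1, 0, 1)})
            else:
                ranges.append({c + d for d in (-1, 0, 1) if 0 <= c + d < ncells[ax]})
        return product(*ranges)

    cell_candidates = {
        key: np.unique(
            np.concatenate([cells[k] for k in neighbor_cells(key) if k in cells])
        )
        for key in cells
    }

    neighbors = [None] * n
    for key, members in cells.items():
        cand = cell_candidates[key]
        cpos = pos[cand]
        for i in members:
            d = minimum_image(pos[i], cpos, box)
            close = np.linalg.norm(d, axis=1) <= cutoff
            nbrs = cand[close]
            neighbors[i] = nbrs[nbrs != i]
    counts = np.array([len(v) for v in neighbors], dtype=int)
    return NeighborList(neighbors, counts, cutoff)


def group_list(neighbors) -> np.ndarray:
    """Connected-component labels of the neighbor graph.

    Group ids are consecutive 0..k-1, assigned in order of each component's
    smallest atom index.  ``neighbors`` is a :class:`NeighborList` or a raw
    per-atom list of neighbor-index arrays.
    """
    lists = neighbors.neighbors if isinstance(neighbors, NeighborList) else neighbors
    n = len(lists)
    if n == 0:
        return np.zeros(0, dtype=int)
    rows = np.concatenate([np.full(len(v), i, dtype=int) for i, v in enumerate(lists)]) \
        if any(len(v) for v in lists) else np.zeros(0, dtype=int)
    cols = np.concatenate([np.asarray(v, dtype=int) for v in lists]) \
        if any(len(v) for v in lists) else np.zeros(0, dtype=int)
    adj = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    k, raw = connected_components(adj, directed=False)
    first = np.full(k, n, dtype=int)
    np.minimum.at(first, raw, np.arange(n))
    new_id = np.empty(k, dtype=int)
    new_id[np.argsort(first, kind="stable")] = np.arange(k)
    return new_id[raw]


def mode_mask(labels) -> np.ndarray:
    """1 for atoms in the most frequent group (smallest label wins ties)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        return np.zeros(0, dtype=int)
    counts = np.bincount(labels)
    winner = int(np.argmax(counts))  # argmax returns the smallest index on ties
    return (labels == winner).astype(int)


def track_cluster(prev_labels, group_labels, min_cluster_size: int = 2) -> np.ndarray:
    """One step of recurrent cluster tracking (see module docstring).

    Returns a binary per-atom label array: 1 on the cluster inheriting the
    label, 0 elsewhere; all zeros when the tracked cluster has dissipated.
    """
    prev = np.asarray(prev_labels, dtype=float) != 0
    groups = np.asarray(group_labels, dtype=int)
    if groups.shape != prev.shape:
        raise ValueError("prev_labels and group_labels must have equal length")
    if groups.size == 0 or not prev.any():
        return np.zeros_like(groups)
    k = int(groups.max()) + 1
    overlap = np.bincount(groups[prev], minlength=k)
    sizes = np.bincount(groups, minlength=k)
    overlap[sizes < min_cluster_size] = 0
    if overlap.max() == 0:
        return np.zeros_like(groups)
    winner = int(np.argmax(overlap))  # smallest group id on ties
    return (groups == winner).astype(int)


def labels2colors(labels, prev_colors, fade_rate: float = 0.05) -> np.ndarray:
    """Fade colors toward red (1) while labeled, toward blue (0) otherwise.

    One call advances the gradient by ``fade_rate`` (clamped to [0, 1]); an
    atom labeled for ceil(1/fade_rate) consecutive frames from 0 reaches
    exactly 1.
    """
    if not (0.0 < fade_rate <= 1.0):
        raise ValueError(f"fade_rate must be in (0, 1], got {fade_rate}")
    labels = np.asarray(labels, dtype=float)
    colors = np.asarray(prev_colors, dtype=float)
    if labels.shape != colors.shape:
        raise ValueError("labels and colors must have equal length")
    if np.any((colors < 0) | (colors > 1)):
        raise ValueError("colors must lie in [0, 1]")
    step = np.where(labels != 0, fade_rate, -fade_rate)
    return np.clip(colors + step, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Node kinds


def _cutoff_check(node, graph, traj):
    cutoff = node.param("cutoff")
    if cutoff is None or not cutoff > 0:
        return [f"needs a positive 'cutoff' parameter, got {cutoff!r}"]
    return []


@node_kind("list_neighbors", inputs=[("positions", "float[2]")],
           outputs=[("neighbors", "int[2]"), ("counts", "int[1]")],
           param_validator=_cutoff_check)
def _node_list_neighbors(ctx, inputs):
    nl = list_neighbors(inputs["positions"], ctx.frame.box, ctx.param("cutoff"))
    return {"neighbors": nl.neighbors, "counts": nl.counts}


@node_kind("group_list", inputs=[("neighbors", "int[2]")],
           outputs=[("labels", "int[1]")])
def _node_group_list(ctx, inputs):
    return {"labels": group_list(inputs["neighbors"])}


@node_kind("mode_mask", inputs=[("labels", "int[1]")],
           outputs=[("mask", "int[1]")])
def _node_mode_mask(ctx, inputs):
    return {"mask": mode_mask(inputs["labels"])}


@node_kind("track_cluster",
           inputs=[("prev_labels", "float[1]"), ("groups", "int[1]")],
           outputs=[("labels", "int[1]")],
           param_defaults={"min_cluster_size": 2})
def _node_track_cluster(ctx, inputs):
    return {
        "labels": track_cluster(
            inputs["prev_labels"], inputs["groups"],
            min_cluster_size=int(ctx.param("min_cluster_size")),
        )
    }


def _fade_check(node, graph, traj):
    rate = node.param("fade_rate", 0.05)
    if not (0.0 < rate <= 1.0):
        return [f"fade_rate must be in (0, 1], got {rate}"]
    return []


@node_kind("labels2colors",
           inputs=[("labels", "float[1]"), ("colors", "float[1]")],
           outputs=[("colors", "float[1]")],
           param_defaults={"fade_rate": 0.05},
           param_validator=_fade_check)
def _node_labels2colors(ctx, inputs):
    return {
        "colors": labels2colors(inputs["labels"], inputs["colors"],
                                fade_rate=float(ctx.param("fade_rate")))
    }


# ---------------------------------------------------------------------------
# Ready-made graphs


def build_largest_cluster_graph(cutoff: float, out_attr: str = "current_label") -> Graph:
    """positions -> list_neighbors -> group_list -> mode_mask -> attribute."""
    g = Graph()
    g.add_node("a_pos", "positions")
    g.add_node("b_neigh", "list_neighbors", {"cutoff": cutoff})
    g.add_node("c_groups", "group_list")
    g.add_node("d_mask", "mode_mask")
    g.add_node("e_save", "set_attribute", {"name": out_attr})
    g.connect("a_pos", "positions", "b_neigh", "positions")
    g.connect("b_neigh", "neighbors", "c_groups", "neighbors")
    g.connect("c_groups", "labels", "d_mask", "labels")
    g.connect("d_mask", "mask", "e_save", "values")
    g.declare_attribute(out_attr, init=0.0, record=True)
    return g


def build_tracking_graph(cutoff: float, label_attr: str = "current_label",
                         save_attr: str = "saved_label",
                         direction: str = "backward",
                         min_cluster_size: int = 2) -> Graph:
    """The recurrent tracking graph: ``label_attr`` is both read and written
    by the track_cluster node (feedback through the attribute store), and a
    second attribute saves the label for the whole trajectory."""
    g = Graph()
    g.add_node("a_pos", "positions")
    g.add_node("b_neigh", "list_neighbors", {"cutoff": cutoff})
    g.add_node("c_groups", "group_list")
    g.add_node("d_prev", "get_attribute", {"name": label_attr})
    g.add_node("e_track", "track_cluster", {"min_cluster_size": min_cluster_size})
    g.add_node("f_update", "set_attribute", {"name": label_attr})
    g.add_node("g_save", "set_attribute", {"name": save_attr})
    g.connect("a_pos", "positions", "b_neigh", "positions")
    g.connect("b_neigh", "neighbors", "c_groups", "neighbors")
    g.connect("c_groups", "labels", "e_track", "groups")
    g.connect("d_prev", "values", "e_track", "prev_labels")
    g.connect("e_track", "labels", "f_update", "values")
    g.connect("e_track", "labels", "g_save", "values")
    g.declare_attribute(label_attr, init=0.0, record=False)
    g.declare_attribute(save_attr, init=0.0, record=True)
    g.direction = direction
    return g


def build_color_graph(fade_rate: float = 0.05, label_attr: str = "saved_label",
                      color_attr: str = "color",
                      direction: str = "forward") -> Graph:
    """Recurrent color graduation: atoms fade to red while labeled and back
    to blue when not.  ``label_attr`` is fed per frame (e.g. the tracking
    run's saved labels); ``color_attr`` carries the gradient between frames."""
    g = Graph()
    g.add_node("a_labels", "get_attribute", {"name": label_attr})
    g.add_node("b_colors", "get_attribute", {"name": color_attr})
    g.add_node("c_fade", "labels2colors", {"fade_rate": fade_rate})
    g.add_node("d_store", "set_attribute", {"name": color_attr})
    g.add_node("e_show", "set_color")
    g.connect("a_labels", "values", "c_fade", "labels")
    g.connect("b_colors", "values", "c_fade", "colors")
    g.connect("c_fade", "colors", "d_store", "values")
    g.connect("c_fade", "colors", "e_show", "values")
    g.declare_attribute(color_attr, init=0.0, record=True)
    g.direction = direction
    return g


def track_main_cluster(traj: Trajectory, cutoff: float,
                       min_cluster_size: int = 2) -> dict[int, np.ndarray]:
    """Identify the largest cluster of the final frame, then track it
    backward through the whole trajectory.

    Returns {frame index -> binary membership array}.  This is the two-run
    composition the node graphs express: the largest-cluster graph on the
    final frame seeds the label attribute, and the recurrent tracking graph
    replays the trajectory backward over the same attribute store.
    """
    n = traj.n_frames
    store = AttributeStore(traj.n_atoms)
    seed_graph = build_largest_cluster_graph(cutoff)
    seed_graph.frames = (n - 1, n)
    execute_trajectory(seed_graph, traj, store=store)
    tracking = build_tracking_graph(cutoff, min_cluster_size=min_cluster_size)
    result = execute_trajectory(tracking, traj, store=store)
    return result.attribute_history["saved_label"]
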