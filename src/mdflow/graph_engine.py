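"""Typed dataflow execution graphs.

An analysis algorithm is a directed acyclic graph of nodes exchanging data
over typed ports.  The engine validates the graph, schedules nodes
topologically (ties broken by node id, so execution is deterministic), and
runs the whole graph once per trajectory frame, forward or backward in time.

Recurrence — state carried from frame to frame — never flows through
connections (those stay acyclic) but through named per-atom *attributes*
(:class:`~mdflow.datamodel.AttributeStore`).  A node may read an attribute
that another node (or itself, on the previous frame) writes; reads and
writes take effect immediately in topological order.  Every output port of
every executed node is cached per frame in the :class:`RunResult`.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np

from .datamodel import AttributeStore, Trajectory

__all__ = [
    "PortType",
    "Node",
    "Connection",
    "AttributeDecl",
    "Graph",
    "Diagnostic",
    "RunResult",
    "NodeKind",
    "register_node_kind",
    "node_kind",
    "get_node_kind",
    "validate",
    "topo_order",
    "execute_frame",
    "execute_trajectory",
    "save_graph",
    "load_graph",
    "GraphValidationError",
    "NodeExecutionError",
    "GraphSchemaError",
]

_BASES = ("int", "float", "string")


@dataclass(frozen=True)
class PortType:
    """Port data type: a base scalar type and an array rank (0 = scalar)."""

    base: str
    rank: int = 0

    def __post_init__(self):
        if self.base not in _BASES:
            raise ValueError(f"unknown base type {self.base!r}; expected one of {_BASES}")
        if self.rank < 0:
            raise ValueError("rank must be >= 0")

    @classmethod
    def parse(cls, text: str) -> "PortType":
        """Parse ``"float"`` or ``"float[2]"`` notation."""
        text = text.strip()
        if text.endswith("]"):
            base, _, rank = text[:-1].partition("[")
            return cls(base.strip(), int(rank))
        return cls(text, 0)

    def __str__(self):
        return f"{self.base}[{self.rank}]" if self.rank else self.base

    def accepts(self, other: "PortType") -> bool:
        """Can a value of type ``other`` flow into a port of this type?

        Identical types are compatible; int promotes to float at any rank;
        rank mismatches never are.
        """
        if self.rank != other.rank:
            return False
        if self.base == other.base:
            return True
        return other.base == "int" and self.base == "float"


@dataclass(frozen=True)
class PortSpec:
    name: str
    ptype: PortType
    required: bool = True


@dataclass
class NodeKind:
    """A registered node implementation.

    ``resolve_ports(params)`` returns ``(inputs, outputs)`` as lists of
    :class:`PortSpec`, letting port layouts depend on parameters (script
    nodes parse their source file here).  ``run(ctx, inputs)`` executes the
    node and returns a dict of output-port values.
    """

    name: str
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    run: object = None
    param_defaults: dict = field(default_factory=dict)
    resolver: object = None  # optional params -> (inputs, outputs)
    param_validator: object = None  # optional (node, graph, traj) -> list[str]

    def resolve_ports(self, params):
        if self.resolver is not None:
            return self.resolver(params)
        return self.inputs, self.outputs


NODE_KINDS: dict[str, NodeKind] = {}


def register_node_kind(kind: NodeKind) -> NodeKind:
    NODE_KINDS[kind.name] = kind
    return kind


def node_kind(name, inputs=(), outputs=(), param_defaults=None, resolver=None,
              param_validator=None):
    """Decorator registering a run function as a node kind.

    Port declarations are ``(name, "type")`` or ``(name, "type", required)``
    tuples; types use :meth:`PortType.parse` notation.
    """

    def to_specs(decls):
        specs = []
        for d in decls:
            name_, type_, *rest = d
            specs.append(PortSpec(name_, PortType.parse(type_), rest[0] if rest else True))
        return specs

    def wrap(fn):
        register_node_kind(
            NodeKind(
                name=name,
                inputs=to_specs(inputs),
                outputs=to_specs(outputs),
                run=fn,
                param_defaults=dict(param_defaults or {}),
                resolver=resolver,
                param_validator=param_validator,
            )
        )
        return fn

    return wrap


def get_node_kind(name: str) -> NodeKind:
    if name not in NODE_KINDS:
        raise KeyError(f"unknown node kind {name!r}; registered: {sorted(NODE_KINDS)}")
    return NODE_KINDS[name]


@dataclass
class Node:
    id: str
    kind: str
    params: dict = field(default_factory=dict)

    def param(self, name, default=None):
        if name in self.params:
            return self.params[name]
        spec = NODE_KINDS.get(self.kind)
        if spec is not None and name in spec.param_defaults:
            return spec.param_defaults[name]
        return default


@dataclass(frozen=True)
class Connection:
    from_node: str
    from_port: str
    to_node: str
    to_port: str


@dataclass
class AttributeDecl:
    name: str
    init: float = 0.0
    record: bool = False


@dataclass(frozen=True)
class Diagnostic:
    code: str
    message: str
    nodes: tuple = ()

    def __str__(self):
        return f"[{self.code}] {self.message}"


class GraphValidationError(ValueError):
    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        super().__init__(
            "graph failed validation:\n" + "\n".join(str(d) for d in self.diagnostics)
        )


class GraphSchemaError(ValueError):
    """Graph JSON does not match the schema; message names the JSON path."""


class NodeExecutionError(RuntimeError):
    """A node raised during execution; carries node id, frame, and the
    partial :class:`RunResult` accumulated for already-completed frames."""

    def __init__(self, node_id, frame_index, cause, partial_result=None):
        super().__init__(
            f"node {node_id!r} failed at frame {frame_index}: {cause}"
        )
        self.node_id = node_id
        self.frame_index = frame_index
        self.cause = cause
        self.partial_result = partial_result


@dataclass
class Graph:
    """A dataflow graph plus its attribute declarations and run options."""

    nodes: dict = field(default_factory=dict)  # id -> Node, insertion ordered
    connections: list = field(default_factory=list)
    attributes: list = field(default_factory=list)  # AttributeDecl
    direction: str = "forward"
    frames: tuple | None = None  # (start, stop) half-open, None = all

    def add_node(self, id: str, kind: str, params: dict | None = None) -> Node:
        if id in self.nodes:
            raise ValueError(f"duplicate node id {id!r}")
        node = Node(id=id, kind=kind, params=dict(params or {}))
        self.nodes[id] = node
        return node

    def connect(self, from_node: str, from_port: str, to_node: str, to_port: str):
        conn = Connection(from_node, from_port, to_node, to_port)
        self.connections.append(conn)
        return conn

    def declare_attribute(self, name: str, init=0.0, record: bool = False):
        self.attributes.append(AttributeDecl(name, init, record))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"id": n.id, "kind": n.kind, "params": dict(n.params)}
                for n in self.nodes.values()
            ],
            "connections": [
                {"from": [c.from_node, c.from_port], "to": [c.to_node, c.to_port]}
                for c in self.connections
            ],
            "attributes": [
                {"name": a.name, "init": a.init, "record": a.record}
                for a in self.attributes
            ],
            "execution": {
                "direction": self.direction,
                "frames": list(self.frames) if self.frames is not None else None,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Graph":
        def need(obj, key, path, types):
            if not isinstance(obj, dict) or key not in obj:
                raise GraphSchemaError(f"{path}: missing key {key!r}")
            val = obj[key]
            if not isinstance(val, types):
                raise GraphSchemaError(f"{path}.{key}: wrong type {type(val).__name__}")
            return val

        g = cls()
        for i, nd in enumerate(data.get("nodes", [])):
            path = f"nodes[{i}]"
            nid = need(nd, "id", path, str)
            kind = need(nd, "kind", path, str)
            if kind not in NODE_KINDS:
                raise GraphSchemaError(f"{path}.kind: unknown node kind {kind!r}")
            params = nd.get("params", {})
            if not isinstance(params, dict):
                raise GraphSchemaError(f"{path}.params: wrong type")
            g.add_node(nid, kind, params)
        for i, cn in enumerate(data.get("connections", [])):
            path = f"connections[{i}]"
            src = need(cn, "from", path, (list, tuple))
            dst = need(cn, "to", path, (list, tuple))
            if len(src) != 2 or len(dst) != 2:
                raise GraphSchemaError(f"{path}: endpoints must be [node, port] pairs")
            g.connect(src[0], src[1], dst[0], dst[1])
        for i, at in enumerate(data.get("attributes", [])):
            path = f"attributes[{i}]"
            name = need(at, "name", path, str)
            g.declare_attribute(name, at.get("init", 0.0), bool(at.get("record", False)))
        execution = data.get("execution", {})
        if not isinstance(execution, dict):
            raise GraphSchemaError("execution: wrong type")
        direction = execution.get("direction", "forward")
        if direction not in ("forward", "backward"):
            raise GraphSchemaError(
                f"execution.direction: must be 'forward' or 'backward', got {direction!r}"
            )
        g.direction = direction
        frames = execution.get("frames")
        if frames is not None:
            if not (isinstance(frames, (list, tuple)) and len(frames) == 2):
                raise GraphSchemaError("execution.frames: must be [start, stop]")
            g.frames = (int(frames[0]), int(frames[1]))
        return g


def save_graph(graph: Graph, path) -> None:
    with open(path, "w") as fh:
        json.dump(graph.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_graph(path) -> Graph:
    with open(path) as fh:
        return Graph.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Validation & scheduling


def _resolved_ports(graph: Graph):
    """Resolve (inputs, outputs) port specs per node; collect failures."""
    resolved = {}
    diags = []
    for node in graph.nodes.values():
        if node.kind not in NODE_KINDS:
            diags.append(
                Diagnostic("unknown-kind", f"node {node.id!r} has unknown kind {node.kind!r}", (node.id,))
            )
            continue
        try:
            inputs, outputs = NODE_KINDS[node.kind].resolve_ports(node.params)
        except Exception as e:
            diags.append(
                Diagnostic("bad-params", f"node {node.id!r}: cannot resolve ports: {e}", (node.id,))
            )
            continue
        resolved[node.id] = ({p.name: p for p in inputs}, {p.name: p for p in outputs})
    return resolved, diags


def validate(graph: Graph, traj: Trajectory | None = None) -> list[Diagnostic]:
    """Check a graph; an empty list means it is executable.

    Covers unknown node kinds, dangling connection endpoints, port type
    mismatches, multiply-wired inputs, connection cycles, unwired required
    inputs, and node-specific parameter errors.  Passing ``traj`` enables
    trajectory-dependent checks (e.g. a wired velocities node on a
    trajectory without velocities).
    """
    resolved, diags = _resolved_ports(graph)

    incoming_count: dict[tuple, int] = {}
    for c in graph.connections:
        ok = True
        for nid, port, side in (
            (c.from_node, c.from_port, "output"),
            (c.to_node, c.to_port, "input"),
        ):
            if nid not in graph.nodes:
                diags.append(
                    Diagnostic("dangling", f"connection references unknown node {nid!r}", (nid,))
                )
                ok = False
            elif nid in resolved:
                ports = resolved[nid][1] if side == "output" else resolved[nid][0]
                if port not in ports:
                    diags.append(
                        Diagnostic(
                            "dangling",
                            f"node {nid!r} has no {side} port {port!r}",
                            (nid,),
                        )
                    )
                    ok = False
        if not ok:
            continue
        if c.from_node in resolved and c.to_node in resolved:
            src_t = resolved[c.from_node][1][c.from_port].ptype
            dst_t = resolved[c.to_node][0][c.to_port].ptype
            if not dst_t.accepts(src_t):
                diags.append(
                    Diagnostic(
                        "type-mismatch",
                        f"{c.from_node}.{c.from_port} ({src_t}) -> "
                        f"{c.to_node}.{c.to_port} ({dst_t}) is incompatible",
                        (c.from_node, c.to_node),
                    )
                )
        key = (c.to_node, c.to_port)
        incoming_count[key] = incoming_count.get(key, 0) + 1
        if incoming_count[key] == 2:
            diags.append(
                Diagnostic(
                    "multiple-inputs",
                    f"input {c.to_node}.{c.to_port} has more than one incoming connection",
                    (c.to_node,),
                )
            )

    # required inputs
    wired = {(c.to_node, c.to_port) for c in graph.connections}
    for nid, (inputs, _) in resolved.items():
        for pname, spec in inputs.items():
            if spec.required and (nid, pname) not in wired:
                diags.append(
                    Diagnostic(
                        "missing-input",
                        f"required input {nid}.{pname} is not connected",
                        (nid,),
                    )
                )

    # cycles over the connection digraph
    cyclic = _cycle_nodes(graph)
    if cyclic:
        diags.append(
            Diagnostic(
                "cycle",
                "connection cycle involving nodes: " + ", ".join(sorted(cyclic)),
                tuple(sorted(cyclic)),
            )
        )

    # node-specific parameter checks
    for node in graph.nodes.values():
        spec = NODE_KINDS.get(node.kind)
        if spec is not None and spec.param_validator is not None:
            for msg in spec.param_validator(node, graph, traj):
                diags.append(Diagnostic("bad-params", f"node {node.id!r}: {msg}", (node.id,)))
    return diags


def _adjacency(graph: Graph):
    succ = {nid: set() for nid in graph.nodes}
    indeg = {nid: 0 for nid in graph.nodes}
    for c in graph.connections:
        if c.from_node in succ and c.to_node in succ:
            if c.to_node not in succ[c.from_node]:
                succ[c.from_node].add(c.to_node)
                indeg[c.to_node] += 1
    return succ, indeg


def _kahn(graph: Graph):
    succ, indeg = _adjacency(graph)
    ready = [nid for nid, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    order = []
    while ready:
        nid = heapq.heappop(ready)
        order.append(nid)
        for nxt in sorted(succ[nid]):
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                heapq.heappush(ready, nxt)
    return order


def _cycle_nodes(graph: Graph) -> set:
    order = _kahn(graph)
    return set(graph.nodes) - set(order)


def topo_order(graph: Graph) -> list[str]:
    """Topological node order; ties broken by lexicographic node id."""
    order = _kahn(graph)
    if len(order) != len(graph.nodes):
        cyc = sorted(set(graph.nodes) - set(order))
        raise GraphValidationError(
            [Diagnostic("cycle", "connection cycle involving nodes: " + ", ".join(cyc), tuple(cyc))]
        )
    return order


# ---------------------------------------------------------------------------
# Execution


@dataclass
class RunResult:
    """Everything a run produces: per-(frame, node, port) cache, recorded
    attribute histories, per-frame visualization state, and plot series."""

    cache: dict = field(default_factory=dict)  # (frame, node, port) -> value
    attribute_history: dict = field(default_factory=dict)  # name -> {frame: arr}
    viz_history: dict = field(default_factory=dict)  # frame -> VisualizationState
    plot_series: dict = field(default_factory=dict)  # node -> {frame: float}
    visit_order: list = field(default_factory=list)

    def value(self, frame: int, node: str, port: str):
        return self.cache[(frame, node, port)]

    def series(self, node: str) -> list[tuple[int, float]]:
        """Plot-node points as (frame, value) in visit order."""
        return [(f, v) for f, v in self.plot_series.get(node, {}).items()]

    def to_json(self) -> str:
        """Canonical JSON serialization (byte-stable for identical runs)."""
        payload = {
            "visit_order": self.visit_order,
            "cache": {
                f"{f}|{n}|{p}": _jsonable(v)
                for (f, n, p), v in sorted(self.cache.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
            },
            "attributes": {
                name: {str(f): _jsonable(a) for f, a in sorted(hist.items())}
                for name, hist in sorted(self.attribute_history.items())
            },
            "viz": {str(f): _jsonable(v) for f, v in sorted(self.viz_history.items())},
            "plots": {
                n: [[f, _jsonable(y)] for f, y in pts.items()]
                for n, pts in sorted(self.plot_series.items())
            },
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, np.generic):
        return v.item()
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if isinstance(v, dict):
        return {str(k): _jsonable(x) for k, x in v.items()}
    if hasattr(v, "to_jsonable"):
        return v.to_jsonable()
    return v


@dataclass
class ExecutionContext:
    """Handed to every node's run function."""

    traj: Trajectory
    frame: object
    frame_index: int
    store: AttributeStore
    viz: object
    node: Node
    direction: str
    result: RunResult

    def param(self, name, default=None):
        return self.node.param(name, default)


def _frame_range(graph: Graph, traj: Trajectory):
    n = traj.n_frames
    if graph.frames is None:
        start, stop = 0, n
    else:
        start, stop = graph.frames
        if not (0 <= start < stop <= n):
            raise ValueError(f"frame range {graph.frames} invalid for {n}-frame trajectory")
    seq = list(range(start, stop))
    if graph.direction == "backward":
        seq.reverse()
    return seq


def _prepare(graph: Graph, traj: Trajectory, store: AttributeStore | None):
    diags = validate(graph, traj)
    if diags:
        raise GraphValidationError(diags)
    if store is None:
        store = AttributeStore(traj.n_atoms)
    for decl in graph.attributes:
        if decl.name in store:
            # keep existing values (lets a previous run seed this one),
            # but honor the recording flag
            store.recorded[decl.name] = store.recorded.get(decl.name, False) or decl.record
            store.history.setdefault(decl.name, {})
        else:
            store.declare(decl.name, init=decl.init, record=decl.record)
    order = _kahn(graph)
    resolved, _ = _resolved_ports(graph)
    in_wires = {}
    for c in graph.connections:
        in_wires[(c.to_node, c.to_port)] = (c.from_node, c.from_port)
    return store, order, resolved, in_wires


def execute_frame(graph, traj, frame_index, store, result=None,
                  frame_attributes=None, _plan=None):
    """Execute every node once for one frame; returns the frame cache.

    Input nodes read this frame's data; attribute reads and writes take
    effect immediately in topological order; recorded attributes and the
    visualization state are snapshotted after the last node.
    """
    from .builtin_nodes import VisualizationState

    if _plan is None:
        store, order, resolved, in_wires = _prepare(graph, traj, store)
    else:
        order, resolved, in_wires = _plan
    if result is None:
        result = RunResult()
    fr = traj.frames[frame_index]

    # refresh attributes imported from the trajectory file / caller
    for name in traj.attributes:
        if name not in store:
            store.declare(name, record=True)
        store.set(name, traj.frame_attribute(name, frame_index))
    if frame_attributes:
        for name, per_frame in frame_attributes.items():
            if fr.index in per_frame:
                if name not in store:
                    store.declare(name)
                store.set(name, per_frame[fr.index])

    viz = VisualizationState.create(traj.n_atoms)
    frame_cache = {}
    for nid in order:
        node = graph.nodes[nid]
        kind = NODE_KINDS[node.kind]
        in_specs, out_specs = resolved[nid]
        inputs = {}
        for pname, spec in in_specs.items():
            wire = in_wires.get((nid, pname))
            if wire is not None:
                inputs[pname] = frame_cache[wire]
        ctx = ExecutionContext(
            traj=traj, frame=fr, frame_index=fr.index, store=store, viz=viz,
            node=node, direction=graph.direction, result=result,
        )
        try:
            outputs = kind.run(ctx, inputs) or {}
            for pname in out_specs:
                if pname not in outputs:
                    raise RuntimeError(f"node produced no value for output port {pname!r}")
        except NodeExecutionError:
            raise
        except Exception as e:
            raise NodeExecutionError(nid, fr.index, e, partial_result=result) from e
        for pname in out_specs:
            val = outputs[pname]
            frame_cache[(nid, pname)] = val
            result.cache[(fr.index, nid, pname)] = val

    for name in list(store.recorded):
        store.snapshot(name, fr.index)
    result.viz_history[fr.index] = viz
    result.visit_order.append(fr.index)
    return frame_cache


def execute_trajectory(graph: Graph, traj: Trajectory, store=None,
                       frame_attributes=None) -> RunResult:
    """Run the graph over the configured frame range in the configured
    direction.  Attribute values persist across frames — this is the
    recurrence mechanism.

    ``store`` may be a pre-populated :class:`AttributeStore` (e.g. seeded by
    a previous run); ``frame_attributes`` maps attribute name -> {frame
    index -> per-atom array} loaded at the start of each frame, like
    attributes imported from a trajectory file.
    """
    store, order, resolved, in_wires = _prepare(graph, traj, store)
    result = RunResult()
    plan = (order, resolved, in_wires)
    for pos in _frame_range(graph, traj):
        try:
            execute_frame(graph, traj, pos, store, result,
                          frame_attributes=frame_attributes, _plan=plan)
        except NodeExecutionError as e:
            e.partial_result = result
            result.attribute_history = store.history
            raise
    result.attribute_history = store.history
    return result
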