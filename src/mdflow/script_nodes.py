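"""User scripts as graph nodes, with no framework API.

A plain Python script becomes a node by annotating the variables it wants to
expose with comment lines of the form::

    # @in xs : float[1]
    # @out n : int

``@in``/``@out`` declare direction, then the variable name, then the port
type (base ``int``/``float``/``string``, optional ``[rank]``, rank 0 if
omitted).  Annotations must immediately precede the statement where the
variable is first assigned or used; everything not annotated stays invisible
to the graph.  The script body contains no imports of, or calls into, this
package — inputs simply appear as variables in its namespace, and outputs
are read back after it runs.  Arrays are copied both ways, so a script can
never alias or mutate another node's data.
"""

from __future__ import annotations

import re
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph_engine import Node, NodeKind, PortSpec, PortType, register_node_kind

__all__ = ["ScriptNodeSpec", "ScriptAnnotationError", "parse_annotations",
           "parse_script_file", "make_script_node"]


class ScriptAnnotationError(ValueError):
    """Malformed @in/@out annotation; message carries the line number."""

    def __init__(self, lineno, message, path=None):
        prefix = f"{path}:{lineno}" if path else f"line {lineno}"
        super().__init__(f"{prefix}: {message}")
        self.lineno = lineno


@dataclass
class ScriptNodeSpec:
    """Parsed interface of a script: its exposed inputs and outputs."""

    source: str
    path: str | None = None
    inputs: list = field(default_factory=list)   # (name, PortType)
    outputs: list = field(default_factory=list)  # (name, PortType)


_ANNOT_RE = re.compile(
    r"^\s*#\s*@(in|out)\s+([^\s:]+)\s*:\s*([^\s\[\]]+)\s*(?:\[\s*(\d+)\s*\])?\s*$"
)
_ANNOT_PREFIX_RE = re.compile(r"^\s*#\s*@(in|out)\b")
_IDENT_RE = re.compile(r"^[A-Za-z_]\w*$")


def parse_annotations(source: str, path=None) -> ScriptNodeSpec:
    """Extract the @in/@out interface of a script.

    Raises :class:`ScriptAnnotationError` for duplicate names, unknown base
    types, invalid identifiers, annotations not adjacent to a statement, or
    a script exposing no outputs.
    """
    lines = source.splitlines()
    spec = ScriptNodeSpec(source=source, path=str(path) if path else None)
    seen: dict[str, int] = {}
    pending: list[tuple[int, str, str, PortType]] = []
    for lineno, line in enumerate(lines, start=1):
        if _ANNOT_PREFIX_RE.match(line):
            m = _ANNOT_RE.match(line)
            if m is None:
                raise ScriptAnnotationError(
                    lineno, f"malformed annotation: {line.strip()!r}", path
                )
            direction, name, base, rank = m.groups()
            if not _IDENT_RE.match(name):
                raise ScriptAnnotationError(
                    lineno, f"invalid variable name {name!r}", path
                )
            try:
                ptype = PortType(base, int(rank) if rank else 0)
            except ValueError as e:
                raise ScriptAnnotationError(lineno, str(e), path) from None
            if name in seen:
                raise ScriptAnnotationError(
                    lineno,
                    f"duplicate annotation for {name!r} (first at line {seen[name]})",
                    path,
                )
            seen[name] = lineno
            pending.append((lineno, direction, name, ptype))
            continue
        stripped = line.strip()
        if pending:
            if not stripped or stripped.startswith("#"):
                raise ScriptAnnotationError(
                    pending[0][0],
                    "annotation is not immediately followed by a statement",
                    path,
                )
            for _, direction, name, ptype in pending:
                target = spec.inputs if direction == "in" else spec.outputs
                target.append((name, ptype))
            pending = []
    if pending:
        raise ScriptAnnotationError(
            pending[0][0], "annotation at end of file precedes no statement", path
        )
    if not spec.outputs:
        raise ScriptAnnotationError(len(lines) or 1, "node exposes no outputs", path)
    for name, _ in spec.inputs + spec.outputs:
        if not re.search(rf"(?<![\w.]){re.escape(name)}\b", _strip_comments(source)):
            raise ScriptAnnotationError(
                seen[name], f"annotated variable {name!r} is never used", path
            )
    return spec


def _strip_comments(source: str) -> str:
    return "\n".join(line.partition("#")[0] for line in source.splitlines())


def parse_script_file(path) -> ScriptNodeSpec:
    path = Path(path)
    return parse_annotations(path.read_text(), path=path)


def _copy_in(value, ptype: PortType):
    if ptype.rank == 0:
        if ptype.base == "int":
            return int(value)
        if ptype.base == "float":
            return float(value)
        return str(value)
    return np.array(value, copy=True)


def _copy_out(name, value, ptype: PortType):
    if value is None:
        raise RuntimeError(f"script did not assign output variable {name!r}")
    if ptype.rank == 0:
        if ptype.base == "int":
            return int(value)
        if ptype.base == "float":
            return float(value)
        return str(value)
    arr = np.array(value, copy=True)
    if arr.ndim != ptype.rank:
        raise RuntimeError(
            f"output {name!r} has rank {arr.ndim}, annotation declares {ptype.rank}"
        )
    return arr


def _run_script(ctx, inputs):
    path = ctx.param("path")
    if path is None:
        raise RuntimeError("script node needs a 'path' parameter")
    spec = parse_script_file(path)
    ns = {"__name__": "__mdflow_script__"}
    for name, ptype in spec.inputs:
        if name not in inputs:
            raise RuntimeError(f"script input {name!r} is not wired")
        ns[name] = _copy_in(inputs[name], ptype)
    code = compile(spec.source, str(path), "exec")
    try:
        exec(code, ns)  # noqa: S102 - scripts are the user's own analysis code
    except Exception as e:
        lineno = _script_lineno(e, str(path))
        where = f"{path}:{lineno}" if lineno else str(path)
        raise RuntimeError(f"script failed at {where}: {type(e).__name__}: {e}") from e
    return {
        name: _copy_out(name, ns.get(name), ptype) for name, ptype in spec.outputs
    }


def _script_lineno(exc, path) -> int | None:
    """Line number inside the script where the exception occurred.

    Because the source is compiled under its original file name, traceback
    line numbers match the user's file.
    """
    if isinstance(exc, SyntaxError) and exc.filename == path:
        return exc.lineno
    for fs in reversed(traceback.extract_tb(exc.__traceback__)):
        if fs.filename == path:
            return fs.lineno
    return None


def _resolve_script_ports(params):
    spec = parse_script_file(params["path"])
    inputs = [PortSpec(n, t) for n, t in spec.inputs]
    outputs = [PortSpec(n, t) for n, t in spec.outputs]
    return inputs, outputs


def _script_param_check(node, graph, traj):
    path = node.param("path")
    if path is None:
        return ["script node needs a 'path' parameter"]
    try:
        parse_script_file(path)
    except FileNotFoundError:
        return [f"script file not found: {path}"]
    except ScriptAnnotationError as e:
        return [str(e)]
    return []


register_node_kind(
    NodeKind(
        name="script",
        run=_run_script,
        resolver=_resolve_script_ports,
        param_validator=_script_param_check,
    )
)


def make_script_node(spec_or_path, node_id: str = "script") -> Node:
    """Build a graph :class:`Node` from a script file (or parsed spec).

    The node's ports are the script's annotated variables; wiring and type
    checking happen through the ordinary graph machinery.
    """
    if isinstance(spec_or_path, ScriptNodeSpec):
        if spec_or_path.path is None:
            raise ValueError("script spec must reference a file path")
        path = spec_or_path.path
    else:
        path = str(spec_or_path)
        parse_script_file(path)  # fail fast on malformed annotations
    return Node(id=node_id, kind="script", params={"path": path})
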