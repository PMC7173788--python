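"""Core trajectory data model: simulation box, atoms, frames, selections, and
the mutable per-atom attribute store used by the graph engine.

Conventions
-----------
* Lengths are in Angstrom, velocities in Angstrom/ps.
* Atom indices are 0-based everywhere inside the package; file formats keep
  their native numbering only at the I/O boundary.
* Boxes are orthorhombic.  Each axis is independently periodic or open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Box",
    "AtomTable",
    "Frame",
    "Trajectory",
    "AttributeStore",
    "SelectionError",
    "minimum_image",
    "select_atoms",
]


class SelectionError(ValueError):
    """Raised for malformed atom-selection expressions."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic simulation cell.

    Parameters
    ----------
    lengths : (3,) float array, Angstrom
        Edge lengths.  Must be positive on periodic axes.
    periodic : (3,) bool array
        Per-axis periodicity flags.
    """

    lengths: np.ndarray
    periodic: np.ndarray

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        periodic = np.asarray(self.periodic, dtype=bool).reshape(3)
        if not np.all(np.isfinite(lengths)):
            raise ValueError("box lengths must be finite")
        if np.any(periodic & (lengths <= 0)):
            raise ValueError("box lengths must be positive on periodic axes")
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "periodic", periodic)

    @classmethod
    def open(cls, lengths=(0.0, 0.0, 0.0)) -> "Box":
        """A fully non-periodic box."""
        return cls(np.asarray(lengths, dtype=float), np.zeros(3, dtype=bool))

    @classmethod
    def cubic(cls, length: float) -> "Box":
        return cls(np.full(3, float(length)), np.ones(3, dtype=bool))


@dataclass(frozen=True)
class AtomTable:
    """Static per-atom metadata shared by all frames of a trajectory."""

    name: np.ndarray
    element: np.ndarray
    residue_name: np.ndarray
    residue_id: np.ndarray
    molecule_id: np.ndarray

    def __post_init__(self):
        name = np.asarray(self.name, dtype=object)
        n = len(name)
        element = np.asarray(self.element, dtype=object)
        residue_name = np.asarray(self.residue_name, dtype=object)
        residue_id = np.asarray(self.residue_id, dtype=int)
        molecule_id = np.asarray(self.molecule_id, dtype=int)
        for arr, label in [
            (element, "element"),
            (residue_name, "residue_name"),
            (residue_id, "residue_id"),
            (molecule_id, "molecule_id"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{label} must have length {n}, got {len(arr)}")
        if n and molecule_id.min() < 0:
            raise ValueError("molecule_id must be non-negative")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "element", element)
        object.__setattr__(self, "residue_name", residue_name)
        object.__setattr__(self, "residue_id", residue_id)
        object.__setattr__(self, "molecule_id", molecule_id)

    @property
    def n_atoms(self) -> int:
        return len(self.name)


@dataclass(frozen=True)
class Frame:
    """One snapshot: positions (and optionally velocities) plus the box."""

    index: int
    positions: np.ndarray
    box: Box
    velocities: np.ndarray | None = None

    def __post_init__(self):
        if self.index < 0:
            raise ValueError("frame index must be >= 0")
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)
        if self.velocities is not None:
            vel = np.asarray(self.velocities, dtype=float)
            if vel.shape != pos.shape:
                raise ValueError("velocities must match positions shape")
            object.__setattr__(self, "velocities", vel)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """An ordered sequence of frames over a fixed atom table.

    ``attributes`` holds per-atom data imported from trajectory files
    (e.g. extra LAMMPS dump columns, SSV attribute columns), one array per
    frame per name.  The graph engine loads these into the attribute store
    at the start of each frame.
    """

    atoms: AtomTable
    frames: list[Frame]
    static_bonds: list[tuple[int, int]] = field(default_factory=list)
    attributes: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        n = self.atoms.n_atoms
        seen = set()
        for fr in self.frames:
            if fr.n_atoms != n:
                raise ValueError(
                    f"frame {fr.index} has {fr.n_atoms} atoms, expected {n}"
                )
            if fr.index in seen:
                raise ValueError(f"duplicate frame index {fr.index}")
            seen.add(fr.index)
        for i, j in self.static_bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j}) for {n} atoms")
        for name, arrs in self.attributes.items():
            if len(arrs) != len(self.frames):
                raise ValueError(
                    f"attribute {name!r} has {len(arrs)} frames, "
                    f"expected {len(self.frames)}"
                )
            for arr in arrs:
                if len(arr) != n:
                    raise ValueError(f"attribute {name!r} has wrong length")

    @property
    def n_atoms(self) -> int:
        return self.atoms.n_atoms

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_attribute(self, name: str, frame_pos: int) -> np.ndarray:
        return np.asarray(self.attributes[name][frame_pos], dtype=float)


def minimum_image(p, q, box: Box) -> np.ndarray:
    """Displacement ``q - p`` under the minimum-image convention.

    Periodic axes are wrapped into ``[-L/2, L/2)`` (a displacement of exactly
    ``L/2`` maps to ``-L/2``); open axes are returned unwrapped.  Accepts
    single 3-vectors or ``(n, 3)`` arrays (broadcast against each other).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("minimum_image requires finite coordinates")
    d = q - p
    per = box.periodic
    if np.any(per):
        L = np.where(per, box.lengths, 1.0)
        shift = np.floor(d / L + 0.5)
        d = d - np.where(per, shift * L, 0.0)
    return d


_CLAUSE_RE = re.compile(r"^(name|resname|element)=(\S+)$")


def _eval_clause(token: str, atoms: AtomTable) -> np.ndarray:
    m = _CLAUSE_RE.match(token)
    if m is None:
        raise SelectionError(f"malformed selection token: {token!r}")
    field_, value = m.groups()
    col = {
        "name": atoms.name,
        "resname": atoms.residue_name,
        "element": atoms.element,
    }[field_]
    # `field=A|B|C` matches any of the alternatives
    alts = set(value.split("|"))
    return np.array([v in alts for v in col], dtype=bool)


def select_atoms(traj: Trajectory | AtomTable, expr: str) -> np.ndarray:
    """Evaluate a selection expression, returning sorted 0-based indices.

    Grammar: whitespace-separated clauses ``name=X``, ``resname=Y``,
    ``element=Z`` combined with ``&`` and ``|`` (``&`` binds tighter).
    A clause value may itself contain ``|`` to match any of several
    alternatives, e.g. ``resname=SOL|HOH|WAT``.
    """
    atoms = traj.atoms if isinstance(traj, Trajectory) else traj
    tokens = expr.split()
    if not tokens:
        raise SelectionError("empty selection expression")

    pos = 0

    def parse_and() -> np.ndarray:
        nonlocal pos
        mask = _eval_clause(tokens[pos], atoms)
        pos += 1
        while pos < len(tokens) and tokens[pos] == "&":
            pos += 1
            if pos >= len(tokens):
                raise SelectionError("selection ends after '&'")
            mask = mask & _eval_clause(tokens[pos], atoms)
            pos += 1
        return mask

    def parse_or() -> np.ndarray:
        nonlocal pos
        mask = parse_and()
        while pos < len(tokens) and tokens[pos] == "|":
            pos += 1
            if pos >= len(tokens):
                raise SelectionError("selection ends after '|'")
            mask = mask | parse_and()
        return mask

    mask = parse_or()
    if pos != len(tokens):
        raise SelectionError(f"unexpected token: {tokens[pos]!r}")
    return np.flatnonzero(mask)


class AttributeStore:
    """Named, mutable per-atom float arrays with optional per-frame history.

    Attributes are the state channel of recurrent graph algorithms: they can
    be read and written at any point during a frame's execution and persist
    between frames.  Reading a name that was never written implicitly
    declares it as all-zeros, so a feedback loop can read its own output on
    the first executed frame.
    """

    def __init__(self, n_atoms: int):
        self.n_atoms = int(n_atoms)
        self._values: dict[str, np.ndarray] = {}
        self.recorded: dict[str, bool] = {}
        self.history: dict[str, dict[int, np.ndarray]] = {}

    @property
    def names(self) -> list[str]:
        return sorted(self._values)

    def declare(self, name: str, init=0.0, record: bool = False) -> None:
        init_arr = np.asarray(init, dtype=float)
        if init_arr.ndim == 0:
            values = np.full(self.n_atoms, float(init_arr))
        else:
            if init_arr.shape != (self.n_atoms,):
                raise ValueError(
                    f"attribute {name!r} init must be scalar or length "
                    f"{self.n_atoms}"
                )
            values = init_arr.copy()
        self._values[name] = values
        self.recorded[name] = bool(record)
        self.history.setdefault(name, {})

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def get(self, name: str) -> np.ndarray:
        if name not in self._values:
            self.declare(name)
        return self._values[name].copy()

    def set(self, name: str, values) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.shape != (self.n_atoms,):
            raise ValueError(
                f"attribute {name!r}: expected length {self.n_atoms}, "
                f"got shape {arr.shape}"
            )
        if name not in self._values:
            self.declare(name)
        self._values[name] = arr.copy()

    def snapshot(self, name: str, frame_index: int) -> None:
        """Copy the current values of ``name`` into its per-frame history."""
        if name not in self._values:
            self.declare(name)
        if self.recorded.get(name, False):
            self.history[name][int(frame_index)] = self._values[name].copy()
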