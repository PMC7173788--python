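"""Trajectory readers and writers.

Supported text formats:

* GRO (GROMACS fixed-column; nm converted to Angstrom on read)
* PDB (ATOM/HETATM records, MODEL/ENDMDL frames, CRYST1, CONECT bonds)
* LAMMPS text dump (``ITEM:`` sections; extra columns become attributes)
* SSV — a generic space-separated-values trajectory format whose header line
  declares the role of each column.  Reserved labels ``x y z vx vy vz name
  resname resid`` map onto the data model; every other label becomes a
  per-atom attribute recorded per frame.

Readers are registered in a table keyed by format name and file extension,
so new formats can be plugged in at run time with :func:`register_reader`.
All parsing is strict: malformed input raises :class:`ParseError` carrying
the offending line number.
"""

from __future__ import annotations

import os
import re

import numpy as np

from .datamodel import AtomTable, Box, Frame, Trajectory

__all__ = [
    "ParseError",
    "read_gro",
    "read_pdb",
    "read_lammps_dump",
    "read_ssv",
    "write_ssv",
    "write_gro",
    "write_pdb",
    "register_reader",
    "detect_format",
    "read_trajectory",
]


class ParseError(ValueError):
    """Malformed trajectory file; message includes path and line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def guess_element(name: str) -> str:
    """First alphabetic character of an atom name (OW -> O, HW1 -> H).

    A deliberate simplification: two-letter elements (Cl, Na, ...) are not
    distinguished.  Use explicit element columns (PDB) when they matter.
    """
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


# ---------------------------------------------------------------------------
# GRO


def _gro_float(path, lineno, text, what):
    try:
        return float(text)
    except ValueError:
        raise ParseError(path, lineno, f"non-numeric {what}: {text.strip()!r}") from None


def read_gro(path) -> Trajectory:
    """Read a (possibly multi-frame, concatenated) GROMACS GRO file.

    Coordinates are converted from nm to Angstrom, velocities from nm/ps to
    Angstrom/ps.  Only orthorhombic boxes (3-value box lines, or longer lines
    whose off-diagonal entries are all zero) are accepted.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames = []
    atoms = None
    lineno = 0
    n_total = len(lines)
    frame_index = 0
    while lineno < n_total:
        if not lines[lineno].strip() and all(
            not l.strip() for l in lines[lineno:]
        ):
            break  # trailing blank lines
        title_line = lineno
        if lineno + 1 >= n_total:
            raise ParseError(path, title_line + 1, "truncated frame header")
        try:
            n_atoms = int(lines[lineno + 1].strip())
        except ValueError:
            raise ParseError(
                path, lineno + 2, f"expected atom count, got {lines[lineno + 1]!r}"
            ) from None
        lineno += 2
        names, resnames, resids = [], [], []
        pos = np.empty((n_atoms, 3))
        vel = np.empty((n_atoms, 3))
        have_vel = True
        for i in range(n_atoms):
            ln = lineno + i
            if ln >= n_total:
                raise ParseError(path, ln + 1, f"expected {n_atoms} atom lines, file ends")
            line = lines[ln]
            if len(line) < 44:
                # could be the box line of a malformed frame
                raise ParseError(
                    path, ln + 1, f"atom line too short ({len(line)} chars, need 44)"
                )
            try:
                resid = int(line[0:5])
            except ValueError:
                raise ParseError(path, ln + 1, f"non-numeric residue id: {line[0:5]!r}") from None
            resids.append(resid)
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            for k in range(3):
                pos[i, k] = _gro_float(path, ln + 1, line[20 + 8 * k : 28 + 8 * k], "coordinate")
            if len(line) >= 68:
                for k in range(3):
                    vel[i, k] = _gro_float(path, ln + 1, line[44 + 8 * k : 52 + 8 * k], "velocity")
            else:
                have_vel = False
        lineno += n_atoms
        if lineno >= n_total:
            raise ParseError(path, lineno + 1, "missing box line")
        box_fields = lines[lineno].split()
        if len(box_fields) < 3:
            raise ParseError(path, lineno + 1, "box line needs at least 3 values")
        vals = [_gro_float(path, lineno + 1, v, "box value") for v in box_fields]
        if len(vals) > 3 and any(abs(v) > 1e-12 for v in vals[3:]):
            raise ParseError(path, lineno + 1, "triclinic boxes are not supported")
        lengths = np.array(vals[:3]) * 10.0  # nm -> Angstrom
        if np.all(lengths > 0):
            box = Box(lengths, np.ones(3, dtype=bool))
        else:
            box = Box.open(np.abs(lengths))
        lineno += 1
        if atoms is None:
            atoms = AtomTable(
                name=names,
                element=[guess_element(n) for n in names],
                residue_name=resnames,
                residue_id=resids,
                molecule_id=resids,
            )
        elif n_atoms != atoms.n_atoms:
            raise ParseError(
                path, title_line + 2, f"frame {frame_index} has {n_atoms} atoms, expected {atoms.n_atoms}"
            )
        frames.append(
            Frame(
                index=frame_index,
                positions=pos * 10.0,
                velocities=vel * 10.0 if have_vel else None,
                box=box,
            )
        )
        frame_index += 1
        while lineno < n_total and not lines[lineno].strip():
            lineno += 1
    if atoms is None:
        raise ParseError(path, 1, "empty GRO file")
    return Trajectory(atoms=atoms, frames=frames)


def write_gro(traj: Trajectory, path, title="mdflow trajectory") -> None:
    """Write all frames as a concatenated GRO file (Angstrom -> nm)."""
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"{title}, frame {fr.index}\n")
            fh.write(f"{traj.n_atoms:5d}\n")
            for i in range(traj.n_atoms):
                resid = int(traj.atoms.residue_id[i]) % 100000
                x, y, z = fr.positions[i] / 10.0
                line = (
                    f"{resid:5d}{traj.atoms.residue_name[i]:<5.5s}"
                    f"{traj.atoms.name[i]:>5.5s}{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}"
                )
                if fr.velocities is not None:
                    vx, vy, vz = fr.velocities[i] / 10.0
                    line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
                fh.write(line + "\n")
            if np.all(fr.box.periodic):
                bx, by, bz = fr.box.lengths / 10.0
            else:
                bx = by = bz = 0.0
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB


def read_pdb(path) -> Trajectory:
    """Read a PDB file. MODEL/ENDMDL delimit frames; CONECT gives bonds.

    Without a CRYST1 record the box is fully non-periodic.  CRYST1 angles
    other than 90 degrees (triclinic cells) are rejected.
    """
    names, elements, resnames, resids = [], [], [], []
    frames_pos: list[list[list[float]]] = [[]]
    box = Box.open()
    bonds = set()
    serial_to_index: dict[int, int] = {}
    first_model_done = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "CRYST1":
                try:
                    a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                    alpha, beta, gamma = (
                        float(line[33:40]),
                        float(line[40:47]),
                        float(line[47:54]),
                    )
                except ValueError:
                    raise ParseError(path, lineno, "malformed CRYST1 record") from None
                if any(abs(ang - 90.0) > 1e-6 for ang in (alpha, beta, gamma)):
                    raise ParseError(path, lineno, "triclinic cells are not supported")
                box = Box(np.array([a, b, c]), np.ones(3, dtype=bool))
            elif record in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(path, lineno, "ATOM record too short for coordinates")
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError:
                    raise ParseError(path, lineno, "non-numeric coordinate") from None
                frames_pos[-1].append([x, y, z])
                if not first_model_done:
                    name = line[12:16].strip()
                    element = line[76:78].strip() if len(line) >= 78 else ""
                    names.append(name)
                    elements.append(element.capitalize() or guess_element(name))
                    resnames.append(line[17:21].strip())
                    try:
                        resid = int(line[22:26])
                    except ValueError:
                        resid = 0
                    resids.append(resid)
                    try:
                        serial = int(line[6:11])
                        serial_to_index[serial] = len(names) - 1
                    except ValueError:
                        pass
            elif record == "ENDMDL":
                first_model_done = True
                frames_pos.append([])
            elif record == "CONECT":
                fields = line.split()[1:]
                try:
                    serials = [int(f) for f in fields]
                except ValueError:
                    raise ParseError(path, lineno, "non-numeric CONECT serial") from None
                if serials:
                    base = serials[0]
                    for other in serials[1:]:
                        if base in serial_to_index and other in serial_to_index:
                            i, j = serial_to_index[base], serial_to_index[other]
                            if i != j:
                                bonds.add((min(i, j), max(i, j)))
    frames_pos = [f for f in frames_pos if f]
    if not frames_pos:
        raise ParseError(path, 1, "no ATOM/HETATM records found")
    n = len(names)
    atoms = AtomTable(
        name=names,
        element=elements,
        residue_name=resnames,
        residue_id=resids,
        molecule_id=[max(r, 0) for r in resids],
    )
    frames = []
    for k, coords in enumerate(frames_pos):
        if len(coords) != n:
            raise ParseError(path, 1, f"model {k + 1} has {len(coords)} atoms, expected {n}")
        frames.append(Frame(index=k, positions=np.array(coords), box=box))
    return Trajectory(atoms=atoms, frames=frames, static_bonds=sorted(bonds))


def write_pdb(traj: Trajectory, path, bfactors=None) -> None:
    """Write a multi-MODEL PDB file.

    ``bfactors`` may map frame position -> per-atom float array; values are
    placed in the B-factor column (used to export per-atom color scalars).
    """
    with open(path, "w") as fh:
        box = traj.frames[0].box
        if np.all(box.periodic):
            a, b, c = box.lengths
            fh.write(
                f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        for k, fr in enumerate(traj.frames):
            fh.write(f"MODEL     {k + 1:4d}\n")
            bf = None if bfactors is None else bfactors.get(k)
            for i in range(traj.n_atoms):
                x, y, z = fr.positions[i]
                b = 0.0 if bf is None else float(bf[i])
                fh.write(
                    "ATOM  {serial:5d} {name:<4.4s} {res:<4.4s}{resid:5d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2.2s}\n".format(
                        serial=(i + 1) % 100000,
                        name=traj.atoms.name[i],
                        res=traj.atoms.residue_name[i],
                        resid=int(traj.atoms.residue_id[i]) % 10000,
                        x=x,
                        y=y,
                        z=z,
                        occ=1.0,
                        b=b,
                        el=traj.atoms.element[i],
                    )
                )
            fh.write("ENDMDL\n")
        for i, j in traj.static_bonds:
            fh.write(f"CONECT{i + 1:5d}{j + 1:5d}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# LAMMPS text dump


def read_lammps_dump(path) -> Trajectory:
    """Read a LAMMPS text dump (``ITEM: TIMESTEP`` sections).

    Requires an ``id`` column and either ``x y z`` or scaled ``xs ys zs``
    coordinates; atoms are sorted by id.  Every other numeric column is
    imported as a per-frame attribute under its column name.  Coordinates
    are taken as Angstrom.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos_frames: list[np.ndarray] = []
    boxes: list[Box] = []
    attr_frames: dict[str, list[np.ndarray]] = {}
    types_first: np.ndarray | None = None
    n_expected = None
    i = 0
    n_total = len(lines)
    while i < n_total:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("ITEM: TIMESTEP"):
            raise ParseError(path, i + 1, f"expected 'ITEM: TIMESTEP', got {line!r}")
        i += 2  # skip timestep value
        if i >= n_total or not lines[i].startswith("ITEM: NUMBER OF ATOMS"):
            raise ParseError(path, i + 1, "expected 'ITEM: NUMBER OF ATOMS'")
        n_atoms = int(lines[i + 1])
        if n_expected is None:
            n_expected = n_atoms
        elif n_atoms != n_expected:
            raise ParseError(path, i + 2, f"frame has {n_atoms} atoms, expected {n_expected}")
        i += 2
        if i >= n_total or not lines[i].startswith("ITEM: BOX BOUNDS"):
            raise ParseError(path, i + 1, "expected 'ITEM: BOX BOUNDS'")
        bounds_header = lines[i].split()[3:]
        if any(t in ("xy", "xz", "yz") for t in bounds_header):
            raise ParseError(path, i + 1, "triclinic boxes are not supported")
        periodic = np.ones(3, dtype=bool)
        flags = [t for t in bounds_header if re.fullmatch(r"[a-z]{2}", t)]
        if len(flags) == 3:
            periodic = np.array([f == "pp" for f in flags])
        lo = np.empty(3)
        hi = np.empty(3)
        for k in range(3):
            fields = lines[i + 1 + k].split()
            if len(fields) < 2:
                raise ParseError(path, i + 2 + k, "malformed box bounds line")
            lo[k], hi[k] = float(fields[0]), float(fields[1])
        box = Box(hi - lo, periodic)
        i += 4
        if i >= n_total or not lines[i].startswith("ITEM: ATOMS"):
            raise ParseError(path, i + 1, "expected 'ITEM: ATOMS'")
        columns = lines[i].split()[2:]
        col_idx = {c: k for k, c in enumerate(columns)}
        if "id" not in col_idx:
            raise ParseError(path, i + 1, "missing required column 'id'")
        scaled = False
        if all(c in col_idx for c in ("x", "y", "z")):
            xyz_cols = [col_idx["x"], col_idx["y"], col_idx["z"]]
        elif all(c in col_idx for c in ("xs", "ys", "zs")):
            xyz_cols = [col_idx["xs"], col_idx["ys"], col_idx["zs"]]
            scaled = True
        else:
            missing = [c for c in ("x", "y", "z") if c not in col_idx]
            raise ParseError(
                path, i + 1, f"missing coordinate column(s) {missing} (or xs ys zs)"
            )
        i += 1
        data = np.empty((n_atoms, len(columns)))
        for a in range(n_atoms):
            if i + a >= n_total:
                raise ParseError(path, i + a + 1, "file ends inside ATOMS section")
            fields = lines[i + a].split()
            if len(fields) != len(columns):
                raise ParseError(
                    path, i + a + 1,
                    f"row has {len(fields)} fields, header declares {len(columns)}",
                )
            try:
                data[a] = [float(f) for f in fields]
            except ValueError:
                raise ParseError(path, i + a + 1, "non-numeric field") from None
        i += n_atoms
        order = np.argsort(data[:, col_idx["id"]], kind="stable")
        data = data[order]
        pos = data[:, xyz_cols]
        if scaled:
            pos = lo + pos * (hi - lo)
        pos_frames.append(pos)
        boxes.append(box)
        if types_first is None:
            if "type" in col_idx:
                types_first = data[:, col_idx["type"]].astype(int)
            else:
                types_first = np.ones(n_atoms, dtype=int)
        skip = {"id", "x", "y", "z", "xs", "ys", "zs"}
        for c in columns:
            if c in skip:
                continue
            attr_frames.setdefault(c, []).append(data[:, col_idx[c]].copy())
    if n_expected is None:
        raise ParseError(path, 1, "empty LAMMPS dump")
    names = [str(t) for t in types_first]
    mol = attr_frames.get("mol")
    atoms = AtomTable(
        name=names,
        element=names,
        residue_name=["X"] * n_expected,
        residue_id=list(range(n_expected)),
        molecule_id=mol[0].astype(int) if mol else list(range(n_expected)),
    )
    frames = [
        Frame(index=k, positions=p, box=b)
        for k, (p, b) in enumerate(zip(pos_frames, boxes))
    ]
    return Trajectory(atoms=atoms, frames=frames, attributes=attr_frames)


# ---------------------------------------------------------------------------
# SSV

_SSV_RESERVED = ("x", "y", "z", "vx", "vy", "vz", "name", "resname", "resid")


def read_ssv(path) -> Trajectory:
    """Read the generic space-separated-values trajectory format.

    Line 1 declares one role per column.  Reserved labels (case-insensitive)
    are ``x y z`` (required, Angstrom), ``vx vy vz``, ``name``, ``resname``
    and ``resid``; any other label defines a per-atom attribute of that name.
    Frames are blank-line-separated blocks of equal row count; the header
    appears once at the top.  Comment lines starting with ``#`` before the
    header are skipped, except a ``# box Lx Ly Lz px py pz`` directive which
    sets the (otherwise non-periodic) simulation cell.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    box = Box.open()
    header = None
    header_lineno = 0
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            fields = s[1:].split()
            if fields and fields[0].lower() == "box":
                if len(fields) != 7:
                    raise ParseError(path, lineno, "box directive needs 6 values")
                lengths = [float(v) for v in fields[1:4]]
                periodic = [bool(int(v)) for v in fields[4:7]]
                box = Box(np.array(lengths), np.array(periodic))
            continue
        header = s.split()
        header_lineno = lineno
        break
    if header is None:
        raise ParseError(path, 1, "empty SSV file")
    lower = [h.lower() for h in header]
    for role in ("x", "y", "z"):
        if lower.count(role) != 1:
            raise ParseError(path, header_lineno, f"header must contain exactly one {role!r} column")
    attr_labels = [h for h, l in zip(header, lower) if l not in _SSV_RESERVED]
    if len(set(attr_labels)) != len(attr_labels):
        raise ParseError(path, header_lineno, "duplicate attribute labels in header")
    col = {l: k for k, l in enumerate(lower) if l in _SSV_RESERVED}
    have_vel = all(c in col for c in ("vx", "vy", "vz"))

    blocks: list[list[tuple[int, list[str]]]] = []
    current: list[tuple[int, list[str]]] = []
    for lineno in range(header_lineno, len(lines)):
        s = lines[lineno].strip()
        if not s:
            if current:
                blocks.append(current)
                current = []
            continue
        if s.startswith("#"):
            continue
        fields = s.split()
        if len(fields) != len(header):
            raise ParseError(
                path, lineno + 1,
                f"row has {len(fields)} fields, header declares {len(header)}",
            )
        current.append((lineno + 1, fields))
    if current:
        blocks.append(current)
    if not blocks:
        raise ParseError(path, header_lineno, "no data rows")
    n = len(blocks[0])
    for b in blocks[1:]:
        if len(b) != n:
            raise ParseError(path, b[0][0], f"block has {len(b)} rows, expected {n}")

    def parse_block(block):
        pos = np.empty((n, 3))
        vel = np.empty((n, 3)) if have_vel else None
        attrs = {a: np.empty(n) for a in attr_labels}
        names, resnames, resids = [], [], []
        for r, (lineno, fields) in enumerate(block):
            try:
                pos[r] = [fields[col["x"]], fields[col["y"]], fields[col["z"]]]
                if have_vel:
                    vel[r] = [fields[col["vx"]], fields[col["vy"]], fields[col["vz"]]]
                for a, h in zip(header, lower):
                    if h not in _SSV_RESERVED:
                        attrs[a][r] = float(fields[header.index(a)])
            except ValueError:
                raise ParseError(path, lineno, "non-numeric field") from None
            names.append(fields[col["name"]] if "name" in col else f"X{r}")
            resnames.append(fields[col["resname"]] if "resname" in col else "X")
            if "resid" in col:
                try:
                    resids.append(int(fields[col["resid"]]))
                except ValueError:
                    raise ParseError(path, lineno, "non-integer resid") from None
            else:
                resids.append(r)
        return pos, vel, attrs, names, resnames, resids

    frames = []
    traj_attrs: dict[str, list[np.ndarray]] = {a: [] for a in attr_labels}
    atoms = None
    for k, block in enumerate(blocks):
        pos, vel, attrs, names, resnames, resids = parse_block(block)
        if atoms is None:
            atoms = AtomTable(
                name=names,
                element=[guess_element(nm) for nm in names],
                residue_name=resnames,
                residue_id=resids,
                molecule_id=[max(r, 0) for r in resids],
            )
        frames.append(Frame(index=k, positions=pos, velocities=vel, box=box))
        for a in attr_labels:
            traj_attrs[a].append(attrs[a])
    return Trajectory(atoms=atoms, frames=frames, attributes=traj_attrs)


def _fmt(v: float) -> str:
    return f"{v:.6g}"


def write_ssv(traj: Trajectory, attr_names=(), path=None) -> None:
    """Write a trajectory in canonical SSV form (6 significant digits).

    ``attr_names`` selects per-frame attributes from ``traj.attributes`` to
    export as extra columns.  Writing the result of :func:`read_ssv` again
    produces a byte-identical file.
    """
    for a in attr_names:
        if a not in traj.attributes:
            raise KeyError(f"unknown attribute {a!r}; trajectory has {sorted(traj.attributes)}")
    have_vel = all(fr.velocities is not None for fr in traj.frames)
    header = ["name", "resname", "resid", "x", "y", "z"]
    if have_vel:
        header += ["vx", "vy", "vz"]
    header += list(attr_names)
    box = traj.frames[0].box
    with open(path, "w") as fh:
        if np.any(box.periodic):
            lengths = " ".join(_fmt(v) for v in box.lengths)
            flags = " ".join(str(int(p)) for p in box.periodic)
            fh.write(f"# box {lengths} {flags}\n")
        fh.write(" ".join(header) + "\n")
        for k, fr in enumerate(traj.frames):
            if k > 0:
                fh.write("\n")
            for i in range(traj.n_atoms):
                fields = [
                    str(traj.atoms.name[i]),
                    str(traj.atoms.residue_name[i]),
                    str(int(traj.atoms.residue_id[i])),
                ]
                fields += [_fmt(v) for v in fr.positions[i]]
                if have_vel:
                    fields += [_fmt(v) for v in fr.velocities[i]]
                for a in attr_names:
                    fields.append(_fmt(float(traj.attributes[a][k][i])))
                fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Reader registry

_READERS: dict[str, object] = {}
_EXTENSIONS: dict[str, str] = {}


def register_reader(name: str, fn, extensions=()) -> None:
    """Register (or replace) a trajectory reader under ``name``.

    ``extensions`` are file suffixes (without dot) mapped to this reader.
    Lookup is case-insensitive.
    """
    _READERS[name.lower()] = fn
    for ext in extensions:
        _EXTENSIONS[ext.lower().lstrip(".")] = name.lower()


register_reader("gro", read_gro, ["gro"])
register_reader("pdb", read_pdb, ["pdb", "ent"])
register_reader("lammps", read_lammps_dump, ["dump", "lammpstrj"])
register_reader("ssv", read_ssv, ["ssv"])


def _sniff(path) -> str | None:
    try:
        with open(path) as fh:
            head = [fh.readline() for _ in range(8)]
    except OSError:
        return None
    text = "".join(head)
    if "ITEM: TIMESTEP" in text:
        return "lammps"
    for line in head:
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM", "CRYST1", "MODEL", "HEADER", "REMARK"):
            return "pdb"
    if len(head) >= 2:
        try:
            int(head[1].strip())
            return "gro"
        except ValueError:
            pass
    return None


def detect_format(path) -> str:
    """Return the registered format name for a file (extension, then sniff)."""
    ext = os.path.splitext(str(path))[1].lstrip(".").lower()
    if ext in _EXTENSIONS:
        return _EXTENSIONS[ext]
    fmt = _sniff(path)
    if fmt is not None:
        return fmt
    supported = sorted(_READERS)
    raise ValueError(
        f"cannot determine format of {path!r}; supported formats: {supported}"
    )


def read_trajectory(path, format=None) -> Trajectory:
    """Read any registered trajectory format (auto-detected by default)."""
    fmt = (format or detect_format(path)).lower()
    if fmt not in _READERS:
        raise ValueError(f"unknown format {fmt!r}; supported: {sorted(_READERS)}")
    return _READERS[fmt](path)
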