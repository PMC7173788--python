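"""Synthetic trajectory generators with analytically known ground truth.

These stand in for external MD data: a droplet-nucleation trajectory with a
scripted merge and known cluster membership per frame, an analytic
guest-pair/water-ring structure satisfying every MCG-1 criterion by
construction, the canonical pentagonal-dodecahedron (5^12) water cage, and
a dilute bulk-water negative control.  All generators are pure functions of
their parameters (seed included).

Scale note: sizes default to tens of atoms and tens of frames — enough to
exercise every code path with exact expected answers, not to emulate the
physics of large simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datamodel import AtomTable, Box, Frame, Trajectory, minimum_image

__all__ = [
    "DropletGroundTruth",
    "gen_lj_droplet",
    "gen_cage_pair",
    "gen_dodecahedral_cage",
    "gen_bulk_water",
    "WATER_OH",
    "WATER_HOH_DEG",
]

# rigid 3-site water geometry (a common convention; any rigid geometry works)
WATER_OH = 0.9572          # O-H bond length, Angstrom
WATER_HOH_DEG = 104.52     # H-O-H angle, degrees


@dataclass
class DropletGroundTruth:
    """Scripted membership of the tracked main cluster.

    ``masks[t, i]`` is 1 iff atom i belongs to the main cluster at frame t
    (zero everywhere before the nucleation frame).  ``events`` records the
    scripted join/leave times of individual gas atoms.
    """

    masks: np.ndarray
    merge_frame: int
    nucleation_frame: int
    events: list = field(default_factory=list)


def _lattice_sites(n: int) -> np.ndarray:
    """First ``n`` integer lattice sites sorted by (norm, x, y, z)."""
    m = 1
    while (2 * m + 1) ** 3 < n:
        m += 1
    grid = np.array(
        [(x, y, z)
         for x in range(-m, m + 1)
         for y in range(-m, m + 1)
         for z in range(-m, m + 1)],
        dtype=float,
    )
    order = sorted(range(len(grid)),
                   key=lambda k: (float(grid[k] @ grid[k]), *grid[k]))
    return grid[order[:n]]


def _place_dilute(rng, count, box, exclusion, margin, what):
    """Rejection-sample ``count`` points > ``margin`` from each other and
    from every point in ``exclusion`` (minimum image)."""
    placed = []
    cloud = exclusion
    for _ in range(count):
        for _attempt in range(5000):
            p = rng.uniform(0.0, box.lengths, size=3)
            if cloud.size and np.linalg.norm(
                minimum_image(p, cloud, box), axis=1
            ).min() <= margin:
                continue
            if placed and np.linalg.norm(
                minimum_image(p, np.array(placed), box), axis=1
            ).min() <= margin:
                continue
            placed.append(p)
            break
        else:
            raise RuntimeError(
                f"could not place {what} without violating the spacing "
                "constraint; use a larger box or fewer atoms"
            )
    return np.array(placed).reshape(count, 3)


def gen_lj_droplet(n_atoms: int = 60, n_frames: int = 20, merge_frame: int = 10,
                   cutoff: float = 3.0, seed: int = 0,
                   nucleation_frame: int | None = None
                   ) -> tuple[Trajectory, DropletGroundTruth]:
    """Scripted droplet-nucleation trajectory.

    Two compact blobs (lattice spacing 0.6 x cutoff, so each is internally
    connected) sit in a dilute gas whose atoms are kept > cutoff from
    everything.  Blob A (the larger; atoms 0..) condenses at
    ``nucleation_frame`` (default merge_frame // 2; before it, A's atoms are
    dispersed gas), the blobs translate toward each other and touch at
    ``merge_frame``, and a few scripted gas atoms join or leave blob A at
    recorded event times.  Returns the trajectory and the per-frame
    main-cluster membership mask.
    """
    if n_atoms < 20:
        raise ValueError("need n_atoms >= 20")
    if not (0 < merge_frame < n_frames):
        raise ValueError("need 0 < merge_frame < n_frames")
    f_nuc = merge_frame // 2 if nucleation_frame is None else int(nucleation_frame)
    if not (0 <= f_nuc < merge_frame):
        raise ValueError("need 0 <= nucleation_frame < merge_frame")
    rng = np.random.default_rng(seed)

    s = 0.6 * cutoff
    n_a = max(8, round(0.25 * n_atoms))
    n_b = max(5, round(0.15 * n_atoms))
    if n_b >= n_a:
        n_b = n_a - 1
    n_gas = n_atoms - n_a - n_b
    a_local = _lattice_sites(n_a) * s
    b_local = _lattice_sites(n_b) * s

    contact = 0.8 * cutoff   # inter-blob surface distance at/after the merge
    step = 0.75 * cutoff     # approach per frame (> 0.2*cutoff, so the gap
    #                          is still > cutoff one frame before the merge)

    def gap(t: int) -> float:
        return contact + max(0, merge_frame - t) * step

    ax_max, ax_min = a_local[:, 0].max(), a_local[:, 0].min()
    bx_max, bx_min = b_local[:, 0].max(), b_local[:, 0].min()
    span = (ax_max - ax_min) + (bx_max - bx_min) + gap(0)
    box_l = max(span + 10 * cutoff, 4.0 * cutoff * (n_gas ** (1 / 3) + 1.5))
    box = Box.cubic(box_l)
    center = np.full(3, box_l / 2.0)

    def blob_centers(t: int):
        ca = center + np.array([-(gap(t) / 2.0 + ax_max), 0.0, 0.0])
        cb = center + np.array([+(gap(t) / 2.0 - bx_min), 0.0, 0.0])
        return ca, cb

    a_pos = {t: a_local + blob_centers(t)[0] for t in range(n_frames)}
    b_pos = {t: b_local + blob_centers(t)[1] for t in range(n_frames)}

    # scripted join/leave events for gas atoms (attached to blob A surface)
    anchors = [int(np.argmax(a_local[:, 1])), int(np.argmin(a_local[:, 1])),
               int(np.argmax(a_local[:, 2]))]
    dirs = [np.array([0.0, 1.0, 0.0]), np.array([0.0, -1.0, 0.0]),
            np.array([0.0, 0.0, 1.0])]
    proposed = [
        (0, f_nuc + 1, n_frames),                      # joins after nucleation
        (1, merge_frame + 1, n_frames),                # joins after the merge
        (2, f_nuc + 2, merge_frame),                   # joins, then leaves
    ]
    events = []
    for k, (slot, t_join, t_leave) in enumerate(proposed):
        if k < n_gas and t_join < t_leave <= n_frames:
            events.append(
                {"atom": n_a + n_b + k, "slot": slot,
                 "join": int(t_join), "leave": int(t_leave)}
            )

    def attach_pos(ev, t):
        return a_pos[t][anchors[ev["slot"]]] + dirs[ev["slot"]] * s

    # exclusion cloud: every scripted position at every frame it is occupied
    cloud = [a_pos[t] for t in range(f_nuc, n_frames)]
    cloud += [b_pos[t] for t in range(n_frames)]
    cloud += [attach_pos(ev, t)[None, :]
              for ev in events for t in range(ev["join"], ev["leave"])]
    cloud = np.concatenate(cloud)

    margin = 1.05 * cutoff
    gas_home = _place_dilute(rng, n_gas, box, cloud, margin, "gas atoms")
    prenuc_cloud = np.concatenate([cloud, gas_home])
    a_prenuc = _place_dilute(rng, n_a, box, prenuc_cloud, margin,
                             "pre-nucleation blob atoms")

    frames = []
    masks = np.zeros((n_frames, n_atoms), dtype=int)
    ev_by_atom = {ev["atom"]: ev for ev in events}
    for t in range(n_frames):
        pos = np.empty((n_atoms, 3))
        pos[:n_a] = a_pos[t] if t >= f_nuc else a_prenuc
        pos[n_a:n_a + n_b] = b_pos[t]
        for k in range(n_gas):
            i = n_a + n_b + k
            ev = ev_by_atom.get(i)
            if ev is not None and ev["join"] <= t < ev["leave"]:
                pos[i] = attach_pos(ev, t)
                masks[t, i] = 1
            else:
                pos[i] = gas_home[k]
        if t >= f_nuc:
            masks[t, :n_a] = 1
            if t >= merge_frame:
                masks[t, n_a:n_a + n_b] = 1
        else:
            masks[t, :] = 0
        frames.append(Frame(index=t, positions=pos, box=box))

    atoms = AtomTable(
        name=["LJ"] * n_atoms,
        element=["Ar"] * n_atoms,
        residue_name=["LJ"] * n_atoms,
        residue_id=np.arange(1, n_atoms + 1),
        molecule_id=np.arange(n_atoms),
    )
    truth = DropletGroundTruth(
        masks=masks, merge_frame=merge_frame, nucleation_frame=f_nuc,
        events=[{k: v for k, v in ev.items() if k != "slot"} for ev in events],
    )
    return Trajectory(atoms=atoms, frames=frames), truth


def _water_table(n_water, first_mol, guests=0):
    """AtomTable rows for ``guests`` methane-like guests followed by
    ``n_water`` three-site waters (O, H1, H2)."""
    name, element, resname, resid, mol = [], [], [], [], []
    for g in range(guests):
        name.append("C")
        element.append("C")
        resname.append("MET")
        resid.append(g + 1)
        mol.append(g + 1)
    for w in range(n_water):
        m = guests + w + first_mol
        for nm, el in (("OW", "O"), ("HW1", "H"), ("HW2", "H")):
            name.append(nm)
            element.append(el)
            resname.append("SOL")
            resid.append(m)
            mol.append(m)
    return AtomTable(name=name, element=element, residue_name=resname,
                     residue_id=resid, molecule_id=mol)


def gen_cage_pair(guest_sep: float = 8.0, ring_radius: float = 2.3,
                  n_ring: int = 5, rotation=None, translation=None) -> Trajectory:
    """Two guests on the z axis with a ring of waters on the midplane.

    The ring radius must keep both guest cone angles <= 45 degrees and all
    consecutive O-O distances <= 3.5 A (checked; infeasible parameters
    raise).  Each water donates one linear hydrogen bond to the next water
    around the ring, so the O-O graph is a single n-cycle.  An optional
    rigid rotation matrix / translation vector is applied to the whole
    structure.  Atoms: guest, guest, then (O, H1, H2) per water.
    """
    if n_ring < 3:
        raise ValueError("need n_ring >= 3")
    half = guest_sep / 2.0
    cone = np.rad2deg(np.arctan2(ring_radius, half))
    if cone > 45.0:
        raise ValueError(
            f"ring_radius {ring_radius} puts waters at {cone:.1f} deg from the "
            "guest axis (> 45); shrink the ring or separate the guests less"
        )
    chord = 2.0 * ring_radius * np.sin(np.pi / n_ring)
    if chord > 3.5:
        raise ValueError(
            f"ring O-O distance {chord:.2f} A exceeds the 3.5 A hydrogen-bond "
            "cutoff; shrink ring_radius"
        )
    if guest_sep <= 0:
        raise ValueError("guest_sep must be positive")

    coords = [np.array([0.0, 0.0, -half]), np.array([0.0, 0.0, +half])]
    theta = 2.0 * np.pi * np.arange(n_ring) / n_ring
    o_pos = np.stack(
        [ring_radius * np.cos(theta), ring_radius * np.sin(theta),
         np.zeros(n_ring)], axis=1
    )
    zhat = np.array([0.0, 0.0, 1.0])
    hoh = np.deg2rad(WATER_HOH_DEG)
    for k in range(n_ring):
        o = o_pos[k]
        u = o_pos[(k + 1) % n_ring] - o
        u = u / np.linalg.norm(u)
        h1 = o + WATER_OH * u                                  # donor, linear
        h2 = o + WATER_OH * (np.cos(hoh) * u + np.sin(hoh) * zhat)
        coords += [o, h1, h2]
    pos = np.stack(coords)
    if rotation is not None:
        pos = pos @ np.asarray(rotation, dtype=float).T
    if translation is not None:
        pos = pos + np.asarray(translation, dtype=float)

    extent = pos.max(axis=0) - pos.min(axis=0)
    lengths = 4.0 * np.maximum(extent, 1.0)
    pos = pos - pos.min(axis=0) + lengths / 4.0
    atoms = _water_table(n_ring, first_mol=1, guests=2)
    frame = Frame(index=0, positions=pos, box=Box.open(lengths))
    return Trajectory(atoms=atoms, frames=[frame])


def _dodecahedron_vertices() -> np.ndarray:
    """Unit-scale pentagonal-dodecahedron vertices (circumradius sqrt(3))."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = [(x, y, z) for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)]
    for a, b in [(1.0 / phi, phi)]:
        v += [(0, -a, -b), (0, -a, b), (0, a, -b), (0, a, b)]
        v += [(-a, -b, 0), (-a, b, 0), (a, -b, 0), (a, b, 0)]
        v += [(-b, 0, -a), (b, 0, -a), (-b, 0, a), (b, 0, a)]
    return np.array(v, dtype=float)


def _orient_cubic_graph(G: nx.Graph) -> list[tuple[int, int]]:
    """Orient a 3-regular graph so every vertex has out-degree <= 2.

    Doubling a perfect matching makes every degree 4; following an Eulerian
    circuit then gives out-degree exactly 2 in the multigraph, and dropping
    the duplicate edge copies can only lower it.
    """
    matching = nx.max_weight_matching(G, maxcardinality=True)
    multi = nx.MultiGraph(G)
    multi.add_edges_from(matching)
    oriented: dict[frozenset, tuple[int, int]] = {}
    for u, v in nx.eulerian_circuit(multi):
        oriented.setdefault(frozenset((u, v)), (u, v))
    return sorted(oriented.values())


def gen_dodecahedral_cage(radius: float | None = None,
                          guest_at_center: bool = False) -> Trajectory:
    """The canonical 5^12 hydrate cage: 20 waters on dodecahedron vertices.

    Hydrogens point along the polyhedron's 30 edges (each edge carries
    exactly one donated H; no water donates more than two), so the
    hydrogen-bond-derived O-O graph is exactly the dodecahedron's edge
    graph with its 12 pentagonal faces.  ``radius`` is the O circumradius;
    the default gives 2.8 A O-O edges.
    """
    verts = _dodecahedron_vertices()
    circum = np.sqrt(3.0)
    edge_unit = 2.0 / ((1.0 + np.sqrt(5.0)) / 2.0)  # edge length at unit scale
    if radius is None:
        radius = 2.8 * circum / edge_unit
    if radius <= 0:
        raise ValueError("radius must be positive")
    scale = radius / circum
    verts = verts * scale
    edge_len = edge_unit * scale

    d = np.linalg.norm(verts[:, None, :] - verts[None, :, :], axis=2)
    G = nx.Graph()
    G.add_nodes_from(range(20))
    for i in range(20):
        for j in range(i + 1, 20):
            if abs(d[i, j] - edge_len) < 1e-6 * max(1.0, edge_len):
                G.add_edge(i, j)
    oriented = _orient_cubic_graph(G)

    donated: dict[int, list[np.ndarray]] = {i: [] for i in range(20)}
    for u, v in oriented:
        unit = (verts[v] - verts[u]) / np.linalg.norm(verts[v] - verts[u])
        donated[u].append(verts[u] + WATER_OH * unit)
    coords = []
    offset = 1 if guest_at_center else 0
    for i in range(20):
        hs = donated[i]
        while len(hs) < 2:  # dangling H: radially outward, bonds nothing
            hs = hs + [verts[i] + WATER_OH * verts[i] / np.linalg.norm(verts[i])]
        coords += [verts[i], hs[0], hs[1]]
    pos = np.stack(([np.zeros(3)] if guest_at_center else []) + coords)

    lengths = np.full(3, 8.0 * radius)
    pos = pos - pos.min(axis=0) + lengths / 4.0
    atoms = _water_table(20, first_mol=1, guests=offset)
    frame = Frame(index=0, positions=pos, box=Box.open(lengths))
    return Trajectory(atoms=atoms, frames=[frame])


def gen_bulk_water(n_molecules: int = 20, box_length: float = 30.0,
                   seed: int = 0) -> Trajectory:
    """Dilute bulk water: random rigid waters with all O-O separations
    > 3.6 A (minimum image), so the hydrogen-bond graph is empty — a
    negative control for the hydrate pipeline."""
    rng = np.random.default_rng(seed)
    box = Box.cubic(box_length)
    o_pos = _place_dilute(rng, n_molecules, box, np.zeros((0, 3)), 3.6,
                          "water molecules")
    hoh = np.deg2rad(WATER_HOH_DEG)
    local = WATER_OH * np.array(
        [[np.sin(hoh / 2), 0.0, np.cos(hoh / 2)],
         [-np.sin(hoh / 2), 0.0, np.cos(hoh / 2)]]
    )
    coords = []
    for w in range(n_molecules):
        rot = _random_rotation(rng)
        coords += [o_pos[w], o_pos[w] + local[0] @ rot.T, o_pos[w] + local[1] @ rot.T]
    atoms = _water_table(n_molecules, first_mol=1)
    frame = Frame(index=0, positions=np.stack(coords), box=box)
    return Trajectory(atoms=atoms, frames=[frame])


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
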