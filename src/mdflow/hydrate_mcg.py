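"""Mutually-coordinated-guest (MCG-1) detection of clathrate-hydrate order.

The pipeline classifies a pair of guest molecules (e.g. methane) as
*mutually coordinated* when a ring of hydrogen-bonded water molecules lies
between them:

1. ``filter_guests`` — guest pairs closer than a cutoff (default 9 A);
2. ``filter_waters`` — water oxygens inside the double cone spanned by a
   pair: the O must lie within ``cone_angle`` (default 45 deg) of the
   guest–guest axis as seen from *both* guests;
3. ``hbonds_filtered`` — geometric hydrogen bonds among the selected
   waters (O-O distance and donor-angle criteria);
4. ``reconnect_water`` — collapse O-H...O bonds to O-O edges;
5. ``find_links`` — simple cycles of exactly n waters (n = 5: the
   pentagonal rings of hydrate cages);
6. ``register_hydrate`` — a pair is mutually coordinated when at least
   ``min_rings`` rings lie wholly inside its coordinated-water set; caged
   guests and their ring oxygens receive connected-component labels.

The per-frame count of classified molecules, plotted over a trajectory,
localizes the onset of hydrate nucleation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datamodel import AtomTable, Box, minimum_image, select_atoms
from .graph_engine import Graph, node_kind

__all__ = [
    "CoordinatedWaters",
    "filter_guests",
    "filter_waters",
    "hbonds_filtered",
    "reconnect_water",
    "find_links",
    "canonical_ring",
    "register_hydrate",
    "classified_count",
    "build_mcg_graph",
    "DEFAULT_WATER_SELECTION",
]

DEFAULT_WATER_SELECTION = "resname=SOL|HOH|WAT"


def filter_guests(positions, guest_indices, box: Box, pair_cutoff: float = 9.0) -> np.ndarray:
    """Guest pairs with minimum-image distance <= ``pair_cutoff``.

    Returns an (m, 2) array of index pairs (i < j) drawn from
    ``guest_indices``.
    """
    if pair_cutoff <= 0:
        raise ValueError("pair_cutoff must be positive")
    per = box.periodic
    if np.any(per & (box.lengths / 2.0 < pair_cutoff)):
        raise ValueError(
            f"pair_cutoff {pair_cutoff} exceeds half the box length on a "
            "periodic axis; minimum image is ill-defined"
        )
    positions = np.asarray(positions, dtype=float)
    guests = np.asarray(guest_indices, dtype=int)
    pairs = []
    for a in range(len(guests)):
        i = guests[a]
        rest = guests[a + 1:]
        if len(rest) == 0:
            continue
        d = minimum_image(positions[i], positions[rest], box)
        close = np.linalg.norm(d, axis=1) <= pair_cutoff
        pairs.extend((int(i), int(j)) for j in rest[close])
    return np.array(sorted(pairs), dtype=int).reshape(-1, 2)


@dataclass
class CoordinatedWaters:
    """Water oxygens coordinated to each guest pair, plus their union."""

    pairs: np.ndarray            # (m, 2) guest index pairs
    per_pair: list               # m int arrays of water-O indices
    selected: np.ndarray         # sorted union of all coordinated O indices


def filter_waters(pairs, positions, water_o_indices, box: Box,
                  cone_angle: float = 45.0,
                  max_dist: float | None = None) -> CoordinatedWaters:
    """Water oxygens lying between each guest pair (symmetric double cone).

    An oxygen O is coordinated to the pair (g1, g2) when the angle between
    O-g1 and the axis g2-g1 *and* the angle between O-g2 and the axis
    g1-g2 are both <= ``cone_angle`` degrees (displacements minimum-image).
    ``max_dist``, if given, additionally caps the O distance to each guest.
    Degenerate pairs (zero separation) are skipped with a warning.
    """
    if not (0.0 < cone_angle < 90.0):
        raise ValueError(f"cone_angle must be in (0, 90) degrees, got {cone_angle}")
    positions = np.asarray(positions, dtype=float)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    waters = np.asarray(water_o_indices, dtype=int)
    cos_min = np.cos(np.deg2rad(cone_angle))
    per_pair = []
    for g1, g2 in pairs:
        axis = minimum_image(positions[g1], positions[g2], box)
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            warnings.warn(
                f"guest pair ({g1}, {g2}) has zero separation; skipped",
                stacklevel=2,
            )
            per_pair.append(np.zeros(0, dtype=int))
            continue
        u = axis / norm
        if len(waters) == 0:
            per_pair.append(np.zeros(0, dtype=int))
            continue
        v1 = minimum_image(positions[g1], positions[waters], box)
        v2 = minimum_image(positions[g2], positions[waters], box)
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        ok = (n1 > 1e-9) & (n2 > 1e-9)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos1 = np.einsum("ij,j->i", v1, u) / n1
            cos2 = np.einsum("ij,j->i", v2, -u) / n2
        ok &= (cos1 >= cos_min) & (cos2 >= cos_min)
        if max_dist is not None:
            ok &= (n1 <= max_dist) & (n2 <= max_dist)
        per_pair.append(waters[ok])
    if per_pair:
        union = np.unique(np.concatenate([p for p in per_pair] or [np.zeros(0, int)]))
    else:
        union = np.zeros(0, dtype=int)
    return CoordinatedWaters(pairs=pairs, per_pair=per_pair, selected=union)


def _water_molecules(atoms: AtomTable, water_sel: str):
    """Map molecule id -> (O index, [H indices]) for the water selection."""
    idx = select_atoms(atoms, water_sel)
    by_mol: dict[int, dict[str, list[int]]] = {}
    for i in idx:
        mol = int(atoms.molecule_id[i])
        slot = by_mol.setdefault(mol, {"O": [], "H": []})
        el = atoms.element[i]
        if el in slot:
            slot[el].append(int(i))
    out = {}
    for mol, slot in by_mol.items():
        if len(slot["O"]) != 1 or len(slot["H"]) != 2:
            raise ValueError(
                f"water molecule {mol} must have 1 O and 2 H, found "
                f"{len(slot['O'])} O / {len(slot['H'])} H"
            )
        out[mol] = (slot["O"][0], slot["H"])
    return out


def hbonds_filtered(atoms: AtomTable, positions, box: Box, selected_o,
                    d_oo_max: float = 3.5, angle_max: float = 30.0,
                    water_sel: str = DEFAULT_WATER_SELECTION) -> np.ndarray:
    """Geometric hydrogen bonds among the selected water oxygens.

    A bond (O_donor, H, O_acceptor) is accepted when both oxygens are
    selected, belong to different molecules, their minimum-image O-O
    distance is <= ``d_oo_max`` A, and the H-O_donor-O_acceptor angle is
    <= ``angle_max`` degrees.  Returns a (k, 3) index array.
    """
    positions = np.asarray(positions, dtype=float)
    selected = np.unique(np.asarray(selected_o, dtype=int))
    if len(selected) == 0:
        return np.zeros((0, 3), dtype=int)
    mols = _water_molecules(atoms, water_sel)
    o_to_mol = {o: mol for mol, (o, _) in mols.items()}
    for o in selected:
        if int(o) not in o_to_mol:
            raise ValueError(f"selected atom {int(o)} is not a water oxygen")
    cos_min = np.cos(np.deg2rad(angle_max))
    sel_pos = positions[selected]
    bonds = []
    for od in selected:
        mol_d = o_to_mol[int(od)]
        d = minimum_image(positions[od], sel_pos, box)
        dist = np.linalg.norm(d, axis=1)
        near = (dist <= d_oo_max) & (dist > 1e-9)
        for oa, doa in zip(selected[near], d[near]):
            if o_to_mol[int(oa)] == mol_d:
                continue
            u_oa = doa / np.linalg.norm(doa)
            for h in mols[mol_d][1]:
                dh = minimum_image(positions[od], positions[h][None, :], box)[0]
                nh = np.linalg.norm(dh)
                if nh < 1e-9:
                    continue
                if float(np.dot(dh / nh, u_oa)) >= cos_min:
                    bonds.append((int(od), int(h), int(oa)))
    return np.array(sorted(bonds), dtype=int).reshape(-1, 3)


def reconnect_water(hbonds) -> np.ndarray:
    """Collapse (O_donor, H, O_acceptor) bonds to unique O-O edges (i < j)."""
    hb = np.asarray(hbonds, dtype=int).reshape(-1, 3)
    edges = {(min(int(a), int(c)), max(int(a), int(c))) for a, _, c in hb}
    return np.array(sorted(edges), dtype=int).reshape(-1, 2)


def canonical_ring(cycle) -> tuple:
    """Canonical form of a cycle: the rotation/reflection minimizing the
    index sequence."""
    cyc = [int(v) for v in cycle]
    n = len(cyc)
    best = None
    for seq in (cyc, cyc[::-1]):
        for s in range(n):
            cand = tuple(seq[s:] + seq[:s])
            if best is None or cand < best:
                best = cand
    return best


def find_links(edges, n: int = 5) -> list[tuple]:
    """All simple cycles of length exactly ``n`` in the edge graph.

    Each ring is returned once, in canonical form, sorted.  n = 5 finds the
    pentagonal water rings of hydrate cages.
    """
    if n < 3:
        raise ValueError("rings need n >= 3")
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    G = nx.Graph()
    G.add_edges_from((int(i), int(j)) for i, j in edges)
    rings = {
        canonical_ring(c)
        for c in nx.simple_cycles(G, length_bound=n)
        if len(c) == n
    }
    return sorted(rings)


def register_hydrate(pairs, coordinated: CoordinatedWaters, rings, n_atoms: int,
                     min_rings: int = 1) -> tuple[np.ndarray, int]:
    """Label caged guests and their ring oxygens; count coordinated pairs.

    A pair is *mutually coordinated* when >= ``min_rings`` rings lie wholly
    within its coordinated-water set (min_rings = 1 is the MCG-1 order
    parameter).  Labels are connected-component ids over qualifying pairs
    sharing a guest, numbered from 1 in order of each component's smallest
    guest index; 0 means unlabeled.  Returns (per-atom labels, mcg_count).
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    ring_sets = [frozenset(int(v) for v in r) for r in rings]
    qualifying = []  # (g1, g2, member atom indices)
    for (g1, g2), waters in zip(pairs, coordinated.per_pair):
        wset = set(int(w) for w in waters)
        own_rings = [rs for rs in ring_sets if rs <= wset]
        if len(own_rings) >= min_rings:
            members = {int(g1), int(g2)}
            for rs in own_rings:
                members |= rs
            qualifying.append((int(g1), int(g2), members))
    labels = np.zeros(n_atoms, dtype=int)
    if not qualifying:
        return labels, 0
    G = nx.Graph()
    for g1, g2, _ in qualifying:
        G.add_edge(g1, g2)
    components = sorted(nx.connected_components(G), key=min)
    comp_id = {g: k + 1 for k, comp in enumerate(components) for g in comp}
    for g1, g2, members in qualifying:
        labels[sorted(members)] = comp_id[g1]
    return labels, len(qualifying)


def classified_count(labels, molecule_ids=None) -> int:
    """Number of classified molecules (labels != 0).

    With ``molecule_ids`` the count is over distinct molecules, so a water
    counted by its oxygen is one molecule, not three atoms.
    """
    labels = np.asarray(labels)
    hit = labels != 0
    if molecule_ids is None:
        return int(np.count_nonzero(hit))
    molecule_ids = np.asarray(molecule_ids, dtype=int)
    return int(len(np.unique(molecule_ids[hit])))


# ---------------------------------------------------------------------------
# Node kinds


def _guest_sel_check(node, graph, traj):
    if not node.param("guest_sel"):
        return ["needs a 'guest_sel' selection parameter"]
    return []


@node_kind("filter_guests", inputs=[("positions", "float[2]")],
           outputs=[("pairs", "int[2]")],
           param_defaults={"cutoff": 9.0},
           param_validator=_guest_sel_check)
def _node_filter_guests(ctx, inputs):
    guests = select_atoms(ctx.traj.atoms, ctx.param("guest_sel"))
    return {
        "pairs": filter_guests(inputs["positions"], guests, ctx.frame.box,
                               pair_cutoff=float(ctx.param("cutoff")))
    }


@node_kind("filter_waters",
           inputs=[("positions", "float[2]"), ("pairs", "int[2]")],
           outputs=[("coordinated", "int[2]"), ("selected", "int[1]")],
           param_defaults={"water_sel": DEFAULT_WATER_SELECTION,
                           "cone_angle": 45.0, "max_dist": None})
def _node_filter_waters(ctx, inputs):
    atoms = ctx.traj.atoms
    sel = select_atoms(atoms, ctx.param("water_sel"))
    oxygens = np.array([i for i in sel if atoms.element[i] == "O"], dtype=int)
    cw = filter_waters(inputs["pairs"], inputs["positions"], oxygens,
                       ctx.frame.box, cone_angle=float(ctx.param("cone_angle")),
                       max_dist=ctx.param("max_dist"))
    mask = np.zeros(ctx.traj.n_atoms, dtype=int)
    mask[cw.selected] = 1
    ctx.store.set("mcg_selected", mask.astype(float))
    return {"coordinated": cw.per_pair, "selected": mask}


@node_kind("hbonds_filtered",
           inputs=[("positions", "float[2]"), ("selected", "int[1]")],
           outputs=[("hbonds", "int[2]")],
           param_defaults={"water_sel": DEFAULT_WATER_SELECTION,
                           "d_oo_max": 3.5, "angle_max": 30.0})
def _node_hbonds(ctx, inputs):
    selected_o = np.flatnonzero(np.asarray(inputs["selected"]) != 0)
    return {
        "hbonds": hbonds_filtered(
            ctx.traj.atoms, inputs["positions"], ctx.frame.box, selected_o,
            d_oo_max=float(ctx.param("d_oo_max")),
            angle_max=float(ctx.param("angle_max")),
            water_sel=ctx.param("water_sel"),
        )
    }


@node_kind("reconnect_water", inputs=[("hbonds", "int[2]")],
           outputs=[("edges", "int[2]")])
def _node_reconnect(ctx, inputs):
    return {"edges": reconnect_water(inputs["hbonds"])}


@node_kind("find_links", inputs=[("edges", "int[2]")],
           outputs=[("rings", "int[2]")], param_defaults={"n": 5})
def _node_find_links(ctx, inputs):
    rings = find_links(inputs["edges"], n=int(ctx.param("n")))
    return {"rings": [np.array(r, dtype=int) for r in rings]}


@node_kind("register_hydrate",
           inputs=[("pairs", "int[2]"), ("coordinated", "int[2]"),
                   ("rings", "int[2]")],
           outputs=[("labels", "int[1]"), ("mcg_count", "int")],
           param_defaults={"min_rings": 1})
def _node_register(ctx, inputs):
    cw = CoordinatedWaters(
        pairs=np.asarray(inputs["pairs"], dtype=int).reshape(-1, 2),
        per_pair=[np.asarray(p, dtype=int) for p in inputs["coordinated"]],
        selected=np.zeros(0, dtype=int),
    )
    labels, count = register_hydrate(
        inputs["pairs"], cw, [tuple(r) for r in inputs["rings"]],
        n_atoms=ctx.traj.n_atoms, min_rings=int(ctx.param("min_rings")),
    )
    return {"labels": labels, "mcg_count": count}


@node_kind("classified_count", inputs=[("labels", "float[1]")],
           outputs=[("count", "int")])
def _node_classified_count(ctx, inputs):
    return {
        "count": classified_count(inputs["labels"], ctx.traj.atoms.molecule_id)
    }


def build_mcg_graph(guest_sel: str, water_sel: str = DEFAULT_WATER_SELECTION,
                    pair_cutoff: float = 9.0, cone_angle: float = 45.0,
                    d_oo_max: float = 3.5, angle_max: float = 30.0,
                    ring_n: int = 5, min_rings: int = 1,
                    label_attr: str = "mcg_label") -> Graph:
    """The complete MCG-1 pipeline as one executable graph.

    Besides the classification chain, the graph stores the per-atom labels
    as a recorded attribute, draws the O-O cage edges as extra bonds, and
    accumulates the classified-molecule count in a plot node
    (``id='l_plot'``) — the order-parameter-vs-frame curve used to date
    nucleation.
    """
    g = Graph()
    g.add_node("a_pos", "positions")
    g.add_node("b_guests", "filter_guests",
               {"guest_sel": guest_sel, "cutoff": pair_cutoff})
    g.add_node("c_waters", "filter_waters",
               {"water_sel": water_sel, "cone_angle": cone_angle})
    g.add_node("d_hbonds", "hbonds_filtered",
               {"water_sel": water_sel, "d_oo_max": d_oo_max,
                "angle_max": angle_max})
    g.add_node("e_edges", "reconnect_water")
    g.add_node("f_rings", "find_links", {"n": ring_n})
    g.add_node("g_register", "register_hydrate", {"min_rings": min_rings})
    g.add_node("h_save", "set_attribute", {"name": label_attr})
    g.add_node("i_bonds", "extra_bonds")
    g.add_node("k_count", "classified_count")
    g.add_node("l_plot", "plot_data")
    g.connect("a_pos", "positions", "b_guests", "positions")
    g.connect("a_pos", "positions", "c_waters", "positions")
    g.connect("b_guests", "pairs", "c_waters", "pairs")
    g.connect("a_pos", "positions", "d_hbonds", "positions")
    g.connect("c_waters", "selected", "d_hbonds", "selected")
    g.connect("d_hbonds", "hbonds", "e_edges", "hbonds")
    g.connect("e_edges", "edges", "f_rings", "edges")
    g.connect("b_guests", "pairs", "g_register", "pairs")
    g.connect("c_waters", "coordinated", "g_register", "coordinated")
    g.connect("f_rings", "rings", "g_register", "rings")
    g.connect("g_register", "labels", "h_save", "values")
    g.connect("e_edges", "edges", "i_bonds", "pairs")
    g.connect("g_register", "labels", "k_count", "labels")
    g.connect("k_count", "count", "l_plot", "y")
    g.declare_attribute(label_attr, init=0.0, record=True)
    g.declare_attribute("mcg_selected", init=0.0, record=True)
    return g
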