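# Methods

## Data model and units

All lengths are Angstrom internally (GRO's nm are converted on read),
velocities Å/ps, and atom indices 0-based; file formats keep their native
numbering only at the I/O boundary.  Boxes are orthorhombic with per-axis
periodicity; triclinic cells are rejected at read time.  The minimum-image
displacement wraps periodic axes into `[-L/2, L/2)` — a separation of
exactly `L/2` deterministically maps to `-L/2` (half-open convention), so
ties cannot flip between runs.

Each trajectory carries a static atom table (names, elements, residues,
molecule ids; molecules need not be contiguous) and per-frame positions and
optional velocities.  Elements absent from a format are guessed as the
first alphabetic character of the atom name; two-letter elements are
therefore not distinguished unless the format provides them (PDB column
77–78).  This is adequate for the water/guest chemistries handled here and
is the only intentional leniency in otherwise strict parsers (every parse
error carries a file and line number).

## The graph engine

A graph is a set of nodes with typed ports (`int`/`float`/`string` at an
array rank; identical types match, `int` promotes to `float` at any rank,
rank mismatches never match), connections (each input port accepts at most
one), per-run attribute declarations, and an execution config (direction,
frame range).  Scheduling is topological with lexicographic node-id
tie-breaking, which makes execution order — and therefore every result —
deterministic.  The connection digraph must be acyclic; feedback is only
possible through attributes.

Attribute reads and writes take effect **immediately, in topological
order**, not at an end-of-frame commit.  The alternative (commit at frame
end) was considered and rejected: with immediate semantics a
read-node scheduled before the writer sees the previous frame's value and
one scheduled after sees the new value, which is exactly the dependency
structure a recurrent tracking loop needs, and the deterministic schedule
makes it unambiguous.  Reading a never-written attribute implicitly
declares it as zeros — a recurrent node can then read its own output on the
first executed frame without special-casing.  A pre-populated attribute
store may be passed into a run, which is how one graph seeds another (the
largest-cluster graph seeds the tracking graph's label attribute).

Every output port of every node is cached per frame; recorded attributes
and the per-frame visualization state (color scalar in [0,1] mapped
blue→red, radius scale, visibility, extra bonds, camera center) are
snapshotted after the last node.  Re-executing a frame overwrites its
snapshots.  `RunResult.to_json()` is canonical, so byte-comparison of two
runs is the determinism test.

Script nodes compile a plain Python file whose exposed variables are
declared by `# @in name : base[rank]` / `# @out ...` comment lines
immediately preceding the statement that first uses them.  The dialect is
this package's own definition, chosen for the same end (no framework code
in user scripts); only Python is supported — compiling C++/Fortran and
dynamically loading the result is toolchain plumbing outside this package's
scope.  Sources are compiled under their original filename so tracebacks
keep the user's line numbers; arrays are copied in and out, so scripts can
never alias engine state.

## Cluster tracking

`list_neighbors` uses a cell list (cells at least one cutoff wide; open
axes are binned over the data extent) and must agree exactly with the
all-pairs oracle — the decomposition is an optimization, never an
approximation.  The cutoff criterion is closed (`d <= r_c`) with the tie
documented; a cutoff above half the box length on a periodic axis is an
error because the minimum image is then ill-defined.  Components are
labeled 0..k−1 in order of each component's smallest atom index, and all
remaining ties in the pack (mode mask, tracking overlap) resolve to the
smallest label/id — again for determinism.

One deliberate definition in `track_cluster`: groups smaller than
`min_cluster_size` (default 2) cannot inherit the label.  A free atom is
not a cluster; without this rule a dispersed cluster's label would cling to
one stray atom forever (every singleton containing a previously labeled
atom has overlap 1), and "the cluster has dissipated, clear the labels"
would be unreachable.  With it, tracking backward past the nucleation
event clears the label exactly when the blob's atoms disperse into the
gas.  Tracking carries a single binary label (the tracked cluster), not
one label per cluster; the operations act per atom, which for single-site
particles coincides with per molecule.

`labels2colors` advances colors by `fade_rate` per frame (default 0.05,
i.e. a 20-frame fade — the gradient scale is a presentation choice) and
clamps to [0,1]; it is monotone while membership is constant, so the
forward and backward passes bracket the max-combined gradient.

## MCG-1

The "waters between a guest pair" criterion is implemented as a symmetric
double cone: O qualifies iff the angle between O−g1 and the axis g2−g1
*and* the angle between O−g2 and the reversed axis are both ≤ `cone_angle`
(default 45°).  This geometric reading — the lens-shaped region between
the guests — is one of several possible placements of the angle's vertex;
it is the package's definition, prominently configurable (`cone_angle`,
plus an optional per-guest distance cap `max_dist`) so alternative
readings can be expressed.  Hydrogen bonds use the standard geometric
criterion (O–O ≤ 3.5 Å, H–O_d–O_a donor angle ≤ 30°, both defaults
configurable); both H of a donor are tested, roles are asymmetric, and
double bonds between one O pair collapse to a single O–O edge.  Ring
perception enumerates simple cycles of exactly n (default 5) and reduces
each to a canonical rotation/reflection; the implementation delegates the
enumeration to networkx with a length bound, and tests compare it against
an independent exhaustive DFS.  `min_rings` = 1 defines the "-1" variant
of the order parameter; pair labels are connected components over pairs
sharing a guest, numbered from 1 by smallest guest index.  The classified
count is over distinct molecule ids, so a water contributes one regardless
of its three sites.

## Synthetic fixtures

The generators produce the smallest structures that exercise every
decision point with an exactly known answer; they make no claim to
thermodynamic realism (no interactions, no integrator — positions are
scripted).  Consequences: passing tests demonstrate algorithmic
correctness on geometry satisfying or violating each criterion by
construction, not robustness to thermal noise, marginal geometries, or
finite-temperature hydrogen-bond populations.

* **Droplet** (default 60 atoms, 20 frames): two lattice blobs (spacing
  0.6 × cutoff keeps them internally connected) in a gas placed by
  rejection sampling with a 1.05 × cutoff margin to everything at every
  frame.  The larger blob condenses at `nucleation_frame`
  (default `merge_frame // 2`; before it its atoms are dispersed, which is
  what gives backward tracking a label-clearing event to recover), the
  blobs approach at 0.75 × cutoff per frame and sit at 0.8 × cutoff
  surface distance from the merge frame on, and up to three gas atoms
  join/leave the main blob at recorded times.  The emitted mask *is* the
  cluster the geometry implies, which the tests verify independently.
* **Cage pair**: guests 8 Å apart, five waters on a midplane circle of
  radius 2.3 Å (cone angle 29.9°, ring O–O 2.70 Å — both inside their
  thresholds with margin; infeasible parameter combinations raise naming
  the violated constraint).  Water geometry is rigid O–H 0.9572 Å,
  H–O–H 104.52°; each water donates one exactly linear H-bond to the next.
  The second hydrogen is tilted out of plane, where it can bond nothing.
* **Dodecahedron**: golden-ratio vertex coordinates scaled to 2.8 Å edges.
  Hydrogens must lie along edges with no water donating more than two:
  doubling a perfect matching of the 3-regular edge graph and walking an
  Eulerian circuit yields an orientation with out-degree ≤ 2, one donated
  H per edge; dangling hydrogens point radially outward (≥ 69° from every
  incident edge, so they bond nothing).
* **Bulk water**: rejection-sampled oxygens at > 3.6 Å minimum-image
  separation — strictly outside the 3.5 Å criterion, so the H-bond graph
  is empty by construction.

All generators are pure functions of their parameters including the seed.

## Numerical and scale choices

Degenerate inputs are rejected loudly rather than coerced: empty centroid
masks, non-finite camera points, zero-separation guest pairs (skipped with
a warning, since other pairs in the frame remain valid), waters without
two hydrogens.  Test and acceptance problem sizes — 500-atom neighbor
configurations, 200-node component graphs, 30-vertex ring graphs, 60-atom
20-frame droplets, 100-case recurrence sweeps — were chosen so the full
suite completes in seconds while still crossing every algorithmic boundary
(periodic wrap, cell-list wraparound, tie-breaks, label clearing).

## Known limitations

Orthorhombic boxes only; centroids ignore periodicity (fixtures keep
clusters whole; real wrapped clusters need pre-unwrapping); element
inference from names is single-letter; SSV stores box geometry only
through this package's own `# box` header comment; no parallel execution —
graphs run frame-sequentially by design, since attributes make frames
causally dependent.
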