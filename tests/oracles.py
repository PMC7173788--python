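"""Independent brute-force oracles used to check the package's algorithms.

Everything here is deliberately naive — O(N^2) scans, breadth-first search,
exhaustive depth-first cycle enumeration, a plain Python recurrence loop —
and shares no code path with the implementations under test.
"""

from __future__ import annotations

import numpy as np


def brute_force_neighbors(positions, lengths, periodic, cutoff):
    """All-pairs neighbor lists under the minimum image (closed cutoff).

    One full N-vector distance computation per atom — no spatial
    decomposition of any kind.
    """
    pos = np.asarray(positions, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    periodic = np.asarray(periodic, dtype=bool)
    n = len(pos)
    out = []
    for i in range(n):
        d = pos - pos[i]
        for ax in range(3):
            if periodic[ax]:
                d[:, ax] -= lengths[ax] * np.floor(d[:, ax] / lengths[ax] + 0.5)
        close = np.sqrt((d * d).sum(axis=1)) <= cutoff
        close[i] = False
        out.append(sorted(int(j) for j in np.flatnonzero(close)))
    return out


def bfs_components(adjacency):
    """Component labels via BFS, numbered by smallest member index."""
    n = len(adjacency)
    labels = [-1] * n
    next_label = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        queue = [start]
        labels[start] = next_label
        while queue:
            v = queue.pop(0)
            for w in adjacency[v]:
                if labels[w] == -1:
                    labels[w] = next_label
                    queue.append(w)
        next_label += 1
    return np.array(labels)


def enumerate_cycles(edges, n):
    """All simple cycles of length exactly n, by exhaustive DFS.

    Cycles are identified by their edge sets (two cycles are the same ring
    iff they use the same edges).  Returns a set of frozensets of
    (i, j) edges with i < j.
    """
    adj: dict[int, set] = {}
    for i, j in edges:
        i, j = int(i), int(j)
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    found = set()

    def dfs(start, path, seen):
        last = path[-1]
        if len(path) == n:
            if start in adj.get(last, ()):
                ring = frozenset(
                    (min(a, b), max(a, b))
                    for a, b in zip(path, path[1:] + [start])
                )
                found.add(ring)
            return
        for nxt in adj.get(last, ()):
            if nxt > start and nxt not in seen:
                dfs(start, path + [nxt], seen | {nxt})

    for start in sorted(adj):
        dfs(start, [start], {start})
    return found


def sequential_affine_recurrence(init, coeffs, n_frames):
    """Unrolled oracle for a chain of per-frame affine updates.

    Per frame the state vector v becomes a_k * (... (a_1*v + b_1) ...) + b_k
    for the coefficient list ``coeffs`` = [(a_1, b_1), ...].  Returns the
    state after every frame.  The visit order (forward or backward) does not
    enter: the recurrence depends only on how many frames were executed.
    """
    v = np.asarray(init, dtype=float).copy()
    states = []
    for _ in range(n_frames):
        for a, b in coeffs:
            v = a * v + b
        states.append(v.copy())
    return states
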