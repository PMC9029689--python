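"""Marching-Cubes case table, generated once at import.

Corner and edge numbering follow the classic convention:

    corners 0..7 at offsets (0,0,0) (1,0,0) (1,1,0) (0,1,0)
                            (0,0,1) (1,0,1) (1,1,1) (0,1,1)
    edges   0..11 connect corners (0,1) (1,2) (2,3) (3,0)
                                  (4,5) (5,6) (6,7) (7,4)
                                  (0,4) (1,5) (2,6) (3,7)

A corner is *inside* when its sample value >= isovalue; case index bit ``c``
is set when corner ``c`` is inside.  The triangulation of each of the 256
cases is derived from the cube-face crossings: on every face the crossing
points pair up so that each maximal run of inside corners is cut off by one
segment.  That pairing depends only on the absolute inside/outside pattern
of the face, so the two cubes sharing a face always triangulate it the same
way and the extracted surface is crack-free for every configuration,
ambiguous faces included.  The pairs chain into closed loops, which are
fan-triangulated; loops are oriented so triangle normals point from the
inside (>= isovalue) region toward the outside.
"""

from __future__ import annotations

import numpy as np

CORNER_OFFSETS = np.array(
    [
        (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
        (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
    ],
    dtype=np.int64,
)

EDGE_CORNERS = np.array(
    [
        (0, 1), (1, 2), (2, 3), (3, 0),
        (4, 5), (5, 6), (6, 7), (7, 4),
        (0, 4), (1, 5), (2, 6), (3, 7),
    ],
    dtype=np.int64,
)

# Each face: 4 corners in cyclic order, and the edge between consecutive
# corners (edge i joins face corner i and i+1 mod 4).
_FACES = (
    ((0, 1, 2, 3), (0, 1, 2, 3)),      # z = 0
    ((4, 5, 6, 7), (4, 5, 6, 7)),      # z = 1
    ((0, 1, 5, 4), (0, 9, 4, 8)),      # y = 0
    ((1, 2, 6, 5), (1, 10, 5, 9)),     # x = 1
    ((2, 3, 7, 6), (2, 11, 6, 10)),    # y = 1
    ((3, 0, 4, 7), (3, 8, 7, 11)),     # x = 0
)


def _face_pairs(inside: tuple[int, ...]) -> list[tuple[int, int]]:
    """Crossing-edge pairs on every face for one cube configuration.

    Walking each face cyclically, a crossing edge flips inside/outside;
    the two crossings flanking one run of inside corners are paired.
    """
    pairs: list[tuple[int, int]] = []
    for corners, edges in _FACES:
        ins = [inside[c] for c in corners]
        if all(ins) or not any(ins):
            continue
        # crossings in cyclic face order
        crossing = [i for i in range(4) if ins[i] != ins[(i + 1) % 4]]
        # rotate so the walk starts at an outside corner just after a crossing
        # then consecutive crossings alternate out->in, in->out: pair them.
        start = next(i for i in crossing if not ins[i] and ins[(i + 1) % 4])
        ordered = sorted(crossing, key=lambda i: (i - start) % 4)
        for a, b in zip(ordered[0::2], ordered[1::2]):
            pairs.append((edges[a], edges[b]))
    return pairs


def _loops(pairs: list[tuple[int, int]]) -> list[list[int]]:
    """Chain face pairs (each crossing edge appears in exactly 2 pairs) into loops."""
    adj: dict[int, list[int]] = {}
    for a, b in pairs:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    loops = []
    seen: set[int] = set()
    for start in sorted(adj):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nxt = next(n for n in adj[cur] if n != prev or adj[cur].count(n) > 1)
            # handle the (rare) double-pair between the same two edges
            if nxt == prev and len(loop) >= 2:
                cand = [n for n in adj[cur] if n not in (prev,)]
                nxt = cand[0] if cand else nxt
            if nxt == start:
                break
            loop.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        loops.append(loop)
    return loops


def _orient(loop: list[int], inside: tuple[int, ...]) -> list[int]:
    """Orient a loop so fan-triangle normals point inside -> outside."""
    mids = (CORNER_OFFSETS[EDGE_CORNERS[loop, 0]] + CORNER_OFFSETS[EDGE_CORNERS[loop, 1]]) / 2.0
    # Newell normal of the polygon
    n = np.zeros(3)
    for i in range(len(loop)):
        a, b = mids[i], mids[(i + 1) % len(loop)]
        n += np.cross(a, b)
    c0, c1 = EDGE_CORNERS[loop[0]]
    if inside[c0]:
        out_dir = CORNER_OFFSETS[c1] - CORNER_OFFSETS[c0]
    else:
        out_dir = CORNER_OFFSETS[c0] - CORNER_OFFSETS[c1]
    if float(n @ out_dir) < 0:
        return loop[::-1]
    return loop


def _build_tri_table() -> list[tuple[tuple[int, int, int], ...]]:
    table: list[tuple[tuple[int, int, int], ...]] = []
    for case in range(256):
        inside = tuple((case >> c) & 1 for c in range(8))
        tris: list[tuple[int, int, int]] = []
        for loop in _loops(_face_pairs(inside)):
            loop = _orient(loop, inside)
            for i in range(1, len(loop) - 1):
                tris.append((loop[0], loop[i], loop[i + 1]))
        table.append(tuple(tris))
    return table


#: TRI_TABLE[case] -> tuple of (e0, e1, e2) edge-index triples.
TRI_TABLE = _build_tri_table()
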