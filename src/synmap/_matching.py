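"""One-to-one matching of two planar point sets under a distance cutoff.

Candidate pairs (distance <= cutoff) come from a KD-tree radius query.
The matching maximises the number of pairs and, among maximum-cardinality
matchings, minimises the total distance; it is computed exactly but
cheaply by solving a linear assignment problem independently on each
connected component of the feasibility graph (components are small for
diffraction-scale cutoffs, so dense fields stay fast).  Output order and
tie-breaks are deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree


def match_points(
    xy_a: np.ndarray, xy_b: np.ndarray, max_dist: float
) -> list[tuple[int, int, float]]:
    """Return one-to-one matches [(i_a, i_b, distance), ...].

    Maximum-cardinality, minimum-total-distance matching within
    ``max_dist``; coincident points (distance exactly 0) are valid
    candidates.  Matches are returned sorted by (distance, i_a, i_b).
    """
    xy_a = np.atleast_2d(np.asarray(xy_a, dtype=float))
    xy_b = np.atleast_2d(np.asarray(xy_b, dtype=float))
    if xy_a.size == 0 or xy_b.size == 0:
        return []
    neighbours = cKDTree(xy_a).query_ball_tree(cKDTree(xy_b), max_dist)

    # union-find over A nodes (0..nA-1) and B nodes (nA..nA+nB-1)
    n_a, n_b = len(xy_a), len(xy_b)
    parent = list(range(n_a + n_b))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int, float]] = []
    for ia, nbrs in enumerate(neighbours):
        for ib in sorted(nbrs):
            d = float(np.hypot(*(xy_a[ia] - xy_b[ib])))
            edges.append((ia, ib, d))
            ra, rb = find(ia), find(n_a + ib)
            if ra != rb:
                parent[rb] = ra
    if not edges:
        return []

    components: dict[int, list[tuple[int, int, float]]] = {}
    for ia, ib, d in edges:
        components.setdefault(find(ia), []).append((ia, ib, d))

    # a cost far above any achievable total distance: cardinality dominates
    big = (max_dist + 1.0) * (len(edges) + 1)
    matches: list[tuple[int, int, float]] = []
    for root in sorted(components):
        comp = components[root]
        rows = sorted({ia for ia, _, _ in comp})
        cols = sorted({ib for _, ib, _ in comp})
        if len(comp) == 1:
            ia, ib, d = comp[0]
            matches.append((ia, ib, d))
            continue
        cost = np.full((len(rows), len(cols)), big)
        row_of = {ia: i for i, ia in enumerate(rows)}
        col_of = {ib: j for j, ib in enumerate(cols)}
        for ia, ib, d in comp:
            cost[row_of[ia], col_of[ib]] = d
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            if cost[i, j] < big:
                matches.append((rows[i], cols[j], float(cost[i, j])))
    matches.sort(key=lambda m: (m[2], m[0], m[1]))
    return matches


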