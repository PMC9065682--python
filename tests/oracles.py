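"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the DBSCAN oracle is a
label propagation over the explicit eps-neighbourhood graph, and the
round-construction oracle enumerates every seed-containing subset.
"""

from itertools import combinations

import numpy as np


def dbscan_oracle(points, eps, min_pts):
    """Labels via explicit neighbourhood graph (noise = -1).

    Clusters are numbered in order of their first core point in the input;
    a border point joins the first cluster (in that order) containing a
    core point within eps — the same deterministic tie rule as the
    implementation.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    neigh = [set(np.nonzero(d2[i] <= eps * eps)[0]) for i in range(n)]
    core = {i for i in range(n) if len(neigh[i]) >= min_pts}
    labels = [-1] * n
    cid = 0
    for i in range(n):
        if i not in core or labels[i] != -1:
            continue
        frontier = [i]
        component = set()
        while frontier:  # connected component of core points
            c = frontier.pop()
            if c in component:
                continue
            component.add(c)
            frontier.extend(j for j in neigh[c] if j in core and j not in component)
        for c in component:
            labels[c] = cid
        for c in sorted(component):
            for j in sorted(neigh[c]):
                if labels[j] == -1:
                    labels[j] = cid
        cid += 1
    return labels


def _interiors_disjoint(a, b):
    return min(a.l_y, b.l_y) <= max(a.r_y, b.r_y)


def best_round_sumy_oracle(boxes):
    """Maximum sumy over all valid rounds, by full subset enumeration.

    A valid round contains the seed (largest delta_y; ties by num then by
    smaller r_y), only boxes no longer than the seed, and is pairwise
    y-disjoint.
    """
    seed = max(boxes, key=lambda b: (b.delta_y, b.num, -b.r_y))
    others = [b for b in boxes if b is not seed and b.delta_y <= seed.delta_y]
    best = seed.delta_y
    for r in range(1, len(others) + 1):
        for combo in combinations(others, r):
            subset = (seed,) + combo
            if all(_interiors_disjoint(a, b)
                   for a, b in combinations(subset, 2)):
                best = max(best, sum(b.delta_y for b in subset))
    return best
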