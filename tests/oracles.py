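"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive: pure-Python path walks, exhaustive
per-edge scans, numerical quadrature, and literal double sums.  None of it
shares code with the package's production paths.
"""

import numpy as np
from scipy.integrate import quad

from aplocal.skeleton import NeuriteSkeleton


def random_tree_skeleton(seed, n_nodes=50, scale_nm=1000.0):
    """Random geometric tree: node k attaches to a uniform previous node."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, 10 * scale_nm, size=(n_nodes, 3))
    radii = rng.uniform(0.2 * scale_nm, 2.0 * scale_nm, size=n_nodes)
    edges = [(int(rng.integers(0, k)), k) for k in range(1, n_nodes)]
    return NeuriteSkeleton(
        node_ids=np.arange(1, n_nodes + 1),
        positions=pos,
        radii=radii,
        edges=np.array(edges),
    )


def electrotonic_quad(d, r1, r2, x1=None, x2=None):
    """Numerical quadrature of integral of dx / sqrt(r(x)) over the cone."""
    if x1 is None:
        x1, x2 = 0.0, d
    if x2 == x1:
        return 0.0
    val, _ = quad(lambda x: 1.0 / np.sqrt(r1 + (r2 - r1) * x / d), x1, x2,
                  epsabs=1e-13, epsrel=1e-12)
    return val


def tree_node_path_length(skel, a, b, weights):
    """Length of the unique a-b path on the tree, found by parent walking."""
    adj = {}
    for e, (u, v) in enumerate(skel.edges.tolist()):
        adj.setdefault(u, []).append((v, weights[e]))
        adj.setdefault(v, []).append((u, weights[e]))
    # BFS from a recording parents
    parent = {a: (None, 0.0)}
    frontier = [a]
    while frontier:
        nxt = []
        for u in frontier:
            for v, w in adj.get(u, ()):
                if v not in parent:
                    parent[v] = (u, w)
                    nxt.append(v)
        frontier = nxt
    total, node = 0.0, b
    while node != a:
        p, w = parent[node]
        total += w
        node = p
    return total


def location_distance_oracle(skel, loc1, loc2, weights, end_piece):
    """Shortest path between two (edge, offset) locations on a tree.

    ``weights[e]`` is the full-edge weight and ``end_piece(e, x1, x2)`` the
    weight of the [x1, x2] stretch of edge e.  On a tree the path between
    two in-edge points either stays on the shared edge or exits through one
    endpoint of each edge (4 combinations).
    """
    e1, o1 = loc1
    e2, o2 = loc2
    if e1 == e2:
        return end_piece(e1, min(o1, o2), max(o1, o2))
    best = np.inf
    L1, L2 = skel.edge_lengths[e1], skel.edge_lengths[e2]
    for end1, d1 in ((skel.edges[e1, 0], end_piece(e1, 0.0, o1)),
                     (skel.edges[e1, 1], end_piece(e1, o1, L1))):
        for end2, d2 in ((skel.edges[e2, 0], end_piece(e2, 0.0, o2)),
                         (skel.edges[e2, 1], end_piece(e2, o2, L2))):
            mid = tree_node_path_length(skel, int(end1), int(end2), weights)
            best = min(best, d1 + mid + d2)
    return best


def real_end_piece(skel):
    return lambda e, x1, x2: x2 - x1


def electrotonic_end_piece(skel):
    def piece(e, x1, x2):
        u, v = skel.edges[e]
        return electrotonic_quad(skel.edge_lengths[e], skel.radii[u], skel.radii[v], x1, x2)

    return piece


def nearest_point_bruteforce(skel, point):
    """Exhaustive scalar scan over every edge for the nearest skeleton point."""
    best = (np.inf, None, None)
    for e in range(skel.n_edges):
        a = skel.positions[skel.edges[e, 0]]
        b = skel.positions[skel.edges[e, 1]]
        ab = b - a
        L2 = float(ab @ ab)
        t = 0.0 if L2 == 0 else float(np.clip((point - a) @ ab / L2, 0.0, 1.0))
        foot = a + t * ab
        d = float(np.linalg.norm(point - foot))
        if d < best[0] - 1e-12:
            best = (d, e, t * np.sqrt(L2))
    return best  # (residual, edge, offset)


def inhibition_double_sum(distances, src_kc, tgt_kc, lam_nm, kc_ids):
    """Literal double loop over synapse pairs for s(k1, k2)."""
    import math

    s = {(a, b): 0.0 for a in kc_ids for b in kc_ids}
    for i, ka in enumerate(src_kc):
        for j, kb in enumerate(tgt_kc):
            w = 1.0 if math.isinf(lam_nm) else math.exp(-distances[i, j] / lam_nm)
            s[(ka, kb)] += w
    return s
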