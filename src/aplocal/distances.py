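"""Exact along-skeleton distances between synapse (or point) sets.

Locations mapped to edge interiors are inserted as extra graph vertices that
split their host edges, so within-edge offsets are respected exactly; the
split pieces carry either their real length or their partial truncated-cone
electrotonic length.  Shortest paths are then a single multi-source Dijkstra
run on the augmented sparse graph (scipy.sparse.csgraph).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .skeleton import partial_electrotonic_distance
from .units import M12_PER_NM12, M_PER_NM

__all__ = ["DistanceMatrix", "pairwise_distances"]

_SNAP_NM = 1e-6  # offsets within this of an endpoint reuse the endpoint vertex


@dataclass
class DistanceMatrix:
    """Dense matrix of along-skeleton distances between two location sets.

    ``values`` is in nm for the real metric and nm^(1/2) for the electrotonic
    metric; ``si_factor`` converts one unit to m (real) or m^(1/2)
    (electrotonic).
    """

    source_ids: np.ndarray
    target_ids: np.ndarray
    values: np.ndarray
    metric: str

    @property
    def si_factor(self):
        return M_PER_NM if self.metric == "real" else M12_PER_NM12

    def to_si(self):
        return self.values * self.si_factor

    def save(self, array_path, sidecar_path):
        np.save(array_path, self.values)
        import pandas as pd

        pd.DataFrame(
            {
                "axis": ["source"] * len(self.source_ids) + ["target"] * len(self.target_ids),
                "id": list(self.source_ids) + list(self.target_ids),
            }
        ).to_csv(sidecar_path, index=False)


def _as_location(loc):
    if hasattr(loc, "edge_index"):
        return int(loc.edge_index), float(loc.offset_nm), getattr(loc, "synapse_id", None)
    e, o = loc
    return int(e), float(o), None


def _augment(skel, locations, metric):
    """Vertex index for every location, plus the augmented sparse graph.

    Returns (vertex_of_location array, csr adjacency).
    """
    n_edges = skel.n_edges
    parsed = []
    for loc in locations:
        e, o, _ = _as_location(loc)
        if not (0 <= e < n_edges):
            raise ValueError(f"edge index {e} outside this skeleton ({n_edges} edges)")
        if o < -_SNAP_NM or o > skel.edge_lengths[e] + max(_SNAP_NM, 1e-9 * skel.edge_lengths[e]) + 1e-9:
            raise ValueError(
                f"offset {o} nm outside edge {e} of length {skel.edge_lengths[e]} nm "
                "(location mapped to a different skeleton?)"
            )
        parsed.append((e, min(max(o, 0.0), skel.edge_lengths[e])))

    # group interior cut points by edge
    cuts = {}  # edge -> sorted list of unique offsets
    for e, o in parsed:
        length = skel.edge_lengths[e]
        if o > _SNAP_NM and o < length - _SNAP_NM:
            cuts.setdefault(e, set()).add(o)
    next_vertex = skel.n_nodes
    cut_vertex = {}  # (edge, offset) -> vertex
    for e in sorted(cuts):
        for o in sorted(cuts[e]):
            cut_vertex[(e, o)] = next_vertex
            next_vertex += 1

    rows, cols, weights = [], [], []

    def add(u, v, w):
        rows.append(u)
        cols.append(v)
        weights.append(w)

    u_all, v_all = skel.edges[:, 0], skel.edges[:, 1]
    r1_all, r2_all = skel.radii[u_all], skel.radii[v_all]
    for e in range(n_edges):
        length = skel.edge_lengths[e]
        interior = sorted(cuts.get(e, ()))
        chain = [(0.0, int(u_all[e]))] + [(o, cut_vertex[(e, o)]) for o in interior] + [
            (length, int(v_all[e]))
        ]
        for (x1, a), (x2, b) in zip(chain[:-1], chain[1:]):
            if metric == "real":
                w = x2 - x1
            else:
                w = partial_electrotonic_distance(length, r1_all[e], r2_all[e], x1, x2)
            add(a, b, w)

    adj = coo_matrix(
        (np.array(weights), (np.array(rows), np.array(cols))),
        shape=(next_vertex, next_vertex),
    ).tocsr()

    vertex_of = np.empty(len(parsed), dtype=np.int64)
    for i, (e, o) in enumerate(parsed):
        length = skel.edge_lengths[e]
        if o <= _SNAP_NM:
            vertex_of[i] = u_all[e]
        elif o >= length - _SNAP_NM:
            vertex_of[i] = v_all[e]
        else:
            vertex_of[i] = cut_vertex[(e, o)]
    return vertex_of, adj


def pairwise_distances(skel, sources, targets, metric="real") -> DistanceMatrix:
    """Shortest along-skeleton distance from every source to every target.

    ``sources`` / ``targets`` are :class:`~aplocal.synapses.MappedSynapse`
    objects or plain ``(edge_index, offset_nm)`` pairs on the same skeleton.
    ``metric`` is ``"real"`` (nm) or ``"electrotonic"`` (nm^(1/2)).
    """
    if metric not in ("real", "electrotonic"):
        raise ValueError(f"unknown metric {metric!r}")
    locations = list(sources) + list(targets)
    vertex_of, adj = _augment(skel, locations, metric)
    ns = len(list(sources))
    src_v = vertex_of[:ns]
    tgt_v = vertex_of[ns:]

    uniq_src, inv_src = np.unique(src_v, return_inverse=True)
    dist_from_uniq = dijkstra(adj, directed=False, indices=uniq_src)
    values = dist_from_uniq[np.ix_(inv_src, tgt_v)]

    def ids(locs, offset):
        out = []
        for i, loc in enumerate(locs):
            _, _, sid = _as_location(loc)
            out.append(sid if sid is not None else i + offset)
        return np.array(out)

    return DistanceMatrix(
        source_ids=ids(list(sources), 0),
        target_ids=ids(list(targets), 0),
        values=values,
        metric=metric,
    )
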