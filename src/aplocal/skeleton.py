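"""Neurite skeletons: SWC I/O, validation, and electrotonic geometry.

A skeleton is a rooted tree embedded in 3D with a radius at every node.  Each
edge is treated as a truncated cone between its endpoint radii.  Two edge
metrics are maintained:

* real length — the Euclidean distance between endpoints (nm);
* electrotonic length — the integral of dx / sqrt(r(x)) along the cone
  (nm^(1/2)), which is the length scale on which passive depolarization
  decays when the space constant varies with the square root of the neurite
  radius.

For a cone of length d with end radii r1, r2 the electrotonic length has the
closed form 2 d (sqrt(r2) - sqrt(r1)) / (r2 - r1), computed here in the
algebraically equivalent, numerically stable form 2 d / (sqrt(r1) + sqrt(r2))
which also covers the cylinder limit r1 == r2 (-> d / sqrt(r)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .units import M12_PER_NM12, M_PER_NM

logger = logging.getLogger(__name__)

__all__ = [
    "NeuriteSkeleton",
    "SkeletonLoadError",
    "read_swc",
    "write_swc",
    "segment_electrotonic_length",
    "partial_electrotonic_distance",
    "skeleton_totals",
]


class SkeletonLoadError(ValueError):
    """Raised when an SWC file does not describe a single connected tree."""


def segment_electrotonic_length(d, r1, r2):
    """Electrotonic length of a truncated-cone segment.

    Parameters
    ----------
    d : float or array
        Segment length (nm, or any length unit; output is unit^(1/2)).
    r1, r2 : float or array
        Radii at the two ends (same unit as ``d``), strictly positive.

    Returns
    -------
    float or array
        ``2 d (sqrt(r2) - sqrt(r1)) / (r2 - r1)``, i.e. ``d / sqrt(r)`` when
        the radii are equal; continuous in (r1, r2).
    """
    d = np.asarray(d, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(d < 0):
        raise ValueError("segment length must be non-negative")
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("radii must be positive")
    out = 2.0 * d / (np.sqrt(r1) + np.sqrt(r2))
    return out if out.ndim else float(out)


def partial_electrotonic_distance(d, r1, r2, x1, x2):
    """Electrotonic distance between two points on one truncated-cone segment.

    ``x1`` and ``x2`` are arc positions measured from the end with radius
    ``r1`` and must satisfy ``0 <= x1 <= x2 <= d``.  Equals
    :func:`segment_electrotonic_length` when ``(x1, x2) == (0, d)``.
    """
    d = np.asarray(d, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("radii must be positive")
    if np.any(x1 < -1e-9) or np.any(x2 - x1 < -1e-9) or np.any(x2 > d + 1e-9):
        raise ValueError("require 0 <= x1 <= x2 <= d")
    # interpolated radii at the two positions; degenerate d=0 -> zero length
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(d > 0, (r2 - r1) / np.where(d > 0, d, 1.0), 0.0)
    a1 = r1 + slope * x1
    a2 = r1 + slope * x2
    out = 2.0 * (x2 - x1) / (np.sqrt(a1) + np.sqrt(a2))
    return out if out.ndim else float(out)


@dataclass
class NeuriteSkeleton:
    """A neurite skeleton as a rooted geometric tree with per-node radii.

    Attributes
    ----------
    node_ids : (N,) int array of original SWC ids (order = file order)
    positions : (N, 3) float array, nm
    radii : (N,) float array, nm (positive after clamping)
    edges : (E, 2) int array of node *indices* (parent, child)
    unit_scale : nm per input coordinate unit
    """

    node_ids: np.ndarray
    positions: np.ndarray
    radii: np.ndarray
    edges: np.ndarray
    unit_scale: float = 1.0
    _index_of: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self._index_of = {int(i): k for k, i in enumerate(self.node_ids)}
        self._validate()
        self._edge_geometry()

    # -- construction / validation -------------------------------------
    def _validate(self):
        n = len(self.node_ids)
        if len(set(self.node_ids.tolist())) != n:
            raise SkeletonLoadError("duplicate node ids")
        if np.any(self.radii <= 0):
            bad = self.node_ids[self.radii <= 0]
            raise SkeletonLoadError(f"non-positive radii at nodes {bad.tolist()}")
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(map(tuple, self.edges.tolist()))
        if g.number_of_edges() != len(self.edges):
            raise SkeletonLoadError("duplicate edges")
        if not nx.is_connected(g):
            comps = [sorted(self.node_ids[list(c)].tolist())[:5] for c in nx.connected_components(g)]
            raise SkeletonLoadError(
                f"skeleton is not connected: {len(comps)} components, e.g. {comps[:4]}"
            )
        if g.number_of_edges() != n - 1:
            cyc = nx.find_cycle(g)
            raise SkeletonLoadError(f"skeleton contains a cycle through edges {cyc[:5]}")

    def _edge_geometry(self):
        u, v = self.edges[:, 0], self.edges[:, 1]
        delta = self.positions[v] - self.positions[u]
        self.edge_lengths = np.linalg.norm(delta, axis=1)
        self.edge_elengths = segment_electrotonic_length(
            self.edge_lengths, self.radii[u], self.radii[v]
        )
        self.edge_elengths = np.atleast_1d(self.edge_elengths)

    # -- convenience ----------------------------------------------------
    @property
    def n_nodes(self):
        return len(self.node_ids)

    @property
    def n_edges(self):
        return len(self.edges)

    def index_of(self, node_id):
        return self._index_of[int(node_id)]

    @property
    def total_length_nm(self):
        return float(self.edge_lengths.sum())

    @property
    def total_electrotonic_length_nm12(self):
        return float(self.edge_elengths.sum())

    def graph(self, metric="real"):
        """Weighted undirected networkx graph over node indices."""
        w = self.edge_lengths if metric == "real" else self.edge_elengths
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for (a, b), weight in zip(self.edges.tolist(), w.tolist()):
            g.add_edge(a, b, weight=weight)
        return g


def read_swc(path, unit_scale=1.0) -> NeuriteSkeleton:
    """Read an SWC file (7 whitespace-separated columns, ``#`` comments).

    Columns: id, type, x, y, z, radius, parent (-1 for the root).  Radii that
    are missing or non-positive are clamped to the smallest positive radius in
    the file (SWC exports routinely carry sentinel radii, and the electrotonic
    form is undefined at r = 0).  Raises :class:`SkeletonLoadError` for
    multiple roots, missing parents, cycles or disconnection.
    """
    ids, xyz, radii, parents = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise SkeletonLoadError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            ids.append(int(parts[0]))
            xyz.append([float(parts[2]), float(parts[3]), float(parts[4])])
            radii.append(float(parts[5]))
            parents.append(int(parts[6]))
    if not ids:
        raise SkeletonLoadError("empty SWC file")
    ids = np.array(ids, dtype=np.int64)
    xyz = np.array(xyz, dtype=float) * unit_scale
    radii = np.array(radii, dtype=float) * unit_scale
    parents = np.array(parents, dtype=np.int64)

    positive = radii[radii > 0]
    if positive.size == 0:
        raise SkeletonLoadError("no positive radius in file; cannot clamp")
    n_clamped = int(np.sum(radii <= 0))
    radii = np.where(radii > 0, radii, positive.min())
    if n_clamped:
        logger.warning("clamped %d non-positive radii to %g nm", n_clamped, positive.min())

    index = {int(i): k for k, i in enumerate(ids)}
    roots = np.flatnonzero(parents == -1)
    if len(roots) == 0:
        raise SkeletonLoadError("no root node (parent = -1)")
    if len(roots) > 1:
        raise SkeletonLoadError(f"multiple roots: nodes {ids[roots].tolist()}")
    edges = []
    for k, p in enumerate(parents):
        if p == -1:
            continue
        if int(p) not in index:
            raise SkeletonLoadError(f"node {int(ids[k])} references absent parent {int(p)}")
        edges.append((index[int(p)], k))
    skel = NeuriteSkeleton(ids, xyz, radii, np.array(edges), unit_scale=unit_scale)
    logger.info(
        "read %d nodes, total length %.4g m, electrotonic length %.4g m^1/2",
        skel.n_nodes,
        skel.total_length_nm * M_PER_NM,
        skel.total_electrotonic_length_nm12 * M12_PER_NM12,
    )
    return skel


def write_swc(skel: NeuriteSkeleton, path):
    """Write a skeleton as SWC (coordinates divided back by ``unit_scale``)."""
    parent_of = {}
    # root the tree at the first node for parent assignment
    g = nx.Graph()
    g.add_nodes_from(range(skel.n_nodes))
    g.add_edges_from(map(tuple, skel.edges.tolist()))
    for child, parent in nx.bfs_predecessors(g, 0):
        parent_of[child] = parent
    s = skel.unit_scale
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(skel.n_nodes):
            p = parent_of.get(k)
            pid = -1 if p is None else int(skel.node_ids[p])
            x, y, z = skel.positions[k] / s
            fh.write(
                f"{int(skel.node_ids[k])} 0 {x:.6f} {y:.6f} {z:.6f} "
                f"{skel.radii[k] / s:.6f} {pid}\n"
            )


def skeleton_totals(skel: NeuriteSkeleton):
    """Total real length (m), total electrotonic length (m^1/2), and ratio.

    The ratio (m^1/2) converts between the space constant in real space
    (lambda) and in electrotonic space (k): lambda = k * ratio.
    """
    total_m = skel.total_length_nm * M_PER_NM
    total_m12 = skel.total_electrotonic_length_nm12 * M12_PER_NM12
    return total_m, total_m12, total_m / total_m12
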