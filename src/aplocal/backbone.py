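"""Backbone skeletons: the 1D coordinate system of the mushroom body.

The mushroom body's three major branches (vertical lobe, horizontal lobe,
peduncle/calyx) are summarized by a polyline per branch, all meeting at a
shared junction.  Spatial profiles are expressed against the distance from
the dorsal calyx measured along this backbone: points on the peduncle/calyx
branch lie at [0, L_calyx]; points in a lobe at L_calyx + (arc from the
junction).  Individual backbones are normalized onto a standard backbone
(per-branch mean length across recordings) by scaling each branch's node
spacing with the ratio of individual to standard branch length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Backbone",
    "StandardBackbone",
    "build_backbone",
    "standardize_backbones",
    "place_nodes",
]

#: conventional branch names; the calyx branch carries the coordinate origin
CALYX_BRANCH = "peduncle_calyx"


def _polyline_arcs(points):
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class Backbone:
    """Polyline per branch (um); every branch's first point is the junction."""

    branches: dict  # name -> (P, 3) float array, um
    calyx_branch: str = CALYX_BRANCH
    _arcs: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.branches = {k: np.asarray(v, dtype=float) for k, v in self.branches.items()}
        self._arcs = {k: _polyline_arcs(v) for k, v in self.branches.items()}

    @property
    def junction(self):
        return next(iter(self.branches.values()))[0]

    @property
    def branch_lengths(self):
        return {k: float(a[-1]) for k, a in self._arcs.items()}

    @property
    def calyx_length(self):
        return self.branch_lengths[self.calyx_branch]

    def point_at(self, branch, arc_from_junction):
        """3D position (um) at a given arc position along a branch."""
        pts, arcs = self.branches[branch], self._arcs[branch]
        s = float(np.clip(arc_from_junction, 0.0, arcs[-1]))
        i = int(np.searchsorted(arcs, s, side="right") - 1)
        i = min(i, len(arcs) - 2)
        t = 0.0 if arcs[i + 1] == arcs[i] else (s - arcs[i]) / (arcs[i + 1] - arcs[i])
        return pts[i] + t * (pts[i + 1] - pts[i])

    def distance_from_calyx(self, branch, arc_from_junction):
        if branch == self.calyx_branch:
            return self.calyx_length - arc_from_junction
        return self.calyx_length + arc_from_junction

    def path_distance(self, loc1, loc2):
        """Along-backbone distance (um) between (branch, arc-from-junction)
        locations; different branches connect through the junction."""
        b1, s1 = loc1
        b2, s2 = loc2
        return abs(s1 - s2) if b1 == b2 else s1 + s2

    def project(self, points_um):
        """Project 3D points (N, 3) onto the backbone.

        Returns a DataFrame with branch, arc_from_junction_um,
        distance_from_calyx_um and residual_um per point (nearest point over
        every branch polyline segment; ties resolved toward the branch listed
        first).
        """
        points_um = np.atleast_2d(np.asarray(points_um, dtype=float))
        best = np.full(len(points_um), np.inf)
        out_branch = np.empty(len(points_um), dtype=object)
        out_arc = np.zeros(len(points_um))
        for name, pts in self.branches.items():
            arcs = self._arcs[name]
            a, b = pts[:-1], pts[1:]
            ab = b - a
            ab2 = np.einsum("ij,ij->i", ab, ab)
            ab2 = np.where(ab2 > 0, ab2, 1.0)
            ap = points_um[:, None, :] - a[None, :, :]
            t = np.clip(np.einsum("pej,ej->pe", ap, ab) / ab2, 0.0, 1.0)
            foot = a[None] + t[..., None] * ab[None]
            d = np.linalg.norm(points_um[:, None, :] - foot, axis=2)
            j = np.argmin(d, axis=1)
            rows = np.arange(len(points_um))
            better = d[rows, j] < best
            best = np.where(better, d[rows, j], best)
            arc = arcs[j] + t[rows, j] * np.sqrt(ab2[j])
            out_arc = np.where(better, arc, out_arc)
            out_branch[better] = name
        dist_cal = np.array(
            [self.distance_from_calyx(b, s) for b, s in zip(out_branch, out_arc)]
        )
        return pd.DataFrame(
            {
                "branch": out_branch,
                "arc_from_junction_um": out_arc,
                "distance_from_calyx_um": dist_cal,
                "residual_um": best,
            }
        )

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "calyx_branch": self.calyx_branch,
                    "branches": {k: v.tolist() for k, v in self.branches.items()},
                },
                fh,
            )

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(branches=d["branches"], calyx_branch=d["calyx_branch"])


def build_backbone(key_points, calyx_branch=CALYX_BRANCH, junction_tol_um=1e-6) -> Backbone:
    """Connect manually defined key points into a backbone.

    ``key_points`` maps branch name -> ordered list of 3D points (um), each
    branch starting at the shared junction.  Raises if a branch has fewer
    than two points or does not start at the junction.
    """
    if calyx_branch not in key_points:
        raise ValueError(f"missing calyx branch {calyx_branch!r}")
    branches = {k: np.asarray(v, dtype=float) for k, v in key_points.items()}
    for name, pts in branches.items():
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValueError(f"branch {name!r} needs >= 2 three-dimensional points")
    junction = branches[calyx_branch][0]
    for name, pts in branches.items():
        if np.linalg.norm(pts[0] - junction) > junction_tol_um:
            raise ValueError(f"branch {name!r} does not start at the shared junction")
    return Backbone(branches=branches, calyx_branch=calyx_branch)


@dataclass
class StandardBackbone:
    """Per-branch mean lengths and the standard node grid.

    Nodes live on the distance-from-calyx axis at multiples of
    ``spacing_um``; nodes beyond the calyx branch exist once per lobe branch.
    """

    branch_lengths: dict
    spacing_um: float
    calyx_branch: str = CALYX_BRANCH

    def node_table(self):
        rows = []
        node_id = 0
        L_cal = self.branch_lengths[self.calyx_branch]
        lobes = [b for b in self.branch_lengths if b != self.calyx_branch]
        d = 0.0
        while d <= L_cal + 1e-9:
            rows.append({"node_id": node_id, "branch": self.calyx_branch,
                         "distance_from_calyx_um": d})
            node_id += 1
            d += self.spacing_um
        for lobe in lobes:
            total = L_cal + self.branch_lengths[lobe]
            d = (np.floor(L_cal / self.spacing_um) + 1) * self.spacing_um
            while d <= total + 1e-9:
                rows.append({"node_id": node_id, "branch": lobe,
                             "distance_from_calyx_um": d})
                node_id += 1
                d += self.spacing_um
        return pd.DataFrame(rows)


def standardize_backbones(backbones, spacing_um=20.0):
    """Average branch lengths across recordings into a standard backbone.

    Returns ``(standard, scales)`` where ``scales[i][branch]`` is the ratio
    of recording i's branch length to the standard length — the factor by
    which that recording's node spacing is stretched so that its nodes land
    on the standard grid.  Standardizing a single backbone returns itself
    (all scales 1): the operation is idempotent.
    """
    if not backbones:
        raise ValueError("no backbones given")
    lengths = []
    for bb in backbones:
        lengths.append(bb.branch_lengths if isinstance(bb, Backbone) else dict(bb))
    names = set(lengths[0])
    calyx = backbones[0].calyx_branch if isinstance(backbones[0], Backbone) else CALYX_BRANCH
    for L in lengths:
        if set(L) != names:
            raise ValueError("backbones have mismatched branch topology")
    std = {b: float(np.mean([L[b] for L in lengths])) for b in names}
    scales = [{b: L[b] / std[b] for b in names} for L in lengths]
    return StandardBackbone(branch_lengths=std, spacing_um=spacing_um, calyx_branch=calyx), scales


def place_nodes(backbone: Backbone, standard: StandardBackbone, scale=None):
    """Node positions for one recording on the standard grid.

    Standard node i (distance i * spacing from the calyx) is placed on this
    backbone at the branch-wise rescaled arc position: within the calyx
    branch at distance d * scale_calyx from the calyx tip, within a lobe at
    L_calyx_individual + (d - L_calyx_standard) * scale_lobe from the
    junction.  Returns a DataFrame with node_id, branch,
    distance_from_calyx_um (standard), x/y/z (um, individual).
    """
    if scale is None:
        scale = {b: backbone.branch_lengths[b] / standard.branch_lengths[b]
                 for b in standard.branch_lengths}
    table = standard.node_table()
    L_cal_std = standard.branch_lengths[standard.calyx_branch]
    L_cal_ind = backbone.branch_lengths[backbone.calyx_branch]
    xyz = []
    for row in table.itertuples(index=False):
        d = row.distance_from_calyx_um
        if row.branch == standard.calyx_branch:
            arc = L_cal_ind - d * scale[row.branch]  # from junction
            xyz.append(backbone.point_at(backbone.calyx_branch, arc))
        else:
            arc = (d - L_cal_std) * scale[row.branch]
            xyz.append(backbone.point_at(row.branch, arc))
    xyz = np.array(xyz)
    out = table.copy()
    out[["x_um", "y_um", "z_um"]] = xyz
    return out
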