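"""Passive activity spread simulated with random points on the skeleton.

Random points are scattered uniformly (by arc length) over the neurite
skeleton; the activity of a 1D backbone segment is the average, over the
points assigned to it, of the exponentially distance-weighted sum of
stimulus carried by every other point:

    activity(s_i) = (1 / N_si) * sum_{j in s_i} sum_k stim(p_k) w(d(p_j, p_k))

With a uniform unit stimulus this is a pure weighted pair count; a localized
stimulus (e.g. fitted dye profiles around an ejection site) weights source
points by the fitted amplitude at their segment.  Distances can be measured
in electrotonic space, in real space with uniform radius, or along the 1D
backbone — the model deliberately ignores current division at branch points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .distances import DistanceMatrix, pairwise_distances
from .inhibition import SpaceConstantSpec, pair_weight
from .units import NM_PER_UM

logger = logging.getLogger(__name__)

__all__ = [
    "SkeletonPoints",
    "StimulusProfile",
    "StimulusFitError",
    "ActivitySimResult",
    "sample_skeleton_points",
    "fit_stimulus_decay",
    "simulate_activity",
    "distance_mode",
]


@dataclass
class SkeletonPoints:
    """Random points on a skeleton: host edge, offset, 3D position, and an
    inclusion flag (points on excluded edges, e.g. the soma neurite outside
    the mushroom body, are flagged rather than dropped)."""

    edge_index: np.ndarray
    offset_nm: np.ndarray
    positions: np.ndarray
    included: np.ndarray
    seed: int

    def __len__(self):
        return len(self.edge_index)

    def locations(self):
        return list(zip(self.edge_index.tolist(), self.offset_nm.tolist()))


def sample_skeleton_points(skel, n, seed, excluded_edges=()) -> SkeletonPoints:
    """Sample ``n`` points uniformly by real arc length over the skeleton.

    ``excluded_edges`` is an iterable of edge indices outside the analysis
    domain (the points are still sampled there — the skeleton's length
    distribution is respected — but flagged not included).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    p = skel.edge_lengths / skel.edge_lengths.sum()
    edges = rng.choice(skel.n_edges, size=n, p=p)
    offsets = rng.uniform(0.0, skel.edge_lengths[edges])
    a = skel.positions[skel.edges[edges, 0]]
    b = skel.positions[skel.edges[edges, 1]]
    with np.errstate(invalid="ignore"):
        t = np.where(skel.edge_lengths[edges] > 0, offsets / skel.edge_lengths[edges], 0.0)
    pos = a + t[:, None] * (b - a)
    excluded_edges = set(int(e) for e in excluded_edges)
    included = np.array([int(e) not in excluded_edges for e in edges])
    if not included.any():
        logger.warning("all %d sampled points fall on excluded edges", n)
    return SkeletonPoints(edges, offsets, pos, included, seed)


class StimulusFitError(RuntimeError):
    pass


@dataclass
class StimulusProfile:
    """Exponential stimulus fits A * exp(-|x - x0| / ell) per branch path.

    ``fits`` maps branch name -> (amplitude, decay length um); ``x0_um`` is
    the ejection site on the distance-from-calyx axis.  Segments claimed by
    several branch paths (the shared peduncle/calyx stretch) get the average
    of the overlapping fits.
    """

    x0_um: float
    fits: dict
    ejection_branch: str | None = None

    def predict(self, distance_um, branch):
        A, ell = self.fits[branch]
        return A * np.exp(-np.abs(np.asarray(distance_um, dtype=float) - self.x0_um) / ell)

    def predict_segments(self, profile: pd.DataFrame):
        """Fitted amplitude per segment, averaging overlapping branch fits.

        ``profile`` needs columns segment, branch, distance_from_calyx_um.
        """
        df = profile.copy()
        df["fitted"] = [
            float(self.predict(r.distance_from_calyx_um, r.branch))
            for r in df.itertuples(index=False)
        ]
        return df.groupby("segment", as_index=True).agg(
            distance_from_calyx_um=("distance_from_calyx_um", "first"),
            fitted=("fitted", "mean"),
        )


def _fit_one_branch(x, y, x0, max_ell_factor=100.0):
    span = max(np.ptp(np.abs(x - x0)), 1e-9)
    pos = y > 0
    if pos.sum() >= 2:
        # log-linear initial guess
        coef = np.polyfit(np.abs(x[pos] - x0), np.log(y[pos]), 1)
        ell0 = -1.0 / coef[0] if coef[0] < 0 else span
        A0 = float(np.exp(coef[1]))
    else:
        ell0, A0 = span / 2, max(float(y.max()), 1e-6)
    ell0 = float(np.clip(ell0, 1e-3, max_ell_factor * span))

    def model(xx, A, ell):
        return A * np.exp(-np.abs(xx - x0) / ell)

    try:
        popt, _ = curve_fit(model, x, y, p0=[A0, ell0], maxfev=20000)
    except RuntimeError as err:
        raise StimulusFitError(f"exponential fit did not converge: {err}") from err
    A, ell = float(popt[0]), float(popt[1])
    if not np.isfinite(ell) or ell <= 0:
        raise StimulusFitError(f"non-physical decay length {ell}")
    if ell > max_ell_factor * span:
        raise StimulusFitError(
            f"decay length {ell:.3g} um exceeds {max_ell_factor}x the data span "
            f"{span:.3g} um (flat profile?)"
        )
    if A < 0:
        raise StimulusFitError(f"negative fitted amplitude {A}")
    return A, ell


def fit_stimulus_decay(profile: pd.DataFrame, x0_um, min_points=4) -> StimulusProfile:
    """Fit A * exp(-|x - x0| / ell) to a per-segment dye profile.

    ``profile`` holds columns branch, distance_from_calyx_um, value; one fit
    per branch path.  Requires at least ``min_points`` finite values per
    branch; flat or diverging profiles raise :class:`StimulusFitError` with
    diagnostics.
    """
    fits = {}
    for branch, grp in profile.groupby("branch", sort=False):
        grp = grp.dropna(subset=["value"])
        if len(grp) < min_points:
            raise StimulusFitError(
                f"branch {branch!r}: only {len(grp)} finite segments (< {min_points})"
            )
        x = grp["distance_from_calyx_um"].to_numpy(dtype=float)
        y = grp["value"].to_numpy(dtype=float)
        fits[branch] = _fit_one_branch(x, y, x0_um)
    return StimulusProfile(x0_um=float(x0_um), fits=fits)


@dataclass
class ActivitySimResult:
    """Per-segment simulated activity with bookkeeping.

    ``activity`` is the raw weighted pair count per segment; ``normalized``
    divides by the maximum responding segment (the convention used when
    comparing with measured profiles).  Segments with no points carry NaN.
    """

    segments: np.ndarray
    activity: np.ndarray
    normalized: np.ndarray
    point_count: np.ndarray
    n_points: int
    n_excluded: int
    seed: int | None = None


def simulate_activity(
    dist: DistanceMatrix, stimulus, segment_of_point, spec: SpaceConstantSpec, seed=None
) -> ActivitySimResult:
    """Average distance-weighted stimulus received by each backbone segment.

    Parameters
    ----------
    dist : DistanceMatrix
        Square matrix among the sampled points, in the metric matching
        ``spec.mode``.
    stimulus : scalar or (n,) array
        Stimulus amplitude carried by each point (uniform 1 reproduces the
        plain weighted pair count).
    segment_of_point : (n,) int array
        Backbone segment of each point; negative = outside the mushroom body
        (excluded from both sums).
    """
    n = dist.values.shape[0]
    if dist.values.shape[1] != n:
        raise ValueError("simulate_activity needs a square point-to-point matrix")
    seg = np.asarray(segment_of_point)
    stim = np.broadcast_to(np.asarray(stimulus, dtype=float), (n,))
    keep = seg >= 0
    n_excluded = int((~keep).sum())
    w = pair_weight(dist.values[np.ix_(keep, keep)], spec)
    received = w @ stim[keep]  # per point j: sum_k stim_k w_jk
    seg_k = seg[keep]
    segments = np.arange(seg_k.max() + 1) if seg_k.size else np.arange(0)
    counts = np.bincount(seg_k, minlength=len(segments))
    sums = np.bincount(seg_k, weights=received, minlength=len(segments))
    with np.errstate(invalid="ignore", divide="ignore"):
        activity = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    finite = np.isfinite(activity)
    peak = np.nanmax(activity) if finite.any() else np.nan
    normalized = activity / peak
    return ActivitySimResult(
        segments=segments,
        activity=activity,
        normalized=normalized,
        point_count=counts,
        n_points=int(keep.sum()),
        n_excluded=n_excluded,
        seed=seed,
    )


def distance_mode(skel, locations, mode, backbone=None, positions_um=None) -> DistanceMatrix:
    """Pairwise distances among locations under one of three conventions.

    ``skeleton_electrotonic`` — along-skeleton electrotonic distance
    (nm^(1/2), for electrotonic-mode space constants k);
    ``skeleton_real_uniform_radius`` — along-skeleton real distance (nm,
    radius ignored); ``backbone`` — each location projected to the nearest
    backbone position, distance measured along the backbone polylines (nm).
    """
    if mode == "skeleton_electrotonic":
        return pairwise_distances(skel, locations, locations, metric="electrotonic")
    if mode == "skeleton_real_uniform_radius":
        return pairwise_distances(skel, locations, locations, metric="real")
    if mode == "backbone":
        if backbone is None:
            raise ValueError("backbone mode requires a Backbone")
        if positions_um is None:
            if hasattr(locations, "positions"):
                positions_um = locations.positions / NM_PER_UM
            else:
                raise ValueError("backbone mode requires 3D positions")
        proj = backbone.project(positions_um)
        locs = list(zip(proj["branch"], proj["arc_from_junction_um"]))
        n = len(locs)
        vals = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                d = backbone.path_distance(locs[i], locs[j])
                vals[i, j] = vals[j, i] = d
        return DistanceMatrix(
            source_ids=np.arange(n),
            target_ids=np.arange(n),
            values=vals * NM_PER_UM,
            metric="real",
        )
    raise ValueError(f"unknown distance mode {mode!r}")
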