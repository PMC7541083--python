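"""Volumetric calcium-imaging quantification on a backbone segment map.

The mushroom-body volume (a 3D mask) is partitioned into Voronoi cells
around evenly spaced backbone nodes; fluorescence is averaged per cell and
frame, background-subtracted, and expressed as dF/F against the mean
pre-stimulus baseline.  Noisy nodes are masked by a channel-specific
threshold on the pre-stimulus dF/F standard deviation, and drug effects are
summarized as the change in windowed response normalized by the peak of the
drug-free response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentMap",
    "DFFProfile",
    "assign_voxels",
    "compute_dff",
    "smooth_and_interpolate",
    "exclude_noisy_nodes",
    "normalized_inhibitory_effect",
    "align_recordings",
    "NOISE_SD_THRESHOLD",
]

#: pre-stimulus dF/F standard-deviation exclusion thresholds per channel
NOISE_SD_THRESHOLD = {"green": 1.0, "red": 0.7}


@dataclass
class SegmentMap:
    """Voronoi assignment of in-mask voxels to backbone nodes.

    ``labels`` is a 3D int array: node index for in-mask voxels, -1 outside.
    """

    labels: np.ndarray
    node_positions_um: np.ndarray
    voxel_size_um: tuple
    voxel_counts: np.ndarray = field(init=False)

    def __post_init__(self):
        n = len(self.node_positions_um)
        inmask = self.labels[self.labels >= 0]
        self.voxel_counts = np.bincount(inmask, minlength=n)

    @property
    def n_nodes(self):
        return len(self.node_positions_um)


def assign_voxels(mask, node_positions_um, voxel_size_um=(1.0, 1.0, 1.0)) -> SegmentMap:
    """Nearest-node (Voronoi) labeling of every in-mask voxel.

    Physical coordinates are voxel centers (index * voxel size), honoring
    anisotropic voxel dimensions; exact distance ties go to the lower node
    index.  ``mask`` is a 3D boolean array in (z, y, x) order and node
    positions are (z, y, x) um.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        raise ValueError("empty mask")
    nodes = np.atleast_2d(np.asarray(node_positions_um, dtype=float))
    idx = np.argwhere(mask).astype(float)
    coords = idx * np.asarray(voxel_size_um, dtype=float)
    labels = np.full(mask.shape, -1, dtype=np.int32)
    # chunked brute-force nearest node; argmin takes the first (lowest) index
    best = np.empty(len(coords), dtype=np.int32)
    chunk = max(1, int(5e6 / max(len(nodes), 1)))
    for s in range(0, len(coords), chunk):
        d2 = ((coords[s : s + chunk, None, :] - nodes[None, :, :]) ** 2).sum(axis=2)
        best[s : s + chunk] = np.argmin(d2, axis=1)
    labels[mask] = best
    return SegmentMap(labels=labels, node_positions_um=nodes, voxel_size_um=tuple(voxel_size_um))


@dataclass
class DFFProfile:
    """Per-node dF/F time series.

    ``values`` is (T, n_nodes); excluded nodes are NaN columns.  ``f0`` and
    ``background`` record the baseline bookkeeping; ``frame_interval_s`` the
    sampling period.
    """

    values: np.ndarray
    channel: str
    frame_interval_s: float
    f0: np.ndarray | None = None
    background: float = 0.0
    smoothing: str = "none"
    excluded: np.ndarray | None = None

    @property
    def n_nodes(self):
        return self.values.shape[1]

    def time_axis(self):
        return np.arange(self.values.shape[0]) * self.frame_interval_s


def compute_dff(
    movie, seg: SegmentMap, prestim_frames, background=0.0,
    channel="green", frame_interval_s=1.0,
) -> DFFProfile:
    """Per-node dF/F from a (T, Z, Y, X) movie.

    Fluorescence is averaged over each node's Voronoi voxels per frame; the
    scalar (or ROI-mean) ``background`` is subtracted, the baseline F0 is
    the mean over ``prestim_frames`` (a slice or index array), and
    dF/F = (F - F0) / (F0 - bg).  Nodes where F0 - bg <= 0 become NaN.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 4:
        raise ValueError("movie must be (T, Z, Y, X)")
    labels = seg.labels
    if movie.shape[1:] != labels.shape:
        raise ValueError("movie frames and segment map differ in shape")
    frames = np.arange(movie.shape[0])[prestim_frames]
    if len(frames) == 0:
        raise ValueError("empty pre-stimulus window")

    flat = labels.ravel()
    inmask = flat >= 0
    lab = flat[inmask]
    n = seg.n_nodes
    counts = np.maximum(seg.voxel_counts, 1)
    f = np.empty((movie.shape[0], n))
    for t in range(movie.shape[0]):
        f[t] = np.bincount(lab, weights=movie[t].ravel()[inmask], minlength=n) / counts
    f0 = f[frames].mean(axis=0)
    denom = f0 - background
    bad = denom <= 0
    if bad.any():
        logger.warning("%d nodes with F0 - background <= 0 set to NaN", int(bad.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        dff = (f - f0[None, :]) / denom[None, :]
    dff[:, bad] = np.nan
    empty = seg.voxel_counts == 0
    dff[:, empty] = np.nan
    return DFFProfile(
        values=dff,
        channel=channel,
        frame_interval_s=frame_interval_s,
        f0=f0,
        background=float(background),
        excluded=bad | empty,
    )


def _boxcar(values, width):
    if width <= 1:
        return values.copy()
    kernel = np.ones(width) / width
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        if np.isnan(col).all():
            out[:, j] = np.nan
        else:
            out[:, j] = np.convolve(col, kernel, mode="same")
    return out


def smooth_and_interpolate(profile: DFFProfile, mode="none", frame_time_out=None) -> DFFProfile:
    """Boxcar-smooth traces and/or resample to a common frame time.

    ``mode`` is ``"trace_boxcar_5frames"``, ``"trace_boxcar_1s"`` (width =
    round(1 s / frame interval)) or ``"none"``.  Smoothing is for displaying
    traces and extracting peaks — responses averaged over stimulus windows
    are always taken from the unsmoothed profile.  ``frame_time_out`` (s)
    triggers linear interpolation onto a uniform grid (0.2 s when comparing
    time courses across recordings).
    """
    if profile.frame_interval_s is None or profile.frame_interval_s <= 0:
        raise ValueError("frame interval must be known and positive")
    if mode == "none":
        values = profile.values.copy()
    elif mode == "trace_boxcar_5frames":
        values = _boxcar(profile.values, 5)
    elif mode == "trace_boxcar_1s":
        width = max(1, round(1.0 / profile.frame_interval_s))
        values = _boxcar(profile.values, width)
    else:
        raise ValueError(f"unknown smoothing mode {mode!r}")
    interval = profile.frame_interval_s
    if frame_time_out is not None and frame_time_out != interval:
        t_in = profile.time_axis()
        t_out = np.arange(0.0, t_in[-1] + 1e-12, frame_time_out)
        resampled = np.empty((len(t_out), values.shape[1]))
        for j in range(values.shape[1]):
            col = values[:, j]
            resampled[:, j] = (
                np.nan if np.isnan(col).all() else np.interp(t_out, t_in, col)
            )
        values = resampled
        interval = frame_time_out
    return replace(profile, values=values, frame_interval_s=interval, smoothing=mode)


def exclude_noisy_nodes(profile: DFFProfile, prestim_frames, threshold=None) -> DFFProfile:
    """Mask nodes whose pre-stimulus dF/F standard deviation is too high.

    High baseline noise indicates poor signal in a segment.  The default
    threshold is per channel: 1.0 (green) or 0.7 (red); a node is excluded
    when its SD is strictly greater.
    """
    if threshold is None:
        threshold = NOISE_SD_THRESHOLD[profile.channel]
    sd = np.nanstd(profile.values[prestim_frames], axis=0, ddof=0)
    with np.errstate(invalid="ignore"):
        noisy = sd > threshold
    values = profile.values.copy()
    values[:, noisy] = np.nan
    excluded = noisy if profile.excluded is None else (profile.excluded | noisy)
    logger.info("excluded %d/%d noisy nodes (%s > %.2f)",
                int(noisy.sum()), profile.n_nodes, profile.channel, threshold)
    return replace(profile, values=values, excluded=excluded)


def normalized_inhibitory_effect(
    odor_only: DFFProfile, odor_plus_drug: DFFProfile, window_frames,
    peak_smoothing="trace_boxcar_5frames",
):
    """Per-node normalized effect of a drug on the odor response.

    (window-mean dF/F with drug - window-mean without) / (peak dF/F
    without).  Window means use the unsmoothed profiles; the peak comes from
    the smoothed trace.  Normalizing by the peak rather than the window mean
    is robust when the odor response is small.  Nodes with peak <= 0 are NaN.
    """
    if odor_only.values.shape[1] != odor_plus_drug.values.shape[1]:
        raise ValueError("profiles are on different segment maps")
    mean_odor = np.nanmean(odor_only.values[window_frames], axis=0)
    mean_drug = np.nanmean(odor_plus_drug.values[window_frames], axis=0)
    smoothed = smooth_and_interpolate(odor_only, mode=peak_smoothing)
    peak = np.nanmax(smoothed.values, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        effect = (mean_drug - mean_odor) / peak
    bad = ~(peak > 0)
    if bad.any():
        logger.warning("%d nodes with non-positive odor peak set to NaN", int(bad.sum()))
    effect[bad] = np.nan
    return effect


def align_recordings(reference_images, max_shift=10):
    """Integer 3D offsets aligning each recording to the first.

    Offsets maximize the normalized cross-correlation between each
    recording's time-averaged reference volume and the first one, over an
    exhaustive (FFT-evaluated, circular) search within ``max_shift`` voxels
    per axis.  Returns one (dz, dy, dx) tuple per recording; applying
    ``np.roll(image, offset)`` aligns it to the reference.
    """
    refs = [np.asarray(r, dtype=float) for r in reference_images]
    base = refs[0] - refs[0].mean()
    if np.allclose(base, 0):
        raise ValueError("flat (degenerate) reference image")
    shape = base.shape
    fbase = np.fft.fftn(base)
    offsets = []
    axes_freq = [np.fft.fftfreq(s, 1.0 / s).astype(int) for s in shape]
    within = np.ix_(*[np.abs(f) <= max_shift for f in axes_freq])
    for img in refs:
        if img.shape != shape:
            raise ValueError("recordings are on different voxel grids")
        a = img - img.mean()
        if np.allclose(a, 0):
            raise ValueError("flat (degenerate) recording image")
        corr = np.fft.ifftn(fbase * np.conj(np.fft.fftn(a))).real
        sub = corr[within]
        flat = int(np.argmax(sub))
        loc = np.unravel_index(flat, sub.shape)
        offsets.append(tuple(int(axes_freq[ax][np.abs(axes_freq[ax]) <= max_shift][i])
                             for ax, i in enumerate(loc)))
    return offsets
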