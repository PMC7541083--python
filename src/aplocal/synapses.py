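"""Synapse tables and mapping of synapses onto a neurite skeleton.

Synapses come in two directions relative to the inhibitory interneuron (APL):
``KC_to_APL`` (a Kenyon cell's output onto APL) and ``APL_to_KC`` (APL's
output onto a Kenyon cell).  Each record is mapped to the nearest point on
the skeleton — the perpendicular foot on an edge, clamped to the segment —
so along-skeleton distances between synapses respect sub-edge offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "KC_TO_APL",
    "APL_TO_KC",
    "SynapseRecord",
    "MappedSynapse",
    "read_synapse_table",
    "write_synapse_table",
    "map_synapses",
]

KC_TO_APL = "KC_to_APL"
APL_TO_KC = "APL_to_KC"
_DIRECTIONS = (KC_TO_APL, APL_TO_KC)


@dataclass(frozen=True)
class SynapseRecord:
    synapse_id: int
    direction: str
    kc_id: str
    position: tuple  # (x, y, z) in nm
    region_label: str = ""
    confidence: float = 1.0

    def __post_init__(self):
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class MappedSynapse:
    """A synapse assigned to a location on the skeleton.

    ``edge_index`` indexes ``skel.edges``; ``offset_nm`` is the arc position
    measured from the edge's first node; ``mapping_distance`` is the Euclidean
    residual between the annotated position and the mapped point.
    """

    synapse_id: int
    direction: str
    kc_id: str
    position: tuple
    region_label: str
    confidence: float
    edge_index: int
    offset_nm: float
    mapping_distance: float


def read_synapse_table(path, unit_scale=1.0):
    """Read a synapse CSV with columns
    synapse_id, direction, kc_id, x, y, z, region, confidence.

    Rows with missing coordinates are rejected with a warning; an unknown
    direction token raises.  Coordinates are multiplied by ``unit_scale``
    (nm per coordinate unit).
    """
    df = pd.read_csv(path, dtype={"kc_id": str, "region": str})
    required = {"synapse_id", "direction", "kc_id", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"synapse table missing columns {sorted(missing)}")
    bad_dir = set(df["direction"]) - set(_DIRECTIONS)
    if bad_dir:
        raise ValueError(f"unknown direction token(s) {sorted(bad_dir)}")
    n_bad = int(df[["x", "y", "z"]].isna().any(axis=1).sum())
    if n_bad:
        logger.warning("rejecting %d rows with missing coordinates", n_bad)
        df = df.dropna(subset=["x", "y", "z"])
    records = [
        SynapseRecord(
            synapse_id=int(r.synapse_id),
            direction=str(r.direction),
            kc_id=str(r.kc_id),
            position=(r.x * unit_scale, r.y * unit_scale, r.z * unit_scale),
            region_label=str(getattr(r, "region", "") or ""),
            confidence=float(getattr(r, "confidence", 1.0)),
        )
        for r in df.itertuples(index=False)
    ]
    counts = pd.Series([r.direction for r in records]).value_counts().to_dict()
    logger.info("read %d synapses (%s)", len(records), counts)
    return records


def write_synapse_table(records, path, unit_scale=1.0):
    rows = [
        {
            "synapse_id": r.synapse_id,
            "direction": r.direction,
            "kc_id": r.kc_id,
            "x": r.position[0] / unit_scale,
            "y": r.position[1] / unit_scale,
            "z": r.position[2] / unit_scale,
            "region": r.region_label,
            "confidence": r.confidence,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=[
        "synapse_id", "direction", "kc_id", "x", "y", "z", "region", "confidence",
    ]).to_csv(path, index=False)


def _nearest_on_edges(skel, points):
    """Nearest point on any skeleton edge for each query point.

    Returns (edge_index, offset_nm, residual) arrays.  Ties in residual are
    broken toward the lowest edge index, then the smallest offset (argmin on
    a row-major scan guarantees the first minimum wins).
    """
    a = skel.positions[skel.edges[:, 0]]  # (E, 3)
    b = skel.positions[skel.edges[:, 1]]
    ab = b - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    ab2 = np.where(ab2 > 0, ab2, 1.0)

    edge_idx = np.empty(len(points), dtype=np.int64)
    offs = np.empty(len(points), dtype=float)
    resid = np.empty(len(points), dtype=float)
    chunk = max(1, int(2e6 / max(len(a), 1)))
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk]  # (P, 3)
        ap = p[:, None, :] - a[None, :, :]  # (P, E, 3)
        t = np.clip(np.einsum("pej,ej->pe", ap, ab) / ab2, 0.0, 1.0)
        foot = a[None, :, :] + t[..., None] * ab[None, :, :]
        d2 = np.einsum("pej,pej->pe", p[:, None, :] - foot, p[:, None, :] - foot)
        # exact-tie rule: lowest edge index wins; np.argmin returns the first
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(p))
        edge_idx[s : s + chunk] = best
        offs[s : s + chunk] = t[rows, best] * np.sqrt(ab2[best])
        resid[s : s + chunk] = np.sqrt(d2[rows, best])
    return edge_idx, offs, resid


def map_synapses(skel, records, warn_distance_nm=2000.0):
    """Map each :class:`SynapseRecord` to its nearest skeleton location.

    Deterministic given the skeleton and records.  Residuals above
    ``warn_distance_nm`` are logged.  Returns a list of
    :class:`MappedSynapse` in input order.
    """
    if not records:
        return []
    pts = np.array([r.position for r in records], dtype=float)
    edge_idx, offs, resid = _nearest_on_edges(skel, pts)
    n_far = int(np.sum(resid > warn_distance_nm))
    if n_far:
        logger.warning(
            "%d synapses mapped with residual > %g nm (max %.1f nm)",
            n_far, warn_distance_nm, resid.max(),
        )
    mapped = [
        MappedSynapse(
            synapse_id=r.synapse_id,
            direction=r.direction,
            kc_id=r.kc_id,
            position=r.position,
            region_label=r.region_label,
            confidence=r.confidence,
            edge_index=int(e),
            offset_nm=float(o),
            mapping_distance=float(d),
        )
        for r, e, o, d in zip(records, edge_idx, offs, resid)
    ]
    for direction in _DIRECTIONS:
        locs = {(m.edge_index, round(m.offset_nm, 3)) for m in mapped if m.direction == direction}
        n = sum(m.direction == direction for m in mapped)
        logger.info("%s: %d synapses at %d unique skeleton locations", direction, n, len(locs))
    return mapped
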