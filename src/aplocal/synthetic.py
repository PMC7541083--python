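"""Synthetic inputs emulating the mushroom-body data the analyses consume.

Everything here is seeded and deterministic.  The generators emulate:

* a Y-shaped "mushroom-body" skeleton — parallel neurites with heterogeneous
  radii running along three branches (vertical lobe, horizontal lobe,
  peduncle/calyx) that meet at a junction, plus an excluded soma neurite;
* per-Kenyon-cell spatially clustered reciprocal synapses (~50 per KC per
  direction), whose clustering is what produces a self-inhibition surplus;
* exponential dye/stimulus profiles with additive noise;
* 4D two-channel-style movies with known per-segment dF/F and background;
* TPM expression tables with known focal-dominant genes.

Defaults follow the biology being emulated: branch lengths giving a
~260 um vertical-path and ~250 um horizontal-path distance-from-calyx axis,
neurite diameters averaging ~0.5 um (range up to ~3 um), and ~50 synapses
per KC per direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .backbone import CALYX_BRANCH, Backbone, StandardBackbone, build_backbone
from .skeleton import NeuriteSkeleton
from .synapses import APL_TO_KC, KC_TO_APL, SynapseRecord
from .units import NM_PER_UM
from .volumetric import SegmentMap

__all__ = [
    "ToyMushroomBodySpec",
    "SyntheticKCPopulation",
    "ToySkeleton",
    "make_toy_skeleton",
    "make_synthetic_synapses",
    "make_dye_profile",
    "make_synthetic_movie",
    "make_expression_table",
]


@dataclass(frozen=True)
class ToyMushroomBodySpec:
    """Geometry of the toy mushroom body (lengths in um).

    The distance-from-calyx coordinate spans calyx branch + lobe, so the
    defaults put the vertical-lobe tip at 160 + 100 = 260 um from the
    dorsal calyx.
    """

    calyx_length_um: float = 160.0
    vertical_length_um: float = 100.0
    horizontal_length_um: float = 90.0
    soma_neurite_um: float = 20.0  # outside the mushroom body; 0 disables
    neurites_per_branch: int = 2
    node_spacing_um: float = 5.0
    mean_diameter_um: float = 0.5
    max_diameter_um: float = 3.0
    jitter_um: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("calyx_length_um", "vertical_length_um", "horizontal_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ToySkeleton:
    """A generated skeleton plus its backbone and bookkeeping."""

    skeleton: NeuriteSkeleton
    backbone: Backbone
    key_points: dict
    edge_branch: np.ndarray  # branch label per skeleton edge
    excluded_edges: np.ndarray  # edge indices outside the mushroom body


_BRANCH_AXES = {
    CALYX_BRANCH: np.array([0.0, 1.0, 0.0]),
    "vertical": np.array([0.0, 0.0, 1.0]),
    "horizontal": np.array([1.0, 0.0, 0.0]),
}


def make_toy_skeleton(spec: ToyMushroomBodySpec = ToyMushroomBodySpec()) -> ToySkeleton:
    """Build the Y-shaped toy skeleton (geometry in nm, backbone in um)."""
    rng = np.random.default_rng(spec.seed)
    lengths = {
        CALYX_BRANCH: spec.calyx_length_um,
        "vertical": spec.vertical_length_um,
        "horizontal": spec.horizontal_length_um,
    }
    node_pos = [np.zeros(3)]  # junction (um)
    node_radius = [spec.mean_diameter_um / 2]
    edges = []
    edge_branch = []
    excluded = []

    def draw_radii(k):
        # lognormal diameters around the mean, clipped to the stated range
        diam = rng.lognormal(np.log(spec.mean_diameter_um), 0.4, size=k)
        diam = np.clip(diam, 0.1, spec.max_diameter_um)
        return diam / 2

    def add_chain(axis, length, branch, origin=np.zeros(3), excluded_chain=False):
        n_seg = max(1, int(round(length / spec.node_spacing_um)))
        step = length / n_seg
        perp = np.eye(3)[np.argsort(np.abs(axis))[:2]]  # two axes orthogonal to growth
        prev = 0  # junction index
        pos = origin.astype(float).copy()
        radii = draw_radii(n_seg)
        for i in range(n_seg):
            pos = pos + axis * step
            jitter = (rng.uniform(-1, 1, 2) * spec.jitter_um) @ perp
            node_pos.append(pos + jitter)
            node_radius.append(radii[i])
            cur = len(node_pos) - 1
            edges.append((prev, cur))
            edge_branch.append(branch)
            if excluded_chain:
                excluded.append(len(edges) - 1)
            prev = cur

    for branch, axis in _BRANCH_AXES.items():
        for _ in range(spec.neurites_per_branch):
            add_chain(axis, lengths[branch], branch)
    if spec.soma_neurite_um > 0:
        add_chain(np.array([0.0, -1.0, 0.0]), spec.soma_neurite_um, "soma",
                  excluded_chain=True)

    positions_nm = np.array(node_pos) * NM_PER_UM
    radii_nm = np.array(node_radius) * NM_PER_UM
    skel = NeuriteSkeleton(
        node_ids=np.arange(1, len(node_pos) + 1),
        positions=positions_nm,
        radii=radii_nm,
        edges=np.array(edges),
        unit_scale=1.0,
    )
    key_points = {
        branch: [np.zeros(3), _BRANCH_AXES[branch] * lengths[branch]]
        for branch in _BRANCH_AXES
    }
    bb = build_backbone(key_points)
    return ToySkeleton(
        skeleton=skel,
        backbone=bb,
        key_points=key_points,
        edge_branch=np.array(edge_branch),
        excluded_edges=np.array(excluded, dtype=int),
    )


@dataclass(frozen=True)
class SyntheticKCPopulation:
    """Kenyon-cell population whose synapses cluster along the skeleton.

    Each KC gets a random anchor point; its synapses are placed at skeleton
    nodes drawn with Gaussian weight exp(-d^2 / 2 sigma^2) in along-skeleton
    distance d from the anchor.  Small sigma co-locates a KC's input and
    output synapses (strong self-inhibition); sigma much larger than the
    skeleton mixes everything (ratio -> 1).
    """

    n_kc: int = 20
    synapses_in: int = 50   # APL -> KC
    synapses_out: int = 50  # KC -> APL
    cluster_sigma_um: float = 15.0
    subtype_proportions: dict = field(
        default_factory=lambda: {"ab": 0.45, "apbp": 0.15, "g": 0.40}
    )
    seed: int = 0

    def __post_init__(self):
        if self.cluster_sigma_um <= 0:
            raise ValueError("cluster sigma must be positive")
        if min(self.synapses_in, self.synapses_out) < 1:
            raise ValueError("each KC needs at least one synapse per direction")


def _node_distance_matrix_rows(skel, sources):
    n = skel.n_nodes
    adj = coo_matrix(
        (skel.edge_lengths, (skel.edges[:, 0], skel.edges[:, 1])), shape=(n, n)
    ).tocsr()
    return dijkstra(adj, directed=False, indices=sources)


def make_synthetic_synapses(toy: ToySkeleton, pop: SyntheticKCPopulation = SyntheticKCPopulation()):
    """Clustered reciprocal synapses for a synthetic KC population.

    Returns ``(records, metadata, truth)``: synapse records (positions in
    nm, jittered slightly off the anchoring skeleton nodes), a kc_id ->
    subtype mapping, and ground truth (per-KC anchor node and the node each
    synapse was drawn at).
    """
    rng = np.random.default_rng(pop.seed)
    skel = toy.skeleton
    # keep anchors off the excluded soma branch
    soma_nodes = set(skel.edges[toy.excluded_edges].ravel().tolist()) - {0}
    candidates = np.array([i for i in range(skel.n_nodes) if i not in soma_nodes])
    anchors = rng.choice(candidates, size=pop.n_kc, replace=True)
    d_anchor = _node_distance_matrix_rows(skel, anchors)  # (n_kc, n_nodes)

    labels = list(pop.subtype_proportions)
    probs = np.array([pop.subtype_proportions[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    subtype_of = {}
    records, truth_rows = [], []
    sid = 1
    sigma_nm = pop.cluster_sigma_um * NM_PER_UM
    for k in range(pop.n_kc):
        kc = f"KC{k:03d}"
        subtype_of[kc] = labels[int(rng.choice(len(labels), p=probs))]
        w = np.exp(-0.5 * (d_anchor[k] / sigma_nm) ** 2)
        w[list(soma_nodes)] = 0.0
        w = w / w.sum()
        for direction, count in ((APL_TO_KC, pop.synapses_in), (KC_TO_APL, pop.synapses_out)):
            nodes = rng.choice(skel.n_nodes, size=count, p=w)
            jitter = rng.normal(0.0, 30.0, size=(count, 3))  # nm, << node spacing
            for node, dj in zip(nodes, jitter):
                pos = skel.positions[node] + dj
                records.append(
                    SynapseRecord(
                        synapse_id=sid,
                        direction=direction,
                        kc_id=kc,
                        position=tuple(pos),
                        region_label="",
                        confidence=float(rng.uniform(0.7, 1.0)),
                    )
                )
                truth_rows.append(
                    {"synapse_id": sid, "kc_id": kc, "direction": direction,
                     "node": int(node), "anchor_node": int(anchors[k])}
                )
                sid += 1
    truth = {
        "anchors": {f"KC{k:03d}": int(a) for k, a in enumerate(anchors)},
        "synapses": pd.DataFrame(truth_rows),
    }
    return records, subtype_of, truth


def make_dye_profile(
    standard: StandardBackbone, x0_um, amplitude=1.0, decay_um=21.6,
    noise_sd=0.0, seed=0, lobes=("vertical", "horizontal"),
):
    """Per-segment dye amplitudes A exp(-|x - x0| / ell) + noise.

    One row per (lobe path, segment): segments on the shared calyx branch
    appear once per lobe path, so downstream per-branch fits can be averaged
    where the paths merge.  A decay length of 21.6 um halves the signal
    every ~15 um, within the observed 10-25 um half-decay range of ejected
    dye.
    """
    if decay_um <= 0:
        raise ValueError("decay length must be positive")
    rng = np.random.default_rng(seed)
    table = standard.node_table()
    rows = []
    for lobe in lobes:
        path = table[table["branch"].isin([standard.calyx_branch, lobe])]
        for r in path.itertuples(index=False):
            x = r.distance_from_calyx_um
            value = amplitude * np.exp(-abs(x - x0_um) / decay_um)
            rows.append(
                {"segment": int(r.node_id), "branch": lobe,
                 "distance_from_calyx_um": x,
                 "value": value + rng.normal(0.0, noise_sd)}
            )
    return pd.DataFrame(rows)


def make_synthetic_movie(
    seg: SegmentMap, dff_truth, f0=100.0, background=50.0, noise_sd=0.0,
    shift=(0, 0, 0), seed=0,
):
    """Movie whose per-node dF/F is known exactly.

    ``dff_truth`` is (T, n_nodes); voxel fluorescence inside node i's
    Voronoi cell at frame t is background + F0 * (1 + dff[t, i]) plus
    Gaussian noise, and ``background`` alone outside the mask.  The whole
    movie is then circularly shifted by ``shift`` voxels (to exercise
    alignment recovery).  Returns (movie (T,Z,Y,X), truth dict).
    """
    dff_truth = np.asarray(dff_truth, dtype=float)
    f0 = np.broadcast_to(np.asarray(f0, dtype=float), (seg.n_nodes,))
    if np.any(f0 < 0):
        raise ValueError("negative F0")
    rng = np.random.default_rng(seed)
    T = dff_truth.shape[0]
    labels = seg.labels
    movie = np.empty((T,) + labels.shape)
    inmask = labels >= 0
    lab = labels[inmask]
    for t in range(T):
        frame = np.full(labels.shape, float(background))
        frame[inmask] = background + f0[lab] * (1.0 + dff_truth[t, lab])
        movie[t] = frame
    if noise_sd > 0:
        movie = movie + rng.normal(0.0, noise_sd, size=movie.shape)
    if any(shift):
        movie = np.roll(movie, shift, axis=(1, 2, 3))
    return movie, {
        "dff": dff_truth, "f0": np.asarray(f0), "background": float(background),
        "shift": tuple(shift), "noise_sd": float(noise_sd),
    }


def make_expression_table(
    n_genes=200, cell_types=("APL", "KCab", "KCg", "MBON1", "PAM1"),
    n_replicates=3, n_focal_high=5, n_focal_low=5, focal="APL",
    transcripts_per_gene=2, seed=0,
):
    """Transcript x (cell type, replicate) TPM table with known extremes.

    The first ``n_focal_high`` genes are boosted ~30x in the focal type, the
    next ``n_focal_low`` suppressed ~30x; the rest vary without systematic
    focal bias.  Returns (table, gene_of, truth) where truth lists the
    constructed high/low gene sets.
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene{g:04d}" for g in range(n_genes)]
    tids, gene_of = [], {}
    for g in genes:
        for v in range(transcripts_per_gene):
            tid = f"{g}.t{v}"
            tids.append(tid)
            gene_of[tid] = g
    cols = pd.MultiIndex.from_product(
        [list(cell_types), [f"rep{r}" for r in range(n_replicates)]]
    )
    base = rng.lognormal(1.0, 1.0, size=(len(tids), 1))
    vals = base * rng.lognormal(0.0, 0.3, size=(len(tids), len(cols)))
    focal_cols = [j for j, c in enumerate(cols) if c[0] == focal]
    high = genes[:n_focal_high]
    low = genes[n_focal_high : n_focal_high + n_focal_low]
    for i, tid in enumerate(tids):
        if gene_of[tid] in high:
            vals[i, focal_cols] *= 30.0
        elif gene_of[tid] in low:
            vals[i, focal_cols] /= 30.0
    # sprinkle true zeros so the log floor is exercised
    zero_rows = rng.choice(len(tids), size=max(1, len(tids) // 50), replace=False)
    vals[zero_rows[:, None], rng.choice(len(cols), size=(len(zero_rows), 1))] = 0.0
    table = pd.DataFrame(vals, index=pd.Index(tids, name="transcript"), columns=cols)
    return table, gene_of, {"focal_high": high, "focal_low": low}
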