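"""The pairwise lateral-inhibition metric s(k1, k2) and its summaries.

The strength with which Kenyon cell KC1 inhibits KC2 through the APL
interneuron is modelled as a weighted count over every pair of a KC1->APL
synapse and an APL->KC2 synapse:

    s(k1, k2) = sum_i sum_j exp(-d(x_i, y_j) / space_constant)

where d is the distance between the two synapses along APL's neurite
skeleton — either real distance with space constant lambda, or electrotonic
distance (length / sqrt(radius)) with space constant k.  A KC inhibiting
itself more strongly than it inhibits the average other KC shows up as a
self/other ratio above 1; shuffling which KC each synapse belongs to
destroys any spatial clustering and drives the ratio back to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .synapses import APL_TO_KC, KC_TO_APL
from .units import M12_PER_NM12, M_PER_NM, M_PER_UM, NM_PER_PIXEL

__all__ = [
    "SpaceConstantSpec",
    "InhibitionMatrix",
    "ImbalanceSummary",
    "pair_weight",
    "compute_inhibition_matrix",
    "self_other_ratio",
    "filter_synapses",
    "calyx_filter",
    "shuffle_synapse_identities",
    "order_kcs_for_display",
]

#: lambda/k conversion ratio of the full APL skeleton (m^1/2):
#: total real length / total electrotonic length = 0.08018 m / 179 m^1/2.
APL_CONVERSION_RATIO_M12 = 0.08018 / 179.0


@dataclass(frozen=True)
class SpaceConstantSpec:
    """Space constant in real space (lambda, um) or electrotonic space (k).

    ``lambda_um`` may be ``inf``, which forces every pair weight to 1.  When
    both ``lambda_um`` and ``k_m12`` are given they must be consistent with
    ``conversion_ratio_m12`` (lambda = k * ratio); giving either one fills in
    the other.
    """

    mode: str = "real"  # "real" or "electrotonic"
    lambda_um: float | None = None
    k_m12: float | None = None
    conversion_ratio_m12: float = APL_CONVERSION_RATIO_M12

    def __post_init__(self):
        if self.mode not in ("real", "electrotonic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        lam, k, ratio = self.lambda_um, self.k_m12, self.conversion_ratio_m12
        if lam is None and k is None:
            raise ValueError("one of lambda_um or k_m12 is required")
        if lam is not None and lam <= 0:
            raise ValueError("lambda must be positive")
        if k is not None and k <= 0:
            raise ValueError("k must be positive")
        if lam is None:
            lam = math.inf if math.isinf(k) else k * ratio / M_PER_UM
            object.__setattr__(self, "lambda_um", lam)
        elif k is None:
            k = math.inf if math.isinf(lam) else lam * M_PER_UM / ratio
            object.__setattr__(self, "k_m12", k)
        else:
            if not (math.isinf(lam) and math.isinf(k)) and not math.isclose(
                lam * M_PER_UM, k * ratio, rel_tol=1e-6
            ):
                raise ValueError("lambda_um and k_m12 inconsistent with conversion ratio")

    @property
    def is_infinite(self):
        return math.isinf(self.lambda_um)


def pair_weight(distance, spec: SpaceConstantSpec):
    """exp(-d / space constant) for distances in the spec's native metric.

    ``distance`` is in nm for mode ``"real"`` and nm^(1/2) for mode
    ``"electrotonic"`` (the units produced by the distance engine).
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if spec.is_infinite:
        out = np.ones_like(d)
    elif spec.mode == "real":
        out = np.exp(-d * M_PER_NM / (spec.lambda_um * M_PER_UM))
    else:
        out = np.exp(-d * M12_PER_NM12 / spec.k_m12)
    return out if out.ndim else float(out)


@dataclass
class InhibitionMatrix:
    """s(k1, k2) for every ordered KC pair.

    Rows index the presynaptic (inhibiting) KC1, columns the postsynaptic
    (inhibited) KC2.  Not symmetric in general: KC->APL and APL->KC synapse
    sets differ.  ``n_out``/``n_in`` are per-KC synapse counts entering the
    double sum.
    """

    kc_ids: np.ndarray
    values: np.ndarray
    subtypes: np.ndarray | None = None
    n_out: np.ndarray | None = None
    n_in: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def as_frame(self):
        return pd.DataFrame(self.values, index=self.kc_ids, columns=self.kc_ids)


def compute_inhibition_matrix(
    dist, source_kc_ids, target_kc_ids, spec, kc_ids=None, subtypes=None
) -> InhibitionMatrix:
    """Aggregate pair weights into s(k1, k2).

    Parameters
    ----------
    dist : DistanceMatrix
        KC->APL synapses (sources, rows) x APL->KC synapses (targets,
        columns), in the metric matching ``spec.mode``.
    source_kc_ids, target_kc_ids : sequences of str
        Owning KC of each source / target synapse.
    kc_ids : sequence of str, optional
        KC universe and ordering; defaults to the sorted union.  Any synapse
        whose KC is absent from this list raises.
    subtypes : mapping kc_id -> subtype label, optional
    """
    source_kc_ids = np.asarray(source_kc_ids, dtype=object)
    target_kc_ids = np.asarray(target_kc_ids, dtype=object)
    if kc_ids is None:
        kc_ids = sorted(set(source_kc_ids) | set(target_kc_ids))
    kc_ids = np.asarray(list(kc_ids), dtype=object)
    index = {k: i for i, k in enumerate(kc_ids)}
    missing = (set(source_kc_ids) | set(target_kc_ids)) - set(index)
    if missing:
        raise KeyError(f"synapse kc_id(s) absent from metadata: {sorted(missing)[:5]}")

    w = pair_weight(dist.values, spec)
    src_idx = np.array([index[k] for k in source_kc_ids])
    tgt_idx = np.array([index[k] for k in target_kc_ids])
    n_kc = len(kc_ids)
    # s = A^T W B with A, B one-hot KC indicators; bincount-based contraction
    tmp = np.zeros((n_kc, w.shape[1]))
    np.add.at(tmp, src_idx, w)
    s = np.zeros((n_kc, n_kc))
    np.add.at(s.T, tgt_idx, tmp.T)

    sub = None
    if subtypes is not None:
        sub = np.array([subtypes[k] for k in kc_ids], dtype=object)
    return InhibitionMatrix(
        kc_ids=kc_ids,
        values=s,
        subtypes=sub,
        n_out=np.bincount(src_idx, minlength=n_kc),
        n_in=np.bincount(tgt_idx, minlength=n_kc),
        provenance={"spec": spec, "metric": dist.metric},
    )


@dataclass
class ImbalanceSummary:
    """Per-KC self- vs. mean-other-inhibition ratios and their quartiles."""

    kc_ids: np.ndarray
    ratios: np.ndarray
    grouping: str
    excluded: list
    median: float
    q25: float
    q75: float


def self_other_ratio(s: InhibitionMatrix, grouping="all") -> ImbalanceSummary:
    """Ratio of self-inhibition s(k1,k1) to the mean of s(k1,k2) over others.

    ``grouping="all"`` compares against every other KC; ``"same_subtype"``
    against other KCs of k1's subtype only (requires subtype labels).  The
    denominator excludes k2 = k1.  KCs lacking synapses in either direction,
    or alone in their group, are excluded and reported.
    """
    if grouping not in ("all", "same_subtype"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if grouping == "same_subtype" and s.subtypes is None:
        raise ValueError("same_subtype grouping requires subtype labels")
    n = len(s.kc_ids)
    kept_ids, ratios, excluded = [], [], []
    for i in range(n):
        if s.n_out is not None and (s.n_out[i] == 0 or s.n_in[i] == 0):
            excluded.append((s.kc_ids[i], "no synapses in one direction"))
            continue
        if grouping == "all":
            others = np.arange(n) != i
        else:
            others = (s.subtypes == s.subtypes[i]) & (np.arange(n) != i)
        if not others.any():
            excluded.append((s.kc_ids[i], "group of size 1"))
            continue
        denom = s.values[i, others].mean()
        if denom == 0:
            excluded.append((s.kc_ids[i], "zero mean inhibition of others"))
            continue
        kept_ids.append(s.kc_ids[i])
        ratios.append(s.values[i, i] / denom)
    ratios = np.array(ratios)
    q25, med, q75 = (
        np.percentile(ratios, [25, 50, 75]) if ratios.size else (np.nan,) * 3
    )
    return ImbalanceSummary(
        kc_ids=np.array(kept_ids, dtype=object),
        ratios=ratios,
        grouping=grouping,
        excluded=excluded,
        median=float(med),
        q25=float(q25),
        q75=float(q75),
    )


def calyx_filter(y_max_pixels=20000.0, excluded_region="PED(R)"):
    """Predicate selecting APL->KC synapses in the calyx.

    A synapse passes if its y coordinate is below ``y_max_pixels`` (hemibrain
    pixels, 8 nm each; 20000 px = 160 um, i.e. posterior to the peduncle) and
    its region label is not the peduncle ROI.  Accessory-calyx synapses lack
    the calyx ROI label, hence the coordinate rule rather than a region
    whitelist.
    """
    y_max_nm = y_max_pixels * NM_PER_PIXEL

    def rule(syn):
        return syn.position[1] < y_max_nm and syn.region_label != excluded_region

    rule.__name__ = f"calyx(y<{y_max_pixels}px, region!={excluded_region})"
    return rule


def filter_synapses(synapses, rule, directions=(APL_TO_KC,)):
    """Keep synapses passing ``rule``; the rule applies only to ``directions``.

    By default the restriction applies to APL->KC synapses only (the calyx
    restriction of the inhibition analysis), and KC->APL synapses pass
    unconditionally.
    """
    return [s for s in synapses if s.direction not in directions or rule(s)]


def shuffle_synapse_identities(synapses, seed, directions=(KC_TO_APL, APL_TO_KC)):
    """Permute which KC each synapse belongs to, within each direction.

    Locations are untouched and the per-direction multiset of kc_ids is
    preserved; only the assignment of identities to locations is randomized.
    Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    synapses = list(synapses)
    out = list(synapses)
    for direction in directions:
        idx = [i for i, s in enumerate(synapses) if s.direction == direction]
        labels = [synapses[i].kc_id for i in idx]
        perm = rng.permutation(len(idx))
        for j, i in enumerate(idx):
            out[i] = replace(synapses[i], kc_id=labels[perm[j]])
    return out


def order_kcs_for_display(s: InhibitionMatrix):
    """KC ordering for heat-map display: subtypes contiguous, similar rows
    adjacent within each subtype (average-linkage clustering on correlation
    distance).  Display-only; identical rows keep their input order.
    """
    if s.subtypes is None:
        raise ValueError("ordering requires subtype labels")
    order = []
    # stable grouping: subtypes in first-appearance order
    seen = {}
    for lab in s.subtypes:
        seen.setdefault(lab, len(seen))
    for lab in sorted(seen, key=seen.get):
        members = np.flatnonzero(s.subtypes == lab)
        if len(members) <= 2:
            order.extend(members.tolist())
            continue
        rows = s.values[members]
        # correlation distance is undefined for constant rows; fall back to
        # euclidean if any row is constant
        metric = "correlation" if np.all(rows.std(axis=1) > 0) else "euclidean"
        d = pdist(rows, metric=metric)
        if np.allclose(d, 0):
            order.extend(members.tolist())
            continue
        leaf_order = leaves_list(linkage(d, method="average"))
        order.extend(members[leaf_order].tolist())
    return s.kc_ids[np.array(order)]
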