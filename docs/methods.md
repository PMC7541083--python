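# Methods

This note documents the models implemented in `aplocal`, the conventions
and defaults they use, what the synthetic-data generators do and do not
emulate, and the design choices made where more than one reasonable
implementation existed.

## The passive-decay model

APL is treated as a passive cable network. Depolarization injected at one
point decays along the neurite as `exp(−d/λ)`, where `d` is the distance
measured *along the skeleton* (never through space) and λ is the space
constant. Because λ for a cylindrical cable scales with the square root of
the radius (`λ = √(r·Rm/2Ra)`), a neurite of varying caliber has no single
λ; the model therefore works in *electrotonic* length, `dₑ = ∫ dx/√r(x)`,
on which decay is `exp(−dₑ/k)` with the radius-free constant
`k = √(Rm/2Ra)` (units m^1/2).

Skeleton edges connect nodes that each carry a radius, so an edge is a
truncated cone. Its electrotonic length has the closed form
`2d(√r₂−√r₁)/(r₂−r₁)`, computed as the algebraically identical
`2d/(√r₁+√r₂)`, which is numerically stable and needs no special-casing of
the cylinder limit `d/√r`. Partial spans `[x₁,x₂]` of a cone use the same
form with the linearly interpolated end radii; both are verified against
numerical quadrature to 1e−8 relative in the tests.

The skeleton-wide ratio (total real length)/(total electrotonic length)
converts between λ and k. For the full APL skeleton this ratio is
0.08018 m / 179 m^1/2 ≈ 4.48e−4 m^1/2, kept as the package constant
`APL_CONVERSION_RATIO_M12`; toy skeletons compute their own ratio via
`skeleton_totals`. The model deliberately ignores current division at
branch points: decay depends on shortest-path distance only. This
overestimates spread past branches, so inferred localization is
conservative.

**Units.** Geometry is held in nm (hemibrain pixel = 8 nm, a named
constant); electrotonic quantities in nm^1/2, converted by the single
constant √(1e−9) m^1/2 per nm^1/2. Reported values use µm and m^1/2.

## Distances and synapse mapping

Synapses are mapped to the nearest point of any skeleton edge
(perpendicular foot clamped to the segment), not to the nearest node —
sub-edge resolution costs nothing and is strictly more faithful; exact
residual ties resolve to the lowest edge index, then the smallest offset.
Note that unique-*location* counts under sub-edge mapping can differ
slightly from node-resolution mapping.

Pairwise distances insert every mapped location as a vertex that splits its
host edge (split pieces carry partial-cone weights) and run one
multi-source Dijkstra over the augmented sparse graph. This replaces
staged nearest-neighbor constructions: it is provably exact on a tree and
is checked against an independent path-enumeration oracle on hundreds of
random trees. Inserting vertices never changes distances between
pre-existing nodes (degree-2 splits preserve path lengths).

Radii ≤ 0 in SWC input (sentinel values) are clamped to the smallest
positive radius in the file, since electrotonic length diverges at r = 0.
Skeletons must be connected trees; anything else fails loading with a
diagnostic naming the components or cycle.

## The inhibition matrix and imbalance

`s(k1,k2)` sums `exp(−d/space constant)` over every ordered pair of a
KC1→APL synapse and an APL→KC2 synapse. Each synapse *record* contributes
one term even when several records share a skeleton location (polyadic
sites); with λ = ∞ the matrix degenerates to the product of synapse counts,
a closed form used as a test. The matrix is not symmetric because the two
synapse sets differ.

The self/other imbalance for KC k1 is `s(k1,k1)` divided by the arithmetic
mean of `s(k1,k2)` over k2 ≠ k1 — the denominator excludes the diagonal,
matching the off-diagonal-average reading of the ratio; grouping can
restrict k2 to k1's subtype. KCs lacking synapses in either direction, or
alone in their group, are excluded and reported rather than dropped
silently. The shuffle null permutes the KC identity labels within each
direction independently, preserving locations and per-direction identity
multisets; on clustered synthetic data 20 shuffle seeds bring the median
ratio into 0.9–1.1.

The calyx restriction keeps APL→KC synapses with y < 20 000 px (160 µm,
posterior to the peduncle) and not labeled with the peduncle ROI — a
coordinate rule rather than a calyx-ROI whitelist because accessory-calyx
synapses lack the calyx label. It applies to the APL→KC side only.

Display ordering of KCs groups subtypes contiguously and orders within a
subtype by average-linkage clustering on correlation distance of matrix
rows. No linkage/metric is canonical here; the choice is display-only and
non-normative (identical rows keep input order).

## Spread simulation

`sample_skeleton_points` scatters points uniformly by real arc length
(edges chosen proportional to length, offsets uniform); points on edges
flagged outside the mushroom body (the soma neurite) are excluded from the
analysis but still counted. Segment activity averages, over the points in
a 10 µm backbone segment, the distance-weighted stimulus received from all
points. As printed, the pair-count form corresponds to a uniform unit
stimulus; a localized stimulus enters multiplicatively as the fitted dye
amplitude at each source point's segment (uniform stimulus recovers the
plain pair count exactly). Self-pairs are included — their O(1/N)
contribution is part of the estimator. Output profiles are normalized to
the highest responding segment, the convention used for measured profiles.

Three distance modes feed both the simulation and the inhibition matrix:
electrotonic (default), real distance with radius ignored, and 1D backbone
distance after projecting each point to the nearest backbone position.

Stimulus/dye profiles are fitted per branch path as `A·exp(−|x−x₀|/ℓ)` by
nonlinear least squares (log-linear initialization); where two branch fits
overlap on the shared peduncle/calyx stretch their predictions are
averaged. Fits with negative amplitude, non-positive ℓ, or ℓ beyond 100×
the data span (a flat profile has no finite decay length) are rejected with
diagnostics. The simulate→fit loop recovers λ ∈ {25, 50, 75} µm within a
few percent on a straight cable with ~2 500 points, the calibration the
acceptance tests assert at 10%.

**Problem sizes.** Simulations in the tests use 350 µm cables (35 × 10 µm
segments, matching the backbone scale) with 2 500 points, and 3 500/7 000
points for the Monte-Carlo stability check; these give per-segment
Monte-Carlo errors well under the asserted tolerances.

## Backbone and volumetric quantification

A backbone is one polyline per branch (vertical lobe, horizontal lobe,
peduncle/calyx), all starting at the shared junction; the 1D coordinate is
distance from the dorsal calyx (calyx-branch tip), so lobe points lie at
L_calyx + arc-from-junction. The standard backbone averages branch lengths
across recordings; each recording's nodes are placed at spacing scaled by
its branch-length ratio so node i always maps to standard distance
i × spacing. Standardizing a single backbone is the identity (scales 1) —
the operation is idempotent. Default node spacing is 20 µm; 10 µm is used
when more spatial resolution is wanted.

Voxels inside the 3D mask are assigned to the nearest backbone node
(Voronoi cells) in physical coordinates, honoring anisotropic voxel sizes;
voxel centers sit at index × voxel size, and exact ties go to the lower
node index. Per node and frame, fluorescence is the mean over the node's
voxels; ΔF/F = (F − F0)/(F0 − bg) with F0 the pre-stimulus mean and bg a
scalar or ROI-derived background (a manual choice on real data; the
synthetic generator emits the true value). Nodes with F0 − bg ≤ 0 or no
voxels are NaN.

Boxcar smoothing (5 frames, or 1 s = round(1/frame interval) frames) is
applied only for displaying traces and extracting peaks; window-averaged
responses always use unsmoothed data. Time courses are linearly
interpolated to a 0.2 s frame time when averaged across recordings. Nodes
whose pre-stimulus ΔF/F standard deviation exceeds 1.0 (green channel) or
0.7 (red) are excluded — high baseline noise means poor signal. The
normalized inhibitory effect is (windowed ΔF/F with drug − without)/(peak
ΔF/F without); the peak denominator is robust when responses are small,
where a window-mean denominator would explode. Quantification windows are
configuration inputs, not constants.

Recordings are aligned by the integer 3D translation maximizing normalized
cross-correlation of time-averaged reference volumes, searched exhaustively
(FFT-evaluated, circular) within ±10 voxels by default; no subvoxel
registration is attempted. Motion correction within a recording is out of
scope.

## Expression screen

TPM is summed across splice variants per gene, log10-taken with zeros set
to −2 (TPM 0.01, below the dataset minimum of 0.1; the floor is the named
constant `LOG10_ZERO_FLOOR`), and averaged across replicates per cell type
— the geometric mean of TPM. The screen keeps genes where the focal type's
mean is *strictly* above (or below) every other type; ties fail. The
low-expression filter works on the raw TPM scale: genes whose mean TPM
across non-focal types falls below 1 are dropped (boundary kept). The
screen uses per-type means rather than per-replicate comparisons; with few
replicates per type the strict-inequality count is somewhat sensitive to
this choice.

## Synthetic data: what it does and does not show

The toy skeleton is a Y of three straight branches (calyx/peduncle 160 µm,
vertical 100 µm, horizontal 90 µm — placing the vertical tip at 260 µm from
the calyx), a configurable number of jittered parallel neurites per branch
rooted at the junction, lognormal diameters around 0.5 µm clipped at 3 µm,
and an excluded 20 µm soma neurite. Synthetic KCs (default 20, with αβ /
α′β′ / γ-like subtype proportions 0.45/0.15/0.40) each receive an anchor
and ~50 synapses per direction drawn at skeleton nodes with Gaussian
weight exp(−d²/2σ²) in along-skeleton distance from the anchor (default
σ = 15 µm); this per-KC clustering is the minimal mechanism that produces a
self-inhibition surplus which identity shuffling destroys. Movies are
built directly from known per-node ΔF/F, background and noise, with
optional integer shifts.

What passing tests therefore show: the estimators are exact or calibrated
on data generated by their own assumed forward models. What they do not
show: faithfulness of real hemibrain synapse statistics (counts per
location, polyadic structure, regional densities), realistic imaging noise
or motion, or the magnitude of the real imbalance — the real-data analysis
needs the actual connectome exports, and only its qualitative structure
(ratio > 1, decreasing in λ, destroyed by shuffling) is asserted
synthetically. Generator sizes are kept small (≤ 50 KCs, ≤ 5 000 synapses,
≤ 64³ voxels) so the whole suite runs in about a minute.

## Numerical conventions

- Electrotonic lengths use the sum-of-square-roots form everywhere; no
  branch on r₁ = r₂.
- Distance ties (synapse mapping, Voronoi assignment) go to the lowest
  index; argmin-first semantics make this deterministic.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator and the shuffle are bit-reproducible under a fixed seed.
- Degenerate inputs fail loudly: non-tree skeletons, unknown direction
  tokens, empty masks, flat alignment references, flat decay profiles,
  non-positive space constants.
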