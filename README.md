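# aplocal

Tools for asking how *local* feedback inhibition is in the *Drosophila*
mushroom body. The APL neuron — a single GABAergic interneuron that
innervates the whole mushroom body and forms reciprocal synapses with every
Kenyon cell (KC) — is non-spiking, so its inhibition can only reach as far
as passive depolarization spreads along its neurites. This package
implements the quantitative machinery behind that question, for
connectomics and imaging researchers:

- **Skeleton geometry** (`aplocal.skeleton`, `aplocal.distances`): SWC
  neurite skeletons as validated geometric trees; along-skeleton shortest
  paths (Dijkstra on the synapse-augmented graph) in *real* length or in
  *electrotonic* length. Each edge is a truncated cone between node radii
  `r₁, r₂`, whose electrotonic length is
  `∫₀ᵈ dx/√r(x) = 2d(√r₂ − √r₁)/(r₂ − r₁)` (→ `d/√r` for a cylinder), so
  that passive decay is `exp(−d_e/k)` with a radius-independent space
  constant `k = √(Rm/2Ra)`.
- **Synapse mapping** (`aplocal.synapses`): KC→APL and APL→KC synapse
  tables mapped to nearest points on the skeleton, with region/coordinate
  filters (e.g. the calyx restriction: y < 20 000 px and not in the
  peduncle ROI).
- **Inhibition matrix** (`aplocal.inhibition`): the pairwise metric
  `s(k1,k2) = Σᵢ Σⱼ exp(−d(xᵢ,yⱼ)/λ)` over all (KC1→APL, APL→KC2) synapse
  pairs; per-KC self/other imbalance ratios; identity-shuffle nulls;
  subtype-grouped display ordering.
- **Spread simulation** (`aplocal.spread`, `aplocal.cable`): λ ↔ k ↔ Rm/Ra
  conversions; exponential fits to dye/stimulus profiles; the random-point
  activity-spread simulation
  `activity(sᵢ) = (1/N_sᵢ) Σ_{j∈sᵢ} Σ_k stim(p_k)·w(d(p_j,p_k))` on the
  skeleton, in electrotonic, uniform-radius or backbone distance modes.
- **Volumetric ΔF/F** (`aplocal.backbone`, `aplocal.volumetric`): backbone
  skeletons and their standardization across recordings, Voronoi
  segmentation of a 3D mask around backbone nodes, per-segment ΔF/F with
  background subtraction, noise-based node exclusion, boxcar/interpolation
  conventions, cross-correlation alignment, and the normalized inhibitory
  effect `(ΔF/F drug − ΔF/F alone)/peak ΔF/F alone`.
- **Expression screen** (`aplocal.expression`): TPM aggregation across
  splice variants (geometric mean over replicates, log10 floor −2) and the
  strict "higher/lower than all other cell types" screen.
- **Synthetic data** (`aplocal.synthetic`): seeded generators for toy
  Y-shaped skeletons, clustered reciprocal synapses, dye profiles, 4D
  movies with known ΔF/F, and expression tables — every analysis above can
  be exercised and calibrated without downloading any dataset.

## Worked example

`examples/inhibition_imbalance.py` builds a toy mushroom body, scatters
clustered reciprocal synapses for 20 synthetic KCs (50 per direction each),
and measures how disproportionately a KC inhibits itself:

```
lambda =    25 um: median self/other ratio = 5.609
lambda =    50 um: median self/other ratio = 3.509
lambda =    75 um: median self/other ratio = 2.599
lambda =      inf: median self/other ratio = 1.000
shuffled identities, lambda = 50 um: median over 20 seeds = 1.001
```

A ratio above 1 means self-inhibition `s(k1,k1)` exceeds the average
lateral inhibition `s(k1,k2)` of other KCs. The imbalance grows as the
space constant shrinks, disappears when inhibition is global (λ = ∞), and
collapses to 1 when synapse-to-KC identities are shuffled — it is carried
by the spatial clustering of each KC's synapses, not by synapse counts.

The other examples cover the cable-parameter conversions
(`cable_constants.py`), the simulate→fit λ-recovery loop
(`spread_simulation.py`), the volumetric ΔF/F pipeline
(`volumetric_dff.py`), and the expression screen (`expression_screen.py`);
each prints its results with a short interpretation.

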