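# Methods

`traumaconn` couples a voxel-level, time-evolving prediction of cell death
to a streamline tractogram and a weighted structural brain network. The
input is a per-voxel history of axonal strain and effective strain rate
over a short (~15 ms) impact window; the output is a sequence of degraded
connectomes and their graph measures over 0–96 h post-impact.

## The injury model

**Cell-death tolerance surfaces.** The damage parameter D is the percent
area of cell death predicted for a tissue region as a function of time from
insult t (days), local axonal strain ε (dimensionless) and local effective
strain rate ε̇ (1/s). The package evaluates multiplicative power-law
surfaces

    D(t, ε, ε̇) = A · t^p · ε^q · ε̇^r     (rate-dependent regions)
    D(t, ε)     = A · t^p · ε^q           (rate-independent regions)

with coefficients stored in a versioned YAML registry
(`src/traumaconn/data/death_params.yaml`), not in code, so that
region-specific criteria can be swapped in without touching the pipeline.
The functional form encodes the structural facts the model relies on:

* D is monotone non-decreasing in t on the validated window 0–4 days —
  cellular repair and regeneration are not modeled, and extrapolating past
  96 h triggers a warning rather than an error;
* D(t=0) = 0 and D(ε=0) = 0: no instantaneous damage, no damage without
  strain;
* the effects of strain, strain rate and time decompose into separate
  multiplicative terms, so each extrinsic factor can be studied in
  isolation;
* cortical cell death depends on strain rate; hippocampal cell death does
  not. Because imaging cannot subdivide the hippocampus into CA1/CA3/
  dentate gyrus, the most conservative (highest-death) hippocampal surface
  is applied to the entire structure (the registry alias `hippocampus →
  hippocampus_ca1`). White matter defaults to the rate-dependent cortical
  surface (`white_matter → cortex`), a substitution the registry makes
  explicit and replaceable.

Default coefficients (cortex A = 16.5, p = 1, q = 2, r = 0.1; conservative
hippocampus A = 30, p = 0.5, q = 1.8) were calibrated once against a single
anchor: a 3 % critical cell-death threshold evaluated at 4 days should mark
approximately the same tissue as the classic 18 % axonal-strain criterion
for degraded electrophysiological function, i.e. D(4 d, ε = 0.18,
ε̇ ≈ 30 s⁻¹) ≈ 3 %. Culture-derived tolerance data ultimately come from rat
tissue and nominal (not axonal) strain; the registry is the package's
acknowledgement that these coefficients are provisional.

**Evaluation rule.** Negative strain and strain rate are clamped to zero
before evaluation (compression is not credited toward cell death). D is
evaluated at every output increment on that increment's (ε, ε̇) pair
*jointly*, and the per-voxel maximum over increments is used; pairing the
max strain with the max rate across different increments would
overestimate damage. A voxel is damaged when D strictly exceeds the
critical threshold D_crit (default 3 %).

**Tract and edge degradation.** A streamline that traverses at least one
damaged voxel is removed in its entirety. Edge strength is degraded
proportionally to the surviving fiber fraction, s′ = s · n_surv / n_base —
the minimal rule consistent with strength being defined by fiber count. An
edge with no surviving fibers is *fully damaged* (strength exactly 0,
disconnected). Nodes are never deleted; disconnection can only arise
through edge loss.

## Network construction and measures

Nodes are ROIs at their centroids; an edge joins two different ROIs
whenever at least one ROI-filtered streamline (both endpoints inside ROI
voxels) connects them, carrying fiber count and mean fiber length.
Strengths are resampled onto Normal(0.5, 0.1) by rank: edges sorted by
fiber count receive the plotting-position quantiles of the target normal,
which compresses the scale without altering the strong-to-weak rank order,
deterministically and without a seed. Tied fiber counts are ordered by ROI
pair (stable) and each tied block receives its block-mean quantile, so
equal counts get equal strengths. Strengths are clipped to (0.001, 0.999)
so costs c = 1 − s stay strictly positive. Degradation is always applied to
the *baseline* resampled strengths; the damaged network is never
re-resampled, so matrices at different timepoints are directly comparable.

All distance-based measures use edge costs. Global efficiency is the mean
inverse shortest-path cost over node pairs (0 for unreachable pairs),
reported normalized by the efficiency of an ideal network — the complete
graph on the same nodes with every edge at the minimum cost of the
*baseline* connectome, so the normalization constant is fixed across
timepoints. Local efficiency of node v is the efficiency of the damaged
subgraph induced on v's **baseline** neighbor set; freezing the
neighborhood keeps the measure comparable before and after damage and lets
removed edges show up as lost efficiency rather than a shrunken
neighborhood. Betweenness defaults to integer counts of node pairs whose
minimal-cost path passes through v, crediting v when it lies on *any*
minimal path (a fractional Brandes variant and a hop-count metric are
available behind flags). Weighted clustering follows the Onnela convention
(triangles weighted by the geometric mean of max-normalized strengths, via
networkx). The small-world coefficient is σ = (C/C_rand)/(L/L_rand) where
the random reference preserves the degree sequence by double-edge swaps
with weights carried by the swapped stubs; σ is averaged over an ensemble
of 10 seeded rewirings (disclosed in output) to reduce reference variance.

## The digital phantom

The phantom replaces subject imaging plus a head-impact finite-element
simulation with a generator whose outputs have the statistical structure
the analysis needs. It is first-class, tested code, not a fixture.

* **Geometry.** An ellipsoidal brain mask on a 40³ grid of 2 mm voxels.
  ROIs are Voronoi regions around seed voxels — 82 % of seeds on the
  cortical shell (normalized radius > 0.72), 18 % in the core as
  subcortical blocks, matching the cortical/subcortical split of an
  83-region atlas; two subcortical labels are tagged hippocampus so the
  rate-independent surface has a substrate.
* **Tractogram.** 3000 streamlines grouped into bundles between random ROI
  pairs with geometric bundle sizes (mean 4), yielding the heavy-tailed
  fiber-count heterogeneity of real connectomes, where fragile edges carried
  by a handful of fibers are the first to be fully damaged. Each streamline
  is a quadratic Bézier arc bent toward the brain center, with endpoints
  placed inside ROI voxels by construction. Per-voxel fiber axes are the
  sign-aligned means of the tangents of the streamline segments crossing
  each voxel.
* **Strain history.** 100 increments of 0.15 ms (a 15 ms window). The
  spatial envelope is (anteroposterior gradient along the impact direction)
  × (centrally peaked shear-focusing bump) × (smooth seeded texture),
  normalized so the maximum voxel strain at the final increment equals the
  configured peak (default 0.33, the largest axonal strain a frontal-impact
  simulation predicts in the temporal region). The temporal profile is a
  sin² ramp whose maximum slope realizes the configured peak strain rate
  (default 50 s⁻¹, a choice in the tens-per-second range typical of impact
  simulations). Strain rate is the per-increment finite difference
  converted to 1/s plus seeded half-normal noise.
* **What the phantom does not emulate.** Real FEM strain fields have
  anatomy-driven asymmetries, skull/CSF boundary effects and viscoelastic
  time structure; real tractography has crossing-fiber ambiguity, length
  biases and false-positive bundles. Tests passing on the phantom certify
  the *pipeline logic* (thresholding, traversal, degradation, metrics), not
  predictive validity on a real subject, whose headline numbers depend on
  subject-specific anatomy and a full solver run.

`inject_lesion` overwrites chosen voxels with supra-threshold strain/rate
at every increment, giving exact ground truth for recovery tests: the
damaged tracts must be exactly those traversing the lesion.

## Element-to-voxel mapping

Externally supplied solver output (element centroids with per-increment
values) is averaged into voxels: each voxel takes the arithmetic mean of
the samples inside its half-open box (half-open so boundary samples are
assigned uniquely), and voxels containing no sample are treated as zero
strain — a conservative choice, since absent evidence produces no damage.
Multiple fiber axes in one voxel are combined by flipping each axis into
the hemisphere of the set's first principal axis, averaging, and
renormalizing; an exactly antipodal pair falls back to the first axis with
a warning.

## Numerical choices

* **Traversal.** Segment–voxel supercover: each segment is sliced at its
  axis-plane crossings and every sub-interval midpoint claims its voxel.
  This is the inclusive reading of "traverses" and is validated against a
  dense-sampling oracle (step = voxel/50); corner-grazing contacts of
  measure zero may be included by the supercover and missed by sampling,
  which is the conservative direction for damage.
* **Coordinates.** 0-based voxel indices; voxel (i,j,k) owns the half-open
  box [i·vs, (i+1)·vs); NIfTI affines carry the half-voxel shift so indices
  map to voxel centers. Streamlines are stored in world mm.
* **Shortest paths** via Dijkstra (scipy.sparse.csgraph); minimal-path ties
  in betweenness use an absolute tolerance of 1e-12 on path cost.
* **Strict inequalities** at both damage thresholds (D > D_crit,
  ε_max > 0.18), so an unreachable threshold (e.g. D_crit = 100 %) masks
  nothing.
* **Degenerate inputs.** Zero-length streamlines claim their containing
  voxel; nodes with fewer than two baseline neighbors have local efficiency
  0 by convention; isolated baseline nodes report 0 % degree change (and
  are logged); disconnected graphs report path length over reachable pairs
  with a `connected = False` flag.
* **Determinism.** One RNG stream per stage, seeded from the run seed with
  fixed offsets; strength resampling is quantile-based and needs no seed.
  Two runs with an identical config produce byte-identical CSVs (fixed
  float format `%.10g`).

## Default run and problem sizes

The default configuration (83 ROIs, 40³ voxels at 2 mm, 3000 streamlines,
100 increments, timepoints 0/24/48/72/96 h, D_crit 3 %, Gaussian 0.5/0.1,
σ ensemble 10) runs the full pipeline in well under a minute on one CPU.
These sizes are the package's chosen study conditions for the phantom: they
yield a few hundred edges with realistic fiber-count heterogeneity, enough
for stable graph measures, while the sensitivity sweep (D_crit 1–10 % in
1 % steps, configurable) re-evaluates only masks and efficiencies per
threshold.

## Known limitations

* The tolerance-surface coefficients are calibrated to a single published
  anchor (3 % death at 96 h ≈ 18 % strain criterion), not fitted to culture
  data; the registry exists so better coefficients can replace them.
* All-or-nothing tract removal ignores partial axonal injury within a
  bundle; strength degradation is linear in surviving fiber count.
* The phantom's strain field is phenomenological; no quantitative spatial
  statistics of real FEM output are reproduced.
* Gray-matter nodes are never degraded, only edges; functional consequences
  of structural damage are out of scope.
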