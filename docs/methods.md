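# Methods

This note documents the models, conventions, and numerical choices behind
`wmhnet`, and what the simulation-based tests do and do not establish.

## Tractography

The tracker implements pure FACT: from each seed voxel center, tracking
proceeds in both signs of the seed voxel's principal direction, and each
step follows the direction stored in the voxel currently occupied, with no
interpolation. Because eigenvector sign is arbitrary, the voxel direction
is flipped when needed so its angle to the previous step is at most 90°
*before* the turning-angle test. A half-track terminates when

* the entered voxel has FA below `fa_threshold` (default 0.2; the seed
  point itself is always retained, so a seed in sub-threshold tissue
  yields a single-point streamline),
* the turning angle between successive step directions strictly exceeds
  `angle_threshold` (default 45°),
* the next position leaves the grid, or
* `max_steps` (default 500) steps have been taken.

Step size defaults to half the smallest voxel dimension; positions are
voxel centers, `(index + 0.5) · voxel_size`, with 0-based indices. These
two quantities are exposed because tractography packages differ in their
defaults and neither is canonical.

## Connectome construction

A streamline defines an edge when its first and last points fall in two
distinct non-background parcellation labels; endpoint-in-background,
endpoint-off-grid, and same-region streamlines are discarded (the network
has no self-loops). Per-streamline FA is the mean of FA sampled at every
*point's* voxel — points, not unique voxels — an explicit choice where
tools are ambiguous; length is polyline arc length. The FN threshold is
strict: an edge survives only with FN > threshold (default 3, so FN = 3
is removed), and surviving edges are weighted FN × meanFA. Thresholding
affects topology only; the analyzed network is weighted.

## Graph measures

Shortest paths use edge length 1/w (the convention of the standard brain
connectivity toolboxes), computed by Dijkstra on the sparse length matrix.
Conventions chosen where the printed formulas are underdetermined:

* **Clustering (network level)** — the Onnela geometric-mean form with
  weights normalized by the network maximum, so the coefficient lies in
  [0, 1]; it is invariant to uniform weight scaling.
* **Nodal clustering** — the binary form E_i / (K_i(K_i−1)/2) on the
  thresholded topology, exactly as the count-based definition implies.
  Nodes of degree < 2 contribute 0 (the formula otherwise divides by 0).
* **Lp and Eg** — Eg is the mean reciprocal shortest distance over ordered
  pairs (unreachable pairs contribute 0) and Lp is defined as its inverse,
  making Lp·Eg = 1 an exact identity; an empty graph has Eg = 0 and Lp is
  flagged as undefined (`DisconnectedGraphError`, or +inf in the bundled
  summary).
* **Nodal path length** — the mean shortest distance to *reachable* nodes;
  a fully isolated node gets +inf rather than contaminating group
  statistics silently (such nodes are treated as missing downstream).
  The exclusion convention is explicit because an unreachable pair would
  otherwise make every nodal mean infinite.
* **Local efficiency** — nodal Eloc(i) is the global efficiency of the
  subgraph induced by i's neighbors (i removed, subgraph's own weights and
  internal paths); the network-level Eloc is the mean over nodes.

Scaling all weights by k > 0 multiplies Eg (and nodal Eloc) by k, divides
Lp by k, and leaves density, both clustering forms, and the topology
unchanged — a property the tests verify, as well as agreement of every
measure with brute-force enumeration (Floyd–Warshall distances, exhaustive
triple and subgraph enumeration) to 1e−10 on hundreds of random graphs.

## Synthetic cohort

The generator emulates the study conditions end to end.

* **Base network** — 90 nodes placed uniformly in the unit cube; exactly
  `round(density · 4005)` edges sampled without replacement with
  probability ∝ exp(−d/0.3), so long-range edges exist but are rarer.
  FN = 4 + Poisson(28·e^(−2.5d)) (every edge survives FN > 3 at full
  strength), FA ≈ N(0.5 − 0.1d, 0.05) clipped to (0.05, 0.95), length =
  100d mm. Default density 0.3.
* **Lesioning** — the longest `lesioned_edge_fraction` (default 0.25) of
  base edges are designated lesion candidates (WMH preferentially damages
  long association fibers); in both patient groups their FN and FA are
  multiplied by `edge_attenuation` (default 0.6). Attenuated counts that
  round below 4 then fall to the FN > 3 threshold, so lesioning degrades
  both weights and topology.
* **Subject noise** — per-subject lognormal FN noise (σ = 0.08 on the log
  scale) and additive FA jitter (σ = 0.015).
* **Lesion volumes** — periventricular and deep volumes are drawn
  log10-normally per group and summed into the total, which enforces
  TWMH ≥ PWMH, DWMH by construction. Group levels emulate an elderly WMH
  cohort: controls ≈ 1.7 ml total versus ≈ 6–7.5 ml in patients, patients
  slightly older and less educated.
* **Implanted mediation** — with X the within-cohort standardized log₁₀
  lesion volume, a latent mediator M = a·X + small covariate paths +
  σ·ε and outcome Y = b·M + c′·X + covariate paths + σ·ε are drawn
  (defaults a = −0.4, b = +0.4, c′ = −0.1, σ = 0.5: heavier lesion load
  lowers the mediator node's efficiency, efficiency predicts memory, and
  the direct lesion effect is negative, so the implant reinforces rather
  than offsets the lesion-induced efficiency loss). M is written into the
  connectome by scaling the designated mediator node's incident fiber
  counts by max(0.2, 1 + 0.3·M); those edges carry no other noise or
  lesioning, so the node's efficiency computed downstream is a
  near-deterministic monotone image of M. Nodal *efficiency* is the
  implant target because it is approximately linear in incident edge
  weight; the default mediator node is IFGoperc.L (AAL index 11). Memory
  test raw scores (VR-DR, AVLT-DDR) are generated from Y; the other tests
  follow a group-shifted general-cognition latent, with timed tests
  (Trail Making, Stroop) oriented so larger raw values mean worse
  performance.
* **Determinism** — all draws flow from one seeded generator in a fixed
  subject order; identical configurations are bit-identical.

What the generator does **not** emulate: MRI acquisition and registration
error, spatially realistic lesion geometry, non-linear metric–cognition
relations, missing data patterns, and volume effects of unequal parcel
sizes. Passing tests therefore demonstrate correctness of the analysis
machinery under a known linear ground truth, not robustness to real-data
artifacts.

## Statistics

* **ANCOVA** — a linear model with two group indicators (controls as
  reference) plus age, a 0/1 male indicator, and education years; the
  omnibus F tests both indicators jointly, adjusted means are evaluated at
  covariate means. A batched solver (shared design, many outcome columns)
  is used for the 90-node scans and calibration simulations and is tested
  to match the single-outcome fit exactly. Complete-case analysis per
  model; exclusion counts are logged.
* **Post hoc** — covariate-adjusted pairwise contrasts from the same fit;
  both the raw p and 3×-multiplied p are reported, with significance
  declared at raw p < 0.05/3 (the two decision rules are equivalent).
* **FDR** — Benjamini–Hochberg step-up at q = 0.01 across nodes; pairwise
  contrasts are examined only for surviving nodes.
* **Composites** — tests are z-scored against the pooled analyzed sample
  by default (a control-only reference is available), reversed (timed)
  tests are negated, and domains average their members. Education-adjusted
  MoCA cut-offs: ≤ 19 (1–6 y), ≤ 24 (7–12 y), < 26 (> 12 y); education
  below one year is unclassifiable rather than silently assigned.

Calibration simulations draw nodal outcomes directly from the group-null
linear model on the covariates of one generated null cohort (1000
replicates for p-value uniformity, 2000 × 90 nodes for the FDR
any-discovery rate). This targets exactly the component being calibrated;
regenerating full connectome cohorts per replicate would add nothing to
the null distribution of the test statistic. The cohort-level null is
exercised once end to end.

## Mediation

Coefficients come from three OLS fits sharing one covariate set, so
c = c′ + a·b holds to machine precision on every dataset. By default all
continuous variables are z-scored first (standardized β, comparable across
metrics); binary indicators are never rescaled. Structural-recovery
checks fit on the natural scale (`standardize=False`), since the implanted
coefficients are defined there — a fully standardized fit rescales the
indirect effect by 1/sd(Y).

The indirect-effect interval is the bias-corrected (BC) percentile
bootstrap: subjects are resampled as whole rows k times (default 5000,
batched normal-equation solves), z₀ = Φ⁻¹(fraction of draws below the
point estimate), and the interval takes the bootstrap quantiles at
Φ(2z₀ ± z₀.₉₇₅). BCa (jackknife acceleration) is available behind a
flag but is not the default, matching the named method. Standardization
happens once, before resampling. A degenerate bootstrap distribution
(all draws equal) collapses the interval to a point and is flagged.

Operating characteristics established by the simulation suite: at n = 300
the implanted indirect effect 0.25 is recovered within ±0.1 with an
interval excluding zero; coverage of the true effect at n = 200 with
moderate paths is ≈ 95%; under a single-path null (a = 0.25, b = 0) the
false-positive rate is ≈ 5%. Two regimes where the BC interval is *known*
not to be nominal, and which the calibration test deliberately avoids:
under the complete null (a = b = 0) the product statistic is degenerate
and the interval is strongly conservative (rejection ≈ 1–2%), while under
a large nonzero path (a = 0.5) the BC correction is mildly
anti-conservative (≈ 7% in our characterization). Both behaviors are
long-documented properties of bootstrap product-of-coefficients tests,
not implementation artifacts.

## Pipeline

One master seed feeds a seed sequence from which the cohort and bootstrap
substreams derive. All tables are TSV/CSV with explicit node-name headers
(0-based indexing never leaks into files), carry the hash of the producing
configuration, and contain no timestamps, so a rerun with the same
configuration is byte-identical. Matrix readers validate symmetry, zero
diagonal, and label agreement, naming the offending entries.

Problem sizes used by the validation suite (chosen to characterize each
component at meaningful precision): 200 random graphs (N ≤ 12) for oracle
equivalence; 1000/2000 replicates for ANCOVA/FDR calibration; 600
simulations for the mediation null and 500–1000 for coverage; the default
135-subject, 90-node cohort for end-to-end recovery.

## Known limitations

* The tracker is deliberately minimal (nearest-voxel FACT): no tensor
  fitting, interpolation, or probabilistic variants.
* Nodal path length for disconnected nodes uses the exclusion convention;
  other toolboxes differ, and values are not comparable across conventions
  when graphs fragment.
* The generator's effect sizes are illustrative: the literature provides
  no calibrated attenuation values for WMH lesioning, so group effect
  magnitudes should not be read as physiological predictions.
* Local efficiency can *rise* under lesioning in the generator (removing
  weak long-range edges raises the mean efficiency of the surviving
  neighbor subgraphs); only strength, Eg, and Lp carry the implanted
  directional claim.
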