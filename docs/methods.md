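# Methods

`neuromosaic` quantifies the 3D spatial organisation of neuron-sized cells
in tomographic grey-level volumes of nervous tissue: where the cells are
(threshold detection), whether they aggregate or disperse relative to
randomness (Ripley K statistics), and how regular their mosaic is (Voronoi
volume fluctuation). This note records the models, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## Cell detection

The detector assumes cells appear as bright compact bodies on a darker
background, with the nucleus as the brightest core — the contrast produced
by X-ray phase-contrast tomography, where grey level tracks electron
density. The steps are:

1. **Intensity statistics.** Mean ⟨I⟩, population standard deviation ΔI
   (divisor N), a 256-bin histogram and the Fisher skewness are computed
   over the ROI (or a user mask). Cell-rich ROIs show a heavy right tail
   (skewness > 1); a constant volume is reported with skewness 0 and an
   explicit "undefined" flag.
2. **Threshold.** Voxels strictly brighter than ⟨I⟩ + k·ΔI are selected
   (k = 2 by default). Ties at exactly the threshold are excluded — a
   measure-zero event for float data. Statistics are global over the ROI
   by default; an optional two-pass mode re-estimates ⟨I⟩ and ΔI inside
   the detected components and re-thresholds once, for the reading in
   which the statistics refer to cell-occupied volume.
3. **Components and size filter.** Connected components are labelled with
   26-connectivity (6/18 configurable). Components smaller than
   `min_cube_side³` = 7³ = 343 μm³ are discarded to suppress noise
   speckle, artifacts and glia-sized objects. The filter compares the
   component *volume* to 343 μm³; a stricter per-axis bounding-box variant
   (`size_filter_mode="per_axis"`) is available.
4. **Cell records.** Each surviving component yields an
   intensity-weighted centroid in physical μm (the bright nucleus
   dominates, which is what localises the cell), voxel count, physical
   volume, equivalent spherical diameter (6V/π)^(1/3) and peak intensity.
5. **Size classes.** Half-open equivalent-diameter intervals: motor
   neurons [30, 50) μm, interneuron-sized [10, 20) μm, glia-sized
   [0, 7) μm; anything else is `unclassified`. Overlapping intervals are
   rejected when the configuration is built.

Limitations: touching cells are not split (no watershed), so overlapping
somata merge into one detection; at thresholds below the noise floor the
background percolates into a single giant component. Detection counts are
therefore only guaranteed to be monotone in k, and exhaustively correct,
for well-separated cells — which is how the validation scenario is built.

## Ripley K analysis

For a pattern of n points in an axis-aligned box of volume V (half-open
`[lo, hi)` so edge weights stay finite), the estimator is

    K̂(x) = V / (n(n−1)) · Σ_{i≠j} w_ij · 1[d_ij ≤ x]

with the translation edge correction
w_ij = V / Π_a (s_a − |Δ_a|), the reciprocal fraction of window
translations keeping both points inside — exact for rectangular windows
and free of isotropy assumptions (the isotropic Ripley correction would be
an alternative; it is not implemented). `edge_correction="none"` (w = 1)
is kept as a diagnostic: it is biased low at large radii.

Under complete spatial randomness K_CSR(x) = (4/3)πx³. Derived summaries:

* **Clustering degree** ρ(Δx) = [K̂(Δx) − K_CSR(Δx)] / K_CSR(Δx);
  ρ > 0 means aggregation at scale Δx, ρ < 0 dispersion (a hard-core
  pattern has ρ = −1 below its inhibition distance). Equivalently, the
  plotted ratio K̂/K_CSR equals ρ + 1.
* **Clustering length** L_c: the upper end of the first contiguous run of
  grid radii on which K̂ > K_CSR — the spatial extent of aggregation.
  Undefined (reported as such, never coerced) when K̂ never exceeds
  K_CSR. No interpolation across the crossing is attempted: the grid
  endpoint is reported with the grid spacing as its resolution, which is
  finer than the uncertainty such estimates carry in practice.
* ρ is reported at Δx = L_c by default (configurable). Two consequences
  are worth knowing. First, when L_c is a genuine crossing, ρ(L_c) is by
  construction a small positive number whose size reflects the local
  fluctuation scale of K̂ rather than the peak aggregation strength;
  comparisons of ρ between groups are therefore most meaningful together
  with the full ratio curve. Second, when K̂ stays above K_CSR through
  the whole admissible range, L_c equals the largest grid radius and
  ρ(L_c) is a genuine large-distance excess — a qualitatively different
  number. This interaction is why the healthy-vs-diseased comparison in
  the validation suite is made on generated point patterns, where both
  groups have genuine crossings.

Radii run from a configurable start (default: min box side / number of
steps; the scenario presets start at 30 μm, the motor-neuron soma scale,
below which pair counts carry no information) up to the smallest box
side — the admissible range for the estimator. 100 linear steps by
default.

**CSR envelopes.** Pointwise Monte-Carlo rank envelopes over `n_sims`
CSR realizations with matched n and box; the `floor(α(n_sims+1))` most
extreme values per tail are discarded at every radius, so α = 0.05 needs
at least 19 simulations and a two-sided 99% band uses α = 0.005 with 199.
Envelopes are pointwise, not simultaneous.

Pair counting uses a k-d tree query capped at the largest radius; the
test suite holds the estimator to an independent O(n²) double loop at
1e−9 relative tolerance.

## Voronoi tessellation

Voronoi regions of boundary points are unbounded, so two policies exist:

* `clip_to_box` (default): each region is intersected with the box. All n
  points contribute and the volumes partition the box exactly (asserted
  to 1e−6 relative). Implemented by mirroring the pattern across all six
  box faces before tessellating: for any point in the box its nearest
  neighbour is always an original point (a reflection can only increase
  distance on the original side), so the regions of the original points
  are bounded, contained in the box, and tile it. This is exact for
  axis-aligned boxes.
* `drop_boundary`: regions touching the box surface are flagged and
  excluded, the convention of the retinal-mosaic literature. Interior
  regions are unaffected by the mirroring and equal the unbounded-domain
  Voronoi cells.

The regularity statistic is the fluctuation dV_v = ΔV_v / V_v (population
standard deviation over mean of the retained volumes): 0 for a perfect
lattice (the population convention makes this exact), and ≈ 0.44 for a
CSR pattern under `clip_to_box` at n = 10⁴ — our frozen reference value
0.443, measured by dedicated simulation; with boundary cells dropped the
value falls to ≈ 0.429, approaching the classical ≈ 0.423 of the
unbounded Poisson–Voronoi tessellation. Clustered patterns give larger
dV_v, hard-core patterns smaller, and the suite asserts this ordering.
Volumes are exact convex-polyhedron volumes (convex hull of the region
vertices); truly degenerate configurations that defeat Qhull are retried
once with a deterministic jitter of 1e−6 of the box side and a warning.

Density is n over box volume, reported in mm⁻³ (1 mm³ = 10⁹ μm³) only at
the reporting layer; everything internal is μm.

## Synthetic data

The generators provide ground truth for every stage:

* `gen_csr` — binomial (fixed-n) uniform pattern, the CSR null.
* `gen_cluster` — Thomas process: Poisson parents (simulated in a box
  padded by 4σ so edge clusters are not truncated), Poisson offspring
  counts, isotropic Gaussian displacements with standard deviation σ.
  Chosen as the minimal standard cluster model with known second-order
  theory.
* `gen_hardcore` — simple sequential inhibition; if the requested count
  cannot be placed the achieved count is returned with a warning.
* `render_volume` — each point becomes two concentric spheres: a soma at
  intensity 100 and a brighter nucleus (half the soma diameter) at 200,
  on a background of 0 with additive Gaussian noise (default σ = 10;
  intensities are arbitrary units, as tomographic grey levels are
  uncalibrated). Somata are painted before nuclei so overlaps never
  erase a nuclear core. Voxel centres sit at origin + (index + ½)·voxel.
  A paired ground-truth table (centre, class, soma diameter) is returned.

What the renderer does *not* emulate: dendrites and realistic soma
morphology, vasculature and fibre tracts, reconstruction artifacts
(rings, streaks), spatially varying background, partial-volume blur.
Detection results on synthetic volumes therefore demonstrate the
correctness of the algorithm, not its performance on degraded real
tomograms.

### Scenario presets

Presets keyed by spinal level carry the motor-neuron densities reported
for ventral-horn ROIs (cervical 3.0×10³, thoracic 2.0×10³, lumbar
5.0×10³, lumbar-EAE 1.0×10³ mm⁻³). Cluster geometry is not identifiable
from published summaries, so σ and the mean offspring were calibrated by
simulation so that the empirical L_c reproduces the reported per-level
scale where the window permits; a key empirical finding of that
calibration is that the first-crossing L_c of a Thomas pattern is
governed by the window size and the overdispersion of the realized count
(which biases K̂/K_CSR low at large distances), not by the theoretical
Thomas K (which never crosses K_CSR). The ROI side per scenario is
therefore chosen so the admissible distance range covers the scale being
emulated: 600 μm for lumbar control (L_c ≈ 270 μm median), 300 μm for
EAE (≈ 130 μm), 400 μm for thoracic (≈ 168 μm, against a reported
165 μm). The cervical scale (55 μm) is not reachable at that density in
a window large enough to analyse; the cervical preset keeps the correct
density and the qualitative tight-cluster geometry. The
`detection_validation` preset uses a hard-core pattern (min distance
55 μm ≈ the largest soma diameter plus a margin) so rendered somata
never merge and detector counts can be compared to ground truth exactly.

Group comparisons aggregate medians over three replicate ROIs per group,
mirroring a multi-specimen design, and flag the qualitative degeneration
signature — density↓, L_c↓, ρ↑ ("rarer but more aggregated") — as a
boolean, not a hypothesis test; no inferential procedure is attached to
group differences.

## Problem sizes in the validation suite

Estimator exactness is checked on 50 patterns up to n = 200; CSR
calibration uses n = 1000 in a 500³ μm³ box over 50 seeds with a
199-simulation envelope; sign recovery uses 20 seeds per process; the
Poisson–Voronoi reference uses n = 10⁴; detection validation renders
300³ μm volumes at 2 μm voxels over 20 seeds; the group comparison runs
3 replicate ROIs per group. These sizes give stable statistics while
keeping the whole suite comfortably fast on one CPU.

## Known limitations

* Anisotropic or inhomogeneous K, the pair-correlation function g(r) and
  cross-type K between size classes are not implemented.
* The K̂-vs-K_CSR comparison inherits the usual small-n volatility; L_c
  from a single sparse ROI is noisy, which is why replicate medians are
  used for comparisons.
* Touching cells are not split; detection on dense clustered tissue
  undercounts and the detected pattern acquires an artificial minimum
  separation at the merge scale.
* The EAE acquisition geometry (3.5 μm voxels) undersamples glia; no
  attempt is made to model per-instrument detection differences.
* Published per-level mean Voronoi volumes and densities are mutually
  inconsistent (their product differs from 1 in every reported row); the
  package reports both quantities independently and does not attempt to
  reconcile them.
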