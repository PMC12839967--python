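# Methods

This note documents the models and procedures implemented in
`perilymph`, the choices made where the procedure was genuinely open, and
what the synthetic-data tests do and do not establish about real data.

## Gradient profiling

**Procedure.** A binary lymphatic-vessel mask aligned to a fluorescence
image (2-D, or a 3-D stack collapsed by maximum-intensity projection) is
converted to a distance map by an exact Euclidean distance transform
(`scipy.ndimage.distance_transform_edt`) with anisotropic pixel spacing
in µm. Distances are rounded to integer µm and pixel intensities sharing
an integer distance are averaged, giving one distance-gradient vector
per image. Vectors average image → mouse (biological replicate) →
condition, and all profiles are divided by the reference condition's
mean intensity at 0 µm.

**Numerical choices.**

* *Rounding*: half away from zero (`floor(d + 0.5)`), not banker's
  rounding — symmetric around bin centres and easy to document. A pixel
  at exactly 2.5 µm belongs to bin 3.
* *On-vessel pixels* are excluded from all bins: the profile describes
  the non-masked tissue. Bin 0 then holds only off-vessel pixels within
  0.5 µm of the mask, which do not exist when the pixel pitch is ≥ 1 µm;
  for such coarse images `include_vessel_as_zero=True` places vessel
  pixels in bin 0. This is a labelled option, never a silent fallback.
* *Missing data*: bins with fewer than `min_count` pixels (default 10)
  are NaN and propagate — never imputed, never treated as zero. Averaged
  levels use the per-bin mean over inputs where the bin is defined, with
  the contributing `n_units` recorded.
* *d_max* defaults to 80 µm (profiles are typically plotted to ≥60 µm).
* *Background* (isotype-level staining) is reported alongside summaries
  and drawn in plots; it is only subtracted when explicitly requested
  (`subtract_background=True`), since the raw readouts are conventionally
  reported against a background line rather than background-corrected.
* *Units of analysis*: the replicate hierarchy (several images per ear,
  one profile per mouse, mice per condition) is explicit in profile
  provenance, and statistics consume per-mouse values only.

**Decay fit.** `fit_decay` fits *I(d) = b + A·e^(−d/λ)* with *b* fixed,
weighted by per-bin pixel count (σᵢ ∝ 1/√nᵢ), via
`scipy.optimize.curve_fit` with a log-linear initial guess for λ and
non-negativity bounds. At least 4 bins above background are required; a
profile flat at background raises instead of returning a degenerate fit.
The exponential form is a modelling choice for synthetic fixtures and
recovery tests — the in-vivo gradient's functional form is not
established, only its decay over tens of µm — so the fit is a
verification tool, not a biological claim.

## 3-D DC localization

Centroids are mapped to their containing voxel (nearest voxel centre;
sub-voxel interpolation would suggest precision the segmentation does
not have). A vessel voxel ⇒ luminal (class 3); otherwise the exact
distance to the nearest vessel voxel decides adherent (≤ *d*₍adh₎,
class 2) vs interstitial (class 1). *d*₍adh₎ defaults to 5 µm — roughly
one dendritic-cell radius — because the visual "adherent to the outer
surface" criterion has no quantitative definition; it is configurable
and recorded in every output, and comparisons against visually scored
data should be read as functions of *d*₍adh₎.

## Track metrics

Definitions as in the README. Points worth stating:

* Directionality (*L*/*D*) and chemotactic index (*D*/*L*) are mutual
  reciprocals; both are computed exactly as defined and reported side by
  side because the two assay conventions are easily confused.
* yFMI is implemented as *D*ᵧ/*L*, the standard forward-migration index
  (bounded in [−1, 1]); the alternative reading *L*/*D*ᵧ is unbounded
  and was rejected.
* Undefined metrics (directionality when *D* = 0; CI/yFMI when *L* = 0)
  are NaN and excluded from cohort means with the reduced *n* reported.
* Inclusion filters use strict inequalities exactly as stated
  (*L* > 50 µm; duration > 10 min AND *L* > 60 µm), so boundary tracks
  (*L* = 50.0) are excluded.
* 3-D tracks use 3-D norms; crawling data are 2-D.
* Track y is the physical chamber axis (toward the attractant),
  decoupled from image pixel-y.

## Lymph-node compartment gating

Thresholds come from marker-negative reference populations: the
empirical *q*-quantile (linear interpolation between order statistics,
default *q* = 0.995 — the standard flow-cytometry-style choice when no
rule is stated) with a floor of 50 reference cells. Gating is
sequential: DAPI above threshold AND nuclear area within a configured
range (default 10–200 µm², a declared convention) → CD11c⁺ → FITC⁺CD11c⁺.
Raising any threshold can only shrink positive sets. Occupancy
percentages are computed over SCS + parenchyma; other compartments
(follicle, "other") are carried in the counts but excluded from the
ratio, which is undefined (NaN, flagged) when the parenchyma count is
zero. `compartment_intensity` divides summed signal by compartment area
(a.u./µm²), so identical fields in compartments of different size give
identical normalized means.

## Statistical layer

Two-tailed Student *t* (pooled variance unpaired; difference-based
paired), with closed-form p-values from the *t* distribution;
zero-variance degenerate cases raise rather than report p = 1 or 0.
One-way ANOVA (with two groups, F = t² exactly) and Tukey HSD, and
two-way condition × distance ANOVA with interaction on per-mouse
profile values, delegate to scipy/statsmodels. Normality is assumed, not
tested. Mixed-effects models are deliberately out of scope; the paired-t
pathway is the supported same-animal analysis.

## Synthetic-data generator

What it emulates, and the study conditions the defaults encode:

* **Vessel masks**: tubes (straight or wiggly polylines) rasterized by
  anisotropy-scaled distance to the centerline; anisotropic spacing is
  supported throughout because real stacks have coarser z than xy.
  Radii below one pixel are rejected.
* **Gradient fields**: *b + A·e^(−d/λ) + ε*, ε ~ N(0, σ²), clipped at 0
  (fluorescence is non-negative; the clipping rate is logged). The
  exponential form and the default λ = 15 µm give a field that decays
  over tens of µm, matching the reported reach of perilymphatic
  gradients (~50 µm).
* **Two-condition study** (`make_gradient_study`): amplitudes 800 vs
  200 a.u. with λ = 4.5 µm on a 120 a.u. background, 1 µm pixels,
  96×96 µm fields, 3 images × 4 mice per condition, pixel noise
  σ = 20 a.u., and a per-mouse background jitter (SD 8 a.u.) shared by
  that mouse's images. The short decay length makes the true profiles
  coincide beyond ~30 µm while differing 3-fold at the vessel; the
  mouse-level jitter puts the between-replicate variance at the mouse,
  so per-mouse tests behave like real replicate structure rather than
  pixel statistics.
* **Walks**: persistent random walks; the heading is a
  persistence-weighted mixture of the previous heading and a fresh
  uniform direction, and with probability `bias` the fresh draw is
  rejection-resampled until it points toward +y — rejection sampling
  keeps the speed distribution independent of the bias. Speeds are
  normal, clipped at 0; defaults (0.1 ± 0.03 µm/s, 30 s frames, ~30 min)
  mimic dendritic cells crawling at ~6 µm/min.
* **DC centroids**: sampled on voxel centres within margin-protected
  distance bands, so an independent distance computation must reproduce
  the generating class exactly; empty bands (margin ≥ *d*₍adh₎/2) and
  unreachable regions are rejected.
* **Cell tables**: marker intensities from normal positive/negative
  distributions clipped at 0, FITC positivity nested within CD11c⁺
  (labelled migratory cells are dendritic cells), deterministic positive
  counts (`round(frac·n)`) so ground-truth ratios are exact, an optional
  debris fraction exercising the DAPI/area gate, and independent
  negative-reference draws for gate derivation.

Every generator is bit-reproducible for a given seed; all draws in one
call flow from a single seeded generator.

**What passing tests do not show.** The generators emulate the
*statistical structure* of the inputs, not microscopy: no point-spread
function, no autofluorescence texture, no vessel-shape irregularity, no
segmentation error, no tracking gaps or misassignments. Agreement on
synthetic data validates the computations (distance transforms, binning,
averaging rules, gates, metrics, tests) — not the upstream imaging,
masking or segmentation steps, which remain the user's responsibility.

## Problem sizes

Verification workloads were sized for desk-scale runs: distance-oracle
checks on grids up to 32×32×8; gradient studies of 24 images at
96×96 px; 50 repetitions for decay recovery; 100 seeded runs for
condition discrimination; cohorts of 200–500 simulated tracks; 10⁴-cell
negative populations for gate calibration; 2000 null simulations for
type-I-error calibration. All scale linearly if larger checks are
wanted.

## Known limitations

* Bin 0 semantics depend on pixel pitch (see above); cross-study
  comparisons should fix `include_vessel_as_zero` consistently.
* The adherent class is threshold-defined; there is no ground-truth
  *d*₍adh₎.
* Gates calibrated to a quantile of negatives necessarily mislabel
  ≈ (1 − q) of true negatives; at q = 0.995 this is the designed 0.5%
  false-positive rate, visible in small, clean populations.
* `fit_decay` assumes a single-exponential decay with known background;
  it is not meant for profiles with mixed or plateauing components.
* Whether per-image vectors should be truncated to common support
  before replicate averaging is not standardized; this package averages
  per bin over the inputs in which the bin is defined and reports the
  per-bin *n*.
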