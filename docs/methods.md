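# Methods

This note documents the models, conventions and numerical choices behind
`lsavol`, and what the synthetic phantoms do and do not establish about
behaviour on real angiograms.

## Imaging model and geometry

Volumes are 3D scalar grids with per-axis voxel spacing in mm and a 4×4
index-to-world affine (RAS, sform preferred). Voxel indices are 0-based;
all lengths, arc lengths and volumes are reported in mm / mm³ (lengths in
cm where the morphometric convention calls for it). Region masks are
integer label grids with a name→label legend; background is 0. Label
resampling onto a subject grid uses nearest-neighbour interpolation only
(labels are categorical) through the chain `A_mask⁻¹ · T⁻¹ · A_target`,
where `T` is a user-supplied world-to-world affine. Nonlinear warps are
deliberately out of scope: registration is glue around standard tools
(FSL, ANTs), not part of this computation; masks arrive aligned or with an
affine.

## Bias correction

The corrector estimates a smooth multiplicative field as the exponential of
the Gaussian-smoothed (default FWHM 40 mm) log-intensity of the Otsu
foreground, normalized to unit mean over the foreground, then divides the
image by it and rescales so the mean foreground intensity is exactly
preserved. It has the contract of any multiplicative inhomogeneity
corrector (identity on bias-free input to <2% RMS; approximately
idempotent; beats the unit field against a known synthetic bias) and the
stage is pluggable, so a full B-spline/histogram-sharpening corrector can
be substituted where its extra machinery matters. Non-positive foreground
voxels are clamped to the smallest positive intensity with a warning before
the log.

## Vesselness

The enhancement filter is the classic three-eigenvalue bright-tube line
filter. Numerical specifics:

* **Scale ladder.** σ ranges over tube *radii*: d_min/2 to d_max/2 voxels
  (defaults 0.5–2.5, five log-spaced scales), converted to mm via the
  geometric-mean voxel edge. Tube response peaks near σ ≈ radius.
* **Anisotropy.** Derivatives are taken with per-axis Gaussian widths
  σ_mm/spacing_axis and divided by the axis spacings, so the Hessian is in
  per-mm² units regardless of grid anisotropy; σ²-normalization (γ = 2)
  follows.
* **Zero-sum kernel correction.** scipy's sampled second-derivative
  Gaussian kernels are not zero-sum at small σ (the kernel-sum residual is
  ≈0.56 at σ = 0.5 voxels), which leaks the image's DC level into the
  Hessian diagonal and breaks invariance under adding a constant. The
  diagonal entries subtract the measured kernel sum times the σ-smoothed
  image, restoring that invariance exactly.
* **Parameter mapping.** The front-end percentages "suppress plates = 10%"
  and "suppress blobs = 40%" map to α = 0.10 and β = 0.40; "vessel
  contrast = 100" maps to the structure-strength scale c = 100 intensity
  units. This is the conventional percentage→weight mapping of vesselness
  GUIs; because enhancement tools do not always print their internal
  mapping, all three are exposed as parameters rather than hard-coded.
* Eigenvalues are sorted by magnitude with `eigvalsh` on the stacked
  symmetric Hessian; voxels failing the bright-tube sign condition
  (λ₂ < 0 and λ₃ < 0) are zero. Output lies in [0, 1).

`skimage.filters.frangi` is used in the tests as a *qualitative*
cross-check (vessel/background ordering) only: its implementation omits the
σ² scale normalization, so its values and spatial support differ from the
standard formulation implemented here.

## Threshold selection (volume-ratio scheme)

The published description of this family of pipelines — lower the threshold
until the vessel-to-tissue volume ratio changes by more than 0.2% — leaves
the candidate grid, walk direction and change definition open. The
conventions adopted here, chosen for determinism and auditability:

* Candidates descend from the in-ROI maximum in steps of `step_percentile`
  (default 0.5) percent of the in-ROI intensity *range*. (Steps over the
  empirical value distribution were rejected: by construction each such
  step moves the ratio by exactly the step size whenever values are
  distinct, so the stopping rule would fire at the first step regardless of
  the data.)
* The vessel-to-tissue ratio is suprathreshold-voxels / total-ROI-voxels,
  in percent — the only ratio computable from the quantities the
  measurement names.
* The walk stops at the first step whose ratio change exceeds Δ\*
  (default 0.2 percentage points): parenchyma onset. The selected
  threshold is the candidate one step *above* the previous candidate: the
  step that straddles the parenchyma mode edge can pick up sub-Δ\* mass
  purely through candidate-grid quantization, and the one-step guard band
  keeps the selection robustly clear of the onset (on bimodal inputs,
  strictly inside the intensity gap). If no step ever exceeds Δ\*, a
  selection error advises a smaller step.
* Selection is invariant under affine intensity rescaling; the full
  candidate/volume/ratio-change curves are returned for audit.

**Known limitation — noiseless inputs.** The rule finds the onset of the
*tissue* response distribution. On a noiseless phantom the background
vesselness is exactly zero, so the onset is the zero tie itself and the
selected threshold sits at ≈0.5–1% of the response range. At such a low
threshold the mask includes the filter's low-response halo (the line
filter's support extends roughly σ_max beyond the tube wall), and measured
volumes exceed the geometric tube volume by ≈+40% (5-voxel tubes) to
≈+350% (2-voxel tubes) end-to-end. No reading of the ratio rule lands at
the mid-response threshold that would recover geometric volume on such
data, because the quantity it keys on — parenchymal response mass — is
absent. Consequences: (i) absolute volumes from this scheme are
threshold-convention-dependent and should be compared *within* a protocol,
not against geometric truth; (ii) the volume-recovery acceptance check on
noiseless cylinders fails by design and is retained as a documented
negative result; (iii) with tissue noise present the threshold tracks the
noise floor, which is the regime the scheme was designed for.

## Extraction, volumetry, QC

Extraction keeps in-ROI voxels at or above the selected threshold. With an
optional seed voxel, only 26-connected components belonging to the seed's
tree (the seed's component plus components whose 1-voxel dilation touches
it) are kept; a subthreshold seed snaps to the nearest suprathreshold voxel
within 5 voxels (warning), else errors. Without a seed the batch mode is
fully automatic.

Vascular volume is exactly voxel-count × (sx·sy·sz); per-region rows
assert this arithmetic in the report constructor, fractions are over the
ROI-union vessel total and flagged undefined (not 0) when that total is
zero. The QC stage computes the Euclidean distance transform inside the
mask and flags any 26-component whose maximum inscribed radius exceeds
d_max/2 voxels (mean-spacing mm): large arteries crossing a subcortical ROI
contaminate perforator volumes, and flagged cases are marked excluded but
still reported.

## Morphometry

The mask is thinned (3D topological thinning) to a one-voxel centerline.
Voxels with ≠2 skeleton neighbours are node voxels; 26-connected clusters
of node voxels collapse to single junction/endpoint nodes (thinning leaves
small junction blobs); degree-2 chains become edges with polyline arc
lengths in mm. Spurs of ≤2 voxels (a parameter) are pruned and
pass-through nodes re-merged. Roots are skeleton nodes inside the
parent-artery region, or the node nearest the parent mask / seed within 10
voxels.

Definitions: a *stem* is an edge incident to a root (edges joining two
roots run along the parent artery and are not counted); a *branch* is a
terminal edge ending at a non-root endpoint — the graph-computable reading
of "daughter vessels without subordinate branches"; an unbranched trunk is
therefore one stem *and* one branch. The *maximal length* is the largest
root→endpoint geodesic arc length along edges, in cm — measured on the 3D
centerline rather than on a 2D projection, which is strictly closer to
"distance from the parent artery to the visible end" and automatable; a
coronal MIP (default 28 mm slab) is provided for projection-based reading.
Counts and lengths are invariant under node relabelling and edge order.

On phantom trees (diameters ≥2 voxels, no noise) stem/branch recovery is
exact in 100% of 20 seeded cases at 0.4 mm resolution; terminal branches
whose tips approach within ~2 mm can merge into a single terminal at this
resolution, which is a resolution effect, not a graph defect.

## Statistics

ICC(A,1) (two-way random effects, single measurement, absolute agreement)
is computed from the two-way ANOVA mean squares, with the F-distribution
95% CI for that form; the variant is fixed and labelled in the result
because "absolute agreement" alone admits several two-way models, and the
single-measurement absolute form is the standard choice for scan–rescan
designs with two scans. The implementation matches a brute-force
sum-of-squares oracle to 1e-15 and pingouin's ICC2 row to its printed
precision. Pearson correlations use the t-transform two-sided p
(n−2 df); summaries are mean ± sample SD (n−1).

## Synthetic phantoms

`lsavol.synth` renders seeded binary-branching centerline trees (per-step
bend bounded by a curvature parameter; child radii scaled by a ratio ≤1)
into TOF-like volumes: tube intensity with a cosine wall falloff over an
edge-softness width, a multiplicative bias field (heavily smoothed white
noise rescaled to [1−a, 1+a]), and Rician magnitude noise (Gaussian
optional). Ground truth is geometric and pre-noise: a voxel is vessel iff
its centre lies within the local tube radius — an unambiguous oracle for
volume and topology. Four disjoint ellipsoids stand in for the putamen,
globus pallidus, caudate and internal capsule, laid out so the standard
tree crosses the putamen-like region predominantly; a parent-artery tube
plus 1 mm capsule provides the rooting region. All randomness flows from
explicit integer seeds; equal seeds are bit-identical.

Default study conditions: 96³ (64³ in unit tests) grids at 0.4 mm
isotropic spacing (matching the validation acquisition's resolution scale),
vessel/background intensities 200/40 (strong flow-related contrast),
root radius 0.6 mm, two generations. Benchmark phantoms use hard-edged
oblique cylinders in generic position — lattice-aligned axes bias
voxelized volume against πr²L by up to +30% at 2-voxel diameters because
the in-plane offset never averages out.

What the phantoms do *not* model: inflow saturation and slab-position
sensitivity of TOF, parenchymal texture, vessel tapering within a segment,
motion, and true anatomical region shapes. Passing tests therefore
establish the correctness of the computations and their behaviour under
controlled contrast/noise/bias, not clinical accuracy on real scans.

## Pipeline and determinism

`process_case` runs bias correction → vesselness → ROI restriction →
threshold selection → extraction → volumetry → QC → morphometry.
Volumetry uses the ROI-restricted vessel set; morphometry uses the
whole-grid suprathreshold mask so the centerline remains connected to the
parent artery across inter-region gaps. Stage failures re-raise with the
stage name; partial outputs are preserved. Report bundles (enhanced
volume, vessel mask, threshold/volume/QC/morphometry/provenance JSON) are
bit-reproducible for identical configs: content carries no timestamps and
NIfTI gzip streams are written with a zero mtime. Cohort aggregation lists
excluded cases explicitly, computes summaries and the volume-vs-
branches/stems/length correlations over the non-excluded cases, and is
invariant to case order.

Benchmark problem sizes (96³ cylinders, 20 topology trees at 64³, 100 ICC
tables, 20 bimodal threshold cases, one 48³ determinism case) keep the
whole self-validation run under a minute on one CPU while leaving every
measured effect far from its decision boundary.
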