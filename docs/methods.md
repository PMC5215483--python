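# Methods

This note documents the measurement model, the synthetic-data generators used
for validation, the default parameters and why they were chosen, and the
numerical decisions that matter for reproducing results.

## 1. Array-tomography measurement model

A stack is an ordered ribbon of 70 nm physical sections, each imaged as a
multi-channel fluorescence plane at 0.1 μm/px (63× objective scale). Voxels
are therefore strongly anisotropic: 0.1 × 0.1 × 0.07 μm.

**Alignment.** The stage never returns to the same position between sections,
so each section carries a small rigid offset. We register neighbor to
neighbor with plain FFT cross-correlation and accumulate the pairwise offsets
(section 0 is the fixed reference). The correlation peak is searched only
within ±15 px: stage jitter is physically bounded, and an unconstrained
global peak can lock onto spurious coincidences when consecutive sparse
sections share few objects. Applied shifts are integer pixels, so voxel
values are moved, never interpolated; an optional subpixel mode parabolically
refines the pairwise estimates before the accumulated offset is rounded.

**Thresholding and despeckling.** Channels are binarized per section
(mirroring per-image acquisition), by default at a fixed level of 0.5 — half
the rendered blob amplitude, ≈3.3σ above the background noise. The binary
mask is then despeckled: any foreground pixel with no 8-connected foreground
neighbor in its own section is removed. Real puncta are diffraction-limited
blobs several pixels wide per section, while shot/read noise produces lone
suprathreshold pixels; a lone noise voxel is worse than wasted volume,
because one sitting directly above a single-section artifact would extend its
apparent section span and defeat the artifact filter (section 4).

**Punctum detection.** Foreground voxels are grouped by 26-connected 3D
labeling. Components smaller than 4 voxels are discarded (a real punctum of
0.25 μm radius covers ≥4 suprathreshold voxels per section at the default
threshold). Each punctum records its voxels, volume, centroid (μm), and
section span.

**Single-slice artifact removal.** Staining precipitate and section-surface
artifacts live on exactly one physical section, whereas a real synaptic
punctum (≈0.5 μm across) spans 2–3 consecutive 70 nm sections. Objects with
section span < 2 are removed. This is the defining quality-control step of
array-tomography synapse counting.

**ROIs, density and colocalization.** Analysis windows are 10 × 10 μm columns
through the full stack depth. A window is *near* if its minimum in-plane
distance to the plaque border is < 20 μm and *far* if > 40 μm; windows in the
20–40 μm transition band are excluded, as are windows touching the alignment
margin. Punctum density is the count of punctum centroids inside the column
divided by the column volume (10 · 10 · n_sections · 0.07 μm³).
Colocalization is the fraction of a window's puncta having at least one voxel
that is also foreground in the (despeckled) Aβ channel mask; it is undefined
(None/NaN) for windows with no puncta.

## 2. Plaques, neurites, cells

**Plaque morphometry (2D histology).** Plaques are segmented by thresholding
and 8-connected labeling with a minimum-area filter. *Burden* is the
percentage of the cortex mask covered by dense cores. *Halo thickness* is the
mean Euclidean distance to the image background over the diffuse-channel
border pixels, measured from the core; equivalently, the average widening of
the diffuse (total-Aβ) object over the dense (ThioS) core. *Dystrophic
neurites* are 2D components of the dystrophy mask with equivalent diameter
> 2.5 μm whose (rounded) centroid lies on the plaque core.

**Neurite metrics.** A trace is an ordered (y, x) polyline in μm. The
*curvature ratio* is total segment length divided by end-to-end chord
distance (1.0 for a straight line; (θ/2)/sin(θ/2) for a circular arc of angle
θ; π/2 for a semicircle). Traces of length ≤ 20 μm are not measured
(`TraceTooShort`) — shorter fragments cannot be traced reliably. *Distance to
plaque* is the mean of three samples: both end points and the arc-length
midpoint, each measured to the nearest plaque border pixel.

**Cell counting.** Cells are 3D points. Counting boxes are 50 × 30 × 30 μm
(depth × width × height) and half-open ([origin, origin+size)), so tiled
boxes partition space with no double counting. The near box must lie within
30 μm of the plaque border without overlapping the core; the far box is
placed ≥ 100 μm from the border in the same row band ("same cortical layer").
Astrocytes are counted in a 30 μm ring around the plaque edge, excluding
points on the core itself.

## 3. Statistics

The animal is the statistical unit: per-ROI or per-section values are first
aggregated to one summary per animal (mean for approximately normal
within-animal distributions, median otherwise, per Shapiro–Wilk at α = 0.05;
animals with fewer than 3 values are flagged). Group comparisons test
normality of the residuals from group means (Shapiro–Wilk, α = 0.05):
parametric branch → Student's t (2 groups) or one-way ANOVA with Tukey HSD
post hoc (≥3 groups); nonparametric branch → Mann–Whitney U or
Kruskal–Wallis. Two fully identical groups stay on the parametric branch
(t = 0, p = 1); the nonparametric fallback fires when a group has zero
variance but the data are not all identical (the t statistic would be
infinite). Every decision is recorded in the result's `decision_trail`.

The genotype × plaque-distance analysis is a two-way ANOVA on per-animal
near/far summaries: ordinary least squares with both main effects and the
interaction, type-II sums of squares.

**A calibration caveat.** `simulate_two_way_summaries` has an
`animal_cv` knob giving each animal a shared baseline across its near and far
summaries (default 0.15, a realistic between-animal coefficient of variation
for density means). Under that correlation structure the plain two-way
ANOVA's genotype test is anti-conservative (≈15% false positives at
α = 0.05), because near/far pairs from one animal are not independent —
modeling within-animal correlation (mixed models) is out of scope here.
Calibration checks therefore use the planted world, `animal_cv = 0`, which
matches the image generator: every simulated animal has identical biology and
only sampling/measurement noise varies. With real data exhibiting strong
between-animal variation, a mixed-effects model would be the appropriate
refinement.

## 4. Synthetic generators and ground truth

One root seed drives independent spawned sub-streams (placement, flags,
jitter, noise), so a given seed yields byte-identical outputs and changing
one stage's draw count cannot silently shift another's.

**Array-tomography stacks.** Synaptic puncta are isotropic 2D Gaussian blobs
(σ = radius/2 per axis, radius 0.25 μm → σ = 1.25 px) rendered at full
amplitude on each of 2–3 consecutive sections; single-section artifacts are
the same blobs on exactly one section. Blob centers are planted uniformly in
a margin-inset region (margin ≥ jitter + blob footprint + 1 px) so that no
planted object can leave the frame under jitter; *planted densities are
defined as planted counts over this inset volume*, and the same inset volume
is used for truth bookkeeping. Optional hard-core separation
(`min_separation_um`) guarantees each planted object resolves as its own
connected component in validation scenarios, enforced across puncta *and*
artifacts of the same channel. With `exact_counts=True` the number of objects
is round(density × volume) instead of Poisson — used where a validation
scenario fixes a count ("200 synapses"). Per-section rigid shifts are drawn
uniformly in ±`section_jitter_px` and applied to all channels; Gaussian noise
(sd 0.15) is added last.

Around a plaque (dense disc rendered in its own channel plus the Aβ channel),
synapse intensity is multiplied by a radial profile: 1 − loss (0.6) from the
border to 20 μm, recovering linearly to 1.0 by 40 μm; colocalization
fractions interpolate similarly from 0.30 (near) to 0.10 (far). Planted
region densities (`true_densities`) are computed from realized counts and
exact region volumes, so recovery tests compare against what was actually
planted, not the expectation.

**Histology scenes.** Plaque sections render non-overlapping dense cores
(channel 0) and the same cores widened by an annular halo (channel 1), with
per-plaque rasterized areas and scene burden recorded. Neurite generators
emit straight lines, circular arcs (analytic curvature truth), or bounded
random walks (truth from the realized path). Cell fields are homogeneous
Poisson point processes with intensity multiplied by (1 − depletion) within
30 μm of the plaque border, with expected counts and exact region volumes
recorded.

## 5. Default parameters and rationale

| Parameter | Default | Rationale |
| --- | --- | --- |
| pixel size | 0.1 μm/px | 63× objective scale of array tomography |
| section thickness | 0.07 μm | the method's defining 70 nm ultrathin sections |
| far synapse density | 0.6 /μm³ per channel | order of cortical synapse density seen by AT |
| near loss fraction | 0.4 | the planted peri-plaque effect size |
| coloc fraction near/far | 0.30 / 0.10 | oligomeric Aβ concentrates at near synapses |
| artifact rate | 0.3 /μm³ | artifacts are common but a minority of detections |
| punctum radius | 0.25 μm | diffraction-limited punctum (σ = radius/2) |
| amplitude / noise sd | 1.0 / 0.15 | SNR ≈ 6.7, a clean but non-trivial image |
| section jitter | 3 px (5 px in the alignment validation) | sub-μm stage repeatability; ±5 px is the stress case |
| detection threshold | 0.5 (≈3.3σ) | half-amplitude; wide margins both against noise and against losing blob pixels |
| min punctum size | 4 voxels | one blob section carries ≥4 suprathreshold voxels at 0.5 |
| max alignment search | ±15 px | bounded stage jitter; excludes spurious global peaks |
| ROI window | 10×10 μm | the sampling unit for density |
| near / far | <20 μm / >40 μm | loss zone vs unaffected reference, with a transition buffer |
| dystrophy floor | 2.5 μm equivalent diameter | distinguishes dystrophies from puncta/debris |
| neuron boxes | 50×30×30 μm, near ≤30 μm / far ≥100 μm | standard cell-density sampling frames |
| astrocyte ring | 30 μm from plaque edge | the reactive-astrocyte zone |
| trace floor | 20 μm | minimum reliably traceable neurite length |
| two-way sim animal CV | 0.15 (0 for calibration) | realism knob vs planted-world calibration, §3 |

Validation problem sizes are the package's own choice: the near/far plaque
scenario uses an 80 × 80 μm plane (800 × 800 px at 0.1 μm/px, 10 sections)
with a 6 μm-radius core near one corner, the smallest geometry in which both
<20 μm and >40 μm zones admit multiple 10 × 10 μm windows; artifact and
colocalization scenarios use 256² and 200² planes with exact counts and
hard-core separation so set-recovery is well defined.

Two validation-scenario isolations are deliberate. (1) The artifact-filter
scenario disables stage jitter: registration of such ultra-sparse stacks
(55 tiny blobs, few shared per section pair) has a 1–2 px residual, which is
a property of alignment — validated separately on dense stacks — and would
confound the filter-exactness property. (2) The despeckle step exists because
a single ≥3.3σ noise voxel adjacent to an artifact on the neighboring section
would otherwise extend its section span; despeckling reduces that mode to
needing two adjacent suprathreshold noise pixels (probability ~10⁻⁴ per
10-stack experiment) while leaving real blob footprints untouched.

## 6. Numerical choices

- Connected components via `scipy.ndimage.label` (26-connectivity in 3D,
  8-connectivity in 2D); a brute-force flood-fill oracle in the test suite
  cross-checks it exactly on random stacks.
- Alignment cross-correlation via real FFTs; the peak is selected inside the
  ±15 px lag window only. Integer shifts preserve voxel values exactly, which
  is what makes exact shift recovery and byte-identical reruns possible.
- Distances to plaque borders use the exact Euclidean distance transform
  (`distance_transform_edt`) with border pixels defined by binary erosion
  (frame edge counts as object interior).
- Statistics use `scipy.stats` (Shapiro–Wilk, t, Mann–Whitney, Kruskal,
  one-way ANOVA) and `statsmodels` (OLS + `anova_lm(typ=2)`, Tukey HSD) —
  established implementations rather than re-derivations.
- All randomness flows from `numpy.random.default_rng` seeds; generators
  spawn sub-streams from one root seed. CSV outputs are byte-identical for a
  given seed.

## 7. Generator realism and limitations

The generators are designed for *validatable* realism, not photorealism:

- Puncta are ideal Gaussian blobs at constant amplitude; real puncta vary in
  brightness, shape and axial profile, and partial-volume effects at section
  boundaries are not modeled.
- Noise is i.i.d. Gaussian; real images have structured background,
  autofluorescence and shot noise.
- Stage jitter is a pure integer translation; rotation, tissue compression
  and section loss are not modeled.
- The plaque is a perfect disc and the loss profile is a deterministic radial
  ramp; real plaques are irregular with heterogeneous halos.
- Animals are biologically identical in the image generator (no random
  effects); between-animal variation is modeled only at the summary level
  (§3).

These simplifications are what make exact ground-truth joins, closed-form
geometry checks and calibration claims possible; conclusions about the
*pipeline's correctness* transfer to real data, while absolute performance
(e.g. detection completeness at a given SNR) does not.
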