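# Methods

This note documents the models implemented in `nichefab`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want to know.

## Calibration state space and kernel interpolation

The printable material properties — Young's modulus E (kPa), linewidth W
(µm), and bound-conjugate signal (a.u.) — are tabulated against two
fabrication coordinates: the unified monomer–photoinitiator index
(`peg_pi`, dimensionless, on the % w/v monomer scale, valid on
|peg_pi − 50| ≤ 40) and the laser focus offset (`focus_z`, mm). Properties
at arbitrary coordinates are Nadaraya–Watson kernel-regression estimates
over the calibration records. Coordinates are normalized by fixed ranges
(40 for the index, 6 for focus) and weighted by a Gaussian kernel of
bandwidth 0.1 in normalized units.

Two kernel forms are provided because the weight definition admits two
readings:

* `product_gaussian` (default): the two normalized differences enter as a
  2-D squared Euclidean distance. This is the standard bivariate kernel; it
  is a proper metric weight and is maximal exactly at a record's
  coordinates.
* `literal_summed`: the signed normalized differences are summed before a
  single division by the bandwidth. This form is non-metric — opposite-signed
  offsets cancel — and is retained only for comparison.

The 1/(0.1·2π) prefactor cancels in the weighted-mean ratio; it is kept in
the weight vector for fidelity but is documented as inert (tests verify
solution invariance under rescaling it).

Interpolated values are convex combinations of the record values, hence
always bounded by the record extrema. Bound-conjugate estimates optionally
restrict the records to the nearest tabulated conjugate concentration
(nearest-neighbor matching on the conjugate axis) because the conjugate
dimension is sampled too sparsely for kernel smoothing, while E and W are
insensitive to it.

## Inverse design

Desired properties (E_des kPa, W_des µm) are mapped to fabrication
coordinates by minimizing the dimensionless objective

    ((E_des − Ê(x,z))/E_des)² + ((W_des − Ŵ(x,z))/W_des)²

with derivative-free Nelder–Mead simplex search (the objective is smooth
but can be multimodal over sparse, noisy tables). Starts are 8 seeded
Latin-hypercube points over the record bounding box plus the three
calibration grid coordinates with the lowest objective; the deterministic
grid-seeded starts guard against local minima introduced by calibration
noise at negligible cost. Ties (objective within 1e−12) break to the
smallest |focus_z| then the smallest index. Targets are validated against
the characterized envelope (E 2–20 kPa, W 40–300 µm, conjugates ≤ 4 mM)
before solving.

The index splits into physical concentrations on the ellipse
((peg_pi − 50)/40)² + ((pi_conc − 0.5)/0.35)² = 1 with peg_conc = peg_pi.
Both roots are positive over the domain; the default upper branch
(pi_conc = 0.5 + 0.35·√(1 − t²)) makes the photoinitiator rise with the
index mid-range, consistent with stiffer prints requiring more initiator.
The lower branch is selectable. At the domain apexes (peg_pi = 10 or 90)
both branches give pi_conc = 0.5 exactly.

Laser power is fixed at 100 % PWM. The scan velocity is emitted as the
constant 100 with an explicit unit field defaulting to mm/min; the unit is
carried explicitly (and is overridable) because the hardware operated at a
fixed setting whose reported unit is inconsistent across sources, and
downstream consumers must not guess.

## Print-plan compilation

Designs are named regions — filament polylines or axis-aligned rectangles in
a lower-left-origin, y-up, µm niche frame — each with a target property set.
Compilation solves each region by inverse design, rasters rectangles as
serpentine paths along x with line spacing equal to the achieved linewidth
(line centers inset by half a linewidth and spaced to guarantee full
footprint coverage), and groups segments by identical photoresist
composition (fields compared at 1e−9). All segments of a composition are
printed contiguously, so the number of resist exchanges equals the number
of distinct compositions minus one — optimal for the contiguity objective.
Batches are ordered stiff-to-soft (descending monomer concentration); the
order is otherwise arbitrary. Coverage is verified geometrically (shapely):
paths dilated by half the linewidth must cover ≥ 99 % of the region
polygon. Plans serialize to versioned JSON plus an optional plain-text
motion listing (one vertex per line) for portability; no vendor G-code is
emitted.

Note that regions differing only in stiffness still require distinct
resists: stiffness is controlled through the monomer–photoinitiator index,
so a stiffness ladder compiles to one batch per rung, whereas regions
differing only in focus share a batch.

## AFM force spectroscopy

Forces follow the Sneddon law for a conical indenter,
F = (2/π)·tanθ·E/(1−ν²)·δ², with θ = 18° (pyramidal-lever cone
approximation) and ν = 0.5 by default (incompressible hydrogel; the ratio
is configurable). Units are chosen so no conversion constants appear:
E in kPa and δ in µm give F in nN directly.

For thin gels bonded to rigid glass, the finite-thickness bottom-effect
cone correction multiplies the Sneddon force by the 4-term bonded-sample
series 1 + 0.721χ + 0.650χ² + 0.491χ³ + 0.225χ⁴ with χ = δ·tanθ/h. These
are the widely reproduced bonded-cone coefficients (the leading one equals
4·1.7795/π²); the series order is fixed at 4. The correction converges to
the uncorrected law as h → ∞ (tests verify agreement within 1 % at
h ≥ 100 × max δ) and omitting it on a 10 µm gel overestimates E by ≈ 7 %
at these acquisition settings.

The indentation is the piezo travel past contact minus the cantilever
deflection, δ = (z − z₀) − F/k (tip–sample separation correction, on by
default, toggleable). Because the measured force provides the deflection,
the contact model is linear in E and the modulus fit is a closed-form
one-parameter least squares over the post-contact samples — no iterative
fitting is needed.

Contact-point detection minimizes the total squared residual of the
piecewise model (flat baseline before z₀, contact law after, both fitted)
over a coarse grid of every 5th sample followed by bounded scalar
refinement between the best candidate's neighbors; ties break to the
smaller z₀. On noise-free curves this recovers z₀ well below one sample
spacing; at 0.05 nN noise the median error is a fraction of a percent of
the indentation depth range.

Quality control targets the force discontinuities produced by slipping
samples: sample-to-sample force steps are detrended with a 7-point median
filter (so the smooth post-contact rise does not register) and the largest
detrended step is compared against jump_sigma (default 6) times a robust
noise scale, 1.4826·MAD of the pre-contact steps. The scale is floored at
1 pN so noise-free curves are not flagged by numerical jitter; a jump
exactly at the threshold rejects (≥ rule). Fits are additionally
`rejected_fit` when the relative residual exceeds 5 % (configurable) or no
post-contact samples exist.

Simulation solves the implicit force–deflection coupling F = S(d − cF) by
damped fixed-point iteration (contractive in the soft-gel/soft-lever
regime used here), terminates at the 10 nN threshold force, and adds
Gaussian force noise; slips are injected as a step subtracted from all
samples past a given piezo position. Defaults mirror standard acquisition:
0.5 µm/s approach, 10 nN threshold, 0.03 N/m lever, 10 nm sampling.

## Image quantification

**N:C ratio.** Per nucleus: mean marker intensity over the nucleus's label
voxels divided by the mean over that cell's non-nuclear cytoplasm. The
cytoplasm mask minus all nuclei is partitioned by nearest nucleus (Voronoi
partition on the Euclidean distance transform, respecting anisotropic
voxel sizes); nuclear voxels are excluded from the cytoplasmic term. Cells
with an empty cytoplasm partition are dropped and counted in the report.
The ratio is invariant to positive rescaling of the channel.

**fat:cyto.** Lipid voxels (Otsu threshold computed within the cytoplasm
mask, or a fixed threshold) over total cytoplasm voxels, per field of view.

**Alizarin score.** mean(R)/mean(R+G+B) over an ROI polygon of a color
image: 1.0 for pure red, exactly 1/3 for any achromatic ROI.

**Expression maps.** Per-nucleus intensities are normalized per replicate
and channel — default: 1st–99th percentile rescaled to [0, 1] and clipped
(min–max selectable); the percentile default makes the pooled maps robust
to per-replicate staining outliers, since the true normalization used for
such plots is generally underdocumented. Each replicate carries a 2-D
affine registering its coordinates into the common niche frame; pooled
cells outside the niche bounding box are excluded and counted, so pooled +
excluded always equals the input cell count. The surface is the binned
mean of normalized intensity (default 50 µm bins), with empty bins flagged
rather than imputed. Per-region summaries (n, mean, raw values) are
computed when region rectangles are supplied; cross-region inference
(one-way ANOVA + Tukey HSD) is delegated to scipy/statsmodels behind a
thin wrapper.

**Segmentation.** A deterministic stand-in segmenter (Gaussian smoothing,
Otsu threshold, size filter, distance-transform watershed) is provided for
label-free inputs; any externally produced integer label image — e.g. from
a star-convex neural segmenter — is accepted wherever labels are expected.

**4PL fits.** y = bottom + (top − bottom)·xʰ/(ec50ʰ + xʰ), least squares
with bounded parameters (hill ∈ [0.1, 10], ec50 within 0.01–100× the dose
range). Decreasing responses are fitted on the negated data and mapped
back, so top ≥ bottom always holds with a signed hill. Constant responses
return a flagged flat fit instead of failing.

## Synthetic generators

The generators emulate the *structure* of the characterization data, not
any measured dataset. The calibration forward model is:

* E = E_base + (E_max − E_base)·S(u)·exp(−c·|z|), u = (peg_pi − 10)/80,
  S(t) = 3t² − 2t³, with E_base = 2, E_max = 20 kPa, c = 0.01/mm. The
  smoothstep gives a strictly monotone rise with gentle plateaus at both
  ends of the index range; the plateaus keep kernel interpolation accurate
  at the envelope boundaries, where a steep profile would otherwise be
  biased inward by edge smoothing and make boundary targets (2 and 20 kPa)
  unattainable on the interpolated surface.
* W = 40 + 65·|z| + 0.6·(peg_pi − 10) µm, with the characterization using
  one-sided focus offsets z ∈ [0, 4] mm. One-sided defocus keeps the
  linewidth trend linear (no kink at the waist), again for edge-stable
  interpolation; linewidths at the far corner reach ≈ 350 µm so that the
  advertised 40–300 µm envelope is interior to the calibration hull.
* Bound signal is proportional to the conjugate concentration with a weak
  index dependence; E and W are exactly independent of conjugate
  concentration, mirroring the characterization result that conjugate
  loading does not alter modulus or linewidth.

Default grid: 17 index levels × 13 focus levels × 3 conjugate levels
(663 records) with 5 % multiplicative noise. Image scenes place
non-overlapping ellipsoidal nuclei (3×5×5 voxels) in cytoplasmic
ellipsoids (5×9×9) on a jittered grid at 1 µm isotropic voxels, with
Poisson shot noise plus 2 ADU Gaussian read noise; lipid droplets are
2-voxel-scale blobs accreted until the requested cytoplasm fraction is
reached, and the achieved fraction is reported as truth. Force-curve and
dose-response generators delegate to the corresponding forward models with
Gaussian noise (0.05 nN force noise, 0.05 response noise by default).

What the generators do **not** emulate: optical point-spread functions,
photopolymerization kinetics, cantilever drift or adhesion, cell shape
irregularity, marker bleed-through, or segmentation errors (analysis tests
use the generated ground-truth labels; the stand-in segmenter is tested
separately). Passing recovery tests therefore demonstrate the correctness
of the estimators under the stated noise models, not robustness to every
artifact of real microscopy or AFM data.

## Problem sizes and determinism

The test suite and the acceptance script use: 100 random in-hull targets
for the inverse-design round trip (sampled in the interior of the
calibration hull, ≥ 0.5 mm from the focus edges and ≥ 5 index units from
the index edges, rejecting targets outside the advertised envelope);
1000-point ellipse sweeps; 50 seeded force curves per modulus level
(2.5/7.5/20 kPa); 100 slip and 100 clean curves for QC; 25 cells per N:C
level and 16-cell fields per lipid fraction; two 25-cell replicates for
map pooling; and 50 seeded dose-response datasets. All randomness flows
from explicit seeds; every generator is bit-reproducible for a fixed seed.

## Known limitations

* Nadaraya–Watson interpolation is biased near the calibration hull
  boundary (kernel mass truncates); targets at the extreme corners of the
  envelope are recovered with a percent-level, not arbitrarily small,
  error. The round-trip acceptance surface is the interpolated state
  space, as it is for the physical workflow.
* The bottom-effect series is a finite (4-term) expansion; for χ ≳ 0.5
  (very thin gels or deep indentation) it under-corrects.
* The Nelder–Mead multistart gives no global-optimality guarantee; the
  deterministic grid seeding makes misses rare on the tables tested but a
  pathological calibration table could still defeat it.
* Print plans are single-layer: 3-D lattice architectures are
  representable as designs but no z-stacking logic is generated.
* The slip-QC detector assumes slips are step-like at the sampling
  resolution; slow partial slips spread over many samples are not flagged.
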