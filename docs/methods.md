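# Methods

This note documents the models behind `nanoburden`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions that affect results.

## Study system

The pipeline targets internal-dose data from a 28-day nose-only rat
inhalation study of two nanoplastics at up to 50 mg/m³: Nile-Red labelled
polystyrene (primary particle ~89 nm, quantified in formalin-fixed tissue
slices by confocal fluorescence microscopy) and polyamide-6 (primary
particle ~67 nm mass-median, quantified in HFIP extracts of dried tissue
by pyrolysis-GC/MS using caprolactam, m/z 113, as marker fragment). Main
sacrifice groups: one day (MG), ~5 weeks (PEG1) and ~13 weeks (PEG2)
after the last exposure.

## Confocal quantification

### Imaging geometry

Stacks are (z, y, x) arrays with anisotropic voxels: 120 nm lateral
pitch, 300 nm z-step (150 nm in the high-sensitivity preset), lateral
field 246 µm × 246 µm, axial range ~100 µm. All sizing uses physical
voxel volume (0.12 × 0.12 × 0.30 µm³ = 0.00432 µm³ by default); voxel
counts alone never enter a diameter.

### Segmentation

Two backends produce a 26-connected label field from the fluorescence
channel:

* **Threshold** — absolute, or Otsu. Foreground occupies ~0.05% of
  voxels in realistic stacks, so a plain global Otsu collapses into the
  background mode; the `"otsu"` method therefore computes the Otsu
  threshold over voxels above a robust background floor
  (median + 3·MAD), a standard variant for extremely unbalanced classes.
* **Trained pixel classifier** — multi-scale Gaussian features (raw
  intensity, smoothed at 1/2/4 voxel scales with axially rescaled sigmas,
  gradient magnitude) fed to a small random forest trained on labelled
  voxels. This emulates interactive classifier tools used for tissue
  stacks; a "more sensitive, less separative" remote-organ preset is an
  absolute threshold just above the noise floor without any separation
  post-processing.

Two emitters closer than the lateral resolution (~200 nm for a 1.40 NA
objective) merge into one object, as in the real acquisition.

### Sizing and the PSF-inflation correction

Each object's volume is its voxel count × voxel volume; the equivalent
sphere diameter is (6V/π)^(1/3). Because the point-spread function
(modelled as a separable Gaussian, FWHM ≈ 200 nm lateral / 500 nm axial,
σ = FWHM/2.355) inflates apparent sizes, each segmented object is
re-thresholded before sizing at

&nbsp;&nbsp;&nbsp;&nbsp;t = background + h · (object peak − background).

For a blurred flat edge h = 0.5 recovers the true boundary exactly. For
spheres near the PSF scale the surface sits *below* half-max (the
boundary curves away from every surface point), and h = 0.5 undersizes
0.6–1.8 µm spheres by ~24% in volume. The default h = 0.4 was calibrated
on synthetic spheres spanning that range at the reference PSF and gives
volume recovery ratios of 0.94–1.02. `h` is exposed as
`refine_height`; for large smooth objects 0.5 is the better choice.

A consequence: sub-resolution particles, which appear as ≥ 6-voxel blobs
in a sensitivity-driven segmentation, shrink to roughly the PSF half-max
ellipsoid (~3 voxels at the reference geometry) after refinement. The
apparent single-particle diameter therefore depends on where in the
pipeline it is measured — consistent with the ambiguity between the
0.29 µm average apparent diameter of single particles and the 0.37 µm
implied by six minimum voxels; the package documents rather than forces
either value.

### Noise filtering, edges, concentrations

Objects spanning ≤ 5 voxels are discarded as noise (`min_voxels=6`, the
printed rule). Objects touching any of the six stack faces are flagged
and excluded from concentration totals (the face rule is applied to all
six faces; the source wording says only "edges"). Concentrations are
reported per (100 µm)³ = 10⁶ µm³. The scanned volume defaults to the
nominal stack extent (`"nominal"`); a `"detected"` mode truncates the
depth at the deepest retained object for stacks limited by fading
contrast. Organ burdens scale the mass concentration by the organ volume
(1 mL = 10⁶ reporting blocks): 0.42 ng/(100 µm)³ × 10 mL lung = 4.2 mg.
The lymph-node figure from the rounded per-animal table is 14.4 µg
(0.48 ng/(100 µm)³ × 0.03 mL); the study's 14.5 µg evidently derives
from unrounded per-animal means.

### Mass model

m = V · φ · ρ with packing density φ = 0.64 (irregular random close
packing of primary particles) and ρ = 1.05 g/cm³ for polystyrene
(helium pycnometry). The packing correction applies uniformly to all
retained objects. The smallest quantifiable agglomerate in the study
workflow (0.0004 µm³, d ≈ 0.091 µm) in the 0.43 mm³ examined volume
corresponds to a detection volume fraction of 9.3 × 10⁻¹³.

## Synthetic confocal stacks

The generator voxelizes spherical emitters (per-axis adaptive
subsampling with sub-grid spacing ≤ r/4, conserving the integrated
signal to ≪ 1%; sub-voxel spheres deposit their signal analytically),
convolves with the Gaussian PSF, applies an exponential depth fade,
adds an autofluorescence background, and corrupts with Poisson shot
noise (via `shot_scale`, intensity units per count) plus Gaussian read
noise. The default fade length, 53/ln 4 ≈ 38.2 µm, puts contrast at 25%
at 53 µm depth — the average depth to which objects remained detectable
in lung tissue. Seeds are mandatory arguments; generators never touch
global random state and are bit-reproducible given (spec, seed).

Not emulated: refractive-index-mismatch aberrations (only their net
depth-fade effect), optical ray tracing, the scattering-contrast
channel, non-spherical agglomerate shapes, and spatial clustering of
agglomerates in macrophages. Passing recovery tests therefore
demonstrate correctness of the measurement chain on well-separated
spherical objects, not performance on densely clustered real tissue.

## Py-GC/MS quantification

Peak areas are modelled as linear in crucible analyte mass; pyrolysis
physics and chromatography are not modelled (the marker-fragment
identity is metadata). Calibration is OLS with a free intercept (it
absorbs instrument baseline); the residual SD uses n − 2 degrees of
freedom. Standards follow the study's two-step dilution (≈ 49 and 62 mg
stock in 25 mL HFIP, 50 µL to 10 mL, 2–300 µL pipetted → 20–1140 ng for
lymph nodes, 37–3700 ng for lungs; which stock maps to which organ is
not recorded, so the ranges are matched by the printed nanogram values).

Organ mass = crucible mass × (extract volume / aliquot volume); per-gram
values divide by wet organ mass. Areas below the fitted intercept report
0 with a below-range flag. Group means over censored (< LOD) values use
LOD/2 substitution by default (configurable to exclusion) — never zeros.

**Detection limits.** LOQ = lowest calibrated mass × dilution factor
(20 ng × 75 = 1.5 µg per lymph node at the 3 mL / 40 µL dilution). The
exact LOD recipe behind the reported 1.2 µg is not stated; the package
uses LOD = (lowest mass − margin) × dilution with the default margin set
to 20% of the lowest mass, the value that reconciles the reported
LOD/LOQ pair exactly. With replicate SD available the margin can be
k·SD (k configurable); without it LOD falls back to LOQ with a warning.

## Aerosol metrics

Gravimetric concentration = filter mass gain / (flow × time), with the
study's 3 L/min and 40/120 min sampling. The impactor model partitions a
lognormal aerosol at the 8-stage Marple cutoffs (21, 15, 10, 6.5, 3.5,
1, 0.7, 0.4 µm); the backup filter is counted as the sub-0.4 µm stage so
mass closes. MMAD/GSD come from an unweighted linear fit of
Φ⁻¹(cumulative undersize fraction) on ln(cutoff): MMAD =
exp(−intercept/slope), GSD = exp(1/slope); fractions at exactly 0 or 1
are excluded. Whether the study's values came from the same regression
or instrument software is unknown; round-trip tests use the package's
convention. SMPS count concentration and geometric mean diameter are
pass-through instrument averages, not refit.

Numerical care: stage fractions and cumulative tails are accumulated
from the small side of each normal tail (CDF for the lower, survival
function for the upper), and the probit of fractions above one half is
evaluated through the opposite tail. Without this the round trip
degrades to ~10⁻⁴ relative error at small GSD from catastrophic
cancellation near cumulative fractions of 1.

## Dosimetry and clearance kinetics

Ventilation rate = 0.8 L/min/kg × body weight, kept unrounded
internally (0.216 L/min for a 270 g male; the display convention rounds
to 0.22, but reproducing the 77.8 mg applied mass requires the unrounded
value). Exposure time defaults to 360 min/day × 20 days (6 h/day,
5 days/week, 4 weeks). Deposition fraction = 100 × lung burden / applied
mass; the deposition predicted by the MPPD model for these aerosols
(6.8% / 6.9%) is stored as a comparison constant, not recomputed.

Clearance is first-order per phase: with exactly two points,
λ = ln(N₁/N₂)/Δt in closed form; with more, log-linear least squares.
Biphasic fits split at user-supplied boundary days (the 5-week sacrifice
at day 35), matching interval-wise calculation; boundaries are not
change-point-detected. Every fitted phase satisfies t½·λ = ln 2 to
machine precision, and the piecewise prediction is continuous across
boundaries. Increasing burdens (e.g. lymph nodes filling while lungs
clear) yield a negative λ with a growth warning rather than an error.

Recomputing the polystyrene half-time from the rounded group-mean
concentrations (0.42 → 0.26 ng/(100 µm)³ over 35 days) gives 50.6 days;
the study reports 46 days, presumably from unrounded inputs. Both values
are reported; they agree within 15%, the tolerance documented for this
check.

**Identifiability limit.** For the biphasic design (days 0/35/91, five
animals per day), the slow phase spans 56 days while its half-time is
226 days. At inter-animal CV = 0.3 the sampling SD of the slow-phase λ̂
is comparable to λ itself, so a noticeable fraction of replicates yields
λ̂ ≤ 0 and per-replicate t½ = ln 2/λ̂ wraps sign; the median of per-seed
half-times is then biased low even though the median λ̂ is unbiased
(implied half-times within ~2% of truth in 200-seed simulations).
Summaries of slow-phase simulations should therefore be formed on λ, not
on t½; the tests do exactly that.

## Synthetic study-arm defaults

Burden time courses use N₀ = 3.8 mg (PA-6 lung, 50 mg/m³), phases
68 d → day 35 and 226 d thereafter, lognormal inter-animal factor with
mean 1, sampling days 0/35/91, five animals per day. The day-35 lung
mean (2.74 mg) is not tabulated in the study report; it is
back-calculated from the slow phase and the 2.31 mg day-91 endpoint and
carried as a derived, flagged value. The PS arm uses N₀ = 4.2 mg and a
single 46-day phase observed to day 35. Default inter-animal CV is 0.3,
consistent with the factor ~2 lung and ~10 lymph-node inter-individual
spread in the per-animal table.

The imaging recovery condition (used by tests and the acceptance
script) is 60 well-separated spheres, diameters lognormal
(median 0.9 µm, GSD 1.25, clipped to 0.6–1.8 µm — the in-tissue mode
just under 1 µm), emitter intensity 200 over background 20 (plateau SNR
≈ 40), shot scale 1, read noise SD 2, negligible depth fade, on a
448 × 448 × 64 stack (53.8 × 53.8 × 19.2 µm). This problem size keeps a
full recovery run in tens of seconds while leaving every object several
PSF widths from its neighbours.

## Known limitations

* The confocal chain is semi-quantitative by construction: it assumes
  even particle deposition across the sampled tissue, spherical
  envelopes and a universal packing density. Densely packed or touching
  agglomerates merge below the resolution limit.
* The half-max refinement constant is calibrated for 0.6–1.8 µm spheres
  at the reference PSF; far outside that range (or for non-Gaussian
  PSFs) the 0.4 height is no longer unbiased.
* The Py-GC/MS module does not model matrix interference (which blocked
  liver quantification in the study) or peak integration.
* Impactor physics (collection-efficiency curves, bounce, wall losses)
  is not modelled; stages partition the ideal lognormal exactly.
* Clearance fits assume first-order kinetics within each phase;
  compartmental (mucociliary vs alveolar) ODE models and PBPK are out
  of scope, as is re-implementing the MPPD deposition model.
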