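# Methods

`spectsbr` re-creates, on fully synthetic data with known ground truth, the
methodology chain used to build normal databases of the striatal specific
binding ratio (SBR) from [123I]FP-CIT (DaTSCAN) brain SPECT: scan
simulation → tomographic reconstruction → SBR quantification → phantom
calibration → database statistics.  This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The quantity of interest

The SBR is the ratio of specific to non-specific count concentrations,

    SBR = c_s / c_ns,

where `c_s` is the dopamine-transporter-specific striatal concentration
(striatal minus background) and `c_ns` the non-specific background
concentration.  In a phantom filled at a striatum:background concentration
ratio *R* the true SBR is *R − 1*; in simulated subjects the true per-side
SBR is prescribed directly.

## Digital phantoms and head models (`phantoms`)

The head is an axis-aligned ellipsoid shell (default semi-axes
70 × 95 × 55 mm) on a 128 × 128 × 64 grid of 2 mm isotropic voxels.  Each
striatum is a caudate + putamen ellipsoid pair whose semi-axes are rescaled
by bisection so the discretised per-side volume matches the nominal
striatal volume (default 11.4 ml, the same constant the Southampton
quantifier assumes, so that estimator is unbiased by construction).  The
label map further carries an occipital reference region, a 10 mm outer rim
(excluded from the Southampton background because peripheral voxels suffer
edge partial-volume losses), and optionally a zero-activity ventricular
void.  Phantoms fill the background at unit concentration and the striata
at *R* times that; human models set per-side striatal concentrations to
`1 + SBR_side`.  Most computations in this repository use a *desk-scale*
variant of the same physical geometry (64 × 64 × 32 voxels at 4 mm,
`PhantomSpec.desk_scale()`), which keeps a full multi-camera experiment in
the minutes range on one CPU; results on the fine grid are qualitatively
identical.

## Projector (`projector`)

Projections are attenuated parallel-beam line integrals computed slice by
slice.  In-plane rotation is a precomputed sparse bilinear-resampling
matrix per angle whose columns are normalised to unit sum, so the forward
projection conserves counts *exactly* (with no attenuation and no blur,
every projection sums to total activity × camera sensitivity), and whose
transpose is used as the backprojector — the exact adjoint pairing OSEM
assumes.  Attenuation uses per-ray cumulative sums of mu with a half-voxel
offset (midpoint rule); the uniform tissue coefficient is mu = 0.143 cm⁻¹.
Camera resolution is a single in-plane Gaussian PSF per camera applied in
the detector plane (distance-dependent resolution is deliberately not
modelled: the emulated protocol fixes the orbit radius).

## Energy-window model (`simulate`)

Energy windows are not simulated physically; the three window contents are
generated from parametric spatial kernels applied to the primary
projections:

* scatter: Gaussian kernel FWHM 60 mm, scaled by the camera scatter
  fraction (default 0.45 of primary counts reaching the photopeak);
* septal penetration: FWHM 150 mm kernel plus 20% flat floor, scaled by
  the camera penetration fraction (default 0.25);
* extra-brain activity (human scans only): a flat floor with a caudal
  gradient totalling `extra_brain_fraction` (default 0.3) of primary
  counts — the chest/abdomen sources seen through septal penetration.

Each component deposits counts into the lower/upper satellite windows with
weights that sum to 2 (scatter 1.7/0.3, penetration 0.6/1.4, extra-brain
0.3/1.7), which makes the triple-energy-window estimate
`(SC_l + SC_u)/(2·W_SC)·W_PH` unbiased for the photopeak contamination in
expectation; residual correction errors come from Poisson noise and
estimate smoothing, as in practice.  Window widths default to 32 keV
(photopeak, 159 keV ± 10%) and 7 keV (satellites); these are conventional
values, configurable because multicentre protocols vary.  The photopeak
expectation is normalised to 2 × 10⁶ counts per study (a clinical
injected-activity/scan-time regime) and all windows are Poisson-sampled.
Every stochastic operation takes an explicit integer seed.

With these defaults the simulated satellite-to-photopeak count-density
ratios (%SC ≈ 50–55% lower window, ≈ 28–50% upper window) sit in the range
reported for real phantom and control acquisitions, and the upper-window
excess of human over phantom scans — the signature of extra-brain septal
penetration — is reproduced with the correct sign on every camera.

## Reconstruction (`reconstruct`)

Four regimes: `FBP` (Butterworth pre-filter on raw projections, then
ramp-filtered back projection, no corrections), `IRNC` (OSEM, no
corrections), `IRAC` (OSEM with attenuation in the system matrix), `ACSC`
(OSEM with attenuation plus TEW-corrected projections).  OSEM follows the
ordered-subsets EM scheme with 10 iterations × 10 subsets for 120
projections and 8 × 12 for 128; angles are assigned to subsets round-robin,
which keeps subset sizes within one of each other for any subset count
(12 does not divide 128, so an even-partition requirement would contradict
the 8 × 12 convention).  All OSEM volumes are Butterworth post-filtered
(default cutoff 0.55 cycles/cm, order 10 — the single-platform default;
the 0.5 cycles/cm variant is a config option) and clipped at zero.

Attenuation is modelled inside the OSEM system matrix (an attenuated
projector), not as a multiplicative post-correction.  Attenuation maps are
binary ellipses filled with 0.143 cm⁻¹, estimated from a preliminary
reconstruction: human scans use a threshold contour (voxels above 10% of
the slice maximum; equatorial axes fitted by second moments over the
central, high-SNR slices and tapered along z as an ellipsoid), phantoms a
fixed 140 × 190 mm skull ellipse at the count centroid, tapered the same
way — phantom shells lack the out-of-shell activity needed for reliable
contouring.  The preliminary reconstruction is TEW-corrected before
contouring; without this the broad extra-brain floor dominates the
threshold and the contour balloons.  The TEW estimate is smoothed with a
2-pixel Gaussian before subtraction and the corrected photopeak is floored
at zero.

## Quantification (`quantify`)

Both quantifiers operate on a reconstructed (or ground-truth) volume with
VOIs placed from the known synthetic geometry; template registration is
out of scope (a count-centroid alignment is available for robustness
tests).

* **BRASS-style**: per side, striatal concentration pools caudate and
  putamen counts over their combined volume; `c_ns` is the occipital mean;
  `c_s = c_striatal − c_ns` (the ratio-minus-one convention, which makes
  the uniform case exactly zero).  Small VOIs ⇒ fully exposed to
  partial-volume losses.
* **Southampton (specific uptake size index)**: per side, total counts in
  a generous VOI (the anatomical striatum dilated by 12 mm, clipped at the
  midline so the sides stay disjoint; at least 3× the anatomical volume)
  minus the background contribution `c_ns × V_VOI`, divided by the assumed
  11.4 ml striatal volume.  `c_ns` is the mean over the whole brain minus
  the striatal VOIs and the 10 mm rim.  Capturing all displaced counts
  makes the estimate blur-invariant: across blur FWHM 4–16 mm it moves by
  < 5% while the BRASS-style value falls monotonically.

Whether the 11.4 ml convention is per striatum or total is ambiguous in
multicentre practice; it is implemented per striatum and configurable.
Per-side records are primary; all statistics operate on the 2N per-striatum
values.

## Calibration (`calibrate`)

Phantom series at filling ratios 10:1, 8:1, 5:1, 4:1 and 1:1 give
(true, measured) SBR pairs per camera × quantifier × reconstruction.  An
OLS line `measured = slope·true + intercept` is fitted — slope and
intercept rather than a single recovery coefficient, because the 1:1
uniform filling anchors the intercept at true SBR 0 — and inverted to
calibrate human measurements.  Factors are refused across mismatched
triples and on already-calibrated records.  Calibration acts at the SBR
level, camera-wide, with no age interaction.

The package reproduces the central limitation this design probes: the
phantom carries no extra-brain activity, so phantom-derived factors cannot
remove the subject-level septal-penetration term, and calibrated
uncorrected (IRNC) human databases remain systematically below calibrated
ACSC ones.

## Statistics (`dbstats`)

Databases (2 records per subject, one per striatum) are compared with the
symmetric mean percentage difference
`100·(1/2N)·Σ (A_i − B_i)/((A_i + B_i)/2)`, with paired t tests under a
Bonferroni-corrected threshold 0.05/m.  Age decline is OLS of SBR on age
over the 2N values; the 95% CI band is two standard errors of the
regression, and summaries report age-corrected (to 65 years) mean, SD and
CoV.  Raw-projection scatter fractions `%SC = (ΣSC/W_SC)/(ΣPH/W_PH)` and
their phantom-vs-control percentage difference estimate the extra-brain
contribution per satellite window.  Double-zero SBR pairs are excluded
from the percentage difference with a warning rather than raising.

## Numerical choices and degenerate inputs

* OSEM: update clamps forward projections at 1e-12; all-zero data maps to
  the all-zero volume (EM fixed point); sensitivity images are computed
  per subset with the exact adjoint.
* Butterworth: zero-phase FFT filter with gain `1/√(1+(f/fc)^(2n))` on the
  radial frequency; DC gain exactly 1; cutoffs at or above Nyquist warn
  and leave the data essentially unchanged.
* Attenuation contour on an empty volume returns an empty map; nearly
  empty slices are logged and skipped.
* Calibration requires ≥ 3 points spanning ≥ 2 distinct true values and a
  positive slope.
* Degenerate paired comparisons: identical databases give p = 1; constant
  non-zero differences give p = 0 rather than a NaN from the zero-variance
  t statistic.

## What the generator does and does not emulate

The synthetic studies include: camera-to-camera resolution and collimation
differences, attenuation in a uniform head, spatially broad scatter and
septal penetration with the correct window asymmetries, extra-brain
contamination confined to human scans, Poisson noise at clinical count
levels, linear age decline with biological spread, and balanced sexes.
They do not include: Monte-Carlo photon transport or real 123I emission
spectra, detector energy resolution, non-uniform (bone/sinus) attenuation,
anatomical variability between subjects (all share one head geometry),
template-registration error, patient motion, or orbit-radius effects.
Passing tests therefore demonstrate the internal consistency and the
qualitative mechanisms of the methodology — partial-volume losses,
correction ordering, first-order calibration — not quantitative agreement
with any particular clinical cohort.

## Problem sizes

Unit tests and the acceptance script run the desk-scale grid (64³-ish,
4 mm) with 3 cameras, 5 phantom fillings and a 6-subject cohort; the two
FBP/OSEM cross-checks that are sensitive to discretisation run on the full
2 mm grid.  These sizes are the package's default study conditions for
reproducible examples; `ExperimentConfig` scales to the full design
(9 cameras, 30+ subjects, all four regimes) unchanged.

## Known limitations

* The rotation-based projector is accurate to the bilinear interpolation
  order; high-frequency ripple from column normalisation is negligible
  after any realistic PSF but visible in unsmoothed point-source images.
* OSEM at 10 × 10 with the open filter recovers ~95% of the true contrast
  on clean data; complete convergence is not claimed (nor is it reached in
  the emulated clinical protocol).
* The threshold contour over-estimates the head outline by roughly the
  PSF width, as any count-threshold method does; the resulting mild
  over-attenuation is absorbed by calibration, mirroring practice.
* BRASS-style quantification here uses the generator's own anatomical
  masks; real template registration adds an error source the package does
  not model.
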