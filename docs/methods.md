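# Methods

This note records the models, parameter choices and numerical decisions
behind `iqspect`, in the order data flows through the pipeline.

## Digital head phantom

The phantom is 2-D multi-slice (default 3 slices of 96×96 voxels at
2.5 mm; all algorithms are slice-separable).  Cerebral slices hold a
convoluted cortical gray-matter band (inner boundary 52 ± 5 mm with a
six-fold sinusoidal modulation whose phase is drawn from the seed, outer
boundary 75 mm), a white-matter core, bilateral basal-ganglia and
thalamic nuclei, and skull (75–82 mm, μ = 0.25 cm⁻¹) and scalp
(82–86 mm, μ = 0.15 cm⁻¹) rings.  An infratentorial slice holds
cerebellar cortex, vermis and pons.  Default flows put gray matter at
35.7 and white matter at 25.8 mL/min/100 g at rest, and 51.7 / 34.3
after the vasodilator — population-mean values for healthy adults in
this age range — giving a simulated whole-GM reactivity of 44.8 %.

**Gray matter is modelled at territory scale (bands of ~20–25 mm), not
at cortical-thickness scale.**  Brain SPECT at 10–17 mm FWHM cannot
resolve 3-mm cortical sheets; what the quantification chain measures and
what its ROI analysis reports are territory-level flows.  A phantom with
anatomically thin cortex would make every ROI mean an uninterpretable
mixture at these resolutions; the territory-scale design keeps the
partial-volume bias of core-sampled ROIs in the few-percent range and
thereby makes parameter recovery a meaningful test of the *method*
rather than of partial-volume physics.  Consequently, recovery results
here do not speak to cortical-thickness-scale partial-volume effects in
real brains.

Masks used for quantification sample region *cores*: the truth GM mask
eroded by 7.5 mm in-plane (the global-anchor and recovery mask), and
atlas-style ROIs eroded by 5 mm, mirroring how clinical ROI templates
sit inside territories away from tissue boundaries.

## Tracer kinetics and input function

Tissue curves follow the one-tissue compartment model dC/dt = f·Ca −
(f/V_d)·C with V_d = 35.0 mL/mL; CBF[mL/min/100 g] = 100·f/ρ with
ρ = 1.06 g/mL.  The ODE is integrated with an exponential
(integrating-factor) update on a 1-s grid; against closed forms
(constant and exponential inputs) the error is < 0.1 %.

The population-standard arterial curve is a synthetic stand-in (the
clinical standard curve is not published): a gamma-variate first pass
peaking at 1.5 min plus a two-exponential recirculation tail (25 and
300 min), normalised to 50 Bq/mL per MBq injected at 10 min — a typical
whole-blood level for this tracer.  Every simulated subject shares the
shape; dose scales it linearly, and the single 10-min blood sample
(counted in well units via CCF) anchors it per subject, exactly as the
clinical calibration does.

During the second scan the first injection's tracer continues with the
rest-phase flow while the second injection's response uses the challenge
flow.  This matches the background-prediction model of the analysis
side; an `acz_onset_min` parameter lets the simulator violate that
assumption for sensitivity studies.

## Acquisition simulation

Institution profiles carry the reconstructed-image resolution (17.13 /
11.22 / 10.26 mm), Becquerel calibration factor (87 956 / 72 281 /
112 419), well-counter cross-calibration factor (0.799 / 0.619 / 0.948),
tracer dose (122.1 / 142.2 / 155.9 MBq) and enrolment (9 / 13 / 10).
The simulator blurs activity by √(FWHM² − 7²) before projection so that
the reconstruction's 7-mm post filter lands the final image at the
profile's nominal resolution.

Projection is rotation-and-sum parallel-beam (bilinear resampling
materialised as a sparse matrix, so the back projector is the exact
adjoint), 60 views over 360°, with per-voxel attenuation through the
*true* heterogeneous head.  Scatter is generated self-consistently as
the fixed point P = P_primary + SF⊙G(P), where SF(t) = 1 − 1/(A − B·t^β)
(A = 2, B = 1, β = 0.5) is the scatter fraction of observed photopeak
counts as a function of chord transmission t, and G is a unit-area
mono-exponential kernel (20 mm decay).  Septal penetration adds a
uniform 3 % of mean counts.  Expected counts scale with dose, frame
duration and a sensitivity ∝ 1/BCF, tuned once so a 28-min rest study
collects a clinically typical ~4×10⁵ counts per slice; Poisson noise is
applied per frame with an explicit seed.

Physical decay of ¹²³I is not simulated (activities are
decay-corrected, as in routine practice).

## Reconstruction

* μ-map: the summed rest study is reconstructed with ramp-filtered
  back-projection; the head outline is the largest connected component
  above a threshold, closed and hole-filled, with μ = 0.160 cm⁻¹ (the
  brain+skull average) inside.  For brain studies the emission edge is
  detected at 50 % of the robust maximum — the half-maximum contour of a
  blurred step is the physical edge — and dilated by an 11-mm
  skull+scalp margin, automating the "adjust the threshold until the
  outline is right" step of the interactive chain.  For uniform
  emission phantoms (cylinder, syringe) the 50 % contour is used
  directly.  The 25 % default of `estimate_mu_map` remains available.
* TDCS: P_corr = (P − o) − SF⊙G(P − o), clipped at zero, with the same
  SF family evaluated on transmissions forward-projected from the
  estimated μ-map and o = frac/(1+frac)·mean counts.
* OS-MLEM: opposed views are combined bin-wise by geometric mean.  The
  pre-correction divides by √T_chord **and** by the distributed-source
  factor sinh(u)/u, where u is half the attenuation integral across the
  *emission support* (the detected brain outline), not the full head
  chord: for an extended source the geometric mean equals the line
  integral times √T·sinh(u)/u, and using the full chord (which includes
  the non-emitting skull/scalp) would under-quantify brain studies by
  ~9 %.  After pre-correction the EM iteration runs with the
  unattenuated 180° system matrix, 5 angle-interleaved subsets, 3
  iterations, uniform initialisation inside the head mask, zero-count
  rays skipped, followed by the 7-mm Gaussian post filter.
* Calibration: BCF is measured on a 30-mm syringe of known activity by
  count conservation (total reconstructed rate over the whole field
  referred to the true source volume), which is insensitive to
  resolution spill-out; CCF compares a well-counter aliquot of the
  16-cm cylinder with the reconstructed Bq/mL.  Calibration scans are
  simulated long (60 min) — calibration should contribute negligible
  error.

With all corrections active the 16-cm cylinder at 50 kBq/mL
reconstructs to within ~2 % of truth at all three institution profiles.

## CBF estimation

The global GM CBF is estimated from the *unsmoothed* calibrated
24–28 min frame over the GM core mask; the 0–28 min look-up table's
activity axis is then rescaled (bisection on [0.2, 5], tolerance 10⁻⁴)
until the pixelwise inverted, 7-mm-smoothed 0–28 image reproduces that
anchor over the same mask.  Applying the anchor to the unsmoothed frame
matters: the rescaling step re-anchors the smoothed output anyway, so
anchor resolution is what controls accuracy.  The background at the
second injection is predicted per voxel by continuing the compartment
model with the rest flow over 0–58 min; the second-injection table (its
own dose and clock, window 0–28 after injection) shares the rest scale
factor.  Because the table is mildly concave (V_d washout), the
invariance of CVR to a common multiplicative calibration error is
first-order: a 15 % error moves CVR by under 2 points while the absolute
CBF absorbs it.

Flow grid: 0–1.2 mL/min/mL in steps of 0.001, linear interpolation;
activities above the table maximum clamp to the top flow and are
flagged.

## Resolution estimation and equalization

The FWHM of a reconstructed phantom image relative to its digital design
is fitted in the Fourier domain on radially averaged power spectra:
P_meas(k) = c·exp(−4π²σ²k²)·P_ref(k) + N, with amplitude c, Gaussian
MTF width σ (FWHM = σ√(8 ln 2)) and noise floor N fitted jointly by
weighted least squares over the band where the reference power exceeds
(5 %)² of its maximum and k ≤ 0.04 cycles/mm (reconstruction point
spreads are Gaussian-like only at low frequency, and that band is where
10–17 mm resolutions separate).  In the pipeline's resolution
experiment, five repeated phantom acquisitions are averaged and the
annular noise power of the mean image is measured directly from
repeat-to-repeat differences and subtracted — fitting a white floor to
post-filter-coloured noise is unstable, measuring it is not.  A
dedicated 9-slice phantom supplies enough independent cortical-fold
spectra; single 3-slice noisy estimates of a 17-mm system scatter by a
couple of mm, the averaged measurement by ~0.2 mm.

Equalization applies √(target² − current²) as a Gaussian filter; the
measured (not nominal) FWHMs are used, so the reconstruction chain's
own ~10 mm of additional blur cancels between scanners.

## Statistics

Mann–Whitney U is exact (full enumeration, mid-ranks for ties) for
groups of ≤ 8, asymptotic with tie correction otherwise.  Steel–Dwass
refers each pair's tie-corrected standardized rank-sum statistic to the
exact permutation distribution of the pairwise maximum when the
relabeling count is ≤ 10⁵ (e.g. n = 4,4,4), and to the studentized-range
asymptote P(Q_k ≥ √2·|t|) otherwise; at n = 10 per group the asymptote's
familywise error is ~3.6 % — slightly conservative.  Cohort summaries
report mean ± sample SD; CVR is computed per subject and then averaged,
not from group means.

Inter-subject variability is log-normal: CV 16 % on global flow
(matching the inter-subject spread of CBF in healthy adults) and CV
12.5 % on the challenge/rest ratio (reproducing a realistic ~18-point
spread of CVR).  The null multicenter experiment uses a *matched-cohort*
design: the same simulated subjects are scanned at all three
institutions (independent counting noise per scanner), so that
inter-institution differences reflect only scanner effects — the
property resolution equalization is supposed to remove — and the
Steel–Dwass battery (10 regions × 2 conditions) is then clean in
essentially every replicate, while a deliberately mis-calibrated
(+20 %) institution is still flagged.  With independent per-institution
cohorts (the default for study realism) roughly 1 replicate in 10
contains an extreme cohort draw that the rank test correctly rejects;
an ROI-level Monte Carlo of the statistical design alone reproduces
that ~92 % clean rate, confirming it is a property of sampling, not of
the pipeline.

## Problem sizes and determinism

Default grids are 96×96 at 2.5 mm with 60 views — chosen so a full
three-institution study (30 subjects, calibration and resolution
experiments included) completes in minutes on one CPU while keeping the
head geometry comfortably sampled.  Every stochastic step takes an
explicit seed; repeated runs are byte-identical.

## Known limitations

* 2-D multi-slice, parallel-beam only; no fan-beam geometry, no
  depth-dependent collimator response, no ¹²³I emission-spectrum
  modelling beyond the uniform septal-penetration offset.
* The synthetic input-function shape, TDCS constants and scatter kernel
  are plausible but not fitted to measured data; the simulator and
  corrector share the TDCS family, so the tests exercise the μ-map and
  calibration approximations, not mis-specification of the scatter
  model itself.
* Registration is assumed exact (simulation provides aligned images);
  real data would need realignment before every step that assumes it.
* Territory-scale phantom: see above — partial-volume behaviour of real
  cortical anatomy is out of scope.
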