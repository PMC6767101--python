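# Methods

`natsc` emulates and analyses a two-site, scan–rescan brain sodium
(²³Na) MRI study: it designs the 3D-cones UTE acquisition, simulates raw
k-space from a digital head phantom, reconstructs by density-compensated
gridding, converts intensities to total sodium concentration (TSC) with a
two-tube calibration, and computes the test–retest statistics a
repeatability study reports. This note records the models, the defaults
that matter, and the design decisions taken where more than one reasonable
choice existed.

## Acquisition model

The protocol constants are those of a matched two-site brain protocol:
24 cm FOV, 4 mm nominal isotropic resolution (kmax = 1/(2·4 mm) =
125 cycles/m, 60³ matrix), 2184 readouts of 10 ms at 166 kHz full readout
bandwidth (1660 samples per readout, full-bandwidth dwell convention),
TE/TR = 0.5/100 ms, 3 averages, 30 mT/m gradient amplitude and 120 T/m/s
slew rate. The slew figure is circulated as "120 mT/s", which is not a
slew-rate unit; we interpret it as 120 T/m/s (120 mT/m/ms), a standard
clinical value, and expose it in the protocol. γ(²³Na) = 11.262 MHz/T.

### Cones trajectory design

The design is self-contained rather than a port of any scanner
implementation; its contract is feasibility and coverage, audited
numerically, not waveform identity.

* Cone angles come from an equal-solid-angle partition of the sphere; the
  number of cones is set by the Nyquist ring spacing at kmax
  (π·kmax·FOV ≈ 94 for the full protocol). Readouts are split across cones
  as evenly as possible and realised as azimuthal rotations of one spiral
  per cone.
* Each readout starts at k = 0 (UTE) with a slew-limited radial ramp to a
  constant radial speed that lands exactly on kmax at the last sample. The
  azimuthal rate at each radius is the maximum permitted by the remaining
  gradient-amplitude budget and by the centripetal slew limit
  (φ̇ ≤ √(η·γ·smax/ρ)), with safety factors (0.95 amplitude, 0.55 slew)
  that leave headroom for discretisation, plus a cap of 0.5 rad of twist
  per dwell near the centre where the slew bound diverges.
* An independent audit estimates gradients by forward differences and slew
  by second differences and checks every sample against the limits; the
  full printed protocol passes at 100% with no empty kmax/15 radial shell.

### Gradient-delay (hysteresis) correction

Reconstruction coordinates are the ideal waveform filtered by a causal
exponential kernel (1/τ)·e^(−t/τ) (discrete one-pole equivalent; default
τ = one dwell) and evaluated at t − delay, with delay = 5 µs by default.
The correction always re-derives from the stored ideal waveform with the
delay accumulated across calls, so applying delays a then b is exactly
equivalent to a + b — the linearity that makes the correction composable.
τ = 0 degenerates to a pure time shift, which for a constant gradient G
displaces k by γ·G·delay (the closed form used in tests).

### Density compensation

Two estimators are provided.

* `voronoi`: exact Voronoi cell volumes (2D areas for planar toy
  trajectories). Cells are clipped to the kmax ball by reflecting
  outer-shell samples about the sphere; duplicated positions (every UTE
  readout starts at k = 0) share their cell volume equally. Practical up
  to ~10⁴ unique points.
* `iterative` (default): the kernel fixed point w ← w/(C∗w), with C the
  gridding-kernel autocorrelation evaluated by grid/degrid round trips.
  Three post-steps convert the converged relative densities into absolute
  cell volumes: (1) the absolute scale is calibrated against the kernel's
  density response to a unit-weight Nyquist lattice; (2) samples within a
  kernel width of the kmax sphere are multiplied by the kernel-mass
  fraction actually inside the ball (half-space correction), removing the
  boundary inflation of the fixed point; (3) each radial shell's weights
  are rescaled so their sum equals the exact shell volume — centre-out
  cones cover every shell by construction, and the fixed point otherwise
  leaves percent-level radial ripple (worst at the heavily duplicated
  centre) that would bias large-structure amplitudes. With all three, a
  uniform sphere's interior is recovered to ~0.3% unwindowed.

## Digital head phantom

The scene is a nested set of analytic solids, each with an exact Fourier
transform (ellipsoids: scaled-sphere form; cylinders: J₁/sinc form), so
the default forward model never shares a grid with the reconstruction (no
inverse crime). A raster mode (NUFFT of supersampled partial-volume maps)
exists for irregular phantoms; per-tissue static k-space makes it exact in
the tissue dimension.

Geometry (defaults, semi-axes in mm): subarachnoid CSF envelope
(71.5, 87.5, 61.5) as a 3.5 mm film over the GM shell (68, 84, 58); WM
core (46, 62, 36); two lateral-ventricle CSF ellipsoids (5, 15, 7) at
x = ±9. Two agar calibration cylinders (24.5 mm diameter × 89 mm, 20 and
80 mM) sit at x = ±95 mm, beside where ear defenders hold them in
practice. Two deliberate choices:

* The subarachnoid film is thinner than a voxel, so it contributes
  partial-volume signal but no voxels to the 95%-probability CSF mask —
  the regime of young adult brains, where thin CSF spaces are sampled only
  partially.
* The ventricles are small (≈70 pure-CSF voxels at 4 mm). That makes the
  CSF region mean the noisiest of the three — which is what drives CSF's
  inferior cross-site reproducibility in the emulated study, mirroring the
  partial-volume argument usually offered for that observation.

`HeadGeometry.verification()` swaps the small ventricles for one large
central CSF body whose pure-voxel core clears the point-spread function;
it exists for exact-recovery experiments (below), not for study emulation.

Tissue parameters: TSC means/SDs WM 41.8 ± 6.7, GM 52.1 ± 7.1,
CSF 85.8 ± 14.3 mM; T₁ = 22 ms for parenchyma, 47 ms for CSF, 35 ms for
agar; biexponential T₂* with short-fraction 0.6 and 3/20 ms for WM/GM,
monoexponential 55 ms for CSF, 0.6 and 5/25 ms for the agar tubes. The
T₂* values are literature-typical rather than protocol-specific and are
fully configurable.

The signal model per compartment is
`tsc · (1 − e^(−TR/T₁)) · (f_s·e^(−t/T₂*s) + (1−f_s)·e^(−t/T₂*l))`
evaluated at each sample time t since excitation. Noise is i.i.d. complex
Gaussian with per-channel SD `noise_sd/√n_averages` (averaging modelled
through the SD, not explicit repeats).

## Cohort model

Eleven subjects; each subject's true per-tissue TSC is drawn once from a
truncated normal and reused at both sites. All subjects are scanned twice
at site A; seven twice and four once at site B. Scans at a site differ
only in noise realisation; sites differ in noise SD (B twice A),
calibration gain (B = 1.05, absorbed exactly by calibration) and gradient
delay (matched at 5 µs — the delay optimisation reached the same value at
both real sites). Seeds expand from the global seed through fixed
`SeedSequence` spawn keys per subject and per (subject, site, scan), so
enlarging the cohort never perturbs existing subjects.

Site noise defaults (3.5e-3 and 7e-3 in the simulator's m³·mM units at the
full protocol; reduced profiles scale by √(sample-count ratio) to keep
image SNR invariant) are set to the largest level at which automatic tube
detection remains reliable (20 mM tube SNR ≈ 8). Under this model the
within-subject CoVs come out at roughly 0.5–2%; a real study's 2–4% also
contains physiological and positioning variance that this generator
intentionally omits (scans differ only in noise), so passing orderings
here says nothing about the absolute CoV a scanner would achieve.

## Reconstruction

Standard convolution gridding: samples × density weights × radial window,
Kaiser-Bessel spreading (width 4, oversampling 1.5, Beatty β) onto the
oversampled grid with periodic wrap, inverse FFT, analytic deapodisation,
central crop, magnitude. The default window is a Hann profile on |k|/kmax
— the role of the sample-density-weighted apodization used to match SNR
between scanners; `tukey` and `none` are available. Weights carry the
k-space volume element, so reconstructed values keep the simulated signal
density's units and a two-point calibration suffices for mM.

Two window regimes matter:

* `hann` (default, study emulation): strong noise suppression; the PSF
  main lobe widens to ~2 voxels, and deltas of compact structures
  (ventricles, tubes) lose 5–12% of their spectral band. Fine for
  repeatability statistics (scale-free), wrong for absolute verification.
* `none` (verification): PSF main lobe ~1 voxel, interior values accurate
  to ~1% after the density-weight corrections above, at the cost of
  visible Gibbs ringing.

SNR is estimated as mean(signal)/σ with σ the background SD divided by
√(2 − π/2) (Rayleigh correction); a noiseless background returns an
infinity sentinel.

## Quantification

Tube detection seeds candidate blobs outside the head at 0.15 of the
robust (99.9th-percentile) maximum of a 3³-box-smoothed image (matched
filter against speckle), with a floor of median + 6·MAD so pure noise
never seeds; blobs are filtered by volume (10–150 ml) and elongation.
Each of the two survivors is re-thresholded at 0.5 of its own interior
plateau (estimated as the median of smoothed values over an eroded
bootstrap core) — the intensity-based peel of partial-volume periphery
voxels — then eroded one voxel in-plane, and end slices with less than
70% of the median cross-section are dropped, as a slice-wise outline
would. The per-tube threshold matters: a single global fraction of the
image maximum would treat the dim 20 mM tube and the bright 80 mM tube
asymmetrically and cannot see both.

The calibration statistic per tube is the plateau of the eroded ROI —
the median of box-smoothed intensities — rather than the plain mask
mean: the mean is diluted several percent by the residual rim under
windowed reconstruction and swings with Gibbs ringing under sharp
reconstruction, whereas the plateau statistic is stable under both and
under noise. The eroded masks themselves are retained for reporting
(per-slice ROI sizes, containment checks).

Calibration is the two-point line through (s₂₀, 20) and (s₈₀, 80), with
intercept by default: the intercept absorbs any additive contamination
common to both tubes (blur tails, noise floor), and the slope absorbs any
global gain — which is exactly why TSC maps are invariant (to 1e-8) under
arbitrary intensity scaling, the property that makes cross-site
comparison meaningful. A through-origin variant is available. Negative
map values are kept and counted, never clipped.

With relaxation enabled and the short agar T₂*, tube blur dilutes the
eroded-tube means and the calibration slope inflates all tissue values by
tens of percent. This is faithful physics for an uncorrected-relaxation
protocol — such studies report biased absolute TSC — and it is why the
two verification experiments below control relaxation explicitly.

## Verification experiments

* **Exact recovery**: verification geometry, relaxation off, zero noise,
  unwindowed reconstruction. Segmented WM/GM/CSF means recover the truth
  within 2%, and the eroded tube means map to exactly 20.0/80.0 mM (forced
  by the two-point fit). Run at 546 readouts / 553 samples — the reduced
  profile — where the result is indistinguishable from the full protocol.
* **CSF saturation bias**: CSF T₁ = 47 ms vs brain 22 ms at TR = 100 ms
  gives CSF a saturation factor of 0.881 against the agar tubes' 0.943.
  With transverse decay matched across compartments (isolating the
  longitudinal mechanism) and a 140 mM CSF truth, the measured CSF
  concentration falls strictly below truth — the direction of the known
  CSF underestimation at short TR.

## Statistics layer

For one region and site, with per-subject scan pairs (x₁, x₂):
wsd_i = |x₁ − x₂|/√2, pooled wsd = √mean(wsd_i²),
CoV = 100·wsd/grand-mean, RC = 1.96·√2·wsd. Reproducibility applies the
same estimator to cross-site first-scan pairs. "CoV of mean values" is
thus read as the RMS within-subject CoV — the standard test–retest
estimator. Bland–Altman reports mean difference ± 1.96·SD(d) with the
sample (n − 1) SD, pooled across regions×subjects per site (matching how
such figures are usually drawn). Interobserver agreement is ICC(2,1) —
two-way random effects, absolute agreement, single rater — with
F-distribution confidence intervals (Satterthwaite degrees of freedom);
zero total variance returns a flagged NaN sentinel. Subjects with a single
scan at a site contribute to per-scan means but never to paired
statistics.

Observer ROIs are 6 mm spheres at bilateral deep-grey ("caudate",
"putamen") and white-matter ("centrum semiovale") analog positions,
centre-jittered by an isotropic Gaussian (default SD 2 mm) per observer
seed; an ROI that would leave its host tissue shrinks with a warning.
With 2 mm jitter the emulated observers' ICC point estimates stay above
0.85 for all regions.

## Problem sizes and profiles

The `ci` profile (546 readouts at 55.3 kHz → 553 samples per readout,
same 4 mm / 60³ geometry) is the package's reduced study scale: the
calibration tubes stay 6 voxels across (they become undetectable at
coarser voxels), per-scan cost drops ~12×, and quantification behaviour is
unchanged — the exact-recovery experiment gives the same result under
both profiles. Site noise is rescaled to keep image SNR invariant, so
statistics are comparable across profiles. The full study emulation (40
scans) takes ~20 s per cohort at `ci` scale and the full printed protocol
~50 s per scan.

## Known limitations

* Within-subject variance is thermal noise only; physiological variation,
  motion, repositioning, CSF flow and B₀/B₁ effects are not modelled, so
  emulated CoVs underestimate real-world ones.
* Inter-site differences are phenomenological (noise, gain, delay); real
  eddy-current blur and contrast differences are richer.
* The head is piecewise-constant ellipsoids; no cortical folding, no
  skull/scalp, ventricle morphology simplified.
* Relaxation weighting is simulated but never corrected for in
  quantification (deliberately, matching uncorrected-TSC practice);
  absolute TSC under relaxation carries the corresponding bias.
* ICC confidence intervals assume the two-way ANOVA normality conditions.
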