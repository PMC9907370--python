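# Methods

This note documents the models, numerical choices, and simulation design
behind `chromasim`, including what the synthetic observers do and do not
capture about real psychophysical data.

## Chromatic models

**Chromatic difference of refraction.** The eye's defocus as a function of
wavelength is the standard reduced-eye polynomial
D(λ) = c₀ − c₂/λ² + c₄/λ⁴ − c₆/λ⁶ with defaults
c₀ = 1.6091 D, c₂ = 6.7094×10⁵ D·nm², c₄ = 5.5533×10¹⁰ D·nm⁴,
c₆ = 5.6000×10¹⁵ D·nm⁶, valid on 400–700 nm.  With these coefficients D is
strictly increasing (verified numerically on a 1-nm grid), crosses zero at
588.5 nm (≈590 nm), and spans 2.21 D across the valid range.  The often
quoted ~2.5-D span for 400–700 nm comes from other datasets; both numbers
are reported by `chromatic_span` users and deliberately not reconciled.
`zero_defocus_wavelength` brackets the sign change on a 1-nm grid and
bisects to 0.1 nm; a brute-force 0.01-nm scan agrees to <0.05 nm.

**Achromatizing-lens (ACL) scaling.** The ACL is modelled as the exact
negative of the eye's dispersion, afocal at 573.5 nm.  Because the vergence
of a beam between pupil conjugates scales with the inverse square of
magnification, the correction delivered at the eye is LCA_ACL·M² with
M = f₂/f₁ the beam magnification at the ACL.  The flattened source formula
is ambiguous between ×M² and ÷M²; ×M² is adopted because enlarging the beam
at the ACL increases the correction, and M is the single exposed control.

**TCA conventions.** All stored horizontal/vertical TCA components use the
visual-field convention (+right, +up); nasal/temporal is derived per eye by
`field_to_temporal` and never stored.  Summary statistics operate on
condition medians (median across repeats within eye × primary-pair ×
LCA-state, then means of |medians| per pair and per state, and per-eye mean
horizontal TCA).  Printed-number comparisons round half away from zero to
two decimals, matching two-decimal reporting conventions.

**Chromostereopsis prediction.** The disparity at which red and blue should
appear equidistant is d = TCA_R − TCA_L (horizontal components, field
convention).  Instrument TCA, when supplied, is added to each eye's
measurement before differencing.

## Retinal image quality

Monochromatic image formation uses the generalized pupil
P = A·exp(i2πW/λ) sampled on a square grid (default 256 samples across the
4-mm pupil, 4× zero-padding; at least 64 samples are enforced).  The PSF is
|FFT(P)|², energy-normalized; the OTF is its normalized Fourier transform,
giving the diffraction-limited cutoff d/λ ≈ 131 cyc/deg at 533 nm.  Defocus
enters as the parabolic sag W₂₀ = D·r²/2 (2 µm marginal sag per diopter on
a 4-mm pupil); astigmatism, coma and spherical aberration are available as
RMS-normalized Zernike terms.  The numerical diffraction-limited MTF matches
the analytic circular-aperture form to <1% RMS, and small-aberration Strehl
ratios match the Maréchal approximation within 2%.

Polychromatic formation is coherent within a wavelength and incoherent
across wavelengths: complex OTFs are combined with nonnegative normalized
spectral weights and the MTF is the magnitude of the sum.  This is a
deliberate choice (documented because some texts sum MTF magnitudes): only
the complex sum lets opposite TCA shifts of two primaries cancel the
compound grating at specific frequencies, which is the mechanism behind the
counterphase contrast-sensitivity condition.  Per-wavelength pupil sampling
is scaled proportionally to wavelength so all OTFs share one cycles/degree
grid exactly, avoiding interpolation.

Two spectral modes are provided: the tri-primary display spectrum
(468/533/616 nm, equal luminance weights — the default, since the
experimental stimuli are tri-primary) and a V(λ)-weighted continuum
(400–700 nm in 5-nm steps).  The bundled photopic efficiency table is the
canonical CIE 1924 2° set tabulated at 10 nm; intermediate wavelengths are
PCHIP-interpolated.  The image-quality scalar is the 2-D trapezoid integral
of the MTF over the disk |f| ≤ 60 cyc/deg (beyond behavioral acuity, well
below the pupil cutoff), normalized by the diffraction-limited area.  At
the default grid, doubling the sampling changes this area by <0.5%.  With
these defaults, full physiological LCA reduces the area substantially more
than a 1-arcmin TCA shift — the package's restatement of the expected
relative benefit of correcting each aberration; only this ordering, not its
magnitude, is treated as a stable result.

## Stimulus rendering

The simulated display has 0.23 arcmin/pixel and a 3° circular field; all
stimuli are evaluated in a 10× up-sampled pixel space and box-averaged down
(area-averaging is used rather than bilinear because it conserves flux at
edges), giving 0.023-arcmin positioning.  Sub-pixel chromatic offsets shift
the green/blue planes relative to red; a shift of w whole pixels plus k
subpixels reduces analytically to a two-tap blend of whole-pixel rolls,
which is what is computed (the identity is verified against the literal
up-sample/roll/down-sample in tests).  Offsets below the quantum are
rounded with a warning.

Stimulus-specific choices: tumbling-E letters use the 5×5 stroke grid
(limb width = height/5, height = 5·MAR with MAR = 10^logMAR arcmin) at a
20% Weber decrement; the "purple" background mixes the three primaries at
equal luminance while "white" uses the display's native luminance
proportions (red:green:blue ≈ 1.35:3.93:0.36); composite Gabors are
equal-peak-luminance red and blue 10-cyc/deg gratings under a σ = 23 arcmin
Gaussian window, tilted ±10°, with the blue grating displaced along the
modulation axis; duochrome targets use a 130-px (≈0.5°) disk, 10-px gaps;
dichoptic bars are 2.30 × 60.0 arcmin with a 2.30-arcmin gap, disparity
split symmetrically between the eyes; Voronoi fields are nearest-seed
partitions with uniform random cell luminances (seed density and luminance
range are exposed parameters — their true statistics are not critical and
were chosen to look like a fine texture at the default field size).
Rendering operates in linear luminance; display gamma is out of scope.

## Psychophysics engine

**Staircases.** 2-down/1-up transformed staircases with multiplicative
(contrast; factor 1.3) or additive (letter size; 0.05 logMAR) steps track
the √0.5 ≈ 70.7%-correct level.  Defaults follow the measurement protocol:
40 trials per run, 8 runs per acuity condition, generous suprathreshold
starts (0.6 logMAR; 0.5 contrast).  A single 40-trial tail wanders by about
a step, so convergence statements average across runs.

**Psychometric fits.** ψ(x) = γ + (1−γ−λ)Φ((x−μ)/σ) fitted by binomial
maximum likelihood (L-BFGS-B on (μ, log σ), three slope initializations;
bootstrap refits warm-start from the point estimate).  γ is fixed by the
task (0.25 for 4AFC acuity, 0.5 for 2AFC).  The lapse rate λ is fixed at
0.02 by default — the sources are silent on it — with a free-λ option
bounded to [0, 0.06].  Criterion thresholds are read off the full
proportion-correct scale (78.1% for acuity, 75% for contrast, 50% for
PSEs): level = μ + σ·Φ⁻¹((c−γ)/(1−γ−λ)).  Confidence intervals are
nonparametric: successes per level are resampled binomially from the
observed proportions (≥200 resamples), each replicate refit, and the
5th/95th percentiles reported.  Data pinned at chance or ceiling raise a
descriptive degenerate-fit error rather than returning extrapolated
numbers.  PSE fits allow a signed slope so that swapping response labels
flips the slope but not the PSE, and flag (rather than forbid) data that
never cross 50%.

**Sinusoid model.** Contrast threshold versus red–blue offset is fit with
c(x) = a·sin(2π(x−p)/6) + b, the period fixed at 6 arcmin (one cycle of a
10-cyc/deg grating).  The model is solved in the linear sin/cos
reparameterization — immune to phase local minima — and canonicalized to
a ≥ 0, p ∈ (−3, 3]; constant data report a = 0 and p = 0 by convention.

**Repeated-measures correlation.** Within-subject association with a
common slope: x and y are centered on subject means, r_rm is the
correlation of the centered values, dof = N − k − 1 for N pairs and k
subjects, and p comes from the t distribution of the common slope.  The
implementation is hand-written from the sums of squares and cross-checked
in tests against an ANCOVA regression and an independent library
implementation.  Degenerate designs (a single subject, or no within-subject
variance in the predictor) raise errors rather than returning NaN.

## Simulated observers

Each synthetic subject carries per-eye LCA offsets at the three primaries
(drawn around the model-eye predictions −0.52/0/+0.43 D with 0.15-D
between-subject jitter), per-eye per-pair TCA vectors (horizontal blue
drawn with left-eye mean −0.5 and right-eye mean +0.6 arcmin, SD 1.0;
green ≈ 0.55× blue), setting-noise SDs, psychometric widths, and a 2%
lapse rate.  Settings tasks add Gaussian noise to the truth and quantize at
the instrument steps (0.1 D; 0.115 arcmin).  Measured TCA is inflated by a
factor 1.28/0.39 ≈ 3.3 when LCA is corrected — a phenomenological knob
reproducing the observed corrected > uncorrected ordering, not a mechanism.

The links from optics to behavior are explicit models, since the
experiments measure rather than model behavior:

* **Acuity.** p(correct) = 0.25 + (0.75−λ)Φ((logMAR − t_c)/σ) with
  t_c = base + Δ(condition).  Δ defaults to 0 on the monochromatic (green)
  background, a fixed 0.06-logMAR penalty for uncorrected LCA on
  polychromatic backgrounds, and 0.02 logMAR per arcmin of blue TCA for
  uncorrected TCA; per-condition Δ dictionaries override the link entirely
  (the null and power simulations in the tests use that override).
* **Grating tilt.** The retinal red–blue offset is the displayed offset
  plus the observer's horizontal blue TCA; the luminance component of the
  composite is |m_r + m_b·e^{iφ}|/2 with m_r, m_b the 10-cyc/deg MTF
  attenuations of the red/blue primaries (diffraction-limited when LCA is
  corrected, defocused by the observer's offsets when not), and
  p(correct) = 0.5 + (0.5−λ)Φ(c·A/σ − criterion).  The observer is
  luminance-only: no chromatic mechanism is modelled, so near counterphase
  with corrected LCA the thresholds rise to the staircase ceiling (capped
  at contrast 1).  Passing tests therefore say nothing about human
  isoluminant (hue) sensitivity.
* **Depth.** p("blue nearer") = λ + (1−2λ)Φ((disparity − PSE)/σ) with the
  generative PSE equal to the interocular horizontal blue-TCA difference
  plus an optional per-state blur bias (default 0, reflecting the absence
  of a blur contribution).  σ defaults to 0.4 arcmin, consistent with
  line-stimulus stereoacuity (tens of arcseconds for thin adjacent lines,
  degraded here by colored and potentially blurred bars).

`generate_study` derives independent RNG substreams per
(subject, task, condition) by hashing, so output is byte-identical for a
seed and stable under task subsetting.  The constant-stimulus disparity
grid (9 levels, 0.5-arcmin spacing) is centered on each subject's
TCA-predicted disparity snapped to the grid spacing — the experimenter
knows the TCA measurement before the depth experiment — keeping the PSE
inside the sampled range even in the inflated LCA-corrected state.

**What the generator does not emulate:** monochromatic aberrations beyond
those explicitly passed to the optics module, accommodation (subjects are
modelled as cyclopleged/presbyopic), binocular fusion and rivalry, hue
sensitivity at isoluminance, learning/fatigue across runs, and any
dependence of setting noise on stimulus blur.  Recovery results on
synthetic data bound the pipeline's correctness, not human variability.

## Analysis pipeline

LCA analysis re-references each subject-eye to its green mean and compares
offsets to the model polynomial.  Acuity analysis pools all trials per
subject × condition ("grouped all the trials"), fits the 4AFC model, reads
the 78.1% threshold, and runs fourteen paired t tests on logMAR across
subjects (pairing per-subject pooled condition thresholds; whether the
original tests paired across runs instead is unknowable from the source, so
the choice is documented here).  Raw p values are reported alongside
Holm-adjusted ones, the adjustment being an extension flagged as such.
Contrast analysis converts displayed offsets to retinal phase using each
subject's measured blue TCA for the matching LCA state before the sinusoid
fit; the reported minimum-threshold location should sit near zero retinal
offset for a luminance-only observer.  Stereo analysis compares
TCA-predicted to observed PSEs (optionally adding instrument TCA), pools
all subject × LCA-state pairs in the repeated-measures correlation, and
reports the mean observed-minus-predicted residual per state — the
differential-blur test, with the sign convention that crossed disparity of
blue is positive.

## Problem sizes and determinism

Test and acceptance simulations use the protocol's own trial counts where
they matter (6 settings per condition; 40-trial staircases; 10 × 9
constant-stimulus judgments) and scale the number of synthetic subjects to
what each property needs (7 for study-shaped checks, 25 when a stable
median over ~50 PSE recoveries is required, 100 replicates for CI-coverage
counts).  All randomness flows from explicit integer seeds; reports and
study bundles are byte-identical across reruns with the same seed.

## Known limitations

* The optics module is paraxial Fourier optics: no off-axis field
  dependence of TCA, no Stiles–Crawford apodization, no scatter or
  polarization.
* The MTF-area analysis fixes one pupil (4 mm), one frequency cutoff
  (60 cyc/deg) and equal-luminance primaries; only orderings, not
  magnitudes, should be quoted.
* The 2-decimal TCA summary reproduction depends on feeding condition
  medians, not raw settings.
* `pse_from_constant_stimuli` fixes the lapse at 0.02; strongly lapsing
  observers would bias PSEs slightly.
* The CIE table is interpolated from the 10-nm tabulation; sub-nm spectral
  structure is irrelevant at the bandwidths involved but the 5-nm values
  are not the official tabulated ones.
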