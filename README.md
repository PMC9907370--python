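# chromasim

Models of the human eye's chromatic aberration and its consequences for
vision, with a full simulated-psychophysics pipeline.

The eye's refractive power varies with wavelength — **longitudinal chromatic
aberration (LCA)** — and the retinal image location varies with wavelength —
**transverse chromatic aberration (TCA)**.  Together they blur and fringe
polychromatic retinal images, and the interocular difference of horizontal
TCA produces an illusory depth between red and blue objects
(**chromostereopsis**).  `chromasim` is for vision scientists and
physiological-optics engineers who want to model these aberrations,
quantify their impact on retinal image quality, render the classic
psychophysical stimuli used to measure them, and validate analysis
pipelines against simulated observers with known ground truth.

## What's inside

* **`chromasim.chromatic`** — the chromatic-difference-of-refraction
  polynomial

  D(λ) = c₀ − c₂/λ² + c₄/λ⁴ − c₆/λ⁶   (λ in nm, D in diopters),

  in focus near 590 nm and spanning ≈2.2 D over 400–700 nm; the
  achromatizing-lens correction scaling LCA_eye = LCA_ACL·M² with trombone
  magnification M = f₂/f₁; TCA bookkeeping (field convention: +right/+up)
  with condition medians and deviation summaries; the chromostereopsis
  prediction d = TCA_R − TCA_L; and diopter/arcmin/pixel/vergence geometry.
* **`chromasim.optics`** — Fourier optics on a sampled pupil: generalized
  pupil → PSF → OTF, Strehl ratios, polychromatic MTF as the magnitude of
  the spectrally weighted sum of complex OTFs (so TCA shifts can interfere),
  and the V(λ)-weighted MTF-area metric normalized to the diffraction limit.
* **`chromasim.stimuli`** — the five stimulus classes on a simulated
  tri-primary display (0.23 arcmin/pixel, 3° circular field): Voronoi focus
  targets, duochrome disk-in-annulus TCA targets, tumbling-E optotypes,
  red+blue composite Gabors, and dichoptic bar pairs — all rendered in a
  10× up-sampled pixel space with 0.1-subpixel chromatic offsets.
* **`chromasim.staircase` / `chromasim.psychometric`** — 2-down/1-up
  transformed staircases; maximum-likelihood cumulative-Gaussian
  psychometric models (`PsychometricModel(...).fit()` →
  `PsychometricResults` with criterion thresholds, bootstrap CIs,
  `summary()`, `plot()`); the fixed-period sinusoid of contrast threshold
  versus red–blue offset; PSE estimation; repeated-measures correlation and
  paired t tests.
* **`chromasim.observers`** — simulated subjects with known LCA, TCA and
  psychometric parameters that perform every task (focus settings, duochrome
  alignments, 4AFC acuity, 2AFC grating tilt, 2AFC depth), plus
  `generate_study` which writes a complete CSV study bundle.
* **`chromasim.pipeline` / CLI `chromasim`** — end-to-end analysis of a
  bundle: LCA versus the model polynomial, TCA summaries, per-condition
  acuity thresholds with fourteen paired comparisons, contrast thresholds
  versus retinal phase with sinusoid fits, and predicted-versus-observed
  chromostereopsis with the repeated-measures correlation.

## Worked example

```python
from chromasim import (ChromaticEyeModel, model_defocus,
                       zero_defocus_wavelength, chromatic_span)

eye = ChromaticEyeModel()
print(f"in-focus wavelength: {zero_defocus_wavelength(eye):.1f} nm")
print(f"defocus at the blue primary (468 nm): "
      f"{model_defocus(eye, 468) - model_defocus(eye, 533):+.2f} D vs green")
print(f"defocus at the red primary  (616 nm): "
      f"{model_defocus(eye, 616) - model_defocus(eye, 533):+.2f} D vs green")
print(f"chromatic span 400-700 nm: {chromatic_span(eye, 400, 700):.2f} D")
```

```
in-focus wavelength: 588.5 nm
defocus at the blue primary (468 nm): -0.52 D vs green
defocus at the red primary  (616 nm): +0.43 D vs green
chromatic span 400-700 nm: 2.21 D
```

The eye model is emmetropic near 590 nm; relative to the green display
primary, blue needs ~0.5 D more power and red ~0.4 D less — about 1 D of
defocus separating the red and blue planes of any polychromatic stimulus.

Simulating a seven-subject study and analysing it end to end:

```python
from chromasim import (sample_population, generate_study, Protocol,
                       StudyBundle, report)

pop = sample_population(n=7, seed=1)
study = generate_study(pop, Protocol(tasks=("lca", "tca", "stereo")), seed=1)
bundle = StudyBundle(study.lca_settings, study.tca_measurements, study.trials)
text, results = report(bundle, sections=("lca", "tca", "stereo"))
print(text)
```

```
Chromatic-aberration study report
========================================

[LCA]
  mean deviation from model -0.023 D (|.| 0.069 D); red-blue span 0.956 D (model 0.954 D)

[TCA]
  mean |TCA| by pair (arcmin): {'blue-vs-red': 0.72, 'green-vs-red': 0.62}
  mean |TCA| by LCA state (arcmin): {'corrected': 1.04, 'uncorrected': 0.3}
  mean horizontal TCA by eye (arcmin): {'left': -0.65, 'right': 0.69}

[STEREO]
  repeated-measures correlation r = 0.9960, dof = 6, p = 1.65e-07
  mean observed-predicted (corrected): -0.053 arcmin
  mean observed-predicted (uncorrected): +0.019 arcmin
```

Reading this: the simulated subjects' focus settings sit on the model
polynomial (red–blue span ≈ 0.95 D); their measured TCA is larger when LCA
is corrected than when it is not (1.04 vs 0.30 arcmin — the inflation the
generator builds in); and the disparity nulling chromostereopsis is
predicted almost perfectly by each subject's interocular TCA difference
(r = 0.996), with no residual shift attributable to blur in either state.

The same study can be driven from the shell:

```bash
chromasim simulate --out bundle --seed 1
chromasim analyze --bundle bundle --section all --out results
chromasim render --spec '{"__type__": "GaborCompositeSpec", "blue_offset_arcmin": 3}' \
    --out counterphase.png
```

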