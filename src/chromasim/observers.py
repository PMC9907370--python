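"""Simulated observers with known chromatic aberration and psychometric
parameters.

Every task in the package can be exercised end-to-end against observers
whose ground truth is known, so each analysis stage is testable by
parameter recovery without human data:

* focus settings per primary (LCA task), Gaussian setting noise quantized
  at the instrument's 0.1-D button step;
* duochrome alignment settings (TCA task), quantized at the 0.115-arcmin
  fine step, with an inflation factor for the LCA-corrected state that
  reproduces the finding that perceived TCA grows when LCA is corrected;
* 4AFC tumbling-E responses following a cumulative-Gaussian psychometric
  function of letter size (logMAR);
* 2AFC grating-tilt responses whose difficulty follows the luminance
  amplitude of the red+blue composite at the retina,
  A(phi) = |m_r + m_b e^(i phi)| / (m_r + m_b), with m_r, m_b the 10-cpd
  MTF attenuations of the red/blue primaries (LCA-state dependent);
* 2AFC depth judgments whose point of subjective equality equals the
  interocular difference of horizontal TCA.

The observer is luminance-only: at exact counterphase with m_r = m_b the
composite carries no luminance signal and performance stays at chance, so
synthetic contrast thresholds there are capped by the staircase ceiling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from . import optics
from .chromatic import ChromaticEyeModel, model_defocus, offset_to_phase
from .staircase import StaircaseConfig, run_staircase

__all__ = [
    "ObserverSpec",
    "ConditionContext",
    "Protocol",
    "StudyData",
    "sample_population",
    "simulate_lca_settings",
    "simulate_tca_alignment",
    "respond_acuity",
    "respond_tilt",
    "respond_depth",
    "generate_study",
    "grating_luminance_amplitude",
    "primary_mtf_10cpd",
]

PRIMARIES = (468, 533, 616)
EYES = ("left", "right")
PAIRS = ("blue-vs-red", "green-vs-red")
LCA_STATES = ("uncorrected", "corrected")
LCA_QUANTUM_D = 0.1
TCA_QUANTUM_ARCMIN = 0.115

#: Ratio of perceived-TCA magnitude, LCA corrected vs uncorrected, matching
#: the measured 1.28 / 0.39 arcmin mean deviations.
DEFAULT_TCA_INFLATION = 1.28 / 0.39


@dataclass(frozen=True)
class ConditionContext:
    """One acuity condition: background color x LCA state x TCA state."""

    background: str  # green | purple | white
    lca_state: str  # corrected | uncorrected
    tca_state: str  # corrected | uncorrected
    eye: str = "right"

    def __post_init__(self):
        if self.background not in ("green", "purple", "white"):
            raise ValueError(f"unknown background {self.background!r}")
        if self.lca_state not in LCA_STATES or self.tca_state not in LCA_STATES:
            raise ValueError("states must be 'corrected' or 'uncorrected'")
        if self.eye not in EYES:
            raise ValueError(f"unknown eye {self.eye!r}")

    @property
    def key(self) -> str:
        return f"{self.background}:{self.lca_state}:{self.tca_state}"

    @classmethod
    def from_key(cls, key: str, eye: str = "right") -> "ConditionContext":
        bg, lca, tca = key.split(":")
        return cls(bg, lca, tca, eye)


@dataclass
class ObserverSpec:
    """Ground truth of one synthetic subject.

    ``lca_offsets_d[eye][primary]`` are refraction offsets in diopters
    relative to the green primary; ``tca_arcmin[(eye, pair)]`` are
    (horizontal, vertical) foveal TCA components in the visual-field
    convention measured with LCA uncorrected.  In the LCA-corrected state
    the effective TCA is scaled by ``tca_inflation_corrected``.
    """

    subject_id: str
    lca_offsets_d: dict[str, dict[int, float]]
    tca_arcmin: dict[tuple[str, str], tuple[float, float]]
    lca_setting_sd_d: float = 0.15
    tca_setting_sd_arcmin: float = 0.3
    tca_inflation_corrected: float = DEFAULT_TCA_INFLATION
    acuity_base_logmar: float = -0.10
    acuity_sigma_logmar: float = 0.08
    acuity_deltas: dict[str, float] | None = None
    tilt_sigma_contrast: float = 0.025
    tilt_criterion: float = 2.0
    stereo_sigma_arcmin: float = 0.4
    stereo_blur_bias_arcmin: dict[str, float] = field(
        default_factory=lambda: {"corrected": 0.0, "uncorrected": 0.0}
    )
    lapse: float = 0.02
    rng_seed: int = 0

    def __post_init__(self):
        if self.acuity_sigma_logmar <= 0 or self.tilt_sigma_contrast <= 0:
            raise ValueError("psychometric sigmas must be positive")
        if self.lca_setting_sd_d < 0 or self.tca_setting_sd_arcmin < 0:
            raise ValueError("setting noise sds must be nonnegative")

    def effective_tca(self, eye: str, pair: str, lca_state: str) -> tuple[float, float]:
        h, v = self.tca_arcmin[(eye, pair)]
        scale = self.tca_inflation_corrected if lca_state == "corrected" else 1.0
        return h * scale, v * scale

    def stereo_pse(self, lca_state: str) -> float:
        """Generative PSE: interocular difference of horizontal blue TCA."""
        tr = self.effective_tca("right", "blue-vs-red", lca_state)[0]
        tl = self.effective_tca("left", "blue-vs-red", lca_state)[0]
        return tr - tl + self.stereo_blur_bias_arcmin.get(lca_state, 0.0)

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["tca_arcmin"] = {f"{e}|{p}": list(v) for (e, p), v in self.tca_arcmin.items()}
        return d


def sample_population(n: int = 7, seed: int = 0, **overrides) -> list[ObserverSpec]:
    """Draw a synthetic population mirroring the measured study cohort.

    LCA offsets are drawn around the chromatic-eye-model predictions at the
    primaries (blue -0.52 D, red +0.43 D relative to green) with
    between-subject jitter sd 0.15 D.  Horizontal blue TCA is drawn with
    left-eye mean -0.5 and right-eye mean +0.6 arcmin (sd 1.0); vertical
    components are zero-mean (sd 0.5); green TCA is ~0.55x blue plus noise,
    matching the observed blue:green magnitude ratio of roughly 2.
    """
    rng = np.random.default_rng(seed)
    eye_model = ChromaticEyeModel()
    ref = model_defocus(eye_model, 533)
    mean_offsets = {p: model_defocus(eye_model, p) - ref for p in PRIMARIES}
    out = []
    for i in range(n):
        lca = {}
        for eye in EYES:
            lca[eye] = {533: 0.0}
            for p in (468, 616):
                lca[eye][p] = float(mean_offsets[p] + rng.normal(0.0, 0.15))
        tca = {}
        for eye in EYES:
            h_mean = -0.5 if eye == "left" else 0.6
            bh = float(rng.normal(h_mean, 1.0))
            bv = float(rng.normal(0.0, 0.5))
            tca[(eye, "blue-vs-red")] = (bh, bv)
            tca[(eye, "green-vs-red")] = (
                float(0.55 * bh + rng.normal(0.0, 0.1)),
                float(0.55 * bv + rng.normal(0.0, 0.1)),
            )
        out.append(
            ObserverSpec(
                subject_id=f"S{i + 1}",
                lca_offsets_d=lca,
                tca_arcmin=tca,
                rng_seed=int(rng.integers(2**31 - 1)),
                **overrides,
            )
        )
    return out


# ---------------------------------------------------------------------------
# setting tasks


def simulate_lca_settings(
    obs: ObserverSpec, eye: str, primary: int, n: int = 6, rng=None
) -> np.ndarray:
    """Focus settings (diopters) for one primary: truth + noise, 0.1-D steps."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng if rng is not None else obs.rng_seed)
    true = obs.lca_offsets_d[eye][primary]
    raw = true + rng.normal(0.0, obs.lca_setting_sd_d, size=n)
    return np.round(raw / LCA_QUANTUM_D) * LCA_QUANTUM_D


def simulate_tca_alignment(
    obs: ObserverSpec, eye: str, pair: str, lca_state: str, n: int = 6, rng=None
) -> np.ndarray:
    """Duochrome alignment settings, shape (n, 2): -(effective TCA) + noise.

    Settings are quantized to the 0.115-arcmin fine adjustment step; the
    negated mean setting recovers the effective TCA of that LCA state.
    Horizontal and vertical noise are independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng if rng is not None else obs.rng_seed)
    h, v = obs.effective_tca(eye, pair, lca_state)
    raw = -np.array([h, v]) + rng.normal(0.0, obs.tca_setting_sd_arcmin, size=(n, 2))
    return np.round(raw / TCA_QUANTUM_ARCMIN) * TCA_QUANTUM_ARCMIN


# ---------------------------------------------------------------------------
# optics-linked response models


@lru_cache(maxsize=64)
def _mtf10_cached(defocus_d: float, wavelength_nm: float) -> float:
    pupil = optics.PupilSpec(samples_across=64, padding=4)
    tf = optics.monochromatic_otf(
        pupil, optics.WavefrontSpec(defocus_d=defocus_d), wavelength_nm
    )
    return optics.mtf_at(tf, 10.0)


def primary_mtf_10cpd(lca_state: str, obs: ObserverSpec | None = None, eye: str = "right") -> tuple[float, float]:
    """(m_r, m_b): 10-cpd MTF attenuation of the red and blue primaries.

    With LCA corrected both primaries are in focus; with LCA present the
    red/blue defocus follows the observer's LCA offsets (or the model eye's
    +0.43 / -0.52 D) relative to the green focus.
    """
    if lca_state == "corrected":
        dr = db = 0.0
    else:
        if obs is not None:
            dr = obs.lca_offsets_d[eye][616]
            db = obs.lca_offsets_d[eye][468]
        else:
            m = ChromaticEyeModel()
            ref = model_defocus(m, 533)
            dr = model_defocus(m, 616) - ref
            db = model_defocus(m, 468) - ref
    m_r = _mtf10_cached(round(float(dr), 3), 616.0)
    m_b = _mtf10_cached(round(float(db), 3), 468.0)
    return m_r, m_b


def grating_luminance_amplitude(
    phase_rad: float, m_r: float, m_b: float, normalized: bool = True
) -> float:
    """Luminance amplitude of the composite grating at the retina.

    With ``normalized=True`` this is the shape function
    A(phi) = |m_r + m_b e^(i phi)| / (m_r + m_b): gratings in phase add
    (A = 1); in counterphase with equal attenuation they cancel (A = 0),
    leaving a hue-only pattern invisible to a luminance-only observer.
    With ``normalized=False`` the amplitude is referenced to perfect optics,
    |m_r + m_b e^(i phi)| / 2, so defocused primaries (LCA present) lower
    the in-phase amplitude and raise thresholds overall - the scaling the
    tilt responder uses.
    """
    if m_r < 0 or m_b < 0 or m_r + m_b == 0:
        raise ValueError("MTF attenuations must be nonnegative, not both zero")
    denom = (m_r + m_b) if normalized else 2.0
    return float(abs(m_r + m_b * np.exp(1j * phase_rad)) / denom)


# ---------------------------------------------------------------------------
# trial-level response models


from scipy.stats import norm as _norm  # noqa: E402


def _acuity_delta(obs: ObserverSpec, ctx: ConditionContext) -> float:
    """Condition threshold shift (logMAR) relative to the base threshold.

    Explicit per-condition deltas win when supplied; otherwise a documented
    default: the green (monochromatic) background is unaffected by either
    correction, while polychromatic backgrounds pay a fixed LCA penalty and
    a TCA penalty proportional to the eye's blue TCA magnitude.
    """
    if obs.acuity_deltas is not None:
        return obs.acuity_deltas.get(ctx.key, 0.0)
    if ctx.background == "green":
        return 0.0
    delta = 0.0
    if ctx.lca_state == "uncorrected":
        delta += 0.06
    if ctx.tca_state == "uncorrected":
        h, v = obs.effective_tca(ctx.eye, "blue-vs-red", ctx.lca_state)
        delta += 0.02 * float(np.hypot(h, v))
    return delta


def respond_acuity(obs: ObserverSpec, logmar: float, ctx: ConditionContext, rng) -> bool:
    """One 4AFC tumbling-E response: correct with probability
    0.25 + (0.75 - lambda) Phi((logMAR - t_c) / sigma)."""
    t_c = obs.acuity_base_logmar + _acuity_delta(obs, ctx)
    p = 0.25 + (0.75 - obs.lapse) * _norm.cdf((logmar - t_c) / obs.acuity_sigma_logmar)
    return bool(rng.random() < p)


def respond_tilt(
    obs: ObserverSpec,
    contrast: float,
    phase_offset_arcmin: float,
    lca_state: str,
    rng,
    eye: str = "right",
    sf_cpd: float = 10.0,
) -> bool:
    """One 2AFC grating-tilt response.

    The retinal red-blue offset is the displayed offset plus the observer's
    effective blue TCA (horizontal); the luminance-component amplitude
    A(phi) scales the effective contrast, and
    p(correct) = 0.5 + (0.5 - lambda) Phi(contrast A / sigma - criterion).
    """
    if not 0 < contrast <= 1:
        raise ValueError("contrast must be in (0, 1]")
    tca_h = obs.effective_tca(eye, "blue-vs-red", lca_state)[0]
    phi = offset_to_phase(phase_offset_arcmin + tca_h, sf_cpd)
    m_r, m_b = primary_mtf_10cpd(lca_state, obs, eye)
    a = grating_luminance_amplitude(phi, m_r, m_b, normalized=False)
    d = contrast * a / obs.tilt_sigma_contrast - obs.tilt_criterion
    p = 0.5 + (0.5 - obs.lapse) * _norm.cdf(d)
    return bool(rng.random() < p)


def respond_depth(obs: ObserverSpec, disparity_arcmin: float, lca_state: str, rng) -> bool:
    """One 2AFC depth judgment: True = "blue nearer".

    p(blue nearer) = lambda + (1 - 2 lambda) Phi((disparity - PSE) / sigma)
    with the generative PSE equal to the interocular horizontal TCA
    difference (plus any blur-bias term, default 0); the symmetric lapse
    keeps responses off the floor/ceiling as real observers do.
    """
    if not np.isfinite(disparity_arcmin):
        raise ValueError("disparity must be finite")
    pse = obs.stereo_pse(lca_state)
    p = obs.lapse + (1 - 2 * obs.lapse) * _norm.cdf(
        (disparity_arcmin - pse) / obs.stereo_sigma_arcmin
    )
    return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# full-study generation


@dataclass(frozen=True)
class Protocol:
    """Trial-count bookkeeping for a complete synthetic study.

    Defaults follow the measurement protocol: six settings per LCA primary
    and per TCA condition, 8 runs x 40 trials of 2-down/1-up staircase per
    acuity condition (0.05-logMAR steps from 0.6), 3 repeats of a 40-trial
    contrast staircase (x1.3 steps from 0.5) at each of seven red-blue
    offsets, and 10 constant-stimulus judgments at each of 9 disparities.
    """

    tasks: tuple[str, ...] = ("lca", "tca", "acuity", "csf", "stereo")
    lca_n_settings: int = 6
    tca_n_settings: int = 6
    acuity_runs: int = 8
    acuity_trials_per_run: int = 40
    acuity_step_logmar: float = 0.05
    acuity_start_logmar: float = 0.6
    csf_repeats: int = 3
    csf_trials_per_run: int = 40
    csf_step_factor: float = 1.3
    csf_start_contrast: float = 0.5
    csf_offsets_arcmin: tuple[float, ...] = (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0)
    stereo_disparities_arcmin: tuple[float, ...] = tuple(
        0.5 * d for d in range(-4, 5)
    )
    stereo_reps: int = 10
    tested_eye: str = "right"

    def acuity_conditions(self) -> list[ConditionContext]:
        """The 10 acuity conditions: green x LCA state (digital TCA correction
        is a no-op on the green background), purple/white x LCA x TCA."""
        out = []
        for lca in LCA_STATES:
            out.append(ConditionContext("green", lca, "uncorrected", self.tested_eye))
        for bg in ("purple", "white"):
            for lca in LCA_STATES:
                for tca in LCA_STATES:
                    out.append(ConditionContext(bg, lca, tca, self.tested_eye))
        return out


@dataclass
class StudyData:
    """In-memory synthetic study: the three data tables plus the truth manifest."""

    lca_settings: pd.DataFrame
    tca_measurements: pd.DataFrame
    trials: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "lca_settings": self.lca_settings,
            "tca_measurements": self.tca_measurements,
            "trials": self.trials,
        }
        for name, df in tables.items():
            if df is not None and not df.empty:
                df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


def _seed_for(base: int, *parts) -> int:
    h = np.uint64(base)
    for p in parts:
        for ch in str(p):
            h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**63 - 1))
    return int(h % (2**31 - 1))


def generate_study(
    population: list[ObserverSpec],
    protocol: Protocol = Protocol(),
    seed: int = 0,
    out_dir=None,
) -> StudyData:
    """Simulate every requested task for every observer; optionally write CSVs.

    Deterministic for a given seed: per-(subject, task, condition) substreams
    are derived by hashing, so adding or removing tasks does not reshuffle
    the remaining ones.  The stereo disparity grid is centered on each
    subject's TCA-predicted disparity for the tested LCA state (the
    experimenter knows the TCA measurement before the stereo run), keeping
    the PSE inside the sampled range.
    """
    lca_rows, tca_rows, trial_rows = [], [], []
    measured_tca: dict[tuple[str, str, str, str], float] = {}

    for obs in population:
        sid = obs.subject_id
        if "lca" in protocol.tasks:
            for eye in EYES:
                for p in PRIMARIES:
                    rng = np.random.default_rng(_seed_for(seed, sid, "lca", eye, p))
                    for j, s in enumerate(
                        simulate_lca_settings(obs, eye, p, protocol.lca_n_settings, rng)
                    ):
                        lca_rows.append(
                            {"subject": sid, "eye": eye, "primary_nm": p,
                             "setting_diopters": round(float(s), 4), "repeat_index": j}
                        )
        if "tca" in protocol.tasks:
            for eye in EYES:
                for pair in PAIRS:
                    for state in LCA_STATES:
                        rng = np.random.default_rng(
                            _seed_for(seed, sid, "tca", eye, pair, state)
                        )
                        settings = simulate_tca_alignment(
                            obs, eye, pair, state, protocol.tca_n_settings, rng
                        )
                        meas = -settings.mean(axis=0)
                        sd = settings.std(axis=0, ddof=1) if len(settings) > 1 else [0.0, 0.0]
                        tca_rows.append(
                            {"subject": sid, "eye": eye, "pair": pair,
                             "lca_state": state,
                             "horizontal_arcmin": round(float(meas[0]), 6),
                             "vertical_arcmin": round(float(meas[1]), 6),
                             "sd_h": round(float(sd[0]), 6),
                             "sd_v": round(float(sd[1]), 6)}
                        )
                        measured_tca[(sid, eye, pair, state)] = float(meas[0])

        if "acuity" in protocol.tasks:
            for ctx in protocol.acuity_conditions():
                for run in range(protocol.acuity_runs):
                    rng = np.random.default_rng(
                        _seed_for(seed, sid, "acuity", ctx.key, run)
                    )
                    cfg = StaircaseConfig(
                        start_level=protocol.acuity_start_logmar,
                        step=protocol.acuity_step_logmar,
                        step_mode="additive",
                        n_trials=protocol.acuity_trials_per_run,
                        min_level=-0.5,
                        max_level=1.2,
                        task="acuity",
                    )
                    recs = run_staircase(
                        cfg,
                        lambda lv: respond_acuity(obs, lv, ctx, rng),
                        rng_seed=_seed_for(seed, sid, "acuity-alt", ctx.key, run),
                    )
                    for r in recs:
                        trial_rows.append(
                            {"subject": sid, "task": "acuity", "condition": ctx.key,
                             "run": run, "trial": r.index,
                             "level": round(r.level, 6), "response": r.response,
                             "correct": int(r.correct)}
                        )

        if "csf" in protocol.tasks:
            for state in LCA_STATES:
                for offset in protocol.csf_offsets_arcmin:
                    for rep in range(protocol.csf_repeats):
                        rng = np.random.default_rng(
                            _seed_for(seed, sid, "csf", state, offset, rep)
                        )
                        cfg = StaircaseConfig(
                            start_level=protocol.csf_start_contrast,
                            step=protocol.csf_step_factor,
                            step_mode="multiplicative",
                            n_trials=protocol.csf_trials_per_run,
                            min_level=1e-4,
                            max_level=1.0,
                            task="csf",
                        )
                        recs = run_staircase(
                            cfg,
                            lambda c: respond_tilt(
                                obs, c, offset, state, rng, eye=protocol.tested_eye
                            ),
                            rng_seed=_seed_for(seed, sid, "csf-alt", state, offset, rep),
                            n_alternatives=2,
                        )
                        for r in recs:
                            trial_rows.append(
                                {"subject": sid, "task": "csf",
                                 "condition": f"{state}:{offset:+.1f}",
                                 "run": rep, "trial": r.index,
                                 "level": round(r.level, 8), "response": r.response,
                                 "correct": int(r.correct)}
                            )

        if "stereo" in protocol.tasks:
            for state in LCA_STATES:
                rng = np.random.default_rng(_seed_for(seed, sid, "stereo", state))
                tr = measured_tca.get((sid, "right", "blue-vs-red", state))
                tl = measured_tca.get((sid, "left", "blue-vs-red", state))
                # center the grid on the TCA-predicted disparity, snapped to
                # the grid spacing so levels stay commensurate across subjects
                if tr is None or tl is None:
                    center = 0.0
                else:
                    spacing = float(
                        np.median(np.diff(sorted(protocol.stereo_disparities_arcmin)))
                    )
                    center = round((tr - tl) / spacing) * spacing
                for d in protocol.stereo_disparities_arcmin:
                    disparity = d + center
                    for rep in range(protocol.stereo_reps):
                        resp = respond_depth(obs, disparity, state, rng)
                        trial_rows.append(
                            {"subject": sid, "task": "stereo", "condition": state,
                             "run": 0, "trial": rep,
                             "level": round(float(disparity), 6),
                             "response": int(resp), "correct": int(resp)}
                        )

    study = StudyData(
        lca_settings=pd.DataFrame(lca_rows),
        tca_measurements=pd.DataFrame(tca_rows),
        trials=pd.DataFrame(trial_rows),
        manifest={
            "seed": seed,
            "protocol": asdict(protocol),
            "observers": [o.to_manifest() for o in population],
        },
    )
    if out_dir is not None:
        study.write(out_dir)
    return study
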