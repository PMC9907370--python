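"""End-to-end analysis of a study bundle (settings and trial tables).

The pipeline mirrors the experimental logic: per-subject LCA refractions
compared against the chromatic-eye-model polynomial; TCA condition medians
and their headline deviation statistics; per-condition acuity thresholds
(pooled trials, 78.1%-correct criterion) with the fourteen paired
comparisons; contrast thresholds versus retinal red-blue phase with the
period-6-arcmin sinusoid fit; and TCA-predicted versus observed
chromostereopsis with the repeated-measures correlation.

Input is a :class:`StudyBundle` - paths or DataFrames for
``lca_settings.csv``, ``tca_measurements.csv`` and ``trials.csv`` in the
schemas written by :func:`chromasim.observers.generate_study`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatic import (
    ChromaticEyeModel,
    TCAMeasurement,
    model_defocus,
    predict_disparity,
    round_half_away,
    tca_summary,
)
from .psychometric import (
    DegenerateFitError,
    PsychometricModel,
    fit_threshold_sinusoid,
    paired_t_test,
    pse_from_constant_stimuli,
    rm_corr,
)

__all__ = [
    "StudyBundle",
    "lca_analysis",
    "tca_analysis",
    "acuity_analysis",
    "csf_analysis",
    "stereo_analysis",
    "report",
    "ACUITY_QUESTIONS",
    "ACUITY_CRITERION",
    "CSF_CRITERION",
]

ACUITY_CRITERION = 0.781
CSF_CRITERION = 0.75
PRIMARIES = (468, 533, 616)


@dataclass
class StudyBundle:
    """The three study tables (+ optional ground-truth manifest)."""

    lca_settings: pd.DataFrame | None = None
    tca_measurements: pd.DataFrame | None = None
    trials: pd.DataFrame | None = None
    manifest: dict | None = None

    _SCHEMAS = {
        "lca_settings": {"subject", "eye", "primary_nm", "setting_diopters", "repeat_index"},
        "tca_measurements": {"subject", "eye", "pair", "lca_state",
                             "horizontal_arcmin", "vertical_arcmin", "sd_h", "sd_v"},
        "trials": {"subject", "task", "condition", "run", "trial", "level",
                   "response", "correct"},
    }

    def __post_init__(self):
        for name, cols in self._SCHEMAS.items():
            df = getattr(self, name)
            if df is not None and not cols.issubset(df.columns):
                missing = cols - set(df.columns)
                raise ValueError(f"{name} is missing columns {sorted(missing)}")

    @classmethod
    def load(cls, directory) -> "StudyBundle":
        d = Path(directory)
        def read(name):
            p = d / f"{name}.csv"
            return pd.read_csv(p) if p.exists() else None
        manifest = None
        if (d / "manifest.json").exists():
            manifest = json.loads((d / "manifest.json").read_text())
        return cls(
            lca_settings=read("lca_settings"),
            tca_measurements=read("tca_measurements"),
            trials=read("trials"),
            manifest=manifest,
        )


# ---------------------------------------------------------------------------
# LCA


def lca_analysis(bundle: StudyBundle, eye_model: ChromaticEyeModel | None = None) -> dict:
    """Per-subject LCA table (mean +- sd per primary, green re-zeroed) and the
    deviation of each subject from the chromatic-eye-model polynomial."""
    df = bundle.lca_settings
    if df is None or df.empty:
        raise ValueError("bundle has no LCA settings")
    eye_model = eye_model or ChromaticEyeModel()
    ref = model_defocus(eye_model, 533)
    model_offsets = {p: model_defocus(eye_model, p) - ref for p in PRIMARIES}

    stats = (
        df.groupby(["subject", "eye", "primary_nm"])["setting_diopters"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    stats["std"] = stats["std"].fillna(0.0)
    stats["low_n"] = stats["count"] < 2
    # re-reference every (subject, eye) to its green mean
    green = stats[stats.primary_nm == 533].set_index(["subject", "eye"])["mean"]
    stats["offset_d"] = stats["mean"] - stats.set_index(["subject", "eye"]).index.map(green)
    stats["model_offset_d"] = stats["primary_nm"].map(model_offsets)
    stats["deviation_d"] = stats["offset_d"] - stats["model_offset_d"]

    incomplete = sorted(
        {
            s
            for s, grp in stats.groupby("subject")
            if set(grp.primary_nm.unique()) != set(PRIMARIES)
        }
    )
    piv = stats.pivot_table(index=["subject", "eye"], columns="primary_nm",
                            values="offset_d")
    if 616 in piv.columns and 468 in piv.columns:
        blue_red = piv[616] - piv[468]
    else:
        blue_red = pd.Series(np.nan, index=piv.index)
    return {
        "table": stats,
        "incomplete_subjects": incomplete,
        "mean_abs_deviation_d": float(stats["deviation_d"].abs().mean()),
        "mean_deviation_d": float(stats["deviation_d"].mean()),
        "red_minus_blue_span_d": float(blue_red.mean()),
        "model_red_minus_blue_d": float(model_offsets[616] - model_offsets[468]),
    }


# ---------------------------------------------------------------------------
# TCA


def tca_analysis(bundle: StudyBundle) -> dict:
    """Per-subject TCA table, condition medians, and headline summaries."""
    df = bundle.tca_measurements
    if df is None or df.empty:
        raise ValueError("bundle has no TCA measurements")
    measurements = [
        TCAMeasurement(
            eye=r.eye, pair=r.pair, lca_state=r.lca_state,
            horizontal=float(r.horizontal_arcmin), vertical=float(r.vertical_arcmin),
            sd_h=float(r.sd_h), sd_v=float(r.sd_v), subject=str(r.subject),
        )
        for r in df.itertuples()
    ]
    summ = tca_summary(measurements)
    expected = {(e, p, s) for e in ("left", "right")
                for p in ("blue-vs-red", "green-vs-red")
                for s in ("corrected", "uncorrected")}
    present = set(map(tuple, df[["eye", "pair", "lca_state"]].drop_duplicates().values))
    return {
        "per_subject": df.copy(),
        "condition_medians": summ.by_condition,
        "abs_dev_by_pair": {k: round_half_away(v) for k, v in summ.abs_dev_by_pair.items()},
        "abs_dev_by_lca_state": {k: round_half_away(v) for k, v in summ.abs_dev_by_lca_state.items()},
        "eye_mean_horizontal": {k: round_half_away(v) for k, v in summ.eye_mean_horizontal.items()},
        "missing_conditions": sorted(expected - present),
    }


# ---------------------------------------------------------------------------
# acuity

#: The fourteen paired questions: (label, condition set A, condition set B);
#: the test asks whether thresholds in A are lower (better) than in B.
#: "mono" = green with LCA corrected; "poly" pools purple and white.
def _cond(bg, lca, tca):
    return f"{bg}:{lca}:{tca}"


_MONO = [_cond("green", "corrected", "uncorrected")]
_POLY_UU = [_cond(bg, "uncorrected", "uncorrected") for bg in ("purple", "white")]
_POLY_CC = [_cond(bg, "corrected", "corrected") for bg in ("purple", "white")]

ACUITY_QUESTIONS = [
    ("Q1 mono vs purple", _MONO, [_cond("purple", "uncorrected", "uncorrected")]),
    ("Q2 mono vs white", _MONO, [_cond("white", "uncorrected", "uncorrected")]),
    ("Q3 mono vs polychromatic", _MONO, _POLY_UU),
    ("Q4 LCA benefit, mono", [_cond("green", "corrected", "uncorrected")],
     [_cond("green", "uncorrected", "uncorrected")]),
    ("Q5 LCA benefit, purple", [_cond("purple", "corrected", "uncorrected")],
     [_cond("purple", "uncorrected", "uncorrected")]),
    ("Q6 LCA benefit, white", [_cond("white", "corrected", "uncorrected")],
     [_cond("white", "uncorrected", "uncorrected")]),
    ("Q7 LCA benefit, polychromatic",
     [_cond("purple", "corrected", "uncorrected"), _cond("white", "corrected", "uncorrected")],
     _POLY_UU),
    ("Q8 TCA benefit, purple", [_cond("purple", "uncorrected", "corrected")],
     [_cond("purple", "uncorrected", "uncorrected")]),
    ("Q9 TCA benefit, white", [_cond("white", "uncorrected", "corrected")],
     [_cond("white", "uncorrected", "uncorrected")]),
    ("Q10 TCA benefit, polychromatic",
     [_cond("purple", "uncorrected", "corrected"), _cond("white", "uncorrected", "corrected")],
     _POLY_UU),
    ("Q11 LCA+TCA benefit, purple", [_cond("purple", "corrected", "corrected")],
     [_cond("purple", "uncorrected", "uncorrected")]),
    ("Q12 LCA+TCA benefit, white", [_cond("white", "corrected", "corrected")],
     [_cond("white", "uncorrected", "uncorrected")]),
    ("Q13 LCA+TCA benefit, polychromatic", _POLY_CC, _POLY_UU),
    ("Q14 mono vs fully corrected polychromatic", _MONO, _POLY_CC),
]


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj


def acuity_analysis(bundle: StudyBundle, criterion: float = ACUITY_CRITERION) -> dict:
    """Pooled psychometric thresholds per subject x condition plus the
    fourteen paired t tests on logMAR (raw and Holm-adjusted p values)."""
    trials = bundle.trials
    if trials is None or trials[trials.task == "acuity"].empty:
        raise ValueError("bundle has no acuity trials")
    acu = trials[trials.task == "acuity"]
    rows, excluded = [], []
    for (subject, condition), grp in acu.groupby(["subject", "condition"]):
        try:
            res = PsychometricModel.from_trials(grp, chance=0.25).fit()
            rows.append(
                {"subject": subject, "condition": condition,
                 "threshold_logmar": res.threshold_at(criterion),
                 "mu": res.mu, "sigma": res.sigma,
                 "n_trials": int(len(grp))}
            )
        except (DegenerateFitError, ValueError) as err:
            excluded.append({"subject": subject, "condition": condition,
                             "reason": str(err)})
    thresholds = pd.DataFrame(rows)
    if thresholds.empty:
        raise ValueError("no acuity condition produced a usable fit")
    wide = thresholds.pivot(index="subject", columns="condition",
                            values="threshold_logmar")

    tests = []
    for label, set_a, set_b in ACUITY_QUESTIONS:
        have_a = [c for c in set_a if c in wide.columns]
        have_b = [c for c in set_b if c in wide.columns]
        if not have_a or not have_b:
            tests.append({"question": label, "t": np.nan, "p": np.nan,
                          "mean_diff_logmar": np.nan, "n": 0})
            continue
        a = wide[have_a].mean(axis=1)
        b = wide[have_b].mean(axis=1)
        paired = pd.concat([a, b], axis=1, keys=["a", "b"]).dropna()
        try:
            t, p = paired_t_test(paired["a"].values, paired["b"].values)
        except ValueError:
            t, p = np.nan, np.nan
        tests.append({"question": label, "t": t, "p": p,
                      "mean_diff_logmar": float((paired["a"] - paired["b"]).mean()),
                      "n": int(len(paired))})
    tests = pd.DataFrame(tests)
    valid = tests["p"].notna()
    tests["p_holm"] = np.nan
    if valid.any():
        tests.loc[valid, "p_holm"] = _holm(tests.loc[valid, "p"].to_numpy())
    group_means = wide.mean(axis=0).to_dict()
    return {"thresholds": thresholds, "group_mean_logmar": group_means,
            "tests": tests, "excluded": excluded}


# ---------------------------------------------------------------------------
# contrast sensitivity


def _blue_tca_h(bundle: StudyBundle, subject, eye: str, lca_state: str) -> float:
    df = bundle.tca_measurements
    if df is None:
        return 0.0
    sel = df[(df.subject == subject) & (df.eye == eye)
             & (df.pair == "blue-vs-red") & (df.lca_state == lca_state)]
    return float(sel.horizontal_arcmin.iloc[0]) if len(sel) else 0.0


def csf_analysis(
    bundle: StudyBundle, criterion: float = CSF_CRITERION, tested_eye: str = "right"
) -> dict:
    """75%-correct contrast thresholds vs retinal phase and the sinusoid fit.

    Displayed red-blue offsets are converted to *retinal* offsets by adding
    the subject's measured horizontal blue TCA for the matching LCA state;
    thresholds are fit (per subject and state) with the fixed-period
    sinusoid, and the offsets of minimum/maximum threshold are reported.
    """
    trials = bundle.trials
    if trials is None or trials[trials.task == "csf"].empty:
        raise ValueError("bundle has no contrast-sensitivity trials")
    csf = trials[trials.task == "csf"].copy()
    parts = csf.condition.str.split(":", expand=True)
    csf["lca_state"], csf["offset"] = parts[0], parts[1].astype(float)

    thr_rows = []
    for (subject, state, offset), grp in csf.groupby(["subject", "lca_state", "offset"]):
        try:
            res = PsychometricModel.from_trials(grp, chance=0.5).fit()
            thr = res.threshold_at(criterion)
        except (DegenerateFitError, ValueError):
            continue
        retinal = offset + _blue_tca_h(bundle, subject, tested_eye, state)
        thr_rows.append(
            {"subject": subject, "lca_state": state, "offset_arcmin": offset,
             "retinal_offset_arcmin": retinal, "threshold_contrast": thr}
        )
    thresholds = pd.DataFrame(thr_rows)
    if thresholds.empty:
        raise ValueError("no contrast condition produced a usable fit")

    fits = []
    for (subject, state), grp in thresholds.groupby(["subject", "lca_state"]):
        if grp.retinal_offset_arcmin.nunique() < 3:
            continue
        fit = fit_threshold_sinusoid(
            grp.retinal_offset_arcmin.values, grp.threshold_contrast.values
        )
        fits.append(
            {"subject": subject, "lca_state": state,
             "amplitude": fit.amplitude, "baseline": fit.offset,
             "phase_arcmin": fit.phase, "argmin_arcmin": fit.argmin,
             "argmax_arcmin": fit.argmax,
             "min_threshold": float(fit.predict(fit.argmin)),
             "min_observed_threshold": float(grp.threshold_contrast.min())}
        )
    return {"thresholds": thresholds, "sinusoid_fits": pd.DataFrame(fits)}


# ---------------------------------------------------------------------------
# chromostereopsis


def stereo_analysis(
    bundle: StudyBundle,
    system_tca: dict[str, float] | None = None,
) -> dict:
    """Predicted (from TCA) versus observed chromostereopsis.

    ``system_tca`` optionally maps eye -> horizontal instrument TCA (arcmin)
    to be added to each eye's measurement before prediction.  Returns the
    per-subject x LCA-state comparison, the repeated-measures correlation
    over all pairs, and the mean observed-minus-predicted residual per state
    (the differential-blur test: a blur contribution would push the
    uncorrected-state residuals toward more crossed disparity).
    """
    trials = bundle.trials
    if trials is None or trials[trials.task == "stereo"].empty:
        raise ValueError("bundle has no stereo trials")
    if bundle.tca_measurements is None:
        raise ValueError("stereo analysis needs TCA measurements")
    sys_tca = system_tca or {"left": 0.0, "right": 0.0}
    stereo = trials[trials.task == "stereo"]

    rows, excluded = [], []
    for (subject, state), grp in stereo.groupby(["subject", "condition"]):
        th = {}
        for eye in ("left", "right"):
            sel = bundle.tca_measurements[
                (bundle.tca_measurements.subject == subject)
                & (bundle.tca_measurements.eye == eye)
                & (bundle.tca_measurements.pair == "blue-vs-red")
                & (bundle.tca_measurements.lca_state == state)
            ]
            if sel.empty:
                excluded.append({"subject": subject, "lca_state": state,
                                 "reason": f"missing {eye}-eye TCA"})
                th = None
                break
            th[eye] = float(sel.horizontal_arcmin.iloc[0]) + sys_tca.get(eye, 0.0)
        if th is None:
            continue
        counts = grp.groupby("level")["response"].agg(["count", "sum"])
        res = pse_from_constant_stimuli(
            counts.index.values, counts["count"].values, counts["sum"].values
        )
        rows.append(
            {"subject": subject, "lca_state": state,
             "predicted_arcmin": predict_disparity(th["right"], th["left"]),
             "observed_pse_arcmin": res.pse,
             "extrapolated": res.extrapolated}
        )
    comparison = pd.DataFrame(rows)
    if comparison.empty:
        raise ValueError("no subject had both TCA and stereo data")
    comparison["residual_arcmin"] = (
        comparison.observed_pse_arcmin - comparison.predicted_arcmin
    )
    corr, corr_error = None, None
    try:
        corr = rm_corr(
            comparison.subject.values,
            comparison.predicted_arcmin.values,
            comparison.observed_pse_arcmin.values,
        )
    except ValueError as err:
        # a single remaining subject keeps the per-subject comparison and
        # carries the diagnostic; degenerate predictors (all equal) raise
        if len(comparison.subject.unique()) >= 2:
            raise
        corr_error = str(err)
    mean_resid = (
        comparison.groupby("lca_state")["residual_arcmin"].mean().to_dict()
    )
    return {"comparison": comparison, "rm_corr": corr,
            "rm_corr_error": corr_error,
            "mean_residual_by_state": mean_resid, "excluded": excluded}


# ---------------------------------------------------------------------------
# report


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        df = obj.reset_index() if not isinstance(obj.index, pd.RangeIndex) else obj
        return json.loads(df.to_json(orient="records", double_precision=10))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "summary") and hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def report(bundle: StudyBundle, sections=("lca", "tca", "acuity", "csf", "stereo"),
           system_tca=None) -> tuple[str, dict]:
    """Run the requested analyses; return (text report, JSON-ready dict).

    Sections whose inputs are absent are reported as "no data" rather than
    failing, so partial bundles still produce a document.
    """
    runners = {
        "lca": lambda: lca_analysis(bundle),
        "tca": lambda: tca_analysis(bundle),
        "acuity": lambda: acuity_analysis(bundle),
        "csf": lambda: csf_analysis(bundle),
        "stereo": lambda: stereo_analysis(bundle, system_tca=system_tca),
    }
    results: dict = {}
    lines = ["Chromatic-aberration study report", "=" * 40]
    for name in sections:
        lines.append(f"\n[{name.upper()}]")
        try:
            res = runners[name]()
        except ValueError as err:
            results[name] = {"no_data": str(err)}
            lines.append(f"  no data ({err})")
            continue
        results[name] = _jsonable(res)
        lines.extend(_section_text(name, res))
    return "\n".join(lines) + "\n", results


def _section_text(name: str, res: dict) -> list[str]:
    out = []
    if name == "lca":
        out.append(
            f"  mean deviation from model {res['mean_deviation_d']:+.3f} D "
            f"(|.| {res['mean_abs_deviation_d']:.3f} D); "
            f"red-blue span {res['red_minus_blue_span_d']:.3f} D "
            f"(model {res['model_red_minus_blue_d']:.3f} D)"
        )
    elif name == "tca":
        pair = res["abs_dev_by_pair"]
        state = res["abs_dev_by_lca_state"]
        eye = res["eye_mean_horizontal"]
        out.append(f"  mean |TCA| by pair (arcmin): {pair}")
        out.append(f"  mean |TCA| by LCA state (arcmin): {state}")
        out.append(f"  mean horizontal TCA by eye (arcmin): {eye}")
    elif name == "acuity":
        for cond, v in sorted(res["group_mean_logmar"].items()):
            out.append(f"  {cond:38s} mean logMAR {v:+.3f}")
        for r in res["tests"].itertuples():
            star = "*" if (r.p == r.p and r.p <= 0.05) else " "
            out.append(f"  {r.question:42s} t={r.t:+.3f} p={r.p:.5f}{star}")
    elif name == "csf":
        for r in res["sinusoid_fits"].itertuples():
            out.append(
                f"  {r.subject} {r.lca_state:11s} min thr {r.min_threshold:.4f} "
                f"at retinal offset {r.argmin_arcmin:+.2f}'; amp {r.amplitude:.4f}"
            )
    elif name == "stereo":
        c = res["rm_corr"]
        out.append(f"  {c.summary()}" if c is not None
                   else f"  rm correlation unavailable: {res['rm_corr_error']}")
        for state, v in sorted(res["mean_residual_by_state"].items()):
            out.append(f"  mean observed-predicted ({state}): {v:+.3f} arcmin")
    return out
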