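"""Psychometric models: cumulative-Gaussian fits, sinusoid threshold curves,
PSEs, repeated-measures correlation, paired tests.

The central object is :class:`PsychometricModel`, a maximum-likelihood
cumulative-Gaussian model of n-alternative forced-choice data,

    psi(x) = gamma + (1 - gamma - lambda) * Phi((x - mu) / sigma),

with chance rate ``gamma`` fixed by the task (0.25 for 4AFC, 0.5 for 2AFC)
and lapse rate ``lambda`` either fixed (default 0.02) or free on [0, 0.06].
``fit()`` returns a :class:`PsychometricResults` carrying the estimates,
criterion thresholds (e.g. 78.1% correct for acuity, 75% for contrast),
nonparametric bootstrap confidence intervals, and a ``summary()`` table.

Also here: the sinusoid model of contrast threshold versus red-blue grating
offset (period 6 arcmin = one cycle of a 10-cpd grating), the
point-of-subjective-equality fit for constant-stimulus depth judgments, the
repeated-measures (within-subject, common-slope) correlation, and the
classical paired t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PsychometricModel",
    "PsychometricResults",
    "DegenerateFitError",
    "fit_psychometric",
    "threshold_at",
    "SinusoidModel",
    "SinusoidResults",
    "fit_threshold_sinusoid",
    "PSEResults",
    "pse_from_constant_stimuli",
    "RmCorrResult",
    "rm_corr",
    "paired_t_test",
]

_NORM = stats.norm


class DegenerateFitError(ValueError):
    """The data cannot constrain a psychometric fit.

    Raised when performance never leaves chance or never leaves ceiling:
    collect trials at easier/harder levels, or widen the staircase range.
    """


# ---------------------------------------------------------------------------
# cumulative-Gaussian psychometric model


@dataclass(frozen=True)
class PsychometricModel:
    """Binomial MLE model of proportion correct versus stimulus level.

    Parameters
    ----------
    levels, n_trials, n_success : array_like
        Distinct stimulus levels, trials shown and correct responses at each.
    chance : float
        Guess rate gamma (1/n for an nAFC task); 0 for yes/no style data.
    lapse : float or "free"
        Fixed lapse rate, or ``"free"`` to estimate it on [0, 0.06].
    """

    levels: tuple[float, ...]
    n_trials: tuple[int, ...]
    n_success: tuple[int, ...]
    chance: float = 0.25
    lapse: float | str = 0.02

    def __post_init__(self):
        x = np.asarray(self.levels, float)
        n = np.asarray(self.n_trials, int)
        k = np.asarray(self.n_success, int)
        if not (x.size == n.size == k.size):
            raise ValueError("levels, n_trials, n_success must be equal length")
        if np.unique(x[n > 0]).size < 2:
            raise ValueError("need trials at >= 2 distinct levels")
        if np.any(k > n) or np.any(k < 0) or np.any(n < 0):
            raise ValueError("require 0 <= successes <= trials at every level")
        if not 0 <= self.chance < 1:
            raise ValueError("chance rate must be in [0, 1)")
        if isinstance(self.lapse, str) and self.lapse != "free":
            raise ValueError("lapse must be a number or 'free'")

    @classmethod
    def from_trials(
        cls,
        df: pd.DataFrame,
        level_col: str = "level",
        correct_col: str = "correct",
        chance: float = 0.25,
        lapse: float | str = 0.02,
    ) -> "PsychometricModel":
        """Aggregate a trial table (one row per trial) into binomial counts."""
        grouped = df.groupby(level_col)[correct_col].agg(["count", "sum"])
        return cls(
            levels=tuple(float(v) for v in grouped.index),
            n_trials=tuple(int(v) for v in grouped["count"]),
            n_success=tuple(int(v) for v in grouped["sum"]),
            chance=chance,
            lapse=lapse,
        )

    # -- likelihood ---------------------------------------------------------

    def _arrays(self):
        x = np.asarray(self.levels, float)
        n = np.asarray(self.n_trials, float)
        k = np.asarray(self.n_success, float)
        keep = n > 0
        return x[keep], n[keep], k[keep]

    def predict(self, x, mu: float, sigma: float, lapse: float) -> np.ndarray:
        g = self.chance
        p = g + (1.0 - g - lapse) * _NORM.cdf((np.asarray(x, float) - mu) / sigma)
        return np.clip(p, 1e-9, 1 - 1e-9)

    def loglike(self, mu: float, sigma: float, lapse: float) -> float:
        x, n, k = self._arrays()
        p = self.predict(x, mu, sigma, lapse)
        return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    # -- fitting ------------------------------------------------------------

    def fit(self, start: tuple[float, float] | None = None) -> "PsychometricResults":
        """Maximum-likelihood fit; raises :class:`DegenerateFitError` when the
        observed proportions never leave chance or ceiling.

        ``start`` optionally warm-starts the optimizer at (mu, sigma) - used
        by the bootstrap, where the point estimate is an excellent start and
        multistart would triple the cost for nothing.
        """
        x, n, k = self._arrays()
        prop = k / n
        if np.all(k == n) or np.all(k == 0):
            raise DegenerateFitError(
                "all responses correct (or all wrong): threshold is unconstrained"
            )
        span = float(x.max() - x.min())
        lapse_free = self.lapse == "free"
        lapse0 = 0.02 if lapse_free else float(self.lapse)

        # initial mu: level whose proportion is closest to the sigmoid midpoint
        mid = self.chance + (1.0 - self.chance - lapse0) / 2.0
        mu0 = float(x[np.argmin(np.abs(prop - mid))])
        sig_lo, sig_hi = span * 1e-4, span * 10.0

        def nll(theta):
            mu, log_sigma = theta[0], theta[1]
            lp = theta[2] if lapse_free else lapse0
            return -self.loglike(mu, np.exp(log_sigma), lp)

        if start is not None:
            starts = [(float(start[0]), float(np.clip(start[1], sig_lo, sig_hi)))]
        else:
            starts = [(mu0, s) for s in (span / 8.0, span / 3.0, span)]
        best = None
        for mu_init, sig0 in starts:
            theta0 = [mu_init, np.log(sig0)] + ([lapse0] if lapse_free else [])
            bounds = [
                (x.min() - 2 * span, x.max() + 2 * span),
                (np.log(sig_lo), np.log(sig_hi)),
            ] + ([(0.0, 0.06)] if lapse_free else [])
            res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        mu = float(best.x[0])
        sigma = float(np.exp(best.x[1]))
        lapse = float(best.x[2]) if lapse_free else lapse0
        return PsychometricResults(
            model=self, mu=mu, sigma=sigma, lapse_rate=lapse, loglike=-float(best.fun)
        )


def threshold_at(mu: float, sigma: float, chance: float, lapse: float, criterion: float) -> float:
    """Stimulus level at a proportion-correct criterion on the full scale.

    level = mu + sigma * Phi^-1((criterion - gamma) / (1 - gamma - lambda)).
    The criterion must lie strictly between chance and 1 - lapse.
    """
    if not chance < criterion < 1.0 - lapse:
        raise ValueError(
            f"criterion {criterion} outside achievable range "
            f"({chance}, {1.0 - lapse})"
        )
    q = (criterion - chance) / (1.0 - chance - lapse)
    return float(mu + sigma * _NORM.ppf(q))


@dataclass(frozen=True)
class PsychometricResults:
    """Fitted cumulative Gaussian with criterion thresholds and bootstrap CIs."""

    model: PsychometricModel
    mu: float
    sigma: float
    lapse_rate: float
    loglike: float

    def predict(self, x) -> np.ndarray:
        return self.model.predict(x, self.mu, self.sigma, self.lapse_rate)

    def threshold_at(self, criterion: float) -> float:
        return threshold_at(
            self.mu, self.sigma, self.model.chance, self.lapse_rate, criterion
        )

    def bootstrap_ci(
        self,
        criterion: float,
        n_boot: int = 500,
        rng_seed: int | None = None,
        ci: float = 0.90,
    ) -> tuple[float, float]:
        """Nonparametric CI on the criterion threshold.

        Successes at each level are resampled Binomial(n_l, p_hat_l) from the
        observed proportions; each replicate is refit and the (1-ci)/2 and
        (1+ci)/2 percentiles of the refitted thresholds are returned.
        Deterministic for a given seed.
        """
        if n_boot < 200:
            raise ValueError("n_boot must be >= 200 for stable percentiles")
        rng = np.random.default_rng(rng_seed)
        x, n, k = self.model._arrays()
        p_obs = k / n
        out = np.empty(n_boot)
        kept = 0
        for _ in range(n_boot):
            k_star = rng.binomial(n.astype(int), p_obs)
            try:
                res = PsychometricModel(
                    tuple(x), tuple(n.astype(int)), tuple(k_star),
                    chance=self.model.chance, lapse=self.model.lapse,
                ).fit(start=(self.mu, self.sigma))
                out[kept] = res.threshold_at(criterion)
                kept += 1
            except (DegenerateFitError, ValueError):
                continue
        if kept < n_boot // 2:
            raise DegenerateFitError("bootstrap resamples mostly degenerate")
        lo, hi = np.percentile(out[:kept], [50 * (1 - ci), 50 * (1 + ci)])
        return float(lo), float(hi)

    def summary(self) -> str:
        m = self.model
        x, n, _ = m._arrays()
        lines = [
            "Cumulative-Gaussian psychometric fit",
            "=" * 40,
            f"levels: {x.size}   trials: {int(n.sum())}   chance: {m.chance:.3f}",
            f"mu      {self.mu: .5g}",
            f"sigma   {self.sigma: .5g}",
            f"lapse   {self.lapse_rate: .4g}"
            + ("  (free)" if m.lapse == "free" else "  (fixed)"),
            f"log-likelihood {self.loglike: .4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "gamma": self.model.chance,
            "lambda": self.lapse_rate,
            "loglike": self.loglike,
            "n_trials": int(np.asarray(self.model.n_trials).sum()),
        }

    def plot(self, ax=None, criterion: float | None = None):
        """Proportion correct vs level with the fitted curve (dot area ~ n)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, n, k = self.model._arrays()
        ax.scatter(x, k / n, s=10 * n, alpha=0.6, label="data")
        grid = np.linspace(x.min(), x.max(), 200)
        ax.plot(grid, self.predict(grid), "r-", label="fit")
        if criterion is not None:
            t = self.threshold_at(criterion)
            ax.axhline(criterion, ls="--", c="gray")
            ax.axvline(t, ls="--", c="gray")
        ax.set_xlabel("stimulus level")
        ax.set_ylabel("proportion correct")
        ax.legend()
        return ax


def fit_psychometric(
    levels, n_trials, n_success, chance: float = 0.25, lapse: float | str = 0.02
) -> PsychometricResults:
    """Functional wrapper: build a :class:`PsychometricModel` and fit it."""
    return PsychometricModel(
        tuple(levels), tuple(n_trials), tuple(n_success), chance=chance, lapse=lapse
    ).fit()


# ---------------------------------------------------------------------------
# sinusoid model of threshold vs offset


@dataclass(frozen=True)
class SinusoidModel:
    """Least-squares sinusoid c(x) = a sin(2 pi (x - p) / period) + b.

    The period is fixed (6 arcmin: one cycle of a 10-cpd grating expressed
    as red-blue offset), so the model is linear in (a sin, a cos, b) and is
    solved in the sin/cos reparameterization, avoiding phase local minima.
    """

    offsets: tuple[float, ...]
    thresholds: tuple[float, ...]
    period: float = 6.0

    def __post_init__(self):
        x = np.asarray(self.offsets, float)
        if np.unique(x).size < 3:
            raise ValueError("sinusoid fit needs >= 3 distinct offsets")
        if len(self.offsets) != len(self.thresholds):
            raise ValueError("offsets and thresholds must be equal length")

    def fit(self) -> "SinusoidResults":
        x = np.asarray(self.offsets, float)
        y = np.asarray(self.thresholds, float)
        w = 2 * np.pi / self.period
        design = np.column_stack([np.sin(w * x), np.cos(w * x), np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        s, c, b = coef
        a = float(np.hypot(s, c))
        # a sin(wx - w p) = a cos(wp) sin(wx) - a sin(wp) cos(wx)
        p = 0.0 if a < 1e-12 else float(np.arctan2(-c, s) / w)
        # canonical form: a >= 0 and p in (-period/2, period/2]
        p = p - self.period * np.floor(p / self.period + 0.5)
        if p <= -self.period / 2:
            p += self.period
        resid = y - (a * np.sin(w * (x - p)) + b)
        return SinusoidResults(
            model=self, amplitude=a, offset=float(b), phase=p,
            rss=float(np.sum(resid**2)),
        )


@dataclass(frozen=True)
class SinusoidResults:
    """Canonicalized sinusoid fit: amplitude >= 0, phase in (-period/2, period/2]."""

    model: SinusoidModel
    amplitude: float
    offset: float
    phase: float
    rss: float

    def predict(self, x) -> np.ndarray:
        w = 2 * np.pi / self.model.period
        return self.amplitude * np.sin(w * (np.asarray(x, float) - self.phase)) + self.offset

    @property
    def argmin(self) -> float:
        """Offset at minimum threshold: phase - period/4 (wrapped)."""
        return self._wrap(self.phase - self.model.period / 4.0)

    @property
    def argmax(self) -> float:
        """Offset at maximum threshold: half a period from the minimum."""
        return self._wrap(self.phase + self.model.period / 4.0)

    def _wrap(self, x: float) -> float:
        T = self.model.period
        x = x - T * np.floor(x / T + 0.5)
        return float(x if x > -T / 2 else x + T)

    def summary(self) -> str:
        return (
            "Sinusoid threshold fit (fixed period "
            f"{self.model.period:g} arcmin)\n"
            f"amplitude a {self.amplitude:.5g}\n"
            f"offset    b {self.offset:.5g}\n"
            f"phase     p {self.phase:.5g} arcmin\n"
            f"RSS         {self.rss:.5g}"
        )


def fit_threshold_sinusoid(offsets, thresholds, period: float = 6.0) -> SinusoidResults:
    """Fit the threshold-vs-offset sinusoid (functional wrapper)."""
    return SinusoidModel(tuple(offsets), tuple(thresholds), period=period).fit()


# ---------------------------------------------------------------------------
# PSE from constant stimuli


@dataclass(frozen=True)
class PSEResults:
    """Point of subjective equality from a constant-stimulus 2AFC run.

    ``slope`` carries the sign of the response convention (positive when
    "blue nearer" grows with disparity); ``extrapolated`` flags data that
    never straddle 50%.
    """

    pse: float
    slope: float
    lapse_rate: float
    loglike: float
    extrapolated: bool
    ci90: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "pse": self.pse,
            "slope": self.slope,
            "lambda": self.lapse_rate,
            "extrapolated": self.extrapolated,
            "ci90": list(self.ci90) if self.ci90 else None,
        }


def pse_from_constant_stimuli(
    levels,
    n_trials,
    n_chosen,
    lapse: float = 0.02,
    n_boot: int = 0,
    rng_seed: int | None = None,
) -> PSEResults:
    """Fit psi(x) = lambda + (1 - 2 lambda) Phi(beta (x - mu)); PSE = mu.

    ``n_chosen`` counts "blue nearer" choices at each disparity.  The slope
    beta is free in sign, so swapping response labels flips the slope but
    leaves the PSE unchanged.  If the observed proportions never cross 0.5
    the fit is returned with ``extrapolated=True``.  Optional nonparametric
    bootstrap (``n_boot`` >= 200) gives a 90% CI on the PSE.
    """
    x = np.asarray(levels, float)
    n = np.asarray(n_trials, float)
    k = np.asarray(n_chosen, float)
    if np.unique(x[n > 0]).size < 2:
        raise ValueError("need >= 2 distinct levels")
    prop = k[n > 0] / n[n > 0]
    extrapolated = not (prop.min() < 0.5 < prop.max())

    def predict(xv, mu, beta):
        p = lapse + (1 - 2 * lapse) * _NORM.cdf(beta * (xv - mu))
        return np.clip(p, 1e-9, 1 - 1e-9)

    def nll(theta):
        p = predict(x, theta[0], theta[1])
        return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

    span = float(x.max() - x.min())
    sign0 = 1.0 if np.polyfit(x[n > 0], prop, 1)[0] >= 0 else -1.0
    best = None
    for beta0 in (sign0 * 4 / span, sign0 * 1 / span, -sign0 * 2 / span):
        res = optimize.minimize(
            nll, [float(np.median(x)), beta0], method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, beta = float(best.x[0]), float(best.x[1])

    ci = None
    if n_boot:
        if n_boot < 200:
            raise ValueError("n_boot must be >= 200")
        rng = np.random.default_rng(rng_seed)
        p_obs = np.clip(k / np.maximum(n, 1), 0, 1)
        boots = []
        for _ in range(n_boot):
            k_star = rng.binomial(n.astype(int), p_obs)
            r = pse_from_constant_stimuli(x, n, k_star, lapse=lapse)
            boots.append(r.pse)
        lo, hi = np.percentile(boots, [5, 95])
        ci = (float(lo), float(hi))
    return PSEResults(
        pse=mu, slope=beta, lapse_rate=lapse, loglike=-float(best.fun),
        extrapolated=extrapolated, ci90=ci,
    )


# ---------------------------------------------------------------------------
# repeated-measures correlation & paired t


@dataclass(frozen=True)
class RmCorrResult:
    """Within-subject (common-slope) correlation with its dof and p value."""

    r: float
    dof: int
    p: float

    def summary(self) -> str:
        return f"repeated-measures correlation r = {self.r:.4f}, dof = {self.dof}, p = {self.p:.4g}"


def rm_corr(subjects: Sequence, x, y) -> RmCorrResult:
    """Repeated-measures correlation (common slope after removing subject means).

    Each subject's x and y are centered on that subject's means; the
    correlation of the centered values estimates the shared within-subject
    association, with dof = N - k - 1 for N pairs and k subjects (one mean
    per subject plus the common slope).  The p value comes from the t
    distribution of the common slope.

    Raises
    ------
    ValueError
        With < 2 subjects, no subject contributing >= 2 pairs, or
        zero within-subject variance in x (e.g. all predictions equal).
    """
    s = np.asarray(subjects)
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    if not (s.size == xv.size == yv.size):
        raise ValueError("subjects, x, y must be equal length")
    uniq = pd.unique(s)
    if uniq.size < 2:
        raise ValueError("repeated-measures correlation needs >= 2 subjects")
    counts = pd.Series(s).value_counts()
    if not (counts >= 2).any():
        raise ValueError("at least one subject must contribute >= 2 pairs")
    df = pd.DataFrame({"s": s, "x": xv, "y": yv})
    xc = df.x - df.groupby("s").x.transform("mean")
    yc = df.y - df.groupby("s").y.transform("mean")
    ssx = float(np.sum(xc**2))
    ssy = float(np.sum(yc**2))
    if ssx <= 0:
        raise ValueError("no within-subject variance in x; r_rm undefined")
    if ssy <= 0:
        raise ValueError("no within-subject variance in y; r_rm undefined")
    r = float(np.sum(xc * yc) / np.sqrt(ssx * ssy))
    dof = int(len(df) - uniq.size - 1)
    if dof <= 0:
        raise ValueError("not enough repeated measurements for a p value")
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r**2))
        p = float(2 * stats.t.sf(abs(t), dof))
    return RmCorrResult(r=r, dof=dof, p=p)


def paired_t_test(x, y) -> tuple[float, float]:
    """Classical two-tailed paired t test on x - y; returns (t, p).

    Raises
    ------
    ValueError
        For unequal lengths, n < 2, or zero-variance differences.
    """
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    if xv.size != yv.size or xv.size < 2:
        raise ValueError("paired t test needs equal-length samples, n >= 2")
    d = xv - yv
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        raise ValueError("zero variance of nonzero differences: t undefined")
    res = stats.ttest_rel(xv, yv)
    return float(res.statistic), float(res.pvalue)
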