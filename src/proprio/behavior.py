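"""Behavioral statistics for the 2AFC forelimb-discrimination task.

The task displaces the mouse forelimb either medially or laterally and the
animal reports the direction by a directional lick. Three pieces of the
analysis live here:

* the adaptive bias controller that picks each trial's stimulus side: the
  bias is the difference in the fraction of correct responses between
  medial and lateral trials over the last 10 non-aborted trials, and the
  probability of a medial trial follows a double-sigmoid of that bias with
  inflection points τ1 = −0.5, τ2 = 0.5 and slopes S1 = 30, S2 = 12;
* psychometric fitting of the fraction of rightward answers against signed
  displacement (medial negative, lateral positive) with a cumulative
  Gaussian including guess and lapse rates, by maximum likelihood with
  profile-likelihood confidence intervals;
* session-level summaries: probe-trial (anterior/posterior) answer
  statistics and the Δ% correct drop for optogenetic inactivation sites
  relative to the control site, with Bonferroni correction across sites.

The printed double-sigmoid is implemented verbatim, including the negative
τ1 (well-defined because S1 is even); as printed it drives the stimulus
distribution hard toward medial except for strongly negative biases, which
corrects only one direction of bias — documented, not "fixed".
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import norm

__all__ = [
    "BiasState",
    "PsychometricParams",
    "PsychometricFit",
    "InactivationSummary",
    "update_bias",
    "p_medial",
    "psychometric_probability",
    "fit_psychometric",
    "probe_answer_analysis",
    "inactivation_delta",
]

TAU1, TAU2 = -0.5, 0.5
S1, S2 = 30, 12
WINDOW_LEN = 10


@dataclass
class BiasState:
    """Sliding 10-trial window of (side, correct) and the resulting bias.

    ``bias`` = fraction correct on medial trials − fraction correct on
    lateral trials within the window; a side absent from the window
    contributes a fraction of 0 (cold-start convention, configurable via
    ``carry_last`` which keeps the previous bias instead).
    """

    window: deque = field(default_factory=lambda: deque(maxlen=WINDOW_LEN))
    bias: float = 0.0
    carry_last: bool = False

    def fractions(self) -> tuple[float, float]:
        med = [c for s, c in self.window if s == "medial"]
        lat = [c for s, c in self.window if s == "lateral"]
        f_med = float(np.mean(med)) if med else 0.0
        f_lat = float(np.mean(lat)) if lat else 0.0
        return f_med, f_lat


def update_bias(state: BiasState, side: str, outcome: str) -> BiasState:
    """Update the controller with one finished trial.

    Aborted trials leave the state untouched. ``side`` is "medial" or
    "lateral"; ``outcome`` is "correct", "incorrect" or "abort".
    """
    if outcome == "abort":
        return state
    if side not in ("medial", "lateral"):
        raise ValueError(f"unknown side {side!r}")
    new_window = deque(state.window, maxlen=WINDOW_LEN)
    new_window.append((side, 1.0 if outcome == "correct" else 0.0))
    new = BiasState(window=new_window, carry_last=state.carry_last)
    f_med, f_lat = new.fractions()
    has_med = any(s == "medial" for s, _ in new_window)
    has_lat = any(s == "lateral" for s, _ in new_window)
    if state.carry_last and not (has_med and has_lat):
        new.bias = state.bias
    else:
        new.bias = f_med - f_lat
    return new


def p_medial(bias: float) -> float:
    """Probability of a medial trial as the printed double sigmoid of bias.

    P_med = 1 − 0.5/(1 + ((bias+1)/τ1)^S1) − 0.5/(1 + ((bias+1)/τ2)^S2)
    with τ1 = −0.5, τ2 = 0.5, S1 = 30, S2 = 12, clamped to [0, 1].
    P_med(−1) = 0 exactly.
    """
    if not -1.0 <= bias <= 1.0:
        raise ValueError("bias must be in [-1, 1]")
    b1 = (bias + 1.0) / TAU1
    b2 = (bias + 1.0) / TAU2
    val = 1.0 - 0.5 / (1.0 + b1**S1) - 0.5 / (1.0 + b2**S2)
    return float(min(max(val, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Psychometric fitting


@dataclass(frozen=True)
class PsychometricParams:
    """Cumulative-Gaussian psychometric parameters.

    ``pse`` (mm) is the point of subjective equality, ``slope_sigma`` (mm)
    the Gaussian SD (inverse slope), ``guess_rate`` the lower asymptote and
    ``lapse_rate`` one minus the upper asymptote.
    """

    pse: float = 0.0
    slope_sigma: float = 1.0
    guess_rate: float = 0.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.slope_sigma <= 0:
            raise ValueError("slope_sigma must be positive")
        if not (0 <= self.guess_rate < 0.5 and 0 <= self.lapse_rate < 0.5):
            raise ValueError("guess and lapse rates must be in [0, 0.5)")


@dataclass
class PsychometricFit:
    params: PsychometricParams
    ci95: dict  # {"pse": (lo, hi), ...} profile-likelihood intervals
    nll: float
    boundary: bool  # True when the fit sits on a parameter bound (separation)
    n_trials: int


def psychometric_probability(x, params: PsychometricParams):
    """P(right answer) at signed displacement x (medial < 0 < lateral)."""
    g, lam = params.guess_rate, params.lapse_rate
    return g + (1.0 - g - lam) * norm.cdf((np.asarray(x, dtype=float) - params.pse)
                                          / params.slope_sigma)

_BOUNDS = [(-20.0, 20.0), (1e-2, 50.0), (0.0, 0.4999), (0.0, 0.4999)]


def _nll(theta, x_levels, n_right, n_total):
    p = psychometric_probability(
        x_levels, PsychometricParams(theta[0], theta[1], theta[2], theta[3])
    )
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -np.sum(n_right * np.log(p) + (n_total - n_right) * np.log(1 - p))


def fit_psychometric(trials: pd.DataFrame, profile_ci: bool = True) -> PsychometricFit:
    """Maximum-likelihood psychometric fit with profile-likelihood 95% CIs.

    ``trials`` needs columns ``signed_displacement_mm`` and ``answer``
    ("left"/"right"); aborted/unanswered trials are ignored. Binomial
    likelihood aggregated per displacement level; CIs from the χ²(1)
    likelihood-ratio threshold (ΔNLL = 1.921). A fit pinned at a parameter
    bound (e.g. complete separation) is flagged ``boundary=True``.
    """
    df = trials[trials["answer"].isin(["left", "right"])]
    levels, inverse = np.unique(
        df["signed_displacement_mm"].to_numpy(dtype=float), return_inverse=True
    )
    if levels.size < 2:
        raise ValueError("need at least 2 signed displacement levels")
    right = df["answer"].to_numpy() == "right"
    n_total = np.bincount(inverse, minlength=levels.size).astype(float)
    n_right = np.bincount(inverse, weights=right, minlength=levels.size)

    x0s = [
        np.array([0.0, max(np.ptp(levels) / 4, 0.5), 0.02, 0.02]),
        np.array([float(np.median(levels)), 1.0, 0.1, 0.1]),
    ]
    best = None
    for x0 in x0s:
        res = optimize.minimize(
            _nll, x0, args=(levels, n_right, n_total), method="L-BFGS-B", bounds=_BOUNDS
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    params = PsychometricParams(*theta)
    on_bound = any(
        np.isclose(theta[i], b, atol=1e-6) for i, (lo, hi) in enumerate(_BOUNDS)
        for b in (lo, hi)
    )
    ci = {}
    if profile_ci:
        names = ("pse", "slope_sigma", "guess_rate", "lapse_rate")
        for i, name in enumerate(names):
            ci[name] = _profile_interval(i, theta, best.fun, levels, n_right, n_total)
    return PsychometricFit(
        params=params, ci95=ci, nll=float(best.fun), boundary=bool(on_bound),
        n_trials=int(n_total.sum()),
    )


def _profile_nll(i, value, theta_hat, levels, n_right, n_total):
    bounds = list(_BOUNDS)
    bounds[i] = (value, value)
    x0 = theta_hat.copy()
    x0[i] = value
    res = optimize.minimize(
        _nll, x0, args=(levels, n_right, n_total), method="L-BFGS-B", bounds=bounds
    )
    return res.fun


def _profile_interval(i, theta_hat, nll_min, levels, n_right, n_total,
                      delta: float = 1.9207):
    """Profile-likelihood interval by bisection on each side of the MLE."""
    lo_bound, hi_bound = _BOUNDS[i]
    target = nll_min + delta

    def crossing(a, b):
        """NLL(a) <= target < NLL(b): bisect for the crossing in (a, b)."""
        for _ in range(40):
            m = 0.5 * (a + b)
            if _profile_nll(i, m, theta_hat, levels, n_right, n_total) <= target:
                a = m
            else:
                b = m
            if abs(b - a) < 1e-4 * max(1.0, abs(theta_hat[i])):
                break
        return 0.5 * (a + b)

    if _profile_nll(i, lo_bound, theta_hat, levels, n_right, n_total) <= target:
        lo = lo_bound
    else:
        lo = crossing(theta_hat[i], lo_bound)
    if _profile_nll(i, hi_bound, theta_hat, levels, n_right, n_total) <= target:
        hi = hi_bound
    else:
        hi = crossing(theta_hat[i], hi_bound)
    return (float(min(lo, hi)), float(max(lo, hi)))


# ---------------------------------------------------------------------------
# Probe-trial and inactivation summaries


def probe_answer_analysis(trials: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """% right answers per stimulus class and session.

    Classes are the trained sides (medial, lateral) and the probe directions
    (anterior, posterior). Returns (per-session table, t, p) where the test
    is a two-sided paired t-test of anterior vs posterior % right across
    sessions. Classes with zero answered trials in a session are left NaN.
    """
    df = trials[trials["answer"].isin(["left", "right"])].copy()
    if "session" not in df.columns:
        df["session"] = 0
    df["right"] = (df["answer"] == "right").astype(float)
    table = (
        df.pivot_table(index="session", columns="stimulus_class", values="right",
                       aggfunc="mean")
        * 100.0
    )
    t, p = np.nan, np.nan
    if {"anterior", "posterior"} <= set(table.columns):
        paired = table[["anterior", "posterior"]].dropna()
        if len(paired) >= 2:
            t, p = stats.ttest_rel(paired["anterior"], paired["posterior"])
    return table, float(t), float(p)


@dataclass(frozen=True)
class InactivationSummary:
    site: str
    delta_pct_correct: float  # mean over sessions, percentage points
    per_session: tuple
    t_stat: float
    p_raw: float
    p_bonferroni: float
    n_sessions: int


def inactivation_delta(
    trials: pd.DataFrame, control_site: str = "control"
) -> list[InactivationSummary]:
    """Δ% correct per inactivation site vs the control site.

    For each session, Δ = % correct on site trials − % correct on control
    trials (negative = performance drop); sessions lacking control trials
    are dropped. The per-site session means are tested against zero with a
    two-sided one-sample t-test, Bonferroni-corrected across sites.
    """
    df = trials[trials["outcome"].isin(["correct", "incorrect"])].copy()
    if "session" not in df.columns:
        df["session"] = 0
    df["correct"] = (df["outcome"] == "correct").astype(float)
    pct = df.pivot_table(index="session", columns="inactivation_site",
                         values="correct", aggfunc="mean") * 100.0
    if control_site not in pct.columns:
        raise ValueError(f"no {control_site!r} trials in any session")
    sites = [s for s in pct.columns if s != control_site]
    out = []
    for site in sites:
        paired = pct[[site, control_site]].dropna()
        deltas = (paired[site] - paired[control_site]).to_numpy()
        if deltas.size == 0:
            continue
        if deltas.size >= 2 and np.ptp(deltas) > 0:
            t, p = stats.ttest_1samp(deltas, 0.0)
        else:
            t, p = np.nan, np.nan
        out.append(
            InactivationSummary(
                site=site,
                delta_pct_correct=float(deltas.mean()),
                per_session=tuple(float(d) for d in deltas),
                t_stat=float(t),
                p_raw=float(p),
                p_bonferroni=float(min(p * len(sites), 1.0)) if np.isfinite(p) else np.nan,
                n_sessions=int(deltas.size),
            )
        )
    return out
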