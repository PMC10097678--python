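"""Directional-tuning statistics and peripersonal-space analyses.

A neuron's peak responses across the eight tested movement directions are
fit with a Gaussian tuning curve

    f(x) = b0 · exp(−((x − b1)/b2)²)

after circularly re-centering the direction axis on the empirical maximum
(so the wrap-around never splits the peak). A neuron is directionally
selective when the 95% confidence intervals of b0 (peak rate) and b2
(tuning width) both exclude zero; b1 is the preferred direction. Population
non-uniformity of preferred directions is assessed with the Rayleigh test.

The peripersonal-space statistics compare movements with matched direction
vectors but different start/end positions: the angular shift between
preferred spatial positions for home-to-target vs target-to-home movements
(180° for direction tuning, 0° for place-like position tuning) and the
Δ ratio (x̄ − ȳ)/max(x̄, ȳ) between mean peak responses of the two movement
types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DirectionalResponses",
    "GaussianTuningFit",
    "DeltaRatio",
    "KinematicSensitivity",
    "fit_direction_tuning",
    "is_directionally_selective",
    "responses_from_session",
    "rayleigh_test",
    "preferred_direction_distribution",
    "circular_mean_deg",
    "angular_shift_analysis",
    "delta_ratio",
    "kinematic_sensitivity",
]


def wrap_deg(angle, half: bool = False):
    """Wrap angles to [0, 360), or to (−180, 180] when ``half``."""
    a = np.asarray(angle, dtype=float) % 360.0
    if half:
        a = np.where(a > 180.0, a - 360.0, a)
    return a if a.ndim else float(a)


def circular_mean_deg(angles_deg) -> tuple[float, float]:
    """Circular mean (degrees in [0, 360)) and resultant length R̄."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    z = np.exp(1j * a).mean()
    return float(np.rad2deg(np.angle(z)) % 360.0), float(np.abs(z))


@dataclass
class DirectionalResponses:
    """Per-direction peak responses of one neuron for one movement phase."""

    directions_deg: np.ndarray
    per_trial: list  # list of per-trial peak arrays, one per direction
    phase: str = "home_to_target"
    neuron_id: int | str = 0

    def __post_init__(self) -> None:
        self.directions_deg = np.asarray(self.directions_deg, dtype=float)
        if len(self.per_trial) != self.directions_deg.size:
            raise ValueError("per_trial must have one entry per direction")
        if np.unique(self.directions_deg % 360.0).size != self.directions_deg.size:
            raise ValueError("directions must be distinct modulo 360")
        if any(len(p) == 0 for p in self.per_trial):
            raise ValueError("every direction needs at least one trial")

    @property
    def mean_peak(self) -> np.ndarray:
        return np.array([float(np.mean(p)) for p in self.per_trial])


@dataclass
class GaussianTuningFit:
    """Fitted (b0, b1, b2) with t-based 95% confidence intervals."""

    b0: float
    b1: float  # preferred direction, degrees in [0, 360)
    b2: float  # tuning width, degrees
    ci95: dict = field(default_factory=dict)  # {"b0": (lo, hi), ...}
    converged: bool = True
    diagnostics: str = ""


@dataclass(frozen=True)
class DeltaRatio:
    xbar: float
    ybar: float
    value: float
    t_stat: float = np.nan
    p_value: float = np.nan


@dataclass(frozen=True)
class KinematicSensitivity:
    slope: float
    intercept: float
    r: float
    p: float
    pct_per_doubling: float | None
    kind: str = "amplitude"


# ---------------------------------------------------------------------------
# Gaussian tuning


def _gauss(x, b0, b1, b2):
    return b0 * np.exp(-(((x - b1) / b2) ** 2))


def fit_direction_tuning(resp: DirectionalResponses) -> GaussianTuningFit:
    """Least-squares Gaussian tuning fit on the re-centered direction axis.

    Directions are mapped to the ±180° interval around the direction of
    maximal mean response before fitting, so the peak never straddles the
    wrap-around; b1 is mapped back to absolute degrees in [0, 360).
    Non-convergence is reported via ``converged=False``, never an exception.
    """
    dirs = resp.directions_deg
    if np.unique(dirs % 360.0).size < 5:
        raise ValueError("need at least 5 distinct directions")
    y = resp.mean_peak
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite mean responses")
    center = dirs[int(np.argmax(y))]
    x = center + wrap_deg(dirs - center, half=True)
    p0 = (max(float(y.max()), 1e-6), float(center), 60.0)
    try:
        popt, pcov = optimize.curve_fit(
            _gauss,
            x,
            y,
            p0=p0,
            bounds=([0.0, center - 180.0, 1e-3], [np.inf, center + 180.0, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        return GaussianTuningFit(
            b0=np.nan, b1=np.nan, b2=np.nan, converged=False, diagnostics=str(exc)
        )
    dof = max(x.size - 3, 1)
    # On flat data the optimizer drives b2 to arbitrarily large widths and
    # the b0/b2 Jacobian columns collapse onto each other; the linearized
    # covariance is then meaningless, so report the degeneracy instead.
    b0h, b1h, b2h = popt
    u = (x - b1h) / b2h
    J = np.column_stack(
        [np.exp(-(u**2)),
         b0h * np.exp(-(u**2)) * 2 * u / b2h,
         b0h * np.exp(-(u**2)) * 2 * u**2 / b2h]
    )
    degenerate = b2h > 1e4 or np.linalg.cond(J) > 1e8
    if degenerate:
        return GaussianTuningFit(
            b0=float(b0h),
            b1=wrap_deg(b1h),
            b2=float(b2h),
            converged=False,
            diagnostics="degenerate fit: tuning indistinguishable from flat",
        )
    if not np.all(np.isfinite(pcov)):
        return GaussianTuningFit(
            b0=float(popt[0]),
            b1=wrap_deg(popt[1]),
            b2=float(popt[2]),
            converged=False,
            diagnostics="singular covariance (flat or degenerate tuning)",
        )
    tcrit = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.diag(pcov))
    ci = {
        name: (float(popt[i] - tcrit * se[i]), float(popt[i] + tcrit * se[i]))
        for i, name in enumerate(("b0", "b1", "b2"))
    }
    return GaussianTuningFit(
        b0=float(popt[0]), b1=wrap_deg(popt[1]), b2=float(popt[2]), ci95=ci
    )


def is_directionally_selective(fit: GaussianTuningFit) -> bool:
    """True iff the 95% CIs of both b0 and b2 exclude zero."""
    if not fit.converged or not fit.ci95:
        return False
    b0_lo, b0_hi = fit.ci95["b0"]
    b2_lo, b2_hi = fit.ci95["b2"]
    return (b0_lo > 0.0 or b0_hi < 0.0) and (b2_lo > 0.0 or b2_hi < 0.0)


# ---------------------------------------------------------------------------
# Population statistics


def rayleigh_test(angles_deg) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    z = n·R̄² with the standard small-sample correction for the p-value
    (Zar, Biostatistical Analysis):
    p = exp(sqrt(1 + 4n + 4(n² − R²)) − (1 + 2n)), R = n·R̄.
    Returns (z, p).
    """
    a = np.asarray(angles_deg, dtype=float)
    n = a.size
    _, rbar = circular_mean_deg(a)
    R = n * rbar
    z = n * rbar**2
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - R**2)) - (1.0 + 2.0 * n))
    return float(z), float(min(p, 1.0))


def preferred_direction_distribution(
    fits, bins_deg=None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Circular histogram of preferred directions + Rayleigh test.

    Returns (bin_centers_deg, counts, rayleigh_z, rayleigh_p). Bins default
    to 45°-wide bins centered on the 8 cardinal/ordinal directions.
    """
    angles = np.array([f.b1 for f in fits if f.converged])
    if angles.size < 10:
        raise ValueError("need at least 10 preferred directions (unstable test below)")
    if bins_deg is None:
        bins_deg = np.arange(0.0, 360.0, 45.0)
    centers = np.asarray(bins_deg, dtype=float)
    width = 360.0 / centers.size
    shifted = wrap_deg(angles - centers[0] + width / 2)
    counts, _ = np.histogram(shifted, bins=np.arange(0.0, 360.0 + width / 2, width))
    z, p = rayleigh_test(angles)
    return centers, counts, z, p


def angular_shift_analysis(
    fits_forward, fits_return
) -> tuple[np.ndarray, float, float]:
    """Per-neuron shift in preferred spatial-position angle, forward vs return.

    The preferred spatial position of a home-to-target (forward) movement is
    at the preferred movement direction seen from the home position; for a
    target-to-home (return) movement with preferred direction b1, the
    movement starts from the target located at b1 + 180° from home. The
    shift is the circular difference of the two position angles in
    [0°, 360°): exactly 180° for pure direction tuning and 0° for pure
    position tuning. Returns (per-neuron shifts, circular mean, R̄).
    """
    if len(fits_forward) != len(fits_return):
        raise ValueError("forward and return fit lists must be matched per neuron")
    shifts = []
    for ff, fr in zip(fits_forward, fits_return):
        if not (ff.converged and fr.converged):
            continue
        pos_fwd = ff.b1
        pos_ret = fr.b1 + 180.0
        shifts.append(wrap_deg(pos_ret - pos_fwd))
    if not shifts:
        raise ValueError("no matched converged fit pairs")
    shifts = np.asarray(shifts)
    mean, rbar = circular_mean_deg(shifts)
    return shifts, mean, rbar


# ---------------------------------------------------------------------------
# Peripersonal and kinematic statistics


def responses_from_session(
    trace, trials, phase: str = "home_to_target", deconvolve: bool = False,
    neuron_id=0,
) -> DirectionalResponses:
    """Per-direction trial peak responses of one neuron from a session.

    ``trace`` is a :class:`~proprio.twophoton.FluorescenceTrace`; ``trials``
    a trial table with ``t_onset_s``, ``direction_deg`` and ``phase``
    columns. The per-trial peak is the stimulus-evoked response (post-window
    max minus pre-window mean) at each movement onset of the requested
    phase, computed on the Δf/f0 trace or, when ``deconvolve`` is set, on
    the AR(1)-deconvolved spike-rate density.
    """
    from .twophoton import deconvolve_ar1, evoked_response, spike_rate_density

    sub = trials[trials["phase"] == phase]
    if sub.empty:
        raise ValueError(f"no trials with phase {phase!r}")
    if deconvolve:
        est = deconvolve_ar1(trace)
        times, series = spike_rate_density(est)
        fs = 1000.0
        t0 = trace.t0_s + float(times[0])
    else:
        series, fs = trace.values, trace.frame_rate_hz
        t0 = trace.t0_s
    per_trial: dict[float, list[float]] = {}
    for _, row in sub.iterrows():
        val = evoked_response(series, fs, float(row["t_onset_s"]), t0_s=t0).value
        per_trial.setdefault(float(row["direction_deg"]), []).append(val)
    dirs = sorted(per_trial)
    return DirectionalResponses(
        directions_deg=np.array(dirs),
        per_trial=[np.array(per_trial[d]) for d in dirs],
        phase=phase,
        neuron_id=neuron_id,
    )


def delta_ratio(per_trial_x, per_trial_y) -> DeltaRatio:
    """Δ ratio = (x̄ − ȳ)/max(x̄, ȳ) with a two-sided Welch t-test.

    x̄ and ȳ are the mean peak responses to home-to-target and
    target-to-home movements (or any two matched movement conditions);
    the value lies in [−1, 1] for non-negative means and is antisymmetric
    under swapping the inputs.
    """
    x = np.asarray(per_trial_x, dtype=float)
    y = np.asarray(per_trial_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both trial lists must be non-empty")
    xbar, ybar = float(x.mean()), float(y.mean())
    denom = max(xbar, ybar)
    if denom <= 0:
        raise ValueError("undefined ratio: max of the means is not positive")
    value = (xbar - ybar) / denom
    if x.size > 1 and y.size > 1:
        t, p = stats.ttest_ind(x, y, equal_var=False)
    else:
        t, p = np.nan, np.nan
    return DeltaRatio(xbar=xbar, ybar=ybar, value=float(value),
                      t_stat=float(t), p_value=float(p))


def population_delta_ratio_test(values) -> tuple[float, float]:
    """Two-sided one-sample t-test of Δ-ratio values against zero."""
    t, p = stats.ttest_1samp(np.asarray(values, dtype=float), 0.0)
    return float(t), float(p)


def kinematic_sensitivity(per_trial_pairs, kind: str = "amplitude") -> KinematicSensitivity:
    """Linear sensitivity of peak responses to amplitude (mm) or velocity.

    Fits peak response = slope·v + intercept over trials, reports the
    Pearson correlation and the % change in the fitted response for a
    doubling of the kinematic variable from the midpoint of the tested
    range: 100·(f(2·v_ref) − f(v_ref))/f(v_ref).
    """
    pairs = np.asarray(per_trial_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("expected (value, kinematic) pairs")
    values, kin = pairs[:, 0], pairs[:, 1]
    levels, counts = np.unique(kin, return_counts=True)
    if levels.size < 3:
        raise ValueError("need at least 3 distinct kinematic levels")
    if counts.min() < 5:
        raise ValueError("need at least 5 repetitions per kinematic level")
    res = stats.linregress(kin, values)
    v_ref = 0.5 * (levels.min() + levels.max())
    f_ref = res.slope * v_ref + res.intercept
    if f_ref > 0:
        pct = 100.0 * (res.slope * 2 * v_ref + res.intercept - f_ref) / f_ref
    else:
        pct = None
    return KinematicSensitivity(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        pct_per_doubling=None if pct is None else float(pct),
        kind=kind,
    )
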