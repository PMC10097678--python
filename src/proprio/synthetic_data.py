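"""Synthetic inputs for every pipeline stage, with ground truth attached.

The generators emulate the recordings of a passive forelimb-displacement
study: direction-tuned neuronal calcium traces (phasic, tonic or mixed
responses), AR(1) null traces for calibrating the randomization test,
dual-channel wide-field stacks with a shared hemodynamic artifact, stereo
projections of a five-landmark forelimb over a planar workspace grid, and
2AFC behavioral sessions driven by the adaptive bias controller and a
latent psychometric observer.

Every generator is deterministic given (config, seed) and returns the
latent parameters downstream recovery tests need. Responses are
phenomenological (kernel amplitudes scaled by a Gaussian tuning curve);
there is no biophysical spiking model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BiasState, PsychometricParams, p_medial, psychometric_probability, update_bias
from .kinematics import JointSet3D, SimilarityTransform, UnreachableError
from .twophoton import EventTimes, FluorescenceTrace
from .widefield import DualChannelStack

__all__ = [
    "SessionConfig",
    "GroundTruthNeuron",
    "LimbGeometry",
    "default_stereo_cameras",
    "gen_tuned_population",
    "gen_null_traces",
    "gen_widefield_stack",
    "gen_stereo_scene",
    "gen_behavior_session",
]

RESPONSE_TYPES = ("phasic", "tonic", "phasic_tonic")
DEFAULT_DIRECTIONS = tuple(float(d) for d in range(0, 360, 45))


def _wrap_half(a):
    a = np.asarray(a, dtype=float) % 360.0
    return np.where(a > 180.0, a - 360.0, a)


@dataclass(frozen=True)
class SessionConfig:
    """Conditions of one simulated imaging session.

    Defaults mirror the study's task: 8 cardinal/ordinal directions, 5–8 mm
    movement amplitude (7 mm default), 2–3 cm/s velocity, ~30 Hz imaging.
    ``noise_sd`` is additive Δf/f0 trace noise (a free parameter of the
    generator, not a measured quantity).
    """

    n_neurons: int = 50
    n_trials_per_direction: int = 20
    directions: tuple = DEFAULT_DIRECTIONS
    amplitude_mm: float = 7.0
    velocity_cms: float = 2.0
    frame_rate_hz: float = 30.0
    noise_sd: float = 0.05
    seed: int = 0
    hold_range_s: tuple = (1.0, 2.0)
    iti_s: float = 3.0
    include_return: bool = True

    def __post_init__(self) -> None:
        if self.n_neurons <= 0 or self.n_trials_per_direction <= 0:
            raise ValueError("n_neurons and n_trials_per_direction must be positive")
        dirs = np.asarray(self.directions, dtype=float)
        if np.any(dirs < 0) or np.any(dirs >= 360):
            raise ValueError("directions must lie in [0, 360)")
        if np.unique(dirs).size != dirs.size:
            raise ValueError("directions must be distinct")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroundTruthNeuron:
    """Latent tuning parameters of one simulated neuron."""

    preferred_direction: float  # degrees, b1
    tuning_width: float  # degrees, b2
    peak_rate: float  # a.u., b0
    response_type: str = "phasic"
    petal_gain: float = 1.0  # gain when the movement ends nearer the body

    def __post_init__(self) -> None:
        if self.tuning_width <= 0:
            raise ValueError("tuning_width must be positive")
        if self.peak_rate < 0:
            raise ValueError("peak_rate must be non-negative")
        if self.response_type not in RESPONSE_TYPES:
            raise ValueError(f"response_type must be one of {RESPONSE_TYPES}")

    def tuning(self, direction_deg) -> np.ndarray:
        """Gaussian tuning b0·exp(−((θ−b1)/b2)²) on the circular difference."""
        d = _wrap_half(np.asarray(direction_deg, dtype=float) - self.preferred_direction)
        return self.peak_rate * np.exp(-((d / self.tuning_width) ** 2))


# ---------------------------------------------------------------------------
# Tuned populations


def _phasic_kernel(fs: float, rise_s: float = 0.05, decay_s: float = 0.8) -> np.ndarray:
    """Difference-of-exponentials transient, unit peak, ~GCaMP-like decay."""
    t = np.arange(0.0, decay_s * 25, 1.0 / fs)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()

def _tonic_kernel(fs: float, hold_s: float, decay_s: float = 0.8) -> np.ndarray:
    """Boxcar over the hold period convolved with the sensor decay, unit peak."""
    t = np.arange(0.0, hold_s + decay_s * 25, 1.0 / fs)
    box = (t <= hold_s).astype(float)
    decay = np.exp(-np.arange(0.0, decay_s * 25, 1.0 / fs) / decay_s)
    k = np.convolve(box, decay)[: t.size]
    return k / k.max()


def _sample_preferred_directions(rng, n, spec) -> np.ndarray:
    """Preferred directions from 'uniform' or a von Mises spec
    {'mean_deg': float, 'kappa': float}."""
    if spec == "uniform":
        return rng.uniform(0.0, 360.0, n)
    try:
        mu = float(spec["mean_deg"])
        kappa = float(spec["kappa"])
    except (TypeError, KeyError) as exc:
        raise ValueError(
            "direction_distribution must be 'uniform' or {'mean_deg', 'kappa'}"
        ) from exc
    return np.rad2deg(rng.vonmises(np.deg2rad(mu), kappa, n)) % 360.0


def gen_tuned_population(
    config: SessionConfig,
    direction_distribution="uniform",
    response_type_probs=(0.7, 0.15, 0.15),
    peak_rate_range=(1.0, 8.0),
    tuning_width_range=(30.0, 120.0),
    petal_gain: float = 1.0,
    body_origin_cm=(0.0, -3.0),
) -> tuple[list[GroundTruthNeuron], list[FluorescenceTrace], pd.DataFrame]:
    """Simulate a direction-tuned population and its session traces.

    Each neuron's trace is baseline (0) plus, for every movement onset, a
    response kernel (phasic transient, tonic plateau during the hold, or
    their sum) scaled by the neuron's Gaussian tuning evaluated at the
    movement's direction, plus additive Gaussian noise. Movements whose end
    position lies nearer ``body_origin_cm`` than their start are scaled by
    ``petal_gain`` (body-petal gain). The trial table carries one row per
    movement (phase ``home_to_target`` or ``target_to_home``) with onsets
    both in seconds and as 0-based trace sample indices.
    """
    rng = np.random.default_rng(config.seed)
    dirs = np.asarray(config.directions, dtype=float)
    n_dir = dirs.size

    neurons = [
        GroundTruthNeuron(
            preferred_direction=float(pd_),
            tuning_width=float(rng.uniform(*tuning_width_range)),
            peak_rate=float(rng.uniform(*peak_rate_range)),
            response_type=RESPONSE_TYPES[
                rng.choice(len(RESPONSE_TYPES), p=response_type_probs)
            ],
            petal_gain=petal_gain,
        )
        for pd_ in _sample_preferred_directions(
            rng, config.n_neurons, direction_distribution
        )
    ]

    # Trial schedule: directions shuffled within blocks; trapezoid-duration
    # movements with random holds, return movement optional.
    amp_cm = config.amplitude_mm / 10.0
    move_dur = amp_cm / config.velocity_cms
    sched = np.tile(dirs, config.n_trials_per_direction)
    rng.shuffle(sched)
    rows = []
    t = 2.0
    home = np.array([0.0, 0.0])
    body = np.asarray(body_origin_cm, dtype=float)
    for trial_id, d in enumerate(sched):
        theta = np.deg2rad(d)
        target = home + amp_cm * np.array([np.cos(theta), np.sin(theta)])
        hold1 = rng.uniform(*config.hold_range_s)
        hold2 = rng.uniform(*config.hold_range_s)
        rows.append((trial_id, t, d, "home_to_target", home, target, hold1))
        t_ret = t + move_dur + hold1
        if config.include_return:
            rows.append(
                (trial_id, t_ret, (d + 180.0) % 360.0, "target_to_home", target, home, hold2)
            )
        t = t_ret + move_dur + hold2 + config.iti_s

    n_samples = int(np.ceil((t + 5.0) * config.frame_rate_hz))
    fs = config.frame_rate_hz
    table = pd.DataFrame(
        {
            "trial_id": [r[0] for r in rows],
            "t_onset_s": [r[1] for r in rows],
            "onset_sample": [int(round(r[1] * fs)) for r in rows],
            "direction_deg": [r[2] for r in rows],
            "amplitude_mm": config.amplitude_mm,
            "velocity_cms": config.velocity_cms,
            "start_x_cm": [r[4][0] for r in rows],
            "start_y_cm": [r[4][1] for r in rows],
            "end_x_cm": [r[5][0] for r in rows],
            "end_y_cm": [r[5][1] for r in rows],
            "hold_s": [r[6] for r in rows],
            "phase": [r[3] for r in rows],
            "outcome": "correct",
            "answer": "none",
            "probe": 0,
            "inactivation_site": "none",
        }
    )
    # snap stored seconds to the sample grid so both encodings agree exactly
    table["t_onset_s"] = table["onset_sample"] / fs

    kern_phasic = _phasic_kernel(fs)
    petal = np.array(
        [
            np.linalg.norm(r[5] - body) < np.linalg.norm(r[4] - body)
            for r in rows
        ]
    )
    traces = []
    for i, nrn in enumerate(neurons):
        values = np.zeros(n_samples)
        for row_i, r in enumerate(rows):
            amp = float(nrn.tuning(r[2]))
            if petal[row_i]:
                amp *= nrn.petal_gain
            if amp == 0.0:
                continue
            onset = int(round(r[1] * fs))
            if nrn.response_type in ("phasic", "phasic_tonic"):
                k = kern_phasic
                end = min(onset + k.size, n_samples)
                values[onset:end] += amp * k[: end - onset]
            if nrn.response_type in ("tonic", "phasic_tonic"):
                k = _tonic_kernel(fs, move_dur + r[6])
                scale = 0.5 if nrn.response_type == "phasic_tonic" else 1.0
                end = min(onset + k.size, n_samples)
                values[onset:end] += scale * amp * k[: end - onset]
        if config.noise_sd > 0:
            values = values + rng.normal(0.0, config.noise_sd, n_samples)
        traces.append(FluorescenceTrace(values=values, frame_rate_hz=fs, neuron_id=i))
    return neurons, traces, table


def gen_directional_peak_responses(
    neurons,
    directions=DEFAULT_DIRECTIONS,
    n_trials: int = 10,
    noise_frac: float = 0.2,
    seed: int = 0,
    phases=("home_to_target", "target_to_home"),
):
    """Per-trial peak responses for both movement phases, at the peak level.

    A movement of nominal direction θ is executed as θ for the
    home-to-target phase and θ+180° for the target-to-home phase; each
    trial's peak response is the neuron's Gaussian tuning at the executed
    movement direction plus Gaussian noise with SD ``noise_frac`` · peak
    rate. Returns {phase: [DirectionalResponses per neuron]} — the direct
    peak-level counterpart of the trace-level generator, for tuning-fit and
    angular-shift studies where trace extraction is not under test.
    """
    from .tuning import DirectionalResponses

    rng = np.random.default_rng(seed)
    dirs = np.asarray(directions, dtype=float)
    out = {ph: [] for ph in phases}
    for i, nrn in enumerate(neurons):
        for ph in phases:
            exec_dirs = dirs if ph == "home_to_target" else (dirs + 180.0) % 360.0
            per_trial = [
                nrn.tuning(d) + rng.normal(0.0, noise_frac * nrn.peak_rate, n_trials)
                for d in exec_dirs
            ]
            out[ph].append(
                DirectionalResponses(
                    directions_deg=exec_dirs, per_trial=per_trial, phase=ph, neuron_id=i
                )
            )
    return out


# ---------------------------------------------------------------------------
# Null traces


def gen_null_traces(
    n: int,
    duration_s: float,
    frame_rate_hz: float = 30.0,
    ar_coeff: float = 0.959,
    noise_sd: float = 0.1,
    n_events: int = 40,
    seed: int = 0,
    min_spacing_s: float = 2.25,
) -> tuple[list[FluorescenceTrace], EventTimes]:
    """AR(1) traces with no stimulus-locked component + valid event times.

    The default AR coefficient exp(−dt/0.8 s) at 30 Hz gives the traces a
    calcium-sensor-like autocorrelation. Event onsets are uniform given a
    minimum spacing of ``min_spacing_s`` (the pre+post analysis window) and
    full-window margins at both ends, so every event admits a [−0.75, 1.5] s
    window. ``noise_sd`` is the innovation SD; 0 yields constant-zero traces.
    """
    if not 0.0 <= ar_coeff < 1.0:
        raise ValueError("ar_coeff must be in [0, 1)")
    if n_events * 2.0 >= duration_s:
        raise ValueError("events too dense for the session duration")
    margin = min_spacing_s
    free = duration_s - 2 * margin - (n_events - 1) * min_spacing_s
    if free <= 0:
        raise ValueError("analysis windows overlap the trace ends")
    rng = np.random.default_rng(seed)
    u = np.sort(rng.uniform(0.0, free, n_events))
    onsets = margin + u + np.arange(n_events) * min_spacing_s
    events = EventTimes(onsets_s=onsets)

    from scipy.signal import lfilter

    n_samples = int(round(duration_s * frame_rate_hz))
    burn = 200
    traces = []
    for i in range(n):
        eps = rng.normal(0.0, noise_sd, n_samples + burn)
        x = lfilter([1.0], [1.0, -ar_coeff], eps)[burn:]
        traces.append(FluorescenceTrace(values=x, frame_rate_hz=frame_rate_hz, neuron_id=i))
    return traces, events


# ---------------------------------------------------------------------------
# Wide-field stacks


def gen_widefield_stack(
    height: int = 64,
    width: int = 64,
    n_frames: int = 480,
    artifact_amp: float = 0.05,
    signal_amp: float = 0.05,
    seed: int = 0,
    acquisition_rate_hz: float = 40.0,
    stim_onset_s: float = 6.0,
    baseline_blue: float = 100.0,
    baseline_violet: float = 60.0,
    hemo_gain: float = 0.8,
    noise_sd: float = 0.2,
    roi_sigma_px: float = 6.0,
) -> tuple[DualChannelStack, dict]:
    """Interleaved blue/violet stack with a shared hemodynamic artifact.

    Blue frames carry baseline·(1 + signal·map·s(t) + γ·h(t)), violet frames
    baseline·(1 + h(t)), each plus additive shot-like noise; h(t) is a slow
    vasomotion-like sum of sinusoids sampled at each frame's own timestamp,
    s(t) an alpha-function time course peaking 250 ms after stimulus onset,
    and the signal map a Gaussian disk whose center is ground truth.

    Returns the stack and a ground-truth dict with keys ``signal_map``,
    ``center_rc``, ``hemo_gain``, ``stim_onset_s``, ``hemo``.
    """
    if height <= 0 or width <= 0:
        raise ValueError("stack dimensions must be positive")
    if n_frames % 2:
        raise ValueError("n_frames must be even (alternating channels)")
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) / acquisition_rate_hz
    labels = np.where(np.arange(n_frames) % 2 == 0, "blue", "violet")

    center = (height * 0.5 + rng.uniform(-height / 6, height / 6),
              width * 0.5 + rng.uniform(-width / 6, width / 6))
    rr, cc = np.mgrid[0:height, 0:width]
    r2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    signal_map = np.exp(-r2 / (2 * roi_sigma_px**2))
    signal_map[r2 > (4 * roi_sigma_px) ** 2] = 0.0

    freqs = rng.uniform(0.08, 0.4, 4)
    phases = rng.uniform(0, 2 * np.pi, 4)
    amps = rng.uniform(0.5, 1.0, 4)
    amps /= np.sqrt((amps**2).sum() / 2)

    def hemo(t):
        return artifact_amp * sum(
            a * np.sin(2 * np.pi * f * t + ph) for a, f, ph in zip(amps, freqs, phases)
        )

    def stim(t):
        x = np.clip((np.asarray(t, dtype=float) - stim_onset_s) / 0.25, 0.0, None)
        return x * np.exp(1.0 - x)

    frames = np.empty((n_frames, height, width))
    for i, (t, lab) in enumerate(zip(times, labels)):
        h = hemo(t)
        if lab == "blue":
            img = baseline_blue * (
                1.0 + signal_amp * signal_map * stim(t) + hemo_gain * h
            )
        else:
            img = baseline_violet * (1.0 + h)
        frames[i] = img + rng.normal(0.0, noise_sd, (height, width))
    stack = DualChannelStack(
        frames=frames,
        frame_times_s=times,
        channel_labels=labels,
        acquisition_rate_hz=acquisition_rate_hz,
    )
    truth = {
        "signal_map": signal_map,
        "center_rc": center,
        "hemo_gain": hemo_gain,
        "stim_onset_s": stim_onset_s,
        "hemo": hemo,
        "signal_amp": signal_amp,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# Stereo scenes


@dataclass(frozen=True)
class LimbGeometry:
    """Forelimb segment lengths (cm) and fixed proximal landmarks in the
    manipulandum frame (X lateral-right, Y anterior, Z up)."""

    humerus_cm: float = 1.6
    forearm_cm: float = 1.9
    hand_cm: float = 0.8
    glenohumeral: tuple = (-0.6, -1.6, 1.8)
    scapulothoracic: tuple = (-1.0, -2.2, 2.4)


def default_stereo_cameras() -> tuple[np.ndarray, np.ndarray]:
    """Two pinhole cameras ~25° apart, world frame = camera-1 frame (mm)."""
    K = np.array([[800.0, 0.0, 640.0], [0.0, 800.0, 480.0], [0.0, 0.0, 1.0]])
    P1 = K @ np.hstack([np.eye(3), np.zeros((3, 1))])
    th = np.deg2rad(25.0)
    R = np.array(
        [[np.cos(th), 0.0, np.sin(th)], [0.0, 1.0, 0.0], [-np.sin(th), 0.0, np.cos(th)]]
    )
    C2 = np.array([-130.0, 0.0, 20.0])
    t = -R @ C2
    P2 = K @ np.hstack([R, t[:, None]])
    return P1, P2


def default_manip_to_world() -> SimilarityTransform:
    """Similarity transform from the manipulandum frame (cm) to camera-world
    (mm): swap Y/Z with a Z flip, scale 10, scene pushed to ~300 mm depth."""
    R = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])
    # det = +1: maps manip (x, y, z) -> world (x, -z, y)
    return SimilarityTransform(rotation=R, scale=10.0, translation=np.array([0.0, 30.0, 300.0]))


def limb_pose(grid_point, geom: LimbGeometry) -> JointSet3D:
    """Deterministic limb configuration over the planar workspace.

    The endpoint sits at the grid point in the manipulandum plane (z = 0),
    the wrist directly above it by the hand length; the elbow is the
    posterior-most point on the intersection circle of the humerus and
    forearm spheres. Raises :class:`UnreachableError` when the segment
    lengths cannot span shoulder to wrist.
    """
    x, y = (float(v) for v in grid_point)
    endpoint = np.array([x, y, 0.0])
    wrist = endpoint + np.array([0.0, 0.0, geom.hand_cm])
    G = np.asarray(geom.glenohumeral, dtype=float)
    d = np.linalg.norm(wrist - G)
    r1, r2 = geom.humerus_cm, geom.forearm_cm
    if d > r1 + r2 or d < abs(r1 - r2):
        raise UnreachableError(
            f"grid point {grid_point} unreachable: shoulder-wrist distance "
            f"{d:.3f} cm outside [{abs(r1 - r2):.3f}, {r1 + r2:.3f}]"
        )
    a = (r1**2 - r2**2 + d**2) / (2 * d)
    rho = np.sqrt(max(r1**2 - a**2, 0.0))
    axis = (wrist - G) / d
    center = G + a * axis
    # basis of the intersection circle; pick the elbow pointing most posterior
    ref = np.array([0.0, -1.0, 0.0])
    u = ref - axis * np.dot(ref, axis)
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        u = np.array([1.0, 0.0, 0.0]) - axis * axis[0]
        nu = np.linalg.norm(u)
    u /= nu
    elbow = center + rho * u
    return JointSet3D(
        scapulothoracic=np.asarray(geom.scapulothoracic, dtype=float),
        glenohumeral=G,
        elbow=elbow,
        wrist=wrist,
        endpoint=endpoint,
    )


def gen_stereo_scene(
    workspace_grid,
    limb_geometry: LimbGeometry | None = None,
    cameras: tuple[np.ndarray, np.ndarray] | None = None,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
    transform: SimilarityTransform | None = None,
) -> tuple[list[dict], list[JointSet3D], SimilarityTransform]:
    """Stereo pixel pairs of the five limb landmarks over a workspace grid.

    For every planar grid point the limb pose is built in the manipulandum
    frame, mapped to camera-world coordinates by a stored similarity
    transform, and projected through both cameras with optional Gaussian
    pixel noise. Returns (per-point landmark→((u1,v1),(u2,v2)) dicts, the
    ground-truth camera-world joint sets, and the transform).
    """
    geom = limb_geometry or LimbGeometry()
    P1, P2 = cameras or default_stereo_cameras()
    P1, P2 = np.asarray(P1, dtype=float), np.asarray(P2, dtype=float)

    def center_of(P):
        _, _, vt = np.linalg.svd(P)
        c = vt[-1]
        return c[:3] / c[3]

    if np.allclose(center_of(P1), center_of(P2), atol=1e-9):
        raise ValueError("degenerate cameras: identical optical centers")
    T = transform or default_manip_to_world()
    rng = np.random.default_rng(seed)
    from .kinematics import JOINT_NAMES

    pixel_sets, truths = [], []
    for gp in workspace_grid:
        pose = limb_pose(gp, geom)
        world = JointSet3D.from_array(T.apply(pose.as_array()))
        pixels = {}
        for name, X in zip(JOINT_NAMES, world.as_array()):
            Xh = np.append(X, 1.0)
            pix = []
            for P in (P1, P2):
                proj = P @ Xh
                uv = proj[:2] / proj[2]
                if pixel_noise_sd > 0:
                    uv = uv + rng.normal(0.0, pixel_noise_sd, 2)
                pix.append(tuple(uv))
            pixels[name] = tuple(pix)
        pixel_sets.append(pixels)
        truths.append(world)
    return pixel_sets, truths, T


# ---------------------------------------------------------------------------
# Behavioral sessions


def gen_behavior_session(
    n_trials: int,
    psychometric: PsychometricParams | None = None,
    probe_fraction: float = 0.15,
    controller_on: bool = True,
    seed: int = 0,
    displacement_levels_mm=(1.0, 2.0, 3.0, 4.0),
    abort_rate: float = 0.05,
    probe_p_right=None,
    forced_answer: str | None = None,
    session: int = 0,
    inactivation_site: str = "none",
) -> pd.DataFrame:
    """One 2AFC session from a latent psychometric observer.

    The stimulus side is medial with probability P_med(bias) from the
    adaptive controller when ``controller_on`` (0.5 otherwise); probe trials
    (anterior/posterior, 15% by default) are answered through the stored
    association probabilities ``probe_p_right`` (defaults: anterior 0.65,
    posterior 0.35, emulating anterior ≈ lateral generalization). Aborts are
    injected at ``abort_rate`` and excluded from the bias window. The logged
    table includes the pre-trial bias and P_med for controller replay.
    """
    if not 0.0 <= probe_fraction < 1.0:
        raise ValueError("probe_fraction must be in [0, 1)")
    psych = psychometric or PsychometricParams(pse=0.0, slope_sigma=1.5)
    probe_p = {"anterior": 0.65, "posterior": 0.35}
    if probe_p_right:
        probe_p.update(probe_p_right)
    rng = np.random.default_rng(seed)
    state = BiasState()
    rows = []
    for trial_id in range(n_trials):
        bias = state.bias
        p_med = p_medial(bias) if controller_on else 0.5
        is_probe = rng.random() < probe_fraction
        aborted = rng.random() < abort_rate
        if is_probe:
            cls = "anterior" if rng.random() < 0.5 else "posterior"
            x = 0.0
            p_right = probe_p[cls]
        else:
            cls = "medial" if rng.random() < p_med else "lateral"
            amp = float(rng.choice(displacement_levels_mm))
            x = -amp if cls == "medial" else amp
            p_right = float(psychometric_probability(x, psych))
        if aborted:
            answer, outcome = "none", "abort"
        else:
            if forced_answer is not None:
                answer = forced_answer
            else:
                answer = "right" if rng.random() < p_right else "left"
            if is_probe:
                outcome = "correct"  # probes are rewarded irrespective of answer
            else:
                outcome = (
                    "correct"
                    if (cls == "lateral") == (answer == "right")
                    else "incorrect"
                )
            if not is_probe:
                state = update_bias(state, cls, outcome)
        rows.append(
            dict(
                trial_id=trial_id,
                session=session,
                stimulus_class=cls,
                signed_displacement_mm=x,
                answer=answer,
                outcome=outcome,
                probe=int(is_probe),
                bias=bias,
                p_med=p_med,
                inactivation_site=inactivation_site,
            )
        )
    return pd.DataFrame(rows)
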