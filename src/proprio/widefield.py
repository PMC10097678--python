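"""Wide-field calcium stack processing.

A wide-field session interleaves calcium-sensitive frames (470 nm, "blue")
with calcium-insensitive reference frames (405 nm, "violet") at 40 fps.
Processing follows the standard dual-wavelength pipeline: the two channels
are demultiplexed and linearly interpolated onto a shared regular 20 Hz
grid; the violet series is regressed onto the blue series per pixel, and
the scaled violet fluctuation is subtracted from blue to remove hemodynamic
and other calcium-independent artifacts; the corrected series is Δf/f0
normalized against the mean of the 1 s preceding stimulus onset and
temporally smoothed with a Savitzky-Golay filter (450 ms window, order 2 =
9 points at 20 Hz). Activation maps are the post-stimulus frame of maximal
spatial-mean activation, normalized to its own peak, registered to an atlas
frame through a 5-landmark least-squares affine, and summarized by the 50%
iso-contour around the peak locus.

Stacks are stored (T, H, W), the axis order multi-frame TIFF readers
produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import savgol_filter
from skimage import measure

__all__ = [
    "DualChannelStack",
    "CorrectedStack",
    "AtlasRegistration",
    "ActivationMap",
    "demux_and_align",
    "hemodynamic_correction",
    "peak_frame",
    "register_to_atlas",
    "apply_affine_to_points",
    "contour_50",
]

ATLAS_LANDMARKS = (
    "bregma",
    "lambda",
    "left_parietal_tip",
    "right_parietal_tip",
    "frontal_pole_median",
)


@dataclass
class DualChannelStack:
    """Interleaved blue(470)/violet(405) frames with per-frame timestamps."""

    frames: np.ndarray  # (T, H, W)
    frame_times_s: np.ndarray  # (T,)
    channel_labels: np.ndarray  # (T,) of {"blue", "violet"}
    acquisition_rate_hz: float = 40.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        self.channel_labels = np.asarray(self.channel_labels)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        t = self.frames.shape[0]
        if self.frame_times_s.shape != (t,) or self.channel_labels.shape != (t,):
            raise ValueError("timestamps and labels must match the frame count")
        if not set(np.unique(self.channel_labels)) <= {"blue", "violet"}:
            raise ValueError("channel labels must be 'blue' or 'violet'")
        same = np.nonzero(self.channel_labels[1:] == self.channel_labels[:-1])[0]
        if same.size:
            raise ValueError(f"channel alternation broken at frame index {int(same[0]) + 1}")


@dataclass
class CorrectedStack:
    """Hemodynamics-corrected Δf/f0 stack at 20 Hz.

    ``dff`` is Savitzky-Golay smoothed; ``dff_raw`` is the unsmoothed Δf/f0
    whose baseline-window mean is exactly zero per pixel by construction.
    """

    dff: np.ndarray  # (T', H, W)
    dff_raw: np.ndarray
    times_s: np.ndarray
    slope: np.ndarray  # (H, W) regression slope (violet -> blue)
    intercept: np.ndarray
    baseline_frames: np.ndarray  # indices of the 1 s pre-stimulus window
    masked_pixels: np.ndarray  # boolean (H, W), True where violet had no variance


@dataclass
class AtlasRegistration:
    """2D affine (2×3) from image pixels to atlas coordinates."""

    affine: np.ndarray
    landmarks_image: np.ndarray  # (n, 2)
    landmarks_atlas: np.ndarray  # (n, 2)
    residual_px: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return apply_affine_to_points(self.affine, points)

    def inverse_affine(self) -> np.ndarray:
        A = np.vstack([self.affine, [0.0, 0.0, 1.0]])
        return np.linalg.inv(A)[:2]


@dataclass
class ActivationMap:
    """Peak-activation frame normalized to max 1, with its peak locus."""

    image: np.ndarray  # (H, W), max exactly 1
    frame_index: int
    time_s: float
    peak_xy: tuple[float, float]  # (x=col, y=row) in image pixels
    peak_atlas_xy: tuple[float, float] | None = None
    contours: list = field(default_factory=list)


# ---------------------------------------------------------------------------


def demux_and_align(
    stack: DualChannelStack, out_rate_hz: float = 20.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Demultiplex the interleaved channels and interpolate both onto a
    common regular grid (20 Hz by default).

    Returns (times_s, blue, violet) with blue/violet shaped (T', H, W).
    """
    blue_sel = stack.channel_labels == "blue"
    violet_sel = ~blue_sel
    tb, tv = stack.frame_times_s[blue_sel], stack.frame_times_s[violet_sel]
    if tb.size < 4 or tv.size < 4:
        raise ValueError("need at least 4 frames per channel")
    t0 = max(tb[0], tv[0])
    t1 = min(tb[-1], tv[-1])
    dt = 1.0 / out_rate_hz
    times = t0 + np.arange(int(np.floor((t1 - t0) / dt)) + 1) * dt
    blue = interp1d(tb, stack.frames[blue_sel], axis=0, assume_sorted=True)(times)
    violet = interp1d(tv, stack.frames[violet_sel], axis=0, assume_sorted=True)(times)
    return times, blue, violet


def hemodynamic_correction(
    times_s: np.ndarray,
    blue: np.ndarray,
    violet: np.ndarray,
    stimulus_onset_s: float,
    baseline_s: float = 1.0,
    sg_window_s: float = 0.45,
    sg_order: int = 2,
) -> CorrectedStack:
    """Per-pixel regression correction, Δf/f0 and temporal smoothing.

    The violet series is regressed onto the blue series per pixel (OLS with
    intercept over the full series) and the scaled violet fluctuation around
    its mean is subtracted from blue, which removes the shared hemodynamic
    component while preserving the blue DC level needed as a Δf/f0 divisor.
    Δf/f0 uses the mean over the ``baseline_s`` preceding stimulus onset as
    f0 per pixel, then a Savitzky-Golay filter (order 2, 450 ms → 9 points
    at 20 Hz) smooths each pixel's time course. Pixels whose violet series
    has zero variance are masked (NaN) and reported.
    """
    blue = np.asarray(blue, dtype=float)
    violet = np.asarray(violet, dtype=float)
    if blue.shape != violet.shape or blue.ndim != 3:
        raise ValueError("blue and violet must be matching (T, H, W) stacks")
    t = np.asarray(times_s, dtype=float)
    base = (t >= stimulus_onset_s - baseline_s) & (t < stimulus_onset_s)
    if not base.any():
        raise ValueError("no frames in the pre-stimulus baseline window")
    vmean = violet.mean(axis=0)
    bmean = blue.mean(axis=0)
    vc = violet - vmean
    var_v = (vc**2).mean(axis=0)
    masked = var_v <= 0
    cov = (vc * (blue - bmean)).mean(axis=0)
    slope = np.divide(cov, var_v, out=np.zeros_like(cov), where=~masked)
    intercept = bmean - slope * vmean
    corrected = blue - slope[None] * vc
    f0 = corrected[base].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff_raw = (corrected - f0[None]) / f0[None]
    dff_raw[:, masked] = np.nan
    dff_raw[:, f0 == 0] = np.nan
    dt = float(np.median(np.diff(t)))
    window = int(round(sg_window_s / dt))
    window += 1 - window % 2  # odd
    window = max(window, sg_order + 1 + (sg_order % 2))
    bad = np.isnan(dff_raw[0])
    dff = savgol_filter(np.nan_to_num(dff_raw), window, sg_order, axis=0, mode="interp")
    dff[:, bad] = np.nan
    return CorrectedStack(
        dff=dff,
        dff_raw=dff_raw,
        times_s=t,
        slope=slope,
        intercept=intercept,
        baseline_frames=np.nonzero(base)[0],
        masked_pixels=masked,
    )


def peak_frame(
    corrected: CorrectedStack,
    stimulus_onset_s: float,
    mask: np.ndarray | None = None,
    smoothed: bool = True,
) -> ActivationMap:
    """Post-stimulus frame of maximal spatial-mean activation, normalized
    to its own peak (ties resolved to the earlier frame)."""
    data = corrected.dff if smoothed else corrected.dff_raw
    sel = corrected.times_s >= stimulus_onset_s
    if not sel.any():
        raise ValueError("stimulus onset beyond the end of the series")
    post = data[sel]
    if mask is None:
        spatial = np.nanmean(post, axis=(1, 2))
    else:
        spatial = np.nanmean(post[:, mask], axis=1)
    k = int(np.argmax(spatial))  # argmax returns the first maximum
    frame_index = int(np.nonzero(sel)[0][k])
    img = data[frame_index]
    peak_val = np.nanmax(img)
    if not np.isfinite(peak_val) or peak_val == 0:
        raise ValueError("cannot normalize an all-zero or all-NaN peak frame")
    norm = img / peak_val
    r, c = np.unravel_index(np.nanargmax(img), img.shape)
    return ActivationMap(
        image=norm,
        frame_index=frame_index,
        time_s=float(corrected.times_s[frame_index]),
        peak_xy=(float(c), float(r)),
    )


# ---------------------------------------------------------------------------
# Atlas registration


def register_to_atlas(landmarks_image, landmarks_atlas) -> AtlasRegistration:
    """Least-squares 2D affine mapping image landmarks to atlas coordinates.

    Five landmarks are expected (bregma, lambda, the anterolateral tips of
    the left and right parietal bones, and the median frontal-pole point),
    but any ≥3 non-collinear correspondences are accepted.
    """
    src = np.atleast_2d(np.asarray(landmarks_image, dtype=float))
    dst = np.atleast_2d(np.asarray(landmarks_atlas, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2 or src.shape[0] < 3:
        raise ValueError("need >= 3 matched 2D landmark pairs")
    ones = np.ones((src.shape[0], 1))
    X = np.hstack([src, ones])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear landmarks: affine underdetermined")
    coef, *_ = np.linalg.lstsq(X, dst, rcond=None)
    affine = coef.T  # (2, 3)
    resid = dst - X @ coef
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return AtlasRegistration(
        affine=affine, landmarks_image=src, landmarks_atlas=dst, residual_px=rms
    )


def apply_affine_to_points(affine: np.ndarray, points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = pts @ affine[:, :2].T + affine[:, 2]
    return out[0] if np.ndim(points) == 1 else out


# ---------------------------------------------------------------------------
# Contours


def contour_50(activation: ActivationMap, level: float = 0.5) -> list[np.ndarray]:
    """Iso-contours at 50% of peak around the peak locus.

    Only the connected super-threshold component containing the peak is
    contoured; each returned polygon is an (n, 2) array of (x, y) image
    coordinates. The contours are also stored on the ActivationMap.
    """
    img = activation.image
    finite = np.nan_to_num(img, nan=-np.inf)
    if np.nanmax(img) <= level or float(np.nanmin(img)) >= level:
        raise ValueError("no valid iso-contour: map does not cross the level")
    labels = measure.label(finite >= level)
    r = int(round(activation.peak_xy[1]))
    c = int(round(activation.peak_xy[0]))
    peak_label = labels[r, c]
    if peak_label == 0:
        raise ValueError("peak locus below the contour level after masking")
    # suppress only the *other* super-level components; sub-level pixels must
    # keep their values so the iso-level interpolation stays exact
    component = np.where((labels == peak_label) | (finite < level), finite, 0.0)
    contours_rc = measure.find_contours(component, level)
    contours_xy = [poly[:, ::-1] for poly in contours_rc]
    activation.contours = contours_xy
    return contours_xy
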