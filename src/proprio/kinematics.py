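"""Pantograph kinematics, trajectories, stereo triangulation and angle maps.

The manipulandum is a planar five-bar (pantograph) linkage driven by two
motors whose hubs sit on the X axis of the manipulandum frame; the origin is
the center of the left motor. Each motor carries a proximal link of length
``lp``; the two distal links of length ``ld`` meet at the endpoint. The
endpoint is always taken on the elbow-up branch (positive-Y intersection of
the two distal-link circles), and the inverse kinematics return the motor
angles consistent with that branch.

3D joint tracking uses two calibrated pinhole cameras: landmark pixel pairs
are triangulated by the linear DLT, and a similarity transform (rotation +
isotropic scale + translation, no reflection) maps camera-world coordinates
into the manipulandum frame. The humerus abduction/adduction angle is the
azimuth of the glenohumeral→elbow vector projected on the XZ plane, measured
from the -Z axis (positive toward +X / lateral = abduction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator

__all__ = [
    "PantographGeometry",
    "MotorAngles",
    "Trajectory",
    "SimilarityTransform",
    "JointSet3D",
    "AngleMap",
    "UnreachableError",
    "forward_kinematics",
    "inverse_kinematics",
    "trapezoid_trajectory",
    "triangulate_point",
    "triangulate_joints",
    "fit_similarity_transform",
    "humerus_azimuth_angle",
    "build_angle_map",
    "angle_change_for_displacement",
]

JOINT_NAMES = ("scapulothoracic", "glenohumeral", "elbow", "wrist", "endpoint")


class UnreachableError(ValueError):
    """Raised when a configuration or target lies outside the workspace."""


@dataclass(frozen=True)
class PantographGeometry:
    """Link dimensions of the five-bar linkage, in cm.

    ``motor_separation_d`` is the distance between the two motor hubs,
    ``proximal_link_lp`` the motor-to-elbow link, ``distal_link_ld`` the
    elbow-to-endpoint link. Defaults are configuration, not measured values.
    """

    motor_separation_d: float = 2.0
    proximal_link_lp: float = 2.0
    distal_link_ld: float = 3.0

    def __post_init__(self) -> None:
        if min(self.motor_separation_d, self.proximal_link_lp, self.distal_link_ld) <= 0:
            raise ValueError("all linkage dimensions must be positive")
        if self.distal_link_ld + self.proximal_link_lp <= self.motor_separation_d / 2:
            raise ValueError("linkage cannot reach the midline: ld + lp <= d/2")


@dataclass(frozen=True)
class MotorAngles:
    """Motor hub angles in radians, counterclockwise from +X at each hub."""

    theta_left: float
    theta_right: float


@dataclass(frozen=True)
class Trajectory:
    """A straight-line endpoint trajectory sampled on a 1 kHz grid."""

    times_s: np.ndarray
    positions: np.ndarray  # (n, 2) cm
    peak_velocity: float  # cm/s
    amplitude: float  # mm
    accel: float  # cm/s^2

    @property
    def speed(self) -> np.ndarray:
        d = np.diff(self.positions, axis=0)
        dt = np.diff(self.times_s)
        return np.hypot(d[:, 0], d[:, 1]) / dt


@dataclass(frozen=True)
class SimilarityTransform:
    """x ↦ scale · R @ x + translation, with det(R) = +1 (no reflection)."""

    rotation: np.ndarray  # (3, 3) orthonormal, det +1
    scale: float
    translation: np.ndarray  # (3,)
    residual_rms: float = 0.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.scale * pts @ self.rotation.T + self.translation
        return out[0] if np.ndim(points) == 1 else out

    def inverse(self) -> "SimilarityTransform":
        r_inv = self.rotation.T
        s_inv = 1.0 / self.scale
        return SimilarityTransform(
            rotation=r_inv,
            scale=s_inv,
            translation=-s_inv * r_inv @ self.translation,
            residual_rms=self.residual_rms,
        )


@dataclass
class JointSet3D:
    """3D coordinates (cm) of the endpoint and four forelimb joints.

    Frame convention: X lateral-right, Y anterior, Z up (manipulandum frame),
    unless the set still lives in camera-world coordinates.
    """

    scapulothoracic: np.ndarray
    glenohumeral: np.ndarray
    elbow: np.ndarray
    wrist: np.ndarray
    endpoint: np.ndarray
    conditioning_warning: bool = False

    def as_array(self) -> np.ndarray:
        return np.stack(
            [self.scapulothoracic, self.glenohumeral, self.elbow, self.wrist, self.endpoint]
        )

    @classmethod
    def from_array(cls, arr: np.ndarray, conditioning_warning: bool = False) -> "JointSet3D":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5, 3):
            raise ValueError("expected a (5, 3) array in landmark order "
                             f"{JOINT_NAMES}, got {arr.shape}")
        return cls(*arr, conditioning_warning=conditioning_warning)


# ---------------------------------------------------------------------------
# Five-bar forward / inverse kinematics


def _circle_intersection_up(c1: np.ndarray, c2: np.ndarray, r1: float, r2: float) -> np.ndarray:
    """Upper (max-y; ties broken toward +x normal) intersection of two circles."""
    d = float(np.hypot(*(c2 - c1)))
    if d > r1 + r2 or d < abs(r1 - r2) or d == 0.0:
        raise UnreachableError(
            f"distal circles do not intersect (centers {d:.4g} apart, radii {r1}, {r2})"
        )
    a = (r1**2 - r2**2 + d**2) / (2 * d)
    h2 = r1**2 - a**2
    h = np.sqrt(max(h2, 0.0))
    mid = c1 + a * (c2 - c1) / d
    normal = np.array([-(c2 - c1)[1], (c2 - c1)[0]]) / d
    p_plus = mid + h * normal
    p_minus = mid - h * normal
    return p_plus if p_plus[1] >= p_minus[1] else p_minus


def forward_kinematics(geom: PantographGeometry, angles: MotorAngles) -> np.ndarray:
    """Endpoint (x, y) in cm for given motor angles, elbow-up branch."""
    lp, ld = geom.proximal_link_lp, geom.distal_link_ld
    e_left = lp * np.array([np.cos(angles.theta_left), np.sin(angles.theta_left)])
    e_right = np.array([geom.motor_separation_d, 0.0]) + lp * np.array(
        [np.cos(angles.theta_right), np.sin(angles.theta_right)]
    )
    return _circle_intersection_up(e_left, e_right, ld, ld)


def inverse_kinematics(geom: PantographGeometry, target) -> MotorAngles:
    """Motor angles reproducing ``target`` under the elbow-up convention.

    For each two-link chain (motor→elbow→endpoint) there are two elbow
    branches; the working mode is elbows-outward (left elbow rotated CCW of
    the motor→target line, right elbow CW), which is the branch
    :func:`forward_kinematics` realizes for endpoints above the motor axis.
    The returned pair is verified by a forward-kinematics round trip.
    """
    target = np.asarray(target, dtype=float)
    lp, ld = geom.proximal_link_lp, geom.distal_link_ld
    hubs = [np.array([0.0, 0.0]), np.array([geom.motor_separation_d, 0.0])]
    candidates = [[], []]
    for i, hub in enumerate(hubs):
        v = target - hub
        r = float(np.hypot(*v))
        if r > lp + ld + 1e-12 or r < abs(lp - ld) - 1e-12:
            side = "left" if i == 0 else "right"
            raise UnreachableError(
                f"target {tuple(target)} unreachable by the {side} chain "
                f"(distance {r:.4g}, limits [{abs(lp - ld):.4g}, {lp + ld:.4g}])"
            )
        alpha = np.arctan2(v[1], v[0])
        cos_beta = np.clip((lp**2 + r**2 - ld**2) / (2 * lp * r), -1.0, 1.0)
        beta = np.arccos(cos_beta)
        # elbows-outward working mode first (left: alpha+beta, right: alpha-beta);
        # several combinations can reach the same endpoint, so the preferred
        # branch must come first, then be verified by a forward round trip.
        candidates[i] = [alpha + beta, alpha - beta] if i == 0 else [alpha - beta, alpha + beta]
    best, best_err = None, np.inf
    for tl in candidates[0]:
        for tr in candidates[1]:
            try:
                p = forward_kinematics(geom, MotorAngles(tl, tr))
            except UnreachableError:
                continue
            err = float(np.hypot(*(p - target)))
            if err < best_err - 1e-12:
                best, best_err = MotorAngles(tl, tr), err
    if best is None or best_err > 1e-6:
        raise UnreachableError(
            f"no elbow-up configuration reproduces target {tuple(target)}"
        )
    return best


def trapezoid_trajectory(
    start, end, peak_velocity: float, accel: float = 20.0, sample_rate_hz: float = 1000.0
) -> Trajectory:
    """Straight-line trajectory with a trapezoidal speed profile.

    Accelerates at ``accel`` to ``peak_velocity``, cruises, and decelerates
    symmetrically; if the distance is too short for a cruise phase the
    profile degenerates to a triangle peaking at sqrt(distance·accel).
    Sampled at 1 kHz by default, endpoint included.
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    dist = float(np.hypot(*(end - start)))
    if dist <= 0:
        raise ValueError("zero-distance trajectory")
    if peak_velocity <= 0 or accel <= 0:
        raise ValueError("peak_velocity and accel must be positive")
    t_acc = peak_velocity / accel
    d_acc = 0.5 * accel * t_acc**2
    if 2 * d_acc <= dist:  # trapezoidal
        t_cruise = (dist - 2 * d_acc) / peak_velocity
        duration = 2 * t_acc + t_cruise
        v_peak = peak_velocity
    else:  # triangular
        v_peak = np.sqrt(dist * accel)
        t_acc = v_peak / accel
        t_cruise = 0.0
        duration = 2 * t_acc
    dt = 1.0 / sample_rate_hz
    times = np.arange(0.0, duration + dt / 2, dt)
    times[-1] = min(times[-1], duration)

    def arc_length(t: np.ndarray) -> np.ndarray:
        t = np.clip(t, 0.0, duration)
        s = np.where(
            t < t_acc,
            0.5 * accel * t**2,
            np.where(
                t < t_acc + t_cruise,
                0.5 * accel * t_acc**2 + v_peak * (t - t_acc),
                dist - 0.5 * accel * np.clip(duration - t, 0, None) ** 2,
            ),
        )
        return s

    frac = arc_length(times) / dist
    positions = start[None, :] + frac[:, None] * (end - start)[None, :]
    return Trajectory(
        times_s=times,
        positions=positions,
        peak_velocity=float(v_peak),
        amplitude=dist * 10.0,  # cm -> mm
        accel=float(accel),
    )


# ---------------------------------------------------------------------------
# Stereo triangulation and similarity transforms


def triangulate_point(
    pixels1, pixels2, P1: np.ndarray, P2: np.ndarray, angle_warn_deg: float = 1.0
) -> tuple[np.ndarray, bool]:
    """Linear (DLT) two-view triangulation of one landmark.

    Returns the 3D point in the world frame of the calibration (camera-1
    optical center at the origin for the standard setup) and a flag that is
    True when the two viewing rays are within ``angle_warn_deg`` of parallel.
    """
    u1, v1 = pixels1
    u2, v2 = pixels2
    A = np.stack(
        [
            u1 * P1[2] - P1[0],
            v1 * P1[2] - P1[1],
            u2 * P2[2] - P2[0],
            v2 * P2[2] - P2[1],
        ]
    )
    _, _, vt = np.linalg.svd(A)
    X = vt[-1]
    if abs(X[3]) < 1e-12:
        raise ValueError("triangulated point at infinity")
    point = X[:3] / X[3]

    def center(P: np.ndarray) -> np.ndarray:
        _, _, vtp = np.linalg.svd(P)
        c = vtp[-1]
        return c[:3] / c[3]

    r1 = point - center(P1)
    r2 = point - center(P2)
    cosang = abs(
        float(np.dot(r1, r2) / (np.linalg.norm(r1) * np.linalg.norm(r2) + 1e-300))
    )
    ill = cosang > np.cos(np.deg2rad(angle_warn_deg))
    return point, ill


def triangulate_joints(pixel_pairs: dict, calibration: tuple[np.ndarray, np.ndarray]) -> JointSet3D:
    """Triangulate the five landmarks of one limb pose.

    ``pixel_pairs`` maps each landmark name in
    ``("scapulothoracic", "glenohumeral", "elbow", "wrist", "endpoint")`` to
    ((u1, v1), (u2, v2)) stereo pixel coordinates. ``calibration`` is the
    pair of 3×4 projection matrices. Near-parallel viewing rays set the
    ``conditioning_warning`` flag on the result instead of raising.
    """
    P1, P2 = (np.asarray(P, dtype=float) for P in calibration)
    for name, P in (("camera 1", P1), ("camera 2", P2)):
        if P.shape != (3, 4) or np.linalg.matrix_rank(P) != 3:
            raise ValueError(f"{name} projection matrix must be rank-3 of shape (3, 4)")
    pts = []
    warn = False
    for name in JOINT_NAMES:
        if name not in pixel_pairs:
            raise KeyError(f"missing landmark {name!r}")
        px1, px2 = pixel_pairs[name]
        p, ill = triangulate_point(px1, px2, P1, P2)
        warn = warn or ill
        pts.append(p)
    if warn:
        warnings.warn("near-parallel viewing rays: triangulation poorly conditioned",
                      RuntimeWarning, stacklevel=2)
    return JointSet3D.from_array(np.stack(pts), conditioning_warning=warn)


def fit_similarity_transform(source_points, target_points) -> SimilarityTransform:
    """Least-squares similarity transform (Umeyama) with det(R) = +1 enforced.

    Maps source → target minimizing Σ‖s·R·x + t − y‖². Reflections are never
    returned; a mirrored correspondence set yields the best proper rotation
    with a correspondingly large residual.
    """
    src = np.asarray(source_points, dtype=float)
    dst = np.asarray(target_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be matched (n, 3) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError("need at least 3 correspondences")
    mu_s, mu_d = src.mean(0), dst.mean(0)
    xs, xd = src - mu_s, dst - mu_d
    if np.linalg.matrix_rank(xs, tol=1e-9 * max(1.0, np.abs(xs).max())) < 2:
        raise ValueError("degenerate (collinear) source points")
    cov = xd.T @ xs / n
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    var_s = (xs**2).sum() / n
    scale = float(np.trace(np.diag(D) @ S) / var_s)
    t = mu_d - scale * R @ mu_s
    resid = dst - (scale * src @ R.T + t)
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return SimilarityTransform(rotation=R, scale=scale, translation=t, residual_rms=rms)


def humerus_azimuth_angle(joints: JointSet3D) -> float:
    """Humerus abduction/adduction angle in degrees.

    Azimuth of the glenohumeral→elbow vector projected on the XZ plane,
    measured from the -Z (straight down) axis; positive toward +X (lateral,
    abduction), negative toward -X (medial, adduction); range (-180, 180].
    """
    v = np.asarray(joints.elbow, dtype=float) - np.asarray(joints.glenohumeral, dtype=float)
    vx, vz = v[0], v[2]
    if np.hypot(vx, vz) < 1e-12:
        raise ValueError("humerus parallel to the Y axis: azimuth undefined")
    ang = np.degrees(np.arctan2(vx, -vz))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


# ---------------------------------------------------------------------------
# Workspace angle maps


@dataclass
class AngleMap:
    """Humerus angle sampled on a planar workspace lattice, with linear
    interpolation between nodes (exact at the nodes)."""

    grid: np.ndarray  # (n, 2) cm
    values: np.ndarray  # (n,) degrees
    _interp: LinearNDInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape[0] != self.values.shape[0]:
            raise ValueError("grid and values must have matching lengths")
        self._interp = LinearNDInterpolator(self.grid, self.values)

    def __call__(self, point) -> float:
        val = float(self._interp(np.atleast_2d(np.asarray(point, dtype=float)))[0])
        if np.isnan(val):
            raise ValueError(f"query point {tuple(np.asarray(point))} outside the grid hull")
        return val


def build_angle_map(grid_joint_sets) -> AngleMap:
    """Angle map from (planar grid point, JointSet3D) pairs."""
    pts, vals = [], []
    for point, joints in grid_joint_sets:
        pts.append(np.asarray(point, dtype=float))
        vals.append(humerus_azimuth_angle(joints))
    return AngleMap(grid=np.stack(pts), values=np.asarray(vals))


def angle_change_for_displacement(
    angle_map: AngleMap, start, direction_deg: float, distance_mm: float
) -> float:
    """Δangle (degrees) for a straight displacement from ``start``.

    Positive Δ = abduction increase. ``direction_deg`` is the azimuth of the
    displacement in the workspace plane; ``distance_mm`` is converted to cm
    to match the grid units.
    """
    start = np.asarray(start, dtype=float)
    d_cm = distance_mm / 10.0
    theta = np.deg2rad(direction_deg)
    end = start + d_cm * np.array([np.cos(theta), np.sin(theta)])
    return angle_map(end) - angle_map(start)
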