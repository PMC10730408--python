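"""Per-frame larva pose extraction from grayscale frames.

Each frame is background subtracted, Gaussian blurred, thresholded, and the
centroid of the largest connected component taken as the larva position
(intensity-weighted).  For the stimulus-locked assays five points are then
stepped along the tail skeleton at equal arc intervals.  Orientation is the
angle of the vector from the first body point toward the centroid; curvature
is the sum of the unsigned angles between successive body segments, so a
straight larva has curvature 0 and an O-bend well above 1.75 rad.

Conventions: pixel coordinates are 0-based (x rightward, y downward);
curvature is unsigned because every downstream classification rule is a
one-sided magnitude threshold.  Frames with no supra-threshold pixels are
reported as missing, not fatal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "Pose", "Trajectory", "DegeneratePostureError",
    "segment_frame", "fit_tail_points", "compute_orientation",
    "compute_curvature", "track_frames",
]

#: Defaults tuned on rendered fixtures (the source videos give no values).
DEFAULT_BLUR_SIGMA = 1.0
DEFAULT_THRESHOLD = 10.0
#: Arc step between successive tail points, px (10 px/mm scale).
DEFAULT_TAIL_STEP_PX = 5.0
N_TAIL_POINTS = 5


class DegeneratePostureError(ValueError):
    """Mask too small or degenerate to place the requested tail points."""


@dataclass
class Pose:
    """Single-frame posture: centroid, tail points (rostral→caudal), angles."""

    centroid: np.ndarray  # (2,) x, y
    tail_points: np.ndarray | None = None  # (5, 2) x, y
    orientation_rad: float = np.nan
    curvature_rad: float = np.nan


@dataclass
class Trajectory:
    """One larva's pose sequence for one recorded segment.

    ``xy`` rows may be NaN where the larva was not detected (missing frames);
    ``tail`` likewise.  Timestamps are ms relative to the segment reference
    (stimulus onset for stimulus-locked windows, phase start for VMR).
    """

    larva_id: str
    well_id: str
    segment_id: str
    frame_rate_fps: float
    time_ms: np.ndarray          # (n,)
    xy: np.ndarray               # (n, 2)
    tail: np.ndarray | None = None   # (n, 5, 2)
    orientation_rad: np.ndarray | None = None  # (n,)
    curvature_rad: np.ndarray | None = None    # (n,)
    t0_ms: float = 0.0           # absolute onset within the block

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.time_ms)

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.frame_rate_fps

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.xy).any(axis=1)

    def displacement(self) -> np.ndarray:
        """Per-frame centroid displacement (px); first frame is 0, NaN across gaps."""
        d = np.full(self.n_frames, np.nan)
        if self.n_frames == 0:
            return d
        step = np.linalg.norm(np.diff(self.xy, axis=0), axis=1)
        d[0] = 0.0
        d[1:] = step
        return d


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_frame(
    frame: np.ndarray,
    background: np.ndarray,
    blur_sigma: float = DEFAULT_BLUR_SIGMA,
    threshold: float = DEFAULT_THRESHOLD,
):
    """Background-subtract, blur, threshold; return (mask, centroid) or (mask, None).

    The centroid is the intensity-weighted center of the largest connected
    component of the thresholded image (ties broken by lowest label in
    row-major scan order, deterministically).  Returns ``(empty mask, None)``
    when no pixel exceeds the threshold ("no object").
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    diff = frame - background
    np.clip(diff, 0.0, None, out=diff)  # larva is brighter than background
    blurred = ndimage.gaussian_filter(diff, sigma=blur_sigma)
    mask = blurred > threshold
    if not mask.any():
        return mask, None
    labels = measure.label(mask, connectivity=2)
    # np.bincount + argmax: first (lowest) label wins area ties.
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    biggest = int(np.argmax(areas))
    comp = labels == biggest
    weights = np.where(comp, blurred, 0.0)
    cy, cx = ndimage.center_of_mass(weights)
    return comp, np.array([cx, cy])


# ---------------------------------------------------------------------------
# Tail points
# ---------------------------------------------------------------------------

def _sample(score: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Cubic-spline interpolation of the score image at (x, y) points."""
    coords = np.vstack([pts[:, 1], pts[:, 0]])  # (row, col) order
    return ndimage.map_coordinates(score, coords, order=3, mode="constant")


def fit_tail_points(
    mask: np.ndarray,
    centroid: np.ndarray,
    n_points: int = N_TAIL_POINTS,
    step_px: float = DEFAULT_TAIL_STEP_PX,
    intensity: np.ndarray | None = None,
) -> np.ndarray:
    """Five ordered tail points stepping along the body ridge at equal arc steps.

    Starting from the centroid, each point is placed ``step_px`` from the
    previous one in the direction maximizing the blurred body image
    (``intensity`` if given, else the mask), searched over a forward-facing
    arc so the trace cannot reverse.  The initial direction is the brighter
    of the two body ends probed beyond the head radius, which selects the
    tail because it is the longer extension.  Points come out ordered
    rostral → caudal.

    Raises :class:`DegeneratePostureError` when the body is too small to
    support ``n_points`` steps.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3 * n_points:
        raise DegeneratePostureError("mask too small to place tail points")
    body = np.asarray(intensity, float) if intensity is not None else mask.astype(float)
    score = ndimage.gaussian_filter(body, sigma=1.5)
    floor = 0.025 * score.max()
    angles = np.linspace(-np.pi, np.pi, 96, endpoint=False)
    c = np.asarray(centroid, float)

    # initial direction: probe beyond the head so the longer (tail) end wins
    probe_r = 2.2 * step_px
    cand = c + probe_r * np.column_stack([np.cos(angles), np.sin(angles)])
    vals = _sample(score, cand)
    if vals.max() <= floor:
        raise DegeneratePostureError("no body ridge beyond the head radius")
    theta = float(angles[int(np.argmax(vals))])

    pts = np.empty((n_points, 2))
    pos = c
    for i in range(n_points):
        rel = np.linspace(-1.85, 1.85, 75)  # ±106° forward search arc
        dirs = theta + rel
        cand = pos + step_px * np.column_stack([np.cos(dirs), np.sin(dirs)])
        vals = _sample(score, cand)
        j = int(np.argmax(vals))
        if vals[j] <= floor:
            raise DegeneratePostureError(
                f"body ridge ended after {i} of {n_points} tail points")
        theta = float(dirs[j])
        if 0 < j < len(dirs) - 1:
            # parabolic sub-grid refinement of the ridge direction
            denom = vals[j - 1] - 2 * vals[j] + vals[j + 1]
            if denom < 0:
                theta += float(np.clip(
                    0.5 * (vals[j - 1] - vals[j + 1]) / denom, -0.5, 0.5)
                ) * (rel[1] - rel[0])
        pos = pos + step_px * np.array([np.cos(theta), np.sin(theta)])
        pts[i] = pos
    return pts


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------

def compute_orientation(pose: Pose | None = None, *, first_point=None, centroid=None) -> float:
    """Heading angle: atan2 of the vector from the first body point to the centroid.

    Accepts either a :class:`Pose` or explicit ``first_point``/``centroid``.
    Result in (−π, π].  Coincident points give NaN (undefined orientation).
    """
    if pose is not None:
        if pose.tail_points is None:
            return np.nan
        first_point = pose.tail_points[0]
        centroid = pose.centroid
    v = np.asarray(centroid, float) - np.asarray(first_point, float)
    if np.allclose(v, 0.0):
        return np.nan
    return float(np.arctan2(v[1], v[0]))


def compute_curvature(points) -> float:
    """Total body bend: sum of unsigned angles between successive segments.

    ``points`` is an (m, 2) array ordered along the body (typically centroid
    followed by the five tail points) or a :class:`Pose`.  Needs at least
    three points; returns NaN otherwise.  Zero-length segments are skipped.
    """
    if isinstance(points, Pose):
        if points.tail_points is None:
            return np.nan
        points = np.vstack([points.centroid, points.tail_points])
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        return np.nan
    vecs = np.diff(pts, axis=0)
    norms = np.linalg.norm(vecs, axis=1)
    keep = norms > 1e-12
    vecs = vecs[keep]
    if len(vecs) < 2:
        return np.nan
    u = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    dots = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
    return float(np.sum(np.arccos(dots)))


# ---------------------------------------------------------------------------
# Frame-stack driver
# ---------------------------------------------------------------------------

def track_frames(
    frames,
    background: np.ndarray,
    blur_sigma: float = DEFAULT_BLUR_SIGMA,
    threshold: float = DEFAULT_THRESHOLD,
    with_tail: bool = True,
    step_px: float = DEFAULT_TAIL_STEP_PX,
) -> list[Pose | None]:
    """Track a stack of frames against a common background.

    Returns one :class:`Pose` per frame, or ``None`` for missing frames
    (no object).  Tail fitting failures degrade gracefully to a centroid-only
    pose (tail/orientation/curvature NaN).
    """
    poses: list[Pose | None] = []
    for frame in frames:
        mask, centroid = segment_frame(frame, background, blur_sigma, threshold)
        if centroid is None:
            poses.append(None)
            continue
        pose = Pose(centroid=centroid)
        if with_tail:
            diff = np.clip(np.asarray(frame, float) - np.asarray(background, float),
                           0.0, None)
            try:
                pose.tail_points = fit_tail_points(mask, centroid, step_px=step_px,
                                                   intensity=diff)
                pose.orientation_rad = compute_orientation(pose)
                pose.curvature_rad = compute_curvature(pose)
            except DegeneratePostureError:
                pass
        poses.append(pose)
    return poses


def poses_to_trajectory(
    poses: list[Pose | None],
    frame_rate_fps: float,
    larva_id: str = "larva0",
    well_id: str = "w00",
    segment_id: str = "seg",
    t0_ms: float = 0.0,
) -> Trajectory:
    """Assemble tracked poses into a :class:`Trajectory` (NaN for missing frames)."""
    n = len(poses)
    frame_ms = 1000.0 / frame_rate_fps
    time_ms = np.arange(n) * frame_ms
    xy = np.full((n, 2), np.nan)
    tail = np.full((n, N_TAIL_POINTS, 2), np.nan)
    ori = np.full(n, np.nan)
    curv = np.full(n, np.nan)
    for i, p in enumerate(poses):
        if p is None:
            continue
        xy[i] = p.centroid
        if p.tail_points is not None:
            tail[i] = p.tail_points
        ori[i] = p.orientation_rad
        curv[i] = p.curvature_rad
    return Trajectory(
        larva_id=larva_id, well_id=well_id, segment_id=segment_id,
        frame_rate_fps=frame_rate_fps, time_ms=time_ms, xy=xy, tail=tail,
        orientation_rad=ori, curvature_rad=curv, t0_ms=t0_ms,
    )
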