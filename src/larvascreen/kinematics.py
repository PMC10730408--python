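"""Swim-bout detection and post-stimulus response classification.

A *bout* is a discrete swim episode read off the per-frame centroid
displacement series: it starts at the first of at least two consecutive
frames with displacement above 0.7 px and ends on the frame preceding the
first pair of consecutive frames at or below that threshold.  Centroid
movement contributes to kinematic features only within bouts.

Post-stimulus *response events* are extracted from the recorded window of
each stimulus: latency to movement onset (the bout criterion applied at the
block frame rate), maximum curvature, maximum per-frame angular velocity,
wrapped orientation change, and path measures over the movement.  Responses
are then classified:

* LF — *react* if max curvature > 0.5 rad with latency > 15 ms;
* DF — *O-bend* if max curvature > 1.75 rad, *react* if 0.5–1.75 rad, both
  gated on latency > 15 ms (earlier movements are *too_early*);
* ASR — *SLC* if max curvature > 0.8 rad with latency < 20 ms, *LLC* if
  > 0.8 rad with latency ≥ 20 ms, *react* if 0.5–0.8 rad.

All thresholds are applied with strict inequality; equality at a boundary
falls to the lower class (an ASR latency of exactly 20 ms is an LLC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import StimulusEvent
from .tracking import Trajectory

__all__ = [
    "KinematicThresholds", "Bout", "ResponseEvent",
    "detect_bouts", "extract_response", "classify", "RESPONSE_LABELS",
]

RESPONSE_LABELS = ("none", "too_early", "react", "obend", "slc", "llc")
#: Labels counting as "reacting or higher" for frequency-of-response metrics.
RESPONDING_LABELS = frozenset({"react", "obend", "slc", "llc"})


@dataclass(frozen=True)
class KinematicThresholds:
    """Classification constants (px, rad, ms) from the published metric rules."""

    bout_disp_px: float = 0.7
    bout_consecutive_frames: int = 2
    react_curv_rad: float = 0.5
    obend_curv_rad: float = 1.75
    slc_llc_curv_rad: float = 0.8
    slc_latency_ms: float = 20.0
    min_latency_ms: float = 15.0
    #: Fraction of missing frames above which a response window is excluded.
    max_missing_frac: float = 0.2
    #: The too-early gate is printed for LF/DF only; set True to extend to ASR.
    too_early_applies_to_asr: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.react_curv_rad < self.slc_llc_curv_rad < self.obend_curv_rad):
            raise ValueError("need 0 < react < slc_llc < obend curvature thresholds")
        if self.bout_disp_px <= 0 or self.bout_consecutive_frames < 1:
            raise ValueError("invalid bout thresholds")


@dataclass
class Bout:
    """One supra-threshold movement episode (frame indices inclusive)."""

    start_frame: int
    end_frame: int
    duration_ms: float = np.nan
    distance_px: float = np.nan      # path length within the bout
    displacement_px: float = np.nan  # net start-to-end displacement
    mean_speed_px_per_ms: float = np.nan
    truncated: bool = False          # movement still above threshold at series end


@dataclass
class ResponseEvent:
    """Kinematics of one post-stimulus window plus its classification."""

    stimulus: StimulusEvent | None
    assay: str
    moved: bool = False
    latency_ms: float = np.nan
    max_curvature_rad: float = np.nan
    max_angular_velocity_rad_per_frame: float = np.nan
    delta_orientation_rad: float = np.nan
    displacement_px: float = np.nan
    distance_px: float = np.nan
    duration_ms: float = np.nan
    truncated: bool = False
    excluded: bool = False  # too many missing frames in the window
    label: str = "none"


# ---------------------------------------------------------------------------
# Bout detection
# ---------------------------------------------------------------------------

def detect_bouts(
    displacement,
    thresholds: KinematicThresholds = KinematicThresholds(),
    frame_ms: float | None = None,
    xy: np.ndarray | None = None,
) -> list[Bout]:
    """Find bouts in a uniformly sampled per-frame displacement series.

    A bout starts at the first of ``bout_consecutive_frames`` consecutive
    frames with displacement above ``bout_disp_px`` and ends at the frame
    preceding the first run of ``bout_consecutive_frames`` consecutive frames
    at or below it.  NaN displacements (missing frames) count as
    sub-threshold.  If ``frame_ms`` is given, durations/speeds are filled;
    if ``xy`` (one row per frame) is given, net displacements are filled
    (``displacement[i]`` being the movement from frame ``i−1`` to ``i``).
    """
    d = np.asarray(displacement, dtype=float)
    k = thresholds.bout_consecutive_frames
    above = np.where(np.isnan(d), False, d > thresholds.bout_disp_px)
    n = len(above)
    bouts: list[Bout] = []
    i = 0
    while i < n:
        if above[i] and i + k <= n and bool(above[i:i + k].all()):
            start = i
            # End: frame preceding the first run of k consecutive below frames.
            end = None
            j = start + 1
            while j + k <= n:
                if not above[j:j + k].any():
                    end = j - 1
                    break
                j += 1
            if end is None:
                # Series ended before a full k-frame below run confirmed the
                # end; the bout runs to the last above-threshold frame and is
                # flagged truncated.
                last = n - 1
                while last > start and not above[last]:
                    last -= 1
                bouts.append(Bout(start, last, truncated=True))
                break
            bouts.append(Bout(start, end))
            i = end + 1
        else:
            i += 1
    # feature fill
    for b in bouts:
        n_frames = b.end_frame - b.start_frame + 1
        seg = d[b.start_frame:b.end_frame + 1]
        b.distance_px = float(np.nansum(seg))
        if frame_ms is not None:
            b.duration_ms = n_frames * frame_ms
            if b.duration_ms > 0:
                b.mean_speed_px_per_ms = b.distance_px / b.duration_ms
        if xy is not None:
            p0 = xy[max(b.start_frame - 1, 0)]
            p1 = xy[b.end_frame]
            b.displacement_px = float(np.linalg.norm(p1 - p0))
    return bouts


# ---------------------------------------------------------------------------
# Response extraction
# ---------------------------------------------------------------------------

def _wrap_pi(angle: np.ndarray | float):
    """Wrap angle difference(s) to (−π, π]."""
    return (np.asarray(angle) + np.pi) % (2 * np.pi) - np.pi


def extract_response(
    trajectory: Trajectory,
    stimulus: StimulusEvent | None,
    record_window_ms: float,
    thresholds: KinematicThresholds = KinematicThresholds(),
    assay: str = "DF",
) -> ResponseEvent:
    """Extract the kinematic response in one post-stimulus window.

    The trajectory segment is assumed stimulus-locked (``time_ms[0]`` at
    stimulus onset).  Movement onset uses the bout criterion at the block
    frame rate; an event whose window has more than ``max_missing_frac``
    missing frames is marked ``excluded``.  The label field is left for
    :func:`classify`.
    """
    frame_ms = trajectory.frame_ms
    in_win = trajectory.time_ms <= record_window_ms + 1e-9
    n = int(np.sum(in_win))
    if n < 2 or trajectory.time_ms[-1] + frame_ms < record_window_ms:
        raise ValueError("trajectory does not cover the record window")
    ev = ResponseEvent(stimulus=stimulus, assay=assay)
    missing = trajectory.missing[:n]
    if missing.mean() > thresholds.max_missing_frac:
        ev.excluded = True
        return ev
    disp = trajectory.displacement()[:n]
    bouts = detect_bouts(disp, thresholds, frame_ms=frame_ms,
                         xy=trajectory.xy[:n])
    if trajectory.curvature_rad is not None:
        curv = trajectory.curvature_rad[:n]
        if np.any(np.isfinite(curv)):
            ev.max_curvature_rad = float(np.nanmax(curv))
    if trajectory.orientation_rad is not None:
        ori = trajectory.orientation_rad[:n]
        dori = np.abs(_wrap_pi(np.diff(ori)))
        if np.any(np.isfinite(dori)):
            ev.max_angular_velocity_rad_per_frame = float(np.nanmax(dori))
    if not bouts:
        return ev
    b = bouts[0]
    ev.moved = True
    ev.latency_ms = float(trajectory.time_ms[b.start_frame])
    ev.duration_ms = b.duration_ms
    ev.distance_px = b.distance_px
    ev.displacement_px = b.displacement_px
    ev.truncated = b.truncated
    if trajectory.orientation_rad is not None:
        o0 = trajectory.orientation_rad[max(b.start_frame - 1, 0)]
        o1 = trajectory.orientation_rad[b.end_frame]
        if np.isfinite(o0) and np.isfinite(o1):
            ev.delta_orientation_rad = float(abs(_wrap_pi(o1 - o0)))
    return ev


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify(
    event: ResponseEvent,
    assay: str | None = None,
    thresholds: KinematicThresholds = KinematicThresholds(),
) -> str:
    """Assign the response label for the event's assay; also stored on the event.

    The labels partition every (max curvature, latency) combination: exactly
    one applies.  Events with no movement are ``none``; excluded events keep
    ``none`` and should be dropped upstream.
    """
    assay = assay or event.assay
    if assay not in ("LF", "DF", "ASR"):
        raise ValueError(f"classification undefined for assay {assay!r}")
    t = thresholds
    if event.excluded or not event.moved:
        event.label = "none"
        return event.label
    curv = event.max_curvature_rad
    lat = event.latency_ms
    if not np.isfinite(curv):
        curv = 0.0
    if assay in ("LF", "DF"):
        if lat <= t.min_latency_ms:
            label = "too_early"
        elif assay == "DF" and curv > t.obend_curv_rad:
            label = "obend"
        elif curv > t.react_curv_rad:
            label = "react"
        else:
            label = "none"
    else:  # ASR
        if t.too_early_applies_to_asr and lat <= t.min_latency_ms:
            label = "too_early"
        elif curv > t.slc_llc_curv_rad:
            label = "slc" if lat < t.slc_latency_ms else "llc"
        elif curv > t.react_curv_rad:
            label = "react"
        else:
            label = "none"
    event.label = label
    return label
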