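"""The 94-metric behavioral vector: 60 VMR + 9 LF + 11 DF + 14 ASR.

VMR metrics are ten base quantities (bout counts, path totals, per-bout
averages, and well-position statistics) in six time bins: first minute,
last minute and full span of each of the lights-on and lights-off phases.
LF/DF/ASR share a nine-metric response summary (response frequency,
no-movement frequency, and means of latency, maximum bend angle, maximum
angular velocity, orientation change, displacement, distance and duration);
DF adds O-bend frequency and O-bend habituation, ASR adds SLC and LLC
frequencies, the startle sensitivity index (area under the SLC-frequency
versus intensity curve, arbitrary units), prepulse inhibition and startle
habituation.

Habituation and PPI are computed as ``1 − (late/attenuated frequency ÷
baseline frequency)`` so that complete suppression scores 1 regardless of
the baseline; both are undefined (missing) when the baseline frequency is
zero.  Missing values propagate as NaN and are never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import (
    Bout,
    KinematicThresholds,
    ResponseEvent,
    RESPONDING_LABELS,
    classify,
    detect_bouts,
    extract_response,
)
from .protocol import Protocol
from .tracking import Trajectory

__all__ = [
    "MetricConfig", "MetricDescriptor", "build_metric_registry",
    "vmr_metrics", "event_summary_metrics", "df_metrics", "asr_metrics",
    "assemble_vector", "metrics_from_trajectories",
    "VMR_BASE_METRICS", "VMR_BINS",
]


@dataclass(frozen=True)
class MetricConfig:
    """Geometry and formula options shared by the metric computations."""

    px_per_mm: float = 10.0
    well_radius_px: float = 45.0          # 9 mm well diameter at 10 px/mm
    rim_fraction: float = 2.0 / 3.0       # outer rim: radius > 2/3 of well radius
    #: Use the literal printed reading (1 − late) ÷ baseline of the
    #: habituation/PPI formulas instead of the conventional 1 − late ÷ baseline.
    literal_ratio_formulas: bool = False
    #: Ordinal abscissae for the sensitivity index (low, medium, high).
    intensity_abscissae: tuple[float, float, float] = (1.0, 2.0, 3.0)


@dataclass(frozen=True)
class MetricDescriptor:
    id: str
    assay: str
    bin: str   # VMR time bin, or "" for event assays
    units: str


VMR_BASE_METRICS = [
    ("n_bouts", "count"),
    ("total_distance_px", "px"),
    ("total_time_moved_ms", "ms"),
    ("avg_speed_px_per_ms", "px/ms"),
    ("avg_dist_from_center_px", "px"),
    ("frac_time_outer_rim", "fraction"),
    ("avg_distance_per_bout_px", "px"),
    ("avg_displacement_per_bout_px", "px"),
    ("avg_time_per_bout_ms", "ms"),
    ("avg_speed_per_bout_px_per_ms", "px/ms"),
]

VMR_BINS = [
    "light_on_first_min", "light_on_last_min", "light_on_full",
    "light_off_first_min", "light_off_last_min", "light_off_full",
]

EVENT_SUMMARY_METRICS = [
    ("freq_react", "fraction"),
    ("freq_no_movement", "fraction"),
    ("avg_latency_ms", "ms"),
    ("avg_max_bend_rad", "rad"),
    ("avg_max_ang_vel_rad_per_frame", "rad/frame"),
    ("avg_delta_orientation_rad", "rad"),
    ("avg_displacement_px", "px"),
    ("avg_distance_px", "px"),
    ("avg_duration_ms", "ms"),
]

DF_EXTRA_METRICS = [("freq_obend", "fraction"), ("habituation_obend", "index")]
ASR_EXTRA_METRICS = [
    ("freq_slc", "fraction"),
    ("freq_llc", "fraction"),
    ("sensitivity_index_au", "AU"),
    ("ppi", "index"),
    ("habituation_slc", "index"),
]


def build_metric_registry() -> list[MetricDescriptor]:
    """The ordered registry of all 94 metric descriptors (60/9/11/14)."""
    reg: list[MetricDescriptor] = []
    for b in VMR_BINS:
        for name, units in VMR_BASE_METRICS:
            reg.append(MetricDescriptor(f"vmr_{b}_{name}", "VMR", b, units))
    for name, units in EVENT_SUMMARY_METRICS:
        reg.append(MetricDescriptor(f"lf_{name}", "LF", "", units))
    for name, units in EVENT_SUMMARY_METRICS + DF_EXTRA_METRICS:
        reg.append(MetricDescriptor(f"df_{name}", "DF", "", units))
    for name, units in EVENT_SUMMARY_METRICS + ASR_EXTRA_METRICS:
        reg.append(MetricDescriptor(f"asr_{name}", "ASR", "", units))
    ids = [m.id for m in reg]
    assert len(ids) == len(set(ids)) == 94
    return reg


def registry_ids(registry: list[MetricDescriptor] | None = None) -> list[str]:
    return [m.id for m in registry or build_metric_registry()]


# ---------------------------------------------------------------------------
# VMR
# ---------------------------------------------------------------------------

def _nanmean_or_nan(values) -> float:
    vals = [v for v in values if np.isfinite(v)]
    return float(np.mean(vals)) if vals else np.nan


def vmr_bin_values(
    bouts: list[Bout],
    avg_dist_from_center_px: float,
    frac_time_outer_rim: float,
) -> dict[str, float]:
    """The ten VMR base metrics for one time bin.

    ``bouts`` are the bouts *starting* in the bin (a bout straddling a bin
    boundary counts wholly toward the bin containing its start).  With zero
    bouts the totals are 0 and the per-bout averages missing.
    """
    n = len(bouts)
    total_distance = float(sum(b.distance_px for b in bouts)) if n else 0.0
    total_time = float(sum(b.duration_ms for b in bouts)) if n else 0.0
    return {
        "n_bouts": float(n),
        "total_distance_px": total_distance,
        "total_time_moved_ms": total_time,
        "avg_speed_px_per_ms": (total_distance / total_time) if total_time > 0 else np.nan,
        "avg_dist_from_center_px": avg_dist_from_center_px,
        "frac_time_outer_rim": frac_time_outer_rim,
        "avg_distance_per_bout_px": _nanmean_or_nan([b.distance_px for b in bouts]),
        "avg_displacement_per_bout_px": _nanmean_or_nan([b.displacement_px for b in bouts]),
        "avg_time_per_bout_ms": _nanmean_or_nan([b.duration_ms for b in bouts]),
        "avg_speed_per_bout_px_per_ms": _nanmean_or_nan(
            [b.mean_speed_px_per_ms for b in bouts]),
    }


def _phase_bins(duration_ms: float) -> dict[str, tuple[float, float]]:
    return {
        "first_min": (0.0, 60_000.0),
        "last_min": (max(duration_ms - 60_000.0, 0.0), duration_ms),
        "full": (0.0, duration_ms),
    }


def vmr_metrics(
    segment_on: Trajectory,
    segment_off: Trajectory,
    thresholds: KinematicThresholds = KinematicThresholds(),
    config: MetricConfig = MetricConfig(),
    well_center: np.ndarray | None = None,
) -> dict[str, float]:
    """All 60 VMR metrics from the two continuously recorded phase segments."""
    if well_center is None:
        well_center = np.zeros(2)
    out: dict[str, float] = {}
    for phase, seg in (("light_on", segment_on), ("light_off", segment_off)):
        disp = seg.displacement()
        bouts = detect_bouts(disp, thresholds, frame_ms=seg.frame_ms, xy=seg.xy)
        start_times = np.array([seg.time_ms[b.start_frame] for b in bouts])
        r = np.linalg.norm(seg.xy - well_center, axis=1)
        duration = float(seg.time_ms[-1] + seg.frame_ms)
        for bin_name, (t0, t1) in _phase_bins(duration).items():
            in_bin = [b for b, t in zip(bouts, start_times) if t0 <= t < t1]
            frame_sel = (seg.time_ms >= t0) & (seg.time_ms < t1)
            r_bin = r[frame_sel & np.isfinite(r)]
            avg_r = float(np.mean(r_bin)) if r_bin.size else np.nan
            rim = (float(np.mean(r_bin > config.rim_fraction * config.well_radius_px))
                   if r_bin.size else np.nan)
            vals = vmr_bin_values(in_bin, avg_r, rim)
            for name, v in vals.items():
                out[f"vmr_{phase}_{bin_name}_{name}"] = v
    return out


# ---------------------------------------------------------------------------
# Event-assay summaries
# ---------------------------------------------------------------------------

def _valid(events: list[ResponseEvent]) -> list[ResponseEvent]:
    return [e for e in events if not e.excluded]


def event_summary_metrics(
    events: list[ResponseEvent], prefix: str
) -> dict[str, float]:
    """The nine response-summary metrics over one stimulus set.

    Frequencies are over all non-excluded stimuli; the feature means are over
    events passing the movement and latency gates (moved, not too early).
    """
    ev = _valid(events)
    if not ev:
        raise ValueError("no stimuli to summarize")
    n = len(ev)
    responders = [e for e in ev if e.label in RESPONDING_LABELS]
    movers = [e for e in ev if e.moved and e.label != "too_early"]
    out = {
        f"{prefix}_freq_react": len(responders) / n,
        f"{prefix}_freq_no_movement": sum(not e.moved for e in ev) / n,
        f"{prefix}_avg_latency_ms": _nanmean_or_nan([e.latency_ms for e in movers]),
        f"{prefix}_avg_max_bend_rad": _nanmean_or_nan(
            [e.max_curvature_rad for e in movers]),
        f"{prefix}_avg_max_ang_vel_rad_per_frame": _nanmean_or_nan(
            [e.max_angular_velocity_rad_per_frame for e in movers]),
        f"{prefix}_avg_delta_orientation_rad": _nanmean_or_nan(
            [e.delta_orientation_rad for e in movers]),
        f"{prefix}_avg_displacement_px": _nanmean_or_nan(
            [e.displacement_px for e in movers]),
        f"{prefix}_avg_distance_px": _nanmean_or_nan(
            [e.distance_px for e in movers]),
        f"{prefix}_avg_duration_ms": _nanmean_or_nan([e.duration_ms for e in movers]),
    }
    return out


def _freq(events: list[ResponseEvent], labels: set[str] | frozenset[str]) -> float:
    ev = _valid(events)
    if not ev:
        return np.nan
    return sum(e.label in labels for e in ev) / len(ev)


def _one_minus_ratio(late: float, base: float, literal: bool) -> float:
    """Habituation/PPI index; missing when the baseline frequency is zero."""
    if not np.isfinite(late) or not np.isfinite(base) or base == 0:
        return np.nan
    return (1.0 - late) / base if literal else 1.0 - late / base


def df_metrics(
    events: list[ResponseEvent],
    config: MetricConfig = MetricConfig(),
) -> dict[str, float]:
    """The 11 DF metrics from the recorded dark-flash trains (blocks 1, 3, 5).

    O-bend habituation compares the last 14 recorded stimuli (train 5) to the
    first 14 (train 1); it is undefined when the train-1 O-bend frequency is 0.
    """
    out = event_summary_metrics(events, "df")
    out["df_freq_obend"] = _freq(events, {"obend"})
    first = [e for e in events if e.stimulus is not None
             and e.stimulus.block_id == "df_block1"]
    last = [e for e in events if e.stimulus is not None
            and e.stimulus.block_id == "df_block5"]
    out["df_habituation_obend"] = _one_minus_ratio(
        _freq(last, {"obend"}), _freq(first, {"obend"}),
        config.literal_ratio_formulas)
    return out


def asr_metrics(
    events: list[ResponseEvent],
    config: MetricConfig = MetricConfig(),
) -> dict[str, float]:
    """The 14 ASR metrics.

    The nine summary metrics, SLC and LLC frequencies are computed over the
    ten no-prepulse high-intensity stimuli at 20 s ISI (the baseline block).
    Habituation compares the last 10 stimuli of the 30-stimulus 1 s-ISI train
    to that baseline; PPI compares the ten PPI4 stimuli (medium prepulse,
    300 ms lead) to it; the sensitivity index is the trapezoidal area under
    SLC frequency at the low/medium/high ordinal intensities.
    """
    by_block: dict[str, list[ResponseEvent]] = {}
    for e in events:
        if e.stimulus is not None:
            by_block.setdefault(e.stimulus.block_id, []).append(e)
    baseline = by_block.get("asr_high20", [])
    if not baseline:
        raise ValueError("no baseline high-intensity 20 s-ISI stimuli")
    out = event_summary_metrics(baseline, "asr")
    f_slc_base = _freq(baseline, {"slc"})
    out["asr_freq_slc"] = f_slc_base
    out["asr_freq_llc"] = _freq(baseline, {"llc"})
    f_low = _freq(by_block.get("asr_low", []), {"slc"})
    f_med = _freq(by_block.get("asr_medium", []), {"slc"})
    x = np.asarray(config.intensity_abscissae, dtype=float)
    y = np.array([f_low, f_med, f_slc_base])
    out["asr_sensitivity_index_au"] = (
        float(np.trapezoid(y, x)) if np.all(np.isfinite(y)) else np.nan)
    out["asr_ppi"] = _one_minus_ratio(
        _freq(by_block.get("asr_ppi4", []), {"slc"}), f_slc_base,
        config.literal_ratio_formulas)
    hab_train = by_block.get("asr_hab", [])
    last10 = hab_train[-10:] if len(hab_train) >= 10 else hab_train
    out["asr_habituation_slc"] = _one_minus_ratio(
        _freq(last10, {"slc"}), f_slc_base, config.literal_ratio_formulas)
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_vector(
    per_assay: dict[str, dict[str, float] | None],
    registry: list[MetricDescriptor] | None = None,
) -> pd.Series:
    """One value (or NaN) per registry id, in registry order.

    ``per_assay`` maps assay name (VMR/LF/DF/ASR) to that assay's metric dict
    (or None if the assay was not run).  Unknown or duplicate metric ids in
    the inputs are an error.
    """
    registry = registry or build_metric_registry()
    known = {m.id for m in registry}
    values: dict[str, float] = {}
    for assay, d in per_assay.items():
        if d is None:
            continue
        for mid, v in d.items():
            if mid not in known:
                raise KeyError(f"unknown metric id {mid!r}")
            if mid in values:
                raise KeyError(f"duplicate metric id {mid!r}")
            values[mid] = v
    return pd.Series(
        [values.get(m.id, np.nan) for m in registry],
        index=[m.id for m in registry],
        dtype=float,
    )


def metrics_from_trajectories(
    segments: dict[str, Trajectory],
    protocol: Protocol,
    thresholds: KinematicThresholds = KinematicThresholds(),
    config: MetricConfig = MetricConfig(),
    well_center: np.ndarray | None = None,
) -> pd.Series:
    """Full per-larva metric vector from tracked trajectory segments.

    ``segments`` maps segment ids to trajectories: ``vmr_on``/``vmr_off`` for
    the VMR phases and one stimulus-locked segment per recorded stimulus,
    keyed ``"{assay}:{stimulus index}"`` (e.g. ``"DF:17"``) with indices into
    the assay block's event list.
    """
    per_assay: dict[str, dict[str, float] | None] = {}
    if "vmr_on" in segments and "vmr_off" in segments:
        per_assay["VMR"] = vmr_metrics(
            segments["vmr_on"], segments["vmr_off"], thresholds, config,
            well_center=well_center)
    for assay in ("LF", "DF", "ASR"):
        block = protocol.block(assay)
        events: list[ResponseEvent] = []
        for idx, stim in enumerate(block.events):
            key = f"{assay}:{idx}"
            if key not in segments:
                continue
            ev = extract_response(segments[key], stim, block.record_window_ms,
                                  thresholds, assay=assay)
            classify(ev, assay, thresholds)
            events.append(ev)
        if not events:
            continue
        if assay == "LF":
            per_assay["LF"] = event_summary_metrics(events, "lf")
        elif assay == "DF":
            per_assay["DF"] = df_metrics(events, config)
        else:
            per_assay["ASR"] = asr_metrics(events, config)
    return assemble_vector(per_assay)
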