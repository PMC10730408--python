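"""Synthetic multi-well cohorts with genotype-dependent behavior.

The generator emulates a ~50-larva plate from a heterozygous incross
(Mendelian 1:2:1 wt:het:mut) run through the full four-assay paradigm.  Each
genotype carries a :class:`BehaviorParams` describing its latent behavior:

* spontaneous swim bouts arise as a Poisson process at a phase-dependent
  rate (lights-on vs lights-off), with log-normal bout speeds and durations;
* each stimulus elicits a response with probability
  ``p · (1 − h)^(k−1) · (1 − ppi)``, where ``p`` is the kind/intensity
  baseline, ``h`` the per-stimulus habituation rate applied within a
  decaying train (the whole 70-flash DF series and the 30-stimulus
  1 s-ISI acoustic train), and the PPI factor applies when a prepulse
  leads the pulse by 50 or 300 ms;
* responding larvae execute a bend whose curvature time-course is a
  raised-cosine pulse peaking at a drawn amplitude after a drawn latency;
  short-latency startles (SLC-like) have latency means below 20 ms,
  long-latency and O-bend-like responses above.

Two output levels share the same latent draws: :func:`simulate_cohort`
synthesizes full pose trajectories (and optionally rendered frames) so the
tracking and kinematic-extraction stages can be exercised, while
:func:`simulate_metric_matrix` feeds the latent per-stimulus records
directly through the classification and metric code — the route used for
screen-scale simulations where pose synthesis would dominate the cost.

Responses preempt spontaneous bouts within their window, so ground truth is
unambiguous.  All randomness flows from a single seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import Bout, KinematicThresholds, ResponseEvent, classify
from .metrics import (
    MetricConfig,
    asr_metrics,
    assemble_vector,
    build_metric_registry,
    df_metrics,
    event_summary_metrics,
    vmr_bin_values,
    _phase_bins,
)
from .protocol import Protocol, StimulusEvent, build_default_protocol
from .tracking import Trajectory

__all__ = [
    "BehaviorParams", "CohortConfig", "GroundTruth",
    "default_behavior_params", "simulate_cohort", "simulate_metric_matrix",
    "render_frames", "recover_parameters", "expected_metric_means",
]

GENOTYPES = ("wt", "het", "mut")

#: Pixel scale: all geometry is in pixels at 10 px/mm; 9 mm well -> 45 px radius.
PX_PER_MM = 10.0
WELL_RADIUS_PX = 45.0

#: Raised-cosine response-pulse durations per response class (ms).
RESPONSE_DURATION_MS = {"slc": 40.0, "llc": 64.0, "obend": 80.0, "react": 64.0}
#: Centroid speed during a response movement (px/ms); 1.5 px per 2 ms frame.
RESPONSE_SPEED_PX_PER_MS = 0.75
#: Minimum gap between a bout's end and the next bout's onset (ms).
BOUT_REFRACTORY_MS = 150.0


@dataclass(frozen=True)
class BehaviorParams:
    """Latent behavioral parameters for one genotype/treatment group.

    Latency and curvature parameters are (mean, sd) of truncated normals per
    response class; clip bounds keep the drawn kinematics on the correct
    side of the classification boundaries so the latent class label is
    recoverable.
    """

    bout_rate_per_min: dict = field(
        default_factory=lambda: {"light": 30.0, "dark": 60.0})
    bout_speed_mu: float = float(np.log(0.05))   # log px/ms
    bout_speed_sigma: float = 0.4
    bout_duration_mu: float = float(np.log(250.0))  # log ms
    bout_duration_sigma: float = 0.3
    p_respond: dict = field(
        default_factory=lambda: {"dark_flash": 0.95, "light_flash": 0.8})
    sensitivity_curve: dict = field(
        default_factory=lambda: {"low": 0.1, "medium": 0.5, "high": 0.9})
    habituation_rate: float = 0.06
    ppi_strength: float = 0.6
    p_slc_given_response: float = 0.85
    p_obend_given_response: float = 0.9
    latency_params: dict = field(default_factory=lambda: {
        "slc": (10.0, 2.0, 4.0, 18.0),        # mean, sd, lo, hi (ms)
        "llc": (45.0, 12.0, 22.0, 150.0),
        "obend": (60.0, 15.0, 22.0, 600.0),
        "react": (50.0, 15.0, 22.0, 350.0),
    })
    curvature_params: dict = field(default_factory=lambda: {
        "slc": (1.3, 0.2, 0.85, 3.0),         # mean, sd, lo, hi (rad)
        "llc": (1.2, 0.2, 0.85, 3.0),
        "obend": (2.3, 0.25, 1.8, 3.2),
        "react": (0.9, 0.15, 0.2, 1.7),
    })
    delta_orientation_params: dict = field(default_factory=lambda: {
        "slc": (0.6, 0.2), "llc": (0.7, 0.2), "obend": (1.2, 0.3),
        "react": (0.4, 0.15),
    })

    def __post_init__(self) -> None:
        probs = [self.habituation_rate, self.ppi_strength,
                 self.p_slc_given_response, self.p_obend_given_response,
                 *self.p_respond.values(), *self.sensitivity_curve.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        if any(r < 0 for r in self.bout_rate_per_min.values()):
            raise ValueError("bout rates must be >= 0")
        if self.latency_params["slc"][0] >= self.latency_params["llc"][0]:
            raise ValueError("SLC latency mean must be below LLC latency mean")

    def replace(self, **kw) -> "BehaviorParams":
        return dataclasses.replace(self, **kw)


def default_behavior_params(**overrides) -> BehaviorParams:
    return BehaviorParams().replace(**overrides) if overrides else BehaviorParams()


@dataclass
class CohortConfig:
    """One simulated behavioral run: plate of larvae from a het incross."""

    n_larvae: int = 50
    genotype_proportions: dict = field(
        default_factory=lambda: {"wt": 0.25, "het": 0.5, "mut": 0.25})
    params: dict = field(
        default_factory=lambda: {g: BehaviorParams() for g in GENOTYPES})
    treatment: str = "E3"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_larvae < 1:
            raise ValueError("n_larvae must be >= 1")
        tot = sum(self.genotype_proportions.values())
        if not np.isclose(tot, 1.0):
            raise ValueError("genotype proportions must sum to 1")

    def rng(self) -> np.random.Generator:
        if self.seed is None:
            raise ValueError("seed is required for deterministic simulation")
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Latent records behind a simulated cohort (one row per event/bout)."""

    genotypes: pd.DataFrame       # larva_id, well_id, genotype, treatment
    stimulus_table: pd.DataFrame  # one row per simulated stimulus presentation
    bout_table: pd.DataFrame      # one row per spontaneous bout
    params: dict                  # genotype -> BehaviorParams
    config: CohortConfig


# ---------------------------------------------------------------------------
# Latent draws
# ---------------------------------------------------------------------------

def _truncnorm(rng, mean, sd, lo, hi, size) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size), lo, hi)


def _acoustic_base_p(stim: StimulusEvent, bp: BehaviorParams) -> float:
    p = bp.sensitivity_curve[stim.intensity]
    if stim.prepulse is not None:
        p *= 1.0 - bp.ppi_strength
    return p


def _stimulus_probabilities(protocol: Protocol, bp: BehaviorParams):
    """Per-stimulus response probability and latent class pools for one genotype.

    Returns a list of (assay, stim_index, event, p, class_pool) covering every
    LF/DF/ASR stimulus in protocol order.  Habituation decays over the whole
    DF flash series and within the 1 s-ISI acoustic train.
    """
    rows = []
    for assay in ("LF", "DF", "ASR"):
        block = protocol.block(assay)
        df_k = 0
        hab_k = 0
        for idx, ev in enumerate(block.events):
            if ev.kind == "light_flash":
                p = bp.p_respond["light_flash"]
                pool = "react"
            elif ev.kind == "dark_flash":
                df_k += 1
                p = bp.p_respond["dark_flash"] * (1 - bp.habituation_rate) ** (df_k - 1)
                pool = "obend"
            elif ev.kind == "acoustic":
                p = _acoustic_base_p(ev, bp)
                if ev.block_id == "asr_hab":
                    hab_k += 1
                    p *= (1 - bp.habituation_rate) ** (hab_k - 1)
                pool = "startle"
            else:
                continue  # illumination state markers
            rows.append((assay, idx, ev, p, pool))
    return rows


def _draw_stimulus_table(
    config: CohortConfig, protocol: Protocol, genotypes: np.ndarray,
    larva_ids: list[str], rng: np.random.Generator,
) -> pd.DataFrame:
    frames = []
    prob_cache = {g: _stimulus_probabilities(protocol, config.params[g])
                  for g in set(genotypes)}
    for lid, g in zip(larva_ids, genotypes):
        bp = config.params[g]
        rows = prob_cache[g]
        n = len(rows)
        p = np.array([r[3] for r in rows])
        responded = rng.random(n) < p
        # latent response class
        cls = np.array(["none"] * n, dtype=object)
        for i, (assay, idx, ev, _, pool) in enumerate(rows):
            if not responded[i]:
                continue
            if pool == "react":
                cls[i] = "react"
            elif pool == "obend":
                cls[i] = ("obend" if rng.random() < bp.p_obend_given_response
                          else "react")
            else:
                cls[i] = ("slc" if rng.random() < bp.p_slc_given_response
                          else "llc")
        lat = np.full(n, np.nan)
        curv = np.full(n, np.nan)
        dori = np.full(n, np.nan)
        for c in ("slc", "llc", "obend", "react"):
            m = cls == c
            if not m.any():
                continue
            mean, sd, lo, hi = bp.latency_params[c]
            lat[m] = _truncnorm(rng, mean, sd, lo, hi, int(m.sum()))
            cmean, csd, clo, chi = bp.curvature_params[c]
            curv[m] = _truncnorm(rng, cmean, csd, clo, chi, int(m.sum()))
            omean, osd = bp.delta_orientation_params[c]
            dori[m] = np.clip(rng.normal(omean, osd, int(m.sum())), 0.05, np.pi)
        # keep latency inside each assay's record window (minus the pulse)
        for i, (assay, idx, ev, _, pool) in enumerate(rows):
            if responded[i]:
                win = protocol.block(assay).record_window_ms
                dur = RESPONSE_DURATION_MS[cls[i]]
                lat[i] = min(lat[i], max(win - dur - 4.0, 18.0))
        speed = np.full(n, np.nan)
        resp = responded.nonzero()[0]
        speed[resp] = np.clip(
            RESPONSE_SPEED_PX_PER_MS * np.exp(rng.normal(0.0, 0.2, len(resp))),
            0.4, None)
        if not rows:
            continue
        frames.append(pd.DataFrame({
            "larva_id": lid,
            "assay": [r[0] for r in rows],
            "stim_index": [r[1] for r in rows],
            "block_id": [r[2].block_id for r in rows],
            "p_used": p,
            "responded": responded,
            "resp_class": cls,
            "latency_ms": lat,
            "peak_curvature_rad": curv,
            "delta_orientation_rad": dori,
            "move_duration_ms": [RESPONSE_DURATION_MS.get(c, np.nan) for c in cls],
            "speed_px_per_ms": speed,
        }))
    if not frames:
        return None
    return pd.concat(frames, ignore_index=True)


def _draw_bout_table(
    config: CohortConfig, genotypes: np.ndarray, larva_ids: list[str],
    rng: np.random.Generator, phase_duration_ms: float = 480_000.0,
) -> pd.DataFrame:
    """Spontaneous VMR bouts: Poisson counts, non-overlapping onsets."""
    recs = {k: [] for k in ("larva_id", "phase", "start_ms", "duration_ms",
                            "speed_px_per_ms")}
    for lid, g in zip(larva_ids, genotypes):
        bp = config.params[g]
        for phase in ("light", "dark"):
            rate = bp.bout_rate_per_min[phase]
            n = rng.poisson(rate * phase_duration_ms / 60_000.0)
            durs = np.exp(rng.normal(bp.bout_duration_mu, bp.bout_duration_sigma, n))
            speeds = np.clip(
                np.exp(rng.normal(bp.bout_speed_mu, bp.bout_speed_sigma, n)),
                0.02, None)
            starts = _place_bouts(rng, n, durs, phase_duration_ms)
            keep = np.isfinite(starts)
            order = np.argsort(starts[keep])
            recs["larva_id"].extend([lid] * int(keep.sum()))
            recs["phase"].extend([phase] * int(keep.sum()))
            recs["start_ms"].extend(starts[keep][order])
            recs["duration_ms"].extend(durs[keep][order])
            recs["speed_px_per_ms"].extend(speeds[keep][order])
    return pd.DataFrame(recs)


def _place_bouts(rng, n, durations, span_ms) -> np.ndarray:
    """Place n non-overlapping bout onsets uniformly at random in the phase.

    Uses the uniform-spacing construction: the free time left after stacking
    all bouts (plus refractory gaps) is split among them by sorted uniform
    offsets, which is equivalent to uniform placement conditioned on
    non-overlap.  If the phase cannot hold all n bouts, a random subset that
    fits is placed and the rest are dropped (NaN starts).
    """
    durations = np.asarray(durations, dtype=float)
    starts = np.full(n, np.nan)
    if n == 0:
        return starts
    busy = durations + BOUT_REFRACTORY_MS
    keep = np.arange(n)
    if busy.sum() > 0.95 * span_ms:
        order = rng.permutation(n)
        fits = np.cumsum(busy[order]) <= 0.95 * span_ms
        keep = np.sort(order[fits])
        busy = busy[keep]
        if len(keep) == 0:
            return starts
    k = len(keep)
    time_order = rng.permutation(k)
    free = span_ms - busy[time_order].sum()
    offsets = np.sort(rng.uniform(0.0, max(free, 0.0), k))
    cum_busy = np.concatenate([[0.0], np.cumsum(busy[time_order])[:-1]])
    starts[keep[time_order]] = offsets + cum_busy
    return starts


def _draw_genotypes(config: CohortConfig, rng) -> tuple[np.ndarray, list[str]]:
    names = list(config.genotype_proportions)
    probs = np.array([config.genotype_proportions[g] for g in names])
    genotypes = rng.choice(names, size=config.n_larvae, p=probs)
    larva_ids = [f"larva{i:03d}" for i in range(config.n_larvae)]
    return genotypes, larva_ids


def simulate_latent(
    config: CohortConfig, protocol: Protocol | None = None,
) -> GroundTruth:
    """Draw the full latent cohort (genotypes, stimulus responses, bouts)."""
    protocol = protocol or build_default_protocol()
    rng = config.rng()
    genotypes, larva_ids = _draw_genotypes(config, rng)
    stim = _draw_stimulus_table(config, protocol, genotypes, larva_ids, rng)
    if stim is None:
        stim = pd.DataFrame(columns=[
            "larva_id", "assay", "stim_index", "block_id", "p_used",
            "responded", "resp_class", "latency_ms", "peak_curvature_rad",
            "delta_orientation_rad", "move_duration_ms", "speed_px_per_ms"])
    bouts = _draw_bout_table(config, genotypes, larva_ids, rng)
    gdf = pd.DataFrame({
        "larva_id": larva_ids,
        "well_id": [f"w{i // 10}{i % 10}" for i in range(config.n_larvae)],
        "genotype": genotypes,
        "treatment": config.treatment,
    })
    return GroundTruth(genotypes=gdf, stimulus_table=stim, bout_table=bouts,
                       params=dict(config.params), config=config)


# ---------------------------------------------------------------------------
# Fast path: latent draws -> events/bouts -> metric matrix
# ---------------------------------------------------------------------------

def _events_for_larva(
    sub: pd.DataFrame, protocol: Protocol,
    thresholds: KinematicThresholds,
) -> dict[str, list[ResponseEvent]]:
    """Build classified ResponseEvents directly from one larva's latent rows."""
    out: dict[str, list[ResponseEvent]] = {"LF": [], "DF": [], "ASR": []}
    blocks = {a: protocol.block(a) for a in ("LF", "DF", "ASR")}
    frame_ms = {a: 1000.0 / blocks[a].frame_rate_fps for a in blocks}
    for row in sub.itertuples(index=False):
        stim = blocks[row.assay].events[row.stim_index]
        if not stim.recorded:
            continue  # unrecorded stimuli leave no tracked window
        ev = ResponseEvent(stimulus=stim, assay=row.assay)
        if row.responded:
            dur = row.move_duration_ms
            ev.moved = True
            # latency as the tracker would measure it: quantized to the frame
            # grid (movement first registers on the frame after onset)
            fm = frame_ms[row.assay]
            ev.latency_ms = float(np.ceil(row.latency_ms / fm) * fm)
            ev.max_curvature_rad = row.peak_curvature_rad
            ev.delta_orientation_rad = row.delta_orientation_rad
            ev.duration_ms = dur
            ev.distance_px = row.speed_px_per_ms * dur
            ev.displacement_px = 0.9 * ev.distance_px
            n_frames = max(dur / fm, 1.0)
            ev.max_angular_velocity_rad_per_frame = (
                1.5 * row.delta_orientation_rad / n_frames)
        classify(ev, row.assay, thresholds)
        out[row.assay].append(ev)
    return out


def _bouts_for_larva(sub: pd.DataFrame, frame_ms: float = 50.0):
    """Latent bout rows -> per-phase Bout lists (frame grid of the VMR camera)."""
    out: dict[str, list[Bout]] = {"light": [], "dark": []}
    for row in sub.itertuples(index=False):
        start_frame = int(row.start_ms // frame_ms)
        n_frames = max(int(round(row.duration_ms / frame_ms)), 1)
        dist = row.speed_px_per_ms * row.duration_ms
        b = Bout(start_frame, start_frame + n_frames - 1,
                 duration_ms=n_frames * frame_ms,
                 distance_px=dist,
                 displacement_px=0.85 * dist,
                 mean_speed_px_per_ms=dist / (n_frames * frame_ms))
        out[row.phase].append(b)
    return out


def _fast_vmr_metrics(
    bouts_by_phase: dict[str, list[Bout]],
    rng: np.random.Generator,
    phase_duration_ms: float = 480_000.0,
    frame_ms: float = 50.0,
    config: MetricConfig = MetricConfig(),
) -> dict[str, float]:
    """VMR metrics from latent bouts plus stationary-position summaries.

    Well-position statistics are drawn from the uniform-in-well stationary
    distribution (mean radius 2R/3; rim occupancy 1 − rim_fraction²) rather
    than integrated along a path.
    """
    out = {}
    r_mean = 2.0 / 3.0 * config.well_radius_px
    rim_p = 1.0 - config.rim_fraction ** 2
    for phase, bin_prefix in (("light", "light_on"), ("dark", "light_off")):
        bouts = bouts_by_phase.get(phase, [])
        starts = np.array([b.start_frame * frame_ms for b in bouts])
        for bin_name, (t0, t1) in _phase_bins(phase_duration_ms).items():
            in_bin = [b for b, t in zip(bouts, starts) if t0 <= t < t1]
            avg_r = float(np.clip(rng.normal(r_mean, 2.0), 0, config.well_radius_px))
            rim = float(np.clip(rng.normal(rim_p, 0.06), 0.0, 1.0))
            for name, v in vmr_bin_values(in_bin, avg_r, rim).items():
                out[f"vmr_{bin_prefix}_{bin_name}_{name}"] = v
    return out


def simulate_metric_matrix(
    config: CohortConfig,
    protocol: Protocol | None = None,
    thresholds: KinematicThresholds = KinematicThresholds(),
    metric_config: MetricConfig = MetricConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Cohort metric matrix via the event-level path (no pose synthesis).

    Returns ``(metric matrix [larva × 94], genotype table, ground truth)``.
    The latent per-stimulus draws go through the same classification and
    metric computations as tracked data.
    """
    protocol = protocol or build_default_protocol()
    gt = simulate_latent(config, protocol)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 917]).generate_state(1)[0])
    registry = build_metric_registry()
    rows = []
    stim_by_larva = dict(tuple(gt.stimulus_table.groupby("larva_id", sort=False)))
    bout_by_larva = dict(tuple(gt.bout_table.groupby("larva_id", sort=False)))
    empty_stim = gt.stimulus_table.iloc[0:0]
    empty_bout = gt.bout_table.iloc[0:0]
    for lid in gt.genotypes["larva_id"]:
        events = _events_for_larva(
            stim_by_larva.get(lid, empty_stim), protocol, thresholds)
        bouts = _bouts_for_larva(bout_by_larva.get(lid, empty_bout))
        per_assay = {
            "VMR": _fast_vmr_metrics(bouts, rng, config=metric_config),
            "LF": event_summary_metrics(events["LF"], "lf") if events["LF"] else None,
            "DF": df_metrics(events["DF"], metric_config) if events["DF"] else None,
            "ASR": asr_metrics(events["ASR"], metric_config) if events["ASR"] else None,
        }
        rows.append(assemble_vector(per_assay, registry))
    matrix = pd.DataFrame(rows, index=list(gt.genotypes["larva_id"]))
    matrix.index.name = "larva_id"
    return matrix, gt.genotypes, gt


# ---------------------------------------------------------------------------
# Trajectory path
# ---------------------------------------------------------------------------

def _unit(theta):
    return np.array([np.cos(theta), np.sin(theta)])


def _synth_tail(centroid, theta, kappa, side, step_px=5.0) -> np.ndarray:
    """Five tail points behind the centroid with total bend exactly ``kappa``.

    The bend is spread equally over the four inter-segment joints, so the
    tracking-side curvature (sum of unsigned segment angles over
    [centroid, p1..p5]) recovers ``kappa`` exactly.
    """
    pts = np.empty((5, 2))
    pos = np.asarray(centroid, float)
    for i in range(5):
        direction = theta + np.pi + side * kappa / 4.0 * i
        pos = pos + step_px * _unit(direction)
        pts[i] = pos
    return pts


def _raised_cosine(tau, duration):
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(tau / duration, 0, 1)))


def _simulate_window_segment(
    lid: str, well: str, assay: str, stim_index: int, row,
    frame_rate: float, window_ms: float, rng: np.random.Generator,
) -> Trajectory:
    """One stimulus-locked segment: quiet unless the latent response fires."""
    frame_ms = 1000.0 / frame_rate
    n = int(round(window_ms / frame_ms)) + 1
    t = np.arange(n) * frame_ms
    theta0 = rng.uniform(-np.pi, np.pi)
    side = rng.choice([-1.0, 1.0])
    xy = np.zeros((n, 2))
    ori = np.full(n, theta0)
    kappa = np.zeros(n)
    if row is not None and row.responded:
        onset = int(np.ceil(row.latency_ms / frame_ms))
        dur_frames = max(int(round(row.move_duration_ms / frame_ms)), 2)
        end = min(onset + dur_frames, n)
        step = row.speed_px_per_ms * frame_ms
        for i in range(onset, end):
            tau = (i - onset + 1) * frame_ms
            frac = min(tau / row.move_duration_ms, 1.0)
            ori[i:] = theta0 + side * row.delta_orientation_rad * frac
            kappa[i] = row.peak_curvature_rad * _raised_cosine(
                tau - frame_ms / 2.0, row.move_duration_ms)
            xy[i:] = xy[i - 1] + step * _unit(ori[i])
        # put the exact drawn peak on the grid midpoint
        mid = onset + int(round(row.move_duration_ms / 2.0 / frame_ms)) - 1
        if onset <= mid < end:
            kappa[mid] = row.peak_curvature_rad
    tail = np.empty((n, 5, 2))
    for i in range(n):
        tail[i] = _synth_tail(xy[i], ori[i], kappa[i], side)
    return Trajectory(
        larva_id=lid, well_id=well, segment_id=f"{assay}:{stim_index}",
        frame_rate_fps=frame_rate, time_ms=t, xy=xy, tail=tail,
        orientation_rad=ori.copy(), curvature_rad=kappa.copy(),
    )


def _simulate_vmr_segment(
    lid: str, well: str, phase_label: str, bouts: pd.DataFrame,
    rng: np.random.Generator, duration_ms: float = 480_000.0,
    frame_rate: float = 20.0,
) -> Trajectory:
    frame_ms = 1000.0 / frame_rate
    n = int(round(duration_ms / frame_ms))
    t = np.arange(n) * frame_ms
    xy = np.zeros((n, 2))
    r0 = WELL_RADIUS_PX * 0.7 * np.sqrt(rng.random())
    a0 = rng.uniform(-np.pi, np.pi)
    pos = r0 * _unit(a0)
    heading = rng.uniform(-np.pi, np.pi)
    xy[:] = pos
    cursor = 0
    for row in bouts.itertuples(index=False):
        start = int(row.start_ms // frame_ms)
        n_frames = max(int(round(row.duration_ms / frame_ms)), 1)
        if start <= cursor:
            continue
        xy[cursor:start] = pos
        heading += rng.normal(0.0, 0.8)
        step = row.speed_px_per_ms * frame_ms
        for i in range(start, min(start + n_frames, n)):
            nxt = pos + step * _unit(heading)
            if np.linalg.norm(nxt) > 0.93 * WELL_RADIUS_PX:
                heading = float(np.arctan2(-nxt[1], -nxt[0])) + rng.normal(0, 0.3)
                nxt = pos + step * _unit(heading)
            pos = nxt
            xy[i] = pos
            heading += rng.normal(0.0, 0.15)
        cursor = min(start + n_frames, n)
    xy[cursor:] = pos
    return Trajectory(
        larva_id=lid, well_id=well, segment_id=phase_label,
        frame_rate_fps=frame_rate, time_ms=t, xy=xy,
    )


def simulate_cohort(
    config: CohortConfig,
    protocol: Protocol | None = None,
) -> tuple[list[Trajectory], pd.DataFrame, GroundTruth]:
    """Full trajectory-level cohort covering every recorded segment.

    Returns one :class:`Trajectory` per (larva, recorded segment): the two
    VMR phases at 20 fps and one stimulus-locked window per recorded
    LF/DF/ASR stimulus at 500 fps.  Deterministic for a fixed seed.
    """
    protocol = protocol or build_default_protocol()
    gt = simulate_latent(config, protocol)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 7211]).generate_state(1)[0])
    segments: list[Trajectory] = []
    stim_by_larva = dict(tuple(gt.stimulus_table.groupby("larva_id", sort=False)))
    bout_by_larva = dict(tuple(gt.bout_table.groupby("larva_id", sort=False)))
    for lrow in gt.genotypes.itertuples(index=False):
        lid, well = lrow.larva_id, lrow.well_id
        bouts = bout_by_larva.get(lid, gt.bout_table.iloc[0:0])
        segments.append(_simulate_vmr_segment(
            lid, well, "vmr_on", bouts[bouts["phase"] == "light"], rng))
        segments.append(_simulate_vmr_segment(
            lid, well, "vmr_off", bouts[bouts["phase"] == "dark"], rng))
        sub = stim_by_larva.get(lid, gt.stimulus_table.iloc[0:0])
        by_key = {(r.assay, r.stim_index): r for r in sub.itertuples(index=False)}
        for assay in ("LF", "DF", "ASR"):
            block = protocol.block(assay)
            for idx, stim in enumerate(block.events):
                if not stim.recorded or stim.kind in ("light_on", "light_off"):
                    continue
                row = by_key.get((assay, idx))
                segments.append(_simulate_window_segment(
                    lid, well, assay, idx, row, block.frame_rate_fps,
                    block.record_window_ms, rng))
    return segments, gt.genotypes, gt


# ---------------------------------------------------------------------------
# Frame rendering (tracker fixture)
# ---------------------------------------------------------------------------

def render_frames(
    trajectory: Trajectory,
    image_size: tuple[int, int] = (128, 128),
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    origin: tuple[float, float] | None = None,
    background_level: float = 12.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a trajectory as grayscale frames; returns (frames, background).

    Each frame draws a bright larva — a Gaussian head blob plus a tapered
    tail along the posture — on a uniform dark background, with optional
    additive Gaussian noise.  The head blob is offset so that the rendered
    intensity centroid coincides with the pose centroid, which is what the
    tracker estimates.  Poses outside the frame bounds raise ``ValueError``;
    missing poses render background only.
    """
    h, w = image_size
    if origin is None:
        origin = (w / 2.0, h / 2.0)
    origin = np.asarray(origin, float)
    rng = rng or np.random.default_rng(0)
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.empty((trajectory.n_frames, h, w), dtype=np.float64)
    background = np.full((h, w), background_level)
    # Head mass dominates the tail (as in the real animal) so the
    # centroid-preserving head offset below stays within a few pixels.
    head_sigma, head_amp = 2.2, 240.0
    tail_sigma = 0.9
    for i in range(trajectory.n_frames):
        img = background.copy()
        c = trajectory.xy[i]
        if np.all(np.isfinite(c)):
            c_img = c + origin
            tail_img = np.zeros((h, w))
            if trajectory.tail is not None and np.all(np.isfinite(trajectory.tail[i])):
                pts = np.vstack([c, trajectory.tail[i]]) + origin
                if (pts.min() < 4) or (pts[:, 0].max() > w - 4) or (pts[:, 1].max() > h - 4):
                    raise ValueError(f"posture outside frame bounds at frame {i}")
                # densely sampled tapered tail
                for j in range(len(pts) - 1):
                    a, b = pts[j], pts[j + 1]
                    for frac in np.linspace(0, 1, 8, endpoint=False):
                        p = a + frac * (b - a)
                        amp = 26.0 * (1.0 - 0.62 * (j + frac) / (len(pts) - 1))
                        d2 = (xx - p[0]) ** 2 + (yy - p[1]) ** 2
                        tail_img += amp * np.exp(-d2 / (2 * tail_sigma ** 2))
            m_t = tail_img.sum()
            # place the head so the combined intensity centroid sits at c
            probe = head_amp * np.exp(
                -((xx - c_img[0]) ** 2 + (yy - c_img[1]) ** 2) / (2 * head_sigma ** 2))
            m_h = probe.sum()
            if m_t > 0:
                tc = np.array([(tail_img * xx).sum(), (tail_img * yy).sum()]) / m_t
                head_c = c_img + (m_t / m_h) * (c_img - tc)
            else:
                head_c = c_img
            if not (4 <= head_c[0] <= w - 4 and 4 <= head_c[1] <= h - 4):
                raise ValueError(f"posture outside frame bounds at frame {i}")
            d2 = (xx - head_c[0]) ** 2 + (yy - head_c[1]) ** 2
            img = img + tail_img + head_amp * np.exp(-d2 / (2 * head_sigma ** 2))
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[i] = np.clip(img, 0.0, 255.0)
    return frames, background


# ---------------------------------------------------------------------------
# Simulated screens (calibration machinery)
# ---------------------------------------------------------------------------

def simulate_screen(
    seed: int,
    n_larvae: int = 50,
    params: dict | None = None,
    planted: tuple[str, float] | None = None,
    protocol: Protocol | None = None,
    line_id: str = "sim_line",
):
    """One full two-experiment screen on simulated cohorts.

    Two independent cohorts are drawn through the event-level path and run
    through the published procedure (per-experiment t tests, reproducibility
    filter, sibling normalization, pooling, Bonferroni 0.05/94).  With
    ``planted=(metric_id, k_sd)`` the mutant group of each experiment is
    shifted by ``k_sd`` sibling SDs on that metric; otherwise the screen is
    null (all genotypes share parameters).
    """
    from .screen import ContrastSpec, ExperimentData, plant_effect, run_screen

    protocol = protocol or build_default_protocol()
    sub_seeds = np.random.SeedSequence(seed).generate_state(2)
    exps = []
    for i, s in enumerate(sub_seeds):
        config = CohortConfig(n_larvae=n_larvae, seed=int(s) % (2 ** 31))
        if params is not None:
            config.params = dict(params)
        matrix, genotypes, _ = simulate_metric_matrix(config, protocol)
        geno = genotypes.set_index("larva_id")["genotype"]
        if planted is not None:
            matrix = plant_effect(matrix, geno, planted[0], planted[1],
                                  ContrastSpec())
        exps.append(ExperimentData(f"exp{i + 1}", matrix, geno))
    return run_screen(exps[0], exps[1], line_id)


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

def _poisson_binomial_pmf(ps: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) (DP convolution)."""
    pmf = np.zeros(len(ps) + 1)
    pmf[0] = 1.0
    for p in ps:
        pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
        pmf[0] *= (1 - p)
    return pmf


def _expected_one_minus_ratio(ps_late: np.ndarray, ps_base: np.ndarray) -> float:
    """E[1 − (L/n_l)/(B/n_b) | B > 0] for independent Poisson-binomial L, B."""
    pmf_b = _poisson_binomial_pmf(ps_base)
    n_b = len(ps_base)
    p_pos = 1.0 - pmf_b[0]
    if p_pos <= 0:
        return np.nan
    e_inv_bhat = sum(pmf_b[b] * n_b / b for b in range(1, n_b + 1)) / p_pos
    e_lhat = float(np.mean(ps_late))
    return 1.0 - e_lhat * e_inv_bhat


def expected_metric_means(
    bp: BehaviorParams, protocol: Protocol | None = None,
) -> dict[str, float]:
    """Closed-form expectations of the recovery-target metrics for one genotype.

    Ratio metrics (habituation, PPI) account for the per-larva ratio
    estimator by exact enumeration over the baseline count distribution.
    """
    protocol = protocol or build_default_protocol()
    rows = _stimulus_probabilities(protocol, bp)
    p_by_block: dict[str, list[float]] = {}
    for assay, idx, ev, p, pool in rows:
        p_by_block.setdefault(ev.block_id, []).append(p)
    p_slc = bp.p_slc_given_response
    p_ob = bp.p_obend_given_response
    base = np.array(p_by_block["asr_high20"]) * p_slc
    ppi4 = np.array(p_by_block["asr_ppi4"]) * p_slc
    hab_last = np.array(p_by_block["asr_hab"][-10:]) * p_slc
    df1 = np.array(p_by_block["df_block1"]) * p_ob
    df5 = np.array(p_by_block["df_block5"]) * p_ob
    df_recorded = np.concatenate(
        [np.array(p_by_block[f"df_block{b}"]) * p_ob for b in (1, 3, 5)])
    return {
        "asr_freq_slc": float(np.mean(base)),
        "asr_ppi": _expected_one_minus_ratio(ppi4, base),
        "asr_habituation_slc": _expected_one_minus_ratio(hab_last, base),
        "df_freq_obend": float(np.mean(df_recorded)),
        "df_habituation_obend": _expected_one_minus_ratio(df5, df1),
        "vmr_light_on_full_n_bouts": bp.bout_rate_per_min["light"] * 8.0,
        "vmr_light_off_full_n_bouts": bp.bout_rate_per_min["dark"] * 8.0,
    }


def recover_parameters(
    metric_matrix: pd.DataFrame,
    ground_truth: GroundTruth,
    genotype: str = "wt",
) -> pd.DataFrame:
    """Compare cohort metric means against their generating expectations.

    Returns one row per recovery-target metric with the observed mean, the
    closed-form expectation under the generating parameters, the bias, the
    standard error of the observed mean, and whether the bias is within two
    standard errors (coverage indicator).
    """
    bp = ground_truth.params[genotype]
    lids = ground_truth.genotypes.loc[
        ground_truth.genotypes["genotype"] == genotype, "larva_id"]
    sub = metric_matrix.loc[metric_matrix.index.isin(lids)]
    expected = expected_metric_means(bp)
    rows = []
    for mid, exp_val in expected.items():
        vals = sub[mid].dropna()
        est = float(vals.mean()) if len(vals) else np.nan
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        bias = est - exp_val
        rows.append({
            "metric": mid, "estimate": est, "expected": exp_val,
            "bias": bias, "se": se, "n": len(vals),
            "within_2se": bool(abs(bias) <= 2 * se) if np.isfinite(se) else False,
        })
    return pd.DataFrame(rows).set_index("metric")
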