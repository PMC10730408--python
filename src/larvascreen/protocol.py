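"""Stimulus-protocol timeline for the four-assay behavioral paradigm.

The paradigm runs four assay blocks in a fixed order on a 100-well plate of
6 dpf larvae:

* **VMR** (visual motor response): 10 min lights-off (unrecorded), 8 min
  lights-on and 8 min lights-off, recorded continuously at 20 fps.
* **LF** (light flash): 15 whole-field light flashes of 500 ms at 30 s ISI,
  each followed by a 500 ms recording window at 500 fps.
* **DF** (dark flash): after 5 min of lights-on adaptation, five trains of
  14 one-second dark flashes (30 s ISI for the first train, 10 s after);
  trains 1, 3 and 5 are recorded for 1 s post-stimulus at 500 fps.
* **ASR** (acoustic startle): 10 low- and 10 medium-intensity vibrational
  stimuli at 20 s ISI, then 10 repetitions of the five-stimulus pattern
  [PPI1, PPI2, PPI3, PPI4, High] at 20 s ISI, then a habituation train of
  30 high-intensity stimuli at 1 s ISI; 200 ms recorded per stimulus at
  500 fps.  PPI1..PPI4 are high-intensity pulses preceded by a weak
  prepulse (low or medium intensity, 50 or 300 ms lead).

Interstimulus intervals are interpreted onset-to-onset.  Unrecorded events
are kept in the timeline with ``recorded=False`` so that stimulus indices
used by habituation bookkeeping are unambiguous.  Acoustic intensities are
ordinal levels (low/medium/high); the physical stimulus magnitudes are not
part of the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

VMR, LF, DF, ASR = "VMR", "LF", "DF", "ASR"
ASSAYS = (VMR, LF, DF, ASR)

STIMULUS_KINDS = frozenset(
    {"light_on", "light_off", "light_flash", "dark_flash", "acoustic"}
)
INTENSITIES = frozenset({"none", "low", "medium", "high"})
PREPULSE_INTENSITIES = frozenset({"low", "medium"})
PREPULSE_LEADS_MS = frozenset({50.0, 300.0})


class ProtocolError(ValueError):
    """Invalid protocol structure or query."""


@dataclass(frozen=True)
class Prepulse:
    """Weak stimulus preceding an acoustic pulse (sensorimotor gating probe)."""

    intensity: str
    lead_ms: float

    def __post_init__(self) -> None:
        if self.intensity not in PREPULSE_INTENSITIES:
            raise ProtocolError(f"prepulse intensity must be low/medium, got {self.intensity!r}")
        if float(self.lead_ms) not in PREPULSE_LEADS_MS:
            raise ProtocolError(f"prepulse lead must be 50 or 300 ms, got {self.lead_ms!r}")


@dataclass(frozen=True)
class StimulusEvent:
    onset_ms: float
    kind: str
    intensity: str = "none"
    duration_ms: float = 0.0
    recorded: bool = True
    block_id: str = ""
    prepulse: Prepulse | None = None

    def __post_init__(self) -> None:
        if self.onset_ms < 0:
            raise ProtocolError("onset_ms must be >= 0")
        if self.kind not in STIMULUS_KINDS:
            raise ProtocolError(f"unknown stimulus kind {self.kind!r}")
        if self.intensity not in INTENSITIES:
            raise ProtocolError(f"unknown intensity {self.intensity!r}")
        if self.prepulse is not None and self.kind != "acoustic":
            raise ProtocolError("prepulse is only valid on acoustic events")


@dataclass
class AssayBlock:
    """One assay's ordered stimulus timeline.

    ``record_window_ms`` is the per-stimulus recording span for the
    stimulus-locked assays (LF 500, DF 1000, ASR 200); ``None`` for the
    continuously recorded VMR.
    """

    assay: str
    frame_rate_fps: float
    record_window_ms: float | None
    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ProtocolError(f"unknown assay {self.assay!r}")
        if self.frame_rate_fps <= 0:
            raise ProtocolError("frame_rate_fps must be positive")
        onsets = [e.onset_ms for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ProtocolError(f"{self.assay}: event onsets must be strictly increasing")


@dataclass
class Protocol:
    blocks: list[AssayBlock]

    def block(self, assay: str) -> AssayBlock:
        for b in self.blocks:
            if b.assay == assay:
                return b
        raise ProtocolError(f"assay {assay!r} not in protocol")

    @property
    def assays(self) -> list[str]:
        return [b.assay for b in self.blocks]


# ---------------------------------------------------------------------------
# Default paradigm
# ---------------------------------------------------------------------------

MINUTE_MS = 60_000.0

#: VMR phase durations (ms): pre lights-off, lights-on, lights-off.
VMR_PRE_OFF_MS = 10 * MINUTE_MS
VMR_PHASE_MS = 8 * MINUTE_MS


def _train(
    start_ms: float,
    n: int,
    isi_ms: float,
    block_id: str,
    **kw,
) -> list[StimulusEvent]:
    return [
        StimulusEvent(onset_ms=start_ms + i * isi_ms, block_id=block_id, **kw)
        for i in range(n)
    ]


def build_default_protocol() -> Protocol:
    """Build the published two-hour paradigm with its printed stimulus counts."""
    vmr = AssayBlock(
        assay=VMR,
        frame_rate_fps=20.0,
        record_window_ms=None,
        events=[
            StimulusEvent(0.0, "light_off", duration_ms=VMR_PRE_OFF_MS,
                          recorded=False, block_id="vmr_off_pre"),
            StimulusEvent(VMR_PRE_OFF_MS, "light_on", duration_ms=VMR_PHASE_MS,
                          recorded=True, block_id="vmr_on"),
            StimulusEvent(VMR_PRE_OFF_MS + VMR_PHASE_MS, "light_off",
                          duration_ms=VMR_PHASE_MS, recorded=True, block_id="vmr_off"),
        ],
    )

    lf = AssayBlock(
        assay=LF,
        frame_rate_fps=500.0,
        record_window_ms=500.0,
        events=_train(0.0, 15, 30_000.0, "lf", kind="light_flash",
                      duration_ms=500.0, recorded=True),
    )

    # DF: 5 min lights-on adaptation, then 5 trains of 14 flashes.  Train 1 at
    # 30 s ISI, trains 2-5 at 10 s ISI; trains 1, 3, 5 recorded.  Each train's
    # first onset follows the previous flash by that train's own ISI.
    df_events = [
        StimulusEvent(0.0, "light_on", duration_ms=5 * MINUTE_MS,
                      recorded=False, block_id="df_adapt"),
    ]
    t = 5 * MINUTE_MS
    for train_idx in range(1, 6):
        isi = 30_000.0 if train_idx == 1 else 10_000.0
        recorded = train_idx in (1, 3, 5)
        for _ in range(14):
            df_events.append(
                StimulusEvent(t, "dark_flash", duration_ms=1000.0,
                              recorded=recorded, block_id=f"df_block{train_idx}")
            )
            t += isi
    df = AssayBlock(assay=DF, frame_rate_fps=500.0, record_window_ms=1000.0,
                    events=df_events)

    # ASR: low ×10, medium ×10 (20 s ISI); 10 reps of [PPI1..PPI4, High]
    # (20 s ISI throughout); habituation train of 30 high at 1 s ISI.
    asr_events: list[StimulusEvent] = []
    t = 0.0

    def _acoustic(intensity: str, block_id: str, prepulse: Prepulse | None = None):
        nonlocal t
        asr_events.append(
            StimulusEvent(t, "acoustic", intensity=intensity, duration_ms=2.0,
                          recorded=True, block_id=block_id, prepulse=prepulse)
        )

    for _ in range(10):
        _acoustic("low", "asr_low")
        t += 20_000.0
    for _ in range(10):
        _acoustic("medium", "asr_medium")
        t += 20_000.0
    ppi_pattern = [
        ("asr_ppi1", Prepulse("low", 50.0)),
        ("asr_ppi2", Prepulse("low", 300.0)),
        ("asr_ppi3", Prepulse("medium", 50.0)),
        ("asr_ppi4", Prepulse("medium", 300.0)),
        ("asr_high20", None),
    ]
    for _ in range(10):
        for block_id, pp in ppi_pattern:
            _acoustic("high", block_id, pp)
            t += 20_000.0
    for _ in range(30):
        _acoustic("high", "asr_hab")
        t += 1000.0
    asr = AssayBlock(assay=ASR, frame_rate_fps=500.0, record_window_ms=200.0,
                     events=asr_events)

    return Protocol(blocks=[vmr, lf, df, asr])


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def events_of(
    protocol: Protocol,
    assay: str,
    predicate: Callable[[StimulusEvent], bool] | None = None,
    **field_filters,
) -> list[StimulusEvent]:
    """Ordered sub-list of an assay's events matching a predicate.

    Keyword filters compare event fields for equality, e.g.
    ``events_of(p, "ASR", block_id="asr_high20")`` or
    ``events_of(p, "DF", recorded=True)``.
    """
    block = protocol.block(assay)
    out = []
    for e in block.events:
        if predicate is not None and not predicate(e):
            continue
        if any(getattr(e, k) != v for k, v in field_filters.items()):
            continue
        out.append(e)
    return out


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _event_to_dict(e: StimulusEvent) -> dict:
    d = {
        "onset_ms": e.onset_ms,
        "kind": e.kind,
        "intensity": e.intensity,
        "duration_ms": e.duration_ms,
        "recorded": e.recorded,
        "block_id": e.block_id,
    }
    if e.prepulse is not None:
        d["prepulse"] = {"intensity": e.prepulse.intensity, "lead_ms": e.prepulse.lead_ms}
    return d


def _event_from_dict(d: dict) -> StimulusEvent:
    pp = d.get("prepulse")
    return StimulusEvent(
        onset_ms=float(d["onset_ms"]),
        kind=d["kind"],
        intensity=d.get("intensity", "none"),
        duration_ms=float(d.get("duration_ms", 0.0)),
        recorded=bool(d.get("recorded", True)),
        block_id=d.get("block_id", ""),
        prepulse=None if pp is None else Prepulse(pp["intensity"], float(pp["lead_ms"])),
    )


def protocol_to_dict(protocol: Protocol) -> dict:
    return {
        "blocks": [
            {
                "assay": b.assay,
                "frame_rate_fps": b.frame_rate_fps,
                "record_window_ms": b.record_window_ms,
                "events": [_event_to_dict(e) for e in b.events],
            }
            for b in protocol.blocks
        ]
    }


def protocol_from_dict(d: dict) -> Protocol:
    return Protocol(
        blocks=[
            AssayBlock(
                assay=b["assay"],
                frame_rate_fps=float(b["frame_rate_fps"]),
                record_window_ms=(None if b.get("record_window_ms") is None
                                  else float(b["record_window_ms"])),
                events=[_event_from_dict(e) for e in b["events"]],
            )
            for b in d["blocks"]
        ]
    )


def save_protocol(protocol: Protocol, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(protocol_to_dict(protocol), fh, indent=2)


def load_protocol(path) -> Protocol:
    with open(path, encoding="utf-8") as fh:
        return protocol_from_dict(json.load(fh))
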