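"""The 94-metric registry and the per-assay metric computations."""

import numpy as np
import pandas as pd
import pytest

from larvascreen.kinematics import Bout, ResponseEvent
from larvascreen.metrics import (
    MetricConfig,
    asr_metrics,
    assemble_vector,
    build_metric_registry,
    df_metrics,
    event_summary_metrics,
    vmr_bin_values,
    vmr_metrics,
)
from larvascreen.protocol import StimulusEvent
from larvascreen.tracking import Trajectory


class TestRegistry:
    def test_cardinalities(self):
        reg = build_metric_registry()
        assert len(reg) == 94
        counts = pd.Series([m.assay for m in reg]).value_counts()
        assert counts["VMR"] == 60
        assert counts["LF"] == 9
        assert counts["DF"] == 11
        assert counts["ASR"] == 14

    def test_vmr_partition_is_ten_by_six(self):
        reg = [m for m in build_metric_registry() if m.assay == "VMR"]
        bins = {m.bin for m in reg}
        assert len(bins) == 6
        for b in bins:
            assert sum(m.bin == b for m in reg) == 10


def _stim(block_id="df_block1"):
    return StimulusEvent(0.0, "dark_flash", recorded=True, block_id=block_id)


def _resp(label, moved=True, latency=40.0, curv=2.0, block_id="df_block1",
          stim=None, **kw):
    ev = ResponseEvent(stimulus=stim or _stim(block_id), assay="DF",
                       moved=moved, latency_ms=latency if moved else np.nan,
                       max_curvature_rad=curv if moved else np.nan)
    ev.label = label
    for k, v in kw.items():
        setattr(ev, k, v)
    return ev


class TestEventSummary:
    def test_response_frequency(self):
        events = [_resp("react") for _ in range(12)] + \
            [_resp("none", moved=False) for _ in range(3)]
        out = event_summary_metrics(events, "lf")
        assert out["lf_freq_react"] == pytest.approx(0.8)
        assert out["lf_freq_no_movement"] == pytest.approx(0.2)

    def test_no_responses_all_means_missing(self):
        events = [_resp("none", moved=False) for _ in range(5)]
        out = event_summary_metrics(events, "lf")
        assert out["lf_freq_no_movement"] == 1.0
        assert out["lf_freq_react"] == 0.0
        assert np.isnan(out["lf_avg_latency_ms"])
        assert np.isnan(out["lf_avg_max_bend_rad"])

    def test_constant_latency(self):
        events = [_resp("react", latency=30.0) for _ in range(4)]
        assert event_summary_metrics(events, "lf")["lf_avg_latency_ms"] == 30.0

    def test_too_early_excluded_from_feature_means(self):
        events = [_resp("react", latency=40.0),
                  _resp("too_early", latency=8.0)]
        out = event_summary_metrics(events, "lf")
        assert out["lf_avg_latency_ms"] == 40.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            event_summary_metrics([], "lf")


class TestDF:
    def _events(self, first_obend, last_obend):
        ev = []
        for block, n_ob in (("df_block1", first_obend), ("df_block3", 7),
                            ("df_block5", last_obend)):
            for i in range(14):
                label = "obend" if i < n_ob else "none"
                ev.append(_resp(label, moved=i < n_ob, block_id=block))
        return ev

    @pytest.mark.parametrize("first,last,expected", [
        (12, 6, 0.5),    # frequencies 6/7 of baseline lost -> index 0.5
        (14, 0, 1.0),    # complete habituation
        (10, 10, 0.0),   # no decay
    ])
    def test_habituation_index(self, first, last, expected):
        out = df_metrics(self._events(first, last))
        assert out["df_habituation_obend"] == pytest.approx(expected)

    def test_habituation_undefined_without_initial_obends(self):
        out = df_metrics(self._events(0, 0))
        assert np.isnan(out["df_habituation_obend"])

    def test_obend_frequency_over_all_recorded(self):
        out = df_metrics(self._events(14, 0))
        assert out["df_freq_obend"] == pytest.approx((14 + 7 + 0) / 42)

    def test_literal_formula_mode(self):
        cfg = MetricConfig(literal_ratio_formulas=True)
        out = df_metrics(self._events(7, 7), cfg)
        # (1 - 0.5) / 0.5 under the literal printed reading
        assert out["df_habituation_obend"] == pytest.approx(1.0)


def _asr_events(base_slc=8, ppi4_slc=2, hab_last_slc=0, low_slc=0, med_slc=5):
    ev = []

    def block(block_id, n, n_slc, intensity="high"):
        for i in range(n):
            stim = StimulusEvent(float(i), "acoustic", intensity=intensity,
                                 block_id=block_id)
            label = "slc" if i < n_slc else "none"
            ev.append(_resp(label, moved=i < n_slc, latency=10.0, curv=1.2,
                            stim=stim))

    block("asr_low", 10, low_slc, "low")
    block("asr_medium", 10, med_slc, "medium")
    block("asr_ppi4", 10, ppi4_slc)
    block("asr_high20", 10, base_slc)
    block("asr_hab", 30, 20 + hab_last_slc)  # first 20 respond, last 10 partial
    return ev


class TestASR:
    def test_sensitivity_index_trapezoid(self):
        out = asr_metrics(_asr_events(base_slc=10, low_slc=0, med_slc=5))
        # SLC freqs 0, 0.5, 1.0 at ordinal intensities 1, 2, 3
        assert out["asr_sensitivity_index_au"] == pytest.approx(1.0)

    def test_sensitivity_monotone_in_any_frequency(self):
        base = asr_metrics(_asr_events())["asr_sensitivity_index_au"]
        for kw in ({"low_slc": 3}, {"med_slc": 8}, {"base_slc": 10}):
            higher = asr_metrics(_asr_events(**kw))["asr_sensitivity_index_au"]
            assert higher >= base

    def test_ppi_index(self):
        out = asr_metrics(_asr_events(base_slc=8, ppi4_slc=2))
        assert out["asr_ppi"] == pytest.approx(0.75)

    def test_habituation_no_decay_is_zero(self):
        out = asr_metrics(_asr_events(base_slc=8, hab_last_slc=8))
        assert out["asr_habituation_slc"] == pytest.approx(0.0)

    def test_indices_undefined_with_zero_baseline(self):
        out = asr_metrics(_asr_events(base_slc=0))
        assert np.isnan(out["asr_ppi"])
        assert np.isnan(out["asr_habituation_slc"])

    def test_slc_llc_frequency_over_baseline_block(self):
        out = asr_metrics(_asr_events(base_slc=8))
        assert out["asr_freq_slc"] == pytest.approx(0.8)
        assert out["asr_freq_llc"] == 0.0


class TestVMRBins:
    def test_zero_bouts(self):
        out = vmr_bin_values([], 10.0, 0.2)
        assert out["n_bouts"] == 0
        assert out["total_distance_px"] == 0
        assert out["total_time_moved_ms"] == 0
        assert np.isnan(out["avg_distance_per_bout_px"])
        assert np.isnan(out["avg_speed_px_per_ms"])

    def test_two_bout_arithmetic(self):
        bouts = [Bout(0, 1, duration_ms=100, distance_px=10,
                      displacement_px=8, mean_speed_px_per_ms=0.1),
                 Bout(5, 8, duration_ms=200, distance_px=20,
                      displacement_px=15, mean_speed_px_per_ms=0.1)]
        out = vmr_bin_values(bouts, 12.0, 0.3)
        assert out["total_distance_px"] == 30
        assert out["avg_distance_per_bout_px"] == 15
        assert out["avg_displacement_per_bout_px"] == 11.5
        assert out["total_time_moved_ms"] == 300
        assert out["avg_speed_px_per_ms"] == pytest.approx(0.1)

    def test_pinned_at_center(self):
        frame_ms = 50.0
        n = int(480_000 / frame_ms)
        t = np.arange(n) * frame_ms
        still = Trajectory("l", "w", "vmr_on", 20.0, t, np.zeros((n, 2)))
        out = vmr_metrics(still, Trajectory("l", "w", "vmr_off", 20.0, t,
                                            np.zeros((n, 2))))
        assert out["vmr_light_on_full_avg_dist_from_center_px"] == 0.0
        assert out["vmr_light_on_full_frac_time_outer_rim"] == 0.0
        assert out["vmr_light_off_full_n_bouts"] == 0.0
        assert len(out) == 60

    def test_bout_counts_in_bin_of_start(self):
        frame_ms = 50.0
        n = int(480_000 / frame_ms)
        t = np.arange(n) * frame_ms
        xy = np.zeros((n, 2))
        # one bout starting in the last frame of the first minute, running over
        start = int(59_950 / frame_ms)
        for i in range(start, start + 10):
            xy[i:] = xy[i - 1] + [2.0, 0.0]
        seg = Trajectory("l", "w", "vmr_on", 20.0, t, xy)
        quiet = Trajectory("l", "w", "vmr_off", 20.0, t, np.zeros((n, 2)))
        out = vmr_metrics(seg, quiet)
        assert out["vmr_light_on_first_min_n_bouts"] == 1.0
        assert out["vmr_light_on_last_min_n_bouts"] == 0.0
        assert out["vmr_light_on_full_n_bouts"] == 1.0


class TestAssemble:
    def test_complete_run_has_94_entries(self):
        vec = assemble_vector({
            "VMR": {m.id: 1.0 for m in build_metric_registry()
                    if m.assay == "VMR"},
            "LF": {m.id: 1.0 for m in build_metric_registry()
                   if m.assay == "LF"},
            "DF": {m.id: 1.0 for m in build_metric_registry()
                   if m.assay == "DF"},
            "ASR": {m.id: 1.0 for m in build_metric_registry()
                    if m.assay == "ASR"},
        })
        assert len(vec) == 94
        assert vec.notna().all()

    def test_partial_run_fills_missing(self):
        vmr_only = {m.id: 1.0 for m in build_metric_registry()
                    if m.assay == "VMR"}
        vec = assemble_vector({"VMR": vmr_only})
        assert len(vec) == 94
        assert vec.notna().sum() == 60
        assert vec.isna().sum() == 34

    def test_empty_run_all_missing(self):
        vec = assemble_vector({})
        assert len(vec) == 94
        assert vec.isna().all()

    def test_unknown_metric_rejected(self):
        with pytest.raises(KeyError):
            assemble_vector({"LF": {"lf_not_a_metric": 1.0}})

    def test_frequencies_within_unit_interval(self):
        out = asr_metrics(_asr_events())
        for k, v in out.items():
            if "freq" in k:
                assert 0.0 <= v <= 1.0
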