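"""Single-channel detection rules and cross-channel agreement."""

import numpy as np
import pytest

from conftest import make_event, make_trace
from samc.detect import (classify_event, detect_channel, raster_to_intervals,
                         samc_combine, to_raster)

FS = 100.0


def rect_trace(spans, n=2000, level=0.9, fs=FS, **kw):
    """norm_power that is `level` inside each (start_s, stop_s) span, 0 outside."""
    norm = np.zeros(n)
    for a, b in spans:
        norm[int(a * fs):int(b * fs)] = level
    return make_trace(norm, fs=fs, **kw)


def band_for(trace, amp=15.0):
    """11–16 Hz surrogate whose p2p is 2×amp wherever the trace is active."""
    t = np.arange(len(trace.norm_power)) / trace.fs
    return amp * np.sin(2 * np.pi * 13.0 * t)


class TestDetectChannel:
    def test_subthreshold_trace_yields_nothing(self):
        tr = rect_trace([], level=0.0)
        assert detect_channel(tr, band_for(tr)) == []

    @pytest.mark.parametrize("dur,expected", [(0.45, 1), (0.30, 0)])
    def test_minimum_duration_rule(self, dur, expected):
        tr = rect_trace([(5.0, 5.0 + dur)])
        evs = detect_channel(tr, band_for(tr))
        assert len(evs) == expected

    def test_maximum_duration_rule(self):
        tr = rect_trace([(5.0, 7.6)])  # 2.6 s exceeds the 2-s cap
        assert detect_channel(tr, band_for(tr)) == []

    @pytest.mark.parametrize("gap,n_events", [(0.08, 1), (0.15, 0)])
    def test_fragment_merge_rule(self, gap, n_events):
        tr = rect_trace([(5.0, 5.3), (5.3 + gap, 5.6 + gap)])
        evs = detect_channel(tr, band_for(tr))
        assert len(evs) == n_events
        if n_events:
            assert evs[0].duration_s == pytest.approx(0.6 + gap, abs=0.02)

    def test_amplitude_criterion(self):
        tr = rect_trace([(5.0, 6.0)])
        assert len(detect_channel(tr, band_for(tr, amp=10.0))) == 1   # p2p 20 ≥ 13
        assert len(detect_channel(tr, band_for(tr, amp=5.0))) == 0    # p2p 10 < 13
        assert len(detect_channel(tr, band_for(tr, amp=5.0), min_p2p_uv=0.0)) == 1

    def test_event_fields(self):
        tr = rect_trace([(5.0, 6.0)], level=0.8, peak_freq=12.0, channel="Cz")
        ev = detect_channel(tr, band_for(tr))[0]
        assert ev.channels == frozenset({"Cz"})
        assert ev.peak_norm_power == pytest.approx(0.8)
        assert ev.peak_freq_hz == 12.0
        assert ev.cls == "slow"
        assert ev.area == pytest.approx(0.8 * 1.0, abs=0.02)  # level × duration

    def test_masked_candidate_suppressed(self):
        keep = np.ones(2000, dtype=bool)
        keep[int(5.5 * FS):int(5.7 * FS)] = False
        tr = rect_trace([(5.0, 6.0)], keep=keep)
        assert detect_channel(tr, band_for(tr)) == []

    def test_boundary_extension_spans_the_power_peak(self):
        """A triangular peak crossing 0.5 only briefly is measured over its
        full extent above the boundary level (0.4 here)."""
        fs = FS
        n = 2000
        norm = np.zeros(n)
        center = int(10.0 * fs)
        half = int(0.6 * fs)      # triangle base half-width 0.6 s, peak 0.7
        ramp = np.linspace(0.0, 0.7, half + 1)
        norm[center - half:center + 1] = ramp
        norm[center:center + half + 1] = ramp[::-1]
        tr = make_trace(norm, fs=fs)
        evs = detect_channel(tr, band_for(tr))
        # bare suprathreshold run: 1.2 × (1 − 0.5/0.7) ≈ 0.34 s < 0.4 → lost;
        # extended to the 0.4 boundary: 1.2 × (1 − 0.4/0.7) ≈ 0.51 s → kept
        assert len(evs) == 1
        assert evs[0].duration_s == pytest.approx(0.51, abs=0.05)

    def test_threshold_monotonicity(self):
        """Lowering the threshold never loses an isolated unimodal peak."""
        rng = np.random.default_rng(0)
        n = 6000
        norm = np.zeros(n)
        peaks = [0.45, 0.55, 0.65, 0.75, 0.85, 0.95]
        for i, pk in enumerate(peaks):
            c = int((5 + 8 * i) * FS)
            w = int(0.5 * FS)
            norm[c - w:c + w] += pk * np.hanning(2 * w)
        tr = make_trace(norm, fs=FS)
        band = band_for(tr)
        counts = [len(detect_channel(tr, band, threshold=th)) for th in (0.6, 0.5, 0.4)]
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]


class TestClassify:
    @pytest.mark.parametrize("freq,cls", [(11.5, "slow"), (14.0, "fast"), (13.0, "fast")])
    def test_boundary(self, freq, cls):
        assert classify_event(freq) == cls


class TestRaster:
    def test_empty_events_all_false(self):
        r = to_raster({"C3": [], "C4": []}, 1000, FS)
        assert not r.mask.any()

    def test_span_sample_count(self):
        r = to_raster({"C3": [make_event(1.0, 2.0)]}, 1000, FS)
        assert r.mask[0].sum() == 100

    def test_round_trip(self):
        events = {"C3": [make_event(1.0, 2.0), make_event(4.5, 5.2)],
                  "C4": [make_event(3.0, 3.8)]}
        r = to_raster(events, 1000, FS)
        ivs = raster_to_intervals(r)
        r2 = to_raster({ch: [make_event(a, b) for a, b in ivs[ch]] for ch in ivs}, 1000, FS)
        np.testing.assert_array_equal(r.mask, r2.mask)

    def test_out_of_range_event_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            to_raster({"C3": [make_event(9.5, 10.5)]}, 1000, FS)


class TestSAMC:
    def test_twenty_percent_overlap_rejected(self):
        evs = {"c1": [make_event(1.0, 2.0, ("c1",))],
               "c2": [make_event(1.8, 2.8, ("c2",))]}
        assert samc_combine(evs) == []

    def test_thirty_percent_overlap_confirmed_and_merged(self):
        evs = {"c1": [make_event(1.0, 2.0, ("c1",), peak=0.9)],
               "c2": [make_event(1.7, 2.7, ("c2",), peak=0.7)]}
        out = samc_combine(evs)
        assert len(out) == 1
        ev = out[0]
        assert ev.onset_s == 1.0 and ev.offset_s == 2.7
        assert ev.channels == frozenset({"c1", "c2"})
        assert ev.peak_norm_power == 0.9  # strongest contributor

    def test_identical_event_on_all_channels(self):
        evs = {c: [make_event(10.0, 11.0, (c,))] for c in ("c1", "c2", "c3")}
        out = samc_combine(evs)
        assert len(out) == 1
        assert out[0].channels == frozenset({"c1", "c2", "c3"})

    def test_exact_quarter_overlap_counts(self):
        evs = {"c1": [make_event(1.0, 2.0, ("c1",))],
               "c2": [make_event(1.75, 2.75, ("c2",))]}
        assert len(samc_combine(evs)) == 1  # 0.25 s = exactly 25%

    def test_three_channel_requirement(self):
        evs = {"c1": [make_event(1.0, 2.0, ("c1",))],
               "c2": [make_event(1.0, 2.0, ("c2",))],
               "c3": []}
        assert samc_combine(evs, min_channels=2) != []
        assert samc_combine(evs, min_channels=3) == []

    def test_too_few_channels_is_config_error(self):
        with pytest.raises(ValueError, match="min_channels"):
            samc_combine({"c1": []}, min_channels=2)

    def test_idempotent_on_own_output(self):
        evs = {"c1": [make_event(1.0, 2.0, ("c1",)), make_event(8.0, 9.0, ("c1",))],
               "c2": [make_event(1.5, 2.5, ("c2",)), make_event(8.2, 9.2, ("c2",))]}
        out1 = samc_combine(evs)
        back = {"c1": [], "c2": []}
        for ev in out1:
            for ch in ev.channels:
                back[ch].append(make_event(ev.onset_s, ev.offset_s, (ch,),
                                           peak=ev.peak_norm_power, freq=ev.peak_freq_hz))
        out2 = samc_combine(back)
        assert [(e.onset_s, e.offset_s, e.channels) for e in out2] == \
               [(e.onset_s, e.offset_s, e.channels) for e in out1]

    def test_union_interval_property(self):
        """Every merged interval is the union of its contributors."""
        rng = np.random.default_rng(1)
        evs = {}
        for c in ("c1", "c2", "c3"):
            lst = []
            t = 2.0
            for _ in range(10):
                t += rng.uniform(2.0, 4.0)
                lst.append(make_event(round(t, 2), round(t + rng.uniform(0.5, 1.5), 2), (c,)))
            evs[c] = lst
        singles = [e for lst in evs.values() for e in lst]
        for ev in samc_combine(evs):
            contrib = [s for s in singles if s.overlap_s(ev) > 0 and s.channels <= ev.channels]
            assert ev.onset_s == min(c.onset_s for c in contrib)
            assert ev.offset_s == max(c.offset_s for c in contrib)
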