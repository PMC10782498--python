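"""Event matching and the performance-metric suite."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from samc.io_edf import Annotation, AnnotationSet
from samc.metrics import (ConfusionCounts, agreement_rate, ccc, f_score,
                          match_events, pad_undurated, ppv, score_events,
                          sensitivity, truncate, union_experts)


class TestPadUndurated:
    def test_mark_becomes_1p6s_window(self):
        refs = AnnotationSet([Annotation(100.0, 0.0)])
        out = pad_undurated(refs)
        ev = out.events[0]
        assert ev.onset_s == pytest.approx(99.6)
        assert ev.duration_s == pytest.approx(1.6)

    def test_durated_event_untouched(self):
        refs = AnnotationSet([Annotation(50.0, 1.0)])
        out = pad_undurated(refs)
        assert out.events[0].onset_s == 50.0 and out.events[0].duration_s == 1.0

    def test_early_mark_clamped_with_warning(self):
        refs = AnnotationSet([Annotation(0.1, 0.0)])
        with pytest.warns(UserWarning, match="clamped"):
            out = pad_undurated(refs)
        ev = out.events[0]
        assert ev.onset_s == 0.0
        assert ev.offset_s == pytest.approx(1.3)


class TestUnionExperts:
    def _set(self, spans, scorer):
        return AnnotationSet([Annotation(a, b - a, scorer=scorer) for a, b in spans])

    def test_disjoint_sets_concatenate(self):
        u = union_experts(self._set([(1, 2), (5, 6), (9, 10)], "e1"),
                          self._set([(20, 21), (30, 31)], "e2"))
        assert len(u) == 5

    def test_identical_sets_collapse(self):
        spans = [(1, 2), (5, 6.5), (9, 10), (12, 13)]
        u = union_experts(self._set(spans, "e1"), self._set(spans, "e2"))
        assert len(u) == 4

    def test_small_overlap_kept_separate(self):
        u = union_experts(self._set([(10.0, 11.0)], "e1"),
                          self._set([(10.9, 11.9)], "e2"))
        assert len(u) == 2  # 0.1-s overlap < 0.25 s

    def test_collapsed_pair_spans_union(self):
        u = union_experts(self._set([(10.0, 11.0)], "e1"),
                          self._set([(10.5, 11.8)], "e2"))
        assert len(u) == 1
        assert (u.events[0].onset_s, u.events[0].offset_s) == (10.0, 11.8)


class TestMatchEvents:
    def test_perfect_agreement(self):
        spans = [(1.0, 2.0), (5.0, 6.0), (9.0, 9.5)]
        c = match_events(spans, spans)
        assert (c.tp, c.fp, c.fn) == (3, 0, 0)

    def test_overlap_below_quarter_second(self):
        c = match_events([(10.8, 11.8)], [(10.0, 11.0)])
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_one_to_one_assignment(self):
        c = match_events([(10.0, 11.0)], [(10.0, 10.6), (10.5, 11.2)])
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_largest_overlap_wins(self):
        pairs = match_events([(10.0, 11.0)], [(9.8, 10.4), (10.3, 11.0)], return_pairs=True)
        assert pairs == [(0, 1)]

    def test_counts_partition_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ref = sorted(rng.uniform(0, 100, size=rng.integers(1, 15)))
            pred = sorted(rng.uniform(0, 100, size=rng.integers(1, 15)))
            refs = [(r, r + rng.uniform(0.3, 2.0)) for r in ref]
            preds = [(p, p + rng.uniform(0.3, 2.0)) for p in pred]
            c = match_events(refs, preds)
            assert c.tp + c.fn == len(refs)
            assert c.tp + c.fp == len(preds)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        refs = [(float(r), float(r) + 1.0) for r in rng.uniform(0, 100, 10)]
        preds = [(float(p), float(p) + 1.0) for p in rng.uniform(0, 100, 12)]
        c1 = match_events(refs, preds)
        rng.shuffle(refs), rng.shuffle(preds)
        c2 = match_events(refs, preds)
        assert (c1.tp, c1.fp, c1.fn) == (c2.tp, c2.fp, c2.fn)

    def test_greedy_matches_brute_force_on_small_sets(self):
        """Brute-force maximal one-to-one assignment oracle: for every
        random instance the greedy TP count equals the maximum possible."""
        def max_matching(refs, preds, i=0, used=frozenset()):
            if i == len(refs):
                return 0
            best = max_matching(refs, preds, i + 1, used)  # leave ref i unmatched
            for j, p in enumerate(preds):
                if j in used:
                    continue
                if min(refs[i][1], p[1]) - max(refs[i][0], p[0]) >= 0.25:
                    best = max(best, 1 + max_matching(refs, preds, i + 1, used | {j}))
            return best

        rng = np.random.default_rng(2)
        for _ in range(30):
            refs = [(float(r), float(r + rng.uniform(0.5, 1.5)))
                    for r in np.sort(rng.uniform(0, 20, rng.integers(1, 5)))]
            preds = [(float(p), float(p + rng.uniform(0.5, 1.5)))
                     for p in np.sort(rng.uniform(0, 20, rng.integers(1, 5)))]
            assert match_events(refs, preds).tp == max_matching(refs, preds)


class TestMetricFormulas:
    # (tp, fn, fp) confusion matrices as printed for the three databases,
    # with every derived value the corresponding table reports.
    CASES = [
        ("nap", 3208, 308, 665, 0.91, 0.82, 0.86, 91.0),
        ("ss2mass", 15325, 505, 1191, 0.96, 0.92, 0.94, 96.0),
        ("dreams", 538, 10, 51, 0.98, 0.91, 0.94, 98.0),
    ]

    @pytest.mark.parametrize("name,tp,fn,fp,sens,p,f,ar", CASES)
    def test_printed_confusion_matrices(self, name, tp, fn, fp, sens, p, f, ar):
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn)
        assert truncate(sensitivity(c)) == sens
        assert truncate(ppv(c)) == p
        assert truncate(f_score(c)) == f
        assert float(int(agreement_rate(tp, tp + fn))) == ar

    def test_truncation_not_rounding(self):
        assert truncate(0.9681) == 0.96   # rounding would give 0.97
        assert truncate(0.8283) == 0.82

    def test_degenerate_denominators(self):
        with pytest.raises(ZeroDivisionError):
            sensitivity(ConfusionCounts(0, 5, 0))
        with pytest.raises(ZeroDivisionError):
            ppv(ConfusionCounts(0, 0, 5))
        with pytest.raises(ZeroDivisionError):
            agreement_rate(0, 0)
        assert sensitivity(ConfusionCounts(5, 0, 0)) == 1.0
        assert ppv(ConfusionCounts(0, 7, 3)) == 0.0


class TestCCC:
    def test_identity(self):
        x = [1.0, 2.0, 5.0, 7.0]
        assert ccc(x, x) == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert ccc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_shift_example(self):
        # x=(1,2,3), y=x+1: ρ=1, σ²=2/3, ρc = 2σ²/(1+2σ²) = 4/7
        assert ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7, abs=1e-12)

    def test_symmetry_and_attenuation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(10, 3, 25)
            y = 0.5 * x + rng.normal(0, 2, 25)
            assert ccc(x, y) == pytest.approx(ccc(y, x), abs=1e-12)
            rho = np.corrcoef(x, y)[0, 1]
            assert abs(ccc(x, y)) <= abs(rho) + 1e-12

    def test_literal_denominator_variant_differs(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        assert ccc(x, y, literal_denominator=True) != pytest.approx(ccc(x, y))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ccc([1, 1, 1], [1, 2, 3])


class TestScoreEvents:
    def test_report_consistency(self):
        ref = [(10.0, 11.0), (20.0, 21.0), (30.0, 31.0)]
        pred = [(10.1, 11.1), (25.0, 26.0)]
        rep = score_events(pred, ref)
        assert (rep.counts.tp, rep.counts.fp, rep.counts.fn) == (1, 1, 2)
        assert rep.sensitivity == pytest.approx(1 / 3)
        assert rep.ppv == pytest.approx(1 / 2)
        assert rep.ar_percent == pytest.approx(100 / 3)
        assert rep.truncated["sensitivity"] == 0.33


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1000, allow_nan=False), min_size=1, max_size=30))
def test_truncate_never_exceeds_value(values):
    for v in values:
        t = truncate(v)
        assert t <= v and v - t < 0.01
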