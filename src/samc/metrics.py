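"""Event-level detector evaluation.

Matching uses the field's 0.25-s overlap rule: a detected event counts as
a true positive when it overlaps a reference (expert) event by at least
0.25 s, one-to-one.  True negatives are never computed — almost all of a
night's EEG is non-spindle, so specificity/accuracy are meaningless at
event level — and the metric set is therefore sensitivity, positive
predictive value (PPV), the F-measure, the agreement rate (AR, %), and
Lin's concordance correlation coefficient (CCC) between scorers' counts:

    sensitivity = TP / (TP + FN)
    PPV         = TP / (TP + FP)
    F           = 2·TP / (2·TP + FN + FP)
    AR (%)      = 100 · matched / reference
    CCC         = 2ρ σx σy / ((μx − μy)² + σx² + σy²)

Reported table values are floored (truncated) to two decimals; the raw
doubles are always retained alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_edf import Annotation, AnnotationSet

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "pad_undurated",
    "union_experts",
    "match_events",
    "sensitivity",
    "ppv",
    "f_score",
    "agreement_rate",
    "ccc",
    "truncate",
    "score_events",
]


def truncate(value: float, decimals: int = 2) -> float:
    """Floor toward zero at *decimals* places (0.9681 → 0.96)."""
    factor = 10 ** decimals
    return math.trunc(value * factor) / factor


@dataclass(frozen=True)
class ConfusionCounts:
    """Event-level TP/FP/FN; TN is undefined and never computed."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_ref(self) -> int:
        return self.tp + self.fn

    @property
    def n_pred(self) -> int:
        return self.tp + self.fp


@dataclass
class MetricReport:
    """Raw metric values plus their two-decimal truncations."""

    counts: ConfusionCounts
    sensitivity: float
    ppv: float
    f_score: float
    ar_percent: float
    ccc: float | None = None

    @property
    def truncated(self) -> dict[str, float]:
        out = {
            "sensitivity": truncate(self.sensitivity),
            "ppv": truncate(self.ppv),
            "f_score": truncate(self.f_score),
            "ar_percent": float(math.trunc(self.ar_percent)),
        }
        if self.ccc is not None:
            out["ccc"] = truncate(self.ccc)
        return out

    def as_dict(self) -> dict:
        d = {
            "tp": self.counts.tp, "fp": self.counts.fp, "fn": self.counts.fn,
            "sensitivity": self.sensitivity, "ppv": self.ppv,
            "f_score": self.f_score, "ar_percent": self.ar_percent,
        }
        if self.ccc is not None:
            d["ccc"] = self.ccc
        d["truncated"] = self.truncated
        return d


# ---------------------------------------------------------------------------
# Reference preparation
# ---------------------------------------------------------------------------

def pad_undurated(refs: AnnotationSet, pre_s: float = 0.4, post_s: float = 1.2) -> AnnotationSet:
    """Expand zero-duration marks to a fixed 1.6-s window.

    Undurated expert marks become ``[onset − pre_s, onset + post_s)``
    (0.4 s before the mark, 1.2 s after it, total 1.6 s by default).
    Events with a positive duration pass through untouched; a padded onset
    that would go negative is clamped to 0 with a warning.
    """
    out = []
    for ev in refs.events:
        if ev.duration_s > 0:
            out.append(ev)
            continue
        onset = ev.onset_s - pre_s
        offset = ev.onset_s + post_s
        if onset < 0:
            warnings.warn(f"padded onset {onset:.3f} s clamped to 0 for mark at {ev.onset_s} s")
            onset = 0.0
        out.append(Annotation(onset_s=onset, duration_s=offset - onset,
                              label=ev.label, scorer=ev.scorer, channel=ev.channel))
    return AnnotationSet(sorted(out, key=lambda e: (e.onset_s, e.duration_s)), refs.source)


def _interval_overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def union_experts(a: AnnotationSet, b: AnnotationSet, min_overlap_s: float = 0.25) -> AnnotationSet:
    """Combine two scorers' (durated) event sets into one reference.

    Pairs of events from the two scorers overlapping by at least
    *min_overlap_s* collapse into a single event spanning their union;
    everything else is kept as scored.  The result therefore has
    ``|a| + |b| − (collapsed pairs)`` events.
    """
    evs_a = sorted(a.events, key=lambda e: (e.onset_s, e.duration_s))
    evs_b = sorted(b.events, key=lambda e: (e.onset_s, e.duration_s))
    pairs = match_events([(e.onset_s, e.offset_s) for e in evs_a],
                         [(e.onset_s, e.offset_s) for e in evs_b],
                         min_overlap_s=min_overlap_s, return_pairs=True)
    matched_a = {ia for ia, _ in pairs}
    matched_b = {ib for _, ib in pairs}
    out: list[Annotation] = []
    for (ia, ib) in pairs:  # (a index, b index)
        ea, eb = evs_a[ia], evs_b[ib]
        onset = min(ea.onset_s, eb.onset_s)
        offset = max(ea.offset_s, eb.offset_s)
        out.append(Annotation(onset_s=onset, duration_s=offset - onset, label=ea.label,
                              scorer=f"{ea.scorer}+{eb.scorer}".strip("+")))
    out.extend(e for j, e in enumerate(evs_a) if j not in matched_a)
    out.extend(e for i, e in enumerate(evs_b) if i not in matched_b)
    return AnnotationSet(sorted(out, key=lambda e: (e.onset_s, e.duration_s)),
                         source=f"{a.source}|{b.source}")


# ---------------------------------------------------------------------------
# Matching and derived metrics
# ---------------------------------------------------------------------------

def _as_intervals(events) -> list[tuple[float, float]]:
    out = []
    for ev in events:
        if isinstance(ev, tuple):
            out.append((float(ev[0]), float(ev[1])))
        elif hasattr(ev, "offset_s"):
            out.append((float(ev.onset_s), float(ev.offset_s)))
        else:
            raise TypeError(f"cannot interpret event {ev!r} as an interval")
    return sorted(out)


def match_events(ref, pred, min_overlap_s: float = 0.25, return_pairs: bool = False):
    """Greedy one-to-one matching of predicted events to reference events.

    Both arguments accept lists of ``(onset, offset)`` tuples or objects
    with ``onset_s``/``offset_s``.  References are visited in onset order;
    each claims the unmatched prediction with the largest overlap, provided
    that overlap reaches *min_overlap_s* (ties go to the earliest-onset
    prediction).  Returns :class:`ConfusionCounts` — or the matched index
    pairs ``(ref_idx, pred_idx)`` with ``return_pairs=True``.
    """
    ref_iv = _as_intervals(ref)
    pred_iv = _as_intervals(pred)
    taken = np.zeros(len(pred_iv), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i, r in enumerate(ref_iv):
        best_j, best_ov = -1, 0.0
        for j, p in enumerate(pred_iv):
            if taken[j]:
                continue
            if p[0] >= r[1]:
                break  # sorted: no later prediction can overlap this ref
            ov = _interval_overlap(r, p)
            if ov > best_ov + 1e-12 or (ov > 0 and abs(ov - best_ov) <= 1e-12 and best_j >= 0
                                        and p[0] < pred_iv[best_j][0]):
                best_j, best_ov = j, ov
        if best_j >= 0 and best_ov >= min_overlap_s - 1e-12:
            taken[best_j] = True
            pairs.append((i, best_j))
    if return_pairs:
        return pairs
    tp = len(pairs)
    return ConfusionCounts(tp=tp, fp=len(pred_iv) - tp, fn=len(ref_iv) - tp)


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no reference events")
    return c.tp / (c.tp + c.fn)


def ppv(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    if c.tp + c.fp == 0:
        raise ZeroDivisionError("PPV undefined: no predicted events")
    return c.tp / (c.tp + c.fp)


def f_score(c: ConfusionCounts) -> float:
    """2·TP / (2·TP + FN + FP)."""
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        raise ZeroDivisionError("F-score undefined: no events at all")
    return 2 * c.tp / denom


def agreement_rate(n_matched: int, n_ref: int) -> float:
    """Matched events over reference events, in percent."""
    if n_ref <= 0:
        raise ZeroDivisionError("agreement rate undefined: no reference events")
    return 100.0 * n_matched / n_ref


def ccc(x: Sequence[float], y: Sequence[float], *, literal_denominator: bool = False) -> float:
    """Lin's concordance correlation coefficient between two count vectors.

    Uses population (1/n) moments:

        ρc = 2·cov(x, y) / ((μx − μy)² + σx² + σy²)

    ``literal_denominator=True`` switches to a variant with the mean
    difference entering unsquared — nonstandard, off by default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("ccc needs two equal-length vectors of length >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()              # population variances
    if vx == 0 or vy == 0:
        raise ValueError("ccc undefined for a zero-variance vector")
    cov = ((x - mx) * (y - my)).mean()
    mean_term = (mx - my) if literal_denominator else (mx - my) ** 2
    return float(2 * cov / (mean_term + vx + vy))


def score_events(pred, ref, min_overlap_s: float = 0.25,
                 counts_x: Sequence[float] | None = None,
                 counts_y: Sequence[float] | None = None) -> MetricReport:
    """Match *pred* against *ref* and assemble the full metric report.

    Optional *counts_x*/*counts_y* (e.g. per-subject or per-segment spindle
    counts from two scorers) add the CCC to the report.
    """
    c = match_events(ref, pred, min_overlap_s=min_overlap_s)
    report = MetricReport(
        counts=c,
        sensitivity=sensitivity(c),
        ppv=ppv(c),
        f_score=f_score(c),
        ar_percent=agreement_rate(c.tp, c.n_ref),
        ccc=ccc(counts_x, counts_y) if counts_x is not None and counts_y is not None else None,
    )
    return report
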