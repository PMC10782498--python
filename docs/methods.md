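# Methods

This note documents the model implemented by `samc`, the defaults and why
they were chosen, the numerical decisions taken where the design was open,
what the synthetic generator does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and pipeline

The detector assumes multichannel scalp EEG in microvolts with per-channel
sampling rates (EDF input). Times are seconds from recording start and all
events are half-open intervals `[onset, offset)`; overlap arithmetic
everywhere uses this convention.

Stages, in order:

1. **Harmonization.** Channels with different native rates are polyphase-
   resampled to the maximum rate. (Mixed-rate montages are common: archival
   polysomnography stores EEG at 256 Hz alongside 200/100/50-Hz auxiliary
   channels.)
2. **Broadband bandpass** 0.2–200 Hz, 4th-order Butterworth applied
   forward–backward. When 200 Hz is at or above a channel's Nyquist
   frequency the upper edge is clipped to 0.45×fs with a logged warning.
   All filters in the package are zero-phase: a filtered burst has zero
   cross-correlation lag against its source, so event boundaries — which
   the duration rules depend on — are not shifted.
3. **Data-driven notch.** The mains frequency is detected, not assumed:
   Welch PSD bins inside 45–65 Hz (and harmonic images) that exceed 10× the
   median power of their ±2 Hz neighborhood are removed with a Q=30 IIR
   notch. A peak-free recording passes through bit-identically. Threshold
   ratio and Q are config keys; there is no published prescription for them.
4. **Artifact-epoch rejection.** Per 2-s epoch and channel, two statistics:
   RMS of the 30–100 Hz component (muscle activity) and peak absolute
   amplitude of the signal *with its 11–16 Hz component subtracted*. An
   epoch is rejected when either statistic exceeds
   `median + 5 × 1.4826 × MAD` across epochs on any channel (a robust
   z-score of 5; the 1.4826 factor scales the MAD to a standard-deviation
   estimate, with an ε floor so a flat recording is kept whole). Rejected
   samples are excluded from the normalization statistics and candidates
   overlapping them are suppressed.

   Two deliberate choices here. The spindle band is subtracted before the
   amplitude statistic because in clean data the largest-amplitude epochs
   *are* the spindles — a rejector keyed on raw amplitude preferentially
   masks the very events the pipeline exists to find, while genuine
   movement artifacts are broadband and survive the subtraction. And the
   rejector is a deterministic thresholding scheme rather than an ICA
   decomposition: determinism and auditability on the core path, with the
   keep-mask injectable by callers who prefer their own artifact pipeline
   (ICA or otherwise).
5. **Narrowband stage.** An 11–16 Hz zero-phase bandpass copy of each
   channel feeds the minimum-amplitude criterion.
6. **Spectral estimation, thresholding, cross-channel agreement** — below.

## Taper bank

Each taper is a complex Gabor atom `g_k(t) = exp(−t²/2S_k²)·exp(i2πf_k t)`
with `S_k = n_k/(2πf_k)`, sampled at 1/fs on a grid symmetric about zero
(odd length) with 2-s support — the maximum spindle duration, so the longest
event still fits inside one atom. Defaults:

| parameter | default | rationale |
|---|---|---|
| frequency grid | 11–16 Hz, 1-Hz step (6 tapers) | one taper per evaluated frequency; 1 Hz resolves slow/fast classes while keeping the bank small; config-exposed |
| cycle counts n_k | log10-spaced 3 → 10, ascending with f | 3 cycles resolves a 0.5-s event at 11 Hz; 10 cycles keeps the 16-Hz atom's ±3σ inside the 2-s support |
| support | 2.0 s | maximum spindle duration |

With n_k ascending, S_k grows along the bank, so the spectral main lobe
narrows monotonically with frequency (property-tested).

**Taper amplitude normalization.** Before convolution each taper is divided
by the L1 norm of its envelope (config `sde.taper_norm`, `"none"`
available). The raw convolution response to a unit sinusoid scales with
S_k, which differs by ~2.3× across the bank; unnormalized, a pure 13-Hz
tone elicits its largest response from the *14-Hz* taper, and slow events
are systematically under-weighted in the max-collapse. After L1
normalization a unit tone at any grid frequency produces a unit-scale
response from its own taper. The detection chain is invariant to any single
global taper scale either way (property-tested); what normalization fixes
is the per-frequency relative scale.

## Power chain

Per channel: `m = |SDE|` per frequency, `p = √m`, collapse across
frequencies per sample by maximum, then min–max normalization over the
kept (artifact-free, non-edge) samples, clipped to [0,1]:

* `p = √m` is the method's printed power definition and the default; it is
  unconventional (power as the square root of a magnitude) but the square
  root is a monotone map, so thresholding is only reparametrized, and its
  compression helps weak events clear a fixed threshold. A conventional
  `p = m²` sits behind `sde.power = "square"`.
* Collapse by **max** keeps a weak slow spindle and a strong fast spindle
  both visible; mean-collapse is available (`sde.collapse`).
* Normalization scope is the **whole recording** per channel by default;
  `sde.norm_scope = "epoch"` renormalizes each 30-s block independently.
  Whole-recording scope makes the 0.5 threshold a single global reference;
  epoch scope adapts to drift but inflates spindle-free blocks (their
  local maximum becomes 1 by construction), which measurably floods the
  detector with background-driven candidates — hence not the default.
* The first/last half-support of the convolution (zero-padded "same"
  output) is flagged and excluded: partial taper overlap biases the edge
  estimates.

Scale invariance — norm_power is unchanged under any global gain on the
raw signal — follows because √ and min–max are order-preserving, and is
verified at gains 0.1× and 10×. The detector therefore needs no amplitude
calibration; the only absolute-amplitude rule is the explicit 13-µV
criterion.

## Single-channel rules

Candidates are suprathreshold runs (`norm_power > 0.5`), then:

1. **Boundaries.** Each run is extended outward over the full power peak,
   down to `max(0.5 × run peak, 0.8 × threshold)` (config
   `detect.boundary_peak_frac`, `detect.boundary_floor_frac`; both set to 1
   reduces boundaries to the bare run). This is a dual-threshold design,
   standard in the spindle-detection literature: the 0.5 threshold decides
   *candidacy*, the boundary level decides *extent* — the duration is that
   of the power peak from its start to its last point, not of the samples
   above the candidacy threshold. Without the extension, a waxing/waning
   0.5–0.8-s event whose normalized peak reaches ~0.7 crosses 0.5 for only
   ~0.3 s and would fail the duration rule that exists to accept it. The
   floor keeps shallow background bumps (peaks barely above 0.5) from
   spreading: their boundary never drops below 0.4.
2. **Merging.** Runs separated by ≤ 0.10 s merge — a fragmented spindle is
   scored as a single spindle.
3. **Duration.** Merged runs are kept iff 0.4 s ≤ duration ≤ 2.0 s. The
   0.4-s lower bound is the 0.5-s definitional minimum with a 0.1-s
   tolerance. The alternative tabulated definition (0.5–2.5 s) ships as
   `config.TABLE_DURATION_PRESET`; the two windows genuinely differ in the
   source material and the discrepancy is documented, not resolved.
4. **Amplitude.** The candidate must reach 13 µV peak-to-peak in the
   11–16 Hz filtered signal within its boundaries (`min_p2p_uv = 0`
   disables). The definitional minimum amplitude is stated but never
   placed in a formula; peak-to-peak of the narrowband signal is this
   implementation's operationalization.

Each surviving candidate carries its peak normalized power, the argmax
frequency at that peak, the norm_power integral over the event ("area",
seconds), the narrowband peak-to-peak, and a slow/fast class at the 13-Hz
boundary (exactly 13 Hz → fast, a documented tie-break).

## Cross-channel agreement

A candidate E on one channel is confirmed when at least `min_channels − 1`
(default 1) *other* channels each overlap E for at least 25% of a reference
duration. The reference is E's own duration by default
(`samc.denominator = "each"`, evaluated symmetrically per candidate);
`"shorter"`/`"longer"` use the pairwise shorter/longer event. Confirmed
candidates overlapping across channels merge transitively into one
multi-channel event spanning the **union** interval (union vs intersection
is not prescribed anywhere; union is the default and config-exposed), with
peak fields from the strongest contributor. The operation is idempotent on
its own output, and every merged interval is exactly the union of
single-channel candidate intervals that each passed the duration rule
(both property-tested).

## Evaluation

Event-level only. Matching is greedy one-to-one in reference-onset order:
each reference claims the unmatched prediction with the largest overlap,
provided the overlap reaches 0.25 s (ties → earlier prediction). Greedy
assignment agrees with brute-force maximum matching on randomized small
instances (tested); only the overlap criterion itself is prescribed, the
assignment scheme is this implementation's choice. Undurated expert marks
(onset-only) are padded to a fixed 1.6-s window — 0.4 s before the mark to
1.2 s after it — before matching; two scorers' sets are combined by
collapsing pairs that overlap ≥ 0.25 s into their union interval.

Lin's CCC is implemented in its standard form
`2ρσxσy / ((μx−μy)² + σx² + σy²)` with population moments. The printed
source formula has the mean-difference term unsquared; that literal variant
is available behind `ccc(..., literal_denominator=True)` but is not the
default, since unsquared it is dimensionally inconsistent and can leave
[−1, 1]. Reported table values are floored (truncated) to two decimals —
the convention the published tables follow (0.9681 prints as 0.96) — with
raw doubles always retained.

## Synthetic generator

`SynthSpec` defaults describe the study condition used throughout the
tests: 6 channels (F3/F4/C3/C4/O1/O2), 600 s at 200 Hz, 1/f (pink)
background at 15 µV RMS, 3 spindles/min — a realistic stage-2 density —
with spindles uniform in 11–16 Hz, 0.5–2.0 s, 30–50 µV peak-to-peak
(≥ 13 µV by construction), 80% of events shared across ≥ 2 channels with
≤ 0.05 s per-channel onset jitter, and optional 50/60-Hz hum and 200-µV
80-Hz muscle bursts. Spindles are sinusoids under a Hanning envelope (the
waxing/waning morphology; Gaussian available). One integer seed fully
determines the output; annotations carry exact onsets, durations and the
channel set of every injected event.

What the generator does **not** emulate: sleep-stage architecture, spectral
nonstationarity across the night, K-complexes and other transients that
share the sigma band, inter-channel volume-conduction correlation of the
background, and realistic artifact diversity. Passing the recovery tests
therefore shows the pipeline implements its rules correctly and recovers
events under controlled SNR — not that it attains any particular accuracy
on real polysomnography, where expert disagreement alone is large.

Recovery is always scored against the **multi-channel** subset of the
ground truth (events injected on ≥ 2 channels): an agreement rule that
requires two channels cannot, by design, confirm a single-channel event,
so with 80% sharing the full-set sensitivity of any implementation is
capped at 0.8. Single-channel injections do not inflate PPV either — they
are absent from both prediction and reference.

## Numerical choices and degenerate inputs

* FFT convolution (`scipy.signal.fftconvolve`) on the core path; it must
  and does agree with direct time-domain convolution to < 1e-9 relative
  (tested; measured ~1e-15).
* Min–max normalization of a constant trace raises `DegenerateInputError`
  rather than dividing by zero; the artifact rejector's MAD has an ε floor
  so an all-zero recording is kept in full.
* EDF is written with a ±400 µV physical range over 16-bit integers
  (≈ 0.012 µV/step); round-trip tests use a two-step tolerance. The EDF
  layer is a minimal reader/writer for plain EDF (per-channel rates
  preserved, µV enforced from the physical-dimension field, mV converted,
  other units rejected by name); it is cross-checked against MNE's EDF
  reader in the test suite. BDF and vendor formats are out of scope.
* Agreement comparisons use a 1e-12 slack so exact-boundary cases (25%
  agreement, 0.25-s overlap) land on the inclusive side deterministically.

## Problem sizes

Test and acceptance runs use 2–10-minute recordings at 200 Hz with 6 or
fewer channels — enough for every rule to bind (dozens of events per run)
while the whole suite stays fast. The pipeline itself is linear in samples
× channels × tapers and handles full-night recordings; nothing in the
implementation is specific to the sizes used in the tests.

## Known limitations

* The whole-recording min–max makes the 0.5 threshold depend on the single
  largest power excursion in the record; very long recordings or a single
  huge artifact surviving rejection compress the dynamic range. The epoch
  scope exists for such material, at the FP cost described above.
* The artifact rejector is a per-epoch amplitude/high-frequency screen,
  not a source-separation method; lower-amplitude artifacts inside the
  sigma band (e.g. rhythmic EMG harmonics) can survive it. A user-supplied
  keep-mask is the intended escape hatch.
* Slow/fast classification uses the argmax frequency at the event's power
  peak on a 1-Hz grid; events with peak frequency near 13 Hz are assigned
  by grid cell, not by sub-Hz estimation.
* The channel-agreement rule assumes reasonably synchronous spindle
  expression across the chosen montage; montages mixing channel groups
  with genuinely independent spindle activity (anterior vs posterior) are
  better analyzed per group, which the channel-subset selection supports.
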