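# Methods

## Background and scope

Cerebral autoregulation (CA) holds cerebral blood flow roughly constant
across a range of arterial pressures; cerebrovascular reactivity (CVR)
is the vessel-caliber mechanism behind it. When reactivity fails,
blood volume follows pressure passively, so slow (0.005–0.05 Hz)
vasogenic fluctuations in a NIRS-derived blood-volume surrogate become
positively correlated with slow fluctuations in arterial blood
pressure. `cvrmap` implements the full multi-channel monitoring chain
around that statistic: dual-rate stream I/O and delay alignment,
short-channel scalp removal, 10-s moving-average decimation, sliding
30-mean Pearson correlation, and topographic heat-map replay — plus a
simulator that replaces the acquisition hardware with a model whose
ground truth is known.

Out of scope by design: device drivers and live streaming, the
optical-density → hemoglobin conversion (device-internal), GUI
interaction (frames are rendered headlessly), and any forecasting of
index maps.

## The index engine

For each channel, five surrogates are correlated with non-invasive
arterial blood pressure (niABP): HbO, HHb, tHb = HbO + HHb,
HbDiff = HbO − HHb, and rSO₂, giving the indices HbOx, HHbx, tHbx,
HbDiffx and COx.

1. **Decimation.** Every trace is reduced by non-overlapping
   moving-average filters of 10-s duration. Each complete wall-clock
   window yields the arithmetic mean of its valid samples, timestamped
   at the window's right edge. This isolates the slow vasogenic band
   and analytically nulls faster confounders: a 0.1 Hz Mayer wave
   completes exactly one period per window, so its uniform-sample mean
   is zero to machine precision.
2. **Sliding correlation.** Pearson correlation over 30 consecutive
   10-s means, updated every 10 s — a fully overlapping 300-s window
   with a 10-s hop (`corr_window=30`, `update_step=1`), the standard
   construction for pressure-reactivity-style indices. Values are
   clipped to [−1, +1] against rounding.

The sliding implementation uses windowed cumulative sums after global
demeaning of each decimated series (correlation is shift-invariant;
demeaning keeps the one-pass formula well conditioned when signals ride
a large offset such as 90 mmHg). The test suite checks it against
per-window two-pass recomputation to 1e−12.

### Dual-rate handling

niABP is sampled at 100 Hz and NIRS at 250 Hz; the tick grids do not
nest. No resampling is performed anywhere: each stream is decimated at
its native rate over *identical wall-clock windows*, anchored at the
aligned record's common start. One consequence worth knowing: the
discrete mean of N uniform samples is centered half a sample period
before the window center, so the 100 Hz and 250 Hz means are offset by
3 ms. For fully coupled noiseless signals this leaves indices at
1 − ~2·10⁻⁷ instead of exactly 1 — negligible at the 10-s scale but
visible in strict float comparisons, which is why exactness tests use
the single-grid construction.

### Delay correction

The niABP device's output lags its measurement (mean measured lag
3.24 s in the emulated system), so alignment shifts NIRS timestamps
forward by a fixed 3.22 s correction. The shift is quantized to whole
samples (exactly 805 samples at 250 Hz, 322 at 100 Hz) and any
sub-sample residual is stored in the record metadata rather than
interpolated away: sub-sample interpolation would alter waveform
morphology for no benefit at 10-s averaging scale. With the simulator's
default 3.24 s true lag, a known 0.02 s residual remains after
correction — two orders of magnitude below the decimation window, and
verified by impulse timing in the tests.

### Missing data

A 10-s mean requires ≥ 50 % valid raw samples
(`min_valid_fraction_per_mean`); an index value requires all 30 means
valid by default (`min_valid_means_per_window`), so windows spanning
gaps are skipped rather than shortened (configurable). Zero-variance
windows yield missing, not an error — flatlined or clamped signals are
physiologically meaningful. Missing values propagate monotonically:
derived traces and indices are never less missing than their inputs,
and CSVs write missing as empty cells, never zeros.

### rSO₂ convention

rSO₂ is computed as `100 × HHb / tHb`, the convention of the emulated
acquisition chain, with `rso2_numerator="HbO"` available for the
textbook oxygen-saturation definition. The choice flips COx's sign
relative to the volume indices (visible in the examples); it is logged
at derivation time. Samples with tHb ≤ 0 yield missing rSO₂.

### Scalp removal

Short (10 mm) reference channels sample scalp only; subtraction from
the 30 mm normal channels is unit-gain by default (`short_scale=1.0`) —
no regression coefficient is fitted, matching the emulated device's
behavior. If a recording already contains device-computed pure-cerebral
columns they are used as-is; derivation only fills gaps.

## The simulator

The generator is a sinusoid-plus-noise model chosen because the
downstream indices are correlations over the slow-wave band, making the
per-channel coupling parameter the directly recoverable ground truth.
No Windkessel/biophysical modeling and no Lassen-curve nonlinearity is
attempted: a pressure-passive vs decoupled dichotomy suffices to
exercise the indices.

* **niABP** = mean (90 mmHg) + cardiac (1.1 Hz, 15 mmHg) + respiratory
  (0.25 Hz, 3 mmHg) + Mayer (0.1 Hz, 3 mmHg) + slow waves (0.02 Hz,
  5 mmHg and 0.033 Hz, 3 mmHg) + white noise (sd 0.05). Component
  phases are seed-derived.
* **Cerebral part** of each channel: `rho ×` (normalized noiseless ABP
  oscillation) `+ (1 − |rho|) ×` an independent slow-band process, all
  scaled by `cerebral_slow_amp` (1 a.u.). The coupled part inherits the
  *full* pressure waveform, not only its slow band — pressure-passive
  vasculature transmits the waveform into blood volume — which forces
  decimated tHb to be an exact affine function of decimated ABP at
  `rho = ±1` with zero noise. The independent process draws 8 sinusoid
  frequencies uniformly within 0.005–0.05 Hz (fresh per channel per
  seed): sharing the band but not the spectral lines of the ABP slow
  waves, so a decoupled channel decorrelates over a 300-s window.
  Reusing the same frequencies with random phases does *not* work: two
  equal-frequency sinusoids correlate at cos Δφ, |mean| ≈ 0.64.
* **Chromophore split**: HbO receives 0.7 and HHb 0.3 of the cerebral
  signal (a blood-volume increase raises both), on baselines of 30 and
  15 a.u. Only ratios matter for rSO₂; hemoglobin units are arbitrary
  because the indices are scale-invariant, so no absolute calibration
  is attempted. The published system states no amplitude ranges for
  hemoglobin slow waves; these defaults are explicit choices.
* **Scalp part**: one slow-band process per channel, scaled by
  `scalp_fraction` (0.3) and added *identically* to the normal and
  short traces of each chromophore, so unit-gain subtraction cancels it
  exactly. Short channels carry 10 % of the normal baselines and no
  cerebral signal.
* **Timing**: NIRS content is advanced by `nirs_delay_true` (default
  3.24 s) relative to the ABP stream, so the pipeline's 3.22 s
  correction leaves the small documented residual.
* **Default montage**: 8 channels, couplings (+0.9 ×4, −0.3 ×4) — an
  impaired left and intact right hemisphere on the `lobar8` layout, a
  plausible unilateral-injury pattern that exercises both colormap
  ends.

All randomness flows through per-purpose child seeds of a single
configuration seed; identical configurations are bit-identical.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data: pulse-waveform morphology (sinusoids, not
dicrotic waveforms), motion and optode-contact artifacts,
nonstationary autoregulation (coupling is constant per run), baseline
drift, and the Lassen-curve saturation of real vasculature. Parameter
recovery here demonstrates the pipeline's correctness, not clinical
validity; published thresholds for related indices (e.g. PRx 0.25/0.05,
COx 0.38) are documentation only and are not reproduced.

## File formats

Recordings are ICM+-style delimited text in two dialects, both with
`#`-prefixed header lines declaring each stream's rate/start/length
(mandatory — a uniform grid cannot be recovered from row times once
samples are missing): a **merged** file whose rows are the union of
both tick grids (the literal "one row per 250 Hz tick" layout is
impossible since 0.01 s is not a multiple of 0.004 s), and a **split**
pair with one file per device. Cells are empty where a stream has no
scheduled tick and `nan` where a scheduled sample is missing; floats
are written with shortest round-trip repr and read back exactly
(`float_precision="round_trip"`). Index CSVs are
`time,<ch>_<index>,...` with one column per channel–index pair.

## Heat maps

Layouts are declarative JSON on a normalized [0,1]² top-view template
(no anatomical registration is claimed); built-ins `lobar8` (8 normal +
8 short channels, one per lobe per hemisphere) and `grid4x4` (4×4
transmitter/receiver checkerboard, 24 channels =
rows·(cols−1)+cols·(rows−1)). Frames replay an index CSV at a 10-s
cadence; each channel is a filled disc at its transmitter–receiver
midpoint, colored by a symmetric blue–white–red diverging ramp
(−1 blue = intact, +1 red = impaired, gray = missing) computed
analytically so that color(−v) is the exact hue mirror of color(+v).
Frame/value association is last-observation-carried-forward up to one
cadence interval; older values go missing. Inter-marker field
interpolation is deliberately not applied (discrete patches match the
emulated display).

## Problem sizes used in the tests

Simulation-based tests use 600–620 s recordings at the native
100/250 Hz rates (≈ 60 decimated means → ≈ 31 sliding windows), the
natural minimum span for the 300-s correlation window; Monte-Carlo
checks use 10 seeds per condition. CLI round-trip tests use reduced
rates (20/50 Hz), which the rate-agnostic pipeline permits, to keep
file sizes small.

## Known limitations

* The merged CSV dialect stores the union grid as text and is bulky
  (~100 MB/h for 8 channels); the split dialect is preferred for
  longer recordings.
* Decimation drops any leading/trailing window not fully covered by a
  stream's sampled span; when `rate × delay` is non-integer the
  whole-sample shift can cost one decimated mean at the record edge.
* COx inherits the sign convention of the configured rSO₂ numerator.
* Rendering draws a fixed cosmetic head outline; optode positions are
  schematic.
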