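# Methods

## Scope and data model

`pupilprep` operates on pupil *diameter* series in millimetres with
timestamps in seconds. A recording is a possibly nonuniform timestamp
vector with one value column per eye; missingness is per eye and encoded
as NaN internally and as an empty cell in the standard CSV. Ingestion
enforces three invariants downstream code relies on: strictly increasing
timestamps (duplicates collapsed, first occurrence kept, so the dilation
speed never divides by a zero time step), positive finite diameters, and
at least one data-carrying eye. Rows carrying no data in either eye are
dropped on (re-)ingestion — they are indistinguishable from a gap.

Tracker exports vary in how they mark invalid samples; the format spec
supports a per-row or per-eye validity column with a configurable
sentinel list (default `0, -1`). The per-eye form is the default because
binocular trackers typically report per-eye confidence.

## Artifact rejection

Each eye is filtered independently through five stages; each stage sees
only the samples still valid, and a per-stage boolean layer records its
verdict (the combined mask is the AND of all layers, so every rejection
remains attributable).

**Range gate** (default 1.5–9 mm, bounds inclusive). Values outside a
feasible physiological window are measurement impossibilities; the gate
runs first so they cannot contaminate the robust statistics below.

**Dilation-speed filter.** The per-sample dilation speed is the larger
of the absolute normalized changes toward either neighbor,
d′[i] = max(|Δd/Δt| backward, |Δd/Δt| forward); normalizing by Δt makes
speeds comparable under nonuniform sampling and across gaps. Endpoints
use their single available neighbor rather than being dropped — this
preserves data and is worth knowing when comparing against
implementations that discard endpoints. Samples are rejected where d′
strictly exceeds median(d′) + n·MAD(d′). The multiplier n (default 16
for both this and the deviation filter) has no universally correct
value — trackers differ in rate, precision and noise — so it is exposed
prominently in the config and echoed in the filter report. With a
strict `>` comparison a constant series rejects nothing even though its
MAD is zero; for series where a majority share one exact value an
optional minimum-threshold epsilon (default 0, i.e. the plain formula)
is available.

**Gap-edge rejection** (margin 50 ms, minimum gap 75 ms). Blinks leave
gaps flanked by underestimated sizes as the eyelid progressively
occludes the pupil, so valid samples whose distance to the nearer
boundary of a qualifying gap is ≤ 50 ms are rejected. Gaps are measured
between consecutive present samples of that eye after the previous
stages; the margin is inclusive and gap qualification strict (> 75 ms),
matching the rule "within 50 ms of gaps larger than 75 ms". The span
before the first sample row does not exist and is not a gap, but a run
of missing rows at the start (or end) of the recording is one, with
only a trailing (or leading) edge.

**Trend-line deviation filter.** Clustered artifacts defeat
sample-to-sample speed tests, but not their distance from a smooth trend
line: currently valid samples are linearly interpolated onto a uniform
1000 Hz grid and smoothed with the same 4 Hz zero-phase low-pass used
for the final signal, and each sample's absolute deviation from this
trend is fed through the same median + n·MAD rule. The filter runs
multiple passes (default 2): every pass rebuilds the trend from the
currently valid samples and re-scores *all* samples that were in scope
at the first pass, so clean samples whose deviation was inflated by a
nearby cluster pulling the trend away are reinstated once the cluster
is gone. Reinstatement is limited to the deviation stage's own scope —
samples rejected by earlier stages never return. The per-pass threshold
is computed from the deviations of the full pass-1 scope each time,
keeping every pass's decision rule identical. The trend line is not
masked over long gaps; it only scores deviations and never becomes
output.

**Sparsity filter** (split gap 40 ms, minimum section 50 ms). Genuine
pupil data are temporally contiguous; the valid-sample sequence is split
at gaps > 40 ms and sections spanning < 50 ms (first to last timestamp,
so a lone sample spans 0 ms) are rejected wholesale.

Stage order is range → speed → gap-edge → deviation → sparsity. Each
stage runs once; new gaps opened by later stages do not re-trigger
earlier ones. This keeps the result deterministic and attributable; the
data-relative speed/deviation thresholds mean a second full run on the
surviving samples could shift those two stages slightly, while range
and sparsity are idempotent by construction.

## Binocular fusion and smoothing

Left and right pupil sizes are highly correlated locally but differ by a
slowly varying offset. At time points where both eyes have valid samples
(mutual nearest neighbors within half the median inter-sample interval)
the fused value is exactly (L+R)/2 and the signed offset o = R − L is
measured; at single-coverage points o is linearly interpolated (held
constant beyond the first/last double-coverage point, avoiding runaway
extrapolation) and the fused value is L + o/2 or R − o/2. Each fused
point carries its provenance (both / left / right). If the two eyes
never overlap the offset is unidentifiable and the eye with more valid
samples passes through unadjusted, with a warning.

The fused (or monocular) series is linearly interpolated onto a uniform
grid at 1000 Hz — linear interpolation cannot overshoot inside gaps —
and smoothed with a first-order Butterworth low-pass at 4 Hz applied
forward–backward (`scipy.signal.filtfilt`), which cancels the phase
response so event timing is preserved; DC gain is exactly 1, and the
effective magnitude response is the squared single-pass response (half
amplitude at the cutoff). Order and cutoff are configurable.
Interpolation is honest only across short gaps: grid points strictly
between raw valid samples more than 250 ms apart are set missing
*after* smoothing, so filter transients inside masked regions are
discarded with them. The mask metadata records exactly which grid
points were interpolated over qualifying gaps.

## Segmentation

Windows are half-open [t_start, t_end) on the uniform grid, so
contiguous segments partition grid points exactly once. Per segment the
mean, max, min, SD (n−1 denominator, reported missing below 2 points)
and missing-data percentage are computed; the percentage counts nominal
grid points in the window, so a segment reaching past the recorded span
counts the uncovered points as missing. Segments above the missing-data
limit are flagged, never silently dropped. The limit `max_missing_pct`
deliberately has **no default** — how much missing data is tolerable is
a study-level decision — and the pipeline aborts with a named error when
it is unset. Fixed-width binning (default 100 ms) averages non-missing
grid points per bin, keeps and flags a trailing partial bin, and
conserves totals: Σ(bin count × bin mean) equals the segment's sum of
non-missing values. Baseline pairing attaches each response segment's
baseline mean using `trial_id` grouping when present and nearest
preceding baseline otherwise; no correction is applied — subtractive or
divisive correction belongs downstream.

## Synthetic recordings

The generator renders what the filters are designed to remove, with a
per-sample ground-truth ledger. The true signal is a sum of sinusoids
(≤ 1 Hz) around a baseline inside the feasible window; the default
scenario is 60 s at 250 Hz, base 4.7 mm with 0.5 mm @ 0.12 Hz and
0.25 mm @ 0.30 Hz components, Gaussian measurement noise of SD 0.03 mm
per eye, and an inter-eye offset of 0.3 mm drifting by ±0.1 mm at
0.03 Hz — magnitudes typical of research-grade video trackers under
stable luminance. Timestamps optionally jitter uniformly by ±5 % of the
nominal interval (order-preserving). Artifacts are placed in
non-overlapping randomly located slots, binocularly (as real blinks
are): 10 blinks (120 ms gaps with 1 mm linear-ramp edge dips over 12 ms,
i.e. ~3 samples — the functional form of occlusion dips is not
constrained by data, so the simplest ramp is used), 8 spikes of 1 mm,
3 five-sample clusters offset 0.6 mm, and 2 islands of 45 ms stranded
in 60 ms gaps. All artifact amplitudes are at least 10× the noise SD.
Identical scenario and seed give bit-identical output.

What the generator does **not** emulate: luminance responses and the
pupillary light reflex, gaze-position foreshortening, slow drift or
head-movement artifacts, tracker-specific quantization, or
monocular-dropout asymmetries between eyes. Passing tests therefore
demonstrate correct mechanics of the filters and the processing chain
under realistic noise and artifact morphology — not performance on any
particular tracker's idiosyncrasies, for which the thresholds should be
tuned empirically per dataset using the diagnostic plots.

## Numerical and design choices

* Robust statistics use `np.median`; thresholds compare strictly (`>`),
  so degenerate MAD = 0 on constant data rejects nothing.
* Trend-line and output smoothing share one implementation; the filter
  refuses series shorter than 3× the filtfilt pad length rather than
  padding creatively.
* The standard CSV writes pandas' shortest round-trip float
  representation and is read back with the `round_trip` parser, so
  write → load is bit-exact on data-carrying rows.
* Uniform grids span [first, last] valid timestamp; no extrapolation
  beyond the data, ever.
* Config parsing rejects unknown keys (typo safety); every effective
  setting and threshold actually used is echoed into the filter report
  and run log, and output CSVs carry a version + config-hash comment.
* Problem sizes in the test suite and acceptance script (20 scenarios of
  60 s at 250 Hz; 10 s probe signals at 1000 Hz) were chosen to exercise
  every stage with comfortable statistics while keeping a full run in
  the order of seconds.

## Known limitations

* No gaze-position (foreshortening) or luminance correction; the output
  is a cleaned size signal, not a cognitively "pure" one.
* Blinks are removed, not labeled; blink-rate analyses need a different
  tool.
* Thresholds are global per recording, not adaptive per segment.
* The speed filter runs once; a gap newly opened by the deviation or
  sparsity stage does not get a second gap-edge pass.
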