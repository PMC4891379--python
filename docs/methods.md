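# Methods

This note documents the models and procedures implemented in `timebench`,
the parameter choices that matter, and what the synthetic-data tests do and
do not establish about real recordings.

## Data model and time conventions

A study is a tree: subjects → modality substructures → uniformly sampled
channels, an event list, and derived results; raw input files are attached
byte-exact and survive bundle round-trips. Channels store a sample rate
and a start time; the time of sample *i* (0-based) is
`start_time + i / sample_rate`. All windows everywhere are half-open
`[start, end)` seconds, so abutting windows (baseline `[0, 2)`, measure
`[6, 7)`) never share a sample. Missing data is NaN internally; file
readers map dialect-specific codes (empty cells, `-1`) onto it at parse
time, so no sentinel magnitudes survive into analysis. The lock flag is
enforced in software (every mutator checks it), matching an archival
rather than cryptographic notion of locking.

## Plugin contract and execution

A plugin is three entry points: `declare` (returns the spec: id, category,
subject- or group-scope, and a settings schema in which every key has a
type, default and optional range/choices), `configure` (normalizes a
validated settings mapping) and `process` (does the work). The split is an
interpretation — it mirrors the separation of self-description, settings
handling and processing that the contract has to cover. Settings are plain
mappings; named sets are one YAML file per (plugin, name), so they diff
and share cleanly; instantiation merges declared defaults ← named set ←
overrides and validates the result, naming the offending key on failure.

The engine applies selected stages in workflow order to selected subjects
(order matters: median filtering and gap interpolation do not commute, and
a test pins this). Re-running a stage overwrites that stage's derived
outputs for the selected subjects; downstream outputs are not invalidated
automatically. The error policy is `abort` (default — safest for
reproduction) or `continue`, which records the failing (plugin, subject)
pair and preserves all prior outputs. Each executed stage appends a
provenance record: settings hash, subject list, engine version, and
content fingerprints of the selected subjects' data before and after
(channel arrays are fingerprinted by their raw bytes, so the snapshot is
cheap enough to take around every stage).

Determinism: one top-level seed; every stochastic stage receives a
substream seeded by `sha256(seed | plugin_id | subject) mod 2^31`, so
results do not depend on selection order, and identical inputs + seed give
bit-identical derived data.

## Processing stages

**Gap interpolation.** A gap is a maximal NaN run. It is filled iff its
length is *strictly* less than `max_gap` (the threshold is read strictly:
at the default 5, length-4 gaps fill, length-5 gaps do not — a boundary
test pins this), it has valid samples on both flanks (edge gaps never
fill), the flank jump is ≤ `max_jump` if set, and all inserted values lie
in `valid_range` if set. Values come from a scipy interpolant over the
valid samples (`nearest`/`linear`/`cubic`); linear filling is exact on
linear signals, and originally valid samples are bitwise untouched.

**Moving filter.** `out[i]` is the NaN-ignoring mean or median over
`[i−h, i+h]` clipped to the channel (pandas centred rolling window,
`min_periods=1`): shrinking edge windows, no padding, no truncation, so
trial alignment is preserved and the symmetric window introduces no phase
shift. An all-missing window yields a missing sample. The case-study
filter stage runs a median pass and then (via the `then_mean` setting) a
mean pass with the same half-width as one workflow stage, keeping the
shipped pipeline at its five published stages.

**Event-related extraction.** Events are snapped to the nearest sample at
or after the event time (a deterministic choice; the alternative —
nearest sample either side — differs by at most one sample at 50 Hz).
Trials whose window exceeds the recording are dropped and counted.
Baseline correction is subtractive (trial minus the mean of its
non-missing baseline samples); a divisive/percentage variant would be a
one-line change but the subtractive reading is the simplest and is what
the tests calibrate against. Latencies are seconds from the event (trial
start), earliest sample winning ties. The trial epoch defaults to
`[0, 10)` s, configurable — long enough to contain the 6–8 s dilation
window with margin. Condition average curves carry pointwise normal-theory
bands, mean ± z·SE across trials with z from the configurable level
(default 95%); with tens of trials per condition the normal approximation
is adequate and it degrades gracefully (band suppressed where fewer than
two trials contribute).

## Bootstrap test

The group comparison is an equal-means two-sample bootstrap: shift both
groups to the pooled mean, resample with replacement within each group,
and compare through the studentized statistic
t = (x̄−ȳ)/√(s²ₓ/nₓ + s²ᵧ/nᵧ), two-sided, with the add-one estimate
p = (1 + #{|t\*| ≥ |t|})/(B + 1), which is never exactly zero. The
studentized form is used because the raw mean-difference comparison is
measurably anti-conservative at the group sizes this plugin sees
(n ≈ 10–15 subjects); with studentization the empirical type-I error at
α = 0.05 sits at ≈ 0.05 (the acceptance suite measures it over 2000 null
replicates). The reported observed statistic remains the plain difference
of means, which is the quantity of scientific interest. Resampling is
performed in a canonical group order so swapping the arguments with the
same seed yields the identical p-value. Zero-variance degenerate groups
define t = 0 when the means agree (hence p = 1 for identical constant
groups). No multiple-comparison correction is applied; the plugin performs
exactly one comparison.

## Synthetic data generator

The generator emulates the mental-multiplication experiment at 50 Hz (the
nominal rate of the named tracker model; configurable). Per trial: an
onset trigger carrying the operand pair, the multiplicand event at
onset + 2 s, the multiplier at onset + 4 s; operands uniform in 1–9 /
6–14 / 11–19 by condition. Because those ranges overlap, the study-wide
stimulus list is drawn with globally unique operand pairs so each raw
trigger maps to exactly one condition; the event-modification stage's
rename rules are derived from that list, which is how a real experimenter
would recode stimulus names into conditions. Every subject sees the same
stimulus set in an independently shuffled order.

The pupil signal is `baseline + gain_s · a_c · g(t − onset) + noise`,
with a log-normal-shaped kernel `g(t) = exp(−ln²(t/peak)/(2w²))` (unit
peak at `peak` = 6.5 s, log-sd `w` = 0.25), condition amplitudes
defaulting to 0.05 / 0.15 / 0.30 mm, a per-subject log-normal gain
(log-sd 0.15) and Gaussian noise (sd 0.05 mm). The kernel width and the
5 s inter-trial interval are chosen so the response has decayed to well
under 1% of peak before the next trial's baseline window opens — the
assumption (baseline recovery between trials) that the experiment's
design itself relies on; with a wider kernel or shorter ITI, carry-over
into the baseline biases first trials relative to later ones. Nuisance
structure: blink gaps at a configurable rate with lengths drawn from an
explicit distribution over {2, 3, 4, 6, 8} samples (placed non-adjacent,
as real blinks are, which also makes the generated length distribution
exactly testable by χ² goodness of fit), isolated ±1 mm single-sample
pupil outliers (what the median pass exists to remove), and AR(1) gaze
wander around screen centre. Files are written in a ClearView-like
combined dialect — tab-separated, integer millisecond timestamps, missing
code `-1`, event labels sharing the file with gaze — with full-precision
float formatting so write → read round-trips are bit-exact.

What passing the synthetic tests does **not** show about real data: no
pupillary light reflex, hippus, saccade dynamics or foreshortening
artefacts are modelled; blink gaps are clean NaN runs without the
characteristic pre/post-blink partial-occlusion ramps; noise is white.
The end-to-end tests therefore establish that the pipeline is correct and
well-calibrated under its stated model, not that the model captures every
property of eyetracker output.

## Bundles, identifiers, locking

A bundle is a zip archive: a JSON manifest (metadata, engine version, lock
state, full workflow with settings, channels/events/derived data), raw
files byte-exact under `data/`, and plugin source snapshots under
`plugins/`. Import validates a fixed manifest schema and names the
offending field on mismatch. Plugin sources from a bundle can be
registered under a bundle-specific namespace so two studies can ship
different plugins of the same name. The UWID is derived locally from a
content hash of the reproducible content (everything except the identifier
itself, the lock flag and provenance timestamps), rendered as two base-36
triplets (`ts-xxx-xxx`); determinism substitutes for central issuance
since no server is in scope. Assigning the identifier snapshots plugin
sources first — they are part of the identified content — which also
guarantees a locked study exports without further mutation.

## Problem sizes used by the tests

The acceptance suite runs the full pipeline at the study's native size
(10 subjects × 12 trials per condition, 50 Hz) over 40 independent seeds
for the parameter-recovery check, 2000 null replicates (n = 15 per group,
B = 500) for the bootstrap calibration, and smaller configurations
(2–4 subjects, 1–6 trials per condition) wherever the property under test
does not depend on scale. `scripts/acceptance.py` uses the native size for
its main run and 10 seeds for the ordering-recovery fraction.

## Known limitations

- One modality level per subject; no nested substructures, no per-channel
  non-uniform timestamps.
- No parallel execution; re-running a stage does not cascade invalidation
  downstream.
- No gaze event parsing (fixations/saccades), areas-of-interest analysis
  or pupil foreshortening correction.
- The bundle format is versioned but only format version 1 exists;
  engine-version compatibility is reported, not negotiated.
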