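# Methods

This note documents the models, conventions and numerical choices behind
`esskit`, in the spirit of the methods documentation that accompanies
simulation and statistics packages: what is computed, under which
assumptions, and what the shipped defaults mean.

## The container model

A study container is a directory with a manifest
(`study_description.xml`) and a fixed layout. The Level-1 layout is:

```
<root>/
  study_description.xml
  README.txt
  additional_documentation/
  session/<N>/
    eeg_session_<N>_<task>_<original>.<ext>
    event_session_<N>_<task>_<original>.tsv
    channel_locations_session_<N>_<task>_<original>.<ext>   (optional)
```

The manifest encodes tasks, *recording parameter sets* (channel layouts
grouped into modalities — contiguous 1-based channel ranges of one
signal kind with a sampling rate, channel labels, and the subset of
labels that are not on the scalp), sessions with anonymized subjects and
data recordings, and the per-task mapping from event codes to HED
annotations. Key schema constraints: task labels are unique and
filesystem-safe; session numbers are unique positive integers; modality
ranges are disjoint and tile `1..N`; label counts match range sizes;
non-scalp labels are a subset of channel labels; event labels are at
most 20 characters and always carry a category tag.

**Element dialect.** The dialect is lowerCamelCase and pinned by the XSD
shipped as package data (`data/study_level1.xsd`). It is a
reconstruction: names that appear in prose (e.g.
`recordingParameterSet`, `dataRecording`, `originalFileNameAndPath`,
`rset_1`) are used exactly; the remainder follow the same style. The XSD
is deliberately lax about UUID and number lexical forms — those are
owned by named validator checks so that a draft manifest can be loaded,
diagnosed and repaired rather than rejected wholesale.

**Serialization policy.** Optional fields are emitted as empty elements,
never omitted, making `write ∘ read` byte-stable (canonical); `read ∘
write` is the identity on the data model (property-tested with random
manifests). Unknown top-level children of the root element are preserved
verbatim and re-emitted; unknown elements nested deeper are not
preserved. Floats are serialized with `repr` so round-trips are exact;
event-file latencies are fixed at six decimals (sub-millisecond at any
plausible sampling rate, stable diffs). Paths use forward slashes
relative to the container root. UUIDs are random version 4, lowercase.

**Event-instance files** have no header line, one `code TAB latency TAB
hedString` row per event, sorted by ascending latency with ties keeping
input order. A header-less three-column format keeps the file trivially
parseable from any platform.

## HED vocabulary and matching

The HED vocabulary is a tree; tags are slash-delimited paths.
Comparison is case-insensitive (canonical case lives in the hierarchy).
A tag string is a comma-separated sequence of tags and parenthesised
groups; groups are searched transparently and carry no attributes of
their own. The tilde (role) syntax of full HED 2.0 is not implemented
and is rejected with a parse error. The shipped vocabulary is a trimmed
snapshot sufficient for auditory-oddball-style annotation, stored as an
indentation-structured text file with `[extensionAllowed]` /
`[takesValue]` flags; the full public vocabulary can be substituted via
`load_hierarchy(path)`.

Matching semantics: query `Q` matches tag `T` iff `Q`'s path is a
case-insensitive prefix of `T`'s. This is the natural reading of
hierarchical selection ("any ancestor selects its subtree") and makes
matching transitive along the hierarchy; the package treats it as a
design decision rather than an externally fixed rule. Vocabulary
validation accepts a tag when its path exists, when it deviates only
below a node flagged `extensionAllowed`, or when it supplies exactly one
value component below a `takesValue` node.

## Validation

Validation is a catalog of 48 independently named checks, each with a
fixed default severity: structural/referential breaks are errors, absent
optional metadata is a warning, and generated identifiers (study and
recording UUIDs) are auto-fixed and reported with severity `fixed`.
File-level checks (payload existence, event-file well-formedness,
ordering, latency-vs-duration, code coverage) run only when a container
root is supplied. Duration-dependent checks are skipped with a warning
when the recording's header cannot be read. Auto-fixes are applied to a
deep copy — the caller's manifest is never mutated — and validation is
idempotent: re-validating the fixed manifest yields no `fixed` issues.

Dependent checks deliberately stand down when their prerequisite is
already broken (e.g. range-contiguity is not evaluated over an invalid
or overlapping range set), so each defect surfaces as exactly one check.
The test suite exploits this: every catalog entry has a mutation oracle
that corrupts a clean manifest in precisely the way the check targets
and asserts that exactly that check fires.

## EDF payloads

Payloads are classic EDF: 16-bit samples with per-channel linear
physical scaling, one-second data records, a common integer sampling
rate. The reader/writer in `esskit.edf` is intentionally minimal and is
cross-checked in the tests against MNE's independent EDF reader. Writing
quantizes with a per-channel scale derived from the observed min/max
(rounded outward to 1e-3), so a round trip reproduces values to about
`range/65536`; date/time header fields are fixed constants so output
bytes depend only on the data. Consequence: signal comparisons across a
container write are made after quantization — byte-level identity of
payloads is only guaranteed for bit-identical inputs, and chained
derivations accumulate at most one quantization step per hop. Raw
Level-1 payloads are copied, never transcoded, so their bytes are
conserved exactly (checksum-verified in tests). Level-2 and derived
payloads are written as EDF because the container convention needs *a*
concrete open format for processed data; the scale is recorded in each
file's own header.

## Level-2 preprocessing

The shipped pipeline is a deliberately simple, documented stand-in with
the standard interface (a full PREP-style implementation can be injected
through the `pipeline` argument):

1. **Noisy-channel detection** (scalp channels only). Deviation
   criterion: per-channel robust standard deviation (1.4826·MAD of the
   samples), converted to a robust z-score across channels
   (median / 1.4826·MAD); flag when z > `deviation_z` (default 5.0).
   Correlation criterion: in non-overlapping 1 s windows, each channel's
   maximum absolute Pearson correlation with any other scalp channel;
   flag when the median across windows is below `min_correlation`
   (default 0.4). Correlation with a zero-variance channel is defined as
   0, which forces flat-lined channels to be flagged. The criteria are
   OR-ed. Both thresholds and the window length are configurable.
2. **Interpolation**: each flagged channel is replaced by the unweighted
   mean of its `neighbor_count` (default 4) nearest good scalp channels
   by Euclidean distance on channel positions. When no measured
   positions are available the pipeline uses a synthetic unit-circle
   layout in label order (`ring_positions`) — a geometry stand-in that
   preserves the "nearest neighbors" semantics deterministically; an
   explicit neighbor graph can be passed instead.
3. **Robust average reference**: the per-sample mean over scalp channels
   *not* flagged as noisy is subtracted from **all** scalp channels
   (flagged ones included); non-scalp channels are untouched. After the
   call the retained-channel mean is zero to numerical precision
   (asserted at 1e-9 relative in tests).

The per-recording quality score is `1 − flagged/scalp`, a monotone
summary of how much of the montage needed repair. A recording that
cannot be read yields a `failed` processing record; the run continues
and the failure is visible in both the manifest and the exit status of
the CLI.

## Derived containers and provenance

A derived container records a `FilterDescription` — function name,
ordered name–value parameters, tool version, run timestamp — and embeds
the parent's manifest XML verbatim under a dedicated `parentStudy`
element (self-containment survives file moves; a file reference would
not). `highPass` interprets its `detrendCutoff` parameter as the cutoff
frequency in Hz of a zero-phase 4th-order Butterworth high-pass applied
forward-backward (`sosfiltfilt`), so the effective magnitude response is
the squared Butterworth magnitude — the tests verify the passband and
stopband against that closed form to within 2%. Filters are registered
by name so the CLI can invoke them; a filter that raises on one
recording marks that output `failed` and processing continues, keeping
output count equal to parent recording count.

## Synthetic studies

The generator emulates the raw inputs to containerization. Signals are
1/f-shaped Gaussian noise (spectral amplitude ∝ f^−1/2, DC removed,
normalized to unit variance per channel) plus a 10 Hz sinusoid with
session-specific phase shared by all scalp channels. The shared
amplitude is 2.0, giving pairwise scalp correlation
(A²/2)/(A²/2 + 1) = 2/3 by the closed form — comfortably above the 0.4
detection threshold, as real EEG's common activity is — while leaving
per-channel variance dominated by independent noise. One seeded scalp
channel per recording optionally receives 100× noise variance as a
planted detection target; with these settings it is the only channel
either criterion flags, which the suite verifies on 100 seeded
recordings. Event streams are homogeneous Poisson processes per code
(defaults: `ding` at 0.8/s, `buzz` at 0.2/s — the classic frequent
standard / rare oddball ratio), truncated to the recording and merged in
latency order. Everything (signal bytes, event times, manifest text) is
a pure function of the seed; per-recording streams are seeded by
(seed, session index, stream) so sessions are independent but
reproducible.

Defaults mirror a 24-participant auditory oddball study — 24 sessions
of one recording, 64 scalp + 4 non-scalp channels in a single EEG
modality (`rset_1`) at 1024 Hz — with a 20 s recording duration, the
package's problem-size choice for the worked example: long enough for
≥16 one-second correlation windows and stable robust statistics, small
enough that the full simulate-containerize-validate chain runs in
seconds. Unit tests use an even smaller shape (3 sessions of 8+2
channels at 128 Hz for 8 s).

What the generator does *not* emulate: event-related potentials, sleep
spindles, line noise, electrode drift, realistic scalp topography, or
multimodal payloads. Passing tests therefore demonstrate the
correctness of the containerization, validation, detection criteria and
provenance machinery under controlled statistics — not the clinical
adequacy of the stand-in preprocessing on real EEG.

## Reports and CLI

HTML reports are generated directly from the data model with inline
styles (a stylesheet applied to the XML would be blocked by browser
security rules for local files) and are deterministic given the
manifest. Every number shown is recomputed by `summarize_study` or the
provenance parser; templates never count anything themselves. The `ess`
CLI is a thin layer over the library; exit codes are 0 (success), 1
(validation or processing failure), 2 (usage).

## Known limitations

* Only classic EDF payloads are parsed; other raw formats are carried
  opaquely at Level 1 (duration-dependent checks are then skipped with
  a warning).
* Unknown-element preservation applies to top-level manifest children
  only.
* The HED snapshot is a trimmed vocabulary, not the full public tree;
  the tilde syntax is unsupported.
* The Level-2 stand-in is not a PREP implementation: no RANSAC
  prediction, high-frequency noisiness criterion, or iterative
  re-referencing. The interface accepts a replacement pipeline.
* Containers are processed sequentially; no parallel execution.
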