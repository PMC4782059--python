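# esskit

Containerized packaging, validation and preprocessing of EEG studies.

## The problem

EEG data collected at great expense routinely becomes unusable once the
details needed to process it — which channels are on the scalp, what the
cryptic event codes meant, which preprocessing was already applied — are
lost or forgotten. Pooling studies for large-scale analysis then
requires per-study manual curation. `esskit` addresses this with **data
containers**: a study is a directory with a fixed folder layout and a
single XML manifest (`study_description.xml`) that encodes everything a
downstream pipeline needs, so code written against the container
interface runs unchanged on any containerized study.

Three container levels are supported:

* **Level 1** — raw recordings, one numbered folder per *session* (all
  data from one montage application), files renamed by a convention
  encoding session number, task label and original name, plus one
  tab-separated *event-instance file* per recording (`code`, latency in
  seconds, annotation) so events are readable without opening binary
  payloads.
* **Level 2** — every recording after a standard automated
  preprocessing pass (noisy-channel detection, interpolation, robust
  average reference) with per-recording quality reports.
* **Level-derived** — the result of applying any named filter function
  with name–value parameters to every recording of a parent container.
  Each derived manifest embeds its parent's manifest XML verbatim, so an
  arbitrarily deep processing chain stays a single self-contained,
  fully documented unit.

Events are annotated with **Hierarchical Event Descriptor (HED)** tags:
slash-delimited paths into a tree vocabulary, e.g.
`Participant/Effect/Cognitive/Oddball/Target`. Because the vocabulary is
hierarchical, a query by any ancestor tag (`Participant/Effect/Cognitive/Oddball`)
selects all matching events across studies with no external code table.
Each event code carries a label of at most 20 characters and a category
tag. The manifest deliberately has **no** field for identifying subject
information; subjects are referred to by lab-specific anonymized codes.

## Core operations

* `validate_level1` runs a catalog of 48 named checks (required fields,
  referential integrity, channel-layout consistency, HED validity,
  event-file ordering and durations, …) and auto-fixes minor issues such
  as missing recording UUIDs.
* `create_level1_container` stages, copies and renames raw recordings
  and generates event-instance files; a built container re-validates
  with zero errors.
* `create_level2_container` applies the default preprocessing pipeline.
  A scalp channel is flagged noisy when the robust z-score (median /
  1.4826·MAD across channels) of its robust standard deviation exceeds
  5.0, or when its median-over-windows maximum absolute correlation with
  every other scalp channel falls below 0.4. Flagged channels are
  interpolated from their nearest neighbors, and all scalp channels are
  re-referenced to the mean of the unflagged ones (robust average
  reference).
* `apply_filter_to_container` produces a derived container from a
  registered filter, e.g. `highPass` — a zero-phase 4th-order
  Butterworth high-pass — with its cutoff given as the `detrendCutoff`
  parameter in Hz; `provenance_chain` recovers the full filter history.
* `generate_source_study` creates a fully synthetic source study
  (EDF recordings, event logs, draft manifest). Its default
  configuration reproduces the shape of a classic 24-participant
  auditory oddball experiment: 64 scalp EEG + 4 EOG channels at
  1024 Hz, frequent `ding` / rare `buzz` stimuli.

## Worked example

`examples/04_level2_preprocessing.py` simulates a 3-session study in
which one channel per recording is corrupted with 100× noise variance,
containerizes it and runs the Level-2 pipeline:

```
recording 1: planted=EEG9   flagged=['EEG9'] interpolated=['EEG9'] quality=0.917
recording 2: planted=EEG6   flagged=['EEG6'] interpolated=['EEG6'] quality=0.917
recording 3: planted=EEG4   flagged=['EEG4'] interpolated=['EEG4'] quality=0.917
```

Every recording's planted bad channel is recovered exactly, and the
quality score is 1 − flagged/scalp = 1 − 1/12 ≈ 0.917. The other
examples cover containerization, validation with auto-fixes, HED event
search and provenance chaining; each prints the numbers it computes and
what they mean.

A command-line interface mirrors the library:

```sh
ess simulate --sessions 24 --seed 1 --dest src/
ess containerize src/study_description.xml --source src/ --dest level1/
ess validate level1/study_description.xml --container level1/
ess level2 level1/study_description.xml --dest level2/
ess derive level2/study_description.xml --fn highPass --param detrendCutoff=0.5 --dest derived/
ess report derived/study_description.xml --out report.html
ess search-events level1/study_description.xml --query "Participant/Effect/Cognitive/Oddball"
```

Exit status is 0 on success, 1 on validation/processing errors, 2 on
usage errors.

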