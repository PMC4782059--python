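"""Catalog-driven validation of Level-1 manifests and containers.

Validation runs a catalog of named checks over a manifest (plus, when a
container root is given, over the container's files) and returns issues
as data rather than exceptions.  A small set of checks auto-fix what they
find — currently generation of missing study/recording UUIDs — and report
a ``fixed`` issue instead of an error.  Severity policy: referential or
structural breaks are errors; absent optional metadata is a warning.

Duration-dependent file checks are skipped with a warning when the raw
recording cannot be read.
"""

from __future__ import annotations

import uuid as uuid_module
from dataclasses import dataclass, field
from pathlib import Path

from . import edf as edf_module
from .hed import (
    MAX_EVENT_LABEL_LENGTH,
    HedHierarchy,
    HedString,
    default_hierarchy,
    validate_hed_string,
)
from .model import (
    StudyLevel1Manifest,
    deep_copy_manifest,
    is_filesystem_safe,
    is_uuid_text,
    manifest_schema,
    manifest_to_element,
)

__all__ = [
    "ValidationIssue",
    "CheckDescriptor",
    "check_catalog",
    "validate_level1",
    "has_errors",
]

SEVERITIES = ("error", "warning", "fixed")


@dataclass(frozen=True)
class ValidationIssue:
    check_id: str
    severity: str  # error | warning | fixed
    location: str  # element path text
    message: str

    def as_tsv(self) -> str:
        return "\t".join((self.severity, self.check_id, self.location, self.message))


@dataclass(frozen=True)
class CheckDescriptor:
    check_id: str
    description: str
    severity: str
    auto_fix: bool = False
    needs_container: bool = False


@dataclass
class _Ctx:
    manifest: StudyLevel1Manifest
    container_root: Path | None
    hierarchy: HedHierarchy
    issues: list[ValidationIssue] = field(default_factory=list)
    current: CheckDescriptor | None = None
    #: per-recording durations read from EDF headers (None = unreadable)
    durations: dict[str, float | None] = field(default_factory=dict)

    def add(self, location: str, message: str, severity: str | None = None) -> None:
        assert self.current is not None
        self.issues.append(
            ValidationIssue(
                check_id=self.current.check_id,
                severity=severity or self.current.severity,
                location=location,
                message=message,
            )
        )

    def session_dir(self, number: int) -> Path:
        assert self.container_root is not None
        return self.container_root / "session" / str(number)


_REGISTRY: list[tuple[CheckDescriptor, callable]] = []


def _check(
    check_id: str,
    description: str,
    severity: str = "error",
    auto_fix: bool = False,
    needs_container: bool = False,
):
    desc = CheckDescriptor(check_id, description, severity, auto_fix, needs_container)

    def deco(fn):
        _REGISTRY.append((desc, fn))
        return fn

    return deco


def check_catalog() -> list[CheckDescriptor]:
    """All registered checks, in execution order."""
    return [d for d, _ in _REGISTRY]


# ---------------------------------------------------------------------------
# Study-level checks


@_check("title-present", "The study has a non-empty title.")
def _c_title(m: StudyLevel1Manifest, ctx: _Ctx) -> None:
    if not m.title.strip():
        ctx.add("studyLevel1/title", "study title is empty")


@_check("description-present", "The study has a description.", "warning")
def _c_description(m, ctx) -> None:
    if not m.description.strip():
        ctx.add("studyLevel1/description", "study description is empty")


@_check("ess-version-present", "The manifest declares its schema version.")
def _c_version(m, ctx) -> None:
    if not m.ess_version.strip():
        ctx.add("studyLevel1/essVersion", "essVersion is empty")


@_check("study-uuid-present", "The study has a UUID (generated when missing).",
        "fixed", auto_fix=True)
def _c_study_uuid(m, ctx) -> None:
    if not m.study_uuid.strip():
        m.study_uuid = str(uuid_module.uuid4())
        ctx.add("studyLevel1/studyUuid", "missing study UUID generated")


@_check("study-uuid-format", "The study UUID is a lowercase hyphenated UUID.")
def _c_study_uuid_fmt(m, ctx) -> None:
    if m.study_uuid and not is_uuid_text(m.study_uuid):
        ctx.add("studyLevel1/studyUuid", f"'{m.study_uuid}' is not a valid UUID")


@_check("point-of-contact-present", "A point of contact is given.", "warning")
def _c_poc(m, ctx) -> None:
    if not m.point_of_contact.strip():
        ctx.add("studyLevel1/pointOfContact", "no point of contact")


# ---------------------------------------------------------------------------
# Tasks


@_check("tasks-present", "At least one task is defined.")
def _c_tasks_present(m, ctx) -> None:
    if not m.tasks:
        ctx.add("studyLevel1/tasks", "no tasks defined")


@_check("task-label-nonempty", "Every task has a non-empty label.")
def _c_task_label(m, ctx) -> None:
    for i, t in enumerate(m.tasks):
        if not t.task_label:
            ctx.add(f"tasks/task[{i + 1}]", "task label is empty")


@_check("task-label-filesystem-safe",
        "Task labels use only letters, digits, hyphen and underscore.")
def _c_task_safe(m, ctx) -> None:
    for i, t in enumerate(m.tasks):
        if t.task_label and not is_filesystem_safe(t.task_label):
            ctx.add(
                f"tasks/task[{i + 1}]",
                f"task label '{t.task_label}' contains unsafe characters",
            )


@_check("task-label-unique", "Task labels are unique.")
def _c_task_unique(m, ctx) -> None:
    seen: set[str] = set()
    for i, t in enumerate(m.tasks):
        if t.task_label in seen:
            ctx.add(f"tasks/task[{i + 1}]", f"duplicate task label '{t.task_label}'")
        seen.add(t.task_label)


# ---------------------------------------------------------------------------
# Sessions


@_check("sessions-present", "The study contains at least one session.", "warning")
def _c_sessions_present(m, ctx) -> None:
    if not m.sessions:
        ctx.add("studyLevel1/sessions", "study has no sessions")


@_check("session-number-positive", "Session numbers are positive integers.")
def _c_session_number(m, ctx) -> None:
    for i, s in enumerate(m.sessions):
        if s.number < 1:
            ctx.add(f"sessions/session[{i + 1}]/number",
                    f"session number {s.number} is not >= 1")


@_check("session-number-unique", "Session numbers are unique.")
def _c_session_unique(m, ctx) -> None:
    seen: set[int] = set()
    for i, s in enumerate(m.sessions):
        if s.number in seen:
            ctx.add(f"sessions/session[{i + 1}]/number",
                    f"duplicate session number {s.number}")
        seen.add(s.number)


@_check("session-task-ref", "Session task labels reference defined tasks.")
def _c_session_task_ref(m, ctx) -> None:
    if not m.tasks:
        return  # tasks-present already fired; avoid cascading
    labels = {t.task_label for t in m.tasks}
    for i, s in enumerate(m.sessions):
        if s.task_label not in labels:
            ctx.add(f"sessions/session[{i + 1}]/taskLabel",
                    f"unknown task '{s.task_label}'")


@_check("session-has-subject", "Every session records at least one subject.")
def _c_session_subject(m, ctx) -> None:
    for i, s in enumerate(m.sessions):
        if not s.subjects:
            ctx.add(f"sessions/session[{i + 1}]/subjects", "session has no subjects")


@_check("session-has-recording", "Every session has at least one data recording.")
def _c_session_recording(m, ctx) -> None:
    for i, s in enumerate(m.sessions):
        if not s.data_recordings:
            ctx.add(f"sessions/session[{i + 1}]/dataRecordings",
                    "session has no data recordings")


@_check("subject-labid-present", "Subjects carry an anonymized lab id.", "warning")
def _c_subject_labid(m, ctx) -> None:
    for i, s in enumerate(m.sessions):
        for j, subj in enumerate(s.subjects):
            if not subj.lab_id.strip():
                ctx.add(
                    f"sessions/session[{i + 1}]/subjects/subject[{j + 1}]/labId",
                    "subject has no lab id",
                )


# ---------------------------------------------------------------------------
# Recording parameter sets


@_check("parameter-sets-present", "At least one recording parameter set exists.")
def _c_psets_present(m, ctx) -> None:
    if not m.recording_parameter_sets:
        ctx.add("studyLevel1/recordingParameterSets",
                "no recording parameter sets defined")


@_check("parameter-set-id-unique", "Recording parameter set ids are unique.")
def _c_pset_unique(m, ctx) -> None:
    seen: set[str] = set()
    for i, ps in enumerate(m.recording_parameter_sets):
        if ps.id in seen:
            ctx.add(f"recordingParameterSets/recordingParameterSet[{i + 1}]",
                    f"duplicate parameter set id '{ps.id}'")
        seen.add(ps.id)


@_check("parameter-set-has-modality", "Every parameter set has >= 1 modality.")
def _c_pset_modality(m, ctx) -> None:
    for i, ps in enumerate(m.recording_parameter_sets):
        if not ps.modalities:
            ctx.add(f"recordingParameterSets/recordingParameterSet[{i + 1}]",
                    f"parameter set '{ps.id}' has no modalities")


def _ranges_valid(ps) -> bool:
    return all(1 <= mod.start_channel <= mod.end_channel for mod in ps.modalities)


@_check("modality-channel-range",
        "Modality channel ranges satisfy 1 <= start <= end.")
def _c_mod_range(m, ctx) -> None:
    for ps in m.recording_parameter_sets:
        for j, mod in enumerate(ps.modalities):
            if not 1 <= mod.start_channel <= mod.end_channel:
                ctx.add(
                    f"recordingParameterSet[{ps.id}]/modality[{j + 1}]",
                    f"invalid channel range {mod.start_channel}..{mod.end_channel}",
                )


@_check("modality-ranges-disjoint", "Modality channel ranges do not overlap.")
def _c_mod_disjoint(m, ctx) -> None:
    for ps in m.recording_parameter_sets:
        if not _ranges_valid(ps):
            continue  # modality-channel-range already fired
        spans = sorted(
            (mod.start_channel, mod.end_channel) for mod in ps.modalities
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                ctx.add(
                    f"recordingParameterSet[{ps.id}]",
                    f"channel ranges {s1}..{e1} and {s2}..{e2} overlap",
                )


@_check("modality-ranges-contiguous",
        "Modality ranges tile channels 1..N without gaps.")
def _c_mod_contiguous(m, ctx) -> None:
    for ps in m.recording_parameter_sets:
        if not ps.modalities or not _ranges_valid(ps):
            continue
        spans = sorted(
            (mod.start_channel, mod.end_channel) for mod in ps.modalities
        )
        if any(s2 <= e1 for (_, e1), (s2, _) in zip(spans, spans[1:])):
            continue  # overlapping: disjointness check owns this
        expected = 1
        ok = True
        for s, e in spans:
            if s != expected:
                ok = False
                break
            expected = e + 1
        if not ok:
            ctx.add(
                f"recordingParameterSet[{ps.id}]",
                f"modality ranges {spans} do not form a contiguous 1..N block",
            )


@_check("channel-label-count",
        "Channel label count equals the modality's channel range size.")
def _c_label_count(m, ctx) -> None:
    for ps in m.recording_parameter_sets:
        for j, mod in enumerate(ps.modalities):
            if not 1 <= mod.start_channel <= mod.end_channel:
                continue
            if len(mod.channel_labels) != mod.channel_count:
                ctx.add(
                    f"recordingParameterSet[{ps.id}]/modality[{j + 1}]",
                    f"{len(mod.channel_labels)} channel labels for "
                    f"{mod.channel_count} channels",
                )


@_check("sampling-rate-positive", "Modality sampling rates are > 0.")
def _c_rate(m, ctx) -> None:
    for ps in m.recording_parameter_sets:
        for j, mod in enumerate(ps.modalities):
            if not mod.sampling_rate > 0:
                ctx.add(
                    f"recordingParameterSet[{ps.id}]/modality[{j + 1}]/samplingRate",
                    f"sampling rate {mod.sampling_rate} is not positive",
                )


@_check("non-scalp-subset",
        "Non-scalp channel labels are a subset of the channel labels.")
def _c_nonscalp(m, ctx) -> None:
    for ps in m.recording_parameter_sets:
        for j, mod in enumerate(ps.modalities):
            extra = set(mod.non_scalp_channel_labels) - set(mod.channel_labels)
            if extra:
                ctx.add(
                    f"recordingParameterSet[{ps.id}]/modality[{j + 1}]",
                    f"non-scalp labels {sorted(extra)} are not channel labels",
                )


@_check("channel-location-info",
        "Channel locations: a standard montage is declared or location files "
        "are provided.", "warning")
def _c_chanloc(m, ctx) -> None:
    for ps in m.recording_parameter_sets:
        for j, mod in enumerate(ps.modalities):
            if mod.type != "EEG":
                continue
            if mod.channel_location_type not in ("", "n/a", "Custom"):
                continue  # standard montage declared
            any_file = any(
                subj.channel_location_file
                for s in m.sessions
                for subj in s.subjects
                for rec in s.data_recordings
                if rec.parameter_set_id == ps.id
            )
            if not any_file:
                ctx.add(
                    f"recordingParameterSet[{ps.id}]/modality[{j + 1}]",
                    "no standard montage declared and no channel location files",
                )


# ---------------------------------------------------------------------------
# Data recordings


@_check("recording-parameter-set-ref",
        "Data recordings reference an existing parameter set.")
def _c_rec_pset_ref(m, ctx) -> None:
    if not m.recording_parameter_sets:
        return  # parameter-sets-present already fired
    ids = {ps.id for ps in m.recording_parameter_sets}
    for i, s in enumerate(m.sessions):
        for j, rec in enumerate(s.data_recordings):
            if rec.parameter_set_id not in ids:
                ctx.add(
                    f"sessions/session[{i + 1}]/dataRecording[{j + 1}]",
                    f"unknown recording parameter set '{rec.parameter_set_id}'",
                )


@_check("recording-uuid-present",
        "Data recordings have a UUID (generated when missing).",
        "fixed", auto_fix=True)
def _c_rec_uuid(m, ctx) -> None:
    for i, s in enumerate(m.sessions):
        for j, rec in enumerate(s.data_recordings):
            if not rec.uuid.strip():
                rec.uuid = str(uuid_module.uuid4())
                ctx.add(
                    f"sessions/session[{i + 1}]/dataRecording[{j + 1}]/uuid",
                    "missing data recording UUID generated",
                )


@_check("recording-uuid-format", "Recording UUIDs are well-formed.")
def _c_rec_uuid_fmt(m, ctx) -> None:
    for i, s in enumerate(m.sessions):
        for j, rec in enumerate(s.data_recordings):
            if rec.uuid and not is_uuid_text(rec.uuid):
                ctx.add(
                    f"sessions/session[{i + 1}]/dataRecording[{j + 1}]/uuid",
                    f"'{rec.uuid}' is not a valid UUID",
                )


@_check("recording-uuid-unique", "Recording UUIDs are unique across the study.")
def _c_rec_uuid_unique(m, ctx) -> None:
    seen: set[str] = set()
    for i, s in enumerate(m.sessions):
        for j, rec in enumerate(s.data_recordings):
            if rec.uuid and rec.uuid in seen:
                ctx.add(
                    f"sessions/session[{i + 1}]/dataRecording[{j + 1}]/uuid",
                    f"duplicate recording UUID '{rec.uuid}'",
                )
            seen.add(rec.uuid)


@_check("ess-filename-conformity",
        "Filled essFilename values follow the ESS naming convention.")
def _c_ess_name(m, ctx) -> None:
    for i, s in enumerate(m.sessions):
        for j, rec in enumerate(s.data_recordings):
            if not rec.ess_filename:
                continue
            prefix = f"eeg_session_{s.number}_{s.task_label}_"
            if not rec.ess_filename.startswith(prefix):
                ctx.add(
                    f"sessions/session[{i + 1}]/dataRecording[{j + 1}]/essFilename",
                    f"'{rec.ess_filename}' does not follow "
                    f"{prefix}<original>",
                )


# ---------------------------------------------------------------------------
# Event-code mappings


@_check("event-mapping-task-ref", "Event-code mappings reference defined tasks.")
def _c_map_task_ref(m, ctx) -> None:
    if not m.tasks:
        return
    labels = {t.task_label for t in m.tasks}
    for i, em in enumerate(m.event_code_mappings):
        if em.task_label not in labels:
            ctx.add(f"eventCodeMappings/eventCodeMapping[{i + 1}]",
                    f"unknown task '{em.task_label}'")


@_check("event-code-nonempty", "Event codes are non-empty.")
def _c_code_nonempty(m, ctx) -> None:
    for i, em in enumerate(m.event_code_mappings):
        if not em.code:
            ctx.add(f"eventCodeMappings/eventCodeMapping[{i + 1}]/code",
                    "event code is empty")


@_check("event-code-length",
        f"Event codes (labels) are at most {MAX_EVENT_LABEL_LENGTH} characters.")
def _c_code_length(m, ctx) -> None:
    for i, em in enumerate(m.event_code_mappings):
        if len(em.code) > MAX_EVENT_LABEL_LENGTH:
            ctx.add(
                f"eventCodeMappings/eventCodeMapping[{i + 1}]/code",
                f"label '{em.code}' has {len(em.code)} characters "
                f"(limit {MAX_EVENT_LABEL_LENGTH})",
            )


@_check("event-category-present", "Every event code carries a category tag.")
def _c_category(m, ctx) -> None:
    for i, em in enumerate(m.event_code_mappings):
        if em.category is None:
            ctx.add(f"eventCodeMappings/eventCodeMapping[{i + 1}]/category",
                    f"event code '{em.code}' has no category tag")


@_check("event-hed-parses", "Event HED strings parse.")
def _c_hed_parses(m, ctx) -> None:
    for i, em in enumerate(m.event_code_mappings):
        if isinstance(em.hed_string, str):  # reader kept raw unparseable text
            ctx.add(
                f"eventCodeMappings/eventCodeMapping[{i + 1}]/hedString",
                f"HED string for code '{em.code}' does not parse: "
                f"'{em.hed_string}'",
            )


@_check("event-hed-vocab",
        "Event HED tags resolve in the vocabulary (or extend legally).",
        "warning")
def _c_hed_vocab(m, ctx) -> None:
    for i, em in enumerate(m.event_code_mappings):
        if not isinstance(em.hed_string, HedString):
            continue  # unparseable handled by event-hed-parses
        for issue in validate_hed_string(em.hed_string, ctx.hierarchy):
            ctx.add(
                f"eventCodeMappings/eventCodeMapping[{i + 1}]/hedString",
                issue.message,
            )
        if em.category is not None:
            for issue in validate_hed_string(HedString([em.category]), ctx.hierarchy):
                ctx.add(
                    f"eventCodeMappings/eventCodeMapping[{i + 1}]/category",
                    issue.message,
                )


@_check("event-mapping-coverage",
        "Every task that has sessions also has event-code mappings.", "warning")
def _c_coverage(m, ctx) -> None:
    mapped = {em.task_label for em in m.event_code_mappings}
    session_tasks = {s.task_label for s in m.sessions}
    for t in m.tasks:
        if t.task_label in session_tasks and t.task_label not in mapped:
            ctx.add(f"tasks/task[{t.task_label}]",
                    f"task '{t.task_label}' has sessions but no event-code mappings")


# ---------------------------------------------------------------------------
# Schema conformance


@_check("xml-schema-conformance",
        "The serialized manifest validates against the pinned XSD.")
def _c_schema(m, ctx) -> None:
    doc = manifest_to_element(m)
    schema = manifest_schema()
    if not schema.validate(doc):
        first = schema.error_log[0]
        ctx.add("studyLevel1", f"schema violation: {first.message}")


# ---------------------------------------------------------------------------
# Container (file-level) checks — run only when a container root is given


def _iter_recordings(m):
    for i, s in enumerate(m.sessions):
        for j, rec in enumerate(s.data_recordings):
            yield i, s, j, rec


@_check("container-data-file-exists",
        "Every essFilename resolves to a file in its session directory.",
        needs_container=True)
def _c_file_exists(m, ctx) -> None:
    for i, s, j, rec in _iter_recordings(m):
        if not rec.ess_filename:
            ctx.add(
                f"sessions/session[{i + 1}]/dataRecording[{j + 1}]/essFilename",
                "essFilename is empty in a built container",
            )
            continue
        if not (ctx.session_dir(s.number) / rec.ess_filename).is_file():
            ctx.add(
                f"sessions/session[{i + 1}]/dataRecording[{j + 1}]/essFilename",
                f"file '{rec.ess_filename}' not found in session {s.number}",
            )


@_check("event-file-exists",
        "Every recording has its event-instance file on disk.",
        needs_container=True)
def _c_event_file_exists(m, ctx) -> None:
    for i, s, j, rec in _iter_recordings(m):
        if not rec.event_instance_filename or not (
            ctx.session_dir(s.number) / rec.event_instance_filename
        ).is_file():
            ctx.add(
                f"sessions/session[{i + 1}]/dataRecording[{j + 1}]"
                "/eventInstanceFilename",
                f"event file '{rec.event_instance_filename}' missing "
                f"in session {s.number}",
            )


def _event_rows(ctx, s, rec):
    """Parsed (code, latency) rows of a recording's event file, or None."""
    path = ctx.session_dir(s.number) / rec.event_instance_filename
    if not rec.event_instance_filename or not path.is_file():
        return None
    rows = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            return "malformed"
        try:
            rows.append((cols[0], float(cols[1])))
        except ValueError:
            return "malformed"
    return rows


@_check("event-file-well-formed",
        "Event files have three tab-separated columns per line.",
        needs_container=True)
def _c_event_wellformed(m, ctx) -> None:
    for i, s, j, rec in _iter_recordings(m):
        if _event_rows(ctx, s, rec) == "malformed":
            ctx.add(
                f"sessions/session[{i + 1}]/dataRecording[{j + 1}]",
                f"event file '{rec.event_instance_filename}' has malformed lines",
            )


@_check("event-latency-nonneg", "Event latencies are >= 0.", needs_container=True)
def _c_latency_nonneg(m, ctx) -> None:
    for i, s, j, rec in _iter_recordings(m):
        rows = _event_rows(ctx, s, rec)
        if rows is None or rows == "malformed":
            continue
        for code, lat in rows:
            if lat < 0:
                ctx.add(
                    f"sessions/session[{i + 1}]/dataRecording[{j + 1}]",
                    f"event '{code}' has negative latency {lat}",
                )


@_check("event-latency-sorted", "Event files are sorted by ascending latency.",
        needs_container=True)
def _c_latency_sorted(m, ctx) -> None:
    for i, s, j, rec in _iter_recordings(m):
        rows = _event_rows(ctx, s, rec)
        if rows is None or rows == "malformed":
            continue
        lats = [lat for _, lat in rows]
        if any(b < a for a, b in zip(lats, lats[1:])):
            ctx.add(
                f"sessions/session[{i + 1}]/dataRecording[{j + 1}]",
                f"event file '{rec.event_instance_filename}' is not sorted",
            )


@_check("event-latency-within-duration",
        "Event latencies do not exceed the recording duration.",
        needs_container=True)
def _c_latency_duration(m, ctx) -> None:
    for i, s, j, rec in _iter_recordings(m):
        rows = _event_rows(ctx, s, rec)
        if rows is None or rows == "malformed" or not rows:
            continue
        path = ctx.session_dir(s.number) / rec.ess_filename
        if rec.uuid not in ctx.durations:
            try:
                ctx.durations[rec.uuid] = edf_module.read_edf_header(
                    path
                ).duration_seconds
            except Exception:
                ctx.durations[rec.uuid] = None
        duration = ctx.durations[rec.uuid]
        loc = f"sessions/session[{i + 1}]/dataRecording[{j + 1}]"
        if duration is None:
            ctx.add(
                loc,
                f"recording '{rec.ess_filename}' unreadable; "
                "latency-vs-duration check skipped",
                severity="warning",
            )
            continue
        for code, lat in rows:
            if lat > duration:
                ctx.add(
                    loc,
                    f"event '{code}' at {lat} s exceeds recording duration "
                    f"{duration} s",
                )


@_check("event-codes-mapped",
        "Every code in an event file has a mapping for the session's task.",
        needs_container=True)
def _c_codes_mapped(m, ctx) -> None:
    for i, s, j, rec in _iter_recordings(m):
        rows = _event_rows(ctx, s, rec)
        if rows is None or rows == "malformed":
            continue
        mapped = {em.code for em in m.mappings_for_task(s.task_label)}
        unknown = sorted({code for code, _ in rows} - mapped)
        if unknown:
            ctx.add(
                f"sessions/session[{i + 1}]/dataRecording[{j + 1}]",
                f"codes {unknown} have no mapping for task '{s.task_label}'",
            )


@_check("channel-location-file-exists",
        "Declared channel-location files exist in the container.",
        needs_container=True)
def _c_chanloc_file(m, ctx) -> None:
    for i, s in enumerate(m.sessions):
        for j, subj in enumerate(s.subjects):
            if not subj.channel_location_file:
                continue
            if not (ctx.session_dir(s.number) / subj.channel_location_file).is_file():
                ctx.add(
                    f"sessions/session[{i + 1}]/subjects/subject[{j + 1}]"
                    "/channelLocationFile",
                    f"channel location file '{subj.channel_location_file}' "
                    f"missing in session {s.number}",
                )


# ---------------------------------------------------------------------------
# Driver


def validate_level1(
    m: StudyLevel1Manifest,
    container_root: str | Path | None = None,
    hierarchy: HedHierarchy | None = None,
) -> tuple[list[ValidationIssue], StudyLevel1Manifest]:
    """Run the full catalog; return (issues, fixed manifest).

    The input manifest is never mutated; auto-fixes are applied to a deep
    copy which is returned.  File-level checks run only when
    *container_root* is given.
    """
    fixed = deep_copy_manifest(m)
    ctx = _Ctx(
        manifest=fixed,
        container_root=Path(container_root) if container_root is not None else None,
        hierarchy=hierarchy or default_hierarchy(),
    )
    for desc, fn in _REGISTRY:
        if desc.needs_container and ctx.container_root is None:
            continue
        ctx.current = desc
        fn(fixed, ctx)
    ctx.current = None
    return ctx.issues, fixed


def has_errors(issues: list[ValidationIssue]) -> bool:
    return any(i.severity == "error" for i in issues)


def issues_as_tsv(issues: list[ValidationIssue]) -> str:
    """Machine-readable issue list: severity, checkId, location, message."""
    return "\n".join(i.as_tsv() for i in issues) + ("\n" if issues else "")
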