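"""Domain types for a Level-1 study and the XML manifest reader/writer.

The manifest (``study_description.xml``) is the container's header: it
encodes tasks, recording parameter sets (channel layouts grouped into
modalities), sessions with subjects and data recordings, and the mapping
from experiment event codes to HED annotations.  The element dialect is
lowerCamelCase and pinned by the XSD shipped as package data; reading a
written manifest reproduces the in-memory value field for field.

Serialization policy: optional fields are emitted as empty elements, not
omitted, so that a round-trip is canonical; unknown top-level elements of
a foreign manifest are preserved verbatim and re-emitted on write.
"""

from __future__ import annotations

import copy
import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Union

from lxml import etree

from .errors import ManifestError
from .hed import EventCodeMapping, HedString, HedTag, parse_hed_string, parse_hed_tag

__all__ = [
    "Modality",
    "RecordingParameterSet",
    "TaskSpec",
    "SubjectRecord",
    "DataRecording",
    "SessionRecord",
    "EventInstance",
    "StudyLevel1Manifest",
    "StudySummary",
    "read_level1_manifest",
    "write_level1_manifest",
    "summarize_study",
    "manifest_schema",
]

ESS_VERSION = "2.0"

MODALITY_TYPES = ("EEG", "EOG", "GSR", "ECG", "Mocap", "EyeTracking", "Other")

_UUID_RE = re.compile(
    r"^[0-9a-f]{8}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{12}$"
)
_SAFE_LABEL_RE = re.compile(r"^[A-Za-z0-9_-]+$")


def is_uuid_text(s: str) -> bool:
    return bool(_UUID_RE.match(s))


def is_filesystem_safe(label: str) -> bool:
    return bool(_SAFE_LABEL_RE.match(label))


# ---------------------------------------------------------------------------
# Types


@dataclass
class TaskSpec:
    task_label: str
    description: str = ""


@dataclass
class Modality:
    """A contiguous block of consecutively numbered channels of one kind."""

    type: str = "EEG"
    start_channel: int = 1
    end_channel: int = 1
    sampling_rate: float = 0.0
    channel_labels: list[str] = field(default_factory=list)
    non_scalp_channel_labels: list[str] = field(default_factory=list)
    channel_location_type: str = "n/a"  # "10-20" | "Custom" | "n/a"
    reference_label: str = ""

    @property
    def channel_count(self) -> int:
        return self.end_channel - self.start_channel + 1


@dataclass
class RecordingParameterSet:
    """Channel-layout description shared by one or more data recordings."""

    id: str
    modalities: list[Modality] = field(default_factory=list)


@dataclass
class SubjectRecord:
    """Anonymized subject metadata.

    Deliberately contains no identifying field (no name, address, email,
    phone or national-id anywhere in the schema); subjects are referred
    to only by lab-specific anonymized codes.
    """

    lab_id: str = ""
    group: str = ""
    gender: str = ""
    age: float | None = None
    hand: str = ""
    height: float | None = None
    weight: float | None = None
    medication: str = ""
    channel_location_file: str = ""


@dataclass
class DataRecording:
    uuid: str = ""
    original_file_name_and_path: str = ""
    ess_filename: str = ""
    event_instance_filename: str = ""
    parameter_set_id: str = ""
    start_date_time: str = ""


@dataclass
class SessionRecord:
    number: int = 1
    task_label: str = ""
    subjects: list[SubjectRecord] = field(default_factory=list)
    notes: str = ""
    data_recordings: list[DataRecording] = field(default_factory=list)


@dataclass
class EventInstance:
    """One row of an event-instance file: code, latency, HED annotation."""

    code: str
    latency: float  # seconds from recording start
    hed_string: HedString | None = None


@dataclass
class StudyLevel1Manifest:
    title: str = ""
    description: str = ""
    ess_version: str = ESS_VERSION
    study_uuid: str = ""
    publications: str = ""
    point_of_contact: str = ""
    license: str = ""
    tasks: list[TaskSpec] = field(default_factory=list)
    recording_parameter_sets: list[RecordingParameterSet] = field(default_factory=list)
    sessions: list[SessionRecord] = field(default_factory=list)
    event_code_mappings: list[EventCodeMapping] = field(default_factory=list)
    #: unknown top-level elements of a foreign manifest, preserved verbatim
    extra_xml: list[str] = field(default_factory=list)

    # convenience lookups -------------------------------------------------
    def parameter_set(self, set_id: str) -> RecordingParameterSet | None:
        for ps in self.recording_parameter_sets:
            if ps.id == set_id:
                return ps
        return None

    def task(self, label: str) -> TaskSpec | None:
        for t in self.tasks:
            if t.task_label == label:
                return t
        return None

    def mappings_for_task(self, label: str) -> list[EventCodeMapping]:
        return [m for m in self.event_code_mappings if m.task_label == label]


# ---------------------------------------------------------------------------
# XML helpers

_PathLike = Union[str, Path]


def _text(parent: etree._Element, name: str) -> str:
    el = parent.find(name)
    return (el.text or "").strip() if el is not None else ""


def _raw_text(parent: etree._Element, name: str) -> str:
    """Untrimmed element text (used for free-text fields like notes)."""
    el = parent.find(name)
    return el.text or "" if el is not None else ""


def _sub(parent: etree._Element, name: str, text: str = "") -> etree._Element:
    el = etree.SubElement(parent, name)
    el.text = text
    return el


def _fmt_float(v: float | None) -> str:
    if v is None:
        return ""
    return repr(float(v))


def _parse_float(s: str, where: str) -> float | None:
    if not s:
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise ManifestError(f"{where}: '{s}' is not a number") from exc


def _parse_int(s: str, where: str) -> int:
    try:
        return int(s)
    except ValueError as exc:
        raise ManifestError(f"{where}: '{s}' is not an integer") from exc


_KNOWN_TOP = {
    "title",
    "description",
    "essVersion",
    "studyUuid",
    "publications",
    "pointOfContact",
    "license",
    "tasks",
    "recordingParameterSets",
    "eventCodeMappings",
    "sessions",
}


# ---------------------------------------------------------------------------
# Reading


def read_level1_manifest(source: _PathLike | IO[bytes]) -> StudyLevel1Manifest:
    """Read a Level-1 manifest document.

    Raises :class:`ManifestError` for malformed XML or a missing required
    element (``title``, ``essVersion``, ``sessions``).  Semantic problems
    (dangling references, bad ranges, ...) are left to the validator so a
    draft manifest can always be loaded and repaired.
    """
    try:
        tree = etree.parse(str(source) if isinstance(source, (str, Path)) else source)
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ManifestError(f"cannot parse manifest: {exc}") from exc
    root = tree.getroot()
    if root.tag != "studyLevel1":
        raise ManifestError(
            f"expected root element 'studyLevel1', found '{root.tag}'"
        )
    for required in ("title", "essVersion", "sessions"):
        if root.find(required) is None:
            raise ManifestError(f"missing required element 'studyLevel1/{required}'")

    m = StudyLevel1Manifest(
        title=_raw_text(root, "title"),
        description=_raw_text(root, "description"),
        ess_version=_text(root, "essVersion"),
        study_uuid=_text(root, "studyUuid"),
        publications=_raw_text(root, "publications"),
        point_of_contact=_raw_text(root, "pointOfContact"),
        license=_raw_text(root, "license"),
    )

    tasks = root.find("tasks")
    if tasks is not None:
        for t in tasks.findall("task"):
            m.tasks.append(
                TaskSpec(
                    task_label=_text(t, "taskLabel"),
                    description=_raw_text(t, "description"),
                )
            )

    psets = root.find("recordingParameterSets")
    if psets is not None:
        for ps in psets.findall("recordingParameterSet"):
            rset = RecordingParameterSet(id=_text(ps, "recordingParameterSetId"))
            for mod in ps.findall("modality"):
                where = f"recordingParameterSet {rset.id}/modality"
                rset.modalities.append(
                    Modality(
                        type=_text(mod, "type"),
                        start_channel=_parse_int(
                            _text(mod, "startChannel") or "0", where
                        ),
                        end_channel=_parse_int(_text(mod, "endChannel") or "0", where),
                        sampling_rate=_parse_float(_text(mod, "samplingRate"), where)
                        or 0.0,
                        channel_labels=[
                            (c.text or "").strip()
                            for c in mod.findall("channelLabels/channelLabel")
                        ],
                        non_scalp_channel_labels=[
                            (c.text or "").strip()
                            for c in mod.findall(
                                "nonScalpChannelLabels/channelLabel"
                            )
                        ],
                        channel_location_type=_text(mod, "channelLocationType"),
                        reference_label=_text(mod, "referenceLabel"),
                    )
                )
            m.recording_parameter_sets.append(rset)

    mappings = root.find("eventCodeMappings")
    if mappings is not None:
        for em in mappings.findall("eventCodeMapping"):
            cat_text = _text(em, "category")
            hed_text = _text(em, "hedString")
            category: HedTag | None = None
            if cat_text:
                try:
                    category = parse_hed_tag(cat_text)
                except Exception:
                    category = None
            hed: HedString | str | None = None
            if hed_text:
                try:
                    hed = parse_hed_string(hed_text)
                except Exception:
                    hed = hed_text  # kept raw; validator flags it
            m.event_code_mappings.append(
                EventCodeMapping(
                    task_label=_text(em, "taskLabel"),
                    code=_text(em, "code"),
                    category=category,
                    hed_string=hed,
                    description=_raw_text(em, "description"),
                )
            )

    sessions = root.find("sessions")
    if sessions is not None:
        for s in sessions.findall("session"):
            sess = SessionRecord(
                number=_parse_int(_text(s, "number") or "0", "session/number"),
                task_label=_text(s, "taskLabel"),
                notes=_raw_text(s, "notes"),
            )
            for subj in s.findall("subjects/subject"):
                sess.subjects.append(
                    SubjectRecord(
                        lab_id=_text(subj, "labId"),
                        group=_text(subj, "group"),
                        gender=_text(subj, "gender"),
                        age=_parse_float(_text(subj, "age"), "subject/age"),
                        hand=_text(subj, "hand"),
                        height=_parse_float(_text(subj, "height"), "subject/height"),
                        weight=_parse_float(_text(subj, "weight"), "subject/weight"),
                        medication=_raw_text(subj, "medication"),
                        channel_location_file=_text(subj, "channelLocationFile"),
                    )
                )
            for rec in s.findall("dataRecordings/dataRecording"):
                sess.data_recordings.append(
                    DataRecording(
                        uuid=_text(rec, "uuid"),
                        original_file_name_and_path=_text(
                            rec, "originalFileNameAndPath"
                        ),
                        ess_filename=_text(rec, "essFilename"),
                        event_instance_filename=_text(rec, "eventInstanceFilename"),
                        parameter_set_id=_text(rec, "recordingParameterSetId"),
                        start_date_time=_text(rec, "startDateTime"),
                    )
                )
            m.sessions.append(sess)

    for child in root:
        if not isinstance(child.tag, str):
            continue  # comments
        if child.tag not in _KNOWN_TOP:
            clone = copy.deepcopy(child)
            clone.tail = None  # drop pretty-printing whitespace
            m.extra_xml.append(etree.tostring(clone, encoding="unicode"))
    return m


# ---------------------------------------------------------------------------
# Writing


def manifest_to_element(m: StudyLevel1Manifest) -> etree._Element:
    root = etree.Element("studyLevel1")
    _sub(root, "title", m.title)
    _sub(root, "description", m.description)
    _sub(root, "essVersion", m.ess_version)
    _sub(root, "studyUuid", m.study_uuid)
    _sub(root, "publications", m.publications)
    _sub(root, "pointOfContact", m.point_of_contact)
    _sub(root, "license", m.license)

    tasks = etree.SubElement(root, "tasks")
    for t in m.tasks:
        te = etree.SubElement(tasks, "task")
        _sub(te, "taskLabel", t.task_label)
        _sub(te, "description", t.description)

    psets = etree.SubElement(root, "recordingParameterSets")
    for ps in m.recording_parameter_sets:
        pe = etree.SubElement(psets, "recordingParameterSet")
        _sub(pe, "recordingParameterSetId", ps.id)
        for mod in ps.modalities:
            me = etree.SubElement(pe, "modality")
            _sub(me, "type", mod.type)
            _sub(me, "startChannel", str(mod.start_channel))
            _sub(me, "endChannel", str(mod.end_channel))
            _sub(me, "samplingRate", _fmt_float(mod.sampling_rate))
            labels = etree.SubElement(me, "channelLabels")
            for lab in mod.channel_labels:
                _sub(labels, "channelLabel", lab)
            nonscalp = etree.SubElement(me, "nonScalpChannelLabels")
            for lab in mod.non_scalp_channel_labels:
                _sub(nonscalp, "channelLabel", lab)
            _sub(me, "channelLocationType", mod.channel_location_type)
            _sub(me, "referenceLabel", mod.reference_label)

    mappings = etree.SubElement(root, "eventCodeMappings")
    for em in m.event_code_mappings:
        ee = etree.SubElement(mappings, "eventCodeMapping")
        _sub(ee, "taskLabel", em.task_label)
        _sub(ee, "code", em.code)
        _sub(ee, "category", str(em.category) if em.category is not None else "")
        hed = em.hed_string
        _sub(ee, "hedString", str(hed) if hed is not None else "")
        _sub(ee, "description", em.description)

    sessions = etree.SubElement(root, "sessions")
    for s in m.sessions:
        se = etree.SubElement(sessions, "session")
        _sub(se, "number", str(s.number))
        _sub(se, "taskLabel", s.task_label)
        _sub(se, "notes", s.notes)
        subjects = etree.SubElement(se, "subjects")
        for subj in s.subjects:
            sue = etree.SubElement(subjects, "subject")
            _sub(sue, "labId", subj.lab_id)
            _sub(sue, "group", subj.group)
            _sub(sue, "gender", subj.gender)
            _sub(sue, "age", _fmt_float(subj.age))
            _sub(sue, "hand", subj.hand)
            _sub(sue, "height", _fmt_float(subj.height))
            _sub(sue, "weight", _fmt_float(subj.weight))
            _sub(sue, "medication", subj.medication)
            _sub(sue, "channelLocationFile", subj.channel_location_file)
        recs = etree.SubElement(se, "dataRecordings")
        for rec in s.data_recordings:
            re_ = etree.SubElement(recs, "dataRecording")
            _sub(re_, "uuid", rec.uuid)
            _sub(re_, "originalFileNameAndPath", rec.original_file_name_and_path)
            _sub(re_, "essFilename", rec.ess_filename)
            _sub(re_, "eventInstanceFilename", rec.event_instance_filename)
            _sub(re_, "recordingParameterSetId", rec.parameter_set_id)
            _sub(re_, "startDateTime", rec.start_date_time)

    for raw in m.extra_xml:
        root.append(etree.fromstring(raw))
    return root


def write_level1_manifest(
    m: StudyLevel1Manifest, destination: _PathLike | IO[bytes]
) -> None:
    """Serialize *m* as UTF-8 XML (optional fields emitted empty)."""
    root = manifest_to_element(m)
    data = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
    if isinstance(destination, (str, Path)):
        Path(destination).write_bytes(data)
    else:
        destination.write(data)


def manifest_to_bytes(m: StudyLevel1Manifest) -> bytes:
    return etree.tostring(
        manifest_to_element(m), pretty_print=True, xml_declaration=True,
        encoding="UTF-8",
    )


# ---------------------------------------------------------------------------
# Schema


_SCHEMA: etree.XMLSchema | None = None


def manifest_schema() -> etree.XMLSchema:
    """The shipped XSD for the Level-1 manifest dialect, loaded once."""
    global _SCHEMA
    if _SCHEMA is None:
        data = (
            importlib.resources.files("esskit")
            .joinpath("data/study_level1.xsd")
            .read_bytes()
        )
        _SCHEMA = etree.XMLSchema(etree.fromstring(data))
    return _SCHEMA


# ---------------------------------------------------------------------------
# Summary


@dataclass
class ModalitySummary:
    parameter_set_id: str
    type: str
    channels: int
    non_scalp_channels: int
    sampling_rate: float


@dataclass
class StudySummary:
    title: str
    ess_version: str
    study_uuid: str
    n_sessions: int
    n_subjects: int
    n_recordings: int
    tasks: list[str]
    modalities: list[ModalitySummary]

    @property
    def scalp_eeg_channels(self) -> int:
        """Scalp EEG channel count summed over EEG modalities (first rset)."""
        first = [m for m in self.modalities if m.type == "EEG"]
        return sum(m.channels - m.non_scalp_channels for m in first)

    @property
    def sampling_rate(self) -> float:
        """Sampling rate of the first EEG modality (0 when absent)."""
        for m in self.modalities:
            if m.type == "EEG":
                return m.sampling_rate
        return 0.0


def summarize_study(m: StudyLevel1Manifest) -> StudySummary:
    """Direct-enumeration counts feeding the HTML report."""
    lab_ids = set()
    n_subjects = 0
    n_recordings = 0
    for s in m.sessions:
        for subj in s.subjects:
            if subj.lab_id:
                lab_ids.add(subj.lab_id)
            else:
                n_subjects += 1  # unlabelled subjects counted individually
        n_recordings += len(s.data_recordings)
    n_subjects += len(lab_ids)
    modalities = [
        ModalitySummary(
            parameter_set_id=ps.id,
            type=mod.type,
            channels=mod.channel_count,
            non_scalp_channels=len(mod.non_scalp_channel_labels),
            sampling_rate=mod.sampling_rate,
        )
        for ps in m.recording_parameter_sets
        for mod in ps.modalities
    ]
    return StudySummary(
        title=m.title,
        ess_version=m.ess_version,
        study_uuid=m.study_uuid,
        n_sessions=len(m.sessions),
        n_subjects=n_subjects,
        n_recordings=n_recordings,
        tasks=[t.task_label for t in m.tasks],
        modalities=modalities,
    )


def deep_copy_manifest(m: StudyLevel1Manifest) -> StudyLevel1Manifest:
    return copy.deepcopy(m)
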