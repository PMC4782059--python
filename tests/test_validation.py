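"""Validator catalog: coverage, auto-fixes, and one mutation per check.

Each catalog check has a mutation oracle that corrupts a clean manifest
(or container) in exactly the way the check targets; the test asserts
that precisely that check fires at its severity class.
"""

from __future__ import annotations

import copy

import pytest

from esskit.hed import parse_hed_string
from esskit.model import (
    RecordingParameterSet,
    TaskSpec,
    is_uuid_text,
    read_level1_manifest,
)
from esskit.validation import (
    check_catalog,
    has_errors,
    issues_as_tsv,
    validate_level1,
)


@pytest.fixture()
def clean_manifest(level1_container):
    _, built = level1_container
    return copy.deepcopy(built)


class TestCatalog:
    def test_more_than_thirty_checks(self):
        assert len(check_catalog()) > 30

    def test_check_ids_unique(self):
        ids = [c.check_id for c in check_catalog()]
        assert len(ids) == len(set(ids))

    def test_uuid_autofix_check_present(self):
        by_id = {c.check_id: c for c in check_catalog()}
        assert by_id["recording-uuid-present"].auto_fix
        assert by_id["study-uuid-present"].auto_fix


class TestCleanInputs:
    def test_built_container_is_clean(self, level1_container):
        root, built = level1_container
        issues, _ = validate_level1(built, container_root=root)
        assert issues == []

    def test_validation_does_not_mutate_input(self, clean_manifest):
        snapshot = copy.deepcopy(clean_manifest)
        clean_manifest.sessions[0].data_recordings[0].uuid = ""
        snapshot.sessions[0].data_recordings[0].uuid = ""
        validate_level1(clean_manifest)
        assert clean_manifest == snapshot

    def test_autofix_populates_uuid_and_reports_fixed(self, clean_manifest):
        clean_manifest.sessions[0].data_recordings[0].uuid = ""
        issues, fixed = validate_level1(clean_manifest)
        assert [i.check_id for i in issues] == ["recording-uuid-present"]
        assert issues[0].severity == "fixed"
        assert is_uuid_text(fixed.sessions[0].data_recordings[0].uuid)

    def test_idempotence_after_fixes(self, clean_manifest):
        clean_manifest.study_uuid = ""
        clean_manifest.sessions[0].data_recordings[0].uuid = ""
        issues1, fixed = validate_level1(clean_manifest)
        assert any(i.severity == "fixed" for i in issues1)
        issues2, _ = validate_level1(fixed)
        assert not any(i.severity == "fixed" for i in issues2)
        assert issues2 == []

    def test_tsv_issue_format(self, clean_manifest):
        clean_manifest.title = ""
        issues, _ = validate_level1(clean_manifest)
        line = issues_as_tsv(issues).splitlines()[0]
        assert line.split("\t")[:2] == ["error", "title-present"]


# ---------------------------------------------------------------------------
# Mutation oracles — manifest-level checks


def _clear_session_filenames(s) -> None:
    # keeps filename-conformity quiet when session identity fields change
    for rec in s.data_recordings:
        rec.ess_filename = ""


def _split_modality(m, ranges):
    """Replace the single 10-channel modality with EEG blocks over `ranges`,
    slicing the existing label list so label counts stay consistent."""
    ps = m.recording_parameter_sets[0]
    base = ps.modalities[0]
    mods = []
    for lo, hi in ranges:
        mod = copy.deepcopy(base)
        mod.start_channel, mod.end_channel = lo, hi
        mod.channel_labels = base.channel_labels[lo - 1 : hi]
        mod.non_scalp_channel_labels = [
            l for l in base.non_scalp_channel_labels if l in mod.channel_labels
        ]
        mods.append(mod)
    ps.modalities = mods


def _mutate_title(m):
    m.title = ""


def _mutate_description(m):
    m.description = ""


def _mutate_version(m):
    m.ess_version = ""


def _mutate_study_uuid_missing(m):
    m.study_uuid = ""


def _mutate_study_uuid_bad(m):
    m.study_uuid = "not-a-uuid"


def _mutate_poc(m):
    m.point_of_contact = ""


def _mutate_no_tasks(m):
    m.tasks, m.sessions, m.event_code_mappings = [], [], []


def _mutate_task_empty_label(m):
    m.tasks.append(TaskSpec(task_label=""))


def _mutate_task_unsafe_label(m):
    m.tasks.append(TaskSpec(task_label="odd ball!"))


def _mutate_task_duplicate(m):
    m.tasks.append(TaskSpec(task_label=m.tasks[0].task_label))


def _mutate_no_sessions(m):
    m.sessions = []


def _mutate_session_number_zero(m):
    m.sessions[0].number = 0
    _clear_session_filenames(m.sessions[0])


def _mutate_session_number_dup(m):
    m.sessions[1].number = m.sessions[0].number
    _clear_session_filenames(m.sessions[1])


def _mutate_session_bad_task(m):
    m.sessions[0].task_label = "nosuchtask"
    _clear_session_filenames(m.sessions[0])


def _mutate_session_no_subject(m):
    m.sessions[0].subjects = []


def _mutate_session_no_recording(m):
    m.sessions[0].data_recordings = []


def _mutate_subject_no_labid(m):
    m.sessions[0].subjects[0].lab_id = ""


def _mutate_no_psets(m):
    m.recording_parameter_sets, m.sessions = [], []


def _mutate_pset_dup_id(m):
    m.recording_parameter_sets.append(copy.deepcopy(m.recording_parameter_sets[0]))


def _mutate_pset_no_modality(m):
    m.recording_parameter_sets.append(RecordingParameterSet(id="rset_empty"))


def _mutate_bad_channel_range(m):
    m.recording_parameter_sets[0].modalities[0].start_channel = 0


def _mutate_overlapping_ranges(m):
    _split_modality(m, [(1, 6), (6, 10)])


def _mutate_gap_in_ranges(m):
    _split_modality(m, [(1, 6), (8, 10)])


def _mutate_label_count(m):
    m.recording_parameter_sets[0].modalities[0].channel_labels.pop(0)


def _mutate_zero_rate(m):
    m.recording_parameter_sets[0].modalities[0].sampling_rate = 0.0


def _mutate_nonscalp_not_subset(m):
    m.recording_parameter_sets[0].modalities[0].non_scalp_channel_labels.append("BOGUS")


def _mutate_no_location_info(m):
    m.recording_parameter_sets[0].modalities[0].channel_location_type = "Custom"


def _mutate_bad_pset_ref(m):
    m.sessions[0].data_recordings[0].parameter_set_id = "nope"


def _mutate_recording_uuid_missing(m):
    m.sessions[0].data_recordings[0].uuid = ""


def _mutate_recording_uuid_bad(m):
    m.sessions[0].data_recordings[0].uuid = "zzz"


def _mutate_recording_uuid_dup(m):
    m.sessions[1].data_recordings[0].uuid = m.sessions[0].data_recordings[0].uuid


def _mutate_nonconforming_name(m):
    m.sessions[0].data_recordings[0].ess_filename = "bogus.edf"


def _mutate_mapping_bad_task(m):
    m.event_code_mappings[0].task_label = "nosuchtask"


def _mutate_empty_code(m):
    m.event_code_mappings[0].code = ""


def _mutate_long_code(m):
    m.event_code_mappings[0].code = "x" * 21


def _mutate_no_category(m):
    m.event_code_mappings[0].category = None


def _mutate_unparseable_hed(m):
    m.event_code_mappings[0].hed_string = "(unbalanced"


def _mutate_off_vocabulary_hed(m):
    m.event_code_mappings[0].hed_string = parse_hed_string("Participant/Nonexistent/X")


def _mutate_no_mappings(m):
    m.event_code_mappings = []


def _mutate_bad_version_text(m):
    m.ess_version = "v2"


MANIFEST_MUTATIONS = {
    "title-present": _mutate_title,
    "description-present": _mutate_description,
    "ess-version-present": _mutate_version,
    "study-uuid-present": _mutate_study_uuid_missing,
    "study-uuid-format": _mutate_study_uuid_bad,
    "point-of-contact-present": _mutate_poc,
    "tasks-present": _mutate_no_tasks,
    "task-label-nonempty": _mutate_task_empty_label,
    "task-label-filesystem-safe": _mutate_task_unsafe_label,
    "task-label-unique": _mutate_task_duplicate,
    "sessions-present": _mutate_no_sessions,
    "session-number-positive": _mutate_session_number_zero,
    "session-number-unique": _mutate_session_number_dup,
    "session-task-ref": _mutate_session_bad_task,
    "session-has-subject": _mutate_session_no_subject,
    "session-has-recording": _mutate_session_no_recording,
    "subject-labid-present": _mutate_subject_no_labid,
    "parameter-sets-present": _mutate_no_psets,
    "parameter-set-id-unique": _mutate_pset_dup_id,
    "parameter-set-has-modality": _mutate_pset_no_modality,
    "modality-channel-range": _mutate_bad_channel_range,
    "modality-ranges-disjoint": _mutate_overlapping_ranges,
    "modality-ranges-contiguous": _mutate_gap_in_ranges,
    "channel-label-count": _mutate_label_count,
    "sampling-rate-positive": _mutate_zero_rate,
    "non-scalp-subset": _mutate_nonscalp_not_subset,
    "channel-location-info": _mutate_no_location_info,
    "recording-parameter-set-ref": _mutate_bad_pset_ref,
    "recording-uuid-present": _mutate_recording_uuid_missing,
    "recording-uuid-format": _mutate_recording_uuid_bad,
    "recording-uuid-unique": _mutate_recording_uuid_dup,
    "ess-filename-conformity": _mutate_nonconforming_name,
    "event-mapping-task-ref": _mutate_mapping_bad_task,
    "event-code-nonempty": _mutate_empty_code,
    "event-code-length": _mutate_long_code,
    "event-category-present": _mutate_no_category,
    "event-hed-parses": _mutate_unparseable_hed,
    "event-hed-vocab": _mutate_off_vocabulary_hed,
    "event-mapping-coverage": _mutate_no_mappings,
    "xml-schema-conformance": _mutate_bad_version_text,
}


# ---------------------------------------------------------------------------
# Mutation oracles — container (file-level) checks


def _session_dir(root, m):
    return root / "session" / str(m.sessions[0].number)


def _rec(m):
    return m.sessions[0].data_recordings[0]


def _edit_event_file(root, m, editor):
    path = _session_dir(root, m) / _rec(m).event_instance_filename
    lines = path.read_text(encoding="utf-8").splitlines()
    path.write_text("".join(l + "\n" for l in editor(lines)), encoding="utf-8")


def _mutc_delete_data(root, m):
    (_session_dir(root, m) / _rec(m).ess_filename).unlink()


def _mutc_delete_events(root, m):
    (_session_dir(root, m) / _rec(m).event_instance_filename).unlink()


def _mutc_two_columns(root, m):
    _edit_event_file(root, m, lambda ls: ls + ["oops\t1.0"])


def _mutc_negative_latency(root, m):
    def edit(lines):
        code, _, hed = lines[0].split("\t")
        lines[0] = f"{code}\t-1.000000\t{hed}"
        return lines

    _edit_event_file(root, m, edit)


def _mutc_unsorted(root, m):
    _edit_event_file(root, m, lambda ls: list(reversed(ls)))


def _mutc_beyond_duration(root, m):
    def edit(lines):
        code, _, hed = lines[-1].split("\t")
        lines[-1] = f"{code}\t999999.000000\t{hed}"
        return lines

    _edit_event_file(root, m, edit)


def _mutc_unknown_code(root, m):
    def edit(lines):
        _, lat, hed = lines[0].split("\t")
        lines[0] = f"zzz\t{lat}\t{hed}"
        return lines

    _edit_event_file(root, m, edit)


def _mutc_missing_chanloc(root, m):
    m.sessions[0].subjects[0].channel_location_file = "missing.sfp"


CONTAINER_MUTATIONS = {
    "container-data-file-exists": _mutc_delete_data,
    "event-file-exists": _mutc_delete_events,
    "event-file-well-formed": _mutc_two_columns,
    "event-latency-nonneg": _mutc_negative_latency,
    "event-latency-sorted": _mutc_unsorted,
    "event-latency-within-duration": _mutc_beyond_duration,
    "event-codes-mapped": _mutc_unknown_code,
    "channel-location-file-exists": _mutc_missing_chanloc,
}


def test_every_check_has_a_mutation():
    assert set(MANIFEST_MUTATIONS) | set(CONTAINER_MUTATIONS) == {
        c.check_id for c in check_catalog()
    }


def _assert_exactly(issues, check_id, severity):
    """The mutation fires exactly `check_id` within its severity class."""
    fired = {i.check_id for i in issues if i.severity == severity}
    assert fired == {check_id}, issues
    if severity == "warning":
        assert not has_errors(issues), issues


@pytest.mark.parametrize("check_id", sorted(MANIFEST_MUTATIONS))
def test_manifest_mutation_triggers_exactly_its_check(check_id, clean_manifest):
    desc = {c.check_id: c for c in check_catalog()}[check_id]
    MANIFEST_MUTATIONS[check_id](clean_manifest)
    issues, _ = validate_level1(clean_manifest)
    _assert_exactly(issues, check_id, desc.severity)


@pytest.mark.parametrize("check_id", sorted(CONTAINER_MUTATIONS))
def test_container_mutation_triggers_exactly_its_check(check_id, level1_copy):
    desc = {c.check_id: c for c in check_catalog()}[check_id]
    m = read_level1_manifest(level1_copy / "study_description.xml")
    CONTAINER_MUTATIONS[check_id](level1_copy, m)
    issues, _ = validate_level1(m, container_root=level1_copy)
    _assert_exactly(issues, check_id, desc.severity)
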