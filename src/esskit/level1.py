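"""Level-1 container assembly.

A Level-1 container is a directory with a fixed layout::

    <root>/
      study_description.xml      the manifest
      README.txt                 generated stub
      additional_documentation/  free-form supporting documents
      session/<N>/               one directory per session number
        eeg_session_<N>_<task>_<original>.<ext>     raw payload, copied
        event_session_<N>_<task>_<original>.tsv     event-instance file

The event-instance file is tab-separated ``code  latency  hedString``
(latency in seconds, six decimals, no header line), sorted by ascending
latency, so events are readable on any platform without opening the raw
binary recordings.
"""

from __future__ import annotations

import re
import shutil
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

from ._version import __version__
from .errors import BuildError, EssError
from .hed import EventCodeMapping, parse_hed_string
from .model import (
    EventInstance,
    StudyLevel1Manifest,
    deep_copy_manifest,
    write_level1_manifest,
)
from .validation import has_errors, validate_level1

__all__ = [
    "ContainerLayout",
    "ess_filename",
    "render_event_instance_file",
    "parse_event_instance_file",
    "read_event_log",
    "create_level1_container",
]

_UNSAFE_RE = re.compile(r"[^A-Za-z0-9._-]")

_KIND_PREFIX = {
    "data": "eeg",
    "event": "event",
    "channelLocations": "channel_locations",
}


@dataclass
class ContainerLayout:
    root: Path

    @property
    def manifest_path(self) -> Path:
        return self.root / "study_description.xml"

    @property
    def readme_path(self) -> Path:
        return self.root / "README.txt"

    @property
    def additional_docs_dir(self) -> Path:
        return self.root / "additional_documentation"

    @property
    def sessions_dir(self) -> Path:
        return self.root / "session"

    def session_dir(self, number: int) -> Path:
        return self.sessions_dir / str(number)


def ess_filename(
    session_number: int, task_label: str, original_name: str, kind: str = "data"
) -> str:
    """ESS name encapsulating session number, task label and original name.

    Template: ``<prefix>_session_<N>_<taskLabel>_<originalStem>.<ext>``
    with prefix ``eeg``/``event``/``channel_locations``; event files get a
    ``.tsv`` extension.  Unsafe characters in the original name are
    replaced with underscores, never rejected.
    """
    if not task_label:
        raise EssError("task label must be non-empty")
    if not original_name:
        raise EssError("original file name must be non-empty")
    try:
        prefix = _KIND_PREFIX[kind]
    except KeyError:
        raise EssError(f"unknown file kind '{kind}'") from None
    name = Path(original_name).name
    stem, dot, ext = name.rpartition(".")
    if not dot:
        stem, ext = name, ""
    stem = _UNSAFE_RE.sub("_", stem)
    ext = _UNSAFE_RE.sub("_", ext)
    if kind == "event":
        ext = "tsv"
    suffix = f".{ext}" if ext else ""
    return f"{prefix}_session_{session_number}_{task_label}_{stem}{suffix}"


# ---------------------------------------------------------------------------
# Event-instance files


def render_event_instance_file(
    events: list[EventInstance],
    mappings: list[EventCodeMapping],
    task: str,
) -> str:
    """Render events as the tab-separated event-instance text.

    One line per event in ascending latency (stable for ties), columns
    ``code``, latency with six decimals, and the full HED string.  Events
    without their own HED string take it from the task's code mapping
    (category tag followed by the mapped annotation).
    """
    lookup = {m.code: m for m in mappings if m.task_label == task}
    lines = []
    for ev in sorted(events, key=lambda e: e.latency):
        if ev.latency < 0:
            raise EssError(f"event '{ev.code}' has negative latency {ev.latency}")
        if ev.hed_string is not None:
            hed = str(ev.hed_string)
        else:
            mapping = lookup.get(ev.code)
            if mapping is None:
                raise EssError(
                    f"event code '{ev.code}' has no mapping for task '{task}'"
                )
            hed = str(mapping.full_hed_string())
        lines.append(f"{ev.code}\t{ev.latency:.6f}\t{hed}")
    return "".join(line + "\n" for line in lines)


def parse_event_instance_file(content: str) -> list[EventInstance]:
    """Inverse of :func:`render_event_instance_file`."""
    events: list[EventInstance] = []
    for lineno, line in enumerate(content.splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise EssError(
                f"line {lineno}: expected 3 tab-separated columns, got {len(cols)}"
            )
        code, lat_text, hed_text = cols
        try:
            latency = float(lat_text)
        except ValueError as exc:
            raise EssError(f"line {lineno}: bad latency '{lat_text}'") from exc
        events.append(
            EventInstance(
                code=code, latency=latency, hed_string=parse_hed_string(hed_text)
            )
        )
    return events


def read_event_log(path: str | Path) -> list[EventInstance]:
    """Read a sidecar event log: two tab-separated columns, code and latency."""
    events: list[EventInstance] = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise EssError(
                f"{path}: line {lineno}: expected 'code<TAB>latency', "
                f"got {len(cols)} columns"
            )
        try:
            latency = float(cols[1])
        except ValueError as exc:
            raise EssError(f"{path}: line {lineno}: bad latency '{cols[1]}'") from exc
        events.append(EventInstance(code=cols[0], latency=latency))
    return events


def default_event_log_path(original: Path) -> Path:
    """Sidecar convention: ``recording.edf`` -> ``recording.events.tsv``."""
    return original.with_suffix(".events.tsv")


# ---------------------------------------------------------------------------
# Container assembly


def _render_readme(m: StudyLevel1Manifest) -> str:
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    return (
        f"{m.title}\n"
        f"{'=' * max(len(m.title), 1)}\n\n"
        f"ESS version: {m.ess_version}\n"
        f"Study UUID: {m.study_uuid}\n"
        f"Sessions: {len(m.sessions)}\n\n"
        f"This directory is a Standardized Data Level 1 container.  The file\n"
        f"study_description.xml is the study manifest; raw recordings and\n"
        f"per-recording event-instance files live under session/<number>/.\n\n"
        f"Built by esskit {__version__} on {stamp}.\n"
    )


def create_level1_container(
    m: StudyLevel1Manifest,
    source_dir: str | Path,
    dest_dir: str | Path,
    event_logs: dict[str, list[EventInstance] | str | Path] | None = None,
    overwrite: bool = False,
) -> tuple[StudyLevel1Manifest, ContainerLayout]:
    """Assemble a Level-1 container from raw files and a validated manifest.

    ``event_logs`` maps a recording UUID to its events (a list, or a path
    to a sidecar log); recordings not in the map fall back to the sidecar
    convention ``<original>.events.tsv`` next to the source file.  All
    staging checks run before the first copy, so a failed build leaves the
    destination untouched.  Returns the updated manifest (with ESS file
    names filled in) and the realized layout; the result re-validates with
    zero errors including file-level checks.
    """
    source_dir = Path(source_dir)
    dest_dir = Path(dest_dir)
    event_logs = dict(event_logs or {})

    issues, m = validate_level1(m)
    if has_errors(issues):
        msgs = "; ".join(i.message for i in issues if i.severity == "error")
        raise BuildError(f"manifest has validation errors: {msgs}")

    # --- staging: resolve every input before any filesystem write
    staged = []  # (session, recording, source path, events)
    for s in m.sessions:
        for rec in s.data_recordings:
            src = source_dir / rec.original_file_name_and_path
            if not src.is_file():
                raise BuildError(f"source recording '{src}' does not exist")
            log = event_logs.get(rec.uuid)
            if log is None:
                log = default_event_log_path(src)
            if isinstance(log, (str, Path)):
                if not Path(log).is_file():
                    raise BuildError(f"event log '{log}' does not exist")
                events = read_event_log(log)
            else:
                events = log
            # fail now (not mid-copy) on unmapped codes or bad latencies
            content = render_event_instance_file(
                events, m.event_code_mappings, s.task_label
            )
            staged.append((s, rec, src, content))

    chanloc_staged = []
    for s in m.sessions:
        for subj in s.subjects:
            if subj.channel_location_file:
                src = source_dir / subj.channel_location_file
                if not src.is_file():
                    raise BuildError(f"channel location file '{src}' does not exist")
                chanloc_staged.append((s, subj, src))

    if dest_dir.exists() and any(dest_dir.iterdir()):
        if not overwrite:
            raise BuildError(
                f"destination '{dest_dir}' is not empty (pass overwrite=True)"
            )
        shutil.rmtree(dest_dir)

    layout = ContainerLayout(root=dest_dir)
    layout.additional_docs_dir.mkdir(parents=True, exist_ok=True)
    layout.sessions_dir.mkdir(parents=True, exist_ok=True)

    for s, rec, src, content in staged:
        sdir = layout.session_dir(s.number)
        sdir.mkdir(parents=True, exist_ok=True)
        rec.ess_filename = ess_filename(s.number, s.task_label, src.name, "data")
        rec.event_instance_filename = ess_filename(
            s.number, s.task_label, src.name, "event"
        )
        shutil.copyfile(src, sdir / rec.ess_filename)
        (sdir / rec.event_instance_filename).write_text(content, encoding="utf-8")

    for s, subj, src in chanloc_staged:
        sdir = layout.session_dir(s.number)
        sdir.mkdir(parents=True, exist_ok=True)
        name = ess_filename(s.number, s.task_label, src.name, "channelLocations")
        shutil.copyfile(src, sdir / name)
        subj.channel_location_file = name

    layout.readme_path.write_text(_render_readme(m), encoding="utf-8")
    write_level1_manifest(m, layout.manifest_path)

    final_issues, m = validate_level1(m, container_root=dest_dir)
    if has_errors(final_issues):
        msgs = "; ".join(i.message for i in final_issues if i.severity == "error")
        raise BuildError(f"built container fails validation: {msgs}")
    return m, layout
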