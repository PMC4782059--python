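"""Level-derived containers: named filters with full provenance chains.

A derived container applies one named filter function (with name-value
parameters) to every recording of a parent container — Level 1, Level 2
or another derived container — and embeds the parent's manifest XML
verbatim inside its own.  Chaining derivations therefore yields a
self-contained document from which the complete processing history back
to the raw Level-1 study is recoverable by recursive parsing, with no
reference to external files.

Filter functions receive a :class:`~esskit.level2.SignalRecording` plus
keyword parameters and return a new recording of the same shape.  They
are registered by name so the command line can invoke them, e.g.::

    ess derive <parent> --fn highPass --param detrendCutoff=0.5

``highPass`` is a zero-phase 4th-order Butterworth high-pass applied
forward-backward per channel; its ``detrendCutoff`` parameter is the
cutoff frequency in Hz.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable

from lxml import etree
from scipy import signal as sps

from . import edf as edf_module
from ._version import __version__
from .errors import BuildError, EssError, ManifestError, SignalError
from .level2 import SignalRecording
from .model import StudyLevel1Manifest, read_level1_manifest

__all__ = [
    "FilterDescription",
    "LevelDerivedManifest",
    "high_pass",
    "identity_filter",
    "register_filter",
    "get_filter",
    "apply_filter_to_container",
    "read_derived_manifest",
    "provenance_chain",
    "level1_ancestor",
]


@dataclass
class FilterDescription:
    function_name: str
    parameters: dict[str, float | str | bool] = field(default_factory=dict)
    tool_version: str = __version__
    run_timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.function_name:
            raise EssError("filter function name must be non-empty")
        if not self.run_timestamp:
            self.run_timestamp = datetime.now(timezone.utc).isoformat(
                timespec="seconds"
            )


@dataclass
class RecordingOutput:
    input_uuid: str
    output_filename: str  # container-root-relative; empty when failed
    status: str = "ok"  # ok | failed
    error: str = ""


@dataclass
class LevelDerivedManifest:
    filter: FilterDescription
    #: serialized XML of the parent container's manifest root element
    parent_content: str
    recording_outputs: list[RecordingOutput] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Filter functions


def high_pass(r: SignalRecording, cutoff_hz: float) -> SignalRecording:
    """Zero-phase 4th-order Butterworth high-pass, per channel.

    Applied forward-backward (``sosfiltfilt``), so the effective
    magnitude response is the squared Butterworth magnitude and the phase
    is zero.  Events are untouched.
    """
    nyquist = r.sampling_rate / 2
    if not 0 < cutoff_hz < nyquist:
        raise SignalError(
            f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyquist} Hz)"
        )
    sos = sps.butter(4, cutoff_hz, btype="highpass", fs=r.sampling_rate, output="sos")
    out = r.copy()
    out.data = sps.sosfiltfilt(sos, out.data, axis=1)
    return out


def identity_filter(r: SignalRecording) -> SignalRecording:
    return r.copy()


_FILTERS: dict[str, Callable[..., SignalRecording]] = {}

#: filter parameter names -> python keyword names, per registered filter
_PARAM_ALIASES: dict[str, dict[str, str]] = {}


def register_filter(
    name: str,
    fn: Callable[..., SignalRecording],
    param_aliases: dict[str, str] | None = None,
) -> None:
    """Register *fn* under *name* for lookup by the CLI and containers."""
    _FILTERS[name] = fn
    _PARAM_ALIASES[name] = dict(param_aliases or {})


def get_filter(name: str) -> Callable[..., SignalRecording]:
    try:
        return _FILTERS[name]
    except KeyError:
        raise EssError(
            f"unknown filter '{name}'; registered: {sorted(_FILTERS)}"
        ) from None


register_filter("highPass", high_pass, {"detrendCutoff": "cutoff_hz"})
register_filter("identity", identity_filter)


def _call_filter(filt: FilterDescription, r: SignalRecording) -> SignalRecording:
    fn = get_filter(filt.function_name)
    aliases = _PARAM_ALIASES.get(filt.function_name, {})
    kwargs = {aliases.get(k, k): v for k, v in filt.parameters.items()}
    return fn(r, **kwargs)


# ---------------------------------------------------------------------------
# Parent-container introspection


def _load_parent_root(parent_root: Path) -> etree._Element:
    path = parent_root / "study_description.xml"
    try:
        return etree.parse(str(path)).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ManifestError(f"cannot parse parent manifest '{path}': {exc}") from exc


def _level1_from_element(el: etree._Element) -> StudyLevel1Manifest:
    data = etree.tostring(el)
    return read_level1_manifest(io.BytesIO(data))


def _find_level1_element(el: etree._Element) -> etree._Element:
    """Descend through nested parentStudy elements to the Level-1 root."""
    current = el
    while current.tag != "studyLevel1":
        parent_el = current.find("parentStudy")
        if parent_el is None or len(parent_el) == 0:
            raise ManifestError(
                f"cannot locate an embedded Level-1 manifest under '{el.tag}'"
            )
        current = parent_el[0]
    return current


def level1_ancestor(manifest_path: str | Path) -> StudyLevel1Manifest:
    """The raw Level-1 manifest at the bottom of any container's ancestry."""
    root = etree.parse(str(manifest_path)).getroot()
    return _level1_from_element(_find_level1_element(root))


def _enumerate_recordings(root_el: etree._Element) -> list[tuple[str, str]]:
    """(uuid, container-relative payload path) pairs for any container level."""
    tag = root_el.tag
    if tag == "studyLevel1":
        m = _level1_from_element(root_el)
        out = []
        for s in m.sessions:
            for rec in s.data_recordings:
                out.append((rec.uuid, f"session/{s.number}/{rec.ess_filename}"))
        return out
    if tag == "studyLevel2":
        return [
            (
                pe.findtext("inputRecordingUuid") or "",
                pe.findtext("outputFilename") or "",
            )
            for pe in root_el.findall("processingRecords/processingRecord")
            if (pe.findtext("status") or "ok") == "ok"
        ]
    if tag == "studyLevelDerived":
        return [
            (
                ro.findtext("inputUuid") or "",
                ro.findtext("outputFilename") or "",
            )
            for ro in root_el.findall("recordingOutputs/recordingOutput")
            if (ro.findtext("status") or "ok") == "ok"
        ]
    raise ManifestError(f"unrecognized container manifest root '{tag}'")


def _event_file_map(level1: StudyLevel1Manifest) -> dict[str, tuple[int, str]]:
    out = {}
    for s in level1.sessions:
        for rec in s.data_recordings:
            out[rec.uuid] = (s.number, rec.event_instance_filename)
    return out


# ---------------------------------------------------------------------------
# Container transformation


def apply_filter_to_container(
    parent_root: str | Path,
    dest_dir: str | Path,
    filt: FilterDescription,
    fn: Callable[..., SignalRecording] | None = None,
    overwrite: bool = False,
) -> LevelDerivedManifest:
    """Apply *filt* to every recording of the parent container.

    The parent may be Level 1, Level 2 or itself derived; its manifest is
    embedded verbatim in the new container's manifest.  A recording on
    which the filter raises is marked failed and processing continues.
    When *fn* is omitted the filter's registered function is used.
    """
    parent_root = Path(parent_root)
    dest_dir = Path(dest_dir)
    parent_el = _load_parent_root(parent_root)
    parent_content = etree.tostring(parent_el, encoding="unicode")
    recordings = _enumerate_recordings(parent_el)
    level1 = _level1_from_element(_find_level1_element(parent_el))
    event_files = _event_file_map(level1)
    non_scalp_by_uuid: dict[str, list[str]] = {}
    for s in level1.sessions:
        for rec in s.data_recordings:
            ps = level1.parameter_set(rec.parameter_set_id)
            labels: list[str] = []
            if ps is not None:
                for mod in ps.modalities:
                    labels.extend(mod.non_scalp_channel_labels)
            non_scalp_by_uuid[rec.uuid] = labels

    if dest_dir.exists() and any(dest_dir.iterdir()):
        if not overwrite:
            raise BuildError(f"destination '{dest_dir}' is not empty")
        import shutil

        shutil.rmtree(dest_dir)
    (dest_dir / "session").mkdir(parents=True, exist_ok=True)

    manifest = LevelDerivedManifest(filter=filt, parent_content=parent_content)
    for uuid, rel_path in recordings:
        status, error = "ok", ""
        try:
            payload = edf_module.read_edf(parent_root / rel_path)
            non_scalp = non_scalp_by_uuid.get(uuid, [])
            signal = SignalRecording(
                data=payload.data,
                sampling_rate=payload.sampling_rate,
                channel_labels=payload.channel_labels,
                non_scalp_channels=[
                    l for l in non_scalp if l in payload.channel_labels
                ],
            )
            if fn is not None:
                result = fn(signal, **filt.parameters)
            else:
                result = _call_filter(filt, signal)
            out_path = dest_dir / rel_path
            out_path.parent.mkdir(parents=True, exist_ok=True)
            edf_module.write_edf(
                out_path, result.data, result.sampling_rate, result.channel_labels
            )
            sess_number, ev_name = event_files.get(uuid, (None, ""))
            if ev_name:
                src_ev = parent_root / Path(rel_path).parent / ev_name
                if src_ev.is_file():
                    (out_path.parent / ev_name).write_text(
                        src_ev.read_text(encoding="utf-8"), encoding="utf-8"
                    )
        except (EssError, OSError, TypeError, ValueError) as exc:
            status, error = "failed", str(exc)
        manifest.recording_outputs.append(
            RecordingOutput(
                input_uuid=uuid,
                output_filename=rel_path if status == "ok" else "",
                status=status,
                error=error,
            )
        )

    write_derived_manifest(manifest, dest_dir / "study_description.xml")
    return manifest


# ---------------------------------------------------------------------------
# Derived manifest XML


def _fmt_param(v) -> tuple[str, str]:
    if isinstance(v, bool):
        return "boolean", "true" if v else "false"
    if isinstance(v, (int, float)):
        return "number", repr(float(v)) if isinstance(v, float) else str(v)
    return "text", str(v)


def write_derived_manifest(m: LevelDerivedManifest, destination: str | Path) -> None:
    root = etree.Element("studyLevelDerived")
    fe = etree.SubElement(root, "filter")
    for tag, value in (
        ("functionName", m.filter.function_name),
        ("toolVersion", m.filter.tool_version),
        ("runTimestamp", m.filter.run_timestamp),
    ):
        e = etree.SubElement(fe, tag)
        e.text = value
    params = etree.SubElement(fe, "parameters")
    for name, value in m.filter.parameters.items():
        typ, text = _fmt_param(value)
        p = etree.SubElement(params, "parameter", name=name, type=typ)
        p.text = text
    outputs = etree.SubElement(root, "recordingOutputs")
    for ro in m.recording_outputs:
        oe = etree.SubElement(outputs, "recordingOutput")
        for tag, value in (
            ("inputUuid", ro.input_uuid),
            ("outputFilename", ro.output_filename),
            ("status", ro.status),
            ("error", ro.error),
        ):
            e = etree.SubElement(oe, tag)
            e.text = value
    parent_el = etree.SubElement(root, "parentStudy")
    parent_el.append(etree.fromstring(m.parent_content.encode("utf-8")))
    Path(destination).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )


def read_derived_manifest(source: str | Path) -> LevelDerivedManifest:
    try:
        root = etree.parse(str(source)).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ManifestError(f"cannot parse derived manifest: {exc}") from exc
    if root.tag != "studyLevelDerived":
        raise ManifestError(f"expected root 'studyLevelDerived', found '{root.tag}'")
    fe = root.find("filter")
    if fe is None:
        raise ManifestError("derived manifest has no filter element")
    parameters: dict[str, float | str | bool] = {}
    for p in fe.findall("parameters/parameter"):
        typ = p.get("type", "text")
        text = p.text or ""
        if typ == "number":
            parameters[p.get("name", "")] = float(text)
        elif typ == "boolean":
            parameters[p.get("name", "")] = text == "true"
        else:
            parameters[p.get("name", "")] = text
    filt = FilterDescription(
        function_name=fe.findtext("functionName") or "",
        parameters=parameters,
        tool_version=fe.findtext("toolVersion") or "",
        run_timestamp=fe.findtext("runTimestamp") or "",
    )
    parent_el = root.find("parentStudy")
    if parent_el is None or len(parent_el) == 0:
        raise ManifestError("derived manifest has no embedded parent content")
    m = LevelDerivedManifest(
        filter=filt,
        parent_content=etree.tostring(parent_el[0], encoding="unicode"),
    )
    for ro in root.findall("recordingOutputs/recordingOutput"):
        m.recording_outputs.append(
            RecordingOutput(
                input_uuid=ro.findtext("inputUuid") or "",
                output_filename=ro.findtext("outputFilename") or "",
                status=ro.findtext("status") or "ok",
                error=ro.findtext("error") or "",
            )
        )
    return m


def provenance_chain(manifest_path: str | Path) -> list[FilterDescription]:
    """Filter descriptions from the given container back toward Level 1.

    The first entry is the outermost (most recent) derivation.  Level-2
    processing appears as a pseudo-filter named after its pipeline
    method; the chain ends when the embedded Level-1 manifest is reached.
    """
    root = etree.parse(str(manifest_path)).getroot()
    chain: list[FilterDescription] = []
    current = root
    while True:
        if current.tag == "studyLevel1":
            break
        if current.tag == "studyLevelDerived":
            fe = current.find("filter")
            parameters: dict[str, float | str | bool] = {}
            if fe is not None:
                for p in fe.findall("parameters/parameter"):
                    typ = p.get("type", "text")
                    text = p.text or ""
                    parameters[p.get("name", "")] = (
                        float(text)
                        if typ == "number"
                        else (text == "true" if typ == "boolean" else text)
                    )
            chain.append(
                FilterDescription(
                    function_name=(
                        fe.findtext("functionName") if fe is not None else ""
                    )
                    or "",
                    parameters=parameters,
                    tool_version=(
                        fe.findtext("toolVersion") if fe is not None else ""
                    )
                    or "",
                    run_timestamp=(
                        fe.findtext("runTimestamp") if fe is not None else ""
                    )
                    or "",
                )
            )
        elif current.tag == "studyLevel2":
            first = current.find("processingRecords/processingRecord")
            chain.append(
                FilterDescription(
                    function_name=(
                        first.findtext("methodName") if first is not None else ""
                    )
                    or "level2-pipeline",
                    parameters={},
                    tool_version=current.findtext("toolVersion") or "",
                    run_timestamp="-",
                )
            )
        else:
            raise ManifestError(f"unrecognized manifest root '{current.tag}'")
        parent_el = current.find("parentStudy")
        if parent_el is None or len(parent_el) == 0:
            raise ManifestError("provenance chain broken: no embedded parent")
        current = parent_el[0]
    return chain
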