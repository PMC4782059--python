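"""Level-2 preprocessing: noisy-channel handling and robust referencing.

A Level-2 container holds the same recordings as its Level-1 parent after
a fully automated preprocessing pass.  The default pipeline shipped here
is a deliberately simple, documented stand-in with the standard
interface: detect artifact-dominated scalp channels, interpolate them
from neighboring channels, and re-reference all scalp channels to the
mean of the channels not flagged as noisy (robust average reference).  A
different pipeline (e.g. a full PREP implementation) can be injected via
the ``pipeline`` argument of :func:`create_level2_container`.

Detection criteria (scalp channels only):

* amplitude deviation — robust z-score (median / 1.4826*MAD across
  channels) of each channel's robust standard deviation exceeds
  ``deviation_z`` (default 5.0);
* low correlation — the median across one-second windows of the maximum
  absolute correlation with any other scalp channel falls below
  ``min_correlation`` (default 0.4).  Correlation with a zero-variance
  channel is defined as 0, so flat-lined channels are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from lxml import etree

from . import edf as edf_module
from ._version import __version__
from .errors import BuildError, EssError, SignalError
from .model import (
    EventInstance,
    StudyLevel1Manifest,
    read_level1_manifest,
)
from .validation import has_errors, validate_level1

__all__ = [
    "SignalRecording",
    "ProcessingRecord",
    "StudyLevel2Manifest",
    "detect_noisy_channels",
    "robust_average_reference",
    "interpolate_channels",
    "ring_positions",
    "default_pipeline",
    "create_level2_container",
    "read_level2_manifest",
]


# ---------------------------------------------------------------------------
# Types


@dataclass
class SignalRecording:
    """A continuous multichannel recording in physical units (microvolts)."""

    data: np.ndarray  # (channels, samples)
    sampling_rate: float
    channel_labels: list[str]
    non_scalp_channels: list[str] = field(default_factory=list)
    events: list[EventInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise SignalError("data must be (channels, samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise SignalError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} labels"
            )
        if not self.sampling_rate > 0:
            raise SignalError("sampling rate must be positive")

    @property
    def scalp_channels(self) -> list[str]:
        non = set(self.non_scalp_channels)
        return [l for l in self.channel_labels if l not in non]

    def index_of(self, label: str) -> int:
        return self.channel_labels.index(label)

    def copy(self) -> "SignalRecording":
        return SignalRecording(
            data=self.data.copy(),
            sampling_rate=self.sampling_rate,
            channel_labels=list(self.channel_labels),
            non_scalp_channels=list(self.non_scalp_channels),
            events=list(self.events),
        )


@dataclass
class ProcessingRecord:
    input_recording_uuid: str
    output_filename: str  # container-root-relative path
    method_name: str
    parameters: dict[str, float | str | bool] = field(default_factory=dict)
    noisy_channels: list[str] = field(default_factory=list)
    interpolated_channels: list[str] = field(default_factory=list)
    quality_score: float = 1.0
    status: str = "ok"  # ok | failed
    error: str = ""


@dataclass
class StudyLevel2Manifest:
    parent_level1: StudyLevel1Manifest
    processing_records: list[ProcessingRecord] = field(default_factory=list)
    pipeline_description: str = ""
    #: serialized XML of the embedded parent manifest document
    parent_xml: str = ""


# ---------------------------------------------------------------------------
# Robust statistics helpers


def _robust_std(x: np.ndarray, axis: int = -1) -> np.ndarray:
    med = np.median(x, axis=axis, keepdims=True)
    return 1.4826 * np.median(np.abs(x - med), axis=axis)


def detect_noisy_channels(
    r: SignalRecording,
    deviation_z: float = 5.0,
    min_correlation: float = 0.4,
    window_seconds: float = 1.0,
) -> list[str]:
    """Scalp channels flagged by amplitude deviation or low correlation.

    Non-scalp channels are never flagged.  Requires at least two scalp
    channels and one second of data.
    """
    scalp = r.scalp_channels
    if len(scalp) < 2:
        raise SignalError("need at least 2 scalp channels to detect noisy ones")
    n_samp = r.data.shape[1]
    if n_samp < r.sampling_rate:
        raise SignalError("need at least 1 second of data")
    idx = [r.index_of(l) for l in scalp]
    X = r.data[idx]

    # deviation criterion
    rstd = _robust_std(X)
    med = np.median(rstd)
    mad = 1.4826 * np.median(np.abs(rstd - med))
    if mad <= 0:
        z = np.zeros_like(rstd)
    else:
        z = (rstd - med) / mad
    dev_flag = z > deviation_z

    # correlation criterion: per 1 s window, max |corr| with any other
    # scalp channel; then the median across windows
    win = max(int(round(window_seconds * r.sampling_rate)), 1)
    n_win = max(n_samp // win, 1)
    max_corrs = np.empty((n_win, len(scalp)))
    for w in range(n_win):
        seg = X[:, w * win : (w + 1) * win] if n_win > 1 else X
        sd = seg.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(seg)
        C = np.nan_to_num(C, nan=0.0)  # zero-variance channels correlate 0
        np.fill_diagonal(C, 0.0)
        C[sd == 0, :] = 0.0
        C[:, sd == 0] = 0.0
        np.fill_diagonal(C, 0.0)
        max_corrs[w] = np.abs(C).max(axis=1)
    corr_flag = np.median(max_corrs, axis=0) < min_correlation

    return [lab for lab, d, c in zip(scalp, dev_flag, corr_flag) if d or c]


def robust_average_reference(
    r: SignalRecording, excluded: list[str] | None = None
) -> SignalRecording:
    """Subtract the mean over retained scalp channels from all scalp channels.

    ``excluded`` channels (typically the noisy ones) are left out of the
    reference signal but are themselves re-referenced; non-scalp channels
    are untouched.  After the call the per-sample mean over retained
    channels is zero to numerical precision.
    """
    excluded = list(excluded or [])
    scalp = r.scalp_channels
    bad = set(excluded) - set(scalp)
    if bad:
        raise SignalError(f"excluded channels {sorted(bad)} are not scalp channels")
    retained = [l for l in scalp if l not in set(excluded)]
    if not retained:
        raise SignalError("all scalp channels excluded from the reference")
    out = r.copy()
    ref = out.data[[r.index_of(l) for l in retained]].mean(axis=0)
    for l in scalp:
        out.data[r.index_of(l)] -= ref
    return out


def ring_positions(labels: list[str]) -> dict[str, np.ndarray]:
    """Synthetic electrode geometry: unit-circle layout in label order.

    Used by the default pipeline when no measured positions are supplied;
    neighborhood in label order stands in for scalp adjacency.
    """
    n = len(labels)
    out = {}
    for i, lab in enumerate(labels):
        theta = 2 * math.pi * i / max(n, 1)
        out[lab] = np.array([math.cos(theta), math.sin(theta), 0.0])
    return out


def interpolate_channels(
    r: SignalRecording,
    bad: list[str],
    neighbor_count: int = 4,
    positions: dict[str, np.ndarray] | None = None,
    neighbors: dict[str, list[str]] | None = None,
) -> SignalRecording:
    """Replace each bad channel by the mean of its nearest good channels.

    Nearest is by Euclidean distance on ``positions``; alternatively an
    explicit ``neighbors`` graph may be given.  Other channels are
    bit-identical in the result.
    """
    if not bad:
        return r.copy()
    scalp = set(r.scalp_channels)
    not_scalp = set(bad) - scalp
    if not_scalp:
        raise SignalError(f"bad channels {sorted(not_scalp)} are not scalp channels")
    good = [l for l in r.scalp_channels if l not in set(bad)]
    if not good:
        raise SignalError("no good scalp channel left to interpolate from")
    if positions is None and neighbors is None:
        raise SignalError("need channel positions or a neighbor graph")
    out = r.copy()
    for label in bad:
        if neighbors is not None:
            cand = [l for l in neighbors.get(label, []) if l in good]
            chosen = cand[:neighbor_count] if cand else good
        else:
            missing = [l for l in (label, *good) if l not in positions]
            if missing:
                raise SignalError(f"no position for channels {missing}")
            p = positions[label]
            ranked = sorted(good, key=lambda l: float(np.linalg.norm(positions[l] - p)))
            chosen = ranked[:neighbor_count]
        out.data[r.index_of(label)] = r.data[
            [r.index_of(l) for l in chosen]
        ].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Default pipeline


def default_pipeline(
    r: SignalRecording,
    deviation_z: float = 5.0,
    min_correlation: float = 0.4,
    neighbor_count: int = 4,
    positions: dict[str, np.ndarray] | None = None,
) -> tuple[SignalRecording, dict]:
    """detect -> interpolate -> robust average reference.

    Returns the processed recording and a metadata dict (method name,
    parameters, flagged/interpolated channels, quality score).  The
    quality score is ``1 - flagged/scalp``, monotonically decreasing in
    the number of flagged scalp channels.
    """
    noisy = detect_noisy_channels(
        r, deviation_z=deviation_z, min_correlation=min_correlation
    )
    if positions is None:
        positions = ring_positions(r.scalp_channels)
    out = interpolate_channels(
        r, noisy, neighbor_count=neighbor_count, positions=positions
    ) if noisy else r.copy()
    out = robust_average_reference(out, excluded=noisy)
    n_scalp = len(r.scalp_channels)
    meta = {
        "method_name": "detect-interpolate-robust-reference",
        "parameters": {
            "deviationZ": deviation_z,
            "minCorrelation": min_correlation,
            "neighborCount": neighbor_count,
        },
        "noisy_channels": noisy,
        "interpolated_channels": noisy,
        "quality_score": 1.0 - len(noisy) / n_scalp if n_scalp else 1.0,
    }
    return out, meta


# ---------------------------------------------------------------------------
# Container transformation


def _non_scalp_for_recording(m: StudyLevel1Manifest, rec) -> list[str]:
    ps = m.parameter_set(rec.parameter_set_id)
    if ps is None:
        return []
    out: list[str] = []
    for mod in ps.modalities:
        out.extend(mod.non_scalp_channel_labels)
    return out


def _quality_report(rec_uuid: str, meta: dict, status: str, error: str) -> str:
    lines = [
        f"Recording: {rec_uuid}",
        f"Status: {status}",
    ]
    if status == "ok":
        lines += [
            f"Method: {meta['method_name']}",
            "Parameters: "
            + ", ".join(f"{k}={v}" for k, v in meta["parameters"].items()),
            f"Noisy channels ({len(meta['noisy_channels'])}): "
            + (", ".join(meta["noisy_channels"]) or "none"),
            f"Interpolated channels: "
            + (", ".join(meta["interpolated_channels"]) or "none"),
            f"Quality score: {meta['quality_score']:.4f}",
        ]
    else:
        lines.append(f"Error: {error}")
    return "\n".join(lines) + "\n"


def create_level2_container(
    level1_root: str | Path,
    dest_dir: str | Path,
    pipeline: Callable[[SignalRecording], tuple[SignalRecording, dict]] | None = None,
    overwrite: bool = False,
    **pipeline_kwargs,
) -> StudyLevel2Manifest:
    """Process every recording of a Level-1 container into a Level-2 one.

    The layout mirrors the parent: processed EDF payloads and copied
    event files under ``session/<N>/``, per-recording quality reports
    under ``reports/``, and a ``study_description.xml`` that embeds the
    parent manifest verbatim.  An unreadable recording yields a failed
    :class:`ProcessingRecord`; processing continues.
    """
    level1_root = Path(level1_root)
    dest_dir = Path(dest_dir)
    manifest_path = level1_root / "study_description.xml"
    parent = read_level1_manifest(manifest_path)
    issues, parent = validate_level1(parent, container_root=level1_root)
    if has_errors(issues):
        msgs = "; ".join(i.message for i in issues if i.severity == "error")
        raise BuildError(f"Level-1 container fails validation: {msgs}")

    if pipeline is None:
        def pipeline(r: SignalRecording):
            return default_pipeline(r, **pipeline_kwargs)

    if dest_dir.exists() and any(dest_dir.iterdir()):
        if not overwrite:
            raise BuildError(f"destination '{dest_dir}' is not empty")
        import shutil

        shutil.rmtree(dest_dir)
    (dest_dir / "session").mkdir(parents=True, exist_ok=True)
    (dest_dir / "reports").mkdir(parents=True, exist_ok=True)

    out = StudyLevel2Manifest(
        parent_level1=parent,
        pipeline_description=(
            "Stand-in preprocessing pipeline: robust-deviation and "
            "correlation-based noisy channel detection, nearest-neighbor "
            "mean interpolation, robust average reference."
        ),
        parent_xml=manifest_path.read_text(encoding="utf-8"),
    )

    for s in parent.sessions:
        sdir = level1_root / "session" / str(s.number)
        out_sdir = dest_dir / "session" / str(s.number)
        out_sdir.mkdir(parents=True, exist_ok=True)
        for rec in s.data_recordings:
            rel_out = f"session/{s.number}/{rec.ess_filename}"
            meta: dict = {}
            status, error = "ok", ""
            try:
                payload = edf_module.read_edf(sdir / rec.ess_filename)
                non_scalp = _non_scalp_for_recording(parent, rec)
                signal = SignalRecording(
                    data=payload.data,
                    sampling_rate=payload.sampling_rate,
                    channel_labels=payload.channel_labels,
                    non_scalp_channels=[
                        l for l in non_scalp if l in payload.channel_labels
                    ],
                )
                processed, meta = pipeline(signal)
                if processed.data.shape != signal.data.shape:
                    raise SignalError("pipeline changed the data shape")
                edf_module.write_edf(
                    dest_dir / rel_out,
                    processed.data,
                    processed.sampling_rate,
                    processed.channel_labels,
                )
                if rec.event_instance_filename:
                    (out_sdir / rec.event_instance_filename).write_text(
                        (sdir / rec.event_instance_filename).read_text(
                            encoding="utf-8"
                        ),
                        encoding="utf-8",
                    )
            except (EssError, OSError) as exc:
                status, error = "failed", str(exc)
            out.processing_records.append(
                ProcessingRecord(
                    input_recording_uuid=rec.uuid,
                    output_filename=rel_out if status == "ok" else "",
                    method_name=meta.get("method_name", ""),
                    parameters=meta.get("parameters", {}),
                    noisy_channels=meta.get("noisy_channels", []),
                    interpolated_channels=meta.get("interpolated_channels", []),
                    quality_score=meta.get("quality_score", 0.0),
                    status=status,
                    error=error,
                )
            )
            (dest_dir / "reports" / f"report_{rec.uuid}.txt").write_text(
                _quality_report(rec.uuid, meta, status, error), encoding="utf-8"
            )

    write_level2_manifest(out, dest_dir / "study_description.xml")
    return out


# ---------------------------------------------------------------------------
# Level-2 manifest XML


def _fmt_param(v) -> tuple[str, str]:
    if isinstance(v, bool):
        return "boolean", "true" if v else "false"
    if isinstance(v, (int, float)):
        return "number", repr(float(v)) if isinstance(v, float) else str(v)
    return "text", str(v)


def write_level2_manifest(m: StudyLevel2Manifest, destination: str | Path) -> None:
    root = etree.Element("studyLevel2")
    el = etree.SubElement(root, "pipelineDescription")
    el.text = m.pipeline_description
    el = etree.SubElement(root, "toolVersion")
    el.text = __version__
    records = etree.SubElement(root, "processingRecords")
    for pr in m.processing_records:
        pe = etree.SubElement(records, "processingRecord")
        for tag, value in (
            ("inputRecordingUuid", pr.input_recording_uuid),
            ("outputFilename", pr.output_filename),
            ("methodName", pr.method_name),
        ):
            e = etree.SubElement(pe, tag)
            e.text = value
        params = etree.SubElement(pe, "parameters")
        for name, value in pr.parameters.items():
            typ, text = _fmt_param(value)
            p = etree.SubElement(params, "parameter", name=name, type=typ)
            p.text = text
        for tag, labels in (
            ("noisyChannels", pr.noisy_channels),
            ("interpolatedChannels", pr.interpolated_channels),
        ):
            le = etree.SubElement(pe, tag)
            for lab in labels:
                ch = etree.SubElement(le, "channelLabel")
                ch.text = lab
        for tag, value in (
            ("qualityScore", repr(float(pr.quality_score))),
            ("status", pr.status),
            ("error", pr.error),
        ):
            e = etree.SubElement(pe, tag)
            e.text = value
    parent_el = etree.SubElement(root, "parentStudy")
    parent_el.append(etree.fromstring(m.parent_xml.encode("utf-8")))
    Path(destination).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )


def _parse_params(params_el) -> dict:
    out: dict = {}
    if params_el is None:
        return out
    for p in params_el.findall("parameter"):
        name = p.get("name", "")
        typ = p.get("type", "text")
        text = p.text or ""
        if typ == "number":
            value: float | str | bool = float(text)
        elif typ == "boolean":
            value = text == "true"
        else:
            value = text
        out[name] = value
    return out


def read_level2_manifest(source: str | Path) -> StudyLevel2Manifest:
    from .errors import ManifestError

    try:
        tree = etree.parse(str(source))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ManifestError(f"cannot parse Level-2 manifest: {exc}") from exc
    root = tree.getroot()
    if root.tag != "studyLevel2":
        raise ManifestError(f"expected root 'studyLevel2', found '{root.tag}'")
    parent_el = root.find("parentStudy")
    if parent_el is None or len(parent_el) == 0:
        raise ManifestError("Level-2 manifest has no embedded parent study")
    parent_xml = etree.tostring(parent_el[0], encoding="unicode")
    import io

    parent = read_level1_manifest(io.BytesIO(parent_xml.encode("utf-8")))
    m = StudyLevel2Manifest(
        parent_level1=parent,
        pipeline_description=(root.findtext("pipelineDescription") or ""),
        parent_xml=parent_xml,
    )
    records = root.find("processingRecords")
    if records is not None:
        for pe in records.findall("processingRecord"):
            m.processing_records.append(
                ProcessingRecord(
                    input_recording_uuid=pe.findtext("inputRecordingUuid") or "",
                    output_filename=pe.findtext("outputFilename") or "",
                    method_name=pe.findtext("methodName") or "",
                    parameters=_parse_params(pe.find("parameters")),
                    noisy_channels=[
                        c.text or ""
                        for c in pe.findall("noisyChannels/channelLabel")
                    ],
                    interpolated_channels=[
                        c.text or ""
                        for c in pe.findall("interpolatedChannels/channelLabel")
                    ],
                    quality_score=float(pe.findtext("qualityScore") or "0"),
                    status=pe.findtext("status") or "ok",
                    error=pe.findtext("error") or "",
                )
            )
    return m
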