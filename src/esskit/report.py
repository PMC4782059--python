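"""Self-contained HTML study reports from a manifest at any level.

The report is generated directly from the data model (not via a
stylesheet applied to the XML, which browsers refuse for local files)
and is deterministic given the manifest bytes: inline styles, no
external fetches.  Every number shown comes from
:func:`esskit.model.summarize_study` or from the provenance parser —
the template never counts anything on its own.
"""

from __future__ import annotations

import html
from pathlib import Path

from lxml import etree

from .derived import provenance_chain, read_derived_manifest
from .errors import ManifestError
from .level2 import StudyLevel2Manifest, read_level2_manifest
from .model import (
    StudyLevel1Manifest,
    StudySummary,
    read_level1_manifest,
    summarize_study,
)

__all__ = ["render_html_report"]

_STYLE = """
body { font-family: sans-serif; margin: 2em; color: #222; }
h1 { border-bottom: 2px solid #346; }
h2 { color: #346; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 0.3em 0.8em; text-align: left; }
th { background: #e8edf5; }
caption { caption-side: top; font-weight: bold; padding: 0.3em; }
"""


def _esc(s) -> str:
    return html.escape(str(s))


def _table(caption: str, headers: list[str], rows: list[list]) -> str:
    head = "".join(f"<th>{_esc(h)}</th>" for h in headers)
    body = "".join(
        "<tr>" + "".join(f"<td>{_esc(c)}</td>" for c in row) + "</tr>"
        for row in rows
    )
    return (
        f"<table><caption>{_esc(caption)}</caption>"
        f"<tr>{head}</tr>{body}</table>"
    )


def _summary_section(summary: StudySummary, m: StudyLevel1Manifest) -> str:
    parts = [f"<h1>{_esc(summary.title) or '(untitled study)'}</h1>"]
    parts.append(
        _table(
            "Study summary",
            ["Field", "Value"],
            [
                ["ESS version", summary.ess_version],
                ["Study UUID", summary.study_uuid],
                ["Sessions", summary.n_sessions],
                ["Subjects", summary.n_subjects],
                ["Data recordings", summary.n_recordings],
                ["Tasks", ", ".join(summary.tasks) or "-"],
                ["Scalp EEG channels", summary.scalp_eeg_channels],
                ["EEG sampling rate (Hz)", summary.sampling_rate],
            ],
        )
    )
    parts.append(
        _table(
            "Modalities",
            ["Parameter set", "Type", "Channels", "Non-scalp", "Rate (Hz)"],
            [
                [
                    mod.parameter_set_id,
                    mod.type,
                    mod.channels,
                    mod.non_scalp_channels,
                    mod.sampling_rate,
                ]
                for mod in summary.modalities
            ],
        )
    )
    parts.append(
        _table(
            "Sessions",
            ["Number", "Task", "Subjects", "Recordings"],
            [
                [
                    s.number,
                    s.task_label,
                    ", ".join(subj.lab_id or "?" for subj in s.subjects),
                    len(s.data_recordings),
                ]
                for s in m.sessions
            ],
        )
    )
    parts.append(
        _table(
            "Event codes",
            ["Task", "Code", "Category", "HED string", "Description"],
            [
                [
                    em.task_label,
                    em.code,
                    em.category or "-",
                    em.hed_string or "-",
                    em.description,
                ]
                for em in m.event_code_mappings
            ],
        )
    )
    return "".join(parts)


def _processing_section(l2: StudyLevel2Manifest) -> str:
    return _table(
        "Processing quality",
        ["Recording UUID", "Status", "Noisy channels", "Interpolated", "Quality"],
        [
            [
                pr.input_recording_uuid,
                pr.status,
                ", ".join(pr.noisy_channels) or "none",
                ", ".join(pr.interpolated_channels) or "none",
                f"{pr.quality_score:.3f}",
            ]
            for pr in l2.processing_records
        ],
    )


def _chain_section(manifest_path: Path) -> str:
    chain = provenance_chain(manifest_path)
    return _table(
        "Processing chain (outermost first)",
        ["Step", "Function", "Parameters", "Tool version", "Run at"],
        [
            [
                i + 1,
                f.function_name,
                ", ".join(f"{k}={v}" for k, v in f.parameters.items()) or "-",
                f.tool_version,
                f.run_timestamp,
            ]
            for i, f in enumerate(chain)
        ],
    )


def render_html_report(manifest_path: str | Path) -> str:
    """Render a formatted report for a manifest at any container level."""
    manifest_path = Path(manifest_path)
    try:
        root_tag = etree.parse(str(manifest_path)).getroot().tag
    except (etree.XMLSyntaxError, OSError) as exc:
        raise ManifestError(f"cannot parse manifest: {exc}") from exc

    sections: list[str] = []
    if root_tag == "studyLevel1":
        m = read_level1_manifest(manifest_path)
        sections.append(_summary_section(summarize_study(m), m))
    elif root_tag == "studyLevel2":
        l2 = read_level2_manifest(manifest_path)
        m = l2.parent_level1
        sections.append(_summary_section(summarize_study(m), m))
        sections.append("<h2>Level-2 processing</h2>")
        sections.append(f"<p>{_esc(l2.pipeline_description)}</p>")
        sections.append(_processing_section(l2))
        sections.append(_chain_section(manifest_path))
    elif root_tag == "studyLevelDerived":
        from .derived import level1_ancestor

        read_derived_manifest(manifest_path)  # structural check
        m = level1_ancestor(manifest_path)
        sections.append(_summary_section(summarize_study(m), m))
        sections.append("<h2>Derivation</h2>")
        sections.append(_chain_section(manifest_path))
    else:
        raise ManifestError(f"unrecognized manifest root '{root_tag}'")

    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>Study report</title><style>{_STYLE}</style></head>"
        "<body>" + "".join(sections) + "</body></html>\n"
    )
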