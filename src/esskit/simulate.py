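"""Synthetic source studies for end-to-end testing without downloads.

The generator emulates the three raw inputs a lab would hand to the
containerization tools: multichannel EDF recordings, per-recording
tab-separated event logs, and a draft XML manifest.  The default
configuration reproduces the shape of a classic 24-participant auditory
oddball study: one session per participant, a single recording parameter
set (``rset_1``) with 64 scalp EEG channels plus 4 non-scalp EOG
channels at 1024 Hz, and two event codes — a frequent expected ``ding``
and a rare oddball target ``buzz`` — annotated with HED tags.

Signals are 1/f-shaped Gaussian noise (unit variance per channel) plus a
10 Hz sinusoid shared by all scalp channels, which gives the
inter-channel correlation real EEG exhibits; optionally one seeded scalp
channel per recording receives 100x noise variance so that noisy-channel
detection has a planted ground truth.  Everything — signal bytes, event
times, manifest text — is fully determined by the configuration seed.
"""

from __future__ import annotations

import uuid as uuid_module
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import edf as edf_module
from .errors import EssError, SignalError
from .hed import EventCodeMapping, parse_hed_string, parse_hed_tag
from .level2 import SignalRecording
from .model import (
    DataRecording,
    EventInstance,
    Modality,
    RecordingParameterSet,
    SessionRecord,
    StudyLevel1Manifest,
    SubjectRecord,
    TaskSpec,
    write_level1_manifest,
)

__all__ = [
    "SynthConfig",
    "generate_signals",
    "generate_events",
    "generate_source_study",
    "draft_manifest",
    "planted_noisy_channel",
]

#: amplitude of the shared 10 Hz component; with unit-variance channel
#: noise this yields pairwise correlation A^2/2 / (A^2/2 + 1) = 2/3,
#: comfortably above the detector's minimum-correlation threshold
SHARED_SINE_AMPLITUDE = 2.0
SHARED_SINE_HZ = 10.0
NOISY_STD_FACTOR = 10.0  # 100x variance

_CATEGORY = "Event/Category/Experimental stimulus"

_DEFAULT_EVENT_CODES = (
    (
        "ding",
        "Sensory Presentation/Auditory/Ding, Participant/Effect/Auditory, "
        "Participant/Effect/Cognitive/Expected",
        0.8,
    ),
    (
        "buzz",
        "Sensory Presentation/Auditory/Buzz, Participant/Effect/Auditory, "
        "Participant/Effect/Cognitive/Oddball/Target",
        0.2,
    ),
)


@dataclass
class SynthConfig:
    """Structure of the generated study; defaults give the oddball shape."""

    n_sessions: int = 24
    scalp_channels: int = 64
    non_scalp_channels: int = 4
    sampling_rate: float = 1024.0
    duration_seconds: float = 20.0
    #: (code, hedString, mean Poisson rate in events/s)
    event_codes: tuple[tuple[str, str, float], ...] = _DEFAULT_EVENT_CODES
    noisy_channel_per_recording: bool = True
    task_label: str = "oddball"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 0 or self.scalp_channels < 0 or self.non_scalp_channels < 0:
            raise EssError("counts must be >= 0")
        if not self.sampling_rate > 0:
            raise EssError("sampling rate must be positive")
        if not self.duration_seconds > 0:
            raise EssError("duration must be positive")

    @property
    def channel_labels(self) -> list[str]:
        return [f"EEG{i + 1}" for i in range(self.scalp_channels)] + [
            f"EXG{i + 1}" for i in range(self.non_scalp_channels)
        ]

    @property
    def non_scalp_labels(self) -> list[str]:
        return [f"EXG{i + 1}" for i in range(self.non_scalp_channels)]


def _one_over_f_noise(rng: np.random.Generator, n_ch: int, n_samp: int) -> np.ndarray:
    """Unit-variance rows with a 1/f power spectrum (amplitude ~ f^-1/2)."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp)
    weights = np.zeros_like(freqs)
    weights[1:] = freqs[1:] ** -0.5  # zero out DC
    x = np.fft.irfft(spec * weights, n=n_samp, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_signals(cfg: SynthConfig, session_index: int) -> SignalRecording:
    """Deterministic recording for the given (seed, session index)."""
    if cfg.scalp_channels < 1:
        raise SignalError("a recording needs at least one scalp channel")
    rng = np.random.default_rng([cfg.seed % (2**31), session_index, 0])
    n_samp = int(round(cfg.duration_seconds * cfg.sampling_rate))
    labels = cfg.channel_labels

    noisy_idx = None
    if cfg.noisy_channel_per_recording and cfg.scalp_channels > 0:
        noisy_idx = int(rng.integers(cfg.scalp_channels))
    noise = _one_over_f_noise(rng, len(labels), n_samp)
    if noisy_idx is not None:
        noise[noisy_idx] *= NOISY_STD_FACTOR

    t = np.arange(n_samp) / cfg.sampling_rate
    phase = rng.uniform(0, 2 * np.pi)
    shared = SHARED_SINE_AMPLITUDE * np.sin(2 * np.pi * SHARED_SINE_HZ * t + phase)
    data = noise
    data[: cfg.scalp_channels] += shared

    return SignalRecording(
        data=data,
        sampling_rate=cfg.sampling_rate,
        channel_labels=labels,
        non_scalp_channels=cfg.non_scalp_labels,
        events=[],
    )


def planted_noisy_channel(cfg: SynthConfig, session_index: int) -> str | None:
    """Label of the channel that generate_signals corrupts, or None."""
    if not (cfg.noisy_channel_per_recording and cfg.scalp_channels > 0):
        return None
    rng = np.random.default_rng([cfg.seed % (2**31), session_index, 0])
    return cfg.channel_labels[int(rng.integers(cfg.scalp_channels))]


def generate_events(cfg: SynthConfig, session_index: int) -> list[EventInstance]:
    """Merged homogeneous-Poisson event streams, sorted by latency."""
    rng = np.random.default_rng([cfg.seed % (2**31), session_index, 1])
    events: list[EventInstance] = []
    for code, _hed, rate in cfg.event_codes:
        n = rng.poisson(rate * cfg.duration_seconds)
        times = np.sort(rng.uniform(0, cfg.duration_seconds, size=n))
        events.extend(EventInstance(code=code, latency=float(t)) for t in times)
    events.sort(key=lambda e: e.latency)
    return events


def _deterministic_uuid(rng: np.random.Generator) -> str:
    return str(uuid_module.UUID(bytes=bytes(rng.bytes(16)), version=4))


def draft_manifest(cfg: SynthConfig) -> StudyLevel1Manifest:
    """Draft Level-1 manifest for *cfg* (no signal files written)."""
    rng = np.random.default_rng([cfg.seed % (2**31), 9999])
    m = StudyLevel1Manifest(
        title="Synthetic auditory oddball study",
        description=(
            f"Synthetic study: {cfg.n_sessions} sessions of an auditory "
            "oddball paradigm with frequent 'ding' and rare 'buzz' stimuli, "
            "generated for containerization testing."
        ),
        study_uuid=_deterministic_uuid(rng),
        point_of_contact="synthetic-study@example.org",
        license="CC0",
        tasks=[
            TaskSpec(
                task_label=cfg.task_label,
                description="Auditory oddball target detection task.",
            )
        ],
        recording_parameter_sets=[
            RecordingParameterSet(
                id="rset_1",
                modalities=[
                    Modality(
                        type="EEG",
                        start_channel=1,
                        end_channel=len(cfg.channel_labels),
                        sampling_rate=cfg.sampling_rate,
                        channel_labels=cfg.channel_labels,
                        non_scalp_channel_labels=cfg.non_scalp_labels,
                        channel_location_type="10-20",
                        reference_label="CMS",
                    )
                ],
            )
        ],
    )
    for code, hed, _rate in cfg.event_codes:
        m.event_code_mappings.append(
            EventCodeMapping(
                task_label=cfg.task_label,
                code=code,
                category=parse_hed_tag(_CATEGORY),
                hed_string=parse_hed_string(hed),
                description=f"synthetic '{code}' stimulus",
            )
        )
    hands = ("R", "L")
    genders = ("F", "M")
    for k in range(cfg.n_sessions):
        subject = SubjectRecord(
            lab_id=f"S{k + 1:02d}",
            group="control",
            gender=genders[int(rng.integers(2))],
            age=float(int(rng.integers(18, 66))),
            hand=hands[int(rng.integers(2))],
            height=float(int(rng.integers(150, 200))),
            weight=float(int(rng.integers(50, 110))),
        )
        m.sessions.append(
            SessionRecord(
                number=k + 1,
                task_label=cfg.task_label,
                subjects=[subject],
                data_recordings=[
                    DataRecording(
                        uuid=_deterministic_uuid(rng),
                        original_file_name_and_path=f"recording_{k + 1}.edf",
                        parameter_set_id="rset_1",
                    )
                ],
            )
        )
    return m


def generate_source_study(
    cfg: SynthConfig, dest_dir: str | Path
) -> StudyLevel1Manifest:
    """Write EDF recordings, event logs and a draft manifest to *dest_dir*.

    The layout matches what containerization expects as its source: one
    ``recording_<k>.edf`` with a sidecar ``recording_<k>.events.tsv`` per
    session, plus ``study_description.xml`` (the draft manifest, which is
    also returned).
    """
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    m = draft_manifest(cfg)
    for k in range(cfg.n_sessions):
        rec = generate_signals(cfg, k)
        edf_module.write_edf(
            dest_dir / f"recording_{k + 1}.edf",
            rec.data,
            cfg.sampling_rate,
            rec.channel_labels,
        )
        events = generate_events(cfg, k)
        lines = "".join(f"{e.code}\t{e.latency:.6f}\n" for e in events)
        (dest_dir / f"recording_{k + 1}.events.tsv").write_text(
            lines, encoding="utf-8"
        )
    write_level1_manifest(m, dest_dir / "study_description.xml")
    return m
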