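"""Generate a small synthetic oddball study and package it as a Level-1
container.

The synthetic source mimics what a lab hands over: one EDF recording and
one tab-separated event log per session, plus a draft manifest.
Containerization validates the manifest, copies the recordings into
session folders under ESS names, and writes per-recording event-instance
files.
"""

import tempfile
from pathlib import Path

from esskit.level1 import create_level1_container
from esskit.model import summarize_study
from esskit.simulate import SynthConfig, generate_source_study

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    cfg = SynthConfig(n_sessions=4, scalp_channels=16, non_scalp_channels=2,
                      sampling_rate=256.0, duration_seconds=10.0, seed=1)
    manifest = generate_source_study(cfg, tmp / "source")
    built, layout = create_level1_container(manifest, tmp / "source", tmp / "level1")

    summary = summarize_study(built)
    print(f"sessions:            {summary.n_sessions}")
    print(f"data recordings:     {summary.n_recordings}")
    print(f"scalp EEG channels:  {summary.scalp_eeg_channels}")
    print(f"sampling rate (Hz):  {summary.sampling_rate:g}")
    print(f"session folders:     {sorted(p.name for p in layout.sessions_dir.iterdir())}")
    first = built.sessions[0].data_recordings[0]
    print(f"example payload:     {first.ess_filename}")
    print(f"example event file:  {first.event_instance_filename}")

# The counts restate the study structure (4 sessions x 1 recording of
# 16 scalp + 2 EOG channels); the file names show the ESS convention
# that encodes session number, task label and original file name.
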