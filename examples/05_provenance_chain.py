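"""Chain derived containers and recover the full processing history.

A derived container applies one named filter to every recording and
embeds the parent's manifest XML verbatim, so an arbitrarily deep chain
remains a single self-contained document.
"""

import tempfile
from pathlib import Path

from esskit.derived import FilterDescription, apply_filter_to_container, provenance_chain
from esskit.level1 import create_level1_container
from esskit.level2 import create_level2_container
from esskit.simulate import SynthConfig, generate_source_study

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    cfg = SynthConfig(n_sessions=2, scalp_channels=8, non_scalp_channels=1,
                      sampling_rate=128.0, duration_seconds=6.0, seed=5)
    manifest = generate_source_study(cfg, tmp / "source")
    create_level1_container(manifest, tmp / "source", tmp / "level1")
    create_level2_container(tmp / "level1", tmp / "level2")

    apply_filter_to_container(
        tmp / "level2", tmp / "highpassed",
        FilterDescription("highPass", {"detrendCutoff": 0.5}),
    )
    apply_filter_to_container(
        tmp / "highpassed", tmp / "rehighpassed",
        FilterDescription("highPass", {"detrendCutoff": 2.0}),
    )

    chain = provenance_chain(tmp / "rehighpassed" / "study_description.xml")
    print("processing chain (outermost first):")
    for i, step in enumerate(chain, start=1):
        params = ", ".join(f"{k}={v}" for k, v in step.parameters.items()) or "-"
        print(f"  {i}. {step.function_name} ({params})")

# The chain lists both high-pass derivations with their cutoff
# parameters, then the Level-2 preprocessing step, ending at the raw
# Level-1 study — the complete, self-contained provenance record.
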