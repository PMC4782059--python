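"""Validate a draft manifest, showing issue reporting and auto-fixes.

The validator runs a catalog of more than 30 named checks.  Structural
breaks are errors, absent optional metadata is a warning, and missing
UUIDs are generated in place and reported with severity "fixed".
"""

from esskit.simulate import SynthConfig, draft_manifest
from esskit.validation import check_catalog, validate_level1

print(f"check catalog size: {len(check_catalog())}")

m = draft_manifest(SynthConfig(n_sessions=2, scalp_channels=8,
                               non_scalp_channels=1, sampling_rate=128.0,
                               duration_seconds=5.0, seed=2))
# corrupt the draft in three ways
m.sessions[0].data_recordings[0].uuid = ""          # fixable
m.event_code_mappings[0].code = "x" * 25            # label too long
m.sessions[1].task_label = "no_such_task"           # dangling reference

issues, fixed = validate_level1(m)
for issue in issues:
    print(f"{issue.severity:8s} {issue.check_id:28s} {issue.message}")
print(f"uuid after fixing: {fixed.sessions[0].data_recordings[0].uuid}")

# Expected: one "fixed" (UUID generated), one error for the 25-character
# label (the limit is 20) and one error for the unknown task label.
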