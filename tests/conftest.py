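"""Shared fixtures: small synthetic studies and built containers.

All fixtures are generated programmatically; expensive container builds
are session-scoped and copied per test where mutation is needed.
"""

from __future__ import annotations

import shutil
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from esskit.level1 import create_level1_container
from esskit.level2 import create_level2_container
from esskit.simulate import SynthConfig, generate_source_study

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: small study shape used throughout the unit tests: 3 sessions of 8 scalp
#: + 2 EOG channels, 128 Hz, 8 s — enough for 8 one-second correlation
#: windows while keeping container builds near-instant
SMALL = dict(
    n_sessions=3,
    scalp_channels=8,
    non_scalp_channels=2,
    sampling_rate=128.0,
    duration_seconds=8.0,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    return SynthConfig(**SMALL)


@pytest.fixture(scope="session")
def source_study(small_cfg, tmp_path_factory) -> tuple[Path, object]:
    """(source directory, draft manifest) for the small study."""
    root = tmp_path_factory.mktemp("source_study")
    manifest = generate_source_study(small_cfg, root)
    return root, manifest


@pytest.fixture(scope="session")
def level1_container(source_study, tmp_path_factory):
    """(container root, built manifest) — session-scoped, treat as read-only."""
    src, manifest = source_study
    dest = tmp_path_factory.mktemp("level1")
    built, layout = create_level1_container(manifest, src, dest, overwrite=True)
    return layout.root, built


@pytest.fixture()
def level1_copy(level1_container, tmp_path):
    """A throwaway copy of the built container for mutation tests."""
    root, _ = level1_container
    dest = tmp_path / "level1"
    shutil.copytree(root, dest)
    return dest


@pytest.fixture(scope="session")
def level2_container(level1_container, tmp_path_factory):
    root, _ = level1_container
    dest = tmp_path_factory.mktemp("level2")
    manifest = create_level2_container(root, dest, overwrite=True)
    return dest, manifest
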