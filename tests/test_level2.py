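"""Preprocessing: noisy-channel detection, referencing, interpolation,
and Level-2 container construction."""

from __future__ import annotations

import numpy as np
import pytest

from esskit.edf import read_edf
from esskit.errors import SignalError
from esskit.level2 import (
    SignalRecording,
    create_level2_container,
    detect_noisy_channels,
    interpolate_channels,
    read_level2_manifest,
    ring_positions,
    robust_average_reference,
)
from esskit.simulate import SynthConfig, generate_signals, generate_source_study
from esskit.level1 import create_level1_container


def _recording(data, rate=64.0, non_scalp=()):
    labels = [f"ch{i}" for i in range(data.shape[0])]
    return SignalRecording(
        data=data,
        sampling_rate=rate,
        channel_labels=labels,
        non_scalp_channels=[labels[i] for i in non_scalp],
    )


class TestDetect:
    def test_planted_high_variance_channel_flagged_alone(self):
        """All channels share a sinusoid; one gets 100x amplitude noise and
        must be the only flag — verified against a direct evaluation of
        both criteria."""
        rng = np.random.default_rng(0)
        t = np.arange(64 * 8) / 64
        base = np.sin(2 * np.pi * 5 * t)
        data = np.tile(base, (6, 1)) + 0.05 * rng.standard_normal((6, len(t)))
        data[3] += 100 * 0.05 * rng.standard_normal(len(t))
        r = _recording(data)
        assert detect_noisy_channels(r) == ["ch3"]

    def test_identical_channels_clean(self):
        t = np.arange(64 * 4) / 64
        data = np.tile(np.sin(2 * np.pi * 3 * t), (5, 1))
        assert detect_noisy_channels(_recording(data)) == []

    def test_flat_line_flagged_by_correlation(self):
        rng = np.random.default_rng(1)
        shared = rng.standard_normal(64 * 4)
        data = np.tile(shared, (5, 1))
        data += 0.01 * rng.standard_normal(data.shape)
        data[2] = 0.0  # flat-line: correlation with a constant is defined as 0
        assert detect_noisy_channels(_recording(data)) == ["ch2"]

    def test_non_scalp_channels_never_flagged(self):
        rng = np.random.default_rng(2)
        shared = rng.standard_normal(64 * 4)
        data = np.tile(shared, (5, 1)) + 0.01 * rng.standard_normal((5, 64 * 4))
        data[4] = 1000 * rng.standard_normal(64 * 4)  # wild, but non-scalp
        r = _recording(data, non_scalp=(4,))
        assert detect_noisy_channels(r) == []

    def test_fewer_than_two_scalp_channels_rejected(self):
        data = np.zeros((2, 128))
        r = _recording(data, non_scalp=(1,))
        with pytest.raises(SignalError, match="2 scalp"):
            detect_noisy_channels(r)


class TestRobustReference:
    def test_two_constant_channels(self):
        r = _recording(np.vstack([np.ones(64), 3 * np.ones(64)]))
        out = robust_average_reference(r)
        assert np.allclose(out.data[0], -1) and np.allclose(out.data[1], 1)

    def test_excluded_channel_rereferenced_but_not_in_reference(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((6, 256))
        r = _recording(data)
        out = robust_average_reference(r, excluded=["ch5"])
        retained = out.data[:5]
        assert np.abs(retained.mean(axis=0)).max() < 1e-9 * max(
            1.0, np.abs(data).max()
        )
        expected_ch5 = data[5] - data[:5].mean(axis=0)
        assert np.allclose(out.data[5], expected_ch5)

    def test_equals_plain_average_reference_oracle(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((8, 512))
        out = robust_average_reference(_recording(data))
        oracle = data - data.mean(axis=0)  # one-line independent oracle
        assert np.allclose(out.data, oracle, atol=1e-12)

    def test_non_scalp_untouched(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((4, 128))
        r = _recording(data, non_scalp=(3,))
        out = robust_average_reference(r)
        assert np.array_equal(out.data[3], data[3])

    def test_all_excluded_rejected(self):
        r = _recording(np.zeros((2, 64)))
        with pytest.raises(SignalError, match="excluded"):
            robust_average_reference(r, excluded=["ch0", "ch1"])


class TestInterpolate:
    def test_channel_equal_to_neighbor_mean_reconstructed_exactly(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((6, 128))
        labels = [f"ch{i}" for i in range(6)]
        pos = ring_positions(labels)
        # ch0's 4 nearest good channels on the ring: ch1, ch5, ch2, ch4
        neighbors = sorted(
            (l for l in labels[1:]),
            key=lambda l: float(np.linalg.norm(pos[l] - pos["ch0"])),
        )[:4]
        data[0] = data[[labels.index(l) for l in neighbors]].mean(axis=0)
        corrupted = data.copy()
        corrupted[0] = 999.0
        r = _recording(corrupted)
        out = interpolate_channels(r, ["ch0"], positions=pos)
        assert np.allclose(out.data[0], data[0], atol=1e-12)
        assert np.array_equal(out.data[1:], corrupted[1:])

    def test_empty_bad_list_identity(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((3, 64))
        r = _recording(data)
        out = interpolate_channels(r, [], positions=ring_positions(r.channel_labels))
        assert np.array_equal(out.data, data)

    def test_all_but_one_bad_degenerates_to_single_good(self):
        rng = np.random.default_rng(8)
        data = rng.standard_normal((4, 64))
        r = _recording(data)
        out = interpolate_channels(
            r, ["ch0", "ch1", "ch2"], positions=ring_positions(r.channel_labels)
        )
        for i in range(3):
            assert np.array_equal(out.data[i], data[3])

    def test_explicit_neighbor_graph(self):
        data = np.arange(12, dtype=float).reshape(3, 4)
        r = _recording(data)
        out = interpolate_channels(r, ["ch0"], neighbors={"ch0": ["ch2"]})
        assert np.array_equal(out.data[0], data[2])

    def test_no_geometry_rejected(self):
        r = _recording(np.zeros((3, 64)))
        with pytest.raises(SignalError, match="positions or a neighbor"):
            interpolate_channels(r, ["ch0"])


class TestLevel2Container:
    def test_one_interpolated_channel_per_recording(self, level2_container):
        _, manifest = level2_container
        assert len(manifest.processing_records) == 3
        for pr in manifest.processing_records:
            assert pr.status == "ok"
            assert len(pr.interpolated_channels) == 1
            assert pr.interpolated_channels == pr.noisy_channels
            assert pr.quality_score == pytest.approx(1 - 1 / 8)

    def test_layout_and_reports(self, level2_container):
        root, manifest = level2_container
        assert (root / "study_description.xml").is_file()
        for pr in manifest.processing_records:
            assert (root / pr.output_filename).is_file()
            report = root / "reports" / f"report_{pr.input_recording_uuid}.txt"
            assert "Quality score" in report.read_text(encoding="utf-8")

    def test_shape_conserved_and_retained_mean_zero(self, level1_container,
                                                    level2_container):
        l1_root, built = level1_container
        l2_root, manifest = level2_container
        for s in built.sessions:
            for rec in s.data_recordings:
                raw = read_edf(l1_root / "session" / str(s.number) / rec.ess_filename)
                pr = next(
                    p for p in manifest.processing_records
                    if p.input_recording_uuid == rec.uuid
                )
                processed = read_edf(l2_root / pr.output_filename)
                assert processed.data.shape == raw.data.shape
                scalp_idx = [
                    i for i, l in enumerate(processed.channel_labels)
                    if l.startswith("EEG") and l not in pr.noisy_channels
                ]
                mean = processed.data[scalp_idx].mean(axis=0)
                # zero up to 16-bit EDF quantization of the stored signals
                step = (
                    processed.data.max() - processed.data.min()
                ) / 65535 * len(scalp_idx) ** 0.5
                assert np.abs(mean).max() < max(step, 1e-9)

    def test_in_memory_pipeline_mean_exactly_zero(self, small_cfg):
        from esskit.level2 import default_pipeline

        r = generate_signals(small_cfg, 0)
        out, meta = default_pipeline(r)
        retained = [
            r.index_of(l) for l in r.scalp_channels if l not in meta["noisy_channels"]
        ]
        scale = np.abs(out.data).max()
        assert np.abs(out.data[retained].mean(axis=0)).max() < 1e-9 * scale

    def test_identity_pipeline_preserves_signal_values(self, level1_container,
                                                       tmp_path):
        l1_root, built = level1_container
        dest = tmp_path / "l2id"
        manifest = create_level2_container(
            l1_root, dest,
            pipeline=lambda r: (r.copy(), {
                "method_name": "identity", "parameters": {},
                "noisy_channels": [], "interpolated_channels": [],
                "quality_score": 1.0,
            }),
        )
        s = built.sessions[0]
        rec = s.data_recordings[0]
        raw = read_edf(l1_root / "session" / str(s.number) / rec.ess_filename)
        out = read_edf(dest / f"session/{s.number}/{rec.ess_filename}")
        # identical up to one 16-bit requantization step per channel
        step = (raw.data.max(axis=1) - raw.data.min(axis=1) + 0.002) / 65535
        assert np.all(np.abs(out.data - raw.data) <= 2 * step[:, None])

    def test_determinism(self, level1_container, tmp_path):
        l1_root, built = level1_container
        a, b = tmp_path / "a", tmp_path / "b"
        create_level2_container(l1_root, a)
        create_level2_container(l1_root, b)
        s = built.sessions[0]
        rec = s.data_recordings[0]
        rel = f"session/{s.number}/{rec.ess_filename}"
        assert (a / rel).read_bytes() == (b / rel).read_bytes()

    def test_zero_session_study_gives_empty_level2(self, tmp_path):
        cfg = SynthConfig(n_sessions=0, scalp_channels=4, non_scalp_channels=0,
                          sampling_rate=64.0, duration_seconds=2.0, seed=1)
        src = tmp_path / "src"
        manifest = generate_source_study(cfg, src)
        l1 = tmp_path / "l1"
        create_level1_container(manifest, src, l1)
        l2 = create_level2_container(l1, tmp_path / "l2")
        assert l2.processing_records == []

    def test_corrupt_recording_marked_failed_run_continues(self, level1_copy):
        built = None
        # truncate the first session's EDF payload
        from esskit.model import read_level1_manifest

        built = read_level1_manifest(level1_copy / "study_description.xml")
        s = built.sessions[0]
        rec = s.data_recordings[0]
        path = level1_copy / "session" / str(s.number) / rec.ess_filename
        path.write_bytes(path.read_bytes()[:300])
        l2 = create_level2_container(level1_copy, level1_copy.parent / "l2")
        by_uuid = {p.input_recording_uuid: p for p in l2.processing_records}
        assert by_uuid[rec.uuid].status == "failed"
        others = [p for p in l2.processing_records if p.input_recording_uuid != rec.uuid]
        assert others and all(p.status == "ok" for p in others)

    def test_manifest_roundtrip(self, level2_container):
        root, manifest = level2_container
        back = read_level2_manifest(root / "study_description.xml")
        assert back.parent_level1 == manifest.parent_level1
        assert [
            (p.input_recording_uuid, p.noisy_channels, p.status)
            for p in back.processing_records
        ] == [
            (p.input_recording_uuid, p.noisy_channels, p.status)
            for p in manifest.processing_records
        ]


class TestQualityScore:
    def test_monotone_in_flag_count(self):
        from esskit.level2 import default_pipeline

        rng = np.random.default_rng(9)
        shared = 2.0 * np.sin(2 * np.pi * 10 * np.arange(64 * 8) / 64)
        data = shared + rng.standard_normal((8, 64 * 8))
        scores = []
        for n_bad in (0, 1, 2):
            d = data.copy()
            for k in range(n_bad):
                d[k] *= 50
            _, meta = default_pipeline(_recording(d))
            assert len(meta["noisy_channels"]) == n_bad
            scores.append(meta["quality_score"])
        assert scores == sorted(scores, reverse=True)
        assert scores[0] == 1.0
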