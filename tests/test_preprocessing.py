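"""Cleaning-stage unit tests beyond the acceptance property suite:
contracts, degenerate inputs, fusion/selection behavior, the full
pipeline, and the segment archive."""

import numpy as np
import pytest

from mindfuse import preprocessing as pp
from mindfuse import synthetic
from mindfuse.io_formats import AlignmentError, Session, SimTrace

FS = 200.0


class TestFilterContracts:
    def test_notch_rejects_cutoffs_at_nyquist(self):
        with pytest.raises(pp.ParameterError):
            pp.notch_filter(np.zeros(1000), fs=100.0, low=46.0, high=54.0)

    def test_notch_zero_in_zero_out(self):
        out = pp.notch_filter(np.zeros(2000), FS)
        np.testing.assert_allclose(out, 0.0)

    def test_notch_preserves_length_multichannel(self, rng):
        x = rng.standard_normal((2000, 4))
        assert pp.notch_filter(x, FS).shape == (2000, 4)

    def test_bandlimit_amplitude_within_1db_at_20hz(self):
        t = np.arange(int(30 * FS)) / FS
        sine = np.sin(2 * np.pi * 20.0 * t)
        out = pp.eeg_bandlimit(sine[:, None], FS)[:, 0]
        core = slice(int(3 * FS), -int(3 * FS))
        ratio_db = 20 * np.log10(np.std(out[core]) / np.std(sine[core]))
        assert abs(ratio_db) < 1.0

    def test_bandlimit_rejects_short_signals(self):
        with pytest.raises(pp.LengthError):
            pp.eeg_bandlimit(np.zeros((100, 6)), FS)

    def test_ecg_highpass_kills_constant(self):
        out = pp.ecg_highpass(np.full(4000, 3.3), FS)
        assert np.abs(out).max() < 1e-6

    def test_ecg_highpass_rejects_cutoff_at_nyquist(self):
        with pytest.raises(pp.ParameterError):
            pp.ecg_highpass(np.zeros(4000), FS, fc=150.0)


class TestAsr:
    def test_zero_variance_channel_is_degenerate(self, rng):
        eeg = rng.standard_normal((int(80 * FS), 6))
        eeg[:, 2] = 5.0
        with pytest.raises(pp.DegenerateInputError):
            pp.asr_clean(eeg, FS)

    def test_output_shape_matches_input(self, rng):
        eeg = synthetic._eeg_session(rng, int(70 * FS), FS, False, 0.0)
        out = pp.asr_clean(eeg, FS)
        assert out.shape == eeg.shape

    def test_invalid_params_rejected(self):
        with pytest.raises(pp.ParameterError):
            pp.AsrParams(cutoff_k=0.0)
        with pytest.raises(pp.ParameterError):
            pp.AsrParams(processing_window_s=-1.0)


class TestSprFuse:
    def test_identical_inputs_identity(self, rng):
        x = rng.standard_normal(int(30 * FS))
        np.testing.assert_allclose(pp.spr_fuse(x, x, FS), x)

    def test_length_mismatch_raises(self):
        with pytest.raises(pp.ShapeError):
            pp.spr_fuse(np.zeros(100), np.zeros(99), FS)

    def test_alternating_spikes_smoother_than_either_input(self, rng):
        n = int(120 * FS)
        t = np.arange(n) / FS
        base = 0.5 + 0.3 * np.sin(2 * np.pi * 0.03 * t)
        spr1, spr2 = base.copy(), base.copy()
        for k, start_s in enumerate(range(10, 110, 10)):
            s = int(start_s * FS)
            spike = 3.0 * np.hanning(int(0.4 * FS))
            if k % 2 == 0:
                spr1[s: s + len(spike)] += spike
            else:
                spr2[s: s + len(spike)] += spike
        fused = pp.spr_fuse(spr1, spr2, FS)
        worst_input = min(np.abs(np.diff(spr1)).max(),
                          np.abs(np.diff(spr2)).max())
        assert np.abs(np.diff(fused)).max() < worst_input


class TestEcgSelect:
    def _clean(self, rng, n=int(30 * FS)):
        ecg, _ = synthetic._ecg_session(rng, n, FS, 72.0)
        return ecg[:, 0] - 0.02 * rng.standard_normal(n)  # near-noiseless

    def test_noisy_lead_rejected(self, rng):
        clean = self._clean(rng)
        noisy = clean + clean.std() * rng.standard_normal(len(clean))
        _, idx = pp.ecg_select(clean, noisy, FS)
        assert idx == 0
        _, idx = pp.ecg_select(noisy, clean, FS)
        assert idx == 1

    def test_tie_breaks_to_first_lead(self, rng):
        clean = self._clean(rng)
        selected, idx = pp.ecg_select(clean, clean.copy(), FS)
        assert idx == 0
        np.testing.assert_array_equal(selected, clean)

    def test_flat_lead_loses(self, rng):
        clean = self._clean(rng)
        _, idx = pp.ecg_select(np.zeros_like(clean), clean, FS)
        assert idx == 1

    def test_both_flat_is_degenerate(self):
        flat = np.zeros(int(30 * FS))
        with pytest.raises(pp.DegenerateInputError):
            pp.ecg_select(flat, flat.copy(), FS)

    def test_minimum_duration_enforced(self):
        with pytest.raises(pp.LengthError):
            pp.ecg_select(np.ones(100), np.ones(100), FS)


class TestExcision:
    def test_trace_shorter_than_recording_raises(self, rng):
        from mindfuse.io_formats import SyncRecording

        n = 2000
        t = np.arange(n) / FS
        rec = SyncRecording(
            subject_id="s", session=Session.MANUAL1, fs=FS,
            time=np.arange(n + 10) / FS,
            eeg=rng.standard_normal((n + 10, 6)),
            spr=rng.standard_normal((n + 10, 2)),
            ecg=rng.standard_normal((n + 10, 2)))
        trace = SimTrace(time=t, longitudinal_position=30 * t,
                         lateral_position=np.zeros(n))
        with pytest.raises(AlignmentError):
            pp.excise_obstacles(rec, trace, [100.0])


class TestGrossArtifactMask:
    def test_flags_whole_one_second_blocks(self, rng):
        eeg = 10.0 * rng.standard_normal((int(10 * FS), 6))
        eeg[int(3.5 * FS), 2] = 800.0
        mask = pp.gross_artifact_mask(eeg, FS, threshold_uv=500.0)
        assert mask[int(3.0 * FS): int(4.0 * FS)].all()
        assert not mask[: int(3.0 * FS)].any()
        assert not mask[int(4.0 * FS):].any()


@pytest.fixture(scope="module")
def session_pair():
    cfg = synthetic.CohortConfig(
        seed=21, n_subjects=1, manual_duration_s=80.0,
        adas_duration_s=40.0, obstacle_positions_m=(600.0,),
        obstacle_span_m=50.0, track_length_m=3000.0,
        zero_gap_rate_per_min=2.0,
    )
    recs, traces, truths = synthetic.generate_subject(cfg, "s01", 0)
    return cfg, recs[0], traces[0], truths[0]


class TestPipeline:
    def test_full_chain_shapes_and_segments(self, session_pair):
        cfg, rec, trace, truth = session_pair
        pcfg = pp.PreprocessConfig(
            asr=pp.AsrParams(calibration_window_s=30.0))
        cleaned = pp.preprocess_session(
            rec, trace, cfg.obstacle_positions_m, pcfg)
        assert cleaned.data.shape[1] == 8
        assert np.isfinite(cleaned.data).all()
        assert cleaned.data.shape[0] < len(rec)  # obstacle span removed
        segs = cleaned.segments()
        assert len(segs) == cleaned.data.shape[0] // 600
        assert all(s.label == 0 for s in segs)

    def test_archive_round_trip(self, session_pair, tmp_path):
        cfg, rec, trace, truth = session_pair
        pcfg = pp.PreprocessConfig(
            asr=pp.AsrParams(calibration_window_s=30.0))
        cleaned = pp.preprocess_session(
            rec, trace, cfg.obstacle_positions_m, pcfg)
        segs = cleaned.segments()
        path = tmp_path / "segments.npz"
        pp.save_segments(segs, path)
        back = pp.load_segments(path)
        assert len(back) == len(segs)
        for a, b in zip(segs, back):
            np.testing.assert_array_equal(a.data, b.data)
            assert (a.label, a.subject_id, a.session) == \
                (b.label, b.subject_id, b.session)


class TestSegmentType:
    def test_rejects_non_finite(self, rng):
        data = rng.standard_normal((600, 8))
        data[5, 2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            pp.Segment(data=data, label=0, subject_id="s",
                       session=Session.MANUAL1)

    def test_rejects_wrong_width(self, rng):
        with pytest.raises(pp.ShapeError):
            pp.Segment(data=rng.standard_normal((600, 7)), label=0,
                       subject_id="s", session=Session.MANUAL1)
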