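"""Shared fixtures: small synthetic cohorts and a light segment path.

The light path turns generated artifact-free recordings into labeled
segments through the fusion stages that change channel count (SPR fusion,
ECG lead selection + high-pass) while leaving the EEG channels raw; the
filtering and ASR stages have dedicated tests with injected corruption.
"""

import numpy as np
import pytest

from mindfuse import preprocessing as pp
from mindfuse import synthetic


def light_segments(cfg: synthetic.CohortConfig) -> list[pp.Segment]:
    segments = []
    for i in range(cfg.n_subjects):
        sid = f"s{i:02d}"
        recs, _, _ = synthetic.generate_subject(cfg, sid, i)
        for rec in recs:
            spr = pp.spr_fuse(rec.spr[:, 0], rec.spr[:, 1], cfg.fs)
            ecg_sel, _ = pp.ecg_select(rec.ecg[:, 0], rec.ecg[:, 1], cfg.fs)
            ecg = pp.ecg_highpass(ecg_sel, cfg.fs)
            data = np.column_stack([rec.eeg, spr, ecg])
            segments += pp.segment_and_label(data, cfg.fs, sid, rec.session)
    return segments


# conditions for the reduced-scale leave-one-subject-out checks:
# 5 subjects, three 90 s manual sessions and a 189 s autonomous session
# -> 153 segments per subject (90 high-engagement + 63 low-engagement)
LOSO_COHORT_KW = dict(
    n_subjects=5,
    manual_duration_s=90.0,
    manual_duration_jitter_s=0.0,
    adas_duration_s=189.0,
    obstacle_positions_m=(),
    track_length_m=100.0,
)


@pytest.fixture(scope="session")
def separable_segments():
    cfg = synthetic.CohortConfig.strongly_separable(
        seed=7, **LOSO_COHORT_KW).without_artifacts()
    return light_segments(cfg)


@pytest.fixture(scope="session")
def null_segments():
    cfg = synthetic.CohortConfig.null_effects(
        seed=11, **LOSO_COHORT_KW).without_artifacts()
    return light_segments(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
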