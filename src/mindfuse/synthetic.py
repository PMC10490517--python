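"""Synthetic multimodal driving-cohort generator.

Emulates a driving-simulator experiment in which every subject completes
three manual sessions (~7 min each, high mental engagement) and one
autonomous ADAS session (~20 min, low engagement) while six EEG channels,
two skin-potential (SPR) channels and two ECG leads are recorded at
200 Sa/s, synchronized with a vehicle-dynamics trace.  Engagement enters
the signals through three class-conditional effects:

* EEG — frontal theta (4–8 Hz) power is raised and occipital alpha
  (8–13 Hz) power lowered under high engagement, on top of a 1/f
  background and band-limited delta/beta activity;
* ECG — heart rate is higher during manual driving;
* SPR — phasic electrodermal responses (fast rise, slow decay) occur at a
  higher rate under high engagement, over a shared slow tonic baseline.

Artifacts (blinks, baseline drift, electrode pops, hand-motion spikes,
respiration wander, dropped-packet zero runs) are injected separately with
full ground-truth bookkeeping so every cleaning stage downstream can be
tested against known corruption.  All randomness flows from one root seed
through per-subject, per-session substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from .io_formats import (
    Session,
    SimTrace,
    SyncRecording,
    write_sim_csv,
    write_sync_csv,
)

EEG_NAMES = ("Fp1", "Fp2", "C3", "C4", "O1", "O2")
FRONTAL = (0, 1)     # Fp1, Fp2
CENTRAL = (2, 3)     # C3, C4
OCCIPITAL = (4, 5)   # O1, O2


class ConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclasses.dataclass
class CohortConfig:
    """Study-design and signal-model parameters for one synthetic cohort.

    Defaults mirror the emulated experiment: 19 subjects, three ~420 s
    manual sessions and one 1200 s autonomous session at 200 Sa/s, a 14 km
    track with six 200 m obstacle zones spaced 2 km apart starting at 2 km,
    driven at ~120 km/h.  Effect sizes are model parameters, not claims
    about real physiology.
    """

    n_subjects: int = 19
    fs: float = 200.0
    manual_sessions: int = 3
    manual_duration_s: float = 420.0
    manual_duration_jitter_s: float = 0.0    # per-subject spread, opt-in
    adas_duration_s: float = 1200.0
    obstacle_positions_m: tuple[float, ...] = (
        2000.0, 4000.0, 6000.0, 8000.0, 10000.0, 12000.0
    )
    obstacle_span_m: float = 200.0
    mean_speed_mps: float = 33.3          # ~120 km/h
    track_length_m: float = 14000.0

    # engagement effects
    eeg_band_power_shift: float = 0.5     # frontal theta up / occipital alpha
                                          # down by this relative factor
    hr_manual_bpm: float = 80.0
    hr_adas_bpm: float = 68.0
    spr_rate_manual_per_min: float = 6.0
    spr_rate_adas_per_min: float = 2.0

    # artifact rates (0 disables)
    blink_rate_per_min: float = 12.0
    drift_amplitude_uv: float = 40.0
    pop_rate_per_min: float = 1.0
    spr_spike_rate_per_min: float = 1.0
    ecg_wander_amplitude_mv: float = 0.25
    zero_gap_rate_per_min: float = 0.5
    zero_gap_max_samples: int = 8

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        for name in ("manual_duration_s", "adas_duration_s", "fs"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        span_end = max(self.obstacle_positions_m, default=0.0) \
            + self.obstacle_span_m
        if self.obstacle_positions_m and span_end > self.track_length_m:
            raise ConfigError("obstacle spans exceed track length")

    @classmethod
    def null_effects(cls, **overrides) -> "CohortConfig":
        """Both classes drawn from one signal distribution (chance-level
        oracle for the downstream classifiers)."""
        return cls(
            eeg_band_power_shift=0.0,
            hr_manual_bpm=72.0, hr_adas_bpm=72.0,
            spr_rate_manual_per_min=3.0, spr_rate_adas_per_min=3.0,
            **overrides,
        )

    @classmethod
    def strongly_separable(cls, **overrides) -> "CohortConfig":
        """Large configured effects on all three modalities; classes are
        separable by construction."""
        return cls(
            eeg_band_power_shift=2.0,
            hr_manual_bpm=85.0, hr_adas_bpm=65.0,
            spr_rate_manual_per_min=8.0, spr_rate_adas_per_min=1.0,
            **overrides,
        )

    def without_artifacts(self) -> "CohortConfig":
        return dataclasses.replace(
            self, blink_rate_per_min=0.0, drift_amplitude_uv=0.0,
            pop_rate_per_min=0.0, spr_spike_rate_per_min=0.0,
            ecg_wander_amplitude_mv=0.0, zero_gap_rate_per_min=0.0,
        )


@dataclasses.dataclass
class SyntheticGroundTruth:
    """Per-session bookkeeping of everything the generator injected."""

    session: Session
    engagement_class: int                      # 0 manual/high, 1 ADAS/low
    obstacle_ranges: list[tuple[int, int]]     # half-open sample ranges of
                                               # the 200 m obstacle cores
    artifacts: dict[str, list[dict]]           # channel -> injected events
    zero_gaps: dict[str, list[tuple[int, int]]]

    def to_json(self) -> dict:
        return {
            "session": self.session.value,
            "engagement_class": self.engagement_class,
            "obstacle_ranges": [list(r) for r in self.obstacle_ranges],
            "artifacts": self.artifacts,
            "zero_gaps": {k: [list(r) for r in v]
                          for k, v in self.zero_gaps.items()},
        }


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                f_lo: float, f_hi: float, rms: float) -> np.ndarray:
    """Gaussian noise band-limited to [f_lo, f_hi] with the requested RMS."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    y = np.fft.irfft(spec, n)
    s = np.std(y)
    return y * (rms / s) if s > 0 else y


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                rms: float) -> np.ndarray:
    """1/f-amplitude background (flat below 1 Hz)."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec *= 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    y = np.fft.irfft(spec, n)
    return y * (rms / np.std(y))


def _eeg_session(rng: np.random.Generator, n: int, fs: float,
                 engaged: bool, shift: float) -> np.ndarray:
    """Six EEG channels (µV): 1/f background + delta/theta/alpha/beta bands
    with engagement-dependent frontal-theta and occipital-alpha power."""
    theta_gain = 1.0 + shift if engaged else 1.0
    alpha_gain = 1.0 / (1.0 + shift) if engaged else 1.0
    eeg = np.empty((n, 6))
    for ch in range(6):
        theta_rms = 4.0 * (theta_gain if ch in FRONTAL else 1.0)
        alpha_base = 8.0 if ch in OCCIPITAL else 5.0
        alpha_rms = alpha_base * (alpha_gain if ch in OCCIPITAL else 1.0)
        eeg[:, ch] = (
            _pink_noise(rng, n, fs, 5.0)
            + _band_noise(rng, n, fs, 1.0, 4.0, 5.0)
            + _band_noise(rng, n, fs, 4.0, 8.0, theta_rms)
            + _band_noise(rng, n, fs, 8.0, 13.0, alpha_rms)
            + _band_noise(rng, n, fs, 13.0, 30.0, 3.0)
        )
    return eeg


# PQRST morphology as Gaussian bumps: (center s, amplitude mV, width s)
_PQRST = (
    (-0.20, 0.12, 0.025),   # P
    (-0.03, -0.15, 0.010),  # Q
    (0.00, 1.00, 0.012),    # R
    (0.03, -0.20, 0.010),   # S
    (0.22, 0.30, 0.050),    # T
)


def _ecg_session(rng: np.random.Generator, n: int, fs: float,
                 hr_bpm: float) -> tuple[np.ndarray, np.ndarray]:
    """Two ECG leads (mV) from one PQRST train at the target heart rate
    with 4% RR jitter; returns (leads (n, 2), r_peak_samples)."""
    mean_rr = 60.0 / hr_bpm
    n_beats = int(np.ceil(n / fs / mean_rr)) + 3
    rr = mean_rr * (1.0 + 0.04 * rng.standard_normal(n_beats))
    r_times = np.cumsum(rr) - rr[0] + 0.4
    t = np.arange(n) / fs
    ecg = np.zeros(n)
    half = 0.45  # template half-width, s
    for rt in r_times:
        if rt - half > t[-1]:
            break
        lo = max(0, int((rt - half) * fs))
        hi = min(n, int((rt + half) * fs) + 1)
        tt = t[lo:hi] - rt
        for c, a, w in _PQRST:
            ecg[lo:hi] += a * np.exp(-0.5 * ((tt - c) / w) ** 2)
    r_peaks = np.array([int(round(rt * fs)) for rt in r_times
                        if 0 <= rt * fs < n])
    lead1 = ecg + 0.02 * rng.standard_normal(n)
    lead2 = 0.7 * ecg + 0.02 * rng.standard_normal(n)
    return np.column_stack([lead1, lead2]), r_peaks


def _spr_session(rng: np.random.Generator, n: int, fs: float,
                 rate_per_min: float) -> np.ndarray:
    """Two SPR channels (mV): shared tonic baseline + shared phasic
    responses (1 s rise, 3 s decay) at the class rate + per-hand noise."""
    t = np.arange(n) / fs
    tonic = _band_noise(rng, n, fs, 0.0, 0.05, 0.3) + 0.5
    phasic = np.zeros(n)
    n_events = rng.poisson(rate_per_min * n / fs / 60.0)
    starts = np.sort(rng.uniform(0, n / fs, n_events))
    kernel_t = np.arange(0, 10.0, 1.0 / fs)
    kernel = (1.0 - np.exp(-kernel_t / 0.8)) * np.exp(-kernel_t / 3.0)
    kernel /= kernel.max()
    for s in starts:
        amp = 0.4 * rng.lognormal(0.0, 0.4)
        i0 = int(s * fs)
        seg = min(len(kernel), n - i0)
        phasic[i0:i0 + seg] += amp * kernel[:seg]
    shared = tonic + phasic
    noise = 0.02 * rng.standard_normal((n, 2))
    return shared[:, None] + noise


def _sim_trace(rng: np.random.Generator, n: int, fs: float,
               mean_speed: float, autonomous: bool) -> SimTrace:
    """1-D track trace: manual speed = mean + slow noise (invertible
    position/time map); autonomous speed is exactly constant."""
    t = np.arange(n) / fs
    if autonomous:
        speed = np.full(n, mean_speed)
    else:
        speed = mean_speed * (1.0 + 0.05 * _band_noise(
            rng, n, fs, 0.0, 0.02, 1.0))
        speed = np.maximum(speed, 1.0)
    pos = np.cumsum(speed) / fs
    pos -= pos[0]
    lateral = 1.5 * _band_noise(rng, n, fs, 0.0, 0.1, 1.0)
    return SimTrace(time=t, longitudinal_position=pos,
                    lateral_position=lateral)


def _obstacle_ranges(trace: SimTrace, positions: tuple[float, ...],
                     span: float) -> list[tuple[int, int]]:
    """Half-open sample ranges where the vehicle is inside an obstacle core."""
    out = []
    pos = trace.longitudinal_position
    for p in positions:
        inside = np.flatnonzero((pos >= p) & (pos < p + span))
        if inside.size:
            out.append((int(inside[0]), int(inside[-1]) + 1))
    return out


def _subject_rng(config: CohortConfig, seed_offset: int,
                 session_idx: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(seed_offset, session_idx))
    return np.random.default_rng(ss)


def generate_subject(
    config: CohortConfig, subject_id: str, seed_offset: int,
) -> tuple[list[SyncRecording], list[SimTrace], list[SyntheticGroundTruth]]:
    """Generate one subject's four sessions (Manual1–3 then ADAS).

    Recording and simulator trace share the session length
    ``round(duration * fs)``; each session draws its own substream of the
    cohort seed, so subjects are independent but fully reproducible.
    """
    sessions = [Session.MANUAL1, Session.MANUAL2, Session.MANUAL3][
        : config.manual_sessions] + [Session.ADAS]
    recs, traces, truths = [], [], []
    for k, sess in enumerate(sessions):
        rng = _subject_rng(config, seed_offset, k)
        engaged = sess.is_manual
        if engaged:
            dur = config.manual_duration_s + config.manual_duration_jitter_s \
                * rng.uniform(-1.0, 1.0)
        else:
            dur = config.adas_duration_s
        n_trace = int(round(dur * config.fs))
        n_rec = n_trace

        trace = _sim_trace(rng, n_trace, config.fs, config.mean_speed_mps,
                           autonomous=not engaged)
        eeg = _eeg_session(rng, n_rec, config.fs, engaged,
                           config.eeg_band_power_shift)
        hr = config.hr_manual_bpm if engaged else config.hr_adas_bpm
        ecg, _ = _ecg_session(rng, n_rec, config.fs, hr)
        rate = (config.spr_rate_manual_per_min if engaged
                else config.spr_rate_adas_per_min)
        spr = _spr_session(rng, n_rec, config.fs, rate)

        rec = SyncRecording(
            subject_id=subject_id, session=sess, fs=config.fs,
            time=np.arange(n_rec) / config.fs,
            eeg=eeg, spr=spr, ecg=ecg,
        )
        rec, truth = inject_artifacts(rec, config, rng)
        truth.session = sess
        truth.engagement_class = 0 if engaged else 1
        truth.obstacle_ranges = _obstacle_ranges(
            trace, config.obstacle_positions_m, config.obstacle_span_m)
        recs.append(rec)
        traces.append(trace)
        truths.append(truth)
    return recs, traces, truths


def _poisson_starts(rng: np.random.Generator, rate_per_min: float,
                    n: int, fs: float) -> np.ndarray:
    count = rng.poisson(rate_per_min * n / fs / 60.0)
    return np.sort(rng.integers(0, n, count))


def inject_artifacts(
    rec: SyncRecording, config: CohortConfig, rng: np.random.Generator,
) -> tuple[SyncRecording, SyntheticGroundTruth]:
    """Corrupt a clean recording with the artifact classes the cleaning
    pipeline targets, returning exact injected locations.

    Blinks on Fp1/Fp2, slow baseline drift on C3/C4, electrode-pop steps on
    O1/O2, motion spikes on one SPR hand at a time, respiration-band wander
    on both ECG leads, and dropped-packet zero runs per sensor group.  All
    rates of zero give an identical output.
    """
    n, fs = len(rec), rec.fs
    ch = rec.channels.copy()
    t = np.arange(n) / fs
    artifacts: dict[str, list[dict]] = {}
    zero_gaps: dict[str, list[tuple[int, int]]] = {}

    def log(channel: str, kind: str, s: int, e: int) -> None:
        artifacts.setdefault(channel, []).append(
            {"kind": kind, "start": int(s), "end": int(e)})

    # blinks: correlated positive bumps on both frontal channels
    if config.blink_rate_per_min > 0:
        width = int(0.12 * fs)
        bump = 150.0 * np.exp(
            -0.5 * ((np.arange(2 * width) - width) / (width / 2.5)) ** 2)
        for s in _poisson_starts(rng, config.blink_rate_per_min, n, fs):
            e = min(n, s + 2 * width)
            amp = rng.uniform(0.8, 1.3)
            ch[s:e, 0] += amp * bump[: e - s]
            ch[s:e, 1] += 0.9 * amp * bump[: e - s]
            log("Fp1", "blink", s, e)
            log("Fp2", "blink", s, e)

    # slow drift on central channels (below the 4 Hz high-pass)
    if config.drift_amplitude_uv > 0:
        for idx, name in ((2, "C3"), (3, "C4")):
            f = rng.uniform(0.05, 0.3)
            phase = rng.uniform(0, 2 * np.pi)
            ch[:, idx] += config.drift_amplitude_uv * np.sin(
                2 * np.pi * f * t + phase)
            log(name, "drift", 0, n)

    # electrode-pop steps with slow decay on occipital channels
    if config.pop_rate_per_min > 0:
        for idx, name in ((4, "O1"), (5, "O2")):
            for s in _poisson_starts(rng, config.pop_rate_per_min, n, fs):
                amp = rng.choice([-1.0, 1.0]) * rng.uniform(150.0, 300.0)
                decay = np.exp(-(t[s:] - t[s]) / 1.0)
                ch[s:, idx] += amp * decay
                log(name, "pop", s, min(n, s + int(3 * fs)))

    # hand-motion spikes, alternating hands
    if config.spr_spike_rate_per_min > 0:
        starts = _poisson_starts(
            rng, 2 * config.spr_spike_rate_per_min, n, fs)
        width = int(0.3 * fs)
        spike = np.hanning(2 * width)
        for i, s in enumerate(starts):
            hand = i % 2            # one channel at a time
            e = min(n, s + 2 * width)
            ch[s:e, 6 + hand] += 2.0 * spike[: e - s]
            log(f"SPR{hand + 1}", "motion_spike", s, e)

    # respiration baseline wander on both ECG leads
    if config.ecg_wander_amplitude_mv > 0:
        f = rng.uniform(0.2, 0.3)
        wander = config.ecg_wander_amplitude_mv * np.sin(2 * np.pi * f * t)
        ch[:, 8] += wander
        ch[:, 9] += 0.8 * wander
        log("ECG1", "wander", 0, n)
        log("ECG2", "wander", 0, n)

    # dropped-packet zero runs, per sensor group
    if config.zero_gap_rate_per_min > 0:
        groups = {
            "EEG": [0, 1, 2, 3, 4, 5],
            "SPR1": [6], "SPR2": [7],
            "ECG": [8, 9],
        }
        names = list(groups)
        for s in _poisson_starts(rng, config.zero_gap_rate_per_min, n, fs):
            g = names[rng.integers(len(names))]
            run = int(rng.integers(1, config.zero_gap_max_samples + 1))
            e = min(n, s + run)
            for idx in groups[g]:
                ch[s:e, idx] = 0.0
                col = ("Fp1", "Fp2", "C3", "C4", "O1", "O2",
                       "SPR1", "SPR2", "ECG1", "ECG2")[idx]
                zero_gaps.setdefault(col, []).append((int(s), int(e)))

    truth = SyntheticGroundTruth(
        session=rec.session, engagement_class=0 if rec.session.is_manual
        else 1, obstacle_ranges=[], artifacts=artifacts,
        zero_gaps=zero_gaps,
    )
    return rec.replace_channels(ch), truth


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> Path:
    """Write a full cohort to disk: one folder per subject with four session
    CSVs, four trace CSVs and a ground-truth JSON sidecar per session, plus
    a cohort manifest.  Deterministic under ``config.seed``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "subjects": [],
    }
    for i in range(config.n_subjects):
        sid = f"subject{i + 1:02d}"
        sdir = out_dir / sid
        sdir.mkdir(exist_ok=True)
        recs, traces, truths = generate_subject(config, sid, i)
        for rec, trace, truth in zip(recs, traces, truths):
            base = f"{sid}_{rec.session.value}"
            write_sync_csv(rec, sdir / f"{base}.csv")
            write_sim_csv(trace, sdir / f"{base}_trace.csv")
            (sdir / f"{base}_truth.json").write_text(
                json.dumps(truth.to_json()))
        manifest["subjects"].append(sid)
    digest = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()
    manifest["config_digest"] = digest
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
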