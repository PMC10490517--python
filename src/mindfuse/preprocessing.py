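"""Signal-cleaning pipeline: notch, EEG band-limit + artifact subspace
reconstruction, SPR two-channel fusion, ECG lead selection + high-pass,
obstacle excision, and segmentation into labeled 3 s windows.

Stage order is fixed: notch on all channels, then per modality
(EEG: FIR band-limit then ASR; SPR: local-energy fusion; ECG: SNR-based
lead selection then 0.5 Hz IIR high-pass), then synchronized removal of
obstacle spans and gross-amplitude blocks, then non-overlapping windowing.
Every stage preserves cross-channel synchronicity: removal operates on one
shared index mask applied to all channels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .io_formats import Session, SimTrace, SyncRecording

CLEAN_CHANNELS = ("Fp1", "Fp2", "C3", "C4", "O1", "O2", "SPR", "ECG")


class ParameterError(ValueError):
    """Filter parameter outside the valid range (e.g. cutoff >= Nyquist)."""


class LengthError(ValueError):
    """Signal too short for the requested operation."""


class ShapeError(ValueError):
    """Mismatched array shapes."""


class DegenerateInputError(ValueError):
    """Input has no usable signal content (flat channel, rank-deficient)."""


@dataclasses.dataclass
class FilterSpec:
    """Declarative filter description used in run configs."""

    kind: str                      # butterworth_bandstop | fir_highpass |
                                   # fir_lowpass | iir_highpass
    cutoffs: tuple[float, ...]     # Hz
    order: int                     # taps (FIR) or poles (IIR)
    zero_phase: bool = True


@dataclasses.dataclass
class AsrParams:
    """Artifact-subspace-reconstruction parameters.

    ``cutoff_k`` is the standard-deviation multiplier on per-component RMS
    statistics of the calibration data; components of a processing window
    whose variance exceeds the rotated threshold are removed and the window
    is reconstructed from the calibration subspace.
    """

    calibration_window_s: float = 60.0
    cutoff_k: float = 20.0
    processing_window_s: float = 0.5
    max_bad_channels_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.cutoff_k <= 0:
            raise ParameterError("cutoff_k must be positive")
        if self.calibration_window_s <= 0 or self.processing_window_s <= 0:
            raise ParameterError("ASR windows must be positive")


@dataclasses.dataclass
class Segment:
    """One labeled 3 s window of the eight cleaned channels.

    label 0 = high engagement (manual driving), 1 = low (autonomous).
    """

    data: np.ndarray          # (window_samples, 8)
    label: int
    subject_id: str
    session: Session

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(CLEAN_CHANNELS):
            raise ShapeError(
                f"segment data must be (n, 8), got {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("segment contains non-finite values")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def notch_filter(x: np.ndarray, fs: float, low: float = 46.0,
                 high: float = 54.0, order: int = 4) -> np.ndarray:
    """Power-line notch: Butterworth band-stop applied forward-backward.

    Works on 1-D signals or (n, channels) arrays along axis 0.
    """
    if high >= fs / 2 or low >= fs / 2:
        raise ParameterError(
            f"notch cutoffs ({low}, {high}) must lie below Nyquist {fs / 2}")
    sos = sps.butter(order, [low, high], btype="bandstop", fs=fs,
                     output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def _fir_taps(fs: float, cutoff: float, transition: float,
              pass_zero: bool) -> np.ndarray:
    # Hamming-window design; ~3.3/Δf normalized transition width
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    return sps.firwin(numtaps, cutoff, fs=fs, pass_zero=pass_zero,
                      window="hamming")


def eeg_bandlimit(eeg: np.ndarray, fs: float, hp: float = 4.0,
                  lp: float = 45.0, hp_transition: float = 2.0,
                  lp_transition: float = 5.0) -> np.ndarray:
    """Linear-phase FIR band-limit of the EEG channels (default 4–45 Hz).

    Windowed-sinc (Hamming) high-pass then low-pass, each applied with the
    group delay compensated (odd tap count, 'same'-mode convolution), so
    EEG events stay time-aligned with the SPR/ECG channels.
    """
    if not 0 < hp < fs / 2 or not 0 < lp < fs / 2:
        raise ParameterError("cutoffs must lie in (0, Nyquist)")
    taps_hp = _fir_taps(fs, hp, hp_transition, pass_zero=False)
    taps_lp = _fir_taps(fs, lp, lp_transition, pass_zero=True)
    n = eeg.shape[0]
    if n < 3 * max(len(taps_hp), len(taps_lp)):
        raise LengthError(
            f"signal length {n} < 3x filter length "
            f"{max(len(taps_hp), len(taps_lp))}")
    x = np.atleast_2d(eeg.T)
    out = np.empty_like(x)
    for i, chan in enumerate(x):
        y = sps.fftconvolve(chan, taps_hp, mode="same")
        out[i] = sps.fftconvolve(y, taps_lp, mode="same")
    return out.T.reshape(eeg.shape)


def ecg_highpass(ecg: np.ndarray, fs: float, fc: float = 0.5,
                 order: int = 2) -> np.ndarray:
    """Baseline-wander removal: Butterworth IIR high-pass, zero phase.

    Default 0.5 Hz, order 2, applied forward-backward so QRS morphology is
    preserved.
    """
    if fc >= fs / 2:
        raise ParameterError(f"cutoff {fc} must lie below Nyquist {fs / 2}")
    sos = sps.butter(order, fc, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, ecg, axis=0)


# ---------------------------------------------------------------------------
# artifact subspace reconstruction
# ---------------------------------------------------------------------------

def _sliding_rms(x: np.ndarray, win: int) -> np.ndarray:
    """RMS over non-overlapping windows, per row of (channels, n)."""
    n = x.shape[-1] // win
    if n == 0:
        raise LengthError("signal shorter than one RMS window")
    y = x[..., : n * win].reshape(*x.shape[:-1], n, win)
    return np.sqrt(np.mean(y ** 2, axis=-1))


def _select_calibration(eeg_t: np.ndarray, fs: float, need_s: float,
                        exclude: np.ndarray | None) -> np.ndarray:
    """Pick the cleanest 1 s blocks (lowest max channel-RMS z-score) until
    the calibration budget is met; returns the concatenated block data."""
    win = int(fs)
    n_blocks = eeg_t.shape[1] // win
    rms = _sliding_rms(eeg_t, win)                       # (ch, blocks)
    mu = rms.mean(axis=1, keepdims=True)
    sd = rms.std(axis=1, keepdims=True) + 1e-12
    score = ((rms - mu) / sd).max(axis=0)                # worst channel
    if exclude is not None:
        blocked = exclude[: n_blocks * win].reshape(n_blocks, win).any(axis=1)
        score = np.where(blocked, np.inf, score)
    order = np.argsort(score, kind="stable")
    take = min(n_blocks, max(1, int(np.ceil(need_s))))
    keep = np.sort(order[:take])
    keep = keep[np.isfinite(score[keep])] if np.isfinite(
        score[keep]).any() else keep[:1]
    blocks = [eeg_t[:, b * win: (b + 1) * win] for b in keep]
    return np.concatenate(blocks, axis=1)


def asr_clean(eeg: np.ndarray, fs: float,
              params: AsrParams | None = None,
              exclude_mask: np.ndarray | None = None) -> np.ndarray:
    """Artifact subspace reconstruction on band-limited EEG (n, channels).

    1. Calibration: the cleanest 1 s blocks by channel-RMS z-score (blocks
       flagged in ``exclude_mask`` are never used) up to
       ``calibration_window_s``.
    2. Per-component thresholds: RMS statistics of the whitened calibration
       data over sliding windows, scaled by ``cutoff_k``.
    3. Each half-overlapping processing window is eigendecomposed in the
       calibration-whitened space; components whose variance exceeds the
       rotated threshold are removed and the window is re-expressed through
       the calibration mixing matrix.
    4. Windows are blended by Hann overlap-add.

    On artifact-free data the output closely matches the input.
    """
    params = params or AsrParams()
    x = eeg.T.astype(np.float64)                         # (ch, n)
    n_ch, n = x.shape
    if n < params.calibration_window_s * fs / 4 or n < fs:
        raise LengthError("not enough data for ASR calibration")
    variances = x.var(axis=1)
    if np.any(variances < 1e-15):
        raise DegenerateInputError(
            f"zero-variance channel(s) {np.flatnonzero(variances < 1e-15)}")

    xc = _select_calibration(x, fs, params.calibration_window_s,
                             exclude_mask)
    cov = xc @ xc.T / xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * evals[-1]:
        raise DegenerateInputError("rank-deficient calibration covariance")
    mixing = evecs @ np.diag(np.sqrt(evals)) @ evecs.T        # sqrtm(cov)
    whitening = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T

    win = max(4, int(round(params.processing_window_s * fs)))
    yc = whitening @ xc
    rms_c = _sliding_rms(yc, win)                        # (ch, windows)
    thresh = rms_c.mean(axis=1) + params.cutoff_k * rms_c.std(axis=1)
    thresh_var = thresh ** 2                             # variance scale

    hop = max(1, win // 2)
    taper = np.hanning(win)
    num = np.zeros_like(x)
    den = np.zeros(n)
    starts = list(range(0, max(1, n - win + 1), hop))
    if starts[-1] + win < n:
        starts.append(n - win)
    for s in starts:
        seg = x[:, s: s + win]
        y = whitening @ seg
        cw = y @ y.T / y.shape[1]
        s_w, u_w = np.linalg.eigh(cw)
        # rotate the per-component variance thresholds into the window basis
        limit = (u_w ** 2 * thresh_var[:, None]).sum(axis=0)
        keep = s_w <= limit
        if keep.all():
            clean = seg
        else:
            proj = u_w @ np.diag(keep.astype(float)) @ u_w.T
            clean = mixing @ (proj @ y)
        w = taper[: seg.shape[1]]
        num[:, s: s + win] += clean * w
        den[s: s + win] += w
    out = np.where(den > 1e-6, num / np.maximum(den, 1e-12), x)
    return out.T.reshape(eeg.shape)


# ---------------------------------------------------------------------------
# SPR fusion and ECG lead selection
# ---------------------------------------------------------------------------

def spr_fuse(spr1: np.ndarray, spr2: np.ndarray, fs: float,
             energy_window_s: float = 1.0,
             crossfade_s: float = 0.1) -> np.ndarray:
    """Fuse the two hands' SPR signals into one motion-robust channel.

    At each sample the signal whose first difference carries less local
    energy (moving average over ``energy_window_s``) is selected — a hand
    moving on the wheel or gear produces a burst of difference energy, so
    the quieter hand wins.  Switches are cross-faded over ``crossfade_s``
    to avoid discontinuities.  Ties select the first (right-hand) channel.
    """
    if spr1.shape != spr2.shape:
        raise ShapeError(
            f"SPR shapes differ: {spr1.shape} vs {spr2.shape}")
    win = max(1, int(round(energy_window_s * fs)))
    kernel = np.ones(win) / win

    def local_energy(x: np.ndarray) -> np.ndarray:
        d = np.diff(x, prepend=x[0])
        return sps.fftconvolve(d ** 2, kernel, mode="same")

    e1, e2 = local_energy(spr1), local_energy(spr2)
    choose1 = (e1 <= e2).astype(np.float64)
    fade = max(1, int(round(crossfade_s * fs)))
    if fade > 1:
        ramp = np.hanning(2 * fade + 1)
        ramp /= ramp.sum()
        weight = sps.fftconvolve(choose1, ramp, mode="same")
        weight = np.clip(weight, 0.0, 1.0)
    else:
        weight = choose1
    return weight * spr1 + (1.0 - weight) * spr2


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float,
                hi: float) -> float:
    m = (freqs >= lo) & (freqs <= hi)
    return float(np.trapezoid(psd[m], freqs[m])) if m.any() else 0.0


def _ecg_snr(x: np.ndarray, fs: float) -> float:
    """QRS-band power over out-of-band power plus residual broadband noise.

    Signal band: 5–25 Hz (QRS energy).  Noise: power outside [0.5, 40] Hz
    plus a robust broadband-noise floor from the median absolute deviation
    of the 40 Hz–Nyquist component.
    """
    if np.var(x) < 1e-18:
        return 0.0
    nper = min(len(x), int(4 * fs))
    freqs, psd = sps.welch(x, fs=fs, nperseg=nper)
    qrs = _band_power(freqs, psd, 5.0, 25.0)
    out_of_band = _band_power(freqs, psd, 0.0, 0.5) \
        + _band_power(freqs, psd, 40.0, fs / 2)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(len(x), 1.0 / fs)
    spec[(f < 40.0)] = 0.0
    hf = np.fft.irfft(spec, len(x))
    mad = np.median(np.abs(hf - np.median(hf)))
    broadband = (mad / 0.6745) ** 2
    return qrs / (out_of_band + broadband + 1e-18)


def ecg_select(ecg1: np.ndarray, ecg2: np.ndarray,
               fs: float) -> tuple[np.ndarray, int]:
    """Pick the higher-SNR ECG lead; ties go to the first lead."""
    if ecg1.shape != ecg2.shape:
        raise ShapeError("ECG leads have different lengths")
    if len(ecg1) < 10 * fs:
        raise LengthError("need at least 10 s of ECG for SNR estimation")
    s1, s2 = _ecg_snr(ecg1, fs), _ecg_snr(ecg2, fs)
    if s1 == 0.0 and s2 == 0.0:
        raise DegenerateInputError("both ECG leads are flat")
    idx = 0 if s1 >= s2 else 1
    return (ecg1 if idx == 0 else ecg2), idx


# ---------------------------------------------------------------------------
# excision and segmentation
# ---------------------------------------------------------------------------

def obstacle_mask(trace: SimTrace, obstacle_positions_m, n: int,
                  span_m: float = 200.0,
                  margin_m: float = 500.0) -> np.ndarray:
    """Boolean mask (length n) of samples whose longitudinal position lies
    within [p - margin, p + span + margin) of any obstacle start p."""
    pos = trace.longitudinal_position[:n]
    mask = np.zeros(n, dtype=bool)
    for p in obstacle_positions_m:
        mask |= (pos >= p - margin_m) & (pos < p + span_m + margin_m)
    return mask


def excise_obstacles(rec: SyncRecording, trace: SimTrace,
                     obstacle_positions_m, span_m: float = 200.0,
                     margin_m: float = 500.0) -> SyncRecording:
    """Drop all samples recorded while traversing an obstacle zone
    (200 m works span extended by 500 m on each side), identically across
    every channel; the time base is rebuilt after concatenation."""
    from .io_formats import AlignmentError

    n = len(rec)
    if len(trace) < n:
        raise AlignmentError(
            f"trace ({len(trace)} samples) shorter than recording ({n})")
    keep = ~obstacle_mask(trace, obstacle_positions_m, n, span_m, margin_m)
    channels = rec.channels[keep]
    time = np.arange(keep.sum()) / rec.fs
    return rec.replace_channels(channels, time=time)


def gross_artifact_mask(eeg: np.ndarray, fs: float,
                        threshold_uv: float = 500.0) -> np.ndarray:
    """Automated stand-in for visual inspection: flag every 1 s block in
    which any EEG channel exceeds ``threshold_uv`` in magnitude."""
    n = eeg.shape[0]
    win = int(fs)
    mask = np.zeros(n, dtype=bool)
    for b in range(0, n, win):
        if np.abs(eeg[b: b + win]).max() > threshold_uv:
            mask[b: b + win] = True
    return mask[:n]


def segment_and_label(data: np.ndarray, fs: float, subject_id: str,
                      session: Session,
                      window_s: float = 3.0) -> list[Segment]:
    """Cut a cleaned 8-channel recording into consecutive non-overlapping
    windows of round(window_s * fs) samples (600 for 3 s at 200 Sa/s); the
    trailing partial window is dropped.  Labels follow the session: 0 for
    manual (high engagement), 1 for autonomous (low)."""
    win = int(round(window_s * fs))
    n_seg = data.shape[0] // win
    label = 0 if session.is_manual else 1
    return [
        Segment(data=data[i * win: (i + 1) * win], label=label,
                subject_id=subject_id, session=session)
        for i in range(n_seg)
    ]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PreprocessConfig:
    """All cleaning-stage parameters with their experiment defaults."""

    notch_low_hz: float = 46.0
    notch_high_hz: float = 54.0
    notch_order: int = 4
    eeg_hp_hz: float = 4.0
    eeg_lp_hz: float = 45.0
    asr: AsrParams = dataclasses.field(default_factory=AsrParams)
    apply_asr: bool = True
    spr_energy_window_s: float = 1.0
    spr_crossfade_s: float = 0.1
    ecg_hp_hz: float = 0.5
    ecg_hp_order: int = 2
    obstacle_span_m: float = 200.0
    obstacle_margin_m: float = 500.0
    gross_threshold_uv: float = 500.0
    window_s: float = 3.0
    min_zero_run: int = 1


@dataclasses.dataclass
class CleanedSession:
    """One session after the full cleaning chain: 8 synchronized channels
    (6 EEG, fused SPR, selected+filtered ECG), obstacle spans removed."""

    subject_id: str
    session: Session
    fs: float
    data: np.ndarray  # (n, 8)
    ecg_lead: int

    def segments(self, window_s: float = 3.0) -> list[Segment]:
        return segment_and_label(self.data, self.fs, self.subject_id,
                                 self.session, window_s)


def preprocess_session(rec: SyncRecording, trace: SimTrace,
                       obstacle_positions_m=(),
                       config: PreprocessConfig | None = None,
                       ) -> CleanedSession:
    """Run the full cleaning chain on one session.

    zero-gap repair -> simulator alignment -> notch -> (EEG band-limit +
    ASR | SPR fusion | ECG selection + high-pass) -> synchronized removal
    of obstacle spans and gross-amplitude blocks.
    """
    from .io_formats import align_to_sim, interpolate_zero_gaps

    cfg = config or PreprocessConfig()
    rec = interpolate_zero_gaps(rec, cfg.min_zero_run)
    rec = align_to_sim(rec, trace)
    fs = rec.fs

    channels = notch_filter(rec.channels, fs, cfg.notch_low_hz,
                            cfg.notch_high_hz, cfg.notch_order)
    eeg, spr, ecg = channels[:, 0:6], channels[:, 6:8], channels[:, 8:10]

    gross = gross_artifact_mask(eeg, fs, cfg.gross_threshold_uv)
    eeg = eeg_bandlimit(eeg, fs, cfg.eeg_hp_hz, cfg.eeg_lp_hz)
    if cfg.apply_asr:
        eeg = asr_clean(eeg, fs, cfg.asr, exclude_mask=gross)

    spr_clean = spr_fuse(spr[:, 0], spr[:, 1], fs,
                         cfg.spr_energy_window_s, cfg.spr_crossfade_s)
    ecg_sel, lead = ecg_select(ecg[:, 0], ecg[:, 1], fs)
    ecg_clean = ecg_highpass(ecg_sel, fs, cfg.ecg_hp_hz, cfg.ecg_hp_order)

    data = np.column_stack([eeg, spr_clean, ecg_clean])
    drop = gross.copy()
    if len(obstacle_positions_m):
        drop |= obstacle_mask(trace, obstacle_positions_m, len(rec),
                              cfg.obstacle_span_m, cfg.obstacle_margin_m)
    data = data[~drop]
    return CleanedSession(subject_id=rec.subject_id, session=rec.session,
                          fs=fs, data=data, ecg_lead=lead)


# ---------------------------------------------------------------------------
# segment archive
# ---------------------------------------------------------------------------

def save_segments(segments: list[Segment], path) -> None:
    """Columnar archive: one (n, window, 8) array plus parallel label,
    subject and session vectors."""
    if not segments:
        raise ValueError("no segments to save")
    np.savez_compressed(
        path,
        data=np.stack([s.data for s in segments]),
        labels=np.array([s.label for s in segments], dtype=np.int64),
        subjects=np.array([s.subject_id for s in segments]),
        sessions=np.array([s.session.value for s in segments]),
    )


def load_segments(path) -> list[Segment]:
    with np.load(path, allow_pickle=False) as z:
        data, labels = z["data"], z["labels"]
        subjects, sessions = z["subjects"], z["sessions"]
    return [
        Segment(data=data[i], label=int(labels[i]),
                subject_id=str(subjects[i]),
                session=Session(str(sessions[i])))
        for i in range(len(labels))
    ]
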