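"""Synchronized-recording I/O, dropped-sample repair, and simulator alignment.

The acquisition GUI stores one CSV per driving session with the column order
``time, Fp1, Fp2, C3, C4, O1, O2, SPR1, SPR2, ECG1, ECG2`` at 200 Sa/s.
When a wireless sensor stalls, the GUI inserts literal zeros; those runs are
repaired here by linear interpolation.  A vehicle-dynamics trace (time,
longitudinal and lateral position) recorded by the driving simulator defines
the authoritative session duration, to which the biosignal recording is
truncated.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path

import numpy as np
import pandas as pd

SYNC_COLUMNS = (
    "time",
    "Fp1", "Fp2", "C3", "C4", "O1", "O2",
    "SPR1", "SPR2",
    "ECG1", "ECG2",
)
EEG_CHANNELS = ("Fp1", "Fp2", "C3", "C4", "O1", "O2")
SPR_CHANNELS = ("SPR1", "SPR2")
ECG_CHANNELS = ("ECG1", "ECG2")

TRACE_COLUMNS = ("time", "longitudinal_position", "lateral_position")


class Session(str, enum.Enum):
    """Driving-session identity; manual sessions elicit high engagement."""

    MANUAL1 = "Manual1"
    MANUAL2 = "Manual2"
    MANUAL3 = "Manual3"
    ADAS = "ADAS"

    @property
    def is_manual(self) -> bool:
        return self is not Session.ADAS


class FormatError(ValueError):
    """Input file does not follow the synchronized-recording dialect."""


class AlignmentError(ValueError):
    """Recording and simulator trace cannot be reconciled."""


class UnrecoverableChannelError(ValueError):
    """A channel contains no valid (nonzero) samples to interpolate from."""


@dataclasses.dataclass
class SyncRecording:
    """One subject-session of synchronized 10-channel biosignals.

    EEG in microvolts, SPR and ECG in millivolts as stored; values are
    preserved exactly as read — units are a convention of the writer.
    """

    subject_id: str
    session: Session
    fs: float
    time: np.ndarray        # (n,) seconds
    eeg: np.ndarray         # (n, 6) Fp1, Fp2, C3, C4, O1, O2
    spr: np.ndarray         # (n, 2) SPR1 (right hand), SPR2 (left hand)
    ecg: np.ndarray         # (n, 2) ECG1, ECG2

    def __post_init__(self) -> None:
        n = len(self.time)
        for name, arr, width in (
            ("eeg", self.eeg, 6), ("spr", self.spr, 2), ("ecg", self.ecg, 2)
        ):
            if arr.shape != (n, width):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected ({n}, {width})"
                )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def channels(self) -> np.ndarray:
        """All 10 signal channels as an (n, 10) array in canonical order."""
        return np.hstack([self.eeg, self.spr, self.ecg])

    def replace_channels(self, channels: np.ndarray,
                         time: np.ndarray | None = None) -> "SyncRecording":
        """New recording with the same identity but different samples."""
        if time is None:
            time = self.time
        return SyncRecording(
            subject_id=self.subject_id,
            session=self.session,
            fs=self.fs,
            time=time,
            eeg=channels[:, 0:6],
            spr=channels[:, 6:8],
            ecg=channels[:, 8:10],
        )


@dataclasses.dataclass
class SimTrace:
    """Vehicle-dynamics trace from the driving simulator at 200 Sa/s."""

    time: np.ndarray                   # (n,) seconds
    longitudinal_position: np.ndarray  # (n,) meters along track, non-decreasing
    lateral_position: np.ndarray       # (n,) meters

    def __len__(self) -> int:
        return len(self.time)


def _session_from_path(path: Path) -> tuple[str, Session]:
    """Best-effort subject/session identity from a ``<subject>_<session>.csv``
    filename; falls back to the stem and Manual1."""
    stem = path.stem
    for sess in Session:
        suffix = f"_{sess.value}"
        if stem.endswith(suffix):
            return stem[: -len(suffix)], sess
    return stem, Session.MANUAL1


def read_sync_csv(path: str | Path, subject_id: str | None = None,
                  session: Session | None = None) -> SyncRecording:
    """Read one synchronized-session CSV.

    The header must contain exactly the 11 canonical columns in canonical
    order; every cell must parse as a float.  No resampling or reordering is
    performed.  Sampling rate is inferred from the median time step.
    """
    path = Path(path)
    header = pd.read_csv(path, nrows=0)
    cols = tuple(header.columns)
    if cols != SYNC_COLUMNS:
        missing = [c for c in SYNC_COLUMNS if c not in cols]
        extra = [c for c in cols if c not in SYNC_COLUMNS]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        if extra:
            raise FormatError(f"{path}: unexpected column(s) {extra}")
        raise FormatError(
            f"{path}: columns out of canonical order: {list(cols)}"
        )
    try:
        # round_trip parser: shortest-repr floats reproduce bit-exactly
        df = pd.read_csv(path, dtype=np.float64,
                         float_precision="round_trip")
    except ValueError:
        # reparse leniently to locate the offending row for the error message
        raw = pd.read_csv(path, dtype=str)
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & raw.notna()
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raise FormatError(
            f"{path}: non-numeric value in column {col!r} at data row {row}"
        ) from None

    time = df["time"].to_numpy()
    if len(time) >= 2:
        fs = 1.0 / float(np.median(np.diff(time)))
    else:
        fs = 200.0
    if subject_id is None or session is None:
        sid, sess = _session_from_path(path)
        subject_id = subject_id if subject_id is not None else sid
        session = session if session is not None else sess
    return SyncRecording(
        subject_id=subject_id,
        session=session,
        fs=fs,
        time=time,
        eeg=df[list(EEG_CHANNELS)].to_numpy(),
        spr=df[list(SPR_CHANNELS)].to_numpy(),
        ecg=df[list(ECG_CHANNELS)].to_numpy(),
    )


def write_sync_csv(rec: SyncRecording, path: str | Path) -> None:
    """Write a recording in the canonical CSV dialect (lossless round-trip).

    Python's shortest-repr float formatting guarantees that
    ``read_sync_csv(write_sync_csv(rec))`` reproduces every finite sample
    bit-for-bit.
    """
    df = pd.DataFrame(
        np.column_stack([rec.time, rec.channels]), columns=list(SYNC_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_sim_csv(path: str | Path) -> SimTrace:
    """Read a simulator-trace CSV (time, longitudinal/lateral position)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = tuple(df.columns)
    if cols != TRACE_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {list(TRACE_COLUMNS)}, got {list(cols)}"
        )
    return SimTrace(
        time=df["time"].to_numpy(dtype=np.float64),
        longitudinal_position=df["longitudinal_position"].to_numpy(np.float64),
        lateral_position=df["lateral_position"].to_numpy(np.float64),
    )


def write_sim_csv(trace: SimTrace, path: str | Path) -> None:
    df = pd.DataFrame({
        "time": trace.time,
        "longitudinal_position": trace.longitudinal_position,
        "lateral_position": trace.lateral_position,
    })
    df.to_csv(path, index=False)


def _interpolate_channel(x: np.ndarray, min_run_length: int) -> np.ndarray:
    """Replace zero runs of length >= min_run_length by linear interpolation
    between the nearest nonzero neighbors (constant at the edges)."""
    zero = x == 0.0
    if not zero.any():
        return x
    if zero.all():
        raise UnrecoverableChannelError("channel is entirely zero")
    if min_run_length > 1:
        # keep short runs (isolated true zero crossings) untouched
        padded = np.concatenate([[False], zero, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[0::2], edges[1::2]
        keep = (ends - starts) < min_run_length
        for s, e in zip(starts[keep], ends[keep]):
            zero[s:e] = False
        if not zero.any():
            return x
    idx = np.arange(len(x))
    out = x.copy()
    # np.interp extends with the boundary values, giving constant
    # extrapolation for leading/trailing runs
    out[zero] = np.interp(idx[zero], idx[~zero], x[~zero])
    return out


def interpolate_zero_gaps(rec: SyncRecording,
                          min_run_length: int = 1) -> SyncRecording:
    """Repair dropped-sample runs the acquisition GUI stored as exact zeros.

    Interior runs are linearly interpolated between the nearest nonzero
    neighbors; leading/trailing runs take the nearest nonzero value.  Runs
    shorter than ``min_run_length`` are left untouched (set it above 1 to
    protect isolated true zero crossings).  Idempotent.
    """
    channels = rec.channels
    out = np.empty_like(channels)
    for j in range(channels.shape[1]):
        try:
            out[:, j] = _interpolate_channel(channels[:, j], min_run_length)
        except UnrecoverableChannelError as err:
            raise UnrecoverableChannelError(
                f"channel {SYNC_COLUMNS[j + 1]}: {err}"
            ) from None
    return rec.replace_channels(out)


def align_to_sim(rec: SyncRecording, trace: SimTrace,
                 tolerance_s: float = 1.0) -> SyncRecording:
    """Truncate a recording to the simulator trace's sample count.

    The simulator (computer) clock is the authoritative session duration;
    the recording, which starts at the same instant, is cut to match.  A
    recording shorter than the trace by more than ``tolerance_s`` indicates
    a synchronization fault and raises :class:`AlignmentError`.  Sample
    values are never modified; the time base is rebuilt from 0 at 1/fs.
    """
    n_rec, n_trace = len(rec), len(trace)
    if n_rec < n_trace - round(tolerance_s * rec.fs):
        raise AlignmentError(
            f"recording ({n_rec} samples) shorter than trace ({n_trace}) "
            f"by more than {tolerance_s} s at fs={rec.fs}"
        )
    n = min(n_rec, n_trace)
    time = np.arange(n) / rec.fs
    return rec.replace_channels(rec.channels[:n], time=time)
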