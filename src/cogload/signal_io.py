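"""Data model, device-export I/O, synchronisation, notch filtering and windowing.

Two wearables are modelled: a Muse-style headband (4-channel EEG at 256 Hz,
3-axis gyroscope at 50 Hz, PPG at 64 Hz) and an Empatica-style wristband
(skin temperature and EDA at 4 Hz, blood-volume pulse at 64 Hz, 3-axis
acceleration at 32 Hz).  All timestamps are UNIX seconds, UTC.

The wristband export dialect is one CSV per signal (TEMP/EDA/BVP/ACC): the
first row holds the start timestamp, the second the sampling rate, and every
following row one sample (three columns for ACC).  The headband dialect is a
single long-format CSV with columns ``timestamp,channel,value``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    InvalidArgumentError,
    LowConfidenceSyncError,
    MissingChannelError,
    ParseError,
)

logger = logging.getLogger(__name__)

#: Activities a protocol block may carry.  ``EyesClosed`` windows are
#: segmented like any other but excluded from classification.
ACTIVITIES = ("Relaxation", "Load", "Summary", "Reading", "Game", "EyesClosed")

#: Canonical channel names and their sampling rates (Hz).
CHANNEL_RATES = {
    "eeg_af7": 256.0,
    "eeg_af8": 256.0,
    "eeg_tp9": 256.0,
    "eeg_tp10": 256.0,
    "gyro_x": 50.0,
    "gyro_y": 50.0,
    "gyro_z": 50.0,
    "ppg_muse": 64.0,
    "ppg_e4": 64.0,
    "eda": 4.0,
    "temp": 4.0,
    "acc_x": 32.0,
    "acc_y": 32.0,
    "acc_z": 32.0,
}

MUSE_CHANNELS = (
    "eeg_af7", "eeg_af8", "eeg_tp9", "eeg_tp10",
    "gyro_x", "gyro_y", "gyro_z", "ppg_muse",
)
E4_CHANNELS = ("temp", "eda", "ppg_e4", "acc_x", "acc_y", "acc_z")
EEG_CHANNELS = ("eeg_af7", "eeg_af8", "eeg_tp9", "eeg_tp10")

# Muse long-format CSV uses device-style labels.
_MUSE_LABELS = {
    "AF7": "eeg_af7", "AF8": "eeg_af8", "TP9": "eeg_tp9", "TP10": "eeg_tp10",
    "GYRO_X": "gyro_x", "GYRO_Y": "gyro_y", "GYRO_Z": "gyro_z",
    "PPG": "ppg_muse",
}
_MUSE_LABELS_INV = {v: k for k, v in _MUSE_LABELS.items()}


@dataclass
class Channel:
    """A uniformly sampled signal.

    The timestamp of sample ``i`` is ``start_time + i / fs``.
    """

    name: str
    samples: np.ndarray
    fs: float
    start_time: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.fs

    def slice(self, t0: float, t1: float) -> np.ndarray:
        """Samples covering [t0, t1); raises if not fully covered."""
        i0 = int(round((t0 - self.start_time) * self.fs))
        n = int(round((t1 - t0) * self.fs))
        if i0 < 0 or i0 + n > len(self.samples):
            raise InvalidArgumentError(
                f"channel {self.name} does not cover [{t0}, {t1})"
            )
        return self.samples[i0:i0 + n]


@dataclass
class MultimodalRecording:
    """One participant-session across both virtual devices."""

    participant_id: str
    session_id: str
    environment: str  # "controlled" | "uncontrolled"
    channels: dict[str, Channel] = field(default_factory=dict)
    #: wristband clock minus headband clock, seconds (0 once synchronised)
    device_offset_s: float = 0.0

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise MissingChannelError(f"missing channels: {', '.join(missing)}")


@dataclass
class ProtocolBlock:
    activity: str
    start: float
    end: float
    environment: str
    workload_response: int
    stress_response: int

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise InvalidArgumentError(f"unknown activity {self.activity!r}")
        if not self.end > self.start:
            raise InvalidArgumentError("block end must exceed start")
        for r in (self.workload_response, self.stress_response):
            if not 1 <= int(r) <= 5:
                raise InvalidArgumentError(f"questionnaire response {r} not in 1..5")


@dataclass
class ProtocolLog:
    """Ordered, non-overlapping task blocks with questionnaire responses."""

    blocks: list[ProtocolBlock]

    def __post_init__(self) -> None:
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise InvalidArgumentError("protocol blocks overlap or are unordered")

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "activity": b.activity,
                "start": b.start,
                "end": b.end,
                "environment": b.environment,
                "workload_response": b.workload_response,
                "stress_response": b.stress_response,
            }
            for b in self.blocks
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProtocolLog":
        payload = json.loads(Path(path).read_text())
        return cls([ProtocolBlock(**b) for b in payload])


@dataclass
class WindowedSegment:
    """One 60 s multimodal slice with its aligned label and activity tag."""

    participant_id: str
    session_id: str
    window_index: int
    start_time: float
    activity: str
    workload_response: int
    stress_response: int
    channels: dict[str, np.ndarray]
    rates: dict[str, float]


# ---------------------------------------------------------------------------
# Wristband export dialect


_E4_FILES = {"TEMP.csv": "temp", "EDA.csv": "eda", "BVP.csv": "ppg_e4",
             "ACC.csv": ("acc_x", "acc_y", "acc_z")}
_E4_UNITS = {"temp": "degC", "eda": "uS", "ppg_e4": "a.u.",
             "acc_x": "g", "acc_y": "g", "acc_z": "g"}


def write_e4_export(recording: MultimodalRecording, directory: str | Path) -> None:
    """Write the wristband channels as per-signal CSVs (TEMP/EDA/BVP/ACC)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    recording.require(*E4_CHANNELS)
    for fname, names in _E4_FILES.items():
        if isinstance(names, str):
            ch = recording.channels[names]
            cols = ch.samples[:, None]
            header = [f"{ch.start_time:.6f}", f"{ch.fs:g}"]
        else:
            chans = [recording.channels[n] for n in names]
            cols = np.column_stack([c.samples for c in chans])
            header = [
                ", ".join(f"{c.start_time:.6f}" for c in chans),
                ", ".join(f"{c.fs:g}" for c in chans),
            ]
        with open(directory / fname, "w") as fh:
            fh.write("\n".join(header) + "\n")
            np.savetxt(fh, cols, fmt="%.10g", delimiter=", ")


def read_e4_export(directory: str | Path) -> dict[str, Channel]:
    """Read a wristband export directory into canonical channels."""
    directory = Path(directory)
    channels: dict[str, Channel] = {}
    for fname, names in _E4_FILES.items():
        path = directory / fname
        if not path.exists():
            raise MissingChannelError(f"missing export file {fname} in {directory}")
        with open(path) as fh:
            lines = fh.read().splitlines()
        try:
            starts = [float(x) for x in lines[0].split(",")]
            rates = [float(x) for x in lines[1].split(",")]
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}: malformed header (lines 1-2): {exc}") from exc
        name_list = [names] if isinstance(names, str) else list(names)
        if len(starts) == 1:
            starts *= len(name_list)
        if len(rates) == 1:
            rates *= len(name_list)
        data = []
        for lineno, line in enumerate(lines[2:], start=3):
            if not line.strip():
                continue
            try:
                row = [float(x) for x in line.split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if len(row) != len(name_list):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(name_list)} values, "
                    f"got {len(row)}"
                )
            data.append(row)
        arr = np.asarray(data, dtype=float).reshape(-1, len(name_list))
        for j, cname in enumerate(name_list):
            channels[cname] = Channel(
                cname, arr[:, j], rates[j], starts[j], _E4_UNITS[cname]
            )
    return channels


# ---------------------------------------------------------------------------
# Headband long-format dialect


def write_muse_csv(recording: MultimodalRecording, path: str | Path) -> None:
    """Write headband channels as a long-format ``timestamp,channel,value`` CSV."""
    recording.require(*MUSE_CHANNELS)
    frames = []
    for name in MUSE_CHANNELS:
        ch = recording.channels[name]
        frames.append(pd.DataFrame({
            # epoch seconds need microsecond precision; %.10g would truncate
            "timestamp": [f"{t:.6f}" for t in ch.times()],
            "channel": _MUSE_LABELS_INV[name],
            "value": ch.samples,
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_muse_csv(path: str | Path) -> dict[str, Channel]:
    """Read a headband long-format CSV; validates the EEG montage is complete."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns) != ["timestamp", "channel", "value"]:
        raise ParseError(
            f"{path}: expected columns timestamp,channel,value, got {list(df.columns)}"
        )
    unknown = set(df["channel"].unique()) - set(_MUSE_LABELS)
    if unknown:
        raise ParseError(f"{path}: unknown channel name(s): {sorted(unknown)}")
    channels: dict[str, Channel] = {}
    for label, grp in df.groupby("channel", sort=False):
        name = _MUSE_LABELS[label]
        t = grp["timestamp"].to_numpy()
        if len(t) < 2:
            raise ParseError(f"{path}: channel {label} has fewer than 2 samples")
        fs = round((len(t) - 1) / (t[-1] - t[0]), 3)
        units = "uV" if name.startswith("eeg") else ("deg/s" if name.startswith("gyro") else "a.u.")
        channels[name] = Channel(name, grp["value"].to_numpy(), fs, t[0], units)
    missing_eeg = [_MUSE_LABELS_INV[c] for c in EEG_CHANNELS if c not in channels]
    if missing_eeg:
        raise ParseError(f"{path}: missing EEG channel(s): {', '.join(missing_eeg)}")
    return channels


# ---------------------------------------------------------------------------
# Synchronisation


def _motion_envelope(ch: Channel, env_fs: float = 32.0) -> tuple[np.ndarray, np.ndarray]:
    """Rectified, smoothed motion energy resampled to ``env_fs``."""
    x = np.abs(ch.samples - np.mean(ch.samples))
    # ~0.25 s odd-length moving average: smooths the burst without the
    # half-sample phase bias an even window would add
    w = max(1, int(round(ch.fs * 0.25)) | 1)
    x = np.convolve(x, np.ones(w) / w, mode="same")
    t = ch.times()
    tg = np.arange(t[0], t[-1], 1.0 / env_fs)
    return tg, np.interp(tg, t, x)


def motion_magnitude(recording: MultimodalRecording, prefix: str) -> Channel:
    """Euclidean magnitude of a 3-axis motion channel group (``gyro``/``acc``)."""
    names = [f"{prefix}_{ax}" for ax in "xyz"]
    recording.require(*names)
    chans = [recording.channels[n] for n in names]
    mag = np.sqrt(sum(c.samples ** 2 for c in chans))
    c0 = chans[0]
    return Channel(f"{prefix}_mag", mag, c0.fs, c0.start_time, c0.units)


def estimate_sync_offset(
    motion_a: Channel,
    motion_b: Channel,
    max_lag_s: float = 30.0,
    min_correlation: float = 0.5,
    env_fs: float = 32.0,
) -> float:
    """Clock offset of ``motion_b`` relative to ``motion_a`` from a shared burst.

    Both signals are reduced to motion-energy envelopes on a common 32 Hz
    grid (per their own claimed timestamps) and cross-correlated; the lag of
    the normalised-correlation peak, refined by parabolic interpolation, is
    returned.  Subtracting the returned offset from ``motion_b``'s clock
    aligns the bursts.

    Raises :class:`LowConfidenceSyncError` if the peak normalised correlation
    falls below ``min_correlation``.
    """
    if motion_a.duration < 10 or motion_b.duration < 10:
        raise InvalidArgumentError("need >= 10 s of motion data on both devices")
    ta, ea = _motion_envelope(motion_a, env_fs)
    tb, eb = _motion_envelope(motion_b, env_fs)
    ea = (ea - ea.mean()) / (ea.std() or 1.0)
    eb = (eb - eb.mean()) / (eb.std() or 1.0)
    # place both envelopes on one absolute grid so claimed clocks matter
    t0 = min(ta[0], tb[0])
    t1 = max(ta[-1], tb[-1])
    grid = np.arange(t0, t1, 1.0 / env_fs)
    ga = np.interp(grid, ta, ea, left=0.0, right=0.0)
    gb = np.interp(grid, tb, eb, left=0.0, right=0.0)
    corr = sps.correlate(gb, ga, mode="full")
    lags = sps.correlation_lags(len(gb), len(ga), mode="full")
    max_lag = int(round(max_lag_s * env_fs))
    keep = np.abs(lags) <= max_lag
    corr, lags = corr[keep], lags[keep]
    norm = np.sqrt(np.sum(ga ** 2) * np.sum(gb ** 2)) or 1.0
    corr = corr / norm
    k = int(np.argmax(corr))
    if corr[k] < min_correlation:
        raise LowConfidenceSyncError(
            f"peak normalised correlation {corr[k]:.3f} < {min_correlation}; "
            "refusing to guess an offset"
        )
    # parabolic refinement around the integer-lag peak
    frac = 0.0
    if 0 < k < len(corr) - 1:
        y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            frac = 0.5 * (y0 - y2) / denom
    return float((lags[k] + frac) / env_fs)


def apply_device_offset(recording: MultimodalRecording, offset_s: float) -> MultimodalRecording:
    """Shift the wristband channels' clocks by ``-offset_s`` (align to headband)."""
    channels = dict(recording.channels)
    for name in E4_CHANNELS:
        if name in channels:
            ch = channels[name]
            channels[name] = replace(ch, start_time=ch.start_time - offset_s)
    return replace(recording, channels=channels,
                   device_offset_s=recording.device_offset_s - offset_s)


def synchronise(recording: MultimodalRecording) -> tuple[MultimodalRecording, float]:
    """Estimate the inter-device offset from the shake burst and apply it."""
    gyro = motion_magnitude(recording, "gyro")
    acc = motion_magnitude(recording, "acc")
    offset = estimate_sync_offset(gyro, acc)
    return apply_device_offset(recording, offset), offset


# ---------------------------------------------------------------------------
# Notch filtering


def notch_filter(channel: Channel, f0: float = 50.0, q: float = 30.0) -> Channel:
    """Zero-phase IIR notch at ``f0``; channels with fs <= 2*f0 pass unchanged.

    Low-rate channels (EDA, temperature at 4 Hz) cannot contain power-line
    interference above Nyquist, so they are returned untouched with a logged
    notice rather than an error.
    """
    if channel.fs <= 2 * f0:
        logger.info(
            "notch skipped for %s: fs=%g Hz <= 2*%g Hz", channel.name, channel.fs, f0
        )
        return channel
    b, a = sps.iirnotch(f0, q, fs=channel.fs)
    filtered = sps.filtfilt(b, a, channel.samples)
    return replace(channel, samples=filtered)


def notch_recording(recording: MultimodalRecording, f0: float = 50.0,
                    q: float = 30.0) -> MultimodalRecording:
    """Notch-filter every channel whose rate permits it (EEG and PPG)."""
    channels = {n: notch_filter(c, f0, q) for n, c in recording.channels.items()}
    return replace(recording, channels=channels)


# ---------------------------------------------------------------------------
# Windowing


def segment_windows(
    recording: MultimodalRecording,
    log: ProtocolLog,
    window_s: float = 60.0,
) -> list[WindowedSegment]:
    """Cut non-overlapping ``window_s`` windows inside each protocol block.

    Windows never straddle block boundaries; a trailing remainder shorter
    than ``window_s`` is dropped.  Each window inherits its block's activity
    and questionnaire responses.  The recording must already be synchronised.
    """
    segments: list[WindowedSegment] = []
    names = list(recording.channels)
    if not names:
        return segments
    # half-sample tolerance: a recovered sync offset leaves sub-sample
    # residuals that Channel.slice's index rounding absorbs
    cover_start = max(c.start_time - 0.5 / c.fs
                      for c in recording.channels.values())
    cover_end = min(c.end_time + 0.5 / c.fs
                    for c in recording.channels.values())
    idx = 0
    emitted_any = False
    for block in log.blocks:
        t = max(block.start, cover_start)
        # snap the first window to the block start when fully covered
        while t + window_s <= min(block.end, cover_end) + 1e-9:
            sliced = {
                n: recording.channels[n].slice(t, t + window_s) for n in names
            }
            segments.append(WindowedSegment(
                participant_id=recording.participant_id,
                session_id=recording.session_id,
                window_index=idx,
                start_time=t,
                activity=block.activity,
                workload_response=block.workload_response,
                stress_response=block.stress_response,
                channels=sliced,
                rates={n: recording.channels[n].fs for n in names},
            ))
            idx += 1
            emitted_any = True
            t += window_s
    if not emitted_any:
        logger.warning(
            "no complete %gs window overlaps the protocol log for %s/%s",
            window_s, recording.participant_id, recording.session_id,
        )
    return segments
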