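"""Synthetic multimodal wearable sessions with a latent cognitive-load state.

The generator emulates the study conditions the analysis assumes: a
headband records 4-channel EEG (AF7, AF8, TP9, TP10) at 256 Hz, a 3-axis
gyroscope at 50 Hz and PPG at 64 Hz; a wristband records skin temperature
and EDA at 4 Hz, blood-volume pulse at 64 Hz and 3-axis acceleration at
32 Hz.  A session is an ordered list of task blocks (relaxation, reading,
summarising, a game, load tasks, eyes-closed baselines), each carrying a
latent load level in [0, 1].  Under a positive effect size the latent load
shifts physiology monotonically: higher β and prefrontal θ EEG power,
higher heart rate, lower inter-beat variability, more skin-conductance
responses, slightly cooler skin.  Questionnaire responses are an ordinal
rounding of the latent load with Gaussian noise on the 5-point scale.

EEG band components are FIR-bandpass-filtered white noise per band, scaled
so the expected band power is proportional to the squared amplitude.  The
PPG is a train of Gaussian systolic pulses whose beat times follow the
instantaneous heart rate with Gaussian inter-beat jitter.  Skin conductance
responses are bi-exponential pulses (rise ~1 s, decay ~4 s) on a tonic
level.  Both devices carry a co-registered 3 s shake burst at session start
so the synchronisation stage has a planted ground truth; the wristband
clock is offset by a configurable amount.

A single master seed spawns independent per-modality child streams, so the
whole dataset is reproducible while modalities stay statistically
independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InvalidArgumentError
from .signal_io import (
    ACTIVITIES,
    Channel,
    MultimodalRecording,
    ProtocolBlock,
    ProtocolLog,
    write_e4_export,
    write_muse_csv,
)

#: Canonical EEG bands, Hz.
EEG_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass
class LoadProfile:
    """Ordered task blocks with latent load, plus effect/noise magnitudes.

    ``effect_size`` scales how strongly the latent load shifts physiology;
    0 yields physiology statistically independent of the load.
    ``label_noise_sd`` is Gaussian noise on the 5-point questionnaire scale.
    """

    blocks: list[tuple[str, float, float]]  # (activity, duration_s, latent_load)
    effect_size: float = 1.0
    label_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.effect_size < 0 or self.label_noise_sd < 0:
            raise InvalidArgumentError("effect_size and label_noise_sd must be >= 0")
        for activity, duration, load in self.blocks:
            if activity not in ACTIVITIES:
                raise InvalidArgumentError(f"unknown activity {activity!r}")
            if duration <= 0:
                raise InvalidArgumentError("block durations must be positive")
            if not 0.0 <= load <= 1.0:
                raise InvalidArgumentError("latent_load must lie in [0, 1]")

    @property
    def duration_s(self) -> float:
        return sum(d for _, d, _ in self.blocks)


def default_profile(effect_size: float = 1.0, label_noise_sd: float = 0.5) -> LoadProfile:
    """The default session protocol: baselines, relaxation/game (low load),
    load task, reading and summarising (high load); ~44 minutes."""
    return LoadProfile(
        blocks=[
            ("EyesClosed", 60.0, 0.0),
            ("Relaxation", 600.0, 0.0),
            ("Game", 360.0, 0.1),
            ("Load", 480.0, 1.0),
            ("Reading", 600.0, 0.75),
            ("Summary", 480.0, 0.9),
            ("EyesClosed", 60.0, 0.0),
        ],
        effect_size=effect_size,
        label_noise_sd=label_noise_sd,
    )


@dataclass
class GeneratorConfig:
    """Sampling rates, device clock offset and physiological baselines."""

    fs_eeg: float = 256.0
    fs_ppg: float = 64.0
    fs_eda: float = 4.0
    fs_temp: float = 4.0
    fs_acc: float = 32.0
    fs_gyro: float = 50.0
    line_noise_amplitude: float = 5.0       # uV on EEG, a.u. on PPG
    inter_device_offset_s: float = 2.5      # wristband clock minus headband clock
    hr_baseline_bpm: float = 65.0
    hrv_sd_baseline_ms: float = 45.0
    scl_baseline_us: float = 2.0
    temp_baseline_c: float = 33.0
    #: per-band EEG component amplitudes (uV RMS)
    band_amplitudes: dict[str, float] = field(default_factory=lambda: {
        "delta": 20.0, "theta": 10.0, "alpha": 15.0, "beta": 8.0, "gamma": 4.0,
    })
    eeg_noise_sd: float = 2.0
    shake_duration_s: float = 3.0
    shake_amplitude: float = 8.0

    # load -> physiology slopes (per unit effect_size x latent_load)
    hr_slope_bpm: float = 15.0
    hrv_slope_ms: float = 15.0
    eeg_gain: float = 0.6        # relative beta / prefrontal-theta gain
    scr_rate_slope_per_min: float = 4.0
    temp_slope_c: float = -0.4


# ---------------------------------------------------------------------------
# Modality synthesisers


def _bandpass_noise(rng: np.random.Generator, n: int, fs: float,
                    lo: float, hi: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise via FIR bandpass."""
    taps = sps.firwin(513, [lo, hi], pass_zero=False, fs=fs)
    x = sps.lfilter(taps, 1.0, rng.standard_normal(n + 1024))[1024:]
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_eeg(
    band_amplitudes: dict[str, float],
    duration_s: float,
    fs: float,
    seed: int | np.random.SeedSequence,
    noise_sd: float = 0.0,
    channel_gain: np.ndarray | None = None,
) -> np.ndarray:
    """Four EEG channels as sums of band-limited noise components.

    Each channel's expected power in band *b* is proportional to
    ``band_amplitudes[b] ** 2`` (components are normalised to unit variance
    and scaled).  ``channel_gain`` optionally maps (4, n_bands) per-channel
    per-band multipliers, e.g. to plant a hemispheric asymmetry; rows are
    ordered AF7, AF8, TP9, TP10.
    """
    if duration_s <= 0 or fs <= 0:
        raise InvalidArgumentError("duration_s and fs must be positive")
    if fs < 2 * 45.0:
        raise InvalidArgumentError("fs must be at least twice the top band edge (45 Hz)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    bands = list(EEG_BANDS)
    if channel_gain is None:
        channel_gain = np.ones((4, len(bands)))
    out = np.zeros((4, n))
    for j, band in enumerate(bands):
        amp = float(band_amplitudes.get(band, 0.0))
        lo, hi = EEG_BANDS[band]
        for ch in range(4):
            a = amp * channel_gain[ch, j]
            if a == 0.0:
                continue
            out[ch] += a * _bandpass_noise(rng, n, fs, lo, hi)
    if noise_sd > 0:
        out += noise_sd * rng.standard_normal((4, n))
    return out


def synthesize_ppg(
    hr_profile: float | np.ndarray,
    hrv_sd_ms: float,
    duration_s: float,
    fs: float,
    seed: int | np.random.SeedSequence,
    noise_sd: float = 0.01,
    pulse_width_s: float = 0.06,
) -> tuple[np.ndarray, np.ndarray]:
    """A pulse waveform following an instantaneous heart-rate course.

    ``hr_profile`` is a scalar bpm or an array sampled at ``fs`` covering the
    whole duration.  Successive inter-beat intervals get independent Gaussian
    jitter of SD ``hrv_sd_ms``.  Returns ``(samples, beat_times)`` — the
    planted systolic peak times are ground truth for beat-detection tests.
    """
    if duration_s <= 0 or fs <= 0:
        raise InvalidArgumentError("duration_s and fs must be positive")
    hr = np.atleast_1d(np.asarray(hr_profile, dtype=float))
    if np.any(hr < 30) or np.any(hr > 220):
        raise InvalidArgumentError("heart rate must lie within [30, 220] bpm")
    n = int(round(duration_s * fs))
    if hr.size == 1:
        hr = np.full(n, hr[0])
    elif hr.size != n:
        raise InvalidArgumentError("hr_profile must be scalar or length duration*fs")
    rng = np.random.default_rng(seed)
    beat_times = []
    t = 0.5  # first systole half a second in
    while t < duration_s:
        beat_times.append(t)
        ibi = 60.0 / hr[min(int(t * fs), n - 1)]
        if hrv_sd_ms > 0:
            ibi = max(60.0 / 220.0, ibi + rng.normal(0.0, hrv_sd_ms / 1000.0))
        t += ibi
    beat_times = np.asarray(beat_times)
    times = np.arange(n) / fs
    x = np.zeros(n)
    half = int(round(4 * pulse_width_s * fs))
    for bt in beat_times:
        c = int(round(bt * fs))
        i0, i1 = max(0, c - half), min(n, c + half + 1)
        x[i0:i1] += np.exp(-0.5 * ((times[i0:i1] - bt) / pulse_width_s) ** 2)
    if noise_sd > 0:
        x += noise_sd * rng.standard_normal(n)
    return x, beat_times


def scr_template(duration_s: float, fs: float,
                 tau_rise: float = 1.0, tau_decay: float = 4.0) -> np.ndarray:
    """Bi-exponential skin-conductance-response pulse, peak-normalised to 1."""
    t = np.arange(int(round(duration_s * fs))) / fs
    h = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    peak = h.max()
    return h / peak if peak > 0 else h


def synthesize_eda(
    tonic_level_us: float,
    scr_event_times: list[float] | np.ndarray,
    scr_amplitude_us: float,
    duration_s: float,
    fs: float,
    seed: int | np.random.SeedSequence,
    drift_slope_us_per_s: float = 0.0,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Tonic drift plus one bi-exponential SCR per event time."""
    if duration_s <= 0 or fs <= 0:
        raise InvalidArgumentError("duration_s and fs must be positive")
    if tonic_level_us < 0:
        raise InvalidArgumentError("tonic level must be >= 0")
    events = np.asarray(scr_event_times, dtype=float)
    if events.size and (events.min() < 0 or events.max() >= duration_s):
        raise InvalidArgumentError("SCR event times must lie within [0, duration)")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = tonic_level_us + drift_slope_us_per_s * t
    if scr_amplitude_us != 0.0:
        tmpl = scr_amplitude_us * scr_template(20.0, fs)
        for et in events:
            i0 = int(round(et * fs))
            i1 = min(n, i0 + len(tmpl))
            x[i0:i1] += tmpl[: i1 - i0]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + noise_sd * rng.standard_normal(n)
    return x


def inject_line_noise(
    samples: np.ndarray,
    fs: float,
    amplitude: float,
    f0_hz: float = 50.0,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Add a power-line sinusoid ``amplitude * sin(2*pi*f0*t + phase)``.

    The phase is drawn from the seed, so repeated calls are reproducible.
    """
    if fs <= 2 * f0_hz:
        raise InvalidArgumentError(
            f"fs={fs} Hz cannot carry a {f0_hz} Hz interference component"
        )
    if amplitude == 0.0:
        return np.asarray(samples, dtype=float)
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(len(samples)) / fs
    return np.asarray(samples, dtype=float) + amplitude * np.sin(
        2.0 * np.pi * f0_hz * t + phase
    )


# ---------------------------------------------------------------------------
# Sessions and populations


def _questionnaire_response(load: float, noise_sd: float,
                            rng: np.random.Generator) -> int:
    raw = 1.0 + 4.0 * load + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
    return int(np.clip(round(raw), 1, 5))


def generate_session(
    config: GeneratorConfig,
    profile: LoadProfile,
    participant_id: str,
    seed: int | np.random.SeedSequence,
    session_id: str = "s1",
    environment: str = "controlled",
    start_time: float = 1_700_000_000.0,
) -> tuple[MultimodalRecording, ProtocolLog]:
    """Generate one participant-session across both virtual devices.

    Latent load modulates physiology proportionally to
    ``profile.effect_size``; with effect size 0 every modality is
    statistically independent of the load.  Both devices record a 3 s shake
    burst at the true session start; the wristband channel clocks are then
    shifted by ``config.inter_device_offset_s`` to emulate unsynchronised
    device clocks.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    (eeg_ss, ppg_ss, eda_ss, temp_ss, motion_ss,
     label_ss, line_ss) = ss.spawn(7)
    label_rng = np.random.default_rng(label_ss)
    e = profile.effect_size

    # --- per-block physiology, concatenated
    eeg_parts, ppg_parts = [], []
    eda_events: list[float] = []
    temp_parts = []
    blocks: list[ProtocolBlock] = []
    t_block = 0.0
    eeg_children = eeg_ss.spawn(len(profile.blocks))
    ppg_children = ppg_ss.spawn(len(profile.blocks))
    eda_rng = np.random.default_rng(eda_ss)
    temp_rng = np.random.default_rng(temp_ss)
    for i, (activity, duration, load) in enumerate(profile.blocks):
        gain = np.ones((4, len(EEG_BANDS)))
        band_idx = {b: j for j, b in enumerate(EEG_BANDS)}
        gain[:, band_idx["beta"]] *= 1.0 + config.eeg_gain * e * load
        gain[:2, band_idx["theta"]] *= 1.0 + config.eeg_gain * e * load  # prefrontal
        eeg_parts.append(synthesize_eeg(
            config.band_amplitudes, duration, config.fs_eeg, eeg_children[i],
            noise_sd=config.eeg_noise_sd, channel_gain=gain,
        ))
        hr = min(200.0, config.hr_baseline_bpm + config.hr_slope_bpm * e * load)
        hrv_sd = max(5.0, config.hrv_sd_baseline_ms - config.hrv_slope_ms * e * load)
        ppg_x, _ = synthesize_ppg(hr, hrv_sd, duration, config.fs_ppg, ppg_children[i])
        ppg_parts.append(ppg_x)
        rate_per_min = 1.0 + config.scr_rate_slope_per_min * e * load
        n_events = eda_rng.poisson(rate_per_min * duration / 60.0)
        offs = np.sort(eda_rng.uniform(2.0, max(2.5, duration - 10.0), n_events))
        eda_events.extend(t_block + offs)
        n_temp = int(round(duration * config.fs_temp))
        temp_parts.append(
            config.temp_baseline_c + config.temp_slope_c * e * load
            + 0.02 * temp_rng.standard_normal(n_temp)
        )
        blocks.append(ProtocolBlock(
            activity=activity,
            start=start_time + t_block,
            end=start_time + t_block + duration,
            environment=environment,
            workload_response=_questionnaire_response(
                load, profile.label_noise_sd, label_rng),
            stress_response=_questionnaire_response(
                load, profile.label_noise_sd, label_rng),
        ))
        t_block += duration

    duration_s = profile.duration_s
    eeg = np.concatenate(eeg_parts, axis=1)
    ppg_muse = np.concatenate(ppg_parts)
    # no session-long tonic drift: blocks keep a fixed order, so any monotone
    # drift lets elapsed time impersonate the load signal after z-scoring
    eda = synthesize_eda(
        config.scl_baseline_us, eda_events, 0.3, duration_s, config.fs_eda,
        eda_ss.spawn(1)[0], drift_slope_us_per_s=0.0, noise_sd=0.003,
    )
    temp = np.concatenate(temp_parts)
    # wristband PPG shares the headband's beat physiology but its own stream
    ppg_e4_parts = []
    e4_children = ppg_ss.spawn(len(profile.blocks) + 1)[1:]
    for i, (activity, duration, load) in enumerate(profile.blocks):
        hr = min(200.0, config.hr_baseline_bpm + config.hr_slope_bpm * e * load)
        hrv_sd = max(5.0, config.hrv_sd_baseline_ms - config.hrv_slope_ms * e * load)
        x, _ = synthesize_ppg(hr, hrv_sd, duration, config.fs_ppg, e4_children[i])
        ppg_e4_parts.append(x)
    ppg_e4 = np.concatenate(ppg_e4_parts)

    # --- motion with a co-registered shake burst at the true session start
    motion_rng = np.random.default_rng(motion_ss)
    shake_env_fs = 128.0
    n_env = int(round(duration_s * shake_env_fs))
    shake = np.zeros(n_env)
    ns = int(round(config.shake_duration_s * shake_env_fs))
    # real shaking is a few Hz: band-limit so both devices (50/32 Hz motion
    # rates) sample the same waveform without aliasing differences
    taps = sps.firwin(129, [2.0, 8.0], pass_zero=False, fs=shake_env_fs)
    burst_src = motion_rng.standard_normal(ns + 256)
    shake[:ns] = config.shake_amplitude * sps.lfilter(taps, 1.0, burst_src)[256:]
    env_t = np.arange(n_env) / shake_env_fs

    def motion_triplet(prefix: str, fs: float) -> dict[str, np.ndarray]:
        n = int(round(duration_s * fs))
        t = np.arange(n) / fs
        burst = np.interp(t, env_t, shake)
        return {
            f"{prefix}_{ax}": 0.05 * motion_rng.standard_normal(n) + burst / 3.0
            for ax in "xyz"
        }

    gyro = motion_triplet("gyro", config.fs_gyro)
    acc = motion_triplet("acc", config.fs_acc)

    # --- power-line interference; only the 256 Hz EEG can carry 50 Hz
    line_rng = np.random.default_rng(line_ss)
    if config.line_noise_amplitude > 0:
        for ch in range(4):
            eeg[ch] = inject_line_noise(
                eeg[ch], config.fs_eeg, config.line_noise_amplitude,
                seed=line_rng.integers(2 ** 31),
            )

    off = config.inter_device_offset_s
    channels = {
        "eeg_af7": Channel("eeg_af7", eeg[0], config.fs_eeg, start_time, "uV"),
        "eeg_af8": Channel("eeg_af8", eeg[1], config.fs_eeg, start_time, "uV"),
        "eeg_tp9": Channel("eeg_tp9", eeg[2], config.fs_eeg, start_time, "uV"),
        "eeg_tp10": Channel("eeg_tp10", eeg[3], config.fs_eeg, start_time, "uV"),
        "ppg_muse": Channel("ppg_muse", ppg_muse, config.fs_ppg, start_time, "a.u."),
        "ppg_e4": Channel("ppg_e4", ppg_e4, config.fs_ppg, start_time + off, "a.u."),
        "eda": Channel("eda", eda, config.fs_eda, start_time + off, "uS"),
        "temp": Channel("temp", temp, config.fs_temp, start_time + off, "degC"),
    }
    for name, x in gyro.items():
        channels[name] = Channel(name, x, config.fs_gyro, start_time, "deg/s")
    for name, x in acc.items():
        channels[name] = Channel(name, x, config.fs_acc, start_time + off, "g")

    recording = MultimodalRecording(
        participant_id=participant_id,
        session_id=session_id,
        environment=environment,
        channels=channels,
        device_offset_s=off,
    )
    return recording, ProtocolLog(blocks)


def generate_population(
    config: GeneratorConfig,
    profile: LoadProfile,
    out_dir,
    n_participants: int = 10,
    sessions_per_participant: int = 1,
    seed: int = 0,
) -> list:
    """Write one export directory per participant-session; returns the paths.

    Each directory contains the wristband per-signal CSVs, the headband
    long-format CSV and a ``protocol.json``.  Deterministic under ``seed``.
    """
    from pathlib import Path

    if n_participants < 2:
        raise InvalidArgumentError(
            "need at least 2 participants (leave-one-participant-out requires it)"
        )
    out_dir = Path(out_dir)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants * sessions_per_participant)
    paths = []
    k = 0
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        for s in range(sessions_per_participant):
            sid = f"s{s + 1}"
            rec, log = generate_session(
                config, profile, pid, children[k], session_id=sid,
                environment="controlled" if s % 2 == 0 else "uncontrolled",
            )
            k += 1
            d = out_dir / f"{pid}_{sid}"
            d.mkdir(parents=True, exist_ok=True)
            write_e4_export(rec, d)
            write_muse_csv(rec, d / "muse.csv")
            log.to_json(d / "protocol.json")
            paths.append(d)
    return paths


def simulate_sessions(
    config: GeneratorConfig,
    profile: LoadProfile,
    n_participants: int = 10,
    sessions_per_participant: int = 1,
    seed: int = 0,
):
    """In-memory variant of :func:`generate_population`; yields (recording, log)."""
    if n_participants < 2:
        raise InvalidArgumentError("need at least 2 participants")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants * sessions_per_participant)
    k = 0
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        for s in range(sessions_per_participant):
            yield generate_session(
                config, profile, pid, children[k], session_id=f"s{s + 1}",
                environment="controlled" if s % 2 == 0 else "uncontrolled",
            )
            k += 1
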