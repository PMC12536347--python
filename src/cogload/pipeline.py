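"""End-to-end glue: sessions → synchronised, filtered, windowed feature tables.

A FeatureTable is a pandas DataFrame with the metadata columns
``participant, session, window_index, activity, workload_response,
stress_response`` followed by the 754 named features (736 EEG + 18
wristband).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .eeg_features import extract_eeg_features
from .peripheral_features import extract_e4_features
from .signal_io import (
    MultimodalRecording,
    ProtocolLog,
    WindowedSegment,
    notch_recording,
    read_e4_export,
    read_muse_csv,
    segment_windows,
    synchronise,
)


def session_to_windows(
    recording: MultimodalRecording,
    log: ProtocolLog,
    window_s: float = 60.0,
    sync: bool = True,
    notch: bool = True,
) -> list[WindowedSegment]:
    """Synchronise, notch-filter and window one session."""
    if sync:
        recording, _ = synchronise(recording)
    if notch:
        recording = notch_recording(recording)
    return segment_windows(recording, log, window_s=window_s)


def extract_features(windows: list[WindowedSegment]) -> pd.DataFrame:
    """One row of 754 named features (plus metadata) per window."""
    rows = []
    for w in windows:
        row = {
            "participant": w.participant_id,
            "session": w.session_id,
            "window_index": w.window_index,
            "activity": w.activity,
            "workload_response": w.workload_response,
            "stress_response": w.stress_response,
        }
        row.update(extract_eeg_features(w))
        row.update(extract_e4_features(w))
        rows.append(row)
    return pd.DataFrame(rows)


def load_session(directory: str | Path) -> tuple[MultimodalRecording, ProtocolLog]:
    """Read one on-disk session (wristband CSVs + headband CSV + protocol.json)."""
    directory = Path(directory)
    channels = read_e4_export(directory)
    channels.update(read_muse_csv(directory / "muse.csv"))
    pid, _, sid = directory.name.partition("_")
    log = ProtocolLog.from_json(directory / "protocol.json")
    environment = log.blocks[0].environment if log.blocks else "controlled"
    rec = MultimodalRecording(
        participant_id=pid, session_id=sid or "s1",
        environment=environment, channels=channels,
    )
    return rec, log


def build_feature_table(
    sessions,
    window_s: float = 60.0,
    sync: bool = True,
    notch: bool = True,
) -> pd.DataFrame:
    """Feature table over many sessions.

    ``sessions`` is an iterable of ``(recording, log)`` pairs or of session
    directories.
    """
    frames = []
    for item in sessions:
        if isinstance(item, (str, Path)):
            rec, log = load_session(item)
        else:
            rec, log = item
        windows = session_to_windows(rec, log, window_s=window_s,
                                     sync=sync, notch=notch)
        if windows:
            frames.append(extract_features(windows))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def validate_real_data(dataset_dir: str | Path, families=("logistic",),
                       seed: int = 0) -> "pd.DataFrame":
    """Optional validation path for a real recorded dataset.

    Expects a directory of ``<participant>_<session>`` subdirectories in the
    export layout this package writes.  Builds the feature table and runs
    the generalised (leave-one-participant-out) evaluation of the reduced
    Both-Modalities set for the 2/3/5-class problems, returning the summary
    frame.  This is a convenience for anyone holding the original study
    recordings; nothing in the package's test surface depends on it.
    """
    from .classification import expand_grid, loo_cv, write_report
    from .labels import ClassificationProblem, reduced_feature_set

    dataset_dir = Path(dataset_dir)
    session_dirs = sorted(p for p in dataset_dir.iterdir() if p.is_dir())
    if not session_dirs:
        raise FileNotFoundError(f"no session directories under {dataset_dir}")
    table = build_feature_table(session_dirs)
    spec = reduced_feature_set("BothModalities")
    grid = {f: expand_grid(f) for f in families}
    reports = [
        loo_cv(table, grid, ClassificationProblem(k), spec, seed=seed)
        for k in (2, 3, 5)
    ]
    return write_report(reports, dataset_dir / "validation_summary")


def simulate_feature_table(
    config=None,
    profile=None,
    n_participants: int = 10,
    sessions_per_participant: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a synthetic population in memory and extract its feature table."""
    from .synthetic import GeneratorConfig, default_profile, simulate_sessions

    config = config or GeneratorConfig()
    profile = profile or default_profile()
    return build_feature_table(
        simulate_sessions(config, profile, n_participants,
                          sessions_per_participant, seed)
    )
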