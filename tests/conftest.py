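import numpy as np
import pytest
from hypothesis import settings

from cogload.synthetic import GeneratorConfig, LoadProfile, generate_session
from cogload.pipeline import session_to_windows

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def tiny_profile() -> LoadProfile:
    """Two-minute session: one low-load and one high-load block."""
    return LoadProfile(
        blocks=[("Relaxation", 60.0, 0.0), ("Load", 60.0, 1.0)],
        effect_size=1.0,
        label_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def tiny_session(gen_config, tiny_profile):
    return generate_session(gen_config, tiny_profile, "P01", seed=42)


@pytest.fixture(scope="session")
def one_window(gen_config, tiny_profile):
    """A single fully processed 60 s window (synchronised + notch-filtered)."""
    rec, log = generate_session(gen_config, tiny_profile, "P01", seed=7)
    windows = session_to_windows(rec, log)
    assert windows, "fixture session produced no windows"
    return windows[0]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_feature_table(
    n_participants: int = 4,
    windows_per_participant: int = 24,
    n_features: int = 6,
    separation: float = 0.0,
    seed: int = 0,
    feature_names: list[str] | None = None,
):
    """Small synthetic feature table for classifier-level tests.

    Half of each participant's windows are low load (response 1), half high
    (response 5); the first feature is shifted by ``separation`` for high
    windows, the rest are pure noise.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(n_features)]
    rows = []
    activities = ["Relaxation", "Load", "Summary", "Reading", "Game"]
    for p in range(n_participants):
        for w in range(windows_per_participant):
            high = w >= windows_per_participant // 2
            feats = rng.standard_normal(len(feature_names))
            if high:
                feats[0] += separation
            row = {
                "participant": f"P{p:02d}",
                "session": "s1",
                "window_index": w,
                "activity": activities[int(rng.integers(len(activities)))],
                "workload_response": 5 if high else 1,
                "stress_response": 5 if high else 1,
            }
            row.update(dict(zip(feature_names, feats)))
            rows.append(row)
    return pd.DataFrame(rows)
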