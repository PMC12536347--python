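"""EEG projections, FFT band powers, workload indices and the DWT feature bank.

Per 60 s window the module produces 736 named EEG features:

* 720 wavelet statistics — 5 source signals (AF7, AF8, TP9, TP10 and the
  all-channel mean) × 2 mother wavelets (db2, haar) × 9 coefficient arrays
  of an 8-level decomposition (cA8, cD8 … cD1) × 8 statistics (STD, MEAN,
  MIN, MAX, Skewness, RelativeWaveletEnergy, Kurtosis, ZeroCrossing);
* 10 band powers — the prefrontal and temporal projections in the canonical
  δ/θ/α/β/γ bands;
* 6 workload indices — Engagement Index, Brain Beat, Cognitive Load Index
  and three hemispheric α-asymmetry indices.

Index formulas live in a registry so alternative literature definitions can
be swapped in; the shipped defaults are EI = β/(α+θ) on the mean
projection, BB = θ/α on the mean projection, and CLI = prefrontal θ /
temporal α.  Asymmetry indices are right-minus-left log α power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .errors import InvalidArgumentError
from .signal_io import EEG_CHANNELS, WindowedSegment
from .synthetic import EEG_BANDS

BANDS = EEG_BANDS  # δ/θ/α/β/γ edges in Hz

WAVELETS = ("db2", "haar")
DWT_LEVEL = 8
DWT_COEFS = ("cA8", "cD8", "cD7", "cD6", "cD5", "cD4", "cD3", "cD2", "cD1")
DWT_STATS = ("STD", "MEAN", "MIN", "MAX", "Skewness",
             "RelativeWaveletEnergy", "Kurtosis", "ZeroCrossing")
DWT_SIGNALS = ("AF7", "AF8", "TP9", "TP10", "mean")

_BAND_TITLE = {"delta": "Delta", "theta": "Theta", "alpha": "Alpha",
               "beta": "Beta", "gamma": "Gamma"}


@dataclass
class ProjectionSet:
    """Spatial projections of one EEG window (all same length)."""

    mean: np.ndarray        # mean of all 4 channels
    prefrontal: np.ndarray  # mean(AF7, AF8)
    temporal: np.ndarray    # mean(TP9, TP10)
    asymmetry: np.ndarray   # right minus left: mean(AF8, TP10) - mean(AF7, TP9)


def project_channels(af7: np.ndarray, af8: np.ndarray,
                     tp9: np.ndarray, tp10: np.ndarray) -> ProjectionSet:
    """Build the mean / prefrontal / temporal / asymmetry projections."""
    arrs = [np.asarray(a, dtype=float) for a in (af7, af8, tp9, tp10)]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise InvalidArgumentError("EEG channels must share the same length")
    af7, af8, tp9, tp10 = arrs
    return ProjectionSet(
        mean=(af7 + af8 + tp9 + tp10) / 4.0,
        prefrontal=(af7 + af8) / 2.0,
        temporal=(tp9 + tp10) / 2.0,
        asymmetry=(af8 + tp10) / 2.0 - (af7 + tp9) / 2.0,
    )


def band_power(series: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Integrated periodogram power inside ``band`` (DC excluded, mean removed).

    A single-segment rectangular-window periodogram is computed on the
    mean-removed series and its density summed over the frequency bins
    strictly inside the band (× bin width), so a sinusoid of amplitude A at
    an in-band bin contributes ≈ A²/2 and white noise contributes power
    proportional to the band width.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < fs:
        raise InvalidArgumentError("need at least one second of signal")
    lo, hi = band
    freqs, pxx = sps.periodogram(series, fs=fs, window="boxcar", detrend="constant")
    mask = (freqs > lo) & (freqs < hi) & (freqs > 0)
    if not np.any(mask):
        raise InvalidArgumentError(
            f"band ({lo}, {hi}) Hz contains no frequency bins at this resolution"
        )
    df = freqs[1] - freqs[0]
    return float(np.sum(pxx[mask]) * df)


def band_power_set(proj: ProjectionSet, channels: dict[str, np.ndarray],
                   fs: float) -> dict[str, float]:
    """Band powers for the four projections and the four raw channels.

    Keys are ``<source>_<band>`` with sources ``mean``, ``prefrontal``,
    ``temporal``, ``asymmetry``, ``AF7``, ``AF8``, ``TP9``, ``TP10``.
    """
    sources = {
        "mean": proj.mean, "prefrontal": proj.prefrontal,
        "temporal": proj.temporal, "asymmetry": proj.asymmetry,
        "AF7": channels["eeg_af7"], "AF8": channels["eeg_af8"],
        "TP9": channels["eeg_tp9"], "TP10": channels["eeg_tp10"],
    }
    return {
        f"{src}_{band}": band_power(x, fs, edges)
        for src, x in sources.items()
        for band, edges in BANDS.items()
    }


# ---------------------------------------------------------------------------
# Workload indices


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def _log_ratio(right: float, left: float) -> float:
    if right > 0 and left > 0:
        return float(np.log(right) - np.log(left))
    return float("nan")


#: Registry of index formulas over a ``band_power_set`` mapping.  Defaults
#: follow the common literature readings: EI = β/(α+θ) (mean projection),
#: BB = θ/α (mean projection), CLI = prefrontal θ / temporal α, asymmetry =
#: right-minus-left log α power per region, ASA = mean of the two regions.
INDEX_REGISTRY = {
    "EngagementIndex": lambda p: _safe_ratio(
        p["mean_beta"], p["mean_alpha"] + p["mean_theta"]),
    "BrainBeat": lambda p: _safe_ratio(p["mean_theta"], p["mean_alpha"]),
    "CLI": lambda p: _safe_ratio(p["prefrontal_theta"], p["temporal_alpha"]),
    "AsymmetryIndexPrefrontal": lambda p: _log_ratio(p["AF8_alpha"], p["AF7_alpha"]),
    "AsymmetryIndexTemporal": lambda p: _log_ratio(p["TP10_alpha"], p["TP9_alpha"]),
}


def compute_indices(powers: dict[str, float],
                    registry: dict | None = None) -> dict[str, float]:
    """Evaluate the workload-index registry on a band-power mapping.

    Undefined ratios (zero denominator power) yield NaN markers; the window
    is retained and the value treated as missing downstream.
    """
    registry = INDEX_REGISTRY if registry is None else registry
    out = {name: float(fn(powers)) for name, fn in registry.items()}
    pre = out.get("AsymmetryIndexPrefrontal", float("nan"))
    tmp = out.get("AsymmetryIndexTemporal", float("nan"))
    out["ASA"] = (pre + tmp) / 2.0
    return out


# ---------------------------------------------------------------------------
# DWT statistics


def _zero_crossings(x: np.ndarray) -> int:
    # strict sign changes; exact zeros never count
    return int(np.sum(x[:-1] * x[1:] < 0))


def _moments(x: np.ndarray) -> tuple[float, float]:
    """Standardised 3rd and 4th central moments (kurtosis not excess-adjusted).

    Defined as 0 for (near-)constant input so degenerate windows stay usable.
    """
    mu = x.mean()
    sd = x.std()  # population convention
    if sd == 0 or not np.isfinite(sd):
        return 0.0, 0.0
    z = (x - mu) / sd
    return float(np.mean(z ** 3)), float(np.mean(z ** 4))


def dwt_features(series: np.ndarray, wavelet: str,
                 level: int = DWT_LEVEL) -> dict[str, float]:
    """The 72 wavelet statistics of one signal under one mother wavelet.

    An ``level``-deep multilevel DWT yields the coefficient arrays cA8 and
    cD8…cD1; each contributes STD (population), MEAN, MIN, MAX, Skewness,
    RelativeWaveletEnergy (its squared norm over the summed squared norms of
    all nine arrays), Kurtosis and ZeroCrossing (strict sign changes).
    Keys are ``<coef>_<stat>``.
    """
    if wavelet not in WAVELETS:
        raise InvalidArgumentError(f"wavelet must be one of {WAVELETS}")
    series = np.asarray(series, dtype=float)
    need = 2 ** level
    if len(series) < need:
        raise InvalidArgumentError(
            f"series too short for a level-{level} DWT: need >= {need} samples, "
            f"got {len(series)}"
        )
    coeffs = pywt.wavedec(series, wavelet, level=level)  # [cA8, cD8, ..., cD1]
    energies = np.array([float(np.sum(c ** 2)) for c in coeffs])
    total = energies.sum()
    out: dict[str, float] = {}
    for name, c, en in zip(DWT_COEFS, coeffs, energies):
        skew, kurt = _moments(c)
        out[f"{name}_STD"] = float(c.std())
        out[f"{name}_MEAN"] = float(c.mean())
        out[f"{name}_MIN"] = float(c.min())
        out[f"{name}_MAX"] = float(c.max())
        out[f"{name}_Skewness"] = skew
        out[f"{name}_RelativeWaveletEnergy"] = float(en / total) if total > 0 else 0.0
        out[f"{name}_Kurtosis"] = kurt
        out[f"{name}_ZeroCrossing"] = float(_zero_crossings(c))
    return out


def dwt_feature_name(signal: str, wavelet: str, coef: str, stat: str) -> str:
    return f"{signal}_{wavelet}_{coef}_{stat}"


def dwt_feature_names() -> list[str]:
    """The full 720-name DWT schema in deterministic order."""
    return [
        dwt_feature_name(s, w, c, st)
        for s in DWT_SIGNALS for w in WAVELETS for c in DWT_COEFS for st in DWT_STATS
    ]


def spectral_feature_names() -> list[str]:
    """The 16 non-DWT EEG feature names."""
    names = [f"{region}{_BAND_TITLE[b]}Power"
             for region in ("Prefrontal", "Temporal") for b in BANDS]
    names += ["EngagementIndex", "BrainBeat", "CLI",
              "AsymmetryIndexPrefrontal", "AsymmetryIndexTemporal", "ASA"]
    return names


def eeg_feature_names() -> list[str]:
    return dwt_feature_names() + spectral_feature_names()


def extract_eeg_features(window: WindowedSegment) -> dict[str, float]:
    """All 736 EEG features of one window, keyed by the stable name schema."""
    for name in EEG_CHANNELS:
        if name not in window.channels:
            raise InvalidArgumentError(f"window lacks EEG channel {name}")
    fs = window.rates["eeg_af7"]
    chans = {n: window.channels[n] for n in EEG_CHANNELS}
    proj = project_channels(chans["eeg_af7"], chans["eeg_af8"],
                            chans["eeg_tp9"], chans["eeg_tp10"])
    sources = {"AF7": chans["eeg_af7"], "AF8": chans["eeg_af8"],
               "TP9": chans["eeg_tp9"], "TP10": chans["eeg_tp10"],
               "mean": proj.mean}
    out: dict[str, float] = {}
    for sig_name, x in sources.items():
        for wavelet in WAVELETS:
            stats = dwt_features(x, wavelet)
            for key, val in stats.items():
                coef, stat = key.split("_", 1)
                out[dwt_feature_name(sig_name, wavelet, coef, stat)] = val
    powers = band_power_set(proj, chans, fs)
    for region, src in (("Prefrontal", "prefrontal"), ("Temporal", "temporal")):
        for band in BANDS:
            out[f"{region}{_BAND_TITLE[band]}Power"] = powers[f"{src}_{band}"]
    out.update(compute_indices(powers))
    return out
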