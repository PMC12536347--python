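"""Workload label construction, correlation analysis and feature-set manifests.

The 5-point workload questionnaire response feeds three classification
problems: the 5-class problem uses the response verbatim; the 3-class
problem merges {1,2} → low, keeps 3 as "neither low nor high", and merges
{4,5} → high; the 2-class problem keeps the two poles and *excludes*
response-3 windows entirely (the binary task names only "low" and "high").

Reduced feature sets are fixed manifests: a Both-Modalities set
(20 features), a headband-only set (20) and a wristband-only set (18).  The twelve wavelet members are pinned in a
versioned manifest (haar cD1/cD7/cD8 summarised by Kurtosis, MEAN and
ZeroCrossing per channel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .eeg_features import dwt_feature_name, eeg_feature_names
from .peripheral_features import E4_FEATURE_NAMES

#: classification-relevant activity vocabulary (fixed one-hot order);
#: eyes-closed baselines are excluded from classification.
ACTIVITY_ORDER = ("Relaxation", "Load", "Summary", "Reading", "Game")

#: columns of a FeatureTable that are metadata, not features
META_COLUMNS = ("participant", "session", "window_index", "activity",
                "workload_response", "stress_response")

EXCLUDED = "excluded"


@dataclass(frozen=True)
class ClassificationProblem:
    """Mapping from the 1..5 questionnaire response to class labels."""

    n_classes: int

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3, 5):
            raise InvalidArgumentError("n_classes must be 2, 3 or 5")

    def map_response(self, response: int) -> int | str:
        """Class label for one response, or ``"excluded"`` (binary, response 3)."""
        response = int(response)
        if not 1 <= response <= 5:
            raise InvalidArgumentError(f"response {response} not in 1..5")
        if self.n_classes == 5:
            return response
        if self.n_classes == 3:
            return {1: 0, 2: 0, 3: 1, 4: 2, 5: 2}[response]
        # binary: low vs high; the neutral midpoint has no pole
        if response == 3:
            return EXCLUDED
        return 0 if response <= 2 else 1


def map_labels(responses, problem: ClassificationProblem) -> pd.Series:
    """Vectorised label mapping; excluded windows become NA."""
    s = pd.Series(responses)
    mapped = s.map(lambda r: problem.map_response(r))
    return mapped.where(mapped != EXCLUDED, other=pd.NA)


# ---------------------------------------------------------------------------
# Correlation analysis


@dataclass
class CorrelationReport:
    """Per-feature label correlations, optionally averaged over participants."""

    method: str                     # "pearson" | "spearman"
    scope: str                      # "pooled" | "per_participant"
    coefficients: pd.Series         # per feature; per_participant: mean |coef|
    feature_matrix: pd.DataFrame | None = None  # feature x feature correlations


def _rankdata(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata
    return rankdata(x)


def correlate_features(
    table: pd.DataFrame,
    labels: pd.Series,
    method: str = "spearman",
    scope: str = "pooled",
    feature_matrix: bool = False,
) -> CorrelationReport:
    """Correlate every feature column with the label series.

    Spearman is computed as Pearson on ranks.  With ``scope="per_participant"``
    the absolute coefficients are averaged across participants (a feature
    constant within a participant contributes a missing value there).
    """
    if method not in ("pearson", "spearman"):
        raise InvalidArgumentError("method must be pearson or spearman")
    if scope not in ("pooled", "per_participant"):
        raise InvalidArgumentError("scope must be pooled or per_participant")
    feats = feature_columns(table)
    y = pd.to_numeric(pd.Series(labels).reset_index(drop=True), errors="coerce")
    if y.nunique(dropna=True) < 2:
        raise InvalidArgumentError("label series is constant; correlations undefined")
    X = table[feats].reset_index(drop=True)

    def corr_block(Xb: pd.DataFrame, yb: pd.Series) -> pd.Series:
        if method == "spearman":
            Xb = Xb.rank()
            yb = yb.rank()
        return Xb.corrwith(yb)

    if scope == "pooled":
        coefs = corr_block(X, y)
    else:
        parts = []
        for _, idx in table.reset_index(drop=True).groupby("participant").groups.items():
            idx = list(idx)
            if len(idx) < 3 or y.iloc[idx].nunique(dropna=True) < 2:
                continue
            parts.append(corr_block(X.iloc[idx], y.iloc[idx]).abs())
        if not parts:
            raise InvalidArgumentError("no participant has enough labelled windows")
        coefs = pd.concat(parts, axis=1).mean(axis=1)
    matrix = None
    if feature_matrix:
        matrix = (X.rank() if method == "spearman" else X).corr()
    return CorrelationReport(method=method, scope=scope,
                             coefficients=coefs, feature_matrix=matrix)


# ---------------------------------------------------------------------------
# Feature sets


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature (non-metadata, non-activity-indicator) columns of a table."""
    return [c for c in table.columns
            if c not in META_COLUMNS and not c.startswith("activity_")]


#: Version tag of the pinned reduced-set manifests.
FEATURE_MANIFEST_VERSION = "1.0"

#: The twelve wavelet members of the reduced sets: per EEG channel, the haar
#: cD1 Kurtosis, cD7 MEAN and cD8 ZeroCrossing statistics.
TWELVE_DWT_FEATURES = tuple(
    dwt_feature_name(ch, "haar", coef, stat)
    for ch in ("AF7", "AF8", "TP9", "TP10")
    for coef, stat in (("cD1", "Kurtosis"), ("cD7", "MEAN"), ("cD8", "ZeroCrossing"))
)

_MUSE_EXTRA = (
    "TemporalDeltaPower", "PrefrontalGammaPower", "TemporalThetaPower",
    "TemporalBetaPower", "TemporalGammaPower", "EngagementIndex",
    "AsymmetryIndexPrefrontal", "CLI",
)

_BOTH_E4 = (
    "max-scr", "HRV-SDNN", "HRV-RMSSD", "Max-Heart-Rate",
    "max-skt", "max-scl", "HRV-MeanNN", "HRV-ratio-LF-HF",
)


@dataclass(frozen=True)
class FeatureSetSpec:
    name: str
    features: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.features)


def reduced_feature_set(name: str,
                        dwt_features: tuple[str, ...] | None = None) -> FeatureSetSpec:
    """A pinned reduced feature set, or the full 754-feature set.

    ``name`` is one of ``BothModalities`` (20), ``MuseS`` (20),
    ``EmpaticaE4`` (18) or ``All`` (754).  The twelve wavelet members
    default to the pinned manifest but can be overridden.
    """
    dwt = tuple(dwt_features) if dwt_features is not None else TWELVE_DWT_FEATURES
    if name == "BothModalities":
        return FeatureSetSpec(name, dwt + _BOTH_E4)
    if name == "MuseS":
        return FeatureSetSpec(name, dwt + _MUSE_EXTRA)
    if name == "EmpaticaE4":
        return FeatureSetSpec(name, tuple(E4_FEATURE_NAMES))
    if name == "All":
        return FeatureSetSpec(name, tuple(eeg_feature_names()) + tuple(E4_FEATURE_NAMES))
    raise InvalidArgumentError(
        f"unknown feature set {name!r}; expected BothModalities, MuseS, "
        "EmpaticaE4 or All"
    )


def write_manifest(spec: FeatureSetSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(
        {"version": FEATURE_MANIFEST_VERSION, "name": spec.name,
         "features": list(spec.features)}, indent=1))


def read_manifest(path: str | Path) -> FeatureSetSpec:
    payload = json.loads(Path(path).read_text())
    return FeatureSetSpec(payload["name"], tuple(payload["features"]))


def select_top_features(report: CorrelationReport, k: int) -> FeatureSetSpec:
    """Top-k features by absolute correlation, ties broken lexicographically."""
    coefs = report.coefficients.abs()
    avail = coefs.dropna()
    if k > len(coefs):
        raise InvalidArgumentError(
            f"k={k} exceeds the {len(coefs)} available features"
        )
    order = sorted(coefs.index, key=lambda f: (-(avail.get(f, -np.inf)), f))
    return FeatureSetSpec(f"top{k}_{report.method}", tuple(order[:k]))


def one_hot_activity(activity: str) -> np.ndarray:
    """5-component indicator under the fixed activity ordering."""
    if activity not in ACTIVITY_ORDER:
        raise InvalidArgumentError(
            f"activity {activity!r} not in {ACTIVITY_ORDER} "
            "(eyes-closed baselines are excluded from classification)"
        )
    vec = np.zeros(len(ACTIVITY_ORDER))
    vec[ACTIVITY_ORDER.index(activity)] = 1.0
    return vec


def activity_indicator_frame(activities) -> pd.DataFrame:
    """One-hot activity columns (``activity_<name>``) for a sequence."""
    rows = [one_hot_activity(a) for a in activities]
    return pd.DataFrame(rows, columns=[f"activity_{a}" for a in ACTIVITY_ORDER])
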