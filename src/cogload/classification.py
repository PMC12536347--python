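"""Normalisation, hyperparameter grids, LOO-CV / personalised CV, reporting.

Two evaluation regimes mirror the study design:

* **generalised** models: leave-one-participant-out cross-validation — each
  fold holds out every window of one participant, so scores measure
  subject-independent transfer;
* **personalised** models: stratified k-fold (default 5) within each
  participant's own windows, optionally augmented with one-hot activity
  context features; per-participant fold aggregates are averaged across
  participants.

Per-participant z-scoring is applied before splitting (participant-level
normalisation precedes any fold logic); min-max scaling and median
imputation are fitted on training rows only inside each fold, with test
values clipped to [0, 1], so no fold statistics leak.  Scores are accuracy
and weighted F1, aggregated as min/mean/max.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .errors import InvalidArgumentError
from .labels import (
    ClassificationProblem,
    FeatureSetSpec,
    activity_indicator_frame,
    feature_columns,
    map_labels,
)

logger = logging.getLogger(__name__)

FAMILIES = ("tree", "logistic", "mlp", "knn", "linear_svm")


# ---------------------------------------------------------------------------
# Hyperparameter grids


def expand_grid(family: str, knn_full_leaf: bool = False) -> list[dict]:
    """The default hyperparameter grid of one classifier family.

    Invalid logistic solver/penalty combinations are pruned.  The KNN
    ``leaf_size`` axis defaults to a {1,10,20,30,40,50} subsample because
    leaf size affects only lookup speed, never predictions; pass
    ``knn_full_leaf=True`` for the full 1..50 range.
    """
    if family == "tree":
        return [
            {"criterion": c, "splitter": s, "max_depth": d}
            for c in ("gini", "entropy")
            for s in ("best", "random")
            for d in range(5, 306, 5)
        ]
    if family == "logistic":
        valid = {
            "lbfgs": ("l2", "none"),
            "liblinear": ("l1", "l2"),
            "sag": ("l2", "none"),
            "saga": ("l1", "l2", "none"),
        }
        return [
            {"solver": s, "penalty": p}
            for s, penalties in valid.items() for p in penalties
        ]
    if family == "mlp":
        return [
            {"activation": a, "hidden_layer_sizes": h}
            for a in ("logistic", "tanh", "relu")
            for h in (3, 10, 30, 50)
        ]
    if family == "knn":
        leaves = range(1, 51) if knn_full_leaf else (1, 10, 20, 30, 40, 50)
        return [
            {"leaf_size": ls, "n_neighbors": k, "p": p}
            for ls in leaves for k in range(1, 31) for p in (1, 2)
        ]
    if family == "linear_svm":
        return [
            {"penalty": p, "C": c}
            for p in ("l1", "l2")
            for c in (0.001, 0.01, 0.1, 1, 10, 100, 1000)
        ]
    raise InvalidArgumentError(f"unknown family {family!r}")


def grid_from_yaml(path) -> dict[str, list[dict]]:
    """Load a ``family -> list of hyperparameter maps`` grid from YAML.

    Unknown families are rejected so a typo cannot silently drop a model.
    """
    import yaml

    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise InvalidArgumentError("grid YAML must map family -> list of configs")
    unknown = set(payload) - set(FAMILIES)
    if unknown:
        raise InvalidArgumentError(f"unknown classifier families: {sorted(unknown)}")
    return {fam: [dict(p) for p in plist] for fam, plist in payload.items()}


def make_estimator(family: str, params: dict, seed: int = 0):
    """Instantiate a scikit-learn estimator for one grid point."""
    if family == "tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "logistic":
        p = dict(params)
        if p.get("penalty") == "none":
            p["penalty"] = None
        return LogisticRegression(max_iter=2000, random_state=seed, **p)
    if family == "mlp":
        p = dict(params)
        p["hidden_layer_sizes"] = (p["hidden_layer_sizes"],)
        return MLPClassifier(max_iter=400, random_state=seed, **p)
    if family == "knn":
        return KNeighborsClassifier(**params)
    if family == "linear_svm":
        return LinearSVC(dual=False, max_iter=5000, random_state=seed, **params)
    raise InvalidArgumentError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Normalisation


def normalize_features(table: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Apply one of the pipeline's normalisation stages to a feature table.

    ``per_participant_z``: within each participant, impute each feature's
    missing values with that participant's median and z-score to mean 0 /
    SD 1 (constant columns become 0).  ``train_fit_minmax`` is fold-internal
    and exposed via :func:`fit_minmax` / :func:`apply_minmax`.
    """
    if stage != "per_participant_z":
        raise InvalidArgumentError(
            "stage must be 'per_participant_z' (min-max is fold-internal; "
            "use fit_minmax/apply_minmax)"
        )
    feats = feature_columns(table)
    out = table.copy()

    def zscore(block: pd.DataFrame) -> pd.DataFrame:
        block = block.fillna(block.median()).fillna(0.0)
        mu = block.mean()
        sd = block.std(ddof=0).replace(0.0, np.nan)
        return ((block - mu) / sd).fillna(0.0)

    out[feats] = (
        out.groupby("participant", group_keys=False)[feats].apply(zscore)
    )
    return out


@dataclass
class MinMaxScaler:
    """Min-max parameters fitted on training rows only."""

    lo: pd.Series
    hi: pd.Series
    medians: pd.Series


def fit_minmax(train: pd.DataFrame) -> MinMaxScaler:
    medians = train.median().fillna(0.0)
    filled = train.fillna(medians)
    return MinMaxScaler(lo=filled.min(), hi=filled.max(), medians=medians)


def apply_minmax(scaler: MinMaxScaler, X: pd.DataFrame, clip: bool) -> np.ndarray:
    X = X.fillna(scaler.medians)
    span = (scaler.hi - scaler.lo).replace(0.0, 1.0)
    Z = (X - scaler.lo) / span
    if clip:
        Z = Z.clip(0.0, 1.0)
    return Z.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Metrics


def weighted_f1(predictions, truths) -> float:
    """Support-weighted mean of per-class F1 scores.

    Classes are taken from the truth labels; a class with an undefined
    precision or recall contributes F1 = 0.
    """
    y_pred = np.asarray(predictions)
    y_true = np.asarray(truths)
    if len(y_pred) != len(y_true):
        raise InvalidArgumentError("predictions and truths must have equal length")
    if len(y_true) == 0:
        raise InvalidArgumentError("empty label sequences")
    total = len(y_true)
    score = 0.0
    for cls in np.unique(y_true):
        tp = np.sum((y_pred == cls) & (y_true == cls))
        fp = np.sum((y_pred == cls) & (y_true != cls))
        fn = np.sum((y_pred != cls) & (y_true == cls))
        support = tp + fn
        denom = 2 * tp + fp + fn
        f1 = (2 * tp / denom) if denom > 0 else 0.0
        score += (support / total) * f1
    return float(score)


def accuracy(predictions, truths) -> float:
    y_pred = np.asarray(predictions)
    y_true = np.asarray(truths)
    if len(y_true) == 0:
        raise InvalidArgumentError("empty label sequences")
    return float(np.mean(y_pred == y_true))


# ---------------------------------------------------------------------------
# Results container


@dataclass
class CVReport:
    """Per-configuration, per-fold scores with min/mean/max aggregation.

    ``rows`` has columns family, params (JSON string), fold, n_test,
    accuracy, weighted_f1, degenerate.  In ``personal`` mode ``fold`` is
    ``<participant>/<k>`` and aggregation first collapses each participant's
    folds to min/mean/max, then averages across participants.
    """

    mode: str                      # "loo" | "personal"
    problem: int                   # number of classes
    feature_set: str
    rows: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def aggregate(self, metric: str = "weighted_f1") -> pd.DataFrame:
        """min/mean/max per (family, params)."""
        if self.mode == "personal":
            per_part = self.rows.assign(
                participant=self.rows["fold"].str.split("/").str[0]
            ).groupby(["family", "params", "participant"])[metric].agg(
                ["min", "mean", "max"])
            agg = per_part.groupby(["family", "params"]).mean()
        else:
            agg = self.rows.groupby(["family", "params"])[metric].agg(
                ["min", "mean", "max"])
        return agg.reset_index()

    def best(self, family: str | None = None,
             metric: str = "weighted_f1") -> tuple[str, dict, pd.Series]:
        """Best configuration by mean score.

        Ties break towards the smaller model (smaller summed numeric
        hyperparameter magnitude), then lexicographically.
        """
        agg = self.aggregate(metric)
        if family is not None:
            agg = agg[agg["family"] == family]
        if agg.empty:
            raise InvalidArgumentError("no rows to select a best configuration from")

        def size_key(params_json: str) -> float:
            params = json.loads(params_json)
            return sum(abs(v) for v in params.values()
                       if isinstance(v, (int, float)))

        ranked = sorted(
            agg.itertuples(index=False),
            key=lambda r: (-r.mean, size_key(r.params), r.family, r.params),
        )
        top = ranked[0]
        return top.family, json.loads(top.params), pd.Series(
            {"min": top.min, "mean": top.mean, "max": top.max})

    def summary(self, metric: str = "weighted_f1") -> pd.DataFrame:
        """One row per family: the best configuration and its min/mean/max."""
        out = []
        for fam in sorted(self.rows["family"].unique()):
            f, params, stats = self.best(family=fam, metric=metric)
            out.append({
                "family": fam, "problem": self.problem,
                "feature_set": self.feature_set, "mode": self.mode,
                "params": json.dumps(params, sort_keys=True),
                "min": stats["min"], "mean": stats["mean"], "max": stats["max"],
            })
        return pd.DataFrame(out)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mode": self.mode, "problem": self.problem,
            "feature_set": self.feature_set, "meta": self.meta,
            "rows": self.rows.to_dict(orient="list"),
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CVReport":
        payload = json.loads(Path(path).read_text())
        return cls(mode=payload["mode"], problem=payload["problem"],
                   feature_set=payload["feature_set"], meta=payload["meta"],
                   rows=pd.DataFrame(payload["rows"]))


# ---------------------------------------------------------------------------
# Cross-validation drivers


def _fit_predict(fam: str, params: dict, seed: int,
                 Ztr: np.ndarray, ytr, Zte: np.ndarray) -> np.ndarray:
    """Fit one grid point and predict; a single-class training fold falls
    back to a majority-vote predictor (the fold is flagged degenerate)."""
    if pd.Series(ytr).nunique() < 2:
        est = DummyClassifier(strategy="most_frequent")
    else:
        est = make_estimator(fam, params, seed=seed)
    est.fit(Ztr, ytr)
    return est.predict(Zte)


def _prepare(table: pd.DataFrame, problem: ClassificationProblem,
             feature_set: FeatureSetSpec, with_activity: bool
             ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Select rows/columns for one problem: X (features [+ activity]), y, groups."""
    df = table[table["activity"] != "EyesClosed"].reset_index(drop=True)
    y = map_labels(df["workload_response"], problem)
    keep = y.notna()
    df, y = df[keep].reset_index(drop=True), y[keep].reset_index(drop=True)
    missing = [f for f in feature_set.features if f not in df.columns]
    if missing:
        raise InvalidArgumentError(
            f"feature table lacks {len(missing)} features of set "
            f"{feature_set.name!r}, e.g. {missing[:3]}"
        )
    X = df[list(feature_set.features)].astype(float)
    if with_activity:
        X = pd.concat(
            [X, activity_indicator_frame(df["activity"]).set_index(X.index)],
            axis=1,
        )
    return X, y.astype(int), df["participant"]


def _grid_items(grid: dict[str, list[dict]] | list[tuple[str, dict]]):
    if isinstance(grid, dict):
        return [(fam, params) for fam, plist in grid.items() for params in plist]
    return list(grid)


def _fold_top_k(Xtr: pd.DataFrame, ytr: pd.Series, groups_tr: pd.Series,
                k: int) -> list[str]:
    """Training-fold-internal top-k selection by mean |Spearman| per participant."""
    from .labels import CorrelationReport, select_top_features

    parts = []
    for p, idx in groups_tr.groupby(groups_tr).groups.items():
        yb = ytr.loc[idx].astype(float)
        if len(idx) < 3 or yb.nunique() < 2:
            continue
        parts.append(Xtr.loc[idx].rank().corrwith(yb.rank()).abs())
    if not parts:
        raise InvalidArgumentError("no training participant supports selection")
    coefs = pd.concat(parts, axis=1).mean(axis=1)
    report = CorrelationReport("spearman", "per_participant", coefs)
    return list(select_top_features(report, k).features)


def loo_cv(
    table: pd.DataFrame,
    grid: dict[str, list[dict]] | list[tuple[str, dict]],
    problem: ClassificationProblem,
    feature_set: FeatureSetSpec,
    seed: int = 0,
    per_participant_z: bool = True,
    with_activity: bool = False,
    select_top_k: int | None = None,
) -> CVReport:
    """Leave-one-participant-out evaluation of every grid configuration.

    Imputation and min-max scaling are fitted on each fold's training rows
    only; folds whose training set lacks a class are scored anyway and
    flagged ``degenerate``.  With ``select_top_k`` the feature set is
    narrowed per fold to the k features with the largest mean absolute
    Spearman correlation across *training* participants (data-driven
    selection on the whole table instead — the overfitting-prone variant —
    is available by passing a pre-selected ``feature_set``).
    """
    if table["participant"].nunique() < 2:
        raise InvalidArgumentError("leave-one-participant-out needs >= 2 participants")
    work = normalize_features(table, "per_participant_z") if per_participant_z else table
    X, y, groups = _prepare(work, problem, feature_set, with_activity)
    participants = sorted(groups.unique())
    rows = []
    fold_columns: dict[str, list[str]] = {}
    for fam, params in _grid_items(grid):
        for p in participants:
            test_mask = (groups == p).to_numpy()
            Xtr, ytr = X[~test_mask], y[~test_mask]
            Xte, yte = X[test_mask], y[test_mask]
            if len(yte) == 0:
                continue
            if select_top_k is not None:
                if p not in fold_columns:
                    fold_columns[p] = _fold_top_k(
                        Xtr.fillna(Xtr.median()), ytr, groups[~test_mask],
                        select_top_k)
                Xtr, Xte = Xtr[fold_columns[p]], Xte[fold_columns[p]]
            degenerate = ytr.nunique() < problem.n_classes or yte.nunique() == 0
            scaler = fit_minmax(Xtr)
            Ztr = apply_minmax(scaler, Xtr, clip=False)
            Zte = apply_minmax(scaler, Xte, clip=True)
            pred = _fit_predict(fam, params, seed, Ztr, ytr, Zte)
            rows.append({
                "family": fam, "params": json.dumps(params, sort_keys=True),
                "fold": p, "n_test": int(len(yte)),
                "accuracy": accuracy(pred, yte),
                "weighted_f1": weighted_f1(pred, yte),
                "degenerate": bool(degenerate),
            })
            logger.debug("loo fold %s %s %s f1=%.3f", fam, params, p,
                         rows[-1]["weighted_f1"])
    return CVReport(mode="loo", problem=problem.n_classes,
                    feature_set=feature_set.name, rows=pd.DataFrame(rows),
                    meta={"seed": seed, "n_participants": len(participants),
                          "with_activity": with_activity,
                          "select_top_k": select_top_k})


def personal_cv(
    table: pd.DataFrame,
    grid: dict[str, list[dict]] | list[tuple[str, dict]],
    problem: ClassificationProblem,
    feature_set: FeatureSetSpec,
    k: int = 5,
    with_activity: bool = False,
    seed: int = 0,
    per_participant_z: bool = True,
) -> CVReport:
    """Within-participant stratified k-fold evaluation (personalised models).

    Participants with too few windows to stratify ``k`` folds are skipped
    with a logged notice.  With ``k`` equal to a participant's window count
    the split degrades gracefully to leave-one-window-out.
    """
    work = normalize_features(table, "per_participant_z") if per_participant_z else table
    X, y, groups = _prepare(work, problem, feature_set, with_activity)
    rows = []
    for fam, params in _grid_items(grid):
        for p in sorted(groups.unique()):
            mask = (groups == p).to_numpy()
            Xp, yp = X[mask].reset_index(drop=True), y[mask].reset_index(drop=True)
            n = len(yp)
            min_support = yp.value_counts().min() if n else 0
            if n < k or (min_support < k and k < n):
                logger.warning(
                    "personal CV: skipping participant %s (%d windows, "
                    "min class support %d < k=%d)", p, n, min_support, k)
                continue
            if k == n:  # leave-one-window-out
                splitter = KFold(n_splits=n)
            else:
                splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                           random_state=seed)
            for fold_i, (tr, te) in enumerate(splitter.split(Xp, yp)):
                ytr, yte = yp.iloc[tr], yp.iloc[te]
                scaler = fit_minmax(Xp.iloc[tr])
                Ztr = apply_minmax(scaler, Xp.iloc[tr], clip=False)
                Zte = apply_minmax(scaler, Xp.iloc[te], clip=True)
                pred = _fit_predict(fam, params, seed, Ztr, ytr, Zte)
                rows.append({
                    "family": fam, "params": json.dumps(params, sort_keys=True),
                    "fold": f"{p}/{fold_i}", "n_test": int(len(yte)),
                    "accuracy": accuracy(pred, yte),
                    "weighted_f1": weighted_f1(pred, yte),
                    "degenerate": bool(ytr.nunique() < problem.n_classes),
                })
                logger.debug("personal fold %s %s %s/%d f1=%.3f", fam, params,
                             p, fold_i, rows[-1]["weighted_f1"])
    return CVReport(mode="personal", problem=problem.n_classes,
                    feature_set=feature_set.name, rows=pd.DataFrame(rows),
                    meta={"seed": seed, "k": k, "with_activity": with_activity})


def permutation_null(
    table: pd.DataFrame,
    config: tuple[str, dict],
    problem: ClassificationProblem,
    feature_set: FeatureSetSpec,
    n_permutations: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Mean weighted F1 under label permutation, one value per permutation.

    Workload responses are shuffled across windows before the full LOO-CV
    pipeline runs, giving the chance-level distribution against which an
    observed score can be calibrated.
    """
    rng = np.random.default_rng(seed)
    scores = np.empty(n_permutations)
    for i in range(n_permutations):
        shuffled = table.copy()
        shuffled["workload_response"] = rng.permutation(
            shuffled["workload_response"].to_numpy())
        rep = loo_cv(shuffled, [config], problem, feature_set, seed=seed)
        scores[i] = rep.aggregate()["mean"].iloc[0]
    return scores


def write_report(reports: list[CVReport], out_path: str | Path) -> pd.DataFrame:
    """Summarise reports (family × problem × set rows) as JSON + CSV files.

    ``out_path`` is a stem; ``<stem>.json`` and ``<stem>.csv`` are written.
    Returns the summary frame.
    """
    if not reports:
        raise InvalidArgumentError("no reports to summarise")
    summary = pd.concat([r.summary() for r in reports], ignore_index=True)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out_path.with_suffix(".csv"), index=False)
    out_path.with_suffix(".json").write_text(
        json.dumps(summary.to_dict(orient="records"), indent=1))
    return summary
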