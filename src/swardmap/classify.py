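"""Random Forest training, replicate-wise spatial cross-validation, metrics.

Hyperparameter defaults mirror the classification setup: 500 trees, √p
candidate features per split, minimum node size 1. Folds hold out one field
replicate at a time (all plots of that replicate form the test set), so
evaluation never mixes spatially adjacent observations between train and
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "RFHyperparams",
    "FoldScheme",
    "ClassificationReport",
    "make_folds",
    "train_rf",
    "run_spatial_cv",
    "compute_metrics",
]


@dataclass(frozen=True)
class RFHyperparams:
    num_trees: int = 500
    mtry: int | None = None  # None → floor(sqrt(p))
    min_node_size: int = 1
    seed: int = 0

    def resolve_mtry(self, n_features: int) -> int:
        if self.mtry is not None:
            return self.mtry
        return max(1, int(np.floor(np.sqrt(n_features))))


@dataclass(frozen=True)
class FoldScheme:
    """Replicate-keyed train/test plot splits."""

    folds: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...]
    # each: (held-out replicate, train plot_ids, test plot_ids)

    def __len__(self) -> int:
        return len(self.folds)


def make_folds(plots: pd.DataFrame) -> FoldScheme:
    """One fold per replicate: test = that replicate's plots, train = rest."""
    if "plot_id" not in plots or "replicate" not in plots:
        raise ValueError("plot table needs plot_id and replicate columns")
    if plots["replicate"].isna().any():
        raise ValueError("every plot needs a replicate label")
    reps = sorted(plots["replicate"].unique())
    if len(reps) < 2:
        raise ValueError("need >= 2 replicates for spatial cross-validation")
    folds = []
    for rep in reps:
        test = tuple(sorted(plots.loc[plots["replicate"] == rep, "plot_id"]))
        train = tuple(sorted(plots.loc[plots["replicate"] != rep, "plot_id"]))
        folds.append((str(rep), train, test))
    return FoldScheme(folds=tuple(folds))


FEATURE_EXCLUDE = ("segment_id", "polygon_id", "class", "class_name",
                   "plot_id", "replicate")


def feature_columns(db: pd.DataFrame) -> list[str]:
    return [c for c in db.columns
            if c not in FEATURE_EXCLUDE and pd.api.types.is_numeric_dtype(db[c])]


def train_rf(db: pd.DataFrame, hp: RFHyperparams | None = None,
             columns: list[str] | None = None) -> RandomForestClassifier:
    """Fit the bagged forest on a learning database (rows: labeled segments)."""
    hp = hp or RFHyperparams()
    columns = columns or feature_columns(db)
    x = db[columns].to_numpy()
    y = db["class"].to_numpy()
    if np.isnan(x).any():
        raise ValueError("missing feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain >= 2 classes")
    clf = RandomForestClassifier(
        n_estimators=hp.num_trees,
        max_features=hp.resolve_mtry(len(columns)),
        min_samples_leaf=hp.min_node_size,
        random_state=hp.seed,
        n_jobs=1,
    )
    clf.fit(x, y)
    return clf


def compute_metrics(confusion: np.ndarray,
                    class_codes: list[int] | None = None) -> dict:
    """OA and per-class precision/recall/F1 from a confusion matrix.

    Rows index truth, columns prediction. A class with zero support in both
    truth and prediction gets NaN (undefined) F1 and is excluded from
    averages.
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (m < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    total = m.sum()
    if total == 0:
        raise ValueError("all-zero confusion matrix")
    k = m.shape[0]
    codes = class_codes if class_codes is not None else list(range(1, k + 1))
    oa = np.trace(m) / total
    per_class = {}
    for i, code in enumerate(codes):
        tp = m[i, i]
        pred = m[:, i].sum()
        true = m[i, :].sum()
        if pred == 0 and true == 0:
            per_class[code] = {"precision": np.nan, "recall": np.nan, "f1": np.nan,
                               "support": 0.0}
            continue
        precision = tp / pred if pred > 0 else 0.0
        recall = tp / true if true > 0 else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if (precision + recall) > 0 else 0.0)
        per_class[code] = {"precision": precision, "recall": recall, "f1": f1,
                           "support": true}
    return {"overall_accuracy": float(oa), "per_class": per_class,
            "confusion": m, "class_codes": codes}


@dataclass
class ClassificationReport:
    class_codes: list[int]
    fold_confusions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def pooled_confusion(self) -> np.ndarray:
        return np.sum(list(self.fold_confusions.values()), axis=0)

    def pooled_metrics(self) -> dict:
        return compute_metrics(self.pooled_confusion, self.class_codes)

    def fold_metrics(self) -> dict[str, dict]:
        return {rep: compute_metrics(m, self.class_codes)
                for rep, m in self.fold_confusions.items()}

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-fold + pooled metric table (one row per fold × class)."""
        rows = []
        items = list(self.fold_metrics().items()) + [("pooled", self.pooled_metrics())]
        for fold, met in items:
            rows.append({"fold": fold, "class": "all", "metric": "overall_accuracy",
                         "value": met["overall_accuracy"]})
            for code, pc in met["per_class"].items():
                for name in ("precision", "recall", "f1"):
                    rows.append({"fold": fold, "class": code, "metric": name,
                                 "value": pc[name]})
        return pd.DataFrame(rows)


def run_spatial_cv(
    db: pd.DataFrame,
    scheme: FoldScheme,
    hp: RFHyperparams | None = None,
    class_codes: list[int] | None = None,
) -> ClassificationReport:
    """Train/test per fold on plot-disjoint rows; accumulate confusions."""
    hp = hp or RFHyperparams()
    codes = class_codes or sorted(db["class"].unique().tolist())
    cols = feature_columns(db)
    report = ClassificationReport(class_codes=list(codes))
    code_index = {c: i for i, c in enumerate(codes)}
    for fi, (rep, train_plots, test_plots) in enumerate(scheme.folds):
        train = db[db["plot_id"].isin(train_plots)]
        test = db[db["plot_id"].isin(test_plots)]
        if test.empty:
            logger.warning("fold %s: no test rows; skipped", rep)
            continue
        # per-fold seed derived deterministically from the global one
        fold_hp = RFHyperparams(hp.num_trees, hp.mtry, hp.min_node_size,
                                seed=hp.seed + 1000 * (fi + 1))
        clf = train_rf(train, fold_hp, columns=cols)
        pred = clf.predict(test[cols].to_numpy())
        m = np.zeros((len(codes), len(codes)))
        for t, p in zip(test["class"].to_numpy(), pred):
            m[code_index[int(t)], code_index[int(p)]] += 1
        report.fold_confusions[rep] = m
    return report
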