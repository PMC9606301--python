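"""Risk-prediction classifiers: training, evaluation, calibration, tuning.

Gradient-boosted trees (XGBoost) are the base algorithm; random forest,
support-vector machine and k-nearest-neighbours serve as comparators.
"Base model" means library-default hyperparameters.  Evaluation is
always on rows the model never saw; classification uses the fixed 0.5
probability threshold; AUC comes from the full score ranking.

Accuracy is reported alongside the other metrics, but on
imbalanced data it is dominated by the majority class — treat it as
imbalance-sensitive and prefer recall/precision/AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .ml_table import LABEL_COLUMN, MLTable

ALGORITHMS = ("gbt", "random_forest", "svm", "knn")

MISSING_LEVEL = -1  # ordinal code reserved for missing / unseen categories


class SingleClassError(ValueError):
    """Operation undefined because only one class is present."""


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.70
    validation: float = 0.15
    test: float = 0.15
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        fr = (self.train, self.validation, self.test)
        if any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str = "gbt"
    hyperparameters: dict = field(default_factory=dict)
    early_stopping: bool = False  # gbt only; uses the validation set when on

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")


@dataclass(frozen=True)
class ModelMetrics:
    recall: float
    precision: float
    auc: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "auc": self.auc,
            "accuracy": self.accuracy,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


@dataclass
class ReliabilityCurve:
    bin_edges: np.ndarray
    mean_predicted: np.ndarray  # NaN where a bin is empty
    observed_fraction: np.ndarray
    counts: np.ndarray

    @property
    def max_deviation(self) -> float:
        filled = self.counts > 0
        return float(np.max(np.abs(self.mean_predicted[filled] - self.observed_fraction[filled])))


@dataclass(frozen=True)
class TuningGrid:
    param_grid: dict
    cv_folds: int = 10

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.param_grid or any(len(v) == 0 for v in self.param_grid.values()):
            raise ValueError("grid must be non-empty")


def default_tuning_grid() -> TuningGrid:
    """Key gradient-boosting knobs: depth, learning rate, rounds, subsample."""
    return TuningGrid(
        {
            "max_depth": [3, 6, 9],
            "learning_rate": [0.1, 0.3],
            "n_estimators": [100, 300],
            "subsample": [0.8, 1.0],
        }
    )


# ---------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------


def split_dataset(table: MLTable, spec: SplitSpec = SplitSpec()) -> tuple[MLTable, MLTable, MLTable]:
    """Disjoint, exhaustive train/validation/test partition of the rows."""
    f = table.frame
    y = f[LABEL_COLUMN]
    if y.nunique() < 2:
        raise SingleClassError("need both classes to split")
    idx = f.index.to_numpy()
    n = len(idx)
    n_test = max(1, round(spec.test * n))
    n_val = max(1, round(spec.validation * n))
    strat = y.to_numpy() if spec.stratified else None
    rest, test = train_test_split(idx, test_size=n_test, stratify=strat, random_state=spec.seed)
    strat_rest = y.loc[rest].to_numpy() if spec.stratified else None
    train, val = train_test_split(rest, test_size=n_val, stratify=strat_rest, random_state=spec.seed)
    parts = []
    for part in (train, val, test):
        if len(part) == 0:
            raise ValueError("a split subset has zero rows")
        parts.append(MLTable(f.loc[part], dict(table.datatypes), dict(table.units), dict(table.origin_datatypes)))
    return tuple(parts)


# ---------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------


class FeatureEncoder:
    """Categorical-table encoder fitted on training rows only.

    ``ordinal`` (trees): each column maps its categories, sorted, to
    0..k-1; missing and unseen-at-transform-time share the dedicated
    level -1.  ``onehot`` (svm/knn): one indicator column per training
    category, missing rows are all-zero in their group, columns are
    standardized with train statistics.
    """

    def __init__(self, mode: str):
        if mode not in ("ordinal", "onehot"):
            raise ValueError("mode must be 'ordinal' or 'onehot'")
        self.mode = mode
        self.columns_: list[str] | None = None
        self.categories_: dict[str, list] = {}

    def fit(self, frame: pd.DataFrame) -> "FeatureEncoder":
        self.columns_ = list(frame.columns)
        for c in self.columns_:
            vals = frame[c].dropna().unique()
            self.categories_[c] = sorted(str(v) for v in vals)
        if self.mode == "onehot":
            raw = self._indicator(frame)
            self._mean = raw.mean(axis=0)
            sd = raw.std(axis=0)
            self._sd = np.where(sd == 0, 1.0, sd)
        return self

    def _ordinal(self, frame: pd.DataFrame) -> np.ndarray:
        out = np.full((len(frame), len(self.columns_)), MISSING_LEVEL, dtype=float)
        for j, c in enumerate(self.columns_):
            lut = {v: i for i, v in enumerate(self.categories_[c])}
            col = frame[c]
            out[:, j] = [lut.get(str(v), MISSING_LEVEL) if pd.notna(v) else MISSING_LEVEL for v in col]
        return out

    def _indicator(self, frame: pd.DataFrame) -> np.ndarray:
        blocks = []
        for c in self.columns_:
            cats = self.categories_[c]
            col = frame[c].astype(object)
            block = np.zeros((len(frame), len(cats)))
            for i, cat in enumerate(cats):
                block[:, i] = [1.0 if (pd.notna(v) and str(v) == cat) else 0.0 for v in col]
            blocks.append(block)
        return np.hstack(blocks) if blocks else np.zeros((len(frame), 0))

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        if self.columns_ is None:
            raise RuntimeError("encoder not fitted")
        frame = frame[self.columns_]
        if self.mode == "ordinal":
            return self._ordinal(frame)
        return (self._indicator(frame) - self._mean) / self._sd

    def decode_ordinal(self, arr: np.ndarray) -> pd.DataFrame:
        """Inverse of the ordinal encoding (missing level -> NaN)."""
        if self.mode != "ordinal":
            raise ValueError("decode only defined for ordinal mode")
        cols = {}
        for j, c in enumerate(self.columns_):
            cats = self.categories_[c]
            cols[c] = [cats[int(v)] if v >= 0 else np.nan for v in arr[:, j]]
        return pd.DataFrame(cols)


def encoder_for(algorithm: str) -> FeatureEncoder:
    return FeatureEncoder("ordinal" if algorithm in ("gbt", "random_forest") else "onehot")


def encode_features(train_frame: pd.DataFrame, algorithm: str) -> FeatureEncoder:
    """Fit the algorithm-appropriate encoder on training rows only."""
    return encoder_for(algorithm).fit(train_frame)


# ---------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------


def make_estimator(spec: ModelSpec, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "gbt":
        return XGBClassifier(random_state=seed, n_jobs=1, **hp)
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if spec.algorithm == "svm":
        return SVC(probability=True, random_state=seed, **hp)
    return KNeighborsClassifier(n_jobs=1, **hp)


@dataclass
class FittedModel:
    """A fitted probability-scoring classifier plus its encoder."""

    estimator: object
    encoder: FeatureEncoder
    variables: list[str]
    spec: ModelSpec

    def predict_proba(self, frame: pd.DataFrame) -> np.ndarray:
        X = self.encoder.transform(frame[self.variables])
        return self.estimator.predict_proba(X)[:, 1]


def train_model(
    train: MLTable,
    validation: MLTable | None,
    spec: ModelSpec,
    seed: int,
    variables: list[str] | None = None,
) -> FittedModel:
    """Fit one classifier; the validation set is only touched when
    gradient-boosting early stopping is explicitly enabled."""
    variables = variables or train.codes
    y = train.frame[LABEL_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        raise SingleClassError("training data contains a single class")
    enc = encode_features(train.frame[variables], spec.algorithm)
    X = enc.transform(train.frame[variables])
    est = make_estimator(spec, seed)
    if spec.algorithm == "gbt" and spec.early_stopping:
        if validation is None:
            raise ValueError("early stopping requires a validation set")
        Xv = enc.transform(validation.frame[variables])
        yv = validation.frame[LABEL_COLUMN].to_numpy()
        est.set_params(early_stopping_rounds=10)
        est.fit(X, y, eval_set=[(Xv, yv)], verbose=False)
    else:
        est.fit(X, y)
    return FittedModel(est, enc, variables, spec)


def metrics_from_scores(y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5) -> ModelMetrics:
    """Confusion-count metrics at the given probability threshold plus AUC."""
    y_true = np.asarray(y_true).astype(int)
    if len(np.unique(y_true)) < 2:
        raise SingleClassError("AUC undefined on a single-class set")
    pred = (np.asarray(y_prob) >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    accuracy = (tp + tn) / len(y_true)
    auc = float(roc_auc_score(y_true, y_prob))
    return ModelMetrics(recall, precision, auc, accuracy, tp, fp, tn, fn)


def evaluate(model: FittedModel, test: MLTable) -> ModelMetrics:
    """Score the held-out test rows (threshold 0.5, AUC from ranking)."""
    y = test.frame[LABEL_COLUMN].to_numpy()
    prob = model.predict_proba(test.frame)
    return metrics_from_scores(y, prob)


def reliability_curve(y_true: np.ndarray, y_prob: np.ndarray, n_bins: int = 10) -> ReliabilityCurve:
    """Calibration curve over equal-width probability bins; empty bins
    are skipped when computing the maximum deviation."""
    y_true = np.asarray(y_true).astype(float)
    y_prob = np.asarray(y_prob, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, y_prob, side="right") - 1, 0, n_bins - 1)
    mean_pred = np.full(n_bins, np.nan)
    obs = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        m = idx == b
        counts[b] = int(m.sum())
        if counts[b]:
            mean_pred[b] = y_prob[m].mean()
            obs[b] = y_true[m].mean()
    return ReliabilityCurve(edges, mean_pred, obs, counts)


def model_reliability(model: FittedModel, test: MLTable, n_bins: int = 10) -> ReliabilityCurve:
    return reliability_curve(test.frame[LABEL_COLUMN].to_numpy(), model.predict_proba(test.frame), n_bins)


def roc_points(model: FittedModel, test: MLTable) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(test.frame[LABEL_COLUMN].to_numpy(), model.predict_proba(test.frame))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------
# hyperparameter optimization
# ---------------------------------------------------------------------


def tune_hyperparameters(
    train: MLTable,
    grid: TuningGrid,
    seed: int,
    algorithm: str = "gbt",
    variables: list[str] | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search with stratified k-fold CV, AUC objective.

    Returns (best hyperparameters, CV table of mean/std AUC per
    combination).  Folds that end up single-class score NaN with a
    warning rather than aborting the search.
    """
    variables = variables or train.codes
    y = train.frame[LABEL_COLUMN].to_numpy()
    enc = encode_features(train.frame[variables], algorithm)
    X = enc.transform(train.frame[variables])
    cv = StratifiedKFold(n_splits=grid.cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        make_estimator(ModelSpec(algorithm), seed),
        grid.param_grid,
        scoring="roc_auc",
        cv=cv,
        refit=False,
        error_score=np.nan,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
    res = pd.DataFrame(search.cv_results_)
    table = res[["params", "mean_test_score", "std_test_score", "rank_test_score"]].copy()
    best = res.loc[res["rank_test_score"].idxmin(), "params"]
    return dict(best), table


def aggressive_candidates() -> list[dict]:
    """Recall-oriented gradient-boosting settings: upweighted positives
    (the imbalance knob) with extended boosting rounds."""
    return [
        {"scale_pos_weight": 4.0, "n_estimators": 300},
        {"scale_pos_weight": 6.0, "n_estimators": 300},
    ]


@dataclass
class OverfitComparison:
    base_metrics: ModelMetrics
    tuned_metrics: ModelMetrics
    base_reliability: ReliabilityCurve
    tuned_reliability: ReliabilityCurve
    tuned_params: dict


def overfitting_comparison(
    table: MLTable,
    variables: list[str],
    split: SplitSpec,
    seed: int,
    candidates: list[dict] | None = None,
    cv_folds: int = 5,
) -> OverfitComparison:
    """Base gradient-boosting model vs one aggressively tuned for recall.

    Candidate settings upweight the positive class and extend boosting;
    the winner is picked by cross-validated recall on the training rows
    (recall being the screening deployment metric).  Both models are then
    compared on the held-out test set: the tuned model matches or beats
    the base model's recall while its reliability curve deviates further
    from the diagonal, because upweighting systematically inflates the
    predicted probabilities — the overfitting/miscalibration signature
    that argues for keeping untuned base models inside learning cycles.
    """
    candidates = candidates if candidates is not None else aggressive_candidates()
    train, val, test = split_dataset(table, split)

    Xf = train.frame
    y = Xf[LABEL_COLUMN].to_numpy()
    enc = encode_features(Xf[variables], "gbt")
    X = enc.transform(Xf[variables])
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    best_params, best_cv = None, -1.0
    for params in candidates:
        recalls = []
        for tr_idx, te_idx in cv.split(X, y):
            est = make_estimator(ModelSpec("gbt", params), seed)
            est.fit(X[tr_idx], y[tr_idx])
            pred = est.predict_proba(X[te_idx])[:, 1] >= 0.5
            pos = y[te_idx] == 1
            recalls.append(pred[pos].mean())
        mean_recall = float(np.mean(recalls))
        if mean_recall > best_cv:
            best_params, best_cv = params, mean_recall

    base = train_model(train, None, ModelSpec("gbt"), seed, variables=variables)
    tuned = train_model(train, None, ModelSpec("gbt", best_params), seed, variables=variables)

    y = test.frame[LABEL_COLUMN].to_numpy()
    base_prob = base.predict_proba(test.frame)
    tuned_prob = tuned.predict_proba(test.frame)
    return OverfitComparison(
        base_metrics=metrics_from_scores(y, base_prob),
        tuned_metrics=metrics_from_scores(y, tuned_prob),
        base_reliability=reliability_curve(y, base_prob),
        tuned_reliability=reliability_curve(y, tuned_prob),
        tuned_params=dict(best_params),
    )


# ---------------------------------------------------------------------
# convenience: end-to-end fit on a converted, variable-selected table
# ---------------------------------------------------------------------


@dataclass
class RunResult:
    spec: ModelSpec
    model: FittedModel
    metrics: ModelMetrics
    reliability: ReliabilityCurve
    train_index: pd.Index
    validation_index: pd.Index
    test_index: pd.Index
    y_test: np.ndarray
    prob_test: np.ndarray


def fit_and_evaluate(
    table: MLTable,
    variables: list[str],
    spec: ModelSpec,
    split: SplitSpec,
    seed: int,
) -> RunResult:
    """Split, encode, train and test one model on the given variables."""
    train, val, test = split_dataset(table, split)
    model = train_model(train, val, spec, seed, variables=variables)
    y = test.frame[LABEL_COLUMN].to_numpy()
    prob = model.predict_proba(test.frame)
    metrics = metrics_from_scores(y, prob)
    rel = reliability_curve(y, prob)
    return RunResult(spec, model, metrics, rel, train.frame.index, val.frame.index, test.frame.index, y, prob)
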