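"""Sequence-function models: tree ensembles, consensus SHAP, evaluation.

Workflow: encode the residue feature matrix, train several tree-ensemble
algorithms (two gradient-boosting flavors and a random forest) under a
shared stratified cross-validation split, compute SHAP values on each
held-out fold, and aggregate.

Two SHAP aggregations are produced, both per fold so no single model or
fold dominates:

* consensus importance — mean |SHAP| per residue, min-max normalized to
  [0, 1] within each (algorithm, fold), then averaged across all
  (algorithm, fold) pairs and ranked;
* dependence profiles — per-row SHAP values of one residue for a chosen
  class, scaled by the fold's maximum absolute SHAP value (to [-1, 1],
  sign preserved) and grouped by the amino acid the row carries at that
  residue.

SHAP values come from each backend's native path-dependent tree explainer
(``pred_contribs`` for the boosters, this package's ``treeshap`` for the
forest).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import ConfigError, DomainError, LookupError_
from .seqfeatures import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldSpec:
    """Cross-validation policy: number of folds, stratification, seed."""

    n_folds: int = 5
    stratified: bool = True
    seed: int = 17

    def __post_init__(self):
        if self.n_folds < 2:
            raise DomainError("n_folds must be >= 2")


def make_cv_folds(n_rows: int, labels, spec: FoldSpec) -> np.ndarray:
    """Deterministic fold assignment: element i is the held-out fold of row i."""
    if n_rows < spec.n_folds:
        raise DomainError(f"{n_rows} rows cannot fill {spec.n_folds} folds")
    labels = np.asarray(labels)
    assign = np.empty(n_rows, dtype=int)
    if spec.stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < spec.n_folds:
            warnings.warn(
                f"smallest class has {counts.min()} < {spec.n_folds} members; "
                "falling back to unstratified folds"
            )
        else:
            skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
            for f, (_, test) in enumerate(skf.split(np.zeros(n_rows), labels)):
                assign[test] = f
            return assign
    kf = KFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    for f, (_, test) in enumerate(kf.split(np.zeros(n_rows))):
        assign[test] = f
    return assign


# ---------------------------------------------------------------------------
# backends


class _XGBBackend:
    name = "xgb"

    def __init__(self, seed: int, params: dict | None = None):
        import xgboost  # noqa: F401

        self.seed = seed
        self.params = dict(n_estimators=100, max_depth=4, learning_rate=0.2)
        self.params.update(params or {})

    def fit(self, X, y_enc, n_classes):
        from xgboost import XGBClassifier

        model = XGBClassifier(
            random_state=self.seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
            **self.params,
        )
        model.fit(X, y_enc)
        return model

    def predict(self, model, X):
        return model.predict(X)

    def shap(self, model, X, n_classes) -> np.ndarray:
        import xgboost as xgb

        contribs = model.get_booster().predict(
            xgb.DMatrix(np.asarray(X, dtype=np.float64)), pred_contribs=True
        )
        if contribs.ndim == 2:  # binary: margin contributions for class 1
            phi1 = contribs[:, :-1]
            return np.stack([-phi1, phi1], axis=2)
        return np.moveaxis(contribs[:, :, :-1], 1, 2)


class _LGBMBackend:
    name = "lgbm"

    def __init__(self, seed: int, params: dict | None = None):
        import lightgbm  # noqa: F401

        self.seed = seed
        self.params = dict(n_estimators=100, num_leaves=31, min_child_samples=5)
        self.params.update(params or {})

    def fit(self, X, y_enc, n_classes):
        from lightgbm import LGBMClassifier

        model = LGBMClassifier(random_state=self.seed, n_jobs=1, verbose=-1, **self.params)
        model.fit(np.asarray(X), np.asarray(y_enc))
        return model

    def predict(self, model, X):
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper warns about feature names on ndarray input
            warnings.simplefilter("ignore", UserWarning)
            return model.predict(np.asarray(X))

    def shap(self, model, X, n_classes) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            contribs = model.predict(np.asarray(X, dtype=np.float64), pred_contrib=True)
        n = contribs.shape[0]
        if n_classes == 2:
            phi1 = contribs[:, :-1]
            return np.stack([-phi1, phi1], axis=2)
        per_class = contribs.reshape(n, n_classes, -1)[:, :, :-1]
        return np.moveaxis(per_class, 1, 2)


class _RFBackend:
    name = "rf"

    def __init__(self, seed: int, params: dict | None = None):
        self.seed = seed
        self.params = dict(n_estimators=200, min_samples_leaf=1)
        self.params.update(params or {})

    def fit(self, X, y_enc, n_classes):
        from sklearn.ensemble import RandomForestClassifier

        model = RandomForestClassifier(random_state=self.seed, n_jobs=1, **self.params)
        model.fit(X, y_enc)
        return model

    def predict(self, model, X):
        return model.predict(X)

    def shap(self, model, X, n_classes) -> np.ndarray:
        from .treeshap import forest_shap_values

        phi, _ = forest_shap_values(model, np.asarray(X, dtype=np.float64))
        return phi


BACKENDS = {"xgb": _XGBBackend, "lgbm": _LGBMBackend, "rf": _RFBackend}
DEFAULT_ALGORITHMS = ("xgb", "lgbm", "rf")


@dataclass
class FoldResult:
    algorithm: str
    fold: int
    model: object
    test_indices: np.ndarray
    y_pred: np.ndarray  # original label space
    shap_values: np.ndarray  # (n_test, n_features, n_classes)


@dataclass
class TrainedModelBundle:
    """All fitted (algorithm, fold) models with held-out predictions and SHAP."""

    results: list[FoldResult]
    residues: list[int]
    classes: np.ndarray
    fold_assignment: np.ndarray
    feature_letters: pd.DataFrame  # rows x residues, single letters
    target: str

    @property
    def algorithms(self) -> list[str]:
        return sorted({r.algorithm for r in self.results})

    def heldout_predictions(self, algorithm: str) -> np.ndarray:
        """Out-of-fold predictions for every row, one per algorithm."""
        n = len(self.fold_assignment)
        out = np.empty(n, dtype=self.classes.dtype)
        seen = np.zeros(n, dtype=bool)
        for r in self.results:
            if r.algorithm == algorithm:
                out[r.test_indices] = r.y_pred
                seen[r.test_indices] = True
        if not seen.all():
            raise DomainError(f"algorithm {algorithm!r} missing predictions for some rows")
        return out

    def class_index(self, class_of_interest) -> int:
        idx = np.nonzero(self.classes == class_of_interest)[0]
        if len(idx) == 0:
            raise LookupError_(f"class {class_of_interest!r} not among {self.classes.tolist()}")
        return int(idx[0])


def _resolve_backends(algorithms, seed, params) -> list:
    backends = []
    for name in algorithms:
        if name not in BACKENDS:
            warnings.warn(f"unknown algorithm {name!r}; skipped")
            continue
        try:
            backends.append(BACKENDS[name](seed, (params or {}).get(name)))
        except ImportError:
            warnings.warn(f"backend {name!r} unavailable; skipped")
    if not backends:
        raise ConfigError("no tree-model backend available")
    return backends


#: small fixed grids for the optional seeded random search
_TUNE_GRID = {
    "xgb": {"n_estimators": [50, 100, 200], "max_depth": [2, 4, 6], "learning_rate": [0.05, 0.1, 0.2]},
    "lgbm": {"n_estimators": [50, 100, 200], "num_leaves": [7, 15, 31], "learning_rate": [0.05, 0.1, 0.2]},
    "rf": {"n_estimators": [100, 200, 400], "min_samples_leaf": [1, 2, 4], "max_features": ["sqrt", 0.5]},
}


def tune_hyperparameters(
    X: np.ndarray,
    y_enc: np.ndarray,
    algorithm: str,
    seed: int,
    n_configs: int = 8,
    n_inner_folds: int = 3,
) -> dict:
    """Seeded random search (<= 16 configs) scored by inner-CV accuracy."""
    n_configs = min(n_configs, 16)
    grid = _TUNE_GRID[algorithm]
    rng = np.random.default_rng(seed)
    n_classes = len(np.unique(y_enc))
    inner = make_cv_folds(len(y_enc), y_enc, FoldSpec(n_inner_folds, True, seed))
    best_params, best_score = {}, -np.inf
    for _ in range(n_configs):
        cand = {k: v[rng.integers(len(v))] for k, v in grid.items()}
        backend = BACKENDS[algorithm](seed, cand)
        hits = 0
        for f in range(n_inner_folds):
            test = inner == f
            model = backend.fit(X[~test], y_enc[~test], n_classes)
            hits += int(np.sum(backend.predict(model, X[test]) == y_enc[test]))
        score = hits / len(y_enc)
        if score > best_score:
            best_score, best_params = score, cand
    return best_params


def train_ensemble(
    features: FeatureMatrix,
    target: str,
    algorithms=DEFAULT_ALGORITHMS,
    spec: FoldSpec = FoldSpec(),
    params: dict | None = None,
    tune: bool = False,
    n_tune_configs: int = 8,
) -> TrainedModelBundle:
    """Fit every algorithm on every CV fold and explain its held-out rows.

    ``target`` is ``"stereochemistry"`` ({-1, 0, 1}) or ``"reactivity"``
    ({0, 1}).  All algorithms share one fold assignment so their SHAP
    aggregates are comparable.  ``tune=True`` runs a small seeded random
    search per algorithm before the outer CV.
    """
    X = features.encoded().astype(np.float64)
    y = features.target(target)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DomainError(f"target {target!r} has a single class")
    y_enc = np.searchsorted(classes, y)
    assign = make_cv_folds(len(y), y, spec)
    if tune:
        params = dict(params or {})
        for name in algorithms:
            if name in BACKENDS and name not in params:
                params[name] = tune_hyperparameters(
                    X, y_enc, name, spec.seed, n_configs=n_tune_configs
                )
    backends = _resolve_backends(algorithms, spec.seed, params)

    results = []
    for backend in backends:
        for f in range(spec.n_folds):
            test = np.nonzero(assign == f)[0]
            train = np.nonzero(assign != f)[0]
            model = backend.fit(X[train], y_enc[train], len(classes))
            pred_enc = np.asarray(backend.predict(model, X[test]), dtype=int)
            phi = backend.shap(model, X[test], len(classes))
            results.append(
                FoldResult(
                    algorithm=backend.name,
                    fold=f,
                    model=model,
                    test_indices=test,
                    y_pred=classes[pred_enc],
                    shap_values=phi,
                )
            )
    return TrainedModelBundle(
        results=results,
        residues=list(features.residues),
        classes=classes,
        fold_assignment=assign,
        feature_letters=features.data.copy(),
        target=target,
    )


@dataclass
class ConsensusImportance:
    """Mean fold-normalized |SHAP| per residue, in [0, 1], with ranks."""

    residues: list[int]
    values: np.ndarray
    ranks: np.ndarray  # rank 1 = most important

    def top(self, n: int = 10) -> pd.DataFrame:
        order = np.argsort(self.ranks)
        return pd.DataFrame(
            {
                "rank": self.ranks[order][:n],
                "residue": np.asarray(self.residues)[order][:n],
                "consensus_importance": self.values[order][:n],
            }
        )

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.residues, name="consensus_importance")


def shap_consensus_importance(bundle: TrainedModelBundle) -> ConsensusImportance:
    """Average fold-normalized mean-|SHAP| importance across all models.

    Within each (algorithm, fold): importance of a residue is the mean of
    |SHAP| over held-out rows and classes, min-max normalized to [0, 1]
    across residues.  The consensus is the plain average of these normalized
    vectors over every (algorithm, fold) pair — a symmetric mean, so the
    result is invariant to algorithm and fold ordering.
    """
    per_fold = []
    for r in bundle.results:
        raw = np.abs(r.shap_values).mean(axis=(0, 2))  # (n_features,)
        lo, hi = raw.min(), raw.max()
        if hi - lo < 1e-300:
            warnings.warn(
                f"({r.algorithm}, fold {r.fold}): all-zero SHAP importances; normalized to zeros"
            )
            per_fold.append(np.zeros_like(raw))
        else:
            per_fold.append((raw - lo) / (hi - lo))
    consensus = np.mean(per_fold, axis=0)
    order = np.argsort(-consensus, kind="stable")
    ranks = np.empty(len(consensus), dtype=int)
    ranks[order] = np.arange(1, len(consensus) + 1)
    return ConsensusImportance(residues=list(bundle.residues), values=consensus, ranks=ranks)


@dataclass
class DependenceProfile:
    """Normalized SHAP values of one residue grouped by amino-acid category."""

    residue: int
    class_of_interest: object
    values_by_aa: dict[str, np.ndarray]

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"amino_acid": aa, "normalized_shap": v}
            for aa, arr in sorted(self.values_by_aa.items())
            for v in arr
        ]
        return pd.DataFrame(rows, columns=["amino_acid", "normalized_shap"])

    def mean_by_aa(self) -> pd.Series:
        return pd.Series({aa: float(np.mean(v)) for aa, v in self.values_by_aa.items()})


def shap_dependence(
    bundle: TrainedModelBundle,
    residue: int,
    class_of_interest,
) -> DependenceProfile:
    """Pool fold-normalized SHAP values for one residue across all models.

    Within each (algorithm, fold) the class-specific SHAP matrix is divided
    by its maximum absolute entry (to [-1, 1], sign preserved); the residue's
    column is then grouped by the amino acid each held-out row carries there.
    """
    if residue not in bundle.residues:
        raise LookupError_(f"residue {residue} not among retained features")
    j = bundle.residues.index(residue)
    k = bundle.class_index(class_of_interest)
    letters = bundle.feature_letters[residue].to_numpy()
    pooled: dict[str, list[float]] = {}
    for r in bundle.results:
        mat = r.shap_values[:, :, k]
        denom = np.abs(mat).max()
        normalized = mat[:, j] / denom if denom > 0 else np.zeros(mat.shape[0])
        for row_pos, v in zip(r.test_indices, normalized):
            pooled.setdefault(str(letters[row_pos]), []).append(float(v))
    return DependenceProfile(
        residue=residue,
        class_of_interest=class_of_interest,
        values_by_aa={aa: np.array(v) for aa, v in pooled.items()},
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class MetricsReport:
    """Accuracy, multiclass MCC (R_K), macro-F1 and the confusion matrix."""

    accuracy: float
    mcc: float | None
    macro_f1: float
    confusion: pd.DataFrame  # rows: observed, columns: predicted


def confusion_matrix_counts(y_pred, y_true, classes) -> pd.DataFrame:
    classes = list(classes)
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        mat.loc[t, p] += 1
    return mat


def mcc_from_confusion(confusion: np.ndarray) -> float | None:
    """Gorodkin's R_K generalization of the Matthews correlation coefficient.

    Reduces to the familiar binary formula for a 2x2 matrix.  Undefined
    (None) when either marginal is concentrated in a single class.
    """
    c = np.asarray(confusion, dtype=float)
    s = c.sum()
    trace = np.trace(c)
    t_k = c.sum(axis=1)  # observed counts
    p_k = c.sum(axis=0)  # predicted counts
    cov_tp = trace * s - t_k @ p_k
    cov_tt = s**2 - t_k @ t_k
    cov_pp = s**2 - p_k @ p_k
    if cov_tt == 0 or cov_pp == 0:
        return None
    return float(cov_tp / np.sqrt(cov_tt * cov_pp))


def macro_f1_from_confusion(confusion: np.ndarray) -> float:
    """Unweighted mean of per-class F1 (classes absent everywhere score 0)."""
    c = np.asarray(confusion, dtype=float)
    f1s = []
    for k in range(c.shape[0]):
        tp = c[k, k]
        fp = c[:, k].sum() - tp
        fn = c[k, :].sum() - tp
        denom = 2 * tp + fp + fn
        f1s.append(0.0 if denom == 0 else 2 * tp / denom)
    return float(np.mean(f1s))


def evaluate_predictions(y_pred, y_true, classes=None) -> MetricsReport:
    """Score predictions: accuracy, multiclass MCC, macro-F1, confusion matrix."""
    y_pred, y_true = np.asarray(y_pred), np.asarray(y_true)
    if len(y_pred) != len(y_true):
        raise DomainError("prediction and observation vectors differ in length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    confusion = confusion_matrix_counts(y_pred, y_true, classes)
    mcc = mcc_from_confusion(confusion.to_numpy())
    if mcc is None:
        warnings.warn("MCC undefined (single-class marginal); reported as missing")
    return MetricsReport(
        accuracy=float(np.mean(y_pred == y_true)),
        mcc=mcc,
        macro_f1=macro_f1_from_confusion(confusion.to_numpy()),
        confusion=confusion,
    )
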