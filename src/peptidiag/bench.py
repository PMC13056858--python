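"""Eight-classifier diagnostic bench: stratified 8:2 split, training,
multi-metric held-out evaluation, cross-validated ROC bands, and the
dimensionality reductions used for visual QC.

The bench follows a model/results idiom: :class:`DiagnosticBench` is built
from a :class:`~peptidiag.peaks.FeatureMatrix`, its :meth:`fit` trains every
configured family on the training partition only, and the returned
:class:`BenchResults` carries the fitted models, held-out metrics, confusion
matrices and cross-validation AUC spread, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.decomposition import PCA, KernelPCA
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from lightgbm import LGBMClassifier
from xgboost import XGBClassifier

from .peaks import FeatureMatrix

__all__ = [
    "FAMILIES",
    "TREE_FAMILIES",
    "ModelSpec",
    "SplitIndices",
    "stratified_split",
    "default_specs",
    "make_estimator",
    "DiagnosticBench",
    "BenchResults",
    "crossval_roc",
    "reduce_dimensions",
]

#: the eight classifier families of the bench
FAMILIES = (
    "SVM",
    "KNN",
    "XGBoost",
    "AdaBoost",
    "LGBM",
    "GaussianNB",
    "DecisionTree",
    "RandomForest",
)

#: families whose per-feature impurity importances are defined
TREE_FAMILIES = ("XGBoost", "AdaBoost", "LGBM", "DecisionTree", "RandomForest")

#: scale-sensitive families that get a train-fitted z-score step
SCALED_FAMILIES = ("SVM", "KNN")

POSITIVE_LABEL = "TC"


@dataclass
class ModelSpec:
    family: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")


@dataclass
class SplitIndices:
    train_ids: list[str]
    test_ids: list[str]
    seed: int


def default_specs(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(family=f, seed=seed) for f in FAMILIES]


def make_estimator(spec: ModelSpec):
    """Instantiate the sklearn-compatible estimator for a family.

    Hyperparameters default to each library's conventional defaults with a
    fixed seed; SVM and KNN are wrapped with a train-fitted z-score scaler
    (tree families consume raw areas).  Every estimator exposes
    ``predict_proba``.
    """
    f, hp, seed = spec.family, dict(spec.hyperparams), spec.seed
    if f == "SVM":
        est = SVC(probability=True, random_state=seed, **hp)
    elif f == "KNN":
        est = KNeighborsClassifier(**hp)
    elif f == "XGBoost":
        est = XGBClassifier(random_state=seed, eval_metric="logloss", n_jobs=1, **hp)
    elif f == "AdaBoost":
        est = AdaBoostClassifier(random_state=seed, **hp)
    elif f == "LGBM":
        est = LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1, **hp)
    elif f == "GaussianNB":
        est = GaussianNB(**hp)
    elif f == "DecisionTree":
        est = DecisionTreeClassifier(random_state=seed, **hp)
    elif f == "RandomForest":
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(f)
    if f in SCALED_FAMILIES:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def stratified_split(labels: pd.Series, train_frac: float = 0.8, seed: int = 0) -> SplitIndices:
    """Per-class random 80/20 partition (banker's rounding of test counts)."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    labels = pd.Series(labels)
    if labels.nunique() < 2:
        raise ValueError("stratified split needs both classes present")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls, grp in labels.groupby(labels, sort=True):
        ids = np.array(grp.index)
        if len(ids) == 0:
            raise ValueError(f"class {cls!r} has no samples")
        n_test = round(len(ids) * (1.0 - train_frac))
        perm = rng.permutation(len(ids))
        test_ids.extend(ids[perm[:n_test]])
        train_ids.extend(ids[perm[n_test:]])
    return SplitIndices(train_ids=sorted(train_ids), test_ids=sorted(test_ids), seed=seed)


def _xy(m: FeatureMatrix, ids: list[str]):
    X = m.values.loc[ids].to_numpy()
    y = (m.labels.loc[ids] == POSITIVE_LABEL).astype(int).to_numpy()
    return X, y


class DiagnosticBench:
    """The eight-family diagnostic model bench over a feature matrix.

    Parameters
    ----------
    m
        Labelled feature matrix (samples x aligned peaks).
    specs
        Model specifications; defaults to all eight families at library
        defaults with the given seed.
    seed
        Seed for the default specs and the internal CV folds.
    """

    def __init__(self, m: FeatureMatrix, specs: list[ModelSpec] | None = None, seed: int = 0):
        if m.labels.empty:
            raise ValueError("feature matrix carries no labels")
        if not np.all(np.isfinite(m.values.to_numpy())):
            raise ValueError("feature matrix contains non-finite values")
        self.m = m
        self.specs = specs if specs is not None else default_specs(seed)
        self.seed = seed

    def fit(self, split: SplitIndices | None = None, cv_folds: int = 5) -> "BenchResults":
        """Train every family on the training partition and evaluate on the
        held-out test partition; CV AUC spread is computed on the training
        partition only."""
        split = split or stratified_split(self.m.labels, seed=self.seed)
        Xtr, ytr = _xy(self.m, split.train_ids)
        if len(np.unique(ytr)) < 2 or len(ytr) < 2:
            raise ValueError("training partition is degenerate")
        models: dict[str, object] = {}
        for spec in self.specs:
            est = make_estimator(spec)
            models[spec.family] = est.fit(Xtr, ytr)
        return BenchResults(bench=self, split=split, models=models, cv_folds=cv_folds)


class BenchResults:
    """Fitted bench: held-out metrics, confusions, CV AUC bands."""

    def __init__(self, bench: DiagnosticBench, split: SplitIndices,
                 models: dict[str, object], cv_folds: int = 5):
        self.bench = bench
        self.split = split
        self.models = models
        self.cv_folds = cv_folds
        self._metrics: pd.DataFrame | None = None
        self.confusions: dict[str, np.ndarray] = {}
        self.cv_aucs: dict[str, np.ndarray] = {}

    def predict_proba(self, family: str, ids: list[str] | None = None) -> np.ndarray:
        ids = ids if ids is not None else self.split.test_ids
        X = self.bench.m.values.loc[ids].to_numpy()
        return self.models[family].predict_proba(X)[:, 1]

    @property
    def metrics(self) -> pd.DataFrame:
        if self._metrics is None:
            self._metrics = self._evaluate()
        return self._metrics

    def _evaluate(self) -> pd.DataFrame:
        m, split = self.bench.m, self.split
        Xte, yte = _xy(m, split.test_ids)
        if len(np.unique(yte)) < 2:
            raise ValueError("test partition contains a single class; AUC undefined")
        rows = []
        for fam, model in self.models.items():
            p = model.predict_proba(Xte)[:, 1]
            pred = (p >= 0.5).astype(int)
            self.confusions[fam] = confusion_matrix(yte, pred)
            cv = self._cv_auc(fam)
            rows.append({
                "family": fam,
                "auc": roc_auc_score(yte, p),
                "accuracy": accuracy_score(yte, pred),
                "precision": precision_score(yte, pred, zero_division=0),
                "recall": recall_score(yte, pred, zero_division=0),
                "f1": f1_score(yte, pred, zero_division=0),
                "mean_average_precision": average_precision_score(yte, p),
                "auc_cv_mean": cv.mean(),
                "auc_cv_sd": cv.std(ddof=0),
            })
        return pd.DataFrame(rows).set_index("family")

    def _cv_auc(self, family: str) -> np.ndarray:
        if family not in self.cv_aucs:
            spec = next(s for s in self.bench.specs if s.family == family)
            _, _, aucs = crossval_roc(
                spec, self.bench.m, self.split, k=self.cv_folds, seed=self.split.seed
            )
            self.cv_aucs[family] = aucs
        return self.cv_aucs[family]

    def summary(self) -> str:
        """Human-readable metrics table, AUC formatted as mean ± sd over CV."""
        df = self.metrics
        lines = [
            f"{'family':<14}{'AUC':>6}{'CV AUC':>14}{'acc':>7}{'prec':>7}"
            f"{'recall':>8}{'F1':>7}{'mAP':>7}",
        ]
        for fam, r in df.iterrows():
            lines.append(
                f"{fam:<14}{r.auc:>6.3f}"
                f"{r.auc_cv_mean:>8.2f} ± {r.auc_cv_sd:<4.2f}"
                f"{r.accuracy:>6.3f}{r.precision:>7.3f}{r.recall:>8.3f}"
                f"{r.f1:>7.3f}{r.mean_average_precision:>7.3f}"
            )
        return "\n".join(lines)


def crossval_roc(
    spec: ModelSpec,
    m: FeatureMatrix,
    split: SplitIndices | None = None,
    k: int = 5,
    seed: int = 0,
    fpr_grid: np.ndarray | None = None,
):
    """Stratified k-fold ROC on the training partition.

    Returns ``(fpr_grid, mean_tpr, fold_aucs)``; the mean curve is the
    fold-wise TPR interpolated on a common FPR grid.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    ids = split.train_ids if split is not None else list(m.values.index)
    X, y = _xy(m, ids)
    counts = np.bincount(y)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class count ({counts.min()})")
    grid = fpr_grid if fpr_grid is not None else np.linspace(0.0, 1.0, 101)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    tprs, aucs = [], []
    for tr, te in skf.split(X, y):
        est = make_estimator(spec)
        est.fit(X[tr], y[tr])
        p = est.predict_proba(X[te])[:, 1]
        aucs.append(roc_auc_score(y[te], p))
        fpr, tpr, _ = roc_curve(y[te], p)
        t = np.interp(grid, fpr, tpr)
        t[0] = 0.0
        tprs.append(t)
    return grid, np.mean(tprs, axis=0), np.array(aucs)


def reduce_dimensions(
    m: FeatureMatrix, method: str = "PCA", dims: int = 2, seed: int = 0
) -> np.ndarray:
    """2-D/3-D coordinates for visualization (PCA deterministic; KPCA and
    t-SNE seeded).  Features are z-scored first."""
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    X = m.values.to_numpy()
    if X.shape[0] < dims + 1:
        raise ValueError("need at least dims + 1 samples")
    X = StandardScaler().fit_transform(X)
    if method == "PCA":
        return PCA(n_components=dims).fit_transform(X)
    if method == "KPCA":
        return KernelPCA(n_components=dims, kernel="rbf", random_state=seed).fit_transform(X)
    if method == "t-SNE":
        per = min(30.0, (X.shape[0] - 1) / 3.0)
        return TSNE(n_components=dims, random_state=seed, perplexity=per).fit_transform(X)
    raise ValueError(f"unknown reduction method {method!r}")
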