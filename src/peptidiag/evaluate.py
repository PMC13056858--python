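"""Diagnostic evaluation machinery: simplified-model rebuild on the core
features, single-marker ROC, decision-curve analysis (net benefit), and the
unsupervised clustering / UMAP cross-check.

Decision-curve analysis scores a probabilistic classifier by its clinical
net benefit over a grid of threshold probabilities pt:

    NB(pt) = TP/N - (FP/N) * pt / (1 - pt)

compared against the treat-all policy (NB = prevalence - (1 - prevalence) *
pt/(1-pt)) and treat-none (NB = 0).  The summary "area" is the trapezoidal
integral of NB over the threshold grid, negative stretches included as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import Birch, BisectingKMeans
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from .bench import POSITIVE_LABEL, DiagnosticBench, SplitIndices
from .explain import CoreFeatureSet
from .peaks import FeatureMatrix

__all__ = [
    "NetBenefitCurve",
    "dca_curve",
    "single_feature_auc",
    "SingleFeatureROC",
    "rebuild_on_core",
    "ClusterResult",
    "cluster_and_embed",
]

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.01, 1.00, 0.01), 10)


@dataclass
class NetBenefitCurve:
    thresholds: np.ndarray
    nb: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    prevalence: float

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.nb, self.thresholds))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pt": self.thresholds,
                "nb_model": self.nb,
                "nb_all": self.nb_all,
                "nb_none": self.nb_none,
            }
        )


def dca_curve(
    probabilities: np.ndarray,
    labels,
    grid: np.ndarray | None = None,
) -> NetBenefitCurve:
    """Net-benefit curve of a probabilistic classifier.

    ``labels`` may be "TC"/"HC" strings or 0/1; prevalence is taken from the
    evaluated set itself.  Ties at the threshold count as positive calls.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        y = (y == POSITIVE_LABEL).astype(int)
    y = y.astype(int)
    grid = DEFAULT_THRESHOLD_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("threshold grid must lie strictly inside (0, 1)")
    n = len(y)
    prevalence = float(y.mean())
    pos = p[:, None] >= grid[None, :]
    tp = (pos & (y == 1)[:, None]).sum(axis=0) / n
    fp = (pos & (y == 0)[:, None]).sum(axis=0) / n
    odds = grid / (1.0 - grid)
    nb = tp - fp * odds
    nb_all = prevalence - (1.0 - prevalence) * odds
    return NetBenefitCurve(
        thresholds=grid, nb=nb, nb_all=nb_all, nb_none=np.zeros_like(grid),
        prevalence=prevalence,
    )


@dataclass
class SingleFeatureROC:
    auc: float
    flipped: bool
    degenerate: bool


def single_feature_auc(feature_values, labels) -> SingleFeatureROC:
    """Orientation-corrected empirical AUC of one feature used as a score.

    Equals the Mann-Whitney U statistic divided by n_TC * n_HC.  Features
    anticorrelated with disease are flipped (AUC -> 1 - AUC, flagged);
    constant features are flagged degenerate with AUC 0.5.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        y = (y == POSITIVE_LABEL).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.all(x == x[0]):
        return SingleFeatureROC(auc=0.5, flipped=False, degenerate=True)
    auc = float(roc_auc_score(y, x))
    if auc < 0.5:
        return SingleFeatureROC(auc=1.0 - auc, flipped=True, degenerate=False)
    return SingleFeatureROC(auc=auc, flipped=False, degenerate=False)


def rebuild_on_core(
    m: FeatureMatrix,
    core: CoreFeatureSet,
    specs=None,
    split: SplitIndices | None = None,
    seed: int = 0,
    cv_folds: int = 5,
):
    """Retrain the whole bench on the shared core features only.

    Returns ``(results, dca)`` where ``results`` is the
    :class:`~peptidiag.bench.BenchResults` of the restricted bench on the
    SAME split, and ``dca`` maps family -> :class:`NetBenefitCurve` on the
    held-out test set.
    """
    if not core.shared:
        raise ValueError("core feature set is empty")
    sub = m.restrict(core.shared)
    bench = DiagnosticBench(sub, specs=specs, seed=seed)
    results = bench.fit(split=split, cv_folds=cv_folds)
    yte = sub.labels.loc[results.split.test_ids]
    dca = {
        fam: dca_curve(results.predict_proba(fam), yte)
        for fam in results.models
    }
    return results, dca


@dataclass
class ClusterResult:
    algorithm: str
    assignments: np.ndarray
    ari_vs_diagnosis: float
    embedding: np.ndarray | None = None


def cluster_and_embed(
    m: FeatureMatrix,
    features=None,
    k: int = 2,
    seed: int = 0,
    compute_embedding: bool = True,
) -> dict[str, ClusterResult]:
    """Unsupervised check: bisecting k-means and Birch on the (optionally
    restricted) matrix, scored by adjusted Rand index against the diagnosis
    labels, with an optional 2-D UMAP embedding."""
    if k < 2:
        raise ValueError("k must be at least 2")
    sub = m.restrict(features) if features is not None else m
    X = np.log1p(sub.values.to_numpy())
    if X.shape[0] <= k:
        raise ValueError("need more samples than clusters")
    y = sub.labels.to_numpy() if not sub.labels.empty else None
    emb = None
    if compute_embedding:
        import umap  # deferred: numba compilation is costly

        emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(X)
    out: dict[str, ClusterResult] = {}
    algos = {
        "bisecting_kmeans": BisectingKMeans(n_clusters=k, random_state=seed),
        "birch": Birch(n_clusters=k),
    }
    for name, algo in algos.items():
        labels_ = algo.fit_predict(X)
        ari = adjusted_rand_score(y, labels_) if y is not None else np.nan
        out[name] = ClusterResult(
            algorithm=name, assignments=labels_, ari_vs_diagnosis=float(ari),
            embedding=emb,
        )
    return out
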