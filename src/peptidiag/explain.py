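"""Feature-importance analysis and core-biomarker selection.

Three importance methods are computed per model family and aggregated by
mean rank across families:

* **Gini** — normalized impurity-decrease importances of the tree
  ensembles.
* **Shapley** — exact per-instance additive attributions from the tree
  libraries' own path-dependent algorithms (XGBoost ``pred_contribs``,
  LightGBM ``pred_contrib``), or a seeded permutation-sampling estimator
  for arbitrary probability classifiers.  Both satisfy local accuracy:
  per-instance attributions plus the expected value reproduce the model
  output (raw margin for the tree libraries, positive-class probability
  for the sampler) to machine precision.
* **LIME-style local surrogates** — per instance, a locality-weighted
  ridge regression fitted to the model's probabilities on seeded Gaussian
  perturbations; importance is the mean absolute surrogate weight.

The diagnostic core-feature set is the intersection of the Shapley and
LIME top-k lists (k = 20 by default), mirroring how global and local
explanations are cross-validated against each other.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.pipeline import Pipeline

from .bench import TREE_FAMILIES

logger = logging.getLogger(__name__)

__all__ = [
    "gini_importance",
    "shap_importance",
    "sampling_shapley",
    "lime_importance",
    "aggregate_mean_rank",
    "CoreFeatureSet",
    "select_core_features",
]


def _final_estimator(model):
    return model.steps[-1][1] if isinstance(model, Pipeline) else model


def gini_importance(tree_models: dict[str, object], feature_names) -> pd.DataFrame:
    """Impurity-decrease importances per tree family, each normalized to sum
    one, with a cross-model mean column."""
    feature_names = list(feature_names)
    cols = {}
    for fam, model in tree_models.items():
        est = _final_estimator(model)
        if fam not in TREE_FAMILIES or not hasattr(est, "feature_importances_"):
            raise ValueError(f"{fam!r} is not a tree-ensemble family")
        imp = np.asarray(est.feature_importances_, dtype=float)
        total = imp.sum()
        cols[fam] = imp / total if total > 0 else imp
    df = pd.DataFrame(cols, index=feature_names)
    df["mean"] = df.mean(axis=1)
    return df


def _tree_contribs(model, X: np.ndarray):
    """Native per-instance additive contributions for XGBoost / LightGBM.

    Returns ``(phi, expected_value)`` with ``phi`` of shape (n, p); the sum
    of a row plus ``expected_value`` equals the model's raw margin for that
    instance.  Returns None when the model has no native attribution.
    """
    est = _final_estimator(model)
    name = type(est).__name__
    if name == "XGBClassifier":
        import xgboost as xgb

        contribs = est.get_booster().predict(xgb.DMatrix(X), pred_contribs=True)
        return contribs[:, :-1], float(contribs[0, -1])
    if name == "LGBMClassifier":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            contribs = est.predict(X, pred_contrib=True)
        return contribs[:, :-1], float(contribs[0, -1])
    return None


def sampling_shapley(
    predict_fn,
    background: np.ndarray,
    eval_rows: np.ndarray,
    n_permutations: int = 32,
    seed: int = 0,
):
    """Permutation-sampling Shapley attribution for any scalar model output.

    For each evaluated instance x, features are switched one at a time from
    a background row b to x along random permutations; the averaged marginal
    contributions are unbiased Shapley-value estimates.  Because each
    permutation's contributions telescope to ``f(x) - f(b)``, the estimates
    satisfy local accuracy exactly: ``sum(phi) = f(x) - mean_b f(b)``.

    Returns ``(phi, expected_value)`` with ``phi`` of shape
    ``(len(eval_rows), p)``.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    eval_rows = np.atleast_2d(np.asarray(eval_rows, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background set is empty")
    rng = np.random.default_rng(seed)
    n_bg, p = background.shape
    expected = float(np.mean(predict_fn(background)))
    phi = np.zeros((eval_rows.shape[0], p))
    for r, x in enumerate(eval_rows):
        acc = np.zeros(p)
        for _ in range(n_permutations):
            perm = rng.permutation(p)
            b = background[rng.integers(n_bg)]
            # states: z_0 = b, z_k = b with perm[:k] switched to x
            states = np.tile(b, (p + 1, 1))
            for k, j in enumerate(perm):
                states[k + 1 :, j] = x[j]
            preds = predict_fn(states)
            acc[perm] += np.diff(preds)
        phi[r] = acc / n_permutations
    # local accuracy correction for the background average (telescoping is
    # exact per permutation; averaging over sampled b leaves a residual only
    # through which b were drawn — spread it uniformly)
    fx = predict_fn(eval_rows)
    resid = fx - expected - phi.sum(axis=1)
    phi += resid[:, None] / p
    return phi, expected


def shap_importance(
    model,
    background: np.ndarray,
    eval_rows: np.ndarray,
    n_permutations: int = 32,
    seed: int = 0,
) -> tuple[pd.Series, np.ndarray, float]:
    """Global Shapley summary: mean |attribution| per feature.

    Uses the exact native tree attribution when the model provides one,
    otherwise the seeded permutation-sampling estimator on the positive-class
    probability with a background of at most 100 rows.

    Returns ``(mean_abs, phi, expected_value)``.
    """
    background = np.atleast_2d(background)
    if background.shape[0] == 0:
        raise ValueError("background set is empty")
    native = _tree_contribs(model, np.atleast_2d(eval_rows))
    if native is not None:
        phi, expected = native
    else:
        bg = background[:100]
        phi, expected = sampling_shapley(
            lambda X: model.predict_proba(X)[:, 1], bg, eval_rows,
            n_permutations=n_permutations, seed=seed,
        )
    return pd.Series(np.abs(phi).mean(axis=0)), phi, expected


def lime_importance(
    model,
    eval_rows: np.ndarray,
    train_scale: np.ndarray,
    n_perturb: int = 1000,
    seed: int = 0,
    kernel_width: float | None = None,
    ridge_alpha: float = 1.0,
    target: str = "logit",
) -> pd.Series:
    """Aggregated local-surrogate importance.

    For each evaluated instance, ``n_perturb`` Gaussian perturbations
    (per-feature scale = the training-data standard deviations) are scored
    by the model; a ridge regression weighted by an exponential locality
    kernel on standardized distance is fitted to the model output.  The
    importance of a feature is the mean absolute surrogate coefficient (on
    the standardized scale) across instances.

    ``target`` selects what the surrogate explains: the positive-class
    log-odds (default — probabilities of a well-fitted diagnostic model
    saturate near 0/1, where they carry almost no local gradient) or the
    raw ``"probability"``.
    """
    eval_rows = np.atleast_2d(np.asarray(eval_rows, dtype=float))
    if n_perturb < 100:
        raise ValueError("n_perturb must be at least 100")
    if target not in ("logit", "probability"):
        raise ValueError(f"unknown surrogate target {target!r}")
    rng = np.random.default_rng(seed)
    scale = np.asarray(train_scale, dtype=float).copy()
    scale[scale <= 0] = 1.0  # zero-variance features perturb trivially
    p = eval_rows.shape[1]
    kw = kernel_width if kernel_width is not None else 0.75 * np.sqrt(p)
    total = np.zeros(p)
    for x in eval_rows:
        z = rng.normal(0.0, 1.0, (n_perturb, p))  # standardized offsets
        X = x + z * scale
        y = model.predict_proba(X)[:, 1]
        if target == "logit":
            y = np.clip(y, 1e-6, 1 - 1e-6)
            y = np.log(y / (1.0 - y))
        d2 = (z**2).sum(axis=1)
        w = np.exp(-d2 / kw**2)
        reg = Ridge(alpha=ridge_alpha)
        reg.fit(z, y, sample_weight=w)
        total += np.abs(reg.coef_)
    return pd.Series(total / eval_rows.shape[0])


def aggregate_mean_rank(scores: pd.DataFrame) -> pd.Series:
    """Mean rank across model families (rank 1 = highest score); lower is
    more important."""
    ranks = scores.rank(ascending=False, axis=0)
    return ranks.mean(axis=1).sort_values()


@dataclass
class CoreFeatureSet:
    """Venn decomposition of the Shapley and LIME top-k feature lists."""

    shap_top: list[float]
    lime_top: list[float]

    @property
    def shared(self) -> list[float]:
        return sorted(set(self.shap_top) & set(self.lime_top))

    @property
    def shap_unique(self) -> list[float]:
        return sorted(set(self.shap_top) - set(self.lime_top))

    @property
    def lime_unique(self) -> list[float]:
        return sorted(set(self.lime_top) - set(self.shap_top))

    def venn_counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "shap_unique": len(self.shap_unique),
            "lime_unique": len(self.lime_unique),
        }

    def to_dict(self) -> dict:
        return {
            "shap_top": list(self.shap_top),
            "lime_top": list(self.lime_top),
            "shared": self.shared,
            "shap_unique": self.shap_unique,
            "lime_unique": self.lime_unique,
            "venn": self.venn_counts(),
        }


def select_core_features(
    shap_scores: pd.DataFrame | pd.Series,
    lime_scores: pd.DataFrame | pd.Series,
    k: int = 20,
) -> CoreFeatureSet:
    """Top-k per method (by mean rank across families for DataFrames, by
    score for Series), intersected into the core feature set."""

    def top(scores) -> list[float]:
        if isinstance(scores, pd.DataFrame):
            order = aggregate_mean_rank(scores).index
        else:
            order = scores.sort_values(ascending=False).index
        kk = min(k, len(order))
        if kk < k:
            logger.warning("k=%d exceeds feature count %d; clipped", k, len(order))
        return [float(f) for f in order[:kk]]

    if list(np.asarray(shap_scores.index)) != list(np.asarray(lime_scores.index)):
        raise ValueError("Shapley and LIME tables must cover the same features")
    return CoreFeatureSet(shap_top=top(shap_scores), lime_top=top(lime_scores))
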