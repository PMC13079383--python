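"""Repeated nested stratified cross-validation with a permutation null.

The estimator of interest is the out-of-sample discriminability of
cases from controls given the AU feature matrix.  The procedure:

* outer stratified k-fold (repeated) estimates generalization;
* univariate feature selection (Welch two-sample test, keep p < alpha)
  runs on the outer-training rows only — never on held-out rows — with an
  all-features fallback when nothing is selected;
* an inner stratified k-fold grid search picks hyperparameters by mean
  inner AUC; the winning model is refit on the whole outer-training set
  and evaluated once on the held-out fold;
* significance comes from a permutation test that relabels participants
  *before* feature selection and reruns the entire pipeline, so the null
  distribution includes selection-induced optimism.

Exposed in statsmodels style: ``NestedCVClassifier(matrix, config).fit()``
returns a :class:`NestedCVResults` carrying fold metrics, selection
frequencies and a ``summary()``; ``results.permutation_test()`` adds the
null distribution and p-values.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._seeds import child_int, stream
from .features import FeatureMatrix

METRIC_NAMES = ("accuracy", "auc", "sensitivity", "specificity", "f1")


def default_grid(model_family: str) -> dict[str, list]:
    if model_family == "random_forest":
        return {"n_estimators": [200], "max_depth": [None, 5], "max_features": ["sqrt", 0.33]}
    if model_family == "svm":
        return {"kernel": ["linear", "rbf"], "C": [0.1, 1.0, 10.0]}
    raise ValueError(f"unknown model family: {model_family}")


@dataclass
class CVConfig:
    """Cross-validation design: 5 outer x 5 inner folds, 5 repeats and 100
    label permutations by default, mirroring the study protocol."""

    n_outer: int = 5
    n_inner: int = 5
    n_repeats: int = 5
    n_permutations: int = 100
    model_family: str = "random_forest"
    hyperparameter_grid: dict[str, list] | None = None
    selection_alpha: float = 0.05
    seed: int = 0
    positive_class: str = "case"
    class_weight: str | None = None
    #: permute the full repeated procedure (True) or a single repetition.
    permute_full_repeats: bool = True

    def __post_init__(self) -> None:
        if self.n_outer < 2 or self.n_inner < 2:
            raise ValueError("folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0.0 < self.selection_alpha <= 1.0:
            raise ValueError("selection_alpha must be in (0, 1]")
        if self.model_family not in ("random_forest", "svm"):
            raise ValueError(f"unknown model family: {self.model_family}")

    @property
    def grid(self) -> list[dict]:
        g = self.hyperparameter_grid or default_grid(self.model_family)
        if not g:
            raise ValueError("hyperparameter grid must be nonempty")
        keys = sorted(g)
        return [dict(zip(keys, combo)) for combo in itertools.product(*(g[k] for k in keys))]


@dataclass
class FoldResult:
    repeat: int
    fold: int
    selected_features: list[str]
    fallback_used: bool
    hyperparameters: dict
    metrics: dict[str, float]


@dataclass
class PermutationResult:
    """Observed statistics, their permutation nulls and add-one p-values."""

    observed: dict[str, float]
    null: dict[str, np.ndarray]
    n_permutations: int

    @property
    def p_values(self) -> dict[str, float]:
        return {
            k: permutation_pvalue(self.observed[k], self.null[k]) for k in self.observed
        }

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p_values": self.p_values,
            "n_permutations": self.n_permutations,
            "null": {k: list(map(float, v)) for k, v in self.null.items()},
        }


def permutation_pvalue(observed: float, null: np.ndarray) -> float:
    """Add-one permutation p: (1 + #{null >= observed}) / (B + 1)."""
    null = np.asarray(null, float)
    if null.size < 1:
        raise ValueError("need at least one permutation")
    return float((1 + np.sum(null >= observed)) / (null.size + 1))


# ---------------------------------------------------------------------------
# core operations


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint stratified folds; per-fold class counts within 1 of
    exact proportionality.  Deterministic given seed."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) smaller than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed & 0x7FFFFFFF)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def select_features(
    X: np.ndarray, y_case: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, bool]:
    """Training-only univariate selection: Welch two-sample test per
    feature, keep p < alpha.  Constant features have an undefined
    statistic and are never selected.  Empty selection falls back to all
    features (``fallback=True``)."""
    X = np.asarray(X, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(X[y_case], X[~y_case], equal_var=False, axis=0)
    keep = np.where(np.nan_to_num(p, nan=1.0) < alpha)[0]
    if keep.size == 0:
        return np.arange(X.shape[1]), True
    return keep, False


def _make_model(config: CVConfig, params: dict, seed: int):
    if config.model_family == "random_forest":
        return RandomForestClassifier(
            random_state=seed, class_weight=config.class_weight, n_jobs=1, **params
        )
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(class_weight=config.class_weight, gamma="scale", **params)),
        ]
    )


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous case-score for AUC (probability or decision function)."""
    if hasattr(model, "predict_proba"):
        cols = list(model.classes_)
        return model.predict_proba(X)[:, cols.index(True)]
    df = model.decision_function(X)
    return df if model.classes_[1] else -df


def _fold_metrics(model, X_te: np.ndarray, y_te: np.ndarray) -> dict[str, float]:
    pred = model.predict(X_te)
    tp = int(np.sum(pred & y_te))
    tn = int(np.sum(~pred & ~y_te))
    fp = int(np.sum(pred & ~y_te))
    fn = int(np.sum(~pred & y_te))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return {
        "accuracy": (tp + tn) / len(y_te),
        "auc": float(roc_auc_score(y_te, _scores(model, X_te))),
        "sensitivity": sens,
        "specificity": spec,
        "f1": f1,
    }


def fit_outer_fold(
    X: np.ndarray,
    y_case: np.ndarray,
    train_idx: np.ndarray,
    config: CVConfig,
    fold_seed: int,
):
    """Select features and tune/refit the model using training rows only.

    Returns (selected indices, fallback flag, best params, fitted model).
    Held-out rows play no role here — the leakage guard asserts exactly
    this by mutating test labels and recomparing.
    """
    X_tr, y_tr = X[train_idx], y_case[train_idx]
    sel, fallback = select_features(X_tr, y_tr, config.selection_alpha)
    grid = config.grid
    if len(grid) == 1:
        best = grid[0]
    else:
        inner = stratified_folds(y_tr, config.n_inner, fold_seed ^ 0x5EED)
        best, best_auc = None, -np.inf
        for params in grid:
            aucs = []
            for itr, ite in inner:
                m = _make_model(config, params, fold_seed)
                m.fit(X_tr[itr][:, sel], y_tr[itr])
                aucs.append(roc_auc_score(y_tr[ite], _scores(m, X_tr[ite][:, sel])))
            mean_auc = float(np.mean(aucs))
            if mean_auc > best_auc:  # ties keep the first (deterministic) combo
                best, best_auc = params, mean_auc
    model = _make_model(config, best, fold_seed)
    model.fit(X_tr[:, sel], y_tr)
    return sel, fallback, best, model


@dataclass
class NestedCVResults:
    """Aggregated outer-fold metrics, selection frequencies, provenance."""

    config: CVConfig
    feature_names: list[str]
    fold_results: list[FoldResult]
    permutation: PermutationResult | None = None

    @property
    def metrics_frame(self) -> pd.DataFrame:
        rows = [
            {"repeat": f.repeat, "fold": f.fold, "fallback": f.fallback_used, **f.metrics}
            for f in self.fold_results
        ]
        return pd.DataFrame(rows)

    @property
    def mean_metrics(self) -> dict[str, float]:
        df = self.metrics_frame
        return {m: float(df[m].mean()) for m in METRIC_NAMES}

    @property
    def sd_metrics(self) -> dict[str, float]:
        df = self.metrics_frame
        return {m: float(df[m].std(ddof=1)) for m in METRIC_NAMES}

    def selection_frequencies(self) -> pd.DataFrame:
        return selection_frequency_report(self.fold_results, self.feature_names)

    def summary(self) -> str:
        n_folds = len(self.fold_results)
        mean, sd = self.mean_metrics, self.sd_metrics
        lines = [
            "Nested stratified cross-validation",
            "=" * 50,
            f"model family: {self.config.model_family}",
            f"outer folds: {self.config.n_outer}  inner folds: {self.config.n_inner}"
            f"  repeats: {self.config.n_repeats}  (n folds = {n_folds})",
            "-" * 50,
        ]
        for m in METRIC_NAMES:
            lines.append(f"{m:>12s}: {mean[m]:.3f} (SD = {sd[m]:.3f})")
        if self.permutation is not None:
            lines.append("-" * 50)
            for k, p in self.permutation.p_values.items():
                lines.append(
                    f"permutation p ({k}): {p:.4f}"
                    f"  [B = {self.permutation.n_permutations}]"
                )
        top = self.selection_frequencies().head(5)
        lines.append("-" * 50)
        lines.append("top selected features (count / folds):")
        for name, row in top.iterrows():
            lines.append(f"  {name:>22s}: {int(row['count'])} / {n_folds}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "mean": self.mean_metrics,
            "sd": self.sd_metrics,
            "n_folds": len(self.fold_results),
            "permutation": None if self.permutation is None else self.permutation.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


class NestedCVClassifier:
    """Model object: a feature matrix plus a CV design, fit on demand.

    Parameters
    ----------
    matrix : FeatureMatrix
        Participants x features table with case/control labels.
    config : CVConfig
    """

    def __init__(self, matrix: FeatureMatrix, config: CVConfig | None = None):
        self.matrix = matrix
        self.config = config or CVConfig()
        self.feature_names = matrix.feature_names
        self._X = matrix.X.to_numpy(float)
        self._y = (matrix.labels == self.config.positive_class).to_numpy()
        if self._y.all() or not self._y.any():
            raise ValueError("labels must contain both classes")

    def outer_fold_plan(self, y_case: np.ndarray | None = None) -> list[tuple]:
        """(repeat, fold, train_idx, test_idx, fold_seed) for every fold."""
        y = self._y if y_case is None else y_case
        plan = []
        for rep in range(self.config.n_repeats):
            seed = child_int(self.config.seed, "outer", rep)
            for k, (tr, te) in enumerate(stratified_folds(y, self.config.n_outer, seed)):
                plan.append((rep, k, tr, te, child_int(self.config.seed, "fold", rep, k)))
        return plan

    def _run(self, y_case: np.ndarray, config: CVConfig) -> list[FoldResult]:
        folds = []
        for rep, k, tr, te, fold_seed in self.outer_fold_plan(y_case):
            if rep >= config.n_repeats:
                continue
            sel, fallback, best, model = fit_outer_fold(self._X, y_case, tr, config, fold_seed)
            metrics = _fold_metrics(model, self._X[te][:, sel], y_case[te])
            folds.append(
                FoldResult(
                    repeat=rep,
                    fold=k,
                    selected_features=[self.feature_names[j] for j in sel],
                    fallback_used=fallback,
                    hyperparameters=best,
                    metrics=metrics,
                )
            )
        return folds

    def fit(self) -> NestedCVResults:
        folds = self._run(self._y, self.config)
        return NestedCVResults(
            config=self.config, feature_names=self.feature_names, fold_results=folds
        )

    def permutation_test(
        self, results: NestedCVResults | None = None, n_permutations: int | None = None
    ) -> PermutationResult:
        """Permute labels before selection, rerun everything, add-one p.

        One permutation of the label vector per replicate, reused across
        that replicate's folds and loops.
        """
        B = n_permutations if n_permutations is not None else self.config.n_permutations
        if B < 1:
            raise ValueError("need at least one permutation")
        if results is None:
            results = self.fit()
        observed = {
            "mean_auc": results.mean_metrics["auc"],
            "mean_accuracy": results.mean_metrics["accuracy"],
        }
        null_cfg = self.config
        if not self.config.permute_full_repeats:
            null_cfg = replace(self.config, n_repeats=1)
        null = {"mean_auc": [], "mean_accuracy": []}
        for b in range(B):
            rng = stream(self.config.seed, "permutation", b)
            y_b = rng.permutation(self._y)
            folds = self._run(y_b, null_cfg)
            df = pd.DataFrame([f.metrics for f in folds])
            null["mean_auc"].append(float(df["auc"].mean()))
            null["mean_accuracy"].append(float(df["accuracy"].mean()))
        perm = PermutationResult(
            observed=observed,
            null={k: np.asarray(v) for k, v in null.items()},
            n_permutations=B,
        )
        results.permutation = perm
        return perm


def run_nested_cv(matrix: FeatureMatrix, config: CVConfig | None = None) -> NestedCVResults:
    """Functional wrapper over :class:`NestedCVClassifier`."""
    return NestedCVClassifier(matrix, config).fit()


def permutation_test(matrix: FeatureMatrix, config: CVConfig | None = None) -> NestedCVResults:
    """Fit and attach the permutation null; returns the results object."""
    clf = NestedCVClassifier(matrix, config)
    results = clf.fit()
    clf.permutation_test(results)
    return results


def selection_frequency_report(
    fold_results: list[FoldResult], feature_names: list[str]
) -> pd.DataFrame:
    """Per-feature selection counts over all folds x repeats, descending.

    A fallback fold counts every feature once.  ``always_selected`` flags
    features present in every fold.
    """
    if not fold_results:
        raise ValueError("need at least one fold result")
    counts = {name: 0 for name in feature_names}
    for f in fold_results:
        for name in f.selected_features:
            counts[name] += 1
    n_folds = len(fold_results)
    df = pd.DataFrame(
        {
            "count": pd.Series(counts),
            "frequency": pd.Series({k: v / n_folds for k, v in counts.items()}),
        }
    )
    df["always_selected"] = df["count"] == n_folds
    df.index.name = "feature"
    return df.sort_values(["count", "feature"], ascending=[False, True], kind="stable")
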