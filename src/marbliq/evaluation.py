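"""Repeated k-fold cross-validation and the classification/regression
metric suites.

Model comparison follows an internal-validation protocol suited to small
measurement tables: 7-fold cross-validation repeated 5 times (35 fitted
models), with the *same* fold assignments reused for every learner so
that differences between models are not confounded with differences
between splits. Predictor scaling is fit inside each training fold.

Classification quality is summarized per group as one-vs-rest
sensitivity, specificity and their mean (balanced accuracy), plus the
overall accuracy with a Clopper–Pearson exact 95% binomial confidence
interval and an exact binomial test against the no-information rate.
Regression quality is summarized by R², RMSE, and — for a chosen "best"
model — the predicted-vs-observed linear fit: slope and intercept with
t-based 95% confidence intervals, the residual standard error (RSE) of
that fit, and a through-origin refit when the intercept is not
significant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import models as _models
from .dataset import PREDICTOR_COLUMNS, TARGET_COLUMN, scale_center

__all__ = [
    "CVScheme",
    "ModelSpec",
    "CVResult",
    "ClassificationReport",
    "RegressionReport",
    "make_cv_scheme",
    "cross_validate",
    "classification_report",
    "regression_report",
    "variable_importance",
    "lda_spec",
    "mda_spec",
    "mlr_spec",
    "svr_spec",
]


# ---------------------------------------------------------------------------
# CV scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVScheme:
    """Shared fold assignments: ``assignments[r, i]`` is the validation
    fold index of sample ``i`` in repetition ``r``."""

    n_samples: int
    k: int
    repeats: int
    seed: int
    assignments: np.ndarray  # (repeats, n_samples) int
    stratified: bool = False

    @property
    def n_splits(self) -> int:
        return self.k * self.repeats

    def iter_splits(self):
        """Yield (repeat, fold, train_idx, val_idx) for all k × repeats splits."""
        for r in range(self.repeats):
            folds = self.assignments[r]
            for f in range(self.k):
                val = np.flatnonzero(folds == f)
                train = np.flatnonzero(folds != f)
                yield r, f, train, val


def make_cv_scheme(
    n: int, k: int = 7, repeats: int = 5, seed: int = 0, strata=None
) -> CVScheme:
    """Build a repeated k-fold partition, optionally stratified.

    Per repetition the samples are shuffled and dealt into k folds whose
    sizes differ by at most one; with ``strata`` the dealing is done
    within each stratum so every fold mirrors the group proportions as
    closely as the counts allow.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} samples")
    rng = np.random.default_rng(seed)
    assignments = np.empty((repeats, n), dtype=int)
    for r in range(repeats):
        if strata is None:
            order = rng.permutation(n)
            assignments[r, order] = np.arange(n) % k
        else:
            strata_arr = np.asarray(strata)
            offset = rng.integers(k)  # rotate so small strata do not pile on fold 0
            for s in np.unique(strata_arr):
                idx = np.flatnonzero(strata_arr == s)
                idx = rng.permutation(idx)
                assignments[r, idx] = (np.arange(idx.size) + offset) % k
                offset += idx.size
    return CVScheme(
        n_samples=n, k=k, repeats=repeats, seed=seed,
        assignments=assignments, stratified=strata is not None,
    )


# ---------------------------------------------------------------------------
# Model specs (uniform fit/predict surface over the models module)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A named learner with a uniform fit/predict surface for CV."""

    name: str
    task: str  # 'classification' | 'regression'
    fit: callable = field(repr=False)
    predict: callable = field(repr=False)
    params: dict = field(default_factory=dict)


def lda_spec(**kw) -> ModelSpec:
    return ModelSpec(
        name="LDA", task="classification",
        fit=lambda X, y: _models.fit_lda(X, y, **kw),
        predict=lambda m, X: _models.predict_lda(m, X)[0],
        params=kw,
    )


def mda_spec(subclasses_per_class: int = 3, seed: int = 0, **kw) -> ModelSpec:
    return ModelSpec(
        name="MDA", task="classification",
        fit=lambda X, y: _models.fit_mda(
            X, y, subclasses_per_class=subclasses_per_class, seed=seed, **kw
        ),
        predict=lambda m, X: _models.predict_mda(m, X)[0],
        params={"subclasses_per_class": subclasses_per_class, "seed": seed, **kw},
    )


def mlr_spec(**kw) -> ModelSpec:
    return ModelSpec(
        name="MLR", task="regression",
        fit=lambda X, y: _models.fit_mlr(X, y, **kw),
        predict=_models.predict_mlr,
        params=kw,
    )


def svr_spec(**kw) -> ModelSpec:
    return ModelSpec(
        name="SVMR-Poly", task="regression",
        fit=lambda X, y: _models.fit_svr_poly(X, y, **kw),
        predict=_models.predict_svr_poly,
        params=kw,
    )


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

@dataclass
class SplitResult:
    repeat: int
    fold: int
    val_idx: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    metrics: dict


@dataclass
class CVResult:
    model_name: str
    task: str
    splits: list
    mean: dict
    sd: dict
    n_degenerate: int
    scheme: CVScheme

    def best_split(self, metric: str | None = None) -> SplitResult:
        metric = metric or ("accuracy" if self.task == "classification" else "r2")
        scored = [s for s in self.splits if metric in s.metrics]
        return max(scored, key=lambda s: s.metrics[metric])


def _cv_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Per-split determination coefficient: squared Pearson correlation
    between observed and predicted (the convention of the R caret
    toolchain this protocol mirrors)."""
    if np.std(observed) == 0 or np.std(predicted) == 0:
        return np.nan
    return float(np.corrcoef(observed, predicted)[0, 1] ** 2)


def cross_validate(
    spec: ModelSpec,
    data: pd.DataFrame,
    scheme: CVScheme,
    predictors=PREDICTOR_COLUMNS,
    target: str = TARGET_COLUMN,
    scale: bool = True,
    global_scaling: bool = False,
) -> CVResult:
    """Fit/evaluate one learner on every split of a shared CV scheme.

    Scaling parameters are estimated on each training fold only
    (``global_scaling=True`` reproduces the laxer whole-table reading).
    Classification splits whose training folds lose an entire class are
    recorded as degenerate and excluded from the averages, with a count.
    """
    if scheme.n_samples != len(data):
        raise ValueError(
            f"scheme built for n={scheme.n_samples} but data has {len(data)} rows"
        )
    data = data.reset_index(drop=True)
    y_all = data[target].to_numpy()
    if spec.task == "classification":
        y_all = y_all.astype(object)
    all_classes = set(np.unique(y_all)) if spec.task == "classification" else None

    if scale and global_scaling:
        fm_global = scale_center(data, columns=predictors)

    splits: list[SplitResult] = []
    n_degenerate = 0
    for r, f, train_idx, val_idx in scheme.iter_splits():
        train, val = data.iloc[train_idx], data.iloc[val_idx]
        y_train, y_val = y_all[train_idx], y_all[val_idx]
        if spec.task == "classification" and set(np.unique(y_train)) != all_classes:
            n_degenerate += 1
            continue
        if scale:
            fm = fm_global if global_scaling else scale_center(train, columns=predictors)
            X_train, X_val = fm.transform(train), fm.transform(val)
        else:
            X_train = train.loc[:, list(predictors)].to_numpy(dtype=float)
            X_val = val.loc[:, list(predictors)].to_numpy(dtype=float)
        try:
            model = spec.fit(X_train, y_train)
        except ValueError:
            # e.g. an MDA class smaller than its subclass count on this fold
            n_degenerate += 1
            continue
        y_pred = np.asarray(spec.predict(model, X_val))
        if spec.task == "classification":
            metrics = {"accuracy": float(np.mean(y_pred == y_val))}
        else:
            metrics = {
                "rmse": float(np.sqrt(np.mean((y_pred - y_val) ** 2))),
            }
            r2 = _cv_r2(y_val.astype(float), y_pred.astype(float))
            if np.isfinite(r2):
                metrics["r2"] = r2
        splits.append(
            SplitResult(repeat=r, fold=f, val_idx=val_idx,
                        y_true=y_val, y_pred=y_pred, metrics=metrics)
        )

    keys = sorted({k for s in splits for k in s.metrics})
    mean = {k: float(np.mean([s.metrics[k] for s in splits if k in s.metrics])) for k in keys}
    sd = {k: float(np.std([s.metrics[k] for s in splits if k in s.metrics], ddof=1)) for k in keys}
    return CVResult(
        model_name=spec.name, task=spec.task, splits=splits,
        mean=mean, sd=sd, n_degenerate=n_degenerate, scheme=scheme,
    )


# ---------------------------------------------------------------------------
# Classification report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationReport:
    classes: tuple
    confusion: np.ndarray  # rows = truth, cols = predicted
    sensitivity: dict
    specificity: dict
    balanced_accuracy: dict
    accuracy: float
    ci_accuracy: tuple[float, float]
    no_information_rate: float
    p_value: float
    n: int
    method: str = "exact"

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "sensitivity": dict(self.sensitivity),
            "specificity": dict(self.specificity),
            "balanced_accuracy": dict(self.balanced_accuracy),
            "Accuracy": self.accuracy,
            "CI_Accuracy": list(self.ci_accuracy),
            "no_information_rate": self.no_information_rate,
            "p_value": self.p_value,
            "n": self.n,
            "method": self.method,
        }

    def to_text(self) -> str:
        lines = [
            f"Accuracy       {self.accuracy:.2f}",
            f"CI_Accuracy    [{self.ci_accuracy[0]:.2f}, {self.ci_accuracy[1]:.2f}]",
            f"p-value        {self.p_value:.3g}",
        ]
        for c in self.classes:
            lines.append(f"{c} balanced accuracy  {self.balanced_accuracy[c]:.2f}")
        return "\n".join(lines)


def classification_report(
    truth, predicted, alpha: float = 0.05, exact: bool = True
) -> ClassificationReport:
    """Confusion matrix and the one-vs-rest metric suite.

    Sensitivity of a group is the fraction of its members predicted into
    it; specificity the fraction of non-members predicted elsewhere;
    balanced accuracy their mean. The accuracy CI is Clopper–Pearson
    exact by default (``exact=False`` for the Wilson normal
    approximation) and the p-value is an exact one-sided binomial test
    of accuracy > the no-information rate (largest class share).
    """
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have the same length")
    classes = tuple(sorted(set(truth) | set(predicted)))
    if len(set(truth)) < 2:
        raise ValueError("need at least 2 classes present in truth")
    idx = {c: i for i, c in enumerate(classes)}
    n = truth.size
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, predicted):
        confusion[idx[t], idx[p]] += 1

    sens, spec, bal = {}, {}, {}
    for c in classes:
        i = idx[c]
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens[c] = tp / (tp + fn) if tp + fn else np.nan
        spec[c] = tn / (tn + fp) if tn + fp else np.nan
        bal[c] = np.nanmean([sens[c], spec[c]])

    correct = int(np.trace(confusion))
    accuracy = correct / n
    bt = stats.binomtest(correct, n)
    method = "exact" if exact else "wilson"
    ci = bt.proportion_ci(confidence_level=1 - alpha, method=method)
    nir = max(np.sum(truth == c) for c in classes) / n
    p_value = stats.binomtest(correct, n, p=nir, alternative="greater").pvalue
    return ClassificationReport(
        classes=classes, confusion=confusion,
        sensitivity={c: float(sens[c]) for c in classes},
        specificity={c: float(spec[c]) for c in classes},
        balanced_accuracy={c: float(bal[c]) for c in classes},
        accuracy=float(accuracy), ci_accuracy=(float(ci.low), float(ci.high)),
        no_information_rate=float(nir), p_value=float(p_value),
        n=n, method=method,
    )


# ---------------------------------------------------------------------------
# Regression report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionReport:
    n: int
    r2: float
    adjusted_r2: float
    rmse: float
    rse: float
    slope: float
    slope_se: float
    ci_slope: tuple[float, float]
    intercept: float
    intercept_se: float
    ci_intercept: tuple[float, float]
    intercept_p_value: float
    origin_fit: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "R2": self.r2,
            "R2_Adjusted": self.adjusted_r2,
            "RMSE": self.rmse,
            "RSE": self.rse,
            "Slope": self.slope,
            "Slope_SE": self.slope_se,
            "CI_Slope": list(self.ci_slope),
            "Intercept": self.intercept,
            "Intercept_SE": self.intercept_se,
            "CI_Intercept": list(self.ci_intercept),
            "Intercept_p_value": self.intercept_p_value,
        }
        if self.origin_fit is not None:
            d["origin_fit"] = dict(self.origin_fit)
        return d

    def to_text(self) -> str:
        lines = [
            f"R2_Adjusted   {self.adjusted_r2:.3f}",
            f"RSE           {self.rse:.2f}",
            f"RMSE          {self.rmse:.2f}",
            f"Slope         {self.slope:.3f} ± {self.slope_se:.3f}",
            f"CI_Slope      [{self.ci_slope[0]:.3f}, {self.ci_slope[1]:.3f}]",
        ]
        if self.intercept_p_value > 0.05:
            lines.append("Intercept     ns")
        else:
            lines.append(f"Intercept     {self.intercept:.2f} ± {self.intercept_se:.2f}")
            lines.append(
                f"CI_Intercept  [{self.ci_intercept[0]:.2f}, {self.ci_intercept[1]:.2f}]"
            )
        return "\n".join(lines)


def regression_report(
    observed, predicted, n_predictors: int = 13, alpha: float = 0.05
) -> RegressionReport:
    """Predicted-vs-observed diagnostics for a regression model.

    Fits the simple linear regression predicted = a + b·observed: a good
    predictive model has slope ≈ 1, intercept ≈ 0 (judged by their
    t-based 95% confidence intervals) and a small residual standard
    error. R² is that fit's determination coefficient; the adjusted R²
    discounts it for the ``n_predictors`` the underlying model consumed.
    RMSE is computed from the raw prediction errors. When the intercept
    is not significant (p > 0.05) a through-origin refit is reported as
    well.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = obs.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.std(obs) == 0:
        raise ValueError("observed values have zero variance")

    design = np.column_stack([np.ones(n), obs])
    beta, *_ = np.linalg.lstsq(design, pred, rcond=None)
    resid = pred - design @ beta
    dof = n - 2
    rse = float(np.sqrt(resid @ resid / dof))
    xtx_inv = np.linalg.inv(design.T @ design)
    se = rse * np.sqrt(np.diag(xtx_inv))
    tcrit = stats.t.ppf(1 - alpha / 2, dof)
    intercept, slope = float(beta[0]), float(beta[1])
    intercept_se, slope_se = float(se[0]), float(se[1])
    t_int = intercept / intercept_se if intercept_se > 0 else np.inf
    p_int = float(2 * stats.t.sf(abs(t_int), dof))

    ss_tot = float(np.sum((pred - pred.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - n_predictors - 1, 1)
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))

    origin = None
    if p_int > alpha:
        b0 = float(obs @ pred / (obs @ obs))
        resid0 = pred - b0 * obs
        dof0 = n - 1
        rse0 = float(np.sqrt(resid0 @ resid0 / dof0))
        se0 = rse0 / float(np.sqrt(obs @ obs))
        t0 = stats.t.ppf(1 - alpha / 2, dof0)
        origin = {
            "Slope": b0,
            "Slope_SE": se0,
            "CI_Slope": [b0 - t0 * se0, b0 + t0 * se0],
            "RSE": rse0,
        }

    return RegressionReport(
        n=n, r2=float(r2), adjusted_r2=float(adj), rmse=rmse, rse=rse,
        slope=slope, slope_se=slope_se,
        ci_slope=(slope - tcrit * slope_se, slope + tcrit * slope_se),
        intercept=intercept, intercept_se=intercept_se,
        ci_intercept=(intercept - tcrit * intercept_se, intercept + tcrit * intercept_se),
        intercept_p_value=p_int, origin_fit=origin,
    )


# ---------------------------------------------------------------------------
# Permutation variable importance
# ---------------------------------------------------------------------------

def variable_importance(
    predict_fn,
    X: pd.DataFrame,
    y,
    metric: str = "r2",
    n_permutations: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance of each predictor for a fitted model.

    Each column in turn is shuffled ``n_permutations`` times and the mean
    drop of the metric (accuracy for classifiers, R² for regressors)
    relative to the intact baseline is reported, with its standard error.
    Rows are sorted by decreasing score; ties break alphabetically by
    predictor name.
    """
    rng = np.random.default_rng(seed)
    X = X.reset_index(drop=True)
    y = np.asarray(y)

    def score(frame: pd.DataFrame) -> float:
        pred = np.asarray(predict_fn(frame))
        if metric == "accuracy":
            return float(np.mean(pred == y))
        if metric == "r2":
            return _cv_r2(y.astype(float), pred.astype(float))
        raise ValueError(f"unknown metric {metric!r}")

    baseline = score(X)
    records = []
    for col in X.columns:
        drops = np.empty(n_permutations)
        for p in range(n_permutations):
            shuffled = X.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            drops[p] = baseline - score(shuffled)
        records.append(
            {
                "predictor": col,
                "importance": float(drops.mean()),
                "se": float(drops.std(ddof=1) / np.sqrt(n_permutations)),
            }
        )
    out = pd.DataFrame(records).sort_values(
        ["importance", "predictor"], ascending=[False, True], kind="mergesort"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
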