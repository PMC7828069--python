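"""The four supervised learners: LDA, MDA, MLR and polynomial-kernel SVR.

Classification of the semi-quantitative IMF groups uses linear
discriminant analysis (LDA: one Gaussian per class, pooled covariance)
and mixture discriminant analysis (MDA: each class a Gaussian mixture of
subclasses sharing one covariance matrix across all subclasses of all
classes, fitted by EM — the classic Hastie–Tibshirani formulation).
Regression of IMF% uses ordinary multiple linear regression (MLR) and
ε-insensitive support vector regression with the polynomial kernel
K(u, v) = (scale·⟨u, v⟩ + offset)^degree.

All fits are deterministic given their seed. Models serialize to plain
JSON dictionaries (means, weights, covariances, support vectors,
hyperparameters) and predict from those stored arrays, so a reloaded
model reproduces its predictions exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.cluster import KMeans
from sklearn.svm import SVR

__all__ = [
    "LDAModel", "MDAModel", "MLRModel", "SVRPolyModel",
    "fit_lda", "predict_lda",
    "fit_mda", "predict_mda",
    "fit_mlr", "predict_mlr",
    "fit_svr_poly", "predict_svr_poly",
]


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D design matrix, got shape {X.shape}")
    return X


# ---------------------------------------------------------------------------
# Linear discriminant analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDAModel:
    classes: tuple
    class_means: np.ndarray        # (k, d)
    pooled_covariance: np.ndarray  # (d, d)
    priors: np.ndarray             # (k,)
    discriminant_axes: np.ndarray  # (d, min(k-1, d)) projection directions

    def to_dict(self) -> dict:
        return {
            "kind": "lda",
            "classes": list(self.classes),
            "class_means": self.class_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": self.priors.tolist(),
            "discriminant_axes": self.discriminant_axes.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        return cls(
            classes=tuple(d["classes"]),
            class_means=np.asarray(d["class_means"], dtype=float),
            pooled_covariance=np.asarray(d["pooled_covariance"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float),
            discriminant_axes=np.asarray(d["discriminant_axes"], dtype=float),
        )


def fit_lda(X, y, ridge: float = 0.0) -> LDAModel:
    """Fit LDA: per-class means, pooled within-class covariance, priors.

    Discriminant axes are the generalized eigenvectors of the
    between-class scatter in the within-class metric, giving the
    projection plane on which group separation is maximal. A singular
    pooled covariance raises unless ``ridge`` adds a diagonal
    regularization of ``ridge × trace/d``.
    """
    X = _as_2d(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("LDA needs at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    n, d = X.shape

    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    Sw = np.zeros((d, d))
    for c, mu in zip(classes, means):
        centered = X[y == c] - mu
        Sw += centered.T @ centered
    pooled = Sw / (n - classes.size)
    if ridge > 0:
        pooled = pooled + ridge * np.trace(pooled) / d * np.eye(d)
    if np.linalg.matrix_rank(pooled) < d:
        raise ValueError(
            "pooled covariance is singular; refit with a positive ridge "
            "regularization (fit_lda(..., ridge=1e-6))"
        )

    grand = X.mean(axis=0)
    Sb = np.zeros((d, d))
    for cnt, mu in zip(counts, means):
        diff = (mu - grand)[:, None]
        Sb += cnt * (diff @ diff.T)
    # generalized eigenproblem Sb v = λ Sw v via the pooled metric
    eigvals, eigvecs = linalg.eigh(Sb, pooled * (n - classes.size))
    order = np.argsort(eigvals)[::-1][: min(classes.size - 1, d)]
    axes = eigvecs[:, order]
    # sign convention: largest-magnitude loading positive, for reproducibility
    for j in range(axes.shape[1]):
        i = np.argmax(np.abs(axes[:, j]))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]

    return LDAModel(
        classes=tuple(classes.tolist()),
        class_means=means,
        pooled_covariance=pooled,
        priors=counts / n,
        discriminant_axes=axes,
    )


def _log_gauss_shared(X: np.ndarray, means: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log N(x; μ_j, Σ) for every row of X and every mean, shared Σ."""
    d = X.shape[1]
    chol = linalg.cholesky(cov, lower=True)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    # squared Mahalanobis distances via triangular solves
    diffs = X[:, None, :] - means[None, :, :]          # (n, k, d)
    flat = diffs.reshape(-1, d).T
    sol = linalg.solve_triangular(chol, flat, lower=True)
    maha = (sol**2).sum(axis=0).reshape(X.shape[0], means.shape[0])
    return -0.5 * (maha + logdet + d * np.log(2 * np.pi))


def predict_lda(model: LDAModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and discriminant scores for new samples.

    Labels come from the highest posterior under the pooled-covariance
    Gaussian rule with class priors; scores are the projections onto the
    (up to two) leading discriminant axes for plotting.
    """
    X = _as_2d(X)
    log_lik = _log_gauss_shared(X, model.class_means, model.pooled_covariance)
    scores = log_lik + np.log(model.priors)
    labels = np.asarray(model.classes, dtype=object)[np.argmax(scores, axis=1)]
    projections = X @ model.discriminant_axes[:, :2]
    return labels, projections


# ---------------------------------------------------------------------------
# Mixture discriminant analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MDAModel:
    classes: tuple
    subclass_means: dict          # class -> (R_j, d) means
    subclass_weights: dict        # class -> (R_j,) mixing weights summing to 1
    covariance: np.ndarray        # (d, d) shared across all subclasses
    priors: np.ndarray            # (k,) class priors
    log_likelihood: float
    n_iterations: int
    seed: int
    per_class_covariance: dict | None = None
    log_likelihood_trace: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "kind": "mda",
            "classes": list(self.classes),
            "subclass_means": {str(c): self.subclass_means[c].tolist() for c in self.classes},
            "subclass_weights": {str(c): self.subclass_weights[c].tolist() for c in self.classes},
            "covariance": self.covariance.tolist(),
            "priors": self.priors.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }


def fit_mda(
    X,
    y,
    subclasses_per_class: int = 3,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    shared_covariance: bool = True,
    ridge: float = 1e-6,
) -> MDAModel:
    """Fit mixture discriminant analysis by EM.

    Each class j is modelled as a mixture of ``subclasses_per_class``
    Gaussians with means μ_jr, weights π_jr and — in the default shared
    form — one covariance Σ common to every subclass of every class.
    Subclass means are initialized by k-means within each class (seeded),
    and EM runs until the total log-likelihood gain drops below ``tol``
    or ``max_iter`` iterations. When a subclass collapses, a diagonal
    ridge of ``ridge × trace/d`` keeps Σ positive definite.

    With one subclass per class and shared covariance, the model reduces
    to LDA (the mixture degenerates to one Gaussian per class).
    """
    X = _as_2d(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n, d = X.shape
    R = int(subclasses_per_class)
    if R < 1:
        raise ValueError("subclasses_per_class must be >= 1")
    if counts.min() < R:
        small = classes[counts < R][0]
        raise ValueError(
            f"class {small!r} has fewer samples than its {R} subclasses"
        )

    # --- initialization: k-means within each class -------------------------
    means = {}
    weights = {}
    resp = {}  # class -> (n_j, R) responsibilities
    for c in classes:
        Xc = X[y == c]
        if R == 1:
            assign = np.zeros(len(Xc), dtype=int)
            centers = Xc.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=R, random_state=seed, n_init=10).fit(Xc)
            assign = km.labels_
            centers = km.cluster_centers_
        means[c] = centers.astype(float)
        w = np.bincount(assign, minlength=R).astype(float)
        w = np.maximum(w, 1e-12)
        weights[c] = w / w.sum()
        r = np.zeros((len(Xc), R))
        r[np.arange(len(Xc)), assign] = 1.0
        resp[c] = r

    def m_step():
        nonlocal means, weights
        cov = np.zeros((d, d))
        per_class_cov = {}
        for c in classes:
            Xc = X[y == c]
            r = resp[c]
            nk = r.sum(axis=0)
            nk_safe = np.maximum(nk, 1e-12)
            means[c] = (r.T @ Xc) / nk_safe[:, None]
            weights[c] = nk_safe / nk_safe.sum()
            Sc = np.zeros((d, d))
            for j in range(R):
                centered = Xc - means[c][j]
                Sc += (r[:, j][:, None] * centered).T @ centered
            cov += Sc
            per_class_cov[c] = Sc / max(len(Xc), 1)
        return cov / n, per_class_cov

    cov, per_class_cov = m_step()

    def regularize(S):
        tr = np.trace(S)
        if tr <= 0:
            tr = 1.0
        S = S + ridge * tr / d * np.eye(d)
        try:
            linalg.cholesky(S, lower=True)
        except linalg.LinAlgError:
            S = S + 1e-3 * tr / d * np.eye(d)
        return S

    prev_ll = -np.inf
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll = 0.0
        for c in classes:
            Xc = X[y == c]
            S = cov if shared_covariance else per_class_cov[c]
            log_comp = _log_gauss_shared(Xc, means[c], regularize(S))
            log_weighted = log_comp + np.log(np.maximum(weights[c], 1e-300))
            m = log_weighted.max(axis=1, keepdims=True)
            log_mix = m[:, 0] + np.log(np.exp(log_weighted - m).sum(axis=1))
            resp[c] = np.exp(log_weighted - log_mix[:, None])
            ll += log_mix.sum()
        if not np.isfinite(ll):
            raise ValueError("non-finite log-likelihood during EM")
        trace.append(float(ll))
        if ll - prev_ll < tol and n_iter > 1:
            prev_ll = ll
            break
        prev_ll = ll
        cov, per_class_cov = m_step()

    cov = regularize(cov)
    per_class_cov = {c: regularize(S) for c, S in per_class_cov.items()}
    return MDAModel(
        classes=tuple(classes.tolist()),
        subclass_means=means,
        subclass_weights=weights,
        covariance=cov,
        priors=counts / n,
        log_likelihood=float(prev_ll),
        n_iterations=n_iter,
        seed=seed,
        per_class_covariance=None if shared_covariance else per_class_cov,
        log_likelihood_trace=tuple(trace),
    )


def predict_mda(model: MDAModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and class posteriors (rows sum to 1)."""
    X = _as_2d(X)
    log_joint = np.empty((X.shape[0], len(model.classes)))
    for i, c in enumerate(model.classes):
        cov = (
            model.covariance
            if model.per_class_covariance is None
            else model.per_class_covariance[c]
        )
        log_comp = _log_gauss_shared(X, model.subclass_means[c], cov)
        log_weighted = log_comp + np.log(np.maximum(model.subclass_weights[c], 1e-300))
        m = log_weighted.max(axis=1, keepdims=True)
        log_mix = m[:, 0] + np.log(np.exp(log_weighted - m).sum(axis=1))
        log_joint[:, i] = log_mix + np.log(model.priors[i])
    m = log_joint.max(axis=1, keepdims=True)
    post = np.exp(log_joint - m)
    post /= post.sum(axis=1, keepdims=True)
    labels = np.asarray(model.classes, dtype=object)[np.argmax(log_joint, axis=1)]
    return labels, post


# ---------------------------------------------------------------------------
# Multiple linear regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLRModel:
    intercept: float
    coefficients: np.ndarray
    df_resid: int
    column_names: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "kind": "mlr",
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "df_resid": self.df_resid,
            "column_names": list(self.column_names) if self.column_names else None,
        }


def fit_mlr(X, y, column_names=None) -> MLRModel:
    """Ordinary least squares with an intercept.

    A rank-deficient design raises with the offending (collinear)
    columns identified by QR column pivoting.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if n <= d + 1:
        raise ValueError(f"need n > {d + 1} samples for {d} predictors plus intercept")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < d + 1:
        _, _, piv = linalg.qr(design, mode="economic", pivoting=True)
        bad = sorted(i - 1 for i in piv[rank:] if i > 0)
        names = (
            [column_names[i] for i in bad] if column_names is not None else bad
        )
        raise ValueError(f"rank-deficient design; collinear column(s): {names}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return MLRModel(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        df_resid=n - d - 1,
        column_names=tuple(column_names) if column_names is not None else None,
    )


def predict_mlr(model: MLRModel, X) -> np.ndarray:
    return model.intercept + _as_2d(X) @ model.coefficients


# ---------------------------------------------------------------------------
# Polynomial-kernel support vector regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVRPolyModel:
    support_vectors: np.ndarray  # (m, d)
    dual_coef: np.ndarray        # (m,) α_i − α_i*
    bias: float
    degree: int
    scale: float
    offset: float
    cost: float
    epsilon: float

    def to_dict(self) -> dict:
        return {
            "kind": "svr_poly",
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "degree": self.degree,
            "scale": self.scale,
            "offset": self.offset,
            "cost": self.cost,
            "epsilon": self.epsilon,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVRPolyModel":
        return cls(
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            bias=d["bias"], degree=d["degree"], scale=d["scale"],
            offset=d["offset"], cost=d["cost"], epsilon=d["epsilon"],
        )


def fit_svr_poly(
    X,
    y,
    degree: int = 3,
    scale: float = 0.1,
    offset: float = 1.0,
    cost: float = 1.0,
    epsilon: float = 0.1,
    tol: float = 1e-6,
) -> SVRPolyModel:
    """ε-insensitive SVR with kernel (scale·⟨u, v⟩ + offset)^degree.

    The working default hyperparameters — degree 3, kernel scale 0.1,
    cost 1 — are the optimized values of the polynomial SVR used for
    IMF% prediction; ε = 0.1 and offset = 1 follow the conventional
    polynomial-kernel parameterization.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float)
    if len(X) < 5:
        raise ValueError("SVR needs at least 5 training samples")
    if degree < 1:
        raise ValueError(f"degree must be >= 1, got {degree}")
    if not cost > 0 or not scale > 0:
        raise ValueError("cost and scale must be positive")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    svr = SVR(
        kernel="poly", degree=degree, gamma=scale, coef0=offset,
        C=cost, epsilon=epsilon, tol=tol,
    ).fit(X, y)
    return SVRPolyModel(
        support_vectors=np.asarray(svr.support_vectors_, dtype=float),
        dual_coef=np.asarray(svr.dual_coef_, dtype=float).ravel(),
        bias=float(svr.intercept_[0]),
        degree=degree, scale=scale, offset=offset, cost=cost, epsilon=epsilon,
    )


def predict_svr_poly(model: SVRPolyModel, X) -> np.ndarray:
    """Predict from the stored kernel expansion: Σ_i α_i K(sv_i, x) + b."""
    X = _as_2d(X)
    K = (model.scale * (X @ model.support_vectors.T) + model.offset) ** model.degree
    return K @ model.dual_coef + model.bias
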