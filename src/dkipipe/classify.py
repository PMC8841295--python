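"""Elastic-net feature selection, SVM classification and evaluation.

Feature selection minimizes the penalized least-squares objective

    (1/N) ||y - X b||^2 + lambda*rho*||b||_1 + lambda*(1-rho)/2*||b||^2

over regression coefficients b, with a {0, 1} class response; features
with nonzero coefficients are "selected".  The L1 term induces sparsity
and the L2 term stabilizes the solution in the p >> n regime.  When
lambda is not given it is chosen on a log-spaced grid by stratified
cross-validation.  Classification uses a maximum-margin SVM on the
selected features with labels encoded {-1, +1}; evaluation reports the
confusion-matrix rates (accuracy, precision, sensitivity, specificity)
and the trapezoidal area under the ROC curve.

Leakage contract: selection, standardization and SVM hyperparameters
are fitted on training data only; test labels enter only the metric
computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ElasticNetConfig",
    "SVMConfig",
    "ClassificationReport",
    "elastic_net_select",
    "svm_train_predict",
    "compute_metrics",
    "SelectClassifyModel",
    "run_experiment",
    "SELECTION_MODES",
    "BIOMARKERS",
]

SELECTION_MODES = ("none", "L1", "PCA", "L1+L2")
BIOMARKERS = ("DT", "KT", "FA", "MD", "MK", "FA+MK")


@dataclass(frozen=True)
class ElasticNetConfig:
    """Elastic-net penalty settings.

    lam       penalty weight lambda (>= 0); None selects it by CV.
    rho       L1/L2 mixing weight in [0, 1]; 1 is the pure LASSO.
    l1_budget optional explicit bound t on ||b||_1, honored through the
              Lagrangian (penalized) form: if the fit at the chosen
              lambda exceeds t, lambda is increased along the grid until
              the bound holds.
    cv_folds  stratified folds for the lambda search.
    n_lambdas grid size for the lambda search.
    """

    lam: float | None = None
    rho: float = 0.5
    l1_budget: float | None = None
    cv_folds: int = 5
    n_lambdas: int = 50

    def __post_init__(self) -> None:
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.l1_budget is not None and self.l1_budget <= 0:
            raise ValueError("l1_budget must be positive")


@dataclass(frozen=True)
class SVMConfig:
    """SVM settings: kernel in {linear, rbf} and the slack penalty c > 0."""

    kernel: str = "linear"
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        if not self.c > 0:
            raise ValueError("c must be positive")


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion-matrix counts and derived metrics for one evaluation.

    Undefined rates (zero denominator) are reported as NaN, never as 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    auc: float
    train_accuracy: float | None = None
    seed: int | None = None
    n_selected: int | None = None

    @property
    def n_test(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _fit_enet(x: np.ndarray, y: np.ndarray, lam: float, rho: float) -> np.ndarray:
    """Coefficients minimizing the package's elastic-net objective.

    The objective maps onto scikit-learn's ElasticNet parameterization
    (which divides the residual term by 2N) with alpha = lambda/2 and
    l1_ratio = rho.
    """
    alpha = lam / 2.0 if lam > 0 else 1e-12
    model = ElasticNet(
        alpha=alpha, l1_ratio=rho, fit_intercept=True, max_iter=100_000, tol=1e-8
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x, y)
    return model.coef_


def _lambda_grid(x: np.ndarray, y: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Log-spaced grid from the smallest all-zero lambda down by 3 decades."""
    yc = y - y.mean()
    l1 = max(rho, 1e-3)
    lam_max = 2.0 * np.max(np.abs(x.T @ yc)) / (x.shape[0] * l1)
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-3), n)


def elastic_net_select(
    features: np.ndarray,
    labels: np.ndarray,
    config: ElasticNetConfig = ElasticNetConfig(),
    random_state: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Select features by the combined L1+L2 penalty.

    Features are standardized internally (constant features dropped); the
    response is the {0, 1} class label.  Returns (selected indices into
    the original feature space, their coefficients).  If every grid point
    zeroes out all coefficients, the selection is empty and a warning is
    issued; callers may fall back to the full feature set.
    """
    x = np.asarray(features, dtype=float)
    y = _binary01(labels)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("features must be (subjects x features) aligned with labels")
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError("need at least 2 subjects per class")

    scaler = StandardScaler()
    xs = scaler.fit_transform(x)
    keep = scaler.scale_ > 0
    xs = xs[:, keep]
    orig_idx = np.flatnonzero(keep)

    if config.lam is not None:
        lam = config.lam
    else:
        lam = _choose_lambda_cv(xs, y, config, random_state)

    coef = _fit_enet(xs, y, lam, config.rho)
    if config.l1_budget is not None and np.abs(coef).sum() > config.l1_budget:
        for lam_up in _lambda_grid(xs, y, config.rho, config.n_lambdas)[::-1]:
            if lam_up <= lam:
                continue
            coef = _fit_enet(xs, y, lam_up, config.rho)
            if np.abs(coef).sum() <= config.l1_budget:
                break
    sel = np.flatnonzero(coef != 0)
    if sel.size == 0:
        warnings.warn("elastic net selected no features", stacklevel=2)
        return np.array([], dtype=int), np.array([])
    return orig_idx[sel], coef[sel]


def _choose_lambda_cv(
    xs: np.ndarray, y: np.ndarray, config: ElasticNetConfig, random_state: int | None
) -> float:
    """Pick lambda minimizing mean validation MSE over stratified folds.

    The whole penalty path is computed per fold with warm-started
    coordinate descent, which is far cheaper than independent fits.
    """
    grid = _lambda_grid(xs, y, config.rho, config.n_lambdas)
    folds = min(config.cv_folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=random_state)
    l1 = max(config.rho, 1e-3)
    mse = np.zeros(grid.size)
    for tr, va in skf.split(xs, y):
        xm = xs[tr].mean(axis=0)
        ym = y[tr].mean()
        xtr, ytr = xs[tr] - xm, y[tr] - ym
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = enet_path(
                xtr, ytr, l1_ratio=l1, alphas=grid / 2.0, max_iter=10_000
            )
        pred = (xs[va] - xm) @ coefs + ym  # (n_va, n_alphas)
        mse += np.mean((y[va][:, None] - pred) ** 2, axis=0)
    return float(grid[np.argmin(mse)])


def _binary01(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, found {classes.size}")
    return (y == classes[1]).astype(int)


def svm_train_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    config: SVMConfig = SVMConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Train a maximum-margin SVM and score the test set.

    Returns (predicted labels in {-1, +1}, continuous decision scores);
    the scores support ROC analysis downstream.
    """
    ytr = np.asarray(train_labels).ravel()
    if np.unique(ytr).size < 2:
        raise ValueError("training set must contain both classes")
    ytr = 2 * _binary01(ytr) - 1
    clf = SVC(kernel=config.kernel, C=config.c, gamma="scale")
    clf.fit(np.asarray(train_features, dtype=float), ytr)
    scores = clf.decision_function(np.asarray(test_features, dtype=float))
    preds = np.where(scores >= 0, 1, -1)
    return preds, scores


def _rate(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(
    predictions: np.ndarray,
    truths: np.ndarray,
    scores: np.ndarray | None = None,
    train_accuracy: float | None = None,
    seed: int | None = None,
    n_selected: int | None = None,
) -> ClassificationReport:
    """Confusion-matrix metrics; AUC by trapezoidal ROC integration.

    accuracy    = (TP+TN)/(TP+TN+FP+FN)
    precision   = TP/(TP+FP)
    sensitivity = TP/(TP+FN)
    specificity = TN/(TN+FP)
    """
    p = _binary01(np.asarray(predictions)) if np.unique(predictions).size == 2 else (
        np.asarray(predictions).ravel() > 0
    ).astype(int)
    t = _binary01(truths)
    if p.size != t.size:
        raise ValueError("predictions and truths must have equal length")
    tp = int(np.sum((p == 1) & (t == 1)))
    tn = int(np.sum((p == 0) & (t == 0)))
    fp = int(np.sum((p == 1) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))
    auc = float("nan")
    if scores is not None and np.unique(t).size == 2:
        fpr, tpr, _ = roc_curve(t, np.asarray(scores, dtype=float).ravel())
        auc = float(np.trapezoid(tpr, fpr))
    return ClassificationReport(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=_rate(tp + tn, tp + tn + fp + fn),
        precision=_rate(tp, tp + fp),
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        auc=auc,
        train_accuracy=train_accuracy,
        seed=seed,
        n_selected=n_selected,
    )


@dataclass
class SelectClassifyModel:
    """Selection + SVM pipeline fitted on training data only.

    Holds everything learned from the training set: the standardizer,
    the selected feature indices (or PCA basis) and the tuned SVM.  Test
    data never influences any fitted attribute.
    """

    selection: str = "L1+L2"
    enet: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    svm_kernel: str = "linear"
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    cv_folds: int = 5
    pca_variance: float = 0.95
    random_state: int | None = 0

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SelectClassifyModel":
        if self.selection not in SELECTION_MODES:
            raise ValueError(f"selection must be one of {SELECTION_MODES}")
        x = np.asarray(x, dtype=float)
        yb = _binary01(y)
        self.scaler_ = StandardScaler().fit(x)
        self.scaler_.scale_[self.scaler_.scale_ == 0] = 1.0
        xs = self.scaler_.transform(x)

        self.pca_ = None
        if self.selection in ("L1", "L1+L2"):
            cfg = self.enet if self.selection == "L1+L2" else ElasticNetConfig(
                rho=1.0,
                lam=self.enet.lam,
                cv_folds=self.enet.cv_folds,
                n_lambdas=self.enet.n_lambdas,
            )
            idx, _ = elastic_net_select(x, yb, cfg, random_state=self.random_state)
            if idx.size == 0:
                idx = np.arange(x.shape[1])  # logged fallback: keep all features
            self.selected_ = idx
            xt = xs[:, idx]
        elif self.selection == "PCA":
            self.pca_ = PCA(n_components=self.pca_variance, random_state=self.random_state)
            xt = self.pca_.fit_transform(xs)
            self.selected_ = np.arange(x.shape[1])
        else:
            self.selected_ = np.arange(x.shape[1])
            xt = xs

        folds = int(min(self.cv_folds, np.bincount(yb).min()))
        svc = SVC(kernel=self.svm_kernel, gamma="scale")
        if folds >= 2:
            search = GridSearchCV(
                svc,
                {"C": list(self.c_grid)},
                cv=StratifiedKFold(folds, shuffle=True, random_state=self.random_state),
                scoring="accuracy",
            )
            search.fit(xt, 2 * yb - 1)
            self.svm_ = search.best_estimator_
        else:
            self.svm_ = svc.set_params(C=1.0).fit(xt, 2 * yb - 1)
        self.train_accuracy_ = float(np.mean(self.svm_.predict(xt) == 2 * yb - 1))
        return self

    def _transform(self, x: np.ndarray) -> np.ndarray:
        xs = self.scaler_.transform(np.asarray(x, dtype=float))
        if self.pca_ is not None:
            return self.pca_.transform(xs)
        return xs[:, self.selected_]

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        return self.svm_.decision_function(self._transform(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.decision_scores(x) >= 0, 1, 0)

    def n_selected(self) -> int:
        if self.pca_ is not None:
            return int(self.pca_.n_components_)
        return int(self.selected_.size)


def run_experiment(
    features: dict[str, np.ndarray],
    labels: np.ndarray,
    selection: str = "L1+L2",
    test_size: float = 0.25,
    seed: int = 0,
    cv_folds: int = 5,
    enet: ElasticNetConfig | None = None,
    svm_kernel: str = "linear",
) -> pd.DataFrame:
    """Evaluate each biomarker's feature set with one stratified split.

    ``features`` maps biomarker names (e.g. DT, KT, FA, MD, MK, FA+MK)
    to subjects x features arrays sharing one subject order.  For each
    biomarker: split -> selection (training data only) -> SVM tuned by
    stratified CV on the training set -> held-out metrics.  Returns a
    per-biomarker comparison table.
    """
    y = _binary01(labels)
    rows = []
    for name, x in features.items():
        x = np.asarray(x, dtype=float)
        if x.shape[0] != y.size:
            raise ValueError(f"{name}: subject count mismatch")
        idx_tr, idx_te = train_test_split(
            np.arange(y.size), test_size=test_size, stratify=y, random_state=seed
        )
        if np.unique(y[idx_tr]).size < 2 or np.unique(y[idx_te]).size < 2:
            raise ValueError("split left a class empty")
        model = SelectClassifyModel(
            selection=selection,
            enet=enet or ElasticNetConfig(cv_folds=cv_folds),
            svm_kernel=svm_kernel,
            cv_folds=cv_folds,
            random_state=seed,
        ).fit(x[idx_tr], y[idx_tr])
        report = compute_metrics(
            model.predict(x[idx_te]),
            y[idx_te],
            scores=model.decision_scores(x[idx_te]),
            train_accuracy=model.train_accuracy_,
            seed=seed,
            n_selected=model.n_selected(),
        )
        rows.append(
            {
                "biomarker": name,
                "train_acc": report.train_accuracy,
                "test_acc": report.accuracy,
                "precision": report.precision,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
                "auc": report.auc,
                "n_selected": report.n_selected,
            }
        )
    return pd.DataFrame(rows)
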