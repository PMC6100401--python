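"""Classifiers and evaluation protocol for fingerprint benchmarks.

Implements the binary-fingerprint kernels (Tanimoto, Sorensen, RBF), the
extreme entropy machine (EEM) — a closed-form classifier combining a random
kernel hidden layer with a regularized Gaussian class-covariance
discriminant — thin contracts over scikit-learn's SVM and Bernoulli naive
Bayes, balanced accuracy, stratified five-fold cross-validation and the
standard hyperparameter grid search.

Hyperparameter grids (defaults)
-------------------------------
* RBF-SVM: C = 10^-3 .. 10^6 and gamma = 10^-3 .. 10^5, powers stepped by 1
  (90 configurations)
* Tanimoto-SVM: C as above (10)
* EEM: h in {0.1, 0.2, 0.5, 1.0}, C in {0, 100, 1000, 100000} (16)
* Bernoulli NB: alpha in {0.01, 0.1, 0.2, 0.5, 1.0} (5)

for a total of 121 enumerated configurations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

DEFAULT_FOLD_SEED = 42


# --- balanced accuracy --------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @staticmethod
    def from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return ConfusionMatrix(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            FP=int(((y_true == 0) & (y_pred == 1)).sum()),
            TN=int(((y_true == 0) & (y_pred == 0)).sum()),
            FN=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """BAC = (sensitivity + specificity) / 2.

    Raises when a class is absent from the evaluation set (the metric is
    undefined there), rather than silently returning 0.
    """
    if cm.TP + cm.FN == 0:
        raise ValueError("balanced accuracy undefined: no positive samples")
    if cm.TN + cm.FP == 0:
        raise ValueError("balanced accuracy undefined: no negative samples")
    return 0.5 * (cm.TP / (cm.TP + cm.FN) + cm.TN / (cm.TN + cm.FP))


# --- kernels ------------------------------------------------------------------

def tanimoto_kernel(x: np.ndarray, y: np.ndarray) -> float:
    """<x,y> / (<x,x> + <y,y> - <x,y>); two zero vectors are similarity 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    xy = float(x @ y)
    denom = float(x @ x) + float(y @ y) - xy
    if denom == 0.0:
        logger.debug("tanimoto 0/0 convention triggered (both-zero vectors)")
        return 1.0
    return xy / denom


def sorensen_kernel(x: np.ndarray, y: np.ndarray) -> float:
    """2<x,y> / (<x,x> + <y,y>); two zero vectors are similarity 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    denom = float(x @ x) + float(y @ y)
    if denom == 0.0:
        logger.debug("sorensen 0/0 convention triggered (both-zero vectors)")
        return 1.0
    return 2.0 * float(x @ y) / denom


def rbf_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||x - y||^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(np.exp(-gamma * np.sum((x - y) ** 2)))


def _pairwise_inner(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, ...]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("dimension mismatch")
    xy = X @ Y.T
    xx = np.einsum("ij,ij->i", X, X)[:, None]
    yy = np.einsum("ij,ij->i", Y, Y)[None, :]
    return xy, xx, yy


def tanimoto_gram(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xy, xx, yy = _pairwise_inner(X, Y)
    denom = xx + yy - xy
    both_zero = denom == 0
    if both_zero.any():
        logger.debug("tanimoto 0/0 convention triggered in Gram matrix")
    out = np.divide(xy, denom, out=np.ones_like(xy), where=~both_zero)
    return out


def sorensen_gram(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    xy, xx, yy = _pairwise_inner(X, Y)
    denom = xx + yy
    both_zero = denom == 0
    if both_zero.any():
        logger.debug("sorensen 0/0 convention triggered in Gram matrix")
    return np.divide(2.0 * xy, denom, out=np.ones_like(xy), where=~both_zero)


def rbf_gram(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    d2 = cdist(np.asarray(X, dtype=float), np.asarray(Y, dtype=float),
               metric="sqeuclidean")
    return np.exp(-gamma * d2)


def gram_matrix(X: np.ndarray, Y: np.ndarray, kernel: str,
                gamma: float | None = None) -> np.ndarray:
    """Pairwise similarity matrix; entry (a, b) = kernel(X_a, Y_b)."""
    if kernel == "tanimoto":
        return tanimoto_gram(X, Y)
    if kernel == "sorensen":
        return sorensen_gram(X, Y)
    if kernel == "rbf":
        if gamma is None:
            raise ValueError("rbf kernel requires gamma")
        return rbf_gram(X, Y, gamma)
    raise ValueError(f"unknown kernel: {kernel!r}")


# --- classifiers --------------------------------------------------------------

def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"binary classification requires 2 classes, got {classes}")
    return y


class KernelSVM:
    """Soft-margin SVM with a precomputed binary-fingerprint kernel
    (Tanimoto or Sorensen), backed by scikit-learn's SVC."""

    def __init__(self, kernel: str = "tanimoto", C: float = 1.0):
        if kernel not in ("tanimoto", "sorensen"):
            raise ValueError(f"unsupported kernel: {kernel!r}")
        if C <= 0:
            raise ValueError("C must be positive")
        self.kernel = kernel
        self.C = C

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KernelSVM":
        y = _check_two_classes(y)
        self._X_train = np.asarray(X, dtype=float)
        self._svc = SVC(kernel="precomputed", C=self.C)
        self._svc.fit(gram_matrix(self._X_train, self._X_train, self.kernel), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(gram_matrix(np.asarray(X, dtype=float),
                                             self._X_train, self.kernel))


class RBFSVM:
    """Soft-margin SVM with the Gaussian kernel exp(-gamma ||x-y||^2)."""

    def __init__(self, C: float = 1.0, gamma: float = 1.0):
        if C <= 0 or gamma <= 0:
            raise ValueError("C and gamma must be positive")
        self.C = C
        self.gamma = gamma

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RBFSVM":
        y = _check_two_classes(y)
        self._svc = SVC(kernel="rbf", C=self.C, gamma=self.gamma)
        self._svc.fit(np.asarray(X, dtype=float), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(np.asarray(X, dtype=float))


class BernoulliNaiveBayes:
    """Bernoulli event model with additive smoothing alpha on per-bit
    conditional probabilities; class priors from training frequencies."""

    def __init__(self, alpha: float = 1.0):
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.alpha = alpha

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BernoulliNaiveBayes":
        y = _check_two_classes(y)
        self._nb = BernoulliNB(alpha=self.alpha)
        self._nb.fit(np.asarray(X, dtype=float), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._nb.predict(np.asarray(X, dtype=float))


class ExtremeEntropyMachine:
    """Extreme entropy machine: random kernel hidden layer plus a
    regularized Gaussian class-covariance discriminant.

    The hidden representation of a sample is its kernel similarity to
    ``hidden_size`` randomly chosen training samples (the *centers*):
    ``phi(x) = exp(-d(x, c)^2 / (2 h^2))`` where ``d`` is the base distance
    (1 - Tanimoto or 1 - Sorensen for binary fingerprints, Euclidean for
    real-valued inputs).  In hidden space the two classes are modelled as
    Gaussians with a pooled covariance; the weight vector is

        w = (S+ + S- + C I + eps I)^-1 (m+ - m-),   eps = 1e-6,

    and the decision threshold is the crossing point of the two univariate
    normal densities fitted to each class's projections (midpoint of the
    projected means when the variances are equal within tolerance).

    Training is a single linear solve — no iterative optimisation — and is
    deterministic given ``random_state``.
    """

    RIDGE = 1e-6

    def __init__(self, h: float = 0.5, C: float = 1000.0,
                 hidden_size: int = 300, base: str = "tanimoto",
                 random_state: int = 0):
        if h <= 0:
            raise ValueError("h must be positive")
        if C < 0:
            raise ValueError("C must be non-negative")
        if base not in ("tanimoto", "sorensen", "euclidean"):
            raise ValueError(f"unsupported base similarity: {base!r}")
        self.h = h
        self.C = C
        self.hidden_size = hidden_size
        self.base = base
        self.random_state = random_state

    # hidden-layer map
    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.base == "euclidean":
            d = cdist(X, self._centers)
        else:
            sim = gram_matrix(X, self._centers, self.base)
            d = 1.0 - sim
        return np.exp(-(d ** 2) / (2.0 * self.h ** 2))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ExtremeEntropyMachine":
        X = np.asarray(X, dtype=float)
        y = _check_two_classes(y)
        self.classes_ = np.unique(y)
        neg, pos = self.classes_
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        m = min(self.hidden_size, n)
        idx = rng.choice(n, size=m, replace=False)
        self._centers = X[np.sort(idx)]

        H = self._transform(X)
        Hp, Hn = H[y == pos], H[y == neg]
        if len(Hp) < 1 or len(Hn) < 1:  # guarded by _check_two_classes
            raise ValueError("both classes must be present")
        m_p = Hp.mean(axis=0)
        m_n = Hn.mean(axis=0)
        S = _ml_cov(Hp) + _ml_cov(Hn)
        reg = (self.C + self.RIDGE) * np.eye(H.shape[1])
        self.w_ = np.linalg.solve(S + reg, m_p - m_n)
        if not np.all(np.isfinite(self.w_)):  # pragma: no cover - ridge prevents
            raise FloatingPointError("non-finite EEM weight vector")

        proj_p = Hp @ self.w_
        proj_n = Hn @ self.w_
        # orient so the positive class projects higher
        if proj_p.mean() < proj_n.mean():
            self.w_ = -self.w_
            proj_p, proj_n = -proj_p, -proj_n
        self.threshold_ = _gaussian_crossing(proj_n, proj_p)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._transform(X) @ self.w_ - self.threshold_

    def predict(self, X: np.ndarray) -> np.ndarray:
        neg, pos = self.classes_
        return np.where(self.decision_function(X) >= 0, pos, neg)


def _ml_cov(H: np.ndarray) -> np.ndarray:
    """Maximum-likelihood covariance (ddof=0); zero matrix for one sample."""
    if H.shape[0] < 2:
        return np.zeros((H.shape[1], H.shape[1]))
    Hc = H - H.mean(axis=0)
    return (Hc.T @ Hc) / H.shape[0]


def _gaussian_crossing(proj_lo: np.ndarray, proj_hi: np.ndarray,
                       rel_tol: float = 1e-3) -> float:
    """Crossing point of two fitted normal densities, between the means.

    Falls back to the midpoint of the means when the standard deviations are
    equal within tolerance or no crossing lies between the means.
    """
    mu_l, mu_h = float(proj_lo.mean()), float(proj_hi.mean())
    sd_l = max(float(proj_lo.std()), 1e-12)
    sd_h = max(float(proj_hi.std()), 1e-12)
    midpoint = 0.5 * (mu_l + mu_h)
    if abs(sd_l - sd_h) <= rel_tol * max(sd_l, sd_h):
        return midpoint
    # equal-density condition: quadratic in x
    a = sd_h ** 2 - sd_l ** 2
    b = 2.0 * (mu_h * sd_l ** 2 - mu_l * sd_h ** 2)
    c = (sd_h ** 2 * mu_l ** 2 - sd_l ** 2 * mu_h ** 2
         - 2.0 * sd_l ** 2 * sd_h ** 2 * math.log(sd_h / sd_l))
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return midpoint
    lo, hi = min(mu_l, mu_h), max(mu_l, mu_h)
    roots = [(-b + s * math.sqrt(disc)) / (2.0 * a) for s in (+1.0, -1.0)]
    inside = [r for r in roots if lo <= r <= hi]
    return inside[0] if inside else midpoint


# --- model specs --------------------------------------------------------------

#: complexity order used for grid-search tie-breaking (simpler first)
MODEL_COMPLEXITY = {"nb": 0, "eem": 1, "tan_svm": 2, "sor_svm": 2, "rbf_svm": 3}


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus explicit hyperparameters."""

    name: str  # nb | eem | tan_svm | sor_svm | rbf_svm
    params: tuple[tuple[str, float], ...] = ()

    @property
    def params_dict(self) -> dict[str, float]:
        return dict(self.params)

    def build(self, seed: int = 0):
        p = self.params_dict
        if self.name == "nb":
            return BernoulliNaiveBayes(alpha=p.get("alpha", 1.0))
        if self.name == "eem":
            return ExtremeEntropyMachine(
                h=p.get("h", 0.5), C=p.get("C", 1000.0),
                hidden_size=int(p.get("hidden_size", 300)),
                base=str(p.get("base", "tanimoto")), random_state=seed)
        if self.name == "tan_svm":
            return KernelSVM(kernel="tanimoto", C=p.get("C", 1.0))
        if self.name == "sor_svm":
            return KernelSVM(kernel="sorensen", C=p.get("C", 1.0))
        if self.name == "rbf_svm":
            return RBFSVM(C=p.get("C", 1.0), gamma=p.get("gamma", 1.0))
        raise ValueError(f"unknown model name: {self.name!r}")


@dataclass
class HyperparameterGrid:
    """The benchmark hyperparameter grids, enumerated in a fixed order:
    NB (alpha ascending), EEM (C then h ascending), Tanimoto-SVM (C
    ascending), RBF-SVM (C then gamma ascending) — simpler families first so
    the first-best configuration wins ties."""

    rbf_svm_C: tuple[float, ...] = tuple(10.0 ** e for e in range(-3, 7))
    rbf_svm_gamma: tuple[float, ...] = tuple(10.0 ** e for e in range(-3, 6))
    tan_svm_C: tuple[float, ...] = tuple(10.0 ** e for e in range(-3, 7))
    eem_h: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0)
    eem_C: tuple[float, ...] = (0.0, 100.0, 1000.0, 100000.0)
    nb_alpha: tuple[float, ...] = (0.01, 0.1, 0.2, 0.5, 1.0)
    models: tuple[str, ...] = ("nb", "eem", "tan_svm", "rbf_svm")

    def configurations(self) -> Iterator[ModelSpec]:
        for name in ("nb", "eem", "tan_svm", "rbf_svm"):
            if name not in self.models:
                continue
            if name == "nb":
                for a in sorted(self.nb_alpha):
                    yield ModelSpec("nb", (("alpha", a),))
            elif name == "eem":
                for C in sorted(self.eem_C):
                    for h in sorted(self.eem_h):
                        yield ModelSpec("eem", (("C", C), ("h", h)))
            elif name == "tan_svm":
                for C in sorted(self.tan_svm_C):
                    yield ModelSpec("tan_svm", (("C", C),))
            elif name == "rbf_svm":
                for C in sorted(self.rbf_svm_C):
                    for g in sorted(self.rbf_svm_gamma):
                        yield ModelSpec("rbf_svm", (("C", C), ("gamma", g)))

    def n_configurations(self) -> int:
        counts = {
            "nb": len(self.nb_alpha),
            "eem": len(self.eem_h) * len(self.eem_C),
            "tan_svm": len(self.tan_svm_C),
            "rbf_svm": len(self.rbf_svm_C) * len(self.rbf_svm_gamma),
        }
        return sum(counts[m] for m in self.models if m in counts)


# --- cross-validation ---------------------------------------------------------

def stratified_kfold(y: np.ndarray, k: int = 5,
                     seed: int = DEFAULT_FOLD_SEED) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold assignment: positives and negatives are split
    independently into k near-equal parts (sizes differ by <= 1 within each
    class); deterministic given the seed."""
    y = np.asarray(y).astype(int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= {k} members for {k}-fold CV (got {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros_like(y), y)]


@dataclass
class FoldResult:
    confusion: ConfusionMatrix
    bac: float


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold confusion matrices and BAC scores,
    their mean and standard error, and the evaluated model configuration."""

    model_name: str
    params: dict[str, float]
    folds: list[FoldResult]
    seed: int

    @property
    def bacs(self) -> np.ndarray:
        return np.array([f.bac for f in self.folds])

    @property
    def mean_bac(self) -> float:
        return float(self.bacs.mean())

    @property
    def sem_bac(self) -> float:
        b = self.bacs
        return float(b.std(ddof=1) / math.sqrt(len(b))) if len(b) > 1 else 0.0

    def summary(self) -> str:
        lines = [
            f"model: {self.model_name}  params: {self.params}",
            f"folds: {len(self.folds)}  seed: {self.seed}",
            "fold BACs: " + ", ".join(f"{b:.4f}" for b in self.bacs),
            f"mean BAC: {self.mean_bac:.4f}  SEM: {self.sem_bac:.4f}",
        ]
        return "\n".join(lines)


def cross_validate(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                   k: int = 5, seed: int = DEFAULT_FOLD_SEED) -> CVResult:
    """Stratified k-fold cross-validation of one model configuration.

    Each fold trains on (k-1)/k of the data and evaluates on the held-out
    part; every sample is evaluated exactly once across folds.
    """
    X = np.asarray(X, dtype=float)
    y = _check_two_classes(y)
    folds = []
    for fold_no, (tr, te) in enumerate(stratified_kfold(y, k=k, seed=seed)):
        model = spec.build(seed=seed + fold_no)
        model.fit(X[tr], y[tr])
        cm = ConfusionMatrix.from_labels(y[te], model.predict(X[te]))
        folds.append(FoldResult(confusion=cm, bac=balanced_accuracy(cm)))
    return CVResult(model_name=spec.name, params=spec.params_dict,
                    folds=folds, seed=seed)


@dataclass
class GridSearchResult:
    best_spec: ModelSpec
    best_cv: CVResult
    table: pd.DataFrame  # one row per configuration

    def summary(self) -> str:
        head = (f"grid search: {len(self.table)} configurations, "
                f"best mean BAC = {self.best_cv.mean_bac:.4f}")
        return head + "\n" + self.best_cv.summary()


def grid_search(X: np.ndarray, y: np.ndarray,
                grid: HyperparameterGrid | None = None,
                k: int = 5, seed: int = DEFAULT_FOLD_SEED) -> GridSearchResult:
    """Evaluate every grid configuration with cross-validation and return the
    argmax of mean BAC.

    Ties prefer the simpler model family (NB < EEM < SVM), then the smaller
    C, then the smaller secondary parameter — enforced by the fixed
    enumeration order plus a strictly-greater argmax.

    The default grid enumerates 121 configurations (90 RBF-SVM + 10
    Tanimoto-SVM + 16 EEM + 5 NB); the benchmark protocol this follows
    reports 117 classifiers without listing which four grid points were
    excluded, so the full printed grid is evaluated and the count is logged.
    """
    grid = grid or HyperparameterGrid()
    n_conf = grid.n_configurations()
    logger.info("grid search: evaluating %d configurations", n_conf)
    if n_conf == 121:
        logger.info(
            "note: the printed grids enumerate 121 configurations; the "
            "original protocol reports 117 classifiers without stating "
            "which four points were excluded — all 121 are evaluated here"
        )
    rows = []
    best: tuple[float, ModelSpec, CVResult] | None = None
    for spec in grid.configurations():
        cv = cross_validate(X, y, spec, k=k, seed=seed)
        rows.append({
            "model": spec.name, **spec.params_dict,
            "mean_bac": cv.mean_bac, "sem_bac": cv.sem_bac,
            **{f"fold{i}_bac": f.bac for i, f in enumerate(cv.folds)},
        })
        if best is None or cv.mean_bac > best[0]:
            best = (cv.mean_bac, spec, cv)
    assert best is not None
    table = pd.DataFrame(rows)
    return GridSearchResult(best_spec=best[1], best_cv=best[2], table=table)
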