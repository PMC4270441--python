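"""Kernel analysis: precision-complexity curves for representations.

A representation is scored by how well a Gaussian-kernel ridge regression on
its features predicts category labels, as a function of the regularization
strength lambda.  *Complexity* is 1/lambda; *precision* is 1 minus the
normalized mean-squared leave-one-out (LOO) error, so a zero predictor
scores exactly 0 and a perfect predictor exactly 1.  The LOO residuals of
kernel ridge have a closed form — alpha_i divided by the i-th diagonal entry
of (K + lambda I)^-1 — which one eigendecomposition of K makes cheap to
evaluate across the whole lambda grid.  The kernel bandwidth sigma is scanned
on a grid centered on the median pairwise distance and, per lambda, the best
sigma (minimum LOO error) is kept.  The area under the precision curve over
log-complexity (KA-AUC) summarizes the curve; bootstrap resampling of
category-balanced image subsets gives its spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .data import FeatureMatrix

__all__ = [
    "KernelGrid",
    "KACurve",
    "gaussian_kernel",
    "median_heuristic_sigma",
    "loo_errors",
    "multiclass_precision",
    "ka_curve",
    "ka_auc",
    "bootstrap_subsets",
    "bootstrap_ka",
    "KernelAnalysis",
]


@dataclass
class KernelGrid:
    """Search grids for the kernel bandwidth and the regularizer.

    sigma is scanned as 2**c * sigma_med for ``n_sigmas`` exponents c evenly
    spaced over ``sigma_log2_range`` (default covers sigma_med/8..8*sigma_med);
    lambda is log-spaced over ``lambda_range``, stored descending so that
    complexity 1/lambda is ascending.
    """

    n_sigmas: int = 32
    sigma_log2_range: tuple[float, float] = (-3.0, 3.0)
    n_lambdas: int = 56
    lambda_range: tuple[float, float] = (1e-6, 1e3)

    def __post_init__(self):
        if self.lambda_range[0] <= 0:
            raise ValueError("lambda values must be strictly positive")
        if self.n_lambdas < 2 or self.n_sigmas < 1:
            raise ValueError("grids need at least 2 lambdas and 1 sigma")

    @property
    def sigma_exponents(self) -> np.ndarray:
        lo, hi = self.sigma_log2_range
        return np.linspace(lo, hi, self.n_sigmas)

    @property
    def lambda_values(self) -> np.ndarray:
        lo, hi = self.lambda_range
        return np.logspace(np.log10(hi), np.log10(lo), self.n_lambdas)

    def sigmas(self, sigma_med: float) -> np.ndarray:
        return sigma_med * 2.0 ** self.sigma_exponents


@dataclass
class KACurve:
    """Precision-complexity curve with optional bootstrap spread."""

    lambdas: np.ndarray
    precision: np.ndarray            # mean over subsets at each lambda
    best_sigma: np.ndarray           # per lambda (of the mean-defining subset 0 run)
    precision_std: np.ndarray | None = None
    per_subset_precision: np.ndarray | None = None   # (n_subsets, n_lambdas)
    per_subset_auc: np.ndarray | None = None
    subsets: list | None = field(default=None, repr=False)

    @property
    def complexity(self) -> np.ndarray:
        return 1.0 / self.lambdas

    @property
    def auc(self) -> float:
        return ka_auc(self)

    @property
    def auc_std(self) -> float | None:
        if self.per_subset_auc is None:
            return None
        return float(np.std(self.per_subset_auc))


def gaussian_kernel(X: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix K_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = np.asarray(X, dtype=float)
    sq = squareform(pdist(X, metric="sqeuclidean"))
    return np.exp(-sq / (2.0 * sigma**2))


def median_heuristic_sigma(X: np.ndarray) -> float:
    """Median of pairwise Euclidean distances between rows."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("median heuristic needs at least 2 rows")
    med = float(np.median(pdist(X, metric="euclidean")))
    if med <= 0:
        raise ValueError("all rows identical: median pairwise distance is zero")
    return med


def _check_symmetric(K: np.ndarray) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kernel matrix must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kernel matrix must be symmetric")
    return K


def _loo_residuals_from_eig(evals: np.ndarray, evecs: np.ndarray,
                            Y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form LOO residuals for kernel ridge at one lambda.

    With K = V diag(e) V', G = K + lam I:  alpha = G^-1 y and the LOO
    residual at example i is alpha_i / (G^-1)_ii.  Y may hold several label
    columns; residuals are returned with the same shape.
    """
    inv = 1.0 / (evals + lam)
    Z = evecs.T @ Y                        # (n, n_labels)
    alpha = evecs @ (inv[:, None] * Z)
    ginv_diag = (evecs**2) @ inv
    return alpha / ginv_diag[:, None]


def loo_errors(K: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Per-example leave-one-out residuals of kernel ridge regression.

    residual_i = y_i - f_{-i}(x_i), the error of a model trained without
    example i, computed in closed form from one eigendecomposition of K.
    """
    K = _check_symmetric(K)
    if lam <= 0:
        raise ValueError("lambda must be strictly positive")
    y = np.asarray(y, dtype=float)
    evals, evecs = np.linalg.eigh(K)
    res = _loo_residuals_from_eig(evals, evecs, y.reshape(-1, 1), lam)
    return res.ravel()


def _label_columns(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized one-vs-all label columns and per-class normalizers.

    Each category's 0/1 indicator is centered (y_c = indicator - p_c) and
    its LOO MSE is later divided by mean(y_c^2) = p_c (1 - p_c).  Under this
    convention the zero predictor — equivalently, predicting the base rate —
    scores a normalized error of exactly 1 (precision 0), and perfect
    prediction scores 0 (precision 1).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 categories")
    Y = (labels[:, None] == classes[None, :]).astype(float)
    counts = Y.sum(axis=0)
    if np.any(counts < 2):
        small = classes[counts < 2].tolist()
        raise ValueError(f"categories with fewer than 2 examples: {small}")
    p = counts / labels.shape[0]
    return Y - p, p * (1.0 - p)


def _precision_grid(X: np.ndarray, labels: np.ndarray,
                    grid: KernelGrid) -> tuple[np.ndarray, np.ndarray]:
    """Precision at every (sigma, lambda) grid point, plus the sigma grid."""
    Y, norms = _label_columns(labels)
    sigma_med = median_heuristic_sigma(X)
    sigmas = grid.sigmas(sigma_med)
    lambdas = grid.lambda_values
    prec = np.empty((sigmas.size, lambdas.size))
    for i, sigma in enumerate(sigmas):
        K = gaussian_kernel(X, sigma)
        evals, evecs = np.linalg.eigh(K)
        evals = np.maximum(evals, 0.0)     # clip tiny negative eigenvalues
        for j, lam in enumerate(lambdas):
            res = _loo_residuals_from_eig(evals, evecs, Y, lam)
            errs = (res**2).mean(axis=0) / norms
            prec[i, j] = 1.0 - errs.mean()
    return prec, sigmas


def multiclass_precision(X: np.ndarray, labels: np.ndarray,
                         lam: float, sigma: float) -> float:
    """One-vs-all precision at a single (lambda, sigma).

    Per category the 0/1 indicator is regressed on the kernel; its LOO MSE is
    normalized by mean(y_c^2) so the zero predictor scores error 1.  Precision
    is 1 minus the category-averaged normalized error.
    """
    Y, norms = _label_columns(labels)
    K = gaussian_kernel(X, sigma)
    evals, evecs = np.linalg.eigh(K)
    evals = np.maximum(evals, 0.0)
    res = _loo_residuals_from_eig(evals, evecs, Y, lam)
    errs = (res**2).mean(axis=0) / norms
    return float(1.0 - errs.mean())


def ka_curve(X, labels: np.ndarray, grid: KernelGrid | None = None) -> KACurve:
    """Precision-complexity curve: per lambda, precision maximized over sigma."""
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    grid = grid or KernelGrid()
    prec, sigmas = _precision_grid(X, labels, grid)
    best = prec.argmax(axis=0)
    return KACurve(lambdas=grid.lambda_values,
                   precision=prec[best, np.arange(prec.shape[1])],
                   best_sigma=sigmas[best])


def ka_auc(curve: KACurve) -> float:
    """Area under precision vs log10(complexity), normalized by the span.

    A constant curve of precision p yields exactly p.
    """
    x = np.log10(curve.complexity)
    if x.size < 2:
        raise ValueError("AUC requires at least 2 grid points")
    order = np.argsort(x)
    x, p = x[order], curve.precision[order]
    return float(np.trapezoid(p, x) / (x[-1] - x[0]))


def bootstrap_subsets(labels: np.ndarray, n_subsets: int = 10,
                      frac: float = 0.8, seed: int = 0,
                      replace: bool = True) -> list[np.ndarray]:
    """Category-balanced bootstrap index sets, fixed by the seed.

    Each subset draws floor(frac * n_min) images per category (with
    replacement by default), where n_min is the smallest category count, so
    categories are equalized.  Generating the subsets once and reusing them
    keeps subset membership identical across representations.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    per_class = [np.where(labels == c)[0] for c in classes]
    m = int(np.floor(frac * min(idx.size for idx in per_class)))
    if m < 2:
        raise ValueError("subset size per category must be at least 2")
    subsets = []
    for _ in range(n_subsets):
        parts = [rng.choice(idx, size=m, replace=replace) for idx in per_class]
        subsets.append(np.concatenate(parts))
    return subsets


def bootstrap_ka(X, labels: np.ndarray, grid: KernelGrid | None = None,
                 n_subsets: int = 10, frac: float = 0.8, seed: int = 0,
                 replace: bool = True,
                 subsets: list[np.ndarray] | None = None) -> KACurve:
    """Kernel-analysis curve with bootstrap spread over image subsets.

    ``subsets`` may be passed explicitly (from :func:`bootstrap_subsets`) to
    share identical image subsets across representations.
    """
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    grid = grid or KernelGrid()
    if subsets is None:
        subsets = bootstrap_subsets(labels, n_subsets, frac, seed, replace)
    curves = [ka_curve(X[idx], labels[idx], grid) for idx in subsets]
    per_prec = np.stack([c.precision for c in curves])
    per_auc = np.array([ka_auc(c) for c in curves])
    return KACurve(lambdas=grid.lambda_values,
                   precision=per_prec.mean(axis=0),
                   precision_std=per_prec.std(axis=0),
                   best_sigma=curves[0].best_sigma,
                   per_subset_precision=per_prec,
                   per_subset_auc=per_auc,
                   subsets=list(subsets))


class KernelAnalysis(BaseEstimator):
    """Estimator interface to kernel analysis.

    ``fit(X, y)`` computes the precision-complexity curve of the
    representation ``X`` for labels ``y`` — bootstrapped over category-
    balanced image subsets when ``n_subsets > 1`` — and exposes the results
    as fitted attributes.

    Parameters
    ----------
    n_sigmas, sigma_log2_range, n_lambdas, lambda_range
        Grid definition; see :class:`KernelGrid`.
    n_subsets, subsample_frac, replace
        Bootstrap over image subsets (``n_subsets=1, subsample_frac=1.0,
        replace=False`` degenerates to a single full-data curve).
    random_state
        Seed fixing subset membership.

    Attributes
    ----------
    curve_ : KACurve
    lambdas_, complexity_, precision_, precision_std_, best_sigma_ : arrays
    auc_ : float
        Mean KA-AUC over subsets.
    auc_std_ : float or None
    """

    def __init__(self, n_sigmas: int = 32,
                 sigma_log2_range: tuple[float, float] = (-3.0, 3.0),
                 n_lambdas: int = 56,
                 lambda_range: tuple[float, float] = (1e-6, 1e3),
                 n_subsets: int = 10, subsample_frac: float = 0.8,
                 replace: bool = True, random_state: int = 0):
        self.n_sigmas = n_sigmas
        self.sigma_log2_range = sigma_log2_range
        self.n_lambdas = n_lambdas
        self.lambda_range = lambda_range
        self.n_subsets = n_subsets
        self.subsample_frac = subsample_frac
        self.replace = replace
        self.random_state = random_state

    def _grid(self) -> KernelGrid:
        return KernelGrid(n_sigmas=self.n_sigmas,
                          sigma_log2_range=tuple(self.sigma_log2_range),
                          n_lambdas=self.n_lambdas,
                          lambda_range=tuple(self.lambda_range))

    def fit(self, X, y, subsets: list[np.ndarray] | None = None):
        grid = self._grid()
        if self.n_subsets == 1 and self.subsample_frac == 1.0 and subsets is None:
            curve = ka_curve(X, y, grid)
            curve = KACurve(lambdas=curve.lambdas, precision=curve.precision,
                            best_sigma=curve.best_sigma,
                            per_subset_precision=curve.precision[None, :],
                            per_subset_auc=np.array([ka_auc(curve)]))
        else:
            curve = bootstrap_ka(X, y, grid, n_subsets=self.n_subsets,
                                 frac=self.subsample_frac,
                                 seed=self.random_state,
                                 replace=self.replace, subsets=subsets)
        self.curve_ = curve
        self.lambdas_ = curve.lambdas
        self.complexity_ = curve.complexity
        self.precision_ = curve.precision
        self.precision_std_ = curve.precision_std
        self.best_sigma_ = curve.best_sigma
        self.auc_ = float(curve.per_subset_auc.mean())
        self.auc_std_ = curve.auc_std
        return self

    def score(self, X=None, y=None) -> float:
        """Mean KA-AUC of the fitted curve."""
        return self.auc_
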