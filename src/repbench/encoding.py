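"""Encoding models of site responses and representational similarity.

Two complementary views of how well a model representation captures neural
variability:

* **Encoding**: per-site ridge regression from model features to the
  trial-averaged response, cross-validated on 80/20 image splits, scored as
  the percentage of *explainable* variance explained — the squared test
  correlation divided by the squared noise ceiling (Spearman-Brown corrected
  split-half trial consistency of the site), median over sites.
* **Representational similarity**: feature vectors are averaged over each
  object's image variations, an object-level representational dissimilarity
  matrix (RDM) of 1 - Pearson correlations is formed (49 x 49 for the
  default task), and two representations are compared by the Spearman rank
  correlation of their RDMs' upper triangles.  A split-half over recording
  sites bounds the similarity attainable given sampling noise, and an
  "+IT-fit" variant first predicts site responses from the model and builds
  the RDM from held-out predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import RidgeCV

from .data import FeatureMatrix, StimulusSet, TrialTensor, spearman_brown

__all__ = [
    "spearman_brown",
    "EncodingResult",
    "ridge_encode",
    "RidgeEncoder",
    "explained_explainable",
    "explainable_ceiling",
    "object_average",
    "compute_rdm",
    "rdm_similarity",
    "object_stratified_splits",
    "split_half_rdm_consistency",
    "it_fit_representation",
]

DEFAULT_ALPHAS = np.logspace(-4, 6, 21)


@dataclass
class EncodingResult:
    """Cross-validated per-site encoding performance."""

    site_r: np.ndarray                  # (n_splits, n_sites) test correlations
    splits: list = field(repr=False, default=None)
    predictions: list = field(repr=False, default=None)   # per split, (n_test, n_sites)
    ceiling_r: np.ndarray | None = None                   # per site
    explained_explainable: np.ndarray | None = None       # (n_splits, n_sites), %
    median_explained_explainable: float | None = None

    @property
    def mean_site_r(self) -> np.ndarray:
        return self.site_r.mean(axis=0)


def object_stratified_splits(stimuli: StimulusSet, n_splits: int = 10,
                             test_frac: float = 0.2, seed: int = 0,
                             ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test image splits with every object present in every test set.

    The same splits (fixed by the seed) should be reused across
    representations so comparisons share image subsets.
    """
    rng = np.random.default_rng(seed)
    obj = stimuli.object_ids
    splits = []
    for _ in range(n_splits):
        test_parts = []
        for o in stimuli.object_names:
            idx = np.where(obj == o)[0]
            n_test = max(1, int(round(test_frac * idx.size)))
            test_parts.append(rng.choice(idx, size=n_test, replace=False))
        test = np.sort(np.concatenate(test_parts))
        train = np.setdiff1d(np.arange(len(stimuli)), test)
        splits.append((train, test))
    return splits


def _fit_predict_split(X: np.ndarray, Y: np.ndarray, train: np.ndarray,
                       test: np.ndarray, alphas) -> np.ndarray:
    """Ridge fit on training rows (per-site GCV penalty), predict test rows."""
    model = RidgeCV(alphas=alphas, alpha_per_target=True)
    model.fit(X[train], Y[train])
    return model.predict(X[test])


def _columnwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("is,is->s", A, B) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return r


def ridge_encode(model_rep: FeatureMatrix, neural_rep: FeatureMatrix,
                 stimuli: StimulusSet | None = None, n_splits: int = 10,
                 train_frac: float = 0.8, seed: int = 0,
                 alphas=DEFAULT_ALPHAS,
                 splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
                 ) -> EncodingResult:
    """Predict each site's response from model features by ridge regression.

    Penalties are chosen per site by generalized cross-validation on the
    training rows only.  Returns per-split, per-site test Pearson r and the
    raw held-out predictions (reused by :func:`it_fit_representation`).
    """
    if model_rep.n_images != neural_rep.n_images:
        raise ValueError("model and neural representations must share image rows")
    X, Y = model_rep.values, neural_rep.values
    zero_var = Y.var(axis=0) == 0
    if zero_var.any():
        warnings.warn(f"zero-variance sites skipped in scoring: "
                      f"{np.where(zero_var)[0].tolist()}")
    if splits is None:
        stim = stimuli or model_rep.stimuli
        if stim is not None:
            splits = object_stratified_splits(stim, n_splits, 1 - train_frac, seed)
        else:
            rng = np.random.default_rng(seed)
            n = X.shape[0]
            n_test = max(1, int(round((1 - train_frac) * n)))
            splits = []
            for _ in range(n_splits):
                test = np.sort(rng.choice(n, size=n_test, replace=False))
                splits.append((np.setdiff1d(np.arange(n), test), test))
    site_r, preds = [], []
    for train, test in splits:
        P = _fit_predict_split(X, Y, train, test, alphas)
        preds.append(P)
        site_r.append(_columnwise_pearson(P, Y[test]))
    return EncodingResult(site_r=np.stack(site_r), splits=list(splits),
                          predictions=preds)


def explainable_ceiling(tensor: TrialTensor, image_idx: np.ndarray | None = None,
                        n_repeats: int = 20, seed: int = 0) -> np.ndarray:
    """Per-site noise ceiling: Spearman-Brown corrected split-half trial
    consistency, optionally restricted to a subset of images (a training set)."""
    from .data import split_half_consistency
    counts = tensor.counts if image_idx is None else tensor.counts[:, image_idx, :]
    sub = TrialTensor(counts=counts, blank_rate=tensor.blank_rate,
                      window=tensor.window)
    cons = split_half_consistency(sub, n_repeats=n_repeats, seed=seed)
    return np.array([c.corrected_r for c in cons])


def explained_explainable(pred_r: np.ndarray, ceiling_r: np.ndarray) -> np.ndarray:
    """Percent explained explainable variance: 100 * pred_r^2 / ceiling_r^2.

    Sites with a non-positive or undefined ceiling are excluded (NaN) with a
    warning; values above 100 are flagged but not clipped.
    """
    pred_r = np.asarray(pred_r, dtype=float)
    ceiling_r = np.asarray(ceiling_r, dtype=float)
    out = np.full(np.broadcast_shapes(pred_r.shape, ceiling_r.shape), np.nan)
    bad = ~(ceiling_r > 0)
    if bad.any():
        warnings.warn(f"{int(np.sum(bad))} sites excluded: non-positive ceiling")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = 100.0 * pred_r**2 / ceiling_r**2
    out = np.where(np.broadcast_to(bad, out.shape), np.nan, vals)
    if np.nanmax(out, initial=0.0) > 100.0 + 1e-6:
        warnings.warn("explained explainable variance exceeds 100% for some sites")
    return out


class RidgeEncoder(BaseEstimator, RegressorMixin):
    """Estimator interface to the encoding protocol.

    ``fit(X, Y)`` cross-validates ridge encoding models from the model
    representation ``X`` to site responses ``Y``; if a ``trial_tensor`` is
    supplied, per-site noise ceilings and the median explained-explainable
    percentage are computed too.  ``predict`` applies a final all-data fit.

    Attributes: ``result_`` (EncodingResult), ``site_r_``, ``ceiling_r_``,
    ``median_explained_explainable_``.
    """

    def __init__(self, n_splits: int = 10, train_frac: float = 0.8,
                 alphas=DEFAULT_ALPHAS, random_state: int = 0):
        self.n_splits = n_splits
        self.train_frac = train_frac
        self.alphas = alphas
        self.random_state = random_state

    def fit(self, X, Y, stimuli: StimulusSet | None = None,
            trial_tensor: TrialTensor | None = None):
        model_rep = X if isinstance(X, FeatureMatrix) else FeatureMatrix(np.asarray(X))
        neural_rep = (Y if isinstance(Y, FeatureMatrix)
                      else FeatureMatrix(np.asarray(Y), feature_kind="neural_multiunit"))
        res = ridge_encode(model_rep, neural_rep, stimuli=stimuli,
                           n_splits=self.n_splits, train_frac=self.train_frac,
                           seed=self.random_state, alphas=self.alphas)
        if trial_tensor is not None:
            ee = []
            for k, (train, _) in enumerate(res.splits):
                ceiling = explainable_ceiling(trial_tensor, train,
                                              seed=self.random_state + k)
                ee.append(explained_explainable(res.site_r[k], ceiling))
            res.ceiling_r = explainable_ceiling(trial_tensor,
                                                seed=self.random_state)
            res.explained_explainable = np.stack(ee)
            # median over sites within each split, then mean over splits
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                per_split = np.nanmedian(res.explained_explainable, axis=1)
            res.median_explained_explainable = float(np.mean(per_split))
        self.result_ = res
        self.site_r_ = res.mean_site_r
        self.ceiling_r_ = res.ceiling_r
        self.median_explained_explainable_ = res.median_explained_explainable
        self._final = RidgeCV(alphas=self.alphas, alpha_per_target=True)
        self._final.fit(model_rep.values, neural_rep.values)
        return self

    def predict(self, X):
        Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        return self._final.predict(Xv)


def object_average(rep: FeatureMatrix | np.ndarray,
                   stimuli: StimulusSet,
                   image_idx: np.ndarray | None = None) -> tuple[np.ndarray, list]:
    """Mean feature vector per object (rows ordered by sorted object name).

    ``image_idx`` restricts the averaging to a subset of images (e.g. a test
    split); every object must still contribute at least one image.  When the
    values matrix has fewer rows than the stimulus set, it is interpreted as
    already indexed by ``image_idx``.
    """
    vals = rep.values if isinstance(rep, FeatureMatrix) else np.asarray(rep, dtype=float)
    obj = stimuli.object_ids
    if image_idx is not None:
        obj = obj[image_idx]
        if vals.shape[0] == len(stimuli):
            vals = vals[image_idx]
    if vals.shape[0] != obj.shape[0]:
        raise ValueError("feature rows do not match the (subset of) stimuli")
    names = stimuli.object_names
    rows = []
    for o in names:
        mask = obj == o
        if not mask.any():
            raise ValueError(f"object {o!r} has no images in the given subset")
        rows.append(vals[mask].mean(axis=0))
    return np.stack(rows), names


def compute_rdm(object_matrix: np.ndarray) -> np.ndarray:
    """Representational dissimilarity matrix: 1 - Pearson r between object rows."""
    M = np.asarray(object_matrix, dtype=float)
    if M.shape[0] < 3:
        raise ValueError("RDM needs at least 3 objects")
    sd = M.std(axis=1)
    if np.any(sd == 0):
        bad = np.where(sd == 0)[0].tolist()
        raise ValueError(f"constant object vectors (correlation undefined): {bad}")
    rdm = 1.0 - np.corrcoef(M)
    np.fill_diagonal(rdm, 0.0)
    return rdm


def rdm_similarity(A: np.ndarray, B: np.ndarray) -> float:
    """Spearman rank correlation of the strictly-upper-triangle entries."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("RDMs must have identical shape and object ordering")
    iu = np.triu_indices(A.shape[0], k=1)
    rho, _ = spearmanr(A[iu], B[iu])
    return float(rho)


def split_half_rdm_consistency(neural_rep: FeatureMatrix, stimuli: StimulusSet,
                               n_repeats: int = 50, n_splits: int = 10,
                               test_frac: float = 0.2, seed: int = 0,
                               splits=None) -> dict:
    """RDM similarity between random halves of the recording sites.

    For each of ``n_repeats`` random site groupings and each image split,
    object-level RDMs are computed per half on the held-out images and their
    Spearman similarity recorded.  Bounds the similarity any model could
    attain given the finite neural sample.
    """
    if neural_rep.n_features < 2:
        raise ValueError("site split-half needs at least 2 sites")
    rng = np.random.default_rng(seed)
    if splits is None:
        splits = object_stratified_splits(stimuli, n_splits, test_frac, seed)
    rhos = []
    n_sites = neural_rep.n_features
    for _ in range(n_repeats):
        perm = rng.permutation(n_sites)
        half1, half2 = perm[: n_sites // 2], perm[n_sites // 2:]
        for _, test in splits:
            M1, _ = object_average(neural_rep.values[:, half1], stimuli, test)
            M2, _ = object_average(neural_rep.values[:, half2], stimuli, test)
            rhos.append(rdm_similarity(compute_rdm(M1), compute_rdm(M2)))
    rhos = np.array(rhos)
    return {"rho_mean": float(rhos.mean()), "rho_std": float(rhos.std()),
            "rhos": rhos}


def it_fit_representation(model_rep: FeatureMatrix, neural_rep: FeatureMatrix,
                          stimuli: StimulusSet, n_splits: int = 10,
                          seed: int = 0, alphas=DEFAULT_ALPHAS,
                          splits=None) -> list[dict]:
    """Neural-fit representation: held-out encoding predictions as features.

    Per object-stratified split, site responses are predicted from the model
    representation on the 20% test images (fit on the other 80%), and the
    object-level RDM is computed from those predictions only — images used
    for fitting never enter the RDM.  Returns per-split dicts with keys
    ``rdm``, ``test_idx`` and ``objects``.
    """
    if splits is None:
        splits = object_stratified_splits(stimuli, n_splits, 0.2, seed)
    enc = ridge_encode(model_rep, neural_rep, stimuli=stimuli,
                       seed=seed, alphas=alphas, splits=splits)
    out = []
    for (train, test), P in zip(enc.splits, enc.predictions):
        M, names = object_average(P, stimuli, test)
        out.append({"rdm": compute_rdm(M), "test_idx": test, "objects": names})
    return out
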