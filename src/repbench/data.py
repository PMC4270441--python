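"""Core data containers and neural-style preprocessing.

The analyses in this package compare *representations*: mappings from a
fixed set of visual stimuli to feature vectors.  A representation may come
from a model (a layer's activations) or from a neural population (trial-
averaged, normalized spike counts).  This module defines the containers —
:class:`StimulusSet`, :class:`FeatureMatrix`, :class:`TrialTensor` — and the
standard path from raw trial-structured spike counts to a feature matrix:
windowed counts, background subtraction, per-site scale normalization and
trial averaging, plus split-half consistency screening of recording sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSet",
    "FeatureMatrix",
    "TrialTensor",
    "SiteConsistency",
    "spearman_brown",
    "preprocess_trials",
    "split_half_consistency",
    "select_top_consistent_sites",
    "subsample_features",
]


class StimulusSet:
    """Per-image metadata defining the categorization task.

    Wraps a table with one row per image: a dense ``image_id`` (0..N-1),
    a ``category`` label, an ``object_id`` label nested within category,
    and optional variation columns (position/scale/pose/background seed).
    The default task has 7 categories x 7 object exemplars x 40 images
    per exemplar = 1960 stimuli.
    """

    REQUIRED = ("image_id", "category", "object_id")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"StimulusSet table missing columns: {missing}")
        table = table.sort_values("image_id").reset_index(drop=True)
        ids = table["image_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(table))):
            raise ValueError("image_id values must be unique and dense (0..N-1)")
        # every object exemplar belongs to exactly one category
        n_cats = table.groupby("object_id", observed=True)["category"].nunique()
        if (n_cats > 1).any():
            bad = n_cats[n_cats > 1].index.tolist()
            raise ValueError(f"objects mapped to multiple categories: {bad}")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def categories(self) -> np.ndarray:
        return self.table["category"].to_numpy()

    @property
    def object_ids(self) -> np.ndarray:
        return self.table["object_id"].to_numpy()

    @property
    def category_names(self) -> list:
        return sorted(self.table["category"].unique().tolist())

    @property
    def object_names(self) -> list:
        return sorted(self.table["object_id"].unique().tolist())

    @property
    def n_categories(self) -> int:
        return self.table["category"].nunique()

    @property
    def n_objects(self) -> int:
        return self.table["object_id"].nunique()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StimulusSet":
        return cls(pd.read_csv(path))

    def __repr__(self) -> str:
        return (f"StimulusSet(n_images={len(self)}, "
                f"n_categories={self.n_categories}, n_objects={self.n_objects})")


@dataclass
class FeatureMatrix:
    """A representation: real matrix of shape (n_images, n_features).

    ``feature_kind`` tags the provenance ({'model', 'neural_multiunit',
    'neural_singleunit'}); noise matching is only applied to model kinds.
    """

    values: np.ndarray
    feature_kind: str = "model"
    stimuli: StimulusSet | None = None

    KINDS = ("model", "neural_multiunit", "neural_singleunit")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("FeatureMatrix values must be 2-D (images x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureMatrix values must be finite")
        if self.feature_kind not in self.KINDS:
            raise ValueError(f"feature_kind must be one of {self.KINDS}")
        if self.stimuli is not None and len(self.stimuli) != self.values.shape[0]:
            raise ValueError(
                f"row count {self.values.shape[0]} does not match "
                f"stimulus set size {len(self.stimuli)}")

    @property
    def n_images(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_neural(self) -> bool:
        return self.feature_kind.startswith("neural")


@dataclass
class TrialTensor:
    """Trial-structured responses: (n_sites, n_images, n_trials) counts.

    ``blank_rate`` holds the per-site background rate measured on blank
    presentations; ``window`` records the spike-count window in ms.
    """

    counts: np.ndarray
    blank_rate: np.ndarray | float = 0.0
    window: tuple[float, float] = (70.0, 170.0)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be 3-D (sites, images, trials)")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("TrialTensor counts must be finite")
        self.blank_rate = np.broadcast_to(
            np.asarray(self.blank_rate, dtype=float), (self.counts.shape[0],)
        ).copy()
        if not self.window[0] < self.window[1]:
            raise ValueError("window start must precede window end")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_images(self) -> int:
        return self.counts.shape[1]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[2]


@dataclass
class SiteConsistency:
    """Split-half trial consistency of one site.

    ``split_half_r`` is the mean Pearson correlation between image-response
    vectors averaged over two random halves of the trials; ``corrected_r``
    applies the Spearman-Brown prophecy formula to estimate full-data
    reliability.  Undefined consistencies (constant responses) are NaN.
    """

    site_id: int
    split_half_r: float
    corrected_r: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.split_half_r)


def spearman_brown(r: float, factor: float = 2.0) -> float:
    """Spearman-Brown prophecy correction of a split-half correlation.

    For the standard two-half split, ``2r / (1 + r)``: the predicted
    reliability if the measurement were lengthened by ``factor``.
    NaN passes through (undefined consistency stays undefined).
    """
    r = float(r)
    if np.isnan(r):
        return np.nan
    denom = 1.0 + (factor - 1.0) * r
    if denom <= 0:
        raise ValueError(f"Spearman-Brown correction undefined for r={r}")
    return factor * r / denom


def preprocess_trials(tensor: TrialTensor,
                      block_std: np.ndarray | None = None) -> FeatureMatrix:
    """Raw trial counts -> trial-averaged, normalized feature matrix.

    Per site: subtract the background (blank) rate, divide by the site's
    response standard deviation (over all images and trials unless an
    explicit per-site ``block_std`` is supplied), then average over trials.
    Returns an images x sites :class:`FeatureMatrix` tagged neural.
    """
    resp = tensor.counts - tensor.blank_rate[:, None, None]
    if block_std is None:
        block_std = resp.std(axis=(1, 2))
    block_std = np.asarray(block_std, dtype=float)
    if block_std.shape != (tensor.n_sites,):
        raise ValueError("block_std must have one entry per site")
    if np.any(block_std <= 0) or not np.all(np.isfinite(block_std)):
        bad = np.where(~(block_std > 0))[0]
        raise ValueError(f"degenerate (non-positive) response scale at sites {bad.tolist()}")
    normalized = resp / block_std[:, None, None]
    site_by_image = normalized.mean(axis=2)
    return FeatureMatrix(site_by_image.T, feature_kind="neural_multiunit")


def _half_split_correlations(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Pearson r per site between image vectors averaged over two random trial halves."""
    n_sites, _, n_trials = counts.shape
    perm = rng.permutation(n_trials)
    a = counts[:, :, perm[: n_trials // 2]].mean(axis=2)
    b = counts[:, :, perm[n_trials // 2:]].mean(axis=2)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("si,si->s", a, b) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan  # constant vector: undefined, never 0
    return r


def split_half_consistency(tensor: TrialTensor, n_repeats: int = 20,
                           seed: int | np.random.Generator = 0) -> list[SiteConsistency]:
    """Mean split-half Pearson consistency per site over random trial splits."""
    if tensor.n_trials < 2:
        raise ValueError("split-half consistency requires at least 2 trials")
    rng = np.random.default_rng(seed)
    rs = np.stack([_half_split_correlations(tensor.counts, rng)
                   for _ in range(n_repeats)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_r = np.nanmean(rs, axis=0)
    all_nan = np.all(np.isnan(rs), axis=0)
    mean_r[all_nan] = np.nan
    return [SiteConsistency(site_id=s, split_half_r=float(mean_r[s]),
                            corrected_r=spearman_brown(mean_r[s]))
            for s in range(tensor.n_sites)]


def select_top_consistent_sites(consistencies: Sequence[SiteConsistency],
                                k: int) -> list[int]:
    """Indices of the k most consistent sites (highest split_half_r).

    Sites with undefined consistency are ineligible.  Ties break toward the
    lower site index so selection is deterministic.
    """
    eligible = [c for c in consistencies if c.defined]
    if k > len(eligible):
        raise ValueError(
            f"requested {k} sites but only {len(eligible)} have defined consistency")
    ranked = sorted(eligible, key=lambda c: (-c.split_half_r, c.site_id))
    return [c.site_id for c in ranked[:k]]


def subsample_features(rep: FeatureMatrix, n: int,
                       seed: int | np.random.Generator = 0) -> FeatureMatrix:
    """Uniform random choice of n feature columns without replacement."""
    if n > rep.n_features:
        raise ValueError(f"cannot subsample {n} of {rep.n_features} features")
    rng = np.random.default_rng(seed)
    cols = rng.choice(rep.n_features, size=n, replace=False)
    return FeatureMatrix(rep.values[:, cols], feature_kind=rep.feature_kind,
                         stimuli=rep.stimuli)
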