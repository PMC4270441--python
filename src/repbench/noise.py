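"""Experimental-noise matching for model representations.

Neural recordings carry trial-to-trial noise that model features lack, so a
raw comparison flatters the models.  The correction estimated here follows
the near-Poisson character of cortical spike counts: after normalizing the
neural population response to unit total variance, the trial variance of
each site is regressed linearly on its trial mean and the coefficients
(a, b) are averaged over sites.  The observed (trial-averaged) variance
splits into a signal part and a standard-error-of-the-mean part
sigma2_noise = mean(a*mu + b)/T; model features are then rescaled to the
signal variance and corrupted with independent Gaussian noise of variance
(a*m + b)/T per entry, matching the neural sample's effective SNR.  This is
deliberately conservative: the neural sample keeps its own residual noise,
so injection penalizes models at least as much as empirical trial noise
penalizes the recording.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .data import FeatureMatrix, TrialTensor, subsample_features

__all__ = [
    "NoiseModel",
    "normalize_population",
    "fit_mean_variance",
    "estimate_signal_noise",
    "fit_noise_model",
    "scale_model_features",
    "inject_noise",
    "noise_match",
    "NoiseMatcher",
]

_SIGNAL_FLOOR = 1e-12


@dataclass
class NoiseModel:
    """Linear mean-variance noise model: Var(response) ~= a * mean + b.

    ``n_trials`` is the number of repetitions T the matched neural features
    average over (47 for the multi-unit sample, 6 for single units); noise is
    injected at the SEM level, i.e. with variance (a*m + b)/T.
    """

    a: float
    b: float
    n_trials: int
    sigma2_total: float | None = None
    sigma2_signal: float | None = None
    sigma2_noise: float | None = None

    def predicted_variance(self, mean: np.ndarray) -> np.ndarray:
        """Trial-to-trial variance at a given mean rate, clipped at 0."""
        return np.clip(self.a * np.asarray(mean, dtype=float) + self.b, 0.0, None)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "NoiseModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def normalize_population(tensor: TrialTensor) -> TrialTensor:
    """Center by the grand mean and scale the population to unit variance.

    The grand mean and variance are taken over sites, images and trials
    jointly; the blank rate is carried through the same affine map so
    downstream background subtraction stays consistent.
    """
    mu = tensor.counts.mean()
    sd = tensor.counts.std()
    if sd <= 0:
        raise ValueError("population response has zero variance")
    return TrialTensor(counts=(tensor.counts - mu) / sd,
                       blank_rate=(tensor.blank_rate - mu) / sd,
                       window=tensor.window)


def fit_mean_variance(tensor: TrialTensor) -> NoiseModel:
    """Per-site linear fit of trial variance on trial mean, averaged over sites.

    The regressor — the T-trial sample mean — carries sampling noise of
    variance Var(trial)/T, which would attenuate a naive least-squares slope
    toward 0 and leak the lost slope into the intercept.  The fit therefore
    uses the measurement-error-corrected moment estimator: the known noise
    variance of the sample mean (mean trial variance / T) is subtracted from
    the regressor variance before forming the slope, giving a consistent
    estimate of the underlying mean-variance relation.  Sites whose mean
    spread does not exceed their sampling noise are excluded with a warning.
    """
    if tensor.n_trials < 2:
        raise ValueError("mean-variance fit requires at least 2 trials")
    T = tensor.n_trials
    means = tensor.counts.mean(axis=2)            # (sites, images)
    variances = tensor.counts.var(axis=2, ddof=1)
    coefs = []
    skipped = []
    for s in range(tensor.n_sites):
        m, v = means[s], variances[s]
        denom = m.var() - v.mean() / T        # true mean spread across images
        if np.ptp(m) == 0 or denom <= 0:
            skipped.append(s)
            continue
        slope = np.cov(m, v)[0, 1] * (m.size - 1) / m.size / denom
        intercept = v.mean() - slope * m.mean()
        coefs.append((slope, intercept))
    if skipped:
        warnings.warn(f"sites with constant mean excluded from noise fit: {skipped}")
    if not coefs:
        raise ValueError("no site had enough mean spread to fit the noise model")
    a, b = np.mean(coefs, axis=0)
    return NoiseModel(a=float(a), b=float(b), n_trials=tensor.n_trials)


def estimate_signal_noise(tensor: TrialTensor, model: NoiseModel) -> NoiseModel:
    """Split observed variance into signal and SEM-level noise parts.

    sigma2_total is the variance of the trial-averaged responses;
    sigma2_noise averages the model-predicted trial variance over all
    (site, image) cells and divides by T (standard error of a T-trial mean);
    sigma2_signal is the remainder, floored just above zero.
    """
    means = tensor.counts.mean(axis=2)
    sigma2_total = float(means.var())
    sem2 = model.predicted_variance(means) / model.n_trials
    sigma2_noise = float(sem2.mean())
    if sigma2_noise >= sigma2_total:
        raise ValueError(
            f"degenerate decomposition: noise variance {sigma2_noise:.4g} "
            f">= total variance {sigma2_total:.4g}; responses carry no "
            "resolvable signal at this trial count")
    sigma2_signal = max(sigma2_total - sigma2_noise, _SIGNAL_FLOOR)
    return NoiseModel(a=model.a, b=model.b, n_trials=model.n_trials,
                      sigma2_total=sigma2_total,
                      sigma2_signal=sigma2_signal,
                      sigma2_noise=sigma2_noise)


def fit_noise_model(tensor: TrialTensor, normalize: bool = True) -> NoiseModel:
    """Full estimation path: normalize, fit (a, b), decompose the variance."""
    if normalize:
        tensor = normalize_population(tensor)
    model = fit_mean_variance(tensor)
    return estimate_signal_noise(tensor, model)


def scale_model_features(rep: FeatureMatrix, model: NoiseModel) -> FeatureMatrix:
    """Center and globally rescale features to the neural signal variance.

    A single multiplier is applied, so all pairwise distance ratios are
    preserved; after subsequent noise injection the total variance matches
    the (unit-normalized) neural sample.
    """
    if model.sigma2_signal is None:
        raise ValueError("noise model lacks sigma2_signal; run estimate_signal_noise")
    vals = rep.values - rep.values.mean()
    total = vals.var()
    if total <= 0:
        raise ValueError("representation has zero variance")
    vals = vals * np.sqrt(model.sigma2_signal / total)
    return FeatureMatrix(vals, feature_kind=rep.feature_kind, stimuli=rep.stimuli)


def inject_noise(rep_scaled: FeatureMatrix, model: NoiseModel,
                 seed: int | np.random.Generator = 0) -> FeatureMatrix:
    """Add rate-dependent Gaussian noise at the SEM level.

    Each entry m gets an independent N(0, max(0, a*m + b)/T) draw.  Negative
    predicted variances (possible for negative normalized entries) clip to 0.
    """
    rng = np.random.default_rng(seed)
    var = model.predicted_variance(rep_scaled.values) / model.n_trials
    noisy = rep_scaled.values + rng.standard_normal(rep_scaled.values.shape) * np.sqrt(var)
    return FeatureMatrix(noisy, feature_kind=rep_scaled.feature_kind,
                         stimuli=rep_scaled.stimuli)


def noise_match(rep: FeatureMatrix, model: NoiseModel, n_features: int,
                n_repeats: int = 10,
                seed: int | np.random.Generator = 0) -> list[FeatureMatrix]:
    """Subsample features, rescale to signal variance, inject matched noise.

    Returns ``n_repeats`` independent noise draws on a single feature
    subsample; downstream metrics are reported as mean +/- std over repeats.
    """
    rng = np.random.default_rng(seed)
    sub = subsample_features(rep, n_features, rng)
    scaled = scale_model_features(sub, model)
    return [inject_noise(scaled, model, rng) for _ in range(n_repeats)]


class NoiseMatcher(BaseEstimator, TransformerMixin):
    """Estimator interface: fit the noise model on a trial tensor, then
    transform model feature matrices into noise-matched versions.

    Parameters
    ----------
    n_features : int or None
        Feature subsample size (80 for multi-unit matching, 40 for single
        units in the reference protocol); None keeps all features.
    n_repeats : int
        Independent noise draws produced by :meth:`transform_repeats`.
    normalize : bool
        Normalize the trial tensor population to unit variance before
        estimation (the reference pipeline does).
    random_state : int

    Attributes
    ----------
    a_, b_ : float        fitted mean-variance coefficients
    n_trials_ : int
    sigma2_total_, sigma2_signal_, sigma2_noise_ : float
    noise_model_ : NoiseModel
    """

    def __init__(self, n_features: int | None = 80, n_repeats: int = 10,
                 normalize: bool = True, random_state: int = 0):
        self.n_features = n_features
        self.n_repeats = n_repeats
        self.normalize = normalize
        self.random_state = random_state

    def fit(self, X: TrialTensor, y=None):
        model = fit_noise_model(X, normalize=self.normalize)
        self.noise_model_ = model
        self.a_, self.b_ = model.a, model.b
        self.n_trials_ = model.n_trials
        self.sigma2_total_ = model.sigma2_total
        self.sigma2_signal_ = model.sigma2_signal
        self.sigma2_noise_ = model.sigma2_noise
        return self

    def transform_repeats(self, rep: FeatureMatrix) -> list[FeatureMatrix]:
        n = rep.n_features if self.n_features is None else self.n_features
        return noise_match(rep, self.noise_model_, n_features=n,
                           n_repeats=self.n_repeats, seed=self.random_state)

    def transform(self, X) -> np.ndarray:
        """Single noise-matched draw; accepts an array or FeatureMatrix."""
        rep = X if isinstance(X, FeatureMatrix) else FeatureMatrix(np.asarray(X))
        return self.transform_repeats(rep)[0].values
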