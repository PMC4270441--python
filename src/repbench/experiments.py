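"""Validation experiments run entirely on synthetic data.

These are the package's built-in checks of the methodology itself:

* :func:`noise_conservativeness` reproduces the logic used to validate the
  noise model — on trial-structured synthetic data, injecting model-derived
  noise (at trial count T) into the fully trial-averaged representation
  should depress KA-AUC at least as much as restricting the empirical
  average to T trials does, because the injected condition retains the base
  representation's own residual noise on top of the injected noise.
* :func:`ranking_experiment` checks that kernel analysis and linear-SVM
  decoding order a family of graded-quality representations identically.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import spearmanr

from .data import TrialTensor, preprocess_trials
from .decoding import svm_cv_accuracy
from .kernel import KernelGrid, ka_auc, ka_curve
from .noise import NoiseModel, fit_mean_variance, estimate_signal_noise, \
    inject_noise, normalize_population, scale_model_features
from .simulate import GeneratorConfig, graded_representations, \
    make_latent_representation, make_stimulus_set, simulate_trials

__all__ = ["noise_conservativeness", "ranking_experiment", "DESK_CONFIG",
           "DESK_GRID", "CONSERVATIVENESS_CONFIG", "RANKING_CONFIG"]

# desk-scale study conditions: a 7-category task small enough for repeated
# kernel analysis, with the default geometry's nesting preserved
DESK_CONFIG = GeneratorConfig(n_categories=7, n_objects_per_category=2,
                              n_images_per_object=10, latent_dims=20,
                              n_sites=40, n_trials=47)
DESK_GRID = KernelGrid(n_sigmas=12, n_lambdas=20)

# the trial-noise comparison needs enough images and sites for AUC estimates
# stable at T=2, where trial averages are noisiest
CONSERVATIVENESS_CONFIG = replace(DESK_CONFIG, n_images_per_object=20,
                                  n_sites=80)

# the graded family needs enough image-level nuisance that its strongest
# members stay below the linear decoder's ceiling (ties at 100% accuracy
# carry no ordering information)
RANKING_CONFIG = replace(DESK_CONFIG, nuisance_signal=4.0, object_signal=1.5,
                         n_images_per_object=20)


def noise_conservativeness(T_values=(2, 6, 12, 47), n_seeds: int = 10,
                           config: GeneratorConfig = CONSERVATIVENESS_CONFIG,
                           grid: KernelGrid = DESK_GRID,
                           seed: int = 0) -> dict:
    """Compare empirical trial noise against noise-model injection.

    For each trial count T and each simulation seed: the *empirical*
    condition averages a random subset of T trials; the *injected* condition
    takes the full trial average, rescales it to the estimated signal
    variance and adds model noise at trial count T.  Returns per-T mean
    KA-AUCs and the paired margin (empirical minus injected); a nonnegative
    margin means injection is at least as punishing as real trial noise.
    """
    T_max = max(T_values)
    base = replace(config, n_trials=T_max)
    results = {T: {"auc_empirical": [], "auc_injected": []} for T in T_values}
    for s in range(n_seeds):
        cfg = replace(base, seed=seed + 1000 * s)
        stimuli = make_stimulus_set(cfg)
        labels = stimuli.categories
        latent = make_latent_representation(stimuli, cfg)
        tensor = simulate_trials(latent, cfg)
        norm = normalize_population(tensor)
        mv = fit_mean_variance(norm)
        # signal variance is a property of the recording, estimated once at
        # the full trial count; only the injected noise level depends on T
        full_model = estimate_signal_noise(norm, mv)
        full_rep = preprocess_trials(tensor)
        rng = np.random.default_rng(seed + 1000 * s + 7)
        for T in T_values:
            trial_idx = rng.choice(T_max, size=T, replace=False)
            emp_tensor = TrialTensor(counts=tensor.counts[:, :, trial_idx],
                                     blank_rate=tensor.blank_rate,
                                     window=tensor.window)
            emp_rep = preprocess_trials(emp_tensor)
            auc_emp = ka_auc(ka_curve(emp_rep, labels, grid))

            model_T = NoiseModel(a=mv.a, b=mv.b, n_trials=T,
                                 sigma2_total=full_model.sigma2_total,
                                 sigma2_signal=full_model.sigma2_signal,
                                 sigma2_noise=full_model.sigma2_noise)
            scaled = scale_model_features(full_rep, model_T)
            inj_rep = inject_noise(scaled, model_T, rng)
            auc_inj = ka_auc(ka_curve(inj_rep, labels, grid))

            results[T]["auc_empirical"].append(auc_emp)
            results[T]["auc_injected"].append(auc_inj)
    summary = {}
    for T in T_values:
        emp = np.array(results[T]["auc_empirical"])
        inj = np.array(results[T]["auc_injected"])
        summary[T] = {"auc_empirical_mean": float(emp.mean()),
                      "auc_injected_mean": float(inj.mean()),
                      "margin": float((emp - inj).mean())}
    return summary


def ranking_experiment(n_seeds: int = 5, config: GeneratorConfig = RANKING_CONFIG,
                       grid: KernelGrid = DESK_GRID,
                       ratios=(0.05, 0.15, 0.4, 1.0, 2.5),
                       n_svm_splits: int = 5, seed: int = 0) -> dict:
    """Agreement of KA-AUC and SVM-accuracy orderings of graded representations.

    Returns per-seed Spearman rho between the two rankings plus the mean
    metric values per grade.
    """
    rhos, ka_all, svm_all = [], [], []
    for s in range(n_seeds):
        cfg = replace(config, seed=seed + 31 * s)
        stimuli = make_stimulus_set(cfg)
        labels = stimuli.categories
        reps = graded_representations(stimuli, cfg, ratios=ratios)
        aucs = np.array([ka_auc(ka_curve(rep, labels, grid))
                         for rep in reps.values()])
        accs = np.array([svm_cv_accuracy(rep, labels, n_splits=n_svm_splits,
                                         seed=seed + 31 * s).mean
                         for rep in reps.values()])
        rho, _ = spearmanr(aucs, accs)
        rhos.append(float(rho))
        ka_all.append(aucs)
        svm_all.append(accs)
    return {"rho_per_seed": rhos,
            "rho_mean": float(np.mean(rhos)),
            "ka_auc": np.stack(ka_all),
            "svm_accuracy": np.stack(svm_all),
            "ratios": list(ratios)}
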