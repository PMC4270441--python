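"""End-to-end comparison workflow binding the analyses together.

For every representation: equalize sampling (subsample features), noise-match
model representations to the neural sample, then evaluate with kernel
analysis, linear-SVM decoding and (given a reference neural representation)
object-level RDM similarity and encoding models — with bootstrap subsets,
decoding splits and RDM image splits generated once and shared across all
representations, so differences between representations are never due to
different image subsets.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .data import FeatureMatrix, StimulusSet, subsample_features
from .decoding import svm_cv_accuracy
from .encoding import (compute_rdm, object_average, object_stratified_splits,
                       rdm_similarity, ridge_encode)
from .io import load_feature_matrix, load_trial_tensor, save_json
from .kernel import KernelGrid, bootstrap_ka, bootstrap_subsets
from .noise import NoiseModel, fit_noise_model, noise_match

__all__ = ["RunConfig", "compare_representations", "run_comparison"]


@dataclass
class RunConfig:
    """File-based configuration for :func:`run_comparison`."""

    stimulus_path: str
    representation_paths: dict[str, str]
    neural_path: str | None = None
    noise_tensor_path: str | None = None
    analyses: tuple[str, ...] = ("ka", "svm", "rdm")
    n_features: int = 80
    n_noise_repeats: int = 10
    n_subsets: int = 10
    n_svm_splits: int = 10
    n_rdm_splits: int = 10
    grid: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "results"


def _metric_summary(values) -> dict:
    arr = np.asarray(values, dtype=float)
    return {"mean": float(arr.mean()), "std": float(arr.std()),
            "values": arr.tolist()}


def compare_representations(representations: dict[str, FeatureMatrix],
                            stimuli: StimulusSet,
                            neural_reference: FeatureMatrix | None = None,
                            noise_model: NoiseModel | None = None,
                            analyses=("ka", "svm", "rdm"),
                            n_features: int = 80, n_noise_repeats: int = 10,
                            n_subsets: int = 10, n_svm_splits: int = 10,
                            n_rdm_splits: int = 10,
                            grid: KernelGrid | None = None,
                            seed: int = 0) -> dict:
    """Evaluate every representation under shared sampling conditions.

    Model-kind representations are noise-matched (when a noise model is
    given) and every metric is reported as mean +/- std over the noise
    repeats; neural-kind representations are subsampled only.
    """
    labels = stimuli.categories
    grid = grid or KernelGrid()
    rng = np.random.default_rng(seed)
    subsets = bootstrap_subsets(labels, n_subsets, seed=seed) if "ka" in analyses else None
    svm_splits = (list(StratifiedShuffleSplit(n_splits=n_svm_splits,
                                              train_size=0.8,
                                              random_state=seed)
                       .split(np.zeros((len(stimuli), 1)), labels))
                  if "svm" in analyses else None)
    rdm_splits = (object_stratified_splits(stimuli, n_rdm_splits, 0.2, seed)
                  if "rdm" in analyses or "encode" in analyses else None)

    ref_rdms = None
    if neural_reference is not None and "rdm" in analyses:
        ref_rdms = []
        for _, test in rdm_splits:
            M, _ = object_average(neural_reference, stimuli, test)
            ref_rdms.append(compute_rdm(M))

    report = {"seed": seed, "n_features": n_features,
              "analyses": list(analyses), "representations": {}}
    for name, rep in representations.items():
        t0 = time.perf_counter()
        n_sub = min(n_features, rep.n_features)
        if rep.is_neural or noise_model is None:
            variants = [subsample_features(rep, n_sub, rng)]
            noise_matched = False
        else:
            variants = noise_match(rep, noise_model, n_sub,
                                   n_repeats=n_noise_repeats, seed=rng)
            noise_matched = True
        entry = {"feature_kind": rep.feature_kind,
                 "noise_matched": noise_matched,
                 "n_features_used": n_sub}
        if "ka" in analyses:
            aucs = []
            for v in variants:
                curve = bootstrap_ka(v, labels, grid, subsets=subsets)
                aucs.append(float(curve.per_subset_auc.mean()))
            entry["ka_auc"] = _metric_summary(aucs)
        if "svm" in analyses:
            accs = [svm_cv_accuracy(v, labels, splits=svm_splits).mean
                    for v in variants]
            entry["svm_accuracy"] = _metric_summary(accs)
        if "rdm" in analyses and ref_rdms is not None:
            rhos = []
            for v in variants:
                for (_, test), ref in zip(rdm_splits, ref_rdms):
                    M, _ = object_average(v, stimuli, test)
                    rhos.append(rdm_similarity(compute_rdm(M), ref))
            entry["rdm_similarity"] = _metric_summary(rhos)
        if "encode" in analyses and neural_reference is not None:
            site_r = [ridge_encode(v, neural_reference, stimuli=stimuli,
                                   splits=rdm_splits).mean_site_r.mean()
                      for v in variants]
            entry["encoding_mean_site_r"] = _metric_summary(site_r)
        entry["wall_time_s"] = round(time.perf_counter() - t0, 3)
        report["representations"][name] = entry
    return report


def run_comparison(config: RunConfig) -> dict:
    """Load inputs per the config, run the comparison and write the report."""
    stimuli = StimulusSet.from_csv(config.stimulus_path)
    reps = {}
    for name, path in config.representation_paths.items():
        rep = load_feature_matrix(path)
        if rep.n_images != len(stimuli):
            raise ValueError(f"representation {path} has {rep.n_images} rows; "
                             f"stimulus set has {len(stimuli)} images")
        rep.stimuli = stimuli
        reps[name] = rep
    neural = (load_feature_matrix(config.neural_path, stimuli=stimuli)
              if config.neural_path else None)
    noise_model = None
    if config.noise_tensor_path:
        noise_model = fit_noise_model(load_trial_tensor(config.noise_tensor_path))
    grid = KernelGrid(**config.grid) if config.grid else KernelGrid()
    report = compare_representations(
        reps, stimuli, neural_reference=neural, noise_model=noise_model,
        analyses=tuple(config.analyses), n_features=config.n_features,
        n_noise_repeats=config.n_noise_repeats, n_subsets=config.n_subsets,
        n_svm_splits=config.n_svm_splits, n_rdm_splits=config.n_rdm_splits,
        grid=grid, seed=config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_json(report, out / "comparison.json")
    rows = []
    for name, entry in report["representations"].items():
        row = {"representation": name}
        for key in ("ka_auc", "svm_accuracy", "rdm_similarity",
                    "encoding_mean_site_r"):
            if key in entry:
                row[f"{key}_mean"] = entry[key]["mean"]
                row[f"{key}_std"] = entry[key]["std"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "comparison.csv", index=False)
    return report
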