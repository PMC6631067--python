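"""End-to-end workflow orchestration: train, release, privacy-eval.

These functions are the library-level backing of the CLI: each reads its
inputs from files, runs the corresponding pipeline stage and writes its
outputs, so a shell user and a Python user go through the same code.
Training persists both the model JSON and the training feature matrix —
the latter is the reference collection from which release-time noise
scales (epsilon = 3*sigma, sensitivity = range) are derived, so a
released batch never calibrates its own noise.
"""

from __future__ import annotations

import json
from pathlib import Path

from .errors import BadInputError
from .evaluation import attacker_evaluation, plot_utility_report
from .features import FeatureMatrix, extract_matrix
from .io import load_dataset, read_labels
from .learner import EnsembleModel, stratified_kfold_cv, train_adaboost
from .privacy import PrivacyConfig, obfuscate, privacy_gate


def run_train(
    data_dir,
    labels_path,
    out_dir,
    H: int = 100,
    K: int = 5,
    seed: int = 0,
    dialect: str = "paper",
) -> dict:
    """Extract features, cross-validate, train the final model.

    Writes ``model.json``, ``train_features.csv`` (the privacy reference
    collection) and ``cv_report.json`` into ``out_dir``; returns the CV
    report as a dict.
    """
    labels = read_labels(labels_path, dialect=dialect)
    dataset = load_dataset(data_dir, labels)
    fm = extract_matrix(dataset)
    cv = stratified_kfold_cv(fm, K=K, H=H, seed=seed)
    model = train_adaboost(fm, H=H, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model.to_json(out_dir / "model.json")
    fm.to_csv(out_dir / "train_features.csv")
    report = {"n_records": fm.n, "rounds": H, "folds": K, "cv": cv.as_dict()}
    with open(out_dir / "cv_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    return report


def _load_test_features(data_dir, labels_path, dialect):
    if labels_path is None:
        raise BadInputError("a label file is required to assemble the test set")
    labels = read_labels(labels_path, dialect=dialect)
    return extract_matrix(load_dataset(data_dir, labels))


def run_release(
    model_path,
    reference_path,
    data_dir,
    labels_path,
    out_path,
    stakeholder: str,
    P: int,
    seed: int = 0,
    tiered: bool = False,
    dialect: str = "paper",
) -> dict:
    """Predict on test recordings and write the gated release payload."""
    model = EnsembleModel.from_json(model_path)
    reference = FeatureMatrix.from_csv(reference_path)
    fm = _load_test_features(data_dir, labels_path, dialect)
    inference = model.predict(fm.values)
    config = PrivacyConfig(privacy_setting=P, tiered=tiered, seed=seed)
    payload = privacy_gate(fm, inference, P, stakeholder, config, reference)
    payload.to_json(out_path)
    return payload.to_dict()


def run_privacy_eval(
    model_path,
    reference_path,
    data_dir,
    labels_path,
    out_path,
    seed: int = 0,
    tiered: bool = False,
    dialect: str = "paper",
    figures_dir=None,
) -> dict:
    """Raw-vs-obfuscated utility report for the model-reuse attacker."""
    model = EnsembleModel.from_json(model_path)
    reference = FeatureMatrix.from_csv(reference_path)
    fm = _load_test_features(data_dir, labels_path, dialect)
    if fm.labels is None:
        raise BadInputError("privacy evaluation needs labeled test data")
    config = PrivacyConfig(privacy_setting=1, tiered=tiered, seed=seed)
    result = obfuscate(fm, config, reference)
    report = attacker_evaluation(model, fm, result.obfuscated, fm.labels)
    report.to_json(out_path)
    if figures_dir is not None:
        plot_utility_report(report, fm, result.obfuscated, figures_dir)
    return report.to_dict()
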