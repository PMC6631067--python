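"""Privacy–utility trade-off quantification.

Three views of what obfuscation costs an attacker who owns the trained
classifier:

* attacker inference degradation — the ensemble's accuracy, sensitivity
  and specificity on raw versus obfuscated features;
* distribution distortion — five-number (Box–Whisker) summaries of each
  feature before and after obfuscation, with the IQR ratio;
* information loss — the plug-in histogram mutual information between a
  raw feature and its obfuscated release, I(F; F_prv), compared with the
  self-information I(F; F) = H(F).

The MI estimator uses a joint equal-width histogram (default 32 bins per
axis, log base 2) whose bin edges span the pooled range of the two
inputs, so the self and cross quantities are measured on a common grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import BadInputError
from .features import FeatureMatrix
from .learner import EnsembleModel, Metrics, evaluate


def mutual_information(x, y, bins: int = 32) -> float:
    """Plug-in mutual information I(X; Y) in bits.

    Equal-width binning over the pooled range of ``x`` and ``y`` (shared
    edges for both axes); empty cells contribute 0.  For y = x this is
    exactly the plug-in entropy of x's binned distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise BadInputError("x and y must be equal-length 1-D arrays")
    if bins < 2:
        raise BadInputError("need at least 2 bins")
    if x.size < bins:
        raise BadInputError(f"need at least {bins} samples for {bins} bins")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise BadInputError("non-finite values")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if lo == hi:
        hi = lo + 1.0  # all mass in one cell; MI is 0
    edges = np.linspace(lo, hi, bins + 1)
    joint, _, _ = np.histogram2d(x, y, bins=[edges, edges])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    ratio = pxy[nz] / np.outer(px, py)[nz]
    return float(np.sum(pxy[nz] * np.log2(ratio)))


def distortion_summary(raw: FeatureMatrix, obf: FeatureMatrix) -> dict:
    """Box–Whisker five-number summaries per feature, raw vs obfuscated.

    Also reports the interquartile-range ratio obfuscated/raw, the
    single-number view of how much the mechanism inflates spread.
    """
    if raw.values.shape != obf.values.shape:
        raise BadInputError("raw and obfuscated matrices differ in shape")
    out = {}
    for j, name in enumerate(raw.feature_names):
        summary = {}
        for cond, mat in (("raw", raw), ("obfuscated", obf)):
            col = mat.values[:, j]
            q = np.percentile(col, [0, 25, 50, 75, 100])
            summary[cond] = {
                "min": float(q[0]),
                "q1": float(q[1]),
                "median": float(q[2]),
                "q3": float(q[3]),
                "max": float(q[4]),
            }
        iqr_raw = summary["raw"]["q3"] - summary["raw"]["q1"]
        iqr_obf = summary["obfuscated"]["q3"] - summary["obfuscated"]["q1"]
        summary["iqr_ratio"] = float(iqr_obf / iqr_raw) if iqr_raw > 0 else float("inf")
        out[name] = summary
    return out


@dataclass
class UtilityReport:
    """Everything the privacy evaluation measures, in one object."""

    metrics_raw: Metrics
    metrics_obf: Metrics
    mi_self: dict
    mi_cross: dict
    quartile_summary: dict

    def to_dict(self) -> dict:
        return {
            "metrics_raw": self.metrics_raw.as_dict(),
            "metrics_obf": self.metrics_obf.as_dict(),
            "mi_self_bits": self.mi_self,
            "mi_cross_bits": self.mi_cross,
            "quartile_summary": self.quartile_summary,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def attacker_evaluation(
    model: EnsembleModel,
    Ftest: FeatureMatrix,
    FtestPrv: FeatureMatrix,
    truth,
    bins: int = 32,
) -> UtilityReport:
    """Model-reuse attacker: the trained ensemble applied to both releases.

    ``metrics_raw`` is the ensemble on the raw features, ``metrics_obf``
    on the obfuscated ones (the attacker's degraded inference I_prv); MI
    quantities are per-feature marginals.
    """
    truth = np.asarray(truth, dtype=int)
    if not (Ftest.n == FtestPrv.n == truth.size):
        raise BadInputError("feature matrices and truth labels are misaligned")
    if Ftest.record_ids != FtestPrv.record_ids:
        raise BadInputError("raw and obfuscated record ids are misaligned")
    metrics_raw = evaluate(model.predict(Ftest.values), truth)
    metrics_obf = evaluate(model.predict(FtestPrv.values), truth)
    bins = min(bins, Ftest.n)  # keep the estimator defined on small batches
    mi_self, mi_cross = {}, {}
    for j, name in enumerate(Ftest.feature_names):
        raw_col = Ftest.values[:, j]
        obf_col = FtestPrv.values[:, j]
        mi_self[name] = mutual_information(raw_col, raw_col, bins=bins)
        mi_cross[name] = mutual_information(raw_col, obf_col, bins=bins)
    return UtilityReport(
        metrics_raw=metrics_raw,
        metrics_obf=metrics_obf,
        mi_self=mi_self,
        mi_cross=mi_cross,
        quartile_summary=distortion_summary(Ftest, FtestPrv),
    )


def plot_utility_report(report: UtilityReport, raw: FeatureMatrix,
                        obf: FeatureMatrix, out_dir) -> list:
    """Write Box–Whisker and MI bar figures; returns the paths written."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, axes = plt.subplots(1, len(raw.feature_names), figsize=(10, 3.2))
    for j, (name, ax) in enumerate(zip(raw.feature_names, np.atleast_1d(axes))):
        ax.boxplot([raw.values[:, j], obf.values[:, j]], tick_labels=["raw", "obf"])
        ax.set_title(name)
    fig.suptitle("Feature distortion under obfuscation")
    fig.tight_layout()
    p = out_dir / "distortion_boxplots.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.2))
    names = list(report.mi_self)
    xpos = np.arange(len(names))
    ax.bar(xpos - 0.18, [report.mi_self[n] for n in names], width=0.36, label="I(F;F)")
    ax.bar(xpos + 0.18, [report.mi_cross[n] for n in names], width=0.36,
           label="I(F;F_prv)")
    ax.set_xticks(xpos, names)
    ax.set_ylabel("bits")
    ax.set_title("Mutual-information loss")
    ax.legend()
    fig.tight_layout()
    p = out_dir / "mutual_information.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    return paths
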