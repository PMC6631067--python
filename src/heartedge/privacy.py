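"""On-demand differential-privacy obfuscation of released PCG features.

The released object is the feature matrix itself (identity query), so
per feature column the empirical sensitivity is the observed range
Delta = max - min of a reference collection, the privacy factor follows
the epsilon = 3*sigma rule (sigma the population standard deviation of
the reference column), and each released value receives independent
Laplace noise of scale b = Delta / epsilon — the standard Laplace
mechanism for epsilon-differential privacy.

"Unique in the crowd" detection runs DBSCAN (minpts = 4, radius 3 on
unit-variance-standardized coordinates, i.e. 3*sigma per dimension) over
the released rows; rows in no density cluster form the outlier set.  In
the optional tiered mode these outliers receive noise inflated by a
factor kappa > 1; by default the mechanism is uniform and the outlier
mask is reported only.

Release gating: critical stakeholders (doctors, caregivers) always get
raw features plus the inference; non-critical stakeholders get raw
features and inference while the privacy setting P = 0, and only the
obfuscated features — no inference — when the user sets P = 1.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.cluster import DBSCAN as _SKDBSCAN

from .errors import BadInputError, DegenerateDataError
from .features import FeatureMatrix

CRITICAL = "critical"
NON_CRITICAL = "non_critical"


@dataclass
class PrivacyConfig:
    """Knobs of the obfuscation mechanism.

    ``epsilon_factor`` and ``distance_factor`` are the multiples of the
    column standard deviation defining the privacy factor (epsilon =
    3*sigma) and the DBSCAN radius (3 sigma on standardized axes).
    """

    privacy_setting: int = 1
    minpts: int = 4
    distance_factor: float = 3.0
    epsilon_factor: float = 3.0
    tiered: bool = False
    tier_factor: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.privacy_setting not in (0, 1):
            raise BadInputError(f"privacy setting must be 0 or 1, got {self.privacy_setting}")
        if self.minpts < 2:
            raise BadInputError("minpts must be >= 2")
        if self.tier_factor <= 1.0:
            raise BadInputError("tier_factor must exceed 1")
        if self.distance_factor <= 0 or self.epsilon_factor <= 0:
            raise BadInputError("distance/epsilon factors must be positive")


def dbscan(points, eps_distance: float, minpts: int):
    """Classical DBSCAN; returns (cluster labels, noise mask).

    Core points have at least ``minpts`` neighbours (the point itself
    included) within ``eps_distance``; clusters are the density-
    reachability closure of core points; unreachable points are noise
    (label -1, mask True).  Euclidean metric.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < 1:
        raise BadInputError("need at least one point")
    if eps_distance <= 0:
        raise BadInputError("eps_distance must be positive")
    if not np.all(np.isfinite(pts)):
        raise BadInputError("non-finite coordinates")
    labels = _SKDBSCAN(eps=eps_distance, min_samples=minpts).fit_predict(pts)
    return labels, labels == -1


def epsilon_policy(column, factor: float = 3.0) -> float:
    """Privacy factor epsilon = 3 * sigma of the reference column.

    sigma is the population (ddof = 0) standard deviation.  Constant
    columns are degenerate: epsilon would be 0, the noise scale infinite.
    """
    col = np.asarray(column, dtype=float)
    if col.size < 2:
        raise BadInputError("need at least 2 values")
    sigma = float(np.std(col))
    if sigma == 0.0:
        raise DegenerateDataError("constant column: epsilon = 3*sigma is zero")
    return factor * sigma


def sensitivity(column) -> float:
    """Empirical identity-query sensitivity: the column range max - min."""
    col = np.asarray(column, dtype=float)
    if col.size < 2:
        raise BadInputError("need at least 2 values")
    return float(np.max(col) - np.min(col))


def laplace_noise(b: float, n: int, seed) -> np.ndarray:
    """n iid zero-location Laplace(b) draws, seeded and reproducible."""
    if b <= 0:
        raise BadInputError(f"Laplace scale must be positive, got {b}")
    return np.random.default_rng(seed).laplace(loc=0.0, scale=b, size=n)


def _record_rng(master_seed: int, record_id: str) -> np.random.Generator:
    # per-record stream so a release is reproducible and order-independent
    digest = hashlib.sha256(f"{master_seed}|{record_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


@dataclass
class ObfuscationResult:
    """Privacy-preserved feature matrix plus the mechanism's bookkeeping."""

    obfuscated: FeatureMatrix
    noise_scale_b: np.ndarray
    epsilon: np.ndarray
    sensitivity: np.ndarray
    outlier_mask: np.ndarray
    tiered: bool


def find_outliers(matrix: FeatureMatrix, config: PrivacyConfig) -> np.ndarray:
    """'Unique in the crowd' rows of a feature matrix.

    Columns are standardized to unit variance (the features live on very
    different scales) and DBSCAN runs with radius ``distance_factor``
    — i.e. 3*sigma per dimension — and ``minpts``.
    """
    vals = matrix.values
    sd = vals.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (vals - vals.mean(axis=0)) / sd
    _, noise = dbscan(z, eps_distance=config.distance_factor, minpts=config.minpts)
    return noise


def obfuscate(
    Ftest: FeatureMatrix,
    config: PrivacyConfig,
    reference: FeatureMatrix,
) -> ObfuscationResult:
    """Laplace-mechanism obfuscation of a released feature matrix.

    Per column j of the reference collection (normally the training
    features, so a released batch never sets its own noise scale):
    epsilon_j = 3*sigma_j, Delta_j = range_j, b_j = Delta_j / epsilon_j.
    Every released cell gets independent Laplace(b_j) noise drawn from a
    per-record stream keyed by (config.seed, record_id).  With
    ``config.tiered``, rows flagged as unique-in-the-crowd get scale
    kappa * b_j instead.
    """
    if reference.feature_names != Ftest.feature_names:
        raise BadInputError("reference and released matrices have different columns")
    p = len(Ftest.feature_names)
    eps = np.empty(p)
    delta = np.empty(p)
    for j in range(p):
        col = reference.values[:, j]
        eps[j] = epsilon_policy(col, factor=config.epsilon_factor)
        delta[j] = sensitivity(col)
    b = delta / eps

    outliers = find_outliers(Ftest, config)
    scales = np.tile(b, (Ftest.n, 1))
    if config.tiered:
        scales[outliers] *= config.tier_factor

    noisy = np.empty_like(Ftest.values)
    for i, rid in enumerate(Ftest.record_ids):
        rng = _record_rng(config.seed, rid)
        noisy[i] = Ftest.values[i] + rng.laplace(0.0, 1.0, p) * scales[i]

    obf = FeatureMatrix(
        record_ids=list(Ftest.record_ids),
        values=noisy,
        labels=None,
        feature_names=Ftest.feature_names,
    )
    return ObfuscationResult(
        obfuscated=obf,
        noise_scale_b=b,
        epsilon=eps,
        sensitivity=delta,
        outlier_mask=outliers,
        tiered=config.tiered,
    )


@dataclass
class ReleasePayload:
    """Stakeholder-facing output of one release."""

    stakeholder_class: str
    features: FeatureMatrix
    inference: Optional[np.ndarray]
    privacy_applied: bool

    def __post_init__(self):
        if self.privacy_applied and self.inference is not None:
            raise BadInputError("a privacy-preserved payload must omit the inference")

    def to_dict(self) -> dict:
        out = {
            "stakeholder_class": self.stakeholder_class,
            "privacy_applied": self.privacy_applied,
            "features": {
                "record_ids": list(self.features.record_ids),
                "columns": list(self.features.feature_names),
                "values": self.features.values.tolist(),
            },
        }
        if self.inference is not None:
            out["inference"] = [int(v) for v in self.inference]
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def privacy_gate(
    Ftest: FeatureMatrix,
    inference,
    P: int,
    stakeholder: str,
    config: PrivacyConfig,
    reference: FeatureMatrix,
) -> ReleasePayload:
    """Build the payload a stakeholder receives under privacy setting P.

    Critical stakeholders always receive (Ftest, I).  Non-critical
    stakeholders receive (Ftest, I) while P = 0 and, when P = 1, only
    the obfuscated features with the inference withheld.
    """
    if stakeholder not in (CRITICAL, NON_CRITICAL):
        raise BadInputError(f"unknown stakeholder class: {stakeholder!r}")
    if P not in (0, 1):
        raise BadInputError(f"privacy setting must be 0 or 1, got {P}")
    inference = None if inference is None else np.asarray(inference, dtype=int)
    if stakeholder == CRITICAL or P == 0:
        return ReleasePayload(
            stakeholder_class=stakeholder,
            features=Ftest,
            inference=inference,
            privacy_applied=False,
        )
    result = obfuscate(Ftest, config, reference)
    return ReleasePayload(
        stakeholder_class=stakeholder,
        features=result.obfuscated,
        inference=None,
        privacy_applied=True,
    )
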