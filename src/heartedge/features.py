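"""The three-dimensional PCG feature space F = {f1, f2, f3}.

Each recording x (a real-valued signal in R^d) is mapped to a
three-vector:

* ``f1`` — excess kurtosis of the squared signal y = x^2, i.e.
  E[(y - mu_y)^4] / sigma_y^4 - 3 with biased (population) moment
  estimators.  Squaring amplifies transient outliers, so murmurs and
  clicks in abnormal recordings push f1 up (leptokurtic).
* ``f2`` — maximum of the analytic-signal envelope |x + j*H(x)|, the
  peak instantaneous amplitude of the recording.
* ``f3`` — maximum over frequency of the time-averaged short-time power
  spectrum (Welch averaged periodogram): spectra of overlapping windowed
  segments are averaged over time first, then the peak over frequency
  bins is taken.  This captures how much sustained band power a
  recording carries, which murmurs raise.

f3's window is specified in seconds so the estimator is well defined for
any sampling rate; no resampling or band-pass filtering is applied
before extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .errors import (
    BadInputError,
    DegenerateSignalError,
    FeatureExtractionError,
    ShortSignalError,
)
from .io import Dataset, PCGRecord

FEATURE_NAMES = ("f1", "f2", "f3")

#: f3 defaults: 1 s Hamming windows, 50% overlap — resolves the 10–400 Hz
#: heart-sound band at fs = 2000 Hz with 1 Hz bins.
DEFAULT_WIN_SECONDS = 1.0
DEFAULT_OVERLAP = 0.5


def kurtosis_squared(x) -> float:
    """Excess kurtosis of the squared signal (feature f1).

    Uses biased moment estimators: E[(y-mu)^4]/sigma^4 - 3 over y = x^2.
    Raises :class:`DegenerateSignalError` when y is constant.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise BadInputError(f"need at least 4 samples for kurtosis, got {x.size}")
    y = x * x
    if np.ptp(y) == 0.0:
        raise DegenerateSignalError("squared signal is constant; kurtosis undefined")
    return float(spstats.kurtosis(y, fisher=True, bias=True))


def hilbert_envelope_max(x) -> float:
    """Maximum of the analytic-signal envelope (feature f2).

    The envelope sqrt(x^2 + H(x)^2) dominates |x| pointwise, so the
    result is always >= max|x|.  An all-zero signal returns 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise BadInputError(f"need at least 2 samples for the envelope, got {x.size}")
    return float(np.max(np.abs(sps.hilbert(x))))


def max_mean_power_spectrum(
    x,
    fs: float,
    win_seconds: float = DEFAULT_WIN_SECONDS,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> float:
    """Peak of the time-averaged short-time power spectrum (feature f3).

    Slides a Hamming window of ``win_seconds`` across the signal with the
    given overlap, averages the one-sided periodograms (density scaling)
    over the segments and returns the maximum over frequency bins.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(win_seconds * fs))
    if nperseg < 16:
        raise BadInputError(
            f"window of {win_seconds} s at fs={fs} gives {nperseg} samples (< 16)"
        )
    if not (0.0 <= overlap_fraction < 1.0):
        raise BadInputError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    if x.size < nperseg:
        raise ShortSignalError(
            f"signal of {x.size} samples shorter than one {nperseg}-sample window"
        )
    _, pxx = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap_fraction)),
        detrend="constant",
        scaling="density",
    )
    return float(np.max(pxx))


@dataclass(frozen=True)
class FeatureVector:
    """One recording's (f1, f2, f3)."""

    f1: float
    f2: float
    f3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3], dtype=float)


@dataclass
class FeatureMatrix:
    """Feature vectors for a collection of recordings, rows aligned to ids.

    ``values`` is (n, 3) in the fixed column order (f1, f2, f3); ``labels``
    is an optional aligned vector of +1/-1.
    """

    record_ids: list
    values: np.ndarray
    labels: Optional[np.ndarray] = None
    feature_names: tuple = FEATURE_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise BadInputError(
                f"feature matrix must be (n, {len(self.feature_names)}), "
                f"got {self.values.shape}"
            )
        if len(self.record_ids) != self.values.shape[0]:
            raise BadInputError("record_ids and rows disagree")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape[0] != self.values.shape[0]:
                raise BadInputError("labels and rows disagree")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def subset(self, indices) -> "FeatureMatrix":
        idx = np.asarray(indices)
        return FeatureMatrix(
            record_ids=[self.record_ids[i] for i in idx],
            values=self.values[idx],
            labels=None if self.labels is None else self.labels[idx],
            feature_names=self.feature_names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "record_id", self.record_ids)
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        missing = [c for c in ("record_id", *FEATURE_NAMES) if c not in df.columns]
        if missing:
            raise BadInputError(f"{Path(path).name}: missing columns {missing}")
        labels = df["label"].to_numpy(dtype=int) if "label" in df.columns else None
        return cls(
            record_ids=df["record_id"].astype(str).tolist(),
            values=df[list(FEATURE_NAMES)].to_numpy(dtype=float),
            labels=labels,
        )


def extract_features(
    record: PCGRecord,
    win_seconds: float = DEFAULT_WIN_SECONDS,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> FeatureVector:
    """Map one recording to its (f1, f2, f3) vector."""
    try:
        return FeatureVector(
            f1=kurtosis_squared(record.samples),
            f2=hilbert_envelope_max(record.samples),
            f3=max_mean_power_spectrum(
                record.samples, record.fs, win_seconds, overlap_fraction
            ),
        )
    except Exception as exc:
        raise FeatureExtractionError({record.record_id: str(exc)}) from exc


def extract_matrix(
    dataset: Dataset,
    win_seconds: float = DEFAULT_WIN_SECONDS,
    overlap_fraction: float = DEFAULT_OVERLAP,
) -> FeatureMatrix:
    """Extract features for every record; all-or-nothing.

    Per-record failures are collected and raised together as a single
    :class:`FeatureExtractionError`; no partial matrix is produced.
    """
    if dataset.n == 0:
        raise BadInputError("cannot extract features from an empty dataset")
    rows, failures = [], {}
    for rec in dataset:
        try:
            rows.append(extract_features(rec, win_seconds, overlap_fraction).as_array())
        except FeatureExtractionError as exc:
            failures.update(exc.failures)
    if failures:
        raise FeatureExtractionError(failures)
    return FeatureMatrix(
        record_ids=[r.record_id for r in dataset],
        values=np.vstack(rows),
        labels=dataset.labels,
    )
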