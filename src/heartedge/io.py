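"""Reading and writing phonocardiogram (PCG) recordings and label files.

A recording is mono PCM audio (WAV), nominally sampled at 2000 Hz and
lasting 5–120 s.  Amplitudes are rescaled to [-1, 1] at read time by the
format's full-scale value so that the amplitude-dependent features are
comparable across files.  Labels follow the convention +1 = clinically
normal, -1 = clinically abnormal; the PhysioNet/CinC 2016 REFERENCE.csv
files use the opposite sign, which the ``physionet2016`` dialect flips
on read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.io import wavfile

from .errors import (
    BadInputError,
    DatasetMismatchError,
    DuplicateIdError,
    EmptyAudioError,
    LabelValueError,
    MultiChannelAudioError,
)

NORMAL = 1
ABNORMAL = -1

#: full-scale divisor per integer PCM dtype
_FULL_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}

# label alphabets: file value -> internal label
_DIALECTS = {
    "paper": {1: NORMAL, -1: ABNORMAL},
    "physionet2016": {-1: NORMAL, 1: ABNORMAL},
}


@dataclass
class PCGRecord:
    """One heart-sound recording.

    Parameters
    ----------
    record_id : str
        Unique identifier (typically the file stem).
    samples : ndarray
        Amplitudes normalized to [-1, 1], dimensionless.
    fs : float
        Sampling rate in Hz.
    label : int, optional
        +1 clinically normal, -1 clinically abnormal.
    segments : list of (float, float, str), optional
        Annotated (start_s, end_s, kind) intervals; only populated by the
        synthetic generator, never required.
    """

    record_id: str
    samples: np.ndarray
    fs: float
    label: Optional[int] = None
    segments: Optional[list] = field(default=None, repr=False)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise BadInputError(f"{self.record_id}: fs must be positive, got {self.fs}")
        if self.samples.size < 1:
            raise EmptyAudioError(f"{self.record_id}: recording has no samples")
        if self.label is not None and self.label not in (NORMAL, ABNORMAL):
            raise LabelValueError(
                f"{self.record_id}: label must be +1 or -1, got {self.label}"
            )
        if np.max(np.abs(self.samples)) > 1.0 + 1e-9:
            raise BadInputError(f"{self.record_id}: samples exceed [-1, 1]")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class Dataset:
    """Ordered collection of :class:`PCGRecord` with unique ids.

    Ordering is a pure function of the record ids (lexicographic), never
    of filesystem enumeration order.
    """

    records: list

    def __post_init__(self):
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate record ids: {', '.join(dupes)}")
        self.records = sorted(self.records, key=lambda r: r.record_id)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> Optional[np.ndarray]:
        labs = [r.label for r in self.records]
        if any(l is None for l in labs):
            return None
        return np.array(labs, dtype=int)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def read_wav(path) -> PCGRecord:
    """Read a mono PCM WAV file into a :class:`PCGRecord`.

    Integer samples are divided by the format's full-scale value
    (e.g. 32768 for 16-bit), floats are taken as already normalized.
    The record id is the file stem; no label is attached.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    fs, data = wavfile.read(str(path))
    if data.ndim > 1:
        raise MultiChannelAudioError(
            f"{path.name}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.size == 0:
        raise EmptyAudioError(f"{path.name}: zero-length audio")
    if data.dtype in _FULL_SCALE:
        samples = data.astype(float) / _FULL_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = np.clip(data.astype(float), -1.0, 1.0)
    else:
        raise BadInputError(f"{path.name}: unsupported sample format {data.dtype}")
    return PCGRecord(record_id=path.stem, samples=samples, fs=float(fs))


def write_wav(record: PCGRecord, path) -> None:
    """Write a record as 16-bit PCM WAV (round-trips within one LSB)."""
    path = Path(path)
    x = np.clip(record.samples, -1.0, 1.0)
    # quantize against the same full scale the reader divides by
    data = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(round(record.fs)), data)


def read_labels(path, dialect: str = "paper") -> dict:
    """Read a ``record_id,label`` CSV into a map id -> {+1, -1}.

    ``dialect='paper'`` keeps the file's signs (+1 normal); the
    ``'physionet2016'`` dialect inverts them, matching the Challenge
    REFERENCE.csv convention where -1 marks a normal recording.
    """
    if dialect not in _DIALECTS:
        raise BadInputError(f"unknown label dialect: {dialect!r}")
    alphabet = _DIALECTS[dialect]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such label file: {path}")
    out: dict = {}
    with open(path, newline="") as fh:
        for row_no, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise LabelValueError(f"{path.name}:{row_no}: expected 'id,label'")
            rid = row[0].strip()
            raw = row[1].strip()
            if row_no == 1 and not _is_int(raw):
                continue  # header line
            if not _is_int(raw) or int(raw) not in alphabet:
                raise LabelValueError(
                    f"{path.name}:{row_no}: label {raw!r} outside dialect alphabet "
                    f"{sorted(alphabet)}"
                )
            if rid in out:
                raise DuplicateIdError(f"{path.name}: duplicate id {rid!r}")
            out[rid] = alphabet[int(raw)]
    if not out:
        raise BadInputError(f"{path.name}: no labels found")
    return out


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def load_dataset(audio_dir, labels: Mapping[str, int]) -> Dataset:
    """Pair WAV files in ``audio_dir`` with ``labels`` into a Dataset.

    The pairing must be exact: every label id needs a matching ``.wav``
    file and vice versa; any mismatch is reported by id.  Record order
    in the result depends only on the ids.
    """
    audio_dir = Path(audio_dir)
    if not audio_dir.is_dir():
        raise FileNotFoundError(f"no such directory: {audio_dir}")
    files = {p.stem: p for p in audio_dir.glob("*.wav")}
    label_ids = set(labels)
    file_ids = set(files)
    if not (label_ids & file_ids):
        raise DatasetMismatchError("no label id matches any audio file")
    missing_audio = sorted(label_ids - file_ids)
    missing_label = sorted(file_ids - label_ids)
    if missing_audio or missing_label:
        parts = []
        if missing_audio:
            parts.append(f"labels without audio: {', '.join(missing_audio)}")
        if missing_label:
            parts.append(f"audio without labels: {', '.join(missing_label)}")
        raise DatasetMismatchError("; ".join(parts))
    records = []
    for rid in sorted(label_ids):
        rec = read_wav(files[rid])
        rec.label = labels[rid]
        records.append(rec)
    return Dataset(records=records)
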