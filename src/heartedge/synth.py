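"""Synthetic labeled PCG recordings.

The generator is a statistical stand-in, not a physiological model: it
reproduces the structure the analysis pipeline is sensitive to — the
S1–systole–S2–diastole cycle at a given heart rate, band-limited
enveloped S1/S2 bursts, a white noise floor, and for the abnormal class
systolic murmurs (band-limited noise) plus sharp Poisson-timed
transients.  Recordings are 2000 Hz by default, 5–120 s long, written at
a fixed gain into [-1, 1].

Class structure is calibrated so the three global features behave like
the real data qualitatively: the transients raise the envelope peak
(f2) and broadband power (f3) of abnormal records markedly, and the
squared-signal kurtosis (f1) by a smaller, consistent margin on top of
a large record-to-record spread shared by both classes.  A classifier
therefore reaches high (but not perfect) accuracy on raw features,
while no feature retains a numeric class separation large relative to
the epsilon = 3*sigma Laplace scales once obfuscation is applied.

Randomness is split into two streams per record: a "base" stream for
everything a normal and an abnormal record with the same seed share
(cycle timing, burst amplitudes, noise floor), and a "pathology" stream
for murmurs and transients, so matched normal/abnormal pairs differ
only by the pathology.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import BadInputError
from .io import ABNORMAL, NORMAL, Dataset, PCGRecord, write_wav

#: defaults for the abnormal class when a caller gives no template
DEFAULT_MURMUR_INTENSITY = 0.35
DEFAULT_SPIKE_RATE = 2.0


@dataclass
class SynthParams:
    """Generator knobs.

    murmur_intensity and spike_rate_per_s are zero for the normal class
    by definition; the abnormal class needs at least one of them
    positive.
    """

    fs: float = 2000.0
    duration_s: float = 10.0
    heart_rate_bpm: float = 70.0
    s1_freq_band: tuple = (30.0, 100.0)
    s2_freq_band: tuple = (60.0, 150.0)
    murmur_intensity: float = 0.0
    spike_rate_per_s: float = 0.0
    noise_floor: float = 0.007
    seed: int = 0

    def validate(self) -> None:
        if not (5.0 <= self.duration_s <= 120.0):
            raise BadInputError(f"duration must be in [5, 120] s, got {self.duration_s}")
        top = max(self.s1_freq_band[1], self.s2_freq_band[1])
        if self.fs <= 2 * top:
            raise BadInputError(f"fs={self.fs} below Nyquist for band edge {top} Hz")
        if self.murmur_intensity < 0 or self.spike_rate_per_s < 0 or self.noise_floor < 0:
            raise BadInputError("intensities and rates must be non-negative")


def _burst(t_rel: np.ndarray, dur: float, freq: float, amp: float, phase: float):
    """Hann-enveloped tone of the given duration; zero outside [0, dur]."""
    inside = (t_rel >= 0) & (t_rel < dur)
    env = np.zeros_like(t_rel)
    env[inside] = 0.5 * (1 - np.cos(2 * np.pi * t_rel[inside] / dur))
    return amp * env * np.sin(2 * np.pi * freq * t_rel + phase)


def generate_pcg(label: int, params: SynthParams) -> PCGRecord:
    """One synthetic recording with the given class label.

    The record's ``segments`` list annotates (start_s, end_s, kind) for
    kinds 's1', 's2', 'murmur' and 'transient'.  Fully deterministic in
    ``params.seed``.
    """
    params.validate()
    pathological = params.murmur_intensity > 0 or params.spike_rate_per_s > 0
    if label == NORMAL and pathological:
        raise BadInputError("normal label with murmur/transient parameters set")
    if label == ABNORMAL and not pathological:
        raise BadInputError("abnormal label needs murmur_intensity or spike_rate > 0")
    if label not in (NORMAL, ABNORMAL):
        raise BadInputError(f"label must be +1 or -1, got {label}")

    rng_base = np.random.default_rng([params.seed, 11])
    rng_path = np.random.default_rng([params.seed, 13])

    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs
    x = np.zeros(n)
    segments = []

    # shared per-record draws (identical for a matched normal/abnormal pair)
    s1_amp = rng_base.uniform(0.10, 0.17)
    s2_amp = s1_amp * rng_base.uniform(0.65, 0.90)
    s1_freq = rng_base.uniform(*params.s1_freq_band)
    s2_freq = rng_base.uniform(*params.s2_freq_band)
    d1 = rng_base.uniform(0.07, 0.15)
    d2 = rng_base.uniform(0.06, 0.12)
    noise_sd = params.noise_floor * rng_base.uniform(0.4, 2.5)

    period = 60.0 / params.heart_rate_bpm
    t0 = 0.05
    while t0 + period <= params.duration_s:
        jitter1 = 1.0 + 0.10 * rng_base.standard_normal()
        jitter2 = 1.0 + 0.10 * rng_base.standard_normal()
        ph1, ph2 = rng_base.uniform(0, 2 * np.pi, 2)
        s2_start = t0 + 0.38 * period
        x += _burst(t - t0, d1, s1_freq, s1_amp * abs(jitter1), ph1)
        x += _burst(t - s2_start, d2, s2_freq, s2_amp * abs(jitter2), ph2)
        segments.append((t0, t0 + d1, "s1"))
        segments.append((s2_start, s2_start + d2, "s2"))
        if params.murmur_intensity > 0:
            segments.append((t0 + d1, s2_start, "murmur"))
        t0 += period

    x += noise_sd * rng_base.standard_normal(n)

    if params.murmur_intensity > 0:
        raw = rng_path.standard_normal(n)
        sos = sps.butter(4, [120.0, 420.0], btype="bandpass", fs=params.fs, output="sos")
        band = sps.sosfiltfilt(sos, raw)
        band /= band.std()
        gate = np.zeros(n)
        for a, b, kind in segments:
            if kind == "murmur":
                gate[int(a * params.fs): int(b * params.fs)] = 1.0
        level = 0.04 * params.murmur_intensity * rng_path.uniform(0.75, 1.30)
        x += level * band * gate

    if params.spike_rate_per_s > 0:
        n_spikes = rng_path.poisson(params.spike_rate_per_s * params.duration_s)
        amp_scale = rng_path.uniform(0.15, 0.30)
        for _ in range(n_spikes):
            tc = rng_path.uniform(0.05, params.duration_s - 0.05)
            width = rng_path.uniform(0.03, 0.08)
            freq = rng_path.uniform(180.0, 450.0)
            amp = amp_scale * rng_path.uniform(0.85, 1.10)
            sign = rng_path.choice([-1.0, 1.0])
            ph = rng_path.uniform(0, 2 * np.pi)
            x += sign * _burst(t - (tc - width / 2), width, freq, amp, ph)
            segments.append((tc - width / 2, tc + width / 2, "transient"))

    np.clip(x, -1.0, 1.0, out=x)
    return PCGRecord(
        record_id=f"synth-{params.seed}",
        samples=x,
        fs=params.fs,
        label=label,
        segments=sorted(segments),
    )


def generate_dataset(
    n_normal: int,
    n_abnormal: int,
    params_template: SynthParams = None,
    seed: int = 0,
) -> Dataset:
    """Labeled dataset of independent synthetic recordings.

    Per-record seeds derive from the master seed, and heart rate and
    burst frequency bands get mild record-to-record jitter around the
    template.  Record ids are ``n####`` / ``a####``; the Dataset orders
    by id, so regeneration with the same seed is byte-identical.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise BadInputError("record counts must be non-negative")
    if n_normal + n_abnormal < 2:
        raise BadInputError("need at least 2 records")
    if params_template is None:
        params_template = SynthParams(
            murmur_intensity=DEFAULT_MURMUR_INTENSITY,
            spike_rate_per_s=DEFAULT_SPIKE_RATE,
        )
    master = np.random.default_rng(seed)
    records = []
    specs = [(NORMAL, f"n{i + 1:04d}") for i in range(n_normal)]
    specs += [(ABNORMAL, f"a{i + 1:04d}") for i in range(n_abnormal)]
    for label, rid in specs:
        child_seed = int(master.integers(2**31))
        hr = params_template.heart_rate_bpm * master.uniform(0.8, 1.25)
        band_jit = master.uniform(0.9, 1.1)
        params = replace(
            params_template,
            seed=child_seed,
            heart_rate_bpm=hr,
            s1_freq_band=tuple(e * band_jit for e in params_template.s1_freq_band),
            s2_freq_band=tuple(e * band_jit for e in params_template.s2_freq_band),
        )
        if label == NORMAL:
            params = replace(params, murmur_intensity=0.0, spike_rate_per_s=0.0)
        rec = generate_pcg(label, params)
        rec.record_id = rid
        records.append(rec)
    return Dataset(records=records)


def write_dataset(dataset: Dataset, out_dir, label_file: str = "labels.csv") -> Path:
    """Write the dataset as WAV files plus a ``record_id,label`` CSV.

    Labels use the internal (+1 normal / -1 abnormal) convention, i.e.
    the io module's ``paper`` dialect.  Returns the label-file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in dataset:
        write_wav(rec, out_dir / f"{rec.record_id}.wav")
    label_path = out_dir / label_file
    with open(label_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for rec in dataset:
            writer.writerow([rec.record_id, rec.label])
    return label_path
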