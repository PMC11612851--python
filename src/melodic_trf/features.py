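"""Stimulus regressor construction.

Builds the eight-column feature matrix used by the encoding models, at the
analysis sampling rate (64 Hz by default, matching the downsampled EEG):

* ``Env``   — acoustic amplitude envelope (non-negative);
* ``EnvD``  — half-wave rectified first derivative of the envelope;
* ``O``     — binary note-onset vector (1 at each onset sample);
* ``P``     — MIDI pitch value at each onset sample, 0 elsewhere;
* ``Ho/So`` — note-onset (timing) entropy / surprisal at onset samples;
* ``Hp/Sp`` — note-pitch (content) entropy / surprisal at onset samples.

Impulse-like columns are built directly at the analysis rate (onset sample
index = round(onset * fs), ties to even, 0-based) rather than at audio rate
and decimated, which would alias the impulses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth import NoteSequence

__all__ = [
    "FEATURE_COLUMNS",
    "INFO_COLUMNS",
    "ACOUSTIC_COLUMNS",
    "FeatureMatrix",
    "onset_vector",
    "pitch_vector",
    "place_information",
    "envelope_from_waveform",
    "halfwave_derivative",
    "build_feature_matrix",
    "standardize_information",
]

FEATURE_COLUMNS = ("Env", "EnvD", "O", "P", "Ho", "So", "Hp", "Sp")
INFO_COLUMNS = ("Ho", "So", "Hp", "Sp")
ACOUSTIC_COLUMNS = ("Env", "EnvD", "O", "P")


@dataclass
class FeatureMatrix:
    """Time x feature regressor matrix with named columns."""

    data: pd.DataFrame
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def select(self, columns: Sequence[str]) -> "FeatureMatrix":
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise KeyError(f"unknown feature columns: {missing}")
        return FeatureMatrix(self.data[list(columns)].copy(), self.fs)

    def to_tsv(self, path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=False, float_format="%.10g")
        sidecar = {"fs": self.fs, "columns": list(self.data.columns)}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        df = pd.read_csv(path, sep="\t")
        return cls(df[sidecar["columns"]], float(sidecar["fs"]))


def _onset_samples(seq: NoteSequence, fs: float, n_samples: int) -> np.ndarray:
    idx = np.rint(seq.onsets * fs).astype(int)
    if len(idx) and (idx.min() < 0 or idx.max() >= n_samples):
        raise ValueError("note onset beyond the end of the signal")
    return idx


def onset_vector(seq: NoteSequence, fs: float, n_samples: int) -> np.ndarray:
    """Binary vector: 1 at each note-onset sample, 0 elsewhere.

    Two notes rounding to the same sample keep a single 1.
    """
    out = np.zeros(n_samples)
    out[_onset_samples(seq, fs, n_samples)] = 1.0
    return out


def pitch_vector(seq: NoteSequence, fs: float, n_samples: int) -> np.ndarray:
    """MIDI pitch at each onset sample, 0 elsewhere (collisions keep the later note)."""
    out = np.zeros(n_samples)
    out[_onset_samples(seq, fs, n_samples)] = seq.pitches
    return out


def place_information(
    seq: NoteSequence, values: Sequence[float], fs: float, n_samples: int
) -> np.ndarray:
    """Per-note values placed at the corresponding onset samples."""
    values = np.asarray(values, dtype=float)
    if len(values) != len(seq):
        raise ValueError(
            f"{len(values)} values for {len(seq)} notes"
        )
    out = np.zeros(n_samples)
    out[_onset_samples(seq, fs, n_samples)] = values
    return out


def envelope_from_waveform(
    wave: np.ndarray, fs_in: float, fs_out: float
) -> np.ndarray:
    """Amplitude envelope of an audio waveform, resampled to ``fs_out``.

    Magnitude of the Hilbert analytic signal, then anti-aliased polyphase
    resampling; clipped at zero (resampling ripple can dip slightly below).
    """
    if fs_out > fs_in:
        raise ValueError("fs_out must not exceed fs_in")
    env = np.abs(sps.hilbert(np.asarray(wave, dtype=float)))
    if fs_out != fs_in:
        from fractions import Fraction

        frac = Fraction(fs_out / fs_in).limit_denominator(10000)
        env = sps.resample_poly(env, frac.numerator, frac.denominator)
    return np.maximum(env, 0.0)


def halfwave_derivative(env: np.ndarray, fs: float = 1.0) -> np.ndarray:
    """Half-wave rectified first difference of the envelope, scaled by fs.

    The first sample is zero-padded so the length is preserved; negative
    slopes are set to zero.
    """
    env = np.asarray(env, dtype=float)
    if env.size < 2:
        raise ValueError("envelope must have at least 2 samples")
    d = np.diff(env, prepend=env[0]) * fs
    return np.maximum(d, 0.0)


def build_feature_matrix(
    seq: NoteSequence,
    info: pd.DataFrame,
    fs: float,
    n_samples: int | None = None,
    envelope: np.ndarray | None = None,
    envelope_tau: float = 0.1,
) -> FeatureMatrix:
    """Assemble the full eight-column matrix for one melody.

    ``info`` holds one row per note with columns Ho, So, Hp, Sp. If no
    ``envelope`` is supplied, the synthetic per-note envelope is used.
    """
    from .synth import synthesize_envelope

    if n_samples is None:
        n_samples = int(round(seq.duration_total * fs))
    if envelope is None:
        envelope = synthesize_envelope(seq, fs, tau=envelope_tau, n_samples=n_samples)
    if len(envelope) != n_samples:
        raise ValueError("envelope length does not match n_samples")
    cols = {
        "Env": np.asarray(envelope, dtype=float),
        "EnvD": halfwave_derivative(envelope, fs),
        "O": onset_vector(seq, fs, n_samples),
        "P": pitch_vector(seq, fs, n_samples),
    }
    for c in INFO_COLUMNS:
        cols[c] = place_information(seq, info[c].to_numpy(), fs, n_samples)
    return FeatureMatrix(pd.DataFrame(cols, columns=list(FEATURE_COLUMNS)), fs)


def standardize_information(
    fm: FeatureMatrix, columns: Sequence[str] = INFO_COLUMNS
) -> FeatureMatrix:
    """Optional z-scoring of information columns over their nonzero entries.

    Zeros (non-onset samples) are left untouched so sparsity is preserved.
    """
    df = fm.data.copy()
    for c in columns:
        x = df[c].to_numpy(dtype=float)
        nz = x != 0
        if nz.sum() < 2:
            continue
        mu, sd = x[nz].mean(), x[nz].std()
        if sd == 0:
            sd = 1.0
        x[nz] = (x[nz] - mu) / sd
        df[c] = x
    return FeatureMatrix(df, fm.fs)
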