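"""Band-specific EEG preprocessing.

Broadband recordings are split into six analysis bands — delta (1-4 Hz),
theta (4-8 Hz), alpha (8-12 Hz), beta (12-30 Hz), gamma (30-48 Hz) and a
low-frequency 1-8 Hz band — with zero-phase (forward-backward) second-order
Butterworth filters. Channels whose standard deviation exceeds three times
the mean SD of all other channels are replaced by distance-weighted
interpolation from the good channels; all channels are then re-referenced to
the mean of the two mastoids. For every band except delta and the
low-frequency band, the narrowband signal is converted to its instantaneous
amplitude modulation (magnitude of the Hilbert analytic signal) and
band-passed 0.5-20 Hz; the result is downsampled to 64 Hz for TRF analysis.

The pipeline order is fixed: band filter -> bad-channel handling ->
re-reference -> (amplitude extraction) -> post-filter -> downsample. Every
step appends to the recording's provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as sps

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "EEGRecording",
    "bandpass",
    "detect_bad_channels",
    "interpolate_channels",
    "rereference_mastoids",
    "band_amplitude",
    "downsample",
    "preprocess_band",
]


@dataclass(frozen=True)
class BandSpec:
    """One analysis frequency band."""

    name: str
    low: float
    high: float
    use_hilbert_amplitude: bool

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"band {self.name}: need 0 < low < high")

    def validate(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band {self.name}: high edge {self.high} Hz >= Nyquist ({fs / 2} Hz)"
            )


DEFAULT_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0, False),
    "theta": BandSpec("theta", 4.0, 8.0, True),
    "alpha": BandSpec("alpha", 8.0, 12.0, True),
    "beta": BandSpec("beta", 12.0, 30.0, True),
    "gamma": BandSpec("gamma", 30.0, 48.0, True),  # expected-null control band
    "low": BandSpec("low", 1.0, 8.0, False),
}


@dataclass
class EEGRecording:
    """Channel x time multichannel recording with layout metadata."""

    data: np.ndarray
    fs: float
    channels: list[str]
    coords: np.ndarray
    band: str = "broadband"
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.coords = np.asarray(self.coords, dtype=float)
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count does not match data rows")
        if self.coords.shape != (len(self.channels), 2):
            raise ValueError("coords must be (n_channels, 2)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def _evolve(self, data: np.ndarray, entry: str, **kw) -> "EEGRecording":
        new = replace(self, data=data, **kw)
        new.log = self.log + [entry]
        return new

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.create_dataset("fs", data=self.fs)
            f.create_dataset(
                "channels", data=np.array(self.channels, dtype="S16")
            )
            f.create_dataset("coords", data=self.coords)
            f.attrs["band"] = self.band
            f.attrs["log"] = "\n".join(self.log)

    @classmethod
    def from_hdf5(cls, path) -> "EEGRecording":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()].astype(float),
                fs=float(f["fs"][()]),
                channels=[c.decode() for c in f["channels"][()]],
                coords=f["coords"][()],
                band=str(f.attrs.get("band", "broadband")),
                log=[s for s in str(f.attrs.get("log", "")).split("\n") if s],
            )


def _butter_sos(low: float, high: float, fs: float) -> np.ndarray:
    return sps.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(eeg: EEGRecording, band: BandSpec) -> EEGRecording:
    """Zero-phase band-pass (two-pass 2nd-order Butterworth, order 4 net)."""
    band.validate(eeg.fs)
    sos = _butter_sos(band.low, band.high, eeg.fs)
    data = sps.sosfiltfilt(sos, eeg.data, axis=1)
    return eeg._evolve(
        data, f"bandpass {band.name} {band.low}-{band.high} Hz", band=band.name
    )


def detect_bad_channels(eeg: EEGRecording) -> list[int]:
    """Channels whose SD strictly exceeds 3x the mean SD of the others.

    Single pass over the full recording; returns channel indices.
    """
    if eeg.n_channels < 3:
        raise ValueError("need at least 3 channels")
    sd = eeg.data.std(axis=1)
    total = sd.sum()
    n = eeg.n_channels
    bads = []
    for c in range(n):
        mean_others = (total - sd[c]) / (n - 1)
        if sd[c] > 3.0 * mean_others:
            bads.append(c)
    return bads


def interpolate_channels(eeg: EEGRecording, bads: list[int]) -> EEGRecording:
    """Replace bad channels with normalized inverse-distance-weighted sums.

    Weights are 1/d^2 over good channels, normalized to 1, so interpolated
    samples always lie within [min, max] of the good-channel values.
    """
    if not bads:
        return eeg._evolve(eeg.data.copy(), "interpolate: none flagged")
    good = [c for c in range(eeg.n_channels) if c not in set(bads)]
    if len(good) < 3:
        raise ValueError("fewer than 3 good channels; cannot interpolate")
    data = eeg.data.copy()
    for b in bads:
        d2 = ((eeg.coords[good] - eeg.coords[b]) ** 2).sum(axis=1)
        if np.any(d2 == 0):
            w = (d2 == 0).astype(float)
        else:
            w = 1.0 / d2
        w /= w.sum()
        data[b] = w @ eeg.data[good]
    return eeg._evolve(data, f"interpolate: channels {sorted(bads)}")


def rereference_mastoids(
    eeg: EEGRecording, mastoids: tuple[str, str] = ("M1", "M2")
) -> EEGRecording:
    """Subtract the instantaneous mean of the two mastoid channels."""
    try:
        i, j = (eeg.channels.index(m) for m in mastoids)
    except ValueError as err:
        raise ValueError(f"mastoid label missing: {err}") from None
    ref = 0.5 * (eeg.data[i] + eeg.data[j])
    return eeg._evolve(eeg.data - ref, f"rereference to mean({mastoids})")


def band_amplitude(
    eeg: EEGRecording,
    band: BandSpec,
    post_low: float = 0.5,
    post_high: float = 20.0,
) -> EEGRecording:
    """Instantaneous amplitude modulation of a narrowband recording.

    Magnitude of the Hilbert analytic signal per channel, then a zero-phase
    0.5-20 Hz band-pass to keep only the modulation frequencies relevant to
    the TRF analysis. Not applicable to the delta / low bands, whose
    waveforms enter the TRF directly.
    """
    if not band.use_hilbert_amplitude:
        raise ValueError(
            f"band {band.name} is analysed as a waveform, not an amplitude"
        )
    analytic = sps.hilbert(eeg.data, axis=1)
    amp = np.abs(analytic)
    sos = _butter_sos(post_low, post_high, eeg.fs)
    data = sps.sosfiltfilt(sos, amp, axis=1)
    return eeg._evolve(
        data, f"hilbert amplitude + {post_low}-{post_high} Hz post-filter"
    )


def downsample(eeg: EEGRecording, fs_out: float = 64.0) -> EEGRecording:
    """Anti-aliased polyphase resampling to ``fs_out``."""
    if fs_out > eeg.fs:
        raise ValueError("upsampling is not supported")
    if fs_out == eeg.fs:
        return eeg._evolve(eeg.data.copy(), "downsample: no-op (already at rate)")
    frac = Fraction(fs_out / eeg.fs).limit_denominator(1000)
    data = sps.resample_poly(eeg.data, frac.numerator, frac.denominator, axis=1)
    return eeg._evolve(data, f"downsample {eeg.fs} -> {fs_out} Hz", fs=fs_out)


def preprocess_band(
    eeg: EEGRecording,
    band: BandSpec | str,
    mastoids: tuple[str, str] = ("M1", "M2"),
    fs_out: float = 64.0,
) -> EEGRecording:
    """Full per-band pipeline in the fixed order.

    band filter -> bad-channel detect/interpolate -> mastoid re-reference ->
    (Hilbert amplitude + 0.5-20 Hz post-filter, non-delta bands) ->
    downsample to ``fs_out``.
    """
    if isinstance(band, str):
        band = DEFAULT_BANDS[band]
    out = bandpass(eeg, band)
    bads = detect_bad_channels(out)
    out = interpolate_channels(out, bads)
    out = rereference_mastoids(out, mastoids)
    if band.use_hilbert_amplitude:
        out = band_amplitude(out, band)
    out = downsample(out, fs_out)
    if not np.all(np.isfinite(out.data)):
        raise RuntimeError("non-finite samples after preprocessing")
    return out
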