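"""Synthetic melody/EEG cohort with known ground truth.

The real study data (Bach piano melodies, 20 listeners, 64-channel EEG) are
not needed to exercise the pipeline: this module generates

* melodies from a first-order Markov model over a pitch alphabet and a
  first-order Markov model over discretized inter-onset-interval (IOI)
  categories — a pluggable stand-in for the variable-order statistical model
  (IDyOM) that supplied note probabilities in the original analyses;
* exact per-note information features (onset/pitch entropy and surprisal)
  computed analytically from that generative model;
* a gated decaying-exponential amplitude envelope as a surrogate for the
  Hilbert envelope of a piano recording;
* multi-channel EEG by convolving stimulus features with known ground-truth
  response kernels, scaled by smooth channel-topography gain maps, plus
  1/f^alpha (pink) and white sensor noise.

Because the note probabilities are known exactly, surprisal
``S = log2(1/p(e_i | context))`` and entropy
``H = sum_e p(e | context) * log2(1/p(e | context))`` are computed in closed
form rather than estimated.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .layout import make_layout
from .preprocess import EEGRecording
from .trf import LagWindow

__all__ = [
    "MarkovMelodyModel",
    "NoteSequence",
    "GroundTruthKernels",
    "CohortSpec",
    "generate_melody",
    "analytic_information",
    "synthesize_envelope",
    "topography_gains",
    "simulate_eeg",
    "kernel_recovery",
    "make_cohort",
    "gaussian_kernel",
    "default_kernels",
]

_PROB_TOL = 1e-12


def _check_distribution(p: np.ndarray, what: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError(f"{what}: negative probability")
    if abs(p.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"{what}: probabilities sum to {p.sum()!r}, not 1")
    return p


@dataclass
class MarkovMelodyModel:
    """Markov note-probability model over pitches and IOI categories.

    The pitch process is an order-``order`` Markov chain over
    ``pitch_alphabet`` (contexts shorter than ``order`` fall back to
    ``pitch_initial``). The timing process is a first-order Markov chain over
    the discrete IOI categories ``ioi_values`` (seconds).
    """

    pitch_alphabet: list[int]
    pitch_transition: dict[tuple[int, ...], np.ndarray]
    pitch_initial: np.ndarray
    ioi_values: np.ndarray
    ioi_transition: np.ndarray  # (K, K) row-stochastic
    ioi_initial: np.ndarray
    order: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pitch_alphabet) == 0:
            raise ValueError("empty pitch alphabet")
        self.pitch_initial = _check_distribution(self.pitch_initial, "pitch_initial")
        self.ioi_initial = _check_distribution(self.ioi_initial, "ioi_initial")
        self.ioi_values = np.asarray(self.ioi_values, dtype=float)
        if np.any(self.ioi_values <= 0):
            raise ValueError("IOI support must be positive")
        self.ioi_transition = np.asarray(self.ioi_transition, dtype=float)
        for k, row in enumerate(self.ioi_transition):
            _check_distribution(row, f"ioi_transition[{k}]")
        for ctx, p in self.pitch_transition.items():
            self.pitch_transition[ctx] = _check_distribution(
                p, f"pitch_transition[{ctx}]"
            )
            if len(ctx) != self.order:
                raise ValueError("pitch context length must equal model order")

    @classmethod
    def random(
        cls,
        n_pitches: int = 12,
        lowest_pitch: int = 60,
        order: int = 1,
        seed: int = 0,
        concentration: float = 0.3,
        ioi_values: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    ) -> "MarkovMelodyModel":
        """Random model with Dirichlet transition rows.

        Small ``concentration`` gives peaky (predictable) transitions, hence
        a wide dynamic range of surprisal and entropy across notes.
        """
        rng = np.random.default_rng(seed)
        alphabet = list(range(lowest_pitch, lowest_pitch + n_pitches))
        if order != 1:
            raise NotImplementedError("random factory supports order=1")
        trans = {
            (p,): rng.dirichlet(np.full(n_pitches, concentration))
            for p in alphabet
        }
        K = len(ioi_values)
        ioi_trans = np.stack([rng.dirichlet(np.full(K, 0.8)) for _ in range(K)])
        return cls(
            pitch_alphabet=alphabet,
            pitch_transition=trans,
            pitch_initial=np.full(n_pitches, 1.0 / n_pitches),
            ioi_values=np.asarray(ioi_values, dtype=float),
            ioi_transition=ioi_trans,
            ioi_initial=np.full(K, 1.0 / K),
            order=order,
            seed=seed,
        )

    def pitch_distribution(self, context: Sequence[int]) -> np.ndarray:
        """p(. | context) over the pitch alphabet."""
        ctx = tuple(context)[-self.order :] if len(context) >= self.order else ()
        if len(ctx) < self.order:
            return self.pitch_initial
        try:
            return self.pitch_transition[ctx]
        except KeyError:
            raise KeyError(f"no transition row for pitch context {ctx}") from None

    def ioi_index(self, ioi: float, tol: float = 1e-6) -> int:
        """Index of the IOI category matching a realized interval."""
        d = np.abs(self.ioi_values - ioi)
        k = int(np.argmin(d))
        if d[k] > tol:
            raise ValueError(
                f"realized IOI {ioi:.6f}s matches no category "
                f"(zero-probability event under this model)"
            )
        return k


@dataclass
class NoteSequence:
    """Ordered note events of one melody/trial."""

    onsets: np.ndarray  # seconds, strictly increasing
    pitches: np.ndarray  # MIDI integers
    durations: np.ndarray  # seconds > 0
    duration_total: float
    velocities: np.ndarray | None = None  # relative loudness in (0, 1]

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.pitches = np.asarray(self.pitches, dtype=int)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.velocities is None:
            self.velocities = np.ones_like(self.onsets)
        else:
            self.velocities = np.asarray(self.velocities, dtype=float)
        if not (
            len(self.onsets)
            == len(self.pitches)
            == len(self.durations)
            == len(self.velocities)
        ):
            raise ValueError("onsets, pitches, durations must have equal length")
        if np.any(self.velocities <= 0):
            raise ValueError("velocities must be positive")
        if len(self.onsets) and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")
        if len(self.onsets) and np.any(
            self.onsets + self.durations > self.duration_total + 1e-9
        ):
            raise ValueError("note extends past duration_total")

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def iois(self) -> np.ndarray:
        """Inter-onset intervals; the first note's IOI is its onset time."""
        if len(self.onsets) == 0:
            return np.empty(0)
        return np.diff(self.onsets, prepend=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.onsets,
                "midi_pitch": self.pitches,
                "duration_s": self.durations,
                "velocity": self.velocities,
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.attrs["duration_total"] = self.duration_total
        with open(path, "w") as fh:
            fh.write(f"# duration_total_s={self.duration_total!r}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "NoteSequence":
        with open(path) as fh:
            first = fh.readline()
            total = None
            if first.startswith("# duration_total_s="):
                total = float(first.split("=", 1)[1])
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        if total is None:
            total = float((df["onset_s"] + df["duration_s"]).max())
        return cls(
            onsets=df["onset_s"].to_numpy(),
            pitches=df["midi_pitch"].to_numpy(),
            durations=df["duration_s"].to_numpy(),
            duration_total=total,
            velocities=(
                df["velocity"].to_numpy() if "velocity" in df.columns else None
            ),
        )


def generate_melody(
    model: MarkovMelodyModel, length_s: float, seed: int
) -> NoteSequence:
    """Sample a melody of approximately ``length_s`` seconds from the model.

    Notes are emitted until the next onset would fall beyond ``length_s``.
    Note durations are 90% of the gap to the following onset (legato-ish
    piano articulation), so notes never overlap.
    """
    if length_s <= 0:
        raise ValueError("length_s must be positive")
    rng = np.random.default_rng(seed)
    # inverse-CDF sampling (cheaper than rng.choice in a tight loop)
    ioi_cum = {None: np.cumsum(model.ioi_initial)}
    for k in range(len(model.ioi_values)):
        ioi_cum[k] = np.cumsum(model.ioi_transition[k])
    pitch_cum: dict = {}

    onsets: list[float] = []
    pitches: list[int] = []
    ioi_idx: list[int] = []
    t = 0.0
    while True:
        prev = ioi_idx[-1] if ioi_idx else None
        k = int(np.searchsorted(ioi_cum[prev], rng.random()))
        t_next = t + model.ioi_values[k]
        # leave a margin so the final onset never rounds past the last
        # sample at any analysis rate >= 16 Hz
        if t_next > length_s - 0.05:
            break
        ctx = tuple(pitches[-model.order :]) if len(pitches) >= model.order else ()
        if ctx not in pitch_cum:
            pitch_cum[ctx] = np.cumsum(model.pitch_distribution(ctx))
        j = int(np.searchsorted(pitch_cum[ctx], rng.random()))
        onsets.append(t_next)
        pitches.append(model.pitch_alphabet[j])
        ioi_idx.append(k)
        t = t_next

    onsets_arr = np.asarray(onsets)
    gaps = np.diff(onsets_arr, append=length_s)
    durations = np.maximum(0.9 * gaps, 1e-3)
    durations = np.minimum(durations, length_s - onsets_arr)
    # per-note loudness (piano dynamics); also keeps the envelope from being
    # an exact linear function of the onset train
    velocities = rng.uniform(0.4, 1.0, size=len(onsets_arr))
    return NoteSequence(
        onsets=onsets_arr,
        pitches=np.asarray(pitches, dtype=int),
        durations=durations,
        duration_total=float(length_s),
        velocities=velocities,
    )


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def analytic_information(
    model: MarkovMelodyModel, seq: NoteSequence
) -> pd.DataFrame:
    """Exact per-note entropy and surprisal, in bits.

    Columns ``Ho``/``So`` come from the IOI (timing) process, ``Hp``/``Sp``
    from the pitch process. Surprisal of note i is the negative log2
    probability of the realized event given its context; entropy is the
    expected surprisal over all possible continuations of that context.
    A realized event with model probability zero is rejected.
    """
    n = len(seq)
    out = np.zeros((n, 4))
    alphabet_index = {p: i for i, p in enumerate(model.pitch_alphabet)}
    iois = seq.iois
    prev_k: int | None = None
    for i in range(n):
        # timing stream
        k = model.ioi_index(iois[i])
        dist_o = model.ioi_initial if prev_k is None else model.ioi_transition[prev_k]
        p_o = float(dist_o[k])
        if p_o <= 0:
            raise ValueError(f"note {i}: realized IOI has probability 0")
        prev_k = k
        # pitch stream
        try:
            j = alphabet_index[int(seq.pitches[i])]
        except KeyError:
            raise ValueError(f"note {i}: pitch outside the model alphabet") from None
        dist_p = model.pitch_distribution(seq.pitches[:i].tolist())
        p_p = float(dist_p[j])
        if p_p <= 0:
            raise ValueError(f"note {i}: realized pitch has probability 0")
        out[i] = (
            _entropy_bits(dist_o),
            -np.log2(p_o),
            _entropy_bits(dist_p),
            -np.log2(p_p),
        )
    return pd.DataFrame(out, columns=["Ho", "So", "Hp", "Sp"])


def synthesize_envelope(
    seq: NoteSequence,
    fs: float,
    tau: float = 0.05,
    tau_slow: float = 0.4,
    n_samples: int | None = None,
) -> np.ndarray:
    """Surrogate amplitude envelope: per-note gated decaying exponentials.

    Each note contributes a velocity-scaled mix of a fast (``tau``) and a
    slow (``tau_slow``) exponential decay, gated to the note duration; the
    mixing weight depends on the pitch class, mimicking the brighter attack
    and longer sustain of different piano registers. Contributions add
    linearly; the result is non-negative and each note's profile peaks at
    its onset.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n_samples is None:
        n_samples = int(round(seq.duration_total * fs))
    t = np.arange(n_samples) / fs
    env = np.zeros(n_samples)
    for onset, dur, vel, pitch in zip(
        seq.onsets, seq.durations, seq.velocities, seq.pitches
    ):
        mask = (t >= onset) & (t <= onset + dur)
        dt = t[mask] - onset
        a = 0.2 + 0.6 * (int(pitch) % 12) / 11.0
        env[mask] += vel * (
            a * np.exp(-dt / tau) + (1 - a) * np.exp(-dt / tau_slow)
        )
    return env


# ---------------------------------------------------------------------------
# Ground-truth response kernels and the EEG forward model
# ---------------------------------------------------------------------------


def gaussian_kernel(
    window: LagWindow, latency_ms: float, width_ms: float, amplitude: float = 1.0
) -> np.ndarray:
    """Gaussian bump over the lag axis, peaking at ``latency_ms``."""
    t = window.times_ms
    return amplitude * np.exp(-0.5 * ((t - latency_ms) / width_ms) ** 2)


@dataclass
class GroundTruthKernels:
    """Known per-(band, feature) response kernels over a lag window."""

    window: LagWindow
    kernels: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        L = self.window.n_lags
        for key, k in self.kernels.items():
            k = np.asarray(k, dtype=float)
            if k.shape != (L,):
                raise ValueError(f"kernel {key}: length {k.shape} != lag axis {L}")
            if not np.all(np.isfinite(k)):
                raise ValueError(f"kernel {key}: non-finite values")
            self.kernels[key] = k

    @property
    def bands(self) -> list[str]:
        return sorted({b for b, _ in self.kernels})

    @property
    def features(self) -> list[str]:
        return sorted({f for _, f in self.kernels})

    def band_kernels(self, band: str) -> dict[str, np.ndarray]:
        return {f: k for (b, f), k in self.kernels.items() if b == band}


def default_kernels(
    window: LagWindow,
    bands: Sequence[str] = ("delta", "theta", "alpha", "beta"),
    features: Sequence[str] = ("Env", "EnvD", "Ho", "Hp"),
) -> GroundTruthKernels:
    """Distinct latency/polarity per feature and band.

    Latencies stagger across features and shorten toward higher bands; the
    onset-entropy (``Ho``) kernel in the delta band carries an additional
    pre-onset negative lobe, mimicking anticipatory encoding of temporal
    predictability.
    """
    band_speed = {"delta": 1.0, "low": 1.0, "theta": 0.8, "alpha": 0.6, "beta": 0.5,
                  "gamma": 0.4}
    kernels: dict[tuple[str, str], np.ndarray] = {}
    for b in bands:
        speed = band_speed.get(b, 1.0)
        for i, f in enumerate(features):
            lat = speed * (90.0 + 70.0 * i)
            sign = 1.0 if i % 2 == 0 else -1.0
            k = gaussian_kernel(window, lat, 45.0 * speed, sign)
            if f == "Ho" and b in ("delta", "beta"):
                k = k + gaussian_kernel(window, -70.0, 35.0, -0.7)
            kernels[(b, f)] = k
    return GroundTruthKernels(window=window, kernels=kernels)


@dataclass
class CohortSpec:
    """Shape and noise model of the simulated cohort.

    Defaults mirror the real dataset's shape: 20 subjects (half musicians),
    10 melodies of ~150 s each presented 3 times (30 trials), 64 channels at
    512 Hz. ``snr`` is the ratio of per-channel signal SD (channel average)
    to total noise SD; noise is pink (1/f^``pink_exponent``) plus white, with
    ``pink_fraction`` of the noise variance in the pink component.
    """

    n_subjects: int = 20
    n_melodies: int = 10
    n_repeats: int = 3
    melody_length_s: float = 150.0
    n_channels: int = 64
    fs_eeg: float = 512.0
    fs_analysis: float = 64.0
    pink_exponent: float = 1.0
    pink_fraction: float = 0.8
    snr: float = 1.0
    musician_gain: float = 1.0
    nonmusician_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.fs_eeg <= 0 or self.fs_analysis <= 0:
            raise ValueError("sampling rates must be positive")
        if not 0 <= self.pink_fraction <= 1:
            raise ValueError("pink_fraction must be in [0, 1]")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_melodies * self.n_repeats

    @property
    def groups(self) -> list[str]:
        half = self.n_subjects // 2
        return [
            "musician" if s < half else "nonmusician"
            for s in range(self.n_subjects)
        ]

    def group_gain(self, subject: int) -> float:
        return (
            self.musician_gain
            if self.groups[subject] == "musician"
            else self.nonmusician_gain
        )


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def topography_gains(
    coords: np.ndarray, features: Sequence[str], seed: int
) -> dict[str, np.ndarray]:
    """Smooth random gain map per feature over the electrode layout.

    Each feature gets a Gaussian blob with a random center inside the head
    outline, giving spatially clustered (hence cluster-testable) effects.
    Deterministic in (seed, feature name).
    """
    gains = {}
    for f in sorted(features):
        tag = zlib.crc32(f.encode("utf8"))
        rng = np.random.default_rng(_derive_seed(seed, 211, tag))
        center = rng.uniform(-0.6, 0.6, size=2)
        sigma = rng.uniform(0.5, 0.8)
        d2 = ((coords - center) ** 2).sum(axis=1)
        gains[f] = np.exp(-0.5 * d2 / sigma**2)
    return gains


def convolve_lagged(x: np.ndarray, kernel: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """y[t] = sum_tau kernel[tau] * x[t - tau], zero-padded, same length."""
    n = len(x)
    lo = int(lags[0])
    full = np.convolve(x, kernel)
    y = np.zeros(n)
    idx = np.arange(n) - lo
    valid = (idx >= 0) & (idx < len(full))
    y[valid] = full[idx[valid]]
    return y


def _pink_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, exponent: float
) -> np.ndarray:
    """Unit-SD 1/f^exponent noise per channel (FFT-filtered white noise)."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    f[0] = f[1]  # avoid division by zero; DC treated like the lowest bin
    spec *= f ** (-exponent / 2.0)
    pink = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def simulate_eeg(
    features,
    kernels: GroundTruthKernels,
    cohort: CohortSpec,
    subject: int,
    trial: int,
    band: str | None = None,
    gains: Mapping[str, np.ndarray] | None = None,
) -> EEGRecording:
    """Forward-simulate one trial of EEG from stimulus features.

    ``features`` is a FeatureMatrix (or anything with ``values``, ``columns``
    and ``fs``) sampled at the kernel window's rate. With ``band`` given,
    only that band's kernels drive the signal and no band filtering is
    applied (the recording represents that band directly). With
    ``band=None``, every band's contribution is filtered into its frequency
    range before summing, yielding a broadband recording for the full
    preprocessing pipeline.

    Channel c receives ``gain[c] * (feature (*) kernel)`` summed over
    features, plus pink and white noise scaled to the cohort's SNR. The
    noise realization is reproducible from (cohort.seed, subject, trial).
    """
    from .preprocess import DEFAULT_BANDS  # local import avoids cycle at load

    X = np.asarray(features.values, dtype=float)
    names = list(features.columns)
    fs = float(features.fs)
    if abs(fs - kernels.window.fs) > 1e-9:
        raise ValueError("feature sampling rate must match the kernel lag axis")
    n = X.shape[0]
    labels, coords = make_layout(cohort.n_channels)
    if gains is None:
        gains = topography_gains(coords, kernels.features, cohort.seed)
    g_scale = cohort.group_gain(subject)

    acoustic = {"Env", "EnvD", "O", "P"}
    lags = kernels.window.lags
    signal = np.zeros((cohort.n_channels, n))
    band_list = [band] if band is not None else kernels.bands
    for b in band_list:
        contrib = np.zeros((cohort.n_channels, n))
        for f, k in kernels.band_kernels(b).items():
            if f not in names:
                raise ValueError(f"kernel feature {f!r} missing from features")
            y = convolve_lagged(X[:, names.index(f)], k, lags)
            gain = gains[f] * (1.0 if f in acoustic else g_scale)
            contrib += np.outer(gain, y)
        if band is None and b in DEFAULT_BANDS:
            from scipy import signal as sps

            spec = DEFAULT_BANDS[b]
            sos = sps.butter(
                2, [spec.low, spec.high], btype="bandpass", fs=fs, output="sos"
            )
            contrib = sps.sosfiltfilt(sos, contrib, axis=1)
        signal += contrib

    rng = np.random.default_rng(
        np.random.SeedSequence([cohort.seed, 1 + subject, 1 + trial])
    )
    sig_sd = float(signal.std(axis=1).mean())
    noise_sd = sig_sd / cohort.snr if sig_sd > 0 else 1.0
    pink = _pink_noise(rng, cohort.n_channels, n, cohort.pink_exponent)
    white = rng.standard_normal((cohort.n_channels, n))
    noise = noise_sd * (
        np.sqrt(cohort.pink_fraction) * pink
        + np.sqrt(1 - cohort.pink_fraction) * white
    )
    return EEGRecording(
        data=signal + noise,
        fs=fs,
        channels=labels,
        coords=coords,
        band=band or "broadband",
        log=[f"simulated subject={subject} trial={trial} snr={cohort.snr}"],
    )


def kernel_recovery(
    fold_models,
    kernels: GroundTruthKernels,
    band: str,
    gains: Mapping[str, np.ndarray],
) -> dict[str, float]:
    """Fold-mean correlation between estimated and planted kernels.

    For each planted feature, the per-channel weight curves of a fitted TRF
    are projected onto the known topography gains (least squares across
    channels), giving one estimated kernel per fold; the returned value is
    the mean over folds of its Pearson correlation with the ground truth.
    """
    out = {}
    for f, true in kernels.band_kernels(band).items():
        g = np.asarray(gains[f], dtype=float)
        rs = []
        for model in fold_models:
            W = model.weights[:, :, model.feature_names.index(f)]
            est = (g @ W) / (g @ g)
            rs.append(float(np.corrcoef(est, true)[0, 1]))
        out[f] = float(np.mean(rs))
    return out


def make_cohort(
    cohort: CohortSpec,
    model: MarkovMelodyModel,
    kernels: GroundTruthKernels,
    outdir,
) -> dict:
    """Write a full synthetic dataset to ``outdir`` and return its manifest.

    Layout: ``melodies/melody_<m>.csv``, ``features/melody_<m>.tsv`` (+ JSON
    sidecar, at the analysis rate), ``eeg/sub<s>_trial<t>.h5``, and
    ``manifest.json`` recording every derived seed, file and group label.
    Deterministic for a fixed spec: regeneration overwrites byte-identically.
    """
    from . import features as feat

    outdir = Path(outdir)
    for sub in ("melodies", "features", "eeg"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    melody_seeds = [_derive_seed(cohort.seed, 17, m) for m in range(cohort.n_melodies)]
    manifest: dict = {
        "cohort": {
            k: getattr(cohort, k)
            for k in (
                "n_subjects", "n_melodies", "n_repeats", "melody_length_s",
                "n_channels", "fs_eeg", "fs_analysis", "pink_exponent",
                "pink_fraction", "snr", "musician_gain", "nonmusician_gain",
                "seed",
            )
        },
        "groups": cohort.groups,
        "melody_seeds": melody_seeds,
        "melodies": [],
        "features": [],
        "eeg": [],
    }

    sim_fms = []
    for m in range(cohort.n_melodies):
        seq = generate_melody(model, cohort.melody_length_s, melody_seeds[m])
        info = analytic_information(model, seq)
        mel_path = outdir / "melodies" / f"melody_{m:02d}.csv"
        seq.to_csv(mel_path)
        fm = feat.build_feature_matrix(seq, info, cohort.fs_analysis)
        fm_path = outdir / "features" / f"melody_{m:02d}.tsv"
        fm.to_tsv(fm_path)
        sim_fms.append(feat.build_feature_matrix(seq, info, cohort.fs_eeg))
        manifest["melodies"].append(str(mel_path.relative_to(outdir)))
        manifest["features"].append(str(fm_path.relative_to(outdir)))

    for s in range(cohort.n_subjects):
        for t in range(cohort.n_trials):
            m = t // cohort.n_repeats
            eeg = simulate_eeg(sim_fms[m], kernels, cohort, s, t)
            path = outdir / "eeg" / f"sub{s:02d}_trial{t:02d}.h5"
            eeg.to_hdf5(path)
            manifest["eeg"].append(
                {
                    "subject": s,
                    "trial": t,
                    "melody": m,
                    "path": str(path.relative_to(outdir)),
                }
            )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
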