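"""Model-comparison ledger for the encoding analysis.

The analysis contrasts TRF models trained on nested regressor sets:

* ``A`` — acoustic baseline (envelope and its rectified derivative; the
  onset and pitch vectors can be added via ``include_onset_pitch``);
* ``AF`` — A plus one or more melodic information features
  (``AHo``, ``AHp``, ``ASo``, ``ASp``, and the combined ``AMo``, ``AMp``,
  ``AH``, ``AS``);
* ``AM`` — the full model with all four information features;
* ``AM-F`` — AM missing one information feature (``AM-Ho`` etc.);
* ``AMshuffled`` — AM with the nonzero entropy/surprisal values permuted
  among their own onset positions, a dimensionality-matched null.

Two derived metrics: *enhancement* of a model over A (gain in channel-mean
reconstruction accuracy) and *unique contribution* of a feature
(r(AM) - r(AM-F)), which controls for collinearity among regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import ACOUSTIC_COLUMNS, INFO_COLUMNS, FeatureMatrix
from .trf import LagWindow, nested_cv

__all__ = [
    "ModelSpec",
    "ComparisonTable",
    "build_model_specs",
    "shuffle_information",
    "evaluate_ledger",
]


@dataclass(frozen=True)
class ModelSpec:
    """One TRF model: a named set of feature columns, optionally shuffled."""

    name: str
    features: tuple[str, ...]
    shuffle: tuple[str, ...] = ()
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.shuffle) - set(self.features)
        if unknown:
            raise ValueError(f"shuffle columns not in feature set: {unknown}")


def build_model_specs(
    acoustic: Sequence[str] = ("Env", "EnvD"),
    include_onset_pitch: bool = False,
    shuffle_seed: int = 0,
) -> list[ModelSpec]:
    """The 14 comparison models plus the shuffled-information control.

    Every spec's feature set includes all of the acoustic baseline ``A``.
    """
    A = tuple(acoustic)
    if include_onset_pitch:
        A = tuple(dict.fromkeys(A + ("O", "P")))
    unknown = set(A) - set(ACOUSTIC_COLUMNS)
    if unknown:
        raise ValueError(f"unknown acoustic features: {unknown}")
    M = INFO_COLUMNS  # (Ho, So, Hp, Sp)
    specs = [ModelSpec("A", A)]
    for f in M:
        specs.append(ModelSpec(f"A{f}", A + (f,)))
    for f in M:
        specs.append(ModelSpec(f"AM-{f}", A + tuple(g for g in M if g != f)))
    specs.append(ModelSpec("AMo", A + ("Ho", "So")))
    specs.append(ModelSpec("AMp", A + ("Hp", "Sp")))
    specs.append(ModelSpec("AH", A + ("Ho", "Hp")))
    specs.append(ModelSpec("AS", A + ("So", "Sp")))
    specs.append(ModelSpec("AM", A + M))
    specs.append(
        ModelSpec("AMshuffled", A + M, shuffle=M, shuffle_seed=shuffle_seed)
    )
    return specs


def shuffle_information(
    fm: FeatureMatrix, columns: Sequence[str], seed: int
) -> FeatureMatrix:
    """Permute each column's nonzero values among its own nonzero positions.

    Zeros (and all other columns) are untouched, so the acoustic structure
    and the onset timing are preserved while the information values are
    decoupled from their notes. Columns with fewer than 2 nonzero entries
    are left unchanged.
    """
    rng = np.random.default_rng(seed)
    df = fm.data.copy()
    for c in columns:
        x = df[c].to_numpy(dtype=float).copy()
        nz = np.flatnonzero(x)
        if nz.size < 2:
            continue
        x[nz] = x[nz][rng.permutation(nz.size)]
        df[c] = x
    return FeatureMatrix(df, fm.fs)


class ComparisonTable:
    """Tidy per-(subject, band, model, channel) reconstruction accuracies."""

    def __init__(self, df: pd.DataFrame):
        required = {"subject", "band", "model", "channel", "r"}
        if not required <= set(df.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        self.df = df.reset_index(drop=True)

    def subject_means(self, band: str | None = None) -> pd.DataFrame:
        """Channel-mean r per subject x model (the group-test scalar)."""
        df = self.df if band is None else self.df[self.df["band"] == band]
        return (
            df.groupby(["subject", "model"])["r"].mean().unstack("model")
        )

    def enhancement(self, model: str, baseline: str = "A",
                    band: str | None = None) -> pd.Series:
        """Per-subject gain in channel-mean r of ``model`` over ``baseline``."""
        means = self.subject_means(band)
        return means[model] - means[baseline]

    def unique_contribution(self, feature: str,
                            band: str | None = None) -> pd.Series:
        """Per-subject r(AM) - r(AM-feature)."""
        means = self.subject_means(band)
        return means["AM"] - means[f"AM-{feature}"]

    def channel_matrix(self, model: str, band: str | None = None) -> np.ndarray:
        """(n_subjects x n_channels) fold-mean r for one model."""
        df = self.df if band is None else self.df[self.df["band"] == band]
        sub = df[df["model"] == model]
        return (
            sub.pivot_table(index="subject", columns="channel", values="r")
            .to_numpy()
        )

    def channel_enhancement(self, model: str, baseline: str = "A",
                            band: str | None = None) -> np.ndarray:
        """Per-channel enhancement matrix for electrode-cluster tests."""
        return self.channel_matrix(model, band) - self.channel_matrix(
            baseline, band
        )

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path) -> "ComparisonTable":
        return cls(pd.read_csv(path, sep="\t"))

    def concat(self, other: "ComparisonTable") -> "ComparisonTable":
        return ComparisonTable(pd.concat([self.df, other.df], ignore_index=True))


def evaluate_ledger(
    subject_trials: Mapping,
    specs: Sequence[ModelSpec],
    window: LagWindow,
    lam_grid: np.ndarray | None = None,
    band: str = "",
    exclude_edges_s: float = 1.0,
) -> ComparisonTable:
    """Run nested cross-validation for every subject x model spec.

    ``subject_trials`` maps a subject id to its list of
    ``(FeatureMatrix, response)`` trials, where the response is an
    EEGRecording or a (channel x time) array. Subjects with fewer than 3
    trials are dropped (nested CV is undefined). Returns the tidy table of
    fold-mean per-channel accuracies.
    """
    rows = []
    for subject, trials in subject_trials.items():
        if len(trials) < 3:
            continue
        for spec in specs:
            pairs = []
            for ti, (fm, resp) in enumerate(trials):
                if spec.shuffle:
                    fm = shuffle_information(
                        fm, spec.shuffle, seed=spec.shuffle_seed * 100003 + ti
                    )
                X = fm.select(spec.features).values
                R = resp.data if hasattr(resp, "data") else np.asarray(resp)
                pairs.append((X, R))
            _, acc = nested_cv(
                pairs,
                window,
                lam_grid,
                feature_names=spec.features,
                exclude_edges_s=exclude_edges_s,
            )
            channel_r = acc.channel_r
            for ch, r in enumerate(channel_r):
                rows.append(
                    {
                        "subject": subject,
                        "band": band,
                        "model": spec.name,
                        "channel": ch,
                        "r": r,
                    }
                )
    return ComparisonTable(pd.DataFrame(rows))
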