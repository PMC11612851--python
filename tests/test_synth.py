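"""Generative melody model, exact information values, and the EEG forward model."""

import numpy as np
import pytest
from scipy import stats as sstats

from melodic_trf.layout import make_layout
from melodic_trf.synth import (
    CohortSpec,
    GroundTruthKernels,
    MarkovMelodyModel,
    NoteSequence,
    analytic_information,
    convolve_lagged,
    default_kernels,
    gaussian_kernel,
    generate_melody,
    make_cohort,
    simulate_eeg,
    synthesize_envelope,
    topography_gains,
)
from melodic_trf.trf import LagWindow, lag_design, reconstruction_accuracy


def _deterministic_model():
    # each context maps to exactly one successor: 60 -> 62 -> 64 -> 60
    alphabet = [60, 62, 64]
    trans = {
        (60,): np.array([0.0, 1.0, 0.0]),
        (62,): np.array([0.0, 0.0, 1.0]),
        (64,): np.array([1.0, 0.0, 0.0]),
    }
    return MarkovMelodyModel(
        pitch_alphabet=alphabet,
        pitch_transition=trans,
        pitch_initial=np.array([1.0, 0.0, 0.0]),
        ioi_values=np.array([0.5]),
        ioi_transition=np.array([[1.0]]),
        ioi_initial=np.array([1.0]),
    )


class TestGenerateMelody:
    def test_deterministic_chain_follows_unique_path(self):
        seq = generate_melody(_deterministic_model(), 10.0, seed=3)
        expected = [60, 62, 64] * (len(seq) // 3 + 1)
        assert seq.pitches.tolist() == expected[: len(seq)]
        assert np.allclose(np.diff(seq.onsets), 0.5)

    def test_same_seed_reproduces_sequence(self, random_model):
        a = generate_melody(random_model, 30.0, seed=9)
        b = generate_melody(random_model, 30.0, seed=9)
        assert np.array_equal(a.onsets, b.onsets)
        assert np.array_equal(a.pitches, b.pitches)
        assert np.array_equal(a.velocities, b.velocities)

    def test_different_seed_changes_sequence(self, random_model):
        a = generate_melody(random_model, 30.0, seed=9)
        b = generate_melody(random_model, 30.0, seed=10)
        assert not np.array_equal(a.pitches, b.pitches)

    def test_uniform_chain_has_uniform_transition_frequencies(self):
        n_p = 12
        alphabet = list(range(60, 60 + n_p))
        trans = {(p,): np.full(n_p, 1.0 / n_p) for p in alphabet}
        model = MarkovMelodyModel(
            pitch_alphabet=alphabet,
            pitch_transition=trans,
            pitch_initial=np.full(n_p, 1.0 / n_p),
            ioi_values=np.array([0.01]),
            ioi_transition=np.array([[1.0]]),
            ioi_initial=np.array([1.0]),
        )
        seq = generate_melody(model, 1001.0, seed=2)
        assert len(seq) > 90_000
        counts = np.bincount(seq.pitches - 60, minlength=n_p)
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        # uniform at alpha = .01
        assert chi2 < sstats.chi2.isf(0.01, df=n_p - 1)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            MarkovMelodyModel(
                pitch_alphabet=[60],
                pitch_transition={(60,): np.array([0.5])},
                pitch_initial=np.array([1.0]),
                ioi_values=np.array([0.5]),
                ioi_transition=np.array([[1.0]]),
                ioi_initial=np.array([1.0]),
            )
        with pytest.raises(ValueError, match="alphabet"):
            MarkovMelodyModel(
                pitch_alphabet=[],
                pitch_transition={},
                pitch_initial=np.array([]),
                ioi_values=np.array([0.5]),
                ioi_transition=np.array([[1.0]]),
                ioi_initial=np.array([1.0]),
            )


class TestAnalyticInformation:
    def test_uniform_distribution_gives_log2_alphabet_entropy(self):
        n_p = 4
        alphabet = [60, 61, 62, 63]
        trans = {(p,): np.full(n_p, 0.25) for p in alphabet}
        model = MarkovMelodyModel(
            pitch_alphabet=alphabet,
            pitch_transition=trans,
            pitch_initial=np.full(n_p, 0.25),
            ioi_values=np.array([0.25, 0.5]),
            ioi_transition=np.full((2, 2), 0.5),
            ioi_initial=np.array([0.5, 0.5]),
        )
        seq = generate_melody(model, 20.0, seed=1)
        info = analytic_information(model, seq)
        assert np.allclose(info["Hp"], 2.0)  # log2(4)
        assert np.allclose(info["Ho"], 1.0)  # log2(2)

    def test_surprisal_closed_form(self, order1_model):
        # pitches 62 -> 60 has p = 0.8; 60 -> 60 has p = 0.5
        seq = NoteSequence(
            onsets=np.array([0.25, 0.5, 1.0]),
            pitches=np.array([62, 60, 60]),
            durations=np.array([0.2, 0.4, 0.2]),
            duration_total=1.5,
        )
        info = analytic_information(order1_model, seq)
        assert info["Sp"][1] == pytest.approx(-np.log2(0.8), abs=1e-12)
        assert info["Sp"][2] == pytest.approx(1.0, abs=1e-12)  # p = 0.5

    def test_two_outcome_context_matches_brute_force(self):
        # context with p = (0.8, 0.2): S(rare) = log2(5), H ~ 0.7219
        p = np.array([0.8, 0.2])
        model = MarkovMelodyModel(
            pitch_alphabet=[60, 62],
            pitch_transition={(60,): p, (62,): p},
            pitch_initial=np.array([1.0, 0.0]),
            ioi_values=np.array([0.5]),
            ioi_transition=np.array([[1.0]]),
            ioi_initial=np.array([1.0]),
        )
        seq = NoteSequence(
            onsets=np.array([0.5, 1.0]),
            pitches=np.array([60, 62]),  # second note is the rare outcome
            durations=np.array([0.4, 0.4]),
            duration_total=2.0,
        )
        info = analytic_information(model, seq)
        brute_H = sum(pi * np.log2(1.0 / pi) for pi in p)
        assert info["Sp"][1] == pytest.approx(np.log2(5.0), abs=1e-12)
        assert info["Hp"][1] == pytest.approx(brute_H, abs=1e-12)
        assert info["Hp"][1] == pytest.approx(0.721928094887, abs=1e-9)

    def test_matches_brute_force_on_random_chain(self, random_model):
        seq = generate_melody(random_model, 15.0, seed=4)
        info = analytic_information(random_model, seq)
        assert np.all(info.to_numpy() >= 0)
        assert np.all(np.isfinite(info.to_numpy()))
        # independent brute force over the model's distributions
        for i in np.arange(1, min(10, len(seq))):
            dist = random_model.pitch_transition[(int(seq.pitches[i - 1]),)]
            j = random_model.pitch_alphabet.index(int(seq.pitches[i]))
            assert info["Sp"][i] == pytest.approx(np.log2(1 / dist[j]), abs=1e-12)
            H = sum(q * np.log2(1 / q) for q in dist if q > 0)
            assert info["Hp"][i] == pytest.approx(H, abs=1e-12)

    def test_zero_probability_event_rejected(self, order1_model):
        # 62 -> 64 has probability 0 under the fixture model
        seq = NoteSequence(
            onsets=np.array([0.25, 0.5]),
            pitches=np.array([62, 64]),
            durations=np.array([0.2, 0.2]),
            duration_total=1.0,
        )
        with pytest.raises(ValueError, match="probability 0"):
            analytic_information(order1_model, seq)

    def test_unmatched_ioi_rejected(self, order1_model):
        seq = NoteSequence(
            onsets=np.array([0.33]),
            pitches=np.array([60]),
            durations=np.array([0.2]),
            duration_total=1.0,
        )
        with pytest.raises(ValueError, match="IOI"):
            analytic_information(order1_model, seq)


class TestEnvelope:
    def test_empty_sequence_gives_zeros(self):
        seq = NoteSequence(
            onsets=np.array([]), pitches=np.array([]), durations=np.array([]),
            duration_total=2.0,
        )
        env = synthesize_envelope(seq, 64.0)
        assert env.shape == (128,)
        assert np.all(env == 0)

    def test_single_note_peaks_at_onset_sample(self):
        seq = NoteSequence(
            onsets=np.array([1.0]), pitches=np.array([60]),
            durations=np.array([0.5]), duration_total=3.0,
        )
        env = synthesize_envelope(seq, 64.0)
        assert np.argmax(env) == 64
        assert np.all(env >= 0)

    def test_superposition_of_single_note_envelopes(self, three_notes):
        full = synthesize_envelope(three_notes, 64.0)
        acc = np.zeros_like(full)
        for i in range(len(three_notes)):
            single = NoteSequence(
                onsets=three_notes.onsets[i : i + 1],
                pitches=three_notes.pitches[i : i + 1],
                durations=three_notes.durations[i : i + 1],
                duration_total=three_notes.duration_total,
                velocities=three_notes.velocities[i : i + 1],
            )
            acc += synthesize_envelope(single, 64.0)
        assert np.allclose(acc, full, atol=1e-12)


class TestSimulateEEG:
    def test_unit_impulse_kernel_delays_feature(self, short_features):
        win = LagWindow(-150, 750, 64.0)
        lag = 8  # 125 ms
        k = np.zeros(win.n_lags)
        k[np.flatnonzero(win.lags == lag)[0]] = 1.0
        kern = GroundTruthKernels(window=win, kernels={("delta", "Env"): k})
        cohort = CohortSpec(
            n_subjects=2, n_melodies=1, n_repeats=1, melody_length_s=20.0,
            n_channels=8, fs_eeg=64.0, snr=1e12, seed=5,
        )
        gains = {"Env": np.ones(8)}
        eeg = simulate_eeg(
            short_features, kern, cohort, 0, 0, band="delta", gains=gains
        )
        x = short_features.values[:, 0]
        assert np.allclose(eeg.data[0, lag:], x[:-lag], atol=1e-4 * x.std())

    def test_kernel_amplitude_scales_linearly(self, short_features):
        win = LagWindow(-150, 750, 64.0)
        k1 = gaussian_kernel(win, 100.0, 40.0)
        cohort = CohortSpec(
            n_subjects=2, n_melodies=1, n_repeats=1, melody_length_s=20.0,
            n_channels=8, fs_eeg=64.0, snr=1e12, seed=5,
        )
        gains = {"Env": np.linspace(0.2, 1.0, 8)}
        e1 = simulate_eeg(
            short_features,
            GroundTruthKernels(window=win, kernels={("delta", "Env"): k1}),
            cohort, 0, 0, band="delta", gains=gains,
        )
        e2 = simulate_eeg(
            short_features,
            GroundTruthKernels(window=win, kernels={("delta", "Env"): 2 * k1}),
            cohort, 0, 0, band="delta", gains=gains,
        )
        assert np.allclose(e2.data, 2 * e1.data, rtol=1e-6, atol=1e-9)

    def test_convolution_matches_lagged_design_product(self, short_features):
        win = LagWindow(-150, 750, 64.0)
        k = gaussian_kernel(win, 150.0, 60.0)
        x = short_features.values[:, 0]
        direct = convolve_lagged(x, k, win.lags)
        design = lag_design(x[:, None], win, ("Env",))
        via_design = design.matrix[:, :-1] @ k
        assert np.allclose(direct, via_design, atol=1e-12)

    def test_null_kernels_give_chance_level_accuracy(self, short_features):
        win = LagWindow(-150, 750, 64.0)
        kern = GroundTruthKernels(
            window=win, kernels={("delta", "Env"): np.zeros(win.n_lags)}
        )
        cohort = CohortSpec(
            n_subjects=2, n_melodies=1, n_repeats=1, melody_length_s=20.0,
            n_channels=8, fs_eeg=64.0, snr=10.0, seed=6,
        )
        from melodic_trf.trf import nested_cv

        trials = [
            (
                short_features.select(["Env", "EnvD"]).values,
                simulate_eeg(short_features, kern, cohort, 0, t, band="delta").data,
            )
            for t in range(4)
        ]
        _, acc = nested_cv(trials, win, np.array([1.0]))
        # pure-noise responses: channel-mean |r| stays below the null band
        null_q = 2.0 / np.sqrt(short_features.n_samples - 128)
        assert abs(acc.mean_r) < null_q

    def test_seed_isolation_noise_changes_features_do_not(
        self, short_features, small_cohort
    ):
        win = LagWindow(-150, 750, 64.0)
        kern = default_kernels(win, bands=["delta"], features=("Env", "Ho"))
        a = simulate_eeg(short_features, kern, small_cohort, 0, 0, band="delta")
        cohort2 = CohortSpec(**{**small_cohort.__dict__, "seed": 99})
        b = simulate_eeg(short_features, kern, cohort2, 0, 0, band="delta")
        assert not np.allclose(a.data, b.data)  # noise realization differs
        # repeated call with same seeds is identical
        c = simulate_eeg(short_features, kern, small_cohort, 0, 0, band="delta")
        assert np.array_equal(a.data, c.data)


class TestMakeCohort(object):
    def test_manifest_counts_and_determinism(self, tmp_path, random_model):
        win = LagWindow(-150, 750, 64.0)
        kern = default_kernels(win, bands=["delta"], features=("Env", "Ho"))
        cohort = CohortSpec(
            n_subjects=2, n_melodies=2, n_repeats=1, melody_length_s=10.0,
            n_channels=6, fs_eeg=64.0, snr=3.0, seed=13,
        )
        man1 = make_cohort(cohort, random_model, kern, tmp_path / "a")
        assert len(man1["eeg"]) == 2 * 2  # n_subjects * n_trials
        assert len(man1["melodies"]) == 2
        man2 = make_cohort(cohort, random_model, kern, tmp_path / "b")
        for rel in man1["features"]:
            assert (tmp_path / "a" / rel).read_bytes() == (
                tmp_path / "b" / rel
            ).read_bytes()

    def test_paper_shaped_spec_has_30_trials_per_subject(self):
        spec = CohortSpec()
        assert spec.n_subjects == 20
        assert spec.n_trials == 30
        assert spec.n_channels == 64
        assert spec.fs_eeg == 512.0
        assert len(spec.groups) == 20
        assert spec.groups.count("musician") == 10


class TestTopographyGains:
    def test_gains_deterministic_and_positive(self, layout16):
        _, coords = layout16
        g1 = topography_gains(coords, ["Env", "Ho"], seed=3)
        g2 = topography_gains(coords, ["Env", "Ho"], seed=3)
        for f in ("Env", "Ho"):
            assert np.array_equal(g1[f], g2[f])
            assert np.all(g1[f] > 0)
        g3 = topography_gains(coords, ["Env"], seed=4)
        assert not np.allclose(g1["Env"], g3["Env"])
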