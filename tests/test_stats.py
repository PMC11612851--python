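"""Signed-rank inference, electrode clusters, TFCE, and peak latencies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from melodic_trf.layout import make_layout
from melodic_trf.stats import (
    _tfce_1d,
    cluster_permutation,
    compare_peak_latencies,
    electrode_adjacency,
    peak_latency,
    select_channels,
    smooth_weights,
    tfce_signflip,
    wilcoxon_signed_rank,
)


class TestWilcoxonSignedRank:
    def test_all_positive_n20_effect_size(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 21.0), alternative="greater")
        # analytic ceiling for n=20: z = (W - mu)/sigma with W = 210
        assert res.w == 210
        assert res.effect_size == pytest.approx(0.8765, abs=5e-5)
        assert round(res.effect_size, 3) == 0.877
        assert res.p < 0.001

    def test_all_positive_n10_effect_size(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 11.0), alternative="greater")
        assert round(res.effect_size, 3) == 0.886
        assert res.p < 0.005

    def test_one_sided_p_matches_exact_enumeration(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal(8)
        res = wilcoxon_signed_rank(d, alternative="greater")
        # exact: all 2^8 sign assignments of the rank vector
        r = sstats.rankdata(np.abs(d))
        w_obs = r[d > 0].sum()
        ws = []
        for bits in range(256):
            signs = [(bits >> i) & 1 for i in range(8)]
            ws.append(sum(ri for ri, s in zip(r, signs) if s))
        ws = np.array(ws)
        exact_p = (ws >= w_obs).mean()
        # normal approximation should be within a few percent of exact
        assert res.p == pytest.approx(exact_p, abs=0.05)
        # and the z matches the direct formula
        mu, sig = 18.0, np.sqrt(8 * 9 * 17 / 24)
        assert res.z == pytest.approx((w_obs - mu) / sig, abs=1e-12)

    def test_matches_scipy_two_sided_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30) * 0.8 + 0.3
        res = wilcoxon_signed_rank(y, x, alternative="two-sided")
        ref = sstats.wilcoxon(
            y, x, alternative="two-sided", correction=False, method="approx"
        )
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_differences_dropped(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, -0.5, 3.0, 1.5, 2.5, 0.7])
        res = wilcoxon_signed_rank(d)
        assert res.n == 7
        assert res.n_zero_dropped == 2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(10))

    @settings(derandomize=True, max_examples=50)
    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        n=st.integers(min_value=5, max_value=40),
    )
    def test_effect_size_bounded_by_analytic_ceiling(self, seed, n):
        """|z/sqrt(n)| never exceeds the all-unanimous ceiling for that n."""
        d = np.random.default_rng(seed).standard_normal(n)
        d = d[d != 0]
        if d.size < 5:
            return
        m = d.size
        res = wilcoxon_signed_rank(d)
        mu = m * (m + 1) / 4
        sig = np.sqrt(m * (m + 1) * (2 * m + 1) / 24)
        ceiling = (m * (m + 1) / 2 - mu) / sig / np.sqrt(m)
        assert abs(res.effect_size) <= ceiling + 1e-12
        # invariant under positive rescaling of the differences
        res2 = wilcoxon_signed_rank(3.7 * d)
        assert res2.z == pytest.approx(res.z, abs=1e-12)

    def test_paired_form_equals_difference_form(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 12))
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(x - y)
        assert a.z == b.z and a.p == b.p


class TestAdjacency:
    def test_symmetric_no_self_edges(self):
        _, coords = make_layout(16)
        adj = electrode_adjacency(coords)
        assert np.array_equal(adj, adj.T)
        assert not adj.diagonal().any()
        # connected-ish scalp coverage: each scalp electrode has a neighbor
        assert adj[:14].sum(axis=1).min() >= 1

    def test_long_edges_pruned(self):
        coords = np.vstack(
            [np.random.default_rng(0).uniform(-1, 1, (10, 2)), [[50.0, 50.0]]]
        )
        adj = electrode_adjacency(coords)
        assert not adj[10].any()  # the far-away point is isolated


class TestClusterPermutation:
    def test_no_edge_graph_equals_max_statistic_test(self):
        rng = np.random.default_rng(6)
        D = rng.standard_normal((12, 6)) + 0.9
        E = D.shape[1]
        adj = np.zeros((E, E), dtype=bool)
        res = cluster_permutation(D, adj, n_perm=500, seed=42)
        for c in res.clusters:
            assert len(c["electrodes"]) == 1
        # independent max-statistic implementation sharing the sign draws
        thresh = sstats.norm.isf(0.025)
        R = np.vstack([sstats.rankdata(np.abs(D[:, e])) for e in range(E)]).T
        sgn = np.sign(D)
        n = D.shape[0]
        mu = n * (n + 1) / 4
        sig = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
        S = np.random.default_rng(42).integers(0, 2, size=(500, n)) * 2.0 - 1.0
        null = []
        for s in S:
            w = ((R * (sgn * s[:, None] > 0))).sum(axis=0)
            z = (w - mu) / sig
            z_sup = np.abs(z)[np.abs(z) > thresh]
            null.append(z_sup.max() if z_sup.size else 0.0)
        null = np.array(null)
        z_obs = (R * (sgn > 0)).sum(axis=0)
        z_obs = (z_obs - mu) / sig
        for c in res.clusters:
            e = c["electrodes"][0]
            assert c["mass"] == pytest.approx(z_obs[e], abs=1e-10)
            p_ref = (1 + (null >= abs(z_obs[e])).sum()) / 501
            assert c["p"] == pytest.approx(p_ref, abs=1e-12)

    def test_planted_connected_effect_detected(self):
        labels, coords = make_layout(16)
        adj = electrode_adjacency(coords)
        rng = np.random.default_rng(7)
        D = rng.standard_normal((20, 16))
        # plant d = 1.5 on a connected patch around electrode 0
        patch = [0] + list(np.flatnonzero(adj[0]))[:5]
        D[:, patch] += 1.5
        res = cluster_permutation(D, adj, n_perm=500, seed=1)
        top = res.clusters[0]
        assert top["p"] < 0.05
        assert set(patch) <= set(top["electrodes"])
        assert set(select_channels(res)) >= set(patch)

    def test_p_floor(self):
        rng = np.random.default_rng(8)
        D = rng.standard_normal((15, 8)) + 3.0
        _, coords = make_layout(8)
        res = cluster_permutation(D, electrode_adjacency(coords), n_perm=200,
                                  seed=2)
        for c in res.clusters:
            assert c["p"] >= 1.0 / 201.0

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            cluster_permutation(np.ones((1, 4)), np.zeros((4, 4), bool))


class TestSmoothWeights:
    def test_constant_series_unchanged(self):
        w = np.full((3, 59), 2.5)
        out = smooth_weights(w, 64.0)
        inner = out[:, 3:-3]
        assert np.allclose(inner, 2.5, atol=1e-12)

    def test_impulse_becomes_unit_sum_hamming(self):
        w = np.zeros(59)
        w[30] = 1.0
        out = smooth_weights(w, 64.0)
        ham = np.hamming(7)
        ham /= ham.sum()
        assert np.allclose(out[27:34], ham, atol=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_window_average(self):
        rng = np.random.default_rng(9)
        w = rng.standard_normal(30)
        out = smooth_weights(w, 64.0)
        ham = np.hamming(7)
        ham /= ham.sum()
        for lag in (5, 12, 20):
            hand = float(np.dot(w[lag - 3 : lag + 4], ham[::-1]))
            assert out[lag] == pytest.approx(hand, abs=1e-12)

    def test_window_longer_than_axis_rejected(self):
        with pytest.raises(ValueError):
            smooth_weights(np.zeros(5), 64.0, width_ms=200.0)


class TestTFCE:
    def test_all_zero_weights_no_significance(self):
        res = tfce_signflip(np.zeros((8, 30)), np.arange(30.0), n_perm=100)
        assert not res.significant.any()
        assert res.windows == []

    def test_global_sign_flip_symmetry(self):
        rng = np.random.default_rng(10)
        W = rng.standard_normal((10, 40)) + np.linspace(0, 1.5, 40)
        t = np.arange(40.0)
        a = tfce_signflip(W, t, n_perm=300, seed=3)
        b = tfce_signflip(-W, t, n_perm=300, seed=3)
        assert np.allclose(np.abs(a.tfce), np.abs(b.tfce), atol=1e-10)
        assert np.array_equal(a.significant, b.significant)

    def test_isolated_lag_matches_threshold_ladder_integral(self):
        stat = np.zeros(21)
        stat[10] = 5.0
        E, H = 0.5, 2.0
        dh = 5.0 / 100
        out = _tfce_1d(stat, E, H, dh, 5.0)
        thresholds = np.arange(dh, 5.0 + dh / 2, dh)
        expected = sum(1.0**E * h**H * dh for h in thresholds)
        assert out[10] == pytest.approx(expected, rel=1e-12)
        # and approximates the continuous integral of h^2 dh to ~2%
        assert out[10] == pytest.approx(5.0**3 / 3.0, rel=0.02)
        assert np.all(out[stat == 0] == 0)

    def test_extent_enters_enhancement(self):
        # a wide plateau must outscore an isolated spike of equal height
        wide = np.zeros(30)
        wide[5:15] = 3.0
        narrow = np.zeros(30)
        narrow[20] = 3.0
        both = wide + narrow
        out = _tfce_1d(both, 0.5, 2.0, 0.03, 3.0)
        assert out[10] > out[20]

    def test_planted_bump_detected(self):
        rng = np.random.default_rng(11)
        lags = np.linspace(-156.25, 750.0, 59)
        bump = 1.2 * np.exp(-0.5 * ((lags - 150.0) / 40.0) ** 2)
        W = rng.standard_normal((20, 59)) + bump
        res = tfce_signflip(W, lags, n_perm=300, seed=4)
        assert res.significant.any()
        centers = [(a + b) / 2 for a, b in res.windows]
        assert any(abs(c - 150.0) < 120.0 for c in centers)


class TestPeakLatency:
    def test_gaussian_bump_latency(self):
        lags = np.linspace(-156.25, 750.0, 59)
        rng = np.random.default_rng(12)
        W = np.stack(
            [
                np.exp(-0.5 * ((lags - 200.0) / 50.0) ** 2)
                + 0.01 * rng.standard_normal(59)
                for _ in range(10)
            ]
        )
        res = peak_latency(W, lags, (0.0, 400.0))
        step = lags[1] - lags[0]
        assert np.all(np.abs(res.latencies_ms - 200.0) <= step + 1e-9)
        assert not res.tied.any()

    def test_zero_window_flagged_earliest(self):
        lags = np.arange(0.0, 100.0, 10.0)
        res = peak_latency(np.zeros((3, 10)), lags, (20.0, 80.0))
        assert np.all(res.latencies_ms == 20.0)
        assert res.tied.all()

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            peak_latency(np.zeros((2, 10)), np.arange(10.0), (500.0, 600.0))

    def test_planted_latency_difference_significant(self):
        lags = np.linspace(-156.25, 750.0, 59)
        rng = np.random.default_rng(13)
        lat_a, lat_b = [], []
        for _ in range(20):
            c1 = 150.0 + rng.normal(0, 10)
            c2 = 210.0 + rng.normal(0, 10)
            w1 = np.exp(-0.5 * ((lags - c1) / 40.0) ** 2)
            w2 = np.exp(-0.5 * ((lags - c2) / 40.0) ** 2)
            lat_a.append(peak_latency(w1[None], lags, (0, 400)).latencies_ms[0])
            lat_b.append(peak_latency(w2[None], lags, (0, 400)).latencies_ms[0])
        res = compare_peak_latencies(lat_a, lat_b)
        assert res.alternative == "two-sided"
        assert res.p < 0.05
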