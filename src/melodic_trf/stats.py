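"""Group-level inference for the encoding analysis.

Implements the within-subject nonparametric toolkit used to compare model
accuracies and TRF weights across subjects:

* one-sided / two-sided Wilcoxon signed-rank tests (normal approximation
  with tie-corrected variance, no continuity correction), with effect size
  reported as z / sqrt(n);
* mass-univariate cluster-based permutation tests over electrodes
  (subject-level sign flips, adjacency-connected clusters, max-cluster-mass
  null) in the Maris-Oostenveld style;
* threshold-free cluster enhancement (TFCE) along the TRF lag axis with a
  sign-flip permutation null, to find lags where group-level weights differ
  from zero without an arbitrary cluster-forming threshold;
* Hamming smoothing of TRF weights and peak-latency extraction/comparison.

Note on effect sizes: z / sqrt(n) is the matched-pairs rank-biserial-like
standardization whose ceiling for n = 20 all-positive differences is
0.8765 (and 0.8864 for n = 10); reporting z divided by n itself cannot
reach such values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats as sstats
from scipy.spatial import Delaunay

__all__ = [
    "SignedRankResult",
    "ClusterResult",
    "TFCEResult",
    "PeakLatencyResult",
    "wilcoxon_signed_rank",
    "electrode_adjacency",
    "cluster_permutation",
    "smooth_weights",
    "tfce_signflip",
    "peak_latency",
    "compare_peak_latencies",
    "select_channels",
]


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


@dataclass
class SignedRankResult:
    n: int
    w: float  # sum of positive ranks
    z: float
    p: float
    effect_size: float  # z / sqrt(n)
    alternative: str
    n_zero_dropped: int = 0


def _signed_rank_terms(diffs: np.ndarray):
    """Per-column rank machinery for a (n x E) matrix of paired differences.

    Zero differences are dropped (rank 0, reduced effective n). Returns
    ranks R (zeros where d == 0), sign(d), and the null mean / SD of the
    positive-rank sum W+ with tie-corrected variance.
    """
    D = np.atleast_2d(np.asarray(diffs, dtype=float))
    n, E = D.shape
    R = np.zeros_like(D)
    mu = np.zeros(E)
    sigma = np.zeros(E)
    n_eff = np.zeros(E, dtype=int)
    for e in range(E):
        d = D[:, e]
        nz = d != 0
        m = int(nz.sum())
        n_eff[e] = m
        if m == 0:
            continue
        r = sstats.rankdata(np.abs(d[nz]))  # midranks for ties
        R[nz, e] = r
        mu[e] = m * (m + 1) / 4.0
        var = m * (m + 1) * (2 * m + 1) / 24.0
        _, counts = np.unique(np.abs(d[nz]), return_counts=True)
        var -= (counts**3 - counts).sum() / 48.0
        sigma[e] = np.sqrt(var)
    return R, np.sign(D), mu, sigma, n_eff


def _signed_rank_z(diffs: np.ndarray) -> np.ndarray:
    """Tie-corrected z of the signed-rank statistic per column."""
    R, sgn, mu, sigma, n_eff = _signed_rank_terms(diffs)
    w_pos = (R * (sgn > 0)).sum(axis=0)
    z = np.zeros_like(mu)
    ok = sigma > 0
    z[ok] = (w_pos[ok] - mu[ok]) / sigma[ok]
    return z


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray | None = None,
    alternative: str = "greater",
) -> SignedRankResult:
    """Paired signed-rank test on x - y (or on x directly if y is None).

    Normal approximation without continuity correction; ties get midranks
    and the variance is tie-corrected; zero differences are dropped and
    counted. ``alternative='greater'`` tests a positive median difference.
    Effect size is z / sqrt(n) over the retained pairs.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.ndim != 1:
        raise ValueError("paired samples must be 1-D")
    n_zero = int((d == 0).sum())
    d_nz = d[d != 0]
    n = d_nz.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        raise ValueError("signed-rank normal approximation needs n >= 5")
    R, sgn, mu, sigma, _ = _signed_rank_terms(d_nz[:, None])
    w_pos = float((R[:, 0] * (sgn[:, 0] > 0)).sum())
    z = (w_pos - mu[0]) / sigma[0]
    if alternative == "greater":
        p = float(sstats.norm.sf(z))
    elif alternative == "less":
        p = float(sstats.norm.cdf(z))
    elif alternative == "two-sided":
        p = float(2 * sstats.norm.sf(abs(z)))
    else:
        raise ValueError("alternative must be greater, less, or two-sided")
    return SignedRankResult(
        n=n,
        w=w_pos,
        z=float(z),
        p=p,
        effect_size=float(z / np.sqrt(n)),
        alternative=alternative,
        n_zero_dropped=n_zero,
    )


# ---------------------------------------------------------------------------
# Electrode-cluster permutation test
# ---------------------------------------------------------------------------


def electrode_adjacency(coords: np.ndarray, prune_factor: float = 1.5) -> np.ndarray:
    """Boolean adjacency from a Delaunay triangulation of the 2-D layout.

    Edges longer than ``prune_factor`` times the median edge length are
    removed so peripheral electrodes (e.g. mastoids) do not bridge across
    the head.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    tri = Delaunay(coords)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((a, b))
    edges = np.array(sorted(edges))
    lengths = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
    keep = lengths <= prune_factor * np.median(lengths)
    for (a, b) in edges[keep]:
        adj[a, b] = adj[b, a] = True
    return adj


@dataclass
class ClusterResult:
    stat: np.ndarray  # per-electrode signed-rank z
    clusters: list  # dicts: electrodes, mass, p
    n_perm: int
    adjacency: np.ndarray
    cluster_alpha: float

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c["p"] < alpha]


def _components(mask: np.ndarray, neighbors: list[np.ndarray]) -> list[list[int]]:
    """Connected components of the suprathreshold electrode set."""
    todo = set(int(i) for i in np.flatnonzero(mask))
    comps = []
    while todo:
        seed = todo.pop()
        comp = [seed]
        frontier = [seed]
        while frontier:
            nxt = []
            for u in frontier:
                for v in neighbors[u]:
                    v = int(v)
                    if v in todo:
                        todo.discard(v)
                        comp.append(v)
                        nxt.append(v)
            frontier = nxt
        comps.append(sorted(comp))
    return comps


def _max_cluster_mass(
    z: np.ndarray, thresh: float, neighbors: list[np.ndarray]
) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        mask = sign * z > thresh
        for comp in _components(mask, neighbors):
            mass = abs(float(z[comp].sum()))
            best = max(best, mass)
    return best


def cluster_permutation(
    diffs: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 10000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based permutation test on per-electrode paired differences.

    ``diffs`` is (n_subjects x n_electrodes), e.g. per-channel enhancement.
    The per-electrode statistic is the tie-corrected signed-rank z;
    electrodes with two-sided p < ``cluster_alpha`` are grouped into
    adjacency-connected clusters whose mass (sum of z) is compared against
    the distribution of the maximal cluster mass under random subject-level
    sign flips. Corrected p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    D = np.atleast_2d(np.asarray(diffs, dtype=float))
    n, E = D.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (E, E):
        raise ValueError("adjacency shape does not match electrode count")
    if E > 1 and not adjacency.any():
        # No edges: every cluster is a single electrode (max-statistic test).
        pass
    neighbors = [np.flatnonzero(adjacency[e]) for e in range(E)]
    thresh = float(sstats.norm.isf(cluster_alpha / 2.0))

    z_obs = _signed_rank_z(D)
    obs_clusters = []
    for sign in (1.0, -1.0):
        mask = sign * z_obs > thresh
        for comp in _components(mask, neighbors):
            obs_clusters.append(
                {"electrodes": comp, "mass": float(z_obs[comp].sum())}
            )

    # Permutation null: ranks of |d| are invariant under sign flips, so the
    # flipped W+ per electrode is (sum(R) + s @ (R * sign)) / 2.
    R, sgn, mu, sigma, _ = _signed_rank_terms(D)
    sr = R * sgn
    total = R.sum(axis=0)
    rng = np.random.default_rng(seed)
    S = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
    W = (total[None, :] + S @ sr) / 2.0
    ok = sigma > 0
    Zp = np.zeros_like(W)
    Zp[:, ok] = (W[:, ok] - mu[ok]) / sigma[ok]
    null_max = np.array(
        [_max_cluster_mass(Zp[i], thresh, neighbors) for i in range(n_perm)]
    )

    for c in obs_clusters:
        c["p"] = float(
            (1 + (null_max >= abs(c["mass"])).sum()) / (1 + n_perm)
        )
    obs_clusters.sort(key=lambda c: c["p"])
    return ClusterResult(
        stat=z_obs,
        clusters=obs_clusters,
        n_perm=n_perm,
        adjacency=adjacency,
        cluster_alpha=cluster_alpha,
    )


def select_channels(result: ClusterResult, alpha: float = 0.05) -> np.ndarray:
    """Union of electrodes over all significant clusters (sorted indices)."""
    chans: set[int] = set()
    for c in result.significant(alpha):
        chans.update(c["electrodes"])
    return np.array(sorted(chans), dtype=int)


# ---------------------------------------------------------------------------
# TRF-weight smoothing, TFCE, peak latency
# ---------------------------------------------------------------------------


def smooth_weights(
    weights: np.ndarray, fs: float, width_ms: float = 100.0
) -> np.ndarray:
    """Smooth TRF weights along the lag axis with a unit-sum Hamming window.

    The window spans ``width_ms`` (rounded to samples, forced odd — 7
    samples at 64 Hz) so a constant weight series is left unchanged.
    Operates on the last axis of any-shaped input.
    """
    w = np.asarray(weights, dtype=float)
    L = int(round(width_ms / 1000.0 * fs))
    if L % 2 == 0:
        L += 1
    if L > w.shape[-1]:
        raise ValueError("smoothing window longer than the lag axis")
    ham = np.hamming(L)
    ham /= ham.sum()
    return ndimage.convolve1d(w, ham, axis=-1, mode="constant", cval=0.0)


def _tfce_1d(
    stat: np.ndarray, E: float, H: float, dh: float, h_max: float
) -> np.ndarray:
    """TFCE enhancement of non-negative statistics along the last axis.

    ``stat`` is (m x L); for each threshold h on the ladder, every
    suprathreshold lag accrues extent^E * h^H * dh, where extent is the
    length of its contiguous suprathreshold run.
    """
    S = np.atleast_2d(stat)
    m, L = S.shape
    out = np.zeros_like(S)
    if dh <= 0 or h_max <= 0:
        return out if stat.ndim > 1 else out[0]
    thresholds = np.arange(dh, h_max + dh / 2.0, dh)
    for h in thresholds:
        mask = S >= h
        if not mask.any():
            break
        prev = np.zeros_like(mask)
        prev[:, 1:] = mask[:, :-1]
        starts = mask & ~prev
        run_id = np.cumsum(starts.reshape(-1)).reshape(m, L) * mask
        counts = np.bincount(run_id.reshape(-1))
        extent = counts[run_id]
        out[mask] += extent[mask] ** E * h**H * dh
    return out if stat.ndim > 1 else out[0]


@dataclass
class TFCEResult:
    t: np.ndarray  # observed per-lag group statistic (mean / SE)
    tfce: np.ndarray  # signed TFCE score per lag
    p: np.ndarray  # corrected p per lag
    significant: np.ndarray  # boolean mask per lag
    windows: list  # contiguous significant (start_ms, end_ms) spans
    times_ms: np.ndarray
    n_perm: int


def _group_t(W: np.ndarray) -> np.ndarray:
    """Per-lag mean / SE across subjects; 0/0 resolves to 0."""
    n = W.shape[0]
    mean = W.mean(axis=0)
    sd = W.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    t = np.zeros_like(mean)
    ok = se > 0
    t[ok] = mean[ok] / se[ok]
    if np.any(~ok & (mean != 0)):
        raise ValueError("degenerate SE with nonzero mean")
    return t


def tfce_signflip(
    weights: np.ndarray,
    times_ms: np.ndarray,
    n_perm: int = 1000,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> TFCEResult:
    """Sign-flip permutation test on subject x lag TRF weights with TFCE.

    The observed statistic is the per-lag group mean divided by its
    standard error. TFCE is applied to the positive and negative parts
    separately (signed score); the null is the maximal |TFCE| over lags
    under whole-series subject sign flips. Lags with corrected p < alpha
    are merged into contiguous significant windows (ms).
    """
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    n, L = W.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    times_ms = np.asarray(times_ms, dtype=float)
    if times_ms.shape != (L,):
        raise ValueError("times_ms length must match the lag axis")

    t_obs = _group_t(W)
    h_max = float(np.abs(t_obs).max())
    if dh is None:
        dh = h_max / 100.0 if h_max > 0 else 0.0
    tfce_obs = _tfce_1d(np.clip(t_obs, 0, None), E, H, dh, h_max) - _tfce_1d(
        np.clip(-t_obs, 0, None), E, H, dh, h_max
    )

    if dh > 0:
        rng = np.random.default_rng(seed)
        S = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
        means = (S @ W) / n
        sq = (W**2).sum(axis=0)
        var = (sq[None, :] - n * means**2) / (n - 1)
        var = np.maximum(var, 0.0)
        se = np.sqrt(var / n)
        Tp = np.zeros_like(means)
        ok = se > 0
        Tp[ok] = means[ok] / se[ok]
        pos = _tfce_1d(np.clip(Tp, 0, None), E, H, dh, float(np.abs(Tp).max()))
        neg = _tfce_1d(np.clip(-Tp, 0, None), E, H, dh, float(np.abs(Tp).max()))
        null_max = np.maximum(pos.max(axis=1), neg.max(axis=1))
        p = (1 + (null_max[:, None] >= np.abs(tfce_obs)[None, :]).sum(axis=0)) / (
            1 + n_perm
        )
    else:
        p = np.ones(L)

    sig = p < alpha
    windows = []
    lab, n_runs = ndimage.label(sig)
    for k in range(1, n_runs + 1):
        idx = np.flatnonzero(lab == k)
        windows.append((float(times_ms[idx[0]]), float(times_ms[idx[-1]])))
    return TFCEResult(
        t=t_obs,
        tfce=tfce_obs,
        p=p,
        significant=sig,
        windows=windows,
        times_ms=times_ms,
        n_perm=n_perm,
    )


@dataclass
class PeakLatencyResult:
    latencies_ms: np.ndarray  # per subject
    tied: np.ndarray  # True where the window was flat (earliest lag returned)


def peak_latency(
    weights: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float],
) -> PeakLatencyResult:
    """Per-subject latency of maximal |weight| within a lag window.

    Ties (including all-zero windows) resolve to the earliest lag and are
    flagged.
    """
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    times_ms = np.asarray(times_ms, dtype=float)
    lo, hi = window_ms
    mask = (times_ms >= lo) & (times_ms <= hi)
    if not mask.any():
        raise ValueError("empty peak window")
    sub = np.abs(W[:, mask])
    idx = np.argmax(sub, axis=1)  # first maximum -> earliest lag
    tied = np.array([(row == row[i]).sum() > 1 for row, i in zip(sub, idx)])
    return PeakLatencyResult(
        latencies_ms=times_ms[mask][idx], tied=tied
    )


def compare_peak_latencies(
    lat_a: np.ndarray, lat_b: np.ndarray
) -> SignedRankResult:
    """Two-sided signed-rank test on paired per-subject latencies."""
    return wilcoxon_signed_rank(
        np.asarray(lat_a, dtype=float),
        np.asarray(lat_b, dtype=float),
        alternative="two-sided",
    )
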