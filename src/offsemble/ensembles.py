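"""Unsupervised ensemble detection from a binary population raster.

Pipeline: (1) a functional network from circular-shift surrogate testing of
pairwise coactivation; (2) raster filtering that keeps only spikes whose
neuron has an active network neighbor in the same frame; (3) hierarchical
clustering of population (column) vectors with Jaccard similarity and Ward
linkage; (4) cluster-count selection by the contrast index; (5) a one-sided
z-test of within-cluster similarity against random frame draws.  Clusters
that pass are ensembles; their occurrences form mutually exclusive binary
signals over the session.  No stimulus information is used anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .synthgen import Raster, substream


@dataclass
class FunctionalNetwork:
    """Significant pairwise-coactivation relation (symmetric, no self-edges)."""

    adjacency: np.ndarray  # (N, N) bool
    alpha: float
    n_surrogates: int

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("self-edges are not allowed")
        self.adjacency = a


@dataclass
class EnsembleModel:
    """Clustered frames, significance, and per-ensemble occurrence signals."""

    frame_labels: np.ndarray  # cluster id per clustered frame (1..k)
    clustered_frames: np.ndarray  # frame indices that entered clustering
    n_clusters: int
    contrast_by_k: dict[int, float]
    cluster_pvalues: dict[int, float]
    z_stats: dict[int, float]
    ensemble_ids: list[int]  # significant cluster ids
    ensemble_signals: dict[int, np.ndarray]  # per-ensemble binary series (full session)
    network: FunctionalNetwork = field(repr=False, default=None)
    filtered_raster: Raster = field(repr=False, default=None)

    def labels_full(self, session_frames: int) -> np.ndarray:
        """Cluster id per frame over the whole session; 0 = unclustered."""
        full = np.zeros(session_frames, dtype=int)
        full[self.clustered_frames] = self.frame_labels
        return full


def coactivation_null_counts(
    x: np.ndarray, n_surrogates: int, rng: np.random.Generator
) -> np.ndarray:
    """Pairwise coactivation counts under random circular shifts.

    Circularly shifting two spike trains independently changes their
    coactivation only through the relative offset, so the null is read off
    the circular cross-correlation (computed for all offsets at once via
    FFT) at ``n_surrogates`` random nonzero offsets shared across pairs.
    Returns an (n_pairs, n_surrogates) integer array in pdist pair order.
    """
    N, F = x.shape
    offsets = rng.integers(1, F, size=n_surrogates)
    ft = np.fft.rfft(x.astype(float), axis=1)
    pairs = []
    for i in range(N - 1):
        cc = np.fft.irfft(ft[i] * np.conj(ft[i + 1 :]), n=F, axis=1)
        pairs.append(np.rint(cc[:, offsets]))
    return np.concatenate(pairs, axis=0).astype(int)


def functional_network(
    raster: Raster,
    n_surrogates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    bonferroni: bool = False,
) -> FunctionalNetwork:
    """Edges where observed coactivation beats the circular-shift null.

    An edge (i, j) is present iff the observed count of frames where both
    neurons spike strictly exceeds the empirical (1 - alpha) quantile of the
    surrogate counts.  All-silent neurons end up isolated.
    """
    x = raster.spikes.astype(np.int64)
    N = x.shape[0]
    if N == 0 or raster.n_frames == 0:
        raise ValueError("raster is empty")
    if bonferroni:
        alpha = alpha / (N * (N - 1) / 2)
    rng = substream(seed, "network")
    observed = squareform(x @ x.T, checks=False)  # condensed pair order
    null = coactivation_null_counts(x, n_surrogates, rng)
    thr = np.quantile(null, 1.0 - alpha, axis=1)
    adj = squareform((observed > thr).astype(np.uint8)).astype(bool)
    np.fill_diagonal(adj, False)
    return FunctionalNetwork(adjacency=adj, alpha=alpha, n_surrogates=n_surrogates)


def filter_raster(raster: Raster, network: FunctionalNetwork) -> Raster:
    """Keep a spike iff its neuron has >= 1 active network neighbor that frame."""
    if network.adjacency.shape[0] != raster.n_neurons:
        raise ValueError("network and raster cover different neurons")
    x = raster.spikes
    supported = network.adjacency.astype(np.uint8) @ x > 0
    return Raster((x.astype(bool) & supported).astype(np.uint8), raster.frame_period_s)


def jaccard_similarity(frame_u: np.ndarray, frame_v: np.ndarray) -> float:
    """|intersection| / |union| of two binary frames; 0 when both are empty."""
    u = np.asarray(frame_u, dtype=bool)
    v = np.asarray(frame_v, dtype=bool)
    if u.shape != v.shape:
        raise ValueError("frames must have equal length")
    union = np.logical_or(u, v).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(u, v).sum() / union)


def jaccard_matrix(frames: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard similarity of binary row vectors (BLAS-backed)."""
    f = np.asarray(frames, dtype=bool)
    counts = f.sum(axis=1).astype(np.float32)
    inter = f.astype(np.float32) @ f.astype(np.float32).T
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    np.fill_diagonal(sim, 1.0)
    return sim  # float32: halves memory traffic in the surrogate z-test


@dataclass
class ClusterResult:
    labels_by_k: dict[int, np.ndarray]
    clustered_frames: np.ndarray
    similarity: np.ndarray  # (n_clustered, n_clustered) Jaccard
    linkage_matrix: np.ndarray


def cluster_frames(filtered_raster: Raster, k_min: int = 2, k_max: int = 10) -> ClusterResult:
    """Ward-linkage hierarchical clustering of nonempty population vectors.

    Distances are 1 - Jaccard; all-zero frames are excluded and never
    clustered.  Returns the dendrogram cut at every k in [k_min, k_max].
    """
    x = filtered_raster.spikes.astype(bool)
    nonempty = np.flatnonzero(x.sum(axis=0) > 0)
    if nonempty.size < k_max:
        raise ValueError(f"only {nonempty.size} nonempty frames; need >= k_max={k_max}")
    frames = x[:, nonempty].T  # (n_clustered, N)
    sim = jaccard_matrix(frames)
    dist = squareform(1.0 - sim, checks=False)
    Z = linkage(dist, method="ward")
    labels_by_k = {k: fcluster(Z, t=k, criterion="maxclust") for k in range(k_min, k_max + 1)}
    return ClusterResult(labels_by_k, nonempty, sim, Z)


def contrast_index(similarity: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of (within-cluster sim - members-to-outside sim).

    Singleton clusters contribute a within-similarity of 1 by convention.
    Raises for a single cluster, where the index is undefined.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if ids.size < 2:
        raise ValueError("contrast index needs >= 2 clusters")
    total = 0.0
    for c in ids:
        inside = labels == c
        m = int(inside.sum())
        sub = similarity[np.ix_(inside, inside)]
        within = 1.0 if m == 1 else (sub.sum() - m) / (m * (m - 1))
        between = float(similarity[np.ix_(inside, ~inside)].mean())
        total += within - between
    return total / ids.size


def select_k(contrast_by_k: dict[int, float]) -> int:
    """k with maximal contrast index; ties resolve to the smallest k."""
    if not contrast_by_k:
        raise ValueError("no candidate k supplied")
    best = max(contrast_by_k.values())
    return min(k for k, v in contrast_by_k.items() if v == best)


def _mean_within_similarity(similarity: np.ndarray, idx: np.ndarray) -> float:
    m = idx.size
    sub = similarity[np.ix_(idx, idx)]
    return float((sub.sum(dtype=np.float64) - m) / (m * (m - 1)))


def test_ensembles(
    frame_labels: np.ndarray,
    similarity: np.ndarray,
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[dict[int, float], dict[int, float], list[int]]:
    """One-sided z-test of within-cluster similarity against random draws.

    For a cluster of m frames, the null is the mean pairwise similarity of m
    frames drawn uniformly without replacement from all clustered frames,
    over ``n_iter`` iterations; z = (s_obs - mean_null) / sd_null and
    p = P(Z >= z).  A zero-variance null falls back to the exceedance
    fraction.  Singleton clusters are excluded with a warning.  Returns
    (p-values, z-stats, significant cluster ids).
    """
    rng = substream(seed, "ensemble-test")
    labels = np.asarray(frame_labels)
    n_frames = labels.size
    pvals: dict[int, float] = {}
    zstats: dict[int, float] = {}
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            warnings.warn(f"cluster {c} has a single frame; significance undefined")
            continue
        s_obs = _mean_within_similarity(similarity, idx)
        m = idx.size
        # Batch v' S v over all draws via BLAS: rows of B are the indicator
        # vectors of m frames sampled without replacement.
        keys = rng.random((n_iter, n_frames))
        draws = np.argpartition(keys, m - 1, axis=1)[:, :m]
        B = np.zeros((n_iter, n_frames), dtype=np.float32)
        np.put_along_axis(B, draws, 1.0, axis=1)
        quad = np.einsum("ij,ij->i", B @ similarity, B, dtype=np.float64)
        null = (quad - m) / (m * (m - 1))
        sd = null.std()
        if sd == 0.0:
            p = float(np.mean(null >= s_obs))
            z = np.inf if s_obs > null.mean() else 0.0
        else:
            z = float((s_obs - null.mean()) / sd)
            p = float(norm.sf(z))
        pvals[int(c)] = p
        zstats[int(c)] = z
    significant = [c for c, p in pvals.items() if p < alpha]
    return pvals, zstats, significant


def ensemble_signals(
    frame_labels: np.ndarray,
    clustered_frames: np.ndarray,
    ensemble_ids: list[int],
    session_frames: int,
) -> dict[int, np.ndarray]:
    """Binary occurrence series per significant ensemble (pairwise disjoint)."""
    signals: dict[int, np.ndarray] = {}
    for e in ensemble_ids:
        sig = np.zeros(session_frames, dtype=np.uint8)
        sig[clustered_frames[np.asarray(frame_labels) == e]] = 1
        signals[e] = sig
    return signals


def detect_ensembles(
    raster: Raster,
    n_surrogates: int = 1000,
    alpha_network: float = 0.05,
    k_min: int = 2,
    k_max: int = 10,
    n_iter: int = 1000,
    alpha_ensemble: float = 0.05,
    seed: int = 0,
    forced_k: int | None = None,
) -> EnsembleModel:
    """Full detection chain on one raster.

    ``forced_k`` bypasses contrast-index selection (used by the
    offsemble-removal control, which must recover a prescribed number of
    activity patterns).
    """
    net = functional_network(raster, n_surrogates=n_surrogates, alpha=alpha_network, seed=seed)
    filtered = filter_raster(raster, net)
    clusters = cluster_frames(filtered, k_min=k_min, k_max=k_max)
    contrast = {
        k: contrast_index(clusters.similarity, lab) for k, lab in clusters.labels_by_k.items()
    }
    k_star = forced_k if forced_k is not None else select_k(contrast)
    if k_star not in clusters.labels_by_k:
        raise ValueError(f"forced k={k_star} outside clustered range")
    labels = clusters.labels_by_k[k_star]
    pvals, zstats, sig = test_ensembles(
        labels, clusters.similarity, n_iter=n_iter, alpha=alpha_ensemble, seed=seed
    )
    signals = ensemble_signals(labels, clusters.clustered_frames, sig, raster.n_frames)
    return EnsembleModel(
        frame_labels=labels,
        clustered_frames=clusters.clustered_frames,
        n_clusters=k_star,
        contrast_by_k=contrast,
        cluster_pvalues=pvals,
        z_stats=zstats,
        ensemble_ids=sig,
        ensemble_signals=signals,
        network=net,
        filtered_raster=filtered,
    )
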