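"""Strain inference from SNP allele-frequency trajectories.

Linked SNPs co-localized on the same genotype rise and fall together, so
clustering major-allele frequency trajectories partitions a species' SNPs
into at most two biologically meaningful clusters: one *differentiating* the
two coexisting strains (tracking the strain-1 frequency f(t)) and one of
*shared*, nearly fixed SNPs separating both strains from the reference
genome. Clustering uses k-means with a dynamic-time-warping assignment
distance (or a UPGMA backend on trajectory correlations); candidate extra
clusters closer than a merge distance are rejected, mirroring the
observation that a third cluster is never statistically distinguishable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import AbundanceTable, SnpTrajectory, ValidationError

__all__ = [
    "StrainModelConfig",
    "StrainModel",
    "dtw_distance",
    "cluster_trajectories",
    "select_strain_model",
    "estimate_strain_frequencies",
    "strain_abundance_table",
]


@dataclass(frozen=True)
class StrainModelConfig:
    max_clusters: int = 3
    merge_distance: float = 0.15     # RMS centroid separation below which clusters merge
    fixed_threshold: float = 0.9     # centroid above this at all times = shared cluster
    min_cluster_coverage: float = 0.8
    backend: str = "dtw-kmeans"      # or "upgma"
    n_init: int = 10
    max_iter: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.fixed_threshold < 1:
            raise ValueError("fixed_threshold must be in (0, 1)")
        if self.merge_distance <= 0:
            raise ValueError("merge_distance must be > 0")
        if self.backend not in ("dtw-kmeans", "upgma"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class StrainModel:
    """Per-species strain decomposition inferred from SNP trajectories."""

    species_id: str
    n_strains: int
    differentiating: list[str]
    shared: list[str]
    unassigned: list[str] = field(default_factory=list)
    frequency: np.ndarray | None = None  # strain-1 frequency f(t)
    major_strain: int = 1                # which strain is major at t0

    def __post_init__(self) -> None:
        if self.n_strains not in (1, 2):
            raise ValidationError("n_strains must be 1 or 2")
        overlap = set(self.differentiating) & set(self.shared)
        if overlap:
            raise ValidationError(f"SNPs in both clusters: {sorted(overlap)[:5]}")
        if self.n_strains == 2 and not self.differentiating:
            raise ValidationError("a two-strain model needs differentiating SNPs")
        if self.frequency is not None:
            f = np.asarray(self.frequency, dtype=float)
            ok = f[np.isfinite(f)]
            if ok.size and (ok.min() < -1e-9 or ok.max() > 1 + 1e-9):
                raise ValidationError("strain frequency must lie in [0, 1]")

    @property
    def genetic_distance(self) -> int:
        """Number of SNPs differentiating the two strains."""
        return len(self.differentiating)


# ---------------------------------------------------------------------------
# Dynamic time warping


def dtw_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Classic DTW distance: local cost |a_i - b_j|, no warping window.

    Full dynamic program over steps {(i-1,j), (i,j-1), (i-1,j-1)}; the
    returned value is the minimal cumulative cost of a monotone alignment of
    the two series.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires non-empty series")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("DTW requires finite values")
    n, m = a.size, b.size
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        cost = np.abs(a[i - 1] - b)
        for j in range(1, m + 1):
            D[i, j] = cost[j - 1] + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return float(D[n, m])


try:  # compiled DTW kernel; the pure-Python dtw_distance stays the reference
    from numba import njit

    @njit(cache=True)
    def _dtw_matrix_kernel(X, C):  # pragma: no cover - exercised via _dtw_matrix
        n, T = X.shape
        k, S = C.shape
        out = np.empty((n, k))
        D = np.empty((T + 1, S + 1))
        for i in range(n):
            for j in range(k):
                D[:, :] = np.inf
                D[0, 0] = 0.0
                for a in range(1, T + 1):
                    for b in range(1, S + 1):
                        cost = abs(X[i, a - 1] - C[j, b - 1])
                        best = D[a - 1, b - 1]
                        if D[a - 1, b] < best:
                            best = D[a - 1, b]
                        if D[a, b - 1] < best:
                            best = D[a, b - 1]
                        out[i, j] = D[a, b] = cost + best
        return out

except ImportError:  # numba unavailable: fall back to the reference DP
    _dtw_matrix_kernel = None


def _dtw_matrix(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    X = np.ascontiguousarray(X, dtype=float)
    centroids = np.ascontiguousarray(centroids, dtype=float)
    if _dtw_matrix_kernel is not None:
        return _dtw_matrix_kernel(X, centroids)
    out = np.empty((X.shape[0], centroids.shape[0]))
    for i, x in enumerate(X):
        for k, c in enumerate(centroids):
            out[i, k] = dtw_distance(x, c)
    return out


def cluster_trajectories(
    trajectories: np.ndarray | Sequence[Sequence[float]],
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means over same-grid time series with DTW assignment distance.

    Assignment uses :func:`dtw_distance`; the centroid update is the
    pointwise mean of members (all series share one time grid), which avoids
    barycenter-averaging ambiguity while keeping DTW as the dissimilarity.
    Returns (assignments, centroids, inertia) of the best of ``n_init``
    restarts, where inertia is the sum of squared DTW distances to the
    assigned centroid.
    """
    X = np.asarray(trajectories, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of trajectories {X.shape[0]}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        idx = rng.choice(X.shape[0], size=k, replace=False)
        centroids = X[idx].copy()
        assign = np.full(X.shape[0], -1)
        for _ in range(max_iter):
            dists = _dtw_matrix(X, centroids)
            new_assign = dists.argmin(axis=1)
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for j in range(k):
                members = X[assign == j]
                if len(members):
                    centroids[j] = members.mean(axis=0)
                else:  # re-seed an empty cluster on the farthest point
                    centroids[j] = X[dists.min(axis=1).argmax()]
        inertia = float((dists[np.arange(X.shape[0]), assign] ** 2).sum())
        if best is None or inertia < best[2]:
            best = (assign.copy(), centroids.copy(), inertia)
    return best


def _upgma_clusters(X: np.ndarray, k: int) -> np.ndarray:
    """UPGMA cut at k clusters on Euclidean distances between rows of the
    SNP-trajectory correlation matrix."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = squareform(
        np.sqrt(np.maximum(0.0, ((corr[:, None, :] - corr[None, :, :]) ** 2).sum(-1))),
        checks=False,
    )
    Z = linkage(dist, method="average")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def _rms_separation(c1: np.ndarray, c2: np.ndarray) -> float:
    return float(np.sqrt(np.mean((c1 - c2) ** 2)))


def select_strain_model(
    trajectories: Sequence[SnpTrajectory],
    config: StrainModelConfig | None = None,
    seed: int = 0,
) -> StrainModel:
    """Fit the per-species strain model from its persistent SNP trajectories.

    Fits k = 1, 2, 3 clusters; a k=3 solution whose closest centroid pair
    sits within ``merge_distance`` (RMS over time points) collapses to k=2,
    and likewise k=2 collapses to k=1 — at most two strains are ever
    reported. A cluster whose centroid exceeds ``fixed_threshold`` at every
    time point is the *shared* (nearly fixed) cluster; a remaining non-fixed
    cluster differentiates two strains. Outliers (DTW distance to the nearest
    centroid beyond the 95th percentile of within-cluster distances) are
    appended to shared when nearly fixed on average, else left unassigned.
    """
    cfg = config or StrainModelConfig()
    if not trajectories:
        return StrainModel("", 1, [], [])
    species_id = trajectories[0].genome_id
    ids = [t.snp_id for t in trajectories]
    X = np.vstack([np.nan_to_num(t.freqs, nan=1.0) for t in trajectories])
    n = X.shape[0]

    if n == 1:
        only = trajectories[0]
        fixed = np.all(np.nan_to_num(only.freqs, nan=1.0) > cfg.fixed_threshold)
        if fixed:
            return StrainModel(species_id, 1, [], ids)
        f, major = estimate_strain_frequencies([only])
        return StrainModel(species_id, 2, ids, [], frequency=f, major_strain=major)

    def fit(k: int) -> tuple[np.ndarray, np.ndarray]:
        if cfg.backend == "upgma":
            assign = _upgma_clusters(X, k)
            centroids = np.vstack([X[assign == j].mean(axis=0) for j in range(assign.max() + 1)])
            return assign, centroids
        assign, centroids, _ = cluster_trajectories(
            X, k, seed=seed, n_init=cfg.n_init, max_iter=cfg.max_iter
        )
        return assign, centroids

    k_use = 1
    assign, centroids = np.zeros(n, dtype=int), X.mean(axis=0, keepdims=True)
    for k in range(min(cfg.max_clusters, n), 0, -1):
        a, c = fit(k)
        live = np.unique(a)
        if live.size < k:
            continue
        seps = [
            _rms_separation(c[i], c[j])
            for i in range(k)
            for j in range(i + 1, k)
        ]
        if seps and min(seps) < cfg.merge_distance:
            continue  # indistinguishable pair: reject this k
        k_use, assign, centroids = k, a, c
        break

    # never report more than two strain-bearing clusters
    if k_use > 2:
        a, c = fit(2)
        if np.unique(a).size == 2 and _rms_separation(c[0], c[1]) >= cfg.merge_distance:
            k_use, assign, centroids = 2, a, c
        else:
            k_use, assign, centroids = 1, np.zeros(n, dtype=int), X.mean(axis=0, keepdims=True)

    # Outlier ("loose SNP") detection against the accepted clustering: beyond
    # the 95th percentile of the SNP's own cluster's distances AND clearly
    # outside that cluster's bulk (2x its median), so tight clusters yield no
    # outliers. Cutoffs are per cluster: cluster noise scales with allele
    # frequency, so pooling would mis-flag the noisier cluster wholesale.
    dists = _dtw_matrix(X, centroids)
    own = dists[np.arange(n), assign]
    outlier = np.zeros(n, dtype=bool)
    if n >= 20:
        for j in range(k_use):
            members = assign == j
            if members.sum() < 5:
                continue
            d_j = own[members]
            cutoff = max(np.percentile(d_j, 95), 2.0 * np.median(d_j))
            outlier[members] = d_j > cutoff

    fixed_cluster = [
        j for j in range(k_use) if np.all(centroids[j] > cfg.fixed_threshold)
    ]
    moving_cluster = [j for j in range(k_use) if j not in fixed_cluster]

    shared: list[str] = []
    unassigned: list[str] = []
    diff: list[str] = []
    diff_idx: list[int] = []
    if len(moving_cluster) > 1:
        # more than one non-fixed cluster is never statistically supported;
        # keep the largest as the differentiating cluster
        warnings.warn(
            f"{species_id}: {len(moving_cluster)} non-fixed clusters; "
            "keeping the largest as differentiating"
        )
        sizes = {j: int((assign == j).sum()) for j in moving_cluster}
        keep = max(sizes, key=sizes.get)
        for j in moving_cluster:
            if j != keep:
                unassigned.extend(ids[i] for i in np.flatnonzero(assign == j))
        moving_cluster = [keep]

    for i in range(n):
        j = assign[i]
        if outlier[i]:
            if np.nanmean(X[i]) > cfg.fixed_threshold:
                shared.append(ids[i])
            else:
                unassigned.append(ids[i])
        elif j in fixed_cluster:
            shared.append(ids[i])
        elif moving_cluster and j == moving_cluster[0]:
            diff.append(ids[i])
            diff_idx.append(i)
        else:
            unassigned.append(ids[i])

    top_two = sorted(np.bincount(assign, minlength=k_use), reverse=True)[:2]
    if sum(top_two) < cfg.min_cluster_coverage * n:
        warnings.warn(
            f"{species_id}: top clusters cover only {sum(top_two) / n:.0%} of SNPs"
        )

    if not diff:
        return StrainModel(species_id, 1, [], shared, unassigned)
    f, major = estimate_strain_frequencies([trajectories[i] for i in diff_idx])
    return StrainModel(
        species_id, 2, diff, shared, unassigned, frequency=f, major_strain=major
    )


def estimate_strain_frequencies(
    trajectories: Sequence[SnpTrajectory],
) -> tuple[np.ndarray, int]:
    """Depth-weighted mean allele frequency of the differentiating cluster.

    f(t) = sum_s depth_s(t) freq_s(t) / sum_s depth_s(t). Time points where
    every SNP has zero depth are marked missing (NaN), not imputed. The
    strain carrying the cluster alleles is *major* (returns 1) iff
    f(t0) >= 0.5 at the first finite time point, else the model's strain 1 is
    the minor strain (returns 2).
    """
    if not trajectories:
        raise ValidationError("need at least one differentiating SNP")
    F = np.vstack([t.freqs for t in trajectories])
    W = np.vstack([t.depths for t in trajectories]).astype(float)
    W = np.where(np.isfinite(F), W, 0.0)
    F0 = np.nan_to_num(F, nan=0.0)
    tot = W.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(tot > 0, (W * F0).sum(axis=0) / tot, np.nan)
    finite = np.flatnonzero(np.isfinite(f))
    if finite.size == 0:
        raise ValidationError("no time point with nonzero depth")
    major = 1 if f[finite[0]] >= 0.5 else 2
    return f, major


def strain_abundance_table(
    models: Sequence[StrainModel], species_table: AbundanceTable
) -> AbundanceTable:
    """Partition species abundances into strain abundances via f(t).

    Two-strain species contribute rows ``<sp>.s1`` (f * A) and ``<sp>.s2``
    ((1-f) * A); one-strain species pass through unchanged. Strain rows of a
    species sum to the species abundance at every time point, so whole-table
    column sums remain 1. The lineage gains a strain label.
    """
    by_species = {m.species_id: m for m in models}
    missing = set(by_species) - set(species_table.taxa)
    if missing:
        raise ValidationError(f"species absent from the abundance table: {sorted(missing)}")
    rows = {}
    lineage_rows = {}
    for taxon in species_table.taxa:
        A = species_table.trajectory(taxon)
        lin = species_table.lineage.loc[taxon]
        model = by_species.get(taxon)
        if model is None or model.n_strains == 1:
            rows[taxon] = A
            lineage_rows[taxon] = dict(lin)
        else:
            f = np.nan_to_num(model.frequency, nan=0.5)
            rows[f"{taxon}.s1"] = f * A
            rows[f"{taxon}.s2"] = (1.0 - f) * A
            for s in (1, 2):
                d = dict(lin)
                d["strain"] = f"{taxon}.s{s}"
                lineage_rows[f"{taxon}.s{s}"] = d
    values = pd.DataFrame(rows, index=species_table.values.columns).T
    lineage = pd.DataFrame(lineage_rows).T
    values.index.name = "taxon_id"
    return AbundanceTable(values, lineage, renormalize=True)
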