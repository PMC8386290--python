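"""Cluster-based permutation statistics over channel × frequency × time.

The unit of analysis is the per-subject condition-difference matrix (S3
minus S1 ERSP in dB).  Group differences are tested with a nonparametric
cluster-based permutation test: an independent-samples t value is computed
at every (channel, frequency, time) point, points exceeding the two-tailed
cluster-forming threshold are linked into sign-consistent clusters —
spatially through triangulation-defined electrode neighbors, spectrally and
temporally through adjacent bins — and each cluster's mass (summed t) is
compared against the null distribution of the maximal cluster mass under
random relabelings of subjects.

Exchanging whole subject difference matrices preserves the within-subject
correlation structure; group sizes are held fixed.  The Monte-Carlo p value
uses the (count + 1) / (n_perm + 1) correction so it is never zero; an
exact mode enumerates every distinct group split for small cohorts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError
from scipy.stats import t as t_dist

from .simulate import ChannelLayout
from .spectral import TFR, BandSpec, band_select


# ---------------------------------------------------------------------------
# Spatial adjacency

@dataclass(frozen=True)
class NeighborGraph:
    """Symmetric, irreflexive channel adjacency."""

    ch_names: tuple[str, ...]
    adjacency: np.ndarray  # (n, n) bool
    method: str = "delaunay"

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.shape != (len(self.ch_names),) * 2:
            raise ValueError("adjacency must be square over channels")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        object.__setattr__(self, "adjacency", a)

    def neighbors(self, name: str) -> list[str]:
        i = self.ch_names.index(name)
        return [self.ch_names[j] for j in np.flatnonzero(self.adjacency[i])]

    def subset(self, names: list[str]) -> "NeighborGraph":
        idx = [self.ch_names.index(n) for n in names]
        return NeighborGraph(tuple(names), self.adjacency[np.ix_(idx, idx)],
                             self.method)


def triangulation_neighbors(layout: ChannelLayout,
                            max_distance: float | None = None) -> NeighborGraph:
    """Channel adjacency from a Delaunay triangulation of sensor positions.

    3D positions are projected to the plane with an azimuthal equidistant
    projection about the vertex, triangulated, and triangle edges become
    neighbor pairs.  ``max_distance`` (in position units) optionally prunes
    long edges; default is no pruning.
    """
    pos = layout.positions / np.linalg.norm(layout.positions, axis=1, keepdims=True)
    theta = np.arccos(np.clip(pos[:, 2], -1.0, 1.0))
    rho = np.hypot(pos[:, 0], pos[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(rho > 1e-12, theta / rho, 0.0)
    pts = pos[:, :2] * scale[:, None]
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError(f"cannot triangulate electrode positions: {exc}") from exc
    n = layout.n_channels
    adj = np.zeros((n, n), dtype=bool)
    for simplex in tri.simplices:
        for i, j in itertools.combinations(simplex, 2):
            adj[i, j] = adj[j, i] = True
    if max_distance is not None:
        d = np.linalg.norm(layout.positions[:, None] - layout.positions[None, :], axis=-1)
        adj &= d <= max_distance
    return NeighborGraph(tuple(layout.channel_names), adj)


# ---------------------------------------------------------------------------
# Subject differences and the pointwise statistic

@dataclass
class SubjectDifference:
    """Per-subject S3 − S1 ERSP difference (dB) with shared dimensions."""

    subject_id: str
    group: str
    data: np.ndarray  # channels × freqs × times
    ch_names: tuple[str, ...]
    freqs: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.ch_names), len(self.freqs), len(self.times)):
            raise ValueError("data shape does not match dimension metadata")


def subject_difference(ersp_s3: TFR, ersp_s1: TFR, subject_id: str = "",
                       group: str = "") -> SubjectDifference:
    """Point-by-point S3 − S1 subtraction of two dB ERSP matrices."""
    if ersp_s3.data.shape != ersp_s1.data.shape:
        raise ValueError("ERSP shapes differ between conditions")
    if (list(ersp_s3.ch_names) != list(ersp_s1.ch_names)
            or not np.allclose(ersp_s3.freqs, ersp_s1.freqs)
            or not np.allclose(ersp_s3.times, ersp_s1.times)):
        raise ValueError("dimension metadata differs between conditions")
    return SubjectDifference(
        subject_id, group, ersp_s3.data - ersp_s1.data,
        tuple(ersp_s3.ch_names), ersp_s3.freqs.copy(), ersp_s3.times.copy())


def pointwise_t(group_a: list, group_b: list):
    """Pooled-variance independent-samples t map comparing the two groups.

    Accepts lists of :class:`SubjectDifference` (or bare arrays of a common
    shape).  Returns ``(t_map, df)``; points with zero pooled variance or
    non-finite data are NaN.
    """
    xa = np.stack([getattr(s, "data", s) for s in group_a])
    xb = np.stack([getattr(s, "data", s) for s in group_b])
    na, nb = len(xa), len(xb)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    df = na + nb - 2
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    ssa = ((xa - ma) ** 2).sum(axis=0)
    ssb = ((xb - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_map = np.where(denom > 0, (ma - mb) / denom, np.nan)
    return t_map, df


# ---------------------------------------------------------------------------
# Cluster formation

@dataclass
class Cluster:
    """A connected set of suprathreshold points with summed-t mass."""

    channels: np.ndarray    # member channel indices
    freq_idx: np.ndarray
    time_idx: np.ndarray
    mass: float
    sign: int               # +1 / -1
    ch_names: tuple[str, ...]
    freqs: np.ndarray       # member frequency values (Hz), aligned with members
    times: np.ndarray       # member time values (s)
    p_value: float = np.nan

    @property
    def n_points(self) -> int:
        return len(self.channels)

    @property
    def electrodes(self) -> list[str]:
        return sorted({self.ch_names[c] for c in self.channels})

    @property
    def freq_range(self) -> tuple[float, float]:
        return float(self.freqs.min()), float(self.freqs.max())

    @property
    def time_range(self) -> tuple[float, float]:
        return float(self.times.min()), float(self.times.max())

    def summary(self) -> dict:
        return {
            "electrodes": self.electrodes,
            "freq_range_hz": list(self.freq_range),
            "time_range_s": list(self.time_range),
            "n_points": self.n_points,
            "mass": float(self.mass),
            "sign": int(self.sign),
            "p_value": float(self.p_value),
        }


def _lattice_adjacency(adj_ch: np.ndarray, n_f: int, n_t: int) -> sparse.csr_matrix:
    """Sparse adjacency over the flattened (channel, freq, time) lattice:
    channel-graph edges at fixed (f, t), plus f±1 and t±1 lattice edges."""
    n_ch = adj_ch.shape[0]
    n_pts = n_ch * n_f * n_t
    rows, cols = [], []

    ft = n_f * n_t
    ci, cj = np.nonzero(np.triu(adj_ch, k=1))
    if len(ci):
        offs = np.arange(ft)
        rows.append((ci[:, None] * ft + offs[None, :]).ravel())
        cols.append((cj[:, None] * ft + offs[None, :]).ravel())

    base = np.arange(n_pts).reshape(n_ch, n_f, n_t)
    if n_f > 1:
        rows.append(base[:, :-1, :].ravel())
        cols.append(base[:, 1:, :].ravel())
    if n_t > 1:
        rows.append(base[:, :, :-1].ravel())
        cols.append(base[:, :, 1:].ravel())

    if not rows:
        return sparse.csr_matrix((n_pts, n_pts))
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    data = np.ones(len(r), dtype=bool)
    a = sparse.coo_matrix((data, (r, c)), shape=(n_pts, n_pts))
    return (a + a.T).tocsr()


def _component_masses(t_flat: np.ndarray, mask: np.ndarray,
                      lattice: sparse.csr_matrix):
    """Connected components of ``mask`` under ``lattice``; returns
    (list of member-index arrays, masses)."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return [], np.empty(0)
    sub = lattice[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    members = [idx[labels == k] for k in range(n_comp)]
    masses = np.array([t_flat[m].sum() for m in members])
    return members, masses


def form_clusters(t_map: np.ndarray, df: int, cluster_alpha: float,
                  neighbors: NeighborGraph, freqs: np.ndarray,
                  times: np.ndarray,
                  lattice: sparse.csr_matrix | None = None) -> list[Cluster]:
    """Group suprathreshold points of like sign into connected clusters.

    The cluster-forming threshold is the two-tailed critical t value at
    ``cluster_alpha`` for ``df`` degrees of freedom.
    """
    if t_map.size == 0:
        raise ValueError("empty t map")
    n_ch, n_f, n_t = t_map.shape
    if n_ch != len(neighbors.ch_names):
        raise ValueError("t map channels do not match neighbor graph")
    thresh = t_dist.ppf(1.0 - cluster_alpha / 2.0, df)
    if lattice is None:
        lattice = _lattice_adjacency(neighbors.adjacency, n_f, n_t)
    t_flat = t_map.ravel()
    finite = np.isfinite(t_flat)
    clusters: list[Cluster] = []
    for sign in (+1, -1):
        mask = finite & (sign * t_flat > thresh)
        members, masses = _component_masses(t_flat, mask, lattice)
        for m, mass in zip(members, masses):
            ci, fi, ti = np.unravel_index(m, t_map.shape)
            clusters.append(Cluster(
                channels=ci, freq_idx=fi, time_idx=ti,
                mass=float(mass), sign=sign,
                ch_names=neighbors.ch_names,
                freqs=freqs[fi], times=times[ti]))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


# ---------------------------------------------------------------------------
# Permutation test

@dataclass
class PermutationResult:
    """Observed clusters with Monte-Carlo p values plus the null that
    produced them."""

    clusters: list[Cluster]
    null_max_mass: np.ndarray
    n_perm: int
    cluster_alpha: float
    df: int
    threshold: float
    band: BandSpec | None
    method: str
    seed: int | None
    freqs: np.ndarray = field(default=None)
    times: np.ndarray = field(default=None)
    ch_names: tuple[str, ...] = field(default=None)
    t_map: np.ndarray = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    def to_dict(self) -> dict:
        return {
            "n_permutations": int(self.n_perm),
            "cluster_alpha": float(self.cluster_alpha),
            "df": int(self.df),
            "threshold_t": float(self.threshold),
            "method": self.method,
            "seed": self.seed,
            "band": None if self.band is None else
                {"name": self.band.name, "f_lo": self.band.f_lo, "f_hi": self.band.f_hi},
            "clusters": [c.summary() for c in self.clusters],
        }


def _max_masses_for_splits(x: np.ndarray, splits: np.ndarray, thresh: float,
                           lattice: sparse.csr_matrix, df: int) -> np.ndarray:
    """Max |cluster mass| for each row of ``splits`` (boolean group-A
    membership matrices over subjects).  ``x`` is (subjects, points)."""
    n_sub, n_pts = x.shape
    na = int(splits[0].sum())
    nb = n_sub - na
    out = np.empty(len(splits))
    x2 = x * x
    tot = x.sum(axis=0)
    tot2 = x2.sum(axis=0)
    for i, in_a in enumerate(splits):
        sa = x[in_a].sum(axis=0)
        sa2 = x2[in_a].sum(axis=0)
        sb = tot - sa
        sb2 = tot2 - sa2
        ma, mb = sa / na, sb / nb
        ss = (sa2 - na * ma**2) + (sb2 - nb * mb**2)
        denom = np.sqrt(ss / df * (1.0 / na + 1.0 / nb))
        with np.errstate(invalid="ignore", divide="ignore"):
            t_flat = np.where(denom > 0, (ma - mb) / denom, np.nan)
        finite = np.isfinite(t_flat)
        best = 0.0
        for sign in (+1, -1):
            _, masses = _component_masses(t_flat, finite & (sign * t_flat > thresh), lattice)
            if len(masses):
                best = max(best, np.abs(masses).max())
        out[i] = best
    return out


def permutation_test(
    group_a: list,
    group_b: list,
    neighbors: NeighborGraph,
    band: BandSpec | None = None,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int | None = None,
    method: str = "montecarlo",
) -> PermutationResult:
    """Cluster-based permutation test between two groups of subject
    difference matrices.

    ``method="montecarlo"`` draws ``n_perm`` random relabelings (default
    1,000); ``method="exact"`` enumerates every distinct group split (small
    cohorts only) and ignores ``n_perm``/``seed``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    if method not in ("montecarlo", "exact"):
        raise ValueError("method must be 'montecarlo' or 'exact'")
    if method == "montecarlo" and n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    def _extract(s):
        if band is not None and hasattr(s, "freqs"):
            mask = (s.freqs >= band.f_lo - 1e-9) & (s.freqs <= band.f_hi + 1e-9)
            if not mask.any():
                raise ValueError(f"band {band.name} selects no frequency bins")
            return getattr(s, "data")[:, mask, :], s.freqs[mask], s.times, tuple(s.ch_names)
        d = getattr(s, "data", np.asarray(s))
        return d, getattr(s, "freqs", np.arange(d.shape[1], dtype=float)), \
            getattr(s, "times", np.arange(d.shape[2], dtype=float)), \
            getattr(s, "ch_names", neighbors.ch_names)

    da, freqs, times, ch_names = _extract(group_a[0])
    arrs_a = [_extract(s)[0] for s in group_a]
    arrs_b = [_extract(s)[0] for s in group_b]
    if tuple(ch_names) != tuple(neighbors.ch_names):
        raise ValueError("subject channels do not match neighbor graph")

    t_map, df = pointwise_t(arrs_a, arrs_b)
    n_ch, n_f, n_t = t_map.shape
    lattice = _lattice_adjacency(neighbors.adjacency, n_f, n_t)
    thresh = t_dist.ppf(1.0 - cluster_alpha / 2.0, df)
    clusters = form_clusters(t_map, df, cluster_alpha, neighbors, freqs, times,
                             lattice=lattice)

    x = np.stack(arrs_a + arrs_b).reshape(len(arrs_a) + len(arrs_b), -1)
    n_sub, na = x.shape[0], len(arrs_a)

    if method == "exact":
        combos = list(itertools.combinations(range(n_sub), na))
        splits = np.zeros((len(combos), n_sub), dtype=bool)
        for i, combo in enumerate(combos):
            splits[i, list(combo)] = True
        null = _max_masses_for_splits(x, splits, thresh, lattice, df)
        n_eff = len(combos)
        for c in clusters:
            c.p_value = float((null >= abs(c.mass) - 1e-12).sum()) / n_eff
    else:
        rng = np.random.default_rng(seed)
        splits = np.zeros((n_perm, n_sub), dtype=bool)
        for i in range(n_perm):
            splits[i, rng.permutation(n_sub)[:na]] = True
        null = _max_masses_for_splits(x, splits, thresh, lattice, df)
        n_eff = n_perm
        for c in clusters:
            c.p_value = (float((null >= abs(c.mass) - 1e-12).sum()) + 1.0) / (n_perm + 1.0)

    return PermutationResult(
        clusters=clusters, null_max_mass=null, n_perm=n_eff,
        cluster_alpha=cluster_alpha, df=df, threshold=float(thresh),
        band=band, method=method, seed=seed,
        freqs=freqs, times=times, ch_names=tuple(ch_names), t_map=t_map)


def cluster_mean_extract(subject: SubjectDifference, cluster: Cluster) -> float:
    """Mean of a subject's difference values over the cluster's points.

    Member points are matched by value (channel name, Hz, s) so a cluster
    found on a band-selected grid can be extracted from any compatible
    subject matrix.
    """
    if cluster.n_points == 0:
        raise ValueError("empty cluster")
    name_to_idx = {n: i for i, n in enumerate(subject.ch_names)}
    try:
        ci = np.array([name_to_idx[cluster.ch_names[c]] for c in cluster.channels])
    except KeyError as exc:
        raise ValueError(f"cluster channel {exc} not in subject data") from exc
    fi = np.searchsorted(subject.freqs, cluster.freqs)
    ti = np.searchsorted(subject.times, cluster.times)
    if (fi >= len(subject.freqs)).any() or (ti >= len(subject.times)).any():
        raise ValueError("cluster points outside subject grid")
    if (not np.allclose(subject.freqs[fi], cluster.freqs)
            or not np.allclose(subject.times[ti], cluster.times, atol=1e-9)):
        raise ValueError("cluster grid does not match subject grid")
    return float(subject.data[ci, fi, ti].mean())
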