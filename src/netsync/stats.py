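"""Inter-network correlation statistics and group inference.

Covers: per-subject between-network Pearson correlations, edge-level
two-sample tests with optional age adjustment, Monte-Carlo cluster-size
correction on the network-pair graph (a network-based-statistic style
family-wise control), voxelwise permutation cluster tests on subject
maps, behavior correlations, and summary-statistics utilities for
reproducing printed demographic tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy import stats as sps
from scipy.special import ndtri

from .dualreg import SubjectNetworkTimecourses

__all__ = [
    "InterNetworkCorrelation",
    "EdgeStat",
    "ClusterResult",
    "VoxelwiseResult",
    "inter_network_correlation",
    "fisher_z",
    "edge_group_test",
    "summary_ttest",
    "chi_square_2x2",
    "mc_cluster_correction",
    "voxelwise_group_test",
    "behavior_edge_correlation",
]


# ---------------------------------------------------------------------------
# correlation containers

@dataclass
class InterNetworkCorrelation:
    """Per-subject K x K symmetric Pearson matrix over network time courses."""

    r: np.ndarray
    subject_id: str
    z: np.ndarray | None = None  # optional Fisher transform, stored alongside

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        K = self.r.shape[0]
        if self.r.shape != (K, K):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher variance-stabilizing transform, atanh(r)."""
    return np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))


def inter_network_correlation(
    tcs: SubjectNetworkTimecourses, store_fisher: bool = False
) -> InterNetworkCorrelation:
    """Pairwise Pearson correlation between every two network time courses."""
    X = tcs.values
    if X.shape[0] < 3:
        raise ValueError("need at least 3 time points for correlation")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = tcs.component_ids[int(np.argmin(sd))]
        raise ValueError(f"constant time course column {bad!r}: r undefined")
    r = np.corrcoef(X.T)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    z = None
    if store_fisher:
        z = fisher_z(r.copy())
        np.fill_diagonal(z, 0.0)
    return InterNetworkCorrelation(r=r, subject_id=tcs.subject_id, z=z)


# ---------------------------------------------------------------------------
# two-sample machinery

def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Pooled-variance two-sample t from raw samples (textbook formula)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def summary_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Pooled two-sample t-test from summary statistics.

    Returns ``(t, df, p)`` with ``df = n1 + n2 - 2`` and a two-sided p;
    used to reproduce printed table values where only means and SDs are
    available.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("invalid SDs")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table, df=1."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin in contingency table")
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


def _age_adjust(
    values: np.ndarray, labels_a: np.ndarray, ages: np.ndarray
) -> np.ndarray:
    """Remove a common age slope while preserving group intercepts.

    Fits ``value ~ group intercepts + age`` and subtracts
    ``slope * (age - mean age)`` so group mean differences not explained
    by age survive.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    X = np.column_stack(
        [labels_a.astype(float), (~labels_a).astype(float), ages]
    )
    Y = values if values.ndim == 2 else values.reshape(-1, 1)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    slope = coef[2]
    adj = Y - np.outer(ages - ages.mean(), slope)
    return adj if values.ndim == 2 else adj[:, 0]


@dataclass
class EdgeStat:
    """Two-sample test result for one network pair."""

    edge: tuple[int, int]
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    df: float
    p: float
    covariate_adjusted: bool = False
    edge_name: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        i, j = self.edge
        if not i < j:
            raise ValueError("edge must be ordered (i < j)")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p out of [0, 1]")
        if not np.isfinite(self.t):
            raise ValueError("non-finite t")


def edge_group_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    age_a: np.ndarray | None = None,
    age_b: np.ndarray | None = None,
    edge: tuple[int, int] = (0, 1),
    edge_name: tuple[str, str] | None = None,
) -> EdgeStat:
    """Pooled two-sample t-test on per-subject edge values.

    By default the test runs on the raw correlation values. When ages are
    supplied, both groups are residualized on age first (common slope,
    group intercepts preserved) and the t-test runs on adjusted values.
    Group summary statistics (mean, sample SD) are always reported on the
    values actually tested.
    """
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    adjusted = False
    if (age_a is None) != (age_b is None):
        raise ValueError("supply ages for both groups or neither")
    if age_a is not None:
        ages = np.concatenate([np.asarray(age_a, float), np.asarray(age_b, float)])
        pooled = np.concatenate([values_a, values_b])
        labels_a = np.zeros(len(pooled), dtype=bool)
        labels_a[: len(values_a)] = True
        adj = _age_adjust(pooled, labels_a, ages)
        values_a, values_b = adj[: len(values_a)], adj[len(values_a):]
        adjusted = True
    t, df, p = _pooled_t(values_a, values_b)
    return EdgeStat(
        edge=edge,
        mean_a=float(values_a.mean()),
        sd_a=float(values_a.std(ddof=1)),
        mean_b=float(values_b.mean()),
        sd_b=float(values_b.std(ddof=1)),
        t=t,
        df=df,
        p=p,
        covariate_adjusted=adjusted,
        edge_name=edge_name,
    )


def _pooled_t_matrix(values: np.ndarray, labels_a: np.ndarray) -> np.ndarray:
    """Vectorized pooled t over columns of ``values`` for one label split."""
    a = values[labels_a]
    b = values[~labels_a]
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.where(denom > 0, t, 0.0)


# ---------------------------------------------------------------------------
# Monte-Carlo cluster correction on the network-pair graph

@dataclass
class ClusterResult:
    """A connected set of supra-threshold network pairs and its corrected p."""

    edges: list[tuple[int, int]]
    size: int
    p_corrected: float
    null_sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size < 1 or self.size != len(self.edges):
            raise ValueError("cluster size must equal its edge count (>= 1)")
        if not 0.0 <= self.p_corrected <= 1.0:
            raise ValueError("p_corrected out of [0, 1]")
        g = nx.Graph(self.edges)
        if nx.number_connected_components(g) != 1:
            raise ValueError("cluster edges must form a connected subgraph")


def _edge_clusters(
    edges: list[tuple[int, int]], supra: np.ndarray
) -> list[list[int]]:
    """Connected components (via shared network nodes) of supra edges.

    Returns lists of indices into ``edges``.
    """
    g = nx.Graph()
    for idx in np.flatnonzero(supra):
        i, j = edges[idx]
        g.add_edge(i, j, idx=int(idx))
    clusters = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        clusters.append(sorted(d["idx"] for _, _, d in sub.edges(data=True)))
    return clusters


def mc_cluster_correction(
    edge_stats: list[EdgeStat],
    subject_edge_values: np.ndarray,
    group_labels: np.ndarray,
    n_sims: int = 10000,
    edge_alpha: float = 0.05,
    seed: int = 0,
    ages: np.ndarray | None = None,
) -> list[ClusterResult]:
    """Cluster-size family-wise correction over the network-pair graph.

    Observed clusters are the connected components (edges sharing a
    network node) of the ``p < edge_alpha`` edge set, sized by edge count.
    The null distribution of the *maximum* cluster size is built from
    ``n_sims`` random permutations of the group labels, recomputing the
    full edge test and clustering on each draw. Corrected p-values use
    +1 smoothing: ``(1 + #{null >= observed}) / (1 + n_sims)``.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    if n_sims < 1.0 / edge_alpha:
        warnings.warn(
            f"n_sims={n_sims} is small for alpha={edge_alpha}; corrected "
            "p-values will be coarse",
            stacklevel=2,
        )
    values = np.asarray(subject_edge_values, dtype=float)
    labels_a = np.asarray(group_labels).astype(bool)
    n_subj, n_edges = values.shape
    if len(edge_stats) != n_edges:
        raise ValueError("edge_stats length does not match value columns")
    if len(labels_a) != n_subj:
        raise ValueError("group_labels length does not match subjects")
    edges = [e.edge for e in edge_stats]
    na, nb = int(labels_a.sum()), int((~labels_a).sum())
    df = na + nb - 2

    obs_p = np.array([e.p for e in edge_stats])
    obs_clusters = _edge_clusters(edges, obs_p < edge_alpha)
    if not obs_clusters:
        return []

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_sims, dtype=int)
    base = values
    for s in range(n_sims):
        perm = rng.permutation(n_subj)
        pl = np.zeros(n_subj, dtype=bool)
        pl[perm[:na]] = True
        vals = _age_adjust(base, pl, ages) if ages is not None else base
        t = _pooled_t_matrix(vals, pl)
        p = 2.0 * sps.t.sf(np.abs(t), df)
        clusters = _edge_clusters(edges, p < edge_alpha)
        if clusters:
            null_max[s] = max(len(c) for c in clusters)

    summary = {
        "n_sims": int(n_sims),
        "max_size_mean": float(null_max.mean()),
        "max_size_q95": float(np.quantile(null_max, 0.95)),
        "max_size_max": int(null_max.max()),
    }
    results = []
    for cluster in obs_clusters:
        size = len(cluster)
        p_corr = (1.0 + int((null_max >= size).sum())) / (1.0 + n_sims)
        results.append(
            ClusterResult(
                edges=[edges[i] for i in cluster],
                size=size,
                p_corrected=float(p_corr),
                null_sizes=summary,
            )
        )
    return sorted(results, key=lambda c: c.p_corrected)


# ---------------------------------------------------------------------------
# voxelwise permutation cluster test

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


def _t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Map t statistics to standard-normal quantiles, tail-symmetric."""
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    with np.errstate(divide="ignore"):
        z[pos] = -ndtri(np.clip(sps.t.sf(t[pos], df), 1e-300, 1.0))
        z[~pos] = ndtri(np.clip(sps.t.sf(-t[~pos], df), 1e-300, 1.0))
    return np.clip(z, -38.0, 38.0)


@dataclass
class VoxelwiseResult:
    """Voxelwise z map plus cluster-extent-corrected significant clusters."""

    z_map: np.ndarray
    t_map: np.ndarray
    df: float
    clusters: list[dict]
    null_max_extent: np.ndarray


def voxelwise_group_test(
    maps_a: list[np.ndarray],
    maps_b: list[np.ndarray],
    mask: np.ndarray,
    n_perm: int = 5000,
    cluster_z: float = 2.3,
    alpha: float = 0.05,
    seed: int = 0,
    ages: np.ndarray | None = None,
) -> VoxelwiseResult:
    """Voxelwise two-sample test with permutation cluster-extent correction.

    The voxelwise pooled t map is converted to z; clusters are formed at
    ``z > cluster_z`` (26-connectivity) and sized by extent. The null of
    the maximum cluster extent comes from ``n_perm`` group-label
    permutations; clusters with corrected ``p < alpha`` are reported.
    With ages supplied, maps are residualized on age as in the edge test.
    """
    mask = np.asarray(mask).astype(bool)
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    A = np.vstack([np.asarray(m, float)[mask] for m in maps_a])
    B = np.vstack([np.asarray(m, float)[mask] for m in maps_b])
    values = np.vstack([A, B])
    n_subj = values.shape[0]
    na = len(maps_a)
    labels_a = np.zeros(n_subj, dtype=bool)
    labels_a[:na] = True
    df = n_subj - 2

    def tmap(vals: np.ndarray, la: np.ndarray) -> np.ndarray:
        v = _age_adjust(vals, la, ages) if ages is not None else vals
        return _pooled_t_matrix(v, la)

    a_var = values[labels_a].var(axis=0, ddof=1)
    b_var = values[~labels_a].var(axis=0, ddof=1)
    degenerate = (a_var + b_var) == 0
    if degenerate.mean() > 0.10:
        warnings.warn(
            f"degenerate variance at {degenerate.mean():.0%} of voxels",
            stacklevel=2,
        )

    t_obs = tmap(values, labels_a)
    z_obs = _t_to_z(t_obs, df)

    def max_extent_and_labels(z_in_mask: np.ndarray):
        z3d = np.zeros(mask.shape)
        z3d[mask] = z_in_mask
        lab, n_lab = ndimage.label(z3d > cluster_z, structure=_CONNECTIVITY_26)
        if n_lab == 0:
            return 0, lab, np.array([], dtype=int)
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n_lab + 1))
        sizes = sizes.astype(int)
        return int(sizes.max()), lab, sizes

    _, obs_labels, obs_sizes = max_extent_and_labels(z_obs)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=int)
    for s in range(n_perm):
        perm = rng.permutation(n_subj)
        pl = np.zeros(n_subj, dtype=bool)
        pl[perm[:na]] = True
        zp = _t_to_z(tmap(values, pl), df)
        null_max[s], _, _ = max_extent_and_labels(zp)

    clusters = []
    for lab_id, size in enumerate(obs_sizes, start=1):
        p_corr = (1.0 + int((null_max >= size).sum())) / (1.0 + n_perm)
        if p_corr < alpha:
            clusters.append(
                {
                    "label": int(lab_id),
                    "extent": int(size),
                    "p_corrected": float(p_corr),
                    "voxels": obs_labels == lab_id,
                }
            )
    z_map = np.zeros(mask.shape)
    z_map[mask] = z_obs
    t_map3 = np.zeros(mask.shape)
    t_map3[mask] = t_obs
    return VoxelwiseResult(
        z_map=z_map,
        t_map=t_map3,
        df=float(df),
        clusters=clusters,
        null_max_extent=null_max,
    )


# ---------------------------------------------------------------------------
# behavior

def behavior_edge_correlation(
    edge_values: np.ndarray, scores: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of per-subject edge values with behavior scores.

    Returns ``(r, p)`` with a two-sided t-based p at ``n - 2`` df.
    """
    x = np.asarray(edge_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r, p
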