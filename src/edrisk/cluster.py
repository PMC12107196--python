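"""One-dimensional k-means risk clustering with an exact oracle.

Per-code admission risk is a single number in [0, 1] (the fraction of a
code's presentations that ended in inpatient admission), so the clustering
problem is one-dimensional. Two solvers are provided:

* :func:`kmeans_1d` — Lloyd's algorithm with random restarts, the procedure
  the analysis uses (random initial centroids drawn from the data, nearest-
  centroid assignment, centroid recomputation until convergence);
* :func:`kmeans_1d_exact` — the globally optimal partition by dynamic
  programming, exploiting the fact that optimal 1-D clusters are contiguous
  in sorted order. It serves as a verification oracle: Lloyd's WCSS can
  never beat it, and with enough restarts should match it.

Cluster labels are always reported in ascending-centroid order, so label 1
is the lowest-admission-risk cluster. Model selection (how many clusters)
uses the gap statistic with a uniform reference, alongside the elbow (WCSS),
silhouette, Calinski-Harabasz and Davies-Bouldin indices, all implemented
here per definition with |.| distance in 1-D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusterModel",
    "ClusterSelectionReport",
    "compute_code_risks",
    "compute_block_risks",
    "kmeans_1d",
    "kmeans_1d_exact",
    "silhouette",
    "calinski_harabasz",
    "davies_bouldin",
    "gap_statistic",
    "selection_report",
    "select_k",
    "propagate_clusters",
    "cluster_presentation_summary",
]


def compute_code_risks(records: pd.DataFrame) -> pd.DataFrame:
    """Per-code presentation count, admissions and admission risk.

    One profile per distinct primary code; counts over profiles sum to the
    record count. Empty input yields an empty frame.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["code", "n", "n_admitted", "risk"])
    grp = records.groupby("icd10", sort=True)["admitted"].agg(["size", "sum"])
    out = pd.DataFrame({
        "code": grp.index,
        "n": grp["size"].to_numpy(),
        "n_admitted": grp["sum"].to_numpy(),
    }).reset_index(drop=True)
    out["risk"] = out["n_admitted"] / out["n"]
    return out


def compute_block_risks(records: pd.DataFrame, blocks) -> pd.DataFrame:
    """Pooled admission risk per ICD-10 block (block n = sum of member-code n)."""
    from .blocks import assign_blocks

    mapped = assign_blocks(records, blocks, policy="strict")
    grp = mapped.groupby("block", sort=True)["admitted"].agg(["size", "sum"])
    out = pd.DataFrame({
        "code": grp.index,
        "n": grp["size"].to_numpy(),
        "n_admitted": grp["sum"].to_numpy(),
    }).reset_index(drop=True)
    out["risk"] = out["n_admitted"] / out["n"]
    return out


@dataclass
class ClusterModel:
    """A fitted 1-D clustering; labels are 1..k in ascending-centroid order."""

    k: int
    centroids: np.ndarray          # strictly increasing
    labels: np.ndarray             # per input value, in 1..k
    wcss: float
    iterations: int
    converged: bool
    assignment: dict[str, int] | None = None   # code -> label, when codes given

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.centroids) >= 0)


def _wcss(values: np.ndarray, centroids: np.ndarray, labels0: np.ndarray,
          weights: np.ndarray) -> float:
    return float(np.sum(weights * (values - centroids[labels0]) ** 2))


def _relabel_ascending(centroids: np.ndarray, labels0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(centroids, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return centroids[order], rank[labels0] + 1


def _check_inputs(values, k) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(values) < k:
        raise ValueError(f"need at least k={k} values, got {len(values)}")
    n_distinct = len(np.unique(values))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct values")
    return values


def kmeans_1d(values, k: int, n_init: int = 50, max_iter: int = 300,
              tol: float = 1e-10, seed=None, codes=None, weights=None) -> ClusterModel:
    """Lloyd's algorithm in 1-D with random restarts.

    Initial centroids are drawn without replacement from the distinct data
    values, D²-weighted (k-means++ style: the first uniformly, each further
    one with probability proportional to its squared distance from the
    nearest centroid chosen so far), which concentrates restarts on
    well-separating starts; each restart runs nearest-centroid assignment (a value
    equidistant to two centroids joins the lower one) and centroid
    recomputation until the largest centroid movement falls below ``tol``.
    An emptied cluster is reseeded with the point farthest from its current
    centroid. Each converged restart gets a single-point boundary-refinement
    pass (in the spirit of Hartigan-Wong, the default of R's kmeans): a
    value moves across an adjacent cluster boundary whenever the move —
    accounting for both centroid updates — lowers the WCSS, which escapes
    the shallow Voronoi-stable local optima Lloyd alone can sit in. The
    best-WCSS restart is returned, relabelled in ascending-centroid order.
    Deterministic given ``seed``.

    ``weights`` optionally weights each value (e.g. by presentation count);
    the default is unweighted, one point per code.
    """
    values = _check_inputs(values, k)
    n = len(values)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float).ravel()
    if w.shape != values.shape or np.any(w <= 0):
        raise ValueError("weights must be positive, one per value")
    rng = np.random.default_rng(seed)
    distinct = np.unique(values)

    order = np.argsort(values, kind="stable")
    vs = values[order]
    ws = w[order]
    cw = np.concatenate([[0.0], np.cumsum(ws)])
    cwv = np.concatenate([[0.0], np.cumsum(ws * vs)])
    cwv2 = np.concatenate([[0.0], np.cumsum(ws * vs * vs)])

    def seg_cost(a: int, b: int) -> float:
        tw = cw[b] - cw[a]
        tv = cwv[b] - cwv[a]
        return (cwv2[b] - cwv2[a]) - tv * tv / tw

    def _seed_centroids() -> np.ndarray:
        chosen = [rng.choice(distinct)]
        for _ in range(k - 1):
            d2 = np.min(np.abs(distinct[:, None] - np.array(chosen)[None, :]),
                        axis=1) ** 2
            chosen.append(rng.choice(distinct, p=d2 / d2.sum()))
        return np.sort(np.array(chosen))

    best: tuple[float, list[int], int, bool] | None = None
    for _ in range(n_init):
        centroids = _seed_centroids()
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # argmin on ascending centroids -> ties join the lower-risk one
            labels0 = np.argmin(np.abs(vs[:, None] - centroids[None, :]), axis=1)
            # repair empty clusters: reseed with the farthest point
            for j in range(k):
                if not np.any(labels0 == j):
                    far = int(np.argmax(np.abs(vs - centroids[labels0])))
                    centroids[j] = vs[far]
                    labels0[far] = j
            new = np.sort([
                np.average(vs[labels0 == j], weights=ws[labels0 == j])
                for j in range(k)
            ])
            move = float(np.max(np.abs(new - np.sort(centroids))))
            centroids = new
            if move < tol:
                converged = True
                break

        # contiguous-segment view of the converged assignment: with ascending
        # centroids the 1-D Voronoi cells are intervals of the sorted values
        labels0 = np.argmin(np.abs(vs[:, None] - centroids[None, :]), axis=1)
        ranks = np.unique(labels0)
        bounds = [0] + [int(np.searchsorted(labels0, r, side="right"))
                        for r in ranks[:-1]] + [n]
        while len(bounds) - 1 < k:
            # a cluster emptied at convergence: split the costliest segment
            # at its best internal cut
            seg = max(((a, b) for a, b in zip(bounds, bounds[1:]) if b - a > 1),
                      key=lambda ab: seg_cost(*ab))
            a, b = seg
            cut = min(range(a + 1, b),
                      key=lambda j: seg_cost(a, j) + seg_cost(j, b))
            bounds = sorted(bounds + [cut])
        wcss = sum(seg_cost(a, b) for a, b in zip(bounds, bounds[1:]))

        # single-point boundary refinement: move one value across an adjacent
        # cluster boundary whenever that lowers the objective (the move
        # condition accounts for both centroid updates, so it is strictly
        # stronger than Lloyd's nearest-centroid stability)
        improved = True
        while improved:
            improved = False
            for bi in range(1, k):
                for d in (-1, 1):
                    nb = bounds[bi] + d
                    if not (bounds[bi - 1] < nb < bounds[bi + 1]):
                        continue
                    delta = (seg_cost(bounds[bi - 1], nb)
                             + seg_cost(nb, bounds[bi + 1])
                             - seg_cost(bounds[bi - 1], bounds[bi])
                             - seg_cost(bounds[bi], bounds[bi + 1]))
                    if delta < -1e-15:
                        bounds[bi] = nb
                        wcss += delta
                        improved = True
        wcss = sum(seg_cost(a, b) for a, b in zip(bounds, bounds[1:]))
        if best is None or wcss < best[0]:
            best = (wcss, list(bounds), it, converged)

    wcss, bounds, iterations, converged = best
    labels_sorted = np.empty(n, dtype=int)
    centroids = np.empty(k)
    for j, (a, b) in enumerate(zip(bounds, bounds[1:])):
        labels_sorted[a:b] = j
        centroids[j] = (cwv[b] - cwv[a]) / (cw[b] - cw[a])
    labels0 = np.empty(n, dtype=int)
    labels0[order] = labels_sorted
    centroids, labels = _relabel_ascending(centroids, labels0)
    assignment = None if codes is None else dict(zip(codes, labels.tolist()))
    return ClusterModel(k=k, centroids=centroids, labels=labels, wcss=max(wcss, 0.0),
                        iterations=iterations, converged=converged, assignment=assignment)


def kmeans_1d_exact(values, k: int, codes=None, weights=None) -> ClusterModel:
    """Globally optimal 1-D k-means by dynamic programming.

    Optimal 1-D clusters are contiguous in sorted order, so the minimum-WCSS
    partition is found by DP over segment boundaries in O(k n^2) using
    prefix sums. Deterministic; ties between boundary positions resolve to
    the leftmost.
    """
    values = _check_inputs(values, k)
    n = len(values)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float).ravel()
    order = np.argsort(values, kind="stable")
    v = values[order]
    ws = w[order]

    cw = np.concatenate([[0.0], np.cumsum(ws)])
    cwv = np.concatenate([[0.0], np.cumsum(ws * v)])
    cwv2 = np.concatenate([[0.0], np.cumsum(ws * v * v)])

    def seg_cost_vec(i: np.ndarray, j: int) -> np.ndarray:
        """Weighted SSE of sorted segment [i, j) for a vector of i."""
        tw = cw[j] - cw[i]
        tv = cwv[j] - cwv[i]
        tv2 = cwv2[j] - cwv2[i]
        return tv2 - tv * tv / tw

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            i = np.arange(m - 1, j)
            cand = cost[m - 1, i] + seg_cost_vec(i, j)
            best = int(np.argmin(cand))
            cost[m, j] = cand[best]
            split[m, j] = m - 1 + best

    labels_sorted = np.empty(n, dtype=int)
    centroids = np.empty(k)
    j = n
    for m in range(k, 0, -1):
        i = split[m, j]
        labels_sorted[i:j] = m - 1
        centroids[m - 1] = (cwv[j] - cwv[i]) / (cw[j] - cw[i])
        j = i

    labels0 = np.empty(n, dtype=int)
    labels0[order] = labels_sorted
    wcss = float(cost[k, n])
    centroids, labels = _relabel_ascending(centroids, labels0)
    assignment = None if codes is None else dict(zip(codes, labels.tolist()))
    return ClusterModel(k=k, centroids=centroids, labels=labels, wcss=max(wcss, 0.0),
                        iterations=0, converged=True, assignment=assignment)


def _groups(labels) -> dict:
    labels = np.asarray(labels)
    return {lab: np.flatnonzero(labels == lab) for lab in np.unique(labels)}


def silhouette(values, labels) -> tuple[float, np.ndarray]:
    """Mean and per-point silhouette scores with |.| distance.

    s_i = (b_i - a_i) / max(a_i, b_i) with a_i the mean distance to the
    point's own cluster and b_i the smallest mean distance to another
    cluster; points in singleton clusters score 0. Requires >= 2 clusters.
    """
    values = np.asarray(values, dtype=float).ravel()
    groups = _groups(labels)
    if len(groups) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    dist = np.abs(values[:, None] - values[None, :])
    n = len(values)
    scores = np.zeros(n)
    for lab, idx in groups.items():
        size = len(idx)
        for i in idx:
            if size == 1:
                scores[i] = 0.0
                continue
            a = dist[i, idx].sum() / (size - 1)
            b = min(dist[i, jdx].mean() for lab2, jdx in groups.items() if lab2 != lab)
            denom = max(a, b)
            scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean()), scores


def calinski_harabasz(values, labels) -> float:
    """Between/within dispersion ratio (B/(k-1)) / (W/(n-k))."""
    values = np.asarray(values, dtype=float).ravel()
    groups = _groups(labels)
    n, k = len(values), len(groups)
    if not 2 <= k < n:
        raise ValueError(f"requires 2 <= k < n, got k={k}, n={n}")
    overall = values.mean()
    B = sum(len(idx) * (values[idx].mean() - overall) ** 2 for idx in groups.values())
    W = sum(((values[idx] - values[idx].mean()) ** 2).sum() for idx in groups.values())
    if W == 0:
        raise ValueError("within-cluster dispersion is zero; index undefined")
    return float((B / (k - 1)) / (W / (n - k)))


def davies_bouldin(values, labels) -> float:
    """Mean over clusters of the worst pairwise (s_i + s_j) / d_ij similarity."""
    values = np.asarray(values, dtype=float).ravel()
    groups = _groups(labels)
    k = len(groups)
    if k < 2:
        raise ValueError("Davies-Bouldin requires at least 2 clusters")
    labs = list(groups)
    cent = np.array([values[groups[lab]].mean() for lab in labs])
    spread = np.array([np.abs(values[groups[lab]] - c).mean() for lab, c in zip(labs, cent)])
    d = np.abs(cent[:, None] - cent[None, :])
    if np.any(d[~np.eye(k, dtype=bool)] == 0):
        raise ValueError("coincident centroids; index undefined")
    ratio = (spread[:, None] + spread[None, :]) / np.where(d == 0, np.inf, d)
    np.fill_diagonal(ratio, -np.inf)
    return float(ratio.max(axis=1).mean())


def gap_statistic(values, k_range, n_reference: int = 100, seed=None,
                  n_init: int = 10) -> dict[int, tuple[float, float]]:
    """Gap statistic with a uniform reference on [min, max].

    gap(k) = mean_b log(W*_kb) - log(W_k) over ``n_reference`` uniform
    reference draws, with s_k = sd_b(log W*_kb) * sqrt(1 + 1/B). Larger gaps
    indicate clustering structure beyond what a featureless reference shows.
    Deterministic given ``seed``.
    """
    values = np.asarray(values, dtype=float).ravel()
    if n_reference < 10:
        raise ValueError("n_reference must be >= 10")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("degenerate values (all equal); gap undefined")
    rng = np.random.default_rng(seed)
    k_range = list(k_range)
    refs = [rng.uniform(lo, hi, size=len(values)) for _ in range(n_reference)]

    out: dict[int, tuple[float, float]] = {}
    for k in k_range:
        w_obs = kmeans_1d(values, k, n_init=n_init, seed=rng.integers(2**31)).wcss
        log_star = np.array([
            np.log(kmeans_1d(ref, k, n_init=n_init, seed=rng.integers(2**31)).wcss)
            for ref in refs
        ])
        gap = float(log_star.mean() - np.log(w_obs))
        s_k = float(log_star.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_reference))
        out[k] = (gap, s_k)
    return out


@dataclass
class ClusterSelectionReport:
    """Per-k model-selection diagnostics over a contiguous k range."""

    k_range: tuple[int, ...]
    wcss: dict[int, float]
    gap: dict[int, float]
    gap_se: dict[int, float]
    silhouette_mean: dict[int, float] = field(default_factory=dict)
    silhouette_points: dict[int, list] = field(default_factory=dict)
    calinski_harabasz: dict[int, float] = field(default_factory=dict)
    davies_bouldin: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k_range": list(self.k_range),
            "wcss": {str(k): v for k, v in self.wcss.items()},
            "gap": {str(k): v for k, v in self.gap.items()},
            "gap_se": {str(k): v for k, v in self.gap_se.items()},
            "silhouette_mean": {str(k): v for k, v in self.silhouette_mean.items()},
            "calinski_harabasz": {str(k): v for k, v in self.calinski_harabasz.items()},
            "davies_bouldin": {str(k): v for k, v in self.davies_bouldin.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def selection_report(values, k_range, n_init: int = 50, n_reference: int = 100,
                     seed=None) -> ClusterSelectionReport:
    """Fit every k in ``k_range`` and collect WCSS, gap and validity indices."""
    values = np.asarray(values, dtype=float).ravel()
    k_range = tuple(k_range)
    rng = np.random.default_rng(seed)
    gaps = gap_statistic(values, k_range, n_reference=n_reference,
                         seed=rng.integers(2**31))
    report = ClusterSelectionReport(
        k_range=k_range,
        wcss={}, gap={k: g for k, (g, _) in gaps.items()},
        gap_se={k: s for k, (_, s) in gaps.items()},
    )
    n = len(values)
    for k in k_range:
        model = kmeans_1d(values, k, n_init=n_init, seed=rng.integers(2**31))
        report.wcss[k] = model.wcss
        if k >= 2:
            mean_s, pts = silhouette(values, model.labels)
            report.silhouette_mean[k] = mean_s
            report.silhouette_points[k] = pts.tolist()
            report.davies_bouldin[k] = davies_bouldin(values, model.labels)
            if k < n:
                try:
                    report.calinski_harabasz[k] = calinski_harabasz(values, model.labels)
                except ValueError:
                    pass
    return report


def select_k(report: ClusterSelectionReport, strategy: str = "gap_1se",
             manual_k: int | None = None) -> int:
    """Choose the number of clusters from a selection report.

    ``gap_1se``: smallest k with gap(k) >= gap(k+1) - s_{k+1} (the
    parsimony rule); ``gap_max``: argmax of the gap; ``manual``: the
    configured override (the report stays attached for the record).
    """
    ks = sorted(report.gap)
    if strategy == "manual":
        if manual_k is None:
            raise ValueError("strategy 'manual' requires manual_k")
        return int(manual_k)
    if strategy == "gap_max":
        return max(ks, key=lambda k: report.gap[k])
    if strategy == "gap_1se":
        for k in ks[:-1]:
            nxt = k + 1
            if nxt in report.gap and report.gap[k] >= report.gap[nxt] - report.gap_se[nxt]:
                return k
        return ks[-1]
    raise ValueError(f"unknown strategy {strategy!r}")


def propagate_clusters(records: pd.DataFrame, model: ClusterModel,
                       on: str = "icd10") -> pd.DataFrame:
    """Attach each presentation's cluster label via its code's assignment."""
    if model.assignment is None:
        raise ValueError("model carries no code assignment")
    unknown = sorted(set(records[on]) - set(model.assignment))
    if unknown:
        raise KeyError(f"codes without cluster assignment: {unknown[:10]}"
                       + ("..." if len(unknown) > 10 else ""))
    out = records.copy()
    out["cluster"] = records[on].map(model.assignment).astype(int)
    return out


def cluster_presentation_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster presentation counts and admission rates."""
    grp = records.groupby("cluster")["admitted"].agg(["size", "sum"])
    total = len(records)
    return pd.DataFrame({
        "cluster": grp.index,
        "n": grp["size"].to_numpy(),
        "n_admitted": grp["sum"].to_numpy(),
        "share": grp["size"].to_numpy() / total,
        "admission_rate": grp["sum"].to_numpy() / grp["size"].to_numpy(),
    }).reset_index(drop=True)
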