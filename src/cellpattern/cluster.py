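"""Cluster-number inference for cell nuclei positions.

The stack: Lloyd's K-means minimizing the total within-cluster variation

    W(C_k) = sum_{x_i in C_k} ||x_i - mu_k||^2,     totW(k) = sum_k W(C_k),

the elbow method on totW(k), the gap statistic

    Gap(k) = mean_b log totW_uni,b(k) - log totW(k)

against B uniform reference sets drawn over the data's bounding box with
the one-standard-error selection rule

    K = min { k : Gap(k) >= Gap(k+1) - s(k+1) },   s(k) = sqrt(1 + 1/B) sd(k),

and the silhouette coefficient per cell

    SilCoef(i) = (x(i) - y(i)) / max(x(i), y(i)),

where y(i) is the mean intracluster distance and x(i) the smallest mean
distance to another cluster.  A mean silhouette width below 0.35 marks a
cluster number as unreliable and triggers re-selection over candidate k;
homogeneously spread patterns never reach the threshold and are flagged.

Per-cluster geometry (area, density, outliers) uses the covariance ellipse
at a configurable coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import chi2

from .geometry import PointPattern

__all__ = [
    "ClusteringResult",
    "GapReport",
    "SilhouetteReport",
    "ClusterMetrics",
    "kmeans",
    "within_variation",
    "elbow_select",
    "gap_statistic",
    "silhouette",
    "select_k",
    "cluster_metrics",
    "CellClusterModel",
    "CellClusterResults",
]


@dataclass
class ClusteringResult:
    """One K-means solution: labels, centroids, within-cluster variation."""

    labels: np.ndarray  # (n,) ints in 0..k-1
    centroids: np.ndarray  # (k, 2) µm
    per_cluster_W: np.ndarray  # µm² per cluster
    totW: float  # µm²
    k: int
    n_iter: int
    seed: int


@dataclass
class GapReport:
    """Per-k gap diagnostics and the one-standard-error selection."""

    k_values: np.ndarray
    gap: np.ndarray
    sd: np.ndarray
    s: np.ndarray
    log_totW_uni: np.ndarray  # mean reference log within-variation
    log_totW_data: np.ndarray
    selected_K: int
    B: int


@dataclass
class SilhouetteReport:
    """Per-cell silhouette coefficients and their means."""

    coef: np.ndarray  # (n,) in [-1, 1]
    x: np.ndarray  # smallest mean distance to another cluster
    y: np.ndarray  # mean intracluster distance
    mean_width: float
    per_cluster_mean: np.ndarray


@dataclass
class ClusterMetrics:
    """Per-cluster size/area/density from coverage covariance ellipses."""

    n_cells: np.ndarray  # per cluster
    ellipse_area: np.ndarray  # mm²; NaN where the cluster has < 3 cells
    density: np.ndarray  # cells per mm²; NaN where area undefined
    outlier_flags: np.ndarray  # (n,) bool, cell outside its cluster ellipse
    coverage: float


def _points(pattern: PointPattern | np.ndarray) -> np.ndarray:
    if isinstance(pattern, PointPattern):
        return pattern.points
    return np.asarray(pattern, dtype=float).reshape(-1, 2)


def within_variation(
    pattern: PointPattern | np.ndarray,
    labels: np.ndarray,
    centroids: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Evaluate W(C_k) per cluster and totW(k), in µm²."""
    pts = _points(pattern)
    labels = np.asarray(labels, dtype=int)
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    k = len(centroids)
    if len(labels) != len(pts):
        raise ValueError("labels must match points in length")
    if len(labels) and (labels.min() < 0 or labels.max() >= k):
        raise ValueError("label out of range for the given centroids")
    sq = ((pts - centroids[labels]) ** 2).sum(axis=1) if len(pts) else np.empty(0)
    per = np.bincount(labels, weights=sq, minlength=k) if len(pts) else np.zeros(k)
    return per, float(per.sum())


def _lloyd_once(pts: np.ndarray, k: int, rng: np.random.Generator, tol: float, max_iter: int):
    """One Lloyd run from a random data-point initialization.

    Returns (labels, centers, totW, n_iter).  Empty clusters are re-seeded
    at the point currently farthest from its assigned centroid; totW is
    asserted non-increasing across iterations.
    """
    n = len(pts)
    centers = pts[rng.choice(n, size=k, replace=False)].copy()
    prev_labels = None
    prev_totw = np.inf
    n_iter = 0
    for n_iter in range(1, 300 + 1):
        d2 = cdist(pts, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)
        counts = np.bincount(labels, minlength=k)
        for empty in np.flatnonzero(counts == 0):
            far = d2[np.arange(n), labels].argmax()
            centers[empty] = pts[far]
            labels[far] = empty
            counts = np.bincount(labels, minlength=k)
            d2[:, empty] = cdist(pts, centers[empty : empty + 1], "sqeuclidean")[:, 0]
        new_centers = np.empty_like(centers)
        for axis in range(2):
            new_centers[:, axis] = np.bincount(labels, weights=pts[:, axis], minlength=k) / counts
        shift = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
        centers = new_centers
        totw = float(((pts - centers[labels]) ** 2).sum())
        # Lloyd guarantee: each assign+update step cannot increase totW
        assert totw <= prev_totw * (1 + 1e-9) + 1e-9, "within-variation increased"
        prev_totw = totw
        if (prev_labels is not None and np.array_equal(labels, prev_labels)) or shift < tol:
            break
        prev_labels = labels
        if max_iter and n_iter >= max_iter:
            break
    return labels, centers, prev_totw, n_iter


def kmeans(
    pattern: PointPattern | np.ndarray,
    k: int,
    seed: int | np.random.SeedSequence = 0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> ClusteringResult:
    """Lloyd's K-means on nuclei positions; best of *n_restarts* by totW.

    Initial centers are drawn uniformly (without replacement) from the
    data points.  Deterministic given *seed*.
    """
    pts = _points(pattern)
    n = len(pts)
    if not (1 <= k <= n):
        raise ValueError(f"k must satisfy 1 <= k <= n cells ({n})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(n_restarts, 1)):
        labels, centers, totw, n_iter = _lloyd_once(pts, k, rng, tol, max_iter)
        if best is None or totw < best[2]:
            best = (labels, centers, totw, n_iter)
    labels, centers, totw, n_iter = best
    per, tot = within_variation(pts, labels, centers)
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    return ClusteringResult(
        labels=labels,
        centroids=centers,
        per_cluster_W=per,
        totW=tot,
        k=k,
        n_iter=n_iter,
        seed=int(seed_int),
    )


def elbow_select(
    pattern: PointPattern | np.ndarray,
    kmax: int,
    seed: int | np.random.SeedSequence = 0,
    n_restarts: int = 10,
) -> tuple[np.ndarray, int, bool]:
    """Elbow rule on the totW(k) curve for k = 1..kmax.

    The bend is located automatically as the argmax of the discrete
    curvature of the (k, totW) polyline after normalizing both axes to
    [0, 1] (kneedle-style rule, since the eye-ball reading of the elbow
    needs an operational counterpart).

    Returns (totW array for k=1..kmax, k_elbow, flagged).  *flagged* marks
    either a pathological non-decreasing curve (k_elbow forced to 1) or a
    featureless curvature profile — no single bend dominating the profile
    (max curvature below half the curvature total), as on a lone Gaussian
    blob — in which case the argmax k is still reported but is low
    confidence.
    """
    if kmax < 3:
        raise ValueError("kmax must be >= 3")
    ss = np.random.SeedSequence(seed) if isinstance(seed, (int, np.integer)) else seed
    children = ss.spawn(kmax)
    totw = np.array(
        [kmeans(pattern, k, children[k - 1], n_restarts).totW for k in range(1, kmax + 1)]
    )
    if np.any(np.diff(totw) > 0) or totw[0] == totw[-1]:
        return totw, 1, True
    x = np.arange(kmax, dtype=float) / (kmax - 1)
    y = (totw - totw.min()) / (totw.max() - totw.min())
    h = x[1] - x[0]
    curv = np.zeros(kmax)
    for i in range(1, kmax - 1):
        d1 = (y[i + 1] - y[i - 1]) / (2 * h)
        d2 = (y[i + 1] - 2 * y[i] + y[i - 1]) / h**2
        curv[i] = abs(d2) / (1 + d1**2) ** 1.5
    k_elbow = int(curv.argmax()) + 1
    flagged = bool(curv.max() < 0.5 * curv.sum())
    return totw, k_elbow, flagged


def gap_statistic(
    pattern: PointPattern | np.ndarray,
    kmax: int,
    B: int = 50,
    seed: int | np.random.SeedSequence = 0,
    n_restarts: int = 10,
    ref_restarts: int = 3,
) -> GapReport:
    """Gap statistic with B uniform reference sets over the bounding box.

    For each reference set, n points are drawn uniformly over the data's
    axis-aligned bounding box and clustered for every k; Gap(k) is the
    mean reference log totW minus the data log totW (natural logs), and
    s(k) = sqrt(1 + 1/B) · sd(k).  K is the smallest k with
    Gap(k) >= Gap(k+1) - s(k+1) (falling back to kmax when the rule never
    fires).

    Reference sets enter only through the mean and spread of log totW over
    the B replicates, so they use fewer restarts (*ref_restarts*) than the
    data fit; restart noise is absorbed into sd(k).
    """
    pts = _points(pattern)
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if B < 2:
        raise ValueError("B must be >= 2")
    if len(pts) < 2 or np.allclose(pts, pts[0]):
        raise ValueError("degenerate data: all points identical")
    ss = np.random.SeedSequence(seed) if isinstance(seed, (int, np.integer)) else seed
    data_seeds = ss.spawn(kmax)
    ref_ss = ss.spawn(1)[0]
    ref_restarts = n_restarts if ref_restarts is None else ref_restarts

    log_w_data = np.array(
        [np.log(kmeans(pts, k, data_seeds[k - 1], n_restarts).totW) for k in range(1, kmax + 1)]
    )

    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    n = len(pts)
    log_w_ref = np.empty((B, kmax))
    for b, child in enumerate(ref_ss.spawn(B)):
        rng = np.random.default_rng(child)
        ref = rng.uniform(lo, hi, size=(n, 2))
        ref_k_seeds = child.spawn(kmax)
        for k in range(1, kmax + 1):
            log_w_ref[b, k - 1] = np.log(kmeans(ref, k, ref_k_seeds[k - 1], ref_restarts).totW)

    mean_ref = log_w_ref.mean(axis=0)
    sd = log_w_ref.std(axis=0, ddof=0)
    s = np.sqrt(1.0 + 1.0 / B) * sd
    gap = mean_ref - log_w_data

    selected = kmax
    for i in range(kmax - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            selected = i + 1
            break
    return GapReport(
        k_values=np.arange(1, kmax + 1),
        gap=gap,
        sd=sd,
        s=s,
        log_totW_uni=mean_ref,
        log_totW_data=log_w_data,
        selected_K=selected,
        B=B,
    )


def silhouette(pattern: PointPattern | np.ndarray, labels: np.ndarray) -> SilhouetteReport:
    """Per-cell silhouette coefficients (x - y)/max(x, y).

    y(i) is the mean distance to the other members of cell i's cluster,
    x(i) the smallest mean distance to the cells of any other cluster.
    Cells in singleton clusters are assigned coefficient 0.
    """
    pts = _points(pattern)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    n = len(pts)
    dist = cdist(pts, pts)
    counts = np.array([(labels == u).sum() for u in uniq])
    # mean distance of every cell to every cluster
    mean_to = np.empty((n, len(uniq)))
    for j, u in enumerate(uniq):
        mean_to[:, j] = dist[:, labels == u].mean(axis=1)
    own = np.searchsorted(uniq, labels)
    own_count = counts[own]
    # intracluster mean excludes the cell itself
    y = np.where(
        own_count > 1,
        mean_to[np.arange(n), own] * own_count / np.maximum(own_count - 1, 1),
        0.0,
    )
    masked = mean_to.copy()
    masked[np.arange(n), own] = np.inf
    x = masked.min(axis=1)
    coef = np.zeros(n)
    nontrivial = own_count > 1
    denom = np.maximum(x, y)
    coef[nontrivial] = (x[nontrivial] - y[nontrivial]) / denom[nontrivial]
    per_cluster = np.array([coef[labels == u].mean() for u in uniq])
    return SilhouetteReport(
        coef=coef,
        x=x,
        y=y,
        mean_width=float(coef.mean()),
        per_cluster_mean=per_cluster,
    )


def select_k(
    pattern: PointPattern | np.ndarray,
    kmax: int = 10,
    threshold: float = 0.35,
    seed: int | np.random.SeedSequence = 0,
    B: int = 50,
    n_restarts: int = 10,
    ref_restarts: int = 3,
) -> tuple[ClusteringResult, SilhouetteReport, dict]:
    """Full cluster-number selection with silhouette quality control.

    The gap statistic proposes a candidate K.  If the mean silhouette
    width at the candidate falls below *threshold* (0.35 by default), the
    mean width is evaluated for every k in 2..kmax and the k with the
    highest width among those reaching the threshold is selected; when no
    k reaches it the max-width k is returned flagged ``unreliable`` —
    the signature of a homogeneously spread (glia-like) pattern.

    Returns (clustering at the selected k, its silhouette report, a
    diagnostics dict with the gap report, per-k widths and quality flag).
    """
    pts = _points(pattern)
    if len(pts) < 4:
        raise ValueError("need at least 4 cells")
    if kmax < 3:
        raise ValueError("kmax must be >= 3")
    ss = np.random.SeedSequence(seed) if isinstance(seed, (int, np.integer)) else seed
    gap_ss, km_ss = ss.spawn(2)
    gap = gap_statistic(pts, kmax, B=B, seed=gap_ss, n_restarts=n_restarts, ref_restarts=ref_restarts)
    km_seeds = km_ss.spawn(kmax)

    clusterings: dict[int, ClusteringResult] = {}
    widths: dict[int, float] = {}
    sils: dict[int, SilhouetteReport] = {}

    def eval_k(k: int) -> float:
        if k not in widths:
            cl = kmeans(pts, k, km_seeds[k - 1], n_restarts)
            clusterings[k] = cl
            sil = silhouette(pts, cl.labels)
            sils[k] = sil
            widths[k] = sil.mean_width
        return widths[k]

    candidate = gap.selected_K
    quality = "ok"
    if candidate >= 2 and eval_k(candidate) >= threshold:
        selected = candidate
    else:
        for k in range(2, kmax + 1):
            eval_k(k)
        passing = [k for k in range(2, kmax + 1) if widths[k] >= threshold]
        if passing:
            selected = max(passing, key=lambda k: widths[k])
            quality = "ok" if selected == candidate else "silhouette-reselected"
        else:
            selected = max(range(2, kmax + 1), key=lambda k: widths[k])
            quality = "unreliable"
    diagnostics = {
        "gap_report": gap,
        "gap_candidate": candidate,
        "silhouette_widths": dict(sorted(widths.items())),
        "threshold": threshold,
        "quality": quality,
        "selected_k": selected,
    }
    return clusterings[selected], sils[selected], diagnostics


def cluster_metrics(
    pattern: PointPattern | np.ndarray,
    clustering: ClusteringResult,
    coverage: float = 0.95,
) -> ClusterMetrics:
    """Per-cluster count, covariance-ellipse area and in-cluster density.

    The cluster area is the covariance ellipse at the given coverage:
    area = π · q · sqrt(det Σ) with q the chi-square(2 d.o.f.) quantile at
    *coverage* and Σ the member covariance.  Cells whose squared
    Mahalanobis distance to their centroid exceeds q are flagged as
    outliers.  Clusters with fewer than 3 cells have no defined ellipse;
    their area and density are NaN.
    """
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must lie in (0, 1)")
    pts = _points(pattern)
    labels = clustering.labels
    k = clustering.k
    q = chi2.ppf(coverage, df=2)
    n_cells = np.bincount(labels, minlength=k)
    area = np.full(k, np.nan)
    density = np.full(k, np.nan)
    outliers = np.zeros(len(pts), dtype=bool)
    import warnings

    for c in range(k):
        members = labels == c
        if n_cells[c] < 3:
            warnings.warn(f"cluster {c} has < 3 cells: ellipse area undefined")
            continue
        sub = pts[members]
        cov = np.cov(sub.T)
        det = np.linalg.det(cov)
        if det <= 0:
            warnings.warn(f"cluster {c} is degenerate (collinear): area undefined")
            continue
        area_um2 = np.pi * q * np.sqrt(det)
        area[c] = area_um2 / 1e6
        density[c] = n_cells[c] / area[c]
        inv = np.linalg.inv(cov)
        diff = sub - sub.mean(axis=0)
        maha2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
        outliers[members] = maha2 > q
    return ClusterMetrics(
        n_cells=n_cells,
        ellipse_area=area,
        density=density,
        outlier_flags=outliers,
        coverage=coverage,
    )


class CellClusterModel:
    """Cluster-number inference model for a pattern of nuclei positions.

    Parameters
    ----------
    pattern : PointPattern or (n, 2) array
        Cell positions in µm.

    Examples
    --------
    >>> from cellpattern import synthetic
    >>> res = CellClusterModel(synthetic.clust_a()).fit(kmax=8, seed=0)
    >>> res.selected_k
    4
    """

    def __init__(self, pattern: PointPattern | np.ndarray):
        self.pattern = pattern
        self.points = _points(pattern)

    @classmethod
    def from_csv(cls, path) -> "CellClusterModel":
        return cls(PointPattern.from_csv(path))

    @classmethod
    def from_dataframe(cls, df, x: str = "x_um", y: str = "y_um") -> "CellClusterModel":
        return cls(df[[x, y]].to_numpy(dtype=float))

    def fit(
        self,
        kmax: int = 10,
        B: int = 50,
        threshold: float = 0.35,
        coverage: float = 0.95,
        seed: int | np.random.SeedSequence = 0,
        n_restarts: int = 10,
        ref_restarts: int = 3,
    ) -> "CellClusterResults":
        clustering, sil, diag = select_k(
            self.points,
            kmax=kmax,
            threshold=threshold,
            seed=seed,
            B=B,
            n_restarts=n_restarts,
            ref_restarts=ref_restarts,
        )
        metrics = cluster_metrics(self.points, clustering, coverage)
        return CellClusterResults(self, clustering, sil, diag, metrics)


@dataclass
class CellClusterResults:
    """Fitted cluster assignment with selection diagnostics and metrics."""

    model: CellClusterModel
    clustering: ClusteringResult
    silhouette: SilhouetteReport
    diagnostics: dict
    metrics: ClusterMetrics

    @property
    def selected_k(self) -> int:
        return self.clustering.k

    @property
    def quality(self) -> str:
        return self.diagnostics["quality"]

    @property
    def gap_report(self) -> GapReport:
        return self.diagnostics["gap_report"]

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Cell cluster-number inference",
            "=" * 54,
            f"n cells            {len(self.model.points):>8}",
            f"selected K         {self.selected_k:>8}",
            f"gap candidate K    {self.diagnostics['gap_candidate']:>8}",
            f"mean silhouette    {self.silhouette.mean_width:8.3f}",
            f"quality            {self.quality:>8}",
            "-" * 54,
            f"{'cluster':>7} {'n_cells':>8} {'area_mm2':>10} {'dens/mm2':>10} {'sil':>6}",
        ]
        for c in range(self.selected_k):
            lines.append(
                f"{c:>7} {m.n_cells[c]:>8} {m.ellipse_area[c]:>10.4f} "
                f"{m.density[c]:>10.1f} {self.silhouette.per_cluster_mean[c]:>6.2f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "selected_k": int(self.selected_k),
            "quality": self.quality,
            "mean_silhouette_width": float(self.silhouette.mean_width),
            "gap_candidate": int(self.diagnostics["gap_candidate"]),
            "per_cluster": [
                {
                    "n_cells": int(self.metrics.n_cells[c]),
                    "area_mm2": None
                    if np.isnan(self.metrics.ellipse_area[c])
                    else float(self.metrics.ellipse_area[c]),
                    "density_per_mm2": None
                    if np.isnan(self.metrics.density[c])
                    else float(self.metrics.density[c]),
                }
                for c in range(self.selected_k)
            ],
        }

    def plot_clusters(self, ax=None):
        """Scatter of cells colored by cluster, with coverage ellipses."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse

        if ax is None:
            _, ax = plt.subplots()
        pts = self.model.points
        labels = self.clustering.labels
        q = chi2.ppf(self.metrics.coverage, df=2)
        for c in range(self.selected_k):
            sub = pts[labels == c]
            ax.scatter(sub[:, 0], sub[:, 1], s=8, label=f"cluster {c}")
            if len(sub) >= 3:
                cov = np.cov(sub.T)
                vals, vecs = np.linalg.eigh(cov)
                if vals.min() > 0:
                    ang = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
                    ell = Ellipse(
                        sub.mean(axis=0),
                        2 * np.sqrt(q * vals[-1]),
                        2 * np.sqrt(q * vals[0]),
                        angle=ang,
                        fill=False,
                        color="0.3",
                        lw=1,
                    )
                    ax.add_patch(ell)
        ax.set_aspect("equal")
        ax.invert_yaxis()
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def plot_gap(self, ax=None):
        """Gap(k) curve with the selected K marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.gap_report
        ax.errorbar(g.k_values, g.gap, yerr=g.s, fmt="o-", capsize=3)
        ax.axvline(g.selected_K, color="C3", ls="--")
        ax.set_xlabel("k")
        ax.set_ylabel("Gap(k)")
        return ax
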