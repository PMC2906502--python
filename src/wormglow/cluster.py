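"""Intensity-independent clustering of 2D intensity images.

The distance between two worms is ``1 - NCC^2`` of their flattened 75 x 15
intensity images (optionally ``1 - NCC`` or plain euclidean as controls).
Because NCC is invariant to positive-affine intensity changes, this distance
compares expression *patterns* while ignoring average brightness — the
property that lets bright and dim worms cluster by pattern rather than by
exposure.  Cluster stability is assessed pvclust-style with multiscale
bootstrap resampling of pixel positions, yielding ordinary bootstrap
probabilities (BP) and approximately unbiased probabilities (AU) per node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import UndefinedCorrelationError
from .imaging import ncc_arrays
from .types import IntensityImage2D

__all__ = [
    "ncc_distance",
    "build_distance_matrix",
    "hierarchical_cluster",
    "Dendrogram",
    "ClusterConfidence",
    "multiscale_bootstrap",
    "order_correlation_matrix",
    "cluster_summary",
    "mean_intensity",
    "correlate_series",
    "PatternClustering",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))
METRICS = ("ncc_squared", "ncc", "euclidean")
LINKAGES = ("average", "complete", "single")


def _values(img) -> np.ndarray:
    return img.values if isinstance(img, IntensityImage2D) else np.asarray(img)


def ncc_distance(A, B, squared: bool = True) -> float:
    """1 - NCC^2 (or 1 - NCC) between two equally shaped intensity images."""
    a, b = _values(A), _values(B)
    if a.shape != b.shape:
        raise ValueError("images must share one shape")
    r = ncc_arrays(a, b)  # raises UndefinedCorrelationError on constant input
    return float(1.0 - r * r) if squared else float(1.0 - r)


def _stack(images: Sequence) -> np.ndarray:
    mats = [_values(i) for i in images]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("all images must share one shape")
    return np.array([m.ravel() for m in mats], dtype=np.float64)


def _corr_rows(X: np.ndarray) -> np.ndarray:
    """Pairwise population Pearson correlation of the rows of X."""
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc * Xc).sum(axis=1))
    if np.any(sd == 0):
        raise UndefinedCorrelationError("constant image in correlation set")
    Xn = Xc / sd[:, None]
    R = Xn @ Xn.T
    return np.clip(R, -1.0, 1.0)


def _distance_from_stack(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff * diff).sum(axis=2))
    else:
        R = _corr_rows(X)
        D = 1.0 - (R * R if metric == "ncc_squared" else R)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def build_distance_matrix(images: Sequence, metric: str = "ncc_squared"
                          ) -> np.ndarray:
    """Symmetric zero-diagonal pairwise distance matrix for a worm set."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if len(images) < 2:
        raise ValueError("need at least two images")
    return _distance_from_stack(_stack(images), metric)


@dataclass
class Dendrogram:
    """Agglomerative merge tree (scipy linkage format) with leaf bookkeeping."""

    Z: np.ndarray
    linkage: str
    ids: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.Z) + 1

    def leaf_order(self) -> list[int]:
        return list(sch.leaves_list(self.Z))

    def node_leaf_sets(self) -> list[frozenset[int]]:
        """Leaf set of every internal node, smallest merges first."""
        n = self.n_leaves
        sets: list[frozenset[int]] = []
        lookup: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for k, (i, j, *_rest) in enumerate(self.Z):
            s = lookup[int(i)] | lookup[int(j)]
            lookup[n + k] = s
            sets.append(s)
        return sets

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels for a given number of clusters."""
        return sch.fcluster(self.Z, t=n_clusters, criterion="maxclust")


def hierarchical_cluster(D: np.ndarray, linkage: str = "average",
                         ids: Optional[Sequence[str]] = None) -> Dendrogram:
    """Agglomerative (hclust-style) clustering of a distance matrix."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] < 2:
        raise ValueError("D must be a square matrix with n >= 2")
    iu = np.triu_indices(D.shape[0], 1)
    Z = sch.linkage(D[iu], method=linkage)
    return Dendrogram(Z=Z, linkage=linkage,
                      ids=list(ids) if ids is not None else
                      [str(i) for i in range(D.shape[0])])


# ---------------------------------------------------------------------------
# Multiscale bootstrap (pvclust-style)
# ---------------------------------------------------------------------------

@dataclass
class ClusterConfidence:
    """Per-node bootstrap (BP) and approximately unbiased (AU) confidences, %."""

    nodes: list[frozenset[int]]
    bp: np.ndarray  # percent at scale ~1
    au: np.ndarray  # percent
    n_boot: int
    scales: tuple[float, ...]
    degenerate: np.ndarray = None  # True where AU was clamped

    def for_leafset(self, leaves: Sequence[int]) -> Optional[tuple[float, float]]:
        """(BP, AU) of the node with this exact leaf set, or None."""
        s = frozenset(leaves)
        for i, node in enumerate(self.nodes):
            if node == s:
                return float(self.bp[i]), float(self.au[i])
        return None

    def best_match(self, leaves: Sequence[int]) -> tuple[float, float, float]:
        """(jaccard, BP, AU) of the node maximizing Jaccard with ``leaves``."""
        s = set(leaves)
        best = (-1.0, 0.0, 0.0)
        for i, node in enumerate(self.nodes):
            jac = len(s & node) / len(s | node)
            if jac > best[0]:
                best = (jac, float(self.bp[i]), float(self.au[i]))
        return best


def _fit_au(scales: np.ndarray, bp: np.ndarray, n_boot: int
            ) -> tuple[float, bool]:
    """AU from the signed-distance model z(r) = v*sqrt(r) + c/sqrt(r).

    ``z(r) = qnorm(1 - BP_r)``; (v, c) are fitted by weighted least squares
    (binomial-variance weights) over scales with non-degenerate BP, and
    AU = 1 - Phi(v - c).  Returns (au, degenerate_flag).
    """
    eps = 0.5 / n_boot
    usable = (bp > 0) & (bp < 1)
    if usable.sum() < 2:
        if np.all(bp >= 1):
            return 1.0, True
        if np.all(bp <= 0):
            return 0.0, True
        # single informative scale: fall back to its BP
        idx = int(np.argmax(usable)) if usable.any() else int(len(bp) // 2)
        return float(bp[idx]), True
    r = scales[usable]
    p = np.clip(bp[usable], eps, 1 - eps)
    z = norm.ppf(1.0 - p)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    wts = n_boot * norm.pdf(z) ** 2 / (p * (1 - p))
    W = np.sqrt(wts)
    coef, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
    v, c = coef
    return float(1.0 - norm.cdf(v - c)), False


def multiscale_bootstrap(images: Sequence, metric: str = "ncc_squared",
                         linkage: str = "average",
                         scales: Sequence[float] = DEFAULT_SCALES,
                         n_boot: int = 1000,
                         seed: int = 0) -> ClusterConfidence:
    """BP/AU confidences for every internal node of the observed dendrogram.

    For each scale r, ``n_boot`` bootstrap replicates draw ``ceil(r*m)``
    pixel positions with replacement (m = pixels per image), recompute the
    distances on the resampled features, recluster, and record whether each
    observed node's leaf set reappears.  BP is reported at the scale closest
    to 1; AU comes from the multiscale extrapolation (see ``_fit_au``).
    """
    X = _stack(images)
    n, m = X.shape
    D = _distance_from_stack(X, metric)
    dend = hierarchical_cluster(D, linkage=linkage)
    nodes = dend.node_leaf_sets()
    # drop the root (always present) but keep all other internal nodes
    nodes = [s for s in nodes if len(s) < n]
    scales = np.asarray(sorted(scales), dtype=np.float64)
    rng = np.random.default_rng(seed)

    counts = np.zeros((len(scales), len(nodes)), dtype=np.int64)
    node_index = {s: i for i, s in enumerate(nodes)}
    iu = np.triu_indices(n, 1)
    for si, r in enumerate(scales):
        m_r = int(np.ceil(r * m))
        for _ in range(n_boot):
            idx = rng.integers(0, m, size=m_r)
            Xb = X[:, idx]
            try:
                Db = _distance_from_stack(Xb, metric)
            except UndefinedCorrelationError:
                continue
            Zb = sch.linkage(Db[iu], method=linkage)
            boot = Dendrogram(Z=Zb, linkage=linkage)
            for s in boot.node_leaf_sets():
                j = node_index.get(s)
                if j is not None and len(s) < n:
                    counts[si, j] += 1

    bp_all = counts / n_boot
    i1 = int(np.argmin(np.abs(scales - 1.0)))
    bp = bp_all[i1]
    au = np.empty(len(nodes))
    degenerate = np.zeros(len(nodes), dtype=bool)
    for j in range(len(nodes)):
        au[j], degenerate[j] = _fit_au(scales, bp_all[:, j], n_boot)
    return ClusterConfidence(nodes=nodes, bp=100.0 * bp, au=100.0 * au,
                             n_boot=n_boot, scales=tuple(scales),
                             degenerate=degenerate)


# ---------------------------------------------------------------------------
# Correlation-matrix ordering and cluster summaries
# ---------------------------------------------------------------------------

def order_correlation_matrix(images: Sequence,
                             groups: Optional[Sequence[str]] = None
                             ) -> tuple[np.ndarray, list[int]]:
    """Squared-NCC matrix ordered by group label, then descending row sum.

    ``groups`` keeps its given label order (order of first appearance);
    within each group rows are sorted by decreasing total squared NCC, which
    pushes the most prototypical pattern of each group to the front.
    """
    X = _stack(images)
    R2 = _corr_rows(X) ** 2
    n = len(X)
    if groups is None:
        groups = ["all"] * n
    if len(groups) != n:
        raise ValueError("groups must match the number of images")
    label_order: list[str] = []
    for g in groups:
        if g not in label_order:
            label_order.append(g)
    rowsum = R2.sum(axis=1)
    order: list[int] = []
    for g in label_order:
        members = [i for i in range(n) if groups[i] == g]
        members.sort(key=lambda i: (-rowsum[i], i))
        order.extend(members)
    M = R2[np.ix_(order, order)]
    return M, order


def cluster_summary(images: Sequence) -> tuple[IntensityImage2D, IntensityImage2D]:
    """Pixelwise mean and relative SD (SD/mean, 0 where mean is 0) of a cluster."""
    X = np.array([_values(i) for i in images], dtype=np.float64)
    if len(X) < 1:
        raise ValueError("empty cluster")
    mean = X.mean(axis=0)
    if len(X) == 1:
        relsd = np.full_like(mean, np.nan)  # undefined for a single member
    else:
        sd = X.std(axis=0, ddof=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            relsd = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), 0.0)
    return (IntensityImage2D(values=mean, id="cluster_mean"),
            IntensityImage2D(values=relsd, id="cluster_relsd"))


def mean_intensity(img) -> float:
    """Average GFP activity of a worm: mean over the full intensity image."""
    return float(_values(img).mean())


def correlate_series(x: Sequence[float], y: Sequence[float]
                     ) -> tuple[float, float, float]:
    """Pearson r plus least-squares (slope, intercept) of y on x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length series with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in series")
    r = ncc_arrays(x, y)
    slope = float(np.cov(x, y, bias=True)[0, 1] / np.var(x))
    intercept = float(y.mean() - slope * x.mean())
    return r, slope, intercept


# ---------------------------------------------------------------------------
# Sklearn-style wrapper
# ---------------------------------------------------------------------------

class PatternClustering(BaseEstimator, ClusterMixin):
    """Sklearn-style estimator for pattern-based worm clustering.

    ``fit(X)`` accepts a list of :class:`IntensityImage2D` (or arrays).
    Fitted attributes: ``distance_matrix_``, ``dendrogram_``, ``labels_``
    (flat cut at ``n_clusters``) and, when ``n_boot > 0``, ``confidence_``.
    """

    def __init__(self, metric: str = "ncc_squared", linkage: str = "average",
                 n_clusters: int = 3, n_boot: int = 0,
                 scales: Sequence[float] = DEFAULT_SCALES, seed: int = 0):
        self.metric = metric
        self.linkage = linkage
        self.n_clusters = n_clusters
        self.n_boot = n_boot
        self.scales = scales
        self.seed = seed

    def fit(self, X, y=None) -> "PatternClustering":
        self.distance_matrix_ = build_distance_matrix(X, metric=self.metric)
        self.dendrogram_ = hierarchical_cluster(self.distance_matrix_,
                                                linkage=self.linkage)
        self.labels_ = self.dendrogram_.cut(self.n_clusters)
        if self.n_boot > 0:
            self.confidence_ = multiscale_bootstrap(
                X, metric=self.metric, linkage=self.linkage,
                scales=self.scales, n_boot=self.n_boot, seed=self.seed)
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
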