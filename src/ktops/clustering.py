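"""Unsupervised K-means sweep, validity indices and CD-based selection.

The number of clusters is not assumed: K-means is run for every K from 2 up
to min(k_max, floor(sqrt(s))) and for each of four assignment distances.
Every resulting partition is scored by three internal validity indices
(Silhouette, Davies-Bouldin, Dunn) under each of seven pairwise metrics,
and the scores are combined into a single cohesion-dispersion (CD) value by
min-max normalizing each index over all (combination, K) cells -- 1 at the
global optimum of each index -- and averaging with configurable weights.
The cell with the largest CD defines the selected clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import ClusterConfig
from .distances import KMEANS_DISTANCES, VALIDATION_METRICS, centroid, pairwise
from .features import FeatureMatrix
from .preprocess import SpikeEvent


class ClusteringError(ValueError):
    pass


@dataclass
class ClusteringResult:
    labels: np.ndarray
    k: int
    distance: str
    centroids: np.ndarray
    inertia: float
    replicate_seed: int


@dataclass
class ValidationScores:
    silhouette: float
    davies_bouldin: float
    dunn: float


@dataclass
class CDCell:
    distance: str
    metric: str
    k: int
    scores: ValidationScores
    p_s: float = np.nan
    p_db: float = np.nan
    p_d: float = np.nan
    cd: float = np.nan


@dataclass
class ClusterTemplate:
    cluster_id: int
    template_fd: np.ndarray
    template_sd: np.ndarray
    n_members: int
    is_outlier: bool = False


# -- K-means ---------------------------------------------------------------

def _update_centers(x: np.ndarray, labels: np.ndarray, k: int,
                    distance: str, rng: np.random.Generator,
                    current: np.ndarray) -> np.ndarray:
    centers = np.empty((k, x.shape[1]))
    d_cur = None
    for j in range(k):
        members = x[labels == j]
        if members.shape[0] == 0:
            # re-seed an empty cluster from the farthest point
            if d_cur is None:
                d_cur = pairwise(x, current, metric=distance).min(axis=1)
            centers[j] = x[int(np.argmax(d_cur))]
        else:
            centers[j] = centroid(members, distance)
    return centers


def _kmeans_pp_init(x: np.ndarray, k: int, distance: str,
                    rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centers = [x[rng.integers(n)]]
    for _ in range(1, k):
        d = pairwise(x, np.asarray(centers), metric=distance).min(axis=1)
        d = np.maximum(d, 0)
        total = d.sum()
        if total == 0:
            centers.append(x[rng.integers(n)])
            continue
        centers.append(x[rng.choice(n, p=d / total)])
    return np.asarray(centers)


def kmeans_fit(x: np.ndarray, k: int, distance: str, seed: int,
               replicates: int = 10, max_iter: int = 100) -> ClusteringResult:
    """Best-of-replicates K-means under one of the four sweep distances.

    k-means++ initialization, empty clusters re-seeded from the farthest
    point; the replicate with the lowest total within-cluster distance under
    the assignment distance wins.  Deterministic given ``seed``.
    """
    if distance not in KMEANS_DISTANCES:
        raise ClusteringError(f"unsupported k-means distance: {distance}")
    rng = np.random.default_rng(seed)
    best: ClusteringResult | None = None
    for rep in range(replicates):
        centers = _kmeans_pp_init(x, k, distance, rng)
        labels = np.zeros(x.shape[0], dtype=int)
        for _ in range(max_iter):
            d = pairwise(x, centers, metric=distance)
            new_labels = d.argmin(axis=1)
            centers = _update_centers(x, new_labels, k, distance, rng,
                                      centers)
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
        inertia = float(pairwise(x, centers, metric=distance)[
            np.arange(x.shape[0]), labels].sum())
        if best is None or inertia < best.inertia:
            best = ClusteringResult(labels=labels, k=k, distance=distance,
                                    centroids=centers, inertia=inertia,
                                    replicate_seed=seed)
    assert best is not None
    return best


def kmeans_sweep(fm: FeatureMatrix, cfg: ClusterConfig,
                 seed: int) -> list[ClusteringResult]:
    """K-means solutions for every (distance, K) cell of the sweep grid.

    K ranges from ``k_min`` to min(k_max, floor(sqrt(s))) for s events.
    """
    x = fm.values
    s = x.shape[0]
    if s < 4:
        raise ClusteringError("need at least 4 events to cluster")
    if np.allclose(x, x[0]):
        raise ClusteringError("degenerate input: all events identical")
    k_hi = min(cfg.k_max, int(np.floor(np.sqrt(s))))
    results = []
    for di, distance in enumerate(cfg.kmeans_distances):
        for k in range(cfg.k_min, k_hi + 1):
            results.append(kmeans_fit(x, k, distance,
                                      seed=seed + 1009 * di + k,
                                      replicates=cfg.replicates,
                                      max_iter=cfg.max_iter))
    return results


# -- validity indices ------------------------------------------------------

def silhouette_from_matrix(d: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette value from a precomputed pairwise distance matrix.

    Singleton clusters contribute 0 by convention.
    """
    n = d.shape[0]
    labs = np.unique(labels)
    sums = np.stack([d[:, labels == lab].sum(axis=1) for lab in labs], axis=1)
    counts = np.array([(labels == lab).sum() for lab in labs])
    s = np.zeros(n)
    for pos, lab in enumerate(labs):
        mask = labels == lab
        if counts[pos] == 1:
            continue
        a = sums[mask, pos] / (counts[pos] - 1)
        other = np.delete(np.arange(labs.size), pos)
        b = (sums[mask][:, other] / counts[other]).min(axis=1)
        denom = np.maximum(a, b)
        s[mask] = np.where(denom > 0, (b - a) / denom, 0.0)
    return float(s.mean())


def davies_bouldin_index(x: np.ndarray, labels: np.ndarray,
                         metric: str) -> float:
    """DB = mean over clusters of max_j (S_i + S_j) / M_ij, where S_i is the
    mean member-to-centroid distance and M_ij the centroid separation."""
    labs = np.unique(labels)
    k = labs.size
    cents = np.stack([centroid(x[labels == lab], metric) for lab in labs])
    scatter = np.array([
        pairwise(x[labels == lab], cents[i][None, :], metric).mean()
        if (labels == lab).sum() > 1 else 0.0
        for i, lab in enumerate(labs)])
    m = pairwise(cents, cents, metric)
    ratio = np.zeros((k, k))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(k):
            for j in range(k):
                if i != j:
                    ratio[i, j] = ((scatter[i] + scatter[j]) / m[i, j]
                                   if m[i, j] > 0 else np.inf)
    return float(ratio.max(axis=1).mean())


def dunn_from_matrix(d: np.ndarray, labels: np.ndarray) -> float:
    """Dunn = min inter-cluster point distance / max cluster diameter."""
    labs = np.unique(labels)
    inter = np.inf
    diam = 0.0
    masks = [labels == lab for lab in labs]
    for i in range(labs.size):
        di = d[masks[i]]
        sub = di[:, masks[i]]
        if sub.size > 1:
            diam = max(diam, float(sub.max()))
        for j in range(i + 1, labs.size):
            inter = min(inter, float(di[:, masks[j]].min()))
    if diam == 0:
        return np.inf if inter > 0 else 0.0
    return inter / diam


def validation_indices(x: np.ndarray, labels: np.ndarray, metric: str,
                       d: np.ndarray | None = None) -> ValidationScores:
    """Silhouette, Davies-Bouldin and Dunn under one pairwise metric."""
    if np.unique(labels).size < 2:
        raise ClusteringError("validity indices require K >= 2")
    if d is None:
        d = pairwise(x, x, metric)
    return ValidationScores(
        silhouette=silhouette_from_matrix(d, labels),
        davies_bouldin=davies_bouldin_index(x, labels, metric),
        dunn=dunn_from_matrix(d, labels))


# -- CD-index --------------------------------------------------------------

def _normalize(values: np.ndarray, best_is_max: bool) -> np.ndarray:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return np.full_like(values, 0.5)
    vmax, vmin = finite.max(), finite.min()
    if vmax == vmin:
        warnings.warn("validity index constant across cells; p set to 0.5")
        return np.full_like(values, 0.5)
    clipped = np.clip(values, vmin, vmax)
    p = (clipped - vmin) / (vmax - vmin)
    return p if best_is_max else 1.0 - p


def cd_index(cells: list[CDCell],
             weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
             normalization: str = "global") -> tuple[list[CDCell], CDCell]:
    """Combine validity scores into CD values and select the best cell.

    p_S and p_D get probability 1 at the maximum of the Silhouette / Dunn
    indices over the normalization domain, p_DB gets 1 at the minimum of
    Davies-Bouldin; CD is the weighted sum.  The domain is all cells
    (``global``), the cells sharing a validation metric (``per-metric`` --
    raw index values are not commensurate across metrics, whose scales
    differ by orders of magnitude), or the cells of one (distance, metric)
    combination (``per-combo``).  Ties are broken by smaller K, then
    lexicographically by (distance, metric).
    """
    if len(cells) < 2:
        raise ClusteringError("need at least 2 scored cells")
    w_s, w_db, w_d = weights
    if normalization == "global":
        domains = [list(range(len(cells)))]
    elif normalization == "per-metric":
        keys = sorted({c.metric for c in cells})
        domains = [[i for i, c in enumerate(cells) if c.metric == key]
                   for key in keys]
    elif normalization == "per-combo":
        keys = sorted({(c.distance, c.metric) for c in cells})
        domains = [[i for i, c in enumerate(cells)
                    if (c.distance, c.metric) == key] for key in keys]
    else:
        raise ClusteringError(f"unknown normalization: {normalization}")
    s = np.array([c.scores.silhouette for c in cells])
    db = np.array([c.scores.davies_bouldin for c in cells])
    dd = np.array([c.scores.dunn for c in cells])
    for dom in domains:
        dom = np.asarray(dom)
        p_s = _normalize(s[dom], best_is_max=True)
        p_db = _normalize(db[dom], best_is_max=False)
        p_d = _normalize(dd[dom], best_is_max=True)
        for i, a, b, e in zip(dom, p_s, p_db, p_d):
            cells[i].p_s, cells[i].p_db, cells[i].p_d = (float(a), float(b),
                                                         float(e))
            cells[i].cd = float(w_s * a + w_db * b + w_d * e)
    best = min(cells, key=lambda c: (-c.cd, c.k, c.distance, c.metric))
    return cells, best


def score_sweep(fm: FeatureMatrix, results: list[ClusteringResult],
                cfg: ClusterConfig, seed: int
                ) -> tuple[list[CDCell], CDCell, ClusteringResult]:
    """Score every sweep solution under every validation metric and pick the
    CD-maximizing (distance, metric, K) cell.

    The pairwise matrices for the indices are evaluated on a random
    subsample of events (``cfg.validation_subsample``) for tractability;
    the K-means fit itself and the returned labels cover all events.
    """
    x = fm.values
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    if n > cfg.validation_subsample:
        sub = np.sort(rng.choice(n, size=cfg.validation_subsample,
                                 replace=False))
    else:
        sub = np.arange(n)
    xs = x[sub]
    index_of: dict[tuple[str, int], ClusteringResult] = {
        (res.distance, res.k): res for res in results}
    usable = [res for res in results
              if np.unique(res.labels[sub]).size >= 2]
    cells: list[CDCell] = []
    # one pairwise matrix at a time keeps peak memory to a single metric
    for metric in cfg.validation_metrics:
        d = pairwise(xs, xs, metric)
        for res in usable:
            labs = res.labels[sub]
            scores = ValidationScores(
                silhouette=silhouette_from_matrix(d, labs),
                davies_bouldin=davies_bouldin_index(xs, labs, metric),
                dunn=dunn_from_matrix(d, labs))
            cells.append(CDCell(distance=res.distance, metric=metric,
                                k=res.k, scores=scores))
        del d
    cells, best = cd_index(cells, cfg.cd_weights, cfg.normalization)
    if cfg.selection == "partition-mean":
        # rank partitions by their mean CD over the validation metrics: a
        # genuinely good clustering scores well under most metrics, while a
        # single cell can top the table through one metric's quirks
        means: dict[tuple[str, int], float] = {}
        counts: dict[tuple[str, int], int] = {}
        for c in cells:
            key = (c.distance, c.k)
            means[key] = means.get(key, 0.0) + c.cd
            counts[key] = counts.get(key, 0) + 1
        ranked = sorted(means, key=lambda key: (-means[key] / counts[key],
                                                key[1], key[0]))
        win = ranked[0]
        best = min((c for c in cells
                    if (c.distance, c.k) == win),
                   key=lambda c: (-c.cd, c.metric))
    return cells, best, index_of[(best.distance, best.k)]


# -- templates -------------------------------------------------------------

def build_templates_and_flag_outliers(
        events: list[SpikeEvent], result: ClusteringResult, thr: float,
        outlier_frac: float = 0.02) -> list[ClusterTemplate]:
    """Mean FD/SD template per cluster, with outlier-cluster flagging.

    Clusters that are too small (fewer than max(2, outlier_frac * s)
    members) or whose template never exceeds the detection threshold are
    flagged; their events are routed to the overlap/outlier pool instead of
    the single-unit output.
    """
    s = len(events)
    min_members = max(2, int(np.ceil(outlier_frac * s)))
    fds = np.array([ev.window_fd for ev in events])
    sds = np.array([ev.window_sd for ev in events])
    templates = []
    for j in range(result.k):
        mask = result.labels == j
        nm = int(mask.sum())
        if nm == 0:
            continue
        tfd = fds[mask].mean(axis=0)
        tsd = sds[mask].mean(axis=0)
        is_outlier = nm < min_members or np.abs(tfd).max() < thr
        templates.append(ClusterTemplate(cluster_id=j, template_fd=tfd,
                                         template_sd=tsd, n_members=nm,
                                         is_outlier=bool(is_outlier)))
    return templates


def pca_projection(fm: FeatureMatrix, n_components: int = 2) -> np.ndarray:
    """Centered PCA scores (diagnostic only; no decision logic uses this)."""
    x = fm.values - fm.values.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    return x @ vt[:n_components].T
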