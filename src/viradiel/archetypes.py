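"""Peak-timing estimation and unsupervised archetype discovery.

Diel populations are characterized by a rank-based peak clock time (the
time-of-day class with the highest mean within-series abundance rank,
ties resolved to the circular midpoint of the tied clock times) and a
day/night label. Their scaled, detrended series are assessed for
clusterability (Hopkins statistic), clustered into archetypes by a 1-D
batch self-organizing map — with PAM medoid and complete-linkage
hierarchical clustering as comparators — and the archetype count is chosen
at the elbow of the mean-silhouette profile, with Calinski–Harabasz as a
companion fit metric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import rankdata
from sklearn.metrics import calinski_harabasz_score, silhouette_score
from sklearn.neighbors import NearestNeighbors

from .core_io import AbundanceMatrix
from .rhythm import detrend

__all__ = [
    "PeakTiming",
    "ClusteringReport",
    "peak_rank_time",
    "classify_day_night",
    "scale_series",
    "hopkins",
    "cluster",
    "cluster_quality",
    "select_archetypes",
    "DEFAULT_NIGHT_WINDOW",
]

logger = logging.getLogger(__name__)

#: Night spans 18:00 (closed) to 06:00 (open), so the observed 04:00 night
#: peak and 12:00 day peak classify as stated.
DEFAULT_NIGHT_WINDOW = (18.0, 6.0)


@dataclass
class PeakTiming:
    """Rank-based peak clock time of one population."""

    population_id: str
    mean_rank_by_class: np.ndarray
    peak_clock_time: float
    day_night: str


@dataclass
class ClusteringReport:
    """One clustering fit plus its quality scores."""

    method: str
    k: int
    labels: np.ndarray = field(repr=False)
    calinski_harabasz: float
    mean_silhouette: float
    hopkins: float
    seed: int | None = None


# ---------------------------------------------------------------------------
# Peak timing


def _circular_midpoint(hours: np.ndarray) -> float:
    """Circular mean of clock hours on the 24-h dial."""
    ang = np.asarray(hours, dtype=float) * 2 * np.pi / 24.0
    s, c = np.sin(ang).mean(), np.cos(ang).mean()
    if np.hypot(s, c) < 1e-9:
        raise ValueError("tied peak times are antipodal; midpoint undefined")
    return float((np.arctan2(s, c) * 24.0 / (2 * np.pi)) % 24.0)


def peak_rank_time(series, clock_classes, mask=None, deltat: float = 4.0,
                   population_id: str = "",
                   night_window=DEFAULT_NIGHT_WINDOW) -> PeakTiming:
    """Peak clock time from within-series abundance ranks.

    All included values are ranked together (mid-ranks on ties); the ranks
    are averaged within each time-of-day class and the peak is the class
    with the highest mean rank. Exact ties between classes resolve to the
    circular midpoint of the tied clock times (20:00 tied with 00:00 gives
    22:00). Rank-based, so invariant to monotone transforms of the series.
    """
    series = np.asarray(series, dtype=float)
    classes = np.asarray(clock_classes, dtype=int)
    if mask is None:
        mask = np.ones(series.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    v = series[mask]
    cl = classes[mask]
    if np.unique(cl).size < 2:
        raise ValueError("need included values in >= 2 classes")
    ranks = rankdata(v)
    n_classes = int(classes.max()) + 1
    mean_rank = np.full(n_classes, np.nan)
    for c in np.unique(cl):
        mean_rank[c] = ranks[cl == c].mean()
    finite = np.nan_to_num(mean_rank, nan=-np.inf)
    top = finite.max()
    if np.isclose(top, np.nanmin(mean_rank)):
        raise ValueError(f"no peak: all classes tied for {population_id!r}")
    tied = np.flatnonzero(np.isclose(finite, top))
    peak = _circular_midpoint(tied * deltat) if tied.size > 1 else float(
        tied[0] * deltat)
    return PeakTiming(
        population_id=population_id,
        mean_rank_by_class=mean_rank,
        peak_clock_time=peak,
        day_night=classify_day_night(peak, night_window),
    )


def classify_day_night(peak_clock_time: float,
                       night_window=DEFAULT_NIGHT_WINDOW) -> str:
    """'night' iff the peak falls in the (circular) night window.

    The window is closed at its start and open at its end, so the default
    18:00–06:00 window labels 18:00 night and 06:00 day.
    """
    t = float(peak_clock_time) % 24.0
    lo, hi = night_window
    if lo <= hi:
        is_night = lo <= t < hi
    else:  # wraps midnight
        is_night = t >= lo or t < hi
    return "night" if is_night else "day"


# ---------------------------------------------------------------------------
# Scaling and clusterability


def scale_series(matrix: AbundanceMatrix, diel_ids: list[str]
                 ) -> tuple[np.ndarray, list[str]]:
    """Detrended, unit-variance time-series vectors of diel populations.

    Each selected row is detrended over included samples and standardized
    to mean 0, sd 1 — dimensionless, so clustering sees waveform shape,
    not magnitude. Zero-variance rows are excluded with a warning. Returns
    (scaled matrix over included samples, kept population ids).
    """
    sub = matrix.subset_populations(diel_ids)
    mask = sub.included_mask()
    times = np.array([s.elapsed_hours for s in sub.samples])
    rows = []
    kept = []
    for pop, row in zip(sub.population_ids, sub.values):
        resid = detrend(row, times, mask)
        sd = resid.std()
        if sd < 1e-12:
            warnings.warn(f"population {pop}: zero variance, excluded from scaling")
            continue
        rows.append((resid - resid.mean()) / sd)
        kept.append(pop)
    if not rows:
        raise ValueError("no nonconstant series to scale")
    return np.vstack(rows), kept


def hopkins(data, m: int | None = None, seed: int | None = None) -> float:
    """Hopkins clustering-tendency statistic on points in R^p.

    Compares nearest-neighbor distances of ``m`` sampled real points
    (without replacement) against ``m`` uniform points drawn in the data's
    per-dimension bounding box: h = sum(u) / (sum(u) + sum(w)). Values near
    0.5 indicate no structure; values near 1 indicate strong clustering.
    """
    x = np.asarray(data, dtype=float)
    n, p = x.shape
    if n < 10:
        raise ValueError("hopkins needs n >= 10")
    if m is None:
        m = int(np.ceil(0.1 * n))
    if m >= n:
        raise ValueError("m must be < n")
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    uniform = rng.uniform(lo, hi, size=(m, p))
    sample_idx = rng.choice(n, size=m, replace=False)
    nn = NearestNeighbors(n_neighbors=2).fit(x)
    u = nn.kneighbors(uniform, n_neighbors=1)[0][:, 0]
    w = nn.kneighbors(x[sample_idx], n_neighbors=2)[0][:, 1]  # skip self
    return float(u.sum() / (u.sum() + w.sum()))


# ---------------------------------------------------------------------------
# Clustering methods


def _som_1d(data: np.ndarray, k: int, seed: int | None,
            epochs: int = 500) -> np.ndarray:
    """Batch-trained 1-D self-organizing map; labels = best-matching unit.

    Prototypes sit on a 1 x k grid; each epoch assigns every point to its
    nearest prototype and moves prototypes to the Gaussian-neighborhood-
    weighted mean of the data, with the neighborhood radius decaying
    linearly from k to 0.5. Empty units are re-seeded from the point
    farthest from its prototype.
    """
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    prototypes = data[rng.choice(n, size=k, replace=False)].copy()
    grid = np.arange(k, dtype=float)
    for epoch in range(epochs):
        radius = k + (0.5 - k) * epoch / max(epochs - 1, 1)
        d = cdist(data, prototypes)
        bmu = d.argmin(axis=1)
        h = np.exp(-((grid[:, None] - grid[bmu][None, :]) ** 2)
                   / (2 * radius**2))  # k x n neighborhood weights
        weight_sum = h.sum(axis=1, keepdims=True)
        prototypes = (h @ data) / weight_sum
    d = cdist(data, prototypes)
    labels = d.argmin(axis=1)
    for unit in range(k):
        if not np.any(labels == unit):
            far = d[np.arange(n), labels].argmax()
            logger.info("SOM unit %d empty; reseeded from farthest point", unit)
            prototypes[unit] = data[far]
            d = cdist(data, prototypes)
            labels = d.argmin(axis=1)
    return labels + 1


def _pam(dist: np.ndarray, k: int, seed: int | None,
         max_iter: int = 100) -> np.ndarray:
    """PAM (partitioning around medoids): BUILD then SWAP on distances."""
    n = dist.shape[0]
    # BUILD: greedy medoid selection minimizing total assignment cost
    medoids = [int(dist.sum(axis=1).argmin())]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(gains.argmax()))
    medoids = np.array(medoids)
    # SWAP: steepest-descent medoid/non-medoid exchanges
    for _ in range(max_iter):
        cost = dist[:, medoids].min(axis=1).sum()
        best = (0.0, None)
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        for mi in range(k):
            trial = medoids.copy()
            for h in non_medoids:
                trial[mi] = h
                delta = dist[:, trial].min(axis=1).sum() - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
    return dist[:, medoids].argmin(axis=1) + 1


def cluster(data=None, distances: np.ndarray | None = None,
            method: str = "som", k: int = 3,
            seed: int | None = None) -> np.ndarray:
    """Cluster scaled series into k groups; labels are 1..k.

    ``som`` (1 x k batch self-organizing map) and hierarchical clustering
    consume the data vectors; ``pam`` consumes the Euclidean distance
    matrix (computed from data if not given). Deterministic given a seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if data is None and distances is None:
        raise ValueError("provide data and/or distances")
    n = data.shape[0] if data is not None else distances.shape[0]
    if k > n:
        raise ValueError("k cannot exceed the number of points")
    if k == 1:
        return np.ones(n, dtype=int)
    if method == "som":
        if data is None:
            raise ValueError("SOM needs data vectors")
        return _som_1d(np.asarray(data, dtype=float), k, seed)
    if method == "pam":
        if distances is None:
            distances = squareform(pdist(np.asarray(data, dtype=float)))
        return _pam(np.asarray(distances, dtype=float), k, seed)
    if method == "hierarchical":
        if data is not None:
            z = linkage(np.asarray(data, dtype=float), method="complete")
        else:
            z = linkage(squareform(distances, checks=False), method="complete")
        return fcluster(z, t=k, criterion="maxclust")
    raise ValueError(f"unknown method {method!r}")


def cluster_quality(data: np.ndarray, distances: np.ndarray,
                    labels: np.ndarray) -> tuple[float, float]:
    """Calinski–Harabasz (on data) and mean silhouette (on distances)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("quality metrics need k >= 2")
    ch = calinski_harabasz_score(np.asarray(data, dtype=float), labels)
    sil = silhouette_score(np.asarray(distances, dtype=float), labels,
                           metric="precomputed")
    return float(ch), float(sil)


# ---------------------------------------------------------------------------
# Model selection


def _elbow_k(ks: list[int], silhouettes: list[float]) -> tuple[int, bool]:
    """Elbow of the mean-silhouette profile over candidate cluster counts.

    The elbow is where the profile's decline begins. A profile that first
    rises has its elbow at the maximum (the decline starts there; ties pick
    the smaller k). A profile decreasing from the start takes the k
    preceding its largest drop — unless no drop reaches twice every other
    drop, in which case there is no clear elbow and the smallest k is
    returned with a flag.
    """
    if len(ks) == 1:
        return ks[0], False
    s = np.asarray(silhouettes, dtype=float)
    if np.any(np.diff(s) > 0):  # rises somewhere: decline begins at the max
        return ks[int(np.argmax(s))], False
    drops = [s[i] - s[i + 1] for i in range(len(ks) - 1)]
    order = sorted(range(len(drops)), key=lambda i: (-drops[i], ks[i]))
    largest = drops[order[0]]
    runner_up = drops[order[1]] if len(drops) > 1 else -np.inf
    if largest <= 0 or (len(drops) > 1 and largest < 2 * runner_up):
        return ks[0], True
    return ks[order[0]], False


def select_archetypes(data: np.ndarray, distances: np.ndarray | None = None,
                      k_range=range(2, 7), seed: int | None = None,
                      hopkins_m: int | None = None
                      ) -> tuple[ClusteringReport, dict]:
    """Fit SOM, PAM, and hierarchical clusterings over k_range and choose.

    Every method is fitted at every k; per method the operating k is the
    elbow of its mean-silhouette profile, and the winning method is the one
    with the highest silhouette at its chosen k. Returns the winning
    :class:`ClusteringReport` plus a detail dict holding each (method, k)
    fit — including the neighbors k*±1 — and the Hopkins statistic.
    """
    ks = sorted(k_range)
    if not ks:
        raise ValueError("k_range is empty")
    data = np.asarray(data, dtype=float)
    if ks[0] < 2 or ks[-1] > data.shape[0] - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    if distances is None:
        distances = squareform(pdist(data))
    h = hopkins(data, m=hopkins_m, seed=seed)

    fits: dict[tuple[str, int], dict] = {}
    per_method: dict[str, tuple[int, float, bool]] = {}
    for method in ("som", "pam", "hierarchical"):
        sils = []
        for k in ks:
            labels = cluster(data=data, distances=distances, method=method,
                             k=k, seed=seed)
            ch, sil = cluster_quality(data, distances, labels)
            fits[(method, k)] = {
                "labels": labels, "calinski_harabasz": ch,
                "mean_silhouette": sil,
            }
            sils.append(sil)
        k_star, no_elbow = _elbow_k(ks, sils)
        if no_elbow:
            warnings.warn(
                f"{method}: no clear silhouette elbow; defaulting to k={k_star}"
            )
        per_method[method] = (k_star, fits[(method, k_star)]["mean_silhouette"],
                              no_elbow)

    best_method = max(per_method, key=lambda m: per_method[m][1])
    best_k = per_method[best_method][0]
    chosen = fits[(best_method, best_k)]
    report = ClusteringReport(
        method=best_method,
        k=best_k,
        labels=chosen["labels"],
        calinski_harabasz=chosen["calinski_harabasz"],
        mean_silhouette=chosen["mean_silhouette"],
        hopkins=h,
        seed=seed,
    )
    detail = {
        "hopkins": h,
        "per_method_choice": {m: {"k": v[0], "mean_silhouette": v[1]}
                              for m, v in per_method.items()},
        "fits": {
            f"{m}:k={k}": {
                "calinski_harabasz": f["calinski_harabasz"],
                "mean_silhouette": f["mean_silhouette"],
            }
            for (m, k), f in fits.items()
        },
        "neighbor_ks": [k for k in (best_k - 1, best_k + 1) if k in ks],
    }
    return report, detail
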