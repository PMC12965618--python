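"""Community diversity and the permutation tests contrasting sample groups.

Alpha diversity is the Inverse Simpson index of each sample's abundance
shares; beta diversity is Bray–Curtis dissimilarity on log2(x+1)-transformed
abundances, ordinated by classical PCoA. Group contrasts (depth layer,
day versus night) use MRPP and ANOSIM permutation tests plus the Wilcoxon
rank-sum test on per-sample alpha diversities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.spatial.distance as ssd
from scipy import stats

from .core_io import AbundanceMatrix

__all__ = [
    "DistanceMatrix",
    "PermTestResult",
    "inverse_simpson",
    "bray_curtis",
    "pcoa",
    "mrpp",
    "anosim",
    "wilcoxon_rank_sum",
    "day_night_groups",
    "DEFAULT_NIGHT_CLOCKS",
    "DEFAULT_DAY_CLOCKS",
]

#: Clock-hour windows for the day/night diversity contrast. The study
#: contrasts night-time and daytime surface samples; the package default
#: takes the three dark sampling hours against the three light ones.
DEFAULT_NIGHT_CLOCKS = (20.0, 0.0, 4.0)
DEFAULT_DAY_CLOCKS = (8.0, 12.0, 16.0)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class PermTestResult:
    """Outcome of a two-group (or k-group) significance test."""

    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    method: str = ""


def inverse_simpson(abundances) -> float:
    """Inverse Simpson index 1 / sum(p_i^2) of one sample's abundances.

    Equals the richness S for a perfectly even community and 1 when a
    single population dominates completely.
    """
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("inverse Simpson undefined for an all-zero sample")
    p = x / total
    return float(1.0 / np.sum(p**2))


def bray_curtis(matrix: AbundanceMatrix, log2_transform: bool = True) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarities between samples.

    With ``log2_transform`` the abundances are first mapped x -> log2(x+1)
    (pseudocount 1; zeros are ubiquitous in virome tables). A pair of
    all-zero samples has undefined Bray–Curtis; it is reported as 0 with a
    warning.
    """
    x = matrix.values.T.astype(float)  # samples x populations
    if log2_transform:
        x = np.log2(x + 1.0)
    with np.errstate(invalid="ignore"):
        d = ssd.squareform(ssd.pdist(x, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero sample pair: Bray-Curtis set to 0")
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(labels=matrix.sample_ids, d=d)


def pcoa(dist: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers -d^2/2, eigendecomposes, and returns coordinates for the
    positive-eigenvalue axes in decreasing eigenvalue order, together with
    those eigenvalues. Negative eigenvalues (non-Euclidean input) are
    dropped. For Euclidean-embeddable distances the retained coordinate
    space reproduces the input distances.
    """
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    if np.allclose(dist.d, 0):
        return np.zeros((dist.n, 0)), np.zeros(0)
    from skbio import DistanceMatrix as _SkbioDM

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(_SkbioDM(dist.d, ids=dist.labels), method="eigh",
                          warn_neg_eigval=False)
    eig = res.eigvals.values
    pos = eig > max(eig.max(), 0) * 1e-10
    return res.samples.values[:, pos], eig[pos]


def _group_indices(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    counts = np.bincount(codes)
    if np.any(counts < 2):
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"singleton group(s): {small}")
    return codes, list(uniq)


def _mrpp_delta(d: np.ndarray, codes: np.ndarray) -> float:
    """Weighted mean within-group distance, weights n_i / N."""
    n = codes.size
    delta = 0.0
    for g in np.unique(codes):
        idx = np.flatnonzero(codes == g)
        sub = d[np.ix_(idx, idx)]
        m = idx.size
        delta += (m / n) * (sub.sum() / (m * (m - 1)))
    return delta


def mrpp(dist: DistanceMatrix, groups, n_perm: int = 999,
         seed: int | None = None) -> PermTestResult:
    """Multi-response permutation procedure.

    The observed statistic is the group-size-weighted mean within-group
    distance (delta); significance is the lower tail over random
    relabelings with the add-one convention, so tight groups give small p.
    """
    codes, _ = _group_indices(groups)
    observed = _mrpp_delta(dist.d, codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _mrpp_delta(dist.d, perm) <= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermTestResult(statistic=float(observed), p_value=float(p),
                          n_permutations=n_perm, seed=seed, method="mrpp")


def _anosim_r(rank_d: np.ndarray, codes: np.ndarray) -> float:
    within = codes[:, None] == codes[None, :]
    iu = np.triu_indices(codes.size, k=1)
    rw = rank_d[iu][within[iu]]
    rb = rank_d[iu][~within[iu]]
    m = iu[0].size
    return float((rb.mean() - rw.mean()) / (m / 2.0))


def anosim(dist: DistanceMatrix, groups, n_perm: int = 999,
           seed: int | None = None) -> PermTestResult:
    """Analysis of similarities on ranked distances.

    R = (mean between-group rank - mean within-group rank) / (M/2) with M
    the number of distance pairs; upper-tail permutation p with the
    add-one convention. R is 1 when all within-group distances fall below
    all between-group ones and near 0 under random labels.
    """
    codes, _ = _group_indices(groups)
    iu = np.triu_indices(dist.n, k=1)
    ranks = np.zeros_like(dist.d)
    r = stats.rankdata(dist.d[iu])
    ranks[iu] = r
    ranks = ranks + ranks.T
    observed = _anosim_r(ranks, codes)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _anosim_r(ranks, perm) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermTestResult(statistic=observed, p_value=float(p),
                          n_permutations=n_perm, seed=seed, method="anosim")


def wilcoxon_rank_sum(x, y) -> PermTestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact by enumeration when both samples have n <= 25 and no ties;
    otherwise the normal approximation with tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and x.size <= 25 and y.size <= 25) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return PermTestResult(statistic=float(res.statistic),
                          p_value=float(res.pvalue), n_permutations=0,
                          method=f"wilcoxon-{method}")


def day_night_groups(matrix: AbundanceMatrix,
                     night_clocks=DEFAULT_NIGHT_CLOCKS,
                     day_clocks=DEFAULT_DAY_CLOCKS,
                     included_only: bool = True) -> dict[str, str]:
    """Map sample ids to 'day'/'night' by their clock hour.

    Samples whose clock hour is in neither window are omitted.
    """
    out: dict[str, str] = {}
    for s in matrix.samples:
        if included_only and not s.included:
            continue
        if s.clock_hours in night_clocks:
            out[s.sample_id] = "night"
        elif s.clock_hours in day_clocks:
            out[s.sample_id] = "day"
    return out
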