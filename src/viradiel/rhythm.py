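"""Diel rhythm detection by a rank-based circular umbrella test.

Each population's abundance series is detrended (OLS on elapsed time over
included samples) and its samples pooled into time-of-day classes (one per
sampling interval within the 24-h cycle). For every "umbrella" alternative —
abundance rising monotonically from a trough class to a peak class around
one arc of the clock and falling back around the other — a Jonckheere–
Terpstra-type statistic counts concordant cross-class pairs along both
arcs. The per-population p-value is the best alternative's p after a
Bonferroni-style correction over the effective number of distinct
alternatives, and Benjamini–Hochberg step-up control across populations
declares diel populations at FDR 0.05.

The null distribution of the statistic (values randomly re-assigned to
classes) is available three ways: an exact dynamic program over rank
placements (tie-free), complete enumeration (any tie pattern, small n), and
a tie-corrected normal approximation derived from the exact permutation
mean and variance of the weighted pair-count statistic.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from math import comb as _comb

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core_io import AbundanceMatrix, HostTable

__all__ = [
    "UmbrellaAlternative",
    "RhythmResult",
    "detrend",
    "enumerate_alternatives",
    "umbrella_weights",
    "jt_umbrella_statistic",
    "jt_null_moments",
    "jt_exact_distribution",
    "jt_pvalue",
    "bh_adjust",
    "rain_scan",
    "host_summed_rhythms",
    "effective_test_count",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UmbrellaAlternative:
    """A circular rise-to-peak / fall-to-trough ordering of time classes.

    ``peak_class`` and ``trough_class`` index the cycle's time-of-day
    classes (0 .. n_classes-1, class k spanning clock hour k*deltat). The
    alternative asserts monotone non-decreasing medians from trough to peak
    along both arcs of the circle.
    """

    peak_class: int
    trough_class: int
    n_classes: int

    def __post_init__(self) -> None:
        c = self.n_classes
        if c < 2:
            raise ValueError("need at least 2 time classes")
        if not (0 <= self.peak_class < c and 0 <= self.trough_class < c):
            raise ValueError("peak/trough class out of range")
        if self.peak_class == self.trough_class:
            raise ValueError("peak and trough classes must differ")

    def rise_path(self) -> list[int]:
        """Classes from trough to peak walking forward around the clock."""
        c = self.n_classes
        steps = (self.peak_class - self.trough_class) % c
        return [(self.trough_class + s) % c for s in range(steps + 1)]

    def fall_path(self) -> list[int]:
        """Classes from trough to peak walking backward around the clock."""
        c = self.n_classes
        steps = (self.trough_class - self.peak_class) % c
        return [(self.trough_class - s) % c for s in range(steps + 1)]


@dataclass
class RhythmResult:
    """Umbrella-scan outcome for one population (or host-genus sum)."""

    population_id: str
    p_value: float
    p_adjusted: float
    best_alternative: UmbrellaAlternative
    is_diel: bool


# ---------------------------------------------------------------------------
# Detrending


def detrend(series, times, mask=None) -> np.ndarray:
    """OLS residuals of ``series`` on elapsed ``times`` over included points.

    Returns the residual vector at included points only (zero mean, zero
    empirical slope). Regression is on elapsed hours, not sample index, so
    masked gaps keep their true spacing.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if mask is None:
        mask = np.ones(series.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    y = series[mask]
    t = times[mask]
    if y.size < 3:
        raise ValueError(f"detrend needs >= 3 included points, got {y.size}")
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


# ---------------------------------------------------------------------------
# Alternatives and the umbrella statistic


def enumerate_alternatives(period: float, deltat: float) -> list[UmbrellaAlternative]:
    """All (peak, trough) umbrella alternatives for a sampling grid.

    ``c = period / deltat`` time-of-day classes give ``c * (c - 1)``
    alternatives (every ordered peak/trough pair).
    """
    ratio = period / deltat
    c = int(round(ratio))
    if abs(ratio - c) > 1e-9:
        raise ValueError(f"period {period} not divisible by deltat {deltat}")
    if c < 2:
        raise ValueError("period/deltat must be >= 2")
    return [
        UmbrellaAlternative(peak_class=p, trough_class=t, n_classes=c)
        for p in range(c)
        for t in range(c)
        if p != t
    ]


def umbrella_weights(alt: UmbrellaAlternative) -> np.ndarray:
    """Pair-weight matrix: w[i, j] = #segments in which class i precedes j.

    Each arc (rise, fall) contributes 1 for every ordered class pair along
    its trough-to-peak direction; the direct trough/peak pair lies on both
    arcs and gets weight 2. Entries are 0 for uncompared pairs.
    """
    c = alt.n_classes
    w = np.zeros((c, c), dtype=int)
    for path in (alt.rise_path(), alt.fall_path()):
        for a, b in itertools.combinations(path, 2):
            w[a, b] += 1
    return w


def effective_test_count(alternatives: list[UmbrellaAlternative]) -> int:
    """Number of distinct umbrella orderings (deduplicated weight matrices)."""
    seen = {umbrella_weights(a).tobytes() for a in alternatives}
    return len(seen)


def _pair_count_matrix(values: np.ndarray, classes: np.ndarray,
                       n_classes: int) -> np.ndarray:
    """U[i, j] = #{x in class i, y in class j : x < y} + 1/2 ties."""
    v = np.asarray(values, dtype=float)
    psi = (v[:, None] < v[None, :]) + 0.5 * (v[:, None] == v[None, :])
    np.fill_diagonal(psi, 0.0)
    g = np.zeros((n_classes, v.size))
    g[classes, np.arange(v.size)] = 1.0
    return g @ psi @ g.T


def jt_umbrella_statistic(values, classes, alt: UmbrellaAlternative
                          ) -> tuple[float, np.ndarray]:
    """Concordant-pair statistic for one alternative.

    Sums, over both arcs and every ordered class pair (i before j on the
    trough-to-peak walk), the count of value pairs with the class-i value
    below the class-j value, ties counted one half. Returns the statistic
    and the per-class sample sizes.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes, dtype=int)
    if values.shape != classes.shape:
        raise ValueError("values and classes must align")
    sizes = np.bincount(classes, minlength=alt.n_classes)
    if np.count_nonzero(sizes) < 2:
        raise ValueError("need >= 2 nonempty classes")
    u = _pair_count_matrix(values, classes, alt.n_classes)
    w = umbrella_weights(alt)
    return float(np.sum(w * u)), sizes


# ---------------------------------------------------------------------------
# Null distribution: exact (DP / enumeration) and normal approximation


def _psi_moments(values: np.ndarray) -> dict[str, float]:
    """Permutation moments of the pair indicator psi over the value multiset.

    psi(x, y) = 1 if x < y, 1/2 on ties, 0 otherwise. Returns expectations
    over ordered tuples of distinct positions, the building blocks of the
    exact variance of any weighted pair-count statistic.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    order = v[:, None] < v[None, :]
    ties = v[:, None] == v[None, :]
    np.fill_diagonal(ties, False)
    greater = order.sum(axis=1)          # values above v_a
    less = order.sum(axis=0)             # values below v_a
    eq = ties.sum(axis=1)
    s_out = greater + eq / 2.0           # sum_y psi(a, y)
    s_in = less + eq / 2.0               # sum_x psi(x, a)
    r_same = float(greater.sum() + eq.sum() / 4.0)
    r_rev = float(eq.sum() / 4.0)
    r_outfan = float(np.sum(s_out**2 - (greater + eq / 4.0)))
    r_infan = float(np.sum(s_in**2 - (less + eq / 4.0)))
    r_chain = float(np.sum(s_in * s_out - eq / 4.0))
    psi_total = n * (n - 1) / 2.0
    sum4 = psi_total**2 - r_same - r_rev - r_outfan - r_infan - 2 * r_chain
    n2 = n * (n - 1)
    n3 = n2 * (n - 2)
    n4 = n3 * (n - 3)
    return {
        "t4": r_same / n2,
        "t5": r_rev / n2,
        "t1": r_outfan / n3 if n3 else 0.0,
        "t2": r_infan / n3 if n3 else 0.0,
        "u": r_chain / n3 if n3 else 0.0,
        "t6": sum4 / n4 if n4 else 0.0,
    }


def _covariance_tensor(sizes: np.ndarray, moments: dict[str, float]) -> np.ndarray:
    """Cov(U_ij, U_kl) for all class quadruples under the permutation null.

    Classifies slot coincidences between the two pair counts (shared first
    group, shared second group, chain overlaps, full overlap, reversal) and
    weights each configuration count by the matching psi product moment.
    """
    m = np.asarray(sizes, dtype=float)
    c = m.size
    eye = np.eye(c)
    ni = m.reshape(c, 1, 1, 1)
    nj = m.reshape(1, c, 1, 1)
    nk = m.reshape(1, 1, c, 1)
    nl = m.reshape(1, 1, 1, c)
    d_ik = eye.reshape(c, 1, c, 1)
    d_jl = eye.reshape(1, c, 1, c)
    d_il = eye.reshape(c, 1, 1, c)
    d_jk = eye.reshape(1, c, c, 1)

    n_pair_same = d_ik * d_jl * ni * nj
    n_pair_rev = d_il * d_jk * ni * nj
    n_outfan = d_ik * ni * (nj * nl - d_jl * nj)
    n_infan = d_jl * nj * (ni * nk - d_ik * ni)
    n_chain1 = d_jk * nj * (ni * nl - d_il * ni)
    n_chain2 = d_il * ni * (nj * nk - d_jk * nj)
    n_total = ni * nj * nk * nl
    n_rest = n_total - (n_pair_same + n_pair_rev + n_outfan + n_infan
                        + n_chain1 + n_chain2)
    second_moment = (
        n_pair_same * moments["t4"]
        + n_pair_rev * moments["t5"]
        + n_outfan * moments["t1"]
        + n_infan * moments["t2"]
        + (n_chain1 + n_chain2) * moments["u"]
        + n_rest * moments["t6"]
    )
    mean_prod = (ni * nj / 2.0) * (nk * nl / 2.0)
    return second_moment - mean_prod


def jt_null_moments(values, classes, alt: UmbrellaAlternative
                    ) -> tuple[float, float]:
    """Exact permutation mean and variance of the umbrella statistic."""
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes, dtype=int)
    sizes = np.bincount(classes, minlength=alt.n_classes)
    w = umbrella_weights(alt).astype(float)
    mean = 0.5 * float(np.einsum("ij,i,j->", w, sizes, sizes))
    cov = _covariance_tensor(sizes, _psi_moments(values))
    var = float(np.einsum("ij,kl,ijkl->", w, w, cov))
    return mean, max(var, 0.0)


def _exact_distribution_dp(sizes: np.ndarray, weights: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Exact tie-free null by dynamic programming over rank placements.

    Ranks are placed smallest-first into classes; adding a rank to class g
    raises the statistic by ``sum_i count_i * w[i, g]``. States are class
    fill counts; each carries an integer arrangement-count vector over
    statistic values. Works for any nonnegative pair-weight matrix, so it
    covers the circular umbrella with its doubled trough-to-peak pair.
    """
    sizes = tuple(int(s) for s in sizes)
    n = sum(sizes)
    # arrangement counts must stay exactly representable in int64
    total = 1
    remaining = n
    for s in sizes:
        total *= _comb(remaining, s)
        remaining -= s
    if total >= 2**62:
        raise ValueError(
            "exact DP: arrangement count overflows int64; use the normal method"
        )
    w = np.asarray(weights, dtype=np.int64)
    max_stat = int(np.einsum("ij,i,j->", w, sizes, sizes))
    start = tuple(0 for _ in sizes)
    states: dict[tuple, np.ndarray] = {
        start: np.array([1] + [0] * max_stat, dtype=np.int64)
    }
    for _ in range(n):
        nxt: dict[tuple, np.ndarray] = {}
        for counts, dist in states.items():
            arr = np.asarray(counts)
            for g, (have, cap) in enumerate(zip(counts, sizes)):
                if have >= cap:
                    continue
                inc = int(arr @ w[:, g])
                key = counts[:g] + (have + 1,) + counts[g + 1:]
                tgt = nxt.setdefault(
                    key, np.zeros(max_stat + 1, dtype=np.int64)
                )
                if inc:
                    tgt[inc:] += dist[: max_stat + 1 - inc]
                else:
                    tgt += dist
        states = nxt
    (final_dist,) = states.values()
    support = np.nonzero(final_dist)[0]
    return support.astype(float), final_dist[support]


def _exact_distribution_enumeration(values: np.ndarray, sizes: np.ndarray,
                                    weights: np.ndarray
                                    ) -> tuple[np.ndarray, np.ndarray]:
    """Exact null by complete enumeration (any tie pattern, n <= 8)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n > 8:
        raise ValueError("complete enumeration limited to n <= 8")
    classes = np.repeat(np.arange(len(sizes)), sizes)
    w_pos = weights[classes[:, None], classes[None, :]].astype(float)
    psi = (v[:, None] < v[None, :]) + 0.5 * (v[:, None] == v[None, :])
    np.fill_diagonal(psi, 0.0)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    psi_perm = psi[perms[:, :, None], perms[:, None, :]]
    stats = np.tensordot(psi_perm, w_pos, axes=([1, 2], [0, 1]))
    support, counts = np.unique(np.round(stats * 2) / 2, return_counts=True)
    return support, counts.astype(np.int64)


def jt_exact_distribution(values, classes, alt: UmbrellaAlternative
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Exact null support and arrangement counts for the umbrella statistic.

    Dispatches to the rank-placement DP when the values are tie-free, else
    to complete enumeration (n <= 8).
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes, dtype=int)
    sizes = np.bincount(classes, minlength=alt.n_classes)
    w = umbrella_weights(alt)
    if np.unique(values).size == values.size:
        return _exact_distribution_dp(sizes, w)
    return _exact_distribution_enumeration(values, sizes, w)


def jt_pvalue(statistic: float, values, classes, alt: UmbrellaAlternative,
              method: str = "auto") -> float:
    """Upper-tail p of the umbrella statistic under the permutation null.

    ``exact`` uses the DP (tie-free) or complete enumeration (n <= 8);
    ``normal`` a Gaussian approximation with the exact tie-corrected
    permutation variance and a 1/2 continuity correction; ``auto`` picks
    exact for tie-free samples of n <= 12, else normal.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes, dtype=int)
    if values.shape != classes.shape:
        raise ValueError("values and classes must align")
    n = values.size
    no_ties = np.unique(values).size == n
    if method == "auto":
        method = "exact" if (no_ties and n <= 12) else "normal"
    if method == "exact":
        support, counts = jt_exact_distribution(values, classes, alt)
        total = counts.sum()
        tail = counts[support >= statistic - 1e-9].sum()
        return float(tail / total)
    if method == "normal":
        from scipy.stats import norm

        mean, var = jt_null_moments(values, classes, alt)
        if var <= 0:
            return 1.0
        z = (statistic - 0.5 - mean) / np.sqrt(var)
        return float(min(1.0, norm.sf(z)))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Multiple testing


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Full scan


def _layer_setup(matrix: AbundanceMatrix, period: float):
    layers = {s.depth_layer for s in matrix.samples}
    if len(layers) != 1:
        raise ValueError(
            f"rain_scan needs a single depth layer, got {sorted(layers)}; "
            "use AbundanceMatrix.subset_layer first"
        )
    included = [s for s in matrix.samples if s.included]
    t = np.array([s.elapsed_hours for s in included])
    gaps = np.diff(sorted({s.elapsed_hours for s in matrix.samples}))
    deltat = float(np.min(gaps))
    c = int(round(period / deltat))
    if abs(period / deltat - c) > 1e-9 or c < 2:
        raise ValueError(f"period {period} incompatible with deltat {deltat}")
    clock = np.array([s.clock_hours for s in included])
    classes = np.round((clock % period) / deltat).astype(int) % c
    mask = matrix.included_mask()
    times_all = np.array([s.elapsed_hours for s in matrix.samples])
    return deltat, c, classes, mask, times_all, t


_DP_TABLE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _exact_sf_tables(sizes: np.ndarray, alternatives: list[UmbrellaAlternative]
                     ) -> list[tuple[np.ndarray, np.ndarray]] | None:
    """Per-alternative (support, upper-tail probability) exact null tables.

    The tie-free null depends only on the class sizes and pair weights, so
    one DP per distinct weight matrix serves every population of a layer;
    a reversal alternative (transposed weights) mirrors an already-computed
    distribution instead of re-running the DP. Returns None when the
    arrangement count is too large for exact integer bookkeeping.
    """
    key_sizes = tuple(int(s) for s in sizes)
    tables = []
    try:
        for alt in alternatives:
            w = umbrella_weights(alt)
            key = (key_sizes, w.tobytes())
            if key not in _DP_TABLE_CACHE:
                key_t = (key_sizes, np.ascontiguousarray(w.T).tobytes())
                if key_t in _DP_TABLE_CACHE:
                    sup_t, cnt_t = _DP_TABLE_CACHE[key_t]
                    total = int(np.einsum("ij,i,j->", w, sizes, sizes))
                    _DP_TABLE_CACHE[key] = ((total - sup_t)[::-1].copy(),
                                            cnt_t[::-1].copy())
                else:
                    _DP_TABLE_CACHE[key] = _exact_distribution_dp(sizes, w)
            sup, cnt = _DP_TABLE_CACHE[key]
            sf = np.cumsum(cnt[::-1].astype(float))[::-1] / float(cnt.sum())
            tables.append((sup, sf))
    except ValueError:
        return None
    return tables


def rain_scan(matrix: AbundanceMatrix, period: float = 24.0,
              alpha: float = 0.05, method: str = "auto") -> list[RhythmResult]:
    """Umbrella-test scan of every population in a single-layer matrix.

    Per population: detrend over included samples, compute each umbrella
    alternative's p-value, take the minimum times the effective number of
    distinct alternatives (capped at 1), then BH-adjust across populations.
    With ``method='auto'`` tie-free series use the exact DP null (shared
    across populations, since it depends only on the class sizes); series
    with ties fall back to the tie-corrected normal approximation.
    Populations with no abundance in any included sample are excluded (they
    are absent from this layer); populations with fewer than 3 included
    samples are skipped with a warning.
    """
    deltat, c, classes, mask, times_all, _ = _layer_setup(matrix, period)
    alternatives = enumerate_alternatives(period, deltat)
    n_eff = effective_test_count(alternatives)
    weight_stack = np.stack([umbrella_weights(a).astype(float)
                             for a in alternatives])
    sizes = np.bincount(classes, minlength=c)
    exact_tables = None
    if method in ("auto", "exact"):
        exact_tables = _exact_sf_tables(sizes, alternatives)
        if exact_tables is None and method == "exact":
            raise ValueError("exact null infeasible for this design")

    results: list[RhythmResult] = []
    raw_p: list[float] = []
    best: list[UmbrellaAlternative] = []
    kept_ids: list[str] = []
    for i, pop in enumerate(matrix.population_ids):
        row = matrix.values[i]
        if not np.any(row[mask] > 0):
            logger.warning("population %s absent in included samples; excluded", pop)
            continue
        if mask.sum() < 3:
            warnings.warn(f"population {pop}: < 3 included samples, skipped")
            continue
        resid = detrend(row, times_all, mask)
        u = _pair_count_matrix(resid, classes, c)
        stats = np.tensordot(weight_stack, u, axes=([1, 2], [0, 1]))
        no_ties = np.unique(resid).size == resid.size
        if exact_tables is not None and no_ties:
            pvals = np.array([
                sf[min(np.searchsorted(sup, round(s) - 1e-9), len(sup) - 1)]
                for s, (sup, sf) in zip(stats, exact_tables)
            ])
        elif method == "exact":
            pvals = np.array([
                jt_pvalue(s, resid, classes, a, method="exact")
                for s, a in zip(stats, alternatives)
            ])
        else:
            moments = _psi_moments(resid)
            cov = _covariance_tensor(sizes, moments)
            means = 0.5 * np.einsum("aij,i,j->a", weight_stack, sizes, sizes)
            variances = np.einsum("aij,akl,ijkl->a", weight_stack,
                                  weight_stack, cov)
            from scipy.stats import norm

            with np.errstate(divide="ignore", invalid="ignore"):
                z = (stats - 0.5 - means) / np.sqrt(np.maximum(variances, 0.0))
            pvals = np.where(variances > 0, norm.sf(z), 1.0)
            pvals = np.minimum(pvals, 1.0)
        j = int(np.argmin(pvals))
        raw_p.append(min(1.0, pvals[j] * n_eff))
        best.append(alternatives[j])
        kept_ids.append(pop)

    if not kept_ids:
        return []
    adjusted = bh_adjust(np.array(raw_p))
    for pop, p, q, alt in zip(kept_ids, raw_p, adjusted, best):
        results.append(RhythmResult(
            population_id=pop,
            p_value=float(p),
            p_adjusted=float(q),
            best_alternative=alt,
            is_diel=bool(q <= alpha),
        ))
    return results


def host_summed_rhythms(matrix: AbundanceMatrix, hosts: HostTable,
                        period: float = 24.0, alpha: float = 0.05,
                        method: str = "auto") -> list[RhythmResult]:
    """Umbrella scan of per-genus summed abundances.

    Populations sharing a predicted host genus are summed per sample and the
    genus-level series scanned exactly like populations. Genera whose sum is
    zero in every included sample are skipped with a warning.
    """
    if not any(p in hosts for p in matrix.population_ids):
        raise ValueError("no population in the matrix has a host prediction")
    import pandas as pd

    frame = matrix.to_frame()
    predicted = [p for p in matrix.population_ids if p in hosts]
    genus = pd.Series({p: hosts.genus[p] for p in predicted})
    summed = frame.loc[predicted].groupby(genus).sum()
    genus_matrix = AbundanceMatrix(
        population_ids=list(summed.index),
        samples=list(matrix.samples),
        values=summed.values,
    )
    return rain_scan(genus_matrix, period=period, alpha=alpha, method=method)
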