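"""Per-position two-group testing, neighbor p-value combination, ranking.

For every reference position two pooled groups of normalized signals —
one from the sample carrying modifications, one from the matched control
— are compared with a two-sample test (Kolmogorov-Smirnov by default,
Mann-Whitney U or Student's t as alternatives).  Because each current
measurement reflects a k-mer rather than a single base, a modification
also perturbs the signals of its neighbors; per-position p-values are
therefore combined over a +/-k window with a weighted Stouffer (or
Fisher) statistic, giving the center position the largest weight.
Finally, neighboring positions carry redundant evidence for the same
modification, so a greedy neighborhood ranking suppresses any site within
a small window of a better-ranked site.

With hundreds of pooled signals per position a strong modification
drives p-values far below the smallest positive double, so every test
also reports its p-value on the log scale and the ranking operates on
log p; the plain ``p`` fields are clamped for reporting only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .signal_model import (
    EventSequence,
    PositionSignalGroups,
    filter_low_coverage,
    pool_position_signals,
)

__all__ = [
    "SiteScore",
    "DetectionConfig",
    "ks_statistic",
    "u_test",
    "t_test",
    "combine_stouffer",
    "combine_fisher",
    "default_weights",
    "neighborhood_rank",
    "score_sites",
    "detect_modifications",
    "ranked_sites",
]

logger = logging.getLogger(__name__)

#: Clamp bounds for reported (linear-scale) p-values.
_P_EPS_LO = 1e-300
_P_EPS_HI = 1.0 - 1e-16
_LOG_P_LO = np.log(_P_EPS_LO)

_LN10 = np.log(10.0)


@dataclass
class SiteScore:
    """Test results for one reference position.

    ``p_single`` and ``p_combined`` are clamped to ``[1e-300, 1]`` for
    reporting; ``log10_p_single`` / ``log10_p_combined`` carry the exact
    log-scale values that the ranking uses.  ``rank`` is assigned by
    :func:`neighborhood_rank`: consecutive integers from 1 for accepted
    sites, ``None`` for sites suppressed as redundant neighbors of a
    better-ranked site.
    """

    ref_position: int
    ref_base: str
    m: int
    n: int
    D: float | None
    p_single: float
    log10_p_single: float = 0.0
    Z: float | None = None
    p_combined: float = 1.0
    log10_p_combined: float = 0.0
    rank: int | None = None


@dataclass
class DetectionConfig:
    """Parameters of the detection pipeline.

    Attributes
    ----------
    test
        Per-position two-sample test: ``"ks"``, ``"u"`` or ``"t"``.
    combiner
        Neighbor p-value combination: ``"stouffer"``, ``"fisher"`` or
        ``"none"`` (rank by the single-base p-value).
    k
        Neighbor half-window for the combiner; the window spans the
        center position plus ``k`` positions on each side.
    weight_decay
        Stouffer weight for a neighbor at distance ``d`` is
        ``weight_decay ** -d``, so the center carries the most weight.
    min_reads
        Minimum distinct reads per group for a position to be tested.
    rank_window
        Half-window of the greedy neighborhood suppression (1 or 2).
    normalize
        Normalize each read's signals (median shift, averaged-absolute-
        difference scale, clip to [-5, 5]) before pooling.
    """

    test: str = "ks"
    combiner: str = "stouffer"
    k: int = 2
    weight_decay: float = 2.0
    min_reads: int = 5
    rank_window: int = 2
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.test not in ("ks", "u", "t"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.combiner not in ("stouffer", "fisher", "none"):
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if self.k < 0 or self.rank_window < 0:
            raise ValueError("k and rank_window must be >= 0")


# ---------------------------------------------------------------------
# log-scale helpers
# ---------------------------------------------------------------------


def _ks_log_sf(lam: float | np.ndarray) -> np.ndarray:
    """log of the asymptotic Kolmogorov survival function.

    ``sf(lam) = 2 sum_{j>=1} (-1)^(j-1) exp(-2 j^2 lam^2)``; beyond the
    underflow range of the alternating series the first term dominates
    (the j=2 term is smaller by a factor ``exp(-6 lam^2)``).
    """
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(
            lam < 5.0,
            np.log(np.maximum(stats.kstwobign.sf(np.minimum(lam, 5.0)), 0.0)),
            np.log(2.0) - 2.0 * lam**2,
        )
    return out


def _norm_isf_from_log(log_p: np.ndarray) -> np.ndarray:
    """Upper-tail standard normal quantile from log p, underflow-safe.

    For moderate p delegates to ``norm.isf``; for extreme p inverts the
    tail approximation ``p ~ phi(z)/z`` by fixed-point iteration on
    ``z = sqrt(-2 (log p + log z + log sqrt(2 pi)))``.
    """
    log_p = np.asarray(log_p, dtype=float)
    out = np.empty_like(log_p)
    moderate = log_p > np.log(1e-280)
    out[moderate] = stats.norm.isf(np.exp(log_p[moderate]))
    lp = log_p[~moderate]
    if lp.size:
        z = np.sqrt(-2.0 * (lp + 0.5 * np.log(2.0 * np.pi)))
        for _ in range(3):
            z = np.sqrt(-2.0 * (lp + np.log(z) + 0.5 * np.log(2.0 * np.pi)))
        out[~moderate] = z
    return out


def _chi2_log_sf(statistic: np.ndarray, df: np.ndarray) -> np.ndarray:
    """log chi-square survival function with a large-deviation fallback."""
    out = stats.chi2.logsf(statistic, df)
    bad = ~np.isfinite(out)
    if np.any(bad):
        x = np.asarray(statistic, dtype=float)[bad] / 2.0
        k = np.asarray(df, dtype=float)[bad] / 2.0
        # leading term of the incomplete-gamma tail for x >> k
        out = np.asarray(out)
        out[bad] = -x + (k - 1.0) * np.log(x) - gammaln(k) + np.log1p((k - 1.0) / x)
    return out


def _clip_p(p: float | np.ndarray) -> np.ndarray:
    return np.clip(p, _P_EPS_LO, 1.0)


# ---------------------------------------------------------------------
# single-position tests
# ---------------------------------------------------------------------


def _ks_d(group1: np.ndarray, group2: np.ndarray) -> tuple[float, int, int]:
    x = np.sort(np.asarray(group1, dtype=float))
    y = np.sort(np.asarray(group2, dtype=float))
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValueError("both groups must be non-empty for the KS test")
    pooled = np.concatenate([x, y])
    cdf1 = np.searchsorted(x, pooled, side="right") / m
    cdf2 = np.searchsorted(y, pooled, side="right") / n
    return float(np.max(np.abs(cdf1 - cdf2))), m, n


def _ks_test_log(group1: np.ndarray, group2: np.ndarray) -> tuple[float, float]:
    d, m, n = _ks_d(group1, group2)
    rt = np.sqrt(m * n / (m + n))
    # Stephens' finite-sample refinement of the asymptotic argument;
    # without it the pooled per-site p-values are visibly non-uniform
    # under the null at a few hundred signals per group.
    lam = (rt + 0.12 + 0.11 / rt) * d
    return d, float(np.minimum(_ks_log_sf(lam), 0.0))


def ks_statistic(group1: np.ndarray, group2: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    ``D`` is the exact supremum of the absolute difference between the
    two empirical distribution functions (the supremum of two right-
    continuous step functions is attained at a sample point, so
    evaluating both ECDFs at every pooled sample value is exhaustive).
    The p-value comes from the asymptotic Kolmogorov distribution
    evaluated at ``D * sqrt(m n / (m + n))``, clamped to ``[1e-300, 1]``.
    """
    d, log_p = _ks_test_log(group1, group2)
    return d, float(_clip_p(np.exp(max(log_p, _LOG_P_LO))))


def _u_test_log(group1: np.ndarray, group2: np.ndarray) -> float:
    """Two-sided Mann-Whitney U log p (normal approximation, continuity
    corrected, no tie correction — signals are continuous)."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValueError("both groups must be non-empty for the U test")
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = float(ranks[:m].sum())
    u1 = r1 - m * (m + 1) / 2.0
    mu = m * n / 2.0
    sd = np.sqrt(m * n * (m + n + 1) / 12.0)
    if sd == 0:
        return 0.0
    z = (abs(u1 - mu) - 0.5) / sd
    return float(min(np.log(2.0) + stats.norm.logsf(max(z, 0.0)), 0.0))


def u_test(group1: np.ndarray, group2: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value, clamped to ``[1e-300, 1]``."""
    return float(_clip_p(np.exp(max(_u_test_log(group1, group2), _LOG_P_LO))))


def _t_test_log(group1: np.ndarray, group2: np.ndarray) -> float:
    """Two-sided pooled-variance t-test log p.

    Falls back to the normal tail for statistics so extreme that the t
    survival function underflows (the degrees of freedom here are in the
    hundreds, where the two tails agree closely).
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    m, n = x.size, y.size
    if m < 2 or n < 2:
        raise ValueError("t test needs at least two values per group")
    df = m + n - 2
    pooled_var = ((m - 1) * x.var(ddof=1) + (n - 1) * y.var(ddof=1)) / df
    if pooled_var == 0.0:
        logger.warning("zero pooled variance in t test; reporting p = 1")
        return 0.0
    t = (x.mean() - y.mean()) / np.sqrt(pooled_var * (1.0 / m + 1.0 / n))
    with np.errstate(divide="ignore"):
        lp = np.log(2.0) + stats.t.logsf(abs(t), df)
    if not np.isfinite(lp):
        lp = np.log(2.0) + stats.norm.logsf(abs(t))
    return float(min(lp, 0.0))


def t_test(group1: np.ndarray, group2: np.ndarray) -> float:
    """Two-sided Student's t-test p-value (pooled variance), clamped.

    A zero pooled variance makes the statistic undefined; such sites are
    reported as entirely non-significant (p = 1) with a warning.
    """
    return float(_clip_p(np.exp(max(_t_test_log(group1, group2), _LOG_P_LO))))


# ---------------------------------------------------------------------
# p-value combination
# ---------------------------------------------------------------------


def _clamp_pvalues(ps: np.ndarray) -> np.ndarray:
    ps = np.asarray(ps, dtype=float)
    if np.any((ps <= 0.0) | (ps >= 1.0)):
        logger.warning("degenerate p-values clamped away from 0/1")
    return np.clip(ps, _P_EPS_LO, _P_EPS_HI)


def default_weights(offsets: Sequence[int], decay: float = 2.0) -> np.ndarray:
    """Neighbor weights ``decay ** -|offset|`` (center offset 0 gets 1)."""
    return np.asarray([float(decay) ** -abs(int(d)) for d in offsets])


def combine_stouffer(
    p_window: Sequence[float], weights: Sequence[float]
) -> tuple[float, float]:
    """Weighted Stouffer combination of a window of p-values.

    ``Z = sum_i w_i PhiInv(1 - p_i) / sqrt(sum_i w_i^2)`` with ``PhiInv``
    the standard normal quantile function; the combined p-value is the
    upper tail ``P(N(0,1) > Z)``.  Invariant to positive rescaling of the
    weight vector.
    """
    ps = _clamp_pvalues(np.asarray(p_window, dtype=float))
    w = np.asarray(weights, dtype=float)
    if ps.size != w.size:
        raise ValueError("one weight is required per p-value")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    z = float(np.sum(w * stats.norm.isf(ps)) / np.sqrt(np.sum(w**2)))
    return z, float(_clip_p(stats.norm.sf(z)))


def combine_fisher(p_window: Sequence[float]) -> float:
    """Fisher combination: ``-2 sum ln p_i`` on ``2 * len`` df, upper tail."""
    ps = _clamp_pvalues(np.asarray(p_window, dtype=float))
    statistic = -2.0 * float(np.sum(np.log(ps)))
    return float(_clip_p(stats.chi2.sf(statistic, 2 * ps.size)))


# ---------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------


def neighborhood_rank(sites: Sequence[SiteScore], window: int = 2) -> list[SiteScore]:
    """Greedy non-redundant ranking of scored sites.

    Sites are visited by ascending combined p-value (on the log scale,
    ties broken by leftmost position).  A site is suppressed if an
    already-accepted site lies within ``window`` bases of it; accepted
    sites receive ranks 1..N.  The result is in visiting order, so
    accepted sites appear in rank order interleaved with their
    suppressed neighbors.
    """
    ordered = sorted(sites, key=lambda s: (s.log10_p_combined, s.ref_position))
    accepted: set[int] = set()
    next_rank = 1
    for site in ordered:
        p = site.ref_position
        if any((p + d) in accepted for d in range(-window, window + 1)):
            site.rank = None
            continue
        accepted.add(p)
        site.rank = next_rank
        next_rank += 1
    return ordered


def ranked_sites(sites: Sequence[SiteScore]) -> list[SiteScore]:
    """The accepted (non-suppressed) sites in rank order."""
    return sorted((s for s in sites if s.rank is not None), key=lambda s: s.rank)


# ---------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------


def _single_base_log_pvalues(
    sites: Sequence[PositionSignalGroups], test: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (D, log p) arrays; D is NaN for the rank/t tests."""
    ds = np.full(len(sites), np.nan)
    ps = np.empty(len(sites))
    for i, site in enumerate(sites):
        if test == "ks":
            ds[i], ps[i] = _ks_test_log(site.group1, site.group2)
        elif test == "u":
            ps[i] = _u_test_log(site.group1, site.group2)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ps[i] = _t_test_log(site.group1, site.group2)
    return ds, ps


def _combine_neighbors_log(
    positions: np.ndarray,
    log_ps: np.ndarray,
    combiner: str,
    k: int,
    weight_decay: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized windowed combination over the tested positions.

    Sites missing part of their +/-k window (sequence ends, filtered
    neighbors) combine over the available truncated window; on any full
    window the scalar :func:`combine_stouffer` / :func:`combine_fisher`
    give the same result up to their reporting clamp.
    """
    span = int(positions.max()) + 1 if positions.size else 0
    full = np.full(span, np.nan)
    full[positions] = np.minimum(log_ps, np.log(_P_EPS_HI))

    offsets = np.arange(-k, k + 1)
    neigh = np.full((offsets.size, positions.size), np.nan)
    for row, d in enumerate(offsets):
        shifted = positions + d
        ok = (shifted >= 0) & (shifted < span)
        neigh[row, ok] = full[shifted[ok]]
    present = ~np.isnan(neigh)

    if combiner == "stouffer":
        w = default_weights(offsets, decay=weight_decay)[:, None] * present
        quantiles = _norm_isf_from_log(np.where(present, neigh, np.log(0.5)))
        z = np.sum(w * quantiles, axis=0) / np.sqrt(np.sum(w**2, axis=0))
        lpc = stats.norm.logsf(z)
    elif combiner == "fisher":
        statistic = -2.0 * np.sum(np.where(present, neigh, 0.0), axis=0)
        df = 2 * present.sum(axis=0)
        z = np.full(positions.size, np.nan)
        lpc = _chi2_log_sf(statistic, df)
    else:
        raise ValueError(f"unknown combiner {combiner!r}")
    return z, np.minimum(lpc, 0.0)


def score_sites(
    sites: Sequence[PositionSignalGroups], config: DetectionConfig
) -> list[SiteScore]:
    """Test, combine and rank a list of pooled, coverage-filtered sites."""
    if not sites:
        return []
    positions = np.array([s.ref_position for s in sites], dtype=np.int64)
    ds, lps = _single_base_log_pvalues(sites, config.test)
    if config.combiner == "none":
        zs = np.full(len(sites), np.nan)
        lpcs = lps.copy()
    else:
        zs, lpcs = _combine_neighbors_log(
            positions, lps, config.combiner, config.k, config.weight_decay
        )
    scored = [
        SiteScore(
            ref_position=int(site.ref_position),
            ref_base=site.ref_base,
            m=site.m,
            n=site.n,
            D=None if np.isnan(ds[i]) else float(ds[i]),
            p_single=float(_clip_p(np.exp(max(lps[i], _LOG_P_LO)))),
            log10_p_single=float(lps[i] / _LN10),
            Z=None if np.isnan(zs[i]) else float(zs[i]),
            p_combined=float(_clip_p(np.exp(max(lpcs[i], _LOG_P_LO)))),
            log10_p_combined=float(lpcs[i] / _LN10),
        )
        for i, site in enumerate(sites)
    ]
    return neighborhood_rank(scored, window=config.rank_window)


def detect_modifications(
    reads_group1: Sequence[EventSequence],
    reads_group2: Sequence[EventSequence],
    reference: str,
    config: DetectionConfig | None = None,
) -> list[SiteScore]:
    """Full detection pipeline on two groups of corrected reads.

    Pools normalized signals per reference position, filters low-coverage
    positions, applies the configured per-position test, combines
    neighbor p-values and produces the neighborhood-pruned ranking.
    Deterministic given its inputs.
    """
    config = config or DetectionConfig()
    if config.normalize:
        reads_group1 = [r if r.normalized else r.normalize() for r in reads_group1]
        reads_group2 = [r if r.normalized else r.normalize() for r in reads_group2]
    pooled = pool_position_signals(reads_group1, reads_group2, reference)
    sites = filter_low_coverage(pooled, min_reads=config.min_reads)
    if not sites:
        logger.warning("no position passed the coverage filter")
        return []
    return score_sites(sites, config)
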