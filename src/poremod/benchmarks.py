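"""Replicated simulation studies comparing detection methods.

Drives the full loop: generate a scenario dataset, run the detection
pipeline under one or more method configurations (per-position test x
combiner), and collect percentile precision/recall curves across
replicates.  Pooling and per-position testing are shared between methods
that only differ in the combiner, so method comparisons run on exactly
the same data.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .evaluation import (
    DEFAULT_PERCENTILES,
    PRPoint,
    average_over_replicates,
    precision_recall_at_percentiles,
)
from .position_stats import (
    DetectionConfig,
    SiteScore,
    _combine_neighbors_log,
    _single_base_log_pvalues,
    _clip_p,
    _LOG_P_LO,
    neighborhood_rank,
)
from .signal_model import filter_low_coverage, pool_position_signals
from .simulator import ScenarioConfig, simulate_dataset

__all__ = ["Method", "scenario_benchmark", "mean_metric"]

_LN10 = np.log(10.0)

#: A detection method is a (single-base test, combiner) pair.
Method = tuple[str, str]


def _score_with(
    pooled_sites,
    positions: np.ndarray,
    ds: np.ndarray,
    lps: np.ndarray,
    combiner: str,
    k: int,
    weight_decay: float,
    rank_window: int,
) -> list[SiteScore]:
    if combiner == "none":
        zs = np.full(len(pooled_sites), np.nan)
        lpcs = lps
    else:
        zs, lpcs = _combine_neighbors_log(positions, lps, combiner, k, weight_decay)
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
        for i, site in enumerate(pooled_sites)
    ]
    return neighborhood_rank(scored, window=rank_window)


def scenario_benchmark(
    scenario: str,
    methods: Sequence[Method],
    n_replicates: int = 20,
    seed: int = 0,
    base_config: DetectionConfig | None = None,
    scenario_kwargs: dict | None = None,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    tolerance: int = 0,
) -> dict[Method, list[list[PRPoint]]]:
    """Run a scenario ``n_replicates`` times and evaluate each method.

    Every replicate draws a fresh reference, pore model, truth set and
    read groups (seeded reproducibly from ``seed``); all methods see the
    identical pooled signals of the replicate.  Returns, per method, the
    list of per-replicate precision/recall curves.
    """
    det = base_config or DetectionConfig()
    rng = np.random.default_rng(seed)
    results: dict[Method, list[list[PRPoint]]] = {m: [] for m in methods}
    tests = sorted({test for test, _ in methods})
    for _ in range(n_replicates):
        config = ScenarioConfig(
            scenario=scenario,
            seed=int(rng.integers(2**31)),
            **(scenario_kwargs or {}),
        )
        mod, ctrl, truth, reference, _ = simulate_dataset(config)
        if det.normalize:
            mod = [r.normalize() for r in mod]
            ctrl = [r.normalize() for r in ctrl]
        pooled = filter_low_coverage(
            pool_position_signals(mod, ctrl, reference), min_reads=det.min_reads
        )
        positions = np.array([s.ref_position for s in pooled], dtype=np.int64)
        per_test = {t: _single_base_log_pvalues(pooled, t) for t in tests}
        for test, combiner in methods:
            ds, lps = per_test[test]
            sites = _score_with(
                pooled, positions, ds, lps, combiner,
                det.k, det.weight_decay, det.rank_window,
            )
            results[(test, combiner)].append(
                precision_recall_at_percentiles(sites, truth, percentiles, tolerance)
            )
    return results


def mean_metric(
    curves: Sequence[Sequence[PRPoint]], percentile: float, metric: str
) -> float:
    """Replicate-averaged precision or recall at one percentile cut."""
    avg = average_over_replicates(curves)
    for point in avg:
        if point.percentile == percentile:
            return getattr(point, metric)
    raise KeyError(f"percentile {percentile} not in the evaluated grid")
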