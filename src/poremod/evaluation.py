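"""Ranked-site precision/recall at fixed percentile cuts.

A detector returns a ranked list of candidate positions.  Performance is
summarized by walking a grid of percentile cuts (fractions of the ranked
list), and computing at each cut the precision (correct predictions over
predictions made) and recall (correct predictions over the number of
truly modified positions).  Curves from replicate simulations are
averaged pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Sequence

import numpy as np

from .position_stats import SiteScore, ranked_sites

__all__ = [
    "PRPoint",
    "DEFAULT_PERCENTILES",
    "EXTENDED_PERCENTILES",
    "precision_recall_at_percentiles",
    "average_over_replicates",
]

#: Percentile cuts (percent of the ranked list) for simulation studies.
DEFAULT_PERCENTILES = (0.1, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0)

#: Extended grid for genome-scale data where true sites are plentiful.
EXTENDED_PERCENTILES = DEFAULT_PERCENTILES + (10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass(frozen=True)
class PRPoint:
    """Precision/recall at one percentile cut of the ranked list."""

    percentile: float
    n_predictions: float
    n_true_hits: float
    precision: float
    recall: float


def _match_predictions(
    predicted: Sequence[int], truth: set[int], tolerance: int
) -> np.ndarray:
    """Cumulative true-hit count along the prediction order.

    A prediction is correct if it lies within ``tolerance`` bases of a
    truth position not already claimed by an earlier prediction.
    """
    unmatched = set(truth)
    hits = np.zeros(len(predicted), dtype=np.int64)
    running = 0
    for i, pos in enumerate(predicted):
        for d in sorted(range(-tolerance, tolerance + 1), key=abs):
            if pos + d in unmatched:
                unmatched.discard(pos + d)
                running += 1
                break
        hits[i] = running
    return hits


def precision_recall_at_percentiles(
    ranked: Sequence[SiteScore],
    truth: set[int] | Iterable[int],
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
    tolerance: int = 0,
) -> list[PRPoint]:
    """Precision and recall at each percentile cut of a ranked site list.

    ``ranked`` may contain suppressed sites; only sites bearing a rank
    are considered, in rank order.  A cut at percentile ``q`` keeps the
    top ``ceil(q/100 * N)`` ranked sites.  Each truth position can be
    matched by at most one prediction, within ``tolerance`` bases.
    """
    truth = set(int(t) for t in truth)
    if not truth:
        raise ValueError("truth set is empty; recall is undefined")
    accepted = ranked_sites(ranked) if any(s.rank is not None for s in ranked) else list(ranked)
    if not accepted:
        raise ValueError("ranked site list is empty")
    order = [s.ref_position for s in accepted]
    cum_hits = _match_predictions(order, truth, tolerance)
    points: list[PRPoint] = []
    for q in percentiles:
        n_pred = min(max(ceil(q / 100.0 * len(order)), 1), len(order))
        hits = int(cum_hits[n_pred - 1])
        points.append(
            PRPoint(
                percentile=q,
                n_predictions=n_pred,
                n_true_hits=hits,
                precision=hits / n_pred,
                recall=hits / len(truth),
            )
        )
    return points


def average_over_replicates(per_dataset: Sequence[Sequence[PRPoint]]) -> list[PRPoint]:
    """Pointwise arithmetic mean of replicate precision/recall curves."""
    if not per_dataset:
        raise ValueError("no replicate curves to average")
    grids = [tuple(p.percentile for p in curve) for curve in per_dataset]
    if len(set(grids)) != 1:
        raise ValueError("replicate curves use different percentile grids")
    out: list[PRPoint] = []
    for i, q in enumerate(grids[0]):
        pts = [curve[i] for curve in per_dataset]
        out.append(
            PRPoint(
                percentile=q,
                n_predictions=float(np.mean([p.n_predictions for p in pts])),
                n_true_hits=float(np.mean([p.n_true_hits for p in pts])),
                precision=float(np.mean([p.precision for p in pts])),
                recall=float(np.mean([p.recall for p in pts])),
            )
        )
    return out
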