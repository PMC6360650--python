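"""Core data types for nanopore event-level signal data.

A basecalled nanopore read is represented as an ordered sequence of
*events*: contiguous runs of raw current measurements, each attributed to
one called base.  After alignment-guided error correction the events of a
read anchor consecutive positions of a known reference sequence, so the
normalized measurements of many reads can be pooled per reference
position and compared between a modified and an unmodified sample.

This module provides the containers (:class:`Event`,
:class:`EventSequence`, :class:`PositionSignalGroups`, :class:`PoreModel`),
per-read signal normalization, the pooling of signals onto reference
positions, and the minimum-coverage filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Event",
    "EventSequence",
    "PositionSignalGroups",
    "PoreModel",
    "DegenerateScaleError",
    "normalize_signals",
    "pool_position_signals",
    "filter_low_coverage",
    "SIGNAL_CLIP",
]

#: Normalized signals are clipped elementwise to this symmetric bound.
SIGNAL_CLIP = 5.0

BASES = "ACGT"


class DegenerateScaleError(ValueError):
    """Raised when a signal vector cannot be standardized (zero spread)."""


@dataclass
class Event:
    """One basecalled event: a run of raw signal values for one base.

    Parameters
    ----------
    start_index
        Offset of the first signal value within the read's flat signal
        series.
    base
        The called nucleotide, one of ``ACGT``.
    signals
        The ordered signal values of the event (raw or normalized).
    """

    start_index: int
    base: str
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.size == 0:
            raise ValueError("an event must contain at least one signal value")
        if self.base not in BASES:
            raise ValueError(f"invalid base {self.base!r}")

    @property
    def length(self) -> int:
        """Number of raw signal values in the event."""
        return int(self.signals.size)


class EventSequence:
    """An ordered event sequence for one read, stored in flat arrays.

    The canonical storage is a flat ``signals`` array plus a per-event
    ``lengths`` array; event ``i`` owns the slice
    ``signals[offsets[i]:offsets[i] + lengths[i]]``.  This keeps
    genome-scale simulations cheap while :attr:`events` still exposes the
    conventional list-of-:class:`Event` view.

    ``position_map`` records, for each consecutive aligned reference
    position starting at ``aligned_ref_start``, the index of the event
    anchored there.  ``None`` means the identity map (event ``i`` is at
    reference position ``aligned_ref_start + i``); after homopolymer
    correction several positions may map to one shared event.
    """

    __slots__ = (
        "read_id",
        "strand",
        "aligned_ref_start",
        "bases",
        "signals",
        "lengths",
        "position_map",
        "normalized",
        "_offsets",
    )

    def __init__(
        self,
        read_id: str,
        strand: str,
        aligned_ref_start: int,
        bases: str,
        signals: np.ndarray,
        lengths: np.ndarray,
        position_map: np.ndarray | None = None,
        normalized: bool = False,
    ) -> None:
        if strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        self.read_id = read_id
        self.strand = strand
        self.aligned_ref_start = int(aligned_ref_start)
        self.bases = bases
        self.signals = np.asarray(signals, dtype=float)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        if len(bases) != self.lengths.size:
            raise ValueError("one called base is required per event")
        if np.any(self.lengths < 1):
            raise ValueError("every event must own at least one signal")
        if int(self.lengths.sum()) != self.signals.size:
            raise ValueError("event lengths do not partition the signal series")
        self.position_map = (
            None if position_map is None else np.asarray(position_map, dtype=np.int64)
        )
        self.normalized = normalized
        self._offsets: np.ndarray | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_events(
        cls,
        read_id: str,
        strand: str,
        aligned_ref_start: int,
        events: Sequence[Event],
        position_map: np.ndarray | None = None,
        normalized: bool = False,
    ) -> "EventSequence":
        if not events:
            raise ValueError("a read needs at least one event")
        signals = np.concatenate([e.signals for e in events])
        lengths = np.array([e.length for e in events], dtype=np.int64)
        bases = "".join(e.base for e in events)
        return cls(
            read_id,
            strand,
            aligned_ref_start,
            bases,
            signals,
            lengths,
            position_map=position_map,
            normalized=normalized,
        )

    # -- views ---------------------------------------------------------

    @property
    def n_events(self) -> int:
        return int(self.lengths.size)

    @property
    def offsets(self) -> np.ndarray:
        """Start offset of each event in the flat signal series."""
        if self._offsets is None:
            off = np.zeros(self.n_events, dtype=np.int64)
            np.cumsum(self.lengths[:-1], out=off[1:])
            self._offsets = off
        return self._offsets

    @property
    def events(self) -> list[Event]:
        """The conventional list-of-events view (built on demand)."""
        off = self.offsets
        return [
            Event(int(off[i]), self.bases[i], self.signals[off[i] : off[i] + self.lengths[i]])
            for i in range(self.n_events)
        ]

    @property
    def n_positions(self) -> int:
        """Number of consecutive aligned reference positions."""
        if self.position_map is None:
            return self.n_events
        return int(self.position_map.size)

    def event_index_at(self, ref_position: int) -> int:
        """Index of the event anchored at an aligned reference position."""
        offset = ref_position - self.aligned_ref_start
        if offset < 0 or offset >= self.n_positions:
            raise IndexError(
                f"reference position {ref_position} outside aligned span of "
                f"read {self.read_id}"
            )
        if self.position_map is None:
            return offset
        return int(self.position_map[offset])

    def signals_at(self, ref_position: int) -> np.ndarray:
        """Signal values anchored at one aligned reference position."""
        i = self.event_index_at(ref_position)
        off = self.offsets
        return self.signals[off[i] : off[i] + self.lengths[i]]

    def position_event_indices(self) -> np.ndarray:
        """Per aligned-position event index (identity map materialized)."""
        if self.position_map is None:
            return np.arange(self.n_events, dtype=np.int64)
        return self.position_map

    # -- normalization -------------------------------------------------

    def normalize(self, scale: str = "mean_abs") -> "EventSequence":
        """Return a copy with the read's signals normalized per read.

        One median and one scale are computed over the whole read, not
        per event, so relative level differences between positions are
        preserved.
        """
        return EventSequence(
            self.read_id,
            self.strand,
            self.aligned_ref_start,
            self.bases,
            normalize_signals(self.signals, scale=scale),
            self.lengths,
            position_map=self.position_map,
            normalized=True,
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"EventSequence({self.read_id!r}, strand={self.strand}, "
            f"start={self.aligned_ref_start}, events={self.n_events}, "
            f"signals={self.signals.size}, normalized={self.normalized})"
        )


@dataclass
class PositionSignalGroups:
    """Two pooled signal groups for one reference position.

    ``group1`` holds the normalized signals of the (putatively) modified
    sample at this position, ``group2`` those of the matched unmodified
    control.  ``reads1``/``reads2`` count the distinct reads contributing
    to each group, which is what the coverage filter operates on.
    """

    ref_position: int
    ref_base: str
    group1: np.ndarray
    group2: np.ndarray
    reads1: int = 0
    reads2: int = 0

    @property
    def m(self) -> int:
        """Number of pooled signal values in the modified group."""
        return int(np.size(self.group1))

    @property
    def n(self) -> int:
        """Number of pooled signal values in the control group."""
        return int(np.size(self.group2))


class PoreModel:
    """Expected signal mean and spread per k-mer.

    Maps every k-mer to the mean ``E_k`` and standard deviation ``D_k``
    of the current level observed while that k-mer dwells in the pore.
    """

    def __init__(self, k: int, table: dict[str, tuple[float, float]]) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        if len(table) != 4**k:
            raise ValueError(
                f"pore model must cover all {4 ** k} {k}-mers, got {len(table)}"
            )
        for kmer, (_, sd) in table.items():
            if len(kmer) != k:
                raise ValueError(f"bad k-mer {kmer!r} for k={k}")
            if sd <= 0:
                raise ValueError(f"non-positive sd for k-mer {kmer!r}")
        self.k = k
        self.table = table

    def __getitem__(self, kmer: str) -> tuple[float, float]:
        return self.table[kmer]

    def __len__(self) -> int:
        return len(self.table)

    def means_for(self, sequence: str) -> np.ndarray:
        """Per-position E_k for the k-mers centered on each position.

        Positions too close to either end (no full k-mer context) get NaN.
        """
        return self._lookup(sequence, 0)

    def sds_for(self, sequence: str) -> np.ndarray:
        """Per-position D_k, NaN where no full k-mer context exists."""
        return self._lookup(sequence, 1)

    def _lookup(self, sequence: str, which: int) -> np.ndarray:
        half = self.k // 2
        out = np.full(len(sequence), np.nan)
        for i in range(half, len(sequence) - (self.k - half) + 1):
            kmer = sequence[i - half : i - half + self.k]
            out[i] = self.table[kmer][which]
        return out


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------


def normalize_signals(raw: np.ndarray, scale: str = "mean_abs") -> np.ndarray:
    """Median-center and scale a signal vector, clipping to [-5, 5].

    The vector is shifted by its median and divided by the averaged
    absolute difference from the median (``scale="mean_abs"``, the
    default) or by the median absolute deviation (``scale="median_abs"``).
    The standardized values are then clipped elementwise to
    ``[-SIGNAL_CLIP, SIGNAL_CLIP]``.

    Raises
    ------
    DegenerateScaleError
        If the vector has fewer than two values or zero spread.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise DegenerateScaleError("need at least two signal values to normalize")
    med = np.median(raw)
    dev = np.abs(raw - med)
    if scale == "mean_abs":
        denom = float(np.mean(dev))
    elif scale == "median_abs":
        denom = float(np.median(dev))
    else:
        raise ValueError(f"unknown scale dialect {scale!r}")
    if denom == 0.0:
        raise DegenerateScaleError("constant signal vector cannot be standardized")
    return np.clip((raw - med) / denom, -SIGNAL_CLIP, SIGNAL_CLIP)


def _group_by_position(
    reads: Iterable[EventSequence], ref_length: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Pool read signals per reference position.

    Returns one array of pooled signals per position plus the per-position
    distinct-read counts.  A shared (homopolymer) event contributes its
    full signal vector to every position it annotates.  Positions whose
    map entry is negative (uncorrectable regions) contribute nothing.
    """
    pos_chunks: list[np.ndarray] = []
    sig_chunks: list[np.ndarray] = []
    read_cov = np.zeros(ref_length, dtype=np.int64)
    for read in reads:
        start = read.aligned_ref_start
        n_pos = read.n_positions
        if start < 0 or start + n_pos > ref_length:
            raise IndexError(
                f"read {read.read_id} anchored at [{start}, {start + n_pos}) "
                f"outside reference of length {ref_length}"
            )
        positions = start + np.arange(n_pos, dtype=np.int64)
        off = read.offsets
        if read.position_map is None:
            pos_chunks.append(np.repeat(positions, read.lengths))
            sig_chunks.append(read.signals)
            read_cov[start : start + n_pos] += 1
        else:
            ev_idx = read.position_map
            valid = ev_idx >= 0
            kept = ev_idx[valid]
            pos_chunks.append(np.repeat(positions[valid], read.lengths[kept]))
            take = np.concatenate(
                [np.arange(off[i], off[i] + read.lengths[i]) for i in kept]
            ) if kept.size else np.empty(0, dtype=np.int64)
            sig_chunks.append(read.signals[take])
            read_cov[positions[valid]] += 1

    groups: list[np.ndarray] = [np.empty(0)] * ref_length
    if pos_chunks:
        pos_all = np.concatenate(pos_chunks)
        sig_all = np.concatenate(sig_chunks)
        order = np.argsort(pos_all, kind="stable")
        pos_all = pos_all[order]
        sig_all = sig_all[order]
        counts = np.bincount(pos_all, minlength=ref_length)
        bounds = np.concatenate([[0], np.cumsum(counts)])
        for p in range(ref_length):
            if counts[p]:
                groups[p] = sig_all[bounds[p] : bounds[p + 1]]
    return groups, read_cov


def pool_position_signals(
    reads_group1: Sequence[EventSequence],
    reads_group2: Sequence[EventSequence],
    reference: str,
) -> list[PositionSignalGroups]:
    """Assign every read's per-position signals to reference positions.

    Each read contributes all signal values of the event(s) anchored at a
    position.  Every reference position yields one
    :class:`PositionSignalGroups`; positions covered by no read in a group
    get an empty vector there.
    """
    ref_length = len(reference)
    g1, cov1 = _group_by_position(reads_group1, ref_length)
    g2, cov2 = _group_by_position(reads_group2, ref_length)
    return [
        PositionSignalGroups(
            ref_position=p,
            ref_base=reference[p],
            group1=g1[p],
            group2=g2[p],
            reads1=int(cov1[p]),
            reads2=int(cov2[p]),
        )
        for p in range(ref_length)
    ]


def filter_low_coverage(
    sites: Sequence[PositionSignalGroups], min_reads: int = 5
) -> list[PositionSignalGroups]:
    """Drop positions with fewer than ``min_reads`` reads in either group.

    Coverage is counted as distinct contributing reads per group, not raw
    signal values.  Order is preserved; the operation is idempotent.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return [s for s in sites if s.reads1 >= min_reads and s.reads2 >= min_reads]
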