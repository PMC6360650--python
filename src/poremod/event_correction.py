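"""Alignment-guided correction of basecalling indel errors.

Basecalled nanopore reads carry frequent insertion/deletion errors.  When
the true sequence is known, the alignment of a read against it exposes
those errors, and the read's events can be repaired so that every aligned
reference position owns exactly one event:

* an *insertion* means two adjacent events probably came from the same
  k-mer, so the inserted event is merged with a neighbor;
* a *deletion* means the neighboring events hide one extra k-mer, so the
  closest neighbor events are pooled and re-segmented into one additional
  event;
* adjacent indels are first merged into one pooled region and then
  re-segmented together;
* the neighbor group grows automatically until every re-segmented event
  receives enough signal values;
* within a single-nucleotide repeat of length ``L > 5`` the middle
  ``L - 4`` positions share one event, because segmentation cannot
  resolve individual bases inside a long homopolymer.

Signal values are never invented or discarded by a correction step (an
uncorrectable region, where the whole read cannot supply enough signals,
is dropped from annotation instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signal_model import Event, EventSequence

__all__ = [
    "AlignmentOp",
    "HomopolymerRun",
    "UncorrectableRegionError",
    "ops_from_cigartuples",
    "find_homopolymer_runs",
    "resegment",
    "correct_insertion",
    "correct_deletion",
    "apply_homopolymer_rule",
    "correct_read",
    "DEFAULT_MIN_SIGNALS_PER_EVENT",
]

logger = logging.getLogger(__name__)

#: Minimum signal values each re-segmented event must receive.
DEFAULT_MIN_SIGNALS_PER_EVENT = 3

# CIGAR operation codes (pysam numeric convention)
_CIGAR_MATCH = {0, 7, 8}  # M, =, X
_CIGAR_INS = 1
_CIGAR_DEL = 2
_CIGAR_SOFT = 4
_CIGAR_HARD = 5
_CIGAR_SKIP = 3


class UncorrectableRegionError(ValueError):
    """The read cannot supply enough signals to re-segment a region."""


@dataclass
class AlignmentOp:
    """One aligned segment of a read: a match run, insertion or deletion.

    ``length`` counts events (= called bases) for match/insertion ops and
    reference positions for match/deletion ops.  ``read_start`` is the
    index of the first event involved, ``ref_start`` the first reference
    position (both meaningless for the op kind that does not consume that
    coordinate, but kept consistent for bookkeeping).
    """

    kind: str  # "match" | "insertion" | "deletion"
    length: int
    read_start: int
    ref_start: int

    def __post_init__(self) -> None:
        if self.kind not in ("match", "insertion", "deletion"):
            raise ValueError(f"unknown alignment op kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("alignment op length must be >= 1")


@dataclass
class HomopolymerRun:
    """A single-nucleotide repeat in the reference."""

    ref_start: int
    length: int
    base: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("run length must be >= 1")


def ops_from_cigartuples(
    cigartuples: Sequence[tuple[int, int]], ref_start: int
) -> list[AlignmentOp]:
    """Convert pysam-style CIGAR tuples into :class:`AlignmentOp` records.

    Soft/hard clips are consumed (the clipped events are excluded from
    annotation) and reference skips are rejected.  ``read_start`` indices
    refer to the read's event list *including* soft-clipped events, which
    matches how a basecalled read stores one event per called base.
    """
    ops: list[AlignmentOp] = []
    read_i = 0
    ref_i = ref_start
    for code, length in cigartuples:
        if code in _CIGAR_MATCH:
            ops.append(AlignmentOp("match", length, read_i, ref_i))
            read_i += length
            ref_i += length
        elif code == _CIGAR_INS:
            ops.append(AlignmentOp("insertion", length, read_i, ref_i))
            read_i += length
        elif code == _CIGAR_DEL:
            ops.append(AlignmentOp("deletion", length, read_i, ref_i))
            ref_i += length
        elif code == _CIGAR_SOFT:
            read_i += length
        elif code == _CIGAR_HARD:
            pass
        elif code == _CIGAR_SKIP:
            raise ValueError("reference skips (N) are not supported")
        else:
            raise ValueError(f"unsupported CIGAR op code {code}")
    return ops


def find_homopolymer_runs(sequence: str, min_length: int = 2) -> list[HomopolymerRun]:
    """All maximal single-nucleotide runs of at least ``min_length``."""
    runs: list[HomopolymerRun] = []
    i = 0
    n = len(sequence)
    while i < n:
        j = i + 1
        while j < n and sequence[j] == sequence[i]:
            j += 1
        if j - i >= min_length:
            runs.append(HomopolymerRun(i, j - i, sequence[i]))
        i = j
    return runs


def _split_sizes(total: int, n_events: int) -> list[int]:
    """Contiguous equal split of ``total`` items, remainder to the left."""
    q, r = divmod(total, n_events)
    return [q + 1] * r + [q] * (n_events - r)


def resegment(
    signals: np.ndarray, n_events: int, bases: str | None = None, start_index: int = 0
) -> list[Event]:
    """Split a pooled signal stretch into ``n_events`` contiguous events.

    The split is equal-length with the remainder assigned left-to-right,
    preserving signal order.  ``bases`` optionally labels the new events
    (default ``A`` placeholders, replaced by the caller from the
    reference).
    """
    signals = np.asarray(signals, dtype=float)
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if signals.size < n_events:
        raise UncorrectableRegionError(
            f"cannot split {signals.size} signals into {n_events} non-empty events"
        )
    if bases is None:
        bases = "A" * n_events
    elif len(bases) != n_events:
        raise ValueError("need one base per output event")
    sizes = _split_sizes(signals.size, n_events)
    events: list[Event] = []
    off = 0
    for size, base in zip(sizes, bases):
        events.append(Event(start_index + off, base, signals[off : off + size]))
        off += size
    return events


def correct_insertion(events: Sequence[Event], ins_index: int) -> list[Event]:
    """Merge an inserted event with one of its flanking events.

    The flank with fewer signal values is chosen (tie: upstream); at a
    read end the single available flank is used.  The output has one
    fewer event and conserves every signal value in order.
    """
    events = list(events)
    if not 0 <= ins_index < len(events):
        raise IndexError("insertion index out of range")
    if len(events) < 2:
        raise ValueError("an insertion needs at least one flanking event")
    up = ins_index - 1 if ins_index > 0 else None
    down = ins_index + 1 if ins_index < len(events) - 1 else None
    if up is None:
        target = down
    elif down is None:
        target = up
    else:
        target = up if events[up].length <= events[down].length else down
    ins = events[ins_index]
    flank = events[target]
    if target < ins_index:
        merged_signals = np.concatenate([flank.signals, ins.signals])
        merged = Event(flank.start_index, flank.base, merged_signals)
        return events[:target] + [merged] + events[ins_index + 1 :]
    merged_signals = np.concatenate([ins.signals, flank.signals])
    merged = Event(ins.start_index, flank.base, merged_signals)
    return events[:ins_index] + [merged] + events[target + 1 :]


def correct_deletion(
    events: Sequence[Event],
    del_index: int,
    n_deletions: int = 1,
    min_signals: int = DEFAULT_MIN_SIGNALS_PER_EVENT,
    bases: str | None = None,
) -> list[Event]:
    """Re-segment neighbor events so the deletion gains its own event.

    ``del_index`` locates the deletion between ``events[del_index - 1]``
    and ``events[del_index]``.  Starting from one upstream and one
    downstream neighbor, the group widens symmetrically one event at a
    time until each output event can receive at least ``min_signals``
    values; the output has ``n_deletions`` more events than were grouped.
    """
    events = list(events)
    if not 0 <= del_index <= len(events):
        raise IndexError("deletion index out of range")
    lo = max(del_index - 1, 0)
    hi = min(del_index, len(events) - 1)
    prefer_left = True
    while True:
        pooled = sum(e.length for e in events[lo : hi + 1])
        n_out = (hi - lo + 1) + n_deletions
        if pooled >= min_signals * n_out:
            break
        grew = False
        for side in (("L", "R") if prefer_left else ("R", "L")):
            if side == "L" and lo > 0:
                lo -= 1
                grew = True
                break
            if side == "R" and hi < len(events) - 1:
                hi += 1
                grew = True
                break
        prefer_left = not prefer_left
        if not grew:
            raise UncorrectableRegionError(
                "read exhausted before every re-segmented event could receive "
                f"{min_signals} signals"
            )
    pooled_signals = np.concatenate([e.signals for e in events[lo : hi + 1]])
    new = resegment(pooled_signals, n_out, bases=bases, start_index=events[lo].start_index)
    return events[:lo] + new + events[hi + 1 :]


def apply_homopolymer_rule(events: Sequence[Event], run: HomopolymerRun) -> list[Event]:
    """Share one event among the middle positions of a long homopolymer.

    ``events`` must be position-anchored: element ``i`` annotates the
    ``i``-th reference position of the span, and ``run.ref_start`` indexes
    into the list.
    For a run of length ``L > 5`` the events of the middle ``L - 4``
    positions are merged and the *same* merged event object is placed at
    each of those positions; the outer two positions on each side keep
    their events.  Runs of length five or shorter are returned unchanged.
    """
    events = list(events)
    L = run.length
    if L <= 5:
        return events
    s = run.ref_start
    if s < 0 or s + L > len(events):
        raise IndexError("homopolymer run outside the annotated span")
    mid_lo, mid_hi = s + 2, s + L - 2  # half-open: the middle L - 4 positions
    merged_signals = np.concatenate([e.signals for e in events[mid_lo:mid_hi]])
    shared = Event(events[mid_lo].start_index, run.base, merged_signals)
    return events[:mid_lo] + [shared] * (mid_hi - mid_lo) + events[mid_hi:]


# ---------------------------------------------------------------------
# whole-read correction
# ---------------------------------------------------------------------


def _indel_clusters(
    pos_event: list[int | None],
    inserted: dict[int, list[int]],
    span: int,
) -> list[list[int]]:
    """Maximal runs of reference offsets that need re-segmentation.

    An offset is marked if it is a deletion or touches an insertion; each
    marked run is expanded by one matched flank on each side (the
    one-upstream/one-downstream neighbor grouping), and overlapping
    groups coalesce.
    """
    bad = np.zeros(span, dtype=bool)
    for t in range(span):
        if pos_event[t] is None:
            bad[t] = True
    for t in inserted:
        if t > 0:
            bad[t - 1] = True
        if t < span:
            bad[t] = True
    marked = bad.copy()
    t = 0
    while t < span:
        if bad[t]:
            u = t
            while u + 1 < span and bad[u + 1]:
                u += 1
            if t > 0:
                marked[t - 1] = True
            if u + 1 < span:
                marked[u + 1] = True
            t = u + 1
        else:
            t += 1
    clusters: list[list[int]] = []
    t = 0
    while t < span:
        if marked[t]:
            u = t
            while u + 1 < span and marked[u + 1]:
                u += 1
            clusters.append([t, u])
            t = u + 1
        else:
            t += 1
    return clusters


def correct_read(
    read: EventSequence,
    alignment: Sequence[AlignmentOp],
    reference: str,
    min_signals: int = DEFAULT_MIN_SIGNALS_PER_EVENT,
) -> EventSequence:
    """Repair a read's events so each aligned position owns one event.

    Matched events outside indel neighborhoods are kept as they are.
    Around every indel, the inserted events plus the grouped flanking
    events are pooled and re-segmented into one event per grouped
    reference position, growing the group until each new event receives
    ``min_signals`` values.  Afterwards the homopolymer sharing rule is
    applied to reference runs longer than five bases.  Total signal count
    over annotated positions is conserved; called bases over the
    corrected span equal the reference bases.
    """
    if not alignment:
        raise ValueError("empty alignment")
    ref_start = min(op.ref_start for op in alignment if op.kind != "insertion")
    ref_end = max(
        op.ref_start + op.length for op in alignment if op.kind != "insertion"
    )
    span = ref_end - ref_start
    if ref_start < 0 or ref_end > len(reference):
        raise IndexError("alignment outside reference bounds")

    events = read.events
    pos_event: list[int | None] = [None] * span
    inserted: dict[int, list[int]] = {}
    for op in alignment:
        if op.kind == "match":
            for j in range(op.length):
                pos_event[op.ref_start - ref_start + j] = op.read_start + j
        elif op.kind == "insertion":
            inserted.setdefault(op.ref_start - ref_start, []).extend(
                range(op.read_start, op.read_start + op.length)
            )
        # deletions leave pos_event entries as None

    clusters = _indel_clusters(pos_event, inserted, span)
    in_cluster = np.full(span, -1, dtype=np.int64)
    for ci, (lo, hi) in enumerate(clusters):
        in_cluster[lo : hi + 1] = ci

    # Resolve each cluster: pool its events (in read order) and re-segment
    # into one event per grouped reference offset, widening as needed.
    out_events: list[list | None] = [None] * span  # per offset: [signals, base]
    dropped: set[int] = set()
    ci = 0
    while ci < len(clusters):
        lo, hi = clusters[ci]
        prefer_left = True
        while True:
            ev_ids = sorted(
                {pos_event[t] for t in range(lo, hi + 1) if pos_event[t] is not None}
                | {
                    i
                    for t, ids in inserted.items()
                    for i in ids
                    if lo <= min(t, span - 1) and max(t - 1, 0) <= hi
                }
            )
            pooled = sum(events[i].length for i in ev_ids)
            n_out = hi - lo + 1
            if pooled >= min_signals * n_out:
                break
            # widen symmetrically one matched offset at a time
            grew = False
            for side in (("L", "R") if prefer_left else ("R", "L")):
                if side == "L" and lo > 0:
                    lo -= 1
                    grew = True
                    break
                if side == "R" and hi < span - 1:
                    hi += 1
                    grew = True
                    break
            prefer_left = not prefer_left
            if grew:
                # widening may run into the next cluster: absorb it
                for cj in range(len(clusters)):
                    if cj != ci and clusters[cj][0] <= hi and clusters[cj][1] >= lo:
                        lo = min(lo, clusters[cj][0])
                        hi = max(hi, clusters[cj][1])
                        clusters[cj] = [span + 1, span]  # emptied
            else:
                logger.warning(
                    "read %s: offsets [%d, %d] uncorrectable (%d signals for %d "
                    "events); dropped from annotation",
                    read.read_id,
                    ref_start + lo,
                    ref_start + hi,
                    pooled,
                    n_out,
                )
                dropped.update(range(lo, hi + 1))
                break
        clusters[ci] = [lo, hi]
        if not dropped.intersection(range(lo, hi + 1)):
            pooled_signals = (
                np.concatenate([events[i].signals for i in ev_ids])
                if ev_ids
                else np.empty(0)
            )
            ref_bases = reference[ref_start + lo : ref_start + hi + 1]
            for offset, ev in zip(
                range(lo, hi + 1), resegment(pooled_signals, n_out, bases=ref_bases)
            ):
                out_events[offset] = [ev.signals, ev.base]
        ci += 1

    covered = {t for lo, hi in clusters if lo <= hi for t in range(lo, hi + 1)}
    for t in range(span):
        if t in covered or t in dropped:
            continue
        i = pos_event[t]
        assert i is not None  # matched offsets outside clusters keep their event
        out_events[t] = [events[i].signals, reference[ref_start + t]]

    # Homopolymer sharing: reference runs with L > 5 fully inside the span.
    shared_group = np.arange(span, dtype=np.int64)  # representative offset
    for run in find_homopolymer_runs(reference[ref_start:ref_end], min_length=6):
        offs = range(run.ref_start + 2, run.ref_start + run.length - 2)
        if any(t in dropped for t in offs):
            continue
        rep = run.ref_start + 2
        merged = np.concatenate([out_events[t][0] for t in offs])
        out_events[rep] = [merged, run.base]
        for t in offs:
            shared_group[t] = rep

    # Assemble flat arrays + position map (shared events appear once).
    sig_chunks: list[np.ndarray] = []
    lengths: list[int] = []
    bases: list[str] = []
    position_map = np.full(span, -1, dtype=np.int64)
    rep_to_index: dict[int, int] = {}
    for t in range(span):
        if t in dropped:
            continue
        rep = int(shared_group[t])
        if rep in rep_to_index:
            position_map[t] = rep_to_index[rep]
            continue
        signals, base = out_events[rep]
        rep_to_index[rep] = len(lengths)
        position_map[t] = rep_to_index[rep]
        sig_chunks.append(signals)
        lengths.append(len(signals))
        bases.append(base)

    if not lengths:
        raise UncorrectableRegionError(f"read {read.read_id}: nothing correctable")
    return EventSequence(
        read.read_id,
        read.strand,
        ref_start,
        "".join(bases),
        np.concatenate(sig_chunks),
        np.asarray(lengths, dtype=np.int64),
        position_map=position_map,
        normalized=read.normalized,
    )
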