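"""Readers and writers for the pipeline's plain-text interchange formats.

The canonical interchange format for signal-annotated reads is a simple
event-table TSV (one row per event) so that whole pipelines can run from
text fixtures; alignments come from SAM via pysam, references from FASTA
via Biopython, and results go to TSV/BED.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .event_correction import AlignmentOp, ops_from_cigartuples
from .evaluation import PRPoint
from .position_stats import SiteScore
from .signal_model import EventSequence, PoreModel

__all__ = [
    "write_event_tsv",
    "read_event_tsv",
    "write_pore_model_tsv",
    "read_pore_model_tsv",
    "write_fasta",
    "read_fasta",
    "write_sam",
    "read_sam_alignments",
    "write_sites_tsv",
    "write_sites_bed",
    "write_truth_bed",
    "read_truth_bed",
    "write_pr_table",
]

_EVENT_COLUMNS = ("read_id", "strand", "ref_position", "base", "signals")


# -- event tables ------------------------------------------------------


def write_event_tsv(reads: Iterable[EventSequence], path: str | Path) -> None:
    """Write reads as an event-table TSV (one row per event, lossless).

    ``ref_position`` is the 0-based anchored position of the event, a
    ``start-end`` inclusive range for a shared homopolymer event, or
    ``.`` for an event of an uncorrected (unanchored) read.  Signal
    values are comma-separated shortest round-trip decimals.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_EVENT_COLUMNS)
        for read in reads:
            off = read.offsets
            if read.position_map is None:
                anchored = read.aligned_ref_start >= 0
                positions: list[str] = [
                    str(read.aligned_ref_start + i) if anchored else "."
                    for i in range(read.n_events)
                ]
            else:
                spans: dict[int, list[int]] = {}
                for t, ev in enumerate(read.position_map):
                    if ev >= 0:
                        spans.setdefault(int(ev), []).append(read.aligned_ref_start + t)
                positions = []
                for i in range(read.n_events):
                    ps = spans.get(i)
                    if ps is None:
                        positions.append(".")
                    elif len(ps) == 1:
                        positions.append(str(ps[0]))
                    else:
                        positions.append(f"{ps[0]}-{ps[-1]}")
            for i in range(read.n_events):
                sig = read.signals[off[i] : off[i] + read.lengths[i]]
                writer.writerow(
                    [
                        read.read_id,
                        read.strand,
                        positions[i],
                        read.bases[i],
                        ",".join(repr(float(v)) for v in sig),
                    ]
                )


def read_event_tsv(path: str | Path, normalized: bool = False) -> list[EventSequence]:
    """Read an event-table TSV back into :class:`EventSequence` objects."""
    rows_by_read: dict[str, list[tuple[str, str, str]]] = {}
    strands: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != _EVENT_COLUMNS:
            raise ValueError(f"{path}: unexpected event-table header {header}")
        for ln, row in enumerate(reader, start=2):
            if len(row) != 5:
                raise ValueError(f"{path}:{ln}: expected 5 columns, got {len(row)}")
            read_id, strand, pos, base, signals = row
            rows_by_read.setdefault(read_id, []).append((pos, base, signals))
            strands[read_id] = strand

    reads: list[EventSequence] = []
    for read_id, rows in rows_by_read.items():
        bases = "".join(base for _, base, _ in rows)
        chunks = [
            np.array([float(v) for v in sig.split(",")]) for _, _, sig in rows
        ]
        lengths = np.array([c.size for c in chunks], dtype=np.int64)
        signals = np.concatenate(chunks)
        pos_fields = [p for p, _, _ in rows]
        if all(p == "." for p in pos_fields):
            reads.append(
                EventSequence(
                    read_id, strands[read_id], 0, bases, signals, lengths,
                    position_map=None, normalized=normalized,
                )
            )
            continue
        event_spans: list[tuple[int, int]] = []
        for p in pos_fields:
            if p == ".":
                raise ValueError(f"mixed anchored/unanchored events in read {read_id}")
            lo, _, hi = p.partition("-")
            event_spans.append((int(lo), int(hi or lo)))
        start = min(lo for lo, _ in event_spans)
        end = max(hi for _, hi in event_spans) + 1
        position_map = np.full(end - start, -1, dtype=np.int64)
        identity = all(hi == lo for lo, hi in event_spans) and len(event_spans) == end - start
        for i, (lo, hi) in enumerate(event_spans):
            position_map[lo - start : hi - start + 1] = i
        reads.append(
            EventSequence(
                read_id,
                strands[read_id],
                start,
                bases,
                signals,
                lengths,
                position_map=None if identity and np.all(position_map >= 0) else position_map,
                normalized=normalized,
            )
        )
    return reads


# -- pore model --------------------------------------------------------


def write_pore_model_tsv(model: PoreModel, path: str | Path) -> None:
    """Write a k-mer table TSV with columns kmer, mean, sd."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["kmer", "mean", "sd"])
        for kmer in sorted(model.table):
            mean, sd = model.table[kmer]
            writer.writerow([kmer, repr(mean), repr(sd)])


def read_pore_model_tsv(path: str | Path) -> PoreModel:
    table: dict[str, tuple[float, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header
        for kmer, mean, sd in reader:
            table[kmer] = (float(mean), float(sd))
    if not table:
        raise ValueError(f"{path}: empty pore model")
    return PoreModel(len(next(iter(table))), table)


# -- FASTA -------------------------------------------------------------


def write_fasta(sequence: str, path: str | Path, name: str = "ref") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read the first record of a FASTA file as ``(name, sequence)``."""
    for record in SeqIO.parse(str(path), "fasta"):
        return record.id, str(record.seq).upper()
    raise ValueError(f"{path}: no FASTA records")


# -- SAM ---------------------------------------------------------------

_OP_TO_CIGAR = {"match": 0, "insertion": 1, "deletion": 2}


def write_sam(
    alignments: Sequence[tuple[EventSequence, Sequence[AlignmentOp]]],
    path: str | Path,
    ref_name: str,
    ref_length: int,
) -> None:
    """Write read alignments as plain-text SAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref_name, "LN": ref_length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read, ops in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.read_id
            seg.query_sequence = read.bases
            seg.flag = 16 if read.strand == "-" else 0
            seg.reference_id = 0
            seg.reference_start = min(
                op.ref_start for op in ops if op.kind != "insertion"
            )
            seg.mapping_quality = 60
            seg.cigartuples = [(_OP_TO_CIGAR[op.kind], op.length) for op in ops]
            out.write(seg)


def read_sam_alignments(
    path: str | Path, min_mapq: int = 0
) -> dict[str, tuple[str, list[AlignmentOp]]]:
    """Read primary alignments from SAM as ``read_id -> (strand, ops)``.

    Secondary and supplementary records are ignored, as are unmapped
    reads and reads below ``min_mapq``.
    """
    out: dict[str, tuple[str, list[AlignmentOp]]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            strand = "-" if aln.is_reverse else "+"
            ops = ops_from_cigartuples(aln.cigartuples, aln.reference_start)
            out[aln.query_name] = (strand, ops)
    return out


# -- results -----------------------------------------------------------

_SITE_COLUMNS = (
    "chrom",
    "start",
    "end",
    "ref_base",
    "m",
    "n",
    "D",
    "p_single",
    "log10_p_single",
    "Z",
    "p_combined",
    "log10_p_combined",
    "rank",
)


def write_sites_tsv(
    sites: Sequence[SiteScore], path: str | Path, chrom: str = "ref"
) -> None:
    """Ranked-site table; intervals are 0-based half-open.

    Suppressed (redundant-neighbor) sites carry an empty rank field.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SITE_COLUMNS)
        for s in sites:
            writer.writerow(
                [
                    chrom,
                    s.ref_position,
                    s.ref_position + 1,
                    s.ref_base,
                    s.m,
                    s.n,
                    "" if s.D is None else f"{s.D:.6g}",
                    f"{s.p_single:.6g}",
                    f"{s.log10_p_single:.6g}",
                    "" if s.Z is None else f"{s.Z:.6g}",
                    f"{s.p_combined:.6g}",
                    f"{s.log10_p_combined:.6g}",
                    "" if s.rank is None else s.rank,
                ]
            )


def write_sites_bed(
    sites: Sequence[SiteScore], path: str | Path, chrom: str = "ref"
) -> None:
    """Accepted sites as sorted BED6 (name = rank, score from p_combined)."""
    accepted = sorted(
        (s for s in sites if s.rank is not None), key=lambda s: s.ref_position
    )
    with open(path, "w") as fh:
        for s in accepted:
            score = int(min(1000, round(-10.0 * np.log10(max(s.p_combined, 1e-100)))))
            fh.write(
                f"{chrom}\t{s.ref_position}\t{s.ref_position + 1}\t"
                f"rank{s.rank}\t{score}\t.\n"
            )


def write_truth_bed(truth: Iterable[int], path: str | Path, chrom: str = "ref") -> None:
    with open(path, "w") as fh:
        for pos in sorted(int(p) for p in truth):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\tmodified\n")


def read_truth_bed(path: str | Path) -> set[int]:
    truth: set[int] = set()
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track")):
                fields = line.split("\t")
                truth.update(range(int(fields[1]), int(fields[2])))
    return truth


def write_pr_table(points: Sequence[PRPoint], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["percentile", "n_predictions", "n_true_hits", "precision", "recall"])
        for p in points:
            writer.writerow(
                [p.percentile, p.n_predictions, p.n_true_hits,
                 f"{p.precision:.6g}", f"{p.recall:.6g}"]
            )
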