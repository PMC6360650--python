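import numpy as np
import pytest

from poremod.event_correction import (
    AlignmentOp,
    HomopolymerRun,
    UncorrectableRegionError,
    apply_homopolymer_rule,
    correct_deletion,
    correct_insertion,
    correct_read,
    find_homopolymer_runs,
    ops_from_cigartuples,
    resegment,
)
from poremod.signal_model import Event, EventSequence
from poremod.simulator import ScenarioConfig, inject_indels, simulate_dataset


def events_of(sizes, bases=None, rng=None):
    rng = rng or np.random.default_rng(0)
    bases = bases or "A" * len(sizes)
    out = []
    off = 0
    for size, base in zip(sizes, bases):
        out.append(Event(off, base, rng.normal(size=size)))
        off += size
    return out


def total_signals(events):
    return sum(e.length for e in events)


def concat_signals(events):
    return np.concatenate([e.signals for e in events])


class TestResegment:
    def test_even_split(self):
        out = resegment(np.arange(30.0), 3)
        assert [e.length for e in out] == [10, 10, 10]
        np.testing.assert_array_equal(concat_signals(out), np.arange(30.0))

    def test_remainder_goes_left(self):
        out = resegment(np.arange(10.0), 3)
        assert [e.length for e in out] == [4, 3, 3]

    def test_infeasible_split(self):
        with pytest.raises(UncorrectableRegionError):
            resegment(np.arange(3.0), 4)


class TestCorrectInsertion:
    def test_merges_into_two_events_conserving_signals(self):
        evs = events_of([10, 6, 10])
        out = correct_insertion(evs, 1)
        assert len(out) == 2
        assert total_signals(out) == 26
        np.testing.assert_array_equal(concat_signals(out), concat_signals(evs))

    def test_smaller_flank_chosen(self):
        evs = events_of([3, 6, 10])
        out = correct_insertion(evs, 1)
        assert [e.length for e in out] == [9, 10]
        evs = events_of([10, 6, 3])
        out = correct_insertion(evs, 1)
        assert [e.length for e in out] == [10, 9]

    def test_tie_merges_upstream(self):
        out = correct_insertion(events_of([4, 6, 4]), 1)
        assert [e.length for e in out] == [10, 4]

    def test_read_end_uses_single_flank(self):
        out = correct_insertion(events_of([6, 10]), 0)
        assert [e.length for e in out] == [16]

    def test_conservation_generic(self):
        evs = events_of([8, 4, 8])
        out = correct_insertion(evs, 1)
        assert len(out) == 2 and total_signals(out) == 20


class TestCorrectDeletion:
    def test_one_additional_event_from_two_flanks(self):
        evs = events_of([15, 15])
        out = correct_deletion(evs, 1)
        assert len(out) == 3
        assert total_signals(out) == 30
        assert [e.length for e in out] == [10, 10, 10]

    def test_group_widens_when_flanks_too_small(self):
        # flanks of 2+2 signals cannot feed 3 events at >= 3 signals each
        evs = events_of([6, 2, 2, 6])
        out = correct_deletion(evs, 2, min_signals=3)
        assert len(out) == 5  # 4 grouped events + 1 deletion
        assert total_signals(out) == 16
        assert min(e.length for e in out) >= 3

    def test_exhausted_read_raises(self):
        with pytest.raises(UncorrectableRegionError):
            correct_deletion(events_of([2, 2]), 1, min_signals=3)

    def test_signals_conserved_in_order(self):
        evs = events_of([4, 9])
        out = correct_deletion(evs, 1)
        np.testing.assert_array_equal(concat_signals(out), concat_signals(evs))


class TestHomopolymerRule:
    @pytest.mark.parametrize("run_len,expected_shared", [(7, 3), (6, 2)])
    def test_middle_positions_share_one_event(self, run_len, expected_shared):
        evs = events_of([3] * run_len, bases="A" * run_len)
        out = apply_homopolymer_rule(evs, HomopolymerRun(0, run_len, "A"))
        assert len(out) == run_len  # positions preserved
        shared = {id(e) for e in out[2 : 2 + expected_shared]}
        assert len(shared) == 1
        assert out[2].length == 3 * expected_shared
        # the 4 outer positions keep their own events
        outer = out[:2] + out[-2:]
        assert len({id(e) for e in outer}) == 4

    def test_short_run_unchanged(self):
        evs = events_of([3] * 5)
        out = apply_homopolymer_rule(evs, HomopolymerRun(0, 5, "A"))
        assert [id(e) for e in out] == [id(e) for e in evs]

    def test_find_runs(self):
        runs = find_homopolymer_runs("AAACCTTTTTTG", min_length=3)
        assert [(r.ref_start, r.length, r.base) for r in runs] == [
            (0, 3, "A"),
            (5, 6, "T"),
        ]


class TestCigarParsing:
    def test_match_insertion_deletion_and_clips(self):
        # 2S 3M 1I 2M 1D 2M 2H at ref 10
        ops = ops_from_cigartuples(
            [(4, 2), (0, 3), (1, 1), (0, 2), (2, 1), (0, 2), (5, 2)], 10
        )
        assert [(o.kind, o.length, o.read_start, o.ref_start) for o in ops] == [
            ("match", 3, 2, 10),
            ("insertion", 1, 5, 13),
            ("match", 2, 6, 13),
            ("deletion", 1, 8, 15),
            ("match", 2, 8, 16),
        ]

    def test_reference_skip_rejected(self):
        with pytest.raises(ValueError):
            ops_from_cigartuples([(0, 2), (3, 5), (0, 2)], 0)


def _clean_read(reference, rng, start=0, counts=None):
    n = len(reference) - start
    counts = counts if counts is not None else rng.integers(3, 8, size=n)
    signals = rng.normal(size=int(np.sum(counts)))
    return EventSequence(
        "read", "+", start, reference[start:], signals, np.asarray(counts)
    )


class TestCorrectRead:
    def test_indel_free_read_is_unchanged(self, rng):
        ref = "ACGTACGTAC"
        read = _clean_read(ref, rng)
        ops = [AlignmentOp("match", 10, 0, 0)]
        out = correct_read(read, ops, ref)
        np.testing.assert_array_equal(out.signals, read.signals)
        np.testing.assert_array_equal(out.lengths, read.lengths)
        assert out.bases == ref

    def test_single_deletion_and_insertion_conserve_signals(self, rng):
        ref = "ACGTACGTACGT"
        # read missing ref position 5, with a spurious event after position 8
        bases = ref[:5] + ref[6:9] + "A" + ref[9:]
        counts = np.full(len(bases), 6)
        signals = rng.normal(size=int(counts.sum()))
        read = EventSequence("r", "+", 0, bases, signals, counts)
        ops = [
            AlignmentOp("match", 5, 0, 0),
            AlignmentOp("deletion", 1, 5, 5),
            AlignmentOp("match", 3, 5, 6),
            AlignmentOp("insertion", 1, 8, 9),
            AlignmentOp("match", 3, 9, 9),
        ]
        out = correct_read(read, ops, ref)
        assert out.bases == ref
        assert out.n_positions == len(ref)
        assert out.signals.size == read.signals.size
        assert np.all(out.position_map >= 0)

    def test_uncorrectable_region_dropped(self, rng):
        # deletion flanked by single-signal events over the whole read
        ref = "ACGTA"
        bases = ref[:2] + ref[3:]
        read = EventSequence(
            "r", "+", 0, bases, rng.normal(size=4), np.array([1, 1, 1, 1])
        )
        ops = [
            AlignmentOp("match", 2, 0, 0),
            AlignmentOp("deletion", 1, 2, 2),
            AlignmentOp("match", 2, 2, 3),
        ]
        # the whole span is consumed by the widening and still starves:
        # nothing is annotatable
        with pytest.raises(UncorrectableRegionError):
            correct_read(read, ops, ref, min_signals=3)

    def test_homopolymer_sharing_in_whole_read(self, rng):
        ref = "ACTTTTTTGA"  # T run of length 6 at positions 2..7
        read = _clean_read(ref, rng)
        out = correct_read(read, [AlignmentOp("match", 10, 0, 0)], ref)
        # middle 6-4=2 positions (4 and 5) share one event
        assert out.event_index_at(4) == out.event_index_at(5)
        assert out.event_index_at(3) != out.event_index_at(4)
        assert out.n_events == len(ref) - 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_injected_indels_round_trip(self, seed):
        """Conservation, base restoration and 1:1 annotation on simulated
        reads corrupted with synthetic basecalling indels."""
        rng = np.random.default_rng(seed)
        config = ScenarioConfig(
            scenario="Mean_STDDif",
            reference_length=300,
            n_modifications=5,
            reads_per_group=5,
            seed=seed,
        )
        mod, ctrl, _, reference, _ = simulate_dataset(config)
        for read in mod + ctrl:
            bad, ops = inject_indels(read, rng, insertion_rate=0.05, deletion_rate=0.05)
            out = correct_read(bad, ops, reference)
            assert out.signals.size == bad.signals.size  # conservation
            span_bases = reference[out.aligned_ref_start :][: out.n_positions]
            assert "".join(
                out.bases[i] for i in out.position_map if i >= 0
            ) == "".join(
                span_bases[t] for t in range(out.n_positions)
                if out.position_map[t] >= 0
            )

    def test_deterministic(self, rng):
        ref = "ACGTACGTACGT"
        read = _clean_read(ref, rng)
        bad, ops = inject_indels(read, np.random.default_rng(3), 0.2, 0.2)
        a = correct_read(bad, ops, ref)
        b = correct_read(bad, ops, ref)
        np.testing.assert_array_equal(a.signals, b.signals)
        np.testing.assert_array_equal(a.position_map, b.position_map)
        assert a.bases == b.bases
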