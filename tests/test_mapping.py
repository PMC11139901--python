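"""Tests for the two branchpoint callers, circle filtering and aggregation."""

import numpy as np
import pytest

import lariatkit as lk
from lariatkit._seq import random_seq, revcomp
from lariatkit.mapping import (
    LariatCall,
    MapParams,
    aggregate_branchpoints,
    filter_intron_circles,
    map_lariats_split,
    map_lariats_ss,
)
from lariatkit.synthetic import SimRead


def make_lariat_read(intr, genome, head_len, tail_len, bp_offset=None):
    """Noise-free branch-spanning read: [ends at branch][starts at pos 0]."""
    seq = intr.seq(genome)
    bp = intr.true_bp_offset if bp_offset is None else bp_offset
    return seq[bp + 1 - head_len : bp + 1] + seq[:tail_len]


@pytest.fixture(scope="module")
def truth_by_read(toy_reads):
    _, truth = toy_reads
    return truth.reads.set_index("read_id")


class TestSplitMapper:
    def test_clean_lariat_read_called_at_truth(self, toy, toy_index):
        genome, introns, _ = toy
        intr = introns[0]
        read = SimRead("r1", make_lariat_read(intr, genome, 25, 25), "")
        calls = map_lariats_split([read], genome, introns, index=toy_index,
                                  prefilter_linear=False)
        assert len(calls) == 1 and calls[0].passed
        c = calls[0]
        assert c.intron_id == intr.intron_id
        assert c.bp_position == intr.true_bp_genomic
        assert c.bp_base == intr.seq(genome)[intr.true_bp_offset]

    def test_linear_read_never_called(self, toy, toy_index):
        genome, introns, genes = toy
        tx = lk.transcript_space(genes, genome)
        read = SimRead("r1", genes[0].spliced_seq(genome)[10:70], "")
        calls = map_lariats_split([read], genome, introns, index=toy_index,
                                  extra=tx)
        assert calls[0].filtered_reason == "linear"

    def test_read_below_32nt_skipped(self, toy, toy_index):
        genome, introns, _ = toy
        read = SimRead("r1", make_lariat_read(introns[0], genome, 15, 15), "")
        calls = map_lariats_split([read], genome, introns, index=toy_index,
                                  prefilter_linear=False)
        assert calls[0].filtered_reason == "too_short"

    def test_minimum_segment_is_16(self, toy, toy_index):
        # a 40-nt read with a 15+25 junction has no valid bipartition:
        # every tried split puts >= 16 nt in each part, misplacing the junction
        genome, introns, _ = toy
        intr = introns[0]
        read = SimRead("r1", make_lariat_read(intr, genome, 15, 25), "")
        calls = map_lariats_split([read], genome, introns, index=toy_index,
                                  prefilter_linear=False)
        assert not calls[0].passed

    def test_rt_misincorporated_branch_base_tolerated(self, toy, toy_index):
        genome, introns, _ = toy
        intr = introns[3]
        seq = make_lariat_read(intr, genome, 25, 25)
        damaged = seq[:24] + ("A" if seq[24] != "A" else "C") + seq[25:]
        params_tol = MapParams(terminal_mismatch=True)
        params_no = MapParams(terminal_mismatch=False)
        with_tol = map_lariats_split([SimRead("r", damaged, "")], genome, introns,
                                     params_tol, index=toy_index, prefilter_linear=False)
        without = map_lariats_split([SimRead("r", damaged, "")], genome, introns,
                                    params_no, index=toy_index, prefilter_linear=False)
        assert with_tol[0].passed
        assert with_tol[0].bp_position == intr.true_bp_genomic
        assert not without[0].passed

    def test_minus_strand_intron_coordinates(self, toy, toy_index):
        genome, introns, _ = toy
        intr = next(i for i in introns if i.strand == "-")
        read = SimRead("r1", make_lariat_read(intr, genome, 28, 28), "")
        calls = map_lariats_split([read], genome, introns, index=toy_index,
                                  prefilter_linear=False)
        assert calls[0].passed
        assert calls[0].bp_position == intr.true_bp_genomic


class TestSsMapper:
    def test_clean_lariat_read_called_at_truth(self, toy, toy_index):
        genome, introns, _ = toy
        intr = introns[5]
        read = SimRead("r1", make_lariat_read(intr, genome, 25, 25), "")
        calls = map_lariats_ss([read], genome, introns, index=toy_index,
                               prefilter_linear=False)
        assert calls[0].passed
        assert calls[0].intron_id == intr.intron_id
        assert calls[0].bp_position == intr.true_bp_genomic

    def test_upstream_and_downstream_alignments_recorded(self, toy, toy_index):
        genome, introns, _ = toy
        intr = introns[5]
        read = SimRead("r1", make_lariat_read(intr, genome, 25, 25), "")
        c = map_lariats_ss([read], genome, introns, index=toy_index,
                           prefilter_linear=False)[0]
        up, down = c.upstream_alignment, c.downstream_alignment
        # upstream block starts exactly at intron position 0
        if intr.strand == "+":
            assert up.ref_start == intr.start
        else:
            assert up.ref_end == intr.end
        assert intr.start <= down.ref_start and down.ref_end <= intr.end

    def test_mismatches_within_budget_accepted(self, toy, toy_index):
        genome, introns, _ = toy
        intr = introns[4]
        seq = make_lariat_read(intr, genome, 40, 25)
        # plant 3 substitutions in the trimmed (downstream) portion: 3/40 < 10%
        s = list(seq)
        for i in (5, 15, 30):
            s[i] = "A" if s[i] != "A" else "G"
        calls = map_lariats_ss([SimRead("r", "".join(s), "")], genome, introns,
                               index=toy_index, prefilter_linear=False)
        assert calls[0].passed
        assert calls[0].bp_position == intr.true_bp_genomic

    def test_single_small_indel_accepted(self, toy, toy_index):
        genome, introns, _ = toy
        intr = introns[4]
        seq = make_lariat_read(intr, genome, 40, 25)
        s = seq[:20] + seq[23:]  # 3-nt deletion inside the trimmed portion
        calls = map_lariats_ss([SimRead("r", s, "")], genome, introns,
                               index=toy_index, prefilter_linear=False)
        assert calls[0].passed
        assert calls[0].bp_position == intr.true_bp_genomic


class TestFilterCascade:
    """Reads violating exactly one stated filter are rejected with the
    matching reason."""

    def _map(self, seq, toy, toy_index, **kw):
        genome, introns, _ = toy
        return map_lariats_ss([SimRead("r", seq, "")], genome, introns,
                              index=toy_index, prefilter_linear=False, **kw)[0]

    def test_ambiguous_characters_over_5_percent(self, toy, toy_index):
        genome, introns, _ = toy
        seq = make_lariat_read(introns[0], genome, 30, 30)
        seq = "NNNN" + seq[4:]  # 4/60 = 6.7% N
        assert self._map(seq, toy, toy_index).filtered_reason == "ambiguous_chars"

    def test_trimmed_portion_under_20nt(self, toy, toy_index):
        genome, introns, _ = toy
        seq = make_lariat_read(introns[0], genome, 19, 41)
        assert self._map(seq, toy, toy_index).filtered_reason == "trimmed_short"

    def test_six_mismatches_rejected(self, toy, toy_index):
        genome, introns, _ = toy
        seq = make_lariat_read(introns[0], genome, 70, 25)
        s = list(seq)
        for i in (4, 14, 24, 34, 44, 54):  # 6 subs, rate 6/70 < 10%
            s[i] = "A" if s[i] != "A" else "G"
        assert self._map("".join(s), toy, toy_index).filtered_reason == "mismatch_budget"

    def test_mismatch_rate_over_10_percent(self, toy, toy_index):
        genome, introns, _ = toy
        seq = make_lariat_read(introns[0], genome, 25, 25)
        s = list(seq)
        for i in (4, 12, 20):  # 3 subs in a 25-nt trimmed portion: 12%
            s[i] = "A" if s[i] != "A" else "G"
        assert self._map("".join(s), toy, toy_index).filtered_reason == "mismatch_rate"

    def test_two_indels_rejected(self, toy, toy_index):
        genome, introns, _ = toy
        seq = make_lariat_read(introns[0], genome, 60, 25)
        s = seq[:10] + "A" + seq[10:40] + "C" + seq[40:]  # two 1-nt insertions
        assert self._map(s, toy, toy_index).filtered_reason == "indel_count"

    def test_indel_of_4nt_rejected(self, toy, toy_index):
        genome, introns, _ = toy
        seq = make_lariat_read(introns[0], genome, 44, 25)
        s = seq[:20] + seq[24:]  # single 4-nt deletion
        assert self._map(s, toy, toy_index).filtered_reason == "indel_length"

    def test_intron_circle_junction_filtered(self, toy, toy_index):
        genome, introns, _ = toy
        intr = introns[0]
        iseq = intr.seq(genome)
        read = iseq[-30:] + iseq[:30]
        c = self._map(read, toy, toy_index)
        assert c.passed  # called, then removed by the circle filter
        calls = filter_intron_circles([c], introns)
        assert calls[0].filtered_reason == "intron_circle"

    def test_multiple_five_ss_hits_rejected(self, toy, toy_index):
        genome, introns, _ = toy
        a, b = introns[0], introns[1]
        seq = a.seq(genome)[:30] + b.seq(genome)[:30]
        assert self._map(seq, toy, toy_index).filtered_reason == "multiple_five_ss"


class TestIntronCircleFilter:
    def _call_at(self, intr, bp_rel):
        return LariatCall("r", intr.intron_id, intr.gene_id,
                          intr.rel_to_genomic(bp_rel), "A", mapper="split")

    def test_boundary_enumeration_at_tol_0(self, toy):
        _, introns, _ = toy
        intr = introns[0]
        last = intr.length - 1
        kept = filter_intron_circles([self._call_at(intr, last - 1)], introns, tol=0)
        assert kept[0].passed
        dropped = filter_intron_circles([self._call_at(intr, last)], introns, tol=0)
        assert dropped[0].filtered_reason == "intron_circle"

    def test_default_tolerance_2(self, toy):
        _, introns, _ = toy
        intr = introns[0]
        last = intr.length - 1
        for off, expect in [(last, False), (last - 2, False), (last - 3, True),
                            (last - 40, True)]:
            out = filter_intron_circles([self._call_at(intr, off)], introns, tol=2)
            assert out[0].passed is expect


class TestAggregation:
    def test_three_reads_same_bp(self, toy):
        _, introns, _ = toy
        intr = introns[0]
        calls = [LariatCall(f"r{i}", intr.intron_id, intr.gene_id,
                            intr.true_bp_genomic, "A") for i in range(3)]
        t = aggregate_branchpoints(calls, n_mapped=100)
        assert len(t.counts) == 1
        assert int(t.counts["support"].iloc[0]) == 3
        assert t.n_lariat == 3

    def test_multi_bp_introns_preserved(self, toy):
        _, introns, _ = toy
        intr = introns[0]
        calls = [
            LariatCall("r1", intr.intron_id, intr.gene_id, intr.true_bp_genomic, "A"),
            LariatCall("r2", intr.intron_id, intr.gene_id, intr.true_bp_genomic - 3, "C"),
        ]
        t = aggregate_branchpoints(calls)
        assert len(t.counts) == 2

    def test_empty_call_list(self):
        t = aggregate_branchpoints([])
        assert t.counts.empty and t.n_lariat == 0


class TestCrossMapperProperties:
    def test_concordance_and_recall_on_simulated_reads(self, toy, toy_index,
                                                       toy_reads, truth_by_read):
        """Noise-free lariat reads: both mappers call every read at the true
        (intron, branchpoint); linear reads produce zero calls."""
        genome, introns, genes = toy
        reads, truth = toy_reads
        tx = lk.transcript_space(genes, genome)
        unmapped = [r for r in reads
                    if not lk.classify_linear(r.seq, toy_index, extra=tx)]
        res = {}
        for name, fn in (("split", map_lariats_split), ("ss", map_lariats_ss)):
            calls = fn(unmapped, genome, introns, index=toy_index,
                       prefilter_linear=False)
            calls = filter_intron_circles(calls, introns)
            res[name] = {c.read_id: (c.intron_id, c.bp_position)
                         for c in calls if c.passed}
        lariat_ids = set(truth_by_read[truth_by_read["read_class"] == "lariat"].index)
        for name in ("split", "ss"):
            assert set(res[name]) == lariat_ids  # 100% recall, no false calls
            for rid, (iid, bp) in res[name].items():
                assert truth_by_read.loc[rid, "intron_id"] == iid
                assert truth_by_read.loc[rid, "bp_genomic"] == bp
        assert res["split"] == res["ss"]

    def test_bp_always_inside_intron(self, toy, toy_index, toy_reads):
        genome, introns, _ = toy
        reads, _ = toy_reads
        by_id = {i.intron_id: i for i in introns}
        calls = map_lariats_split(reads, genome, introns, index=toy_index,
                                  prefilter_linear=True)
        for c in calls:
            if c.passed:
                intr = by_id[c.intron_id]
                assert intr.start <= c.bp_position < intr.end

    def test_terminal_mismatch_tolerance_never_lowers_recall(self, toy, toy_index):
        genome, introns, _ = toy
        from lariatkit.synthetic import ErrorModel

        counts = {"lariat": {i.intron_id: 6 for i in introns}}
        reads, _ = lk.simulate_reads(
            genome, introns, counts, read_len=60, seed=21, min_block=20,
            error_model=ErrorModel(rt_branch_misincorporation=0.5),
        )
        n_with = sum(c.passed for c in map_lariats_split(
            reads, genome, introns, MapParams(terminal_mismatch=True),
            index=toy_index, prefilter_linear=False))
        n_without = sum(c.passed for c in map_lariats_split(
            reads, genome, introns, MapParams(terminal_mismatch=False),
            index=toy_index, prefilter_linear=False))
        assert n_with >= n_without
        assert n_with > n_without  # half the reads carry the branch mismatch
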