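"""Branchpoint calling from inverted (branch-spanning) reads.

Two independent algorithms are provided:

* the split mapper: every bipartition of an unmapped read into two segments
  of at least 16 nt is tried; a call requires one segment to align uniquely
  starting at the first nucleotide of an annotated intron and the other to
  align uniquely within the 3' portion of the same intron.  The genomic end
  of the downstream segment is the branchpoint.

* the splice-site mapper: reads carrying exactly one perfect 20-nt intron
  5'SS match are trimmed at the match and the remaining 5' portion is
  aligned to the last-250-nt windows of introns of the same gene; the
  highest-scoring alignment passing the mismatch/indel filters (<=5
  mismatches, <=10% mismatch rate, at most one indel of <=3 nt) ends at the
  branchpoint.

Calls whose downstream segment ends at the intron's 3' terminus are intron
circles, not lariats, and are filtered out.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from ._seq import revcomp
from .align import (
    Alignment,
    KmerIndex,
    LinearParams,
    MATCH,
    MISMATCH,
    SearchSpace,
    classify_linear,
    diagnose_fit,
    fit_search,
)
from .synthetic import IntronRecord, SimRead, ToyGenome

logger = logging.getLogger(__name__)

# rejection reasons, in cascade order
REASONS = (
    "none",
    "ambiguous_chars",
    "linear",
    "no_five_ss",
    "multiple_five_ss",
    "trimmed_short",
    "no_alignment",
    "mismatch_budget",
    "mismatch_rate",
    "indel_count",
    "indel_length",
    "order",
    "ambiguous",
    "intron_circle",
    "too_short",
)


@dataclass
class LariatCall:
    """One read-level branchpoint call (or a recorded rejection)."""

    read_id: str
    intron_id: str | None = None
    gene_id: str | None = None
    bp_position: int | None = None  # 0-based genomic position of the branch base
    bp_base: str | None = None  # strand-corrected genomic base at bp_position
    upstream_alignment: Alignment | None = None  # read block at intron position 0
    downstream_alignment: Alignment | None = None  # read block ending at the branch
    mapper: str = ""
    filtered_reason: str = "none"

    @property
    def passed(self) -> bool:
        return self.filtered_reason == "none"


@dataclass
class MapParams:
    min_segment: int = 16  # ">15 bp" read strictly
    circle_tolerance: int = 2
    max_mismatch: int = 5
    max_mismatch_rate: float = 0.10
    max_indels: int = 1
    max_indel_len: int = 3
    five_ss_len: int = 20
    min_trimmed: int = 20
    max_ambiguous_frac: float = 0.05
    terminal_mismatch: bool = True  # tolerate RT misincorporation at the branch base
    linear: LinearParams = field(default_factory=LinearParams)


@dataclass
class BranchpointTable:
    """Distinct branchpoints per intron with read support, plus sample totals."""

    counts: pd.DataFrame  # columns: intron_id, bp_position, support
    n_lariat: int
    n_mapped: int
    sample_id: str = ""

    def intron_counts(self) -> pd.Series:
        if self.counts.empty:
            return pd.Series(dtype=int)
        return self.counts.groupby("intron_id")["support"].sum()


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _intron_alignment(intr: IntronRecord, rel_start: int, rel_end: int, mismatches=0,
                      indels=None) -> Alignment:
    """Intron-relative [rel_start, rel_end) (transcript orientation) -> Alignment."""
    if intr.strand == "+":
        ref_start = intr.start + rel_start
        ref_end = intr.start + rel_end
    else:
        ref_start = intr.end - rel_end
        ref_end = intr.end - rel_start
    n = rel_end - rel_start
    indels = indels or []
    q_len = n - sum(g for g in indels)
    score = (q_len - mismatches - sum(-g for g in indels if g < 0)) * MATCH + mismatches * MISMATCH
    for g in indels:
        score -= 3 + abs(g)
    return Alignment(
        contig=intr.contig,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=intr.strand,
        q_start=0,
        q_end=q_len,
        mismatches=mismatches,
        indels=list(indels),
        score=score,
    )


def _frac_ambiguous(seq: str) -> float:
    return sum(1 for c in seq if c not in "ACGT") / max(1, len(seq))


def _exact_occurrences(seg: str, index: KmerIndex) -> list[tuple[str, int, str]]:
    """All exact genomic occurrences of *seg* (len >= k), via first-k seeding."""
    k = index.k
    hits = []
    for contig, p, strand in index.lookup(seg[:k]):
        seq = index.genome.contigs[contig]
        if strand == "+":
            if seq[p : p + len(seg)] == seg:
                hits.append((contig, p, "+"))
        else:
            # seed matches revcomp at its plus-strand footprint end
            start = p + k - len(seg)
            if start >= 0 and seq[start : p + k] == revcomp(seg):
                hits.append((contig, start, "-"))
    return hits


# ---------------------------------------------------------------------------
# split mapper
# ---------------------------------------------------------------------------


class _SplitContext:
    def __init__(self, genome: ToyGenome, introns: list[IntronRecord], index: KmerIndex):
        self.genome = genome
        self.index = index
        self.k = index.k
        self.introns = introns
        self.seqs = {i.intron_id: i.seq(genome) for i in introns}
        self.prefix: dict[str, list[IntronRecord]] = defaultdict(list)
        for i in introns:
            self.prefix[self.seqs[i.intron_id][: self.k]].append(i)


def _find_in_intron(seg_core: str, iseq: str) -> list[int]:
    """Start offsets of exact occurrences of seg_core within the intron."""
    out, p = [], iseq.find(seg_core)
    while p != -1:
        out.append(p)
        p = iseq.find(seg_core, p + 1)
    return out


def map_lariats_split(
    reads: list[SimRead],
    genome: ToyGenome,
    introns: list[IntronRecord],
    params: MapParams | None = None,
    *,
    index: KmerIndex | None = None,
    prefilter_linear: bool = True,
    extra: SearchSpace | None = None,
) -> list[LariatCall]:
    """Iterative read-splitting branchpoint caller.

    Reads are assumed unmapped (any read with a full linear mapping is
    discarded first when ``prefilter_linear`` is set).  Among multiple valid
    bipartitions the one maximizing total alignment score wins; ties across
    distinct (intron, branchpoint) pairs are discarded as ambiguous.
    """
    params = params or MapParams()
    index = index or KmerIndex(genome, 12)
    ctx = _SplitContext(genome, introns, index)
    calls = []
    for read in reads:
        calls.append(_map_one_split(read, ctx, params, prefilter_linear, extra))
    n_ok = sum(c.passed for c in calls)
    logger.info("split mapper: %d reads in, %d calls", len(reads), n_ok)
    return calls


def _map_one_split(read: SimRead, ctx: _SplitContext, params: MapParams,
                   prefilter_linear: bool, extra) -> LariatCall:
    rid, seq = read.read_id, read.seq
    L = len(seq)
    if L < 2 * params.min_segment:
        return LariatCall(rid, mapper="split", filtered_reason="too_short")
    if _frac_ambiguous(seq) > params.max_ambiguous_frac:
        return LariatCall(rid, mapper="split", filtered_reason="ambiguous_chars")
    if prefilter_linear and classify_linear(seq, ctx.index, params.linear, extra):
        return LariatCall(rid, mapper="split", filtered_reason="linear")

    candidates = []  # (total_score, intron_id, bp_rel, tail_len, head_rel_start, head_mm)
    for oriented in (seq, revcomp(seq)):
        for c in range(params.min_segment, L - params.min_segment + 1):
            head, tail = oriented[:c], oriented[c:]
            # the read's 3' part must sit at the first nucleotide of an intron
            cand = [
                i
                for i in ctx.prefix.get(tail[: ctx.k], ())
                if ctx.seqs[i.intron_id].startswith(tail)
            ]
            if len(cand) != 1:
                continue
            intr = cand[0]
            # genome-wide uniqueness of the upstream segment
            if len(_exact_occurrences(tail, ctx.index)) != 1:
                continue
            iseq = ctx.seqs[intr.intron_id]
            # the read's 5' part maps within the intron, ending at the branch;
            # one terminal mismatch at the branch-adjacent base is tolerated
            core = head[:-1] if params.terminal_mismatch else head
            positions = [
                p
                for p in _find_in_intron(core, iseq)
                if p >= 1 and p + len(head) <= len(iseq)
            ]
            if len(positions) != 1:
                continue
            p = positions[0]
            bp_rel = p + len(head) - 1
            if bp_rel < len(tail):  # not in inverted order
                continue
            term_mm = 1 if (params.terminal_mismatch and iseq[bp_rel] != head[-1]) else 0
            score = len(tail) * MATCH + (len(head) - term_mm) * MATCH + term_mm * MISMATCH
            candidates.append((score, intr.intron_id, bp_rel, len(tail), p, term_mm))

    if not candidates:
        return LariatCall(rid, mapper="split", filtered_reason="no_alignment")
    best_score = max(c[0] for c in candidates)
    best = {(c[1], c[2]) for c in candidates if c[0] == best_score}
    if len(best) > 1:
        return LariatCall(rid, mapper="split", filtered_reason="ambiguous")
    score, iid, bp_rel, tail_len, head_start, head_mm = next(
        c for c in candidates if c[0] == best_score
    )
    intr = next(i for i in ctx.introns if i.intron_id == iid)
    bp_pos = intr.rel_to_genomic(bp_rel)
    return LariatCall(
        read_id=rid,
        intron_id=iid,
        gene_id=intr.gene_id,
        bp_position=bp_pos,
        bp_base=ctx.genome.base(intr.contig, bp_pos, intr.strand),
        upstream_alignment=_intron_alignment(intr, 0, tail_len),
        downstream_alignment=_intron_alignment(intr, head_start, bp_rel + 1, head_mm),
        mapper="split",
    )


# ---------------------------------------------------------------------------
# splice-site mapper
# ---------------------------------------------------------------------------


class _SsContext:
    def __init__(self, genome: ToyGenome, introns: list[IntronRecord], params: MapParams):
        self.genome = genome
        self.introns = introns
        self.by_id = {i.intron_id: i for i in introns}
        self.five_ss: dict[str, list[IntronRecord]] = defaultdict(list)
        n = params.five_ss_len
        for i in introns:
            self.five_ss[i.five_ss_seq[:n]].append(i)
        # per-gene 3'-tail windows (strand-corrected), with intron-relative offset
        self.gene_tails: dict[str, list[tuple[IntronRecord, int, str]]] = defaultdict(list)
        for i in introns:
            tail = i.three_tail_seq
            self.gene_tails[i.gene_id].append((i, i.length - len(tail), tail))
        self.gene_spaces: dict[str, SearchSpace] = {
            gid: SearchSpace([(idx, t[2]) for idx, t in enumerate(tails)])
            for gid, tails in self.gene_tails.items()
        }


def map_lariats_ss(
    reads: list[SimRead],
    genome: ToyGenome,
    introns: list[IntronRecord],
    params: MapParams | None = None,
    *,
    index: KmerIndex | None = None,
    prefilter_linear: bool = True,
    extra: SearchSpace | None = None,
) -> list[LariatCall]:
    """Splice-site-anchored branchpoint caller (full filter cascade).

    Cascade: drop reads with >5% ambiguous characters; drop linearly mapped
    reads; require a unique perfect 20-nt intron 5'SS match; trim from the
    match to the read end and require the remaining 5' portion >= 20 nt;
    align the trimmed portion to the last-250-nt intron windows of the same
    gene; keep alignments with <=5 mismatches, mismatch rate <=10% and at
    most one indel of <=3 nt, in inverted mapping order; choose the highest
    scoring survivor.  Every rejection is recorded with its reason.
    """
    params = params or MapParams()
    index = index or KmerIndex(genome, 12)
    ctx = _SsContext(genome, introns, params)
    calls = []
    for read in reads:
        calls.append(_map_one_ss(read, ctx, index, params, prefilter_linear, extra))
    n_ok = sum(c.passed for c in calls)
    logger.info("ss mapper: %d reads in, %d calls", len(reads), n_ok)
    return calls


def _map_one_ss(read: SimRead, ctx: _SsContext, index, params: MapParams,
                prefilter_linear: bool, extra) -> LariatCall:
    rid, seq = read.read_id, read.seq
    n = params.five_ss_len
    if _frac_ambiguous(seq) > params.max_ambiguous_frac:
        return LariatCall(rid, mapper="ss", filtered_reason="ambiguous_chars")
    if prefilter_linear and classify_linear(seq, index, params.linear, extra):
        return LariatCall(rid, mapper="ss", filtered_reason="linear")

    # unique, perfect 5'SS hit (searched in both read orientations)
    hits = []  # (oriented read, position, intron)
    for oriented in (seq, revcomp(seq)):
        for p in range(0, len(oriented) - n + 1):
            window = oriented[p : p + n]
            for intr in ctx.five_ss.get(window, ()):
                hits.append((oriented, p, intr))
    if not hits:
        return LariatCall(rid, mapper="ss", filtered_reason="no_five_ss")
    if len(hits) > 1:
        return LariatCall(rid, mapper="ss", filtered_reason="multiple_five_ss")
    oriented, pos, intr = hits[0]

    trimmed = oriented[:pos]
    if len(trimmed) < params.min_trimmed:
        return LariatCall(rid, mapper="ss", filtered_reason="trimmed_short")

    space = ctx.gene_spaces[intr.gene_id]
    tails = ctx.gene_tails[intr.gene_id]
    strict = _search_tails(trimmed, space, params.max_mismatch, params.max_indels,
                           params.max_indel_len)
    in_budget = [
        h for h in strict
        if h[3] <= params.max_mismatch
        and h[3] / len(trimmed) <= params.max_mismatch_rate
    ]
    if not in_budget:
        return _diagnose_ss(rid, trimmed, tails, space, params)

    # inverted mapping order: the trimmed block must lie 3' of the 5'SS block
    ordered = []
    for widx, woff, score, mm, indel in in_budget:
        t_intr, t_off, _ = tails[widx]
        rel_start = t_off + woff
        span = len(trimmed) + (indel[1] if indel else 0)
        rel_end = rel_start + span
        if rel_start >= params.five_ss_len:
            ordered.append((score, t_intr, rel_start, rel_end, mm, indel))
    if not ordered:
        return LariatCall(rid, mapper="ss", filtered_reason="order")

    best_score = max(o[0] for o in ordered)
    winners = [o for o in ordered if o[0] == best_score]
    distinct = {(w[1].intron_id, w[3] - 1) for w in winners}
    if len(distinct) > 1:
        return LariatCall(rid, mapper="ss", filtered_reason="ambiguous")
    score, t_intr, rel_start, rel_end, mm, indel = winners[0]
    bp_rel = rel_end - 1
    bp_pos = t_intr.rel_to_genomic(bp_rel)
    return LariatCall(
        read_id=rid,
        intron_id=t_intr.intron_id,
        gene_id=t_intr.gene_id,
        bp_position=bp_pos,
        bp_base=ctx.genome.base(t_intr.contig, bp_pos, t_intr.strand),
        upstream_alignment=_intron_alignment(intr, 0, params.five_ss_len),
        downstream_alignment=_intron_alignment(
            t_intr, rel_start, rel_end, mm, [indel[1]] if indel else []
        ),
        mapper="ss",
    )


def _search_tails(trimmed: str, space: SearchSpace, max_mm: int, max_indels: int,
                  max_indel_len: int):
    return fit_search(trimmed, space, max_mm, max_indels, max_indel_len)


def _diagnose_ss(rid: str, trimmed: str, tails, space: SearchSpace, params: MapParams) -> LariatCall:
    """Attribute a rejection reason when no in-budget alignment exists.

    A relaxed enumeration (two extra mismatches, one longer indel) is tried
    first; if it finds nothing, a full dynamic-programming fit over the tail
    windows identifies which stated filter the best alignment violates.
    """
    relaxed = _search_tails(trimmed, space, params.max_mismatch + 2, 1,
                            params.max_indel_len + 2)
    best = None  # (score, mismatches, gaps)
    if relaxed:
        top = max(relaxed, key=lambda h: h[2])
        best = (top[2], top[3], [top[4][1]] if top[4] else [])
    diag = diagnose_fit(trimmed, [t[2] for t in tails])
    if diag is not None:
        _, score, mm, gaps = diag
        # require the fit to look like a real (if damaged) alignment, and
        # prefer the highest-scoring explanation of the rejection
        if score > 0 and mm <= max(params.max_mismatch + 3, int(0.4 * len(trimmed))):
            if best is None or score > best[0]:
                best = (score, mm, gaps)
    if best is None:
        return LariatCall(rid, mapper="ss", filtered_reason="no_alignment")
    _, mm, gaps = best
    if mm > params.max_mismatch:
        reason = "mismatch_budget"
    elif mm / len(trimmed) > params.max_mismatch_rate:
        reason = "mismatch_rate"
    elif len(gaps) > params.max_indels:
        reason = "indel_count"
    elif any(abs(g) > params.max_indel_len for g in gaps):
        reason = "indel_length"
    else:
        reason = "no_alignment"
    return LariatCall(rid, mapper="ss", filtered_reason=reason)


# ---------------------------------------------------------------------------
# intron-circle filtering and aggregation
# ---------------------------------------------------------------------------


def filter_intron_circles(
    calls: list[LariatCall], introns: list[IntronRecord], tol: int = 2
) -> list[LariatCall]:
    """Mark calls whose branchpoint sits within *tol* nt of the intron 3'
    terminus as intron circles (they join the intron end to its start)."""
    by_id = {i.intron_id: i for i in introns}
    out = []
    for c in calls:
        if c.passed and c.intron_id is not None:
            intr = by_id[c.intron_id]
            bp_rel = intr.genomic_to_rel(c.bp_position)
            if bp_rel >= intr.length - 1 - tol:
                c = LariatCall(**{**c.__dict__, "filtered_reason": "intron_circle"})
        out.append(c)
    return out


def aggregate_branchpoints(
    calls: list[LariatCall], n_mapped: int = 0, sample_id: str = ""
) -> BranchpointTable:
    """Aggregate unfiltered calls into distinct branchpoints per intron."""
    passed = [c for c in calls if c.passed]
    counter = Counter((c.intron_id, c.bp_position) for c in passed)
    df = pd.DataFrame(
        [(iid, bp, n) for (iid, bp), n in sorted(counter.items())],
        columns=["intron_id", "bp_position", "support"],
    )
    table = BranchpointTable(df, n_lariat=len(passed), n_mapped=n_mapped, sample_id=sample_id)
    assert int(df["support"].sum()) == len(passed) if not df.empty else len(passed) == 0
    return table


def rejection_summary(calls: list[LariatCall]) -> pd.Series:
    return pd.Series(Counter(c.filtered_reason for c in calls)).sort_index()
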