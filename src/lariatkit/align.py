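"""Minimal seed-and-extend aligner for toy genomes.

Fits a whole query into a reference window ("glocal" alignment): the query
aligns end to end, the reference contributes a substring.  The search is
exhaustive over every placement with at most one internal indel, so the
best-alignment set it reports is exact within that budget; an affine
dynamic-programming fallback (:func:`align_dp`) handles diagnosis of
alignments outside the enumeration budget (e.g. two indels).

Scoring scheme (fixed, documented): match +1, mismatch -2, gap open -3,
gap extend -1 per gap base, so a gap of length g costs 3 + g.  All filter
thresholds downstream are expressed in mismatch/indel counts; the scheme
only breaks ties.  An ambiguous base (N) in a read never counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, revcomp
from .synthetic import ToyGenome

MATCH = 1
MISMATCH = -2
GAP_OPEN = -3
GAP_EXTEND = -1


def gap_cost(g: int) -> int:
    return -(3 + g)


@dataclass
class Alignment:
    """One fit of a query into the reference.

    ``indels`` holds signed gap lengths: positive = extra reference bases
    (gap in the query), negative = unaligned query bases (gap in the
    reference), so ``ref_end - ref_start == (q_end - q_start) + sum(indels)``.
    """

    contig: str
    ref_start: int
    ref_end: int
    strand: str
    q_start: int
    q_end: int
    mismatches: int
    indels: list[int] = field(default_factory=list)
    score: int = 0
    unique: bool = False

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


class KmerIndex:
    """Exact k-mer -> occurrence map over both strands of a toy genome.

    Plus-strand k-mers are stored directly; a minus-strand occurrence of a
    query k-mer q at (contig, p) means ``revcomp(q) == contig[p:p+k]`` and is
    found by looking up the reverse complement.
    """

    def __init__(self, genome: ToyGenome, k: int):
        if not (8 <= k <= 16):
            raise ValueError("k must be in [8, 16]")
        shortest = min(len(s) for s in genome.contigs.values())
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest contig length {shortest}")
        self.genome = genome
        self.k = k
        self._map: dict[str, list[tuple[str, int]]] = {}
        for name, seq in genome.contigs.items():
            for p in range(len(seq) - k + 1):
                self._map.setdefault(seq[p : p + k], []).append((name, p))

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All occurrences of *kmer*, as (contig, plus-strand position, strand)."""
        if len(kmer) != self.k:
            raise ValueError(f"query k-mer length {len(kmer)} != k={self.k}")
        out = [(c, p, "+") for c, p in self._map.get(kmer, ())]
        rc = revcomp(kmer)
        out += [(c, p, "-") for c, p in self._map.get(rc, ())]
        return sorted(out)


def build_index(genome: ToyGenome, k: int = 12) -> KmerIndex:
    return KmerIndex(genome, k)


# ---------------------------------------------------------------------------
# exhaustive fit search (vectorised enumeration, <= 1 internal indel)
# ---------------------------------------------------------------------------

_SEP = np.uint8(250)  # separator code: mismatches everything


def _prefix_mismatch(q: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """P[c, s] = mismatches of q[:c] placed at reference offset s.

    N in the query (code 4) and separator bases always mismatch.
    Shape (Q+1, R - Q + 1); columns are placements of the full query.
    """
    Q, R = len(q), len(ref)
    S = R - Q + 1
    P = np.zeros((Q + 1, S), dtype=np.int32)
    for i in range(Q):
        neq = (ref[i : i + S] != q[i]) | (q[i] > 3) | (ref[i : i + S] >= 4)
        P[i + 1] = P[i] + neq
    return P


def _enumerate_fits(q: np.ndarray, ref: np.ndarray, max_mismatch: int,
                    max_indels: int, max_indel_len: int):
    """All in-budget fits as (ref_start, mismatches, indel or None).

    indel is (query split position c, signed gap length g): positive g means
    g unaligned reference bases between q[:c] and q[c:], negative g means
    q[c:c-g] is unaligned (gap in the reference).
    """
    Q, R = len(q), len(ref)
    results = []
    P = _prefix_mismatch(q, ref) if Q <= R else None
    perfect = False
    if P is not None:
        m0 = P[Q]
        for s in np.nonzero(m0 <= max_mismatch)[0]:
            results.append((int(s), int(m0[s]), None))
        # a gapless perfect fit dominates every gapped or mismatched fit
        # under the scoring scheme, so the indel enumeration cannot change
        # the best-scoring set
        perfect = bool((m0 == 0).any())
    if max_indels >= 1 and max_indel_len >= 1 and Q >= 2 and P is not None and not perfect:
        for g in range(1, max_indel_len + 1):
            # gap in query: reference span Q + g; split c in [1, Q-1]
            Sg = R - Q - g + 1
            if Sg > 0:
                for c in range(1, Q):
                    # prefix q[:c] at s, suffix q[c:] at shifted offset s+g
                    mm = P[c, :Sg] + (P[Q, g : g + Sg] - P[c, g : g + Sg])
                    for s in np.nonzero(mm <= max_mismatch)[0]:
                        results.append((int(s), int(mm[s]), (int(c), g)))
            # gap in reference: reference span Q - g; split c in [1, Q-g-1]
            Sg = R - (Q - g) + 1
            if Q - g >= 2 and Sg > 0:
                for c in range(1, Q - g):
                    pre = _sub_mismatch(q[:c], ref, Sg)
                    suf = _sub_mismatch(q[c + g :], ref, Sg, start=c)
                    mm = pre + suf
                    for s in np.nonzero(mm <= max_mismatch)[0]:
                        results.append((int(s), int(mm[s]), (int(c), -g)))
    return results


def _sub_mismatch(qpart: np.ndarray, ref: np.ndarray, S: int, start: int = 0) -> np.ndarray:
    """Mismatches of qpart placed at ref offset s+start, for s in [0, S)."""
    out = np.zeros(S, dtype=np.int32)
    for i, qi in enumerate(qpart):
        col = ref[start + i : start + i + S]
        out += (col != qi) | (qi > 3) | (col >= 4)
    return out


def _score(q_len: int, mismatches: int, indel: tuple[int, int] | None) -> int:
    if indel is None:
        return (q_len - mismatches) * MATCH + mismatches * MISMATCH
    _, g = indel
    aligned = q_len - (-g if g < 0 else 0)
    return (aligned - mismatches) * MATCH + mismatches * MISMATCH + gap_cost(abs(g))


class SearchSpace:
    """Pre-encoded reference windows for repeated exhaustive fit searches.

    Windows are concatenated with separator sentinels so no fit can span two
    windows; each window remembers its provenance (an arbitrary label plus
    the genomic placement of window offset 0).
    """

    def __init__(self, windows: list[tuple[str, str]]):
        """windows: list of (label, sequence) in search orientation."""
        self.labels = [w[0] for w in windows]
        self.seqs = [w[1] for w in windows]
        parts, bounds, off = [], [], 0
        for s in self.seqs:
            bounds.append((off, off + len(s)))
            parts.append(encode(s))
            parts.append(np.array([_SEP], dtype=np.uint8))
            off += len(s) + 1
        self.codes = (
            np.concatenate(parts[:-1]) if parts else np.empty(0, dtype=np.uint8)
        )
        self.bounds = bounds

    def locate(self, pos: int) -> tuple[int, int]:
        """Concatenated offset -> (window index, offset within window)."""
        for i, (s, e) in enumerate(self.bounds):
            if s <= pos < e:
                return i, pos - s
        raise ValueError(f"position {pos} not inside any window")


def fit_search(
    seq: str,
    space: SearchSpace,
    max_mismatch: int = 0,
    max_indels: int = 0,
    max_indel_len: int = 0,
) -> list[tuple[int, int, int, int, tuple[int, int] | None]]:
    """All in-budget fits of *seq* into *space*.

    Returns tuples (window index, offset in window, score, mismatches,
    indel) where indel is None or (query split position, signed gap length).
    """
    if not seq or set(seq) <= {"N"}:
        raise ValueError("empty or ambiguous-only query sequence")
    q = encode(seq)
    hits = []
    for s, mm, indel in _enumerate_fits(q, space.codes, max_mismatch, max_indels, max_indel_len):
        span = len(q) + (indel[1] if indel else 0)
        try:
            widx, woff = space.locate(s)
        except ValueError:
            continue
        wstart, wend = space.bounds[widx]
        if s + span > wend:  # would cross a separator into the next window
            continue
        hits.append((widx, woff, _score(len(q), mm, indel), mm, indel))
    return hits


# ---------------------------------------------------------------------------
# public alignment operations
# ---------------------------------------------------------------------------


def _genome_spaces(genome: ToyGenome, region=None) -> list[tuple[str, int, str, str]]:
    """(contig, start, strand, seq) windows to search, both strands."""
    out = []
    if region is None:
        items = [(c, 0, len(s)) for c, s in genome.contigs.items()]
    else:
        items = [tuple(r) for r in region]
    for contig, start, end in items:
        plus = genome.contigs[contig][start:end]
        out.append((contig, start, "+", plus))
        out.append((contig, start, "-", revcomp(plus)))
    return out


def align_segment(
    seq: str,
    index: KmerIndex | ToyGenome,
    max_mismatch: int = 0,
    max_indels: int = 0,
    max_indel_len: int = 0,
    region: list[tuple[str, int, int]] | None = None,
) -> list[Alignment]:
    """All maximum-scoring alignments of *seq* within the stated budget.

    The whole query is aligned (fit alignment); both strands are searched.
    ``unique`` is set only when exactly one best-scoring hit exists.
    ``region`` restricts the search to genomic intervals.
    """
    genome = index.genome if isinstance(index, KmerIndex) else index
    windows = _genome_spaces(genome, region)
    space = SearchSpace([(i, w[3]) for i, w in enumerate(windows)])
    raw = fit_search(seq, space, max_mismatch, max_indels, max_indel_len)
    alns: list[Alignment] = []
    for widx, woff, score, mm, indel in raw:
        contig, start, strand, wseq = windows[widx]
        span = len(seq) + (indel[1] if indel else 0)
        if strand == "+":
            ref_start = start + woff
        else:
            ref_start = start + len(wseq) - (woff + span)
        alns.append(
            Alignment(
                contig=contig,
                ref_start=ref_start,
                ref_end=ref_start + span,
                strand=strand,
                q_start=0,
                q_end=len(seq),
                mismatches=mm,
                indels=[indel[1]] if indel else [],
                score=score,
            )
        )
    if not alns:
        return []
    best = max(a.score for a in alns)
    winners = [a for a in alns if a.score == best]
    for a in winners:
        a.unique = len(winners) == 1
    return winners


def align_dp(seq: str, ref: str):
    """Affine-gap fit alignment of *seq* into *ref* by full dynamic programming.

    Returns (score, mismatches, indel signed lengths, ref_start, ref_end) of
    one optimal path.  Used as a diagnostic fallback when the enumeration
    budget (one indel) is exceeded; tie-breaking prefers fewer gap openings.
    """
    q = encode(seq)
    r = encode(ref)
    Q, R = len(q), len(r)
    NEG = -(10**6)
    # three-state affine DP; query consumed fully, reference free at both ends
    M = np.full((Q + 1, R + 1), NEG, dtype=np.int64)  # last op: (mis)match
    X = np.full((Q + 1, R + 1), NEG, dtype=np.int64)  # gap in query (ref consumed)
    Y = np.full((Q + 1, R + 1), NEG, dtype=np.int64)  # gap in ref (query consumed)
    M[0, :] = 0
    ptr: dict[tuple[int, int, int], tuple] = {}
    for i in range(1, Q + 1):
        for j in range(0, R + 1):
            if j > 0:
                sub = MATCH if (q[i - 1] == r[j - 1] and q[i - 1] <= 3) else MISMATCH
                cands = (
                    (M[i - 1, j - 1], 0),
                    (X[i - 1, j - 1], 1),
                    (Y[i - 1, j - 1], 2),
                )
                prev, state = max(cands, key=lambda t: t[0])
                M[i, j] = prev + sub
                ptr[(0, i, j)] = (state, i - 1, j - 1, sub == MISMATCH)
                xo = M[i, j - 1] + GAP_OPEN + GAP_EXTEND
                xe = X[i, j - 1] + GAP_EXTEND
                if xo >= xe:
                    X[i, j] = xo
                    ptr[(1, i, j)] = (0, i, j - 1, False)
                else:
                    X[i, j] = xe
                    ptr[(1, i, j)] = (1, i, j - 1, False)
            yo = M[i - 1, j] + GAP_OPEN + GAP_EXTEND
            ye = Y[i - 1, j] + GAP_EXTEND
            if yo >= ye:
                Y[i, j] = yo
                ptr[(2, i, j)] = (0, i - 1, j, False)
            else:
                Y[i, j] = ye
                ptr[(2, i, j)] = (2, i - 1, j, False)
    finals = np.stack([M[Q], X[Q], Y[Q]])
    state, j = np.unravel_index(int(np.argmax(finals)), finals.shape)
    score = int(finals[state, j])
    # traceback
    mism = 0
    gaps: list[int] = []
    i, j_end = Q, int(j)
    st, jj = int(state), int(j)
    cur_gap = 0
    while i > 0:
        pst, pi, pj, was_mm = ptr[(st, i, jj)]
        if st == 0:
            if cur_gap:
                gaps.append(cur_gap)
                cur_gap = 0
            if was_mm:
                mism += 1
        elif st == 1:
            cur_gap = cur_gap + 1 if cur_gap > 0 else 1
        else:
            cur_gap = cur_gap - 1 if cur_gap < 0 else -1
        st, i, jj = pst, pi, pj
    if cur_gap:
        gaps.append(cur_gap)
    return score, mism, gaps[::-1], jj, j_end


def diagnose_fit(seq: str, windows: list[str]):
    """Best DP fit of *seq* across candidate windows; returns
    (window index, score, mismatches, gaps) or None if no window fits."""
    best = None
    for i, w in enumerate(windows):
        if not w:
            continue
        score, mm, gaps, _, _ = align_dp(seq, w)
        if best is None or score > best[1]:
            best = (i, score, mm, gaps)
    return best


# ---------------------------------------------------------------------------
# linear read classification
# ---------------------------------------------------------------------------


@dataclass
class LinearParams:
    max_mismatch_rate: float = 0.05
    seed_step: int = 1


def transcript_space(genes, genome: ToyGenome, k: int = 12) -> KmerIndex:
    """K-mer index over spliced transcript sequences, so exon-junction reads
    can be classified as linearly mapped."""
    return KmerIndex(ToyGenome({g.gene_id: g.spliced_seq(genome) for g in genes}), k)


def _seed_scan(read: str, rc: str, index: KmerIndex, budget: int, step: int) -> bool:
    """Seed-and-verify end-to-end placement of the read in an indexed space."""
    L = len(read)
    k = index.k
    tried: set[tuple[str, int, str]] = set()
    for s in list(range(0, L - k + 1, step)) + [L - k]:
        kmer = read[s : s + k]
        if "N" in kmer:
            continue
        for contig, p, strand in index.lookup(kmer):
            if strand == "+":
                start = p - s
                query = read
            else:
                start = p - (L - k - s)
                query = rc
            key = (contig, start, strand)
            if key in tried:
                continue
            tried.add(key)
            ref = index.genome.contigs[contig]
            if start < 0 or start + L > len(ref):
                continue
            mm = sum(1 for a, b in zip(query, ref[start : start + L]) if a != b or a == "N")
            if mm <= budget:
                return True
    return False


def classify_linear(
    read: str,
    index: KmerIndex,
    params: LinearParams | None = None,
    extra: KmerIndex | None = None,
) -> bool:
    """True iff the whole read aligns end-to-end within the mismatch budget.

    Candidate placements come from exact k-mer seeds (complete for reads
    whose longest error-free stretch is at least k, which holds at the
    default 5% budget for the read lengths this toolkit simulates);
    indel-containing linear alignments are out of scope.  ``extra`` (e.g. a
    :func:`transcript_space`) is searched in addition to the genome so
    exon-junction reads can be counted as linearly mapped.
    """
    params = params or LinearParams()
    L = len(read)
    budget = int(params.max_mismatch_rate * L)
    if L < index.k:
        return False
    rc = revcomp(read)
    if _seed_scan(read, rc, index, budget, params.seed_step):
        return True
    if extra is not None and L >= extra.k:
        return _seed_scan(read, rc, extra, budget, params.seed_step)
    return False
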