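"""Synthetic genomes, annotations, reads and count tables.

Everything downstream of this module assumes the statistical structure
produced here: intron-containing genes on both strands, a planted branchpoint
near each intron's 3' end in a YTNAY-like context, lariat-spanning reads with
an inverted block structure, and count tables for the reporter-assay and
auxiliary-assay statistics.  The generator is the study-condition oracle for
the whole pipeline: simulated truth (read classes, branchpoint positions,
expected abundances) is emitted alongside every read set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import decode, random_seq, revcomp

PYRIMIDINES = "CT"

DEFAULT_BP_COMPOSITION = {"A": 0.78, "G": 0.10, "C": 0.06, "T": 0.06}

READ_CLASSES = ("linear_mRNA", "pre_mRNA", "lariat", "intron_circle")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ToyGenome:
    """A toy reference: contig name -> A/C/G/T sequence."""

    contigs: dict[str, str]

    def __post_init__(self):
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - set("ACGT")
            if bad:
                raise ValueError(f"contig {name!r} has non-ACGT characters: {sorted(bad)}")

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Strand-corrected subsequence of [start, end) on the reference."""
        seq = self.contigs[contig][start:end]
        return revcomp(seq) if strand == "-" else seq

    def base(self, contig: str, pos: int, strand: str = "+") -> str:
        return self.fetch(contig, pos, pos + 1, strand)


@dataclass
class IntronRecord:
    """One annotated intron (coordinates 0-based, half-open, genomic).

    ``five_ss_seq`` and ``three_tail_seq`` are strand-corrected (transcript
    orientation).  ``true_bp_offset`` is the 0-based offset of the branch
    nucleotide from the intron start in transcript orientation; it is only
    present for simulated annotations.
    """

    intron_id: str
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    intron_class: str  # "U2" | "U12"
    five_ss_seq: str
    three_tail_seq: str
    true_bp_offset: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def seq(self, genome: ToyGenome) -> str:
        return genome.fetch(self.contig, self.start, self.end, self.strand)

    def rel_to_genomic(self, offset: int) -> int:
        """Transcript-orientation intron offset -> genomic position."""
        if self.strand == "+":
            return self.start + offset
        return self.end - 1 - offset

    def genomic_to_rel(self, pos: int) -> int:
        if self.strand == "+":
            return pos - self.start
        return self.end - 1 - pos

    @property
    def true_bp_genomic(self) -> int | None:
        if self.true_bp_offset is None:
            return None
        return self.rel_to_genomic(self.true_bp_offset)


@dataclass
class GeneModel:
    """Single-transcript gene: alternating exons and introns on one contig.

    ``exons`` are genomic intervals sorted by genomic coordinate; intron i of
    ``intron_ids`` (transcript order) sits between transcript-order exons i
    and i+1.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    intron_ids: list[str]

    def _ordered_exons(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    def spliced_seq(self, genome: ToyGenome) -> str:
        return "".join(
            genome.fetch(self.contig, s, e, self.strand) for s, e in self._ordered_exons()
        )

    def unspliced_seq(self, genome: ToyGenome) -> str:
        start = min(s for s, _ in self.exons)
        end = max(e for _, e in self.exons)
        return genome.fetch(self.contig, start, end, self.strand)

    def junction_offsets(self, genome: ToyGenome) -> list[int]:
        """Transcript offsets of exon-exon junctions in the spliced sequence
        (offset = first base of the downstream exon)."""
        offs, acc = [], 0
        ordered = self._ordered_exons()
        for s, e in ordered[:-1]:
            acc += e - s
            offs.append(acc)
        return offs

    def boundary_offsets(self, genome: ToyGenome) -> list[tuple[int, int]]:
        """Per intron (transcript order): offsets of the exon-intron and
        intron-exon boundaries in the unspliced (pre-mRNA) sequence.

        Each offset is the first base of the intron / of the downstream exon.
        """
        ordered = self._ordered_exons()
        out, acc = [], 0
        for i, (s, e) in enumerate(ordered[:-1]):
            acc += e - s
            intron_len = (
                self.exons[i + 1][0] - self.exons[i][1]
                if self.strand == "+"
                else self.exons[-1 - i][0] - self.exons[-2 - i][1]
            )
            # intron starts at pre-mRNA offset acc, ends at acc + intron_len
            out.append((acc, acc + intron_len))
            acc += intron_len
        return out


@dataclass
class DebranchKinetics:
    """Sequence-dependent lariat survival under debranching.

    ``base_survival`` is the survival fraction of the reference substrate (an
    'A' branchpoint with no 5'SS modifier) in the debranching-active
    condition.  Non-reference substrates survive as
    ``base_survival ** (rate(branch base) * motif_modifier)``, so a slower
    relative debranching rate (< 1) yields a larger survival fraction.  In the
    debranching-null condition every lariat survives.
    """

    base_survival: float = 0.05
    branch_rates: dict[str, float] = field(
        default_factory=lambda: {"A": 1.0, "C": 1.0, "G": 1.0, "T": 1.0}
    )
    five_ss_g_modifier: float = 1.0  # applied when intron has G at 5'SS offsets
    five_ss_g_positions: tuple[int, ...] = (2, 4)  # 1-based intron positions
    u12_rate_factor: float = 1.0
    condition: str = "active"  # "active" | "null"

    def __post_init__(self):
        if not (0.0 < self.base_survival <= 1.0):
            raise ValueError("base_survival must be in (0, 1]")
        if self.condition not in ("active", "null"):
            raise ValueError("condition must be 'active' or 'null'")

    def survival(self, intron: IntronRecord, branch_base: str | None = None) -> float:
        if self.condition == "null":
            return 1.0
        if branch_base is None:
            if intron.true_bp_offset is None:
                raise ValueError("branch base unknown and intron has no true_bp_offset")
            tail_start = intron.length - len(intron.three_tail_seq)
            branch_base = intron.three_tail_seq[intron.true_bp_offset - tail_start]
        rate = self.branch_rates.get(branch_base, 1.0)
        mod = 1.0
        for pos in self.five_ss_g_positions:
            if pos - 1 < len(intron.five_ss_seq) and intron.five_ss_seq[pos - 1] == "G":
                mod = self.five_ss_g_modifier
                break
        if intron.intron_class == "U12":
            rate *= self.u12_rate_factor
        return min(1.0, self.base_survival ** (rate * mod))


@dataclass
class TruthTable:
    """Simulator ground truth.

    ``reads``: one row per emitted read (read_id, read_class, gene_id,
    intron_id, bp_genomic).  ``abundance``: optional per intron x condition
    expected lariat read counts.
    """

    reads: pd.DataFrame
    abundance: pd.DataFrame | None = None

    def class_counts(self) -> pd.Series:
        return self.reads["read_class"].value_counts()


@dataclass
class SimRead:
    read_id: str
    seq: str
    quality: str


# ---------------------------------------------------------------------------
# genome / annotation generation
# ---------------------------------------------------------------------------


def _draw_branch_context(rng, branch_base: str) -> str:
    """YTNAY-like 5-mer around the branch: Y T N <branch> Y."""
    return (
        rng.choice(list(PYRIMIDINES))
        + "T"
        + random_seq(rng, 1)
        + branch_base
        + rng.choice(list(PYRIMIDINES))
    )


def _make_intron(
    rng,
    length: int,
    intron_class: str,
    bp_composition: dict[str, float],
    u12_five_ss: str,
    bp_tail_distance: tuple[int, int],
    ppt_purity: float,
) -> tuple[str, int]:
    """Build one intron in transcript orientation; returns (seq, bp_offset)."""
    bases, probs = zip(*sorted(bp_composition.items()))
    branch = rng.choice(bases, p=np.asarray(probs) / sum(probs))
    lo, hi = bp_tail_distance
    hi = min(hi, 99, length - 10)
    lo = min(lo, hi)
    dist = int(rng.integers(lo, hi + 1))  # branch-to-3'-terminus distance
    bp_offset = length - 1 - dist

    seq = list(random_seq(rng, length))
    seq[0:2] = "GT"
    if intron_class == "U12":
        seq[0 : len(u12_five_ss)] = u12_five_ss
    ctx = _draw_branch_context(rng, branch)
    seq[bp_offset - 3 : bp_offset + 2] = ctx
    # polypyrimidine tract between the branch context and the 3'SS
    for i in range(bp_offset + 2, length - 2):
        if rng.random() < ppt_purity:
            seq[i] = rng.choice(list(PYRIMIDINES))
    seq[-2:] = "AG"
    return "".join(seq), bp_offset


def make_genome(
    n_genes: int,
    intron_len_range: tuple[int, int] = (300, 600),
    seed: int = 0,
    *,
    introns_per_gene: int = 2,
    exon_len_range: tuple[int, int] = (150, 250),
    bp_composition: dict[str, float] | None = None,
    u12_fraction: float = 0.0,
    u12_five_ss: str = "GTATCCTT",
    bp_tail_distance: tuple[int, int] = (22, 70),
    ppt_purity: float = 0.85,
    genes_per_contig: int = 25,
    intergenic_len_range: tuple[int, int] = (100, 300),
) -> tuple[ToyGenome, list[IntronRecord], list[GeneModel]]:
    """Generate a toy genome with intron-containing genes on both strands.

    Each intron carries a planted branch nucleotide (default composition 78%
    A / 10% G / 6% C / 6% T) in a YTNAY-like context followed by a
    polypyrimidine tract, sits within the last 100 nt of the intron, and the
    intron starts GT / ends AG (U12 introns get a distinct 5'SS motif).
    Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = intron_len_range
    if lo < 70 or hi > 10_000 or lo > hi:
        raise ValueError("intron_len_range must lie within [70, 10000]")
    comp = dict(DEFAULT_BP_COMPOSITION if bp_composition is None else bp_composition)

    rng = np.random.default_rng(seed)
    introns: list[IntronRecord] = []
    genes: list[GeneModel] = []
    contigs: dict[str, list[str]] = {}
    seen_five_ss: set[str] = set()

    for g in range(n_genes):
        contig = f"chr{g // genes_per_contig + 1}"
        parts = contigs.setdefault(contig, [])
        offset = sum(len(p) for p in parts)
        strand = "+" if rng.random() < 0.5 else "-"
        is_u12 = rng.random() < u12_fraction
        gene_id = f"gene{g:04d}"

        # build the gene in transcript orientation
        n_introns = introns_per_gene
        exon_seqs = [
            random_seq(rng, int(rng.integers(exon_len_range[0], exon_len_range[1] + 1)))
            for _ in range(n_introns + 1)
        ]
        intron_seqs: list[str] = []
        bp_offsets: list[int] = []
        classes: list[str] = []
        for i in range(n_introns):
            # only the first intron of a U12 gene is minor class
            icls = "U12" if (is_u12 and i == 0) else "U2"
            for _attempt in range(50):
                ilen = int(rng.integers(lo, hi + 1))
                iseq, bp_off = _make_intron(
                    rng, ilen, icls, comp, u12_five_ss, bp_tail_distance, ppt_purity
                )
                if iseq[:20] not in seen_five_ss:
                    break
            else:  # pragma: no cover - vanishingly unlikely
                raise RuntimeError("could not draw a unique intron 5'SS 20-mer")
            seen_five_ss.add(iseq[:20])
            intron_seqs.append(iseq)
            bp_offsets.append(bp_off)
            classes.append(icls)

        tx_parts = []
        for i in range(n_introns):
            tx_parts.append(exon_seqs[i])
            tx_parts.append(intron_seqs[i])
        tx_parts.append(exon_seqs[-1])
        gene_seq_tx = "".join(tx_parts)
        gene_genomic = gene_seq_tx if strand == "+" else revcomp(gene_seq_tx)

        # transcript-order feature intervals -> genomic intervals
        feat, acc = [], 0
        for i, part in enumerate(tx_parts):
            feat.append((acc, acc + len(part), "exon" if i % 2 == 0 else "intron"))
            acc += len(part)
        gene_len = acc

        def tx_to_genomic(iv):
            s, e = iv
            if strand == "+":
                return offset + s, offset + e
            return offset + gene_len - e, offset + gene_len - s

        exon_ivs, intron_ivs = [], []
        for s, e, kind in feat:
            (exon_ivs if kind == "exon" else intron_ivs).append(tx_to_genomic((s, e)))
        exon_ivs.sort()

        intron_ids = []
        for i, (gs, ge) in enumerate(intron_ivs):
            iid = f"{gene_id}.i{i}"
            intron_ids.append(iid)
            iseq = intron_seqs[i]
            introns.append(
                IntronRecord(
                    intron_id=iid,
                    gene_id=gene_id,
                    contig=contig,
                    start=gs,
                    end=ge,
                    strand=strand,
                    intron_class=classes[i],
                    five_ss_seq=iseq[:20],
                    three_tail_seq=iseq[-250:],
                    true_bp_offset=bp_offsets[i],
                )
            )
        genes.append(GeneModel(gene_id, contig, strand, sorted(exon_ivs), intron_ids))

        parts.append(gene_genomic)
        parts.append(random_seq(rng, int(rng.integers(*intergenic_len_range))))

    genome = ToyGenome({c: "".join(p) for c, p in contigs.items()})
    # sanity: annotated windows are exact genome substrings
    for intr in introns:
        assert intr.seq(genome)[:20] == intr.five_ss_seq
    return genome, introns, genes


# ---------------------------------------------------------------------------
# abundance under debranching kinetics
# ---------------------------------------------------------------------------


def simulate_lariat_abundance(
    introns: list[IntronRecord],
    expression: dict[str, float] | float,
    kinetics: DebranchKinetics,
    seed: int | None = None,
    genome: ToyGenome | None = None,
) -> pd.DataFrame:
    """Expected and (optionally Poisson-sampled) lariat read counts per intron.

    The debranching-null condition sees the full expression; the active
    condition sees expression x survival(branch base, 5'SS motif).  When a
    seed is given, Poisson sampling is applied to both conditions.
    """
    rows = []
    for intr in introns:
        expr = expression if isinstance(expression, (int, float)) else expression.get(intr.intron_id, 0.0)
        if expr < 0:
            raise ValueError(f"negative expression for {intr.intron_id}")
        if intr.true_bp_offset is None:
            raise ValueError(f"{intr.intron_id} has no planted branchpoint")
        if genome is not None:
            bb = genome.base(intr.contig, intr.rel_to_genomic(intr.true_bp_offset), intr.strand)
        else:
            bb = intr.three_tail_seq[intr.true_bp_offset - (intr.length - len(intr.three_tail_seq))]
        surv = replace(kinetics, condition="active").survival(intr, bb)
        rows.append((intr.intron_id, bb, expr, expr * surv))
    df = pd.DataFrame(rows, columns=["intron_id", "branch_base", "expected_null", "expected_active"])
    df = df.set_index("intron_id")
    if seed is not None:
        rng = np.random.default_rng(seed)
        df["null"] = rng.poisson(df["expected_null"].to_numpy())
        df["active"] = rng.poisson(df["expected_active"].to_numpy())
    else:
        df["null"] = df["expected_null"]
        df["active"] = df["expected_active"]
    return df


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class ErrorModel:
    """Per-base read noise plus reverse-transcriptase branch readthrough.

    ``rt_branch_misincorporation`` is the probability of a substitution at
    the branch nucleotide itself -- the first template base copied after the
    reverse transcriptase crosses the 2'-5' branch linkage.
    """

    sub_rate: float = 0.0
    n_rate: float = 0.0
    indel_rate: float = 0.0
    rt_branch_misincorporation: float = 0.0

    def apply(self, seq: str, rng) -> str:
        if self.sub_rate == 0 and self.n_rate == 0 and self.indel_rate == 0:
            return seq
        out = []
        for ch in seq:
            r = rng.random()
            if r < self.indel_rate / 2:
                continue  # deletion
            if r < self.indel_rate:
                out.append(random_seq(rng, 1))  # insertion before the base
            r = rng.random()
            if r < self.sub_rate:
                choices = [b for b in "ACGT" if b != ch]
                out.append(rng.choice(choices))
            elif r < self.sub_rate + self.n_rate:
                out.append("N")
            else:
                out.append(ch)
        return "".join(out)


NOISE_FREE = ErrorModel()


def _substitute(rng, base: str) -> str:
    return rng.choice([b for b in "ACGT" if b != base])


def simulate_reads(
    genome: ToyGenome,
    introns: list[IntronRecord],
    counts: dict[str, dict[str, int]],
    read_len: int = 50,
    error_model: ErrorModel = NOISE_FREE,
    seed: int = 0,
    *,
    genes: list[GeneModel] | None = None,
    min_block: int = 1,
    quality_char: str = "?",  # Phred+33 Q30
) -> tuple[list[SimRead], TruthTable]:
    """Simulate reads of the four classes with ground truth.

    ``counts`` maps read class -> {source id: n reads}; lariat and
    intron_circle sources are intron ids, linear_mRNA and pre_mRNA sources
    are gene ids.  Lariat reads are built as
    ``[intron sequence ending at the branch nucleotide][intron sequence
    starting at position 0]`` with the junction uniform along the read
    subject to both blocks >= ``min_block`` nt.
    """
    if read_len < 40:
        raise ValueError("read_len must be >= 40")
    if min_block < 1:
        raise ValueError("min_block must be >= 1")
    if 2 * min_block > read_len:
        raise ValueError("min_block leaves no valid junction placement")
    # separate streams so per-base noise does not perturb read placements
    rng, noise_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    )
    imap = {i.intron_id: i for i in introns}
    gmap = {g.gene_id: g for g in (genes or [])}

    reads: list[SimRead] = []
    truth_rows: list[tuple] = []
    serial = 0

    def emit(seq: str, cls: str, gene_id: str | None, intron_id: str | None, bp: int | None):
        nonlocal serial
        rid = f"r{serial:07d}_{cls}"
        serial += 1
        seq = error_model.apply(seq, noise_rng)
        reads.append(SimRead(rid, seq, quality_char * len(seq)))
        truth_rows.append((rid, cls, gene_id, intron_id, bp))

    for cls, per_source in counts.items():
        if cls not in READ_CLASSES:
            raise ValueError(f"unknown read class {cls!r}")
        for source, n in per_source.items():
            for _ in range(int(n)):
                if cls == "lariat":
                    intr = imap[source]
                    s = intr.seq(genome)
                    bp = intr.true_bp_offset
                    j_hi = min(read_len - min_block, bp + 1)
                    j_lo = max(min_block, read_len - len(s))
                    if j_lo > j_hi:
                        raise ValueError(
                            f"no junction placement for {source}: both blocks would "
                            f"not fit in a {read_len} nt read"
                        )
                    j = int(rng.integers(j_lo, j_hi + 1))
                    block1 = s[bp + 1 - j : bp + 1]
                    block2 = s[0 : read_len - j]
                    seq = block1 + block2
                    if (
                        error_model.rt_branch_misincorporation > 0
                        and noise_rng.random() < error_model.rt_branch_misincorporation
                    ):
                        seq = seq[: j - 1] + _substitute(noise_rng, seq[j - 1]) + seq[j:]
                    emit(seq, cls, intr.gene_id, source, intr.rel_to_genomic(bp))
                elif cls == "intron_circle":
                    intr = imap[source]
                    s = intr.seq(genome)
                    j_hi = min(read_len - min_block, len(s))
                    j_lo = max(min_block, read_len - len(s))
                    j = int(rng.integers(j_lo, j_hi + 1))
                    seq = s[len(s) - j :] + s[0 : read_len - j]
                    emit(seq, cls, intr.gene_id, source, None)
                else:
                    gene = gmap.get(source)
                    if gene is None:
                        raise ValueError(f"gene model for {source!r} not supplied")
                    tx = gene.spliced_seq(genome) if cls == "linear_mRNA" else gene.unspliced_seq(genome)
                    if len(tx) < read_len:
                        raise ValueError(f"transcript of {source} shorter than read length")
                    start = int(rng.integers(0, len(tx) - read_len + 1))
                    emit(tx[start : start + read_len], cls, source, None, None)

    truth = TruthTable(
        pd.DataFrame(
            truth_rows, columns=["read_id", "read_class", "gene_id", "intron_id", "bp_genomic"]
        )
    )
    assert len(truth.reads) == len(reads)
    return reads, truth


def uniform_counts(ids: list[str], total: int) -> dict[str, int]:
    """Spread *total* reads evenly (remainder to the first ids)."""
    n = len(ids)
    base, rem = divmod(total, n)
    return {x: base + (1 if i < rem else 0) for i, x in enumerate(ids)}


# ---------------------------------------------------------------------------
# eCLIP-style binding sites
# ---------------------------------------------------------------------------


def simulate_eclip_sites(
    introns: list[IntronRecord],
    rbp: str,
    bound_fraction: float,
    placement: str = "near_bp",
    seed: int = 0,
    *,
    site_len: int = 20,
    max_circular_distance: int = 50,
) -> pd.DataFrame:
    """BED6-style binding sites inside introns.

    ``near_bp`` placement concentrates site midpoints within
    ``max_circular_distance`` nt of the planted branchpoint along the
    circular lariat topology; ``uniform`` scatters midpoints uniformly.
    """
    if not (0.0 <= bound_fraction <= 1.0):
        raise ValueError("bound_fraction must be in [0, 1]")
    if placement not in ("near_bp", "uniform"):
        raise ValueError("placement must be 'near_bp' or 'uniform'")
    rng = np.random.default_rng(seed)
    n_bound = int(round(bound_fraction * len(introns)))
    chosen = (
        list(rng.choice(len(introns), size=n_bound, replace=False)) if n_bound else []
    )
    half = site_len // 2
    rows = []
    for idx in sorted(chosen):
        intr = introns[idx]
        L = intr.length
        if placement == "uniform":
            x = int(rng.integers(half, L - half))
        else:
            bp = intr.true_bp_offset
            if bp is None:
                raise ValueError(f"{intr.intron_id} has no planted branchpoint")
            d = int(rng.integers(0, max_circular_distance + 1))
            arm = rng.choice(["loop_upstream", "through_junction", "tail"])
            if arm == "loop_upstream":
                x = bp - d
            elif arm == "through_junction":
                x = d - 1 if d >= 1 else bp
            else:
                x = bp + d
            x = int(np.clip(x, half, L - half - 1))
        g_mid = intr.rel_to_genomic(x)
        start = max(intr.start, g_mid - half)
        end = min(intr.end, g_mid + site_len - half)
        rows.append((intr.contig, start, end, rbp, 0, intr.strand))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name", "score", "strand"])


# ---------------------------------------------------------------------------
# count-table fixtures (reporter assay, editing, spectral counts)
# ---------------------------------------------------------------------------


def simulate_mpra_counts(
    true_efficiency: dict[str, float],
    depth: int,
    seed: int = 0,
    *,
    n_barcode_pairs: int = 4,
    replicates: int = 1,
) -> pd.DataFrame:
    """Input/output reporter counts for hexamers with known efficiencies.

    Input counts are multinomial over species at uniform proportions; output
    counts are multinomial with probabilities proportional to
    input x true efficiency.  Deterministic per seed.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    hexamers = list(true_efficiency)
    species = [
        (f"{h}_bc{b}", h, b) for h in hexamers for b in range(n_barcode_pairs)
    ]
    eff = np.array([true_efficiency[h] for _, h, _ in species], dtype=float)
    if (eff < 0).any():
        raise ValueError("efficiencies must be >= 0")
    rows = []
    for rep in range(replicates):
        inp = rng.multinomial(depth, np.full(len(species), 1.0 / len(species)))
        p_out = inp * eff
        p_out = p_out / p_out.sum()
        out = rng.multinomial(depth, p_out)
        for (sid, h, b), i_j, o_j in zip(species, inp, out):
            rows.append((sid, h, b, rep + 1, int(i_j), int(o_j)))
    return pd.DataFrame(
        rows,
        columns=["species_id", "hexamer", "barcode_pair", "replicate", "input_count", "output_count"],
    )


def simulate_editing_counts(
    true_rates: dict[str, float],
    background_rate: float,
    n_bases: int | dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial A-to-G edited-base counts per condition at rate background+signal."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond, signal in true_rates.items():
        rate = background_rate + signal
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"total editing rate for {cond} outside [0, 1]")
        n = n_bases[cond] if isinstance(n_bases, dict) else n_bases
        rows.append((cond, int(rng.binomial(n, rate)), int(n)))
    return pd.DataFrame(rows, columns=["condition", "edited", "total"])


def simulate_spectral_counts(
    true_hits: list[str],
    seed: int = 0,
    *,
    n_background: int = 50,
    hit_ip_mean: float = 20.0,
    hit_ctrl_mean: float = 0.3,
    background_mean: float = 5.0,
) -> pd.DataFrame:
    """Spectral-count table: 3 control + 3 IP replicates per protein.

    ``true_hits`` are enriched in the IP and near-absent in controls;
    background proteins appear equally in both.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name in true_hits:
        ctrl = rng.poisson(hit_ctrl_mean, 3)
        ip = rng.poisson(hit_ip_mean, 3)
        rows.append((name, *ctrl, *ip, True))
    for i in range(n_background):
        ctrl = rng.poisson(background_mean, 3)
        ip = rng.poisson(background_mean, 3)
        rows.append((f"bg{i:03d}", *ctrl, *ip, False))
    return pd.DataFrame(
        rows,
        columns=["protein", "ctrl1", "ctrl2", "ctrl3", "ip1", "ip2", "ip3", "true_hit"],
    )
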