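"""Readers/writers for the toolkit's external formats, plus run configuration.

FASTA/FASTQ pass through Biopython; BED and TSV tables through pandas with
validation that names the offending line.  All coordinates are 0-based
half-open (BED convention).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic import IntronRecord, SimRead, ToyGenome

INTRON_COLUMNS = [
    "intron_id", "gene_id", "contig", "start", "end", "strand",
    "intron_class", "five_ss_seq", "three_tail_seq", "true_bp_offset",
]

BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path) -> ToyGenome:
    contigs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{path}: contig {rec.id} has non-ACGTN characters {sorted(bad)}")
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"{path}: no FASTA records")
    return ToyGenome(contigs)


def write_fasta(genome: ToyGenome, path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in genome.contigs.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> list[SimRead]:
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(SimRead(rec.id, str(rec.seq).upper(), qual))
    except ValueError as e:
        raise ValueError(f"{path}: malformed FASTQ ({e})") from e
    return reads


def write_fastq(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if len(r.seq) != len(r.quality):
                raise ValueError(f"read {r.read_id}: sequence/quality length mismatch")
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------


def read_bed(path, genome: ToyGenome | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :6]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.end <= row.start:
            raise ValueError(f"{path} line {i}: end <= start")
        if genome is not None:
            if row.contig not in genome.contigs:
                raise ValueError(f"{path} line {i}: unknown contig {row.contig!r}")
            if row.end > genome.length(row.contig):
                raise ValueError(f"{path} line {i}: interval beyond contig end")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_introns(introns: list[IntronRecord], path) -> None:
    rows = [
        [i.intron_id, i.gene_id, i.contig, i.start, i.end, i.strand,
         i.intron_class, i.five_ss_seq, i.three_tail_seq,
         -1 if i.true_bp_offset is None else i.true_bp_offset]
        for i in introns
    ]
    write_tsv(pd.DataFrame(rows, columns=INTRON_COLUMNS), path)


def read_introns(path) -> list[IntronRecord]:
    df = read_tsv(path)
    missing = set(INTRON_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing intron columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        off = None if row.true_bp_offset < 0 else int(row.true_bp_offset)
        out.append(IntronRecord(
            row.intron_id, row.gene_id, row.contig, int(row.start), int(row.end),
            row.strand, row.intron_class, row.five_ss_seq, row.three_tail_seq, off,
        ))
    return out


def write_calls(calls, path) -> None:
    rows = []
    for c in calls:
        rows.append({
            "read_id": c.read_id,
            "intron_id": c.intron_id or "",
            "gene_id": c.gene_id or "",
            "bp_position": -1 if c.bp_position is None else c.bp_position,
            "bp_base": c.bp_base or "",
            "mapper": c.mapper,
            "filtered_reason": c.filtered_reason,
        })
    write_tsv(pd.DataFrame(rows), path)


def write_branchpoint_bed(table, introns, path) -> None:
    """Branchpoints as BED6: name=intron_id, score=read support."""
    by_id = {i.intron_id: i for i in introns}
    rows = []
    for r in table.counts.itertuples(index=False):
        intr = by_id[r.intron_id]
        rows.append([intr.contig, r.bp_position, r.bp_position + 1,
                     r.intron_id, r.support, intr.strand])
    write_bed(pd.DataFrame(rows, columns=BED_COLUMNS), path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of the end-to-end knockout-vs-wildtype workflow.

    Every stochastic stage derives its seed from ``seed``; re-running with
    the same config reproduces the report byte for byte.
    """

    seed: int = 1
    out_dir: str = "lariatkit_run"
    # synthetic genome
    n_genes: int = 60
    introns_per_gene: int = 2
    intron_len_range: tuple[int, int] = (300, 600)
    u12_fraction: float = 0.0
    # kinetics
    base_survival: float = 0.05
    branch_rates: dict = field(default_factory=lambda: {"A": 1.0, "C": 1.0, "G": 1.0, "T": 1.0})
    five_ss_g_modifier: float = 1.0
    # reads
    read_len: int = 60
    min_block: int = 16
    lariat_reads_null: int = 4000
    linear_reads: int = 2000
    pre_mrna_reads: int = 500
    circle_reads: int = 100
    sub_rate: float = 0.0
    rt_branch_misincorporation: float = 0.0
    # mapper thresholds
    min_segment: int = 16
    circle_tolerance: int = 2
    max_mismatch: int = 5
    max_mismatch_rate: float = 0.10
    max_indel_len: int = 3
    # analytics
    pseudocount: float = 0.5
    logo_window: int = 11
    conditions: tuple[str, str] = ("KO", "WT")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("intron_len_range", "conditions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if not Path(self.out_dir).parent.exists():
            raise ValueError(f"parent of out_dir {self.out_dir!r} does not exist")
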