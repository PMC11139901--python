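"""Descriptive and comparative statistics over branchpoint tables.

Normalization convention: the lariat recovery rate is lariat reads per
million linearly mapped reads; all fold-change contrasts are computed on
these per-million-normalized levels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import BranchpointTable, LariatCall
from .synthetic import GeneModel, IntronRecord, SimRead, ToyGenome

logger = logging.getLogger(__name__)


@dataclass
class SampleStats:
    sample_id: str
    condition: str
    n_lariat: int
    n_mapped: int

    @property
    def recovery_rate(self) -> float:
        return recovery_rate(self.n_lariat, self.n_mapped)


def recovery_rate(n_lariat: int, n_mapped: int) -> float:
    """Lariat reads per million linearly mapped reads (exact ratio x 1e6)."""
    if n_mapped <= 0:
        raise ValueError("n_mapped must be > 0")
    return n_lariat / n_mapped * 1e6


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------


def _normalized_intron_levels(table: BranchpointTable) -> pd.Series:
    """Per-intron lariat level in reads per million mapped."""
    if table.n_mapped <= 0:
        raise ValueError("branchpoint table lacks a mapped-read total")
    return table.intron_counts() / table.n_mapped * 1e6


def fold_change(
    table_a: BranchpointTable,
    table_b: BranchpointTable,
    level: str = "intron",
    pseudocount: float = 0.5,
    intron_set: list[str] | None = None,
) -> pd.DataFrame | float:
    """Fold change in normalized lariat levels, A over B.

    At ``level='intron'`` returns a frame with per-intron normalized levels
    and (a_norm + pc) / (b_norm + pc).  At ``level='set'`` the normalized
    levels are summed over the set (default: all introns seen) before the
    ratio; no pseudocount is applied there.
    """
    na = _normalized_intron_levels(table_a)
    nb = _normalized_intron_levels(table_b)
    idx = sorted(set(na.index) | set(nb.index))
    if intron_set is not None:
        idx = [i for i in idx if i in set(intron_set)]
    na = na.reindex(idx, fill_value=0.0)
    nb = nb.reindex(idx, fill_value=0.0)
    if level == "set":
        sa, sb = float(na.sum()), float(nb.sum())
        if sa == 0 and sb == 0:
            raise ValueError("both conditions have zero lariat signal in the set")
        return sa / sb if sb > 0 else np.inf
    if level != "intron":
        raise ValueError("level must be 'intron' or 'set'")
    out = pd.DataFrame({"a_norm": na, "b_norm": nb})
    out["fold_change"] = (out["a_norm"] + pseudocount) / (out["b_norm"] + pseudocount)
    out.attrs["pseudocount"] = pseudocount
    return out


def u12_u2_contrast(
    fold_changes: pd.DataFrame, introns: list[IntronRecord]
) -> dict[str, float]:
    """Mean fold change of U12 introns vs U2 introns from U12-hosting genes.

    Returns the two class means and their ratio (U12 / U2)."""
    cls = {i.intron_id: i.intron_class for i in introns}
    gene = {i.intron_id: i.gene_id for i in introns}
    u12_ids = [i for i in fold_changes.index if cls.get(i) == "U12"]
    u12_genes = {gene[i] for i in u12_ids}
    u2_ids = [
        i for i in fold_changes.index
        if cls.get(i) == "U2" and gene.get(i) in u12_genes
    ]
    if not u12_ids or not u2_ids:
        raise ValueError("both U12 and same-gene U2 introns are required")
    m12 = float(fold_changes.loc[u12_ids, "fold_change"].mean())
    m2 = float(fold_changes.loc[u2_ids, "fold_change"].mean())
    return {"mean_u12": m12, "mean_u2": m2, "ratio": m12 / m2,
            "n_u12": len(u12_ids), "n_u2": len(u2_ids)}


# ---------------------------------------------------------------------------
# branch composition and sequence logos
# ---------------------------------------------------------------------------


def bp_composition(calls: list[LariatCall], genome: ToyGenome | None = None) -> pd.Series:
    """Fractions of {A,C,G,T} at the genomic branch base of unfiltered calls.

    The branch base is taken from the genome (strand-corrected), not from
    the read, because reverse transcription across the branch is unreliable.
    """
    passed = [c for c in calls if c.passed]
    if not passed:
        raise ValueError("no unfiltered calls")
    counts = pd.Series(0, index=list("ACGT"), dtype=float)
    for c in passed:
        counts[c.bp_base] += 1
    return counts / counts.sum()


def _window_seq(genome: ToyGenome, intron: IntronRecord, rel_anchor: int,
                up: int, down: int) -> str | None:
    """Strand-corrected window [anchor-up, anchor+down] around an
    intron-relative anchor; None if it leaves the contig."""
    lo = intron.rel_to_genomic(rel_anchor - up)
    hi = intron.rel_to_genomic(rel_anchor + down)
    start, end = (lo, hi + 1) if intron.strand == "+" else (hi, lo + 1)
    if start < 0 or end > genome.length(intron.contig):
        return None
    return genome.fetch(intron.contig, start, end, intron.strand)


def build_logo_pfm(
    calls: list[LariatCall],
    genome: ToyGenome,
    introns: list[IntronRecord],
    anchor: str = "bp",
    window: tuple[int, int] = (5, 5),
    restrict_single_bp: bool = False,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Position frequency matrix of sequences around branchpoints or 5'SSs.

    ``anchor='bp'`` stacks one window per distinct (intron, branchpoint);
    ``restrict_single_bp`` keeps only introns with a single recovered
    branchpoint.  ``anchor='five_ss'`` stacks the 5'SS window of the top
    ``top_n`` introns ranked by lariat read count (ties broken by intron id
    for determinism).  Columns sum to 1.
    """
    by_id = {i.intron_id: i for i in introns}
    passed = [c for c in calls if c.passed]
    if not passed:
        raise ValueError("no unfiltered calls to stack")
    up, down = window

    seqs: list[str] = []
    if anchor == "bp":
        support = {}
        for c in passed:
            support[(c.intron_id, c.bp_position)] = support.get((c.intron_id, c.bp_position), 0) + 1
        if restrict_single_bp:
            per_intron = pd.Series([k[0] for k in support]).value_counts()
            keep = set(per_intron[per_intron == 1].index)
            support = {k: v for k, v in support.items() if k[0] in keep}
        for iid, bp in sorted(support):
            intr = by_id[iid]
            s = _window_seq(genome, intr, intr.genomic_to_rel(bp), up, down)
            if s is not None:
                seqs.append(s)
    elif anchor == "five_ss":
        per_intron = pd.Series([c.intron_id for c in passed]).value_counts()
        ranked = sorted(per_intron.index, key=lambda i: (-per_intron[i], i))
        if top_n is not None:
            if top_n > len(ranked):
                warnings.warn(
                    f"requested top {top_n} introns but only {len(ranked)} available"
                )
            ranked = ranked[:top_n]
        for iid in ranked:
            s = _window_seq(genome, by_id[iid], 0, up, down)
            if s is not None:
                seqs.append(s)
    else:
        raise ValueError("anchor must be 'bp' or 'five_ss'")

    if not seqs:
        raise ValueError("no sequences available for the logo")
    return pfm_from_sequences(seqs)


def render_logo(pfm: pd.DataFrame, path, title: str = "") -> None:
    """Render a PFM as a simple information-content sequence logo (SVG/PNG).

    Letter heights are the column information content (2 - entropy, bits)
    split by base frequency; adequate for inspecting toy-scale logos.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    freqs = pfm.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(np.where(freqs > 0, freqs * np.log2(freqs), 0.0), axis=0)
    ic = 2.0 - ent
    fig, ax = plt.subplots(figsize=(0.45 * pfm.shape[1] + 1, 2.2))
    for j in range(pfm.shape[1]):
        bottom = 0.0
        order = np.argsort(freqs[:, j])
        for i in order:
            h = freqs[i, j] * ic[j]
            if h <= 0:
                continue
            base = pfm.index[i]
            ax.bar(j, h, bottom=bottom, width=0.9, color=colors[base],
                   edgecolor="none")
            if h > 0.15:
                ax.text(j, bottom + h / 2, base, ha="center", va="center",
                        fontsize=9, fontweight="bold", color="white")
            bottom += h
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xlabel("position")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def pfm_from_sequences(seqs: list[str]) -> pd.DataFrame:
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("sequences must share a common width")
    mat = np.zeros((4, width))
    idx = {b: i for i, b in enumerate("ACGT")}
    for s in seqs:
        for j, ch in enumerate(s):
            if ch in idx:
                mat[idx[ch], j] += 1
    col = mat.sum(axis=0)
    col[col == 0] = 1.0
    pfm = pd.DataFrame(mat / col, index=list("ACGT"))
    assert np.allclose(pfm.sum(axis=0), 1.0, atol=1e-9)
    return pfm


# ---------------------------------------------------------------------------
# positional enrichment (chi-square built from the textbook formula)
# ---------------------------------------------------------------------------


def pearson_chi2_2x2(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, statistic from sum((O-E)^2/E).

    Yates continuity correction optional; p from the chi-square distribution
    with 1 df.  Raises on a zero margin.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in contingency table")
    exp = np.outer(rows, cols) / obs.sum()
    diff = np.abs(obs - exp)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / exp).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def position_enrichment(
    calls_a: list[LariatCall],
    calls_b: list[LariatCall],
    genome: ToyGenome,
    introns: list[IntronRecord],
    position: int,
    base: str,
    correction: bool = False,
) -> dict[str, float]:
    """2x2 chi-square of base-vs-other at a 1-based intron position, A vs B.

    Position 1 is the first intron base; the base is read strand-corrected
    from the genome for each call's intron.
    """
    by_id = {i.intron_id: i for i in introns}

    def counts(calls):
        yes = no = 0
        for c in calls:
            if not c.passed:
                continue
            intr = by_id[c.intron_id]
            b = genome.base(intr.contig, intr.rel_to_genomic(position - 1), intr.strand)
            if b == base:
                yes += 1
            else:
                no += 1
        return yes, no

    ya, na = counts(calls_a)
    yb, nb = counts(calls_b)
    if (ya + na) == 0 or (yb + nb) == 0:
        raise ValueError("both call sets must be non-empty")
    stat, p = pearson_chi2_2x2(np.array([[ya, na], [yb, nb]]), correction)
    return {"statistic": stat, "p": p, "frac_a": ya / (ya + na), "frac_b": yb / (yb + nb)}


# ---------------------------------------------------------------------------
# spliced / unspliced ratio
# ---------------------------------------------------------------------------


def spliced_unspliced_ratio(
    reads: list[SimRead],
    genome: ToyGenome,
    genes: list[GeneModel],
    introns: list[IntronRecord],
    overhang: int = 6,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-intron ratio of exon-exon junction reads to intron-boundary reads.

    A read counts as spliced for an intron when it spans that intron's
    exon-exon junction with >= ``overhang`` nt on each side of the junction
    in the spliced transcript, and as unspliced when it spans either the
    exon-intron or intron-exon boundary likewise in the pre-mRNA.  Reads are
    located by exact substring match against the transcript models (read or
    reverse complement).  Introns with no overlapping reads are excluded.
    """
    from ._seq import revcomp

    spliced = {g.gene_id: g.spliced_seq(genome) for g in genes}
    unspliced = {g.gene_id: g.unspliced_seq(genome) for g in genes}
    junctions = {g.gene_id: g.junction_offsets(genome) for g in genes}
    boundaries = {g.gene_id: g.boundary_offsets(genome) for g in genes}
    gene_introns = {g.gene_id: g.intron_ids for g in genes}

    s_counts: dict[str, int] = {}
    u_counts: dict[str, int] = {}
    for read in reads:
        for seq in (read.seq, revcomp(read.seq)):
            hit = False
            for gid, tx in spliced.items():
                p = tx.find(seq)
                while p != -1:
                    for k, j in enumerate(junctions[gid]):
                        if p + overhang <= j <= p + len(seq) - overhang:
                            iid = gene_introns[gid][k]
                            s_counts[iid] = s_counts.get(iid, 0) + 1
                            hit = True
                    p = tx.find(seq, p + 1)
            for gid, tx in unspliced.items():
                p = tx.find(seq)
                while p != -1:
                    for k, (b5, b3) in enumerate(boundaries[gid]):
                        span = False
                        for b in (b5, b3):
                            if p + overhang <= b <= p + len(seq) - overhang:
                                span = True
                        if span:
                            iid = gene_introns[gid][k]
                            u_counts[iid] = u_counts.get(iid, 0) + 1
                            hit = True
                    p = tx.find(seq, p + 1)
            if hit:
                break  # orientation resolved
    ids = sorted(set(s_counts) | set(u_counts))
    skipped = [i.intron_id for i in introns if i.intron_id not in set(ids)]
    if skipped:
        logger.info("spliced/unspliced: %d introns with no junction reads excluded",
                    len(skipped))
    rows = [
        (iid, s_counts.get(iid, 0), u_counts.get(iid, 0),
         s_counts.get(iid, 0) / (u_counts.get(iid, 0) + pseudocount))
        for iid in ids
    ]
    return pd.DataFrame(rows, columns=["intron_id", "spliced", "unspliced", "ratio"])


# ---------------------------------------------------------------------------
# functional-score annotation
# ---------------------------------------------------------------------------


def annotate_functional_score(
    bp_positions: list[tuple[str, int]],
    score_track: dict[str, np.ndarray],
    window: int = 11,
) -> pd.Series:
    """Maximum score-track value in an odd window centered on each branchpoint.

    Windows are truncated (with a warning) at contig edges; positions with a
    fully absent track yield NaN.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    half = window // 2
    out = {}
    for contig, pos in bp_positions:
        track = score_track[contig]
        lo, hi = pos - half, pos + half + 1
        if lo < 0 or hi > len(track):
            warnings.warn(f"window truncated at contig edge for {contig}:{pos}")
            lo, hi = max(0, lo), min(len(track), hi)
        vals = track[lo:hi]
        finite = vals[np.isfinite(vals)]
        out[(contig, pos)] = float(finite.max()) if finite.size else np.nan
    return pd.Series(out)
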