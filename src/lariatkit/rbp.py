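"""eCLIP-interval conditioning of lariat levels and motif analysis.

"Bound" introns fully contain at least one binding site of the RBP of
interest; the control pool holds introns with no site of any analyzed RBP.
Distances from binding sites to branchpoints are measured along the
circular topology of the lariat: a site just downstream of the 5' splice
site is close to the branchpoint via the 2'-5' branch junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import encode, revcomp
from .analytics import fold_change
from .mapping import BranchpointTable
from .synthetic import IntronRecord, ToyGenome

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# intron partitioning and control sampling
# ---------------------------------------------------------------------------


def _contained(site, intr: IntronRecord) -> bool:
    return (
        site.contig == intr.contig
        and site.start >= intr.start
        and site.end <= intr.end
    )


def partition_introns(
    sites: pd.DataFrame,
    introns: list[IntronRecord],
    rbp: str,
    partial_overlap: bool = False,
) -> tuple[list[str], list[str]]:
    """Split introns into (bound by *rbp*, pool with no site of any RBP).

    A site is assigned to an intron only when fully contained in it (a site
    spanning an intron boundary does not bind the intron); set
    ``partial_overlap`` to relax to any overlap.
    """
    bound: set[str] = set()
    touched: set[str] = set()  # introns with a site of ANY analyzed RBP
    for site in sites.itertuples(index=False):
        for intr in introns:
            if site.contig != intr.contig:
                continue
            if partial_overlap:
                inside = site.start < intr.end and site.end > intr.start
            else:
                inside = _contained(site, intr)
            if inside:
                touched.add(intr.intron_id)
                if site.name == rbp:
                    bound.add(intr.intron_id)
    pool = [i.intron_id for i in introns if i.intron_id not in touched]
    return sorted(bound), pool


def sample_controls(
    bound: list[str],
    pool: list[str],
    mode: str = "size_matched",
    seed: int = 0,
    introns: list[IntronRecord] | None = None,
) -> list[str]:
    """Control introns for an enrichment contrast.

    ``size_matched`` samples |bound| introns from the pool without
    replacement (deterministic per seed); ``same_gene`` returns every pool
    intron whose gene also hosts a bound intron.
    """
    if mode == "size_matched":
        if len(pool) < len(bound):
            raise ValueError("control pool smaller than the bound set")
        rng = np.random.default_rng(seed)
        return sorted(np.array(pool, dtype=object)[
            rng.choice(len(pool), size=len(bound), replace=False)
        ])
    if mode == "same_gene":
        if introns is None:
            raise ValueError("same_gene mode requires the intron annotation")
        gene = {i.intron_id: i.gene_id for i in introns}
        bound_genes = {gene[i] for i in bound}
        return sorted(i for i in pool if gene.get(i) in bound_genes)
    raise ValueError("mode must be 'size_matched' or 'same_gene'")


# ---------------------------------------------------------------------------
# enrichment contrast (Welch t built from the textbook formula)
# ---------------------------------------------------------------------------


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sided t-test: statistic, degrees of freedom, p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return 0.0, float(nx + ny - 2), 1.0
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def enrichment_contrast(
    bound: list[str],
    control: list[str],
    table_ko: BranchpointTable,
    table_wt: BranchpointTable,
    pseudocount: float = 0.5,
) -> dict[str, float]:
    """Compare per-intron KO/WT lariat enrichment between bound and control
    introns (two-sided Welch t-test on log2 fold changes)."""
    fc = fold_change(table_ko, table_wt, level="intron", pseudocount=pseudocount)
    fc_all = fc["fold_change"]

    def levels(ids):
        vals = fc_all.reindex(ids)
        # introns never seen in either sample have fold change 1 (pc/pc)
        return np.log2(vals.fillna(1.0).to_numpy())

    xb, xc = levels(bound), levels(control)
    t, df, p = welch_t(xb, xc)
    return {
        "mean_bound": float(xb.mean()),
        "mean_control": float(xc.mean()),
        "difference": float(xb.mean() - xc.mean()),
        "t": t,
        "df": df,
        "p": p,
        "n_bound": len(xb),
        "n_control": len(xc),
    }


# ---------------------------------------------------------------------------
# circular branchpoint distance
# ---------------------------------------------------------------------------


def circular_bp_distance(
    site: tuple[int, int], intron: IntronRecord, bp_position: int
) -> int:
    """Distance (nt) from a binding site to the branchpoint along the lariat.

    The site is summarized by its midpoint x (intron-relative, transcript
    orientation).  Within the loop (x <= branch offset B) the distance is
    the shorter of the direct upstream path (B - x) and the path through the
    branch junction past the 5'SS (x + 1); in the tail it is x - B.
    """
    start, end = site
    if start < intron.start or end > intron.end:
        raise ValueError("site not contained in the intron")
    mid_genomic = (start + end - 1) // 2
    x = intron.genomic_to_rel(mid_genomic)
    b = intron.genomic_to_rel(bp_position)
    if not (0 <= b < intron.length):
        raise ValueError("branchpoint outside the intron")
    if x <= b:
        return min(b - x, x + 1)
    return x - b


# ---------------------------------------------------------------------------
# motif construction and scanning
# ---------------------------------------------------------------------------


@dataclass
class MotifPFM:
    pfm: pd.DataFrame  # rows A/C/G/T, columns sum to 1
    kmers: list[tuple[str, int]]  # aligned (kmer, offset) pairs

    @property
    def width(self) -> int:
        return self.pfm.shape[1]

    def log_odds(self, pseudo: float = 1e-3) -> np.ndarray:
        f = self.pfm.to_numpy()
        return np.log2((f + pseudo) / (0.25 + pseudo))


def _kmer_counts(seqs: list[str], k: int) -> pd.Series:
    counts: dict[str, int] = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= set("ACGT"):
                counts[w] = counts.get(w, 0) + 1
    return pd.Series(counts, dtype=float).sort_index()


def _best_overlap_offset(seed: str, kmer: str) -> int:
    """Offset of *kmer* relative to *seed* maximizing agreeing overlap;
    ties prefer the smallest |offset|, then the negative one."""
    k = len(seed)
    best = (-1, 0)
    for off in sorted(range(-(k - 1), k), key=lambda o: (abs(o), o)):
        lo, hi = max(0, off), min(k, k + off)
        agree = sum(
            1 for i in range(lo, hi) if seed[i] == kmer[i - off]
        )
        if agree > best[0]:
            best = (agree, off)
    return best[1]


def build_motif(
    site_seqs: list[str],
    k: int = 5,
    top_m: int = 10,
    background: str = "uniform",
    min_enrichment: float = 0.0,
) -> MotifPFM:
    """Enriched-k-mer motif from binding-site sequences.

    k-mers are ranked by log2 enrichment over a uniform background
    expectation; the top ``top_m`` are greedily aligned to the top k-mer by
    maximal-overlap offset and stacked with equal weight into a position
    frequency matrix.
    """
    if len(site_seqs) < 10:
        raise ValueError("at least 10 site sequences are required")
    counts = _kmer_counts(site_seqs, k)
    if counts.empty:
        raise ValueError("no unambiguous k-mers in the site sequences")
    expected = counts.sum() / 4**k
    enrich = np.log2((counts + 1.0) / (expected + 1.0))
    enrich = enrich.sort_values(ascending=False, kind="stable")
    top = enrich[enrich > min_enrichment]
    if top.empty:
        raise ValueError("no k-mer enriched above the threshold")
    chosen = list(top.index[:top_m])
    seed = chosen[0]
    aligned = [(seed, 0)] + [(w, _best_overlap_offset(seed, w)) for w in chosen[1:]]
    lo = min(off for _, off in aligned)
    hi = max(off + k for _, off in aligned)
    width = hi - lo
    mat = np.zeros((4, width))
    idx = {b: i for i, b in enumerate("ACGT")}
    for w, off in aligned:
        for j, ch in enumerate(w):
            mat[idx[ch], off - lo + j] += 1
    colsum = mat.sum(axis=0)
    colsum[colsum == 0] = 1.0
    pfm = pd.DataFrame(mat / colsum, index=list("ACGT"))
    return MotifPFM(pfm, aligned)


def scan_motif(
    pfm: MotifPFM | pd.DataFrame,
    introns: list[IntronRecord],
    genome: ToyGenome,
    threshold: float = 0.8,
) -> tuple[list[str], pd.DataFrame]:
    """Introns containing a motif instance at >= threshold x maximal score.

    The PFM's log-odds (vs uniform background) is scored at every offset of
    each intron's strand-corrected sequence and its reverse complement.
    Returns (motif-bearing intron ids, per-hit table).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    lo_mat = pfm.log_odds() if isinstance(pfm, MotifPFM) else np.log2(
        (pfm.to_numpy() + 1e-3) / (0.25 + 1e-3)
    )
    width = lo_mat.shape[1]
    max_score = float(lo_mat.max(axis=0).sum())
    cut = threshold * max_score
    hits = []
    for intr in introns:
        seq = intr.seq(genome)
        for strand_label, s in (("sense", seq), ("antisense", revcomp(seq))):
            codes = encode(s)
            n = len(codes) - width + 1
            if n <= 0:
                continue
            scores = np.zeros(n)
            for j in range(width):
                col = codes[j : j + n]
                ok = col <= 3
                scores += np.where(ok, lo_mat[np.minimum(col, 3), j], -np.inf)
            for off in np.nonzero(scores >= cut)[0]:
                hits.append((intr.intron_id, strand_label, int(off), float(scores[off])))
    df = pd.DataFrame(hits, columns=["intron_id", "orientation", "offset", "score"])
    return sorted(df["intron_id"].unique()), df
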