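"""Branchpoint reporter-assay library design and scoring.

A reporter library replaces the 6-bp window around a model intron's
branchpoint (-3 to +2 relative to the branch nucleotide, so the branch sits
at hexamer offset 3) with all 4096 hexamers, each carried by four pairs of
11-nt intronic/exonic barcodes.  Barcodes must avoid TAA/TGA/TCA (potential
cryptic branch sites) and rank in the bottom half of five hexamer-based
splicing-regulatory score tables by the sum of squared overlapping-hexamer
scores.

Splicing efficiency of species j with input count i_j and output count o_j:

    SE_j = ((o_j + 1) / (i_j + 1)) / (sum_k (o_k + 1) / sum_k (i_k + 1))

The branchpoint functional score of a hexamer is log2 of the mean SE over
its four barcode pairs.  By construction the input-weighted mean of SE over
all species is exactly 1.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from ._seq import codes_to_kmer_codes, decode, encode
from .synthetic import IntronRecord, ToyGenome

HEXAMERS = ["".join(p) for p in product("ACGT", repeat=6)]
BARCODE_LEN = 11
N_BARCODE_PAIRS = 4
BRANCH_OFFSET = 3  # branch nucleotide position within the hexamer

SCORE_TABLE_NAMES = (
    "exon_inclusion",
    "a3ss_exonic",
    "a5ss_exonic",
    "a3ss_intronic",
    "a5ss_intronic",
)


def hexamer_index(hexamer: str) -> int:
    codes = encode(hexamer)
    if (codes > 3).any():
        raise ValueError(f"ambiguous base in hexamer {hexamer!r}")
    return int(codes_to_kmer_codes(codes, 6)[0])


def make_score_tables(seed: int = 0) -> dict[str, np.ndarray]:
    """Seeded synthetic stand-ins for the five published hexamer score
    tables (standard-normal scores per hexamer)."""
    rng = np.random.default_rng(seed)
    return {name: rng.normal(0.0, 1.0, 4096) for name in SCORE_TABLE_NAMES}


# ---------------------------------------------------------------------------
# barcode filtering
# ---------------------------------------------------------------------------


def _barcode_code_matrix(barcodes: np.ndarray | list[str]) -> np.ndarray:
    if isinstance(barcodes, np.ndarray) and barcodes.ndim == 2:
        return barcodes
    mat = np.zeros((len(barcodes), BARCODE_LEN), dtype=np.uint8)
    for i, b in enumerate(barcodes):
        if len(b) != BARCODE_LEN:
            raise ValueError(f"barcode {b!r} is not {BARCODE_LEN} nt")
        mat[i] = encode(b)
    return mat


def _motif_fail(codes: np.ndarray) -> np.ndarray:
    """True where a barcode contains TAA, TGA or TCA (i.e. T, non-T, A)."""
    n = codes.shape[0]
    fail = np.zeros(n, dtype=bool)
    for off in range(BARCODE_LEN - 2):
        tri = codes[:, off : off + 3]
        fail |= (tri[:, 0] == 3) & (tri[:, 1] != 3) & (tri[:, 2] == 0)
    return fail


def _overlapping_hexamer_codes(codes: np.ndarray) -> np.ndarray:
    """(n, 6) base-4 codes of the 6 overlapping hexamers of each barcode,
    computed with a rolling update."""
    n = codes.shape[0]
    n_hex = BARCODE_LEN - 6 + 1
    hx = np.empty((n, n_hex), dtype=np.int32)
    pw = (4 ** np.arange(5, -1, -1)).astype(np.int32)
    cur = codes[:, :6].astype(np.int32) @ pw
    hx[:, 0] = cur
    for off in range(1, n_hex):
        cur = (cur % 4**5) * 4 + codes[:, off + 5]
        hx[:, off] = cur
    return hx


def _hexamer_sums(codes: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Sum of squared scores over the 6 overlapping hexamers of each barcode."""
    hx = _overlapping_hexamer_codes(codes)
    return (table[hx] ** 2).sum(axis=1)


def _filter_codes(
    codes: np.ndarray, score_tables: dict[str, np.ndarray], combine: str
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized verdicts on a code matrix: (motif fail, rank pass)."""
    if combine not in ("each", "sum"):
        raise ValueError("combine must be 'each' or 'sum'")
    mfail = _motif_fail(codes)
    candidates = ~mfail
    rank_pass = candidates.copy()
    if not candidates.any():
        return mfail, rank_pass
    hx = _overlapping_hexamer_codes(codes[candidates])
    sums = [
        np.take((t**2).astype(np.float32), hx).sum(axis=1, dtype=np.float32)
        for t in score_tables.values()
    ]
    sub_pass = np.ones(hx.shape[0], dtype=bool)
    if combine == "sum":
        total = np.sum(sums, axis=0)
        sub_pass &= total <= np.median(total)
    else:
        for s in sums:
            sub_pass &= s <= np.median(s)
    rank_pass[candidates] = sub_pass
    return mfail, rank_pass


def filter_barcodes(
    barcodes: list[str] | np.ndarray,
    score_tables: dict[str, np.ndarray],
    combine: str = "each",
) -> pd.DataFrame:
    """Apply both barcode filters over a candidate pool.

    The rank filter is pool-relative: a barcode passes a table when its sum
    of squared overlapping-hexamer scores is at or below the pool median
    among motif-passing barcodes (ties at the boundary pass).  With
    ``combine='each'`` a barcode must sit in the bottom half of every table
    independently; ``combine='sum'`` ranks the summed statistic instead.
    """
    codes = _barcode_code_matrix(barcodes)
    mfail, rank_pass = _filter_codes(codes, score_tables, combine)
    reason = np.where(mfail, "stop_motif", np.where(rank_pass, "", "rank"))
    if isinstance(barcodes, np.ndarray) and barcodes.ndim == 2:
        names = [decode(row) for row in barcodes]
    else:
        names = list(barcodes)
    return pd.DataFrame(
        {"barcode": names, "passed": ~mfail & rank_pass, "reason": reason}
    )


def filter_barcode(
    barcode: str,
    score_tables: dict[str, np.ndarray],
    pool: list[str] | None = None,
) -> tuple[bool, str]:
    """Verdict for a single barcode; the rank filter needs a *pool* context
    (without one, only the stop-motif filter applies)."""
    if pool is None:
        codes = _barcode_code_matrix([barcode])
        if _motif_fail(codes)[0]:
            return False, "stop_motif"
        return True, ""
    df = filter_barcodes([barcode] + list(pool), score_tables)
    row = df.iloc[0]
    return bool(row["passed"]), str(row["reason"])


# ---------------------------------------------------------------------------
# library enumeration
# ---------------------------------------------------------------------------


def _full_space_codes() -> np.ndarray:
    """Code matrix of every 11-mer, in lexicographic order."""
    space = 4**BARCODE_LEN
    codes = np.empty((space, BARCODE_LEN), dtype=np.uint8)
    for i in range(BARCODE_LEN):
        period = 4 ** (BARCODE_LEN - 1 - i)
        codes[:, i] = np.tile(np.repeat(np.arange(4, dtype=np.uint8), period), 4**i)
    return codes


def generate_barcode_pool(
    n_required: int,
    score_tables: dict[str, np.ndarray],
    seed: int = 0,
    combine: str = "each",
) -> np.ndarray:
    """Filter the full 11-mer space and return *n_required* passing barcodes
    as a code matrix, in a seed-determined random order.

    The bottom-half rank filter on five tables keeps only ~2% of all
    11-mers, so the whole space is scanned in one vectorized pass.
    """
    codes = _full_space_codes()
    mfail, rank_pass = _filter_codes(codes, score_tables, combine)
    passing = codes[~mfail & rank_pass]
    if len(passing) < n_required:
        raise ValueError(
            f"barcode space exhausted: {len(passing)} passing < {n_required} required"
        )
    rng = np.random.default_rng(seed)
    return passing[rng.permutation(len(passing))[:n_required]]


def enumerate_library(
    template: dict[str, str] | None = None,
    barcode_pool: list[str] | np.ndarray | None = None,
    score_tables: dict[str, np.ndarray] | None = None,
    seed: int = 0,
    assume_filtered: bool = False,
) -> pd.DataFrame:
    """Enumerate all 4096 branchpoint hexamers x 4 barcode pairs.

    Returns one row per species (16,384 rows) with its hexamer, intronic and
    exonic barcode; assignment is deterministic per seed.  Intronic and
    exonic barcodes are drawn from the same filtered pool (the two roles
    occupy different positions in the construct, so a barcode may serve both
    roles); each role uses 16,384 distinct barcodes and no species pairs a
    barcode with itself.  ``barcode_pool`` supplies candidate barcodes
    (filtered here unless ``assume_filtered``); ``template`` optionally
    carries the reporter context sequences and is stored in the frame attrs.
    """
    score_tables = score_tables or make_score_tables(seed)
    need = 4096 * N_BARCODE_PAIRS  # per role
    rng = np.random.default_rng(seed)
    if barcode_pool is None:
        pool_codes = generate_barcode_pool(need, score_tables, seed)
        passing = [decode(row) for row in pool_codes]
    else:
        if assume_filtered:
            passing = (
                [decode(row) for row in barcode_pool]
                if isinstance(barcode_pool, np.ndarray)
                else list(barcode_pool)
            )
        else:
            verdict = filter_barcodes(barcode_pool, score_tables)
            passing = verdict.loc[verdict["passed"], "barcode"].tolist()
        if len(passing) < need:
            raise ValueError(
                f"barcode pool too small after filtering: {len(passing)} < {need}"
            )
        passing = [passing[i] for i in rng.permutation(len(passing))[:need]]
    intronic = passing[:need]
    exonic = passing[1:] + passing[:1]  # distinct pairing, same role pool
    rows = []
    for h_i, hexamer in enumerate(HEXAMERS):
        for pair in range(N_BARCODE_PAIRS):
            j = h_i * N_BARCODE_PAIRS + pair
            rows.append((f"{hexamer}_bc{pair}", hexamer, pair, intronic[j], exonic[j]))
    df = pd.DataFrame(
        rows, columns=["species_id", "hexamer", "barcode_pair", "intronic_bc", "exonic_bc"]
    )
    if template:
        df.attrs["template"] = dict(template)
    assert df["hexamer"].nunique() == 4096
    return df


# ---------------------------------------------------------------------------
# splicing efficiency and functional score
# ---------------------------------------------------------------------------


def splicing_efficiency(counts: pd.DataFrame) -> pd.DataFrame:
    """Add the pseudocounted, library-normalized splicing efficiency ``se``.

    Normalization is per replicate when a ``replicate`` column is present.
    The input-weighted mean of SE across each run is 1 by construction
    (asserted to 1e-12).
    """
    if counts.empty:
        raise ValueError("empty count table")
    df = counts.copy()

    def _one(group: pd.DataFrame) -> pd.Series:
        o = group["output_count"].to_numpy(dtype=float) + 1.0
        i = group["input_count"].to_numpy(dtype=float) + 1.0
        ratio = o.sum() / i.sum()
        se = (o / i) / ratio
        assert abs(float((se * i / i.sum()).sum()) - 1.0) < 1e-12
        return pd.Series(se, index=group.index)

    if "replicate" in df.columns:
        parts = [_one(grp) for _, grp in df.groupby("replicate")]
        df["se"] = pd.concat(parts).reindex(df.index)
    else:
        df["se"] = _one(df)
    return df


def functional_score(se_table: pd.DataFrame) -> pd.DataFrame:
    """Per-hexamer branchpoint functional score: log2(mean SE of its barcode
    pairs), with the spread across pairs and (if present) replicates."""
    if "se" not in se_table.columns:
        se_table = splicing_efficiency(se_table)
    rows = []
    for hexamer, grp in se_table.groupby("hexamer", sort=True):
        mean_se = float(grp["se"].mean())
        row = {
            "hexamer": hexamer,
            "mean_se": mean_se,
            "sd_se": float(grp["se"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "functional_score": float(np.log2(mean_se)),
        }
        if "replicate" in grp.columns and grp["replicate"].nunique() > 1:
            rep_scores = np.log2(grp.groupby("replicate")["se"].mean())
            row["score_rep_mean"] = float(rep_scores.mean())
            row["score_rep_sd"] = float(rep_scores.std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows).set_index("hexamer")


# ---------------------------------------------------------------------------
# genomic score track
# ---------------------------------------------------------------------------


def _scores_array(scores) -> np.ndarray:
    if isinstance(scores, np.ndarray):
        if scores.shape != (4096,):
            raise ValueError("score array must have length 4096")
        return scores.astype(float)
    if isinstance(scores, pd.DataFrame):
        scores = scores["functional_score"]
    arr = np.full(4096, np.nan)
    for hexamer, v in scores.items():
        arr[hexamer_index(hexamer)] = v
    if np.isnan(arr).any():
        raise ValueError("scores must cover all 4096 hexamers")
    return arr


_RC_CODE = None


def _revcomp_code_table() -> np.ndarray:
    global _RC_CODE
    if _RC_CODE is None:
        tab = np.zeros(4096, dtype=np.int64)
        for code in range(4096):
            digits = [(code >> (2 * i)) & 3 for i in range(6)]  # last base first
            rc = 0
            for d in digits:  # reversing + complementing
                rc = rc * 4 + (3 - d)
            # digits are already reversed order; complementing each gives rc
            tab[code] = rc
        _RC_CODE = tab
    return _RC_CODE


def score_track(
    genome: ToyGenome,
    scores,
    introns: list[IntronRecord] | None = None,
) -> dict[str, np.ndarray]:
    """Per-genomic-position branchpoint functional score.

    Position p gets the score of the hexamer occupying [p-3, p+3) with the
    branch at hexamer offset 3, read on the plus strand; positions inside
    minus-strand introns are overwritten with the reverse-complement
    (transcript-orientation) hexamer's score.  Positions within 3 nt of a
    contig edge are NaN.
    """
    arr = _scores_array(scores)
    rc = _revcomp_code_table()
    tracks: dict[str, np.ndarray] = {}
    for contig, seq in genome.contigs.items():
        codes6 = codes_to_kmer_codes(encode(seq), 6)  # code of window starting at q
        track = np.full(len(seq), np.nan)
        valid = codes6 >= 0
        # plus strand: branch at q + BRANCH_OFFSET
        pos = np.arange(len(codes6)) + BRANCH_OFFSET
        track[pos[valid]] = arr[codes6[valid]]
        tracks[contig] = track
    if introns:
        for intr in introns:
            if intr.strand != "-":
                continue
            seq_codes = codes_to_kmer_codes(encode(genome.contigs[intr.contig]), 6)
            track = tracks[intr.contig]
            for p in range(intr.start, intr.end):
                q = p - 2  # genomic window [p-2, p+4) revcomp'd has branch at offset 3
                if 0 <= q < len(seq_codes) and seq_codes[q] >= 0:
                    track[p] = arr[rc[seq_codes[q]]]
    return tracks
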