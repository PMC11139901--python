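"""Low-level nucleotide sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# uint8 encoding: A=0 C=1 G=2 T=3, N=4, anything else 255
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("N")] = 4
_ENCODE[ord("n")] = 4


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3, N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return bytes(lut[codes]).decode("ascii")


def random_seq(rng: np.random.Generator, n: int, p=None) -> str:
    codes = rng.choice(4, size=n, p=p).astype(np.uint8)
    return decode(codes)


def gc_checked(seq: str) -> str:
    """Validate that *seq* contains only A/C/G/T; return it unchanged."""
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return seq


def kmer_code(seq: str) -> int:
    """Base-4 integer code of a k-mer (A=0 C=1 G=2 T=3); raises on N."""
    code = 0
    for ch in seq:
        v = _ENCODE[ord(ch)]
        if v > 3:
            raise ValueError(f"ambiguous base in k-mer {seq!r}")
        code = code * 4 + int(v)
    return code


def codes_to_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Sliding base-4 codes of all k-mers of an encoded sequence.

    Windows containing an ambiguous base get code -1.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        col = codes[i : i + n].astype(np.int64)
        bad |= col > 3
        out = out * 4 + np.where(col > 3, 0, col)
    out[bad] = -1
    return out
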