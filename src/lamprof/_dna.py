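"""Small DNA helpers shared across modules.

Coordinates everywhere in the package are 1-based, both-ends-inclusive, on the
plus strand; conversion to 0-based half-open happens only at BED boundaries.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

# IUPAC nucleotide codes -> set of plain bases they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVNacgtrywskmbdhvn",
                            "TGCAYRWSMKVHDBNtgcayrwsmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_bytes(seq: str) -> np.ndarray:
    """Uppercase DNA string as a uint8 array (for vectorised comparisons)."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length strings")
    if not a:
        return 0
    return int((seq_to_bytes(a) != seq_to_bytes(b)).sum())


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.25) -> str:
    """i.i.d. DNA with the given GC fraction (AT split evenly, likewise GC)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(np.array(list("ACGT"))[idx])


def sliding_mismatches(seq: str, query: str) -> np.ndarray:
    """Mismatch count of ``query`` against every start offset of ``seq``.

    Returns an array of length ``len(seq) - len(query) + 1`` (empty if the
    query is longer than the sequence).
    """
    n, m = len(seq), len(query)
    if m == 0 or m > n:
        return np.zeros(0, dtype=np.int64)
    s = seq_to_bytes(seq)
    q = seq_to_bytes(query)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    return (windows != q).sum(axis=1)


def chunked(it: Iterable, size: int):
    buf = []
    for x in it:
        buf.append(x)
        if len(buf) == size:
            yield buf
            buf = []
    if buf:
        yield buf
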