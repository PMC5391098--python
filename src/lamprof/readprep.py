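"""Read preparation: pair merging, primer checks, element and primer trimming.

Read pairs are merged across their overlap into "pseudoreads"; pseudoreads
shorter than 100 nt are discarded.  The element-derived part of each
pseudoread is located by local alignment against the element model and
trimmed off; the genomic remainder is stored junction-first so that the
library primer (tRNA-family primer) or the adapter (plus its 6 primer-derived
random bases) forms a suffix that can be trimmed.  Genomic parts shorter
than 40 nt are discarded to avoid imprecise placements in A+T-rich
intergenic sequence.

Bases between the element match and the genomic part may be non-templated
extra nucleotides; their attribution is deferred to integration calling,
because only the genome alignment can tell which side they belong to.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._dna import revcomp, seq_to_bytes, sliding_mismatches
from .catalog import Interval
from .mapping import MapParams, smith_waterman
from .simulate import ElementModel


@dataclass
class PrepParams:
    min_pseudoread_len: int = 100
    min_overlap: int = 10
    max_overlap_mismatch_rate: float = 0.1
    primer_max_mismatches: int = 1
    min_trimmed_len: int = 40
    element_min_match_len: int = 20
    element_max_divergence: float = 0.1

    def __post_init__(self) -> None:
        if min(self.min_pseudoread_len, self.min_overlap, self.primer_max_mismatches,
               self.min_trimmed_len, self.element_min_match_len) < 0:
            raise ValueError("parameters must be nonnegative")
        for r in (self.max_overlap_mismatch_rate, self.element_max_divergence):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class PseudoRead:
    id: str
    sequence: str
    quality: str
    library_type: str = "tdna"
    source_pair: tuple[str, str] = ("", "")


@dataclass
class MergeOutcome:
    status: str  # merged | rejected
    pseudoread: PseudoRead | None = None
    reason: str = ""


def merge_pair(
    r1: tuple[str, str],
    r2: tuple[str, str],
    params: PrepParams | None = None,
    read_id: str = "",
    library_type: str = "tdna",
) -> MergeOutcome:
    """Join a read pair across its best overlap into one pseudoread.

    The reverse complement of read 2 is slid along read 1; the overlap with
    the lowest mismatch rate (ties: longest overlap) wins, provided it is at
    least ``min_overlap`` long with a mismatch rate at most
    ``max_overlap_mismatch_rate``.  Conflicting bases take the
    higher-quality call.  Merges shorter than ``min_pseudoread_len`` are
    rejected.
    """
    params = params or PrepParams()
    s1, q1 = r1
    s2, q2 = r2
    if not s1 or not s2:
        return MergeOutcome("rejected", reason="empty_read")
    b = revcomp(s2)
    bq = q2[::-1]
    a1, a2 = seq_to_bytes(s1), seq_to_bytes(b)
    n1, n2 = len(s1), len(b)
    best = None  # (rate, -ov, s)
    for s in range(0, n1 - params.min_overlap + 1):
        ov = min(n1 - s, n2)
        if ov < params.min_overlap:
            break
        mm = int((a1[s : s + ov] != a2[:ov]).sum())
        rate = mm / ov
        if rate <= params.max_overlap_mismatch_rate:
            cand = (rate, -ov, s)
            if best is None or cand < best:
                best = cand
    if best is None:
        return MergeOutcome("rejected", reason="no_overlap")
    _, _, s = best
    ov = min(n1 - s, n2)
    consensus = "".join(
        s1[s + i] if (s1[s + i] == b[i] or q1[s + i] >= bq[i]) else b[i]
        for i in range(ov)
    )
    merged_seq = s1[:s] + consensus + b[ov:]
    merged_qual = q1[:s] + "".join(max(q1[s + i], bq[i]) for i in range(ov)) + bq[ov:]
    if len(merged_seq) < params.min_pseudoread_len:
        return MergeOutcome("rejected", reason="too_short")
    return MergeOutcome(
        "merged",
        PseudoRead(read_id, merged_seq, merged_qual, library_type,
                   (read_id + "/1", read_id + "/2")),
    )


def require_primer(pr: PseudoRead, primer: str, params: PrepParams | None = None) -> bool:
    """Keep iff the primer (or its reverse complement) occurs with at most
    ``primer_max_mismatches`` substitutions.  Applied to adapter-library
    pseudoreads to remove artificial constructs lacking the nested primer."""
    params = params or PrepParams()
    for q in (primer, revcomp(primer)):
        mm = sliding_mismatches(pr.sequence, q)
        if mm.size and mm.min() <= params.primer_max_mismatches:
            return True
    return False


@dataclass
class JunctionFragment:
    read_id: str
    pseudoread_len: int
    genomic_part: str        # junction-first; primer/adapter forms the suffix
    element_part: str
    element_interval_on_read: Interval
    element_5p_coord_on_element: int  # 1 = first base of the retained UTR
    extras_candidate: str = ""        # resolved during integration calling
    primer_part: str = ""
    primer_found: bool = False
    library_type: str = "tdna"

    @property
    def truncation(self) -> int:
        return self.element_5p_coord_on_element - 1

    def partition_lengths(self) -> tuple[int, int, int, int]:
        return (len(self.element_part), len(self.extras_candidate),
                len(self.genomic_part), len(self.primer_part))


@dataclass
class TrimOutcome:
    status: str  # trimmed | rejected
    fragment: JunctionFragment | None = None
    reason: str = ""


_ELEMENT_ALN = MapParams()


from functools import lru_cache


@lru_cache(maxsize=4)
def _element_kmers(sequence: str, k: int) -> frozenset[str]:
    return frozenset(sequence[i : i + k] for i in range(len(sequence) - k + 1))


def locate_and_trim_element(
    pr: PseudoRead, element: ElementModel, params: PrepParams | None = None
) -> TrimOutcome:
    """Find the element-derived segment of a pseudoread and split it off.

    The pseudoread is oriented so the element reads forward (genomic part 5'
    of it); the distance of the match start from element position 1 (the
    first base of the retained UTR) is the 5' truncation.  The genomic part
    is returned reverse-complemented, i.e. junction-first with the library
    primer at its 3' end.
    """
    params = params or PrepParams()
    if element.orf1_primer_site is None or element.nested_primer_site is None:
        raise ValueError("element model lacks primer coordinates")
    # cheap orientation pre-check: shared k-mers with the element sequence
    k = 11
    elem_kmers = _element_kmers(element.full_sequence, k)
    fwd, rev = pr.sequence, revcomp(pr.sequence)
    n_fwd = sum(1 for i in range(0, len(fwd) - k + 1, 4) if fwd[i : i + k] in elem_kmers)
    n_rev = sum(1 for i in range(0, len(rev) - k + 1, 4) if rev[i : i + k] in elem_kmers)
    if n_fwd == n_rev == 0:
        return TrimOutcome("rejected", reason="no_element")
    order = [fwd, rev] if n_fwd >= n_rev else [rev, fwd]
    if abs(n_fwd - n_rev) > 2:
        order = order[:1]  # orientation unambiguous
    best = None
    for q in order:
        aln = smith_waterman(q, element.full_sequence, _ELEMENT_ALN)
        if aln is None:
            continue
        if best is None or aln.score > best[1].score:
            best = (q, aln)
    if best is None:
        return TrimOutcome("rejected", reason="no_element")
    q, aln = best
    match_len = aln.q_end - aln.q_start + 1
    divergence = 1.0 - (aln.n_match / aln.n_cols if aln.n_cols else 0.0)
    if match_len < params.element_min_match_len or divergence > params.element_max_divergence:
        return TrimOutcome("rejected", reason="no_element")
    g = q[: aln.q_start - 1]
    frag = JunctionFragment(
        read_id=pr.id,
        pseudoread_len=len(pr.sequence),
        genomic_part=revcomp(g),
        element_part=q[aln.q_start - 1 :],  # trailing bases count as element side
        element_interval_on_read=Interval(aln.q_start, len(q)),
        element_5p_coord_on_element=aln.t_start,
        library_type=pr.library_type,
    )
    return TrimOutcome("trimmed", frag)


def _suffix_matches(seq: str, query: str, max_mm: int) -> bool:
    if len(seq) < len(query):
        return False
    a = seq_to_bytes(seq[-len(query):])
    b = seq_to_bytes(query)
    return int((a != b).sum()) <= max_mm


def trim_target_end(
    frag: JunctionFragment,
    library_type: str,
    primers_or_adapter,
    params: PrepParams | None = None,
    hexamer_len: int = 6,
) -> JunctionFragment:
    """Remove the tDNA-primer suffix (tdna) or adapter suffix (adapter).

    For the adapter library the 6 primer-derived random bases adjacent to
    the adapter are removed as well.  If no primer/adapter is found the
    fragment is returned unchanged with ``primer_found`` False.
    """
    params = params or PrepParams()
    gp = frag.genomic_part
    if library_type == "tdna":
        for primer in primers_or_adapter:
            if _suffix_matches(gp, primer, params.primer_max_mismatches):
                frag.primer_part = gp[-len(primer):]
                frag.genomic_part = gp[: -len(primer)]
                frag.primer_found = True
                return frag
        return frag
    adapter_rc = revcomp(primers_or_adapter)
    if _suffix_matches(gp, adapter_rc, params.primer_max_mismatches):
        cut = len(adapter_rc) + hexamer_len
        cut = min(cut, len(gp))
        frag.primer_part = gp[-cut:]
        frag.genomic_part = gp[:-cut]
        frag.primer_found = True
    return frag


def length_filter(frag: JunctionFragment, params: PrepParams | None = None) -> bool:
    """Keep iff the trimmed genomic part is at least ``min_trimmed_len``."""
    params = params or PrepParams()
    return len(frag.genomic_part) >= params.min_trimmed_len
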