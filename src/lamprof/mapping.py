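"""Placement of genomic junction fragments on the reference set.

A seeded local aligner (exact k-mer seeds, windows extended by full affine
Smith-Waterman) produces scored hits; the acceptance filter then applies the
profiling rules: a hit is kept if it is unique, or if the second-best score
is at most 75% of the best and the fragment aligns over at least 95% of its
length (both boundaries inclusive).  Score-tied hits that all fall in one
duplicate group (loci with identical flanks, e.g. the mirrored arms of the
rDNA palindrome) are accepted as a placement on the group.

The 75% ratio is relative to the scoring scheme declared in MapParams
(match +1, mismatch -1, gap open -2, gap extend -1 by default); a different
scheme changes what the ratio means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

from ._dna import revcomp, seq_to_bytes
from .catalog import ReferenceSequence


@dataclass
class MapParams:
    seed_k: int = 11
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2   # score of the first gapped position
    gap_extend: int = -1  # score of each further gapped position
    second_best_ratio: float = 0.75
    min_query_coverage: float = 0.95
    #: whether the 95%-length rule also applies to unique hits (switchable;
    #: the original rule text lists it under the multi-hit case only)
    coverage_applies_to_unique: bool = True
    window_pad: int = 24
    diag_band: int = 16
    #: minimum seeds per diagonal cluster before DP extension; two seeds
    #: means a clean stretch of seed_k+1 bases, cutting chance single-k-mer
    #: windows in A+T-rich references
    min_cluster_seeds: int = 2
    #: up to this many unaligned bases at the query start (the junction side
    #: of a junction-first fragment) are exempt from the coverage
    #: denominator: they are candidate non-templated extra nucleotides,
    #: which are element-side rather than genomic
    coverage_exempt_prefix: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.second_best_ratio <= 1):
            raise ValueError("second_best_ratio must be in (0, 1]")
        if not (0 < self.min_query_coverage <= 1):
            raise ValueError("min_query_coverage must be in (0, 1]")


class AlignmentHit(NamedTuple):
    ref_id: str
    start: int   # 1-based inclusive, plus strand
    end: int
    strand: str  # '+': query as given aligns to the plus strand
    score: int
    query_coverage: float
    identity: float
    q_start: int  # 1-based inclusive on the query as given
    q_end: int


class LocalAlignment(NamedTuple):
    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    n_match: int
    n_cols: int


_NEG = -(10 ** 9)


def smith_waterman(query: str, target: str, params: MapParams | None = None) -> LocalAlignment | None:
    """Best local alignment under affine gap scoring (deterministic).

    Forward pass is vectorised over target positions; the horizontal (gap in
    query) term is computed with a prefix-max scan, which is exact for affine
    scoring because re-opening a gap immediately after closing one is never
    optimal when the open penalty is at least the extend penalty.
    """
    params = params or MapParams()
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        return None
    q = seq_to_bytes(query)
    t = seq_to_bytes(target)
    go, ge = -params.gap_open, -params.gap_extend  # positive penalties

    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    H0 = np.zeros((n + 1, m + 1), dtype=np.int32)  # H before horizontal term
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int32)
    jj = np.arange(m, dtype=np.int32)
    for i in range(1, n + 1):
        sub = np.where(t == q[i - 1], params.match, params.mismatch).astype(np.int32)
        F[i, 1:] = np.maximum(H[i - 1, 1:] - go, F[i - 1, 1:] - ge)
        h0 = np.maximum(H[i - 1, :-1] + sub, F[i, 1:])
        np.maximum(h0, 0, out=h0)
        H0[i, 1:] = h0
        # E[j] = max_{k<j} H0[k] - go - (j-1-k)*ge, via prefix max of A[k]=H0[k]+ge*k
        a = h0 + ge * (jj + 1)  # A[k] for k = 1..m; A[0] = 0
        pref = np.maximum.accumulate(np.concatenate(([0], a)))
        E[i, 1:] = pref[:-1] - go - ge * jj  # pref[j-1] - go - ge*(j-1)
        H[i, 1:] = np.maximum(h0, E[i, 1:])
    best = int(H.max())
    if best <= 0:
        return None
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    i, j = int(i), int(j)
    q_end, t_end = i, j
    n_match = n_cols = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = params.match if q[i - 1] == t[j - 1] else params.mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                n_cols += 1
                if q[i - 1] == t[j - 1]:
                    n_match += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            n_cols += 1
            if F[i, j] == H[i - 1, j] - go:
                state = "H"
            i -= 1
        else:  # E: gap in query, consume target
            n_cols += 1
            if E[i, j] == H0[i, j - 1] - go:
                state = "H"
            j -= 1
    return LocalAlignment(best, i + 1, q_end, j + 1, t_end, n_match, n_cols)


class ReferenceIndex:
    """Exact k-mer index over a reference set (built once, reused)."""

    def __init__(self, refs: Sequence[ReferenceSequence], k: int = 11):
        self.refs = list(refs)
        self.k = k
        self.by_id = {r.id: r for r in refs}
        self._index: dict[str, dict[str, list[int]]] = {}
        for r in refs:
            d: dict[str, list[int]] = {}
            s = r.sequence
            for i in range(len(s) - k + 1):
                d.setdefault(s[i : i + k], []).append(i)
            self._index[r.id] = d

    def seed_positions(self, ref_id: str, kmer: str) -> list[int]:
        return self._index[ref_id].get(kmer, [])


def _candidate_windows(query: str, ref: ReferenceSequence, index: ReferenceIndex,
                       params: MapParams) -> list[tuple[int, int]]:
    k = params.seed_k
    diags: list[tuple[int, int]] = []  # (diag, tpos)
    for qpos in range(len(query) - k + 1):
        for tpos in index.seed_positions(ref.id, query[qpos : qpos + k]):
            diags.append((tpos - qpos, tpos))
    if not diags:
        return []
    diags.sort()
    clusters: list[list[tuple[int, int]]] = [[diags[0]]]
    for d in diags[1:]:
        if d[0] - clusters[-1][-1][0] <= params.diag_band:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    windows = []
    for cl in clusters:
        if len(cl) < params.min_cluster_seeds:
            continue
        lo = min(d[0] for d in cl) - params.window_pad
        hi = max(d[0] for d in cl) + len(query) + params.window_pad
        windows.append((max(0, lo), min(len(ref), hi)))
    if not windows:
        return []
    # merge overlaps
    windows.sort()
    merged = [windows[0]]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def align_fragment(
    fragment: str,
    refs: Sequence[ReferenceSequence] | ReferenceIndex,
    params: MapParams | None = None,
) -> list[AlignmentHit]:
    """All seed-reachable local alignments of a fragment, best first.

    Both orientations of the fragment are tried; a '-' hit means the reverse
    complement of the fragment matches the plus strand, and is reported with
    plus-strand coordinates.  Query coordinates are on the fragment as given.
    """
    params = params or MapParams()
    if isinstance(refs, ReferenceIndex):
        index = refs
    else:
        if not refs:
            raise ValueError("empty reference set")
        index = ReferenceIndex(refs, params.seed_k)
    if not index.refs:
        raise ValueError("empty reference set")
    hits: list[AlignmentHit] = []
    n = len(fragment)
    for strand, q in (("+", fragment), ("-", revcomp(fragment))):
        for ref in index.refs:
            for lo, hi in _candidate_windows(q, ref, index, params):
                aln = smith_waterman(q, ref.sequence[lo:hi], params)
                if aln is None:
                    continue
                t_start, t_end = aln.t_start + lo, aln.t_end + lo
                if strand == "+":
                    q_start, q_end = aln.q_start, aln.q_end
                else:
                    q_start, q_end = n - aln.q_end + 1, n - aln.q_start + 1
                denom = n - min(q_start - 1, params.coverage_exempt_prefix)
                hits.append(
                    AlignmentHit(
                        ref_id=ref.id,
                        start=t_start,
                        end=t_end,
                        strand=strand,
                        score=aln.score,
                        query_coverage=(aln.q_end - aln.q_start + 1) / denom,
                        identity=aln.n_match / aln.n_cols if aln.n_cols else 0.0,
                        q_start=q_start,
                        q_end=q_end,
                    )
                )
    # one hit per (ref, locus, strand): keep the best-scoring
    best: dict[tuple, AlignmentHit] = {}
    for h in hits:
        key = (h.ref_id, h.strand, h.start, h.end)
        if key not in best or h.score > best[key].score:
            best[key] = h
    out = sorted(best.values(), key=lambda h: (-h.score, h.ref_id, h.start, h.strand))
    return out


@dataclass
class Placement:
    status: str                     # accepted | rejected
    hit: AlignmentHit | None = None
    group: str | None = None        # duplicate-group id for group placements
    group_hits: list[AlignmentHit] = field(default_factory=list)
    reason: str = ""
    category: str = "unplaced"      # target_genome | plasmid_actin6 | unplaced

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def accept_hits(
    hits: Sequence[AlignmentHit],
    params: MapParams | None = None,
    group_of: Callable[[AlignmentHit], str | None] | None = None,
) -> Placement:
    """Apply the hit-acceptance rules to a score-sorted hit list.

    unique hit -> accept (coverage permitting); multiple hits -> accept the
    best iff second_best <= ratio * best ("not exceed": inclusive) and
    coverage >= minimum (inclusive); an exact score tie whose members all
    belong to one duplicate group is treated as a unique hit on that group,
    with the ratio rule applied against the best hit outside the group.
    """
    params = params or MapParams()
    if not hits:
        return Placement("rejected", reason="no_hit")
    best = hits[0]

    def cov_ok(h: AlignmentHit, unique: bool) -> bool:
        if unique and not params.coverage_applies_to_unique:
            return True
        return h.query_coverage >= params.min_query_coverage

    if len(hits) == 1:
        if cov_ok(best, unique=True):
            return Placement("accepted", hit=best)
        return Placement("rejected", hit=best, reason="low_coverage")

    ties = [h for h in hits if h.score == best.score]
    if len(ties) > 1:
        if group_of is not None:
            groups = {group_of(h) for h in ties}
            if len(groups) == 1 and None not in groups:
                rest = [h for h in hits if h.score < best.score]
                if rest and rest[0].score > params.second_best_ratio * best.score:
                    return Placement("rejected", hit=best, reason="second_best_too_close")
                if cov_ok(best, unique=True):
                    return Placement(
                        "accepted", hit=best, group=groups.pop(), group_hits=ties
                    )
                return Placement("rejected", hit=best, reason="low_coverage")
        return Placement("rejected", hit=best, reason="ambiguous_tie")

    second = hits[1]
    if second.score > params.second_best_ratio * best.score:
        return Placement("rejected", hit=best, reason="second_best_too_close")
    if not cov_ok(best, unique=False):
        return Placement("rejected", hit=best, reason="low_coverage")
    return Placement("accepted", hit=best)


def classify_placement(
    placement: Placement, refs_by_id: dict[str, ReferenceSequence]
) -> str:
    """Category for stage accounting: genomic, plasmid/actin6, or unplaced.

    Reads placing on the plasmid context (the transformed element's promoter
    region, the actin6-promoter analog) are counted but excluded from
    integration calling.
    """
    if not placement.accepted:
        placement.category = "unplaced"
    elif refs_by_id[placement.hit.ref_id].kind == "plasmid":
        placement.category = "plasmid_actin6"
    else:
        placement.category = "target_genome"
    return placement.category
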