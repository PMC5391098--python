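"""Catalog of RNA polymerase III integration targets.

A target is a tRNA gene, a 5S gene, or a bare A/B-box locus (a pair of
internal-promoter motifs without any tRNA gene context, as found on the
extrachromosomal rDNA palindrome).  Each target carries the +1 position of
the (real or hypothetical) mature transcript, which is the reference point
for integration distances: in most D. discoideum tRNA genes the +1 is a G
located 7 bp upstream of the A box, whose own position is fixed at +8.

B boxes are found with the consensus GTTCRANNC; candidate A boxes upstream
of a B box are accepted with the permissive motif TNNNNNANNNG and labelled
"stringent" when they also match TRRYNNARYNG.  Functional spacing between
the boxes (bases strictly between A-box end and B-box start) is 30-60 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np

from ._dna import IUPAC_CODES, revcomp, seq_to_bytes

logger = logging.getLogger(__name__)

B_BOX = "GTTCRANNC"
A_BOX_PERMISSIVE = "TNNNNNANNNG"
A_BOX_STRINGENT = "TRRYNNARYNG"

REF_KINDS = ("chromosome", "palindrome_arm", "plasmid")
TARGET_CLASSES = ("trna", "five_s", "ab_box")


class Interval(NamedTuple):
    """1-based, both-ends-inclusive plus-strand interval."""

    start: int
    end: int

    def __str__(self) -> str:  # used in BED extra columns
        return f"{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "Interval | None":
        if text in (".", ""):
            return None
        a, b = text.split("-")
        return cls(int(a), int(b))


@dataclass(frozen=True)
class IupacMotif:
    """A degenerate nucleotide motif over the IUPAC alphabet."""

    pattern: str

    def __post_init__(self) -> None:
        bad = set(self.pattern.upper()) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in motif: {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)

    def revcomp(self) -> "IupacMotif":
        return IupacMotif(revcomp(self.pattern))


@dataclass
class ReferenceSequence:
    id: str
    sequence: str
    kind: str = "chromosome"

    def __post_init__(self) -> None:
        if self.kind not in REF_KINDS:
            raise ValueError(f"unknown reference kind {self.kind!r}")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"reference {self.id}: non-ACGTN characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PolIIITarget:
    id: str
    ref_id: str
    plus_one_pos: int
    strand: str
    target_class: str
    a_box: Interval | None = None
    b_box: Interval | None = None
    a_box_class: str = "absent"  # stringent | permissive | absent
    family: str = ""
    duplicate_group: str | None = None


@dataclass
class CatalogParams:
    spacing_min: int = 30
    spacing_max: int = 60
    plus_one_offset: int = 7
    flank_len_for_duplicates: int = 200
    scan_both_strands: bool = True
    #: if True a reference N matches every motif position; by default N only
    #: matches a motif N (conservative).
    n_matches_all: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.spacing_min <= self.spacing_max):
            raise ValueError("need 0 < spacing_min <= spacing_max")
        if self.plus_one_offset <= 0:
            raise ValueError("plus_one_offset must be positive")


class MotifMatch(NamedTuple):
    position: int  # 1-based plus-strand start of the matched window
    strand: str


def _scan_plus(sequence: str, motif: IupacMotif, n_matches_all: bool) -> np.ndarray:
    """0-based start offsets of plus-strand matches (vectorised per column)."""
    arr = seq_to_bytes(sequence)
    L, m = len(arr), len(motif)
    if m > L:
        return np.zeros(0, dtype=np.int64)
    n_win = L - m + 1
    ok = np.ones(n_win, dtype=bool)
    for i, code in enumerate(motif.pattern):
        allowed = set(IUPAC_CODES[code])
        if code == "N" or n_matches_all:
            allowed.add("N")
        allowed_b = np.frombuffer("".join(sorted(allowed)).encode(), dtype=np.uint8)
        ok &= np.isin(arr[i : i + n_win], allowed_b)
        if not ok.any():
            break
    return np.nonzero(ok)[0]


def scan_motif(
    ref: ReferenceSequence,
    motif: IupacMotif | str,
    both_strands: bool = True,
    params: CatalogParams | None = None,
) -> list[MotifMatch]:
    """All matches of a degenerate motif, sorted by plus-strand start.

    Reverse-strand matches are reported with strand "-" and the plus-strand
    start coordinate of the matched window.  Overlapping matches are all
    reported.
    """
    if isinstance(motif, str):
        motif = IupacMotif(motif)
    n_all = params.n_matches_all if params is not None else False
    hits = [MotifMatch(int(p) + 1, "+") for p in _scan_plus(ref.sequence, motif, n_all)]
    if both_strands:
        rc = motif.revcomp()
        hits += [MotifMatch(int(p) + 1, "-") for p in _scan_plus(ref.sequence, rc, n_all)]
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


class ABoxPartner(NamedTuple):
    interval: Interval
    a_class: str  # stringent | permissive
    spacing: int


def _matches_at(sequence: str, motif: IupacMotif, start0: int, n_all: bool) -> bool:
    window = sequence[start0 : start0 + len(motif)]
    if len(window) < len(motif):
        return False
    for base, code in zip(window, motif.pattern):
        allowed = set(IUPAC_CODES[code])
        if code == "N" or n_all:
            allowed.add("N")
        if base not in allowed:
            return False
    return True


def find_a_box_partners(
    ref: ReferenceSequence,
    b_box_match: MotifMatch,
    params: CatalogParams | None = None,
) -> list[ABoxPartner]:
    """Permissive A-box matches upstream of a B box at functional spacing.

    Spacing is counted as bases strictly between the A-box end and the B-box
    start, measured on the B box's strand.  Matches also satisfying the
    stringent motif are labelled "stringent".
    """
    params = params or CatalogParams()
    perm = IupacMotif(A_BOX_PERMISSIVE)
    strict = IupacMotif(A_BOX_STRINGENT)
    m = len(perm)
    out: list[ABoxPartner] = []
    if b_box_match.strand == "+":
        b_start = b_box_match.position
        # A box plus-interval [s, s+m-1]; spacing = b_start - (s+m-1) - 1
        s_lo = b_start - m - params.spacing_max
        s_hi = b_start - m - params.spacing_min
        for s in range(max(1, s_lo), s_hi + 1):
            if _matches_at(ref.sequence, perm, s - 1, params.n_matches_all):
                spacing = b_start - (s + m - 1) - 1
                cls = (
                    "stringent"
                    if _matches_at(ref.sequence, strict, s - 1, params.n_matches_all)
                    else "permissive"
                )
                out.append(ABoxPartner(Interval(s, s + m - 1), cls, spacing))
    else:
        b_end = b_box_match.position + len(B_BOX) - 1
        perm_rc, strict_rc = perm.revcomp(), strict.revcomp()
        # upstream on the minus strand = higher plus coordinates
        s_lo = b_end + params.spacing_min + 1
        s_hi = b_end + params.spacing_max + 1
        for s in range(s_lo, min(s_hi, len(ref) - m + 1) + 1):
            if _matches_at(ref.sequence, perm_rc, s - 1, params.n_matches_all):
                spacing = s - b_end - 1
                cls = (
                    "stringent"
                    if _matches_at(ref.sequence, strict_rc, s - 1, params.n_matches_all)
                    else "permissive"
                )
                out.append(ABoxPartner(Interval(s, s + m - 1), cls, spacing))
    return out


def assign_plus_one(
    a_box: Interval, strand: str, params: CatalogParams, ref_len: int
) -> int | None:
    """+1 coordinate implied by an A box (offset bp upstream of its start).

    On the minus strand the A-box "start" is the plus-coordinate end of the
    interval and upstream means higher plus coordinates.  Returns None (with
    a warning) if the position falls outside the reference.
    """
    if strand == "+":
        pos = a_box.start - params.plus_one_offset
    else:
        pos = a_box.end + params.plus_one_offset
    if not (1 <= pos <= ref_len):
        logger.warning("+1 position %d outside reference (len %d); locus dropped", pos, ref_len)
        return None
    return pos


@dataclass
class SoloBBox:
    ref_id: str
    position: int
    strand: str


def build_ab_box_catalog(
    refs: Sequence[ReferenceSequence],
    params: CatalogParams | None = None,
) -> tuple[list[PolIIITarget], list[SoloBBox]]:
    """Scan references for A/B-box loci and emit one target per paired B box.

    The stringent partner is preferred; among equals the one whose spacing is
    nearest the midpoint of the allowed range wins.  Solo B boxes (no A-box
    partner at functional spacing) are recorded but are not targets: a bare B
    box recruits TFIIIC but is a poor integration target.
    """
    params = params or CatalogParams()
    midpoint = (params.spacing_min + params.spacing_max) / 2
    targets: list[PolIIITarget] = []
    solos: list[SoloBBox] = []
    for ref in refs:
        if ref.kind == "plasmid":
            continue
        for hit in scan_motif(ref, B_BOX, params.scan_both_strands, params):
            partners = find_a_box_partners(ref, hit, params)
            if not partners:
                solos.append(SoloBBox(ref.id, hit.position, hit.strand))
                continue
            stringent = [p for p in partners if p.a_class == "stringent"]
            pool = stringent or partners
            best = min(pool, key=lambda p: (abs(p.spacing - midpoint), p.interval.start))
            plus_one = assign_plus_one(best.interval, hit.strand, params, len(ref))
            if plus_one is None:
                continue
            b_iv = Interval(hit.position, hit.position + len(B_BOX) - 1)
            targets.append(
                PolIIITarget(
                    id=f"{ref.id}:abbox:{plus_one}:{hit.strand}",
                    ref_id=ref.id,
                    plus_one_pos=plus_one,
                    strand=hit.strand,
                    target_class="ab_box",
                    a_box=best.interval,
                    b_box=b_iv,
                    a_box_class=best.a_class,
                    family="ab_box",
                )
            )
    targets.sort(key=lambda t: (t.ref_id, t.plus_one_pos, t.strand))
    return targets, solos


def upstream_flank(
    target: PolIIITarget, refs_by_id: dict[str, ReferenceSequence], flank_len: int
) -> str:
    """Flanking sequence upstream of the +1, read on the target's own strand."""
    seq = refs_by_id[target.ref_id].sequence
    p = target.plus_one_pos
    if target.strand == "+":
        return seq[max(0, p - 1 - flank_len) : p - 1]
    return revcomp(seq[p : p + flank_len])


def group_duplicate_loci(
    catalog: Sequence[PolIIITarget],
    refs: Sequence[ReferenceSequence],
    params: CatalogParams | None = None,
) -> list[PolIIITarget]:
    """Fill duplicate_group: identical upstream flanks -> one group.

    Loci whose flanking sequence is identical over the configured flank
    length cannot be told apart by short-fragment placement (nor by PCR), so
    they share a group id; every other locus gets its own group.
    """
    params = params or CatalogParams()
    refs_by_id = {r.id: r for r in refs}
    flank_to_group: dict[str, str] = {}
    out: list[PolIIITarget] = []
    for t in catalog:
        flank = upstream_flank(t, refs_by_id, params.flank_len_for_duplicates)
        if flank not in flank_to_group:
            flank_to_group[flank] = f"dg{len(flank_to_group) + 1}"
        out.append(replace(t, duplicate_group=flank_to_group[flank]))
    return out


def validate_target(
    target: PolIIITarget, params: CatalogParams | None = None
) -> list[str]:
    """Invariant violations for one target (empty list = valid)."""
    params = params or CatalogParams()
    problems = []
    if target.strand not in "+-":
        problems.append(f"bad strand {target.strand!r}")
    if target.target_class not in TARGET_CLASSES:
        problems.append(f"bad class {target.target_class!r}")
    if target.plus_one_pos < 1:
        problems.append("plus_one_pos < 1")
    if target.a_box is not None:
        expected = (
            target.a_box.start - params.plus_one_offset
            if target.strand == "+"
            else target.a_box.end + params.plus_one_offset
        )
        if expected != target.plus_one_pos:
            problems.append(
                f"+1 {target.plus_one_pos} is not {params.plus_one_offset} bp "
                f"upstream of A box {target.a_box}"
            )
    if target.a_box is not None and target.b_box is not None:
        if target.strand == "+":
            spacing = target.b_box.start - target.a_box.end - 1
        else:
            spacing = target.a_box.start - target.b_box.end - 1
        if not (params.spacing_min <= spacing <= params.spacing_max):
            problems.append(f"A/B spacing {spacing} outside bounds")
    return problems


# ---------------------------------------------------------------------------
# IO: BED6+ and GFF3
# ---------------------------------------------------------------------------

_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\t"
    "class\tplus_one\ta_box\tb_box\ta_class\tdup_group"
)


def _target_span(t: PolIIITarget) -> Interval:
    coords = [t.plus_one_pos]
    for iv in (t.a_box, t.b_box):
        if iv is not None:
            coords += [iv.start, iv.end]
    return Interval(min(coords), max(coords))


def write_catalog_bed(catalog: Sequence[PolIIITarget], path) -> None:
    """BED6+ catalog; spacing convention: bases strictly between box edges."""
    with open(path, "w") as fh:
        fh.write("#lamprof catalog; coords in extra columns are 1-based inclusive;"
                 " A/B spacing = bases strictly between A-box end and B-box start\n")
        fh.write(_BED_HEADER + "\n")
        for t in catalog:
            span = _target_span(t)
            fields = [
                t.ref_id,
                str(span.start - 1),  # 0-based half-open at the boundary only
                str(span.end),
                t.id,
                "0",
                t.strand,
                t.target_class,
                str(t.plus_one_pos),
                str(t.a_box) if t.a_box else ".",
                str(t.b_box) if t.b_box else ".",
                t.a_box_class,
                t.duplicate_group or ".",
            ]
            fh.write("\t".join(fields) + "\n")


def write_catalog_gff3(catalog: Sequence[PolIIITarget], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in catalog:
            span = _target_span(t)
            attrs = [f"ID={t.id}", f"plus_one={t.plus_one_pos}", f"a_class={t.a_box_class}"]
            if t.family:
                attrs.append(f"family={t.family}")
            if t.duplicate_group:
                attrs.append(f"dup_group={t.duplicate_group}")
            if t.a_box:
                attrs.append(f"a_box={t.a_box}")
            if t.b_box:
                attrs.append(f"b_box={t.b_box}")
            fh.write(
                "\t".join(
                    [
                        t.ref_id,
                        "lamprof",
                        t.target_class,
                        str(span.start),
                        str(span.end),
                        ".",
                        t.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def load_target_catalog(path, fmt: str = "BED") -> list[PolIIITarget]:
    """Load a catalog written by :func:`write_catalog_bed` / ``..._gff3``."""
    fmt = fmt.upper()
    if fmt not in ("BED", "GFF"):
        raise ValueError(f"unsupported catalog format {fmt!r}")
    targets: list[PolIIITarget] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                if fmt == "BED":
                    targets.append(_parse_bed_line(line))
                else:
                    targets.append(_parse_gff_line(line))
            except Exception as exc:  # malformed record -> rejected with line number
                raise ValueError(f"{path}: malformed record at line {lineno}: {exc}") from exc
    return targets


def _parse_bed_line(line: str) -> PolIIITarget:
    f = line.split("\t")
    if len(f) != 12:
        raise ValueError(f"expected 12 columns, got {len(f)}")
    return PolIIITarget(
        id=f[3],
        ref_id=f[0],
        plus_one_pos=int(f[7]),
        strand=f[5],
        target_class=f[6],
        a_box=Interval.parse(f[8]),
        b_box=Interval.parse(f[9]),
        a_box_class=f[10],
        duplicate_group=None if f[11] == "." else f[11],
    )


def _parse_gff_line(line: str) -> PolIIITarget:
    f = line.split("\t")
    if len(f) != 9:
        raise ValueError(f"expected 9 columns, got {len(f)}")
    attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if kv)
    return PolIIITarget(
        id=attrs["ID"],
        ref_id=f[0],
        plus_one_pos=int(attrs["plus_one"]),
        strand=f[6],
        target_class=f[2],
        a_box=Interval.parse(attrs.get("a_box", ".")),
        b_box=Interval.parse(attrs.get("b_box", ".")),
        a_box_class=attrs.get("a_class", "absent"),
        family=attrs.get("family", ""),
        duplicate_group=attrs.get("dup_group"),
    )


def write_solo_report(solos: Sequence[SoloBBox], path) -> None:
    with open(path, "w") as fh:
        fh.write("#ref_id\tposition\tstrand\n")
        for s in solos:
            fh.write(f"{s.ref_id}\t{s.position}\t{s.strand}\n")
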