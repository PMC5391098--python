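"""Target catalog: IUPAC scanning, A/B pairing, +1 assignment, IO."""

from __future__ import annotations

import re

import numpy as np
import pytest

from lamprof._dna import random_dna, revcomp
from lamprof.catalog import (
    A_BOX_PERMISSIVE,
    A_BOX_STRINGENT,
    B_BOX,
    CatalogParams,
    Interval,
    IupacMotif,
    MotifMatch,
    PolIIITarget,
    ReferenceSequence,
    assign_plus_one,
    build_ab_box_catalog,
    find_a_box_partners,
    group_duplicate_loci,
    load_target_catalog,
    scan_motif,
    validate_target,
    write_catalog_bed,
    write_catalog_gff3,
)

IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "Y": "[CT]",
    "W": "[AT]", "S": "[CG]", "K": "[GT]", "M": "[AC]", "B": "[CGT]",
    "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def regex_scan(seq: str, pattern: str):
    """Independent oracle: overlap-aware regex scan on both strands."""
    out = []
    for strand, pat in (("+", pattern), ("-", revcomp(pattern))):
        rx = re.compile("(?=(" + "".join(IUPAC_RE[c] for c in pat) + "))")
        out += [(m.start() + 1, strand) for m in rx.finditer(seq)]
    return sorted(out)


def test_scan_finds_consensus_instance():
    ref = ReferenceSequence("r", "AAGTTCAAACCTT")
    hits = scan_motif(ref, B_BOX, both_strands=False)
    assert hits == [MotifMatch(3, "+")]


def test_scan_rejects_nonmatching_degenerate_position():
    # 5th base of GTTCRANNC must be a purine
    ref = ReferenceSequence("r", "GTTCTAACC")
    assert scan_motif(ref, B_BOX, both_strands=False) == []


def test_invalid_iupac_character_rejected():
    with pytest.raises(ValueError):
        IupacMotif("GTTXRANNC")


@pytest.mark.parametrize("motif", [B_BOX, A_BOX_PERMISSIVE, A_BOX_STRINGENT])
def test_scan_matches_regex_oracle(motif):
    rng = np.random.default_rng(5)
    for _ in range(60):
        seq = random_dna(rng, int(rng.integers(200, 2000)), gc=0.4)
        ref = ReferenceSequence("r", seq)
        got = sorted((h.position, h.strand) for h in scan_motif(ref, motif))
        assert got == regex_scan(seq, motif)


def _embed(b_pos: int, a_seq: str, spacing: int, length: int = 200) -> ReferenceSequence:
    """Plus-strand B box at b_pos with an A-box instance at the given spacing."""
    seq = list("A" * length)
    b = "GTTCAAACC"
    seq[b_pos - 1 : b_pos - 1 + 9] = b
    a_start = b_pos - spacing - len(a_seq)
    seq[a_start - 1 : a_start - 1 + len(a_seq)] = a_seq
    return ReferenceSequence("r", "".join(seq))


def test_a_box_partner_at_valid_spacing():
    ref = _embed(100, "TAGGCGATTAG", spacing=45)
    partners = find_a_box_partners(ref, MotifMatch(100, "+"))
    assert len(partners) == 1
    assert partners[0].spacing == 45
    assert partners[0].a_class == "permissive"


def test_a_box_too_close_is_no_partner():
    ref = _embed(100, "TAGGCGATTAG", spacing=25)
    assert find_a_box_partners(ref, MotifMatch(100, "+")) == []


def test_stringent_a_box_labelled():
    ref = _embed(100, "TGGCTTAGTTG", spacing=40)
    partners = find_a_box_partners(ref, MotifMatch(100, "+"))
    assert [p.a_class for p in partners] == ["stringent"]


def test_minus_strand_partner_mirrors_plus():
    ref = _embed(100, "TGGCTTAGTTG", spacing=40)
    rc = ReferenceSequence("rc", revcomp(ref.sequence))
    (b_rc,) = [h for h in scan_motif(rc, B_BOX) if h.strand == "-"]
    partners = find_a_box_partners(rc, b_rc)
    assert len(partners) == 1 and partners[0].spacing == 40


def test_plus_one_arithmetic():
    params = CatalogParams()
    assert assign_plus_one(Interval(108, 118), "+", params, 1000) == 101
    assert assign_plus_one(Interval(8, 18), "+", params, 1000) == 1
    assert assign_plus_one(Interval(490, 500), "-", params, 1000) == 507
    # mirror check: a minus-strand A box equals the plus-strand construction
    # on the reverse complement
    L = 1000
    plus_iv, strand = Interval(108, 118), "+"
    plus_one = assign_plus_one(plus_iv, strand, params, L)
    rc_iv = Interval(L - plus_iv.end + 1, L - plus_iv.start + 1)
    rc_plus_one = assign_plus_one(rc_iv, "-", params, L)
    assert rc_plus_one == L - plus_one + 1


def test_plus_one_outside_reference_dropped():
    assert assign_plus_one(Interval(4, 14), "+", CatalogParams(), 1000) is None


def _toy_arm() -> ReferenceSequence:
    """Three B boxes: one stringent partner, one permissive, one solo."""
    seq = list("A" * 600)

    def put(pos, s):
        seq[pos - 1 : pos - 1 + len(s)] = s

    put(150, "TGGCTTAGTTG")   # stringent A box
    put(150 + 11 + 40, "GTTCAAACC")
    put(300, "TAGGCGATTAG")   # permissive-only A box
    put(300 + 11 + 35, "GTTCGAACC")
    put(500, "GTTCAAACC")     # solo
    return ReferenceSequence("arm", "".join(seq))


def test_build_catalog_toy_arm():
    targets, solos = build_ab_box_catalog([_toy_arm()], CatalogParams(scan_both_strands=False))
    assert len(targets) == 2
    assert sorted(t.a_box_class for t in targets) == ["permissive", "stringent"]
    assert len(solos) == 1 and solos[0].position == 500
    for t in targets:
        assert validate_target(t) == []


def test_palindrome_catalog_is_mirror_of_arm():
    arm = _toy_arm()
    pal = ReferenceSequence("pal", arm.sequence + revcomp(arm.sequence))
    arm_targets, _ = build_ab_box_catalog([arm])
    pal_targets, _ = build_ab_box_catalog([pal])
    assert len(pal_targets) == 2 * len(arm_targets)
    L = 2 * len(arm)
    plus = {(t.plus_one_pos, t.strand) for t in pal_targets if t.plus_one_pos <= len(arm)}
    minus = {(t.plus_one_pos, t.strand) for t in pal_targets if t.plus_one_pos > len(arm)}
    assert {(L - p + 1, "-") for p, _ in plus} == minus


def test_empty_or_n_reference_gives_empty_catalog():
    targets, solos = build_ab_box_catalog([ReferenceSequence("n", "N" * 500)])
    assert targets == [] and solos == []


def test_catalog_bed_roundtrip(tmp_path, small_world):
    _, refs, catalog = small_world
    path = tmp_path / "cat.bed"
    write_catalog_bed(catalog[:5], path)
    back = load_target_catalog(path, "BED")
    for a, b in zip(catalog[:5], back):
        assert (a.id, a.ref_id, a.plus_one_pos, a.strand, a.target_class,
                a.a_box, a.b_box, a.a_box_class, a.duplicate_group) == (
            b.id, b.ref_id, b.plus_one_pos, b.strand, b.target_class,
            b.a_box, b.b_box, b.a_box_class, b.duplicate_group)


def test_catalog_gff_roundtrip(tmp_path, small_world):
    _, refs, catalog = small_world
    path = tmp_path / "cat.gff3"
    write_catalog_gff3(catalog[:5], path)
    back = load_target_catalog(path, "GFF")
    assert [(t.id, t.plus_one_pos, t.strand) for t in back] == [
        (t.id, t.plus_one_pos, t.strand) for t in catalog[:5]]


def test_malformed_record_reports_line_number(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("#header\nchr1\t10\t20\tonly-four\n")
    with pytest.raises(ValueError, match="line 2"):
        load_target_catalog(path, "BED")


def test_duplicate_grouping_by_flank_identity():
    rng = np.random.default_rng(7)
    flank = random_dna(rng, 200, 0.25)
    gene = "G" + random_dna(rng, 40, 0.25)
    filler = random_dna(rng, 300, 0.25)
    seq = flank + gene + filler + flank + gene + filler
    # third locus: flank differs at one base
    mut = list(flank)
    mut[100] = {"A": "C"}.get(mut[100], "A")
    seq += "".join(mut) + gene
    ref = ReferenceSequence("r", seq)
    p1 = len(flank) + 1
    p2 = len(flank) + len(gene) + len(filler) + len(flank) + 1
    p3 = p2 + len(gene) + len(filler) + len(flank)
    mk = lambda i, p: PolIIITarget(f"t{i}", "r", p, "+", "trna")
    grouped = group_duplicate_loci([mk(1, p1), mk(2, p2), mk(3, p3)], [ref])
    assert grouped[0].duplicate_group == grouped[1].duplicate_group
    assert grouped[2].duplicate_group != grouped[0].duplicate_group


def test_emitted_targets_satisfy_invariants(small_world):
    _, refs, catalog = small_world
    scanned, _ = build_ab_box_catalog(refs)
    for t in scanned:
        assert validate_target(t) == [], t
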