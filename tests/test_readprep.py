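"""Pair merging, primer checks, element trimming and length filtering."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lamprof._dna import random_dna, revcomp
from lamprof.readprep import (
    JunctionFragment,
    PrepParams,
    PseudoRead,
    length_filter,
    locate_and_trim_element,
    merge_pair,
    require_primer,
    trim_target_end,
)
from lamprof.simulate import default_element_model


def _reads_from_fragment(frag: str, read_len: int):
    r1 = frag[:read_len]
    r2 = revcomp(frag)[:read_len]
    return (r1, "I" * len(r1)), (r2, "I" * len(r2))


def test_merge_reconstructs_fragment():
    rng = np.random.default_rng(0)
    frag = random_dna(rng, 110, 0.4)
    out = merge_pair(*_reads_from_fragment(frag, 60))
    assert out.status == "merged"
    assert out.pseudoread.sequence == frag


def test_merge_rejects_short_pseudoread():
    # 90-nt fragment merges fine but fails the 100-nt minimum
    rng = np.random.default_rng(1)
    frag = random_dna(rng, 90, 0.4)
    out = merge_pair(*_reads_from_fragment(frag, 60))
    assert out.status == "rejected" and out.reason == "too_short"


def test_merge_rejects_disjoint_reads():
    rng = np.random.default_rng(2)
    a, b = random_dna(rng, 80, 0.5), random_dna(rng, 80, 0.5)
    out = merge_pair((a, "I" * 80), (revcomp(b), "I" * 80))
    assert out.status == "rejected" and out.reason == "no_overlap"


@settings(max_examples=30, derandomize=True)
@given(frag_len=st.integers(110, 400), read_len=st.integers(80, 300), seed=st.integers(0, 10**6))
def test_merge_property_reconstruction(frag_len, read_len, seed):
    """Any fragment covered by its two reads with >=10 bp overlap merges back."""
    if 2 * read_len - frag_len < 10:
        return
    rng = np.random.default_rng(seed)
    frag = random_dna(rng, frag_len, 0.35)
    out = merge_pair(*_reads_from_fragment(frag, read_len))
    assert out.status == "merged" and out.pseudoread.sequence == frag


def test_merge_consensus_takes_higher_quality_base():
    rng = np.random.default_rng(9)
    frag = random_dna(rng, 120, 0.4)
    r1 = frag[:70]
    r2 = revcomp(frag)[:70]
    # corrupt one overlap base on read 1 with low quality
    wrong = "C" if frag[60] != "C" else "G"
    r1 = r1[:60] + wrong + r1[61:]
    q1 = "I" * 60 + "#" + "I" * 9
    out = merge_pair((r1, q1), (r2, "I" * 70))
    assert out.status == "merged"
    assert out.pseudoread.sequence == frag


def test_require_primer_cases():
    primer = "ACGTACGTACGTACGTACGT"
    rng = np.random.default_rng(3)
    body = random_dna(rng, 80, 0.3)
    pr = PseudoRead("x", body + primer + body, "I" * (160 + 20))
    assert require_primer(pr, primer)
    two_mm = "TT" + primer[2:]
    pr2 = PseudoRead("x", body + two_mm + body, "I" * (160 + 20))
    assert not require_primer(pr2, primer)
    pr3 = PseudoRead("x", body + revcomp(primer) + body, "I" * (160 + 20))
    assert require_primer(pr3, primer)


def test_locate_and_trim_on_planted_reads(clean_run):
    """Truth oracle: called truncation equals the planted truncation and the
    partition reconstructs the pseudoread exactly."""
    element = default_element_model()
    by_ev = {e.event_id: e for e in clean_run["events"]}
    checked = 0
    for rp in clean_run["pairs"]:
        e = by_ev.get(clean_run["sources"][rp.read_id])
        if e is None:
            continue
        merged = merge_pair((rp.seq1, rp.qual1), (rp.seq2, rp.qual2),
                            read_id=rp.read_id)
        assert merged.status == "merged"
        out = locate_and_trim_element(merged.pseudoread, element)
        assert out.status == "trimmed"
        frag = out.fragment
        assert frag.truncation == e.truncation
        # partition conservation
        el, ex, gp, pp = frag.partition_lengths()
        assert el + ex + gp + pp == frag.pseudoread_len
        # reassembled read: genomic part is stored reverse-complemented
        assert revcomp(frag.genomic_part) + frag.element_part == merged.pseudoread.sequence
        checked += 1
    assert checked >= 20


def test_read_without_element_rejected():
    rng = np.random.default_rng(4)
    pr = PseudoRead("bg", random_dna(rng, 200, 0.25), "I" * 200)
    out = locate_and_trim_element(pr, default_element_model())
    assert out.status == "rejected" and out.reason == "no_element"


def test_read_entirely_within_element_has_empty_genomic_part():
    element = default_element_model()
    pr = PseudoRead("orf", element.full_sequence[50:260], "I" * 210)
    out = locate_and_trim_element(pr, element)
    assert out.status == "trimmed"
    assert out.fragment.genomic_part == ""
    assert not length_filter(out.fragment)


def _frag(genomic: str) -> JunctionFragment:
    from lamprof.catalog import Interval

    return JunctionFragment(
        read_id="f", pseudoread_len=len(genomic) + 100, genomic_part=genomic,
        element_part="E" * 100, element_interval_on_read=Interval(1, 100),
        element_5p_coord_on_element=1,
    )


def test_trim_tdna_primer_suffix():
    rng = np.random.default_rng(5)
    primer = random_dna(rng, 20, 0.4)
    frag = trim_target_end(_frag(random_dna(rng, 50, 0.25) + primer), "tdna", [primer])
    assert frag.primer_found and frag.primer_part == primer
    assert len(frag.genomic_part) == 50


def test_trim_adapter_removes_hexamer_too():
    rng = np.random.default_rng(6)
    adapter = random_dna(rng, 24, 0.5)
    h6 = random_dna(rng, 6, 0.5)
    gp = random_dna(rng, 60, 0.25) + revcomp(h6) + revcomp(adapter)
    frag = trim_target_end(_frag(gp), "adapter", adapter)
    assert frag.primer_found
    assert len(frag.genomic_part) == 60


def test_trim_without_primer_flags_fragment():
    rng = np.random.default_rng(7)
    frag = trim_target_end(_frag(random_dna(rng, 60, 0.25)), "tdna",
                           [random_dna(rng, 20, 0.5)])
    assert not frag.primer_found and len(frag.genomic_part) == 60


@pytest.mark.parametrize("n,keep", [(40, True), (39, False), (0, False)])
def test_length_filter_boundary(n, keep):
    assert length_filter(_frag("A" * n)) is keep


def test_higher_error_rate_lowers_retention(small_world):
    from lamprof.simulate import SimParams, plant_integrations, simulate_amplicons
    from conftest import SMALL

    _, refs, catalog = small_world
    element = default_element_model()
    retained = []
    for err in (0.0, 0.03, 0.10):
        frac = []
        for seed in (21, 22):
            p = SimParams(seed=seed, n_events=8, error_rate=err,
                          background_fraction=0.0, **SMALL)
            ev, _ = plant_integrations(refs, catalog, p)
            pairs, _ = simulate_amplicons(ev, refs, p)
            ok = 0
            for rp in pairs:
                m = merge_pair((rp.seq1, rp.qual1), (rp.seq2, rp.qual2))
                if m.status != "merged":
                    continue
                t = locate_and_trim_element(m.pseudoread, element)
                if t.status == "trimmed" and length_filter(t.fragment):
                    ok += 1
            frac.append(ok / len(pairs))
        retained.append(sum(frac) / len(frac))
    assert retained[0] >= retained[1] >= retained[2]
    assert retained[0] > retained[2]
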