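"""Synthetic-data generator: determinism, planted structure, distributions."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from lamprof._dna import revcomp
from lamprof.catalog import build_ab_box_catalog
from lamprof.simulate import (
    SimParams,
    default_element_model,
    distance_pmf,
    make_genome,
    plant_integrations,
    sample_distances,
    simulate_amplicons,
    tdna_primer_for,
)
from conftest import SMALL


def _small(**kw) -> SimParams:
    merged = {**SMALL, **kw}
    return SimParams(**merged)


def test_generator_is_deterministic():
    p = _small(seed=1, n_events=8, error_rate=0.01)
    out = []
    for _ in range(2):
        refs, cat = make_genome(p)
        ev, truth = plant_integrations(refs, cat, p)
        pairs, src = simulate_amplicons(ev, refs, p)
        out.append((
            [(r.id, r.sequence) for r in refs],
            [(t.id, t.plus_one_pos, t.strand, t.duplicate_group) for t in cat],
            truth.to_csv(),
            [(q.read_id, q.seq1, q.seq2) for q in pairs],
        ))
    assert out[0] == out[1]


def test_zero_gc_background_is_all_at():
    p = _small(seed=2, gc_content=0.0, n_trna_genes=2, n_trna_families=1)
    refs, cat = make_genome(p)
    chrom = refs[0].sequence
    # outside planted cassettes (which contain motif-constrained G/C) the
    # background must be pure A/T; check a window far from any target
    far = chrom[100:1000]
    assert set(far) <= set("AT")


def test_planted_targets_rediscovered_by_scanner(small_world):
    _, refs, catalog = small_world
    scanned, _ = build_ab_box_catalog(refs)
    found = {(t.ref_id, t.plus_one_pos, t.strand) for t in scanned}
    for t in catalog:
        if t.a_box is not None:  # tRNA genes and A/B-box loci carry boxes
            assert (t.ref_id, t.plus_one_pos, t.strand) in found


def test_palindrome_twins_share_duplicate_group(small_world):
    _, refs, catalog = small_world
    by_id = {t.id: t for t in catalog}
    for t in catalog:
        if t.ref_id == "palindrome" and not t.id.endswith("m"):
            twin = by_id[t.id + "m"]
            assert twin.duplicate_group == t.duplicate_group
            assert twin.strand != t.strand


def test_distance_sampler_matches_configured_distribution():
    p = _small()
    values, probs = distance_pmf(p)
    draws = sample_distances(p, 10_000, np.random.default_rng(3))
    obs = np.array([(draws == v).sum() for v in values])
    exp = probs * len(draws)
    # pool bins with tiny expectation into one tail bin
    keep = exp >= 5
    obs_p = np.append(obs[keep], obs[~keep].sum())
    exp_p = np.append(exp[keep], exp[~keep].sum())
    chi = stats.chisquare(obs_p, exp_p)
    assert chi.pvalue > 0.01


def test_planted_distances_follow_distribution(small_world):
    """Truth-table distances pass a goodness-of-fit check at n=10,000.

    Key uniqueness is switched off here: with it on, collisions in a small
    key space deliberately re-draw distances and the truth table is no
    longer a plain sample of the configured distribution.
    """
    params, refs, catalog = small_world
    p = _small(seed=4, n_events=10_000, unique_event_keys=False,
               p_truncation=0.0, p_extra_nt=0.0)
    _, truth = plant_integrations(refs, catalog, p)
    d = truth["distance_to_plus_one"].to_numpy()
    values, probs = distance_pmf(p)
    obs = np.array([(d == v).sum() for v in values])
    exp = probs * len(d)
    keep = exp >= 5
    obs_p = np.append(obs[keep], obs[~keep].sum())
    exp_p = np.append(exp[keep], exp[~keep].sum())
    chi = stats.chisquare(obs_p, exp_p)
    assert chi.pvalue > 0.01


def test_degenerate_distance_distribution():
    p = _small(seed=5, n_events=10, distance_min=47, distance_max=47)
    refs, cat = make_genome(p)
    _, truth = plant_integrations(refs, cat, p)
    assert (truth["distance_to_plus_one"] == 47).all()


def test_forced_extras_always_present():
    p = _small(seed=6, n_events=10, p_extra_nt=1.0, extra_len_range=(1, 1))
    refs, cat = make_genome(p)
    _, truth = plant_integrations(refs, cat, p)
    assert (truth["extras"].str.len() == 1).all()


def test_element_five_prime_end_faces_target(small_world):
    """By construction the element 5' terminus is junction-proximal."""
    _, refs, catalog = small_world
    p = _small(seed=7, n_events=6, p_truncation=0.0, p_extra_nt=0.0)
    ev, _ = plant_integrations(refs, catalog, p)
    element = default_element_model()
    for e in ev:
        S = {r.id: r for r in refs}[e.target.ref_id].sequence
        w = e.hap_window
        head = element.full_sequence[:25]
        if e.target.strand == "+":
            # plus layout: ... rc(element) | spacer | gene -> the rc of the
            # element 5' end abuts the junction base
            i = w.index(revcomp(head))
            spacer = w[i + 25 : i + 25 + e.distance]
        else:
            i = w.index(head)
            spacer = w[i - e.distance : i]
        assert len(spacer) == e.distance
        assert spacer in S  # spacer is untouched genomic sequence


def test_error_free_reads_reconstruct_junction(clean_run):
    """Merged pseudoread equals a contiguous slice of the mutated haplotype."""
    by_ev = {e.event_id: e for e in clean_run["events"]}
    n = 0
    for rp in clean_run["pairs"]:
        e = by_ev.get(clean_run["sources"][rp.read_id])
        if e is None:
            continue
        assert rp.seq1 in e.hap_window or revcomp(rp.seq1) in e.hap_window
        n += 1
    assert n > 0


def test_background_fraction_half_gives_equal_counts(small_world):
    _, refs, catalog = small_world
    p = _small(seed=8, n_events=10, background_fraction=0.5,
               n_reads_per_event=(5, 5))
    ev, _ = plant_integrations(refs, catalog, p)
    pairs, src = simulate_amplicons(ev, refs, p)
    n_bg = sum(1 for v in src.values() if v.startswith("bg_"))
    assert len(pairs) == 100 and n_bg == 50


def test_library_reads_contain_their_primers(small_world):
    _, refs, catalog = small_world
    element = default_element_model()
    refs_by_id = {r.id: r for r in refs}
    for lib in ("tdna", "adapter"):
        p = _small(seed=9, n_events=6, library_type=lib, error_rate=0.0,
                   background_fraction=0.0)
        ev, _ = plant_integrations(refs, catalog, p)
        pairs, src = simulate_amplicons(ev, refs, p)
        by_ev = {e.event_id: e for e in ev}
        for rp in pairs:
            frag = rp.seq1  # R1 is the fragment prefix; fragment <= read span
            full = frag if len(frag) < p.read_len else None
            e = by_ev[src[rp.read_id]]
            if lib == "adapter":
                nested = element.nested_primer_seq
                assert nested in rp.seq1 or nested in revcomp(rp.seq2)
            else:
                primer = tdna_primer_for(e.target, refs_by_id)
                assert revcomp(primer) in rp.seq1 or primer in rp.seq2


def test_infeasible_packing_rejected():
    with pytest.raises(ValueError, match="pack"):
        make_genome(SimParams(genome_len=5_000, n_trna_genes=40))
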