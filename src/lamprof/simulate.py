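"""Synthetic genomes, planted integrations and LAM-PCR-shaped reads.

The generator emulates the study system at desk scale: an A+T-rich genome
carrying tRNA genes (+1 G, A box fixed at +8, B box at 32-57 bp spacing), a
mirror-symmetric two-arm palindrome carrying bare A/B-box loci and a 5S-like
gene, and a tagged non-LTR element that integrates orientation-specifically
upstream of Pol III targets, with 5' truncations, non-templated extra
nucleotides at the 5' junction, and target-site duplications.  Reads mimic
the two library designs: amplicons ending at a tRNA-gene-family primer
("tdna") or at an adapter ligated via a random hexamer ("adapter"),
plus plasmid (promoter-context) and unrelated-genome background pairs.

Every output is deterministic given the seed, and every planted event is
recorded in a machine-readable truth table for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._dna import IUPAC_CODES, random_dna, revcomp
from .catalog import (
    A_BOX_PERMISSIVE,
    A_BOX_STRINGENT,
    B_BOX,
    CatalogParams,
    Interval,
    IupacMotif,
    PolIIITarget,
    ReferenceSequence,
    group_duplicate_loci,
    scan_motif,
)

# tDNA primer geometry: the family primer anneals at gene positions +18..+37
# (on the gene strand), so after primer trimming the genomic part of a read
# is spacer + 17 gene bases; the shortest observed spacer (23 bp) then sits
# exactly at the 40-nt length filter.
TDNA_PRIMER_OFFSET = 18
TDNA_PRIMER_LEN = 20

ADAPTER_SEQ = "CCATCTCATCCCTGCGTGTCTCCG"  # adapter-oligo analog (fixed)

_QUAL = "?"  # constant Q30


@dataclass
class ElementModel:
    """The tagged element as transformed: retained UTR + marked ORF1 body."""

    full_sequence: str
    retained_utr_len: int = 42
    orf1_primer_site: Interval = Interval(261, 290)    # LAM primer analog
    nested_primer_site: Interval = Interval(231, 260)  # nested primer analog
    plasmid_context: str = ""  # promoter region upstream of the element

    def __post_init__(self) -> None:
        L = len(self.full_sequence)
        for iv in (self.orf1_primer_site, self.nested_primer_site):
            if not (1 <= iv.start <= iv.end <= L):
                raise ValueError("primer site outside element sequence")
        if self.retained_utr_len >= L:
            raise ValueError("retained UTR longer than element")

    @property
    def nested_primer_seq(self) -> str:
        s, e = self.nested_primer_site
        return self.full_sequence[s - 1 : e]


def default_element_model() -> ElementModel:
    """A fixed 300-bp element analog: 42-bp retained UTR + codon-adapted body."""
    rng = np.random.default_rng(20170413)
    utr = random_dna(rng, 42, gc=0.30)
    body = random_dna(rng, 258, gc=0.45)
    context = random_dna(rng, 250, gc=0.30)
    return ElementModel(full_sequence=utr + body, plasmid_context=context)


@dataclass
class SimParams:
    genome_len: int = 120_000
    gc_content: float = 0.25
    n_trna_genes: int = 40
    n_trna_families: int = 20
    arm_len: int = 9_000
    ab_spacing_range: tuple[int, int] = (32, 57)
    distance_mean: float = 47.0
    distance_sd: float = 2.0
    distance_min: int = 23
    distance_max: int = 181
    tsd_len_range: tuple[int, int] = (0, 15)
    p_truncation: float = 0.3
    truncation_geom_p: float = 0.3
    max_truncation: int = 40
    p_extra_nt: float = 0.4
    extra_len_range: tuple[int, int] = (1, 3)
    read_len: int = 300
    frag_len_range: tuple[int, int] = (260, 430)
    error_rate: float = 0.005
    library_type: str = "tdna"  # tdna | adapter
    n_reads_per_event: tuple[int, int] = (2, 8)
    n_events: int = 500
    background_fraction: float = 0.05
    background_plasmid_fraction: float = 0.5
    target_classes: tuple[str, ...] | None = None
    #: enforce unique (target group, distance, truncation, extras) keys so
    #: the called event multiset is comparable to the truth table; disable
    #: for distribution-level studies, where key collisions would otherwise
    #: distort the sampled distances
    unique_event_keys: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.gc_content, self.p_truncation, self.truncation_geom_p,
                  self.p_extra_nt, self.error_rate, self.background_fraction,
                  self.background_plasmid_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.library_type not in ("tdna", "adapter"):
            raise ValueError(f"unknown library_type {self.library_type!r}")
        if self.distance_min < 1:
            raise ValueError("distance support must be positive")


def distance_pmf(params: SimParams) -> tuple[np.ndarray, np.ndarray]:
    """Integer-Gaussian insertion-distance distribution, truncated."""
    values = np.arange(params.distance_min, params.distance_max + 1)
    z = (values - params.distance_mean) / params.distance_sd
    w = np.exp(-0.5 * z * z)
    return values, w / w.sum()


def sample_distances(params: SimParams, n: int,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw n insertion distances from the configured distribution."""
    rng = rng or np.random.default_rng(params.seed)
    values, probs = distance_pmf(params)
    return rng.choice(values, size=n, p=probs)


def _sample_motif(rng: np.random.Generator, pattern: str) -> str:
    return "".join(rng.choice(sorted(IUPAC_CODES[c])) for c in pattern)


def _sample_permissive_only_abox(rng: np.random.Generator) -> str:
    strict = IupacMotif(A_BOX_STRINGENT)
    for _ in range(100):
        s = _sample_motif(rng, A_BOX_PERMISSIVE)
        if any(s[i] not in IUPAC_CODES[c] for i, c in enumerate(strict.pattern)):
            return s
    raise RuntimeError("could not sample a permissive-only A box")


def _pol3_cassette(rng: np.random.Generator, spacing: int, gc: float,
                   a_class: str = "stringent") -> tuple[str, int]:
    """+1 G .. B-box cassette on its own strand; returns (seq, b_start offset).

    Layout (1-based offsets within the returned string): +1 G at 1, A box at
    8..18, spacer of ``spacing`` bases, B box of 9 bp, short tail.
    """
    if a_class == "stringent":
        a_box = _sample_motif(rng, A_BOX_STRINGENT)
    else:
        a_box = _sample_permissive_only_abox(rng)
    spacer = random_dna(rng, spacing, gc).replace("G", "A")  # no chance A-box G
    b_box = _sample_motif(rng, B_BOX)
    tail = random_dna(rng, 12, gc) + "TTTTTT"
    seq = "G" + random_dna(rng, 6, gc) + a_box + spacer + b_box + tail
    return seq, 19 + spacing


def _window_is_clean(seq: str, b_start: int, a_start: int, a_class: str,
                     cat_params: CatalogParams) -> bool:
    """True iff the planted A box is the unique viable partner of its B box.

    ``seq`` is read on the locus strand; offsets are 1-based within it.  A
    competing stringent match (or, for permissive-only loci, any competing
    permissive match) in the spacing window would make the catalog builder
    pick a different partner, so such draws are rejected.
    """
    from .catalog import find_a_box_partners, MotifMatch

    ref = ReferenceSequence("w", seq.replace("N", "A"))
    partners = find_a_box_partners(ref, MotifMatch(b_start, "+"), cat_params)
    if a_class == "stringent":
        competing = [p for p in partners if p.a_class == "stringent"]
    else:
        if any(p.a_class == "stringent" for p in partners):
            return False
        competing = partners
    return len(competing) == 1 and competing[0].interval.start == a_start


@dataclass
class _Locus:
    """A feature to stamp on a reference under construction."""

    target_class: str
    family: str
    plus_one_offset_in_seq: int  # +1 offset within the stamped string (1-based)
    sequence: str                # on the locus strand
    a_rel: Interval | None
    b_rel: Interval | None
    a_class: str


def _make_trna_family(rng: np.random.Generator, params: SimParams,
                      cat_params: CatalogParams, family: str) -> _Locus:
    lo, hi = params.ab_spacing_range
    for _ in range(200):
        spacing = int(rng.integers(lo, hi + 1))
        seq, b_start = _pol3_cassette(rng, spacing, params.gc_content)
        head = random_dna(rng, 80, params.gc_content)
        if _window_is_clean(head + seq, b_start + 80, 8 + 80, "stringent", cat_params):
            return _Locus("trna", family, 1, seq, Interval(8, 18),
                          Interval(b_start, b_start + 8), "stringent")
    raise RuntimeError("could not build a clean tRNA gene cassette")


def _make_ab_box_locus(rng: np.random.Generator, params: SimParams,
                       cat_params: CatalogParams, a_class: str) -> _Locus:
    lo, hi = params.ab_spacing_range
    for _ in range(200):
        spacing = int(rng.integers(lo, hi + 1))
        seq, b_start = _pol3_cassette(rng, spacing, params.gc_content, a_class)
        head = random_dna(rng, 80, params.gc_content)
        if _window_is_clean(head + seq, b_start + 80, 8 + 80, a_class, cat_params):
            return _Locus("ab_box", "ab_box", 1, seq, Interval(8, 18),
                          Interval(b_start, b_start + 8), a_class)
    raise RuntimeError("could not build a clean A/B box locus")


def _make_solo_bbox(rng: np.random.Generator, params: SimParams) -> str:
    """A bare B box whose upstream spacing window cannot host an A box."""
    # permissive A boxes need a G at motif position 11; a G-free window
    # upstream of the B box therefore guarantees the box stays solo.
    upstream = random_dna(rng, 75, params.gc_content).replace("G", "C")
    return upstream + _sample_motif(rng, B_BOX)


def _stamp(background: list[str], start0: int, seq: str) -> None:
    if start0 < 0 or start0 + len(seq) > len(background):
        raise ValueError("feature does not fit inside the reference")
    background[start0 : start0 + len(seq)] = list(seq)


def make_genome(
    params: SimParams, seed: int | None = None,
    cat_params: CatalogParams | None = None,
) -> tuple[list[ReferenceSequence], list[PolIIITarget]]:
    """Background DNA with planted targets, plus the matching truth catalog.

    Returns a chromosome with tRNA genes (family copies share the gene
    sequence; flanks are unique), a two-arm mirror palindrome with A/B-box
    loci, solo B boxes and a 5S-like gene, a plasmid-context reference, and
    the catalog of every planted target (duplicate groups filled).
    """
    cat_params = cat_params or CatalogParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    element = default_element_model()

    # --- chromosome with tRNA genes ---------------------------------------
    n = params.n_trna_genes
    slot = params.genome_len // (n + 1)
    min_span = 700 + params.distance_max
    if slot < min_span:
        raise ValueError(
            f"cannot pack {n} tRNA genes into {params.genome_len} bp without overlap"
        )
    families = [f"fam{i + 1:02d}" for i in range(min(params.n_trna_families, n))]
    fam_loci = {}
    chrom = list(random_dna(rng, params.genome_len, params.gc_content))
    targets: list[PolIIITarget] = []
    for i in range(n):
        family = families[i % len(families)]
        if family not in fam_loci:
            fam_loci[family] = _make_trna_family(rng, params, cat_params, family)
        locus = fam_loci[family]
        anchor = (i + 1) * slot + int(rng.integers(-slot // 8, slot // 8 + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        targets.append(
            _plant_locus(chrom, "chr1", locus, anchor, strand,
                         f"tRNA-{family}-{i + 1}", rng, params, cat_params)
        )

    # --- palindrome arm: A/B box loci, solo B boxes, 5S --------------------
    arm = list(random_dna(rng, params.arm_len, params.gc_content))
    arm_targets: list[PolIIITarget] = []
    pal_specs = [("stringent", 3), ("permissive", 2)]
    pos = 2_000
    # 9 features (5 A/B-box loci, 3 solo B boxes, the 5S gene) must fit with
    # room for flanks and the widest insertion-distance window
    step = (params.arm_len - 2_350) // 9
    if step < 300:
        raise ValueError(
            f"cannot pack palindrome features into a {params.arm_len} bp arm"
        )
    k = 0
    for a_class, count in pal_specs:
        for _ in range(count):
            locus = _make_ab_box_locus(rng, params, cat_params, a_class)
            k += 1
            arm_targets.append(
                _plant_locus(arm, "palindrome", locus, pos, "+",
                             f"abbox-{k}", rng, params, cat_params)
            )
            pos += step
    for _ in range(3):  # solo B boxes: catalogued by the scanner, not targets
        solo = _make_solo_bbox(rng, params)
        _stamp(arm, pos, solo)
        pos += step
    five_s = "G" + random_dna(rng, 118, 0.45)
    _stamp(arm, pos, five_s)
    arm_targets.append(
        PolIIITarget(id="5S-1", ref_id="palindrome", plus_one_pos=pos + 1,
                     strand="+", target_class="five_s", family="5S")
    )

    arm_seq = "".join(arm)
    palindrome = arm_seq + revcomp(arm_seq)
    # mirror twins on the second arm (identical flanks by construction)
    twins = []
    for t in arm_targets:
        p2 = 2 * params.arm_len - t.plus_one_pos + 1
        twins.append(
            PolIIITarget(
                id=t.id + "m",
                ref_id="palindrome",
                plus_one_pos=p2,
                strand="-",
                target_class=t.target_class,
                a_box=_mirror_iv(t.a_box, params.arm_len),
                b_box=_mirror_iv(t.b_box, params.arm_len),
                a_box_class=t.a_box_class,
                family=t.family,
            )
        )
    targets += arm_targets + twins

    refs = [
        ReferenceSequence("chr1", "".join(chrom), "chromosome"),
        ReferenceSequence("palindrome", palindrome, "palindrome_arm"),
        ReferenceSequence("plasmid", element.plasmid_context, "plasmid"),
    ]
    catalog = group_duplicate_loci(targets, refs, cat_params)
    return refs, catalog


def _mirror_iv(iv: Interval | None, arm_len: int) -> Interval | None:
    if iv is None:
        return None
    return Interval(2 * arm_len - iv.end + 1, 2 * arm_len - iv.start + 1)


def _plant_locus(background: list[str], ref_id: str, locus: _Locus, anchor: int,
                 strand: str, target_id: str, rng: np.random.Generator,
                 params: SimParams, cat_params: CatalogParams) -> PolIIITarget:
    """Stamp one cassette at ``anchor`` (plus coord of the +1), redrawing the
    local flank until the planted A box is its B box's unique viable partner."""
    gene = locus.sequence
    G = len(gene)
    for _ in range(100):
        if strand == "+":
            start0 = anchor - 1
            _stamp(background, start0, gene)
            flank = "".join(background[start0 - 80 : start0])
            check = flank + gene
        else:
            start0 = anchor - G
            _stamp(background, start0, revcomp(gene))
            flank = revcomp("".join(background[start0 + G : start0 + G + 80]))
            check = flank + gene
        b_rel, a_rel = locus.b_rel, locus.a_rel
        if locus.a_rel is None or _window_is_clean(
            check, b_rel.start + 80, a_rel.start + 80, locus.a_class, cat_params
        ):
            break
        # redraw the flank that confused the partner search
        fresh = random_dna(rng, 80, params.gc_content)
        if strand == "+":
            _stamp(background, start0 - 80, fresh)
        else:
            _stamp(background, start0 + G, fresh)
    else:
        raise RuntimeError(f"could not plant clean locus {target_id}")

    if strand == "+":
        a_box = Interval(anchor + a_rel.start - 1, anchor + a_rel.end - 1) if a_rel else None
        b_box = Interval(anchor + b_rel.start - 1, anchor + b_rel.end - 1) if b_rel else None
    else:
        a_box = Interval(anchor - a_rel.end + 1, anchor - a_rel.start + 1) if a_rel else None
        b_box = Interval(anchor - b_rel.end + 1, anchor - b_rel.start + 1) if b_rel else None
    return PolIIITarget(
        id=target_id, ref_id=ref_id, plus_one_pos=anchor, strand=strand,
        target_class=locus.target_class, a_box=a_box, b_box=b_box,
        a_box_class=locus.a_class, family=locus.family,
    )


# ---------------------------------------------------------------------------
# planting integrations
# ---------------------------------------------------------------------------


@dataclass
class PlantedEvent:
    event_id: str
    target: PolIIITarget
    distance: int
    truncation: int
    extras: str
    tsd_len: int
    n_reads: int
    junction_pos: int       # plus coord of the junction-adjacent genomic base
    hap_window: str         # mutated reference window around the insertion
    hap_window_start: int   # plus coord of hap_window[0]


TRUTH_COLUMNS = [
    "event_id", "target_id", "duplicate_group", "ref_id",
    "distance_to_plus_one", "truncation", "extras", "tsd_len", "n_reads_emitted",
]


def truth_table(events: Sequence[PlantedEvent]) -> pd.DataFrame:
    rows = [
        (e.event_id, e.target.id, e.target.duplicate_group, e.target.ref_id,
         e.distance, e.truncation, e.extras, e.tsd_len, e.n_reads)
        for e in events
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def _prefix_scores_stay_negative(pairs: list[tuple[str, str]]) -> bool:
    """True iff every prefix of +1/-1 match scores is <= -1 (no extension)."""
    s = 0
    for a, b in pairs:
        s += 1 if a == b else -1
        if s >= 0:
            return False
    return True


def _junction_identifiable(S: str, p: int, strand: str, d: int, t: int, x: str,
                           element: ElementModel) -> bool:
    """Check that maximal-extension calling recovers (d, t, x) exactly.

    Rejected draws are ones where a truncated element base, an extra
    nucleotide, or a displaced reference base happens to match its neighbour,
    which would let the element match or the genomic alignment extend past
    the true junction.
    """
    full = element.full_sequence
    reach = t + len(x) + 4
    if strand == "+":
        c = p - d - 1  # junction base is S[c+1] (1-based)
        # element-strand neighbours walking 5'-ward from the element terminus:
        # extras (last to first), then complemented genomic bases from the
        # junction toward the gene (the fragment is the genome minus strand).
        genomic_walk = [revcomp(b) for b in S[c : c + reach]]
        # displaced reference bases the genomic alignment could extend onto,
        # compared (on the plus strand) against complemented extras.
        displaced_pairs = [
            (x[k], revcomp(S[c - 1 - k])) for k in range(len(x)) if c - 1 - k >= 0
        ]
    else:
        j = p + d  # junction base is S[j] (1-based)
        genomic_walk = list(S[max(0, j - reach) : j][::-1])
        displaced_pairs = [(x[k], S[j + k]) for k in range(len(x)) if j + k < len(S)]
    neighbours = list(x[::-1]) + genomic_walk
    # 1) element match must stop exactly at element position t+1
    if t >= 1:
        elem_walk = full[t - 1 :: -1]  # full[t], full[t-1], ... (1-based)
        if not _prefix_scores_stay_negative(list(zip(neighbours, elem_walk))):
            return False
    # 2) genomic alignment must stop at the junction (extras stay unaligned)
    if x:
        if len(displaced_pairs) < len(x):
            return False  # reference too short to verify; resample
        if not _prefix_scores_stay_negative(displaced_pairs):
            return False
    return True


def _junction_recovers_exactly(S: str, p: int, strand: str, d: int, t: int,
                               x: str, element: ElementModel) -> bool:
    """Align a canonical error-free fragment and require exact recovery.

    The gapless prefix check above misses offset homologies (gapped
    extensions onto chance A+T-rich similarity between genome and element
    UTR), so candidate events are additionally verified with the same local
    aligner the caller uses: the element match must start at element
    position t+1 and claim exactly the element part of the fragment, and
    the genomic alignment must end exactly at the junction with the extras
    left unaligned.
    """
    from .mapping import smith_waterman

    ne = element.nested_primer_site.end
    elem_part = element.full_sequence[t:ne]
    K = 60  # genomic context; junction-local behaviour is what matters
    if strand == "+":
        j = p - d  # 1-based junction base coordinate
        X = revcomp(S[j - 1 : j - 1 + K])
    else:
        j = p + d
        X = S[max(0, j - K) : j]
    frag = X + x + elem_part
    aln = smith_waterman(frag, element.full_sequence)
    if aln is None or aln.t_start != t + 1 or aln.q_start != len(X) + len(x) + 1:
        return False
    # genomic side: junction-first genomic part against a local ref window
    gp = revcomp(X + x)  # = rc(x) + oriented genomic bases
    lo = max(0, j - 1 - K - 20)
    hi = min(len(S), j + K + 20)
    aln2 = smith_waterman(gp, S[lo:hi])
    if aln2 is None or aln2.q_start != len(x) + 1 or aln2.q_end != len(gp):
        return False
    if strand == "+":
        return aln2.t_start + lo == j
    return aln2.t_end + lo == j


def plant_integrations(
    refs: Sequence[ReferenceSequence],
    catalog: Sequence[PolIIITarget],
    params: SimParams,
    seed: int | None = None,
    element: ElementModel | None = None,
    forced_distances: Sequence[int] | None = None,
) -> tuple[list[PlantedEvent], pd.DataFrame]:
    """Sample integration events and build per-event mutated haplotypes.

    Each event inserts the element (minus its sampled 5' truncation, plus
    sampled extra nucleotides at the 5' junction, flanked by a target-site
    duplication) upstream of a catalog target, with the element's 5' end
    facing the target's 5' end.  Events are clone-specific, so each gets its
    own haplotype window.  Event keys (target group, distance, truncation,
    extras) are unique, and junctions are re-sampled until exactly
    identifiable (see methods), so error-free recovery is well defined.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    element = element or default_element_model()
    rng = np.random.default_rng((params.seed if seed is None else seed) + 1)
    classes = params.target_classes
    if classes is None:
        classes = ("trna",) if params.library_type == "tdna" else ("trna", "five_s", "ab_box")
    pool = [t for t in catalog if t.target_class in classes]
    if params.library_type == "tdna":
        pool = [t for t in pool if t.target_class == "trna"]
    if not pool:
        raise ValueError("no eligible targets for this library type")
    refs_by_id = {r.id: r for r in refs}
    values, probs = distance_pmf(params)

    n_events = len(forced_distances) if forced_distances is not None else params.n_events
    events: list[PlantedEvent] = []
    seen_keys: set[tuple] = set()
    for i in range(n_events):
        for attempt in range(500):
            target = pool[int(rng.integers(len(pool)))]
            d = (int(forced_distances[i]) if forced_distances is not None
                 else int(rng.choice(values, p=probs)))
            t = 0
            if rng.random() < params.p_truncation:
                t = min(int(rng.geometric(params.truncation_geom_p)), params.max_truncation)
            x = ""
            if rng.random() < params.p_extra_nt:
                lo, hi = params.extra_len_range
                x = random_dna(rng, int(rng.integers(lo, hi + 1)), 0.5)
            tsd = int(rng.integers(params.tsd_len_range[0], params.tsd_len_range[1] + 1))
            tsd = min(tsd, d)
            key = (target.duplicate_group or target.id, d, t, x)
            if params.unique_event_keys and key in seen_keys:
                continue
            S = refs_by_id[target.ref_id].sequence
            if not _junction_identifiable(S, target.plus_one_pos, target.strand,
                                          d, t, x, element):
                continue
            # a complete 5' end with no extras is always exactly recoverable
            # (the exact-match alignment cannot be extended or beaten), so
            # the aligner self-check is only needed for truncated/decorated
            # junctions
            if (t > 0 or x) and not _junction_recovers_exactly(
                S, target.plus_one_pos, target.strand, d, t, x, element
            ):
                continue
            seen_keys.add(key)
            break
        else:
            raise RuntimeError("could not sample an identifiable unique event")
        lo, hi = params.n_reads_per_event
        n_reads = int(rng.integers(lo, hi + 1))
        events.append(_build_haplotype(
            f"ev{i + 1:04d}", target, S, d, t, x, tsd, n_reads, element))
    return events, truth_table(events)


def _build_haplotype(event_id: str, target: PolIIITarget, S: str, d: int,
                     t: int, x: str, tsd: int, n_reads: int,
                     element: ElementModel) -> PlantedEvent:
    p = target.plus_one_pos
    elem_ins = element.full_sequence[t:]
    if target.strand == "+":
        c = p - d - 1  # 1-based coord of the last base left of the insertion
        dup = S[c : c + tsd] if tsd else ""  # target-proximal spacer bases
        block = dup + revcomp(x + elem_ins)
        ws = max(0, c - len(block) - 60)
        we = min(len(S), p + 80)
        window = S[ws:c] + block + S[c:we]
        junction = c + 1
    else:
        j = p + d  # junction base coordinate
        dup = S[j - tsd : j] if tsd else ""  # target-proximal spacer bases
        block = (x + elem_ins) + dup
        ws = max(0, p - 81)
        we = min(len(S), j + len(block) + 60)
        window = S[ws:j] + block + S[j:we]
        junction = j
    return PlantedEvent(event_id, target, d, t, x, tsd, n_reads,
                        junction, window, ws + 1)


# ---------------------------------------------------------------------------
# amplicon simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


def tdna_primer_for(target: PolIIITarget, refs_by_id: dict[str, ReferenceSequence],
                    offset: int = TDNA_PRIMER_OFFSET, length: int = TDNA_PRIMER_LEN) -> str:
    """Family primer sequence: gene-strand bases +offset..+offset+length-1."""
    S = refs_by_id[target.ref_id].sequence
    p = target.plus_one_pos
    if target.strand == "+":
        return S[p + offset - 2 : p + offset - 2 + length]
    return revcomp(S[p - offset - length + 1 : p - offset + 1])


def _junction_fragment(event: PlantedEvent, S: str, element: ElementModel,
                       library: str, rng: np.random.Generator,
                       params: SimParams) -> str:
    """One amplicon fragment, written 5'->3' on the element strand:
    [adapter? / tDNA-primer-side genomic] ... junction ... extras ... element."""
    p = event.target.plus_one_pos
    ne = element.nested_primer_site.end
    elem_part = element.full_sequence[event.truncation : ne]
    j = event.junction_pos
    if library == "tdna":
        K = TDNA_PRIMER_OFFSET + TDNA_PRIMER_LEN - 1  # last gene position covered
        if event.target.strand == "+":
            X = revcomp(S[j - 1 : p + K - 1])
        else:
            X = S[p - K : j]
        return X + event.extras + elem_part
    # adapter library: genomic extent to a random hexamer-primed endpoint
    frag_target = int(rng.integers(params.frag_len_range[0], params.frag_len_range[1] + 1))
    La = frag_target - len(elem_part) - len(event.extras) - len(ADAPTER_SEQ)
    La = int(np.clip(La, 46, 220))
    if event.target.strand == "+":
        X = revcomp(S[j - 1 : j - 1 + La])
    else:
        X = S[max(0, j - La) : j]
    h6 = random_dna(rng, 6, 0.5)  # primer-derived random hexamer
    return ADAPTER_SEQ + h6 + X[6:] + event.extras + elem_part


def _background_fragment(kind: str, refs_by_id: dict[str, ReferenceSequence],
                         element: ElementModel, library: str,
                         rng: np.random.Generator, params: SimParams) -> str:
    ne = element.nested_primer_site.end
    if kind == "plasmid":
        ctx = element.plasmid_context
        Lp = int(rng.integers(46, len(ctx) + 1))
        X = ctx[-Lp:]
        if library == "adapter":
            h6 = random_dna(rng, 6, 0.5)
            return ADAPTER_SEQ + h6 + X[6:] + element.full_sequence[:ne]
        return X + element.full_sequence[:ne]
    chrom = refs_by_id["chr1"].sequence
    L = int(rng.integers(params.frag_len_range[0], params.frag_len_range[1] + 1))
    s = int(rng.integers(0, len(chrom) - L))
    return chrom[s : s + L]


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.array(list("ACGT"))
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def _pair_from_fragment(read_id: str, frag: str, params: SimParams,
                        rng: np.random.Generator) -> ReadPair:
    r1 = _add_errors(frag[: params.read_len], params.error_rate, rng)
    r2 = _add_errors(revcomp(frag)[: params.read_len], params.error_rate, rng)
    return ReadPair(read_id, r1, _QUAL * len(r1), r2, _QUAL * len(r2))


def simulate_amplicons(
    events: Sequence[PlantedEvent],
    refs: Sequence[ReferenceSequence],
    params: SimParams,
    seed: int | None = None,
    element: ElementModel | None = None,
) -> tuple[list[ReadPair], dict[str, str]]:
    """LAM-PCR-shaped read pairs for planted events plus background pairs.

    Returns the pairs and a read-id -> source map (event id, "bg_plasmid",
    or "bg_genomic").  Deterministic given the seed.
    """
    if not events:
        raise ValueError("no events to simulate")
    element = element or default_element_model()
    rng = np.random.default_rng((params.seed if seed is None else seed) + 2)
    refs_by_id = {r.id: r for r in refs}
    pairs: list[ReadPair] = []
    source: dict[str, str] = {}
    serial = 0
    for ev in events:
        S = refs_by_id[ev.target.ref_id].sequence
        for _ in range(ev.n_reads):
            frag = _junction_fragment(ev, S, element, params.library_type, rng, params)
            serial += 1
            rid = f"{params.library_type}:{serial:06d}"
            pairs.append(_pair_from_fragment(rid, frag, params, rng))
            source[rid] = ev.event_id
    n_junction = len(pairs)
    bf = params.background_fraction
    n_back = int(round(n_junction * bf / (1 - bf))) if bf < 1 else 0
    for _ in range(n_back):
        kind = "plasmid" if rng.random() < params.background_plasmid_fraction else "genomic"
        frag = _background_fragment(kind, refs_by_id, element, params.library_type,
                                    rng, params)
        serial += 1
        rid = f"{params.library_type}:{serial:06d}"
        pairs.append(_pair_from_fragment(rid, frag, params, rng))
        source[rid] = f"bg_{kind}"
    return pairs, source


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_fastq_pairs(pairs: Sequence[ReadPair], r1_path, r2_path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def write_truth(truth: pd.DataFrame, path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"#lamprof truth table; seed={seed}\n")
        truth.to_csv(fh, sep="\t", index=False)


def load_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       dtype={"extras": str}, keep_default_na=False,
                       na_values=[]).astype({"distance_to_plus_one": int})
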