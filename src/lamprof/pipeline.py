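"""End-to-end orchestration: pairs -> pseudoreads -> fragments -> events.

Also provides the plain-text interchange formats used by the CLI between
stages (fragments as FASTA with structured headers, placements as TSV), so
each stage can be run separately on files or all at once in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .calling import CallParams, assign_target, deduplicate_events, infer_junction
from .catalog import PolIIITarget, ReferenceSequence
from .mapping import (
    AlignmentHit,
    MapParams,
    Placement,
    ReferenceIndex,
    accept_hits,
    align_fragment,
    classify_placement,
)
from .readprep import (
    JunctionFragment,
    PrepParams,
    length_filter,
    locate_and_trim_element,
    merge_pair,
    require_primer,
    trim_target_end,
)
from .simulate import (
    ADAPTER_SEQ,
    ElementModel,
    ReadPair,
    default_element_model,
    tdna_primer_for,
)
from .stats import (
    DistanceSummary,
    HotspotSummary,
    OccupancySummary,
    StageAccounting,
    WindowSpec,
    distance_distribution,
    hotspot_summary,
    occupancy_matrix,
)

PER_READ_COLUMNS = [
    "read_id", "key", "target_id", "duplicate_group", "ref_id",
    "distance_to_plus_one", "truncation", "extras", "library_type",
]


@dataclass
class PipelineResult:
    accounting: StageAccounting
    per_read: pd.DataFrame
    events: pd.DataFrame
    fragments: list[JunctionFragment]
    placements: list[tuple[JunctionFragment, Placement]]
    locus_read_counts: dict[str, int]

    def summaries(
        self, catalog: Sequence[PolIIITarget], window: WindowSpec | None = None,
        prior_set: Sequence[str] | None = None,
    ) -> tuple[DistanceSummary, OccupancySummary, HotspotSummary]:
        dist = distance_distribution(self.events, window)
        occ = occupancy_matrix(catalog, self.events, prior_set)
        hot = hotspot_summary(self.locus_read_counts, len(catalog))
        return dist, occ, hot


def tdna_primers(catalog: Sequence[PolIIITarget],
                 refs: Sequence[ReferenceSequence]) -> list[str]:
    """One family primer per tRNA family (copies share the gene sequence)."""
    refs_by_id = {r.id: r for r in refs}
    primers: dict[str, str] = {}
    for t in catalog:
        if t.target_class == "trna" and t.family not in primers:
            primers[t.family] = tdna_primer_for(t, refs_by_id)
    return list(primers.values())


def run_pipeline(
    pairs: Sequence[ReadPair],
    refs: Sequence[ReferenceSequence],
    catalog: Sequence[PolIIITarget],
    library_type: str = "tdna",
    element: ElementModel | None = None,
    prep_params: PrepParams | None = None,
    map_params: MapParams | None = None,
    call_params: CallParams | None = None,
    adapter: str = ADAPTER_SEQ,
) -> PipelineResult:
    """Run merge -> primer check -> element trim -> map -> call on read pairs.

    Every assembled pseudoread ends in exactly one terminal accounting
    category, so counts are conserved through the stages.
    """
    element = element or default_element_model()
    prep_params = prep_params or PrepParams()
    map_params = map_params or MapParams()
    call_params = call_params or CallParams()
    refs_by_id = {r.id: r for r in refs}
    index = ReferenceIndex(refs, map_params.seed_k)
    primers = tdna_primers(catalog, refs) if library_type == "tdna" else []
    acc = StageAccounting()
    fragments: list[JunctionFragment] = []
    kept: list[tuple[JunctionFragment, Placement]] = []
    rows = []

    def group_of(hit: AlignmentHit) -> str | None:
        junction = hit.start if hit.strand == "+" else hit.end
        assigned = assign_target(junction, hit.strand, hit.ref_id, catalog, call_params)
        return assigned[0].duplicate_group if assigned else None

    for pair in pairs:
        acc.read_pairs += 1
        merged = merge_pair((pair.seq1, pair.qual1), (pair.seq2, pair.qual2),
                            prep_params, read_id=pair.read_id,
                            library_type=library_type)
        if merged.status != "merged":
            continue
        acc.assembled_pseudoreads += 1
        pr = merged.pseudoread
        if library_type == "adapter" and not require_primer(
            pr, element.nested_primer_seq, prep_params
        ):
            acc.bump("no_nested_primer")
            continue
        trimmed = locate_and_trim_element(pr, element, prep_params)
        if trimmed.status != "trimmed":
            acc.bump("no_element")
            continue
        acc.element_mapped += 1
        frag = trim_target_end(
            trimmed.fragment, library_type,
            primers if library_type == "tdna" else adapter, prep_params,
        )
        if frag.primer_found:
            acc.target_end_trimmed += 1
        if not length_filter(frag, prep_params):
            acc.bump("too_short")
            continue
        acc.length_ge_min += 1
        fragments.append(frag)
        hits = align_fragment(frag.genomic_part, index, map_params)
        placement = accept_hits(hits, map_params, group_of)
        classify_placement(placement, refs_by_id)
        if not placement.accepted:
            acc.bump("unplaced")
            continue
        acc.mapped_to_reference += 1
        if placement.category == "plasmid_actin6":
            acc.bump("plasmid_actin6")
            continue
        kept.append((frag, placement))
        jc = infer_junction(placement, frag)
        if jc.status != "ok":
            acc.bump("remaining")
            continue
        assigned = assign_target(jc.junction, jc.facing, placement.hit.ref_id,
                                 catalog, call_params)
        if assigned is None:
            acc.bump("remaining")
            continue
        target, distance = assigned
        if placement.group is not None and target.duplicate_group != placement.group:
            acc.bump("remaining")
            continue
        kind = refs_by_id[target.ref_id].kind
        acc.bump("assigned_palindrome" if kind == "palindrome_arm" else "assigned_chromosome")
        rows.append((pair.read_id, target.duplicate_group or target.id, target.id,
                     target.duplicate_group, target.ref_id, distance,
                     frag.truncation, jc.extras, library_type))

    per_read = pd.DataFrame(rows, columns=PER_READ_COLUMNS)
    events = deduplicate_events(per_read.drop(columns=["read_id"]))
    counts = per_read["key"].value_counts().to_dict() if not per_read.empty else {}
    return PipelineResult(acc, per_read, events, fragments, kept, counts)


# ---------------------------------------------------------------------------
# interchange formats for the staged CLI
# ---------------------------------------------------------------------------


def write_fragments_fasta(fragments: Sequence[JunctionFragment], path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(
                f">{f.read_id} trunc={f.truncation} lib={f.library_type} "
                f"elem={len(f.element_part)} primer={len(f.primer_part)} "
                f"prlen={f.pseudoread_len}\n{f.genomic_part}\n"
            )


def read_fragments_fasta(path) -> list[JunctionFragment]:
    from .catalog import Interval

    out: list[JunctionFragment] = []
    with open(path) as fh:
        header = None
        seq_lines: list[str] = []
        for line in list(fh) + [">"]:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    seq = "".join(seq_lines)
                    name, *kvs = header.split()
                    kv = dict(s.split("=", 1) for s in kvs)
                    trunc = int(kv["trunc"])
                    elem_len = int(kv["elem"])
                    out.append(JunctionFragment(
                        read_id=name,
                        pseudoread_len=int(kv["prlen"]),
                        genomic_part=seq,
                        element_part="N" * elem_len,
                        element_interval_on_read=Interval(1, elem_len),
                        element_5p_coord_on_element=trunc + 1,
                        primer_part="N" * int(kv["primer"]),
                        primer_found=int(kv["primer"]) > 0,
                        library_type=kv["lib"],
                    ))
                header = line[1:]
                seq_lines = []
            else:
                seq_lines.append(line)
    return out


PLACEMENT_COLUMNS = ["read_id", "ref_id", "start", "end", "strand", "score",
                     "coverage", "q_start", "q_end", "category", "group"]


def placements_frame(items: Sequence[tuple[JunctionFragment, Placement]]) -> pd.DataFrame:
    rows = []
    for frag, p in items:
        h = p.hit
        rows.append((frag.read_id, h.ref_id, h.start, h.end, h.strand, h.score,
                     round(h.query_coverage, 4), h.q_start, h.q_end,
                     p.category, p.group or "."))
    return pd.DataFrame(rows, columns=PLACEMENT_COLUMNS)
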