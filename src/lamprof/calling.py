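"""Integration calling: junctions, target assignment, deduplication.

An accepted genomic placement implies a junction: the genomic base adjacent
to the element's 5' terminus.  The element integrates orientation-
specifically, its 5' end facing the 5' end of the targeted gene, so the
junction "faces" along the strand of the placement and is assigned to the
nearest catalog target on that strand, at a distance counted as the bases
strictly between the element's 5'-terminal nucleotide and the target's +1.
Non-templated extra nucleotides are element-side: they are the unaligned
junction-proximal bases of the genomic part and are excluded from the
distance.

Events are keyed by (target group, distance, truncation, extras): two
insertions at exactly the same position can still be told apart by a 5'
truncation or by extra nucleotides.  Single-read events are retained but
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._dna import revcomp
from .catalog import PolIIITarget
from .mapping import Placement
from .readprep import JunctionFragment

#: unaligned junction prefixes longer than this are treated as evidence of a
#: chimeric/artifact read rather than extra nucleotides
MAX_EXTRAS_LEN = 8


@dataclass
class CallParams:
    max_assign_distance: int = 250
    require_orientation: bool = True

    def __post_init__(self) -> None:
        if self.max_assign_distance < 1:
            raise ValueError("max_assign_distance must be >= 1")


@dataclass
class JunctionCall:
    status: str  # ok | discarded
    junction: int = 0       # plus-strand coord of the junction-adjacent base
    facing: str = "+"       # direction from the junction toward the target
    extras: str = ""
    reason: str = ""


def infer_junction(placement: Placement, frag: JunctionFragment) -> JunctionCall:
    """Junction coordinate, element orientation and resolved extras.

    The genomic part is stored junction-first, so the placement's
    junction-side alignment end gives the coordinate, and any unaligned
    prefix is the (reverse-complemented) extra-nucleotide string.
    """
    if not placement.accepted or placement.category != "target_genome":
        return JunctionCall("discarded", reason="not_genomic")
    hit = placement.hit
    prefix = frag.genomic_part[: hit.q_start - 1]
    if len(prefix) > MAX_EXTRAS_LEN:
        return JunctionCall("discarded", reason="junction_unaligned")
    extras = revcomp(prefix)  # back to the element strand
    if hit.strand == "+":
        return JunctionCall("ok", junction=hit.start, facing="+", extras=extras)
    return JunctionCall("ok", junction=hit.end, facing="-", extras=extras)


def assign_target(
    junction: int,
    facing: str,
    ref_id: str,
    catalog: Sequence[PolIIITarget],
    params: CallParams | None = None,
) -> tuple[PolIIITarget, int] | None:
    """Nearest catalog target downstream of the junction on the facing strand.

    distance = bases strictly between the element 5' terminus (excluding
    extras) and the target's +1.  Returns None when no target lies within
    ``max_assign_distance`` (or the orientation is wrong and orientation is
    required).
    """
    params = params or CallParams()
    best: tuple[int, PolIIITarget] | None = None
    for t in catalog:
        if t.ref_id != ref_id:
            continue
        if t.strand == facing:
            d = t.plus_one_pos - junction if facing == "+" else junction - t.plus_one_pos
        elif params.require_orientation:
            continue
        else:  # wrong-orientation target, unsigned distance
            d = abs(t.plus_one_pos - junction)
        if d < 1 or d > params.max_assign_distance:
            continue
        if best is None or (d, t.id) < (best[0], best[1].id):
            best = (d, t)
    if best is None:
        return None
    return best[1], best[0]


EVENT_COLUMNS = [
    "key", "target_id", "duplicate_group", "ref_id", "distance_to_plus_one",
    "truncation", "extras", "read_support", "library_type", "flagged_single_read",
]


def call_events(
    items: Sequence[tuple[JunctionFragment, Placement]],
    catalog: Sequence[PolIIITarget],
    params: CallParams | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-read junction calls for genomic placements, deduplicated to events.

    Group placements (score ties confined to one duplicate group) are
    assigned through their first hit and keyed by the group; members must
    agree or the read is discarded.  Returns the event table and per-reason
    discard counts (assigned reads are counted under "assigned").
    """
    params = params or CallParams()
    drops: dict[str, int] = {}
    rows = []
    for frag, placement in items:
        jc = infer_junction(placement, frag)
        if jc.status != "ok":
            drops[jc.reason] = drops.get(jc.reason, 0) + 1
            continue
        hit = placement.hit
        assigned = assign_target(jc.junction, jc.facing, hit.ref_id, catalog, params)
        if assigned is None:
            drops["unassigned"] = drops.get("unassigned", 0) + 1
            continue
        target, distance = assigned
        if placement.group is not None and target.duplicate_group != placement.group:
            drops["group_inconsistent"] = drops.get("group_inconsistent", 0) + 1
            continue
        key = target.duplicate_group or target.id
        rows.append((key, target.id, target.duplicate_group, target.ref_id,
                     distance, frag.truncation, jc.extras, frag.library_type))
        drops["assigned"] = drops.get("assigned", 0) + 1
    per_read = pd.DataFrame(
        rows,
        columns=["key", "target_id", "duplicate_group", "ref_id",
                 "distance_to_plus_one", "truncation", "extras", "library_type"],
    )
    events = deduplicate_events(per_read)
    return events, drops


def deduplicate_events(per_read: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-read calls into events keyed by
    (target group, distance, truncation, extras)."""
    if per_read.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    grouped = (
        per_read.groupby(
            ["key", "target_id", "duplicate_group", "ref_id",
             "distance_to_plus_one", "truncation", "extras", "library_type"],
            dropna=False, sort=True,
        )
        .size()
        .reset_index(name="read_support")
    )
    grouped["flagged_single_read"] = grouped["read_support"] == 1
    return grouped[EVENT_COLUMNS]


def write_events_bed(events: pd.DataFrame, catalog: Sequence[PolIIITarget], path) -> None:
    """Events as BED6+ (one record per event, anchored at the target's +1)."""
    by_id = {t.id: t for t in catalog}
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\t"
                 "target\tdistance\ttruncation\textras\tsupport\n")
        for _, e in events.iterrows():
            t = by_id[e.target_id]
            fh.write("\t".join([
                t.ref_id, str(t.plus_one_pos - 1), str(t.plus_one_pos),
                f"{e.key}@{e.distance_to_plus_one}", "0", t.strand,
                e.target_id, str(e.distance_to_plus_one), str(e.truncation),
                e.extras or ".", str(e.read_support),
            ]) + "\n")
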