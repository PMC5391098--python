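"""Profiling summaries: distances, occupancy, hot spots, stage accounting."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .catalog import PolIIITarget


@dataclass
class WindowSpec:
    """The canonical integration window: 47 +/- 3 bp upstream of the +1."""

    center: int = 47
    halfwidth: int = 3


@dataclass
class DistanceSummary:
    histogram: pd.DataFrame          # columns: distance, n_events
    fraction_in_window: float | None  # None when there are no events
    window: WindowSpec


def distance_distribution(
    events: pd.DataFrame, window: WindowSpec | None = None
) -> DistanceSummary:
    """Per-distance event counts and the fraction inside the window."""
    window = window or WindowSpec()
    if events.empty:
        hist = pd.DataFrame(columns=["distance", "n_events"])
        return DistanceSummary(hist, None, window)
    d = events["distance_to_plus_one"]
    hist = d.value_counts().sort_index().rename_axis("distance").reset_index(name="n_events")
    inside = (d - window.center).abs() <= window.halfwidth
    return DistanceSummary(hist, float(inside.mean()), window)


@dataclass
class OccupancySummary:
    table: pd.DataFrame  # target_id, status
    n_targeted: int
    n_overlap_prior: int


def occupancy_matrix(
    catalog: Sequence[PolIIITarget],
    events: pd.DataFrame,
    prior_set: Sequence[str] | None = None,
) -> OccupancySummary:
    """Per-target status: untargeted, targeted, or targeted_and_prior.

    ``prior_set`` plays the role of targets already occupied in the
    reference population (e.g. by natural element copies); the overlap is
    the number of prior targets re-hit de novo.
    """
    prior = set(prior_set or [])
    hit = set(events["target_id"]) if not events.empty else set()
    # events keyed on a duplicate group hit every member of the group
    groups_hit = set(events["duplicate_group"].dropna()) if not events.empty else set()
    rows = []
    for t in catalog:
        targeted = t.id in hit or (t.duplicate_group in groups_hit)
        if targeted and t.id in prior:
            status = "targeted_and_prior"
        elif targeted:
            status = "targeted"
        else:
            status = "untargeted"
        rows.append((t.id, status))
    table = pd.DataFrame(rows, columns=["target_id", "status"])
    n_targeted = int((table["status"] != "untargeted").sum())
    n_overlap = int((table["status"] == "targeted_and_prior").sum())
    return OccupancySummary(table, n_targeted, n_overlap)


def occupancy_union(tables: Sequence[pd.DataFrame]) -> set[str]:
    """Targets hit in at least one run/library."""
    out: set[str] = set()
    for t in tables:
        out |= set(t.loc[t["status"] != "untargeted", "target_id"])
    return out


@dataclass
class HotspotSummary:
    expected_average: float       # total reads / catalog size (exact)
    expected_average_display: int  # rounded for reporting
    n_above_average: int
    read_share_of_above: float    # percent of reads on above-average loci


def hotspot_summary(
    locus_read_counts: Mapping[str, int], n_catalog_targets: int
) -> HotspotSummary:
    """How biased are per-locus read counts relative to a uniform spread?

    The expected average assumes the mapped reads distribute evenly over
    every catalog target; loci strictly above that average are counted and
    their share of all mapped reads reported (in percent).
    """
    total = sum(locus_read_counts.values())
    if n_catalog_targets <= 0:
        raise ValueError("n_catalog_targets must be positive")
    avg = total / n_catalog_targets
    above = {k: v for k, v in locus_read_counts.items() if v > avg}
    share = 100.0 * sum(above.values()) / total if total else 0.0
    return HotspotSummary(avg, int(round(avg)), len(above), share)


# ---------------------------------------------------------------------------
# stage accounting (mapping-summary table analog)
# ---------------------------------------------------------------------------

#: terminal categories; every assembled pseudoread lands in exactly one
TERMINAL_CATEGORIES = (
    "no_element",
    "no_nested_primer",
    "too_short",
    "unplaced",
    "plasmid_actin6",
    "assigned_chromosome",
    "assigned_palindrome",
    "remaining",
)


@dataclass
class StageAccounting:
    read_pairs: int = 0
    assembled_pseudoreads: int = 0
    element_mapped: int = 0
    target_end_trimmed: int = 0
    length_ge_min: int = 0
    mapped_to_reference: int = 0
    terminal: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in TERMINAL_CATEGORIES:
            self.terminal.setdefault(c, 0)

    def bump(self, category: str) -> None:
        if category not in self.terminal:
            raise KeyError(f"unknown terminal category {category!r}")
        self.terminal[category] += 1

    def conservation_ok(self) -> bool:
        return sum(self.terminal.values()) == self.assembled_pseudoreads

    def as_table(self) -> pd.DataFrame:
        """Ordered stage rows in the style of a mapping-summary table."""
        t = self.terminal
        rows = [
            ("read_pairs", self.read_pairs),
            ("assembled_pseudoreads", self.assembled_pseudoreads),
            ("mapped_to_element", self.element_mapped),
            ("target_end_trimmed", self.target_end_trimmed),
            (f"pseudoreads_ge_min_len", self.length_ge_min),
            ("mapped_to_reference", self.mapped_to_reference),
            ("assigned_to_targets", t["assigned_chromosome"]),
            ("mapped_to_actin6", t["plasmid_actin6"]),
            ("mapped_to_palindrome", t["assigned_palindrome"]),
            ("remaining", t["remaining"]),
        ]
        return pd.DataFrame(rows, columns=["stage", "count"])


def run_summary(
    accounting: StageAccounting,
    distances: DistanceSummary,
    occupancy: OccupancySummary,
    hotspots: HotspotSummary,
) -> dict[str, float | int | None]:
    """Flat machine-readable summary of one pipeline run."""
    out: dict[str, float | int | None] = {}
    for _, row in accounting.as_table().iterrows():
        out[f"stage.{row['stage']}"] = int(row["count"])
    out["distance.fraction_in_window"] = distances.fraction_in_window
    out["distance.window_center"] = distances.window.center
    out["distance.window_halfwidth"] = distances.window.halfwidth
    out["occupancy.n_targeted"] = occupancy.n_targeted
    out["occupancy.n_overlap_prior"] = occupancy.n_overlap_prior
    out["hotspot.expected_average"] = hotspots.expected_average
    out["hotspot.n_above_average"] = hotspots.n_above_average
    out["hotspot.read_share_pct"] = hotspots.read_share_of_above
    return out
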