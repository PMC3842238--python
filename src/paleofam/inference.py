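"""Ancestral homologue-count inference on a ranked taxonomy.

The walk proceeds bottom-up, rank by rank (species -> genus -> ... ->
phylum).  A parent taxon is credited with the gene family only under a
*strict majority* rule: more than half of its surveyed children must
themselves carry the family.  When the majority passes, the ancestral copy
number is the integer L1 median of the carrying children's counts (the
integer minimising the summed absolute difference to those counts, ties
broken toward the smaller integer) — the assignment that minimises the
total gain+loss magnitude implied on the child branches, i.e. the maximally
parsimonious count.

From the assignment map the module derives:

* the family **origin**: the highest-ranked taxon credited with the family
  that has no credited ancestor;
* **horizontal-transfer candidates**: every other maximal credited taxon —
  presences that cannot be connected to the origin clade by vertical
  descent under the majority rule;
* **gains and losses**: credited parent/child pairs whose counts differ.

Unsurveyed children (no completely sequenced genome in the subtree) are
ignored entirely: absence of evidence in an unsequenced clade is not
evidence of absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .taxonomy import RANKS, ROOT_RANK, SpeciesRecord, TaxonNode

__all__ = [
    "Assignment",
    "AssignmentMap",
    "CountEvent",
    "EventReport",
    "l1_median",
    "assign_ancestral_counts",
    "find_origin",
    "detect_hgt",
    "detect_gains_losses",
    "build_event_report",
    "phenotype_crosstab",
]


@dataclass(frozen=True)
class Assignment:
    """Per-node outcome of the majority walk.

    ``inferred_count`` is ``None`` exactly when the strict majority failed
    (``majority_passed`` False).  At species rank the inferred count is the
    observed count and the majority flag simply records presence.
    """

    inferred_count: Optional[int]
    majority_passed: bool
    supporting_children: int
    surveyed_children: int


AssignmentMap = dict[TaxonNode, Assignment]


def l1_median(values: Sequence[int]) -> int:
    """Integer minimising sum(|x - v|), ties broken toward the smaller x.

    For sorted values the minimisers form the interval between the lower
    and upper median; the tie-break picks the lower median.
    """
    if not values:
        raise ValueError("l1_median of an empty sequence")
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def assign_ancestral_counts(root: TaxonNode) -> AssignmentMap:
    """Run the strict-majority walk and return the per-node assignments.

    Raises if any species tip lacks an observed count (tree built without
    counts attached).
    """
    amap: AssignmentMap = {}

    def visit(node: TaxonNode) -> None:
        if node.is_species():
            if node.observed_count is None:
                raise ValueError(
                    f"species {node.name!r} has no observed homologue count"
                )
            amap[node] = Assignment(
                inferred_count=node.observed_count,
                majority_passed=node.observed_count > 0,
                supporting_children=0,
                surveyed_children=0,
            )
            return
        for child in node.children:
            visit(child)
        surveyed = [c for c in node.children if c.surveyed]
        supporting = [
            c
            for c in surveyed
            if amap[c].majority_passed and (amap[c].inferred_count or 0) > 0
        ]
        # the synthetic root is outside the genus-to-phylum walk
        passed = (
            node.rank != ROOT_RANK and 2 * len(supporting) > len(surveyed)
        )
        count = (
            l1_median([amap[c].inferred_count for c in supporting])
            if passed
            else None
        )
        amap[node] = Assignment(
            inferred_count=count,
            majority_passed=passed,
            supporting_children=len(supporting),
            surveyed_children=len(surveyed),
        )

    visit(root)
    return amap


def _is_credited(node: TaxonNode, amap: AssignmentMap) -> bool:
    return amap[node].majority_passed


def maximal_credited(root: TaxonNode, amap: AssignmentMap) -> list[TaxonNode]:
    """Credited nodes with no credited ancestor, in tree order."""
    out: list[TaxonNode] = []

    def visit(node: TaxonNode, ancestor_credited: bool) -> None:
        credited = _is_credited(node, amap)
        if credited and not ancestor_credited:
            out.append(node)
        for child in node.children:
            visit(child, ancestor_credited or credited)

    visit(root, False)
    return out


def _bearing_surveyed_species(node: TaxonNode) -> int:
    return sum(
        1
        for s in node.species()
        if s.surveyed and (s.observed_count or 0) > 0
    )


def find_origin(root: TaxonNode, amap: AssignmentMap) -> Optional[TaxonNode]:
    """The highest-ranked maximal credited taxon, or None if family absent.

    Ties on rank are broken toward the clade with more homologue-bearing
    surveyed species, then lexicographically by name.
    """
    candidates = maximal_credited(root, amap)
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda n: (n.rank_index(), -_bearing_surveyed_species(n), n.name),
    )


def detect_hgt(
    root: TaxonNode, amap: AssignmentMap, origin: Optional[TaxonNode]
) -> list[TaxonNode]:
    """Maximal credited taxa other than the origin: unexpected presences.

    Because a homologue-bearing species is itself credited, any bearer
    outside every credited internal clade surfaces here as a species-rank
    entry; the reported node is always the deepest-rooted credited taxon
    covering the presence.
    """
    return [n for n in maximal_credited(root, amap) if n is not origin]


@dataclass(frozen=True)
class CountEvent:
    taxon: str
    rank: str
    child_count: int
    parent_count: int

    @property
    def magnitude(self) -> int:
        return abs(self.child_count - self.parent_count)


@dataclass
class EventReport:
    """Inferred history of the family on the taxonomy."""

    origin: Optional[str]
    origin_rank: Optional[str]
    hgt_candidates: list[str] = field(default_factory=list)
    gains: list[CountEvent] = field(default_factory=list)
    losses: list[CountEvent] = field(default_factory=list)
    complete_losses: list[CountEvent] = field(default_factory=list)

    @property
    def family_absent(self) -> bool:
        return self.origin is None

    def to_dict(self) -> dict:
        def events(items: list[CountEvent]) -> list[dict]:
            return [
                {
                    "taxon": e.taxon,
                    "rank": e.rank,
                    "child_count": e.child_count,
                    "parent_count": e.parent_count,
                }
                for e in items
            ]

        return {
            "origin": self.origin,
            "origin_rank": self.origin_rank,
            "family_absent": self.family_absent,
            "hgt_candidates": self.hgt_candidates,
            "gains": events(self.gains),
            "losses": events(self.losses),
            "complete_losses": events(self.complete_losses),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        if self.origin is not None:
            rows.append(
                {"event": "origin", "taxon": self.origin, "rank": self.origin_rank,
                 "child_count": "", "parent_count": ""}
            )
        for name in self.hgt_candidates:
            rows.append({"event": "hgt_candidate", "taxon": name, "rank": "",
                         "child_count": "", "parent_count": ""})
        for kind, items in (
            ("gain", self.gains),
            ("loss", self.losses),
            ("complete_loss", self.complete_losses),
        ):
            for e in items:
                rows.append(
                    {"event": kind, "taxon": e.taxon, "rank": e.rank,
                     "child_count": e.child_count, "parent_count": e.parent_count}
                )
        return pd.DataFrame(
            rows, columns=["event", "taxon", "rank", "child_count", "parent_count"]
        )


def detect_gains_losses(root: TaxonNode, amap: AssignmentMap) -> EventReport:
    """Compare every credited parent/child pair of counts.

    child > parent -> gain; 0 < child < parent -> loss (paralogue
    reduction); child == 0 under a credited parent -> complete loss,
    reported separately because the family has vanished from the lineage
    rather than contracted.
    """
    report = EventReport(origin=None, origin_rank=None)

    def visit(node: TaxonNode) -> None:
        parent_assigned = _is_credited(node, amap)
        for child in node.children:
            if parent_assigned and child.surveyed:
                pcount = amap[node].inferred_count
                ccount = amap[child].inferred_count
                if ccount is not None and pcount is not None:
                    event = CountEvent(child.name, child.rank, ccount, pcount)
                    if ccount > pcount:
                        report.gains.append(event)
                    elif 0 < ccount < pcount:
                        report.losses.append(event)
                    elif ccount == 0:
                        report.complete_losses.append(event)
                elif ccount is None and child.is_species():  # pragma: no cover
                    pass
            visit(child)

    visit(root)
    return report


def build_event_report(root: TaxonNode) -> tuple[EventReport, AssignmentMap]:
    """Full pipeline: assignments, origin, HGT candidates, gains/losses."""
    amap = assign_ancestral_counts(root)
    origin = find_origin(root, amap)
    report = detect_gains_losses(root, amap)
    report.origin = origin.name if origin is not None else None
    report.origin_rank = origin.rank if origin is not None else None
    report.hgt_candidates = [n.name for n in detect_hgt(root, amap, origin)]
    return report, amap


# ---------------------------------------------------------------------------
# Phenotype co-distribution
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeCrosstab:
    """Presence vs growth-phenotype cross-tabulation.

    ``bearers_not_hyperthermophilic`` lists homologue-bearing species whose
    hyperthermophily flag is explicitly False; ``thermoacidophiles_without_
    homologue`` lists species flagged both hyperthermophilic and acidophilic
    that nevertheless lack the family.  Unknown flags are excluded from the
    tables and never put a species on a violator list.
    """

    hyperthermophile: pd.DataFrame
    acidophile: pd.DataFrame
    bearers_not_hyperthermophilic: list[str]
    thermoacidophiles_without_homologue: list[str]


def phenotype_crosstab(records: Iterable[SpeciesRecord]) -> PhenotypeCrosstab:
    recs = list(records)

    def table(flag_attr: str) -> pd.DataFrame:
        rows = [
            {"presence": r.homologue_count > 0, "flag": getattr(r, flag_attr)}
            for r in recs
            if getattr(r, flag_attr) is not None
        ]
        df = pd.DataFrame(rows, columns=["presence", "flag"])
        return pd.crosstab(df["presence"], df["flag"], dropna=False)

    violators_a = sorted(
        r.name
        for r in recs
        if r.homologue_count > 0 and r.hyperthermophile is False
    )
    violators_b = sorted(
        r.name
        for r in recs
        if r.homologue_count == 0
        and r.hyperthermophile is True
        and r.acidophile is True
    )
    return PhenotypeCrosstab(
        hyperthermophile=table("hyperthermophile"),
        acidophile=table("acidophile"),
        bearers_not_hyperthermophilic=violators_a,
        thermoacidophiles_without_homologue=violators_b,
    )
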