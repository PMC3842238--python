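"""Ranked taxonomy trees for gene-family presence mapping.

A lineage table (one row per species/strain, with the six canonical ranks
phylum > class > order > family > genus > species) is turned into a single
rooted tree whose tips are species.  The tree is the substrate for the
ancestral-count walk in :mod:`paleofam.inference`: every internal node knows
whether its subtree contains at least one completely sequenced genome
("surveyed"), and every species tip carries the observed homologue count.

Conventions
-----------
* Unclassified species (``classified=False``) are dropped before building.
* Multiple strains of one species are merged into a single tip; the
  homologue count is aggregated with ``max`` by default (``sum`` optional).
* Ranks missing from a lineage are bridged by placeholder nodes named
  ``<child>_incertae_<rank>`` so that every root-to-tip path visits exactly
  one node per rank.
* Children are kept sorted by name, so the build is order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import dendropy
import pandas as pd

__all__ = [
    "RANKS",
    "ROOT_RANK",
    "SpeciesRecord",
    "TaxonNode",
    "build_taxonomy",
    "read_lineage_table",
    "write_lineage_table",
    "write_annotated_newick",
    "read_annotated_newick",
    "tree_to_dict",
]

#: Canonical ranks from most to least inclusive.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")

#: Rank of the synthetic root that holds the phyla together.
ROOT_RANK = "root"

_RANK_INDEX = {rank: i for i, rank in enumerate(RANKS)}


@dataclass(frozen=True)
class SpeciesRecord:
    """One species (or strain) row of a lineage table.

    ``hyperthermophile`` and ``acidophile`` are tri-state: ``True``,
    ``False`` or ``None`` when the growth optimum is not known.
    ``disputed`` marks rows whose homologue count is textually inconsistent
    in the source material and should not anchor exact numeric assertions.
    """

    name: str
    lineage: Mapping[str, str]
    homologue_count: int
    genome_sequenced: bool = True
    classified: bool = True
    hyperthermophile: Optional[bool] = None
    acidophile: Optional[bool] = None
    disputed: bool = False

    def __post_init__(self) -> None:
        if self.homologue_count < 0:
            raise ValueError(f"homologue_count must be >= 0 for {self.name!r}")
        lineage = dict(self.lineage)
        lineage.setdefault("species", self.name)
        object.__setattr__(self, "lineage", lineage)


@dataclass(eq=False)
class TaxonNode:
    """A node of the ranked taxonomy (hashable by identity)."""

    name: str
    rank: str
    children: list["TaxonNode"] = field(default_factory=list)
    parent: Optional["TaxonNode"] = field(default=None, repr=False)
    surveyed: bool = False
    observed_count: Optional[int] = None
    record: Optional[SpeciesRecord] = None

    def is_species(self) -> bool:
        return self.rank == "species"

    def walk(self) -> Iterator["TaxonNode"]:
        """Pre-order traversal (children in canonical name order)."""
        yield self
        for child in self.children:
            yield from child.walk()

    def species(self) -> list["TaxonNode"]:
        return [n for n in self.walk() if n.is_species()]

    def find(self, name: str) -> Optional["TaxonNode"]:
        for node in self.walk():
            if node.name == name:
                return node
        return None

    def rank_index(self) -> int:
        return -1 if self.rank == ROOT_RANK else _RANK_INDEX[self.rank]


def _merge_flag(a: Optional[bool], b: Optional[bool]) -> Optional[bool]:
    if a is None:
        return b
    if b is None:
        return a
    return a or b


def _merge_strains(records: list[SpeciesRecord], aggregate: str) -> list[SpeciesRecord]:
    merged: dict[str, SpeciesRecord] = {}
    for rec in records:
        prev = merged.get(rec.name)
        if prev is None:
            merged[rec.name] = rec
            continue
        if aggregate == "max":
            count = max(prev.homologue_count, rec.homologue_count)
        elif aggregate == "sum":
            count = prev.homologue_count + rec.homologue_count
        else:  # pragma: no cover - guarded by build_taxonomy
            raise ValueError(f"unknown aggregate mode {aggregate!r}")
        merged[rec.name] = replace(
            prev,
            homologue_count=count,
            genome_sequenced=prev.genome_sequenced or rec.genome_sequenced,
            hyperthermophile=_merge_flag(prev.hyperthermophile, rec.hyperthermophile),
            acidophile=_merge_flag(prev.acidophile, rec.acidophile),
            disputed=prev.disputed or rec.disputed,
        )
    return list(merged.values())


def _full_chain(record: SpeciesRecord) -> list[tuple[str, str]]:
    """(rank, name) per canonical rank, bridging gaps with placeholders.

    A placeholder for rank r is named after the nearest *named* taxon below
    it, e.g. ``Nanoarchaeum_incertae_class``.
    """
    names = [record.lineage.get(rank) or None for rank in RANKS]
    if names[-1] is None:
        names[-1] = record.name
    # fill from species upwards so the naming anchor always exists
    for i in range(len(RANKS) - 2, -1, -1):
        if names[i] is None:
            anchor = next(n for n in names[i + 1 :] if n and "_incertae_" not in n)
            names[i] = f"{anchor}_incertae_{RANKS[i]}"
    return list(zip(RANKS, names))


def build_taxonomy(
    records: Iterable[SpeciesRecord], aggregate: str = "max"
) -> TaxonNode:
    """Build the rooted ranked tree from species records.

    Parameters
    ----------
    records:
        Species rows; rows with ``classified=False`` are excluded.
    aggregate:
        How to combine homologue counts when several strains of the same
        species are present: ``"max"`` (default) or ``"sum"``.

    Returns
    -------
    TaxonNode
        The synthetic root (rank ``root``) whose children are phyla.
    """
    if aggregate not in ("max", "sum"):
        raise ValueError(f"aggregate must be 'max' or 'sum', got {aggregate!r}")
    kept = [r for r in records if r.classified]
    if not kept:
        raise ValueError("no classified records: cannot build a taxonomy")
    kept = _merge_strains(kept, aggregate)

    # reject a taxon name appearing under two different parents at one rank
    seen_parent: dict[tuple[str, str], str] = {}
    chains = []
    for rec in kept:
        chain = _full_chain(rec)
        parent_name = "Archaea"
        for rank, name in chain:
            key = (rank, name)
            if key in seen_parent and seen_parent[key] != parent_name:
                raise ValueError(
                    f"conflicting lineages: taxon {name!r} at rank {rank!r} appears "
                    f"under both {seen_parent[key]!r} and {parent_name!r}"
                )
            seen_parent[key] = parent_name
            parent_name = name
        chains.append((rec, chain))

    root = TaxonNode(name="Archaea", rank=ROOT_RANK)
    for rec, chain in chains:
        node = root
        for rank, name in chain:
            child = next(
                (c for c in node.children if c.name == name and c.rank == rank), None
            )
            if child is None:
                child = TaxonNode(name=name, rank=rank, parent=node)
                node.children.append(child)
            node = child
        node.observed_count = rec.homologue_count
        node.record = rec

    for node in root.walk():
        node.children.sort(key=lambda c: c.name)
    _set_surveyed(root)
    return root


def _set_surveyed(node: TaxonNode) -> bool:
    if node.is_species():
        node.surveyed = bool(node.record and node.record.genome_sequenced)
    else:
        node.surveyed = any([_set_surveyed(c) for c in node.children])
    return node.surveyed


# ---------------------------------------------------------------------------
# Lineage-table I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "genome_sequenced",
    "hyperthermophile",
    "acidophile",
    "classified",
    "homologue_count",
)

_TRUE = {"1", "true", "yes", "t", "y"}
_FALSE = {"0", "false", "no", "f", "n"}


def _parse_flag(value: str, default: Optional[bool] = None) -> Optional[bool]:
    v = value.strip().lower()
    if not v:
        return default
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean flag")


def read_lineage_table(path: str | Path) -> list[SpeciesRecord]:
    """Read a TSV lineage table into species records.

    Blank ``hyperthermophile``/``acidophile`` cells become ``None``
    ("unknown"), never ``False``.  A missing mandatory column or a
    non-integer homologue count is rejected with a message naming the
    column / row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"lineage table {path} is missing column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header row
        raw = dict(zip(df.columns, row))
        try:
            count = int(raw["homologue_count"])
        except ValueError:
            raise ValueError(
                f"row {i} of {path}: homologue_count "
                f"{raw['homologue_count']!r} is not an integer"
            ) from None
        lineage = {
            rank: raw[rank].strip() for rank in RANKS if raw.get(rank, "").strip()
        }
        records.append(
            SpeciesRecord(
                name=raw["species"].strip(),
                lineage=lineage,
                homologue_count=count,
                genome_sequenced=_parse_flag(raw["genome_sequenced"], default=False),
                classified=_parse_flag(raw["classified"], default=True),
                hyperthermophile=_parse_flag(raw["hyperthermophile"]),
                acidophile=_parse_flag(raw["acidophile"]),
                disputed=_parse_flag(raw.get("disputed", ""), default=False) or False,
            )
        )
    return records


def _flag_cell(value: Optional[bool]) -> str:
    return "" if value is None else ("1" if value else "0")


def write_lineage_table(records: Iterable[SpeciesRecord], path: str | Path) -> None:
    """Write records back to the TSV layout read_lineage_table expects."""
    rows = []
    for rec in records:
        rows.append(
            {
                "species": rec.name,
                "genus": rec.lineage.get("genus", ""),
                "family": rec.lineage.get("family", ""),
                "order": rec.lineage.get("order", ""),
                "class": rec.lineage.get("class", ""),
                "phylum": rec.lineage.get("phylum", ""),
                "genome_sequenced": _flag_cell(rec.genome_sequenced),
                "hyperthermophile": _flag_cell(rec.hyperthermophile),
                "acidophile": _flag_cell(rec.acidophile),
                "classified": _flag_cell(rec.classified),
                "homologue_count": rec.homologue_count,
                "disputed": _flag_cell(rec.disputed),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotated Newick
# ---------------------------------------------------------------------------


def _quote_label(name: str) -> str:
    return "'" + name.replace("'", "''") + "'"


def _annotation(node: TaxonNode, inferred: Optional[int]) -> str:
    parts = [f"rank={node.rank}", f"surveyed={int(node.surveyed)}"]
    if node.observed_count is not None:
        parts.append(f"count={node.observed_count}")
    if inferred is not None:
        parts.append(f"inferred={inferred}")
    if node.record is not None:
        for key, val in (
            ("hyper", node.record.hyperthermophile),
            ("acid", node.record.acidophile),
        ):
            parts.append(f"{key}={'?' if val is None else int(val)}")
        parts.append(f"sequenced={int(node.record.genome_sequenced)}")
    return "[&" + ",".join(parts) + "]"


def write_annotated_newick(
    root: TaxonNode,
    path: Optional[str | Path] = None,
    assignments: Optional[Mapping[TaxonNode, object]] = None,
) -> str:
    """Serialise the tree to Newick with ``[&key=value,...]`` annotations.

    ``assignments`` may be the map produced by
    :func:`paleofam.inference.assign_ancestral_counts`; assigned ancestral
    counts are then embedded as ``inferred=<n>`` comments.
    """

    def render(node: TaxonNode) -> str:
        inferred = None
        if assignments is not None and node in assignments:
            a = assignments[node]
            inferred = getattr(a, "inferred_count", None)
        label = _quote_label(node.name) + _annotation(node, inferred)
        if not node.children:
            return label
        return "(" + ",".join(render(c) for c in node.children) + ")" + label

    text = render(root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def _parse_annotation(comment: str) -> dict[str, str]:
    body = comment.lstrip("&")
    out = {}
    for item in body.split(","):
        if "=" in item:
            key, val = item.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def read_annotated_newick(source: str | Path) -> TaxonNode:
    """Parse Newick written by :func:`write_annotated_newick`.

    Parsing is delegated to dendropy; annotations are recovered from the
    square-bracket comments attached to each node.
    """
    if isinstance(source, Path) or ";" not in str(source):
        text = Path(source).read_text()
    else:
        text = str(source)
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=False,
        preserve_underscores=True,
        extract_comment_metadata=False,
    )

    def convert(dnode: dendropy.Node, parent: Optional[TaxonNode]) -> TaxonNode:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        meta: dict[str, str] = {}
        for comment in dnode.comments:
            meta.update(_parse_annotation(comment))
        node = TaxonNode(
            name=label,
            rank=meta.get("rank", "unknown"),
            parent=parent,
            surveyed=meta.get("surveyed") == "1",
        )
        if "count" in meta:
            node.observed_count = int(meta["count"])
        if node.rank == "species":
            flags = {}
            for key, attr in (("hyper", "hyperthermophile"), ("acid", "acidophile")):
                raw = meta.get(key, "?")
                flags[attr] = None if raw == "?" else bool(int(raw))
            node.record = SpeciesRecord(
                name=label,
                lineage=_lineage_from_ancestry(node),
                homologue_count=node.observed_count or 0,
                genome_sequenced=meta.get("sequenced") == "1",
                **flags,
            )
        node.children = [convert(c, node) for c in dnode.child_nodes()]
        node.children.sort(key=lambda c: c.name)
        return node

    return convert(tree.seed_node, None)


def _lineage_from_ancestry(node: TaxonNode) -> dict[str, str]:
    lineage = {}
    cur: Optional[TaxonNode] = node
    while cur is not None and cur.rank != ROOT_RANK:
        if cur.rank in _RANK_INDEX:
            lineage[cur.rank] = cur.name
        cur = cur.parent
    return lineage


def tree_to_dict(root: TaxonNode) -> dict:
    """JSON-serialisable nested dict view of the tree."""
    out: dict = {"name": root.name, "rank": root.rank, "surveyed": root.surveyed}
    if root.observed_count is not None:
        out["observed_count"] = root.observed_count
    if root.children:
        out["children"] = [tree_to_dict(c) for c in root.children]
    return out


def tree_to_json(root: TaxonNode, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_to_dict(root), indent=2) + "\n")
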