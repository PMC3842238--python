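"""Report rendering and provenance for CLI outputs."""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from . import __version__
from .inference import AssignmentMap
from .taxonomy import SpeciesRecord, TaxonNode

__all__ = ["render_presence_matrix", "provenance_block", "report_schema"]


def render_presence_matrix(
    root: TaxonNode, assignments: Optional[AssignmentMap] = None
) -> pd.DataFrame:
    """One row per species, in taxonomy walk order.

    Columns mirror the classic presence figure: sequenced genome,
    hyperthermophile, acidophile, homologue count (tri-state flags rendered
    as 1/0/?).
    """

    def cell(value) -> str:
        return "?" if value is None else str(int(value))

    rows = []
    for node in root.walk():
        if not node.is_species():
            continue
        rec = node.record
        rows.append(
            {
                "species": node.name,
                "lineage": ";".join(
                    a.name for a in _ancestry(node) if a.rank != "root"
                ),
                "sequenced": cell(rec.genome_sequenced if rec else None),
                "hyperthermophile": cell(rec.hyperthermophile if rec else None),
                "acidophile": cell(rec.acidophile if rec else None),
                "homologue_count": node.observed_count or 0,
            }
        )
    return pd.DataFrame(rows)


def _ancestry(node: TaxonNode) -> list[TaxonNode]:
    chain = []
    cur = node.parent
    while cur is not None:
        chain.append(cur)
        cur = cur.parent
    return list(reversed(chain))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def provenance_block(
    config: Mapping[str, object], inputs: Iterable[str | Path] = ()
) -> dict:
    """Version, echoed configuration and input checksums for JSON outputs."""
    return {
        "tool": "paleofam",
        "version": __version__,
        "config": {k: v for k, v in config.items()},
        "inputs": {str(p): _sha256(p) for p in inputs},
    }


def report_schema() -> dict:
    """The shipped JSON schema for inference reports."""
    text = resources.files("paleofam").joinpath("data/report.schema.json").read_text()
    return json.loads(text)
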