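"""Packaged example data.

``load_thermopsin_lineages`` returns the family A5 (thermopsin) survey
table: every archaeal species with a homologue plus representative
completely sequenced genomes without one, with ranked lineages, growth
phenotypes and per-species homologue counts.  Counts marked ``disputed``
are textually inconsistent between different statements of the source
survey (or, for *Ferroplasma acidarmanus*, not stated explicitly) and
should not anchor exact numeric assertions; the qualitative presence/
absence pattern is what the table is for.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .taxonomy import SpeciesRecord, read_lineage_table

__all__ = ["thermopsin_lineages_path", "load_thermopsin_lineages"]


def thermopsin_lineages_path() -> Path:
    return Path(resources.files("paleofam").joinpath("data/thermopsin_lineages.tsv"))


def load_thermopsin_lineages() -> list[SpeciesRecord]:
    return read_lineage_table(thermopsin_lineages_path())
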