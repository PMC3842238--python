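import numpy as np
import pytest

import paleofam as pf
from paleofam.taxonomy import RANKS, SpeciesRecord


@pytest.fixture(scope="session")
def survey_records():
    return pf.load_thermopsin_lineages()


@pytest.fixture(scope="session")
def survey_tree(survey_records):
    return pf.build_taxonomy(survey_records)


def make_record(
    name,
    phylum="P",
    klass="C",
    order="O",
    family="F",
    genus="G",
    count=0,
    sequenced=True,
    classified=True,
    hyper=None,
    acid=None,
):
    return SpeciesRecord(
        name=name,
        lineage={
            "phylum": phylum,
            "class": klass,
            "order": order,
            "family": family,
            "genus": genus,
            "species": name,
        },
        homologue_count=count,
        genome_sequenced=sequenced,
        classified=classified,
        hyperthermophile=hyper,
        acidophile=acid,
    )


def random_records(rng: np.random.Generator, max_tips: int = 50):
    """A random patchy lineage table with <= max_tips species.

    Counts are mostly zero with occasional multi-copy species, and a
    fraction of species lack a sequenced genome, exercising the surveyed
    bookkeeping.
    """
    records = []
    for p in range(int(rng.integers(1, 4))):
        for c in range(int(rng.integers(1, 3))):
            for o in range(int(rng.integers(1, 3))):
                for f in range(int(rng.integers(1, 3))):
                    for g in range(int(rng.integers(1, 3))):
                        for s in range(int(rng.integers(1, 4))):
                            name = f"p{p}c{c}o{o}f{f}g{g}s{s}"
                            count = (
                                int(rng.integers(1, 7))
                                if rng.random() < 0.35
                                else 0
                            )
                            records.append(
                                make_record(
                                    name,
                                    phylum=f"p{p}",
                                    klass=f"p{p}c{c}",
                                    order=f"p{p}c{c}o{o}",
                                    family=f"p{p}c{c}o{o}f{f}",
                                    genus=f"p{p}c{c}o{o}f{f}g{g}",
                                    count=count,
                                    sequenced=bool(rng.random() < 0.85),
                                )
                            )
                            if len(records) >= max_tips:
                                return records
    return records
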