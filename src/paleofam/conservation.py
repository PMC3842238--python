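"""Alignment-column conservation relative to a reference numbering.

The peptidase-domain alignment is read into a :class:`ReferenceAlignment`
whose coordinate system is the *ungapped* reference sequence (for the
thermopsin family, the preprothermopsin precursor: signal peptide +
propeptide + mature domain).  Per-position residue tallies then let the
caller ask "how many sequences keep an Asp at precursor position 257?" and
scan for columns conserved above a threshold within a residue class.

Residue classes group chemically interchangeable residues (Asp/Asn through
deamidation, Thr/Ser as alternative nucleophiles), so a position can be
called conserved even when no single residue dominates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

from Bio import SeqIO, AlignIO

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_RESIDUE_CLASSES",
    "ReferenceAlignment",
    "ConservationProfile",
    "CandidateSite",
    "read_alignment",
    "make_alignment",
    "write_fasta",
    "count_residue_at",
    "conservation_profile",
    "scan_candidate_sites",
    "extract_motif",
]

#: The twenty standard residues; gaps and ambiguity codes never match.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

GAP_CHARS = frozenset("-.")

#: Default classes: Asp; Asp/Asn (deamidation); Glu; Glu/Gln; Thr/Ser.
DEFAULT_RESIDUE_CLASSES: tuple[frozenset[str], ...] = (
    frozenset("D"),
    frozenset("DN"),
    frozenset("E"),
    frozenset("EQ"),
    frozenset("ST"),
)


@dataclass(frozen=True)
class ReferenceAlignment:
    """Equal-length aligned sequences plus the reference position map.

    ``pos2col`` maps 1-based ungapped reference positions to 1-based
    alignment columns and is strictly increasing.
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    reference_id: str
    pos2col: dict[int, int]

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def reference_length(self) -> int:
        return len(self.pos2col)

    def row(self, seq_id: str) -> str:
        try:
            return self.sequences[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None

    def column(self, col: int) -> str:
        """1-based alignment column as a string over sequences."""
        return "".join(seq[col - 1] for seq in self.sequences)


def _normalise(seq: str) -> str:
    return seq.upper().replace(".", "-")


def make_alignment(
    entries: Sequence[tuple[str, str]], reference_id: Optional[str] = None
) -> ReferenceAlignment:
    """Build a ReferenceAlignment from (id, aligned sequence) pairs."""
    if len(entries) < 2:
        raise ValueError("an alignment needs at least 2 sequences")
    ids = tuple(i for i, _ in entries)
    seqs = tuple(_normalise(s) for _, s in entries)
    width = len(seqs[0])
    for sid, seq in zip(ids, seqs):
        if len(seq) != width:
            raise ValueError(
                f"sequence {sid!r} has length {len(seq)}, expected {width}: "
                "ragged alignments are rejected"
            )
    ref_id = reference_id if reference_id is not None else ids[0]
    if ref_id not in ids:
        raise ValueError(f"reference id {ref_id!r} not found in alignment")
    ref = seqs[ids.index(ref_id)]
    pos2col = {}
    pos = 0
    for col, char in enumerate(ref, start=1):
        if char not in GAP_CHARS:
            pos += 1
            pos2col[pos] = col
    return ReferenceAlignment(
        ids=ids, sequences=seqs, reference_id=ref_id, pos2col=pos2col
    )


def read_alignment(
    path: str | Path, format: str = "fasta", reference_id: Optional[str] = None
) -> ReferenceAlignment:
    """Read a FASTA or Clustal alignment.

    Case is normalised to upper and ``.`` gaps to ``-``.  Unequal sequence
    lengths are rejected naming the offending id; the reference id (default:
    first sequence) must be present.
    """
    if format == "fasta":
        entries = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    elif format == "clustal":
        aln = AlignIO.read(str(path), "clustal")
        entries = [(r.id, str(r.seq)) for r in aln]
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    if not entries:
        raise ValueError(f"no sequences found in {path}")
    return make_alignment(entries, reference_id=reference_id)


def write_fasta(aln: ReferenceAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


def _check_position(aln: ReferenceAlignment, ref_pos: int) -> int:
    if ref_pos not in aln.pos2col:
        raise ValueError(
            f"reference position {ref_pos} out of range 1..{aln.reference_length}"
        )
    return aln.pos2col[ref_pos]


def count_residue_at(
    aln: ReferenceAlignment, ref_pos: int, residues: Iterable[str]
) -> int:
    """Sequences whose residue at the reference position is in the set.

    Gaps and ambiguity codes (anything outside the 20 standard residues)
    never match, whatever the caller puts in ``residues``.
    """
    col = _check_position(aln, ref_pos)
    wanted = {r.upper() for r in residues} & AMINO_ACIDS
    return sum(1 for c in aln.column(col) if c in wanted)


@dataclass(frozen=True)
class ConservationProfile:
    """Per-reference-position residue tallies."""

    counts: dict[int, Counter]
    gap_counts: dict[int, int]
    n_sequences: int

    def fraction(self, ref_pos: int, residues: Iterable[str]) -> float:
        wanted = {r.upper() for r in residues} & AMINO_ACIDS
        return sum(self.counts[ref_pos][r] for r in wanted) / self.n_sequences


def conservation_profile(aln: ReferenceAlignment) -> ConservationProfile:
    counts: dict[int, Counter] = {}
    gaps: dict[int, int] = {}
    for pos, col in aln.pos2col.items():
        column = aln.column(col)
        tally: Counter = Counter()
        gap = 0
        for c in column:
            if c in AMINO_ACIDS:
                tally[c] += 1
            else:
                gap += 1  # gaps and ambiguity codes pooled as non-matches
        counts[pos] = tally
        gaps[pos] = gap
    return ConservationProfile(counts=counts, gap_counts=gaps, n_sequences=aln.n_sequences)


class CandidateSite(NamedTuple):
    ref_pos: int
    residues: str  # sorted members of the matched class, e.g. "DN"
    count: int
    fraction: float


def scan_candidate_sites(
    aln: ReferenceAlignment,
    residue_classes: Sequence[Iterable[str]] = DEFAULT_RESIDUE_CLASSES,
    min_fraction: float = 0.6,
) -> list[CandidateSite]:
    """Reference positions conserved above ``min_fraction`` in some class.

    Returns one entry per (position, class) pair meeting the threshold,
    sorted by position then class string.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    classes = [frozenset(r.upper() for r in cls) for cls in residue_classes]
    profile = conservation_profile(aln)
    hits = []
    for pos in sorted(aln.pos2col):
        for cls in classes:
            count = sum(profile.counts[pos][r] for r in cls & AMINO_ACIDS)
            fraction = count / aln.n_sequences
            if fraction >= min_fraction:
                hits.append(
                    CandidateSite(pos, "".join(sorted(cls)), count, fraction)
                )
    hits.sort(key=lambda h: (h.ref_pos, h.residues))
    return hits


def extract_motif(
    aln: ReferenceAlignment, seq_id: str, ref_start: int, ref_end: int
) -> str:
    """Slice of a sequence between two reference positions (inclusive).

    The slice is taken on alignment columns, so insertion columns relative
    to the reference are included and gap characters are preserved.
    """
    if ref_start > ref_end:
        raise ValueError("ref_start must be <= ref_end")
    start = _check_position(aln, ref_start)
    end = _check_position(aln, ref_end)
    return aln.row(seq_id)[start - 1 : end]
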