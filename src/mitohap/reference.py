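"""Circular mitochondrial reference model and fixed coordinate catalogues.

Coordinates follow forensic convention throughout: 1-based, intervals
inclusive, and arithmetic wraps circularly so that the position after
16,569 is 1.  The control region spans the origin (nps 16,024-16,569 and
1-576); the coding region (CDS) is its complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RCRS_LENGTH = 16569

#: Historical placeholder position in the rCRS; carried as 'N' and excluded
#: from difference counting and distance site totals.
PLACEHOLDER_POSITION = 3107

#: Control region: wraps the origin.
CONTROL_REGION: tuple[tuple[int, int], ...] = ((16024, 16569), (1, 576))

#: The nine regions that commonly exhibit length heteroplasmy.
LENGTH_HET_REGIONS: tuple[tuple[int, int], ...] = (
    (303, 315),
    (452, 463),
    (513, 524),
    (565, 573),
    (956, 966),
    (5891, 5899),
    (8270, 8289),
    (12418, 12425),
    (16180, 16193),
)

#: Insertion positions ignored in haplotype comparison and database queries.
IGNORED_INSERTION_POSITIONS: frozenset[int] = frozenset(
    {16193, 309, 315, 455, 463, 573, 960, 5899, 8276, 8285}
)

#: Interval screened for nuclear-mitochondrial (NUMT) interference when the
#: four-amplicon enrichment is used (the 4C amplicon).
NUMT_SCREEN_INTERVAL: tuple[int, int] = (6636, 11428)


class RegionError(KeyError):
    """Unknown named region."""


@dataclass(frozen=True)
class MitoReference:
    """A circular mitochondrial reference sequence.

    Parameters
    ----------
    name:
        Sequence identifier (FASTA header).
    sequence:
        Upper-case base string over ``{A, C, G, T, N}``.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"reference contains non-IUPAC bases: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def wrap(self, position: int) -> int:
        """Map any integer onto 1..length circularly."""
        return (position - 1) % self.length + 1

    def base(self, position: int) -> str:
        """Reference base at a (circularly wrapped) 1-based position."""
        return self.sequence[self.wrap(position) - 1]

    def fetch(self, start: int, end: int) -> str:
        """Inclusive slice ``start..end``, wrapping the origin if start > end."""
        start, end = self.wrap(start), self.wrap(end)
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]


@dataclass(frozen=True)
class RegionCatalog:
    """Fixed coordinate sets used by calling, comparison and reporting."""

    control_region: tuple[tuple[int, int], ...] = CONTROL_REGION
    length_het_regions: tuple[tuple[int, int], ...] = LENGTH_HET_REGIONS
    ignored_insertion_positions: frozenset[int] = IGNORED_INSERTION_POSITIONS
    genome_length: int = RCRS_LENGTH

    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Complement of the control region within 1..genome_length."""
        # CR spans the origin, so the CDS is a single interval.
        return ((577, 16023),)

    def intervals(self, name: str) -> tuple[tuple[int, int], ...]:
        if name == "control_region":
            return self.control_region
        if name == "whole_mitogenome":
            return ((1, self.genome_length),)
        if name == "cds":
            return self.cds_intervals()
        raise RegionError(name)

    def in_region(self, position: int, name: str) -> bool:
        """True iff ``position`` lies in any interval of the named region."""
        if not 1 <= position <= self.genome_length:
            raise ValueError(f"position {position} outside 1-{self.genome_length}")
        return any(a <= position <= b for a, b in self.intervals(name))

    def in_length_het_region(self, position: int) -> bool:
        return any(a <= position <= b for a, b in self.length_het_regions)

    def length_het_region_at(self, position: int) -> tuple[int, int] | None:
        for a, b in self.length_het_regions:
            if a <= position <= b:
                return (a, b)
        return None


DEFAULT_CATALOG = RegionCatalog()


def in_region(position: int, name: str, catalog: RegionCatalog = DEFAULT_CATALOG) -> bool:
    """Module-level convenience wrapper around :meth:`RegionCatalog.in_region`."""
    return catalog.in_region(position, name)


def read_reference(path: str | Path) -> MitoReference:
    """Read a single-record FASTA reference (circularity is a convention,
    not encoded in the file)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return MitoReference(name=rec.id, sequence=str(rec.seq))


def write_reference(reference: MitoReference, path: str | Path) -> None:
    rec = SeqRecord(Seq(reference.sequence), id=reference.name, description="")
    SeqIO.write([rec], str(path), "fasta")
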