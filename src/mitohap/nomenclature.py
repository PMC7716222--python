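"""Forensic mtDNA variant nomenclature and haplotype profiles.

A haplotype is stored as a list of named differences from the circular
reference plus an interpretation range.  Variant strings follow forensic
convention: ``A263G`` (substitution), ``315.1C`` (insertion after np 315),
``249DEL`` / ``249-`` (deletion).  Point heteroplasmy (PHP) is coded with
the two-base IUPAC ambiguity code of the observed pair, e.g. ``C16192Y``.

Indels inside homopolymeric or repeated stretches are re-expressed at
their 3'-most equivalent placement (relative to the light-strand
reference orientation), the standard forensic alignment rule.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .reference import MitoReference, PLACEHOLDER_POSITION, RCRS_LENGTH

#: Two-base IUPAC ambiguity codes (PHP coding).  Three-base codes are
#: deliberately rejected: at most two bases are reported above threshold
#: at a single position.
IUPAC_PAIRS: dict[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}
PAIR_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_PAIRS.items()}

#: Transitions are A<->G (purine, code R) and C<->T (pyrimidine, code Y).
TRANSITION_CODES = frozenset({"R", "Y"})

VariantKind = Literal["substitution", "insertion", "deletion"]


class VariantParseError(ValueError):
    """Malformed or inconsistent forensic variant string."""


@dataclass(frozen=True, order=True)
class Variant:
    """One named difference from the reference.

    ``call`` is a single base for fixed calls, a two-base IUPAC code for
    PHPs, and empty for deletions.  ``major_frequency`` is the fraction of
    the dominant base at a PHP site; ``major_base`` records which base
    that is (needed to resolve a PHP to its major molecule).
    """

    position: int
    kind: VariantKind = "substitution"
    ref_base: str = ""
    call: str = ""
    insert_index: int | None = None
    major_frequency: float | None = None
    major_base: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.position <= RCRS_LENGTH:
            raise VariantParseError(f"position {self.position} outside 1-{RCRS_LENGTH}")
        if self.kind == "insertion":
            if self.insert_index is None or self.insert_index < 1:
                raise VariantParseError("insertion requires a positive insert index")
        elif self.insert_index is not None:
            raise VariantParseError("insert_index only valid for insertions")
        if self.kind == "deletion" and self.call:
            raise VariantParseError("deletion carries an empty call")
        if self.kind != "deletion" and not self.call:
            raise VariantParseError(f"{self.kind} requires a call")
        if len(self.call) > 1 and self.kind == "substitution":
            raise VariantParseError("substitution call is a single IUPAC character")
        if self.call and self.call not in "ACGT" and self.kind == "substitution":
            if self.call not in IUPAC_PAIRS:
                raise VariantParseError(
                    f"call {self.call!r} is not a base or two-base IUPAC code"
                )

    @property
    def is_php(self) -> bool:
        return self.kind == "substitution" and self.call in IUPAC_PAIRS

    @property
    def php_pair(self) -> frozenset[str] | None:
        return IUPAC_PAIRS.get(self.call)

    def sort_key(self) -> tuple[int, int]:
        return (self.position, self.insert_index or 0)


def parse_variant(text: str, reference: MitoReference | None = None) -> Variant:
    """Parse a forensic variant string.

    Accepted forms: ``<REF><pos><ALT>`` (ALT may be an ambiguity code),
    ``<pos>.<k><BASES>`` (insertion), ``<pos>DEL`` or ``<pos>-``
    (deletion).  If a reference is supplied, the stated reference base is
    checked against it.
    """
    token = text.strip()
    m = re.fullmatch(r"(\d+)\.(\d+)([ACGT]+)", token)
    if m:
        pos, idx, bases = int(m.group(1)), int(m.group(2)), m.group(3)
        return Variant(position=pos, kind="insertion", call=bases, insert_index=idx)
    m = re.fullmatch(r"(\d+)(?:DEL|del|-)", token)
    if m:
        pos = int(m.group(1))
        ref_base = reference.base(pos) if reference else ""
        return Variant(position=pos, kind="deletion", ref_base=ref_base)
    m = re.fullmatch(r"([ACGT])(\d+)([ACGTRYSWKM])", token)
    if m:
        ref_base, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if reference is not None and reference.base(pos) != ref_base:
            raise VariantParseError(
                f"{token!r}: stated reference base {ref_base} conflicts with "
                f"{reference.base(pos)} at np {pos}"
            )
        if alt in IUPAC_PAIRS and ref_base not in IUPAC_PAIRS[alt]:
            # e.g. A263Y — an ambiguity code that excludes the reference
            # base still denotes heteroplasmy between two non-ref bases.
            pass
        return Variant(position=pos, kind="substitution", ref_base=ref_base, call=alt)
    raise VariantParseError(f"unrecognised variant string {token!r}")


def format_variant(variant: Variant, deletion_style: str = "DEL") -> str:
    """Canonical string form; inverse of :func:`parse_variant`."""
    if variant.kind == "insertion":
        return f"{variant.position}.{variant.insert_index}{variant.call}"
    if variant.kind == "deletion":
        suffix = "-" if deletion_style == "-" else "DEL"
        return f"{variant.position}{suffix}"
    return f"{variant.ref_base}{variant.position}{variant.call}"


def php_variant(
    position: int,
    ref_base: str,
    bases: Iterable[str],
    major_base: str | None = None,
    major_frequency: float | None = None,
) -> Variant:
    """Construct a PHP substitution from the observed base pair."""
    pair = frozenset(bases)
    if len(pair) != 2:
        raise VariantParseError(f"PHP requires exactly two bases, got {sorted(pair)}")
    code = PAIR_TO_IUPAC.get(pair)
    if code is None:
        raise VariantParseError(f"no IUPAC code for pair {sorted(pair)}")
    return Variant(
        position=position,
        kind="substitution",
        ref_base=ref_base,
        call=code,
        major_base=major_base,
        major_frequency=major_frequency,
    )


@dataclass(frozen=True)
class AuditRecord:
    """One tracked profile edit: remove ``removed``, add ``added``."""

    operation: str
    removed: tuple[str, ...]
    added: tuple[str, ...]
    reason: str
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )


Interval = tuple[int, int]
WHOLE_MITOGENOME: tuple[Interval, ...] = ((1, RCRS_LENGTH),)


def _interval_contains(interval: Interval, position: int) -> bool:
    a, b = interval
    if a <= b:
        return a <= position <= b
    return position >= a or position <= b  # wraps the origin


@dataclass(frozen=True)
class MitoProfile:
    """A sample's haplotype: named differences plus interpretation range."""

    sample_id: str
    variants: tuple[Variant, ...] = ()
    range: tuple[Interval, ...] = WHOLE_MITOGENOME
    haplogroup: str | None = None
    population: str | None = None
    source: str | None = None
    mixture_suspect_sites: tuple[int, ...] = ()
    length_het_regions: tuple[Interval, ...] = ()
    audit: tuple[AuditRecord, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.variants, key=Variant.sort_key))
        object.__setattr__(self, "variants", ordered)
        seen: set[tuple[int, str, int | None]] = set()
        for v in ordered:
            key = (v.position, v.kind, v.insert_index)
            if key in seen:
                raise ValueError(f"duplicate variant at {key}")
            seen.add(key)
            if not self.covers(v.position):
                raise ValueError(
                    f"variant at np {v.position} outside interpretation range"
                )

    def covers(self, position: int) -> bool:
        return any(_interval_contains(iv, position) for iv in self.range)

    def php_variants(self) -> tuple[Variant, ...]:
        return tuple(v for v in self.variants if v.is_php)

    def with_variants(self, variants: Iterable[Variant], audit_extra=()) -> "MitoProfile":
        return replace(
            self, variants=tuple(variants), audit=self.audit + tuple(audit_extra)
        )


def _shift_insertion_3prime(
    position: int, motif: str, reference: MitoReference
) -> tuple[int, str]:
    """3'-most equivalent placement of inserting ``motif`` after ``position``.

    Inserting after np p equals inserting after p+1 whenever the base at
    p+1 matches the motif's first base (the motif rotates as it shifts).
    """
    pos, m = position, motif
    while pos < reference.length and reference.base(pos + 1) == m[0]:
        pos, m = pos + 1, m[1:] + m[0]
    return pos, m


def _shift_deletion_block_3prime(
    start: int, end: int, reference: MitoReference
) -> tuple[int, int]:
    """3'-most placement of deleting the block ``start..end`` (inclusive).

    Deleting [p, q] equals deleting [p+1, q+1] iff base(p) == base(q+1).
    """
    p, q = start, end
    while q < reference.length and reference.base(q + 1) == reference.base(p):
        p, q = p + 1, q + 1
    return p, q


def normalize_indels(
    profile: MitoProfile, reference: MitoReference
) -> MitoProfile:
    """Re-express indels at their 3'-most equivalent placement.

    Substitutions are untouched; every change is recorded in the
    profile's audit trail.  A deletion run (adjacent deleted positions)
    shifts as a block, so e.g. a deletion written at the 5' end of an AC
    repeat lands on the 3'-most AC.  Idempotent.
    """
    subs = [v for v in profile.variants if v.kind == "substitution"]
    insertions = [v for v in profile.variants if v.kind == "insertion"]
    deletions = sorted(
        (v for v in profile.variants if v.kind == "deletion"),
        key=lambda v: v.position,
    )

    out: list[Variant] = list(subs)
    audit: list[AuditRecord] = []

    for v in insertions:
        pos, motif = _shift_insertion_3prime(v.position, v.call, reference)
        if pos != v.position or motif != v.call:
            new = replace(v, position=pos, call=motif)
            if not profile.covers(pos):
                raise ValueError(
                    f"insertion {format_variant(v)} shifts to np {pos}, outside range"
                )
            audit.append(
                AuditRecord(
                    operation="normalize_indels",
                    removed=(format_variant(v),),
                    added=(format_variant(new),),
                    reason="3'-most placement",
                )
            )
            out.append(new)
        else:
            out.append(v)

    # group adjacent deletions into blocks
    blocks: list[list[Variant]] = []
    for v in deletions:
        if blocks and v.position == blocks[-1][-1].position + 1:
            blocks[-1].append(v)
        else:
            blocks.append([v])
    for block in blocks:
        start, end = block[0].position, block[-1].position
        new_start, new_end = _shift_deletion_block_3prime(start, end, reference)
        if new_start == start:
            out.extend(block)
            continue
        new_block = [
            Variant(position=p, kind="deletion", ref_base=reference.base(p))
            for p in range(new_start, new_end + 1)
        ]
        for nv in new_block:
            if not profile.covers(nv.position):
                raise ValueError(
                    f"deletion block {start}-{end} shifts to "
                    f"{new_start}-{new_end}, outside range"
                )
        audit.append(
            AuditRecord(
                operation="normalize_indels",
                removed=tuple(format_variant(v) for v in block),
                added=tuple(format_variant(v) for v in new_block),
                reason="3'-most placement",
            )
        )
        out.extend(new_block)

    return profile.with_variants(out, audit)


PhpResolution = Literal["major", "ambiguity"]


def profile_to_sequence(
    profile: MitoProfile,
    reference: MitoReference,
    interval: Interval | None = None,
    php_resolution: PhpResolution = "ambiguity",
) -> str:
    """Reconstruct the sample sequence over ``interval`` (inclusive).

    Reference bases are replaced by profile calls, insertions are
    spliced after their anchor position, deletions are removed.  A PHP
    is rendered as its major base (``php_resolution='major'``, requiring
    the recorded major base or frequency) or kept as its ambiguity code.
    """
    if interval is None:
        interval = (1, reference.length)
    start, end = interval
    positions: list[int] = []
    p = reference.wrap(start)
    while True:
        positions.append(p)
        if p == reference.wrap(end):
            break
        p = reference.wrap(p + 1)
        if len(positions) > reference.length:
            raise ValueError("interval longer than the genome")

    by_pos: dict[int, list[Variant]] = {}
    for v in profile.variants:
        by_pos.setdefault(v.position, []).append(v)

    pieces: list[str] = []
    for pos in positions:
        base = reference.base(pos)
        inserts: list[Variant] = []
        for v in by_pos.get(pos, []):
            if v.kind == "substitution":
                if v.is_php:
                    if php_resolution == "ambiguity":
                        base = v.call
                    else:
                        base = _php_major_base(v)
                else:
                    base = v.call
            elif v.kind == "deletion":
                base = ""
            else:
                inserts.append(v)
        pieces.append(base)
        for v in sorted(inserts, key=lambda i: i.insert_index or 0):
            pieces.append(v.call)
    return "".join(pieces)


def _php_major_base(v: Variant) -> str:
    if v.major_base:
        return v.major_base
    if v.major_frequency is None:
        raise ValueError(
            f"PHP {format_variant(v)} has no recorded major base or frequency; "
            "cannot resolve to the major molecule"
        )
    # A recorded frequency without an explicit major base: the reference
    # member of the pair is taken as dominant (the variant base is
    # typically the minor one in practice).
    pair = v.php_pair or frozenset()
    if v.ref_base in pair:
        return v.ref_base
    raise ValueError(f"cannot infer major base of {format_variant(v)}")


# ---------------------------------------------------------------------------
# EMPOP-style haplotype tables

def format_range(intervals: Sequence[Interval]) -> str:
    return ";".join(f"{a}-{b}" for a, b in intervals)


def parse_range(text: str) -> tuple[Interval, ...]:
    out = []
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        a, b = part.split("-")
        out.append((int(a), int(b)))
    if not out:
        raise ValueError(f"empty range string {text!r}")
    return tuple(out)


def read_profile_table(
    path: str | Path, reference: MitoReference | None = None
) -> list[MitoProfile]:
    """Read a tab-separated haplotype table.

    Columns: SampleID, [Population], [Haplogroup], Range, Variants
    (space-separated forensic strings; empty for the reference itself).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    profiles = []
    for _, row in df.iterrows():
        variants = tuple(
            parse_variant(tok, reference)
            for tok in str(row.get("Variants", "")).split()
        )
        profiles.append(
            MitoProfile(
                sample_id=row["SampleID"],
                variants=variants,
                range=parse_range(row.get("Range", "1-16569") or "1-16569"),
                haplogroup=row.get("Haplogroup") or None,
                population=row.get("Population") or None,
            )
        )
    return profiles


def write_profile_table(
    profiles: Sequence[MitoProfile], path: str | Path, deletion_style: str = "DEL"
) -> None:
    """Write profiles with deterministic ordering (by sample id)."""
    rows = []
    for p in sorted(profiles, key=lambda q: q.sample_id):
        rows.append(
            {
                "SampleID": p.sample_id,
                "Population": p.population or "",
                "Haplogroup": p.haplogroup or "",
                "Range": format_range(p.range),
                "Variants": " ".join(
                    format_variant(v, deletion_style) for v in p.variants
                ),
            }
        )
    pd.DataFrame(
        rows, columns=["SampleID", "Population", "Haplogroup", "Range", "Variants"]
    ).to_csv(path, sep="\t", index=False)
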