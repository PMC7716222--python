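"""Length-heteroplasmy resolution by spanning-read motif counting.

Homopolymer and repeat regions produce mixtures of molecules that
differ in length, which confounds per-column variant calling.  Reads
that span an entire catalogued region (plus one anchor base on each
side) are grouped by the sequence motif they carry across it; motifs
supported by five or more reads are listed, and the motif with the most
reads — the major length molecule — is reported.  The variants that the
major motif implies relative to the reference are obtained by a minimal
edit script, with indels re-expressed at their 3'-most placement.
Point heteroplasmy inside a region is detected by comparing same-length
motifs position by position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .calling import AlignedRead, CallParams
from .nomenclature import (
    AuditRecord,
    MitoProfile,
    Variant,
    format_variant,
    normalize_indels,
    php_variant,
)
from .reference import DEFAULT_CATALOG, MitoReference, RegionCatalog

#: Motifs with fewer spanning reads than this are not listed.
MOTIF_READ_FLOOR = 5


@dataclass(frozen=True)
class MotifTable:
    """Spanning-read counts per sequence motif for one region.

    ``motifs`` lists only motifs with at least :data:`MOTIF_READ_FLOOR`
    reads; ``total_spanning`` counts every spanning read, so the listed
    counts may sum to less than it.
    """

    region: tuple[int, int]
    motifs: dict[str, int]
    total_spanning: int


@dataclass(frozen=True)
class MajorMoleculeCall:
    """The major length molecule of one region and its implied variants."""

    region: tuple[int, int]
    major_motif: str
    major_count: int
    minor_motifs: tuple[tuple[str, int], ...]
    derived_variants: tuple[Variant, ...]
    length_het_present: bool
    total_spanning: int


def spanning_motifs(
    reads: Sequence[AlignedRead],
    region: tuple[int, int],
    catalog: RegionCatalog = DEFAULT_CATALOG,
) -> MotifTable:
    """Count region-spanning reads by the motif they carry.

    A read counts if it covers the full region plus one anchor base on
    each side with no masked base inside.  The motif is the read's
    bases strictly between the anchors, with deletions removed and
    insertion motifs spliced after their anchor.
    """
    if region not in catalog.length_het_regions:
        raise ValueError(f"region {region} not in the length-heteroplasmy catalogue")
    start, end = region
    counts: dict[str, int] = {}
    total = 0
    for read in reads:
        first, last = read.start, read.start + len(read) - 1
        if first > start - 1 or last < end + 1:
            continue
        lo, hi = start - 1 - read.start, end + 1 - read.start
        window = read.bases[lo : hi + 1]
        if "N" in window:
            continue
        total += 1
        pieces: list[str] = []
        ins0 = read.insertions.get(start - 1)
        if ins0:
            pieces.append(ins0)
        for offset, pos in enumerate(range(start, end + 1)):
            b = window[1 + offset]
            if b != "-":
                pieces.append(b)
            ins = read.insertions.get(pos)
            if ins:
                pieces.append(ins)
        motif = "".join(pieces)
        counts[motif] = counts.get(motif, 0) + 1
    listed = {m: c for m, c in sorted(counts.items()) if c >= MOTIF_READ_FLOOR}
    return MotifTable(region=region, motifs=listed, total_spanning=total)


# ---------------------------------------------------------------------------
# Minimal edit script between a motif and the reference segment

def _edit_script(ref_seg: str, motif: str) -> list[tuple[str, int, str]]:
    """Minimal-cost edit script (unit costs) as ops on the reference segment.

    Returns ``(op, ref_offset, base)`` tuples: ``sub`` replaces the base
    at ref_offset, ``del`` removes it, ``ins`` inserts ``base`` after
    ref_offset (-1 for an insertion before the segment).  Traceback is
    deterministic, preferring diagonal, then deletion, then insertion;
    indel placement is normalised downstream.
    """
    n, m = len(ref_seg), len(motif)
    cost = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        cost[i][0] = i
    for j in range(1, m + 1):
        cost[0][j] = j
    for i in range(1, n + 1):
        ci, cim = cost[i], cost[i - 1]
        for j in range(1, m + 1):
            ci[j] = min(
                cim[j - 1] + (ref_seg[i - 1] != motif[j - 1]),
                cim[j] + 1,
                ci[j - 1] + 1,
            )
    ops: list[tuple[str, int, str]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and cost[i][j] == cost[i - 1][j - 1] + (
            ref_seg[i - 1] != motif[j - 1]
        ):
            if ref_seg[i - 1] != motif[j - 1]:
                ops.append(("sub", i - 1, motif[j - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and cost[i][j] == cost[i - 1][j] + 1:
            ops.append(("del", i - 1, ""))
            i -= 1
        else:
            ops.append(("ins", i - 1, motif[j - 1]))
            j -= 1
    ops.reverse()
    return ops


def motif_variants(
    motif: str, region: tuple[int, int], reference: MitoReference
) -> tuple[Variant, ...]:
    """Variants a motif implies against the reference, 3'-normalised.

    Consecutive inserted bases after one anchor merge into a single
    insertion motif; indels are then shifted to their 3'-most placement
    on the full circular reference.
    """
    start, end = region
    ref_seg = reference.fetch(start, end)
    ops = _edit_script(ref_seg, motif)
    variants: list[Variant] = []
    ins_acc: dict[int, list[str]] = {}
    for op, offset, base in ops:
        pos = start + offset
        if op == "sub":
            variants.append(
                Variant(
                    position=pos,
                    kind="substitution",
                    ref_base=reference.base(pos),
                    call=base,
                )
            )
        elif op == "del":
            variants.append(
                Variant(position=pos, kind="deletion", ref_base=reference.base(pos))
            )
        else:
            ins_acc.setdefault(pos, []).append(base)
    for pos, bases in ins_acc.items():
        anchor = pos if pos >= start else start - 1
        variants.append(
            Variant(
                position=anchor, kind="insertion", call="".join(bases), insert_index=1
            )
        )
    if not variants:
        return ()
    probe = MitoProfile(sample_id="_motif", variants=tuple(variants))
    return normalize_indels(probe, reference).variants


def major_molecule(
    table: MotifTable, reference: MitoReference
) -> MajorMoleculeCall:
    """Select the most-read-supported motif and derive its variants.

    Ties between equally supported motifs are broken toward the motif
    whose length is closest to the reference segment, then
    lexicographically.  Length heteroplasmy is declared when at least
    two listed motifs differ in length.
    """
    if not table.motifs:
        raise ValueError(f"empty motif table for region {table.region}")
    start, end = table.region
    ref_len = end - start + 1
    ranked = sorted(
        table.motifs.items(),
        key=lambda kv: (-kv[1], abs(len(kv[0]) - ref_len), kv[0]),
    )
    major, major_count = ranked[0]
    lengths = {len(m) for m in table.motifs}
    return MajorMoleculeCall(
        region=table.region,
        major_motif=major,
        major_count=major_count,
        minor_motifs=tuple(ranked[1:]),
        derived_variants=motif_variants(major, table.region, reference),
        length_het_present=len(lengths) > 1,
        total_spanning=table.total_spanning,
    )


def php_in_region(
    table: MotifTable,
    reference: MitoReference,
    params: CallParams | None = None,
) -> tuple[Variant, ...]:
    """Detect point heteroplasmy among same-length listed motifs.

    Within each length class, positions where the motifs disagree are
    examined; a minor base whose spanning-read fraction reaches the
    variant-frequency threshold is emitted as a PHP.  Motif offsets map
    to genome positions through the alignment of the class's dominant
    motif to the reference segment.
    """
    params = params or CallParams()
    if not table.motifs:
        return ()
    start, end = table.region
    ref_seg = reference.fetch(start, end)
    by_length: dict[int, list[tuple[str, int]]] = {}
    for motif, count in table.motifs.items():
        by_length.setdefault(len(motif), []).append((motif, count))
    out: list[Variant] = []
    seen_positions: set[int] = set()
    for length, group in sorted(
        by_length.items(), key=lambda kv: -sum(c for _, c in kv[1])
    ):
        if len(group) < 2:
            continue
        group.sort(key=lambda mc: (-mc[1], mc[0]))
        top = group[0][0]
        # genome position of each motif offset (None where inserted)
        pos_map = _offset_positions(ref_seg, top, start)
        group_total = sum(c for _, c in group)
        for i in range(length):
            pos = pos_map[i]
            if pos is None or pos in seen_positions:
                continue
            base_counts: dict[str, int] = {}
            for motif, count in group:
                base_counts[motif[i]] = base_counts.get(motif[i], 0) + count
            if len(base_counts) < 2:
                continue
            ranked = sorted(base_counts.items(), key=lambda kv: (-kv[1], kv[0]))
            (major, major_n), (minor, minor_n) = ranked[0], ranked[1]
            if minor_n / table.total_spanning < params.vf_threshold:
                continue
            seen_positions.add(pos)
            out.append(
                php_variant(
                    position=pos,
                    ref_base=reference.base(pos),
                    bases=(major, minor),
                    major_base=major,
                    major_frequency=major_n / group_total,
                )
            )
    return tuple(sorted(out, key=Variant.sort_key))


def _offset_positions(ref_seg: str, motif: str, start: int) -> list[int | None]:
    """Genome position carried by each motif offset (None for inserted bases)."""
    ops = _edit_script(ref_seg, motif)
    consumed: dict[int, str] = {}  # ref offset -> 'sub'/'del'
    inserted_after: dict[int, int] = {}
    for op, offset, _ in ops:
        if op in ("sub", "del"):
            consumed[offset] = op
        else:
            inserted_after[offset] = inserted_after.get(offset, 0) + 1
    positions: list[int | None] = []
    for _ in range(inserted_after.get(-1, 0)):
        positions.append(None)
    for offset in range(len(ref_seg)):
        if consumed.get(offset) != "del":
            positions.append(start + offset)
        for _ in range(inserted_after.get(offset, 0)):
            positions.append(None)
    return positions


def apply_length_calls(
    profile: MitoProfile,
    calls: Sequence[MajorMoleculeCall],
    extra_php: Sequence[Variant] = (),
) -> MitoProfile:
    """Insert major-molecule variants (and any in-region PHPs) into a
    profile whose region indels were withheld by the caller.

    Every edit is written to the audit trail; regions whose motif
    tables showed more than one length are annotated as
    length-heteroplasmic.  A conflicting substitution already present
    inside a region indicates broken upstream withholding and raises.
    """
    existing = {(v.position, v.kind, v.insert_index): v for v in profile.variants}
    new_variants = list(profile.variants)
    audit: list[AuditRecord] = []
    het_regions: list[tuple[int, int]] = list(profile.length_het_regions)
    for call in calls:
        added: list[str] = []
        for v in call.derived_variants:
            key = (v.position, v.kind, v.insert_index)
            if key in existing:
                if existing[key].call != v.call:
                    raise ValueError(
                        f"conflicting call at np {v.position}: profile has "
                        f"{format_variant(existing[key])}, major molecule implies "
                        f"{format_variant(v)}"
                    )
                continue
            existing[key] = v
            new_variants.append(v)
            added.append(format_variant(v))
        if added:
            audit.append(
                AuditRecord(
                    operation="apply_length_calls",
                    removed=(),
                    added=tuple(added),
                    reason=f"major length molecule in {call.region[0]}-{call.region[1]}",
                )
            )
        if call.length_het_present and call.region not in het_regions:
            het_regions.append(call.region)
    for v in extra_php:
        key = (v.position, v.kind, v.insert_index)
        if key in existing:
            if existing[key].call != v.call:
                raise ValueError(
                    f"conflicting PHP at np {v.position}: {format_variant(existing[key])}"
                    f" vs {format_variant(v)}"
                )
            continue
        existing[key] = v
        new_variants.append(v)
        audit.append(
            AuditRecord(
                operation="apply_length_calls",
                removed=(),
                added=(format_variant(v),),
                reason="PHP from in-region motif comparison",
            )
        )
    out = profile.with_variants(new_variants, audit)
    return replace(out, length_het_regions=tuple(het_regions))


def resolve_length_heteroplasmy(
    profile: MitoProfile,
    reads: Sequence[AlignedRead],
    reference: MitoReference,
    params: CallParams | None = None,
    catalog: RegionCatalog = DEFAULT_CATALOG,
) -> tuple[MitoProfile, dict[tuple[int, int], MajorMoleculeCall]]:
    """Run motif counting over all catalogued regions and rewrite the profile.

    Regions with no listed motif are left as no-calls (unresolved, low
    confidence).  Returns the updated profile and the per-region calls.
    """
    params = params or CallParams()
    calls: dict[tuple[int, int], MajorMoleculeCall] = {}
    php: list[Variant] = []
    for region in catalog.length_het_regions:
        table = spanning_motifs(reads, region, catalog)
        if not table.motifs:
            continue
        call = major_molecule(table, reference)
        calls[region] = call
        php.extend(php_in_region(table, reference, params))
    updated = apply_length_calls(profile, list(calls.values()), php)
    return updated, calls
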