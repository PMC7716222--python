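"""Threshold-based mitogenome variant and heteroplasmy calling.

The caller consumes pre-aligned reads (or a per-position, per-strand
count pileup) and applies the pipeline's interpretation rules: 5'/3'
read trimming, a neighbourhood base-quality mask, a minimum filtered
depth of 100x, a 5% variant-frequency threshold, and a 1% per-allele
forward/reverse strand-balance filter.  Two bases above threshold at one
position yield a point heteroplasmy (PHP) coded with the IUPAC ambiguity
code of the pair.  A secondary 2% pass screens for nuclear-mitochondrial
(NUMT) interference below the reporting threshold.

Indels inside the nine catalogued length-heteroplasmy regions are
withheld here; the length-heteroplasmy module resolves those regions by
spanning-read motif counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .nomenclature import (
    MitoProfile,
    PAIR_TO_IUPAC,
    Variant,
    normalize_indels,
)
from .reference import (
    DEFAULT_CATALOG,
    MitoReference,
    NUMT_SCREEN_INTERVAL,
    RegionCatalog,
)

_BASES = "ACGT"
_ALLELES = "ACGT-"  # '-' is the deletion allele class
_ALLELE_INDEX = {a: i for i, a in enumerate(_ALLELES)}


@dataclass(frozen=True)
class CallParams:
    """Interpretation thresholds for variant calling.

    Defaults follow the validated forensic pipeline: 100x minimum
    filtered depth, 5% variant frequency, neighbourhood quality mask
    (radius 5, minimum 30), 1% per-allele strand balance, 20 nt 5'
    trim (plus 20 nt 3' trim for paired reads), 40 bp minimum read
    length, and a 2% secondary threshold for the NUMT screen.
    """

    min_depth: int = 100
    vf_threshold: float = 0.05
    numt_screen_vf: float = 0.02
    bq_radius: int = 5
    bq_central: int = 30
    bq_neighborhood: int = 30
    strand_balance_min: float = 0.01
    trim_5p: int = 20
    trim_3p_paired: int = 20
    min_read_length: int = 40
    min_identity: float = 0.8  # SAM admission (similarity fraction)

    def __post_init__(self) -> None:
        if not 0 < self.numt_screen_vf < self.vf_threshold < 0.5:
            raise ValueError("require 0 < numt_screen_vf < vf_threshold < 0.5")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class AlignedRead:
    """A read aligned to the circular reference.

    ``bases[i]`` sits on reference position ``start + i`` (wrapping);
    ``'-'`` marks a deleted reference base, ``'N'`` a masked base that
    contributes nothing to any column.  ``insertions`` maps an anchor
    position to the motif inserted immediately after it.
    """

    read_id: str
    start: int
    strand: Literal["+", "-"]
    bases: str
    qualities: tuple[int, ...]
    paired: bool = False
    insertions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.bases):
            raise ValueError("qualities and bases must have equal length")

    def __len__(self) -> int:
        return len(self.bases)


def trim_reads(reads: Iterable[AlignedRead], params: CallParams) -> list[AlignedRead]:
    """5' trim all reads; additionally 3' trim paired reads; drop short reads.

    Trimming is in sequencing orientation: the 5' end of a
    reverse-strand read is its highest reference coordinate.
    """
    out = []
    for read in reads:
        left = params.trim_5p if read.strand == "+" else (
            params.trim_3p_paired if read.paired else 0
        )
        right = params.trim_5p if read.strand == "-" else (
            params.trim_3p_paired if read.paired else 0
        )
        n = len(read)
        if n - left - right < params.min_read_length:
            continue
        new_start = read.start + left
        bases = read.bases[left : n - right if right else n]
        quals = read.qualities[left : n - right if right else n]
        kept = {
            pos: motif
            for pos, motif in read.insertions.items()
            if 0 <= pos - new_start < len(bases) - 1
        }
        out.append(
            replace(read, start=new_start, bases=bases, qualities=quals, insertions=kept)
        )
    return out


def quality_mask(read: AlignedRead, params: CallParams) -> AlignedRead:
    """Mask bases failing the neighbourhood quality filter.

    A base is excluded when its own quality is below ``bq_central`` or
    when the minimum quality within ``bq_radius`` bases on either side
    is below ``bq_neighborhood`` (window truncated at read ends).  This
    is a per-base interpretation of the published neighbourhood filter;
    the original tool's exact semantics are unpublished.
    """
    q = np.asarray(read.qualities, dtype=np.int32)
    n = q.size
    if n == 0:
        return read
    r = params.bq_radius
    window_min = q.copy()
    for shift in range(1, r + 1):
        window_min[shift:] = np.minimum(window_min[shift:], q[:-shift])
        window_min[:-shift] = np.minimum(window_min[:-shift], q[shift:])
    bad = (q < params.bq_central) | (window_min < params.bq_neighborhood)
    if not bad.any():
        return read
    bases = "".join(
        "N" if m else b for b, m in zip(read.bases, bad)
    )
    kept_ins = {
        pos: motif
        for pos, motif in read.insertions.items()
        if not bad[pos - read.start]
    }
    return replace(read, bases=bases, insertions=kept_ins)


class Pileup:
    """Per-position, per-strand allele counts over the circular genome.

    ``counts[pos-1, allele, strand]`` with alleles ``A C G T -`` and
    strands forward/reverse.  Insertion motifs are counted on their
    anchoring position.
    """

    def __init__(self, reference: MitoReference):
        self.reference = reference
        self.counts = np.zeros((reference.length, 5, 2), dtype=np.int64)
        self.insertions: dict[int, dict[str, np.ndarray]] = {}

    @property
    def depth(self) -> np.ndarray:
        """Filtered depth per position (1-based position p at index p-1)."""
        return self.counts.sum(axis=(1, 2))

    def add_insertion(self, position: int, motif: str, strand: int, count: int = 1) -> None:
        slot = self.insertions.setdefault(position, {}).setdefault(
            motif, np.zeros(2, dtype=np.int64)
        )
        slot[strand] += count

    def column(self, position: int) -> "PileupColumn":
        idx = self.reference.wrap(position) - 1
        ins = {
            motif: counts.copy()
            for motif, counts in self.insertions.get(position, {}).items()
        }
        return PileupColumn(
            position=position, counts=self.counts[idx].copy(), insertion_observations=ins
        )


@dataclass
class PileupColumn:
    """One position's per-strand allele counts."""

    position: int
    counts: np.ndarray  # (5 alleles, 2 strands)
    insertion_observations: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def filtered_depth(self) -> int:
        return int(self.counts.sum())


def build_pileup(reads: Sequence[AlignedRead], reference: MitoReference) -> Pileup:
    """Accumulate masked, trimmed reads into a pileup (circular wrap handled)."""
    pile = Pileup(reference)
    L = reference.length
    for read in reads:
        if len(read) > 2 * L:
            raise ValueError(f"read {read.read_id} longer than twice the genome")
        strand = 0 if read.strand == "+" else 1
        offsets = np.arange(len(read))
        positions = (read.start - 1 + offsets) % L
        allele_idx = np.array(
            [_ALLELE_INDEX.get(b, -1) for b in read.bases], dtype=np.int64
        )
        keep = allele_idx >= 0  # drops 'N'
        np.add.at(pile.counts, (positions[keep], allele_idx[keep], strand), 1)
        for pos, motif in read.insertions.items():
            pile.add_insertion(reference.wrap(pos), motif, strand)
    return pile


@dataclass(frozen=True)
class ColumnCall:
    """Outcome of interpreting one pileup column."""

    position: int
    status: Literal["no_call", "reference", "variant", "php", "mixture_suspect"]
    variant: Variant | None = None
    retained: tuple[tuple[str, int], ...] = ()


def _retained_alleles(
    counts: np.ndarray, vf: float, strand_min: float
) -> list[tuple[str, int]]:
    """Alleles passing the frequency and per-allele strand-balance rules."""
    depth = int(counts.sum())
    if depth == 0:
        return []
    out = []
    for i, allele in enumerate(_ALLELES):
        fwd, rev = int(counts[i, 0]), int(counts[i, 1])
        total = fwd + rev
        if total == 0 or total / depth < vf:
            continue
        if fwd / total < strand_min or rev / total < strand_min:
            continue
        out.append((allele, total))
    return sorted(out, key=lambda t: (-t[1], t[0]))


def call_column(
    column: PileupColumn, ref_base: str, params: CallParams
) -> ColumnCall:
    """Interpret one column under the depth/VF/strand rules.

    One retained non-reference base yields a fixed substitution; two
    retained bases yield a PHP with the IUPAC code of the pair and the
    recorded major-base frequency; more than two retained alleles flag
    the column as mixture-suspect and no call is emitted.  Ties between
    equally supported bases keep both (PHP), the major designated by
    base order A<C<G<T.
    """
    depth = column.filtered_depth
    pos = column.position
    if depth < params.min_depth:
        return ColumnCall(pos, "no_call")
    retained = _retained_alleles(
        column.counts, params.vf_threshold, params.strand_balance_min
    )
    if len(retained) > 2:
        return ColumnCall(pos, "mixture_suspect", retained=tuple(retained))
    if not retained or (len(retained) == 1 and retained[0][0] == ref_base):
        return ColumnCall(pos, "reference", retained=tuple(retained))
    if len(retained) == 1:
        allele = retained[0][0]
        if allele == "-":
            v = Variant(position=pos, kind="deletion", ref_base=ref_base)
        else:
            v = Variant(position=pos, kind="substitution", ref_base=ref_base, call=allele)
        return ColumnCall(pos, "variant", variant=v, retained=tuple(retained))
    # two retained alleles
    alleles = [a for a, _ in retained]
    if "-" in alleles:
        # base/deletion mixture: report the dominant allele as fixed
        major = retained[0][0]
        if major == "-":
            v = Variant(position=pos, kind="deletion", ref_base=ref_base)
        elif major == ref_base:
            return ColumnCall(pos, "reference", retained=tuple(retained))
        else:
            v = Variant(position=pos, kind="substitution", ref_base=ref_base, call=major)
        return ColumnCall(pos, "variant", variant=v, retained=tuple(retained))
    pair = frozenset(alleles)
    code = PAIR_TO_IUPAC[pair]
    major, major_count = retained[0]
    v = Variant(
        position=pos,
        kind="substitution",
        ref_base=ref_base,
        call=code,
        major_base=major,
        major_frequency=major_count / depth,
    )
    return ColumnCall(pos, "php", variant=v, retained=tuple(retained))


@dataclass(frozen=True)
class CallMetrics:
    """Coverage and major-base-frequency summaries over the called range."""

    average_read_depth: float
    average_major_base_frequency: float
    average_major_base_frequency_excl_het: float
    variant_position_depth: float
    positions_below_min_depth: tuple[int, ...]


def _intervals_from_positions(positions: np.ndarray) -> tuple[tuple[int, int], ...]:
    if positions.size == 0:
        return ()
    breaks = np.where(np.diff(positions) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [positions.size - 1]))
    return tuple((int(positions[s]), int(positions[e])) for s, e in zip(starts, ends))


def call_profile(
    source: Pileup | Sequence[AlignedRead],
    reference: MitoReference,
    params: CallParams | None = None,
    sample_id: str = "sample",
    catalog: RegionCatalog = DEFAULT_CATALOG,
    vf_threshold: float | None = None,
) -> tuple[MitoProfile, CallMetrics]:
    """Call a haplotype profile and its metrics from reads or a pileup.

    Reads are trimmed, quality-masked and piled up first; a pileup is
    used as-is.  Indels inside the nine length-heteroplasmy regions are
    withheld (the length-heteroplasmy module resolves them from
    spanning-read motifs).  The interpretation range is the set of
    positions at or above the minimum depth.
    """
    params = params or CallParams()
    vf = params.vf_threshold if vf_threshold is None else vf_threshold
    if isinstance(source, Pileup):
        pile = source
    else:
        reads = [quality_mask(r, params) for r in trim_reads(source, params)]
        pile = build_pileup(reads, reference)

    depth = pile.depth
    covered = depth > 0
    if not covered.any():
        raise ValueError("no covered positions")

    callable_mask = depth >= params.min_depth
    below = np.nonzero(covered & ~callable_mask)[0] + 1
    range_intervals = _intervals_from_positions(np.nonzero(callable_mask)[0] + 1)
    if not range_intervals:
        raise ValueError("no positions at or above the minimum read depth")

    ref_arr = np.frombuffer(reference.sequence.encode(), dtype=np.uint8)
    ref_idx = np.full(reference.length, -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        ref_idx[ref_arr == ord(b)] = i

    totals = pile.counts.sum(axis=2)  # (L, 5)
    # candidate columns: any non-reference allele could reach the threshold
    nonref = totals.copy()
    rows = np.nonzero(ref_idx >= 0)[0]
    nonref[rows, ref_idx[rows]] = 0
    candidates = np.nonzero(
        callable_mask & (nonref.max(axis=1) >= np.maximum(vf * depth, 1))
    )[0]

    variants: list[Variant] = []
    suspect_sites: list[int] = []
    php_positions: set[int] = set()
    col_params = replace(params, vf_threshold=vf) if vf != params.vf_threshold else params
    for idx in candidates:
        pos = int(idx) + 1
        call = call_column(pile.column(pos), reference.base(pos), col_params)
        if call.status == "mixture_suspect":
            suspect_sites.append(pos)
            continue
        if call.variant is None:
            continue
        if call.variant.kind == "deletion" and catalog.in_length_het_region(pos):
            continue  # withheld for motif-based resolution
        if call.status == "php":
            php_positions.add(pos)
        variants.append(call.variant)

    # insertion calling: same depth/VF/strand rules, anchored at the column
    for pos, motifs in sorted(pile.insertions.items()):
        idx = reference.wrap(pos) - 1
        if not callable_mask[idx] or catalog.in_length_het_region(pos):
            continue
        col_depth = int(depth[idx])
        for motif, strands in sorted(motifs.items()):
            total = int(strands.sum())
            if total / col_depth < vf:
                continue
            fwd, rev = int(strands[0]), int(strands[1])
            if fwd / total < params.strand_balance_min or rev / total < params.strand_balance_min:
                continue
            variants.append(
                Variant(position=pos, kind="insertion", call=motif, insert_index=1)
            )

    in_het = np.zeros(reference.length, dtype=bool)
    for a, b in catalog.length_het_regions:
        in_het[a - 1 : b] = True

    with np.errstate(invalid="ignore", divide="ignore"):
        major_freq = np.where(depth > 0, totals.max(axis=1) / np.maximum(depth, 1), np.nan)
    sel = callable_mask
    excl = sel & ~in_het
    if php_positions:
        php_idx = np.array(sorted(php_positions)) - 1
        excl_php = np.zeros(reference.length, dtype=bool)
        excl_php[php_idx] = True
        excl = excl & ~excl_php
    var_positions = [v.position - 1 for v in variants]
    metrics = CallMetrics(
        average_read_depth=float(depth[sel].mean()),
        average_major_base_frequency=float(np.nanmean(major_freq[sel])),
        average_major_base_frequency_excl_het=float(np.nanmean(major_freq[excl]))
        if excl.any()
        else float("nan"),
        variant_position_depth=float(depth[var_positions].mean())
        if var_positions
        else float("nan"),
        positions_below_min_depth=tuple(int(p) for p in below),
    )
    profile = MitoProfile(
        sample_id=sample_id,
        variants=tuple(variants),
        range=range_intervals,
        mixture_suspect_sites=tuple(suspect_sites),
    )
    profile = normalize_indels(profile, reference)
    return profile, metrics


@dataclass(frozen=True)
class ScreenHit:
    """A sub-threshold variant reported by the NUMT screen."""

    position: int
    base: str
    frequency: float
    in_numt_interval: bool


def numt_screen(
    source: Pileup | Sequence[AlignedRead],
    reference: MitoReference,
    params: CallParams | None = None,
    catalog: RegionCatalog = DEFAULT_CATALOG,
) -> list[ScreenHit]:
    """Report alleles passing all filters at the 2% screen threshold but
    failing the 5% reporting threshold, annotated with whether they fall
    inside the NUMT-prone interval (nps 6636-11,428)."""
    params = params or CallParams()
    if isinstance(source, Pileup):
        pile = source
    else:
        reads = [quality_mask(r, params) for r in trim_reads(source, params)]
        pile = build_pileup(reads, reference)
    depth = pile.depth
    totals = pile.counts.sum(axis=2)
    callable_mask = depth >= params.min_depth
    lo, hi = NUMT_SCREEN_INTERVAL
    hits: list[ScreenHit] = []
    cand = np.nonzero(callable_mask & (totals.max(axis=1) < depth))[0]
    for idx in cand:
        pos = int(idx) + 1
        ref_base = reference.base(pos)
        counts = pile.counts[idx]
        col_depth = int(depth[idx])
        low = _retained_alleles(counts, params.numt_screen_vf, params.strand_balance_min)
        high = {a for a, _ in _retained_alleles(counts, params.vf_threshold, params.strand_balance_min)}
        for allele, total in low:
            if allele in high or allele == ref_base:
                continue
            hits.append(
                ScreenHit(
                    position=pos,
                    base=allele,
                    frequency=total / col_depth,
                    in_numt_interval=lo <= pos <= hi,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# I/O: SAM ingestion and the TSV pileup dialect

def read_sam(
    path: str | Path, reference: MitoReference, params: CallParams | None = None
) -> list[AlignedRead]:
    """Import mapped reads from SAM (single reference contig).

    Admission mirrors the alignment acceptance contract: clipped reads
    (length fraction < 1.0) are dropped, as are reads under the 0.8
    identity fraction when an NM tag is present.
    """
    import pysam

    params = params or CallParams()
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            cigar = aln.cigartuples or []
            if any(op in (4, 5) for op, _ in cigar):  # soft/hard clip
                continue
            if aln.has_tag("NM"):
                aligned = sum(n for op, n in cigar if op in (0, 7, 8))
                if aligned and 1 - aln.get_tag("NM") / aligned < params.min_identity:
                    continue
            seq = aln.query_sequence
            quals = aln.query_qualities
            if quals is None:
                quals = [40] * len(seq)
            bases: list[str] = []
            qual_out: list[int] = []
            insertions: dict[int, str] = {}
            qpos = 0
            rpos = aln.reference_start  # 0-based
            for op, n in cigar:
                if op in (0, 7, 8):  # M/=/X
                    bases.append(seq[qpos : qpos + n])
                    qual_out.extend(quals[qpos : qpos + n])
                    qpos += n
                    rpos += n
                elif op == 1:  # I: anchored on the previous reference base
                    insertions[rpos] = seq[qpos : qpos + n]
                    qpos += n
                elif op == 2:  # D
                    bases.append("-" * n)
                    qual_out.extend([40] * n)
                    rpos += n
                else:
                    raise ValueError(f"unsupported CIGAR op {op}")
            out.append(
                AlignedRead(
                    read_id=aln.query_name or "read",
                    start=aln.reference_start + 1,
                    strand="-" if aln.is_reverse else "+",
                    bases="".join(bases),
                    qualities=tuple(qual_out),
                    paired=aln.is_paired,
                    insertions=insertions,
                )
            )
    return out


_PILEUP_COLUMNS = [
    "position", "refbase",
    "A_f", "A_r", "C_f", "C_r", "G_f", "G_r", "T_f", "T_r", "del_f", "del_r",
    "ins_json",
]


def write_pileup_tsv(pile: Pileup, path: str | Path) -> None:
    """Write covered columns in the TSV pileup dialect."""
    depth = pile.depth
    rows = []
    for idx in np.nonzero(depth > 0)[0]:
        pos = int(idx) + 1
        c = pile.counts[idx]
        ins = {
            motif: [int(v[0]), int(v[1])]
            for motif, v in sorted(pile.insertions.get(pos, {}).items())
        }
        rows.append(
            [pos, pile.reference.base(pos)]
            + [int(c[i, s]) for i in range(5) for s in (0, 1)]
            + [json.dumps(ins) if ins else ""]
        )
    pd.DataFrame(rows, columns=_PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: str | Path, reference: MitoReference) -> Pileup:
    df = pd.read_csv(path, sep="\t", dtype={"ins_json": str}, keep_default_na=False)
    pile = Pileup(reference)
    for _, row in df.iterrows():
        idx = reference.wrap(int(row["position"])) - 1
        for i, allele in enumerate(_ALLELES):
            name = "del" if allele == "-" else allele
            pile.counts[idx, i, 0] = int(row[f"{name}_f"])
            pile.counts[idx, i, 1] = int(row[f"{name}_r"])
        if row["ins_json"]:
            for motif, (f, r) in json.loads(row["ins_json"]).items():
                pile.add_insertion(idx + 1, motif, 0, int(f))
                pile.add_insertion(idx + 1, motif, 1, int(r))
    return pile
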