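"""Seeded synthetic mitogenome populations, read stacks and pileups.

Everything the pipeline consumes can be generated here with a declared
truth: a circular rCRS-like reference whose nine length-heteroplasmy
regions carry homopolymer/repeat content (the rest of the sequence is
seeded-random — this is a synthetic stand-in, not the real rCRS);
populations of haplotypes with a declared haplotype-class partition or
a star-phylogeny mutation process; point heteroplasmies with a
hotspot-weighted position spectrum, 95% transitions, and a folded
variant-frequency spectrum skewed low; per-region length-heteroplasmy
motif mixtures; optional NUMT spike-ins at 2-3% confined to the
NUMT-prone interval; and optional two-donor mixtures.

Defaults reproduce the study conditions the pipeline was validated
under: 28% of individuals carry a PHP (80.8% / 16.4% / 2.7% carrying
1 / 2 / 3), 32% of folded VFs fall in 0.05-0.10 and 47.5% below 0.15,
length heteroplasmy rates of 86.9% (HVII), 19.8% (HVI) and 7.9%
(HVIII), mean depth 1000x and ~0.5% background noise.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .calling import AlignedRead, Pileup
from .lengthhet import _edit_script, motif_variants
from .nomenclature import MitoProfile, Variant, php_variant
from .reference import (
    DEFAULT_CATALOG,
    LENGTH_HET_REGIONS,
    MitoReference,
    NUMT_SCREEN_INTERVAL,
    PLACEHOLDER_POSITION,
    RCRS_LENGTH,
)

DEFAULT_REFERENCE_SEED = 1290

#: PHP hotspot positions (control region) given extra sampling weight.
PHP_HOTSPOTS = (146, 152, 204, 16093)

_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Designed content of the length-heteroplasmy regions in the synthetic
#: reference (np -> base string starting at the region's first position).
_DESIGNED_SEGMENTS: dict[int, str] = {
    303: "CCCCCCCTCCCCC",      # 303-315: 7C + T + 5C
    452: "TTAACCCCCCCC",       # 452-463: C-tract ending at 463
    513: "ACACACACACAC",       # 513-524: (AC) x 6
    565: "ACCCCCCCC",          # 565-573: C-tract ending at 573
    956: "CCCCCTAGCAT",        # 956-966: C-tract ending at 960
    5891: "CCCCCCCCC",         # 5891-5899: C-tract ending at 5899
    8270: "CCCCCCCTACCCCCCCTAGA",  # 8270-8289: runs ending 8276/8285, T at 8277
    12418: "AAAAAAAA",         # 12418-12425: poly-A ending at 12425
    16180: "AAACCCCCTCCCCC",   # 16180-16193: C-tract ending at 16193
}


@functools.lru_cache(maxsize=4)
def generate_reference(seed: int = DEFAULT_REFERENCE_SEED) -> MitoReference:
    """Deterministic synthetic rCRS-like circular reference (16,569 bp).

    Length-heteroplasmy regions carry designed homopolymer/repeat
    motifs; each region is flanked by anchor bases that cannot extend
    its terminal run; np 3107 is 'N'; all other positions are
    seeded-random.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=RCRS_LENGTH)
    for start, segment in _DESIGNED_SEGMENTS.items():
        seq[start - 1 : start - 1 + len(segment)] = list(segment)
        # anchors: must differ from the adjacent run base on each side
        left, right = segment[0], segment[-1]
        if start >= 2:
            seq[start - 2] = "G" if left != "G" else "A"
        end = start + len(segment) - 1
        if end < RCRS_LENGTH:
            seq[end] = "G" if right != "G" else "A"
    seq[PLACEHOLDER_POSITION - 1] = "N"
    return MitoReference(name=f"synthetic-rCRS-{seed}", sequence="".join(seq))


@dataclass(frozen=True)
class NumtConfig:
    """NUMT spike-in: extra variants confined to the NUMT-prone interval."""

    fraction: float = 0.025
    n_diff_sites: int = 5


@dataclass(frozen=True)
class MixtureConfig:
    """Second donor added at ``minor_fraction`` differing at ``n_diff_sites``."""

    minor_fraction: float = 0.10
    n_diff_sites: int = 12


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for population and read simulation."""

    seed: int = 0
    n_individuals: int = 100
    haplotype_partition: tuple[int, ...] | None = None
    n_variants_mean: float = 25.0
    ts_tv_ratio: float = 20.0
    php_individual_rate: float = 0.28
    php_count_distribution: tuple[tuple[int, float], ...] = (
        (1, 0.808), (2, 0.164), (3, 0.027)
    )
    #: folded-VF spectrum: (low, high, mass) bins over [0.05, 0.5]
    php_vf_bins: tuple[tuple[float, float, float], ...] = (
        (0.05, 0.10, 0.320),
        (0.10, 0.15, 0.155),
        (0.15, 0.50, 0.525),
    )
    #: probability the variant (non-reference) base is the dominant one
    php_variant_major_rate: float = 0.22
    length_het_region_rates: tuple[tuple[tuple[int, int], float], ...] = (
        ((303, 315), 0.869),
        ((16180, 16193), 0.198),
        ((565, 573), 0.079),
        ((513, 524), 0.041),
        ((12418, 12425), 0.044),
        ((452, 463), 0.010),
        ((956, 966), 0.010),
        ((5891, 5899), 0.010),
        ((8270, 8289), 0.005),
    )
    #: probability a length-heteroplasmic region's major motif is the
    #: non-reference length (yielding an indel in the profile)
    length_het_major_shift: float = 0.30
    length_het_major_fraction_range: tuple[float, float] = (0.55, 0.80)
    depth_mean: float = 1000.0
    base_error_rate: float = 0.005
    strand_fraction: float = 0.5
    read_length: int = 150
    paired: bool = False
    numt: NumtConfig | None = None
    mixture: MixtureConfig | None = None


@dataclass(frozen=True)
class SampleTruth:
    """Declared truth for one simulated individual."""

    profile: MitoProfile
    substitutions: tuple[tuple[int, str], ...]  # fixed non-reference bases
    phps: tuple[tuple[int, str, str, float], ...]  # (pos, major, minor, minor_vf)
    motif_mixtures: tuple[tuple[tuple[int, int], tuple[tuple[str, float], ...]], ...]
    numt_sites: tuple[tuple[int, str, float], ...] = ()


@dataclass(frozen=True)
class TruthSet:
    """Per-sample truths, emitted before any reads are generated."""

    samples: tuple[SampleTruth, ...]

    def profiles(self) -> list[MitoProfile]:
        return [s.profile for s in self.samples]

    def diagnostic_sites(self, sample_id: str) -> set[int]:
        """Haplotype-defining substitution positions for one sample."""
        for s in self.samples:
            if s.profile.sample_id == sample_id:
                return {p for p, _ in s.substitutions}
        raise KeyError(sample_id)


def _candidate_positions(reference: MitoReference) -> np.ndarray:
    """Positions eligible for haplotype substitutions: outside the
    length-heteroplasmy regions, hotspots, and the placeholder."""
    excluded = {PLACEHOLDER_POSITION, *PHP_HOTSPOTS}
    for a, b in LENGTH_HET_REGIONS:
        excluded.update(range(a - 1, b + 2))  # region plus anchors
    return np.array(
        [p for p in range(1, reference.length + 1) if p not in excluded]
    )


def _draw_substitution(pos: int, reference: MitoReference, rng) -> tuple[int, str]:
    ref = reference.base(pos)
    if rng.random() < 20.0 / 21.0:  # ts:tv default 20
        return pos, _TRANSITION_PARTNER[ref]
    others = [b for b in "ACGT" if b != ref and b != _TRANSITION_PARTNER[ref]]
    return pos, others[rng.integers(len(others))]


def simulate_population(
    config: SimConfig, reference: MitoReference | None = None
) -> tuple[list[MitoProfile], TruthSet]:
    """Generate a population of haplotypes with declared truth.

    With ``haplotype_partition`` the haplotype-class sizes are imposed
    exactly (distinct classes get distinct variant sets); otherwise each
    individual is an independent star-phylogeny lineage with a Poisson
    number of substitutions.  PHPs are layered per individual with
    hotspot-weighted positions, ~95% transitions, and the configured
    folded-VF spectrum.  Length-heteroplasmy motif mixtures are drawn
    per region at the configured rates.
    """
    reference = reference or generate_reference()
    rng = np.random.default_rng(config.seed)
    candidates = _candidate_positions(reference)

    if config.haplotype_partition is not None:
        partition = tuple(config.haplotype_partition)
        if sum(partition) != config.n_individuals:
            raise ValueError(
                f"partition sums to {sum(partition)}, expected {config.n_individuals}"
            )
    else:
        partition = tuple([1] * config.n_individuals)

    # distinct variant sets per haplotype class
    class_subs: list[tuple[tuple[int, str], ...]] = []
    seen_keys: set[tuple] = set()
    for _ in partition:
        while True:
            k = max(1, int(rng.poisson(config.n_variants_mean)))
            pos = rng.choice(candidates, size=min(k, candidates.size), replace=False)
            subs = tuple(
                sorted(_draw_substitution(int(p), reference, rng) for p in pos)
            )
            if subs not in seen_keys:
                seen_keys.add(subs)
                class_subs.append(subs)
                break

    # PHP machinery
    php_counts, php_probs = zip(*config.php_count_distribution)
    php_probs = np.array(php_probs) / sum(php_probs)
    hotspot_weight = 200.0
    php_pool = candidates
    weights = np.ones(php_pool.size + len(PHP_HOTSPOTS))
    php_pool = np.concatenate([php_pool, np.array(PHP_HOTSPOTS)])
    weights[-len(PHP_HOTSPOTS):] = hotspot_weight
    weights = weights / weights.sum()

    bins = config.php_vf_bins
    bin_mass = np.array([m for _, _, m in bins])
    bin_mass = bin_mass / bin_mass.sum()

    region_rates = dict(config.length_het_region_rates)
    lo_frac, hi_frac = config.length_het_major_fraction_range

    samples: list[SampleTruth] = []
    sample_idx = 0
    for class_i, size in enumerate(partition):
        for _ in range(size):
            sample_id = f"S{sample_idx:04d}"
            sample_idx += 1
            subs = class_subs[class_i]
            sub_positions = {p for p, _ in subs}
            variants: list[Variant] = [
                Variant(
                    position=p,
                    kind="substitution",
                    ref_base=reference.base(p),
                    call=b,
                )
                for p, b in subs
            ]

            phps: list[tuple[int, str, str, float]] = []
            if rng.random() < config.php_individual_rate:
                n_php = int(php_counts[rng.choice(len(php_counts), p=php_probs)])
                taken: set[int] = set()
                while len(taken) < n_php:
                    pos = int(php_pool[rng.choice(php_pool.size, p=weights)])
                    if pos in taken or pos in sub_positions:
                        continue
                    taken.add(pos)
                    ref = reference.base(pos)
                    _, alt = _draw_substitution(pos, reference, rng)
                    b = int(rng.choice(len(bins), p=bin_mass))
                    lo, hi, _ = bins[b]
                    folded = float(rng.uniform(lo, hi))
                    if rng.random() < config.php_variant_major_rate:
                        major, minor, minor_vf = alt, ref, folded
                    else:
                        major, minor, minor_vf = ref, alt, folded
                    phps.append((pos, major, minor, minor_vf))
                    variants.append(
                        php_variant(
                            position=pos,
                            ref_base=ref,
                            bases=(major, minor),
                            major_base=major,
                            major_frequency=1 - minor_vf,
                        )
                    )

            mixtures: list[tuple[tuple[int, int], tuple[tuple[str, float], ...]]] = []
            het_regions: list[tuple[int, int]] = []
            for region, rate in sorted(region_rates.items()):
                if rng.random() >= rate:
                    continue
                ref_motif = reference.fetch(*region)
                plus, minus = _shifted_motifs(ref_motif)
                major_frac = float(rng.uniform(lo_frac, hi_frac))
                if rng.random() < config.length_het_major_shift:
                    major_motif, minor_motif = plus, ref_motif
                else:
                    major_motif, minor_motif = ref_motif, (
                        plus if rng.random() < 0.7 else minus
                    )
                mixtures.append(
                    (region, ((major_motif, major_frac), (minor_motif, 1 - major_frac)))
                )
                het_regions.append(region)
                for v in motif_variants(major_motif, region, reference):
                    variants.append(v)

            numt_sites: list[tuple[int, str, float]] = []
            if config.numt is not None:
                lo, hi = NUMT_SCREEN_INTERVAL
                pool = [
                    p for p in range(lo, hi + 1)
                    if p not in sub_positions and reference.base(p) in "ACGT"
                ]
                for p in rng.choice(len(pool), config.numt.n_diff_sites, replace=False):
                    pos = pool[int(p)]
                    numt_sites.append(
                        (pos, _TRANSITION_PARTNER[reference.base(pos)],
                         config.numt.fraction)
                    )

            profile = MitoProfile(
                sample_id=sample_id,
                variants=tuple(variants),
                population=None,
                length_het_regions=tuple(het_regions),
            )
            samples.append(
                SampleTruth(
                    profile=profile,
                    substitutions=subs,
                    phps=tuple(sorted(phps)),
                    motif_mixtures=tuple(mixtures),
                    numt_sites=tuple(sorted(numt_sites)),
                )
            )

    truth = TruthSet(samples=tuple(samples))
    return truth.profiles(), truth


def _shifted_motifs(ref_motif: str) -> tuple[str, str]:
    """Motifs one repeat unit longer and shorter than the reference motif.

    The unit is the longest single-base run's base, or the dinucleotide
    for a perfect two-base repeat (e.g. the AC tract).
    """
    n = len(ref_motif)
    if n % 2 == 0 and ref_motif == ref_motif[:2] * (n // 2) and ref_motif[0] != ref_motif[1]:
        unit = ref_motif[:2]
        return ref_motif + unit, ref_motif[:-2]
    best_base, best_len, best_end = ref_motif[0], 0, 0
    i = 0
    while i < n:
        j = i
        while j < n and ref_motif[j] == ref_motif[i]:
            j += 1
        if j - i > best_len:
            best_base, best_len, best_end = ref_motif[i], j - i, j
        i = j
    plus = ref_motif[:best_end] + best_base + ref_motif[best_end:]
    minus = ref_motif[: best_end - 1] + ref_motif[best_end:]
    return plus, minus


def mixture_pair(
    config: SimConfig, reference: MitoReference | None = None
) -> tuple[SampleTruth, SampleTruth]:
    """A two-donor mixture scenario: the minor donor differs from the
    major donor at exactly ``config.mixture.n_diff_sites`` positions.

    Feed both truths to :func:`simulate_pileup` with
    ``minor_fraction=config.mixture.minor_fraction``.
    """
    reference = reference or generate_reference()
    mix = config.mixture or MixtureConfig()
    base_cfg = replace(config, n_individuals=1, mixture=None)
    _, truth = simulate_population(base_cfg, reference)
    a = truth.samples[0]
    rng = np.random.default_rng(config.seed + 1)
    taken = {p for p, _ in a.substitutions}
    pool = _candidate_positions(reference)
    pool = pool[~np.isin(pool, sorted(taken))]
    picks = rng.choice(pool.size, mix.n_diff_sites, replace=False)
    extra = tuple(
        sorted(_draw_substitution(int(pool[i]), reference, rng) for i in picks)
    )
    subs_b = tuple(sorted(a.substitutions + extra))
    profile_b = MitoProfile(
        sample_id=a.profile.sample_id + "_minor",
        variants=tuple(
            Variant(position=p, kind="substitution",
                    ref_base=reference.base(p), call=b)
            for p, b in subs_b
        ),
    )
    b = SampleTruth(
        profile=profile_b, substitutions=subs_b, phps=(), motif_mixtures=()
    )
    return a, b


# ---------------------------------------------------------------------------
# Pileup-level simulation (fast path)

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def simulate_pileup(
    truth: SampleTruth,
    reference: MitoReference,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    second_truth: SampleTruth | None = None,
    minor_fraction: float = 0.0,
    numt: NumtConfig | None = None,
    numt_sites: Sequence[tuple[int, str, float]] = (),
) -> Pileup:
    """Simulate per-position per-strand counts directly.

    Depth is Poisson(depth_mean); each read base errs independently at
    the base-error rate; PHP positions emit the minor base at its truth
    VF; a second donor's alleles are blended at ``minor_fraction``;
    NUMT sites receive their configured low-level allele.  Length-
    heteroplasmy motif mixtures are not represented at pileup level
    (those regions are resolved from reads).
    """
    rng = rng or np.random.default_rng(config.seed)
    L = reference.length
    e = config.base_error_rate

    def base_array(t: SampleTruth) -> np.ndarray:
        arr = np.array(
            [_BASE_IDX.get(b, -1) for b in reference.sequence], dtype=np.int64
        )
        for p, b in t.substitutions:
            arr[p - 1] = _BASE_IDX[b]
        return arr

    major = base_array(truth)
    # per-position probability of each base (4, L)
    probs = np.full((4, L), 0.0)
    valid = major >= 0
    probs[:, valid] = e / 3
    probs[major[valid], np.nonzero(valid)[0]] = 1 - e
    for pos, major_b, minor_b, minor_vf in truth.phps:
        i = pos - 1
        probs[:, i] = e / 3
        probs[_BASE_IDX[major_b], i] = (1 - minor_vf) * (1 - e) + minor_vf * e / 3
        probs[_BASE_IDX[minor_b], i] = minor_vf * (1 - e) + (1 - minor_vf) * e / 3

    if second_truth is not None and minor_fraction > 0:
        other = base_array(second_truth)
        probs2 = np.full((4, L), 0.0)
        valid2 = other >= 0
        probs2[:, valid2] = e / 3
        probs2[other[valid2], np.nonzero(valid2)[0]] = 1 - e
        probs = (1 - minor_fraction) * probs + minor_fraction * probs2

    for pos, base, fraction in list(numt_sites) + list(truth.numt_sites):
        i = pos - 1
        probs[:, i] = probs[:, i] * (1 - fraction)
        probs[_BASE_IDX[base], i] += fraction

    # normalise (N positions have zero mass -> no coverage counted there)
    col = probs.sum(axis=0)
    covered = col > 0
    probs[:, covered] /= col[covered]

    depth = rng.poisson(config.depth_mean, size=L)
    depth[~covered] = 0

    counts = np.zeros((L, 5, 2), dtype=np.int64)
    remaining = depth.copy()
    cum = 0.0
    acc = np.zeros(L)
    for b in range(4):
        p = probs[b]
        denom = 1.0 - acc
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(denom > 0, np.clip(p / denom, 0, 1), 0.0)
        n_b = rng.binomial(remaining, q)
        fwd = rng.binomial(n_b, config.strand_fraction)
        counts[:, b, 0] = fwd
        counts[:, b, 1] = n_b - fwd
        remaining -= n_b
        acc += p

    pile = Pileup(reference)
    pile.counts = counts
    return pile


# ---------------------------------------------------------------------------
# Read-level simulation

def _motif_overlay(
    motif: str, region: tuple[int, int], reference: MitoReference
) -> tuple[str, dict[int, str]]:
    """Region bases ('-' for deleted) and insertion map realising a motif."""
    start, end = region
    ref_seg = reference.fetch(start, end)
    bases = list(ref_seg)
    ins: dict[int, str] = {}
    for op, off, b in _edit_script(ref_seg, motif):
        if op == "sub":
            bases[off] = b
        elif op == "del":
            bases[off] = "-"
        else:
            anchor = start + off  # off == -1 -> anchor before the region
            ins[anchor] = ins.get(anchor, "") + b
    return "".join(bases), ins


def simulate_reads(
    truth: SampleTruth,
    reference: MitoReference,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    interval: tuple[int, int] | None = None,
) -> list[AlignedRead]:
    """Simulate pre-aligned reads over ``interval`` (default whole genome).

    Read count is calibrated so post-trim depth matches ``depth_mean``.
    A read fully spanning a length-heteroplasmy region (with anchors)
    draws a motif from the sample's declared mixture; PHP positions
    emit the minor base at its VF; sequencing errors are i.i.d.
    """
    rng = rng or np.random.default_rng(config.seed)
    if interval is None:
        interval = (1, reference.length)
    start, end = interval
    span = (end - start) % reference.length + 1
    trim = 20 + (20 if config.paired else 0)
    eff_len = config.read_length - trim
    if eff_len < 40:
        raise ValueError("read_length too short after trimming")
    n_reads = int(np.ceil(config.depth_mean * span / eff_len))

    base_arr = np.array(list(reference.sequence))
    for p, b in truth.substitutions:
        base_arr[p - 1] = b
    php_map = {pos: (major, minor, vf) for pos, major, minor, vf in truth.phps}

    overlays: dict[tuple[int, int], list[tuple[float, str, dict[int, str]]]] = {}
    for region, mixture in truth.motif_mixtures:
        overlays[region] = [
            (frac, *_motif_overlay(motif, region, reference))
            for motif, frac in mixture
        ]

    reads: list[AlignedRead] = []
    L = reference.length
    starts = (start - 1 + rng.integers(0, span, size=n_reads)) % L + 1
    strands = rng.random(n_reads) < config.strand_fraction
    for ridx in range(n_reads):
        rstart = int(starts[ridx])
        positions = [(rstart - 1 + k) % L + 1 for k in range(config.read_length)]
        bases = [base_arr[p - 1] for p in positions]
        insertions: dict[int, str] = {}
        first, last = positions[0], positions[-1]
        # length-het regions fully spanned by this read (no wrap handling
        # needed: regions sit far from the origin)
        for region, opts in overlays.items():
            a, b = region
            if first <= a - 1 and last >= b + 1 and first <= last:
                u = rng.random()
                accum = 0.0
                chosen = opts[-1]
                for frac, seg, ins in opts:
                    accum += frac
                    if u < accum:
                        chosen = (frac, seg, ins)
                        break
                _, seg, ins = chosen
                off = a - first
                for k, ch in enumerate(seg):
                    bases[off + k] = ch
                for anchor, motif in ins.items():
                    insertions[anchor] = motif
        for p, (major, minor, vf) in php_map.items():
            if first <= p <= last:
                bases[p - first] = minor if rng.random() < vf else major
        if config.base_error_rate > 0:
            errs = np.nonzero(rng.random(config.read_length) < config.base_error_rate)[0]
            for k in errs:
                if bases[k] in "ACGT":
                    alts = [b for b in "ACGT" if b != bases[k]]
                    bases[k] = alts[rng.integers(3)]
        reads.append(
            AlignedRead(
                read_id=f"{truth.profile.sample_id}_r{ridx}",
                start=rstart,
                strand="+" if strands[ridx] else "-",
                bases="".join(bases),
                qualities=tuple([40] * config.read_length),
                paired=config.paired,
                insertions=insertions,
            )
        )
    return reads


def write_sam(
    reads: Sequence[AlignedRead], reference: MitoReference, path: str | Path
) -> None:
    """Write reads as plain-text SAM against the single reference contig.

    Reads wrapping the origin are split into two records.
    """
    L = reference.length
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:{reference.name}\tLN:{L}",
    ]
    for read in reads:
        pieces = [(read, read.start, read.bases, read.qualities, read.insertions)]
        if read.start + len(read.bases) - 1 > L:
            cut = L - read.start + 1
            pieces = [
                (read, read.start, read.bases[:cut], read.qualities[:cut],
                 {p: m for p, m in read.insertions.items() if p <= L}),
                (read, 1, read.bases[cut:], read.qualities[cut:],
                 {((p - 1) % L + 1): m for p, m in read.insertions.items() if p > L}),
            ]
        for part_i, (r, start, bases, quals, ins) in enumerate(pieces):
            if not bases:
                continue
            name = r.read_id if len(pieces) == 1 else f"{r.read_id}_p{part_i}"
            flag = 16 if r.strand == "-" else 0
            if r.paired:
                flag |= 1
            cigar_parts: list[str] = []
            seq_parts: list[str] = []
            qual_parts: list[str] = []
            run_op, run_len = "", 0

            def flush():
                nonlocal run_op, run_len
                if run_len:
                    cigar_parts.append(f"{run_len}{run_op}")
                run_op, run_len = "", 0

            for k, ch in enumerate(bases):
                pos = start + k
                op = "D" if ch == "-" else "M"
                if op != run_op:
                    flush()
                    run_op = op
                run_len += 1
                if op == "M":
                    seq_parts.append(ch)
                    qual_parts.append(chr(quals[k] + 33))
                motif = ins.get(pos)
                if motif:
                    flush()
                    cigar_parts.append(f"{len(motif)}I")
                    seq_parts.append(motif)
                    qual_parts.append("I" * len(motif))  # Q40
            flush()
            lines.append(
                "\t".join(
                    [
                        name, str(flag), reference.name, str(start), "60",
                        "".join(cigar_parts), "*", "0", "0",
                        "".join(seq_parts), "".join(qual_parts),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Partition-constrained dataset fixtures

def make_partition_dataset(
    name: str,
    n: int,
    partition: Sequence[int],
    reference: MitoReference | None = None,
) -> "PopulationDataset":
    """A dataset whose haplotype keys realise exactly the given partition.

    Class ``i`` carries a single distinguishing substitution at a fixed
    eligible position, so keying under default comparison options
    yields the requested class sizes.
    """
    from .popstats import PopulationDataset

    if sum(partition) != n:
        raise ValueError(f"partition sums to {sum(partition)}, expected n={n}")
    reference = reference or generate_reference()
    pool = _candidate_positions(reference)
    profiles: list[MitoProfile] = []
    idx = 0
    for class_i, size in enumerate(partition):
        pos = int(pool[1000 + class_i])  # fixed, deterministic, eligible
        ref = reference.base(pos)
        variant = Variant(
            position=pos,
            kind="substitution",
            ref_base=ref,
            call=_TRANSITION_PARTNER[ref],
        )
        for _ in range(size):
            profiles.append(
                MitoProfile(
                    sample_id=f"{name}{idx:04d}",
                    variants=(variant,),
                    population=name,
                )
            )
            idx += 1
    return PopulationDataset(name=name, profiles=tuple(profiles))
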