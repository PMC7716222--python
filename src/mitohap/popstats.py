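"""Lineage-marker population statistics for mitogenome haplotypes.

Haplotypes are compared as canonical keys built from their variant
lists under forensic comparison rules: insertions at ten common
length-heteroplasmy positions are ignored, and point heteroplasmies can
be counted as differences or ignored.  From the haplotype-class
partition {k_i} of a dataset of n samples:

* observed RMP  = sum p_i^2             (p_i = k_i / n)
* empirical RMP = sum k_i (k_i - 1) / (n (n - 1))
* diversity H   = n (1 - sum p_i^2) / (n - 1)

Genetic distance between datasets uses pairwise PhiST: an AMOVA
decomposition of squared Kimura 2-parameter distances into among- and
within-population components, with significance from a permutation test.
The PhiST matrix feeds a principal coordinate analysis (classical
metric MDS via double centering).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .nomenclature import (
    IUPAC_PAIRS,
    MitoProfile,
    Variant,
    format_variant,
    profile_to_sequence,
)
from .reference import (
    DEFAULT_CATALOG,
    IGNORED_INSERTION_POSITIONS,
    MitoReference,
    RegionCatalog,
)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (display convention for reported statistics)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Haplotype keying and counting

RangeName = Literal["whole_mitogenome", "control_region", "custom"]


@dataclass(frozen=True)
class ComparisonOptions:
    """Rules for pairwise haplotype comparison and keying."""

    range: RangeName = "whole_mitogenome"
    custom_intervals: tuple[tuple[int, int], ...] = ()
    php_mode: Literal["differences", "ignored"] = "differences"
    ignored_insertion_positions: frozenset[int] = IGNORED_INSERTION_POSITIONS
    catalog: RegionCatalog = field(default=DEFAULT_CATALOG)

    def intervals(self) -> tuple[tuple[int, int], ...]:
        if self.range == "custom":
            if not self.custom_intervals:
                raise ValueError("custom range requires custom_intervals")
            return self.custom_intervals
        return self.catalog.intervals(self.range)

    def contains(self, position: int) -> bool:
        return any(
            (a <= position <= b) if a <= b else (position >= a or position <= b)
            for a, b in self.intervals()
        )


def haplotype_key(
    profile: MitoProfile, options: ComparisonOptions | None = None
) -> str:
    """Canonical comparison key for a haplotype.

    Variants outside the comparison range are dropped, as are
    insertions at the ignored common length-heteroplasmy positions;
    ``php_mode='ignored'`` additionally drops PHP variants (so a sample
    with a PHP merges with the same haplotype lacking it).
    """
    options = options or ComparisonOptions()
    kept: list[Variant] = []
    for v in profile.variants:
        if not options.contains(v.position):
            continue
        if v.kind == "insertion" and v.position in options.ignored_insertion_positions:
            continue
        if v.is_php and options.php_mode == "ignored":
            continue
        kept.append(v)
    return " ".join(format_variant(v) for v in sorted(kept, key=Variant.sort_key))


@dataclass(frozen=True)
class PopulationDataset:
    """A named set of finalized profiles (one metapopulation sample set)."""

    name: str
    profiles: tuple[MitoProfile, ...]

    def __len__(self) -> int:
        return len(self.profiles)


@dataclass(frozen=True)
class HaplotypeCounts:
    """Haplotype-class partition of a dataset: n samples in classes k_i."""

    n: int
    groups: tuple[int, ...]  # class sizes, descending

    def __post_init__(self) -> None:
        if sum(self.groups) != self.n:
            raise ValueError("class sizes must sum to n")
        object.__setattr__(self, "groups", tuple(sorted(self.groups, reverse=True)))

    @property
    def distinct(self) -> int:
        return len(self.groups)

    @property
    def unique(self) -> int:
        return sum(1 for k in self.groups if k == 1)


def tabulate(
    dataset: PopulationDataset | Sequence[MitoProfile],
    options: ComparisonOptions | None = None,
) -> HaplotypeCounts:
    """Group a dataset by haplotype key and return the class partition."""
    profiles = dataset.profiles if isinstance(dataset, PopulationDataset) else dataset
    if len(profiles) < 2:
        raise ValueError("tabulate requires at least two samples")
    counts: dict[str, int] = {}
    for p in profiles:
        key = haplotype_key(p, options)
        counts[key] = counts.get(key, 0) + 1
    return HaplotypeCounts(n=len(profiles), groups=tuple(counts.values()))


def observed_rmp(counts: HaplotypeCounts, exact: bool = False) -> float | Fraction:
    """Probability two individuals drawn with replacement share a haplotype."""
    s = Fraction(sum(k * k for k in counts.groups), counts.n**2)
    return s if exact else float(s)


def empirical_rmp(counts: HaplotypeCounts, exact: bool = False) -> float | Fraction:
    """Fraction of matching pairs among all ordered pairs of distinct samples."""
    if counts.n < 2:
        raise ValueError("empirical RMP requires n >= 2")
    s = Fraction(
        sum(k * (k - 1) for k in counts.groups), counts.n * (counts.n - 1)
    )
    return s if exact else float(s)


def haplotype_diversity(counts: HaplotypeCounts, exact: bool = False) -> float | Fraction:
    """Unbiased probability that two sampled haplotypes differ."""
    if counts.n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    obs = observed_rmp(counts, exact=True)
    h = Fraction(counts.n, counts.n - 1) * (1 - obs)
    return h if exact else float(h)


def summary_statistics(counts: HaplotypeCounts) -> dict[str, float]:
    """The reported display values: RMPs as percent (2 d.p.), diversity 4 d.p."""
    return {
        "n": counts.n,
        "total_haplotypes": counts.distinct,
        "unique_haplotypes": counts.unique,
        "observed_rmp_pct": round_half_up(100 * float(observed_rmp(counts)), 2),
        "empirical_rmp_pct": round_half_up(100 * float(empirical_rmp(counts)), 2),
        "haplotype_diversity": round_half_up(float(haplotype_diversity(counts)), 4),
    }


def matching_partitions(
    n: int,
    distinct: int,
    unique: int,
    observed_pct: float | None = None,
    empirical_pct: float | None = None,
    diversity: float | None = None,
) -> list[tuple[int, ...]]:
    """Exhaustively enumerate haplotype-class partitions consistent with
    printed summary counts and statistics.

    Partitions have ``unique`` singleton classes plus ``distinct - unique``
    classes of size >= 2 summing to ``n - unique``; a partition is kept if
    its display-rounded statistics equal every supplied printed value.
    """
    rest, parts = n - unique, distinct - unique
    found: list[tuple[int, ...]] = []

    def gen(remaining: int, nparts: int, minimum: int, acc: list[int]):
        if nparts == 0:
            if remaining == 0:
                candidate = tuple(acc + [1] * unique)
                counts = HaplotypeCounts(n=n, groups=candidate)
                stats = summary_statistics(counts)
                if observed_pct is not None and stats["observed_rmp_pct"] != observed_pct:
                    return
                if empirical_pct is not None and stats["empirical_rmp_pct"] != empirical_pct:
                    return
                if diversity is not None and stats["haplotype_diversity"] != diversity:
                    return
                found.append(tuple(sorted(candidate, reverse=True)))
            return
        for k in range(minimum, remaining - 2 * (nparts - 1) + 1):
            gen(remaining - k, nparts - 1, k, acc + [k])

    if parts == 0:
        gen(rest, 0, 2, [])
    else:
        gen(rest, parts, 2, [])
    return found


# ---------------------------------------------------------------------------
# Kimura 2-parameter distance

_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


class SaturationError(ArithmeticError):
    """K2P distance undefined: divergence beyond the model's reach."""


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura 2-parameter distance between equal-length base strings.

    Sites where either sequence is not a plain base (N, ambiguity
    codes) are skipped.  With transition fraction P and transversion
    fraction Q over compared sites, d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    sites = transitions = transversions = 0
    for x, y in zip(seq_a, seq_b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if frozenset((x, y)) in _TRANSITION_PAIRS:
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no comparable sites")
    P, Q = transitions / sites, transversions / sites
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated: P={P:.4f}, Q={Q:.4f}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
# transition iff both purines or both pyrimidines: A,G -> 0 ; C,T -> 1
_PURINE = {"A": 0, "G": 0, "C": 1, "T": 1}


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(arr.size, -1, dtype=np.int8)
    kind = np.zeros(arr.size, dtype=np.int8)
    for b, c in _BASE_CODE.items():
        m = arr == ord(b)
        code[m] = c
        kind[m] = _PURINE[b]
    return code, kind, code >= 0


def substitution_sequence(
    profile: MitoProfile,
    reference: MitoReference,
    interval: tuple[int, int] | None = None,
) -> str:
    """Sample sequence with substitutions only (indels excluded so all
    sequences stay reference-length), PHPs resolved to the major base
    when known and left as ambiguity codes (excluded sites) otherwise."""
    subs = []
    for v in profile.variants:
        if v.kind != "substitution":
            continue
        if v.is_php and v.major_base is None and v.major_frequency is None:
            continue  # unknown major molecule: leave the ambiguity code
        subs.append(v)
    stripped = MitoProfile(
        sample_id=profile.sample_id, variants=tuple(subs), range=profile.range
    )
    resolution = "major"
    try:
        return profile_to_sequence(stripped, reference, interval, resolution)
    except ValueError:
        return profile_to_sequence(stripped, reference, interval, "ambiguity")


def k2p_matrix(
    profiles: Sequence[MitoProfile],
    reference: MitoReference,
    options: ComparisonOptions | None = None,
) -> np.ndarray:
    """Pairwise K2P distances over the comparison range (pairwise deletion
    of non-ACGT sites)."""
    options = options or ComparisonOptions()
    seqs = []
    for p in profiles:
        parts = [
            substitution_sequence(p, reference, iv) for iv in options.intervals()
        ]
        seqs.append("".join(parts))
    enc = [_encode(s) for s in seqs]
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        ci, ki, vi = enc[i]
        for j in range(i + 1, n):
            cj, kj, vj = enc[j]
            valid = vi & vj
            sites = int(valid.sum())
            if sites == 0:
                raise ValueError("no comparable sites between profiles")
            diff = valid & (ci != cj)
            ts = int((diff & (ki == kj)).sum())
            tv = int(diff.sum()) - ts
            P, Q = ts / sites, tv / sites
            w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
            if w1 <= 0 or w2 <= 0:
                raise SaturationError(
                    f"saturated pair ({profiles[i].sample_id}, {profiles[j].sample_id})"
                )
            D[i, j] = D[j, i] = -0.5 * math.log(w1 * math.sqrt(w2))
    return D


# ---------------------------------------------------------------------------
# PhiST (AMOVA on squared distances) with permutation test

@dataclass(frozen=True)
class FstResult:
    populations: tuple[str, str]
    phi_st: float
    p_value: float
    n_permutations: int
    seed: int


def _phist_from_d2(d2: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    na, nb = idx_a.size, idx_b.size
    N = na + nb
    ss_total = d2.sum() / (2 * N)  # full matrix counts each pair twice
    ss_a = d2[np.ix_(idx_a, idx_a)].sum() / (2 * na)
    ss_b = d2[np.ix_(idx_b, idx_b)].sum() / (2 * nb)
    ss_within = ss_a + ss_b
    ss_among = ss_total - ss_within
    df_w = N - 2
    sigma_w = ss_within / df_w
    n0 = (N - (na * na + nb * nb) / N)  # / (G - 1) with G = 2
    sigma_a = (ss_among - sigma_w) / n0  # MS_among has df 1
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def pairwise_phist(
    pop_a: PopulationDataset,
    pop_b: PopulationDataset,
    reference: MitoReference,
    options: ComparisonOptions | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> FstResult:
    """PhiST between two datasets with a label-permutation p-value.

    The AMOVA decomposes squared K2P distances into among- and
    within-population variance components; PhiST = sigma_a^2 /
    (sigma_a^2 + sigma_w^2).  The p-value is the fraction of
    permutations (individuals shuffled between the populations, sizes
    preserved) with PhiST >= observed, with +1 smoothing.
    """
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValueError("each population needs at least two samples")
    profiles = list(pop_a.profiles) + list(pop_b.profiles)
    D = k2p_matrix(profiles, reference, options)
    d2 = D * D
    na, nb = len(pop_a), len(pop_b)
    N = len(profiles)
    idx = np.arange(N)
    observed = _phist_from_d2(d2, idx[:na], idx[na:])
    rng = np.random.default_rng(seed)
    # vectorised permutation kernel: within-group sums via indicators
    ind = np.zeros((n_permutations, N))
    for m in range(n_permutations):
        ind[m, rng.permutation(N)[:na]] = 1.0
    half = ind @ d2
    sa = np.einsum("mi,mi->m", half, ind)
    sb = np.einsum("mi,mi->m", (1 - ind) @ d2, 1 - ind)
    ss_within = sa / (2 * na) + sb / (2 * nb)
    ss_total = d2.sum() / (2 * N)
    ss_among = ss_total - ss_within
    df_w = N - 2
    sigma_w = ss_within / df_w
    n0 = N - (na * na + nb * nb) / N
    sigma_a = (ss_among - sigma_w) / n0
    denom = sigma_a + sigma_w
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom != 0, sigma_a / np.where(denom == 0, 1, denom), 0.0)
    hits = int((phi >= observed - 1e-12).sum())
    p = (hits + 1) / (n_permutations + 1)
    return FstResult(
        populations=(pop_a.name, pop_b.name),
        phi_st=observed,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
    )


def phist_matrix(
    datasets: Sequence[PopulationDataset],
    reference: MitoReference,
    options: ComparisonOptions | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """All pairwise PhiST values and p-values among datasets."""
    names = [d.name for d in datasets]
    k = len(datasets)
    phi = np.zeros((k, k))
    pval = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = pairwise_phist(
                datasets[i], datasets[j], reference, options,
                n_permutations, seed + i * k + j,
            )
            phi[i, j] = phi[j, i] = res.phi_st
            pval[i, j] = pval[j, i] = res.p_value
    return phi, pval, names


# ---------------------------------------------------------------------------
# Principal coordinate analysis

@dataclass(frozen=True)
class PCoAResult:
    coordinates: np.ndarray  # (n, axes), positive-eigenvalue axes only
    explained: np.ndarray    # fraction of variation per axis
    eigenvalues: np.ndarray  # all eigenvalues, descending


def pcoa(dissimilarity: np.ndarray, atol: float = 1e-10) -> PCoAResult:
    """Classical metric scaling of a symmetric zero-diagonal matrix.

    Gower double-centering of -D^2/2, eigendecomposition, coordinates
    scaled by the square root of the positive eigenvalues; explained
    fractions are over the positive eigenvalues.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=atol):
        raise ValueError("dissimilarity must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-12 if vals.size else 0.0
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    total = vals[pos].sum()
    explained = vals[pos] / total if total > 0 else np.zeros(int(pos.sum()))
    return PCoAResult(coordinates=coords, explained=explained, eigenvalues=vals)


# ---------------------------------------------------------------------------
# Heteroplasmy characterization

@dataclass(frozen=True)
class PhpRecord:
    sample_id: str
    position: int
    code: str
    pair: tuple[str, str]
    is_transition: bool
    transition_class: str | None  # 'R' (purine) / 'Y' (pyrimidine)
    region: str  # 'CR' or 'CDS'
    folded_vf: float | None


@dataclass(frozen=True)
class PhpSummary:
    records: tuple[PhpRecord, ...]
    individuals_total: int
    individuals_with_php: int
    php_count_histogram: dict[int, int]  # PHPs per individual -> individuals

    @property
    def n_php(self) -> int:
        return len(self.records)

    @property
    def n_transitions(self) -> int:
        return sum(1 for r in self.records if r.is_transition)


def php_characterize(
    profiles: Sequence[MitoProfile],
    catalog: RegionCatalog = DEFAULT_CATALOG,
) -> PhpSummary:
    """Tabulate PHP prevalence, substitution class, region and folded VF.

    The folded variant frequency is min(VF, 1-VF) of the non-reference
    base, mapping dominant variants onto the same 0-0.5 scale as minor
    ones.  Transitions are the R (A/G) and Y (C/T) pairs.
    """
    records: list[PhpRecord] = []
    hist: dict[int, int] = {}
    with_php = 0
    for p in profiles:
        phps = p.php_variants()
        hist[len(phps)] = hist.get(len(phps), 0) + 1
        if phps:
            with_php += 1
        for v in phps:
            pair = tuple(sorted(IUPAC_PAIRS[v.call]))
            is_ts = v.call in ("R", "Y")
            folded = None
            if v.major_frequency is not None:
                if v.major_base is not None and v.major_base != v.ref_base:
                    vf = v.major_frequency  # variant base dominant
                else:
                    vf = 1 - v.major_frequency
                folded = min(vf, 1 - vf)
            records.append(
                PhpRecord(
                    sample_id=p.sample_id,
                    position=v.position,
                    code=v.call,
                    pair=pair,  # type: ignore[arg-type]
                    is_transition=is_ts,
                    transition_class=v.call if is_ts else None,
                    region="CR"
                    if catalog.in_region(v.position, "control_region")
                    else "CDS",
                    folded_vf=folded,
                )
            )
    return PhpSummary(
        records=tuple(records),
        individuals_total=len(profiles),
        individuals_with_php=with_php,
        php_count_histogram=hist,
    )


# ---------------------------------------------------------------------------
# Continental ancestry from haplogroup labels

DEFAULT_ANCESTRY_MAP: dict[str, str] = {
    "L": "African",
    "H": "European", "HV": "European", "I": "European", "J": "European",
    "K": "European", "T": "European", "U": "European", "V": "European",
    "W": "European", "X": "European",
    "A2": "Native American", "B2": "Native American", "C1": "Native American",
    "C4c": "Native American", "D1": "Native American",
    "A": "Asian", "B": "Asian", "C": "Asian", "D": "Asian", "E": "Asian",
    "F": "Asian", "G": "Asian", "M": "Asian", "N": "Asian", "Y": "Asian",
    "Z": "Asian",
}


def assign_ancestry(
    haplogroup: str, mapping: Mapping[str, str] = DEFAULT_ANCESTRY_MAP
) -> str:
    """Continental ancestry by longest-prefix match; never guessed."""
    best = ""
    for prefix in mapping:
        if haplogroup.startswith(prefix) and len(prefix) > len(best):
            best = prefix
    return mapping[best] if best else "unassigned"


def ancestry_proportions(
    profiles: Sequence[MitoProfile],
    mapping: Mapping[str, str] = DEFAULT_ANCESTRY_MAP,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-dataset continental proportions and per-haplogroup frequencies.

    Profiles without a haplogroup label, or with an unmapped one, count
    under ``unassigned``.
    """
    n = len(profiles)
    if n == 0:
        raise ValueError("empty dataset")
    continents: dict[str, int] = {}
    haplogroups: dict[str, int] = {}
    for p in profiles:
        hg = p.haplogroup or ""
        haplogroups[hg or "unassigned"] = haplogroups.get(hg or "unassigned", 0) + 1
        cont = assign_ancestry(hg, mapping) if hg else "unassigned"
        continents[cont] = continents.get(cont, 0) + 1
    return (
        {k: v / n for k, v in sorted(continents.items())},
        {k: v / n for k, v in sorted(haplogroups.items())},
    )
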