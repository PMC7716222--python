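"""Replicate-based QC: PHP confirmation, mixture flagging, shared-haplotype
detection, dual-analyst comparison, Sanger concordance, and audit replay.

Low-level point heteroplasmies (minor base < 10%) must be reproduced in
an independent amplification to be reported; unconfirmed PHPs revert to
the major base.  Mixtures are flagged from reduced overall major-base
frequency together with multiple PHPs, or from PHPs sitting on
haplogroup-diagnostic sites.  Samples sharing a haplotype (ignoring PHP
and length differences) are grouped as candidates for nuclear-DNA
kinship testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .calling import CallMetrics
from .nomenclature import (
    AuditRecord,
    IUPAC_PAIRS,
    MitoProfile,
    Variant,
    format_variant,
    parse_variant,
)
from .popstats import ComparisonOptions, haplotype_key
from .reference import DEFAULT_CATALOG, RegionCatalog

#: Minor-base frequency below which a PHP requires replicate confirmation.
PHP_CONFIRM_THRESHOLD = 0.10


@dataclass
class QCReport:
    """Aggregated QC outcome for one sample."""

    sample_id: str
    confirmed_php: tuple[Variant, ...] = ()
    unconfirmed_php: tuple[Variant, ...] = ()
    unresolvable_php: tuple[Variant, ...] = ()
    mixture_flag: bool = False
    mixture_reasons: tuple[str, ...] = ()
    below_depth_positions: tuple[int, ...] = ()
    concordance_diffs: tuple[tuple[int, str, str], ...] = ()
    audit: tuple[AuditRecord, ...] = ()


def _minor_frequency(v: Variant) -> float | None:
    return None if v.major_frequency is None else 1.0 - v.major_frequency


def confirm_php(
    primary: MitoProfile,
    replicate: MitoProfile,
    threshold: float = PHP_CONFIRM_THRESHOLD,
) -> tuple[MitoProfile, QCReport]:
    """Confirm low-level PHPs against an independent replicate.

    A PHP with minor frequency below ``threshold`` is kept only if the
    replicate calls a PHP with the same base pair at that position;
    otherwise the call reverts to the recorded major base (or is
    dropped when the major base is the reference).  A replicate lacking
    coverage leaves the PHP unresolvable: it is excluded, never
    silently confirmed.  PHPs at or above the threshold pass without
    replication.  All edits land in the audit trail.
    """
    replicate_php = {v.position: v for v in replicate.php_variants()}
    confirmed: list[Variant] = []
    unconfirmed: list[Variant] = []
    unresolvable: list[Variant] = []
    out_variants: list[Variant] = []
    audit: list[AuditRecord] = []
    for v in primary.variants:
        if not v.is_php:
            out_variants.append(v)
            continue
        minor = _minor_frequency(v)
        if minor is not None and minor >= threshold:
            confirmed.append(v)
            out_variants.append(v)
            continue
        if not replicate.covers(v.position):
            unresolvable.append(v)
            audit.append(
                AuditRecord(
                    operation="confirm_php",
                    removed=(format_variant(v),),
                    added=_revert_strings(v),
                    reason="replicate lacks coverage; PHP unresolvable",
                )
            )
            out_variants.extend(_revert_variant(v))
            continue
        rep = replicate_php.get(v.position)
        if rep is not None and rep.call == v.call:
            confirmed.append(v)
            out_variants.append(v)
        else:
            unconfirmed.append(v)
            audit.append(
                AuditRecord(
                    operation="confirm_php",
                    removed=(format_variant(v),),
                    added=_revert_strings(v),
                    reason="PHP not reproduced in replicate amplification",
                )
            )
            out_variants.extend(_revert_variant(v))
    final = primary.with_variants(out_variants, audit)
    report = QCReport(
        sample_id=primary.sample_id,
        confirmed_php=tuple(confirmed),
        unconfirmed_php=tuple(unconfirmed),
        unresolvable_php=tuple(unresolvable),
        audit=tuple(audit),
    )
    return final, report


def _revert_variant(v: Variant) -> tuple[Variant, ...]:
    """Revert a PHP to its major base: a fixed substitution if the major
    differs from the reference, nothing otherwise."""
    major = v.major_base
    if major is None or major == v.ref_base:
        return ()
    return (
        Variant(
            position=v.position, kind="substitution", ref_base=v.ref_base, call=major
        ),
    )


def _revert_strings(v: Variant) -> tuple[str, ...]:
    return tuple(format_variant(x) for x in _revert_variant(v))


@dataclass(frozen=True)
class MixtureFlag:
    flagged: bool
    reasons: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.flagged


def flag_mixture(
    profile: MitoProfile,
    metrics: CallMetrics,
    diagnostic_sites: Iterable[int] | None = None,
    php_count_min: int = 3,
    major_freq_max: float = 0.98,
) -> MixtureFlag:
    """Flag a profile as a possible two-donor mixture.

    Triggers: reduced overall major-base frequency (excluding
    length-heteroplasmy regions) combined with several PHPs; any PHP on
    a supplied haplogroup-diagnostic site; or any column that retained
    more than two alleles.  The numeric defaults are configurable — the
    underlying definition is qualitative.
    """
    reasons: list[str] = []
    php = profile.php_variants()
    if (
        metrics.average_major_base_frequency_excl_het < major_freq_max
        and len(php) >= php_count_min
    ):
        reasons.append(
            f"reduced major base frequency "
            f"({metrics.average_major_base_frequency_excl_het:.4f}) with "
            f"{len(php)} PHPs"
        )
    if diagnostic_sites is not None:
        sites = set(diagnostic_sites)
        hits = sorted(v.position for v in php if v.position in sites)
        if hits:
            reasons.append(f"diagnostic-site PHP at {hits}")
    if profile.mixture_suspect_sites:
        reasons.append(
            f">2 alleles above threshold at {list(profile.mixture_suspect_sites)}"
        )
    return MixtureFlag(flagged=bool(reasons), reasons=tuple(reasons))


def find_shared_haplotypes(
    profiles: Sequence[MitoProfile],
    options: ComparisonOptions | None = None,
    exclude: Iterable[str] = (),
) -> list[tuple[str, ...]]:
    """Group samples sharing a haplotype key, excluding PHP and length
    differences — the candidate list for nuclear-DNA kinship testing.

    ``exclude`` drops known duplicates/relatives before grouping.
    """
    options = options or ComparisonOptions(php_mode="ignored")
    if options.php_mode != "ignored":
        options = replace(options, php_mode="ignored")
    excluded = set(exclude)
    groups: dict[str, list[str]] = {}
    for p in profiles:
        if p.sample_id in excluded:
            continue
        groups.setdefault(haplotype_key(p, options), []).append(p.sample_id)
    return [
        tuple(sorted(ids)) for _, ids in sorted(groups.items()) if len(ids) >= 2
    ]


def compare_analyst_profiles(
    a: MitoProfile, b: MitoProfile
) -> list[tuple[int, str, str]]:
    """Symmetric difference of two analysts' profiles for one sample.

    Returns ``(position, call_a, call_b)`` with ``''`` where one side
    has no variant; an empty list means the analyses are concordant.
    """
    if a.sample_id != b.sample_id:
        raise ValueError(
            f"profiles are for different samples: {a.sample_id!r} vs {b.sample_id!r}"
        )
    return _profile_diff(a, b)


def _profile_diff(a: MitoProfile, b: MitoProfile) -> list[tuple[int, str, str]]:
    va = {(v.position, v.kind, v.insert_index): v for v in a.variants}
    vb = {(v.position, v.kind, v.insert_index): v for v in b.variants}
    diffs: list[tuple[int, str, str]] = []
    for key in sorted(set(va) | set(vb), key=lambda k: (k[0], k[2] or 0)):
        x, y = va.get(key), vb.get(key)
        sx = format_variant(x) if x else ""
        sy = format_variant(y) if y else ""
        if sx != sy:
            diffs.append((key[0], sx, sy))
    return diffs


def sanger_concordance(
    ngs: MitoProfile,
    sanger: MitoProfile,
    catalog: RegionCatalog = DEFAULT_CATALOG,
    ignore_low_level_php: bool = True,
) -> list[tuple[int, str, str]]:
    """Diff an NGS profile against a control-region Sanger haplotype.

    Both profiles are restricted to the control region.  When
    ``ignore_low_level_php`` is set, a difference where one side's PHP
    pair contains the other side's fixed (or reference) base is
    suppressed — Sanger background noise hides low-level heteroplasmy.
    """
    def cr_variants(p: MitoProfile) -> dict:
        return {
            (v.position, v.kind, v.insert_index): v
            for v in p.variants
            if catalog.in_region(v.position, "control_region")
        }

    va, vb = cr_variants(ngs), cr_variants(sanger)
    diffs: list[tuple[int, str, str]] = []
    for key in sorted(set(va) | set(vb), key=lambda k: (k[0], k[2] or 0)):
        x, y = va.get(key), vb.get(key)
        sx = format_variant(x) if x else ""
        sy = format_variant(y) if y else ""
        if sx == sy:
            continue
        if ignore_low_level_php and _php_masks_diff(x, y):
            continue
        diffs.append((key[0], sx, sy))
    return diffs


def _php_masks_diff(x: Variant | None, y: Variant | None) -> bool:
    """True when one side is a PHP whose pair contains the other side's
    effective base (the fixed call, or the reference when absent)."""
    for php, other in ((x, y), (y, x)):
        if php is None or not php.is_php:
            continue
        pair = IUPAC_PAIRS[php.call]
        other_base = other.call if other is not None else php.ref_base
        if other_base in pair:
            return True
    return False


def replay_audit(
    initial: MitoProfile, audit: Sequence[AuditRecord]
) -> set[str]:
    """Replay audit records over the initial call's variant strings.

    Returns the resulting set of variant strings; equality with the
    final profile's strings verifies that every change between first
    call and final form is reconstructible from the trail.
    """
    state = {format_variant(v) for v in initial.variants}
    for rec in audit:
        for s in rec.removed:
            state.discard(s)
        for s in rec.added:
            if s:
                state.add(s)
    return state


def profile_variant_strings(profile: MitoProfile) -> set[str]:
    return {format_variant(v) for v in profile.variants}
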