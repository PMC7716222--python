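# Methods

This note records the models, rules and numerical choices behind
`mitohap`, and what the synthetic data can and cannot show.

## Coordinate model and nomenclature

Coordinates are 1-based with inclusive intervals, matching forensic
convention; the genome is circular, so the control region (nps
16,024–16,569 and 1–576) wraps the origin and the position after
16,569 is 1. Position 3107 — a historical placeholder in the rCRS — is
carried as `N` and excluded from difference counting and distance site
totals.

Variants are named against the reference: substitutions
(`<ref><pos><alt>`), insertions (`<pos>.<k><bases>`), deletions
(`<pos>DEL`, with `<pos>-` accepted on input and the emitted form
configurable). PHPs use two-base IUPAC codes only; three-base
ambiguity is rejected because at most two bases are reported above
threshold at one position. Indels inside homopolymeric or repeated
stretches are re-expressed at their 3′-most equivalent placement on
the light strand: insertions shift rightwards while the next reference
base matches the (rotating) motif; adjacent deletions shift as a
block, so a deletion written at the 5′ end of the 513–524 AC repeat
lands on the 3′-most AC. Normalisation is idempotent and every move is
audit-logged.

## Variant calling

The caller consumes pre-aligned reads or a per-position, per-strand
count pileup; alignment itself is upstream. When reads arrive as SAM,
an admission check mirrors the alignment acceptance contract (no
clipped reads — length fraction 1.0 — and ≥0.8 identity when an NM tag
is present); re-implementing the aligner is out of scope.

Interpretation rules, in order:

* **Trimming** — 20 nt off each read's 5′ end, a further 20 nt off the
  3′ end of paired reads, reads <40 bp discarded. Trimming acts in
  sequencing orientation (the 5′ end of a reverse-strand read is its
  highest reference coordinate).
* **Quality mask** — a base is excluded when its own quality is <30 or
  any quality within ±5 bases is <30 (window truncated at read ends).
  This per-base reading of the published neighbourhood filter is an
  approximation: the original tool's exact semantics are unpublished.
* **Column calling** — minimum filtered depth 100×; an allele is
  retained at ≥5% frequency with ≥1% of *its own* supporting reads on
  each strand (the strand rule is applied per allele, not per column —
  a documented open choice). One retained non-reference base is a
  fixed substitution; two retained bases are a PHP with the pair's
  IUPAC code and the recorded major base and frequency; more than two
  retained alleles flag the column as mixture-suspect and emit no
  call. Exact count ties keep both bases, the major designated by base
  order A<C<G<T. The deletion allele competes as a fifth class;
  insertion motifs are tested under the same depth/frequency/strand
  rules on their anchoring column.
* **Withholding** — indels inside the nine length-heteroplasmy regions
  are never called per column; those regions are resolved from
  spanning-read motifs.
* **NUMT screen** — the same filters at a 2% threshold; alleles passing
  2% but failing 5% are reported with a flag for the NUMT-prone
  interval nps 6636–11,428. Spike-ins at 2–3% therefore appear in the
  screen but never in the 5% profile.

Metrics cover the called range (positions at or above minimum depth):
mean filtered depth, mean major-base frequency including and excluding
heteroplasmic positions (PHP columns and length-heteroplasmy regions),
depth at variant sites, and the below-depth position list.

## Length heteroplasmy

A read contributes to a region's motif table when it covers the region
plus one anchor base on each side with no masked base inside; one-base
anchoring makes motif boundaries well-defined (the underlying method
requires only that reads extend across the region). Motifs with fewer
than five reads are dropped from the listing — an absolute count, not
a proportion — but still count toward the spanning total. The most
supported motif is the major length molecule; ties break toward the
length closest to the reference segment, then lexicographically, and
are deterministic. The variants a motif implies are computed by a
minimal unit-cost edit script against the reference segment and then
3′-normalised, so an 8C major molecule in the 7C HVII tract becomes
`309.1C`. Same-length listed motifs are compared position by position:
a minor base reaching the 5% threshold of spanning reads is emitted as
an in-region PHP. Deletion-carrying spanning reads form distinct motif
strings. Regions are processed independently; a read may contribute to
several.

## Quality control

PHP confirmation requires the same IUPAC pair in the replicate at the
calling threshold; frequency agreement is not required (presence is
confirmed, not level). A replicate without coverage leaves the PHP
unresolvable — excluded and logged, never silently confirmed. The
mixture definition is qualitative, so the numeric triggers are
configurable defaults: average major-base frequency (excluding
length-het regions) below 0.98 together with ≥3 PHPs, any PHP on a
supplied diagnostic site, or any column that retained more than two
alleles. Shared-haplotype grouping keys profiles with PHPs ignored and
the ten common insertion positions dropped, and accepts an external
exclusion list for known duplicates/relatives; kinship likelihoods
themselves are out of scope. The audit trail stores each edit as
removed/added variant strings, so the final profile is reconstructible
by replay from the first call — a property the tests assert across the
normalise → length-call → confirmation chain.

## Population statistics

Haplotype keys drop variants outside the comparison range (whole
mitogenome or control region), drop insertions at nps 16,193, 309,
315, 455, 463, 573, 960, 5899, 8276 and 8285, and either keep PHP
codes literally or drop PHP variants entirely. "Excluding PHPs" is
implemented as the drop rule (a PHP sample merges with the same
haplotype lacking it), which reproduces the published
distinct-haplotype counts; wildcard-style matching would merge more
pairs and is not the default.

The three summary statistics are computed from the class partition in
exact rational arithmetic and display-rounded half-up (percentages to
two decimals, diversity to four). They satisfy, identically,
`empirical = (n·observed − 1)/(n − 1)` and
`H = n(1 − observed)/(n − 1)`.

K2P distances use substitution-only sequences (indel sites excluded so
all sequences stay reference-length) with PHPs resolved to their major
base; any site where either sequence carries `N` or an ambiguity code
is skipped pairwise. Φst is the two-group AMOVA on squared distances:
`SS_total = Σd²/(2N)`, within-group sums analogously, `σ²_w = SS_w/(N−2)`,
`σ²_a = (SS_a − σ²_w)/n₀` with `n₀ = N − (n_a² + n_b²)/N`, and
`Φst = σ²_a/(σ²_a + σ²_w)`. The estimate can be slightly negative when
among-group variance is absent — populations built as exact copies of
one another give a small negative value by construction — and is
reported unclamped. Significance comes from shuffling individuals
between the two populations with sizes preserved (1000 permutations by
default, seeded, +1 smoothing), vectorised so large calibration runs
stay cheap. PCoA is classical metric scaling: Gower double-centering
of −D²/2, eigendecomposition, coordinates scaled by the square roots
of positive eigenvalues, explained fractions over positive eigenvalues
only.

PHP characterisation classifies each pair as transition (R/Y) or
transversion, assigns CR/CDS by the region catalogue, and folds the
variant frequency to `min(VF, 1−VF)` so dominant variants land on the
same 0–0.5 scale as minor ones. Ancestry uses longest-prefix matching
of haplogroup labels onto continental classes (so B2 is Native
American while B4 falls to Asian B); unmapped labels are reported as
unassigned, never guessed.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not any real specimen set. The reference is a deterministic synthetic
rCRS-like circle: the nine length-heteroplasmy regions carry designed
homopolymer/repeat content (7C-T-5C at 303–315, (AC)×6 at 513–524, a
reference T at 8277, poly-A at 12,418–12,425, C-tracts ending at each
ignorable insertion position), each flanked by anchors that cannot
extend the terminal run; everything else is seeded-random. It is
labelled synthetic and is not the rCRS.

Populations are star-phylogeny lineages (independent Poisson-25
substitution sets, transition:transversion 20:1) or an imposed
haplotype-class partition with distinct variant sets per class.
Defaults encode the study conditions: 28% of individuals carry PHPs
(1/2/3 PHPs with probability 0.808/0.164/0.027), hotspots 146, 152,
204 and 16,093 get 200× sampling weight, 95% of injected PHPs are
transitions, and folded VFs draw 32% mass from 0.05–0.10, 15.5% from
0.10–0.15 and the rest uniformly to 0.5 (the interior of that spectrum
is an interpolation; only the outer masses are anchored). The variant
base is dominant with probability 0.22. Length-heteroplasmy rates
default to 0.869 (HVII), 0.198 (HVI), 0.079 (HVIII), 0.041 (AC
repeat), 0.044 (poly-A) and small values elsewhere; a heteroplasmic
region mixes the reference motif with a ±1-unit motif, the major
fraction drawn from 0.55–0.80, and the major molecule is the
non-reference length 30% of the time. Depth is Poisson(1000) with
i.i.d. base errors at 0.5% and balanced strands; NUMT spike-ins (2.5%,
five sites in nps 6636–11,428) and two-donor mixtures (10% minor,
configurable difference count) are optional. Truth is emitted before
any reads and regeneration is deterministic under a fixed seed.

Two read models exist: a fast pileup-level path (per-position binomial
chains; no motif mixtures, since those regions are resolved from
reads) and a read-level path that realises motif mixtures, PHP draws
and errors per read, with SAM and TSV-pileup writers. The amplicon
structure of the laboratory protocol is not modelled as a coverage
feature, and there is no quality-by-cycle error profile, no polymerase
stutter beyond declared motif mixtures, and no NUMT sequence database
— so passing tests demonstrate correctness of the interpretation
rules under idealised noise, not robustness to instrument-specific
artefacts.

## Problem sizes and thresholds in the tests

Property suites run at sizes chosen to make the binomial bounds sharp
while staying quick: noiseless truth recovery over 100 simulated
profiles at 500×; PHP detection aggregated over minor fractions
0.06–0.45 at depth 1000 (the rate at exactly 6% is ≈92% against a hard
5% threshold, so the ≥99% bound applies to the grid aggregate, and
mean reported major frequencies stay within 3 points of truth);
major-motif recovery over 500 seeded replicates with ≥200 spanning
reads; Φst type-I error over 200 null splits at 1000 permutations;
mixture-flag sensitivity over 200 simulated 10%/12-site mixtures and
specificity over 200 clean samples. The estimator identities are
checked on 10,000 random partitions in exact arithmetic.

## Known limitations

* The caller's neighbourhood quality mask and the per-allele strand
  rule are documented interpretations of briefly described filters.
* PHP major-base resolution needs the recorded major base; a bare
  frequency falls back to treating the reference member of the pair as
  dominant.
* Insertions are keyed by anchor position and motif; nested or
  multi-index insertion stacks (`.2`, `.3`) are representable but the
  caller emits single-index insertions only.
* Haplogroup labels are user-supplied inputs; no phylogenetic calling
  is performed.
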