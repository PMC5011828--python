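# Methods

## The signal

Within a population, linkage disequilibrium between biallelic SNPs decays
with the physical distance separating them on the *true* genome. The
assembly only asserts where markers sit; the genotypes know where they
really are. A marker whose strongest genotype correlations (r², the squared
Pearson correlation of 0/1/2 dosage vectors) point at another chromosome, or
at a region ≥ 10 Mb away on its own chromosome, is therefore evidence of a
misplaced probe or a misassembled contig. `mismap` operationalises that
evidence as a deterministic rule-based screen; no phasing, no haplotype
model, and no hypothesis testing is involved at the detection stage.

## Detection rules and their boundaries

Tag markers are those with r² strictly above 0.5 with the focal SNP. The
focal SNP is flagged when (rule 1) a single chromosome other than its own
holds strictly more than half of its tags, or — only if rule 1 does not
fire — (rule 2) same-chromosome tags at distance ≥ 10 Mb strictly outnumber
those below 10 Mb. All four boundaries are sharp and tested: r² = 0.5 is not
a tag; exactly half the tags on another chromosome does not fire; a tag at
exactly 10 Mb is long; long = short does not fire. With a majority fraction
of 0.5 at most one chromosome can qualify, so ties cannot fire rule 1. A
focal marker with fewer than `min_tags` (default 1) tags is never flagged.

r² is computed over pairwise-complete samples (both genotypes non-missing),
undefined when fewer than 2 complete pairs remain or either vector is
constant on the complete subset; undefined values are treated as absence of
evidence, not as zero, so they never dilute the count tables. The all-pairs
scan is evaluated in column chunks of exact integer-valued cross products;
chunked and per-pair evaluation agree to the last bit, so chunk size is
purely a memory/speed knob.

## Quality control

Order: per-sample call rate ≥ 0.90 → GRM relatedness pruning (< 0.4) →
per-marker call rate ≥ 0.95 → MAF > 0.03 → exact Hardy–Weinberg p > 1e-8.
The exact HWE test conditions on the observed allele counts and sums the
probabilities of all heterozygote counts no more probable than the observed
one; it is computed in exact integer arithmetic (multinomial weights × 2^h),
so the comparison "no more probable" is never subject to floating-point
ties. The GRM is the variance-standardised form
mean[(xᵢ−2p)(xⱼ−2p)/(2p(1−p))] over polymorphic markers with
pairwise-complete missing handling; pruning is greedy (most-violating sample
first; ties by lower call rate, then later index) and guarantees no
remaining pair ≥ cutoff. Two caveats are documented rather than hidden:
the cascade is idempotent except through the GRM step (the matrix is
re-estimated from retained samples, so borderline pairs can shift), and on a
desk-scale genome (2 × 20 Mb) the GRM has so few independent blocks that its
off-diagonal noise SD is ~0.17 — the 0.4 cutoff then prunes ~30 % of
perfectly unrelated samples. Both effects vanish on genome-scale input.

## From markers to segments

Each CMM maps to the unique AGP contig containing its (reported) position;
CMMs landing in gap components are emitted as diagnostics, never silently
dropped. Contigs with ≥ 1 CMM are CMCs. Consecutive CMCs merge into one
candidate misassembled segment when every intervening component is a gap or
a contig without testable markers (QC-emptied contigs count as gap-like),
both contigs carry a CMM majority, and their modal target chromosomes agree;
minority-CMM contigs always stand alone. Aliases R1, R2, … follow genome
order per run.

Signatures: a single-marker segment is a MisSNP. A segment is a MisSeg when
≥ 80 % of its testable members are CMMs (`misseg_cmm_fraction`) *and* no
non-CMM member shows r² ≥ 0.2 (`local_r2_max`) with a non-member marker
within 1 Mb (`local_window_bp`) of the span — such local LD would mean the
marker genuinely belongs there. Everything else is a PMisCon. The original
screen drew these distinctions by visual inspection of LD-decay plots; the
three thresholds replace eyes with reproducible numbers and are exposed in
the configuration. Whole contigs are classified; sub-contig breakpoints are
out of scope.

## Relocation

The segment's target chromosome is the modal chromosome over all member
CMMs' tag markers, with tags that are themselves segment members excluded
(their coordinates are the thing under suspicion). Tags on the target
chromosome are clustered by splitting at gaps > 10 Mb; if more than one
cluster holds over 25 % of the tags the estimate is withheld as ambiguous
(the data support two candidate regions). The 5′ estimate is the position of
the tag with the highest r² to the most proximal member CMM; the 3′ estimate
likewise for the most distal; exact r² ties break toward the tag closest to
the other estimate. If the raw 5′ estimate exceeds the 3′ one the segment is
reported as inverted (coordinates are stored min/max). A tolerance-based tie
rule ("statistically indistinguishable maxima count as tied") was tried and
rejected: pulling near-ties toward the opposite estimate systematically
collapses the interval onto one side and *worsens* recovery.

Corrected positions are drawn uniformly at integer coordinates, without
replacement, from the open estimated interval, sorted, and assigned in the
markers' current order — order preservation keeps the local LD structure of
the corrected map interpretable. The draw is deterministic given the
relocation seed; original coordinates are retained in an audit column. A
degenerate (single-point) interval cannot host markers and raises; the
pipeline records such estimates as not applied instead of guessing.

## The simulator: what it emulates and what it does not

`mismap.simulate` emulates the study design the screen is built for: two
divergent populations genotyped on a shared MAF-ascertained array over an
AGP-structured reference. Haplotypes are founder mosaics (copying switches
between adjacent markers with probability 1 − exp(−ρ·d)); founders carry
distance-decaying allelic correlation from a thresholded Gaussian AR(1)
whose per-marker allele frequency follows its own AR(1) on (0.2, 0.8), so
markers in strong LD also have matched frequencies — without that, the
attainable r² between neighbours is capped and regional frequency drift
parks whole blocks below the MAF floor, neither of which resembles an
ascertained array. Defaults (frozen after design-stage calibration, before
the validation suite was fixed):

| parameter | default | why |
|---|---|---|
| genome | 2 chromosomes × 20 Mb | smallest layout exercising both decision rules |
| markers | 1000 per chromosome (~19 kb spacing) | scaled-down HD array density |
| founder haplotypes | 200 per population, 50 % shared | effective population size ~100 diploids, divergent-breed pair |
| copying/correlation rate ρ | 2 × 10⁻⁷ per bp | r² > 0.5 out to ~300 kb, background beyond ~2 Mb |
| samples | 200 per population | medium genotyping cohort |
| missing rate | 0.002; MAF floor 0.05 | array-typical |

Corruption edits only the reported map and AGP: a `move_segment` event
relocates a run of 6–10 markers' worth of contigs+gaps to another chromosome
(the source is replaced by an equal-length gap, so source-side coordinates
stay comparable); `move_snp` re-homes one marker into a marker-free contig
elsewhere; `partial_shuffle` injects half of one contig's markers into a
marker-bearing contig on the other chromosome. The 6–10-marker run size
mirrors the typical real-world misassembled contig (tens of kb, a handful of
HD probes) and keeps segments smaller than the tag-LD range, which the
cross-chromosome majority rule needs. Genotypes are never modified, so the
truth table is exact.

Not emulated: recombination hotspots and realistic genetic maps, selection,
mutation, genotyping error beyond missingness, sex chromosomes, ascertainment
bias *between* the populations, and genome-scale marker counts. Passing the
planted-event suite therefore shows the pipeline recovers coordinate
corruption whenever LD decays with distance at array-like density; it does
not certify performance on signals these omissions could create (e.g.
breed-specific ascertainment artefacts, which on real data are controlled by
requiring detection in both populations).

## Validation design

The validation suite (and `scripts/acceptance.py`) scores 20 replicate
cohorts at the defaults above: marker-level sensitivity on planted
move_segment markers, the false-flag rate when the same genotypes and tag
sets are classified under the uncorrupted map, per-class signature recovery,
relocation interval overlap with the true source and midpoint error measured
against twice the median marker spacing, and a round-trip check — after
applying the estimated correction, the segment's CMM count must be
statistically indistinguishable from the background rate (one-sided binomial
test at 5 %). Independent oracles back the primitives: a brute-force
flowchart implementation for the detector (exhaustive agreement on ≤ 50-
marker panels), Fraction-arithmetic enumeration for the HWE test (exhaustive
to n = 50 at 1e-12), byte-level decoding for the PLINK codec, and
cross-format PLINK/VCF identity. Problem sizes were chosen so the whole
suite runs on one CPU in a few minutes.

## Numerical and degenerate-input choices

All dosage sums are integer-valued and exact in float64, so zero-variance
detection is exact and results are independent of chunking; TSVs are written
with a fixed float format, making identical runs byte-identical. Coordinates
are 1-based inclusive everywhere inside the package (BIM/AGP convention);
conversion to 0-based half-open happens only at the BED boundary and is a
tested bijection. Degenerate cases: an all-missing marker fails call rate
and never reaches MAF logic; a zero-genotype HWE input returns p = 1
(flagged upstream); monomorphic focal markers are a scan error (QC should
have removed them) while monomorphic *partners* simply yield no entry;
multi-allelic VCF records are dropped with a warning; chromosome names are
opaque strings ordered numerically when possible, and any autosome
restriction is an explicit allow-list in the run configuration.

## Known limitations

Detection is population-dependent: markers filtered in one population are
untestable there and are reported as such, never as "not misplaced".
Whole-contig granularity overstates the misassembled genome fraction when a
contig is only partially wrong (PMisCon). The relocation estimator inherits
the local density of tags — its accuracy is a few marker spacings at best
and degrades where realized LD is weak on one side of the true interval. The
screen cannot distinguish a misassembled reference from a structural variant
shared by *both* screened populations; resolving that requires re-alignment
of raw assembly data, which is outside this package's scope.
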