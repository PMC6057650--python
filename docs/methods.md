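# Methods

This note records the models behind `trioaudit`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic cohorts do
and do not establish about real data.

## Study design being modelled

A trio audit sequences both parents and each embryo of a cohort in which
some embryos were CRISPR-treated (here, two guides against a coat-colour
locus) and others serve as injection/handling controls. Candidate de novo
mutations (DNMs) are embryo variants carried by neither parent; after
filtration, per-embryo DNM counts are compared across groups. The null
result the pipeline is built to probe is that treated embryos are
statistically indistinguishable from untreated ones, both in overall DNM
burden and in DNM proximity to predicted guide off-target sites.

## Synthetic cohorts

The generator (`synthetic_trio`) produces the statistical structure the
analysis assumes, at toy genome scale. Defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| `mean_depth` | 39.5x | the cohort's median mapped depth |
| `inherited_het_rate` | 1.2e-4 /base | ≈325k variants per sample over a 2.8 Gb genome, an inbred-colony level |
| `repeat_fraction` | 0.40 | ≈1.2 Gb of merged repeat annotation in 2.8 Gb |
| `dnm_count_mean` | 20 /embryo | the observed ~19–20 filtered DNMs per embryo |
| `dnm_stage_probs` | {1: 0.5, 2: 0.5} | both anchored stages; see stage model |
| `parental_mosaic_count` / `vaf` | 2 / 0.05 | prevalence is not quantified in the source work; a handful of low-VAF mosaics per parent is the scenario the parental/cross-noise and shared-variant filters exist for. Exposed in config, never asserted. |
| `error_rate` | 1e-3 /read | stray alt reads in non-carrier samples so the noise filters have realistic input; no error model is stated in the source work |
| `microsat_per_mb` | 50 | enough annotated runs to host artifact indels |
| `artifact_indel_count` | 5 /embryo | microsatellite-adjacent false indels, the class the indel screen removes |

**Stage model.** A heterozygous mutation arising in one cell of a
2^(s−1)-cell embryo is carried by 2^(1−s) of cells, so its expected allele
fraction is VAF(s) = 0.5 × 2^(1−s): 0.5 at the one-cell stage, 0.25 at the
two-cell stage. Only s = 1, 2 are empirically anchored (the observed median
on-target VAF of 0.28 corresponds to a two-cell event); the extension to
s > 2 is the simplest lineage-symmetric model through both anchors.

**Mendelian transmission.** Each parental heterozygous variant transmits to
each offspring independently with probability 1/2. Parental mosaics are
present in the parent's reads at their VAF but genotyped 0/0; each embryo
inherits the allele with probability equal to that VAF (the germline
contribution). This is precisely the mechanism that creates false DNMs
shared between siblings, which the shared-variant filter targets.

**Read evidence.** Depth per sample and locus is Poisson(`mean_depth`);
variant reads are Binomial(depth, VAF); non-carrier samples draw stray alt
reads at `error_rate` per read. Mosaic (non-constitutional) evidence is
genotyped as carrying the alt when it reaches 2 reads and 5% of depth,
mirroring a sensitivity-configured joint caller; constitutional alleles are
genotyped 0/1 regardless of the sampled reads.

**DNM placement.** Planted DNMs avoid annotated repeat and microsatellite
intervals (±2 bp): the pipeline excludes repeat-proximal variants by
construction, so the generator models the callable-genome DNM component.
Artifact indels are deliberately placed 0–1 bp from microsatellite runs.

**Edits.** With probability `on_target_efficiency` an embryo receives k
distinct indel alleles at the cut site (k from the observed mosaicism
spectrum, default 30%/50%/20% for 1/2/3 alleles); allele VAFs follow the
stage model with stages forced ≥ 2 when k ≥ 2, resampled if the fractions
would exceed 1. Off-target edits can be planted at caller-specified sites
for power experiments. One long-deletion edit class is representable (an
indel allele of arbitrary size) but its discovery is not modelled.

**What the simulator does not emulate:** read-level artifacts (mapping,
strand bias, base-quality structure), indel left-alignment ambiguity beyond
the anchored-VCF convention, GC/coverage waves, structural variation, and
real repeat sequence content (repeat intervals are annotation only).
Passing tests therefore demonstrate that the *logic* of calling, filtering
and testing behaves as specified under the assumed statistical model — not
that the thresholds are optimal for any particular real dataset.

## Candidate calling

TrioDeNovo-style likelihood modelling is deliberately not reimplemented.
The trio caller is the genotype-level Mendelian-violation rule (embryo
genotype carries an alt absent from both parent genotypes): the pipeline's
conclusions flow from the downstream filters, the caller's role is
candidate generation, and the truth ledger measures the stand-in's
completeness directly. The somatic mode emits embryo-vs-single-parent
candidates whenever the embryo has ≥ 1 alt read and that parent has none;
the cascade later intersects the two parental comparisons. Two independent
quality gates run first: QUAL strictly above 10 (QUAL ≤ 10 is the
low-quality condition) and depth ≥ 10 in every cohort sample — the two
quality conventions are kept as separate switches rather than collapsed.

## Filter cascade

Stages run in the published order; all per-variant predicates commute, so
the final survivor set is order-independent except for the shared-variant
and re-insertion stages (asserted by test). Numerical conventions:

* VAF floor is inclusive (0.10 survives), parental noise fires on ≥ 1 alt
  read in either parent (threshold 0, configurable).
* Cross noise is the **aggregate** alt-read fraction over all samples other
  than the embryo and its own parents, strictly greater than 2%; a
  per-sample-maximum variant is available (`cross_noise_per_sample`) since
  the published wording admits both readings.
* Repeat and microsatellite proximity use 0-based positions of the anchored
  record and a ±1 bp adjacency on merged intervals.
* Known-variant matching is exact on (chrom, pos, alt).
* Mosaic re-insertion (the one count-increasing stage) re-adds a second alt
  allele at a surviving locus when the same embryo's reads support it at
  the VAF floor. Re-inserted candidates are exempt from the per-variant
  predicates — they stand in for manual re-addition — but indels still face
  the microsatellite screen. This exemption is what makes the cascade a
  fixed point on its own survivors.
* The indel microsatellite screen is the deterministic stand-in for visual
  alignment inspection: drop indels within ±1 bp of an annotated
  homopolymer/dinucleotide run of ≥ 8 units.
* Candidates inside a declared on-target window are tallied separately
  before stage 1 and never counted as DNMs.

**Validation classification.** A candidate fails deep-resequencing
validation iff the pooled parent sample shows > 100 alt reads **and** > 1%
alt fraction, or the embryo shows < 1% alt fraction.

**Distant-parent analysis.** Re-running the caller with a fixed wrong
parent pair and a truncated cascade (VAF, parental noise, known variants,
repeats — the stages that stay well-defined under wrong parentage)
quantifies the inflation of apparent DNMs; the median over non-control
embryos is reported. Inflation grows with the divergence between true and
assumed founders, which the tests assert as strict monotonicity.

**Somatic-mode cascade.** Mirrors the tumour/normal re-analysis: optional
alignment-score floor (ASMD ≥ 140 when the annotation is supplied — the
score itself is treated as a supplied per-variant number, never computed
from alignments), depth ≥ 10 in embryo and parents with ≥ 4 embryo alt
reads for SNVs, VAF ≥ 10%, zero parental alt reads, presence against both
parents, no sharing between embryos, known catalogues (any strain), repeat
proximity.

## Statistics

Rank tests reproduce R's conventions because the published statistics were
computed with `kruskal.test` and `wilcox.test` and the Wilcoxon W is
convention-dependent: W is the rank-sum of the first sample minus
n1(n1+1)/2 (its Mann-Whitney U), so group order is part of each test's
definition. Kruskal-Wallis H uses midranks with the tie correction
1 − Σ(t³−t)/(N³−N) and a χ²(k−1) p-value. The Wilcoxon p-value is exact
(full enumeration of the null rank-sum distribution via the standard
dynamic programme) when both samples are < 50 and untied, otherwise a
normal approximation with tie-corrected variance and a 0.5 continuity
correction; two-sided throughout. All-identical observations give H = 0,
p = 1. scipy's implementations serve as independent cross-checks in the
test suite only.

The Bonferroni gate covers the four within-arm tests (family α = 0.05,
critical value 0.0125); the combined untreated-vs-treated test is reported
alongside.

**Power model.** The variant-read count at a mosaic locus is modelled as
Poisson with mean λ = round(VAF × depth) (the integerised default matches
quoting "11 of 39.5 reads"; an exact-product mode exists). Calling requires
at least ceil(min_VAF × floor(depth)) variant reads (clamped to ≥ 1), and
detection probability is the Poisson upper tail. At depth 39.5, VAF 0.28,
min_VAF 0.10 this gives λ = 11, a 4-read requirement and a miss probability
of 0.005.

**Expected chance intersections.** With n DNMs uniform on a genome of G
bases and m windowed sites of footprint w (site span 23 + 10 bp window each
side = 43), the expected number of (DNM, site) intersection pairs is
n·w·m/G. The published full-scale inputs use the 276,254-site count (the
site count also printed in prose; a second, transposed-digit figure of
276,524 appears once inside the printed formula, and only the former
reproduces the printed result of 31.6).

## Off-target enumeration

A site is a protospacer+PAM alignment on either strand with at most
`max_mm_nobulge` mismatches (default 4), or — when bulges are enabled — at
most `max_mm_bulge` (default 3) with exactly one 1-nt bulge: a DNA bulge is
one extra unpaired genomic base inside the protospacer alignment (24-base
genomic span), an RNA bulge one unpaired guide base (22-base span). Bulges
are interior-only (never at an alignment terminus, never in the PAM), so a
bulged alignment never re-describes the plain 23-mer. The PAM matches IUPAC
patterns (default NGG; the relaxed 7-mismatch scan uses NGG+NAG with
bulges off) on the protospacer-adjacent 3' side of the matched strand.
Spans containing N never match. One site is reported per (chrom, span,
strand, bulge class) with the minimum mismatch count; a span reachable both
with and without a bulge appears once per class. The scanner is
numpy-vectorised (prefix-sum mismatch counts over all bulge placements);
the test suite proves set-equality against an exhaustive brute-force oracle
on multi-kilobase genomes for every (mismatch, bulge) setting.

## Problem sizes used in tests

Test cohorts use 60 kb–1 Mb single-chromosome genomes with 2–3 embryos per
group (the full end-to-end check runs 5 groups × 3 embryos on 1 Mb at
~40x), 20 kb genomes for the enumerator-vs-oracle equality, 10,000 draws
for read-sampling/power agreement, and 200–300 Monte-Carlo replicates for
the intersection formula — scales at which every stochastic assertion uses
a 3-standard-error band around its analytic expectation.

## Known limitations

* Genotype-level stand-ins for read-level callers: per-candidate counts of
  the original tools are not matched, only the filtered endpoints'
  statistical behaviour.
* The recall of the cascade on noisy data is bounded by design: with any
  stray parental reads, the zero-tolerance parental-noise filter removes
  true DNMs at the rate at which parents show ≥ 1 matching alt read
  (~4% per parent at 40x and a 1e-3 error rate) — the same sensitivity
  trade-off the real pipeline makes.
* Validation classification consumes pooled-parent summary numbers; the
  deep-resequencing experiment itself is out of scope.
* Off-target enumeration reports sites, not cleavage propensity: no
  CFD/MIT-style scoring or ranking.
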