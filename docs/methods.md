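# Methods

## Data model and coordinate conventions

External formats keep their native conventions: VCF and catalog positions
are 1-based, BED intervals 0-based half-open. All internal arithmetic is
0-based half-open; `to_zero_based`/`to_one_based` are the only conversion
points and are exact inverses. Genotypes are diploid dosage codes
(0 hom-ref, 1 het, 2 hom-alt, −1 missing); missing calls are never imputed,
each downstream operation defines its own exclusion rule. Multi-allelic VCF
records are split alt-by-alt into biallelic sites by default (policy
configurable to `reject`); indels are compared after trimming of shared
prefix/suffix and, when reference context is available, left-alignment —
without a shared normalization the same 2 bp insertion written by two
callers would not match the catalog.

## Consequence calling

Each variant is mapped into spliced-CDS space (minus-strand genes are
handled by reverse-complementing alleles; codon indices always count from
the initiator Met = 1), the mutant CDS is rebuilt and translated under the
standard genetic code, and the change is classified as synonymous,
missense, stop-gained, in-frame indel or frameshift. A frameshift is
followed in the shifted frame to the first stop codon *within the annotated
CDS*; if none appears the consequence is flagged stop-loss/extension rather
than scanning into 3′ flank. An allele spanning an exon junction raises an
explicit unsupported-case error — silent misannotation is worse than a
refusal. A REF allele contradicting the supplied reference CDS is a
validation error at the single-variant level; during catalog screening such
sites are skipped with a warning, since they cannot realize a catalog
protein change.

The 12 bp ABCC2 insertion is modelled as what its length dictates: an
in-frame insertion whose inserted sequence carries a stop codon
(consequence kind `stop_gained` with a premature-stop index). This
reproduces the premature-stop, loss-of-function phenotype without calling a
length-divisible-by-three change a frameshift.

## Screening

A catalog entry is realized by a VCF site either through an exact
normalized genomic match or, when no genomic spec is present, by
consequence equality with the protein spec (an alt-residue set such as
P799K/R matches any of its residues). A carrier holds at least one
resistance allele; zygosity is the strongest call over the realizing sites,
and a sample is excluded from a mutation's denominator only when every
realizing site is uncalled. A mutation with no realizing VCF record is
reported absent in all genotyped samples — in resequencing data the absence
of a variant call at a screened position means homozygous reference.
Denominators are always emitted alongside proportions, and resistance-allele
frequencies are reported in addition to carrier proportions. Codon spectra
are phased naively: an individual heterozygous at one site in a codon shows
both codons; heterozygous at two or more sites it is counted as
"ambiguous" rather than assigned a guessed haplotype (read-level phasing is
out of scope).

## F_ST and the resampling null

Per-locus Weir–Cockerham variance components (a: among groups, b: among
individuals within groups, c: within individuals) are computed for r = 2
groups of diploids at biallelic sites; the formulas are spelled out in
`resistscan/fst.py`. Per-locus θ = a/(a+b+c) is deliberately not truncated
at zero — truncation would bias the multi-locus ratio. The multi-locus
estimate is the ratio of sums Σa/Σ(a+b+c) over informative loci (both
groups ≥ 2 called genotypes, pooled frequency polymorphic), the "weighted"
convention of the common command-line tooling; the mean-of-ratios variant
is available but not default. Zero informative loci raise an error rather
than reporting 0.

The empirical null for a candidate interval of length L draws windows of
the same length uniformly over the genome: a chromosome with probability
proportional to its placeable length (length − L + 1), then a uniform
start. Windows with no informative SNP are redrawn and counted (scoring
them 0 would deflate the null and overstate significance), with a redraw
budget of 10× the replicate count. Sampling is with replacement and windows
may overlap the target; excluding the target is available behind a flag.
`p_plain` counts replicates ≥ observed with a 1e-12 tie tolerance
(conservative reading of "higher than"); `p_conservative` = (k+1)/(n+1) is
also reported. Replicates come from a counter-based Philox stream keyed on
the run seed, so results are independent of batching. The
complete-differentiation scan reports sites with θ ≥ 1 − 1e-12, labeled
exonic/intronic/intergenic from the gene models.

## CNV burden and the exact test

Copy numbers map to states by the diploid convention (<2 deleted, =2
neutral, >2 duplicated); a gene counts once per individual regardless of
magnitude. The clan-level contrast pools gene-level events across a
cohort's individuals into a 2×2 table (cohorts × dup/del events); because
pooled events within an individual are not independent, per-individual
means are reported alongside the test. The two-tailed Fisher p sums, over
all tables with the observed margins, the hypergeometric point
probabilities not exceeding the observed one with a 1e-7 relative tie
tolerance (the minimum-likelihood convention of the usual statistical
environment); evaluation is in log space so totals up to ~1e5 lose no
precision. A zero margin yields p = 1, flagged degenerate. The
conditional-MLE odds ratio is taken from scipy; the p-value is computed
here. No multiple-testing correction is applied; the run report prints the
number of exact tests performed.

## Detection power

The miss probability (1 − p)^(2N) assumes 2N independently sampled alleles
— no inbreeding, no pooling, no population structure within the sample;
this is documented, not corrected for. Evaluation uses
exp(2N·log1p(−p)); the planning inverse is the smallest N with miss ≤ α,
closed form ⌈ln α / (2 ln(1−p))⌉ nudged against floating error so the
boundary inequalities hold exactly.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
the biology of real genomes:

- **Assembly.** Two 2 Mb chromosomes carrying the four catalog genes (ABCC2
  and AChE on chr1, VGSC — minus strand — and RyR on chr2), with CDS
  sequences drawn once from a fixed internal seed so every caller sees the
  same reference. Codons at catalog positions carry the susceptible residue
  and are chosen so a single base change realizes each catalog substitution
  (one consequence: from a proline codon the K of P799K/R is not reachable
  by one substitution, so fixtures plant the R allele; the K/R alt-set
  matching is still exercised).
- **Genotypes.** Catalog sites: per-population Hardy–Weinberg draws at the
  specified resistance-allele frequency. Background SNPs: positions uniform
  over the genome (no linkage — the resampling null assumes exchangeable
  loci, which the generator satisfies by construction), ancestral frequency
  uniform on (0.05, 0.95), per-population frequencies Balding–Nichols
  Beta(p₀(1−F)/F, (1−p₀)(1−F)/F). Balding–Nichols was chosen because its F
  parameter coincides with the Weir–Cockerham estimand, giving a direct
  parameter-recovery check; F = 0 shares p₀ across populations exactly.
  Background SNPs falling inside a synthetic CDS take the true reference
  base so the data are self-consistent with the gene models.
- **Cohorts.** Default population sizes follow the study design: 78
  invasive and 99 native individuals.
- **CNV.** Per individual and clan, duplication and deletion counts are
  Poisson at cohort-specific rates and assigned to distinct genes. Default
  clan sizes follow the observed CNV-variable P450 complement (4 clan2, 12
  clan3, 22 clan4, 9 other); default rates (invasive 1.0 dup/0.25 del per
  clan, native the reverse) are the package's own choice of a clearly
  opposed, realistic regime — the source study reports no rates. Rates
  exceeding a clan's gene count are rejected; the rare draw exceeding it is
  capped, and recorded truth is always the realized count.
- **Worked-example fixture.** Encodes the published carrier table exactly:
  2 bp GC insertion het in PR1, PR18, PR19, PR27, PR31, PR33 and hom in
  PR5, PR12, PR14, PR16, PR30; GY deletion and P799R hom in CC44 and CC69;
  12 bp insertion het in rCC25 and rCC5. Padding defaults are 33 Puerto
  Rico individuals (the highest published carrier index; the study never
  prints a per-population n), 6 susceptible and 4 resistant Brazilians (the
  published counts).

What passing tests on these data do **not** show: robustness to linkage
disequilibrium, allele-frequency spectra of real populations, genotyping
error, reference bias, or multi-gene families with paralogous mapping —
none of which the generators model.

## Problem sizes used in the validation suite

The test suite scales simulations to what the properties need: 1,000
random loci for estimator-oracle equivalence (tolerance 1e-12), 5,000 loci
× 50 diploids/group for Balding–Nichols recovery (±0.02), 200 experiments
× 500 replicates for null calibration (KS uniformity, p > 0.01), 500
random tables (totals ≤ 80) for enumeration-exact Fisher agreement
(1e-10), 50 seeded cohorts for exact planted-carrier recovery, and 10,000
draws for Hardy–Weinberg and Monte-Carlo power checks (3 SE).

## Known limitations

- Screening matches catalog entries; it does not discover novel resistance
  alleles beyond the complete-differentiation scan.
- Codon spectra and zygosity rely on unphased short-variant calls; read- or
  phase-aware validation is out of scope.
- The exact-test contrast treats pooled CNV events as exchangeable across
  individuals; the per-individual means are the honest companion statistic.
- The detection-power formula ignores inbreeding and sampling design.
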