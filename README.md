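# resistscan

Population-level monitoring of insecticide-resistance mutations in the fall
armyworm (*Spodoptera frugiperda*), an invasive crop pest. Given whole-genome
resequencing genotypes from native and invasive populations, `resistscan`
answers four questions:

1. **Who carries known resistance mutations?** A curated catalog of
   target-site mutations — five Bt-resistance changes at the ABCC2
   transporter (a 2 bp GC insertion causing a frameshift and premature stop,
   a GY in-frame deletion, a 12 bp insertion carrying a premature stop,
   P799K/R and G1088D), three organophosphate/carbamate substitutions at
   acetylcholinesterase (F209V, A201S, G227A), three pyrethroid *kdr*-type
   substitutions at the voltage-gated sodium channel (T929I, L932F, L1014F)
   and two diamide substitutions at the ryanodine receptor (I4734M, G4946E) —
   is screened against a VCF, by normalized genomic change or by
   protein-level consequence (codon translation, frameshift tracking to the
   first premature stop). Carrier proportions are summarized per population
   and cohort with exact two-tailed contrasts.
2. **Is a candidate gene unusually differentiated?** Weir–Cockerham
   F<sub>ST</sub> = Σa / Σ(a+b+c) between two groups over a candidate
   interval, with an empirical p-value from resampling same-length windows
   uniformly across the genome, plus a scan for completely differentiated
   SNPs (θ = 1) labeled exonic/intronic/intergenic.
3. **Do cohorts differ in detoxification-gene copy number?** Per-clan
   duplication/deletion burden of the cytochrome P450 family, per individual
   and pooled, contrasted with a from-first-principles two-tailed Fisher
   exact test.
4. **Could a rare allele have been missed?** The miss probability
   (1 − p)<sup>2N</sup> for an allele at frequency p in N diploids, and its
   inversion for sample-size planning.

Because the original resequencing data are not publicly deposited, the
package ships generators for every input it consumes — Hardy–Weinberg
genotypes at catalog sites, Balding–Nichols background SNPs with a chosen
differentiation F, Poisson CNV events with cohort-specific rates — with
recorded ground truth, plus a fixture encoding the published carrier table
exactly. See `docs/methods.md` for the models and their assumptions.

## Worked example

Generate the packaged worked-example cohort (33 Puerto Rico, 6 susceptible
and 4 resistant Brazilian individuals) and screen it:

```bash
resistscan simulate --table1 --out demo
resistscan screen --vcf demo/table1.vcf --catalog demo/catalog.json \
    --genes demo/genes.bed --cds demo/cds.fasta \
    --popmap demo/popmap.tsv --out demo/scr
head -4 demo/scr.populations.tsv
```

```
group        mutation_id     carrier_count  n_genotyped  proportion
Puerto Rico  ABCC2_GCins2bp  11             33           0.3333333333333333
Brazil       ABCC2_GCins2bp  0              10           0.0
Puerto Rico  ABCC2_GYdel     0              33           0.0
```

Eleven of 33 Puerto Rico individuals carry the 2 bp GC insertion (six
heterozygous, five homozygous — see `demo/scr.zygosity.tsv`), and the GY
deletion is confined to Brazil, where exactly two individuals are homozygous
carriers. Detection power for a rare allele:

```bash
resistscan power --freq 0.01 --n 99
# miss probability at p=0.01, N=99: 0.1367 (13.67%)
resistscan power --freq 0.01 --alpha 0.05
# minimal N with miss <= 0.05 at p=0.01: 150
```

A sample of 99 diploids misses an allele at frequency 0.01 with probability
13.67%; pushing the miss probability below 5% requires 150 individuals.
Other entry points: `resistscan fst` (candidate-interval F<sub>ST</sub> +
resampling null), `resistscan cnv-burden` (per-clan CNV contrasts),
`resistscan run --config cfg.json` (full pipeline into one JSON report).

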