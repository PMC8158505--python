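"""Protein-level consequence calling and catalog-driven genotype screening.

Given a gene model and its spliced reference CDS, every variant is mapped
into CDS space, the mutant CDS is rebuilt and translated under the standard
genetic code, and the change is classified (synonymous / missense /
in-frame indel / frameshift / stop-gained).  Frameshifts are followed in
the shifted reading frame until the first stop codon inside the annotated
CDS; if none appears before the annotated end the consequence is flagged
as a stop-loss/extension rather than scanning into 3' flanking sequence.

Screening matches each catalog entry against the genotype matrix — by
normalized genomic change when the catalog carries one, otherwise by
protein-level consequence (an alt-residue set like P799K/R matches any of
its residues) — and aggregates carrier counts per population and cohort.
A carrier holds at least one resistance allele (het or hom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .model import (GeneModel, GenomicSpec, GenotypeMatrix, HET, HOM_ALT,
                    HOM_REF, InFrameDeletion, InFrameInsertion, Frameshift,
                    MISSING, PopulationMap, ResistanceMutation, Substitution,
                    ValidationError, ZYGOSITY_LABELS, revcomp)

log = logging.getLogger(__name__)


class UnsupportedVariantError(ValueError):
    """Variant geometry the annotator refuses to guess about
    (e.g. an allele spanning an exon boundary)."""


@dataclass(frozen=True)
class Consequence:
    variant: GenomicSpec
    gene_id: str
    kind: str  # synonymous | missense | in_frame_indel | frameshift | stop_gained | non_coding
    protein_change: str = ""
    premature_stop_codon_index: Optional[int] = None
    note: str = ""


def translate(cds: str) -> str:
    return str(Seq(cds).translate())


def _cds_edit(variant: GenomicSpec, gene: GeneModel,
              cds_seq: str) -> tuple[int, str, str]:
    """Map a genomic change into CDS space.

    Returns (cds_start, cds_ref, cds_alt): replace
    ``cds_seq[cds_start:cds_start+len(cds_ref)]`` by ``cds_alt``.
    Raises UnsupportedVariantError when the REF allele does not lie in a
    single exon.
    """
    pos0 = variant.pos - 1
    span = range(pos0, pos0 + len(variant.ref))
    idx = [gene.genomic_to_cds(p) for p in span]
    if any(i is None for i in idx):
        raise UnsupportedVariantError(
            f"{variant.chrom}:{variant.pos} {variant.ref}>{variant.alt}: "
            f"allele extends outside the CDS of {gene.gene_id} "
            f"(exon-boundary-spanning variants are not annotated)")
    if gene.strand == "+":
        start = idx[0]
        if idx != list(range(start, start + len(idx))):
            raise UnsupportedVariantError(
                f"{variant.chrom}:{variant.pos}: REF allele spans an exon "
                f"junction of {gene.gene_id}")
        cds_ref, cds_alt = variant.ref, variant.alt
    else:
        start = idx[-1]
        if idx != list(range(start + len(idx) - 1, start - 1, -1)):
            raise UnsupportedVariantError(
                f"{variant.chrom}:{variant.pos}: REF allele spans an exon "
                f"junction of {gene.gene_id}")
        cds_ref, cds_alt = revcomp(variant.ref), revcomp(variant.alt)
    have = cds_seq[start:start + len(cds_ref)]
    if have != cds_ref:
        raise ValidationError(
            f"{gene.gene_id}: reference mismatch at CDS {start}: "
            f"CDS has {have!r}, variant REF implies {cds_ref!r}")
    return start, cds_ref, cds_alt


def annotate_consequence(variant: GenomicSpec, gene: GeneModel,
                         cds_seq: str) -> Consequence:
    """Classify one normalized variant against a gene's reference CDS."""
    if len(cds_seq) != gene.cds_length:
        raise ValidationError(
            f"{gene.gene_id}: CDS sequence length {len(cds_seq)} != model "
            f"length {gene.cds_length}")
    pos0 = variant.pos - 1
    overlaps = any(gene.genomic_to_cds(p) is not None
                   for p in range(pos0, pos0 + len(variant.ref)))
    if variant.chrom != gene.chrom or not overlaps:
        return Consequence(variant, gene.gene_id, "non_coding")

    start, cds_ref, cds_alt = _cds_edit(variant, gene, cds_seq)
    mutant = cds_seq[:start] + cds_alt + cds_seq[start + len(cds_ref):]
    dlen = len(cds_alt) - len(cds_ref)
    first_codon = start // 3  # 0-based codon of first touched base

    if dlen % 3 != 0:
        return _frameshift(variant, gene, mutant, first_codon)

    ref_prot = translate(cds_seq)[:-1]  # drop terminal stop
    mut_prot_full = translate(mutant[:len(mutant) - len(mutant) % 3])
    term = mut_prot_full.find("*")
    mut_prot = mut_prot_full if term < 0 else mut_prot_full[:term]

    if dlen == 0:
        if mut_prot_full == translate(cds_seq):
            aa = ref_prot[first_codon] if first_codon < len(ref_prot) else "*"
            return Consequence(variant, gene.gene_id, "synonymous",
                               f"p.{aa}{first_codon + 1}=")
        if term >= 0 and term < len(ref_prot):
            return Consequence(variant, gene.gene_id, "stop_gained",
                               f"p.{ref_prot[term]}{term + 1}*",
                               premature_stop_codon_index=term + 1)
        changes = [(i, a, b) for i, (a, b)
                   in enumerate(zip(ref_prot, mut_prot)) if a != b]
        i, a, b = changes[0]
        return Consequence(variant, gene.gene_id, "missense",
                           f"p.{a}{i + 1}{b}")

    # in-frame indel: align by common prefix/suffix of the two proteins
    if term >= 0 and term < len(ref_prot) and dlen > 0:
        # inserted material (or the junction it creates) carries a stop
        return Consequence(variant, gene.gene_id, "stop_gained",
                           f"p.{ref_prot[term] if term < len(ref_prot) else '?'}"
                           f"{term + 1}*",
                           premature_stop_codon_index=term + 1,
                           note="in-frame insertion introducing a stop codon")
    k = 0
    while k < min(len(ref_prot), len(mut_prot)) and ref_prot[k] == mut_prot[k]:
        k += 1
    if dlen < 0:
        ndel = (-dlen) // 3
        # right-align through the common suffix so the reported residues are
        # the leftmost equivalent deletion
        deleted = ref_prot[k:k + ndel]
        change = f"p.{deleted}-del"
    else:
        nins = dlen // 3
        inserted = mut_prot[k:k + nins]
        change = f"p.{inserted}-ins@{k + 1}"
    return Consequence(variant, gene.gene_id, "in_frame_indel", change)


def _frameshift(variant: GenomicSpec, gene: GeneModel, mutant: str,
                first_codon: int) -> Consequence:
    ref_len = gene.cds_length // 3
    prot = translate(mutant[:len(mutant) - len(mutant) % 3])
    stop = prot.find("*", first_codon)
    change = f"p.{first_codon + 1}fs"
    if stop < 0:
        return Consequence(variant, gene.gene_id, "frameshift", change,
                           note="stop_lost/extension: no stop codon before "
                                "the annotated CDS end")
    note = "" if stop + 1 < ref_len else \
        "stop at/after the reference stop position"
    return Consequence(variant, gene.gene_id, "frameshift", change,
                       premature_stop_codon_index=stop + 1, note=note)


# ---------------------------------------------------------------------------
# Catalog matching
# ---------------------------------------------------------------------------

def consequence_matches(cons: Consequence,
                        mut: ResistanceMutation) -> bool:
    """Does an annotated consequence realize a catalog protein spec?"""
    p = mut.protein_spec
    if p is None or cons.gene_id != mut.gene_id:
        return False
    if isinstance(p, Substitution):
        if cons.kind not in ("missense", "stop_gained"):
            return False
        want = {f"p.{p.ref_aa}{p.codon_index}{alt}" for alt in p.alt_aas}
        return cons.protein_change in want
    if isinstance(p, InFrameDeletion):
        return (cons.kind == "in_frame_indel"
                and cons.protein_change == f"p.{p.deleted_aa}-del")
    if isinstance(p, Frameshift):
        v = cons.variant
        return (cons.kind == "frameshift"
                and abs(len(v.alt) - len(v.ref)) == p.indel_length
                and (p.expected_premature_stop is None
                     or cons.premature_stop_codon_index
                     == p.expected_premature_stop))
    if isinstance(p, InFrameInsertion):
        v = cons.variant
        if abs(len(v.alt) - len(v.ref)) != p.inserted_length:
            return False
        if p.introduces_stop:
            return cons.kind == "stop_gained"
        return cons.kind == "in_frame_indel"
    return False


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    """Per-sample zygosity and per-population / per-cohort carrier counts.

    ``per_sample`` columns: sample, mutation_id, zygosity;
    ``per_population`` / ``per_cohort`` columns: group, mutation_id,
    carrier_count, n_genotyped, proportion.  Denominators are always
    emitted: samples with a missing genotype at a mutation's site are
    excluded from that mutation's denominator only.
    """

    per_sample: pd.DataFrame
    per_population: pd.DataFrame
    per_cohort: pd.DataFrame
    allele_frequency: pd.DataFrame  # group-level resistance-allele frequency
    skipped_mutations: list[str] = field(default_factory=list)

    def zygosity(self, sample: str, mutation_id: str) -> str:
        df = self.per_sample
        sel = df[(df["sample"] == sample) & (df["mutation_id"] == mutation_id)]
        return sel["zygosity"].iloc[0] if len(sel) else "absent"

    def carriers(self, mutation_id: str,
                 population: Optional[str] = None) -> list[str]:
        df = self.per_sample
        sel = df[(df["mutation_id"] == mutation_id)
                 & df["zygosity"].isin(["heterozygous", "homozygous"])]
        if population is not None:
            sel = sel[sel["population"] == population]
        return sorted(map(str, sel["sample"]))


def _match_sites(gm: GenotypeMatrix, mut: ResistanceMutation,
                 gene_models: dict[str, GeneModel],
                 cds_seqs: dict[str, str]) -> Optional[list[int]]:
    """Site indices realizing a mutation, or None to skip (no gene model)."""
    if mut.genomic_spec is not None:
        lookup = gm.site_lookup()
        g = mut.genomic_spec
        i = lookup.get((g.chrom, g.pos, g.ref, g.alt))
        return [] if i is None else [i]
    gene = gene_models.get(mut.gene_id)
    cds = cds_seqs.get(mut.gene_id)
    if gene is None or cds is None:
        return None
    lo, hi = gene.span
    idx = np.flatnonzero(gm.in_region(gene.chrom, lo, hi))
    hits = []
    for i in idx:
        chrom, pos, ref, alt = gm.site_key(int(i))
        try:
            cons = annotate_consequence(GenomicSpec(chrom, pos, ref, alt),
                                        gene, cds)
        except UnsupportedVariantError:
            continue
        except ValidationError as exc:
            # REF disagrees with the supplied reference CDS: the site
            # cannot realize a catalog protein change; skip it loudly
            log.warning("screen: %s", exc)
            continue
        if consequence_matches(cons, mut):
            hits.append(int(i))
    return hits


def screen(gm: GenotypeMatrix, catalog: Sequence[ResistanceMutation],
           gene_models: dict[str, GeneModel], popmap: PopulationMap,
           cds_seqs: Optional[dict[str, str]] = None) -> ScreeningResult:
    """Screen every sample for every catalog mutation.

    A sample's zygosity for a mutation is the strongest call over the
    sites realizing it (several VCF records can encode one catalog entry,
    e.g. the two alt residues of P799K/R); it is missing only when every
    realizing site is uncalled.  A mutation with no realizing record in
    the VCF is reported absent in all genotyped samples — in resequencing
    data, no variant call at a screened position means homozygous
    reference.
    """
    cds_seqs = cds_seqs or {}
    popmap.require_cover(gm.samples)
    sample_arr = np.array(gm.samples)
    pops = np.array([popmap.population(s) for s in gm.samples])
    cohorts = np.array([popmap.cohort(s) for s in gm.samples])

    rows_sample, skipped = [], []
    group_rows: dict[str, list] = {"population": [], "cohort": []}
    for mut in catalog:
        sites = _match_sites(gm, mut, gene_models, cds_seqs)
        if sites is None:
            log.warning("screen: gene %s of %s has no gene model/CDS; skipped",
                        mut.gene_id, mut.mutation_id)
            skipped.append(mut.mutation_id)
            continue
        if sites:
            sub = gm.calls[sites, :]          # (k, n)
            zyg = sub.max(axis=0)             # strongest call; MISSING=-1 loses
            all_missing = (sub == MISSING).all(axis=0)
            zyg = np.where(all_missing, MISSING, np.maximum(zyg, HOM_REF))
            alt_counts = np.where(sub == MISSING, 0, sub).sum(axis=0)
        else:
            zyg = np.full(gm.n_samples, HOM_REF, dtype=np.int8)
            alt_counts = np.zeros(gm.n_samples, dtype=int)
        for s, z in zip(sample_arr, zyg):
            rows_sample.append((s, mut.mutation_id, ZYGOSITY_LABELS[int(z)]))
        for level, groups in (("population", pops), ("cohort", cohorts)):
            for gname in pd.unique(groups):
                m = groups == gname
                called = m & (zyg != MISSING)
                n_gt = int(called.sum())
                carriers = int(((zyg >= HET) & called).sum())
                n_alleles = 2 * n_gt
                freq = (float(np.where(called, alt_counts, 0).sum())
                        / n_alleles if n_alleles else np.nan)
                group_rows[level].append(
                    (gname, mut.mutation_id, carriers, n_gt,
                     carriers / n_gt if n_gt else np.nan, freq))

    per_sample = pd.DataFrame(rows_sample,
                              columns=["sample", "mutation_id", "zygosity"])
    per_sample["population"] = per_sample["sample"].map(popmap.population)
    per_sample["cohort"] = per_sample["sample"].map(popmap.cohort)
    cols = ["group", "mutation_id", "carrier_count", "n_genotyped",
            "proportion", "allele_frequency"]
    per_pop = pd.DataFrame(group_rows["population"], columns=cols)
    per_coh = pd.DataFrame(group_rows["cohort"], columns=cols)
    freq = pd.concat([per_pop.assign(level="population"),
                      per_coh.assign(level="cohort")], ignore_index=True
                     )[["level", "group", "mutation_id", "allele_frequency"]]
    return ScreeningResult(per_sample,
                           per_pop.drop(columns="allele_frequency"),
                           per_coh.drop(columns="allele_frequency"),
                           freq, skipped)


def cohort_contrast(result: ScreeningResult, mutation_id: str
                    ) -> tuple[np.ndarray, float, "pd.DataFrame"]:
    """Carrier-count 2x2 table (cohorts x carrier/non-carrier) and the
    two-tailed exact p for one mutation."""
    from .burden import fisher_exact_two_tailed

    df = result.per_cohort
    sel = df[df["mutation_id"] == mutation_id].sort_values("group")
    if len(sel) < 2:
        raise ValidationError(f"{mutation_id}: need two cohorts, have "
                              f"{sel['group'].tolist()}")
    zero = sel[sel["n_genotyped"] == 0]
    if len(zero):
        raise ValidationError(
            f"{mutation_id}: cohort(s) with zero genotyped samples: "
            f"{zero['group'].tolist()}")
    table = np.array([[int(r.carrier_count),
                       int(r.n_genotyped - r.carrier_count)]
                      for r in sel.itertuples()])
    _, p = fisher_exact_two_tailed(table)
    return table, p, sel


# ---------------------------------------------------------------------------
# Codon spectrum
# ---------------------------------------------------------------------------

def codon_spectrum(gm: GenotypeMatrix, gene: GeneModel, cds_seq: str,
                   codon_index: int, popmap: PopulationMap) -> pd.DataFrame:
    """Observed codon sequences at one codon, counted per population.

    Unphased diploid calls cannot resolve two heterozygous sites inside a
    single codon, so such individuals land in an "ambiguous" bucket rather
    than a guessed haplotype; an individual heterozygous at exactly one
    site contributes to both of its codons.  Positions with no VCF record
    are homozygous reference.  Columns: population, codon, n_individuals.
    """
    popmap.require_cover(gm.samples)
    if not 1 <= codon_index <= gene.protein_length + 1:
        raise ValidationError(f"codon {codon_index} outside {gene.gene_id}")
    ref_codon = cds_seq[3 * (codon_index - 1): 3 * codon_index]
    gpos = gene.codon_genomic_positions(codon_index)  # 5'->3' CDS order

    # per codon slot: (site index in gm, alt base in CDS orientation) or None
    slot_alt: list[Optional[tuple[int, str]]] = [None, None, None]
    pos_series = gm.sites["pos"].to_numpy() - 1
    for slot, p0 in enumerate(gpos):
        hits = np.flatnonzero((gm.sites["chrom"] == gene.chrom).to_numpy()
                              & (pos_series == p0))
        for i in hits:
            _, _, ref, alt = gm.site_key(int(i))
            if len(ref) == 1 == len(alt):
                base = alt if gene.strand == "+" else revcomp(alt)
                slot_alt[slot] = (int(i), base)

    counts: dict[tuple[str, str], int] = {}
    for j, sample in enumerate(gm.samples):
        pop = popmap.population(sample)
        calls = []
        for slot in range(3):
            if slot_alt[slot] is None:
                calls.append((HOM_REF, ref_codon[slot]))
            else:
                i, base = slot_alt[slot]
                calls.append((int(gm.calls[i, j]), base))
        states = [c for c, _ in calls]
        if MISSING in states:
            key = (pop, "missing")
            counts[key] = counts.get(key, 0) + 1
            continue
        if sum(c == HET for c in states) >= 2:
            key = (pop, "ambiguous")
            counts[key] = counts.get(key, 0) + 1
            continue
        codons = {""}
        observed = set()
        base_codon = list(ref_codon)
        for slot, (c, base) in enumerate(calls):
            if c == HOM_ALT:
                base_codon[slot] = base
        hom_codon = "".join(base_codon)
        observed.add(hom_codon)
        het_slots = [s for s, (c, _) in enumerate(calls) if c == HET]
        if het_slots:
            s = het_slots[0]
            alt_codon = list(hom_codon)
            alt_codon[s] = calls[s][1]
            observed.add("".join(alt_codon))
        for codon in observed:
            key = (pop, codon)
            counts[key] = counts.get(key, 0) + 1
    rows = [(pop, codon, n) for (pop, codon), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["population", "codon", "n_individuals"])
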