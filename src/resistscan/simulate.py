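"""Synthetic inputs with recorded ground truth for every pipeline stage.

The package's raw study data are not publicly deposited, so everything the
pipeline consumes can be generated here: a small synthetic assembly with
the four catalog genes (engineered so each catalog substitution is one
base change away from its reference codon), Hardy-Weinberg genotypes at
catalog sites with per-population allele frequencies, Balding-Nichols
background SNPs with a chosen differentiation F, Poisson CNV events with
cohort-specific rates, and a fixture that encodes the published worked
example of carrier individuals exactly.

Under the Balding-Nichols model a locus with ancestral frequency p0 gets
per-population frequencies Beta(p0 (1-F)/F, (1-p0)(1-F)/F), whose
expected Weir-Cockerham theta is the parameter F itself — which is what
makes the generator usable for parameter-recovery checks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import catalog_io
from .consequence import annotate_consequence, translate
from .model import (GeneModel, GenomicSpec, GenotypeMatrix, HET, HOM_ALT,
                    HOM_REF, PopulationMap, ResistanceMutation,
                    ValidationError, ZYGOSITY_LABELS, CnvStateTable)

# ---------------------------------------------------------------------------
# Synthetic reference (assembly "rs-syn-1")
# ---------------------------------------------------------------------------

GENOME_EXTENT = {"chr1": 2_000_000, "chr2": 2_000_000}

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - _STOPS)

# residue-anchored codons: one base change realizes each catalog substitution
_ENGINEERED = {
    "ABCC2": {780: "GGA", 781: "TAT", 799: "CCA", 1088: "GGT"},
    "AChE": {201: "GCG", 209: "TTT", 227: "GGA"},
    "VGSC": {929: "ACA", 932: "TTA", 1014: "CTT"},
    "RyR": {4734: "ATA", 4946: "GGA"},
}

_GENE_LAYOUT = {
    # gene: (chrom, strand, n_codons, exon intervals 0-based half-open)
    "ABCC2": ("chr1", "+", 1250,
              ((100_000, 101_200), (102_000, 103_500), (104_500, 105_550))),
    "AChE": ("chr1", "+", 650, ((500_000, 501_000), (501_500, 502_450))),
    "VGSC": ("chr2", "-", 1100, ((300_000, 301_650), (302_650, 304_300))),
    "RyR": ("chr2", "+", 5000, ((600_000, 615_000),)),
}

_REFERENCE_SEED = 20210517  # fixed: the synthetic assembly is a constant


def synthetic_reference() -> tuple[dict[str, GeneModel], dict[str, str]]:
    """The synthetic gene models and their reference CDS sequences.

    Deterministic (internal fixed seed): every caller sees the same
    assembly.  Each CDS starts with ATG, ends with TAA, has no internal
    stop, and carries the engineered codons above.
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    models, cds = {}, {}
    for gene, (chrom, strand, n_codons, exons) in _GENE_LAYOUT.items():
        model = GeneModel(gene, chrom, strand, exons)
        assert model.cds_length == 3 * n_codons, gene
        codons = list(rng.choice(_SENSE_CODONS, size=n_codons))
        codons[0] = "ATG"
        codons[-1] = "TAA"
        for idx, codon in _ENGINEERED.get(gene, {}).items():
            codons[idx - 1] = codon
        seq = "".join(codons)
        prot = translate(seq)
        assert prot[0] == "M" and prot[-1] == "*" and "*" not in prot[:-1]
        models[gene] = model
        cds[gene] = seq
    return models, cds


def _abcc2_variants() -> dict[str, GenomicSpec]:
    """Genomic specs (assembly rs-syn-1) of the five ABCC2 catalog changes."""
    models, cds = synthetic_reference()
    gm, seq = models["ABCC2"], cds["ABCC2"]

    def anchor(cds_i: int) -> tuple[int, str]:
        pos0 = gm.cds_to_genomic(cds_i)
        return pos0 + 1, seq[cds_i]

    # 2 bp GC insertion after the last base of codon 300 (CDS index 899)
    pos1, base = anchor(899)
    gc_ins = GenomicSpec("chr1", pos1, base, base + "GC")
    # GY deletion: codons 780-781 (CDS 2337..2343), anchored one base left
    pos1, base = anchor(2336)
    gy_del = GenomicSpec("chr1", pos1, base + seq[2337:2343], base)
    # 12 bp insertion after codon 868 (CDS index 2603); second inserted
    # codon is TAA -> premature stop without frameshift
    pos1, base = anchor(2603)
    ins12 = GenomicSpec("chr1", pos1, base, base + "GCTTAAGCTGCT")
    # P799R: middle base of codon 799 (CCA -> CGA)
    i = 3 * 798 + 1
    pos1, base = anchor(i)
    p799r = GenomicSpec("chr1", pos1, base, "G")
    # G1088D: middle base of codon 1088 (GGT -> GAT)
    i = 3 * 1087 + 1
    pos1, base = anchor(i)
    g1088d = GenomicSpec("chr1", pos1, base, "A")
    return {"ABCC2_GCins2bp": gc_ins, "ABCC2_GYdel": gy_del,
            "ABCC2_ins12bp": ins12, "ABCC2_P799KR": p799r,
            "ABCC2_G1088D": g1088d}


def catalog_with_genomic_specs() -> list[ResistanceMutation]:
    """Default catalog with assembly-specific genomic overlays.

    Indels and single-residue ABCC2 entries get explicit genomic specs on
    the synthetic assembly; multi-residue entries (P799K/R) and the other
    genes stay protein-matched so both screening paths are exercised.
    """
    overlays = _abcc2_variants()
    out = []
    for mut in catalog_io.default_catalog():
        if mut.mutation_id in ("ABCC2_GCins2bp", "ABCC2_GYdel",
                               "ABCC2_ins12bp", "ABCC2_G1088D"):
            out.append(mut.with_genomic(overlays[mut.mutation_id]))
        else:
            out.append(mut)
    return out


# ---------------------------------------------------------------------------
# Simulation spec
# ---------------------------------------------------------------------------

def _default_populations() -> list[tuple[str, str, int]]:
    # study-shaped cohorts: 78 invasive (29 sfC + 49 sfR), 99 native
    # (70 sfC + 29 sfR)
    return [("invasive_pop", "invasive", 78), ("native_pop", "native", 99)]


def _default_clan_genes() -> dict[str, list[str]]:
    # CNV-variable P450 complement: 4 clan2, 12 clan3, 22 clan4, 9 other
    return {"clan2": [f"CYP2_{i}" for i in range(1, 5)],
            "clan3": [f"CYP3_{i}" for i in range(1, 13)],
            "clan4": [f"CYP4_{i}" for i in range(1, 23)],
            "other": [f"CYPmito_{i}" for i in range(1, 10)]}


def _default_cnv_rates() -> dict[str, dict[str, tuple[float, float]]]:
    clans = ("clan2", "clan3", "clan4", "other")
    return {"invasive": {c: (1.0, 0.25) for c in clans},
            "native": {c: (0.25, 1.0) for c in clans}}


@dataclass
class SimSpec:
    """Everything the generators need, with study-shaped defaults."""

    seed: int = 0
    populations: list[tuple[str, str, int]] = field(
        default_factory=_default_populations)
    # mutation_id -> {population -> resistance-allele frequency}
    catalog_site_freqs: dict[str, dict[str, float]] = field(
        default_factory=dict)
    n_background_loci: int = 1000
    background_f: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    genome_extent: dict[str, int] = field(
        default_factory=lambda: dict(GENOME_EXTENT))
    clan_genes: dict[str, list[str]] = field(
        default_factory=_default_clan_genes)
    cnv_rates: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_cnv_rates)

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_f < 1.0:
            raise ValidationError("background F must be in [0, 1)")
        for mut, per_pop in self.catalog_site_freqs.items():
            for pop, q in per_pop.items():
                if not 0.0 <= q <= 1.0:
                    raise ValidationError(
                        f"{mut}/{pop}: frequency {q} outside [0, 1]")
        for _, cohort, n in self.populations:
            if n <= 0:
                raise ValidationError("population sizes must be positive")
            if cohort not in ("native", "invasive"):
                raise ValidationError(f"unknown cohort {cohort!r}")

    def popmap(self) -> PopulationMap:
        recs = {}
        for name, cohort, n in self.populations:
            prefix = "".join(w[0] for w in name.split("_")).upper() or "S"
            for i in range(1, n + 1):
                recs[f"{prefix}_{name}_{i}"] = (name, cohort)
        return PopulationMap.from_records(recs)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimSpec":
        d = json.loads(Path(path).read_text())
        if "populations" in d:
            d["populations"] = [tuple(p) for p in d["populations"]]
        if "cnv_rates" in d:
            d["cnv_rates"] = {co: {cl: tuple(r) for cl, r in per.items()}
                              for co, per in d["cnv_rates"].items()}
        if "ancestral_freq_range" in d:
            d["ancestral_freq_range"] = tuple(d["ancestral_freq_range"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------

_CODING_BASE_CACHE: Optional[dict[tuple[str, int], str]] = None
_COMPLEMENT = dict(zip("ACGT", "TGCA"))


def _coding_reference_bases() -> dict[tuple[str, int], str]:
    """(chrom, pos0) -> genomic-strand reference base over all CDS exons."""
    global _CODING_BASE_CACHE
    if _CODING_BASE_CACHE is None:
        models, cds = synthetic_reference()
        lookup: dict[tuple[str, int], str] = {}
        for gene, model in models.items():
            seq = cds[gene]
            for cds_i in range(model.cds_length):
                pos0 = model.cds_to_genomic(cds_i)
                base = seq[cds_i]
                if model.strand == "-":
                    base = _COMPLEMENT[base]
                lookup[(model.chrom, pos0)] = base
        _CODING_BASE_CACHE = lookup
    return _CODING_BASE_CACHE

def _hwe_draw(rng: np.random.Generator, q: float, n: int) -> np.ndarray:
    """n diploid genotype codes under HWE at alt frequency q."""
    return rng.binomial(2, q, size=n).astype(np.int8)


def simulate_genotypes(spec: SimSpec, out_dir: Optional[str | Path] = None
                       ) -> tuple[GenotypeMatrix, PopulationMap, dict]:
    """HWE genotypes at catalog sites plus Balding-Nichols background SNPs.

    Returns (genotypes, popmap, truth); with ``out_dir`` also writes
    genotypes.vcf, popmap.tsv and truth.json.  The truth dict records
    every planted carrier and every per-population frequency.
    """
    rng = np.random.default_rng(spec.seed)
    popmap = spec.popmap()
    samples = popmap.samples
    pop_slices: dict[str, np.ndarray] = {}
    pops = np.array([popmap.population(s) for s in samples])
    for name, _, _ in spec.populations:
        pop_slices[name] = np.flatnonzero(pops == name)

    catalog = catalog_with_genomic_specs()
    by_id = {m.mutation_id: m for m in catalog}
    rows, calls_list = [], []
    truth: dict = {"seed": spec.seed, "mutation_carriers": {},
                   "catalog_freqs": spec.catalog_site_freqs,
                   "background": {}}

    for mut_id, per_pop in spec.catalog_site_freqs.items():
        mut = by_id.get(mut_id)
        if mut is None or mut.genomic_spec is None:
            raise ValidationError(
                f"{mut_id}: not in catalog or lacks a genomic spec on the "
                f"synthetic assembly")
        g = mut.genomic_spec
        site = np.zeros(len(samples), dtype=np.int8)
        for pop, q in per_pop.items():
            idx = pop_slices[pop]
            site[idx] = _hwe_draw(rng, q, len(idx))
        rows.append({"chrom": g.chrom, "pos": g.pos, "ref": g.ref,
                     "alt": g.alt})
        calls_list.append(site)
        truth["mutation_carriers"][mut_id] = {
            samples[j]: ZYGOSITY_LABELS[int(site[j])]
            for j in np.flatnonzero(site > 0)}

    # background SNPs
    n_bg = spec.n_background_loci
    chroms = list(spec.genome_extent)
    lengths = np.array([spec.genome_extent[c] for c in chroms], dtype=float)
    taken = {(r["chrom"], r["pos"]) for r in rows}
    bg_pos: list[tuple[str, int]] = []
    while len(bg_pos) < n_bg:
        need = n_bg - len(bg_pos)
        ci = rng.choice(len(chroms), size=need, p=lengths / lengths.sum())
        ps = rng.integers(1, lengths[ci].astype(np.int64) + 1)
        for c, p in zip(ci, ps):
            key = (chroms[c], int(p))
            if key not in taken:
                taken.add(key)
                bg_pos.append(key)
    p0 = rng.uniform(*spec.ancestral_freq_range, size=n_bg)
    F = spec.background_f
    pop_freqs: dict[str, np.ndarray] = {}
    for name, _, _ in spec.populations:
        if F == 0.0:
            pop_freqs[name] = p0.copy()
        else:
            pop_freqs[name] = rng.beta(p0 * (1 - F) / F,
                                       (1 - p0) * (1 - F) / F)
    bases = "ACGT"
    coding_base = _coding_reference_bases()
    for k, (chrom, pos) in enumerate(bg_pos):
        # inside a synthetic CDS the REF base must match the reference
        ref = coding_base.get((chrom, pos - 1))
        if ref is None:
            ref = bases[rng.integers(4)]
        alt = bases[int(rng.integers(4))]
        while alt == ref:
            alt = bases[int(rng.integers(4))]
        site = np.zeros(len(samples), dtype=np.int8)
        for name, idx in pop_slices.items():
            site[idx] = _hwe_draw(rng, pop_freqs[name][k], len(idx))
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
        calls_list.append(site)
    truth["background"] = {
        "F": F, "n_loci": n_bg,
        "positions": [[c, p] for c, p in bg_pos],
        "p0": p0.tolist(),
        "pop_freqs": {k: v.tolist() for k, v in pop_freqs.items()}}

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    calls = np.vstack(calls_list)
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    gm = GenotypeMatrix(sites.iloc[order].reset_index(drop=True),
                        list(samples), calls[order])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        catalog_io.write_vcf(gm, out / "genotypes.vcf",
                             contigs=spec.genome_extent)
        catalog_io.write_popmap(popmap, out / "popmap.tsv")
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return gm, popmap, truth


# ---------------------------------------------------------------------------
# Worked-example fixture
# ---------------------------------------------------------------------------

TABLE1_HET = {"ABCC2_GCins2bp": ["PR1", "PR18", "PR19", "PR27", "PR31",
                                 "PR33"],
              "ABCC2_ins12bp": ["rCC25", "rCC5"]}
TABLE1_HOM = {"ABCC2_GCins2bp": ["PR5", "PR12", "PR14", "PR16", "PR30"],
              "ABCC2_GYdel": ["CC44", "CC69"],
              "ABCC2_P799KR": ["CC44", "CC69"]}


def table1_fixture(n_pr: int = 33, n_cc: int = 6, n_rcc: int = 4,
                   out_dir: Optional[str | Path] = None
                   ) -> tuple[GenotypeMatrix, PopulationMap,
                              list[ResistanceMutation],
                              dict[str, GeneModel], dict[str, str]]:
    """The published worked example of ABCC2 carrier individuals.

    Encodes exactly: the 2 bp GC insertion heterozygous in PR1, PR18,
    PR19, PR27, PR31, PR33 and homozygous in PR5, PR12, PR14, PR16, PR30;
    the GY deletion and the P799R allele homozygous in CC44 and CC69; the
    12 bp insertion heterozygous in rCC25 and rCC5.  Non-carrier padding
    defaults: 33 Puerto Rico individuals (the highest published carrier
    index), 6 susceptible (CC) and 4 resistant (rCC) Brazilians.
    """
    if n_pr < 33 or n_cc < 2 or n_rcc < 2:
        raise ValidationError("fixture needs n_pr >= 33, n_cc >= 2, "
                              "n_rcc >= 2 to host the published carriers")
    pr = [f"PR{i}" for i in range(1, n_pr + 1)]
    cc = ["CC44", "CC69"] + [f"CC{i}" for i in range(1, n_cc - 1)]
    rcc = ["rCC5", "rCC25"] + [f"rCC{i}" for i in range(1, n_rcc - 1)]
    samples = pr + cc + rcc
    recs: dict[str, tuple[str, str, str]] = {}
    for s in pr:
        recs[s] = ("Puerto Rico", "native", "")
    for s in cc:
        recs[s] = ("Brazil", "native", "sfC")
    for s in rcc:
        recs[s] = ("Brazil", "native", "sfC")
    popmap = PopulationMap.from_records(recs)

    models, cds = synthetic_reference()
    overlays = _abcc2_variants()
    # P799K/R is screened through its protein spec; plant the R allele
    planted = ["ABCC2_GCins2bp", "ABCC2_GYdel", "ABCC2_P799KR",
               "ABCC2_ins12bp"]
    sidx = {s: j for j, s in enumerate(samples)}
    rows, calls_list = [], []
    for mut_id in planted:
        g = overlays[mut_id]
        site = np.zeros(len(samples), dtype=np.int8)
        for s in TABLE1_HET.get(mut_id, []):
            site[sidx[s]] = HET
        for s in TABLE1_HOM.get(mut_id, []):
            site[sidx[s]] = HOM_ALT
        rows.append({"chrom": g.chrom, "pos": g.pos, "ref": g.ref,
                     "alt": g.alt})
        calls_list.append(site)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    calls = np.vstack(calls_list)
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    gm = GenotypeMatrix(sites.iloc[order].reset_index(drop=True),
                        samples, calls[order])
    catalog = [m for m in catalog_with_genomic_specs()
               if m.gene_id == "ABCC2"]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        catalog_io.write_vcf(gm, out / "table1.vcf", contigs=GENOME_EXTENT)
        catalog_io.write_popmap(popmap, out / "popmap.tsv")
        catalog_io.write_catalog(catalog, out / "catalog.json")
        catalog_io.write_gene_models_bed12(models, out / "genes.bed")
        catalog_io.write_cds_fasta(cds, out / "cds.fasta")
    return gm, popmap, catalog, models, cds


# ---------------------------------------------------------------------------
# CNV simulation
# ---------------------------------------------------------------------------

def simulate_cnv(spec: SimSpec, out_dir: Optional[str | Path] = None
                 ) -> tuple[CnvStateTable, PopulationMap, dict]:
    """Per-individual per-clan Poisson duplication/deletion events.

    Event counts are drawn at the cohort's (dup_rate, del_rate) for each
    clan and assigned to distinct genes; a combined rate exceeding the
    clan's gene count is rejected up front, and the rare draw exceeding it
    is capped at the clan size (recorded counts in the truth dict are the
    realized ones).
    """
    for cohort, per_clan in spec.cnv_rates.items():
        for clan, (dup, dele) in per_clan.items():
            n_genes = len(spec.clan_genes.get(clan, []))
            if dup < 0 or dele < 0:
                raise ValidationError(f"negative CNV rate for {clan}")
            if dup + dele > n_genes:
                raise ValidationError(
                    f"{cohort}/{clan}: combined rate {dup + dele} exceeds "
                    f"the {n_genes} genes available")
    rng = np.random.default_rng(spec.seed + 1)  # independent of genotypes
    popmap = spec.popmap()
    genes = [g for gs in spec.clan_genes.values() for g in gs]
    clan_of_gene = {g: clan for clan, gs in spec.clan_genes.items()
                    for g in gs}
    states = pd.DataFrame("neutral", index=popmap.samples, columns=genes)
    truth: dict = {"seed": spec.seed, "events": {}}
    for s in popmap.samples:
        cohort = popmap.cohort(s)
        truth["events"][s] = {}
        for clan, gene_list in spec.clan_genes.items():
            dup_rate, del_rate = spec.cnv_rates[cohort][clan]
            k_dup = min(int(rng.poisson(dup_rate)), len(gene_list))
            k_del = min(int(rng.poisson(del_rate)), len(gene_list) - k_dup)
            perm = rng.permutation(gene_list)
            for g in perm[:k_dup]:
                states.at[s, g] = "duplicated"
            for g in perm[k_dup:k_dup + k_del]:
                states.at[s, g] = "deleted"
            truth["events"][s][clan] = {"duplicated": k_dup, "deleted": k_del}
    cnv = CnvStateTable(states, clan_of_gene)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        catalog_io.write_cnv_table(cnv, out / "cnv.tsv", out / "clans.tsv")
        catalog_io.write_popmap(popmap, out / "popmap.tsv")
        (out / "cnv_truth.json").write_text(json.dumps(truth, indent=1))
    return cnv, popmap, truth
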