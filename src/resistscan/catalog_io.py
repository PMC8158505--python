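"""Readers and writers for every external format the pipeline consumes.

VCF ingestion goes through cyvcf2; gene models come in as BED12 or
GFF3-lite CDS features; the mutation catalog as JSON (schema shipped under
``resistscan/data``) or TSV; population maps and CNV tables as TSV.  Each
reader returns the corresponding :mod:`resistscan.model` object and every
format round-trips through its writer.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (CNV_STATES, FormatError, GeneModel, GenomicSpec,
                    GenotypeMatrix, InFrameDeletion, InFrameInsertion,
                    Frameshift, MISSING, PopulationMap, ProteinSpec,
                    ResistanceMutation, Substitution, CnvStateTable,
                    ValidationError, copy_number_to_state)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Variant normalization
# ---------------------------------------------------------------------------

def trim_variant(pos1: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove shared suffix then shared prefix, keeping >=1 base per allele."""
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos1 += 1
    return pos1, ref, alt


def normalize_variant(chrom: str, pos1: int, ref: str, alt: str,
                      ref_seq: Optional[str] = None) -> GenomicSpec:
    """Left-align (when reference context is available) and trim.

    ``ref_seq`` is the full chromosome sequence (0-based indexing); without
    it only prefix/suffix trimming is applied.  Catalog and VCF records are
    both passed through here before matching, so a "2 bp GC insertion"
    written differently by two callers still compares equal.
    """
    pos1, ref, alt = trim_variant(pos1, ref, alt)
    if ref_seq is not None and len(ref) != len(alt):
        # canonical left-shift: while the variant ends with the base to its
        # left, roll it one base left and re-trim
        while True:
            if len(ref) > 1 and len(alt) > 1:
                pos1, ref, alt = trim_variant(pos1, ref, alt)
                continue
            if ref[-1] == alt[-1] and pos1 >= 2:
                left = ref_seq[pos1 - 2].upper()
                ref = left + ref[:-1]
                alt = left + alt[:-1]
                pos1 -= 1
                continue
            break
    return GenomicSpec(chrom, pos1, ref, alt)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path,
             region_filter: Optional[Sequence[tuple[str, int, int]]] = None,
             multiallelic: str = "split",
             reference: Optional[dict[str, str]] = None) -> GenotypeMatrix:
    """Read a VCF v4.x with GT into a biallelic :class:`GenotypeMatrix`.

    Parameters
    ----------
    region_filter
        Optional list of (chrom, start0, end0) half-open intervals; records
        outside every interval are dropped (and counted in the log).
    multiallelic
        "split" (default) decomposes each ALT into its own biallelic site at
        the same position; "reject" raises on multi-allelic records.
    reference
        Optional chrom -> sequence map used to left-align indels.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("split", "reject"):
        raise ValueError("multiallelic must be 'split' or 'reject'")
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise FormatError("duplicate sample names in VCF header")

    rows: list[dict] = []
    calls: list[np.ndarray] = []
    n_dropped_region = n_dropped_alt = 0
    for var in vcf:
        if var.FORMAT and "GT" not in var.FORMAT:
            raise FormatError(f"record {var.CHROM}:{var.POS} lacks GT")
        if not var.ALT:
            n_dropped_alt += 1
            continue
        if region_filter is not None:
            pos0 = var.POS - 1
            if not any(c == var.CHROM and s <= pos0 < e
                       for c, s, e in region_filter):
                n_dropped_region += 1
                continue
        if len(var.ALT) > 1 and multiallelic == "reject":
            raise FormatError(
                f"multi-allelic record at {var.CHROM}:{var.POS} "
                f"(policy 'reject')")
        gts = var.genotypes  # [a1, a2, phased] per sample
        for k, alt in enumerate(var.ALT, start=1):
            if alt in (".", "*"):
                n_dropped_alt += 1
                continue
            spec = normalize_variant(
                var.CHROM, var.POS, var.REF, alt,
                None if reference is None else reference.get(var.CHROM))
            site_calls = np.empty(len(samples), dtype=np.int8)
            for j, g in enumerate(gts):
                a = [x for x in g[:-1] if x is not None]
                if len(a) < 2 or any(x < 0 for x in a):
                    site_calls[j] = MISSING
                else:
                    site_calls[j] = int(a[0] == k) + int(a[1] == k)
            rows.append({"chrom": spec.chrom, "pos": spec.pos,
                         "ref": spec.ref, "alt": spec.alt})
            calls.append(site_calls)
    vcf.close()
    if n_dropped_region or n_dropped_alt:
        log.info("read_vcf: dropped %d records outside regions, "
                 "%d ALT-less/symbolic records", n_dropped_region, n_dropped_alt)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    arr = (np.vstack(calls) if calls
           else np.empty((0, len(samples)), dtype=np.int8))
    order = np.lexsort((sites["pos"].to_numpy(),
                        sites["chrom"].to_numpy())) if len(sites) else []
    if len(sites):
        sites = sites.iloc[order].reset_index(drop=True)
        arr = arr[order]
    return GenotypeMatrix(sites, samples, arr)


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              contigs: Optional[dict[str, int]] = None) -> None:
    """Write a GenotypeMatrix as a minimal VCF v4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=resistscan\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for i in range(gm.n_sites):
            chrom, pos, ref, alt = gm.site_key(i)
            gts = "\t".join(_GT_STRING[int(c)] for c in gm.calls[i])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df.columns = [c.lower() for c in df.columns]
    if "sample" not in df.columns:
        raise FormatError("population map needs a 'sample' column")
    return PopulationMap(df.set_index("sample"))


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    popmap.table.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Mutation catalog (JSON / TSV)
# ---------------------------------------------------------------------------

def _protein_spec_from_dict(d: dict) -> ProteinSpec:
    kind = d["kind"]
    if kind == "substitution":
        return Substitution(d["ref_aa"], int(d["codon_index"]),
                            frozenset(d["alt_aas"]))
    if kind == "in_frame_deletion":
        return InFrameDeletion(d["deleted_aa"], int(d["start_codon_index"]))
    if kind == "frameshift":
        stop = d.get("expected_premature_stop")
        return Frameshift(int(d["indel_length"]),
                          None if stop is None else int(stop))
    if kind == "in_frame_insertion":
        return InFrameInsertion(int(d["inserted_length"]),
                                bool(d.get("introduces_stop", False)))
    raise FormatError(f"unknown protein spec kind {kind!r}")


def _protein_spec_to_dict(p: ProteinSpec) -> dict:
    d = dataclasses.asdict(p)
    d["kind"] = p.kind
    if isinstance(p, Substitution):
        d["alt_aas"] = sorted(p.alt_aas)
    return d


def _mutation_from_dict(d: dict) -> ResistanceMutation:
    gspec = None
    if d.get("genomic"):
        g = d["genomic"]
        gspec = normalize_variant(g["chrom"], int(g["pos"]),
                                  g["ref"], g["alt"])
    pspec = _protein_spec_from_dict(d["protein"]) if d.get("protein") else None
    return ResistanceMutation(
        mutation_id=d["mutation_id"], gene_id=d["gene_id"],
        insecticide_class=d["insecticide_class"],
        origin_population=d.get("origin_population", ""),
        protein_spec=pspec, genomic_spec=gspec, note=d.get("note", ""))


def _mutation_to_dict(m: ResistanceMutation) -> dict:
    d: dict = {"mutation_id": m.mutation_id, "gene_id": m.gene_id,
               "insecticide_class": m.insecticide_class,
               "origin_population": m.origin_population}
    if m.protein_spec is not None:
        d["protein"] = _protein_spec_to_dict(m.protein_spec)
    if m.genomic_spec is not None:
        d["genomic"] = dataclasses.asdict(m.genomic_spec)
    if m.note:
        d["note"] = m.note
    return d


def read_catalog(path: str | Path,
                 gene_models: Optional[dict[str, GeneModel]] = None
                 ) -> list[ResistanceMutation]:
    """Read a resistance-mutation catalog (JSON or TSV by extension).

    With ``gene_models`` supplied, every codon index is range-checked
    against the protein length of its gene.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        warnings.warn(f"empty catalog file {path}")
        return []
    if path.suffix.lower() in (".json",):
        data = json.loads(path.read_text())
        entries = data["mutations"] if isinstance(data, dict) else data
        muts = [_mutation_from_dict(e) for e in entries]
    else:
        muts = _read_catalog_tsv(path)
    if not muts:
        warnings.warn(f"catalog {path} contains no entries")
    seen: set[str] = set()
    for m in muts:
        if m.mutation_id in seen:
            raise ValidationError(f"duplicate mutation_id {m.mutation_id}")
        seen.add(m.mutation_id)
    if gene_models is not None:
        validate_catalog(muts, gene_models)
    return muts


def validate_catalog(muts: Sequence[ResistanceMutation],
                     gene_models: dict[str, GeneModel]) -> None:
    for m in muts:
        gm = gene_models.get(m.gene_id)
        if gm is None:
            continue
        p = m.protein_spec
        idx = None
        if isinstance(p, Substitution):
            idx = p.codon_index
        elif isinstance(p, InFrameDeletion):
            idx = p.start_codon_index + len(p.deleted_aa) - 1
        if idx is not None and not 1 <= idx <= gm.protein_length:
            raise ValidationError(
                f"{m.mutation_id}: codon index {idx} beyond protein length "
                f"{gm.protein_length} of {m.gene_id}")


def _read_catalog_tsv(path: Path) -> list[ResistanceMutation]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    muts = []
    for _, r in df.iterrows():
        d: dict = {"mutation_id": r["mutation_id"], "gene_id": r["gene_id"],
                   "insecticide_class": r["insecticide_class"],
                   "origin_population": r.get("origin_population", "")}
        if r.get("chrom"):
            d["genomic"] = {"chrom": r["chrom"], "pos": r["pos"],
                            "ref": r["ref"], "alt": r["alt"]}
        if r.get("protein_kind"):
            pd_ = {"kind": r["protein_kind"]}
            pd_.update(json.loads(r["protein_detail"]))
            d["protein"] = pd_
        muts.append(_mutation_from_dict(d))
    return muts


def write_catalog(muts: Sequence[ResistanceMutation], path: str | Path) -> None:
    payload = {"schema": "resistscan-catalog-v1",
               "mutations": [_mutation_to_dict(m) for m in muts]}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def default_catalog() -> list[ResistanceMutation]:
    """The 13-entry shipped catalog: 5 ABCC2 (Bt), 3 AChE
    (organophosphate/carbamate), 3 VGSC (pyrethroid), 2 RyR (diamide)."""
    path = resources.files("resistscan").joinpath("data/catalog.json")
    with path.open() as fh:
        data = json.load(fh)
    return [_mutation_from_dict(e) for e in data["mutations"]]


# ---------------------------------------------------------------------------
# Gene models (BED12 / GFF3-lite) and CDS sequences
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read gene models from BED12 (blocks = CDS exons) or GFF3 CDS lines."""
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    if first.count("\t") >= 8 and first.split("\t")[6] in "+-.":
        return _read_gff3_cds(path)
    return _read_bed12(path)


def _read_bed12(path: Path) -> dict[str, GeneModel]:
    models = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"BED12 line with {len(f)} fields")
            chrom, start = f[0], int(f[1])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + s, start + s + L)
                          for s, L in zip(starts, sizes))
            models[name] = GeneModel(name, chrom, strand, exons)
    return models


def _read_gff3_cds(path: Path) -> dict[str, GeneModel]:
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gene = attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID")
            if gene is None:
                raise FormatError("GFF3 CDS line without gene_id/Parent/ID")
            rec = per_gene.setdefault(
                gene, {"chrom": f[0], "strand": f[6], "exons": [],
                       "protein_id": attrs.get("protein_id", "")})
            rec["exons"].append((int(f[3]) - 1, int(f[4])))
    return {g: GeneModel(g, r["chrom"], r["strand"], tuple(sorted(r["exons"])),
                         r["protein_id"])
            for g, r in per_gene.items()}


def write_gene_models_bed12(models: dict[str, GeneModel],
                            path: str | Path) -> None:
    with open(path, "w") as fh:
        for gm in models.values():
            exons = sorted(gm.cds_exons)
            start, end = exons[0][0], exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - start) for s, _ in exons)
            fh.write("\t".join(map(str, [
                gm.chrom, start, end, gm.gene_id, 0, gm.strand, start, end,
                "0,0,0", len(exons), sizes, starts])) + "\n")


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """gene_id -> spliced reference CDS sequence (5'->3')."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_cds_fasta(cds: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, seq in cds.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# CNV table
# ---------------------------------------------------------------------------

def read_clan_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    return dict(zip(df["gene"], df["clan"]))


def write_clan_map(clan_of_gene: dict[str, str], path: str | Path) -> None:
    pd.DataFrame({"gene": list(clan_of_gene),
                  "clan": list(clan_of_gene.values())}
                 ).to_csv(path, sep="\t", index=False)


def read_cnv_table(path: str | Path,
                   clan_map_path: str | Path) -> CnvStateTable:
    """Read a long-format TSV (sample, gene, copy_number or state).

    Integer copy numbers are mapped to states by the diploid convention
    (<2 deleted, ==2 neutral, >2 duplicated).  Genes absent from the clan
    map are assigned clan "other" with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    value_col = next((c for c in ("state", "copy_number") if c in df.columns),
                     None)
    if value_col is None or not {"sample", "gene"} <= set(df.columns):
        raise FormatError(
            "CNV table needs columns sample, gene, and state|copy_number")
    if value_col == "copy_number":
        df["state"] = [copy_number_to_state(int(x)) for x in df["copy_number"]]
    else:
        bad = set(df["state"]) - set(CNV_STATES)
        if bad:
            raise FormatError(f"unknown CNV states {sorted(bad)}")
    wide = df.pivot_table(index="sample", columns="gene", values="state",
                          aggfunc="first")
    if wide.isna().any().any():
        wide = wide.fillna("neutral")
        warnings.warn("CNV table incomplete; missing sample x gene cells "
                      "treated as neutral (copy number 2)")
    clan = read_clan_map(clan_map_path)
    orphans = sorted(set(wide.columns) - set(clan))
    if orphans:
        warnings.warn(f"genes absent from clan map assigned 'other': {orphans}")
        for g in orphans:
            clan[g] = "other"
    return CnvStateTable(wide, {g: clan[g] for g in wide.columns})


def write_cnv_table(cnv: CnvStateTable, path: str | Path,
                    clan_map_path: Optional[str | Path] = None) -> None:
    long = (cnv.states.stack().rename("state").reset_index())
    long.columns = ["sample", "gene", "state"]
    long.to_csv(path, sep="\t", index=False)
    if clan_map_path is not None:
        write_clan_map(cnv.clan_of_gene, clan_map_path)
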