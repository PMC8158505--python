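"""Shared in-memory data model.

Coordinate conventions
----------------------
External formats keep their native conventions (VCF and mutation-catalog
positions are 1-based; BED intervals are 0-based half-open).  Everything
internal — exon lists, CDS indices, window arithmetic — is 0-based
half-open.  :func:`to_zero_based` / :func:`to_one_based` are the only
conversion points and are exact inverses.

Genotype calls are stored as a small integer code per sample per site:
0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

ZYGOSITY_LABELS = {HOM_REF: "absent", HET: "heterozygous",
                   HOM_ALT: "homozygous", MISSING: "missing"}


def to_zero_based(pos1: int) -> int:
    """1-based position -> 0-based index."""
    return pos1 - 1


def to_one_based(pos0: int) -> int:
    """0-based index -> 1-based position."""
    return pos0 + 1


class FormatError(ValueError):
    """A file violates its format contract (missing GT, bad field...)."""


class ValidationError(ValueError):
    """An object violates a data-model invariant."""


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """CDS structure of one protein-coding gene.

    ``cds_exons`` are genomic 0-based half-open intervals stored in
    transcription order (ascending start for '+' genes, descending for
    '-' genes).  ``codon_index`` arguments throughout the package count
    from the initiator Met = 1.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        exons = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValidationError(f"{self.gene_id}: overlapping CDS exons")
        for s, e in exons:
            if e <= s:
                raise ValidationError(f"{self.gene_id}: empty CDS exon {s}-{e}")
        want = tuple(exons) if self.strand == "+" else tuple(exons[::-1])
        if tuple(self.cds_exons) != want:
            object.__setattr__(self, "cds_exons", want)
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exons)

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3 - 1  # excludes the stop codon

    @property
    def span(self) -> tuple[int, int]:
        """Genomic 0-based half-open extent (first to last CDS base)."""
        starts = [s for s, _ in self.cds_exons]
        ends = [e for _, e in self.cds_exons]
        return min(starts), max(ends)

    def genomic_to_cds(self, pos0: int) -> Optional[int]:
        """0-based genomic position -> 0-based CDS index, or None if intronic/outside."""
        offset = 0
        for s, e in self.cds_exons:
            if s <= pos0 < e:
                if self.strand == "+":
                    return offset + (pos0 - s)
                return offset + (e - 1 - pos0)
            offset += e - s
        return None

    def cds_to_genomic(self, cds_i: int) -> int:
        """Inverse of :meth:`genomic_to_cds`."""
        if not 0 <= cds_i < self.cds_length:
            raise IndexError(f"CDS index {cds_i} outside [0, {self.cds_length})")
        offset = 0
        for s, e in self.cds_exons:
            n = e - s
            if cds_i < offset + n:
                k = cds_i - offset
                return s + k if self.strand == "+" else e - 1 - k
            offset += n
        raise AssertionError("unreachable")

    def codon_genomic_positions(self, codon_index: int) -> list[int]:
        """Genomic 0-based positions of a 1-based codon's three bases (5'->3')."""
        i0 = 3 * (codon_index - 1)
        return [self.cds_to_genomic(i0 + k) for k in range(3)]

    def classify_position(self, chrom: str, pos0: int) -> str:
        if chrom != self.chrom:
            return "intergenic"
        lo, hi = self.span
        if not lo <= pos0 < hi:
            return "intergenic"
        return "exonic" if self.genomic_to_cds(pos0) is not None else "intronic"


# ---------------------------------------------------------------------------
# Resistance-mutation catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicSpec:
    """Left-aligned, trimmed genomic change (1-based position)."""
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class Substitution:
    ref_aa: str
    codon_index: int
    alt_aas: frozenset[str]  # P799K/R -> {'K','R'}

    kind = "substitution"


@dataclass(frozen=True)
class InFrameDeletion:
    deleted_aa: str
    start_codon_index: int

    kind = "in_frame_deletion"


@dataclass(frozen=True)
class Frameshift:
    indel_length: int
    expected_premature_stop: Optional[int] = None

    kind = "frameshift"


@dataclass(frozen=True)
class InFrameInsertion:
    """In-frame insertion; ``introduces_stop`` marks a premature stop inside
    the inserted sequence (loss-of-function without a frameshift)."""
    inserted_length: int
    introduces_stop: bool = False

    kind = "in_frame_insertion"


ProteinSpec = Substitution | InFrameDeletion | Frameshift | InFrameInsertion


@dataclass(frozen=True)
class ResistanceMutation:
    mutation_id: str
    gene_id: str
    insecticide_class: str
    origin_population: str
    protein_spec: Optional[ProteinSpec] = None
    genomic_spec: Optional[GenomicSpec] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.protein_spec is None and self.genomic_spec is None:
            raise ValidationError(
                f"{self.mutation_id}: needs a protein or genomic specification")
        g, p = self.genomic_spec, self.protein_spec
        if g is not None and p is not None:
            dlen = abs(len(g.alt) - len(g.ref))
            is_fs = isinstance(p, Frameshift)
            if is_fs != (dlen % 3 != 0):
                raise ValidationError(
                    f"{self.mutation_id}: frameshift flag inconsistent with "
                    f"indel length {dlen} (mod 3 = {dlen % 3})")

    def with_genomic(self, spec: GenomicSpec) -> "ResistanceMutation":
        return dataclasses.replace(self, genomic_spec=spec)


INSECTICIDE_CLASSES = {"Bt", "organophosphate/carbamate", "pyrethroid", "diamide"}


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

@dataclass
class PopulationMap:
    """sample -> (population, cohort[, strain]) with cohort in {native, invasive}."""

    table: pd.DataFrame  # index sample_id; columns population, cohort, strain

    def __post_init__(self) -> None:
        req = {"population", "cohort"}
        if not req <= set(self.table.columns):
            raise FormatError(f"population map needs columns {sorted(req)}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate samples in population map: {dups}")
        bad = set(self.table["cohort"]) - {"native", "invasive"}
        if bad:
            raise ValidationError(f"unknown cohorts {sorted(bad)}")
        if "strain" not in self.table.columns:
            self.table["strain"] = ""

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def population(self, sample: str) -> str:
        return self.table.at[sample, "population"]

    def cohort(self, sample: str) -> str:
        return self.table.at[sample, "cohort"]

    def cohort_samples(self, cohort: str) -> list[str]:
        return list(self.table.index[self.table["cohort"] == cohort])

    def require_cover(self, samples: Iterable[str]) -> None:
        missing = sorted(set(samples) - set(self.table.index))
        extra = sorted(set(self.table.index) - set(samples))
        if missing:
            raise ValidationError(
                f"samples absent from population map: {missing}; "
                f"map-only samples: {extra}")

    @classmethod
    def from_records(cls, records: dict[str, tuple[str, str] | tuple[str, str, str]]
                     ) -> "PopulationMap":
        rows = {}
        for s, rec in records.items():
            pop, cohort = rec[0], rec[1]
            strain = rec[2] if len(rec) > 2 else ""
            rows[s] = {"population": pop, "cohort": cohort, "strain": strain}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "sample"
        return cls(df)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic sites x samples, diploid calls with explicit missingness.

    ``sites`` has columns chrom, pos (1-based), ref, alt; ``calls`` is an
    int8 array of shape (n_sites, n_samples) using the module-level codes.
    Positions are non-decreasing within each chromosome (split
    multi-allelics legitimately share a position).
    """

    sites: pd.DataFrame
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValidationError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sites)}, {len(self.samples)})")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValidationError(f"{chrom}: positions not sorted")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_key(self, i: int) -> tuple[str, int, str, str]:
        row = self.sites.iloc[i]
        return (row["chrom"], int(row["pos"]), row["ref"], row["alt"])

    def site_lookup(self) -> dict[tuple[str, int, str, str], int]:
        return {self.site_key(i): i for i in range(self.n_sites)}

    def sample_index(self, samples: Iterable[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        return np.array([idx[s] for s in samples], dtype=np.intp)

    def in_region(self, chrom: str, start0: int, end0: int) -> np.ndarray:
        """Boolean mask of sites whose (1-based) position falls in the
        0-based half-open genomic window [start0, end0)."""
        pos0 = self.sites["pos"].to_numpy() - 1
        return ((self.sites["chrom"] == chrom).to_numpy()
                & (pos0 >= start0) & (pos0 < end0))

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sites.loc[np.asarray(mask)].copy(),
                              list(self.samples), self.calls[np.asarray(mask)])


# ---------------------------------------------------------------------------
# CNV states
# ---------------------------------------------------------------------------

CNV_STATES = ("deleted", "neutral", "duplicated")


def copy_number_to_state(cn: int) -> str:
    """Diploid convention: <2 deleted, ==2 neutral, >2 duplicated."""
    if cn < 0:
        raise ValidationError(f"negative copy number {cn}")
    return "deleted" if cn < 2 else ("neutral" if cn == 2 else "duplicated")


@dataclass
class CnvStateTable:
    """Per-sample per-gene CNV state plus a gene -> clan annotation."""

    states: pd.DataFrame      # index sample, columns gene, values in CNV_STATES
    clan_of_gene: dict[str, str]

    def __post_init__(self) -> None:
        bad = set(np.unique(self.states.to_numpy())) - set(CNV_STATES)
        if bad:
            raise ValidationError(f"unknown CNV states {sorted(bad)}")
        missing = set(self.states.columns) - set(self.clan_of_gene)
        if missing:
            raise ValidationError(
                f"genes without clan assignment: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.states.index)

    @property
    def genes(self) -> list[str]:
        return list(self.states.columns)

    @property
    def clans(self) -> list[str]:
        return sorted(set(self.clan_of_gene[g] for g in self.genes))
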