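from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import resistscan.catalog_io as cio
from resistscan.model import (FormatError, GeneModel, GenotypeMatrix,
                              PopulationMap, ValidationError,
                              copy_number_to_state, to_one_based,
                              to_zero_based)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')


def write_vcf_text(path, body, samples=("s1", "s2", "s3")):
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    path.write_text(VCF_HEADER + cols + "\t".join(samples) + "\n" + body)


class TestReadVcf:
    def test_gt_codes_map_to_dosage(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf_text(p, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        gm = cio.read_vcf(p)
        assert gm.samples == ["s1", "s2", "s3"]
        assert gm.calls.tolist() == [[0, 1, 2]]

    def test_missing_and_phased_genotypes(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf_text(p, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t0|1\t1|1\n")
        gm = cio.read_vcf(p)
        assert gm.calls.tolist() == [[-1, 1, 2]]

    def test_two_bp_insertion_alt_ref_length(self, tmp_path):
        # insertion record like the catalog's 2 bp GC change
        p = tmp_path / "a.vcf"
        write_vcf_text(p, "chr1\t500\t.\tT\tTGC\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n")
        gm = cio.read_vcf(p)
        chrom, pos, ref, alt = gm.site_key(0)
        assert len(alt) - len(ref) == 2

    def test_multiallelic_split_matches_manual_split(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf_text(p, "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2\t2/2\n")
        gm = cio.read_vcf(p, multiallelic="split")
        # manual decomposition: alt G -> dosages (1,1,0); alt T -> (0,1,2)
        assert gm.n_sites == 2
        assert {gm.site_key(0)[3], gm.site_key(1)[3]} == {"G", "T"}
        by_alt = {gm.site_key(i)[3]: gm.calls[i].tolist() for i in range(2)}
        assert by_alt["G"] == [1, 1, 0]
        assert by_alt["T"] == [0, 1, 2]
        assert gm.site_key(0)[1] == gm.site_key(1)[1] == 100

    def test_multiallelic_reject_policy(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf_text(p, "chr1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t1/2\t2/2\n")
        with pytest.raises(FormatError, match="multi-allelic"):
            cio.read_vcf(p, multiallelic="reject")

    def test_region_filter_drops_outside_records(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf_text(p, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1\n"
                          "chr1\t900\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n")
        gm = cio.read_vcf(p, region_filter=[("chr1", 0, 500)])
        assert gm.n_sites == 1 and gm.site_key(0)[1] == 100

    def test_no_samples_silently_dropped(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_vcf_text(p, "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        gm = cio.read_vcf(p)
        assert gm.n_samples == 3

    def test_roundtrip_write_then_read(self, tmp_path):
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [5, 9],
                              "ref": ["A", "CT"], "alt": ["G", "C"]})
        calls = np.array([[0, 1, 2, -1], [2, 2, 0, 1]], dtype=np.int8)
        gm = GenotypeMatrix(sites, ["a", "b", "c", "d"], calls)
        path = tmp_path / "rt.vcf"
        cio.write_vcf(gm, path, contigs={"chr1": 1000})
        back = cio.read_vcf(path)
        assert back.samples == gm.samples
        assert back.calls.tolist() == gm.calls.tolist()
        assert back.sites.equals(gm.sites)


class TestNormalization:
    def test_trim_shared_suffix_and_prefix(self):
        spec = cio.normalize_variant("c", 100, "CAGT", "CCGT")
        assert (spec.pos, spec.ref, spec.alt) == (101, "A", "C")

    def test_left_align_with_reference(self):
        # TA deletion in a TATA run must shift to the run's left edge
        ref_seq = "GGTATATACC"
        right = cio.normalize_variant("c", 6, "ATA", "A", ref_seq=ref_seq)
        assert (right.pos, right.ref, right.alt) == (2, "GTA", "G")
        # already-left-aligned representation is a fixed point
        again = cio.normalize_variant("c", 2, "GTA", "G", ref_seq=ref_seq)
        assert again == right

    @given(st.integers(2, 50), st.text("ACGT", min_size=1, max_size=6),
           st.text("ACGT", min_size=1, max_size=6))
    def test_trim_is_idempotent(self, pos, ref, alt):
        p1, r1, a1 = cio.trim_variant(pos, ref, alt)
        assert (p1, r1, a1) == cio.trim_variant(p1, r1, a1)

    @given(st.integers(0, 10_000))
    def test_coordinate_conversions_are_inverses(self, pos0):
        assert to_zero_based(to_one_based(pos0)) == pos0


class TestCatalog:
    def test_shipped_catalog_has_13_entries(self):
        cat = cio.default_catalog()
        assert len(cat) == 13
        by_gene = {}
        for m in cat:
            by_gene.setdefault(m.gene_id, []).append(m)
        assert {g: len(v) for g, v in by_gene.items()} == {
            "ABCC2": 5, "AChE": 3, "VGSC": 3, "RyR": 2}

    def test_empty_file_gives_empty_catalog_with_warning(self, tmp_path):
        p = tmp_path / "empty.json"
        p.write_text("")
        with pytest.warns(UserWarning):
            assert cio.read_catalog(p) == []

    def test_codon_index_beyond_protein_length_rejected(self, tmp_path,
                                                        reference):
        models, _ = reference
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"mutations": [{
            "mutation_id": "x", "gene_id": "AChE",
            "insecticide_class": "Bt", "origin_population": "",
            "protein": {"kind": "substitution", "ref_aa": "A",
                        "codon_index": 9999, "alt_aas": ["S"]}}]}))
        with pytest.raises(ValidationError, match="beyond protein length"):
            cio.read_catalog(p, models)

    def test_frameshift_flag_must_match_indel_length(self):
        from resistscan.model import (Frameshift, GenomicSpec,
                                      ResistanceMutation)

        with pytest.raises(ValidationError, match="frameshift flag"):
            ResistanceMutation(
                "x", "ABCC2", "Bt", "", protein_spec=Frameshift(3),
                genomic_spec=GenomicSpec("chr1", 10, "A", "AGGG"))

    def test_json_roundtrip(self, tmp_path):
        cat = cio.default_catalog()
        p = tmp_path / "cat.json"
        cio.write_catalog(cat, p)
        assert cio.read_catalog(p) == cat


class TestGeneModels:
    def test_bed12_roundtrip(self, tmp_path, reference):
        models, _ = reference
        p = tmp_path / "genes.bed"
        cio.write_gene_models_bed12(models, p)
        back = cio.read_gene_models(p)
        assert back == models

    def test_gff3_cds_reader(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "chr9\tsrc\tgene\t1\t500\t.\t+\t.\tID=g1\n"
            "chr9\tsrc\tCDS\t11\t40\t.\t+\t0\tParent=g1\n"
            "chr9\tsrc\tCDS\t101\t130\t.\t+\t0\tParent=g1\n")
        models = cio.read_gene_models(p)
        assert models["g1"].cds_exons == ((10, 40), (100, 130))
        assert models["g1"].cds_length == 60

    def test_minus_strand_exons_in_transcription_order(self):
        gm = GeneModel("g", "c", "-", ((10, 16), (30, 36)))
        assert gm.cds_exons == ((30, 36), (10, 16))
        # first CDS base is the last base of the rightmost exon
        assert gm.cds_to_genomic(0) == 35
        assert gm.genomic_to_cds(35) == 0

    def test_genomic_cds_conversion_inverse(self, reference):
        models, _ = reference
        for gm in models.values():
            for cds_i in (0, 1, gm.cds_length // 2, gm.cds_length - 1):
                assert gm.genomic_to_cds(gm.cds_to_genomic(cds_i)) == cds_i

    def test_cds_length_must_be_multiple_of_three(self):
        with pytest.raises(ValidationError, match="divisible by 3"):
            GeneModel("g", "c", "+", ((0, 10),))


class TestPopmap:
    def test_roundtrip(self, tmp_path):
        pm = PopulationMap.from_records(
            {"a": ("X", "native", "sfC"), "b": ("Y", "invasive")})
        p = tmp_path / "pm.tsv"
        cio.write_popmap(pm, p)
        back = cio.read_popmap(p)
        assert list(back.table.index) == ["a", "b"]
        assert back.cohort("b") == "invasive"

    def test_sample_mismatch_reports_set_difference(self):
        pm = PopulationMap.from_records({"a": ("X", "native")})
        with pytest.raises(ValidationError, match=r"\['b'\]"):
            pm.require_cover(["a", "b"])

    def test_unknown_cohort_rejected(self):
        with pytest.raises(ValidationError, match="unknown cohorts"):
            PopulationMap.from_records({"a": ("X", "resistant")})


class TestCnvTable:
    def test_copy_number_thresholds(self):
        assert [copy_number_to_state(c) for c in (0, 1, 2, 3, 4)] == \
            ["deleted", "deleted", "neutral", "duplicated", "duplicated"]

    def test_all_twos_read_as_neutral(self, tmp_path):
        (tmp_path / "cnv.tsv").write_text(
            "sample\tgene\tcopy_number\ns1\tg1\t2\ns1\tg2\t2\ns2\tg1\t2\n"
            "s2\tg2\t2\n")
        (tmp_path / "clans.tsv").write_text("gene\tclan\ng1\tclan2\ng2\tclan3\n")
        cnv = cio.read_cnv_table(tmp_path / "cnv.tsv", tmp_path / "clans.tsv")
        assert (cnv.states == "neutral").all().all()

    def test_gene_missing_from_clan_map_becomes_other(self, tmp_path):
        (tmp_path / "cnv.tsv").write_text(
            "sample\tgene\tstate\ns1\tg1\tduplicated\ns1\tg2\tdeleted\n")
        (tmp_path / "clans.tsv").write_text("gene\tclan\ng1\tclan2\n")
        with pytest.warns(UserWarning, match="other"):
            cnv = cio.read_cnv_table(tmp_path / "cnv.tsv",
                                     tmp_path / "clans.tsv")
        assert cnv.clan_of_gene["g2"] == "other"

    def test_simulated_table_roundtrips(self, tmp_path):
        from resistscan.simulate import SimSpec, simulate_cnv

        cnv, _, _ = simulate_cnv(SimSpec(
            seed=11, populations=[("p1", "invasive", 5), ("p2", "native", 5)]))
        cio.write_cnv_table(cnv, tmp_path / "cnv.tsv", tmp_path / "clans.tsv")
        back = cio.read_cnv_table(tmp_path / "cnv.tsv", tmp_path / "clans.tsv")
        assert back.clan_of_gene == cnv.clan_of_gene
        pd.testing.assert_frame_equal(
            back.states.sort_index(axis=0).sort_index(axis=1),
            cnv.states.sort_index(axis=0).sort_index(axis=1),
            check_names=False)
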