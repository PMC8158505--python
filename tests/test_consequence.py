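from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from resistscan.consequence import (UnsupportedVariantError,
                                    annotate_consequence, codon_spectrum,
                                    cohort_contrast, screen)
from resistscan.model import (GeneModel, GenomicSpec, GenotypeMatrix,
                              PopulationMap, ValidationError)
from resistscan.simulate import SimSpec, simulate_genotypes

from oracles import fisher_oracle, translate_oracle


class TestAnnotateSNV:
    def test_random_snvs_agree_with_codon_table_oracle(self, reference, rng):
        """Translation-level classification of 200 random coding SNVs must
        match an independent table-lookup oracle, on both strands."""
        models, cds = reference
        for gene in ("ABCC2", "VGSC"):  # '+' and '-' strand
            gm, seq = models[gene], cds[gene]
            for _ in range(100):
                cds_i = int(rng.integers(3, gm.cds_length - 3))
                ref_base = seq[cds_i]
                alt_base = rng.choice([b for b in "ACGT" if b != ref_base])
                pos0 = gm.cds_to_genomic(cds_i)
                if gm.strand == "+":
                    g_ref, g_alt = ref_base, alt_base
                else:
                    comp = dict(zip("ACGT", "TGCA"))
                    g_ref, g_alt = comp[ref_base], comp[alt_base]
                cons = annotate_consequence(
                    GenomicSpec(gm.chrom, pos0 + 1, g_ref, g_alt), gm, seq)
                codon_i = cds_i // 3
                ref_codon = seq[3 * codon_i: 3 * codon_i + 3]
                alt_codon = (ref_codon[:cds_i % 3] + alt_base
                             + ref_codon[cds_i % 3 + 1:])
                aa_ref = translate_oracle(ref_codon)
                aa_alt = translate_oracle(alt_codon)
                if aa_ref == aa_alt:
                    assert cons.kind == "synonymous"
                elif aa_alt == "*":
                    assert cons.kind == "stop_gained"
                    assert cons.premature_stop_codon_index == codon_i + 1
                else:
                    assert cons.kind == "missense"
                    assert cons.protein_change == \
                        f"p.{aa_ref}{codon_i + 1}{aa_alt}"

    def test_synonymous_ala_codon_third_position(self, reference):
        # GCG -> GCA at the screened AChE codon 201 (both encode Ala)
        models, cds = reference
        gm, seq = models["AChE"], cds["AChE"]
        pos0 = gm.cds_to_genomic(3 * 200 + 2)
        cons = annotate_consequence(
            GenomicSpec(gm.chrom, pos0 + 1, "G", "A"), gm, seq)
        assert cons.kind == "synonymous"
        assert cons.protein_change == "p.A201="

    def test_variant_outside_cds_is_non_coding(self, reference):
        models, cds = reference
        gm, seq = models["ABCC2"], cds["ABCC2"]
        intron_pos1 = 101_500  # between ABCC2 exons 1 and 2
        cons = annotate_consequence(
            GenomicSpec("chr1", intron_pos1, "A", "T"), gm, seq)
        assert cons.kind == "non_coding"


class TestAnnotateIndels:
    def test_two_bp_insertion_is_frameshift_with_premature_stop(
            self, reference):
        models, cds = reference
        gm, seq = models["ABCC2"], cds["ABCC2"]
        from resistscan.simulate import _abcc2_variants

        v = _abcc2_variants()["ABCC2_GCins2bp"]
        cons = annotate_consequence(v, gm, seq)
        assert cons.kind == "frameshift"
        assert cons.premature_stop_codon_index is not None
        assert cons.premature_stop_codon_index < gm.protein_length

    def test_six_bp_deletion_reports_gy_del(self, reference):
        models, cds = reference
        gm, seq = models["ABCC2"], cds["ABCC2"]
        from resistscan.simulate import _abcc2_variants

        v = _abcc2_variants()["ABCC2_GYdel"]
        cons = annotate_consequence(v, gm, seq)
        assert cons.kind == "in_frame_indel"
        assert cons.protein_change == "p.GY-del"

    def test_twelve_bp_insertion_with_internal_stop_is_stop_gained(
            self, reference):
        models, cds = reference
        gm, seq = models["ABCC2"], cds["ABCC2"]
        from resistscan.simulate import _abcc2_variants

        v = _abcc2_variants()["ABCC2_ins12bp"]
        cons = annotate_consequence(v, gm, seq)
        assert cons.kind == "stop_gained"
        assert cons.premature_stop_codon_index == 870

    def test_exon_boundary_spanning_allele_is_explicit_error(self, reference):
        models, cds = reference
        gm, seq = models["ABCC2"], cds["ABCC2"]
        # deletion whose REF reaches past the exon-1 end (101_200)
        pos1 = 101_199
        ref = "N" * 5
        with pytest.raises(UnsupportedVariantError):
            annotate_consequence(GenomicSpec("chr1", pos1, ref, "N"), gm, seq)

    def test_minus_strand_snv(self, reference):
        # VGSC T929I: CDS ACA->ATA; genomic change is on the minus strand
        models, cds = reference
        gm, seq = models["VGSC"], cds["VGSC"]
        cds_i = 3 * 928 + 1
        pos0 = gm.cds_to_genomic(cds_i)
        # CDS middle base C -> T is genomic G -> A
        cons = annotate_consequence(
            GenomicSpec(gm.chrom, pos0 + 1, "G", "A"), gm, seq)
        assert cons.kind == "missense"
        assert cons.protein_change == "p.T929I"


class TestScreen:
    def test_published_carrier_sets_recovered_exactly(self, table1):
        gm, popmap, catalog, models, cds = table1
        res = screen(gm, catalog, models, popmap, cds)
        pr = res.carriers("ABCC2_GCins2bp", population="Puerto Rico")
        assert pr == sorted(["PR1", "PR5", "PR12", "PR14", "PR16", "PR18",
                             "PR19", "PR27", "PR30", "PR31", "PR33"])
        het = {s for s in pr if res.zygosity(s, "ABCC2_GCins2bp")
               == "heterozygous"}
        assert het == {"PR1", "PR18", "PR19", "PR27", "PR31", "PR33"}
        assert res.carriers("ABCC2_GYdel") == ["CC44", "CC69"]
        assert all(res.zygosity(s, "ABCC2_GYdel") == "homozygous"
                   for s in ("CC44", "CC69"))
        assert res.carriers("ABCC2_P799KR") == ["CC44", "CC69"]
        assert res.carriers("ABCC2_ins12bp") == ["rCC25", "rCC5"]
        assert all(res.zygosity(s, "ABCC2_ins12bp") == "heterozygous"
                   for s in ("rCC25", "rCC5"))
        assert res.carriers("ABCC2_G1088D") == []

    def test_planted_carriers_recovered(self):
        spec = SimSpec(seed=42, n_background_loci=50,
                       catalog_site_freqs={
                           "ABCC2_GCins2bp": {"invasive_pop": 0.15,
                                              "native_pop": 0.0},
                           "ABCC2_G1088D": {"invasive_pop": 0.0,
                                            "native_pop": 0.3}})
        gm, popmap, truth = simulate_genotypes(spec)
        from resistscan.simulate import catalog_with_genomic_specs, \
            synthetic_reference

        models, cds = synthetic_reference()
        res = screen(gm, catalog_with_genomic_specs(), models, popmap, cds)
        for mut_id in ("ABCC2_GCins2bp", "ABCC2_G1088D"):
            assert set(res.carriers(mut_id)) == \
                set(truth["mutation_carriers"][mut_id])

    def test_empty_catalog_gives_zero_rows(self, table1):
        gm, popmap, _, models, cds = table1
        res = screen(gm, [], models, popmap, cds)
        assert len(res.per_sample) == 0

    def test_missing_gene_model_skips_with_warning(self, table1):
        import dataclasses

        gm, popmap, catalog, _, _ = table1
        stripped = [dataclasses.replace(m, genomic_spec=None)
                    for m in catalog]
        res = screen(gm, stripped, {}, popmap, {})
        assert set(res.skipped_mutations) == {m.mutation_id for m in catalog}

    def test_zygosity_conservation(self, table1):
        gm, popmap, catalog, models, cds = table1
        res = screen(gm, catalog, models, popmap, cds)
        counts = res.per_sample.groupby("mutation_id")["zygosity"].count()
        assert (counts == gm.n_samples).all()

    def test_sample_order_permutation_equivariance(self, table1, rng):
        gm, popmap, catalog, models, cds = table1
        perm = rng.permutation(gm.n_samples)
        gm2 = GenotypeMatrix(gm.sites.copy(),
                             [gm.samples[i] for i in perm],
                             gm.calls[:, perm])
        r1 = screen(gm, catalog, models, popmap, cds)
        r2 = screen(gm2, catalog, models, popmap, cds)
        key = ["group", "mutation_id"]
        pd.testing.assert_frame_equal(
            r1.per_population.sort_values(key).reset_index(drop=True),
            r2.per_population.sort_values(key).reset_index(drop=True))

    def test_missing_genotypes_leave_denominator(self, table1):
        gm, popmap, catalog, models, cds = table1
        gm2 = GenotypeMatrix(gm.sites.copy(), list(gm.samples),
                             gm.calls.copy())
        site = gm2.site_lookup()[
            next((c, p, r, a) for c, p, r, a in map(gm2.site_key,
                                                    range(gm2.n_sites))
                 if len(a) - len(r) == 2)]
        gm2.calls[site, :3] = -1  # first three samples uncalled
        res = screen(gm2, catalog, models, popmap, cds)
        row = res.per_cohort[(res.per_cohort["mutation_id"]
                              == "ABCC2_GCins2bp")]
        assert int(row["n_genotyped"].iloc[0]) == gm.n_samples - 3


class TestCohortContrast:
    @staticmethod
    def _result_with_counts(inv, native):
        """ScreeningResult stub with given (carriers, n) per cohort."""
        from resistscan.consequence import ScreeningResult

        per_cohort = pd.DataFrame([
            ("invasive", "m", inv[0], inv[1], inv[0] / inv[1], 0.1),
            ("native", "m", native[0], native[1], native[0] / native[1], 0.1)],
            columns=["group", "mutation_id", "carrier_count", "n_genotyped",
                     "proportion", "allele_frequency"])
        empty = pd.DataFrame()
        return ScreeningResult(empty, empty,
                               per_cohort.drop(columns="allele_frequency"),
                               per_cohort)

    def test_p_matches_enumeration_oracle(self):
        res = self._result_with_counts((61, 76), (55, 76))
        table, p, _ = cohort_contrast(res, "m")
        assert table.tolist() == [[61, 15], [55, 21]]
        assert p == pytest.approx(fisher_oracle([[61, 15], [55, 21]]),
                                  rel=1e-10)

    def test_identical_proportions_give_p_one(self):
        res = self._result_with_counts((30, 60), (30, 60))
        _, p, _ = cohort_contrast(res, "m")
        assert p == pytest.approx(1.0)

    def test_fully_separated_cohorts(self):
        res = self._result_with_counts((10, 10), (0, 10))
        _, p, _ = cohort_contrast(res, "m")
        # two extreme tables of C(20,10) equally likely arrangements
        import math

        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_zero_genotyped_cohort_is_error(self):
        from resistscan.consequence import ScreeningResult

        per_cohort = pd.DataFrame(
            [("invasive", "m", 0, 0, np.nan), ("native", "m", 3, 10, 0.3)],
            columns=["group", "mutation_id", "carrier_count", "n_genotyped",
                     "proportion"])
        res = ScreeningResult(pd.DataFrame(), pd.DataFrame(), per_cohort,
                              pd.DataFrame())
        with pytest.raises(ValidationError, match="invasive"):
            cohort_contrast(res, "m")


class TestCodonSpectrum:
    @staticmethod
    def _matrix_at_codon(reference, gene, codon_index, slot, alt_cds_base,
                         calls):
        models, cds = reference
        gm_model, seq = models[gene], cds[gene]
        pos0 = gm_model.codon_genomic_positions(codon_index)[slot]
        if gm_model.strand == "+":
            ref, alt = seq[3 * (codon_index - 1) + slot], alt_cds_base
        else:
            comp = dict(zip("ACGT", "TGCA"))
            ref = comp[seq[3 * (codon_index - 1) + slot]]
            alt = comp[alt_cds_base]
        sites = pd.DataFrame({"chrom": [gm_model.chrom], "pos": [pos0 + 1],
                              "ref": [ref], "alt": [alt]})
        samples = [f"s{i}" for i in range(len(calls))]
        gm = GenotypeMatrix(sites, samples,
                            np.array([calls], dtype=np.int8).T.reshape(1, -1))
        pm = PopulationMap.from_records(
            {s: ("Benin", "invasive") for s in samples})
        return gm, pm, gm_model, seq

    def test_all_hom_ref_single_reference_codon(self, reference):
        gm, pm, model, seq = self._matrix_at_codon(
            reference, "AChE", 201, 2, "A", [0, 0, 0, 0])
        out = codon_spectrum(gm, model, seq, 201, pm)
        assert out.to_dict("records") == [
            {"population": "Benin", "codon": "GCG", "n_individuals": 4}]

    def test_planted_synonymous_codon_counted(self, reference):
        # three GCA carriers (two hom, one het) among five individuals
        gm, pm, model, seq = self._matrix_at_codon(
            reference, "AChE", 201, 2, "A", [2, 2, 1, 0, 0])
        out = codon_spectrum(gm, model, seq, 201, pm)
        counts = dict(zip(out["codon"], out["n_individuals"]))
        assert counts["GCA"] == 3  # every carrier shows the GCA codon
        assert counts["GCG"] == 3  # het + two hom-ref show GCG

    def test_two_het_sites_in_one_codon_is_ambiguous(self, reference):
        models, cds = reference
        model, seq = models["AChE"], cds["AChE"]
        pos = model.codon_genomic_positions(201)
        ref_codon = seq[600:603]
        sites = pd.DataFrame({
            "chrom": [model.chrom] * 2,
            "pos": [pos[0] + 1, pos[2] + 1],
            "ref": [ref_codon[0], ref_codon[2]], "alt": ["T", "A"]})
        gm = GenotypeMatrix(sites, ["s0"],
                            np.array([[1], [1]], dtype=np.int8))
        pm = PopulationMap.from_records({"s0": ("Benin", "invasive")})
        out = codon_spectrum(gm, model, seq, 201, pm)
        assert out.to_dict("records") == [
            {"population": "Benin", "codon": "ambiguous", "n_individuals": 1}]
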