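{
 "schema": "resistscan-catalog-v1",
 "comment": "Reported target-site insecticide-resistance mutations in Spodoptera frugiperda. Protein-level specs are the primary keys; genomic specs are assembly-specific overlays added at run time (see resistscan.simulate.catalog_with_genomic_specs). Gene accessions: ABCC2 QGS83596, AChE MK226188 (XP_022819835 annotation), VGSC KC435025, RyR XP_022819835.",
 "mutations": [
  {"mutation_id": "ABCC2_GCins2bp", "gene_id": "ABCC2",
   "insecticide_class": "Bt", "origin_population": "Puerto Rico",
   "protein": {"kind": "frameshift", "indel_length": 2},
   "note": "2 bp GC insertion; frameshift with premature stop; disrupts Cry1F/Cry1A receptor function"},
  {"mutation_id": "ABCC2_GYdel", "gene_id": "ABCC2",
   "insecticide_class": "Bt", "origin_population": "Brazil",
   "protein": {"kind": "in_frame_deletion", "deleted_aa": "GY", "start_codon_index": 780},
   "note": "in-frame 6 bp deletion removing Gly-Tyr"},
  {"mutation_id": "ABCC2_ins12bp", "gene_id": "ABCC2",
   "insecticide_class": "Bt", "origin_population": "Brazil",
   "protein": {"kind": "in_frame_insertion", "inserted_length": 12, "introduces_stop": true},
   "note": "12 bp insertion carrying a premature stop codon"},
  {"mutation_id": "ABCC2_P799KR", "gene_id": "ABCC2",
   "insecticide_class": "Bt", "origin_population": "Brazil",
   "protein": {"kind": "substitution", "ref_aa": "P", "codon_index": 799, "alt_aas": ["K", "R"]}},
  {"mutation_id": "ABCC2_G1088D", "gene_id": "ABCC2",
   "insecticide_class": "Bt", "origin_population": "Brazil",
   "protein": {"kind": "substitution", "ref_aa": "G", "codon_index": 1088, "alt_aas": ["D"]}},
  {"mutation_id": "AChE_F209V", "gene_id": "AChE",
   "insecticide_class": "organophosphate/carbamate", "origin_population": "native range",
   "protein": {"kind": "substitution", "ref_aa": "F", "codon_index": 209, "alt_aas": ["V"]},
   "note": "F402V in Torpedo-convention numbering"},
  {"mutation_id": "AChE_A201S", "gene_id": "AChE",
   "insecticide_class": "organophosphate/carbamate", "origin_population": "native range",
   "protein": {"kind": "substitution", "ref_aa": "A", "codon_index": 201, "alt_aas": ["S"]},
   "note": "A314S in Torpedo-convention numbering"},
  {"mutation_id": "AChE_G227A", "gene_id": "AChE",
   "insecticide_class": "organophosphate/carbamate", "origin_population": "native range",
   "protein": {"kind": "substitution", "ref_aa": "G", "codon_index": 227, "alt_aas": ["A"]},
   "note": "G340A in Torpedo-convention numbering"},
  {"mutation_id": "VGSC_T929I", "gene_id": "VGSC",
   "insecticide_class": "pyrethroid", "origin_population": "native range",
   "protein": {"kind": "substitution", "ref_aa": "T", "codon_index": 929, "alt_aas": ["I"]}},
  {"mutation_id": "VGSC_L932F", "gene_id": "VGSC",
   "insecticide_class": "pyrethroid", "origin_population": "native range",
   "protein": {"kind": "substitution", "ref_aa": "L", "codon_index": 932, "alt_aas": ["F"]}},
  {"mutation_id": "VGSC_L1014F", "gene_id": "VGSC",
   "insecticide_class": "pyrethroid", "origin_population": "native range",
   "protein": {"kind": "substitution", "ref_aa": "L", "codon_index": 1014, "alt_aas": ["F"]},
   "note": "classic kdr substitution"},
  {"mutation_id": "RyR_I4734M", "gene_id": "RyR",
   "insecticide_class": "diamide", "origin_population": "native range",
   "protein": {"kind": "substitution", "ref_aa": "I", "codon_index": 4734, "alt_aas": ["M"]}},
  {"mutation_id": "RyR_G4946E", "gene_id": "RyR",
   "insecticide_class": "diamide", "origin_population": "native range",
   "protein": {"kind": "substitution", "ref_aa": "G", "codon_index": 4946, "alt_aas": ["E"]}}
 ]
}
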