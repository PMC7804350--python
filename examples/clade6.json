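{
 "divergence": 0.08,
 "gene_lengths": {
  "atp6": 250,
  "atp8": 48,
  "atp9": 74,
  "cob": 380,
  "cox1": 520,
  "cox2": 250,
  "cox3": 270,
  "nad1": 320,
  "nad2": 480,
  "nad3": 135,
  "nad4": 450,
  "nad4L": 89,
  "nad5": 600,
  "nad6": 200,
  "rnl": 3150,
  "rns": 1629,
  "rps3": 470
 },
 "gene_overrides": {},
 "groups": [
  {
   "shared_fraction": 0.6,
   "taxa": [
    "T1",
    "T2"
   ]
  }
 ],
 "intron_plan": [
  {
   "has_orf": true,
   "orf_family": "LAGLIDADG",
   "ref_position": 383,
   "taxa": [
    "T1",
    "T2"
   ]
  },
  {
   "ref_position": 706,
   "taxa": [
    "T3"
   ]
  }
 ],
 "n_dpo": 2,
 "n_free_orfs": 3,
 "n_taxa": 6,
 "omega": 0.2,
 "orf_codons": 300,
 "rearrangement_plan": [
  {
   "length": 4,
   "op": "inversion",
   "start": 5,
   "taxon": "T3"
  }
 ],
 "repeat_plan": [
  {
   "identity": 0.9,
   "length": 400,
   "taxon": "T1"
  },
  {
   "copies": 2,
   "tandem": true,
   "taxon": "T2",
   "unit_length": 74
  }
 ],
 "seed": 11,
 "spacer_len": 400,
 "taxon_names": [],
 "trna_mutations": {
  "T2": 5
 }
}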