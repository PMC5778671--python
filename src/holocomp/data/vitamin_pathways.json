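[
 {
  "pathway_id": "biotin",
  "target_compound": "biotin",
  "precursor_compounds": ["pimeloyl-ACP"],
  "transportable_compounds": [],
  "reactions": [
   {"reaction_id": "bio_r1", "ec": "2.3.1.47", "substrates": ["pimeloyl-ACP"], "products": ["KAPA"], "reversible": false},
   {"reaction_id": "bio_r2", "ec": "2.6.1.62", "substrates": ["KAPA"], "products": ["DAPA"], "reversible": false},
   {"reaction_id": "bio_r3", "ec": "6.3.3.3", "substrates": ["DAPA"], "products": ["dethiobiotin"], "reversible": false},
   {"reaction_id": "bio_r4", "ec": "2.8.1.6", "substrates": ["dethiobiotin"], "products": ["biotin"], "reversible": false}
  ]
 },
 {
  "pathway_id": "folate",
  "target_compound": "tetrahydrofolate",
  "precursor_compounds": ["GTP"],
  "transportable_compounds": [],
  "reactions": [
   {"reaction_id": "fol_r1", "ec": "3.5.4.16", "substrates": ["GTP"], "products": ["dihydroneopterin-3P"], "reversible": false},
   {"reaction_id": "fol_r2", "ec": "2.5.1.15", "substrates": ["dihydroneopterin-3P"], "products": ["dihydropteroate"], "reversible": false},
   {"reaction_id": "fol_r3", "ec": "6.3.2.17", "substrates": ["dihydropteroate"], "products": ["dihydrofolate"], "reversible": false},
   {"reaction_id": "fol_r4", "ec": "1.5.1.3", "substrates": ["dihydrofolate"], "products": ["tetrahydrofolate"], "reversible": false}
  ]
 },
 {
  "pathway_id": "nad",
  "target_compound": "NAD",
  "precursor_compounds": ["L-aspartate"],
  "transportable_compounds": [],
  "reactions": [
   {"reaction_id": "nad_r1", "ec": "1.4.3.16", "substrates": ["L-aspartate"], "products": ["iminoaspartate"], "reversible": false},
   {"reaction_id": "nad_r2", "ec": "2.5.1.72", "substrates": ["iminoaspartate"], "products": ["quinolinate"], "reversible": false},
   {"reaction_id": "nad_r3", "ec": "2.4.2.19", "substrates": ["quinolinate"], "products": ["NaMN"], "reversible": false},
   {"reaction_id": "nad_r4", "ec": "2.7.7.18", "substrates": ["NaMN"], "products": ["NaAD"], "reversible": false},
   {"reaction_id": "nad_r5", "ec": "6.3.1.5", "substrates": ["NaAD"], "products": ["NAD"], "reversible": false}
  ]
 },
 {
  "pathway_id": "riboflavin",
  "target_compound": "riboflavin",
  "precursor_compounds": ["GTP"],
  "transportable_compounds": [],
  "reactions": [
   {"reaction_id": "rib_r1", "ec": "3.5.4.25", "substrates": ["GTP"], "products": ["DARPP"], "reversible": false},
   {"reaction_id": "rib_r2", "ec": "1.1.1.193", "substrates": ["DARPP"], "products": ["ARPP"], "reversible": false},
   {"reaction_id": "rib_r3", "ec": "2.5.1.78", "substrates": ["ARPP"], "products": ["DMRL"], "reversible": false},
   {"reaction_id": "rib_r4", "ec": "2.5.1.9", "substrates": ["DMRL"], "products": ["riboflavin"], "reversible": false}
  ]
 },
 {
  "pathway_id": "b6",
  "target_compound": "pyridoxal-5P",
  "precursor_compounds": ["D-erythrose-4P"],
  "transportable_compounds": [],
  "reactions": [
   {"reaction_id": "b6_r1", "ec": "1.2.1.72", "substrates": ["D-erythrose-4P"], "products": ["4-phosphoerythronate"], "reversible": false},
   {"reaction_id": "b6_r2", "ec": "1.1.1.290", "substrates": ["4-phosphoerythronate"], "products": ["OHPB"], "reversible": false},
   {"reaction_id": "b6_r3", "ec": "2.6.1.52", "substrates": ["OHPB"], "products": ["4-phosphohydroxy-L-threonine"], "reversible": false},
   {"reaction_id": "b6_r4", "ec": "1.1.1.262", "substrates": ["4-phosphohydroxy-L-threonine"], "products": ["AHAP"], "reversible": false},
   {"reaction_id": "b6_r5", "ec": "2.6.99.2", "substrates": ["AHAP"], "products": ["pyridoxal-5P"], "reversible": false}
  ]
 }
]
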