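[
 {
  "pathway_id": "trp",
  "target_compound": "L-tryptophan",
  "precursor_compounds": ["chorismate"],
  "transportable_compounds": [],
  "reactions": [
   {"reaction_id": "trp_r1", "ec": "4.1.3.27", "substrates": ["chorismate"], "products": ["anthranilate"], "reversible": false},
   {"reaction_id": "trp_r2", "ec": "2.4.2.18", "substrates": ["anthranilate"], "products": ["PR-anthranilate"], "reversible": false},
   {"reaction_id": "trp_r3", "ec": "4.1.1.48", "substrates": ["PR-anthranilate"], "products": ["indole-3-glycerol-P"], "reversible": false},
   {"reaction_id": "trp_r4", "ec": "4.2.1.20", "substrates": ["indole-3-glycerol-P"], "products": ["L-tryptophan"], "reversible": false}
  ]
 },
 {
  "pathway_id": "phe",
  "target_compound": "L-phenylalanine",
  "precursor_compounds": ["chorismate"],
  "transportable_compounds": [],
  "reactions": [
   {"reaction_id": "phe_r1", "ec": "5.4.99.5", "substrates": ["chorismate"], "products": ["prephenate"], "reversible": false},
   {"reaction_id": "phe_r2", "ec": "4.2.1.51", "substrates": ["prephenate"], "products": ["phenylpyruvate"], "reversible": false},
   {"reaction_id": "phe_r3", "ec": "2.6.1.57", "substrates": ["phenylpyruvate"], "products": ["L-phenylalanine"], "reversible": false}
  ]
 },
 {
  "pathway_id": "thr",
  "target_compound": "L-threonine",
  "precursor_compounds": ["L-aspartate"],
  "transportable_compounds": [],
  "reactions": [
   {"reaction_id": "thr_r1", "ec": "2.7.2.4", "substrates": ["L-aspartate"], "products": ["L-aspartyl-4-P"], "reversible": false},
   {"reaction_id": "thr_r2", "ec": "1.2.1.11", "substrates": ["L-aspartyl-4-P"], "products": ["L-aspartate-semialdehyde"], "reversible": false},
   {"reaction_id": "thr_r3", "ec": "1.1.1.3", "substrates": ["L-aspartate-semialdehyde"], "products": ["L-homoserine"], "reversible": false},
   {"reaction_id": "thr_r4", "ec": "2.7.1.39", "substrates": ["L-homoserine"], "products": ["O-phospho-L-homoserine"], "reversible": false},
   {"reaction_id": "thr_r5", "ec": "4.2.3.1", "substrates": ["O-phospho-L-homoserine"], "products": ["L-threonine"], "reversible": false}
  ]
 },
 {
  "pathway_id": "arg",
  "target_compound": "L-arginine",
  "precursor_compounds": ["L-ornithine"],
  "transportable_compounds": [],
  "reactions": [
   {"reaction_id": "arg_r1", "ec": "2.1.3.3", "substrates": ["L-ornithine"], "products": ["L-citrulline"], "reversible": false},
   {"reaction_id": "arg_r2", "ec": "6.3.4.5", "substrates": ["L-citrulline"], "products": ["argininosuccinate"], "reversible": false},
   {"reaction_id": "arg_r3", "ec": "4.3.2.1", "substrates": ["argininosuccinate"], "products": ["L-arginine"], "reversible": false}
  ]
 },
 {
  "pathway_id": "his",
  "target_compound": "L-histidine",
  "precursor_compounds": ["PRPP"],
  "transportable_compounds": [],
  "reactions": [
   {"reaction_id": "his_r1", "ec": "2.4.2.17", "substrates": ["PRPP"], "products": ["PR-ATP"], "reversible": false},
   {"reaction_id": "his_r2", "ec": "3.5.4.19", "substrates": ["PR-ATP"], "products": ["PR-AMP"], "reversible": false},
   {"reaction_id": "his_r3", "ec": "3.1.3.15", "substrates": ["PR-AMP"], "products": ["L-histidinol"], "reversible": false},
   {"reaction_id": "his_r4", "ec": "1.1.1.23", "substrates": ["L-histidinol"], "products": ["L-histidine"], "reversible": false}
  ]
 },
 {
  "pathway_id": "cys",
  "target_compound": "L-cysteine",
  "precursor_compounds": ["L-serine"],
  "transportable_compounds": [],
  "reactions": [
   {"reaction_id": "cys_r1", "ec": "2.3.1.30", "substrates": ["L-serine"], "products": ["O-acetyl-L-serine"], "reversible": false},
   {"reaction_id": "cys_r2", "ec": "2.5.1.47", "substrates": ["O-acetyl-L-serine"], "products": ["L-cysteine"], "reversible": false}
  ]
 },
 {
  "pathway_id": "pro",
  "target_compound": "L-proline",
  "precursor_compounds": ["L-glutamate"],
  "transportable_compounds": [],
  "reactions": [
   {"reaction_id": "pro_r1", "ec": "2.7.2.11", "substrates": ["L-glutamate"], "products": ["L-glutamyl-5-P"], "reversible": false},
   {"reaction_id": "pro_r2", "ec": "1.2.1.41", "substrates": ["L-glutamyl-5-P"], "products": ["L-glutamate-5-semialdehyde"], "reversible": false},
   {"reaction_id": "pro_r3", "ec": "1.5.1.2", "substrates": ["L-glutamate-5-semialdehyde"], "products": ["L-proline"], "reversible": false}
  ]
 }
]
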