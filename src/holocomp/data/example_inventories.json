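{
 "_comment": "Synthetic illustrative enzyme inventories for a whitefly-like host, its primary symbiont and its secondary symbiont. EC assignments encode the host-upstream/symbiont-terminal amino-acid patterns and the symbiont-only vitamin pattern at figure-level granularity; they are NOT a database extraction.",
 "roles": {
  "host": "host",
  "portiera": "primary_symbiont",
  "hamiltonella": "secondary_symbiont"
 },
 "ec_sets": {
  "host": ["4.1.3.27", "2.4.2.18", "5.4.99.5", "2.7.2.4", "1.2.1.11",
           "6.3.4.5", "4.3.2.1", "3.1.3.15", "1.1.1.23",
           "2.3.1.30", "2.5.1.47", "2.7.2.11", "1.2.1.41", "1.5.1.2"],
  "portiera": ["4.1.1.48", "4.2.1.20", "4.2.1.51", "2.6.1.57",
               "1.1.1.3", "2.7.1.39", "4.2.3.1", "2.1.3.3",
               "2.4.2.17", "3.5.4.19"],
  "hamiltonella": ["2.3.1.30", "2.5.1.47", "2.7.2.11", "1.2.1.41", "1.5.1.2",
                   "2.3.1.47", "2.6.1.62", "6.3.3.3", "2.8.1.6",
                   "3.5.4.16", "2.5.1.15", "6.3.2.17", "1.5.1.3",
                   "1.4.3.16", "2.5.1.72", "2.4.2.19", "2.7.7.18", "6.3.1.5",
                   "3.5.4.25", "1.1.1.193", "2.5.1.78", "2.5.1.9",
                   "1.2.1.72", "1.1.1.290", "2.6.1.52", "1.1.1.262", "2.6.99.2"]
 }
}
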