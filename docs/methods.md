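# Methods

This note documents the models and procedures implemented in `holocomp`,
the parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical/design decisions made
where several reasonable options existed.

## Syntenic divergence

Divergence between two assemblies is measured over non-overlapping pairwise
alignment blocks. The denominator of every fraction is the focal genome's
own aligned (non-gap) base count inside blocks — the number of base pairs
actually compared — not the whole-genome length and not the column count.
This makes the substitution and indel components exactly additive:
`total = substitution% + indel%` holds identically for any block set, which
is asserted in tests. Indels are counted in gap *bases* (total span), not
events, and charged symmetrically to both genomes' summaries. Columns
containing `N` in either row are treated as unaligned and excluded from
every count (numerator and denominator), so base-calling ambiguity cannot
inflate divergence. `aligned_fraction` alone uses the full genome length.

The toy aligner (`toy_align`) seeds on k-mers that are unique in each
genome (default `k = 21`, both query strands), chains them colinearly
(greedy, max anchor gap 2 kb), and fills inter-anchor gaps with a global
Needleman–Wunsch alignment under affine gap penalties (match +1, mismatch
−2, open −6, extend −1). Affine penalties matter: a unit-cost edit distance
systematically converts some substitutions into spurious gap pairs and
biased the recovered substitution fraction low by several binomial standard
deviations in testing; with affine gaps the recovered fraction matches the
planted one within 3 binomial SDs at 100 kb. Overlapping chains are
resolved greedily by descending anchor count, ties by leftmost reference
coordinate, for determinism. The aligner is a desk-scale stand-in for a
whole-genome aligner and makes no claim to its scoring model; rearranged
segments become separate blocks.

## Pairwise Ka/Ks

The selection screen uses Nei–Gojobori (1986) counting with the
Jukes–Cantor correction. Site counts per codon enumerate all nine possible
single-nucleotide changes; a change creating a stop codon counts as
nonsynonymous, which keeps `n_sites + s_sites = 3` exactly per codon (and
`N + S = 3L` per gene). Differences between codon pairs average the
synonymous/nonsynonymous classification of steps over all minimal
mutational pathways, excluding pathways that traverse a stop codon; in the
rare case that every pathway is excluded, each differing position is
classified directly against the first codon. Site counts are averaged over
the two sequences; differences are summed over codon columns. `Ks = 0`
pairs are `undefined_Ks_zero`, proportions ≥ 3/4 are `saturated`; both are
excluded from cohort means, and the cohort mean ratio is the mean of
per-pair ratios, never a ratio of means.

NG86 was chosen over approximate maximum-likelihood counting (YN00-style)
because every step is exactly specifiable and checkable against an
independent enumeration oracle — the test suite requires agreement to
1e-9 on random codon alignments — while preserving the semantics of the
screen (ratio against 1). The report header names the model.

Ortholog pairing uses reciprocal best hits. The built-in search compares
translated proteins by global edit distance and accepts mutual best hits
within 50 % distance of the longer protein; when an external hit table is
supplied instead, best hits are chosen by bit score (ties by e-value, then
subject id) after discarding hits above the e-value ceiling (default 1e-7).

## Codon-pair simulator

`evolve_codon_pairs` evolves both copies of a random stop-free ancestor by
a discrete proposal chain: a random nucleotide position mutates with
transition:transversion weight `kappa : 1`; proposals creating stops are
rejected; nonsynonymous proposals are accepted with probability
`min(1, ω)` and synonymous ones with `min(1, 1/ω)`, so the realized
nonsynonymous/synonymous acceptance ratio is exactly ω at every ω. The
default branch length `t = 0.4` expected proposals per nucleotide site
(split over the two lineages) yields `Ks` around 0.2–0.4, the regime of the
intended application, far from saturation. With ω = κ = 1 the chain is a
uniform nucleotide process with stop avoidance, and the NG86 estimate of
the cohort mean ratio falls in [0.8, 1.2] at 500 pairs × 300 codons.

## Pathway complementation

A pathway is a reaction list (EC-labelled, each with substrates, products,
optional reversibility), a precursor set and a target compound. Completion
for a genome subset is fixed-point reachability: a reaction fires when its
EC is present in the subset's pooled annotation and all substrates are
reachable. By default all intermediates are exchangeable within the queried
consortium — the permissive-transport assumption mirrors the pervasive
host↔symbiont exchange in these systems and avoids inventing membrane
biology; a restricted mode confines intermediates to the producing genome
and shares only the pathway's declared transportable compounds. EC matching
treats trailing-dash partial ECs (`2.6.1.-`) as wildcards on either side,
since KEGG-style annotations are often truncated.

Minimal contributor sets are found by exhaustive subset enumeration
(limited to 6 genomes), pruned to an antichain. Labels derive from the
minimal sets: `incomplete` (none), `host_only`/`symbiont_only` (unique
singleton minimal set), `redundant` (≥ 2 pairwise-disjoint minimal sets),
`joint` (every minimal set has ≥ 2 genomes). "Joint" therefore means "no
single genome suffices", the two-party reading of host–symbiont
complementation.

The shipped amino-acid and vitamin pathway files are synthetic teaching
fixtures encoding, at figure-level granularity, the characteristic
patterns of a sap-feeding insect holobiont: essential amino acids needing
host + primary symbiont (host-upstream/symbiont-terminal for Trp, Phe, Thr;
symbiont-upstream/host-terminal for Arg, His), amino acids that host and
secondary symbiont can each complete alone (Cys, Pro), and five B vitamins
only the secondary symbiont can complete. They are not a database
extraction.

## HGT calling

Hit-table affinity uses the alien index — best bacterial minus best
metazoan bit score, with missing groups scored 0 — and a threshold
`tau = 30` (configurable). The threshold is an explicit surrogate for
phylogenetic evidence: the gene-tree mode is the faithful path, calling a
gene when its sister clade is purely bacterial, including the
basal-to-bacterial case where the focal leaf sits at the base of a
bacterial clade whose neighbour contains metazoa. Unrooted trees are
midpoint-rooted first (deterministic); branch support values are ignored.
Best hits break ties by smaller e-value, then lexicographic subject id, so
calls are invariant to hit-table row order.

Candidates must additionally pass at least one of two anti-contamination
conditions (OR semantics): (1) another gene on the same scaffold has a
metazoan best overall hit — a gene alone on its scaffold fails this; or
(2) the gene's transcript is supported. Intron counts and 5′-UTR presence
are summarised for candidates but deliberately not used as filters, since
prokaryote-derived genes can acquire eukaryotic structure after transfer.

## Read binning and UGP scaffold linking

`bin_reads` computes, per read, the fraction of its canonical k-mers
(default `k = 21`) contained in each reference's k-mer set and assigns the
read to the best reference if containment ≥ 0.5 and the margin over the
runner-up is ≥ 0.1; in paired mode, a pair is `paired` when both mates
assign to the same reference and `single` when exactly one assigns. This is
a k-mer surrogate for mismatch-tolerant short-read mapping; canonical
k-mers make every decision strand-independent.

The UGP procedure builds unique tags from each scaffold's terminal flanks
(default 20 kb; whole scaffold when shorter than two flanks): a k-mer
(default 31) is kept only if it occurs exactly once across the full
sequences of all scaffolds, both strands. Tags are taken *from* the flanks
— terminal tags are what BAC spanning evidence can link. BACs of ≥ 150 kb
are excluded; a BAC links two scaffold ends when it matches each with at
least `min_tag_hits = 5` distinct tags (suppressing single-k-mer noise),
and BACs matching more than two distinct scaffolds are discarded as
chimeric or repeat-ridden. Super-scaffold paths traverse the link graph on
scaffold ends; an end with two or more conflicting links contributes no
join at all, so ambiguity yields shorter paths, never wrong joins. Every
scaffold appears exactly once across paths.

## Synthetic-data generators

All generators are deterministic in their seed (byte-identical files) and
attach a `ScenarioTruth` with the planted parameters and realized outcomes.
Default study conditions: genome pairs of 100 kb with substitution rate
p = 0.05 and indel rate q = 0.02 expected indel bases per ancestral base
(geometric indel lengths, mean 3 — short indels dominate intra-species
comparisons); codon cohorts of 500 pairs × 300 codons for neutrality
checks; symbiosis scenarios of one host plus two symbionts; HGT cohorts of
100 genes with 5 planted transfers and a ≥ 100-bit score gap; scaffold
layouts of 8 scaffolds (~6 kb each at test scale so the full pipeline runs
in seconds, with flank windows scaled to 2 kb accordingly) with a
junction-spanning BAC per junction; read pools at 70/30 mixture, 100 bp
reads, 1 % error.

What the generators do **not** emulate: repeat content and segmental
duplication (so unique-anchor and unique-tag steps are easier than on real
assemblies), sequencing-quality models and indel read errors, codon usage
bias and selection heterogeneity along genes, incomplete or erroneous
enzyme annotation, and horizontal transfer with diverged or partial genes.
Passing the planted-recovery suites therefore demonstrates correctness of
the decision logic under clean signals, not performance on real data.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open on the forward strand everywhere;
1-based dialects (AXT, GFF3) are converted at the I/O boundary only.
Minus-strand AXT query coordinates require the query's forward-strand
length (`query_sizes`), since the format itself does not carry it; the MAF
subset is self-contained. Empty alignments from `toy_align` (no anchors)
are an empty list, not an error; an empty read set or empty inventories
are errors where a ratio would be undefined. The Jukes–Cantor pole
(p ≥ 3/4) and `Sd = 0` are explicit statuses rather than NaNs. Stage
reports are plain dataclasses serialized to JSON; their structure is fixed
by the code rather than an external schema.

## Known limitations

The toy aligner does not model rearrangement breakpoints precisely and can
trim a few anchor-free bases at block edges; divergence statistics are
therefore evaluated against realized (not expected) planted counts. The
alien-index mode cannot distinguish HGT from contamination by itself —
that is exactly what the filters are for — and the filters assume scaffold
assignments are trustworthy. The subset-enumeration complementation
labeller is exponential in genome count and intentionally capped at 6
genomes. The UGP link step uses exact canonical k-mer matching, which is
stricter than a BLASTn search against tags; diverged BAC sequence would
need the alignment-based variant the desk-scale design omits.
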