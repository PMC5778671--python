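import math

import dendropy
import pytest

from holocomp import synthetic_data as syn
from holocomp import formats_io as fio


class TestDivergentGenomePair:
    def test_zero_rates_identity(self):
        a, b, truth = syn.generate_divergent_genome_pair(2000, 0.0, 0.0, seed=1)
        assert a == b
        assert truth.realized["substitutions"] == 0
        assert truth.realized["indel_bases"] == 0

    def test_determinism(self):
        out1 = syn.generate_divergent_genome_pair(2000, 0.05, 0.03, seed=1)
        out2 = syn.generate_divergent_genome_pair(2000, 0.05, 0.03, seed=1)
        assert out1[0] == out2[0] and out1[1] == out2[1]

    def test_realized_substitutions_near_p(self):
        _, _, truth = syn.generate_divergent_genome_pair(100_000, 0.05, 0.0, seed=2)
        frac = truth.realized["substitution_fraction"]
        sd3 = 3 * math.sqrt(0.05 * 0.95 / 100_000)
        assert abs(frac - 0.05) < sd3

    def test_saturating_p_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_divergent_genome_pair(2000, 0.8, 0.0)

    def test_rearrangements_preserve_content(self):
        a, b, _ = syn.generate_divergent_genome_pair(2000, 0.0, 0.0,
                                                     rearrangement_count=3, seed=3)
        assert sorted(a) == sorted(b)
        assert a != b


class TestCodonPairs:
    def test_low_omega_low_ratio(self):
        from holocomp.kaks import kaks_pair, selection_screen
        pairs, _ = syn.evolve_codon_pairs(200, 100, omega=0.01, seed=4)
        _, summ = selection_screen([kaks_pair(p) for p in pairs])
        assert summ.mean_ratio < 0.2

    def test_fasta_bytes_deterministic(self, tmp_path):
        for d in ("d1", "d2"):
            pairs, _ = syn.evolve_codon_pairs(5, 50, omega=0.5, seed=6)
            recs = [fio.SequenceRecord(p.gene_id_pair[0], p.seq_a) for p in pairs]
            (tmp_path / d).mkdir()
            fio.write_fasta(recs, tmp_path / d / "a.fa")
        assert (tmp_path / "d1" / "a.fa").read_bytes() == (tmp_path / "d2" / "a.fa").read_bytes()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            syn.evolve_codon_pairs(5, 50, omega=0.0)
        with pytest.raises(ValueError):
            syn.evolve_codon_pairs(5, 50, omega=1.0, kappa=-1.0)

    def test_no_stops_generated(self):
        from holocomp.kaks import STOP_CODONS
        pairs, _ = syn.evolve_codon_pairs(20, 80, omega=2.0, seed=7)
        for p in pairs:
            for c in (p.seq_a[i:i + 3] for i in range(0, len(p.seq_a), 3)):
                assert c not in STOP_CODONS


class TestSymbiosisScenario:
    def test_all_host_only_completable_by_host(self):
        from holocomp import pathway_complementation as pc
        pws, anns, truth = syn.generate_symbiosis_scenario(["host_only"] * 4, seed=8)
        invs = pc.inventories_from_annotations(anns, truth.realized["roles"])
        for pw in pws:
            assert pc.pathway_completion(pw, invs, {"host"}).complete

    def test_joint_breaks_without_either_genome(self):
        from holocomp import pathway_complementation as pc
        pws, anns, truth = syn.generate_symbiosis_scenario(["joint"] * 4, seed=9)
        invs = pc.inventories_from_annotations(anns, truth.realized["roles"])
        for pw in pws:
            msets = pc.minimal_contributor_sets(pw, invs)
            (only,) = msets
            assert len(only) == 2
            for g in only:
                assert not pc.pathway_completion(pw, invs, only - {g}).complete

    def test_impossible_label_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            syn.generate_symbiosis_scenario(["joint"], genomes=(("host", "host"),))

    def test_determinism(self):
        a = syn.generate_symbiosis_scenario(["joint", "redundant"], seed=10)
        b = syn.generate_symbiosis_scenario(["joint", "redundant"], seed=10)
        assert a[0] == b[0] and a[1] == b[1]


class TestScaffoldBacLayout:
    def test_truth_marks_junction_and_interior_bacs(self):
        scaffolds, bacs, truth = syn.generate_scaffold_bac_layout(
            5, 5000, 4, seed=11)
        spans = truth.realized["bac_spans"]
        for bid, pair in truth.realized["junction_bacs"].items():
            assert set(pair) <= set(spans[bid])
            i = truth.realized["order"].index(pair[0])
            assert truth.realized["order"][i + 1] == pair[1]
        interior = [b for b in bacs if len(spans[b.id]) == 1]
        assert interior, "expected at least one single-scaffold BAC"

    def test_bac_lengths_bounded(self):
        _, bacs, truth = syn.generate_scaffold_bac_layout(
            5, 5000, 6, bac_len_range=(2000, 3000), cover_junctions=False, seed=12)
        assert all(2000 <= len(b.seq) <= 3000 for b in bacs)

    def test_scaffolds_reassemble_super_sequence(self):
        scaffolds, _, truth = syn.generate_scaffold_bac_layout(4, 4000, 0, seed=13)
        by_id = {s.id: s.seq for s in scaffolds}
        parts = []
        for sid in truth.realized["order"]:
            seq = by_id[sid]
            if truth.realized["orientation"][sid] == "-":
                seq = fio.reverse_complement(seq)
            parts.append(seq)
        total = sum(truth.realized["scaffold_lengths"].values())
        assert len("".join(parts)) == total


class TestHomologyEvidence:
    def test_no_hgt_no_bacterial_best(self):
        hits, _, _, _, truth = syn.generate_homology_evidence(30, 0, seed=14)
        assert truth.realized["hgt_genes"] == []
        best = {}
        for h in hits:
            if h.query_gene not in best or h.bit_score > best[h.query_gene].bit_score:
                best[h.query_gene] = h
        assert all(h.taxon_group == "metazoa" for h in best.values())

    def test_planted_gene_score_gap(self):
        hits, _, _, _, truth = syn.generate_homology_evidence(40, 5, seed=15)
        for gid in truth.realized["hgt_genes"]:
            mine = [h for h in hits if h.query_gene == gid]
            b = max(h.bit_score for h in mine if h.taxon_group == "bacteria")
            m = max(h.bit_score for h in mine if h.taxon_group == "metazoa")
            assert b - m >= 100

    def test_trees_parse_and_contain_focal(self):
        _, _, _, trees, truth = syn.generate_homology_evidence(
            20, 3, seed=16, emit_trees=True)
        assert set(trees) == set(truth.realized["hgt_genes"])
        for gid, nwk in trees.items():
            t = dendropy.Tree.get(data=nwk, schema="newick")
            assert gid in {lf.taxon.label for lf in t.leaf_node_iter()}


class TestMetagenomeReads:
    def _refs(self, rng):
        from conftest import random_dna
        return [fio.SequenceRecord("r1", random_dna(rng, 3000)),
                fio.SequenceRecord("r2", random_dna(rng, 3000))]

    def test_degenerate_proportions(self, rng):
        reads, truth = syn.generate_metagenome_reads(self._refs(rng), [1, 0],
                                                     n_reads=50, seed=17)
        assert set(truth.realized["origin"].values()) == {"r1"}

    def test_error_free_reads_are_substrings(self, rng):
        refs = self._refs(rng)
        reads, truth = syn.generate_metagenome_reads(refs, [0.5, 0.5],
                                                     n_reads=50, error_rate=0.0, seed=18)
        seqs = {r.id: r.seq + "#" + fio.reverse_complement(r.seq) for r in refs}
        for read in reads:
            src = seqs[truth.realized["origin"][read.id]]
            assert read.seq in src

    def test_realized_proportions_within_3sd(self, rng):
        n = 10_000
        _, truth = syn.generate_metagenome_reads(self._refs(rng), [0.7, 0.3],
                                                 n_reads=n, seed=19)
        frac = truth.realized["counts"]["r1"] / n
        assert abs(frac - 0.7) < 3 * math.sqrt(0.7 * 0.3 / n)
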