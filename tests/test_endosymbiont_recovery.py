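from collections import Counter

import numpy as np
import pytest

from holocomp import endosymbiont_recovery as er
from holocomp.formats_io import SequenceRecord, reverse_complement
from holocomp.synthetic_data import (
    generate_metagenome_reads,
    generate_scaffold_bac_layout,
)
from conftest import random_dna


class TestBinReads:
    def _refs(self, rng):
        return [SequenceRecord("A", random_dna(rng, 5000)),
                SequenceRecord("B", random_dna(rng, 5000))]

    def test_exact_read_full_containment(self, rng):
        refs = self._refs(rng)
        read = SequenceRecord("r", refs[0].seq[1000:1100])
        (res,) = er.bin_reads([read], refs)
        assert res.assigned_reference == "A"
        assert res.containment["A"] == 1.0

    def test_random_read_unassigned(self, rng):
        refs = self._refs(rng)
        read = SequenceRecord("r", random_dna(rng, 100))
        (res,) = er.bin_reads([read], refs)
        assert res.assigned_reference is None

    def test_reverse_complement_invariance(self, rng):
        refs = self._refs(rng)
        fwd = SequenceRecord("f", refs[1].seq[2000:2100])
        rev = SequenceRecord("v", reverse_complement(fwd.seq))
        res = er.bin_reads([fwd, rev], refs)
        assert res[0].assigned_reference == res[1].assigned_reference == "B"

    def test_k_longer_than_read_error(self, rng):
        refs = self._refs(rng)
        with pytest.raises(ValueError):
            er.bin_reads([SequenceRecord("r", "ACGTACGT")], refs, k=21)

    def test_pair_status(self, rng):
        refs = self._refs(rng)
        reads = [SequenceRecord("p1", refs[0].seq[:100]),
                 SequenceRecord("p2", refs[0].seq[200:300]),
                 SequenceRecord("s1", refs[0].seq[400:500]),
                 SequenceRecord("s2", random_dna(rng, 100)),
                 SequenceRecord("u1", random_dna(rng, 100)),
                 SequenceRecord("u2", random_dna(rng, 100))]
        res = er.bin_reads(reads, refs, mate_pairs=[("p1", "p2"), ("s1", "s2"), ("u1", "u2")])
        by = {r.read_id: r.pair_status for r in res}
        assert by["p1"] == by["p2"] == "paired"
        assert by["s1"] == by["s2"] == "single"
        assert by["u1"] == by["u2"] == "unmapped"

    def test_planted_origin_recovery(self, rng):
        refs = self._refs(rng)
        reads, truth = generate_metagenome_reads(refs, [0.6, 0.4], read_len=100,
                                                 n_reads=2000, error_rate=0.01, seed=31)
        res = er.bin_reads(reads, refs)
        assigned = [r for r in res if r.assigned_reference is not None]
        correct = sum(truth.realized["origin"][r.read_id] == r.assigned_reference
                      for r in assigned)
        assert len(assigned) > 0.8 * len(reads)
        assert correct / len(assigned) >= 0.99


class TestUniqueTags:
    def test_flank_window_rule(self, rng):
        sc = SequenceRecord("s1", random_dna(rng, 50_000))
        idx = er.build_unique_tags([sc], k=31, flank_len=20_000)
        offsets = [off for (_, _, off) in idx.tags.values()]
        assert offsets
        assert all(o < 20_000 or o >= 30_000 - 31 + 1 for o in offsets)

    def test_repeated_unit_scaffold_empty(self):
        sc = SequenceRecord("rep", ("ACGTTGCA" * 125) * 10)  # repeated 1-kb unit
        idx = er.build_unique_tags([sc], k=31, flank_len=2000)
        assert len(idx) == 0

    def test_every_tag_unique_by_recount(self, rng):
        scaffolds, _, _ = generate_scaffold_bac_layout(4, 3000, 0, seed=32)
        idx = er.build_unique_tags(scaffolds, k=31, flank_len=1000)
        counts = Counter()
        for sc in scaffolds:
            counts.update(er.canonical_kmers(sc.seq, 31))
        assert all(counts[t] == 1 for t in idx.tags)

    def test_small_k_rejected(self, rng):
        with pytest.raises(ValueError):
            er.build_unique_tags([SequenceRecord("s", random_dna(rng, 1000))], k=9)


class TestLinkScaffolds:
    def _layout(self, seed=33, **kw):
        scaffolds, bacs, truth = generate_scaffold_bac_layout(
            6, 5000, 4, seed=seed, **kw)
        tags = er.build_unique_tags(scaffolds, k=31, flank_len=1500)
        return scaffolds, bacs, truth, tags

    def test_junction_bac_links_adjacent_scaffolds(self):
        scaffolds, bacs, truth, tags = self._layout()
        links = er.link_scaffolds(tags, bacs, min_tag_hits=5)
        linked_pairs = {frozenset((l.end_a[0], l.end_b[0])) for l in links}
        for pair in truth.realized["junction_bacs"].values():
            assert frozenset(pair) in linked_pairs

    def test_interior_bac_makes_no_link(self):
        scaffolds, bacs, truth, tags = self._layout()
        interior = [b for b in bacs
                    if len(truth.realized["bac_spans"][b.id]) == 1]
        links = er.link_scaffolds(tags, interior or bacs[:0], min_tag_hits=5) \
            if interior else []
        assert links == []

    def test_chimeric_bac_discarded(self):
        scaffolds, bacs, truth, tags = self._layout(seed=34, n_chimeric=3)
        links = er.link_scaffolds(tags, bacs, min_tag_hits=5)
        used = set().union(*(l.supporting_bacs for l in links)) if links else set()
        assert not used & set(truth.realized["chimeric_bacs"])

    def test_long_bacs_excluded(self, rng):
        scaffolds, bacs, truth, tags = self._layout()
        long_bac = SequenceRecord("LONG", bacs[0].seq + random_dna(rng, 200_000))
        links_with = er.link_scaffolds(tags, list(bacs) + [long_bac])
        assert all("LONG" not in l.supporting_bacs for l in links_with)

    def test_permutation_invariance(self):
        scaffolds, bacs, truth, tags = self._layout()
        fwd = er.link_scaffolds(tags, bacs)
        rev = er.link_scaffolds(tags, list(reversed(bacs)))
        assert {l.key for l in fwd} == {l.key for l in rev}


class TestSuperscaffoldPaths:
    def _link(self, a, ea, b, eb, bac="x"):
        return er.ScaffoldLink((a, ea), (b, eb), frozenset({bac}))

    def test_simple_chain(self):
        links = [self._link("S1", "right", "S2", "left"),
                 self._link("S2", "right", "S3", "left")]
        paths = er.superscaffold_paths(links, ["S1", "S2", "S3"])
        assert len(paths) == 1
        assert [s for s, _ in paths[0]] in (["S1", "S2", "S3"], ["S3", "S2", "S1"])

    def test_conflicting_links_leave_end_unjoined(self):
        links = [self._link("S1", "right", "S2", "left", "b1"),
                 self._link("S1", "right", "S3", "left", "b2")]
        paths = er.superscaffold_paths(links, ["S1", "S2", "S3"])
        assert sorted(len(p) for p in paths) == [1, 1, 1]

    def test_partition_conservation(self):
        links = [self._link("S1", "right", "S2", "left")]
        paths = er.superscaffold_paths(links, ["S1", "S2", "S3", "S4"])
        seen = [s for p in paths for s, _ in p]
        assert sorted(seen) == ["S1", "S2", "S3", "S4"]

    def test_planted_order_recovered_across_seeds(self):
        for seed in range(20):
            scaffolds, bacs, truth = generate_scaffold_bac_layout(
                8, 6000, 6, n_chimeric=2, seed=seed)
            tags = er.build_unique_tags(scaffolds, k=31, flank_len=2000)
            links = er.link_scaffolds(tags, bacs, min_tag_hits=5)
            paths = er.superscaffold_paths(links, [s.id for s in scaffolds])
            main = max(paths, key=len)
            order = [s for s, _ in main]
            true = truth.realized["order"]
            assert order in (true, true[::-1])

    def test_withheld_junctions_give_partial_but_correct_paths(self):
        scaffolds, bacs, truth = generate_scaffold_bac_layout(6, 5000, 0, seed=35)
        keep = {b.id for i, b in enumerate(bacs) if i % 2 == 0}  # drop half the junctions
        tags = er.build_unique_tags(scaffolds, k=31, flank_len=1500)
        links = er.link_scaffolds(tags, [b for b in bacs if b.id in keep])
        paths = er.superscaffold_paths(links, [s.id for s in scaffolds])
        true = truth.realized["order"]
        pos = {sid: i for i, sid in enumerate(true)}
        for p in paths:
            idx = [pos[s] for s, _ in p]
            diffs = {b - a for a, b in zip(idx, idx[1:])}
            assert diffs <= {1} or diffs <= {-1}  # contiguous, never a wrong join
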