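import numpy as np
import pytest

from holocomp import pathway_complementation as pc
from holocomp.fixtures import load_amino_acid_fixture, load_vitamin_fixture
from holocomp.formats_io import PathwayDefinition, Reaction
from holocomp.synthetic_data import generate_symbiosis_scenario
from oracles import oracle_pathway_complete


def linear_pathway(n=4, pid="pw"):
    ecs = [f"1.1.{i + 1}.1" for i in range(n)]
    rxs = tuple(Reaction(f"{pid}_r{i}", ecs[i], frozenset({f"c{i}"}), frozenset({f"c{i + 1}"}))
                for i in range(n))
    return PathwayDefinition(pid, f"c{n}", frozenset({"c0"}), rxs), ecs


def inv(gid, role, ecs):
    return pc.GenomeInventory(gid, role, frozenset(ecs))


class TestCompletion:
    def test_empty_inventories_incomplete(self):
        pw, _ = linear_pathway()
        invs = [inv("host", "host", []), inv("sym", "primary_symbiont", [])]
        res = pc.pathway_completion(pw, invs, {"host", "sym"})
        assert not res.complete
        assert res.reachable_compounds == pw.precursor_compounds

    def test_host_upstream_symbiont_terminal(self):
        # host contributes precursor steps, symbiont completes the synthesis
        pw, ecs = linear_pathway(4)
        invs = [inv("host", "host", ecs[:2]), inv("sym", "primary_symbiont", ecs[2:])]
        assert not pc.pathway_completion(pw, invs, {"host"}).complete
        assert pc.pathway_completion(pw, invs, {"host", "sym"}).complete

    def test_missing_ecs_identified(self):
        pw, ecs = linear_pathway(3)
        invs = [inv("host", "host", ecs[:1])]
        res = pc.pathway_completion(pw, invs, {"host"})
        assert res.missing_ecs == {ecs[1]}  # next unreachable step only

    def test_unknown_genome_error(self):
        pw, _ = linear_pathway()
        with pytest.raises(ValueError, match="unknown genome"):
            pc.pathway_completion(pw, [inv("host", "host", [])], {"nope"})

    def test_reversible_reaction_fires_backwards(self):
        rx = (Reaction("r1", "1.1.1.1", frozenset({"target"}), frozenset({"pre"}),
                       reversible=True),)
        pw = PathwayDefinition("rev", "target", frozenset({"pre"}), rx)
        res = pc.pathway_completion(pw, [inv("h", "host", ["1.1.1.1"])], {"h"})
        assert res.complete

    def test_restricted_transport_confines_intermediates(self):
        pw, ecs = linear_pathway(4)
        # no transportable intermediates: split inventories cannot cooperate
        invs = [inv("host", "host", ecs[:2]), inv("sym", "primary_symbiont", ecs[2:])]
        res = pc.pathway_completion(pw, invs, {"host", "sym"}, restrict_transport=True)
        assert not res.complete
        # declaring the hand-over compound transportable restores completion
        pw2 = PathwayDefinition(pw.pathway_id, pw.target_compound,
                                pw.precursor_compounds, pw.reactions,
                                frozenset({"c2", pw.target_compound}))
        assert pc.pathway_completion(pw2, invs, {"host", "sym"},
                                     restrict_transport=True).complete

    def test_matches_bfs_oracle_on_random_pathways(self, rng):
        for trial in range(30):
            n = int(rng.integers(3, 9))
            rxs = []
            for i in range(n):
                sub = {f"c{int(rng.integers(0, i + 1))}"}
                prod = {f"c{i + 1}"}
                rxs.append(Reaction(f"r{i}", f"2.3.{i + 1}.1", frozenset(sub),
                                    frozenset(prod), bool(rng.random() < 0.3)))
            pw = PathwayDefinition(f"p{trial}", f"c{n}", frozenset({"c0"}), tuple(rxs))
            ec_subset = {r.ec for r in rxs if rng.random() < 0.7}
            invs = [inv("h", "host", ec_subset)]
            mine = pc.pathway_completion(pw, invs, {"h"}).complete
            assert mine == oracle_pathway_complete(pw, ec_subset)


class TestMinimalSets:
    def test_redundant_pattern(self):
        pw, ecs = linear_pathway(3)
        invs = [inv("host", "host", ecs),
                inv("ham", "secondary_symbiont", ecs),
                inv("por", "primary_symbiont", [])]
        msets = pc.minimal_contributor_sets(pw, invs)
        assert set(map(frozenset, msets)) == {frozenset({"host"}), frozenset({"ham"})}

    def test_no_enzymes_empty(self):
        pw, _ = linear_pathway()
        assert pc.minimal_contributor_sets(pw, [inv("h", "host", [])]) == []

    def test_antichain_property(self, rng):
        for seed in range(10):
            pws, anns, truth = generate_symbiosis_scenario(
                ["joint", "redundant", "host_only"], seed=seed)
            invs = pc.inventories_from_annotations(anns, truth.realized["roles"])
            for pw in pws:
                msets = pc.minimal_contributor_sets(pw, invs)
                for i, a in enumerate(msets):
                    for b in msets[i + 1:]:
                        assert not (a <= b or b <= a)

    def test_too_many_genomes_rejected(self):
        pw, _ = linear_pathway()
        invs = [inv(f"g{i}", "primary_symbiont" if i else "host", []) for i in range(7)]
        with pytest.raises(ValueError, match="6 genomes"):
            pc.minimal_contributor_sets(pw, invs)

    def test_monotone_in_added_genome(self):
        pw, ecs = linear_pathway(4)
        invs = [inv("host", "host", ecs[:2]),
                inv("sym", "primary_symbiont", ecs[2:]),
                inv("extra", "secondary_symbiont", [])]
        base = pc.pathway_completion(pw, invs, {"host", "sym"})
        more = pc.pathway_completion(pw, invs, {"host", "sym", "extra"})
        assert base.complete and more.complete
        assert base.reachable_compounds <= more.reachable_compounds


class TestLabels:
    ROLES = {"host": "host", "por": "primary_symbiont", "ham": "secondary_symbiont"}

    def test_host_only(self):
        lab = pc.label_pathway("p", [frozenset({"host"})], self.ROLES)
        assert lab.label == "host_only"

    def test_redundant_disjoint_sets(self):
        lab = pc.label_pathway("p", [frozenset({"host"}), frozenset({"ham"})], self.ROLES)
        assert lab.label == "redundant"

    def test_joint(self):
        lab = pc.label_pathway("p", [frozenset({"host", "por"})], self.ROLES)
        assert lab.label == "joint"

    def test_incomplete(self):
        assert pc.label_pathway("p", [], self.ROLES).label == "incomplete"

    def test_nested_sets_rejected(self):
        with pytest.raises(ValueError, match="antichain"):
            pc.label_pathway("p", [frozenset({"host"}), frozenset({"host", "por"})],
                             self.ROLES)

    def test_planted_labels_recovered(self):
        labels = ["host_only", "symbiont_only", "joint", "redundant", "incomplete"]
        for seed in range(20):
            pws, anns, truth = generate_symbiosis_scenario(labels, seed=seed)
            invs = pc.inventories_from_annotations(anns, truth.realized["roles"])
            table = pc.complementation_report(pws, invs)
            got = dict(zip(table["pathway_id"], table["label"]))
            assert got == truth.realized["labels"]


class TestShippedFixtures:
    def test_amino_acid_patterns(self):
        pws, invs = load_amino_acid_fixture()
        table = pc.complementation_report(pws, invs)
        labels = dict(zip(table["pathway_id"], table["label"]))
        # essential amino acids need host and primary symbiont together
        for aa_id in ("trp", "phe", "thr", "arg", "his"):
            assert labels[aa_id] == "joint"
        # host and secondary symbiont can each complete these alone
        for aa_id in ("cys", "pro"):
            assert labels[aa_id] == "redundant"

    def test_vitamins_symbiont_only(self):
        pws, invs = load_vitamin_fixture()
        table = pc.vitamin_report(pws, invs)
        assert set(table["label"]) == {"symbiont_only"}

    def test_vitamins_incomplete_without_symbiont(self):
        pws, invs = load_vitamin_fixture()
        no_ham = [i for i in invs if i.genome_id != "hamiltonella"]
        table = pc.vitamin_report(pws, no_ham)
        assert set(table["label"]) == {"incomplete"}
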