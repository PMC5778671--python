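"""Host-endosymbiont metabolic pathway complementation.

Given pathway definitions (reaction lists with EC numbers) and per-genome
enzyme inventories, this module decides which genome subsets can complete
each biosynthetic pathway and labels the pathway by the structure of its
minimal complete subsets:

* ``host_only`` — the host alone is the unique minimal set;
* ``symbiont_only`` — a single symbiont is the unique minimal set;
* ``redundant`` — two or more disjoint minimal sets (e.g. host and a
  symbiont can each complete the route independently);
* ``joint`` — every minimal set pools enzymes from at least two genomes;
* ``incomplete`` — even the union of all genomes cannot reach the target.

Completion is a fixed-point reachability computation: compounds start at the
pathway's precursors and a reaction fires once its EC is available in the
queried subset and all its substrates are reachable.  By default all
intermediates are exchangeable within the queried consortium; a restricted
mode shares only the pathway's declared transportable compounds across
genomes, confining other intermediates to the genome whose enzyme produced
them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats_io import EnzymeAnnotation, PathwayDefinition, Reaction, ec_matches

__all__ = [
    "GenomeInventory",
    "CompletionResult",
    "ComplementationLabel",
    "inventories_from_annotations",
    "pathway_completion",
    "minimal_contributor_sets",
    "label_pathway",
    "vitamin_report",
    "complementation_report",
]

ROLES = ("host", "primary_symbiont", "secondary_symbiont")


@dataclass(frozen=True)
class GenomeInventory:
    genome_id: str
    role: str
    ec_set: frozenset[str]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"genome {self.genome_id}: unknown role {self.role!r}")

    def has_ec(self, required: str) -> bool:
        return any(ec_matches(ec, required) for ec in self.ec_set)


@dataclass(frozen=True)
class CompletionResult:
    pathway_id: str
    genome_subset: frozenset[str]
    status: str  # complete | incomplete
    reachable_compounds: frozenset[str]
    missing_ecs: frozenset[str]

    @property
    def complete(self) -> bool:
        return self.status == "complete"


@dataclass(frozen=True)
class ComplementationLabel:
    pathway_id: str
    label: str  # host_only | symbiont_only | joint | redundant | incomplete
    minimal_sets: tuple[frozenset[str], ...]


def inventories_from_annotations(annotations: Iterable[EnzymeAnnotation],
                                 roles: Mapping[str, str]) -> list[GenomeInventory]:
    """Aggregate per-gene EC annotations into per-genome inventories."""
    ec_by_genome: dict[str, set[str]] = {g: set() for g in roles}
    for ann in annotations:
        if ann.genome_id not in ec_by_genome:
            raise ValueError(f"annotation for unknown genome {ann.genome_id!r}")
        ec_by_genome[ann.genome_id] |= ann.ec_numbers
    return [GenomeInventory(g, roles[g], frozenset(ecs))
            for g, ecs in ec_by_genome.items()]


def _can_fire(rx: Reaction, available: set[str], forward: bool) -> bool:
    need = rx.substrates if forward else rx.products
    return need <= available


def pathway_completion(pathway: PathwayDefinition,
                       inventories: Sequence[GenomeInventory],
                       subset: Iterable[str],
                       restrict_transport: bool = False) -> CompletionResult:
    """Decide whether a genome subset can complete a pathway.

    In the default (permissive-transport) mode all reachable compounds are
    pooled across the subset.  With ``restrict_transport`` each genome keeps
    its own compound pool; only precursors and the pathway's
    ``transportable_compounds`` cross genome boundaries.
    """
    subset = frozenset(subset)
    if not subset:
        raise ValueError("pathway_completion: empty genome subset")
    by_id = {inv.genome_id: inv for inv in inventories}
    unknown = subset - by_id.keys()
    if unknown:
        raise ValueError(f"unknown genome id(s): {sorted(unknown)}")
    members = [by_id[g] for g in sorted(subset)]

    if not restrict_transport:
        pooled = set(pathway.precursor_compounds)
        enabled = [rx for rx in pathway.reactions
                   if any(inv.has_ec(rx.ec) for inv in members)]
        changed = True
        while changed:
            changed = False
            for rx in enabled:
                if _can_fire(rx, pooled, True) and not rx.products <= pooled:
                    pooled |= rx.products
                    changed = True
                if rx.reversible and _can_fire(rx, pooled, False) and not rx.substrates <= pooled:
                    pooled |= rx.substrates
                    changed = True
        reachable = frozenset(pooled)
    else:
        shared = set(pathway.precursor_compounds)
        pools: dict[str, set[str]] = {inv.genome_id: set(shared) for inv in members}
        changed = True
        while changed:
            changed = False
            for inv in members:
                pool = pools[inv.genome_id]
                before = len(pool)
                pool |= shared
                for rx in pathway.reactions:
                    if not inv.has_ec(rx.ec):
                        continue
                    for forward in ((True, False) if rx.reversible else (True,)):
                        made = rx.products if forward else rx.substrates
                        if _can_fire(rx, pool, forward) and not made <= pool:
                            pool |= made
                            shared |= made & pathway.transportable_compounds
                if len(pool) != before:
                    changed = True
        reachable = frozenset(set().union(*pools.values()) | shared)

    status = "complete" if pathway.target_compound in reachable else "incomplete"
    # ECs whose addition (to any member) would newly fire a reaction whose
    # substrates are already reachable — the pathway's observable gaps.
    missing = frozenset(
        rx.ec for rx in pathway.reactions
        if not any(inv.has_ec(rx.ec) for inv in members)
        and rx.substrates <= reachable and not rx.products <= reachable
    )
    return CompletionResult(pathway.pathway_id, subset, status, reachable, missing)


def minimal_contributor_sets(pathway: PathwayDefinition,
                             inventories: Sequence[GenomeInventory],
                             restrict_transport: bool = False) -> list[frozenset[str]]:
    """All minimal genome subsets that complete the pathway.

    Exhaustive subset enumeration, limited to at most 6 genomes; the result
    is an antichain (no returned set contains another).  An empty list means
    even the union of all genomes is incomplete.
    """
    ids = sorted(inv.genome_id for inv in inventories)
    if len(ids) > 6:
        raise ValueError("more than 6 genomes: query explicit subsets instead")
    complete: list[frozenset[str]] = []
    for size in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, size):
            s = frozenset(combo)
            if any(m <= s for m in complete):
                continue  # a subset already completes; s is not minimal
            if pathway_completion(pathway, inventories, s, restrict_transport).complete:
                complete.append(s)
    return sorted(complete, key=lambda s: (len(s), sorted(s)))


def label_pathway(pathway_id: str, minimal_sets: Sequence[frozenset[str]],
                  roles: Mapping[str, str]) -> ComplementationLabel:
    """Derive the complementation label from the minimal contributor sets.

    Rules, in order: ``incomplete`` when no set completes; ``host_only`` /
    ``symbiont_only`` when a singleton host / symbiont set is the unique
    minimal set; ``redundant`` when at least two pairwise-disjoint minimal
    sets exist; ``joint`` when every minimal set needs two or more genomes.
    """
    sets = tuple(minimal_sets)
    for a, b in itertools.combinations(sets, 2):
        if a <= b or b <= a:
            raise ValueError("minimal_sets is not an antichain")
    if not sets:
        label = "incomplete"
    elif len(sets) == 1 and len(sets[0]) == 1:
        (genome,) = sets[0]
        label = "host_only" if roles[genome] == "host" else "symbiont_only"
    elif any(a.isdisjoint(b) for a, b in itertools.combinations(sets, 2)):
        label = "redundant"
    elif all(len(s) >= 2 for s in sets):
        label = "joint"
    else:
        # A singleton minimal set alongside overlapping larger ones: the
        # single genome suffices, so the pathway is not joint.
        (genome,) = min(sets, key=len)
        label = "host_only" if roles[genome] == "host" else "symbiont_only"
    return ComplementationLabel(pathway_id, label, sets)


def complementation_report(pathways: Sequence[PathwayDefinition],
                           inventories: Sequence[GenomeInventory],
                           restrict_transport: bool = False) -> pd.DataFrame:
    """Label every pathway; returns a table with one row per pathway."""
    roles = {inv.genome_id: inv.role for inv in inventories}
    rows = []
    for p in pathways:
        msets = minimal_contributor_sets(p, inventories, restrict_transport)
        lab = label_pathway(p.pathway_id, msets, roles)
        union = pathway_completion(p, inventories, list(roles), restrict_transport)
        rows.append({
            "pathway_id": p.pathway_id,
            "target_compound": p.target_compound,
            "label": lab.label,
            "minimal_sets": ";".join("+".join(sorted(s)) for s in msets) or ".",
            "missing_ecs": ",".join(sorted(union.missing_ecs)) or ".",
        })
    return pd.DataFrame(rows)


def vitamin_report(pathways: Sequence[PathwayDefinition],
                   inventories: Sequence[GenomeInventory],
                   restrict_transport: bool = False) -> pd.DataFrame:
    """Complementation labels for vitamin biosynthesis pathways (same
    machinery as amino acids; provided for symmetry with the shipped
    vitamin fixture set)."""
    return complementation_report(pathways, inventories, restrict_transport)
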