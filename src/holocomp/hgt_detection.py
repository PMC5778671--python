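"""Horizontal-gene-transfer candidate calling with anti-contamination filters.

A host gene is an HGT *affinity* candidate when its homology evidence ties it
to bacteria rather than to other metazoa.  Two evidence modes are supported:

* **hit-table mode** — an alien index (best bacterial bit score minus best
  metazoan bit score) above a threshold ``tau`` marks the gene as a
  candidate.  This is an explicit surrogate for phylogenetic evidence.
* **gene-tree mode** — the gene's leaf in a (midpoint-rooted, if unrooted)
  gene tree has a purely bacterial sister clade, or sits at the base of an
  otherwise-bacterial clade adjacent to a metazoan clade.

An affinity candidate is only *called* after passing at least one of two
anti-contamination conditions: (1) its scaffold carries at least one other
gene whose best overall hit is metazoan, or (2) its transcript is supported
by transcriptome evidence.  Gene structure (introns, 5'-UTR) is reported as
corroborating eukaryotic context, not used as a filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy

from .formats_io import GeneModel, HomologHit, TranscriptEvidence

__all__ = [
    "AffinityEvidence",
    "FilterOutcome",
    "HgtCall",
    "HgtSummary",
    "DEFAULT_TAU",
    "affinity_from_hits",
    "affinity_from_tree",
    "contamination_filters",
    "call_hgt",
]

DEFAULT_TAU = 30.0


@dataclass(frozen=True)
class AffinityEvidence:
    gene_id: str
    mode: str  # hit_table | gene_tree
    best_bacterial_bitscore: float = 0.0
    best_metazoan_bitscore: float = 0.0
    sister_composition: str | None = None  # bacterial | metazoan | mixed | basal_to_bacterial
    candidate: bool = False

    @property
    def alien_index(self) -> float:
        return self.best_bacterial_bitscore - self.best_metazoan_bitscore


@dataclass(frozen=True)
class FilterOutcome:
    gene_id: str
    scaffold_context_pass: bool
    transcript_pass: bool

    @property
    def passes(self) -> bool:
        return self.scaffold_context_pass or self.transcript_pass


@dataclass(frozen=True)
class HgtCall:
    gene_id: str
    affinity_candidate: bool
    filter: FilterOutcome
    intron_count: int
    has_5utr: bool
    final: str  # hgt_candidate | rejected_affinity | rejected_contamination


@dataclass(frozen=True)
class HgtSummary:
    n_candidates: int
    n_with_introns: int
    n_with_5utr: int


def _best_hit(hits: Sequence[HomologHit], group: str) -> HomologHit | None:
    pool = [h for h in hits if h.taxon_group == group]
    if not pool:
        return None
    # deterministic: max bit score, ties by smaller e-value then subject id
    return min(pool, key=lambda h: (-h.bit_score, h.e_value, h.subject_id))


def affinity_from_hits(gene_id: str, hits: Sequence[HomologHit],
                       tau: float = DEFAULT_TAU) -> AffinityEvidence:
    """Alien-index affinity from a gene's homology hit list.

    Missing taxon groups score 0; the gene is a candidate when
    ``best_bacterial - best_metazoan > tau``.
    """
    if not hits:
        raise ValueError(f"gene {gene_id}: no hits")
    bact = _best_hit(hits, "bacteria")
    met = _best_hit(hits, "metazoa")
    b = bact.bit_score if bact else 0.0
    m = met.bit_score if met else 0.0
    return AffinityEvidence(gene_id, "hit_table", b, m, None, (b - m) > tau)


def affinity_from_tree(newick: str, focal_leaf: str,
                       leaf_taxon_map: Mapping[str, str]) -> AffinityEvidence:
    """Sister-clade affinity from a gene tree.

    Unrooted trees are midpoint-rooted first.  The sister composition is the
    taxon makeup of the focal leaf's sister clade; ``basal_to_bacterial``
    marks the case where the focal leaf is sister to a purely bacterial clade
    whose own neighbour contains metazoan leaves — the "base of a bacterial
    clade adjacent to an insect clade" topology.  The gene is a candidate
    when the sister is bacterial or basal_to_bacterial.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    unmapped = [l for l in leaves if l not in leaf_taxon_map]
    if unmapped:
        raise ValueError(f"leaves missing from taxon map: {unmapped}")
    if focal_leaf not in leaves:
        raise ValueError(f"focal leaf {focal_leaf!r} not in tree")
    if len(tree.seed_node.child_nodes()) != 2:
        tree.reroot_at_midpoint(update_bipartitions=True)

    focal = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == focal_leaf)

    def clade_groups(node) -> set[str]:
        return {leaf_taxon_map[lf.taxon.label]
                for lf in node.leaf_iter() if lf.taxon.label != focal_leaf}

    parent = focal.parent_node
    if parent is None:
        raise ValueError("degenerate single-leaf tree")
    sisters = [c for c in parent.child_nodes() if c is not focal]
    sister_groups = set().union(*(clade_groups(s) for s in sisters)) if sisters else set()

    if sister_groups == {"bacteria"}:
        # Does the (focal + bacterial sister) clade neighbour metazoa?
        grand = parent.parent_node
        composition = "bacterial"
        if grand is not None:
            uncles = [c for c in grand.child_nodes() if c is not parent]
            uncle_groups = set().union(*(clade_groups(u) for u in uncles)) if uncles else set()
            if "metazoa" in uncle_groups:
                composition = "basal_to_bacterial"
        candidate = True
    elif sister_groups <= {"metazoa"} and sister_groups:
        composition, candidate = "metazoan", False
    else:
        composition, candidate = "mixed", False
    return AffinityEvidence(focal_leaf, "gene_tree", 0.0, 0.0, composition, candidate)


def contamination_filters(gene: GeneModel,
                          cohort_hits: Mapping[str, Sequence[HomologHit]],
                          gene_models: Sequence[GeneModel],
                          transcripts: Mapping[str, bool]) -> FilterOutcome:
    """Apply the two anti-contamination conditions (OR semantics).

    Condition 1 (scaffold context): some *other* gene on the same scaffold
    has a metazoan best overall hit — a gene alone on its scaffold fails.
    Condition 2 (transcript): the gene's transcript is supported.
    """
    neighbours = [g for g in gene_models
                  if g.scaffold_id == gene.scaffold_id and g.gene_id != gene.gene_id]
    context = False
    for nb in neighbours:
        hits = cohort_hits.get(nb.gene_id, ())
        if not hits:
            continue
        best = min(hits, key=lambda h: (-h.bit_score, h.e_value, h.subject_id))
        if best.taxon_group == "metazoa":
            context = True
            break
    transcript = bool(transcripts.get(gene.gene_id, False))
    return FilterOutcome(gene.gene_id, context, transcript)


def call_hgt(evidence: Sequence[AffinityEvidence],
             gene_models: Sequence[GeneModel],
             cohort_hits: Mapping[str, Sequence[HomologHit]],
             transcripts: Iterable[TranscriptEvidence] | Mapping[str, bool]) -> tuple[list[HgtCall], HgtSummary]:
    """Combine affinity evidence and contamination filters into final calls.

    Every gene model must have exactly one evidence record.  The summary
    counts candidates and, among them, those with introns and with a 5'-UTR.
    """
    if not isinstance(transcripts, Mapping):
        transcripts = {t.gene_id: t.supported for t in transcripts}
    ev_by_gene = {e.gene_id: e for e in evidence}
    models_by_gene = {g.gene_id: g for g in gene_models}
    missing = sorted(models_by_gene.keys() - ev_by_gene.keys())
    if missing:
        raise ValueError(f"missing affinity evidence for gene(s): {missing}")

    calls: list[HgtCall] = []
    for gid in sorted(models_by_gene):
        gene = models_by_gene[gid]
        ev = ev_by_gene[gid]
        filt = contamination_filters(gene, cohort_hits, gene_models, transcripts)
        if not ev.candidate:
            final = "rejected_affinity"
        elif not filt.passes:
            final = "rejected_contamination"
        else:
            final = "hgt_candidate"
        calls.append(HgtCall(gid, ev.candidate, filt, gene.intron_count,
                             gene.has_5utr, final))
    cands = [c for c in calls if c.final == "hgt_candidate"]
    summary = HgtSummary(
        n_candidates=len(cands),
        n_with_introns=sum(1 for c in cands if c.intron_count > 0),
        n_with_5utr=sum(1 for c in cands if c.has_5utr),
    )
    return calls, summary
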