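"""Seeded generators for every input the pipeline consumes, each returning a
``ScenarioTruth`` recording the planted ground truth.

The generators emulate, at desk scale, the data classes of a two-species
comparative-genome study of a phloem-feeding insect host and its bacterial
endosymbionts: genome pairs diverged by known substitution and indel rates,
codon-pair sets evolved at known dN/dS, multi-genome enzyme inventories with
planted complementation labels, scaffold/BAC layouts with known adjacency,
gene cohorts with planted bacterial-origin members, and mixed host+symbiont
read pools.

Every generator is deterministic in its ``seed``: identical arguments and
seed give identical outputs (and byte-identical files when written through
:mod:`holocomp.formats_io`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .formats_io import (
    EnzymeAnnotation,
    GeneModel,
    HomologHit,
    PathwayDefinition,
    Reaction,
    SequenceRecord,
    TranscriptEvidence,
    reverse_complement,
)
from .kaks import CODON_TABLE, STOP_CODONS, CodonAlignment

__all__ = [
    "ScenarioTruth",
    "generate_divergent_genome_pair",
    "evolve_codon_pairs",
    "generate_symbiosis_scenario",
    "generate_scaffold_bac_layout",
    "generate_homology_evidence",
    "generate_metagenome_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_NONSTOP_CODONS = sorted(c for c in CODON_TABLE if c not in STOP_CODONS)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class ScenarioTruth:
    """Planted parameters and realized outcomes of one generated dataset."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    realized: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, (frozenset, set)):
                return sorted(o)
            if isinstance(o, np.generic):
                return o.item()
            raise TypeError(f"not JSON-serializable: {type(o)}")
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=default)
            fh.write("\n")


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# Divergent genome pairs
# ---------------------------------------------------------------------------


def generate_divergent_genome_pair(length: int, p: float, q: float,
                                   indel_len_mean: float = 3.0,
                                   rearrangement_count: int = 0,
                                   seed: int = 0) -> tuple[str, str, ScenarioTruth]:
    """Derive genome B from a random ancestor A of ``length`` bases.

    Each retained base of A is substituted with probability ``p``; indel
    events occur at ``q / indel_len_mean`` per ancestral base with
    geometric lengths (mean ``indel_len_mean``), so ``q`` is the expected
    indel bases per ancestral base; finally B is cut into
    ``rearrangement_count + 1`` pieces and the pieces shuffled.

    The truth records *realized* counts: substitutions on bases present in
    both genomes, and total inserted+deleted bases.
    """
    if not 0 <= p < 0.75:
        raise ValueError("substitution rate p must be in [0, 0.75) "
                         "(Jukes-Cantor correction is undefined beyond)")
    if q < 0:
        raise ValueError("indel rate q must be >= 0")
    if length < 1000:
        raise ValueError("length must be >= 1000")
    rng = np.random.default_rng(seed)
    genome_a = _random_dna(rng, length)

    event_rate = q / indel_len_mean if indel_len_mean > 0 else 0.0
    sub_mask = rng.random(length) < p
    indel_mask = rng.random(length) < event_rate

    out: list[str] = []
    n_sub = n_kept = n_ins = n_del = 0
    i = 0
    geo_p = 1.0 / indel_len_mean if indel_len_mean >= 1.0 else 1.0
    while i < length:
        if indel_mask[i]:
            ilen = int(rng.geometric(geo_p))
            if rng.random() < 0.5:  # deletion of [i, i+ilen)
                dlen = min(ilen, length - i)
                n_del += dlen
                i += dlen
                continue
            out.append(_random_dna(rng, ilen))  # insertion before position i
            n_ins += ilen
        base = genome_a[i]
        if sub_mask[i]:
            alt = rng.integers(0, 3)
            base = "ACGT".replace(base, "")[alt]
            n_sub += 1
        n_kept += 1
        out.append(base)
        i += 1
    genome_b = "".join(out)

    if rearrangement_count > 0:
        cuts = sorted(rng.choice(np.arange(1, len(genome_b)), size=rearrangement_count,
                                 replace=False))
        pieces = [genome_b[s:e] for s, e in zip([0] + cuts, cuts + [len(genome_b)])]
        order = rng.permutation(len(pieces))
        genome_b = "".join(pieces[j] for j in order)

    truth = ScenarioTruth(
        kind="divergent_genome_pair",
        params={"length": length, "p": p, "q": q, "indel_len_mean": indel_len_mean,
                "rearrangement_count": rearrangement_count, "seed": seed},
        realized={
            "substitutions": n_sub,
            "kept_bases": n_kept,
            "substitution_fraction": n_sub / n_kept if n_kept else 0.0,
            "inserted_bases": n_ins,
            "deleted_bases": n_del,
            "indel_bases": n_ins + n_del,
        },
    )
    return genome_a, genome_b, truth


# ---------------------------------------------------------------------------
# Codon-pair evolution
# ---------------------------------------------------------------------------


def _evolve_codons(codons: list[str], n_proposals: int, omega: float, kappa: float,
                   rng: np.random.Generator) -> list[str]:
    """Discrete-generation codon Markov chain.

    Proposals pick a random nucleotide position and draw the new base with
    transition:transversion weight ``kappa:1``; proposals creating stop
    codons are rejected; nonsynonymous proposals are accepted with relative
    probability ``omega`` compared to synonymous ones.
    """
    acc_syn = min(1.0, 1.0 / omega)
    acc_non = min(1.0, omega)
    L = len(codons)
    positions = rng.integers(0, 3 * L, size=n_proposals)
    kind = rng.random(n_proposals)       # transition vs transversion
    which_tv = rng.integers(0, 2, size=n_proposals)
    accept = rng.random(n_proposals)
    p_ts = kappa / (kappa + 2.0)
    for t in range(n_proposals):
        pos = int(positions[t])
        ci, off = divmod(pos, 3)
        codon = codons[ci]
        old = codon[off]
        if kind[t] < p_ts:
            new = _TRANSITION[old]
        else:
            tvs = [b for b in "ACGT" if b != old and b != _TRANSITION[old]]
            new = tvs[which_tv[t]]
        mutant = codon[:off] + new + codon[off + 1:]
        if mutant in STOP_CODONS:
            continue
        syn = CODON_TABLE[mutant] == CODON_TABLE[codon]
        if accept[t] < (acc_syn if syn else acc_non):
            codons[ci] = mutant
    return codons


def evolve_codon_pairs(n_pairs: int, codons_per_gene: int, omega: float,
                       kappa: float = 2.0, t: float = 0.4,
                       seed: int = 0) -> tuple[list[CodonAlignment], ScenarioTruth]:
    """Evolve ``n_pairs`` coding-sequence pairs at dN/dS ratio ``omega``.

    Each pair descends from a random stop-free ancestor; both copies evolve
    independently for ``t/2`` expected proposals per nucleotide site under a
    codon chain with ts/tv weight ``kappa`` and nonsynonymous/synonymous
    acceptance ratio ``omega``.
    """
    if omega <= 0 or kappa <= 0:
        raise ValueError("omega and kappa must be > 0")
    if n_pairs < 1 or codons_per_gene < 1:
        raise ValueError("n_pairs and codons_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    pairs: list[CodonAlignment] = []
    n_nt = 3 * codons_per_gene
    for i in range(n_pairs):
        ancestor = [
            _NONSTOP_CODONS[j]
            for j in rng.integers(0, len(_NONSTOP_CODONS), size=codons_per_gene)
        ]
        n_prop = int(rng.poisson(0.5 * t * n_nt))
        seq_a = "".join(_evolve_codons(list(ancestor), n_prop, omega, kappa, rng))
        n_prop = int(rng.poisson(0.5 * t * n_nt))
        seq_b = "".join(_evolve_codons(list(ancestor), n_prop, omega, kappa, rng))
        pairs.append(CodonAlignment((f"gA{i:04d}", f"gB{i:04d}"), seq_a, seq_b))
    truth = ScenarioTruth(
        kind="codon_pairs",
        params={"n_pairs": n_pairs, "codons_per_gene": codons_per_gene,
                "omega": omega, "kappa": kappa, "t": t, "seed": seed},
    )
    return pairs, truth


# ---------------------------------------------------------------------------
# Symbiosis scenarios (pathways + enzyme inventories with planted labels)
# ---------------------------------------------------------------------------

_LABELS = ("host_only", "symbiont_only", "joint", "redundant", "incomplete")


def generate_symbiosis_scenario(label_mix: Sequence[str],
                                genomes: Sequence[tuple[str, str]] = (
                                    ("host", "host"),
                                    ("p_symbiont", "primary_symbiont"),
                                    ("s_symbiont", "secondary_symbiont"),
                                ),
                                min_reactions: int = 4,
                                max_reactions: int = 8,
                                seed: int = 0) -> tuple[
                                    list[PathwayDefinition],
                                    list[EnzymeAnnotation],
                                    ScenarioTruth]:
    """Build one linear pathway per requested label, with EC assignments
    across genomes realizing that label.

    ``label_mix`` lists the desired complementation label of each pathway;
    ``genomes`` is ``(genome_id, role)`` with exactly one host.  Labels that
    need a symbiont raise an error when none is present.
    """
    roles = dict(genomes)
    hosts = [g for g, r in genomes if r == "host"]
    symbionts = [g for g, r in genomes if r != "host"]
    if len(hosts) != 1:
        raise ValueError("exactly one host genome required")
    host = hosts[0]
    for lab in label_mix:
        if lab not in _LABELS:
            raise ValueError(f"unknown label {lab!r}")
        if lab in ("symbiont_only", "joint", "redundant") and not symbionts:
            raise ValueError(f"label {lab!r} impossible without a symbiont genome")

    rng = np.random.default_rng(seed)
    pathways: list[PathwayDefinition] = []
    annotations: list[EnzymeAnnotation] = []
    truth_labels: dict[str, str] = {}

    for pi, label in enumerate(label_mix):
        pid = f"pw{pi:03d}"
        n_rx = int(rng.integers(min_reactions, max_reactions + 1))
        compounds = [f"{pid}_c{j}" for j in range(n_rx + 1)]
        ecs = [f"{int(rng.integers(1, 7))}.{pi + 1}.{j + 1}.{int(rng.integers(1, 100))}"
               for j in range(n_rx)]
        reactions = tuple(
            Reaction(f"{pid}_r{j}", ecs[j], frozenset({compounds[j]}),
                     frozenset({compounds[j + 1]}))
            for j in range(n_rx)
        )
        pathway = PathwayDefinition(pid, compounds[-1], frozenset({compounds[0]}),
                                    reactions, frozenset(compounds))
        pathways.append(pathway)
        truth_labels[pid] = label

        def grant(genome: str, ec_list: Sequence[str]) -> None:
            for j, ec in enumerate(ec_list):
                annotations.append(EnzymeAnnotation(
                    genome, f"{genome}_{pid}_g{j}", frozenset({ec})))

        sym = symbionts[int(rng.integers(0, len(symbionts)))] if symbionts else None
        if label == "host_only":
            grant(host, ecs)
            # partial (strictly prefix) coverage elsewhere keeps host unique
            for s in symbionts:
                grant(s, ecs[: max(0, n_rx - 2)])
        elif label == "symbiont_only":
            grant(sym, ecs)
            grant(host, ecs[: max(0, n_rx - 2)])
        elif label == "joint":
            split = int(rng.integers(1, n_rx))
            grant(host, ecs[:split])
            grant(sym, ecs[split:])
        elif label == "redundant":
            grant(host, ecs)
            grant(sym, ecs)
        elif label == "incomplete":
            missing = int(rng.integers(0, n_rx))
            grant(host, [e for j, e in enumerate(ecs) if j != missing])
            for s in symbionts:
                grant(s, ecs[: max(0, missing - 1)])

    truth = ScenarioTruth(
        kind="symbiosis_scenario",
        params={"label_mix": list(label_mix), "genomes": [list(g) for g in genomes],
                "seed": seed},
        realized={"labels": truth_labels,
                  "roles": roles},
    )
    return pathways, annotations, truth


# ---------------------------------------------------------------------------
# Scaffold / BAC layouts
# ---------------------------------------------------------------------------


def generate_scaffold_bac_layout(n_scaffolds: int = 10,
                                 scaffold_len: int = 8000,
                                 n_bacs: int = 10,
                                 bac_len_range: tuple[int, int] = (3000, 6000),
                                 junction_overlap: int = 1200,
                                 n_chimeric: int = 0,
                                 cover_junctions: bool = True,
                                 flip_prob: float = 0.5,
                                 seed: int = 0) -> tuple[
                                     list[SequenceRecord],
                                     list[SequenceRecord],
                                     ScenarioTruth]:
    """Slice a hidden super-sequence into scaffolds and sample BACs from it.

    Scaffolds are contiguous slices (each independently reverse-complemented
    with probability ``flip_prob``); with ``cover_junctions`` one BAC is
    placed across every scaffold junction with at least ``junction_overlap``
    bases on each side, plus ``n_bacs`` random slices and ``n_chimeric``
    three-scaffold chimeras stitched from terminal pieces of non-adjacent
    scaffolds.  The truth records true order, orientation and every BAC's
    span.
    """
    if n_scaffolds < 2:
        raise ValueError("need at least 2 scaffolds")
    rng = np.random.default_rng(seed)
    lens = rng.integers(int(0.8 * scaffold_len), int(1.2 * scaffold_len) + 1,
                        size=n_scaffolds)
    bounds = np.concatenate([[0], np.cumsum(lens)])
    total = int(bounds[-1])
    super_seq = _random_dna(rng, total)

    ids = [f"S{i:03d}" for i in range(n_scaffolds)]
    flips = rng.random(n_scaffolds) < flip_prob
    scaffolds = []
    for i, sid in enumerate(ids):
        seq = super_seq[bounds[i]:bounds[i + 1]]
        scaffolds.append(SequenceRecord(sid, reverse_complement(seq) if flips[i] else seq))
    emit_order = rng.permutation(n_scaffolds)
    scaffolds_out = [scaffolds[j] for j in emit_order]

    def span_of(lo: int, hi: int) -> list[str]:
        return [ids[i] for i in range(n_scaffolds)
                if lo < bounds[i + 1] and bounds[i] < hi]

    bacs: list[SequenceRecord] = []
    bac_spans: dict[str, list[str]] = {}
    junction_bacs: dict[str, tuple[str, str]] = {}
    if cover_junctions:
        for j in range(n_scaffolds - 1):
            b = int(bounds[j + 1])
            left = int(rng.integers(junction_overlap, junction_overlap + 800))
            right = int(rng.integers(junction_overlap, junction_overlap + 800))
            lo, hi = max(0, b - left), min(total, b + right)
            bid = f"BACJ{j:03d}"
            seq = super_seq[lo:hi]
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            bacs.append(SequenceRecord(bid, seq))
            bac_spans[bid] = span_of(lo, hi)
            junction_bacs[bid] = (ids[j], ids[j + 1])
    for j in range(n_bacs):
        blen = int(rng.integers(bac_len_range[0], bac_len_range[1] + 1))
        lo = int(rng.integers(0, max(1, total - blen)))
        hi = lo + blen
        bid = f"BACR{j:03d}"
        seq = super_seq[lo:hi]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        bacs.append(SequenceRecord(bid, seq))
        bac_spans[bid] = span_of(lo, hi)
    chimeric_ids = []
    for j in range(n_chimeric):
        picks = rng.choice(n_scaffolds, size=3, replace=False)
        pieces = []
        for s in picks:
            lo, hi = int(bounds[s]), int(bounds[s + 1])
            pieces.append(super_seq[lo:lo + junction_overlap]
                          if rng.random() < 0.5 else super_seq[hi - junction_overlap:hi])
        bid = f"BACX{j:03d}"
        bacs.append(SequenceRecord(bid, "".join(pieces)))
        bac_spans[bid] = sorted(ids[s] for s in picks)
        chimeric_ids.append(bid)

    truth = ScenarioTruth(
        kind="scaffold_bac_layout",
        params={"n_scaffolds": n_scaffolds, "scaffold_len": scaffold_len,
                "n_bacs": n_bacs, "n_chimeric": n_chimeric, "seed": seed},
        realized={
            "order": ids,
            "orientation": {sid: ("-" if flips[i] else "+") for i, sid in enumerate(ids)},
            "scaffold_lengths": {sid: int(lens[i]) for i, sid in enumerate(ids)},
            "bac_spans": bac_spans,
            "junction_bacs": {b: list(pair) for b, pair in junction_bacs.items()},
            "chimeric_bacs": chimeric_ids,
        },
    )
    return scaffolds_out, bacs, truth


# ---------------------------------------------------------------------------
# Homology evidence with planted HGT genes
# ---------------------------------------------------------------------------


def generate_homology_evidence(n_genes: int, n_hgt: int, seed: int = 0,
                               emit_trees: bool = False,
                               genes_per_scaffold: int = 4) -> tuple[
                                   list[HomologHit],
                                   list[GeneModel],
                                   list[TranscriptEvidence],
                                   dict[str, str],
                                   ScenarioTruth]:
    """Plant ``n_hgt`` bacterial-origin genes in an ``n_genes`` cohort.

    Planted genes get bacterial best hits well above their metazoan hits
    (bit-score gap >= 100); background genes get metazoan best hits.  Every
    planted gene shares its scaffold with at least one metazoan-best gene and
    has transcript support, so both anti-contamination conditions can be
    evaluated.  With ``emit_trees`` a newick gene tree (focal leaf sister to
    a bacterial clade) is returned per planted gene.
    """
    if n_hgt > n_genes:
        raise ValueError("n_hgt cannot exceed n_genes")
    if n_genes < 2 and n_hgt > 0:
        raise ValueError("need at least one background gene for scaffold context")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    hgt_ids = set(rng.choice(n_genes, size=n_hgt, replace=False).tolist())
    hgt_genes = {gene_ids[i] for i in hgt_ids}

    hits: list[HomologHit] = []
    models: list[GeneModel] = []
    transcripts: list[TranscriptEvidence] = []
    trees: dict[str, str] = {}

    # Round-robin scaffold assignment; background genes outnumber planted
    # ones on mixed scaffolds as long as genes_per_scaffold >= 2.
    n_scaf = max(1, (n_genes + genes_per_scaffold - 1) // genes_per_scaffold)
    for i, gid in enumerate(gene_ids):
        scaf = f"scf{i % n_scaf:03d}"
        start = 1000 * (i // n_scaf)
        is_hgt = gid in hgt_genes
        n_exons = int(rng.integers(1, 4)) if (not is_hgt or rng.random() < 0.6) else 1
        exon_len = 120
        exons = tuple((start + 2 * exon_len * j, start + 2 * exon_len * j + exon_len)
                      for j in range(n_exons))
        end = exons[-1][1]
        has_utr = bool(rng.random() < (0.4 if is_hgt else 0.5))
        models.append(GeneModel(gid, scaf, start, end, "+", exons, has_utr))

        if is_hgt:
            b = float(rng.uniform(200, 300))
            m = float(rng.uniform(50, 100))
            hits.append(HomologHit(gid, f"bact_{gid}", "bacteria", b, 1e-50, 80.0))
            hits.append(HomologHit(gid, f"met_{gid}", "metazoa", m, 1e-10, 40.0))
            transcripts.append(TranscriptEvidence(gid, True))
            if emit_trees:
                trees[gid] = (
                    f"(({gid}:0.10,(bact1_{gid}:0.05,bact2_{gid}:0.05):0.08):0.30,"
                    f"(met1_{gid}:0.10,met2_{gid}:0.10):0.30);"
                )
        else:
            m = float(rng.uniform(150, 300))
            hits.append(HomologHit(gid, f"met_{gid}", "metazoa", m, 1e-60, 85.0))
            if rng.random() < 0.3:
                hits.append(HomologHit(gid, f"bact_{gid}", "bacteria",
                                       float(rng.uniform(30, 60)), 1e-5, 30.0))
            transcripts.append(TranscriptEvidence(gid, bool(rng.random() < 0.8)))

    truth = ScenarioTruth(
        kind="homology_evidence",
        params={"n_genes": n_genes, "n_hgt": n_hgt, "seed": seed},
        realized={"hgt_genes": sorted(hgt_genes)},
    )
    return hits, models, transcripts, trees, truth


# ---------------------------------------------------------------------------
# Metagenome read pools
# ---------------------------------------------------------------------------


def generate_metagenome_reads(references: Sequence[SequenceRecord],
                              proportions: Sequence[float],
                              read_len: int = 100,
                              n_reads: int = 1000,
                              error_rate: float = 0.0,
                              seed: int = 0) -> tuple[list[SequenceRecord], ScenarioTruth]:
    """Draw reads from labelled references at the given proportions, with
    per-base substitution errors; the truth stores each read's origin."""
    if len(references) != len(proportions):
        raise ValueError("one proportion per reference required")
    props = np.asarray(proportions, dtype=float)
    if props.sum() <= 0 or (props < 0).any():
        raise ValueError("proportions must be non-negative and sum > 0")
    props = props / props.sum()
    for ref in references:
        if len(ref.seq) < read_len:
            raise ValueError(f"reference {ref.id} shorter than read length")
    rng = np.random.default_rng(seed)
    origins = rng.choice(len(references), size=n_reads, p=props)
    reads: list[SequenceRecord] = []
    truth_origin: dict[str, str] = {}
    for i, oi in enumerate(origins):
        ref = references[int(oi)]
        pos = int(rng.integers(0, len(ref.seq) - read_len + 1))
        seq = ref.seq[pos:pos + read_len]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        if error_rate > 0:
            chars = list(seq)
            err = np.nonzero(rng.random(read_len) < error_rate)[0]
            for j in err:
                chars[j] = "ACGT".replace(chars[j], "")[int(rng.integers(0, 3))]
            seq = "".join(chars)
        rid = f"r{i:06d}"
        reads.append(SequenceRecord(rid, seq))
        truth_origin[rid] = ref.id
    truth = ScenarioTruth(
        kind="metagenome_reads",
        params={"proportions": props.tolist(), "read_len": read_len,
                "n_reads": n_reads, "error_rate": error_rate, "seed": seed},
        realized={"origin": truth_origin,
                  "counts": {references[j].id: int((origins == j).sum())
                             for j in range(len(references))}},
    )
    return reads, truth
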