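"""Reference-guided read binning and unique k-mer scaffold linking.

Two desk-scale procedures for recovering and improving endosymbiont genome
assemblies from mixed host+symbiont sequencing data:

* :func:`bin_reads` assigns each read to the reference whose canonical
  k-mer set contains the largest fraction of the read's k-mers, subject to a
  minimum containment and a margin over the runner-up.  It is a k-mer
  surrogate for mismatch-tolerant short-read mapping.

* The UGP ("unique genome profile") linking procedure: 31-mers that occur
  exactly once across all scaffolds are collected from each scaffold's
  terminal flanks (:func:`build_unique_tags`); BAC sequences shorter than
  150 kb are queried against the tag index (:func:`link_scaffolds`) and a
  BAC matching exactly two scaffolds links the matched ends.  BACs matching
  more than two scaffolds are discarded as chimeric or repeat-ridden.
  :func:`superscaffold_paths` then walks the unambiguous link graph into
  ordered, oriented scaffold paths.

All k-mers are canonical (lexicographic minimum of the k-mer and its reverse
complement), so every decision is strand-independent.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .formats_io import SequenceRecord, reverse_complement

__all__ = [
    "ReadBinResult",
    "TagIndex",
    "ScaffoldLink",
    "canonical_kmers",
    "bin_reads",
    "build_unique_tags",
    "link_scaffolds",
    "superscaffold_paths",
]


def canonical_kmers(seq: str, k: int) -> Iterable[str]:
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        rc = reverse_complement(kmer)
        yield min(kmer, rc)


@dataclass(frozen=True)
class ReadBinResult:
    read_id: str
    assigned_reference: str | None
    containment: dict[str, float]
    pair_status: str | None = None  # paired | single | unmapped (paired mode)


@dataclass(frozen=True)
class TagIndex:
    k: int
    flank_len: int
    # canonical k-mer -> (scaffold_id, end "left"/"right", offset in scaffold)
    tags: Mapping[str, tuple[str, str, int]]

    def __len__(self) -> int:
        return len(self.tags)


@dataclass(frozen=True)
class ScaffoldLink:
    end_a: tuple[str, str]  # (scaffold_id, "left"|"right")
    end_b: tuple[str, str]
    supporting_bacs: frozenset[str]

    def __post_init__(self) -> None:
        if self.end_a[0] == self.end_b[0]:
            raise ValueError(f"self-link on scaffold {self.end_a[0]}")
        if not self.supporting_bacs:
            raise ValueError("link without supporting BACs")

    @property
    def key(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return tuple(sorted((self.end_a, self.end_b)))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Read binning
# ---------------------------------------------------------------------------


def bin_reads(reads: Sequence[SequenceRecord],
              references: Sequence[SequenceRecord],
              k: int = 21,
              min_containment: float = 0.5,
              margin: float = 0.1,
              mate_pairs: Sequence[tuple[str, str]] | None = None) -> list[ReadBinResult]:
    """Assign reads to references by canonical k-mer containment.

    A read is assigned to the reference with the highest containment if that
    containment is at least ``min_containment`` and exceeds the runner-up by
    at least ``margin``; otherwise it is unassigned.  With ``mate_pairs``
    (pairs of read ids), ``pair_status`` is ``paired`` when both mates assign
    to the same reference, ``single`` when exactly one assigns, ``unmapped``
    otherwise.
    """
    if not references:
        raise ValueError("bin_reads: no references")
    ref_sets = {ref.id: frozenset(canonical_kmers(ref.seq, k)) for ref in references}

    results: dict[str, ReadBinResult] = {}
    for read in reads:
        if k > len(read.seq):
            raise ValueError(f"read {read.id}: k={k} exceeds read length {len(read.seq)}")
        kmers = list(canonical_kmers(read.seq, k))
        if not kmers:
            containment = {rid: 0.0 for rid in ref_sets}
        else:
            containment = {rid: sum(km in rs for km in kmers) / len(kmers)
                           for rid, rs in ref_sets.items()}
        ranked = sorted(containment.items(), key=lambda kv: (-kv[1], kv[0]))
        best_id, best_c = ranked[0]
        runner = ranked[1][1] if len(ranked) > 1 else 0.0
        assigned = best_id if (best_c >= min_containment and best_c - runner >= margin) else None
        results[read.id] = ReadBinResult(read.id, assigned, containment)

    if mate_pairs is not None:
        for r1, r2 in mate_pairs:
            a1 = results[r1].assigned_reference
            a2 = results[r2].assigned_reference
            if a1 is not None and a1 == a2:
                status = "paired"
            elif (a1 is None) != (a2 is None):
                status = "single"
            else:
                status = "unmapped"  # neither assigned, or discordant pair
            for rid in (r1, r2):
                old = results[rid]
                results[rid] = ReadBinResult(old.read_id, old.assigned_reference,
                                             old.containment, status)
    return [results[r.id] for r in reads]


# ---------------------------------------------------------------------------
# UGP scaffold linking
# ---------------------------------------------------------------------------


def build_unique_tags(scaffolds: Sequence[SequenceRecord],
                      k: int = 31, flank_len: int = 20000) -> TagIndex:
    """Index unique canonical k-mers from every scaffold's terminal flanks.

    Candidate k-mers come from the first and last ``flank_len`` bases of each
    scaffold (the whole scaffold when it is shorter than two flanks); a
    candidate is kept only if it occurs exactly once across the full
    sequences of *all* scaffolds, counting both strands via canonical form.
    """
    if not scaffolds:
        raise ValueError("build_unique_tags: no scaffolds")
    if k < 11:
        raise ValueError("build_unique_tags: k < 11 makes uniqueness meaningless")

    counts: Counter[str] = Counter()
    for sc in scaffolds:
        counts.update(canonical_kmers(sc.seq, k))

    tags: dict[str, tuple[str, str, int]] = {}
    for sc in scaffolds:
        seq = sc.seq.upper()
        L = len(seq)
        if L < k:
            continue
        if L <= 2 * flank_len:
            windows = [("left", 0, L)]  # whole scaffold; end decided by midpoint
        else:
            windows = [("left", 0, flank_len), ("right", L - flank_len, L)]
        for _end, lo, hi in windows:
            for i in range(lo, hi - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                canon = min(kmer, reverse_complement(kmer))
                if counts[canon] != 1:
                    continue
                end = "left" if (i + k / 2) < L / 2 else "right"
                tags[canon] = (sc.id, end, i)
    return TagIndex(k, flank_len, tags)


def link_scaffolds(tags: TagIndex, bacs: Sequence[SequenceRecord],
                   max_bac_len: int = 150000,
                   min_tag_hits: int = 5) -> list[ScaffoldLink]:
    """Derive scaffold-end adjacencies from BAC sequences.

    Per BAC: tag matches are tallied per scaffold end; an end counts as
    matched when it accrues at least ``min_tag_hits`` distinct tag k-mers.
    BACs of length >= ``max_bac_len`` are excluded up front; BACs matching
    more than two distinct scaffolds are discarded (chimera/repeat guard);
    BACs matching exactly two scaffolds link the best-supported end of each.
    Duplicate links are merged with their supporting BAC sets unioned.
    """
    if not bacs:
        raise ValueError("link_scaffolds: no BAC sequences")
    merged: dict[tuple, set[str]] = defaultdict(set)
    for bac in bacs:
        if len(bac.seq) >= max_bac_len:
            continue
        end_hits: Counter[tuple[str, str]] = Counter()
        for canon in set(canonical_kmers(bac.seq, tags.k)):
            hit = tags.tags.get(canon)
            if hit is not None:
                end_hits[(hit[0], hit[1])] += 1
        matched_ends = {e for e, n in end_hits.items() if n >= min_tag_hits}
        scaffolds = {s for s, _ in matched_ends}
        if len(scaffolds) != 2:
            continue  # interior (<=1) or chimeric (>2): no link
        picked = []
        for s in sorted(scaffolds):
            ends = [(e, end_hits[e]) for e in matched_ends if e[0] == s]
            ends.sort(key=lambda it: (-it[1], it[0][1]))
            picked.append(ends[0][0])
        key = tuple(sorted(picked))
        merged[key].add(bac.id)
    return [ScaffoldLink(a, b, frozenset(ids))
            for (a, b), ids in sorted(merged.items())]


def superscaffold_paths(links: Sequence[ScaffoldLink],
                        scaffold_ids: Sequence[str]) -> list[list[tuple[str, str]]]:
    """Walk the link graph into ordered, oriented scaffold paths.

    Nodes are scaffold ends; each scaffold contributes an internal
    left--right edge.  A scaffold end with two or more conflicting links
    contributes no join at all (ambiguity rule).  The result is a list of
    maximal simple paths of ``(scaffold_id, orientation)`` with orientation
    ``"+"`` when traversed left→right; every scaffold appears exactly once
    across all paths (unlinked scaffolds as singleton ``"+"`` paths).
    """
    join_count: Counter[tuple[str, str]] = Counter()
    for ln in links:
        join_count[ln.end_a] += 1
        join_count[ln.end_b] += 1

    g = nx.Graph()
    for sid in scaffold_ids:
        g.add_edge((sid, "left"), (sid, "right"), kind="internal")
    for ln in links:
        if join_count[ln.end_a] == 1 and join_count[ln.end_b] == 1:
            g.add_edge(ln.end_a, ln.end_b, kind="join")

    paths: list[list[tuple[str, str]]] = []
    seen: set[str] = set()
    # Deterministic traversal: start from free ends in sorted order, then
    # any remaining (circular) components.
    free_ends = sorted(n for n in g.nodes if g.degree(n) == 1)
    starts = free_ends + sorted(g.nodes)
    for start in starts:
        sid = start[0]
        if sid in seen:
            continue
        path: list[tuple[str, str]] = []
        node = start
        prev = None
        while True:
            scaffold, end = node
            other_end = (scaffold, "right" if end == "left" else "left")
            seen.add(scaffold)
            path.append((scaffold, "+" if end == "left" else "-"))
            nxt = [n for n in g.neighbors(other_end) if n != node and n[0] not in seen]
            prev, node = other_end, (nxt[0] if nxt else None)
            if node is None:
                break
        paths.append(path)
    return paths
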