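"""Syntenic-block divergence statistics and read-mapping rate summaries.

Divergence between two assemblies is computed over a set of non-overlapping
pairwise alignment blocks:

* ``substitution_fraction`` — mismatch columns divided by the focal genome's
  aligned bases within blocks, as a percentage;
* ``indel_fraction`` — gap bases in either row divided by the same
  denominator;
* ``total_divergence`` — their exact sum.

The denominator is each genome's own aligned (non-gap) base count inside the
blocks, i.e. the number of base pairs actually compared, so the two
components add exactly.  Columns containing ``N`` in either row are treated
as unaligned and excluded from every count, so base-calling ambiguity never
inflates divergence.

``toy_align`` is a desk-scale anchor-and-chain aligner (unique shared k-mers
chained colinearly, gaps filled by global alignment with edlib) intended for
synthetic genomes; it stands in for a whole-genome aligner, not for its
scoring model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

from .formats_io import AlignmentBlock, reverse_complement

__all__ = [
    "GenomeDivergence",
    "DivergenceSummary",
    "MappingSummary",
    "toy_align",
    "divergence_stats",
    "mapping_rate_report",
]


@dataclass(frozen=True)
class GenomeDivergence:
    aligned_bases: int
    aligned_fraction: float
    substitution_fraction: float
    indel_fraction: float

    @property
    def total_divergence(self) -> float:
        return self.substitution_fraction + self.indel_fraction


@dataclass(frozen=True)
class DivergenceSummary:
    ref: GenomeDivergence
    query: GenomeDivergence
    n_blocks: int
    mismatch_columns: int
    gap_bases: int


@dataclass(frozen=True)
class MappingSummary:
    paired_ratio: float
    single_ratio: float

    @property
    def total_ratio(self) -> float:
        return self.paired_ratio + self.single_ratio


# ---------------------------------------------------------------------------
# Toy anchor-based aligner
# ---------------------------------------------------------------------------


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        if kmer in dup:
            continue
        if kmer in pos:
            del pos[kmer]
            dup.add(kmer)
        else:
            pos[kmer] = i
    return pos


# Affine gap penalties so that isolated substitutions are never realigned
# into spurious gap pairs (a unit-cost edit distance would underestimate the
# substitution fraction of diverged genome pairs).
_FILL_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=1, mismatch_score=-2,
    open_gap_score=-6, extend_gap_score=-1,
)


def _global_rows(ref_seg: str, qry_seg: str) -> tuple[str, str]:
    if not ref_seg and not qry_seg:
        return "", ""
    if not ref_seg:
        return "-" * len(qry_seg), qry_seg
    if not qry_seg:
        return ref_seg, "-" * len(ref_seg)
    aln = _FILL_ALIGNER.align(ref_seg, qry_seg)[0]
    ref_rows, qry_rows = [], []
    pi = pj = 0
    for (ti, tj), (qi, qj) in zip(*aln.aligned):
        if ti > pi:  # unaligned ref bases -> gap in query
            ref_rows.append(ref_seg[pi:ti])
            qry_rows.append("-" * (ti - pi))
        if qi > pj:
            ref_rows.append("-" * (qi - pj))
            qry_rows.append(qry_seg[pj:qi])
        ref_rows.append(ref_seg[ti:tj])
        qry_rows.append(qry_seg[qi:qj])
        pi, pj = tj, qj
    if len(ref_seg) > pi:
        ref_rows.append(ref_seg[pi:])
        qry_rows.append("-" * (len(ref_seg) - pi))
    if len(qry_seg) > pj:
        ref_rows.append("-" * (len(qry_seg) - pj))
        qry_rows.append(qry_seg[pj:])
    return "".join(ref_rows), "".join(qry_rows)


def _chain_anchors(anchors: list[tuple[int, int]], k: int, max_gap: int
                   ) -> list[tuple[list[tuple[int, int]], int, int]]:
    """Greedy colinear chaining of (ref_pos, qry_pos) anchors sorted by ref.

    Returns chains as ``(anchors, ref_end, qry_end)``; overlapping anchors on
    the same diagonal are not added to the chain but do extend its ends, so a
    chain over an identity region covers it completely.
    """
    chains: list[tuple[list[tuple[int, int]], int, int]] = []
    cur: list[tuple[int, int]] = []
    a_end = b_end = 0
    for a in anchors:
        if not cur:
            cur, a_end, b_end = [a], a[0] + k, a[1] + k
            continue
        pr, pq = cur[-1]
        dr, dq = a[0] - pr, a[1] - pq
        if dr >= k and dq >= k and dr <= max_gap and dq <= max_gap:
            cur.append(a)
            a_end, b_end = a[0] + k, a[1] + k
        elif 0 <= dr < k or 0 <= dq < k:
            if dr == dq and dr > 0:  # same diagonal: extend coverage
                a_end, b_end = max(a_end, a[0] + k), max(b_end, a[1] + k)
            continue
        else:
            chains.append((cur, a_end, b_end))
            cur, a_end, b_end = [a], a[0] + k, a[1] + k
    if cur:
        chains.append((cur, a_end, b_end))
    return chains


def toy_align(genome_a: str, genome_b: str, anchor_k: int = 21,
              min_chain: int = 2, max_gap: int = 2000,
              ref_name: str = "A", query_name: str = "B") -> list[AlignmentBlock]:
    """Align two related genome sequences into syntenic blocks.

    Unique shared ``anchor_k``-mers (checked on both strands of the query)
    seed colinear chains; chains of at least ``min_chain`` anchors are
    gap-filled by global alignment into :class:`AlignmentBlock` records.
    Overlapping chains are resolved greedily by descending anchor count, ties
    by leftmost reference coordinate.  Returns an empty list when no anchors
    are found.
    """
    genome_a, genome_b = genome_a.upper(), genome_b.upper()
    if not genome_a or not genome_b:
        raise ValueError("toy_align: empty genome sequence")
    if anchor_k < 11:
        raise ValueError("toy_align: anchor_k must be >= 11")
    ka = _unique_kmers(genome_a, anchor_k)
    kb_fwd = _unique_kmers(genome_b, anchor_k)
    b_rc = reverse_complement(genome_b)
    kb_rev = _unique_kmers(b_rc, anchor_k)

    candidate_chains: list[tuple[int, int, str, list[tuple[int, int]], int, int]] = []
    for strand, kb, btext in (("+", kb_fwd, genome_b), ("-", kb_rev, b_rc)):
        shared = [(ka[m], kb[m]) for m in ka.keys() & kb.keys()]
        shared.sort()
        for chain, a_end, b_end in _chain_anchors(shared, anchor_k, max_gap):
            if len(chain) >= min_chain:
                candidate_chains.append((len(chain), chain[0][0], strand, chain,
                                         a_end, b_end))

    # Greedy overlap resolution: best (longest) chains claim their intervals.
    candidate_chains.sort(key=lambda c: (-c[0], c[1]))
    taken_a: list[tuple[int, int]] = []
    taken_b: list[tuple[int, int]] = []

    def overlaps(iv: tuple[int, int], taken: list[tuple[int, int]]) -> bool:
        return any(iv[0] < e and s < iv[1] for s, e in taken)

    blocks: list[AlignmentBlock] = []
    for _, _, strand, chain, a_end, b_end in candidate_chains:
        btext = genome_b if strand == "+" else b_rc
        a_lo, a_hi = chain[0][0], a_end
        b_lo, b_hi = chain[0][1], b_end
        if overlaps((a_lo, a_hi), taken_a) or overlaps((b_lo, b_hi), taken_b):
            continue
        taken_a.append((a_lo, a_hi))
        taken_b.append((b_lo, b_hi))

        ref_rows, qry_rows = [], []
        pa, pb = a_lo, b_lo
        for (ra, rb) in chain[1:] + [(a_hi, b_hi)]:
            seg_end_a = ra if (ra, rb) != (a_hi, b_hi) else a_hi
            seg_end_b = rb if (ra, rb) != (a_hi, b_hi) else b_hi
            r, q = _global_rows(genome_a[pa:seg_end_a], btext[pb:seg_end_b])
            ref_rows.append(r)
            qry_rows.append(q)
            pa, pb = seg_end_a, seg_end_b
        ref_aln, qry_aln = "".join(ref_rows), "".join(qry_rows)
        if strand == "+":
            qs, qe = b_lo, b_hi
        else:
            qs, qe = len(genome_b) - b_hi, len(genome_b) - b_lo
        blocks.append(AlignmentBlock(ref_name, query_name, a_lo, a_hi, qs, qe,
                                     strand, ref_aln, qry_aln))
    blocks.sort(key=lambda b: b.ref_start)
    return blocks


# ---------------------------------------------------------------------------
# Divergence statistics
# ---------------------------------------------------------------------------


def _check_non_overlapping(blocks: Sequence[AlignmentBlock]) -> None:
    for which, key in (("reference", lambda b: (b.ref_name, b.ref_start, b.ref_end)),
                       ("query", lambda b: (b.query_name, b.query_start, b.query_end))):
        ivs = sorted(key(b) for b in blocks)
        for prev, cur in zip(ivs, ivs[1:]):
            if prev[0] == cur[0] and cur[1] < prev[2]:
                raise ValueError(
                    f"overlapping blocks on {which} {prev[0]}: "
                    f"[{prev[1]},{prev[2]}) and [{cur[1]},{cur[2]})"
                )


def divergence_stats(blocks: Sequence[AlignmentBlock], len_a: int, len_b: int) -> DivergenceSummary:
    """Substitution, indel and total per-nucleotide divergence over blocks.

    ``len_a`` / ``len_b`` are the full (forward-strand) lengths of the
    reference and query genomes, used only for ``aligned_fraction``.  Columns
    with ``N`` in either row are excluded from all counts; gap bases are
    charged symmetrically to both genomes' summaries, each normalised by its
    own aligned-base denominator.
    """
    _check_non_overlapping(blocks)
    aligned_a = aligned_b = 0
    mismatches = 0
    gap_bases = 0
    for b in blocks:
        for r, q in zip(b.ref_aln, b.query_aln):
            if r == "N" or q == "N":
                continue
            if r != "-":
                aligned_a += 1
            if q != "-":
                aligned_b += 1
            if r == "-" or q == "-":
                gap_bases += 1
            elif r != q:
                mismatches += 1

    def summary(aligned: int, genome_len: int) -> GenomeDivergence:
        if aligned == 0:
            return GenomeDivergence(0, 0.0, 0.0, 0.0)
        return GenomeDivergence(
            aligned_bases=aligned,
            aligned_fraction=100.0 * aligned / genome_len,
            substitution_fraction=100.0 * mismatches / aligned,
            indel_fraction=100.0 * gap_bases / aligned,
        )

    return DivergenceSummary(summary(aligned_a, len_a), summary(aligned_b, len_b),
                             len(blocks), mismatches, gap_bases)


def mapping_rate_report(read_assignments: Iterable[str]) -> MappingSummary:
    """Summarise read-mapping outcomes into paired/single/total percentages.

    Each read is labelled ``paired``, ``single`` or ``unmapped``; ratios are
    over all reads and ``total_ratio`` is their exact sum.
    """
    n = paired = single = 0
    for label in read_assignments:
        if label not in ("paired", "single", "unmapped"):
            raise ValueError(f"unknown read assignment label {label!r}")
        n += 1
        if label == "paired":
            paired += 1
        elif label == "single":
            single += 1
    if n == 0:
        raise ValueError("mapping_rate_report: empty read set")
    return MappingSummary(100.0 * paired / n, 100.0 * single / n)
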