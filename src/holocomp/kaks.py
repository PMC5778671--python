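"""Pairwise Ka/Ks estimation by Nei-Gojobori (1986) counting with the
Jukes-Cantor distance correction, plus the positive-selection screen.

The NG86 method counts, for each codon, the expected fraction of random
single-nucleotide changes that would be synonymous (``s_sites``, with
``n_sites = 3 - s_sites``), averages site counts over the two sequences,
classifies every observed difference as synonymous or nonsynonymous by
averaging over all minimal mutational pathways between the two codons
(pathways passing through a stop codon are excluded), and corrects the
resulting proportions ``pN = Nd/N`` and ``pS = Sd/S`` for multiple hits with
``d = -(3/4) ln(1 - (4/3) p)``.

A single-nucleotide change that would create a stop codon is counted as
nonsynonymous in the site tally, which keeps ``n_sites + s_sites == 3``
exactly for every codon.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import edlib
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "SelectionCall",
    "CohortSummary",
    "ng86_sites",
    "ng86_differences",
    "kaks_pair",
    "selection_screen",
    "rbh_orthologs",
    "rbh_from_hit_table",
    "jukes_cantor",
    "CODON_TABLE",
    "STOP_CODONS",
]

_BASES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    CODON_TABLE[_stop] = "*"


def _translate(codon: str) -> str:
    try:
        return CODON_TABLE[codon]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-free, in-frame pair of aligned coding sequences.

    Terminal stop codons are stripped on construction; internal stops are an
    error.
    """

    gene_id_pair: tuple[str, str]
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        if len(a) != len(b):
            raise ValueError(f"{self.gene_id_pair}: sequences differ in length")
        if len(a) % 3 != 0:
            raise ValueError(f"{self.gene_id_pair}: length not divisible by 3")
        if "-" in a or "-" in b:
            raise ValueError(f"{self.gene_id_pair}: codon alignments must be gap-free")
        if len(a) >= 3 and (a[-3:] in STOP_CODONS or b[-3:] in STOP_CODONS):
            a, b = a[:-3], b[:-3]
        if not a:
            raise ValueError(f"{self.gene_id_pair}: no codons left after stop stripping")
        for i in range(0, len(a), 3):
            if a[i:i + 3] in STOP_CODONS or b[i:i + 3] in STOP_CODONS:
                raise ValueError(f"{self.gene_id_pair}: internal stop codon at {i}")
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i:i + 3], self.seq_b[i:i + 3]


@dataclass(frozen=True)
class KaKsResult:
    gene_id_pair: tuple[str, str]
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    ka: float | None
    ks: float | None
    ratio: float | None
    status: str  # "ok" | "undefined_Ks_zero" | "saturated"

    @property
    def scored(self) -> bool:
        return self.status == "ok"


@dataclass(frozen=True)
class SelectionCall:
    gene_id_pair: tuple[str, str]
    klass: str  # positive_candidate | purifying_or_neutral | unscored


@dataclass(frozen=True)
class CohortSummary:
    n_total: int
    n_scored: int
    mean_ka: float | None
    mean_ks: float | None
    mean_ratio: float | None
    n_positive: int

    @property
    def empty(self) -> bool:
        return self.n_scored == 0


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Nonsynonymous and synonymous site counts of one codon.

    For each of the three positions, the fraction of the three possible
    single-nucleotide changes that preserve the amino acid contributes to
    ``s_sites``; changes to a stop codon count as nonsynonymous.  Returns
    ``(n_sites, s_sites)`` with ``n_sites + s_sites == 3``.
    """
    codon = codon.upper()
    aa = _translate(codon)
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site counts")
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if CODON_TABLE[mutant] == aa:  # stop translates to '*' != aa
                s += 1.0 / 3.0
    return 3.0 - s, s


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Nonsynonymous and synonymous difference counts between two codons.

    Steps of every minimal mutational pathway between the codons are
    classified and averaged over pathways; pathways traversing a stop codon
    are excluded.  If every pathway is excluded, each differing position is
    classified directly by substituting it alone into ``codon_a``.
    """
    a, b = codon_a.upper(), codon_b.upper()
    if _translate(a) == "*" or _translate(b) == "*":
        raise ValueError("stop codons cannot be compared")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0

    pathway_counts: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        cur = a
        nd = sd = 0.0
        valid = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if _translate(nxt) == "*":
                valid = False
                break
            if _translate(nxt) == _translate(cur):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        if valid:
            pathway_counts.append((nd, sd))

    if not pathway_counts:
        # All pathways pass through stops (possible only for 2-3 differences);
        # fall back to per-position direct classification against codon_a.
        nd = sd = 0.0
        for pos in diff_pos:
            mutant = a[:pos] + b[pos] + a[pos + 1:]
            if _translate(mutant) != "*" and _translate(mutant) == _translate(a):
                sd += 1.0
            else:
                nd += 1.0
        return nd, sd

    nd = sum(c[0] for c in pathway_counts) / len(pathway_counts)
    sd = sum(c[1] for c in pathway_counts) / len(pathway_counts)
    return nd, sd


def jukes_cantor(p: float) -> float | None:
    """Jukes-Cantor multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks_pair(alignment: CodonAlignment) -> KaKsResult:
    """Compute the NG86 Ka/Ks result for one aligned ortholog pair.

    Site counts are averaged over the two sequences; differences are summed
    over codon columns.  ``status`` is ``undefined_Ks_zero`` when no
    synonymous difference was observed and ``saturated`` when either
    proportion reaches the Jukes-Cantor pole.
    """
    n_a = s_a = n_b = s_b = 0.0
    nd = sd = 0.0
    for ca, cb in alignment.codon_pairs():
        na, sa = ng86_sites(ca)
        nb, sb = ng86_sites(cb)
        n_a += na
        s_a += sa
        n_b += nb
        s_b += sb
        d_n, d_s = ng86_differences(ca, cb)
        nd += d_n
        sd += d_s
    n_sites = (n_a + n_b) / 2.0
    s_sites = (s_a + s_b) / 2.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    ka = jukes_cantor(pn)
    ks = jukes_cantor(ps)
    if ka is None or ks is None:
        status, ratio = "saturated", None
    elif sd == 0.0:
        status, ratio = "undefined_Ks_zero", None
    else:
        status, ratio = "ok", ka / ks
    return KaKsResult(alignment.gene_id_pair, n_sites, s_sites, nd, sd, pn, ps,
                      ka, ks, ratio, status)


def selection_screen(results: Sequence[KaKsResult]) -> tuple[list[SelectionCall], CohortSummary]:
    """Classify each pair and summarise the scored cohort.

    Unscored pairs (undefined or saturated) are excluded from every mean; the
    mean ratio is the mean of per-pair ratios, not a ratio of means.
    """
    if not results:
        raise ValueError("selection_screen needs at least one result")
    calls: list[SelectionCall] = []
    scored = [r for r in results if r.scored]
    for r in results:
        if not r.scored:
            klass = "unscored"
        elif r.ratio is not None and r.ratio > 1.0:
            klass = "positive_candidate"
        else:
            klass = "purifying_or_neutral"
        calls.append(SelectionCall(r.gene_id_pair, klass))
    if not scored:
        return calls, CohortSummary(len(results), 0, None, None, None, 0)
    mean = lambda xs: sum(xs) / len(xs)
    summary = CohortSummary(
        n_total=len(results),
        n_scored=len(scored),
        mean_ka=mean([r.ka for r in scored]),
        mean_ks=mean([r.ks for r in scored]),
        mean_ratio=mean([r.ratio for r in scored]),
        n_positive=sum(1 for r in scored if r.ratio > 1.0),
    )
    return calls, summary


# ---------------------------------------------------------------------------
# Reciprocal-best-hit ortholog pairing
# ---------------------------------------------------------------------------


def _protein(cds: str) -> str:
    prot = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3].upper()
        aa = CODON_TABLE.get(codon, "X")
        if aa == "*":
            break
        prot.append(aa)
    return "".join(prot)


def rbh_orthologs(cds_set_a: dict[str, str], cds_set_b: dict[str, str],
                  max_distance_frac: float = 0.5) -> list[tuple[str, str]]:
    """Pair genes across two CDS sets by reciprocal best hit.

    Translated sequences are compared by global edit distance; each gene's
    best hit is its minimum-distance partner (ties broken lexicographically),
    and a pair is emitted when the relationship is mutual and the distance is
    below ``max_distance_frac`` of the longer protein.  This is a desk-scale
    stand-in for a BLAST-based family clustering.
    """
    if not cds_set_a or not cds_set_b:
        raise ValueError("rbh_orthologs: empty input set")
    prots_a = {g: _protein(s) for g, s in cds_set_a.items()}
    prots_b = {g: _protein(s) for g, s in cds_set_b.items()}

    def best(query: str, targets: dict[str, str]) -> tuple[str, int] | None:
        best_id, best_d = None, None
        for tid in sorted(targets):
            d = edlib.align(query, targets[tid], mode="NW", task="distance")["editDistance"]
            if best_d is None or d < best_d:
                best_id, best_d = tid, d
        return (best_id, best_d) if best_id is not None else None

    best_ab = {g: best(p, prots_b) for g, p in prots_a.items()}
    best_ba = {g: best(p, prots_a) for g, p in prots_b.items()}
    pairs = []
    for ga, hit in sorted(best_ab.items()):
        if hit is None:
            continue
        gb, dist = hit
        back = best_ba.get(gb)
        if back is None or back[0] != ga:
            continue
        longer = max(len(prots_a[ga]), len(prots_b[gb]), 1)
        if dist / longer <= max_distance_frac:
            pairs.append((ga, gb))
    return pairs


def rbh_from_hit_table(hits_ab, hits_ba, evalue_max: float = 1e-7) -> list[tuple[str, str]]:
    """Reciprocal best hits from externally produced hit tables.

    ``hits_ab`` / ``hits_ba`` are sequences of :class:`~holocomp.formats_io.HomologHit`
    in each search direction; hits above ``evalue_max`` are discarded, best
    hits are chosen by bit score (ties by smaller e-value, then subject id).
    """
    if not hits_ab or not hits_ba:
        raise ValueError("rbh_from_hit_table: empty input set")

    def bests(hits):
        by_query: dict[str, object] = {}
        for h in hits:
            if h.e_value > evalue_max:
                continue
            cur = by_query.get(h.query_gene)
            key = (-h.bit_score, h.e_value, h.subject_id)
            if cur is None or key < (-cur.bit_score, cur.e_value, cur.subject_id):
                by_query[h.query_gene] = h
        return {q: h.subject_id for q, h in by_query.items()}

    fwd, rev = bests(hits_ab), bests(hits_ba)
    return sorted((ga, gb) for ga, gb in fwd.items() if rev.get(gb) == ga)
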