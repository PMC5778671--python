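"""Independent brute-force oracles used by the test suite.

These are deliberately separate implementations of the quantities the
package computes: a per-codon enumeration Ka/Ks calculator built on
Biopython's translation, and a breadth-first compound-set search for
pathway completion.  They share no code with the modules they check.
"""

from __future__ import annotations

import math
from itertools import permutations

from Bio.Seq import Seq

BASES = "ACGT"


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str) -> tuple[float, float]:
    """(n_sites, s_sites) by direct enumeration of all 9 single changes."""
    syn = 0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if aa(mut) != "*" and aa(mut) == aa(codon):
                syn += 1
    s = syn / 3.0
    return 3.0 - s, s


def oracle_diffs(ca: str, cb: str) -> tuple[float, float]:
    """(nd, sd) by exhaustive pathway enumeration with stop exclusion."""
    pos = [i for i in range(3) if ca[i] != cb[i]]
    if not pos:
        return 0.0, 0.0
    tallies = []
    for order in permutations(pos):
        cur, nd, sd, ok = ca, 0, 0, True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1:]
            if aa(nxt) == "*":
                ok = False
                break
            if aa(nxt) == aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            tallies.append((nd, sd))
    if not tallies:
        nd = sd = 0
        for p in pos:
            mut = ca[:p] + cb[p] + ca[p + 1:]
            if aa(mut) != "*" and aa(mut) == aa(ca):
                sd += 1
            else:
                nd += 1
        return float(nd), float(sd)
    return (sum(t[0] for t in tallies) / len(tallies),
            sum(t[1] for t in tallies) / len(tallies))


def oracle_kaks(seq_a: str, seq_b: str):
    """Full NG86+JC result computed codon by codon; returns a dict."""
    n = s = nd = sd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        na, sa = oracle_sites(ca)
        nb, sb = oracle_sites(cb)
        n += (na + nb) / 2.0
        s += (sa + sb) / 2.0
        d = oracle_diffs(ca, cb)
        nd += d[0]
        sd += d[1]
    pn, ps = nd / n, sd / s

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ka, ks = jc(pn), jc(ps)
    if ka is None or ks is None:
        status, ratio = "saturated", None
    elif sd == 0:
        status, ratio = "undefined_Ks_zero", None
    else:
        status, ratio = "ok", ka / ks
    return {"n": n, "s": s, "nd": nd, "sd": sd, "pn": pn, "ps": ps,
            "ka": ka, "ks": ks, "ratio": ratio, "status": status}


def oracle_pathway_complete(pathway, ec_union: set[str]) -> bool:
    """Breadth-first search over compound-set states.

    States are frozensets of reachable compounds; firing any one enabled
    reaction is a transition.  The pathway is complete when any explored
    state contains the target.
    """
    def enabled(rx):
        return any(_ec_match(have, rx.ec) for have in ec_union)

    start = frozenset(pathway.precursor_compounds)
    seen = {start}
    queue = [start]
    while queue:
        state = queue.pop(0)
        if pathway.target_compound in state:
            return True
        for rx in pathway.reactions:
            if not enabled(rx):
                continue
            moves = [(rx.substrates, rx.products)]
            if rx.reversible:
                moves.append((rx.products, rx.substrates))
            for need, make in moves:
                if need <= state:
                    nxt = frozenset(state | make)
                    if nxt not in seen:
                        seen.add(nxt)
                        queue.append(nxt)
    return False


def _ec_match(a: str, b: str) -> bool:
    for fa, fb in zip(a.split("."), b.split(".")):
        if fa == "-" or fb == "-":
            return True
        if fa != fb:
            return False
    return True
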