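"""Readers, writers and domain types for every external representation the
pipeline touches.

All coordinates are 0-based, half-open, on the forward strand.  Dialects that
use other conventions (AXT is 1-based inclusive, with minus-strand query
coordinates given on the reverse-complemented query) are converted at the
boundary, in this module only.

Formats supported:

* FASTA (DNA, alphabet ``{A,C,G,T,N}``; lowercase accepted and uppercased)
* AXT and a single-pair MAF subset for pairwise alignment blocks
* a GFF3 subset (``gene`` / ``exon`` / ``five_prime_UTR`` features)
* TSV tables for homology hits, enzyme annotations and transcript evidence
* JSON pathway definitions (documented schema of our own design)
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "AlignmentBlock",
    "GeneModel",
    "HomologHit",
    "EnzymeAnnotation",
    "Reaction",
    "PathwayDefinition",
    "TranscriptEvidence",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_alignment_blocks",
    "write_alignment_blocks",
    "read_gene_models",
    "write_gene_models",
    "read_homolog_hits",
    "write_homolog_hits",
    "read_enzyme_annotations",
    "write_enzyme_annotations",
    "read_transcript_evidence",
    "write_transcript_evidence",
    "read_pathways",
    "write_pathways",
    "reverse_complement",
    "ec_is_valid",
    "ec_matches",
]

DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# EC number: four fields, digits, with trailing fields optionally dashes
# (dashes must be a suffix: "2.6.1.-" is valid, "2.-.1.1" is not).
_EC_RE = re.compile(r"^\d+\.(?:\d+|-)\.(?:\d+|-)\.(?:\d+|-)$")


class FormatError(ValueError):
    """Raised for any syntactic or semantic violation in an input file."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def ec_is_valid(ec: str) -> bool:
    if not _EC_RE.match(ec):
        return False
    # dashes only as a suffix of fields
    fields = ec.split(".")
    seen_dash = False
    for f in fields[1:]:
        if f == "-":
            seen_dash = True
        elif seen_dash:
            return False
    return True


def ec_matches(annotated: str, required: str) -> bool:
    """Whether an annotated EC satisfies a required EC.

    A trailing-dash (partial) EC on either side matches any completion of the
    specified fields: ``2.6.1.-`` matches ``2.6.1.42`` and vice versa.
    """
    fa, fb = annotated.split("."), required.split(".")
    for a, b in zip(fa, fb):
        if a == "-" or b == "-":
            return True
        if a != b:
            return False
    return True


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence record {self.id!r} contains invalid characters "
                f"{sorted(bad)} (alphabet is A,C,G,T,N; RNA 'U' is not accepted)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentBlock:
    """One gapped pairwise alignment segment between two genomes.

    Coordinates are 0-based half-open on the forward strand of each genome;
    ``query_strand`` records whether the aligned query text is the reverse
    complement of ``[query_start, query_end)``.
    """

    ref_name: str
    query_name: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    query_strand: str  # "+" or "-"
    ref_aln: str
    query_aln: str

    def __post_init__(self) -> None:
        if self.query_strand not in "+-":
            raise FormatError(f"invalid strand {self.query_strand!r}")
        if len(self.ref_aln) != len(self.query_aln):
            raise FormatError(
                f"block {self.ref_name}:{self.ref_start}: gapped rows differ "
                f"in length ({len(self.ref_aln)} vs {len(self.query_aln)})"
            )
        for name, aln, start, end in (
            (self.ref_name, self.ref_aln, self.ref_start, self.ref_end),
            (self.query_name, self.query_aln, self.query_start, self.query_end),
        ):
            ungapped = len(aln) - aln.count("-")
            if ungapped != end - start:
                raise FormatError(
                    f"block {name}:{start}-{end}: ungapped row length "
                    f"{ungapped} does not match coordinate span {end - start}"
                )
            bad = set(aln) - DNA_ALPHABET - {"-"}
            if bad:
                raise FormatError(f"block row contains invalid characters {sorted(bad)}")
        for r, q in zip(self.ref_aln, self.query_aln):
            if r == "-" and q == "-":
                raise FormatError("alignment column with gap in both rows")

    @property
    def n_columns(self) -> int:
        return len(self.ref_aln)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    has_5utr: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"gene {self.gene_id}: empty interval")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise FormatError(f"gene {self.gene_id}: empty exon")
            if s < self.start or e > self.end:
                raise FormatError(f"gene {self.gene_id}: exon outside gene span")
            if prev_end is not None and s < prev_end:
                raise FormatError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def intron_count(self) -> int:
        return max(len(self.exons) - 1, 0)


@dataclass(frozen=True)
class HomologHit:
    query_gene: str
    subject_id: str
    taxon_group: str  # bacteria | metazoa | fungi | other
    bit_score: float
    e_value: float
    identity_pct: float

    def __post_init__(self) -> None:
        if self.taxon_group not in {"bacteria", "metazoa", "fungi", "other"}:
            raise FormatError(f"unknown taxon group {self.taxon_group!r}")
        if not (self.bit_score >= 0 and self.bit_score < float("inf")):
            raise FormatError(f"hit {self.query_gene}->{self.subject_id}: bad bit score")
        if self.e_value < 0:
            raise FormatError(f"hit {self.query_gene}->{self.subject_id}: negative e-value")
        if not 0 <= self.identity_pct <= 100:
            raise FormatError(f"hit {self.query_gene}->{self.subject_id}: identity out of range")


@dataclass(frozen=True)
class EnzymeAnnotation:
    genome_id: str
    gene_id: str
    ec_numbers: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ec_numbers:
            raise FormatError(f"gene {self.gene_id}: empty EC set")
        for ec in self.ec_numbers:
            if not ec_is_valid(ec):
                raise FormatError(f"gene {self.gene_id}: invalid EC number {ec!r}")


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    ec: str
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise FormatError(f"reaction {self.reaction_id}: needs >=1 substrate and product")
        if not ec_is_valid(self.ec):
            raise FormatError(f"reaction {self.reaction_id}: invalid EC {self.ec!r}")


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    target_compound: str
    precursor_compounds: frozenset[str]
    reactions: tuple[Reaction, ...]
    transportable_compounds: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        # Structural sanity: the target must be reachable from the precursors
        # when every reaction is enabled, otherwise the definition is broken.
        reachable = set(self.precursor_compounds)
        changed = True
        while changed:
            changed = False
            for rx in self.reactions:
                if rx.substrates <= reachable and not rx.products <= reachable:
                    reachable |= rx.products
                    changed = True
                if rx.reversible and rx.products <= reachable and not rx.substrates <= reachable:
                    reachable |= rx.substrates
                    changed = True
        if self.target_compound not in reachable:
            raise FormatError(
                f"pathway {self.pathway_id}: target {self.target_compound!r} "
                "unreachable from precursors even with all reactions enabled"
            )

    @property
    def ec_set(self) -> frozenset[str]:
        return frozenset(rx.ec for rx in self.reactions)


@dataclass(frozen=True)
class TranscriptEvidence:
    gene_id: str
    supported: bool


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a DNA FASTA file into validated records, in file order."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise FormatError(f"{path}: record {rec.id!r} contains 'U' (RNA not accepted)")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(rec.id, seq, desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignment blocks: AXT and single-pair MAF subset
# ---------------------------------------------------------------------------


def _axt_to_block(header: Sequence[str], ref_row: str, query_row: str,
                  index: int, query_sizes: dict[str, int] | None) -> AlignmentBlock:
    (_, ref_name, ref_start, ref_end, query_name, q_start, q_end, strand, _score) = header
    rs, re_ = int(ref_start) - 1, int(ref_end)  # 1-based inclusive -> 0-based half-open
    qs, qe = int(q_start) - 1, int(q_end)
    if strand == "-":
        # AXT minus-strand query coordinates are on the reverse-complemented
        # query sequence; converting to forward-strand needs its length.
        if query_sizes is None or query_name not in query_sizes:
            raise FormatError(
                f"block {index}: minus-strand AXT block needs query_sizes[{query_name!r}]"
            )
        size = query_sizes[query_name]
        qs, qe = size - qe, size - qs
    return AlignmentBlock(ref_name, query_name, rs, re_, qs, qe, strand,
                          ref_row.upper(), query_row.upper())


def _read_axt(path: str | Path, query_sizes: dict[str, int] | None) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip() or lines[i].startswith("#"):
            i += 1
            continue
        header = lines[i].split()
        if len(header) != 9:
            raise FormatError(f"{path}: malformed AXT header at line {i + 1}")
        if i + 2 >= len(lines):
            raise FormatError(f"{path}: truncated AXT block at line {i + 1}")
        try:
            blocks.append(_axt_to_block(header, lines[i + 1], lines[i + 2],
                                        len(blocks), query_sizes))
        except FormatError as err:
            raise FormatError(f"{path}: block {len(blocks)}: {err}") from err
        i += 3
    return blocks


def _write_axt(blocks: Iterable[AlignmentBlock], path: str | Path,
               query_sizes: dict[str, int] | None) -> None:
    with open(path, "w") as fh:
        for i, b in enumerate(blocks):
            qs, qe = b.query_start, b.query_end
            if b.query_strand == "-":
                if query_sizes is None or b.query_name not in query_sizes:
                    raise FormatError(
                        f"writing minus-strand AXT needs query_sizes[{b.query_name!r}]"
                    )
                size = query_sizes[b.query_name]
                qs, qe = size - b.query_end, size - b.query_start
            fh.write(
                f"{i} {b.ref_name} {b.ref_start + 1} {b.ref_end} "
                f"{b.query_name} {qs + 1} {qe} {b.query_strand} 0\n"
            )
            fh.write(b.ref_aln + "\n" + b.query_aln + "\n\n")


def _read_maf(path: str | Path) -> list[AlignmentBlock]:
    """Single-pair MAF subset: each ``a`` block holds exactly two ``s`` lines
    (reference first).  MAF carries source sizes, so minus-strand conversion
    is self-contained."""
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    cur: list[list[str]] = []

    def flush() -> None:
        if not cur:
            return
        if len(cur) != 2:
            raise FormatError(f"{path}: block {len(blocks)}: expected exactly 2 's' lines")
        (rname, rstart, rsize, rstrand, _rsrc, rrow) = cur[0]
        (qname, qstart, qsize, qstrand, qsrc, qrow) = cur[1]
        if rstrand != "+":
            raise FormatError(f"{path}: block {len(blocks)}: reference must be + strand")
        rs = int(rstart)
        re_ = rs + int(rsize)
        qs = int(qstart)
        qe = qs + int(qsize)
        if qstrand == "-":
            qs, qe = int(qsrc) - qe, int(qsrc) - qs
        try:
            blocks.append(AlignmentBlock(rname, qname, rs, re_, qs, qe, qstrand,
                                         rrow.upper(), qrow.upper()))
        except FormatError as err:
            raise FormatError(f"{path}: block {len(blocks)}: {err}") from err
        cur.clear()

    for ln in lines:
        if ln.startswith("a"):
            flush()
        elif ln.startswith("s"):
            parts = ln.split()
            if len(parts) != 7:
                raise FormatError(f"{path}: malformed 's' line: {ln!r}")
            cur.append(parts[1:])
        elif not ln.strip() or ln.startswith("#"):
            continue
    flush()
    return blocks


def _write_maf(blocks: Iterable[AlignmentBlock], path: str | Path,
               ref_sizes: dict[str, int], query_sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            fh.write("a score=0\n")
            fh.write(
                f"s {b.ref_name} {b.ref_start} {b.ref_end - b.ref_start} + "
                f"{ref_sizes[b.ref_name]} {b.ref_aln}\n"
            )
            qsize = query_sizes[b.query_name]
            if b.query_strand == "-":
                qstart = qsize - b.query_end
            else:
                qstart = b.query_start
            fh.write(
                f"s {b.query_name} {qstart} {b.query_end - b.query_start} "
                f"{b.query_strand} {qsize} {b.query_aln}\n\n"
            )


def read_alignment_blocks(path: str | Path, dialect: str = "axt",
                          query_sizes: dict[str, int] | None = None) -> list[AlignmentBlock]:
    """Read pairwise alignment blocks, normalising all coordinates to 0-based
    half-open forward-strand convention.

    ``query_sizes`` (forward-strand sequence lengths, keyed by query name) is
    required only for minus-strand AXT blocks, whose coordinates are given on
    the reverse strand; MAF is self-contained.
    """
    if dialect == "axt":
        return _read_axt(path, query_sizes)
    if dialect in ("maf", "maf-subset"):
        return _read_maf(path)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_alignment_blocks(blocks: Sequence[AlignmentBlock], path: str | Path,
                           dialect: str = "axt",
                           ref_sizes: dict[str, int] | None = None,
                           query_sizes: dict[str, int] | None = None) -> None:
    if dialect == "axt":
        _write_axt(blocks, path, query_sizes)
    elif dialect in ("maf", "maf-subset"):
        if ref_sizes is None or query_sizes is None:
            raise ValueError("MAF output needs ref_sizes and query_sizes")
        _write_maf(blocks, path, ref_sizes, query_sizes)
    else:
        raise ValueError(f"unknown alignment dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Gene models (GFF3 subset)
# ---------------------------------------------------------------------------

_GFF_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 subset with ``gene``, ``exon`` and ``five_prime_UTR``
    features; exons/UTRs reference their gene via ``Parent=``."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, ln in enumerate(fh, 1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            try:
                s0, e0 = int(start) - 1, int(end)  # GFF3 is 1-based inclusive
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from err
            attr = dict(_GFF_ATTR_RE.findall(attrs))
            if ftype == "gene":
                gid = attr.get("ID")
                if not gid:
                    raise FormatError(f"{path}:{lineno}: gene feature without ID")
                if gid in genes:
                    raise FormatError(f"{path}:{lineno}: duplicate gene id {gid!r}")
                genes[gid] = {"scaffold": seqid, "start": s0, "end": e0,
                              "strand": strand, "exons": [], "utr5": False}
                order.append(gid)
            elif ftype in ("exon", "five_prime_UTR"):
                parent = attr.get("Parent")
                if not parent or parent not in genes:
                    raise FormatError(f"{path}:{lineno}: {ftype} with unknown Parent")
                if ftype == "exon":
                    genes[parent]["exons"].append((s0, e0))
                else:
                    genes[parent]["utr5"] = True
    out = []
    for gid in order:
        g = genes[gid]
        exons = tuple(sorted(g["exons"]))
        out.append(GeneModel(gid, g["scaffold"], g["start"], g["end"], g["strand"],
                             exons, g["utr5"]))
    return out


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.scaffold_id}\tholocomp\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for s, e in g.exons:
                fh.write(f"{g.scaffold_id}\tholocomp\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tParent={g.gene_id}\n")
            if g.has_5utr:
                s, e = (g.exons[0] if g.exons else (g.start, g.start + 1))
                fh.write(f"{g.scaffold_id}\tholocomp\tfive_prime_UTR\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tParent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> list[tuple[int, dict[str, str]]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty table")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing column(s) {missing}")
        rows = []
        for lineno, row in enumerate(reader, 2):
            if any(row[c] is None for c in required):
                raise FormatError(f"{path}:{lineno}: short row")
            rows.append((lineno, row))
    return rows


def read_homolog_hits(path: str | Path) -> list[HomologHit]:
    hits = []
    for lineno, row in _read_tsv(path, ["query_gene", "subject_id", "taxon_group",
                                        "bit_score", "e_value", "identity_pct"]):
        try:
            hits.append(HomologHit(row["query_gene"], row["subject_id"], row["taxon_group"],
                                   float(row["bit_score"]), float(row["e_value"]),
                                   float(row["identity_pct"])))
        except (ValueError, FormatError) as err:
            raise FormatError(f"{path}:{lineno}: {err}") from err
    return hits


def write_homolog_hits(hits: Iterable[HomologHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_gene\tsubject_id\ttaxon_group\tbit_score\te_value\tidentity_pct\n")
        for h in hits:
            fh.write(f"{h.query_gene}\t{h.subject_id}\t{h.taxon_group}\t"
                     f"{h.bit_score:g}\t{h.e_value:g}\t{h.identity_pct:g}\n")


def read_enzyme_annotations(path: str | Path) -> list[EnzymeAnnotation]:
    out = []
    for lineno, row in _read_tsv(path, ["genome_id", "gene_id", "ec_numbers"]):
        ecs = frozenset(e.strip() for e in row["ec_numbers"].split(",") if e.strip())
        try:
            out.append(EnzymeAnnotation(row["genome_id"], row["gene_id"], ecs))
        except FormatError as err:
            raise FormatError(f"{path}:{lineno}: {err}") from err
    return out


def write_enzyme_annotations(anns: Iterable[EnzymeAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgene_id\tec_numbers\n")
        for a in anns:
            fh.write(f"{a.genome_id}\t{a.gene_id}\t{','.join(sorted(a.ec_numbers))}\n")


def read_transcript_evidence(path: str | Path) -> list[TranscriptEvidence]:
    out, seen = [], set()
    for lineno, row in _read_tsv(path, ["gene_id", "supported"]):
        gid = row["gene_id"]
        if gid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate transcript record for {gid!r}")
        seen.add(gid)
        val = row["supported"].strip().lower()
        if val not in ("true", "false", "1", "0"):
            raise FormatError(f"{path}:{lineno}: unparseable boolean {row['supported']!r}")
        out.append(TranscriptEvidence(gid, val in ("true", "1")))
    return out


def write_transcript_evidence(evs: Iterable[TranscriptEvidence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsupported\n")
        for ev in evs:
            fh.write(f"{ev.gene_id}\t{str(ev.supported).lower()}\n")


# ---------------------------------------------------------------------------
# Pathway definitions (JSON)
# ---------------------------------------------------------------------------


def read_pathways(path: str | Path) -> list[PathwayDefinition]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise FormatError(f"{path}: top level must be a list of pathway objects")
    out = []
    for i, p in enumerate(data):
        try:
            reactions = tuple(
                Reaction(r["reaction_id"], r["ec"], frozenset(r["substrates"]),
                         frozenset(r["products"]), bool(r.get("reversible", False)))
                for r in p["reactions"]
            )
            out.append(PathwayDefinition(
                p["pathway_id"], p["target_compound"],
                frozenset(p["precursor_compounds"]), reactions,
                frozenset(p.get("transportable_compounds", [])),
            ))
        except (KeyError, TypeError) as err:
            raise FormatError(f"{path}: pathway #{i}: missing field {err}") from err
    return out


def write_pathways(pathways: Iterable[PathwayDefinition], path: str | Path) -> None:
    data = [
        {
            "pathway_id": p.pathway_id,
            "target_compound": p.target_compound,
            "precursor_compounds": sorted(p.precursor_compounds),
            "transportable_compounds": sorted(p.transportable_compounds),
            "reactions": [
                {"reaction_id": r.reaction_id, "ec": r.ec,
                 "substrates": sorted(r.substrates), "products": sorted(r.products),
                 "reversible": r.reversible}
                for r in p.reactions
            ],
        }
        for p in pathways
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")
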