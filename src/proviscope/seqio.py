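"""Sequence I/O, ORF calling and the dataset-level filters.

Replicons are plain nucleotide records (ACGTN alphabet).  Gene calls either
come from a deterministic three-start-codon ORF scanner or are imported from
GFF3, mirroring how a pipeline would consume external gene predictions.
Coordinates are 0-based half-open throughout the library; GFF3 import/export
converts to and from the 1-based inclusive convention of that format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = frozenset("ACGTN")
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class ParseError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class Replicon:
    """A nucleotide replicon (contig, chromosome or extracted provirus)."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - NUCLEOTIDES
        if bad:
            raise ValueError(f"replicon {self.id!r}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneCall:
    """A protein-coding gene on a replicon.

    ``source`` distinguishes ORFs predicted by :func:`call_orfs` from gene
    models imported from GFF3; predicted calls satisfy the frame invariants
    (span divisible by three, protein length = span/3 - 1).
    """

    replicon_id: str
    start: int
    end: int
    strand: str
    protein: str
    source: str = "predicted"
    gene_id: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad gene span [{self.start}, {self.end})")
        if self.source == "predicted":
            span = self.end - self.start
            if span % 3 != 0:
                raise ValueError("predicted call span not divisible by 3")
            if len(self.protein) != span // 3 - 1:
                raise ValueError("predicted call protein length inconsistent with span")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Replicon]:
    """Read a FASTA file into :class:`Replicon` records.

    Sequences are upper-cased; duplicate ids are rejected.  A non-empty file
    whose first non-blank line is not a header raises :class:`ParseError`
    with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(f"{path}:{lineno}: expected FASTA header, got {line.strip()[:40]!r}")
                break
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(Replicon(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[Replicon], path: str | Path, width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an ordered ``{id: sequence}`` mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_protein_fasta(proteins: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Dataset filters
# ---------------------------------------------------------------------------

def filter_min_length(records: Sequence[Replicon], min_len: int = 10_000) -> list[Replicon]:
    """Keep replicons of length >= ``min_len`` (inclusive), preserving order.

    The default reproduces the standard 10-kbp contig floor used when mining
    assemblies for integrated viruses (``seqkit seq -m 10000`` semantics).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in records if len(r) >= min_len]


def dedup_identical(records: Sequence[Replicon]) -> tuple[list[Replicon], dict[str, str]]:
    """Collapse records with byte-identical sequences (100% identity).

    Returns the survivors (first occurrence wins, order preserved) and a
    mapping from each removed record id to the id it duplicated.
    """
    kept: list[Replicon] = []
    by_seq: dict[str, str] = {}
    removed: dict[str, str] = {}
    for rec in records:
        owner = by_seq.get(rec.sequence)
        if owner is None:
            by_seq[rec.sequence] = rec.id
            kept.append(rec)
        else:
            removed[rec.id] = owner
    return kept, removed


# ---------------------------------------------------------------------------
# Translation and ORF calling
# ---------------------------------------------------------------------------

def translate(dna: str) -> str:
    """Translate an in-frame coding sequence to protein.

    Alternative starts GTG/TTG are rendered as M, matching prokaryotic
    initiator-tRNA behaviour; a single trailing stop codon is trimmed; an
    internal stop raises ``ValueError`` naming its nucleotide offset.
    """
    dna = dna.upper()
    if len(dna) % 3 != 0:
        raise ValueError(f"coding sequence length {len(dna)} not divisible by 3")
    aas = []
    n_codons = len(dna) // 3
    for i in range(n_codons):
        codon = dna[3 * i : 3 * i + 3]
        aa = _CODON_TABLE.get(codon)
        if aa is None:
            raise ValueError(f"untranslatable codon {codon!r} at offset {3 * i}")
        if aa == "*":
            if i != n_codons - 1:
                raise ValueError(f"internal stop codon at offset {3 * i}")
            break
        aas.append(aa)
    if aas and dna[:3] in ("GTG", "TTG"):
        aas[0] = "M"
    return "".join(aas)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _scan_strand(seq: str, min_aa: int) -> list[tuple[int, int, str]]:
    """Forward-strand ORF scan: (start, end, protein) per complete ORF."""
    n = len(seq)
    out = []
    for frame in range(3):
        pending_start = -1  # first start codon seen since the last in-frame stop
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if pending_start >= 0:
                    end = pos + 3
                    if (end - pending_start) // 3 - 1 >= min_aa:
                        out.append((pending_start, end, translate(seq[pending_start:end])))
                pending_start = -1
            elif pending_start < 0 and codon in START_CODONS:
                pending_start = pos
    return out


def call_orfs(replicon: Replicon, min_aa: int = 100) -> list[GeneCall]:
    """Deterministic ORF caller over both strands.

    An ORF runs from the first start codon (ATG/GTG/TTG) following the
    previous in-frame stop to the next in-frame stop, and must encode at
    least ``min_aa`` residues.  This is a stand-in for statistical gene
    finders: it recovers well-formed genes exactly but has no composition
    model, so imported annotations take precedence in the pipeline when
    available.
    """
    seq = replicon.sequence
    n = len(seq)
    calls = []
    for start, end, prot in _scan_strand(seq, min_aa):
        calls.append(GeneCall(replicon.id, start, end, "+", prot))
    for start, end, prot in _scan_strand(reverse_complement(seq), min_aa):
        calls.append(GeneCall(replicon.id, n - end, n - start, "-", prot))
    calls.sort(key=lambda c: (c.start, c.end, c.strand))
    return [
        replace(c, gene_id=f"{replicon.id}_orf{i + 1}")
        for i, c in enumerate(calls)
    ]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gff3Feature:
    """One GFF3 row; start/end stored 0-based half-open."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    def to_line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items()) or "."
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.type,
                str(self.start + 1),
                str(self.end),
                ".",
                self.strand,
                ".",
                attrs,
            ]
        )


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            attrs = {}
            if parts[8] not in (".", ""):
                for item in parts[8].split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        attrs[k.strip()] = v.strip()
            feats.append(
                Gff3Feature(
                    seqid=parts[0],
                    source=parts[1],
                    type=parts[2],
                    start=int(parts[3]) - 1,
                    end=int(parts[4]),
                    strand=parts[6] if parts[6] in "+-" else "+",
                    attributes=attrs,
                )
            )
    return feats


def write_gff3(features: Iterable[Gff3Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            fh.write(feat.to_line() + "\n")


def genes_from_gff3(
    features: Sequence[Gff3Feature], replicons: dict[str, Replicon]
) -> list[GeneCall]:
    """Import CDS/gene features as :class:`GeneCall` objects.

    Proteins are translated from the replicon sequence when the span is a
    clean coding frame; otherwise the protein field is left empty (imported
    annotations may describe pseudo-genes or partial models).
    """
    calls = []
    for feat in features:
        if feat.type not in ("CDS", "gene"):
            continue
        rep = replicons.get(feat.seqid)
        if rep is None:
            continue
        dna = rep.sequence[feat.start : feat.end]
        if feat.strand == "-":
            dna = reverse_complement(dna)
        try:
            protein = translate(dna)
        except ValueError:
            protein = ""
        calls.append(
            GeneCall(
                replicon_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                protein=protein,
                source="imported",
                gene_id=feat.attributes.get("ID", f"{feat.seqid}_{feat.start}"),
                product=feat.attributes.get("product", ""),
            )
        )
    calls.sort(key=lambda c: (c.replicon_id, c.start, c.end))
    return calls


def trnas_from_gff3(features: Sequence[Gff3Feature]) -> list[Gff3Feature]:
    return [f for f in features if f.type.lower() in ("trna", "trna_gene")]
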