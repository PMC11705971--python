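"""Synthetic-genome forge.

Builds host replicons with implanted provirus cassettes and CRISPR loci and
emits exact ground truth for every feature, so the whole discovery pipeline
is testable without real assemblies.  The forge emulates the signatures the
pipeline keys on -- an HK97-like major capsid protein (MCP) anchor, an
integrase at one cassette end, the direct-repeat attL/attR pair created by
integration-site duplication, and a tRNA gene at one boundary -- on an
i.i.d. nucleotide background at a configurable GC fraction.  It makes no
attempt to model real archaeal composition; what that implies for
interpreting recovery rates is discussed in the methods documentation.

All coordinates are 0-based half-open.  Identical configurations (including
``rng_seed``) produce byte-identical output; per-replicon streams are split
from one root seed so outputs are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import (
    GeneCall,
    Gff3Feature,
    Replicon,
    write_fasta,
    write_gff3,
)

_NT = np.array(list("ACGT"))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
# Codons per amino acid, stops excluded; used to reverse-translate proteins.
_CODONS_BY_AA = {
    "F": ["TTT", "TTC"], "L": ["CTT", "CTC", "CTA", "CTG", "TTA", "TTG"],
    "I": ["ATT", "ATC", "ATA"], "M": ["ATG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"], "Y": ["TAT", "TAC"],
    "H": ["CAT", "CAC"], "Q": ["CAA", "CAG"], "N": ["AAT", "AAC"],
    "K": ["AAA", "AAG"], "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"], "W": ["TGG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
}

# Stop codon in every reading frame, A/T only, free of start codons: keeps
# the deterministic ORF scanner from extending through intergenic space.
FRAME_BLOCKER = "TAAATAAATAA"

CORE_STRUCTURAL_ROLES = (
    "portal protein",
    "head maturation protease",
    "terminase large subunit",
    "minor tail protein",
    "tail assembly chaperone",
)


class ForgeConfigError(ValueError):
    """Raised when a forge configuration is internally infeasible."""


@dataclass(frozen=True)
class CrisprArraySpec:
    """One CRISPR array to forge: ``n_spacers`` spacers between
    ``n_spacers + 1`` identical copies of a random repeat."""

    n_spacers: int
    repeat_length: int = 30
    spacer_length_range: tuple[int, int] = (34, 38)
    with_cas_cluster: bool = False

    def __post_init__(self) -> None:
        if self.n_spacers < 1:
            raise ForgeConfigError("n_spacers must be >= 1")
        if self.repeat_length < 18:
            raise ForgeConfigError("repeat_length must be >= 18")
        lo, hi = self.spacer_length_range
        if lo > hi or lo < 1:
            raise ForgeConfigError("empty spacer_length_range")


@dataclass(frozen=True)
class ForgeConfig:
    """Parameters of the synthetic dataset.

    Defaults mirror the observed conditions the pipeline is built for:
    host replicons well above the 10-kbp contig floor, provirus cassettes
    spanning 10.0--62.7 kbp, and a 30-bp integration-site duplication.
    """

    rng_seed: int = 0
    n_replicons: int = 1
    host_length: int = 100_000
    gc_fraction: float = 0.45
    n_proviruses: int = 1
    provirus_length_range: tuple[int, int] = (10_000, 62_700)
    dr_length: int = 30
    dr_mismatches: int = 0
    trna_at_boundary: bool = True
    integrase_end: str = "left"
    include_lysis_genes: bool = False
    n_decoy_repeats: int = 0
    crispr_spec: tuple[CrisprArraySpec, ...] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.provirus_length_range
        if not (1 <= lo <= hi < self.host_length):
            raise ForgeConfigError(
                "provirus_length_range must lie within [1, host_length)"
            )
        if self.dr_mismatches >= self.dr_length:
            raise ForgeConfigError("dr_mismatches must be < dr_length")
        if self.integrase_end not in ("left", "right"):
            raise ForgeConfigError("integrase_end must be 'left' or 'right'")
        if min(self.n_replicons, self.n_proviruses, self.n_decoy_repeats) < 0:
            raise ForgeConfigError("counts must be >= 0")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ForgeConfigError("gc_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Exact coordinates of one implanted provirus."""

    replicon_id: str
    provirus_start: int
    provirus_end: int
    attL_start: int
    attL_end: int
    attR_start: int
    attR_end: int
    mcp_gene_span: tuple[int, int]
    integrase_gene_span: tuple[int, int]
    trna_span: tuple[int, int] | None
    gene_roles: tuple[tuple[int, int, str, str], ...]  # (start, end, strand, role)

    def __post_init__(self) -> None:
        if not (self.attL_start < self.attL_end <= self.attR_start < self.attR_end):
            raise ValueError("attL must precede attR")
        if not (
            self.provirus_start <= self.mcp_gene_span[0]
            and self.mcp_gene_span[1] <= self.provirus_end
        ):
            raise ValueError("provirus span must contain the MCP gene")


@dataclass(frozen=True)
class CrisprArrayTruth:
    start: int
    end: int
    repeat_consensus: str
    repeat_positions: tuple[int, ...]  # start of each repeat copy
    spacers: tuple[str, ...]
    spacer_positions: tuple[int, ...]
    orientation: str = "+"

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_positions)


@dataclass(frozen=True)
class CrisprLocusTruth:
    arrays: tuple[CrisprArrayTruth, ...]
    cas_genes: tuple[tuple[int, int, str, str], ...]  # (start, end, strand, name)
    nested: bool


# ---------------------------------------------------------------------------
# Low-level sequence synthesis
# ---------------------------------------------------------------------------

def random_dna(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_NT, size=length, p=p))


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def encode_protein(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate a protein into an ORF: ATG + codons + TAA.

    The initial residue is encoded as ATG regardless of its identity, so the
    translated gene starts with M as a real initiator would.
    """
    codons = ["ATG"]
    for aa in protein[1:]:
        choices = _CODONS_BY_AA[aa]
        codons.append(choices[rng.integers(len(choices))])
    codons.append("TAA")
    return "".join(codons)


def mutate_protein(
    protein: str, identity: float, rng: np.random.Generator
) -> str:
    """Return a copy of ``protein`` at approximately the given fractional
    identity, introduced by residue substitutions at random positions."""
    n_sub = round((1.0 - identity) * len(protein))
    positions = rng.choice(len(protein), size=n_sub, replace=False)
    out = list(protein)
    for pos in positions:
        alternatives = _AA20.replace(out[pos], "")
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def mutate_dna(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = "ACGT".replace(out[pos], "")
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Provirus cassette
# ---------------------------------------------------------------------------

def forge_provirus_cassette(
    config: ForgeConfig,
    rng: np.random.Generator,
    target_length: int | None = None,
) -> tuple[str, list[tuple[int, int, str, str, str]]]:
    """Build one provirus cassette.

    Returns the cassette sequence and a gene-role map of
    ``(start, end, strand, role, protein)`` tuples with cassette-local
    coordinates.  The cassette carries one MCP gene, one integrase at the
    configured end, at least three further structural genes, optional
    holin/endolysin genes, and is padded to ``target_length`` with
    hypothetical-protein cargo genes.  Every gene is a clean ORF preceded by
    an all-frame stop motif.
    """
    if target_length is None:
        lo, hi = config.provirus_length_range
        target_length = int(rng.integers(lo, hi + 1)) - 2 * config.dr_length
    roles: list[str] = ["HK97-like major capsid protein"]
    roles.extend(CORE_STRUCTURAL_ROLES)
    if config.include_lysis_genes:
        roles.extend(["holin", "endolysin"])
    if config.integrase_end == "left":
        roles.insert(0, "integrase")

    min_gene_nt = len(FRAME_BLOCKER) + (110 + 2) * 3
    if target_length < (len(roles) + 1) * min_gene_nt:
        raise ForgeConfigError(
            f"cassette target {target_length} bp cannot hold {len(roles) + 1} genes"
        )

    parts: list[str] = []
    gene_map: list[tuple[int, int, str, str, str]] = []
    pos = 0

    def new_protein(length: int) -> str:
        return "M" + random_protein(rng, length - 1)

    def emit_gene(role: str, protein: str) -> None:
        nonlocal pos
        dna = encode_protein(protein, rng)
        parts.append(FRAME_BLOCKER)
        pos += len(FRAME_BLOCKER)
        gene_map.append((pos, pos + len(dna), "+", role, protein))
        parts.append(dna)
        pos += len(dna)

    # When the integrase marks the right end it is emitted last; reserve
    # its footprint so cargo filling leaves exactly enough room.
    tail_protein = None
    fill_target = target_length
    if config.integrase_end == "right":
        tail_protein = new_protein(int(rng.integers(110, 311)))
        fill_target -= len(FRAME_BLOCKER) + 3 * (len(tail_protein) + 1)

    for role in roles:
        emit_gene(role, new_protein(int(rng.integers(110, 311))))

    # Cargo genes fill the remaining span; tail filler keeps exact length.
    while fill_target - pos >= min_gene_nt + len(FRAME_BLOCKER):
        room = (fill_target - pos - len(FRAME_BLOCKER)) // 3 - 2
        length = int(rng.integers(110, min(room, 310) + 1))
        emit_gene("hypothetical protein", new_protein(length))
    if tail_protein is not None:
        pad = fill_target - pos
        if pad > 0:
            parts.append(
                FRAME_BLOCKER[:pad]
                if pad <= len(FRAME_BLOCKER)
                else FRAME_BLOCKER + random_dna(rng, pad - len(FRAME_BLOCKER), config.gc_fraction)
            )
            pos = fill_target
        emit_gene("integrase", tail_protein)
    elif target_length > pos:
        pad = target_length - pos
        parts.append(
            FRAME_BLOCKER[:pad]
            if pad <= len(FRAME_BLOCKER)
            else FRAME_BLOCKER + random_dna(rng, pad - len(FRAME_BLOCKER), config.gc_fraction)
        )
        pos = target_length

    cassette = "".join(parts)
    assert len(cassette) == target_length
    return cassette, gene_map


# ---------------------------------------------------------------------------
# Implantation
# ---------------------------------------------------------------------------

def implant_provirus(
    host: str,
    cassette: str,
    gene_map: Sequence[tuple[int, int, str, str, str]],
    site: int,
    config: ForgeConfig,
    rng: np.random.Generator,
    replicon_id: str = "replicon",
    trna_length: int = 75,
) -> tuple[str, TruthRecord]:
    """Integrate a cassette at ``site``, duplicating the integration site.

    The ``dr_length`` host bases at the site become attL; an identical copy
    (up to ``dr_mismatches`` substitutions) is written after the cassette as
    attR, mimicking integrase-mediated target-site duplication.  When
    ``trna_at_boundary`` is set the duplicated bases are treated as the
    3'-distal end of a tRNA gene, whose span then overlaps attL.
    """
    dr = config.dr_length
    if site < 0 or site + dr > len(host):
        raise ValueError(f"integration site {site} out of range for host of {len(host)} bp")
    att_seq = host[site : site + dr]
    att_r = mutate_dna(att_seq, config.dr_mismatches, rng) if config.dr_mismatches else att_seq

    # The duplicated segment is by definition maximal: if the bases just
    # outside the two copies matched, the duplication would simply be
    # longer.  Enforce that so truth coordinates are unambiguous.
    host_list = list(host)
    if site > 0 and host_list[site - 1] == cassette[-1]:
        host_list[site - 1] = "ACGT".replace(cassette[-1], "")[
            rng.integers(3)
        ]
    if site + dr < len(host) and host_list[site + dr] == cassette[0]:
        host_list[site + dr] = "ACGT".replace(cassette[0], "")[rng.integers(3)]
    host = "".join(host_list)
    att_seq = host[site : site + dr]

    replicon = host[: site + dr] + cassette + att_r + host[site + dr :]

    attL_start, attL_end = site, site + dr
    attR_start = site + dr + len(cassette)
    attR_end = attR_start + dr

    trna_span = None
    if config.trna_at_boundary:
        upstream = max(0, trna_length - dr)
        trna_span = (max(0, attL_start - upstream), attL_end)

    offset = site + dr
    genes = tuple(
        (s + offset, e + offset, strand, role)
        for (s, e, strand, role, _prot) in gene_map
    )
    mcp_span = next((s, e) for (s, e, _st, role) in genes if "capsid" in role)
    intg_span = next((s, e) for (s, e, _st, role) in genes if role == "integrase")

    truth = TruthRecord(
        replicon_id=replicon_id,
        provirus_start=attL_start,
        provirus_end=attR_end,
        attL_start=attL_start,
        attL_end=attL_end,
        attR_start=attR_start,
        attR_end=attR_end,
        mcp_gene_span=mcp_span,
        integrase_gene_span=intg_span,
        trna_span=trna_span,
        gene_roles=genes,
    )
    return replicon, truth


def forge_replicon(
    config: ForgeConfig, replicon_id: str, rng: np.random.Generator
) -> tuple[Replicon, list[TruthRecord], list[tuple[int, int, str, str, str]]]:
    """Forge one replicon: host background + implanted proviruses + decoys.

    Returns the replicon, one truth record per provirus (final
    coordinates), and the combined gene map (replicon coordinates,
    including proteins) for GFF3/role-table output.
    """
    host = random_dna(rng, config.host_length, config.gc_fraction)

    # Decoy exact repeats: paste a repeated word at two host positions.
    for _ in range(config.n_decoy_repeats):
        word = random_dna(rng, config.dr_length, config.gc_fraction)
        sep = int(rng.integers(2 * config.dr_length, config.host_length // 2))
        p1 = int(rng.integers(0, config.host_length - sep - config.dr_length))
        host = (
            host[:p1] + word + host[p1 + config.dr_length :]
        )
        p2 = p1 + sep
        host = host[:p2] + word + host[p2 + config.dr_length :]

    cassettes = []
    total_cassette = 0
    for _ in range(config.n_proviruses):
        cassette, gene_map = forge_provirus_cassette(config, rng)
        cassettes.append((cassette, gene_map))
        total_cassette += len(cassette)

    margin = 500
    n = config.n_proviruses
    usable = config.host_length - 2 * margin - n * (2 * config.dr_length + margin)
    if n > 0 and usable < 0:
        raise ForgeConfigError("host too short for requested proviruses")
    # Integration sites in original host coordinates, ascending, spaced out.
    sites = sorted(
        int(x)
        for x in rng.choice(
            np.arange(margin, config.host_length - margin - config.dr_length),
            size=n,
            replace=False,
        )
    ) if n else []
    # Enforce pairwise spacing in host coordinates.
    for i in range(1, len(sites)):
        if sites[i] - sites[i - 1] < margin + config.dr_length:
            sites[i] = sites[i - 1] + margin + config.dr_length
    if sites and sites[-1] + config.dr_length + margin > config.host_length:
        raise ForgeConfigError("could not place non-overlapping integration sites")

    truths: list[TruthRecord] = []
    all_genes: list[tuple[int, int, str, str, str]] = []
    seq = host
    offset = 0
    for (cassette, gene_map), site in zip(cassettes, sites):
        seq, truth = implant_provirus(
            seq, cassette, gene_map, site + offset, config, rng, replicon_id
        )
        truths.append(truth)
        all_genes.extend(
            (s + truth.attL_end, e + truth.attL_end, st, role, prot)
            for (s, e, st, role, prot) in gene_map
        )
        offset += len(cassette) + config.dr_length

    return Replicon(id=replicon_id, sequence=seq), truths, all_genes


# ---------------------------------------------------------------------------
# CRISPR loci
# ---------------------------------------------------------------------------

_CAS_IB = ("cas6", "cas8b", "cas7", "cas5", "cas3", "cas4", "cas1", "cas2")


def forge_crispr_locus(
    specs: Sequence[CrisprArraySpec],
    rng: np.random.Generator,
    gc: float = 0.45,
    shared_repeat: bool = True,
    orientation: str = "+",
) -> tuple[str, CrisprLocusTruth]:
    """Forge a CRISPR locus, optionally nested inside a cas gene cluster.

    Arrays use identical repeat copies of one random consensus (shared
    across arrays when ``shared_repeat``) separated by mutually distinct
    spacers.  When any spec requests a cas cluster and there are at least
    two arrays, the cluster is split around the arrays so that both arrays
    sit between cas genes, all in one transcriptional orientation --
    the nested-layout configuration.
    """
    if not specs:
        raise ForgeConfigError("at least one array spec required")
    parts: list[str] = []
    pos = 0
    arrays: list[CrisprArrayTruth] = []
    cas_genes: list[tuple[int, int, str, str]] = []
    want_cas = any(s.with_cas_cluster for s in specs)
    nested = want_cas and len(specs) >= 2

    consensus_shared = random_dna(rng, specs[0].repeat_length, gc) if shared_repeat else None
    seen_spacers: set[str] = set()

    def emit(seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    def emit_cas(names: Sequence[str]) -> None:
        for name in names:
            emit(FRAME_BLOCKER)
            prot = "M" + random_protein(rng, int(rng.integers(150, 400)) - 1)
            dna = encode_protein(prot, rng)
            cas_genes.append((pos, pos + len(dna), orientation, name))
            emit(dna)

    emit(random_dna(rng, 200, gc))
    if want_cas:
        emit_cas(_CAS_IB[:4])
        emit(random_dna(rng, 150, gc))

    for k, spec in enumerate(specs):
        if consensus_shared is not None and len(consensus_shared) == spec.repeat_length:
            consensus = consensus_shared
        else:
            consensus = random_dna(rng, spec.repeat_length, gc)
        start = pos
        repeat_positions: list[int] = []
        spacers: list[str] = []
        spacer_positions: list[int] = []
        lo, hi = spec.spacer_length_range
        for i in range(spec.n_spacers + 1):
            repeat_positions.append(pos)
            emit(consensus)
            if i < spec.n_spacers:
                while True:
                    spacer = random_dna(rng, int(rng.integers(lo, hi + 1)), gc)
                    if spacer not in seen_spacers:
                        seen_spacers.add(spacer)
                        break
                spacers.append(spacer)
                spacer_positions.append(pos)
                emit(spacer)
        arrays.append(
            CrisprArrayTruth(
                start=start,
                end=pos,
                repeat_consensus=consensus,
                repeat_positions=tuple(repeat_positions),
                spacers=tuple(spacers),
                spacer_positions=tuple(spacer_positions),
                orientation=orientation,
            )
        )
        if k < len(specs) - 1:
            emit(random_dna(rng, 300, gc))

    if want_cas:
        emit(random_dna(rng, 150, gc))
        emit_cas(_CAS_IB[4:])
    emit(random_dna(rng, 200, gc))

    truth = CrisprLocusTruth(
        arrays=tuple(arrays), cas_genes=tuple(cas_genes), nested=nested
    )
    return "".join(parts), truth


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------

def forge_dataset(config: ForgeConfig, outdir: str | Path) -> dict[str, Path]:
    """Forge a full dataset and write FASTA + GFF3 + truth BED + role TSV.

    Per-replicon RNG streams are split from the root seed, so each
    replicon's content is independent of how many others are forged.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.rng_seed)
    children = root.spawn(config.n_replicons)

    replicons: list[Replicon] = []
    features: list[Gff3Feature] = []
    bed_rows: list[str] = []
    role_rows: list[str] = ["replicon_id\tgene_id\tstart\tend\tstrand\trole\tprotein"]

    for i, child in enumerate(children):
        rid = f"SYN{i + 1:04d}"
        rng = np.random.default_rng(child)
        rep, truths, genes = forge_replicon(config, rid, rng)
        replicons.append(rep)
        for j, (s, e, st, role, prot) in enumerate(genes):
            gid = f"{rid}_g{j + 1}"
            features.append(
                Gff3Feature(rid, "proviscope_forge", "CDS", s, e, st,
                            {"ID": gid, "product": role})
            )
            role_rows.append(f"{rid}\t{gid}\t{s}\t{e}\t{st}\t{role}\t{prot}")
        for k, t in enumerate(truths):
            bed_rows.append(f"{rid}\t{t.provirus_start}\t{t.provirus_end}\t{rid}_pro{k + 1}")
            for name, (s, e) in (("attL", (t.attL_start, t.attL_end)),
                                 ("attR", (t.attR_start, t.attR_end))):
                features.append(
                    Gff3Feature(rid, "proviscope_forge", "direct_repeat", s, e, "+",
                                {"ID": f"{rid}_{name}{k + 1}", "Name": name})
                )
            if t.trna_span is not None:
                features.append(
                    Gff3Feature(rid, "proviscope_forge", "tRNA",
                                t.trna_span[0], t.trna_span[1], "+",
                                {"ID": f"{rid}_trna{k + 1}"})
                )

    paths = {
        "fasta": outdir / "replicons.fna",
        "gff3": outdir / "features.gff3",
        "bed": outdir / "truth_proviruses.bed",
        "roles": outdir / "gene_roles.tsv",
    }
    write_fasta(replicons, paths["fasta"])
    write_gff3(features, paths["gff3"])
    paths["bed"].write_text("".join(row + "\n" for row in bed_rows))
    paths["roles"].write_text("".join(row + "\n" for row in role_rows))
    return paths


def gene_calls_from_map(
    replicon_id: str, genes: Sequence[tuple[int, int, str, str, str]]
) -> list[GeneCall]:
    """Convert a forge gene map into imported-style :class:`GeneCall` rows."""
    return [
        GeneCall(
            replicon_id=replicon_id,
            start=s,
            end=e,
            strand=st,
            protein=prot,
            source="imported",
            gene_id=f"{replicon_id}_g{i + 1}",
            product=role,
        )
        for i, (s, e, st, role, prot) in enumerate(genes)
    ]
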