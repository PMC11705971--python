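"""Lifestyle calling, summary counts, and pipeline orchestration.

A provirus has lytic potential when it carries lysis effectors (holin or
endolysin genes) or an external lifestyle classifier labels it Virulent;
integration-capable but lysis-gene-carrying proviruses therefore still
count as lysis-capable.  External labels are an optional input (a
PhaTYP-style prediction table); when absent, records default to Temperate
so the lysis-gene rule alone drives the call.

The package ships a published compilation of lifestyle predictions for 39
archaeal proviruses (accession, genome length, predicted lifestyle with
its score, and whether holin/endolysin genes were annotated) as a worked
dataset for the summarization functions.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import boundary, featureannot, genenet, mcpsearch, protcompare, seqio
from .featureannot import FunctionalTag, Lexicon

SUMMARY_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ProvirusRecord:
    accession: str
    length: int
    lifestyle_label: str  # "Virulent" | "Temperate"
    label_score: float
    has_lysis_genes: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.label_score <= 1.0):
            raise ValueError("label_score must be in [0, 1]")


@dataclass(frozen=True)
class SummaryCounts:
    n_total: int
    n_virulent: int
    n_temperate: int
    n_virulent_with_lysis: int
    n_temperate_with_lysis: int
    n_lytic_potential: int


def load_lifestyle_table(path: str | Path | None = None) -> list[ProvirusRecord]:
    """Load a lifestyle prediction table (the bundled compilation by default)."""
    if path is None:
        ref = importlib.resources.files("proviscope") / "data" / "lifestyle_predictions.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    records = []
    seen = set()
    for row in df.itertuples():
        if row.accession in seen:
            raise ValueError(f"duplicate accession {row.accession!r}")
        seen.add(row.accession)
        records.append(
            ProvirusRecord(
                accession=row.accession,
                length=int(row.length_bp),
                lifestyle_label=row.lifestyle,
                label_score=float(row.score),
                has_lysis_genes=bool(row.lysis_genes),
            )
        )
    return records


def call_lifestyle(
    tags: Iterable[FunctionalTag] | None,
    external_label: str | None = None,
    has_lysis_genes: bool | None = None,
) -> tuple[bool, str]:
    """Combine lysis-gene evidence with an external lifestyle label.

    ``lytic_potential`` is true when any lysis-category tag is present (or
    ``has_lysis_genes`` is set, for pre-tabulated records) OR the external
    label is Virulent.  Returns the flag and the clause that fired
    ("lysis-gene", "external", or "none").
    """
    lysis = bool(has_lysis_genes)
    if tags is not None:
        lysis = lysis or any(t.category == "lysis" for t in tags)
    if lysis:
        return True, "lysis-gene"
    if external_label == "Virulent":
        return True, "external"
    return False, "none"


def summarize(records: Sequence[ProvirusRecord]) -> SummaryCounts:
    """Count lifestyles and lysis-capable records.

    Lytic potential combines the Virulent label with the lysis-gene flag,
    so n_lytic_potential = n_virulent + n_temperate_with_lysis.
    """
    for rec in records:
        if rec.lifestyle_label not in ("Virulent", "Temperate"):
            raise ValueError(
                f"record {rec.accession!r}: unknown label {rec.lifestyle_label!r}"
            )
    n_vir = sum(r.lifestyle_label == "Virulent" for r in records)
    n_tem = len(records) - n_vir
    n_vl = sum(
        r.lifestyle_label == "Virulent" and r.has_lysis_genes for r in records
    )
    n_tl = sum(
        r.lifestyle_label == "Temperate" and r.has_lysis_genes for r in records
    )
    n_lytic = sum(
        call_lifestyle(None, r.lifestyle_label, r.has_lysis_genes)[0]
        for r in records
    )
    return SummaryCounts(
        n_total=len(records),
        n_virulent=n_vir,
        n_temperate=n_tem,
        n_virulent_with_lysis=n_vl,
        n_temperate_with_lysis=n_tl,
        n_lytic_potential=n_lytic,
    )


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration.

    ``genome_fasta`` is mandatory; gene annotations (GFF3), seed MCP
    proteins (FASTA) and a lifestyle label table (TSV) are optional.
    Stages: filter -> gene import/ORF calling -> MCP search -> boundary
    delimitation -> extraction -> proteome comparison -> gene-sharing
    network -> annotation -> summary.
    """

    genome_fasta: str
    seeds_fasta: str | None = None
    annotations_gff3: str | None = None
    labels_tsv: str | None = None
    out_dir: str = "proviscope_run"
    min_contig_len: int = 10_000
    min_orf_aa: int = 100
    skip_network: bool = False
    skip_compare: bool = False
    search: mcpsearch.SearchConfig = mcpsearch.SearchConfig()
    boundary: boundary.BoundaryConfig = boundary.BoundaryConfig()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full discovery pipeline and write a run directory.

    Deterministic: identical inputs and configuration give byte-identical
    summary output.  Returns the summary dictionary.
    """
    out = Path(config.out_dir)
    genome_path = Path(config.genome_fasta)
    if not genome_path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {genome_path}")
    if config.seeds_fasta is not None and not Path(config.seeds_fasta).exists():
        raise FileNotFoundError(f"seed FASTA not found: {config.seeds_fasta}")
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(msg: str) -> None:
        log.append(msg)

    # Stage 1: length filter + dedup.
    replicons = seqio.read_fasta(genome_path)
    replicons = seqio.filter_min_length(replicons, config.min_contig_len)
    replicons, removed = seqio.dedup_identical(replicons)
    rep_by_id = {r.id: r for r in replicons}
    stage(f"filter: {len(replicons)} replicons kept, {len(removed)} redundant removed")

    # Stage 2: gene calls (imported GFF3 takes precedence) and tRNAs.
    trnas: list[seqio.Gff3Feature] = []
    if config.annotations_gff3:
        feats = seqio.read_gff3(config.annotations_gff3)
        gene_calls = seqio.genes_from_gff3(feats, rep_by_id)
        trnas = seqio.trnas_from_gff3(feats)
        stage(f"genes: imported {len(gene_calls)} calls, {len(trnas)} tRNAs")
    else:
        gene_calls = []
        for rep in replicons:
            gene_calls.extend(seqio.call_orfs(rep, config.min_orf_aa))
        stage(f"genes: predicted {len(gene_calls)} ORFs")

    # Stage 3: MCP search.
    scheme = mcpsearch.ScoringScheme()
    hits: list[mcpsearch.AlignmentHit] = []
    if config.seeds_fasta:
        seeds = seqio.read_protein_fasta(config.seeds_fasta)
        db = {
            g.gene_id: g.protein for g in gene_calls if g.protein
        }
        hits, _queries = mcpsearch.iterative_search(seeds, db, scheme, config.search)
        mcpsearch.hits_to_tsv(hits, out / "mcp_hits.tsv")
    stage(f"mcpsearch: {len(hits)} accepted MCP hits")

    # Stage 4/5: boundary calls and extraction.
    gene_by_id = {g.gene_id: g for g in gene_calls}
    mcp_by_rep: dict[str, list[seqio.GeneCall]] = {}
    for h in hits:
        gene = gene_by_id[h.subject_id]
        mcp_by_rep.setdefault(gene.replicon_id, []).append(gene)
    calls: list[boundary.ProvirusCall] = []
    extracted: list[seqio.Replicon] = []
    features: list[seqio.Gff3Feature] = []
    for rid in sorted(mcp_by_rep):
        rep = rep_by_id[rid]
        rep_genes = [g for g in gene_calls if g.replicon_id == rid]
        rep_trnas = [t for t in trnas if t.seqid == rid]
        for call in boundary.call_provirus(
            rep, mcp_by_rep[rid], rep_genes, rep_trnas, config.boundary
        ):
            calls.append(call)
            if call.completeness == "complete":
                sub, feats = boundary.extract_provirus(rep, call)
                extracted.append(sub)
                features.extend(feats)
    n_complete = sum(c.completeness == "complete" for c in calls)
    stage(f"boundary: {n_complete} complete calls, {len(calls) - n_complete} partial")
    if extracted:
        seqio.write_fasta(extracted, out / "proviruses.fna")
        seqio.write_gff3(features, out / "proviruses.gff3")
    with open(out / "calls.tsv", "w") as fh:
        fh.write("replicon_id\tstart\tend\tcompleteness\tscore\tmcp_gene\n")
        for c in calls:
            fh.write(
                f"{c.replicon_id}\t{c.start}\t{c.end}\t{c.completeness}\t"
                f"{c.score:.2f}\t{c.mcp_gene.gene_id}\n"
            )
    with open(out / "truth_spans.bed", "w") as fh:
        for c in calls:
            if c.completeness == "complete":
                fh.write(f"{c.replicon_id}\t{c.start}\t{c.end}\t{c.replicon_id}_pro\n")

    # Proteomes of extracted proviruses (genes within each call).
    proteomes: dict[str, dict[str, str]] = {}
    for c in calls:
        if c.completeness != "complete":
            continue
        pid = f"{c.replicon_id}_pro"
        proteomes[pid] = {
            g.gene_id: g.protein
            for g in gene_calls
            if g.replicon_id == c.replicon_id
            and g.start >= c.start
            and g.end <= c.end
            and g.protein
        }

    # Stage 6: proteome comparison.
    if not config.skip_compare and len(proteomes) >= 2:
        metrics = protcompare.all_pair_metrics(proteomes, scheme)
        for field in ("aai", "of", "sg"):
            protcompare.metrics_matrix(metrics, field).to_csv(
                out / f"matrix_{field}.tsv", sep="\t"
            )
        if len(proteomes) >= 3:
            dist = 1.0 - protcompare.metrics_matrix(metrics, "sg")
            (out / "proteome_tree.nwk").write_text(protcompare.nj_tree(dist) + "\n")
        stage(f"compare: {len(metrics)} genome pairs")

    # Stage 7: gene-sharing network.
    if not config.skip_network and len(proteomes) >= 2:
        flat = {
            (gid, pid): seq
            for gid, prots in proteomes.items()
            for pid, seq in prots.items()
        }
        pcs = genenet.build_pcs(flat, scheme)
        edges = genenet.build_edges(pcs, genomes=proteomes)
        assignments, vcs = genenet.assign_vcs(edges, proteomes)
        with open(out / "network_edges.tsv", "w") as fh:
            fh.write("genome_a\tgenome_b\tshared_pcs\tsig\n")
            for e in edges:
                fh.write(f"{e.genome_a}\t{e.genome_b}\t{e.c}\t{e.sig:.3f}\n")
        with open(out / "vc_membership.tsv", "w") as fh:
            fh.write("genome\tstate\tvc_ids\n")
            for g in sorted(assignments):
                a = assignments[g]
                fh.write(f"{g}\t{a.state}\t{','.join(a.vc_ids)}\n")
        stage(f"network: {len(pcs)} PCs, {len(vcs)} VCs")

    # Stage 8: annotation + lifestyle.
    lexicon = Lexicon.default()
    labels: dict[str, tuple[str, float]] = {}
    if config.labels_tsv:
        for rec in load_lifestyle_table(config.labels_tsv):
            labels[rec.accession] = (rec.lifestyle_label, rec.label_score)
    records: list[ProvirusRecord] = []
    for c in calls:
        if c.completeness != "complete":
            continue
        pid = f"{c.replicon_id}_pro"
        ann = [
            (g.gene_id, g.product)
            for g in gene_calls
            if g.replicon_id == c.replicon_id
            and g.start >= c.start
            and g.end <= c.end
        ]
        tags = featureannot.tag_functions(ann, lexicon)
        label, score = labels.get(pid, ("Temperate", 0.5))
        lytic, _basis = call_lifestyle(tags, label)
        records.append(
            ProvirusRecord(
                accession=pid,
                length=c.end - c.start,
                lifestyle_label=label,
                label_score=score,
                has_lysis_genes=any(t.category == "lysis" for t in tags),
            )
        )
    counts = summarize(records) if records else SummaryCounts(0, 0, 0, 0, 0, 0)

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "n_replicons": len(replicons),
        "n_mcp_hits": len(hits),
        "n_provirus_calls": len(calls),
        "n_complete": n_complete,
        "n_partial": len(calls) - n_complete,
        "counts": asdict(counts),
        "log": log,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
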