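"""Iterative major-capsid-protein homology search.

The anchor of provirus discovery is a protein-level homology search seeded
with known MCP sequences.  Alignment is optimal local Smith--Waterman under
affine gaps (BLOSUM62 by default); significance uses the Karlin--Altschul
statistic E = K*m*n*exp(-lambda*S) with published gapped BLOSUM62
parameters.  Hits passing the acceptance thresholds (E-value < 1e-5,
identity > 30%, coverage > 50%) join the query set for the next round, a
deterministic seed-set expansion standing in for PSSM-based iteration: the
thresholds, not the exact profile statistics, are the contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from Bio.Align import PairwiseAligner, substitution_matrices

VALID_AA = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*")

# Gapped BLOSUM62 Karlin-Altschul parameters (open 11 / extend 1 regime).
DEFAULT_LAMBDA = 0.267
DEFAULT_KAPPA = 0.041


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring and E-value calibration.

    ``gap_open`` and ``gap_extend`` are positive penalties; a gap of length
    g costs ``gap_open + g * gap_extend``.  ``m`` and ``n`` are the
    effective query and database lengths used by the E-value formula; raw
    lengths are used, with no edge-effect correction.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    lam: float = DEFAULT_LAMBDA
    kappa: float = DEFAULT_KAPPA
    m: int | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("lambda and kappa must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def with_lengths(self, m: int, n: int) -> "ScoringScheme":
        return replace(self, m=m, n=n)

    @property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


@dataclass(frozen=True)
class AlignmentHit:
    """One scored local protein alignment."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    evalue: float
    identity: float
    query_coverage: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    round_found: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.query_coverage <= 1.0):
            raise ValueError("identity and coverage must be fractions in [0, 1]")
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")


@dataclass(frozen=True)
class SearchConfig:
    """Acceptance thresholds of the iterative search."""

    evalue_max: float = 1e-5
    identity_min: float = 0.30
    coverage_min: float = 0.50
    max_iterations: int = 10
    validate_hits: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.identity_min <= 1 and 0 < self.coverage_min <= 1):
            raise ValueError("fractional thresholds must be in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    def passes(self, hit: AlignmentHit) -> bool:
        return (
            hit.evalue < self.evalue_max
            and hit.identity > self.identity_min
            and hit.query_coverage > self.coverage_min
        )


def _check_protein(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty protein sequence")
    for i, ch in enumerate(seq):
        if ch not in VALID_AA:
            raise ValueError(f"{label}: invalid residue {ch!r} at position {i}")


def _make_aligner(scheme: ScoringScheme) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    """Normalized score S' = (lambda*S - ln K) / ln 2."""
    return (scheme.lam * raw_score - math.log(scheme.kappa)) / math.log(2.0)


def evalue(raw_score: float, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if scheme.m is None or scheme.n is None:
        raise ValueError("scheme not calibrated: effective lengths m, n unset")
    return scheme.kappa * scheme.m * scheme.n * math.exp(-scheme.lam * raw_score)


def align_local(
    query: str,
    subject: str,
    scheme: ScoringScheme,
    query_id: str = "query",
    subject_id: str = "subject",
    db_length: int | None = None,
) -> AlignmentHit | None:
    """Optimal Smith--Waterman alignment of two proteins.

    Identity is the fraction of identical columns over the alignment length
    (gap columns included); coverage is the aligned fraction of the query.
    Returns ``None`` when no alignment scores above zero.  Among co-optimal
    tracebacks the aligner's canonical first path is taken, which is fixed
    for given inputs, so identity and coverage are reproducible.

    ``db_length`` overrides the database length n of the E-value (used when
    the subject is one record of a larger searched database).
    """
    _check_protein(query, query_id)
    _check_protein(subject, subject_id)
    aligner = _make_aligner(scheme)
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    alignment = next(iter(aligner.align(query, subject)))

    qa, sa = alignment[0], alignment[1]
    n_cols = len(qa)
    n_ident = sum(1 for a, b in zip(qa, sa) if a == b and a != "-")
    q_aligned = sum(1 for a in qa if a != "-")

    eff = scheme.with_lengths(
        m=len(query), n=db_length if db_length is not None else len(subject)
    )
    (q0, q1), = [(alignment.aligned[0][0][0], alignment.aligned[0][-1][1])]
    (s0, s1), = [(alignment.aligned[1][0][0], alignment.aligned[1][-1][1])]
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=float(score),
        bit_score=bit_score(float(score), scheme),
        evalue=evalue(float(score), eff),
        identity=n_ident / n_cols,
        query_coverage=q_aligned / len(query),
        query_span=(int(q0), int(q1)),
        subject_span=(int(s0), int(s1)),
    )


def search_db(
    queries: Mapping[str, str],
    db: Mapping[str, str],
    scheme: ScoringScheme,
    config: SearchConfig,
    round_no: int = 1,
) -> list[AlignmentHit]:
    """Align every query against every db protein; keep passing hits.

    The E-value of each hit uses n = total database residue count, the
    whole-database search convention.
    """
    total_n = sum(len(s) for s in db.values())
    hits = []
    for qid in sorted(queries):
        for sid in sorted(db):
            hit = align_local(
                queries[qid], db[sid], scheme,
                query_id=qid, subject_id=sid, db_length=total_n,
            )
            if hit is not None and config.passes(hit):
                hits.append(replace(hit, round_found=round_no))
    return hits


def iterative_search(
    seed_proteins: Mapping[str, str],
    proteome_db: Mapping[str, str],
    scheme: ScoringScheme,
    config: SearchConfig | None = None,
) -> tuple[list[AlignmentHit], dict[str, str]]:
    """Iterative homology search by seed-set expansion.

    Each round aligns the current query set against the database; subjects
    of passing hits (deduplicated at 100% sequence identity against the
    existing query set) become additional queries.  Iteration stops at a
    fixpoint or after ``max_iterations`` rounds.  Returns the accepted hits
    (first round of acceptance recorded per subject) and the final query
    set.
    """
    config = config or SearchConfig()
    if not seed_proteins:
        raise ValueError("at least one seed protein required")
    queries: dict[str, str] = dict(seed_proteins)
    query_seqs = set(queries.values())
    accepted: dict[str, AlignmentHit] = {}
    new_queries = dict(queries)

    for round_no in range(1, config.max_iterations + 1):
        hits = search_db(new_queries, proteome_db, scheme, config, round_no)
        new_queries = {}
        for hit in hits:
            if hit.subject_id not in accepted:
                accepted[hit.subject_id] = hit
                seq = proteome_db[hit.subject_id]
                if seq not in query_seqs:  # dedup at 100% identity
                    query_seqs.add(seq)
                    new_queries[hit.subject_id] = seq
        if not new_queries:
            break
        queries.update(new_queries)

    return sorted(accepted.values(), key=lambda h: h.subject_id), queries


# Annotation terms that conflict with a capsid assignment: other structural
# roles a true MCP hit should not carry.
CONFLICTING_STRUCTURAL_TERMS = (
    "portal",
    "tail",
    "terminase",
    "baseplate",
    "sheath",
    "neck",
    "tape measure",
)


@dataclass(frozen=True)
class ScreenedHit:
    hit: AlignmentHit
    conflict: str | None = None


def screen_hits(
    hits: Iterable[AlignmentHit],
    config: SearchConfig,
    annotations: Mapping[str, str] | None = None,
) -> list[ScreenedHit]:
    """Validation pass over accepted hits.

    Thresholds are re-checked (hits failing any are dropped); hits whose
    subject carries an imported annotation naming a conflicting,
    non-capsid structural role are flagged but retained, leaving the final
    judgement to the analyst.
    """
    annotations = annotations or {}
    out = []
    for hit in hits:
        if not config.passes(hit):
            continue
        product = annotations.get(hit.subject_id, "").lower()
        conflict = None
        if product and "capsid" not in product:
            for term in CONFLICTING_STRUCTURAL_TERMS:
                if term in product:
                    conflict = term
                    break
        out.append(ScreenedHit(hit=hit, conflict=conflict))
    return out


def hits_to_tsv(hits: Iterable[AlignmentHit], path) -> None:
    """Write hits in BLAST outfmt-6-style columns."""
    header = "qseqid\tsseqid\tpident\tlength\tevalue\tbitscore\tqcovs\tround\n"
    with open(path, "w") as fh:
        fh.write(header)
        for h in hits:
            aln_len = h.query_span[1] - h.query_span[0]
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity * 100:.2f}\t{aln_len}\t"
                f"{h.evalue:.3g}\t{h.bit_score:.1f}\t{h.query_coverage * 100:.1f}\t{h.round_found}\n"
            )
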