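"""Pairwise proteome comparison and taxonomic rank assignment.

Two genomes are compared through reciprocal best hits (RBH) of their
proteomes: AAI is the mean percent identity over RBH pairs, the
orthologous fraction OF is the RBH count over the smaller proteome, and SG
is a bit-score-normalized whole-proteome similarity in [0, 1] (the min
over the two directions of total best-hit bit score divided by total
self-hit bit score).  Rank assignment follows the prevailing
protein-sharing conventions for head-tailed viruses: members of one genus
share at least 60% of their proteins, one family 20--50% (with SG > 0.05),
and distinct families less than 10%; the 10--20% band with supporting SG
is reported as ambiguous rather than forced into a rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mcpsearch import AlignmentHit, ScoringScheme, align_local


@dataclass(frozen=True)
class ProteomePairMetrics:
    genome_a: str
    genome_b: str
    n_a: int
    n_b: int
    n_orth: int
    aai: float | None  # mean percent identity over RBH pairs; None if no orthologs
    of: float
    sg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.of <= 1.0 and 0.0 <= self.sg <= 1.0):
            raise ValueError("of and sg must lie in [0, 1]")
        if self.n_orth > 0 and self.aai is None:
            raise ValueError("aai undefined only when n_orth == 0")


@dataclass(frozen=True)
class RankAssignment:
    genome_a: str
    genome_b: str
    rank: str  # same_genus | same_family | ambiguous | distinct_family


def _best_hits(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    scheme: ScoringScheme,
    evalue_max: float,
    identity_min: float,
) -> dict[str, AlignmentHit]:
    """Best passing hit in B for each protein of A.

    Best = highest bit score; ties broken by lower E-value, then
    lexicographically smallest subject id.
    """
    best: dict[str, AlignmentHit] = {}
    for pid in sorted(proteome_a):
        for qid in sorted(proteome_b):
            hit = align_local(
                proteome_a[pid], proteome_b[qid], scheme,
                query_id=pid, subject_id=qid,
            )
            if hit is None:
                continue
            if hit.evalue > evalue_max or hit.identity < identity_min:
                continue
            cur = best.get(pid)
            if (
                cur is None
                or hit.bit_score > cur.bit_score
                or (hit.bit_score == cur.bit_score and hit.evalue < cur.evalue)
            ):
                best[pid] = hit
    return best


def reciprocal_best_hits(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-5,
    identity_min: float = 0.30,
) -> list[tuple[AlignmentHit, AlignmentHit]]:
    """Reciprocal best hits between two proteomes.

    A pair (p in A, q in B) is orthologous when q is p's best passing hit
    and p is q's best passing hit, under the ortholog-calling thresholds
    (E-value 1e-5, identity 30% by default).
    """
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    scheme = scheme or ScoringScheme()
    fwd = _best_hits(proteome_a, proteome_b, scheme, evalue_max, identity_min)
    rev = _best_hits(proteome_b, proteome_a, scheme, evalue_max, identity_min)
    pairs = []
    for pid, hit in sorted(fwd.items()):
        back = rev.get(hit.subject_id)
        if back is not None and back.subject_id == pid:
            pairs.append((hit, back))
    return pairs


def pair_metrics(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    rbh_pairs: Sequence[tuple[AlignmentHit, AlignmentHit]],
    genome_a: str = "A",
    genome_b: str = "B",
    sg: float | None = None,
    scheme: ScoringScheme | None = None,
) -> ProteomePairMetrics:
    """Assemble AAI / OF (and SG when not supplied) for one genome pair.

    AAI is the unweighted mean of the forward-hit identities x100; OF
    divides the ortholog count by the smaller proteome (the conservative
    denominator, so OF(x, x) = 1).
    """
    n_a, n_b = len(proteome_a), len(proteome_b)
    n_orth = len(rbh_pairs)
    aai = (
        100.0 * sum(h.identity for h, _ in rbh_pairs) / n_orth if n_orth else None
    )
    of = n_orth / min(n_a, n_b) if min(n_a, n_b) else 0.0
    if sg is None:
        sg = sg_similarity(proteome_a, proteome_b, scheme)
    return ProteomePairMetrics(
        genome_a=genome_a, genome_b=genome_b,
        n_a=n_a, n_b=n_b, n_orth=n_orth,
        aai=aai, of=min(of, 1.0), sg=sg,
    )


def sg_similarity(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-5,
    identity_min: float = 0.30,
) -> float:
    """Bit-score-normalized proteome similarity in [0, 1].

    Each direction sums the best passing hit bit score per protein and
    normalizes by the summed self-hit bit scores of the query proteome;
    the symmetric score is the minimum of the two directions, so
    sg(x, x) = 1 and unrelated proteomes score 0.
    """
    scheme = scheme or ScoringScheme()

    def direction(pa: Mapping[str, str], pb: Mapping[str, str]) -> float:
        best = _best_hits(pa, pb, scheme, evalue_max, identity_min)
        total = 0.0
        self_total = 0.0
        for pid in pa:
            self_hit = align_local(pa[pid], pa[pid], scheme, pid, pid)
            assert self_hit is not None
            self_total += self_hit.bit_score
            if pid in best:
                total += best[pid].bit_score
        return min(total / self_total, 1.0) if self_total else 0.0

    return min(direction(proteome_a, proteome_b), direction(proteome_b, proteome_a))


def assign_rank(metrics: ProteomePairMetrics) -> RankAssignment:
    """Map (OF, SG) to a taxonomic-rank verdict.

    same_genus at OF >= 0.60; same_family at OF >= 0.20 with SG > 0.05;
    distinct_family at OF < 0.10 or SG <= 0.05; the remaining band
    (OF in [0.10, 0.20) with SG > 0.05) is ambiguous.
    """
    of, sg = metrics.of, metrics.sg
    if of >= 0.60:
        rank = "same_genus"
    elif of >= 0.20 and sg > 0.05:
        rank = "same_family"
    elif of < 0.10 or sg <= 0.05:
        rank = "distinct_family"
    else:
        rank = "ambiguous"
    return RankAssignment(metrics.genome_a, metrics.genome_b, rank)


def all_pair_metrics(
    proteomes: Mapping[str, Mapping[str, str]],
    scheme: ScoringScheme | None = None,
) -> list[ProteomePairMetrics]:
    """Metrics for every unordered genome pair (diagonal included)."""
    scheme = scheme or ScoringScheme()
    names = sorted(proteomes)
    out = []
    for i, a in enumerate(names):
        for b in names[i:]:
            rbh = reciprocal_best_hits(proteomes[a], proteomes[b], scheme)
            out.append(
                pair_metrics(
                    proteomes[a], proteomes[b], rbh,
                    genome_a=a, genome_b=b, scheme=scheme,
                )
            )
    return out


def metrics_matrix(
    metrics: Sequence[ProteomePairMetrics], field: str = "sg"
) -> pd.DataFrame:
    """Symmetric genomes x genomes matrix of one metric field."""
    names = sorted({m.genome_a for m in metrics} | {m.genome_b for m in metrics})
    df = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for m in metrics:
        value = getattr(m, field)
        if value is None:
            value = np.nan
        df.loc[m.genome_a, m.genome_b] = value
        df.loc[m.genome_b, m.genome_a] = value
    return df


def nj_tree(distance: pd.DataFrame) -> str:
    """Neighbor-joining dendrogram from a symmetric distance matrix.

    Distances are typically 1 - SG.  Negative branch lengths are clamped
    to zero; tie-breaks are by lowest index pair, so the result is
    deterministic for a given row order.  Returns a newick string.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    names = list(distance.index)
    if len(names) < 3:
        raise ValueError("neighbor joining requires at least 3 genomes")
    data = distance.to_numpy(dtype=float)
    if not np.allclose(data, data.T):
        raise ValueError("distance matrix must be symmetric")
    np.fill_diagonal(data, 0.0)
    tree = skbio_nj(DistanceMatrix(data, ids=names))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()
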