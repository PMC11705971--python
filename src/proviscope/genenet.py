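"""Gene-sharing network over viral genomes.

Proteins are grouped into protein clusters (PCs); genome pairs sharing PCs
get an edge whose weight is the significance of the overlap under a
hypergeometric null: drawing ``b`` PCs from a universe of ``n_pc`` and
observing at least ``c`` of genome A's ``a`` PCs.  Thresholding the
significance graph and refining its components yields the four membership
states used for viral clusters (VCs): clustered, overlap (attached to
several VCs), outlier (weakly attached), and singleton (no passing edge).

The clustering here is deliberately simple and deterministic: PCs are
connected components of the pairwise-hit graph, and VCs are refined
components of the significance graph.  That expresses the same membership
semantics as Markov/ClusterONE-based pipelines without their stochastic
and implementation-defined behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .mcpsearch import ScoringScheme, align_local


@dataclass(frozen=True)
class ProteinCluster:
    pc_id: str
    members: tuple[tuple[str, str], ...]  # (genome_id, protein_id)


@dataclass(frozen=True)
class NetworkEdge:
    genome_a: str
    genome_b: str
    a: int  # PCs in genome_a
    b: int  # PCs in genome_b
    c: int  # shared PCs
    n_pc: int
    p_hyper: float
    sig: float

    def __post_init__(self) -> None:
        if self.c > min(self.a, self.b):
            raise ValueError("shared PCs cannot exceed either genome's PC count")
        if not (0.0 <= self.p_hyper <= 1.0) or self.sig < 0:
            raise ValueError("invalid significance")


@dataclass(frozen=True)
class VCAssignment:
    genome: str
    state: str  # clustered | overlap | outlier | singleton
    vc_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.state == "clustered" and len(self.vc_ids) != 1:
            raise ValueError("clustered genome must belong to exactly one VC")
        if self.state == "overlap" and len(self.vc_ids) < 2:
            raise ValueError("overlap genome must touch at least two VCs")
        if self.state in ("outlier", "singleton") and self.vc_ids:
            raise ValueError("outlier/singleton genomes carry no VC ids")


def build_pcs(
    proteins: Mapping[tuple[str, str], str],
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-5,
) -> list[ProteinCluster]:
    """Partition proteins into clusters by single-linkage over hits.

    ``proteins`` maps (genome_id, protein_id) to sequence.  Two proteins
    are linked when either direction aligns with E <= ``evalue_max``; PCs
    are the connected components, and every protein (including singletons)
    lands in exactly one PC.  PC ids are taken from the lexicographically
    smallest member for stability.
    """
    if not proteins:
        raise ValueError("at least one protein required")
    scheme = scheme or ScoringScheme()
    keys = sorted(proteins)
    graph = nx.Graph()
    graph.add_nodes_from(keys)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            hit = align_local(
                proteins[ka], proteins[kb], scheme,
                query_id="/".join(ka), subject_id="/".join(kb),
            )
            if hit is not None and hit.evalue <= evalue_max:
                graph.add_edge(ka, kb)
            else:
                back = align_local(
                    proteins[kb], proteins[ka], scheme,
                    query_id="/".join(kb), subject_id="/".join(ka),
                )
                if back is not None and back.evalue <= evalue_max:
                    graph.add_edge(ka, kb)
    clusters = []
    for comp in nx.connected_components(graph):
        members = tuple(sorted(comp))
        clusters.append(
            ProteinCluster(pc_id=f"PC_{members[0][0]}_{members[0][1]}", members=members)
        )
    clusters.sort(key=lambda pc: pc.pc_id)
    return clusters


def edge_significance(a: int, b: int, c: int, n_pc: int) -> tuple[float, float]:
    """Upper-tail hypergeometric probability of sharing >= c PCs.

    P = sum_{i=c}^{min(a,b)} C(a, i) C(n_pc - a, b - i) / C(n_pc, b),
    evaluated in log space via log-gamma so small tails keep full
    precision.  Returns (P, -log10 P).
    """
    if not (0 <= c <= min(a, b) <= n_pc) or b > n_pc or a > n_pc:
        raise ValueError(f"inconsistent counts a={a}, b={b}, c={c}, n_pc={n_pc}")
    if c == 0:
        return 1.0, 0.0

    def log_comb(n: int, k: int) -> float:
        return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))

    denom = log_comb(n_pc, b)
    terms = []
    for i in range(c, min(a, b) + 1):
        if b - i > n_pc - a:
            continue  # impossible draw
        terms.append(log_comb(a, i) + log_comb(n_pc - a, b - i) - denom)
    if not terms:
        return 0.0, math.inf
    peak = max(terms)
    log_p = peak + math.log(sum(math.exp(t - peak) for t in terms))
    log_p = min(log_p, 0.0)
    p = math.exp(log_p)
    sig = max(-log_p / math.log(10.0), 0.0)
    return p, sig


def genome_profiles(
    clusters: Sequence[ProteinCluster],
) -> dict[str, set[str]]:
    """PC membership profile per genome."""
    profiles: dict[str, set[str]] = {}
    for pc in clusters:
        for genome, _pid in pc.members:
            profiles.setdefault(genome, set()).add(pc.pc_id)
    return profiles


def build_edges(
    clusters: Sequence[ProteinCluster],
    genomes: Iterable[str] | None = None,
) -> list[NetworkEdge]:
    """Hypergeometric edges for every genome pair sharing >= 1 PC."""
    profiles = genome_profiles(clusters)
    if genomes is not None:
        for g in genomes:
            profiles.setdefault(g, set())
    n_pc = len(clusters)
    names = sorted(profiles)
    edges = []
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            shared = profiles[ga] & profiles[gb]
            if not shared:
                continue  # c = 0 edges are never materialized
            p, sig = edge_significance(
                len(profiles[ga]), len(profiles[gb]), len(shared), n_pc
            )
            edges.append(
                NetworkEdge(ga, gb, len(profiles[ga]), len(profiles[gb]),
                            len(shared), n_pc, p, sig)
            )
    return edges


def assign_vcs(
    edges: Sequence[NetworkEdge],
    genomes: Iterable[str],
    sig_min: float = 1.0,
    cohesion_fraction: float = 0.5,
) -> tuple[dict[str, VCAssignment], dict[str, tuple[str, ...]]]:
    """Viral-cluster membership states from the significance graph.

    Edges with sig >= ``sig_min`` form the working graph.  Within each
    component, genomes bridging two or more otherwise-separate subgroups
    (articulation points whose removal leaves >= 2 parts of >= 2 genomes,
    none of which holds a strict majority of the genome's edges) are set
    aside as overlap candidates.  The remaining components of >= 2
    genomes become VCs, refined by a cohesion rule: a member whose mean
    within-VC significance falls below ``cohesion_fraction`` times the VC
    mean becomes an outlier.  Genomes with no passing edge at all are
    singletons; genomes left without a VC after refinement are outliers.

    Returns per-genome assignments and the VC membership map.
    """
    genomes = sorted(set(genomes))
    graph = nx.Graph()
    graph.add_nodes_from(genomes)
    sig_of: dict[tuple[str, str], float] = {}
    for e in edges:
        sig_of[(e.genome_a, e.genome_b)] = e.sig
        sig_of[(e.genome_b, e.genome_a)] = e.sig
        if e.sig >= sig_min:
            graph.add_edge(e.genome_a, e.genome_b, sig=e.sig)

    # Overlap candidates: articulation genomes joining >= 2 real subgroups,
    # with no single subgroup holding a strict majority of their edges
    # (a genome mostly embedded in one group belongs to that group).
    overlap_candidates: list[str] = []
    for node in sorted(nx.articulation_points(graph)):
        trial = graph.copy()
        trial.remove_node(node)
        counts = [
            sum(graph.has_edge(node, g) for g in comp)
            for comp in nx.connected_components(trial)
            if len(comp) >= 2 and any(graph.has_edge(node, g) for g in comp)
        ]
        if len(counts) >= 2 and max(counts) <= sum(counts) / 2:
            overlap_candidates.append(node)

    work = graph.copy()
    work.remove_nodes_from(overlap_candidates)

    vcs: dict[str, tuple[str, ...]] = {}
    member_vc: dict[str, str] = {}
    outliers: set[str] = set()
    comps = sorted(
        (sorted(comp) for comp in nx.connected_components(work) if len(comp) >= 2),
        key=lambda comp: comp[0],
    )
    for idx, comp in enumerate(comps):
        vc_id = f"VC_{idx + 1}"
        comp_edges = [
            work.edges[u, v]["sig"] for u, v in work.subgraph(comp).edges
        ]
        vc_mean = float(np.mean(comp_edges)) if comp_edges else 0.0
        members = []
        for g in comp:
            own = [
                work.edges[g, nb]["sig"] for nb in work.neighbors(g) if nb in comp
            ]
            if own and float(np.mean(own)) < cohesion_fraction * vc_mean:
                outliers.add(g)
            else:
                members.append(g)
        if len(members) >= 2:
            vcs[vc_id] = tuple(members)
            for g in members:
                member_vc[g] = vc_id
        else:
            outliers.update(members)

    assignments: dict[str, VCAssignment] = {}
    for g in genomes:
        if g in member_vc:
            assignments[g] = VCAssignment(g, "clustered", (member_vc[g],))
        elif g in overlap_candidates:
            touched = tuple(
                sorted(
                    {
                        member_vc[nb]
                        for nb in graph.neighbors(g)
                        if nb in member_vc
                    }
                )
            )
            if len(touched) >= 2:
                assignments[g] = VCAssignment(g, "overlap", touched)
            elif graph.degree(g) == 0:
                assignments[g] = VCAssignment(g, "singleton", ())
            else:
                assignments[g] = VCAssignment(g, "outlier", ())
        elif graph.degree(g) == 0:
            assignments[g] = VCAssignment(g, "singleton", ())
        else:
            assignments[g] = VCAssignment(g, "outlier", ())
    return assignments, vcs
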