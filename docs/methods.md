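# Methods

This note documents the models and procedures implemented in proviscope,
the assumptions behind them, the parameters that matter, and what the
synthetic data used by the tests does and does not demonstrate.

## Provirus model and boundary delimitation

An integrated head-tailed provirus is modelled as a contiguous cassette in
a host replicon, anchored by an HK97-fold major capsid protein (MCP) gene,
with an integrase gene near one end. Site-specific integration duplicates
its target, so the provirus is flanked by a direct repeat — the attL/attR
attachment sites — and integration frequently occurs in the 3′- or
5′-distal region of a tRNA gene, placing a tRNA at one boundary.

**Direct-repeat finding.** Matching is substitution-only (no indels):
indel-free matching keeps "maximal" well defined and attachment-site
duplications are short and near-exact. For every copy-to-copy offset *d*
permitted by the span limits, the finder reads maximal windows off the
mismatch-position list of that diagonal. A pair is reported when the
copies are equal length ≥ `dr_min_len`, differ by ≤ `dr_max_mismatch`
substitutions, and are *delimited*: the columns immediately outside the
window on both sides mismatch (or fall off the sequence). Delimited
windows include every budget-saturated maximal window **and** the exact
extent of a planted duplication with its exact mismatch count. This is
deliberate: under pure budget-maximality an exactly duplicated site would
only ever surface merged with absorbed flanking mismatches, and its true
coordinates would be unrecoverable. The sweep is exhaustively equivalent
to quadratic brute-force enumeration, and the test suite verifies that
equivalence on a grid of configurations (`brute_force_direct_repeats` is
retained as the reference implementation).

**Candidate scoring.** Repeat pairs whose enclosed span (first base of
attL through last base of attR) brackets the MCP gene and lies within
[`span_min`, `span_max`] are scored additively:

    score = 3·[integrase within 5 kb of a copy, inside the span]
          + 2·[tRNA within 500 bp of a copy]
          + min(repeat_length / 50, 1)
          − 0.5·mismatches

The best candidate at score ≥ 2 becomes a complete call (ties: longer
repeat, then shorter span); anchors without a convincing candidate yield a
partial, anchor-only record. The provirus span includes **both** repeat
copies — the literature does not settle whether one or both copies belong
to the provirus, and including both is conservative and reversible.

**Default parameters.** `span_min` = 10 kb echoes the contig floor applied
to input assemblies; `span_max` = 80 kb comfortably exceeds the largest
expected integrated head-tailed virus; `window` = 70 kb per side bounds the
scan around each anchor. The repeat floor and mismatch budget default to
**20 bp / 1 mismatch**. This pair was chosen from a false-boundary-rate
analysis: at 14 bp / 2 mismatches a 25-kb random-background replicon
contains on the order of 10² chance repeat windows, and a handful sit
close enough to the integrase or boundary tRNA to assemble a complete call
even when the true repeat is absent; at 20 bp / 1 mismatch chance windows
essentially vanish at desk scale while genuine attachment-site
duplications (typically 20–60 bp, near-exact) are retained. All values are
configuration fields, not constants.

## Alignment and search statistics

Pairwise protein alignment is optimal local Smith–Waterman with affine
gaps (BLOSUM62; a gap of length *g* costs `gap_open + g·gap_extend`,
defaults 10/1), delegated to Biopython's `PairwiseAligner`. Identity is
counted over all alignment columns (gaps included); coverage is the
aligned fraction of the query. Among co-optimal tracebacks the aligner's
canonical first path is used — fixed for given inputs, so identity and
coverage are reproducible.

Significance uses the Karlin–Altschul form *E = K·m·n·e^(−λS)* with the
published gapped BLOSUM62 parameters λ = 0.267, K = 0.041 and raw sequence
lengths as effective lengths (no edge-effect correction, no per-query
recalibration). The acceptance thresholds (*E* < 10⁻⁵, identity > 30%,
coverage > 50%) — not absolute E-values — are the contract, so calibration
subtleties do not propagate into decisions.

The iterative search expands the seed set instead of building a
position-specific profile: subjects of passing hits become queries for the
next round, deduplicated at 100% sequence identity, until a fixpoint or
the round limit. This is a documented divergence from PSSM-based
iteration; it is deterministic, order-independent, and monotone (the
accepted set never shrinks), at the cost of the sensitivity a true profile
would add.

## Proteome comparison and rank assignment

Orthologs are reciprocal best hits (best = highest bit score, ties by
lower E-value then subject id) under the ortholog-calling thresholds
(*E* ≤ 10⁻⁵, identity ≥ 30%). AAI is the unweighted mean percent identity
over RBH pairs. OF divides the ortholog count by the **smaller** proteome,
so OF(x, x) = 1. SG is a bit-score-normalized proteome similarity: per
direction, the sum of best-hit bit scores over the sum of self-hit bit
scores, symmetrized by taking the minimum; it is *not* a tBLASTx
genome-wide score, and the 0.05 decision threshold is reused as-is — a
documented approximation whose transferability to the original score is
untested. Rank assignment: same genus at OF ≥ 0.60; same family at
OF ≥ 0.20 with SG > 0.05; distinct families at OF < 0.10 or SG ≤ 0.05; the
OF band [0.10, 0.20) with supporting SG is reported as **ambiguous**
rather than forced into a rank, because the classification conventions
leave it undefined. Dendrograms use standard neighbor joining (scikit-bio)
on *d* = 1 − SG with negative branch lengths clamped to zero.

## Gene-sharing network

Protein clusters (PCs) are connected components of the pairwise-hit graph
(either-direction hit at *E* ≤ 10⁻⁵); singleton proteins form their own
PCs. Genome–genome edges carry the upper-tail hypergeometric probability
of sharing ≥ *c* PCs given profile sizes *a*, *b* in a universe of *n_pc*
PCs, evaluated as an exact term sum in log space (log-gamma binomials +
log-sum-exp), with significance −log₁₀ *P*; edges with *c* = 0 are never
materialized. Viral clusters are components of the graph thresholded at
sig ≥ 1 (P ≤ 0.1), after setting aside *overlap* genomes — articulation
points joining ≥ 2 subgroups of ≥ 2 genomes, with no single subgroup
holding a strict majority of their edges — and refining each cluster by
cohesion: members whose mean within-cluster significance falls below half
the cluster mean become *outliers*; genomes with no passing edge are
*singletons*. Markov clustering and ClusterONE are deliberately replaced
by this deterministic procedure: it expresses the same four membership
states without stochastic or implementation-defined behavior, and makes no
attempt to reproduce any particular tool's cluster numbering.

## Functional tagging, CRISPR arrays, lifestyle

Functional categories come from case-insensitive substring matching of
product strings against an editable lexicon TSV (first longest match
wins; unmatched products are hypothetical). Working from supplied
annotations rather than live database searches is a design decision:
database-dependent counts are irreproducible. Defense systems (DISARM,
Dnd, PARIS, HMA, pAgo, R-M, CRISPR-Cas) are called present when at least
two member symbols occur, capped at the system's size so single-gene
systems need only their one symbol.

CRISPR arrays are detected structurally: exact 10-mer seeds recurring at
gaps compatible with one repeat plus one spacer are chained; the repeat
extent grows column-by-column while ≥ 80% of copies agree on the consensus
base; copies beyond the per-copy mismatch budget, and spacer gaps outside
the configured range, break the chain; copies that lost their seed to
substitutions are rescued by a Hamming scan at the expected period. Arrays
report n_spacers + 1 repeats by construction. Orientation is inferred only
from the strand vote of a neighboring cas cluster; a *nested* system
requires ≥ 2 arrays enclosed by cas genes within a 10-kb locus, all in one
transcriptional orientation. Spacer–protospacer matching is ungapped over
both strands at full spacer coverage (protospacers are short; gaps add
only ambiguity); the default identity floor is 0.90.

Lifestyle: a provirus has lytic potential when it carries lysis-category
genes (holin/endolysin) OR an external classifier labels it Virulent.
External labels are consumed as an optional input table; absent labels
default to Temperate so the lysis-gene rule alone drives the call. The
package ships a 39-record compilation of published lifestyle predictions
as a worked dataset; its row count is carried verbatim even though the
accompanying narrative refers to 38 genomes.

## Synthetic data: what it shows and what it does not

The forge writes i.i.d. nucleotide backgrounds at a configurable GC
fraction (default 0.45) and implants fully ground-truthed features:
cassettes of clean ORFs (MCP, integrase at a configured end, ≥ 3 further
structural genes, optional holin/endolysin, hypothetical-protein cargo),
exact attL/attR duplications with a configurable mismatch count, a
boundary tRNA overlapping attL, optional decoy repeats, and CRISPR loci
with identical repeats and mutually distinct spacers. Genes are preceded
by an all-frame stop motif so the deterministic ORF caller recovers them
at exact coordinates, and the bases immediately flanking the implanted
repeat copies are forced to mismatch — by definition a duplication is
maximal, so matching flanks would make the true repeat longer than
intended and the truth coordinates ambiguous. Default cassette sizes span
10.0–62.7 kb, matching the genome-size range reported for complete
archaeal proviruses; one published record exceeds that range (65.9 kb),
an inconsistency in the source material that is noted, not resolved.

Passing tests on forged data demonstrate algorithmic correctness —
exact-coordinate recovery, threshold behavior, determinism — not
real-data performance: real archaeal replicons have compositional
structure (skews, repeat families, mobile elements) that inflates the
repeat background, and real gene annotation is noisier than the forge's
clean ORFs. The deterministic three-start-codon ORF caller is a stand-in
for statistical gene finders; imported GFF3 annotations take precedence in
the pipeline precisely so externally annotated data can be analyzed as-is.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a desk machine: boundary
recovery uses 40 forged replicons of 25 kb hosts with 10.5–16 kb
proviruses (the recovery criterion is ≥ 95% exact-coordinate calls);
oracle equivalence runs on ≤ 2 kb sequences over a config grid; the
hypergeometric statistic is swept exhaustively against exact rational
arithmetic for all parameter combinations with n_pc ≤ 30 (observed
agreement ~10⁻¹² in log₁₀P, asserted < 10⁻⁹); alignment scores are checked
against an independent full-DP implementation on 100 random pairs. RNG
streams derive from `numpy.random.SeedSequence`, split per replicon so
per-replicon outputs are order-independent; identical configurations give
byte-identical outputs. Coordinates are 0-based half-open internally;
GFF3 I/O converts to 1-based inclusive.

## Known limitations

- Inverted-repeat attachment sites, circularly permuted proviruses across
  contig ends, and excision/induction dynamics are out of scope.
- Seed-set expansion is less sensitive than profile-based iteration for
  remote homologs.
- SG is a stand-in score; its 0.05 threshold is inherited, not
  recalibrated.
- CRISPR detection assumes ≥ 18 bp repeats and 18–60 bp spacers and seeds
  on exact 10-mers, so arrays whose repeat copies are all heavily mutated
  can be missed; cas subtype classification is not attempted.
- tRNA genes are consumed from annotations (GFF3); no de novo tRNA
  prediction.
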