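"""Rule-based functional annotation and CRISPR array analysis.

Functional categories (structural, replication, defense, antitoxin, AMG,
lysis, mobilization, hypothetical) are assigned by case-insensitive
substring matching of product strings against an editable lexicon shipped
with the package.  Working from supplied annotation strings rather than
live database searches keeps the tagging reproducible: the counts depend
only on the inputs and the lexicon.

CRISPR arrays are found structurally -- near-identical repeats of 18-55 bp
separated by unique 18-60 bp spacers -- by exact-seed chaining plus
consensus extension, with a Hamming rescue for repeat copies that carry
substitutions.  Spacer-protospacer matching is ungapped over both strands;
protospacers are short enough that gaps add nothing but ambiguity.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import reverse_complement

CATEGORIES = frozenset(
    {"structural", "replication", "defense", "antitoxin", "amg",
     "lysis", "mobilization", "hypothetical"}
)


@dataclass(frozen=True)
class LexiconEntry:
    term: str
    category: str
    symbol: str
    system: str | None = None


class Lexicon:
    """Term -> (category, symbol, system) lookup with longest-match wins."""

    def __init__(self, entries: Sequence[LexiconEntry]):
        symbol_cat: dict[str, str] = {}
        for e in entries:
            if e.category not in CATEGORIES:
                raise ValueError(f"unknown category {e.category!r} for term {e.term!r}")
            prev = symbol_cat.setdefault(e.symbol, e.category)
            if prev != e.category:
                raise ValueError(f"symbol {e.symbol!r} mapped to two categories")
        # Longest term first, then lexicographic: deterministic matching.
        self.entries = sorted(entries, key=lambda e: (-len(e.term), e.term))

    def match(self, product: str) -> LexiconEntry | None:
        text = product.lower()
        for entry in self.entries:
            if entry.term in text:
                return entry
        return None

    @property
    def systems(self) -> dict[str, set[str]]:
        """Defense system -> member symbols."""
        out: dict[str, set[str]] = {}
        for e in self.entries:
            if e.system:
                out.setdefault(e.system, set()).add(e.symbol)
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        df = pd.read_csv(path, sep="\t", dtype=str)
        entries = [
            LexiconEntry(
                term=row.term.lower(),
                category=row.category,
                symbol=row.symbol,
                system=None if pd.isna(row.system) else row.system,
            )
            for row in df.itertuples()
        ]
        return cls(entries)

    @classmethod
    def default(cls) -> "Lexicon":
        ref = importlib.resources.files("proviscope") / "data" / "lexicon.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class FunctionalTag:
    gene_id: str
    product: str
    category: str
    symbol: str
    system: str | None = None


def tag_functions(
    annotations: Sequence[tuple[str, str]], lexicon: Lexicon | None = None
) -> list[FunctionalTag]:
    """Tag (gene_id, product string) pairs with functional categories.

    The first longest-matching lexicon term wins; products matching
    nothing are tagged hypothetical.  Tagging is pure string lookup:
    idempotent and independent of input order.
    """
    lexicon = lexicon or Lexicon.default()
    tags = []
    for gene_id, product in annotations:
        entry = lexicon.match(product)
        if entry is None:
            tags.append(FunctionalTag(gene_id, product, "hypothetical", "hyp"))
        else:
            tags.append(
                FunctionalTag(gene_id, product, entry.category, entry.symbol, entry.system)
            )
    return tags


# ---------------------------------------------------------------------------
# CRISPR arrays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrisprArray:
    start: int
    end: int
    repeat_positions: tuple[int, ...]
    repeat_consensus: str
    spacers: tuple[str, ...]
    spacer_positions: tuple[int, ...]
    orientation: str = "unknown"  # "+", "-", "unknown"

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_positions)

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    @property
    def repeat_length(self) -> int:
        return len(self.repeat_consensus)


_SEED_LEN = 10  # exact-seed length for repeat chaining


def _consensus(columns: list[str]) -> str:
    out = []
    for col in zip(*columns):
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        out.append(max(sorted(counts), key=lambda ch: counts[ch]))
    return "".join(out)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def detect_crispr_arrays(
    seq: str,
    repeat_len_range: tuple[int, int] = (18, 55),
    spacer_len_range: tuple[int, int] = (18, 60),
    max_repeat_mismatch: int = 2,
    min_spacers: int = 2,
) -> list[CrisprArray]:
    """Find CRISPR arrays as chains of near-identical periodic repeats.

    Candidate chains are seeded by exact 10-mers recurring at gaps
    compatible with one repeat plus one spacer; the repeat extent is then
    grown column-by-column while at least 80% of the copies agree on the
    consensus base.  Copies exceeding ``max_repeat_mismatch`` differences
    from the consensus break the chain, as do spacer gaps outside
    ``spacer_len_range``; chains missing a seed in one copy (a mutated
    repeat) are rescued by a Hamming scan at the expected period.  Arrays
    with fewer than ``min_spacers`` spacers are discarded; survivors are
    non-overlapping and sorted by position.
    """
    seq = seq.upper()
    n = len(seq)
    r_lo, r_hi = repeat_len_range
    s_lo, s_hi = spacer_len_range
    if r_lo < _SEED_LEN:
        raise ValueError(f"minimum repeat length must be >= {_SEED_LEN}")
    if s_lo > s_hi or r_lo > r_hi:
        raise ValueError("empty length range")
    if n <= 2 * r_lo:
        return []
    period_lo, period_hi = r_lo + s_lo, r_hi + s_hi

    kmer_pos: dict[str, list[int]] = {}
    for i in range(n - _SEED_LEN + 1):
        kmer_pos.setdefault(seq[i : i + _SEED_LEN], []).append(i)

    accepted: list[CrisprArray] = []

    def covered(a: int, b: int) -> bool:
        return any(not (b <= arr.start or a >= arr.end) for arr in accepted)

    # Visit seeds with the most occurrences first: real repeats dominate.
    for kmer in sorted(kmer_pos, key=lambda k: (-len(kmer_pos[k]), k)):
        positions = kmer_pos[kmer]
        if len(positions) < min_spacers + 1:
            continue
        # Split occurrence list into chains of period-compatible gaps.
        chains: list[list[int]] = [[positions[0]]]
        for pos in positions[1:]:
            gap = pos - chains[-1][-1]
            if period_lo <= gap <= period_hi:
                chains[-1].append(pos)
            else:
                chains.append([pos])
        for chain in chains:
            if len(chain) < min_spacers + 1:
                continue
            if covered(chain[0], chain[-1] + _SEED_LEN):
                continue
            array = _grow_array(
                seq, chain, r_lo, r_hi, s_lo, s_hi, max_repeat_mismatch, min_spacers
            )
            if array is not None and not covered(array.start, array.end):
                accepted.append(array)

    accepted.sort(key=lambda a: a.start)
    return accepted


def _grow_array(
    seq: str,
    chain: list[int],
    r_lo: int,
    r_hi: int,
    s_lo: int,
    s_hi: int,
    max_mm: int,
    min_spacers: int,
) -> CrisprArray | None:
    n = len(seq)
    k = _SEED_LEN

    def column_ok(offsets: list[int]) -> bool:
        bases = [seq[o] for o in offsets if 0 <= o < n]
        if len(bases) < len(offsets):
            return False
        counts: dict[str, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        return max(counts.values()) >= math.ceil(0.8 * len(bases))

    left = 0
    while k + left < r_hi and column_ok([p - left - 1 for p in chain]):
        # Keep at least one spacer base between consecutive repeat copies.
        if any(
            chain[i] - left - 1 < chain[i - 1] + k for i in range(1, len(chain))
        ):
            break
        left += 1
    right = 0
    while k + left + right < r_hi and column_ok([p + k + right for p in chain]):
        if any(
            chain[i - 1] + k + right >= chain[i] - left for i in range(1, len(chain))
        ):
            break
        right += 1

    rep_len = k + left + right
    if rep_len < r_lo:
        return None
    starts = [p - left for p in chain]
    copies = [seq[s : s + rep_len] for s in starts]
    consensus = _consensus(copies)

    # Rescue mutated copies that lost their seed: probe one period beyond
    # both ends, and the middle of double-period interior gaps.
    def best_match(lo: int, hi: int) -> int | None:
        best_pos, best_mm = None, max_mm + 1
        for s in range(max(0, lo), min(hi, n - rep_len) + 1):
            mm = _hamming(seq[s : s + rep_len], consensus)
            if mm < best_mm:
                best_pos, best_mm = s, mm
        return best_pos if best_mm <= max_mm else None

    changed = True
    while changed:
        changed = False
        pos = best_match(starts[0] - rep_len - s_hi, starts[0] - rep_len - s_lo)
        if pos is not None and starts[0] - (pos + rep_len) >= s_lo:
            starts.insert(0, pos)
            changed = True
        pos = best_match(starts[-1] + rep_len + s_lo, starts[-1] + rep_len + s_hi)
        if pos is not None and pos - (starts[-1] + rep_len) >= s_lo:
            starts.append(pos)
            changed = True
    filled: list[int] = [starts[0]]
    for s in starts[1:]:
        gap = s - (filled[-1] + rep_len)
        if gap > s_hi:  # try to place one repeat inside the long gap
            pos = best_match(filled[-1] + rep_len + s_lo, s - rep_len - s_lo)
            if pos is not None:
                filled.append(pos)
        filled.append(s)
    starts = filled

    # Mismatch budget: copies beyond it break the chain; keep the best run.
    runs: list[list[int]] = [[]]
    for s in starts:
        if _hamming(seq[s : s + rep_len], consensus) <= max_mm:
            runs[-1].append(s)
        else:
            runs.append([])
    # Spacer-range violations also split runs.
    split: list[list[int]] = []
    for run in runs:
        cur: list[int] = []
        for s in run:
            if cur and not (s_lo <= s - (cur[-1] + rep_len) <= s_hi):
                split.append(cur)
                cur = []
            cur.append(s)
        split.append(cur)
    best_run = max(split, key=len)
    if len(best_run) < min_spacers + 1:
        return None

    copies = [seq[s : s + rep_len] for s in best_run]
    consensus = _consensus(copies)
    spacers = tuple(
        seq[best_run[i] + rep_len : best_run[i + 1]] for i in range(len(best_run) - 1)
    )
    spacer_positions = tuple(s + rep_len for s in best_run[:-1])
    return CrisprArray(
        start=best_run[0],
        end=best_run[-1] + rep_len,
        repeat_positions=tuple(best_run),
        repeat_consensus=consensus,
        spacers=spacers,
        spacer_positions=spacer_positions,
    )


# ---------------------------------------------------------------------------
# Nested systems and spacer matching
# ---------------------------------------------------------------------------

def orient_arrays(
    arrays: Sequence[CrisprArray],
    cas_features: Sequence[tuple[int, int, str]],
    neighborhood: int = 10_000,
) -> list[CrisprArray]:
    """Infer array orientation from the strand vote of neighboring cas genes.

    Arrays with no cas gene within ``neighborhood`` stay unknown.
    """
    out = []
    for arr in arrays:
        if arr.orientation != "unknown":
            out.append(arr)
            continue
        votes: dict[str, int] = {}
        for start, end, strand in cas_features:
            gap = max(arr.start - end, start - arr.end, 0)
            if gap <= neighborhood:
                votes[strand] = votes.get(strand, 0) + 1
        if votes:
            strand = max(sorted(votes), key=lambda s: votes[s])
            arr = CrisprArray(
                start=arr.start, end=arr.end,
                repeat_positions=arr.repeat_positions,
                repeat_consensus=arr.repeat_consensus,
                spacers=arr.spacers, spacer_positions=arr.spacer_positions,
                orientation=strand,
            )
        out.append(arr)
    return out


def detect_nested_system(
    arrays: Sequence[CrisprArray],
    cas_features: Sequence[tuple[int, int, str]],
    max_gap: int = 10_000,
) -> tuple[bool, dict]:
    """Recognize the nested configuration: >= 2 CRISPR arrays positioned
    between the genes of one cas cluster, everything in the same
    transcriptional orientation.

    Returns (nested, layout) where layout describes the arrays, the cas
    span and the shared orientation (or the reason the call failed).
    """
    layout: dict = {"n_arrays": len(arrays), "n_cas": len(cas_features)}
    if len(arrays) < 2 or not cas_features:
        layout["reason"] = "needs >=2 arrays and a cas cluster"
        return False, layout

    arrays = orient_arrays(arrays, cas_features, neighborhood=max_gap)
    known = {a.orientation for a in arrays if a.orientation != "unknown"}
    cas_strands = {strand for _s, _e, strand in cas_features}
    if len(known) > 1 or len(cas_strands) > 1:
        layout["reason"] = "mixed transcriptional orientations"
        return False, layout

    arr_sorted = sorted(arrays, key=lambda a: a.start)
    first, last = arr_sorted[0], arr_sorted[-1]
    cas_before = [
        (s, e) for s, e, _ in cas_features
        if e <= first.start and first.start - e <= max_gap
    ]
    cas_after = [
        (s, e) for s, e, _ in cas_features
        if s >= last.end and s - last.end <= max_gap
    ]
    # Consecutive arrays must stay within one locus.
    gaps_ok = all(
        arr_sorted[i + 1].start - arr_sorted[i].end <= max_gap
        for i in range(len(arr_sorted) - 1)
    )
    nested = bool(cas_before and cas_after and gaps_ok)
    orientation = (known | cas_strands).pop() if (known | cas_strands) else "unknown"
    layout.update(
        {
            "arrays": [(a.start, a.end, a.n_spacers) for a in arr_sorted],
            "cas_span": (
                min(s for s, _e, _ in cas_features),
                max(e for _s, e, _ in cas_features),
            ),
            "orientation": orientation,
            "nested": nested,
        }
    )
    if not nested:
        layout.setdefault("reason", "arrays not enclosed by cas genes within the locus")
    return nested, layout


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    target_id: str
    coverage: float
    identity: float
    strand: str
    target_start: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0 and 0.0 <= self.identity <= 1.0):
            raise ValueError("coverage and identity must be fractions")


def match_spacer(
    spacer: str,
    targets: Mapping[str, str],
    min_coverage: float = 1.0,
    min_identity: float = 0.90,
    spacer_id: str = "spacer",
) -> SpacerMatch | None:
    """Best ungapped protospacer match of one spacer across target genomes.

    The spacer is slid full-length over both strands of every target;
    identity is the fraction of identical positions.  The best hit is the
    highest identity at full coverage, with ties resolved by target id,
    forward strand first, then leftmost position.  Returns ``None`` when
    no window reaches ``min_identity``.
    """
    spacer = spacer.upper()
    if len(spacer) < 18:
        raise ValueError("spacer too short to match reliably (< 18 nt)")
    if min_coverage < 1.0:
        raise ValueError("only full-coverage ungapped matching is supported")
    L = len(spacer)
    sp = np.frombuffer(spacer.encode(), dtype=np.uint8)
    best: SpacerMatch | None = None
    for tid in sorted(targets):
        for strand in ("+", "-"):
            t = targets[tid].upper()
            if strand == "-":
                t = reverse_complement(t)
            if len(t) < L:
                continue
            arr = np.frombuffer(t.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            matches = (windows == sp).sum(axis=1)
            idx = int(np.argmax(matches))
            identity = float(matches[idx]) / L
            if identity < min_identity:
                continue
            cand = SpacerMatch(
                spacer_id=spacer_id, target_id=tid,
                coverage=1.0, identity=identity,
                strand=strand, target_start=idx,
            )
            if best is None or cand.identity > best.identity:
                best = cand
    return best


# ---------------------------------------------------------------------------
# Defense inventory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DefenseReport:
    systems_present: tuple[str, ...]
    symbols_by_system: dict
    crispr_arrays: int


def inventory_defense(
    tags: Iterable[FunctionalTag],
    arrays: Sequence[CrisprArray] = (),
    lexicon: Lexicon | None = None,
    min_members: int = 2,
) -> DefenseReport:
    """Group defense tags into named systems.

    A system counts as present when at least ``min_members`` of its member
    symbols occur (capped at the system's size, so single-gene systems
    like pAgo need only their one symbol).  CRISPR is reported present
    whenever arrays were detected, independent of cas gene tags.
    """
    lexicon = lexicon or Lexicon.default()
    system_members = lexicon.systems
    seen: dict[str, set[str]] = {}
    for tag in tags:
        if tag.category == "defense" and tag.system:
            seen.setdefault(tag.system, set()).add(tag.symbol)
    present = []
    for system in sorted(seen):
        needed = min(min_members, len(system_members.get(system, {0})))
        if len(seen[system]) >= needed:
            present.append(system)
    if arrays and "CRISPR-Cas" not in present:
        present.append("CRISPR (array)")
    return DefenseReport(
        systems_present=tuple(sorted(present)),
        symbols_by_system={k: tuple(sorted(v)) for k, v in sorted(seen.items())},
        crispr_arrays=len(arrays),
    )
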