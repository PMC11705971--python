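"""Functional tagging, CRISPR arrays, nested systems, spacer matching."""

import numpy as np
import pytest

from proviscope import featureannot as fa
from proviscope import synthgenome as sg


class TestTagFunctions:
    LEX = fa.Lexicon.default()

    @pytest.mark.parametrize(
        "product,category,symbol",
        [
            ("phage holin family protein", "lysis", "hol"),
            ("HYPOTHETICAL PROTEIN", "hypothetical", "hyp"),
            ("tyrosine decarboxylase", "amg", "mfnA"),
            ("HK97-like major capsid protein", "structural", "MCP"),
            ("portal protein", "structural", "portal"),
            ("site-specific integrase", "mobilization", "int"),
            ("DrmB protein", "defense", "DrmB"),
            ("phycocyanobilin lyase subunit alpha CpcE", "amg", "cpcE"),
            ("completely novel widget", "hypothetical", "hyp"),
        ],
    )
    def test_category_assignment(self, product, category, symbol):
        [tag] = fa.tag_functions([("g1", product)], self.LEX)
        assert (tag.category, tag.symbol) == (category, symbol)

    def test_longest_match_wins(self):
        # "terminase large subunit" must beat the bare "terminase" term.
        [tag] = fa.tag_functions([("g", "putative terminase large subunit")], self.LEX)
        assert tag.symbol == "terL"
        [tag] = fa.tag_functions([("g", "endolysin-like protein")], self.LEX)
        assert tag.symbol == "lys"

    def test_idempotent_and_order_independent(self):
        ann = [("a", "holin"), ("b", "portal protein"), ("c", "DndC")]
        fwd = fa.tag_functions(ann, self.LEX)
        rev = fa.tag_functions(list(reversed(ann)), self.LEX)
        assert sorted(t.gene_id for t in fwd) == sorted(t.gene_id for t in rev)
        assert {t.gene_id: t.category for t in fwd} == {
            t.gene_id: t.category for t in rev
        }

    def test_symbol_category_uniqueness_enforced(self):
        with pytest.raises(ValueError, match="two categories"):
            fa.Lexicon(
                [
                    fa.LexiconEntry("foo", "lysis", "X"),
                    fa.LexiconEntry("bar", "defense", "X"),
                ]
            )


class TestDetectCrisprArrays:
    def test_forged_array_recovered_exactly(self):
        rng = np.random.default_rng(2)
        seq, truth = sg.forge_crispr_locus(
            [sg.CrisprArraySpec(n_spacers=5, repeat_length=30)], rng
        )
        arrays = fa.detect_crispr_arrays(seq)
        assert len(arrays) == 1
        arr, want = arrays[0], truth.arrays[0]
        assert arr.n_spacers == 5 and arr.repeat_length == 30
        assert arr.repeat_consensus == want.repeat_consensus
        assert arr.repeat_positions == want.repeat_positions
        assert arr.spacers == want.spacers

    @pytest.mark.parametrize("n_spacers,repeat_len,spacer_range", [
        (3, 24, (20, 26)),
        (8, 36, (30, 40)),
        (12, 30, (34, 38)),
    ])
    def test_parameter_grid_against_truth(self, n_spacers, repeat_len, spacer_range):
        rng = np.random.default_rng(n_spacers * 100 + repeat_len)
        seq, truth = sg.forge_crispr_locus(
            [sg.CrisprArraySpec(n_spacers, repeat_len, spacer_range)], rng
        )
        arrays = fa.detect_crispr_arrays(seq)
        assert len(arrays) == 1
        assert arrays[0].n_spacers == n_spacers
        assert arrays[0].repeat_consensus == truth.arrays[0].repeat_consensus

    def test_repeat_spacer_count_invariant(self, nested_crispr_locus):
        seq, _truth = nested_crispr_locus
        for arr in fa.detect_crispr_arrays(seq):
            assert arr.n_repeats == arr.n_spacers + 1

    def test_random_sequence_yields_nothing(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        assert fa.detect_crispr_arrays(seq) == []

    def test_substituted_copy_within_budget_keeps_chain(self):
        rng = np.random.default_rng(4)
        seq, truth = sg.forge_crispr_locus(
            [sg.CrisprArraySpec(n_spacers=5, repeat_length=30)], rng
        )
        # Mutate one base in the middle repeat copy.
        arr = truth.arrays[0]
        pos = arr.repeat_positions[2] + 13
        mutated = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1 :]
        arrays = fa.detect_crispr_arrays(mutated, max_repeat_mismatch=2)
        assert len(arrays) == 1 and arrays[0].n_spacers == 5

    def test_over_budget_copy_breaks_chain(self):
        rng = np.random.default_rng(5)
        seq, truth = sg.forge_crispr_locus(
            [sg.CrisprArraySpec(n_spacers=7, repeat_length=30)], rng
        )
        arr = truth.arrays[0]
        # Scatter substitutions across the middle copy, beyond any budget.
        s = list(seq)
        for off in range(0, 30, 4):
            pos = arr.repeat_positions[3] + off
            s[pos] = "A" if s[pos] != "A" else "C"
        arrays = fa.detect_crispr_arrays("".join(s), max_repeat_mismatch=2)
        assert arrays and max(a.n_spacers for a in arrays) < 7


class TestNestedSystem:
    def test_forged_nested_locus_detected(self, nested_crispr_locus):
        seq, truth = nested_crispr_locus
        arrays = fa.detect_crispr_arrays(seq)
        cas = [(s, e, st) for s, e, st, _n in truth.cas_genes]
        nested, layout = fa.detect_nested_system(arrays, cas)
        assert nested and layout["orientation"] == "+"

    def test_single_array_not_nested(self):
        rng = np.random.default_rng(6)
        seq, _ = sg.forge_crispr_locus(
            [sg.CrisprArraySpec(n_spacers=4, repeat_length=30)], rng
        )
        arrays = fa.detect_crispr_arrays(seq)
        nested, _ = fa.detect_nested_system(arrays, [])
        assert not nested

    def test_opposite_orientations_rejected(self, nested_crispr_locus):
        seq, truth = nested_crispr_locus
        arrays = fa.detect_crispr_arrays(seq)
        flipped = []
        for i, arr in enumerate(arrays):
            flipped.append(
                fa.CrisprArray(
                    start=arr.start, end=arr.end,
                    repeat_positions=arr.repeat_positions,
                    repeat_consensus=arr.repeat_consensus,
                    spacers=arr.spacers, spacer_positions=arr.spacer_positions,
                    orientation="+" if i == 0 else "-",
                )
            )
        cas = [(s, e, st) for s, e, st, _n in truth.cas_genes]
        nested, layout = fa.detect_nested_system(flipped, cas)
        assert not nested and "orientation" in layout["reason"]

    def test_orientation_inferred_from_cas_strand(self, nested_crispr_locus):
        seq, truth = nested_crispr_locus
        arrays = fa.detect_crispr_arrays(seq)
        assert all(a.orientation == "unknown" for a in arrays)
        cas = [(s, e, st) for s, e, st, _n in truth.cas_genes]
        oriented = fa.orient_arrays(arrays, cas)
        assert all(a.orientation == "+" for a in oriented)


class TestMatchSpacer:
    TARGET = (
        "CCATGAACGGTAGCATTGGCAAACCTTGTTGAGCCGTTAGACGATTACGGCTT"
        "AGGCTTACCAATGGCCTTAAACCGGTTAACCGGTT"
    )

    def test_exact_match(self):
        spacer = self.TARGET[10:44]
        m = fa.match_spacer(spacer, {"t": self.TARGET})
        assert m.coverage == 1.0 and m.identity == 1.0
        assert m.target_start == 10 and m.strand == "+"

    def test_two_substitutions_identity(self):
        spacer = list(self.TARGET[10:44])
        spacer[5] = "A" if spacer[5] != "A" else "C"
        spacer[20] = "A" if spacer[20] != "A" else "C"
        m = fa.match_spacer("".join(spacer), {"t": self.TARGET})
        assert m.identity == pytest.approx(32 / 34)

    def test_reverse_strand_found(self):
        from proviscope.seqio import reverse_complement

        spacer = reverse_complement(self.TARGET[20:54])
        m = fa.match_spacer(spacer, {"t": self.TARGET})
        assert m is not None and m.strand == "-"
        assert m.identity == 1.0

    def test_absent_spacer_none(self):
        rng = np.random.default_rng(7)
        spacer = "".join(rng.choice(list("ACGT"), size=34))
        assert fa.match_spacer(spacer, {"t": self.TARGET}) is None

    def test_short_spacer_rejected(self):
        with pytest.raises(ValueError, match="18"):
            fa.match_spacer("ACGTACGT", {"t": self.TARGET})


class TestInventoryDefense:
    LEX = fa.Lexicon.default()

    def _tags(self, products):
        return fa.tag_functions([(f"g{i}", p) for i, p in enumerate(products)], self.LEX)

    def test_disarm_present_with_three_members(self):
        report = fa.inventory_defense(self._tags(["DrmA", "DrmB", "DrmE"]))
        assert "DISARM" in report.systems_present

    def test_single_member_listed_but_absent(self):
        report = fa.inventory_defense(self._tags(["DrmC protein"]))
        assert "DISARM" not in report.systems_present
        assert report.symbols_by_system["DISARM"] == ("DrmC",)

    def test_dnd_present(self):
        report = fa.inventory_defense(self._tags(["PbeA", "DndC", "DndD"]))
        assert "Dnd" in report.systems_present

    def test_single_gene_system_needs_one_symbol(self):
        report = fa.inventory_defense(self._tags(["pPIWI domain protein"]))
        assert "pAgo" in report.systems_present

    def test_crispr_reported_from_arrays(self, nested_crispr_locus):
        seq, _ = nested_crispr_locus
        arrays = fa.detect_crispr_arrays(seq)
        report = fa.inventory_defense([], arrays)
        assert report.crispr_arrays == len(arrays) > 0
        assert any("CRISPR" in s for s in report.systems_present)
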