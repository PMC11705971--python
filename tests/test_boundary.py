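"""Direct-repeat finding and provirus delimitation."""

import numpy as np
import pytest

from proviscope import boundary as bd
from proviscope import seqio
from proviscope import synthgenome as sg
from proviscope.seqio import GeneCall, Gff3Feature, Replicon


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _toy_config(**kw):
    defaults = dict(
        span_min=300, span_max=900, dr_min_len=10, dr_max_mismatch=1,
        low_complexity_filter=False, window=5_000,
    )
    defaults.update(kw)
    return bd.BoundaryConfig(**defaults)


class TestFindDirectRepeats:
    def test_oracle_equivalence_on_config_grid(self):
        """The vectorized sweep must agree exactly with brute force."""
        rng = np.random.default_rng(101)
        configs = [
            _toy_config(),
            _toy_config(dr_max_mismatch=0),
            _toy_config(dr_max_mismatch=2, dr_min_len=12),
            _toy_config(span_min=200, span_max=600, dr_min_len=8),
            _toy_config(low_complexity_filter=True),
        ]
        for trial in range(4):
            seq = list(_random_seq(rng, 1_500))
            # Plant a few duplications at in-range offsets, some mutated.
            for length, offset, n_mut in ((25, 500, 0), (15, 700, 1), (30, 420, 2)):
                start = int(rng.integers(0, 1_500 - offset - length))
                copy = seq[start : start + length]
                for _ in range(n_mut):
                    j = int(rng.integers(length))
                    copy[j] = "ACGT".replace(copy[j], "")[int(rng.integers(3))]
                seq[start + offset : start + offset + length] = copy
            s = "".join(seq)
            for config in configs:
                fast = bd.find_direct_repeats(s, config)
                slow = bd.brute_force_direct_repeats(s, config)
                assert fast == slow, f"trial {trial}, config {config}"

    def test_planted_exact_pair_reported_at_truth_coordinates(self):
        rng = np.random.default_rng(7)
        seq = list(_random_seq(rng, 13_000))
        word = list("ACGTTGCAGGATCCATTGCAAGGCTTCAGA")  # 30 bp
        seq[1000:1030] = word
        seq[12_000:12_030] = word
        # Delimit the copies so the planted extent is unambiguous.
        seq[999], seq[11_999] = "A", "C"
        seq[1030], seq[12_030] = "G", "T"
        found = bd.find_direct_repeats("".join(seq), bd.BoundaryConfig())
        exact = [
            r for r in found
            if (r.rep1_start, r.rep1_end, r.rep2_start, r.rep2_end)
            == (1000, 1030, 12_000, 12_030)
        ]
        assert len(exact) == 1 and exact[0].mismatches == 0

    def test_planted_mismatched_pair_found_with_count(self):
        rng = np.random.default_rng(8)
        seq = list(_random_seq(rng, 12_500))
        word = list("ACGTTGCAGGATCCATTGCAAGGCTTCAGA")
        seq[500:530] = word
        mutated = word.copy()
        mutated[14] = "ACGT".replace(mutated[14], "")[0]
        seq[11_000:11_030] = mutated
        seq[499], seq[10_999] = "A", "C"
        seq[530], seq[11_030] = "G", "T"
        found = bd.find_direct_repeats("".join(seq), bd.BoundaryConfig())
        match = [
            r for r in found
            if (r.rep1_start, r.rep2_start) == (500, 11_000) and r.length == 30
        ]
        assert len(match) == 1 and match[0].mismatches == 1

    def test_low_complexity_filter_suppresses_poly_a(self):
        seq = "A" * 1_200
        config = _toy_config(low_complexity_filter=True)
        assert bd.find_direct_repeats(seq, config) == []

    def test_entropy_measure(self):
        config = bd.BoundaryConfig()
        assert bd.dinucleotide_entropy("AAAAAAAA") == 0.0
        assert bd.dinucleotide_entropy("ATATATATAT") < config.entropy_min_bits
        assert bd.dinucleotide_entropy("ACGTTGCAGGATCCATTGCAAGGCTTCAGA") > config.entropy_min_bits


class TestAttCandidates:
    MCP = GeneCall("R", 20_000, 21_000, "+", "", source="imported", gene_id="mcp")

    def _pair(self, start, end_offset):
        return bd.DirectRepeat(start, start + 30, start + end_offset, start + end_offset + 30, 0, "A" * 30)

    def test_bracketing_and_span_filters(self):
        config = bd.BoundaryConfig()
        inside = self._pair(15_000, 12_000)  # span 15_000..27_030, brackets MCP
        not_bracketing = self._pair(30_000, 12_000)
        too_short = bd.DirectRepeat(19_000, 19_030, 27_990, 28_020, 0, "A" * 30)
        kept = bd.enumerate_att_candidates(
            [inside, not_bracketing, too_short], self.MCP, config
        )
        assert kept == [inside]

    def test_short_span_excluded_at_threshold(self):
        config = bd.BoundaryConfig()
        pair = bd.DirectRepeat(16_000, 16_030, 24_970, 25_000, 0, "A" * 30)
        assert (25_000 - 16_000) < config.span_min
        assert bd.enumerate_att_candidates([pair], self.MCP, config) == []


class TestScoreAtt:
    def test_full_evidence_worked_example(self):
        config = bd.BoundaryConfig()
        pair = bd.DirectRepeat(1_000, 1_030, 21_000, 21_030, 0, "G" * 30)
        integrase = GeneCall(
            "R", 1_200, 2_400, "+", "", source="imported",
            gene_id="i", product="tyrosine integrase",
        )
        trna = Gff3Feature("R", "t", "tRNA", 900, 1_010, "+")
        score, intg, tr = bd.score_att(pair, [integrase], [trna], config)
        assert score == pytest.approx(3 + 2 + 0.6 - 0.0)
        assert intg is integrase and tr is trna

    def test_no_evidence_short_mismatched_pair(self):
        config = bd.BoundaryConfig()
        pair = bd.DirectRepeat(1_000, 1_014, 21_000, 21_014, 2, "G" * 14)
        score, intg, tr = bd.score_att(pair, [], [], config)
        assert score == pytest.approx(0 + 0 + 14 / 50 - 1.0)
        assert intg is None and tr is None

    def test_score_symmetric_in_copy_labels(self):
        config = bd.BoundaryConfig()
        pair = bd.DirectRepeat(2_000, 2_030, 22_000, 22_030, 1, "G" * 30)
        trna_left = Gff3Feature("R", "t", "tRNA", 1_900, 1_990, "+")
        trna_right = Gff3Feature("R", "t", "tRNA", 22_040, 22_130, "+")
        s_left, *_ = bd.score_att(pair, [], [trna_left], config)
        s_right, *_ = bd.score_att(pair, [], [trna_right], config)
        assert s_left == s_right


class TestCallProvirus:
    def test_clean_forged_replicon_exact_call(self, forged_replicon):
        _config, replicon, truth, genes = forged_replicon
        gene_calls = sg.gene_calls_from_map(replicon.id, genes)
        mcp = [g for g in gene_calls if "capsid" in g.product]
        trnas = [
            Gff3Feature(replicon.id, "t", "tRNA", truth.trna_span[0], truth.trna_span[1], "+")
        ]
        calls = bd.call_provirus(replicon, mcp, gene_calls, trnas)
        assert len(calls) == 1
        call = calls[0]
        assert call.completeness == "complete"
        assert (call.start, call.end) == (truth.provirus_start, truth.provirus_end)
        assert call.integrase_gene is not None and call.trna is not None

    def test_repeats_removed_yields_partial_only(self, forged_replicon):
        config, replicon, truth, genes = forged_replicon
        # Rebuild the replicon without the attR duplication.
        seq = (
            replicon.sequence[: truth.attR_start]
            + replicon.sequence[truth.attR_end :]
        )
        stripped = Replicon(id="STRIPPED", sequence=seq)
        gene_calls = [
            GeneCall("STRIPPED", g.start, g.end, g.strand, g.protein,
                     source="imported", gene_id=g.gene_id, product=g.product)
            for g in sg.gene_calls_from_map(replicon.id, genes)
        ]
        trnas = [
            Gff3Feature("STRIPPED", "t", "tRNA", truth.trna_span[0], truth.trna_span[1], "+")
        ]
        mcp = [g for g in gene_calls if "capsid" in g.product]
        calls = bd.call_provirus(stripped, mcp, gene_calls, trnas)
        assert [c.completeness for c in calls] == ["partial"]

    def test_two_proviruses_recovered_without_overlap(self):
        cfg = sg.ForgeConfig(
            rng_seed=21, host_length=60_000, n_proviruses=2,
            provirus_length_range=(10_500, 13_000),
        )
        rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed))
        replicon, truths, genes = sg.forge_replicon(cfg, "R2", rng)
        gene_calls = sg.gene_calls_from_map("R2", genes)
        mcp = [g for g in gene_calls if "capsid" in g.product]
        trnas = [
            Gff3Feature("R2", "t", "tRNA", t.trna_span[0], t.trna_span[1], "+")
            for t in truths
        ]
        calls = bd.call_provirus(replicon, mcp, gene_calls, trnas)
        spans = sorted((c.start, c.end) for c in calls if c.completeness == "complete")
        want = sorted((t.provirus_start, t.provirus_end) for t in truths)
        assert spans == want
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_span_bounds_invariant(self, forged_replicon):
        config, replicon, truth, genes = forged_replicon
        gene_calls = sg.gene_calls_from_map(replicon.id, genes)
        mcp = [g for g in gene_calls if "capsid" in g.product]
        bconfig = bd.BoundaryConfig()
        calls = bd.call_provirus(replicon, mcp, gene_calls, [], bconfig)
        for c in calls:
            if c.completeness == "complete":
                assert bconfig.span_min <= c.end - c.start <= bconfig.span_max


class TestExtract:
    def _complete_call(self, forged_replicon):
        _config, replicon, truth, genes = forged_replicon
        gene_calls = sg.gene_calls_from_map(replicon.id, genes)
        mcp = [g for g in gene_calls if "capsid" in g.product]
        trnas = [
            Gff3Feature(replicon.id, "t", "tRNA", truth.trna_span[0], truth.trna_span[1], "+")
        ]
        return replicon, truth, bd.call_provirus(replicon, mcp, gene_calls, trnas)[0]

    def test_extracted_sequence_and_id(self, forged_replicon):
        replicon, truth, call = self._complete_call(forged_replicon)
        sub, feats = bd.extract_provirus(replicon, call)
        assert sub.id == f"{replicon.id}_pro"
        assert sub.sequence == replicon.sequence[truth.provirus_start : truth.provirus_end]
        mcp_feat = next(f for f in feats if f.attributes.get("product") == "major capsid protein")
        assert mcp_feat.start == call.mcp_gene.start - call.start
        names = {f.attributes.get("Name") for f in feats}
        assert {"attL", "attR"} <= names

    def test_partial_call_cannot_be_extracted(self, forged_replicon):
        _config, replicon, _truth, _genes = forged_replicon
        mcp = GeneCall(replicon.id, 100, 400, "+", "", source="imported", gene_id="m")
        partial = bd.ProvirusCall(
            replicon_id=replicon.id, start=100, end=400, att=None,
            mcp_gene=mcp, integrase_gene=None, trna=None,
            score=0.0, completeness="partial",
        )
        with pytest.raises(ValueError, match="partial"):
            bd.extract_provirus(replicon, partial)
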