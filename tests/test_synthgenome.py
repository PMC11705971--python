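"""The synthetic-genome forge: determinism and truth consistency."""

import numpy as np
import pytest

from proviscope import seqio
from proviscope.synthgenome import (
    CrisprArraySpec,
    ForgeConfig,
    ForgeConfigError,
    forge_crispr_locus,
    forge_dataset,
    forge_provirus_cassette,
    forge_replicon,
    implant_provirus,
    mutate_protein,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestConfig:
    def test_invalid_ranges_rejected(self):
        with pytest.raises(ForgeConfigError):
            ForgeConfig(provirus_length_range=(200_000, 300_000), host_length=100_000)
        with pytest.raises(ForgeConfigError):
            ForgeConfig(dr_length=10, dr_mismatches=10)
        with pytest.raises(ForgeConfigError):
            ForgeConfig(integrase_end="middle")
        with pytest.raises(ForgeConfigError):
            ForgeConfig(gc_fraction=1.5)

    def test_crispr_spec_validation(self):
        with pytest.raises(ForgeConfigError):
            CrisprArraySpec(n_spacers=0)
        with pytest.raises(ForgeConfigError):
            CrisprArraySpec(n_spacers=3, repeat_length=12)
        with pytest.raises(ForgeConfigError):
            CrisprArraySpec(n_spacers=3, spacer_length_range=(40, 30))


class TestCassette:
    CFG = ForgeConfig(host_length=30_000, provirus_length_range=(10_500, 12_000))

    def test_gene_inventory_and_orf_validity(self):
        cassette, gene_map = forge_provirus_cassette(self.CFG, _rng(1), 11_000)
        roles = [g[3] for g in gene_map]
        assert roles.count("integrase") == 1
        assert sum("capsid" in r for r in roles) == 1
        assert sum(r not in ("integrase", "hypothetical protein") for r in roles) >= 4
        assert "holin" not in roles and "endolysin" not in roles
        for start, end, _strand, _role, protein in gene_map:
            dna = cassette[start:end]
            assert dna[:3] == "ATG" and dna[-3:] in ("TAA", "TAG", "TGA")
            assert seqio.translate(dna) == protein  # no internal stops

    def test_lysis_genes_on_request(self):
        cfg = ForgeConfig(
            host_length=30_000,
            provirus_length_range=(10_500, 12_000),
            include_lysis_genes=True,
        )
        _, gene_map = forge_provirus_cassette(cfg, _rng(2), 11_000)
        roles = [g[3] for g in gene_map]
        assert "holin" in roles and "endolysin" in roles

    def test_integrase_at_configured_end(self):
        _, left_map = forge_provirus_cassette(self.CFG, _rng(3), 11_000)
        intg = next(g for g in left_map if g[3] == "integrase")
        assert intg[0] <= 0.10 * 11_000
        cfg = ForgeConfig(
            host_length=30_000,
            provirus_length_range=(10_500, 12_000),
            integrase_end="right",
        )
        cassette, right_map = forge_provirus_cassette(cfg, _rng(3), 11_000)
        intg = next(g for g in right_map if g[3] == "integrase")
        # Last protein-coding gene before any tail filler.
        assert intg[1] >= max(g[1] for g in right_map)

    def test_infeasible_target_raises(self):
        with pytest.raises(ForgeConfigError, match="cannot hold"):
            forge_provirus_cassette(self.CFG, _rng(4), 1_000)


class TestImplant:
    def test_exact_duplication_and_substring_identity(self, forged_replicon):
        config, replicon, truth, _genes = forged_replicon
        seq = replicon.sequence
        attL = seq[truth.attL_start : truth.attL_end]
        attR = seq[truth.attR_start : truth.attR_end]
        assert attL == attR  # dr_mismatches = 0
        assert len(attL) == config.dr_length
        span = seq[truth.attL_start : truth.attR_end]
        cassette = seq[truth.attL_end : truth.attR_start]
        assert span == attL + cassette + attR
        assert truth.trna_span is not None
        assert truth.trna_span[1] >= truth.attL_start  # overlaps or abuts attL

    def test_mismatched_repeat_copy(self):
        cfg = ForgeConfig(
            host_length=30_000,
            provirus_length_range=(10_500, 12_000),
            dr_mismatches=2,
        )
        rng = _rng(5)
        rep, truths, _ = forge_replicon(cfg, "R", rng)
        t = truths[0]
        a = rep.sequence[t.attL_start : t.attL_end]
        b = rep.sequence[t.attR_start : t.attR_end]
        assert sum(x != y for x, y in zip(a, b)) == 2

    def test_site_out_of_range(self):
        cfg = ForgeConfig(host_length=30_000, provirus_length_range=(10_500, 12_000))
        cassette, gene_map = forge_provirus_cassette(cfg, _rng(6), 10_500)
        with pytest.raises(ValueError, match="out of range"):
            implant_provirus("ACGT" * 100, cassette, gene_map, 10_000, cfg, _rng(6))

    def test_determinism(self):
        cfg = ForgeConfig(host_length=25_000, provirus_length_range=(10_500, 12_000))
        r1, t1, g1 = forge_replicon(cfg, "R", _rng(9))
        r2, t2, g2 = forge_replicon(cfg, "R", _rng(9))
        assert r1.sequence == r2.sequence
        assert t1 == t2 and g1 == g2


class TestDataset:
    def test_no_proviruses_empty_bed(self, tmp_path):
        cfg = ForgeConfig(
            rng_seed=1, host_length=20_000, n_proviruses=0,
            provirus_length_range=(10_000, 12_000),
        )
        paths = forge_dataset(cfg, tmp_path / "d0")
        assert paths["bed"].read_text() == ""
        assert len(seqio.read_fasta(paths["fasta"])) == 1

    def test_three_proviruses_non_overlapping(self, tmp_path):
        cfg = ForgeConfig(
            rng_seed=2, host_length=90_000, n_proviruses=3,
            provirus_length_range=(10_500, 12_000),
        )
        paths = forge_dataset(cfg, tmp_path / "d3")
        rows = [l.split("\t") for l in paths["bed"].read_text().splitlines()]
        spans = sorted((int(r[1]), int(r[2])) for r in rows)
        assert len(spans) == 3
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_gc_fraction_honoured(self, tmp_path):
        cfg = ForgeConfig(
            rng_seed=3, host_length=100_000, n_proviruses=0,
            gc_fraction=0.55, provirus_length_range=(10_000, 12_000),
        )
        paths = forge_dataset(cfg, tmp_path / "gc")
        seq = seqio.read_fasta(paths["fasta"])[0].sequence
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.55) <= 0.02

    def test_dataset_determinism_and_round_trip(self, tmp_path):
        cfg = ForgeConfig(
            rng_seed=4, host_length=25_000, provirus_length_range=(10_500, 12_000),
        )
        p1 = forge_dataset(cfg, tmp_path / "a")
        p2 = forge_dataset(cfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()
        replicons = seqio.read_fasta(p1["fasta"])
        feats = seqio.read_gff3(p1["gff3"])
        calls = seqio.genes_from_gff3(feats, {r.id: r for r in replicons})
        assert calls and all(c.protein for c in calls)
        assert seqio.trnas_from_gff3(feats)


class TestCrisprForge:
    def test_repeat_and_spacer_counts(self):
        seq, truth = forge_crispr_locus(
            [CrisprArraySpec(n_spacers=3, repeat_length=30)], _rng(1)
        )
        arr = truth.arrays[0]
        assert arr.n_repeats == 4 and arr.n_spacers == 3
        for pos in arr.repeat_positions:
            assert seq[pos : pos + 30] == arr.repeat_consensus
        for pos, spacer in zip(arr.spacer_positions, arr.spacers):
            assert seq[pos : pos + len(spacer)] == spacer

    def test_spacers_pairwise_distinct(self):
        _, truth = forge_crispr_locus(
            [CrisprArraySpec(n_spacers=40, repeat_length=24)], _rng(2)
        )
        spacers = truth.arrays[0].spacers
        assert len(set(spacers)) == len(spacers)

    def test_nested_layout_flag_and_orientation(self, nested_crispr_locus):
        _seq, truth = nested_crispr_locus
        assert truth.nested
        assert {a.orientation for a in truth.arrays} == {"+"}
        assert {g[2] for g in truth.cas_genes} == {"+"}
        first = min(a.start for a in truth.arrays)
        last = max(a.end for a in truth.arrays)
        assert any(e <= first for _s, e, _st, _n in truth.cas_genes)
        assert any(s >= last for s, _e, _st, _n in truth.cas_genes)

    def test_single_array_no_cas_is_not_nested(self):
        _, truth = forge_crispr_locus(
            [CrisprArraySpec(n_spacers=3, repeat_length=30)], _rng(3)
        )
        assert not truth.nested and truth.cas_genes == ()


class TestMutateProtein:
    @pytest.mark.parametrize("identity", [0.9, 0.6, 0.3])
    def test_controlled_identity(self, identity):
        rng = _rng(7)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        mutant = mutate_protein(protein, identity, rng)
        matches = sum(a == b for a, b in zip(protein, mutant))
        assert matches == round(identity * 200)
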