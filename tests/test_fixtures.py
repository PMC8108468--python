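"""Determinism and truth-consistency of the synthetic-data generators."""

import numpy as np
import pytest

from opsinminer import fixtures as fx
from opsinminer import pipeline as pl
from opsinminer.seq import K296, map_to_reference, residue_at, write_fasta


class TestOpsinVariant:
    def test_rate_zero_is_copy(self, templates):
        v = fx.make_opsin_variant(templates["LWS"], 0.0, seed=1)
        assert v.seq == templates["LWS"].seq

    def test_realized_identity_within_binomial_bounds(self, templates):
        # rate 0.05 over 346 mutable sites: 99% binomial band ~ [0.017, 0.083]
        tpl = templates["LWS"]
        v = fx.make_opsin_variant(tpl, 0.05, seed=8)
        diffs = sum(a != b for a, b in zip(v.seq, tpl.seq))
        assert 0.017 <= diffs / 346 <= 0.083

    def test_k_site_masked_across_seeds(self, templates, bovine):
        tpl = templates["MWS"]
        for s in range(100):
            v = fx.make_opsin_variant(tpl, 0.2, seed=s)
            pmap = map_to_reference(v, bovine)
            assert residue_at(v, pmap, K296) == "K"

    def test_rate_one_rejected(self, templates):
        with pytest.raises(ValueError):
            fx.make_opsin_variant(templates["LWS"], 1.0, seed=1)


class TestDecoy:
    def test_fails_k296_but_survives_prescreen(self, templates, ref_db, bovine):
        decoy = fx.make_decoy_gpcr(templates["LWS"], seed=4)
        assert not pl.check_k296(decoy, bovine)[0]
        cand = pl.OrfCandidate("c", 1, 1, 3 * len(decoy), decoy.seq, True)
        assert len(pl.prescreen([cand], ref_db)) == 1

    def test_distinct_seeds_distinct_decoys(self, templates, bovine):
        d1 = fx.make_decoy_gpcr(templates["LWS"], seed=1)
        d2 = fx.make_decoy_gpcr(templates["LWS"], seed=2)
        assert d1.seq != d2.seq
        for d in (d1, d2):
            assert not pl.check_k296(d, bovine)[0]


class TestAssembly:
    def test_contig_count_and_truth_rows(self, templates):
        spec = fx.FixtureSpec(seed=1, n_opsins_per_class={"LWS": 3, "MWS": 1}, n_decoys=2)
        contigs, truth = fx.make_assembly(spec, templates)
        assert len(contigs) == len(truth) == 6
        assert (truth.kind == "opsin").sum() == 4
        assert (truth.kind == "decoy").sum() == 2

    def test_truth_peptides_retranslate(self, templates):
        from oracles import _CODON_TABLE, revcomp

        spec = fx.FixtureSpec(seed=2, fragment_fraction=0.25,
                              n_opsins_per_class={"LWS": 4, "MWS": 2})
        contigs, truth = fx.make_assembly(spec, templates)
        by_id = {c.id: c for c in contigs}
        for row in truth.itertuples():
            s = by_id[row.contig_id].seq
            frames = [
                "".join(
                    _CODON_TABLE[t[p : p + 3]] for p in range(o, len(t) - 2, 3)
                )
                for t in (s, revcomp(s))
                for o in range(3)
            ]
            assert any(row.peptide in f for f in frames), row.contig_id

    def test_fragments_marked_not_full_length(self, templates):
        spec = fx.FixtureSpec(seed=3, n_opsins_per_class={"LWS": 4}, n_decoys=0,
                              fragment_fraction=0.5)
        _, truth = fx.make_assembly(spec, templates)
        assert (~truth.full_length).sum() == 2

    def test_byte_identical_for_same_spec(self, tmp_path, templates):
        spec = fx.FixtureSpec(seed=9, fragment_fraction=0.3, near_duplicates=1)
        for name in ("a", "b"):
            contigs, _ = fx.make_assembly(spec, templates)
            write_fasta(contigs, tmp_path / f"{name}.fasta")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_no_templates_errors(self):
        with pytest.raises(ValueError):
            fx.make_assembly(fx.FixtureSpec(seed=1), templates={})


class TestGroupedSet:
    def test_deterministic(self):
        a, _ = fx.make_grouped_set(seed=4, n_baikal=12, n_euro_lws=3, n_euro_mws=2,
                                   plants=[fx.PlantedEvent(115, (0, 1))])
        b, _ = fx.make_grouped_set(seed=4, n_baikal=12, n_euro_lws=3, n_euro_mws=2,
                                   plants=[fx.PlantedEvent(115, (0, 1))])
        assert [r.seq for r in a] == [r.seq for r in b]

    def test_unmappable_position_errors(self):
        with pytest.raises(ValueError, match="unmappable"):
            fx.make_grouped_set(seed=1, n_baikal=10,
                                plants=[fx.PlantedEvent(400, (0,))])
        with pytest.raises(ValueError, match="protected"):
            fx.make_grouped_set(seed=1, n_baikal=10,
                                plants=[fx.PlantedEvent(K296, (0,))])

    def test_default_plants_shape(self):
        plants = fx.default_plants(102)
        counts = sorted((len(p.carriers) for p in plants), reverse=True)
        assert len(plants) == 32
        assert counts[:5] == [48, 30, 19, 14, 12]
        assert all(c <= 10 for c in counts[5:])
        top3 = {p.bovine_pos: set(p.carriers) for p in plants[:3]}
        assert len(set.intersection(*top3.values())) == 11
        positions = {p.bovine_pos for p in plants}
        assert {90, 109, 115, 123} <= positions
        assert len(positions) == 32

    def test_truth_carriers_are_baikal_rows(self):
        seqs, truth = fx.make_grouped_set(seed=5, n_baikal=15, n_euro_lws=3,
                                          n_euro_mws=2,
                                          plants=[fx.PlantedEvent(200, (0, 3, 7))])
        baikal_ids = {s.id for s in seqs if s.group == "BAIKAL_LWS"}
        assert len(truth) == 1
        assert truth[0].carriers <= baikal_ids
        # the planted residue really sits at the planted position
        by_id = {s.id: s for s in seqs}
        for sid in truth[0].carriers:
            assert by_id[sid].seq[199] == truth[0].residue


class TestDepthTable:
    def test_shape_and_determinism(self):
        a = fx.make_depth_table(seed=3)
        b = fx.make_depth_table(seed=3)
        assert a.equals(b)
        assert len(a) == 43
        assert (a.n_opsins >= 0).all()
        assert set(a.columns) == {"species", "depth_m", "n_opsins", "lineage"}

    def test_true_slope_recoverable(self):
        # with noise off, the fitted slope equals the generating slope
        df = fx.make_depth_table(seed=1, n_species=30, slope=-0.006,
                                 intercept=5.0, noise_sd=0.0)
        from opsinminer.depth import fit_depth_model

        fit = fit_depth_model(df)
        assert fit.slope == pytest.approx(-0.006, rel=0.15)
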