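"""MWS-like substitution calling, occurrence spectra and co-occurrence."""

import numpy as np
import pytest

from opsinminer import fixtures as fx
from opsinminer import profiler as pf
from opsinminer.profiler import GroupedAlignment, SubstitutionEvent
from opsinminer.seq import SequenceRecord

from oracles import mws_like_tripleloop

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_ga(rows, groups, bovine_map=None):
    """Build a GroupedAlignment directly from explicit gapped rows."""
    ncol = len(next(iter(rows.values())))
    if bovine_map is None:
        bovine_map = {i: i for i in range(1, ncol + 1)}
    return GroupedAlignment(
        rows=dict(rows), groups=dict(groups), bovine_row="A" * ncol, bovine_map=bovine_map
    )


def random_ga(rng, n_rows=8, n_cols=20):
    letters = AA[:6] + "-X"
    ids = [f"s{i}" for i in range(n_rows)]
    rows = {
        i: "".join(letters[j] for j in rng.integers(len(letters), size=n_cols))
        for i in ids
    }
    groups = {}
    # guarantee one row per group, the rest random
    pool = ["BAIKAL_LWS", "EUROPEAN_LWS", "EUROPEAN_MWS"]
    for k, i in enumerate(ids):
        groups[i] = pool[k] if k < 3 else pool[rng.integers(3)]
    # map a random subset of columns to bovine positions, monotonically
    cols = sorted(rng.choice(n_cols, size=max(1, n_cols // 2), replace=False) + 1)
    bovine_map = {p + 1: int(c) for p, c in enumerate(cols)}
    return make_ga(rows, groups, bovine_map)


class TestCallMwsLike:
    def test_toy_column(self):
        ga = make_ga(
            {"b1": "A", "b2": "A", "b3": "G", "m1": "A", "l1": "G"},
            {
                "b1": "BAIKAL_LWS",
                "b2": "BAIKAL_LWS",
                "b3": "BAIKAL_LWS",
                "m1": "EUROPEAN_MWS",
                "l1": "EUROPEAN_LWS",
            },
        )
        events = pf.call_mws_like(ga)
        assert len(events) == 1
        e = events[0]
        assert (e.bovine_pos, e.residue, e.carriers) == (1, "A", frozenset({"b1", "b2"}))

    def test_residue_shared_with_euro_lws_excluded(self):
        ga = make_ga(
            {"b1": "A", "m1": "A", "l1": "A"},
            {"b1": "BAIKAL_LWS", "m1": "EUROPEAN_MWS", "l1": "EUROPEAN_LWS"},
        )
        assert pf.call_mws_like(ga) == []

    def test_gaps_and_x_never_count(self):
        ga = make_ga(
            {"b1": "A", "b2": "X", "m1": "A", "l1": "-"},
            {
                "b1": "BAIKAL_LWS",
                "b2": "BAIKAL_LWS",
                "m1": "EUROPEAN_MWS",
                "l1": "EUROPEAN_LWS",
            },
        )
        events = pf.call_mws_like(ga)
        assert len(events) == 1 and events[0].carriers == frozenset({"b1"})

    def test_matches_tripleloop_oracle(self):
        rng = np.random.default_rng(101)
        for _ in range(100):
            ga = random_ga(rng, n_rows=int(rng.integers(3, 13)),
                           n_cols=int(rng.integers(4, 31)))
            got = {(e.bovine_pos, e.residue, e.carriers) for e in pf.call_mws_like(ga)}
            assert got == mws_like_tripleloop(ga.rows, ga.groups, ga.bovine_map)

    def test_invariant_under_row_and_column_permutation(self):
        rng = np.random.default_rng(55)
        ga = random_ga(rng, n_rows=9, n_cols=18)
        base = {(e.bovine_pos, e.residue, e.carriers) for e in pf.call_mws_like(ga)}
        # permute row insertion order
        ids = list(ga.rows)
        rng.shuffle(ids)
        ga_rows = make_ga({i: ga.rows[i] for i in ids},
                          {i: ga.groups[i] for i in ids}, ga.bovine_map)
        got = {(e.bovine_pos, e.residue, e.carriers) for e in pf.call_mws_like(ga_rows)}
        assert got == base
        # permute columns, remapping bovine positions consistently
        perm = list(rng.permutation(18))
        inv = {old: new for new, old in enumerate(perm)}
        rows2 = {i: "".join(r[j] for j in perm) for i, r in ga.rows.items()}
        bmap2 = {p: inv[c - 1] + 1 for p, c in ga.bovine_map.items()}
        ga_cols = make_ga(rows2, ga.groups, bmap2)
        got2 = {(e.bovine_pos, e.residue, e.carriers) for e in pf.call_mws_like(ga_cols)}
        assert got2 == base

    def test_added_euro_lws_carrier_removes_exactly_one_event(self):
        rng = np.random.default_rng(77)
        ga = random_ga(rng, n_rows=10, n_cols=25)
        events = pf.call_mws_like(ga)
        if not events:
            pytest.skip("random draw produced no events")
        target = events[0]
        col = ga.bovine_map[target.bovine_pos]
        ncol = len(next(iter(ga.rows.values())))
        new_row = "".join(
            target.residue if j + 1 == col else "-" for j in range(ncol)
        )
        rows = dict(ga.rows, extra_lws=new_row)
        groups = dict(ga.groups, extra_lws="EUROPEAN_LWS")
        after = pf.call_mws_like(make_ga(rows, groups, ga.bovine_map))
        before_set = {(e.bovine_pos, e.residue, e.carriers) for e in events}
        after_set = {(e.bovine_pos, e.residue, e.carriers) for e in after}
        assert before_set - after_set == {
            (target.bovine_pos, target.residue, target.carriers)
        }
        assert after_set <= before_set


class TestSpectrumAndCooccurrence:
    def _ev(self, pos, carriers):
        return SubstitutionEvent(pos, "A", frozenset(carriers))

    def test_spectrum_threshold_strict(self):
        events = [
            self._ev(10, [f"s{i}" for i in range(n)]) for n in (48, 30, 19, 2)
        ]
        counts, n_over = pf.occurrence_spectrum(events, threshold=10)
        assert counts == [48, 30, 19, 2] and n_over == 3
        # a count of exactly 10 does not qualify as "more than 10"
        _, n10 = pf.occurrence_spectrum([self._ev(1, [f"s{i}" for i in range(10)])], 10)
        assert n10 == 0

    def test_empty_spectrum(self):
        assert pf.occurrence_spectrum([]) == ([], 0)

    def test_counts_recount_on_random_alignments(self):
        rng = np.random.default_rng(202)
        for _ in range(50):
            ga = random_ga(rng)
            events = pf.call_mws_like(ga)
            counts, _ = pf.occurrence_spectrum(events)
            recount = sorted((len(e.carriers) for e in events), reverse=True)
            assert counts == recount

    def test_saturated_cooccurrence(self):
        ids = [f"b{i}" for i in range(5)]
        rows = {i: "AA" for i in ids}
        rows.update(m1="AA", l1="GG")
        groups = {i: "BAIKAL_LWS" for i in ids}
        groups.update(m1="EUROPEAN_MWS", l1="EUROPEAN_LWS")
        ga = make_ga(rows, groups)
        events = pf.call_mws_like(ga)
        assert len(events) == 2
        res = pf.cooccurrence(ga, events)
        assert res.observed_count == 5
        assert res.expected_fraction == pytest.approx(1.0)

    def test_expected_fraction_arithmetic_and_order_invariance(self):
        ids = [f"b{i}" for i in range(100)]
        groups = {i: "BAIKAL_LWS" for i in ids}
        groups.update(m1="EUROPEAN_MWS", l1="EUROPEAN_LWS")
        rows = {i: ("CD" if int(i[1:]) < 10 else "AA") for i in ids}
        rows.update(m1="CD", l1="AA")
        ga = make_ga(rows, groups)
        events = pf.call_mws_like(ga)  # two events, 10 carriers each
        assert [e.count for e in events] == [10, 10]
        res = pf.cooccurrence(ga, events)
        assert res.expected_fraction * 100 == pytest.approx(1.0)
        res_rev = pf.cooccurrence(ga, list(reversed(events)))
        assert res_rev.expected_fraction == res.expected_fraction

    def test_foreign_event_rejected(self):
        ga = make_ga(
            {"b1": "A", "m1": "A", "l1": "G"},
            {"b1": "BAIKAL_LWS", "m1": "EUROPEAN_MWS", "l1": "EUROPEAN_LWS"},
        )
        foreign = SubstitutionEvent(1, "A", frozenset({"nobody"}))
        with pytest.raises(ValueError, match="does not belong"):
            pf.cooccurrence(ga, [foreign, foreign])

    def test_tuning_sites_flagged(self):
        assert SubstitutionEvent(115, "N", frozenset({"a"})).is_tuning_site
        assert not SubstitutionEvent(200, "N", frozenset({"a"})).is_tuning_site


class TestBuildGroupedAlignment:
    def test_missing_group_errors(self, bovine):
        seqs = [
            SequenceRecord(id="a", seq=bovine.seq, group="BAIKAL_LWS"),
            SequenceRecord(id="b", seq=bovine.seq, group="EUROPEAN_LWS"),
        ]
        with pytest.raises(ValueError, match="EUROPEAN_MWS"):
            pf.build_grouped_alignment(seqs, bovine)

    def test_identical_sequences_align_gap_free(self, bovine):
        seqs = [
            SequenceRecord(id="a", seq=bovine.seq, group="BAIKAL_LWS"),
            SequenceRecord(id="b", seq=bovine.seq, group="EUROPEAN_LWS"),
            SequenceRecord(id="c", seq=bovine.seq, group="EUROPEAN_MWS"),
        ]
        ga = pf.build_grouped_alignment(seqs, bovine)
        assert ga.n_columns == len(bovine)
        assert all("-" not in row for row in ga.rows.values())
        # bovine self-consistency: the 296th bovine residue maps to its column
        assert ga.bovine_map[296] == 296
        assert ga.n_columns >= max(len(s.seq) for s in seqs)

    def test_planted_events_recovered_exactly(self, bovine):
        plants = [
            fx.PlantedEvent(115, tuple(range(5))),
            fx.PlantedEvent(90, (5, 6, 7)),
        ]
        seqs, truth = fx.make_grouped_set(
            seed=5, n_baikal=20, n_euro_lws=4, n_euro_mws=3, plants=plants
        )
        ga = pf.build_grouped_alignment(seqs, bovine)
        events = pf.call_mws_like(ga)
        got = {(e.bovine_pos, e.residue, e.carriers) for e in events}
        want = {(e.bovine_pos, e.residue, e.carriers) for e in truth}
        assert got == want
        assert sorted(e.count for e in events) == [3, 5]
        assert all(e.is_tuning_site for e in events)

    def test_no_plants_no_events(self, bovine):
        seqs, truth = fx.make_grouped_set(
            seed=6, n_baikal=10, n_euro_lws=3, n_euro_mws=2, plants=[]
        )
        assert truth == []
        ga = pf.build_grouped_alignment(seqs, bovine)
        assert pf.call_mws_like(ga) == []
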