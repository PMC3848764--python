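import math

import numpy as np
import pytest

from ctgrspan.ctgr_miner import (
    MiningParams,
    Pattern,
    candidate_extensions,
    growth_prefix,
    length1_patterns,
    mine,
    parse_pattern,
    pattern_support,
    project,
    support_threshold,
)
from ctgrspan.errors import ParameterError, ParseError
from ctgrspan.reference_miners import brute_force_mine
from ctgrspan.sequence_io import SequenceDB

from .conftest import it, make_db, random_db

UNCONSTRAINED = MiningParams(min_supp=0.5)

# The full walkthrough result on the 4-patient toy database at minSupp 50%,
# SWS 0, maxTC unbounded: three frequent items plus six grown patterns.
WALKTHROUGH_PATTERNS = {
    "<(G1+)>": 4,
    "<(G2-)>": 4,
    "<(G3+)>": 4,
    "<(G1+)(G2-)>": 4,
    "<(G1+)(G3+)>": 4,
    "<(G2-)(G3+)>": 2,
    "<(G3+)(G2-)>": 2,
    "<(G3+)(G3+)>": 3,
    "<(G1+)(G3+)(G3+)>": 2,
}


class TestParamsAndThreshold:
    @pytest.mark.parametrize(
        "min_supp,n,expected",
        [(0.5, 4, 2), (1.0, 7, 7), (0.95, 20, 19), (0.95, 11, 11), (1.0, 0, 0)],
    )
    def test_ceiling_with_float_guard(self, min_supp, n, expected):
        assert support_threshold(min_supp, n) == expected

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            MiningParams(min_supp=0)
        with pytest.raises(ParameterError):
            MiningParams(min_supp=0.5, sws=-1)
        with pytest.raises(ParameterError):
            MiningParams(min_supp=0.5, max_tc=0)
        with pytest.raises(ParameterError):
            MiningParams(min_supp=0.5, sws=2, max_tc=1)
        # an infinite gap bound tolerates any window
        MiningParams(min_supp=0.5, sws=5, max_tc=math.inf)


class TestPatternType:
    def test_serialize_parse_round_trip(self):
        for text in ("<(G1+)>", "<(G1+G2-)(G3+)>", "<(G3+G3+)>"):
            assert parse_pattern(text).serialize() == text

    def test_malformed_pattern_rejected(self):
        for bad in ("(G1+)", "<G1+>", "<(G1)>", "<(G1+)x(G2-)>"):
            with pytest.raises(ParseError):
                parse_pattern(bad)

    def test_growth_prefix_peels_last_item(self):
        p = parse_pattern("<(G1+G2-)(G3+)>")
        assert growth_prefix(p).serialize() == "<(G1+G2-)>"
        assert growth_prefix(parse_pattern("<(G1+G2-)>")).serialize() == "<(G1+)>"
        assert growth_prefix(parse_pattern("<(G1+)>")) is None


class TestLength1:
    def test_frequent_items_of_walkthrough(self, table4):
        ps = length1_patterns(table4, UNCONSTRAINED)
        assert {p.serialize(): p.support for p in ps} == {
            "<(G1+)>": 4,
            "<(G2-)>": 4,
            "<(G3+)>": 4,
        }

    def test_full_support_requirement(self, table4):
        ps = length1_patterns(table4, MiningParams(min_supp=1.0))
        assert ps.serializations() == {"<(G1+)>", "<(G2-)>", "<(G3+)>"}

    def test_empty_db(self):
        assert len(length1_patterns(SequenceDB([]), UNCONSTRAINED)) == 0


class TestProjection:
    def test_root_projection_on_first_occurrence(self, table4):
        projdb = project(table4, it("G1+"), UNCONSTRAINED)
        assert len(projdb.entries) == 4
        p2 = next(e for e in projdb.entries if table4.sequences[e.seq_index].patient_id == "2")
        assert p2.anchor == 1
        postfix = projdb.postfix(p2)
        assert [t.timestamp for t in postfix] == [2, 4, 5]
        assert postfix[0].items == {it("G3+")}

    def test_second_level_projection_drops_empty_postfixes(self, table4):
        g1 = project(table4, it("G1+"), UNCONSTRAINED)
        g1g2 = project(g1, it("G2-"), UNCONSTRAINED, mode="sequence")
        # only patients 1 and 2 retain non-empty postfixes
        got = {
            (
                table4.sequences[e.seq_index].patient_id,
                tuple(t.timestamp for t in g1g2.postfix(e)),
            )
            for e in g1g2.entries
        }
        assert got == {("1", (3.0,)), ("2", (5.0,))}

    def test_projection_on_absent_item(self, table4):
        assert project(table4, it("G9+"), UNCONSTRAINED).entries == []


class TestCandidateExtensions:
    def test_unconstrained_sequence_candidates(self, table4):
        cands = candidate_extensions(project(table4, it("G1+"), UNCONSTRAINED), UNCONSTRAINED)
        assert cands["itemset"] == {}
        assert cands["sequence"] == {it("G2-"): 4, it("G3+"): 4}

    def test_window_reclassifies_first_occurrences(self, table4):
        params = MiningParams(min_supp=0.5, sws=1)
        cands = candidate_extensions(project(table4, it("G1+"), params), params)
        # within the 1-unit window the first occurrences merge into the
        # element; G2- read as a later element reaches only patient 2
        assert cands["itemset"] == {it("G2-"): 3, it("G3+"): 4}
        assert cands["sequence"] == {}

    def test_gap_bound_discards_distant_occurrences(self, table4):
        params = MiningParams(min_supp=0.5, max_tc=1)
        cands = candidate_extensions(project(table4, it("G3+"), params), params)
        assert cands["sequence"] == {it("G3+"): 2}
        assert cands["itemset"] == {}


class TestMine:
    def test_walkthrough_output_exact(self, table4):
        ps = mine(table4, UNCONSTRAINED)
        assert {p.serialize(): p.support for p in ps} == WALKTHROUGH_PATTERNS

    def test_window_length2_patterns(self, table4):
        ps = mine(table4, MiningParams(min_supp=0.5, sws=1))
        got = {p.serialize() for p in ps if p.length == 2}
        assert got == {"<(G1+G2-)>", "<(G1+G3+)>", "<(G2-G3+)>", "<(G3+G3+)>"}

    def test_gap_bound_multi_element_patterns(self, table4):
        ps = mine(table4, MiningParams(min_supp=0.5, max_tc=1))
        got = {p.serialize() for p in ps if p.length > 1}
        assert got == {"<(G1+)(G2-)>", "<(G1+)(G3+)>", "<(G2-)(G3+)>", "<(G3+)(G3+)>"}

    def test_unreachable_threshold_yields_nothing(self):
        db = make_db({"p": [(1, ["A+"]), (2, ["B-"])], "q": [(1, ["C+"])]})
        assert len(mine(db, MiningParams(min_supp=1.0))) == 0

    def test_single_sequence_full_support(self):
        db = make_db({"p": [(1, ["A+"]), (2, ["B-"])]})
        got = {p.serialize() for p in mine(db, MiningParams(min_supp=1.0))}
        assert got == {"<(A+)>", "<(B-)>", "<(A+)(B-)>"}

    def test_deterministic_order(self, table4):
        a = [p.serialize() for p in mine(table4, UNCONSTRAINED)]
        b = [p.serialize() for p in mine(table4, UNCONSTRAINED)]
        assert a == b
        lengths = [p.length for p in mine(table4, UNCONSTRAINED)]
        assert lengths == sorted(lengths)

    def test_downward_closure_on_walkthrough(self, table4):
        mine(table4, UNCONSTRAINED).check_downward_closure()

    def test_no_same_transaction_elements_without_window(self, table4):
        # simultaneous items (e.g. G2- and G3+ at one timepoint) must never
        # form one element when the window is closed
        ps = mine(table4, UNCONSTRAINED)
        assert all(p.n_elements == p.length for p in ps)


class TestPatternSupport:
    @pytest.mark.parametrize(
        "text,params,expected",
        [
            ("<(G1+)(G2-)>", MiningParams(0.5), 4),
            ("<(G3+)(G2-)>", MiningParams(0.5, max_tc=1), 1),
            ("<(G1+)>", MiningParams(0.5), 4),
            ("<(G5+)>", MiningParams(0.5), 1),
            ("<(G1+G3+)>", MiningParams(0.5, sws=1), 4),
        ],
    )
    def test_declarative_counts(self, table4, text, params, expected):
        assert pattern_support(table4, parse_pattern(text), params) == expected

    def test_single_item_reduces_to_sequence_count(self, table4):
        for tok in ("G1+", "G2-", "G3+", "G4-"):
            pat = Pattern(((it(tok),),))
            count = sum(
                1 for s in table4 if any(it(tok) in t.items for t in s)
            )
            assert pattern_support(table4, pat, UNCONSTRAINED) == count


class TestMinerProperties:
    """Seeded randomized invariants of the miner against the oracle."""

    def test_equivalence_and_closure_on_random_dbs(self):
        rng = np.random.default_rng(20130924)
        for _ in range(60):
            db = random_db(rng)
            if db.n == 0:
                continue
            params = MiningParams(min_supp=0.5)
            mined = mine(db, params)
            mined.check_downward_closure()
            oracle = brute_force_mine(db, params, max_len=7)
            assert mined.serializations() == oracle.serializations()
            for p in mined:
                assert p.support == oracle.get(p).support

    def test_subset_under_constraints(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            db = random_db(rng)
            if db.n == 0:
                continue
            sws = float(rng.integers(0, 2))
            max_tc = float(rng.integers(max(1, int(sws)), 4))
            params = MiningParams(min_supp=0.5, sws=sws, max_tc=max_tc)
            mined = mine(db, params)
            mined.check_downward_closure()
            oracle = brute_force_mine(db, params, max_len=6)
            assert mined.serializations() <= oracle.serializations()
            for p in mined:
                assert p.support <= oracle.get(p).support

    def test_monotone_in_min_supp_and_max_tc(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            db = random_db(rng)
            if db.n == 0:
                continue
            loose = mine(db, MiningParams(min_supp=0.4)).serializations()
            tight = mine(db, MiningParams(min_supp=0.8)).serializations()
            assert tight <= loose
            narrow = mine(db, MiningParams(min_supp=0.5, max_tc=1)).serializations()
            wide = mine(db, MiningParams(min_supp=0.5, max_tc=3)).serializations()
            free = mine(db, MiningParams(min_supp=0.5)).serializations()
            assert narrow <= wide <= free

    def test_mined_supports_are_sound(self):
        # every reported support must be witnessed by actual embeddings
        rng = np.random.default_rng(4242)
        for _ in range(25):
            db = random_db(rng)
            if db.n == 0:
                continue
            params = MiningParams(min_supp=0.5, sws=float(rng.integers(0, 2)))
            for p in mine(db, params):
                assert pattern_support(db, p, params) >= p.support
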