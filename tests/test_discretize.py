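import io
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ctgrspan.discretize import (
    DiscretizationParams,
    avg_transaction_length,
    discretize,
    filter_timepoint_support,
    fold_change_matrix,
    remove_housekeeping,
    signed_fold_change,
)
from ctgrspan.errors import DomainError, ParameterError
from ctgrspan.sequence_io import SequenceDB, read_sequence_db, write_sequence_db

from .conftest import make_db

# The expected conversion of the toy expression table at threshold 1.5:
# every |signed fold change| >= 1.5 against the first timepoint becomes an
# item, the baseline transaction is never emitted.
TABLE3_TEXT = """\
1\t<(G1+ G2- G3-)2 (G1- G2+ G3-)3 (G1- G2+ G3-)4>
2\t<(G1+ G2+)2 (G2+)3 (G1+ G2- G3+)4>
3\t<(G1- G2+ G3+)2 (G1- G3+)3 (G1- G2- G3+)4>
"""

def round2(v: float) -> float:
    """Half-away-from-zero rounding to 2 decimals, as printed tables use
    (banker's rounding would turn e.g. -2.775 into -2.77, not -2.78)."""
    from decimal import ROUND_HALF_UP, Decimal

    return float(Decimal(repr(v)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# The full signed fold-change matrix of the toy table, rounded to 2 decimals.
EXPECTED_FOLDS = {
    ("1", "G1"): [1.00, 2.63, -2.49, -4.98],
    ("1", "G2"): [1.00, -3.33, 2.33, 2.97],
    ("1", "G3"): [1.00, -2.00, -3.18, -1.50],
    ("2", "G1"): [1.00, 7.72, 1.10, 2.88],
    ("2", "G2"): [1.00, 4.45, 2.67, -2.78],
    ("2", "G3"): [1.00, -1.35, -1.22, 2.45],
    ("3", "G1"): [1.00, -4.13, -5.00, -10.00],
    ("3", "G2"): [1.00, 1.94, 1.30, -6.67],
    ("3", "G3"): [1.00, 3.00, 4.00, 5.00],
}


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "value,baseline,expected",
        [(656, 249, 2.63), (100, 333, -3.33), (250, 500, -2.00), (950, 123, 7.72)],
    )
    def test_printed_cells(self, value, baseline, expected):
        assert round(signed_fold_change(value, baseline), 2) == expected

    def test_baseline_identity(self):
        for b in (0.5, 1, 333, 1e6):
            assert signed_fold_change(b, b) == 1.0

    def test_rejects_non_positive(self):
        with pytest.raises(DomainError):
            signed_fold_change(0, 5)
        with pytest.raises(DomainError):
            signed_fold_change(5, -1)

    @given(
        st.floats(min_value=0.01, max_value=1e4),
        st.floats(min_value=0.01, max_value=1e4),
    )
    def test_antisymmetry_and_magnitude(self, a, b):
        sfc = signed_fold_change(a, b)
        assert abs(sfc) >= 1
        if a != b:
            assert signed_fold_change(b, a) == pytest.approx(-sfc)

    def test_fold_change_matrix_matches_printed_table(self, table1):
        frame = fold_change_matrix(table1)
        for (patient, gene), row in EXPECTED_FOLDS.items():
            got = [round2(v) for v in frame.loc[(patient, gene)]]
            assert got == row, (patient, gene)


class TestDiscretize:
    def test_reproduces_converted_database_exactly(self, table3_db):
        expected = read_sequence_db(io.StringIO(TABLE3_TEXT))
        buf = io.StringIO()
        write_sequence_db(table3_db, buf)
        assert buf.getvalue() == TABLE3_TEXT
        assert table3_db.sequences == expected.sequences

    def test_boundary_cell_kept_by_geq_rule(self, table3_db):
        # patient 1 / G3 at the last timepoint: 333 vs 500 gives -1.5015...,
        # which meets the threshold 1.5 and must be emitted as G3-down
        items = table3_db.sequences[0].transactions[2].items
        assert any(i.token == "G3-" for i in items)

    def test_huge_threshold_gives_empty_db(self, table1):
        db = discretize(table1, DiscretizationParams(fold_threshold=1e9))
        assert db.n == 0
        assert db.n_total == 3  # denominator keeps all patients

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ParameterError):
            DiscretizationParams(fold_threshold=1.0)

    def test_unknown_baseline_rejected(self, table1):
        with pytest.raises(ParameterError):
            discretize(table1, DiscretizationParams(1.5, baseline=99))

    def test_single_timepoint_warns_and_returns_empty(self, caplog):
        from ctgrspan.sequence_io import read_expression_table

        ds = read_expression_table(io.StringIO("p\tg\t1\nA\tX\t5\n"))
        with caplog.at_level("WARNING"):
            db = discretize(ds, DiscretizationParams(1.5))
        assert db.n == 0 and db.n_total == 1
        assert any("single timepoint" in r.message for r in caplog.records)

    def test_items_shrink_as_threshold_grows(self, table1):
        def items(th):
            db = discretize(table1, DiscretizationParams(th))
            return {
                (s.patient_id, t.timestamp, i)
                for s in db
                for t in s
                for i in t.items
            }

        assert items(2.5) <= items(1.5) <= items(1.1)


class TestFilters:
    def test_remove_housekeeping_drops_gene_everywhere(self, table3_db):
        db = remove_housekeeping(table3_db, {"G3"})
        assert all(i.gene != "G3" for s in db for t in s for i in t.items)
        p2 = next(s for s in db if s.patient_id == "2")
        toks = [sorted(i.token for i in t.items) for t in p2]
        assert toks == [["G1+", "G2+"], ["G2+"], ["G1+", "G2-"]]
        assert db.n_total == 3

    def test_remove_housekeeping_identity_and_annihilation(self, table3_db):
        assert remove_housekeeping(table3_db, set()).sequences == table3_db.sequences
        gone = remove_housekeeping(table3_db, {"G1", "G2", "G3"})
        assert gone.n == 0 and gone.n_total == 3

    def test_min_tsupp_removes_constitutive_items(self, table3_db):
        db = filter_timepoint_support(table3_db, 1.0)
        p1 = next(s for s in db if s.patient_id == "1")
        assert all(i.token != "G3-" for t in p1 for i in t.items)
        p3 = next(s for s in db if s.patient_id == "3")
        survivors = {i.token for t in p3 for i in t.items}
        assert "G1-" not in survivors and "G3+" not in survivors
        p2 = next(s for s in db if s.patient_id == "2")
        assert p2.transactions == table3_db.sequences[1].transactions

    def test_min_tsupp_ceiling_boundary(self):
        db = make_db({"p": [(1, ["A+", "B-"]), (2, ["A+"]), (3, ["C+"])]})
        # A+ sits in 2 of 3 transactions: kept at 100%, removed at 2/3
        kept = filter_timepoint_support(db, 1.0)
        assert any(i.token == "A+" for s in kept for t in s for i in t.items)
        gone = filter_timepoint_support(db, 2 / 3)
        assert all(i.token != "A+" for s in gone for t in s for i in t.items)

    def test_min_tsupp_pooled_scope_counts_across_patients(self):
        db = make_db(
            {
                "p": [(1, ["A+"]), (2, ["A+"])],
                "q": [(1, ["A+"]), (2, ["B-"])],
            }
        )
        pooled = filter_timepoint_support(db, 0.75, scope="pooled")
        assert all(i.token != "A+" for s in pooled for t in s for i in t.items)
        per_seq = filter_timepoint_support(db, 0.75, scope="sequence")
        q = next(s for s in per_seq if s.patient_id == "q")
        assert any(i.token == "A+" for t in q for i in t.items)

    def test_min_tsupp_range_checked(self, table3_db):
        for bad in (0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                filter_timepoint_support(table3_db, bad)

    def test_lowering_min_tsupp_never_lengthens_transactions(self, table3_db):
        lengths = [
            avg_transaction_length(filter_timepoint_support(table3_db, f))
            for f in (1.0, 0.9, 0.66, 0.5)
        ]
        assert all(a >= b for a, b in zip(lengths, lengths[1:]))


class TestAvgTransactionLength:
    def test_converted_toy_value(self, table3_db):
        assert avg_transaction_length(table3_db) == pytest.approx(23 / 9)

    def test_single_transaction(self):
        db = make_db({"p": [(1, ["A+", "B-", "C+"])]})
        assert avg_transaction_length(db) == 3

    def test_empty_db(self):
        assert avg_transaction_length(SequenceDB([])) == 0.0
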