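"""Conversion of expression matrices into transactional sequence databases.

The discretization follows the classic signed-fold-change convention: every
value is divided by the patient's baseline reading for that gene; ratios
below one are reported as the negated reciprocal, so the magnitude is always
>= 1 and the sign encodes direction.  A gene whose absolute fold change
meets a threshold becomes a signed item in that timepoint's transaction.

Two pre-mining item filters live here as well:

* a housekeeping-gene list filter, removing well-known maintenance genes;
* a minimum-timepoint-support (minTSupp) filter, removing items that recur
  in so many of a patient's timepoints that they behave like housekeeping
  genes rather than stimulus responses.

Both filters drop transactions (and patients) that become empty, but the
support denominator of the returned database stays at the original patient
count, so pattern supports remain "out of all patients".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError
from .sequence_io import (
    DOWN,
    UP,
    ExpressionDataset,
    Item,
    Sequence,
    SequenceDB,
    Transaction,
)

logger = logging.getLogger(__name__)

# Guards ceil() against floating-point noise in products like 0.95 * 20.
_CEIL_EPS = 1e-9


def _ceil_count(fraction: float, total: int) -> int:
    return math.ceil(fraction * total - _CEIL_EPS)


@dataclass(frozen=True)
class DiscretizationParams:
    """Settings for expression-to-transaction conversion.

    fold_threshold
        Unitless significance bar on |signed fold change|; must exceed 1
        (a threshold <= 1 is degenerate: every cell would pass).
    baseline
        Timepoint label used as the per-patient reference; defaults to the
        earliest timepoint.
    """

    fold_threshold: float
    baseline: float | None = None

    def __post_init__(self):
        if not self.fold_threshold > 1:
            raise ParameterError(
                f"fold_threshold must exceed 1, got {self.fold_threshold}"
            )


def signed_fold_change(value: float, baseline_value: float) -> float:
    """Signed ratio of ``value`` to ``baseline_value``.

    Returns ``value / baseline_value`` when that ratio is >= 1 and
    ``-(baseline_value / value)`` otherwise, so ``|result| >= 1`` always and
    the baseline maps to exactly +1.  Computation uses unrounded values;
     2-decimal rounding is presentation only.
    """
    if not (value > 0 and baseline_value > 0):
        raise DomainError(
            f"signed_fold_change needs positive values, got {value} vs {baseline_value}"
        )
    ratio = value / baseline_value
    if ratio >= 1:
        return ratio
    return -(baseline_value / value)


def fold_change_matrix(
    dataset: ExpressionDataset, baseline: float | None = None
) -> pd.DataFrame:
    """Signed fold changes of every cell against the patient/gene baseline.

    Returns a DataFrame indexed by (patient, gene) with one column per
    timepoint; cells missing either the value or the baseline are NaN.
    The baseline column is exactly +1 wherever present.
    """
    b_idx = _baseline_index(dataset, baseline)
    rows = {}
    for pi, patient in enumerate(dataset.patients):
        for gi, gene in enumerate(dataset.genes):
            base = dataset.values[pi, gi, b_idx]
            out = []
            for ti in range(len(dataset.timepoints)):
                v = dataset.values[pi, gi, ti]
                if math.isnan(v) or math.isnan(base):
                    out.append(math.nan)
                else:
                    out.append(signed_fold_change(v, base))
            rows[(patient, gene)] = out
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(dataset.timepoints))
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["patient", "gene"])
    return frame


def _baseline_index(dataset: ExpressionDataset, baseline: float | None) -> int:
    if baseline is None:
        return 0
    baseline = float(baseline)
    if baseline not in dataset.timepoints:
        raise ParameterError(
            f"baseline timepoint {baseline} not among {dataset.timepoints}"
        )
    return dataset.timepoints.index(baseline)


def discretize(dataset: ExpressionDataset, params: DiscretizationParams) -> SequenceDB:
    """Convert a dataset into a sequence database of signed significant items.

    For each patient and non-baseline timepoint ``t``, gene ``g`` becomes
    item ``g+`` when its signed fold change is >= ``fold_threshold`` and
    ``g-`` when it is <= ``-fold_threshold`` ("exceeding" is implemented as
    ``>=`` on the unrounded value).  The baseline transaction is never
    emitted; empty transactions are dropped; the support denominator is the
    full patient count.
    """
    b_idx = _baseline_index(dataset, params.baseline)
    if len(dataset.timepoints) < 2:
        logger.warning(
            "dataset has a single timepoint; discretization yields an empty database"
        )
        return SequenceDB([], n_total=len(dataset.patients))
    sequences = []
    for pi, patient in enumerate(dataset.patients):
        transactions = []
        for ti, t in enumerate(dataset.timepoints):
            if ti == b_idx:
                continue
            items = []
            for gi, gene in enumerate(dataset.genes):
                v = dataset.values[pi, gi, ti]
                base = dataset.values[pi, gi, b_idx]
                if math.isnan(v) or math.isnan(base):
                    continue
                sfc = signed_fold_change(v, base)
                if sfc >= params.fold_threshold:
                    items.append(Item(gene, UP))
                elif sfc <= -params.fold_threshold:
                    items.append(Item(gene, DOWN))
            if items:
                transactions.append(Transaction(t, items))
        if transactions:
            sequences.append(Sequence(patient, transactions))
    return SequenceDB(sequences, n_total=len(dataset.patients))


def remove_housekeeping(db: SequenceDB, genes: set[str]) -> SequenceDB:
    """Drop every item whose gene appears in the housekeeping list.

    Transactions (and patients) emptied by the removal are dropped, but the
    support denominator keeps the original patient count.
    """
    sequences = []
    for seq in db:
        transactions = [
            Transaction(t.timestamp, [it for it in t.items if it.gene not in genes])
            for t in seq
        ]
        kept = Sequence(seq.patient_id, transactions)
        if len(kept):
            sequences.append(kept)
    return SequenceDB(sequences, n_total=db.n_total)


def filter_timepoint_support(
    db: SequenceDB, min_tsupp: float, scope: str = "sequence"
) -> SequenceDB:
    """Remove housekeeping-like items that recur in too many timepoints.

    With ``scope="sequence"`` (default) each patient is judged against its
    own timepoint count: an item present in at least
    ``ceil(min_tsupp * T_p)`` of that patient's ``T_p`` transactions is
    removed from all of them.  With ``scope="pooled"`` occurrences are
    counted over every transaction of every patient and removal is global.
    """
    if not (0 < min_tsupp <= 1):
        raise ParameterError(f"min_tsupp must lie in (0, 1], got {min_tsupp}")
    if scope not in ("sequence", "pooled"):
        raise ParameterError(f"scope must be 'sequence' or 'pooled', got {scope!r}")

    if scope == "pooled":
        total = sum(len(seq) for seq in db)
        counts: dict[Item, int] = {}
        for seq in db:
            for trans in seq:
                for it in trans.items:
                    counts[it] = counts.get(it, 0) + 1
        cut = _ceil_count(min_tsupp, total) if total else 0
        doomed_by_seq = {
            seq.patient_id: {it for it, c in counts.items() if c >= cut} for seq in db
        }
    else:
        doomed_by_seq = {}
        for seq in db:
            counts = {}
            for trans in seq:
                for it in trans.items:
                    counts[it] = counts.get(it, 0) + 1
            cut = _ceil_count(min_tsupp, len(seq))
            doomed_by_seq[seq.patient_id] = {it for it, c in counts.items() if c >= cut}

    sequences = []
    for seq in db:
        doomed = doomed_by_seq[seq.patient_id]
        transactions = [
            Transaction(t.timestamp, [it for it in t.items if it not in doomed])
            for t in seq
        ]
        kept = Sequence(seq.patient_id, transactions)
        if len(kept):
            sequences.append(kept)
    return SequenceDB(sequences, n_total=db.n_total)


def avg_transaction_length(db: SequenceDB) -> float:
    """Mean number of items per transaction (0 for an empty database)."""
    n_trans = sum(len(seq) for seq in db)
    if n_trans == 0:
        return 0.0
    n_items = sum(len(t) for seq in db for t in seq)
    return n_items / n_trans


def count_items(db: SequenceDB) -> int:
    """Total item occurrences, used by the conversion log to track filters."""
    return int(sum(len(t) for seq in db for t in seq))
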