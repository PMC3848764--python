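"""Independent correctness baselines for the main miner.

Two reference implementations live here:

* :func:`brute_force_mine` — an exhaustive existential-embedding miner.  It
  enumerates candidate patterns over the frequent item alphabet and counts
  each one's support declaratively with
  :func:`~ctgrspan.ctgr_miner.pattern_support`, independent of the
  projection machinery.  It is the oracle in property tests: the main
  miner must match it exactly when SWS = 0 and maxTC is unbounded, and be
  a subset of it under finite constraints.

* :func:`traditional_mine` — a classic unconstrained pattern-growth miner
  whose elements are same-transaction itemsets.  It exists to demonstrate
  what the cross-timepoint restriction removes: on the toy walkthrough
  database it reports patterns like ``<(G1+)(G2-G3+)>`` whose trailing
  element is a simultaneous itemset, which the main miner by design never
  emits.
"""

from __future__ import annotations

from typing import Iterable

from .ctgr_miner import (
    MiningParams,
    Pattern,
    PatternSet,
    pattern_support,
    support_threshold,
)
from .errors import SizeError
from .sequence_io import Item, Sequence, SequenceDB, _item_key

#: Default budget for the exhaustive search guard:
#: sequences x transactions x alphabet size.
DEFAULT_BUDGET = 2000


def _frequent_items(db: SequenceDB, min_supp: float) -> list[tuple[Item, int]]:
    thr = support_threshold(min_supp, db.n_total)
    counts: dict[Item, int] = {}
    for seq in db:
        for it in {it for t in seq for it in t.items}:
            counts[it] = counts.get(it, 0) + 1
    return sorted(
        ((it, c) for it, c in counts.items() if c >= thr), key=lambda x: _item_key(x[0])
    )


def brute_force_mine(
    db: SequenceDB,
    params: MiningParams,
    max_len: int,
    budget: int = DEFAULT_BUDGET,
) -> PatternSet:
    """Exhaustively enumerate frequent patterns up to ``max_len`` items.

    Enumeration grows patterns item by item over the individually frequent
    alphabet (downward closure makes this pruning sound) and scores every
    candidate with the declarative embedding counter.  Guarded against
    large inputs: sequences x transactions x alphabet must stay within
    ``budget``.
    """
    if max_len < 1:
        raise SizeError(f"max_len must be >= 1, got {max_len}")
    n_trans = sum(len(seq) for seq in db)
    alphabet = _frequent_items(db, params.min_supp)
    cost = db.n * n_trans * max(1, len(alphabet))
    if cost > budget:
        raise SizeError(
            f"input too large for exhaustive search ({cost} > budget {budget}); "
            "use the main miner"
        )
    thr = support_threshold(params.min_supp, db.n_total)
    results: list[Pattern] = []

    def grow(pattern: Pattern) -> None:
        results.append(pattern)
        if pattern.length >= max_len:
            return
        modes = ["sequence"] + (["itemset"] if params.sws > 0 else [])
        for mode in modes:
            for it, _ in alphabet:
                elements = list(pattern.elements)
                if mode == "itemset":
                    elements[-1] = elements[-1] + (it,)
                else:
                    elements.append((it,))
                cand = Pattern(tuple(elements))
                supp = pattern_support(db, cand, params)
                if supp >= thr:
                    grow(cand.with_support(supp))

    for it, supp in alphabet:
        grow(Pattern(((it,),), support=supp))
    return PatternSet(results, params, db.n_total)


# ---------------------------------------------------------------------------
# Traditional (same-transaction itemset) pattern growth
# ---------------------------------------------------------------------------


def _contains_itemset_sequence(
    seq: Sequence, elements: tuple[frozenset[Item], ...]
) -> bool:
    """Standard subsequence containment: each element inside one transaction."""

    def rec(ei: int, pos: int) -> bool:
        if ei == len(elements):
            return True
        for p in range(pos, len(seq.transactions)):
            if elements[ei] <= seq.transactions[p].items:
                if rec(ei + 1, p + 1):
                    return True
        return False

    return rec(0, 0)


def _itemset_pattern(elements: Iterable[frozenset[Item]], support: int) -> Pattern:
    return Pattern(
        tuple(tuple(sorted(e, key=_item_key)) for e in elements), support
    )


def traditional_mine(
    db: SequenceDB, min_supp: float, max_len: int = 6, budget: int = DEFAULT_BUDGET
) -> PatternSet:
    """Unconstrained pattern-growth mining with same-transaction itemsets.

    Elements are sets of items drawn from a single transaction; consecutive
    elements come from strictly later transactions.  This is the classic
    sequential-pattern semantics the cross-timepoint miner restricts, and
    its output is a superset of the main miner's singleton-element patterns
    at SWS = 0, maxTC = inf.
    """
    params = MiningParams(min_supp=min_supp)
    n_trans = sum(len(seq) for seq in db)
    alphabet = _frequent_items(db, min_supp)
    cost = db.n * n_trans * max(1, len(alphabet))
    if cost > budget:
        raise SizeError(
            f"input too large for exhaustive search ({cost} > budget {budget})"
        )
    thr = support_threshold(min_supp, db.n_total)
    results: list[Pattern] = []

    def count(elements: tuple[frozenset[Item], ...]) -> int:
        return sum(1 for seq in db if _contains_itemset_sequence(seq, elements))

    def grow(elements: tuple[frozenset[Item], ...], support: int) -> None:
        results.append(_itemset_pattern(elements, support))
        if sum(len(e) for e in elements) >= max_len:
            return
        # itemset extension: only items canonically after the element's
        # maximum keep the enumeration duplicate-free
        last_max = max(_item_key(it) for it in elements[-1])
        for it, _ in alphabet:
            if _item_key(it) <= last_max:
                continue
            cand = elements[:-1] + (elements[-1] | {it},)
            supp = count(cand)
            if supp >= thr:
                grow(cand, supp)
        for it, _ in alphabet:
            cand = elements + (frozenset({it}),)
            supp = count(cand)
            if supp >= thr:
                grow(cand, supp)

    for it, supp in alphabet:
        grow((frozenset({it}),), supp)
    return PatternSet(results, params, db.n_total)


def diff_pattern_sets(
    a: PatternSet, b: PatternSet
) -> tuple[set[str], set[str], list[tuple[str, int, int]]]:
    """Compare two pattern sets over the same database by serialization.

    Returns ``(only_a, only_b, support_disagreements)`` where the last
    entry lists ``(pattern, support_a, support_b)`` for shared patterns
    with unequal supports.
    """
    keys_a, keys_b = a.serializations(), b.serializations()
    only_a = keys_a - keys_b
    only_b = keys_b - keys_a
    disagreements = [
        (k, a.get(k).support, b.get(k).support)
        for k in sorted(keys_a & keys_b)
        if a.get(k).support != b.get(k).support
    ]
    return only_a, only_b, disagreements


def write_diff_report(
    a: PatternSet, b: PatternSet, sink, labels: tuple[str, str] = ("a", "b")
) -> None:
    """Three-section tab-separated diff report of two pattern sets."""
    from .sequence_io import _as_writer

    only_a, only_b, disagreements = diff_pattern_sets(a, b)
    fh, close = _as_writer(sink)
    try:
        fh.write(f"# only_{labels[0]}\n")
        for k in sorted(only_a):
            fh.write(k + "\n")
        fh.write(f"# only_{labels[1]}\n")
        for k in sorted(only_b):
            fh.write(k + "\n")
        fh.write("# support_disagreements\n")
        for k, sa, sb in disagreements:
            fh.write(f"{k}\t{sa}\t{sb}\n")
    finally:
        if close:
            fh.close()
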