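"""Pattern-growth mining of cross-timepoint gene regulation sequential
patterns (CTGR-SPs).

A CTGR-SP is a frequent, time-ordered pattern of signed gene items in which
consecutive items always come from *different* timepoints: items may share
one pattern element (be treated as simultaneous) only when a sliding window
merges nearby timepoints, never because they sat in the same transaction.
This is the defining restriction that keeps every reported pattern readable
as a chain of candidate regulations rather than a frequent itemset.

The miner is a prefix-projection / depth-first pattern-growth search:

1. find frequent length-1 items;
2. for each frequent prefix, build a projected database holding, per
   patient, the postfix that starts right after the *first* admissible
   occurrence of the prefix;
3. scan the projected postfixes once for extension candidates and recurse.

For every postfix and item only the item's first occurrence is considered,
and it is classified by its time gap ``g`` from the current element anchor:
an itemset extension (merged into the element) when ``0 < g <= SWS``, a
sequence extension (new element) when ``SWS < g <= maxTC``, and ignored
otherwise.  Supports count distinct patient sequences.  First-occurrence
projection makes the search fast and equals exhaustive existential mining
when SWS = 0 and maxTC is unbounded; under finite constraints it may miss
embeddings anchored at later occurrences, so its output is then a subset of
the declarative semantics implemented by :func:`pattern_support`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterator, Union

import pandas as pd

from .errors import DomainError, ParameterError, ParseError
from .sequence_io import (
    DOWN,
    UP,
    Item,
    Sequence,
    SequenceDB,
    Source,
    _as_reader,
    _as_writer,
    _item_key,
)

_CEIL_EPS = 1e-9

_PATTERN_ELEMENT_RE = re.compile(r"\(([^()]*)\)")
_ITEM_RE = re.compile(r"([^()+\-<>\s]+)([+-])")


@dataclass(frozen=True)
class MiningParams:
    """Constraint settings for the miner.

    min_supp
        Minimum support as a fraction in (0, 1] of patient sequences.
    sws
        Sliding window size (>= 0) in the study's time units: items whose
        gap from the current element anchor is within the window merge into
        one element, as if simultaneous.
    max_tc
        Maximum time constraint (> 0, possibly ``inf``): the largest
        allowed gap between consecutive pattern elements.
    window_anchor
        Where the element anchor sits while the window slides: ``"first"``
        measures every gap from the element's first item (element span
        <= sws); ``"last"`` measures from the most recently added item.
    """

    min_supp: float
    sws: float = 0.0
    max_tc: float = math.inf
    window_anchor: str = "first"

    def __post_init__(self):
        if not (0 < self.min_supp <= 1):
            raise ParameterError(f"min_supp must lie in (0, 1], got {self.min_supp}")
        if self.sws < 0:
            raise ParameterError(f"sws must be >= 0, got {self.sws}")
        if not self.max_tc > 0:
            raise ParameterError(f"max_tc must be > 0 (or inf), got {self.max_tc}")
        if math.isfinite(self.max_tc) and self.sws > self.max_tc:
            raise ParameterError(
                f"sws ({self.sws}) must not exceed a finite max_tc ({self.max_tc})"
            )
        if self.window_anchor not in ("first", "last"):
            raise ParameterError(
                f"window_anchor must be 'first' or 'last', got {self.window_anchor!r}"
            )


@dataclass(frozen=True)
class Pattern:
    """An ordered list of elements, each an ordered tuple of signed items.

    Item order inside an element is temporal growth order (the order the
    window encountered them), so duplicates such as ``<(G3+G3+)>`` are
    legal when the window is open.  ``support`` counts distinct patient
    sequences containing the pattern.
    """

    elements: tuple[tuple[Item, ...], ...]
    support: int = 0

    def __post_init__(self):
        if not self.elements or any(len(e) == 0 for e in self.elements):
            raise DomainError("pattern elements must be non-empty")

    @property
    def length(self) -> int:
        """Total item count across elements."""
        return sum(len(e) for e in self.elements)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def items_flat(self) -> tuple[Item, ...]:
        return tuple(it for e in self.elements for it in e)

    def genes(self) -> set[str]:
        return {it.gene for it in self.items_flat()}

    def serialize(self) -> str:
        return "<" + "".join("(" + "".join(it.token for it in e) + ")" for e in self.elements) + ">"

    def with_support(self, support: int) -> "Pattern":
        return Pattern(self.elements, support)

    def __repr__(self) -> str:
        return f"Pattern({self.serialize()!r}, support={self.support})"


def parse_pattern(text: str, support: int = 0) -> Pattern:
    """Parse a serialized pattern such as ``<(G1+G2-)(G3+)>``."""
    text = text.strip()
    if not (text.startswith("<") and text.endswith(">")):
        raise ParseError(f"pattern must be wrapped in <...>, got {text!r}")
    inner = text[1:-1]
    elements = []
    covered = ""
    for m in _PATTERN_ELEMENT_RE.finditer(inner):
        covered += m.group(0)
        content = m.group(1)
        toks = list(_ITEM_RE.finditer(content))
        if "".join(t.group(0) for t in toks) != "".join(content.split()):
            raise ParseError(f"malformed item token(s) in ({content})")
        elements.append(
            tuple(Item(t.group(1), UP if t.group(2) == "+" else DOWN) for t in toks)
        )
    if covered != "".join(inner.split()):
        raise ParseError(f"malformed pattern body {inner!r}")
    return Pattern(tuple(elements), support)


def growth_prefix(pattern: Pattern) -> Pattern | None:
    """The pattern minus its last item (None for length-1 patterns)."""
    if pattern.length == 1:
        return None
    elements = list(pattern.elements)
    last = elements[-1][:-1]
    if last:
        elements[-1] = last
    else:
        elements.pop()
    return Pattern(tuple(elements))


@dataclass(frozen=True)
class ProjectedEntry:
    """One patient's postfix inside a projected database.

    ``start`` indexes the first postfix transaction of the patient's
    sequence; ``anchor`` is the timestamp the next gap is measured from
    (the current element's anchor item).  Entries with empty postfixes are
    never stored.
    """

    seq_index: int
    start: int
    anchor: float


class ProjectedDB:
    """A prefix pattern plus the anchored postfix entries that drive growth."""

    __slots__ = ("prefix", "entries", "db", "n_total")

    def __init__(self, prefix: Pattern, entries: list[ProjectedEntry], db: SequenceDB):
        seen = {e.seq_index for e in entries}
        if len(seen) != len(entries):
            raise DomainError("at most one projected entry per sequence")
        for e in entries:
            seq = db.sequences[e.seq_index]
            if e.start >= len(seq.transactions):
                raise DomainError("empty postfixes must not be stored")
            if not e.anchor < seq.transactions[e.start].timestamp:
                raise DomainError("anchor must precede the first postfix transaction")
        self.prefix = prefix
        self.entries = entries
        self.db = db
        self.n_total = db.n_total

    def __len__(self) -> int:
        return len(self.entries)

    def postfix(self, entry: ProjectedEntry):
        return self.db.sequences[entry.seq_index].transactions[entry.start :]


class PatternSet:
    """A deduplicated collection of mined patterns with their supports."""

    def __init__(self, patterns, params: MiningParams, n_total: int):
        ordered = sorted(patterns, key=lambda p: (p.length, p.serialize()))
        self._by_key: dict[str, Pattern] = {}
        for p in ordered:
            key = p.serialize()
            if key in self._by_key:
                raise DomainError(f"duplicate pattern {key}")
            self._by_key[key] = p
        self.params = params
        self.n_total = int(n_total)

    @property
    def patterns(self) -> list[Pattern]:
        return list(self._by_key.values())

    def serializations(self) -> set[str]:
        return set(self._by_key)

    def get(self, key: Union[str, Pattern]) -> Pattern | None:
        if isinstance(key, Pattern):
            key = key.serialize()
        return self._by_key.get(key)

    def __contains__(self, key: Union[str, Pattern]) -> bool:
        return self.get(key) is not None

    def __iter__(self) -> Iterator[Pattern]:
        return iter(self._by_key.values())

    def __len__(self) -> int:
        return len(self._by_key)

    def check_downward_closure(self) -> None:
        """Raise if any pattern's growth-prefix is absent or less supported."""
        for p in self:
            parent = growth_prefix(p)
            if parent is None:
                continue
            got = self.get(parent)
            if got is None:
                raise DomainError(f"growth-prefix of {p.serialize()} missing")
            if got.support < p.support:
                raise DomainError(
                    f"support of {parent.serialize()} ({got.support}) below its "
                    f"extension {p.serialize()} ({p.support})"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pattern": p.serialize(),
                "support_count": p.support,
                "support_fraction": p.support / self.n_total if self.n_total else 0.0,
                "length": p.length,
                "n_elements": p.n_elements,
            }
            for p in self
        ]
        return pd.DataFrame(
            rows, columns=["pattern", "support_count", "support_fraction", "length", "n_elements"]
        )

    def __repr__(self) -> str:
        return f"PatternSet({len(self)} patterns, n_total={self.n_total})"


def write_pattern_table(patterns: PatternSet, sink: Source) -> None:
    """Write a tab-separated pattern table (with a metadata comment line)."""
    fh, close = _as_writer(sink)
    try:
        p = patterns.params
        max_tc = "inf" if math.isinf(p.max_tc) else repr(float(p.max_tc))
        fh.write(
            f"# n_total={patterns.n_total} min_supp={p.min_supp} sws={p.sws} "
            f"max_tc={max_tc} window_anchor={p.window_anchor}\n"
        )
        fh.write("pattern\tsupport_count\tsupport_fraction\tlength\tn_elements\n")
        for pat in patterns:
            frac = pat.support / patterns.n_total if patterns.n_total else 0.0
            fh.write(
                f"{pat.serialize()}\t{pat.support}\t{frac:.6g}\t{pat.length}\t{pat.n_elements}\n"
            )
    finally:
        if close:
            fh.close()


def read_pattern_table(source: Source) -> PatternSet:
    """Read a pattern table written by :func:`write_pattern_table`."""
    fh, close = _as_reader(source)
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    meta = {"n_total": 0, "min_supp": 1.0, "sws": 0.0, "max_tc": math.inf,
            "window_anchor": "first"}
    patterns = []
    for lineno, ln in enumerate(lines, start=1):
        if ln.startswith("#"):
            for tok in ln[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    if k in ("min_supp", "sws", "max_tc"):
                        meta[k] = float(v)
                    elif k == "n_total":
                        meta[k] = int(v)
                    elif k == "window_anchor":
                        meta[k] = v
            continue
        if ln.strip() == "" or ln.startswith("pattern\t"):
            continue
        fields = ln.split("\t")
        if len(fields) < 2:
            raise ParseError("pattern table rows need pattern and support", line=lineno)
        patterns.append(parse_pattern(fields[0], support=int(fields[1])))
    params = MiningParams(
        min_supp=meta["min_supp"], sws=meta["sws"], max_tc=meta["max_tc"],
        window_anchor=meta["window_anchor"],
    )
    n_total = meta["n_total"] or max((p.support for p in patterns), default=0)
    return PatternSet(patterns, params, n_total)


# ---------------------------------------------------------------------------
# Support counting
# ---------------------------------------------------------------------------


def support_threshold(min_supp: float, n: int) -> int:
    """Absolute support bar: ``ceil(min_supp * n)`` distinct sequences.

    Guarded against floating-point noise so e.g. 95% of 20 patients is 19,
    not 20.
    """
    if not (0 < min_supp <= 1):
        raise ParameterError(f"min_supp must lie in (0, 1], got {min_supp}")
    if n < 0:
        raise ParameterError(f"sequence count must be >= 0, got {n}")
    return math.ceil(min_supp * n - _CEIL_EPS)


def length1_patterns(db: SequenceDB, params: MiningParams) -> PatternSet:
    """Frequent single items, each counted once per containing sequence."""
    thr = support_threshold(params.min_supp, db.n_total)
    counts: dict[Item, int] = {}
    for seq in db:
        for it in {it for t in seq for it in t.items}:
            counts[it] = counts.get(it, 0) + 1
    kept = [
        Pattern(((it,),), support=c)
        for it, c in counts.items()
        if c >= thr
    ]
    return PatternSet(kept, params, db.n_total)


# ---------------------------------------------------------------------------
# Projection and growth
# ---------------------------------------------------------------------------


def _first_occurrence(seq: Sequence, item: Item, start: int) -> int | None:
    for idx in range(start, len(seq.transactions)):
        if item in seq.transactions[idx].items:
            return idx
    return None


def project(
    source: Union[SequenceDB, ProjectedDB],
    item: Item,
    params: MiningParams,
    mode: str | None = None,
) -> ProjectedDB:
    """Project a database (or a projected database) on an extension item.

    From the root database the whole sequence is scanned with no gap test
    and the prefix becomes the length-1 pattern of ``item``.  From a
    projected database, the first occurrence of ``item`` in each postfix is
    admissible only if its gap ``g`` from the entry anchor fits the
    requested extension ``mode``: ``0 < g <= sws`` for ``"itemset"``,
    ``sws < g <= max_tc`` for ``"sequence"``.  New entries start at the
    transaction after the occurrence; empty postfixes contribute nothing.
    """
    if isinstance(source, SequenceDB):
        entries = []
        for si, seq in enumerate(source.sequences):
            idx = _first_occurrence(seq, item, 0)
            if idx is None or idx + 1 >= len(seq.transactions):
                continue
            entries.append(
                ProjectedEntry(si, idx + 1, seq.transactions[idx].timestamp)
            )
        return ProjectedDB(Pattern(((item,),)), entries, source)

    if mode not in ("itemset", "sequence"):
        raise ParameterError(
            f"projection from a projected database needs mode 'itemset' or "
            f"'sequence', got {mode!r}"
        )
    db = source.db
    entries = []
    for entry in source.entries:
        seq = db.sequences[entry.seq_index]
        idx = _first_occurrence(seq, item, entry.start)
        if idx is None:
            continue
        t = seq.transactions[idx].timestamp
        gap = t - entry.anchor
        if mode == "itemset":
            admissible = 0 < gap <= params.sws
            anchor = entry.anchor if params.window_anchor == "first" else t
        else:
            admissible = params.sws < gap <= params.max_tc
            anchor = t
        if not admissible or idx + 1 >= len(seq.transactions):
            continue
        entries.append(ProjectedEntry(entry.seq_index, idx + 1, anchor))
    prefix = _extend_pattern(source.prefix, item, mode)
    return ProjectedDB(prefix, entries, db)


def _extend_pattern(prefix: Pattern, item: Item, mode: str, support: int = 0) -> Pattern:
    elements = list(prefix.elements)
    if mode == "itemset":
        elements[-1] = elements[-1] + (item,)
    else:
        elements.append((item,))
    return Pattern(tuple(elements), support)


def candidate_extensions(
    projdb: ProjectedDB, params: MiningParams
) -> dict[str, dict[Item, int]]:
    """Frequent extension candidates of a projected database, by class.

    Each entry contributes at most one occurrence per item — its first in
    the postfix — classified by the gap ``g`` from the entry anchor:
    itemset extension when ``0 < g <= sws``, sequence extension when
    ``sws < g <= max_tc``, ignored beyond ``max_tc``.  Only candidates
    whose sequence count meets the support threshold are returned.
    """
    thr = support_threshold(params.min_supp, projdb.n_total)
    counts: dict[str, dict[Item, int]] = {"itemset": {}, "sequence": {}}
    for entry in projdb.entries:
        seq = projdb.db.sequences[entry.seq_index]
        seen: set[Item] = set()
        for trans in seq.transactions[entry.start :]:
            gap = trans.timestamp - entry.anchor
            for it in trans.items:
                if it in seen:
                    continue
                seen.add(it)
                if gap <= 0:
                    continue
                if gap <= params.sws:
                    cls = "itemset"
                elif gap <= params.max_tc:
                    cls = "sequence"
                else:
                    continue
                counts[cls][it] = counts[cls].get(it, 0) + 1
    return {
        cls: {it: c for it, c in by_item.items() if c >= thr}
        for cls, by_item in counts.items()
    }


def mine(db: SequenceDB, params: MiningParams) -> PatternSet:
    """Mine all CTGR-SPs of a database under the given constraints.

    Returns the frequent length-1 patterns plus every pattern reachable by
    recursive first-occurrence projection whose support meets the
    threshold, in deterministic order (by length, then serialization).
    """
    results: list[Pattern] = []
    l1 = length1_patterns(db, params)
    for pat in sorted(l1, key=lambda p: _item_key(p.elements[0][0])):
        results.append(pat)
        projdb = project(db, pat.elements[0][0], params)
        if projdb.entries:
            _grow(pat, projdb, params, results)
    return PatternSet(results, params, db.n_total)


def _grow(
    prefix: Pattern, projdb: ProjectedDB, params: MiningParams, out: list[Pattern]
) -> None:
    cands = candidate_extensions(projdb, params)
    for mode in ("itemset", "sequence"):
        for item in sorted(cands[mode], key=_item_key):
            support = cands[mode][item]
            newpat = _extend_pattern(prefix, item, mode, support)
            out.append(newpat)
            newproj = project(projdb, item, params, mode)
            if newproj.entries:
                _grow(newpat, newproj, params, out)


# ---------------------------------------------------------------------------
# Declarative containment (used by tests and the brute-force oracle)
# ---------------------------------------------------------------------------


def sequence_contains(seq: Sequence, pattern: Pattern, params: MiningParams) -> bool:
    """Existential embedding check of a pattern in one sequence.

    An embedding assigns every pattern item to a transaction such that
    within an element the items come from strictly later, distinct
    transactions all within the window of the element anchor, and the
    anchor-to-anchor gap of consecutive elements lies in ``(sws, max_tc]``.
    Same-transaction co-occurrence is never an embedding: elements arise
    only through the window.
    """
    trans = seq.transactions
    sws, max_tc = params.sws, params.max_tc
    last_anchor = params.window_anchor == "last"

    def match_element(ei: int, pos: int, prev_anchor: float | None) -> bool:
        if ei == len(pattern.elements):
            return True
        element = pattern.elements[ei]
        for p0 in range(pos, len(trans)):
            t0 = trans[p0].timestamp
            if prev_anchor is not None:
                gap = t0 - prev_anchor
                if gap <= sws:
                    continue
                if gap > max_tc:
                    break
            if element[0] not in trans[p0].items:
                continue
            if match_rest(element, 1, p0 + 1, t0, t0, ei):
                return True
        return False

    def match_rest(
        element: tuple[Item, ...],
        k: int,
        pos: int,
        window_ref: float,
        anchor: float,
        ei: int,
    ) -> bool:
        if k == len(element):
            next_anchor = anchor if not last_anchor else window_ref
            return match_element(ei + 1, pos, next_anchor)
        for p in range(pos, len(trans)):
            t = trans[p].timestamp
            if t - window_ref > sws:
                break
            if element[k] in trans[p].items:
                ref = t if last_anchor else window_ref
                if match_rest(element, k + 1, p + 1, ref, anchor, ei):
                    return True
        return False

    return match_element(0, 0, None)


def pattern_support(db: SequenceDB, pattern: Pattern, params: MiningParams) -> int:
    """Number of sequences containing at least one embedding of the pattern."""
    return sum(1 for seq in db if sequence_contains(seq, pattern, params))
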