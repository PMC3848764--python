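"""Readers, writers and in-memory containers for expression tables and
transactional sequence databases.

Two text dialects are defined here:

* **Wide expression tables** — tab-separated, one row per (patient, gene),
  one column per numeric timepoint::

      patient  gene  1      2      3      4
      1        G1    249    656    100    50

* **Sequence databases** — one line per patient, each transaction written
  as a parenthesised set of signed gene items followed by its timestamp::

      2   <(G1+ G4-)1 (G3+)2 (G2- G3+)4 (G5+)5>

An item token is a gene symbol immediately followed by ``+`` (up-regulated)
or ``-`` (down-regulated).  Gene symbols may not contain whitespace or any
of the reserved characters ``( ) + - < >``; such genes are rejected rather
than escaped.

Timestamps are real numbers taken from the column labels (days, weeks, or
plain indices), not positional ranks, so non-uniformly spaced designs keep
their true gaps.
"""

from __future__ import annotations

import io
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence as TSequence, TextIO, Union

import numpy as np

from .errors import (
    DomainError,
    DuplicateRecordError,
    FixtureLookupError,
    FormatError,
    ParseError,
)

logger = logging.getLogger(__name__)

Source = Union[str, Path, TextIO]

_GENE_RE = re.compile(r"^[^()+\-<>\s]+$")
_ITEM_RE = re.compile(r"([^()+\-<>\s]+)([+-])")
_MISSING = {"", "NA", "NaN", "nan", "na"}

UP = "up"
DOWN = "down"


def _fmt_num(x: float) -> str:
    """Render a number without trailing zeros; integers without a dot."""
    if math.isfinite(x) and float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def _as_reader(source: Source) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def _as_writer(sink: Source) -> tuple[TextIO, bool]:
    if isinstance(sink, (str, Path)):
        return open(sink, "w", encoding="utf-8"), True
    return sink, False


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Item:
    """A signed gene item: a gene symbol plus a regulation direction."""

    gene: str
    direction: str  # "up" or "down"

    def __post_init__(self):
        if not _GENE_RE.match(self.gene):
            raise DomainError(
                f"invalid gene symbol {self.gene!r}: must be non-empty and free of "
                "whitespace and the reserved characters ( ) + - < >"
            )
        if self.direction not in (UP, DOWN):
            raise DomainError(f"direction must be 'up' or 'down', got {self.direction!r}")

    @property
    def sign(self) -> str:
        return "+" if self.direction == UP else "-"

    @property
    def token(self) -> str:
        return self.gene + self.sign

    @classmethod
    def from_token(cls, token: str) -> "Item":
        m = _ITEM_RE.fullmatch(token)
        if m is None:
            raise DomainError(f"malformed item token {token!r}")
        return cls(m.group(1), UP if m.group(2) == "+" else DOWN)

    def __repr__(self) -> str:  # compact: Item('G1+')
        return f"Item({self.token!r})"


def _item_key(item: Item) -> tuple[str, int]:
    """Canonical ordering: gene lexicographic, '+' before '-'."""
    return (item.gene, 0 if item.direction == UP else 1)


class Transaction:
    """The set of significant items of one patient at one timepoint."""

    __slots__ = ("timestamp", "items")

    def __init__(self, timestamp: float, items: Iterable[Item]):
        timestamp = float(timestamp)
        if not math.isfinite(timestamp):
            raise DomainError(f"transaction timestamp must be finite, got {timestamp}")
        items = frozenset(items)
        genes = [it.gene for it in items]
        if len(set(genes)) != len(genes):
            dup = sorted({g for g in genes if genes.count(g) > 1})
            raise DuplicateRecordError(
                f"gene(s) {dup} carry more than one direction in the transaction "
                f"at time {_fmt_num(timestamp)}"
            )
        self.timestamp = timestamp
        self.items = items

    def sorted_items(self) -> list[Item]:
        return sorted(self.items, key=_item_key)

    def __len__(self) -> int:
        return len(self.items)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Transaction)
            and self.timestamp == other.timestamp
            and self.items == other.items
        )

    def __hash__(self) -> int:
        return hash((self.timestamp, self.items))

    def __repr__(self) -> str:
        toks = " ".join(it.token for it in self.sorted_items())
        return f"({toks}){_fmt_num(self.timestamp)}"


class Sequence:
    """One patient's time-ordered list of non-empty transactions."""

    __slots__ = ("patient_id", "transactions")

    def __init__(self, patient_id: str, transactions: Iterable[Transaction]):
        transactions = tuple(t for t in transactions if len(t) > 0)
        times = [t.timestamp for t in transactions]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DomainError(
                f"timestamps of patient {patient_id!r} must strictly increase: {times}"
            )
        self.patient_id = str(patient_id)
        self.transactions = transactions

    def __len__(self) -> int:
        return len(self.transactions)

    def __iter__(self) -> Iterator[Transaction]:
        return iter(self.transactions)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Sequence)
            and self.patient_id == other.patient_id
            and self.transactions == other.transactions
        )

    def __hash__(self) -> int:
        return hash((self.patient_id, self.transactions))

    def __repr__(self) -> str:
        return f"{self.patient_id}\t<{' '.join(repr(t) for t in self.transactions)}>"


class SequenceDB:
    """A transactional sequence database: one :class:`Sequence` per patient.

    ``n_total`` is the support denominator.  It defaults to the number of
    stored sequences but may be larger when filters dropped patients whose
    sequences became empty: supports stay expressed "out of all patients".
    """

    __slots__ = ("sequences", "n_total")

    def __init__(self, sequences: Iterable[Sequence], n_total: int | None = None):
        sequences = list(sequences)
        ids = [s.patient_id for s in sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateRecordError(f"duplicate patient id(s): {dup}")
        self.sequences = sequences
        self.n_total = len(sequences) if n_total is None else int(n_total)
        if self.n_total < len(sequences):
            raise DomainError("n_total cannot be smaller than the number of sequences")

    @property
    def n(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.sequences)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SequenceDB)
            and self.sequences == other.sequences
            and self.n_total == other.n_total
        )

    def item_alphabet(self) -> list[Item]:
        """All distinct items, in canonical order."""
        items = {it for s in self for t in s for it in t.items}
        return sorted(items, key=_item_key)

    def __repr__(self) -> str:
        return f"SequenceDB(n={self.n}, n_total={self.n_total})"


class ExpressionDataset:
    """Patients x genes x ordered numeric timepoints of expression values.

    Values are positive real intensities; missing cells are ``NaN`` and
    simply yield no item downstream.
    """

    __slots__ = ("patients", "genes", "timepoints", "values")

    def __init__(
        self,
        patients: TSequence[str],
        genes: TSequence[str],
        timepoints: TSequence[float],
        values: np.ndarray,
    ):
        self.patients = tuple(str(p) for p in patients)
        self.genes = tuple(str(g) for g in genes)
        self.timepoints = tuple(float(t) for t in timepoints)
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise DomainError(f"timepoints must strictly increase: {self.timepoints}")
        values = np.asarray(values, dtype=float)
        expected = (len(self.patients), len(self.genes), len(self.timepoints))
        if values.shape != expected:
            raise DomainError(f"values shape {values.shape} != {expected}")
        bad = np.argwhere(~np.isnan(values) & (values <= 0))
        if bad.size:
            p, g, t = bad[0]
            raise DomainError(
                f"expression value must be positive: patient {self.patients[p]!r}, "
                f"gene {self.genes[g]!r}, timepoint {_fmt_num(self.timepoints[t])} "
                f"has {values[p, g, t]}"
            )
        self.values = values

    def value(self, patient: str, gene: str, timepoint: float) -> float:
        """The cell value (NaN if missing)."""
        return float(
            self.values[
                self.patients.index(str(patient)),
                self.genes.index(str(gene)),
                self.timepoints.index(float(timepoint)),
            ]
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionDataset)
            and self.patients == other.patients
            and self.genes == other.genes
            and self.timepoints == other.timepoints
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    def __repr__(self) -> str:
        return (
            f"ExpressionDataset({len(self.patients)} patients x "
            f"{len(self.genes)} genes x {len(self.timepoints)} timepoints)"
        )


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def read_expression_table(source: Source) -> ExpressionDataset:
    """Read a wide tab-separated expression table.

    The header names a patient-id column, a gene column, and numeric
    timepoint columns; body cells are positive numbers or a missing marker
    (empty or ``NA``).  Axes keep first-appearance order.
    """
    fh, close = _as_reader(source)
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise FormatError("expression table is empty (no header row)")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError("header must name patient, gene and timepoint columns")
    tp_labels = header[2:]
    timepoints: list[float] = []
    for lab in tp_labels:
        try:
            timepoints.append(float(lab))
        except ValueError:
            raise FormatError(f"non-numeric timepoint column header {lab!r}") from None

    patients: list[str] = []
    genes: list[str] = []
    rows: dict[tuple[str, str], list[float]] = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"expected {len(header)} tab-separated fields, found {len(fields)}",
                line=lineno,
            )
        patient, gene = fields[0].strip(), fields[1].strip()
        key = (patient, gene)
        if key in rows:
            raise DuplicateRecordError(
                f"line {lineno}: duplicate row for patient {patient!r}, gene {gene!r}"
            )
        vals: list[float] = []
        for lab, cell in zip(tp_labels, fields[2:]):
            cell = cell.strip()
            if cell in _MISSING:
                vals.append(math.nan)
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(f"non-numeric cell {cell!r}", line=lineno) from None
            if v <= 0:
                raise DomainError(
                    f"line {lineno}: non-positive expression value {v} for patient "
                    f"{patient!r}, gene {gene!r}, timepoint {lab}"
                )
            vals.append(v)
        rows[key] = vals
        if patient not in patients:
            patients.append(patient)
        if gene not in genes:
            genes.append(gene)

    values = np.full((len(patients), len(genes), len(timepoints)), math.nan)
    for (patient, gene), vals in rows.items():
        values[patients.index(patient), genes.index(gene), :] = vals
    return ExpressionDataset(patients, genes, timepoints, values)


def write_expression_table(dataset: ExpressionDataset, sink: Source) -> None:
    """Emit the same wide dialect read by :func:`read_expression_table`."""
    fh, close = _as_writer(sink)
    try:
        fh.write("patient\tgene\t" + "\t".join(_fmt_num(t) for t in dataset.timepoints) + "\n")
        for pi, patient in enumerate(dataset.patients):
            for gi, gene in enumerate(dataset.genes):
                cells = [
                    "NA" if math.isnan(v) else _fmt_num(v)
                    for v in dataset.values[pi, gi, :]
                ]
                fh.write("\t".join([patient, gene] + cells) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Sequence databases
# ---------------------------------------------------------------------------


def _parse_sequence_body(body: str, lineno: int, patient_id: str) -> Sequence:
    body = body.strip()
    if not (body.startswith("<") and body.endswith(">")):
        raise ParseError(f"sequence must be wrapped in <...>, got {body!r}", line=lineno)
    inner = body[1:-1].strip()
    transactions: list[Transaction] = []
    pos = 0
    while pos < len(inner):
        if inner[pos].isspace():
            pos += 1
            continue
        if inner[pos] != "(":
            raise ParseError(f"expected '(' at position {pos} in {inner!r}", line=lineno)
        end = inner.find(")", pos)
        if end < 0:
            raise ParseError("unbalanced parenthesis", line=lineno)
        content = inner[pos + 1 : end]
        pos = end + 1
        start = pos
        while pos < len(inner) and not inner[pos].isspace() and inner[pos] != "(":
            pos += 1
        ts_token = inner[start:pos]
        if not ts_token:
            raise ParseError("transaction missing its timestamp", line=lineno)
        try:
            timestamp = float(ts_token)
        except ValueError:
            raise ParseError(f"malformed timestamp token {ts_token!r}", line=lineno) from None
        matches = list(_ITEM_RE.finditer(content))
        covered = "".join(m.group(0) for m in matches)
        if covered != "".join(content.split()):
            raise ParseError(f"malformed item token(s) in ({content})", line=lineno)
        items = [Item(m.group(1), UP if m.group(2) == "+" else DOWN) for m in matches]
        if len(set(items)) != len(items):
            raise DuplicateRecordError(
                f"line {lineno}: duplicate item within transaction ({content})"
            )
        try:
            transactions.append(Transaction(timestamp, items))
        except DuplicateRecordError as exc:
            raise DuplicateRecordError(f"line {lineno}: {exc}") from None
    try:
        return Sequence(patient_id, transactions)
    except DomainError as exc:
        raise ParseError(str(exc), line=lineno) from None


def read_sequence_db(source: Source) -> SequenceDB:
    """Read a sequence database, one ``patient<TAB><(items)ts ...>`` line each."""
    fh, close = _as_reader(source)
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    sequences = []
    for lineno, ln in enumerate(lines, start=1):
        if ln.strip() == "" or ln.lstrip().startswith("#"):
            continue
        if "\t" not in ln:
            raise ParseError("expected 'patient_id<TAB><sequence>'", line=lineno)
        patient_id, body = ln.split("\t", 1)
        sequences.append(_parse_sequence_body(body, lineno, patient_id.strip()))
    return SequenceDB(sequences)


def write_sequence_db(db: SequenceDB, sink: Source) -> None:
    """Write a sequence database in the line dialect of :func:`read_sequence_db`.

    Items within a transaction are serialized in canonical order (gene
    lexicographic, ``+`` before ``-``); timestamps carry no trailing zeros.
    """
    fh, close = _as_writer(sink)
    try:
        for seq in db:
            parts = []
            for trans in seq:
                toks = " ".join(it.token for it in trans.sorted_items())
                parts.append(f"({toks}){_fmt_num(trans.timestamp)}")
            fh.write(f"{seq.patient_id}\t<{' '.join(parts)}>\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Gene lists and gene sets
# ---------------------------------------------------------------------------


def read_gene_list(source: Source) -> set[str]:
    """Read a plain-text gene list (one symbol per line, ``#`` comments)."""
    fh, close = _as_reader(source)
    try:
        genes = set()
        for ln in fh.read().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            genes.add(ln)
        return genes
    finally:
        if close:
            fh.close()


def read_gene_sets(source: Source) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name, description, members per line.

    Duplicate set names keep the last definition and log a warning.
    """
    fh, close = _as_reader(source)
    try:
        sets: dict[str, set[str]] = {}
        for lineno, ln in enumerate(fh.read().splitlines(), start=1):
            if ln.strip() == "":
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line needs name, description and >=1 gene, got {len(fields)} fields",
                    line=lineno,
                )
            name = fields[0].strip()
            members = {g.strip() for g in fields[2:] if g.strip()}
            if name in sets:
                logger.warning("duplicate gene-set name %r: keeping the later definition", name)
            sets[name] = members
        return sets
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Bundled toy fixtures
# ---------------------------------------------------------------------------

# A 3-patient, 3-gene, 4-timepoint microarray toy (1-day fixed interval).
_TABLE1_TEXT = """\
patient\tgene\t1\t2\t3\t4
1\tG1\t249\t656\t100\t50
1\tG2\t333\t100\t777\t989
1\tG3\t500\t250\t157\t333
2\tG1\t123\t950\t135\t354
2\tG2\t222\t987\t592\t80
2\tG3\t300\t222\t246\t735
3\tG1\t500\t121\t100\t50
3\tG2\t400\t777\t520\t60
3\tG3\t100\t300\t400\t500
"""

# A 4-patient transactional toy database used by the mining walkthroughs.
_TABLE4_TEXT = """\
1\t<(G1+)1 (G2- G3+)2 (G3+)3>
2\t<(G1+ G4-)1 (G3+)2 (G2- G3+)4 (G5+)5>
3\t<(G8-)1 (G1+ G2-)2 (G2- G3+)3>
4\t<(G7+)1 (G1+ G3+ G6-)2 (G2- G3+)3>
"""

_FIXTURES = {"table1": _TABLE1_TEXT, "table4": _TABLE4_TEXT}


def load_fixture(name: str) -> ExpressionDataset | SequenceDB:
    """Return a bundled toy dataset.

    ``"table1"`` is the raw expression toy (:class:`ExpressionDataset`);
    ``"table4"`` is the transactional toy (:class:`SequenceDB`).
    """
    if name not in _FIXTURES:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    text = _FIXTURES[name]
    if name == "table1":
        return read_expression_table(io.StringIO(text))
    return read_sequence_db(io.StringIO(text))
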