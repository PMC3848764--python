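"""Pattern-set summaries, parameter sweeps and flat gene-set enrichment.

The characteristics table mirrors the row structure used when tuning the
miner: pattern counts, maximal pattern length, how many patterns reach it,
and the distinct genes / ordered gene pairs carried by the longest
patterns.  Sweeps vary one mining parameter at a time, holding the others
fixed, which is how sensible defaults are located in practice.

Enrichment here is deliberately flat: user-supplied gene sets (GMT) are
scored with an upper-tail hypergeometric test against a stated universe.
Ontology structure (term propagation over a DAG) is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence as TSequence

import pandas as pd
from scipy import stats

from .ctgr_miner import MiningParams, Pattern, PatternSet, mine
from .discretize import filter_timepoint_support as _filter_timepoint_support
from .errors import ParameterError
from .sequence_io import SequenceDB

#: Row labels of the characteristics table, in presentation order.
CHARACTERISTIC_ROWS = [
    "# of CTGR-SPs",
    "# of longest CTGR-SPs",
    "Maximal length of CTGR-SPs",
    "# of genes in CTGR-SPs",
    "# of genes in longest CTGR-SPs",
    "# of gene pairs in longest CTGR-SPs",
]


@dataclass(frozen=True)
class Characteristics:
    """Summary statistics of one mining run."""

    n_patterns: int
    n_longest: int
    max_length: int
    n_genes: int
    n_genes_longest: int
    n_gene_pairs_longest: int

    def as_series(self) -> pd.Series:
        return pd.Series(
            [
                self.n_patterns,
                self.n_longest,
                self.max_length,
                self.n_genes,
                self.n_genes_longest,
                self.n_gene_pairs_longest,
            ],
            index=CHARACTERISTIC_ROWS,
        )


def _gene_pairs(pattern: Pattern, mode: str) -> set[tuple]:
    """Ordered gene pairs with temporal precedence inside one pattern.

    ``mode="ordered"`` ignores directions and pairs every earlier item with
    every later one; ``"directed"`` keeps directions; ``"consecutive"``
    pairs only adjacent items.  All modes use the flat temporal item order.
    """
    flat = pattern.items_flat()
    pairs: set[tuple] = set()
    if mode == "consecutive":
        idx_pairs = [(i, i + 1) for i in range(len(flat) - 1)]
    else:
        idx_pairs = [(i, j) for i in range(len(flat)) for j in range(i + 1, len(flat))]
    for i, j in idx_pairs:
        if mode == "directed":
            pairs.add((flat[i].token, flat[j].token))
        else:
            pairs.add((flat[i].gene, flat[j].gene))
    return pairs


def characterize(
    patterns: PatternSet,
    include_length1: bool = True,
    pair_mode: str = "ordered",
) -> Characteristics:
    """Summarize a pattern set with the standard characteristics rows.

    The "longest" statistics consider only longest patterns with at least
    two items, so a run whose maximal length is 1 reports zero genes and
    zero gene pairs there.  Gene pairs are distinct ordered
    (earlier, later) pairs within each longest pattern, deduplicated
    across patterns; see :func:`_gene_pairs` for the selectable counting
    modes (the default ignores item directions).
    """
    if pair_mode not in ("ordered", "directed", "consecutive"):
        raise ParameterError(f"unknown pair_mode {pair_mode!r}")
    pats = [p for p in patterns if include_length1 or p.length > 1]
    if not pats:
        return Characteristics(0, 0, 0, 0, 0, 0)
    max_length = max(p.length for p in pats)
    longest = [p for p in pats if p.length == max_length and p.length >= 2]
    genes = set().union(*(p.genes() for p in pats))
    genes_longest = set().union(*(p.genes() for p in longest)) if longest else set()
    pairs: set[tuple] = set()
    for p in longest:
        pairs |= _gene_pairs(p, pair_mode)
    return Characteristics(
        n_patterns=len(pats),
        n_longest=len([p for p in pats if p.length == max_length]),
        max_length=max_length,
        n_genes=len(genes),
        n_genes_longest=len(genes_longest),
        n_gene_pairs_longest=len(pairs),
    )


_SWEEPABLE = ("min_supp", "min_tsupp", "sws", "max_tc")


def sweep(
    db: SequenceDB,
    vary: str,
    values: TSequence[float],
    fixed: MiningParams,
    min_tsupp_scope: str = "sequence",
    include_length1: bool = True,
) -> pd.DataFrame:
    """Characteristics of one mine run per value of a single parameter.

    ``vary`` names one of ``min_supp``, ``min_tsupp``, ``sws`` or
    ``max_tc``; the other mining parameters come from ``fixed``.  Returns
    a table with one column per grid value and the characteristics rows.
    All values are validated before any mining starts.
    """
    if vary not in _SWEEPABLE:
        raise ParameterError(f"vary must be one of {_SWEEPABLE}, got {vary!r}")
    if len(values) == 0:
        raise ParameterError("parameter grid is empty")
    grids: list[MiningParams] = []
    for v in values:
        if vary == "min_tsupp":
            if not (0 < v <= 1):
                raise ParameterError(f"min_tsupp grid value {v} outside (0, 1]")
            grids.append(fixed)
        else:
            grids.append(
                MiningParams(
                    min_supp=v if vary == "min_supp" else fixed.min_supp,
                    sws=v if vary == "sws" else fixed.sws,
                    max_tc=v if vary == "max_tc" else fixed.max_tc,
                    window_anchor=fixed.window_anchor,
                )
            )
    columns = {}
    for v, params in zip(values, grids):
        run_db = (
            _filter_timepoint_support(db, v, scope=min_tsupp_scope)
            if vary == "min_tsupp"
            else db
        )
        chars = characterize(mine(run_db, params), include_length1=include_length1)
        label = "inf" if isinstance(v, float) and math.isinf(v) else v
        columns[label] = chars.as_series()
    return pd.DataFrame(columns)


# ---------------------------------------------------------------------------
# Flat gene-set enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail hypergeometric enrichment of one gene set."""

    set_name: str
    universe_size: int
    set_size: int
    query_size: int
    overlap: int
    p_value: float
    neg_log10_p: float
    adj_p_value: float | None = None


def enrich(
    query_genes: set[str],
    gene_sets: Mapping[str, set[str]],
    universe: set[str],
    correction: str = "none",
) -> list[EnrichmentResult]:
    """Score a gene list against flat gene sets by hypergeometric tail.

    For each set the p-value is ``P(X >= overlap)`` where X counts query
    genes drawn without replacement from the universe that land in the set
    (sets are intersected with the universe first).  Results are sorted by
    p ascending.  ``correction="bh"`` adds Benjamini-Hochberg adjusted
    p-values; the raw values are reported either way.
    """
    if not universe:
        raise ParameterError("universe must be non-empty")
    if not query_genes <= universe:
        missing = sorted(query_genes - universe)[:5]
        raise ParameterError(f"query genes outside the universe, e.g. {missing}")
    if correction not in ("none", "bh"):
        raise ParameterError(f"correction must be 'none' or 'bh', got {correction!r}")
    M, N = len(universe), len(query_genes)
    results = []
    for name, members in gene_sets.items():
        members = members & universe
        K = len(members)
        k = len(members & query_genes)
        # P(X >= k); survival function at k-1
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        p = min(max(p, 0.0), 1.0)
        neg = -math.log10(p) if p > 0 else math.inf
        results.append(
            EnrichmentResult(
                set_name=name,
                universe_size=M,
                set_size=K,
                query_size=N,
                overlap=k,
                p_value=p,
                neg_log10_p=neg,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_name))
    if correction == "bh":
        m = len(results)
        adj = [None] * m
        running = 1.0
        for rank in range(m, 0, -1):
            r = results[rank - 1]
            running = min(running, r.p_value * m / rank)
            adj[rank - 1] = running
        results = [
            EnrichmentResult(
                r.set_name, r.universe_size, r.set_size, r.query_size,
                r.overlap, r.p_value, r.neg_log10_p, adj_p_value=a,
            )
            for r, a in zip(results, adj)
        ]
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = [
        "set_name", "universe_size", "set_size", "query_size",
        "overlap", "p_value", "neg_log10_p",
    ]
    if results and results[0].adj_p_value is not None:
        cols.append("adj_p_value")
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)
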