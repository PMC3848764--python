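# ctgrspan

Constrained sequential-pattern mining of **cross-timepoint gene regulation**
from time-course gene-expression data.

## The problem

Repeated-measures expression studies — e.g. a cohort of patients profiled at
ten timepoints during an infection or a drug treatment — yield, per patient,
a gene × timepoint matrix. Differential-expression analysis says *which*
genes respond at *which* time, but not whether responses follow each other:
"G1 goes up, and some timepoints later G3 goes up" is a candidate regulation
that only a sequential view across patients can surface.

The classic route is to discretize each patient's time course into a
*sequence* of *transactions* (the significantly up/down-regulated gene items
at each timepoint) and mine frequent sequential patterns. On expression
data this breaks down: each transaction holds hundreds to thousands of
items, so classic miners (GSP/PrefixSpan-style) drown in patterns built from
*simultaneous* items — frequent itemsets that say nothing about regulation
over time, and that blow up the search space.

`ctgrspan` mines only **cross-timepoint** patterns: consecutive pattern
items must come from different timepoints. Items may share one pattern
element (be treated as simultaneous) only when an explicit sliding window
merges nearby timepoints — never because they sat in the same transaction.

## Model and parameters

For patient *p* with baseline reading *b* and later reading *v* of a gene,
the **signed fold change** is

    sfc = v / b        if v / b >= 1
    sfc = -(b / v)     otherwise

so |sfc| ≥ 1 and the sign encodes direction. A gene with |sfc| ≥ the
**fold-change threshold** becomes a signed item (`G1+` / `G1-`) in that
timepoint's transaction. Mining is a prefix-projection pattern-growth
search governed by four parameters:

| parameter  | meaning                                                           | units |
|------------|-------------------------------------------------------------------|-------|
| `minSupp`  | minimum fraction of patient sequences containing a pattern        | fraction / percent |
| `minTSupp` | per-patient timepoint recurrence above which an item is treated as housekeeping-like and removed before mining | fraction / percent |
| `SWS`      | sliding window: items within this gap of the element anchor merge into one element | time units |
| `maxTC`    | maximum gap between consecutive pattern elements                  | time units |

Supports use `ceil(minSupp × n)` distinct sequences. The package also
ships a declarative brute-force miner (the correctness oracle), a classic
same-transaction pattern-growth miner (to demonstrate what the restriction
removes), characteristics/sweep reports, flat (GMT) hypergeometric gene-set
enrichment, and a seeded synthetic-cohort generator with planted, lagged
regulation cascades.

## Worked example

The bundled toy fixtures (`load_fixture("table1")`, a 3-patient expression
matrix, and `load_fixture("table4")`, a 4-patient transactional database)
drive the whole pipeline. Converting the expression toy at threshold 1.5:

```sh
$ ctgrspan convert --input table1.tsv --fold-threshold 1.5 --output converted.db
INFO ctgrspan: converted: 3 patients, 9 transactions, 23 items (N)
$ cat converted.db
1	<(G1+ G2- G3-)2 (G1- G2+ G3-)3 (G1- G2+ G3-)4>
2	<(G1+ G2+)2 (G2+)3 (G1+ G2- G3+)4>
3	<(G1- G2+ G3+)2 (G1- G3+)3 (G1- G2- G3+)4>
```

Patient 1's reading of G1 rises from 249 to 656 (sfc +2.63 ≥ 1.5 → `G1+` at
timepoint 2); the baseline timepoint never emits a transaction. Mining the
transactional toy at 50% support with no window and no gap bound:

```sh
$ ctgrspan mine --db table4.db --min-supp 50 --sws 0 --max-tc inf --output patterns.tsv
$ cat patterns.tsv
pattern	support_count	support_fraction	length	n_elements
<(G1+)>	4	1	1	1
<(G2-)>	4	1	1	1
<(G3+)>	4	1	1	1
<(G1+)(G2-)>	4	1	2	2
<(G1+)(G3+)>	4	1	2	2
<(G2-)(G3+)>	2	0.5	2	2
<(G3+)(G2-)>	2	0.5	2	2
<(G3+)(G3+)>	3	0.75	2	2
<(G1+)(G3+)(G3+)>	2	0.5	3	3
```

`<(G1+)(G2-)>	4` reads: in all 4 patients, G1 was up-regulated at some
timepoint and G2 down-regulated at a strictly later one. The length-3
pattern chains three such steps. With `--sws 1` nearby timepoints merge
(`<(G1+G2-)>`-style elements appear); with `--max-tc 1` only steps at most
one time unit apart survive. Compare against the classic semantics with
`--engine traditional`, or validate against exhaustive search with
`--engine brute`.

The same pipeline is available as a library:

```python
from ctgrspan import MiningParams, load_fixture, mine

patterns = mine(load_fixture("table4"), MiningParams(min_supp=0.5))
for p in patterns:
    print(p.serialize(), p.support)
```

A synthetic cohort with planted cascades exercises everything end to end:

```sh
ctgrspan synth --seed 7 --out-prefix cohort
ctgrspan mine --input cohort.expression.tsv --fold-threshold 1.5 \
    --min-supp 80 --output cohort.patterns.tsv
```

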