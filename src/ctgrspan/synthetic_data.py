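"""Synthetic multi-patient time-course expression data with planted,
lagged regulation cascades.

The generator emulates the shape of clinical time-course cohorts — a
modest number of patients sampled at roughly ten timepoints — so the whole
convert-to-transactions-then-mine pipeline can be exercised end to end
without any download.  Each planted *chain* is an ordered cascade of
(gene, direction, lag) events; for every patient carrying the chain
(a per-patient penetrance draw), the gene's expression at the lagged
timepoint is the patient's baseline reading multiplied (up) or divided
(down) by ``fold_magnitude``, so its signed fold change crosses any
discretization threshold below that magnitude by construction.  All other
cells carry multiplicative lognormal jitter far below the threshold, plus
optional spurious threshold-crossing "noise events" sprinkled at a given
per-cell rate.

Noise is injected directly as threshold-crossing events rather than via a
calibrated variance model: the generator's contract is only that planted
structure dominates at the stated settings, not that it reproduces probe-
level artifacts or the correlation structure of a real cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from .ctgr_miner import Pattern, PatternSet
from .errors import ConfigError
from .sequence_io import DOWN, UP, ExpressionDataset, Item

#: One cascade event: gene symbol, "up"/"down", positive lag in time units.
ChainEvent = tuple[str, str, float]

_DEFAULT_CHAINS: tuple[tuple[ChainEvent, ...], ...] = (
    (("RGA1", "up", 1.0), ("RGA2", "down", 2.0), ("RGA3", "up", 2.0)),
    (("RGB1", "down", 1.0), ("RGB2", "up", 3.0)),
)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of a synthetic cohort.

    Defaults mirror a small clinical time course: 11 patients followed
    over 10 unit-spaced timepoints, two planted cascades among 30 genes,
    90% chain penetrance, a fold magnitude of 4 (comfortably above common
    discretization thresholds of 1.5-2), 5% lognormal jitter and a 1%
    spurious event rate.
    """

    n_patients: int = 11
    n_genes: int = 30
    timepoints: tuple[float, ...] = tuple(float(t) for t in range(10))
    baseline_level: float = 100.0
    chains: tuple[tuple[ChainEvent, ...], ...] = _DEFAULT_CHAINS
    penetrance: float = 0.9
    fold_magnitude: float = 4.0
    noise_event_rate: float = 0.01
    jitter_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_genes < 1:
            raise ConfigError("n_patients and n_genes must be positive")
        tps = tuple(float(t) for t in self.timepoints)
        if len(tps) < 2 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ConfigError(f"timepoints must strictly increase: {tps}")
        if not (0 <= self.penetrance <= 1 and 0 <= self.noise_event_rate <= 1):
            raise ConfigError("penetrance and noise_event_rate must lie in [0, 1]")
        if not self.fold_magnitude > 1:
            raise ConfigError(f"fold_magnitude must exceed 1, got {self.fold_magnitude}")
        if not self.baseline_level > 0:
            raise ConfigError("baseline_level must be positive")
        if self.jitter_sigma < 0:
            raise ConfigError("jitter_sigma must be >= 0")
        object.__setattr__(self, "timepoints", tps)
        object.__setattr__(
            self, "chains", tuple(tuple(tuple(e) for e in c) for c in self.chains)
        )
        for chain in self.chains:
            if not chain:
                raise ConfigError("chains must be non-empty")
            t = tps[0]
            for gene, direction, lag in chain:
                if direction not in (UP, DOWN):
                    raise ConfigError(f"chain direction must be up/down, got {direction!r}")
                if not lag > 0:
                    raise ConfigError(f"chain lags must be positive, got {lag}")
                t += lag
                if not any(math.isclose(t, tp) for tp in tps):
                    raise ConfigError(
                        f"chain event for {gene!r} lands at time {t}, which is not "
                        f"a timepoint of {tps}"
                    )
        chain_genes = [g for c in self.chains for g, _, _ in c]
        if len(set(chain_genes)) > self.n_genes:
            raise ConfigError("n_genes smaller than the number of distinct chain genes")

    @classmethod
    def from_yaml(cls, source) -> "SynthConfig":
        from .sequence_io import _as_reader

        fh, close = _as_reader(source)
        try:
            raw = yaml.safe_load(fh) or {}
        finally:
            if close:
                fh.close()
        if "chains" in raw:
            raw["chains"] = tuple(
                tuple((str(g), str(d), float(l)) for g, d, l in chain)
                for chain in raw["chains"]
            )
        if "timepoints" in raw:
            raw["timepoints"] = tuple(float(t) for t in raw["timepoints"])
        return cls(**raw)


def _gene_names(config: SynthConfig) -> list[str]:
    names: list[str] = []
    for chain in config.chains:
        for gene, _, _ in chain:
            if gene not in names:
                names.append(gene)
    filler = 1
    while len(names) < config.n_genes:
        cand = f"N{filler:03d}"
        if cand not in names:
            names.append(cand)
        filler += 1
    return names


def generate(config: SynthConfig) -> tuple[ExpressionDataset, list[Pattern]]:
    """Build a synthetic cohort plus the cascades as ground-truth patterns.

    Deterministic given ``config.seed``.  Returns the expression dataset
    and, for each chain, the sequential pattern (one singleton element per
    event, in cascade order) the miner should recover, with its support
    set to the number of carrier patients.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config)
    gene_idx = {g: i for i, g in enumerate(genes)}
    tps = config.timepoints
    tp_idx = {tp: i for i, tp in enumerate(tps)}
    n_p, n_g, n_t = config.n_patients, len(genes), len(tps)

    values = config.baseline_level * np.exp(
        rng.normal(0.0, config.jitter_sigma, size=(n_p, n_g, n_t))
    )

    planted = np.zeros((n_p, n_g, n_t), dtype=bool)
    truth: list[Pattern] = []
    for chain in config.chains:
        carriers = rng.random(n_p) < config.penetrance
        t = tps[0]
        events = []
        for gene, direction, lag in chain:
            t += lag
            ti = next(i for tp, i in tp_idx.items() if math.isclose(tp, t))
            events.append((gene_idx[gene], direction, ti))
        for p in np.flatnonzero(carriers):
            for gi, direction, ti in events:
                base = values[p, gi, 0]
                values[p, gi, ti] = (
                    base * config.fold_magnitude
                    if direction == UP
                    else base / config.fold_magnitude
                )
                planted[p, gi, ti] = True
        truth.append(
            Pattern(
                tuple(((Item(gene, direction),) for gene, direction, _ in chain)),
                support=int(carriers.sum()),
            )
        )

    if config.noise_event_rate > 0:
        hits = rng.random((n_p, n_g, n_t)) < config.noise_event_rate
        ups = rng.random((n_p, n_g, n_t)) < 0.5
        hits[:, :, 0] = False  # baseline column stays clean
        hits &= ~planted
        for p, gi, ti in np.argwhere(hits):
            base = values[p, gi, 0]
            values[p, gi, ti] = (
                base * config.fold_magnitude
                if ups[p, gi, ti]
                else base / config.fold_magnitude
            )

    patients = [f"P{i + 1:02d}" for i in range(n_p)]
    dataset = ExpressionDataset(patients, genes, tps, values)
    return dataset, truth


def recovery_score(mined: PatternSet, truth: list[Pattern]) -> float:
    """Fraction of ground-truth patterns present in the mined set.

    Matching is by exact serialization.  An empty truth list has no
    defined score and returns ``nan`` (distinct from a genuine 0.0).
    """
    if not truth:
        return math.nan
    hits = sum(1 for p in truth if p.serialize() in mined)
    return hits / len(truth)
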