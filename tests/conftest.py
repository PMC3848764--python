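import numpy as np
import pytest
from hypothesis import settings

from ctgrspan.sequence_io import (
    DOWN,
    UP,
    Item,
    Sequence,
    SequenceDB,
    Transaction,
    load_fixture,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def it(token: str) -> Item:
    return Item.from_token(token)


def make_db(spec: dict[str, list[tuple[float, list[str]]]]) -> SequenceDB:
    """Build a SequenceDB from {patient: [(timestamp, [tokens]), ...]}."""
    seqs = [
        Sequence(pid, [Transaction(ts, [it(t) for t in toks]) for ts, toks in trans])
        for pid, trans in spec.items()
    ]
    return SequenceDB(seqs)


def random_db(
    rng: np.random.Generator,
    max_seq: int = 5,
    max_tp: int = 6,
    genes: str = "ABCDE",
    p_tp: float = 0.7,
    p_item: float = 0.25,
) -> SequenceDB:
    """A small random sequence database for property tests."""
    n_seq = int(rng.integers(1, max_seq + 1))
    seqs = []
    for i in range(n_seq):
        trans = []
        for t in range(1, max_tp + 1):
            if rng.random() >= p_tp:
                continue
            items = []
            for g in genes:
                r = rng.random()
                if r < p_item / 2:
                    items.append(Item(g, UP))
                elif r < p_item:
                    items.append(Item(g, DOWN))
            if items:
                trans.append(Transaction(float(t), items))
        if trans:
            seqs.append(Sequence(str(i + 1), trans))
    return SequenceDB(seqs)


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4")


@pytest.fixture()
def table3_db(table1):
    from ctgrspan.discretize import DiscretizationParams, discretize

    return discretize(table1, DiscretizationParams(fold_threshold=1.5))
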