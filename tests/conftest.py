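import random

import pytest

from gatewaynet.datasets import load_demo_transactions
from gatewaynet.transactions import History, TransactionDatabase


@pytest.fixture
def demo_db():
    """The five-history worked example over {I1, I2, I3}."""
    return load_demo_transactions()


def random_database(rng: random.Random, n_labels=4, n_histories=6, max_time=10) -> TransactionDatabase:
    """Small random database for property tests (labels L1..Ln)."""
    labels = [f"L{i}" for i in range(1, rng.randint(1, n_labels) + 1)]
    histories = {}
    for hid in range(rng.randint(1, n_histories)):
        recs = []
        for t in range(max_time + 1):
            if rng.random() < 0.35:
                size = rng.randint(1, min(3, len(labels)))
                recs.append((t, rng.sample(labels, size)))
        if recs:
            histories[str(hid)] = History(recs)
    if not histories:
        histories["0"] = History([(0, [labels[0]])])
    return TransactionDatabase(histories)
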