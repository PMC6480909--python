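"""Small built-in example data, constructed programmatically."""

from __future__ import annotations

import numpy as np

from .simulate import MarkovChain
from .transactions import NULL_EVENT, TransactionDatabase

__all__ = ["load_demo_transactions", "load_demo_chain"]

# the five-history demonstration database used throughout the docs and tests
_DEMO_RECORDS = [
    ("1", 0, ["I1", "I2"]),
    ("1", 1, ["I3"]),
    ("1", 4, ["I2", "I3"]),
    ("2", 0, ["I2"]),
    ("3", 2, ["I1"]),
    ("3", 5, ["I2"]),
    ("4", 0, ["I1"]),
    ("4", 2, ["I2", "I3"]),
    ("4", 3, ["I1", "I2"]),
    ("5", 0, ["I1"]),
    ("5", 1, ["I1", "I2"]),
    ("5", 4, ["I1", "I2", "I3"]),
]


def load_demo_transactions() -> TransactionDatabase:
    """Five short histories over the alphabet {I1, I2, I3}.

    Handy for worked examples: e.g. sup({I1}) = 0.8, sup(I1 -> I3) = 0.6 and
    cert(I1 -> I3) = +inf, so I1 is a gateway into I3 at the default cutoff.
    """
    return TransactionDatabase.from_records(_DEMO_RECORDS)


def load_demo_chain() -> MarkovChain:
    """A small four-state transition matrix over {ε, I1, I2, I3}.

    The I2 row is deliberately left un-normalized (sum 1.46) so it exercises
    the chain validator's row-sum warning.
    """
    states = (NULL_EVENT, "I1", "I2", "I3")
    matrix = np.array(
        [
            [0.750, 0.050, 0.120, 0.080],
            [0.900, 0.010, 0.045, 0.045],
            [0.250, 0.500, 0.550, 0.160],
            [0.750, 0.050, 0.120, 0.080],
        ]
    )
    return MarkovChain(states, matrix)
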