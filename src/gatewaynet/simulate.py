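"""Markov-chain simulation of synthetic event histories.

The generator models a population that keeps returning to events it prefers
while occasionally experimenting with new ones.  States are the events plus a
distinguished *null event* ε ("nothing happened"); transitions are governed by
a first-order row-stochastic matrix built from two per-event parameters:

* **affinity** ``a_i`` in [0, 1] — the pre-normalization self-transition mass
  of event ``i`` (how strongly a subject sticks with it), and
* **interest** ``s_j`` >= 0 — a weight discounting how much of the remaining
  row mass other events leave available to ``j`` before normalization.

Each history starts in ε at time 0; the first opportunity for an initiation
is therefore t = 1.  At every step, one successor is drawn for each event
active at the previous step (from that event's row), topped up with draws
from the ε row until the configured number of draws per step (2-3 by
default) is reached.  Null outcomes record nothing; the union of non-null
outcomes, when non-empty, becomes the history's itemset at that time.  A
history ends after ``max_records`` non-empty records or a fixed horizon of
time steps, whichever comes first.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .transactions import NULL_EVENT, History, TransactionDatabase

__all__ = [
    "MarkovChain",
    "SimulationConfig",
    "build_chain",
    "simulate_history",
    "simulate_database",
    "read_chain",
    "write_chain",
]

logger = logging.getLogger(__name__)

#: rows are considered stochastic when they sum to 1 within this tolerance
ROW_SUM_TOL = 1e-6
#: tolerance guaranteed by :func:`build_chain` after normalization
BUILD_TOL = 1e-9


@dataclass(frozen=True)
class MarkovChain:
    """A first-order transition matrix over ``E_0 = {ε} ∪ E``.

    The constructor validates shape and ordering (state 0 must be ε) and
    *warns* — rather than errors — on rows that do not sum to 1 within
    ``ROW_SUM_TOL``, so that externally supplied matrices with rounding slack
    can still be inspected.
    """

    states: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "states", tuple(self.states))
        k = len(self.states)
        if m.ndim != 2 or m.shape != (k, k):
            raise ValueError(f"transition matrix must be {k}x{k}, got shape {m.shape}")
        if not self.states or self.states[0] != NULL_EVENT:
            raise ValueError(f"the first state must be the null event {NULL_EVENT!r}")
        if len(set(self.states)) != k:
            raise ValueError("state labels must be unique")
        if (m < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        sums = m.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > ROW_SUM_TOL)[0]
        for i in bad:
            warnings.warn(
                f"row {self.states[i]!r} sums to {sums[i]:.6g}, not 1",
                UserWarning,
                stacklevel=2,
            )

    @property
    def events(self) -> tuple[str, ...]:
        """The event alphabet E (states minus ε)."""
        return self.states[1:]

    def row(self, state: str) -> np.ndarray:
        return self.matrix[self.states.index(state)]

    def normalized(self) -> "MarkovChain":
        sums = self.matrix.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValueError("cannot normalize a row of all zeros")
        return MarkovChain(self.states, self.matrix / sums)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic-history generator.

    Defaults reproduce the reference synthetic protocol: 12 events, 8192
    histories, at most 12 non-empty records per history, 2-3 draws per time
    step, ε self-affinity 0.75, horizon of 24 time steps.  ``affinities`` and
    ``interests`` default to None, in which case :func:`build_chain` draws
    them uniformly on [0, 1] per event from the supplied generator.
    """

    n_events: int = 12
    affinities: tuple[float, ...] | None = None
    interests: tuple[float, ...] | None = None
    null_affinity: float = 0.75
    n_histories: int = 8192
    max_records: int = 12
    min_events_per_step: int = 2
    max_events_per_step: int = 3
    horizon: int = 24
    seed: int | None = None

    def __post_init__(self):
        if self.n_events < 1 or self.n_histories < 0 or self.max_records < 1:
            raise ValueError("n_events >= 1, n_histories >= 0 and max_records >= 1 required")
        if not 0.0 <= self.null_affinity <= 1.0:
            raise ValueError("null_affinity must be in [0, 1]")
        if not 1 <= self.min_events_per_step <= self.max_events_per_step:
            raise ValueError("need 1 <= min_events_per_step <= max_events_per_step")
        for name in ("affinities", "interests"):
            v = getattr(self, name)
            if v is not None:
                v = tuple(float(x) for x in v)
                if len(v) != self.n_events:
                    raise ValueError(f"{name} must have one value per event")
                object.__setattr__(self, name, v)
        if self.affinities is not None and any(not 0.0 <= a <= 1.0 for a in self.affinities):
            raise ValueError("affinities must lie in [0, 1]")
        if self.interests is not None and any(s < 0 for s in self.interests):
            raise ValueError("interests must be >= 0")

    @property
    def event_labels(self) -> tuple[str, ...]:
        return tuple(f"I{i}" for i in range(1, self.n_events + 1))


def _prenormalized_row(i: int, diag: float, interests: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One pre-normalization row: diagonal = affinity, off-diagonals sampled
    sequentially left to right, each uniform on [0, max(0, 1 - s_j * mass
    committed so far)].  Rows are renormalized afterwards, so readings that
    differ only by row scale are behaviorally equivalent."""
    k = len(interests)
    row = np.empty(k)
    committed = 0.0
    for j in range(k):
        if j == i:
            row[j] = diag
        else:
            upper = max(0.0, 1.0 - interests[j] * committed)
            row[j] = rng.uniform(0.0, upper)
        committed += row[j]
    return row


def build_chain(config: SimulationConfig, rng: np.random.Generator) -> MarkovChain:
    """Randomly construct a row-stochastic chain from affinities/interests.

    Missing affinities/interests are drawn uniformly on [0, 1] per event.
    Every returned row sums to 1 within ``BUILD_TOL``.
    """
    n = config.n_events
    affinities = config.affinities
    interests = config.interests
    if affinities is None:
        affinities = tuple(rng.uniform(0.0, 1.0, size=n))
    if interests is None:
        interests = tuple(rng.uniform(0.0, 1.0, size=n))
    states = (NULL_EVENT,) + config.event_labels
    # interest weight for ε itself is 0: other events do not discount the null
    s = np.concatenate([[0.0], np.asarray(interests, dtype=float)])
    diag = np.concatenate([[config.null_affinity], np.asarray(affinities, dtype=float)])
    pre = np.vstack([_prenormalized_row(i, diag[i], s, rng) for i in range(n + 1)])
    sums = pre.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        # all-zero row (affinity 0 and every draw 0): fall back to self-loop
        for i in np.where(sums[:, 0] == 0)[0]:
            pre[i, i] = 1.0
        sums = pre.sum(axis=1, keepdims=True)
    return MarkovChain(states, pre / sums)


def _draw(cdf: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(cdf, rng.random(), side="right"))


def simulate_history(chain: MarkovChain, config: SimulationConfig, rng: np.random.Generator) -> History:
    """Generate one history; the state at t = 0 is ε (never recorded)."""
    cdfs = np.cumsum(chain.matrix, axis=1)
    index = {s: i for i, s in enumerate(chain.states)}
    records: list[tuple[int, set[str]]] = []
    active: set[str] = set()  # non-null events recorded at the previous step
    n_records = 0
    for t in range(1, config.horizon + 1):
        if n_records >= config.max_records:
            break
        k_draws = int(rng.integers(config.min_events_per_step, config.max_events_per_step + 1))
        sources = sorted(active) if active else [NULL_EVENT]
        outcomes: set[str] = set()
        draws = 0
        for src in sources:  # one successor per active event
            outcomes.add(chain.states[_draw(cdfs[index[src]], rng)])
            draws += 1
        while draws < k_draws:  # top-up draws come from the null row
            outcomes.add(chain.states[_draw(cdfs[0], rng)])
            draws += 1
        events = outcomes - {NULL_EVENT}
        if events:
            records.append((t, events))
            n_records += 1
        active = events
    return History(records)


def simulate_database(chain: MarkovChain, config: SimulationConfig, rng: np.random.Generator) -> TransactionDatabase:
    """Generate ``config.n_histories`` independent histories with sequential IDs."""
    width = max(1, len(str(max(config.n_histories, 1))))
    histories = {
        str(i + 1).zfill(width): simulate_history(chain, config, rng)
        for i in range(config.n_histories)
    }
    db = TransactionDatabase(histories)
    total_records = sum(len(h) for h in db)
    total_events = sum(len(h[t]) for h in db for t in h.times)
    mean_events = total_events / len(db) if len(db) else 0.0
    logger.info(
        "simulated %d histories: %d records, %d events (%.2f events/history)",
        len(db), total_records, total_events, mean_events,
    )
    return db


def write_chain(chain: MarkovChain, path) -> None:
    """Write the chain as a labeled square CSV (ε row/column first)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(chain.matrix, index=list(chain.states), columns=list(chain.states))
    df.to_csv(path, float_format="%.12g", encoding="utf-8")


def read_chain(path) -> MarkovChain:
    """Read a labeled square transition-matrix CSV.

    Errors on a non-square matrix or a missing leading ε state; warns (via the
    :class:`MarkovChain` validator) on rows that do not sum to 1.
    """
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    states = tuple(str(s) for s in df.columns)
    if tuple(str(s) for s in df.index) != states:
        raise ValueError(f"{path}: row labels do not match column labels (matrix must be square)")
    if not states or states[0] != NULL_EVENT:
        raise ValueError(f"{path}: first state must be the null event {NULL_EVENT!r}")
    return MarkovChain(states, df.to_numpy(dtype=float))
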