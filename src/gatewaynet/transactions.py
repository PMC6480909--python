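"""Event histories and transaction databases.

A *history* is one subject's timestamped sequence of event itemsets: a sparse
map from a non-negative integer time (abstract steps for simulated data,
minutes for screening data) to the non-empty set of event labels recorded at
that time.  A *transaction database* is a collection of histories keyed by an
opaque string identifier, together with the event alphabet ``E``.  Support is
always counted at the history level: an itemset is supported by a history when
it is contained in the union of everything that history ever recorded.

The reserved null-event label ``"ε"`` (:data:`NULL_EVENT`) is used by the
simulator's Markov chain and is never a member of a database's alphabet.
"""

from __future__ import annotations

import bisect
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Reserved label for the simulator's null event; excluded from every alphabet.
NULL_EVENT = "ε"

__all__ = [
    "NULL_EVENT",
    "History",
    "TransactionDatabase",
    "ParseError",
    "read_transactions",
    "write_transactions",
    "cumulative_union",
    "itemset_count",
    "itemset_support",
]


class ParseError(ValueError):
    """A transaction file row that cannot be interpreted."""


def _check_label(label: str) -> str:
    if not isinstance(label, str) or not label:
        raise ValueError(f"event labels must be non-empty strings, got {label!r}")
    if label == NULL_EVENT:
        raise ValueError(f"the null event {NULL_EVENT!r} cannot appear in a history")
    return label


class History(Mapping[int, frozenset]):
    """One subject's event sequence: sparse map time -> itemset.

    Duplicate times passed to the constructor are merged by set union; times
    not stored are treated as the empty itemset on lookup.

    Parameters
    ----------
    records
        Mapping or iterable of ``(time, itemset)`` pairs. Times must be
        integers >= 0; itemsets must be non-empty collections of labels.
    """

    __slots__ = ("_records", "_times", "_star")

    def __init__(self, records: Mapping[int, Iterable[str]] | Iterable[tuple[int, Iterable[str]]] = ()):
        merged: dict[int, set[str]] = {}
        items = records.items() if isinstance(records, Mapping) else records
        for t, itemset in items:
            if not isinstance(t, int) or isinstance(t, bool) or t < 0:
                raise ValueError(f"times must be non-negative integers, got {t!r}")
            labels = {_check_label(x) for x in itemset}
            if not labels:
                raise ValueError(f"empty itemset at time {t}")
            merged.setdefault(t, set()).update(labels)
        self._records = {t: frozenset(s) for t, s in sorted(merged.items())}
        self._times = tuple(self._records)
        self._star: frozenset | None = None

    # Mapping protocol: absent times are *not* KeyErrors conceptually, but the
    # Mapping view exposes only recorded times; use .itemset() for the
    # empty-set-on-absence semantics.
    def __getitem__(self, t: int) -> frozenset:
        return self._records[t]

    def __iter__(self):
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __repr__(self) -> str:
        inner = ", ".join(f"{t}: {{{', '.join(sorted(s))}}}" for t, s in self._records.items())
        return f"History({{{inner}}})"

    def __eq__(self, other) -> bool:
        return isinstance(other, History) and self._records == other._records

    def __hash__(self) -> int:
        return hash(tuple(self._records.items()))

    @property
    def times(self) -> tuple[int, ...]:
        """Recorded times in increasing order."""
        return self._times

    def itemset(self, t: int) -> frozenset:
        """Itemset at time ``t``; the empty set if nothing was recorded."""
        return self._records.get(t, frozenset())

    @property
    def star(self) -> frozenset:
        """Union of every itemset ever recorded (the history's ``S*``)."""
        if self._star is None:
            out: set[str] = set()
            for s in self._records.values():
                out |= s
            self._star = frozenset(out)
        return self._star

    def cumulative_union(self, from_t: int, to_t: int) -> frozenset:
        """Union of the itemsets at times ``from_t..to_t`` inclusive.

        Absent times contribute the empty set, so ranges extending beyond the
        recorded span (including ``from_t < 0``) are harmless; an inverted
        range returns the empty set.
        """
        if from_t > to_t or not self._times:
            return frozenset()
        lo = bisect.bisect_left(self._times, from_t)
        hi = bisect.bisect_right(self._times, to_t)
        out: set[str] = set()
        for t in self._times[lo:hi]:
            out |= self._records[t]
        return frozenset(out)

    def union_before(self, t: int) -> frozenset:
        """Union of all itemsets recorded at times strictly before ``t``."""
        hi = bisect.bisect_left(self._times, t)
        out: set[str] = set()
        for u in self._times[:hi]:
            out |= self._records[u]
        return frozenset(out)


@dataclass(frozen=True)
class TransactionDatabase:
    """A set of histories keyed by ID, with the event alphabet ``E``."""

    histories: dict[str, History]
    alphabet: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        observed: set[str] = set()
        for h in self.histories.values():
            observed |= h.star
        if self.alphabet is None:
            object.__setattr__(self, "alphabet", tuple(sorted(observed)))
        else:
            alpha = tuple(self.alphabet)
            if NULL_EVENT in alpha:
                raise ValueError(f"the null event {NULL_EVENT!r} cannot be in the alphabet")
            missing = observed - set(alpha)
            if missing:
                raise ValueError(f"labels occur outside the alphabet: {sorted(missing)}")
            object.__setattr__(self, "alphabet", alpha)

    def __len__(self) -> int:
        return len(self.histories)

    def __iter__(self):
        return iter(self.histories.values())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TransactionDatabase)
            and self.histories == other.histories
            and set(self.alphabet) == set(other.alphabet)
        )

    @classmethod
    def from_records(cls, rows: Iterable[tuple[str, int, Iterable[str]]]) -> "TransactionDatabase":
        """Build a database from ``(id, time, itemset)`` triples."""
        acc: dict[str, list[tuple[int, Iterable[str]]]] = {}
        for hid, t, itemset in rows:
            acc.setdefault(str(hid), []).append((t, itemset))
        return cls({hid: History(recs) for hid, recs in acc.items()})

    def to_frame(self) -> pd.DataFrame:
        """Long one-item-per-row frame, sorted by (id, time, item)."""
        rows = [
            (hid, t, item)
            for hid, h in self.histories.items()
            for t in h.times
            for item in h[t]
        ]
        rows.sort()
        return pd.DataFrame(rows, columns=["id", "time", "item"])


def read_transactions(path, dialect: str = "long") -> TransactionDatabase:
    """Read a long-format transaction CSV.

    Parameters
    ----------
    path
        CSV/TSV file with header ``id,time,item``.
    dialect
        ``"long"`` — one item per row; ``"itemset"`` — the item column may hold
        a ``;``-delimited itemset (``"I1;I2"``).

    Duplicate ``(id, time)`` rows merge by set union.  Malformed rows raise
    :class:`ParseError` naming the offending file line.
    """
    if dialect not in ("long", "itemset"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return TransactionDatabase({})
    expected = ["id", "time", "item"]
    if list(df.columns[:3]) != expected:
        raise ParseError(f"{path}: expected header {expected}, got {list(df.columns)}")
    rows: list[tuple[str, int, list[str]]] = []
    for idx, (hid, t_raw, item) in enumerate(zip(df["id"], df["time"], df["item"])):
        line = idx + 2  # header is line 1
        try:
            t = int(t_raw)
        except (TypeError, ValueError):
            raise ParseError(f"{path}:{line}: non-integer time {t_raw!r}") from None
        if t < 0:
            raise ParseError(f"{path}:{line}: negative time {t}")
        labels = item.split(";") if dialect == "itemset" else [item]
        labels = [x.strip() for x in labels]
        if any(not x for x in labels):
            raise ParseError(f"{path}:{line}: empty item")
        rows.append((hid, t, labels))
    return TransactionDatabase.from_records(rows)


def write_transactions(db: TransactionDatabase, path) -> None:
    """Write ``db`` as long CSV (header ``id,time,item``), sorted rows.

    ``read_transactions(write_transactions(db))`` reproduces ``db`` exactly.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    db.to_frame().to_csv(path, index=False)


def cumulative_union(h: History, from_t: int, to_t: int) -> frozenset:
    """Functional alias for :meth:`History.cumulative_union`."""
    return h.cumulative_union(from_t, to_t)


def itemset_count(db: TransactionDatabase, X: Iterable[str]) -> int:
    """Number of histories whose full union ``S*`` contains ``X``."""
    Xf = frozenset(X)
    return sum(1 for h in db if Xf <= h.star)


def itemset_support(db: TransactionDatabase, X: Iterable[str]) -> float:
    """``count(X) / |T|``; raises on an empty database."""
    if len(db) == 0:
        raise ValueError("itemset support is undefined on an empty database (|T| = 0)")
    return itemset_count(db, X) / len(db)
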