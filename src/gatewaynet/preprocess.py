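"""Preparation of raw longitudinal screening data for mining.

Covers the pipeline used for urine-drug-screening (UDS) style records:
converting (day number, minutes of day) stamps to per-history minute offsets
anchored at each subject's first record, collapsing raw assay labels into
canonical drug categories (e.g. methamphetamine and MDMA are amphetamines,
methadone is an opiate), admitting only histories that can in principle
support an initiation (at least two time points, at least one positive, and
at least one record after the first positive), and removing mined rules whose
subsequent is an event known to be administered rather than chosen (e.g.
``x -> OPIATES``).
"""

from __future__ import annotations

import datetime as _dt
from collections.abc import Iterable, Mapping
from dataclasses import replace

import pandas as pd

from .irm import RuleSet
from .transactions import History, TransactionDatabase

__all__ = [
    "MINUTES_PER_DAY",
    "LILIAN_EPOCH",
    "lilian_day",
    "calibrate_times",
    "read_screenings",
    "read_remap",
    "remap_items",
    "filter_histories",
    "drop_rules_by_subsequent",
]

MINUTES_PER_DAY = 1440

#: Lilian day 1 is the first day of the Gregorian calendar.
LILIAN_EPOCH = _dt.date(1582, 10, 15)


def lilian_day(date: _dt.date) -> int:
    """Lilian day number of ``date`` (day 1 = 1582-10-15)."""
    return (date - LILIAN_EPOCH).days + 1


def calibrate_times(raw: Iterable[tuple[str, int, int, Iterable[str] | str]]) -> TransactionDatabase:
    """Turn raw ``(id, day_number, minutes_of_day, items)`` records into a database.

    The absolute timestamp is ``day_number * 1440 + minutes_of_day``; each
    history is then shifted so its first record sits at t = 0.  Records
    sharing a raw timestamp merge by union.
    """
    staged: dict[str, list[tuple[int, list[str]]]] = {}
    for hid, day, minutes, items in raw:
        if not 0 <= int(minutes) < MINUTES_PER_DAY:
            raise ValueError(f"minutes_of_day must be in [0, {MINUTES_PER_DAY}), got {minutes!r}")
        stamp = int(day) * MINUTES_PER_DAY + int(minutes)
        labels = [items] if isinstance(items, str) else list(items)
        staged.setdefault(str(hid), []).append((stamp, labels))
    histories = {}
    for hid, recs in staged.items():
        t0 = min(t for t, _ in recs)
        histories[hid] = History([(t - t0, labels) for t, labels in recs])
    return TransactionDatabase(histories)


def read_screenings(path) -> TransactionDatabase:
    """Read a raw screening CSV (``id,day_number,minutes_of_day,item``)."""
    df = pd.read_csv(path, dtype={"id": str, "item": str})
    required = ["id", "day_number", "minutes_of_day", "item"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"{path}: expected header {required}, got {list(df.columns)}")
    return calibrate_times(
        (r["id"], int(r["day_number"]), int(r["minutes_of_day"]), r["item"])
        for r in df.to_dict("records")
    )


def read_remap(path) -> dict[str, str]:
    """Read a two-column ``raw,canonical`` remap CSV into a dict."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: remap file needs two columns (raw, canonical)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def remap_items(db: TransactionDatabase, remap: Mapping[str, str]) -> TransactionDatabase:
    """Replace raw labels by canonical ones; unmapped labels pass through.

    Two raw labels mapping to one canonical label collapse to a single item,
    and the operation is idempotent provided the mapping's values are fixed
    points of the mapping.
    """
    histories = {
        hid: History([(t, {remap.get(x, x) for x in h[t]}) for t in h.times])
        for hid, h in db.histories.items()
    }
    return TransactionDatabase(histories)


def filter_histories(
    db: TransactionDatabase,
    positive_items: Iterable[str] | None = None,
    min_timepoints: int = 2,
) -> TransactionDatabase:
    """Keep only histories able to exhibit an initiation after a positive.

    A history is retained when it has (a) at least ``min_timepoints`` recorded
    time points, (b) at least one record containing a *positive* item, and
    (c) at least one recorded time point strictly after the first positive
    record.  By default every item counts as positive.
    """
    positive = frozenset(positive_items) if positive_items is not None else frozenset(db.alphabet)
    kept = {}
    for hid, h in db.histories.items():
        times = h.times
        if len(times) < min_timepoints:
            continue
        first_pos = next((t for t in times if h[t] & positive), None)
        if first_pos is None:
            continue
        if not any(t > first_pos for t in times):
            continue
        kept[hid] = h
    return TransactionDatabase(kept, db.alphabet)


def drop_rules_by_subsequent(rules: RuleSet, banned: Iterable[str]) -> RuleSet:
    """Remove rules whose subsequent intersects ``banned``.

    Rules carrying banned labels only in the antecedent are retained, and
    retained rules keep their metrics untouched.
    """
    banned_set = frozenset(banned)
    kept = tuple(r for r in rules if not (r.subsequent & banned_set))
    return replace(rules, rules=kept)
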