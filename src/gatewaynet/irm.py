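"""Initiation rule mining.

An *initiation rule* ``a -> b`` asserts that the itemset ``b`` appears in a
history for the first time immediately after a time by which ``a`` has already
appeared.  Formally, the unwindowed relation holds in a history ``S`` when
there is a recorded time ``u`` with ``b ⊆ S_u``, ``a ⊆ S*_{<u}`` (union of
everything recorded strictly before ``u``) and ``b ⊄ S*_{<u}`` (novelty).  The
windowed variant with window ``z >= 1`` restricts both the antecedent search
and the novelty test to the ``z`` time units ending just before ``u`` — the
union over times ``[u - z, u - 1]`` — so that re-initiations separated by gaps
longer than the window count again.  ``z = 0`` denotes the unwindowed
relation.  Rules with ``b ⊆ a`` are vacuously false (the antecedent window
containing ``a`` would contain ``b``, defeating novelty) and are never
constructed.

Rule support is the fraction of histories in which the relation holds, and the
standard association-mining measures (confidence, lift, conviction) are
derived from it together with itemset supports.  Two additional quantities
drive causal screening: the rule probability ``p = sup(a->b)/sup(b)`` — the
fraction of b-containing histories in which b was initiated by a — and its
odds form, the *certainty* ``p/(1-p) = sup(a->b)/(sup(b)-sup(a->b))``.  A rule
with certainty above the threshold ``l_cert`` (default 1, i.e. p > 50%) is a
*gateway rule*: a candidate probabilistic-causal link.

Candidate generation uses the a priori principle: itemset support is
anti-monotone, so only frequent itemsets (count >= l_count and support >=
l_sup) are paired into candidates, up to the maximum degree ``d_max`` where
``deg(a -> b) = max(|a|, |b|)``.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator

from .transactions import TransactionDatabase, History, itemset_count, itemset_support

__all__ = [
    "InitiationRule",
    "MiningThresholds",
    "RuleSet",
    "UndefinedMetricError",
    "InitiationRuleMiner",
    "initiation_holds",
    "rule_count_support",
    "rule_metrics",
    "frequent_itemsets",
    "propose_rules",
    "mine",
    "classify_gateway",
    "default_certainty_threshold",
    "read_rules",
    "write_rules",
]

INF = math.inf


class UndefinedMetricError(ValueError):
    """A rule metric whose defining ratio has a zero denominator."""


def _canon(items: Iterable[str]) -> frozenset:
    s = frozenset(items)
    if not s:
        raise ValueError("itemsets in rules must be non-empty")
    return s


def _sort_key(itemset: frozenset) -> tuple:
    return tuple(sorted(itemset))


@dataclass(frozen=True, order=False)
class InitiationRule:
    """A mined rule ``a -> b`` within window ``z`` and its quality measures."""

    antecedent: frozenset
    subsequent: frozenset
    window: int = 0
    count: int = 0
    support: float = 0.0
    confidence: float = 0.0
    lift: float = 0.0
    conviction: float = 0.0
    probability: float = 0.0
    certainty: float = 0.0
    is_gateway: bool = False

    def __post_init__(self):
        a = _canon(self.antecedent)
        b = _canon(self.subsequent)
        if b <= a:
            raise ValueError(
                f"rule {sorted(a)} -> {sorted(b)}: the subsequent is contained in "
                "the antecedent, which makes the initiation relation vacuously false"
            )
        if self.window < 0:
            raise ValueError("window must be >= 0")
        object.__setattr__(self, "antecedent", a)
        object.__setattr__(self, "subsequent", b)

    @property
    def degree(self) -> int:
        """max(|a|, |b|)."""
        return max(len(self.antecedent), len(self.subsequent))

    def canonical_key(self) -> tuple:
        return (self.window, self.degree, _sort_key(self.antecedent), _sort_key(self.subsequent))

    def label(self) -> str:
        arrow = "->" if self.window == 0 else f"-{self.window}->"
        return f"{';'.join(sorted(self.antecedent))} {arrow} {';'.join(sorted(self.subsequent))}"


@dataclass(frozen=True)
class MiningThresholds:
    """Inclusion thresholds for mining.

    ``l_count`` applies to the co-occurrence count of ``a ∪ b`` (and to
    frequent-itemset screening); ``l_sup``/``l_conf``/``l_lift`` are lower
    bounds on rule support, confidence and lift; conviction must fall in
    ``[l_conv, h_conv]``; ``l_cert`` is the strict gateway cutoff; ``d_max``
    the maximum rule degree; ``z`` the window (0 = unwindowed).
    """

    l_count: int = 0
    l_sup: float = 0.0
    l_conf: float = 0.0
    l_lift: float = 0.0
    l_conv: float = 0.0
    h_conv: float = INF
    l_cert: float = 1.0
    d_max: int = 2
    z: int = 0

    def __post_init__(self):
        if self.l_count < 0 or self.d_max < 1 or self.z < 0:
            raise ValueError("l_count >= 0, d_max >= 1 and z >= 0 are required")
        if self.l_conv > self.h_conv:
            raise ValueError(f"inconsistent conviction bounds: l_conv={self.l_conv} > h_conv={self.h_conv}")
        if self.l_cert <= 0:
            raise ValueError("l_cert must be > 0")


@dataclass(frozen=True)
class RuleSet:
    """Mined rules in canonical order, with mining provenance."""

    rules: tuple[InitiationRule, ...]
    thresholds: MiningThresholds
    n_histories: int
    alphabet: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def get(self, a: Iterable[str], b: Iterable[str]) -> InitiationRule | None:
        af, bf = frozenset(a), frozenset(b)
        for r in self.rules:
            if r.antecedent == af and r.subsequent == bf:
                return r
        return None

    def gateways(self) -> tuple[InitiationRule, ...]:
        return tuple(r for r in self.rules if r.is_gateway)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "antecedent": ";".join(sorted(r.antecedent)),
                "subsequent": ";".join(sorted(r.subsequent)),
                "window": r.window,
                "degree": r.degree,
                "count": r.count,
                "support": r.support,
                "confidence": r.confidence,
                "lift": r.lift,
                "conviction": r.conviction,
                "probability": r.probability,
                "certainty": r.certainty,
                "is_gateway": r.is_gateway,
            }
            for r in self.rules
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "antecedent", "subsequent", "window", "degree", "count", "support",
                "confidence", "lift", "conviction", "probability", "certainty", "is_gateway",
            ],
        )


# ---------------------------------------------------------------------------
# relation semantics


def _window_union(h: History, u: int, z: int) -> frozenset:
    """The antecedent/novelty scope for a subsequent occurring at time u."""
    if z == 0:
        return h.union_before(u)
    return h.cumulative_union(u - z, u - 1)


def initiation_holds(h: History, a: Iterable[str], b: Iterable[str], z: int = 0) -> bool:
    """Whether the (possibly windowed) initiation relation ``a -> b`` holds in ``h``.

    Only recorded times need to be scanned as candidate occurrences of ``b``:
    the relation requires ``b ⊆ S_u``, which forces ``u`` to be recorded.
    """
    af, bf = _canon(a), _canon(b)
    if bf <= af:
        raise ValueError("b ⊆ a: the initiation relation is vacuously false by construction")
    if z < 0:
        raise ValueError("z must be >= 0")
    for u in h.times:
        if not bf <= h[u]:
            continue
        scope = _window_union(h, u, z)
        if af <= scope and not bf <= scope:
            return True
    return False


def rule_count_support(
    db: TransactionDatabase, a: Iterable[str], b: Iterable[str], z: int = 0
) -> tuple[int, float]:
    """(number, fraction) of histories in which ``a -> b`` holds within ``z``."""
    if len(db) == 0:
        raise ValueError("rule support is undefined on an empty database (|T| = 0)")
    n = sum(1 for h in db if initiation_holds(h, a, b, z))
    return n, n / len(db)


@dataclass(frozen=True)
class RuleMetrics:
    confidence: float
    lift: float
    conviction: float
    probability: float
    certainty: float


def _metrics_from_supports(sup_rule: float, sup_a: float, sup_b: float) -> RuleMetrics:
    if sup_a == 0:
        raise UndefinedMetricError("sup(a) = 0: confidence and lift are undefined")
    if sup_b == 0:
        raise UndefinedMetricError("sup(b) = 0: lift, probability and certainty are undefined")
    confidence = sup_rule / sup_a
    lift = sup_rule / (sup_a * sup_b)
    conviction = INF if confidence == 1 else (1 - sup_b) / (1 - confidence)
    probability = sup_rule / sup_b
    certainty = INF if sup_b == sup_rule else sup_rule / (sup_b - sup_rule)
    return RuleMetrics(confidence, lift, conviction, probability, certainty)


def rule_metrics(
    db: TransactionDatabase, a: Iterable[str], b: Iterable[str], z: int = 0
) -> RuleMetrics:
    """Confidence, lift, conviction, probability and certainty of ``a -> b``.

    Conviction is +inf at confidence 1 and certainty is +inf when every
    b-containing history had b initiated by a (sup(b) = sup(a->b)); both are
    interpreted as approaching infinity.
    """
    af, bf = _canon(a), _canon(b)
    _, sup_rule = rule_count_support(db, af, bf, z)
    return _metrics_from_supports(sup_rule, itemset_support(db, af), itemset_support(db, bf))


# ---------------------------------------------------------------------------
# candidate generation (a priori)


def frequent_itemsets(
    db: TransactionDatabase, l_count: int = 0, l_sup: float = 0.0, max_size: int = 2
) -> list[tuple[frozenset, int, float]]:
    """Levelwise enumeration of frequent itemsets up to ``max_size``.

    An itemset is frequent when ``count(X) >= l_count`` and ``sup(X) >=
    l_sup``; size-k candidates are unions of frequent (k-1)-sets with frequent
    1-sets, pruned by anti-monotonicity.  Results are sorted by (size, labels)
    with exact counts.
    """
    if max_size < 1:
        return []
    n = len(db)
    stars = [h.star for h in db]

    def count(X: frozenset) -> int:
        return sum(1 for s in stars if X <= s)

    def ok(c: int) -> bool:
        return c >= l_count and (n > 0 and c / n >= l_sup)

    out: list[tuple[frozenset, int, float]] = []
    level = []
    for e in db.alphabet:
        X = frozenset([e])
        c = count(X)
        if n > 0 and ok(c):
            level.append(X)
            out.append((X, c, c / n))
    singles = list(level)
    k = 2
    while level and k <= max_size:
        seen: set[frozenset] = set()
        nxt = []
        for base in level:
            for s in singles:
                X = base | s
                if len(X) != k or X in seen:
                    continue
                seen.add(X)
                c = count(X)
                if ok(c):
                    nxt.append(X)
                    out.append((X, c, c / n))
        level = nxt
        k += 1
    out.sort(key=lambda rec: (len(rec[0]), _sort_key(rec[0])))
    return out


def propose_rules(frequent: Sequence[Iterable[str]], d_max: int) -> list[tuple[frozenset, frozenset]]:
    """All ordered candidate pairs (a, b) of frequent itemsets.

    Pairs with ``max(|a|,|b|) > d_max`` or ``b ⊆ a`` (vacuously false) are
    excluded; output is in canonical (antecedent labels, subsequent labels)
    order.
    """
    if d_max < 1:
        return []
    sets = sorted({frozenset(x) for x in frequent}, key=_sort_key)
    cands = [
        (a, b)
        for a in sets
        for b in sets
        if max(len(a), len(b)) <= d_max and not b <= a
    ]
    cands.sort(key=lambda ab: (_sort_key(ab[0]), _sort_key(ab[1])))
    return cands


def classify_gateway(rule_or_certainty, l_cert: float = 1.0) -> bool:
    """Strict gateway test: certainty > ``l_cert`` (+inf always qualifies)."""
    cert = rule_or_certainty.certainty if isinstance(rule_or_certainty, InitiationRule) else float(rule_or_certainty)
    return cert > l_cert


def default_certainty_threshold(n_events: int) -> float:
    """Chance-level certainty cutoff ``1/(|E| - 1)``.

    With |E| equally likely antecedent events, a rule attributable to chance
    alone has probability 1/|E|, whose odds form is 1/(|E|-1); a certainty
    above this is better than chance.
    """
    if n_events < 2:
        raise ValueError("the chance-level threshold requires |E| >= 2")
    return 1.0 / (n_events - 1)


# ---------------------------------------------------------------------------
# the miner


class InitiationRuleMiner(BaseEstimator):
    """Mine initiation rules from a transaction database.

    scikit-learn-style estimator: thresholds are constructor parameters,
    :meth:`fit` runs the a priori candidate proposal and threshold screening,
    and the discovered rules land in fitted attributes.

    Parameters
    ----------
    l_count : int, default=0
        Minimum co-occurrence count of ``a ∪ b`` (criterion i) and
        frequent-itemset count floor.
    l_sup, l_conf, l_lift : float, default=0
        Lower bounds on rule support, confidence and lift.
    l_conv, h_conv : float, default=(0, inf)
        Conviction must fall in ``[l_conv, h_conv]``.
    l_cert : float, default=1.0
        Strict certainty cutoff for flagging gateway rules.
    d_max : int, default=2
        Maximum rule degree ``max(|a|, |b|)``.
    z : int, default=0
        Initiation window; 0 mines the unwindowed relation.

    Attributes
    ----------
    rules_ : RuleSet
        Accepted rules in canonical order, with all metrics and gateway flags.
    frequent_itemsets_ : list of (frozenset, count, support)
    n_candidates_ : int
        Number of ordered candidate pairs evaluated.
    n_histories_ : int
    alphabet_ : tuple of str

    Examples
    --------
    >>> from gatewaynet.datasets import load_demo_transactions
    >>> miner = InitiationRuleMiner(l_sup=0.5, l_conf=0.5, l_lift=1.0, d_max=1)
    >>> miner.fit(load_demo_transactions())                     # doctest: +ELLIPSIS
    InitiationRuleMiner(...)
    >>> [r.label() for r in miner.rules_]
    ['I1 -> I3']
    """

    def __init__(self, l_count=0, l_sup=0.0, l_conf=0.0, l_lift=0.0,
                 l_conv=0.0, h_conv=INF, l_cert=1.0, d_max=2, z=0):
        self.l_count = l_count
        self.l_sup = l_sup
        self.l_conf = l_conf
        self.l_lift = l_lift
        self.l_conv = l_conv
        self.h_conv = h_conv
        self.l_cert = l_cert
        self.d_max = d_max
        self.z = z

    def thresholds(self) -> MiningThresholds:
        return MiningThresholds(
            l_count=self.l_count, l_sup=self.l_sup, l_conf=self.l_conf,
            l_lift=self.l_lift, l_conv=self.l_conv, h_conv=self.h_conv,
            l_cert=self.l_cert, d_max=self.d_max, z=self.z,
        )

    def fit(self, X: TransactionDatabase, y=None) -> "InitiationRuleMiner":
        """Mine ``X``; ``y`` is ignored (present for API conformance)."""
        th = self.thresholds()  # validates
        if not isinstance(X, TransactionDatabase):
            raise TypeError("X must be a TransactionDatabase")
        if len(X) == 0:
            raise ValueError("cannot mine an empty database")
        n = len(X)
        freq = frequent_itemsets(X, th.l_count, th.l_sup, th.d_max)
        counts = {f: c for f, c, _ in freq}
        candidates = propose_rules([f for f, _, _ in freq], th.d_max)

        accepted: list[InitiationRule] = []
        for a, b in candidates:
            sup_a = counts[a] / n
            sup_b = counts[b] / n
            if sup_a == 0 or sup_b == 0:
                continue  # metrics undefined; the rule cannot hold anyway
            union_count = counts.get(a | b)
            if union_count is None:
                union_count = itemset_count(X, a | b)
            if union_count < th.l_count:
                continue
            count, sup_rule = rule_count_support(X, a, b, th.z)
            if count == 0 or sup_rule < th.l_sup:
                continue  # a rule that never holds is not a mined rule
            m = _metrics_from_supports(sup_rule, sup_a, sup_b)
            if m.confidence < th.l_conf or m.lift < th.l_lift:
                continue
            if not (th.l_conv <= m.conviction <= th.h_conv):
                continue
            accepted.append(InitiationRule(
                antecedent=a, subsequent=b, window=th.z, count=count,
                support=sup_rule, confidence=m.confidence, lift=m.lift,
                conviction=m.conviction, probability=m.probability,
                certainty=m.certainty,
                is_gateway=classify_gateway(m.certainty, th.l_cert),
            ))
        accepted.sort(key=InitiationRule.canonical_key)
        self.rules_ = RuleSet(tuple(accepted), th, n, X.alphabet)
        self.frequent_itemsets_ = freq
        self.n_candidates_ = len(candidates)
        self.n_histories_ = n
        self.alphabet_ = X.alphabet
        return self

    def transform(self, X: TransactionDatabase) -> pd.DataFrame:
        """Fit on ``X`` if unfitted, then return the rule table."""
        if not hasattr(self, "rules_"):
            self.fit(X)
        return self.rules_.to_frame()


def mine(db: TransactionDatabase, thresholds: MiningThresholds | None = None, **kwargs) -> RuleSet:
    """Functional front end: mine ``db`` and return the :class:`RuleSet`."""
    if thresholds is not None:
        if kwargs:
            raise TypeError("pass either a MiningThresholds or keyword thresholds, not both")
        params = {f: getattr(thresholds, f) for f in MiningThresholds.__dataclass_fields__}
    else:
        params = kwargs
    return InitiationRuleMiner(**params).fit(db).rules_


# ---------------------------------------------------------------------------
# rule CSV I/O (infinite values serialized as the literal "inf")


def write_rules(rules: RuleSet, path) -> None:
    df = rules.to_frame()
    df.to_csv(path, index=False, float_format="%.12g")


def read_rules(path) -> RuleSet:
    """Read a rule CSV back into a :class:`RuleSet`.

    Provenance thresholds are not stored in the CSV; the returned set carries
    default thresholds with the window taken from the rules themselves.
    """
    df = pd.read_csv(path)
    rules = []
    for row in df.to_dict("records"):
        rules.append(InitiationRule(
            antecedent=frozenset(str(row["antecedent"]).split(";")),
            subsequent=frozenset(str(row["subsequent"]).split(";")),
            window=int(row["window"]), count=int(row["count"]),
            support=float(row["support"]), confidence=float(row["confidence"]),
            lift=float(row["lift"]), conviction=float(row["conviction"]),
            probability=float(row["probability"]), certainty=float(row["certainty"]),
            is_gateway=bool(row["is_gateway"]),
        ))
    rules.sort(key=InitiationRule.canonical_key)
    z = rules[0].window if rules else 0
    alphabet = tuple(sorted({x for r in rules for x in r.antecedent | r.subsequent}))
    return RuleSet(tuple(rules), MiningThresholds(z=z), 0, alphabet)
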