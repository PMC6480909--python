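"""Initiation-rule semantics, metrics, a priori mining and gateway screening."""

import math
import random
from itertools import chain, combinations

import pytest

from gatewaynet.irm import (
    InitiationRule,
    InitiationRuleMiner,
    MiningThresholds,
    UndefinedMetricError,
    classify_gateway,
    default_certainty_threshold,
    frequent_itemsets,
    initiation_holds,
    mine,
    propose_rules,
    read_rules,
    rule_count_support,
    rule_metrics,
    write_rules,
)
from gatewaynet.transactions import History, TransactionDatabase, itemset_count

from conftest import random_database

INF = math.inf


# ---------------------------------------------------------------------------
# independent oracle: evaluate the windowed relation over *all* integer times
# by brute force, never just the recorded ones.


def oracle_holds(h: History, a, b, z):
    a, b = frozenset(a), frozenset(b)
    if not h.times:
        return False
    t_max = max(h.times)
    for t in range(0, t_max):  # b must occur at t+1
        if z == 0:
            scope = frozenset().union(*(h.itemset(i) for i in range(0, t + 1)))
        else:
            scope = frozenset().union(*(h.itemset(i) for i in range(t - z + 1, t + 1)))
        if a <= scope and b <= h.itemset(t + 1) and not b <= scope:
            return True
    return False


def nonempty_subsets(labels, max_size):
    return [
        frozenset(c)
        for k in range(1, max_size + 1)
        for c in combinations(sorted(labels), k)
    ]


def oracle_mine(db, z, d_max=2):
    """All (a, b, support) with positive support, by exhaustive enumeration."""
    out = {}
    sets = nonempty_subsets(db.alphabet, d_max)
    for a in sets:
        for b in sets:
            if b <= a:
                continue
            n = sum(oracle_holds(h, a, b, z) for h in db)
            if n:
                out[(a, b)] = n / len(db)
    return out


class TestInitiationHolds:
    def test_unwindowed_holds_in_history_3(self, demo_db):
        # I1 at t=2 precedes the first (and only) I2 at t=5
        assert initiation_holds(demo_db.histories["3"], {"I1"}, {"I2"}, z=0)

    def test_window_2_excludes_history_3(self, demo_db):
        # the antecedent fell out of the two-step window [3, 4] before u=5
        assert not initiation_holds(demo_db.histories["3"], {"I1"}, {"I2"}, z=2)

    def test_self_rule_rejected(self, demo_db):
        h = demo_db.histories["1"]
        with pytest.raises(ValueError, match="vacuously false"):
            initiation_holds(h, {"I1"}, {"I1"})
        with pytest.raises(ValueError, match="vacuously false"):
            InitiationRule(frozenset({"I1", "I2"}), frozenset({"I2"}))

    def test_matches_oracle_on_random_histories(self):
        rng = random.Random(42)
        for _ in range(60):
            db = random_database(rng, n_labels=4, n_histories=4, max_time=8)
            for h in db:
                for a in nonempty_subsets(db.alphabet, 1):
                    for b in nonempty_subsets(db.alphabet, 1):
                        if b <= a:
                            continue
                        for z in (0, 1, 2, 3):
                            assert initiation_holds(h, a, b, z) == oracle_holds(h, a, b, z)

    def test_subset_rules_never_hold(self):
        """b ⊆ a is vacuously false in every history, by direct evaluation."""
        rng = random.Random(5)
        for _ in range(40):
            db = random_database(rng, n_labels=3)
            for h in db:
                for a in nonempty_subsets(db.alphabet, 2):
                    for b in nonempty_subsets(a, 2):
                        for z in (0, 2):
                            assert not oracle_holds(h, a, b, z)


class TestRuleSupport:
    @pytest.mark.parametrize(
        "a, b, z, count, sup",
        [
            ({"I1"}, {"I3"}, 0, 3, 0.6),
            ({"I1"}, {"I2"}, 0, 3, 0.6),
            ({"I2"}, {"I3"}, 0, 2, 0.4),
            ({"I1"}, {"I2"}, 2, 2, 0.4),
        ],
    )
    def test_worked_example(self, demo_db, a, b, z, count, sup):
        assert rule_count_support(demo_db, a, b, z) == (count, pytest.approx(sup))

    def test_rule_count_bounded_by_union_count(self):
        rng = random.Random(13)
        for _ in range(30):
            db = random_database(rng)
            for a in nonempty_subsets(db.alphabet, 1):
                for b in nonempty_subsets(db.alphabet, 1):
                    if b <= a:
                        continue
                    n, _ = rule_count_support(db, a, b, 0)
                    assert n <= itemset_count(db, a | b)

    def test_empty_database_raises(self):
        with pytest.raises(ValueError, match="empty database"):
            rule_count_support(TransactionDatabase({}), {"a"}, {"b"})


class TestRuleMetrics:
    def test_worked_example_values(self, demo_db):
        m = rule_metrics(demo_db, {"I1"}, {"I3"})
        assert m.lift == pytest.approx(1.25)
        assert m.confidence == pytest.approx(0.75)
        assert m.conviction == pytest.approx(1.6)
        assert m.probability == pytest.approx(1.0)
        assert m.certainty == INF  # sup(b) == sup(a->b): approaches infinity

    def test_certainty_of_I1_to_I2(self, demo_db):
        assert rule_metrics(demo_db, {"I1"}, {"I2"}).certainty == pytest.approx(1.5)

    def test_zero_support_antecedent_named_in_error(self, demo_db):
        db = TransactionDatabase(demo_db.histories, demo_db.alphabet + ("I9",))
        with pytest.raises(UndefinedMetricError, match=r"sup\(a\) = 0"):
            rule_metrics(db, {"I9"}, {"I2"})
        with pytest.raises(UndefinedMetricError, match=r"sup\(b\) = 0"):
            rule_metrics(db, {"I2"}, {"I9"})

    def test_algebraic_identities(self):
        """lift = conf/sup(b) and conv = (1-sup(b))/(1-conf) wherever defined."""
        rng = random.Random(29)
        checked = 0
        for _ in range(30):
            db = random_database(rng)
            for a in nonempty_subsets(db.alphabet, 1):
                for b in nonempty_subsets(db.alphabet, 1):
                    if b <= a:
                        continue
                    from gatewaynet.transactions import itemset_support

                    if itemset_support(db, a) == 0 or itemset_support(db, b) == 0:
                        continue
                    m = rule_metrics(db, a, b)
                    sup_b = itemset_support(db, b)
                    assert m.lift == pytest.approx(m.confidence / sup_b)
                    if m.confidence < 1:
                        assert m.conviction == pytest.approx((1 - sup_b) / (1 - m.confidence))
                    checked += 1
        assert checked > 50

    def test_certainty_monotone_in_probability(self):
        probs = [i / 20 for i in range(20)]
        certs = [p / (1 - p) for p in probs]
        assert certs == sorted(certs)
        assert all((c > 1) == (p > 0.5) for p, c in zip(probs, certs))


class TestFrequentItemsets:
    def test_worked_example_all_itemsets(self, demo_db):
        got = {f: (c, s) for f, c, s in frequent_itemsets(demo_db, 0, 0.6, 3)}
        expected = {
            frozenset({"I1"}): (4, 0.8),
            frozenset({"I2"}): (5, 1.0),
            frozenset({"I3"}): (3, 0.6),
            frozenset({"I1", "I2"}): (4, 0.8),
            frozenset({"I1", "I3"}): (3, 0.6),
            frozenset({"I2", "I3"}): (3, 0.6),
            frozenset({"I1", "I2", "I3"}): (3, 0.6),
        }
        assert {f: c for f, (c, _) in got.items()} == {f: c for f, (c, _) in expected.items()}
        for f, (_, s) in expected.items():
            assert got[f][1] == pytest.approx(s)

    def test_threshold_0_7_keeps_three(self, demo_db):
        got = {f for f, _, _ in frequent_itemsets(demo_db, 0, 0.7, 3)}
        assert got == {frozenset({"I1"}), frozenset({"I2"}), frozenset({"I1", "I2"})}

    def test_impossible_support_gives_empty(self, demo_db):
        assert frequent_itemsets(demo_db, 0, 1.1, 3) == []

    def test_matches_brute_force_on_random_databases(self):
        rng = random.Random(99)
        for _ in range(25):
            db = random_database(rng, n_labels=4, n_histories=6)
            l_count, l_sup = rng.choice([(0, 0.0), (1, 0.25), (2, 0.5)])
            got = {f for f, _, _ in frequent_itemsets(db, l_count, l_sup, 3)}
            brute = {
                X
                for X in nonempty_subsets(db.alphabet, 3)
                if itemset_count(db, X) >= l_count
                and itemset_count(db, X) / len(db) >= l_sup
            }
            assert got == brute


class TestProposeRules:
    def test_three_singletons_give_six_candidates(self):
        singles = [frozenset({x}) for x in ("I1", "I2", "I3")]
        assert len(propose_rules(singles, d_max=1)) == 6

    def test_single_itemset_proposes_nothing(self):
        assert propose_rules([frozenset({"I1"})], d_max=1) == []

    def test_subset_subsequents_excluded(self, demo_db):
        freq = [f for f, _, _ in frequent_itemsets(demo_db, 0, 0.0, 2)]
        cands = propose_rules(freq, d_max=2)
        assert (frozenset({"I1", "I2"}), frozenset({"I2"})) not in cands
        assert all(not b <= a for a, b in cands)

    def test_d_max_below_one_is_empty(self):
        assert propose_rules([frozenset({"I1"})], d_max=0) == []


class TestMine:
    def test_worked_example_single_rule(self, demo_db):
        rules = mine(demo_db, l_sup=0.5, l_conf=0.5, l_lift=1.0, d_max=1)
        assert [r.label() for r in rules] == ["I1 -> I3"]
        r = rules.rules[0]
        assert r.lift == pytest.approx(1.25)
        assert r.certainty == INF and r.is_gateway

    def test_permissive_thresholds_keep_every_supported_candidate(self, demo_db):
        rules = mine(demo_db, d_max=1)
        labels = {r.label() for r in rules}
        assert labels == {"I1 -> I2", "I1 -> I3", "I2 -> I3"}

    def test_windowed_mining_uses_windowed_support(self, demo_db):
        rules = mine(demo_db, l_sup=0.5, l_conf=0.5, l_lift=1.0, d_max=1, z=2)
        # I1 ->(2) I3 has literal windowed support 0.4 < 0.5, so nothing passes
        assert len(rules) == 0

    def test_inconsistent_conviction_bounds_raise(self, demo_db):
        with pytest.raises(ValueError, match="l_conv"):
            mine(demo_db, l_conv=2.0, h_conv=1.0)

    def test_agrees_with_exhaustive_oracle(self):
        """mine() at permissive thresholds = brute-force evaluation of the
        relation over every integer time and every candidate pair."""
        rng = random.Random(2024)
        for _ in range(40):
            db = random_database(rng, n_labels=4, n_histories=8, max_time=10)
            z = rng.choice([0, 1, 2, 3])
            rules = mine(db, d_max=2, z=z)
            got = {(r.antecedent, r.subsequent): r.support for r in rules}
            expected = oracle_mine(db, z, d_max=2)
            assert got.keys() == expected.keys()
            for k in expected:
                assert got[k] == pytest.approx(expected[k])

    def test_deterministic_and_row_order_independent(self, demo_db):
        a = mine(demo_db, d_max=2)
        b = mine(demo_db, d_max=2)
        assert a.to_frame().equals(b.to_frame())
        rows = [
            (hid, t, item)
            for hid, h in demo_db.histories.items()
            for t in h.times
            for item in sorted(h[t])
        ]
        random.Random(1).shuffle(rows)
        shuffled = TransactionDatabase.from_records((i, t, [x]) for i, t, x in rows)
        assert mine(shuffled, d_max=2).to_frame().equals(a.to_frame())

    def test_estimator_api(self, demo_db):
        miner = InitiationRuleMiner(l_sup=0.5, l_conf=0.5, l_lift=1.0, d_max=1)
        assert miner.get_params()["l_sup"] == 0.5
        cloned = miner.set_params(l_lift=0.0)
        assert cloned.l_lift == 0.0
        miner.set_params(l_lift=1.0).fit(demo_db)
        assert miner.n_candidates_ == 6
        assert len(miner.rules_) == 1

    def test_rule_csv_round_trip(self, demo_db, tmp_path):
        rules = mine(demo_db, d_max=2)
        path = tmp_path / "rules.csv"
        write_rules(rules, path)
        text = path.read_text()
        assert "inf" in text  # infinite certainty serialized literally
        back = read_rules(path)
        assert [(r.antecedent, r.subsequent, r.window) for r in back] == [
            (r.antecedent, r.subsequent, r.window) for r in rules
        ]
        for x, y in zip(back, rules):  # serialized at 12 significant digits
            if math.isinf(y.certainty):
                assert math.isinf(x.certainty)
            else:
                assert x.certainty == pytest.approx(y.certainty, rel=1e-11)


class TestGatewayClassification:
    def test_infinite_certainty_is_gateway(self, demo_db):
        rules = mine(demo_db, l_sup=0.5, l_conf=0.5, l_lift=1.0, d_max=1)
        assert rules.rules[0].certainty == INF and rules.rules[0].is_gateway

    def test_windowed_I1_I2_not_a_gateway(self, demo_db):
        rules = mine(demo_db, d_max=1, z=2)
        r = rules.get({"I1"}, {"I2"})
        assert r.support == pytest.approx(0.4)
        assert r.certainty == pytest.approx(0.4 / 0.6)
        assert not r.is_gateway

    def test_strict_inequality_at_threshold(self):
        assert not classify_gateway(1.0, l_cert=1.0)
        assert classify_gateway(1.0000001, l_cert=1.0)
        assert classify_gateway(INF, l_cert=1.0)

    @pytest.mark.parametrize("n, expected", [(2, 1.0), (3, 0.5), (11, 0.1)])
    def test_chance_level_threshold_closed_form(self, n, expected):
        assert default_certainty_threshold(n) == pytest.approx(expected)

    def test_threshold_needs_two_events(self):
        with pytest.raises(ValueError):
            default_certainty_threshold(1)


def test_thresholds_validate():
    with pytest.raises(ValueError):
        MiningThresholds(d_max=0)
    with pytest.raises(ValueError):
        MiningThresholds(l_cert=0.0)
    assert MiningThresholds().h_conv == INF
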