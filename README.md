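# gatewaynet

Initiation rule mining over timestamped event histories, with a certainty
measure for screening candidate probabilistic-causal ("gateway") links, DOT
export of the resulting network, and a Markov-chain simulator for validation
data.

The motivating application is the *gateway hypothesis* in substance-use
epidemiology — does use of one drug raise the probability of later initiating
another? — with longitudinal urine-drug-screening records as the data
modality. Nothing in the library is specific to drugs, though: any collection
of per-subject sequences of discrete event sets can be mined.

## The model

A **history** is a sparse map `S : t ↦ S_t ⊆ E` from non-negative integer
time to a set of events; a **transaction database** `T` is a set of
histories. Write `S*_t` for the union of everything recorded up to `t`.

An **initiation rule** `a → b` holds in a history when `b` appears for the
first time immediately after a time by which `a` had already appeared: there
is a recorded time `u` with `b ⊆ S_u`, `a ⊆ S*_{<u}` and `b ⊄ S*_{<u}`. The
**windowed** form `a →ᶻ b` (z ≥ 1) restricts both the antecedent search and
the novelty test to the union over the `z` time units `[u−z, u−1]`, so
re-initiations after long gaps count again; `z = 0` denotes the unwindowed
relation. Rules with `b ⊆ a` are vacuously false and never proposed. The
degree of a rule is `max(|a|, |b|)`.

Rule support is the fraction of histories in which the relation holds.
Confidence, lift and conviction are the usual association-mining measures
computed from rule support and itemset supports (support is counted at the
history level: `sup(X) = |{S ∈ T : X ⊆ S*}| / |T|`). Two further quantities
drive causal screening:

    p(a → b)    = sup(a → b) / sup(b)
    cert(a → b) = p / (1 − p) = sup(a → b) / (sup(b) − sup(a → b))

`p` is the fraction of b-containing histories in which `b` was initiated by
`a`, and the **certainty** is its odds form: `cert > 1` means `a` explains
more than half of all initiations of `b`, and the rule is flagged as a
**gateway rule** `a ⤳ b`. When every instance of `b` follows `a`, certainty
approaches +∞. The chance-level cutoff for an alphabet of `|E|` events is
`1/(|E|−1)`.

Candidates are proposed with the a priori principle (itemset support is
anti-monotone) and screened by thresholds `l_count` (on `count(a ∪ b)`),
`l_sup`, `l_conf`, `l_lift` and conviction bounds `[l_conv, h_conv]`.

## Worked example

The built-in demonstration database has five histories over `{I1, I2, I3}`:

```python
>>> from gatewaynet import InitiationRuleMiner, rule_metrics, rule_count_support
>>> from gatewaynet.datasets import load_demo_transactions
>>> db = load_demo_transactions()
>>> miner = InitiationRuleMiner(l_sup=0.5, l_conf=0.5, l_lift=1.0, d_max=1).fit(db)
>>> miner.rules_.to_frame()[["antecedent", "subsequent", "support", "lift", "certainty", "is_gateway"]]
  antecedent subsequent  support  lift  certainty  is_gateway
0         I1         I3      0.6  1.25        inf        True
```

Of the six degree-1 candidates only `I1 → I3` survives: its support is 0.6
(it holds in 3 of 5 histories), its lift 0.6/(0.8×0.6) = 1.25, and since
every history containing `I3` had it initiated by `I1` (`sup(I3) = sup(I1→I3)
= 0.6`) the certainty is infinite — `I1 ⤳ I3` is a gateway. For comparison,
`cert(I1 → I2) = 0.6/(1−0.6) = 1.5` unwindowed, but within a window of
`z = 2` its support drops to 0.4 (one history's antecedent falls out of the
window) and the certainty to 0.4/0.6 ≈ 0.67 — no longer a gateway.

The same run from the shell, plus a rendered network:

```sh
gatewaynet mine --in txns.csv --l-sup 0.5 --l-conf 0.5 --l-lift 1 --d-max 1 \
    --rules-out rules.csv
gatewaynet network --rules rules.csv --mode highlight --out net.dot
```

Synthetic validation data comes from a first-order Markov chain over the
events plus a null state ε ("nothing happened"), built from per-event
*affinity* (self-transition tendency) and *interest* (attraction weight)
parameters:

```sh
gatewaynet simulate --events 12 --histories 8192 --seed 7 \
    --out txns.csv --chain-out chain.csv
```

Every subcommand is deterministic given its flags and seed, and writes a JSON
run manifest beside its output.

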