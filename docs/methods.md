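# Methods

This note documents the semantics the package implements, the parameters
that matter, the synthetic-data generator, and the places where the design
was genuinely open.

## Initiation relation semantics

The unwindowed relation `a → b` is evaluated per history as: there exists a
recorded time `u` with `b ⊆ S_u`, `a ⊆ S*_{<u}` (the union of all itemsets
recorded strictly before `u`) and `b ⊄ S*_{<u}`. Scanning only recorded
times is equivalent to the disjunction over all integer times, because the
subsequent condition `b ⊆ S_{t+1}` can only be met at a recorded time; the
test suite verifies this equivalence against a brute-force oracle that
enumerates every integer time.

For the windowed relation `a →ᶻ b` (z ≥ 1) the antecedent scope is the union
over the `z` time units `[u−z, u−1]`, and — deliberately — the novelty test
`b ⊄ ·` is applied against *that same window*, not against the full past.
This means an event re-occurring after a gap longer than `z` counts as a
fresh initiation, which is the stated purpose of windowing (discounting
associations across long gaps). A consequence worth knowing: windowed rule
sets are *not* guaranteed to be subsets of the unwindowed rule set, because a
subsequent that occurred long before the window can become "novel" again; we
therefore do not assert subsetness as an invariant.

Rules with `b ⊆ a` are vacuously false (the scope that contains `a` contains
`b`, defeating novelty) and are pruned at candidate-proposal time.

### Known inconsistencies in the published worked example

The five-history demonstration database has a published companion table of
windowed (z = 2) counts that literal evaluation under the semantics above
does not fully reproduce: the printed count for `I1 →² I3` is 3 where literal
evaluation gives 2, and for `I2 →² I3` it is 2 where literal evaluation gives
1 (in both cases the window `[2, 3]` before the subsequent at `u = 4` in
history 5 is empty). The same table also prints a *windowed itemset count*
for `{I1, I2}` of 3 versus the unwindowed table's 4, although itemset counts
cannot depend on `z` — so that table appears to have been computed under some
other, unrecoverable convention. The prose walkthrough of history 3
(`sup(I1 →² I2) = 0.4`) *is* reproduced exactly by our semantics, and no
single alternative window convention we tried reproduces both the table and
the walkthrough; we follow the walkthrough and the windowed definition as
written. The discrepant cells are excluded from the test suite by design.

## Rule support

Rule support is the fraction of histories in which the initiation relation
holds. An alternative definition sometimes written as `sup(a → b) =
sup(a ∪ b)` is inconsistent with the demonstration values
(`sup({I1, I2}) = 0.8` while `sup(I1 → I2) = 0.6`) and would make support
independent of temporal order; the co-occurrence count `count(a ∪ b)`
survives only as inclusion criterion (i), a sample-size floor. A mined rule
must additionally hold in at least one history: zero-support candidates are
never emitted even at fully permissive thresholds.

## Metrics and degenerate cases

With `n = |T|` histories, all supports are exact small rationals `k/n`.
Confidence, lift and conviction follow the standard definitions on rule
support; `p(a→b) = sup(a→b)/sup(b)`; certainty is `p/(1−p)`. Two ratios can
degenerate:

* conviction is +∞ when confidence = 1 (including the 0/0 case sup(b) = 1,
  confidence = 1, by convention);
* certainty is +∞ when `sup(b) = sup(a→b)` — every instance of the
  subsequent was initiated by the antecedent.

Infinities are carried as IEEE `inf` and serialized as the literal string
`inf` in rule CSVs. Threshold comparisons are exact `>=`/`<=` on double
precision with no epsilon: all quantities involved are ratios of small
integers and the thresholds users set (0, 0.05, 0.25, 1.0, …) are intended
as exact cutoffs. The gateway test `cert > l_cert` is strict; `l_cert`
defaults to 1 (the "explains more than half of all initiations" point), and
`default_certainty_threshold(|E|) = 1/(|E|−1)` gives the chance-level floor.

## Mining procedure

Frequent itemsets are enumerated levelwise (size-k candidates are unions of
frequent (k−1)-sets with frequent 1-sets), exact counts recomputed per
candidate; anti-monotonicity makes the pruning sound and is property-tested.
Candidates are all ordered pairs of frequent itemsets with
`max(|a|,|b|) ≤ d_max` and `b ⊄ a`, in canonical (sorted-labels) order.
Defaults: all threshold floors 0, `h_conv = ∞`, `l_cert = 1`, `d_max = 2`,
`z = 0`. Mining is deterministic and independent of input row order; rules
are reported sorted by (window, degree, antecedent labels, subsequent
labels).

Complexity is the a priori algorithm's: exponential in `d_max` in the worst
case, linear in histories and in recorded times per history for each
candidate. No FP-growth/vertical-format optimization is attempted.

## Gateway network rendering

Vertices are events; each rule contributes one edge holding its support
(pen width, `1 + 4·support`) and certainty. A rule of degree ≥ 2 cannot be a
plain edge, so its multi-event side becomes a boxed junction vertex labeled
`{x,y}`, tied to its constituent events by unweighted dotted member edges
(inbound for antecedents, outbound for subsequents); the weighted rule edge
connects the junction. If two rules map to the same (source, target) pair
the higher-certainty rule wins and a warning is logged.

The certainty gradient maps `log10(cert)` linearly from white (#FFFFFF) to
blue (#0000FF) between the smallest and largest finite gateway certainty in
the graph (+∞ saturates at blue; a degenerate spread anchors the ramp at
`[l_cert, 100·l_cert]`). Log scaling keeps certainties spanning ~0.6 to 30+
simultaneously visible. Serialization is deterministic (sorted vertices and
edges, fixed float formatting) so reruns are byte-identical. Layout and
rasterization are delegated to external GraphViz binaries.

## Synthetic-data generator

The generator emulates a population fixated on preferred events but prone to
experimentation. States are `E_0 = {ε} ∪ E` with ε the null event. The
pre-normalization matrix `P′` has the per-event *affinity* `a_i ∈ [0,1]` on
the diagonal; off-diagonal entries are drawn sequentially left-to-right,
each uniform on `[0, max(0, 1 − s_j·m)]` where `s_j ≥ 0` is the target
event's *interest* weight and `m` the row mass committed so far. This
reading of the generator recipe is isolated in one private function
(`_prenormalized_row`); since rows are renormalized afterwards, any reading
differing only by row scale is behaviorally equivalent. Rows of the built
chain sum to 1 within 1e−9. Externally supplied matrices are accepted with a
*warning* (not an error) when a row is off by more than 1e−6, because the
published sample matrix itself contains a row summing to 1.46.

History generation: state at t = 0 is ε (never recorded); at each step one
successor is drawn per event active at the previous step (from that event's
row; ε's row if none), topped up with independent ε-row draws until the
per-step draw count — uniform on {2, 3} by default — is reached. Null
outcomes record nothing; the union of non-null outcomes becomes `S_t`. A
history stops at 12 non-empty records or a horizon of 24 time steps,
whichever comes first (the record cap is part of the reference protocol; the
horizon is this package's choice, needed because a sticky null state could
otherwise wander indefinitely). Whether "2–3 initiations per time point"
means attempted draws or recorded novel events is ambiguous in the reference
protocol; we implement the draw-count reading, and the mechanism is a single
function that can be swapped.

Defaults are the reference study conditions: 12 events, 8192 histories,
max 12 records, ε self-affinity 0.75 (the published sample matrix's ε
diagonal). Affinities and interests default to independent Uniform(0, 1)
draws per event, since the reference protocol says only that the chain is
"randomly constructed". Under these defaults a full-scale run (8192
histories, seed 9) produced 98,304 records and a mean of ≈20.7 events per
history — denser than the reference protocol's reported 56,578 records and
≈2.5–3.6 events per history, whose realized (unpublished) chain evidently
returned to the null state far more aggressively (its printed sample matrix
sends `I1` back to ε with probability 0.9). The sanity test on event rate
therefore asserts only a broad plausibility band, [0.5, 25] mean events per
history, fixed before measurement. (The reference report is itself
internally inconsistent here, quoting 29,412 events over 8192 histories as
"2.49 per history" where the quotient is 3.59.)

What the generator does *not* emulate about real screening data: panel
false-positives, censoring between visits, medically administered events,
metabolite clearance-time bias, or era-dependent panels. Passing the
parameter-recovery tests therefore shows the miner detects structure the
chain actually encodes — not that it is robust to those artifacts.

### Planted-transition recovery

The recovery experiment plants `P(I1 → I2) = 0.9` (remainder uniform across
the other states) in a 3-state chain whose null row is sticky
(`ε→ε = 0.75`, leaking mostly to `I1`: 0.20, with 0.05 to `I2`), with a
uniform `I2` row. The sticky null row is essential and was chosen by
analysis, not tuning: with a uniform null row the target event appears
spontaneously at the first time step in roughly two-thirds of histories,
destroying novelty and capping certainty below 1 no matter how strong the
planted transition is. With the sticky row, `I2`'s first appearance almost
always follows `I1`, and mining 2000 simulated histories recovers
`I1 ⤳ I2` (certainty > 1) in 20 of 20 seeded replicates in the acceptance
battery.

## Preprocessing

Raw screening records arrive as (id, day number, minutes of day, item);
the absolute timestamp is `day·1440 + minutes`, each history is shifted so
its first record is t = 0, and coincident records merge by union. A helper
converts calendar dates to Lilian day numbers (day 1 = 1582‑10‑15) but is
off the critical path. Category remapping (e.g. METHAMPHETAMINE and MDMA →
AMPHETAMINES, METHADONE → OPIATES) collapses duplicates set-wise and is
idempotent. History admission requires ≥ 2 time points, ≥ 1 positive record,
and ≥ 1 record strictly after the first positive; "positive" is
parameterized as membership in a configurable positive-item set (default:
any item), since the original panel semantics are not reproducible without
the undeposited data. Any later time point satisfies the third condition,
positive or not — the literal reading. Post-mining, rules whose subsequent
intersects a banned label set (e.g. events known to be administered rather
than chosen) can be dropped; the intersection reading is deliberately
conservative for degree-≥2 subsequents.

## Problem sizes used in the checked examples

The worked-example checks run on the 5-history demonstration database; the
oracle-equivalence battery uses 200 random databases of ≤ 5 labels and ≤ 8
histories over times ≤ 10; parameter recovery uses 20 replicates of 2000
histories on a 3-state chain; the full-scale simulator invariants are
spot-checked at 512 histories with the 8192-history defaults exercised via
the CLI and available to users unchanged.

## Known limitations

* The windowed/unwindowed subset relationship does not hold in general (see
  above); consumers comparing windowed runs should compare rule sets, not
  assume monotonicity.
* Rule CSVs do not carry mining thresholds; re-loading a CSV for network
  rendering reconstructs rules but not full provenance (the JSON run
  manifest written by the CLI carries it instead).
* The miner is the plain a priori algorithm; alphabets beyond a few dozen
  events with `d_max > 2` will be slow.
* A first-order chain cannot encode multi-event antecedents, so degree-2
  rules mined from simulated data reflect co-occurrence dynamics, not
  planted joint causes.
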