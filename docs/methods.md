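# Methods

## Scope and model

`decidenet` implements the backend of a collaborative decision-analysis
workflow for wildlife management: it converts one stakeholder elicitation
(a *session*) into an exact expected-utility comparison of two resource
allocations over a fixed-topology Bayesian decision network. The network
has one decision node (two options), 0–2 binary external-factor nodes, 3–6
binary objective nodes (achieve / fail the desired condition), three binary
sustainability-dimension nodes (up-or-stable / decrease), and one utility
node over the 8 joint dimension states. Objectives and dimensions are
conditionally independent given the option and the external-factor scenario
assignment; a dimension's probability of staying up-or-stable is the
unweighted mean of its objectives' achievement probabilities, which assumes
each objective influences its dimension equally.

No inference engine is needed: the state space is at most 2^11, so all
expectations are exact enumerations in linear probability space.

## Scale mappings

All user entries are 5-point scores. Three lookup tables convert them:

| table | default | role |
| --- | --- | --- |
| importance | 0, 25, 50, 75, 100 % | objective importance → weight |
| uncertainty | 1.0, 0.875, 0.75, 0.625, 0.5 | score → Pr(anticipated scenario) |
| prediction | 0.1, 0.3, 0.5, 0.7, 0.9 | score → Pr(achieve desired condition) |

The importance quarters are fixed by the elicitation design. The two
probability tables are conventions of this package: the uncertainty map
descends in quarter-of-a-half steps so that maximal uncertainty (5) means
equiprobable scenarios, mirroring the quarter structure of the importance
scale; the prediction map is the symmetric linear ramp 0.1 + 0.2·(s−1),
centred on the neutral midpoint 0.5 and deliberately avoiding degenerate
0/1 probabilities so that no single entry can make an outcome certain.
Both tables can be overridden in the run configuration (monotonicity and
range are enforced at construction), and every report records the mapping
actually used.

The first label of a session's `scenario_pair` is *defined* as the
anticipated trajectory — the one favoured at uncertainty scores below 5.
This convention is stored in the session file itself, so a session is
self-describing.

## Utility construction

Per stakeholder group: each dimension is scored by the mean importance
percent of its 1–2 objectives; the 8 joint states are ordered by *badness*
— the summed scores of the decreasing dimensions — ranked 1..8 with tie
averaging, and mapped to utility along the exact line through (1, 100) and
(8, 0), U = 100·(8−r)/7. The rounded two-decimal form of this line
(intercept 114.29, |slope| 14.286) is available as the
`printed_coefficients` mode; the two differ by under 0.01 utility units.

Badness as the ordering criterion is this package's design choice; the
four-step procedure it implements leaves the criterion implicit, and
badness reproduces all of the procedure's published tie examples. Ties in
badness are detected by exact equality (safe on the quarter grid;
overridden real-valued mappings use a 1e-9 tolerance). Two tie policies:

* `midrank` (default): every group of badness-tied states receives the mean
  of the integer ranks it spans; midranks always sum to 36.
* `paper_literal`: identical to midrank except when exactly two dimension
  scores tie, where the positional rank table (1, 1.5, 1.5, 3.5, 5.5, 6.5,
  6.5, 8) is applied along the badness order. These half-step adjustments
  are reproduced as a lookup because they follow from no ordering we could
  derive, and the resulting table is *not* additive despite being motivated
  as preserving additivity. With all-distinct scores both policies coincide
  (ranks 1..8); with a three-way tie both give (1, 3, 3, 3, 6, 6, 6, 8).

Within equal badness the listing order puts states with fewer decreasing
dimensions first (then a fixed lexicographic key), matching the published
two-tie state numbering; under midrank this order never affects results.

### Degenerate importance

A dimension whose objectives all score importance 1 has weight 0, so states
differing only in that dimension tie in badness and share a rank. The
stakeholder is then genuinely indifferent, and the averaged utility
reflects that — but the global anchors U(all-up)=100 / U(all-down)=0 hold
only when every dimension score is positive. This is the faithful reading
of rank-averaging; we did not add an artificial tie-break that would value
a zero-importance dimension.

### Additive decomposition

`additive_decomposition` fits U(state) ≈ c + Σᵢ Uᵢ(stateᵢ) over the 8
states by least squares and reports the maximal absolute residual. The
expected-utility form that multiplies per-dimension marginals by
per-dimension utilities (`expected_utility_additive`) uses this fit; it
equals the canonical joint computation exactly when the table is additive
and otherwise deviates by at most the residual (a three-way-tie table, for
example, has residual 25/7 ≈ 3.57). The canonical joint computation is the
default everywhere because the rank-based table is generally non-additive.

## Aggregation and recommendation

Per option, expected satisfaction is computed once per stakeholder group
(each group's own importance entries, shared predictions). The aggregate is
a weighted mean with weights proportional to the importance percent of each
group's elicited relative-importance score, the focal user entering at the
maximum score's weight; `unweighted` averages all groups equally (both
readings of "averaged across stakeholder groups" are defensible, so both
are exposed, weighted by default). Options whose expected utilities agree
within 1e-9 are reported as "no preference", never tie-broken.

## EVPI

For the focal user, the expected value of perfect information about factor
F is Σ_b Pr(b)·max_k E(U_k | F=b) − max_k E(U_k), computed by clamping F's
scenario distribution and re-enumerating. It is non-negative by
construction; values within 1e-9 of zero are reported as exactly 0.

## Synthetic sessions

No deposited elicitation data exist, so the generator emulates a workshop:
5-point scores drawn from a mildly centre-peaked categorical distribution
(0.10/0.20/0.30/0.25/0.15 — facilitated groups avoid scale endpoints),
defaults at the maximal configuration (2 objectives per dimension, 2
external factors, 6 stakeholder groups, 3 actions per option), integer
allocation percentages from largest-remainder rounding of random weights,
and either trajectory of a scenario pair as the anticipated one. One seeded
`numpy` stream drives each call; the seed is stored in the emitted
session's metadata. What the generator does **not** emulate: response
biases, correlated scores within a stakeholder group, strategic scoring,
or free-text content — passing tests therefore demonstrate the arithmetic
and its invariances, not the behaviour of real elicitations.

## Numerical choices and verification

Probabilities combine in linear space (the joint space is ≤ 2^11, so no
underflow). The modular expected-utility computation is verified against a
brute-force enumeration of the full joint distribution of every stochastic
node on 100 seeded synthetic sessions spanning all admissible
configurations, to 1e-9 — that scale runs in seconds and already covers the
complete discrete topology space, so nothing larger is informative.
Allocation sums are checked to 1e-9; a zero allocation to a selected action
is a validation error (selecting an action implies investing in it).

## Known limitations

* The probability tables behind the uncertainty and prediction scales are
  conventions; analyses intended to match another implementation of this
  workflow must override them with that implementation's constants.
* The bundled factor catalog's entry texts are representative placeholders;
  the counts (24 objectives split 7/7/10, 8 external factors, 21 actions,
  6 stakeholder groups) are structural, the wording is not.
* The network topology is fixed; this is not a general Bayesian-network
  library, and CPTs are never learned from data.
* Utilities are rank-based and piecewise flat in importance: small changes
  in importance scores that do not reorder the dimensions do not change the
  utility table.
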