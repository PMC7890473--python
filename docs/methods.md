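# Methods

## Model

`ordpred` studies short-term prediction of a univariate series through its
*ordinal patterns*. A window of D consecutive values (time delay τ between
elements) is replaced by the permutation of its ranks — for the D = 3, τ = 1
case the package centres on, one of six patterns, coded 1–6 in
lexicographic order:

```
1 = {0,1,2}  2 = {0,2,1}  3 = {1,0,2}  4 = {1,2,0}  5 = {2,0,1}  6 = {2,1,0}
```

Because consecutive windows share D − 1 values, a pattern can be followed
by only D of the D! patterns (the *legal-transition graph*): the successor's
first D − 1 ranks must order-match the predecessor's last D − 1 ranks, and
the only freedom is the rank slot of the newly arrived value. At D = 3 each
pattern has exactly 3 legal successors (half the alphabet), only the two
monotone patterns {0,1,2} and {2,1,0} may repeat, and two of the three
successors of {0,1,2} imply that the next raw value falls. The graph is
3-regular in both directions.

Patterns split into *upward waves* (last rank above first: codes 1–3) and
*downward waves* (codes 4–6); the rank complement r → 2 − r (flipping the
series upside down) exchanges the clusters.

### Features of an epoch

For a target window starting at raw index t, the *epoch* is the stretch of
`epoch_len` raw values ending at index t − 1, so epoch and target never
share a value. PRE is the pattern of the window starting at t − 1; it
necessarily shares two values with the target (that overlap is the point —
it carries the transition constraint) and one with the epoch.

From the epoch we compute:

* **TPS** — the 18 legal-cell transition probabilities. The joint
  estimate n_ij / n_transitions is the default feature set; row-normalised
  conditional probabilities are available via `tps_mode="conditional"`
  (summary tables always report conditionals). An `epoch_len` of N values
  yields N − 2 patterns and N − 3 transitions, so at N = 10 most cells are
  zero; features are reported raw, without shrinkage — sparsity is the
  classifier's problem, and smoothing the features would leak a prior the
  short-memory setting does not grant.
* **IRR** — KL(forward ‖ backward) between the pattern distribution of the
  epoch and that of the epoch read in reverse, in nats. Both 6-bin count
  vectors get additive (Laplace) smoothing α before normalisation, so the
  divergence is finite even for degenerate epochs; α = 1 by default and
  configurable. The forward distribution is the reference because the
  backward reading is the probe. For tie-free data the backward histogram
  equals the forward one with every pattern rank-reversed, which the batch
  path does *not* exploit: it encodes the reversed series once, so ties are
  handled identically to the definition.
* **IRR_SYM** — per pattern, the ratio of conditional transition mass
  leaving its wave cluster to the mass staying inside it; the scalar score
  is the arithmetic mean of the six components (components are also exposed
  individually — they are the feature set of the trend analyses). The same
  α smooths each row's three legal cells; the out/in ratio is invariant to
  row normalisation, so it is computed directly from counts as
  (out + α·n_out)/(in + α·n_in). With α = 0 an unobserved row raises
  rather than silently fabricating a value.

### Experiment protocol

Targets are sampled by their own pattern code, `n_per_class` per class
(default 10 000 → 60 000 rows, 1/6 ≈ 17% per class), uniformly without
replacement among positions with a full epoch, a PRE window and a complete
target window. Labels derived from each target: its code (analysis 1);
up-wave-after-up-wave and down-after-down flags comparing PRE's and the
target's clusters (analyses 2a/2b, fitted separately); and UP — whether the
raw value after the shared pair exceeds its predecessor, i.e.
v[t+2] > v[t+1] with ties counting as not-up (analysis 3).

The design matrix one-hot-encodes PRE (fair to the linear learner; trees
are indifferent) and appends the analysis-specific epoch features. Rows are
split 64/16/20 into train/validation/test, stratified by label, with
seeded, reproducible partitions. Gradient boosting (the default learner)
spends the validation fraction on early stopping via its internal holdout;
logistic regression, a shallow decision tree (a rule-list stand-in),
k-nearest-neighbours and random forest train on the training rows alone.
Metrics are macro-averaged precision and recall and macro one-vs-rest AUC
(classes are balanced by design, so macro ≈ micro), next to the chance
baseline — 1/k for the k-class task, positive prevalence for the binary
ones. Tree ensembles additionally report relative feature influences
normalised to sum to 100.

### The Analysis-1 precision floor

A subtlety worth stating plainly: on *any* data, PRE alone confines the
target to its three legal successors, and on exchangeable (IID) data the
new value falls into each rank slot with probability (1/4, 1/4, 1/2) —
balanced resampling preserves this because raw class frequencies are
uniform. The Bayes-optimal per-PRE guess is then a bijection onto the six
classes, each correct half the time, so Analysis-1 macro precision sits
near 0.5 even with a completely uninformative epoch. Precision near the
1/6 class rate is therefore *not* the no-signal reference for Analysis 1;
the transition constraint itself is a predictor. Epoch features matter at
the margin above that floor.

## Synthetic generators

Real minute-price data is not redistributable here, so every stage runs on
seeded generators that plant the structure the method is meant to detect:

* `iid_noise` — exchangeable Gaussian draws: uniform pattern law,
  reversible; the null for every score.
* `random_walk` — cumulated Gaussian steps: monotone patterns at 1/4,
  mixed at 1/8 (two same-sign steps vs opposite signs plus a magnitude
  ordering), reversible, self-loop-enriched; the price-like null.
* `asymmetric_wave(theta)` — a zero-drift walk with frequent small
  up-steps (probability 1/2 + 0.35·θ, exponential mean 1) and rare large
  down-steps (mean balancing the drift): slow rises, sharp falls. θ = 0 is
  an exactly symmetric, reversible walk; both irreversibility scores rise
  strictly in θ (measured over 20 seeds at n = 20 000: mean IRR
  0.0005 → 2.75, mean IRR_SYM 0.84 → 1.38). A deterministic sawtooth was
  rejected for this role: its peak and valley patterns have essentially no
  in-cluster transition mass, so the IRR_SYM denominator is carried by the
  smoothing constant alone and the score becomes a count artefact that
  *falls* as θ grows.
* `pattern_markov(M)` — samples a chain over the six patterns from a
  row-stochastic matrix supported on the legal graph, then renders values
  so each window realises its pattern exactly: the new value goes to the
  midpoint of the admissible interval between the two shared values, or
  one unit beyond the running extreme when the interval is half-infinite
  (linear growth; repeated midpoint insertion can shrink intervals
  geometrically, but runs long enough to underflow are astronomically rare
  for non-degenerate matrices). Re-encoding the emitted series returns the
  sampled chain exactly, every run. Seeded with the transition matrix
  measured on a year of minute-resolution Bitcoin closing prices
  (`BITCOIN_MINUTE_TPM`; its one 0.99-sum row is renormalised), this is the
  study stand-in: it reproduces that dataset's published pattern
  frequencies and transition table to within Monte-Carlo error.

What the generators do *not* emulate: volatility clustering, heavy-tailed
and autocorrelated step sizes, intraday seasonality, data gaps, repeated
(tied) prices, and any dependence of transition probabilities on history
beyond one pattern. Passing tests therefore demonstrate that the machinery
recovers planted ordinal structure, not that real markets carry it.

## Numerical and interface choices

* Ties: the earlier element takes the lower rank (stable argsort) — the
  standard convention; generators emit tie-free series so property tests
  are never contaminated by the rule. Note the rule makes tied steps count
  as "increase" patterns while the UP label counts ties as not-up.
* Windows are indexed by the 0-based position of their first element;
  a series of length N yields N − (D−1)τ windows.
* Legality is derived from the overlap rule for any D (τ = 1 only; τ > 1
  has a different constraint structure and is out of scope); the D = 3
  table is additionally pinned as a regression fixture in the tests.
* Pattern serialisation: rank strings "{0,1,2}" and integer codes 1–6;
  feature columns are `pre`, `tps_<i>_<j>` (18), `irr`, `irr_sym`,
  `irr_sym_c1..c6`.
* Timestamps are metadata; gaps in a loaded CSV are reported (count,
  location, missing steps against the modal interval) but never imputed.
* Desk-scale defaults in the analysis scripts and tests: series of
  2×10⁴–2×10⁵ values and 500–1 000 targets per class, which puts
  Monte-Carlo noise on pattern frequencies below ±0.01 and keeps any
  single experiment in seconds. The full 10 000-per-class protocol runs
  unchanged when pointed at a year of minute data.

## Limitations

Single univariate series; D fixed at 3 for everything beyond the
combinatorics; no surrogate-based significance testing of the
irreversibility scores; no hyperparameter search (classifiers run at
library defaults plus early stopping); classifier results on synthetic
data characterise the pipeline, not any market.
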