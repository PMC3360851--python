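# Methods

## Model

A two-arm trial with a binary endpoint is modelled as two independent
binomial samples: events `a ~ Bin(n, p_exp)` in the experimental arm and
`c ~ Bin(m, p_ctrl)` in the control arm. All effect measures are
functions of the two event proportions; no time-to-event structure is
modelled (hazard-ratio-based or person-time NNTs are out of scope — an
NNT here always refers to a fixed trial horizon against a stated
comparator).

### Sign conventions

Efficacy endpoints: ARR = control rate − experimental rate, positive when
the experimental arm does better. Harm endpoints: difference =
experimental − control, positive when the experimental arm causes more
adverse events. A difference that is negative in the stated direction is
reported as `not_applicable` (the "NA" cell of a benefit/harm ledger)
rather than a negative NNT; exactly zero gives an `infinite` status.
Swapping the arms converts a finite benefit into `not_applicable` and
vice versa — this symmetry is property-tested.

### Rounding

NNT integers use the ceiling of the reciprocal by default: ⌈1/ARR⌉ is the
smallest number of patients whose expected averted events reach one,
which a brute-force search over k = 1, 2, … confirms in the tests. An
exactly integer reciprocal stays (1/0.10 → 10). Published tables often
round to nearest instead, so a `rounding="nearest"` mode exists, and the
unrounded reciprocal is always carried in the result so display rounding
never propagates into downstream arithmetic.

### Exact printed-percentage arithmetic

Rates given as printed percentages are stored as `fractions.Fraction`
(e.g. 30.7 % → 307/1000). Differences and reciprocals of such rates are
exact rationals, which removes the float-tie hazard in ⌈1/ARR⌉ (in
binary floating point, 0.35 − 0.25 is slightly below 0.1 and its ceiling
reciprocal would be 11, not 10). For float inputs the reciprocal is
snapped to an integer when within a 1e-9 relative tolerance before the
ceiling. When a table is built from rates, counts are reconstructed as
round(rate × size) (half away from zero) and flagged; point estimates
always use the supplied rates, and the reconstructed counts serve only
for interval estimation.

## Interval estimation

* Risk difference: Wald, `diff ± z·√(p̂ₑ(1−p̂ₑ)/n + p̂𝒸(1−p̂𝒸)/m)`, as the
  default — the reciprocal NNT-interval construction presumes a symmetric
  difference interval. The Newcombe hybrid-score interval
  (statsmodels implementation) is available for small samples.
* RR and OR: log-normal approximation, `exp(log Est ± z·SE)` with the
  usual delta-method standard errors. With a zero cell the point is
  undefined and an `UndefinedRatioError` is raised; an opt-in 0.5
  continuity adjustment to all cells rescues the interval (and the point
  only when no unadjusted point exists — point estimates are never
  silently adjusted). Adjusted limits are clamped to bracket the
  unadjusted point.
* NNT/NNH interval: reciprocals of the difference limits,
  (⌈1/upper⌉, ⌈1/lower⌉) when both are positive. When the difference
  interval contains zero the NNT interval is (⌈1/upper⌉, ∞) with an
  explicit `spans_zero` flag: the comparison is not significant at that
  level, but the point NNT is still reported because published analyses
  do exactly that "for comparative purposes" — the flag preserves both
  readings. Both limits negative: bounds are reported on the opposite
  (harm/benefit) side.
* Default level 0.95 throughout.

## Ledger reproduction and match classification

The embedded fixtures carry the printed one-decimal percentages and arm
sizes of the three denosumab vs. zoledronic-acid SRE-prevention trials
(efficacy and safety populations differ in size and are kept separately).
Each recomputed cell is classified against the published integer:

* `exact` — identical;
* `off_by_rounding` — within ±1 (ceiling vs round-to-nearest ambiguity);
* `mismatch` — further off: the publication evidently computed from
  unrounded source rates (prostate bone surgery 317, cord compression 96,
  fracture 163) or misprinted (other-tumors hypocalcemia NNH 5, where the
  printed 5.0 % difference implies 20);
* `na_match` — negative difference correctly printed as NA.

Mismatching cells are flagged and logged, never corrected, since the
point of the pipeline is to audit printed tables. The ±1 tolerance
deliberately separates rounding-convention ambiguity from genuine
unrounded-source discrepancies. The one non-significant any-SRE
comparison is computed anyway but stamped with `significance_note`.

## Synthetic trials

`simulate_trial` draws the two arms as independent binomials — exactly
the model above — and `simulate_endpoint_panel` produces multi-endpoint
ledgers in the same schema the reproduction pipeline consumes. One
top-level seed with per-scenario substreams (seed + index) keeps panels
extensible without perturbing earlier rows. The generator does **not**
emulate within-patient correlation between endpoints, informative
dropout, or time-to-event structure; passing tests therefore demonstrate
correctness of the estimators under independent binomial sampling, not
robustness to those real-data features.

## Monte-Carlo experiments

* `coverage_experiment`: replicate trials, Wald difference interval per
  replicate, empirical coverage of the true ARR and of the true NNT by
  the reciprocal interval (a spans-zero replicate covers when the true
  NNT exceeds its finite benefit-side bound). Monte-Carlo SE
  √(p(1−p)/reps) is reported. Default 5,000 replicates — sub-second,
  with MC SE ≈ 0.003 at 95 % coverage.
* `nnt_sampling_distribution`: median and IQR of the replicate point
  NNTs; replicates with zero or negative observed differences are
  tallied as separate proportions, never averaged into the location
  summary (the mean of a reciprocal near zero is undefined in any useful
  sense).
* `extrapolation_bias`: applying a trial RRR at other baseline risks
  gives implied ARR = RRR × baseline and implied NNT ⌈1/(RRR·baseline)⌉;
  the ratio of raw reciprocals to the trial's own baseline is identically
  trial_baseline / baseline, which quantifies how an NNT quietly inflates
  when a relative effect from a high-risk trial population is applied to
  lower-risk patients.

## Numerical and design choices

* Exact rational arithmetic wherever inputs admit it; floats only inside
  interval formulas and simulations.
* z-quantiles from `scipy.stats.norm`; vectorized numpy binomial
  simulation with `default_rng` for reproducibility.
* Simulation sizes in the test and acceptance runs (5,000 replicates,
  arms up to 10,000) were chosen as desk-scale settings where binomial
  Monte-Carlo error is well below the assertion bands.
* Known limitations: no survival/person-time NNT, no exact
  (Clopper–Pearson-style) or Bayesian intervals, no correlated
  endpoints, no meta-analysis across trials.
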