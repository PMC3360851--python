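# nnt-bench

Effect measures for two-arm clinical trials with binary endpoints, built
around the **number needed to treat (NNT)** and **number needed to harm
(NNH)**, with exact reproduction of published benefit/harm ledgers and
Monte-Carlo diagnostics of the estimator.

It is written for biostatisticians, pharmacists, and clinical-evidence
reviewers who need to turn the event percentages printed in a trial report
into interpretable benefit/harm numbers — and to know when those numbers
are fragile.

## The statistics

For a 2×2 table with `a` events among `n` experimental-arm patients and
`c` events among `m` control-arm patients:

| measure | definition |
|---|---|
| relative risk | RR = (a/n) / (c/m) |
| relative risk reduction | RRR = 1 − RR |
| absolute risk reduction | ARR = c/m − a/n (efficacy orientation) |
| odds ratio | OR = (a·d) / (b·c) |
| number needed to treat | NNT = ⌈1 / ARR⌉ for ARR > 0 |
| number needed to harm | NNH = ⌈1 / (a/n − c/m)⌉ for an adverse-event excess |

A negative difference in the stated direction yields **NA** (not
applicable), a zero difference yields an infinite NNT. Confidence limits
for the NNT are the reciprocals of the risk-difference confidence limits
(Wald by default, Newcombe hybrid-score optional); when that interval
contains zero the NNT interval runs through infinity and carries an
explicit spans-zero flag. Integer NNTs are rounded **up** by default
(`rounding="nearest"` is available), and the unrounded reciprocal is always
reported alongside.

Rates supplied as printed percentages (e.g. "30.7 %") are stored as exact
rationals, so reproduction of published tables is exact, not approximate.

## Worked example

```python
from nntbench import TwoArmBinomial

res = TwoArmBinomial.from_counts(25, 75, 35, 65).fit()
print(res.summary())
```

```
Two-arm binomial effect measures
========================================================
events/size   experimental 25/100   control 35/100
event rate    experimental 0.2500   control 0.3500
CI method: wald (difference), log-normal (ratios); level 95%
--------------------------------------------------------
Relative risk             0.7143  [0.4637, 1.1002]
Rel. risk reduction        28.6%  [-10.0%, 53.6%]
Risk difference            10.0%  [-2.6%, 22.6%]
Odds ratio                0.6190  [0.3359, 1.1408]
NNT                           10  [5, Inf]  (CI spans zero)   (1/diff = 10.00)
========================================================
```

Reading: the experimental arm cut recurrence from 35 % to 25 %, a relative
risk of 0.71 (29 % relative reduction) and an absolute reduction of 10
percentage points, so about 10 patients must be treated to avert one
event. At 100 patients per arm, however, the 95 % risk-difference interval
crosses zero, so the NNT interval runs from 5 through infinity — a single
printed "NNT = 10" would hide that instability.

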