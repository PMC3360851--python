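"""Monte-Carlo experiments on the NNT estimator and its interval.

Quantifies behaviour a single printed NNT hides:

* ``coverage_experiment`` — frequentist coverage of the risk-difference
  confidence interval and of the reciprocal NNT interval built from it;
* ``nnt_sampling_distribution`` — the sampling distribution of the point
  NNT, which is the reciprocal of a noisy difference and therefore heavy
  tailed and unstable when the true difference is near zero (replicates
  whose observed difference is zero or negative are tallied separately,
  never averaged in);
* ``extrapolation_bias`` — how the NNT implied by a fixed relative risk
  reduction inflates as the baseline risk falls (closed form: implied NNT
  scales as 1/baseline, so the ratio to the trial's own NNT is exactly
  trial_baseline / baseline).

All experiments are vectorized binomial simulation, deterministic under
the scenario seed, and report the Monte-Carlo standard error of coverage
proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .measures import nnt, nnt_from_baseline
from .simulate import TrialScenario

__all__ = [
    "SimulationReport",
    "coverage_experiment",
    "nnt_sampling_distribution",
    "extrapolation_bias",
]


@dataclass(frozen=True)
class SimulationReport:
    """Aggregate results of a replicated two-arm simulation.

    Coverage fields are proportions over replicates; ``nnt_coverage`` and
    ``median_nnt`` are None when the true difference is not positive (no
    true NNT exists).  ``mc_se_coverage`` is sqrt(p(1-p)/reps) at the
    estimated ARR coverage.
    """

    scenario: TrialScenario
    replicates: int
    seed: int
    coverage: Optional[float] = None
    nnt_coverage: Optional[float] = None
    median_nnt: Optional[int] = None
    iqr_nnt: Optional[Tuple[float, float]] = None
    prop_spans_zero: Optional[float] = None
    prop_not_applicable: Optional[float] = None
    prop_infinite: Optional[float] = None
    mc_se_coverage: Optional[float] = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for nm in ("coverage", "nnt_coverage", "prop_spans_zero",
                   "prop_not_applicable", "prop_infinite"):
            v = getattr(self, nm)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be a proportion in [0, 1], got {v}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenario"] = asdict(self.scenario)
        return d


def _replicate_cis(s: TrialScenario, reps: int, level: float):
    """Vectorized Wald machinery shared by the experiments."""
    rng = np.random.default_rng(s.seed)
    a = rng.binomial(s.n_exp, s.p_exp, size=reps)
    c = rng.binomial(s.n_ctrl, s.p_ctrl, size=reps)
    pe = a / s.n_exp
    pc = c / s.n_ctrl
    arr = pc - pe
    se = np.sqrt(pe * (1 - pe) / s.n_exp + pc * (1 - pc) / s.n_ctrl)
    z = float(norm.ppf(0.5 + level / 2.0))
    return arr, arr - z * se, arr + z * se


def _ceil_reciprocal_array(x: np.ndarray) -> np.ndarray:
    """ceil(1/x) elementwise for positive x, snapping near-integer
    reciprocals before the ceiling (same tie rule as measures.nnt)."""
    r = 1.0 / x
    nearest = np.rint(r)
    snapped = np.isclose(r, nearest, rtol=1e-9)
    return np.where(snapped, nearest, np.ceil(r))


def coverage_experiment(
    s: TrialScenario, reps: int, level: float = 0.95
) -> SimulationReport:
    """Estimate coverage of the Wald ARR interval and of the reciprocal
    NNT interval under repeated sampling from the scenario.

    A replicate's NNT interval contains the true NNT if the true value lies
    between the reciprocal bounds; spans-zero replicates cover whenever the
    true NNT exceeds their finite benefit-side bound (their upper bound is
    infinity).  Replicates are never discarded.
    """
    if reps < 100:
        raise ValueError("coverage estimation needs reps >= 100")
    true_arr = s.true_arr
    arr, lower, upper = _replicate_cis(s, reps, level)
    covered = (lower <= true_arr) & (true_arr <= upper)
    coverage = float(np.mean(covered))
    spans = (lower < 0) & (upper > 0)

    nnt_cov = None
    median = None
    iqr = None
    if true_arr > 0:
        true_nnt = nnt(true_arr).value
        contains = np.zeros(reps, dtype=bool)
        pos_lo = lower > 0
        if np.any(pos_lo):
            lo_b = _ceil_reciprocal_array(upper[pos_lo])   # lower NNT bound
            hi_b = _ceil_reciprocal_array(lower[pos_lo])   # upper NNT bound
            contains[pos_lo] = (lo_b <= true_nnt) & (true_nnt <= hi_b)
        span_pos = spans & (upper > 0)
        if np.any(span_pos):
            lo_b = _ceil_reciprocal_array(upper[span_pos])
            contains[span_pos] = lo_b <= true_nnt
        nnt_cov = float(np.mean(contains))
        finite = arr > 0
        if np.any(finite):
            pts = _ceil_reciprocal_array(arr[finite])
            median = int(np.median(pts))
            iqr = (float(np.quantile(pts, 0.25)), float(np.quantile(pts, 0.75)))

    return SimulationReport(
        scenario=s,
        replicates=reps,
        seed=s.seed,
        coverage=coverage,
        nnt_coverage=nnt_cov,
        median_nnt=median,
        iqr_nnt=iqr,
        prop_spans_zero=float(np.mean(spans)),
        mc_se_coverage=math.sqrt(coverage * (1 - coverage) / reps),
    )


def nnt_sampling_distribution(
    s: TrialScenario, reps: int, level: float = 0.95
) -> SimulationReport:
    """Summarize the sampling distribution of the point NNT.

    The median and IQR are taken over replicates with a positive observed
    difference (finite NNT); zero and negative differences are reported as
    separate proportions because averaging an infinite or not-applicable
    NNT into a location summary is meaningless.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    arr, lower, upper = _replicate_cis(s, reps, level)
    finite = arr > 0
    zero = arr == 0
    neg = arr < 0
    median = None
    iqr = None
    if np.any(finite):
        pts = _ceil_reciprocal_array(arr[finite])
        median = int(np.median(pts))
        iqr = (float(np.quantile(pts, 0.25)), float(np.quantile(pts, 0.75)))
    return SimulationReport(
        scenario=s,
        replicates=reps,
        seed=s.seed,
        median_nnt=median,
        iqr_nnt=iqr,
        prop_spans_zero=float(np.mean((lower < 0) & (upper > 0))),
        prop_not_applicable=float(np.mean(neg)),
        prop_infinite=float(np.mean(zero)),
    )


def extrapolation_bias(
    rrr: float, trial_baseline: float, baseline_grid: Sequence[float]
) -> pd.DataFrame:
    """NNT implied by a fixed RRR across a grid of baseline risks.

    Columns: baseline, implied_nnt (integer, ceiling rule), raw_reciprocal
    (1/(rrr*baseline), unrounded) and ratio_to_trial (raw reciprocal over
    the raw reciprocal at the trial's own baseline — identically
    trial_baseline/baseline).
    """
    if not 0 < float(rrr) <= 1:
        raise ValueError(f"rrr must be in (0, 1], got {rrr!r}")
    ref = nnt_from_baseline(rrr, trial_baseline)
    rows = []
    for b in baseline_grid:
        res = nnt_from_baseline(rrr, b)
        rows.append({
            "baseline": float(b),
            "implied_nnt": res.value if res.status == "finite" else math.inf,
            "raw_reciprocal": res.raw_reciprocal,
            "ratio_to_trial": res.raw_reciprocal / ref.raw_reciprocal,
        })
    return pd.DataFrame(rows)
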