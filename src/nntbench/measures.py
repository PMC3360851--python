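"""Effect measures for two-arm binary endpoints.

Implements the classical 2x2 measures — relative risk (RR), relative risk
reduction (RRR = 1 - RR), absolute risk reduction (ARR), odds ratio (OR) —
and the number-needed-to-treat family built on the ARR:

* NNT = ceil(1 / ARR) with ARR = control rate - experimental rate
  (positive when the experimental arm does better on an efficacy endpoint);
* NNH uses the harm difference, experimental rate - control rate, so a
  positive value means the experimental arm causes more adverse events;
* NNT/NNH confidence limits are the reciprocals of the risk-difference
  confidence limits; when that interval spans zero the NNT interval runs
  through infinity and is flagged.

Sign conventions are fixed so that a negative difference in the stated
direction yields a ``not_applicable`` result (the "NA" cells of trial
benefit/harm ledgers) and a zero difference yields ``infinite``.

Interval methods: Wald (normal approximation) is the default for the risk
difference, with the Newcombe hybrid-score interval available for small
samples; ratio measures use the usual log-normal approximation.  Point
estimates are exact rationals whenever the table carries exact rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Literal, Optional, Tuple, Union

from scipy.stats import norm

from .tables import TwoByTwoTable, as_rate

__all__ = [
    "IntervalEstimate",
    "NNTInterval",
    "NNTResult",
    "UndefinedRatioError",
    "relative_risk",
    "relative_risk_reduction",
    "absolute_risk_reduction",
    "odds_ratio",
    "nnt",
    "nnt_interval",
    "nnh",
    "nnt_from_baseline",
]

RoundingMode = Literal["ceiling", "nearest"]
CIMethod = Literal["wald", "newcombe"]

#: relative slack when deciding whether 1/ARR hit an integer exactly,
#: so float inputs like ARR=0.10 give NNT 10, not 11
_TIE_RTOL = 1e-9


class UndefinedRatioError(ZeroDivisionError):
    """A ratio measure's denominator is zero and no continuity adjustment
    was requested."""


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with optional two-sided confidence limits.

    ``point`` may be an exact :class:`~fractions.Fraction` (tables built
    from printed percentages) or a float; the limits are floats.  ``scale``
    records whether the quantity lives on the probability-difference scale
    or the ratio scale.
    """

    point: Union[float, Fraction]
    lower: Optional[float] = None
    upper: Optional[float] = None
    level: float = 0.95
    scale: Literal["probability", "ratio"] = "probability"

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError(f"confidence level must be in (0, 1), got {self.level}")
        if self.lower is not None and self.upper is not None:
            if not (self.lower <= self.point <= self.upper):
                raise ValueError(
                    f"interval limits must bracket the point: "
                    f"{self.lower} <= {self.point} <= {self.upper} fails"
                )

    @property
    def has_limits(self) -> bool:
        return self.lower is not None and self.upper is not None


@dataclass(frozen=True)
class NNTInterval:
    """Confidence bounds for an NNT/NNH, each a positive integer or inf.

    ``spans_zero`` marks a risk-difference interval containing zero: the
    NNT interval then runs from the benefit-side bound through infinity
    (the NNTB-to-NNTH situation) and the comparison is not statistically
    significant at the interval's level.
    """

    lower: float  # int-valued or math.inf
    upper: float
    spans_zero: bool = False
    side: Literal["benefit", "harm"] = "benefit"


@dataclass(frozen=True)
class NNTResult:
    """An NNT or NNH with its status and provenance.

    ``status`` is ``finite`` (positive difference in the stated direction),
    ``not_applicable`` (difference runs the other way, the "NA" cell of a
    benefit/harm table) or ``infinite`` (difference exactly zero).
    ``raw_reciprocal`` keeps the unrounded 1/difference so that display
    rounding never contaminates downstream arithmetic.
    """

    value: Optional[int]
    status: Literal["finite", "not_applicable", "infinite"]
    direction: Literal["benefit", "harm"]
    raw_reciprocal: Optional[float] = None
    interval: Optional[NNTInterval] = None

    def __post_init__(self) -> None:
        if self.status == "finite":
            if self.value is None or self.value < 1:
                raise ValueError("finite NNT must be a positive integer")
        elif self.value is not None:
            raise ValueError(f"status {self.status!r} carries no integer value")


def _z(level: float) -> float:
    return float(norm.ppf(0.5 + level / 2.0))


def _adjusted_cells(t: TwoByTwoTable) -> tuple[float, float, float, float]:
    # 0.5 added to every cell; used for CI (and, when the user opts in,
    # point) computation in the presence of zero cells
    return t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5


def relative_risk(
    t: TwoByTwoTable, level: float = 0.95, continuity: bool = False
) -> IntervalEstimate:
    """Relative risk (a/n)/(c/m) with a log-normal confidence interval.

    Requires a non-zero control event rate; with ``continuity=True`` a 0.5
    adjustment to all cells rescues zero-cell tables (and is then used for
    the point as well, since the unadjusted point is undefined).  The CI is
    ``exp(log RR +/- z * sqrt(1/a - 1/n + 1/c - 1/m))`` and is omitted
    (limits None) when a = 0 or c = 0 without adjustment.
    """
    if t.ctrl_rate == 0 and not continuity:
        raise UndefinedRatioError("control event rate is zero; RR undefined")
    if t.c == 0 and t.ctrl_rate == 0:
        # only reachable with continuity on
        a, b, c, d = _adjusted_cells(t)
        point: Union[float, Fraction] = (a / (a + b)) / (c / (c + d))
    else:
        point = t.exp_rate / t.ctrl_rate

    lower = upper = None
    if continuity and (t.a == 0 or t.c == 0):
        a, b, c, d = _adjusted_cells(t)
        n, m = a + b, c + d
        se = math.sqrt(1 / a - 1 / n + 1 / c - 1 / m)
        center = math.log((a / n) / (c / m))
        lower, upper = math.exp(center - _z(level) * se), math.exp(center + _z(level) * se)
        lower = min(lower, float(point))
        upper = max(upper, float(point))
    elif t.a > 0 and t.c > 0:
        se = math.sqrt(1 / t.a - 1 / t.n + 1 / t.c - 1 / t.m)
        center = math.log(float(Fraction(t.a, t.n) / Fraction(t.c, t.m)))
        lower, upper = math.exp(center - _z(level) * se), math.exp(center + _z(level) * se)
        # keep the exact point inside float limits
        lower = min(lower, float(point))
        upper = max(upper, float(point))
    return IntervalEstimate(point, lower, upper, level, scale="ratio")


def relative_risk_reduction(
    t: TwoByTwoTable, level: float = 0.95, continuity: bool = False
) -> IntervalEstimate:
    """Relative risk reduction, 1 - RR, as a proportion.

    The CI maps the RR interval through x -> 1 - x (limits swap).
    """
    rr = relative_risk(t, level=level, continuity=continuity)
    lower = None if rr.upper is None else 1.0 - rr.upper
    upper = None if rr.lower is None else 1.0 - rr.lower
    return IntervalEstimate(1 - rr.point, lower, upper, level, scale="probability")


def absolute_risk_reduction(
    t: TwoByTwoTable, level: float = 0.95, method: CIMethod = "wald"
) -> IntervalEstimate:
    """Absolute risk reduction, control rate minus experimental rate.

    Positive means the experimental arm has fewer events (benefit on an
    efficacy endpoint).  ``method="wald"`` gives point +/- z*sqrt(pe(1-pe)/n
    + pc(1-pc)/m); ``method="newcombe"`` delegates to the hybrid-score
    interval of statsmodels (recommended for small samples), which for
    reconstructed tables necessarily uses the back-calculated counts.
    """
    point = t.ctrl_rate - t.exp_rate
    if method == "wald":
        pe, pc = float(t.exp_rate), float(t.ctrl_rate)
        se = math.sqrt(pe * (1 - pe) / t.n + pc * (1 - pc) / t.m)
        half = _z(level) * se
        lower, upper = float(point) - half, float(point) + half
    elif method == "newcombe":
        from statsmodels.stats.proportion import confint_proportions_2indep

        lower, upper = confint_proportions_2indep(
            t.c, t.m, t.a, t.n, method="newcomb", compare="diff", alpha=1 - level
        )
        lower, upper = float(lower), float(upper)
        # score limits are for the count-based difference; keep the exact
        # supplied-rate point inside them
        lower = min(lower, float(point))
        upper = max(upper, float(point))
    else:
        raise ValueError(f"unknown CI method {method!r}; use 'wald' or 'newcombe'")
    return IntervalEstimate(point, lower, upper, level, scale="probability")


def odds_ratio(
    t: TwoByTwoTable, level: float = 0.95, continuity: bool = False
) -> IntervalEstimate:
    """Odds ratio (a*d)/(b*c) with a log-normal confidence interval.

    Zero in b, c or d makes the point undefined; ``continuity=True``
    applies a 0.5 adjustment to all cells for the CI (and for the point
    only when the unadjusted point does not exist).
    """
    if (t.b == 0 or t.c == 0 or t.d == 0) and not continuity:
        raise UndefinedRatioError("zero cell makes the odds ratio undefined")
    if t.b == 0 or t.c == 0 or t.d == 0:
        a, b, c, d = _adjusted_cells(t)
        point: Union[float, Fraction] = (a * d) / (b * c)
    else:
        point = Fraction(t.a * t.d, t.b * t.c)

    lower = upper = None
    if continuity and min(t.a, t.b, t.c, t.d) == 0:
        a, b, c, d = _adjusted_cells(t)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        center = math.log((a * d) / (b * c))
        lower, upper = math.exp(center - _z(level) * se), math.exp(center + _z(level) * se)
        lower = min(lower, float(point))
        upper = max(upper, float(point))
    elif min(t.a, t.b, t.c, t.d) > 0:
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        center = math.log(float(point))
        lower, upper = math.exp(center - _z(level) * se), math.exp(center + _z(level) * se)
        lower = min(lower, float(point))
        upper = max(upper, float(point))
    return IntervalEstimate(point, lower, upper, level, scale="ratio")


def _reciprocal_int(x, rounding: RoundingMode) -> int:
    """Integer NNT from a positive difference x.

    Exact for Rational inputs.  For floats, a reciprocal within relative
    tolerance of an integer is snapped to it before the ceiling, so an ARR
    entered as 0.10 maps to 10 (the exact-integer-stays convention), not 11.
    """
    if isinstance(x, Rational):
        r = Fraction(1, 1) / x
        if rounding == "ceiling":
            return math.ceil(r)
        return int(r + Fraction(1, 2))
    r = 1.0 / float(x)
    nearest = round(r)
    if nearest > 0 and math.isclose(r, nearest, rel_tol=_TIE_RTOL):
        return int(nearest)
    if rounding == "ceiling":
        return math.ceil(r)
    return math.floor(r + 0.5)


def nnt(
    arr: Union[IntervalEstimate, float, Fraction],
    direction: Literal["benefit", "harm"] = "benefit",
    rounding: RoundingMode = "ceiling",
) -> NNTResult:
    """Number needed to treat from an absolute risk reduction.

    The difference must already be oriented so that positive means effect
    in the stated direction.  Positive -> finite NNT = ceil(1/ARR) (default
    rounding); zero -> infinite; negative -> not_applicable.  When ``arr``
    carries confidence limits the NNT interval is attached.
    """
    est = arr if isinstance(arr, IntervalEstimate) else IntervalEstimate(arr)
    point = est.point
    interval = nnt_interval(est, side=direction) if est.has_limits else None
    if point > 0:
        return NNTResult(
            value=_reciprocal_int(point, rounding),
            status="finite",
            direction=direction,
            raw_reciprocal=1.0 / float(point),
            interval=interval,
        )
    if point == 0:
        return NNTResult(
            value=None,
            status="infinite",
            direction=direction,
            raw_reciprocal=math.inf,
            interval=interval,
        )
    return NNTResult(
        value=None,
        status="not_applicable",
        direction=direction,
        raw_reciprocal=None,
        interval=interval,
    )


def nnt_interval(
    arr: IntervalEstimate,
    rounding: RoundingMode = "ceiling",
    side: Literal["benefit", "harm"] = "benefit",
) -> NNTInterval:
    """NNT confidence bounds by taking reciprocals of the risk-difference
    confidence limits.

    Both limits positive: (ceil(1/upper), ceil(1/lower)).  Interval spans
    zero: (ceil(1/upper), inf) with ``spans_zero=True`` — the NNT runs
    through infinity and the effect is not significant at this level.  Both
    limits negative: the bounds are reported on the opposite side with the
    same reciprocal construction on the magnitudes.
    """
    if not arr.has_limits:
        raise ValueError("risk-difference estimate carries no confidence limits")
    lo, up = arr.lower, arr.upper
    if lo > 0:
        return NNTInterval(
            lower=_reciprocal_int(up, rounding),
            upper=_reciprocal_int(lo, rounding),
            spans_zero=False,
            side=side,
        )
    if up < 0:
        other = "harm" if side == "benefit" else "benefit"
        return NNTInterval(
            lower=_reciprocal_int(-lo, rounding),
            upper=_reciprocal_int(-up, rounding),
            spans_zero=False,
            side=other,
        )
    lower = _reciprocal_int(up, rounding) if up > 0 else math.inf
    return NNTInterval(lower=lower, upper=math.inf, spans_zero=True, side=side)


def nnh(
    t: TwoByTwoTable,
    level: float = 0.95,
    method: CIMethod = "wald",
    rounding: RoundingMode = "ceiling",
) -> NNTResult:
    """Number needed to harm for an adverse-event endpoint.

    The harm difference is experimental rate minus control rate, so a
    positive value means the experimental arm produces more events; the
    reciprocal-and-ceiling construction is then identical to the NNT.  A
    negative difference (experimental arm safer) yields not_applicable.
    """
    benefit = absolute_risk_reduction(t, level=level, method=method)
    harm = IntervalEstimate(
        point=-benefit.point,
        lower=None if benefit.upper is None else -benefit.upper,
        upper=None if benefit.lower is None else -benefit.lower,
        level=level,
        scale="probability",
    )
    return nnt(harm, direction="harm", rounding=rounding)


def nnt_from_baseline(
    rrr, baseline_risk, rounding: RoundingMode = "ceiling"
) -> NNTResult:
    """NNT implied by a relative risk reduction at a given baseline risk.

    Under the common (and often wrong) assumption that the RRR transfers
    unchanged across risk strata, the implied ARR is rrr * baseline and the
    NNT its ceiling reciprocal; at the trial's own control rate this equals
    the trial NNT identically.  A zero baseline yields an infinite NNT.
    """
    r = as_rate(rrr)
    b = as_rate(baseline_risk)
    if r <= 0:
        raise ValueError(f"relative risk reduction must be in (0, 1], got {rrr!r}")
    if b == 0:
        return NNTResult(value=None, status="infinite", direction="benefit",
                         raw_reciprocal=math.inf)
    return nnt(r * b, direction="benefit", rounding=rounding)
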