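"""Model/Results interface over the effect-measure functions.

``TwoArmBinomial`` treats a two-arm trial with a binary endpoint as two
independent binomial samples; ``fit()`` evaluates the full family of
effect measures and returns a ``TwoArmBinomialResults`` carrying point
estimates, confidence intervals and the NNT/NNH, with a ``summary()``
table in the spirit of statsmodels results objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Literal, Optional

from . import measures
from .measures import CIMethod, IntervalEstimate, NNTResult, RoundingMode, UndefinedRatioError
from .tables import TwoByTwoTable, from_counts, from_rates

__all__ = ["TwoArmBinomial", "TwoArmBinomialResults"]


class TwoArmBinomial:
    """Two-arm binary-endpoint model: events ~ Binomial(n, p) per arm.

    Parameters
    ----------
    table : TwoByTwoTable
        Validated 2x2 table (use the classmethod constructors for counts,
        rates or endpoint rows).
    endpoint_class : {"efficacy", "harm"}
        Orients the risk difference: efficacy endpoints count a lower
        experimental rate as benefit, harm endpoints count a higher
        experimental rate as harm.

    Examples
    --------
    >>> m = TwoArmBinomial.from_counts(25, 75, 35, 65)
    >>> res = m.fit()
    >>> round(float(res.relative_risk.point), 2)
    0.71
    >>> res.nnt.value
    10
    """

    def __init__(self, table: TwoByTwoTable,
                 endpoint_class: Literal["efficacy", "harm"] = "efficacy"):
        if endpoint_class not in ("efficacy", "harm"):
            raise ValueError(f"endpoint_class must be 'efficacy' or 'harm', got {endpoint_class!r}")
        self.table = table
        self.endpoint_class = endpoint_class

    @classmethod
    def from_counts(cls, a: int, b: int, c: int, d: int,
                    endpoint_class: Literal["efficacy", "harm"] = "efficacy"):
        return cls(from_counts(a, b, c, d), endpoint_class)

    @classmethod
    def from_rates(cls, exp_rate, ctrl_rate, n: int, m: int,
                   endpoint_class: Literal["efficacy", "harm"] = "efficacy"):
        return cls(from_rates(exp_rate, ctrl_rate, n, m), endpoint_class)

    @classmethod
    def from_endpoint_row(cls, row):
        """Build from a :class:`nntbench.trials.EndpointRow`."""
        return cls(row.table(), row.endpoint_class)

    def fit(self, level: float = 0.95, ci_method: CIMethod = "wald",
            rounding: RoundingMode = "ceiling",
            continuity: bool = False) -> "TwoArmBinomialResults":
        """Evaluate all effect measures at the requested confidence level."""
        return TwoArmBinomialResults(self, level, ci_method, rounding, continuity)


@dataclass(frozen=True)
class TwoArmBinomialResults:
    model: TwoArmBinomial
    level: float
    ci_method: CIMethod
    rounding: RoundingMode
    continuity: bool

    @property
    def table(self) -> TwoByTwoTable:
        return self.model.table

    @cached_property
    def risk_difference(self) -> IntervalEstimate:
        """ARR on the benefit orientation (control minus experimental)."""
        return measures.absolute_risk_reduction(
            self.table, level=self.level, method=self.ci_method)

    @property
    def arr(self) -> IntervalEstimate:
        """Alias for :attr:`risk_difference`."""
        return self.risk_difference

    @cached_property
    def relative_risk(self) -> IntervalEstimate:
        return measures.relative_risk(self.table, level=self.level,
                                      continuity=self.continuity)

    @cached_property
    def relative_risk_reduction(self) -> IntervalEstimate:
        return measures.relative_risk_reduction(self.table, level=self.level,
                                                continuity=self.continuity)

    @cached_property
    def odds_ratio(self) -> IntervalEstimate:
        return measures.odds_ratio(self.table, level=self.level,
                                   continuity=self.continuity)

    @cached_property
    def nnt(self) -> NNTResult:
        """NNT (efficacy orientation) or NNH (harm orientation), following
        the model's endpoint class."""
        if self.model.endpoint_class == "harm":
            return measures.nnh(self.table, level=self.level,
                                method=self.ci_method, rounding=self.rounding)
        return measures.nnt(self.risk_difference, rounding=self.rounding)

    def summary(self) -> str:
        """Plain-text summary table of every measure with its interval."""
        t = self.table
        pct = self.level * 100
        lines = [
            "Two-arm binomial effect measures",
            "=" * 56,
            f"events/size   experimental {t.a}/{t.n}   control {t.c}/{t.m}",
            f"event rate    experimental {float(t.exp_rate):.4f}   control {float(t.ctrl_rate):.4f}",
            f"CI method: {self.ci_method} (difference), log-normal (ratios); "
            f"level {pct:.0f}%",
            "-" * 56,
        ]

        def fmt(name: str, est: Optional[IntervalEstimate], as_pct=False):
            if est is None:
                lines.append(f"{name:<22} undefined (zero cell)")
                return
            scalefn = (lambda v: f"{float(v) * 100:.1f}%") if as_pct else (
                lambda v: f"{float(v):.4f}")
            ci = (f"[{scalefn(est.lower)}, {scalefn(est.upper)}]"
                  if est.has_limits else "[--, --]")
            lines.append(f"{name:<22} {scalefn(est.point):>9}  {ci}")

        fmt("Relative risk", self.relative_risk)
        fmt("Rel. risk reduction", self.relative_risk_reduction, as_pct=True)
        fmt("Risk difference", self.risk_difference, as_pct=True)
        try:
            fmt("Odds ratio", self.odds_ratio)
        except UndefinedRatioError:
            fmt("Odds ratio", None)
        r = self.nnt
        label = "NNH" if r.direction == "harm" else "NNT"
        if r.status == "finite":
            iv = r.interval
            if iv is not None:
                hi = "Inf" if iv.upper == float("inf") else f"{int(iv.upper)}"
                lo = "Inf" if iv.lower == float("inf") else f"{int(iv.lower)}"
                extra = f"  [{lo}, {hi}]" + ("  (CI spans zero)" if iv.spans_zero else "")
            else:
                extra = ""
            lines.append(f"{label:<22} {r.value:>9}{extra}"
                         f"   (1/diff = {r.raw_reciprocal:.2f})")
        else:
            word = "NA (difference favors the other arm)" \
                if r.status == "not_applicable" else "Inf (zero difference)"
            lines.append(f"{label:<22} {word}")
        lines.append("=" * 56)
        return "\n".join(lines)
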