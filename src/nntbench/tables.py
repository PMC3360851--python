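"""The 2x2 contingency table for a two-arm trial with a binary endpoint.

Cell layout follows the standard epidemiological convention:

=============  =======  ==========  =====
arm            event    no event    size
=============  =======  ==========  =====
experimental   a        b           n=a+b
control        c        d           m=c+d
=============  =======  ==========  =====

Tables can be built from raw counts (:func:`from_counts`) or from event
proportions plus arm sizes (:func:`from_rates`), the latter being the form
in which trial publications usually report secondary endpoints (percentages
printed at one decimal).  Rates supplied that way are stored exactly as
:class:`fractions.Fraction` so that downstream risk differences and their
reciprocals reproduce printed-table arithmetic without floating-point drift;
the integer counts reconstructed from them are kept only for interval
estimation and carry a ``reconstructed`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from fractions import Fraction

__all__ = ["TwoByTwoTable", "from_counts", "from_rates", "as_rate"]


def as_rate(value) -> Fraction:
    """Coerce a proportion given as float, int, str, Decimal or Fraction to
    an exact Fraction in [0, 1].

    Floats go through their shortest decimal repr, so ``0.307`` becomes
    exactly 307/1000 rather than the nearest binary double.
    """
    if isinstance(value, Fraction):
        rate = value
    elif isinstance(value, bool):
        raise TypeError("rate must be numeric, not bool")
    elif isinstance(value, int):
        rate = Fraction(value)
    elif isinstance(value, float):
        rate = Fraction(Decimal(repr(value)))
    elif isinstance(value, (str, Decimal)):
        try:
            rate = Fraction(Decimal(value))
        except InvalidOperation as exc:
            raise ValueError(f"malformed rate: {value!r}") from exc
    else:
        raise TypeError(f"cannot interpret {type(value).__name__} as a rate")
    if not 0 <= rate <= 1:
        raise ValueError(f"rate {value!r} outside [0, 1]")
    return rate


def _round_half_away(x: Fraction) -> int:
    # round-half-away-from-zero for non-negative rationals
    return int(x + Fraction(1, 2))


@dataclass(frozen=True)
class TwoByTwoTable:
    """Validated 2x2 table of event counts for two independent arms.

    Attributes
    ----------
    a, b : int
        Events / non-events in the experimental arm.
    c, d : int
        Events / non-events in the control arm.
    supplied_exp_rate, supplied_ctrl_rate : Fraction or None
        Exact event proportions as supplied by the user (set when the table
        was built from printed percentages).  When present, point estimates
        use these rather than the reconstructed counts.
    reconstructed : bool
        True when a and c were back-calculated from supplied rates.
    """

    a: int
    b: int
    c: int
    d: int
    supplied_exp_rate: Fraction | None = field(default=None)
    supplied_ctrl_rate: Fraction | None = field(default=None)
    reconstructed: bool = False

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.a + self.b < 1:
            raise ValueError("experimental arm is empty (a + b = 0)")
        if self.c + self.d < 1:
            raise ValueError("control arm is empty (c + d = 0)")
        for name in ("supplied_exp_rate", "supplied_ctrl_rate"):
            r = getattr(self, name)
            if r is not None and not 0 <= r <= 1:
                raise ValueError(f"{name} outside [0, 1]")

    @property
    def n(self) -> int:
        """Experimental arm size."""
        return self.a + self.b

    @property
    def m(self) -> int:
        """Control arm size."""
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.n + self.m

    @property
    def exp_rate(self) -> Fraction:
        """Event proportion in the experimental arm (exact)."""
        if self.supplied_exp_rate is not None:
            return self.supplied_exp_rate
        return Fraction(self.a, self.n)

    @property
    def ctrl_rate(self) -> Fraction:
        """Event proportion in the control arm (exact)."""
        if self.supplied_ctrl_rate is not None:
            return self.supplied_ctrl_rate
        return Fraction(self.c, self.m)

    def swapped(self) -> "TwoByTwoTable":
        """Return the table with arms exchanged."""
        return TwoByTwoTable(
            self.c, self.d, self.a, self.b,
            supplied_exp_rate=self.supplied_ctrl_rate,
            supplied_ctrl_rate=self.supplied_exp_rate,
            reconstructed=self.reconstructed,
        )


def from_counts(a: int, b: int, c: int, d: int) -> TwoByTwoTable:
    """Build a table from the four raw cell counts."""
    return TwoByTwoTable(a, b, c, d)


def from_rates(exp_rate, ctrl_rate, n: int, m: int) -> TwoByTwoTable:
    """Build a table from per-arm event proportions and arm sizes.

    Counts are reconstructed as round(rate * size), half away from zero, and
    flagged; the exact supplied rates are stored and take precedence in
    every point estimate.
    """
    if not (isinstance(n, int) and isinstance(m, int)) or n < 1 or m < 1:
        raise ValueError(f"arm sizes must be integers >= 1, got n={n!r}, m={m!r}")
    pe = as_rate(exp_rate)
    pc = as_rate(ctrl_rate)
    a = _round_half_away(pe * n)
    c = _round_half_away(pc * m)
    return TwoByTwoTable(
        a, n - a, c, m - c,
        supplied_exp_rate=pe,
        supplied_ctrl_rate=pc,
        reconstructed=True,
    )
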