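"""Interval-valued q-rung orthopair fuzzy numbers (IVq-ROFNs).

An IVq-ROFN carries an interval membership degree ``[mu_lo, mu_hi]`` and an
interval non-membership degree ``[nu_lo, nu_hi]``, both inside the unit
interval, together with an integer rung ``q >= 1``.  The defining constraint
is ``mu_hi**q + nu_hi**q <= 1``; the rungs q = 1, 2, 3 recover the
interval-valued intuitionistic, Pythagorean and Fermatean families, and
larger q admits progressively bolder assessments.

The residual indeterminacy of an assessment is its hesitancy interval
``pi = [ (1 - mu_hi**q - nu_hi**q)**(1/q), (1 - mu_lo**q - nu_lo**q)**(1/q) ]``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "IVqROFN",
    "HesitancyInterval",
    "Relation",
    "ValidationError",
    "CONSTRAINT_TOL",
    "validate",
    "hesitancy",
    "complement",
    "relate",
]

#: Slack on the rung constraint so that 1-decimal boundary data (for example
#: mu_hi = 0.6, nu_hi = 0.8 at q = 2) is admitted exactly on the boundary.
CONSTRAINT_TOL = 1e-9


class ValidationError(ValueError):
    """A fuzzy number (or one of its fields) violates its invariants.

    ``field`` names the offending component when a single field is at fault.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class Relation(enum.Enum):
    """Verdict of comparing two IVq-ROFNs with the basic set relations."""

    EQUAL = "equal"
    SUBSET = "subset"
    PRECEDES = "precedes"
    INCOMPARABLE = "incomparable"


@dataclass(frozen=True)
class HesitancyInterval:
    pi_lo: float
    pi_hi: float


@dataclass(frozen=True)
class IVqROFN:
    """One interval-valued q-rung orthopair fuzzy number.

    Parameters
    ----------
    mu_lo, mu_hi : float
        Lower/upper bound of the membership degree, ``0 <= mu_lo <= mu_hi <= 1``.
    nu_lo, nu_hi : float
        Lower/upper bound of the non-membership degree.
    q : int
        Rung; the constraint is ``mu_hi**q + nu_hi**q <= 1``.
    """

    mu_lo: float
    mu_hi: float
    nu_lo: float
    nu_hi: float
    q: int = 2

    def __post_init__(self):
        validate(self, raise_on_invalid=True)

    @property
    def mu(self) -> tuple[float, float]:
        return (self.mu_lo, self.mu_hi)

    @property
    def nu(self) -> tuple[float, float]:
        return (self.nu_lo, self.nu_hi)

    def __str__(self) -> str:  # mirrors the <[.,.],[.,.]> table notation
        return (
            f"<[{self.mu_lo:g}, {self.mu_hi:g}], "
            f"[{self.nu_lo:g}, {self.nu_hi:g}]>"
        )


def _check_fields(n: IVqROFN) -> None:
    """Raise ValidationError for non-numeric or out-of-range fields."""
    for field in ("mu_lo", "mu_hi", "nu_lo", "nu_hi"):
        value = getattr(n, field)
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValidationError(f"{field} must be a real number, got {value!r}", field)
        if not 0.0 <= float(value) <= 1.0:
            raise ValidationError(f"{field}={value} outside the unit interval", field)
    q = n.q
    if not isinstance(q, int) or isinstance(q, bool) or q < 1:
        raise ValidationError(f"q must be an integer >= 1, got {q!r}", "q")


def validate(n: IVqROFN, tol: float = CONSTRAINT_TOL, *, raise_on_invalid: bool = False) -> bool:
    """Check the IVq-ROFN invariants.

    Returns True iff the bounds are ordered and ``mu_hi**q + nu_hi**q <= 1 + tol``.
    With ``raise_on_invalid`` a :class:`ValidationError` naming the offending
    field is raised instead of returning False.  The input is never mutated.
    """
    try:
        _check_fields(n)
        if n.mu_lo > n.mu_hi:
            raise ValidationError(
                f"mu_lo={n.mu_lo} > mu_hi={n.mu_hi}: membership bounds unordered", "mu_lo"
            )
        if n.nu_lo > n.nu_hi:
            raise ValidationError(
                f"nu_lo={n.nu_lo} > nu_hi={n.nu_hi}: non-membership bounds unordered", "nu_lo"
            )
        power_sum = n.mu_hi**n.q + n.nu_hi**n.q
        if power_sum > 1.0 + tol:
            raise ValidationError(
                f"mu_hi^q + nu_hi^q = {power_sum:.6f} > 1 at q={n.q}", "nu_hi"
            )
    except ValidationError:
        if raise_on_invalid:
            raise
        return False
    return True


def hesitancy(n: IVqROFN, tol: float = CONSTRAINT_TOL) -> HesitancyInterval:
    """Hesitancy interval ``[pi_lo, pi_hi]`` of a valid IVq-ROFN.

    ``pi_lo`` uses the upper membership/non-membership bounds, ``pi_hi`` the
    lower ones, so the interval is always ordered.  Radicands that are
    negative by no more than ``tol`` (boundary-touching data) are clamped to 0.
    """
    validate(n, tol, raise_on_invalid=True)
    q = n.q

    def _root(radicand: float) -> float:
        if radicand < 0.0:
            if radicand < -tol:
                raise ValidationError(f"negative hesitancy radicand {radicand}")
            radicand = 0.0
        return radicand ** (1.0 / q)

    pi_lo = _root(1.0 - n.mu_hi**q - n.nu_hi**q)
    pi_hi = _root(1.0 - n.mu_lo**q - n.nu_lo**q)
    return HesitancyInterval(pi_lo, pi_hi)


def complement(n: IVqROFN) -> IVqROFN:
    """Swap membership and non-membership intervals (an involution)."""
    validate(n, raise_on_invalid=True)
    return IVqROFN(n.nu_lo, n.nu_hi, n.mu_lo, n.mu_hi, n.q)


def relate(a: IVqROFN, b: IVqROFN) -> Relation:
    """Classify the pair (a, b) with the basic IVq-ROFS relations.

    Checked in priority order: equality (all four bounds equal), subset
    (``a ⊆ b``: membership bounds componentwise <=, non-membership bounds
    componentwise >=), precedence (``a ≼ b``: mu_lo <=, mu_hi >=, nu_lo >=,
    nu_hi <=), otherwise incomparable.
    """
    if a.q != b.q:
        raise ValidationError(f"incompatible rungs: q={a.q} vs q={b.q}", "q")
    validate(a, raise_on_invalid=True)
    validate(b, raise_on_invalid=True)
    if (a.mu_lo, a.mu_hi, a.nu_lo, a.nu_hi) == (b.mu_lo, b.mu_hi, b.nu_lo, b.nu_hi):
        return Relation.EQUAL
    if (
        a.mu_lo <= b.mu_lo
        and a.mu_hi <= b.mu_hi
        and a.nu_lo >= b.nu_lo
        and a.nu_hi >= b.nu_hi
    ):
        return Relation.SUBSET
    if (
        a.mu_lo <= b.mu_lo
        and a.mu_hi >= b.mu_hi
        and a.nu_lo >= b.nu_lo
        and a.nu_hi <= b.nu_hi
    ):
        return Relation.PRECEDES
    return Relation.INCOMPARABLE
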