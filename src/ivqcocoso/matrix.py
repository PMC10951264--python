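"""Decision-matrix containers.

``FuzzyDecisionMatrix`` holds one expert's alternatives x criteria grid of
IVq-ROFNs as a float array of shape ``(n_alternatives, n_criteria, 4)`` with
the last axis ordered ``(mu_lo, mu_hi, nu_lo, nu_hi)``.  ``CrispDecisionMatrix``
and ``WeightVector`` wrap the standardized real matrix and the criterion
weights as pandas objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CONSTRAINT_TOL, IVqROFN, ValidationError

__all__ = [
    "BOUND_FIELDS",
    "FuzzyDecisionMatrix",
    "CrispDecisionMatrix",
    "WeightVector",
    "AlignmentError",
    "check_aligned",
]

BOUND_FIELDS = ("mu_lo", "mu_hi", "nu_lo", "nu_hi")


class AlignmentError(ValueError):
    """Sources disagree on alternatives, criteria or rung."""


@dataclass
class FuzzyDecisionMatrix:
    """One source's complete grid of IVq-ROFN assessments.

    Parameters
    ----------
    alternatives, criteria : sequence of str
        Ordered labels for the grid axes.
    values : ndarray, shape (n_alternatives, n_criteria, 4)
        Bounds in the order ``(mu_lo, mu_hi, nu_lo, nu_hi)``.
    q : int
        Common rung of every cell.
    source_id : str
        Label of the expert/source that produced the grid.
    """

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    values: np.ndarray
    q: int = 2
    source_id: str = "S1"

    def __post_init__(self):
        self.alternatives = tuple(self.alternatives)
        self.criteria = tuple(self.criteria)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.alternatives), len(self.criteria), 4)
        if self.values.shape != expected:
            raise ValidationError(
                f"values shape {self.values.shape} != {expected} for "
                f"{len(self.alternatives)} alternatives x {len(self.criteria)} criteria"
            )
        self.validate_cells()

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.alternatives), len(self.criteria))

    def validate_cells(self, tol: float = CONSTRAINT_TOL) -> None:
        """Raise with cell coordinates on the first invalid cell."""
        v = self.values
        if np.isnan(v).any() or (v < 0).any() or (v > 1).any():
            i, j, _ = np.argwhere(~((v >= 0) & (v <= 1)))[0]
            raise ValidationError(
                f"cell ({self.alternatives[i]}, {self.criteria[j]}) of source "
                f"{self.source_id} has a bound outside [0, 1]"
            )
        bad_mu = v[:, :, 0] > v[:, :, 1]
        bad_nu = v[:, :, 2] > v[:, :, 3]
        power = v[:, :, 1] ** self.q + v[:, :, 3] ** self.q
        bad_q = power > 1.0 + tol
        for mask, what in ((bad_mu, "mu_lo > mu_hi"), (bad_nu, "nu_lo > nu_hi"),
                           (bad_q, f"mu_hi^q + nu_hi^q > 1 at q={self.q}")):
            if mask.any():
                i, j = np.argwhere(mask)[0]
                raise ValidationError(
                    f"cell ({self.alternatives[i]}, {self.criteria[j]}) of source "
                    f"{self.source_id}: {what}"
                )

    def cell(self, alternative: str, criterion: str) -> IVqROFN:
        i = self.alternatives.index(alternative)
        j = self.criteria.index(criterion)
        return IVqROFN(*self.values[i, j], q=self.q)

    def iter_cells(self):
        for i, alt in enumerate(self.alternatives):
            for j, crit in enumerate(self.criteria):
                yield alt, crit, IVqROFN(*self.values[i, j], q=self.q)

    @classmethod
    def from_cells(cls, cells, alternatives, criteria, q=2, source_id="S1"):
        """Build from a mapping ``(alternative, criterion) -> 4 bounds``."""
        alternatives = tuple(alternatives)
        criteria = tuple(criteria)
        values = np.full((len(alternatives), len(criteria), 4), np.nan)
        for (alt, crit), bounds in cells.items():
            values[alternatives.index(alt), criteria.index(crit)] = bounds
        if np.isnan(values).any():
            i, j, _ = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing cell ({alternatives[i]}, {criteria[j]}) in source {source_id}"
            )
        return cls(alternatives, criteria, values, q=q, source_id=source_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per cell."""
        rows = []
        for i, alt in enumerate(self.alternatives):
            for j, crit in enumerate(self.criteria):
                rows.append((self.source_id, alt, crit, *self.values[i, j]))
        return pd.DataFrame(rows, columns=["source", "alternative", "criterion", *BOUND_FIELDS])


@dataclass
class CrispDecisionMatrix:
    """Entropy-standardized real decision matrix (alternatives x criteria).

    When ``normalized`` is set, each criterion's column over the alternatives
    sums to 1.
    """

    table: pd.DataFrame
    normalized: bool = False

    def __post_init__(self):
        self.table = self.table.astype(float)
        if (self.table.values < 0).any():
            raise ValidationError("crisp decision values must be nonnegative")
        if self.normalized:
            sums = self.table.sum(axis=0).values
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValidationError(
                    f"normalized matrix columns must sum to 1, got {sums}"
                )

    @property
    def alternatives(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    @property
    def criteria(self) -> tuple[str, ...]:
        return tuple(self.table.columns)

    @property
    def values(self) -> np.ndarray:
        return self.table.values


@dataclass
class WeightVector:
    """Nonnegative criterion weights; ``normalized`` vectors sum to 1."""

    weights: pd.Series
    normalized: bool = True

    def __post_init__(self):
        self.weights = self.weights.astype(float)
        if (self.weights.values < 0).any():
            raise ValidationError("weights must be nonnegative")
        if self.normalized and not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValidationError(
                f"normalized weights must sum to 1, got {self.weights.sum()!r}"
            )

    @property
    def criteria(self) -> tuple[str, ...]:
        return tuple(self.weights.index)

    @property
    def values(self) -> np.ndarray:
        return self.weights.values

    @classmethod
    def from_dict(cls, mapping, normalized=True):
        return cls(pd.Series(mapping), normalized=normalized)


def check_aligned(sources: list[FuzzyDecisionMatrix]) -> None:
    """Raise AlignmentError naming the first mismatching axis."""
    if not sources:
        raise AlignmentError("need at least one source matrix")
    first = sources[0]
    for other in sources[1:]:
        if other.alternatives != first.alternatives:
            raise AlignmentError(
                f"alternatives of {other.source_id} differ from {first.source_id}"
            )
        if other.criteria != first.criteria:
            raise AlignmentError(
                f"criteria of {other.source_id} differ from {first.source_id}"
            )
        if other.q != first.q:
            raise AlignmentError(
                f"rung mismatch: {other.source_id} has q={other.q}, "
                f"{first.source_id} has q={first.q}"
            )
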