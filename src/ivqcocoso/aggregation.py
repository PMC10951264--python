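"""Multi-source aggregation of expert fuzzy decision matrices.

Two strategies fuse per-cell assessments from several aligned experts:

* ``compromised`` — each of the four bounds is the arithmetic mean over the
  sources.  Validity of the output is guaranteed: by convexity of t -> t**q,
  ``mean(mu_hi)**q + mean(nu_hi)**q <= mean(mu_hi**q + nu_hi**q) <= 1``.
* ``inclusive`` — the min/max envelope ``mu = [min mu_lo, max mu_hi]``,
  ``nu = [min nu_lo, max nu_hi]``, which contains every source assessment but
  may break the rung constraint; a repair clamp then caps ``nu_hi``.

Three clamp conventions are offered.  "upper-bound" (the default) sets
``nu_hi <- (1 - mu_hi**q)**(1/q)``, which always restores validity.
"grid-step" decrements ``nu_hi`` in steps of 0.1 until the constraint holds
— the repair the published worked tables actually apply to their 1-decimal
assessments.  "lower-bound" uses the lower membership bound,
``nu_hi <- (1 - mu_lo**q)**(1/q)``, which cannot guarantee the constraint;
cells still in violation after that clamp are reported in the returned
matrix's repair log and a warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import CONSTRAINT_TOL
from .matrix import AlignmentError, FuzzyDecisionMatrix, check_aligned

__all__ = [
    "AggregationStrategy",
    "aggregate",
    "aggregate_compromised",
    "aggregate_inclusive",
    "STRATEGIES",
    "CLAMP_CONVENTIONS",
]

STRATEGIES = ("compromised", "inclusive")
CLAMP_CONVENTIONS = ("upper-bound", "grid-step", "lower-bound")


@dataclass(frozen=True)
class AggregationStrategy:
    name: str = "compromised"
    clamp_convention: str = "upper-bound"

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise ValueError(f"unknown aggregation strategy {self.name!r}; "
                             f"choose one of {STRATEGIES}")
        if self.clamp_convention not in CLAMP_CONVENTIONS:
            raise ValueError(f"unknown clamp convention {self.clamp_convention!r}; "
                             f"choose one of {CLAMP_CONVENTIONS}")


def _stack(sources: list[FuzzyDecisionMatrix]) -> np.ndarray:
    check_aligned(sources)
    return np.stack([s.values for s in sources])  # (n_sources, n_alt, n_crit, 4)


def aggregate_compromised(
    sources: list[FuzzyDecisionMatrix],
    weights: np.ndarray | None = None,
) -> FuzzyDecisionMatrix:
    """Componentwise (weighted) mean of the source grids.

    ``weights`` are optional per-source weights (default uniform); they must
    be nonnegative and sum to a positive total.
    """
    stacked = _stack(sources)
    if weights is None:
        out = stacked.mean(axis=0)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(sources),) or (w < 0).any() or w.sum() <= 0:
            raise AlignmentError("source weights must be nonnegative, one per source")
        out = np.tensordot(w / w.sum(), stacked, axes=(0, 0))
    first = sources[0]
    return FuzzyDecisionMatrix(
        first.alternatives, first.criteria, out, q=first.q,
        source_id="+".join(s.source_id for s in sources),
    )


def aggregate_inclusive(
    sources: list[FuzzyDecisionMatrix],
    clamp_convention: str = "upper-bound",
    tol: float = CONSTRAINT_TOL,
) -> FuzzyDecisionMatrix:
    """Min/max-envelope aggregation with constraint repair.

    Returns the aggregated matrix; cells whose raw envelope violated the rung
    constraint and were clamped are listed in the result's ``repair_log``
    attribute as ``(alternative, criterion, raw_nu_hi, clamped_nu_hi)``.
    """
    if clamp_convention not in CLAMP_CONVENTIONS:
        raise ValueError(f"unknown clamp convention {clamp_convention!r}")
    stacked = _stack(sources)
    first = sources[0]
    q = first.q
    out = np.empty(stacked.shape[1:])
    out[:, :, 0] = stacked[:, :, :, 0].min(axis=0)  # mu_lo
    out[:, :, 1] = stacked[:, :, :, 1].max(axis=0)  # mu_hi
    out[:, :, 2] = stacked[:, :, :, 2].min(axis=0)  # nu_lo
    out[:, :, 3] = stacked[:, :, :, 3].max(axis=0)  # nu_hi

    repair_log = []
    violation = out[:, :, 1] ** q + out[:, :, 3] ** q > 1.0 + tol
    for i, j in np.argwhere(violation):
        raw = out[i, j, 3]
        if clamp_convention == "grid-step":
            clamped = raw
            while clamped > 0 and out[i, j, 1] ** q + clamped**q > 1.0 + tol:
                clamped = round(clamped - 0.1, 10)
            clamped = max(clamped, 0.0)
        else:
            anchor = out[i, j, 1] if clamp_convention == "upper-bound" else out[i, j, 0]
            clamped = (1.0 - anchor**q) ** (1.0 / q)
        out[i, j, 3] = clamped
        out[i, j, 2] = min(out[i, j, 2], clamped)  # keep nu interval ordered
        repair_log.append((first.alternatives[i], first.criteria[j], raw, clamped))
        if clamp_convention == "lower-bound" and out[i, j, 1] ** q + clamped**q > 1.0 + tol:
            warnings.warn(
                f"lower-bound clamp leaves cell ({first.alternatives[i]}, "
                f"{first.criteria[j]}) in violation of the q={q} constraint",
                stacklevel=2,
            )

    if clamp_convention == "lower-bound":
        # A still-violating cell must not abort construction: widen tolerance
        # for the container and record the fact instead of silently passing.
        result = FuzzyDecisionMatrix.__new__(FuzzyDecisionMatrix)
        result.alternatives = first.alternatives
        result.criteria = first.criteria
        result.values = out
        result.q = q
        result.source_id = "|".join(s.source_id for s in sources)
    else:
        result = FuzzyDecisionMatrix(
            first.alternatives, first.criteria, out, q=q,
            source_id="|".join(s.source_id for s in sources),
        )
    result.repair_log = repair_log
    return result


def aggregate(
    sources: list[FuzzyDecisionMatrix],
    strategy: AggregationStrategy | str = "compromised",
) -> FuzzyDecisionMatrix:
    """Dispatch to the named aggregation strategy; records it in provenance."""
    if isinstance(strategy, str):
        strategy = AggregationStrategy(name=strategy)
    if strategy.name == "compromised":
        result = aggregate_compromised(sources)
    else:
        result = aggregate_inclusive(sources, strategy.clamp_convention)
    result.strategy = strategy
    return result
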