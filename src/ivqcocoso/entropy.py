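"""Parametric fuzzy entropy, standardization and entropy-based weights.

The entropy of one IVq-ROFN measures its fuzziness relative to the balance
point ``mu = nu = [k**(1/q), k**(1/q)]``:

    E = 1 - (mu_dn + nu_dn + mu_up + nu_up) / 2

with ``mu_dn = min(|mu_lo**q - k|, |mu_hi**q - k|)``,
``mu_up = max(...)`` and likewise for nu.  E is 0 exactly on the crisp
elements (mu=[0,0], nu=[1,1] or vice versa) and 1 exactly at the balance
point; it is symmetric under swapping mu and nu, so complementation leaves
it unchanged.  The balance parameter ``k`` in [0, 1] tunes where maximal
fuzziness sits.

A fuzzy matrix is standardized to a crisp one by taking each cell's entropy
(benefit criteria) or its complement ``1 - E`` (cost criteria) and then
normalizing each criterion's column over the alternatives to sum to 1.

Criterion weights follow the entropy weight method: the mean cell entropy
per criterion is normalized across criteria, and criteria with lower
normalized fuzziness receive proportionally higher weight.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .core import IVqROFN, ValidationError, validate
from .matrix import CrispDecisionMatrix, FuzzyDecisionMatrix, WeightVector

__all__ = [
    "EntropyParams",
    "AttributeEntropyProfile",
    "element_entropy",
    "matrix_entropy",
    "standardize",
    "attribute_weights",
    "entropy_axiom_suite",
]


@dataclass(frozen=True)
class EntropyParams:
    """Balance parameter k in [0, 1] and rung q >= 1."""

    k: float = 1.0 / 3.0
    q: int = 2

    def __post_init__(self):
        if not 0.0 <= self.k <= 1.0:
            raise ValidationError(f"k={self.k} outside [0, 1]", "k")
        if not isinstance(self.q, int) or self.q < 1:
            raise ValidationError(f"q must be an integer >= 1, got {self.q!r}", "q")


@dataclass
class AttributeEntropyProfile:
    """Per-criterion mean entropy (raw) and its across-criteria normalization."""

    raw: pd.Series
    normalized: pd.Series


def _entropy_array(values: np.ndarray, k: float, q: int) -> np.ndarray:
    """Vectorized entropy; ``values[..., 4]`` ordered (mu_lo, mu_hi, nu_lo, nu_hi)."""
    powered = values.astype(float) ** q
    dev = np.abs(powered - k)
    # grouped per degree so that swapping mu and nu is float-exact symmetric
    mu_span = np.minimum(dev[..., 0], dev[..., 1]) + np.maximum(dev[..., 0], dev[..., 1])
    nu_span = np.minimum(dev[..., 2], dev[..., 3]) + np.maximum(dev[..., 2], dev[..., 3])
    return 1.0 - 0.5 * (mu_span + nu_span)


def element_entropy(n: IVqROFN, params: EntropyParams | None = None) -> float:
    """Fuzzy entropy of one IVq-ROFN (uses the element's own rung)."""
    params = params or EntropyParams(q=n.q)
    validate(n, raise_on_invalid=True)
    return float(
        _entropy_array(np.array([n.mu_lo, n.mu_hi, n.nu_lo, n.nu_hi]), params.k, params.q)
    )


def matrix_entropy(matrix: FuzzyDecisionMatrix, k: float = 1.0 / 3.0) -> pd.DataFrame:
    """Per-cell entropy of a fuzzy decision matrix (alternatives x criteria)."""
    e = _entropy_array(matrix.values, k, matrix.q)
    return pd.DataFrame(e, index=list(matrix.alternatives), columns=list(matrix.criteria))


def standardize(
    matrix: FuzzyDecisionMatrix,
    directions: dict[str, str],
    k: float = 1.0 / 3.0,
) -> CrispDecisionMatrix:
    """Entropy-standardize a fuzzy matrix into a normalized crisp one.

    ``directions`` maps every criterion to "benefit" or "cost".  Benefit
    criteria keep the cell entropy, cost criteria use its complement 1 - E;
    each criterion's column is then normalized to sum to 1 over the
    alternatives.
    """
    for crit in matrix.criteria:
        if crit not in directions:
            raise ValidationError(f"no direction given for criterion {crit!r}")
        if directions[crit] not in ("benefit", "cost"):
            raise ValidationError(
                f"direction for {crit!r} must be 'benefit' or 'cost', "
                f"got {directions[crit]!r}"
            )
    e = matrix_entropy(matrix, k)
    r = e.copy()
    for crit in matrix.criteria:
        if directions[crit] == "cost":
            r[crit] = 1.0 - e[crit]
    sums = r.sum(axis=0)
    if (sums == 0).any():
        bad = sums.index[sums == 0][0]
        raise ValidationError(f"criterion {bad!r} has zero column sum; cannot normalize")
    # For k > 1/2 the entropy can leave [0, 1] and a uniformly negative
    # column normalizes back to positive shares; only a sign-mixed column is
    # genuinely degenerate, and the container check below rejects it.
    return CrispDecisionMatrix(r / sums, normalized=True)


def attribute_weights(
    matrix: FuzzyDecisionMatrix,
    k: float = 1.0 / 3.0,
) -> tuple[WeightVector, AttributeEntropyProfile]:
    """Entropy-method criterion weights.

    Per criterion j the raw entropy ``E_j`` is the mean cell entropy over the
    alternatives; the ``E_j`` are normalized across criteria to ``Ebar_j``
    (summing to 1) and converted to weights
    ``w_j = (1 - Ebar_j) / (m - sum(Ebar))`` with m the number of criteria,
    renormalized to sum to 1.  Lower normalized entropy means higher weight.
    """
    e = matrix_entropy(matrix, k)
    raw = e.mean(axis=0)
    m = len(matrix.criteria)
    if m == 1:
        warnings.warn("single criterion: weight fixed at 1", stacklevel=2)
        profile = AttributeEntropyProfile(raw=raw, normalized=raw / raw.sum())
        return WeightVector(pd.Series([1.0], index=list(matrix.criteria))), profile
    total = raw.sum()
    if total == 0:
        raise ValidationError("criterion entropies sum to zero; weights undefined")
    # For k > 1/2 the mean entropies can be uniformly negative; the
    # normalization is sign-invariant, and a malformed (sign-mixed) outcome
    # is caught by the WeightVector nonnegativity check.
    normalized = raw / total
    w = (1.0 - normalized) / (m - normalized.sum())
    w = w / w.sum()
    profile = AttributeEntropyProfile(raw=raw, normalized=normalized)
    return WeightVector(w), profile


def _random_valid(rng: np.ndarray, n: int, q: int) -> np.ndarray:
    """Draw n valid bound quadruples at rung q (constructive sampling)."""
    mu_hi = rng.uniform(0.0, 1.0, n)
    nu_hi = rng.uniform(0.0, (1.0 - mu_hi**q) ** (1.0 / q))
    mu_lo = rng.uniform(0.0, mu_hi)
    nu_lo = rng.uniform(0.0, nu_hi)
    return np.column_stack([mu_lo, mu_hi, nu_lo, nu_hi])


def entropy_axiom_suite(
    params: EntropyParams,
    n_draws: int = 10_000,
    seed: int = 0,
) -> dict:
    """Empirically check the entropy axioms on random valid draws.

    Checks, over ``n_draws`` constructively valid random elements: the [0, 1]
    range; E = 0 on crisp elements; E = 1 at the balance point
    ``mu = nu = [k**(1/q), k**(1/q)]``; exact complement symmetry; and
    monotonicity on "crisper-than" pairs (shrinking both intervals toward the
    balance point cannot decrease entropy).

    The balance point is a *feasible* element only when ``2k <= 1`` (its
    constraint load is exactly 2k), and for ``k > 1/2`` the measure can leave
    [0, 1] on valid elements; the range, balance-point and monotonicity
    checks therefore only apply on that domain and are recorded as None
    (not applicable) beyond it.  Returns a report dict whose ``passed`` flag
    is False iff any applicable check found a counterexample (the first one
    is recorded under ``counterexamples``).
    """
    rng = np.random.default_rng(seed)
    q, k = params.q, params.k
    report = {"params": params, "n_draws": n_draws, "checks": {}, "counterexamples": {}}
    balanced_feasible = 2.0 * k <= 1.0 + 1e-12

    draws = _random_valid(rng, n_draws, q)
    e = _entropy_array(draws, k, q)

    if balanced_feasible:
        in_range = (e >= -1e-12) & (e <= 1.0 + 1e-12)
        report["checks"]["range"] = bool(in_range.all())
        if not in_range.all():
            report["counterexamples"]["range"] = draws[~in_range][0].tolist()
    else:
        report["checks"]["range"] = None

    crisp = np.array([[0.0, 0.0, 1.0, 1.0], [1.0, 1.0, 0.0, 0.0]])
    e_crisp = _entropy_array(crisp, k, q)
    report["checks"]["crisp_zero"] = bool(np.allclose(e_crisp, 0.0, atol=1e-12))

    root = k ** (1.0 / q)
    if balanced_feasible:
        fixed = np.array([root, root, root, root])
        report["checks"]["balance_one"] = bool(
            np.isclose(_entropy_array(fixed, k, q), 1.0, atol=1e-12)
        )
    else:
        report["checks"]["balance_one"] = None

    swapped = draws[:, [2, 3, 0, 1]]
    sym = _entropy_array(swapped, k, q) == e
    report["checks"]["complement_symmetry"] = bool(sym.all())
    if not sym.all():
        report["counterexamples"]["complement_symmetry"] = draws[~sym][0].tolist()

    if balanced_feasible:
        # Valid crisper-than pairs above the balance point, sampled in power
        # space so the rung constraint holds: B interpolates A toward the
        # balance point (in bound space), so A is crisper than B.
        p_mu_hi = rng.uniform(k, 1.0 - k, n_draws)
        p_nu_hi = rng.uniform(k, 1.0 - p_mu_hi)
        p_mu_lo = rng.uniform(k, p_mu_hi)
        p_nu_lo = rng.uniform(k, p_nu_hi)
        a = np.column_stack([p_mu_lo, p_mu_hi, p_nu_lo, p_nu_hi]) ** (1.0 / q)
        t = rng.uniform(0.0, 1.0, (n_draws, 1))
        b = root + (a - root) * t
        mono = _entropy_array(a, k, q) <= _entropy_array(b, k, q) + 1e-12
        report["checks"]["crisper_monotone"] = bool(mono.all())
        if not mono.all():
            report["counterexamples"]["crisper_monotone"] = (
                a[~mono][0].tolist(), b[~mono][0].tolist()
            )
    else:
        report["checks"]["crisper_monotone"] = None

    report["passed"] = all(v for v in report["checks"].values() if v is not None)
    return report
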