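"""Combined Compromise Solution (CoCoSo) scoring engines.

Two engines are provided.  The improved engine operates on an
entropy-standardized, column-normalized crisp matrix and a criterion weight
vector: it forms a weighted sum S_i and a power aggregate M_i per
alternative, fuses them into three dependent compromise scores

    s1_i = (S_i + M_i) / sum(S + M)           (share of total)
    s2_i = S_i / min S + M_i / min M          (relative to the worst, >= 2)
    s3_i = (eps*S_i + (1-eps)*M_i) / (eps*max S + (1-eps)*max M)

and a final score ``(s1 + s2 + s3)/3 + (s1*s2*s3)**(1/3)``, ranked
descending.  The classical engine implements the original method on a raw
crisp matrix with min-max normalization and a true weighted product.

The power aggregate defaults to the power *sum* ``sum_j r_ij**w_j`` (the
classical P_i operator); the literal power product is available via
``m_mode="power-product"``.  The optional ``s2_mode="log-normalized"``
rescales s2 as ``ln(s2_i) / sum_i ln(s2_i)`` to bring it onto the same [0, 1]
scale as s1 and s3; the default leaves s2 untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError
from .matrix import CrispDecisionMatrix, WeightVector

__all__ = [
    "CoCoSoParams",
    "CoCoSoResult",
    "weighted_sum",
    "power_aggregate",
    "compromise_scores",
    "final_scores",
    "improved_cocoso",
    "original_cocoso",
    "rank_descending",
]

S2_MODES = ("as-printed", "log-normalized")
M_MODES = ("power-sum", "power-product")


@dataclass(frozen=True)
class CoCoSoParams:
    """Equilibrium parameter and score-variant switches."""

    epsilon: float = 0.5
    s2_mode: str = "as-printed"
    m_mode: str = "power-sum"

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValidationError(f"epsilon={self.epsilon} outside [0, 1]", "epsilon")
        if self.s2_mode not in S2_MODES:
            raise ValueError(f"s2_mode must be one of {S2_MODES}")
        if self.m_mode not in M_MODES:
            raise ValueError(f"m_mode must be one of {M_MODES}")


@dataclass
class CoCoSoResult:
    """Per-alternative aggregates, compromise scores, final score and rank."""

    table: pd.DataFrame  # columns: S, M, s1, s2, s3, final, rank
    params: CoCoSoParams

    @property
    def ranking(self) -> list[str]:
        """Alternative labels from best (rank 1) to worst."""
        return list(self.table.sort_values("rank").index)

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda x: f"{x:.9g}")


def _align(matrix: CrispDecisionMatrix, w: WeightVector) -> tuple[np.ndarray, np.ndarray]:
    if tuple(w.criteria) != tuple(matrix.criteria):
        raise ValidationError(
            f"weight criteria {w.criteria} do not match matrix criteria {matrix.criteria}"
        )
    return matrix.values, w.values


def weighted_sum(matrix: CrispDecisionMatrix, w: WeightVector) -> pd.Series:
    """S_i = sum_j w_j r_ij."""
    r, omega = _align(matrix, w)
    return pd.Series(r @ omega, index=list(matrix.alternatives), name="S")


def power_aggregate(
    matrix: CrispDecisionMatrix, w: WeightVector, m_mode: str = "power-sum"
) -> pd.Series:
    """M_i = sum_j r_ij**w_j (default) or prod_j r_ij**w_j."""
    if m_mode not in M_MODES:
        raise ValueError(f"m_mode must be one of {M_MODES}")
    r, omega = _align(matrix, w)
    if m_mode == "power-product":
        if (r <= 0).any():
            raise ValidationError("power-product requires strictly positive entries")
        return pd.Series(np.prod(r**omega, axis=1), index=list(matrix.alternatives), name="M")
    return pd.Series(np.sum(r**omega, axis=1), index=list(matrix.alternatives), name="M")


def compromise_scores(
    S: pd.Series, M: pd.Series, params: CoCoSoParams | None = None
) -> pd.DataFrame:
    """The three dependent compromise scores s1, s2, s3 from S and M."""
    params = params or CoCoSoParams()
    S = S.astype(float)
    M = M.astype(float)
    if (S <= 0).any() or (M <= 0).any():
        raise ValidationError("compromise scores require strictly positive S and M")
    eps = params.epsilon
    s1 = (S + M) / (S + M).sum()
    s2 = S / S.min() + M / M.min()
    s3 = (eps * S + (1 - eps) * M) / (eps * S.max() + (1 - eps) * M.max())
    if params.s2_mode == "log-normalized":
        logs = np.log(s2)
        s2 = logs / logs.sum()
    return pd.DataFrame({"s1": s1, "s2": s2, "s3": s3})


def rank_descending(final: pd.Series) -> pd.Series:
    """Dense 1..m ranks, best first; ties broken by label order with a warning."""
    if final.duplicated().any():
        warnings.warn("tied final scores; breaking ties by alternative label order",
                      stacklevel=2)
    order = sorted(final.index, key=lambda a: (-final[a], list(final.index).index(a)))
    ranks = pd.Series({a: i + 1 for i, a in enumerate(order)}, name="rank")
    return ranks.reindex(final.index)


def final_scores(triples: pd.DataFrame, params: CoCoSoParams | None = None) -> pd.DataFrame:
    """Fuse (s1, s2, s3) into the final score and attach ranks."""
    s1, s2, s3 = triples["s1"], triples["s2"], triples["s3"]
    final = (s1 + s2 + s3) / 3.0 + (s1 * s2 * s3) ** (1.0 / 3.0)
    out = triples.copy()
    out["final"] = final
    out["rank"] = rank_descending(final)
    return out


def improved_cocoso(
    matrix: CrispDecisionMatrix,
    w: WeightVector,
    params: CoCoSoParams | None = None,
) -> CoCoSoResult:
    """Full improved-CoCoSo scoring of a normalized crisp matrix."""
    params = params or CoCoSoParams()
    if not matrix.normalized:
        raise ValidationError("improved CoCoSo expects a column-normalized matrix")
    S = weighted_sum(matrix, w)
    M = power_aggregate(matrix, w, params.m_mode)
    triples = compromise_scores(S, M, params)
    scored = final_scores(triples, params)
    table = pd.concat([S, M], axis=1).join(scored)
    return CoCoSoResult(table=table, params=params)


@dataclass
class BaselineInputs:
    """Raw crisp inputs for the classical engine.

    ``m_mode`` selects the second aggregate: the power sum (classical P_i,
    the runnable default) or the literal weighted product, which under
    min-max normalization always meets a zero entry (each criterion's worst
    alternative normalizes to 0) and then raises a domain error.
    """

    matrix: pd.DataFrame  # alternatives x criteria, arbitrary positive scale
    directions: dict[str, str]
    weights: WeightVector
    epsilon: float = 0.5
    constant_column: str = "error"  # or "zero-fill"
    m_mode: str = "power-sum"


def minmax_normalize(
    x: pd.DataFrame, directions: dict[str, str], constant_column: str = "error"
) -> pd.DataFrame:
    """Per-criterion min-max scaling: benefit (x-min)/range, cost (max-x)/range."""
    norm = pd.DataFrame(index=x.index, columns=x.columns, dtype=float)
    for crit in x.columns:
        if crit not in directions:
            raise ValidationError(f"no direction given for criterion {crit!r}")
        col = x[crit].astype(float)
        tau = col.max() - col.min()
        if tau == 0:
            if constant_column == "zero-fill":
                norm[crit] = 0.0
                continue
            raise ValidationError(f"criterion {crit!r} is constant; min-max undefined")
        if directions[crit] == "benefit":
            norm[crit] = (col - col.min()) / tau
        else:
            norm[crit] = (col.max() - col) / tau
    return norm


def original_cocoso(inputs: BaselineInputs) -> CoCoSoResult:
    """Classical CoCoSo on a raw crisp matrix.

    Min-max normalizes each criterion, forms the weighted sum S and the
    second aggregate M per ``inputs.m_mode``, then the three compromise
    scores and the final fusion.  A constant column (zero range) raises by
    default or maps to all-zero under ``constant_column="zero-fill"``.
    """
    if inputs.m_mode not in M_MODES:
        raise ValueError(f"m_mode must be one of {M_MODES}")
    norm = minmax_normalize(inputs.matrix, inputs.directions, inputs.constant_column)
    omega = inputs.weights.weights.reindex(norm.columns)
    S = pd.Series(norm.values @ omega.values, index=norm.index, name="S")
    if inputs.m_mode == "power-product":
        if (norm.values == 0).any():
            raise ValidationError(
                "weighted product undefined: min-max normalization produced a "
                "zero entry; use m_mode='power-sum'"
            )
        M = pd.Series(np.prod(norm.values ** omega.values, axis=1),
                      index=norm.index, name="M")
    else:
        M = pd.Series(np.sum(norm.values ** omega.values, axis=1),
                      index=norm.index, name="M")
    params = CoCoSoParams(epsilon=inputs.epsilon, m_mode=inputs.m_mode)
    triples = compromise_scores(S, M, params)
    scored = final_scores(triples, params)
    table = pd.concat([S, M], axis=1).join(scored)
    return CoCoSoResult(table=table, params=params)
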