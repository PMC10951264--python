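"""Model/Results facade over the full group-decision pipeline.

``CoCoSoModel`` is built from the raw multi-expert data (a list of aligned
fuzzy decision matrices plus per-criterion benefit/cost directions) and the
method parameters; ``fit()`` runs aggregation -> entropy standardization ->
weighting -> CoCoSo scoring and returns a ``CoCoSoResults`` object carrying
every intermediate, a ``summary()`` table, and the sensitivity sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregation import AggregationStrategy, aggregate
from .cocoso import CoCoSoParams, CoCoSoResult, improved_cocoso, rank_descending
from .entropy import AttributeEntropyProfile, attribute_weights, matrix_entropy, standardize
from .matrix import CrispDecisionMatrix, FuzzyDecisionMatrix, WeightVector, check_aligned

__all__ = ["CoCoSoModel", "CoCoSoResults", "sensitivity_sweep"]


class CoCoSoModel:
    """Improved-CoCoSo group decision model.

    Parameters
    ----------
    sources : sequence of FuzzyDecisionMatrix
        One aligned matrix per expert/source (same alternatives, criteria, q).
    directions : dict
        Maps every criterion to "benefit" or "cost".
    k : float
        Entropy balance parameter (default 1/3).
    epsilon : float
        Equilibrium parameter of the third compromise score (default 0.5).
    aggregation : str or AggregationStrategy
        "compromised" (mean) or "inclusive" (envelope with repair clamp).
    weights : WeightVector, optional
        Override for the criterion weights; when omitted they are derived
        from the aggregated matrix by the entropy weight method.
    s2_mode, m_mode : str
        Score-variant switches forwarded to the scoring engine.
    """

    def __init__(
        self,
        sources: Sequence[FuzzyDecisionMatrix],
        directions: dict[str, str],
        *,
        k: float = 1.0 / 3.0,
        epsilon: float = 0.5,
        aggregation: str | AggregationStrategy = "compromised",
        weights: WeightVector | None = None,
        s2_mode: str = "as-printed",
        m_mode: str = "power-sum",
    ):
        self.sources = list(sources)
        check_aligned(self.sources)
        self.directions = dict(directions)
        self.k = float(k)
        self.epsilon = float(epsilon)
        self.aggregation = (
            aggregation if isinstance(aggregation, AggregationStrategy)
            else AggregationStrategy(name=aggregation)
        )
        self.weights_override = weights
        self.params = CoCoSoParams(epsilon=self.epsilon, s2_mode=s2_mode, m_mode=m_mode)

    @property
    def q(self) -> int:
        return self.sources[0].q

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, directions: dict[str, str], q: int = 2, **kwargs
    ) -> "CoCoSoModel":
        """Build from a long-format frame with columns
        ``source, alternative, criterion, mu_lo, mu_hi, nu_lo, nu_hi``."""
        from .io import matrices_from_frame

        return cls(matrices_from_frame(frame, q=q), directions, **kwargs)

    def fit(self, k: float | None = None, epsilon: float | None = None) -> "CoCoSoResults":
        """Run the pipeline; optional k/epsilon overrides for sweeps."""
        k = self.k if k is None else float(k)
        eps = self.epsilon if epsilon is None else float(epsilon)
        aggregated = aggregate(self.sources, self.aggregation)
        entropies = matrix_entropy(aggregated, k)
        crisp = standardize(aggregated, self.directions, k)
        if self.weights_override is not None:
            weights, profile = self.weights_override, None
        else:
            weights, profile = attribute_weights(aggregated, k)
        params = CoCoSoParams(epsilon=eps, s2_mode=self.params.s2_mode,
                              m_mode=self.params.m_mode)
        scored = improved_cocoso(crisp, weights, params)
        return CoCoSoResults(
            model=self, k=k, epsilon=eps, aggregated=aggregated,
            entropies=entropies, crisp=crisp, weights=weights,
            entropy_profile=profile, result=scored,
        )


@dataclass
class CoCoSoResults:
    """Fitted pipeline: every intermediate plus the scored ranking."""

    model: CoCoSoModel
    k: float
    epsilon: float
    aggregated: FuzzyDecisionMatrix
    entropies: pd.DataFrame
    crisp: CrispDecisionMatrix
    weights: WeightVector
    entropy_profile: AttributeEntropyProfile | None
    result: CoCoSoResult

    @property
    def scores(self) -> pd.DataFrame:
        return self.result.table

    @property
    def ranking(self) -> list[str]:
        return self.result.ranking

    def summary(self) -> str:
        lines = [
            "Improved CoCoSo group decision results",
            "=" * 54,
            f"sources:      {', '.join(s.source_id for s in self.model.sources)}",
            f"aggregation:  {self.model.aggregation.name} "
            f"(clamp: {self.model.aggregation.clamp_convention})",
            f"q = {self.model.q}, k = {self.k:.6g}, epsilon = {self.epsilon:.6g}",
            f"weights:      {'user override' if self.model.weights_override is not None else 'entropy-derived'}",
            "",
            "criterion weights:",
            self.weights.weights.to_string(float_format=lambda x: f"{x:.8f}"),
            "",
            "scores (best rank = 1):",
            self.scores.to_string(float_format=lambda x: f"{x:.9g}"),
            "",
            "ranking: " + " > ".join(self.ranking),
        ]
        return "\n".join(lines)

    def sensitivity(
        self,
        k_grid: Sequence[float] | None = None,
        epsilon_grid: Sequence[float] | None = None,
    ) -> "SensitivityReport":
        return sensitivity_sweep(self.model, k_grid, epsilon_grid)

    def plot_scores(self, ax=None):
        """Bar chart of final scores in ranking order (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ordered = self.scores.sort_values("rank")
        ax.bar(ordered.index, ordered["final"])
        ax.set_ylabel("final compromise score")
        ax.set_xlabel("alternative")
        return ax


@dataclass
class SensitivityReport:
    """Grid of rankings/scores over (k, epsilon) with stability diagnostics."""

    table: pd.DataFrame  # long format: k, epsilon, alternative, final, rank
    ranking_invariant: bool
    rankings: dict  # (k, epsilon) -> tuple of labels, best first
    min_gaps: pd.Series  # per-k minimum pairwise final-score gap (at base epsilon)
    degenerate: list  # (k, epsilon) points where the pipeline is undefined

    def ranking_at(self, k: float, epsilon: float) -> tuple[str, ...]:
        key = min(self.rankings, key=lambda ke: abs(ke[0] - k) + abs(ke[1] - epsilon))
        return self.rankings[key]


def sensitivity_sweep(
    model: CoCoSoModel,
    k_grid: Sequence[float] | None = None,
    epsilon_grid: Sequence[float] | None = None,
    gap_resolution: float = 1e-3,
) -> SensitivityReport:
    """Re-fit the pipeline on a (k, epsilon) grid and report rank stability.

    ``k`` enters both the entropy standardization and the entropy-derived
    weights (a user weight override is ignored here, because fixed weights
    cannot respond to k); ``epsilon`` enters the third compromise score.
    ``min_gaps`` records, per k at the model's base epsilon, the minimum
    pairwise gap between final scores — small gaps mean the ranking at that
    k is poorly resolved.

    For k > 1/2 the entropy can leave [0, 1] and some grid points make the
    standardization sign-degenerate; those points are collected under
    ``degenerate`` (and excluded from the invariance verdict) instead of
    aborting the sweep.
    """
    from .core import ValidationError

    if k_grid is None:
        k_grid = np.round(np.arange(0.0, 1.0 + 1e-12, 0.1), 10)
    if epsilon_grid is None:
        epsilon_grid = np.round(np.arange(0.0, 1.0 + 1e-12, 0.1), 10)
    if len(k_grid) == 0 or len(epsilon_grid) == 0:
        raise ValueError("k and epsilon grids must be non-empty")

    sweep_model = CoCoSoModel(
        model.sources, model.directions, k=model.k, epsilon=model.epsilon,
        aggregation=model.aggregation, weights=None,
        s2_mode=model.params.s2_mode, m_mode=model.params.m_mode,
    )
    rows = []
    rankings = {}
    gaps = {}
    degenerate = []
    for k in k_grid:
        for eps in epsilon_grid:
            try:
                res = sweep_model.fit(k=k, epsilon=eps)
            except ValidationError:
                degenerate.append((float(k), float(eps)))
                continue
            final = res.scores["final"]
            rankings[(float(k), float(eps))] = tuple(res.ranking)
            for alt in final.index:
                rows.append((float(k), float(eps), alt, float(final[alt]),
                             int(res.scores.loc[alt, "rank"])))
        try:
            base = sweep_model.fit(k=k, epsilon=model.epsilon).scores["final"].sort_values()
            gaps[float(k)] = float(np.diff(base.values).min())
        except ValidationError:
            gaps[float(k)] = float("nan")
    table = pd.DataFrame(rows, columns=["k", "epsilon", "alternative", "final", "rank"])
    unique = set(rankings.values())
    return SensitivityReport(
        table=table,
        ranking_invariant=(len(unique) == 1),
        rankings=rankings,
        min_gaps=pd.Series(gaps, name="min_final_score_gap"),
        degenerate=degenerate,
    )
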