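# ivqcocoso

Multi-expert decision analysis with interval-valued q-rung orthopair fuzzy
sets (IVq-ROFS): multi-source aggregation, parametric fuzzy entropy
weighting, and an improved CoCoSo (Combined Compromise Solution) ranking
engine.

## Who this is for

Analysts running multi-attribute **group** decision problems — several
experts each rate the same alternatives on the same criteria, and the
ratings are uncertain.  Each assessment is an IVq-ROFN: an interval
membership degree μ = [μ⁻, μ⁺] and an interval non-membership degree
ν = [ν⁻, ν⁺] with (μ⁺)^q + (ν⁺)^q ≤ 1.  The rung q controls how bold the
assessments may be (q = 1, 2, 3 recover the interval-valued intuitionistic,
Pythagorean and Fermatean families).  The package ships a worked clinical
example — six suspected-sepsis patients assessed by two physicians on nine
clinical attributes — and a supplier-selection example.

## The pipeline

1. **Aggregation** (per cell over experts): *compromised* — the componentwise
   mean, always valid by convexity of t ↦ t^q — or *inclusive* — the
   min/max envelope [min μ⁻, max μ⁺], [min ν⁻, max ν⁺], with a repair clamp
   on ν⁺ when the envelope breaks the rung constraint.
2. **Entropy standardization.** Each aggregated cell gets the parametric
   fuzzy entropy

   E = 1 − ½ (μ↘ + μ↗ + ν↘ + ν↗),   μ↘ = min(|μ⁻^q − k|, |μ⁺^q − k|),  μ↗ = max(…),

   which is 0 on crisp elements and 1 at the balance point
   μ = ν = [k^{1/q}, k^{1/q}].  Benefit criteria keep E, cost criteria use
   1 − E, and each criterion's column is normalized to sum to 1 over the
   alternatives.
3. **Entropy weighting.** Criterion weights ω_j ∝ (1 − Ē_j)/(m − ΣĒ), where
   Ē_j is the criterion's normalized mean entropy: the less fuzzy a
   criterion, the more it weighs.  A user-supplied weight vector can
   override this step.
4. **Improved CoCoSo.** Weighted sum S_i = Σ_j ω_j r̄_ij and power sum
   M_i = Σ_j r̄_ij^{ω_j} feed three compromise scores — s1 (share of total),
   s2 (relative to the worst, ≥ 2), s3 (ε-balanced share of the best) — and
   the fusion S_i = (s1+s2+s3)/3 + (s1·s2·s3)^{1/3}; alternatives are ranked
   by descending fusion.  The classical CoCoSo on raw crisp matrices is also
   provided (`original_cocoso`), as are sensitivity sweeps over (k, ε).

## Worked example

```python
from ivqcocoso import CoCoSoModel, datasets

sources = datasets.sepsis_sources()          # two experts, 6 patients x 9 attrs
model = CoCoSoModel(
    sources,
    datasets.sepsis_directions(),            # benefit/cost per attribute
    weights=datasets.sepsis_published_weights()  # published objective weights
)
results = model.fit()
print(results.summary())
```

prints (abridged):

```
scores (best rank = 1):
             S          M          s1         s2          s3      final  rank
A1 0.170021524 7.37435007 0.167143785 2.16178667 0.992056496 1.81735782     4
A2 0.171558144 7.39336818  0.16759917 2.17473651 0.994759366 1.82543504     2
A3 0.172061248 7.38270212 0.167374012 2.17663987 0.993422975 1.82511798     3
A4 0.179167787 7.42561241 0.168482123 2.23029976           1 1.85454252     1
A5 0.160126185  7.3293088 0.165926677 2.08910356 0.984832538 1.77885075     5
A6 0.148906892 7.22983205 0.163474232          2 0.970276425 1.72659489     6

ranking: A4 > A2 > A3 > A1 > A5 > A6
```

Patient A4 is the strongest sepsis suspect under the combined expert
evidence; A6 the weakest.  S and M are the two aggregates, s1–s3 the
compromise scores (note s2's different scale — the motivation for the
log-normalized s2 variant), and `final` their fusion.  The same numbers are
available stage by stage (`results.aggregated`, `results.crisp`,
`results.weights`) and from the command line:

```bash
ivqcocoso rank --fixture sepsis --weights published
ivqcocoso sensitivity --fixture sepsis --k 0:1:0.1 --epsilon 0:1:0.1
ivqcocoso synth --seed 7 --out my_experts.csv
```

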