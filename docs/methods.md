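# Methods

## The model

An IVq-ROFN assessment carries an interval membership degree μ = [μ⁻, μ⁺]
and interval non-membership degree ν = [ν⁻, ν⁺] in [0, 1] with
(μ⁺)^q + (ν⁺)^q ≤ 1 for an integer rung q ≥ 1.  The residual hesitancy is
π = [(1 − μ⁺^q − ν⁺^q)^{1/q}, (1 − μ⁻^q − ν⁻^q)^{1/q}].  A decision problem
is a set of such assessments on an alternatives × criteria grid, one grid
per expert, with a benefit/cost direction per criterion.  All grids in one
problem must share a single q; mixed rungs are rejected, because every
downstream formula is parameterized on q.

The pipeline is: multi-source aggregation → parametric fuzzy entropy
standardization → entropy weighting → improved CoCoSo scoring → ranking.
The stages are exposed individually and through the `CoCoSoModel` /
`CoCoSoResults` facade.

## Parameters that matter

| parameter | meaning | default | notes |
|---|---|---|---|
| q | rung of the fuzzy numbers | 2 (sepsis data) | 1/2/3 = intuitionistic / Pythagorean / Fermatean special cases |
| k | entropy balance parameter ∈ [0, 1] | 1/3 | locates maximal fuzziness at μ = ν = [k^{1/q}, k^{1/q}] |
| ε | equilibrium weight in the third compromise score | 0.5 | ε = 1 → S/max S, ε = 0 → M/max M |
| clamp | inclusive-envelope repair | upper-bound | see below |
| m_mode | second aggregate | power-sum | power-product available for the literal formula |
| s2_mode | scale of s2 | as-printed | log-normalized variant maps s2 into (0, 1] |

## Aggregation and the repair clamp

The compromised aggregate is the componentwise mean; its validity is
guaranteed (by convexity of t ↦ t^q, mean(μ⁺)^q + mean(ν⁺)^q ≤
mean(μ⁺^q + ν⁺^q) ≤ 1).  Expert weights are uniform by default; a per-source
weight vector is accepted as an extension hook.

The inclusive aggregate is the min/max envelope, which can violate the rung
constraint.  Three repair conventions for ν⁺ are implemented:

* **upper-bound** (default): ν⁺ ← (1 − (μ⁺)^q)^{1/q}; always restores
  validity, and is the only anchor that can.
* **grid-step**: decrement ν⁺ by 0.1 until valid — the repair the published
  worked tables actually apply to their 1-decimal data (their two violated
  cells print 0.8 → 0.7 and 0.9 → 0.8, not the upper-bound values 0.7141
  and 0.8660).  Used by the golden fixtures; sensible only for assessments
  on a 0.1 grid.
* **lower-bound**: ν⁺ ← (1 − (μ⁻)^q)^{1/q}, kept for fidelity to the
  rule's published wording.  It cannot guarantee the constraint (e.g. for
  the envelope of ⟨[0.5,0.8],[0.1,0.3]⟩ and ⟨[0.2,0.6],[0.4,0.7]⟩ at q = 2
  it leaves 0.64 + 0.96 > 1); still-violating cells are recorded in the
  repair log and a warning is emitted rather than silently passing.  When a
  clamp lands below ν⁻, ν⁻ is capped at the clamped ν⁺ to keep the interval
  ordered.

## Entropy: domain of validity

E = 1 − ½(μ↘ + μ↗ + ν↘ + ν↗) with μ↘/μ↗ the min/max of |μ^q − k| over the
two bounds, likewise for ν.  E is exactly symmetric under swapping μ and ν
(the implementation groups the summation so the symmetry is float-exact),
zero on crisp elements for every k, and one exactly at the balance point.

The balance point is a *feasible* element only when 2k ≤ 1 (its constraint
load is (k^{1/q})^q · 2 = 2k, independent of q).  For k > 1/2 the measure
provably leaves [0, 1]: at q = 2, k = 1 the valid element μ = ν = [0.5, 0.5]
has E = −0.5.  The axiom checks for range, balance point and
crisper-monotonicity therefore apply on k ≤ 1/2 only; complement symmetry
and the crisp fixed points hold for every k.  Standardization remains
well-defined at large k whenever each column is uniformly signed before
normalization (the sign cancels in r̄ = r/Σr); sign-mixed columns are
genuinely degenerate and raise, and the sensitivity sweep records such grid
points instead of failing (on the sepsis data this affects k ∈ {0.6, 0.7,
0.8}).

## Weighting

Per criterion, the raw entropy E_j is the mean cell entropy over
alternatives; Ē_j = E_j/ΣE_i sums to 1 across criteria, and
ω_j = (1 − Ē_j)/(m − ΣĒ_i), renormalized, gives the weights — lower
normalized fuzziness, higher weight.  With ΣĒ = 1 the renormalization is a
no-op, so the weights sum to 1 by construction.  A single-criterion problem
returns weight 1 with a warning (the denominator m − ΣĒ degenerates).

The published sepsis weight vector could **not** be re-derived from this
(or any variant we tried: Shannon entropy on the standardized matrix,
cost-complemented entropies, sum instead of mean); it is therefore shipped
verbatim as a fixture (summing to 1.00184178, not 1) and injected as a
weight override for the golden score chain, while the library's own
weighting path always renormalizes.

## CoCoSo scoring

The improved engine consumes the column-normalized standardized matrix.
The second aggregate defaults to the power **sum** Σ_j r̄^{ω_j}: the
published intermediate values can only be power sums (a weighted product of
sub-unit entries cannot exceed 1, yet the published values are ≈ 7.4), and
the power sum is the classical CoCoSo P_i operator.  The literal power
product remains available.  Guaranteed score identities: Σ s1 = 1 always;
min s2 = 2 and max s3 = 1 exactly when one alternative attains both
component minima (maxima), which holds in the case data — in general they
are one-sided bounds.  Ties in the final score are broken by alternative
label order with a warning.

The classical engine (`original_cocoso`) min-max normalizes a raw crisp
matrix.  Its literal weighted-product aggregate is degenerate there — each
criterion's worst alternative normalizes to 0, so some product is 0 and s2
divides by zero on *every* input — so the engine defaults to the power sum
and the product mode raises a domain error when it meets a zero.

The log-normalized s2 variant (s2′ = ln s2_i / Σ ln s2_i) implements the
idea of mapping s2 onto the same [0, 1] scale as s1 and s3; no reference
values exist for it, so it is never used in golden tests.

## Reproducing the published chain

The bundled examples reproduce the published tables cell for cell under the
following conventions, each established by residual analysis (an
order-of-magnitude drop in the worst residual when the convention is
adopted):

* sepsis rung q = 2 and the compromised aggregate feed the standardized
  matrix (its published caption says "inclusive", but its contents derive
  from the compromised aggregate — the numbers, not the caption, are
  followed);
* the balance parameter was carried as **k = 0.333333** (the six-digit
  truncation of the stated 1/3) and the standardized matrix at **9 decimal
  places**; with these, every published weighted sum, power sum and
  compromise score reproduces to < 2 units of its last printed digit
  (worst 1.84), while exact k = 1/3 leaves s2 off by ~480 units;
* the supplier example states no q; q = 3 is used — the first rung at which
  every printed cell, including the inclusive envelope's ⟨[0.1,0.6],
  [0.2,0.9]⟩, is valid.

Misprints found and corrected in the bundled fixtures (the package computes
everything from the corrected sources; the corrections are the unique
1-decimal values consistent with *all* downstream tables):

* supplier compromised aggregate, row O6: the published row repeats the
  second expert's input row; the fixture stores the defining componentwise
  mean;
* sepsis expert tables: X2 cell (C3, A2) lower membership 0.3 → 0.2 and X1
  cell (C8, A6) upper non-membership 0.5 → 0.6;
* two obvious notation slips ("0.1.0.5", an unclosed bracket) transcribed
  by intent.

Two published results are documented as irreproducible and excluded from
assertions: the final-score *values* of the ranking tables (direct fusion
of the published triples gives e.g. 1.8173576 for A1 against a published
1.670855; the implied transformation is not stated — the *ranking* agrees
and is asserted), and the inclusive-chain ranking (computed
A4 > A5 > A2 > A1 > A3 > A6 under either weight choice against a published
A2 > A1 > A3 > A5 > A4 > A6).

## Sensitivity analysis

`sensitivity_sweep` re-runs the pipeline over a (k, ε) grid, re-deriving
the entropy weights at each k (a fixed override cannot respond to k) and
reporting the per-point rankings, an invariance flag, the per-k minimum
pairwise final-score gap (a resolution measure), and degenerate grid
points.  On the sepsis data the ranking is invariant in ε at k = 1/3, and
k = 1 resolves the alternatives more poorly than k = 1/3 (minimum gap
0.00042 vs 0.00072) — both behaviors the sweep is designed to surface.

## Synthetic data

`generate_synthetic` draws valid-by-construction cells: μ⁺ ~ U(0, 1),
ν⁺ ~ U(0, (1 − μ⁺^q)^{1/q}), μ⁻ ~ U(0, μ⁺), ν⁻ ~ U(0, ν⁺), deterministic
per seed.  Defaults mirror the sepsis study (6 alternatives, 9 criteria, 2
sources, q = 2, 4/9 cost criteria).  The generator emulates structural
validity and shape only: real expert panels exhibit 0.1-gridded values,
inter-expert correlation and benefit/cost asymmetries that independent
uniform draws do not, so passing randomized suites demonstrates algebraic
correctness of the pipeline, not calibration to clinical data.

## Numerical choices

Tolerances: rung-constraint slack 1e-9 (admits 1-decimal boundary data such
as 0.6² + 0.8² = 1 exactly); hesitancy radicands negative by ≤ 1e-9 clamp
to 0; normalization sums checked at 1e-9.  Golden tests compare at 1 ulp of
the printed decimals (standardized matrix) and 2 ulp (score tables);
property tests compare double precision against a 50-digit mpmath oracle at
1e-12.  Degenerate inputs (constant columns in min-max scaling, zero or
sign-mixed normalization columns, single criteria) raise structured errors
or warn, as described above.

## Known limitations

* Published final-score values and the inclusive-chain ranking are not
  reproducible (previous section); rank-level fidelity only.
* The entropy is a proper [0, 1] fuzziness measure only for k ≤ 1/2; the
  sweep reports rather than ranks the degenerate k region.
* No support for incomplete grids, per-expert criterion subsets, or
  hesitant/complex fuzzy extensions; one rung per problem.
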