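# Methods

`pnnet` estimates and summarizes a partial-correlation network over a
12-variable panel measured on newly diagnosed head-and-neck cancer
patients: five patient-reported psychoneurological symptom scores (PSQI
sleep quality, HADS anxiety and depression, EORTC QLQ-H&N35 oral pain,
MFI general fatigue), the diurnal cortisol slope, four blood
inflammation markers (CRP, IL-6, IL-10, TNF-α), and two covariates (age,
BMI). This note records the model, the numerical choices, what the
synthetic-data generator does and does not emulate, and the package's
design decisions where the design was genuinely open.

## Model and pipeline

The statistical model is a Gaussian copula graphical model. Each
variable is assumed to be a monotone transform of a latent Gaussian;
edges are partial correlations of the latent Gaussian, i.e. associations
that survive conditioning on all remaining variables. The pipeline:

1. **Derived variables.** The diurnal cortisol slope is
   (awakening − 22:00 concentration) / elapsed hours, using the
   patient-noted clock times; the two mid-morning samples are collected
   but not used by the slope. A negative slope means cortisol rose
   during the day. BMI is weight (kg) / height² (m²) — note the kg/m²
   unit implies the squared-height formula even where the linear form is
   sometimes written.
2. **Listwise selection.** Only rows complete on all 12 variables enter
   the analysis.
3. **Nonparanormal transform.** Per column: average ranks `r_i`,
   shrunken ECDF `u_i = r_i/(n+1)` winsorized to `[δ, 1−δ]` with
   `δ = 1/(4 n^{1/4} √(π log n))`, standard-normal quantiles, rescaled
   to unit sample SD. Monotone per column; ties map to identical values;
   the winsorization ties the most extreme ~`δ·n` ranks at each tail.
4. **Covariance.** Maximum-likelihood divisor `n` (matching the
   penalized-likelihood formulation; an `n−1` toggle exists). After the
   transform all variables have unit variance, so covariance vs
   correlation input is immaterial.
5. **Targeted ridge precision.** Closed form
   `Ω(λ) = {[λI + ¼(S−λT)²]^{1/2} + ½(S−λT)}^{-1}`, evaluated through
   the symmetric eigendecomposition of `S − λT` (the matrix is
   symmetrized `(M+Mᵀ)/2` first; symmetry is enforced to `1e-10`). Every
   eigenvalue of `Ω(λ)` is positive for every `λ > 0`, so the estimate
   is positive definite even for singular `S`. Default target
   `T = νI` with `ν = p/trace(S)` (scaled identity); zero, identity and
   explicit PSD targets are accepted.
6. **Penalty selection.** The penalty is not a quantity the reference
   analysis reports, so it is chosen by 5-fold cross-validated held-out
   Gaussian log-likelihood over a logarithmic grid `1e-4 … 1e2`
   (25 points), with seeded fold assignment. Held-out scatter is
   computed around the training mean. This is the principal caveat for
   numerical reproduction of any particular fitted edge weight: with an
   unreported penalty, edge *weights* are reproducible only
   qualitatively, while the *structure* is robust across a wide penalty
   range at the 0.1 threshold.
7. **Sparsification.** Edge `(i,j)` present iff `|pcor_ij| ≥ 0.1`
   (inclusive). Edges keep their signed weight.
8. **Graph summaries.** All centralities are computed on the
   *unweighted* sparsified graph: degree; closeness as the reciprocal of
   the shortest-path distance **sum** (not mean); betweenness as
   unnormalized Brandes counts with each unordered pair counted once.
   The unweighted/sum conventions are fixed by the published table
   itself: its closeness values are reciprocals of integers
   (0.040 = 1/25, 0.033 = 1/30, …) and its betweenness values are thirds
   (11.33, 25.33), the signature of unweighted shortest-path counting
   with tie splitting. Communities come from Girvan–Newman edge
   removal (unweighted edge betweenness, recomputed after every removal,
   ties broken by lexicographic edge order) with the dendrogram cut that
   maximizes unweighted Newman–Girvan modularity on the original graph;
   the trivial one-community cut (modularity 0) is a candidate, so a
   modularity-negative split is never forced. Display layout is seeded
   Fruchterman–Reingold.

Display rounding mirrors the reference table: betweenness to 2 decimals,
closeness to 3.

### Numerical and degenerate-input choices

- Constant columns, missing values inside the estimator, non-positive
  penalties, asymmetric inputs, and non-positive precision diagonals are
  rejected with diagnostics rather than silently repaired.
- Disconnected sparsified graphs: closeness is computed within each
  connected component with a warning (isolates get closeness 0);
  `strict=True` rejects instead.
- The ridge estimator is rotation-equivariant but *not* equivariant
  under per-variable rescaling (the matrix square root does not commute
  with diagonal scaling). The pipeline therefore standardizes to unit
  variance (step 3) before estimation. The exact invariance that does
  hold — `S → cS`, `T → T/c`, `λ → c²λ` gives `Ω → Ω/c` and unchanged
  partial correlations — is what the tests assert.

## Reconstructing the published network from its centrality table

The cohort behind the reference analysis is access-restricted, so the
published per-node centrality table is used as a worked example in
reverse: a backtracking search enumerates **all** simple labeled graphs
on the 12 named nodes whose degree column matches exactly and whose
closeness (or betweenness) column matches within a rounding tolerance,
together with the one edge the accompanying text pins down (the
cortisol-slope node is a pendant attached to sleep, the network's single
negative edge).

Search machinery: pendants are eliminated analytically
(`distsum(pendant) = distsum(neighbor) + n − 2` propagates the closeness
constraint onto the attachment); the 10-node core is enumerated by
deciding each node's neighborhood in descending-degree order, pruned by
Erdős–Gallai graphicality of the residual degree sequence, per-node
distance-sum lower bounds from BFS over the *potential graph* (decided
edges plus a clique over nodes that can still gain edges), distance-sum
upper bounds from BFS over decided edges, and — when the betweenness
column is the constraint — two further implications: a printed
betweenness of 0 forces a clique neighborhood (a non-adjacent neighbor
pair would contribute at least 1/10 on 12 nodes), and the identity
`Σ_pairs d(u,v) = Σ_v betweenness(v) + C(n,2)` pins the total distance
sum exactly. Adjacency is held in bitmasks; the two full-size searches
take on the order of one to five minutes each on one CPU.

Outcomes, verified by the tests:

- **Degree + closeness (±0.0015), betweenness withheld:** exactly two
  labeled solutions, which are the same graph up to swapping the labels
  of depression and IL-6 (both have degree 4 and closeness 0.045, so the
  constrained columns cannot tell them apart). The swap is resolved by
  the published two-cluster community memberships (a constraint that is
  independent of the withheld betweenness column): the swapped variant
  wires depression into the cytokine cluster and is rejected. The
  surviving graph reproduces the entire printed betweenness column to
  2 decimals. The betweenness values of sleep, oral pain, TNF-α and
  anxiety are unanimous across both solutions even without the
  community constraint.
- **Degree + betweenness (±0.005), closeness withheld:** a unique
  solution — the same graph — whose closeness column reproduces the
  printed one within ±0.0015.
- **Closeness tolerance.** The printed closeness of the cortisol node
  (0.028) is one rounding step away from the value its forced pendant
  position implies (1/35 = 0.0286 → 0.029). The tolerance is therefore
  one rounding step loose (±0.0015 rather than ±0.0005); with a strict
  half-step tolerance the constraint set is infeasible, which localizes
  the tension to that single printed cell rather than hiding it.

## Synthetic cohort generator

The generator defines the study conditions for all stochastic tests.

- **Latent structure.** The ground-truth partial-correlation matrix has
  unit diagonal and the 18-edge support of the reconstructed published
  network, weight +0.2 on every edge except sleep–cortisol at −0.2 (the
  single negative edge). The implied precision `2I − P` has minimum
  eigenvalue ≈ 0.26, comfortably positive definite. Latent rows are
  multivariate normal with the corresponding correlation matrix.
- **Marginals.** Each column is the latent normal pushed through a
  quantile transform anchored to the published per-variable summaries:
  Gaussian for age (65, SD 8.2) and BMI (26.1, SD 4.5); for skewed
  variables a piecewise-linear quantile function through the published
  quartiles with exponential tails whose scale matches the adjacent
  inter-quartile slope — applied on the log scale for CRP and the
  cytokines (keeping them positive with lognormal-type tails) and on the
  natural scale for the bounded instrument scores and the cortisol slope
  (which must admit negative values). Bounded scores are clipped to
  their instrument range and rounded to the instrument step (integers
  for PSQI/HADS/MFI, 0.1 for the 0–100 oral-pain score); clipping and
  rounding leave the quartile anchors essentially unchanged because the
  anchors sit well inside the bounds. Item-level questionnaire
  simulation is deliberately out of scope.
- **Missingness.** Completely at random per variable, at the published
  per-variable missing fractions (e.g. cortisol slope 340/739 ≈ 46%,
  sleep 179/739 ≈ 24%, age 0%). The real cohort's missingness was
  component-wise (patients opted out of assessment blocks), i.e.
  *correlated* across variables, which is why its observed 36%
  complete-case fraction is higher than independent masking at the same
  rates yields (≈ 9%); the generator makes no attempt to match that
  fraction, and the tests compare against an independent-masking
  Monte-Carlo oracle instead.
- **Saliva profiles.** Four samples (awakening ~N(07:00, 45 min), +30
  and +60 min, 22:00) with a 20–60% post-awakening peak; the evening
  concentration is lognormal (median 2 nmol/L) and the awakening value
  is evening + slope × elapsed hours, with the slope drawn from the
  published slope distribution, so the derived slope median is ≈ 0.47
  nmol/L/h by construction. Values below the assay's quantitation limit
  (1.0 nmol/L) are flagged, and awakening values are floored at
  0.2 nmol/L (this truncation affects only the far-left tail).
- **Seeding.** One master seed is split into named substreams (latent,
  missingness, saliva), so each stage is independently reproducible and
  bit-identical under an identical seed and spec.

**What passing tests show — and don't.** The generator reproduces the
published marginal locations/spreads, a known sparse conditional
dependence structure, and per-variable missingness rates. It does not
reproduce item-level score granularity beyond simple rounding,
block-correlated missingness, assay measurement error, or any
between-variable structure beyond the Gaussian copula. Structure
recovery on these cohorts (sensitivity and specificity ≥ 0.9 at n=2000,
true |pcor| = 0.2, threshold 0.1) therefore demonstrates correctness of
the estimation code under the model's own assumptions, not performance
on real, messier data.

## Group comparison machinery

Complete vs incomplete groups are compared per variable with the test
chosen by a declared kind: chi-square on contingency counts (no Yates
correction by default, toggle available), unpaired t-test, or
Mann-Whitney U (normal approximation with tie and continuity correction;
exact enumeration below 8 per group). Raw two-sided p-values are
adjusted by Benjamini–Hochberg step-up FDR (Benjamini–Yekutieli
available); significance at adjusted p < 0.05. Which variables count as
normal vs skewed follows the display convention of the reference
cohort table: mean/SD rows → t-test, median/IQR rows → Mann-Whitney,
percent rows → chi-square. Reproducing that table's actual values is
impossible without the restricted cohort and is not attempted.

## Problem sizes used by the test and acceptance runs

Synthetic cohorts of n = 2000 for structure recovery and marginal
checks (n = 20000 once for quartile convergence); 500 random graphs of
up to 9 nodes for the exhaustive centrality cross-check; the two
full-size reconstruction searches run once each. These sizes keep the
whole suite within a few minutes while leaving the stochastic assertions
far from their tolerance boundaries.

## Known limitations

- The ridge penalty used in the reference analysis is unreported;
  penalty selection is the package's own choice (documented above), so
  fitted edge weights are comparable only in structure and sign.
- The constraint search assumes the printed table was produced under
  the unweighted sum-reciprocal closeness and pair-once Brandes
  betweenness conventions; the numeric fingerprints above support this,
  but it remains an inference.
- MCAR missingness and the Gaussian copula are simplifications of the
  real cohort's data-generating process (see above).
- Community detection returns a single best-modularity cut; near-ties
  between cuts are not surfaced.
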