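# Methods

This note documents the statistical model behind `morbigraph`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Cohort model

The unit of analysis is a person-level table: age at index date, one binary
flag per study disease, and two follow-up utilisation counts (outpatient
interactions; unplanned inpatient admissions). The disease universe is an
Elixhauser-derived catalogue of 29 flags collapsed to 26 by OR-merging three
condition/complication pairs (cancer + metastatic cancer → Any Cancer;
diabetes ± complication; hypertension ± complication), which would otherwise
co-occur almost by construction and pseudocluster. Persons with no flagged
disease remain in the cohort: they contribute to the population size `P` and
to prevalence denominators, but never to an edge. Utilisation counts are
treated as fixed per-person totals over the follow-up window; there is no
censoring or person-time adjustment.

## Hypergraph construction

**Edge universe.** Hyperedges are the unique *exact profiles* of size ≥ 2
observed in the cohort — the set of study diseases a person carries and no
others. This is the only edge definition under which the exact-set HRU
weighting assigns each edge a non-overlapping person stratum (each
multimorbid person feeds exactly one edge, so Σ n_exact equals the number of
multimorbid persons — a tested invariant), and it sidesteps the exponential
cost of enumerating all co-occurring subsets. Each edge carries two support
counts: `n_exact` (persons whose profile equals the set) and `n_all`
(persons carrying every member, supersets included).

**Prevalence/overlap weights.** Node weight `w^N_i = |X_i|/P`. Edge weight
is the generalised overlap coefficient
`|X_i ∩ … ∩ X_l| / min(|X_i|, …, |X_l|)` — the fraction of the rarest
member's carriers who carry every member. The numerator is `n_all` (carriers
of all members, other diseases permitted), not `n_exact`. It is undefined
when a member has no carrier, which cannot happen for observed edges.

**HRU weights.** Node and edge weights are directly age-standardised event
rates per 100,000: per 5-year band `b`, the crude rate `r_b` = events /
persons in the stratum, combined as `100,000 · Σ w_b r_b / Σ w_b` with
ESP 2013 band weights, the sum running over bands the stratum occupies
(renormalisation over occupied bands, so small strata are not penalised for
empty bands; switchable with `renormalise=False`). Bands are half-open
`[lower, upper)`, 5-year, from 20–24 to 90+, the standard convention for an
adult cohort. Edge strata are exact profiles; node strata are exact
singletons by default, because it keeps nodes and edges on the same footing
(`node_stratum="all_carriers"` is available, since either reading is
defensible). An empty stratum gets weight 0 with a logged warning, which
keeps bootstrap replicates computable when a rare stratum disappears.

## Dual eigenvector centrality

The importance of disease *sets* is the node centrality of the dual
hypergraph. With `M` the node×edge incidence, `W_N = diag(w^N)` and
`S = diag(√w^E)`, the dual adjacency is

    A* = S (Mᵀ W_N M) S,  diagonal zeroed.

Two sets are adjacent with strength = node-weight mass of their shared
diseases, scaled by both sets' own edge weights. Choices made here:

* the symmetric square-root weighting guarantees a real spectrum and a
  non-negative Perron vector, and makes a set's score depend on its own
  weight and its neighbours' weights in the same way; a linear alternative
  would be a one-function swap in `dual_adjacency`;
* the diagonal is zeroed (standard for graph eigenvector centrality;
  prevents large sets from self-inflating);
* centralities are rescaled to max = 1, not unit L2 norm, so values are
  comparable across hypergraphs before combination.

The leading eigenvector is computed by power iteration on `A* + cI` with
`c` = maximum row sum. The shift preserves eigenvectors and makes the
leading eigenvalue strictly dominant in modulus; without it, iteration
oscillates on bipartite adjacency structures (the 3-edge path has spectrum
±√2, 0). Defaults: tolerance 1e-10 on the max-norm difference of successive
max-normalised iterates, 10,000 iterations, deterministic all-ones start
(which also resolves the measure-zero tie between disconnected components of
equal spectral radius). Isolated edges get exactly 0. A dense symmetric
eigendecomposition (`brute_force_centrality`, guarded at 2,000 edges) serves
as an independent cross-check; the two agree to < 1e-8 on every test
instance.

## Bootstrap uncertainty and the discard rule

Persons are resampled with replacement, cohort-sized, `B` times; the whole
hypergraph-and-centrality pipeline is rerun per replicate and replicates are
aligned by canonical disease-set label. A set absent from a replicate's edge
list contributes centrality 0 there — deliberately, because the discard rule
then behaves correctly for rare sets: a 1-person set is absent from ≈ 1/e of
replicates, so its 2.5th percentile is 0 and it is discarded. The estimate
is the bootstrap mean; the 95% interval is the empirical 2.5/97.5 percentile
pair (linear interpolation — noted because `B` is small). Sets with
`ci_lower ≤ 0` (including exactly 0) are discarded. Per-replicate generators
are seeded as `(master_seed, replicate_index)`, so any replicate is
reproducible in isolation and results are independent of execution order.
`B` defaults to 100; desk-scale analyses and the test suite use 25–50.

## Composite importance

To find sets important on several axes at once: keep sets strictly above the
median retained centrality in *every* component table (strictness is the
documented boundary rule; a set missing from any table is excluded), then
max-normalise each surviving component vector and score by the Euclidean
combination √(Σ components²). Components are equally weighted by default;
an optional weight vector scales components before squaring. Ranks are
deterministic: descending composite, ties to the smaller set, then
lexicographic label. Single-disease appearance summaries count how often
each disease features among the listed sets; the denominator is the full
combined table by default, with a top-k variant available, since either
convention is reasonable.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
population:

* **Disease flags** come from a latent-factor threshold model: per person,
  independent standard-normal factor scores `f_k` and noise; disease `i` is
  flagged when `ε_i + Σ_k s_k λ_{ki} f_k` exceeds the normal quantile
  matched to the (age-adjusted) marginal, standardised by the score's exact
  variance. Marginals are therefore recovered exactly in expectation (a
  tested property), while shared factors induce co-occurrence blocks.
* **Age** enters prevalence through a log-odds slope per decade anchored at
  age 50, and is drawn from configurable adult (20+) band probabilities.
* **Utilisation counts** are zero-inflated negative binomial (gamma–Poisson)
  with log-mean = log(baseline) + β·(number of diseases) + γ_S for persons
  whose exact profile equals a planted cost set S. Defaults, chosen once as
  clinically plausible: outpatient π = 0.25, baseline 2.0 visits per
  follow-up window, β = 0.35 (each extra disease multiplies visits by ≈1.4),
  dispersion 1.2; inpatient π = 0.5, baseline 0.3, β = 0.40, dispersion 0.8.
  This reproduces the geometric-like count decay with an enhanced zero
  count seen in routine interaction data.
* **Planted structure**: a co-occurrence plant forces a whole set on with
  probability (boost − 1) × Π(member marginals), i.e. a boost-fold increase
  of the joint probability over the independence baseline; a cost plant adds
  γ to the log-mean of exact-profile matches. Because the cost increment
  applies only to exact profiles, a detectable cost plant needs real exact
  support — in the recovery tests it rides on a co-occurrence-boosted triple.

Default study conditions: 20,000 persons, the 26 merged diseases at their
realistic marginal prevalences, three co-occurrence blocks (cardiometabolic,
respiratory/frailty, mental health), one planted triple
(Diabetes & Hypertension & Obesity, boost 50 ≈ 2% of the cohort) and one
planted high-cost pair (Diabetes & Hypertension, γ = 1.5).

**What passing tests show — and don't.** The generator produces exactly
binary flags, exchangeable persons, and stationary utilisation; it does not
simulate coding noise, death/censoring, longitudinal trajectories, or the
dependence structure of any real cohort (which is unknowable from published
marginals alone). Tests on it demonstrate that the pipeline's algebra is
correct, that planted signal of realistic size is recovered, and that the
discard rule removes low-support sets — not that rankings from any
particular healthcare system would be reproduced.

## Numerical and scale choices

Problem sizes in the test suite and acceptance script — 20,000-person
cohorts, 10–26 diseases, 25–50 bootstrap replicates, 20 seeds for recovery
frequencies — were chosen so a full run completes in a few minutes on one
CPU while leaving the statistical conclusions stable; all are parameters,
not limits. Profiles are bit-packed into int64 keys (≤ 62 diseases), so
edge enumeration is a single `unique` plus a chunked bitwise subset scan.
Degenerate inputs are defined behaviour: an empty edge list warns and flows
through as empty outputs; a replicate with < 2 edges contributes 0 for every
set; power-iteration non-convergence in a replicate is retried once with a
perturbed start and then raised with its residual.

## Known limitations

* The dual-adjacency construction is one defensible reading of
  "centrality of the dual representation"; variants (degree corrections,
  non-zeroed diagonal, linear weight scaling) would change numbers, which is
  why the construction is isolated in one function.
* Percentile intervals at B ≈ 25–100 are coarse (granularity 1/B) and not
  bias-corrected; no BCa or studentised intervals.
* HRU rates over very small exact strata are heavy-tailed; the CI discard
  rule removes most but not all low-support noise (absence probability falls
  below 2.5% once a stratum holds ≥ 4 persons).
* Composite scores carry no propagated uncertainty.
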