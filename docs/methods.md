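# Methods

This note documents the models, estimators, numerical choices and known
limitations behind egakit.

## The model

The data model is a battery of p continuous, standardized scores with a
positive manifold (all pairwise correlations non-negative). Dimensionality
is defined operationally: the communities of the Gaussian graphical model
(GGM) whose edges are regularized partial correlations. A zero edge means
conditional independence given all other scores; a community is a set of
scores that remain mutually associated after the shared variance with the
rest of the battery has been partialled out.

Estimation composes three standard pieces:

* **Graphical lasso** (scikit-learn's coordinate-descent implementation)
  for the L1-penalized precision matrix at each penalty λ;
* **EBIC** model selection over a log-spaced path of `n_lambda = 100`
  penalties from λ_max = max|r_ij| down to `lambda_min_ratio = 0.01` of
  it, with γ = 0.50 (γ is the sparsity preference; 0 recovers BIC);
* **Walktrap** community detection (python-igraph) with 4-step random
  walks on the absolute edge weights, cutting the merge dendrogram at
  maximum weighted modularity.

The bootstrap layer re-runs that whole unit on parametric resamples and
summarizes the sampling distribution of solutions.

## Parameters that matter

| Parameter | Default | Meaning / why |
| --- | --- | --- |
| `gamma` | 0.50 | EBIC sparsity preference; the field-standard starting value for psychometric networks. |
| `n_lambda`, `lambda_min_ratio` | 100, 0.01 | Penalty path resolution and lower endpoint, following the reference implementations of EBIC-glasso model selection. |
| `tol`, `max_iter` | 1e-3, 50 | Coordinate-descent stopping rule. Validated against tol=1e-4/max_iter=200: identical selected edge sets on batteries of this size, at ~10x speed. Dense small-λ fits may stop at `max_iter` with a small dual gap; those models never win EBIC selection, so the solver's convergence warning is suppressed rather than raised. |
| Walktrap `steps` | 4 | The algorithm's canonical random-walk length. |
| `n_boot` | 500 | Bootstrap replicates; stability proportions then have Monte-Carlo SE ≤ ~0.022. |
| `item_stability_threshold` | 0.70 | An item is "stable" when it lands in its own empirical dimension in ≥ 70% of replicates. |
| `consistency_threshold` | 0.75 | A dimension is "stable" when its exact item set recurs in ≥ 75% of replicates. |

## Numerical choices

* **Partial correlations** are computed as ρ_ij = −θ_ij/√(θ_ii θ_jj) from
  the precision matrix Θ; diagonal set to zero by convention. Inputs whose
  smallest eigenvalue is ≤ 1e−10 are rejected as singular.
* **Non-positive-definite inputs** (resampled or hand-entered matrices)
  are repaired by clipping eigenvalues at 1e−6 and rescaling to unit
  diagonal, with a warning; bootstrap replicates must not abort a run.
* **Edge counting for EBIC** uses |ρ| > 1e−8, so numerical zeros are not
  billed as parameters. The Gaussian log-likelihood drops the additive
  constant −(n/2)p·log 2π, which is identical across candidate models.
* **EBIC ties** break toward the larger penalty (sparser model): the path
  is traversed from λ_max downward and a candidate must *strictly* beat
  the incumbent.
* **Non-nested glasso paths.** The glasso active set is not strictly
  nested in λ: a precision coefficient can cross zero as λ decreases, so
  the exact-zero edge count can dip by an edge of negligible magnitude
  (observed weights ~1e−4) before reappearing. Material edges (above the
  solver resolution, 1e−3) are monotone; tests check monotonicity at that
  resolution on sampled data and at exact-zero resolution on population
  matrices.
* **Dendrogram cut.** Modularity is evaluated at every achievable
  community count and ties break toward fewer communities. Networks with
  no edges yield all-singleton solutions; isolated nodes become
  singletons. Dimensions are numbered by first occurrence in the input
  label order so reports are stable under re-runs.
* **Bootstrap streams.** Replicate b draws from a stream seeded
  `seed + b`; redraws after a failed replicate use streams past the
  replicate range; more than 10% failures abort. The re-estimation stage
  after item removal uses `seed + 100003` (a fixed prime stride), and
  group i in a multi-group run uses `seed + 13·100003·i mod 2^31`, so
  every reported number is a pure function of (inputs, config, seed).
* **Dimension-count summary.** SD uses the n−1 denominator; the normal CI
  is median ± z·SD with z the standard-normal quantile at
  (1+confidence)/2; the percentile CI uses inverted-CDF quantiles, so its
  endpoints are attained replicate values.

## Aligning replicate solutions

Replicate community labels are arbitrary, so item stability requires a
matching to the empirical solution. Per replicate:

1. replicate dimensions whose item set *equals* a reference dimension are
   pinned to it first — this guarantees the algebraic invariant that a
   dimension's structural consistency can never exceed any member's item
   stability;
2. the remaining replicate dimensions are matched one-to-one to remaining
   reference dimensions by maximizing total Jaccard overlap (optimal
   assignment); zero-overlap pairs stay unmatched;
3. unmatched replicate dimensions become *overflow* columns (largest
   first); overflow sets from different replicates share a column when
   they resemble the column's first-seen prototype at Jaccard ≥ 0.5,
   mirroring how analysts aggregate a recurring "extra" dimension.

Every item appears in exactly one replicate dimension per replicate, so
item-stability rows sum to one with overflow included. Structural
consistency is computed by exact set equality, independent of alignment.

## The synthetic-data generator

Real standardization-sample correlation matrices for instruments like
intelligence batteries are copyrighted, so the generator emulates them
with a correlated common-factor model: Σ = ΛΦΛᵀ + Θ with Θ diagonal and
θ_i = 1 − communality_i (indicators standardized — the analysis operates
on correlation matrices, so unit variances lose nothing). Scores are
multivariate normal, matching the parametric bootstrap's own assumption.
Ordinal discretization, missing data and non-normal marginals are
deliberately out of scope.

Presets use the 15 canonical subtest abbreviations (SI, VO, IN, CO, BD,
VP, MR, FW, AR, DS, PS, LN, CD, SS, CA):

* `three_dim` — verbal (4 items), perceptual (8), speed (3); pure
  loadings 0.70, factor correlations 0.40–0.55. Implied correlations span
  0.20–0.49: a clean, well-separated benchmark.
* `five_dim` — the publisher-style five factors (VC/VS/FR/WM/speed) with
  a strong positive manifold (cognitive factor correlations 0.55–0.65,
  speed 0.40–0.45), pure loadings 0.70.
* `five_dim_with_crossloaders` — the five-factor layout with the six
  subtests that behave multidimensionally in real batteries (FW, AR, DS,
  PS, LN, CA) given near-equal loadings (0.40–0.45) on two factors whose
  indicators end up in *different* network communities (reasoning↔verbal,
  working-memory↔verbal/speed, speed↔reasoning).

Calibration of the crossloader preset was the one genuinely open design
problem. Several geometries were explored (balanced two-cluster bridges,
marginally separable "splinter" subgroups, minor pair-factors, diffusely
weak loadings): configurations whose ambiguous items sit *inside* one
merged community are perfectly stable, and configurations giving the six
items strong mutual glue make them a stable block of their own. The
adopted design places each ambiguous item between two communities that
never merge, under a strong positive manifold that keeps all partial
correlations small — the regime in which placements genuinely churn
across bootstrap replicates.

One property of the parametric bootstrap bounds what any such preset can
deliver: replicates are drawn from the *sample* matrix, whose own
sampling error ("tilt", order 1/√n) is as large as the replicate-level
noise. A given sample therefore tends to sit clearly on one side of any
placement boundary, and the bootstrap faithfully reproduces that side.
Consequently each ambiguous item shows low own-dimension stability in
roughly half of independently generated samples, not in all of them —
and the subset of the six items flagged as unstable varies from sample to
sample. This mirrors the behavior of such batteries across real
standardization groups, where different age samples flag different
(overlapping) subsets of the same borderline subtests. Tests of the
planted-instability workflow therefore assert distributional properties
(crossloaders are less stable than pure indicators; flagged items are
removed; consistency improves after removal) rather than a fixed flagged
set per sample.

## What passing tests do and do not show

The generator's multivariate-normal world matches the bootstrap's
assumptions exactly; real score distributions are ordinal and skewed, and
real batteries have minor factors and correlated residuals the presets
omit. Passing recovery and stability tests therefore demonstrate the
correctness of the estimators and workflow mechanics, not that any real
instrument has a particular dimensionality. Runtime-sensitive checks use
reduced problem sizes (20–50 datasets per grid cell, 100–500 bootstrap
replicates) chosen to keep the full suite in the minutes range on one
CPU; the statistical margins at those sizes are wide (binomial SE ≤ 0.07
at 50 datasets).

## Known limitations

* Only Pearson correlations on complete data; no polychoric/Spearman
  input, no missing-data handling, no nonparanormal transform.
* No unidimensionality adjustment: batteries that are truly
  one-dimensional are estimated as a single community only when the
  network is dense enough for Walktrap to merge everything.
* Nonparametric (row-resampling) bootstrap is available only when raw
  scores are supplied; the default pipeline is parametric by design since
  its inputs are correlation matrices.
* The item-removal workflow flags items against the *initial* empirical
  solution (single pass by default); an `iterative` worst-first mode is
  provided for sensitivity analysis but has the usual stepwise-selection
  caveats.
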