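# egakit

Network-psychometric dimensionality analysis for test batteries:
**exploratory graph analysis** (EGA) and its **bootstrap stability
companion** (bootEGA), plus the item-removal workflow that keeps only
stably placed indicators.

## Who this is for

Psychometricians and methodologists who want to know *how many dimensions*
underlie a battery of positively correlated scores (subtests, items,
scales) — and, just as importantly, *how reproducible* that answer and the
placement of each score are under sampling variability. The package works
directly from a correlation matrix plus its sample size, so published
summary tables are sufficient input; raw score matrices are also accepted.

## The method

EGA treats dimensionality as community structure in a Gaussian graphical
model:

1. **Network estimation.** From the correlation matrix *S* of *p*
   variables, estimate a sparse precision matrix Θ by the graphical lasso
   over ~100 log-spaced penalties λ, from λ_max (the largest off-diagonal
   |r|, where the network is empty) down to 0.01·λ_max. Edges are
   regularized partial correlations ρ_ij = −θ_ij/√(θ_ii θ_jj).
2. **Model selection.** Pick the λ minimizing the extended Bayesian
   information criterion

   EBIC = −2·ℓ(Θ) + E·log n + 4·γ·E·log p,

   with ℓ(Θ) = (n/2)(log det Θ − tr(SΘ)), E the number of nonzero edges,
   and γ = 0.50 by default (γ = 0 recovers BIC; larger γ prefers sparser
   graphs).
3. **Community detection.** Run Walktrap (4-step random walks) on the
   absolute edge weights and cut the dendrogram at maximum modularity.
   Communities are the dimensions; their count is the estimate.
4. **bootEGA.** Draw replicate samples of size n from a multivariate
   normal with covariance *S* (parametric bootstrap), re-run EGA on each,
   and summarize: the dimension-count distribution (frequencies, median,
   SD, normal and percentile confidence intervals), the *typical network*
   (edge-wise median across replicates), per-dimension **structural
   consistency** (how often the exact item set recurs), and per-item
   **stability** (how often each item lands in each dimension after
   aligning replicate solutions to the empirical one).
5. **Refinement.** Items whose own-dimension stability falls below 0.70
   are removed and the analysis is re-estimated, yielding a reduced
   battery with homogeneous, replicable dimensions (structural consistency
   ≥ 0.75 is treated as stable).

## Worked example

```python
import egakit as ek

# a 15-subtest battery with three planted clusters, sampled at n = 1000
spec = ek.wisc_like_preset("three_dim")
data = ek.sample_scores(spec, n=1000, seed=42)

res = ek.BootEGA(data.correlation()).fit(n_boot=200, seed=42)
print(res.summary())
```

```
Bootstrap Exploratory Graph Analysis
====================================================
items: 15   n: 1000   replicates: 200
empirical dimensions: 3   typical (median network): 3
median count: 3.0  sd: 0.000  95% normal CI: (3.00, 3.00)  percentile CI: (3, 3)
dimension-count frequencies:
  3 dims: 100.0%
structural consistency:
  dim1 (CO, IN, SI, VO): 100.0%
  dim2 (AR, BD, DS, FW, LN, MR, PS, VP): 100.0%
  dim3 (CA, CD, SS): 100.0%
unstable items (< 0.70): none
```

Reading the output: every one of the 200 bootstrap replicates reproduced
the three planted clusters exactly (frequencies and structural consistency
at 100%), and every subtest stayed in its own dimension in every replicate
— a fully stable solution, as expected for well-separated clusters at this
sample size. On ambiguous batteries (see the
`five_dim_with_crossloaders` preset) the same report shows sub-0.70 item
stabilities; `egakit.analyze_group` then removes those items and
re-estimates:

```python
corr = ek.sample_scores(ek.wisc_like_preset("five_dim_with_crossloaders"),
                        500, seed=1).correlation()
result = ek.analyze_group(corr, ek.PipelineConfig(n_boot=200, seed=1))
print(result.removed)                 # e.g. ('LN', 'DS', 'FW', 'AR')
print(result.final.summary())
```

A command-line interface mirrors this:

```bash
egakit simulate --preset three_dim --n 500 --seed 1 --out scores.csv --corr-out corr.csv
egakit run --corr corr.csv --n 500 --boots 500 --seed 1 --out report/
```

`report/` then contains `report.md` (one row per group: EGA clusters,
bootEGA typical clusters, final clusters after removal), `report.json`
(full numeric payload) and per-group CSV tables.

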