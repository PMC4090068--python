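# bearcensus

Dual-platform abundance estimation for polar bears (or any sparse, bright,
countable megafauna) on a closed island during the ice-free season:

* **Satellite census** — two observers independently review one
  high-resolution image of the whole island; their point sets are matched
  into two-occasion capture histories and abundance is estimated with the
  full-likelihood closed-population model with observer-specific detection
  (the classic M_t model).
* **Helicopter line-transect survey** — perpendicular sighting distances
  from systematic transects are fitted with conventional and
  multiple-covariate distance-sampling detection functions, ranked by AICc,
  and combined into a model-averaged Horvitz–Thompson abundance estimate
  with unconditional variance. A Huggins double-observer analysis checks
  the g(0)=1 assumption first.

Because the imagery behind such surveys is commercial and sighting data are
rarely released, the package ships a seeded synthetic scene generator (a
~1,100 km² island, ~94 independent bears, persistent rock and ephemeral
foam/cloud confusers, transects at 7-km spacing) plus a deterministic
imagery change-detection stage (top-of-atmosphere reflectance, percentile
stretch, cross-date bright-spot filtering), so every stage runs and is
tested end-to-end without external data.

## The models

**Closed-population census.** With n₁, n₂ bears recorded by the two
observers and m by both, M = n₁ + n₂ − m distinct bears were seen, and

    L(N, p₁, p₂) ∝ N!/(N−M)! · Π_t p_t^{n_t} (1−p_t)^{N−n_t}.

Profiling p_t = n_t/N leaves a one-dimensional likelihood maximised over
integer N ≥ M; the continuous optimum is the Lincoln–Petersen estimate
n₁n₂/m. Confidence intervals follow the closed-captures convention: a
lognormal interval on f₀ = N̂ − M, so the lower bound never falls below the
number of bears actually seen.

**Line-transect survey.** Distances x on [0, w] have density
f(x) = g(x)/μ with detection function g (half-normal, hazard-rate, or
uniform key with cosine adjustments; covariates act log-linearly on the
scale) and effective strip width μ = ∫₀ʷ g. Group density is
D = n/(2μL); abundance N = D·A·s̄ for stratum area A and mean group size
s̄, with CV²(N) = CV²(n/L) + CV²(μ) + CV²(s̄). Competing models are
weighted by exp(−ΔAICc/2) (ΔAICc < 3) and averaged with unconditional
variance Σ wᵢ√(varᵢ + (Nᵢ − N̄)²).

## Worked example

```python
from bearcensus import CaptureSummary, fit_closed_mt, observer_detection_report, model_average

# satellite census: observer A marked 90 points, B marked 40, 38 shared
counts = CaptureSummary(n1=90, n2=40, m=38)
fit = fit_closed_mt(counts)
det = observer_detection_report(counts, fit)
print(f"abundance N-hat     : {fit.n_hat}  (continuous {fit.n_hat_continuous:.2f})")
print(f"95% CI              : {fit.ci_low:.1f} - {fit.ci_high:.1f}")
print(f"observer detection  : A {det['conditional']['p1_pct']}%, B {det['conditional']['p2_pct']}%")

# aerial survey: average a fitted model set by Akaike weight
table = [(0.00, 97, 17.8), (0.15, 104, 21.0), (1.12, 105, 21.3),
         (1.38, 108, 22.1), (2.62, 100, 22.5)]   # (delta-AICc, N, SE)
d, n, s = zip(*table)
ma = model_average(list(n), aicc_values=list(d), ses=list(s))
print(f"model-averaged N    : {ma.n_bar:.1f}  95% CI {ma.ci_low:.0f} - {ma.ci_high:.0f}")
```

prints

```
abundance N-hat     : 94  (continuous 94.74)
95% CI              : 92.6 - 105.3
observer detection  : A 95%, B 42%
model-averaged N    : 102.3  95% CI 69 - 152
```

The census counts 92 distinct bears and estimates 2.7 more were missed by
both observers; the interval is asymmetric because the uncertainty lives
entirely in the never-seen fraction. The transect survey reaches a
compatible point estimate (102) but a far wider interval: it adds
encounter-rate and detection-function variance that a full-coverage census
does not have.

A full synthetic run of both platforms on one simulated island:

```sh
bearcensus compare --seed 7 --out-dir out/
# satellite N = 94 (CV 2.3%); aerial N = 91 (CV 24.6%); CI overlap: True; CV ratio 10.5
```

`bearcensus simulate | detect | mr-fit | ds-fit | all` expose the
individual stages; every run is reproducible from its `--seed` and config.

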