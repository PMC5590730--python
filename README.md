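# metapower

Power analysis for fixed-effect and random-effects meta-analysis.

Meta-analyses are widely assumed to have more power to detect effects than
the studies they combine. Under the fixed-effect (common-effect) model this
is guaranteed, but under the random-effects model it is not: between-study
heterogeneity inflates the standard error of the pooled estimate, and the
between-study variance τ² must itself be estimated, which perturbs the test
in small samples. `metapower` provides the tools to quantify this for
systematic reviewers, biostatisticians and methods researchers: study-level
powers, three methods for the power of a DerSimonian–Laird random-effects
meta-analysis, planning-stage power surfaces, and a retrospective pipeline
that compares each meta-analysis's power with the power of its own studies.

## The model

Study `i` reports an estimate `Yᵢ ~ N(μᵢ, σᵢ²)` with the within-study
standard error `σᵢ` treated as fixed and known. The random-effects model
takes `μᵢ ~ N(μ, τ²)`; τ² = 0 recovers the fixed-effect model. All tests
are two-sided Z tests at critical value `Z_a` (1.96 by default), testing
`μ = μ₀` for the meta-analysis and `μᵢ = μ₀` per study, with δ = μ − μ₀.

Powers provided:

* **Study level** — `βᵢ = 1 + Φ(−Z_a + δ/σᵢ) − Φ(Z_a + δ/σᵢ)` (with a
  directional variant `Φ(−Z_a + δ/σᵢ)` that excludes wrong-sign
  rejections), and the random-effects average over `δᵢ ~ N(δ, τ²)`.
* **Fixed-effect** — the same form with `σᵢ` replaced by `√V_F`,
  `V_F = 1/Σσᵢ⁻²`; strictly dominates every study power for δ ≠ 0, k ≥ 2.
* **Random-effects, conventional analytic** — replaces `V_F` by
  `V_R = 1/Σ(σᵢ² + τ²)⁻¹` with τ² treated as known.
* **Random-effects, Monte Carlo** — simulates meta-analyses
  `Xᵢ ~ N(δ, σᵢ² + τ²)`, re-estimates τ² by DerSimonian–Laird inside each,
  and counts rejections `|T| ≥ Z_a`. This propagates the uncertainty in
  τ̂²; the resulting power can fall below α (the DL test is conservative
  near τ² = 0) or far exceed the analytic value (anticonservative for
  small k with severe heterogeneity).
* **Random-effects, equal-size analytical** — when all studies are the
  same size, the exact CDF of T is a mixture of a truncation point mass
  and a χ² integral, parameterised only by k, `I² = τ²/(σ² + τ²)` and the
  noncentrality `Δ = δ√k/σ`. Unequal-σ meta-analyses are mapped onto it
  through a typical within-study variance (Higgins–Thompson or reciprocal
  mean precision). Ideal for planning-stage power surfaces over (Δ, I²).

## Worked example

A four-study meta-analysis on the log risk ratio scale, retrospective
("observed") power with δ = |pooled estimate| and τ² = τ̂²:

```python
from metapower import (MetaAnalysisData, EffectScenario, MCConfig, fit_re,
                       power_re_analytic, power_re_mc, study_powers_random,
                       map_to_equal_size, power_re_equal)

data = MetaAnalysisData.from_arrays(
    y=[-0.61, -0.11, -0.42, 0.09], se=[0.28, 0.22, 0.35, 0.30])
fit = fit_re(data)
print(f"Q = {fit.q:.4f}  tau2_hat = {fit.tau2_hat:.4f}  "
      f"mu_hat = {fit.mu_hat:.4f}  T = {fit.t_stat:.4f}")

sc = EffectScenario(delta=abs(fit.mu_hat), tau2=fit.tau2_hat)
pm = power_re_mc(data.se, sc, mc=MCConfig(10000, seed=1))
sp = study_powers_random(data, sc)
print(f"analytic power = {power_re_analytic(data, sc).power:.4f}")
print(f"Monte Carlo power = {pm.power:.4f} (mc_se {pm.mc_se:.4f})")
print(f"study powers: mean {sp.mean:.4f}  median {sp.median:.4f}  max {sp.max:.4f}")

es = map_to_equal_size(data, sc.delta, sc.tau2)
print(f"equal-size mapping: I2 = {es.i2:.4f}, Delta = {es.delta_nc:.4f}")
print(f"equal-size mixture power = {power_re_equal(es).power:.4f}")
```

prints

```
Q = 3.5693  tau2_hat = 0.0150  mu_hat = -0.2418  T = -1.5904
analytic power = 0.3560
Monte Carlo power = 0.3301 (mc_se 0.0047)
study powers: mean 0.1654  median 0.1552  max 0.2298
equal-size mapping: I2 = 0.1595, Delta = 1.7187
equal-size mixture power = 0.3216
```

The meta-analysis (MC power 0.33) clearly beats its average study (0.17)
and its best study (0.23) here, but the conventional analytic value (0.36)
overstates the power because it ignores the estimation of τ² at k = 4. The
equal-size approximation (0.32) tracks the Monte Carlo answer closely.

The same computations are available from the shell:

```bash
metapower power re --csv studies.csv --method mc --delta from-fit --tau2 from-fit
metapower grid --k 5 --i2-grid 0:0.95:20 --delta-grid 0:6:25 --out grid.csv --plot grid.png
metapower simulate --n-meta 500 --seed 1 --out sim/
metapower compare --csv sim/corpus.csv --iterations 2000 --seed 1 --out cmp/
```

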