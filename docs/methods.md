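# Methods

This note documents the statistical model, the numerical choices and the
synthetic-data design behind `metapower`, and what the tests do and do not
establish.

## Model and assumptions

Study `i` contributes an estimate `Yᵢ` and a within-study standard error
`σᵢ`. Throughout, `Yᵢ ~ N(μᵢ, σᵢ²)` with `σᵢ` treated as fixed and known —
the conventional normal approximation for meta-analysis; the fact that
`σᵢ` is itself estimated upstream is suppressed. The random-effects model
takes `μᵢ ~ N(μ, τ²)`; the fixed-effect model is the τ² = 0 special case.
The only estimator of τ² implemented is the DerSimonian–Laird (DL) moment
estimator `τ̂² = max(0, (Q − (k−1))/(S₁ − S₂/S₁))`, kept behind a single
code path so alternative estimators remain an explicit extension point.
All hypothesis tests are two-sided Z tests (`|T| ≥ Z_a` against a standard
normal), including for the random-effects pooled estimate — no
Hartung–Knapp modification and no t quantiles. Two-sided powers include
"type III" (wrong-sign) rejections; the directional power
`Φ(−Z_a + δ/σ)` is the opt-out.

For binary outcomes the effect scale is the log risk ratio with the
standard large-sample SE `√(1/a − 1/n₁ + 1/c − 1/n₂)`. When a 2×2 table
contains a zero cell, 0.5 (configurable) is added to both event counts and
both denominators before computing the estimate and SE; double-zero
studies are dropped with a warning since their log risk ratio is
undefined. This is standard practice, not a claim about how any particular
database was preprocessed. All power machinery consumes only `(yᵢ, σᵢ)`,
so any effect scale with an (approximately) normal estimate works.

## The three random-effects power methods

1. **Conventional analytic.** Plug a known τ² into
   `V_R = 1/Σ(σᵢ² + τ²)⁻¹` and use the normal power formula. Cheap,
   bounded below by α, but blind to the estimation of τ².
2. **Monte Carlo.** Simulate `Xᵢ ~ N(δ, σᵢ² + τ²)`, re-fit DL within each
   simulated meta-analysis (τ² estimation is location invariant, so the
   null value never needs subtracting), reject when `|T| ≥ Z_a`. This is
   the reference method: it sees both the σᵢ distribution and the
   sampling distribution of τ̂².
3. **Equal-size analytical.** With `σᵢ = σ` for all i, write
   `I² = τ²/(σ² + τ²)` and `Δ = δ√k/σ`. Then `T = Z / max(√(1−I²), x)`
   where `Z ~ N(Δ√(1−I²), 1)` and `x = √(C/(k−1))`, `C ~ χ²_{k−1}`,
   independent. τ̂² truncates to zero exactly when `C ≤ (1−I²)(k−1)`, so

       P(T ≤ t) = Pr(χ²_{k−1} ≤ (1−I²)(k−1)) · Φ((t − Δ)√(1−I²))
                + ∫ Φ(t·√(C/(k−1)) − Δ√(1−I²)) f_{χ²_{k−1}}(C) dC,

   the integral running over `C > (1−I²)(k−1)`. The leading coefficient is
   the *regularised* lower incomplete gamma — the mixture weights must sum
   to one, which fixes the normalisation — and the whole CDF is validated
   against the Monte Carlo method (Kolmogorov distance < 0.005 at 2×10⁵
   replicates over a factorial in k, I², Δ). Power is
   `1 − [P(T ≤ Z_a) − P(T ≤ −Z_a)]` and depends on Δ only through |Δ|.
   DL, REML and Paule–Mandel estimates of τ² coincide in the equal-size
   case, so the result applies to all three.

Ignoring the uncertainty in τ̂² gives the closed form
`β(Δ, I²) = 1 + Φ(−Z_a + Δ√(1−I²)) − Φ(Z_a + Δ√(1−I²))`, which is both
the large-k limit of the mixture CDF power and an exact reparameterisation
of method 1 on k equal studies (`V_R = (σ² + τ²)/k`). The k = 1,
known-τ² comparison formulas show the study-level test is equivalent to
the meta-analysis test with the *smaller* critical value `Z_a√(1−I²)`:
with any heterogeneity, a single study has more power to detect its own
effect than a meta-analysis of it has to detect the average effect.

Real meta-analyses with unequal σᵢ are mapped onto the equal-size
machinery through a typical within-study variance: the Higgins–Thompson
form `(k−1)S₁/(S₁² − S₂)` (default) or the reciprocal mean precision
`k/S₁`. The latter is implemented as a typical *variance* — a
harmonic-type mean of the σᵢ² — since with weights `wᵢ = σᵢ⁻²` that is
its unit; both reduce to the common σ² for equal studies. The mapping is
an approximation whose error grows with the dispersion of the σᵢ².

## Numerical choices

* **Quadrature.** The mixture integral is evaluated in C-space (a bounded
  smooth Φ factor against the χ²_{k−1} density) by panelled Gauss–Legendre
  quadrature: panels break at the χ² quantiles {5, 25, 50, 75, 90, 99,
  99.9}% above the truncation point, 64 nodes per panel, tail cut where
  the survival function drops below 10⁻¹³. Agreement with adaptive
  `scipy.integrate.quad` is asserted to 10⁻⁷ in the tests; evaluation is
  vectorised over t so a whole CDF grid costs one pass.
* **Monte Carlo RNG.** A counter-based Philox generator keyed on the user
  seed, drawing in fixed-size blocks of 2¹⁴ iterations, makes every power
  bit-for-bit reproducible and independent of internal vectorisation.
  The binomial standard error `√(p(1−p)/n)` is attached to every MC power
  (reported for n ≥ 100).
* **Degenerate inputs.** k = 1: Q and τ̂² are undefined; the fit applies
  τ̂² := 0 with a warning and degrades to fixed-effect (the known-τ²
  k = 1 formulas are separate, clearly named functions). I² = 1 is
  rejected by the mixture CDF (degenerate lower limit) but handled by the
  closed form (power α). Weights always satisfy `S₁² > S₂` for k ≥ 2, so
  the DL denominator is safe.
* **Retrospective convention.** "Observed power" sets δ = |μ̂_RE| and
  τ² = τ̂² per meta-analysis; the sign is irrelevant because two-sided
  power is symmetric in δ.

## The synthetic corpus

No real review database ships with the package; `generate_corpus` emulates
one for testing and for the retrospective comparison. Per meta-analysis:
k is drawn from six strata with probabilities ≈ (0.306, 0.162, 0.119,
0.085, 0.178, 0.151) for k = 2, 3, 4, 5, 6–9, ≥10 — the mix of study
counts typical of large collections of binary-outcome reviews, dominated
by very small k — with k uniform within 6–9 and 10 + (Geometric(0.25) − 1)
above. The average log risk ratio is `μ ~ N(0, 0.4²)`; τ² is a 50/50
mixture of exact homogeneity and LogNormal(log 0.06, 1) heterogeneity
(median I² moderate, with a realistic share of τ̂² truncations); control
risks are Uniform(0.05, 0.5); each study uses one common arm size,
log-uniform on (20, 500); event counts are binomial with the treatment
risk `p_c·exp(δᵢ)` clamped to (0, 1). Every latent draw is recorded in a
truth log, and generation is bit-reproducible from the seed.

What the generator does *not* emulate: publication bias and small-study
effects (estimates are independent of their precisions by construction,
matching the assumption of the power formulas), correlated outcomes within
reviews, non-normal random effects, and rare-event meta-analyses beyond
what the clamped binomial model produces. Tests passing on this corpus
therefore validate the power machinery under its own assumptions; they do
not certify behaviour on data where those assumptions fail.

Default problem sizes — 2×10⁵ Monte Carlo replicates for CDF validation,
500 meta-analyses at 2 000 iterations for the corpus comparison — were
chosen to keep every Monte Carlo standard error well below the effects
being measured while the full suite runs in minutes.

## Known limitations and open edges

* Strict monotonicity of the beats-mean proportion across all six
  k-strata is a noisy statistic on a 500-meta-analysis corpus (stratum
  sizes 35–150): the gradient and its endpoints are robust, but adjacent
  middle strata can invert by sampling error of a few percentage points.
  The robust directional claim — the k ≥ 10 stratum beats the k = 2
  stratum — is what the unit suite asserts.
* The conventional DL test does not hold its nominal level at small k
  (conservative at τ² ≈ 0, anticonservative under severe heterogeneity),
  so part of any "power" attributed to it at small k is a level artifact;
  the package measures this rather than correcting it.
* Odds ratios, risk differences and continuous outcomes are out of scope
  (the machinery is effect-scale agnostic; only the 2×2 front-end is
  log-RR specific). REML/Paule–Mandel fitting, Hartung–Knapp corrections
  and binomial within-study likelihoods are deliberately not implemented.
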