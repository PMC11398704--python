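# Methods

## The distribution

The modified Kies Topp-Leone (MKTL) family has CDF

    F(x; η, β) = 1 − exp(−t(x)^(−β)),   t(x) = (1 − (1−x)²)^(−η) − 1,

on 0 < x < 1 with shapes η, β > 0.  Writing G(x) = x(2−x) = 1−(1−x)²
(the Topp-Leone kernel), t = (1−G^η)/G^η is the odds of the Topp-Leone
survival, so F is the modified Kies transform of a Topp-Leone baseline.
The density follows by differentiation and simplifies, using
1 − G^η = G^η·t, to

    log f = log(2βη) + log(1−x) − (1+η)·log G − (β+1)·log t − t^(−β).

All distribution functions are mutually consistent by construction:
`cdf(quantile(u)) = u` holds to 1e-10 across the tested parameter grid.
One practical warning: the quantile function uses natural logarithms
throughout, as the CDF's exponential form requires.  Quantile tables
produced elsewhere with base-10 logarithms in `log(1/(1−u))` are *not*
quantiles of this CDF (they correspond to a distribution with an extra
factor ln 10 in the exponent) and will not round-trip; this package keeps
the self-consistent convention everywhere.

### Numerical evaluation

* log G = log x + log1p(1−x) is exact at both endpoints; t is evaluated as
  expm1(−η log G) and its logarithm as a + log1p(−e^(−a)) with
  a = −η log G, so neither tail overflows.
* The quantile uses the cancellation-free form
  1 − sqrt(1−G) = G/(1+sqrt(1−G)) and log1p/logaddexp throughout, keeping
  quantiles accurate to full precision near both endpoints.
* Near x = 0 the density behaves like x^(ηβ−1) and diverges when ηβ < 1
  (the singularity is integrable).  Integrals of g(x)·f(x) split at 0.5;
  when ηβ < 1 the left piece is computed after the substitution
  s = x^(ηβ), which makes the transformed integrand bounded.  Adaptive
  quadrature (QUADPACK) with absolute tolerance 1e-10 then reproduces the
  reference moment grid to the printed precision; raw moments are *not*
  computed from series expansions.
* Moment-based shape coefficients use the standard central-moment
  formulas: CS = (μ₃′ − 3μ₁′μ₂′ + 2μ₁′³)/σ³,
  CK = (μ₄′ − 4μ₁′μ₃′ + 6μ₁′²μ₂′ − 3μ₁′⁴)/σ⁴, CV = σ/μ₁′.
* Quantile-based shape measures are the Bowley quartile skewness and the
  Moors octile kurtosis.
* Reliability quantities (hazard, reversed hazard, cumulative hazard, odds
  ratio, failure-rate average, Mills ratio) are defined through the
  identities h = f/R, τ = f/F, H = −log R, OR = F/R, FRA = H/x, MR = 1/h.
  The cumulative hazard is H(x) = t(x)^(−β), non-negative by definition.
  In double precision R(x) underflows to zero deep in the right tail
  (H ≳ 745); ratio identities are exact only where R is representable.

## Estimation

Twelve estimators are defined as objectives over the ordered sample
x₍₁₎ ≤ … ≤ x₍ₙ₎ with Fᵢ = F(x₍ᵢ₎):

| method | objective (minimized unless noted) |
|---|---|
| MLE | −Σ log f(x₍ᵢ₎) |
| ADE | −n − (1/n)Σ(2i−1)[log Fᵢ + log(1−F₍ₙ₊₁₋ᵢ₎)] |
| CME | 1/(12n) + Σ(Fᵢ − (2i−1)/(2n))² |
| MPS | (1/(n+1))Σ log Λᵢ, **maximized** |
| LSE | Σ(Fᵢ − i/(n+1))² |
| RADE | n/2 − 2ΣFᵢ − (1/n)Σ(2i−1) log(1−F₍ₙ₊₁₋ᵢ₎) |
| WLSE | Σ (n+1)²(n+2)/(i(n−i+1)) (Fᵢ − i/(n+1))² |
| LADE | −3n/2 + 2ΣFᵢ − (1/n)Σ(2i−1) log Fᵢ |
| MSALD | Σ \|log Λᵢ − log 1/(n+1)\| |
| ADLTS | 2Σ log Fᵢ + (1/n)Σ(2i−1)/Fᵢ |
| PE | Σ(x₍ᵢ₎ − Q(i/(n+1)))² |
| MSSL | Σ(log Λᵢ − log 1/(n+1))² |

with spacings Λᵢ = Fᵢ − Fᵢ₋₁, F₀ = 0, Fₙ₊₁ = 1.  Design choices that are
genuinely open and how they were resolved:

* **MPS direction.** The mean log-spacing is bounded above by
  log 1/(n+1) (Jensen); minimizing it is degenerate, so MPS is a
  maximization.
* **RADE index pairing.** A variant of this statistic that pairs
  (2i−1) with log(1−Fᵢ) at the *direct* index appears in some write-ups;
  its population minimizer satisfies F(Q₀(u)) = 1−u — the anti-fit — and
  cannot recover parameters (empirically it drives β → 0).  The classical
  reversed-index pairing is therefore the default; the direct-index form
  remains available via `printed_form=True` for comparison.
* **ADLTS second term.** The per-term minimum of
  2 log F + ((2i−1)/n)/F sits at F = (2i−1)/(2n), the standard plotting
  position, which is what makes this a proper minimum-distance objective
  (and what its derivative, with F² in the denominator, implies).
* **Ties.** Tied observations produce zero spacings; logs are floored at
  1e-300 so the spacing-based objectives (MPS/MSALD/MSSL) remain finite.
  With many ties these estimators are intrinsically poorly behaved — a
  property of the objectives, not of the implementation.
* **Optimizer.** All objectives are minimized over (log η, log β)
  (positivity by construction) with Nelder-Mead from a fixed 5×5 start
  grid η, β ∈ {0.25, 0.5, 1, 2, 4}; the best objective value wins, ties
  broken by grid order.  No randomness, so fits are deterministic and
  order-invariant.  Invalid proposals evaluate to a large finite sentinel.
* **Inference.** Standard errors are reported for the MLE only, from the
  inverse of the observed information matrix obtained by central finite
  differences (`statsmodels.tools.numdiff.approx_hess3`) at the optimum.
  The analytic score is implemented separately and used as a stationarity
  check in the tests, not by the optimizer.

## Goodness of fit

Information criteria on k parameters and n observations:
AIC = −2ℓ + 2k, BIC = −2ℓ + k log n, CAIC = AIC + 2k(k+1)/(n−k−1),
HQIC = −2ℓ + 2k log log n.  Distance statistics are computed on the
probability-integral transform of the ordered sample: the one-sample
Kolmogorov-Smirnov D, the Cramér-von Mises W (p-value from the asymptotic
null via `scipy.stats.cramervonmises` on the PIT values) and the
Anderson-Darling A (p-value from the Marsaglia & Marsaglia series for the
fully specified case, implemented here because no installed library
exposes it).  The KS p-value is the Kolmogorov series
2Σ(−1)^(k−1)exp(−2k²nD²).

All three p-values treat the fitted parameters as known ("case 0").  With
estimated parameters this is anti-conservative — a parametric bootstrap
would give smaller p-values — but it is the convention under which the
reference values this package is validated against were produced, and the
report documents it.  A null-calibration test confirms the case-0
approximations reject a true (known-parameter) null at 3–8% for a nominal
5% at n = 100.

## Monte Carlo estimator comparison

For each scenario (true (η, β)) and sample size n, `reps` samples are
drawn by inverse transform from per-replicate `SeedSequence` streams
spawned from one master seed; every method is fitted to the same samples
(common random numbers), so method comparisons are paired.  Fits
warm-start at the true parameters — the standard protocol for recovery
studies of this design, whose published instances state the truth as the
initial value — with the multi-start grid retained for data analysis.
Failed fits are excluded and counted; an exclusion rate above 1% flags
the cell.  Rank aggregation: within each (scenario, n), methods are
ranked by η-MSE and β-MSE separately (1 = smallest, average ranks on
ties — several of the distance objectives can produce numerically
identical results on the same samples) and the two ranks summed; totals
over all cells give the overall ranking.

Default study conditions are the reference design: n ∈ {30, 150, 300,
500, 800}, 1000 replicates.  The validation suite runs the MLE column of
the (0.4, 0.4) scenario at n ∈ {300, 800} with the full 1000 replicates;
the remaining scenarios are exercised at reduced size by the unit tests,
a problem-size choice of this package's test design.

## Quantile regression

Solving Q(q; η, β) = τ for η gives the re-parameterized shape
r(q, τ, β) = −log(1 + L^(−1/β))/log(1−(1−τ)²) with L = log(1/(1−q)),
evaluated with logaddexp so small β (where L^(−1/β) explodes) stays
finite.  The conditional density of yᵢ is the MKTL density with
η = r(q, τᵢ, β) and τᵢ = logistic(xᵢ'α).  The log-likelihood
Σ log f(yᵢ; β, τᵢ) is maximized over (α, log β) by Nelder-Mead; the
default start profiles an intercept-only model through the unconditional
two-parameter MLE (with an intercept-only design the fit reproduces that
MLE exactly, a tested equivalence).  Wald standard errors come from the
observed information on the natural scale (α, β) — β's confidence
interval is built on the natural scale, matching how the reference
interval widths behave — and p-values are 2Φ(−|est/se|).

Cox-Snell residuals rᵢ = −log(1 − F(yᵢ; r(q, τ̂ᵢ, β̂), β̂)) are standard
exponential under a correct model; the tests verify this distributionally
(KS against Exp(1)) and the plug-in identity rᵢ = −log(1−q) for an
observation at its fitted conditional quantile.

The recovery simulation generates x₁ ~ Uniform(0,1) and
x₂ ~ Bernoulli(0.5) once per (scenario, n) and holds them fixed across
replicates; responses come from the inversion formula
yᵢ = Q(uᵢ; r(q, τᵢ, β), β).  Reported metrics per parameter and n:
average estimate (AE), mean absolute bias (AB), RMSE, 95% Wald coverage
(CP), average confidence limits (LCL/UCL) and average CI width
(AWCI = UCL − LCL by construction).  Simulation fits start at the truth.

## What the synthetic data does and does not emulate

All simulated samples are exact inverse-transform draws from the model,
i.e. the correctly specified case with continuous, tie-free data.  Real
unit-interval data — including the bundled burr measurements, which are
rounded to two decimals and heavily tied — contain ties (which degrade
the spacing-based estimators), measurement rounding, and possible model
misspecification; passing recovery tests therefore demonstrate correctness
of the estimators under the model, not robustness to these features.  The
covariate scheme in the regression simulation (one uniform, one balanced
binary regressor, fixed across replicates) matches the reference design
and does not probe collinear or heavy-tailed designs.

## Known limitations

* Case-0 p-values for W and A after estimating parameters are
  anti-conservative (documented above; Lilliefors-type corrections are out
  of scope).
* The MPS/MSALD/MSSL estimators are unreliable on heavily tied data; they
  are reported but should not be preferred there.
* Deep right-tail reliability ratios are limited by the underflow of the
  survival function in double precision.
* Wald intervals for β can be poor when β is very small relative to its
  SE; no profile-likelihood intervals are provided.
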