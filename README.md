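# mktl

Statistical toolkit for the **modified Kies Topp-Leone (MKTL) distribution**,
a two-parameter family on the open unit interval for modeling proportions,
rates and other bounded measurements (burr sizes relative to sheet thickness,
soil-moisture fractions, attainment indices, ...). The package provides the
full distribution layer, twelve parameter-estimation methods, goodness-of-fit
and model-comparison machinery, a Monte Carlo harness for benchmarking the
estimators, and a parametric quantile-regression model with a logit link.

## The model

The Topp-Leone CDF `G(x; η) = (1-(1-x)²)^η` is inserted into the modified
Kies transform `F = 1 - exp(-[G/(1-G)]^β)`, giving

    F(x; η, β) = 1 - exp( -[ (1-(1-x)²)^(-η) - 1 ]^(-β) ),   0 < x < 1,

with shapes η, β > 0. The density can be declining, unimodal, left- or
right-skewed; the hazard rate can be increasing, J-shaped or bathtub.  The
quantile function is closed-form,

    Q(u) = 1 - sqrt( 1 - (1 + [log(1/(1-u))]^(-1/β))^(-1/η) ),

which makes inverse-transform sampling, quantile-based shape measures
(Bowley skewness, Moors kurtosis) and quantile regression cheap and exact.

For regression, the density is re-parameterized so a chosen quantile level
`q` becomes the location parameter: η is replaced by
`r(q) = -log(1 + [log(1/(1-q))]^(-1/β)) / log(1-(1-τ)²)`, and the
conditional quantile τᵢ is linked to covariates by
`τᵢ = exp(xᵢ'α)/(1+exp(xᵢ'α))`.  Fitting is by maximum likelihood with Wald
inference; Cox-Snell residuals `-log(1-F(yᵢ))` diagnose the fit.

Estimation methods: maximum likelihood (MLE), Anderson-Darling (ADE) and its
right-tail (RADE), left-tail (LADE) and left-tail-second-order (ADLTS)
variants, Cramér-von Mises (CME), maximum product of spacings (MPS),
ordinary/weighted least squares on the CDF (LSE/WLSE), minimum spacing
absolute-log and square-log distance (MSALD/MSSL), and percentile
estimation (PE).

## Worked example

Fit the bundled burr-measurement data (50 values in (0,1)) and inspect the
goodness of fit:

```sh
$ mktl fit --data burr50 --method MLE
{
 "MLE": {
  "eta": 0.6552296880032911,
  "beta": 1.9321445677506546,
  "se": [0.03564707625080183, 0.20737862266155885],
  "loglik": 57.312537865521534,
  "neg2loglik": -114.62507573104307,
  ...
 }
}
$ mktl gof --data burr50
{
 ...
 "gof": {
  "neg2loglik": -114.62507573104307,
  "aic": -110.62507573104307,
  "bic": -106.80102972018678,
  "caic": -110.3697565821069,
  "hqic": -109.16885719948928,
  "ks_stat": 0.09060522261724052,  "ks_p": 0.8062998896162011,
  "w_stat": 0.07334687224673038,   "w_p": 0.7334106921849131,
  "a_stat": 0.44581797435728987,   "a_p": 0.8023851339632333,
  ...
 }
}
```

Reading: the fitted shapes are η̂ = 0.655 (SE 0.036) and β̂ = 1.932
(SE 0.207).  The Kolmogorov-Smirnov distance between the empirical CDF and
the fitted model is 0.091 with asymptotic p ≈ 0.81, and the Cramér-von Mises
and Anderson-Darling statistics tell the same story — the MKTL fit is not
rejected at any conventional level.  The information criteria
(AIC = -110.6, BIC = -106.8, ...) are what you would compare against
competing unit-interval models fitted to the same data.

The same functionality is available as a library:

```python
import mktl
from mktl import MKTLParams

r = mktl.fit(mktl.load_fixture("burr50").values, "MLE")
print(r.params)            # MKTLParams(eta=0.6552..., beta=1.9321...)
print(mktl.quantile(0.5, r.params))   # fitted median
```

Estimator benchmarking and the quantile-regression recovery simulation run
from the CLI as `mktl simulate ...` and `mktl qsim ...`; both honor
`--seed` and write tidy CSV tables.

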