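# paleosel

Extinction-selectivity analysis for stratigraphic abundance data.

When a mass-extinction interval is sampled by several deep cores, each
species leaves a short, gappy count series (fossil elements per
sample) and each core carries a gamma-ray log that proxies water depth
(clay/organic-rich, deeper-water facies emit more). `paleosel` asks:
*which properties of a species predicted whether it survived?* It is
aimed at paleobiologists and quantitative ecologists working with
presence/abundance series through turnover events.

The package computes ten species-level predictors from the raw series
and then models survival selectivity:

* abundance structure — mean positive abundance ā; the averaged local
  variation coefficient CV̄ (mean of sd/mean over adjacent positive
  pairs); the rescaled-range Hurst exponent H = ln(RS)/ln(T); the
  spectral exponent ν (minus the log-log slope of the Lomb periodogram
  with a +1 offset on frequency and power); abundance skewness G(a)
  (adjusted G1, zeros excluded);
* occupancy turnover — apparent extirpation E(t) and colonization I(t)
  rates from gap analysis of the trimmed range (for the pattern
  `XX000X0XX`: t = 8, z = 4 zeros, two extirpations and two
  colonizations, both rates 2/4);
* habitat affinity — mean γ̄, standard deviation σ(γ) and skewness
  G(γ) of gamma-ray values at positive occurrences.

Selectivity is then quantified three ways: a bivariate logistic screen
(slope Wald p < 0.1), an exhaustive set of multivariate logistic
models ranked by AICc with Akaike weights ω and Tjur's discrimination
coefficient D, and an ANOVA-impurity regression tree with
rpart-style controls (minsplit 20, minbucket 7, cp 0.01). A synthetic
multi-core generator with steerable noise color, habitat preference
and survival effects makes every stage testable without any data
download. See `docs/methods.md` for the full definitions.

## Worked example

```python
from paleosel import SurvivalSelectivityModel
from paleosel.synth import SynthConfig, synth_assembly

data = synth_assembly(SynthConfig(seed=3))        # 5 cores, 34 species
model = SurvivalSelectivityModel(data.predictors)  # table incl. survival 0/1
results = model.fit()
print(results.summary())
```

```
Survival selectivity analysis
==============================

Bivariate screen (slope p < 0.1):
               beta     se      p   n  tjur_d  candidate
predictor
a_bar         0.110  0.101  0.277  34   0.035      False
cv_bar        0.845  3.387  0.803  34   0.002      False
hurst        -0.291  5.847  0.960  34   0.000      False
nu           -0.448  0.249  0.072  34   0.101       True
skew_a        0.823  0.420  0.050  34   0.143       True
extirpation   3.446  2.564  0.179  34   0.054      False
colonization -4.114  3.296  0.212  34   0.051      False
gamma_mean   -0.132  0.117  0.259  34   0.039      False
gamma_sd      0.358  0.805  0.656  34   0.006      False
gamma_skew   -0.025  0.863  0.977  34   0.000      False

Model ranking (culled complete-case n = 34):
             k   aicc  weight  loglik  deviance_explained  tjur_d
nu + skew_a  3  45.86     1.0  -19.53                16.3     0.2

Best model coefficients:
            beta     se      p
intercept -1.284  1.206  0.287
nu        -0.429  0.265  0.106
skew_a     0.790  0.430  0.066

Regression tree (28.4% deviance explained):
n=34 P=0.56  split: skew_a < 2.869
  [skew_a < 2.869] n=17 P=0.29 *
  [skew_a >= 2.869] n=17 P=0.82 *
```

Reading the output: each screen row is one bivariate logistic fit of
survival on that predictor over its complete cases (n), with the
log-odds slope β, its Wald standard error and p, and Tjur's D. Here
abundance skewness (β = 0.82, p = 0.05) and the spectral exponent
pass the 0.1 screen; both enter one multivariate model (two candidates
give a single subset of size ≥ 2), which explains 16.3% of deviance at
AICc 45.86. The tree splits the 34 species once, on skewness: the 17
high-skew species survived at P = 0.82 versus P = 0.29 below the
threshold. At this 34-species scale, which correlated predictor wins
a fit is sampling-noise-dependent — exactly the regime the method is
designed to report honestly via its n, p and ω columns.

The same stages are available from the shell:

```sh
paleosel synth --out-dir data/ --seed 3
paleosel predictors --samples data/samples.csv --survival data/survival.csv --out predictors.csv
paleosel select --predictors predictors.csv --alpha 0.1 --out report.json
```

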