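# prandial

Analysis of postprandial amino-acid responses in crossover nutrition
trials: parametric curve fitting, analytic summary parameters, curation,
non-responder imputation, and mixed-model comparison of protein
interventions against a reference.

## Who this is for

In a protein-digestibility crossover trial, each participant consumes
several protein meals (one an easily digestible reference such as whey) in
successive periods, and blood amino-acid concentrations are sampled
repeatedly for a few hours after each meal. The scientific questions are
how *completely* and how *fast* each test protein is taken up relative to
the reference. `prandial` turns the raw concentration table into exactly
that comparison, with every curation and imputation step recorded.

## The model

Each time course (one participant × one meal × one amino acid) is fitted
with a baseline-extended Wood curve

```
y(t) = d + a · t^(m·c) · e^(−c·t)        (b = m·c)
```

where `d` is the fasting baseline, `m` the time of the peak maximum
(minutes), `c` the decay rate (1/min) and `a` an amplitude scale. Fitting
is multi-start bounded nonlinear least squares (500 random starts by
default). The three parameters of interest (PoIs) then follow in closed
form, all relative to the baseline:

- **Time2Max** = `m`
- **Height** = `a (b/c)^b e^(−b)`
- **AUC(t_f)** = `a · γ(b+1, c·t_f) / c^(b+1)`, with `γ` the lower
  incomplete gamma function and `t_f` the integration endpoint (by default
  the last sampling time).

Implausible curve parameters or PoIs (defaults: AUC > 0, Height in
(0, 1000), Time2Max in (15, 200) min) are curated to missing with an audit
report. Missing AUC/Height of non-responders can optionally be imputed
from the 0.2–0.8 quantile spread of the raw series. Finally, per amino
acid and PoI a linear mixed model

```
PoI ~ Intervention + Period + (1 | Participant)
```

estimates each test-vs-reference contrast — as a ratio for AUC (the
response is log-transformed before fitting) and as a difference for Height
and Time2Max — with Satterthwaite degrees of freedom and Holm-adjusted
p-values.

Because trial data are rarely shareable, the package ships a synthetic
study generator (12 participants × 3 interventions × 3 periods, 10 samples
within 180 min, 9 essential amino acids) with known ground truth, used
throughout the tests.

## Worked example

```python
from prandial import (supro_like_design, simulate_study, fit_all,
                      FitSettings, extract_pois, curate, compare_pois)

table, truth = simulate_study(supro_like_design(seed=11))
fits = fit_all(table, FitSettings(n_starts=50, n_refine=5, seed=11))
pois = extract_pois(fits)
curated, report = curate(pois, fits)
results = compare_pois(curated, reference="REF")
print(results[results.analyte == "His"].head(4).to_string(index=False))
```

```
analyte    poi      contrast       type   estimate     ci_low   ci_high    p_raw  n_used   df     df_method  p_adjusted
    His    auc  TESTA vs REF      ratio   0.817628   0.589241  1.134537 0.214446      36 20.0 satterthwaite    0.857785
    His    auc  TESTB vs REF      ratio   0.694688   0.500642  0.963946 0.031045      36 20.0 satterthwaite    0.243644
    His height  TESTA vs REF difference  -8.500302 -14.046727 -2.953877 0.004528      36 20.0 satterthwaite    0.018113
    His height  TESTB vs REF difference -11.714352 -17.260777 -6.167927 0.000273      36 20.0 satterthwaite    0.001636
```

Reading the first row: the TESTA protein reached an estimated 82% of the
reference histidine AUC (95% CI 0.59–1.13, not significant after Holm
correction across the nine amino acids), while its peak height was 8.5
µmol/L lower (CI −14.0 to −3.0). The default synthetic design gives the
test proteins genuinely lower, slower uptake, which is what the contrasts
recover. `df = 20` is the classical residual df of the balanced 12 × 3
crossover, which the Satterthwaite approximation reproduces exactly here.

The same chain is available from the shell:

```sh
prandial simulate --seed 11 --out study.csv
prandial fit study.csv --reference REF --seed 11 --out fits.csv
prandial pois fits.csv --out pois.csv
prandial curate pois.csv --fits fits.csv
prandial compare pois_curated.csv --reference REF --out comparisons.csv
prandial plot forest --results comparisons.csv --out forest.png
# or everything at once from a config file:
prandial run --config config.yaml
```

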