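# twinchol

Liability-threshold twin modelling of eating-disorder symptomatology and
substance use disorders (SUDs): synthetic female twin cohorts, interview-item
phenotype scoring, family-clustered association analysis, and
maximum-likelihood univariate ACE / bivariate Cholesky model fitting on
ordinal raw data.

## Who this is for

Researchers in psychiatric and behavioral genetics who want a reproducible,
fully scriptable re-implementation of the classic twin comorbidity pipeline:
build analysis phenotypes from interview items (a bulimia-nervosa symptom
count, broad BN/AN diagnoses, combined SUD variables), run the phenotypic
stage (prevalence and chronology tables, logistic regression with
family-clustered sandwich standard errors), and decompose the covariance
between an eating-disorder symptom count and each SUD into additive-genetic
(A), shared-environmental (C) and unique-environmental (E) parts.  Because
the original interview data are not public, the package ships a calibrated
synthetic-cohort generator that emulates the study's statistical structure
(about 600 MZ and 440 DZ female pairs; symptom count with mean 1.27, sd 2.5,
range 0–11; SUD prevalences of 8.14% illicit, 14% alcohol, 23% caffeine,
43% regular smoking), so every stage is testable end to end.

## The model

Each ordinal or binary trait arises from a standard-normal liability cut at
increasing thresholds.  For a pair of traits the A/C/E covariance structure
is parameterized by triangular Cholesky paths

```
a11, a21, a22,  c11, c21, c22,  e11, e21, e22
```

with co-twin correlations 1.0 (MZ) / 0.5 (DZ) for A, 1.0 for C and 0 for E.
Squared standardized paths give the variance shares (a², c², e²); the
between-trait component correlations are

```
r_a = a21 / sqrt(a21² + a22²)     (a11 > 0),  and likewise r_c, r_e.
```

A pair's likelihood is the rectangle probability of the 2- or 4-dimensional
liability vector between the observed categories' thresholds (dimension 1 or
2 for singletons, whose co-twin is integrated out exactly).  Models are
compared by the likelihood-ratio Δχ² and by ΔAIC = Δχ² − 2Δdf; confidence
intervals are profile-likelihood based.  The phenotypic stage uses
independence-working-model logistic ML with the cluster-aggregated sandwich
variance (families as clusters) — the standard GEE reduction for twin data.

## Worked example

```bash
python examples/univariate_ace.py
```

prints, for a simulated regular-smoking cohort (generating a² = 0.81,
c² = 0.05, e² = 0.14 at 43% prevalence, 600 MZ + 440 DZ pairs):

```
model   a2     c2     e2     -2lnL
ACE    0.873  0.009  0.118     2495.25
AE     0.882  0.000  0.118     2495.26
CE     0.000  0.730  0.270     2547.74
E      0.000  0.000  1.000     2838.87

nested comparisons against the full ACE model:
  ACE -> AE: dchi2 =   0.00 (df 1, p = 0.948), dAIC = -2.00
  ACE -> CE: dchi2 =  52.49 (df 1, p = 0.000), dAIC = +50.49
  ACE -> E: dchi2 = 343.62 (df 2, p = 0.000), dAIC = +339.62

profile 95% CI for a2 under ACE: (0.62, 0.92)
```

The ACE fit recovers the generating heritability (0.87 vs 0.81, within
sampling error at ~1,000 pairs); dropping C costs nothing (Δχ² ≈ 0, ΔAIC
−2), while dropping A is decisively rejected — the expected picture when
the generating shared-environment share is small.  The other examples cover
cohort simulation, symptom scoring, the comorbidity/chronology tables and
the bivariate Cholesky decomposition.

The same stages are scriptable from the shell:

```bash
twinchol simulate --config bnsc_alcohol --n-mz 600 --n-dz 440 --seed 7 --out cohort.csv
twinchol twinfit --cohort cohort.csv --trait1 bnsc --trait2 alcohol \
    --models ACE,AE --seed 0 --out fit.json
twinchol run --config examples/pipeline.yaml   # simulate -> score -> associate -> twinfit -> tables
```

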