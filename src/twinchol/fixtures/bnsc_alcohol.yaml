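# Bivariate Cholesky generating model: BNSC x alcohol use disorder.
#
# Marginal structures from the univariate fixtures (BNSC AE 0.42/0.58;
# alcohol 0.53/0.47 at 14% prevalence).  Cross-trait correlations set to the
# published bivariate estimates: genetic correlation +0.53, unique-
# environmental correlation -0.03; no shared-environment variance on either
# trait, so the shared-environmental correlation carries no information.
# Comorbid onset ordering (ED-first / SUD-first / same) follows the
# published chronology split 70% / 15% / 15% for this trait pair.
seed: 0
missing_pair_rate: 0.005
traits:
  - name: bnsc
    kind: ordinal
    description: bulimia nervosa symptom count (0-11)
    marginals: [0.630000, 0.165935, 0.042202, 0.029646, 0.023690, 0.020114,
                0.017707, 0.015980, 0.014697, 0.013746, 0.013104, 0.013178]
  - name: alcohol
    kind: binary
    description: alcohol abuse/dependence
    prevalence: 0.14
components:
  trait1: {a2: 0.42, c2: 0.0, e2: 0.58}
  trait2: {a2: 0.53, c2: 0.0, e2: 0.47}
correlations: {r_a: 0.53, r_c: 0.0, r_e: -0.03}
onset:
  bnsc: {mean: 20.0, sd: 7.4}
  alcohol: {mean: 21.0, sd: 5.0}
  ordering: [0.70, 0.15, 0.15]
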