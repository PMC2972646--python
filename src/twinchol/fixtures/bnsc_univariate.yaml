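# Univariate bulimia-nervosa symptom-count (BNSC) generating model.
#
# Generating variance shares are the published univariate AE estimates for
# the symptom count (a2 = 0.42, e2 = 0.58).  The category-frequency table is
# a calibrated stand-in: the source reports only mean 1.27, sd 2.5, range
# 0-11 and a 63% entry-question non-endorsement rate, so counts 1..11 carry
# 37% mass shaped as a discretized Beta(0.325, 0.948), calibrated once so
# the full distribution has mean 1.27 and sd 2.50.
seed: 0
missing_pair_rate: 0.005
traits:
  - name: bnsc
    kind: ordinal
    description: bulimia nervosa symptom count (0-11)
    marginals: [0.630000, 0.165935, 0.042202, 0.029646, 0.023690, 0.020114,
                0.017707, 0.015980, 0.014697, 0.013746, 0.013104, 0.013178]
components:
  trait1: {a2: 0.42, c2: 0.0, e2: 0.58}
onset:
  bnsc: {mean: 20.0, sd: 7.4}   # age binge eating began
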