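# Regular smoking (>= 7 episodes/month), binary, full ACE generating model:
# a2 = 0.81, c2 = 0.05, e2 = 0.14 with lifetime prevalence 43%.
seed: 0
missing_pair_rate: 0.005
traits:
  - name: regular_smoker
    kind: binary
    description: lifetime regular smoking
    prevalence: 0.43
components:
  trait1: {a2: 0.81, c2: 0.05, e2: 0.14}
onset:
  regular_smoker: {mean: 17.0, sd: 3.0}
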