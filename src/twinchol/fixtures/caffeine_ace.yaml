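# Caffeine abuse/dependence, binary, ACE generating model:
# a2 = 0.27, e2 = 0.73, prevalence 23%.
seed: 0
missing_pair_rate: 0.005
traits:
  - name: caffeine
    kind: binary
    description: caffeine abuse/dependence
    prevalence: 0.23
components:
  trait1: {a2: 0.27, c2: 0.0, e2: 0.73}
onset:
  caffeine: {mean: 22.0, sd: 6.0}
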