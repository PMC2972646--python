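# Alcohol abuse/dependence, binary, ACE generating model:
# a2 = 0.53, e2 = 0.47 (no shared-environment variance), prevalence 14%.
seed: 0
missing_pair_rate: 0.005
traits:
  - name: alcohol
    kind: binary
    description: alcohol abuse/dependence
    prevalence: 0.14
components:
  trait1: {a2: 0.53, c2: 0.0, e2: 0.47}
onset:
  alcohol: {mean: 21.0, sd: 5.0}
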