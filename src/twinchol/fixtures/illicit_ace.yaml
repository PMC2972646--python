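# Any illicit drug use disorder, binary, ACE generating model:
# a2 = 0.68, e2 = 0.32 (no shared-environment variance), prevalence 8.14%.
seed: 0
missing_pair_rate: 0.005
traits:
  - name: any_illicit
    kind: binary
    description: any illicit drug abuse/dependence
    prevalence: 0.0814
components:
  trait1: {a2: 0.68, c2: 0.0, e2: 0.32}
onset:
  any_illicit: {mean: 19.0, sd: 4.0}
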