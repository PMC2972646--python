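# Full pipeline demo: simulate a bivariate BNSC x alcohol cohort, score
# chronology, build the prevalence/comorbidity tables, run the clustered
# association, fit the twin models, and render the publication-style tables.
#
#     twinchol run --config examples/pipeline.yaml
out_dir: twinchol_out
seed: 7
simulate:
  model: bnsc_alcohol
  n_mz: 600
  n_dz: 440
score:
  ed: bnsc
  suds: [alcohol]
prevalence:
  - group: bnsc
    suds: [alcohol]
associate:
  - symptom: bnsc
    sud: alcohol
twinfit:
  - traits: [bnsc, alcohol]
    models: [ACE, AE]
tables: [T1, T2, T3, T4]
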