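"""Bivariate Cholesky decomposition: shared risk between a symptom count
and a substance-use disorder.

Simulates BNSC x alcohol-disorder twin data with generating genetic
correlation +0.53 and unique-environmental correlation -0.03, then fits the
bivariate Cholesky ACE and AE models and prints the component correlations.
"""

from twinchol import FitOptions, compare_models, fit_model, load_generating_model, simulate_cohort

model = load_generating_model("bnsc_alcohol", seed=41)
records = simulate_cohort(model, 600, 440)
opts = FitOptions(seed=0)

traits = ["bnsc", "alcohol"]
ace = fit_model(records, traits, "ACE", opts)
ae = fit_model(records, traits, "AE", opts)

for label, fit in (("ACE", ace), ("AE", ae)):
    c = fit.components
    rc = "   —  " if c.r_c is None else f"{c.r_c:+.3f}"
    print(f"{label}: a2 = ({c.a2[0]:.2f}, {c.a2[1]:.2f})  "
          f"r_a = {c.r_a:+.3f}  r_c = {rc}  r_e = {c.r_e:+.3f}  "
          f"-2lnL = {fit.minus2_loglik:.2f}")

cr = compare_models(ace, ae)
print(f"dropping all three C paths: dchi2 = {cr.delta_chi2:.2f} "
      f"(df {cr.delta_df}, p = {cr.p_value:.2f}), dAIC = {cr.aic_delta:+.2f}")
print("""
r_a is the correlation between the two traits' additive-genetic risk
factors.  At ~1,000 pairs the full ACE fit often cannot separate A from C
on the covariance side: C components may soak up familial covariance and
push the ACE r_a toward a boundary, while the shared-environmental
correlation is essentially unidentified (its CI spans -1..+1).  The AE
model -- the better fit by AIC whenever dchi2 is ~0 -- gives the stable
estimate, here close to the generating value +0.53 with r_e near 0: the
comorbidity runs through familial liability, not person-specific
environment.""")
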