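"""Stepwise covariate modelling (SCM) on a single simulated dataset.

Forward inclusion at p<0.05 picks, step by step, the candidate with the
largest significant drop in objective function; backward elimination at
p<0.01 then prunes the model.  With a strong true effect (theta_cov=0.045)
the true covariate is selected almost surely.
"""

from covselpk import scm, simulate as sim

covariates = sim.sample_covariates(sim.default_covariate_specs(),
                                   corr=0.5, n=80, seed=11)
dataset = sim.simulate_dataset(covariates, sim.default_design(),
                               sim.default_true_params(theta_cov=0.045), seed=12)

result = scm.run_scm(dataset, scm.ScmSettings(forward_p=0.05, backward_p=0.01),
                     seed=13)
print("decision trace:")
print(result.trace.to_string(index=False))
print("\nfinal model covariates:", [c for c, _ in result.selected])
for cov, _ in result.selected:
    print(f"  beta_{cov} = {result.coefficient(cov):.4f} per covariate unit "
          "(true effect on COVI: 0.045)")
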