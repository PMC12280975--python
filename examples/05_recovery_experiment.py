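"""Small parameter-recovery experiment.

Simulates datasets at slopes beta in {0, 1} and refits each one, reporting
bias, RMSE, 89 %-interval coverage and sign accuracy.  This is the
validation loop behind the package's calibration claims, shrunk to a few
replicates so it runs in about a minute.
"""

from phylodom import PhyloGLMSpec, SyntheticTruth, recovery_experiment

truths = [SyntheticTruth(beta=b, eta=0.5, n_species=60) for b in (0.0, 1.0)]
spec = PhyloGLMSpec(draws_total=4000, warmup_per_chain=500)
per_rep, agg = recovery_experiment(truths, n_replicates=10, seed=99,
                                   outcome="binomial", fit_spec=spec)

cols = ["beta_true", "bias", "rmse", "coverage", "sign_accuracy",
        "reliable_rate", "n_nonconverged"]
print(agg[cols].round(3).to_string(index=False))
print("\ncoverage is the fraction of 89% intervals containing the true")
print("slope (nominally 0.89); at beta = 0 'reliable_rate' is the false-")
print("positive rate and should be well below 0.5; non-converged fits are")
print("counted, never silently dropped.")
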