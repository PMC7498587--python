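"""Map how strongly a mean-zero normal prior can pull the trend estimate.

Refits one synthetic region over prior variances from 100 (vague) down to
0.001, at reduced MCMC length.  Expected pattern: variances >= 0.1 barely
move the mode; tighter priors shrink it toward the prior mean (zero).
"""

import chltrend as ct

mask = ct.generate_region_layout(1, (8, 8), seed=31)
truth = ct.random_truth([0], seed=32)
field = ct.simulate_chl_field(truth, mask, 120)

config = ct.STModelConfig(n_iterations=1500, n_burnin=500, seed=8)
result = ct.sensitivity_scan(
    field, mask, 0,
    mean_grid=[0.0],
    variance_grid=[100.0, 10.0, 1.0, 0.1, 0.01, 0.001],
    reduced_config=config,
)
print(f"true trend: {truth.region_trends[0]:+.2f} % / yr")
print(result.table[["prior_var_pct_yr", "mode_pct_yr", "hdi_width_pct_yr"]].to_string(index=False))
print("tight mean-zero priors pull the posterior mode toward zero;")
print("a variance of 100 reproduces the vague-prior fit.")
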