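"""Multiple imputation of missing outcomes and Rubin pooling.

Masks outcomes MAR, imputes by chained equations with predictive mean
matching, and shows that the pooled outcome mean recovers the
complete-data mean within its pooled standard error.
"""

from cpgmediation import (
    chained_equations_impute,
    generate_cohort,
    inject_missingness,
    rubin_pool_mean,
    rubin_pool_r2,
    scenario_config,
)

cfg = scenario_config("full_mediation", n_per_arm=(250, 250), missing_frac=0.25, seed=3)
complete = generate_cohort(cfg)
masked = inject_missingness(complete, cfg)
stack = chained_equations_impute(masked, m=5, iterations=5, seed=4)

n = len(complete)
mu = complete["internalizing"].mean()
qs = [ds["internalizing"].mean() for ds in stack.datasets]
us = [ds["internalizing"].var(ddof=1) / n for ds in stack.datasets]
qbar, se = rubin_pool_mean(qs, us)
print(f"complete-data mean internalizing score: {mu:.4f}")
print(f"pooled mean after 25% MAR masking + imputation: {qbar:.4f} (SE {se:.4f})")
print(f"deviation in pooled-SE units: {abs(qbar - mu) / se:.2f} "
      "(values below ~3 indicate successful recovery)")

# R2 pooling across imputations uses Fisher-z of the multiple correlation
print(f"rubin_pool_r2([0.2, 0.3, 0.4]) = {rubin_pool_r2([0.2, 0.3, 0.4]):.4f} "
      "(slightly below the arithmetic mean: the z-scale average)")
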