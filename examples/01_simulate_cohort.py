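"""Generate a synthetic longitudinal cohort and inspect its structure.

The simulator emulates an annual cohort of older adults with a four-level
alcohol exposure, a time-varying health confounder, informative dropout,
and a J-shaped causal effect on probable depression (CES-D-10 >= 8). The
counterfactual oracle reports the true marginal odds ratios the estimator
should recover.
"""

from jshape import SimulationConfig, simulate_cohort, true_marginal_effects

config = SimulationConfig(n_participants=5000, n_waves=5, seed=1)
cohort = simulate_cohort(config)

base = cohort.baseline()
print(f"participants: {cohort.n_participants}, waves: {cohort.n_waves}, "
      f"rows (observed person-waves): {len(cohort.data)}")
print("\nbaseline category shares (target 26.9 / 21.2 / 32.6 / 19.3%):")
print(base.alcohol_category.value_counts(normalize=True).round(3).to_string())
print(f"\nper-wave prevalence of probable depression: "
      f"{cohort.data.depressed.mean():.3f} (target ~0.09)")
retention = cohort.data.groupby("wave").size() / cohort.n_participants
print(f"retention by wave: {retention.round(2).to_dict()}")

truth = true_marginal_effects(config, n_mc=100_000, seed=2)
print("\ntrue marginal odds ratios vs moderate (counterfactual Monte Carlo):")
for cat, or_ in truth.or_vs_moderate.items():
    print(f"  {cat:16s} {or_:.3f}  (MC SE of log-OR {truth.mc_se_log_or[cat]:.4f})")
print("\nThe J-shape: risk is lowest under sustained moderate consumption and "
      "elevated for sustained abstinence, occasional and above-guideline use.")
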