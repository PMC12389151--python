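"""Per-protocol and intention-to-treat weighted analyses vs the known truth.

The per-protocol analysis uses annually time-updated exposure with
treatment x censoring weights and a one-year exposure-outcome lag; the
intention-to-treat analysis carries the baseline category forward. Both fit
weighted logistic estimating equations with participant clustering and
robust variance.
"""

from jshape import SimulationConfig, run_itt, run_pp, simulate_cohort, true_marginal_effects

config = SimulationConfig(n_participants=16_563, n_waves=6, seed=4)
cohort = simulate_cohort(config)
truth = true_marginal_effects(config, n_mc=100_000, seed=5)

pp = run_pp(cohort)
itt = run_itt(cohort)

print("per-protocol (time-updated exposure), odds ratio vs moderate:")
print(f"{'contrast':28s} {'naive':>7s} {'weighted':>9s} {'95% CI':>15s} {'truth':>7s}")
for w, u in zip(pp.weighted, pp.unadjusted):
    cat = w.contrast.split(" vs ")[0]
    print(f"{w.contrast:28s} {u.odds_ratio:7.3f} {w.odds_ratio:9.3f} "
          f"({w.ci_low:5.3f}-{w.ci_high:5.3f}) {truth.or_vs_moderate[cat]:7.3f}")

print("\nintention-to-treat (baseline category carried forward):")
for w in itt.weighted:
    print(f"{w.contrast:28s} {w.odds_ratio:9.3f} ({w.ci_low:5.3f}-{w.ci_high:5.3f})")

print("\nNaive estimates are confounded (abstainers look worse, above-guideline "
      "drinkers better, than their causal effect); weighting recovers the truth. "
      "ITT attenuates toward the null where categories switch over follow-up.")
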