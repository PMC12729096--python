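"""Condition-level workload statistics on a synthetic cohort.

Draws a 24-participant session-metric table from the generative model
(2 traffic x 3 complexity within-subject design), runs the repeated-measures
ANOVAs with Huynh-Feldt correction, and correlates the ocular indices with
the subjective workload scales over the six condition means.
"""

from atcgaze import CohortParams, rm_anova_2x3, simulate_metric_table, \
    spearman_condition_matrix

table = simulate_metric_table(CohortParams(), seed=1)

for metric in ("pupil_mean_mm", "blink_count", "isa_mean"):
    sub = table.rename(columns={metric: "value"})[
        ["participant", "traffic", "complexity", "value"]]
    res = rm_anova_2x3(sub)
    t = res["traffic"]
    print(f"{metric:14s} traffic effect: F({t.df1:.0f},{t.df2:.0f}) = "
          f"{t.F:7.2f}, p = {t.p:.4f}, eta_p^2 = {t.eta_p_sq:.2f}")

means = table.groupby(["traffic", "complexity"])[
    ["pupil_mean_mm", "blink_count", "isa_mean", "nasa_sum"]].mean()
rho, p, _ = spearman_condition_matrix(means)
print(f"\nSpearman over the 6 condition means:")
print(f"  rho(ISA, pupil)  = {rho.loc['isa_mean', 'pupil_mean_mm']:+.2f}")
print(f"  rho(ISA, blinks) = {rho.loc['isa_mean', 'blink_count']:+.2f}")
print()
print("Larger pupils and suppressed blinking accompany higher self-reported")
print("workload; the traffic manipulation drives most of the variance.")
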