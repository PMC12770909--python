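"""Individualized montage selection.

Anatomy (here: jittered site positions and field gains) makes different
montages optimal for different individuals.  This script generates a
heterogeneous cohort, selects the montage minimising the deviation from
the intended field direction (delta-DotP on the M1 sheet) per individual,
and compares the result with the best single fixed montage.
"""

from dstacs import (
    Objective,
    SyntheticCohort,
    analyze_cohort,
    default_montages,
    individualized_summary,
    make_cohort,
    select_best_montage,
)

# candidate montages with comparable inter-site overlap, so the best choice
# genuinely depends on each individual's anatomy rather than on one montage
# dominating everyone
candidates_specs = [
    s for s in default_montages() if s.montage_id in ("3x1a", "4x1a", "ring_b")
]
cohort = make_cohort(
    candidates_specs,
    SyntheticCohort(n_individuals=10, seed=8),
    subdivisions=3,
)
metrics = analyze_cohort(cohort)
candidates = sorted(metrics["montage_id"].unique())

objective = Objective(metric="delta_dotp", direction="minimize", region_set="M1s")
selection = select_best_montage(metrics, objective, candidates)
summary = individualized_summary(metrics, selection)

print("chosen montage per individual (objective: minimise delta-DotP, M1s):")
for ind, montage in sorted(selection.chosen.items()):
    print(f"  {ind}: {montage}  (lag-averaged delta-DotP "
          f"{selection.per_individual_value[ind]:.4f})")
print("\nfraction choosing each montage:")
for m in candidates:
    print(f"  {m:8s} {selection.fraction_choosing(m):5.1f}%")

print(f"\nbest fixed montage:        {summary.best_fixed_montage}")
print(f"mean delta-DotP, fixed:    {summary.mean_fixed_best:.4f}  "
      f"(CV {summary.cv_fixed_best:.0f}%)")
print(f"mean delta-DotP, per-ind.: {summary.mean_individualized:.4f}  "
      f"(CV {summary.cv_individualized:.0f}%)")
print(
    "\nPer-individual selection can never be worse than the best fixed"
    "\nmontage (it is a pointwise optimum) and improves the mean whenever"
    "\nindividuals disagree about the best montage."
)
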