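"""Is a metric significantly modulated by the phase lag?

A metric that truly ignores the phase lag is exchangeable across lag
labels; the weighted Hermans-Rasson permutation test quantifies the
evidence against that.  This script generates a small overlapping-mode
cohort, tests the redistribution (RDM) and peak-magnitude metrics for each
montage, and applies Holm correction across montages.
"""

from dstacs import (
    SyntheticCohort,
    analyze_cohort,
    default_montages,
    holm_correct,
    make_cohort,
    phase_modulation_test,
)

cohort = make_cohort(
    default_montages()[:3],
    SyntheticCohort(n_individuals=8, seed=4),
    subdivisions=3,
)
metrics = analyze_cohort(cohort)

for metric in ("rdm", "peak_magnitude"):
    sub = metrics[(metrics["metric"] == metric) & (metrics["region_set"] == "M1s")]
    results = [
        phase_modulation_test(records, n_perm=999, seed=i)
        for i, (_, records) in enumerate(sub.groupby("montage_id"))
    ]
    adjusted = holm_correct([r.p_raw for r in results])
    print(f"\n{metric} on the M1 sheet (999 permutations, Holm-corrected):")
    for res, p_adj in zip(results, adjusted):
        print(f"  {res.montage_id:8s} WHR = {res.statistic:10.3f}  "
              f"p_raw = {res.p_raw:.3f}  p_holm = {p_adj:.3f}")

print(
    "\nRDM varies strongly and systematically with the lag, so its test"
    "\nreaches the smallest attainable p-value; a small p means the metric"
    "\nis phase-lag dependent and lag conditions are not interchangeable."
)
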