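"""Idealised case: spatially separated site fields.

When the two stimulation sites' fields share no cortical nodes, changing
the phase lag shifts only the relative timing of the two fields — every
spatial property is untouched.  This script builds a separated-mode
synthetic individual, runs the full metric pipeline, and shows that the
envelope RDM and the deviation from the ideal direction (delta-DotP) vanish
at every lag while the DotP itself traces the analytic separated-fields
curve.
"""

import numpy as np

from dstacs import (
    SyntheticCohort,
    analyze_montage,
    default_montages,
    make_cohort,
)

individual = make_cohort(
    default_montages("separated")[:1],
    SyntheticCohort(n_individuals=1, seed=0),
    subdivisions=3,
)[0]
basis = individual.basis_by_montage["3x1a"]

table = analyze_montage(individual.sheet, basis, rdm_mode="envelope")
m1 = table[table["region_set"] == "M1s"].pivot(
    index="phase_lag", columns="metric", values="value"
)

print("separated-mode metrics on the M1 target sheet (montage 3x1a):")
print(f"{'lag/pi':>7} {'peak [V/m]':>11} {'RDM(env)':>10} {'DotP':>8} {'ideal':>8} {'dDotP':>9}")
for lag, row in m1.iterrows():
    print(
        f"{lag / np.pi:7.2f} {row['peak_magnitude']:11.4f} {row['rdm']:10.2e} "
        f"{row['dotp']:8.3f} {row['ideal_dotp']:8.3f} {row['delta_dotp']:9.2e}"
    )

print(
    "\nPeak magnitude is constant across lags, envelope RDM and delta-DotP are"
    "\nzero to machine precision: with disjoint fields the lag changes timing"
    "\nonly. The DotP column follows the ideal two-site curve (cos-weighted"
    "\noverlap of the two sinusoids), dipping to 0 at antiphase for balanced"
    "\nsite powers."
)
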