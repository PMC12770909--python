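"""Realistic case: partially overlapping site fields.

With overlapping fields the phase lag is no longer a pure timing knob: on
the nodes both sites reach, the sinusoids interfere differently at each
lag, redistributing the field (RDM > 0), bending its direction away from
the separated-fields ideal (delta-DotP > 0) and modulating the effective
stimulation area.  This script compares a focal and a wide synthetic
montage on one individual.
"""

import numpy as np
from dataclasses import replace

from dstacs import analyze_montage, default_montages, make_basis_fields, make_sphere_sheet

sheet = make_sphere_sheet(subdivisions=3)

for overlap, label in ((0.02, "focal montage (overlap 0.02)"),
                       (0.30, "wide montage  (overlap 0.30)")):
    spec = replace(default_montages()[3], overlap=overlap, montage_id=label)
    table = analyze_montage(sheet, make_basis_fields(sheet, spec))
    surr = table[table["region_set"] == "surrounding"].pivot(
        index="phase_lag", columns="metric", values="value"
    )
    print(f"\n{label} — surrounding grey-matter sheet:")
    print(f"{'lag/pi':>7} {'RDM':>7} {'dDotP':>8} {'peak normal [V/m]':>19}")
    for lag, row in surr.iterrows():
        print(f"{lag / np.pi:7.2f} {row['rdm']:7.3f} {row['delta_dotp']:8.4f} "
              f"{row['peak_normal']:19.4f}")

print(
    "\nThe wider montage shows larger RDM and delta-DotP at intermediate"
    "\nlags: more inter-site overlap means stronger phase-lag-dependent"
    "\ninterference, the trade-off between field strength and separability."
)
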