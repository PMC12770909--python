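# Methods

This note records what `dstacs` computes, the assumptions behind it, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real head models.

## Field reconstruction by superposition

The quasi-static forward problem is linear in the injected currents, so
the dual-site field at any phase lag φ is reconstructed from three static
basis fields (central and surround channels of site 1, whole site 2, each
solved against a common return electrode):

E(p, t) = I₀ [ (E_R1(p) − E_C1(p)) sin(2πft) + E_R2(p) sin(2πft + φ) ].

The lag is applied to the second site only. Basis fields are stored per
unit channel current (V/m per mA), so central-vs-surround current ratios
(3:1, 4:1, or equal for rings) are the field producer's responsibility.
Defaults: I₀ = 2 mA (4 mA peak-to-peak), f = 20 Hz, eight lags
{0, π/4, …, 7π/4}, 24 time steps per cycle. All metrics scale linearly in
I₀, so results transfer to other intensities.

**Time-grid anchoring.** The 24 equally spaced samples are taken at
t_k = (k + ½)/(24 f). An unshifted grid (t_k = k/(24 f)) contains two
exact zero crossings of sin(2πft), at which the entire zero-lag field
vanishes and normalised comparison metrics are 0/0. The half-step offset
removes those degeneracies for every default lag while preserving equal
spacing over one period. A second guard at the metric level (below)
covers accidental cancellations the grid cannot anticipate. A convenient
side effect: for lags that are multiples of π/4, the sampled values of
|sin(2πft + φ)| form the same 24-point set for every lag, so per-node
cycle envelopes are exactly lag-independent when fields do not overlap.

## Threshold cleanup

Finite-element fields carry artefacts at both extremes. Per condition
(montage × lag) and per scalar family — field magnitude, and absolute
normal component — the cycle envelope is computed per node and a two-sided
mask derived from it: nodes above the 99.9th percentile
(linear-interpolation percentile) are *excluded* from all metric node
sets; nodes below 2 % of that percentile are *zeroed* (value set to 0,
node and area retained). Computing masks on envelopes rather than per
time step keeps each metric's node support stable across the cycle; the
magnitude and normal-component families are masked independently.
Exclusion and zeroing counts are logged because they are scientific
choices, not noise.

## Metrics

All comparison metrics relate the condition at lag φ to the φ = 0
reference of the same montage, on the intersection of the two conditions'
kept node sets, with both conditions' zeroing floors applied.

- **Peaks**: max over kept region nodes and time steps of |E| and of
  |E·n|; the inward peak (max of −E·n, normals pointing outward) is
  reported alongside, since cortex-normal inward current is the
  physiologically potent direction. Sign conventions affect labels only;
  all peak metrics are sign-invariant.
- **RDM** (per step): ‖ |a|/‖a‖ − |b|/‖b‖ ‖ with a, b the spatial
  vectors of normal components; averaged over non-degenerate steps. With
  element-wise absolute values the analytic maximum is √2 (disjoint
  supports), not 2 — the bound 2 holds only for signed vectors. The
  element-wise-absolute form is implemented as stated; the discrepancy in
  the often-quoted bound is noted here deliberately.
- **RDM modes**: `timewise` (default) applies the formula per time step.
  For perfectly separated fields at lags ∉ {0, π} it is *nonzero* —
  the two sites' |sin| weightings differ within a step even though the
  per-node envelopes are identical. `envelope` mode applies the same
  formula once to the per-node cycle envelopes and is exactly zero for
  separated fields at every lag; it isolates genuine spatial
  redistribution from pure within-cycle timing. Both are provided because
  both answers are legitimate: "does the instantaneous pattern move?"
  versus "does the cycle-integrated pattern move?".
- **DotP** (per step): cosine similarity of the signed vectors, averaged
  over non-degenerate steps, clipped to [−1, 1] against rounding.
- **Ideal DotP / ΔDotP**: the ideal is what perfectly separated fields
  would give. It is computed by brute force: two disjoint single-node
  sites whose squared normal-component powers P₁ = Σ (n·I₀(E_R1 − E_C1))²
  and P₂ = Σ (n·I₀E_R2)² are taken per individual over the same masked
  comparison node set, run through the actual superposition + DotP code.
  With this definition, observed = ideal is an exact identity whenever
  the two sites' fields are spatially disjoint — which is precisely what
  "ideal" means here — and ΔDotP = |ideal − observed| measures the
  overlap-induced deviation alone. Per-individual powers (rather than a
  fixed montage-level ratio) were chosen for the same reason: the
  identity must hold per individual.
- **Degenerate-step guard**: steps where either series' vector norm falls
  below 10⁻⁸ × that series' maximum step norm are dropped from RDM/DotP
  averages (normalising a numerically zero vector is meaningless). On the
  default grid no step is degenerate.
- **Effective area**: per step, the reference peak is max |E·n| over the
  surrounding sheet including both targets; the target area where |E·n| ≥
  50 % of it is summed (barycentric node areas, mm²) and averaged over
  the cycle.
- Metrics are node-based (per-node normal components, per-node areas);
  triangle-centre evaluation would be an equivalent alternative.

## Geometry

Vertex normals are angle-weighted averages of incident triangle normals,
globally oriented outward (away from the centroid) for closed surfaces;
degenerate triangles contribute nothing (with a warning) and isolated
nodes are an error. Node areas follow the barycentric one-third rule, so
they sum exactly to the mesh area. Coordinates are mm, areas mm².

## Statistics

**Modulation test.** Whether a metric depends on the phase lag is tested
with a weighted Hermans–Rasson statistic
T = Σᵢⱼ wᵢwⱼ k(θᵢ − θⱼ), k(d) = |π − |d|| − π/2 − 2.895(|sin d| − 2/π),
where θ are the lag angles and w the metric values min–max scaled to
[0, 1] once per montage (making T scale-free). The second-form kernel
with the subtracted |sin| term is used because it has omnibus power: both
synphase and antiphase weight concentrations raise T. That matters here
because every lag profile of a sinusoidal superposition is symmetric
about π, so axial (second-harmonic) patterns are the typical alternative;
a kernel with the opposite sign on the |sin| term has essentially no
power against them. Peak metrics enter as max-over-time values, the
others as cycle averages.

The null distribution permutes lag labels independently within each
individual (preserving each individual's value multiset and hence all
between-individual structure); p = (1 + #{T\* ≥ T}) / (1 + n_perm) with
n_perm = 10 000 by default, which is a valid p-value at any finite
permutation count. Because significance comes from the permutation null,
type-I error control holds for any fixed kernel — the kernel choice
affects power only. The within-individual value multiset is asserted on
every run. Holm's step-down correction (via statsmodels) controls for
multiple montages.

**Variability.** CV = sample SD (n−1) / mean × 100 %, computed across
individuals per (metric, montage, lag), then averaged across lags. The
strict CV errors on a zero mean; the individualization summary maps the
degenerate all-values-identical case to CV 0 before averaging.

**Individualization.** Per individual, the candidate montage optimising
the lag-aggregated objective (mean over lags by default; worst-case
available). The trivial zero-lag self-comparison rows are excluded from
rdm/dotp/ΔDotP aggregation (they are identically 0/1/0) and included for
peaks and areas. Ties break lexicographically by montage id. The
individualized mean can never be worse than the best fixed montage's mean
(pointwise optimum), and is strictly better whenever any individual's
choice strictly beats the fixed best.

## Synthetic data

The generator emulates the structure the analysis assumes, not
electrostatics. An icosphere (radius 80 mm, subdivision 4 by default,
2562 nodes) carries two 10°-radius target caps 72° apart (the C3/C4 arc)
and a 35° surrounding belt. Each site's pattern is an inward-normal
Gaussian central lobe (peak 0.2 V/m per mA), outward surround lobes
(discrete 3×/4× positions or a ring) flux-balanced to the central lobe,
tangential components along the lobes' surface gradients (30 % of
normal), and a broad far-field lobe (σ = 50°) whose amplitude is
`overlap × peak` — the single knob for inter-site coupling. Site 2's
field is scaled to a configurable power ratio. Nine default montages span
the common high-definition families with overlaps from 0.02 to 0.25,
chosen so wider layouts trade separability for field strength. In
`separated` mode all supports are truncated to disjoint caps, which makes
the ideal-case identities (envelope RDM = 0, ΔDotP = 0, lag-constant
peaks) hold to machine precision.

Cohorts (default n = 18) jitter each site centre by a 2-D Gaussian
tangent step (σ = 3°) and draw lognormal per-site gains (σ = 0.2) from
one seeded generator; identical (spec, seed) pairs are bit-identical.
These values are plausible for electrode-placement and anatomical
variability, and produce inter-individual CVs and heterogeneous montage
preferences of the kind the analysis is meant to summarise.

**What passing tests do not show.** Synthetic fields are smooth,
normal-dominant and noiseless; real FEM fields have gyral-folding
direction structure, conductivity-driven hotspots and numerical noise,
and real targets are not circular caps. Tests on synthetic cohorts
validate the *analysis machinery* (identities, invariances, calibration,
dominance), not the magnitudes of any metric on real heads.

## Problem sizes

Tests run on subdivision-2/3 spheres (162/642 nodes) with cohorts of 2–6
individuals and 199–999 permutations; the permutation-calibration check
uses 2000 simulated cohorts of 18 individuals at 999 permutations. The
acceptance script uses one subdivision-4 individual. These sizes were
chosen so the whole suite completes in well under a minute of compute per
module while exercising every code path at full metric fidelity.

## Known limitations

- No FEM, segmentation, electrode or conductivity modelling: basis fields
  are inputs.
- The literal per-step RDM conflates timing and redistribution at lags
  ∉ {0, π}; use envelope mode to isolate redistribution.
- The WHR weighting and scaling conventions are package choices
  (validity is permutation-based; power depends on them).
- The effective-area reference peak is recomputed per time step, so the
  metric is not monotone in the lag in general.
- Icosphere caps approximate equal-area targets only as well as the mesh
  resolution allows; antipodal symmetry holds exactly, generic positions
  within one ring of triangles.
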