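"""Synthetic cortical sheets and basis fields with the structure the
analysis assumes.

Real inputs to this package are MRI-derived finite-element solves; the
generator replaces them with a controlled phenomenological stand-in so that
every stage of the pipeline runs without MRI data.  A spherical cortical
sheet carries two circular target patches ("M1_left" / "M1_right") and an
annular surrounding belt.  Each stimulation site produces a high-definition
field pattern: an inward-normal Gaussian lobe under the central electrode,
opposite-polarity lobes under the surround electrodes (discrete 3x/4x
positions or a ring), flux-balanced so the net injected current is zero, and
a tangential component following the surface gradient of each lobe.  Field
construction is normal-dominant and phenomenological, not electrostatically
exact: the analysis pipeline is agnostic to how basis fields arose, and the
generator preserves the structural features that drive the metrics —
polarity layout, partial inter-site overlap, and normal dominance.

Two modes matter scientifically:

* ``overlapping`` — lobes have Gaussian tails; an ``overlap`` parameter
  widens them so the two sites' fields coexist on intermediate nodes, the
  regime in which phase lags modulate field metrics.
* ``separated`` — supports are truncated to disjoint caps, reproducing the
  idealised case in which phase lags change timing but no spatial metric.

Cohorts add inter-individual variability by jittering the site centres on
the sphere and drawing lognormal per-site amplitude scalings from a single
seeded generator, so identical (spec, seed) pairs give bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .geometry import CorticalSheet
from .superposition import BasisFieldSet

__all__ = [
    "SyntheticMontageSpec",
    "SyntheticCohort",
    "Individual",
    "default_site_centres",
    "default_montages",
    "make_sphere_sheet",
    "make_basis_fields",
    "make_cohort",
]

DEFAULT_RADIUS_MM = 80.0
DEFAULT_SUBDIVISIONS = 4
DEFAULT_CAP_RADIUS = np.deg2rad(10.0)
DEFAULT_BAND_RADIUS = np.deg2rad(35.0)
#: peak normal field of the central lobe, V/m per mA of channel current
DEFAULT_PEAK_FIELD = 0.2


def default_site_centres(separation: float = np.deg2rad(72.0)) -> tuple[np.ndarray, np.ndarray]:
    """Unit directions of the two stimulation sites.

    Site 1 (the lag-fixed site, right hemisphere) and site 2 (the
    lag-shifted site, left hemisphere) sit symmetrically about the vertex at
    the given angular separation — 72 degrees matches the C4/C3 arc of the
    10-20 system.
    """
    half = separation / 2.0
    c1 = np.array([np.sin(half), 0.0, np.cos(half)])   # right
    c2 = np.array([-np.sin(half), 0.0, np.cos(half)])  # left
    return c1, c2


@dataclass(frozen=True)
class SyntheticMontageSpec:
    """Geometry and overlap structure of one synthetic montage.

    ``surround`` is either ``("mse", n, offset)`` — n discrete surround
    lobes at angular distance ``offset`` (rad) from the centre — or
    ``("ring", offset)`` — an annular surround at that angular distance.
    ``overlap`` >= 0 widens every lobe (sigma scale 1 + 3*overlap) so the two
    sites' fields increasingly coexist on intermediate nodes.
    ``amplitude_ratio`` is the site-2 / site-1 field power ratio.
    """

    montage_id: str
    site_centres: tuple[np.ndarray, np.ndarray] = field(default_factory=default_site_centres)
    central_spread: float = np.deg2rad(8.0)
    surround: tuple = ("mse", 4, np.deg2rad(18.0))
    overlap: float = 0.15
    amplitude_ratio: float = 1.0
    mode: str = "overlapping"
    tangential_frac: float = 0.3
    peak_field: float = DEFAULT_PEAK_FIELD
    #: gain (relative to peak_field, per unit of ``overlap``) and angular
    #: sigma of the broad far-field lobe each site adds.  Volume-conducted
    #: fields decay slowly, so each site reaches the other site's target
    #: with a few percent of its local peak; the far-field amplitude is
    #: ``far_gain * overlap * peak_field``, making ``overlap`` the single
    #: knob for inter-site coupling (overlap 0 = uncoupled sites)
    far_gain: float = 1.0
    far_spread: float = np.deg2rad(50.0)

    def __post_init__(self):
        if self.mode not in ("overlapping", "separated"):
            raise ValueError("mode must be 'overlapping' or 'separated'")
        if self.overlap < 0:
            raise ValueError("overlap must be non-negative")
        if self.surround[0] not in ("mse", "ring"):
            raise ValueError("surround kind must be 'mse' or 'ring'")

    @property
    def sigma_scale(self) -> float:
        return 1.0 + 3.0 * self.overlap


@dataclass(frozen=True)
class SyntheticCohort:
    """Inter-individual variability parameters of a synthetic cohort."""

    n_individuals: int = 18
    seed: int = 0
    site_jitter_sigma: float = np.deg2rad(3.0)   # angular site displacement
    amplitude_sigma: float = 0.2                 # lognormal sigma of site gains

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")


@dataclass
class Individual:
    """One synthetic individual: a labelled sheet plus per-montage bases."""

    individual_id: str
    sheet: CorticalSheet
    basis_by_montage: dict[str, BasisFieldSet]


def default_montages(mode: str = "overlapping") -> list[SyntheticMontageSpec]:
    """Nine candidate montages emulating the common high-definition
    families: 3x1 and 4x1 multiple-small-electrode layouts and four ring
    sizes.  Wider layouts trade focality for field strength, so the set
    spans a range of inter-site overlap.
    """
    d = np.deg2rad
    specs = [
        SyntheticMontageSpec("3x1a", central_spread=d(8), surround=("mse", 3, d(20)), overlap=0.10),
        SyntheticMontageSpec("3x1b", central_spread=d(7), surround=("mse", 3, d(16)), overlap=0.05),
        SyntheticMontageSpec("3x1c", central_spread=d(10), surround=("mse", 3, d(26)), overlap=0.25),
        SyntheticMontageSpec("4x1a", central_spread=d(8), surround=("mse", 4, d(18)), overlap=0.10),
        SyntheticMontageSpec("4x1b", central_spread=d(6), surround=("mse", 4, d(14)), overlap=0.02),
        SyntheticMontageSpec("ring_a", central_spread=d(9), surround=("ring", d(22)), overlap=0.20),
        SyntheticMontageSpec("ring_b", central_spread=d(8), surround=("ring", d(18)), overlap=0.12),
        SyntheticMontageSpec("ring_c", central_spread=d(7), surround=("ring", d(16)), overlap=0.08),
        SyntheticMontageSpec("ring_d", central_spread=d(7), surround=("ring", d(14)), overlap=0.05),
    ]
    return [replace(s, mode=mode) for s in specs]


# ---------------------------------------------------------------------------
# sphere sheet
# ---------------------------------------------------------------------------

def _angles_to(points_unit: np.ndarray, centre: np.ndarray) -> np.ndarray:
    return np.arccos(np.clip(points_unit @ centre, -1.0, 1.0))


def make_sphere_sheet(
    radius: float = DEFAULT_RADIUS_MM,
    subdivisions: int = DEFAULT_SUBDIVISIONS,
    spec: SyntheticMontageSpec | None = None,
    cap_radius: float = DEFAULT_CAP_RADIUS,
    band_radius: float = DEFAULT_BAND_RADIUS,
) -> CorticalSheet:
    """Icosphere cortical sheet with target caps and a surrounding belt.

    Nodes within ``cap_radius`` of the two site centres are labelled
    "M1_right" (site 1) and "M1_left" (site 2); nodes within ``band_radius``
    of either centre but outside the caps form "surrounding"; the rest stay
    unlabelled (label -1).
    """
    if subdivisions < 2:
        raise ValueError("subdivisions must be at least 2")
    c1, c2 = (spec.site_centres if spec is not None else default_site_centres())
    separation = float(np.arccos(np.clip(c1 @ c2, -1.0, 1.0)))
    if separation < 2.0 * cap_radius:
        raise ValueError("site centres too close: target caps would overlap")

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    coords = np.asarray(mesh.vertices, dtype=float)
    tris = np.asarray(mesh.faces, dtype=np.intp)
    unit = coords / np.linalg.norm(coords, axis=1, keepdims=True)
    a1 = _angles_to(unit, c1)
    a2 = _angles_to(unit, c2)

    labels = np.full(coords.shape[0], -1, dtype=int)
    labels[(a1 < band_radius) | (a2 < band_radius)] = 3
    labels[a2 < cap_radius] = 2   # M1_left, site 2
    labels[a1 < cap_radius] = 1   # M1_right, site 1
    region_sets = {
        "M1_right": frozenset({1}),
        "M1_left": frozenset({2}),
        "surrounding": frozenset({3}),
    }
    return CorticalSheet.from_mesh(coords, tris, labels, region_sets)


# ---------------------------------------------------------------------------
# basis fields
# ---------------------------------------------------------------------------

def _lobe(
    unit: np.ndarray,
    normals: np.ndarray,
    centre: np.ndarray,
    sigma: float,
    polarity: float,
    tangential_frac: float,
    ring_offset: float | None = None,
) -> np.ndarray:
    """Gaussian field lobe around ``centre``: polarity * g(alpha) along the
    normal plus a tangential component following the surface gradient of g.
    """
    alpha = _angles_to(unit, centre)
    if ring_offset is None:
        arg = alpha
    else:
        arg = alpha - ring_offset
    g = np.exp(-(arg**2) / (2.0 * sigma**2))
    dg = -(arg / sigma**2) * g

    # unit tangent at each node pointing away from the lobe centre
    toward = centre[None, :] - (unit @ centre)[:, None] * unit
    norm = np.linalg.norm(toward, axis=1)
    away = np.zeros_like(unit)
    ok = norm > 1e-12
    away[ok] = -toward[ok] / norm[ok, None]

    return polarity * (g[:, None] * normals - tangential_frac * dg[:, None] * away)


def _site_pattern(
    sheet: CorticalSheet,
    centre: np.ndarray,
    spec: SyntheticMontageSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """(central_field, surround_field) of one site, flux-balanced.

    The central lobe points inward (negative normal polarity, the polarity
    under the centre electrode of a high-definition layout); the surround
    pattern points outward and is scaled so its area-weighted absolute
    normal flux matches the central lobe's, emulating a zero net current.
    """
    unit = sheet.node_coords / np.linalg.norm(sheet.node_coords, axis=1, keepdims=True)
    sig_c = spec.central_spread * spec.sigma_scale
    central = spec.peak_field * _lobe(
        unit, sheet.normals, centre, sig_c, -1.0, spec.tangential_frac
    )

    kind = spec.surround[0]
    if kind == "mse":
        _, n_lobes, offset = spec.surround
        sig_s = sig_c
        # orthonormal frame at the site centre for placing surround lobes
        ref = np.array([0.0, 0.0, 1.0])
        if abs(centre @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        u = np.cross(centre, ref)
        u /= np.linalg.norm(u)
        v = np.cross(centre, u)
        surround = np.zeros_like(central)
        for k in range(n_lobes):
            az = 2.0 * np.pi * k / n_lobes
            pos = np.cos(offset) * centre + np.sin(offset) * (np.cos(az) * u + np.sin(az) * v)
            surround += spec.peak_field * _lobe(
                unit, sheet.normals, pos, sig_s, +1.0, spec.tangential_frac
            )
    else:
        _, offset = spec.surround
        sig_s = sig_c * 0.6
        surround = spec.peak_field * _lobe(
            unit, sheet.normals, centre, sig_s, +1.0, spec.tangential_frac,
            ring_offset=offset,
        )

    flux_c = float(np.abs(np.einsum("ij,ij->i", central, sheet.normals)) @ sheet.node_areas)
    flux_s = float(np.abs(np.einsum("ij,ij->i", surround, sheet.normals)) @ sheet.node_areas)
    if flux_s > 0:
        surround *= flux_c / flux_s

    # broad far-field lobe: the slowly decaying remainder of the volume-
    # conducted field, which is what makes the two sites overlap at each
    # other's targets
    far_amp = spec.far_gain * spec.overlap * spec.peak_field
    if far_amp > 0:
        central = central + far_amp * _lobe(
            unit, sheet.normals, centre, spec.far_spread, -1.0, spec.tangential_frac
        )
    return central, surround


def make_basis_fields(
    sheet: CorticalSheet,
    spec: SyntheticMontageSpec,
    seed: int | None = None,
    site_gains: tuple[float, float] = (1.0, 1.0),
) -> BasisFieldSet:
    """The three basis fields of one montage on one sheet.

    E_C1 is the (sign-flipped) central lobe of site 1, E_R1 its surround
    pattern, so the lag-fixed combination E_R1 - E_C1 is the full site-1
    high-definition pattern; E_R2 is the full site-2 pattern, scaled so that
    its total squared field is ``amplitude_ratio`` times site 1's.  In
    ``separated`` mode both sites' fields are truncated to disjoint caps, so
    the supports of (E_R1 - E_C1) and E_R2 share no node.  ``site_gains``
    multiplies each site's fields (the cohort generator's per-individual
    variability hook).  Deterministic given (sheet, spec, gains); ``seed``
    is accepted for interface symmetry with the cohort generator.
    """
    del seed  # construction is deterministic; cohorts randomise via site_gains
    c1, c2 = spec.site_centres
    central1, surround1 = _site_pattern(sheet, np.asarray(c1, float), spec)
    central2, surround2 = _site_pattern(sheet, np.asarray(c2, float), spec)

    site1 = surround1 + central1          # = E_R1 - E_C1
    site2 = surround2 + central2
    p1 = float(np.einsum("ij,ij->", site1, site1))
    p2 = float(np.einsum("ij,ij->", site2, site2))
    if p2 > 0:
        site2 *= np.sqrt(spec.amplitude_ratio * p1 / p2)

    if spec.mode == "separated":
        unit = sheet.node_coords / np.linalg.norm(sheet.node_coords, axis=1, keepdims=True)
        separation = float(np.arccos(np.clip(np.asarray(c1) @ np.asarray(c2), -1, 1)))
        trunc = 0.45 * separation
        central1 = np.where((_angles_to(unit, c1) < trunc)[:, None], central1, 0.0)
        surround1 = np.where((_angles_to(unit, c1) < trunc)[:, None], surround1, 0.0)
        site2 = np.where((_angles_to(unit, c2) < trunc)[:, None], site2, 0.0)
        site1 = surround1 + central1
        both = (np.abs(site1).sum(axis=1) > 0) & (np.abs(site2).sum(axis=1) > 0)
        assert not both.any(), "separated mode produced overlapping supports"

    g1, g2 = site_gains
    return BasisFieldSet(
        e_r1=g1 * surround1,
        e_c1=-g1 * central1,
        e_r2=g2 * site2,
        montage_id=spec.montage_id,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _jitter_direction(rng: np.random.Generator, centre: np.ndarray, sigma: float) -> np.ndarray:
    """Displace a unit vector by a 2-D Gaussian step in its tangent plane."""
    dx, dy = rng.normal(0.0, sigma, size=2)
    rho = np.hypot(dx, dy)
    if rho == 0 or sigma == 0:
        return centre
    ref = np.array([0.0, 0.0, 1.0])
    if abs(centre @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(centre, ref)
    u /= np.linalg.norm(u)
    v = np.cross(centre, u)
    step = (dx * u + dy * v) / rho
    return np.cos(rho) * centre + np.sin(rho) * step


def make_cohort(
    montage_specs: list[SyntheticMontageSpec] | None = None,
    cohort: SyntheticCohort | None = None,
    radius: float = DEFAULT_RADIUS_MM,
    subdivisions: int = DEFAULT_SUBDIVISIONS,
    cap_radius: float = DEFAULT_CAP_RADIUS,
    band_radius: float = DEFAULT_BAND_RADIUS,
) -> list[Individual]:
    """Generate a cohort of individuals with per-montage basis fields.

    Per individual, both site centres are jittered on the sphere and each
    site receives a lognormal amplitude gain; the same jittered anatomy is
    shared by all candidate montages of that individual, mirroring how a
    real cohort holds anatomy fixed while montages vary.  All randomness
    comes from one generator seeded by ``cohort.seed``.
    """
    montage_specs = montage_specs if montage_specs is not None else default_montages()
    cohort = cohort or SyntheticCohort()
    rng = np.random.default_rng(cohort.seed)
    base_c1, base_c2 = montage_specs[0].site_centres

    individuals = []
    for i in range(cohort.n_individuals):
        c1 = _jitter_direction(rng, np.asarray(base_c1, float), cohort.site_jitter_sigma)
        c2 = _jitter_direction(rng, np.asarray(base_c2, float), cohort.site_jitter_sigma)
        gains = tuple(np.exp(rng.normal(0.0, cohort.amplitude_sigma, size=2)))
        ind_id = f"sub{i + 1:03d}"
        sheet = make_sphere_sheet(
            radius, subdivisions,
            spec=replace(montage_specs[0], site_centres=(c1, c2)),
            cap_radius=cap_radius, band_radius=band_radius,
        )
        basis_map = {}
        for spec in montage_specs:
            ind_spec = replace(spec, site_centres=(c1, c2))
            basis = make_basis_fields(sheet, ind_spec, site_gains=gains)
            basis.individual_id = ind_id
            basis_map[spec.montage_id] = basis
        individuals.append(Individual(ind_id, sheet, basis_map))
    return individuals
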