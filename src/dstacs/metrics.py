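"""Phase-lag-dependent E-field metrics on the cortical sheet.

Five metric families characterise how the dual-site field at a nonzero phase
lag differs from the zero-lag reference, per region set:

* **peak_magnitude** — the maximum field magnitude over nodes and time steps
  (V/m), a standard dose measure.
* **peak_normal** — the maximum absolute cortex-normal component (V/m), the
  "effective" dose along pyramidal dendrites; the inward peak is reported
  alongside.
* **rdm** — the relative difference measure between the normalised absolute
  normal-component distributions at lag 0 and lag phi, per time step,
  averaged over the cycle.  0 means identical spatial distributions.
* **dotp / delta_dotp** — the cosine similarity between the signed
  normal-component vectors of the two conditions (per step, averaged), and
  its absolute deviation from the value that perfectly separated two-site
  fields would give.
* **effective_area** — the target-region area (mm²) where the absolute
  normal component reaches at least half the reference-region peak, per
  step, averaged.

All comparison metrics operate on per-node normal-component series after the
two-sided threshold cleanup; region sets follow the sheet's labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import CorticalSheet, normal_component
from .superposition import (
    BasisFieldSet,
    TimeResolvedField,
    default_phase_lags,
    make_time_grid,
    superpose,
)
from .thresholding import (
    DEFAULT_FLOOR_FRACTION,
    DEFAULT_PERCENTILE,
    ThresholdMask,
    threshold_mask,
)

__all__ = [
    "peak_magnitude",
    "peak_normal_component",
    "rdm",
    "dotp",
    "ideal_dotp",
    "delta_dotp",
    "effective_area",
    "analyze_montage",
    "analyze_cohort",
]

#: steps whose vector norm falls below this fraction of the series' largest
#: step norm are dropped from normalised (rdm / dotp) averages
DEGENERATE_STEP_TOL = 1e-8

METRIC_UNITS = {
    "peak_magnitude": "V/m",
    "peak_normal": "V/m",
    "peak_normal_inward": "V/m",
    "rdm": "",
    "dotp": "",
    "ideal_dotp": "",
    "delta_dotp": "",
    "effective_area": "mm^2",
}


# ---------------------------------------------------------------------------
# low-level metric operations
# ---------------------------------------------------------------------------

def _masked_region_values(values: np.ndarray, mask: ThresholdMask, region_nodes: np.ndarray):
    """(T, K) values over the kept region nodes, with zeroed nodes at 0."""
    kept = region_nodes & mask.kept
    if not kept.any():
        raise ValueError("region is empty after threshold masking")
    out = np.array(values[:, kept], dtype=float)
    out[:, mask.zeroed[kept]] = 0.0
    return out


def peak_magnitude(
    field: TimeResolvedField, mask: ThresholdMask, region_nodes: np.ndarray
) -> float:
    """Maximum field magnitude over kept region nodes and all time steps (V/m)."""
    return float(_masked_region_values(field.magnitudes, mask, region_nodes).max())


def peak_normal_component(
    field: TimeResolvedField,
    normals: np.ndarray,
    mask: ThresholdMask,
    region_nodes: np.ndarray,
) -> tuple[float, float]:
    """Peak absolute and peak inward normal component (V/m).

    The inward peak is the maximum of the negated signed component (normals
    point outward, so inward-directed fields have negative components).
    """
    comp = normal_component(field.vectors, normals)
    vals = _masked_region_values(comp, mask, region_nodes)
    return float(np.abs(vals).max()), float((-vals).max())


def _validate_pair(series_zero: np.ndarray, series_phi: np.ndarray):
    s0 = np.asarray(series_zero, dtype=float)
    s1 = np.asarray(series_phi, dtype=float)
    if s0.ndim == 1:
        s0 = s0[None, :]
    if s1.ndim == 1:
        s1 = s1[None, :]
    if s0.shape != s1.shape:
        raise ValueError(f"series shapes differ: {s0.shape} vs {s1.shape}")
    return s0, s1


def _nondegenerate_steps(s0: np.ndarray, s1: np.ndarray) -> np.ndarray:
    n0 = np.linalg.norm(s0, axis=1)
    n1 = np.linalg.norm(s1, axis=1)
    keep = (n0 >= DEGENERATE_STEP_TOL * n0.max(initial=0.0)) & (
        n1 >= DEGENERATE_STEP_TOL * n1.max(initial=0.0)
    ) & (n0 > 0) & (n1 > 0)
    if not keep.any():
        raise ValueError("all time steps are degenerate (zero-norm series)")
    return keep


def rdm(series_zero: np.ndarray, series_phi: np.ndarray, mode: str = "timewise") -> float:
    """Relative difference measure between two normal-component series.

    ``timewise`` (the literal per-step definition): at each non-degenerate
    step, take the element-wise absolute values of both spatial vectors,
    normalise each to unit Euclidean norm, and measure the Euclidean norm of
    their difference; average over retained steps.  ``envelope`` applies the
    same formula once to the per-node cycle envelopes of the absolute normal
    component, which is insensitive to pure within-cycle timing shifts.

    Identical distributions give 0; series with disjoint spatial supports
    give sqrt(2) (two orthogonal non-negative unit vectors).
    """
    s0, s1 = _validate_pair(series_zero, series_phi)
    if mode == "timewise":
        keep = _nondegenerate_steps(s0, s1)
        a = np.abs(s0[keep])
        b = np.abs(s1[keep])
        a = a / np.linalg.norm(a, axis=1, keepdims=True)
        b = b / np.linalg.norm(b, axis=1, keepdims=True)
        return float(np.linalg.norm(a - b, axis=1).mean())
    if mode == "envelope":
        e0 = np.abs(s0).max(axis=0)
        e1 = np.abs(s1).max(axis=0)
        n0 = np.linalg.norm(e0)
        n1 = np.linalg.norm(e1)
        if n0 == 0 or n1 == 0:
            raise ValueError("zero envelope: rdm undefined")
        return float(np.linalg.norm(e0 / n0 - e1 / n1))
    raise ValueError(f"unknown rdm mode {mode!r}; expected 'timewise' or 'envelope'")


def dotp(series_zero: np.ndarray, series_phi: np.ndarray) -> float:
    """Cosine similarity of the signed normal-component vectors, per
    non-degenerate time step, averaged over retained steps.  1 means the two
    conditions share the field direction at every node; -1 means globally
    opposite direction.
    """
    s0, s1 = _validate_pair(series_zero, series_phi)
    keep = _nondegenerate_steps(s0, s1)
    s0, s1 = s0[keep], s1[keep]
    num = np.einsum("ij,ij->i", s0, s1)
    den = np.linalg.norm(s0, axis=1) * np.linalg.norm(s1, axis=1)
    return float(np.clip(num / den, -1.0, 1.0).mean())


def ideal_dotp(
    site_powers: tuple[float, float],
    phase_lag: float,
    times: np.ndarray,
    f: float | None = None,
) -> float:
    """DotP that *perfectly separated* two-site fields would produce.

    Two disjoint single-node "sites" are built whose squared normal-component
    powers match the montage: P1 drives the lag-fixed site, P2 the
    lag-shifted one.  Running the actual superposition and DotP machinery on
    them yields the idealised reference value; the observed DotP of a real
    montage deviates from it exactly insofar as the two fields overlap in
    space.
    """
    p1, p2 = site_powers
    if p1 < 0 or p2 < 0:
        raise ValueError("site powers must be non-negative")
    if p1 + p2 == 0:
        raise ValueError("at least one site power must be positive")
    if f is None:
        from .superposition import DEFAULT_FREQUENCY_HZ

        f = DEFAULT_FREQUENCY_HZ
    zero = np.zeros(3)
    basis = BasisFieldSet(
        e_r1=np.array([[np.sqrt(p1), 0.0, 0.0], zero]),
        e_c1=np.zeros((2, 3)),
        e_r2=np.array([zero, [np.sqrt(p2), 0.0, 0.0]]),
        io_amp=1.0,
        f=f,
    )
    normals = np.tile([1.0, 0.0, 0.0], (2, 1))
    s_ref = normal_component(superpose(basis, 0.0, times).vectors, normals)
    s_phi = normal_component(superpose(basis, phase_lag, times).vectors, normals)
    return dotp(s_ref, s_phi)


def delta_dotp(observed: float, ideal: float) -> float:
    """Absolute deviation of the observed DotP from the ideal one."""
    return abs(float(ideal) - float(observed))


def effective_area(
    series: np.ndarray,
    target_nodes: np.ndarray,
    node_areas: np.ndarray,
    frac: float = 0.5,
) -> float:
    """Effective area of stimulation (mm²).

    ``series`` holds the (masked) normal components over the *reference* node
    set (surrounding grey matter plus both targets); ``target_nodes`` marks
    the target's nodes within that set.  Per time step, the area of target
    nodes whose absolute component reaches at least ``frac`` of the
    reference-set peak is summed; the result is the average over all steps.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[None, :]
    target_nodes = np.asarray(target_nodes, dtype=bool)
    node_areas = np.asarray(node_areas, dtype=float)
    if series.shape[1] == 0:
        raise ValueError("empty reference node set")
    if series.shape[1] != target_nodes.shape[0] or series.shape[1] != node_areas.shape[0]:
        raise ValueError("series, target_nodes and node_areas must share the node axis")
    abs_comp = np.abs(series)
    peak_t = abs_comp.max(axis=1, keepdims=True)          # reference peak per step
    hot = abs_comp >= frac * peak_t
    areas_t = (hot[:, target_nodes] * node_areas[target_nodes]).sum(axis=1)
    return float(areas_t.mean())


# ---------------------------------------------------------------------------
# per-montage analysis driver
# ---------------------------------------------------------------------------

def _record(basis: BasisFieldSet, lag: float, region: str, metric: str, value: float) -> dict:
    return {
        "individual_id": basis.individual_id,
        "montage_id": basis.montage_id,
        "phase_lag": float(lag),
        "region_set": region,
        "metric": metric,
        "value": float(value),
        "units": METRIC_UNITS[metric],
    }


def analyze_montage(
    sheet: CorticalSheet,
    basis: BasisFieldSet,
    phase_lags: np.ndarray | None = None,
    n_steps: int = 24,
    rdm_mode: str = "timewise",
    pct: float = DEFAULT_PERCENTILE,
    floor_frac: float = DEFAULT_FLOOR_FRACTION,
) -> pd.DataFrame:
    """All metric families for one (individual, montage) across phase lags.

    Returns a tidy table with one row per (phase_lag, region_set, metric).
    Comparison metrics (rdm, dotp, delta_dotp) relate each lag to the
    zero-lag reference over the intersection of the two conditions' kept
    node sets, with the zeroing floors of both conditions applied; peak and
    area metrics use each condition's own mask.  Thresholds are taken over
    all mesh nodes, one mask per condition per scalar family (magnitude and
    absolute normal component).
    """
    if rdm_mode not in ("timewise", "envelope"):
        raise ValueError(f"unknown rdm mode {rdm_mode!r}")
    if phase_lags is None:
        phase_lags = default_phase_lags()
    phase_lags = np.asarray(phase_lags, dtype=float)
    times = make_time_grid(n_steps, basis.f)

    lags = phase_lags if np.isclose(phase_lags, 0.0).any() else np.concatenate([[0.0], phase_lags])
    fields: dict[float, TimeResolvedField] = {}
    ncomp: dict[float, np.ndarray] = {}
    masks_mag: dict[float, ThresholdMask] = {}
    masks_n: dict[float, ThresholdMask] = {}
    for lag in lags:
        fld = superpose(basis, lag, times)
        comp = normal_component(fld.vectors, sheet.normals)
        fields[lag] = fld
        ncomp[lag] = comp
        masks_mag[lag] = threshold_mask(fld.magnitudes.max(axis=0), pct, floor_frac)
        masks_n[lag] = threshold_mask(np.abs(comp).max(axis=0), pct, floor_frac)

    m1s = sheet.nodes_in("M1_left", "M1_right")
    surrounding = sheet.nodes_in("surrounding")
    regions = {"M1s": m1s, "surrounding": surrounding}
    reference_nodes = m1s | surrounding

    # normal-component patterns of the two sites, for the ideal-DotP powers
    site1_comp = normal_component(basis.site1_pattern, sheet.normals)
    site2_comp = normal_component(basis.site2_pattern, sheet.normals)

    rows: list[dict] = []
    for lag in phase_lags:
        for region_name, region in regions.items():
            rows.append(
                _record(basis, lag, region_name, "peak_magnitude",
                        peak_magnitude(fields[lag], masks_mag[lag], region))
            )
            abs_peak, inward_peak = peak_normal_component(
                fields[lag], sheet.normals, masks_n[lag], region
            )
            rows.append(_record(basis, lag, region_name, "peak_normal", abs_peak))
            rows.append(_record(basis, lag, region_name, "peak_normal_inward", inward_peak))

            # comparison against the zero-lag reference on the shared node set
            shared = region & masks_n[0.0].kept & masks_n[lag].kept
            if not shared.any():
                raise ValueError(f"region {region_name!r} empty after masking")
            floor = masks_n[0.0].zeroed | masks_n[lag].zeroed
            s0 = np.array(ncomp[0.0][:, shared])
            s1 = np.array(ncomp[lag][:, shared])
            s0[:, floor[shared]] = 0.0
            s1[:, floor[shared]] = 0.0
            rdm_val = rdm(s0, s1, mode=rdm_mode)
            dotp_val = dotp(s0, s1)
            a1 = np.where(floor[shared], 0.0, site1_comp[shared])
            a2 = np.where(floor[shared], 0.0, site2_comp[shared])
            ideal = ideal_dotp((float(a1 @ a1), float(a2 @ a2)), lag, times, f=basis.f)
            rows.append(_record(basis, lag, region_name, "rdm", rdm_val))
            rows.append(_record(basis, lag, region_name, "dotp", dotp_val))
            rows.append(_record(basis, lag, region_name, "ideal_dotp", ideal))
            rows.append(
                _record(basis, lag, region_name, "delta_dotp", delta_dotp(dotp_val, ideal))
            )

        # effective area per target, against the whole reference sheet's peak
        ref = reference_nodes & masks_n[lag].kept
        if not ref.any():
            raise ValueError("reference node set empty after masking")
        series = np.array(ncomp[lag][:, ref])
        series[:, masks_n[lag].zeroed[ref]] = 0.0
        for target_name in ("M1_left", "M1_right"):
            target = sheet.nodes_in(target_name)[ref]
            rows.append(
                _record(basis, lag, target_name, "effective_area",
                        effective_area(series, target, sheet.node_areas[ref]))
            )

    return pd.DataFrame(rows)


def analyze_cohort(
    individuals,
    phase_lags: np.ndarray | None = None,
    n_steps: int = 24,
    rdm_mode: str = "timewise",
    pct: float = DEFAULT_PERCENTILE,
    floor_frac: float = DEFAULT_FLOOR_FRACTION,
) -> pd.DataFrame:
    """Concatenate :func:`analyze_montage` over a cohort.

    ``individuals`` is an iterable of objects with ``sheet`` and
    ``basis_by_montage`` attributes (as produced by the synthetic-data
    module) or of ``(sheet, {montage_id: basis})`` pairs.
    """
    tables = []
    for ind in individuals:
        if hasattr(ind, "sheet"):
            sheet, basis_map = ind.sheet, ind.basis_by_montage
        else:
            sheet, basis_map = ind
        for basis in basis_map.values():
            tables.append(
                analyze_montage(
                    sheet, basis, phase_lags=phase_lags, n_steps=n_steps,
                    rdm_mode=rdm_mode, pct=pct, floor_frac=floor_frac,
                )
            )
    return pd.concat(tables, ignore_index=True)
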