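"""Circular statistics and variability summaries for phase-lag metrics.

Whether a metric is modulated by the phase lag is a question about a
function on the circle: the eight lags sample one full cycle, so a metric
that ignores the lag is uniform over angles once each observation is
weighted by its metric value.  This is tested with a weighted
Hermans-Rasson statistic whose null distribution is generated by permuting
the phase-lag labels within each individual, which preserves every
individual's value multiset and therefore all between-individual structure.
Because significance comes from the permutation null, the test's type-I
error control does not depend on the particular kernel.

Inter-individual variability is summarised by the coefficient of variation
(CV = SD / mean * 100%), computed across individuals per phase lag and then
averaged over lags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "whr_statistic",
    "phase_modulation_test",
    "holm_correct",
    "coefficient_of_variation",
    "cv_by_montage",
]

#: constant of the second-form Hermans-Rasson kernel
_HR_CONSTANT = 2.895


@dataclass
class TestResult:
    """Outcome of one permutation test of phase-lag modulation."""

    metric: str
    montage_id: str
    region_set: str
    statistic: float
    p_raw: float
    p_adjusted: float | None
    n_permutations: int
    seed: int


def _hr_kernel(delta: np.ndarray) -> np.ndarray:
    """Hermans-Rasson (second form) pair kernel at angle differences (rad).

    k(d) = |pi - |d|| - pi/2 - 2.895*(|sin d| - 2/pi).  Even and
    2*pi-periodic, so the statistic depends only on angle differences and
    is invariant under common rotation of all angles.  The subtracted
    |sin| term is what gives the test omnibus power: both synphase
    (differences near 0) and antiphase (differences near pi) weight
    concentrations raise the statistic, which matters here because every
    phase-lag profile of a sinusoidal superposition is symmetric about pi.
    """
    delta = np.abs(np.asarray(delta, dtype=float))
    return (
        np.abs(np.pi - delta) - np.pi / 2.0
        - _HR_CONSTANT * (np.abs(np.sin(delta)) - 2.0 / np.pi)
    )


def _minmax_weights(values: np.ndarray) -> np.ndarray:
    """Min-max scale metric values to [0, 1]; constant values map to 1."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def whr_statistic(angles: np.ndarray, weights: np.ndarray) -> float:
    """Weighted Hermans-Rasson statistic over all observation pairs.

    T = sum_ij w_i w_j k(theta_i - theta_j) with the second-form kernel.
    Larger T indicates a less uniform weighted angular distribution.  The
    weights are the (pre-scaled) metric values; scaling is the caller's
    responsibility so that permutation nulls reuse a fixed scaling.
    """
    angles = np.asarray(angles, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if angles.shape != weights.shape or angles.ndim != 1:
        raise ValueError("angles and weights must be equal-length 1-D arrays")
    if angles.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if not np.isfinite(weights).all():
        raise ValueError("weights must be finite")
    kernel = _hr_kernel(angles[:, None] - angles[None, :])
    return float(weights @ kernel @ weights)


def phase_modulation_test(
    records: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    value_col: str = "value",
) -> TestResult:
    """Permutation test of phase-lag modulation for one (metric, montage,
    region set).

    ``records`` must contain every (individual, phase lag) cell exactly once,
    with columns ``individual_id``, ``phase_lag`` and ``value_col``.  Metric
    values are min-max scaled to [0, 1] (once, over the whole table) and used
    as weights of the Hermans-Rasson statistic at the phase-lag angles.  The
    null is generated by permuting phase-lag labels independently within each
    individual;  p = (1 + #{T_perm >= T_obs}) / (1 + n_perm), which is a
    valid p-value at any finite number of permutations.
    """
    required = {"individual_id", "phase_lag", value_col}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values are very coarse",
                      RuntimeWarning, stacklevel=2)
    pivot = records.pivot_table(
        index="individual_id", columns="phase_lag", values=value_col, aggfunc="first"
    )
    if pivot.isna().any().any():
        raise ValueError("missing (individual, phase_lag) cells")
    counts = records.groupby(["individual_id", "phase_lag"]).size()
    if (counts != 1).any():
        raise ValueError("duplicate (individual, phase_lag) cells")

    values = pivot.to_numpy()                     # (n_ind, n_lags)
    angles = pivot.columns.to_numpy(dtype=float)  # (n_lags,)
    n_ind, n_lags = values.shape
    weights = _minmax_weights(values.ravel()).reshape(n_ind, n_lags)

    # T = s K s with s the per-lag column sums of the weights, because the
    # kernel depends on the lag slots only; permuting labels within an
    # individual permutes that row of the weight matrix
    kernel = _hr_kernel(angles[:, None] - angles[None, :])
    s_obs = weights.sum(axis=0)
    t_obs = float(s_obs @ kernel @ s_obs)

    rng = np.random.default_rng(seed)
    perm_w = rng.permuted(
        np.broadcast_to(weights, (n_perm, n_ind, n_lags)).copy(), axis=2
    )
    # each permuted row keeps its individual's weight multiset
    assert np.allclose(np.sort(perm_w, axis=2), np.sort(weights, axis=1)[None])
    s_perm = perm_w.sum(axis=1)                   # (n_perm, n_lags)
    t_perm = np.einsum("pl,lm,pm->p", s_perm, kernel, s_perm)

    n_ge = int((t_perm >= t_obs - 1e-12 * max(1.0, abs(t_obs))).sum())
    p_raw = (1 + n_ge) / (1 + n_perm)
    meta = records.iloc[0]
    return TestResult(
        metric=str(meta.get("metric", "")),
        montage_id=str(meta.get("montage_id", "")),
        region_set=str(meta.get("region_set", "")),
        statistic=t_obs,
        p_raw=float(p_raw),
        p_adjusted=None,
        n_permutations=int(n_perm),
        seed=int(seed),
    )


def holm_correct(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment, capped at 1, monotone."""
    p_values = np.asarray(list(p_values), dtype=float)
    if p_values.size == 0:
        return p_values
    if ((p_values <= 0) | (p_values > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p_values, method="holm")[1]


def coefficient_of_variation(values) -> float:
    """CV = sample SD / mean * 100%, across individuals.

    Uses the n-1 denominator for the standard deviation.  Undefined (error)
    for a zero mean.
    """
    values = np.asarray(list(values), dtype=float)
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    return float(sd / mean * 100.0)


def cv_by_montage(
    records: pd.DataFrame, metric: str, region_set: str, value_col: str = "value"
) -> pd.Series:
    """Across-individual CV per montage, averaged over phase lags.

    For each (montage, phase lag), the CV is taken across individuals; the
    per-montage value is the mean of those CVs over all lags present.
    """
    sub = records[(records["metric"] == metric) & (records["region_set"] == region_set)]
    if sub.empty:
        raise ValueError(f"no records for metric={metric!r}, region_set={region_set!r}")
    per_lag = sub.groupby(["montage_id", "phase_lag"])[value_col].apply(
        coefficient_of_variation
    )
    return per_lag.groupby("montage_id").mean()
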