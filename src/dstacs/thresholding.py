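"""Two-sided field-value cleanup applied before metric computation.

Finite-element fields carry numerical artefacts at both extremes: a handful
of nodes with implausibly large values (singular corners, thin tissue) and a
broad fringe of negligible values whose direction is unreliable and which are
physiologically irrelevant.  Both are removed before metrics are computed:

* nodes whose value exceeds the 99.9th percentile are *excluded* — dropped
  from every subsequent metric node set;
* nodes whose value falls below 2% of that percentile are *zeroed* — the
  field value is replaced by zero but the node stays in the set (its area
  still counts in area-normalised metrics).

One mask is computed per condition from the time envelope of the relevant
scalar (field magnitude for magnitude metrics, absolute normal component for
normal-component metrics), so the node support of a metric does not flicker
across time steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ThresholdMask", "threshold_mask", "apply_mask"]

DEFAULT_PERCENTILE = 99.9
DEFAULT_FLOOR_FRACTION = 0.02


@dataclass
class ThresholdMask:
    """Outcome of the two-sided cleanup on one per-node scalar.

    ``excluded`` and ``zeroed`` are disjoint boolean node masks; ``upper`` is
    the percentile cut (V/m) and ``lower`` the zeroing floor (V/m).
    """

    excluded: np.ndarray
    zeroed: np.ndarray
    upper: float
    lower: float

    @property
    def kept(self) -> np.ndarray:
        """Nodes that survive exclusion (zeroed nodes are kept)."""
        return ~self.excluded

    def summary(self) -> dict[str, float | int]:
        return {
            "n_excluded": int(self.excluded.sum()),
            "n_zeroed": int(self.zeroed.sum()),
            "upper": float(self.upper),
            "lower": float(self.lower),
        }


def threshold_mask(
    values: np.ndarray,
    pct: float = DEFAULT_PERCENTILE,
    floor_frac: float = DEFAULT_FLOOR_FRACTION,
) -> ThresholdMask:
    """Two-sided mask from non-negative per-node values.

    ``upper`` is the linear-interpolation percentile of ``values`` at ``pct``;
    values strictly above it are excluded, values strictly below
    ``floor_frac * upper`` are zeroed.  The mask is scale invariant: scaling
    all values by a positive constant yields the same node sets.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be a per-node 1-D array")
    if values.shape[0] < 10:
        raise ValueError("need at least 10 nodes for a stable percentile")
    if (values < 0).any():
        raise ValueError("values must be non-negative (magnitudes or |components|)")

    upper = float(np.percentile(values, pct))  # linear interpolation between order stats
    if upper == 0.0:
        warnings.warn("all-zero input: empty threshold mask", RuntimeWarning, stacklevel=2)
        n = values.shape[0]
        return ThresholdMask(
            excluded=np.zeros(n, dtype=bool),
            zeroed=np.zeros(n, dtype=bool),
            upper=0.0,
            lower=0.0,
        )
    lower = floor_frac * upper
    excluded = values > upper
    zeroed = (values < lower) & ~excluded
    return ThresholdMask(excluded=excluded, zeroed=zeroed, upper=upper, lower=lower)


def apply_mask(series: np.ndarray, mask: ThresholdMask) -> np.ndarray:
    """Zero out the zeroed nodes of a ``(T, N)`` or ``(N,)`` series.

    Exclusion is a node-set operation and is applied by the caller when
    selecting metric node sets; this helper only applies the floor.
    """
    series = np.array(series, dtype=float, copy=True)
    series[..., mask.zeroed] = 0.0
    return series
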