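"""Per-individual montage selection and group-level summaries.

No single electrode montage is optimal for every individual: head anatomy
shifts where the two sites' fields overlap, so the montage that best
preserves the intended field direction or spatial distribution differs
between individuals.  Given a metric table over a set of candidate montages,
this module picks the best montage per individual for a chosen objective and
quantifies the gain over the best single fixed montage, in both the mean of
the objective and its inter-individual variability (CV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import coefficient_of_variation

__all__ = ["Objective", "MontageSelection", "IndividualizationSummary",
           "select_best_montage", "individualized_summary"]

#: metrics for which the zero-lag row is a trivial self-comparison and is
#: excluded from the phase-lag average used for selection
_SELF_COMPARISON_METRICS = {"rdm", "dotp", "delta_dotp"}


@dataclass(frozen=True)
class Objective:
    """What to optimise: a metric name, a direction and a region set.

    ``aggregate`` controls how the per-lag values of one (individual,
    montage) are collapsed before comparison: ``"mean"`` (default) or
    ``"worst"`` (the least favourable lag).
    """

    metric: str
    direction: str = "minimize"   # or "maximize"
    region_set: str = "M1s"
    aggregate: str = "mean"

    def __post_init__(self):
        if self.direction not in ("minimize", "maximize"):
            raise ValueError("direction must be 'minimize' or 'maximize'")
        if self.aggregate not in ("mean", "worst"):
            raise ValueError("aggregate must be 'mean' or 'worst'")


@dataclass
class MontageSelection:
    """Chosen montage per individual for one objective."""

    chosen: dict[str, str]
    objective: Objective
    candidates: tuple[str, ...]
    per_individual_value: dict[str, float] = field(default_factory=dict)

    def fraction_choosing(self, montage_id: str) -> float:
        """Fraction of individuals (in %) whose best montage is ``montage_id``."""
        if not self.chosen:
            return 0.0
        n = sum(1 for m in self.chosen.values() if m == montage_id)
        return 100.0 * n / len(self.chosen)


@dataclass
class IndividualizationSummary:
    """Fixed-best versus individualized comparison for one objective."""

    best_fixed_montage: str
    mean_fixed_best: float
    mean_individualized: float
    cv_fixed_best: float
    cv_individualized: float


def _aggregated(records: pd.DataFrame, objective: Objective, candidates) -> pd.DataFrame:
    """(individual x montage) table of lag-aggregated objective values."""
    sub = records[
        (records["metric"] == objective.metric)
        & (records["region_set"] == objective.region_set)
        & (records["montage_id"].isin(candidates))
    ]
    if objective.metric in _SELF_COMPARISON_METRICS:
        sub = sub[~np.isclose(sub["phase_lag"], 0.0)]
    if sub.empty:
        raise ValueError(f"no records match objective {objective}")
    if objective.aggregate == "mean":
        agg = sub.groupby(["individual_id", "montage_id"])["value"].mean()
    else:  # worst case across lags
        fn = "max" if objective.direction == "minimize" else "min"
        agg = sub.groupby(["individual_id", "montage_id"])["value"].agg(fn)
    table = agg.unstack("montage_id")
    missing = table.columns.symmetric_difference(pd.Index(candidates))
    if len(missing) or table.isna().any().any():
        raise ValueError(f"missing (individual, montage) cells for {sorted(missing)}")
    return table[sorted(candidates)]  # lexicographic column order fixes ties


def select_best_montage(
    records: pd.DataFrame, objective: Objective, candidates
) -> MontageSelection:
    """Best candidate montage per individual for the objective.

    The per-(individual, montage) score is the objective metric aggregated
    over phase lags (the trivial zero-lag self-comparison is excluded for
    rdm / dotp / delta_dotp).  Ties break deterministically toward the
    lexicographically first montage id.
    """
    candidates = tuple(candidates)
    table = _aggregated(records, objective, candidates)
    best = table.idxmin(axis=1) if objective.direction == "minimize" else table.idxmax(axis=1)
    chosen = {str(i): str(m) for i, m in best.items()}
    per_val = {str(i): float(table.loc[i, m]) for i, m in best.items()}
    return MontageSelection(
        chosen=chosen, objective=objective, candidates=candidates,
        per_individual_value=per_val,
    )


def individualized_summary(
    records: pd.DataFrame, selection: MontageSelection, objective: Objective | None = None
) -> IndividualizationSummary:
    """Compare the best fixed montage against per-individual selection.

    The fixed reference is the candidate with the best population-average
    aggregated objective.  Means are averages of the aggregated objective
    across individuals; CVs are computed across individuals per phase lag
    and averaged over lags, using each individual's montage (selected or
    fixed).  Individualized means can never be worse than the fixed-best
    mean, because the per-individual optimum is a pointwise bound.
    """
    objective = objective or selection.objective
    table = _aggregated(records, objective, selection.candidates)
    col_means = table.mean(axis=0)
    best_fixed = (
        col_means.idxmin() if objective.direction == "minimize" else col_means.idxmax()
    )
    mean_fixed = float(col_means[best_fixed])
    per_ind = pd.Series(selection.per_individual_value)
    mean_ind = float(per_ind.mean())

    sub = records[
        (records["metric"] == objective.metric)
        & (records["region_set"] == objective.region_set)
    ]
    if objective.metric in _SELF_COMPARISON_METRICS:
        sub = sub[~np.isclose(sub["phase_lag"], 0.0)]

    def _cv(values) -> float:
        # all-identical values (e.g. exact zeros of a self-comparison) have
        # no variability; the strict CV is undefined there because of the
        # zero mean
        if np.ptp(np.asarray(list(values), dtype=float)) == 0:
            return 0.0
        return coefficient_of_variation(values)

    def _cv_over_lags(montage_of) -> float:
        rows = sub[[montage_of(i) == m for i, m in
                    zip(sub["individual_id"], sub["montage_id"])]]
        per_lag = rows.groupby("phase_lag")["value"].apply(_cv)
        return float(per_lag.mean())

    cv_fixed = _cv_over_lags(lambda i: best_fixed)
    cv_ind = _cv_over_lags(lambda i: selection.chosen[str(i)])
    return IndividualizationSummary(
        best_fixed_montage=str(best_fixed),
        mean_fixed_best=mean_fixed,
        mean_individualized=mean_ind,
        cv_fixed_best=cv_fixed,
        cv_individualized=cv_ind,
    )
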