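"""One-way ANOVA discrimination of endpoints across CTCAE grades.

Two groupings are analysed: the intermediate-grade comparisons
({2,3,4}, {2,3}, {3,4}, {2,4}) that probe whether an endpoint can tell
neighbouring toxicity grades apart, and the binary clinical split into
radioresistant (grades 0-2) vs radiosensitive (grades 3-5) patients.
Observations are per-cell-line endpoint means; records missing the
endpoint are dropped per comparison (their count is reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .cohort import Cohort, patmmax
from .exceptions import DegenerateDataError, InsufficientDataError

__all__ = [
    "ENDPOINTS",
    "GRADE_COMPARISONS",
    "DiscriminationReport",
    "one_way_anova",
    "grade_discrimination",
    "binary_discrimination",
]

ENDPOINTS = ("sf2", "mn_24h", "h2ax_24h", "patmmax")

GRADE_COMPARISONS: Tuple[Tuple[int, ...], ...] = (
    (2, 3, 4), (2, 3), (3, 4), (2, 4),
)

#: smallest reportable p-value, used when within-group variance vanishes
#: while group means differ (perfect separation)
_P_FLOOR = np.finfo(float).tiny


@dataclass
class DiscriminationReport:
    """F statistics and p-values for one endpoint across grade comparisons."""

    endpoint: str
    comparisons: Dict[str, float] = field(default_factory=dict)   # label -> p
    f_statistics: Dict[str, float] = field(default_factory=dict)  # label -> F
    group_sizes: Dict[str, List[int]] = field(default_factory=dict)
    n_dropped: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "p_values": dict(self.comparisons),
            "f_statistics": dict(self.f_statistics),
            "group_sizes": dict(self.group_sizes),
            "n_dropped_missing": dict(self.n_dropped),
        }


def one_way_anova(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Classical one-way ANOVA: (F statistic, p-value).

    F is the ratio of the between-group to the within-group mean square;
    the p-value is the upper tail of the F(k-1, N-k) distribution.  With
    zero within-group variance but distinct means (perfect separation) F
    is infinite and the p-value collapses to the smallest positive float.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise InsufficientDataError("every group needs >= 2 values")
    values = np.concatenate(arrays)
    if np.ptp(values) == 0:
        raise DegenerateDataError("all values identical across all groups")
    grand = values.mean()
    k = len(arrays)
    n_total = len(values)
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        # distinct group means with zero scatter inside groups: perfect
        # separation (all-identical data were already rejected above)
        return float("inf"), _P_FLOOR
    f_stat = ms_between / ms_within
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), max(p, _P_FLOOR)


def _endpoint_values(cohort: Cohort, endpoint: str, grades: Sequence[int]):
    """Per-grade value lists and the number of records dropped as missing."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; choose from {ENDPOINTS}")
    per_grade: Dict[int, List[float]] = {g: [] for g in grades}
    dropped = 0
    for rec in cohort:
        if rec.ctcae_grade not in per_grade:
            continue
        if endpoint == "patmmax":
            value = (None if rec.patm_10min is None and rec.patm_1h is None
                     else patmmax(rec))
        else:
            value = getattr(rec, endpoint)
        if value is None:
            dropped += 1
            continue
        per_grade[rec.ctcae_grade].append(value)
    return per_grade, dropped


def grade_discrimination(cohort: Cohort, endpoint: str,
                         comparisons: Optional[Tuple[Tuple[int, ...], ...]] = None
                         ) -> DiscriminationReport:
    """ANOVA of one endpoint over the intermediate-grade comparisons."""
    comparisons = comparisons or GRADE_COMPARISONS
    needed = sorted({g for comp in comparisons for g in comp})
    per_grade, dropped = _endpoint_values(cohort, endpoint, needed)
    for grade in needed:
        if len(per_grade[grade]) < 2:
            raise InsufficientDataError(
                f"endpoint {endpoint!r}: grade {grade} has "
                f"{len(per_grade[grade])} usable records (need >= 2)"
            )
    report = DiscriminationReport(endpoint=endpoint)
    for comp in comparisons:
        label = ",".join(map(str, comp))
        f_stat, p = one_way_anova([per_grade[g] for g in comp])
        report.comparisons[label] = p
        report.f_statistics[label] = f_stat
        report.group_sizes[label] = [len(per_grade[g]) for g in comp]
        report.n_dropped[label] = dropped
    return report


def binary_discrimination(cohort: Cohort, endpoint: str) -> Tuple[float, float]:
    """ANOVA under the binary radioresistant (grades 0-2) vs
    radiosensitive (grades 3-5) grouping: returns (F, p)."""
    per_grade, _ = _endpoint_values(cohort, endpoint, list(range(6)))
    resistant = [v for g in (0, 1, 2) for v in per_grade[g]]
    sensitive = [v for g in (3, 4, 5) for v in per_grade[g]]
    if len(resistant) < 2 or len(sensitive) < 2:
        raise InsufficientDataError(
            f"endpoint {endpoint!r}: binary groups have sizes "
            f"{len(resistant)} and {len(sensitive)} (need >= 2 each)"
        )
    return one_way_anova([resistant, sensitive])
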