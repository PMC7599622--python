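"""Per-participant behavioral predictors.

Three session summaries serve as predictors of inattention: the median and
interquartile range (IQR) of the recorded jump distances, and the omission
count.  Each is computed over the whole session and stratified by nominal
IS class (SHORT/MEDIUM/LONG).  Auto-jump (omission) events carry distance
0 by construction; they are excluded from the distance statistics by
default and counted separately, with a flag to include the zeros instead.
Quantiles use linear interpolation between order statistics.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_sim import Cohort
from .errors import DegenerateDataError
from .schedule import ISClass
from .task_engine import SessionLog

__all__ = ["Scope", "MetricsSummary", "summarize", "metrics_table"]


class Scope(str, enum.Enum):
    """Which gaps a summary covers: the whole session or one IS class."""

    ALL = "ALL"
    SHORT = "SHORT"
    MEDIUM = "MEDIUM"
    LONG = "LONG"

    @property
    def is_classes(self) -> tuple[ISClass, ...]:
        if self is Scope.ALL:
            return (ISClass.SHORT, ISClass.MEDIUM, ISClass.LONG)
        return (ISClass(self.value),)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class MetricsSummary:
    """Distance/omission summary of one participant in one scope.

    ``median_distance``/``iqr_distance`` are NaN when the scope contains no
    usable distances (all gaps omitted and omission distances excluded).
    """

    participant_id: str
    scope: Scope
    median_distance: float
    iqr_distance: float
    n_omissions: int
    n_voluntary: int

    @property
    def has_distances(self) -> bool:
        return not math.isnan(self.median_distance)


def summarize(
    log: SessionLog,
    scope: Scope = Scope.ALL,
    include_omission_distances: bool = False,
) -> MetricsSummary:
    """Summarize one session log within a scope.

    Raises :class:`DegenerateDataError` if the scope selects no gaps.
    With zero voluntary jumps (and the flag off) the distance statistics
    are NaN while the omission count is still reported.
    """
    classes = set(scope.is_classes)
    records = [r for r in log.records if r.is_nominal in classes]
    if not records:
        raise DegenerateDataError(
            f"session {log.participant_id}: no gaps in scope {scope.value}"
        )
    n_omissions = sum(r.omission for r in records)
    distances = [r.distance for r in records if r.voluntary]
    n_voluntary = len(distances)
    if include_omission_distances:
        distances = distances + [0.0] * n_omissions
    if distances:
        arr = np.asarray(distances, dtype=float)
        median = float(np.median(arr))
        q1, q3 = np.percentile(arr, [25.0, 75.0])  # linear interpolation
        iqr = float(q3 - q1)
    else:
        median = iqr = float("nan")
    return MetricsSummary(
        participant_id=log.participant_id,
        scope=scope,
        median_distance=median,
        iqr_distance=iqr,
        n_omissions=n_omissions,
        n_voluntary=n_voluntary,
    )


def metrics_table(
    cohort: Cohort, include_omission_distances: bool = False
) -> pd.DataFrame:
    """Per-participant, per-scope predictor table.

    One row per participant per scope (4·n rows), columns
    ``participant_id, scope, median, iqr, omissions, n_voluntary``.
    """
    rows = []
    for profile, log in zip(cohort.profiles, cohort.logs):
        if log is None:
            raise DegenerateDataError(
                f"participant {profile.participant_id} has no session log"
            )
        for scope in Scope:
            s = summarize(log, scope, include_omission_distances)
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "scope": scope.value,
                    "median": s.median_distance,
                    "iqr": s.iqr_distance,
                    "omissions": s.n_omissions,
                    "n_voluntary": s.n_voluntary,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "scope", "median", "iqr", "omissions", "n_voluntary"],
    )
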