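"""Per-subject regime trajectories, transition detection and event alignment.

Per-sample cluster labels are noisy: single-sample excursions to another
cluster are common near regime boundaries.  A regime change is therefore
declared only when a run of at least ``min_run`` consecutive samples carries a
new label; shorter excursions are relabelled to the surrounding regime.  The
transition day is the day of the first sample of the stable new run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44  # mean Gregorian month


@dataclass
class RegimeTrajectory:
    """Ordered (day, raw label, smoothed label) records plus detected transitions."""

    subject_id: str
    days: list[int]
    raw_labels: list
    smoothed_labels: list
    transitions: list[tuple] = field(default_factory=list)  # (from, to, day)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_id,
            "day": self.days,
            "raw_label": self.raw_labels,
            "smoothed_label": self.smoothed_labels,
        })


def _runs(labels) -> list[tuple[int, int]]:
    """(start index, length) of each maximal constant run."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i - start))
            start = i
    return runs


def smooth_and_detect(days, labels, min_run: int = 3, subject_id: str = "") -> RegimeTrajectory:
    """Run-length smoothing and transition detection.

    A new regime starts at the first sample of a run of >= ``min_run``
    consecutive samples with a new label; shorter excursions are relabelled to
    the current regime.  The rule is idempotent, and raising ``min_run`` can
    only remove transitions.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    days = list(days)
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    if len(days) != len(labels):
        raise ValueError("days and labels differ in length")
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("days must be strictly increasing")

    current = labels[0]
    smoothed = []
    transitions: list[tuple] = []
    for start, length in _runs(labels):
        lab = labels[start]
        if lab != current and length >= min_run:
            transitions.append((current, lab, days[start]))
            current = lab
        smoothed.extend([current] * length)
    return RegimeTrajectory(
        subject_id=subject_id, days=days, raw_labels=labels,
        smoothed_labels=smoothed, transitions=transitions,
    )


@dataclass
class TransitionSummary:
    pair: tuple
    n: int
    median_months: float | None
    min_months: float | None
    max_months: float | None
    days: dict[str, int] = field(default_factory=dict)  # subject -> first transition day


def transition_summary(trajectories, pair) -> TransitionSummary:
    """Median/min/max age (months, 30.44 d/month) of the first occurrence of an
    ordered (from, to) transition across subjects."""
    pair = tuple(pair)
    days_by_subject: dict[str, int] = {}
    for traj in trajectories:
        for frm, to, day in traj.transitions:
            if (frm, to) == pair:
                days_by_subject[traj.subject_id] = day
                break
    if not days_by_subject:
        return TransitionSummary(pair=pair, n=0, median_months=None,
                                 min_months=None, max_months=None)
    months = np.array(sorted(days_by_subject.values())) / DAYS_PER_MONTH
    return TransitionSummary(
        pair=pair, n=len(days_by_subject),
        median_months=float(np.median(months)),
        min_months=float(months.min()), max_months=float(months.max()),
        days=days_by_subject,
    )


def event_offset(trajectories, events: pd.DataFrame, pair, event: str) -> pd.Series:
    """Signed per-subject offsets (transition day - event day) in days.

    ``event`` is 'wean' or 'solid_food'; subjects missing the transition or
    the event are skipped with a log entry.
    """
    col = {"wean": "wean_day", "solid_food": "solid_food_day"}.get(event)
    if col is None:
        raise ValueError("event must be 'wean' or 'solid_food'")
    summary = transition_summary(trajectories, pair)
    offsets = {}
    skipped = 0
    for traj in trajectories:
        sid = traj.subject_id
        if sid not in summary.days or sid not in events.index or pd.isna(events.loc[sid, col]):
            skipped += 1
            logger.info("subject %s skipped for event offset (missing datum)", sid)
            continue
        offsets[sid] = int(summary.days[sid]) - int(events.loc[sid, col])
    if skipped:
        logger.info("%d subject(s) excluded from %s offsets", skipped, event)
    return pd.Series(offsets, dtype=float, name=f"offset_{event}")


@dataclass
class ContingencyTable:
    """Microbiota clusters (rows) x SCFA types (columns)."""

    counts: pd.DataFrame
    row_percentages: pd.DataFrame

    def rendered(self, decimals: int = 1) -> pd.DataFrame:
        return self.row_percentages.round(decimals)


def crosstab(cluster_labels: pd.Series, type_labels: pd.Series) -> ContingencyTable:
    """Cross-tabulate two labelings of the same sample set with row percentages."""
    cluster_labels = pd.Series(cluster_labels)
    type_labels = pd.Series(type_labels)
    if not cluster_labels.index.sort_values().equals(type_labels.index.sort_values()):
        raise ValueError("the two labelings must cover the same samples")
    type_labels = type_labels.reindex(cluster_labels.index)
    counts = pd.crosstab(cluster_labels, type_labels)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return ContingencyTable(counts=counts, row_percentages=pct)
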