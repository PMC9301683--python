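"""Table-1-style group summaries and diagnosis-overlap partitions.

Percentages are reported to one decimal with round-half-up, matching the
display convention of clinical registry tables; raw values are retained in
the summary objects.  Visit frequencies come in two definitions: visits per
year from first to last visit (undefined for patients with fewer than two
visits or zero span) and visits per year from first visit to the study end.
Years use a 365.25-day divisor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rhinoreg.errors import ValidationError
from rhinoreg.phenotyping import OTHER_DISEASE_CATEGORIES

__all__ = [
    "CohortSummary",
    "OverlapPartition",
    "proportion",
    "visit_frequency",
    "summarize_group",
    "summary_table",
    "overlap_partition",
    "plot_overlap",
]

DAYS_PER_YEAR = 365.25


def proportion(count: int, total: int) -> float:
    """Percentage ``100 * count / total`` to one decimal, round-half-up."""
    if total == 0:
        raise ValidationError("proportion undefined for total = 0")
    if not 0 <= count <= total:
        raise ValidationError("count must satisfy 0 <= count <= total")
    pct = Decimal(100) * Decimal(count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def visit_frequency(
    visit_dates: Sequence[date],
    mode: str,
    study_end: date | None = None,
) -> float | None:
    """Visits per year under one of the two frequency definitions.

    ``first_to_last``: n / span(first, last) in years; ``None`` when fewer
    than two visits or zero span.  ``first_to_end``: n / span(first,
    study_end) in years.
    """
    dates = list(visit_dates)
    if sorted(dates) != dates:
        raise ValidationError("visit_dates must be sorted ascending")
    n = len(dates)
    if n == 0:
        return None
    if mode == "first_to_last":
        if n < 2:
            return None
        span = (dates[-1] - dates[0]).days
        if span == 0:
            return None
        return n / (span / DAYS_PER_YEAR)
    if mode == "first_to_end":
        if study_end is None:
            raise ValidationError("first_to_end mode requires study_end")
        span = (study_end - dates[0]).days
        if span <= 0:
            return None
        return n / (span / DAYS_PER_YEAR)
    raise ValidationError(f"unknown mode {mode!r}")


def _mean_sd(values: Sequence[float]) -> tuple[float | None, float | None]:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return None, None
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else None


@dataclass
class CohortSummary:
    """One Table-1 column: demographics, visit statistics, comorbidity counts."""

    group_label: str
    n: int
    percent_of_total: float | None
    n_female: int = 0
    percent_female: float | None = None
    age_mean: float | None = None
    age_sd: float | None = None
    age_mean_male: float | None = None
    age_sd_male: float | None = None
    age_mean_female: float | None = None
    age_sd_female: float | None = None
    n_pediatric: int = 0
    percent_pediatric: float | None = None
    visits_mean: float | None = None
    visits_sd: float | None = None
    visits_by_department: dict[str, tuple[float | None, float | None]] = field(
        default_factory=dict
    )
    interval_mean: float | None = None
    interval_sd: float | None = None
    interval_n_patients: int = 0
    freq_first_to_last_mean: float | None = None
    freq_first_to_last_sd: float | None = None
    freq_first_to_end_mean: float | None = None
    freq_first_to_end_sd: float | None = None
    followup_mean: float | None = None
    followup_sd: float | None = None
    comorbidity_counts: dict[str, tuple[int, float]] = field(default_factory=dict)
    other_bucket_counts: dict[str, tuple[int, float]] = field(default_factory=dict)
    any_bucket_counts: dict[str, tuple[int, float]] = field(default_factory=dict)


def summarize_group(
    profiles: pd.DataFrame,
    visits: pd.DataFrame,
    patients: pd.DataFrame,
    group_flag: str | None,
    study_end: date,
    group_label: str | None = None,
) -> CohortSummary:
    """Summarize one patient group (rows of ``profiles`` where ``group_flag``).

    ``profiles`` is indexed by patient_id with boolean flag columns and
    bucket labels; ``visits`` has columns patient_id, date (datetime-like),
    department; ``patients`` has patient_id, sex, birth_date.  With
    ``group_flag=None`` the whole cohort is summarized.  Inter-visit
    interval statistics use only patients with at least two visits; age is
    taken at the first visit; follow-up runs from first visit to
    ``study_end``.
    """
    total = len(profiles)
    if group_flag is None:
        members = profiles.index
        label = group_label or "all"
    else:
        if group_flag not in profiles.columns:
            raise ValidationError(f"unknown group flag {group_flag!r}")
        members = profiles.index[profiles[group_flag].astype(bool)]
        label = group_label or group_flag
    n = len(members)
    summary = CohortSummary(
        group_label=label,
        n=n,
        percent_of_total=proportion(n, total) if total else None,
    )
    if n == 0:
        return summary

    pat = patients.set_index("patient_id").loc[members]
    vis = visits[visits["patient_id"].isin(set(members))].copy()
    vis["date"] = pd.to_datetime(vis["date"])
    end = pd.Timestamp(study_end)

    first_visit = vis.groupby("patient_id")["date"].min()
    last_visit = vis.groupby("patient_id")["date"].max()
    n_visits = vis.groupby("patient_id").size().reindex(members, fill_value=0)

    summary.n_female = int((pat["sex"] == "female").sum())
    summary.percent_female = proportion(summary.n_female, n)

    birth = pd.to_datetime(pat["birth_date"])
    age = (first_visit.reindex(members) - birth).dt.days / DAYS_PER_YEAR
    summary.age_mean, summary.age_sd = _mean_sd(age.dropna())
    for sex, (m_attr, s_attr) in (
        ("male", ("age_mean_male", "age_sd_male")),
        ("female", ("age_mean_female", "age_sd_female")),
    ):
        sel = age[pat["sex"] == sex].dropna()
        m, s = _mean_sd(sel)
        setattr(summary, m_attr, m)
        setattr(summary, s_attr, s)
    pediatric = int((age < 18).sum())
    summary.n_pediatric = pediatric
    summary.percent_pediatric = proportion(pediatric, n)

    summary.visits_mean, summary.visits_sd = _mean_sd(n_visits)
    for dept in sorted(vis["department"].unique()):
        per_patient = (
            vis[vis["department"] == dept].groupby("patient_id").size()
            .reindex(members, fill_value=0)
        )
        summary.visits_by_department[dept] = _mean_sd(per_patient)

    intervals: list[float] = []
    interval_patients = 0
    for _, grp in vis.groupby("patient_id"):
        d = grp["date"].sort_values()
        if len(d) >= 2:
            interval_patients += 1
            intervals.extend(d.diff().dropna().dt.days.tolist())
    summary.interval_mean, summary.interval_sd = _mean_sd(intervals)
    summary.interval_n_patients = interval_patients

    f2l, f2e = [], []
    for pid, grp in vis.groupby("patient_id"):
        dates = sorted(grp["date"].dt.date)
        f2l.append(visit_frequency(dates, "first_to_last"))
        f2e.append(visit_frequency(dates, "first_to_end", study_end))
    summary.freq_first_to_last_mean, summary.freq_first_to_last_sd = _mean_sd(f2l)
    summary.freq_first_to_end_mean, summary.freq_first_to_end_sd = _mean_sd(f2e)

    followup = (end - first_visit.reindex(members)).dt.days
    summary.followup_mean, summary.followup_sd = _mean_sd(followup.dropna())

    sub = profiles.loc[members]
    for cat in OTHER_DISEASE_CATEGORIES:
        if cat in sub.columns:
            cnt = int(sub[cat].astype(bool).sum())
            summary.comorbidity_counts[cat] = (cnt, proportion(cnt, n))
    for col, target, labels in (
        ("other_bucket", "other_bucket_counts", ("0", "1", "2", "3", "≥4")),
        ("any_bucket", "any_bucket_counts", ("1", "2", "3", "4", "≥5")),
    ):
        if col in sub.columns:
            counts = sub[col].value_counts()
            getattr(summary, target).update(
                {lab: (int(counts.get(lab, 0)), proportion(int(counts.get(lab, 0)), n))
                 for lab in labels}
            )
    return summary


def summary_table(summaries: Sequence[CohortSummary]) -> pd.DataFrame:
    """Flatten summaries into a groups x fields table (one column per group)."""
    cols = {}
    for s in summaries:
        col: dict[str, object] = {
            "n": s.n,
            "percent_of_total": s.percent_of_total,
            "n_female": s.n_female,
            "percent_female": s.percent_female,
            "age_mean": s.age_mean,
            "age_sd": s.age_sd,
            "n_pediatric": s.n_pediatric,
            "percent_pediatric": s.percent_pediatric,
            "visits_mean": s.visits_mean,
            "visits_sd": s.visits_sd,
            "interval_mean_days": s.interval_mean,
            "interval_sd_days": s.interval_sd,
            "freq_first_to_last_mean": s.freq_first_to_last_mean,
            "freq_first_to_end_mean": s.freq_first_to_end_mean,
            "followup_mean_days": s.followup_mean,
            "followup_sd_days": s.followup_sd,
        }
        for cat, (cnt, pct) in s.comorbidity_counts.items():
            col[f"{cat}_n"] = cnt
            col[f"{cat}_pct"] = pct
        for lab, (cnt, pct) in s.other_bucket_counts.items():
            col[f"other_diseases_{lab}_n"] = cnt
            col[f"other_diseases_{lab}_pct"] = pct
        for lab, (cnt, pct) in s.any_bucket_counts.items():
            col[f"any_diseases_{lab}_n"] = cnt
            col[f"any_diseases_{lab}_pct"] = pct
        cols[s.group_label] = col
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class OverlapPartition:
    """Disjoint three-set region counts (Venn layout)."""

    labels: tuple[str, str, str]
    a_only: int
    b_only: int
    c_only: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    @property
    def union_size(self) -> int:
        return (self.a_only + self.b_only + self.c_only + self.ab_only
                + self.ac_only + self.bc_only + self.abc)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "100": self.a_only, "010": self.b_only, "001": self.c_only,
            "110": self.ab_only, "101": self.ac_only, "011": self.bc_only,
            "111": self.abc,
        }


def overlap_partition(
    flags_a: pd.Series,
    flags_b: pd.Series,
    flags_c: pd.Series,
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> OverlapPartition:
    """Exact counts of the seven disjoint regions of three patient sets."""
    if not (flags_a.index.equals(flags_b.index) and flags_b.index.equals(flags_c.index)):
        raise ValidationError("flag vectors must share one patient index")
    a = flags_a.astype(bool)
    b = flags_b.astype(bool)
    c = flags_c.astype(bool)
    return OverlapPartition(
        labels=labels,
        a_only=int((a & ~b & ~c).sum()),
        b_only=int((~a & b & ~c).sum()),
        c_only=int((~a & ~b & c).sum()),
        ab_only=int((a & b & ~c).sum()),
        ac_only=int((a & ~b & c).sum()),
        bc_only=int((~a & b & c).sum()),
        abc=int((a & b & c).sum()),
    )


def plot_overlap(partition: OverlapPartition, path=None):
    """Render a simple three-circle overlap diagram with region counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    fig, ax = plt.subplots(figsize=(5, 5))
    centers = [(-0.5, 0.3), (0.5, 0.3), (0.0, -0.55)]
    for (x, y), lab in zip(centers, partition.labels):
        ax.add_patch(Circle((x, y), 1.0, alpha=0.3))
        ax.annotate(lab, (x, y + 1.05), ha="center")
    positions = {
        "a_only": (-0.9, 0.5), "b_only": (0.9, 0.5), "c_only": (0.0, -1.0),
        "ab_only": (0.0, 0.6), "ac_only": (-0.55, -0.35), "bc_only": (0.55, -0.35),
        "abc": (0.0, 0.0),
    }
    for name, (x, y) in positions.items():
        ax.annotate(str(getattr(partition, name)), (x, y), ha="center")
    ax.set_xlim(-2, 2)
    ax.set_ylim(-2, 2)
    ax.set_aspect("equal")
    ax.axis("off")
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
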