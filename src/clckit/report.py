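"""Per-subject and cohort orchestration of the coupling pipeline.

:func:`analyze_subject` runs the whole minute-level analysis for one
subject (classification, occurrence, bouts, null model, comparison) on
already-aligned data; :func:`run_subject` adds file ingest in front.
:func:`run_cohort` aggregates subjects the way the source study reports:
cohort values are medians (with inter-quartile ranges) of per-subject
values, paired contrasts use Wilcoxon signed-rank with effect size r,
the age split uses Kruskal-Wallis on per-subject median ratios, and
subjects are grouped by the moderate-minus-vigorous occurrence
difference D.

Everything numeric a report holds is reproducible: the default null
method is exact, and file outputs are plain CSV/JSON with stable
ordering.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import coupling, ingest, null_model, stats
from .config import AnalysisConfig

logger = logging.getLogger(__name__)

__all__ = ["SubjectReport", "CohortReport", "analyze_subject", "run_subject", "run_cohort"]


def _median_iqr(values) -> tuple:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return (float("nan"), float("nan"))
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    return (float(med), float(q75 - q25))


@dataclass
class SubjectReport:
    """Table-1-style summary for one subject plus the detailed tables."""

    subject_id: str
    empty: bool = False
    n_instances: int = 0
    resting_hr_median: float = float("nan")
    resting_hr_iqr: float = float("nan")
    r_median: float = float("nan")
    r_iqr: float = float("nan")
    clc_occurrence: float = float("nan")
    weak_occurrence: float = float("nan")
    pearson_r: float = float("nan")
    pearson_p: float = float("nan")
    d_statistic: float = float("nan")
    group: str = ""
    occurrence_by_intensity: Optional[pd.DataFrame] = field(default=None, repr=False)
    duration_by_class: Optional[pd.DataFrame] = field(default=None, repr=False)
    observed: Optional[null_model.ObservedDistribution] = field(default=None, repr=False)
    null: Optional[null_model.NullDistribution] = field(default=None, repr=False)
    comparison: Optional[null_model.DistributionComparison] = field(default=None, repr=False)
    instances: Optional[pd.DataFrame] = field(default=None, repr=False)
    bouts: Optional[pd.DataFrame] = field(default=None, repr=False)
    # optional demographics
    age: Optional[float] = None
    height: Optional[float] = None
    gender: Optional[str] = None

    def summary_row(self) -> dict:
        return {
            "subject": self.subject_id,
            "age": self.age, "height": self.height, "gender": self.gender,
            "resting_hr_median": self.resting_hr_median,
            "resting_hr_iqr": self.resting_hr_iqr,
            "r_median": self.r_median, "r_iqr": self.r_iqr,
            "clc_occurrence_pct": self.clc_occurrence,
            "weak_clc_occurrence_pct": self.weak_occurrence,
            "pearson_r": self.pearson_r,
            "d_statistic": self.d_statistic,
            "group": self.group,
            "n_instances": self.n_instances,
            "p_weak_or_clc_observed": self.observed.p_weak_or_clc if self.observed else float("nan"),
            "p_weak_or_clc_null": self.null.p_weak_or_clc if self.null else float("nan"),
            "p_clc_null": self.null.p_clc if self.null else float("nan"),
            "skewness_observed": self.observed.skewness if self.observed else float("nan"),
            "skewness_null": self.null.skewness if self.null else float("nan"),
            "iqr_observed": self.observed.iqr if self.observed else float("nan"),
            "iqr_null": self.null.iqr if self.null else float("nan"),
            "ks_statistic": self.comparison.ks_statistic if self.comparison else float("nan"),
            "ks_p": self.comparison.ks_p if self.comparison else float("nan"),
        }


def analyze_subject(hr_minutes: pd.DataFrame, sr_minutes: pd.DataFrame,
                    subject_id: str = "subject",
                    config: AnalysisConfig = AnalysisConfig(),
                    null_method: str = "exact",
                    n_samples: int = 100_000, seed: int = 0) -> SubjectReport:
    """Run the full analysis on one subject's minute-level streams.

    ``hr_minutes`` has columns ``timestamp``/``hr`` (already averaged per
    minute), ``sr_minutes`` has ``timestamp``/``steps``.  Resting HR is
    summarised from the below-threshold minutes that the activity filter
    discards.
    """
    merged = hr_minutes.merge(
        sr_minutes.rename(columns={"steps": "sr"})[["timestamp", "sr"]],
        on="timestamp", how="inner")
    records = merged[merged["sr"] >= config.sr_threshold].reset_index(drop=True)
    if len(records) < 2:
        logger.warning("%s: no post-filter minutes; report flagged empty", subject_id)
        return SubjectReport(subject_id=subject_id, empty=True)

    rest = merged[merged["sr"] < config.sr_threshold]
    rest_med, rest_iqr = _median_iqr(rest["hr"]) if len(rest) else (float("nan"),) * 2

    instances = coupling.classify(records, config)
    bouts = coupling.segment_bouts(instances, config)
    occ_int = coupling.occurrence(instances, stratify_by_intensity=True)
    occ_mod = coupling.occurrence_pct(instances, "CLC", "moderate")
    occ_vig = coupling.occurrence_pct(instances, "CLC", "vigorous")
    if np.isnan(occ_mod) or np.isnan(occ_vig):
        d_stat, group = float("nan"), "undefined"
    else:
        assignment = coupling.group_subject(occ_mod, occ_vig, config.d_cut)
        d_stat, group = assignment.d_statistic, assignment.group

    observed = null_model.observed_distribution(instances, config)
    hr_vals = instances["hr"].to_numpy(float)
    sr_vals = instances["sr"].to_numpy(float)
    if null_method == "exact":
        null = null_model.null_exact(hr_vals, sr_vals, config)
    else:
        null = null_model.null_sampled(hr_vals, sr_vals, n_samples, seed, config)
    comparison = null_model.compare(observed, null)
    pearson = stats.pearson_correlation(hr_vals, sr_vals)

    r_med, r_iqr = _median_iqr(instances["ratio"])
    return SubjectReport(
        subject_id=subject_id, n_instances=len(instances),
        resting_hr_median=rest_med, resting_hr_iqr=rest_iqr,
        r_median=r_med, r_iqr=r_iqr,
        clc_occurrence=coupling.occurrence_pct(instances, "CLC"),
        weak_occurrence=coupling.occurrence_pct(instances, "weak_CLC"),
        pearson_r=pearson.statistic, pearson_p=pearson.p_value,
        d_statistic=d_stat, group=group,
        occurrence_by_intensity=occ_int,
        duration_by_class=coupling.bout_duration_by_class(bouts) if len(bouts) else None,
        observed=observed, null=null, comparison=comparison,
        instances=instances, bouts=bouts,
    )


def run_subject(hr_path, sr_path, subject_id: str = "subject",
                dialect: str = "csv",
                config: AnalysisConfig = AnalysisConfig(),
                null_method: str = "exact",
                n_samples: int = 100_000, seed: int = 0,
                out_dir=None) -> SubjectReport:
    """File-level entry point: ingest both streams, then analyze.

    With ``out_dir`` the intermediate tables (instances, bouts,
    occurrence, null histogram) are persisted as CSV.
    """
    hr = ingest.read_heart_rate(hr_path, dialect=dialect)
    sr = ingest.read_steps(sr_path, dialect=dialect)
    hr_min = ingest.minutely_hr(hr.records, min_samples_per_minute=config.min_hr_samples)
    report = analyze_subject(hr_min, sr.records, subject_id=subject_id, config=config,
                             null_method=null_method, n_samples=n_samples, seed=seed)
    if out_dir is not None and not report.empty:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.instances.to_csv(out / "instances.csv", index=False)
        report.bouts.to_csv(out / "bouts.csv", index=False)
        report.occurrence_by_intensity.to_csv(out / "occurrence.csv", index=False)
        null_hist = report.null.histogram()
        null_hist.insert(0, "subject", subject_id)
        null_hist.to_csv(out / "null.csv", index=False)
    return report


def _paired_contrast(name: str, x: Sequence[float], y: Sequence[float]) -> dict:
    """Wilcoxon paired contrast over subjects, dropping NaN pairs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    row = {"contrast": name, "n": int(keep.sum())}
    if keep.sum() < 5:
        row.update({"statistic": float("nan"), "p_value": float("nan"),
                    "effect_size_r": float("nan"), "flagged": True,
                    "note": "fewer than 5 complete pairs"})
        return row
    res = stats.wilcoxon_paired(x[keep], y[keep])
    row.update({"statistic": res.statistic, "p_value": res.p_value,
                "effect_size_r": res.effect_size, "flagged": res.flagged,
                "note": res.note})
    return row


@dataclass
class CohortReport:
    """Cohort-level medians, contrasts and group table."""

    subjects: pd.DataFrame                       # one summary row per subject
    cohort_medians: dict                         # field -> (median, iqr)
    contrasts: pd.DataFrame                      # Wilcoxon paired tests
    group_table: Optional[pd.DataFrame] = None   # Table-2-style by group
    age_split: Optional[stats.TestResult] = None
    time_of_day: Optional[stats.TestResult] = None
    n_excluded: int = 0

    def to_json_dict(self) -> dict:
        return {
            "cohort_medians": {k: list(v) for k, v in self.cohort_medians.items()},
            "n_subjects": int(len(self.subjects)),
            "n_excluded": self.n_excluded,
            "contrasts": self.contrasts.to_dict(orient="records"),
            "age_split": dataclasses.asdict(self.age_split) if self.age_split else None,
            "time_of_day": dataclasses.asdict(self.time_of_day) if self.time_of_day else None,
        }


_NUMERIC_SUMMARY_FIELDS = (
    "resting_hr_median", "r_median", "r_iqr", "clc_occurrence_pct",
    "weak_clc_occurrence_pct", "pearson_r", "d_statistic", "n_instances",
    "p_weak_or_clc_observed", "p_weak_or_clc_null", "p_clc_null",
    "skewness_observed", "skewness_null", "iqr_observed", "iqr_null",
)


def run_cohort(reports: Sequence[SubjectReport],
               config: AnalysisConfig = AnalysisConfig(),
               demographics: Optional[pd.DataFrame] = None,
               out_dir=None) -> CohortReport:
    """Aggregate per-subject reports into the cohort summary.

    ``demographics`` (optional) is a frame with columns ``subject`` and
    any of ``age``/``height``/``gender``; absent fields stay missing.
    Raises if fewer than 2 subjects are non-empty.
    """
    kept = [r for r in reports if not r.empty]
    n_excluded = len(reports) - len(kept)
    if n_excluded:
        logger.warning("run_cohort: excluding %d empty subject report(s)", n_excluded)
    if len(kept) < 2:
        raise ValueError("run_cohort needs at least 2 non-empty subjects")

    if demographics is not None:
        demo = demographics.drop_duplicates(subset="subject")
        demo = demo.set_index(demo["subject"].astype(str))
        for r in kept:
            if str(r.subject_id) in demo.index:
                row = demo.loc[str(r.subject_id)]
                r.age = float(row["age"]) if "age" in row and pd.notna(row.get("age")) else None
                r.height = float(row["height"]) if "height" in row and pd.notna(row.get("height")) else None
                r.gender = row.get("gender")

    summary = pd.DataFrame([r.summary_row() for r in kept])
    cohort_medians = {f: _median_iqr(summary[f]) for f in _NUMERIC_SUMMARY_FIELDS}

    # paired contrasts over subjects
    def occ(r: SubjectReport, cls: str, intensity: str) -> float:
        return coupling.occurrence_pct(r.instances, cls, intensity)

    def duration(r: SubjectReport, cls: str) -> float:
        tab = r.duration_by_class
        if tab is None or cls not in set(tab["bout_class"]):
            return float("nan")
        return float(tab.loc[tab["bout_class"] == cls, "median_duration"].iloc[0])

    contrasts = pd.DataFrame([
        _paired_contrast("clc_occ_moderate_vs_light",
                         [occ(r, "CLC", "moderate") for r in kept],
                         [occ(r, "CLC", "light") for r in kept]),
        _paired_contrast("weak_occ_moderate_vs_light",
                         [occ(r, "weak_CLC", "moderate") for r in kept],
                         [occ(r, "weak_CLC", "light") for r in kept]),
        _paired_contrast("p_weak_or_clc_observed_vs_null",
                         [r.observed.p_weak_or_clc for r in kept],
                         [r.null.p_weak_or_clc for r in kept]),
        _paired_contrast("iqr_observed_vs_null",
                         [r.observed.iqr for r in kept],
                         [r.null.iqr for r in kept]),
        _paired_contrast("skewness_observed_vs_null",
                         [r.observed.skewness for r in kept],
                         [r.null.skewness for r in kept]),
        _paired_contrast("duration_clc_vs_no_clc",
                         [duration(r, "CLC") for r in kept],
                         [duration(r, "no_CLC") for r in kept]),
        _paired_contrast("duration_weak_vs_no_clc",
                         [duration(r, "weak_CLC") for r in kept],
                         [duration(r, "no_CLC") for r in kept]),
    ])

    # age split on per-subject median R (Kruskal-Wallis, >=40 vs <40)
    age_split = None
    ages = np.array([r.age if r.age is not None else np.nan for r in kept], float)
    if np.sum(~np.isnan(ages)) >= 5:
        older = [r.r_median for r, a in zip(kept, ages) if not np.isnan(a) and a >= config.age_split]
        young = [r.r_median for r, a in zip(kept, ages) if not np.isnan(a) and a < config.age_split]
        if len(older) >= 1 and len(young) >= 1:
            age_split = stats.kruskal_wallis_groups([older, young])

    # time-of-day vs coupling class: KW of bout start hours across classes
    all_bouts = pd.concat([r.bouts for r in kept if r.bouts is not None], ignore_index=True)
    time_of_day = None
    hour_groups = [g["start_hour"].to_numpy(float)
                   for _, g in all_bouts.groupby("bout_class") if len(g) > 0]
    if len(hour_groups) >= 2:
        time_of_day = stats.kruskal_wallis_groups(hour_groups)

    # Table-2-style group characteristics
    group_rows = []
    for grp, sub in summary.groupby("group"):
        row = {"group": grp, "n_subjects": len(sub)}
        for fld in ("age", "resting_hr_median", "r_median", "clc_occurrence_pct",
                    "n_instances"):
            med, iqr = _median_iqr(sub[fld]) if fld in sub else (float("nan"),) * 2
            row[f"{fld}_median"], row[f"{fld}_iqr"] = med, iqr
        group_rows.append(row)
    group_table = pd.DataFrame(group_rows)

    report = CohortReport(subjects=summary, cohort_medians=cohort_medians,
                          contrasts=contrasts, group_table=group_table,
                          age_split=age_split, time_of_day=time_of_day,
                          n_excluded=n_excluded)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "subjects.csv", index=False)
        contrasts.to_csv(out / "stats.csv", index=False)
        group_table.to_csv(out / "groups.csv", index=False)
        (out / "cohort_report.json").write_text(
            json.dumps(report.to_json_dict(), indent=1, sort_keys=True, default=str))
    return report
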