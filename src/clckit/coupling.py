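"""Coupling-ratio classification, intensity strata, bouts and grouping.

The coupling ratio of an aligned minute is ``R = SR / HR`` (steps/min
over beats/min).  A minute is coupled (CLC) when SR deviates from HR by
at most 1%, weakly coupled when the deviation is in (1%, 10%], and
uncoupled beyond 10%.  The deviation is computed as ``|SR − HR| / HR``
— algebraically identical to ``|R − 1|`` but numerically exact at the
band edges (99 vs 100 beats/min is a deviation of exactly 0.01).

Intensity follows the walking-cadence convention: light [60, 100),
moderate [100, 130), vigorous [130, ∞) steps/min.

An activity bout is a maximal run of kept minutes in which consecutive
observations are less than one hour apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig

__all__ = [
    "COUPLING_CLASSES", "INTENSITY_CLASSES",
    "classify", "occurrence", "segment_bouts", "bout_duration_by_class",
    "group_subject", "time_of_day_profile", "GroupAssignment",
]

COUPLING_CLASSES = ("CLC", "weak_CLC", "no_CLC")     # strongest first
INTENSITY_CLASSES = ("light", "moderate", "vigorous")


def classify(records: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Annotate aligned minutes with ratio, deviation and both classes.

    Parameters
    ----------
    records:
        Frame with columns ``timestamp``, ``hr``, ``sr`` (post-filter).
    config:
        Band and cut thresholds.

    Returns the frame with added columns ``ratio``, ``deviation``,
    ``coupling_class`` and ``intensity_class``.  Classification is total:
    every row receives exactly one class of each kind.
    """
    hr = np.asarray(records["hr"], dtype=float)
    sr = np.asarray(records["sr"], dtype=float)
    if np.any(hr <= 0):
        raise ValueError("heart rate must be positive for every record")

    out = records.copy()
    out["ratio"] = sr / hr
    deviation = np.abs(sr - hr) / hr
    out["deviation"] = deviation
    out["coupling_class"] = np.select(
        [deviation <= config.clc_threshold, deviation <= config.weak_threshold],
        ["CLC", "weak_CLC"], default="no_CLC",
    )
    mod_cut, vig_cut = config.intensity_cuts
    out["intensity_class"] = np.select(
        [sr >= vig_cut, sr >= mod_cut], ["vigorous", "moderate"], default="light",
    )
    return out


def occurrence(instances: pd.DataFrame, stratify_by_intensity: bool = False) -> pd.DataFrame:
    """Percentage of minutes in each coupling class.

    With ``stratify_by_intensity`` the percentages are computed within
    each intensity stratum (each stratum's three classes sum to 100).

    Returns a tidy frame with columns ``intensity_class`` (or the pooled
    marker ``"all"``), ``coupling_class``, ``percentage``, ``n``
    (stratum denominator).
    """
    if instances.empty:
        import logging
        logging.getLogger(__name__).warning("occurrence: empty instance set")
        return pd.DataFrame(columns=["intensity_class", "coupling_class", "percentage", "n"])

    strata = (
        [(label, group) for label, group in instances.groupby("intensity_class", observed=True)]
        if stratify_by_intensity else [("all", instances)]
    )
    rows = []
    for label, group in strata:
        n = len(group)
        counts = group["coupling_class"].value_counts()
        for cls in COUPLING_CLASSES:
            rows.append({
                "intensity_class": label,
                "coupling_class": cls,
                "percentage": 100.0 * counts.get(cls, 0) / n,
                "n": n,
            })
    return pd.DataFrame(rows)


def occurrence_pct(instances: pd.DataFrame, coupling_class: str = "CLC",
                   intensity_class: str | None = None) -> float:
    """Convenience scalar: percentage of one coupling class (optionally
    within one intensity stratum).  NaN if the stratum is empty."""
    subset = instances
    if intensity_class is not None:
        subset = subset[subset["intensity_class"] == intensity_class]
    if len(subset) == 0:
        return float("nan")
    return 100.0 * float((subset["coupling_class"] == coupling_class).mean())


def _bout_label(classes: pd.Series, min_share: float) -> str:
    counts = classes.value_counts()
    n = counts.sum()
    for cls in COUPLING_CLASSES:            # strongest first
        if counts.get(cls, 0) / n >= min_share:
            return cls
    top = counts.max()
    for cls in COUPLING_CLASSES:            # modal, ties to stronger
        if counts.get(cls, 0) == top:
            return cls
    raise AssertionError("unreachable")


def segment_bouts(instances: pd.DataFrame,
                  config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Split classified minutes into activity bouts.

    A new bout starts wherever the gap to the previous kept minute is
    ``>= config.gap_minutes`` (so a 59-minute gap merges and a 60-minute
    gap splits).  Returns one row per bout with ``start``, ``end``,
    ``duration`` (inclusive span, minutes), ``n_instances``,
    ``bout_class``, ``start_hour`` and per-class instance counts; the
    instance frame gains a ``bout_id`` column (returned frame's index).
    """
    if instances.empty:
        return pd.DataFrame(columns=["bout_id", "start", "end", "duration", "n_instances",
                                     "bout_class", "start_hour"])
    inst = instances.sort_values("timestamp", kind="mergesort")
    ts = inst["timestamp"]
    gaps = ts.diff().dt.total_seconds().div(60.0)
    bout_id = (gaps >= config.gap_minutes).fillna(False).cumsum()
    inst = inst.assign(bout_id=bout_id.to_numpy())

    rows = []
    for bid, group in inst.groupby("bout_id"):
        start, end = group["timestamp"].iloc[0], group["timestamp"].iloc[-1]
        rows.append({
            "bout_id": int(bid),
            "start": start,
            "end": end,
            "duration": (end - start).total_seconds() / 60.0 + 1.0,
            "n_instances": len(group),
            "bout_class": _bout_label(group["coupling_class"], config.bout_class_min_share),
            "start_hour": int(start.hour),
        })
    instances["bout_id"] = inst["bout_id"].reindex(instances.index)
    return pd.DataFrame(rows)


def bout_duration_by_class(bouts: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of bout duration per coupling class.

    Classes with no bouts are simply absent (not reported as zero).
    """
    if bouts.empty:
        raise ValueError("bout_duration_by_class needs at least one bout")
    rows = []
    for cls, group in bouts.groupby("bout_class"):
        dur = group["duration"].to_numpy(float)
        q25, q75 = np.percentile(dur, [25, 75])
        rows.append({
            "bout_class": cls,
            "median_duration": float(np.median(dur)),
            "iqr_duration": float(q75 - q25),
            "n_bouts": len(group),
        })
    order = {c: i for i, c in enumerate(COUPLING_CLASSES)}
    return (pd.DataFrame(rows)
            .sort_values("bout_class", key=lambda s: s.map(order))
            .reset_index(drop=True))


@dataclass(frozen=True)
class GroupAssignment:
    """Subject grouping by where coupling predominates.

    ``d_statistic`` is the CLC occurrence in moderate minus vigorous
    activity, in percentage points; subjects with D ≤ −1.5 couple most
    during vigorous activity, D ≥ +1.5 during moderate, otherwise the
    extent is similar in both (``constant``).
    """

    d_statistic: float
    group: str


def group_subject(occ_moderate: float, occ_vigorous: float,
                  d_cut: float = 1.5) -> GroupAssignment:
    """Assign the coupling-pattern group from two occurrence percentages."""
    for name, value in (("occ_moderate", occ_moderate), ("occ_vigorous", occ_vigorous)):
        if not 0.0 <= value <= 100.0:
            raise ValueError(f"{name} must be a percentage in [0, 100]")
    d = occ_moderate - occ_vigorous
    if d <= -d_cut:
        group = "most_vigorous"
    elif d >= d_cut:
        group = "most_moderate"
    else:
        group = "constant"
    return GroupAssignment(d_statistic=d, group=group)


def time_of_day_profile(bouts: pd.DataFrame) -> pd.DataFrame:
    """Distribution of bout start hours per coupling class.

    Returns a tidy frame (``bout_class``, ``start_hour``, ``count``,
    ``fraction``); fraction normalises within each class.  Association
    between class and hour is tested separately (stats module).
    """
    if bouts.empty:
        return pd.DataFrame(columns=["bout_class", "start_hour", "count", "fraction"])
    rows = []
    for cls, group in bouts.groupby("bout_class"):
        counts = group["start_hour"].value_counts().sort_index()
        for hour, count in counts.items():
            rows.append({
                "bout_class": cls,
                "start_hour": int(hour),
                "count": int(count),
                "fraction": count / len(group),
            })
    return pd.DataFrame(rows)
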