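"""Reading raw wearable streams and building the aligned minute table.

Two input dialects are supported:

* ``csv`` — headers ``timestamp,bpm`` / ``timestamp,steps`` with ISO-8601
  timestamps;
* ``fitbit-json`` — arrays of ``{"dateTime": "MM/DD/YY HH:MM:SS",
  "value": ...}`` objects as deposited in PMData-style exports (heart
  rate values are ``{"bpm": int, "confidence": int}`` objects, step
  values are ints or int-strings).

Heart rate arrives every few seconds and is averaged per calendar minute
to match the per-minute step resolution; the two streams are then joined
on the minute timestamp and minutes below the activity threshold
(default 60 steps/min; strictly-below excluded) are dropped.  Timestamps
are treated as local wall clock throughout — the analysis only uses
time-of-day and gaps.

Malformed or out-of-range rows are never silently dropped: each reader
logs and counts them (see :class:`ReadResult.n_rejected`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ReadResult", "read_heart_rate", "read_steps", "minutely_hr", "align_and_filter"]

HR_BPM_MIN, HR_BPM_MAX = 20, 250       # open interval (20, 250)
SR_STEPS_MAX = 300


@dataclass
class ReadResult:
    """Parsed stream plus bookkeeping about rejected rows."""

    records: pd.DataFrame
    n_rejected: int
    rejected_reasons: dict


def _finish(df: pd.DataFrame, valid: pd.Series, reasons: dict, sort_col: str,
            what: str, path) -> ReadResult:
    n_rejected = int((~valid).sum())
    if n_rejected:
        logger.warning("%s: rejected %d %s row(s): %s", path, n_rejected, what, reasons)
    out = df.loc[valid].sort_values(sort_col, kind="mergesort").reset_index(drop=True)
    if out.empty:
        logger.warning("%s: no valid %s records", path, what)
    return ReadResult(records=out, n_rejected=n_rejected, rejected_reasons=reasons)


def _parse_fitbit_json(path):
    try:
        payload = json.loads(open(path).read())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON at line {exc.lineno}") from exc
    if not isinstance(payload, list):
        raise ValueError(f"{path}: expected a JSON array of records")
    return payload


def read_heart_rate(path, dialect: str = "csv") -> ReadResult:
    """Read a heart-rate stream (``timestamp``, ``bpm``).

    Rows with bpm outside the physiological open interval (20, 250) or
    with unparseable timestamps are rejected and counted.  An empty file
    yields an empty frame with a warning.
    """
    reasons: dict = {}
    if dialect == "csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["timestamp", "bpm"])
        missing = {"timestamp", "bpm"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: csv heart-rate file missing column(s) {sorted(missing)}")
        ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
        bpm = pd.to_numeric(df["bpm"], errors="coerce")
    elif dialect == "fitbit-json":
        payload = _parse_fitbit_json(path)
        rows = []
        for i, rec in enumerate(payload):
            try:
                rows.append((rec["dateTime"], rec["value"]["bpm"]))
            except (TypeError, KeyError):
                raise ValueError(f"{path}: malformed heart-rate record {i}")
        df = pd.DataFrame(rows, columns=["timestamp", "bpm"])
        ts = pd.to_datetime(df["timestamp"], format="%m/%d/%y %H:%M:%S", errors="coerce")
        bpm = pd.to_numeric(df["bpm"], errors="coerce")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    bad_ts = ts.isna()
    bad_bpm = bpm.isna() | (bpm <= HR_BPM_MIN) | (bpm >= HR_BPM_MAX)
    if bad_ts.any():
        reasons["bad_timestamp"] = int(bad_ts.sum())
    if (bad_bpm & ~bad_ts).any():
        reasons["bpm_out_of_range"] = int((bad_bpm & ~bad_ts).sum())
    out = pd.DataFrame({"timestamp": ts, "bpm": bpm.astype(float)})
    return _finish(out, ~(bad_ts | bad_bpm), reasons, "timestamp", "heart-rate", path)


def read_steps(path, dialect: str = "csv") -> ReadResult:
    """Read a per-minute step stream (``timestamp``, ``steps``).

    Steps must be non-negative integers at most 300; non-integer values
    in the csv dialect are rejected, not rounded.  Duplicate minutes keep
    the first record (logged).
    """
    reasons: dict = {}
    if dialect == "csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["timestamp", "steps"])
        missing = {"timestamp", "steps"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: csv steps file missing column(s) {sorted(missing)}")
        ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
        steps = pd.to_numeric(df["steps"], errors="coerce")
    elif dialect == "fitbit-json":
        payload = _parse_fitbit_json(path)
        rows = []
        for i, rec in enumerate(payload):
            try:
                rows.append((rec["dateTime"], rec["value"]))
            except (TypeError, KeyError):
                raise ValueError(f"{path}: malformed steps record {i}")
        df = pd.DataFrame(rows, columns=["timestamp", "steps"])
        ts = pd.to_datetime(df["timestamp"], format="%m/%d/%y %H:%M:%S", errors="coerce")
        steps = pd.to_numeric(df["steps"], errors="coerce")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    bad_ts = ts.isna()
    non_integer = steps.notna() & (steps != np.floor(steps))
    bad_steps = steps.isna() | non_integer | (steps < 0) | (steps > SR_STEPS_MAX)
    if bad_ts.any():
        reasons["bad_timestamp"] = int(bad_ts.sum())
    if non_integer.any():
        reasons["non_integer_steps"] = int(non_integer.sum())
    oor = (bad_steps & ~non_integer & steps.notna())
    if oor.any():
        reasons["steps_out_of_range"] = int(oor.sum())

    valid = ~(bad_ts | bad_steps)
    out = pd.DataFrame({"timestamp": ts.dt.floor("min"), "steps": steps})
    out = out.loc[valid].sort_values("timestamp", kind="mergesort")
    dup = out["timestamp"].duplicated(keep="first")
    if dup.any():
        reasons["duplicate_minute"] = int(dup.sum())
        logger.warning("%s: %d duplicate minute(s), keeping first", path, int(dup.sum()))
        out = out.loc[~dup]
    out = out.reset_index(drop=True)
    out["steps"] = out["steps"].astype(int)
    n_rejected = int((~valid).sum())
    if n_rejected:
        logger.warning("%s: rejected %d steps row(s): %s", path, n_rejected, reasons)
    if out.empty:
        logger.warning("%s: no valid steps records", path)
    return ReadResult(records=out, n_rejected=n_rejected, rejected_reasons=reasons)


def minutely_hr(samples: pd.DataFrame, min_samples_per_minute: int = 6) -> pd.DataFrame:
    """Average heart-rate samples to calendar minutes.

    A minute is kept only if it holds at least ``min_samples_per_minute``
    samples (half the nominal twelve 5-second samples by default); its
    value is the arithmetic mean of the samples whose timestamps
    floor-truncate to that minute.

    Returns a frame with columns ``timestamp`` (minute) and ``hr``.
    """
    if samples.empty:
        return pd.DataFrame({"timestamp": pd.DatetimeIndex([]), "hr": []})
    minute = samples["timestamp"].dt.floor("min")
    grouped = samples.groupby(minute)["bpm"].agg(["mean", "size"])
    kept = grouped[grouped["size"] >= min_samples_per_minute]
    return pd.DataFrame({
        "timestamp": pd.DatetimeIndex(kept.index),
        "hr": kept["mean"].to_numpy(float),
    }).reset_index(drop=True)


def align_and_filter(hr_minutes: pd.DataFrame, sr_minutes: pd.DataFrame,
                     sr_threshold: float = 60.0) -> pd.DataFrame:
    """Join minute HR and SR on timestamp and apply the activity filter.

    Inner join (a minute must carry both signals), then keep only minutes
    with ``sr >= sr_threshold`` — data strictly below the threshold are
    excluded as rest or sleep.  Output columns: ``timestamp``, ``hr``,
    ``sr``; sorted by timestamp.
    """
    sr = sr_minutes.rename(columns={"steps": "sr"})
    merged = hr_minutes.merge(sr[["timestamp", "sr"]], on="timestamp", how="inner")
    if merged.empty:
        logger.warning("align_and_filter: empty timestamp intersection")
        return pd.DataFrame({"timestamp": pd.DatetimeIndex([]), "hr": [], "sr": []})
    kept = merged[merged["sr"] >= sr_threshold]
    return kept.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def load_subject(hr_path, sr_path, dialect: str = "csv",
                 sr_threshold: float = 60.0,
                 min_hr_samples: int = 6) -> pd.DataFrame:
    """Full ingest for one subject: read both streams, average, align, filter."""
    hr = read_heart_rate(hr_path, dialect=dialect)
    sr = read_steps(sr_path, dialect=dialect)
    hr_min = minutely_hr(hr.records, min_samples_per_minute=min_hr_samples)
    return align_and_filter(hr_min, sr.records, sr_threshold=sr_threshold)
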