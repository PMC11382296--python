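"""Synthetic wearable cohort generator.

Produces per-subject wrist-device streams — 5-second heart-rate samples
and per-minute step counts — with a known ground truth, so every stage of
the coupling pipeline can be validated against injected parameters.

The generator is a validation scaffold, not a statistical replica of any
real cohort.  Its design priorities, in order:

1. *Recovery*: with sensor noise off, the fraction of active minutes the
   pipeline classifies as coupled must equal the injected
   ``couple_fraction``.  Non-entrained minutes therefore keep their
   step-to-heart ratio away from the ±1% coupling band (subject base
   ratio ~0.93, clipped to [0.90, 0.96]).
2. *Calibration*: an ``hr_mode="independent"`` configuration breaks the
   minute-level HR–cadence dependence entirely, giving data under which
   the random-pairing null model must be exact.
3. *Realistic bookkeeping*: daytime bouts (06:00–23:00), multi-hour gaps,
   sleep with zero steps, integer device outputs, step undercounting and
   multiplicative HR error with a calibrated mean absolute percentage
   error.

Each subject uses RNG seed ``config.seed + subject_index`` and is
therefore individually reproducible; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig

__all__ = ["GroundTruth", "generate_subject", "generate_cohort", "write_subject_files"]

_EPOCH = pd.Timestamp("2023-01-02 00:00:00")  # arbitrary fixed Monday
_WAKE_START = 6 * 60    # 06:00, minutes from midnight
_WAKE_END = 23 * 60     # 23:00 (sleep 23:00-06:00, steps forced to 0)
_SCHED_END = 22 * 60 + 30   # bouts truncated at 22:30
_HR_CAP = 185.0         # physiological ceiling for the cadence-driven target


@dataclass
class GroundTruth:
    """What the generator actually injected, for downstream validation.

    Attributes
    ----------
    minutes:
        One row per scheduled active minute: ``timestamp``, ``bout_id``,
        ``scheduled_cadence`` (the per-bout base cadence), ``entrained``.
    bouts:
        One row per scheduled bout: ``bout_id``, ``start``, ``end``,
        ``duration`` (inclusive minutes), ``base_cadence``,
        ``intensity_class``.
    resting_hr, ratio_base:
        Subject-level traits.
    """

    minutes: pd.DataFrame
    bouts: pd.DataFrame
    resting_hr: float
    ratio_base: float

    @property
    def entrained_timestamps(self) -> pd.DatetimeIndex:
        m = self.minutes
        return pd.DatetimeIndex(m.loc[m["entrained"], "timestamp"])

    @property
    def entrained_fraction(self) -> float:
        if len(self.minutes) == 0:
            return float("nan")
        return float(self.minutes["entrained"].mean())


def _intensity_of(cadence: float) -> str:
    if cadence >= 130:
        return "vigorous"
    if cadence >= 100:
        return "moderate"
    return "light"


def _schedule_day(rng: np.random.Generator, config: CohortConfig) -> list[tuple[int, int]]:
    """Bout (start_minute, duration) pairs for one day, non-overlapping."""
    n = rng.poisson(config.bout_rate)
    if n == 0:
        return []
    starts = np.sort(rng.integers(_WAKE_START, _SCHED_END - 5, size=n))
    durations = np.clip(
        np.round(rng.normal(config.bout_duration_mean, config.bout_duration_sd, size=n)),
        5, 180,
    ).astype(int)
    bouts: list[tuple[int, int]] = []
    prev_end = -(10 ** 6)
    for start, dur in zip(starts, durations):
        if start < prev_end + config.min_bout_spacing:
            continue
        dur = int(min(dur, _SCHED_END - start))
        if dur < 5:
            continue
        bouts.append((int(start), dur))
        prev_end = start + dur
    return bouts


def generate_subject(config: CohortConfig, subject_index: int):
    """Generate one subject's raw streams and ground truth.

    Returns
    -------
    hr_samples : pandas.DataFrame
        Columns ``timestamp`` (5-s resolution, 06:00–23:00 only — the
        device charges overnight) and ``bpm`` (int).
    sr_minutes : pandas.DataFrame
        Columns ``timestamp`` (minute resolution, full day) and
        ``steps`` (int; 0 during sleep hours).
    truth : GroundTruth
    """
    if config.days <= 0 or config.n_subjects <= 0:
        raise ValueError("days and n_subjects must be positive")
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError(f"subject_index {subject_index} out of range")

    rng = np.random.default_rng(config.seed + subject_index)
    resting_hr = float(rng.uniform(*config.resting_hr_range))
    ratio_base = float(np.clip(rng.normal(config.ratio_base_mean, config.ratio_base_sd),
                               0.89, 0.945))
    alpha = 1.0 - np.exp(-1.0 / config.hr_tau_minutes)

    n_min_day = 24 * 60
    total_minutes = config.days * n_min_day
    # per-minute state over the whole recording
    hr_true = np.full(total_minutes, np.nan)     # minute HR before sensor noise
    sr_true = np.zeros(total_minutes)            # minute step rate before sensor noise
    active = np.zeros(total_minutes, dtype=bool)
    entrained = np.zeros(total_minutes, dtype=bool)
    bout_id_arr = np.full(total_minutes, -1, dtype=int)
    sched_cadence = np.full(total_minutes, np.nan)

    bout_rows = []
    bout_counter = 0
    for day in range(config.days):
        day0 = day * n_min_day
        for start, dur in _schedule_day(rng, config):
            sl = slice(day0 + start, day0 + start + dur)
            base_cadence = float(rng.uniform(*config.cadence_range))
            cadence = np.clip(
                base_cadence + rng.normal(0.0, config.cadence_minute_sd, size=dur),
                60.0, _HR_CAP,
            )
            effort = rng.normal(0.0, config.effort_sd, size=dur)
            if config.hr_mode == "tracking":
                target = np.minimum(cadence / ratio_base, _HR_CAP) + effort
            else:
                target = resting_hr + config.hr_boost + effort
            # first-order response toward the target; the bout starts at
            # the target (no onset transient: a rise from resting HR would
            # sweep the ratio through 1 and register as spurious coupling)
            h = np.empty(dur)
            h[0] = target[0]
            for t in range(1, dur):
                h[t] = h[t - 1] + alpha * (target[t] - h[t - 1])
            flags = (rng.random(dur) < config.couple_fraction)
            if dur < config.entrain_min_bout_minutes:
                flags[:] = False
            hr_true[sl] = h
            sr_true[sl] = np.where(flags, h, cadence)
            active[sl] = True
            entrained[sl] = flags
            bout_id_arr[sl] = bout_counter
            sched_cadence[sl] = base_cadence
            bout_rows.append({
                "bout_id": bout_counter,
                "start": _EPOCH + pd.Timedelta(minutes=day0 + start),
                "end": _EPOCH + pd.Timedelta(minutes=day0 + start + dur - 1),
                "duration": dur,
                "base_cadence": base_cadence,
                "intensity_class": _intensity_of(base_cadence),
            })
            bout_counter += 1

    # rest (wake, non-bout) and sleep minutes
    minute_of_day = np.arange(total_minutes) % n_min_day
    wake = (minute_of_day >= _WAKE_START) & (minute_of_day < _WAKE_END)
    rest = wake & ~active
    hr_true[rest] = resting_hr + rng.normal(0.0, 2.0, size=int(rest.sum()))
    sr_true[rest] = rng.poisson(6.0, size=int(rest.sum()))

    # --- emit device streams ---------------------------------------------
    per_min = 60 // config.hr_sample_period
    wake_idx = np.flatnonzero(wake)
    hr_minute_vals = hr_true[wake_idx]
    samples = np.repeat(hr_minute_vals, per_min)
    if config.hr_noise_mape > 0:
        sigma = config.hr_noise_mape * np.sqrt(np.pi / 2.0)
        samples = samples * (1.0 + rng.normal(0.0, sigma, size=samples.size))
    bpm = np.clip(np.round(samples), 25, 230).astype(int)
    offsets = (np.repeat(wake_idx, per_min) * 60
               + np.tile(np.arange(per_min) * config.hr_sample_period, wake_idx.size))
    hr_samples = pd.DataFrame({
        "timestamp": _EPOCH + pd.to_timedelta(offsets, unit="s"),
        "bpm": bpm,
    })

    steps = sr_true * (1.0 + config.sr_bias)
    if config.sr_jitter_sd > 0:
        jitter = rng.normal(0.0, config.sr_jitter_sd, size=total_minutes)
        steps = np.where(sr_true > 0, steps + jitter, steps)
    steps = np.clip(np.round(steps), 0, 300).astype(int)
    sr_minutes = pd.DataFrame({
        "timestamp": _EPOCH + pd.to_timedelta(np.arange(total_minutes), unit="m"),
        "steps": steps,
    })

    minutes = pd.DataFrame({
        "timestamp": _EPOCH + pd.to_timedelta(np.flatnonzero(active), unit="m"),
        "bout_id": bout_id_arr[active],
        "scheduled_cadence": sched_cadence[active],
        "entrained": entrained[active],
    })
    bouts = pd.DataFrame(
        bout_rows,
        columns=["bout_id", "start", "end", "duration", "base_cadence", "intensity_class"],
    )
    truth = GroundTruth(minutes=minutes, bouts=bouts,
                        resting_hr=resting_hr, ratio_base=ratio_base)
    return hr_samples, sr_minutes, truth


# --- file output -----------------------------------------------------------

def _fitbit_time(ts: pd.Timestamp) -> str:
    return ts.strftime("%m/%d/%y %H:%M:%S")


def write_subject_files(hr_samples: pd.DataFrame, sr_minutes: pd.DataFrame,
                        truth: GroundTruth, subject_dir: Path,
                        dialects=("csv",)) -> dict:
    """Write one subject's streams plus the ground-truth sidecar.

    Returns a manifest fragment with file names and record counts.
    """
    subject_dir = Path(subject_dir)
    subject_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for dialect in dialects:
        if dialect == "csv":
            hr_path = subject_dir / "heart_rate.csv"
            out = hr_samples.copy()
            out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
            out.rename(columns={"bpm": "bpm"}).to_csv(hr_path, index=False)
            sr_path = subject_dir / "steps.csv"
            out = sr_minutes.copy()
            out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
            out.to_csv(sr_path, index=False)
        elif dialect == "fitbit-json":
            hr_path = subject_dir / "heart_rate.json"
            records = [
                {"dateTime": _fitbit_time(ts), "value": {"bpm": int(b), "confidence": 2}}
                for ts, b in zip(hr_samples["timestamp"], hr_samples["bpm"])
            ]
            hr_path.write_text(json.dumps(records))
            sr_path = subject_dir / "steps.json"
            records = [
                {"dateTime": _fitbit_time(ts), "value": str(int(s))}
                for ts, s in zip(sr_minutes["timestamp"], sr_minutes["steps"])
            ]
            sr_path.write_text(json.dumps(records))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        files[dialect] = {"heart_rate": hr_path.name, "steps": sr_path.name}

    gt = truth.minutes.copy()
    gt["timestamp"] = gt["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    gt = gt.rename(columns={"entrained": "entrained_flag"})
    gt.to_csv(subject_dir / "ground_truth.csv", index=False)

    return {
        "files": files,
        "ground_truth": "ground_truth.csv",
        "n_hr_samples": int(len(hr_samples)),
        "n_sr_minutes": int(len(sr_minutes)),
        "n_active_minutes": int(len(truth.minutes)),
        "n_entrained_minutes": int(truth.minutes["entrained"].sum()),
        "n_bouts": int(len(truth.bouts)),
        "resting_hr": round(truth.resting_hr, 4),
        "ratio_base": round(truth.ratio_base, 4),
    }


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_cohort(config: CohortConfig, output_dir, dialects=("csv",),
                    force: bool = False) -> dict:
    """Generate all subjects and write them under ``output_dir``.

    One subdirectory per subject (``subject_00`` ...), each containing the
    requested stream dialects and a ground-truth sidecar, plus a
    ``manifest.json`` at the top with per-subject seeds, record counts and
    file checksums.  Refuses to overwrite an existing manifest unless
    ``force`` is true.
    """
    output_dir = Path(output_dir)
    manifest_path = output_dir / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    output_dir.mkdir(parents=True, exist_ok=True)

    manifest = {
        "config": dataclasses.asdict(config),
        "dialects": list(dialects),
        "subjects": [],
    }
    for i in range(config.n_subjects):
        name = f"subject_{i:02d}"
        hr, sr, truth = generate_subject(config, i)
        entry = write_subject_files(hr, sr, truth, output_dir / name, dialects)
        entry.update({"name": name, "index": i, "seed": config.seed + i})
        entry["checksums"] = {
            f.name: _checksum(f) for f in sorted((output_dir / name).iterdir())
        }
        manifest["subjects"].append(entry)
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
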