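"""Configuration objects for simulation and analysis.

Two dataclasses hold every tunable threshold in the pipeline:
:class:`CohortConfig` for the synthetic cohort generator and
:class:`AnalysisConfig` for the analysis thresholds (activity filter,
coupling bands, intensity cuts, bout gap, grouping cut, histogram bins).

Configs round-trip through a flat ``key = value`` text format so a whole
run is reproducible from a single small file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the coupling analysis.

    Attributes
    ----------
    sr_threshold:
        Activity filter in steps/min; minutes with ``sr`` strictly below
        this are excluded ("below 60 steps/min" treated as keep ``sr >= 60``).
    clc_threshold, weak_threshold:
        Relative deviation bands: CLC if ``|SR - HR|/HR <= clc_threshold``,
        weak CLC if deviation is in ``(clc_threshold, weak_threshold]``.
    intensity_cuts:
        Cadence cuts (steps/min) separating light / moderate / vigorous.
    gap_minutes:
        A new activity bout starts when consecutive kept minutes are
        ``>= gap_minutes`` apart.
    d_cut:
        Grouping cut (percentage points) on D = occurrence(moderate)
        − occurrence(vigorous).
    bin_width, r_support:
        Coupling-ratio histogram: bin width (1% of R) and closed support;
        mass outside the support goes to two overflow bins.
    min_hr_samples:
        Minimum 5-s samples required to keep a minute-averaged HR value.
    age_split:
        Age (years) splitting the cohort into young (<) and older (>=).
    bout_class_min_share:
        A bout is labelled with the strongest coupling class reaching this
        share of its minutes, else with the modal class (ties to stronger).
    """

    sr_threshold: float = 60.0
    clc_threshold: float = 0.01
    weak_threshold: float = 0.10
    intensity_cuts: Tuple[float, float] = (100.0, 130.0)
    gap_minutes: float = 60.0
    d_cut: float = 1.5
    bin_width: float = 0.01
    r_support: Tuple[float, float] = (0.3, 3.0)
    min_hr_samples: int = 6
    age_split: float = 40.0
    bout_class_min_share: float = 0.20

    def __post_init__(self) -> None:
        if not (0 <= self.clc_threshold <= self.weak_threshold):
            raise ValueError("need 0 <= clc_threshold <= weak_threshold")
        lo, hi = self.intensity_cuts
        if not (self.sr_threshold <= lo < hi):
            raise ValueError("intensity cuts must satisfy sr_threshold <= moderate < vigorous")
        if self.gap_minutes <= 0 or self.bin_width <= 0:
            raise ValueError("gap_minutes and bin_width must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic wearable cohort.

    The generator emulates a wrist-worn device: per-minute step counts and
    5-second HR samples, daytime activity bouts, a tunable fraction of
    active minutes entrained at SR = HR, and device noise (multiplicative
    HR error with a target mean absolute percentage error, step
    undercounting bias and jitter).

    Attributes
    ----------
    n_subjects, days, seed:
        Cohort size and root RNG seed; subject ``i`` uses ``seed + i`` so
        subjects are independently reproducible.
    resting_hr_range:
        Uniform range (beats/min) for per-subject resting HR.
    bout_rate:
        Expected scheduled activity bouts per day (Poisson).
    bout_duration_mean, bout_duration_sd:
        Normal parameters (minutes) of bout duration, clipped to
        ``[5, 180]``.
    cadence_range:
        Uniform range (steps/min) for the per-bout base cadence; minute
        cadence wiggles around it with SD ``cadence_minute_sd``.
    couple_fraction:
        Probability that an active minute is entrained (underlying SR set
        equal to the minute-mean HR before sensor noise).
    hr_noise_mape:
        Target mean absolute percentage error of emitted 5-s HR samples
        (multiplicative, zero-mean Gaussian, sigma = mape * sqrt(pi/2)).
    sr_bias:
        Multiplicative step-count bias (negative = undercount).
    sr_jitter_sd:
        Additive step-count noise SD (steps/min) before integer rounding.
    hr_sample_period:
        Seconds between HR samples; must divide 60.
    hr_mode:
        ``"tracking"`` (default): minute HR follows cadence via a
        per-subject base ratio ``ratio_base`` so that SR/HR sits near
        ``ratio_base`` during activity.  ``"independent"``: active-minute
        HR is resting + ``hr_boost`` + noise, independent of concurrent
        cadence — the configuration used to calibrate the random-pairing
        null model.
    ratio_base_mean, ratio_base_sd:
        Subject-level SR/HR base ratio distribution (tracking mode),
        clipped to [0.89, 0.945] so non-entrained minutes stay clear of
        the ±1% CLC band even in the distribution's upper tail.
    effort_sd:
        Minute-level HR effort noise SD (beats/min).
    hr_boost:
        Activity HR rise over resting (beats/min, independent mode).
    hr_tau_minutes:
        First-order HR response time constant toward the within-bout target.
    entrain_min_bout_minutes:
        If > 0, entrainment only occurs in bouts at least this long.
    min_bout_spacing:
        Minimum minutes between the end of one scheduled bout and the
        start of the next.
    """

    n_subjects: int = 16
    days: int = 14
    seed: int = 0
    resting_hr_range: Tuple[float, float] = (47.0, 70.0)
    bout_rate: float = 3.0
    bout_duration_mean: float = 45.0
    bout_duration_sd: float = 25.0
    cadence_range: Tuple[float, float] = (70.0, 170.0)
    cadence_minute_sd: float = 2.0
    couple_fraction: float = 0.05
    hr_noise_mape: float = 0.11
    sr_bias: float = -0.03
    sr_jitter_sd: float = 2.0
    hr_sample_period: int = 5
    hr_mode: str = "tracking"
    ratio_base_mean: float = 0.92
    ratio_base_sd: float = 0.012
    effort_sd: float = 1.5
    hr_boost: float = 14.0
    hr_tau_minutes: float = 2.0
    entrain_min_bout_minutes: float = 0.0
    min_bout_spacing: float = 75.0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.days <= 0:
            raise ValueError("days must be positive")
        if not 0.0 <= self.couple_fraction <= 1.0:
            raise ValueError("couple_fraction must be in [0, 1]")
        lo, hi = self.cadence_range
        if not (60.0 <= lo <= hi <= 200.0):
            raise ValueError("cadence_range must lie within [60, 200]")
        if 60 % self.hr_sample_period != 0:
            raise ValueError("hr_sample_period must divide 60")
        if self.hr_mode not in ("tracking", "independent"):
            raise ValueError("hr_mode must be 'tracking' or 'independent'")

    def noiseless(self) -> "CohortConfig":
        """Copy of this config with all sensor noise switched off."""
        return dataclasses.replace(
            self, hr_noise_mape=0.0, sr_bias=0.0, sr_jitter_sd=0.0
        )


def independent_pairing_config(seed: int, *, n_subjects: int = 16, days: int = 14) -> CohortConfig:
    """Cohort configuration with no minute-level HR–SR dependence.

    Used to calibrate the random-pairing null model: with
    ``couple_fraction = 0`` and HR independent of concurrent cadence, the
    observed ratio distribution should be statistically indistinguishable
    from the null.  The marginals and activity volume are chosen so the
    weak∪CLC band probability is ~5% and each subject accumulates ~4,000
    active minutes over two weeks: large enough that per-subject band
    counts are approximately symmetric (so a signed-rank test across
    subjects stays calibrated), small enough that the binomial sampling
    error of the band probability stays well below 0.01.
    """
    return CohortConfig(
        n_subjects=n_subjects,
        days=days,
        seed=seed,
        couple_fraction=0.0,
        hr_mode="independent",
        resting_hr_range=(58.0, 62.0),
        bout_rate=5.0,
        bout_duration_mean=60.0,
        cadence_range=(100.0, 110.0),
        cadence_minute_sd=3.0,
        effort_sd=4.0,
        hr_boost=23.0,
    )


_TUPLE_FIELDS = {"resting_hr_range", "cadence_range", "intensity_cuts", "r_support"}


def _format_value(value) -> str:
    if isinstance(value, tuple):
        return ",".join(repr(v) for v in value)
    return repr(value)


def _parse_value(name: str, text: str, target_type):
    text = text.strip()
    if name in _TUPLE_FIELDS:
        return tuple(float(part) for part in text.split(","))
    if target_type is int:
        return int(text)
    if target_type is float:
        return float(text)
    return text.strip("'\"")


def save_config(config, path) -> None:
    """Write a config dataclass as flat ``key = value`` lines."""
    lines = [f"{f.name} = {_format_value(getattr(config, f.name))}"
             for f in dataclasses.fields(config)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path, cls=CohortConfig):
    """Read a flat ``key = value`` file into ``cls`` (unknown keys rejected)."""
    known = {f.name: f.type for f in dataclasses.fields(cls)}
    types = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        name, _, raw = line.partition("=")
        name = name.strip()
        if name not in known:
            raise ValueError(f"{path}:{lineno}: unknown key {name!r} for {cls.__name__}")
        default = types[name].default
        target = type(default) if default is not dataclasses.MISSING else float
        kwargs[name] = _parse_value(name, raw, target)
    return cls(**kwargs)
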