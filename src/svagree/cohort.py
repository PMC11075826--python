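"""Synthetic beat-level cohort generator.

Emulates a lower-body-negative-pressure (LBNP) protocol with alternating
isometric handgrip (IHG): subjects lie in an LBNP chamber whose pressure is
lowered in 20 mmHg steps every 6 minutes (0 to 80 mmHg, or until
hemodynamic decompensation).  Each 6-minute level consists of three
2-minute periods -- a stabilization period followed by IHG and rest in an
alternating order that is block-randomized across subjects and flips from
level to level.

Two stroke-volume "methods" are simulated per beat:

* ``sv_us`` -- Doppler-ultrasound-like stroke volume: the latent stroke
  volume plus beat-scale noise plus an independent 30-s-scale method error.
* ``sv_pwa`` -- pulse-wave-analysis-like stroke volume: the latent stroke
  volume plus a method discrepancy that grows with latent systemic
  vascular resistance (SVR), a subject-level random offset, a
  level-scale disagreement residual, plus its own beat- and bin-scale
  noise.

The discrepancy model is the generative counterpart of the mixed-model
agreement analysis in :mod:`svagree.agreement`: with all noise at zero the
per-beat difference is exactly
``delta0 + beta_svr * (SVR_latent - svr_ref) + subject_offset``.

The default parameter values are a frozen calibration: they were chosen
once, by simulation, so that the full pipeline (generate -> 30-s trimmed
bins -> mixed-model agreement analysis) reproduces the agreement estimates
of the reference study (see :mod:`svagree.reference` and
``docs/methods.md``).  They are deliberately not round numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng

from .errors import InvalidArgumentError

__all__ = [
    "ProtocolConfig",
    "SubjectProfile",
    "TrajectoryParams",
    "DiscrepancyParams",
    "Period",
    "ProtocolSchedule",
    "DEFAULT_DROPOUT",
    "BEAT_COLUMNS",
    "PROFILE_COLUMNS",
    "randomize_ihg_order",
    "build_schedule",
    "draw_profiles",
    "simulate_subject",
    "simulate_cohort",
    "synthesize_beat_waveforms",
]

PHASE_STABILIZATION = "stabilization"
PHASE_IHG = "ihg"
PHASE_REST = "rest"

BEAT_COLUMNS = [
    "subject_id", "sex", "t_onset", "rr", "lbnp", "level_index",
    "period_index", "phase", "period_time", "sv_us", "sv_pwa", "map",
]

PROFILE_COLUMNS = [
    "subject_id", "sex", "age", "height", "weight", "mvc",
    "ihg_first", "decompensation_level",
]

#: Default distribution of the highest completed LBNP level (mmHg), matching
#: the reference study's completion counts out of 16 subjects: all completed
#: 20 mmHg, 15 completed 40, 11 completed 60 and 2 completed 80.
DEFAULT_DROPOUT: dict[float, float] = {20.0: 1 / 16, 40.0: 4 / 16, 60.0: 9 / 16, 80.0: 2 / 16}


def _as_generator(rng_seed) -> Generator:
    if isinstance(rng_seed, Generator):
        return rng_seed
    return default_rng(rng_seed)


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and structure of the LBNP/IHG protocol.

    Each level lasts ``level_duration`` seconds and is divided into three
    ``period_duration``-second periods (stabilization, then IHG/rest in
    alternating order).
    """

    lbnp_levels: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0)
    level_duration: float = 360.0
    period_duration: float = 120.0
    block_sizes: tuple[int, ...] = (2, 4)
    mvc_fraction: float = 0.40

    def __post_init__(self):
        levels = tuple(float(x) for x in self.lbnp_levels)
        object.__setattr__(self, "lbnp_levels", levels)
        if len(levels) < 1 or any(x < 0 for x in levels):
            raise InvalidArgumentError("lbnp_levels must be non-negative")
        if any(b >= a for a, b in zip(levels[1:], levels[:-1])):
            raise InvalidArgumentError("lbnp_levels must be strictly increasing")
        if not math.isclose(self.level_duration, 3 * self.period_duration):
            raise InvalidArgumentError("level_duration must equal 3 x period_duration")
        if not self.block_sizes or any(b <= 0 or b % 2 for b in self.block_sizes):
            raise InvalidArgumentError("block sizes must be positive and even")
        if not 0 < self.mvc_fraction < 1:
            raise InvalidArgumentError("mvc_fraction must lie in (0, 1)")

    @property
    def n_periods_per_level(self) -> int:
        return int(round(self.level_duration / self.period_duration))


@dataclass(frozen=True)
class SubjectProfile:
    """One simulated volunteer."""

    subject_id: str
    sex: str                      # "female" | "male"
    age: float                    # years
    height: float                 # cm
    weight: float                 # kg
    mvc: float                    # newtons, mean of three attempts
    ihg_first: bool               # from block randomization
    decompensation_level: float   # highest completed LBNP level, mmHg

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise InvalidArgumentError(f"unknown sex: {self.sex!r}")
        if self.mvc <= 0:
            raise InvalidArgumentError("mvc must be positive")


@dataclass(frozen=True)
class TrajectoryParams:
    """Latent hemodynamic trajectories and measurement noise.

    Latent stroke volume falls linearly with level index, heart rate and
    MAP rise linearly with level index, and IHG adds a linear MAP ramp
    over the 2-minute handgrip period (peaking at ``map_ihg_boost`` at the
    end of the period).  SVR is emergent: MAP / (SV x HR / 1000).

    Noise enters at two scales: independent per-beat Gaussian noise
    (``beat_noise_sd``, ``map_beat_noise_sd``) and per-method Gaussian
    noise drawn once per 30-s bin and shared by all beats of the bin
    (``bin_noise_sd_us``, ``bin_noise_sd_pwa``).  Bin-scale noise is what
    survives 30-s aggregation, so the method-precision statistic (1.96 x
    residual SD of 30-s values at rest) recovers approximately
    1.96 x ``bin_noise_sd_*``.
    """

    sv_baseline: float = 81.0        # mL at LBNP 0
    sv_drop_per_level: float = 10.5  # mL per 20-mmHg level
    hr_baseline: float = 62.0        # bpm at LBNP 0
    hr_rise_per_level: float = 4.5   # bpm per level
    map_baseline: float = 85.0       # mmHg at LBNP 0, rest
    map_rise_per_level: float = 6.825  # mmHg per level (sympathetic activation)
    map_ihg_boost: float = 17.94     # mmHg at the end of a 2-min IHG period
    beat_noise_sd: float = 2.0       # mL, independent per beat
    map_beat_noise_sd: float = 1.5   # mmHg, independent per beat
    bin_noise_sd_us: float = 1.869   # mL, per 30-s bin (US method error)
    bin_noise_sd_pwa: float = 1.863  # mL, per 30-s bin (PWA method error)
    bin_noise_width: float = 30.0    # s, scale at which method noise is drawn
    rr_jitter_sd: float = 0.0        # s, optional R-R jitter

    def __post_init__(self):
        for name in ("sv_baseline", "hr_baseline", "map_baseline"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        for name in ("sv_drop_per_level", "hr_rise_per_level", "map_rise_per_level",
                     "map_ihg_boost", "beat_noise_sd", "map_beat_noise_sd",
                     "bin_noise_sd_us", "bin_noise_sd_pwa", "rr_jitter_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be non-negative")

    def latent_sv(self, level_index) -> np.ndarray:
        """Latent stroke volume (mL) at a level index."""
        return self.sv_baseline - self.sv_drop_per_level * np.asarray(level_index, float)

    def latent_hr(self, level_index) -> np.ndarray:
        """Latent heart rate (bpm) at a level index."""
        return self.hr_baseline + self.hr_rise_per_level * np.asarray(level_index, float)

    def latent_map(self, level_index, period_time, is_ihg, period_duration: float) -> np.ndarray:
        """Latent MAP (mmHg); IHG ramps linearly from 0 to ``map_ihg_boost``."""
        base = self.map_baseline + self.map_rise_per_level * np.asarray(level_index, float)
        ramp = np.where(np.asarray(is_ihg, bool),
                        self.map_ihg_boost * np.asarray(period_time, float) / period_duration,
                        0.0)
        return base + ramp

    def latent_svr(self, level_index, period_time, is_ihg, period_duration: float) -> np.ndarray:
        """Latent SVR (mmHg.min/L) implied by the latent SV, HR and MAP."""
        sv = self.latent_sv(level_index)
        hr = self.latent_hr(level_index)
        map_ = self.latent_map(level_index, period_time, is_ihg, period_duration)
        return map_ / (sv * hr / 1000.0)


@dataclass(frozen=True)
class DiscrepancyParams:
    """Generative model of the between-method difference.

    For a beat of subject ``i`` on level ``l``::

        diff(i, l, t) = delta0 + beta * (SVR_latent(t) - svr_ref)
                        + offset_i + epsilon(i, l)

    with ``offset_i ~ N(0, sigma_between^2)`` and ``epsilon ~ N(0,
    sigma_within^2)`` drawn once per completed LBNP level.  The
    level-scale placement of the disagreement residual makes it
    contribute to the within-subject limits of agreement (levels vary
    within a subject) without inflating the 30-s method precision at
    rest, mirroring how the two monitors' state-dependent disagreement
    behaves in practice; 30-s-scale method noise is separate
    (``bin_noise_sd_*`` in :class:`TrajectoryParams`).  ``beta`` is
    ``beta_svr`` unless both sex-specific slopes are set, in which case
    males use ``beta_svr_male`` and females ``beta_svr_female``.
    """

    delta0: float = 27.0          # mL at SVR = svr_ref
    beta_svr: float = 0.5626      # mL per mmHg.min/L
    svr_ref: float = 22.04        # mmHg.min/L, cohort-average latent SVR
    sigma_between: float = 13.99  # mL, SD of the subject offset
    sigma_within: float = 4.742   # mL, SD of the level-scale disagreement residual
    beta_svr_male: float | None = None
    beta_svr_female: float | None = None

    def __post_init__(self):
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise InvalidArgumentError("discrepancy SDs must be non-negative")
        if (self.beta_svr_male is None) != (self.beta_svr_female is None):
            raise InvalidArgumentError(
                "set both beta_svr_male and beta_svr_female, or neither")

    @property
    def sex_specific(self) -> bool:
        return self.beta_svr_male is not None

    def beta_for_sex(self, sex: str) -> float:
        if not self.sex_specific:
            return self.beta_svr
        return self.beta_svr_male if sex == "male" else self.beta_svr_female


#: Sex-specific discrepancy calibration (used for the exploratory
#: sex-interaction recovery): per-sex SVR slopes with the 9F/7M cohort mix
#: implying approximately the pooled default slope.
DEFAULT_SEX_SPECIFIC_DISCREPANCY = DiscrepancyParams(
    beta_svr_male=0.8154, beta_svr_female=0.3415)


@dataclass(frozen=True)
class Period:
    """One 2-minute protocol period."""

    lbnp: float
    level_index: int
    period_index: int   # 0, 1, 2 within the level
    phase: str          # stabilization | ihg | rest
    start: float        # s from protocol start
    end: float


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered periods for one subject, with IHG release times."""

    subject_id: str
    periods: tuple[Period, ...]
    ihg_release_times: tuple[float, ...]


def randomize_ihg_order(n_subjects: int, block_sizes: Iterable[int] = (2, 4),
                        rng_seed=None) -> list[bool]:
    """Block-randomized IHG-first flags.

    Blocks are drawn uniformly from ``block_sizes`` (all even); within a
    block exactly half the subjects start their first non-stabilization
    period with IHG.  The stream is truncated to ``n_subjects``, so the
    final block may be incomplete.
    """
    if n_subjects < 1:
        raise InvalidArgumentError("n_subjects must be >= 1")
    sizes = sorted(set(int(b) for b in block_sizes))
    if not sizes or any(b <= 0 or b % 2 for b in sizes):
        raise InvalidArgumentError("block sizes must be positive even integers")
    rng = _as_generator(rng_seed)
    flags: list[bool] = []
    while len(flags) < n_subjects:
        size = int(rng.choice(sizes))
        block = [True] * (size // 2) + [False] * (size // 2)
        rng.shuffle(block)
        flags.extend(block)
    return flags[:n_subjects]


def build_schedule(config: ProtocolConfig, profile: SubjectProfile) -> ProtocolSchedule:
    """Per-subject protocol schedule up to the decompensation level.

    Period 0 of every level is stabilization.  Periods 1 and 2 are IHG and
    rest; their order on the first level follows ``profile.ihg_first`` and
    flips on every subsequent level.
    """
    if profile.decompensation_level not in config.lbnp_levels:
        raise InvalidArgumentError(
            f"decompensation_level {profile.decompensation_level} is not a protocol level")
    periods: list[Period] = []
    releases: list[float] = []
    for li, lbnp in enumerate(config.lbnp_levels):
        if lbnp > profile.decompensation_level:
            break
        level_start = li * config.level_duration
        ihg_in_period_1 = profile.ihg_first == (li % 2 == 0)
        phases = [PHASE_STABILIZATION]
        phases += [PHASE_IHG, PHASE_REST] if ihg_in_period_1 else [PHASE_REST, PHASE_IHG]
        for pi, phase in enumerate(phases):
            start = level_start + pi * config.period_duration
            end = start + config.period_duration
            periods.append(Period(lbnp, li, pi, phase, start, end))
            if phase == PHASE_IHG:
                releases.append(end)
    return ProtocolSchedule(profile.subject_id, tuple(periods), tuple(releases))


def draw_profiles(n_subjects: int, config: ProtocolConfig | None = None,
                  dropout_dist: Mapping[float, float] | None = None,
                  rng_seed=None,
                  female_pattern_period: int = 16,
                  n_female_per_period: int = 9) -> list[SubjectProfile]:
    """Draw subject profiles: anthropometrics, MVC, IHG order, stop level.

    Sex follows a fixed 9-females-per-16-subjects pattern (the reference
    cohort mix) so cohorts of any size keep the same sex proportion.
    Anthropometric sampling uses the reference cohort's summary statistics
    (age 24 +/- 3 y, height 177 +/- 11 cm, weight 71 +/- 14 kg).
    """
    if n_subjects < 1:
        raise InvalidArgumentError("n_subjects must be >= 1")
    config = config or ProtocolConfig()
    dist = _validate_dropout(dropout_dist, config)
    rng = _as_generator(rng_seed)
    ihg_first = randomize_ihg_order(n_subjects, config.block_sizes, rng)
    stop_levels = list(dist.keys())
    stop_probs = list(dist.values())
    profiles = []
    width = max(3, len(str(n_subjects)))
    for i in range(n_subjects):
        sex = "female" if (i % female_pattern_period) < n_female_per_period else "male"
        age = float(np.clip(rng.normal(24.0, 3.0), 18.0, 45.0))
        height = float(np.clip(rng.normal(177.0, 11.0), 150.0, 205.0))
        weight = float(np.clip(rng.normal(71.0, 14.0), 45.0, 120.0))
        attempts = rng.normal(300.0 if sex == "male" else 220.0, 30.0, size=3)
        attempts = np.clip(attempts, 50.0, None)
        mvc = float(attempts.mean())
        stop = float(rng.choice(stop_levels, p=stop_probs))
        profiles.append(SubjectProfile(
            subject_id=f"S{i + 1:0{width}d}", sex=sex, age=age, height=height,
            weight=weight, mvc=mvc, ihg_first=bool(ihg_first[i]),
            decompensation_level=stop))
    return profiles


def _validate_dropout(dropout_dist, config: ProtocolConfig) -> dict[float, float]:
    if dropout_dist is None:
        dropout_dist = {k: v for k, v in DEFAULT_DROPOUT.items() if k in config.lbnp_levels}
    dist = {float(k): float(v) for k, v in dropout_dist.items()}
    if not dist:
        raise InvalidArgumentError("dropout_dist must not be empty")
    eligible = [x for x in config.lbnp_levels if x >= 20.0] or list(config.lbnp_levels)
    if any(k not in eligible for k in dist):
        raise InvalidArgumentError("dropout levels must be protocol levels >= 20 mmHg")
    if not math.isclose(sum(dist.values()), 1.0, abs_tol=1e-9):
        raise InvalidArgumentError("dropout_dist must sum to 1")
    return dist


def simulate_subject(config: ProtocolConfig, profile: SubjectProfile,
                     traj: TrajectoryParams, disc: DiscrepancyParams,
                     rng_seed=None) -> pd.DataFrame:
    """Simulate one subject's beat series.

    Beats tile each 2-minute period; the first beat of a period starts at
    the period boundary, R-R intervals come from the latent heart rate
    (plus optional jitter), and no beat onset crosses into the next
    period.  Returns a frame with :data:`BEAT_COLUMNS`.
    """
    deepest = len([x for x in config.lbnp_levels if x <= profile.decompensation_level]) - 1
    if traj.latent_sv(deepest) <= 0:
        raise InvalidArgumentError(
            "trajectory drives latent stroke volume <= 0 at the deepest level")
    rng = _as_generator(rng_seed)
    schedule = build_schedule(config, profile)
    subject_offset = rng.normal(0.0, disc.sigma_between)
    eps_level = rng.normal(0.0, disc.sigma_within, size=deepest + 1)
    beta = disc.beta_for_sex(profile.sex)
    frames = []
    for per in schedule.periods:
        hr = float(traj.latent_hr(per.level_index))
        rr_nominal = 60.0 / hr
        n_max = int(math.ceil(config.period_duration / rr_nominal)) + 8
        if traj.rr_jitter_sd > 0:
            rr = rr_nominal + rng.normal(0.0, traj.rr_jitter_sd, size=n_max)
            rr = np.clip(rr, 0.3, 3.0)
        else:
            rr = np.full(n_max, rr_nominal)
        onsets = per.start + np.concatenate(([0.0], np.cumsum(rr[:-1])))
        keep = onsets < per.end - 1e-9
        onsets, rr = onsets[keep], rr[keep]
        n = onsets.size
        period_time = onsets - per.start
        is_ihg = per.phase == PHASE_IHG
        sv_lat = float(traj.latent_sv(per.level_index))
        map_lat = traj.latent_map(per.level_index, period_time, is_ihg,
                                  config.period_duration)
        svr_lat = map_lat / (sv_lat * hr / 1000.0)

        n_bins = int(math.ceil(config.period_duration / traj.bin_noise_width))
        bin_idx = np.minimum((period_time / traj.bin_noise_width).astype(int), n_bins - 1)
        e_us = rng.normal(0.0, traj.bin_noise_sd_us, size=n_bins)[bin_idx]
        e_pwa = rng.normal(0.0, traj.bin_noise_sd_pwa, size=n_bins)[bin_idx]

        sv_us = sv_lat + rng.normal(0.0, traj.beat_noise_sd, size=n) + e_us
        discrepancy = (disc.delta0 + beta * (svr_lat - disc.svr_ref)
                       + subject_offset + eps_level[per.level_index])
        sv_pwa = (sv_lat + rng.normal(0.0, traj.beat_noise_sd, size=n)
                  + e_pwa + discrepancy)
        map_obs = map_lat + rng.normal(0.0, traj.map_beat_noise_sd, size=n)

        frames.append(pd.DataFrame({
            "subject_id": profile.subject_id, "sex": profile.sex,
            "t_onset": onsets, "rr": rr, "lbnp": per.lbnp,
            "level_index": per.level_index, "period_index": per.period_index,
            "phase": per.phase, "period_time": period_time,
            "sv_us": sv_us, "sv_pwa": sv_pwa, "map": map_obs,
        }))
    return pd.concat(frames, ignore_index=True)[BEAT_COLUMNS]


def simulate_cohort(n_subjects: int, config: ProtocolConfig | None = None,
                    traj: TrajectoryParams | None = None,
                    disc: DiscrepancyParams | None = None,
                    dropout_dist: Mapping[float, float] | None = None,
                    rng_seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Returns ``(beats, profiles)`` frames.  Reproducible: the same
    ``rng_seed`` yields bit-identical output.  Per-subject randomness uses
    independent child streams of the seed, so individual subjects are
    stable under changes of ``n_subjects`` beyond their index.
    """
    if n_subjects < 1:
        raise InvalidArgumentError("n_subjects must be >= 1")
    config = config or ProtocolConfig()
    traj = traj or TrajectoryParams()
    disc = disc or DiscrepancyParams()
    ss = SeedSequence(rng_seed) if not isinstance(rng_seed, SeedSequence) else rng_seed
    profile_seed, *subject_seeds = ss.spawn(n_subjects + 1)
    profiles = draw_profiles(n_subjects, config, dropout_dist,
                             default_rng(profile_seed))
    beats = pd.concat(
        [simulate_subject(config, prof, traj, disc, default_rng(child))
         for prof, child in zip(profiles, subject_seeds)],
        ignore_index=True)
    prof_df = pd.DataFrame([{
        "subject_id": p.subject_id, "sex": p.sex, "age": p.age,
        "height": p.height, "weight": p.weight, "mvc": p.mvc,
        "ihg_first": p.ihg_first, "decompensation_level": p.decompensation_level,
    } for p in profiles])[PROFILE_COLUMNS]
    return beats, prof_df


def schedules_for_profiles(config: ProtocolConfig,
                           profiles: Iterable[SubjectProfile] | pd.DataFrame
                           ) -> dict[str, ProtocolSchedule]:
    """Build the per-subject schedules for a cohort (profiles or frame)."""
    if isinstance(profiles, pd.DataFrame):
        profiles = [SubjectProfile(
            subject_id=r.subject_id, sex=r.sex, age=r.age, height=r.height,
            weight=r.weight, mvc=r.mvc, ihg_first=bool(r.ihg_first),
            decompensation_level=float(r.decompensation_level))
            for r in profiles.itertuples()]
    return {p.subject_id: build_schedule(config, p) for p in profiles}


def synthesize_beat_waveforms(beat, sampling_rate: float = 1000.0,
                              lvot_area_cm2: float = 3.5,
                              pulse_pressure: float = 40.0
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize per-beat pressure and velocity traces for one beat record.

    Fixture plumbing for testing the waveform-level operations: produces a
    pressure trace (mmHg) whose time-weighted mean reproduces ``beat.map``
    and a velocity trace (m/s) whose velocity-time integral times
    ``lvot_area_cm2`` reproduces ``beat.sv_us``, both within 0.5%.

    ``beat`` is any object (e.g. a beats-frame row) with ``rr`` (s),
    ``map`` (mmHg) and ``sv_us`` (mL) attributes.
    """
    if sampling_rate < 100.0:
        raise InvalidArgumentError("sampling_rate must be >= 100 Hz")

    def _field(name):
        try:
            return float(beat[name])  # mapping / Series row
        except (TypeError, KeyError, IndexError):
            return float(getattr(beat, name))

    rr = _field("rr")
    n = int(round(rr * sampling_rate))
    if n < 2:
        raise InvalidArgumentError("beat shorter than 2 samples")
    t = np.arange(n) / sampling_rate
    duration = t[-1]

    # Pressure: MAP plus a systolic bump made exactly zero-mean in the
    # trapezoidal sense, so the time-weighted integral equals MAP.
    t_sys = min(0.3, rr / 3.0)
    bump = np.where(t < t_sys, np.sin(np.pi * t / t_sys), 0.0)
    bump_mean = np.trapezoid(bump, t) / duration
    pressure = _field("map") + pulse_pressure * (bump - bump_mean)

    # Velocity: half-sine ejection scaled so that the discrete VTI times
    # the LVOT area reproduces sv_us exactly.
    t_ej = min(0.3, rr / 3.0)
    vel = np.where(t < t_ej, np.sin(np.pi * t / t_ej), 0.0)
    vti_raw_cm = np.trapezoid(vel, t) * 100.0
    target_vti_cm = _field("sv_us") / lvot_area_cm2
    velocity = vel * (target_vti_cm / vti_raw_cm)
    return pressure, velocity
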