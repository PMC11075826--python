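"""Beat-level processing: waveform-derived variables, protocol-driven
exclusions, and 30-s trimmed-mean aggregation.

The analysis unit is the 30-s bin, aligned to the start of each 2-minute
protocol period.  Per bin, stroke volume (both methods), MAP and
instantaneous heart rate (60/RR) are summarized with a symmetric trimmed
mean (default: the ceil(5% n) highest and lowest beats per tail, per
variable independently).  Cardiac output, SVR, the between-method
difference and the mean of methods are derived per bin.

Exclusion rules applied before binning:

* beats within 30 s after each IHG release (rapid post-release
  transients),
* all beats on LBNP levels a subject did not complete.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import hemodynamics
from .cohort import ProtocolSchedule
from .errors import DataIntegrityError, InvalidArgumentError

__all__ = [
    "LvotGeometry",
    "BIN_COLUMNS",
    "time_weighted_map",
    "velocity_time_integral",
    "lvot_area",
    "sv_from_vti",
    "trimmed_mean",
    "exclude_post_ihg",
    "drop_incomplete_levels",
    "bin_30s",
]

logger = logging.getLogger(__name__)

BIN_COLUMNS = [
    "subject_id", "sex", "lbnp", "level_index", "phase", "bin_start",
    "period_time_bin", "n_beats_used", "sv_us", "sv_pwa", "hr", "map",
    "co_us", "svr_us", "diff", "mean",
]


@dataclass(frozen=True)
class LvotGeometry:
    """Left ventricular outflow tract geometry (circular cross-section)."""

    diameter: float  # cm, inner edge to inner edge

    def __post_init__(self):
        if self.diameter <= 0:
            raise InvalidArgumentError("LVOT diameter must be positive")

    @property
    def area(self) -> float:
        """Cross-sectional area, cm^2."""
        return lvot_area(self.diameter)


def lvot_area(diameter_cm: float) -> float:
    """Circular LVOT cross-sectional area, cm^2, from the diameter in cm."""
    if diameter_cm <= 0:
        raise InvalidArgumentError("diameter must be positive")
    return math.pi * (diameter_cm / 2.0) ** 2


def sv_from_vti(vti_cm: float, area_cm2: float) -> float:
    """Stroke volume (mL) as VTI (cm) x LVOT area (cm^2)."""
    if vti_cm < 0:
        raise InvalidArgumentError("VTI must be non-negative")
    if area_cm2 <= 0:
        raise InvalidArgumentError("LVOT area must be positive")
    return float(vti_cm * area_cm2)


def _slice_window(trace, sampling_rate, window):
    trace = np.asarray(trace, dtype=float)
    if sampling_rate <= 0:
        raise InvalidArgumentError("sampling_rate must be positive")
    if window is not None:
        t0, t1 = window
        i0 = int(math.ceil(t0 * sampling_rate - 1e-9))
        i1 = int(math.ceil(t1 * sampling_rate - 1e-9))  # half-open [t0, t1)
        if i0 < 0 or i1 > trace.size:
            raise InvalidArgumentError("window extends beyond the trace")
        trace = trace[i0:i1]
    if trace.size < 2:
        raise InvalidArgumentError("window must contain at least 2 samples")
    return trace


def time_weighted_map(pressure_mmhg, sampling_rate: float,
                      window: tuple[float, float] | None = None) -> float:
    """Time-weighted mean of an arterial pressure trace over a beat window.

    Computes (integral of p dt) / duration by the trapezoidal rule over
    the samples in the half-open window ``[t0, t1)`` (seconds), or the
    whole trace when ``window`` is None.
    """
    p = _slice_window(pressure_mmhg, sampling_rate, window)
    t = np.arange(p.size) / sampling_rate
    return float(np.trapezoid(p, t) / t[-1])


def velocity_time_integral(velocity_m_s, sampling_rate: float,
                           window: tuple[float, float] | None = None) -> float:
    """Velocity-time integral (cm) of the forward part of a velocity trace.

    Negative samples (diastolic backflow or noise) are clipped to zero
    before integration.  An all-negative trace yields 0 with a logged
    warning.
    """
    v = _slice_window(velocity_m_s, sampling_rate, window)
    if np.all(v < 0):
        logger.warning("velocity trace is entirely negative; VTI set to 0")
        return 0.0
    v = np.clip(v, 0.0, None)
    t = np.arange(v.size) / sampling_rate
    return float(np.trapezoid(v, t) * 100.0)  # m -> cm


def trimmed_mean(values, trim_fraction: float = 0.05) -> float:
    """Symmetric trimmed mean with per-tail count ceil(trim_fraction x n).

    Removes the k largest and k smallest values, k = ceil(trim_fraction x
    n), so trimming stays active for the ~25-50 beats of a 30-s bin.
    Falls back to the plain mean if trimming would remove everything.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidArgumentError("cannot take the trimmed mean of an empty list")
    if not 0 <= trim_fraction < 0.5:
        raise InvalidArgumentError("trim_fraction must lie in [0, 0.5)")
    k = math.ceil(trim_fraction * v.size)
    if 2 * k >= v.size:
        return float(v.mean())
    if k == 0:
        return float(v.mean())
    v = np.sort(v)
    return float(v[k:v.size - k].mean())


def _grouped_trimmed_mean(codes: np.ndarray, values: np.ndarray, n_groups: int,
                          trim_fraction: float) -> np.ndarray:
    """Vectorized per-group trimmed mean (same rule as :func:`trimmed_mean`).

    ``codes`` must be group codes in [0, n_groups); groups must be
    non-empty.  Sorts values within groups once, then uses prefix sums.
    """
    order = np.lexsort((values, codes))
    vs = values[order]
    counts = np.bincount(codes, minlength=n_groups)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    cs = np.concatenate(([0.0], np.cumsum(vs)))
    k = np.ceil(trim_fraction * counts).astype(int)
    k = np.where(2 * k >= counts, 0, k)  # fall back to plain mean
    lo = starts + k
    hi = starts + counts - k
    return (cs[hi] - cs[lo]) / (counts - 2 * k)


def _release_times_by_subject(schedule) -> Mapping[str, Iterable[float]]:
    if isinstance(schedule, ProtocolSchedule):
        return {schedule.subject_id: schedule.ihg_release_times}
    if isinstance(schedule, Mapping):
        out = {}
        for key, val in schedule.items():
            out[key] = val.ihg_release_times if isinstance(val, ProtocolSchedule) else val
        return out
    if isinstance(schedule, Iterable):
        return {s.subject_id: s.ihg_release_times for s in schedule}
    raise InvalidArgumentError("cannot extract IHG release times from schedule")


def exclude_post_ihg(beats: pd.DataFrame, schedule,
                     exclusion_window: float = 30.0) -> pd.DataFrame:
    """Drop beats within ``[release, release + window)`` of any IHG release.

    ``schedule`` may be a :class:`~svagree.cohort.ProtocolSchedule`, an
    iterable of them, or a mapping ``subject_id -> release times``.
    Membership is by beat onset, half-open window.
    """
    if beats.empty:
        return beats.copy()
    releases = _release_times_by_subject(schedule)
    drop = np.zeros(len(beats), dtype=bool)
    t = beats["t_onset"].to_numpy(float)
    indices = beats.groupby("subject_id", sort=False, observed=True).indices
    for subject, idx in indices.items():
        for rel in releases.get(subject, ()):
            sub_t = t[idx]
            drop[idx[(sub_t >= rel) & (sub_t < rel + exclusion_window)]] = True
    return beats.loc[~drop].reset_index(drop=True)


def drop_incomplete_levels(beats: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Keep only beats on levels at or below each subject's stop level."""
    if beats.empty:
        return beats.copy()
    known = set(profiles["subject_id"])
    unknown = set(beats["subject_id"]) - known
    if unknown:
        raise InvalidArgumentError(f"unknown subject ids in beats: {sorted(unknown)}")
    stop = beats["subject_id"].map(
        profiles.set_index("subject_id")["decompensation_level"])
    return beats.loc[beats["lbnp"].to_numpy(float) <= stop.to_numpy(float)].reset_index(drop=True)


def bin_30s(beats: pd.DataFrame, schedule=None, bin_width: float = 30.0,
            trim_fraction: float = 0.05, min_beats: int = 5,
            period_duration: float = 120.0) -> pd.DataFrame:
    """Aggregate beats into 30-s bins aligned to period starts.

    Per (subject, period, bin): trimmed means of ``sv_us``, ``sv_pwa``,
    ``map`` and of instantaneous heart rate 60/RR; bins with fewer than
    ``min_beats`` beats are dropped with a logged warning.  Derived
    columns follow the bin-record invariants: ``co_us = sv_us x hr /
    1000``, ``svr_us = map / co_us``, ``diff = sv_pwa - sv_us``,
    ``mean = (sv_pwa + sv_us) / 2``.

    ``schedule`` is optional and only used to validate that protocol
    periods do not overlap (a :class:`DataIntegrityError` otherwise).
    """
    if schedule is not None:
        for sched in _iter_schedules(schedule):
            periods = sorted(sched.periods, key=lambda p: p.start)
            for a, b in zip(periods, periods[1:]):
                if b.start < a.end - 1e-9:
                    raise DataIntegrityError(
                        f"overlapping periods for subject {sched.subject_id}")
    if beats.empty:
        return pd.DataFrame(columns=BIN_COLUMNS)
    if bin_width <= 0:
        raise InvalidArgumentError("bin_width must be positive")

    df = beats
    period_start = df["t_onset"].to_numpy(float) - df["period_time"].to_numpy(float)
    period_id = np.round(period_start / period_duration).astype(int)
    bin_idx = np.floor(df["period_time"].to_numpy(float) / bin_width).astype(int)

    subj_codes, _ = pd.factorize(df["subject_id"], sort=True)
    p_span = int(period_id.max()) + 1
    b_span = int(bin_idx.max()) + 1
    combo = (subj_codes.astype(np.int64) * p_span + period_id) * b_span + bin_idx
    _, codes = np.unique(combo, return_inverse=True)  # codes ordered by (subject, period, bin)
    n_groups = int(codes.max()) + 1

    counts = np.bincount(codes, minlength=n_groups)
    agg = {}
    hr_inst = 60.0 / df["rr"].to_numpy(float)
    for name, vals in (("sv_us", df["sv_us"].to_numpy(float)),
                       ("sv_pwa", df["sv_pwa"].to_numpy(float)),
                       ("map", df["map"].to_numpy(float)),
                       ("hr", hr_inst)):
        agg[name] = _grouped_trimmed_mean(codes, vals, n_groups, trim_fraction)

    first = np.zeros(n_groups, dtype=int)
    first[codes[::-1]] = np.arange(len(codes))[::-1]  # first row index per group
    out = pd.DataFrame({
        "subject_id": df["subject_id"].to_numpy()[first],
        "sex": df["sex"].to_numpy()[first],
        "lbnp": df["lbnp"].to_numpy(float)[first],
        "level_index": df["level_index"].to_numpy(int)[first],
        "phase": df["phase"].to_numpy()[first],
        "bin_start": period_start[first] + bin_idx[first] * bin_width,
        "period_time_bin": bin_idx[first],
        "n_beats_used": counts,
        "sv_us": agg["sv_us"], "sv_pwa": agg["sv_pwa"],
        "hr": agg["hr"], "map": agg["map"],
    })
    sparse = out["n_beats_used"] < min_beats
    if sparse.any():
        logger.warning("dropping %d bins with fewer than %d beats",
                       int(sparse.sum()), min_beats)
        out = out.loc[~sparse].reset_index(drop=True)

    out["co_us"] = hemodynamics.cardiac_output(out["sv_us"], out["hr"])
    out["svr_us"] = hemodynamics.svr(out["map"], out["co_us"])
    out["diff"] = out["sv_pwa"] - out["sv_us"]
    out["mean"] = (out["sv_pwa"] + out["sv_us"]) / 2.0
    out = out.sort_values(["subject_id", "bin_start"], kind="stable").reset_index(drop=True)
    return out[BIN_COLUMNS]


def _iter_schedules(schedule):
    if isinstance(schedule, ProtocolSchedule):
        return [schedule]
    if isinstance(schedule, Mapping):
        return [v for v in schedule.values() if isinstance(v, ProtocolSchedule)]
    return list(schedule)
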