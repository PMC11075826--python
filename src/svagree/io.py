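"""File formats and run configuration.

CSV files are UTF-8 with a header row, '.' decimal and a fixed column
order; all timestamps are seconds from protocol start.  Results are
serialized to JSON with units embedded per field.  The run configuration
is a YAML (or JSON) key-value file mirroring the parameter dataclasses.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, beats, cohort
from .errors import DataFormatError, InvalidArgumentError
from .pipeline import AnalysisOptions

__all__ = [
    "RunConfig", "load_config",
    "write_beats", "read_beats", "write_subjects", "read_subjects",
    "write_bins", "read_bins", "write_results", "write_plot_data",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 0
    n_subjects: int = 16
    protocol: cohort.ProtocolConfig = field(default_factory=cohort.ProtocolConfig)
    trajectory: cohort.TrajectoryParams = field(default_factory=cohort.TrajectoryParams)
    discrepancy: cohort.DiscrepancyParams = field(default_factory=cohort.DiscrepancyParams)
    dropout: dict[float, float] | None = None
    options: AnalysisOptions = field(default_factory=AnalysisOptions)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "protocol": dataclasses.asdict(self.protocol),
            "trajectory": dataclasses.asdict(self.trajectory),
            "discrepancy": dataclasses.asdict(self.discrepancy),
            "dropout": self.dropout,
            "options": dataclasses.asdict(self.options),
        }


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML/JSON key-value file.

    Unknown keys raise :class:`InvalidArgumentError`; missing blocks fall
    back to the calibrated defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    def build(cls, block):
        if block is None:
            return cls()
        if not isinstance(block, dict):
            raise InvalidArgumentError(f"expected a mapping for {cls.__name__}")
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block) - names
        if unknown:
            raise InvalidArgumentError(
                f"unknown keys for {cls.__name__}: {sorted(unknown)}")
        coerced = {}
        for k, v in block.items():
            coerced[k] = tuple(v) if isinstance(v, list) else v
        return cls(**coerced)

    known = {"seed", "n_subjects", "protocol", "trajectory", "discrepancy",
             "dropout", "options"}
    unknown = set(raw) - known
    if unknown:
        raise InvalidArgumentError(f"unknown top-level config keys: {sorted(unknown)}")
    dropout = raw.get("dropout")
    if dropout is not None:
        dropout = {float(k): float(v) for k, v in dropout.items()}
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        n_subjects=int(raw.get("n_subjects", 16)),
        protocol=build(cohort.ProtocolConfig, raw.get("protocol")),
        trajectory=build(cohort.TrajectoryParams, raw.get("trajectory")),
        discrepancy=build(cohort.DiscrepancyParams, raw.get("discrepancy")),
        dropout=dropout,
        options=build(AnalysisOptions, raw.get("options")),
    )


def _write_csv(df: pd.DataFrame, path, columns):
    df[columns].to_csv(path, index=False, encoding="utf-8")


def _read_csv(path, required, kind) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    for col in required:
        if col not in df.columns:
            raise DataFormatError(f"{kind} file {path} is missing column {col!r}",
                                  column=col)
    return df


def write_beats(df, path):
    _write_csv(df, path, cohort.BEAT_COLUMNS)


def read_beats(path) -> pd.DataFrame:
    return _read_csv(path, cohort.BEAT_COLUMNS, "beats")


def write_subjects(df, path):
    _write_csv(df, path, cohort.PROFILE_COLUMNS)


def read_subjects(path) -> pd.DataFrame:
    return _read_csv(path, cohort.PROFILE_COLUMNS, "subjects")


def write_bins(df, path):
    _write_csv(df, path, beats.BIN_COLUMNS)


def read_bins(path) -> pd.DataFrame:
    return _read_csv(path, beats.BIN_COLUMNS, "bins")


def _lmm_dict(lmm: agreement.LmmFit) -> dict:
    return {
        "fixed_effects": {
            term: {k: _num(v) for k, v in row.items()}
            for term, row in lmm.fixed_effects.iterrows()
        },
        "sigma_between_ml": _num(lmm.sigma_between),
        "sigma_level_ml": _num(lmm.sigma_level),
        "sigma_resid_ml": _num(lmm.sigma_resid),
        "n_obs": int(lmm.n_obs),
        "n_subjects": int(lmm.n_subjects),
        "restricted_loglike": _num(lmm.loglike),
        "formula": lmm.formula,
    }


def _num(x):
    x = float(x)
    return None if not np.isfinite(x) else x


def results_to_dict(fits: dict) -> dict:
    """Serialize the analysis fits to a JSON-ready dict with units."""
    ba = fits["bland_altman"]
    out = {
        "bland_altman": {
            "bias_ml": _num(ba.bias),
            "loa_half_width_ml": _num(ba.loa_half_width),
            "ws_loa_half_width_ml": _num(ba.ws_loa_half_width),
            "percentage_error_pct": _num(ba.percentage_error),
            "grand_mean_of_methods_ml": _num(ba.grand_mean_of_methods),
            "lmm": _lmm_dict(ba.lmm),
        },
    }
    for key in ("sloped_bias", "svr", "svr_sex", "time_proxy"):
        cf = fits[key]
        entry = {
            "slope": _num(cf.slope),
            "slope_ci": [_num(cf.slope_ci[0]), _num(cf.slope_ci[1])],
            "slope_p": _num(cf.slope_p),
            "slope_units": cf.slope_units,
            "lmm": _lmm_dict(cf.lmm),
        }
        if cf.loa_half_width is not None:
            entry["loa_half_width_ml"] = _num(cf.loa_half_width)
            entry["ws_loa_half_width_ml"] = _num(cf.ws_loa_half_width)
            entry["percentage_error_pct"] = _num(cf.percentage_error)
        if cf.sex_slopes is not None:
            entry["sex_slopes"] = {
                sex: {k: _num(v) for k, v in row.items()}
                for sex, row in cf.sex_slopes.iterrows()
            }
        out[key] = entry
    for key in ("precision_us", "precision_pwa"):
        pr = fits[key]
        out[key] = {"method": pr.method, "half_width_ml": _num(pr.half_width),
                    "lmm": _lmm_dict(pr.lmm)}
    return out


def write_results(fits: dict, path):
    Path(path).write_text(json.dumps(results_to_dict(fits), indent=2) + "\n",
                          encoding="utf-8")


def write_plot_data(bins: pd.DataFrame, fits: dict, path):
    """Plot-ready CSV to redraw the Bland-Altman figure.

    One row per analysis bin: mean, diff, subject, the fitted bias line
    (constant and sloped), and the LOA / within-subject LOA lines.
    """
    ba = fits["bland_altman"]
    sb = fits["sloped_bias"]
    sloped_line = (sb.lmm.coef("Intercept") + sb.slope * bins["mean"])
    df = pd.DataFrame({
        "subject_id": bins["subject_id"],
        "mean_ml": bins["mean"],
        "diff_ml": bins["diff"],
        "bias_ml": ba.bias,
        "loa_low_ml": ba.bias - ba.loa_half_width,
        "loa_high_ml": ba.bias + ba.loa_half_width,
        "ws_loa_low_ml": ba.bias - ba.ws_loa_half_width,
        "ws_loa_high_ml": ba.bias + ba.ws_loa_half_width,
        "sloped_bias_ml": sloped_line,
        "sloped_loa_low_ml": sloped_line - sb.loa_half_width,
        "sloped_loa_high_ml": sloped_line + sb.loa_half_width,
    })
    df.to_csv(path, index=False, encoding="utf-8")
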