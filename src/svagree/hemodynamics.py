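"""Derived hemodynamic quantities.

Small, exactly testable formulas shared by the synthetic-cohort generator
and the beat-processing pipeline:

* cardiac output as stroke volume x heart rate,
* systemic vascular resistance (SVR) as mean arterial pressure over
  cardiac output, with central venous pressure (CVP) assumed constant at
  zero by default,
* body surface area (Du Bois by default, Mosteller optionally),
* BSA-indexed stroke volume,
* the isometric-handgrip target force as a fraction of the maximal
  voluntary contraction (MVC), where MVC is the mean of three attempts.

All functions are pure, accept scalars or numpy arrays, and raise
:class:`~svagree.errors.InvalidArgumentError` outside their stated domain.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "cardiac_output",
    "svr",
    "bsa",
    "sv_indexed",
    "target_force",
]


def cardiac_output(sv, hr):
    """Cardiac output in L/min from stroke volume (mL) and heart rate (bpm).

    CO = SV x HR / 1000.
    """
    sv = np.asarray(sv, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(sv < 0):
        raise InvalidArgumentError("stroke volume must be non-negative")
    if np.any(hr <= 0):
        raise InvalidArgumentError("heart rate must be positive")
    out = sv * hr / 1000.0
    return float(out) if out.ndim == 0 else out


def svr(map_mmhg, co_l_min, cvp_mmhg=0.0):
    """Systemic vascular resistance in mmHg.min/L.

    SVR = (MAP - CVP) / CO.  CVP defaults to 0 (assumed constant); the
    optional ``cvp_mmhg`` argument supports sensitivity analyses.
    """
    map_mmhg = np.asarray(map_mmhg, dtype=float)
    co = np.asarray(co_l_min, dtype=float)
    if np.any(co <= 0):
        raise InvalidArgumentError("cardiac output must be positive")
    out = (map_mmhg - cvp_mmhg) / co
    return float(out) if out.ndim == 0 else out


def bsa(height_cm, weight_kg, formula: str = "dubois"):
    """Body surface area in m^2.

    ``formula`` selects the estimator:

    * ``"dubois"`` (default): 0.007184 x height^0.725 x weight^0.425
    * ``"mosteller"``: sqrt(height x weight / 3600)
    """
    h = np.asarray(height_cm, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    if np.any(h <= 0) or np.any(w <= 0):
        raise InvalidArgumentError("height and weight must be positive")
    if formula == "dubois":
        out = 0.007184 * h**0.725 * w**0.425
    elif formula == "mosteller":
        out = np.sqrt(h * w / 3600.0)
    else:
        raise InvalidArgumentError(f"unknown BSA formula: {formula!r}")
    return float(out) if out.ndim == 0 else out


def sv_indexed(sv_ml, bsa_m2):
    """Stroke volume indexed to body surface area, mL/m^2."""
    sv_ml = np.asarray(sv_ml, dtype=float)
    bsa_m2 = np.asarray(bsa_m2, dtype=float)
    if np.any(bsa_m2 <= 0):
        raise InvalidArgumentError("BSA must be positive")
    out = sv_ml / bsa_m2
    return float(out) if out.ndim == 0 else out


def target_force(mvc_attempts, fraction: float = 0.40) -> float:
    """Handgrip target force in newtons.

    The maximal voluntary contraction is the mean of exactly three
    attempts; the target is ``fraction`` (default 40%) of that mean.
    """
    attempts = np.asarray(mvc_attempts, dtype=float)
    if attempts.shape != (3,):
        raise InvalidArgumentError("exactly three MVC attempts are required")
    if np.any(attempts <= 0):
        raise InvalidArgumentError("MVC attempts must be positive forces")
    if not 0 < fraction < 1:
        raise InvalidArgumentError("fraction must lie in (0, 1)")
    return float(fraction * attempts.mean())
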