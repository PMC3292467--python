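"""SUV computation, late-frame SUV, and recovery-coefficient partial-volume
correction.

SUV = tissue concentration (Bq/g) / (injected dose (Bq) / body weight (g)).
The late SUV is the duration-weighted mean over frames fully inside the
55-60 min window, which on the default 28-frame schedule is exactly the final
300 s frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import TimeActivityCurve

__all__ = [
    "RecoveryModel",
    "QuantResult",
    "suv",
    "suv_curve",
    "late_suv",
    "recovery_coefficient",
    "pvc_correct",
    "LATE_WINDOW_S",
    "DEFAULT_RECOVERY_ANCHORS",
]

#: assessment window for the late-uptake SUV, seconds post-injection.
LATE_WINDOW_S = (3300.0, 3600.0)

#: phantom-measured recovery anchors (object diameter mm, recovery fraction).
DEFAULT_RECOVERY_ANCHORS = ((3.0, 0.32), (8.0, 0.85))

_RC_FLOOR = 0.01
_RC_CAP = 1.0


@dataclass(frozen=True)
class RecoveryModel:
    """Piecewise-linear recovery coefficient vs. object diameter."""

    anchors: tuple[tuple[float, float], ...] = DEFAULT_RECOVERY_ANCHORS

    def __post_init__(self) -> None:
        anchors = tuple(sorted((float(d), float(rc)) for d, rc in self.anchors))
        object.__setattr__(self, "anchors", anchors)
        if len(anchors) < 1:
            raise ValueError("need at least one recovery anchor")
        ds = [d for d, _ in anchors]
        rcs = [rc for _, rc in anchors]
        if any(d <= 0 for d in ds):
            raise ValueError("anchor diameters must be positive")
        if any(not 0 < rc <= 1 for rc in rcs):
            raise ValueError("recovery coefficients must lie in (0, 1]")
        if any(b < a for a, b in zip(rcs, rcs[1:])):
            raise ValueError("recovery coefficients must be nondecreasing with diameter")


def recovery_coefficient(model: RecoveryModel, diameter_mm: float) -> float:
    """Interpolated recovery coefficient at the given object diameter.

    Linear between anchors; linear extrapolation outside, floored at 0.01
    below and capped at 1.0 above so the result stays a physical fraction.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    ds = np.array([d for d, _ in model.anchors])
    rcs = np.array([rc for _, rc in model.anchors])
    if ds.size == 1:
        return float(rcs[0])
    if diameter_mm <= ds[0]:
        slope = (rcs[1] - rcs[0]) / (ds[1] - ds[0])
        rc = rcs[0] + slope * (diameter_mm - ds[0])
        return float(max(rc, _RC_FLOOR))
    if diameter_mm >= ds[-1]:
        slope = (rcs[-1] - rcs[-2]) / (ds[-1] - ds[-2])
        rc = rcs[-1] + slope * (diameter_mm - ds[-1])
        return float(min(rc, _RC_CAP))
    return float(np.interp(diameter_mm, ds, rcs))


def pvc_correct(value, model: RecoveryModel, diameter_mm: float):
    """Partial-volume correction: divide by the recovery coefficient.

    Accepts a scalar or an array of activity concentrations / SUVs; emits a
    warning when the coefficient sits at the extrapolation floor.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("values to correct must be nonnegative")
    rc = recovery_coefficient(model, diameter_mm)
    if rc <= _RC_FLOOR:
        warnings.warn(
            f"recovery coefficient at extrapolation floor {_RC_FLOOR} for "
            f"diameter {diameter_mm} mm; corrected values are unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    out = arr / rc
    return out if np.ndim(value) else float(out)


def pvc_correct_tac(tac: TimeActivityCurve, model: RecoveryModel, diameter_mm: float) -> TimeActivityCurve:
    """Apply pvc_correct to every frame of a TAC."""
    return tac.with_values(pvc_correct(tac.values, model, diameter_mm))


def suv(concentration_bq_per_g, dose_bq: float, weight_g: float):
    """Standardized uptake value: concentration * weight / dose (unitless)."""
    if dose_bq <= 0:
        raise ValueError("injected dose must be positive")
    if weight_g <= 0:
        raise ValueError("body weight must be positive")
    arr = np.asarray(concentration_bq_per_g, dtype=float)
    if np.any(arr < 0):
        raise ValueError("concentration must be nonnegative")
    out = arr * weight_g / dose_bq
    return out if np.ndim(concentration_bq_per_g) else float(out)


def suv_curve(tac: TimeActivityCurve, dose_bq: float, weight_g: float) -> TimeActivityCurve:
    """Convert an activity-concentration TAC to SUV units."""
    return tac.with_values(suv(tac.values, dose_bq, weight_g), units="SUV")


def late_suv(suv_tac: TimeActivityCurve) -> float:
    """Duration-weighted mean SUV over frames fully inside the 55-60 min window."""
    sched = suv_tac.schedule
    lo, hi = LATE_WINDOW_S
    inside = (sched.start_s >= lo - 1e-9) & (sched.end_s <= hi + 1e-9)
    if not np.any(inside):
        raise ValueError(
            f"schedule has no frame fully inside [{lo:.0f}, {hi:.0f}] s"
        )
    covered = float(np.sum(sched.duration_s[inside]))
    if covered < (hi - lo) - 1e-6:
        raise ValueError(
            f"frames inside [{lo:.0f}, {hi:.0f}] s cover only {covered:.0f} s"
        )
    w = sched.duration_s[inside]
    return float(np.sum(w * suv_tac.values[inside]) / np.sum(w))


@dataclass
class QuantResult:
    """SUV curve plus the late-window SUV for one VOI."""

    suv_curve: TimeActivityCurve
    late_suv: float
    pvc_applied: bool

    def to_dict(self) -> dict:
        return {
            "late_suv": self.late_suv,
            "pvc_applied": self.pvc_applied,
            "suv_values": self.suv_curve.values.tolist(),
        }


def quantify(
    tac: TimeActivityCurve,
    dose_bq: float,
    weight_g: float,
    recovery: RecoveryModel | None = None,
    diameter_mm: float | None = None,
) -> QuantResult:
    """SUV conversion with optional partial-volume correction first."""
    work = tac
    pvc = recovery is not None and diameter_mm is not None
    if pvc:
        work = pvc_correct_tac(tac, recovery, diameter_mm)
    curve = suv_curve(work, dose_bq, weight_g)
    return QuantResult(suv_curve=curve, late_suv=late_suv(curve), pvc_applied=pvc)
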