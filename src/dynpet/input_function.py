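"""Image-derived blood input functions modeled as sums of decaying exponentials.

The blood curve Cp(t) is represented by a delay t0 and up to three
(amplitude, decay-rate) terms:

    Cp(t) = sum_i A_i * exp(-lambda_i * (t - t0))   for t >= t0, else 0.

Fitting selects the number of terms (1..max_terms) by small-sample corrected
AIC on the post-peak frames, using frame-duration weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from ._expmix import ExpMixture, integrate_mixture
from .core import FrameSchedule, TimeActivityCurve

__all__ = [
    "InputFunctionModel",
    "InputFunctionFit",
    "evaluate_input",
    "input_frame_means",
    "fit_input_exponentials",
]

MAX_TERMS = 3


@dataclass(frozen=True)
class InputFunctionModel:
    """Delay plus 1-3 decaying exponential terms; time in minutes."""

    terms: tuple[tuple[float, float], ...]  # (amplitude, decay_rate 1/min)
    delay_t0: float = 0.0

    def __post_init__(self) -> None:
        terms = tuple((float(a), float(lam)) for a, lam in self.terms)
        object.__setattr__(self, "terms", terms)
        if not 1 <= len(terms) <= MAX_TERMS:
            raise ValueError(f"input model needs 1..{MAX_TERMS} terms, got {len(terms)}")
        for a, lam in terms:
            if not (np.isfinite(a) and np.isfinite(lam)):
                raise ValueError("term parameters must be finite")
            if a < 0:
                raise ValueError("amplitudes must be nonnegative")
            if lam < 0:
                raise ValueError("decay rates must be nonnegative")
        if not np.isfinite(self.delay_t0):
            raise ValueError("delay must be finite")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.terms])

    @property
    def decay_rates(self) -> np.ndarray:
        return np.array([lam for _, lam in self.terms])

    def as_mixture(self) -> ExpMixture:
        """Mixture in the shifted variable u = t - t0."""
        return ExpMixture(
            coef=self.amplitudes,
            rate=self.decay_rates,
            order=np.zeros(len(self.terms), dtype=int),
        )

    def __call__(self, t_min) -> np.ndarray:
        return evaluate_input(self, t_min)

    def to_dict(self) -> dict:
        return {
            "delay_t0_min": self.delay_t0,
            "terms": [
                {"amplitude": a, "decay_rate_per_min": lam} for a, lam in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InputFunctionModel":
        return cls(
            terms=tuple(
                (t["amplitude"], t["decay_rate_per_min"]) for t in d["terms"]
            ),
            delay_t0=float(d.get("delay_t0_min", 0.0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "InputFunctionModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def evaluate_input(model: InputFunctionModel, t_min) -> np.ndarray:
    """Cp(t) in the model's activity units; zero before the delay."""
    t = np.atleast_1d(np.asarray(t_min, dtype=float))
    u = t - model.delay_t0
    out = np.zeros_like(u)
    mask = u >= 0
    for a, lam in model.terms:
        out[mask] += a * np.exp(-lam * u[mask])
    return out if np.ndim(t_min) else float(out[0])


def input_frame_means(model: InputFunctionModel, schedule: FrameSchedule) -> np.ndarray:
    """Frame-averaged Cp: (1/duration) * integral of Cp over each frame."""
    a_u = np.clip(schedule.start_min - model.delay_t0, 0.0, None)
    b_u = np.clip(schedule.end_min - model.delay_t0, 0.0, None)
    integral = integrate_mixture(model.as_mixture(), a_u, b_u)
    return integral / schedule.duration_min


@dataclass
class InputFunctionFit:
    """Fitted exponential model plus diagnostics and pre-peak interpolation."""

    model: InputFunctionModel
    n_terms: int
    wrss: float
    aicc_table: dict[int, float]
    peak_index: int
    prepeak_times_min: np.ndarray = field(repr=False)
    prepeak_values: np.ndarray = field(repr=False)
    clamped_rate: bool = False

    def evaluate(self, t_min) -> np.ndarray:
        """Model value post-peak; linear interpolation through pre-peak frames."""
        t = np.atleast_1d(np.asarray(t_min, dtype=float))
        out = evaluate_input(self.model, t)
        if self.prepeak_times_min.size:
            t_fit = self.model.delay_t0
            pre = t < t_fit
            if np.any(pre):
                xp = np.concatenate([self.prepeak_times_min, [t_fit]])
                fp = np.concatenate(
                    [self.prepeak_values, [float(evaluate_input(self.model, t_fit))]]
                )
                out[pre] = np.interp(t[pre], xp, fp, left=fp[0])
        return out if np.ndim(t_min) else float(out[0])

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "n_terms": self.n_terms,
            "wrss": self.wrss,
            "aicc": {str(k): v for k, v in self.aicc_table.items()},
            "peak_index": self.peak_index,
            "clamped_rate": self.clamped_rate,
        }


def _fit_k_exponentials(
    t_mid: np.ndarray,
    a_u: np.ndarray,
    b_u: np.ndarray,
    dur: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_starts: int = 8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted LS fit of k exponential terms to frame means; returns (A, lam, wrss)."""
    sw = np.sqrt(w)

    def residual(x: np.ndarray) -> np.ndarray:
        amps = x[:k]
        lams = x[k:]
        mix = ExpMixture(amps, lams, np.zeros(k, dtype=int))
        pred = integrate_mixture(mix, a_u, b_u) / dur
        return sw * (pred - y)

    span = max(t_mid[-1] - t_mid[0], 1e-6)
    y0 = max(y.max(), 1e-12)
    # crude decay-rate scale from endpoint ratio; guards flat/increasing data
    ratio = max(y[0], 1e-12) / max(y[-1], 1e-12)
    lam0 = np.log(ratio) / span if ratio > 1 else 0.0
    lam0 = max(lam0, 1e-3)

    lb = np.concatenate([np.zeros(k), np.zeros(k)])
    ub = np.concatenate([np.full(k, 10.0 * y0 + 1e-12), np.full(k, 50.0)])

    best = None
    starts = []
    # deterministic geometric ladder of rates, then random jitter starts
    base_lams = lam0 * np.geomspace(0.2, 5.0, k) if k > 1 else np.array([lam0])
    starts.append(np.concatenate([np.full(k, y0 / k), base_lams]))
    for _ in range(n_starts - 1):
        jitter = np.exp(rng.normal(0.0, 1.0, size=k))
        starts.append(np.concatenate([np.full(k, y0 / k) * np.exp(rng.normal(0, 0.5, k)), base_lams * jitter]))
    for x0 in starts:
        x0 = np.clip(x0, lb + 1e-12, ub - 1e-12)
        try:
            sol = least_squares(
                residual, x0, bounds=(lb, ub), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:  # pragma: no cover - optimizer failure on a start
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("input-function fit failed for all starts")
    amps = best.x[:k]
    lams = best.x[k:]
    order = np.argsort(-lams)  # fastest term first
    wrss = float(2.0 * best.cost)
    return amps[order], lams[order], wrss


def _aicc(wrss: float, n: int, n_params: int) -> float:
    """Small-sample corrected AIC for a Gaussian weighted-LS fit."""
    wrss = max(wrss, 1e-300)
    aic = n * np.log(wrss / n) + 2 * n_params
    denom = n - n_params - 1
    if denom <= 0:
        return np.inf
    return aic + 2 * n_params * (n_params + 1) / denom


def fit_input_exponentials(
    blood_tac: TimeActivityCurve,
    max_terms: int = MAX_TERMS,
    seed: int = 0,
    n_starts: int = 8,
) -> InputFunctionFit:
    """Fit a 1..max_terms decaying-exponential model to a blood TAC.

    The fit window runs from the peak frame to the end of the acquisition;
    the number of terms is chosen by AICc (ties broken toward fewer terms).
    Frames before the peak are preserved for evaluation by linear
    interpolation.
    """
    if not 1 <= max_terms <= MAX_TERMS:
        raise ValueError(f"max_terms must be in 1..{MAX_TERMS}")
    sched = blood_tac.schedule
    values = blood_tac.values
    peak = int(np.argmax(values))
    window = slice(peak, sched.n_frames)
    t_mid = sched.mid_min[window]
    y = values[window]
    dur = sched.duration_min[window]
    n_win = y.size
    if n_win < 2 * max_terms + 1:
        raise ValueError(
            f"need at least {2 * max_terms + 1} frames after the peak, got {n_win}"
        )

    t0 = float(sched.start_min[peak])
    a_u = sched.start_min[window] - t0
    b_u = sched.end_min[window] - t0
    w = dur  # longer frames carry less noise
    rng = np.random.default_rng(seed)

    # wrss floor at the square of ~1e-8 relative data precision, so that a
    # noiseless exact fit does not make AICc prefer superfluous extra terms
    wrss_floor = 1e-16 * float(np.sum(w * y**2))
    results: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    aicc_table: dict[int, float] = {}
    for k in range(1, max_terms + 1):
        if n_win < 2 * k + 1:
            break
        amps, lams, wrss = _fit_k_exponentials(
            t_mid, a_u, b_u, dur, y, w, k, rng, n_starts=n_starts
        )
        results[k] = (amps, lams, wrss)
        aicc_table[k] = _aicc(max(wrss, wrss_floor), n_win, 2 * k)

    best_k = 1
    for k in sorted(aicc_table):
        if aicc_table[k] < aicc_table[best_k] - 1e-12:
            best_k = k
    amps, lams, wrss = results[best_k]

    clamped = False
    trend = np.polyfit(t_mid, y, 1)[0] if n_win > 1 else 0.0
    if np.any(lams <= 1e-6) and trend > 0:
        clamped = True
        warnings.warn(
            "blood curve is non-decaying in the fit window; decay rate clamped at 0",
            RuntimeWarning,
            stacklevel=2,
        )

    model = InputFunctionModel(
        terms=tuple((float(a), float(lam)) for a, lam in zip(amps, lams)),
        delay_t0=t0,
    )
    return InputFunctionFit(
        model=model,
        n_terms=best_k,
        wrss=wrss,
        aicc_table=aicc_table,
        peak_index=peak,
        prepeak_times_min=sched.mid_min[:peak].copy(),
        prepeak_values=values[:peak].copy(),
        clamped_rate=clamped,
    )
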