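"""Seeded synthetic cohorts: blood input curves, tumor TACs, and animal
metadata with the statistical structure the downstream analysis assumes.

Two tracer groups are emulated: B (bombesin analog, n = 5 by default) and
R (RGD tetramer, n = 4).  Per-animal kinetic parameters are drawn
log-normally around group median values with group-specific relative
spreads; tumor TACs are simulated through the two-tissue compartment forward
model; frame noise is zero-mean Gaussian, proportional to the frame value
and scaled by sqrt(30 s / duration) so that longer frames are less noisy.

All generated activities are decay-corrected by convention; an optional
flag applies Ga-68 physical decay (half-life 67.71 min) for testing
decay-handling code paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import FrameSchedule, TimeActivityCurve, default_schedule
from .input_function import InputFunctionModel, input_frame_means
from .kinetics import KineticParams, simulate_tac

__all__ = [
    "CohortSpec",
    "StudyRecord",
    "generate_input_curve",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "default_spec_b",
    "default_spec_r",
    "B_PARAM_CENTER",
    "R_PARAM_CENTER",
    "B_PARAM_SPREAD",
    "R_PARAM_SPREAD",
    "DEFAULT_INPUT_MODEL",
    "B_INPUT_MODEL",
    "R_INPUT_MODEL",
    "GA68_HALF_LIFE_MIN",
]

GA68_HALF_LIFE_MIN = 67.71

#: group-median kinetic parameters (1/min; VB unitless) used as generator
#: centers for the bombesin-analog (B) and RGD-tetramer (R) groups.
B_PARAM_CENTER = KineticParams(K1=0.3506, k2=0.5216, k3=0.1177, k4=0.1005, vb=0.0903)
R_PARAM_CENTER = KineticParams(K1=0.2728, k2=0.5721, k3=0.1180, k4=0.0442, vb=0.0574)

#: relative spreads (group SD / mean) applied log-normally around the centers.
B_PARAM_SPREAD = KineticParams(K1=0.193, k2=0.273, k3=0.432, k4=0.531, vb=0.427)
R_PARAM_SPREAD = KineticParams(K1=0.175, k2=0.183, k3=0.272, k4=0.117, vb=0.175)

#: three-exponential heart-derived blood curve template (Bq/mL, 1/min): one
#: fast washout term, one intermediate, one slow, peaking at t = 0.  The
#: amplitudes correspond to the reference dose/weight below (peak blood SUV
#: around 15, about the injected dose diluted in a rat's blood volume); the
#: generator rescales them per animal by (dose / ref) * (ref / weight).
B_INPUT_MODEL = InputFunctionModel(
    terms=((1.1e6, 4.0), (3.6e5, 0.35), (1.8e5, 0.02)),
    delay_t0=0.0,
)

#: the RGD tetramer clears from blood faster; its slow-term amplitude is
#: lower so that group-median late tumor SUVs land near the B > R ordering.
R_INPUT_MODEL = InputFunctionModel(
    terms=((1.1e6, 4.0), (3.6e5, 0.35), (1.1e5, 0.02)),
    delay_t0=0.0,
)

DEFAULT_INPUT_MODEL = B_INPUT_MODEL

REFERENCE_DOSE_BQ = 3.0e7
REFERENCE_WEIGHT_G = 300.0

_MAX_RESAMPLES = 100


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic tracer group."""

    group_label: str
    n_animals: int
    param_center: KineticParams
    param_spread: KineticParams
    input_spec: InputFunctionModel = DEFAULT_INPUT_MODEL
    noise_level: float = 0.05
    dose_range_bq: tuple[float, float] = (2.0e7, 4.0e7)
    weight_range_g: tuple[float, float] = (250.0, 350.0)
    seed: int = 0
    apply_physical_decay: bool = False

    def __post_init__(self) -> None:
        if self.group_label not in ("B", "R"):
            raise ValueError("group_label must be 'B' or 'R'")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if not self.param_center.is_acceptable():
            raise ValueError("param_center violates the kinetic-parameter constraints")
        lo, hi = self.dose_range_bq
        if not 0 < lo <= hi:
            raise ValueError("invalid dose range")
        lo, hi = self.weight_range_g
        if not 0 < lo <= hi:
            raise ValueError("invalid weight range")


@dataclass
class StudyRecord:
    """One animal: metadata, blood and tumor TACs, and (if synthetic) truth."""

    animal_id: str
    group: str
    injected_dose_bq: float
    body_weight_g: float
    blood_tac: TimeActivityCurve
    tumor_tac: TimeActivityCurve
    true_params: KineticParams | None = None

    def __post_init__(self) -> None:
        if self.injected_dose_bq <= 0:
            raise ValueError("dose must be positive")
        if self.body_weight_g <= 0:
            raise ValueError("weight must be positive")
        if self.blood_tac.schedule != self.tumor_tac.schedule:
            raise ValueError("blood and tumor TACs must share one schedule")


def _decay_factor(schedule: FrameSchedule) -> np.ndarray:
    lam = np.log(2.0) / GA68_HALF_LIFE_MIN
    return np.exp(-lam * schedule.mid_min)


def _add_frame_noise(
    values: np.ndarray,
    schedule: FrameSchedule,
    noise_level: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Proportional Gaussian noise with SD scaled by sqrt(30 s / duration)."""
    if noise_level == 0:
        return np.clip(values, 0.0, None)
    sd = noise_level * np.abs(values) * np.sqrt(30.0 / schedule.duration_s)
    noisy = values + rng.normal(0.0, 1.0, size=values.shape) * sd
    return np.clip(noisy, 0.0, None)


def generate_input_curve(
    input_spec: InputFunctionModel,
    schedule: FrameSchedule,
    noise_level: float,
    seed: int,
    apply_physical_decay: bool = False,
) -> TimeActivityCurve:
    """Frame-averaged blood curve with proportional frame noise."""
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    rng = np.random.default_rng(seed)
    values = input_frame_means(input_spec, schedule)
    if apply_physical_decay:
        values = values * _decay_factor(schedule)
    values = _add_frame_noise(values, schedule, noise_level, rng)
    return TimeActivityCurve(schedule=schedule, values=values)


def _draw_params(
    center: KineticParams,
    spread: KineticParams,
    rng: np.random.Generator,
) -> KineticParams:
    """Log-normal draw around the center with per-parameter relative SDs.

    The center is the distribution median; sigma^2 = ln(1 + r^2) maps a
    relative SD r onto the log scale.  Draws violating the acceptance
    constraints are resampled (bounded)."""
    centers = np.append(center.rates, center.vb)
    rels = np.append(spread.rates, spread.vb)
    sigma = np.sqrt(np.log1p(rels**2))
    for _ in range(_MAX_RESAMPLES):
        draw = centers * np.exp(rng.normal(0.0, 1.0, size=5) * sigma)
        params = KineticParams.from_array(draw)
        if params.is_acceptable():
            return params
    raise RuntimeError(
        f"failed to draw acceptable kinetic parameters in {_MAX_RESAMPLES} tries; "
        "reduce param_spread"
    )


def _generate_group(
    spec: CohortSpec,
    schedule: FrameSchedule,
    start_index: int,
) -> list[StudyRecord]:
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_animals):
        params = _draw_params(spec.param_center, spec.param_spread, rng)
        dose = float(rng.uniform(*spec.dose_range_bq))
        weight = float(rng.uniform(*spec.weight_range_g))
        # blood concentration scales with injected dose per unit body mass
        scale = (dose / REFERENCE_DOSE_BQ) * (REFERENCE_WEIGHT_G / weight)
        input_model = InputFunctionModel(
            terms=tuple((a * scale, lam) for a, lam in spec.input_spec.terms),
            delay_t0=spec.input_spec.delay_t0,
        )
        blood_clean = input_frame_means(input_model, schedule)
        tumor_clean = simulate_tac(params, input_model, schedule).values
        if spec.apply_physical_decay:
            decay = _decay_factor(schedule)
            blood_clean = blood_clean * decay
            tumor_clean = tumor_clean * decay
        blood = _add_frame_noise(blood_clean, schedule, spec.noise_level, rng)
        tumor = _add_frame_noise(tumor_clean, schedule, spec.noise_level, rng)
        records.append(
            StudyRecord(
                animal_id=f"{spec.group_label}{start_index + i + 1:02d}",
                group=spec.group_label,
                injected_dose_bq=dose,
                body_weight_g=weight,
                blood_tac=TimeActivityCurve(schedule=schedule, values=blood),
                tumor_tac=TimeActivityCurve(schedule=schedule, values=tumor),
                true_params=params,
            )
        )
    return records


def generate_cohort(
    spec_b: CohortSpec,
    spec_r: CohortSpec,
    schedule: FrameSchedule | None = None,
) -> list[StudyRecord]:
    """Generate the full two-group cohort (B animals first)."""
    schedule = schedule or default_schedule()
    return _generate_group(spec_b, schedule, 0) + _generate_group(
        spec_r, schedule, 0
    )


def default_spec_b(seed: int = 0, noise_level: float = 0.05, **kwargs) -> CohortSpec:
    """Default B-group spec: n = 5, dose 20-40 MBq."""
    kwargs.setdefault("input_spec", B_INPUT_MODEL)
    return CohortSpec(
        group_label="B",
        n_animals=5,
        param_center=B_PARAM_CENTER,
        param_spread=B_PARAM_SPREAD,
        noise_level=noise_level,
        dose_range_bq=(2.0e7, 4.0e7),
        seed=seed,
        **kwargs,
    )


def default_spec_r(seed: int = 1, noise_level: float = 0.05, **kwargs) -> CohortSpec:
    """Default R-group spec: n = 4, dose 10-30 MBq."""
    kwargs.setdefault("input_spec", R_INPUT_MODEL)
    return CohortSpec(
        group_label="R",
        n_animals=4,
        param_center=R_PARAM_CENTER,
        param_spread=R_PARAM_SPREAD,
        noise_level=noise_level,
        dose_range_bq=(1.0e7, 3.0e7),
        seed=seed,
        **kwargs,
    )


def write_cohort(records: list[StudyRecord], out_dir) -> Path:
    """Write per-VOI TAC CSVs and a cohort manifest JSON; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"animals": []}
    for rec in records:
        blood_path = out / f"{rec.animal_id}_blood.csv"
        tumor_path = out / f"{rec.animal_id}_tumor.csv"
        rec.blood_tac.to_csv(blood_path)
        rec.tumor_tac.to_csv(tumor_path)
        manifest["animals"].append(
            {
                "animal_id": rec.animal_id,
                "group": rec.group,
                "dose_bq": rec.injected_dose_bq,
                "weight_g": rec.body_weight_g,
                "blood_tac": blood_path.name,
                "tumor_tac": tumor_path.name,
                "true_params": (
                    rec.true_params.to_dict() if rec.true_params else None
                ),
            }
        )
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest_path


def read_cohort(manifest_path) -> list[StudyRecord]:
    """Load a cohort written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    records = []
    for entry in manifest["animals"]:
        true_params = entry.get("true_params")
        records.append(
            StudyRecord(
                animal_id=entry["animal_id"],
                group=entry["group"],
                injected_dose_bq=float(entry["dose_bq"]),
                body_weight_g=float(entry["weight_g"]),
                blood_tac=TimeActivityCurve.from_csv(base / entry["blood_tac"]),
                tumor_tac=TimeActivityCurve.from_csv(base / entry["tumor_tac"]),
                true_params=(
                    KineticParams.from_dict(true_params) if true_params else None
                ),
            )
        )
    return records
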