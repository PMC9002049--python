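"""Synthetic dynamic renal PET cohorts with known ground truth.

No clinical image data ship with this package, so every downstream stage is
exercised on simulated data: a bolus-shaped arterial input (linear rise then
two-exponential washout), renal cortical TACs generated by the 1-tissue
compartment model with a fractional blood volume, a delayed urine signal that
contaminates the cortical curve, an oversized-VOI measurement table that the
input-function correction inverts exactly, and frame-duration-dependent
Gaussian count noise.

Ground truth (K1, k2, vB, V_RC per kidney) is stored with every patient, so
parameter- and GFR-recovery are verifiable end to end:
GFR_total = sum over kidneys of V_RC * (1 - vB) * K1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gfr as gfr_mod
from .aif import AortaVoiMeasurement, to_plasma
from .frames import (
    DEFAULT_SCHEDULE_SPEC,
    FrameSchedule,
    SampledCurve,
    ValidationError,
    make_frame_schedule,
    require_same_schedule,
)
from .gfr import PatientRecord
from .kinetics import solve_model

__all__ = [
    "InputFunctionParams",
    "KidneyTruth",
    "NoiseModel",
    "CohortConfig",
    "SyntheticKidney",
    "SyntheticPatient",
    "SyntheticCohort",
    "simulate_plasma_input",
    "simulate_kidney_tac",
    "simulate_aorta_voi_table",
    "simulate_cohort",
]

#: Volume of the 10-mm-diameter spherical urine VOI in the renal pelvis (ml).
URINE_SPHERE_VOLUME_ML = 4.0 / 3.0 * np.pi * 0.5**3  # 0.5236 ml


@dataclass(frozen=True)
class InputFunctionParams:
    """Parametric whole-blood aortic input: bolus rise then biexponential washout.

    The tracer is purely glomerularly filtered, so after vascular mixing its
    blood clearance is well described by a fast mixing/redistribution
    component and a slow renal-clearance component.  Defaults give a ~60
    kBq/ml first-pass peak about 20 s after injection, plausible for a
    ~110 MBq bolus measured in the abdominal aorta.
    """

    bolus_arrival_s: float = 15.0
    rise_time_s: float = 8.0
    amplitude_kbq_ml: float = 60.0
    clearance_fractions: tuple[float, float] = (0.7, 0.3)
    clearance_rates_per_min: tuple[float, float] = (0.35, 0.012)

    def __post_init__(self) -> None:
        if self.amplitude_kbq_ml < 0:
            raise ValidationError("bolus amplitude must be >= 0")
        if self.rise_time_s <= 0 or self.bolus_arrival_s < 0:
            raise ValidationError("bolus timing must be positive")
        if any(r <= 0 for r in self.clearance_rates_per_min):
            raise ValidationError("clearance rates must be positive")
        fr = self.clearance_fractions
        if any(not 0 <= f <= 1 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValidationError("clearance fractions must lie in [0,1] and sum to 1")

    @property
    def peak_time_s(self) -> float:
        return self.bolus_arrival_s + self.rise_time_s


def _input_value(params: InputFunctionParams, t: np.ndarray) -> np.ndarray:
    """Continuous model concentration at times t (seconds)."""
    t = np.asarray(t, dtype=float)
    t0, tp = params.bolus_arrival_s, params.peak_time_s
    a = params.amplitude_kbq_ml
    out = np.zeros_like(t)
    rising = (t > t0) & (t < tp)
    out[rising] = a * (t[rising] - t0) / params.rise_time_s
    after = t >= tp
    ta = t[after] - tp
    decay = np.zeros_like(ta)
    for f, rate in zip(params.clearance_fractions, params.clearance_rates_per_min):
        decay += f * np.exp(-(rate / 60.0) * ta)
    out[after] = a * decay
    return out


def _input_integral(params: InputFunctionParams, t: np.ndarray) -> np.ndarray:
    """Analytic running integral of the continuous model, kBq/ml * s."""
    t = np.asarray(t, dtype=float)
    t0, tp = params.bolus_arrival_s, params.peak_time_s
    a, rise = params.amplitude_kbq_ml, params.rise_time_s
    out = np.zeros_like(t)
    in_rise = (t > t0) & (t <= tp)
    out[in_rise] = a * (t[in_rise] - t0) ** 2 / (2.0 * rise)
    after = t > tp
    f_peak = a * rise / 2.0
    ta = t[after] - tp
    tail = np.zeros_like(ta)
    for f, rate in zip(params.clearance_fractions, params.clearance_rates_per_min):
        lam = rate / 60.0
        tail += f * (1.0 - np.exp(-lam * ta)) / lam
    out[after] = f_peak + a * tail
    return out


def simulate_plasma_input(
    params: InputFunctionParams, schedule: FrameSchedule
) -> SampledCurve:
    """Noise-free input curve: analytic frame-average of the continuous model."""
    f_start = _input_integral(params, schedule.starts)
    f_end = _input_integral(params, schedule.ends)
    values = (f_end - f_start) / schedule.durations
    return SampledCurve(schedule, values, units="kBq/ml")


@dataclass(frozen=True)
class KidneyTruth:
    """Ground-truth kinetic parameters of one synthetic kidney."""

    k1_per_min: float
    k2_per_min: float  # urinary washout; ~0 models complete obstruction
    vb: float
    v_rc_ml: float
    spill_fraction: float = 0.0
    spill_delay_s: float = 60.0
    obstruction: bool = False

    def __post_init__(self) -> None:
        if self.k1_per_min < 0 or self.k2_per_min < 0:
            raise ValidationError("rate constants must be >= 0")
        if not 0 <= self.vb <= 1:
            raise ValidationError("vB must lie in [0, 1]")
        if self.v_rc_ml <= 0:
            raise ValidationError("V_RC must be positive")
        if self.spill_fraction < 0:
            raise ValidationError("spill fraction must be >= 0")

    @property
    def v_ec_ml(self) -> float:
        return self.v_rc_ml * (1.0 - self.vb)

    @property
    def gfr_ml_min(self) -> float:
        """Ground-truth single-kidney GFR: V_RC * (1 - vB) * K1."""
        return self.v_ec_ml * self.k1_per_min


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian surrogate for reconstructed-PET count noise.

    Frame SD = sigma0 * sqrt(max(value, floor) / duration): noise shrinks
    with frame duration and grows with activity, as count statistics do.
    """

    sigma0: float = 1.0
    floor_kbq_ml: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 < 0:
            raise ValidationError("sigma0 must be >= 0")

    def sample(
        self, values: np.ndarray, durations: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        if self.sigma0 == 0:
            return values.copy()
        sd = self.sigma0 * np.sqrt(
            np.maximum(values, self.floor_kbq_ml) / durations
        )
        return values + rng.normal(0.0, 1.0, size=values.shape) * sd


def simulate_kidney_tac(
    plasma: SampledCurve,
    aorta: SampledCurve,
    truth: KidneyTruth,
    schedule: FrameSchedule,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SampledCurve, SampledCurve]:
    """Simulate one kidney's cortical and urine-VOI curves.

    The noise-free cortical curve is the operational model curve plus a
    urine spill-over term: spill_fraction times the pelvis concentration,
    where the pelvis holds the accumulated cortical outflow k2 * A_EC,
    delayed by spill_delay and normalized to the 10-mm-sphere VOI volume.
    """
    require_same_schedule(plasma, aorta)
    if plasma.schedule != schedule:
        raise ValidationError("curves are not on the requested schedule")
    curves = solve_model(truth.k1_per_min, truth.k2_per_min, truth.vb, plasma, aorta)
    mid = schedule.mid_times
    a_ec = curves.c_ec.values * truth.v_ec_ml  # kBq
    outflow_rate = (truth.k2_per_min / 60.0) * a_ec  # kBq/s
    cum_out = np.concatenate(
        ([0.0], np.cumsum(np.diff(mid) * (outflow_rate[1:] + outflow_rate[:-1]) / 2.0))
    )
    delayed = np.interp(mid - truth.spill_delay_s, mid, cum_out, left=0.0)
    c_urine = delayed / URINE_SPHERE_VOLUME_ML
    cortical = curves.c_model.values + truth.spill_fraction * c_urine
    if noise is not None and noise.sigma0 > 0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        cortical = noise.sample(cortical, schedule.durations, rng)
        c_urine = noise.sample(c_urine, schedule.durations, rng)
    return (
        SampledCurve(schedule, cortical, units="kBq/ml"),
        SampledCurve(schedule, c_urine, units="kBq/ml"),
    )


def simulate_aorta_voi_table(
    aorta_true: SampledCurve,
    geometry: tuple[float, float],
    background_level: SampledCurve | float,
) -> AortaVoiMeasurement:
    """Forward-model the oversized-VOI measurement table.

    A_oversized(t) = C_aorta(t) * V_aorta + C_background(t) * (V_over - V_aorta);
    the table is exactly invertible by ``aif.correct_oversized_voi``.
    """
    v_aorta, v_oversized = geometry
    if not v_oversized > v_aorta > 0:
        raise ValidationError("need V_oversized > V_aorta > 0")
    if isinstance(background_level, SampledCurve):
        require_same_schedule(aorta_true, background_level)
        bg = background_level.values
    else:
        bg = np.full(aorta_true.schedule.n_frames, float(background_level))
    a_over = aorta_true.values * v_aorta + bg * (v_oversized - v_aorta)
    return AortaVoiMeasurement(
        schedule=aorta_true.schedule,
        a_oversized_kbq=a_over,
        c_background_kbq_ml=bg,
        v_oversized_ml=v_oversized,
        v_aorta_ml=v_aorta,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Stated world of the synthetic cohort.

    Defaults mirror the 12-patient clinical cohort: the 72-frame 30-min
    schedule, 10/12 male, ages 46-79, three patients with urinary
    obstruction (two both-sided, one right-sided), and truth ranges that put
    total GFR around 40-120 ml/min.
    """

    n_patients: int = 12
    schedule_spec: tuple[tuple[int, float], ...] = tuple(DEFAULT_SCHEDULE_SPEC)
    sigma0: float = 1.0
    #: None -> clinical prevalence of 1 in 4 (3 of 12), rounded down.
    n_obstructed: int | None = None
    k1_range: tuple[float, float] = (0.15, 0.45)
    k2_range: tuple[float, float] = (0.02, 0.15)
    vb_range: tuple[float, float] = (0.10, 0.30)
    v_rc_range: tuple[float, float] = (100.0, 180.0)
    spill_range: tuple[float, float] = (5e-4, 2e-3)
    spill_delay_range: tuple[float, float] = (30.0, 120.0)
    obstructed_k2: float = 1e-3
    male_fraction: float = 10.0 / 12.0
    age_range: tuple[int, int] = (46, 79)
    hct_range: tuple[float, float] = (0.26, 0.41)
    aorta_volume_ml: float = 14.0
    oversized_volume_ml: float = 31.5
    background_scale: float = 0.08
    ckd_discrepancy_sd: float = 0.12  # lognormal SD of reference vs truth GFR

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        if self.n_obstructed is not None and not (
            0 <= self.n_obstructed <= self.n_patients
        ):
            raise ValidationError("n_obstructed out of range")

    @property
    def effective_n_obstructed(self) -> int:
        if self.n_obstructed is not None:
            return self.n_obstructed
        return self.n_patients // 4


@dataclass(frozen=True)
class SyntheticKidney:
    truth: KidneyTruth
    cortical: SampledCurve
    urine: SampledCurve


@dataclass(frozen=True)
class SyntheticPatient:
    record: PatientRecord
    schedule: FrameSchedule
    input_params: InputFunctionParams
    aorta_true: SampledCurve
    plasma_true: SampledCurve
    voi_table: AortaVoiMeasurement
    kidneys: dict[str, SyntheticKidney]  # "left" / "right"
    activity_mbq: float

    @property
    def truth_total_gfr(self) -> float:
        return sum(k.truth.gfr_ml_min for k in self.kidneys.values())


@dataclass(frozen=True)
class SyntheticCohort:
    config: CohortConfig
    seed: int
    patients: tuple[SyntheticPatient, ...]


def _sample_truth(
    rng: np.random.Generator, cfg: CohortConfig, obstructed: bool
) -> KidneyTruth:
    k2 = (
        cfg.obstructed_k2
        if obstructed
        else float(rng.uniform(*cfg.k2_range))
    )
    return KidneyTruth(
        k1_per_min=float(rng.uniform(*cfg.k1_range)),
        k2_per_min=k2,
        vb=float(rng.uniform(*cfg.vb_range)),
        v_rc_ml=float(rng.uniform(*cfg.v_rc_range)),
        spill_fraction=float(rng.uniform(*cfg.spill_range)),
        spill_delay_s=float(rng.uniform(*cfg.spill_delay_range)),
        obstruction=obstructed,
    )


def simulate_cohort(config: CohortConfig = CohortConfig(), seed: int = 0) -> SyntheticCohort:
    """Generate a full cohort; bit-identical under identical (config, seed).

    The first ``n_obstructed`` patients (by id) carry urinary obstruction:
    all but the last of them both-sided, the last right-sided only, echoing
    the clinical 2-both + 1-right pattern at the default count of 3.
    """
    rng = np.random.default_rng(seed)
    schedule = make_frame_schedule(list(config.schedule_spec))
    n_obstructed = config.effective_n_obstructed
    patients = []
    for i in range(config.n_patients):
        pid = f"S{i + 1:02d}"
        obstructed_patient = i < n_obstructed
        if obstructed_patient:
            sides = (
                ("left", "right")
                if i < n_obstructed - 1
                else ("right",)
            )
        else:
            sides = ()
        sex = "male" if rng.uniform() < config.male_fraction else "female"
        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        bsa = float(np.clip(rng.normal(1.95, 0.20), 1.45, 2.35))
        hct = float(rng.uniform(*config.hct_range))
        activity = float(rng.uniform(79.0, 137.0))

        params = InputFunctionParams(
            bolus_arrival_s=float(rng.uniform(10.0, 20.0)),
            rise_time_s=float(rng.uniform(6.0, 12.0)),
            amplitude_kbq_ml=float(rng.uniform(40.0, 80.0)) * activity / 112.0,
        )
        aorta_true = simulate_plasma_input(params, schedule)
        plasma_true = to_plasma(aorta_true, hct)
        # smooth soft-tissue background: scaled, slightly delayed blood signal
        bg_vals = config.background_scale * np.interp(
            schedule.mid_times - 10.0, schedule.mid_times, aorta_true.values, left=0.0
        )
        voi_table = simulate_aorta_voi_table(
            aorta_true,
            (config.aorta_volume_ml, config.oversized_volume_ml),
            SampledCurve(schedule, bg_vals),
        )

        noise = NoiseModel(sigma0=config.sigma0, seed=seed)
        kidneys: dict[str, SyntheticKidney] = {}
        for side in ("left", "right"):
            truth = _sample_truth(rng, config, obstructed=side in sides)
            cortical, urine = simulate_kidney_tac(
                plasma_true, aorta_true, truth, schedule, noise=noise, rng=rng
            )
            kidneys[side] = SyntheticKidney(truth, cortical, urine)

        total_truth = sum(k.truth.gfr_ml_min for k in kidneys.values())
        ckd_target = total_truth * float(
            np.exp(rng.normal(0.0, config.ckd_discrepancy_sd))
        )
        creat = gfr_mod.creatinine_for_gfr(sex, age, bsa, ckd_target)
        record = PatientRecord(
            id=pid,
            sex=sex,
            age_years=age,
            bsa_m2=bsa,
            creatinine_mg_dl=float(np.clip(creat, 0.2, 15.0)),
            hct=hct,
        )
        patients.append(
            SyntheticPatient(
                record=record,
                schedule=schedule,
                input_params=params,
                aorta_true=aorta_true,
                plasma_true=plasma_true,
                voi_table=voi_table,
                kidneys=kidneys,
                activity_mbq=activity,
            )
        )
    return SyntheticCohort(config=config, seed=seed, patients=tuple(patients))
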