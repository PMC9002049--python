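"""GFR derivation from kinetic fits and the serum-creatinine reference.

Per kidney, GFR = V_RC * (1 - vB) * K1: the influx constant K1 is glomerular
filtration per unit extravascular cortical volume, so multiplying by
V_EC = V_RC * (1 - vB) recovers the absolute filtration rate in ml/min.
Total GFR is the sum over both kidneys.

The reference standard is the 2009 CKD-EPI creatinine equation (no race
coefficient), de-normalized from ml/min/1.73 m^2 to absolute ml/min by
multiplying with the patient's body surface area over 1.73.  The sex-specific
leading constants are the tabulated 141 (male) / 144 (female).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .frames import ValidationError
from .kinetics import KineticFit

__all__ = [
    "RenalCortexRegion",
    "PatientRecord",
    "GFRResult",
    "gfr_from_fit",
    "total_gfr",
    "ckd_epi_normalized",
    "ckd_epi_absolute",
    "creatinine_for_gfr",
]


@dataclass(frozen=True)
class RenalCortexRegion:
    """Functional renal cortical volume of one kidney."""

    side: str  # "left" | "right"
    v_rc_ml: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.v_rc_ml <= 0:
            raise ValidationError("V_RC must be positive")


@dataclass(frozen=True)
class PatientRecord:
    """Demographics and labs needed for the creatinine reference GFR."""

    id: str
    sex: str  # "female" | "male"
    age_years: float
    bsa_m2: float
    creatinine_mg_dl: float
    hct: float

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.age_years <= 0 or self.bsa_m2 <= 0:
            raise ValidationError("age and BSA must be positive")
        if self.creatinine_mg_dl <= 0:
            raise ValidationError("serum creatinine must be positive")
        if not 0 < self.hct < 1:
            raise ValidationError("haematocrit must lie in (0, 1)")


@dataclass(frozen=True)
class GFRResult:
    """Per-kidney and total PET GFR plus the creatinine reference, ml/min."""

    gfr_left: float
    gfr_right: float
    gfr_total: float
    gfr_ckd: float
    variant: str = "PET-30"

    def __post_init__(self) -> None:
        for v in (self.gfr_left, self.gfr_right, self.gfr_total, self.gfr_ckd):
            if v < 0:
                raise ValidationError("GFR values must be non-negative")


def gfr_from_fit(region: RenalCortexRegion, fit: KineticFit) -> float:
    """Single-kidney GFR in ml/min: V_RC * (1 - vB) * K1."""
    return region.v_rc_ml * (1.0 - fit.vb) * fit.k1


def total_gfr(left: float, right: float) -> float:
    """Sum of the two single-kidney GFRs (ml/min)."""
    if left < 0 or right < 0:
        raise ValidationError("single-kidney GFR must be non-negative")
    return left + right


# 2009 CKD-EPI creatinine equation, tabulated sex-specific form.
_CKD_EPI = {
    "female": (0.7, -0.329, 144.0),  # kappa, alpha, leading constant
    "male": (0.9, -0.411, 141.0),
}


def ckd_epi_normalized(sex: str, age_years: float, creatinine_mg_dl: float) -> float:
    """CKD-EPI eGFR in ml/min/1.73 m^2 (2009 creatinine equation, no race term)."""
    if sex not in _CKD_EPI:
        raise ValidationError(f"sex must be 'female' or 'male', got {sex!r}")
    if creatinine_mg_dl <= 0:
        raise ValidationError("serum creatinine must be positive")
    kappa, alpha, const = _CKD_EPI[sex]
    ratio = creatinine_mg_dl / kappa
    return (
        const
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993**age_years
    )


def ckd_epi_absolute(p: PatientRecord) -> float:
    """Absolute (de-normalized) CKD-EPI GFR in ml/min: eGFR * BSA / 1.73."""
    return ckd_epi_normalized(p.sex, p.age_years, p.creatinine_mg_dl) * p.bsa_m2 / 1.73


def creatinine_for_gfr(
    sex: str, age_years: float, bsa_m2: float, gfr_abs_ml_min: float
) -> float:
    """Serum creatinine (mg/dl) whose CKD-EPI absolute GFR equals the target.

    Inverse of :func:`ckd_epi_absolute`; used by the synthetic-cohort
    generator so demographics stay consistent with ground-truth GFR.
    """
    if gfr_abs_ml_min <= 0:
        raise ValidationError("target GFR must be positive")
    target = gfr_abs_ml_min * 1.73 / bsa_m2

    def f(scr: float) -> float:
        return ckd_epi_normalized(sex, age_years, scr) - target

    # eGFR is strictly decreasing in creatinine; bracket generously.
    lo, hi = 0.05, 30.0
    if f(lo) < 0 or f(hi) > 0:
        raise ValidationError("target GFR outside invertible range")
    return float(brentq(f, lo, hi, xtol=1e-10))


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (clinical-report convention)."""
    factor = 10.0**decimals
    import math

    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
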