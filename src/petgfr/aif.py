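"""Image-derived arterial input function.

The whole-blood input is measured in an oversized volume of interest (VOI)
drawn generously around the abdominal aorta so that, despite partial-volume
blur and patient motion, all aortal activity is captured.  The price is
cross-contamination from surrounding tissue, which is removed by subtracting
the background concentration scaled to the non-aortic part of the VOI:

    C_aorta(t) = (A_oversized(t) - C_background(t) * (V_oversized - V_aorta)) / V_aorta

The plasma concentration driving glomerular filtration is then obtained from
whole blood via the haematocrit, C_P = C_aorta / (1 - HCT), exploiting that
the tracer stays in plasma (negligible red-cell uptake and protein binding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .frames import FrameSchedule, SampledCurve, ValidationError

__all__ = ["AortaVoiMeasurement", "PlasmaInput", "correct_oversized_voi", "to_plasma"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AortaVoiMeasurement:
    """Per-frame oversized-VOI quantities feeding the background correction.

    Attributes
    ----------
    schedule : FrameSchedule
    a_oversized_kbq : array
        Total activity (kBq) inside the oversized VOI per frame.
    c_background_kbq_ml : array
        Mean background concentration (kBq/ml) per frame.
    v_oversized_ml, v_aorta_ml : float
        VOI volumes; the oversized VOI must strictly contain the aorta VOI.
    """

    schedule: FrameSchedule
    a_oversized_kbq: np.ndarray
    c_background_kbq_ml: np.ndarray
    v_oversized_ml: float
    v_aorta_ml: float

    def __post_init__(self) -> None:
        a = np.asarray(self.a_oversized_kbq, dtype=float)
        b = np.asarray(self.c_background_kbq_ml, dtype=float)
        object.__setattr__(self, "a_oversized_kbq", a)
        object.__setattr__(self, "c_background_kbq_ml", b)
        if not (self.v_oversized_ml > self.v_aorta_ml > 0):
            raise ValidationError(
                f"need V_oversized > V_aorta > 0, got "
                f"{self.v_oversized_ml} / {self.v_aorta_ml} ml"
            )
        n = self.schedule.n_frames
        if a.size != n or b.size != n:
            raise ValidationError("VOI measurement length does not match schedule")


@dataclass(frozen=True)
class PlasmaInput:
    """Whole-blood aortic curve, its plasma conversion, and the haematocrit used."""

    c_aorta: SampledCurve
    c_p: SampledCurve
    hct: float


def correct_oversized_voi(m: AortaVoiMeasurement) -> SampledCurve:
    """Background-correct the oversized-VOI activity to the aortic concentration.

    Negative corrected frames (possible under noise when background overshoots)
    are preserved, not clipped, so least-squares residuals stay unbiased; a
    warning is logged instead.
    """
    v_bg = m.v_oversized_ml - m.v_aorta_ml
    c_aorta = (m.a_oversized_kbq - m.c_background_kbq_ml * v_bg) / m.v_aorta_ml
    n_neg = int(np.sum(c_aorta < 0))
    if n_neg:
        log.warning(
            "oversized-VOI correction produced %d negative frame(s); kept unclipped",
            n_neg,
        )
    return SampledCurve(m.schedule, c_aorta, units="kBq/ml")


def to_plasma(c_aorta: SampledCurve, hct: float) -> SampledCurve:
    """Convert whole-blood to plasma concentration: C_P = C_aorta / (1 - HCT)."""
    if not 0 < hct < 1:
        raise ValidationError(f"haematocrit must lie in (0, 1), got {hct}")
    return c_aorta.scaled(1.0 / (1.0 - hct))


def estimate_plasma_input(m: AortaVoiMeasurement, hct: float) -> PlasmaInput:
    """Full input-function estimate: background correction then plasma conversion."""
    c_aorta = correct_oversized_voi(m)
    return PlasmaInput(c_aorta=c_aorta, c_p=to_plasma(c_aorta, hct), hct=hct)
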