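"""End-to-end pipeline: simulate -> input function -> kinetic fits -> GFR -> agreement.

``run_pipeline`` generates (or accepts) a synthetic cohort, estimates every
patient's plasma input from the oversized-VOI table, fits the 1-tissue
compartment model per kidney for each requested window variant, assembles a
per-patient GFR table (creatinine reference plus the four PET variants), and
runs the agreement battery on every PET-vs-reference column pair.  The whole
run is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement
from .aif import estimate_plasma_input
from .frames import ValidationError
from .gfr import ckd_epi_absolute, gfr_from_fit, total_gfr, RenalCortexRegion
from .kinetics import FIT_VARIANTS, FitWindow, KineticFit, fit_1tc
from .synthetic import CohortConfig, SyntheticCohort, simulate_cohort
from .tacio import provenance_hash, write_tac, write_voi_table

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "GFR_COLUMNS"]

GFR_COLUMNS = ["gfr_pet30", "gfr_pet30_wo2to10", "gfr_pet15", "gfr_pet15_wo2to10"]
_VARIANT_BY_COLUMN = {
    "gfr_pet30": "PET-30",
    "gfr_pet30_wo2to10": "PET-30_wo2to10",
    "gfr_pet15": "PET-15",
    "gfr_pet15_wo2to10": "PET-15_wo2to10",
}


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    weights: str = "uniform"
    variants: tuple[str, ...] = tuple(FIT_VARIANTS)
    icc_form: str = "consistency"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValidationError("at least one fit-window variant is required")
        unknown = [v for v in self.variants if v not in FIT_VARIANTS]
        if unknown:
            raise ValidationError(f"unknown variant(s) {unknown}")


@dataclass(frozen=True)
class PipelineResult:
    gfr_table: pd.DataFrame
    fits: dict[tuple[str, str, str], KineticFit]  # (patient, side, variant)
    agreement: dict[str, agreement.AgreementResult]
    truth_table: pd.DataFrame
    cohort: SyntheticCohort


def _column_for(variant: str) -> str:
    for col, var in _VARIANT_BY_COLUMN.items():
        if var == variant:
            return col
    raise KeyError(variant)


def run_pipeline(
    config: PipelineConfig, cohort: SyntheticCohort | None = None
) -> PipelineResult:
    """Run the full analysis; writes delimited reports if out_dir is set."""
    if cohort is None:
        cohort = simulate_cohort(config.cohort, seed=config.seed)
    rows = []
    truth_rows = []
    fits: dict[tuple[str, str, str], KineticFit] = {}
    for patient in cohort.patients:
        log.info("stage=aif patient=%s status=start", patient.record.id)
        plasma_input = estimate_plasma_input(patient.voi_table, patient.record.hct)
        row: dict[str, object] = {
            "patient_id": patient.record.id,
            "gfr_ckd": ckd_epi_absolute(patient.record),
            "obstruction": any(
                k.truth.obstruction for k in patient.kidneys.values()
            ),
        }
        for variant in config.variants:
            window = FIT_VARIANTS[variant]
            per_kidney = {}
            for side, kidney in patient.kidneys.items():
                fit = fit_1tc(
                    kidney.cortical,
                    plasma_input.c_p,
                    plasma_input.c_aorta,
                    window=window,
                    weights=config.weights,
                )
                if not fit.converged:
                    log.warning(
                        "stage=fit patient=%s kidney=%s variant=%s status=non-converged",
                        patient.record.id, side, variant,
                    )
                fits[(patient.record.id, side, variant)] = fit
                region = RenalCortexRegion(side, kidney.truth.v_rc_ml)
                per_kidney[side] = gfr_from_fit(region, fit)
            row[_column_for(variant)] = total_gfr(
                per_kidney.get("left", 0.0), per_kidney.get("right", 0.0)
            )
        rows.append(row)
        for side, kidney in patient.kidneys.items():
            t = kidney.truth
            truth_rows.append(
                {
                    "patient_id": patient.record.id,
                    "side": side,
                    "K1_per_min": t.k1_per_min,
                    "k2_per_min": t.k2_per_min,
                    "vB": t.vb,
                    "V_RC_ml": t.v_rc_ml,
                    "gfr_true": t.gfr_ml_min,
                }
            )
    gfr_table = pd.DataFrame(rows)
    truth_table = pd.DataFrame(truth_rows)

    agree: dict[str, agreement.AgreementResult] = {}
    unobstructed = ~gfr_table["obstruction"].to_numpy(dtype=bool)
    for col in GFR_COLUMNS:
        if col not in gfr_table.columns or len(gfr_table) < 4:
            continue
        pairs = {
            f"{col}_vs_ckd": agreement.PairedSeries(
                gfr_table["gfr_ckd"].to_numpy(), gfr_table[col].to_numpy()
            )
        }
        if 4 <= unobstructed.sum() < len(gfr_table):
            pairs[f"{col}_vs_ckd_unobstructed"] = agreement.PairedSeries(
                gfr_table["gfr_ckd"].to_numpy()[unobstructed],
                gfr_table[col].to_numpy()[unobstructed],
            )
        for name, series in pairs.items():
            agree[name] = agreement.compare(series, icc_form=config.icc_form)
    if {"gfr_pet30", "gfr_pet15"} <= set(gfr_table.columns) and len(gfr_table) >= 4:
        agree["gfr_pet15_vs_pet30"] = agreement.compare(
            agreement.PairedSeries(
                gfr_table["gfr_pet30"].to_numpy(), gfr_table["gfr_pet15"].to_numpy()
            ),
            icc_form=config.icc_form,
        )

    result = PipelineResult(gfr_table, fits, agree, truth_table, cohort)
    if config.out_dir is not None:
        _write_bundle(result, config)
    return result


def _agreement_frame(agree: dict[str, agreement.AgreementResult]) -> pd.DataFrame:
    recs = []
    for name, a in agree.items():
        recs.append(
            {
                "comparison": name,
                "n": a.n,
                "pcc": round(a.pcc, 2),
                "pcc_ci_low": round(a.pcc_ci[0], 2),
                "pcc_ci_high": round(a.pcc_ci[1], 2),
                "icc": round(a.icc, 2),
                "icc_lower": round(a.icc_bounds[0], 2),
                "icc_upper": round(a.icc_bounds[1], 2),
                "icc_category": a.icc_category,
                "bias": round(a.bias, 2),
                "bias_ci_low": round(a.bias_ci[0], 2),
                "bias_ci_high": round(a.bias_ci[1], 2),
                "loa_low": round(a.loa[0], 2),
                "loa_high": round(a.loa[1], 2),
            }
        )
    return pd.DataFrame(recs)


def _write_bundle(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)  # type: ignore[arg-type]
    out.mkdir(parents=True, exist_ok=True)
    hashed = dataclasses.asdict(config)
    hashed.pop("out_dir", None)  # identical science -> identical bytes anywhere
    prov = provenance_hash(hashed)
    header = (
        f"# units: GFR ml/min\n# provenance: {prov}\n"
        "# differences: second method minus first (new minus reference)\n"
    )
    with open(out / "gfr_table.csv", "w") as fh:
        fh.write(header)
        result.gfr_table.to_csv(fh, index=False)
    with open(out / "agreement.csv", "w") as fh:
        fh.write(header)
        _agreement_frame(result.agreement).to_csv(fh, index=False)
    with open(out / "truth.csv", "w") as fh:
        fh.write(f"# units: K1,k2 1/min; V_RC ml; GFR ml/min\n# provenance: {prov}\n")
        result.truth_table.to_csv(fh, index=False)
    fit_rows = [
        {
            "patient_id": pid,
            "side": side,
            "variant": variant,
            "K1_per_min": f.k1,
            "k2_per_min": f.k2,
            "vB": f.vb,
            "chi2": f.chi2,
            "aic": f.aic,
            "n_points": f.n_points,
            "converged": f.converged,
        }
        for (pid, side, variant), f in result.fits.items()
    ]
    with open(out / "fits.csv", "w") as fh:
        fh.write(f"# units: K1,k2 1/min\n# provenance: {prov}\n")
        pd.DataFrame(fit_rows).to_csv(fh, index=False)


def write_cohort_files(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort to disk: manifest, truth, TACs, and VOI tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = provenance_hash({"seed": cohort.seed, **dataclasses.asdict(cohort.config)})
    manifest = []
    truth = []
    for p in cohort.patients:
        r = p.record
        manifest.append(
            {
                "patient_id": r.id,
                "sex": r.sex,
                "age_years": r.age_years,
                "bsa_m2": r.bsa_m2,
                "creatinine_mg_dl": r.creatinine_mg_dl,
                "hct": r.hct,
                "activity_mbq": p.activity_mbq,
                "V_RC_left_ml": p.kidneys["left"].truth.v_rc_ml,
                "V_RC_right_ml": p.kidneys["right"].truth.v_rc_ml,
            }
        )
        write_voi_table(p.voi_table, out / f"{r.id}_aorta_voi.csv", provenance=prov)
        for side, kidney in p.kidneys.items():
            write_tac(kidney.cortical, out / f"{r.id}_{side}_cortex.csv", provenance=prov)
            write_tac(kidney.urine, out / f"{r.id}_{side}_urine.csv", provenance=prov)
            t = kidney.truth
            truth.append(
                {
                    "patient_id": r.id,
                    "side": side,
                    "K1_per_min": t.k1_per_min,
                    "k2_per_min": t.k2_per_min,
                    "vB": t.vb,
                    "gfr_true": t.gfr_ml_min,
                }
            )
    with open(out / "manifest.csv", "w") as fh:
        fh.write(f"# units: age y, BSA m2, creatinine mg/dl, V_RC ml\n# provenance: {prov}\n")
        pd.DataFrame(manifest).to_csv(fh, index=False)
    with open(out / "truth.csv", "w") as fh:
        fh.write(f"# units: K1,k2 1/min; GFR ml/min\n# provenance: {prov}\n")
        pd.DataFrame(truth).to_csv(fh, index=False)
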