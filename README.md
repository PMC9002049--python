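# petgfr

Non-invasive estimation of the glomerular filtration rate (GFR) from dynamic
renal PET, for researchers in nuclear medicine and tracer kinetics who want a
tested, reproducible reference implementation of the whole analysis chain —
from time–activity curves to method-agreement statistics — without needing
clinical image data.

## The model

A freely filtered, non-reabsorbed PET tracer (e.g. a ⁶⁸Ga-labelled chelate)
enters the extravascular functional renal cortex (EC) only by glomerular
filtration and leaves it by urinary excretion:

```
dC_EC/dt = K1 · C_P(t) − k2 · C_EC(t),    C_EC(0) = 0
C_EC(t)  = K1 · C_P(t) ⊗ e^(−k2 t)
```

with `C_P` the plasma input, `K1 = GFR / V_EC` (1/min) the influx constant,
`k2` (1/min) the urinary washout constant, and `⊗` the convolution integral.
The operational curve fitted to the measured cortical TAC adds a fractional
blood volume `vB`:

```
C_model(t) = (1 − vB) · C_EC(t) + vB · C_aorta(t)
```

Per kidney, `GFR = V_RC · (1 − vB) · K1`, with `V_RC` the segmented
functional cortical volume; total GFR is the sum over both kidneys.

The plasma input is image-derived: the aortic whole-blood concentration comes
from an oversized VOI with background subtraction,

```
C_aorta(t) = (A_oversized(t) − C_background(t) · (V_oversized − V_aorta)) / V_aorta
```

and is converted to plasma by the haematocrit, `C_P = C_aorta / (1 − HCT)`.
The serum-creatinine reference is the 2009 CKD-EPI equation, de-normalized to
absolute ml/min via the patient's body surface area (× BSA / 1.73).

Because activity in the collecting system spills into the cortical VOI —
delayed, and most prominent 2–10 min after injection — each kidney is fitted
four ways: on the full 30-min and truncated 15-min data, each with and
without excluding frames whose mid-times fall in [120 s, 600 s].

## Worked example

```python
from petgfr import CohortConfig
from petgfr.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1, cohort=CohortConfig(n_patients=12)))
print(result.gfr_table.head(3).round(1).to_string(index=False))
a = result.agreement["gfr_pet30_vs_ckd"]
print(f"PET-30 vs reference: PCC {a.pcc:.2f}, ICC {a.icc:.2f} "
      f"({a.icc_bounds[0]:.2f}-{a.icc_bounds[1]:.2f}) [{a.icc_category}], "
      f"bias {a.bias:.2f} ml/min")
```

prints

```
patient_id  gfr_ckd  obstruction  gfr_pet30  gfr_pet30_wo2to10  gfr_pet15  gfr_pet15_wo2to10
       S01     87.2         True       73.3               73.7       73.5               76.0
       S02     66.4         True       66.2               65.7       66.8               65.9
       S03     82.4         True       76.3               75.1       77.4               77.4
PET-30 vs reference: PCC 0.93, ICC 0.90 (0.68-0.97) [good], bias -4.68 ml/min
```

Each row is one simulated patient: `gfr_ckd` is the absolute CKD-EPI
reference (ml/min) derived from the simulated creatinine, and the four PET
columns are total GFR from the four fitting variants. The agreement line
says the 30-min PET estimate correlates strongly with the reference
(Pearson 0.93), has good reliability (ICC 0.90 with its 95% bounds), and
underestimates it by 4.7 ml/min on average in this noisy cohort.

The same battery runs on the packaged 12-patient clinical GFR table:

```python
from petgfr import PairedSeries, pearson_ci
from petgfr.tacio import load_table4, unobstructed_ids

t4 = load_table4()
r, lo, hi = pearson_ci(PairedSeries(t4["gfr_ckd"], t4["gfr_pet30"]))
print(round(r, 2))   # 0.78 over all 12 patients; 0.95 in the n=9
                     # subgroup without urinary obstruction
```

A command-line interface mirrors the library:
`petgfr simulate | aif | fit | gfr | agree | pipeline` (see `petgfr --help`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the complete pipeline from scratch on the default synthetic cohort —
cohort simulation, input-function estimation, all 96 kinetic fits, GFR
derivation, and the agreement battery — and recomputes the correlation
statistics of the packaged clinical GFR table, printing all results and
writing the JSON manifest to `--out`.
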