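# modioloc

Method-comparison analysis for cochlear-implant electrode localization:
coordinate transforms with multi-turn angle unwrapping, post-hoc collocation
of the mid-modiolar axis, and a Bland–Altman / ICC agreement battery, with a
synthetic spiral-cohort simulator for validation.

## The problem

After cochlear implantation, each electrode contact is localized in
post-operative imaging by two polar parameters relative to the mid-modiolar
axis (the central axis of the cochlear spiral): the electrode-to-modiolar-axis
distance **EMD** (mm) and the angular depth of insertion **aDOI** (degrees
from the round window; > 360° past a full turn). When an automatic
localization tool is compared against manual expert measurements — or one
rater against another — the two sides choose the mid-modiolar axis
independently. A between-method axis offset leaves a systematic, partially
periodic pattern in the per-electrode differences that inflates the limits of
agreement even when the electrodes themselves were found consistently.

`modioloc` implements the full comparison workflow for audiology/otology
researchers validating automatic localization methods:

* **measurement model** — `x = EMD·cos(aDOI)`, `y = EMD·sin(aDOI)` and the
  inverse with multi-turn unwrapping (a wrap event is a consecutive electrode
  pair crossing from [270°, 360°] to [0°, 90°]; each adds 360° downstream);
* **collocation** — the axis offset between two measurement sets is removed
  by minimising
  `cost(shift) = (1 − ρ(EMD_t, EMD_ref)) + (1 − ρ(aDOI_t, aDOI_ref))`
  over uniform 2-D translations of the moving set (Nelder–Mead multi-start,
  with a brute-force grid oracle for verification);
* **agreement statistics** — Bland–Altman bias and limits of agreement
  (bias ± 1.96·SD), percentage error, Pearson r with Fisher-z CI, two-way
  absolute-agreement ICC, Lilliefors-corrected KS normality, and subgroup
  bias tests (rank-sum / one-way ANOVA) for confounder screening;
* **synthetic cohorts** — log-spiral electrode trajectories, hidden axis
  offsets and noise calibrated to a given interrater precision
  (LoA = 1.96·√2·σ), with ground-truth sidecars for parameter recovery.

See `docs/methods.md` for the model, numerical choices and limitations.

## Worked example

`examples/04_full_pipeline.py` simulates a 50-array cohort measured by a
"manual" reference and an "auto" candidate whose axis is offset by ~0.3 mm
per array, derives a-priori interrater criteria, and compares the methods
before and after collocation:

```text
a-priori criteria: +/-0.206 mm EMD, +/-10.13 deg aDOI
[EMD] bias +0.019 mm (criterion +/-0.206: PASS)
  LoA half-width 0.461 -> 0.179 mm (61.2% reduction)
[aDOI] bias -0.233 deg (criterion +/-10.129: PASS)
  LoA half-width 15.099 -> 10.211 deg (32.4% reduction)
```

Reading: the interrater precision of the reference method (±0.206 mm,
±10.1°) is the a-priori ceiling for an acceptable between-method bias; both
parameters pass. Collocating the axes shrinks the EMD limits of agreement by
~61% — the systematic axis-offset component is gone and the residual scatter
is near the interrater noise floor — while aDOI, which is less sensitive to
a radial axis offset, shrinks by ~32%. The run also writes scatter,
Bland–Altman (pre/post), polar per-electrode mean and shift-map figures plus
`report.json` to `pipeline_out/`.

The other examples demonstrate the coordinate round-trip (`01`), hidden-offset
recovery to micrometre precision on noise-free pairs (`02`), and the
statistics battery on interrater-style data (`03`).

## Command line

The same workflow is available as a thin CLI:

```sh
modioloc simulate --seed 5 --n-arrays 50 --out cohort
modioloc apriori --seed 5 --out criteria.json
modioloc compare --input cohort/measurements.csv --criteria criteria.json \
    --seed 5 --out run
modioloc report --run-dir run
```

Input CSVs have one row per (array, method, electrode):
`array_id,method,electrode,emd_mm,adoi_deg`.

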