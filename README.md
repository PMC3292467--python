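# dynpet

Quantitative analysis of dynamic small-animal PET studies comparing two
receptor tracers in two animal groups. The package covers the full desk-side
pipeline:

- **`dynpet.core`** — acquisition frame schedules and time–activity curves
  (TACs), with the default 28-frame, 60-min protocol (10×30 s, 5×60 s,
  5×120 s, 8×300 s) and CSV I/O.
- **`dynpet.kinetics`** — two-tissue compartment model with vascular
  fraction: closed-form impulse response and frame-averaged forward
  simulation, influx `Ki = K1·k3/(k2+k3)` and receptor-binding macro
  parameters, and bounded multi-start weighted nonlinear least-squares
  fitting of (K1, k2, k3, k4, VB).
- **`dynpet.input_function`** — image-derived blood curves as sums of up to
  three decaying exponentials, with AICc term selection on post-peak frames.
- **`dynpet.quantification`** — SUV conversion, late (55–60 min) SUV, and
  recovery-coefficient partial-volume correction (anchors 0.32 @ 3 mm,
  0.85 @ 8 mm by default).
- **`dynpet.fractal`** — box-counting fractal dimension of the time–SUV
  curve (grids 1..7, SUV normalized by 20).
- **`dynpet.stats`** — group summaries, two-sided Wilcoxon rank-sum tests
  (normal approximation without continuity/tie corrections by default, plus
  an exact enumeration oracle), and SVM-RFE feature ranking.
- **`dynpet.synthetic`** — seeded synthetic two-group cohorts (blood curves,
  tumor TACs, metadata) for testing every downstream stage without real
  data.
- **`dynpet.pipeline`** — end-to-end orchestration (PVC → input fit → 2TCM
  fit → SUV → FD → group statistics) with deterministic, hashable reports.

## CLI

```sh
# generate a synthetic 5+4 cohort
dynpet simulate --out cohort/ --seed 1 --noise 0.05

# fit the compartment model for one animal
dynpet fit --tumor cohort/B01_tumor.csv --input cohort/B01_blood.csv \
    --out fit.json --starts 32 --seed 1

# SUV and fractal dimension
dynpet suv --tac cohort/B01_tumor.csv --dose 3e7 --weight 300
dynpet fd  --tac cohort/B01_tumor.csv --dose 3e7 --weight 300

# full pipeline on a cohort manifest, or one-shot simulate+run
dynpet run    --manifest cohort/manifest.json --out report.json
dynpet simrun --out report.json --seed 1
```

Pipeline options (diameters, recovery anchors, fit starts/seed, FD and
statistics settings, failure policy) come from a YAML config passed with
`--config`; see `dynpet.pipeline.StudyConfig` for keys and defaults.

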