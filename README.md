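# thermoperf

Thermal-physiology analysis pipeline for comparative ectotherm studies:

* **Thermal performance curves (TPCs)** — three unimodal curve families
  (exponentially modified Gaussian, asymmetric logistic, Gumbel peak),
  fitted to per-treatment swimming speeds with zero-performance anchors at
  the mean critical thermal limits, selected by small-sample AICc after an
  R² floor, with derived metrics: maximum performance (Vmax), optimum
  temperature (To), performance breadth (B80), thermal safety margin (TSM)
  and tolerance breadth (TTB).
* **Swim-trial kinematics** — per-segment video frame counts → segment
  speeds → per-trial maximum swimming speed.
* **Open-flow respirometry** — excurrent CO₂ traces reduced by the
  lowest-100-s-window rule, VCO₂ = flow × (FeCO₂ − FiCO₂), and Q10 thermal
  sensitivity between treatments and overall.
* **Metabolic scaling statistics** — log10 RMR modelled by seven candidate
  mixed models (individual random intercept, ML objective, AICc selection,
  conditional R²), mass-adjusted marginal means with pairwise contrasts,
  and tie-corrected Kruskal–Wallis + Dunn (Holm) rank tests.
* **Synthetic data** — seeded generators for every pipeline input,
  parameterized so the default three-species system reproduces the
  reference study's qualitative structure end to end.

## Command line

```bash
# write a synthetic CSV bundle (speeds, trials, tolerance, rmr [, traces])
thermoperf simulate --out data/ --seed 1

# full pipeline: TPC fits/metrics, RMR, Q10, model selection, contrasts
thermoperf report --out results/ --seed 1 \
    --speeds data/speeds.csv --tolerance data/tolerance.csv --rmr data/rmr.csv

# single stages and schema validation
thermoperf tpc --speeds data/speeds.csv --tolerance data/tolerance.csv --out results/
thermoperf rmr --traces data/traces.csv --out results/
thermoperf models --rmr data/rmr.csv --out results/
thermoperf validate data/speeds.csv --schema speeds
```

Options can also come from a YAML file via `--config` (keys mirror
`thermoperf.pipeline.RunConfig`). Exit codes: 0 ok, 1 validation error,
2 computation error. Every run writes a `manifest.json` recording the seed,
config hash and per-stage row counts, and refuses to overwrite a previous
run unless `--overwrite` is given.

## Layout

```
src/thermoperf/
  families.py        curve family registry (catalog hook for new families)
  tpc.py             tolerance types, anchored fitting, AICc, selection, metrics
  kinematics.py      frame counts → segment speeds → trial maximum
  respirometry.py    traces → stable window → VCO₂ → RMR → Q10
  metabolic_stats.py mixed models, marginal means, rank tests
  synthetic.py       species profiles + seeded generators
  io.py              CSV schemas, validation, readers/writers
  pipeline.py        run_all orchestration + manifest
  cli.py             click command line
```
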