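# oscivar

Day-to-day variability of respiratory resistance from daily home oscillometry
— simulation, intra-breath signal processing, and diagnostic evaluation.

## The problem

Excessive day-to-day variability of lung function is a hallmark of asthma,
but conventional peak-flow monitoring separates asthma from COPD poorly.
Daily *oscillometry* (forced oscillation technique) offers an alternative: a
small 5 Hz sinusoidal pressure is superimposed on quiet tidal breathing at
the mouth, and the respiratory resistance

    R = Re(Z),   Z(f₀) = P̂(f₀) / Q̂(f₀)

is estimated from the oscillatory pressure/flow ratio at the forcing
frequency f₀.  How variable R is from day to day depends critically on
*which part of the breath is sampled*: expiration is contaminated by dynamic
airway compression and expiratory flow limitation (severe in COPD), and
early inspiration by end-expiratory volume history.  Sampling only the
central 20–80 % of inspiration (R_mid-insp) isolates the airway-calibre
signal, and its day-to-day coefficient of variation over a two-week window,

    CVR = SDR / meanR,

is specifically elevated in asthma, independent of the degree of airflow
obstruction.

`oscivar` implements that entire analysis as a tested pipeline, plus a
synthetic-cohort generator with known ground truth, so every stage — from
raw pressure/flow samples to the diagnostic cutoff — can be validated
without clinical recordings.

## What is in the package

| module | contents |
| --- | --- |
| `oscivar.cohort` | synthetic cohorts: per-subject physiology, lognormal daily resistance levels, full raw-signal synthesis through a single-compartment model (R, elastance, inertance), artifact injection, ground truth |
| `oscivar.processing` | zero-phase component separation, per-cycle sine-fit impedance estimation, hysteresis breath segmentation, artifact rejection, the three intra-breath sampling schemes (full breath / full inspiration / 20–80 % mid-inspiration) |
| `oscivar.variability` | daily series with missing-day handling, adherence-based subject retention, CVR at arbitrary time scales (sliding windows, ≥10-of-14-points rule) |
| `oscivar.diagnostics` | rank AUC with bootstrap CI, exponential AUC-vs-time-scale fit (time constant τ, 5τ minimum-observation rule), stratified 5-fold cross-validated Youden cutoff, sensitivity/specificity/diagnostic odds ratio with CIs |
| `oscivar.recording`, `oscivar.config`, `oscivar.cli` | CSV recording format, YAML configuration with `development`/`validation` presets, and the `oscivar` command line |

## Worked example

```python
from oscivar import (CohortSpec, generate_cohort, process_cohort,
                     variability_from_cohort, diagnostic_report)

spec = CohortSpec(group_sizes={"asthma": 15, "healthy": 12, "copd": 8},
                  n_days=14, rng_seed=42)
cohort = generate_cohort(spec)                      # raw 2-min recordings
breaths = process_cohort(cohort)                    # per-breath resistance
table = variability_from_cohort(cohort, breaths,    # 14-day CVR per subject
                                scales=[14], schemes=("mid_insp",))
print(table.groupby("group")[["meanR", "SDR", "CVR"]].mean().round(3))
rep = diagnostic_report(table, scheme="mid_insp", scale=14,
                        k_folds=5, seed=42, n_boot=500)
print(f"AUC = {rep['auc']:.3f}")
```

prints

```
         meanR    SDR    CVR
group
asthma   3.437  0.523  0.142
copd     5.155  0.555  0.107
healthy  2.339  0.165  0.068
AUC = 0.744
```

Asthmatic subjects show the largest mid-inspiratory CVR (0.142) even though
COPD subjects are the most obstructed (meanR 5.2 cmH₂O·s·L⁻¹) — variability,
not obstruction, carries the asthma signal.  SDR tracks meanR across groups
while CVR does not.  The AUC of 0.74 reflects this deliberately small
35-subject cohort; at the published cohort sizes (45/33/20) the simulated
AUC averages 0.86.

The same pipeline is available from the shell:

```bash
oscivar simulate --config cohort.yaml --out data/ --seed 1
oscivar process --in data/ --out breaths.csv
oscivar variability --breaths breaths.csv --manifest data/manifest.json \
        --scales 2:14 --out var.csv
oscivar evaluate --var var.csv --scheme mid_insp --scale 14 --seed 1 \
        --out report.json
# or all four stages in memory:
oscivar run --preset validation --out out/ --seed 1
```

Identical seed and configuration give byte-identical outputs.

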