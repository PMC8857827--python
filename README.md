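# growthdx

Compare a **customized fetal growth standard** against a **table-based
population standard** for predicting neonatal undernutrition in high-risk
(hypertensive) pregnancies.

The package implements:

* **Customized standard** (`growthdx.customized`) — a linear term-optimal-weight
  model of maternal age, pregestational weight, height and fetal sex, scaled
  across gestation by a cubic proportionality polynomial; z-scores via a fixed
  coefficient of variation (0.12) and SGA/AGA/LGA classification at the
  10th/90th centiles. A config-driven log10 biometry EFW utility is included.
* **Population standard** (`growthdx.population`) — a pluggable sex × GA table
  of weight centile parameters (normal or skew-normal rows) with linear
  interpolation and strict coverage checks. The packaged table is a clearly
  labelled *synthetic demonstration* table, not a published standard; a real
  one drops in via the same CSV schema.
* **Neonatal nutrition** (`growthdx.nutrition`) — neonatal BMI and ponderal
  index, sex × completed-week reference tables (packaged as CSV), centile
  lookup and undernourished/normal/overnourished classification (overnourished
  records are flagged for exclusion from diagnostics).
* **Diagnostics** (`growthdx.diagnostics`) — audited 2×2 construction
  (SGA exposure vs undernutrition outcome), sensitivity/specificity/PPV/NPV
  (Clopper–Pearson CIs), LR±/DOR (log-normal CIs), Youden index (seeded
  bootstrap or delta-method CI), Katz relative risks, log-scale comparison of
  two RRs, McNemar paired tests and χ² proportion comparisons.
* **Synthetic cohorts** (`growthdx.simulate`) — seeded cohort generator with
  realistic maternal marginals, a Gaussian-copula coupling between fetal-size
  and nutrition latents, and an optional growth-restriction shift; plus a
  Monte-Carlo harness for operating-characteristic recovery.
* **Pipeline + CLI** (`growthdx.pipeline`, `growthdx.cli`) — end-to-end
  classify → nutrition → diagnostics → report, stratified (all / term 37–42 /
  preterm < 37 weeks), emitting tidy CSVs, a forest-plot-ready DOR CSV and a
  Markdown report.

## CLI

```bash
# generate a synthetic 226-pregnancy cohort with a growth-restriction shift
growthdx simulate --out cohort.csv --n 226 --seed 1 --hdp-shift -0.8

# per-record size (both standards) + nutrition classification
growthdx classify --input cohort.csv --out classified.csv            # EFW at scan GA (default)
growthdx classify --input cohort.csv --out classified.csv --mode birth

# diagnostics from a persisted classification file
growthdx compare --classifications classified.csv --outdir report/

# end-to-end
growthdx all --input cohort.csv --outdir report/ --seed 1
```

Exit codes: `0` success, `2` validation failure, `3` empty analysis set.

Cohort CSV columns: `maternal_age, maternal_height, pregestational_weight,
sex, ga_scan, efw, ga_birth, birthweight, birth_length` (sex as
`male`/`female`/`M`/`F`/`1`/`0`).

## Conventions worth knowing

* The proportionality polynomial is used **raw** — its value at 40 weeks is
  ~100.3%, not renormalised, which is what reproduces the published worked
  example (66.21% at 34 weeks).
* Centile ties at exactly the 10th/90th are classified AGA (size) and normal
  (nutrition).
* Nutrition reference lookup floors gestational age to completed weeks;
  records outside 32–42 completed weeks are flagged out-of-coverage and
  excluded with an audit count, never dropped silently.
* Continuity corrections (+0.5 per cell) are opt-in and always recorded.
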