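# fetalhand

Analysis toolkit for inferring postnatal handedness from prenatal
arm-movement kinematics. It implements, as a tested reusable pipeline:

- **data model & I/O** — tidy per-movement CSVs (fetus, handedness label,
  gestational week ∈ {14, 18, 22}, target ∈ {eye, mouth, wall}, hand, MT,
  TPV), a packaged movement-count fixture, and descriptive summaries;
- **kinematics** — MT/TPV extraction from calibrated 2-D tracked
  trajectories sampled at 4 Hz (intraocular-distance calibration,
  finite-difference speeds, threshold onset/offset detection);
- **robust statistics** — Hodges-Lehmann two-sample location estimator,
  Welch U-test (Welch's t on pooled mid-ranks), Benjamini-Hochberg FDR
  control, Spearman/Pearson, exact binomial, Wilcoxon rank-sum;
- **lateralization analyses** — right-hand-use proportions with binomial
  tests, total-movement comparisons, the 18 per-condition group
  comparisons, within-subject RH/LH correlations;
- **HAA classification** — per-fetus hand-asymmetry advantage
  (HAA = RH − LH; rHAA = 2(RH−LH)/(RH+LH)), sign-rule classification with
  label-permutation p-values, group HAA separation, a min-distance
  silhouette variant, leave-one-out cross-validated logistic regression,
  and the pooled-mouth analysis;
- **developmental trajectory** — Spearman MT-vs-week trend and 8-bin mutual
  information with the Treves-Panzeri first-order bias correction;
- **synthetic cohorts** — a seeded generator with the statistical structure
  the analyses assume (shared per-fetus speed offsets, ±δ/2 dominant-hand
  splits, published count marginals), so the full pipeline is testable
  offline.

## CLI

```bash
# generate a synthetic cohort (optionally overriding the generator config)
fetalhand simulate --seed 1 --out cohort.csv
fetalhand simulate --config cfg.yaml --seed 1 --null --out null_cohort.csv

# run the full analysis pipeline -> tidy CSVs + manifest.json
fetalhand analyze --input cohort.csv --outdir report/ --seed 1

# human-readable summary of a report bundle
fetalhand report --bundle report/

# quick internal oracle battery (brute-force cross-checks)
fetalhand selfcheck
```

`analyze` emits one CSV per stage (counts, RH-use proportions, 18-condition
comparisons per metric, the HAA accuracy/separation grid per metric, the
Spearman/LOOCV/silhouette follow-up grid, developmental trends/MI) plus a
`manifest.json` echoing config, seeds, permutation counts, and exclusion
diagnostics. Reruns with the same input, config and seed are byte-identical.
Exit codes: 2 for input validation failures, 1 for computation failures.

## Conventions

- MT is stored in milliseconds internally; CSVs may declare seconds via an
  `mt_s` column, converted on read. TPV is a percentage of MT in (0, 100).
- Sign conventions: per-fetus HAA = RH mean − LH mean. For MT, `haa < 0`
  predicts right-handedness (dominant hand faster); for TPV, `haa > 0`
  (dominant hand decelerates for a shorter fraction of the movement).
- Permutation p-values default to the literal strictly-greater rule;
  `rule={"greater","greater-equal","mid"}` and an add-one-smoothed variant
  are available (see docstrings for the tie-handling trade-offs at small n).
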