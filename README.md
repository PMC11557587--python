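# deltapet

Differential task-associated FDG-PET analysis for paired-scan
(pre/post behavioral task) small-animal studies, plus the behavioral and
statistical machinery around it:

- **synthetic** — phantom PET cohorts (two scans per subject, two groups,
  planted group-by-region uptake effects) and frame-wise activity traces
  with group-specific freezing-bout structure, so every downstream stage
  is testable with no external data.
- **behavior** — freezing scoring from activity traces: threshold
  classification, 10-s epoch percentages, ≥2-s bout detection from the
  unbinned mask, windowed summaries and pre/post change.
- **roi** — the core differential quantification: normalize each scan to
  its within-brain mean, extract mean uptake per (region, coronal slice,
  hemisphere) mask object, and difference the two sessions into
  delta-SUV (post − pre).
- **stats** — pooled/Welch t tests (from raw samples or printed
  mean ± SEM summaries), two-sample KS tests, linear mixed models
  (delta-SUV ~ group with a per-subject random intercept), and
  region-vs-behavior Pearson correlations.
- **classify** — leave-one-out cross-validated classification of
  subjects from the 8 region features (linear logistic, linear
  max-margin, and GentleBoost with regression stumps implemented from
  its exact weight updates), with confusion rates, pooled-score ROC/AUC
  and scrambled-label controls.
- **ort** — ordinal-trend covariance-pattern analysis: PCA of the
  subject-and-condition centered scan matrix, AIC selection over
  component subsets, within-subject condition-flip permutation test, and
  subject-level bootstrap voxel reliability maps.
- **cli / report** — a `deltapet` command-line tool and a pipeline
  orchestrator emitting plot-ready CSV/JSON tables (epoch time-series
  with mean ± SEM, bout tables, network maps, ROC points) and NIfTI
  voxel maps, with a checksummed run manifest.

## CLI

```bash
# write a synthetic fixture bundle (volumes, masks, traces, manifest)
deltapet simulate demo_bundle --n-per-group 9,15 --noise-sd 0.02 --seed 1

# run the whole pipeline on it
deltapet run --bundle-dir demo_bundle --out-dir demo_out --seed 1

# or individual stages
deltapet freeze demo_bundle/trace_CON00_F3.csv --threshold 0.1 --window 180,480
deltapet suv demo_bundle --session F1 --out-csv f1.csv
deltapet suv demo_bundle --session F3 --out-csv f3.csv
deltapet delta f1.csv f3.csv --out-csv delta.csv
deltapet stats delta.csv
deltapet classify delta.csv --model linear-logistic --scrambles 50 --seed 1
deltapet ort demo_bundle --n-perm 500 --n-boot 500 --seed 1
```

A full run can also be driven from a YAML config (see
`deltapet.report.RunConfig`): `deltapet run config.yaml`.

## Conventions worth knowing

- "SUV" here means uptake normalized to the scan's within-brain mean
  (dimensionless), not dose/body-weight scaling.
- A frame whose activity score equals the threshold counts as inactive
  (configurable tie rule); trailing partial epochs are reported
  separately and excluded from averages.
- Delta tables pool slices and hemispheres unweighted; a voxel-weighted
  mean is available.
- Permutation and bootstrap p-values use add-one numerators and
  denominators and are therefore never exactly zero.
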