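# stancelab

Clinical acceptability assessment for AI-predicted lower-extremity joint
moments during the stance phase of gait, in three steps:

1. **Kinetics labeling** — each record's measured moment trace defines its
   own acceptance band via the standardized peak `(max − mean) / sd`: the
   lower and upper kinetic limits are 10% and 20% of it.  The nRMSE
   between measured and predicted moments (RMSE over the peak-to-peak of
   the measured curve) is compared against the band to give a traffic-light
   label: **Green** (below the lower limit), **Yellow** (within the band,
   boundaries inclusive), **Red** (above the upper limit).
2. **Kinematic profiling** — MAX / ROM / MEAN per sagittal variable
   (pelvic tilt, hip flexion, knee flexion, ankle dorsiflexion), the Gait
   Profile Score against a typically-developed reference, label-conditioned
   summaries, and a five-subphase decomposition of the prediction error.
3. **Feasibility classification** — an 80/20 split and a linear
   discriminant model (empirical priors, pooled covariance, conditional
   ridge) mapping kinematic features to moment labels, scored by accuracy
   and per-class F-score, including the Green+Yellow merge.  Label-wise
   nRMSE distributions are compared with one-way ANOVA and
   Bonferroni-corrected pairwise t-tests (three labels at α = 0.05 give a
   corrected α of 0.017).

A synthetic cohort generator stands in for clinical data: crouch-like
sagittal kinematics driven by a severity parameter, physiological moment
templates, and injected smooth prediction error hitting exact per-record
nRMSE targets whose tier odds shift toward Red as severity rises.

All curves are time-normalized to 60 stance samples; left and right sides
are independent records.

## CLI

```sh
# generate a synthetic cohort (cohort.csv + meta, ground_truth.csv, reference.csv)
stancelab synth --n 500 --seed 1 --out-dir cohort_dir

# label a cohort's predicted moments per joint
stancelab label --cohort cohort_dir/cohort.csv --joint all --out labels.csv

# full three-step analysis with the report bundle
stancelab run --n 500 --seed 1 --out-dir report_dir
stancelab run --cohort cohort_dir/cohort.csv --reference cohort_dir/reference.csv \
              --seed 1 --out-dir report_dir
```

The report bundle contains per-record labels, the label-population table,
the features-by-label table, the classifier table, nRMSE histogram data,
subphase error profiles, and a run manifest — all as CSV/JSON.

Cohort files are long-form CSV (`subject_id, side, variable, sample_index
0–59, value`); moments are encoded as `HipMom_measured` /
`HipMom_predicted` (likewise `KneeMom`, `AnkleMom`), kinematics by plain
variable name.  A JSON mirror is available through the API
(`write_cohort_json` / `read_cohort_json`).

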