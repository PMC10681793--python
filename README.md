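# vitalalert

Early-warning scoring and machine-learning-assisted alerting for remote
patient monitoring of noncritical, ambulatory patients.

Remote patient monitoring systems that alarm on single thresholded vital
signs generate enough false alarms to desensitise clinicians (alarm
fatigue). `vitalalert` implements an alerting rule that requires *multiple
independent abnormality indicators* to agree before an alert is raised, plus
everything needed to develop and validate it without access to restricted
clinical data:

- **NEWS2 scoring** (`vitalalert.news2`): the National Early Warning Score 2
  banded chart for respiration rate, SpO₂ (scales 1 and 2), systolic blood
  pressure, pulse rate and body temperature, with the aggregate score and
  the low / low-medium / medium / high clinical-risk tiers. Consciousness is
  fixed to *alert* and breathing to *room air* — the noncritical monitoring
  setting — so those chart rows always contribute 0.
- **Alert fusion** (`vitalalert.alert_engine`): three binary indicators —
  classifier-predicted abnormality, NEWS2 aggregate above a threshold
  (default: strictly above 7), and resting heart rate outside 60–100 bpm —
  are counted into an alert score in {0, 1, 2, 3}, mapped to green / yellow /
  orange / red. Alerts are raised at orange and red only.
- **Risk classifiers** (`vitalalert.risk_model`): a registry of six
  configured models (random forest, logistic regression, decision tree, KNN,
  linear SVM, XGBoost) over eight unnormalised features (age, BMI, heart
  rate, systolic BP, respiration rate, temperature, SpO₂, blood sugar), with
  70/30 splitting, the confusion-matrix metric suite (accuracy, precision,
  recall, F1, MAE, RMSE on hard predictions; *abnormal* is the positive
  class), 10-fold cross-validation and a benchmark harness.
- **Synthetic cohorts** (`vitalalert.synthetic_cohort`): labelled cohorts
  whose marginals reproduce the published summary statistics (mean, std,
  min, max per variable) of the 1,177-record MIMIC-III vital-signs extract
  the original system was fitted on, via moment-matched truncated normals.
  The binary label rule is explicit and configurable (NEWS2-latent logistic
  or a known linear-logistic model), with optional label noise, injected
  missingness and group-mean imputation.
- **Records, pipeline and CLI** (`vitalalert.records`, `vitalalert.cli`):
  validated CSV/JSON patient records, automatic BMI (kg/m²), the batch
  pipeline NEWS2 → classify → HR flag → fuse, and the `vitalalert` command
  with `score`, `alert`, `simulate`, `train`, `benchmark` and `evaluate`
  verbs.

## Worked example

```python
import vitalalert as va

# NEWS2 for one set of vitals
vitals = va.VitalSigns(respiration_rate=22, spo2=95, systolic_bp=108,
                       pulse_rate=112, temperature=38.4)
news2 = va.compute_news2(vitals)
print(news2.component_scores, news2.aggregate, news2.clinical_risk.value)
# {'respiration_rate': 2, 'spo2': 1, 'systolic_bp': 1, 'pulse_rate': 2,
#  'temperature': 1} 7 high

# train and evaluate a risk classifier on a synthetic study-sized cohort
cohort = va.generate_cohort(va.CohortConfig(n=1177), seed=42)
train, test = va.split_dataset(cohort, 0.7, seed=42)   # 824 / 353 records
model = va.train_classifier(va.ClassifierSpec("logistic_regression"), train, seed=42)
cm, metrics = va.evaluate(model, test)
print(f"accuracy={metrics.accuracy:.3f} recall={metrics.recall:.3f} mae={metrics.mae:.3f}")
# accuracy=0.793 recall=0.606 mae=0.207

# full alerting pipeline on patient records
records = va.cohort_to_records(cohort.iloc[:5], seed=42)
result = va.run_pipeline(records, model)
print(result.summary)
# {'green': 3, 'yellow': 2, 'orange': 0, 'red': 0}
```

The vitals in the first block score 2+1+1+2+1 = 7 on the chart (high
clinical risk), but with a normal classifier outcome the NEWS2 alert
component would not fire under the default strict threshold (aggregate must
exceed 7) — the fusion rule demands more evidence than a single borderline
score. In the pipeline block, the two yellow patients each have exactly one
abnormal indicator; no alert is raised below two.

Or from the shell:

```bash
vitalalert simulate --n 1177 --seed 42 --out cohort.csv
vitalalert train --in cohort.csv --seed 42 --out model.joblib
vitalalert benchmark --in cohort.csv --seed 42 --out benchmark.csv
vitalalert alert --in cohort.csv --model-file model.joblib --out alerts.json
```

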