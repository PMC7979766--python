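# metasurv

Censoring-aware, image-based time-to-event modelling of distant metastasis
(DM) in head-and-neck cancer, for researchers who want to go beyond binary
outcome classification on masked planning CTs. The package implements the
full pipeline — masked-CT preprocessing, 2D/3D convolutional and
clinical-covariate survival networks with a discrete-time likelihood,
survival-curve output, fixed-horizon concordance, cross-validation
ensemble averaging, bootstrap 83% confidence intervals and Kaplan–Meier
risk stratification — together with a synthetic imaging-cohort generator
with known hazard structure, so every stage is testable end-to-end on a
desk without any data download.

## Model

Follow-up is discretised into 10 half-year intervals. A network maps the
GTV-masked CT (and/or seven clinical covariates) to per-interval
conditional DM-free probabilities *p<sub>j</sub>* through a sigmoid layer;
the survival curve is *S<sub>j</sub> = ∏<sub>k≤j</sub> p<sub>k</sub>*.
Training maximises the censoring-aware discrete-time likelihood

&nbsp;&nbsp;ℓ = −Σ<sub>patients</sub> Σ<sub>j</sub>
[ s<sub>j</sub> log p<sub>j</sub> + e<sub>j</sub> log(1 − p<sub>j</sub>) ],

where *s<sub>j</sub>* marks intervals fully survived (censored patients
get half-interval credit) and *e<sub>j</sub>* the event interval. The
scalar risk 1 − S(3 y) feeds Harrell's concordance index (HCI), the
bootstrap median with 83% percentile interval (two disjoint 83% intervals
≈ a difference at α = 0.05), and a high/low-risk split whose threshold is
derived from validation folds only and tested with the log-rank statistic.
See `docs/methods.md` for the full description.

## Worked example

Train the clinical-covariate survival ANN with 3-fold cross-validation on
a synthetic 300-patient cohort whose hazard is driven by tumor volume,
then evaluate the frozen fold models on an independent synthetic cohort
of 100 patients:

```python
from metasurv.synthetic import GeneratorConfig, generate_cohort
from metasurv.workflow import ExperimentConfig, full_experiment
from metasurv.models import TrainConfig
from metasurv.preprocessing import PreprocessConfig

gen = dict(volume_shape=32, voxel_spacing=2.0, event_prevalence_target=0.3,
           hazard_coefficients=(3.0, 0.0, 0.0))
cv_cohort = generate_cohort(GeneratorConfig(n_patients=300, seed=1, **gen))
test_cohort = generate_cohort(GeneratorConfig(n_patients=100, seed=2, **gen))

config = ExperimentConfig(
    task="time_to_event", model_family="ann", n_bootstrap=1000,
    preprocess=PreprocessConfig(target_spacing=2.0, input_extent=32, crop_extent=32),
    train=TrainConfig(learning_rate=1e-2, batch_size=32, epochs=2000,
                      early_stopping_patience=800),
    seed=0)
report = full_experiment(config, cv_cohort, {"external": test_cohort},
                         out_dir="example_out")
```

Output (deterministic for these seeds):

```
cv fold HCIs: [0.875, 0.815, 0.868]
external: median HCI 0.858 (83% CI 0.813-0.898)
threshold 0.209; high/low risk 34/66; log-rank p = 3.49e-14
```

The three fold HCIs are the per-fold validation concordances; the external
cohort is summarised by the bootstrap median HCI of the model-averaged
predictions with its 83% interval. The threshold 0.209 — learned on
validation folds only — splits the external cohort into 34 high-risk and
66 low-risk patients whose DM-free curves separate decisively (log-rank
p ≈ 3×10⁻¹⁴). `example_out/` receives the JSON report, Kaplan–Meier
tables/plots and per-patient survival curves.

The same experiment runs from the shell (`metasurv simulate`,
`metasurv train-cv`, `metasurv test`, `metasurv run`) driven by a YAML
config; image-based families (`cnn3d`, `cnn2d_clinical`, …) and the
texture-ablating binary input mode are selected the same way.

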