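# qsarkit

A QSAR (quantitative structure–activity relationship) toolkit for modelling
kinase-inhibitor potency, built around the wild-type / L858R-mutant EGFR
setting: quinazoline-type inhibitors of the wild-type kinase,
pyrazolopyrimidine-type inhibitors of the mutant, and the question of how
well a model trained on one chemotype transfers to the other.

It is aimed at computational medicinal chemists who want a reproducible,
scriptable version of the classical descriptor-selection-SVR workflow:

* **I/O** — SMILES/SDF structures joined with IC50 (nM) activity tables;
  potency as pIC50 = 9 − log10(IC50 nM); seeded 80/20 train/validation
  splits; docking-energy CSVs (the seven AutoDock-style terms) as optional
  feature columns.
* **Descriptors** — six RDKit-computed families: physicochemical,
  topological and constitutional blocks plus substructure, path-based and
  MACCS-like binary fingerprints.
* **Feature selection** — degenerate-column removal → pairwise-correlation
  pruning (|r| > 0.9) → CFS merit subset search
  (merit = k·r̄_cf / √(k + k(k−1)·r̄_ff), with the classical locally
  predictive post-pass) → remove-one backward elimination scored by
  cross-validated Pearson R → a floor(n/4) feature budget.
* **Models** — epsilon-SVR (linear/polynomial/RBF) on standardised
  features, 5-fold cross-validation with pooled out-of-fold predictions,
  JSON model persistence that reproduces predictions exactly.
* **Evaluation** — R, R² (1 − SSE/SST), MAE, RMSE; cross-class prediction
  reports.
* **Fragment analysis** — per-class enrichment of fingerprint bits,
  frequency(f, c) = (N_fc/N_c)/(N_f/N), plus strict and relaxed
  class-exclusive fragment detection and common-fragment listing.
* **Synthetic data** — a generator that enumerates substituted quinazoline
  and pyrazolo[3,4-d]pyrimidine series with a planted
  descriptor–activity mapping, nM-scale IC50s over ~3 log units and
  simulated docking energies, so the entire pipeline is testable without
  proprietary compound sets.

## Worked example

```python
from qsarkit import SynthConfig, generate_dataset, run_protocol, ProtocolConfig, SvrConfig
from qsarkit.metrics import EvaluationReport

config = SynthConfig(n_per_class=128, n_class_b=0, noise_sigma=0.3, seed=1)
compounds, energies, truth = generate_dataset(config)

result = run_protocol(
    compounds, energies, protocol="wild",
    config=ProtocolConfig(seed=1, svr=SvrConfig(seed=1)),
)

print(EvaluationReport.table_header())
for report in result.reports.values():
    print(report.to_table_row())
print("selected:", result.selected_features)
print("planted: ", sorted(truth["informative_features"]))
```

Output:

```
dataset                          n        R       R2      MAE     RMSE
wild_whole (fit)               128    0.982    0.964    0.185    0.230
wild_train (5-fold CV)         103    0.969    0.934    0.231    0.315
wild_valid                      25    0.961    0.910    0.274    0.331
selected: ['sub_fp_primary_amine', 'maccs_fp_025', 'maccs_fp_091', 'maccs_fp_093', 'maccs_fp_095']
planted:  ['maccs_fp_025', 'maccs_fp_091', 'maccs_fp_093', 'maccs_fp_095', 'sub_fp_primary_amine']
```

Reading it: 128 synthetic quinazoline analogues whose pIC50 is a planted
function of five fingerprint bits plus 0.3 log units of noise. The pipeline
re-selected exactly the five planted bits out of ~490 candidate
descriptors. The three rows mirror the classical whole / train / valid
report: the whole-set row is a training fit, the train row is pooled 5-fold
cross-validation on the 103-compound split, and the valid row applies the
training-split model to the 25 held-out compounds — R = 0.961 against an
attainable ceiling of ≈ 0.95–0.97 at this noise level. (The selected
feature set here contains no docking-energy term: the simulated binding
energy is only weakly activity-linked by default, and selection discards
it.)

The same run from the shell:

```bash
qsarkit synth --n-per-class 128 --seed 1 --outdir data/
qsarkit protocol data/structures.smi data/activity.csv --scope wild --seed 1 --outdir run/
qsarkit predict run/model.json data/structures.smi data/activity.csv
qsarkit fragments data/structures.smi data/activity.csv --strict-exclusive
```

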