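# pesuq — uncertainty quantification for reactive ML potential energy surfaces

Machine-learned potential energy surfaces (PES) interpolate superbly and
extrapolate poorly — and for *reactive* surfaces the chemically decisive
regions (transition states, distorted geometries) are exactly where training
data is sparse. `pesuq` is a toolbox for deciding **when to trust such a
model**: it implements the main uncertainty-quantification (UQ) families
used for neural PES models, the metrics that judge them as outlier
detectors, and a synthetic reactive benchmark with ground-truth
out-of-distribution (OOD) structures so everything can be validated end to
end without any quantum-chemistry data.

For a structure with reference energy `E_ref` and model prediction
`E_pred`, the question is whether a model-supplied uncertainty score ranks
the large-error structures (outliers, `ΔE = E_ref − E_pred`) at the top.
The implemented scores are:

- **Query-by-committee ensembles** — N independently initialized models;
  the uncertainty is the committee spread
  `σ_E = sqrt(1/N Σₙ (Ẽₙ − Ē)²)` (Ens-6 and the 1,3,5 sub-committee Ens-3).
- **Deep evidential regression (DER)** — a single network predicts the
  parameters of a Normal-Inverse-Gamma prior (γ, ν, α, β) over the Gaussian
  energy likelihood; aleatoric variance `β/(α−1)`, epistemic `β/(ν(α−1))`.
  Three flavours: DER-S (Student-t marginal NLL + evidence regularizer
  `λ(|ΔE|(2ν+α) − ε)`), DER-L (plus a Lipschitz-bounded error term with
  bound `U = min(U_ν, U_α)`), and DER-M (a bivariate Normal-Inverse-Wishart
  over energy and charge with scale matrix L and `ν ∈ (3,13)`).
- **Feature-space GMM** — a BIC-selected Gaussian mixture fitted to the
  training-set molecule feature vectors of one trained model; a test
  structure's uncertainty is the NLL of its features under the mixture
  (a rank score, deliberately never mapped to an energy variance).
- **Structure-based rank** — model-free: each of the R = n(n−1)/2
  interatomic distances scores 1 (bonded, inside the training 5–95%
  quantile band), 0.5 (non-bonded, in band) or 0; bonded means below 1.2×
  the mean of the two van der Waals radii. Low rank = structurally OOD.

Evaluation follows the outlier-detection protocol: top-k accuracy
`|TopErr(N_err) ∩ TopVar(N_var)| / min(N_err, N_var)` and its 2-D
reliability grid, TP/FP/TN/FN threshold classification with sensitivity /
precision / fall-out / miss rates, RMSE-vs-RMV calibration curves, and
rank-vs-error reports. NVE velocity-Verlet dynamics and finite-difference
harmonic frequencies validate any energy/force provider (the analytic
benchmark or a trained model).

## Worked example

The benchmark is an 8-atom double-well H-transfer system (Morse/angle/LJ
terms plus a calibrated transfer term; exact analytic forces). A window on
the transfer coordinate `q = r(D–H) − r(A–H)` around the transition state
is *excluded from training* and provides ground-truth outliers:

```bash
python examples/01_build_benchmark.py
```

```
rigid-scan barrier      : 20.000 kcal/mol
well asymmetry          : 5.000 kcal/mol
transfer coordinate q at reactant/saddle/product: -0.345 / +0.095 / +0.506 Å
held-out window on q    : (-0.169, +0.342) Å

train/validation        : 500 structures, relative energies 0.7-75.2 kcal/mol (cap 400)
test set                : 250 structures, 50 inside the held-out transition-state window
median relative energy  : in-distribution 21.3, held-out 11.3 kcal/mol
```

Note the held-out structures sit at *moderate* energies — outliers near
the transition state, not at the top of the energy distribution, which is
what makes the detection problem non-trivial. Training a committee and
scoring it (`examples/02_ensemble_uq.py`) then shows the committee
variance several-fold higher on the held-out structures than on
in-distribution ones, and top-k detection accuracies far above the random
baseline. The other examples cover the evidential heads
(`03_evidential_heads.py`), GMM scoring (`04_gmm_scoring.py`), the
detection/classification/calibration metrics (`05_outlier_metrics.py`),
the structure rank (`06_rank_metric.py`) and MD validation
(`07_md_validation.py`).

A thin CLI wraps the same library for shell pipelines:

```bash
pesuq generate --seed 7 --out run
pesuq train --data run/trainval.xyz --members 6 --out run
pesuq predict --data run/test.xyz --models run/model_scalar_*.npz --out run
pesuq eval-outliers --scores run/scores.csv --n-err 25 --n-var 100 --out run
```

Subcommands: `generate`, `train`, `predict`, `eval-outliers`, `classify`,
`calibrate`, `rank`, `md`, `report`; each writes its outputs plus a
`manifest.json` record into the run directory and refuses to overwrite
without `--force`.

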