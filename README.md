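# abvisc

Antibody viscosity prediction from the electrostatic-potential surface of
the variable fragment, with a 3D convolutional network and
integrated-gradients interpretation.

## The problem

Therapeutic monoclonal antibodies are formulated at high concentration
(≥150 mg/mL), where some candidates become too viscous to manufacture or
inject. Rheometric viscosity measurement needs >100 mg of purified protein,
so measured datasets are tiny — a few dozen molecules — which rules out
conventional deep learning on raw structures. `abvisc` implements a
biophysically constrained alternative: the model sees only the
electrostatic potential (ESP) φ on a ~2 Å shell around the solvent-excluded
surface of the Fv domain, voxelized on a cubic grid (±36 Å, 0.75 Å
spacing), and regresses log₁₀ η (η in centipoise at 150 mg/mL) with a small
3D CNN:

    x ∈ R^(128³)  (masked ESP shell, zero elsewhere)
    F(x) = Linear ∘ Dropout ∘ Flatten ∘ [Conv3×3×3 → ReLU → MaxPool2]⁶ (x)

trained with Huber loss, Adam, batch size 1, rotation augmentation (10
random poses per structure), and a 10-fold cross-validation ensemble whose
10 × 10 pose × model predictions are averaged at inference. Trained models
are interpreted with integrated gradients: voxels with |score| above one
standard deviation of the pooled nonzero scores form surface *patches*
(1.5 Å linkage) whose size, biophysical composition (Asp/Glu, acceptor,
aromatic, donor, lipophilic) and Fv-segment composition quantify what the
network has learned. The ESP itself comes from a finite-difference
linearized Poisson–Boltzmann solver (ε_in = 1, ε_out = 80) written on the
same grid.

Everything — including the CNN forward/backward passes — is implemented on
numpy/scipy, so results are bit-reproducible under a fixed seed. See
`docs/methods.md` for the full model description and design rationale.

## Worked example

Synthetic structures stand in for antibody Fv models: pseudo-proteins with
controllable negative surface patches whose log-viscosity is generated as a
noisy monotone function of *negative patch area* (shell voxels with
φ ≤ −1 kT/e), computed by the package's own pipeline.

```python
from abvisc import CnnViscosityRegressor
from abvisc.synthetic import make_labeled_dataset

recs = make_labeled_dataset(24, seed=1)      # structures + labels in cP
X = [r.structure for r in recs]
y = [r.viscosity_cP for r in recs]

reg = CnnViscosityRegressor(n_folds=3, epochs=200, seed=7)  # desk profile
reg.fit(X[:20], y[:20])
print(reg.predict(X[20:]).round(1), [round(v, 1) for v in y[20:]])
```

The same study, run end to end with held-out predictions and attribution
analysis:

```python
from abvisc.studies import run_recovery_study
study = run_recovery_study(seed=1)
print(round(study.heldout_spearman, 3),
      round(study.top_quartile_mean_patch, 2),
      round(study.bottom_quartile_mean_patch, 2))
```

prints

```
0.99 6.0 4.31
```

i.e. each of the 24 structures, predicted by the cross-validation fold that
held it out, ranks with Spearman ρ ≈ 0.99 against its true viscosity, and
the mean total positive-attribution patch area (per model × rotation
replica) of the top-quartile-viscosity structures exceeds the bottom
quartile's — the model attributes high predicted viscosity to the
engineered negative surface patches.

There is also a CLI covering the whole pipeline:

```sh
abvisc synth --n 24 --seed 1 --out data/
abvisc train --labels data/labels.csv --out ens/ --preset desk-test --seed 1
abvisc predict --ensemble ens/ --pdb data/toy000.pdb --out pred.csv
abvisc attribute --ensemble ens/ --pdb data/toy000.pdb --out attr/
abvisc evaluate --pred pred.csv --labels data/labels.csv --out metrics.json
```

`--preset paper-full` selects the full-scale profile (128³ grid, 6 blocks,
2000 epochs, 10 folds × 10 rotations); `desk-test` is the scaled profile
used throughout the tests.

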