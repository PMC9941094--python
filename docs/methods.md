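# Methods

## Problem and model

`abvisc` predicts the viscosity of a concentrated (150 mg/mL) antibody
solution from the 3D structure of the variable fragment (Fv) alone. The
premise is biophysical: high-concentration viscosity is driven largely by
intermolecular association mediated by surface electrostatics — in
particular clustered negative charge on the Fv surface — so a model that
sees only the electrostatic potential (ESP) on a thin shell around the
molecular surface should capture the relevant physics while being blind to
interior structural detail it could otherwise overfit.

The pipeline is:

1. **Structure preparation** (`structure_io`). A PDB file is read (waters
   and hetero groups dropped), partial charges and van der Waals radii are
   assigned from a bundled minimal table, and coordinates are translated so
   the center of mass is at the origin. The charge table localizes formal
   charges on the ionizable side-chain groups (Asp/Glu carboxylates −1, Lys
   amine +1, Arg guanidine +1, His and the termini neutral by default but
   configurable) and puts a small internally-neutral dipole on the backbone
   (N −0.47 / CA +0.47, C +0.51 / O −0.51). Every residue therefore sums
   exactly to its formal charge. This is deliberately not a force field: it
   preserves the sign structure and rough magnitude of the molecular ESP
   without any proprietary parameter source.
2. **Surface and shell** (`surface`). The solvent-excluded (Connolly-style)
   surface is computed morphologically on a cubic grid (default ±36 Å,
   0.75 Å spacing, 1.4 Å probe): voxels within `r_atom + r_probe` of an atom
   center form the probe-inflated volume, and voxels of it reachable by a
   probe sphere centered at any outside voxel are eroded away. Distances
   are exact Euclidean between voxel centers (`scipy.ndimage`
   distance transforms), so the result provably equals brute-force probe
   placement — the test suite checks voxel-exact agreement. The network
   input mask is the *shell*: exterior voxels within 2 Å of the exterior
   boundary layer of the surface.
3. **Electrostatics** (`fields`). The linearized Poisson–Boltzmann equation
   ∇·(ε∇φ) − ε κ² φ = −4π C ρ is discretized with a 7-point stencil,
   harmonic-mean face dielectrics (ε = 1 inside the molecular volume, 80
   outside), trilinear charge spreading, and Dirichlet boundary values from
   a Debye–Hückel sum; the sparse SPD system is solved by preconditioned
   conjugate gradients to a 1e-6 relative residual. Potentials are in kT/e
   at 298 K; ionic strength defaults to 0 (κ = 0). A direct screened-
   Coulomb summation (`solve_esp_debye`) serves as a fast reference and
   supplies the boundary condition. For a unit charge in uniform ε = 80 the
   FD solution is within 2% of the analytic Coulomb potential for
   r ∈ [3, 20] Å on a 65³ grid.
4. **Input grids**. The ESP is zeroed outside the shell mask and the
   physical block is centered in a zero-padded cube (97³ → 128³ at full
   scale) so that six max-pool halvings leave a 2³ spatial map. An
   alternative two-channel representation maps hydrophobic and hydrophilic
   atomic densities (Eisenberg-scale sign classification; unit-height
   Gaussians whose width is 3×|scale|, falling to e⁻¹ at that radius) onto
   the same shell; a three-channel variant concatenates ESP with both.
5. **Network** (`network`). Six blocks of [3×3×3 conv (same padding) → ReLU
   → 2× max-pool], filter counts 4, 8, …, 128, then flatten (1024 features
   at 128³), dropout 0.05, and a single linear output. Glorot
   initialization, Huber loss (δ = 1), Adam (default betas) at learning
   rate 1e-5, batch size 1, 2000 epochs; the checkpoint with the best
   validation loss within the last 50 epochs is kept (ties go to the later
   epoch). Training targets are log10(η/cP) by default (viscosity
   distributions are strongly right-skewed; raw-cP regression is available
   by configuration), and predictions are inverse-transformed to cP before
   averaging.
6. **Protocol**. Training uses rotation augmentation: each structure is
   randomly rotated (uniform quaternions) 10 times and all rotations stay
   on the same side of every split. An ensemble is 10 networks from a
   10-fold cross-validation split by structure. Inference featurizes 10
   fresh random rotations and averages the 10 × 10 = 100 model × pose
   predictions. The leave-one-out protocol holds out one structure of a
   21-member set while training on the remaining 20 plus all 38 of a second
   set (58 per fold).
7. **Attribution** (`attribution`). Integrated gradients along the straight
   line from an all-zero baseline, midpoint Riemann rule, 128 steps by
   default; scores are exactly zero at masked voxels and satisfy the
   completeness identity to <1% at 128 steps. Significance is one standard
   deviation of the pooled nonzero scores over a test set; significant
   voxels of each sign are grouped into patches with a 1.5 Å linkage rule
   (KD-tree + union of connected components, verified against a brute-force
   BFS). Patches are decomposed by the biophysical category of each voxel's
   nearest protein heavy atom with priority Asp/Glu side chain > acceptor
   oxygen > aromatic side chain (His/Phe/Tyr/Trp) > donor nitrogen and
   Lys/Arg group > lipophilic carbon, and by Fv segment (framework vs.
   Chothia CDRs L1–L3/H1–H3; bundled ranges L1 24–34, L2 50–56, L3 89–97,
   H1 26–32, H2 52–56, H3 95–102). The carboxylate analysis partitions
   Asp/Glu by the minimum carboxylate-to-cation-center distance (proximal
   ≤ 3.5 Å, distal ≥ 5 Å, the gap excluded) and averages the attribution of
   grid points whose nearest heavy atom is in the carboxyl motif and which
   lie within 4 Å of it.

## The network is implemented in numpy

No deep-learning framework is used. The convolution, pooling, dropout and
linear layers implement forward and analytic backward passes directly on
numpy arrays (im2col + GEMM for the convolutions), with Adam and Huber loss
written out. This keeps the package light, makes training bit-reproducible
under a fixed seed and thread count, and provides the exact input gradients
that integrated gradients needs. Parameter gradients agree with central
finite differences to ~1e-10 in the tests. The cost is speed at full scale:
the 128³ / 2000-epoch profile is far slower than a GPU framework, and the
package's quantitative studies therefore run at the desk profile below.

## Desk-scale profile and the synthetic recovery study

Real antibody structures and their viscosities are not distributed with the
package, so the statistical behavior of the pipeline is demonstrated on
synthetic structures whose ground truth is known and generated by
construction:

- **Toy structures** (`synthetic`): residues on a ~4 Å spherical scaffold,
  side chains pointing outward (geometry mildly compressed so the largest
  toys fit the ±12 Å desk grid), real residue and atom names throughout. A
  patch specification turns the residues nearest a chosen direction into
  Asp/Glu (negative patches) or Lys/Arg (cation patches).
- **Labels**: log10(η/cP) = 1.0 + 0.6·z + N(0, 0.15), where z is the
  standardized *negative patch area* — the number of shell voxels with
  ESP ≤ −1 kT/e, computed by the package's own SES/PB pipeline. The noise
  SD of 0.15 log-units (~1.4-fold) is on the order of inter-laboratory
  viscosity assay variability; the slope spreads 24 structures over roughly
  1–100 cP, straddling the 20 cP viscous/non-viscous threshold.
- **Ionic strength**: the desk featurization runs the PB solver at 0.15 M
  (Debye length ≈ 7.9 Å). On a 4 Å-radius toy inside a ±12 Å grid the
  unscreened (κ = 0) potential of any charge reaches every voxel — the
  monopole far field — so a nominal "patch" turns the entire shell
  negative and patch *area* degenerates. Physiological screening keeps the
  negative area a local surface feature, which is the geometry the study is
  meant to emulate. Full-scale runs keep the κ = 0 default.
- **Desk profile**: ±12 Å grid at 1.5 Å spacing (17³ physical, padded to
  32³), 5 conv blocks (32 is not divisible by 2⁶; filters 4…64, flatten
  64), 3 folds, 200 epochs, 2 training and 2 inference rotations, learning
  rate 1e-3. The higher rate compensates for having ~10× fewer batch-1
  steps than the full protocol; 1e-5 moves the weights too little in 200
  epochs to fit anything.

In the recovery study (`studies.run_recovery_study`, also exercised by the
test suite and `scripts/acceptance.py`), each of 24 structures is predicted
by the fold model that held it out; held-out Spearman correlations are
≈0.94–0.99 at the seeds reported by the tests and acceptance script. The
attribution analysis mirrors the replica protocol: integrated gradients are
computed per (model × rotated pose), the significance threshold is pooled
per model over all of its test-set replicas, positive patch totals are
found per replica and averaged. Averaging the maps *before* thresholding
sounds natural but attenuates the per-replica scores so strongly at this
grid size (~10³ shell voxels) that almost no voxel stays significant; the
per-replica convention is also what error bars over an ensemble of
predictions imply. Under it, the total positive-attribution patch area of
the top-quartile-viscosity structures exceeds the bottom quartile's and the
patch-size/viscosity rank correlation is positive — the signature expected
when the model has learned that negative surface patches drive the label.

What this does and does not show: the synthetic generator emulates the
*causal structure* the method assumes (a monotone map from negative surface
patch area to log-viscosity with realistic noise) but none of the
confounders of real data — conformational uncertainty of homology models,
correlated sequence families, hydrophobic/electrostatic interplay, or
assay-condition differences. Passing the recovery study shows the pipeline
can extract a surface-electrostatic signal end to end at low N; it does not
certify accuracy on real antibodies.

## Baselines

- **Sequence model** (`baselines.fit_sharma`): ordinary least squares of
  (transformed) viscosity on Fv net charge, the VL×VH charge product, and a
  hydrophobicity index. Per-chain charges are Henderson–Hasselbalch sums
  over D/E/H/K/R (and optionally the termini) with a bundled pKa table at
  the formulation pH (default 5.8). The hydrophobicity index is
  Σ(positive Eisenberg values) / |Σ(negative values)| over both chains
  (whole-chain by default; the original definition used CDRs, which is
  available by slicing the sequences before the call), and degenerates to 0
  when a sequence has no hydrophilic residues.
- **Clustered-negative-charge score** (`baselines.scm_score`): for every
  solvent-exposed heavy atom (≥10% of golden-spiral probe points outside
  the SES), the partial charges within 10 Å are summed; the score is the
  absolute value of the sum of the negative parts. It is non-parametric,
  increases when exposed acidic residues are added or clustered, and
  correlates positively with the synthetic labels by construction of the
  generator.

## Numerical choices and edge cases

- Voxel shell membership uses voxel-center distance to the exterior
  boundary layer; at zero thickness the shell is exactly that layer, and an
  empty interior yields an empty shell.
- Atoms whose inflated radius extends past the grid extent raise an error
  rather than being clipped, since silent truncation would corrupt the ESP.
- PB non-convergence within 10,000 CG iterations raises with the residual;
  ESP values are not clipped or normalized before the network (a symmetric
  clip is available but off by default).
- Patch sorting is by size descending with ties broken by (sign,
  lexicographically smallest voxel); max-pool ties take the first index, so
  everything is deterministic.
- The 1.5 Å linkage neighborhood at 0.75 Å spacing includes up-to-2-voxel
  axial offsets, so `scipy.ndimage.label`'s 3³ structuring elements cannot
  express it; connectivity is built from a KD-tree pair query instead.
- Bootstrap CIs are percentile intervals over 500 paired resamples;
  resamples with undefined metrics (single-class draws) are skipped and an
  error is raised if they exceed half.
- The ROC optimal operating point is the threshold closest to the (0, 1)
  corner, ties toward higher sensitivity; Youden's J is available by
  configuration and the choice is recorded in every report.

## Known limitations

- The charge model ignores polarization, His tautomers and pKa shifts;
  protonation is fixed by configuration, not predicted.
- The SES is voxelized; no analytic surface or SASA is produced.
- The PB solver is single-grid CG — adequate to 97³, but no multigrid, no
  nonlinear PB, no explicit ions.
- Training at the full 128³ / 2000-epoch profile on CPU is slow (hours per
  fold); the desk profile exists precisely so every code path can be
  exercised quickly.
- How attributions from the 10 × 10 model/rotation replicas are combined
  into one map per molecule is a convention (average on the common frame;
  per-model significance pooling), as is the all-zero IG baseline.
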