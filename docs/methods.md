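# Methods

## The problem and the metric

Crystallographic model validation needs a per-residue score that says how
well a set of coordinates explains the *correct* electron density, not how
well it explains the map that was phased with those same coordinates.
Conventional real-space correlation (RSCC) is computed against the model's
own map over the model's own atomic footprint, so misplaced atoms inflate
their B-factors, phase bias drags the map toward the model, and the score
stays high — worst at low resolution.

The box correlation coefficient (bCC) addresses both failure modes at
once. For a residue with heavy-atom centroid **c**:

1. The model's coordinates are converted to density with every atom's
   displacement parameter fixed at B_iso = 2.0 Å², so only the coordinates
   matter:

   ρ_atom(r) = Σ_j a_j (4π/(B_iso+b_j))^{3/2} exp(−4π² r² / (B_iso+b_j)),

   where (a_j, b_j) are Gaussian scattering-factor terms with the constant
   term folded in at width B_iso (so ρ integrates to Z electrons exactly).
2. Both the observed map and this calculated map are sampled on a cubic
   box of edge 12 Å and spacing 0.5 Å (24³ voxels) centered on **c**.
3. bCC = Pearson correlation of the two boxes over all voxels.

Because the box covers the residue *and* everything around it, bCC scores
local environment quality (contacts, neighboring residues, ligands), and
because it only ever references the high-resolution map of the correct
structure it is independent of the model's own map — the model-bias
independence that the acceptance suite demonstrates against RSCC on paired
resolution-truncated maps.

A 3D-CNN regressor per amino-acid type learns to predict bCC from five
voxel channels (observed map + per-element C/N/O/S calculated density), so
the score can be estimated when no high-resolution map exists.

## Density engine

* **Scattering factors.** The shipped table (`data/scattering_xray.json`)
  is the standard analytic X-ray fit (Cromer–Mann form: four Gaussians
  plus a constant, padded to a five-Gaussian schema), satisfying
  f(0) = Σa + c = Z to <0.1% for H/C/N/O/S. The table is a versioned data
  file and swappable; a unit test cross-checks values and densities
  against gemmi's independent implementation. Different published fits
  shift bCC values in roughly the third decimal.
* **Real space.** Maps are direct Gaussian sums with a per-atom dynamic
  cutoff at 1e-6 of the peak (below float32 map precision), periodic
  images included by index wrapping; triclinic cells are supported through
  the fractional metric.
* **Sampling adequacy.** A Gaussian of width B needs grid spacing h with
  exp(−B(1/h)²/4) small, or the lattice sum aliases (Poisson summation).
  At B = 2 the sharpest carbon term (B+b = 2.57 Ų) aliases by ~18% on a
  0.5 Å grid with the atom on a grid point, which is why calculated maps
  default to 0.25–0.3 Å grids while 0.5 Å suffices for observed-style
  B ≳ 15. Electron-count conservation within 1% is verified at both
  matched settings; a dedicated test documents the aliasing at B=2/0.5 Å.
* **Fourier space.** Structure factors are direct sums
  F(h) = Σ occ·f_el(s)·exp(−B s²)·exp(2πi h·x), s = 1/(2d) = sinθ/λ —
  the exact Fourier pair of the real-space formula (verified by a
  >0.999 direct-vs-FFT map correlation oracle and a Parseval identity to
  1e-6). Reflection sets store the Friedel-unique half; map synthesis is
  a zero-filled inverse FFT with a Nyquist guard, on grids with ≥3 samples
  per d_min.

## Boxes, rotations, metrics

Boxes are axis-aligned (no per-residue frame): orientation invariance is
supplied by training-time augmentation with the 24 proper cube rotations,
which act on voxel arrays as pure index permutations (no interpolation).
The centroid is the unweighted heavy-atom mean (mass weighting is a flag);
trilinear interpolation in fractional space is exact on affine fields and
exactly periodic. Zero-variance boxes raise a typed `DegenerateBoxError`
instead of returning 0, so empty solvent regions can never silently enter
labels. RSCC is implemented as a mask-radius (default 1.5 Å) Pearson
approximation of the conventional atomic-footprint statistic and is
labeled as an approximation in CLI output.

## Synthetic data: what it emulates, what it does not

The simulator exists so every pipeline stage can be exercised end-to-end
from a `(config, seed)` pair with no downloads:

* **Structures**: idealized α-helical polypeptides (NeRF construction from
  internal coordinates, 11 residue templates, seeded φ/ψ/χ jitter, clash
  checks) in orthorhombic P1 cells padded 6 Å per side. Multi-chain 2×2
  bundles reproduce protein-interior packing (~90–115 heavy atoms per
  12 Å box) for environment-sensitive checks such as the single-oxygen
  bound.
* **Observed maps**: per-atom B = 15 Ų base + up to 25 Ų ramp with
  distance from the molecular centroid (a solvent-exposure proxy), direct
  structure factors, truncation to the target d_min, complex Gaussian
  reflection noise (σ = 0.05 × RMS|F| by default), FFT synthesis. No
  refinement program is invoked; consequently simulated maps carry *no*
  model bias, and low-resolution error modes that arise from re-refinement
  against truncated data are not reproduced. Real-data workflows consume
  externally refined 2mFo-DFc maps instead.
* **Incorrect models**: parametric perturbations (coordinate jitter with
  calibrated RMSD, side-chain rotation, segment shifts, rigid motions)
  rather than homology models; magnitude directly controls the label
  distribution.
* **Labels**: with this observed-map model, correct structures score
  bCC ≈ 0.55–0.75 (matching the 0.59–0.79 range seen on real
  high-resolution structures) and 2 Å-jittered models ≈ 0.2, so corpora
  span roughly [0.15, 0.75] across ≥5 histogram bins of width 0.1. A
  sharp-map simulation would push correct labels toward 1 but would not
  resemble experimental maps.

Passing tests on this generator demonstrate that the metric, descriptor,
and training machinery behave correctly under controlled conditions; they
do not certify prediction accuracy on real crystallographic data, which
additionally involves model bias, solvent, anisotropy and refinement
artifacts that the simulator deliberately omits.

## Descriptors and learning

Each record holds five 24³ float32 channels — observed box plus C/N/O/S
calculated boxes (B = 2, hydrogen-stripped, per-element maps synthesized
once per structure) — with the bCC_act label computed against the
finest-resolution correct map. Channel linearity (element channels sum to
the combined calculated box) is tested to 1e-6. Archives are HDF5 with
lzf-compressed chunks and a hashed JSON manifest (counts, label histogram,
full provenance).

The regressor is a scikit-learn-style estimator around a numpy CNN:
four convolutions (3³, 3³, 3³, 1³), ReLU, max-pool after stages 1–2,
dropout 0.5 before the last convolution, global average pooling, linear
head; MSE loss under Adam; predictions clamped to [0, 1]. Earlier drafts
used squeeze/expand filter pairs per stage, but that doubles the
convolution count for no measurable gain at this scale, so one
convolution per stage was kept. The published-style default config
(lr 1e-5, 40 epochs, all 24 rotations per sample) suits large corpora;
the `desk_scale_config` preset — used by the acceptance experiment —
average-pools inputs to 12³, draws one random rotation per sample per
epoch, and raises the learning rate to 1e-3 so three per-amino-acid
models train in minutes on one CPU.

Normalization: the default z-scores each channel with training-set
statistics stored in the checkpoint. The desk-scale preset additionally
standardizes the observed channel within each record, because simulated
observed maps at different resolutions differ in absolute scale — a pure
nuisance for a scale-free target (bCC is invariant to affine rescaling of
either box). This raised held-out correlation substantially on mixed-
resolution corpora.

Validation splits are per-structure (all variants and resolutions of a
held-out structure stay together) to avoid leakage between near-identical
boxes. Models are trained only for amino-acid types present in the
corpus.

## Problem sizes used by the test and acceptance suites

Chosen as the smallest sizes at which each property is stably
demonstrated on a single CPU:

* Metric/geometry oracles: random 24³ boxes, exhaustive 24-rotation
  enumeration, 2-residue dipeptides.
* Monotone degradation: 20 structures × 8 residues × jitter
  {0, 0.5, 1.0, 2.0} Å against 1.8 Å simulated maps.
* Parameter recovery: 17 structures × 12 residues × 6 perturbation
  magnitudes × 2 resolutions (~2450 records over ALA/LEU/PHE; 3 held-out
  structures), balanced and subsampled to ~200/~800/~1700 training
  records. Held-out Pearson r reached ≈0.0 / 0.57 / 0.88 respectively —
  monotone in corpus size, with per-type r ≈ 0.89–0.92 at full size.
* Single-oxygen bound: four-helix bundle, ~190 atoms, one water oxygen;
  contribution 0.5–0.85% across seeds.

## Known limitations

* No space-group symmetry anywhere in the math: non-P1 inputs must arrive
  as maps already expanded to the unit cell.
* No bulk solvent, no anisotropic B, no sigma-A weighting; simulated maps
  are noise-added truncations, not refined 2mFo-DFc syntheses.
* The RSCC implementation is a documented mask-Pearson approximation, not
  a re-implementation of EDSTATS weighting.
* The numpy CNN targets desk-scale corpora (10³–10⁴ boxes); it is not a
  GPU training stack and does not attempt the full-corpus accuracy of a
  production run.
* Idealized helical geometry only; no rotamer library, no β-sheets. The
  learned models transfer to nothing outside the simulator and exist to
  validate the training machinery.
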