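# boxcc

Local quality assessment of protein crystal structures from electron
density maps, built around the **box correlation coefficient (bCC)**.

## Who this is for

Structural biologists and methods developers who need a per-residue score
of how well coordinates explain the *correct* (high-resolution) electron
density — including at low resolution, where conventional real-space
correlation (RSCC) is inflated by refined B-factors and model bias — and
who want to train resolution-independent predictors of that score.

## The metric

For a residue with heavy-atom centroid **c**, the model's coordinates are
converted to density with a fixed B_iso = 2.0 Å²,

ρ_atom(r) = Σ_{i} a_i (4π/(B_iso+b_i))^{3/2} exp(−4π² r²/(B_iso+b_i)),

with (a_i, b_i) standard Gaussian scattering-factor coefficients; the
observed map ρ_obs and the calculated map ρ_calc are both cut into a
12 Å cube of 0.5 Å voxels centered on **c**, and

bCC = cov(ρ_obs, ρ_calc) / sqrt(var(ρ_obs) · var(ρ_calc))

over the 24³ voxels. The box includes the residue's surroundings, so bCC
scores the local environment; it references only the correct map, so it
is free of model bias. A five-channel voxel descriptor (observed map +
C/N/O/S calculated density) feeds per-amino-acid 3D-CNN regressors that
predict bCC when no high-resolution map is available.

The toolkit contains the full pipeline: PDB/mmCIF and CCP4/MRC I/O
(via gemmi), real- and Fourier-space density synthesis, resolution
truncation and reflection noise, box extraction with the 24-rotation
augmentation group, bCC / RSCC / ligand Δ-bCC metrics, descriptor and
dataset-archive construction, a numpy 3D-CNN training backend, and a
fully seeded synthetic crystal simulator that generates ground-truth
structures, observed maps and labeled training corpora from scratch.

## Worked example

Score a model against a map (here generated by the built-in simulator,
so the example is fully self-contained):

```python
import boxcc

truth = boxcc.generate_structure(10, seed=2)             # P1 helix, 10 residues
obs = boxcc.simulate_observed_map(truth, d_min=1.5, seed=11)

model = boxcc.perturb_structure(                          # a damaged model
    truth, boxcc.PerturbationSpec("jitter", 1.0, seed=4))

print(boxcc.per_residue_bcc(truth, obs).bcc.round(3).tolist())
print(boxcc.per_residue_bcc(model, obs).bcc.round(3).tolist())
```

prints

```
[0.638, 0.591, 0.63, 0.656, 0.642, 0.63, 0.63, 0.601, 0.568, 0.612]
[0.428, 0.39, 0.392, 0.4, 0.396, 0.395, 0.395, 0.404, 0.36, 0.426]
```

The correct coordinates score ≈0.6 against a realistic 1.5 Å map (the
observed map is blurred by refined-style B-factors while the calculated
density uses B = 2, so 1.0 is not approachable — the same range seen on
real high-resolution structures), and a 1 Å coordinate jitter drops every
residue's score. Residue-level tables, bCC-colored PDB exports and JSON
summaries are also available from the command line:

```bash
boxcc score model.pdb observed.ccp4 --out-prefix run1      # TSV + PDB + JSON
boxcc simulate corpus.yaml corpus.h5                       # labeled training data
boxcc train corpus.h5 LEU leu_model.npz                    # one model per residue type
boxcc predict leu_model.npz model.pdb observed.ccp4        # bCC without a correct map
boxcc ligand bound.pdb unbound.pdb observed.ccp4           # Δ-bCC at a binding site
```

Every run writes a `*.run.json` with its resolved options and seeds, so
any output can be regenerated exactly.

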