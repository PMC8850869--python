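# bigflica

Scalable multimodal linked independent component analysis for population
brain imaging.

Population imaging studies acquire many MRI modalities — task contrasts,
resting-state maps, diffusion and structural measures — for tens of
thousands of subjects.  Linked ICA fuses them into a single set of modes of
population variability: a joint decomposition

    Y⁽ᵏ⁾ = H W⁽ᵏ⁾ X⁽ᵏ⁾ + E⁽ᵏ⁾,   k = 1…K

of the K subjects × voxels matrices, where the subject mode **H** is shared
across modalities (the "link"), **W⁽ᵏ⁾** is a positive diagonal matrix of
per-mode modality weights, **X⁽ᵏ⁾** are modality-specific spatial maps, and
**E⁽ᵏ⁾** is modality-specific Gaussian noise.  The columns of H are
data-driven imaging phenotypes usable to predict behavioural and health
variables; W exposes how modalities contribute to, and relate through, each
mode.

Fitting this model directly at biobank scale is infeasible, so `bigflica`
wraps the variational-Bayes linked ICA core with two compression stages:

* **mMIGP** — a streaming multimodal incremental PCA that reduces the
  subject dimension N to L\* (exact truncated SVD whenever the sketch rank
  covers the data rank);
* **DicL** — sparse dictionary learning in the transposed convention
  (voxels coded sparsely over a norm-constrained subject-space basis) that
  reduces the feature dimension P to L\*\*; the linked ICA consumes the
  feature loadings, and voxel maps are reconstructed afterwards by
  voxel-wise regression on the subject mode.

The package also ships the evaluation harness used to validate such
decompositions: a multimodal ground-truth simulator, greedy component
matching, a nested cross-validated elastic-net phenotype-prediction
protocol, a generalized-least-squares paired test for comparing correlated
per-phenotype accuracies, split-half reproducibility of spatial maps, and
modality-contribution analysis.  See `docs/methods.md` for the model,
priors and all numerical conventions.

## Worked example

Simulate a two-modality dataset with known ground truth, reduce it, fit
the linked ICA, and score recovery:

```python
import numpy as np
import bigflica as bf

cfg = bf.SimulationConfig(n_subjects=200, grid=(12, 12, 12), n_shared=10,
                          n_unique_per_modality=2, snr=4.0, seed=1)
dataset, truth = bf.simulate_dataset(cfg)
print("modality shapes:", [m.matrix.shape for m in dataset])

red = bf.mmigp(dataset, L_star=60)
print("explained variance at L*=60: %.3f" % bf.explained_variance(red, dataset))

model = bf.flica_fit(red.V_per_modality, L=10, n_iter=500, tol=1e-6, seed=0)
H = bf.backproject_subject_mode(red.U, model.H_star)
match = bf.greedy_match(H, truth.H)
print("mean matched |r| vs ground truth: %.3f" % match.mean_correlation)
print("free energy: start %.4g, end %.4g, iterations %d"
      % (model.free_energy_trace[0], model.free_energy_trace[-1], model.n_iter_run))
Wmat = bf.modality_weight_matrix(model)
print("modality cosine similarity:\n", np.round(bf.modality_similarity(Wmat), 3))
```

Output:

```
modality shapes: [(200, 1728), (200, 1728)]
explained variance at L*=60: 0.774
mean matched |r| vs ground truth: 0.925
free energy: start -3.561e+05, end -3.393e+05, iterations 97
modality cosine similarity:
 [[1.    0.841]
 [0.841 1.   ]]
```

The two 200 × 1728 matrices are reduced to a shared 60-dimensional subject
basis capturing 77% of the data variance; the ten fitted modes match the
ground-truth subject loadings at mean |r| = 0.93; the free energy rose
monotonically to convergence in 97 iterations; and the two modalities'
weight profiles are strongly related (cosine 0.84), as expected when most
components are shared.

A command-line interface mirrors the stages (`bigflica simulate`,
`reduce-migp`, `reduce-dicl`, `fit`, `maps`, `predict`, `compare`,
`reproducibility`, `stability`); run `bigflica --help`.

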