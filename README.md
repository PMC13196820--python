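# pdmdiff

Correspondence-preserving denoising diffusion for **point distribution
models** (PDMs): ordered point-set shape representations in which point
index *i* marks the same anatomical locus in every subject.

## Why

Shape analysis of brain structures — e.g. localizing hippocampal atrophy in
Alzheimer's disease — relies on *point correspondence*: per-index group
statistics only make sense when index *i* means the same place in every
shape. Classical statistical shape models respect correspondence; modern
point-cloud generative models do not (they sample unordered clouds).
`pdmdiff` implements a denoising diffusion probabilistic model (DDPM) whose
generated shapes keep their indices at the right anatomical loci, plus the
surrounding toolkit:

* a PointNet-style **U-Net of row-wise feature transformation blocks**
  (shared per-point linear weights + timestep/label scale-shift), with
  learned **correspondence embeddings** (a trainable N×z matrix added to
  per-point activations — the component that deliberately breaks
  permutation equivariance) and **masked self-attention** over the
  k-nearest-neighbor graph of the training mean shape;
* the DDPM forward/reverse machinery: q(X(t)|X(t−1)) = N(√(1−β_t) X(t−1),
  β_t I), ε-prediction training loss ‖ε − ε_θ(X(t), t)‖², ancestral
  sampling with reverse variance β_t I;
* a **PCA baseline** (flatten, truncated SVD basis, Gaussian scores,
  invert);
* **evaluation metrics**: MMD, k-NN-ball coverage and density (k = 7)
  under Chamfer distance, exact Earth Mover's Distance (Hungarian
  assignment), and correspondence-aware per-index L2;
* **downstream analyses**: class-conditional generation, per-index group
  mean-difference (atrophy) maps, a shape classifier, classifier-guided
  counterfactual generation, correspondence color maps and a quantitative
  correspondence score;
* a **synthetic population generator** (ellipsoids with a Fibonacci-lattice
  parameterization, per-subject log-normal semi-axes, a localized
  class-dependent radial "atrophy" patch, per-point noise) providing exact
  ground truth for every test;
* file I/O for ShapeWorks-style `.particles` files, CSV manifests and HDF5
  containers, and a `pdmdiff` CLI.

Everything runs on numpy/scipy on a single CPU; the network trains on a
small reverse-mode autodiff engine included in the package.

## Worked example

Generate a synthetic population, train the diffusion model, sample, and
evaluate (about five minutes on one CPU):

```bash
pdmdiff synth --n-points 64 --n-per-class "healthy=400" --seed 7 --out data
pdmdiff train --data data/dataset.h5 --out model.h5 \
    --steps 100 --beta-start 0.001 --beta-end 0.2 \
    --n-steps 2000 --batch-size 32 --widths 32,64 --seed 0
pdmdiff sample --model model.h5 --n-samples 200 --seed 1 --out samples
pdmdiff evaluate --real data/dataset.h5 --gen samples/samples.h5 \
    --k 7 --distances emd,l2
```

which prints (abridged):

```
final loss 0.0127; checkpoint at model.h5
{
  "EMD": { "mmd": 0.0669, "coverage": 0.0075, "density": 0.0021, ... },
  "L2":  { "mmd": 0.0727, "coverage": 0.0025, "density": 0.0007, ... }
}
```

and in Python:

```python
>>> from pdmdiff.shape_io import load_dataset_h5
>>> from pdmdiff.downstream import correspondence_score
>>> real = load_dataset_h5("data/dataset.h5")
>>> gen = load_dataset_h5("samples/samples.h5")
>>> round(correspondence_score(real, gen), 4)
0.9998
```

How to read this: the correspondence-aware L2 MMD (0.073) is nearly equal
to the permutation-invariant EMD MMD (0.067) — generated indices sit at the
right loci, which the per-index correspondence score (0.9998, where 1.0 is
perfect) confirms. An unordered generator of equally good geometry would
show L2 MMD an order of magnitude above EMD MMD (shuffle the sample indices
and re-evaluate to see this). Coverage/density at k = 7 are low at this
desk scale because the 2000-step model's samples carry slightly more
residual noise than the very tight synthetic population; between two real
halves of the same population they calibrate to ≈ 1 (see below).

`--conditional` training, `sample --label AD`, `train-classifier`,
`counterfactual` and `baseline-pca` cover the remaining workflows; every
command writes a YAML config snapshot next to its outputs for exact replay.

## Layout

```
src/pdmdiff/
  shape_io.py    .particles / manifest / HDF5 I/O, flipping, normalization
  synthetic.py   ground-truthed synthetic shape populations
  autodiff.py    minimal reverse-mode autodiff over numpy
  network.py     RFT U-Net backbone, correspondence embeddings, masked attention
  diffusion.py   schedules, forward/reverse processes, training, sampling
  pca.py         PCA generative baseline
  metrics.py     CD / EMD / L2, MMD, coverage, density
  downstream.py  group difference maps, classifier, counterfactuals, color maps
  cli.py         pdmdiff command-line interface
docs/methods.md  model, assumptions, parameter choices, limitations
```
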