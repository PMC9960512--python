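# measd — unsupervised hyperspectral band selection

Hyperspectral cubes carry hundreds of strongly correlated spectral bands;
most downstream classifiers and regressors work as well — often better —
on a dozen well-chosen bands.  `measd` selects such band subsets without
labels, exploiting the *ordered* structure of the spectral axis: adjacent
bands are nearly redundant, so rather than clustering bands freely it
partitions the band axis into `K` contiguous subspaces and picks one
representative band per subspace, which makes it structurally impossible
to select two neighboring bands.

## Method

For a cube with `N` pixels and `L` bands, band `i` is the pixel vector
`x_i ∈ R^N`.  A locally scaled Gaussian affinity compares bands:

    ω_ij = exp( −‖x_i − x_j‖² / (σ_i σ_j) ),   σ_i = ‖x_i − x_d(i)‖²

where `x_d(i)` is the `d`-th adjacent band of `i` (default `d = 7`,
nearest-by-distance convention).  A partition of `[0, L)` into contiguous
subspaces `X_1 … X_K` is scored by a normalized-association criterion
restricted to *adjacent* subspaces,

    Fitness = Σ_k  ( Σ_{i,j∈X_k} ω_ij ) / ( Σ_{i∈X_k, j∈X_k∪X_adj(k)} ω_ij ),

so each term ∈ (0, 1] rewards subspaces that are internally coherent and
decoupled from their immediate spectral neighbors — exactly where a
redundant pick would come from.

The partition is encoded by its `K−1` boundary bands and optimized by a
multimodal differential evolution (FERDE): parents are drawn by roulette
over the fitness–Euclidean-distance ratio
`FER(j,i) = (f(p_j) − f(p_w)) / ‖p_j − p_i‖`, favoring near-and-better
neighbors, and an offspring replaces the *nearest* existing individual
only if strictly better.  Both mechanisms preserve niches, so a single run
returns several distinct near-optimal partitions, not one.  From the top
`k` distinct partitions, each subspace contributes its maximum-entropy
band (Shannon entropy of the 256-level gray histogram,
`H_i = −Σ_z p(z) log p(z)`); the `k` band subsets train `k` predictors
whose outputs are combined by majority vote (classification) or mean
(regression).

## Worked example

Generate a labeled synthetic cube with five planted band groups (30
bands, 200 pixels), select five bands, and evaluate:

```bash
$ measd synth --seed 0 --labels classification --n-classes 2 --quiet
wrote cube.npz (N=200, L=30); structure check: ok

# split the npz into cube/labels files, then:
$ measd select cube_only.npz --n-bands 5 --seed 0 --quiet
fitness=3.264250  bands(1-based)=[6, 8, 14, 22, 30]
fitness=3.244724  bands(1-based)=[6, 8, 14, 22, 30]
fitness=3.168641  bands(1-based)=[6, 11, 14, 22, 30]

$ measd evaluate cube_only.npz --subsets subsets.csv --labels labels.npz \
      --task classification --seed 0 --quiet
OA=0.9700  AA=0.9762
```

The three lines from `select` are the top-3 distinct partitions by
fitness; each prints one selected band per subspace (1-based; the CSV
carries both conventions).  The planted groups are bands 1–6, 7–12,
13–18, 19–24, 25–30, and every subset contains exactly one band from each
group.  `evaluate` trains a nearest-centroid classifier per subset on half
the pixels and reports overall accuracy (OA, fraction correct) and
average per-class accuracy (AA) of the integrated prediction on the rest.

Cubes can also be read from ENVI (`.hdr` + raw, BSQ/BIL/BIP), MATLAB
`.mat`, NPZ, or CSV files; see `measd select --help`.

## Library use

```python
from measd import RunConfig, run, select_band_subsets
from measd.synthetic import SyntheticSpec, generate_block_cube

cube, truth = generate_block_cube(SyntheticSpec(seed=0))
pop = run(cube, n_bands=5, config=RunConfig(seed=0))
for s in select_band_subsets(pop, cube, k=3):
    print(s.bands, s.fitness)
```

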