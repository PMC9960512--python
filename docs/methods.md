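# Methods

## Problem setting

Given a hyperspectral cube flattened to an `N × L` pixel-by-band matrix,
the task is unsupervised selection of `K` bands that preserve the cube's
information.  The band axis is ordered and locally redundant, so the
search space is restricted to partitions of `[0, L)` into `K` contiguous
subspaces; a subset takes one band per subspace.  Two consequences drive
the design: selected bands can never be spectrally adjacent when
subspaces have length ≥ 2, and the optimization variable is the compact
vector of `K − 1` subspace boundaries rather than a `K`-of-`L` subset.

## Band affinity

`ω_ij = exp(−‖x_i − x_j‖² / (σ_i σ_j))` with a per-band local scale
`σ_i = ‖x_i − x_d(i)‖²`, the **squared** distance to the `d`-th adjacent
band.  Two conventions for "`d`-th adjacent" are implemented:

* `knn` (default): the `d`-th nearest band by Euclidean distance, the
  self-tuning spectral-clustering convention from which the default
  `d = 7` comes;
* `index`: the band at spectral offset `i + d` (falling back to `i − d`
  near the top of the range), for sensitivity checks.

The squared-norm scale is kept as the primary definition; classic local
scaling divides by the product of *unsquared* distances, and that variant
is available via `squared_sigma=False`.  The squared convention is not
scale-invariant: distances enter as raw sums over pixels, so multiplying
the cube by `c` multiplies exponents by `1/c²`, and for between-group
distances ≫ 1 all exponents collapse toward 0 and ω → 1 everywhere.  The
kernel resolves block structure when typical between-group squared
distances are of order one — for a few hundred pixels that means
reflectance-scale amplitudes (see the generator below).  `sigma_floor`
(default 1e−12) bounds σ away from zero when a band has an exact
duplicate among its `d` nearest neighbors; if *every* scale is floored
(a constant cube) a warning is emitted and the degenerate all-ones matrix
returned.  One global `L × L` matrix is computed per run (cost `O(N L²)`)
and shared by all fitness evaluations; `subsample_pixels` bounds `N` for
large scenes.

## Partition fitness

Each subspace `X_k` is scored by a normalized-association ratio whose
normalizing universe is local:

    term_k = within_k / (within_k + cross_k),
    within_k = Σ_{i,j∈X_k} ω_ij   (diagonal included),
    cross_k  = Σ_{i∈X_k, j∈X_adj(k)} ω_ij,

with `X_adj(k)` the union of the immediately preceding and following
subspaces (end subspaces have a single neighbor).  Each term lies in
(0, 1], the sum is bounded by `K`, and on a block-diagonal affinity the
score is maximized exactly at the true block edges (verified by
exhaustive enumeration in the tests).  A strictly-adjacent denominator
(`cross_k` alone) is available via `adjacent_only=True`; that form is
unbounded and is provably maximized by degenerate partitions — a large
subspace flanked by a single-band neighbor drives its denominator toward
zero — so it is provided for comparison, not as the default.  A
`include_diagonal=False` flag removes the `i = j` terms from `within_k`.
Evaluations use a 2-D prefix sum of ω, so each costs `O(K)` block-sum
lookups after `O(L²)` setup; a denominator floor of 1e−300 guards the
strictly-adjacent variant against floating-point underflow of ω.

## Boundary encoding and repair

Chromosomes are continuous vectors of `D = K − 1` genes.  Decoding
rounds to the nearest integer, clips to `[1, L − 1]`, sorts, and repairs
duplicates deterministically (the later duplicate moves to the smallest
free slot above, wrapping to the largest free slot below when the top is
occupied).  Decoding is a pure function: idempotent on feasible integer
genes and invariant to gene order.  Evolution operates on the continuous
genes; repair happens only inside evaluation and when measuring
phenotype distances, so the real-valued difference-vector arithmetic of
the optimizer is undisturbed.

## Multimodal search (FERDE)

Maximization, population `M` (default 50), at most `T_max = 300`
generations, early stop when the best fitness has not improved by more
than `improvement_tol = 1e−12` for 10 consecutive generations.  Per
individual `i`, per generation:

1. **Selection.** `FER(j, i) = (f(p_j) − f(p_w)) / ‖p_j − p_i‖` over
   personal bests, `p_w` the worst personal best (numerator ≥ 0 under
   maximization).  Three distinct parents are drawn by roulette with
   weights `max(FER, 0) + 1e−12`; pairs at zero gene distance carry no
   niche information and are excluded, entering uniformly only if fewer
   than three weighted candidates remain.  The epsilon keeps the roulette
   defined on flat landscapes, where selection degrades to uniform.
2. **Mutation.** `v = x_r1 + u ⊙ (x_r2 − x_r3)`, `u_d ~ U(0,1)` drawn
   independently per dimension.
3. **Crossover.** Binomial against `x_r1` with rate `CR`; one uniformly
   chosen dimension is forced mutant.  `CR` is drawn once per offspring
   from U(0, 1) by default (`CR_mode="fixed"` supplies a constant).
4. **Replacement.** The offspring replaces the member whose *decoded
   boundary vector* is nearest in Euclidean distance (ties to the lowest
   index), and only if strictly fitter; its personal best is re-seeded
   from the offspring.  Strict improvement means equal-fitness clones
   never displace existing diversity, and since any member is only ever
   replaced by something fitter, the population maximum is
   non-decreasing.

Phenotype distance (decoded boundaries, not raw genes) makes gene vectors
that round to the same partition compete for one slot instead of
crowding a niche.  FER and the roulette are recomputed per offspring, the
tightest reading of the per-individual loop.  All randomness flows from
one seeded generator, so runs are bit-reproducible.

## Representative bands and the ensemble

Per-band Shannon entropy is computed on a min-max quantized gray
histogram: each band is scaled to `[0, bins−1]` (default 256 levels, the
8-bit gray convention) and floored; `H_i = −Σ p log p` in nats (a base-2
flag exists).  Entropy is invariant to affine band rescaling; a constant
band scores 0.  From the final population, members are sorted by fitness
and deduplicated by decoded phenotype; the top `k` distinct partitions
(default 3) each yield the subset of per-subspace entropy argmaxes (ties
to the lowest band index).  `k` predictors are trained, one per subset,
on features restricted to that subset's bands (any object with
`fit`/`predict`; sklearn estimators are cloned per subset).  Integration
is per-sample majority vote for classification — ties resolved by the
highest-fitness subset's prediction — and the unweighted mean for
regression, with a fitness-weighted mean behind a flag.

## Synthetic generator

`generate_block_cube` plants the structure the method assumes: the band
axis is split into contiguous groups; group `g` gets a base pixel profile
`between_sep · z_g`, `z_g ~ N(0, I_N)`, and each band in `g` adds
independent `N(0, within_noise²)` noise per pixel.  Defaults: `L = 30`
bands in 5 equal groups, `N = 200` pixels, `between_sep = 0.05`,
`within_noise = 0.005` (10:1 separation-to-noise).  The amplitude 0.05
is deliberate: it is the size of regime-crossing reflectance steps in
real spectra, and it keeps between-group squared band distances of order
one at `N = 200`, the informative regime of the squared-scale kernel
described above.  `generate_mirrored_cube` appends a band-reversed copy
of a half-cube, producing a landscape exactly symmetric under band
reversal in which every partition has an identically scoring mirror —
the ground truth for testing that the search retains multiple tied
optima.

Labels are a deterministic function of the informative bands (the middle
band of each group).  Classification labels are a converged
nearest-centroid rule: an initial assignment from random class-specific
linear readouts of the standardized informative bands is refined by
Lloyd iterations until stable, so classes are exactly centroid-separable
in the informative bands (an emptied class keeps its previous centroid);
an optional `label_noise` fraction is then flipped.  Regression targets
are a linear combination of the informative bands plus Gaussian noise.

What the generator does **not** emulate: smooth spectral continua within
groups (bands in a group are exchangeable here), spatial pixel
correlation, sensor striping, or mixed pixels.  Tests passing on these
cubes show the pipeline recovers planted contiguous correlation
structure; they do not certify accuracy figures on real scenes.

## Problem sizes and numerical choices

Search-behavior checks run scaled-down study conditions chosen so
exhaustive enumeration stays an available oracle: `L = 10, K = 3` (36
candidate partitions) and `L = 30, K = 5` with population 20 and at most
100 generations, 20 search seeds per rate; end-to-end accuracy runs the
full reference protocol (population 50, up to 300 generations).  On
these instances the whole suite and the acceptance script each finish in
well under a minute.  Recovery of all five planted boundaries within ±1
band holds in roughly 75–85% of seeds under the scaled-down budget — the
residual failures are early convergence to a neighboring local optimum
under the 10-generation patience rule, and disappear under the reference
protocol.

Other fixed choices: band indices are 0-based internally and every
human-facing output prints both 0- and 1-based forms; 3-D rasters are
flattened row-major and label rasters identically; NaN inputs are
rejected by default with an optional per-band mean imputation;
tie-breaks (duplicate repair, nearest-member replacement, entropy
argmax, vote ties) are all deterministic so that equal seeds give
byte-identical outputs.

## Known limitations

* `K` is user-supplied; the criterion value is not comparable across
  different `K`, so the package does not auto-select the subset size.
* The affinity computation is dense `O(N L²)`; very large scenes should
  use `subsample_pixels`.
* The squared local scale ties kernel behavior to the data's amplitude
  scale (see above); for data far from reflectance scale, min-max band
  scaling (`scale_bands=True`) or the unsquared variant is advisable.
* Niching preserves tied optima reliably, but distinct subsets are only
  as diverse as the fitness landscape allows; on single-optimum
  landscapes the top-`k` request may return fewer subsets (with a
  warning).
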