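# Methods

## Intrinsic neural timescales

Per voxel and run, the sample ACF uses the biased estimator
`ACF(k) = sum_{t<=N-k} d_t d_{t+k} / sum_t d_t^2`, `d = y - mean(y)`: one mean
subtraction per series, denominator of length N. This keeps `|ACF| <= 1` and
the curve positive semidefinite, and matches the common `adjusted=False`
convention of time-series toolboxes.

The INT is the sum of ACF values over the initial positive period. Decisions
inside that definition:

- **Lag 0 is excluded** (it is identically 1 and carries no information); an
  `include_lag0` flag exists for sensitivity analyses since both readings
  occur in the literature.
- **Crossing condition is `ACF(k) <= 0`** — an exact zero ends the "positive
  period".
- **`max_lag` defaults to `min(N-1, 100)`**: at N = 700 the ACF beyond ~100
  lags is estimation noise.
- **Censoring**: a voxel whose ACF never crosses zero within `max_lag` keeps
  the truncated sum and is flagged. Censored runs are dropped from that
  voxel's cross-run mean; a voxel censored in every run stays flagged.
  Region means include censored voxels by default (a `strict` mode excludes
  them); the count is always reported. Constant (zero-variance) series are an
  error at the single-series level and a flagged NaN voxel at the map level —
  never a silent 0.
- The first zero-crossing lag times the TR (default 1.1 s) is reported as a
  time constant in seconds; it is exactly an integer multiple of the TR for a
  single run and a mean of such multiples after run averaging.
- Aggregation is mean-of-means at every level (runs -> subject -> group);
  maps are never smoothed.
- Hierarchies sort regions ascending by mean INT with ties broken by region
  id, so the ordering is deterministic.

## FC gradients

Pearson FC matrices are combined across runs and subjects by Fisher-z
averaging with entries clipped at `|r| = 1 - 1e-7` (keeps the unit diagonal
finite; the inverse transform returns clipped values at `>= 1 - 2e-7`). The
combination rule (average FC first, then one embedding) was chosen over
averaging per-run gradients: it is the cheaper and more common convention and
avoids aligning sign-arbitrary components across runs.

"10% sparsity" is implemented as **retaining the top 10% of entries per row
by signed value** and zeroing the rest (ties at the cutoff keep the lower
column index). Signed rather than absolute ranking means the survivors are
the strongest positive correlations, which is what a nonnegative diffusion
kernel needs; the retained density is configurable.

The affinity is the cosine similarity between sparsified connectivity
profiles (rows), with the rare negative similarities clipped to 0 and the
diagonal fixed at 1. All-zero profiles are a hard error naming the voxels.

Diffusion embedding: with affinity `W` and degrees `d`, the kernel is
renormalised to `W_ij / (d_i d_j)^alpha` with `alpha = 0.5` (discounts
density effects), row-normalised into a Markov operator, and
eigendecomposed through its symmetric conjugate (`eigh`, numerically stable
and deterministic up to sign). The stationary component is discarded;
component j is scaled by `lambda_j / (1 - lambda_j)` at diffusion time 0
(multiscale convention) or `lambda_j^t` otherwise. Components have unit norm
under the chain's stationary distribution — the weight under which they are
orthogonal — which is what makes the independent dense-eigensolver oracle in
the tests comparable to 1e-8 up to per-component sign. A disconnected
affinity graph raises with the component sizes; gradients are estimated
bilaterally by default simply because the voxel set is whatever mask is
supplied.

## Topography

Gradient signs are arbitrary, so `map_correlation` reports `(r, |r|, n)` and
`best_gradient` maximises `|r|` (ties to the lower component index,
1-based: G1, G2, ...). Projections use **signed** correlation — "most
correlated" is read as the largest positive r — with `argmax` per target
voxel for gradient projection and the mean over the top-k (default 10)
source voxels for INT reconstruction; ties keep the lowest source index.
Post-projection smoothing is off by default so core outputs stay exact.

## Reliability

Fisher z uses the same `1e-7` clip. Hierarchy stability enumerates subject
subsets lexicographically (deterministic logs), averages each subset's
region means, and computes Spearman's rho (average ranks on ties) against
the **full-group** ordering, including the held-in subjects — the cheaper of
the two readings and the one consistent with "the group-level ordering".
With 9 subjects and subsets of 4 this is exactly C(9,4) = 126 comparisons.

## Synthetic data: what it emulates and what it does not

The generator is a stand-in — the analyses were designed for real BOLD data,
which has no known generative model — so it plants exactly the two structures
the pipeline is supposed to recover:

1. **Timescales.** Each region has an AR(1) coefficient phi in [0,1); the
   voxel's innovation sequence is passed through the AR(1) filter, so the
   population ACF is exactly `phi^k` and the population INT proxy
   `phi/(1-phi)` is strictly increasing in phi. AR(1) was chosen over
   continuous OU integration because the data are discrete-time and the
   closed-form ACF anchors the unit tests.
2. **Topography.** Before filtering, innovations mix shared latent white
   noise with Gaussian-bump weights centred at equally spaced positions
   along a planted axis in [0,1], so FC profiles change smoothly along the
   axis. Because mixing happens in the innovations and the AR filter comes
   after, the planted connectivity does not distort the planted ACF.

Stated-world defaults: 9 subjects, 5 runs, 700 timepoints at TR 1.1 s; six
regions with phi ascending 0.1–0.85 tiling the axis in order, so timescales
increase monotonically along the connectivity axis. Free parameters chosen
once on first-principles grounds: 20 voxels/region (desk scale), 10 latent
signals with bandwidth 0.15 (about one region's width — smooth but
resolvable), shared innovation fraction 0.6 (FC in strongly coupled cortical
neighbourhoods is large but below 1), observation noise SD 0.5 relative to
unit innovation variance. An optional double-gamma HRF convolution (default
off, to keep the AR(1) closed form exact in unit tests) lengthens apparent
timescales when enabled.

Randomness is counter-based: `default_rng([seed, subject, run])`, so
datasets are bit-identical under regeneration and independent of generation
order.

Not emulated: vascular/physiological noise spectra, scanner drift and
artifacts, spatial autocorrelation of noise, hemispheric structure, surface
geometry. A green recovery test therefore establishes that the estimators
invert this generative model at realistic SNR — not that they are unbiased
on real BOLD data.

## Numerical choices

- ACF via real FFT with zero padding; identical to the direct sum to 1e-10.
- Fisher clip 1e-7; Fisher round trip exact to 1e-9 inside the clipped
  domain.
- `eigh` on the symmetric conjugate rather than `eig` on the Markov
  operator; eigenvalue order enforced descending.
- Voxel flattening order is x-fastest (Fortran ravel) everywhere, recorded
  in each output's JSON provenance sidecar along with a config hash.

## Known limitations

- The INT statistic is TR-dependent (it sums discrete lags); comparisons
  across acquisitions with different TRs should use the time-constant map.
- Diffusion gradients assume the sparsified affinity graph is connected; the
  pipeline fails loudly rather than embedding components separately.
- `project_int` needs at least k finite correlations per target voxel;
  voxels with fewer are returned as NaN.
- Group gradients are computed from the Fisher-mean FC; per-run gradient
  averaging (with alignment) is out of scope.
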