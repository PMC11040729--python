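# Methods

## Model and procedure

`acsftune` treats descriptor design as a density-estimation problem.
A trajectory samples the vibrational/conformational landscape of a
molecule; the element-typed pairwise distances `{r_ij}` and angular
triples `{r_ij, r_ik, θ_ijk}` pooled over its frames are the empirical
distributions a good descriptor must resolve. Each distribution is
fitted with a Gaussian mixture, and every mixture component is mapped
onto one (or, under the resampling schemes, several) symmetry
function(s), so descriptor resolution is spent exactly where the
system's geometry actually lives.

Assumptions worth stating explicitly:

- **Single topology.** All frames share one ordered element list; no
  bond breaking. Periodic systems are out of scope (no minimum-image
  convention).
- **Locally Gaussian environments.** The mapping is only as good as
  the mixture's ability to describe the pooled distributions. Strongly
  skewed or heavy-tailed environment distributions are approximated by
  several Gaussian clusters, which inflates the descriptor length.
- **Angular deduplication.** For a trio centred on atom i only the
  unordered neighbor set {j, k} is counted, with a deterministic
  canonical ordering (unlike elements: j alphabetically first; like
  elements: j closer, ties by index). The inner angle depends only on
  the origin atom, so the other two orderings of a trio carry no new
  information.

## Weighted EM and model selection

The mixture is fitted by expectation–maximization with per-sample
weights `s_n`: responsibilities are the usual posterior component
memberships, and the M-step updates are weighted averages with
`s_n · r_nc` in place of `r_nc`. Under the *hard* cutoff scheme all
`s_n = 1` and this reduces to standard EM; under the *soft* scheme
`s_n` is the cosine-kernel attenuation `f_c` of the sample (product of
the two legs' attenuations for angular triples), so configurations near
the cutoff edge influence the clustering in proportion to their weight
in the descriptor they will parameterize. This is the one place the
two cutoff schemes differ ahead of feature evaluation.

Numerical choices:

- **Initialization** is k-means++-style seeding of the means
  (selection probability ∝ `s_n · D²`), hard assignment, per-cluster
  weighted covariances, equal component weights. Deterministic given
  the seed; every fit records its seed.
- **Regularization**: `1e-6` (squared units) is added to the
  covariance diagonal at every M-step. This is applied unconditionally
  rather than on detected near-singularity — the perturbation is far
  below any physically meaningful spread (σ ≳ 0.01 Å / rad) and an
  unconditional guard has no failure mode to detect.
- **Convergence**: relative log-likelihood change below `1e-6`, cap
  500 iterations. The per-iteration log-likelihood history is kept on
  the fit object and asserted non-decreasing in the test suite.
- **BIC**: `k·ln(n_eff) − 2·ln L̂` with `k = M(d + d(d+1)/2 + 1) − 1`
  (1-D: `3M−1`; 3-D full covariance: `10M−1`) and `n_eff = Σ s_n`, the
  weighted-likelihood analogue of the sample count.
- **Component-count selection**: `min_bic` scans `M = 1…n_max` and
  takes the global minimum. The `threshold` criterion stops early at
  the first `M` where the relative BIC improvement falls below the
  score threshold (default 30%) *and* the discrete BIC gradient has
  shrunk by more than the gradient threshold (default 40%) relative to
  the previous step; if no `M` qualifies it falls back to the scan's
  minimum. The gradient condition needs three consecutive BIC values,
  so the earliest possible data-driven stop is `M = 2` (where only the
  score condition applies). These semantics are deliberately isolated
  behind the criterion switch.
- 3-D components use **full covariance**: angular clusters are
  visibly anisotropic (bond and angle spreads differ by an order of
  magnitude in natural units) and correlated.

## Cluster → function mapping

Radial: `r_s = μ`, `η = 1/(2σ²)` — exact, since the radial symmetry
function and the mixture component share the same exponential kernel.

Angular: the heavily modified angular form has a *single* radial grid
for both legs, so the 3-D cluster's two radial dimensions must be
pooled: `r_s = (μ_rij + μ_rik)/2` and `η = 1/(2σ̄²)` with
`σ̄ = (σ_rij + σ_rik)/2` (arithmetic means of the marginal statistics;
cross-covariance terms cannot be represented by the kernel and are
dropped). The angular offset is pinned at the centroid, `θ_s = μ_θ`.
The cosine-power sharpness ξ has no closed form against a Gaussian, so
it is fitted by least squares between the normalized kernel
`2^(1−ξ)(1+cos(θ−θ_s))^ξ / 2` and the normalized Gaussian on a uniform
181-point grid over [0, π]: coarse log-spaced bracketing over
ξ ∈ [1, 1000] followed by bounded scalar refinement, with ξ ≥ 1
enforced (the flattest admissible kernel, reached in the flat-cluster
limit σ_θ → ∞). Agreement with a dense-grid oracle is within a
fraction of a percent across σ_θ ∈ [0.1, 0.4] rad; the kernel's FWHM
tracks the Gaussian's within 15% over σ_θ ∈ [0.05, 0.5] rad.

## Resampling layouts and auxiliaries

A Gaussian centred on a cluster responds symmetrically to bond
compression and elongation; the resampling layouts break that
degeneracy:

- **decomposed**: K subcomponents evenly spaced over [μ−σ, μ+σ]
  (K = 1 degenerates to the plain mapping), common width chosen so
  adjacent subcomponents cross at half height.
- **displaced**: one function at `r_s = μ + α·σ` with width `α·σ`, so
  the whole cluster span [μ−α·σ, μ+α·σ] lies on the strictly rising
  flank; α = 3 spans 99.7% of the cluster population.
- **binary**: a pair at `μ ± α·σ`, both with width `β·σ`; the
  upper−lower difference is strictly monotone across the cluster,
  giving even resolution at both edges. Defaults α = 3, β = 1, the
  best-performing combination for nonlinear downstream regressors.

Auxiliary functions fill gaps between sparse clusters: functions are
scanned in `r_s` order and whenever the smaller of the two Gaussian
values at the inter-center midpoint falls below `min_overlap`
(default 0.01), one auxiliary is inserted at the midpoint with
σ = half the center gap. The midpoint-value criterion is monotone in
the gap and cheap; it is a documented package-level construction, as is
the decomposed span/crossing geometry above.

The evenly distributed baseline (`uniform_radial_basis`) places n
centers over [r_min, r_c] with the same half-height-crossing width
rule; it typically produces dead functions outside the sampled range,
which `prune_dead` removes (activation threshold `1e-8`, far below any
physically meaningful activation).

## Feature assembly and normalization

AEV rows are evaluated per (frame, atom) in deterministic order; the
column order is the SFSet's (radial before angular, then by neighbor
typing, `r_s`, `θ_s`). Because per-element function sets generally have
different lengths, the general container is one feature matrix per
center element (`build_element_matrices`) — matching the element-wise
models these descriptors feed. `build_feature_matrix` provides the
single positionally stacked matrix when all element sets have equal
length, and errors otherwise. The sklearn-facing
`TailoredACSF.transform` returns the per-element blocks concatenated
into one wide matrix with zeros outside an atom's own element block, so
it composes with `Pipeline` without a custom container.

Normalization is per-column min–max fitted on a designated training row
subset only; values outside the training range map outside [0, 1]
(no clipping), constant columns map to 0. Min–max (rather than
z-scoring) keeps the bounded image that activation-like features
suggest, and the record is serialized so it can be swapped.

## Synthetic fixtures: what they emulate and what they don't

`OscillatorSpec`/`generate_trajectory` stand in for MD or normal-mode
sampling: small molecules (2–5 atoms, tree-shaped bond topology) whose
bond lengths and listed angles are drawn independently per frame from
Gaussians about their means, rebuilt to Cartesians by
natural-extension-reference-frame placement with dihedrals held at the
chosen conformer's equilibrium values, plus optional two-conformer
switching (independent Bernoulli per frame). Independent Gaussian
internal coordinates are exactly the cluster structure the pipeline is
supposed to recover — the strongest available oracle — but they lack
the anharmonicity, mode coupling and kinetic correlation of real
ensembles, and the tree restriction excludes rings. Passing tests
therefore demonstrate the correctness of the machinery (collection,
clustering, mapping, evaluation, invariances), not the physical quality
of descriptors for any real system. The synthetic atomic property
(linear in a bond-length deviation) plays the role of a quantum-derived
per-atom target for end-to-end feature-quality checks; it is invariant
under rigid motion by construction.

Study conditions used by the test suite and the acceptance script:
water-like triatomic with O–H ~ N(0.96 Å, 0.03²) and angle
~ N(104.5°, 3°); mixture-recovery fixture
0.5·N(1.0, 0.05²) + 0.5·N(2.0, 0.05²) with 2000 samples; two-conformer
fixture switching between (0.96 Å, 104.5°) and (1.15 Å, 115°) with
probability 0.5 and σ = 0.02 Å / 3°, 5000 frames. These sizes keep the
whole suite under a minute while leaving every statistical bound
(3-standard-error or binomial) comfortably resolvable.

## Design choices that were genuinely open

- **Soft-cutoff weights enter the EM fit** as sample weights. The two
  cutoff schemes are collection-time options; carrying the attenuation
  into the likelihood is the only reading under which they differ
  before feature evaluation, and it degrades gracefully to standard EM
  for hard cutoffs.
- **Homonuclear radial pairs are counted in both directions** (i→j and
  j→i): each atom acts as a center in turn. This only rescales the
  sample pool symmetrically and does not shift cluster statistics.
- **Linear-probe evaluation uses β = 2.** In the end-to-end check a
  *linear* model reads the binary-scheme AEVs. With β = 1 the two
  functions are pure far-tail Gaussians across the cluster span
  (values e^{−4.5}…e^{−0.5}), so strongly convex that the best linear
  fit of a linear-in-r property caps near R² ≈ 0.4–0.87 regardless of
  sample size — a nonlinear regressor absorbs this, a linear probe
  cannot. β = 2 (inside the moderate β ∈ [1, 2] band the method
  targets) makes the flanks quasi-linear over the cluster and is used
  for the linear-probe tests; package defaults remain α = 3, β = 1.
- **`ξ` search domain [1, 1000]**: practical angular sharpness sits
  well below 100; the headroom costs nothing with log-spaced
  bracketing.

## Known limitations

- Brute-force neighbor enumeration (no cell lists): appropriate for
  desk-scale molecules, not condensed phases.
- No analytical gradients of AEVs with respect to coordinates.
- The parameter table stores `θ_s` in degrees (user-facing unit);
  reading it back reproduces radians to ~1 ulp, not bit-exactly —
  all other fields round-trip bit-exactly via `repr`.
- The angular branch of the `threshold` criterion inherits BIC's
  tendency to over-segment non-Gaussian 3-D distributions; `nmax` and
  `afrac` are the practical guards.
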