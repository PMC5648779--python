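# Methods

This note documents the models implemented in `kinescape`, the defaults and
why they were chosen, what the synthetic data generator does and does not
emulate, and the numerical conventions a careful user should know about.
Every number quoted here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not verify.

## Markov state models

Frames are clustered into discrete states with Gonzalez farthest-point
k-centers under a fixed covering radius (default 2 Å): the first frame
seeds center 0, and the frame farthest from its nearest center is promoted
until that distance drops below the radius. The algorithm is deterministic
given frame order, and guarantees every frame lies within the radius of its
center. Clustering can run on feature vectors (Euclidean metric) or
directly on coordinates under minimal backbone RMSD. Because the seeding is
order-dependent, absolute state counts are not meaningful observables; the
spectral quantities downstream are.

Transitions are counted per trajectory at an integer lag (default 5 ns)
with a sliding window — every frame that has a partner one lag later in the
*same* trajectory contributes — so data use is maximal; strided counting is
available as an option. Counting never crosses trajectory boundaries, which
is what lets many short trajectories describe kinetics longer than any one
of them. The count graph is trimmed to its largest strongly connected
component (ties broken by total counts, then lowest original index) so the
network is ergodic.

Estimation enforces reversibility by literal count symmetrization,
`C' = (C + Cᵀ)/2`, followed by row normalization, `T_ij = C'_ij / Σ_k C'_ik`.
For symmetrized counts the stationary distribution has the closed form
`π_i = Σ_k C'_ik / Σ_jk C'_jk`, and detailed balance `π_i T_ij = π_j T_ji`
holds to rounding error by construction (verified to 1e-14 on random count
matrices up to 50 states). This estimator is simple, exactly reproducible,
and adequate when both jump directions are well sampled; it is *not* the
maximum-likelihood reversible estimator, and with very asymmetric sampling
it biases populations toward the better-sampled direction (a known
limitation, see below).

Spectra are computed through the symmetrized similar matrix
`D_π^{1/2} T D_π^{-1/2}`, which is symmetric under detailed balance — so
eigenvalue realness is structural, not a magnitude-taking convention; an
asymmetry above 1e-8 raises an error rather than silently proceeding.

## Validation

*Implied timescales.* For each candidate lag τ a fresh model is built and
`t_k = -τ / ln μ_k(τ)` reported for the top non-unit eigenvalues.
Non-positive eigenvalues yield NaN markers, never fabricated numbers.
Lag-independence ("flatness") of `t_k` beyond some τ is the usual
Markovianity heuristic; on data generated by an exactly Markovian chain the
scan is flat to sampling error (tested), and on the synthetic landscape it
flattens by the 5 ns working lag.

*Chapman–Kolmogorov basin-escape test.* The model curve starts from the
stationary distribution renormalized on a user-chosen basin (matching the
frame-weighted start of the empirical estimate), propagates `Tᵏ`, and sums
probability over the basin; the empirical curve is the fraction of
basin frames still in the basin k·τ later within the same trajectory, with
binomial standard errors. The suite requires agreement within 3 SE on
Markovian data *and* requires the test to fire (>3 SE) on a planted
hidden-state process whose observable has long memory — a validation test
that cannot fail is not a test.

## Dynamical free-energy landscapes

Initial probability vectors are propagated by iterated vector–matrix
products (`p(kτ) = p(0)·Tᵏ`), renormalizing away ~1e-16 rounding drift per
step. The default initial vector is uniform over the states containing each
trajectory's first frame — the package's concrete reading of "probability
localized in the starting configurations" — and is configurable. Dynamical
free energies are `F_i(t) = -ln p_i(t)` in kT; zero-probability states
carry an explicit infinite-F marker.

For projection onto an order-parameter pair, each state's probability is
split uniformly over `n_per_state` (default 10) representative frames drawn
uniformly with replacement from the state's members (replacement so small
states honor the count; deterministic given the seed), and deposited into a
2-D grid; `F = -ln(mass)` with each time slice renormalized independently
(documented convention — slices are directly comparable only up to their
own normalization). Unoccupied bins are marked missing, never zero. The
cosmetic default grid is 50×50 over the padded observed ranges; for
*quantitative* basin location the tests use ~1 Å bins, i.e. half the
cluster radius, because surface structure finer than the state radius only
samples representative-draw noise.

## λ-ensemble dissipation analysis

Each jump of a reversible chain produces entropy `q_ij = ln(T_ij/T_ji)`
(antisymmetric; zero on the diagonal; defined because symmetrized
estimation guarantees a symmetric edge set). The path ensemble is
exponentially tilted by total dissipation: the matrix
`T̃_ij(λ) = T_ij e^{(λ-1) q_ij} = T_ij^λ / T_ji^{λ-1}` generates the
weighted path sum; it reduces to T at λ = 1 and is deliberately never
row-renormalized. Propagation renormalizes the *vector* at each step while
accumulating the log normalization, so underflow cannot occur and both
conventions — normalized conditional distribution (default) and raw weight
ratios — are recoverable; they differ only by a state-independent offset
per time. Dissipative free energy changes are
`ΔF_i(t) = -ln(p̃_i(t)/p_i(t))`; λ = 1 gives exact zeros.

The module's ground truth is exhaustive path enumeration: on random chains
with ≤5 states and ≤6 steps, matrix propagation reproduces the brute-force
weighted path sum to 1e-10 (100 instances in the acceptance script).

**An exact structural identity worth knowing.** For a detailed-balanced T,
per-path dissipation telescopes to `ln(π_end/π_start)`, so
`ΔF_i(t) = -ln π_i + c(t)` wherever `p_i(t) > 0`: the dissipative surface
is the equilibrium free-energy surface up to a time-dependent offset,
masked to the states actually reached. Three consequences shape the
expected signature of a two-stage mechanism probed at early times:

* the currently dominant, quasi-equilibrated initial basin sits at
  ΔF ≈ 0 (the offset c(t) is pinned by where the mass is);
* strong negative ΔF concentrates in the *deeper* states newly reached by
  entropy-producing barrier crossings — in the default landscape,
  overwhelmingly the final basin (ΔF ≈ −1 kT at the 30 ns probe);
* low-π barrier-top states show ΔF > 0, and basins nearly degenerate with
  the initial one (the intermediate, by design ~0.5 kT deeper) hover near
  zero, with a sign that is sensitive to clustering granularity.

The acceptance test asserts exactly this identity-consistent pattern and
confirms it against path enumeration on a 5-state lumped chain whose
per-state weights mirror the landscape's depth contrasts.

## The synthetic landscape generator

The generator supplies data with the statistical structure the analysis
assumes, with full ground truth:

* **Potential.** Three inverted Gaussians plus a quartic confinement:
  basins A (initial) at (8, 11) Å, I (intermediate) at (15, 11) Å, and B
  (final) at (15, 3.2) Å; depths (6.8, 7.1, 9.0) kT, widths 2 Å,
  confinement `1.0·(|r−r₀|/7)⁴`. Latent coordinates are interpreted in Å
  so embedded features live on realistic order-parameter scales. Line-scan
  barriers: A→I 3.5 kT, I→B 4.7 kT.
* **Dynamics.** Overdamped Langevin (Euler–Maruyama), kT = 1, γ = 1,
  dt = 0.01 time units, with a construction-time stability check
  (per-step displacement ≪ well width) that suggests a valid dt on
  failure. Both coordinates are distances, so the integrator reflects at
  zero — a zero-flux boundary that leaves the Boltzmann distribution on
  the positive quadrant unchanged. One RNG stream per trajectory, spawned
  from the master seed via `SeedSequence.spawn`, so adding trajectories
  never perturbs existing ones; same seed ⇒ bit-identical output.
* **Reference kinetics.** A nearest-neighbour hopping generator on a
  regular grid (default 80×80) with symmetric-split rates
  `k_ij = (D/h²) e^{-(V_j-V_i)/2kT}`. These satisfy detailed balance with
  respect to the grid Boltzmann weights *exactly* (`w_i k_ij = (D/h²)√(w_i w_j)`
  is symmetric, verified to 1e-16) and have O(h²) drift error; the classic
  `min(1, e^{-βΔV})` rule was rejected after measurement because its O(h)
  drift bias leaves the oracle ~25% slower than the continuum dynamics at
  any feasible grid. Timescales are grid-converged to <1% at the default
  resolution. Exact mean first-passage times come from a sparse linear
  solve on the generator.
* **Tuned stage separation.** Depths and basin placement were fixed, once,
  against the reference oracle so the two slowest relaxation times have
  ratio ≈ 5 (t₁ = 302.8, t₂ = 61.2 time units; ratio 4.95) — a fast
  cleft-opening-like stage I and a ~5× slower anchoring-like stage II.
  The nominal mapping 1 time unit = 0.5 ns places the conventional 5 ns
  analysis lag between the intra-well relaxation (≈1.7 ns) and stage I
  (≈30.6 ns).
* **Sampling design.** Defaults are 6 trajectories × 10⁶ steps. A and I
  are nearly balanced (ΔV ≈ 0.56 kT) and B moderately dominant
  (ΔV ≈ 1.5 kT vs I) so that *both* slow processes are crossed many times
  per run; this is what makes 25%-level timescale recovery statistically
  meaningful at desk scale. The flip side: in this regime the slowest
  relaxation (~150 ns nominal) is shorter than one trajectory (1 μs
  nominal per trajectory at the default mapping), so the
  longer-than-any-trajectory aggregation regime of real MSM studies is
  exercised structurally (per-trajectory counting, boundary handling,
  seed-split streams) but not statistically. Recovering kinetics that are
  5× longer than every trajectory would need far more trajectories than a
  test budget allows.
* **Pseudo-atom embedding.** A 34-atom pseudo-protein with labeled
  residues (32, 33, 40, 48, 54, 87). One residue translates along x so the
  32:CA–87:CA distance equals latent coordinate 1 *exactly*; another
  translates along y so the 48/54 side-chain heavy-atom centroid
  separation equals latent coordinate 2 exactly. The embedding is
  invertible by the featurizer to 1e-6, making the geometric pipeline
  testable without real MD output. Latent values must be non-negative
  (they are distances); violations are hard errors.

What the generator does *not* emulate: real force fields, solvent, atomic
fluctuations orthogonal to the two order parameters, non-two-state basin
anatomy, and experimental noise. Passing tests therefore demonstrate the
*analysis machinery* is correct on data satisfying its assumptions, not
that any particular molecular system is well described by a 2-D landscape.

## Geometry kernels

* **Kabsch RMSD** by SVD with the determinant sign correction (proper
  rotations only). The residual is evaluated on the superposed
  coordinates, not via the trace formula, which cancels catastrophically
  near zero; rigid-motion invariance holds to 1e-9 and agreement with a
  dense rotation-search oracle to 1e-6. "Backbone" means N, CA, C, O.
* **Shrake–Rupley SASA** with deterministic golden-spiral sphere points
  (default 960; minimum 92), probe 1.4 Å, bundled Bondi radii (unknown
  elements are hard errors, never silent defaults). All atoms occlude;
  only target atoms contribute area. Isolated-sphere accuracy at 960
  points is ~0.01%; the two-sphere spherical-cap closed form is matched
  to well under 2%.
* **Distances** in single-atom or unweighted-centroid mode; "side chain"
  selections mean non-hydrogen atoms excluding the backbone, a symmetric
  and ring-flip-invariant convention. Residue numbering is taken verbatim
  from the input structure.
* Whether a residue's SASA uses all atoms or side-chain-only is a
  selection-level option (default: whole residue).

## Pipeline conventions

A single validated config (unknown keys rejected with their path;
cross-field checks such as lag ∣ frame-interval run before any stage)
plus the master seed fully determines every artifact. Artifacts are tidy
CSV, MatrixMarket + JSON sidecars, multi-model PDB and JSON manifests; the
manifest stores per-stage input hashes and per-file content hashes, so
re-runs skip unchanged stages and deterministic stages are byte-identical
across runs (tested). Stage failures abort with the stage name and leave a
FAILED marker. Exit codes: 0 success, 2 config error, 3 stage error.

## Problem sizes used by the tests and acceptance script

Chosen as the package's study conditions: random-matrix contracts at ≤50
states × 20 instances; path enumeration at ≤5 states × ≤6 steps × 100
instances; chain-recovery at 6×10⁵ steps across 6 segments; CK checks at
3×10⁵ steps; the end-to-end landscape at the generator defaults
(6×10⁶ total steps, ~60 000 saved frames). On one CPU the full suite runs
in ~3 minutes and the acceptance script in well under two.

## Known limitations

* Count symmetrization is not maximum-likelihood reversible estimation;
  no Bayesian error bars on T; no coarse-graining (PCCA) or TPT.
* k-centers state counts depend on frame order (documented and
  deterministic, but not permutation-invariant).
* The CK test covers basin escape only, not the full eigenvector test.
* The λ-ensemble implements one tilt convention (per-jump entropy
  production); λ-spectrum scans and large-deviation rate functions are out
  of scope, and for detailed-balanced models the ΔF surface carries no
  information beyond −ln π plus an offset (see the identity above) — its
  value is in *where* mass has and has not propagated at each probe time.
* Binary trajectory formats are not parsed; ingestion is multi-model PDB
  (an adapter can construct `MolecularFrameSet` objects from any source).
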