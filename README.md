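# kinescape

Markov state models, time-resolved free-energy landscapes and dissipative
(λ-ensemble) trajectory analysis for molecular simulations.

## The problem

Molecular-dynamics studies of slow conformational changes — a binding cleft
opening, a side chain swinging from one β-strand to another — face a basic
mismatch: the mechanism unfolds over microseconds, while affordable
individual trajectories are much shorter. The standard remedy is to pool
many independent trajectories into a **Markov state model (MSM)**: cluster
the sampled conformations into discrete states, count lag-time transitions
within each trajectory, and estimate a transition probability matrix whose
spectrum describes kinetics far beyond any single trajectory's length.

`kinescape` implements that machinery end to end for users who want a small,
transparent, fully tested alternative to monolithic MSM suites:

* **geometry** — multi-model PDB ingestion and order parameters: minimal
  (Kabsch) backbone RMSD, residue-pair distances (Cα–Cα or side-chain
  centroids), Shrake–Rupley solvent-accessible surface area with
  golden-spiral quadrature and Bondi radii;
* **msm** — fixed-radius Gonzalez k-centers clustering, sliding-window
  lag-time counting, strongly-connected-component (ergodic) trimming,
  count symmetrization and row normalization;
* **validation** — implied relaxation timescales `t_k = -τ/ln μ_k(τ)`
  versus lag, and the Chapman–Kolmogorov basin-survival test against raw
  trajectories;
* **landscape** — Chapman–Kolmogorov propagation `p(kτ) = p(0)·Tᵏ`,
  dynamical free energies `F_i(t) = -ln p_i(t)` (kT), and their projection
  onto order-parameter pairs through per-state representative
  conformations;
* **dissipation** — the λ-ensemble: tilt every jump by its entropy
  production `q_ij = ln(T_ij/T_ji)`, propagate `T̃_ij(λ) = T_ij e^{(λ-1)q_ij}`
  (λ = 1 unbiased, λ = 2 dissipative), and report dissipative free energy
  changes `ΔF_i = -ln(p̃_i/p_i)`;
* **synthetic** — a first-class generator of ground-truth data: overdamped
  Langevin dynamics on a three-basin, two-stage landscape (fast stage I,
  ~5× slower stage II), an exact pseudo-atom embedding so the geometric
  featurizer can be tested against known latent coordinates, and a
  grid-discretized rate-matrix reference whose eigendecomposition provides
  exact timescales;
* **pipeline / CLI** — `kinescape run config.yaml` drives the whole chain
  with plain-text artifacts, content-hash caching and a reproducibility
  manifest.

## Worked example

`examples/03_build_and_validate_msm.py` simulates four trajectories on the
default two-stage landscape, builds a 2 Å / 5 ns MSM and validates it:

```
k-centers states (radius 2 Å): 33
states after ergodic trimming: 33

implied timescales (ns) vs lag:
rank        1     2
lag_ns
1.0      96.9  19.5
2.5     107.0  22.1
5.0     109.8  23.9
10.0    113.9  23.5

Chapman-Kolmogorov basin-survival:
 k  time_ns  model_survival  empirical_survival  empirical_se  n_samples
 0      0.0           1.000               1.000         0.000       1392
 1      5.0           0.662               0.658         0.013       1376
 2     10.0           0.603               0.602         0.013       1360
 4     20.0           0.512               0.503         0.014       1338
 8     40.0           0.395               0.379         0.013       1306
max |model - empirical| in SE units: 1.16
```

The two implied timescales flatten beyond the 5 ns lag — the discretized
dynamics are Markovian there — and approach the generator's exact reference
values (151.4 ns and 30.6 ns at the full default sampling; this reduced run
sits ~25% low on the slowest mode). The Chapman–Kolmogorov curves agree
within ~1 standard error at every probe, so the model reproduces the raw
trajectories' escape kinetics from the starting basin.

`examples/05_dissipation_analysis.py` continues to the λ = 2 ensemble:

```
basin | delta_F(lambda=2) at 30 ns (kT)
  A   | +0.174
  I   | -0.106
  B   | -1.118
```

The initial basin, still near local equilibrium, is essentially untouched
by the dissipative bias, while the deep final basin — reached through
entropy-producing barrier crossings — is strongly enriched
(ΔF ≈ −1.1 kT ≈ threefold probability increase).

The other examples cover structure featurization (01), the synthetic
landscape and its exact reference kinetics (02), time-resolved landscape
projection (04) and the cached full pipeline (06); each prints its results
with a short interpretation.

## Layout

```
src/kinescape/     library (geometry, synthetic, msm, validation,
                   landscape, dissipation, io, pipeline, cli)
examples/          one narrative script per capability
tests/             pytest suite with independent oracles
scripts/           acceptance script
docs/methods.md    models, assumptions, numerical choices, limitations
```
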