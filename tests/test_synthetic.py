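import numpy as np
import pytest
from scipy import stats

import kinescape as ks
from kinescape.errors import EstimationError, NumericalError, TopologyError
from kinescape.synthetic import LangevinParams, PotentialSpec


def quiet_params(**kw):
    defaults = dict(n_steps=20_000, n_trajectories=2, save_stride=10, seed=11)
    defaults.update(kw)
    return LangevinParams(**defaults)


class TestPotential:
    def test_three_wells_required(self):
        with pytest.raises(TopologyError):
            PotentialSpec(well_centers=((0, 0), (1, 1)), well_depths=(1, 1), well_widths=(1, 1))

    def test_confining_at_large_radius(self):
        pot = ks.default_potential()
        far = np.array([[200.0, 200.0], [-150.0, 30.0]])
        assert np.all(pot.potential(far) > 100.0)

    def test_gradient_matches_finite_differences(self):
        pot = ks.default_potential()
        rng = np.random.default_rng(3)
        pts = rng.uniform(2, 18, size=(20, 2))
        eps = 1e-6
        for p in pts:
            g = pot.gradient(p)
            for d in range(2):
                dp = np.zeros(2)
                dp[d] = eps
                fd = (pot.potential(p + dp) - pot.potential(p - dp)) / (2 * eps)
                assert g[d] == pytest.approx(fd, abs=1e-5)

    def test_barrier_heights_positive_and_ordered(self):
        b1, b2 = ks.default_potential().barrier_heights()
        assert 0 < b1 < b2  # stage II climbs the higher barrier


class TestSimulate:
    def test_zero_temperature_fixed_point(self):
        pot = ks.default_potential()
        start = pot.well_minima()[0]
        ens = ks.simulate(pot, quiet_params(kT=0.0, n_trajectories=1), start=start)
        drift = np.linalg.norm(ens.latent - start, axis=1)
        assert drift.max() < 1e-6

    def test_equipartition_in_a_quasi_harmonic_well(self):
        # deep wide Gaussian well: curvature κ = depth/width² = 1 kT/Å²,
        # anharmonic corrections O(kT/depth) ≈ 4%
        pot = PotentialSpec(
            well_centers=((30.0, 30.0), (90.0, 30.0), (30.0, 90.0)),
            well_depths=(25.0, 0.01, 0.01),
            well_widths=(5.0, 1.0, 1.0),
            confinement_strength=0.5,
            confinement_center=(30.0, 30.0),
            confinement_scale=30.0,
        )
        ens = ks.simulate(pot, quiet_params(n_steps=400_000, n_trajectories=1, save_stride=100), start=(30.0, 30.0))
        var = ens.latent.var(axis=0)
        # ~4000 saved frames at ~1 correlation time spacing: 3 SE ≈ 0.07
        assert np.all(np.abs(var - 1.0) < 0.12)

    def test_seed_determinism_and_stream_splitting(self):
        pot = ks.default_potential()
        a = ks.simulate(pot, quiet_params(n_trajectories=2))
        b = ks.simulate(pot, quiet_params(n_trajectories=2))
        assert np.array_equal(a.latent, b.latent)
        wider = ks.simulate(pot, quiet_params(n_trajectories=4))
        # adding trajectories must not perturb earlier ones
        n_saved = np.sum(a.trajectory_ids == 0)
        assert np.array_equal(
            wider.latent[wider.trajectory_ids < 2], a.latent
        )
        assert not np.array_equal(
            wider.latent[wider.trajectory_ids == 2][: n_saved], a.latent[a.trajectory_ids == 0]
        )

    def test_dt_stability_check_suggests_dt(self):
        with pytest.raises(NumericalError, match="use dt"):
            ks.simulate(ks.default_potential(), quiet_params(dt=2.0))

    def test_boltzmann_occupancy_chi_square(self):
        # fast-mixing single-well landscape; pre-registered 4x4 bins over
        # the 2-sigma box, chi-square at alpha = 0.01
        pot = PotentialSpec(
            well_centers=((30.0, 30.0), (90.0, 30.0), (30.0, 90.0)),
            well_depths=(25.0, 0.01, 0.01),
            well_widths=(5.0, 1.0, 1.0),
            confinement_strength=0.5,
            confinement_center=(30.0, 30.0),
            confinement_scale=30.0,
        )
        ens = ks.simulate(pot, quiet_params(n_steps=600_000, n_trajectories=1, save_stride=200), start=(30.0, 30.0))
        samples = ens.latent[10:] - 30.0  # recenter; drop the short transient
        edges = np.linspace(-2.0, 2.0, 5)
        obs = np.histogram2d(samples[:, 0], samples[:, 1], bins=(edges, edges))[0].ravel()
        # expected occupancy from fine-grid Boltzmann integration per bin
        fine = 40
        exp_mass = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                xs = np.linspace(edges[i], edges[i + 1], fine)
                ys = np.linspace(edges[j], edges[j + 1], fine)
                xx, yy = np.meshgrid(xs, ys, indexing="ij")
                exp_mass[i, j] = np.exp(-pot.potential(np.stack([xx + 30.0, yy + 30.0], -1))).mean()
        expected = exp_mass.ravel() / exp_mass.sum() * obs.sum()
        chi2 = np.sum((obs - expected) ** 2 / expected)
        crit = stats.chi2.ppf(0.99, df=obs.size - 1)
        # saved frames are ~2 correlation times apart, i.e. independent
        assert chi2 < crit


class TestEmbedding:
    def test_round_trip_is_exact(self):
        latent = np.array([[10.0, 4.0], [8.25, 12.5], [15.0, 3.0]])
        frames = ks.embed_pseudo_atoms(latent)
        fm = ks.featurize(frames, ks.pseudo_atom_features())
        assert np.allclose(fm.values, latent, atol=1e-6)

    def test_constant_path_has_zero_variance(self):
        latent = np.tile([[9.0, 9.0]], (5, 1))
        fm = ks.featurize(ks.embed_pseudo_atoms(latent), ks.pseudo_atom_features())
        assert np.all(fm.values.std(axis=0) < 1e-12)

    def test_negative_latent_is_an_error(self):
        with pytest.raises(TopologyError, match="negative"):
            ks.embed_pseudo_atoms(np.array([[-0.5, 4.0]]))

    def test_trajectory_tags_preserved(self):
        latent = np.array([[8.0, 11.0]] * 4)
        tids = np.array([0, 0, 1, 1])
        frames = ks.embed_pseudo_atoms(latent, trajectory_ids=tids, frame_interval_ns=0.5)
        assert np.array_equal(frames.trajectory_ids, tids)
        assert frames.frame_interval_ns == 0.5


class TestReferenceKinetics:
    def test_symmetric_double_well_populations(self):
        pot = PotentialSpec(
            well_centers=((-4.0, 0.0), (4.0, 0.0), (0.0, 40.0)),
            well_depths=(6.0, 6.0, 1e-6),
            well_widths=(1.5, 1.5, 1.0),
            confinement_strength=1.0,
            confinement_center=(0.0, 0.0),
        )
        rk = ks.reference_kinetics(pot, shape=(40, 40), extents=((-8.0, 8.0), (-8.0, 8.0)))
        pts = rk.cell_centers()
        left = rk.stationary[pts[:, 0] < 0].sum()
        right = rk.stationary[pts[:, 0] > 0].sum()
        assert left == pytest.approx(right, abs=1e-10)

    def test_stationary_equals_boltzmann_weights(self):
        pot = ks.default_potential()
        rk = ks.reference_kinetics(pot, shape=(30, 30))
        v = pot.potential(rk.cell_centers())
        w = np.exp(-(v - v.min()))
        assert np.allclose(rk.stationary, w / w.sum(), atol=1e-12)
        assert np.all(np.isfinite(rk.timescales)) and np.all(rk.timescales > 0)

    def test_generator_contract(self):
        rk = ks.reference_kinetics(ks.default_potential(), shape=(25, 25))
        q = rk.generator.toarray()
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        off = q - np.diag(np.diag(q))
        assert np.all(off >= 0)
        # exact detailed balance w.r.t. the stationary vector
        flux = rk.stationary[:, None] * q
        assert np.max(np.abs(flux - flux.T)) < 1e-16

    def test_default_landscape_stage_separation(self):
        rk = ks.reference_kinetics(ks.default_potential())
        ratio = rk.timescales[0] / rk.timescales[1]
        assert 3.0 <= ratio <= 7.0

    def test_grid_too_coarse_is_an_error(self):
        with pytest.raises(EstimationError, match="coarse"):
            ks.reference_kinetics(ks.default_potential(), shape=(4, 4))
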