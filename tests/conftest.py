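import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def end_to_end():
    """Full analysis of the default synthetic two-stage landscape.

    Shared across the slower integration/acceptance tests: simulate →
    embed pseudo-atoms → featurize → cluster → MSM → validation →
    propagation → surfaces → dissipation, all at the generator's default
    study conditions (6 trajectories × 10⁶ steps).
    """
    import kinescape as ks

    pot = ks.default_potential()
    params = ks.default_params(seed=2024)
    reference = ks.reference_kinetics(pot)
    ens = ks.simulate(pot, params)
    frames = ks.embed_pseudo_atoms(ens)
    features = ks.featurize(frames, ks.pseudo_atom_features())
    dtraj, centers = ks.kcenters_cluster(features, radius=2.0)
    lag_steps = int(round(5.0 / features.frame_interval_ns))  # 5 ns lag
    model, mapping, relabeled = ks.build_msm(dtraj, lag_steps)
    from kinescape.landscape import default_initial_distribution

    p0 = default_initial_distribution(relabeled, model.n_states)
    scan = ks.implied_timescales(dtraj, [2, 5, lag_steps, 2 * lag_steps], n_timescales=2)
    reps = ks.sample_state_representatives(model, n_per_state=10, seed=2024)
    return {
        "potential": pot,
        "params": params,
        "reference": reference,
        "ensemble": ens,
        "features": features,
        "dtraj": dtraj,
        "model": model,
        "relabeled": relabeled,
        "p0": p0,
        "scan": scan,
        "representatives": reps,
        "lag_steps": lag_steps,
    }
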