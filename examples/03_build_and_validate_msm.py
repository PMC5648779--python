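"""Estimate and validate a Markov state model from synthetic trajectories.

Clusters the featurized frames into 2 Å states (Gonzalez k-centers),
counts 5 ns-lag transitions per trajectory, trims to the ergodic core,
symmetrizes, and normalizes. Validation: implied-timescale lag scan and
a Chapman-Kolmogorov basin-survival test.
"""

import numpy as np

import kinescape as ks
from kinescape.landscape import default_initial_distribution

potential = ks.default_potential()
params = ks.LangevinParams(seed=3, n_steps=400_000, n_trajectories=4)
ensemble = ks.simulate(potential, params)
features = ks.featurize(ks.embed_pseudo_atoms(ensemble), ks.pseudo_atom_features())

dtraj, centers = ks.kcenters_cluster(features, radius=2.0)
print("k-centers states (radius 2 Å):", dtraj.n_states)

lag_steps = int(round(5.0 / features.frame_interval_ns))  # 5 ns lag
model, index_map, relabeled = ks.build_msm(dtraj, lag_steps)
print("states after ergodic trimming:", model.n_states)

scan = ks.implied_timescales(dtraj, [2, 5, 10, 20], n_timescales=2)
print("\nimplied timescales (ns) vs lag:")
print(scan.to_dataframe().pivot(index="lag_ns", columns="rank", values="timescale_ns").round(1))

basin = np.flatnonzero(default_initial_distribution(relabeled, model.n_states) > 0)
ck = ks.ck_test(model, relabeled, basin=basin, probe_multiples=[0, 1, 2, 4, 8])
print("\nChapman-Kolmogorov basin-survival:")
print(ck.to_dataframe().round(3).to_string(index=False))
print("max |model - empirical| in SE units: %.2f" % ck.max_z())
print()
print(
    "Flat timescales beyond the working lag indicate Markovian dynamics;\n"
    "a CK deviation under ~3 SE means the model reproduces the raw\n"
    "trajectories' escape kinetics from the starting basin."
)
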