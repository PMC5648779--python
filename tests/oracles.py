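"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own computational paths:
brute-force rotation search for minimal RMSD, closed-form sphere-cap areas,
exhaustive weighted path enumeration for tilted ensembles, an independent
discrete-chain simulator, and closed-form chain timescales via direct
eigendecomposition of the generating matrix.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def rigid_motion(coords: np.ndarray, rotvec, translation) -> np.ndarray:
    rot = Rotation.from_rotvec(np.asarray(rotvec, float))
    return rot.apply(coords) + np.asarray(translation, float)


def rmsd_of_rotation(a: np.ndarray, b: np.ndarray, rotvec: np.ndarray) -> float:
    """RMSD after centering both sets and rotating b by rotvec."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    br = Rotation.from_rotvec(rotvec).apply(b0)
    return float(np.sqrt(np.mean(np.sum((a0 - br) ** 2, axis=1))))


def rotation_search_rmsd(a: np.ndarray, b: np.ndarray, n_grid: int = 4000, seed: int = 0) -> float:
    """Minimal RMSD by dense random rotation search plus local refinement."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_grid, random_state=rng)
    best_val = np.inf
    best_vec = None
    for rv in rots.as_rotvec():
        v = rmsd_of_rotation(a, b, rv)
        if v < best_val:
            best_val, best_vec = v, rv
    res = minimize(lambda rv: rmsd_of_rotation(a, b, rv), best_vec, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return float(min(best_val, res.fun))


def two_sphere_sasa(radius: float, probe: float, separation: float) -> float:
    """Closed-form SASA of two equal spheres: 2(4πR² − 2πRh), h = R − d/2."""
    big_r = radius + probe
    if separation >= 2 * big_r:
        return 2 * 4 * np.pi * big_r**2
    h = big_r - separation / 2.0
    return 2 * (4 * np.pi * big_r**2 - 2 * np.pi * big_r * h)


def enumerate_tilted_paths(
    t_matrix: np.ndarray, lambda_bias: float, p0: np.ndarray, n_steps: int
) -> tuple[np.ndarray, float]:
    """Exhaustive λ-ensemble path sum.

    Each path x_0..x_k carries weight
    ``p0[x_0] ∏ T[x_t, x_{t+1}] · exp((λ-1) Σ ln(T[x_t,x_{t+1}]/T[x_{t+1},x_t]))``.
    Returns (normalized end-state distribution, total weight).
    """
    t_matrix = np.asarray(t_matrix, float)
    n = t_matrix.shape[0]
    w_end = np.zeros(n)
    for path in itertools.product(range(n), repeat=n_steps + 1):
        w = p0[path[0]]
        if w == 0.0:
            continue
        ok = True
        for a, b in zip(path[:-1], path[1:]):
            tp = t_matrix[a, b]
            if tp == 0.0:
                ok = False
                break
            if a != b:
                q = np.log(tp / t_matrix[b, a])
                w *= tp * np.exp((lambda_bias - 1.0) * q)
            else:
                w *= tp
        if ok:
            w_end[path[-1]] += w
    total = w_end.sum()
    return w_end / total, float(total)


def random_reversible_chain(n: int, rng: np.random.Generator, sparsity: float = 0.0):
    """Random ergodic reversible transition matrix from symmetric counts."""
    c = rng.uniform(0.1, 5.0, size=(n, n))
    if sparsity > 0:
        mask = rng.random((n, n)) < sparsity
        mask = mask | mask.T
        np.fill_diagonal(mask, False)
        c[mask] = 0.0
    c = (c + c.T) / 2.0
    c += np.diag(rng.uniform(1.0, 5.0, size=n))  # keep every state connected
    t = c / c.sum(axis=1, keepdims=True)
    pi = c.sum(axis=1) / c.sum()
    return t, pi


def simulate_chain(t_matrix: np.ndarray, n_steps: int, seed: int, start: int = 0) -> np.ndarray:
    """Independent discrete-time Markov chain simulator."""
    t_matrix = np.asarray(t_matrix, float)
    cum = np.cumsum(t_matrix, axis=1)
    rng = np.random.default_rng(seed)
    u = rng.random(n_steps)
    out = np.empty(n_steps + 1, dtype=np.int64)
    out[0] = start
    s = start
    for i in range(n_steps):
        s = int(np.searchsorted(cum[s], u[i]))
        out[i + 1] = s
    return out


def chain_timescales(t_matrix: np.ndarray, lag_time: float = 1.0) -> np.ndarray:
    """Closed-form relaxation timescales −τ/ln|μ_k| of a transition matrix."""
    evals = np.linalg.eigvals(np.asarray(t_matrix, float))
    evals = np.sort(np.real(evals))[::-1][1:]
    evals = evals[evals > 0]
    return -lag_time / np.log(evals)


def empirical_mfpt(
    latent: np.ndarray,
    trajectory_ids: np.ndarray,
    source: np.ndarray,
    target: np.ndarray,
    core_radius: float = 1.5,
) -> tuple[float, int]:
    """Mean first-passage time (frames) from entering the source core to
    next reaching the target core, averaged over events."""
    times = []
    for tid in np.unique(trajectory_ids):
        xy = latent[trajectory_ids == tid]
        in_src = np.linalg.norm(xy - source, axis=1) < core_radius
        in_tgt = np.linalg.norm(xy - target, axis=1) < core_radius
        waiting = False
        start = 0
        for i in range(len(xy)):
            if in_tgt[i]:
                if waiting:
                    times.append(i - start)
                    waiting = False
            elif in_src[i] and not waiting:
                waiting = True
                start = i
    if not times:
        return np.nan, 0
    return float(np.mean(times)), len(times)


def hidden_state_trajectory(n_steps: int, seed: int) -> np.ndarray:
    """Planted non-Markovian observable: a 3-state hidden chain whose first
    two hidden states project onto one observed state with very different
    exit kinetics, so the observed 2-state process has long memory."""
    t_hidden = np.array(
        [
            [0.995, 0.005, 0.000],
            [0.020, 0.900, 0.080],
            [0.000, 0.020, 0.980],
        ]
    )
    hidden = simulate_chain(t_hidden, n_steps, seed=seed, start=0)
    observed = np.where(hidden <= 1, 0, 1)
    return observed
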