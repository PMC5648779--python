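"""Time-resolved free-energy landscapes on Markov state models.

Initial probability vectors localized in the starting conformations are
propagated with the Chapman–Kolmogorov relation ``p(kτ) = p(0) Tᵏ``. The
dynamical free energy of a state is the negative log of its probability at
a given time, ``F_i(t) = -ln p_i(t)`` (kT units); as ``t → ∞`` these
converge to the equilibrium free energies ``-ln π_i``.

To visualize the landscape, each state's probability is split uniformly
over a fixed number of randomly drawn representative conformations, whose
order-parameter values deposit the probability onto a 2-D grid; the binned
mass gives the projected surface ``F(op₁, op₂; t) = -ln(mass)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import EstimationError, FeatureError
from .geometry import FeatureMatrix
from .msm import DiscreteTrajectorySet, MarkovModel

__all__ = [
    "ProbabilityEvolution",
    "LandscapeGrid",
    "propagate",
    "dynamical_free_energy",
    "sample_state_representatives",
    "project_surface",
    "equilibrium_surface",
    "default_initial_distribution",
]


@dataclass
class ProbabilityEvolution:
    """State probability vectors at multiples of the model lag."""

    times_ns: np.ndarray
    distributions: np.ndarray  # (n_times, n_states)

    def __post_init__(self):
        self.distributions = np.asarray(self.distributions, float)
        self.times_ns = np.asarray(self.times_ns, float)
        if self.distributions.ndim != 2:
            raise EstimationError("distributions must be 2-D (n_times, n_states)")
        if self.times_ns.shape[0] != self.distributions.shape[0]:
            raise EstimationError("one time per distribution required")
        if np.any(self.distributions < -1e-15):
            raise EstimationError("distributions must be non-negative")
        sums = self.distributions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise EstimationError("each distribution must sum to 1 (±1e-12)")

    @property
    def n_times(self) -> int:
        return self.distributions.shape[0]

    @property
    def n_states(self) -> int:
        return self.distributions.shape[1]


@dataclass
class LandscapeGrid:
    """2-D projected free-energy surfaces, one slice per time.

    Unoccupied bins carry ``+inf`` free energy (explicitly infinite, never
    zero); ``exp(-F)`` over occupied bins sums to 1 per slice.
    """

    op_names: tuple[str, str]
    x_edges: np.ndarray
    y_edges: np.ndarray
    times_ns: np.ndarray
    free_energy: np.ndarray  # (n_times, nx, ny), kT
    occupied: np.ndarray  # bool, same shape

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def argmin_bin(self, time_index: int = -1, near: Sequence[float] | None = None, radius: float = np.inf) -> tuple[int, int]:
        """Grid indices of the lowest-F occupied bin, optionally restricted
        to bins whose centers lie within ``radius`` of ``near``."""
        f = self.free_energy[time_index].copy()
        f[~self.occupied[time_index]] = np.inf
        if near is not None:
            xc, yc = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
            d = np.hypot(xc - near[0], yc - near[1])
            f[d > radius] = np.inf
        if not np.isfinite(f).any():
            raise EstimationError("no occupied bins in the requested neighborhood")
        return tuple(int(v) for v in np.unravel_index(np.argmin(f), f.shape))

    def to_dataframe(self):
        import pandas as pd

        xc, yc = self.x_centers, self.y_centers
        rows = []
        for i, t in enumerate(self.times_ns):
            occ = self.occupied[i]
            xi, yi = np.nonzero(occ)
            rows.append(
                pd.DataFrame(
                    {
                        "time_ns": t,
                        f"{self.op_names[0]}_bin_center": xc[xi],
                        f"{self.op_names[1]}_bin_center": yc[yi],
                        "free_energy_kT": self.free_energy[i][xi, yi],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def plot(self, time_index: int = -1, ax=None, vmax_kT: float = 8.0):
        """Render one time slice as a free-energy heat map."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = np.where(self.occupied[time_index], self.free_energy[time_index], np.nan)
        mesh = ax.pcolormesh(
            self.x_edges, self.y_edges, f.T, vmin=0.0, vmax=vmax_kT, cmap="viridis"
        )
        ax.set_xlabel(f"{self.op_names[0]} (Å)")
        ax.set_ylabel(f"{self.op_names[1]} (Å)")
        ax.set_title(f"t = {self.times_ns[time_index]:g} ns")
        plt.colorbar(mesh, ax=ax, label="free energy (kT)")
        return ax


def default_initial_distribution(
    model_dtraj: DiscreteTrajectorySet, n_states: int
) -> np.ndarray:
    """Uniform distribution over the states holding each trajectory's first frame.

    This is the package's reading of "probability localized in
    near-starting configurations": mass is placed where the trajectories
    actually began.
    """
    first_states = []
    for _, labels in model_dtraj.segments():
        valid = labels[labels >= 0]
        if valid.size:
            first_states.append(int(valid[0]))
    if not first_states:
        raise EstimationError("no labeled starting frames found")
    p0 = np.zeros(n_states)
    for s in set(first_states):
        p0[s] = 1.0
    return p0 / p0.sum()


def propagate(model: MarkovModel, p0: np.ndarray, n_steps: int) -> ProbabilityEvolution:
    """Chapman–Kolmogorov propagation ``p(kτ) = p0 Tᵏ`` for k = 0..n_steps.

    Implemented as iterated vector–matrix products; each step renormalizes
    away the ~1e-16 rounding drift so normalization holds to 1e-12.
    """
    p0 = np.asarray(p0, float)
    if p0.shape != (model.n_states,):
        raise EstimationError(
            f"p0 has dimension {p0.shape}, model has {model.n_states} states"
        )
    if np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0, atol=1e-10):
        raise EstimationError("p0 must be a probability vector")
    if n_steps < 0:
        raise EstimationError("n_steps must be >= 0")
    dists = np.empty((n_steps + 1, model.n_states))
    dists[0] = p0 / p0.sum()
    t = model.transition_matrix
    for k in range(1, n_steps + 1):
        nxt = dists[k - 1] @ t
        dists[k] = nxt / nxt.sum()
    return ProbabilityEvolution(
        times_ns=np.arange(n_steps + 1) * model.lag_ns,
        distributions=dists,
    )


def dynamical_free_energy(evolution: ProbabilityEvolution) -> np.ndarray:
    """``F_i(t) = -ln p_i(t)`` in kT; zero-probability states get +inf."""
    with np.errstate(divide="ignore"):
        return np.where(
            evolution.distributions > 0.0,
            -np.log(np.where(evolution.distributions > 0, evolution.distributions, 1.0)),
            np.inf,
        )


def sample_state_representatives(
    model: MarkovModel, n_per_state: int = 10, seed: int = 0
) -> dict[int, np.ndarray]:
    """Draw ``n_per_state`` frames uniformly (with replacement) per state.

    Replacement is mandatory so states holding fewer than ``n_per_state``
    frames still honor the requested count. Deterministic given the seed.
    """
    if n_per_state < 1:
        raise EstimationError("n_per_state must be >= 1")
    rng = np.random.default_rng(seed)
    reps: dict[int, np.ndarray] = {}
    for s in range(model.n_states):
        frames = model.state_representatives.get(s)
        if frames is None or len(frames) == 0:
            raise EstimationError(f"state {s} has no assigned frames")
        reps[s] = rng.choice(frames, size=n_per_state, replace=True)
    return reps


def _deposit(
    distributions: np.ndarray,
    representatives: Mapping[int, np.ndarray],
    xvals: np.ndarray,
    yvals: np.ndarray,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
) -> np.ndarray:
    """Bin per-state probability fragments; returns (n_times, nx, ny) mass."""
    n_states = distributions.shape[1]
    frag_state = []
    frag_x = []
    frag_y = []
    for s in range(n_states):
        frames = np.asarray(representatives[s], int)
        frag_state.append(np.full(frames.size, s))
        frag_x.append(xvals[frames])
        frag_y.append(yvals[frames])
    frag_state = np.concatenate(frag_state)
    frag_x = np.concatenate(frag_x)
    frag_y = np.concatenate(frag_y)
    ix = np.clip(np.searchsorted(x_edges, frag_x, side="right") - 1, 0, len(x_edges) - 2)
    iy = np.clip(np.searchsorted(y_edges, frag_y, side="right") - 1, 0, len(y_edges) - 2)
    n_per = {s: np.sum(frag_state == s) for s in range(n_states)}
    weights_per_state = np.array([1.0 / n_per[s] for s in frag_state])
    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    mass = np.zeros((distributions.shape[0], nx, ny))
    for i in range(distributions.shape[0]):
        w = distributions[i, frag_state] * weights_per_state
        np.add.at(mass[i], (ix, iy), w)
    return mass


def _auto_edges(vals: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(vals.min()), float(vals.max())
    pad = 0.05 * (hi - lo) if hi > lo else 0.5
    return np.linspace(lo - pad, hi + pad, bins + 1)


def project_surface(
    evolution: ProbabilityEvolution,
    representatives: Mapping[int, np.ndarray],
    features: FeatureMatrix,
    op_pair: tuple[str, str],
    bins: int | tuple[np.ndarray, np.ndarray] = 50,
    time_indices: Sequence[int] | None = None,
) -> LandscapeGrid:
    """Project probability evolutions onto an order-parameter pair.

    Each state's probability is split uniformly over its representative
    frames and deposited in the grid bin holding that frame's
    (op₁, op₂) values; ``F = -ln(binned mass)`` per time slice (each slice
    renormalizes on its own occupied bins).
    """
    if op_pair[0] == op_pair[1]:
        raise FeatureError("op_pair must name two distinct order parameters")
    xvals = features.column(op_pair[0])
    yvals = features.column(op_pair[1])
    for s, frames in representatives.items():
        fr = np.asarray(frames, int)
        if fr.size and (fr.min() < 0 or fr.max() >= features.n_frames):
            raise FeatureError(f"state {s}: representative frame outside the feature matrix")
    if isinstance(bins, int):
        x_edges = _auto_edges(xvals, bins)
        y_edges = _auto_edges(yvals, bins)
    else:
        x_edges, y_edges = (np.asarray(b, float) for b in bins)
    if time_indices is None:
        time_indices = range(evolution.n_times)
    time_indices = list(time_indices)
    dists = evolution.distributions[time_indices]
    mass = _deposit(dists, representatives, xvals, yvals, x_edges, y_edges)
    mass /= mass.sum(axis=(1, 2), keepdims=True)
    occupied = mass > 0.0
    with np.errstate(divide="ignore"):
        f = np.where(occupied, -np.log(np.where(occupied, mass, 1.0)), np.inf)
    return LandscapeGrid(
        op_names=(op_pair[0], op_pair[1]),
        x_edges=x_edges,
        y_edges=y_edges,
        times_ns=evolution.times_ns[time_indices],
        free_energy=f,
        occupied=occupied,
    )


def equilibrium_surface(
    model: MarkovModel,
    representatives: Mapping[int, np.ndarray],
    features: FeatureMatrix,
    op_pair: tuple[str, str],
    bins: int | tuple[np.ndarray, np.ndarray] = 50,
) -> LandscapeGrid:
    """Project the stationary distribution (the long-time limit surface)."""
    evo = ProbabilityEvolution(
        times_ns=np.array([np.inf]), distributions=model.stationary[None, :]
    )
    return project_surface(evo, representatives, features, op_pair, bins=bins)
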