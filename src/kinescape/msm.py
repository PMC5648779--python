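"""Markov state model estimation.

Turns featurized (or raw-coordinate) trajectories into a reversible Markov
state model through the classic pipeline:

1. fixed-radius k-centers clustering (Gonzalez farthest-point with a radius
   stopping rule) into discrete conformational states,
2. lag-time transition counting within each trajectory (sliding window by
   default; strided optional),
3. trimming to the largest strongly connected component so the network is
   ergodic,
4. count symmetrization ``C' = (C + Cᵀ)/2`` to enforce detailed balance,
   followed by row normalization into an N×N transition probability matrix.

For symmetrized counts the stationary distribution is available in closed
form, ``π_i = Σ_k C'_ik / Σ_jk C'_jk``, and detailed balance
``π_i T_ij = π_j T_ji`` holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import EstimationError
from .geometry import FeatureMatrix, MolecularFrameSet, Selection, kabsch_rmsd

__all__ = [
    "DiscreteTrajectorySet",
    "CountMatrix",
    "MarkovModel",
    "kcenters_cluster",
    "count_transitions",
    "trim_ergodic",
    "estimate_model",
    "build_msm",
]


@dataclass
class DiscreteTrajectorySet:
    """Per-frame state labels with trajectory boundaries preserved."""

    state_labels: np.ndarray
    trajectory_ids: np.ndarray
    n_states: int
    frame_interval_ns: float

    def __post_init__(self):
        self.state_labels = np.asarray(self.state_labels, dtype=int)
        self.trajectory_ids = np.asarray(self.trajectory_ids, dtype=int)
        if self.state_labels.shape != self.trajectory_ids.shape:
            raise EstimationError("state_labels and trajectory_ids must align")
        if self.state_labels.size and (
            self.state_labels.min() < -1 or self.state_labels.max() >= self.n_states
        ):
            raise EstimationError("state labels out of range [0, n_states) (-1 = trimmed)")

    @property
    def n_frames(self) -> int:
        return self.state_labels.size

    def segments(self):
        """Yield (trajectory_id, label array) per contiguous trajectory."""
        ids = self.trajectory_ids
        if ids.size == 0:
            return
        breaks = np.flatnonzero(np.diff(ids) != 0) + 1
        for seg in np.split(np.arange(ids.size), breaks):
            yield int(ids[seg[0]]), self.state_labels[seg]

    def frames_of_state(self, state: int) -> np.ndarray:
        return np.flatnonzero(self.state_labels == state)

    def relabel(self, mapping: np.ndarray, n_states: int) -> "DiscreteTrajectorySet":
        """Apply an old→new state map (-1 = dropped) to every frame."""
        new_labels = np.where(self.state_labels >= 0, mapping[self.state_labels], -1)
        return DiscreteTrajectorySet(
            state_labels=new_labels,
            trajectory_ids=self.trajectory_ids.copy(),
            n_states=n_states,
            frame_interval_ns=self.frame_interval_ns,
        )

    def to_dataframe(self):
        import pandas as pd

        frame_index = np.empty(self.n_frames, dtype=int)
        for tid in np.unique(self.trajectory_ids):
            m = self.trajectory_ids == tid
            frame_index[m] = np.arange(m.sum())
        return pd.DataFrame(
            {
                "trajectory_id": self.trajectory_ids,
                "frame_index": frame_index,
                "state": self.state_labels,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class CountMatrix:
    """Lag-time transition counts (possibly symmetrized)."""

    counts: np.ndarray
    lag_ns: float
    symmetrized: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise EstimationError("counts must be square")
        if np.any(self.counts < 0):
            raise EstimationError("counts must be non-negative")
        if self.symmetrized and not np.array_equal(self.counts, self.counts.T):
            raise EstimationError("symmetrized flag set but counts != counts.T")

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


@dataclass
class MarkovModel:
    """Row-stochastic transition matrix with stationary distribution.

    ``state_representatives`` maps each state to the indices of the frames
    assigned to it (in the frame universe the clustering ran on), so
    downstream analyses can draw representative conformations per state.
    """

    transition_matrix: np.ndarray
    lag_ns: float
    stationary: np.ndarray
    state_representatives: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.transition_matrix, dtype=float)
        self.transition_matrix = t
        self.stationary = np.asarray(self.stationary, dtype=float)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise EstimationError("transition matrix must be square")
        if np.any(t < 0):
            raise EstimationError("transition matrix has negative entries")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise EstimationError("transition matrix rows must sum to 1 (±1e-12)")
        if not np.isclose(self.stationary.sum(), 1.0, atol=1e-10):
            raise EstimationError("stationary vector must sum to 1")
        if not np.allclose(self.stationary @ t, self.stationary, atol=1e-10):
            raise EstimationError("stationary vector is not invariant under T")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        """Real eigenvalues of T, descending (T is detailed-balanced).

        Computed through the symmetrized similar matrix
        ``D_π^{1/2} T D_π^{-1/2}``, which is symmetric under detailed
        balance, so realness holds by construction rather than by taking
        magnitudes.
        """
        pi = self.stationary
        if np.any(pi <= 0):
            raise EstimationError("stationary vector must be strictly positive post-trim")
        sq = np.sqrt(pi)
        m = (sq[:, None] * self.transition_matrix) / sq[None, :]
        sym_err = np.max(np.abs(m - m.T))
        if sym_err > 1e-8:
            raise EstimationError(
                f"transition matrix violates detailed balance (asymmetry {sym_err:.2e}); "
                "eigenvalues would be complex"
            )
        evals = np.linalg.eigvalsh((m + m.T) / 2.0)[::-1]
        return evals[:k] if k is not None else evals


# ---------------------------------------------------------------------------


def _kcenters_generic(
    n_frames: int,
    dist_to: Callable[[int], np.ndarray],
    radius: float,
    max_states: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gonzalez farthest-point with radius stopping.

    ``dist_to(i)`` returns the distance from frame ``i`` to every frame.
    Seeds with frame 0; repeatedly promotes the frame farthest from its
    nearest center until the covering radius drops to ``radius``.
    """
    centers = [0]
    d_near = dist_to(0)
    assign = np.zeros(n_frames, dtype=int)
    while True:
        far = int(np.argmax(d_near))
        if d_near[far] <= radius:
            break
        if max_states is not None and len(centers) >= max_states:
            break
        centers.append(far)
        d_new = dist_to(far)
        closer = d_new < d_near
        assign[closer] = len(centers) - 1
        d_near = np.where(closer, d_new, d_near)
    return assign, np.asarray(centers, dtype=int)


def kcenters_cluster(
    data: FeatureMatrix | MolecularFrameSet,
    radius: float,
    metric: str = "euclidean_feature",
    selection: Selection | None = None,
    max_states: int | None = None,
) -> tuple[DiscreteTrajectorySet, np.ndarray]:
    """Fixed-radius k-centers clustering of frames into discrete states.

    ``metric='euclidean_feature'`` clusters rows of a
    :class:`FeatureMatrix`; ``metric='backbone_rmsd'`` clusters a
    :class:`MolecularFrameSet` under minimal pairwise RMSD on the given
    selection (default: backbone atoms). Deterministic given frame order;
    the covering radius of the returned states is guaranteed ≤ ``radius``.

    Returns (assignments, center frame indices).
    """
    if radius <= 0:
        raise EstimationError(f"cluster radius must be positive, got {radius}")
    if metric == "euclidean_feature":
        if not isinstance(data, FeatureMatrix):
            raise EstimationError("euclidean_feature metric requires a FeatureMatrix")
        x = data.values
        if x.shape[0] < 1:
            raise EstimationError("need at least one frame to cluster")

        def dist_to(i: int) -> np.ndarray:
            return np.linalg.norm(x - x[i], axis=1)

        n = x.shape[0]
    elif metric == "backbone_rmsd":
        if not isinstance(data, MolecularFrameSet):
            raise EstimationError("backbone_rmsd metric requires a MolecularFrameSet")
        sel = selection if selection is not None else Selection(part="backbone")
        idx = sel.resolve(data.atoms)
        coords = data.frames[:, idx, :]
        n = coords.shape[0]

        def dist_to(i: int) -> np.ndarray:
            ref = coords[i]
            return np.array([kabsch_rmsd(ref, coords[t]) for t in range(n)])

    else:
        raise EstimationError(f"unknown clustering metric {metric!r}")
    assign, centers = _kcenters_generic(n, dist_to, radius, max_states)
    dtraj = DiscreteTrajectorySet(
        state_labels=assign,
        trajectory_ids=data.trajectory_ids.copy(),
        n_states=len(centers),
        frame_interval_ns=data.frame_interval_ns,
    )
    return dtraj, centers


def count_transitions(
    traj: DiscreteTrajectorySet, lag_steps: int, mode: str = "sliding"
) -> CountMatrix:
    """Count lag-time transitions per trajectory.

    ``sliding`` (default): every frame t with a partner t+lag in the same
    trajectory contributes one (s_t, s_{t+lag}) count. ``strided``: windows
    advance by the lag, so each frame is used once. Counting never crosses
    trajectory boundaries; frames labeled -1 (trimmed) never contribute.
    """
    if lag_steps < 1:
        raise EstimationError(f"lag_steps must be >= 1, got {lag_steps}")
    if mode not in ("sliding", "strided"):
        raise EstimationError(f"unknown counting mode {mode!r}")
    n = traj.n_states
    counts = np.zeros((n, n))
    any_window = False
    for _, labels in traj.segments():
        if labels.size <= lag_steps:
            continue
        a = labels[:-lag_steps]
        b = labels[lag_steps:]
        if mode == "strided":
            a = labels[:-lag_steps:lag_steps]
            b = labels[lag_steps::lag_steps]
        valid = (a >= 0) & (b >= 0)
        if not np.any(valid):
            continue
        any_window = True
        np.add.at(counts, (a[valid], b[valid]), 1.0)
    if not any_window:
        raise EstimationError(
            f"no transitions countable: all trajectory segments are shorter than lag {lag_steps}"
        )
    return CountMatrix(counts=counts, lag_ns=lag_steps * traj.frame_interval_ns)


def trim_ergodic(counts: CountMatrix) -> tuple[CountMatrix, np.ndarray]:
    """Restrict counts to the largest strongly connected component.

    Components are compared by size; ties break by larger total internal
    counts, then by lowest original state index. Returns the trimmed
    counts and the old→new index map (-1 marks removed states).
    """
    c = counts.counts
    n = counts.n_states
    if n == 0 or not np.any(c > 0):
        raise EstimationError("empty transition graph: no positive counts")
    graph = sp.csr_matrix((c > 0).astype(np.int8))
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    best = None
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        size = members.size
        total = float(c[np.ix_(members, members)].sum())
        key = (size, total, -int(members.min()))
        if best is None or key > best[0]:
            best = (key, members)
    members = best[1]
    mapping = np.full(n, -1, dtype=int)
    mapping[members] = np.arange(members.size)
    trimmed = CountMatrix(
        counts=c[np.ix_(members, members)],
        lag_ns=counts.lag_ns,
        symmetrized=counts.symmetrized,
    )
    return trimmed, mapping


def estimate_model(
    counts: CountMatrix,
    representatives_source: DiscreteTrajectorySet | None = None,
) -> MarkovModel:
    """Symmetrize counts and normalize into a reversible Markov model.

    ``C' = (C + Cᵀ)/2``; ``T_ij = C'_ij / Σ_k C'_ik``;
    ``π_i = Σ_k C'_ik / Σ C'``. If ``representatives_source`` is given its
    labels must already live in the trimmed state space (see
    :meth:`DiscreteTrajectorySet.relabel`).
    """
    c_sym = (counts.counts + counts.counts.T) / 2.0
    row = c_sym.sum(axis=1)
    if np.any(row == 0):
        dead = np.flatnonzero(row == 0)
        raise EstimationError(
            f"states {dead.tolist()} have no counts after symmetrization; trim first"
        )
    t = c_sym / row[:, None]
    pi = row / row.sum()
    reps: dict[int, np.ndarray] = {}
    if representatives_source is not None:
        if representatives_source.n_states != counts.n_states:
            raise EstimationError(
                "representatives_source state space does not match counts; "
                "apply the trim index map first"
            )
        for s in range(counts.n_states):
            reps[s] = representatives_source.frames_of_state(s)
    return MarkovModel(
        transition_matrix=t,
        lag_ns=counts.lag_ns,
        stationary=pi,
        state_representatives=reps,
    )


def build_msm(
    dtraj: DiscreteTrajectorySet, lag_steps: int, mode: str = "sliding"
) -> tuple[MarkovModel, np.ndarray, DiscreteTrajectorySet]:
    """Count → trim → estimate in one call.

    Returns (model, old→new index map, relabeled trajectories).
    """
    counts = count_transitions(dtraj, lag_steps, mode=mode)
    trimmed, mapping = trim_ergodic(counts)
    relabeled = dtraj.relabel(mapping, trimmed.n_states)
    model = estimate_model(trimmed, relabeled)
    return model, mapping, relabeled
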