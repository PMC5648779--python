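"""Synthetic two-stage conformational landscape generator.

The kinetic analysis in this package assumes data with a particular
statistical structure: several independent, finite molecular-dynamics
trajectories diffusing on a free-energy landscape with three metastable
basins — an initial basin A, an on-pathway intermediate I reached quickly
(stage I), and a final basin B reached roughly five times more slowly
(stage II). This module generates exactly that structure so every
downstream stage (featurization, clustering, Markov-model estimation,
validation, landscape projection, dissipation analysis) can be tested
end-to-end against known ground truth:

* :func:`simulate` — overdamped Langevin (Euler–Maruyama) dynamics of a 2-D
  latent coordinate on a three-well potential,
* :func:`embed_pseudo_atoms` — an exact geometric embedding of the latent
  coordinates into a small pseudo-protein, so the geometric featurizer can
  recover them as residue-pair distances,
* :func:`reference_kinetics` — an independent fine-grid discretization of
  the same potential whose eigen-decomposition provides reference
  relaxation timescales, stationary distribution and mean first-passage
  times.

The latent coordinates are interpreted in Å: coordinate 1 plays the role of
a binding-cleft opening distance, coordinate 2 of a side-chain pair
separation, so the embedded features live on the same scale as real
order-parameter axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh, spsolve

from .errors import EstimationError, NumericalError, TopologyError
from .geometry import (
    AtomRecord,
    DistanceFeature,
    MolecularFrameSet,
    Selection,
    VDW_RADII,
)

__all__ = [
    "PotentialSpec",
    "LangevinParams",
    "SimulatedEnsemble",
    "ReferenceKinetics",
    "default_potential",
    "default_params",
    "simulate",
    "embed_pseudo_atoms",
    "pseudo_atom_features",
    "reference_kinetics",
]


@dataclass(frozen=True)
class PotentialSpec:
    """Three-well 2-D potential: inverted Gaussians plus quartic confinement.

    ``V(r) = -Σ_k d_k exp(-|r-c_k|²/(2 w_k²)) + s (|r-c₀|/L)⁴``

    with well centers ``c_k`` (basin A = initial, I = intermediate,
    B = final), depths ``d_k`` (kT), widths ``w_k`` (Å), and a confining
    quartic centered at ``c₀`` (the centroid of the wells by default) that
    keeps the potential bounded below and diverging at large radius.
    Barrier heights are a consequence of the well layout; they are reported
    by :meth:`barrier_heights` via line scans between adjacent wells.
    """

    well_centers: tuple[tuple[float, float], ...] = ((8.0, 11.0), (15.0, 11.0), (15.0, 3.2))
    well_depths: tuple[float, ...] = (6.8, 7.1, 9.0)
    well_widths: tuple[float, ...] = (2.0, 2.0, 2.0)
    confinement_strength: float = 1.0
    confinement_scale: float = 7.0
    confinement_center: tuple[float, float] | None = None

    def __post_init__(self):
        if not (len(self.well_centers) == len(self.well_depths) == len(self.well_widths) == 3):
            raise TopologyError("exactly three wells (A, I, B) are required")
        if any(d <= 0 for d in self.well_depths) or any(w <= 0 for w in self.well_widths):
            raise TopologyError("well depths and widths must be positive")

    @property
    def centers(self) -> np.ndarray:
        return np.asarray(self.well_centers, float)

    @property
    def _conf_center(self) -> np.ndarray:
        if self.confinement_center is not None:
            return np.asarray(self.confinement_center, float)
        return self.centers.mean(axis=0)

    def potential(self, xy: np.ndarray) -> np.ndarray:
        """Potential energy (kT) at points ``xy`` of shape (..., 2)."""
        xy = np.asarray(xy, float)
        diff = xy[..., None, :] - self.centers
        r2 = np.sum(diff * diff, axis=-1)
        w2 = np.asarray(self.well_widths) ** 2
        wells = -np.sum(np.asarray(self.well_depths) * np.exp(-r2 / (2 * w2)), axis=-1)
        dc = xy - self._conf_center
        conf = self.confinement_strength * (np.sum(dc * dc, axis=-1) / self.confinement_scale**2) ** 2
        return wells + conf

    def gradient(self, xy: np.ndarray) -> np.ndarray:
        """∇V at points ``xy`` of shape (..., 2), kT/Å."""
        xy = np.asarray(xy, float)
        diff = xy[..., None, :] - self.centers  # (..., 3, 2)
        r2 = np.sum(diff * diff, axis=-1)  # (..., 3)
        w2 = np.asarray(self.well_widths) ** 2
        amp = (np.asarray(self.well_depths) / w2) * np.exp(-r2 / (2 * w2))
        grad = np.sum(amp[..., None] * diff, axis=-2)
        dc = xy - self._conf_center
        r2c = np.sum(dc * dc, axis=-1, keepdims=True)
        grad += self.confinement_strength * 4.0 * r2c / self.confinement_scale**4 * dc
        return grad

    def well_minima(self) -> np.ndarray:
        """Locations of the three local minima (descent-refined centers)."""
        from scipy.optimize import minimize

        out = []
        for c in self.centers:
            res = minimize(lambda p: float(self.potential(p)), c, jac=lambda p: self.gradient(p))
            out.append(res.x)
        return np.asarray(out)

    def barrier_heights(self, n_scan: int = 400) -> tuple[float, float]:
        """(A→I, I→B) barrier heights (kT) from straight-line saddle scans.

        The default well layout puts A→I along one axis and I→B along the
        other, so the straight segment between adjacent minima passes close
        to the true saddle.
        """
        minima = self.well_minima()
        heights = []
        for a, b in ((0, 1), (1, 2)):
            lam = np.linspace(0.0, 1.0, n_scan)[:, None]
            path = minima[a] + lam * (minima[b] - minima[a])
            v = self.potential(path)
            heights.append(float(v.max() - self.potential(minima[a])))
        return heights[0], heights[1]


@dataclass(frozen=True)
class LangevinParams:
    """Integration parameters for the overdamped Langevin simulator.

    ``kT`` sets the thermal energy (dimensionless, energies in kT units),
    ``friction`` the drag γ (1/time-unit; diffusion D = kT/γ in Å²/unit),
    ``dt`` the Euler–Maruyama step (time units). ``time_unit_ns`` is the
    nominal mapping between internal time units and nanoseconds, chosen so
    a default trajectory (n_steps·dt = 10⁴ units) reads as 1 μs.
    ``save_stride`` thins the saved frames. The seed fully determines all
    trajectories: one independent RNG stream per trajectory, spawned from
    the master seed with numpy's SeedSequence, so increasing the trajectory
    count never perturbs earlier trajectories.
    """

    kT: float = 1.0
    friction: float = 1.0
    dt: float = 0.01
    n_steps: int = 1_000_000
    n_trajectories: int = 6
    seed: int = 2024
    save_stride: int = 100
    time_unit_ns: float = 0.5

    def __post_init__(self):
        if self.kT < 0 or self.friction <= 0 or self.dt <= 0:
            raise NumericalError("kT must be >= 0, friction and dt positive")
        if self.n_steps < 1 or self.n_trajectories < 1 or self.save_stride < 1:
            raise NumericalError("n_steps, n_trajectories and save_stride must be >= 1")

    @property
    def frame_interval_ns(self) -> float:
        return self.dt * self.save_stride * self.time_unit_ns

    def step_noise_std(self) -> float:
        return float(np.sqrt(2.0 * self.kT * self.dt / self.friction))


@dataclass
class SimulatedEnsemble:
    """Latent 2-D trajectories from :func:`simulate`."""

    latent: np.ndarray  # (n_saved_frames_total, 2)
    trajectory_ids: np.ndarray
    frame_interval_ns: float
    potential: PotentialSpec
    params: LangevinParams

    @property
    def n_frames(self) -> int:
        return self.latent.shape[0]

    def to_dataframe(self):
        import pandas as pd

        step = np.empty(self.n_frames, dtype=int)
        for tid in np.unique(self.trajectory_ids):
            m = self.trajectory_ids == tid
            step[m] = np.arange(m.sum())
        return pd.DataFrame(
            {
                "trajectory_id": self.trajectory_ids,
                "step": step,
                "x": self.latent[:, 0],
                "y": self.latent[:, 1],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def default_potential() -> PotentialSpec:
    """The default two-stage landscape (see module docstring)."""
    return PotentialSpec()


def default_params(seed: int = 2024) -> LangevinParams:
    return LangevinParams(seed=seed)


def _check_dt(potential: PotentialSpec, params: LangevinParams) -> None:
    step_std = params.step_noise_std()
    min_width = min(potential.well_widths)
    if params.kT > 0 and step_std > 0.25 * min_width:
        good_dt = (0.25 * min_width) ** 2 * params.friction / (2.0 * params.kT)
        raise NumericalError(
            f"dt={params.dt} too large: per-step displacement std {step_std:.3f} Å "
            f"exceeds a quarter of the narrowest well width {min_width} Å; "
            f"use dt <= {good_dt:.2e}"
        )


def simulate(
    potential: PotentialSpec,
    params: LangevinParams,
    start: Sequence[float] | None = None,
) -> SimulatedEnsemble:
    """Integrate overdamped Langevin dynamics on the landscape.

    ``dx = -∇V/γ dt + sqrt(2 kT dt/γ) ξ`` (Euler–Maruyama), all
    trajectories starting at basin A's center (or ``start``). The latent
    coordinates represent interatomic distances, so both are reflected at
    zero (a zero-flux boundary, which leaves the Boltzmann distribution on
    the positive quadrant unchanged). Bit-for-bit reproducible given
    (seed, dt, n_steps, n_trajectories, save_stride).
    """
    _check_dt(potential, params)
    n_traj = params.n_trajectories
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(params.seed).spawn(n_traj)]
    start = potential.centers[0] if start is None else np.asarray(start, float)
    pos = np.tile(start, (n_traj, 1))
    drift = params.dt / params.friction
    noise_scale = params.step_noise_std()
    n_saved = params.n_steps // params.save_stride + 1
    saved = np.empty((n_traj, n_saved, 2))
    saved[:, 0] = pos
    chunk = 20_000
    step = 0
    save_ptr = 1
    while step < params.n_steps:
        this = min(chunk, params.n_steps - step)
        if params.kT > 0:
            noise = np.stack([g.standard_normal((this, 2)) for g in streams], axis=0)
        else:
            noise = np.zeros((n_traj, this, 2))
        for t in range(this):
            pos -= drift * potential.gradient(pos)
            if noise_scale:
                pos += noise_scale * noise[:, t]
            np.abs(pos, out=pos)  # reflecting boundary: distances stay >= 0
            step += 1
            if step % params.save_stride == 0:
                saved[:, save_ptr] = pos
                save_ptr += 1
    latent = saved.reshape(n_traj * n_saved, 2)
    tids = np.repeat(np.arange(n_traj), n_saved)
    return SimulatedEnsemble(
        latent=latent,
        trajectory_ids=tids,
        frame_interval_ns=params.frame_interval_ns,
        potential=potential,
        params=params,
    )


# ---------------------------------------------------------------------------
# pseudo-atom embedding

_C = "C"
_N = "N"
_O = "O"

# fixed scaffold: (residue_name, residue_number, atom_name, element, base xyz)
# Moving parts are filled per frame:
#   GLY 87 translates along +x so that d(F32:CA, G87:CA) = latent x exactly;
#   TRP 54 translates along +y so that the Y48/W54 side-chain heavy-atom
#   centroid separation equals latent y exactly.
_SCAFFOLD: list[tuple[str, int, str, str, tuple[float, float, float]]] = [
    # PHE 32 — anchor; CA at the origin
    ("PHE", 32, "N", _N, (-1.3, -0.6, 0.0)),
    ("PHE", 32, "CA", _C, (0.0, 0.0, 0.0)),
    ("PHE", 32, "C", _C, (1.1, -0.8, 0.2)),
    ("PHE", 32, "O", _O, (1.9, -0.4, 1.0)),
    ("PHE", 32, "CB", _C, (0.2, 1.3, 0.9)),
    ("PHE", 32, "CG", _C, (0.4, 2.5, 1.6)),
    # GLU 33 — fixed bystander
    ("GLU", 33, "N", _N, (1.5, -2.0, -0.3)),
    ("GLU", 33, "CA", _C, (2.6, -2.8, -0.6)),
    ("GLU", 33, "C", _C, (3.8, -2.2, -1.2)),
    ("GLU", 33, "O", _O, (4.8, -2.9, -1.4)),
    ("GLU", 33, "CB", _C, (2.2, -4.0, -1.4)),
    ("GLU", 33, "CD", _C, (3.1, -5.2, -1.6)),
    # ARG 40 — fixed bystander
    ("ARG", 40, "N", _N, (-2.5, -3.0, 0.5)),
    ("ARG", 40, "CA", _C, (-3.6, -3.7, 0.9)),
    ("ARG", 40, "C", _C, (-4.8, -3.0, 1.3)),
    ("ARG", 40, "O", _O, (-5.9, -3.6, 1.2)),
    ("ARG", 40, "CB", _C, (-3.3, -4.9, 1.8)),
    ("ARG", 40, "CZ", _C, (-3.9, -6.2, 1.9)),
    # TYR 48 — side chain (CB, OH) centroid fixed at (0, 0, 6)
    ("TYR", 48, "N", _N, (-1.6, -1.2, 5.6)),
    ("TYR", 48, "CA", _C, (-0.7, -2.0, 6.0)),
    ("TYR", 48, "C", _C, (0.5, -2.6, 6.4)),
    ("TYR", 48, "O", _O, (0.6, -3.8, 6.5)),
    ("TYR", 48, "CB", _C, (0.0, -0.8, 6.0)),
    ("TYR", 48, "OH", _O, (0.0, 0.8, 6.0)),
    # TRP 54 — translated by latent y along +y; side-chain centroid base (0, 0, 6)
    ("TRP", 54, "N", _N, (-1.7, 1.1, 5.7)),
    ("TRP", 54, "CA", _C, (-0.8, 2.0, 6.1)),
    ("TRP", 54, "C", _C, (0.4, 2.7, 6.3)),
    ("TRP", 54, "O", _O, (0.5, 3.9, 6.2)),
    ("TRP", 54, "CB", _C, (-0.9, -0.8, 6.0)),
    ("TRP", 54, "CG", _C, (0.9, 0.8, 6.0)),
    # GLY 87 — translated by latent x along +x; CA base at the origin
    ("GLY", 87, "N", _N, (-1.1, 0.9, -0.4)),
    ("GLY", 87, "CA", _C, (0.0, 0.0, 0.0)),
    ("GLY", 87, "C", _C, (1.2, 0.7, -0.5)),
    ("GLY", 87, "O", _O, (2.3, 0.2, -0.7)),
]


def _template_atoms() -> list[AtomRecord]:
    return [
        AtomRecord(
            atom_name=name,
            residue_name=res,
            residue_number=num,
            element=elem,
            vdw_radius=VDW_RADII[elem],
        )
        for res, num, name, elem, _ in _SCAFFOLD
    ]


def embed_pseudo_atoms(
    latent: np.ndarray,
    trajectory_ids: np.ndarray | None = None,
    frame_interval_ns: float = 1.0,
) -> MolecularFrameSet:
    """Embed latent 2-D paths into a pseudo-protein frame set.

    Exact by construction: the F32:CA–G87:CA distance equals latent
    coordinate 1 and the Y48–W54 side-chain centroid separation equals
    latent coordinate 2 in every frame, so :func:`kinescape.geometry.featurize`
    inverts the embedding to machine precision.
    """
    if isinstance(latent, SimulatedEnsemble):
        ens = latent
        latent, trajectory_ids = ens.latent, ens.trajectory_ids
        frame_interval_ns = ens.frame_interval_ns
    latent = np.asarray(latent, float)
    if latent.ndim != 2 or latent.shape[1] != 2:
        raise TopologyError("latent paths must have shape (n_frames, 2)")
    if np.any(latent < 0):
        bad = int(np.argmax(np.any(latent < 0, axis=1)))
        raise TopologyError(
            f"latent frame {bad} has negative coordinates {latent[bad]}; "
            "the pseudo-atom embedding is defined for non-negative distances only"
        )
    n_frames = latent.shape[0]
    if trajectory_ids is None:
        trajectory_ids = np.zeros(n_frames, dtype=int)
    base = np.array([xyz for *_, xyz in _SCAFFOLD])
    frames = np.broadcast_to(base, (n_frames,) + base.shape).copy()
    res_nums = np.array([num for _, num, *_ in _SCAFFOLD])
    frames[:, res_nums == 54, 1] += latent[:, 1][:, None]
    frames[:, res_nums == 87, 0] += latent[:, 0][:, None]
    return MolecularFrameSet(
        atoms=_template_atoms(),
        frames=frames,
        frame_interval_ns=frame_interval_ns,
        trajectory_ids=np.asarray(trajectory_ids, int),
    )


def pseudo_atom_features() -> list[DistanceFeature]:
    """Order parameters that exactly invert the pseudo-atom embedding."""
    return [
        DistanceFeature(
            name="cleft_opening",
            group_a=Selection(residue_number=32, atom_names=("CA",)),
            group_b=Selection(residue_number=87, atom_names=("CA",)),
            mode="single_atom",
        ),
        DistanceFeature(
            name="sidechain_separation",
            group_a=Selection(residue_number=48, part="sidechain"),
            group_b=Selection(residue_number=54, part="sidechain"),
            mode="centroid",
        ),
    ]


# ---------------------------------------------------------------------------
# reference kinetics oracle


@dataclass
class ReferenceKinetics:
    """Exact kinetics of the grid-discretized landscape.

    Nearest-neighbour hopping generator with symmetric-split rates
    ``k_ij = (D/h²) e^{-(V_j - V_i)/(2 kT)}`` on a regular grid. Like the
    classic Metropolis rule this satisfies detailed balance with respect to
    the grid Boltzmann weights exactly (``w_i k_ij = (D/h²)√(w_i w_j)`` is
    symmetric), but its drift error is O(h²) rather than O(h), so the
    discretized kinetics track the continuum Langevin dynamics far more
    faithfully at feasible grid resolutions. The stationary vector equals
    the normalized Boltzmann weights of the grid exactly. Relaxation
    timescales come from the eigenvalues of the (symmetrized) generator.
    """

    generator: sp.csr_matrix
    stationary: np.ndarray
    timescales: np.ndarray  # time units, slowest first
    x_centers: np.ndarray
    y_centers: np.ndarray
    shape: tuple[int, int]
    potential: PotentialSpec
    kT: float
    diffusion: float

    def cell_of(self, point: Sequence[float]) -> int:
        ix = int(np.argmin(np.abs(self.x_centers - point[0])))
        iy = int(np.argmin(np.abs(self.y_centers - point[1])))
        return ix * self.shape[1] + iy

    def cell_centers(self) -> np.ndarray:
        xx, yy = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()])

    def basin_cells(self, center: Sequence[float], radius: float) -> np.ndarray:
        pts = self.cell_centers()
        d = np.linalg.norm(pts - np.asarray(center, float), axis=1)
        return np.flatnonzero(d <= radius)

    def mfpt(self, start: Sequence[float], target_center: Sequence[float], target_radius: float = 1.5) -> float:
        """Mean first-passage time (time units) from a point to a basin."""
        targets = self.basin_cells(target_center, target_radius)
        if targets.size == 0:
            raise EstimationError("target basin contains no grid cells")
        n = self.generator.shape[0]
        keep = np.setdiff1d(np.arange(n), targets)
        q = self.generator[np.ix_(keep, keep)].tocsc()
        m = spsolve(q, -np.ones(keep.size))
        full = np.zeros(n)
        full[keep] = m
        return float(full[self.cell_of(start)])


def reference_kinetics(
    potential: PotentialSpec,
    shape: tuple[int, int] = (80, 80),
    extents: tuple[tuple[float, float], tuple[float, float]] | None = None,
    kT: float = 1.0,
    friction: float = 1.0,
    n_timescales: int = 5,
) -> ReferenceKinetics:
    """Build the continuous-time reference generator on a regular grid."""
    if extents is None:
        c = potential.centers
        pad = 4.0
        # the missing-flux edge at 0 matches the simulator's reflecting wall
        extents = (
            (max(c[:, 0].min() - pad, 0.0), c[:, 0].max() + pad),
            (max(c[:, 1].min() - pad, 0.0), c[:, 1].max() + pad),
        )
    nx, ny = shape
    (x0, x1), (y0, y1) = extents
    hx = (x1 - x0) / nx
    hy = (y1 - y0) / ny
    if hx > min(potential.well_widths) or hy > min(potential.well_widths):
        raise EstimationError(
            f"grid too coarse: cell size ({hx:.2f}, {hy:.2f}) Å exceeds the "
            f"narrowest well width {min(potential.well_widths)} Å; "
            "need at least ~3 cells per well"
        )
    x_centers = x0 + (np.arange(nx) + 0.5) * hx
    y_centers = y0 + (np.arange(ny) + 0.5) * hy
    xx, yy = np.meshgrid(x_centers, y_centers, indexing="ij")
    v = potential.potential(np.stack([xx, yy], axis=-1))
    w = np.exp(-(v - v.min()) / kT)  # unnormalized Boltzmann weights
    d_coeff = kT / friction

    def idx(ix, iy):
        return ix * ny + iy

    rows, cols, vals = [], [], []
    # symmetric-split rates expressed through sqrt(w_i w_j)/w_i so that
    # w_i k_ij == w_j k_ji holds bit-for-bit.
    for (dx, dy, c_hop) in ((1, 0, d_coeff / hx**2), (0, 1, d_coeff / hy**2)):
        wi = w[: nx - dx, : ny - dy]
        wj = w[dx:, dy:]
        m = np.sqrt(wi * wj)
        i_idx, j_idx = np.meshgrid(
            np.arange(nx - dx), np.arange(ny - dy), indexing="ij"
        )
        a = idx(i_idx, j_idx).ravel()
        b = idx(i_idx + dx, j_idx + dy).ravel()
        rate_ab = (c_hop * m / wi).ravel()
        rate_ba = (c_hop * m / wj).ravel()
        rows.extend([a, b])
        cols.extend([b, a])
        vals.extend([rate_ab, rate_ba])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    n = nx * ny
    q = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    q = q - sp.diags(np.asarray(q.sum(axis=1)).ravel())
    wflat = w.ravel()
    pi = wflat / wflat.sum()
    # symmetrized generator A_ij = sqrt(w_i/w_j) q_ij shares q's spectrum
    sq = np.sqrt(wflat)
    a_sym = sp.diags(sq) @ q @ sp.diags(1.0 / sq)
    a_sym = (a_sym + a_sym.T) / 2.0
    k = min(n_timescales + 1, n - 2)
    evals = eigsh(a_sym, k=k, which="LA", return_eigenvectors=False)
    evals = np.sort(evals)[::-1]  # 0 first, then slow relaxations
    relax = evals[1:]
    relax = relax[relax < -1e-300]
    ts = -1.0 / relax
    return ReferenceKinetics(
        generator=q,
        stationary=pi,
        timescales=np.sort(ts)[::-1][:n_timescales],
        x_centers=x_centers,
        y_centers=y_centers,
        shape=shape,
        potential=potential,
        kT=kT,
        diffusion=d_coeff,
    )
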