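"""Geometric featurization of molecular trajectories.

Reads multi-model PDB trajectories into :class:`MolecularFrameSet` objects and
evaluates scalar order parameters on every frame:

* minimal (Kabsch) backbone RMSD to a reference conformation,
* residue-pair distances (single atom, e.g. Cα–Cα, or group centroids, e.g.
  side-chain–side-chain separations),
* Shrake–Rupley solvent-accessible surface area (SASA).

These are the order parameters onto which the kinetic analysis downstream
projects its free-energy landscapes: e.g. the opening of a binding cleft
measured as a Cα separation, the sequestration of an aromatic side chain
measured as a side-chain centroid separation or as a drop in SASA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FeatureError, SelectionError, TopologyError

__all__ = [
    "AtomRecord",
    "MolecularFrameSet",
    "FeatureMatrix",
    "Selection",
    "DistanceFeature",
    "RmsdFeature",
    "SasaFeature",
    "read_structure",
    "write_structure",
    "kabsch_rmsd",
    "pair_distance",
    "shrake_rupley_sasa",
    "sphere_points",
    "featurize",
    "VDW_RADII",
    "BACKBONE_ATOM_NAMES",
]

# Bondi van der Waals radii (Å), with the common extensions for biologically
# relevant metals. Unknown elements are a hard error — silent defaults would
# corrupt SASA values.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "NA": 2.27,
    "MG": 1.73,
    "K": 2.75,
    "CA": 2.31,
    "ZN": 1.39,
}

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology template.

    Coordinates live in :attr:`MolecularFrameSet.frames`; an ``AtomRecord``
    may optionally carry a single set of coordinates when used standalone.
    """

    atom_name: str
    residue_name: str
    residue_number: int
    element: str
    vdw_radius: float
    coordinates: tuple[float, float, float] | None = None

    def __post_init__(self):
        if not self.vdw_radius > 0:
            raise TopologyError(
                f"atom {self.atom_name} ({self.residue_name}{self.residue_number}): "
                f"vdw_radius must be positive, got {self.vdw_radius}"
            )
        if self.coordinates is not None and not np.all(np.isfinite(self.coordinates)):
            raise TopologyError(
                f"atom {self.atom_name}: non-finite coordinates {self.coordinates}"
            )

    @property
    def is_backbone(self) -> bool:
        return self.atom_name in BACKBONE_ATOM_NAMES

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


def _check_contiguous(trajectory_ids: np.ndarray) -> None:
    ids = np.asarray(trajectory_ids)
    if ids.ndim != 1:
        raise TopologyError("trajectory_ids must be one-dimensional")
    # each id must occupy one contiguous block
    change = np.flatnonzero(np.diff(ids) != 0)
    seen = ids[np.concatenate(([0], change + 1))] if ids.size else ids
    if len(set(seen.tolist())) != len(seen):
        raise TopologyError("frames with the same trajectory_id must be contiguous")


@dataclass
class MolecularFrameSet:
    """An ordered set of frames sharing one atom template.

    Parameters
    ----------
    atoms:
        Topology template, one :class:`AtomRecord` per atom.
    frames:
        Coordinates, shape ``(n_frames, n_atoms, 3)``, Å.
    frame_interval_ns:
        Time between successive frames of the same trajectory, ns.
    trajectory_ids:
        Per-frame integer tag; frames of one trajectory are contiguous and
        time-ordered. Transition counting downstream never crosses a
        trajectory boundary.
    """

    atoms: list[AtomRecord]
    frames: np.ndarray
    frame_interval_ns: float
    trajectory_ids: np.ndarray

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.trajectory_ids = np.asarray(self.trajectory_ids, dtype=int)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TopologyError(f"frames must have shape (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[1] != len(self.atoms):
            raise TopologyError(
                f"{len(self.atoms)} template atoms but frames carry {self.frames.shape[1]} atoms"
            )
        if self.trajectory_ids.shape != (self.frames.shape[0],):
            raise TopologyError("trajectory_ids must have one entry per frame")
        if not self.frame_interval_ns > 0:
            raise TopologyError("frame_interval_ns must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise TopologyError("frames contain non-finite coordinates")
        _check_contiguous(self.trajectory_ids)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def times_ns(self) -> np.ndarray:
        """Per-frame time since the start of its own trajectory, ns."""
        t = np.empty(self.n_frames)
        for tid in np.unique(self.trajectory_ids):
            mask = self.trajectory_ids == tid
            t[mask] = np.arange(mask.sum()) * self.frame_interval_ns
        return t

    @staticmethod
    def concatenate(parts: Sequence["MolecularFrameSet"]) -> "MolecularFrameSet":
        if not parts:
            raise TopologyError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if len(p.atoms) != len(first.atoms) or any(
                a.atom_name != b.atom_name or a.residue_number != b.residue_number
                for a, b in zip(p.atoms, first.atoms)
            ):
                raise TopologyError("cannot concatenate frame sets with different atom templates")
            if p.frame_interval_ns != first.frame_interval_ns:
                raise TopologyError("cannot concatenate frame sets with different frame intervals")
        return MolecularFrameSet(
            atoms=first.atoms,
            frames=np.concatenate([p.frames for p in parts], axis=0),
            frame_interval_ns=first.frame_interval_ns,
            trajectory_ids=np.concatenate([p.trajectory_ids for p in parts]),
        )


@dataclass
class FeatureMatrix:
    """Per-frame values of named order parameters.

    ``values`` has one row per frame and one column per feature; trajectory
    tags are copied unchanged from the source frames so downstream counting
    can respect trajectory boundaries.
    """

    feature_names: list[str]
    values: np.ndarray
    trajectory_ids: np.ndarray
    frame_interval_ns: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.trajectory_ids = np.asarray(self.trajectory_ids, dtype=int)
        if self.values.ndim != 2:
            raise FeatureError("values must be 2-D (n_frames, n_features)")
        if self.values.shape[1] != len(self.feature_names):
            raise FeatureError("one column per feature name required")
        if self.values.shape[0] != self.trajectory_ids.shape[0]:
            raise FeatureError("one value row per frame required")
        if not np.all(np.isfinite(self.values)):
            raise FeatureError("feature values contain NaN/inf")
        _check_contiguous(self.trajectory_ids)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise FeatureError(f"no feature named {name!r}; have {self.feature_names}") from None
        return self.values[:, j]

    def to_dataframe(self):
        import pandas as pd

        frame_index = np.empty(self.n_frames, dtype=int)
        for tid in np.unique(self.trajectory_ids):
            mask = self.trajectory_ids == tid
            frame_index[mask] = np.arange(mask.sum())
        df = pd.DataFrame(
            {
                "trajectory_id": self.trajectory_ids,
                "frame_index": frame_index,
                "time_ns": frame_index * self.frame_interval_ns,
            }
        )
        for j, name in enumerate(self.feature_names):
            df[name] = self.values[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @staticmethod
    def from_csv(path, frame_interval_ns: float | None = None) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path)
        meta = {"trajectory_id", "frame_index", "time_ns"}
        names = [c for c in df.columns if c not in meta]
        if frame_interval_ns is None:
            tns = df["time_ns"].to_numpy()
            positive = tns[tns > 0]
            frame_interval_ns = float(positive.min()) if positive.size else 1.0
        return FeatureMatrix(
            feature_names=names,
            values=df[names].to_numpy(float),
            trajectory_ids=df["trajectory_id"].to_numpy(int),
            frame_interval_ns=frame_interval_ns,
        )

    @staticmethod
    def concatenate(parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise FeatureError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.feature_names != first.feature_names:
                raise FeatureError("feature name mismatch between parts")
        return FeatureMatrix(
            feature_names=first.feature_names,
            values=np.concatenate([p.values for p in parts], axis=0),
            trajectory_ids=np.concatenate([p.trajectory_ids for p in parts]),
            frame_interval_ns=first.frame_interval_ns,
        )


# ---------------------------------------------------------------------------
# selections


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection on the topology template.

    Residue numbering is taken verbatim from the input structure (no
    renumbering). ``part`` restricts to the standard backbone (N, CA, C, O)
    or to side-chain heavy atoms (all non-hydrogen atoms that are not
    backbone).
    """

    residue_number: int | None = None
    residue_name: str | None = None
    atom_names: tuple[str, ...] | None = None
    part: str = "any"  # any | backbone | sidechain

    def __post_init__(self):
        if self.part not in ("any", "backbone", "sidechain"):
            raise SelectionError(f"unknown selection part {self.part!r}")

    def matches(self, atom: AtomRecord) -> bool:
        if self.residue_number is not None and atom.residue_number != self.residue_number:
            return False
        if self.residue_name is not None and atom.residue_name != self.residue_name:
            return False
        if self.atom_names is not None and atom.atom_name not in self.atom_names:
            return False
        if self.part == "backbone" and not atom.is_backbone:
            return False
        if self.part == "sidechain" and (atom.is_backbone or not atom.is_heavy):
            return False
        return True

    def resolve(self, atoms: Sequence[AtomRecord]) -> np.ndarray:
        idx = np.array([i for i, a in enumerate(atoms) if self.matches(a)], dtype=int)
        if idx.size == 0:
            raise SelectionError(f"selection {self} matched no atoms")
        return idx

    def __str__(self) -> str:  # used in error messages
        bits = []
        if self.residue_name is not None:
            bits.append(self.residue_name)
        if self.residue_number is not None:
            bits.append(str(self.residue_number))
        if self.atom_names is not None:
            bits.append("/".join(self.atom_names))
        if self.part != "any":
            bits.append(self.part)
        return "Selection(" + " ".join(bits or ["<all>"]) + ")"


# ---------------------------------------------------------------------------
# kernels


def kabsch_rmsd(reference: np.ndarray, mobile: np.ndarray) -> float:
    """Minimal RMSD between two corresponding point sets (Å).

    Minimises over all proper rotations and translations (Kabsch
    superposition via SVD, with the determinant sign fix that excludes
    reflections). Symmetric in its arguments.
    """
    a = np.asarray(reference, float)
    b = np.asarray(mobile, float)
    if a.shape != b.shape:
        raise SelectionError(f"mismatched selections: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3:
        raise SelectionError("coordinate sets must have shape (n_atoms, 3)")
    n = a.shape[0]
    if n < 3:
        raise SelectionError(f"RMSD needs at least 3 atoms, got {n}")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # evaluate the residual on the superposed coordinates rather than via the
    # trace formula: the latter cancels catastrophically near rmsd = 0
    aligned = b0 @ rot.T
    return float(np.sqrt(np.mean(np.sum((a0 - aligned) ** 2, axis=1))))


def pair_distance(
    frame: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    mode: str = "centroid",
) -> float:
    """Distance (Å) between two atom groups in one frame.

    ``single_atom`` requires exactly one atom per group; ``centroid`` uses the
    unweighted mean position of each group.
    """
    frame = np.asarray(frame, float)
    ia = np.asarray(group_a, int)
    ib = np.asarray(group_b, int)
    if ia.size == 0:
        raise SelectionError("empty selection for group A")
    if ib.size == 0:
        raise SelectionError("empty selection for group B")
    if mode == "single_atom":
        if ia.size != 1 or ib.size != 1:
            raise SelectionError(
                f"single_atom mode requires exactly one atom per group, got {ia.size} and {ib.size}"
            )
        pa, pb = frame[ia[0]], frame[ib[0]]
    elif mode == "centroid":
        pa, pb = frame[ia].mean(axis=0), frame[ib].mean(axis=0)
    else:
        raise SelectionError(f"unknown distance mode {mode!r}")
    return float(np.linalg.norm(pa - pb))


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (golden-spiral rule)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    frame: np.ndarray,
    radii: np.ndarray,
    target: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Solvent-accessible surface area (Å²) of the target atoms.

    Every atom in the frame participates as an occluder; only the atoms in
    ``target`` contribute area. For each target atom a sphere of radius
    ``r_i + probe`` is sampled with golden-spiral points, and the accessible
    fraction scales the exact sphere area 4π(r_i + probe)².
    """
    frame = np.asarray(frame, float)
    radii = np.asarray(radii, float)
    target = np.asarray(target, int)
    if target.size == 0:
        raise SelectionError("empty target selection for SASA")
    if n_points < 92:
        raise FeatureError(f"n_points must be >= 92, got {n_points}")
    if probe_radius < 0:
        raise FeatureError("probe_radius must be non-negative")
    unit = sphere_points(n_points)
    expanded = radii + probe_radius
    total = 0.0
    for i in target:
        ri = expanded[i]
        pts = frame[i] + ri * unit
        # occluders: any other atom whose expanded sphere can reach these points
        d_centers = np.linalg.norm(frame - frame[i], axis=1)
        occ = np.flatnonzero((d_centers < ri + expanded) & (np.arange(len(frame)) != i))
        accessible = np.ones(n_points, dtype=bool)
        for j in occ:
            d = np.linalg.norm(pts - frame[j], axis=1)
            accessible &= d >= expanded[j]
        total += accessible.mean() * 4.0 * np.pi * ri * ri
    return float(total)


# ---------------------------------------------------------------------------
# order-parameter definitions and featurization


@dataclass(frozen=True)
class DistanceFeature:
    name: str
    group_a: Selection
    group_b: Selection
    mode: str = "centroid"


@dataclass(frozen=True)
class RmsdFeature:
    """Minimal RMSD to a reference frame over a selection (default backbone)."""

    name: str
    selection: Selection = field(default_factory=lambda: Selection(part="backbone"))
    reference_frame: int = 0


@dataclass(frozen=True)
class SasaFeature:
    name: str
    target: Selection
    probe_radius: float = 1.4
    n_points: int = 960


FeatureDefinition = DistanceFeature | RmsdFeature | SasaFeature


def featurize(frames: MolecularFrameSet, definitions: Sequence[FeatureDefinition]) -> FeatureMatrix:
    """Evaluate every order-parameter definition on every frame."""
    if not definitions:
        raise FeatureError("no order parameters defined")
    names = [d.name for d in definitions]
    if len(set(names)) != len(names):
        raise FeatureError(f"duplicate feature names in {names}")
    n = frames.n_frames
    values = np.empty((n, len(definitions)))
    radii = np.array([a.vdw_radius for a in frames.atoms])
    for j, d in enumerate(definitions):
        if isinstance(d, DistanceFeature):
            ia = d.group_a.resolve(frames.atoms)
            ib = d.group_b.resolve(frames.atoms)
            if d.mode == "single_atom" and (ia.size != 1 or ib.size != 1):
                raise SelectionError(
                    f"feature {d.name!r}: single_atom mode requires one atom per group, "
                    f"got {ia.size} and {ib.size}"
                )
            if d.mode not in ("single_atom", "centroid"):
                raise SelectionError(f"feature {d.name!r}: unknown distance mode {d.mode!r}")
            pa = frames.frames[:, ia, :].mean(axis=1)
            pb = frames.frames[:, ib, :].mean(axis=1)
            values[:, j] = np.linalg.norm(pa - pb, axis=1)
        elif isinstance(d, RmsdFeature):
            idx = d.selection.resolve(frames.atoms)
            if not 0 <= d.reference_frame < n:
                raise FeatureError(
                    f"feature {d.name!r}: reference frame {d.reference_frame} out of range"
                )
            ref = frames.frames[d.reference_frame, idx, :]
            for t in range(n):
                values[t, j] = kabsch_rmsd(ref, frames.frames[t, idx, :])
        elif isinstance(d, SasaFeature):
            idx = d.target.resolve(frames.atoms)
            for t in range(n):
                try:
                    values[t, j] = shrake_rupley_sasa(
                        frames.frames[t], radii, idx, d.probe_radius, d.n_points
                    )
                except (SelectionError, FeatureError) as exc:
                    raise FeatureError(f"feature {d.name!r} at frame {t}: {exc}") from exc
        else:
            raise FeatureError(f"unknown feature definition type {type(d).__name__}")
    return FeatureMatrix(
        feature_names=names,
        values=values,
        trajectory_ids=frames.trajectory_ids.copy(),
        frame_interval_ns=frames.frame_interval_ns,
    )


# ---------------------------------------------------------------------------
# structure I/O (multi-model PDB via biotite)


def _radius_for(element: str, atom_name: str) -> float:
    key = element.strip().upper()
    if key not in VDW_RADII:
        raise TopologyError(
            f"unknown element {element!r} for atom {atom_name!r}; "
            f"known elements: {sorted(VDW_RADII)}"
        )
    return VDW_RADII[key]


def read_structure(path, format: str = "pdb_multimodel", frame_interval_ns: float = 1.0) -> MolecularFrameSet:
    """Read a multi-model PDB into a :class:`MolecularFrameSet`.

    One frame per MODEL record; atom ordering must be identical across
    models (a model with a different atom count is a hard error naming it).
    Van der Waals radii come from the bundled Bondi table.
    """
    if format != "pdb_multimodel":
        raise TopologyError(f"unsupported trajectory format {format!r}")
    if not Path(path).is_file():
        raise TopologyError(f"structure file not found: {path}")
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise TopologyError(f"{path}: no models found")
    first = pdb_file.get_structure(model=1)
    n_atoms = first.array_length()
    coords = np.empty((n_models, n_atoms, 3))
    coords[0] = first.coord
    for m in range(2, n_models + 1):
        arr = pdb_file.get_structure(model=m)
        if arr.array_length() != n_atoms:
            raise TopologyError(
                f"{path}: MODEL {m} has {arr.array_length()} atoms, expected {n_atoms}"
            )
        coords[m - 1] = arr.coord
    atoms = [
        AtomRecord(
            atom_name=str(first.atom_name[i]),
            residue_name=str(first.res_name[i]),
            residue_number=int(first.res_id[i]),
            element=str(first.element[i]),
            vdw_radius=_radius_for(str(first.element[i]), str(first.atom_name[i])),
        )
        for i in range(n_atoms)
    ]
    return MolecularFrameSet(
        atoms=atoms,
        frames=coords,
        frame_interval_ns=frame_interval_ns,
        trajectory_ids=np.zeros(n_models, dtype=int),
    )


def write_structure(frames: MolecularFrameSet, path) -> None:
    """Write a frame set as a multi-model PDB (one MODEL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_frames, n_atoms = frames.n_frames, frames.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = frames.frames.astype(np.float32)
    stack.atom_name = np.array([a.atom_name for a in frames.atoms])
    stack.res_name = np.array([a.residue_name for a in frames.atoms])
    stack.res_id = np.array([a.residue_number for a in frames.atoms])
    stack.element = np.array([a.element for a in frames.atoms])
    stack.chain_id = np.full(n_atoms, "A")
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
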