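import numpy as np
import pytest
from hypothesis import given, strategies as st

import kinescape as ks
from kinescape.errors import FeatureError, SelectionError, TopologyError
from kinescape.geometry import BACKBONE_ATOM_NAMES

from oracles import rigid_motion, rotation_search_rmsd, two_sphere_sasa


def make_frameset(coords, elements=None, frame_interval=1.0):
    coords = np.asarray(coords, float)
    n_atoms = coords.shape[1]
    elements = elements or ["C"] * n_atoms
    atoms = [
        ks.AtomRecord(
            atom_name=f"C{i}",
            residue_name="GLY",
            residue_number=i + 1,
            element=e,
            vdw_radius=ks.geometry.VDW_RADII[e],
        )
        for i, e in enumerate(elements)
    ]
    return ks.MolecularFrameSet(
        atoms=atoms,
        frames=coords,
        frame_interval_ns=frame_interval,
        trajectory_ids=np.zeros(coords.shape[0], dtype=int),
    )


# ---------------------------------------------------------------------------
# structure I/O


class TestStructureIO:
    def test_multimodel_round_trip(self, tmp_path):
        latent = np.array([[10.0, 4.0], [8.5, 11.2], [12.25, 7.75]])
        frames = ks.embed_pseudo_atoms(latent)
        path = tmp_path / "pseudo.pdb"
        ks.write_structure(frames, path)
        back = ks.read_structure(path)
        assert back.n_frames == 3
        assert back.n_atoms == frames.n_atoms
        # PDB stores 3 decimals; coordinates survive within 1e-3 Å
        assert np.allclose(back.frames, frames.frames, atol=1.5e-3)
        assert [a.atom_name for a in back.atoms] == [a.atom_name for a in frames.atoms]
        assert [a.residue_number for a in back.atoms] == [a.residue_number for a in frames.atoms]

    def test_inconsistent_model_is_named(self, tmp_path):
        frames = ks.embed_pseudo_atoms(np.array([[10.0, 4.0], [9.0, 5.0]]))
        path = tmp_path / "bad.pdb"
        ks.write_structure(frames, path)
        lines = path.read_text().splitlines()
        # drop one ATOM record from the second model
        second_model = next(i for i, l in enumerate(lines) if l.startswith("MODEL") and "2" in l.split())
        atom_line = next(i for i in range(second_model, len(lines)) if lines[i].startswith("ATOM"))
        del lines[atom_line]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TopologyError, match="MODEL 2"):
            ks.read_structure(path)

    def test_unknown_element_is_an_error(self, tmp_path):
        path = tmp_path / "odd.pdb"
        path.write_text(
            "MODEL        1\n"
            "ATOM      1  XX  UNK A   1       0.000   0.000   0.000  1.00  0.00          Xx\n"
            "ATOM      2  CA  UNK A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CB  UNK A   1       0.000   1.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        with pytest.raises(TopologyError, match="XX"):
            ks.read_structure(path)

    def test_trajectory_ids_must_be_contiguous(self):
        with pytest.raises(TopologyError, match="contiguous"):
            ks.MolecularFrameSet(
                atoms=make_frameset(np.zeros((1, 3, 3))).atoms,
                frames=np.zeros((3, 3, 3)),
                frame_interval_ns=1.0,
                trajectory_ids=np.array([0, 1, 0]),
            )


# ---------------------------------------------------------------------------
# Kabsch RMSD


SQUARE = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)


class TestKabschRmsd:
    def test_identity_is_zero(self):
        assert ks.kabsch_rmsd(SQUARE, SQUARE) == 0.0

    def test_rigid_motion_invariance(self):
        moved = rigid_motion(SQUARE, [0, 0, np.pi / 2], [5.0, 5.0, 5.0])
        assert ks.kabsch_rmsd(SQUARE, moved) <= 1e-9

    def test_matches_rotation_search_oracle_on_toy_set(self):
        b = SQUARE.copy()
        b[3] = [0.0, 1.0, 1.0]
        expected = rotation_search_rmsd(SQUARE, b)
        assert ks.kabsch_rmsd(SQUARE, b) == pytest.approx(expected, abs=1e-6)

    def test_symmetric_in_arguments(self):
        b = SQUARE + np.array([[0.1, -0.2, 0.3]] * 4) * np.arange(1, 5)[:, None]
        assert ks.kabsch_rmsd(SQUARE, b) == pytest.approx(ks.kabsch_rmsd(b, SQUARE), abs=1e-12)

    def test_too_few_atoms(self):
        with pytest.raises(SelectionError, match="at least 3"):
            ks.kabsch_rmsd(SQUARE[:2], SQUARE[:2])

    def test_mismatched_selections(self):
        with pytest.raises(SelectionError, match="mismatched"):
            ks.kabsch_rmsd(SQUARE, SQUARE[:3])

    @given(
        st.integers(0, 2**32 - 1),
        st.floats(-np.pi, np.pi),
        st.floats(-50, 50),
    )
    def test_rigid_motion_invariance_property(self, seed, angle, shift):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 3)) * 3.0
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        moved = rigid_motion(pts, axis * angle, [shift, -shift, 0.5 * shift])
        assert ks.kabsch_rmsd(pts, moved) <= 1e-9


# ---------------------------------------------------------------------------
# distances


class TestPairDistance:
    def test_three_four_five(self):
        frame = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        assert ks.pair_distance(frame, [0], [1], mode="single_atom") == pytest.approx(5.0)

    def test_same_group_is_zero(self):
        frame = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert ks.pair_distance(frame, [0, 1], [0, 1], mode="centroid") == 0.0

    def test_centroid_arithmetic(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0], [1.0, 3.0, 0], [1.0, 5.0, 0]])
        assert ks.pair_distance(frame, [0, 1], [2, 3], mode="centroid") == pytest.approx(4.0)

    def test_empty_selection_names_group(self):
        frame = np.zeros((2, 3))
        with pytest.raises(SelectionError, match="group B"):
            ks.pair_distance(frame, [0], [], mode="centroid")

    def test_single_atom_requires_one_atom(self):
        frame = np.zeros((3, 3))
        with pytest.raises(SelectionError, match="single_atom"):
            ks.pair_distance(frame, [0, 1], [2], mode="single_atom")

    @given(st.integers(0, 2**32 - 1))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        frame = rng.normal(size=(3, 3)) * 10
        d01 = ks.pair_distance(frame, [0], [1], mode="single_atom")
        d12 = ks.pair_distance(frame, [1], [2], mode="single_atom")
        d02 = ks.pair_distance(frame, [0], [2], mode="single_atom")
        assert d02 <= d01 + d12 + 1e-12


# ---------------------------------------------------------------------------
# SASA


class TestShrakeRupleySasa:
    R = 1.7
    PROBE = 1.4

    def test_isolated_sphere_closed_form(self):
        frame = np.array([[0.0, 0, 0]])
        area = ks.shrake_rupley_sasa(frame, np.array([self.R]), [0], self.PROBE, 960)
        exact = 4 * np.pi * (self.R + self.PROBE) ** 2
        assert area == pytest.approx(exact, rel=0.01)

    def test_non_overlapping_additivity(self):
        frame = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        area = ks.shrake_rupley_sasa(frame, np.array([self.R, self.R]), [0, 1], self.PROBE, 960)
        assert area == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=0.01)

    def test_two_sphere_cap_closed_form(self):
        d = 3.1
        frame = np.array([[0.0, 0, 0], [d, 0, 0]])
        area = ks.shrake_rupley_sasa(frame, np.array([self.R, self.R]), [0, 1], self.PROBE, 960)
        assert area == pytest.approx(two_sphere_sasa(self.R, self.PROBE, d), rel=0.02)

    def test_quadrature_error_shrinks_with_points(self):
        d = 3.1
        frame = np.array([[0.0, 0, 0], [d, 0, 0]])
        exact = two_sphere_sasa(self.R, self.PROBE, d)
        errs = [
            abs(ks.shrake_rupley_sasa(frame, np.array([self.R, self.R]), [0, 1], self.PROBE, n) - exact)
            for n in (92, 3840)
        ]
        assert errs[1] < errs[0]

    def test_buried_atom_has_zero_area(self):
        frame = np.array([[0.0, 0, 0], [0.0, 0, 0.01]])
        area = ks.shrake_rupley_sasa(frame, np.array([5.0, 0.5]), [1], self.PROBE, 960)
        assert area == 0.0

    def test_contract_errors(self):
        frame = np.zeros((1, 3))
        with pytest.raises(SelectionError):
            ks.shrake_rupley_sasa(frame, np.array([1.0]), [], 1.4, 960)
        with pytest.raises(FeatureError, match="92"):
            ks.shrake_rupley_sasa(frame, np.array([1.0]), [0], 1.4, 50)


# ---------------------------------------------------------------------------
# featurize


class TestFeaturize:
    def test_single_distance_two_frames(self):
        coords = np.array(
            [[[0.0, 0, 0], [3.0, 4, 0]], [[0.0, 0, 0], [6.0, 8, 0]]]
        )
        fs = make_frameset(coords)
        fm = ks.featurize(
            fs,
            [
                ks.DistanceFeature(
                    "d",
                    ks.Selection(residue_number=1),
                    ks.Selection(residue_number=2),
                    mode="single_atom",
                )
            ],
        )
        assert fm.values.shape == (2, 1)
        assert fm.values[:, 0] == pytest.approx([5.0, 10.0])

    def test_empty_spec_is_an_error(self):
        fs = make_frameset(np.zeros((1, 2, 3)))
        with pytest.raises(FeatureError, match="no order parameters"):
            ks.featurize(fs, [])

    def test_unresolvable_selection_propagates(self):
        fs = make_frameset(np.zeros((1, 2, 3)))
        with pytest.raises(SelectionError):
            ks.featurize(
                fs,
                [ks.DistanceFeature("d", ks.Selection(residue_number=99), ks.Selection(residue_number=1))],
            )

    def test_concatenation_commutes(self):
        rng = np.random.default_rng(5)
        a = make_frameset(rng.normal(size=(4, 3, 3)))
        b = make_frameset(rng.normal(size=(3, 3, 3)))
        b.trajectory_ids[:] = 1
        defs = [
            ks.DistanceFeature("d", ks.Selection(residue_number=1), ks.Selection(residue_number=2)),
            ks.RmsdFeature("r", ks.Selection(), reference_frame=0),
        ]
        both = ks.MolecularFrameSet.concatenate([a, b])
        fm_both = ks.featurize(both, defs)
        fm_a = ks.featurize(a, defs)
        # distance features commute with concatenation (RMSD reference frame
        # is global frame 0, which lives in part a)
        assert np.allclose(fm_both.values[:4, 0], fm_a.values[:, 0])

    def test_backbone_and_sidechain_parts(self):
        frames = ks.embed_pseudo_atoms(np.array([[10.0, 4.0]]))
        backbone = ks.Selection(residue_number=48, part="backbone").resolve(frames.atoms)
        side = ks.Selection(residue_number=48, part="sidechain").resolve(frames.atoms)
        names_bb = {frames.atoms[i].atom_name for i in backbone}
        names_sc = {frames.atoms[i].atom_name for i in side}
        assert names_bb <= BACKBONE_ATOM_NAMES
        assert names_sc.isdisjoint(BACKBONE_ATOM_NAMES)

    def test_feature_csv_round_trip(self, tmp_path):
        frames = ks.embed_pseudo_atoms(np.array([[10.0, 4.0], [9.0, 5.0]]))
        fm = ks.featurize(frames, ks.pseudo_atom_features())
        p = tmp_path / "features.csv"
        fm.to_csv(p)
        back = ks.FeatureMatrix.from_csv(p)
        assert back.feature_names == fm.feature_names
        assert np.allclose(back.values, fm.values)
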