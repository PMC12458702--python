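"""Structure I/O, superposition metrics and RMSD clustering."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from confdyn.core import (
    ClusterResult,
    cluster_frames,
    pairwise_rmsd_matrix,
    radius_of_gyration,
    read_structure,
    rmsd,
    rmsf,
    superpose,
    write_structure,
)
from confdyn.errors import (
    DegenerateGeometryError,
    EmptyInputError,
    ParameterError,
    ParseError,
)
from confdyn.synthetic import SyntheticSpec, make_ensemble, make_toy_protein

from conftest import bead_ensemble


# -- PDB I/O ----------------------------------------------------------------

class TestPdbIO:
    def test_roundtrip_multimodel(self, tmp_path, toy_ensemble):
        path = tmp_path / "traj.pdb"
        sub = toy_ensemble.with_frames(toy_ensemble.frames[:3])
        write_structure(sub, str(path))
        back = read_structure(str(path))
        assert back.n_frames == 3
        assert back.n_atoms == sub.n_atoms
        # PDB stores 3 decimals
        assert np.allclose(back.frames, sub.frames, atol=2e-3)
        assert [a.name for a in back.atoms] == [a.name for a in sub.atoms]
        assert [a.residue_index for a in back.atoms] == \
            [a.residue_index for a in sub.atoms]

    def test_single_model_three_atoms(self, tmp_path):
        pdb = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C\n"
            "END\n")
        path = tmp_path / "tiny.pdb"
        path.write_text(pdb)
        ens = read_structure(str(path))
        assert ens.n_frames == 1
        assert ens.n_atoms == 3
        assert ens.atoms[1].element.upper() == "C"

    def test_mismatched_model_atom_counts(self, tmp_path):
        pdb = (
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n")
        path = tmp_path / "bad.pdb"
        path.write_text(pdb)
        with pytest.raises(ParseError, match="mismatched"):
            read_structure(str(path))

    def test_malformed_record_names_line(self, tmp_path):
        pdb = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       3.8xx   0.000   0.000  1.00  0.00           C\n")
        path = tmp_path / "bad.pdb"
        path.write_text(pdb)
        with pytest.raises(ParseError, match=":2:"):
            read_structure(str(path))

    def test_zero_atoms(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(EmptyInputError):
            read_structure(str(path))


# -- superposition ----------------------------------------------------------

def brute_force_min_rmsd(mobile, reference, restarts=8):
    """Independent oracle: direct minimisation over rotation vectors of the
    centred RMSD (no Kabsch)."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def cost(rotvec):
        moved = Rotation.from_rotvec(rotvec).apply(mob)
        return np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))

    rng = np.random.default_rng(0)
    best = np.inf
    for _ in range(restarts):
        x0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 4000})
        best = min(best, res.fun)
    return best


class TestSuperpose:
    def test_self_rmsd_zero(self, rng):
        frame = rng.normal(size=(10, 3))
        _, val = superpose(frame, frame)
        assert val < 1e-10

    def test_translation_invariance(self, rng):
        frame = rng.normal(size=(10, 3))
        _, val = superpose(frame + np.array([10.0, 0, 0]), frame)
        assert val < 1e-9

    def test_rotation_is_proper_and_matches_bruteforce(self):
        ref = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]],
                       dtype=float)
        mob = ref.copy()
        mob[3] = [0, 0, 5]  # displaced 2 A along a symmetry-preserving axis
        mob = Rotation.from_euler("xyz", [0.3, -0.8, 1.1]).apply(mob) + 5.0
        moved, val = superpose(mob, ref)
        oracle = brute_force_min_rmsd(mob, ref)
        assert abs(val - oracle) < 1e-3

    def test_collinear_selection_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                        dtype=float)
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line + 1.0)

    def test_rmsd_symmetry_property(self, rng):
        for _ in range(5):
            a = rng.normal(size=(20, 3))
            b = rng.normal(size=(20, 3))
            assert abs(rmsd(a, b) - rmsd(b, a)) < 1e-9


# -- RMSF / Rg --------------------------------------------------------------

class TestFluctuationMetrics:
    def test_static_ensemble_zero_rmsf(self, rng):
        frame = rng.normal(size=(6, 3))
        ens = bead_ensemble(np.repeat(frame[None], 4, axis=0))
        assert np.allclose(rmsf(ens, fit=False), 0.0)

    def test_two_frame_hand_value(self):
        # one bead alternates between (0,0,0) and (2,0,0): RMSF = 1.0 A
        frames = np.zeros((2, 4, 3))
        frames[:, :3, :] = [[0, 5, 0], [5, 0, 0], [5, 5, 5]]
        frames[1, 3, 0] = 2.0
        ens = bead_ensemble(frames)
        vals = rmsf(ens, fit=False)
        assert vals[3] == pytest.approx(1.0, abs=1e-12)

    def test_rigid_translation_fit_removes_motion(self, rng):
        frame = rng.normal(size=(8, 3))
        frames = np.stack([frame + np.array([k * 3.0, 0, 0])
                           for k in range(5)])
        ens = bead_ensemble(frames)
        assert np.all(rmsf(ens, fit=True) < 1e-9)

    def test_rg_closed_forms(self):
        one = bead_ensemble(np.zeros((1, 1, 3)))
        assert radius_of_gyration(one) == pytest.approx(0.0)
        two = bead_ensemble(np.array([[[0, 0, 0], [2, 0, 0]]]))
        assert radius_of_gyration(two) == pytest.approx(1.0)
        corners = np.array([[x, y, z] for x in (-1, 1) for y in (-1, 1)
                            for z in (-1, 1)], dtype=float)
        cube = bead_ensemble(corners[None])
        assert radius_of_gyration(cube) == pytest.approx(np.sqrt(3.0))

    def test_rg_rigid_motion_invariance(self, rng):
        frame = rng.normal(size=(12, 3))
        rot = Rotation.from_euler("zyx", [0.4, 1.2, -0.7])
        a = radius_of_gyration(bead_ensemble(frame[None]))
        b = radius_of_gyration(bead_ensemble((rot.apply(frame) + 9.0)[None]))
        assert a == pytest.approx(b, abs=1e-9)


# -- clustering -------------------------------------------------------------

def two_state_ensemble(seed=5, n1=30, n2=20, displacement=15.0):
    spec1 = SyntheticSpec(seed=seed, n_frames=n1, domain_sigma=0.1)
    ref, part = make_toy_protein(spec1)
    e1 = make_ensemble(spec1)
    ref2 = ref.with_frames(ref.frames.copy())
    ref2.frames[0, part.residues("PIWI"), :] += [0.0, 0.0, displacement]
    spec2 = SyntheticSpec(seed=seed + 1, n_frames=n2, domain_sigma=0.1)
    e2 = make_ensemble(spec2, reference=ref2)
    return e1.concat(e2)


class TestClustering:
    def test_identical_frames_single_cluster(self, rng):
        frame = rng.normal(size=(6, 3))
        ens = bead_ensemble(np.repeat(frame[None], 10, axis=0))
        result = cluster_frames(ens, epsilon=3.0)
        assert len(result.representatives) == 1
        assert result.representatives[0][1] == pytest.approx(1.0)

    def test_two_planted_conformers_recovered(self):
        ens = two_state_ensemble()
        result = cluster_frames(ens, epsilon=3.0)
        pops = [w for _, w in result.representatives]
        assert pops == pytest.approx([0.6, 0.4])
        # representative frames belong to their clusters
        for cid, (frame, _) in enumerate(result.representatives):
            assert result.assignments[frame] == cid

    def test_large_epsilon_single_cluster(self):
        ens = two_state_ensemble()
        result = cluster_frames(ens, epsilon=1e6)
        assert len(result.representatives) == 1

    def test_epsilon_must_be_positive(self, toy_ensemble):
        with pytest.raises(ParameterError):
            cluster_frames(toy_ensemble, epsilon=0.0)

    def test_frame_permutation_invariance(self):
        ens = two_state_ensemble(n1=12, n2=8)
        result = cluster_frames(ens, epsilon=3.0)
        rng = np.random.default_rng(3)
        perm = rng.permutation(ens.n_frames)
        permuted = ens.with_frames(ens.frames[perm])
        result_p = cluster_frames(permuted, epsilon=3.0)
        # same partition of frames up to cluster relabeling
        orig = {}
        for f, c in enumerate(result_p.assignments):
            orig.setdefault(c, set()).add(perm[f])
        expected = {}
        for f, c in enumerate(result.assignments):
            expected.setdefault(c, set()).add(f)
        assert set(map(frozenset, orig.values())) == \
            set(map(frozenset, expected.values()))

    def test_population_sum_validated(self):
        with pytest.raises(ParameterError):
            ClusterResult(assignments=np.zeros(2, dtype=int),
                          representatives=[(0, 0.5), (1, 0.4)])
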