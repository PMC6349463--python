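import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from mitocarrier import (
    CorrespondenceMap,
    RigidTransform,
    align_sequences,
    displacement_field,
    iterative_superpose,
    kabsch,
    make_ideal_helix,
    rotation_angle,
)


def _random_rotation(rng):
    return Rotation.random(random_state=rng).as_matrix()


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        reflection = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(reflection, np.zeros(3))

    def test_compose_and_inverse(self, rng):
        R = _random_rotation(rng)
        t = rng.normal(size=3)
        T = RigidTransform(R, t)
        x = rng.normal(size=(10, 3))
        assert np.allclose(T.inverse().apply(T.apply(x)), x, atol=1e-12)
        T2 = RigidTransform(_random_rotation(rng), rng.normal(size=3))
        assert np.allclose(
            T2.compose(T).apply(x), T2.apply(T.apply(x)), atol=1e-12
        )


class TestKabsch:
    def test_self_superposition_is_identity(self, rng):
        x = rng.normal(size=(20, 3))
        res = kabsch(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-12)

    def test_recovers_random_rigid_transform(self, rng):
        for _ in range(10):
            x = rng.normal(size=(15, 3)) * 5
            R = _random_rotation(rng)
            t = rng.normal(size=3) * 10
            res = kabsch(x, x @ R.T + t)
            assert np.allclose(res.transform.rotation, R, atol=1e-8)
            assert np.allclose(res.transform.translation, t, atol=1e-7)
            assert res.rmsd < 1e-9

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            kabsch(line, line)

    def test_optimality_against_rotation_grid_oracle(self, rng):
        """Kabsch RMSD never exceeds the best RMSD over a dense SO(3) grid."""
        angles = np.radians(np.arange(0, 360, 12))
        betas = np.radians(np.arange(0, 181, 12))
        grid = [
            Rotation.from_euler("zyz", [a, b, c]).as_matrix()
            for a in angles for b in betas for c in angles
        ]
        grid = np.stack(grid)
        for _ in range(3):
            n = rng.integers(4, 11)
            target = rng.normal(size=(n, 3)) * 4
            mobile = target @ _random_rotation(rng).T + rng.normal(size=(n, 3)) * 0.5
            res = kabsch(mobile, target)
            mc = mobile - mobile.mean(axis=0)
            tc = target - target.mean(axis=0)
            rotated = np.einsum("rij,nj->rni", grid, mc)
            rmsds = np.sqrt(((rotated - tc) ** 2).sum(axis=(1, 2)) / n)
            assert res.rmsd <= rmsds.min() + 1e-9


class TestRotationAngle:
    def test_identity(self):
        angle, axis = rotation_angle(RigidTransform.identity())
        assert angle == 0.0
        assert np.allclose(axis, [0, 0, 1])

    def test_closed_form_15_degrees_about_z(self):
        R = Rotation.from_euler("z", 15, degrees=True).as_matrix()
        angle, axis = rotation_angle(RigidTransform(R, np.zeros(3)))
        assert angle == pytest.approx(15.0, abs=1e-9)
        assert np.allclose(axis, [0, 0, 1], atol=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_angle_of_fit_equals_angle_of_rotation(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(12, 3)) * 3
        rot = Rotation.random(random_state=rng)
        expected = np.degrees(rot.magnitude())
        res = kabsch(x, x @ rot.as_matrix().T)
        angle, _ = rotation_angle(res.transform)
        assert angle == pytest.approx(expected, abs=1e-6)


class TestIterativeSuperpose:
    def _paired(self, rng, n_res=20):
        x = rng.normal(size=(n_res * 4, 3)) * 4
        labels = [i // 4 for i in range(n_res * 4)]
        return x, labels

    def test_no_outliers_identical_to_kabsch(self, rng):
        x, labels = self._paired(rng)
        res = iterative_superpose(x, x.copy(), labels)
        assert res.cycles == 1
        assert res.rejected_residues == []
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_displaced_residue_rejected(self, rng):
        x, labels = self._paired(rng)
        y = x.copy()
        y[12:16] += 10.0  # displace residue 3 by 10 A
        res = iterative_superpose(x, y, labels)
        assert res.rejected_residues == [3]
        assert res.rmsd < 0.01
        assert res.n_atoms_used == len(x) - 4

    def test_invariant_to_atom_order_within_residue(self, rng):
        x, labels = self._paired(rng)
        y = x.copy()
        y[20:24] += 8.0
        res1 = iterative_superpose(x, y, labels)
        perm = np.arange(len(x))
        for r in range(20):
            perm[r * 4:(r + 1) * 4] = perm[r * 4:(r + 1) * 4][::-1]
        res2 = iterative_superpose(x[perm], y[perm], list(np.array(labels)[perm]))
        assert res1.rejected_residues == res2.rejected_residues
        assert res1.rmsd == pytest.approx(res2.rmsd, abs=1e-12)

    def test_all_rejected_raises(self):
        x = np.diag([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            iterative_superpose(x, x + 100, [0, 0, 0], cutoff_factor=0.5)


def _gotoh_score(a, b, matrix, open_=-10.0, extend=-0.5):
    """Affine-gap global alignment score with free end gaps (oracle)."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consuming a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consuming b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0  # free end gaps
    for j in range(1, m + 1):
        Y[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + (open_ if j < m else 0.0),
                          X[i - 1, j] + (extend if j < m else 0.0))
            Y[i, j] = max(M[i, j - 1] + (open_ if i < n else 0.0),
                          Y[i, j - 1] + (extend if i < n else 0.0))
    return max(M[n, m], X[n, m], Y[n, m])


class TestAlignSequences:
    def test_identical_sequences(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        result = align_sequences(seq, seq)
        assert result.percent_identity == pytest.approx(100.0)
        assert result.pairs == [(i, i) for i in range(1, len(seq) + 1)]

    def test_insertion_offsets_mapping(self):
        seq_a = "MKTAYIAKQRQISFVKSHFSRQ"
        seq_b = seq_a[:10] + "W" + seq_a[10:]
        result = align_sequences(seq_a, seq_b)
        mapping = dict(result.pairs)
        for i in range(1, 11):
            assert mapping[i] == i
        for i in range(11, len(seq_a) + 1):
            assert mapping[i] == i + 1

    def test_score_matches_affine_dp_oracle(self, rng):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        from mitocarrier.rigidfit import _make_aligner

        aligner = _make_aligner()
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = "".join(rng.choice(list(alphabet), size=rng.integers(5, 15)))
            b = "".join(rng.choice(list(alphabet), size=rng.integers(5, 15)))
            assert aligner.score(a, b) == pytest.approx(
                _gotoh_score(a, b, blosum), abs=1e-9
            )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_sequences("", "ACD")

    def test_pairs_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            CorrespondenceMap([(1, 2), (1, 3)], 50.0)


class TestDisplacementField:
    def test_identical_models_all_zero(self):
        helix = make_ideal_helix(15)
        corr = CorrespondenceMap([(i, i) for i in range(1, 16)], 100.0)
        disp = displacement_field(helix, helix, corr, frame="none")
        assert all(v == pytest.approx(0.0) for v in disp.values())

    def test_translated_subset_measured_exactly_with_frame_none(self):
        helix = make_ideal_helix(15)
        coords = helix.coords.copy()
        mask = np.array([a.residue_number > 10 for a in helix.atoms])
        coords[mask] += [3.0, 4.0, 0.0]  # |t| = 5
        moved = helix.with_coords(coords)
        corr = CorrespondenceMap([(i, i) for i in range(1, 16)], 100.0)
        disp = displacement_field(helix, moved, corr, frame="none")
        for res, value in disp.items():
            expected = 5.0 if res > 10 else 0.0
            assert value == pytest.approx(expected, abs=1e-12)

    def test_global_fit_frame_invariant_to_rigid_pretransform(self, rng):
        helix = make_ideal_helix(20)
        coords = helix.coords.copy()
        mask = np.array([a.residue_number > 12 for a in helix.atoms])
        coords[mask] += [2.0, 0.0, 1.0]
        moved = helix.with_coords(coords)
        corr = CorrespondenceMap([(i, i) for i in range(1, 21)], 100.0)
        base = displacement_field(helix, moved, corr, frame="global-fit")
        R = _random_rotation(rng)
        t = rng.normal(size=3) * 20
        shifted = helix.transformed(R, t)
        again = displacement_field(shifted, moved, corr, frame="global-fit")
        for res in base:
            assert again[res] == pytest.approx(base[res], abs=1e-9)
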