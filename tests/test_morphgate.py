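import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mitocarrier import (
    AtomRecord,
    GateParams,
    RigidTransform,
    StructureModel,
    apply_rigid_perturbation,
    clash_score,
    find_occluded_frames,
    gate_metrics,
    interpolate_states,
    kabsch,
    make_gated_pore,
    rotation_angle,
    select_atoms,
)
from mitocarrier.morphgate import Trajectory
from mitocarrier.statemodels import StateModel
from mitocarrier.topology import derive_elements


def _states(model_a, model_b):
    return (
        StateModel(model_a, "c", "crystal"),
        StateModel(model_b, "m", "crystal"),
    )


@pytest.fixture(scope="module")
def morph_setup(clean_bundle):
    model, topology = clean_bundle
    elements = derive_elements(topology)
    R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    moved, _ = apply_rigid_perturbation(
        model, [elements.gate_elements[1]], RigidTransform(R, np.zeros(3))
    )
    return model, moved, elements


class TestInterpolateStates:
    def test_endpoints_bit_equal(self, morph_setup):
        model, moved, elements = morph_setup
        traj = interpolate_states(*_states(model, moved), elements, 7)
        assert np.array_equal(traj.frames[0].model.coords, model.coords)
        assert np.array_equal(traj.frames[-1].model.coords, moved.coords)

    def test_two_frames_are_exactly_the_inputs(self, morph_setup):
        model, moved, elements = morph_setup
        traj = interpolate_states(*_states(model, moved), elements, 2)
        assert traj.n_frames == 2
        assert np.array_equal(traj.frames[0].model.coords, model.coords)
        assert np.array_equal(traj.frames[1].model.coords, moved.coords)

    def test_midpoint_has_half_the_rotation(self, morph_setup):
        model, moved, elements = morph_setup
        traj = interpolate_states(*_states(model, moved), elements, 5)
        lo, hi = elements.gate_elements[1]
        start, _ = select_atoms(model, residue_ranges=[(lo, hi)])
        mid, _ = select_atoms(traj.frames[2].model, residue_ranges=[(lo, hi)])
        angle, _ = rotation_angle(kabsch(start, mid).transform)
        assert angle == pytest.approx(15.0, abs=1e-9)

    def test_reversed_morph_matches_framewise(self, morph_setup):
        model, moved, elements = morph_setup
        fwd = interpolate_states(*_states(model, moved), elements, 6)
        rev = interpolate_states(
            StateModel(moved, "m", "crystal"), StateModel(model, "c", "crystal"),
            elements, 6,
        )
        for i in range(6):
            dev = np.abs(
                fwd.frames[i].model.coords - rev.frames[5 - i].model.coords
            ).max()
            assert dev < 1e-9

    def test_single_frame_rejected(self, morph_setup):
        model, moved, elements = morph_setup
        with pytest.raises(ValueError):
            interpolate_states(*_states(model, moved), elements, 1)

    def test_mismatched_atoms_rejected(self, morph_setup):
        model, moved, elements = morph_setup
        truncated = StructureModel(moved.atoms[:-4], "short")
        with pytest.raises(ValueError, match="share atom identities"):
            interpolate_states(*_states(model, truncated), elements, 4)


class TestClashScore:
    def test_single_residue_never_clashes(self):
        atoms = [
            AtomRecord("A", 1, "", "GLY", f"X{i}", "C", (0.1 * i, 0.0, 0.0))
            for i in range(5)
        ]
        assert clash_score(StructureModel(atoms, "one")) == 0

    def test_two_close_atoms_in_different_residues(self):
        atoms = [
            AtomRecord("A", 1, "", "GLY", "CA", "C", (0.0, 0.0, 0.0)),
            AtomRecord("A", 5, "", "GLY", "CA", "C", (2.0, 0.0, 0.0)),
        ]
        assert clash_score(StructureModel(atoms, "pair")) == 1

    def test_sequence_neighbors_excluded(self):
        atoms = [
            AtomRecord("A", 1, "", "GLY", "C", "C", (0.0, 0.0, 0.0)),
            AtomRecord("A", 2, "", "GLY", "N", "N", (1.3, 0.0, 0.0)),
        ]
        assert clash_score(StructureModel(atoms, "bonded")) == 0

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            clash_score(StructureModel([], "none"))


class TestGateMetrics:
    def test_closed_shell_is_occluded(self, occluded_pore, pore_topology):
        gm = gate_metrics(occluded_pore, pore_topology)
        assert gm.occluded
        assert not gm.accessible_from_matrix
        assert not gm.accessible_from_cytoplasm

    def test_funnel_open_one_side_only(self, top_open_pore, pore_topology):
        gm = gate_metrics(top_open_pore, pore_topology)
        assert gm.accessible_from_cytoplasm  # +z face with matrix at -z
        assert not gm.accessible_from_matrix
        assert not gm.occluded
        flipped = gate_metrics(
            make_gated_pore(0.0, 15.0), pore_topology
        )
        assert flipped.accessible_from_matrix
        assert not flipped.accessible_from_cytoplasm

    def test_booleans_stable_under_grid_halving(self, occluded_pore,
                                                top_open_pore, pore_topology):
        for model in (occluded_pore, top_open_pore):
            coarse = gate_metrics(model, pore_topology, GateParams(grid_spacing=1.0))
            fine = gate_metrics(model, pore_topology, GateParams(grid_spacing=0.5))
            assert coarse.accessible_from_matrix == fine.accessible_from_matrix
            assert coarse.accessible_from_cytoplasm == fine.accessible_from_cytoplasm

    def test_invariant_under_rigid_transform_with_axis(self, top_open_pore,
                                                       pore_topology, rng):
        base = gate_metrics(top_open_pore, pore_topology)
        R = Rotation.random(random_state=rng).as_matrix()
        moved = top_open_pore.transformed(R, rng.normal(size=3) * 10)
        axis = R @ np.array([0.0, 0.0, 1.0])
        params = GateParams(axis=tuple(axis))
        got = gate_metrics(moved, pore_topology, params)
        assert got.accessible_from_matrix == base.accessible_from_matrix
        assert got.accessible_from_cytoplasm == base.accessible_from_cytoplasm
        assert got.gate_thickness == pytest.approx(base.gate_thickness, abs=1.5)

    def test_matrix_side_sign_flips_interpretation(self, top_open_pore,
                                                   pore_topology):
        gm = gate_metrics(
            top_open_pore, pore_topology,
            GateParams(matrix_side_sign=+1),
        )
        assert gm.accessible_from_matrix
        assert not gm.accessible_from_cytoplasm

    def test_missing_binding_site_rejected(self, occluded_pore, pore_topology):
        bare = type(pore_topology)(
            domain_spans=pore_topology.domain_spans, binding_site=set(), chain="A"
        )
        with pytest.raises(ValueError, match="binding-site"):
            gate_metrics(occluded_pore, bare)


class TestFindOccludedFrames:
    def test_identical_open_frames_give_empty_list(self, pore_topology):
        open_pore = make_gated_pore(15.0, 15.0)
        traj = Trajectory([StateModel(open_pore, "frame", "interpolated")] * 3)
        assert find_occluded_frames(traj, pore_topology) == []

    def test_open_closed_open_trajectory_finds_the_middle(self, pore_topology):
        gaps = [15.0, 8.0, 0.0, 8.0, 15.0]
        frames = [
            StateModel(make_gated_pore(g, 0.0), "frame", "interpolated")
            for g in gaps
        ]
        got = find_occluded_frames(Trajectory(frames), pore_topology)
        assert 2 in got
        assert 0 not in got and 4 not in got

    def test_short_trajectory_rejected(self, pore_topology):
        traj = Trajectory(
            [StateModel(make_gated_pore(15.0, 15.0), "frame", "interpolated")] * 2
        )
        with pytest.raises(ValueError):
            find_occluded_frames(traj, pore_topology)
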