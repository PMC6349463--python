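import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mitocarrier import (
    RigidTransform,
    apply_rigid_perturbation,
    build_uninhibited_c,
    estimate_c3_axis,
    extract_sequence,
    kabsch,
    repeat_correspondence,
    select_atoms,
    symmetrize,
)
from mitocarrier.statemodels import SymmetrizeParams
from mitocarrier.topology import derive_elements


@pytest.fixture(scope="module")
def bundle_with_triples(clean_bundle):
    model, topology = clean_bundle
    seq, numbers = extract_sequence(model, topology.chain)
    triples = repeat_correspondence(topology, seq, numbers)
    return model, topology, triples


class TestRepeatCorrespondence:
    def test_identical_repeats_align_every_residue(self, bundle_with_triples):
        model, topology, triples = bundle_with_triples
        lo, hi = topology.domain_spans[1]
        assert len(triples) == hi - lo + 1 - 10  # two helices minus the gap
        first = triples[0]
        assert first[1] - first[0] == topology.domain_spans[2][0] - lo

    def test_too_few_triples_raises(self, bundle_with_triples):
        model, topology, _ = bundle_with_triples
        seq, numbers = extract_sequence(model, topology.chain)
        with pytest.raises(ValueError, match="triples"):
            repeat_correspondence(topology, seq, numbers, min_triples=10_000)


class TestEstimateC3Axis:
    def test_perfect_bundle_axis_is_z(self, bundle_with_triples):
        model, _, triples = bundle_with_triples
        axis = estimate_c3_axis(model, triples)
        assert abs(axis.direction @ [0, 0, 1]) > np.cos(np.radians(1.0))
        assert all(r < 0.5 for r in axis.residuals.values())

    def test_rotated_bundle_rotates_the_axis(self, bundle_with_triples, rng):
        model, _, triples = bundle_with_triples
        R = Rotation.random(random_state=rng).as_matrix()
        moved = model.transformed(R, np.zeros(3))
        axis = estimate_c3_axis(moved, triples)
        expected = R @ np.array([0.0, 0.0, 1.0])
        assert abs(axis.direction @ expected) > np.cos(np.radians(1.0))


class TestSymmetrize:
    def test_idempotent_on_symmetric_bundle(self, bundle_with_triples):
        model, topology, triples = bundle_with_triples
        state = symmetrize(model, topology, triples)
        assert state.converged
        shift = np.abs(state.model.coords - model.coords).max()
        assert shift < SymmetrizeParams().tol

    def test_single_domain_displacement_removed(self, bundle_with_triples):
        model, topology, triples = bundle_with_triples
        R = Rotation.from_euler("x", 8, degrees=True).as_matrix()
        displaced, _ = apply_rigid_perturbation(
            model, topology.domain_spans[1], RigidTransform(R, np.array([1.0, 0, 0]))
        )
        state = symmetrize(displaced, topology, triples)
        ca_orig, _ = select_atoms(model, atom_names=("CA",))
        ca_symm, _ = select_atoms(state.model, atom_names=("CA",))
        assert kabsch(ca_symm, ca_orig).rmsd <= 0.5

    def test_displaced_domain_moves_much_more_than_others(self, bundle_with_triples):
        model, topology, triples = bundle_with_triples
        R = Rotation.from_euler("x", 8, degrees=True).as_matrix()
        displaced, _ = apply_rigid_perturbation(
            model, topology.domain_spans[1], RigidTransform(R, np.array([1.0, 0, 0]))
        )
        state = symmetrize(displaced, topology, triples)
        shifts = {}
        for d in (1, 2, 3):
            before, _ = select_atoms(
                displaced, residue_ranges=[topology.domain_spans[d]], atom_names=("CA",)
            )
            after, _ = select_atoms(
                state.model, residue_ranges=[topology.domain_spans[d]], atom_names=("CA",)
            )
            shifts[d] = float(np.linalg.norm(before - after, axis=1).mean())
        assert shifts[1] > 2 * shifts[2]
        assert shifts[1] > 2 * shifts[3]

    def test_second_pass_moves_nothing(self, bundle_with_triples):
        model, topology, triples = bundle_with_triples
        R = Rotation.from_euler("y", 6, degrees=True).as_matrix()
        displaced, _ = apply_rigid_perturbation(
            model, topology.domain_spans[3], RigidTransform(R, np.zeros(3))
        )
        once = symmetrize(displaced, topology, triples)
        twice = symmetrize(once.model, topology, triples)
        tol = SymmetrizeParams().tol
        assert np.abs(twice.model.coords - once.model.coords).max() <= tol

    def test_internal_domain_geometry_exactly_preserved(self, bundle_with_triples):
        model, topology, triples = bundle_with_triples
        R = Rotation.from_euler("z", 5, degrees=True).as_matrix()
        displaced, _ = apply_rigid_perturbation(
            model, topology.domain_spans[2], RigidTransform(R, np.zeros(3))
        )
        state = symmetrize(displaced, topology, triples)
        for d in (1, 2, 3):
            a, _ = select_atoms(displaced, residue_ranges=[topology.domain_spans[d]])
            b, _ = select_atoms(state.model, residue_ranges=[topology.domain_spans[d]])
            da = np.linalg.norm(a[:, None] - a[None, :], axis=-1)
            db = np.linalg.norm(b[:, None] - b[None, :], axis=-1)
            assert np.abs(da - db).max() < 1e-6

    def test_axis_residuals_do_not_worsen(self, bundle_with_triples):
        model, topology, triples = bundle_with_triples
        R = Rotation.from_euler("x", 8, degrees=True).as_matrix()
        displaced, _ = apply_rigid_perturbation(
            model, topology.domain_spans[1], RigidTransform(R, np.zeros(3))
        )
        before = estimate_c3_axis(displaced, triples)
        state = symmetrize(displaced, topology, triples)
        after = state.axis
        assert max(after.residuals.values()) <= max(before.residuals.values()) + 1e-9


class TestBuildUninhibitedC:
    def test_self_hybrid_is_identity(self, clean_bundle):
        model, topology = clean_bundle
        elements = derive_elements(topology)
        state = build_uninhibited_c(model, model, elements)
        assert np.abs(state.model.coords - model.coords).max() < 1e-9
        assert state.provenance == "hybrid"
        assert set(state.element_transforms) == {
            "core1", "core2", "core3", "gate1", "gate2", "gate3"
        }

    def test_perturbed_elements_transplanted_back(self, clean_bundle, rng):
        """Moving elements rigidly and transplanting onto the unperturbed
        template recovers the template."""
        model, topology = clean_bundle
        elements = derive_elements(topology)
        perturbed = model
        for d in (1, 2, 3):
            R = Rotation.random(random_state=rng).as_matrix()
            # small random rotations of each core element
            R = Rotation.from_rotvec(
                Rotation.from_matrix(R).as_rotvec() * 0.1
            ).as_matrix()
            perturbed, _ = apply_rigid_perturbation(
                perturbed, elements.core_elements[d], RigidTransform(R, np.zeros(3))
            )
        state = build_uninhibited_c(perturbed, model, elements)
        for d in (1, 2, 3):
            lo, hi = elements.core_elements[d][0]
            a, _ = select_atoms(state.model, residue_ranges=[(lo, hi)])
            b, _ = select_atoms(model, residue_ranges=[(lo, hi)])
            assert np.abs(a - b).max() < 1e-6

    def test_too_few_matched_residues_raises(self, clean_bundle):
        model, topology = clean_bundle
        elements = derive_elements(topology)
        from mitocarrier import CorrespondenceMap

        tiny = CorrespondenceMap([(1, 1), (2, 2)], 100.0)
        with pytest.raises(ValueError, match="fewer than 3"):
            build_uninhibited_c(model, model, elements, correspondence=tiny)
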