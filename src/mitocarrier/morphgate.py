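"""Element-wise morphing between states and accessibility/occlusion metrics.

A naive whole-molecule interpolation between carrier states opens clefts in
the protein wall; morphing each core and gate element as a rigid body (with
constant-angular-velocity rotation interpolation) keeps the fold intact and
lets the transition be scored frame by frame.  Accessibility of the central
substrate-binding site from each membrane side is measured with a
probe-inflated grid flood fill: a side is open when solvent entering from
that face of the bounding box can reach a free cell next to the binding
site.  An occluded frame is one where neither side is open — the hallmark
of an alternating-access transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation, Slerp

from .rigidfit import kabsch
from .statemodels import StateModel
from .structure_io import StructureModel
from .topology import CarrierTopology, ElementSet

__all__ = [
    "Trajectory",
    "GateParams",
    "GateMetrics",
    "interpolate_states",
    "clash_score",
    "gate_metrics",
    "find_occluded_frames",
]

#: van der Waals radii (A) by element; unknown elements fall back to carbon.
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}


@dataclass
class Trajectory:
    frames: list[StateModel]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def models(self) -> list[StructureModel]:
        return [f.model for f in self.frames]


@dataclass(frozen=True)
class GateParams:
    probe_radius: float = 1.4          # A, water-sized probe
    grid_spacing: float = 1.0          # A
    site_contact_distance: float = 4.0  # A, free cell to binding-site atom
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)  # membrane normal
    matrix_side_sign: int = -1         # matrix side lies at sign * axis
    gate_search_radius: float = 8.0    # A from axis for thickness profiling
    #: implicit lipid: the central fraction of the structure's axial extent
    #: is treated as membrane, and cells there lying laterally outside the
    #: protein footprint are blocked so solvent cannot wrap around the
    #: outside from one face to the other
    membrane_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.grid_spacing > self.probe_radius + 1e-9:
            raise ValueError("grid spacing must not exceed the probe radius... "
                             "use spacing <= probe_radius for a leak-free fill")
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-6:
            raise ValueError("axis must be a unit vector")
        if self.matrix_side_sign not in (-1, 1):
            raise ValueError("matrix_side_sign must be +1 or -1")


@dataclass(frozen=True)
class GateMetrics:
    accessible_from_matrix: bool
    accessible_from_cytoplasm: bool
    gate_thickness: float
    clash_count: int

    @property
    def occluded(self) -> bool:
        return not (self.accessible_from_matrix or self.accessible_from_cytoplasm)


def interpolate_states(
    state_a: StateModel,
    state_b: StateModel,
    elements: ElementSet,
    n_frames: int,
) -> Trajectory:
    """Element-wise rigid morph from state A to state B.

    For each element the A->B least-squares rigid transform is decomposed
    into a rotation (interpolated by spherical linear interpolation, i.e.
    constant angular velocity) about the moving element centroid and a
    linear centroid path; atoms outside every element blend linearly.
    Frames 0 and ``n_frames - 1`` are the input coordinates exactly.
    """
    if n_frames < 2:
        raise ValueError("a morph needs at least 2 frames")
    ma, mb = state_a.model, state_b.model
    ids_a = {(a.residue_id, a.atom_name): i for i, a in enumerate(ma.atoms)}
    ids_b = {(a.residue_id, a.atom_name): i for i, a in enumerate(mb.atoms)}
    shared = [k for k in ids_a if k in ids_b]
    if len(shared) < len(ma.atoms) or len(shared) < len(mb.atoms):
        raise ValueError("states must share atom identities to be morphed")
    # reorder B to A's atom order
    perm = [ids_b[k] for k in ids_a]
    A = ma.coords
    B = mb.coords[perm]

    n_atoms = len(A)
    elem_of = np.full(n_atoms, -1)
    names = []
    fits = []
    for e_idx, (name, ranges) in enumerate(elements.element_ranges().items()):
        mask = np.array(
            [any(lo <= a.residue_number <= hi for lo, hi in ranges) for a in ma.atoms]
        )
        if mask.sum() < 3:
            raise ValueError(f"element {name} has fewer than 3 atoms")
        elem_of[mask] = e_idx
        names.append(name)
        fits.append(kabsch(A[mask], B[mask]))

    transforms = {n: f.transform for n, f in zip(names, fits)}
    fractions = np.linspace(0.0, 1.0, n_frames)
    frames: list[StateModel] = []
    for fi, s in enumerate(fractions):
        if fi == 0:
            coords = A.copy()
        elif fi == n_frames - 1:
            coords = B.copy()
        else:
            coords = (1.0 - s) * A + s * B  # linker default: linear blend
            for e_idx, (name, fit) in enumerate(zip(names, fits)):
                mask = elem_of == e_idx
                R = fit.transform.rotation
                rot = Rotation.from_matrix(np.stack([np.eye(3), R]))
                R_s = Slerp([0.0, 1.0], rot)(s).as_matrix()
                ca = A[mask].mean(axis=0)
                cb = B[mask].mean(axis=0)
                # symmetric blend: exact at both endpoints, half-rotation at s=1/2
                inner = (1.0 - s) * (A[mask] - ca) + s * (B[mask] - cb) @ R
                coords[mask] = inner @ R_s.T + (1.0 - s) * ca + s * cb
        frames.append(
            StateModel(
                ma.with_coords(coords, label=f"morph-frame-{fi}"),
                state_label="frame",
                provenance="interpolated",
                element_transforms=transforms,
            )
        )
    return Trajectory(frames)


def clash_score(model: StructureModel, clash_distance: float = 2.6) -> int:
    """Count of non-bonded atom pairs closer than ``clash_distance``.

    Pairs within one residue, and pairs between sequence-adjacent residues
    of the same chain (i, i+1), are excluded as covalently linked.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    coords = model.coords
    tree = cKDTree(coords)
    count = 0
    for i, j in tree.query_pairs(clash_distance):
        a, b = model.atoms[i], model.atoms[j]
        if a.chain_id == b.chain_id and abs(a.residue_number - b.residue_number) <= 1 \
                and a.insertion_code == b.insertion_code:
            continue
        count += 1
    return count


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if np.allclose(axis, [0.0, 0.0, 1.0], atol=1e-12):
        return np.eye(3)
    if np.allclose(axis, [0.0, 0.0, -1.0], atol=1e-12):
        return Rotation.from_euler("x", 180, degrees=True).as_matrix()
    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis])
    return rot.as_matrix()


def gate_metrics(
    model: StructureModel,
    topology: CarrierTopology,
    params: GateParams = GateParams(),
) -> GateMetrics:
    """Per-side accessibility of the substrate-binding site, by flood fill.

    The model is rotated so the membrane normal is +z, embedded in a grid
    with a 6 A solvent margin; cells within (vdW radius + probe radius) of
    any atom are blocked.  Free cells are flood-filled from the top and
    bottom grid faces separately; a side is accessible when its fill
    reaches a free cell within ``site_contact_distance`` of a binding-site
    atom.  ``gate_thickness`` is the axial extent of the largest contiguous
    run of grid layers in which no near-axis free cell (within
    ``gate_search_radius`` of the axis) is reachable from either face.
    """
    site_residues = topology.binding_site
    if not site_residues:
        raise ValueError("topology has no binding-site residues")
    Rz = _rotation_to_z(np.asarray(params.axis, dtype=float))
    coords = model.coords @ Rz.T
    radii = np.array(
        [VDW_RADII.get(a.element, VDW_RADII["C"]) for a in model.atoms]
    )
    site_mask = np.array(
        [a.chain_id == topology.chain and a.residue_number in site_residues
         for a in model.atoms]
    )
    if not site_mask.any():
        raise ValueError("no binding-site atoms present in the model")

    margin = 6.0
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    h = params.grid_spacing
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / h)) + 1 for k in range(3))
    axes_1d = [lo[k] + h * np.arange(shape[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes_1d, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    blocked = np.zeros(len(points), dtype=bool)
    for r in np.unique(radii):
        sub = coords[radii == r]
        tree = cKDTree(sub)
        d, _ = tree.query(points, k=1, workers=-1)
        blocked |= d < (r + params.probe_radius)

    # implicit membrane: inside the central axial slab, cells laterally
    # outside the protein footprint are lipid, not solvent — without this a
    # flood from one face would wrap around the outside of the protein
    site_xy = coords[site_mask][:, :2].mean(axis=0)
    z_lo, z_hi = coords[:, 2].min(), coords[:, 2].max()
    half_slab = 0.5 * params.membrane_fraction * (z_hi - z_lo)
    z_mid = 0.5 * (z_lo + z_hi)
    in_slab = np.abs(points[:, 2] - z_mid) <= half_slab
    lateral = np.hypot(points[:, 0] - site_xy[0], points[:, 1] - site_xy[1])
    atom_lateral = np.hypot(coords[:, 0] - site_xy[0], coords[:, 1] - site_xy[1])
    for zi in range(shape[2]):
        z = axes_1d[2][zi]
        if abs(z - z_mid) > half_slab:
            continue
        layer_atoms = np.abs(coords[:, 2] - z) <= 2.0
        if not layer_atoms.any():
            continue
        footprint = atom_lateral[layer_atoms].max()
        layer_cells = points[:, 2] == z
        blocked |= layer_cells & in_slab & (lateral > footprint)
    free = ~blocked.reshape(shape)

    labels, _ = ndimage.label(free)
    top_labels = set(np.unique(labels[:, :, -1])) - {0}
    bottom_labels = set(np.unique(labels[:, :, 0])) - {0}

    site_coords = coords[site_mask]
    site_tree = cKDTree(site_coords)
    free_idx = np.flatnonzero(free.ravel())
    d_site, _ = site_tree.query(points[free_idx], k=1, workers=-1)
    near_site = free_idx[d_site <= params.site_contact_distance]
    near_site_labels = set(labels.ravel()[near_site]) - {0}

    plus_is_matrix = params.matrix_side_sign > 0
    matrix_labels = top_labels if plus_is_matrix else bottom_labels
    cyto_labels = bottom_labels if plus_is_matrix else top_labels
    accessible_matrix = bool(near_site_labels & matrix_labels)
    accessible_cyto = bool(near_site_labels & cyto_labels)

    # gate thickness: z-layers with no face-connected free cell near the axis
    axis_xy = site_coords[:, :2].mean(axis=0)
    near_axis = (
        (points[:, 0] - axis_xy[0]) ** 2 + (points[:, 1] - axis_xy[1]) ** 2
    ) <= params.gate_search_radius**2
    near_axis = near_axis.reshape(shape)
    reachable = np.isin(labels, sorted(top_labels | bottom_labels))
    open_layer = (near_axis & reachable).any(axis=(0, 1))
    thickness = 0
    run = 0
    for is_open in open_layer:
        run = 0 if is_open else run + 1
        thickness = max(thickness, run)
    return GateMetrics(
        accessible_from_matrix=accessible_matrix,
        accessible_from_cytoplasm=accessible_cyto,
        gate_thickness=thickness * h,
        clash_count=clash_score(model),
    )


def find_occluded_frames(
    trajectory: Trajectory,
    topology: CarrierTopology,
    params: GateParams = GateParams(),
) -> list[int]:
    """Indices of trajectory frames whose binding site is sealed both ways."""
    if trajectory.n_frames < 3:
        raise ValueError("need at least 3 frames to search for occlusion")
    return [
        i for i, frame in enumerate(trajectory.frames)
        if gate_metrics(frame.model, topology, params).occluded
    ]
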