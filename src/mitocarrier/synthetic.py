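"""Idealized helical-bundle generators with known ground truth.

Every quantitative operation in the package (axis fits, kink angles, rigid
superposition, symmetrization, contact detection, occlusion analysis) is
validated against structures built here, where the true kink angles,
rigid-body transforms, planted charge-pair distances and symmetry axis are
known by construction.  The generators emulate the mitochondrial-carrier
fold at the level the analysis needs: six transmembrane helices around a
central axis with approximate C3 symmetry, optional kinks, pseudo-side-chain
atoms for charged groups, rigid perturbations of sub-elements, and Gaussian
coordinate noise.  They do not attempt side-chain rotamers, loops or lipids.

All randomness is drawn from a ``numpy`` generator seeded through the spec,
so identical inputs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .rigidfit import RigidTransform
from .structure_io import AtomRecord, StructureModel
from .topology import CarrierTopology

__all__ = [
    "SyntheticBundleSpec",
    "make_ideal_helix",
    "make_pseudo_c3_bundle",
    "apply_rigid_perturbation",
    "make_gated_pore",
    "make_state_pair",
]

# Cylindrical placement of N, CA and C relative to the C-alpha helix:
# (radius scale vs CA, phase offset deg, z offset A), derived once from a
# polyalanine backbone built with ideal internal coordinates
# (phi=-63.5, psi=-41.5, omega=180; natural twist 99.2 deg, rise 1.54 A).
# Carbonyl O is placed in the peptide plane (anti to the following N)
# rather than on its own cylinder, which keeps the O(i)..N(i+4) hydrogen
# bond at ~2.9 A and all other non-bonded contacts above 2.9 A.
_BACKBONE_CYL = {
    "N": (1.5274 / 2.2832, -26.447, -0.9081),
    "CA": (1.0, 0.0, 0.0),
    "C": (1.7117 / 2.2832, 27.492, 1.0566),
}
_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O"}
_C_O_BOND = 1.231     # A
_CA_C_O_ANGLE = 120.8  # deg


def _place_dihedral(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Point at given bond/angle/torsion from the chain a-b-c (NeRF step)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


@dataclass(frozen=True)
class SyntheticBundleSpec:
    """Recipe for a pseudo-C3 helical bundle with planted ground truth."""

    n_helices: int = 6
    residues_per_helix: int = 26
    helix_rise: float = 1.5          # A per residue
    twist: float = 100.0             # deg per residue
    bundle_radius: float = 12.0      # A, helix axis to bundle axis
    ca_radius: float = 2.3           # A, C-alpha to helix axis
    helix_gap: int = 10              # numbering gap between consecutive helices
    kinks: list[tuple[int, int, float]] = field(default_factory=list)
    #: (residue_a, residue_b, target distance A, "salt_bridge"|"hbond_brace")
    planted_pairs: list[tuple[int, int, float, str]] = field(default_factory=list)
    #: (residue range, transform applied about the range's centroid)
    perturbations: list[tuple[tuple[int, int], RigidTransform]] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices % 3:
            raise ValueError("n_helices must be divisible by 3")
        if self.residues_per_helix < 8:
            raise ValueError("residues_per_helix must be at least 8")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for _, _, angle in self.kinks:
            if not 0 <= angle < 120:
                raise ValueError(f"kink angle {angle} outside [0, 120)")

    def helix_start(self, index: int) -> int:
        return index * (self.residues_per_helix + self.helix_gap) + 1


def make_ideal_helix(
    n_res: int,
    kink_at: int | None = None,
    kink_angle: float = 0.0,
    rise: float = 1.5,
    twist: float = 100.0,
    ca_radius: float = 2.3,
    chain: str = "A",
    start_residue: int = 1,
    residue_name: str = "ALA",
    label: str = "ideal-helix",
) -> StructureModel:
    """Backbone (N, CA, C, O) of an ideal alpha helix along +z.

    ``kink_at`` is the 1-based residue position within the helix; residues
    beyond it are rigidly rotated by ``kink_angle`` degrees about an axis
    perpendicular to the helix axis through that residue's C-alpha, so the
    angle between the N-side and C-side axis directions equals
    ``kink_angle`` exactly.
    """
    if n_res < 8:
        raise ValueError("helix needs at least 8 residues")
    if kink_at is not None and not 5 <= kink_at <= n_res - 4:
        raise ValueError(
            f"kink position {kink_at} too close to a terminus for {n_res} residues"
        )
    ncc: dict[str, list[np.ndarray]] = {"N": [], "CA": [], "C": []}
    for i in range(n_res):
        phase = np.radians(twist * i)
        for name, (rscale, dphi, dz) in _BACKBONE_CYL.items():
            r = ca_radius * rscale
            phi = phase + np.radians(dphi)
            ncc[name].append(
                np.array([r * np.cos(phi), r * np.sin(phi), rise * i + dz])
            )
    if kink_at is not None and kink_angle != 0.0:
        k = kink_at - 1
        pivot = ncc["CA"][k].copy()
        pivot_phase = np.radians(twist * k)
        # bend about the tangential horizontal direction at the pivot
        axis = np.array([-np.sin(pivot_phase), np.cos(pivot_phase), 0.0])
        R = Rotation.from_rotvec(np.radians(kink_angle) * axis).as_matrix()
        for name in ncc:
            for i in range(k + 1, n_res):
                ncc[name][i] = R @ (ncc[name][i] - pivot) + pivot
    # carbonyl O follows the (possibly kinked) peptide plane
    oxy: list[np.ndarray] = []
    for i in range(n_res):
        if i + 1 < n_res:
            ref, torsion = ncc["N"][i + 1], 180.0
        else:  # C-terminal residue: no next N; keep the helical direction
            ref, torsion = ncc["N"][i], 0.0
        oxy.append(
            _place_dihedral(ref, ncc["CA"][i], ncc["C"][i],
                            _C_O_BOND, _CA_C_O_ANGLE, torsion)
        )
    atoms: list[AtomRecord] = []
    for i in range(n_res):
        for name, pos in (("N", ncc["N"][i]), ("CA", ncc["CA"][i]),
                          ("C", ncc["C"][i]), ("O", oxy[i])):
            atoms.append(
                AtomRecord(
                    chain_id=chain,
                    residue_number=start_residue + i,
                    insertion_code="",
                    residue_name=residue_name,
                    atom_name=name,
                    element=_ELEMENT_OF[name],
                    position=tuple(pos),
                )
            )
    return StructureModel(atoms, label=label)


def _plant_pair_atoms(model: StructureModel, spec: SyntheticBundleSpec) -> StructureModel:
    """Attach single charged-group pseudo-atoms realizing planted distances.

    For a salt bridge the pair becomes LYS(NZ)/ASP(OD1); for a brace
    hydrogen bond TYR(OH)/ASP(OD1).  Each pseudo-atom sits on the line
    between the two C-alphas so the planted atom-atom distance is exact.
    """
    atoms = list(model.atoms)
    chain = model.chains()[0]
    for res_a, res_b, dist, pair_class in spec.planted_pairs:
        if pair_class not in ("salt_bridge", "hbond_brace"):
            raise ValueError(f"unknown pair class {pair_class!r}")
        ca_a = model.atom(chain, res_a, "CA").xyz
        ca_b = model.atom(chain, res_b, "CA").xyz
        sep = np.linalg.norm(ca_b - ca_a)
        u = (ca_b - ca_a) / sep
        ext = (sep - dist) / 2.0
        pos_a = ca_a + ext * u
        pos_b = ca_b - ext * u
        name_a = "NZ" if pair_class == "salt_bridge" else "OH"
        res_name_a = "LYS" if pair_class == "salt_bridge" else "TYR"
        renames = {res_a: res_name_a, res_b: "ASP"}
        atoms = [
            replace(a, residue_name=renames[a.residue_number])
            if a.residue_number in renames and a.chain_id == chain else a
            for a in atoms
        ]
        for res, name, elem, pos in (
            (res_a, name_a, name_a[0], pos_a),
            (res_b, "OD1", "O", pos_b),
        ):
            atoms.append(
                AtomRecord(chain, res, "", renames[res], name, elem, tuple(pos))
            )
    # keep atoms grouped by residue so PDB output stays well-formed
    order = {rid: i for i, rid in enumerate(model.residue_ids())}
    atoms.sort(key=lambda a: order[a.residue_id])
    return StructureModel(atoms, model.label)


def make_pseudo_c3_bundle(
    spec: SyntheticBundleSpec,
) -> tuple[StructureModel, CarrierTopology]:
    """Helical bundle with three-fold pseudosymmetry about +z.

    Helix triplets are placed at 0/120/240 degrees about z, antiparallel
    within each domain (odd helices run N->C along +z, even helices along
    -z), emulating the carrier's six-helix arrangement.  Returns the model
    together with the ground-truth topology: helix spans, domain spans,
    contact points one third into each even helix, and network sets for the
    planted charge pairs (assigned to the cytoplasmic network for pairs on
    the +z side, matrix otherwise).
    """
    n_per_domain = spec.n_helices // 3
    R = spec.residues_per_helix
    height = (R - 1) * spec.helix_rise
    kinks_by_helix: dict[int, tuple[int, float]] = {
        h: (pos, ang) for h, pos, ang in spec.kinks
    }
    all_atoms: list[AtomRecord] = []
    helix_spans: dict[str, tuple[int, int]] = {}
    for j in range(spec.n_helices):
        domain = j // n_per_domain
        slot = j % n_per_domain
        start = spec.helix_start(j)
        kink = kinks_by_helix.get(j)
        helix = make_ideal_helix(
            R,
            kink_at=kink[0] if kink else None,
            kink_angle=kink[1] if kink else 0.0,
            rise=spec.helix_rise,
            twist=spec.twist,
            ca_radius=spec.ca_radius,
            start_residue=start,
        )
        coords = helix.coords
        coords[:, 2] -= height / 2.0
        if j % 2 == 1:  # even-numbered helices run antiparallel
            flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()
            coords = coords @ flip.T
        # spread helices of a domain tangentially, then rotate to the sector
        slot_angle = (slot - (n_per_domain - 1) / 2.0) * 60.0
        sector = Rotation.from_euler("z", 120.0 * domain + slot_angle, degrees=True)
        coords = coords @ sector.as_matrix().T
        offset = sector.apply(np.array([spec.bundle_radius, 0.0, 0.0]))
        coords += offset
        all_atoms.extend(helix.with_coords(coords).atoms)
        helix_spans[f"H{j + 1}"] = (start, start + R - 1)

    model = StructureModel(all_atoms, label=f"c3-bundle-seed{spec.seed}")
    contact_points = {}
    domain_spans = {}
    for d in range(3):
        first = d * n_per_domain
        last = first + n_per_domain - 1
        domain_spans[d + 1] = (spec.helix_start(first), spec.helix_start(last) + R - 1)
        even = f"H{last + 1}"
        contact_points[even] = spec.helix_start(last) + R // 3

    model = _plant_pair_atoms(model, spec)

    cyto, matrix, braces = set(), set(), set()
    chain = model.chains()[0]
    for res_a, res_b, _, pair_class in spec.planted_pairs:
        mean_z = (model.atom(chain, res_a, "CA").xyz[2]
                  + model.atom(chain, res_b, "CA").xyz[2]) / 2.0
        target = cyto if mean_z > 0 else matrix
        if pair_class == "hbond_brace":
            braces.update((res_a, res_b))
            target.update((res_a, res_b))
        else:
            target.update((res_a, res_b))

    truth = CarrierTopology(
        domain_spans=domain_spans,
        contact_points=contact_points,
        helix_spans=helix_spans,
        binding_site=set(contact_points.values()),
        cytoplasmic_network=cyto,
        matrix_network=matrix,
        braces=braces,
        chain=chain,
        name=model.label,
    )

    rng = np.random.default_rng(spec.seed)
    for element, transform in spec.perturbations:
        model, _ = apply_rigid_perturbation(model, element, transform)
    if spec.noise_sigma > 0:
        noisy = model.coords + rng.normal(0.0, spec.noise_sigma, (len(model), 3))
        model = model.with_coords(noisy)
    return model, truth


def apply_rigid_perturbation(
    model: StructureModel,
    element: tuple[int, int] | Sequence[tuple[int, int]],
    transform: RigidTransform,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[StructureModel, RigidTransform]:
    """Rigidly move the atoms of a residue range about the range centroid.

    The rotation acts about the element's centroid, then the transform's
    translation is added; Gaussian noise (if any) is applied to *all* atoms
    afterwards.  Returns the perturbed model and the ground-truth transform
    expressed in the global frame (``x' = R x + t_global``), which is what a
    superposition of the element before/after should recover.
    """
    ranges = [element] if isinstance(element[0], int) else list(element)
    sel = np.array(
        [any(lo <= a.residue_number <= hi for lo, hi in ranges) for a in model.atoms]
    )
    if not sel.any():
        raise ValueError(f"element {ranges} selects no atoms")
    coords = model.coords
    centroid = coords[sel].mean(axis=0)
    R, t = transform.rotation, transform.translation
    coords[sel] = (coords[sel] - centroid) @ R.T + centroid + t
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
    truth = RigidTransform(R, centroid - R @ centroid + t)
    return model.with_coords(coords), truth


def make_gated_pore(
    top_gap: float,
    bottom_gap: float,
    wall_radius: float = 8.0,
    half_height: float = 12.0,
    cap_radius: float = 11.0,
    spacing: float = 1.8,
    label: str = "gated-pore",
) -> StructureModel:
    """Pseudo-atom barrel around +z with sliding caps: the occlusion fixture.

    A cylindrical wall encloses a central binding-site atom at the origin;
    flat caps sit ``top_gap`` / ``bottom_gap`` Angstrom above and below the
    barrel mouths.  A gap of 0 seals that side; a gap much larger than the
    probe-inflated atom radius leaves it open.  Used to construct occluded,
    one-sided-open and open->closed->open test cases with known answers.
    """
    atoms: list[AtomRecord] = [
        AtomRecord("A", 1, "", "GLY", "CA", "C", (0.0, 0.0, 0.0))
    ]

    def add(res: int, pos: np.ndarray) -> None:
        atoms.append(
            AtomRecord("A", res, "", "UNK", f"X{len(atoms) % 100}", "C", tuple(pos))
        )

    n_ring = int(np.ceil(2 * np.pi * wall_radius / spacing))
    for z in np.arange(-half_height, half_height + 1e-9, spacing):
        for k in range(n_ring):
            phi = 2 * np.pi * k / n_ring
            add(2, np.array([wall_radius * np.cos(phi), wall_radius * np.sin(phi), z]))
    for sign, gap, res in ((+1, top_gap, 3), (-1, bottom_gap, 4)):
        z = sign * (half_height + gap)
        for r in np.arange(0.0, cap_radius + 1e-9, spacing):
            n = max(1, int(np.ceil(2 * np.pi * r / spacing)))
            for k in range(n):
                phi = 2 * np.pi * k / n
                add(res, np.array([r * np.cos(phi), r * np.sin(phi), z]))
    return StructureModel(atoms, label=label)


def make_state_pair(
    seed: int = 0,
    core_angle: float = 15.0,
    gate_angle: float = 25.0,
    kink_a: float = 76.0,
    kink_b: float = 43.0,
    percent_identity: float = 75.0,
    pair_distance: float = 3.0,
    noise_sigma: float = 0.0,
    residues_per_helix: int = 30,
) -> tuple[StructureModel, StructureModel, CarrierTopology, dict]:
    """Two synthetic conformational states with planted inter-state motions.

    State A plays the cytoplasmic-open role and state B the matrix-open
    role.  Relative to A, state B has

    - each domain's core element rigidly rocked by ``core_angle`` degrees
      about a membrane-parallel axis through the element centroid,
    - each gate element (even helix from the contact point down) rotated
      ``gate_angle`` degrees about the bundle axis direction through the
      contact-point C-alpha, emulating the inward gate movement,
    - helix H3 rebuilt with its kink changed from ``kink_a`` to ``kink_b``
      degrees at the planted signature proline,
    - three charged pseudo-atom pairs across the gate-element ends formed at
      ``pair_distance`` (absent in A, where the partners are far apart),
    - residue names mutated so global alignment of the two sequences
      recovers ``percent_identity``.

    Returns ``(state_a, state_b, ground-truth topology, truth dict)``.
    """
    R = residues_per_helix
    kink_pos = R - 7  # near the matrix end of the odd helix, flank-fittable
    base_kinks_a = [(2, kink_pos, kink_a)]
    base_kinks_b = [(2, kink_pos, kink_b)]
    spec_a = SyntheticBundleSpec(
        residues_per_helix=R, kinks=base_kinks_a, seed=seed, noise_sigma=0.0
    )
    spec_b = SyntheticBundleSpec(
        residues_per_helix=R, kinks=base_kinks_b, seed=seed, noise_sigma=0.0
    )
    state_a, topo = make_pseudo_c3_bundle(spec_a)
    state_b, _ = make_pseudo_c3_bundle(spec_b)

    # mark the kink residue of H3 as the signature proline in both states
    h3_start = spec_a.helix_start(2)
    pro = h3_start + kink_pos - 1
    topo.signature_prolines = {pro}

    truth_transforms: dict[str, RigidTransform] = {}
    from .topology import derive_elements  # local import avoids cycle at import time

    elements = derive_elements(topo)
    chain = topo.chain
    for d in (1, 2, 3):
        sector = np.radians(120.0 * (d - 1))
        rock_axis = np.array([-np.sin(sector), np.cos(sector), 0.0])
        Rrock = Rotation.from_rotvec(np.radians(core_angle) * rock_axis).as_matrix()
        state_b, t_core = apply_rigid_perturbation(
            state_b, elements.core_elements[d], RigidTransform(Rrock, np.zeros(3))
        )
        truth_transforms[f"core{d}"] = t_core
        # gate elements swing about the contact-point C-alpha (the pivot of
        # the even-helix kink), tilting their ends toward the bundle axis
        gate_lo, gate_hi = elements.gate_elements[d]
        pivot = state_b.atom(chain, gate_lo, "CA").xyz
        helix_angle = np.radians(120.0 * (d - 1) + 30.0)
        swing_axis = np.array([-np.sin(helix_angle), np.cos(helix_angle), 0.0])
        Rgate = Rotation.from_rotvec(np.radians(gate_angle) * swing_axis).as_matrix()
        t_gate = RigidTransform(Rgate, pivot - Rgate @ pivot)
        mask = np.array(
            [gate_lo <= a.residue_number <= gate_hi for a in state_b.atoms]
        )
        coords_b = state_b.coords
        coords_b[mask] = t_gate.apply(coords_b[mask])
        state_b = state_b.with_coords(coords_b)
        truth_transforms[f"gate{d}"] = t_gate

    # plant the cytoplasmic-style network: pairs across neighbouring gate
    # ends, formed in B only; in A the charged arms point radially outward
    # so the partners are far apart, as in the cytoplasmic-open carrier
    pairs = []
    gate_ends = [elements.gate_elements[d][1] for d in (1, 2, 3)]
    for i in range(3):
        res_a = gate_ends[i] - 2
        res_b = gate_ends[(i + 1) % 3] - 7
        pairs.append((res_a, res_b, pair_distance, "salt_bridge"))
    spec_pairs_b = replace(spec_b, planted_pairs=pairs)
    state_b = _plant_pair_atoms(state_b, spec_pairs_b)
    atoms_a = list(state_a.atoms)
    chain = topo.chain
    for res_a, res_b, _, _ in pairs:
        renames = {res_a: "LYS", res_b: "ASP"}
        atoms_a = [
            replace(a, residue_name=renames[a.residue_number])
            if a.residue_number in renames and a.chain_id == chain else a
            for a in atoms_a
        ]
        for res, name, elem in ((res_a, "NZ", "N"), (res_b, "OD1", "O")):
            ca = state_a.atom(chain, res, "CA").xyz
            outward = ca * np.array([1.0, 1.0, 0.0])
            outward /= np.linalg.norm(outward)
            atoms_a.append(
                AtomRecord(chain, res, "", renames[res], name, elem,
                           tuple(ca + 2.0 * outward))
            )
    order = {rid: i for i, rid in enumerate(state_a.residue_ids())}
    atoms_a.sort(key=lambda a: order[a.residue_id])
    state_a = StructureModel(atoms_a, state_a.label)
    for res_a, res_b, _, _ in pairs:
        topo.cytoplasmic_network.update((res_a, res_b))

    # mutate residue names in B so sequence identity equals the target
    rng = np.random.default_rng(seed)
    residues = topo_residue_numbers = [n for _, n, _ in state_a.residue_ids(chain)]
    protected = set().union(
        topo.cytoplasmic_network, topo.matrix_network, topo.signature_prolines
    )
    candidates = [n for n in topo_residue_numbers if n not in protected]
    n_mut = round(len(residues) * (1.0 - percent_identity / 100.0))
    n_mut = min(n_mut, len(candidates))
    mutate = set(rng.choice(candidates, size=n_mut, replace=False).tolist())
    state_b = StructureModel(
        [
            replace(a, residue_name="VAL")
            if a.residue_number in mutate and a.residue_name == "ALA" else a
            for a in state_b.atoms
        ],
        label="synthetic-m-state",
    )
    state_a.label = "synthetic-c-state"

    if noise_sigma > 0:
        state_a = state_a.with_coords(
            state_a.coords + rng.normal(0.0, noise_sigma, (len(state_a), 3))
        )
        state_b = state_b.with_coords(
            state_b.coords + rng.normal(0.0, noise_sigma, (len(state_b), 3))
        )

    truth = {
        "transforms": truth_transforms,
        "core_angle": core_angle,
        "gate_angle": gate_angle,
        "kink_a": kink_a,
        "kink_b": kink_b,
        "kink_residue": pro,
        "planted_pairs": pairs,
        "percent_identity": 100.0 * (1.0 - n_mut / len(residues)),
    }
    return state_a, state_b, topo, truth
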