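"""Building uninhibited conformational-state models.

The two crystal structures are both inhibitor-locked, and each inhibitor
distorts its state: bongkrekic acid displaces domain 1 of the matrix-open
carrier, carboxyatractyloside kinks H2 and H3 of the cytoplasmic-open one.
Following the analysis logic of the carrier study, the uninhibited
matrix-open (m) state is obtained by pseudo-C3 symmetrization of the
BKA-inhibited structure with the domains kept internally rigid, and the
uninhibited cytoplasmic-open (c) state by transplanting the six core/gate
elements of the BKA-inhibited structure onto the CATR-inhibited template.

Symmetrization here is iterative rigid-body averaging about the estimated
three-fold axis rather than a restraint-based optimizer: domain copies are
rotated into a common sector, averaged into a template, and each domain is
rigidly re-fitted onto its sector's template until convergence.  Domains
stay exactly rigid throughout, which is the stated rigid-body limit of the
original restraint weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .rigidfit import (
    CorrespondenceMap,
    RigidTransform,
    align_sequences,
    iterative_superpose,
    kabsch,
)
from .structure_io import BACKBONE_ATOMS, StructureModel
from .topology import CarrierTopology, ElementSet

__all__ = [
    "AxisEstimate",
    "SymmetrizeParams",
    "StateModel",
    "repeat_correspondence",
    "estimate_c3_axis",
    "symmetrize",
    "build_uninhibited_c",
    "build_uninhibited_m",
]


@dataclass(frozen=True)
class AxisEstimate:
    point: np.ndarray
    direction: np.ndarray
    residuals: dict[str, float]  # |rotation angle - 120| per domain pair, deg

    def rotation_about(self, angle_deg: float) -> RigidTransform:
        """Rigid rotation by ``angle_deg`` about this axis line."""
        R = Rotation.from_rotvec(np.radians(angle_deg) * self.direction).as_matrix()
        t = self.point - R @ self.point
        return RigidTransform(R, t)


@dataclass(frozen=True)
class SymmetrizeParams:
    weight: float = 2.0   # documentation of the restraint weight; rigid-body limit
    tol: float = 0.01     # A, max C-alpha movement for convergence
    max_iter: int = 50

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.tol <= 0 or self.max_iter < 1:
            raise ValueError("weight and tol must be positive, max_iter >= 1")


@dataclass
class StateModel:
    model: StructureModel
    state_label: str   # "c" | "m" | "occluded" | "frame"
    provenance: str    # "crystal" | "hybrid" | "symmetrized" | "interpolated"
    element_transforms: dict[str, RigidTransform] = field(default_factory=dict)
    axis: AxisEstimate | None = None
    converged: bool = True


def repeat_correspondence(
    topology: CarrierTopology,
    sequence: str,
    numbers: Sequence[int],
    min_triples: int = 50,
) -> list[tuple[int, int, int]]:
    """Symmetry-related residue triples across the three domains.

    Domains 1:2 and 2:3 are aligned pairwise (global, affine gaps) on their
    subsequences; a triple is reported wherever both alignments place the
    domain-2 residue.  Fewer than ``min_triples`` triples indicates
    misconfigured or too-divergent domains and raises.
    """
    numbers = list(numbers)
    subseqs: dict[int, tuple[str, list[int]]] = {}
    for d, (lo, hi) in topology.domain_spans.items():
        idx = [i for i, n in enumerate(numbers) if lo <= n <= hi]
        subseqs[d] = ("".join(sequence[i] for i in idx), [numbers[i] for i in idx])
    aln12 = align_sequences(
        subseqs[1][0], subseqs[2][0], subseqs[1][1], subseqs[2][1]
    )
    aln23 = align_sequences(
        subseqs[2][0], subseqs[3][0], subseqs[2][1], subseqs[3][1]
    )
    to3 = dict(aln23.pairs)
    triples = [
        (n1, n2, to3[n2]) for n1, n2 in aln12.pairs if n2 in to3
    ]
    if len(triples) < min_triples:
        raise ValueError(
            f"only {len(triples)} symmetry triples found (need {min_triples}); "
            "domain spans are likely misconfigured"
        )
    return triples


def _triplet_cas(
    model: StructureModel, triples: Sequence[tuple[int, int, int]], chain: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int, int]]]:
    cols: list[list[np.ndarray]] = [[], [], []]
    used = []
    for tri in triples:
        try:
            xyz = [model.atom(chain, r, "CA").xyz for r in tri]
        except KeyError:
            continue
        for c, p in zip(cols, xyz):
            c.append(p)
        used.append(tri)
    if len(used) < 3:
        raise ValueError("not enough triples with C-alpha atoms present")
    return np.array(cols[0]), np.array(cols[1]), np.array(cols[2]), used


def _axis_point(R: np.ndarray, t: np.ndarray, direction: np.ndarray) -> np.ndarray:
    # fixed line of the screw transform: solve (I - R) p = t - (t.n) n
    rhs = t - np.dot(t, direction) * direction
    p, *_ = np.linalg.lstsq(np.eye(3) - R, rhs, rcond=None)
    # remove any component along the (singular) axis direction
    return p - np.dot(p, direction) * direction


def estimate_c3_axis(
    model: StructureModel,
    triples: Sequence[tuple[int, int, int]],
    chain: str | None = None,
) -> AxisEstimate:
    """Pseudo-three-fold axis from the inter-domain rigid transforms.

    Rigid fits of the triplet C-alphas, domain 1 onto 2 and domain 2 onto
    3, each yield a rotation of roughly 120 degrees; the axis is the mean
    rotation axis and the per-transform residual is the deviation of the
    rotation angle from 120 degrees.
    """
    chain = chain or model.chains()[0]
    ca1, ca2, ca3, _ = _triplet_cas(model, triples, chain)
    from .rigidfit import rotation_angle

    fits = {"d1->d2": kabsch(ca1, ca2), "d2->d3": kabsch(ca2, ca3)}
    axes, points, residuals = [], [], {}
    reference = None
    for label, fit in fits.items():
        angle, axis = rotation_angle(fit.transform)
        if angle < 30.0:
            raise ValueError(
                f"degenerate inter-domain transform ({label}: {angle:.1f} deg)"
            )
        if reference is None:
            reference = axis
        elif np.dot(axis, reference) < 0:
            axis = -axis
        axes.append(axis)
        points.append(
            _axis_point(fit.transform.rotation, fit.transform.translation, axis)
        )
        residuals[label] = abs(angle - 120.0)
    direction = np.mean(axes, axis=0)
    direction /= np.linalg.norm(direction)
    point = np.mean(points, axis=0)
    return AxisEstimate(point, direction, residuals)


def _domain_atom_mask(
    model: StructureModel, topology: CarrierTopology, domain: int
) -> np.ndarray:
    lo, hi = topology.domain_spans[domain]
    return np.array(
        [a.chain_id == topology.chain and lo <= a.residue_number <= hi
         for a in model.atoms]
    )


def _blend_unassigned(
    model: StructureModel,
    coords: np.ndarray,
    transforms: list[tuple[tuple[int, int], RigidTransform]],
    chain: str,
) -> np.ndarray:
    """Place atoms outside all transformed ranges by linear blending.

    Atoms between two transformed ranges interpolate the two flanking
    placements by residue position; atoms before the first or after the
    last range follow the nearest range's transform.
    """
    transforms = sorted(transforms, key=lambda rt: rt[0][0])
    original = model.coords
    for i, a in enumerate(model.atoms):
        if a.chain_id != chain:
            continue
        n = a.residue_number
        inside = any(lo <= n <= hi for (lo, hi), _ in transforms)
        if inside:
            continue
        prev_t = next_t = None
        prev_hi = next_lo = None
        for (lo, hi), t in transforms:
            if hi < n:
                prev_t, prev_hi = t, hi
            elif lo > n and next_t is None:
                next_t, next_lo = t, lo
        x = original[i]
        if prev_t is None and next_t is None:
            continue
        if prev_t is None:
            coords[i] = next_t.apply(x)
        elif next_t is None:
            coords[i] = prev_t.apply(x)
        else:
            w = (n - prev_hi) / (next_lo - prev_hi)
            coords[i] = (1.0 - w) * prev_t.apply(x) + w * next_t.apply(x)
    return coords


def symmetrize(
    model: StructureModel,
    topology: CarrierTopology,
    triples: Sequence[tuple[int, int, int]],
    params: SymmetrizeParams = SymmetrizeParams(),
) -> StateModel:
    """Impose pseudo-C3 symmetry on the three domains, kept rigid.

    Iterates: estimate the three-fold axis; rotate each domain's triplet
    C-alphas into a common sector (0/-120/-240 degrees about the axis);
    average the three copies into a template; rigidly fit every domain
    (all atoms) onto the template rotated back into its own sector.  Stops
    when no C-alpha moves more than ``params.tol`` or after
    ``params.max_iter`` iterations (then ``converged`` is False).
    Inter-domain linker atoms are blended between the flanking domain
    placements.  Intra-domain geometry is preserved exactly.
    """
    chain = topology.chain
    current = model
    total: dict[int, RigidTransform] = {d: RigidTransform.identity() for d in (1, 2, 3)}
    axis = None
    converged = False
    for _ in range(params.max_iter):
        cas = _triplet_cas(current, triples, chain)[:3]
        # Each cyclic inter-domain fit proposes a three-fold generator
        # (its rotation projected to exactly 120 deg about its axis line).
        # The candidate whose full symmetrization step moves the structure
        # least is applied: with one displaced domain, the clean pair's
        # axis corrects the outlier while leaving the others in place,
        # whereas an axis inferred through the displaced domain would drag
        # the whole carrier after it.
        from .rigidfit import rotation_angle

        cyclic = {(0, 1): kabsch(cas[0], cas[1]),
                  (1, 2): kabsch(cas[1], cas[2]),
                  (2, 0): kabsch(cas[2], cas[0])}
        best = None
        for pair, fit in cyclic.items():
            angle, direction = rotation_angle(fit.transform)
            if angle < 30.0:
                continue
            point = _axis_point(
                fit.transform.rotation, fit.transform.translation, direction
            )
            cand_axis = AxisEstimate(point, direction, {"anchor": abs(angle - 120.0)})
            sector_in = [cand_axis.rotation_about(-120.0 * k) for k in range(3)]
            mapped = [t.apply(ca) for t, ca in zip(sector_in, cas)]
            template = np.mean([mapped[k] for k in pair], axis=0)
            steps = {}
            movement = 0.0
            max_shift = 0.0
            for d in (1, 2, 3):
                target = sector_in[d - 1].inverse().apply(template)
                dfit = kabsch(cas[d - 1], target)
                steps[d] = dfit.transform
                ca_shift = np.linalg.norm(
                    dfit.transform.apply(cas[d - 1]) - cas[d - 1], axis=1
                )
                movement += float(ca_shift.mean())
                max_shift = max(max_shift, float(ca_shift.max()))
            if best is None or movement < best[0]:
                best = (movement, steps, cand_axis, max_shift)
        if best is None:
            raise ValueError("all inter-domain transforms are degenerate (< 30 deg)")
        _, step, axis, max_shift = best
        coords = current.coords
        new_coords = coords.copy()
        for d in (1, 2, 3):
            mask = _domain_atom_mask(current, topology, d)
            new_coords[mask] = step[d].apply(coords[mask])
        ranges = [(topology.domain_spans[d], step[d]) for d in (1, 2, 3)]
        new_coords = _blend_unassigned(current, new_coords, ranges, chain)
        current = current.with_coords(new_coords)
        total = {d: step[d].compose(total[d]) for d in (1, 2, 3)}
        if max_shift < params.tol:
            converged = True
            break
    assert axis is not None
    final_axis = estimate_c3_axis(current, triples, chain)
    return StateModel(
        model=current,
        state_label="m",
        provenance="symmetrized",
        element_transforms={f"domain{d}": total[d] for d in (1, 2, 3)},
        axis=final_axis,
        converged=converged,
    )


def build_uninhibited_c(
    m_model: StructureModel,
    c_template: StructureModel,
    elements: ElementSet,
    correspondence: CorrespondenceMap | None = None,
    reject_elements: Sequence[str] = ("core2", "gate1"),
    chain_m: str | None = None,
    chain_c: str | None = None,
) -> StateModel:
    """Uninhibited cytoplasmic-open model by element transplantation.

    Each of the six core/gate elements of the matrix-state structure is
    independently superposed (backbone least squares) onto the
    corresponding residues of the cytoplasmic-state template; elements
    listed in ``reject_elements`` use iterative outlier rejection, matching
    the observation that only core element 2 and the H2 gate carry
    inhibitor-induced distortions.  Linker atoms between elements are
    placed by per-atom linear blending between the flanking element
    transforms.  Element ranges and output numbering follow ``m_model``.
    """
    chain_m = chain_m or m_model.chains()[0]
    chain_c = chain_c or c_template.chains()[0]
    if correspondence is None:
        shared = sorted(
            {n for _, n, _ in m_model.residue_ids(chain_m)}
            & {n for _, n, _ in c_template.residue_ids(chain_c)}
        )
        correspondence = CorrespondenceMap([(n, n) for n in shared], 100.0)
    to_c = dict(correspondence.pairs)

    coords = m_model.coords
    new_coords = coords.copy()
    transforms: dict[str, RigidTransform] = {}
    named_ranges: list[tuple[tuple[int, int], RigidTransform]] = []
    for name, ranges in elements.element_ranges().items():
        mob, tgt, labels = [], [], []
        for lo, hi in ranges:
            for n in range(lo, hi + 1):
                nc = to_c.get(n)
                if nc is None:
                    continue
                for atom in BACKBONE_ATOMS:
                    try:
                        a = m_model.atom(chain_m, n, atom)
                        b = c_template.atom(chain_c, nc, atom)
                    except KeyError:
                        continue
                    mob.append(a.xyz)
                    tgt.append(b.xyz)
                    labels.append(n)
        if len({*labels}) < 3:
            raise ValueError(f"element {name} has fewer than 3 matched residues")
        mob_arr, tgt_arr = np.array(mob), np.array(tgt)
        if name in reject_elements:
            fit = iterative_superpose(mob_arr, tgt_arr, labels)
        else:
            fit = kabsch(mob_arr, tgt_arr)
        transforms[name] = fit.transform
        mask = np.array(
            [a.chain_id == chain_m
             and any(lo <= a.residue_number <= hi for lo, hi in ranges)
             for a in m_model.atoms]
        )
        new_coords[mask] = fit.transform.apply(coords[mask])
        for rng in ranges:
            named_ranges.append((rng, fit.transform))
    new_coords = _blend_unassigned(m_model, new_coords, named_ranges, chain_m)
    built = m_model.with_coords(new_coords, label="uninhibited-c-state")
    return StateModel(built, "c", "hybrid", transforms)


def build_uninhibited_m(
    m_model: StructureModel,
    topology: CarrierTopology,
    triples: Sequence[tuple[int, int, int]],
    params: SymmetrizeParams = SymmetrizeParams(),
) -> StateModel:
    """Uninhibited matrix-open model: the symmetrized matrix-state structure."""
    state = symmetrize(m_model, topology, triples, params)
    state.state_label = "m"
    state.model.label = "uninhibited-m-state"
    return state
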