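"""Rigid superposition, residue correspondence and displacement analysis.

Least-squares superposition (Kabsch, SVD form with reflection correction)
is the workhorse behind every structural comparison in the package: element
RMSDs between conformational states, rotation angles of core and gate
elements, and the global frame used for displacement fields.  Sequence
correspondence between homologous carriers is established by global affine
alignment (BLOSUM62, gap open 10, extend 0.5) before any cross-structure
fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import BACKBONE_ATOMS, StructureModel

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "CorrespondenceMap",
    "align_sequences",
    "kabsch",
    "iterative_superpose",
    "rotation_angle",
    "displacement_field",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation plus translation, applied as ``x' = R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation matrix has determinant != +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms_used: int
    n_atoms_input: int
    rejected_residues: list = field(default_factory=list)
    cycles: int = 1

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                **self.transform.to_dict(),
                "rmsd": self.rmsd,
                "n_atoms_used": self.n_atoms_used,
                "n_atoms_input": self.n_atoms_input,
                "rejected_residues": list(self.rejected_residues),
                "cycles": self.cycles,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass
class CorrespondenceMap:
    """Aligned residue-number pairs between two sequences/structures."""

    pairs: list[tuple[int, int]]
    percent_identity: float

    def __post_init__(self) -> None:
        a = [p[0] for p in self.pairs]
        b = [p[1] for p in self.pairs]
        if sorted(a) != a or sorted(b) != b or len(set(a)) != len(a) or len(set(b)) != len(b):
            raise ValueError("correspondence pairs must strictly increase in both numberings")

    def b_for_a(self, number_a: int) -> int | None:
        for a, b in self.pairs:
            if a == number_a:
                return b
        return None

    def to_tsv(self, path: str | Path) -> Path:
        lines = ["residue_a\tresidue_b"]
        lines += [f"{a}\t{b}" for a, b in self.pairs]
        Path(path).write_text("\n".join(lines) + "\n")
        return Path(path)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    # do not penalize terminal gaps: sequences may differ in construct ends
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def align_sequences(
    seq_a: str,
    seq_b: str,
    numbers_a: Sequence[int] | None = None,
    numbers_b: Sequence[int] | None = None,
) -> CorrespondenceMap:
    """Global alignment of two one-letter sequences.

    Identity is identical pairs divided by alignment columns, end gaps
    excluded.  ``numbers_a``/``numbers_b`` translate sequence positions to
    author residue numbers; they default to 1-based positions.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    numbers_a = list(numbers_a) if numbers_a is not None else list(range(1, len(seq_a) + 1))
    numbers_b = list(numbers_b) if numbers_b is not None else list(range(1, len(seq_b) + 1))
    if len(numbers_a) != len(seq_a) or len(numbers_b) != len(seq_b):
        raise ValueError("residue-number lists must parallel the sequences")
    # BLOSUM62 has no column for unknowns; scan with X mapped to a rare
    # placeholder that biopython's matrix does carry
    clean = str.maketrans({"U": "C", "O": "K"})
    aln = _make_aligner().align(seq_a.translate(clean), seq_b.translate(clean))[0]
    pairs: list[tuple[int, int]] = []
    n_ident = 0
    n_cols = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((numbers_a[i], numbers_b[j]))
            n_cols += 1
            if seq_a[i] == seq_b[j]:
                n_ident += 1
    # internal gap columns count in the denominator; end gaps do not:
    # columns between the first and last aligned pair = residues of A in
    # that region + residues of B in that region - aligned pairs
    if pairs:
        ia0 = numbers_a.index(pairs[0][0])
        ia1 = numbers_a.index(pairs[-1][0])
        ib0 = numbers_b.index(pairs[0][1])
        ib1 = numbers_b.index(pairs[-1][1])
        span_a = ia1 - ia0 + 1
        span_b = ib1 - ib0 + 1
        n_cols = span_a + span_b - len(pairs)
    identity = 100.0 * n_ident / n_cols if n_cols else 0.0
    return CorrespondenceMap(pairs, identity)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Optimal least-squares rigid superposition of paired point sets.

    Returns the proper rotation and translation minimizing the RMSD of
    ``R @ mobile + t`` against ``target``; a reflection in the SVD solution
    is corrected by flipping the smallest singular direction.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise ValueError(f"need at least 3 paired points, got {n}")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12:
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    diff = mobile @ R.T + t - target
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(RigidTransform(R, t), rmsd, n, n)


def iterative_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    residue_labels: Sequence,
    cutoff_factor: float = 2.0,
    max_cycles: int = 5,
) -> SuperpositionResult:
    """Superposition with per-residue outlier rejection.

    Cycles of fit-and-reject: after each fit, residues whose mean backbone
    deviation exceeds ``cutoff_factor`` times the current RMSD are dropped
    and the fit repeated, stopping when no residue is rejected, fewer than
    half of the input atoms would remain, or ``max_cycles`` is reached.
    This emulates the reject/refit behaviour of interactive superposition
    tools with a pinned, reproducible rule.
    """
    if cutoff_factor <= 1.0:
        raise ValueError("cutoff_factor must exceed 1")
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    labels = list(residue_labels)
    if len(labels) != len(mobile):
        raise ValueError("one residue label per atom is required")
    n_input = len(mobile)
    keep_residues = list(dict.fromkeys(labels))
    rejected: list = []
    result = None
    for cycle in range(1, max_cycles + 1):
        mask = np.array([lab in keep_residues for lab in labels])
        result = kabsch(mobile[mask], target[mask])
        result.n_atoms_input = n_input
        result.cycles = cycle
        if cycle == max_cycles:
            break
        moved = mobile[mask] @ result.transform.rotation.T + result.transform.translation
        dev = np.linalg.norm(moved - target[mask], axis=1)
        per_res: dict = {}
        for lab, d in zip(np.array(labels, dtype=object)[mask], dev):
            per_res.setdefault(lab, []).append(d)
        threshold = cutoff_factor * max(result.rmsd, 1e-12)
        bad = [lab for lab, ds in per_res.items() if float(np.mean(ds)) > threshold]
        if not bad:
            break
        survivors = [lab for lab in keep_residues if lab not in bad]
        if not survivors:
            raise ValueError("outlier rejection removed every residue")
        n_left = sum(labels.count(lab) for lab in survivors)
        if n_left < 0.5 * n_input:
            break
        # only residues actually excluded from the next (and final) fit
        # are reported as rejected
        keep_residues = survivors
        rejected.extend(bad)
    assert result is not None
    result.rejected_residues = rejected
    return result


def rotation_angle(transform: RigidTransform) -> tuple[float, np.ndarray]:
    """Rotation angle in degrees (in [0, 180]) and unit axis of a transform.

    The axis is the +1 eigenvector of the rotation, with sign chosen so the
    angle about it is positive; for the identity the angle is 0 and the axis
    defaults to +z.
    """
    R = transform.rotation
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_theta)))
    if angle < 1e-9:
        return 0.0, np.array([0.0, 0.0, 1.0])
    w, v = np.linalg.eig(R)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis /= np.linalg.norm(axis)
    # orient so that the rotation about +axis is by +angle
    skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if np.dot(skew, axis) < 0:
        axis = -axis
    return angle, axis


def displacement_field(
    model_a: StructureModel,
    model_b: StructureModel,
    correspondence: CorrespondenceMap,
    frame: str = "global-fit",
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> dict[int, float]:
    """Per-residue C-alpha displacement between two models, in Angstrom.

    With ``frame="global-fit"`` all mapped C-alphas of A are first rigidly
    superposed onto B, so the field reports internal rearrangement rather
    than any overall placement difference.  Keys are residue numbers of
    model A.
    """
    if frame not in ("global-fit", "none"):
        raise ValueError(f"unknown frame {frame!r}")
    if not correspondence.pairs:
        raise ValueError("empty correspondence")
    chain_a = chain_a or model_a.chains()[0]
    chain_b = chain_b or model_b.chains()[0]
    ca_a, ca_b, numbers = [], [], []
    for na, nb in correspondence.pairs:
        try:
            a = model_a.atom(chain_a, na, "CA")
            b = model_b.atom(chain_b, nb, "CA")
        except KeyError:
            continue
        ca_a.append(a.xyz)
        ca_b.append(b.xyz)
        numbers.append(na)
    if not numbers:
        raise ValueError("no mapped residues have C-alpha atoms in both models")
    A = np.array(ca_a)
    B = np.array(ca_b)
    if frame == "global-fit":
        fit = kabsch(A, B)
        A = fit.transform.apply(A)
    d = np.linalg.norm(A - B, axis=1)
    return {num: float(x) for num, x in zip(numbers, d)}


def superpose_models(
    mobile: StructureModel,
    target: StructureModel,
    correspondence: CorrespondenceMap | None = None,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
) -> SuperpositionResult:
    """Convenience wrapper: backbone superposition of whole models.

    Without a correspondence, residues are paired by author number on the
    first chain of each model.
    """
    chain_m = mobile.chains()[0]
    chain_t = target.chains()[0]
    if correspondence is None:
        nums_m = {n for _, n, _ in mobile.residue_ids(chain_m)}
        nums_t = {n for _, n, _ in target.residue_ids(chain_t)}
        shared = sorted(nums_m & nums_t)
        pairs = [(n, n) for n in shared]
    else:
        pairs = correspondence.pairs
    cm, ct, labels = [], [], []
    for na, nb in pairs:
        for name in atom_names:
            try:
                a = mobile.atom(chain_m, na, name)
                b = target.atom(chain_t, nb, name)
            except KeyError:
                continue
            cm.append(a.xyz)
            ct.append(b.xyz)
            labels.append(na)
    return kabsch(np.array(cm), np.array(ct))
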