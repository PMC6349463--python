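"""Helix axis fitting and kink-angle measurement.

A kink angle here is the deviation from collinearity of the two helix-axis
directions fitted on either side of a designated break residue: a straight
helix scores ~0 degrees and the angle grows as the helix bends.  The
carrier's odd-numbered helices are L-shaped, kinked at the proline of the
Px[DE]xx[KR] signature motif, and the even-numbered helices kink at the
substrate-binding contact points; both are quantified with this metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure_io import StructureModel, select_atoms

__all__ = ["HelixAxis", "KinkMeasurement", "fit_axis", "kink_angle",
           "kink_report"]


@dataclass(frozen=True)
class HelixAxis:
    point: np.ndarray          # centroid of the fitted C-alphas
    direction: np.ndarray      # unit vector, oriented N -> C
    span: tuple[int, int] | None
    fit_quality: float         # fraction of C-alpha variance explained

    def angle_to(self, other: "HelixAxis") -> float:
        c = float(np.clip(np.dot(self.direction, other.direction), -1.0, 1.0))
        return float(np.degrees(np.arccos(c)))


@dataclass(frozen=True)
class KinkMeasurement:
    break_residue: int
    angle_deg: float
    n_side_axis: HelixAxis
    c_side_axis: HelixAxis


def fit_axis(ca_coords: np.ndarray, span: tuple[int, int] | None = None) -> HelixAxis:
    """Axis of a helical C-alpha trace given in N->C residue order.

    Each window of four consecutive C-alphas yields a local axis direction
    from the cross product of successive bond-difference vectors (both are
    chords perpendicular to the helix axis, so their cross product lies
    along it — exact for an ideal helix of any length); the directions are
    averaged and sign-fixed to point from the N- toward the C-terminus.
    The fit quality is the fraction of positional variance explained by
    the axis for the turn-averaged trace (raw C-alphas carry the helical
    radius, so raw PCA would saturate near 93% even for a perfect helix).
    """
    coords = np.asarray(ca_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("expected an (n, 3) C-alpha array")
    n = len(coords)
    if n < 4:
        raise ValueError(f"axis fit needs at least 4 residues, got {n}")
    bonds = np.diff(coords, axis=0)            # ca[i+1] - ca[i]
    kinks = np.diff(bonds, axis=0)             # perpendicular to the axis
    locals_ = np.cross(kinks[:-1], kinks[1:])  # one per 4-residue window
    norms = np.linalg.norm(locals_, axis=1)
    good = norms > 1e-9
    if not good.any():
        raise ValueError("degenerate (collinear) C-alpha trace")
    dirs = locals_[good] / norms[good, None]
    # consistent orientation before averaging
    dirs[(dirs @ dirs[0]) < 0] *= -1.0
    direction = dirs.mean(axis=0)
    direction /= np.linalg.norm(direction)
    if np.dot(direction, coords[-1] - coords[0]) < 0:
        direction = -direction
    centroid = coords.mean(axis=0)
    # quality on the turn-averaged trace (window of 4 ~ one helical turn)
    if n >= 7:
        smoothed = np.stack([coords[i:i + 4].mean(axis=0) for i in range(n - 3)])
    else:
        smoothed = coords
    centered = smoothed - smoothed.mean(axis=0)
    total = float((centered**2).sum())
    along = float(((centered @ direction) ** 2).sum())
    quality = along / total if total > 0 else 1.0
    return HelixAxis(centroid, direction, span, quality)


def kink_angle(
    model: StructureModel,
    helix_span: tuple[int, int],
    break_residue: int,
    flank: int = 7,
    chain: str | None = None,
) -> KinkMeasurement:
    """Kink angle at a break residue of one helix.

    Axes are fitted to the ``flank`` residues on each side of the break
    (the break residue itself is excluded from both fits); the angle is the
    angle between the two N->C directions, so a straight helix gives ~0.
    The default flank of 7 (about two helical turns) gives stable axes.
    """
    lo, hi = helix_span
    if not (lo + flank <= break_residue <= hi - flank):
        raise ValueError(
            f"break residue {break_residue} needs {flank} flank residues "
            f"inside span {lo}-{hi}"
        )
    chain = chain or model.chains()[0]
    n_coords, _ = select_atoms(
        model, chain=chain,
        residue_ranges=[(break_residue - flank, break_residue - 1)],
        atom_names=("CA",),
    )
    c_coords, _ = select_atoms(
        model, chain=chain,
        residue_ranges=[(break_residue + 1, break_residue + flank)],
        atom_names=("CA",),
    )
    n_axis = fit_axis(n_coords, (break_residue - flank, break_residue - 1))
    c_axis = fit_axis(c_coords, (break_residue + 1, break_residue + flank))
    return KinkMeasurement(break_residue, n_axis.angle_to(c_axis), n_axis, c_axis)


def kink_report(
    measurements: dict[str, KinkMeasurement],
    path: str | Path | None = None,
    flank: int = 7,
) -> str:
    """TSV table of kink measurements keyed by helix name."""
    lines = ["helix\tbreak_residue\tangle_deg\tflank\tn_fit_quality\tc_fit_quality"]
    for helix, m in measurements.items():
        lines.append(
            f"{helix}\t{m.break_residue}\t{m.angle_deg:.2f}\t{flank}\t"
            f"{m.n_side_axis.fit_quality:.4f}\t{m.c_side_axis.fit_quality:.4f}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
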