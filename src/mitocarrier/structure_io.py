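"""Read, write and query macromolecular coordinate sets.

The universal container is :class:`StructureModel`, an ordered list of
:class:`AtomRecord`.  Files are parsed with gemmi (PDB and mmCIF); output is
always PDB, with multi-model files used for trajectories.  Hydrogens and
waters are dropped on input and alternate locations are resolved to a single
copy, because every downstream metric (superposition, kink angles, contact
networks, cavity accessibility) is defined on a single protein conformer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "read_structure",
    "write_structure",
    "extract_sequence",
    "select_atoms",
    "BACKBONE_ATOMS",
]

#: Fixed backbone atom order used by all backbone selections.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues that still carry a parent identity
    "MSE": "M", "SEC": "U", "PYL": "O",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom with author-numbered identity and position in Angstrom."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.atom_name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class StructureModel:
    """Ordered atomic model.

    Atom identity (chain, residue number, insertion code, atom name) is
    unique after altloc resolution; residue numbers within a chain are
    ordered but need not be consecutive.
    """

    atoms: list[AtomRecord] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """All positions as an (n_atoms, 3) array, in input order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residue_ids(self, chain: str | None = None) -> list[tuple[str, int, str]]:
        """Ordered unique residue ids, optionally restricted to one chain."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            if chain is None or a.chain_id == chain:
                seen.setdefault(a.residue_id, None)
        return list(seen)

    def residue_name(self, chain: str, number: int, icode: str = "") -> str:
        for a in self.atoms:
            if a.residue_id == (chain, number, icode):
                return a.residue_name
        raise KeyError(f"residue {chain}/{number}{icode} not in model")

    def atom(self, chain: str, number: int, name: str, icode: str = "") -> AtomRecord:
        for a in self.atoms:
            if a.residue_id == (chain, number, icode) and a.atom_name == name:
                return a
        raise KeyError(f"atom {chain}/{number}{icode}/{name} not in model")

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "StructureModel":
        """Copy of the model with every position replaced (order preserved)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [replace(a, position=tuple(p)) for a, p in zip(self.atoms, coords)]
        return StructureModel(atoms, self.label if label is None else label)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return self.with_coords(new)

    def subset(self, residue_ids: Iterable[tuple[str, int, str]]) -> "StructureModel":
        wanted = set(residue_ids)
        return StructureModel(
            [a for a in self.atoms if a.residue_id in wanted], self.label
        )


def _resolve_altlocs(atoms: list[AtomRecord], policy: str) -> list[AtomRecord]:
    if policy not in ("highest_occupancy", "first"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    groups: dict[tuple, list[AtomRecord]] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (*a.residue_id, a.atom_name)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    out = []
    for key in order:
        group = groups[key]
        if len(group) == 1 or policy == "first":
            best = group[0]
        else:
            # highest occupancy; ties broken by lowest altloc letter ("A" first)
            best = min(group, key=lambda a: (-a.occupancy, a.altloc or "~"))
        out.append(replace(best, altloc=""))
    return out


def read_structure(
    path: str | Path,
    model_index: int = 0,
    chains: Sequence[str] | None = None,
    altloc_policy: str = "highest_occupancy",
    include_waters: bool = False,
    include_hydrogens: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    model_index
        Zero-based index into the file's MODEL records.
    chains
        Chain ids to keep; ``None`` keeps everything.  A requested chain
        missing from the file raises ``KeyError`` naming it.
    altloc_policy
        ``"highest_occupancy"`` (ties go to altloc "A") or ``"first"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if not 0 <= model_index < len(st):
        raise IndexError(
            f"model index {model_index} out of range: {path.name} has {len(st)} model(s)"
        )
    model = st[model_index]
    present = [ch.name for ch in model]
    if chains is not None:
        missing = [c for c in chains if c not in present]
        if missing:
            raise KeyError(
                f"chain(s) {missing} not in {path.name}; available: {present}"
            )
    atoms: list[AtomRecord] = []
    for ch in model:
        if chains is not None and ch.name not in chains:
            continue
        for res in ch:
            if not include_waters and (res.is_water() or res.name in _WATER_NAMES):
                continue
            for at in res:
                if not include_hydrogens and at.element.name in ("H", "D"):
                    continue
                atoms.append(
                    AtomRecord(
                        chain_id=ch.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        residue_name=res.name,
                        atom_name=at.name,
                        element=at.element.name,
                        position=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        altloc=(at.altloc or "").strip(),
                    )
                )
    return StructureModel(_resolve_altlocs(atoms, altloc_policy), label=path.stem)


def _to_gemmi(models: Sequence[StructureModel], name: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    for i, m in enumerate(models):
        gm = gemmi.Model(i + 1)
        by_chain: dict[str, gemmi.Chain] = {}
        last_res: dict[str, tuple] = {}
        for a in m.atoms:
            ch = by_chain.get(a.chain_id)
            if ch is None:
                ch = gemmi.Chain(a.chain_id)
                by_chain[a.chain_id] = ch
            rid = (a.residue_number, a.insertion_code, a.residue_name)
            if last_res.get(a.chain_id) != rid:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
                ch.add_residue(res)
                last_res[a.chain_id] = rid
            res = ch[len(ch) - 1]
            at = gemmi.Atom()
            at.name = a.atom_name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*[round(v, 3) for v in a.position])
            at.occ = a.occupancy
            res.add_atom(at)
        for ch in by_chain.values():
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(
    model: StructureModel | Sequence[StructureModel], path: str | Path
) -> Path:
    """Write a model (or a trajectory of models) as a PDB file.

    Trajectories become multi-model PDB files (MODEL/ENDMDL blocks), one
    block per frame.  Coordinates are serialized to 3 decimals.
    """
    path = Path(path)
    models = [model] if isinstance(model, StructureModel) else list(model)
    if not models or any(len(m) == 0 for m in models):
        raise ValueError("refusing to write an empty model")
    st = _to_gemmi(models, path.stem)
    opts = gemmi.PdbWriteOptions()
    opts.cryst1_record = False
    st.write_pdb(str(path), opts)
    return path


def extract_sequence(
    model: StructureModel, chain: str
) -> tuple[str, list[int]]:
    """One-letter sequence of a chain plus the parallel residue-number list.

    Nonstandard residues without a tabulated parent map to ``"X"``.  Gaps in
    author numbering are reflected in the number list only; the sequence
    string itself carries no gap characters.
    """
    if chain not in model.chains():
        raise KeyError(f"chain {chain!r} not in model; available: {model.chains()}")
    seq, numbers = [], []
    for cid, num, icode in model.residue_ids(chain):
        name = model.residue_name(cid, num, icode)
        seq.append(_THREE_TO_ONE.get(name, "X"))
        numbers.append(num)
    return "".join(seq), numbers


def write_fasta(
    path: str | Path, sequences: dict[str, str], width: int = 60
) -> Path:
    """Write sequences as FASTA, one record per ``{header: sequence}`` entry."""
    lines = []
    for header, seq in sequences.items():
        lines.append(f">{header}")
        lines.extend(seq[i:i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def select_atoms(
    model: StructureModel,
    chain: str | None = None,
    residue_ranges: Sequence[tuple[int, int]] | None = None,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
    strict: bool = True,
) -> tuple[np.ndarray, list[tuple[str, int, str, str]]]:
    """Coordinates for a (chain, residue-ranges, atom-name) selection.

    Residue ranges are author-numbered and inclusive on both ends.  Output
    order is residue order, then the fixed ``atom_names`` order, independent
    of the atom order inside the file.  In strict mode a residue missing a
    requested atom raises ``KeyError`` naming it; otherwise missing atoms
    are silently omitted.
    """

    def in_ranges(num: int) -> bool:
        if residue_ranges is None:
            return True
        return any(lo <= num <= hi for lo, hi in residue_ranges)

    index: dict[tuple, AtomRecord] = {}
    for a in model.atoms:
        index[(*a.residue_id, a.atom_name)] = a

    coords: list[np.ndarray] = []
    identities: list[tuple[str, int, str, str]] = []
    for cid, num, icode in model.residue_ids(chain):
        if not in_ranges(num):
            continue
        for name in atom_names:
            rec = index.get((cid, num, icode, name))
            if rec is None:
                if strict:
                    raise KeyError(
                        f"residue {cid}/{num}{icode} has no atom {name!r}"
                    )
                continue
            coords.append(rec.xyz)
            identities.append((cid, num, icode, name))
    if not identities and strict:
        raise ValueError("selection matched no atoms")
    arr = np.array(coords) if coords else np.zeros((0, 3))
    return arr, identities
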