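"""Detection and classification of the carrier's polar interaction networks.

The transport cycle is gated by two triplets of inter-domain charge pairs:
the matrix salt-bridge network (from the Px[DE]xx[KR] signature motifs)
closes the matrix side in the cytoplasmic-open state, and the cytoplasmic
network (from the [YF][DE]xx[KR] motifs), reinforced by tyrosine/arginine
braces one helical turn away, closes the cytoplasmic side in the
matrix-open state.  Detection is purely distance-based on charged-group
and hydroxyl/amide side-chain atoms; no hydrogens are placed and no bond
angles are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import StructureModel
from .topology import CarrierTopology

__all__ = [
    "PolarContact",
    "SaltBridgeNetwork",
    "find_polar_contacts",
    "classify_network",
    "compare_states",
]

# side-chain atoms carrying formal charge (histidine included as a donor —
# an inclusive default; no carrier network residue is His)
_POSITIVE_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
_NEGATIVE_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
# hydroxyl / amide side-chain atoms that can brace a charged group
_BRACE_DONOR_ATOMS = {
    "TYR": ("OH",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
}


@dataclass(frozen=True)
class PolarContact:
    residue_a: int
    residue_b: int
    atom_a: str
    atom_b: str
    distance: float
    contact_class: str      # "salt_bridge" | "hbond_brace"
    domain_relation: str    # "intra" | "inter" | "unknown"

    def pair_key(self) -> tuple[int, int]:
        return (min(self.residue_a, self.residue_b), max(self.residue_a, self.residue_b))


@dataclass
class SaltBridgeNetwork:
    contacts: list[PolarContact]
    network_label: str  # "matrix" | "cytoplasmic" | "other"

    @property
    def n_interdomain_polar(self) -> int:
        return sum(1 for c in self.contacts if c.domain_relation == "inter")

    def pair_keys(self) -> set[tuple[int, int]]:
        return {c.pair_key() for c in self.contacts}


def _group_atoms(model: StructureModel, table: dict, chain: str) -> dict[int, list]:
    out: dict[int, list] = {}
    for a in model.atoms:
        if a.chain_id != chain:
            continue
        names = table.get(a.residue_name)
        if names and a.atom_name in names:
            out.setdefault(a.residue_number, []).append(a)
    return out


def find_polar_contacts(
    model: StructureModel,
    topology: CarrierTopology | None = None,
    sb_cutoff: float = 4.0,
    hb_cutoff: float = 3.6,
    chain: str | None = None,
) -> tuple[list[PolarContact], list[int]]:
    """All polar residue-pair contacts in a model.

    A salt bridge is a side-chain N of K/R/H within ``sb_cutoff`` of a
    side-chain carboxylate O of D/E; a brace hydrogen bond is a
    hydroxyl/amide side-chain O or N (Y, S, T, N, Q) within ``hb_cutoff``
    of a charged side-chain atom.  Each residue pair is reported once, at
    its minimum-distance atom pair, ordered so ``residue_a < residue_b``.

    If a topology is given, contacts are tagged intra-/inter-domain and the
    second return value lists topology network/brace residues whose
    side-chain atoms are absent from the model (unevaluable), instead of
    silently dropping them.
    """
    chain = chain or model.chains()[0]
    pos = _group_atoms(model, _POSITIVE_ATOMS, chain)
    neg = _group_atoms(model, _NEGATIVE_ATOMS, chain)
    brace = _group_atoms(model, _BRACE_DONOR_ATOMS, chain)
    charged = {**{r: ats for r, ats in pos.items()}, **{r: ats for r, ats in neg.items()}}

    best: dict[tuple[int, int], PolarContact] = {}

    def consider(res_a, atoms_a, res_b, atoms_b, cutoff, cls):
        if res_a == res_b:
            return
        for aa in atoms_a:
            for ab in atoms_b:
                d = float(np.linalg.norm(aa.xyz - ab.xyz))
                if d > cutoff:
                    continue
                key = (min(res_a, res_b), max(res_a, res_b))
                current = best.get(key)
                if current is not None and (
                    current.contact_class == "salt_bridge" and cls != "salt_bridge"
                ):
                    continue  # a salt bridge outranks a brace for the same pair
                if current is None or d < current.distance or (
                    cls == "salt_bridge" and current.contact_class != "salt_bridge"
                ):
                    rel = "unknown"
                    if topology is not None:
                        da, db = topology.domain_of(key[0]), topology.domain_of(key[1])
                        if da is not None and db is not None:
                            rel = "intra" if da == db else "inter"
                    a_first, b_first = (aa, ab) if res_a < res_b else (ab, aa)
                    best[key] = PolarContact(
                        key[0], key[1], a_first.atom_name, b_first.atom_name,
                        d, cls, rel,
                    )

    for ra, atoms_a in pos.items():
        for rb, atoms_b in neg.items():
            consider(ra, atoms_a, rb, atoms_b, sb_cutoff, "salt_bridge")
    for ra, atoms_a in brace.items():
        for rb, atoms_b in charged.items():
            consider(ra, atoms_a, rb, atoms_b, hb_cutoff, "hbond_brace")

    unevaluable: list[int] = []
    if topology is not None:
        evaluable = set(pos) | set(neg) | set(brace)
        listed = (
            topology.matrix_network | topology.cytoplasmic_network | topology.braces
        )
        unevaluable = sorted(listed - evaluable)

    ordered = sorted(best.values(), key=lambda c: (c.residue_a, c.residue_b))
    return ordered, unevaluable


def classify_network(
    contacts: list[PolarContact], topology: CarrierTopology
) -> dict[str, SaltBridgeNetwork]:
    """Partition contacts into matrix / cytoplasmic / other networks.

    A contact belongs to a named network when both residues are members of
    that network's residue set or its brace set (braces count toward the
    cytoplasmic network, as in the carrier).
    """
    matrix_set = set(topology.matrix_network)
    cyto_set = set(topology.cytoplasmic_network) | set(topology.braces)
    out = {label: SaltBridgeNetwork([], label) for label in ("matrix", "cytoplasmic", "other")}
    for c in contacts:
        pair = {c.residue_a, c.residue_b}
        if pair <= matrix_set:
            out["matrix"].contacts.append(c)
        elif pair <= cyto_set:
            out["cytoplasmic"].contacts.append(c)
        else:
            out["other"].contacts.append(c)
    return out


def compare_states(
    network_a: SaltBridgeNetwork, network_b: SaltBridgeNetwork
) -> tuple[list[PolarContact], list[PolarContact], list[PolarContact]]:
    """Contacts formed, broken and retained going from state A to state B.

    Both networks must use the same residue numbering frame (same protein,
    or one already mapped through a residue correspondence).  Returns
    ``(formed, broken, retained)`` keyed by residue pair: formed contacts
    exist only in B, broken only in A.
    """
    keys_a = network_a.pair_keys()
    keys_b = network_b.pair_keys()
    formed = [c for c in network_b.contacts if c.pair_key() not in keys_a]
    broken = [c for c in network_a.contacts if c.pair_key() not in keys_b]
    retained = [c for c in network_b.contacts if c.pair_key() in keys_a]
    return formed, broken, retained
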