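"""Annotation of the mitochondrial-carrier fold.

A carrier is built from three homologous ~100-residue domains, each with an
odd-numbered transmembrane helix, a short matrix helix, and an even-numbered
transmembrane helix.  This module holds that annotation (helix and domain
spans, the substrate-binding "contact point" residues where the even helices
kink, the matrix and cytoplasmic salt-bridge network residues, braces,
hydrophobic plug and ceiling), scans sequences for the family's conserved
motifs, and derives the core/gate element decomposition used throughout the
conformational analysis: the gate element of a domain is the C-terminal part
of its even-numbered helix from the contact point onward, the core element
is the rest of the domain.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "CarrierTopology",
    "ElementSet",
    "MotifHit",
    "MOTIF_PATTERNS",
    "detect_motif",
    "build_topology",
    "derive_elements",
    "ttaac_topology",
    "scaac2_topology",
]

#: Conserved carrier motifs as regular expressions over one-letter codes.
#: "pi" denotes the small-residue class {G, A, S} (C and T excluded to keep
#: the class conservative; override via a custom pattern if needed).
MOTIF_PATTERNS = {
    "signature": r"P.[DE]..[KR]",
    "cyto_motif": r"[YF][DE]..[KR]",
    "GxxxG": r"G...G",
    "pixxxpi": r"[GAS]...[GAS]",
}

Span = tuple[int, int]


@dataclass(frozen=True)
class MotifHit:
    pattern_id: str
    start: int  # residue number of the first matched position
    matched: str

    def __post_init__(self) -> None:
        if not re.fullmatch(MOTIF_PATTERNS[self.pattern_id], self.matched):
            raise ValueError(
                f"{self.matched!r} does not satisfy pattern {self.pattern_id}"
            )


@dataclass
class CarrierTopology:
    """Residue-level annotation of one carrier chain (author numbering)."""

    domain_spans: dict[int, Span]
    contact_points: dict[str, int] = field(default_factory=dict)
    helix_spans: dict[str, Span] = field(default_factory=dict)
    binding_site: set[int] = field(default_factory=set)
    matrix_network: set[int] = field(default_factory=set)
    cytoplasmic_network: set[int] = field(default_factory=set)
    braces: set[int] = field(default_factory=set)
    hydrophobic_plug: set[int] = field(default_factory=set)
    ceiling: set[int] = field(default_factory=set)
    signature_prolines: set[int] = field(default_factory=set)
    chain: str = "A"
    name: str = ""

    _EVEN_HELIX_FOR_DOMAIN = {1: "H2", 2: "H4", 3: "H6"}

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, full_networks: bool = False) -> None:
        if sorted(self.domain_spans) != [1, 2, 3]:
            raise ValueError("exactly three domains (1, 2, 3) are required")
        spans = [self.domain_spans[d] for d in (1, 2, 3)]
        for lo, hi in spans:
            if lo > hi:
                raise ValueError(f"invalid domain span {lo}-{hi}")
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if hi1 >= lo2:
                raise ValueError(
                    f"domain spans overlap or are out of order: {hi1} >= {lo2}"
                )
        for helix, (lo, hi) in self.helix_spans.items():
            if lo > hi:
                raise ValueError(f"invalid span for {helix}: {lo}-{hi}")
        for domain, helix in self._EVEN_HELIX_FOR_DOMAIN.items():
            cp = self.contact_points.get(helix)
            if cp is None:
                continue
            lo, hi = self.domain_spans[domain]
            if not lo <= cp <= hi:
                raise ValueError(f"contact point {helix}={cp} outside domain {domain}")
            if helix in self.helix_spans:
                hlo, hhi = self.helix_spans[helix]
                if not hlo <= cp <= hhi:
                    raise ValueError(
                        f"contact point {helix}={cp} outside helix span {hlo}-{hhi}"
                    )
        if full_networks:
            for label in ("matrix_network", "cytoplasmic_network"):
                members = getattr(self, label)
                if len(members) != 6:
                    raise ValueError(f"{label} must have exactly 6 members, got {len(members)}")

    def domain_of(self, residue: int) -> int | None:
        for d, (lo, hi) in self.domain_spans.items():
            if lo <= residue <= hi:
                return d
        return None


@dataclass
class ElementSet:
    """Core/gate partition of the three domains.

    ``core_elements[d]`` is a list of residue ranges and ``gate_elements[d]``
    a single range; within each domain the two partition the domain span,
    with the contact-point residue itself belonging to the gate (the pivot
    moves with the kink).
    """

    core_elements: dict[int, list[Span]]
    gate_elements: dict[int, Span]

    def element_ranges(self) -> dict[str, list[Span]]:
        """All six elements keyed ``core1..core3, gate1..gate3``."""
        out: dict[str, list[Span]] = {}
        for d in (1, 2, 3):
            out[f"core{d}"] = list(self.core_elements[d])
            out[f"gate{d}"] = [self.gate_elements[d]]
        return out


def detect_motif(sequence: str, pattern_id: str, numbers: list[int] | None = None) -> list[MotifHit]:
    """All matches of a conserved-motif pattern, overlapping starts allowed.

    ``numbers`` maps sequence positions to residue numbers (defaults to
    1-based positions); hit starts are reported in that numbering.
    """
    if pattern_id not in MOTIF_PATTERNS:
        raise KeyError(
            f"unknown pattern {pattern_id!r}; choose from {sorted(MOTIF_PATTERNS)}"
        )
    if not re.fullmatch(r"[A-Z]*", sequence):
        raise ValueError("sequence must be uppercase one-letter amino-acid codes")
    numbers = numbers if numbers is not None else list(range(1, len(sequence) + 1))
    pattern = re.compile(f"(?=({MOTIF_PATTERNS[pattern_id]}))")
    hits = [
        MotifHit(pattern_id, numbers[m.start()], m.group(1))
        for m in pattern.finditer(sequence)
    ]
    return hits


def build_topology(config: dict | str | Path) -> CarrierTopology:
    """Construct and validate a topology from a configuration mapping.

    ``config`` is a mapping (or path to a JSON file) with keys matching the
    :class:`CarrierTopology` fields; spans are two-element lists, residue
    sets are lists of integers.
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    cfg = dict(config)
    kwargs: dict = {}
    kwargs["domain_spans"] = {int(k): tuple(v) for k, v in cfg.pop("domain_spans").items()}
    if "helix_spans" in cfg:
        kwargs["helix_spans"] = {k: tuple(v) for k, v in cfg.pop("helix_spans").items()}
    if "contact_points" in cfg:
        kwargs["contact_points"] = {k: int(v) for k, v in cfg.pop("contact_points").items()}
    for key in (
        "binding_site", "matrix_network", "cytoplasmic_network", "braces",
        "hydrophobic_plug", "ceiling", "signature_prolines",
    ):
        if key in cfg:
            kwargs[key] = set(cfg.pop(key))
    for key in ("chain", "name"):
        if key in cfg:
            kwargs[key] = cfg.pop(key)
    if cfg:
        raise ValueError(f"unknown topology config keys: {sorted(cfg)}")
    return CarrierTopology(**kwargs)


def derive_elements(topology: CarrierTopology) -> ElementSet:
    """Split each domain into its core and gate elements.

    Gate element d runs from the contact point of the domain's even helix to
    the domain's C-terminal end; the core element is the remainder of the
    domain span.
    """
    core: dict[int, list[Span]] = {}
    gate: dict[int, Span] = {}
    for d in (1, 2, 3):
        lo, hi = topology.domain_spans[d]
        helix = CarrierTopology._EVEN_HELIX_FOR_DOMAIN[d]
        cp = topology.contact_points.get(helix)
        if cp is None:
            raise ValueError(f"no contact point for {helix}; cannot derive elements")
        if cp >= hi:
            raise ValueError(f"contact point {cp} at domain {d} end: empty gate element")
        if cp <= lo:
            raise ValueError(f"contact point {cp} at domain {d} start: empty core element")
        gate[d] = (cp, hi)
        core[d] = [(lo, cp - 1)]
    return ElementSet(core, gate)


def ttaac_topology() -> CarrierTopology:
    """Default annotation for the *T. thermophila* ADP/ATP carrier (TtAac).

    Domain spans, contact points and functional residue sets follow the
    structure of the bongkrekic-acid-inhibited carrier.  Helix spans are
    approximate (chosen consistent with the domain boundaries and the
    helical fragments used to phase the structure) since no standard
    secondary-structure assignment is bundled.
    """
    topo = CarrierTopology(
        domain_spans={1: (13, 107), 2: (116, 211), 3: (220, 306)},
        contact_points={"H2": 88, "H4": 192, "H6": 287},
        helix_spans={
            "H1": (16, 45), "h12": (50, 60), "H2": (70, 107),
            "H3": (116, 152), "h34": (156, 166), "H4": (175, 211),
            "H5": (220, 252), "h56": (257, 267), "H6": (275, 306),
        },
        binding_site={30, 88, 192, 193, 196, 238, 287},
        matrix_network={37, 40, 142, 145, 242, 245},
        cytoplasmic_network={101, 104, 205, 208, 299, 302},
        braces={100, 204, 298},
        hydrophobic_plug={97, 201, 295},
        ceiling={96, 200, 294},
        # Px[DE]xx[KR]: the acidic residue sits at P+2 and the basic at P+5,
        # so the prolines precede the matrix-network charges by two positions
        signature_prolines={35, 140, 240},
        chain="A",
        name="TtAac",
    )
    topo.validate(full_networks=True)
    return topo


def scaac2_topology() -> CarrierTopology:
    """Annotation for *S. cerevisiae* Aac2p, derived from TtAac by the
    residue correspondence between the two carriers (+8 in domain 1, +7 in
    domains 2 and 3, e.g. TtAac R100 = ScAac2 K108, TtAac L135 = ScAac2
    L142, TtAac G291 = ScAac2 G298)."""
    base = ttaac_topology()
    offsets = {1: 8, 2: 7, 3: 7}

    def shift(res: int) -> int:
        d = base.domain_of(res)
        return res + offsets.get(d, 7)

    def shift_span(span: Span) -> Span:
        return (shift(span[0]), shift(span[1]))

    topo = CarrierTopology(
        domain_spans={d: shift_span(s) for d, s in base.domain_spans.items()},
        contact_points={h: shift(r) for h, r in base.contact_points.items()},
        helix_spans={h: shift_span(s) for h, s in base.helix_spans.items()},
        binding_site={shift(r) for r in base.binding_site},
        matrix_network={shift(r) for r in base.matrix_network},
        cytoplasmic_network={shift(r) for r in base.cytoplasmic_network},
        braces={shift(r) for r in base.braces},
        hydrophobic_plug={shift(r) for r in base.hydrophobic_plug},
        ceiling={shift(r) for r in base.ceiling},
        signature_prolines={shift(r) for r in base.signature_prolines},
        chain="A",
        name="ScAac2",
    )
    topo.validate(full_networks=True)
    return topo
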