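"""Compartmentalized CA1 pyramidal-neuron geometry.

The model cell is a chain: soma -> axon initial segment (AIS) -> myelinated
axon with 21 nodes of Ranvier (node_0 ... node_20), where each internodal
stretch between consecutive nodes is the five-section repeat
PNJ-JXP-IND-JXP-PNJ (paranodal junction, juxtaparanode, internode).  Five
passive/active dendritic branches attach in a star to the soma.

Coordinates: the axon lies along +y; the neuron may be displaced laterally
along +x and vertically along +z relative to the stimulation electrode.
All lengths are in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SegmentKind",
    "Segment",
    "Morphology",
    "MorphoParams",
    "build_morphology",
    "segment_positions",
    "validate_morphology",
]


class SegmentKind(str, Enum):
    SOMA = "soma"
    DENDRITE = "dendrite"
    AIS = "AIS"
    NODE = "node"
    PNJ = "PNJ"
    JXP = "JXP"
    IND = "IND"


#: kinds that carry a peri-axonal (sub-myelin) space
PERIAXONAL_KINDS = frozenset({SegmentKind.PNJ, SegmentKind.JXP, SegmentKind.IND})


@dataclass(frozen=True)
class Segment:
    """One computational compartment.

    ``axial_position`` is the midpoint coordinate along the axon axis (y),
    with node_0 starting at y = 0; somatic structures sit at negative y.
    ``section_index`` groups sub-compartments that came from the same
    anatomical section.
    """

    id: int
    kind: SegmentKind
    length: float  # um
    diameter: float  # um
    parent_id: Optional[int]
    axial_position: float  # um (midpoint along y)
    periaxonal_width: Optional[float] = None  # um, internodal kinds only
    section_index: int = 0

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(
                f"segment {self.id}: length and diameter must be positive"
            )
        has_w = self.periaxonal_width is not None
        if has_w != (self.kind in PERIAXONAL_KINDS):
            raise ValueError(
                f"segment {self.id} ({self.kind.value}): periaxonal_width must be "
                "present exactly for PNJ/JXP/IND compartments"
            )


@dataclass(frozen=True)
class MorphoParams:
    """Anatomical defaults for the CA1 pyramidal model.

    The internodal repeat satisfies
    ``2*pnj_length + 2*jxp_length + ind_length + node_length == internode_length``.
    """

    soma_length: float = 15.0
    soma_diameter: float = 10.0  # maximum diameter, treated as uniform
    ais_length: float = 50.0
    ais_diameter: float = 1.0
    dendrite_length: float = 20.0
    dendrite_diameter: float = 2.5
    n_dendrites: int = 5
    axon_diameter: float = 1.0
    internode_length: float = 100.0  # node-center to node-center
    node_length: float = 1.0
    node_diameter: float = 0.7
    pnj_length: float = 3.0
    pnj_diameter: float = 0.7
    jxp_length: float = 5.0
    jxp_diameter: float = 0.8
    ind_length: float = 83.0
    ind_diameter: float = 0.8
    periaxonal_width_pnj: float = 0.004
    periaxonal_width_jxp_ind: float = 0.012
    n_nodes: int = 21

    def validate(self) -> None:
        for name in (
            "soma_length", "soma_diameter", "ais_length", "ais_diameter",
            "dendrite_length", "dendrite_diameter", "axon_diameter",
            "internode_length", "node_length", "node_diameter",
            "pnj_length", "pnj_diameter", "jxp_length", "jxp_diameter",
            "ind_length", "ind_diameter", "periaxonal_width_pnj",
            "periaxonal_width_jxp_ind",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"MorphoParams.{name} must be positive")
        if self.n_nodes < 1 or self.n_dendrites < 0:
            raise ValueError("n_nodes must be >= 1 and n_dendrites >= 0")
        repeat = (
            2 * self.pnj_length + 2 * self.jxp_length
            + self.ind_length + self.node_length
        )
        if not math.isclose(repeat, self.internode_length, rel_tol=0, abs_tol=1e-9):
            raise ValueError(
                "inconsistent section lengths: 2*PNJ + 2*JXP + IND + node = "
                f"{repeat} um != internode spacing {self.internode_length} um"
            )


@dataclass
class Morphology:
    segments: list[Segment]
    node_ids: list[int]
    soma_id: int
    dendrite_ids: list[int]
    params: MorphoParams = field(default_factory=MorphoParams)

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def ids_of_kind(self, kind: SegmentKind) -> list[int]:
        return [s.id for s in self.segments if s.kind is kind]

    def axon_chain_ids(self) -> list[int]:
        """Axonal compartments (nodes + internodal) in axial order."""
        axon = [s for s in self.segments
                if s.kind in PERIAXONAL_KINDS or s.kind is SegmentKind.NODE]
        return [s.id for s in sorted(axon, key=lambda s: s.axial_position)]

    def jxp_adjacent_to_node(self, node_index: int, side: str = "auto") -> int:
        """Id of the JXP compartment nearest a node (``node_index`` in 0..n-1).

        ``side='auto'`` picks the distal side for node 0, otherwise proximal;
        this mirrors the recording convention of the analysis layer.
        """
        node = self.segments[self.node_ids[node_index]]
        jxps = [s for s in self.segments if s.kind is SegmentKind.JXP]
        if side == "auto":
            side = "distal" if node_index == 0 else "proximal"
        if side == "distal":
            cands = [s for s in jxps if s.axial_position > node.axial_position]
        else:
            cands = [s for s in jxps if s.axial_position < node.axial_position]
        if not cands:
            raise ValueError(f"no JXP on the {side} side of node {node_index}")
        return min(cands, key=lambda s: abs(s.axial_position - node.axial_position)).id

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": s.id,
                "kind": s.kind.value,
                "parent": -1 if s.parent_id is None else s.parent_id,
                "length_um": s.length,
                "diam_um": s.diameter,
                "y_um": s.axial_position,
                "periax_width_um": (
                    np.nan if s.periaxonal_width is None else s.periaxonal_width
                ),
            }
            for s in self.segments
        ]
        return pd.DataFrame(rows)


def _n_sub(length: float, dx: float, minimum: int = 1) -> int:
    return max(minimum, int(math.ceil(length / dx - 1e-9)))


def build_morphology(
    params: MorphoParams | None = None,
    spatial_discretization: float = 30.0,
) -> Morphology:
    """Construct the compartment chain from anatomical parameters.

    Sections longer than ``spatial_discretization`` are subdivided into equal
    sub-compartments that inherit the section's kind and peri-axonal width;
    the internode (IND) is always split into at least 3 sub-compartments so
    the peri-axonal diffusion chain is resolved.
    """
    p = params or MorphoParams()
    p.validate()
    if spatial_discretization <= 0:
        raise ValueError("spatial_discretization must be positive")

    segs: list[Segment] = []
    section_counter = 0

    def add_section(kind, length, diam, parent, y_start, width=None, min_sub=1,
                    forward=True):
        nonlocal section_counter
        n = _n_sub(length, spatial_discretization, min_sub)
        sub = length / n
        last = parent
        for i in range(n):
            y_mid = y_start + (i + 0.5) * sub * (1 if forward else -1)
            seg = Segment(
                id=len(segs), kind=kind, length=sub, diameter=diam,
                parent_id=last, axial_position=y_mid,
                periaxonal_width=width, section_index=section_counter,
            )
            segs.append(seg)
            last = seg.id
        section_counter += 1
        return last

    # soma centered below the AIS: AIS spans [-ais_length, 0], soma below it.
    soma_y = -(p.ais_length + p.soma_length / 2.0)
    soma = Segment(
        id=0, kind=SegmentKind.SOMA, length=p.soma_length,
        diameter=p.soma_diameter, parent_id=None, axial_position=soma_y,
        section_index=section_counter,
    )
    segs.append(soma)
    section_counter += 1

    dendrite_ids = []
    for _ in range(p.n_dendrites):
        did = add_section(
            SegmentKind.DENDRITE, p.dendrite_length, p.dendrite_diameter,
            soma.id, soma_y, forward=False,
        )
        dendrite_ids.extend(
            s.id for s in segs if s.section_index == section_counter - 1
        )

    last = add_section(
        SegmentKind.AIS, p.ais_length, p.ais_diameter, soma.id,
        -p.ais_length, forward=True,
    )

    node_ids = []
    y = 0.0
    for i_node in range(p.n_nodes):
        last = add_section(
            SegmentKind.NODE, p.node_length, p.node_diameter, last, y
        )
        node_ids.append(last)
        y += p.node_length
        if i_node == p.n_nodes - 1:
            break
        for kind, length, diam, width, min_sub in (
            (SegmentKind.PNJ, p.pnj_length, p.pnj_diameter,
             p.periaxonal_width_pnj, 1),
            (SegmentKind.JXP, p.jxp_length, p.jxp_diameter,
             p.periaxonal_width_jxp_ind, 1),
            (SegmentKind.IND, p.ind_length, p.ind_diameter,
             p.periaxonal_width_jxp_ind, 3),
            (SegmentKind.JXP, p.jxp_length, p.jxp_diameter,
             p.periaxonal_width_jxp_ind, 1),
            (SegmentKind.PNJ, p.pnj_length, p.pnj_diameter,
             p.periaxonal_width_pnj, 1),
        ):
            last = add_section(kind, length, diam, last, y, width, min_sub)
            y += length

    m = Morphology(
        segments=segs, node_ids=node_ids, soma_id=soma.id,
        dendrite_ids=dendrite_ids, params=p,
    )
    violations = validate_morphology(m)
    if violations:
        raise ValueError("invalid morphology: " + "; ".join(violations))
    return m


def segment_positions(
    m: Morphology, neuron_offset: tuple[float, float] = (0.0, 0.0)
) -> dict[int, tuple[float, float, float]]:
    """3-D midpoint coordinates of every compartment.

    The whole cell lies on a line parallel to the y axis at lateral offset
    ``x`` and height offset ``z``; dendrites are collapsed onto the soma
    midpoint for field-coupling purposes (their 20-um spans are small
    relative to the field length scales).
    """
    x, z = float(neuron_offset[0]), float(neuron_offset[1])
    pos: dict[int, tuple[float, float, float]] = {}
    soma_y = m.segments[m.soma_id].axial_position
    for s in m.segments:
        y = soma_y if s.kind is SegmentKind.DENDRITE else s.axial_position
        pos[s.id] = (x, y, z)
    return pos


def validate_morphology(m: Morphology) -> list[str]:
    """Return human-readable invariant violations (empty list when valid)."""
    p = m.params
    out: list[str] = []
    if len(m.node_ids) != p.n_nodes:
        out.append(
            f"node count: expected {p.n_nodes}, found {len(m.node_ids)}"
        )
    n_dend_sections = len(
        {m.segments[i].section_index for i in m.dendrite_ids}
    )
    if n_dend_sections != p.n_dendrites:
        out.append(
            f"dendrite count: expected {p.n_dendrites}, found {n_dend_sections}"
        )
    for s in m.segments:
        if s.length <= 0 or s.diameter <= 0:
            out.append(f"segment {s.id}: non-positive geometry")
        has_w = s.periaxonal_width is not None
        if has_w != (s.kind in PERIAXONAL_KINDS):
            out.append(f"segment {s.id}: periaxonal width presence mismatch")

    # node spacing and internodal repeat pattern
    node_centers = [m.segments[i].axial_position for i in m.node_ids]
    for a, b in zip(node_centers, node_centers[1:]):
        if not math.isclose(b - a, p.internode_length, abs_tol=1e-6):
            out.append(
                f"node spacing: {b - a:g} um between node centers "
                f"(expected {p.internode_length:g})"
            )
            break

    chain = [m.segments[i] for i in m.axon_chain_ids()]
    ys = [s.axial_position for s in chain]
    if any(b <= a for a, b in zip(ys, ys[1:])):
        out.append("axial positions not strictly increasing along the axon")
    # section-level pattern between consecutive nodes
    section_kinds: list[SegmentKind] = []
    for s in chain:
        if not section_kinds or s.section_index != last_section:
            section_kinds.append(s.kind)
        last_section = s.section_index
    expected_repeat = [
        SegmentKind.PNJ, SegmentKind.JXP, SegmentKind.IND,
        SegmentKind.JXP, SegmentKind.PNJ, SegmentKind.NODE,
    ]
    if section_kinds and section_kinds[0] is not SegmentKind.NODE:
        out.append("axon chain does not start at a node")
    body = section_kinds[1:]
    for i in range(0, len(body), 6):
        if body[i:i + 6] != expected_repeat[: len(body[i:i + 6])]:
            out.append(
                "internodal repeat pattern is not PNJ-JXP-IND-JXP-PNJ-node "
                f"(repeat {i // 6})"
            )
            break
    return out
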