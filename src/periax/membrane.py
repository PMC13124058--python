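"""Channel complement, electrical parameters, and their spatial layout.

Conductance densities follow the electrical-parameter table of the model:
somato-dendritic Na / slow K / fast K / K(Ca) / HVA-Ca, strong AIS Na and K
(printed as ranges; defaults here are the range midpoints), nodal Na_X
(0.86 S/cm2) and M-type K_M (0.02 S/cm2), juxtaparanodal fast K_f
(0.02 S/cm2), and a passive myelin sheath (0.001 S/cm2, 0.1 uF/cm2) over
the internodal sections.

The K reversal is dynamic (Nernst of the local peri-axonal [K+]o) for the
axonal K channels (K_M at nodes, K_f and the juxtaparanodal K leak at the
JXP); somato-dendritic and AIS K channels use the fixed -90 mV baseline,
since only peri-axonal potassium is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .kinetics import DEFAULT_GATES, GateKinetics, apply_overrides, gate_rates
from .morphology import SegmentKind

__all__ = [
    "ChannelSpec",
    "MembraneParams",
    "channel_current",
    "init_steady_state",
    "channel_layout",
]


@dataclass(frozen=True)
class ChannelSpec:
    """One conductance on one morphological region."""

    name: str  # kinetics table key ("" for gateless leaks)
    gmax: float  # S/cm2
    reversal: float | str  # mV, or "K_dyn" for the local Nernst potential
    ca_gated: bool = False  # K(Ca): activation from the Ca pool, no V gates
    is_ca_current: bool = False  # feeds the intracellular Ca pool
    feeds_pool: bool = False  # K efflux feeds the peri-axonal K+ pool


@dataclass
class MembraneParams:
    """Electrical parameters (S/cm2, uF/cm2, mV, Ohm*cm, degC)."""

    cm: float = 1.0
    cm_myelin: float = 0.1
    ra: float = 80.0  # axial resistivity; not printed, standard CNS value
    e_leak: float = -65.0
    e_na: float = 45.0
    e_k: float = -90.0  # baseline; axonal K uses the dynamic Nernst value
    e_ca: float = 140.0
    temperature: float = 37.0
    q10: float = 3.0

    g_na_soma: float = 8e-3
    g_kslow_soma: float = 3e-5
    g_kfast_soma: float = 2e-3
    g_kca_soma: float = 3e-4
    g_cahva_soma: float = 3e-5
    g_leak_soma: float = 3.3e-5

    g_na_ais: float = 0.215  # midpoint of the printed 0.11-0.32 range
    g_k_ais: float = 0.06  # midpoint of the printed 0.02-0.1 range
    g_leak_ais: float = 3.3e-5

    g_nax_node: float = 0.86
    g_km_node: float = 0.02
    g_leak_node: float = 2e-3

    g_kf_jxp: float = 0.02
    #: juxtaparanodal background K conductance with dynamic reversal; this is
    #: the pathway through which peri-axonal K+ depolarizes the fibre.
    g_kleak_jxp: float = 2.5e-3
    g_myelin: float = 1e-3

    # intracellular Ca pool (soma/dendrites) for the K(Ca) conductance
    ca_rest: float = 0.05  # uM
    ca_tau: float = 100.0  # ms
    ca_alpha: float = 0.5  # uM cm2 / (uA ms): influx per unit Ca current
    kca_kd: float = 2.0  # uM, half-activation of K(Ca)

    kinetics_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.cm <= 0 or self.cm_myelin <= 0 or self.ra <= 0:
            raise ValueError("capacitances and axial resistivity must be positive")
        for name, value in vars(self).items():
            if name.startswith("g_") and value < 0:
                raise ValueError(f"MembraneParams.{name} must be >= 0")

    def gate_table(self) -> dict[str, tuple[GateKinetics, ...]]:
        if self.kinetics_overrides:
            return apply_overrides(self.kinetics_overrides)
        return DEFAULT_GATES


def channel_layout(p: MembraneParams) -> dict[SegmentKind, tuple[ChannelSpec, ...]]:
    """Active conductances per morphological region (leaks handled apart).

    Na_X and K_M sit only at nodes, K_f only at the JXP; PNJ and IND carry
    just the passive myelin membrane.
    """
    soma_set = (
        ChannelSpec("Na_soma", p.g_na_soma, p.e_na),
        ChannelSpec("K_fast_soma", p.g_kfast_soma, p.e_k),
        ChannelSpec("K_slow_soma", p.g_kslow_soma, p.e_k),
        ChannelSpec("Ca_HVA", p.g_cahva_soma, p.e_ca, is_ca_current=True),
        ChannelSpec("K_Ca", p.g_kca_soma, p.e_k, ca_gated=True),
    )
    return {
        SegmentKind.SOMA: soma_set,
        SegmentKind.DENDRITE: soma_set,
        SegmentKind.AIS: (
            ChannelSpec("Na_AIS", p.g_na_ais, p.e_na),
            ChannelSpec("K_AIS", p.g_k_ais, p.e_k),
        ),
        SegmentKind.NODE: (
            ChannelSpec("Na_X", p.g_nax_node, p.e_na),
            ChannelSpec("K_M", p.g_km_node, "K_dyn"),
        ),
        SegmentKind.JXP: (
            ChannelSpec("K_f", p.g_kf_jxp, "K_dyn", feeds_pool=True),
            ChannelSpec("K_leak_JXP", p.g_kleak_jxp, "K_dyn"),
        ),
        SegmentKind.PNJ: (),
        SegmentKind.IND: (),
    }


def leak_conductance(p: MembraneParams, kind: SegmentKind) -> float:
    """Passive membrane conductance (S/cm2) per region (myelin included)."""
    return {
        SegmentKind.SOMA: p.g_leak_soma,
        SegmentKind.DENDRITE: p.g_leak_soma,
        SegmentKind.AIS: p.g_leak_ais,
        SegmentKind.NODE: p.g_leak_node,
        SegmentKind.PNJ: p.g_myelin,
        SegmentKind.JXP: p.g_myelin,
        SegmentKind.IND: p.g_myelin,
    }[kind]


def capacitance(p: MembraneParams, kind: SegmentKind) -> float:
    """Specific capacitance (uF/cm2): 0.1 under myelin, 1 elsewhere."""
    if kind in (SegmentKind.PNJ, SegmentKind.JXP, SegmentKind.IND):
        return p.cm_myelin
    return p.cm


def channel_current(
    spec: ChannelSpec,
    gates: tuple[float, ...],
    v: float,
    e: float,
    gate_table: dict[str, tuple[GateKinetics, ...]] | None = None,
) -> float:
    """Ohmic channel current density, mA/cm2, outward positive.

    ``gates`` are the instantaneous activation values (one per gating
    particle, in channel-table order); gate powers come from the kinetics
    table.  For gateless or Ca-gated channels pass the single activation
    value (or an empty tuple for pure ohmic conductances).
    """
    table = DEFAULT_GATES if gate_table is None else gate_table
    open_fraction = 1.0
    if spec.name in table:
        specs = table[spec.name]
        if len(gates) != len(specs):
            raise ValueError(
                f"{spec.name}: expected {len(specs)} gate values, got {len(gates)}"
            )
        for g, gs in zip(gates, specs):
            if not 0.0 <= g <= 1.0:
                raise ValueError(f"{spec.name}: gate value {g} outside [0, 1]")
            open_fraction *= g ** gs.power
    elif gates:
        g = gates[0]
        if not 0.0 <= g <= 1.0:
            raise ValueError(f"{spec.name}: gate value {g} outside [0, 1]")
        open_fraction = g
    return spec.gmax * open_fraction * (v - e)  # S/cm2 * mV = mA/cm2


def init_steady_state(
    p: MembraneParams, v0: float,
    channels: Optional[list[str]] = None,
) -> dict[str, tuple[float, ...]]:
    """Gate values at their voltage steady state for a holding potential.

    Returns ``{channel name: (gate values...)}`` for every voltage-gated
    channel (deterministic; two calls give identical values).
    """
    if not math.isfinite(v0):
        raise ValueError("v0 must be finite")
    table = p.gate_table()
    names = channels if channels is not None else list(table)
    return {
        name: tuple(
            inf for inf, _tau in gate_rates(name, v0, p.temperature, p.q10, table)
        )
        for name in names
    }
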