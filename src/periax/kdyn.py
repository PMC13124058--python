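"""Peri-axonal potassium accumulation and clearance.

Outward K+ current through the juxtaparanodal fast K channels (K_f)
discharges into the nanometre-wide peri-axonal space between axolemma and
myelin.  Accumulated K+ is cleared by (1) Fickian axial diffusion along the
PNJ-JXP-IND-JXP-PNJ chain and radial escape into the bath at the
node-facing paranode ends, and (2) reuptake by Na-K pumps distributed
uniformly along the internodal membrane (2 K+ imported per pump cycle).
The local K reversal potential follows the Nernst equation, which is how
accumulation depolarizes the fibre and ultimately produces conduction
block.

Units: concentrations mM, volumes um3, lengths um, areas for diffusion um2,
membrane areas cm2, currents uA/cm2, time ms.  The bookkeeping unit of ion
amount is mM*um3 (1e-18 mol).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .morphology import Morphology, SegmentKind

__all__ = [
    "FARADAY",
    "KDynParams",
    "PeriaxonalState",
    "fick_flux",
    "nak_pump_current",
    "nernst_potential",
    "build_periaxonal_state",
    "update_periaxonal_K",
]

FARADAY = 96485.332  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)

#: uA/cm2 of K+ current -> mM*um3/ms of amount per cm2 of membrane
CURRENT_TO_AMOUNT = 1e9 / FARADAY


@dataclass
class KDynParams:
    """Peri-axonal K+ parameters.

    ``k_bath`` defaults to 3.66 mM, the concentration whose Nernst
    potential equals the -90 mV baseline K reversal given [K+]i = 106 mM at
    37 degC, so the resting model is exactly consistent with its fixed
    somatic E_K.
    """

    d_coeff: float = 1.85  # um2/ms
    a_pnj: float = 0.009  # um2, axial cross-section at PNJ
    a_jxp_ind: float = 0.03  # um2, axial cross-section at JXP/IND
    a_radial_node: float = 8.16  # um2, radial cross-section at the node
    i_nak_max: float = 2.46  # uA/cm2
    km_k: float = 5.3  # mM
    km_na: float = 27.9  # mM
    na_i: float = 10.0  # mM
    k_i: float = 106.0  # mM
    k_bath: float = 3.66  # mM
    temperature: float = 37.0  # degC
    accumulation_enabled: bool = True
    radial_path_um: float = 3.0  # diffusion length of the nodal exit (~PNJ)
    ko_floor: float = 0.1  # mM

    def validate(self) -> None:
        for name in ("d_coeff", "a_pnj", "a_jxp_ind", "a_radial_node",
                     "km_k", "km_na", "na_i", "k_i", "k_bath",
                     "radial_path_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"KDynParams.{name} must be positive")


def fick_flux(d_coeff: float, area: float, gradient: float) -> float:
    """Fick's-law flux J = D * A * d[K]/dx, in mM*um3/ms.

    Positive flux flows down the gradient (out of the compartment with the
    higher concentration).
    """
    if area <= 0:
        raise ValueError("cross-sectional area must be positive")
    return d_coeff * area * gradient


def nak_pump_current(ko: float, na_i: float, v: float, p: KDynParams) -> float:
    """Na-K pump transport current density, uA/cm2.

    I = I_max * [Ko/(Ko+KmK)] * [Nai^1.5/(Nai^1.5+KmNa^1.5)] * (V+150)/(V+200).
    The pump imports 2 K+ per cycle; callers apply that stoichiometry when
    converting the current into a K+ clearance rate.
    """
    if ko <= 0:
        raise ValueError("[K+]o must be positive")
    if v <= -200.0:
        raise ValueError("pump voltage factor undefined for V <= -200 mV")
    sat_k = ko / (ko + p.km_k)
    na15 = na_i ** 1.5
    sat_na = na15 / (na15 + p.km_na ** 1.5)
    return p.i_nak_max * sat_k * sat_na * (v + 150.0) / (v + 200.0)


def nernst_potential(ko: float, ki: float, temperature: float = 37.0) -> float:
    """Nernst potential of a monovalent cation, mV."""
    if ko <= 0 or ki <= 0:
        raise ValueError("concentrations must be positive")
    t_kelvin = 273.15 + temperature
    return 1e3 * GAS_CONSTANT * t_kelvin / FARADAY * math.log(ko / ki)


@dataclass
class PeriaxonalState:
    """Peri-axonal K+ pools along every internodal chain.

    One pool per internodal compartment; chains (one per internode) are
    contiguous index ranges ``chain_ptr[c]:chain_ptr[c+1]`` running
    PNJ-JXP-IND...-JXP-PNJ between consecutive nodes.  ``g_axial`` holds
    the D*A/dx diffusion conductances (um3/ms) between in-chain neighbours,
    ``g_bath`` the radial exit conductance at both chain ends.
    """

    comp_ids: np.ndarray  # morphology segment id per pool
    ko: np.ndarray  # mM
    volume: np.ndarray  # um3
    area_cm2: np.ndarray  # internodal membrane area per pool
    chain_ptr: np.ndarray  # int, len n_chains+1
    g_axial: np.ndarray  # um3/ms, per in-chain interface (aligned left)
    g_bath: float  # um3/ms, radial exit at chain ends
    # cumulative budgets, mM*um3
    efflux_in: float = 0.0
    diffused_out: float = 0.0
    pumped_out: float = 0.0
    clip_events: int = 0

    def pool_index(self) -> dict[int, int]:
        return {int(c): k for k, c in enumerate(self.comp_ids)}


def build_periaxonal_state(m: Morphology, p: KDynParams) -> PeriaxonalState:
    """Assemble pools, volumes and diffusion conductances from a morphology."""
    p.validate()
    chain_kinds = (SegmentKind.PNJ, SegmentKind.JXP, SegmentKind.IND)
    axon = [m.segments[i] for i in m.axon_chain_ids()]
    comp_ids, vols, areas = [], [], []
    chain_ptr = [0]
    g_axial: list[float] = []
    current_chain: list = []

    def flush_chain():
        nonlocal current_chain
        if not current_chain:
            return
        for a, b in zip(current_chain, current_chain[1:]):
            area = (
                p.a_pnj
                if SegmentKind.PNJ in (a.kind, b.kind)
                else p.a_jxp_ind
            )
            dx = b.axial_position - a.axial_position
            g_axial.append(p.d_coeff * area / dx)
        for s in current_chain:
            comp_ids.append(s.id)
            vols.append(math.pi * s.diameter * s.periaxonal_width * s.length)
            areas.append(math.pi * s.diameter * s.length * 1e-8)
        chain_ptr.append(len(comp_ids))
        current_chain = []

    for s in axon:
        if s.kind in chain_kinds:
            current_chain.append(s)
        else:  # node: chain boundary
            flush_chain()
    flush_chain()

    g_bath = p.d_coeff * p.a_radial_node / p.radial_path_um
    n = len(comp_ids)
    return PeriaxonalState(
        comp_ids=np.asarray(comp_ids, dtype=np.int64),
        ko=np.full(n, p.k_bath, dtype=np.float64),
        volume=np.asarray(vols, dtype=np.float64),
        area_cm2=np.asarray(areas, dtype=np.float64),
        chain_ptr=np.asarray(chain_ptr, dtype=np.int64),
        g_axial=np.asarray(g_axial, dtype=np.float64),
        g_bath=float(g_bath),
    )


def update_periaxonal_K(
    state: PeriaxonalState,
    k_membrane_currents: np.ndarray,
    dt: float,
    p: KDynParams,
    v_membrane: np.ndarray | float = -65.0,
    pump_enabled: bool = True,
    diffusion_enabled: bool = True,
) -> PeriaxonalState:
    """Advance every pool by one time step (in place; state is returned).

    Channel efflux (``k_membrane_currents``, uA/cm2 outward positive, one
    entry per pool) and the Na-K pump are applied explicitly; diffusion is
    applied implicitly (backward Euler) per chain, with the bath held at
    ``k_bath`` beyond the radial exits.  The pump clearance is measured
    relative to its own resting rate at ``k_bath`` so that an unstimulated
    pool is exactly stationary; below-baseline pools therefore recover
    toward ``k_bath`` through the same term.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not p.accumulation_enabled:
        return state
    ko = state.ko
    n = ko.size
    cur = np.broadcast_to(np.asarray(k_membrane_currents, dtype=np.float64), (n,))
    vm = np.broadcast_to(np.asarray(v_membrane, dtype=np.float64), (n,))

    efflux = cur * state.area_cm2 * CURRENT_TO_AMOUNT  # mM um3 / ms
    if pump_enabled:
        sat_na = p.na_i ** 1.5 / (p.na_i ** 1.5 + p.km_na ** 1.5)
        vfac = (vm + 150.0) / (vm + 200.0)
        i_net = p.i_nak_max * sat_na * vfac * (
            ko / (ko + p.km_k) - p.k_bath / (p.k_bath + p.km_k)
        )
        pump = 2.0 * i_net * state.area_cm2 * CURRENT_TO_AMOUNT
    else:
        pump = np.zeros(n)

    src = efflux - pump
    new_ko = np.empty_like(ko)
    diffused = 0.0
    for c in range(state.chain_ptr.size - 1):
        lo, hi = state.chain_ptr[c], state.chain_ptr[c + 1]
        nn = hi - lo
        vol = state.volume[lo:hi]
        diag = vol / dt
        rhs = vol / dt * ko[lo:hi] + src[lo:hi]
        lower = np.zeros(nn)
        upper = np.zeros(nn)
        if diffusion_enabled:
            g = state.g_axial[lo - c:hi - c - 1]  # nn-1 interface values
            diag[:-1] += g
            diag[1:] += g
            lower[1:] = -g
            upper[:-1] = -g
            diag[0] += state.g_bath
            diag[-1] += state.g_bath
            rhs[0] += state.g_bath * p.k_bath
            rhs[-1] += state.g_bath * p.k_bath
        # Thomas solve
        cp = np.empty(nn)
        dp = np.empty(nn)
        cp[0] = upper[0] / diag[0]
        dp[0] = rhs[0] / diag[0]
        for i in range(1, nn):
            denom = diag[i] - lower[i] * cp[i - 1]
            cp[i] = upper[i] / denom
            dp[i] = (rhs[i] - lower[i] * dp[i - 1]) / denom
        x = np.empty(nn)
        x[-1] = dp[-1]
        for i in range(nn - 2, -1, -1):
            x[i] = dp[i] - cp[i] * x[i + 1]
        new_ko[lo:hi] = x
        if diffusion_enabled:
            diffused += state.g_bath * (
                (x[0] - p.k_bath) + (x[-1] - p.k_bath)
            ) * dt

    clipped = new_ko < p.ko_floor
    if clipped.any():
        state.clip_events += int(clipped.sum())
        warnings.warn(
            f"[K+]o clipped at the {p.ko_floor} mM floor in "
            f"{int(clipped.sum())} pools",
            RuntimeWarning,
            stacklevel=2,
        )
        new_ko = np.where(clipped, p.ko_floor, new_ko)

    state.efflux_in += float(np.sum(efflux) * dt)
    state.pumped_out += float(np.sum(pump) * dt)
    state.diffused_out += float(diffused)
    state.ko[:] = new_ko
    return state
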