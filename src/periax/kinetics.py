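"""Hodgkin-Huxley-style gating kinetics for every channel class.

This file is the single authoritative definition of the gate kinetics used
by the model.  Steady-state activation/inactivation curves are Boltzmann
functions

    x_inf(V) = 1 / (1 + exp(-(V - vh) / k))          (k < 0: inactivation)

and voltage-dependent time constants are bell curves

    tau_x(V) = tau_min + tau_amp / (exp((V - vt)/s1) + exp(-(V - vt)/s2))

in ms, defined at the reference temperature of 37 degC and scaled by a Q10
factor (default 3) when the simulation runs at a different temperature.

Every number below is a model choice, exposed through
:class:`~periax.membrane.MembraneParams.kinetics_overrides` so a user can
replace any gate parameter from a run configuration without editing code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = ["GateKinetics", "DEFAULT_GATES", "gate_rates", "q10_factor"]

T_REF_C = 37.0


@dataclass(frozen=True)
class GateKinetics:
    """One gating particle: steady state Boltzmann + bell time constant."""

    name: str
    power: int
    vh: float  # half-activation voltage, mV
    k: float  # slope, mV (negative => inactivation gate)
    tau_min: float  # ms
    tau_amp: float  # ms
    vt: float  # mV, tau peak
    s1: float  # mV
    s2: float  # mV

    def steady_state(self, v: float) -> float:
        return 1.0 / (1.0 + math.exp(-(v - self.vh) / self.k))

    def time_constant(self, v: float, temperature: float = T_REF_C,
                      q10: float = 3.0) -> float:
        tau = self.tau_min + self.tau_amp / (
            math.exp((v - self.vt) / self.s1)
            + math.exp(-(v - self.vt) / self.s2)
        )
        return tau / q10_factor(temperature, q10)


def q10_factor(temperature: float, q10: float = 3.0) -> float:
    """Rate speed-up relative to the 37 degC reference."""
    return q10 ** ((temperature - T_REF_C) / 10.0)


def _g(name, power, vh, k, tau_min, tau_amp, vt, s1, s2):
    return GateKinetics(name, power, vh, k, tau_min, tau_amp, vt, s1, s2)


# Gate tables per channel.  Channel names follow the spatial layout:
# somato-dendritic Na / slow K / fast K / Ca-dependent K / HVA Ca, the AIS
# Na and K, the nodal Na_X and slow M-type K_M, and the juxtaparanodal fast
# K_f.  The somatic scheme is a reduced pyramidal-cell set; the axonal
# schemes follow the fast-axonal-sodium / slow-M / juxtaparanodal-Kv1
# lineage used for myelinated CA1 axons.
DEFAULT_GATES: dict[str, tuple[GateKinetics, ...]] = {
    "Na_soma": (
        _g("m", 3, -33.0, 6.0, 0.05, 0.30, -33.0, 10.0, 10.0),
        _g("h", 1, -50.0, -6.0, 0.30, 6.00, -55.0, 8.0, 8.0),
    ),
    "K_fast_soma": (
        _g("n", 4, -40.0, 9.0, 0.50, 4.00, -40.0, 15.0, 15.0),
    ),
    "K_slow_soma": (
        _g("z", 1, -35.0, 10.0, 20.0, 150.0, -35.0, 15.0, 15.0),
    ),
    "Ca_HVA": (
        _g("m", 2, -20.0, 7.0, 0.50, 1.00, -20.0, 12.0, 12.0),
    ),
    "Na_AIS": (
        _g("m", 3, -52.0, 6.0, 0.02, 0.10, -38.0, 10.0, 10.0),
        _g("h", 1, -55.0, -7.0, 0.30, 4.00, -60.0, 9.0, 9.0),
    ),
    "K_AIS": (
        _g("n", 4, -45.0, 7.0, 0.30, 2.50, -45.0, 12.0, 12.0),
    ),
    "Na_X": (
        _g("m", 3, -45.0, 6.0, 0.015, 0.08, -38.0, 10.0, 10.0),
        _g("h", 1, -66.7, -4.5, 0.60, 6.00, -60.0, 8.0, 8.0),
    ),
    "K_M": (
        _g("z", 1, -43.0, 9.0, 200.0, 3000.0, -43.0, 12.0, 12.0),
    ),
    "K_f": (
        _g("n", 4, -55.0, 5.0, 10.0, 20.0, -54.0, 12.0, 12.0),
    ),
}


def gate_rates(channel: str, v: float, temperature: float = T_REF_C,
               q10: float = 3.0,
               gates: dict[str, tuple[GateKinetics, ...]] | None = None,
               ) -> list[tuple[float, float]]:
    """(steady-state, time-constant ms) for every gate of ``channel`` at ``v``.

    Raises ``KeyError`` for channels without voltage gates (leaks, the
    Ca-dependent K channel).
    """
    if not math.isfinite(v):
        raise ValueError("voltage must be finite")
    table = DEFAULT_GATES if gates is None else gates
    return [
        (g.steady_state(v), g.time_constant(v, temperature, q10))
        for g in table[channel]
    ]


def apply_overrides(
    overrides: dict[str, dict[str, dict[str, float]]],
) -> dict[str, tuple[GateKinetics, ...]]:
    """Return a gate table with ``{channel: {gate: {field: value}}}`` applied."""
    table = {}
    for chan, gates in DEFAULT_GATES.items():
        chan_over = overrides.get(chan, {})
        table[chan] = tuple(
            replace(g, **chan_over.get(g.name, {})) for g in gates
        )
    return table
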