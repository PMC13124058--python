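"""Biphasic pulse trains and extracellular potentials at the compartments.

The stimulating electrode is modelled quasi-statically as a point current
source (optionally a source-sink pair) in an infinite homogeneous isotropic
medium of conductivity sigma:  V = I / (4 pi sigma r).  Externally computed
field maps (e.g. finite-element solutions) can be imported from a gridded
file instead; both routes produce a per-compartment weight in mV per mA of
electrode current, and coupling into the cable is linear in the stimulus
current by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "PulseTrain",
    "ElectrodeConfig",
    "FieldMap",
    "make_pulse_train",
    "extracellular_potential",
    "field_at_segments",
    "load_field_map",
]


@dataclass(frozen=True)
class PulseTrain:
    """Charge-balanced biphasic rectangular pulse train.

    The default polarity is cathodic-first (negative phase leading), 0.1 ms
    per phase, 100 Hz for 10 s.
    """

    frequency: float = 100.0  # Hz
    phase_width: float = 0.1  # ms
    amplitude: float = 0.1  # mA
    polarity: int = -1  # sign of the first phase
    duration: float = 10.0  # s

    def __post_init__(self):
        if self.frequency <= 0 or self.phase_width <= 0 or self.duration <= 0:
            raise ValueError("frequency, phase_width and duration must be positive")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be -1 or +1")
        if 2.0 * self.phase_width * self.frequency >= 1000.0:
            raise ValueError(
                "pulses overlap: frequency * 2*phase_width must stay below 1 s/s"
            )

    @property
    def n_pulses(self) -> int:
        return int(round(self.frequency * self.duration))


@dataclass(frozen=True)
class ElectrodeConfig:
    """Point-source electrode in a homogeneous medium.

    ``model`` is one of ``monopole`` (distant return electrode), ``bipole``
    (return pole offset along z), or ``imported-map``.
    """

    position: tuple[float, float, float] = (0.0, 0.0, 0.0)  # um
    model: str = "monopole"
    sigma: float = 0.3  # S/m, typical gray matter
    bipole_offset: float = 1000.0  # um, return-pole displacement along +z
    min_radius: float = 5.0  # um, electrode-surface proxy
    field_map_path: str | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError("electrode position must be finite")
        if self.model not in ("monopole", "bipole", "imported-map"):
            raise ValueError(f"unknown electrode model {self.model!r}")


@dataclass(frozen=True)
class FieldMap:
    """Per-compartment extracellular potential per unit stimulus current."""

    weights: dict[int, float]  # segment id -> mV/mA

    def as_array(self, order: list[int]) -> np.ndarray:
        return np.asarray([self.weights[i] for i in order], dtype=np.float64)


def make_pulse_train(cfg: PulseTrain, dt: float) -> np.ndarray:
    """Sampled stimulus current (mA) at resolution ``dt`` ms.

    Each pulse is two contiguous rectangular phases of opposite sign and
    equal duration (zero net charge); pulse k starts at k/frequency.
    """
    if cfg.phase_width < 2.0 * dt - 1e-12:
        raise ValueError("phase_width must be at least 2*dt")
    n_steps = int(round(cfg.duration * 1000.0 / dt))
    wave = np.zeros(n_steps, dtype=np.float64)
    period_ms = 1000.0 / cfg.frequency
    n_phase = int(round(cfg.phase_width / dt))
    for k in range(cfg.n_pulses):
        i0 = int(round(k * period_ms / dt))
        i1 = min(i0 + n_phase, n_steps)
        i2 = min(i0 + 2 * n_phase, n_steps)
        wave[i0:i1] = cfg.polarity * cfg.amplitude
        wave[i1:i2] = -cfg.polarity * cfg.amplitude
    return wave


def _point_potential(e: ElectrodeConfig, source, point, current_ma: float) -> float:
    r = math.dist(source, point)
    if r < e.min_radius:
        warnings.warn(
            f"observation point {r:.2f} um from the electrode clamped to the "
            f"{e.min_radius} um surface radius",
            RuntimeWarning,
            stacklevel=3,
        )
        r = e.min_radius
    # I[mA]/(4 pi sigma[S/m] r[um]) -> V; express in mV
    return current_ma * 1e-3 / (4.0 * math.pi * e.sigma * r * 1e-6) * 1e3


def extracellular_potential(
    e: ElectrodeConfig,
    point: tuple[float, float, float],
    current_ma: float = 1.0,
) -> float:
    """Extracellular potential (mV) at ``point`` for electrode current I.

    Monopole: V = I/(4 pi sigma r); bipole: source plus an opposite sink
    displaced by ``bipole_offset`` along +z.  Linear in I.
    """
    v = _point_potential(e, e.position, point, current_ma)
    if e.model == "bipole":
        sink = (
            e.position[0],
            e.position[1],
            e.position[2] + e.bipole_offset,
        )
        v -= _point_potential(e, sink, point, current_ma)
    return v


def field_at_segments(
    e: ElectrodeConfig,
    positions: dict[int, tuple[float, float, float]],
) -> FieldMap:
    """Unit-current potential weight (mV/mA) at every compartment midpoint."""
    if e.model == "imported-map":
        if e.field_map_path is None:
            raise ValueError("imported-map electrode needs field_map_path")
        return load_field_map(e.field_map_path, positions)
    return FieldMap(
        {i: extracellular_potential(e, xyz, 1.0) for i, xyz in positions.items()}
    )


def load_field_map(
    path: str, positions: dict[int, tuple[float, float, float]]
) -> FieldMap:
    """Interpolate an externally computed field grid onto the compartments.

    The file is a CSV table with columns ``x_um, y_um, z_um, v_per_mA``
    forming a full rectilinear grid; trilinear interpolation is used at the
    compartment midpoints, and a compartment outside the grid bounds raises
    an error naming it.
    """
    df = pd.read_csv(path)
    required = {"x_um", "y_um", "z_um", "v_per_mA"}
    if not required.issubset(df.columns):
        raise ValueError(f"field map must provide columns {sorted(required)}")
    xs = np.unique(df["x_um"].to_numpy())
    ys = np.unique(df["y_um"].to_numpy())
    zs = np.unique(df["z_um"].to_numpy())
    if len(df) != xs.size * ys.size * zs.size:
        raise ValueError("field map is not a full rectilinear grid")
    vals = (
        df.sort_values(["x_um", "y_um", "z_um"])["v_per_mA"]
        .to_numpy()
        .reshape(xs.size, ys.size, zs.size)
    )
    interp = RegularGridInterpolator(
        (xs, ys, zs), vals, method="linear", bounds_error=True
    )
    weights = {}
    for i, xyz in positions.items():
        try:
            weights[i] = float(interp(np.asarray(xyz))[0])
        except ValueError as err:
            raise ValueError(
                f"compartment {i} at {xyz} lies outside the field-map grid"
            ) from err
    return FieldMap(weights)
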