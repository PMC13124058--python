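"""Sweep drivers and bifurcation analyses.

Three computational experiments probe how firing patterns bifurcate:
(1) neuron-electrode distance sweeps (equal x = z offsets) and electrode
position sweeps along the axon, (2) bath/initial peri-axonal [K+]o sweeps
with accumulation enabled, and (3) fixed-[K+]o scans with accumulation
disabled, measuring the mean inter-pulse resting potential V_m1 and mean
per-pulse peak potential V_m2 at a named node to localize the abrupt
excitability transition.  All drivers are pure functions of their spec and
deterministic.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import Recording, SimulationConfig, run_simulation
from .spikemetrics import (
    FiringMetrics,
    PatternLabel,
    SpikeTrain,
    classify_pattern,
    conduction_metrics,
    detect_spikes,
    isi_stats,
)

__all__ = [
    "SweepSpec",
    "KoScanResult",
    "PhaseTrajectory",
    "config_hash",
    "analyze_recording",
    "sweep_distance",
    "sweep_electrode_node",
    "sweep_kbath",
    "fixed_ko_scan",
    "detect_transition",
    "phase_trajectory",
    "calibrate_amplitude",
]


def config_hash(cfg: SimulationConfig) -> str:
    """Stable hash of every effective parameter (sweep provenance)."""
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SweepSpec:
    kind: str  # distance | electrode_node | kbath | fixed_ko
    grid: Sequence[float]
    base: SimulationConfig = field(default_factory=SimulationConfig)
    context: str = "simulation"
    analysis_window_s: Optional[tuple[float, float]] = None  # default: final 8 s
    scan_node: int = 0  # fixed_ko: node at which V_m1/V_m2 are measured
    scan_duration_s: float = 3.0  # fixed_ko runs are short; see methods note

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=np.float64)
        if g.size == 0 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be non-empty and strictly increasing")


def _window(cfg: SimulationConfig,
            override: Optional[tuple[float, float]]) -> tuple[float, float]:
    if override is not None:
        return override
    dur = cfg.pulses.duration
    return (max(0.0, dur - 8.0), dur)


def analyze_recording(
    rec: Recording,
    window_s: Optional[tuple[float, float]] = None,
    context: str = "simulation",
    match_window_ms: tuple[float, float] = (0.0, 5.0),
    threshold_mv: float = 0.0,
    refractory_ms: float = 2.0,
) -> FiringMetrics:
    """Initiation/conduction/rate + pattern label over the analysis window.

    Node APs are counted at the stimulated node; the analysis window
    defaults to the final 8 s of the train.
    """
    enode = rec.meta["electrode_node"]
    dur = rec.meta["duration_s"]
    freq = rec.meta["frequency_hz"]
    t0, t1 = window_s if window_s is not None else (max(0.0, dur - 8.0), dur)
    node_lab = f"node_{enode}"
    node = detect_spikes(rec.vm[node_lab], rec.time_s, threshold_mv,
                         refractory_ms, node_lab).window(t0, t1)
    soma = detect_spikes(rec.vm["soma"], rec.time_s, threshold_mv,
                         refractory_ms, "soma").window(t0, t1)
    n_pulses = int(round(freq * (t1 - t0)))
    fm = conduction_metrics(node, soma, n_pulses, match_window_ms,
                            window_s=t1 - t0)
    label = classify_pattern(
        fm.stats, context=context, n_spikes=len(soma),
        window_s=t1 - t0, stim_rate_hz=freq,
    )
    return replace(fm, label=label)


def _metrics_row(cfg: SimulationConfig, window, context) -> dict:
    rec = run_simulation(cfg)
    fm = analyze_recording(rec, _window(cfg, window), context)
    enode = cfg.electrode_node if cfg.electrode_node is not None else 10
    adj = f"jxp_adj_{enode}"
    ko_tr = rec.ko.get(adj)
    t = rec.time_s
    if ko_tr is not None:
        sel = (t >= 4.9) & (t <= 5.4)
        ko_late = float(np.mean(ko_tr[sel])) if sel.any() else float(ko_tr[-1])
    else:
        ko_late = np.nan
    return {
        "initiation_ratio": fm.initiation_ratio,
        "conduction_ratio": fm.conduction_ratio,
        "somatic_rate": fm.somatic_rate,
        "cv": fm.stats.cv,
        "bi": fm.stats.bi,
        "label": fm.label.value,
        "ko_jxp_5s_mM": ko_late,
        "config": config_hash(cfg),
    }


def sweep_distance(spec: SweepSpec) -> pd.DataFrame:
    """Equal x = z diagonal distance sweep with the electrode over node_10."""
    rows = []
    for d in spec.grid:
        cfg = replace(spec.base, neuron_offset=(float(d), float(d)))
        rows.append({"distance_um": float(d),
                     **_metrics_row(cfg, spec.analysis_window_s, spec.context)})
    return pd.DataFrame(rows)


def sweep_electrode_node(spec: SweepSpec) -> pd.DataFrame:
    """Electrode position sweep along the axon at fixed (x, z)."""
    rows = []
    for nn in spec.grid:
        cfg = replace(spec.base, electrode_node=int(nn))
        rows.append({"electrode_node": int(nn),
                     **_metrics_row(cfg, spec.analysis_window_s, spec.context)})
    return pd.DataFrame(rows)


def sweep_kbath(spec: SweepSpec) -> pd.DataFrame:
    """Initial peri-axonal [K+]o sweep (accumulation enabled)."""
    rows = []
    for kb in spec.grid:
        cfg = replace(
            spec.base, kdyn=replace(spec.base.kdyn, k_bath=float(kb),
                                    accumulation_enabled=True),
        )
        rows.append({"k_bath_mM": float(kb),
                     **_metrics_row(cfg, spec.analysis_window_s, spec.context)})
    return pd.DataFrame(rows)


@dataclass
class KoScanResult:
    node: int
    ko_mM: np.ndarray
    vm1_mV: np.ndarray  # mean inter-pulse resting potential
    vm2_mV: np.ndarray  # mean per-pulse peak potential
    transition_mM: Optional[tuple[float, float]] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ko_mM": self.ko_mM, "vm1_mV": self.vm1_mV, "vm2_mV": self.vm2_mV}
        )


def _vm12(rec: Recording, node_label: str,
          window_s: tuple[float, float]) -> tuple[float, float]:
    """V_m1 = mean V over the 2 ms before each pulse; V_m2 = mean per-pulse
    peak V; both averaged over pulses inside the window."""
    t = rec.time_s
    v = rec.vm[node_label]
    freq = rec.meta["frequency_hz"]
    period = 1.0 / freq
    t0, t1 = window_s
    pulses = np.arange(np.ceil(t0 / period) * period, t1 - period, period)
    v1, v2 = [], []
    for tp in pulses:
        pre = (t >= tp - 0.002) & (t < tp)
        cyc = (t >= tp) & (t < tp + period)
        if pre.any() and cyc.any():
            v1.append(float(np.mean(v[pre])))
            v2.append(float(np.max(v[cyc])))
    return float(np.mean(v1)), float(np.mean(v2))


def fixed_ko_scan(spec: SweepSpec) -> KoScanResult:
    """V_m1/V_m2 at a named node across imposed fixed [K+]o levels.

    Accumulation is disabled and the peri-axonal concentration is clamped
    at each grid value; runs are short (APs are highly reproducible without
    accumulation) and analysed over their second half.
    """
    node_lab = f"node_{spec.scan_node}"
    vm1s, vm2s = [], []
    for ko in spec.grid:
        cfg = replace(
            spec.base,
            kdyn=replace(spec.base.kdyn, k_bath=float(ko),
                         accumulation_enabled=False),
            pulses=replace(spec.base.pulses, duration=spec.scan_duration_s),
            record_sites=("soma", f"node_{spec.base.electrode_node or 10}",
                          node_lab),
        )
        rec = run_simulation(cfg)
        half = (spec.scan_duration_s / 2.0, spec.scan_duration_s)
        v1, v2 = _vm12(rec, node_lab, half)
        vm1s.append(v1)
        vm2s.append(v2)
    result = KoScanResult(
        node=spec.scan_node,
        ko_mM=np.asarray(spec.grid, dtype=np.float64),
        vm1_mV=np.asarray(vm1s),
        vm2_mV=np.asarray(vm2s),
    )
    result.transition_mM = detect_transition(result)
    return result


def detect_transition(
    scan: KoScanResult, amplitude_drop_mv: float = 20.0
) -> Optional[tuple[float, float]]:
    """Grid interval across which V_m2 collapses by more than the drop.

    Returns the unique bracketing (ko_low, ko_high); None if no interval
    qualifies; if several do, the first is returned with a warning.
    """
    drops = scan.vm2_mV[:-1] - scan.vm2_mV[1:]
    idx = np.flatnonzero(drops > amplitude_drop_mv)
    if idx.size == 0:
        return None
    if idx.size > 1:
        warnings.warn(
            f"multiple V_m2 collapse intervals found: "
            f"{[(float(scan.ko_mM[i]), float(scan.ko_mM[i + 1])) for i in idx]}",
            RuntimeWarning,
            stacklevel=2,
        )
    i = int(idx[0])
    return float(scan.ko_mM[i]), float(scan.ko_mM[i + 1])


@dataclass
class PhaseTrajectory:
    site: str
    v_mV: np.ndarray
    ko_mM: np.ndarray
    time_s: np.ndarray
    dwell_excitable: np.ndarray  # bool per interpulse interval
    pulse_times_s: np.ndarray


def phase_trajectory(
    rec: Recording, site: str, window_s: tuple[float, float],
    threshold_mv: float = 0.0,
) -> PhaseTrajectory:
    """Paired (V_m, [K+]o) samples at a node plus per-pulse dwell labels.

    [K+]o is read at the recorded pool nearest the site (the flanking JXP
    for a node site); a dwell interval is excitable when the pulse evoked a
    node AP inside it.
    """
    if site not in rec.vm:
        raise KeyError(f"site {site!r} not recorded")
    ko_lab = site if site in rec.ko else None
    if ko_lab is None:
        if site.startswith("node_"):
            cand = f"jxp_adj_{site.split('_')[1]}"
            if cand in rec.ko:
                ko_lab = cand
        if ko_lab is None and rec.ko:
            ko_lab = next(iter(rec.ko))
    if ko_lab is None:
        raise KeyError("recording has no peri-axonal [K+]o trace")
    t = rec.time_s
    sel = (t >= window_s[0]) & (t <= window_s[1])
    freq = rec.meta["frequency_hz"]
    period = 1.0 / freq
    spikes = detect_spikes(rec.vm[site], t, threshold_mv, 2.0, site)
    pulses = np.arange(
        np.ceil(window_s[0] / period) * period, window_s[1] - period, period
    )
    excitable = np.array(
        [np.any((spikes.times >= tp) & (spikes.times < tp + period))
         for tp in pulses]
    )
    return PhaseTrajectory(
        site=site,
        v_mV=rec.vm[site][sel],
        ko_mM=rec.ko[ko_lab][sel],
        time_s=t[sel],
        dwell_excitable=excitable,
        pulse_times_s=pulses,
    )


_calibration_cache: dict[str, float] = {}


def calibrate_amplitude(
    base: SimulationConfig,
    grid_lo: float = 0.03,
    grid_hi: float = 0.1,
    n_grid: int = 6,
    max_extensions: int = 2,
) -> float:
    """Smallest stimulus amplitude giving perfect following at (10, 10) um.

    Scans a log-spaced amplitude grid and returns the smallest value for
    which the near configuration (x = z = 10 um, electrode over node_10)
    yields initiation ratio = conduction ratio = 1.0 over the final 8 s.
    Perfect following must hold at the configured time step and at half
    that step, so the frozen amplitude is a dt-converged operating point
    rather than a numerically fragile threshold.  The grid is extended
    upward decade-by-decade (with a warning) if no value within the
    experimental range suffices.  Deterministic and cached per
    configuration.
    """
    probe = replace(base, neuron_offset=(10.0, 10.0), electrode_node=10)
    key = config_hash(probe) + f":{grid_lo}:{grid_hi}:{n_grid}"
    if key in _calibration_cache:
        return _calibration_cache[key]

    def perfect(cfg):
        fm = analyze_recording(run_simulation(cfg))
        return fm.initiation_ratio >= 1.0 and fm.conduction_ratio >= 1.0

    lo, hi = grid_lo, grid_hi
    for ext in range(max_extensions + 1):
        grid = np.geomspace(lo, hi, n_grid)
        for amp in grid:
            cfg = replace(
                probe, pulses=replace(probe.pulses, amplitude=float(amp))
            )
            if perfect(cfg) and perfect(replace(cfg, dt=cfg.dt / 2)):
                _calibration_cache[key] = float(amp)
                return float(amp)
        warnings.warn(
            f"no amplitude in [{lo:g}, {hi:g}] mA achieves perfect following; "
            "extending the grid upward",
            RuntimeWarning,
            stacklevel=2,
        )
        lo, hi = hi, hi * (grid_hi / grid_lo)
    raise RuntimeError("amplitude calibration failed to reach 1:1 following")
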