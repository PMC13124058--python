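"""Coupled cable / potassium simulation engine.

The spatially discretized cable equation on the soma-dendrite-axon tree is
advanced with an unconditionally stable implicit (backward-Euler) update:
gates advance by exponential integration at the pre-step voltage, ionic
conductances are then frozen over the step so the voltage solve is a linear
tree system (solved directly in O(N)), and the peri-axonal K+ pools advance
by an operator-split step (explicit channel efflux and pump, implicit
diffusion).  Extracellular stimulation enters as equivalent injected
currents proportional to the second spatial difference of the electrode's
unit-current potential weights (the activating function), so coupling is
exactly linear in the stimulus current.

Units inside the kernel: mV, ms, nF, uS, nA, mM, um3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit

from . import kdyn as _kdyn
from .kdyn import KDynParams, build_periaxonal_state
from .membrane import (
    MembraneParams,
    capacitance,
    channel_layout,
    leak_conductance,
)
from .kinetics import q10_factor
from .morphology import (
    Morphology,
    MorphoParams,
    SegmentKind,
    build_morphology,
    segment_positions,
)
from .stimfield import ElectrodeConfig, PulseTrain, field_at_segments, make_pulse_train

__all__ = [
    "SimulationConfig",
    "Recording",
    "CableModel",
    "run_simulation",
    "record_sites_default",
]

AMOUNT_PER_UA_MS = 1e9 / _kdyn.FARADAY  # uA * ms -> mM*um3


@dataclass
class SimulationConfig:
    """Everything needed for one deterministic run."""

    morpho: MorphoParams = field(default_factory=MorphoParams)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    kdyn: KDynParams = field(default_factory=KDynParams)
    pulses: PulseTrain = field(default_factory=PulseTrain)
    electrode: ElectrodeConfig = field(default_factory=ElectrodeConfig)
    electrode_node: Optional[int] = 10  # place electrode above this node
    neuron_offset: tuple[float, float] = (10.0, 10.0)  # (x, z) um
    dt: float = 0.01  # ms; resolves the 0.1 ms pulse phases with 10 steps
    settle_ms: float = 200.0  # quiescent pre-stimulus settling
    v_init: float = -68.0
    spatial_discretization: float = 30.0
    record_interval: float = 0.05  # ms (20 kHz, the experimental rate)
    record_sites: Optional[Sequence[str]] = None  # labels; default set if None
    rng_seed: int = 0  # reserved; core dynamics are deterministic

    def __post_init__(self):
        if self.dt <= 0 or self.record_interval < self.dt:
            raise ValueError("need dt > 0 and record_interval >= dt")
        if self.pulses.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class Recording:
    """Time base (s, 0 = stimulus onset), V_m and [K+]o traces, stimulus echo."""

    time_s: np.ndarray
    vm: dict[str, np.ndarray]  # mV per recorded site label
    ko: dict[str, np.ndarray]  # mM per recorded peri-axonal pool label
    stim: np.ndarray  # mA at the sample times
    sites: dict[str, int]  # label -> segment id
    ko_sites: dict[str, int]
    meta: dict

    def __post_init__(self):
        n = self.time_s.size
        for name, tr in list(self.vm.items()) + list(self.ko.items()):
            if tr.size != n:
                raise ValueError(f"trace {name} length mismatch")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])

    def window(self, t0: float, t1: float) -> "Recording":
        sel = (self.time_s >= t0) & (self.time_s <= t1)
        return Recording(
            time_s=self.time_s[sel],
            vm={k: v[sel] for k, v in self.vm.items()},
            ko={k: v[sel] for k, v in self.ko.items()},
            stim=self.stim[sel],
            sites=self.sites,
            ko_sites=self.ko_sites,
            meta=self.meta,
        )

    def save_h5(self, path) -> None:
        import h5py
        import json

        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.time_s)
            f.create_dataset("stim", data=self.stim)
            for k, v in self.vm.items():
                f.create_dataset(f"vm/{k}", data=v)
            for k, v in self.ko.items():
                f.create_dataset(f"ko/{k}", data=v)
            f.attrs["sites"] = json.dumps(self.sites)
            f.attrs["ko_sites"] = json.dumps(self.ko_sites)
            f.attrs["meta"] = json.dumps(
                {k: v for k, v in self.meta.items()
                 if isinstance(v, (int, float, str, bool, list, tuple))}
            )

    @classmethod
    def load_h5(cls, path) -> "Recording":
        import h5py
        import json

        with h5py.File(path, "r") as f:
            return cls(
                time_s=f["time"][:],
                vm={k: f["vm"][k][:] for k in f["vm"]} if "vm" in f else {},
                ko={k: f["ko"][k][:] for k in f["ko"]} if "ko" in f else {},
                stim=f["stim"][:],
                sites=json.loads(f.attrs["sites"]),
                ko_sites=json.loads(f.attrs["ko_sites"]),
                meta=json.loads(f.attrs["meta"]),
            )

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {"time_s": self.time_s, "stim_mA": self.stim}
        cols.update({f"vm_{k}_mV": v for k, v in self.vm.items()})
        cols.update({f"ko_{k}_mM": v for k, v in self.ko.items()})
        pd.DataFrame(cols).to_csv(path, index=False)


def record_sites_default(m: Morphology, electrode_node: int) -> list[str]:
    """Soma, stimulated node, node_0, and the JXP flanking the stimulated node
    (distal side when the electrode sits over node_0, else proximal)."""
    labels = ["soma", f"node_{electrode_node}", "node_0",
              f"jxp_adj_{electrode_node}"]
    out: list[str] = []
    for lab in labels:  # de-duplicate, preserving order
        if lab not in out:
            out.append(lab)
    return out


# ---------------------------------------------------------------------------
# model assembly


class CableModel:
    """Compiled arrays for one configuration; reusable across stimuli."""

    def __init__(self, cfg: SimulationConfig):
        cfg.membrane.validate()
        cfg.kdyn.validate()
        self.cfg = cfg
        self.morph = build_morphology(cfg.morpho, cfg.spatial_discretization)
        m = self.morph
        if cfg.electrode_node is not None:
            if not 0 <= cfg.electrode_node < len(m.node_ids):
                raise ValueError("electrode_node out of range")
            y_e = m.segments[m.node_ids[cfg.electrode_node]].axial_position
            electrode = replace(cfg.electrode, position=(0.0, y_e, 0.0))
        else:
            electrode = cfg.electrode
        self.electrode = electrode
        self.positions = segment_positions(m, cfg.neuron_offset)
        self.field = field_at_segments(electrode, self.positions)
        self.pax = build_periaxonal_state(m, cfg.kdyn)
        self._assemble()

    # -- label resolution ---------------------------------------------------
    def comp_of_label(self, label: str) -> int:
        m = self.morph
        if label == "soma":
            return m.soma_id
        if label.startswith("node_"):
            return m.node_ids[int(label.split("_")[1])]
        if label.startswith("jxp_adj_"):
            return m.jxp_adjacent_to_node(int(label.split("_")[-1]))
        if label.startswith("seg_"):
            return int(label.split("_")[1])
        raise KeyError(f"unknown site label {label!r}")

    def pool_of_comp(self, comp: int) -> int:
        idx = self.pax.pool_index()
        if comp not in idx:
            raise KeyError(f"segment {comp} has no peri-axonal pool")
        return idx[comp]

    # -- assembly -----------------------------------------------------------
    def _assemble(self) -> None:
        cfg = self.cfg
        m = self.morph
        memb = cfg.membrane
        kp = cfg.kdyn
        n = len(m.segments)
        qf = q10_factor(memb.temperature, memb.q10)
        gate_table = memb.gate_table()

        parent = np.full(n, -1, dtype=np.int64)
        gpa = np.zeros(n)
        area = np.zeros(n)
        c_nf = np.zeros(n)
        gl = np.zeros(n)
        el = np.full(n, memb.e_leak)
        kind_code = np.zeros(n, dtype=np.int64)

        def half_r(seg):  # MOhm-free: plain Ohms
            l_cm = seg.length * 1e-4 / 2.0
            d_cm = seg.diameter * 1e-4
            return 4.0 * memb.ra * l_cm / (math.pi * d_cm * d_cm)

        for s in m.segments:
            area[s.id] = math.pi * s.diameter * s.length * 1e-8  # cm2
            c_nf[s.id] = capacitance(memb, s.kind) * area[s.id] * 1e3
            gl[s.id] = leak_conductance(memb, s.kind) * area[s.id] * 1e6
            kind_code[s.id] = list(SegmentKind).index(s.kind)
            if s.parent_id is not None:
                parent[s.id] = s.parent_id
                r = half_r(s) + half_r(m.segments[s.parent_id])
                gpa[s.id] = 1e6 / r  # uS

        gdiag = gpa.copy()
        for i in range(n):
            if parent[i] >= 0:
                gdiag[parent[i]] += gpa[i]

        w = self.field.as_array([s.id for s in m.segments])
        drive = np.zeros(n)
        for i in range(n):
            if parent[i] >= 0:
                drive[i] += gpa[i] * (w[parent[i]] - w[i])
                drive[parent[i]] += gpa[i] * (w[i] - w[parent[i]])

        # channel instances
        layout = channel_layout(memb)
        pool_of = {int(c): k for k, c in enumerate(self.pax.comp_ids)}
        cols: dict[str, list] = {k: [] for k in (
            "comp", "g", "scheme", "efix", "edyn", "p1", "vh1", "k1",
            "tmin1", "tamp1", "vt1", "s11", "s21", "p2", "vh2", "k2",
            "tmin2", "tamp2", "vt2", "s12", "s22", "feeds", "casrc", "kd",
        )}
        for s in m.segments:
            for spec in layout[s.kind]:
                if spec.gmax <= 0:
                    continue
                cols["comp"].append(s.id)
                cols["g"].append(spec.gmax * area[s.id] * 1e6)  # uS
                dyn = spec.reversal == "K_dyn"
                cols["edyn"].append(1 if dyn else 0)
                cols["efix"].append(memb.e_k if dyn else float(spec.reversal))
                cols["feeds"].append(pool_of[s.id] if spec.feeds_pool else -1)
                cols["casrc"].append(1 if spec.is_ca_current else 0)
                cols["kd"].append(memb.kca_kd)
                if spec.ca_gated:
                    cols["scheme"].append(1)
                    gates = ()
                elif spec.name in gate_table:
                    cols["scheme"].append(0)
                    gates = gate_table[spec.name]
                else:
                    cols["scheme"].append(2)  # ohmic (e.g. JXP K leak)
                    gates = ()
                padded = list(gates) + [None, None]
                for gi, suff in ((0, "1"), (1, "2")):
                    g = padded[gi]
                    if g is None:
                        for key, val in (("p", 0), ("vh", 0.0), ("k", 1.0),
                                         ("tmin", 1.0), ("tamp", 0.0),
                                         ("vt", 0.0), ("s1", 10.0), ("s2", 10.0)):
                            cols[key + suff].append(val)
                    else:
                        cols["p" + suff].append(g.power)
                        cols["vh" + suff].append(g.vh)
                        cols["k" + suff].append(g.k)
                        cols["tmin" + suff].append(g.tau_min / qf)
                        cols["tamp" + suff].append(g.tau_amp / qf)
                        cols["vt" + suff].append(g.vt)
                        cols["s1" + suff].append(g.s1)
                        cols["s2" + suff].append(g.s2)

        to_i = lambda k: np.asarray(cols[k], dtype=np.int64)
        to_f = lambda k: np.asarray(cols[k], dtype=np.float64)
        self.ch = {
            "comp": to_i("comp"), "g": to_f("g"), "scheme": to_i("scheme"),
            "efix": to_f("efix"), "edyn": to_i("edyn"),
            "p1": to_i("p1"), "vh1": to_f("vh1"), "k1": to_f("k1"),
            "tmin1": to_f("tmin1"), "tamp1": to_f("tamp1"), "vt1": to_f("vt1"),
            "s11": to_f("s11"), "s21": to_f("s21"),
            "p2": to_i("p2"), "vh2": to_f("vh2"), "k2": to_f("k2"),
            "tmin2": to_f("tmin2"), "tamp2": to_f("tamp2"), "vt2": to_f("vt2"),
            "s12": to_f("s12"), "s22": to_f("s22"),
            "feeds": to_i("feeds"), "casrc": to_i("casrc"), "kd": to_f("kd"),
        }

        # dynamic-EK bookkeeping: pooled comps and nodes (nodes read the
        # mean of their flanking PNJ pools, which vent to the bath)
        pooled_comp = self.pax.comp_ids.astype(np.int64)
        node_comp, node_pa, node_pb = [], [], []
        pnj_ids = [s.id for s in m.segments if s.kind is SegmentKind.PNJ]
        for ni, nid in enumerate(m.node_ids):
            y = m.segments[nid].axial_position
            prox = [i for i in pnj_ids if m.segments[i].axial_position < y]
            dist = [i for i in pnj_ids if m.segments[i].axial_position > y]
            pa = max(prox, key=lambda i: m.segments[i].axial_position) if prox else -1
            pb = min(dist, key=lambda i: m.segments[i].axial_position) if dist else -1
            node_comp.append(nid)
            node_pa.append(pool_of.get(pa, -1))
            node_pb.append(pool_of.get(pb, -1))

        rtf = 1e3 * _kdyn.GAS_CONSTANT * (273.15 + kp.temperature) / _kdyn.FARADAY
        sat_na = kp.na_i ** 1.5 / (kp.na_i ** 1.5 + kp.km_na ** 1.5)

        self.arrays = dict(
            parent=parent, gpa=gpa, gdiag=gdiag, c_nf=c_nf, gl=gl, el=el,
            drive=drive, area=area, kind=kind_code,
            pooled_comp=pooled_comp,
            node_comp=np.asarray(node_comp, dtype=np.int64),
            node_pa=np.asarray(node_pa, dtype=np.int64),
            node_pb=np.asarray(node_pb, dtype=np.int64),
            pool_vol=self.pax.volume, pool_area=self.pax.area_cm2,
            chain_ptr=self.pax.chain_ptr, g_axial=self.pax.g_axial,
        )
        self.consts = dict(
            rtf=rtf, k_i=kp.k_i, k_bath=kp.k_bath, km_k=kp.km_k,
            pump_pref=kp.i_nak_max * sat_na, g_bath=self.pax.g_bath,
            ko_floor=kp.ko_floor, accum=1 if kp.accumulation_enabled else 0,
            e_k_fixed=memb.e_k,
            ca_rest=memb.ca_rest, ca_tau=memb.ca_tau, ca_alpha=memb.ca_alpha,
        )

    # -- state --------------------------------------------------------------
    def init_state(self) -> dict:
        """Voltage, gates, Ca and [K+]o at their holding steady state."""
        v0 = self.cfg.v_init
        ch = self.ch
        n = len(self.morph.segments)
        nch = ch["comp"].size
        g1 = np.zeros(nch)
        g2 = np.zeros(nch)
        for j in range(nch):
            if ch["scheme"][j] == 0:
                g1[j] = 1.0 / (1.0 + math.exp(-(v0 - ch["vh1"][j]) / ch["k1"][j]))
                if ch["p2"][j] > 0:
                    g2[j] = 1.0 / (1.0 + math.exp(-(v0 - ch["vh2"][j]) / ch["k2"][j]))
        ek0 = _kdyn.nernst_potential(
            self.cfg.kdyn.k_bath, self.cfg.kdyn.k_i, self.cfg.kdyn.temperature
        )
        return dict(
            v=np.full(n, float(v0)),
            g1=g1, g2=g2,
            ca=np.full(n, self.consts["ca_rest"]),
            ko=np.full(self.pax.volume.size, self.cfg.kdyn.k_bath),
            ek=np.full(n, ek0),
            budgets=np.zeros(5),  # efflux, pumped, diffused, clips, content0
            step=0,
        )

    # -- integration --------------------------------------------------------
    def advance(
        self,
        state: dict,
        stim_wave: np.ndarray,
        record_stride: int = 0,
        rec_comps: np.ndarray | None = None,
        rec_pools: np.ndarray | None = None,
    ):
        """Advance by ``len(stim_wave)`` steps; optionally record every
        ``record_stride`` steps.  Returns (v_samples, ko_samples,
        stim_samples) or (None, None, None) when not recording."""
        a, c, ch = self.arrays, self.consts, self.ch
        n_steps = stim_wave.size
        if record_stride > 0:
            n_sam = n_steps // record_stride
            rc = rec_comps if rec_comps is not None else np.zeros(0, np.int64)
            rp = rec_pools if rec_pools is not None else np.zeros(0, np.int64)
            out_v = np.empty((n_sam, rc.size))
            out_ko = np.empty((n_sam, rp.size))
            out_stim = np.empty(n_sam)
        else:
            rc = np.zeros(0, np.int64)
            rp = np.zeros(0, np.int64)
            out_v = np.empty((0, 0))
            out_ko = np.empty((0, 0))
            out_stim = np.empty(0)
        status = _advance_kernel(
            stim_wave, self.cfg.dt,
            state["v"], state["g1"], state["g2"], state["ca"], state["ko"],
            state["ek"], state["budgets"],
            a["parent"], a["gpa"], a["gdiag"], a["c_nf"], a["gl"], a["el"],
            a["drive"],
            ch["comp"], ch["g"], ch["scheme"], ch["efix"], ch["edyn"],
            ch["p1"], ch["vh1"], ch["k1"], ch["tmin1"], ch["tamp1"],
            ch["vt1"], ch["s11"], ch["s21"],
            ch["p2"], ch["vh2"], ch["k2"], ch["tmin2"], ch["tamp2"],
            ch["vt2"], ch["s12"], ch["s22"],
            ch["feeds"], ch["casrc"], ch["kd"], a["area"],
            a["pooled_comp"], a["node_comp"], a["node_pa"], a["node_pb"],
            a["pool_vol"], a["pool_area"], a["chain_ptr"], a["g_axial"],
            c["rtf"], c["k_i"], c["k_bath"], c["km_k"], c["pump_pref"],
            c["g_bath"], c["ko_floor"], c["accum"],
            c["ca_rest"], c["ca_tau"], c["ca_alpha"],
            record_stride, rc, rp, out_v, out_ko, out_stim,
        )
        if status >= 0:
            t_ms = state["step"] * self.cfg.dt
            raise FloatingPointError(
                f"non-finite membrane potential in compartment {status} "
                f"near t = {t_ms:.3f} ms"
            )
        state["step"] += n_steps
        if record_stride > 0:
            return out_v, out_ko, out_stim
        return None, None, None

    def step(self, state: dict, dt: float | None = None) -> dict:
        """Single zero-stimulus integration step (testing hook)."""
        if dt is not None and not math.isclose(dt, self.cfg.dt):
            raise ValueError("step dt is fixed by the configuration")
        self.advance(state, np.zeros(1))
        return state


@njit(cache=True)
def _advance_kernel(
    stim, dt, v, g1, g2, ca, ko, ek, budgets,
    parent, gpa, gdiag, c_nf, gl, el, drive,
    ch_comp, ch_g, ch_scheme, ch_efix, ch_edyn,
    p1, vh1, k1, tmin1, tamp1, vt1, s11, s21,
    p2, vh2, k2, tmin2, tamp2, vt2, s12, s22,
    feeds, casrc, kd, area,
    pooled_comp, node_comp, node_pa, node_pb,
    pool_vol, pool_area, chain_ptr, g_axial,
    rtf, k_i, k_bath, km_k, pump_pref, g_bath, ko_floor, accum,
    ca_rest, ca_tau, ca_alpha,
    stride, rec_comp, rec_pool, out_v, out_ko, out_stim,
):
    n = v.size
    nch = ch_comp.size
    npool = ko.size
    nchain = chain_ptr.size - 1
    gtot = np.zeros(n)
    ge = np.zeros(n)
    ica = np.zeros(n)
    src = np.zeros(npool)
    pump = np.zeros(npool)
    diag = np.zeros(n)
    rhs = np.zeros(n)
    sample = 0

    max_chain = 0
    for cix in range(nchain):
        L = chain_ptr[cix + 1] - chain_ptr[cix]
        if L > max_chain:
            max_chain = L
    cp = np.zeros(max_chain)
    dp = np.zeros(max_chain)

    for t in range(stim.size):
        i_stim = stim[t]

        # 1) refresh dynamic K reversal potentials
        for k in range(npool):
            ek[pooled_comp[k]] = rtf * math.log(ko[k] / k_i)
        for q in range(node_comp.size):
            pa = node_pa[q]
            pb = node_pb[q]
            if pa >= 0 and pb >= 0:
                local = 0.5 * (ko[pa] + ko[pb])
            elif pa >= 0:
                local = ko[pa]
            elif pb >= 0:
                local = ko[pb]
            else:
                local = k_bath
            ek[node_comp[q]] = rtf * math.log(local / k_i)

        # 2) gates (exponential Euler at V^n) and frozen conductances
        for i in range(n):
            gtot[i] = 0.0
            ge[i] = 0.0
            ica[i] = 0.0
        for j in range(nch):
            i = ch_comp[j]
            vi = v[i]
            sch = ch_scheme[j]
            if sch == 0:
                inf = 1.0 / (1.0 + math.exp(-(vi - vh1[j]) / k1[j]))
                tau = tmin1[j] + tamp1[j] / (
                    math.exp((vi - vt1[j]) / s11[j])
                    + math.exp(-(vi - vt1[j]) / s21[j])
                )
                g1[j] += (inf - g1[j]) * (1.0 - math.exp(-dt / tau))
                act = 1.0
                for _ in range(p1[j]):
                    act *= g1[j]
                if p2[j] > 0:
                    inf2 = 1.0 / (1.0 + math.exp(-(vi - vh2[j]) / k2[j]))
                    tau2 = tmin2[j] + tamp2[j] / (
                        math.exp((vi - vt2[j]) / s12[j])
                        + math.exp(-(vi - vt2[j]) / s22[j])
                    )
                    g2[j] += (inf2 - g2[j]) * (1.0 - math.exp(-dt / tau2))
                    for _ in range(p2[j]):
                        act *= g2[j]
            elif sch == 1:
                act = ca[i] / (ca[i] + kd[j])
            else:
                act = 1.0
            e = ek[i] if ch_edyn[j] == 1 else ch_efix[j]
            gg = ch_g[j] * act
            gtot[i] += gg
            ge[i] += gg * e

        # 3) implicit voltage solve on the tree (Hines elimination)
        for i in range(n):
            diag[i] = c_nf[i] / dt + gtot[i] + gl[i] + gdiag[i]
            rhs[i] = c_nf[i] / dt * v[i] + ge[i] + gl[i] * el[i] \
                + i_stim * drive[i]
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = gpa[i] / diag[i]
            diag[p] -= f * gpa[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] + gpa[i] * v[parent[i]]) / diag[i]

        # 4) K+ pools: channel efflux, pump, implicit diffusion
        if accum == 1:
            for k in range(npool):
                src[k] = 0.0
            for j in range(nch):
                if feeds[j] >= 0:
                    i = ch_comp[j]
                    act = 1.0
                    for _ in range(p1[j]):
                        act *= g1[j]
                    if p2[j] > 0:
                        for _ in range(p2[j]):
                            act *= g2[j]
                    i_na = ch_g[j] * act * (v[i] - ek[i])  # nA, outward +
                    src[feeds[j]] += i_na * 1e-3 * AMOUNT_PER_UA_MS
            base_sat = k_bath / (k_bath + km_k)
            for k in range(npool):
                vi = v[pooled_comp[k]]
                vfac = (vi + 150.0) / (vi + 200.0)
                i_net = pump_pref * vfac * (ko[k] / (ko[k] + km_k) - base_sat)
                pump[k] = 2.0 * i_net * pool_area[k] * AMOUNT_PER_UA_MS
                budgets[0] += src[k] * dt
                budgets[1] += pump[k] * dt
            for cix in range(nchain):
                lo = chain_ptr[cix]
                hi = chain_ptr[cix + 1]
                nn = hi - lo
                goff = lo - cix
                # assemble tridiagonal in place via Thomas
                d0 = pool_vol[lo] / dt + g_bath + g_axial[goff]
                r0 = pool_vol[lo] / dt * ko[lo] + (src[lo] - pump[lo]) \
                    + g_bath * k_bath
                cp[0] = -g_axial[goff] / d0
                dp[0] = r0 / d0
                for w in range(1, nn):
                    gl_ = g_axial[goff + w - 1]
                    gr_ = g_axial[goff + w] if w < nn - 1 else 0.0
                    dd = pool_vol[lo + w] / dt + gl_ + gr_
                    rr = pool_vol[lo + w] / dt * ko[lo + w] \
                        + (src[lo + w] - pump[lo + w])
                    if w == nn - 1:
                        dd += g_bath
                        rr += g_bath * k_bath
                    denom = dd - (-gl_) * cp[w - 1]
                    cp[w] = -gr_ / denom
                    dp[w] = (rr - (-gl_) * dp[w - 1]) / denom
                ko[hi - 1] = dp[nn - 1]
                for w in range(nn - 2, -1, -1):
                    ko[lo + w] = dp[w] - cp[w] * ko[lo + w + 1]
                budgets[2] += g_bath * (
                    (ko[lo] - k_bath) + (ko[hi - 1] - k_bath)
                ) * dt
                for w in range(lo, hi):
                    if ko[w] < ko_floor:
                        ko[w] = ko_floor
                        budgets[3] += 1.0

        # 5) Ca pools and Ca currents (soma/dendrites)
        for j in range(nch):
            if casrc[j] == 1:
                i = ch_comp[j]
                act = 1.0
                for _ in range(p1[j]):
                    act *= g1[j]
                ica[i] += ch_g[j] * act * (v[i] - ch_efix[j])  # nA
        for i in range(n):
            if ica[i] != 0.0 or ca[i] != ca_rest:
                if area[i] > 0.0:
                    dens = ica[i] * 1e-3 / area[i]  # uA/cm2
                    dca = (-ca_alpha * dens - (ca[i] - ca_rest) / ca_tau) * dt
                    ca[i] += dca
                    if ca[i] < 1e-4:
                        ca[i] = 1e-4

        # 6) record / divergence check
        if stride > 0 and (t + 1) % stride == 0:
            for q in range(rec_comp.size):
                out_v[sample, q] = v[rec_comp[q]]
            for q in range(rec_pool.size):
                out_ko[sample, q] = ko[rec_pool[q]]
            out_stim[sample] = i_stim
            sample += 1
        if (t & 255) == 0:
            for i in range(n):
                if not math.isfinite(v[i]):
                    return i
    return -1


# ---------------------------------------------------------------------------


def run_simulation(cfg: SimulationConfig) -> Recording:
    """Settle to rest without stimulation, then deliver the pulse train.

    Records V_m at the requested sites (default: soma, stimulated node,
    node_0, flanking JXP) at the recording interval, plus peri-axonal [K+]o
    at every recorded site that has a pool and at the JXP flanking the
    stimulated node.  Deterministic: identical configs give identical
    recordings.
    """
    model = CableModel(cfg)
    return _run_on_model(model)


def _run_on_model(model: CableModel) -> Recording:
    cfg = model.cfg
    m = model.morph
    labels = list(
        cfg.record_sites
        if cfg.record_sites is not None
        else record_sites_default(m, cfg.electrode_node or 10)
    )
    sites = {}
    for lab in labels:
        cid = model.comp_of_label(lab)
        if lab not in sites:
            sites[lab] = cid
    pool_idx = model.pax.pool_index()
    ko_sites = {}
    for lab, cid in sites.items():
        if cid in pool_idx:
            ko_sites[lab] = cid
    enode = cfg.electrode_node if cfg.electrode_node is not None else 10
    adj_lab = f"jxp_adj_{enode}"
    adj_cid = model.comp_of_label(adj_lab)
    if adj_lab not in ko_sites and adj_cid in pool_idx:
        ko_sites[adj_lab] = adj_cid

    rec_comps = np.asarray(list(sites.values()), dtype=np.int64)
    rec_pools = np.asarray(
        [pool_idx[c] for c in ko_sites.values()], dtype=np.int64
    )

    stride = int(round(cfg.record_interval / cfg.dt))
    state = model.init_state()
    state["budgets"][4] = float(np.sum(state["ko"] * model.pax.volume))

    n_settle = int(round(cfg.settle_ms / cfg.dt))
    settle_v, settle_ko, settle_stim = model.advance(
        state, np.zeros(n_settle), stride, rec_comps, rec_pools
    )
    wave = make_pulse_train(cfg.pulses, cfg.dt)
    stim_v, stim_ko, stim_stim = model.advance(
        state, wave, stride, rec_comps, rec_pools
    )

    v_all = np.vstack([settle_v, stim_v])
    ko_all = np.vstack([settle_ko, stim_ko])
    stim_all = np.concatenate([settle_stim, stim_stim])
    n_sam = v_all.shape[0]
    t_ms = (np.arange(1, n_sam + 1) * cfg.record_interval) - cfg.settle_ms
    content_end = float(np.sum(state["ko"] * model.pax.volume))
    b = state["budgets"]
    meta = {
        "amplitude_mA": cfg.pulses.amplitude,
        "frequency_hz": cfg.pulses.frequency,
        "n_pulses": cfg.pulses.n_pulses,
        "duration_s": cfg.pulses.duration,
        "k_bath_mM": cfg.kdyn.k_bath,
        "accumulation_enabled": cfg.kdyn.accumulation_enabled,
        "neuron_offset_um": tuple(cfg.neuron_offset),
        "electrode_node": enode,
        "dt_ms": cfg.dt,
        "settle_ms": cfg.settle_ms,
        "k_budget": {
            "efflux_in": float(b[0]),
            "pumped_out": float(b[1]),
            "diffused_out": float(b[2]),
            "clip_events": float(b[3]),
            "content_start": float(b[4]),
            "content_end": content_end,
        },
        "ko_final": state["ko"].copy(),
        "rest_v": float(settle_v[-1, 0]) if settle_v.size else None,
    }
    return Recording(
        time_s=t_ms / 1000.0,
        vm={lab: v_all[:, q] for q, lab in enumerate(sites)},
        ko={lab: ko_all[:, q] for q, lab in enumerate(ko_sites)},
        stim=stim_all,
        sites=sites,
        ko_sites=ko_sites,
        meta=meta,
    )
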