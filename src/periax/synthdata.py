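"""Synthetic spike trains and fixture recordings.

These generators emulate the statistical structure of CA1 pyramidal-cell
firing at baseline and under sustained 100 Hz stimulation — spontaneous
burst firing (short ~5 ms intra-burst ISIs, exponential inter-burst gaps),
clustered firing with long or short activity-silence alternation
(log-normal gaps), and regular trains — so the analysis layer is testable
without running simulations.  All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .spikemetrics import SpikeTrain

__all__ = [
    "SynthSpec",
    "gen_regular",
    "gen_burst",
    "gen_clustered",
    "gen_recording_fixture",
]


@dataclass(frozen=True)
class SynthSpec:
    pattern: str = "regular"  # regular | burst | clustered_long | clustered_short
    rate_hz: float = 4.6  # target mean rate (baseline burst default)
    intra_isi_ms: float = 5.0
    spikes_per_burst: float = 3.0  # mean of the geometric burst-size law
    gap_mean_ms: float = 300.0  # cluster-gap scale (log-normal median)
    gap_sigma: float = 0.3  # log-normal shape for cluster gaps
    cluster_len: int = 3  # spikes per cluster (short-cluster variant)
    jitter_ms: float = 0.0
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration and rate must be positive")


def _finish(times: np.ndarray, spec: SynthSpec, rng) -> SpikeTrain:
    if spec.jitter_ms > 0:
        times = times + rng.normal(0.0, spec.jitter_ms / 1000.0, times.size)
    times = np.sort(times)
    times = times[(times >= 0) & (times <= spec.duration_s)]
    times = times[np.concatenate(([True], np.diff(times) > 1e-6))]
    return SpikeTrain(spec.pattern, times)


def gen_regular(spec: SynthSpec) -> SpikeTrain:
    """Near-constant ISIs at the target rate with optional Gaussian jitter."""
    rng = np.random.default_rng(spec.seed)
    isi = 1.0 / spec.rate_hz
    times = np.arange(isi / 2.0, spec.duration_s, isi)
    return _finish(times, spec, rng)


def gen_burst(spec: SynthSpec) -> SpikeTrain:
    """Bursts (geometric size, fixed intra-burst ISI) with exponential gaps.

    The exponential inter-burst gap mean is tuned so the overall rate hits
    the target: with mean burst size s and intra-ISI d, bursts must recur
    every s/rate seconds on average.
    """
    if spec.intra_isi_ms / 1000.0 >= spec.spikes_per_burst / spec.rate_hz:
        raise ValueError("intra-burst ISI too long for the target rate")
    rng = np.random.default_rng(spec.seed)
    d = spec.intra_isi_ms / 1000.0
    s_mean = max(1.0, spec.spikes_per_burst)
    period = s_mean / spec.rate_hz
    times = []
    t = 0.0
    while t < spec.duration_s:
        size = 1 + rng.geometric(1.0 / s_mean) - 1 if s_mean > 1 else 1
        size = max(1, size)
        burst_span = (size - 1) * d
        gap_mean = max(1e-3, period - burst_span)
        for k in range(size):
            tt = t + k * d
            if tt > spec.duration_s:
                break
            times.append(tt)
        t += burst_span + rng.exponential(gap_mean)
    return _finish(np.asarray(times), spec, rng)


def gen_clustered(spec: SynthSpec) -> SpikeTrain:
    """Alternating ~100-Hz activity stretches and silent gaps.

    ``clustered_long``: many-spike clusters with long log-normal gaps
    (drives CV above the long-cluster threshold).  ``clustered_short``:
    short clusters (``cluster_len`` spikes) with moderate, tight gaps,
    which keeps CV low while the mean/mode ISI ratio stays high.  A zero
    gap scale degenerates to a tonic-like train.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.intra_isi_ms / 1000.0
    times = []
    t = 0.0
    long_variant = spec.pattern != "clustered_short"
    while t < spec.duration_s:
        n_in = (
            max(2, int(rng.normal(40, 10))) if long_variant
            else max(2, spec.cluster_len)
        )
        for k in range(n_in):
            tt = t + k * d
            if tt > spec.duration_s:
                break
            times.append(tt)
        if spec.gap_mean_ms <= 0:
            gap = 0.0
        else:
            gap = rng.lognormal(
                np.log(spec.gap_mean_ms / 1000.0), spec.gap_sigma
            )
        t += (n_in - 1) * d + d + gap
    return _finish(np.asarray(times), spec, rng)


def generate(spec: SynthSpec) -> SpikeTrain:
    if spec.pattern == "regular":
        return gen_regular(spec)
    if spec.pattern == "burst":
        return gen_burst(spec)
    if spec.pattern in ("clustered_long", "clustered_short"):
        return gen_clustered(spec)
    raise ValueError(f"unknown pattern {spec.pattern!r}")


def _ap_template(dt_ms: float) -> np.ndarray:
    """Stylized 2-ms action-potential waveform (depolarize, overshoot,
    after-hyperpolarize), peak +30 mV relative to baseline offset."""
    t = np.arange(0.0, 2.0, dt_ms)
    rise = np.exp(-((t - 0.5) / 0.15) ** 2)
    ahp = -0.25 * np.exp(-((t - 1.1) / 0.4) ** 2)
    return 95.0 * rise + 95.0 * ahp  # mV above the -65 baseline


def gen_recording_fixture(
    spike_times_s: np.ndarray,
    artifact_times_s: np.ndarray,
    duration_s: float = 1.0,
    dt_ms: float = 0.05,
    noise_mv: float = 0.5,
    artifact_mv: float = 80.0,
    artifact_width_ms: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voltage trace with template APs, square stimulus artifacts and noise.

    Returns ``(sample_times_s, trace_mV, truth_spike_times_s)``; the truth
    list contains the spikes actually rendered inside the trace span.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, dt_ms / 1000.0)
    y = np.full(t.size, -65.0)
    if noise_mv > 0:
        y = y + rng.normal(0.0, noise_mv, t.size)
    tmpl = _ap_template(dt_ms)
    truth = []
    for ts in np.sort(np.asarray(spike_times_s, dtype=np.float64)):
        i0 = int(round(ts / (dt_ms / 1000.0)))
        if 0 <= i0 < t.size - tmpl.size:
            y[i0:i0 + tmpl.size] += tmpl
            truth.append(t[i0])
    n_art = max(1, int(round(artifact_width_ms / dt_ms)))
    for ta in np.asarray(artifact_times_s, dtype=np.float64):
        i0 = int(round(ta / (dt_ms / 1000.0)))
        if 0 <= i0 < t.size - n_art:
            y[i0:i0 + n_art] += artifact_mv
    return t, y, np.asarray(truth)
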