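"""Spike detection and firing-pattern statistics.

The pattern taxonomy follows the two-threshold classification used for
HFS-evoked firing: the burst index BI = mean ISI / mode ISI and the
coefficient of variation CV = SD(ISI) / mean(ISI).  For experimental
trains, CV > 1.5 marks long clustered firing, CV <= 1.5 with BI > 5.0
short clustered firing, and the rest regular firing.  For simulated trains
the clustered threshold is CV > 0.8, a somatically silent train is
"blocked", and sub-stimulus-rate regular trains are "low_rate_regular".

Conventions stated explicitly so results are exactly reproducible: the ISI
mode is the centre of the most populated 1-ms histogram bin (bins centred
on integers, ties resolved toward the shortest ISI) and the SD is the
sample standard deviation (n-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "SpikeTrain",
    "ISIStats",
    "FiringMetrics",
    "PatternLabel",
    "remove_artifacts",
    "detect_spikes",
    "isi_stats",
    "classify_pattern",
    "conduction_metrics",
    "autocorrelogram",
    "load_trains_csv",
    "save_trains_csv",
]


class PatternLabel(str, Enum):
    TONIC = "tonic"
    LONG_CLUSTERED = "long_clustered"
    SHORT_CLUSTERED = "short_clustered"
    REGULAR = "regular"
    LOW_RATE_REGULAR = "low_rate_regular"
    BLOCKED = "blocked"


@dataclass(frozen=True)
class SpikeTrain:
    site: str
    times: np.ndarray  # s, strictly increasing

    def __post_init__(self):
        t = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", t)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self):
        return self.times.size

    def window(self, t0: float, t1: float) -> "SpikeTrain":
        sel = (self.times >= t0) & (self.times <= t1)
        return SpikeTrain(self.site, self.times[sel])


@dataclass(frozen=True)
class ISIStats:
    isis_ms: np.ndarray
    mean_ms: float
    mode_ms: float
    sd_ms: float
    cv: float
    bi: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.cv)


_UNDEFINED = None  # set below


@dataclass(frozen=True)
class FiringMetrics:
    initiation_ratio: float
    conduction_ratio: float
    somatic_rate: float  # spikes/s
    stats: ISIStats
    label: Optional[PatternLabel] = None


def remove_artifacts(
    trace: np.ndarray,
    sample_times: np.ndarray,
    stim_times: np.ndarray,
    window_ms: float,
) -> np.ndarray:
    """Replace stimulus-artifact segments with straight interpolation lines.

    Samples strictly inside each ``[t, t + window]`` interval are replaced
    by the line between the last sample at-or-before t and the first sample
    at-or-after t + window; all other samples are untouched.  Overlapping
    windows are merged (with a warning).
    """
    t = np.asarray(sample_times, dtype=np.float64)
    y = np.array(trace, dtype=np.float64, copy=True)
    if len(t) != len(y):
        raise ValueError("trace and sample_times lengths differ")
    w = window_ms / 1000.0
    starts = np.sort(np.asarray(stim_times, dtype=np.float64))
    merged: list[list[float]] = []
    overlap = False
    for s in starts:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], s + w)
            overlap = True
        else:
            merged.append([s, s + w])
    if overlap:
        warnings.warn("overlapping artifact windows merged", RuntimeWarning,
                      stacklevel=2)
    for a, b in merged:
        if a < t[0] or b > t[-1]:
            raise ValueError("artifact window outside the trace span")
        i0 = int(np.searchsorted(t, a, side="right")) - 1
        i1 = int(np.searchsorted(t, b, side="left"))
        if i1 <= i0 + 1:
            continue
        y[i0:i1 + 1] = np.interp(t[i0:i1 + 1], [t[i0], t[i1]],
                                 [y[i0], y[i1]])
    return y


def detect_spikes(
    trace: np.ndarray,
    sample_times: np.ndarray,
    threshold: float = 0.0,
    refractory_ms: float = 2.0,
    site: str = "",
) -> SpikeTrain:
    """Upward threshold crossings with a refractory veto.

    The spike time is the time of the crossing sample; crossings within the
    refractory period of an accepted spike are suppressed.
    """
    y = np.asarray(trace, dtype=np.float64)
    t = np.asarray(sample_times, dtype=np.float64)
    up = np.flatnonzero((y[1:] >= threshold) & (y[:-1] < threshold)) + 1
    refr = refractory_ms / 1000.0
    out: list[float] = []
    last = -np.inf
    for i in up:
        if t[i] - last >= refr:
            out.append(t[i])
            last = t[i]
    return SpikeTrain(site, np.asarray(out))


def _undefined_stats() -> ISIStats:
    return ISIStats(np.empty(0), np.nan, np.nan, np.nan, np.nan, np.nan)


def isi_stats(train: SpikeTrain, mode_bin_ms: float = 1.0) -> ISIStats:
    """Mean/mode/SD of the ISI sequence, CV = SD/mean, BI = mean/mode.

    Requires at least 3 spikes (2 ISIs); otherwise returns the
    undefined-stats marker (all NaN).  The mode is the centre of the most
    populated histogram bin of width ``mode_bin_ms`` (bins centred on
    integer multiples of the width; ties break toward shorter ISIs).
    """
    if len(train) < 3:
        return _undefined_stats()
    isis = np.diff(train.times) * 1000.0  # ms
    mean = float(np.mean(isis))
    sd = float(np.std(isis, ddof=1))
    nbins = int(np.floor(isis.max() / mode_bin_ms + 0.5)) + 1
    edges = (np.arange(nbins + 1) - 0.5) * mode_bin_ms
    counts, _ = np.histogram(isis, bins=edges)
    mode = float(np.argmax(counts) * mode_bin_ms)
    if mode == 0.0:
        mode = mode_bin_ms / 2.0  # sub-bin ISIs: use the half-bin centre
    return ISIStats(
        isis_ms=isis, mean_ms=mean, mode_ms=mode, sd_ms=sd,
        cv=sd / mean if mean > 0 else np.nan,
        bi=mean / mode,
    )


def _cluster_flavour(stats: ISIStats) -> PatternLabel:
    """Long vs short clustered firing, via cluster segmentation.

    Clusters are split at ISIs exceeding 5x the mode; the pattern is long
    when the median inter-cluster gap exceeds 10x the median intra-cluster
    ISI, otherwise short.
    """
    isis = stats.isis_ms
    gap_thr = 5.0 * stats.mode_ms
    gaps = isis[isis > gap_thr]
    intra = isis[isis <= gap_thr]
    if gaps.size == 0 or intra.size == 0:
        return PatternLabel.LONG_CLUSTERED
    if np.median(gaps) > 10.0 * np.median(intra):
        return PatternLabel.LONG_CLUSTERED
    return PatternLabel.SHORT_CLUSTERED


def classify_pattern(
    stats: ISIStats,
    context: str = "experimental",
    n_spikes: Optional[int] = None,
    window_s: Optional[float] = None,
    stim_rate_hz: float = 100.0,
) -> PatternLabel:
    """Assign the firing-pattern label from (CV, BI).

    ``context='experimental'``: CV > 1.5 -> long clustered; CV <= 1.5 and
    BI > 5.0 -> short clustered; otherwise regular.

    ``context='simulation'``: an empty somatic train is blocked; the
    clustered threshold drops to CV > 0.8 (long/short via the cluster-gap
    heuristic); non-clustered trains are tonic when the rate keeps up with
    the stimulus (>= 95% of ``stim_rate_hz``), low-rate regular below half
    the stimulus rate, and regular in between.
    """
    if context not in ("experimental", "simulation"):
        raise ValueError("context must be 'experimental' or 'simulation'")
    if context == "simulation" and n_spikes is not None and n_spikes == 0:
        return PatternLabel.BLOCKED
    if not stats.defined:
        if context == "simulation":
            return PatternLabel.BLOCKED if not n_spikes else \
                PatternLabel.LOW_RATE_REGULAR
        return PatternLabel.REGULAR
    if context == "experimental":
        if stats.cv > 1.5:
            return PatternLabel.LONG_CLUSTERED
        if stats.bi > 5.0:
            return PatternLabel.SHORT_CLUSTERED
        return PatternLabel.REGULAR
    # simulation context
    if stats.cv > 0.8:
        return _cluster_flavour(stats)
    rate = None
    if n_spikes is not None and window_s:
        rate = n_spikes / window_s
    else:
        rate = 1000.0 / stats.mean_ms
    if rate >= 0.95 * stim_rate_hz:
        return PatternLabel.TONIC
    if rate < 0.5 * stim_rate_hz:
        return PatternLabel.LOW_RATE_REGULAR
    return PatternLabel.REGULAR


def conduction_metrics(
    node_train: SpikeTrain,
    soma_train: SpikeTrain,
    n_pulses: int,
    match_window_ms: tuple[float, float] = (0.0, 5.0),
    window_s: Optional[float] = None,
) -> FiringMetrics:
    """Initiation ratio, conduction ratio and somatic rate.

    initiation = node spikes / stimulus pulses; conduction = soma spikes
    matched to a node spike within the latency window / node spikes (each
    soma spike matches at most one node spike, greedily in time order);
    somatic rate = soma spikes / analysis window.
    """
    if n_pulses <= 0:
        raise ValueError("n_pulses must be positive")
    lo, hi = match_window_ms[0] / 1000.0, match_window_ms[1] / 1000.0
    nt, st = node_train.times, soma_train.times
    matched = 0
    j = 0
    for t in nt:
        while j < st.size and st[j] < t + lo:
            j += 1
        if j < st.size and st[j] <= t + hi:
            matched += 1
            j += 1
    if window_s is None:
        window_s = float(nt[-1] - nt[0]) if nt.size > 1 else np.nan
    initiation = min(1.0, nt.size / n_pulses)
    conduction = matched / nt.size if nt.size else 0.0
    rate = st.size / window_s if window_s and window_s > 0 else 0.0
    return FiringMetrics(
        initiation_ratio=initiation,
        conduction_ratio=conduction,
        somatic_rate=rate,
        stats=isi_stats(soma_train),
    )


def save_trains_csv(trains: list[SpikeTrain], path) -> None:
    """Write spike trains as a two-column CSV (site, time_s)."""
    import pandas as pd

    pd.DataFrame(
        [(tr.site, t) for tr in trains for t in tr.times],
        columns=["site", "time_s"],
    ).to_csv(path, index=False)


def load_trains_csv(path) -> list[SpikeTrain]:
    """Read spike trains from a two-column CSV (site, time_s)."""
    import pandas as pd

    df = pd.read_csv(path)
    return [
        SpikeTrain(str(site), np.sort(g["time_s"].to_numpy(dtype=float)))
        for site, g in df.groupby("site", sort=True)
    ]


def autocorrelogram(
    train: SpikeTrain, bin_ms: float = 1.0, max_lag_ms: float = 50.0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of positive spike-pair lags in (0, max_lag].

    Returns (bin centres ms, counts).  Zero-lag self-pairs are excluded;
    the definition is symmetric, so only positive lags are tabulated.
    """
    t = train.times * 1000.0
    nb = int(round(max_lag_ms / bin_ms))
    edges = np.arange(nb + 1) * bin_ms
    counts = np.zeros(nb, dtype=np.int64)
    for i in range(t.size):
        right = t[i + 1:]
        lags = right[right - t[i] <= max_lag_ms] - t[i]
        if lags.size:
            counts += np.histogram(lags, bins=edges)[0]
    centres = edges[:-1] + bin_ms / 2.0
    return centres, counts
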