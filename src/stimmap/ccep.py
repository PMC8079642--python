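"""Cortico-cortical evoked potentials: epoching, N1 z-scoring, graphs.

Single-pulse stimulation at an electrode pair evokes, at connected
sites, an early deflection (N1) within 10–50 ms. The trial-averaged
waveform at each response channel is normalized by its pre-stimulus
baseline (−500…−10 ms): the z-score is the maximal absolute deviation
from the baseline mean inside the search window, in units of the
baseline SD of the averaged waveform. Responses with z > 6 (strict) are
significant and become directed edges stim-pair → channel of the
effective-connectivity graph.

The 0–10 ms post-pulse span is treated as stimulation artifact and takes
no part in any statistic. Epochs are demeaned by their own baseline
before averaging, which removes slow drift and keeps the baseline-SD
estimate of the average stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import Session

#: strict significance threshold on the N1 z-score
Z_THRESHOLD = 6.0

#: width (ms) of the zero-phase boxcar applied to the averaged waveform
#: before N1 scoring; damps broadband residual noise that would otherwise
#: bias the max-deviation statistic upward at low response amplitudes
SMOOTH_MS = 5


def boxcar_smooth(waveform, width_ms: int = SMOOTH_MS):
    """Zero-phase moving average along the last axis (odd width)."""
    w = np.asarray(waveform, dtype=np.float64)
    width = int(width_ms)
    if width <= 1:
        return w.copy()
    if width % 2 == 0:
        width += 1
    kernel = np.ones(width) / width
    return np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same"), -1, w
    )


@dataclass
class CCEPRecord:
    """Averaged response of every analyzable channel to one stim pair."""

    stim_pair: str
    channels: np.ndarray  # response channel indices
    mean_waveforms: np.ndarray  # (n_response_channels, n_samples), µV
    times_ms: np.ndarray  # relative to pulse, e.g. -500..+300
    n1_latency_ms: np.ndarray
    n1_z: np.ndarray
    significant: np.ndarray  # bool
    n_epochs: int = 0


@dataclass
class CCEPGraph:
    """Significant-edge set over all stimulated pairs.

    ``z`` keeps every response z-score (significant or not) so the
    z-weighted network feature can be built; ``edge_count`` counts only
    significant responses.
    """

    records: dict  # pair -> CCEPRecord
    edges: list = field(default_factory=list)  # (pair, channel, z)
    edge_count: dict = field(default_factory=dict)  # pair -> int

    def z_lookup(self, pair: str) -> dict:
        rec = self.records[pair]
        return dict(zip(rec.channels.tolist(), rec.n1_z.tolist()))

    def to_table(self) -> pd.DataFrame:
        rows = []
        for pair, rec in self.records.items():
            for c, lat, z, sig in zip(
                rec.channels, rec.n1_latency_ms, rec.n1_z, rec.significant
            ):
                rows.append(
                    dict(pair=pair, channel=int(c), latency_ms=float(lat),
                         z=float(z), significant=bool(sig))
                )
        return pd.DataFrame(rows)


def epoch_and_average(
    session: Session,
    pair: str,
    window_ms: tuple = (-500.0, 300.0),
    min_pulses: int = 10,
):
    """Pulse-locked average waveform per analyzable response channel.

    Response channels exclude the two stimulated channels and bad
    channels. Each epoch is demeaned by its pre-stimulus baseline
    (−500…−10 ms) before averaging; incomplete edge epochs are dropped
    with a warning.

    Returns
    -------
    channels : ndarray of response channel indices
    waveforms : ndarray (n_response, n_samples)
    times_ms : ndarray relative to the pulse
    n_used : int
    """
    if session.stim_log is None:
        raise ValueError("session has no stimulation log")
    log = session.stim_log
    pulses = log.loc[log["pair"] == pair, "pulse_onset_ms"].to_numpy(float)
    if pulses.size < min_pulses:
        raise ValueError(
            f"pair {pair}: {pulses.size} pulses < required {min_pulses}"
        )
    fs = session.sample_rate
    if fs != 1000.0:
        raise ValueError("CCEP analysis expects a 1 kHz session")
    i, j = session.pair_indices(pair)
    resp = np.flatnonzero(session.good_mask)
    resp = resp[(resp != i) & (resp != j)]
    lo = int(round(window_ms[0]))
    hi = int(round(window_ms[1]))
    times = np.arange(lo, hi)
    base_cols = (times >= -500) & (times <= -10)
    acc = np.zeros((resp.size, times.size))
    n_used = 0
    dropped = 0
    for t0 in pulses:
        s = int(round(t0)) + lo
        e = int(round(t0)) + hi
        if s < 0 or e > session.n_samples:
            dropped += 1
            continue
        ep = session.signals[resp, s:e]
        ep = ep - ep[:, base_cols].mean(axis=1, keepdims=True)
        acc += ep
        n_used += 1
    if dropped:
        warnings.warn(f"pair {pair}: dropped {dropped} incomplete epoch(s)")
    if n_used < min_pulses:
        raise ValueError(
            f"pair {pair}: only {n_used} complete epochs (< {min_pulses})"
        )
    return resp, acc / n_used, times.astype(float), n_used


def n1_zscore(
    mean_waveform,
    times_ms,
    search_ms: tuple = (10.0, 50.0),
    baseline_ms: tuple = (-500.0, -10.0),
):
    """Locate the N1 and z-score it against the pre-stimulus baseline.

    The detector uses the maximal absolute deviation from the baseline
    mean (robust to montage polarity); z is a ratio, so it is invariant
    to amplitude scaling of the waveform.
    """
    w = np.asarray(mean_waveform, dtype=np.float64)
    t = np.asarray(times_ms, dtype=np.float64)
    base = w[(t >= baseline_ms[0]) & (t <= baseline_ms[1])]
    if base.size <= 100:
        raise ValueError("baseline span too short (need > 100 samples)")
    mu = base.mean()
    sd = base.std(ddof=1)
    if sd == 0:
        raise ValueError("zero baseline standard deviation")
    win = (t >= search_ms[0]) & (t <= search_ms[1])
    dev = np.abs(w[win] - mu)
    k = int(np.argmax(dev))
    return float(t[win][k]), float(dev[k] / sd)


def analyze_pair(
    session: Session,
    pair: str,
    window_ms: tuple = (-500.0, 300.0),
    z_threshold: float = Z_THRESHOLD,
) -> CCEPRecord:
    """Epoch, average and z-score every response channel for one pair.

    The 0–10 ms artifact span is zeroed before a zero-phase boxcar
    smooths the average, so no artifact energy can leak into the search
    window through the smoothing kernel.
    """
    resp, wave, times, n_used = epoch_and_average(session, pair, window_ms)
    blanked = wave.copy()
    blanked[:, (times >= 0) & (times < 10)] = 0.0
    smooth = boxcar_smooth(blanked)
    lats = np.empty(resp.size)
    zs = np.empty(resp.size)
    for k in range(resp.size):
        lats[k], zs[k] = n1_zscore(smooth[k], times)
    return CCEPRecord(
        stim_pair=pair,
        channels=resp,
        mean_waveforms=wave,
        times_ms=times,
        n1_latency_ms=lats,
        n1_z=zs,
        significant=zs > z_threshold,
        n_epochs=n_used,
    )


def build_graph(records, z_threshold: float = Z_THRESHOLD) -> CCEPGraph:
    """Assemble the effective-connectivity graph from CCEP records."""
    if not records:
        raise ValueError("need at least one CCEP record")
    by_pair = {}
    edges = []
    counts = {}
    for rec in records:
        if rec.stim_pair in by_pair:
            raise ValueError(f"duplicate record for pair {rec.stim_pair}")
        by_pair[rec.stim_pair] = rec
        sig = rec.n1_z > z_threshold
        for c, z in zip(rec.channels[sig], rec.n1_z[sig]):
            edges.append((rec.stim_pair, int(c), float(z)))
        counts[rec.stim_pair] = int(sig.sum())
    return CCEPGraph(records=by_pair, edges=edges, edge_count=counts)
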