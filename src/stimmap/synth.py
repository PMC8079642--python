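"""Synthetic iEEG sessions with planted activation, connectivity and
ESM ground truth.

Every downstream stage is testable without patient data: the generator
plants (i) task-evoked 70–150 Hz bursts at a known set of "active"
channels, (ii) N1-like evoked deflections whose amplitudes follow a
known stim-pair × channel connectivity matrix, and (iii) ESM± labels
drawn from a logistic model over the pair's own activation, its planted
network centrality, and its connectivity-weighted network activation.

Background noise is 1/f ("pink") Gaussian noise band-limited to
≥ 1 Hz (the analogue of the amplifier high-pass), plus a shared
per-block common-mode pink component (so CAR has something to remove),
plus a 60 Hz line sinusoid. Burst carriers are band-limited Gaussian
noise, not pure tones, matching broadband high-gamma phenomenology.

Connectivity weights are expressed in units of target z: the planted N1
amplitude at a response channel is ``weight × SD`` where SD is the
baseline standard deviation that the trial-averaged waveform of that
channel's own background noise actually exhibits (measured inside the
generator before the deflections are added). A weight of 10 therefore
aims at a downstream z-score of about 10.

Determinism: all draws come from streams spawned from the config seed
with fixed tags, in a fixed order (ground truth first, then session
noise, then bursts/deflections, then labels), so identical configs give
bit-identical sessions and labels, and ESM labels can be re-planted
with different coefficients without touching the signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .ccep import boxcar_smooth
from .session import Session, make_channel_table, pair_id

# seed-stream tags (documented draw order)
_TAG_TRUTH = 1
_TAG_TASK = 2
_TAG_SPES = 3
_TAG_LABELS = 4
_TAG_GAINS = 5


@dataclass
class SynthConfig:
    """Study conditions for one synthetic patient.

    Defaults emulate the recorded cohort: 1 kHz sampling, 50 single
    pulses per stimulated pair at 2–5 s jittered intervals, N1 latencies
    drawn from a normal with mean 9.63 ms and SD 8.94 ms truncated to
    the 10–50 ms search window, and 40 task trials with 70–150 Hz bursts
    at the active channels.
    """

    n_channels: int = 16
    n_blocks: int = 2
    sample_rate: float = 1000.0
    n_task_trials: int = 40
    n_pulses_per_pair: int = 50
    active_channels: tuple | None = None  # drawn from seed when None
    hg_burst_gain: float = 4.0  # burst in-band RMS in units of background in-band RMS
    burst_onset_ms: float = 200.0
    burst_duration_ms: float = 400.0
    burst_jitter_sd_ms: float = 20.0
    trial_interval_ms: tuple = (3200.0, 4000.0)
    trial_window_ms: tuple = (-1000.0, 2000.0)
    connectivity: np.ndarray | None = None  # (n_pairs, n_channels), drawn when None
    n1_latency_mean_ms: float = 9.63
    n1_latency_sd_ms: float = 8.94
    n1_width_ms: float = 3.0
    isi_range_s: tuple = (2.0, 5.0)
    line_noise_amp: float = 5.0  # µV
    noise_std: float = 10.0  # µV, per-channel pink background
    common_mode_std: float = 5.0  # µV, per-block shared pink component
    esm_link_coefficients: tuple = (0.0, 0.3, 0.0, 4.0)  # intercept, activation, centrality, connectivity
    pink_fmin_hz: float = 1.0
    channel_gain_sigma: float = 0.4  # lognormal spread of per-channel amplitude
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1 or self.n_channels < 2 * self.n_blocks:
            raise ValueError("need at least 2 channels per CAR block")
        if self.sample_rate < 1000:
            raise ValueError("sample_rate must be >= 1000 Hz")
        lo, hi = self.trial_window_ms
        if not (0 <= self.burst_onset_ms and
                self.burst_onset_ms + self.burst_duration_ms <= hi):
            raise ValueError("burst window must lie inside the trial window")
        if self.connectivity is not None:
            conn = np.asarray(self.connectivity, dtype=float)
            if conn.shape != (len(self.pairs()), self.n_channels):
                raise ValueError(
                    "connectivity must be (n_pairs, n_channels) = "
                    f"{(len(self.pairs()), self.n_channels)}"
                )
            if np.any(conn < 0):
                raise ValueError("connectivity weights must be nonnegative")
        if self.active_channels is not None:
            ac = np.asarray(self.active_channels, dtype=int)
            if ac.size and (ac.min() < 0 or ac.max() >= self.n_channels):
                raise ValueError("active channel id outside channel range")
        if len(self.esm_link_coefficients) != 4:
            raise ValueError("esm_link_coefficients must be (g0, g1, g2, g3)")

    # -- structure -----------------------------------------------------------

    def block_labels(self) -> np.ndarray:
        """Contiguous, near-equal CAR block assignment per channel."""
        out = np.empty(self.n_channels, dtype=int)
        for b, idx in enumerate(np.array_split(np.arange(self.n_channels), self.n_blocks)):
            out[idx] = b
        return out

    def channel_names(self) -> list:
        return [f"ch{i:02d}" for i in range(self.n_channels)]

    def pairs(self) -> list:
        """Adjacent within-block electrode pairs (the ESM/SPES pairs)."""
        names = self.channel_names()
        labels = self.block_labels()
        return [
            pair_id(names[i], names[i + 1])
            for i in range(self.n_channels - 1)
            if labels[i] == labels[i + 1]
        ]

    def pair_indices(self) -> dict:
        names = self.channel_names()
        labels = self.block_labels()
        return {
            pair_id(names[i], names[i + 1]): (i, i + 1)
            for i in range(self.n_channels - 1)
            if labels[i] == labels[i + 1]
        }

    def _rng(self, tag: int, *extra) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), tag, *map(int, extra)])
        )

    def channel_gains(self) -> np.ndarray:
        """Per-channel amplitude factors (lognormal, seed-determined).

        Real iEEG channels differ in impedance and hence broadband
        amplitude by factors of a few; identical-variance channels would
        make the robust bad-channel statistic unrealistically tight.
        """
        rng = self._rng(_TAG_GAINS)
        return np.exp(rng.normal(0.0, self.channel_gain_sigma, self.n_channels))

    def inband_rms_fraction(self, band=(70.0, 150.0)) -> float:
        """Fraction of pink-background RMS inside the high-gamma band.

        The idealized pink spectrum has power density ∝ 1/f between
        ``pink_fmin_hz`` and Nyquist, so the in-band variance fraction
        is a ratio of logarithms.
        """
        lo, hi = band
        nyq = self.sample_rate / 2.0
        return float(
            np.sqrt(np.log(hi / lo) / np.log(nyq / self.pink_fmin_hz))
        )


@dataclass
class GroundTruth:
    """Planted structure a recovery test can grade against."""

    active_channels: tuple
    connectivity: np.ndarray  # (n_pairs, n_channels)
    pairs: list
    pair_indices: dict
    esm_labels: dict  # pair -> {0, 1}
    planted_coefficients: tuple
    linear_predictor: dict = field(default_factory=dict)  # pair -> float
    label_probability: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# noise primitives
# ---------------------------------------------------------------------------


def _pink(rng: np.random.Generator, n_rows: int, n_samples: int,
          fs: float, fmin: float) -> np.ndarray:
    """Unit-RMS pink (1/f) Gaussian noise, flat below ``fmin``."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(freqs, fmin))
    amp[0] = 0.0
    spec = (
        rng.standard_normal((n_rows, freqs.size))
        + 1j * rng.standard_normal((n_rows, freqs.size))
    ) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _band_noise(rng: np.random.Generator, n_samples: int, fs: float,
                band=(70.0, 150.0)) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` (burst carrier)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.zeros(freqs.size, dtype=complex)
    spec[keep] = rng.standard_normal(keep.sum()) + 1j * rng.standard_normal(keep.sum())
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _background(config: SynthConfig, rng: np.random.Generator,
                n_samples: int) -> np.ndarray:
    """Pink + per-block common mode + 60 Hz line, shape (channels, samples)."""
    fs = config.sample_rate
    gains = config.channel_gains()
    sig = config.noise_std * gains[:, None] * _pink(
        rng, config.n_channels, n_samples, fs, config.pink_fmin_hz
    )
    labels = config.block_labels()
    common = _pink(rng, config.n_blocks, n_samples, fs, config.pink_fmin_hz)
    t = np.arange(n_samples) / fs
    for b in range(config.n_blocks):
        phase = rng.uniform(0, 2 * np.pi)
        line = config.line_noise_amp * np.sin(2 * np.pi * 60.0 * t + phase)
        sig[labels == b] += config.common_mode_std * common[b] + line
    return sig


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


def ground_truth(config: SynthConfig) -> GroundTruth:
    """Resolve (deterministically from the seed) the planted structure.

    Draw order within the truth stream: active set, then one
    (n_targets, targets, weights) triple per pair in pair order.
    """
    rng = config._rng(_TAG_TRUTH)
    pairs = config.pairs()
    pair_idx = config.pair_indices()
    if config.active_channels is not None:
        active = tuple(sorted(int(c) for c in config.active_channels))
    else:
        k = max(2, int(round(0.35 * config.n_channels)))
        active = tuple(
            sorted(int(c) for c in rng.choice(config.n_channels, size=k, replace=False))
        )
    if config.connectivity is not None:
        conn = np.asarray(config.connectivity, dtype=float)
    else:
        conn = np.zeros((len(pairs), config.n_channels))
        for p, pair in enumerate(pairs):
            i, j = pair_idx[pair]
            candidates = np.setdiff1d(np.arange(config.n_channels), [i, j])
            n_targets = int(rng.integers(0, 5))
            targets = rng.choice(candidates, size=n_targets, replace=False)
            conn[p, targets] = rng.uniform(8.0, 14.0, size=n_targets)
    truth = GroundTruth(
        active_channels=active,
        connectivity=conn,
        pairs=pairs,
        pair_indices=pair_idx,
        esm_labels={},
        planted_coefficients=tuple(config.esm_link_coefficients),
    )
    plant_esm_labels(truth, config)
    return truth


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def plant_esm_labels(truth: GroundTruth, config: SynthConfig,
                     coefficients=None) -> dict:
    """Draw ESM± labels from the planted logistic model.

    The linear predictor combines, per pair: the pair's own activation
    (sum over its electrodes of squared activation indicators), its
    planted centrality (uniform over active channels, mirroring the
    near-unit correlation of co-bursting sites), and the
    connectivity-weighted network activation
    Σ_c connectivity[pair, c] · active[c] / n_channels. The three
    planted features are z-scored across pairs before the coefficients
    apply, so coefficient magnitudes are comparable across cohorts.

    Labels are drawn from a dedicated seed stream: re-planting with new
    coefficients never changes the signals.
    """
    g0, g1, g2, g3 = (
        coefficients if coefficients is not None else config.esm_link_coefficients
    )
    act = np.zeros(config.n_channels)
    act[list(truth.active_channels)] = 1.0
    n_active = max(1, len(truth.active_channels))
    cent = act / n_active
    a = np.array(
        [
            act[i] ** 2 + act[j] ** 2
            for i, j in (truth.pair_indices[p] for p in truth.pairs)
        ]
    )
    c = np.array(
        [
            cent[i] ** 2 + cent[j] ** 2
            for i, j in (truth.pair_indices[p] for p in truth.pairs)
        ]
    )
    net = truth.connectivity @ act / config.n_channels
    eta = g1 * _zscore(a) + g2 * _zscore(c) + g3 * _zscore(net)
    # center at the cohort median so ESM+ prevalence sits near 50% for
    # any coefficient scale (the recorded cohorts were near-balanced);
    # the intercept then shifts prevalence away from that anchor
    eta = eta - np.median(eta) + g0
    prob = 1.0 / (1.0 + np.exp(-eta))
    rng = config._rng(_TAG_LABELS)
    draws = rng.uniform(size=len(truth.pairs))
    truth.esm_labels = {
        p: int(draws[k] < prob[k]) for k, p in enumerate(truth.pairs)
    }
    truth.linear_predictor = {p: float(eta[k]) for k, p in enumerate(truth.pairs)}
    truth.label_probability = {p: float(prob[k]) for k, p in enumerate(truth.pairs)}
    truth.planted_coefficients = (g0, g1, g2, g3)
    return truth.esm_labels


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------


def _channel_table(config: SynthConfig) -> pd.DataFrame:
    return make_channel_table(
        config.channel_names(), config.block_labels(), modality="grid"
    )


def generate_task_session(config: SynthConfig):
    """Task run with planted high-gamma bursts at the active channels.

    Returns ``(session, truth)``. Draw order in the task stream:
    trial intervals, background noise, then per-trial (jitter, one
    carrier per active channel).
    """
    truth = ground_truth(config)
    rng = config._rng(_TAG_TASK)
    fs = config.sample_rate
    if fs != 1000.0:
        raise ValueError("task generator is defined at 1 kHz")
    lo, hi = config.trial_interval_ms
    intervals = rng.uniform(lo, hi, size=config.n_task_trials)
    onsets = 1500.0 + np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    n_samples = int(onsets[-1] + config.trial_window_ms[1] + 1500)
    sig = _background(config, rng, n_samples)

    inband = config.noise_std * config.channel_gains() * config.inband_rms_fraction()
    span = int(config.burst_duration_ms)
    sigma_env = config.burst_duration_ms / 4.0
    for onset in onsets:
        for ch in truth.active_channels:
            jitter = rng.normal(0.0, config.burst_jitter_sd_ms)
            start = int(round(onset + jitter + config.burst_onset_ms))
            center = start + span / 2.0
            t = np.arange(start, start + span)
            envelope = np.exp(-((t - center) ** 2) / (2 * sigma_env**2))
            carrier = _band_noise(rng, span, fs)
            if config.hg_burst_gain > 0 and start >= 0 and start + span <= n_samples:
                sig[ch, start : start + span] += (
                    config.hg_burst_gain * inband[ch] * envelope * carrier
                )
    events = pd.DataFrame(
        {
            "onset_ms": onsets,
            "duration_ms": np.full(onsets.size, config.burst_duration_ms),
            "trial_type": ["task"] * onsets.size,
        }
    )
    session = Session(
        signals=sig,
        sample_rate=fs,
        channels=_channel_table(config),
        events=events,
        meta={"kind": "task", "seed": config.seed},
    )
    return session, truth


def _n1_kernel(width_ms: float, half_span_ms: float = 15.0):
    """Negative Gaussian trough, peak −1 at lag 0."""
    t = np.arange(-half_span_ms, half_span_ms + 1)
    return t.astype(int), -np.exp(-(t**2) / (2 * width_ms**2))


def _artifact_kernel():
    """Damped 300 Hz oscillation confined to 0–8 ms post pulse."""
    t = np.arange(0, 9)
    return t, np.exp(-t / 3.0) * np.sin(2 * np.pi * 0.3 * t)


def generate_spes_session(config: SynthConfig, pair: str) -> Session:
    """Single-pulse stimulation run for one pair.

    Pulses are jittered within ``isi_range_s``; the stimulated channels
    carry a large 0–8 ms artifact (inside the 0–10 ms blanking span);
    every connected response channel receives a negative deflection at a
    latency drawn once per channel from the truncated N1 latency
    distribution, with amplitude ``weight × measured baseline SD`` of
    that channel's trial-averaged background (see module docstring).
    """
    if config.n_pulses_per_pair <= 0:
        raise ValueError("n_pulses_per_pair must be positive")
    truth = ground_truth(config)
    if pair not in truth.pairs:
        raise ValueError(f"{pair!r} is not a stimulated pair of this config")
    p = truth.pairs.index(pair)
    i, j = truth.pair_indices[pair]
    rng = config._rng(_TAG_SPES, p)
    fs = config.sample_rate
    lo_s, hi_s = config.isi_range_s
    intervals = rng.uniform(lo_s * 1000, hi_s * 1000, size=config.n_pulses_per_pair)
    pulses = 1000.0 + np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    n_samples = int(pulses[-1] + 1500)
    sig = _background(config, rng, n_samples)

    # per-channel baseline SD of the trial-averaged (baseline-demeaned)
    # background, measured before deflections are added
    pulse_idx = np.round(pulses).astype(int)
    base_sd = _averaged_baseline_sd(sig, pulse_idx)

    art_t, art = _artifact_kernel()
    for t0 in pulse_idx:
        sig[i, t0 + art_t] += 500.0 * art
        sig[j, t0 + art_t] += 500.0 * art
        sig[:, t0 + art_t] += 50.0 * art  # common stimulus break-through

    weights = truth.connectivity[p]
    lat_a = (10.0 - config.n1_latency_mean_ms) / config.n1_latency_sd_ms
    lat_b = (50.0 - config.n1_latency_mean_ms) / config.n1_latency_sd_ms
    ker_t, ker = _n1_kernel(config.n1_width_ms)
    # peak attenuation of the trough under the scorer's smoothing; the
    # planted amplitude is inflated by 1/r so the *smoothed* trough hits
    # the requested multiple of the smoothed baseline SD
    r = float(np.max(np.abs(boxcar_smooth(ker))))
    planted_latency = {}
    planted_amplitude = {}
    for c in range(config.n_channels):
        if c in (i, j) or weights[c] <= 0:
            continue
        lat = float(
            truncnorm.rvs(
                lat_a,
                lat_b,
                loc=config.n1_latency_mean_ms,
                scale=config.n1_latency_sd_ms,
                random_state=rng,
            )
        )
        lat = float(round(lat))
        amp = weights[c] * base_sd[c] / r
        planted_latency[c] = lat
        planted_amplitude[c] = amp
        for t0 in pulse_idx:
            idx = t0 + int(lat) + ker_t
            sig[c, idx] += amp * ker
    stim_log = pd.DataFrame(
        {
            "pair": [pair] * pulses.size,
            "pulse_onset_ms": pulses,
            "current_ma": np.full(pulses.size, 5.0),
        }
    )
    return Session(
        signals=sig,
        sample_rate=fs,
        channels=_channel_table(config),
        events=None,
        stim_log=stim_log,
        meta={
            "kind": "spes",
            "pair": pair,
            "seed": config.seed,
            "planted_latency_ms": planted_latency,
            "planted_amplitude_uv": planted_amplitude,
            "baseline_sd_uv": {c: float(base_sd[c]) for c in planted_latency},
        },
    )


def _averaged_baseline_sd(sig: np.ndarray, pulse_idx: np.ndarray,
                          window=(-500, 300)) -> np.ndarray:
    """Baseline SD of the pulse-averaged, demeaned, smoothed waveform.

    Mirrors the downstream CCEP scorer (per-epoch baseline demeaning,
    averaging, boxcar smoothing) so planted amplitudes expressed in
    "baseline SD" units calibrate the z-score the analysis will report.
    """
    lo, hi = window
    times = np.arange(lo, hi)
    base_cols = (times >= -500) & (times <= -10)
    acc = np.zeros((sig.shape[0], times.size))
    n = 0
    for t0 in pulse_idx:
        if t0 + lo < 0 or t0 + hi > sig.shape[1]:
            continue
        ep = sig[:, t0 + lo : t0 + hi]
        ep = ep - ep[:, base_cols].mean(axis=1, keepdims=True)
        acc += ep
        n += 1
    mean = boxcar_smooth(acc / max(n, 1))
    return mean[:, base_cols].std(axis=1, ddof=1)
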