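"""In-memory container for a multichannel iEEG recording session.

A :class:`Session` bundles the signal matrix with the channel table,
task events, and the single-pulse stimulation log. All onset/time
columns are in milliseconds relative to recording start; signals are in
microvolts; channel indexing is 0-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: required columns of the channel table
CHANNEL_COLUMNS = ("name", "car_block", "bad", "modality")


def make_channel_table(
    names,
    car_blocks,
    bad=None,
    modality="grid",
) -> pd.DataFrame:
    """Build a channel table with the canonical columns."""
    names = list(names)
    n = len(names)
    bad = np.zeros(n, dtype=bool) if bad is None else np.asarray(bad, dtype=bool)
    if np.isscalar(modality) or isinstance(modality, str):
        modality = [modality] * n
    return pd.DataFrame(
        {
            "name": names,
            "car_block": np.asarray(car_blocks),
            "bad": bad,
            "modality": list(modality),
        }
    )


def pair_id(name_a: str, name_b: str) -> str:
    return f"{name_a}-{name_b}"


def parse_pair(pair: str, channels: pd.DataFrame) -> tuple[int, int]:
    """Resolve a ``"nameA-nameB"`` pair id to channel indices.

    Channel names themselves may contain hyphens only if the split is
    unambiguous; synthetic sessions use hyphen-free names.
    """
    names = list(channels["name"])
    for cut in range(1, len(pair)):
        a, sep, b = pair[:cut], pair[cut], pair[cut + 1 :]
        if sep == "-" and a in names and b in names:
            return names.index(a), names.index(b)
    raise ValueError(f"pair {pair!r} does not reference two known channels")


@dataclass
class Session:
    """One recording: signals + channel table + event/stim logs.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        Voltage traces in microvolts.
    sample_rate : float
        Sampling rate in Hz.
    channels : DataFrame
        One row per channel with columns ``name, car_block, bad, modality``.
    events : DataFrame, optional
        Task events with columns ``onset_ms, duration_ms, trial_type``.
    stim_log : DataFrame, optional
        Single-pulse log with columns ``pair, pulse_onset_ms, current_ma``.
    """

    signals: np.ndarray
    sample_rate: float
    channels: pd.DataFrame
    events: pd.DataFrame | None = None
    stim_log: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (channels x samples)")
        for col in CHANNEL_COLUMNS:
            if col not in self.channels.columns:
                raise ValueError(f"channel table missing column {col!r}")
        if len(self.channels) != self.signals.shape[0]:
            raise ValueError(
                f"channel table has {len(self.channels)} rows for "
                f"{self.signals.shape[0]} signal channels"
            )
        if self.sample_rate < 1000:
            raise ValueError("sample_rate must be at least 1000 Hz")
        if self.events is not None and len(self.events):
            bad_rows = self.events.index[
                (self.events["onset_ms"] < 0)
                | (self.events["onset_ms"] > self.duration_ms)
            ].tolist()
            if bad_rows:
                raise ValueError(
                    f"event onsets outside recording at rows {bad_rows}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sample_rate * 1000.0

    @property
    def good_mask(self) -> np.ndarray:
        return ~self.channels["bad"].to_numpy(dtype=bool)

    def copy_with(self, **updates) -> "Session":
        """Shallow copy with selected fields replaced."""
        return dataclasses.replace(self, **updates)

    def pair_indices(self, pair: str) -> tuple[int, int]:
        return parse_pair(pair, self.channels)
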