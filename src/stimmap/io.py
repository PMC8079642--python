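"""On-disk formats: HDF5 session container, TSV/CSV tables, JSON reports.

Conventions (used everywhere): all time columns in milliseconds relative
to recording start, 0-based channel indexing, UTF-8 text, header rows
mandatory, tab separation for ``.tsv`` and comma for ``.csv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .session import CHANNEL_COLUMNS, Session

_EVENT_COLUMNS = ("onset_ms", "duration_ms", "trial_type")
_STIM_COLUMNS = ("pair", "pulse_onset_ms", "current_ma")


def write_session(session: Session, path) -> Path:
    """Write a session to an HDF5 container (signals + tables)."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("signals", data=session.signals)
        fh.attrs["sample_rate"] = session.sample_rate
        grp = fh.create_group("channels")
        for col in CHANNEL_COLUMNS:
            vals = session.channels[col].to_numpy()
            if vals.dtype.kind in ("U", "O"):
                vals = vals.astype("S")
            grp.create_dataset(col, data=vals)
        for name, df, cols in (
            ("events", session.events, _EVENT_COLUMNS),
            ("stim_log", session.stim_log, _STIM_COLUMNS),
        ):
            if df is None:
                continue
            g = fh.create_group(name)
            for col in cols:
                vals = df[col].to_numpy()
                if vals.dtype.kind in ("U", "O"):
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)
    return path


def _read_table(grp, cols) -> pd.DataFrame:
    data = {}
    for col in cols:
        vals = grp[col][()]
        if vals.dtype.kind == "S":
            vals = vals.astype(str)
        data[col] = vals
    return pd.DataFrame(data)


def read_session(path) -> Session:
    """Read a session container written by :func:`write_session`."""
    path = Path(path)
    with h5py.File(path, "r") as fh:
        if "signals" not in fh:
            raise ValueError(f"{path}: missing 'signals' dataset")
        if "channels" not in fh:
            raise ValueError(f"{path}: missing channel table")
        signals = fh["signals"][()]
        sample_rate = float(fh.attrs["sample_rate"])
        channels = _read_table(fh["channels"], CHANNEL_COLUMNS)
        channels["bad"] = channels["bad"].astype(bool)
        events = (
            _read_table(fh["events"], _EVENT_COLUMNS) if "events" in fh else None
        )
        stim_log = (
            _read_table(fh["stim_log"], _STIM_COLUMNS)
            if "stim_log" in fh
            else None
        )
    return Session(
        signals=signals,
        sample_rate=sample_rate,
        channels=channels,
        events=events,
        stim_log=stim_log,
    )


def write_events_tsv(events: pd.DataFrame, path) -> Path:
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path, duration_ms: float | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing event columns {sorted(missing)}")
    if duration_ms is not None:
        bad = df.index[df["onset_ms"] > duration_ms].tolist()
        if bad:
            raise ValueError(
                f"{path}: onsets beyond recording length at rows {bad}"
            )
    return df


def write_stim_tsv(stim_log: pd.DataFrame, path) -> Path:
    path = Path(path)
    stim_log.to_csv(path, sep="\t", index=False)
    return path


def read_stim_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_STIM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing stim columns {sorted(missing)}")
    return df


def write_ground_truth(truth, path) -> Path:
    path = Path(path)
    payload = {
        "active_channels": [int(c) for c in truth.active_channels],
        "connectivity": np.asarray(truth.connectivity).tolist(),
        "pairs": truth.pairs,
        "esm_labels": truth.esm_labels,
        "planted_coefficients": list(truth.planted_coefficients),
        "linear_predictor": truth.linear_predictor,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path


def write_significance_csv(sig_map, path) -> Path:
    """Long-format (channel, bin_ms, t, p, masked) raster."""
    n_ch, n_bins = sig_map.t_values.shape
    ch = np.repeat(np.arange(n_ch), n_bins)
    bins = np.tile(sig_map.bin_centers_ms, n_ch)
    df = pd.DataFrame(
        {
            "channel": ch,
            "bin_ms": bins,
            "t": sig_map.t_values.ravel(),
            "p": sig_map.p_values.ravel(),
            "masked": sig_map.fdr_mask.ravel(),
        }
    )
    df.to_csv(path, index=False)
    return Path(path)


def write_features_csv(features: pd.DataFrame, path) -> Path:
    features.to_csv(path, index=False)
    return Path(path)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ccep_table(graph, path) -> Path:
    graph.to_table().to_csv(path, index=False)
    return Path(path)
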