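"""Bad-channel exclusion, decimation to 1 kHz, and block-wise CAR.

The common average reference (CAR) subtracts, within each channel
block, the instantaneous mean of the block's usable channels:

    x_car[n, t] = x[n, t] - (1/N) * sum_k x[k, t]

where the sum runs over the N non-bad channels of the block. Blocks are
taken from the ``car_block`` column of the channel table (one block for
standard and one for high-density subdural arrays; one block per depth
shank for stereo-EEG).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .session import Session


class BadChannelDetector(BaseEstimator):
    """Flag channels with outlying broadband amplitude within their block.

    Computes log-RMS per channel and flags channels whose robust z-score
    (deviation from the block median in scaled-MAD units) exceeds
    ``mad_factor``. With ``mad_factor=inf`` nothing is flagged.

    Attributes
    ----------
    bad_mask_ : ndarray of bool, shape (n_channels,)
    log_rms_ : ndarray, shape (n_channels,)
    robust_z_ : ndarray, shape (n_channels,)
    """

    #: scale factor making MAD consistent with the SD of a Gaussian
    _MAD_SCALE = 1.4826

    def __init__(self, mad_factor: float = 5.0):
        self.mad_factor = mad_factor

    def fit(self, X, y=None, *, blocks=None):
        X = np.asarray(X, dtype=np.float64)
        blocks = np.zeros(X.shape[0]) if blocks is None else np.asarray(blocks)
        rms = np.sqrt(np.mean(X**2, axis=1))
        if np.any(rms == 0):
            rms = np.maximum(rms, np.finfo(float).tiny)
        log_rms = np.log(rms)
        z = np.zeros_like(log_rms)
        for blk in np.unique(blocks):
            idx = np.flatnonzero(blocks == blk)
            if idx.size < 3:
                raise ValueError(
                    f"block {blk!r} has {idx.size} channels; need at least 3"
                )
            med = np.median(log_rms[idx])
            mad = np.median(np.abs(log_rms[idx] - med)) * self._MAD_SCALE
            if mad == 0:
                z[idx] = 0.0
            else:
                z[idx] = (log_rms[idx] - med) / mad
        self.log_rms_ = log_rms
        self.robust_z_ = z
        if np.isinf(self.mad_factor):
            self.bad_mask_ = np.zeros(X.shape[0], dtype=bool)
        else:
            self.bad_mask_ = np.abs(z) > self.mad_factor
        for blk in np.unique(blocks):
            idx = np.flatnonzero(blocks == blk)
            if self.bad_mask_[idx].all():
                raise ValueError(f"all channels of block {blk!r} flagged bad")
        return self


class CommonAverageReference(TransformerMixin, BaseEstimator):
    """Block-wise common average reference.

    Parameters
    ----------
    blocks : array-like, shape (n_channels,), optional
        Block label per channel; a single block if omitted.
    exclude : boolean array-like, shape (n_channels,), optional
        Channels excluded from the average (bad channels). Excluded
        channels pass through unreferenced.
    """

    def __init__(self, blocks=None, exclude=None):
        self.blocks = blocks
        self.exclude = exclude

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        n = X.shape[0]
        blocks = (
            np.zeros(n) if self.blocks is None else np.asarray(self.blocks)
        )
        excl = (
            np.zeros(n, dtype=bool)
            if self.exclude is None
            else np.asarray(self.exclude, dtype=bool)
        )
        out = X.copy()
        for blk in np.unique(blocks):
            idx = np.flatnonzero((blocks == blk) & ~excl)
            if idx.size < 2:
                raise ValueError(
                    f"block {blk!r} has {idx.size} usable channels; need >= 2"
                )
            out[idx] -= X[idx].mean(axis=0, keepdims=True)
        return out


def flag_bad_channels(session: Session, mad_factor: float = 5.0) -> Session:
    """Return a session whose channel table has outlier channels flagged bad.

    Flags accumulate: channels already marked bad stay bad.
    """
    det = BadChannelDetector(mad_factor=mad_factor)
    det.fit(session.signals, blocks=session.channels["car_block"].to_numpy())
    channels = session.channels.copy()
    channels["bad"] = channels["bad"].to_numpy(dtype=bool) | det.bad_mask_
    return session.copy_with(channels=channels)


def decimate_signal(X, fs_in: float, fs_out: float = 1000.0, cutoff_hz: float = 400.0):
    """Anti-alias low-pass (zero-phase FIR) and downsample to ``fs_out``."""
    X = np.asarray(X, dtype=np.float64)
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"sample rate {fs_in} Hz is not an integer multiple of {fs_out} Hz; "
            "resample before decimating"
        )
    q = int(round(ratio))
    if q == 1:
        return X.copy()
    numtaps = 30 * q + 1
    taps = sps.firwin(numtaps, cutoff_hz, fs=fs_in)
    filtered = sps.filtfilt(taps, [1.0], X, axis=-1)
    return filtered[..., ::q]


def decimate_to_1khz(session: Session) -> Session:
    """Decimate a session to 1 kHz; event/pulse times (in ms) are unchanged."""
    if session.sample_rate == 1000.0:
        return session.copy_with(signals=session.signals.copy())
    out = decimate_signal(session.signals, session.sample_rate, 1000.0)
    return session.copy_with(signals=out, sample_rate=1000.0)


def common_average_reference(session: Session) -> Session:
    """Apply block-wise CAR over non-bad channels."""
    car = CommonAverageReference(
        blocks=session.channels["car_block"].to_numpy(),
        exclude=session.channels["bad"].to_numpy(dtype=bool),
    )
    return session.copy_with(signals=car.transform(session.signals))


def preprocess_session(
    session: Session, mad_factor: float = 5.0, car: bool = True
) -> Session:
    """flag bad channels -> decimate to 1 kHz -> (optionally) CAR."""
    out = flag_bad_channels(session, mad_factor=mad_factor)
    out = decimate_to_1khz(out)
    if car:
        out = common_average_reference(out)
    return out
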