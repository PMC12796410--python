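"""Band-filtering, epoching, and weighted Phase Lag Index estimation.

The connectivity statistic used throughout is the weighted Phase Lag Index

    wPLI_ij = |sum_k Im(S_ij,k)| / sum_k |Im(S_ij,k)|

where the sum runs over all cross-spectral samples k = (epoch, in-band
frequency bin) from Hann-tapered per-epoch DFTs.  Because only the imaginary
part of the cross-spectrum enters, instantaneous (zero-lag) coupling such as
volume conduction contributes nothing to either numerator or denominator.
Pairs whose denominator is exactly zero are assigned wPLI = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "BandSpec",
    "EpochSet",
    "ConnectivityMatrix",
    "DELTA",
    "THETA",
    "ALPHA",
    "BETA",
    "BROADBAND",
    "bandpass",
    "epoch",
    "wpli",
]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band ``[low_hz, high_hz]`` with a conventional name."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band {self.name!r} requires 0 < low < high, got "
                f"[{self.low_hz}, {self.high_hz}]"
            )

    def check_nyquist(self, rate_hz: float) -> None:
        if self.high_hz >= rate_hz / 2.0:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high_hz} Hz is not "
                f"below the Nyquist frequency {rate_hz / 2.0} Hz"
            )


# Conventional band definitions.  The delta lower edge follows the broadband
# high-pass (0.5 Hz); the upper edge of 4 Hz is the "< 4 Hz" convention.
DELTA = BandSpec("delta", 0.5, 4.0)
THETA = BandSpec("theta", 4.0, 8.0)
ALPHA = BandSpec("alpha", 8.0, 13.0)
BETA = BandSpec("beta", 13.0, 30.0)
#: The broadband pre-filter applied to continuous recordings before epoching.
BROADBAND = BandSpec("broadband", 0.5, 45.0)


@dataclass
class Recording:
    """One participant x condition multichannel signal block.

    ``data`` is channels x samples.
    """

    participant_id: str
    condition: str
    channel_labels: list[str]
    rate_hz: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("data must be channels x samples with >= 2 channels")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match channel count")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class EpochSet:
    """Non-overlapping equal-length segments: array (n_epochs, channels, L)."""

    epochs: np.ndarray
    epoch_length_s: float
    rate_hz: float
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]


@dataclass
class ConnectivityMatrix:
    """Symmetric per-band wPLI weight matrix with zero diagonal."""

    weights: np.ndarray
    band: BandSpec
    participant_id: str = ""
    condition: str = ""
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValueError("wPLI entries must lie in [0, 1]")
        self.weights = w

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


def _fir_taps(band: BandSpec, rate_hz: float) -> np.ndarray:
    """Hamming-window linear-phase FIR bandpass taps.

    The transition bandwidth is 25% of each band edge frequency (clamped to
    the available headroom below Nyquist); the tap count follows the Hamming
    window rule N ~ 3.3 / (normalized transition width), forced odd so the
    group delay (N-1)/2 is integral.
    """
    nyq = rate_hz / 2.0
    trans_low = 0.25 * band.low_hz
    trans_high = min(0.25 * band.high_hz, nyq - band.high_hz)
    if trans_high <= 0:
        raise ValueError("no transition headroom below Nyquist")
    trans = min(trans_low, trans_high)
    numtaps = int(np.ceil(3.3 * rate_hz / trans))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(
        numtaps,
        [band.low_hz, band.high_hz],
        pass_zero=False,
        fs=rate_hz,
        window="hamming",
    )


def _zero_phase_filter(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR with reflect padding and delay compensation.

    A symmetric (linear-phase) kernel applied once and shifted by its group
    delay is exactly zero-phase, so no forward-backward pass is needed.
    """
    half = (len(taps) - 1) // 2
    n = data.shape[-1]
    if half >= n:
        raise ValueError(
            f"signal too short for filter: {n} samples < {half + 1} needed"
        )
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(half, half)], mode="reflect")
    out = signal.fftconvolve(padded, taps[np.newaxis, :], mode="same", axes=-1)
    return out[..., half:-half]


def bandpass(rec: Recording, band: BandSpec) -> Recording:
    """Zero-phase FIR bandpass of a recording; same shape out.

    Stopband attenuation one octave outside the passband is >= 20 dB by the
    Hamming design (typical sidelobe floor ~ -53 dB).
    """
    band.check_nyquist(rec.rate_hz)
    taps = _fir_taps(band, rec.rate_hz)
    filtered = _zero_phase_filter(rec.data, taps)
    return replace(rec, data=filtered, channel_labels=list(rec.channel_labels))


def epoch(rec: Recording, epoch_length_s: float = 4.0) -> EpochSet:
    """Cut a recording into non-overlapping ``epoch_length_s`` segments.

    ``floor(duration/epoch_length)`` epochs are produced; any trailing
    remainder is discarded.  A recording shorter than one epoch is an error.
    """
    L = int(round(epoch_length_s * rec.rate_hz))
    if L <= 0:
        raise ValueError("epoch length must be positive")
    n_ep = rec.n_samples // L
    if n_ep == 0:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s is shorter than one "
            f"{epoch_length_s} s epoch"
        )
    trimmed = rec.data[:, : n_ep * L]
    epochs = trimmed.reshape(rec.n_channels, n_ep, L).transpose(1, 0, 2)
    return EpochSet(
        epochs=np.ascontiguousarray(epochs),
        epoch_length_s=epoch_length_s,
        rate_hz=rec.rate_hz,
        channel_labels=list(rec.channel_labels),
    )


def band_bins(n_samples: int, rate_hz: float, band: BandSpec) -> np.ndarray:
    """Indices of rfft bins with low_hz <= f <= high_hz (inclusive)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    idx = np.nonzero((freqs >= band.low_hz) & (freqs <= band.high_hz))[0]
    if idx.size == 0:
        raise ValueError(
            f"band {band.name!r} contains no DFT bins at resolution "
            f"{rate_hz / n_samples:.4f} Hz"
        )
    return idx


def wpli(
    epochs: EpochSet,
    band: BandSpec,
    participant_id: str = "",
    condition: str = "",
) -> ConnectivityMatrix:
    """Weighted Phase Lag Index pooled over epochs and in-band bins.

    Each epoch is Hann-tapered and transformed with an rfft; cross-spectra
    ``S_ij = Z_i conj(Z_j)`` at all in-band bins of all epochs form the
    sample set over which the |E Im| / E |Im| ratio is taken.
    """
    if epochs.n_epochs < 2:
        raise ValueError("wPLI needs at least 2 epochs")
    band.check_nyquist(epochs.rate_hz)

    variances = epochs.epochs.var(axis=(0, 2))
    dead = np.nonzero(variances == 0)[0]
    if dead.size:
        labels = [
            epochs.channel_labels[i] if epochs.channel_labels else str(i)
            for i in dead
        ]
        logger.warning(
            "zero-variance channel(s) %s: connectivity row/column set to 0",
            labels,
        )

    L = epochs.samples_per_epoch
    taper = np.hanning(L)
    Z = np.fft.rfft(epochs.epochs * taper, axis=-1)
    Z = Z[:, :, band_bins(L, epochs.rate_hz, band)]

    # Im(S_ij) over (epoch, i, j, bin); pooled sums over epochs and bins.
    im = np.einsum("eif,ejf->eijf", Z, np.conj(Z)).imag
    num = np.abs(im.sum(axis=(0, 3)))
    den = np.abs(im).sum(axis=(0, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    w = 0.5 * (w + w.T)  # symmetrize away float asymmetry
    np.fill_diagonal(w, 0.0)
    w = np.clip(w, 0.0, 1.0)
    return ConnectivityMatrix(
        weights=w,
        band=band,
        participant_id=participant_id or getattr(epochs, "participant_id", ""),
        condition=condition,
        channel_labels=list(epochs.channel_labels),
    )
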