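"""Epoch segmentation, artifact rejection, epoch subsampling, PSD and band-pass filtering.

The preprocessing chain mirrors a standard resting-state EEG protocol:
a continuous multichannel recording is cut into fixed-length epochs, epochs
containing high-amplitude artifacts or a theta/alpha power ratio above 1 are
discarded, a fixed number of the surviving epochs is drawn at random, and the
retained epochs are band-pass filtered into canonical frequency bands before
connectivity estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges: {self.low}-{self.high} Hz")


#: Canonical 11-band table used throughout the pipeline.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("beta1", 12.0, 18.0),
    BandDefinition("beta2", 18.0, 22.0),
    BandDefinition("beta3", 22.0, 30.0),
    BandDefinition("beta4", 18.0, 30.0),
    BandDefinition("gamma", 30.0, 55.0),
)


def band_table() -> list[BandDefinition]:
    """Return the canonical 11-entry frequency band table."""
    return list(BANDS)


def get_band(name: str) -> BandDefinition:
    """Look up a band by name (case-insensitive)."""
    for b in BANDS:
        if b.name == name.lower():
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in BANDS]}")


@dataclass
class EpochSet:
    """A fixed-length multichannel epoch collection for one subject.

    Attributes
    ----------
    data : ndarray, shape (n_epochs, n_nodes, n_samples)
        Signal amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    node_labels : list of str
        One label per node/channel.
    """

    data: np.ndarray
    fs: float
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, nodes, samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.node_labels:
            self.node_labels = [f"node{i:03d}" for i in range(self.data.shape[1])]
        if len(self.node_labels) != self.data.shape[1]:
            raise ValueError("node_labels length must match node axis")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_seconds(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "EpochSet":
        return EpochSet(data=data, fs=self.fs, node_labels=list(self.node_labels))


def segment_epochs(continuous: np.ndarray, fs: float, epoch_seconds: float = 2.0) -> EpochSet:
    """Cut a continuous (nodes x samples) recording into non-overlapping epochs.

    The trailing remainder shorter than one epoch is discarded.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    n_nodes, n_samples = continuous.shape
    per = int(round(fs * epoch_seconds))
    if per < 1:
        raise ValueError("epoch length must be at least one sample")
    n_ep = n_samples // per
    if n_ep == 0:
        raise ValueError(
            f"recording of {n_samples} samples is shorter than one "
            f"{epoch_seconds} s epoch at {fs} Hz"
        )
    trimmed = continuous[:, : n_ep * per]
    data = trimmed.reshape(n_nodes, n_ep, per).transpose(1, 0, 2)
    return EpochSet(data=data, fs=fs)


def reject_amplitude(epochs: EpochSet, limit: float = 100.0) -> tuple[EpochSet, np.ndarray]:
    """Drop epochs where any sample at any node strictly exceeds ``|limit|`` microvolts.

    Returns the surviving epochs and a boolean keep-mask over the input epochs.
    The boundary is strict: a sample exactly at the limit is kept.
    """
    if limit <= 0:
        raise ValueError("limit must be positive")
    keep = ~(np.abs(epochs.data) > limit).any(axis=(1, 2))
    if not keep.any():
        warnings.warn("amplitude rejection removed every epoch", stacklevel=2)
    return epochs.copy_with(epochs.data[keep]), keep


def psd_periodogram(epoch: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram PSD of a (nodes x samples) epoch.

    Returns (freqs, psd) with psd in power per Hz; integrating the PSD over
    the full one-sided grid recovers the mean signal power (Parseval).
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[-1] < 2:
        raise ValueError("need at least 2 samples for a periodogram")
    freqs, psd = signal.periodogram(epoch, fs=fs, window="boxcar",
                                    detrend=False, scaling="density", axis=-1)
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Rectangle-rule power integral over periodogram bins strictly inside the band."""
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    inside = (freqs > band.low) & (freqs < band.high)
    return psd[..., inside].sum(axis=-1) * df


def reject_theta_alpha(
    epochs: EpochSet, threshold: float = 1.0
) -> tuple[EpochSet, np.ndarray]:
    """Drop epochs whose node-averaged theta/alpha power ratio strictly exceeds ``threshold``.

    Band powers are integrated from the per-epoch periodogram (theta 4-8 Hz,
    alpha 8-12 Hz) and averaged over nodes before forming the ratio. An epoch
    with zero alpha power has an undefined ratio and is removed with a warning.
    """
    theta, alpha = get_band("theta"), get_band("alpha")
    keep = np.ones(epochs.n_epochs, dtype=bool)
    for i in range(epochs.n_epochs):
        freqs, psd = psd_periodogram(epochs.data[i], epochs.fs)
        p_theta = float(band_power(freqs, psd, theta).mean())
        p_alpha = float(band_power(freqs, psd, alpha).mean())
        if p_alpha == 0.0:
            warnings.warn(
                f"epoch {i}: zero alpha power, theta/alpha ratio undefined; removed",
                stacklevel=2,
            )
            keep[i] = False
        elif p_theta / p_alpha > threshold * (1.0 + 1e-9):
            # strict "exceeding"; the epsilon keeps exact power ties (ratio == 1
            # up to float rounding) on the "kept" side of the boundary
            keep[i] = False
    return epochs.copy_with(epochs.data[keep]), keep


def select_epochs(
    epochs: EpochSet, k: int = 30, seed: int | np.random.Generator = 0,
    allow_fewer: bool = False,
) -> EpochSet:
    """Draw ``k`` epochs uniformly without replacement, preserving temporal order."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if epochs.n_epochs < k:
        if not allow_fewer:
            raise ValueError(f"only {epochs.n_epochs} epochs available, need {k}")
        warnings.warn(
            f"only {epochs.n_epochs} epochs available (< {k}); keeping all", stacklevel=2
        )
        return epochs.copy_with(epochs.data.copy())
    idx = np.sort(rng.choice(epochs.n_epochs, size=k, replace=False))
    return epochs.copy_with(epochs.data[idx])


def bandpass(epochs: EpochSet, band: BandDefinition, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass of every epoch and node.

    A 4th-order design applied forward-backward (``sosfiltfilt``) gives ~unit
    gain in-band and steep attenuation one octave outside the edges.
    """
    nyq = epochs.fs / 2.0
    if band.high >= nyq:
        raise ValueError(f"band {band.name} upper edge {band.high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [band.low, band.high], btype="bandpass",
                        fs=epochs.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.copy_with(filtered)
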