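"""Instantaneous phase and phase-locking value (PLV) connectivity.

The PLV between two signals is the magnitude of the time-averaged unit phasor
of their instantaneous phase difference,

    PLV = | mean_t exp(i (phi_x(t) - phi_y(t))) |,

which is 1 for a constant lag and decays toward the finite-sample floor
~ sqrt(pi)/(2 sqrt(T_eff)) for independent phases. Phases are extracted from
the analytic signal (Hilbert transform) of band-limited data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import BandDefinition, EpochSet


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node PLV matrix for one frequency band."""

    values: np.ndarray
    band: BandDefinition | None = None
    n_epochs_used: int = 0
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("PLV entries must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Analytic-signal phase of a 1-D signal, in (-pi, pi].

    For a pure sinusoid of frequency f the unwrapped phase has slope 2*pi*f.
    Constant input has no defined phase and raises.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("instantaneous_phase expects a 1-D signal")
    if np.ptp(x) == 0:
        raise ValueError("phase is undefined for a constant signal")
    return np.angle(hilbert(x))


def plv_pair(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """PLV of two phase series: |mean exp(i(phase_x - phase_y))|."""
    phase_x = np.asarray(phase_x, dtype=float)
    phase_y = np.asarray(phase_y, dtype=float)
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase series must have equal length")
    if phase_x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.exp(1j * (phase_x - phase_y)).mean()))


def _epoch_phasors(epoch: np.ndarray, edge_fraction: float) -> np.ndarray:
    """Unit phasors of the analytic-signal phase, edges trimmed, nodes x samples."""
    if (np.ptp(epoch, axis=-1) == 0).any():
        raise ValueError("constant node signal: phase undefined")
    n = epoch.shape[-1]
    trim = int(round(edge_fraction * n))
    if n - 2 * trim < 2:
        raise ValueError("edge trimming leaves fewer than 2 samples")
    z = hilbert(epoch, axis=-1)
    z = z[..., trim: n - trim] if trim else z
    return z / np.abs(z)


def plv_matrix(
    band_filtered: EpochSet,
    edge_fraction: float = 0.1,
    mode: str = "epochs",
    band: BandDefinition | None = None,
) -> ConnectivityMatrix:
    """All-pairs PLV matrix of a band-filtered epoch set.

    Parameters
    ----------
    band_filtered : EpochSet
        Band-limited epochs (see :func:`srcnet.preprocess.bandpass`).
    edge_fraction : float
        Fraction of samples discarded at each epoch edge before the PLV, to
        suppress filter and Hilbert edge effects.
    mode : {"epochs", "concatenate"}
        ``"epochs"`` computes a PLV per epoch and averages across epochs
        (epochs are the unit of artifact control); ``"concatenate"`` pools the
        phasor samples of all epochs into a single estimate, which has a lower
        finite-sample floor.

    Notes
    -----
    The per-epoch estimator is upward-biased for weakly coupled pairs:
    with B effectively independent phase samples per epoch,
    E[PLV_B] ~= sqrt(R^2 + (1 - R^2)/B) where R is the asymptotic PLV.
    """
    if band_filtered.n_epochs < 1:
        raise ValueError("empty epoch set")
    if mode not in ("epochs", "concatenate"):
        raise ValueError("mode must be 'epochs' or 'concatenate'")
    mats = []
    phasors = []
    for e in range(band_filtered.n_epochs):
        z = _epoch_phasors(band_filtered.data[e], edge_fraction)
        if mode == "epochs":
            t = z.shape[-1]
            mats.append(np.abs(z @ z.conj().T) / t)
        else:
            phasors.append(z)
    if mode == "epochs":
        m = np.mean(mats, axis=0)
    else:
        z = np.concatenate(phasors, axis=-1)
        m = np.abs(z @ z.conj().T) / z.shape[-1]
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    np.clip(m, 0.0, 1.0, out=m)
    return ConnectivityMatrix(
        values=m,
        band=band,
        n_epochs_used=band_filtered.n_epochs,
        node_labels=list(band_filtered.node_labels),
    )


def null_plv_floor(n_effective: int) -> float:
    """Expected PLV of independent phases with ``n_effective`` independent samples."""
    if n_effective < 1:
        raise ValueError("n_effective must be >= 1")
    return float(np.sqrt(np.pi) / (2.0 * np.sqrt(n_effective)))


def warn_if_low_epochs(n_epochs: int, minimum: int = 5) -> None:
    if n_epochs < minimum:
        warnings.warn(
            f"PLV averaged over only {n_epochs} epochs; estimates will be noisy",
            stacklevel=2,
        )
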