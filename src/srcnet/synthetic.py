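"""Synthetic cohorts of phase-coupled node time series with PANSS-like scores.

This module is a test harness, not a biophysical model: it produces node-level
oscillatory signals whose pairwise phase coupling is known in closed form, so
that every downstream stage (filtering, PLV, graph metrics, classification)
can be validated against ground truth.

Coupling model
--------------
For a coupled node pair sharing a carrier at f0 Hz, each node's signal is

    x(t) = A * cos(2*pi*f0*t + phi0 + theta(t)) + noise,

where theta(t) is a stationary Gaussian phase-jitter process. The two nodes'
jitters are independent with variance sigma^2/2 each, so the phase difference
is Gaussian with variance sigma^2 and the asymptotic phase-locking value is

    E[PLV] = |E[exp(i * dtheta)]| = exp(-sigma^2 / 2).

The jitter is smooth (white noise circularly convolved with a Gaussian kernel
and rescaled to an exact marginal standard deviation), keeping the signal
narrowband so analytic-signal phase extraction is well behaved; a
piecewise-constant jitter would inject broadband transients at every block
boundary. The kernel width only controls how many effectively independent
phase samples a finite window contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .panss import ALL_ITEMS, PanssRecord
from .preprocess import EpochSet, get_band


@dataclass(frozen=True)
class CouplingSpec:
    """Phase coupling imposed on node pairs within one frequency band.

    ``edges`` lists (node_i, node_j, jitter_sigma) triples; jitter_sigma is the
    standard deviation (radians) of the pairwise phase difference, so the
    expected PLV of the pair is exp(-jitter_sigma**2 / 2).
    """

    band_name: str
    edges: tuple[tuple[int, int, float], ...]
    base_frequency: float

    def __post_init__(self) -> None:
        band = get_band(self.band_name)
        if not (band.low <= self.base_frequency <= band.high):
            raise ValueError(
                f"base_frequency {self.base_frequency} Hz outside band "
                f"{band.name} ({band.low}-{band.high} Hz)"
            )
        for i, j, sigma in self.edges:
            if i == j:
                raise ValueError(f"self-coupling edge ({i}, {j})")
            if min(i, j) < 0:
                raise ValueError("node indices must be non-negative")
            if sigma < 0:
                raise ValueError("jitter_sigma must be >= 0")

    def validate_nodes(self, n_nodes: int) -> None:
        for i, j, _ in self.edges:
            if max(i, j) >= n_nodes:
                raise ValueError(f"edge ({i}, {j}) exceeds n_nodes={n_nodes}")


@dataclass
class CohortConfig:
    """Full specification of a two-group (or k-group) synthetic cohort.

    Defaults mirror the analysis protocol: two-second epochs at 1000 Hz,
    30 epochs per subject, 148 nodes.
    """

    n_subjects_per_group: int
    group_coupling: Sequence[Sequence[CouplingSpec]]
    n_nodes: int = 148
    fs: float = 1000.0
    epoch_seconds: float = 2.0
    n_epochs: int = 30
    noise_sd: float = 5.0          # broadband background, microvolts
    osc_amplitude: float = 10.0    # coupled-oscillation amplitude, microvolts
    artifact_rate: float = 0.0     # probability an epoch receives a pulse artifact
    artifact_amplitude: float = 150.0  # microvolts, exceeds the +/-100 uV rule
    panss_effects: Sequence[Mapping[str, float]] | None = None  # per-group item shifts
    group_names: Sequence[str] | None = None
    seed: int = 0
    jitter_smooth_seconds: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1 or self.n_nodes < 2 or self.n_epochs < 1:
            raise ValueError("counts must be positive (and n_nodes >= 2)")
        if self.fs <= 0 or self.epoch_seconds <= 0:
            raise ValueError("fs and epoch_seconds must be positive")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate must be in [0, 1]")
        for specs in self.group_coupling:
            for spec in specs:
                spec.validate_nodes(self.n_nodes)
                if spec.base_frequency >= self.fs / 2:
                    raise ValueError("coupling frequency at or above Nyquist")
        n_groups = len(self.group_coupling)
        if self.group_names is None:
            self.group_names = [chr(ord("A") + g) for g in range(n_groups)]
        if len(self.group_names) != n_groups:
            raise ValueError("group_names must match group_coupling length")
        if self.panss_effects is not None and len(self.panss_effects) != n_groups:
            raise ValueError("panss_effects must have one mapping per group")


@dataclass
class SyntheticSubject:
    epochs: EpochSet
    group: str
    panss: PanssRecord


def smooth_phase_jitter(
    rng: np.random.Generator, n_samples: int, fs: float, sigma: float,
    smooth_seconds: float = 0.1,
) -> np.ndarray:
    """Stationary Gaussian phase jitter with exact marginal sd ``sigma``.

    White noise is circularly convolved with a Gaussian kernel and rescaled by
    the kernel's exact noise gain, so every sample is N(0, sigma^2) and the
    correlation time is set by ``smooth_seconds``.
    """
    if sigma == 0:
        return np.zeros(n_samples)
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    s = max(smooth_seconds * fs, 1e-9)
    pos = np.arange(n_samples, dtype=float)
    pos = np.minimum(pos, n_samples - pos)  # circular distance from 0
    kernel = np.exp(-0.5 * (pos / s) ** 2)
    gain = np.sqrt(np.sum(kernel**2))
    white = rng.standard_normal(n_samples)
    jitter = np.fft.irfft(np.fft.rfft(white) * np.fft.rfft(kernel), n=n_samples)
    return jitter * (sigma / gain)


def generate_phase_coupled_pair(
    fs: float, duration: float, f0: float, jitter_sigma: float, seed: int,
    smooth_seconds: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Two unit-amplitude cosines whose phase difference is N(0, jitter_sigma^2).

    Returns (x, y) with expected asymptotic PLV exp(-jitter_sigma**2 / 2).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if f0 >= fs / 2:
        raise ValueError("f0 must be below the Nyquist frequency")
    rng = np.random.default_rng(seed)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    phi0 = rng.uniform(0, 2 * np.pi)
    half = jitter_sigma / np.sqrt(2.0)
    th1 = smooth_phase_jitter(rng, n, fs, half, smooth_seconds)
    th2 = smooth_phase_jitter(rng, n, fs, half, smooth_seconds)
    x = np.cos(2 * np.pi * f0 * t + phi0 + th1)
    y = np.cos(2 * np.pi * f0 * t + phi0 + th2)
    return x, y


def generate_panss_items(
    group_label: str,
    panss_effects: Mapping[str, float] | None,
    seed: int | np.random.Generator,
    baseline: float = 3.0,
    item_sd: float = 1.5,
) -> PanssRecord:
    """Draw 30 ordinal item scores from a discretized, clipped normal on 1-7.

    ``panss_effects`` maps item codes to additive shifts of the latent mean
    for this subject's group; unlisted items sit at ``baseline``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    effects = dict(panss_effects or {})
    unknown = [k for k in effects if k not in ALL_ITEMS]
    if unknown:
        raise ValueError(f"unknown PANSS items in effects: {unknown}")
    items = {}
    for code in ALL_ITEMS:
        latent = rng.normal(baseline + effects.get(code, 0.0), item_sd)
        items[code] = int(np.clip(np.rint(latent), 1, 7))
    return PanssRecord(items=items)


def _subject_epochs(
    rng: np.random.Generator, config: CohortConfig, coupling: Sequence[CouplingSpec]
) -> EpochSet:
    n_samp = int(round(config.fs * config.epoch_seconds))
    t = np.arange(n_samp) / config.fs
    data = rng.normal(0.0, config.noise_sd,
                      size=(config.n_epochs, config.n_nodes, n_samp))
    for e in range(config.n_epochs):
        for spec in coupling:
            f0 = spec.base_frequency
            for i, j, sigma in spec.edges:
                phi0 = rng.uniform(0, 2 * np.pi)
                half = sigma / np.sqrt(2.0)
                thi = smooth_phase_jitter(rng, n_samp, config.fs, half,
                                          config.jitter_smooth_seconds)
                thj = smooth_phase_jitter(rng, n_samp, config.fs, half,
                                          config.jitter_smooth_seconds)
                carrier = 2 * np.pi * f0 * t + phi0
                data[e, i] += config.osc_amplitude * np.cos(carrier + thi)
                data[e, j] += config.osc_amplitude * np.cos(carrier + thj)
        if config.artifact_rate > 0 and rng.random() < config.artifact_rate:
            node = rng.integers(config.n_nodes)
            width = max(int(round(0.05 * config.fs)), 1)
            start = rng.integers(max(n_samp - width, 1))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            data[e, node, start: start + width] += sign * config.artifact_amplitude
    return EpochSet(data=data, fs=config.fs)


def generate_cohort(config: CohortConfig) -> list[SyntheticSubject]:
    """Generate all subjects of a cohort; bit-identical under a fixed seed.

    Randomness flows from one root ``SeedSequence(config.seed)``: two child
    streams per subject (signals and PANSS items), spawned in a fixed
    group-major order.
    """
    root = np.random.SeedSequence(config.seed)
    n_groups = len(config.group_coupling)
    children = root.spawn(2 * n_groups * config.n_subjects_per_group)
    subjects: list[SyntheticSubject] = []
    idx = 0
    for g in range(n_groups):
        name = config.group_names[g]
        effects = config.panss_effects[g] if config.panss_effects is not None else None
        for _ in range(config.n_subjects_per_group):
            sig_rng = np.random.default_rng(children[idx])
            panss_rng = np.random.default_rng(children[idx + 1])
            idx += 2
            epochs = _subject_epochs(sig_rng, config, config.group_coupling[g])
            panss = generate_panss_items(name, effects, panss_rng)
            subjects.append(SyntheticSubject(epochs=epochs, group=name, panss=panss))
    return subjects
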