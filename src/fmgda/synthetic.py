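"""Synthetic data generators.

Two families of fixtures:

* labeled Grassmann "class clouds" — K prototype subspaces, each class
  populated by perturbing its prototype with scaled Gaussian noise and
  re-orthonormalizing; used for recovery and invariance experiments;
* Bonn-like single-channel EEG segments — per class a sum of band-limited
  oscillations with random phases, white Gaussian noise, and (for the
  seizure-analogue class) a Poisson train of high-amplitude biphasic
  spikes, at the Bonn segment length (4097 samples) and sampling rate
  (173.61 Hz).

Both generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .eeg import BONN_GROUP_TO_FOLDER, BONN_SAMPLING_RATE, EEGError, EEGSegment
from .grassmann import (
    GrassmannPoint,
    LabeledGrassmannSet,
    orthonormalize,
    pairwise_projection_distances,
)


class FeasibilityError(ValueError):
    """Requested prototype separation is unattainable for (K, p, D)."""


@dataclass(frozen=True)
class GrassmannSimSpec:
    """Parameters of the Grassmann class-cloud generator.

    ``noise`` is the scale sigma of the Gaussian basis perturbation
    (members are ``orthonormalize(prototype + sigma * G)`` for standard
    normal G); ``prototype_separation`` is the minimum pairwise delta_P
    required between class prototypes (maximum attainable value is p).
    """

    n_classes: int = 3
    n_per_class: int = 30
    ambient_dim: int = 40
    subspace_dim: int = 5
    noise: float = 0.05
    prototype_separation: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.subspace_dim <= self.ambient_dim:
            raise ValueError("need 1 <= p <= D")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.n_classes < 1 or self.n_per_class < 1:
            raise ValueError("class counts must be >= 1")


def _draw_prototypes(spec: GrassmannSimSpec, rng: np.random.Generator) -> np.ndarray:
    K, D, p = spec.n_classes, spec.ambient_dim, spec.subspace_dim
    sep = spec.prototype_separation
    if sep > p + 1e-12:
        raise FeasibilityError(f"separation {sep} exceeds the maximum delta_P = p = {p}")
    if sep >= p - 1e-9:
        # maximal separation: mutually orthogonal prototypes, only possible
        # when K*p directions fit in R^D; rejection sampling cannot hit
        # delta_P = p exactly
        if K * p > D:
            raise FeasibilityError(
                f"{K} mutually orthogonal {p}-dim subspaces do not fit in R^{D}"
            )
        Q, _ = orthonormalize(rng.standard_normal((D, K * p)))
        return np.stack([Q[:, k * p : (k + 1) * p] for k in range(K)])
    for _ in range(200):
        protos = np.stack(
            [orthonormalize(rng.standard_normal((D, p)))[0] for _ in range(K)]
        )
        if K == 1:
            return protos
        dists = pairwise_projection_distances(protos, protos)
        off = dists[~np.eye(K, dtype=bool)]
        if off.min() >= sep:
            return protos
    raise FeasibilityError(
        f"could not draw {K} prototypes in G({p},{D}) with pairwise "
        f"delta_P >= {sep} after 200 attempts"
    )


def gen_grassmann_classes(spec: GrassmannSimSpec) -> LabeledGrassmannSet:
    """Generate K noisy Grassmann classes around separated prototypes."""
    rng = np.random.default_rng(spec.seed)
    protos = _draw_prototypes(spec, rng)
    D, p = spec.ambient_dim, spec.subspace_dim
    bases = np.empty((spec.n_classes * spec.n_per_class, D, p))
    labels = np.empty(spec.n_classes * spec.n_per_class, dtype=int)
    i = 0
    for k in range(spec.n_classes):
        for _ in range(spec.n_per_class):
            M = protos[k] + spec.noise * rng.standard_normal((D, p))
            bases[i], _ = orthonormalize(M)
            labels[i] = k
            i += 1
    return LabeledGrassmannSet(bases, labels)


def class_prototypes(spec: GrassmannSimSpec) -> LabeledGrassmannSet:
    """The prototypes a given spec would generate around (one per class)."""
    rng = np.random.default_rng(spec.seed)
    protos = _draw_prototypes(spec, rng)
    return LabeledGrassmannSet(protos, np.arange(spec.n_classes))


@dataclass(frozen=True)
class BandSpec:
    """One band-limited oscillation: [low, high] Hz at a given power."""

    low: float
    high: float
    power: float = 1.0


@dataclass(frozen=True)
class EEGClassSpec:
    """Spectral signature of one synthetic EEG class."""

    name: str
    bands: tuple[BandSpec, ...]
    noise_sd: float = 0.2
    spike_rate: float = 0.0  # Poisson spikes per second
    spike_amplitude: float = 0.0


def default_eeg_classes(noise_sd: float = 0.2) -> tuple[EEGClassSpec, ...]:
    """Five Bonn-analogue classes with disjoint dominant bands.

    A/B mimic awake surface recordings (alpha- and beta-range rhythms),
    C/D the interictal groups (slow and fast rhythms), and E the ictal
    group: a high-frequency rhythm plus high-amplitude biphasic spiking.
    """
    return (
        EEGClassSpec("A", (BandSpec(8.0, 13.0),), noise_sd=noise_sd),
        EEGClassSpec("B", (BandSpec(14.0, 20.0),), noise_sd=noise_sd),
        EEGClassSpec("C", (BandSpec(2.0, 6.0),), noise_sd=noise_sd),
        EEGClassSpec("D", (BandSpec(25.0, 35.0),), noise_sd=noise_sd),
        EEGClassSpec(
            "E",
            (BandSpec(40.0, 55.0, power=1.5),),
            noise_sd=1.5 * noise_sd,
            spike_rate=6.0,
            spike_amplitude=6.0,
        ),
    )


@dataclass(frozen=True)
class EEGSimSpec:
    """Parameters of the synthetic EEG generator (Bonn-shaped defaults)."""

    classes: tuple[EEGClassSpec, ...] = field(default_factory=default_eeg_classes)
    n_per_class: int = 100
    n_samples: int = 4097
    sampling_rate: float = BONN_SAMPLING_RATE
    amplitude_scale: float = 50.0  # arbitrary ADC-like units
    seed: int = 0

    def __post_init__(self) -> None:
        nyquist = self.sampling_rate / 2.0
        for cls in self.classes:
            for band in cls.bands:
                if not 0.0 <= band.low < band.high:
                    raise EEGError(f"class {cls.name}: bad band [{band.low}, {band.high}]")
                if band.high > nyquist:
                    raise EEGError(
                        f"class {cls.name}: band edge {band.high} Hz exceeds "
                        f"the Nyquist frequency {nyquist:.2f} Hz"
                    )
        if self.n_per_class < 1:
            raise EEGError("n_per_class must be >= 1")


def _band_component(
    rng: np.random.Generator, n: int, fs: float, band: BandSpec
) -> np.ndarray:
    """Unit-RMS band-limited noise scaled to sqrt(power).

    Built in the frequency domain: unit magnitude with random phase on the
    band's bins, zero elsewhere; the inverse real FFT is exactly
    band-limited by construction.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band.low) & (freqs <= band.high)
    if not mask.any():
        raise EEGError(
            f"band [{band.low}, {band.high}] Hz contains no FFT bin at "
            f"length {n}, rate {fs}"
        )
    spectrum = np.zeros(freqs.size, dtype=complex)
    spectrum[mask] = np.exp(2j * np.pi * rng.random(int(mask.sum())))
    x = np.fft.irfft(spectrum, n)
    rms = np.sqrt(np.mean(x * x))
    return np.sqrt(band.power) * x / rms


def _spike_train(
    rng: np.random.Generator, n: int, fs: float, rate: float, amplitude: float
) -> np.ndarray:
    """Poisson-timed biphasic pulses (a seizure-analogue transient train)."""
    out = np.zeros(n)
    n_spikes = rng.poisson(rate * n / fs)
    if n_spikes == 0:
        return out
    # biphasic kernel: one damped sine cycle, ~90 ms
    width = max(int(round(0.09 * fs)), 4)
    t = np.arange(width) / width
    kernel = np.sin(2 * np.pi * t) * np.exp(-3.0 * t)
    kernel /= np.abs(kernel).max()
    starts = rng.integers(0, max(n - width, 1), size=n_spikes)
    for s in starts:
        seg = out[s : s + width]
        seg += amplitude * kernel[: seg.size]
    return out


def gen_synthetic_eeg(spec: EEGSimSpec) -> list[EEGSegment]:
    """Generate Bonn-shaped labeled EEG segments, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    segments: list[EEGSegment] = []
    for cls in spec.classes:
        for i in range(spec.n_per_class):
            x = np.zeros(spec.n_samples)
            for band in cls.bands:
                x += _band_component(rng, spec.n_samples, spec.sampling_rate, band)
            if cls.noise_sd > 0:
                x += cls.noise_sd * rng.standard_normal(spec.n_samples)
            if cls.spike_rate > 0 and cls.spike_amplitude > 0:
                x += _spike_train(
                    rng,
                    spec.n_samples,
                    spec.sampling_rate,
                    cls.spike_rate,
                    cls.spike_amplitude,
                )
            segments.append(
                EEGSegment(
                    samples=spec.amplitude_scale * x,
                    sampling_rate=spec.sampling_rate,
                    label=cls.name,
                    source_id=f"SYN-{cls.name}-{i:03d}",
                )
            )
    return segments


def write_bonn_layout(segments: list[EEGSegment], root: str | Path) -> None:
    """Write segments as a Bonn-layout ASCII tree (folders Z/O/N/F/S).

    Samples are rounded to integers, one per line, matching the archive's
    file format so the real-data reader is exercised end to end.
    """
    root = Path(root)
    counters: dict[str, int] = {}
    for seg in segments:
        folder = BONN_GROUP_TO_FOLDER.get(seg.label)
        if folder is None:
            raise EEGError(
                f"segment {seg.source_id!r} has label {seg.label!r}; Bonn "
                f"layout needs groups A-E"
            )
        counters[folder] = counters.get(folder, 0) + 1
        d = root / folder
        d.mkdir(parents=True, exist_ok=True)
        path = d / f"{folder}{counters[folder]:03d}.txt"
        np.savetxt(path, np.round(seg.samples).astype(int), fmt="%d")
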