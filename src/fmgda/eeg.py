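"""EEG front-end: Bonn-style readers, STFT log-power spectrograms, and
SVD subspace embedding.

One single-channel recording is cut into sub-epochs; each sub-epoch
yields an m x n log-power spectrogram (time frames x frequency bins);
the M spectrograms of a recording are vectorized, stacked as columns of
Y, and the top-p left singular vectors of Y give one Grassmann point in
G(p, m*n) — the same image-set construction used for video clips.

The Bonn archive layout is five folders Z/O/N/F/S (groups A-E: healthy
eyes open / eyes closed, two interictal conditions, ictal), each holding
100 ASCII files of ~4097 samples (one integer per line) recorded at
173.61 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.signal

from .grassmann import GrassmannPoint, LabeledGrassmannSet, RankError, orthonormalize

#: Bonn archive folder -> group letter.
BONN_FOLDER_TO_GROUP = {"Z": "A", "O": "B", "N": "C", "F": "D", "S": "E"}
BONN_GROUP_TO_FOLDER = {v: k for k, v in BONN_FOLDER_TO_GROUP.items()}
BONN_SAMPLING_RATE = 173.61

#: floor added to the power before the logarithm, to keep log finite
LOG_POWER_EPS = 1e-12


class EEGError(ValueError):
    """Base class for EEG front-end errors."""


@dataclass(frozen=True)
class EEGSegment:
    """One single-channel recording: samples, rate, group label, source id."""

    samples: np.ndarray
    sampling_rate: float = BONN_SAMPLING_RATE
    label: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sampling_rate <= 0:
            raise EEGError("sampling_rate must be positive")
        if not np.all(np.isfinite(samples)):
            raise EEGError(f"segment {self.source_id!r} contains non-finite samples")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class Spectrogram:
    """Log-power time-frequency matrix: values[frame, bin]."""

    values: np.ndarray  # (m frames, n bins)
    frame_times: np.ndarray  # seconds, length m
    freqs: np.ndarray  # Hz, length n

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise EEGError("spectrogram contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SpectrumSet:
    """The M same-shape spectrograms of one recording, plus its label."""

    spectrograms: tuple[Spectrogram, ...]
    label: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.spectrograms) == 0:
            raise EEGError("a spectrum set needs at least one spectrogram")
        shapes = {s.shape for s in self.spectrograms}
        if len(shapes) != 1:
            raise EEGError(f"spectrograms have mixed shapes: {sorted(shapes)}")

    @property
    def n_spectra(self) -> int:
        return len(self.spectrograms)


def read_bonn_directory(root: str | Path) -> list[EEGSegment]:
    """Read a Bonn-layout directory tree into EEG segments.

    ``root`` must contain the five group folders Z/O/N/F/S (case
    insensitive), each holding ASCII files with one sample per line.
    Group letters are mapped Z->A, O->B, N->C, F->D, S->E and the Bonn
    sampling rate of 173.61 Hz is attached.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"no such directory: {root}")
    folders = {d.name.upper(): d for d in root.iterdir() if d.is_dir()}
    missing = [f for f in BONN_FOLDER_TO_GROUP if f not in folders]
    if missing:
        raise FileNotFoundError(
            f"missing Bonn group folder(s) {missing} under {root}"
        )
    segments: list[EEGSegment] = []
    for folder_name in sorted(BONN_FOLDER_TO_GROUP):
        group = BONN_FOLDER_TO_GROUP[folder_name]
        files = sorted(p for p in folders[folder_name].iterdir() if p.is_file())
        if not files:
            raise FileNotFoundError(f"folder {folders[folder_name]} is empty")
        for path in files:
            segments.append(
                EEGSegment(
                    samples=_read_sample_file(path),
                    sampling_rate=BONN_SAMPLING_RATE,
                    label=group,
                    source_id=path.stem,
                )
            )
    return segments


def _read_sample_file(path: Path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError as exc:
                raise EEGError(f"{path}:{lineno}: cannot parse {text!r}") from exc
    if not values:
        raise EEGError(f"{path}: no samples found")
    return np.asarray(values)


def read_csv_segment(
    path: str | Path,
    label: str = "",
    sampling_rate: float = BONN_SAMPLING_RATE,
    column: str = "sample",
) -> EEGSegment:
    """Read one segment from a CSV file with a ``sample`` column."""
    import pandas as pd

    df = pd.read_csv(path)
    if column not in df.columns:
        raise EEGError(f"{path}: no column {column!r} (found {list(df.columns)})")
    return EEGSegment(
        samples=df[column].to_numpy(float),
        sampling_rate=sampling_rate,
        label=label,
        source_id=Path(path).stem,
    )


def split_subepochs(
    samples: np.ndarray | EEGSegment, subepoch_len: int, hop: int
) -> np.ndarray:
    """Cut a sample series into windows [i*hop, i*hop + subepoch_len).

    Returns a (n_windows, subepoch_len) array; the trailing remainder that
    does not fill a full window is dropped.
    """
    x = samples.samples if isinstance(samples, EEGSegment) else np.asarray(samples, float)
    if hop < 1:
        raise EEGError("hop must be >= 1")
    if subepoch_len > x.size:
        raise EEGError(
            f"subepoch_len {subepoch_len} exceeds series length {x.size}"
        )
    n_windows = (x.size - subepoch_len) // hop + 1
    idx = np.arange(subepoch_len)[None, :] + hop * np.arange(n_windows)[:, None]
    return x[idx]


def log_spectrogram(
    window: np.ndarray,
    sampling_rate: float,
    stft_window: int = 128,
    stft_overlap: int = 64,
    fft_size: int = 128,
) -> Spectrogram:
    """Hann-tapered STFT magnitude-squared power, log-compressed.

    The output matrix has one row per time frame and one column per
    frequency bin (n = fft_size // 2 + 1 for real input); values are
    ``log(power + eps)`` with ``eps = 1e-12`` so all-zero input stays
    finite (a warning is emitted in that case).  Frames are taken without
    boundary padding, so an L-sample window yields
    ``(L - stft_window) // (stft_window - stft_overlap) + 1`` frames.
    """
    x = np.asarray(window, dtype=float).ravel()
    if not stft_overlap < stft_window <= x.size:
        raise EEGError(
            f"need stft_overlap < stft_window <= window length, got "
            f"overlap={stft_overlap}, window={stft_window}, length={x.size}"
        )
    if np.all(x == 0.0):
        warnings.warn(
            "all-zero input window; log-spectrogram is the eps floor",
            RuntimeWarning,
            stacklevel=2,
        )
    freqs, times, Z = scipy.signal.stft(
        x,
        fs=sampling_rate,
        window="hann",
        nperseg=stft_window,
        noverlap=stft_overlap,
        nfft=fft_size,
        boundary=None,
        padded=False,
    )
    power = np.abs(Z) ** 2  # (n bins, m frames)
    return Spectrogram(
        values=np.log(power.T + LOG_POWER_EPS),
        frame_times=np.asarray(times),
        freqs=np.asarray(freqs),
    )


def block_average(values: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Downsample a matrix to ``target_shape`` by averaging rectangular blocks.

    Trailing rows/columns that do not fill a whole block are discarded, so
    the source shape need not divide evenly.
    """
    m, n = values.shape
    mt, nt = target_shape
    if not (1 <= mt <= m and 1 <= nt <= n):
        raise EEGError(f"cannot block-average {values.shape} to {target_shape}")
    bm, bn = m // mt, n // nt
    trimmed = values[: mt * bm, : nt * bn]
    return trimmed.reshape(mt, bm, nt, bn).mean(axis=(1, 3))


def embed_spectrum_set(
    spectrum_set: SpectrumSet,
    p: int,
    resize: tuple[int, int] | None = None,
) -> GrassmannPoint:
    """Embed one spectrum set as a Grassmann point via SVD.

    Each spectrogram is vectorized in column-major (Fortran) order; the M
    vectors are stacked as columns of Y and Y = U S V^T is factorized; the
    first p columns of U form the returned basis in G(p, m*n).  Raises
    :class:`RankError` when p exceeds the numerical rank of Y.
    """
    mats = [s.values for s in spectrum_set.spectrograms]
    if resize is not None:
        mats = [block_average(v, resize) for v in mats]
    Y = np.column_stack([np.asarray(v).ravel(order="F") for v in mats])
    U, s, _ = scipy.linalg.svd(Y, full_matrices=False)
    rank = int(np.sum(s > max(Y.shape) * np.finfo(float).eps * (s[0] if s.size else 0)))
    if p > rank:
        raise RankError(
            f"requested p={p} exceeds numerical rank {rank} of the "
            f"{Y.shape[0]}x{Y.shape[1]} spectrum matrix"
        )
    # deterministic sign convention: largest-magnitude entry of each
    # singular vector made positive
    B = U[:, :p].copy()
    for j in range(p):
        i = np.argmax(np.abs(B[:, j]))
        if B[i, j] < 0:
            B[:, j] = -B[:, j]
    return GrassmannPoint(B)


@dataclass(frozen=True)
class FeaturizeConfig:
    """Knobs of the segment -> Grassmann-point pipeline.

    Defaults give M = 8 sub-epochs per ~4097-sample Bonn segment and
    7 x 65 spectrograms, i.e. points in G(p, 455).
    """

    subepoch_len: int = 512
    hop: int = 512
    stft_window: int = 128
    stft_overlap: int = 64
    fft_size: int = 128
    subspace_dim: int = 5
    resize: tuple[int, int] | None = None

    def fingerprint(self) -> dict:
        return {
            "subepoch_len": self.subepoch_len,
            "hop": self.hop,
            "stft_window": self.stft_window,
            "stft_overlap": self.stft_overlap,
            "fft_size": self.fft_size,
            "subspace_dim": self.subspace_dim,
            "resize": list(self.resize) if self.resize else None,
        }


def spectrum_set_from_segment(
    segment: EEGSegment, config: FeaturizeConfig
) -> SpectrumSet:
    """Split a segment into sub-epochs and compute one spectrogram each."""
    windows = split_subepochs(segment, config.subepoch_len, config.hop)
    specs = tuple(
        log_spectrogram(
            w,
            segment.sampling_rate,
            config.stft_window,
            config.stft_overlap,
            config.fft_size,
        )
        for w in windows
    )
    return SpectrumSet(specs, label=segment.label, source_id=segment.source_id)


def featurize_dataset(
    segments: list[EEGSegment], config: FeaturizeConfig | None = None
) -> LabeledGrassmannSet:
    """Run split -> log-spectrogram -> SVD embedding over a list of segments.

    Produces one Grassmann point per segment.  Group labels (sorted
    unique order) become integer class ids 0..K-1, recorded in
    ``label_names``.  Any per-segment failure aborts naming the source id.
    """
    if config is None:
        config = FeaturizeConfig()
    if not segments:
        raise EEGError("no segments to featurize")
    rates = {s.sampling_rate for s in segments}
    if len(rates) != 1:
        raise EEGError(f"segments have mixed sampling rates: {sorted(rates)}")
    names = sorted({s.label for s in segments})
    name_to_id = {name: i for i, name in enumerate(names)}
    points: list[GrassmannPoint] = []
    labels: list[int] = []
    for seg in segments:
        try:
            sset = spectrum_set_from_segment(seg, config)
            points.append(
                embed_spectrum_set(sset, config.subspace_dim, config.resize)
            )
        except (EEGError, RankError) as exc:
            raise EEGError(f"featurizing segment {seg.source_id!r} failed: {exc}") from exc
        labels.append(name_to_id[seg.label])
    return LabeledGrassmannSet.from_points(points, labels, label_names=names)
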