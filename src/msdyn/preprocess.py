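"""EEG input, filtering, re-referencing, channel repair and global field power.

The preprocessing chain mirrors a standard resting-state microstate workflow:
band-pass filter (default 1-40 Hz), downsample (default 125 Hz), spherical-spline
repair of bad channels, average reference, then the global field power (GFP)
series whose local maxima are the samples submitted to topographic clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import scipy.signal
import yaml
from scipy.special import eval_legendre

from .errors import CapabilityError, FormatError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "GfpSeries",
    "read_recording",
    "bandpass_filter",
    "resample",
    "average_reference",
    "interpolate_channels",
    "compute_gfp",
    "detect_gfp_peaks",
]


@dataclass(frozen=True)
class EEGRecording:
    """A multichannel EEG segment.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Scalp potentials in microvolt.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        One label per row of ``data``.
    channel_positions : ndarray, shape (n_channels, 3), optional
        Unit-sphere electrode coordinates (x: right, y: anterior, z: up).
    reference : {"original", "average"}
        Whether the per-sample channel mean has been removed.
    bad_channels : tuple of str
        Channels flagged for interpolation; must be a subset of channel_names.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple
    channel_positions: np.ndarray | None = None
    reference: str = "original"
    bad_channels: tuple = field(default_factory=tuple)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(self, "bad_channels", tuple(self.bad_channels))
        if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
            raise ParameterError(
                f"data must be (n_channels>=2, n_samples>=2); got {data.shape}"
            )
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be positive; got {self.fs}")
        if len(self.channel_names) != data.shape[0]:
            raise ParameterError("channel_names length must match data rows")
        if self.reference not in ("original", "average"):
            raise ParameterError(f"unknown reference {self.reference!r}")
        if not set(self.bad_channels) <= set(self.channel_names):
            raise ParameterError("bad_channels must be a subset of channel_names")
        if self.channel_positions is not None:
            pos = np.asarray(self.channel_positions, dtype=float)
            if pos.shape != (data.shape[0], 3):
                raise ParameterError("channel_positions must be (n_channels, 3)")
            object.__setattr__(self, "channel_positions", pos)
        if self.reference == "average":
            rms = np.sqrt(np.mean(data**2)) or 1.0
            if np.max(np.abs(data.mean(axis=0))) > 1e-9 * rms:
                raise ParameterError(
                    "reference='average' but per-sample channel means are nonzero"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data, **kw) -> "EEGRecording":
        return replace(self, data=data, **kw)


@dataclass(frozen=True)
class GfpSeries:
    """Global field power trace and the indices of its local maxima."""

    values: np.ndarray
    peak_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        peaks = np.asarray(self.peak_indices, dtype=int)
        if np.any(values < 0):
            raise ParameterError("GFP values must be nonnegative")
        if peaks.size and (np.any(np.diff(peaks) <= 0)):
            raise ParameterError("peak indices must be strictly increasing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "peak_indices", peaks)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _find_sidecar(path: Path) -> Path | None:
    for cand in (path.with_suffix(".yaml"), path.with_suffix(".yml"),
                 Path(str(path) + ".yaml"), Path(str(path) + ".yml")):
        if cand.exists():
            return cand
    return None


def read_recording(path, format: str | None = None) -> EEGRecording:
    """Read an EEG recording from EDF or a channels x samples matrix + YAML sidecar.

    ``format`` is ``"edf"`` or ``"matrix"``; when None it is inferred from the
    file extension (``.edf`` -> EDF; ``.h5``/``.hdf5`` -> HDF5 matrix; anything
    else -> delimited text matrix).  Matrix formats require a YAML sidecar
    (``<stem>.yaml``) with at least a ``fs`` key; ``channel_names`` and
    ``positions`` are optional.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if format is None:
        format = "edf" if suffix == ".edf" else "matrix"

    if format == "edf":
        import mne

        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:  # pragma: no cover - mne error classes vary
            raise FormatError(f"cannot parse EDF file {path}: {exc}") from exc
        fs = float(raw.info["sfreq"])
        data = raw.get_data(units="uV")
        return EEGRecording(data=data, fs=fs, channel_names=tuple(raw.ch_names))

    if format != "matrix":
        raise ParameterError(f"unknown format {format!r}")

    if suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise FormatError(f"{path}: HDF5 file lacks a 'data' dataset")
            data = np.asarray(f["data"], dtype=float)
    else:
        try:
            data = np.loadtxt(path, delimiter=None, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric payload: {exc}") from exc

    sidecar = _find_sidecar(path)
    if sidecar is None:
        raise FormatError(f"{path}: matrix format requires a YAML sidecar with 'fs'")
    with open(sidecar) as f:
        meta = yaml.safe_load(f) or {}
    if "fs" not in meta:
        raise FormatError(f"{sidecar}: sidecar is missing required key 'fs'")
    fs = float(meta["fs"])
    names = meta.get("channel_names")
    if names is None:
        names = [f"ch{i:03d}" for i in range(data.shape[0])]
    positions = meta.get("positions")
    if positions is not None:
        positions = np.asarray(positions, dtype=float)
    return EEGRecording(
        data=data, fs=fs, channel_names=tuple(names), channel_positions=positions
    )


def write_matrix_recording(rec: EEGRecording, path) -> None:
    """Write a recording as delimited text (or HDF5 for .h5/.hdf5) plus YAML sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=rec.data)
    else:
        np.savetxt(path, rec.data, fmt="%.6f")
    meta = {"fs": float(rec.fs), "channel_names": list(rec.channel_names)}
    if rec.channel_positions is not None:
        meta["positions"] = [[float(v) for v in row] for row in rec.channel_positions]
    with open(path.with_suffix(".yaml"), "w") as f:
        yaml.safe_dump(meta, f)


# ---------------------------------------------------------------------------
# Filtering / resampling / referencing
# ---------------------------------------------------------------------------

def bandpass_filter(rec: EEGRecording, low: float, high: float, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass (forward-backward, effective order 2*order)."""
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ParameterError(
            f"band edges must satisfy 0 < low < high < fs/2; got ({low}, {high}) at fs={rec.fs}"
        )
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.with_data(filtered)


def resample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Polyphase anti-aliased downsampling to ``target_fs`` (upsampling is refused)."""
    if target_fs > rec.fs:
        raise ParameterError(f"cannot upsample: target {target_fs} > fs {rec.fs}")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = scipy.signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    n_expected = int(round(rec.n_samples * target_fs / rec.fs))
    out = out[:, :n_expected]
    if out.shape[1] < n_expected:  # resample_poly may be short by one sample
        out = np.pad(out, ((0, 0), (0, n_expected - out.shape[1])), mode="edge")
    return rec.with_data(out, fs=float(target_fs))


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the per-sample mean across channels (common average reference)."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.with_data(data, reference="average")


# ---------------------------------------------------------------------------
# Spherical-spline channel interpolation (Perrin-style)
# ---------------------------------------------------------------------------

def _g_matrix(cosang: np.ndarray, m: int = 4, n_terms: int = 7) -> np.ndarray:
    """Spherical-spline kernel g(cos angle) with Legendre expansion up to degree n_terms."""
    g = np.zeros_like(cosang, dtype=float)
    for n in range(1, n_terms + 1):
        g += (2 * n + 1) / (n**m * (n + 1) ** m) * eval_legendre(n, cosang)
    return g / (4 * np.pi)


def interpolate_channels(
    rec: EEGRecording,
    bad: list | tuple | None = None,
    m: int = 4,
    n_terms: int = 7,
    reg: float = 1e-5,
) -> EEGRecording:
    """Replace bad channels by spherical-spline estimates from the good channels.

    Good channels are returned bit-identical; ``bad`` defaults to
    ``rec.bad_channels``.  Requires unit-sphere channel positions.
    """
    bad = tuple(rec.bad_channels if bad is None else bad)
    if not bad:
        return rec
    if rec.channel_positions is None:
        raise CapabilityError("channel positions are required for interpolation")
    if not set(bad) <= set(rec.channel_names):
        raise ParameterError("bad channels not found in recording")
    bad_idx = np.array([rec.channel_names.index(b) for b in bad])
    good_idx = np.array([i for i in range(rec.n_channels) if i not in set(bad_idx)])
    if good_idx.size < 2:
        raise ParameterError("at least two good channels are required")

    pos = rec.channel_positions / np.linalg.norm(rec.channel_positions, axis=1, keepdims=True)
    pg, pb = pos[good_idx], pos[bad_idx]
    G = _g_matrix(np.clip(pg @ pg.T, -1.0, 1.0), m, n_terms)
    Gb = _g_matrix(np.clip(pb @ pg.T, -1.0, 1.0), m, n_terms)

    ng = good_idx.size
    # Spline system with zero-sum constraint: [[G + reg*I, 1], [1^T, 0]] [c; c0] = [v; 0]
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = G + reg * np.eye(ng)
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    rhs = np.zeros((ng + 1, rec.n_samples))
    rhs[:ng] = rec.data[good_idx]
    sol = np.linalg.solve(A, rhs)
    c, c0 = sol[:ng], sol[ng]

    data = rec.data.copy()
    data[bad_idx] = Gb @ c + c0
    logger.info("interpolated %d channel(s): %s", len(bad), ", ".join(bad))
    return rec.with_data(data, bad_channels=())


# ---------------------------------------------------------------------------
# Global field power
# ---------------------------------------------------------------------------

def compute_gfp(rec: EEGRecording) -> GfpSeries:
    """Global field power: population standard deviation across channels per sample.

    For average-referenced data this equals the RMS across channels.
    """
    return GfpSeries(values=np.std(rec.data, axis=0))


def detect_gfp_peaks(gfp: GfpSeries, max_peaks: int | None = None) -> GfpSeries:
    """Mark strict local maxima of the GFP trace (endpoints excluded).

    A plateau counts as one peak at its first sample, and only if the distinct
    values on both sides are lower.  ``max_peaks`` optionally keeps only the
    largest peaks (order preserved).
    """
    v = gfp.values
    if v.size < 3:
        raise ParameterError("need at least 3 samples to detect peaks")
    # run-length encode to give plateaus a single representative
    change = np.flatnonzero(np.diff(v) != 0)
    starts = np.concatenate(([0], change + 1))
    vals = v[starts]
    peaks = []
    for i in range(1, len(vals) - 1):
        if vals[i] > vals[i - 1] and vals[i] > vals[i + 1]:
            peaks.append(starts[i])
    peaks = np.asarray(peaks, dtype=int)
    if max_peaks is not None and peaks.size > max_peaks:
        keep = np.sort(np.argsort(v[peaks])[::-1][:max_peaks])
        peaks = peaks[keep]
    return GfpSeries(values=v, peak_indices=peaks)
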