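"""Back-fitting of template maps to continuous EEG and temporal statistics.

Every sample of the (average-referenced) recording is assigned to the template
with the highest absolute spatial correlation (winner-takes-all, polarity
ignored).  The label sequence can then be regularised with the classic
segmentation-smoothing scheme -- a data-fit term GFP^2*(1 - r^2) traded
against a neighbourhood bonus lambda * N_{b,k} (window half-size b, strength
lambda, the "Besag factor") -- so that noise at low GFP does not artificially
interrupt stable segments.  From the final labels, per-class occurrence (1/s),
coverage (%), mean duration (ms), and GFP^2-weighted global explained
variance are extracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .clustering import MicrostateModel
from .errors import DimensionError, ParameterError, UndefinedStatisticError
from .preprocess import EEGRecording, GfpSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothingParams",
    "Segmentation",
    "TemporalStats",
    "backfit_labels",
    "smooth_labels",
    "extract_segments",
    "temporal_parameters",
    "global_explained_variance",
]


@dataclass(frozen=True)
class SmoothingParams:
    """Temporal smoothing settings: window half-size b (samples), strength lambda."""

    window_half_size: int = 3
    besag_factor: float = 10.0
    max_iterations: int = 100

    def __post_init__(self):
        if self.window_half_size < 0:
            raise ParameterError("window_half_size must be >= 0")
        if self.besag_factor < 0:
            raise ParameterError("besag_factor must be >= 0")


@dataclass(frozen=True)
class Segmentation:
    """Winner-takes-all microstate labels for one recording.

    ``labels`` holds 0-based class indices (one per sample), ``corr`` the
    winning absolute spatial correlation.  ``corr_all`` (samples x K) keeps
    the full |correlation| matrix needed by the smoothing step; it is carried
    by backfit_labels and may be dropped afterwards.
    """

    labels: np.ndarray
    corr: np.ndarray
    fs: float
    n_classes: int
    n_channels: int = 0
    smoothing: SmoothingParams | None = None
    corr_all: np.ndarray | None = None
    gfp: np.ndarray | None = None

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        corr = np.asarray(self.corr, dtype=float)
        if labels.shape != corr.shape:
            raise ParameterError("labels and corr must have equal length")
        if labels.size == 0:
            raise ParameterError("empty segmentation")
        if not self.fs > 0:
            raise ParameterError("fs must be positive")
        if labels.min() < 0 or labels.max() >= self.n_classes:
            raise ParameterError("labels out of range [0, n_classes)")
        if np.any((corr < -1e-9) | (corr > 1 + 1e-9)):
            raise ParameterError("winning correlations must lie in [0, 1]")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "corr", np.clip(corr, 0.0, 1.0))

    @property
    def n_samples(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class TemporalStats:
    """Per-class temporal parameters of a segmentation.

    occurrence: segments per second; coverage: percent of analysed time;
    duration: mean dwell per segment in ms; gev_class/gev_total: GFP^2-weighted
    explained variance (NaN until computed from data).
    """

    occurrence: np.ndarray
    coverage: np.ndarray
    duration: np.ndarray
    gev_class: np.ndarray | None = None
    gev_total: float = np.nan
    boundary_mode: str = "mixed"

    def __post_init__(self):
        for name in ("occurrence", "coverage", "duration"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ParameterError(f"{name} must be nonnegative")
            object.__setattr__(self, name, arr)
        if self.gev_class is not None:
            g = np.asarray(self.gev_class, dtype=float)
            if abs(np.sum(g) - self.gev_total) > 1e-9:
                raise ParameterError("gev_total must equal the sum of gev_class")
            if not (0 - 1e-9 <= self.gev_total <= 1 + 1e-9):
                raise ParameterError("gev_total must lie in [0, 1]")
            object.__setattr__(self, "gev_class", g)

    @property
    def n_classes(self) -> int:
        return self.occurrence.size

    def with_gev(self, gev_class, gev_total) -> "TemporalStats":
        return replace(self, gev_class=np.asarray(gev_class, float), gev_total=float(gev_total))


# ---------------------------------------------------------------------------
# Back-fitting
# ---------------------------------------------------------------------------

def backfit_labels(rec: EEGRecording, model: MicrostateModel) -> Segmentation:
    """Assign every sample to the template with the highest |spatial correlation|.

    Polarity is ignored; ties break toward the lower class index.  Samples of
    zero spatial variance (flat maps) inherit the previous sample's label
    (class 0 if they open the recording).
    """
    if rec.reference != "average":
        raise ParameterError("recording must be average-referenced before back-fitting")
    if rec.n_channels != model.n_channels:
        raise DimensionError(
            f"channel mismatch: recording {rec.n_channels}, model {model.n_channels}"
        )
    X = rec.data.T  # (n_samples, n_channels), zero-mean rows
    norms = np.linalg.norm(X, axis=1)
    flat = norms == 0
    safe = np.where(flat, 1.0, norms)
    corr_all = np.abs((X / safe[:, None]) @ model.maps.T)  # |r|, since rows are zero-mean
    corr_all[flat] = 0.0
    labels = np.argmax(corr_all, axis=1)  # argmax takes the first (lowest) index on ties
    if np.any(flat):
        logger.warning("%d flat sample(s); carrying previous label forward", int(flat.sum()))
        idx = np.flatnonzero(flat)
        for t in idx:
            labels[t] = labels[t - 1] if t > 0 else 0
    corr = corr_all[np.arange(len(labels)), labels]
    gfp = norms / np.sqrt(rec.n_channels)  # = spatial RMS = GFP for average reference
    return Segmentation(
        labels=labels, corr=corr, fs=rec.fs, n_classes=model.k,
        n_channels=rec.n_channels, corr_all=corr_all, gfp=gfp,
    )


# ---------------------------------------------------------------------------
# Temporal smoothing
# ---------------------------------------------------------------------------

def _neighbour_counts(labels: np.ndarray, k: int, b: int) -> np.ndarray:
    """N_{b,k}(t): how many samples within +-b of t (excluding t) carry label k."""
    n = labels.size
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    kernel = np.ones(2 * b + 1)
    counts = np.empty_like(onehot)
    for j in range(k):
        counts[:, j] = np.convolve(onehot[:, j], kernel, mode="same")
    return counts - onehot


def smooth_labels(
    seg: Segmentation, gfp: GfpSeries | np.ndarray | None = None,
    params: SmoothingParams = SmoothingParams(),
) -> Segmentation:
    """Regularise a label sequence with the window/Besag-factor smoothing scheme.

    Iteratively reassigns each sample to the class minimising
    ``GFP_t^2 (1 - r_{t,k}^2) / (2 e (C-1)) - lambda N_{b,k}(t)`` where ``e``
    is the current mean residual noise variance, until the labelling is a
    fixed point or ``max_iterations`` is reached.  ``lambda = 0`` returns the
    input unchanged.
    """
    if params.besag_factor == 0:
        return replace(seg, smoothing=params)
    if seg.corr_all is None:
        raise ParameterError("smoothing needs the full correlation matrix (corr_all)")
    gfp_values = seg.gfp if gfp is None else (gfp.values if isinstance(gfp, GfpSeries) else np.asarray(gfp, float))
    if gfp_values is None or gfp_values.size != seg.n_samples:
        raise ParameterError("GFP series must match the segmentation length")
    b = params.window_half_size
    if b >= seg.n_samples:
        raise ParameterError("window half-size must be smaller than the series length")

    n, k = seg.corr_all.shape
    cm1 = max(seg.n_channels - 1, 1)
    gfp2 = gfp_values**2
    misfit = gfp2[:, None] * (1.0 - seg.corr_all**2)  # (n, k)
    labels = seg.labels.copy()
    parity = np.arange(n) % 2
    for _ in range(params.max_iterations):
        e = np.sum(misfit[np.arange(n), labels]) / (n * cm1)
        e = max(e, 1e-300)
        changed = False
        # alternating odd/even half-passes avoid the flip-flop cycles a fully
        # synchronous relabelling can fall into at large lambda
        for par in (0, 1):
            counts = _neighbour_counts(labels, k, b)
            cost = misfit / (2.0 * e * cm1) - params.besag_factor * counts
            new_labels = np.argmin(cost, axis=1)
            mask = parity == par
            if np.any(new_labels[mask] != labels[mask]):
                changed = True
                labels = np.where(mask, new_labels, labels)
        if not changed:
            break
    corr = seg.corr_all[np.arange(n), labels]
    return replace(seg, labels=labels, corr=corr, smoothing=params)


# ---------------------------------------------------------------------------
# Segments and temporal parameters
# ---------------------------------------------------------------------------

def extract_segments(seg: Segmentation):
    """Maximal constant-label runs as (class, start, length, is_boundary) tuples."""
    labels = seg.labels
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [labels.size]))
    out = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        boundary = i == 0 or i == len(starts) - 1
        out.append((int(labels[s]), int(s), int(e - s), boundary))
    return out


def temporal_parameters(seg: Segmentation, boundary_mode: str = "mixed") -> TemporalStats:
    """Occurrence (1/s), coverage (%), and mean duration (ms) per class.

    ``boundary_mode`` controls whether the first and last (truncated) runs are
    counted: ``"inclusive"`` counts them for occurrence and duration,
    ``"exclusive"`` drops them from both, and the default ``"mixed"`` keeps
    them for occurrence but drops them from duration (edge runs bias dwell
    estimates downward).  Coverage always uses all samples.  In inclusive mode
    ``occurrence * duration/1000 == coverage/100`` holds exactly per class.
    """
    if boundary_mode not in ("inclusive", "exclusive", "mixed"):
        raise ParameterError(f"unknown boundary_mode {boundary_mode!r}")
    k = seg.n_classes
    runs = extract_segments(seg)
    seconds = seg.n_samples / seg.fs
    occurrence = np.zeros(k)
    coverage = np.zeros(k)
    duration = np.zeros(k)
    occ_runs = runs if boundary_mode in ("inclusive", "mixed") else [r for r in runs if not r[3]]
    dur_runs = runs if boundary_mode == "inclusive" else [r for r in runs if not r[3]]
    for cls, _, length, _ in runs:
        coverage[cls] += length
    coverage = 100.0 * coverage / seg.n_samples
    for cls, _, _, _ in occ_runs:
        occurrence[cls] += 1
    occurrence /= seconds
    for cls in range(k):
        lengths = [r[2] for r in dur_runs if r[0] == cls]
        if lengths:
            duration[cls] = np.mean(lengths) * 1000.0 / seg.fs
        else:
            logger.debug("class %d has no countable runs; duration set to 0", cls)
    return TemporalStats(
        occurrence=occurrence, coverage=coverage, duration=duration,
        boundary_mode=boundary_mode,
    )


def global_explained_variance(
    rec: EEGRecording | None, seg: Segmentation, model: MicrostateModel | None = None
):
    """GFP^2-weighted squared-correlation explained variance per class and total.

    ``gev_class[k] = sum_{t: label=k} GFP_t^2 r_t^2 / sum_t GFP_t^2``; the
    total is the sum over classes.  ``rec``/``model`` may be omitted when the
    segmentation already carries its GFP trace (as produced by backfit_labels).
    """
    if seg.gfp is not None:
        gfp2 = seg.gfp**2
    elif rec is not None:
        gfp2 = np.std(rec.data, axis=0) ** 2
    else:
        raise ParameterError("need a recording or a segmentation with a stored GFP trace")
    if gfp2.size != seg.n_samples:
        raise DimensionError("GFP length does not match segmentation")
    denom = float(np.sum(gfp2))
    if denom == 0:
        raise UndefinedStatisticError("GEV undefined: all-zero GFP")
    contrib = gfp2 * seg.corr**2
    gev_class = np.bincount(seg.labels, weights=contrib, minlength=seg.n_classes) / denom
    return gev_class, float(np.sum(gev_class))
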