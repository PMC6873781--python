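"""Ground-truth-labelled synthetic EEG cohorts for pipeline validation.

The generator emulates the statistical structure that resting-state
microstate analysis assumes: each subject's scalp topography is a sequence of
quasi-stable template maps (a first-order Markov chain over k classes with
geometric dwell times), multiplied by an alpha-band oscillatory amplitude with
segment-wise random phase and sign (so that polarity carries no information),
plus spatially white sensor noise.  A two-group cohort plants a multiplicative
increase of one class's entry rate in the patient group, and clinical scores
are drawn with group means/SDs shaped like a euthymic-bipolar vs control
sample (MADRS/YMRS low in both groups, STAI elevated in patients).

Default study conditions: two groups of 17 subjects, 32 channels on a unit
sphere, 125 Hz, 120 s per subject, five orthogonal template maps, 80 ms mean
dwell, amplitude SNR 5, 10 Hz carrier, +35% patient entry rate into class 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .preprocess import EEGRecording
from .segmentation import Segmentation, temporal_parameters

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "Cohort",
    "fibonacci_sphere",
    "make_template_maps",
    "simulate_label_sequence",
    "simulate_recording",
    "simulate_cohort",
    "true_stats_table",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic two-group cohort."""

    n_channels: int = 32
    fs: float = 125.0
    duration: float = 120.0  # seconds per subject
    k_true: int = 5
    mean_dwell: float = 80.0  # ms
    snr: float = 5.0  # signal-to-noise amplitude ratio
    alpha_freq: float = 10.0  # Hz
    group_effect: float = 0.35  # multiplicative boost of class-0 entry rate in patients
    n_per_group: int = 17
    amplitude: float = 15.0  # carrier amplitude, µV
    seed: int = 0

    def __post_init__(self):
        if self.k_true < 2:
            raise ParameterError("k_true must be >= 2")
        if self.mean_dwell <= 1000.0 / self.fs:
            raise ParameterError("mean_dwell must exceed one sample period")
        if not self.snr > 0:
            raise ParameterError("snr must be positive")
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if self.k_true >= self.n_channels:
            raise ParameterError("k_true must be smaller than n_channels")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass(frozen=True)
class GroundTruth:
    """Planted templates, per-subject true label sequences and true temporal stats."""

    templates: np.ndarray  # (k_true, n_channels)
    labels: tuple  # per-subject int arrays
    true_params: pd.DataFrame = field(repr=False, default=None)  # long-form per subject x class


@dataclass(frozen=True)
class Cohort:
    """A synthetic two-group study: recordings, clinical scores, ground truth."""

    recordings: tuple  # EEGRecording per subject (may be empty if not materialised)
    clinical: pd.DataFrame
    ground_truth: GroundTruth
    spec: SyntheticSpec = None


def fibonacci_sphere(n: int) -> np.ndarray:
    """n roughly uniform unit-sphere points (electrode positions for synthesis)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def make_template_maps(n_channels: int, k: int, seed=None) -> np.ndarray:
    """k mutually orthogonal, zero-mean, unit-norm channel vectors (random rotation)."""
    if k >= n_channels:
        raise ParameterError("k must be smaller than n_channels")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_channels, k))
    g -= g.mean(axis=0, keepdims=True)  # restrict to the average-reference subspace
    q, r = np.linalg.qr(g)
    q *= np.sign(np.diag(r))  # make the decomposition deterministic in distribution
    return q.T  # (k, n_channels); columns of q are orthonormal and zero-mean


def _entry_weights(spec: SyntheticSpec, group: str) -> np.ndarray:
    w = np.ones(spec.k_true)
    if group == "patient":
        w[0] *= 1.0 + spec.group_effect
    elif group != "control":
        raise ParameterError(f"unknown group {group!r}")
    return w


def simulate_label_sequence(spec: SyntheticSpec, group: str = "control", seed=None) -> np.ndarray:
    """First-order Markov label sequence with geometric dwell times.

    Self-transition probability is set so the expected dwell equals
    ``mean_dwell``; on a switch the destination class j != current is drawn
    with probability proportional to entry weight w_j (class 0 boosted by
    ``1 + group_effect`` for patients).  Implemented by the thinning identity:
    an i.i.d. categorical(w) sequence with consecutive duplicates collapsed is
    exactly that jump chain, which allows full vectorisation.
    """
    rng = np.random.default_rng(seed)
    dwell_samples = spec.mean_dwell / 1000.0 * spec.fs
    if dwell_samples <= 1:
        raise ParameterError("mean dwell is shorter than one sample")
    p_switch = 1.0 / dwell_samples
    n = spec.n_samples
    w = _entry_weights(spec, group)
    probs = w / w.sum()

    n_seg_guess = max(int(n * p_switch * 1.5) + 20, 30)
    states = np.empty(0, dtype=int)
    lengths = np.empty(0, dtype=int)
    total = 0
    while total < n:
        draws = rng.choice(spec.k_true, size=2 * n_seg_guess, p=probs)
        keep = np.concatenate(([True], draws[1:] != draws[:-1]))
        if states.size:  # collapse across chunk boundary too
            first_keep = np.flatnonzero(keep)
            if first_keep.size and draws[first_keep[0]] == states[-1]:
                keep[first_keep[0]] = False
        jumps = draws[keep]
        lens = rng.geometric(p_switch, size=jumps.size)
        states = np.concatenate([states, jumps])
        lengths = np.concatenate([lengths, lens])
        total = int(lengths.sum())
    labels = np.repeat(states, lengths)[:n]
    return labels


def simulate_recording(
    spec: SyntheticSpec, templates: np.ndarray, labels: np.ndarray, seed=None
) -> EEGRecording:
    """Quasi-stable topography x oscillatory amplitude + white noise, average-referenced.

    ``x_t = templates[label_t] * a_t + noise_t`` with ``a_t`` an alpha-frequency
    sinusoid whose phase and sign are re-drawn at every segment boundary
    (polarity carries no class information), and spatially white Gaussian noise
    scaled so the entry-wise RMS signal-to-noise ratio equals ``spec.snr``.
    """
    rng = np.random.default_rng(seed)
    templates = np.asarray(templates, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if templates.shape[0] <= labels.max():
        raise ParameterError("labels refer to a template that does not exist")
    if templates.shape[1] != spec.n_channels:
        raise ParameterError("templates and spec disagree on channel count")

    t = np.arange(n) / spec.fs
    starts = np.concatenate(([0], np.flatnonzero(np.diff(labels) != 0) + 1))
    seg_id = np.cumsum(np.isin(np.arange(n), starts)) - 1
    phases = rng.uniform(0, 2 * np.pi, size=starts.size)
    signs = rng.choice([-1.0, 1.0], size=starts.size)
    a = spec.amplitude * signs[seg_id] * np.sin(
        2 * np.pi * spec.alpha_freq * t + phases[seg_id]
    )
    data = (templates[labels] * a[:, None]).T  # (n_channels, n)

    if np.isfinite(spec.snr):
        signal_rms = np.sqrt(np.mean(a**2) / spec.n_channels)  # templates are unit-norm
        sigma = signal_rms / spec.snr
        noise = rng.standard_normal(data.shape) * sigma
        data = data + noise
    data -= data.mean(axis=0, keepdims=True)
    names = tuple(f"ch{i:03d}" for i in range(spec.n_channels))
    return EEGRecording(
        data=data, fs=spec.fs, channel_names=names,
        channel_positions=fibonacci_sphere(spec.n_channels), reference="average",
    )


def _clinical_row(rng, subject, group):
    """Truncated-normal clinical scores with euthymic-cohort-like group structure."""
    pat = group == "patient"

    def tnorm(mean, sd, lo, hi):
        for _ in range(100):
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                return v
        return float(np.clip(v, lo, hi))

    return {
        "subject": subject,
        "group": group,
        "age": round(tnorm(36.0, 13.0, 18, 70)),
        "education": round(tnorm(2.35, 0.55, 1, 3), 1),
        "MADRS": round(tnorm(2.3 if pat else 1.4, 2.9 if pat else 1.6, 0, 11)),
        "YMRS": round(tnorm(0.8, 1.4, 0, 5)),
        "STAI_state": round(tnorm(36.9 if pat else 26.7, 15.2 if pat else 4.8, 20, 80)),
        "STAI_trait": round(tnorm(42.9 if pat else 27.4, 13.3 if pat else 5.2, 20, 80)),
    }


def true_stats_table(labels_per_subject, subjects, groups, fs: float, k: int) -> pd.DataFrame:
    """Long-form per-subject per-class temporal parameters from true label sequences."""
    rows = []
    for labels, subject, group in zip(labels_per_subject, subjects, groups):
        seg = Segmentation(
            labels=labels, corr=np.ones(labels.size), fs=fs, n_classes=k
        )
        ts = temporal_parameters(seg, boundary_mode="mixed")
        for cls in range(k):
            rows.append({
                "subject": subject, "group": group, "class": cls,
                "occurrence": ts.occurrence[cls],
                "coverage": ts.coverage[cls],
                "duration": ts.duration[cls],
            })
    return pd.DataFrame(rows)


def simulate_cohort(spec: SyntheticSpec, seed=None, make_recordings: bool = True) -> Cohort:
    """A full two-group cohort: recordings, clinical scores, and ground truth.

    The same seed yields a bit-identical cohort.  ``make_recordings=False``
    skips EEG synthesis (labels and clinical scores only), which is what
    replicate-based statistical validation needs.
    """
    root = np.random.default_rng(spec.seed if seed is None else seed)
    ss = root.spawn(4)
    templates = make_template_maps(spec.n_channels, spec.k_true, ss[0])

    subjects, groups, labels_all, recordings = [], [], [], []
    label_rng, rec_rng = ss[1], ss[2]
    for group in ("patient", "control"):
        for i in range(spec.n_per_group):
            sid = f"{'bd' if group == 'patient' else 'hc'}{i + 1:02d}"
            subjects.append(sid)
            groups.append(group)
            labels = simulate_label_sequence(spec, group, label_rng.spawn(1)[0])
            labels_all.append(labels)
            if make_recordings:
                recordings.append(
                    simulate_recording(spec, templates, labels, rec_rng.spawn(1)[0])
                )
    clin_rng = np.random.default_rng(ss[3])
    clinical = pd.DataFrame(
        [_clinical_row(clin_rng, s, g) for s, g in zip(subjects, groups)]
    )
    table = true_stats_table(labels_all, subjects, groups, spec.fs, spec.k_true)
    gt = GroundTruth(templates=templates, labels=tuple(labels_all), true_params=table)
    return Cohort(
        recordings=tuple(recordings), clinical=clinical, ground_truth=gt, spec=spec
    )
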