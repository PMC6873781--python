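"""Group statistics for microstate temporal parameters and clinical scores.

Covers the statistical layer of a two-group resting-state microstate study:
rank-based group comparison (Mann-Whitney U with a tie- and continuity-
corrected normal Z), Benjamini-Hochberg FDR within each parameter family,
Spearman correlations with clinical scores, Levene variance checks, Student
t-tests for demographics, and Welch-averaged alpha-band power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .errors import ParameterError, UndefinedStatisticError
from .preprocess import EEGRecording

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "mann_whitney_z",
    "bh_fdr",
    "spearman_rho",
    "levene_test",
    "students_t",
    "alpha_band_power",
    "compare_groups",
    "correlate_clinical",
    "validate_clinical",
]

CLINICAL_COLUMNS = ("subject", "group", "MADRS", "YMRS", "STAI_state", "STAI_trait")


@dataclass(frozen=True)
class CorrelationResult:
    """A Spearman rank correlation between one score and one microstate parameter."""

    pair: tuple
    rho: float
    p: float

    def __post_init__(self):
        if abs(self.rho) > 1 + 1e-12:
            raise ParameterError("|rho| must not exceed 1")


def validate_clinical(scores: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical-score table: required columns, groups, STAI in [20, 80]."""
    missing = [c for c in CLINICAL_COLUMNS if c not in scores.columns]
    if missing:
        raise ParameterError(f"clinical table is missing columns: {missing}")
    if not set(scores["group"]) <= {"patient", "control"}:
        raise ParameterError("group must be 'patient' or 'control'")
    for col in ("STAI_state", "STAI_trait"):
        v = scores[col].to_numpy(dtype=float)
        if np.any((v < 20) | (v > 80)):
            raise ParameterError(f"{col} outside the [20, 80] score range")
    return scores


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def mann_whitney_z(x, y):
    """Mann-Whitney U with a tie-corrected, continuity-corrected normal Z.

    Returns ``(U, Z, p)`` where U is the statistic of the first sample
    (midranks for ties), Z the normal approximation, and p the two-sided
    normal tail probability.  Two identical samples give Z = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    u = float(np.sum(ranks[:nx]) - nx * (nx + 1) / 2)
    mu = nx * ny / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 0.0, 1.0
    diff = u - mu
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / np.sqrt(var) if diff != 0 else 0.0
    p = 2.0 * scipy.stats.norm.sf(abs(z))
    return u, float(z), float(min(p, 1.0))


def bh_fdr(p_values, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the ascending order statistics,
    capped at 1, with ``m`` the family size (defaults to ``len(p_values)``).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size if family_size is None else int(family_size)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def spearman_rho(x, y, pair=("x", "y")) -> CorrelationResult:
    """Spearman rank correlation (Pearson on midranks) with the t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need paired samples of equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("Spearman correlation undefined for constant input")
    rho, p = scipy.stats.spearmanr(x, y)
    return CorrelationResult(pair=tuple(pair), rho=float(rho), p=float(p))


def levene_test(*groups, center: str = "mean"):
    """Levene's test (ANOVA on absolute deviations from the group mean).

    Degenerate input with no within-group deviation anywhere returns (0.0, 1.0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ParameterError("need >= 2 groups with >= 2 values each")
    devs = [np.abs(g - g.mean()) for g in groups]
    if all(np.allclose(d, d[0]) for d in devs) and len({d[0] for d in devs}) <= 1:
        return 0.0, 1.0
    w, p = scipy.stats.levene(*groups, center=center)
    if np.isnan(w):
        return 0.0, 1.0
    return float(w), float(p)


def students_t(x, y, welch: bool = False):
    """Two-sample t-test (pooled-variance by default, Welch by flag), two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("need >= 2 values per sample")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = scipy.stats.ttest_ind(x, y, equal_var=not welch)
    if not np.isfinite(t):
        raise UndefinedStatisticError("t undefined: zero pooled variance")
    return float(t), float(p)


def alpha_band_power(
    rec: EEGRecording, band=(8.0, 14.0), window_sec: float = 2.0, overlap: float = 0.5
) -> float:
    """Mean band power across channels from Hanning-windowed Welch periodograms.

    The PSD is integrated over the requested band (microvolt^2), then averaged
    across channels; a pure in-band sinusoid of amplitude a yields ~a^2/2.
    """
    low, high = band
    if rec.fs <= 2 * high:
        raise ParameterError(f"fs={rec.fs} too low for band {band}")
    if rec.reference != "average":
        raise ParameterError("recording must be average-referenced")
    nperseg = int(round(window_sec * rec.fs))
    if rec.n_samples < nperseg:
        raise ParameterError("recording shorter than one analysis window")
    freqs, psd = scipy.signal.welch(
        rec.data, fs=rec.fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap), axis=1,
    )
    mask = (freqs >= low) & (freqs <= high)
    df = freqs[1] - freqs[0]
    return float(np.mean(np.sum(psd[:, mask], axis=1) * df))


# ---------------------------------------------------------------------------
# Table-level operations
# ---------------------------------------------------------------------------

PARAMETERS = ("occurrence", "coverage", "duration")


def compare_groups(
    stats_table: pd.DataFrame,
    grouping: pd.DataFrame | None = None,
    parameters=PARAMETERS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Class-wise Mann-Whitney comparisons with BH-FDR per parameter family.

    ``stats_table`` is long-form with columns (subject, group?, class,
    occurrence, coverage, duration); ``grouping`` supplies subject -> group if
    the table has no group column.  For each parameter the K class-wise tests
    form one FDR family.  Returns a table with one row per parameter x class:
    group means +- sd, U, Z, p, p_fdr, significant.
    """
    table = stats_table.copy()
    if "group" not in table.columns:
        if grouping is None:
            raise ParameterError("need a 'group' column or a grouping table")
        table = table.merge(grouping[["subject", "group"]], on="subject", how="left")
    if table["group"].isna().any():
        raise ParameterError("some subjects have no group label")
    for g in ("patient", "control"):
        if table.loc[table["group"] == g, "subject"].nunique() < 2:
            raise ParameterError(f"need >= 2 subjects in group {g!r}")

    classes = sorted(table["class"].unique())
    subjects = table[["subject", "group"]].drop_duplicates()
    full = subjects.merge(pd.DataFrame({"class": classes}), how="cross")
    merged = full.merge(table, on=["subject", "group", "class"], how="left")
    n_missing = int(merged[list(parameters)].isna().any(axis=1).sum())
    if n_missing:
        logger.warning("%d subject x class entries missing; treated as zeros", n_missing)
        merged[list(parameters)] = merged[list(parameters)].fillna(0.0)
    table = merged
    rows = []
    for param in parameters:
        pvals = []
        for cls in classes:
            sub = table[table["class"] == cls]
            x = sub.loc[sub["group"] == "patient", param].to_numpy(dtype=float)
            y = sub.loc[sub["group"] == "control", param].to_numpy(dtype=float)
            u, z, p = mann_whitney_z(x, y)
            pvals.append(p)
            rows.append({
                "parameter": param, "class": cls,
                "mean_patient": x.mean(), "sd_patient": x.std(ddof=1),
                "mean_control": y.mean(), "sd_control": y.std(ddof=1),
                "U": u, "Z": z, "p": p,
            })
        q = bh_fdr(pvals)
        for i, cls in enumerate(classes):
            rows[-len(classes) + i]["p_fdr"] = q[i]
    out = pd.DataFrame(rows)
    out["significant"] = out["p_fdr"] < alpha
    return out


def correlate_clinical(
    stats_table: pd.DataFrame,
    scores: pd.DataFrame,
    which,
    score_columns=("MADRS", "YMRS", "STAI_state", "STAI_trait"),
):
    """Spearman correlations between clinical scores and selected microstate parameters.

    ``which`` is an iterable of (parameter, class) pairs -- typically the ones
    with significant group differences.  Each pair is correlated with every
    score column across all subjects.  Constant score columns are reported as
    missing (logged) rather than raising.
    """
    results = []
    for param, cls in which:
        sub = stats_table[stats_table["class"] == cls][["subject", param]]
        merged = sub.merge(scores, on="subject", how="inner")
        for col in score_columns:
            try:
                res = spearman_rho(
                    merged[col].to_numpy(dtype=float),
                    merged[param].to_numpy(dtype=float),
                    pair=(col, f"{param}:{cls}"),
                )
            except UndefinedStatisticError:
                logger.warning("constant column %s; correlation reported as missing", col)
                continue
            results.append(res)
    return results
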