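"""Full study replica: preprocess -> subject/group/global clustering -> back-fit -> stats.

One YAML-able configuration drives the whole chain with a single master seed
expanded into per-stage streams; every output directory receives delimited
tables plus a provenance JSON recording versions, seeds and parameters, so a
re-run with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    MicrostateModel,
    choose_k_meta_criterion,
    modified_kmeans,
    multilevel_clustering,
)
from .errors import ParameterError, StageError
from .preprocess import (
    average_reference,
    bandpass_filter,
    compute_gfp,
    detect_gfp_peaks,
    interpolate_channels,
    read_recording,
    resample,
)
from .segmentation import (
    SmoothingParams,
    backfit_labels,
    global_explained_variance,
    smooth_labels,
    temporal_parameters,
)
from .stats import (
    alpha_band_power,
    compare_groups,
    correlate_clinical,
    levene_test,
    mann_whitney_z,
    students_t,
    validate_clinical,
)
from .synthetic import SyntheticSpec, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyResult", "run_full_study", "load_config"]


@dataclass
class StudyConfig:
    """Everything needed to run the study replica once, reproducibly."""

    # input: either a manifest of (path, group) records or a synthetic cohort spec
    subjects: list = field(default_factory=list)  # [{"path":..., "group":..., "subject":...}]
    synthetic: dict | None = None  # kwargs for SyntheticSpec; used when subjects is empty
    clinical_scores: str | None = None  # path to a delimited clinical table

    band: tuple = (1.0, 40.0)
    target_fs: float = 125.0
    reference: str = "average"
    exclude_channels: list = field(default_factory=list)
    analysis_window: tuple | None = None  # (start_s, stop_s), applied per subject

    candidate_ks: tuple = (2, 8)  # inclusive range searched by the meta-criterion
    subject_k: int | str = "auto"
    global_k: int | str = "auto"
    n_restarts: int = 20
    use_gfp_peaks: bool = True

    smooth_half_window: int = 3
    smooth_besag: float = 10.0
    boundary_mode: str = "mixed"
    alpha_band: tuple = (8.0, 14.0)

    seed: int = 17
    outdir: str | None = None


@dataclass
class StudyResult:
    """In-memory bundle of everything the study replica produced."""

    subject_models: dict
    group_models: dict
    global_model: MicrostateModel
    chosen_k: int
    segmentations: dict
    stats_table: pd.DataFrame
    comparison: pd.DataFrame
    levene: pd.DataFrame
    clinical_tests: pd.DataFrame
    correlations: list
    alpha_power: pd.DataFrame
    provenance: dict
    ground_truth: object = None  # GroundTruth when the input cohort was synthetic


def load_config(path) -> StudyConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return StudyConfig(**raw)


def _stage(name):
    logger.info("stage: %s", name)
    return name


def _load_subjects(config: StudyConfig, rng):
    """Return (subject ids, groups, recordings, clinical table)."""
    if config.subjects:
        ids, groups, recs = [], [], []
        for i, entry in enumerate(config.subjects):
            rec = read_recording(entry["path"])
            ids.append(entry.get("subject", f"s{i + 1:02d}"))
            groups.append(entry["group"])
            recs.append(rec)
        clinical = None
        if config.clinical_scores:
            clinical = validate_clinical(pd.read_csv(config.clinical_scores))
        return ids, groups, recs, clinical, None
    spec = SyntheticSpec(**(config.synthetic or {}))
    cohort = simulate_cohort(spec, seed=int(rng.integers(2**31)))
    ids = list(cohort.clinical["subject"])
    groups = list(cohort.clinical["group"])
    return ids, groups, list(cohort.recordings), cohort.clinical, cohort.ground_truth


def _preprocess_one(rec, config: StudyConfig):
    if config.exclude_channels:
        keep = [i for i, n in enumerate(rec.channel_names) if n not in set(config.exclude_channels)]
        rec = rec.with_data(
            rec.data[keep],
            channel_names=tuple(rec.channel_names[i] for i in keep),
            channel_positions=None if rec.channel_positions is None else rec.channel_positions[keep],
            bad_channels=tuple(b for b in rec.bad_channels if b not in set(config.exclude_channels)),
        )
    low, high = config.band
    if not (low < high < rec.fs / 2):
        logger.info("skipping band-pass: band %s invalid at fs=%g", config.band, rec.fs)
    else:
        rec = bandpass_filter(rec, low, high)
    if config.target_fs and config.target_fs < rec.fs:
        rec = resample(rec, config.target_fs)
    if rec.bad_channels:
        rec = interpolate_channels(rec)
    if config.reference == "average":
        rec = average_reference(rec)
    if config.analysis_window is not None:
        start, stop = config.analysis_window
        i0, i1 = int(start * rec.fs), int(stop * rec.fs)
        if not 0 <= i0 < i1 <= rec.n_samples:
            raise ParameterError(f"analysis window {config.analysis_window} outside recording")
        rec = rec.with_data(rec.data[:, i0:i1])
    return rec


def run_full_study(config: StudyConfig, outdir=None) -> StudyResult:
    """Run the whole replica; write tables and provenance if an outdir is given."""
    outdir = outdir or config.outdir
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(s.integers(2**31))
        for name, s in zip(
            ("load", "subject", "group", "global", "fit"), master.spawn(5)
        )
    }

    stage = _stage("load")
    try:
        ids, groups, recs, clinical, ground_truth = _load_subjects(
            config, np.random.default_rng(stage_seeds["load"])
        )
        for g in ("patient", "control"):
            if groups.count(g) < 2:
                raise ParameterError(f"need >= 2 subjects in group {g!r}")
        recs = [_preprocess_one(r, config) for r in recs]
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- subject-level clustering on GFP peaks -----------------------------
    stage = _stage("subject_clustering")
    kmin, kmax = config.candidate_ks
    subject_models = {}
    try:
        rng = np.random.default_rng(stage_seeds["subject"])
        for sid, rec in zip(ids, recs):
            gfp = detect_gfp_peaks(compute_gfp(rec))
            idx = gfp.peak_indices if config.use_gfp_peaks and gfp.peak_indices.size else np.arange(rec.n_samples)
            peak_maps = rec.data[:, idx].T
            if config.subject_k == "auto":
                sel = choose_k_meta_criterion(
                    peak_maps, range(kmin, kmax + 1),
                    seed=rng.integers(2**31), n_restarts=config.n_restarts,
                )
                k = sel.chosen_k
            else:
                k = int(config.subject_k)
            subject_models[sid] = modified_kmeans(
                peak_maps, k, n_restarts=config.n_restarts, seed=rng.integers(2**31)
            )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- group-level and global clustering ---------------------------------
    stage = _stage("group_clustering")
    try:
        rng = np.random.default_rng(stage_seeds["group"])
        group_models = {}
        for g in ("patient", "control"):
            members = [subject_models[s] for s, gg in zip(ids, groups) if gg == g]
            pooled = np.vstack([m.maps for m in members])
            if config.global_k == "auto":
                sel = choose_k_meta_criterion(
                    pooled, range(kmin, kmax + 1),
                    seed=rng.integers(2**31), n_restarts=config.n_restarts,
                )
                gk = sel.chosen_k
            else:
                gk = int(config.global_k)
            group_models[g] = multilevel_clustering(
                members, gk, seed=rng.integers(2**31), level="group",
                n_restarts=config.n_restarts,
            )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    stage = _stage("global_clustering")
    try:
        rng = np.random.default_rng(stage_seeds["global"])
        all_models = [subject_models[s] for s in ids]
        pooled = np.vstack([m.maps for m in all_models])
        if config.global_k == "auto":
            sel = choose_k_meta_criterion(
                pooled, range(kmin, kmax + 1),
                seed=rng.integers(2**31), n_restarts=config.n_restarts,
            )
            chosen_k = sel.chosen_k
        else:
            chosen_k = int(config.global_k)
        global_model = multilevel_clustering(
            all_models, chosen_k, seed=rng.integers(2**31), level="global",
            n_restarts=config.n_restarts,
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- back-fitting and temporal parameters ------------------------------
    stage = _stage("backfit")
    try:
        smooth = SmoothingParams(
            window_half_size=config.smooth_half_window, besag_factor=config.smooth_besag
        )
        segmentations, gev_rows, stat_rows = {}, [], []
        for sid, group, rec in zip(ids, groups, recs):
            seg = smooth_labels(backfit_labels(rec, global_model), params=smooth)
            segmentations[sid] = seg
            ts = temporal_parameters(seg, boundary_mode=config.boundary_mode)
            gev_class, gev_total = global_explained_variance(rec, seg)
            gev_rows.append({"subject": sid, "gev_total": gev_total})
            for cls in range(global_model.k):
                stat_rows.append({
                    "subject": sid, "group": group, "class": cls,
                    "occurrence": ts.occurrence[cls], "coverage": ts.coverage[cls],
                    "duration": ts.duration[cls], "gev": gev_class[cls],
                })
        stats_table = pd.DataFrame(stat_rows)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- statistics ---------------------------------------------------------
    stage = _stage("stats")
    try:
        comparison = compare_groups(stats_table)
        lev_rows = []
        for param in ("occurrence", "coverage", "duration"):
            for cls in sorted(stats_table["class"].unique()):
                sub = stats_table[stats_table["class"] == cls]
                w, p = levene_test(
                    sub.loc[sub["group"] == "patient", param],
                    sub.loc[sub["group"] == "control", param],
                )
                lev_rows.append({"parameter": param, "class": cls, "W": w, "p": p})
        levene_table = pd.DataFrame(lev_rows)

        clin_rows = []
        if clinical is not None:
            pat = clinical[clinical["group"] == "patient"]
            con = clinical[clinical["group"] == "control"]
            for col in ("age", "education", "MADRS", "YMRS", "STAI_state", "STAI_trait"):
                if col not in clinical.columns:
                    continue
                t, p = students_t(con[col], pat[col])
                clin_rows.append({
                    "characteristic": col,
                    "mean_control": con[col].mean(), "sd_control": con[col].std(ddof=1),
                    "mean_patient": pat[col].mean(), "sd_patient": pat[col].std(ddof=1),
                    "t": t, "p": p,
                })
        clinical_tests = pd.DataFrame(clin_rows)

        significant = [
            (r["parameter"], r["class"])
            for _, r in comparison.iterrows() if r["significant"]
        ]
        correlations = (
            correlate_clinical(stats_table, clinical, significant)
            if clinical is not None and significant else []
        )

        alpha_rows = []
        for sid, group, rec in zip(ids, groups, recs):
            try:
                power = alpha_band_power(rec, band=config.alpha_band)
            except ParameterError:
                continue
            alpha_rows.append({"subject": sid, "group": group, "alpha_power": power})
        alpha_table = pd.DataFrame(alpha_rows)
        if len(alpha_table):
            u, z, p = mann_whitney_z(
                alpha_table.loc[alpha_table["group"] == "patient", "alpha_power"],
                alpha_table.loc[alpha_table["group"] == "control", "alpha_power"],
            )
            alpha_table.attrs["comparison"] = {"U": u, "Z": z, "p": p}
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    provenance = {
        "package": "msdyn",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("subjects",)
        },
        "chosen_k": int(chosen_k),
        "global_gev": float(global_model.gev),
    }

    result = StudyResult(
        subject_models=subject_models, group_models=group_models,
        global_model=global_model, chosen_k=int(chosen_k),
        segmentations=segmentations, stats_table=stats_table,
        comparison=comparison, levene=levene_table, clinical_tests=clinical_tests,
        correlations=correlations, alpha_power=alpha_table, provenance=provenance,
        ground_truth=ground_truth,
    )
    if out:
        _write_outputs(result, out)
    return result


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(6)


def _write_outputs(result: StudyResult, out: Path) -> None:
    _fmt(result.stats_table).to_csv(out / "subject_stats.csv", index=False)
    _fmt(result.comparison).to_csv(out / "group_comparison.csv", index=False)
    _fmt(result.levene).to_csv(out / "levene.csv", index=False)
    if len(result.clinical_tests):
        _fmt(result.clinical_tests).to_csv(out / "clinical_tests.csv", index=False)
    if len(result.alpha_power):
        _fmt(result.alpha_power).to_csv(out / "alpha_power.csv", index=False)
    if result.correlations:
        pd.DataFrame(
            [{"score": c.pair[0], "parameter": c.pair[1], "rho": c.rho, "p": c.p}
             for c in result.correlations]
        ).round(6).to_csv(out / "clinical_correlations.csv", index=False)
    np.savetxt(out / "global_maps.csv", result.global_model.maps, delimiter=",", fmt="%.8f")
    with open(out / "provenance.json", "w") as f:
        json.dump(result.provenance, f, indent=2, sort_keys=True)
    logger.info("wrote study bundle to %s", out)
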