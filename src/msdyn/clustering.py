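"""Polarity-invariant topographic clustering of EEG maps.

Microstate template maps are derived by a modified k-means in which a map and
its negation are equivalent: assignment maximises the *squared* spatial
correlation with each template, and the template update is the dominant
eigenvector of the assigned maps' cross-product matrix.  The number of
clusters can be chosen by a meta-criterion that combines several standard
cluster-validity indices by a median vote.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import DimensionError, ParameterError, UndefinedStatisticError

logger = logging.getLogger(__name__)

__all__ = [
    "MicrostateModel",
    "KSelection",
    "spatial_correlation",
    "modified_kmeans",
    "choose_k_meta_criterion",
    "multilevel_clustering",
    "load_canonical_maps",
    "CRITERIA",
]


@dataclass(frozen=True)
class MicrostateModel:
    """A set of K microstate template maps.

    ``maps`` is (K, n_channels), each row zero-mean and unit-norm; polarity is
    ambiguous (a row and its negation denote the same microstate).  ``gev`` is
    the global explained variance the templates achieve on their fitting data.
    ``labels_meta`` carries class tags (A-E after canonical alignment) or None.
    """

    maps: np.ndarray
    level: str = "subject"  # subject | group | global
    gev: float = np.nan
    labels_meta: tuple | None = None

    def __post_init__(self):
        maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if self.level not in ("subject", "group", "global"):
            raise ParameterError(f"unknown level {self.level!r}")
        norms = np.linalg.norm(maps, axis=1)
        if np.any(np.abs(norms - 1) > 1e-6):
            raise ParameterError("template maps must be unit-norm")
        if np.any(np.abs(maps.mean(axis=1)) > 1e-6):
            raise ParameterError("template maps must be zero-mean (average-reference space)")
        if not np.isnan(self.gev) and not (0 <= self.gev <= 1 + 1e-9):
            raise ParameterError(f"gev must lie in [0, 1]; got {self.gev}")
        if maps.shape[0] > 1:
            r = maps @ maps.T
            off = np.abs(r[~np.eye(maps.shape[0], dtype=bool)])
            if np.any(off > 1 - 1e-9):
                raise ParameterError("two templates are identical up to sign")
        object.__setattr__(self, "maps", maps)
        if self.labels_meta is not None:
            object.__setattr__(self, "labels_meta", tuple(self.labels_meta))

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass(frozen=True)
class KSelection:
    """Result of the meta-criterion search over candidate cluster counts."""

    candidate_ks: tuple
    criterion_scores: dict = field(default_factory=dict)
    votes: dict = field(default_factory=dict)
    chosen_k: int = 0

    def __post_init__(self):
        object.__setattr__(self, "candidate_ks", tuple(self.candidate_ks))
        if self.chosen_k not in self.candidate_ks:
            raise ParameterError("chosen_k must be one of the candidates")


def spatial_correlation(a, b) -> float:
    """Pearson correlation of two maps across channels (signed, in [-1, 1]).

    Polarity-invariant comparisons use the absolute value of this quantity.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"maps have different channel counts: {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedStatisticError("spatial correlation undefined for a zero-variance map")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


# ---------------------------------------------------------------------------
# Modified k-means
# ---------------------------------------------------------------------------

def _prepare_maps(peak_maps) -> np.ndarray:
    X = np.atleast_2d(np.asarray(peak_maps, dtype=float))
    X = X - X.mean(axis=1, keepdims=True)  # enforce average-reference space
    return X


def _dominant_eigenvector(X: np.ndarray) -> np.ndarray:
    """Unit-norm dominant eigenvector of X^T X (polarity-proof template of maps X)."""
    # X rows are zero-mean, so the constant vector is in the null space and the
    # dominant eigenvector stays zero-mean.
    S = X.T @ X
    w, V = np.linalg.eigh(S)
    v = V[:, -1]
    # deterministic sign: largest-magnitude component positive
    i = np.argmax(np.abs(v))
    if v[i] < 0:
        v = -v
    return v


def _gev_of_assignment(X, templates, assign, total_ss) -> float:
    # GEV = sum over maps of (x . a_label)^2 / sum ||x||^2  (GFP^2-weighted r^2)
    proj = np.einsum("ij,ij->i", X, templates[assign])
    return float(np.sum(proj**2) / total_ss)


def modified_kmeans(
    peak_maps,
    k: int,
    n_restarts: int = 100,
    seed=None,
    max_iter: int = 500,
    tol: float = 1e-8,
    level: str = "subject",
) -> MicrostateModel:
    """Polarity-invariant modified k-means on a set of EEG maps.

    Each map is assigned to the template with the highest squared spatial
    correlation; each template is re-estimated as the dominant eigenvector of
    its assigned maps' cross-product matrix.  The best of ``n_restarts``
    seeded initialisations by global explained variance (GEV) is returned.
    An emptied cluster is re-seeded from the currently worst-fit map.
    """
    X = _prepare_maps(peak_maps)
    n, c = X.shape
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}]; got {k}")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ParameterError("zero-variance map in input")
    total_ss = float(np.sum(norms**2))
    rng = np.random.default_rng(seed)

    best_gev, best_templates, best_assign = -1.0, None, None
    for _ in range(n_restarts):
        init = rng.choice(n, size=k, replace=False)
        templates = X[init] / norms[init, None]
        assign = np.full(n, -1)
        gev = -1.0
        for _ in range(max_iter):
            proj = X @ templates.T  # (n, k)
            new_assign = np.argmax(proj**2, axis=1)
            # re-seed empty clusters from the worst-fit map
            for j in range(k):
                if not np.any(new_assign == j):
                    fit = np.max(proj**2, axis=1) / norms**2
                    worst = int(np.argmin(fit))
                    templates[j] = X[worst] / norms[worst]
                    new_assign[worst] = j
            for j in range(k):
                members = X[new_assign == j]
                templates[j] = _dominant_eigenvector(members)
            new_gev = _gev_of_assignment(X, templates, new_assign, total_ss)
            if np.array_equal(new_assign, assign) or abs(new_gev - gev) < tol:
                assign, gev = new_assign, new_gev
                break
            assign, gev = new_assign, new_gev
        if gev > best_gev:
            best_gev, best_templates, best_assign = gev, templates.copy(), assign.copy()

    order = np.argsort(-np.bincount(best_assign, minlength=k))  # largest cluster first
    return MicrostateModel(maps=best_templates[order], level=level, gev=best_gev)


# ---------------------------------------------------------------------------
# Cluster-validity criteria and the meta-criterion
# ---------------------------------------------------------------------------

def _cluster_stats(X, model):
    """Assignment, per-cluster residual dispersion and totals for validity indices."""
    norms = np.linalg.norm(X, axis=1)
    proj = X @ model.maps.T
    assign = np.argmax(proj**2, axis=1)
    win = proj[np.arange(len(X)), assign]
    resid = norms**2 - win**2  # squared distance to the template's line
    W = float(np.sum(resid))
    # normalised-map versions for silhouette / Davies-Bouldin
    r2 = (proj / norms[:, None]) ** 2  # squared correlation with each template
    return assign, resid, W, r2


def _elbow_vote(values, ks, decreasing=False):
    """K at the maximum discrete curvature of a monotone criterion curve."""
    v = np.asarray(values, dtype=float)
    if decreasing:
        v = -v
    if len(v) < 3:
        return ks[0]
    gain = np.diff(v)  # gain[i] = v[i+1] - v[i]
    curvature = gain[:-1] - gain[1:]  # high where the curve bends
    return ks[1 + int(np.argmax(curvature))]


def _meta_indices(X, models_by_k, ks):
    """Per-K scores of the criterion bank. Returns {criterion: {k: score}} plus votes."""
    n, c = X.shape
    p = c - 1  # effective dimensionality in average-reference space
    stats = {k: _cluster_stats(X, models_by_k[k]) for k in models_by_k}
    W = {k: stats[k][2] for k in stats}
    gev = {k: models_by_k[k].gev for k in models_by_k}
    # K=1 dispersion: residual to the single dominant eigenvector
    t1 = _dominant_eigenvector(X)
    W1 = float(np.sum(np.linalg.norm(X, axis=1) ** 2 - (X @ t1) ** 2))

    scores: dict[str, dict[int, float]] = {name: {} for name in CRITERIA}
    for k in ks:
        assign, resid, Wk, r2 = stats[k]
        counts = np.bincount(assign, minlength=k)
        # cross-validation criterion (residual variance with df penalty)
        scores["cv"][k] = (
            (Wk / (n * (c - 1))) * ((c - 1) / (c - 1 - k)) ** 2 if k < c - 1 else np.inf
        )
        # Calinski-Harabasz on projection residuals, K=1 dispersion as total
        scores["calinski_harabasz"][k] = (
            ((W1 - Wk) / max(k - 1, 1)) / (Wk / (n - k)) if n > k else 0.0
        )
        # Davies-Bouldin with chordal template distances and correlation-space scatter
        S = np.zeros(k)
        for j in range(k):
            members = r2[assign == j, j]
            S[j] = np.sqrt(np.mean(np.clip(1.0 - members, 0.0, None))) if members.size else 0.0
        rT = np.abs(models_by_k[k].maps @ models_by_k[k].maps.T)
        d = np.sqrt(np.clip(1.0 - rT**2, 0.0, None))
        db = 0.0
        for i in range(k):
            ratios = [(S[i] + S[j]) / d[i, j] for j in range(k) if j != i and d[i, j] > 0]
            db += max(ratios) if ratios else 0.0
        scores["davies_bouldin"][k] = db / k if k > 1 else np.inf
        # silhouette on chordal distance to templates
        dmat = np.sqrt(np.clip(1.0 - r2, 0.0, None))  # (n, k)
        a = dmat[np.arange(n), assign]
        dmat_other = dmat.copy()
        dmat_other[np.arange(n), assign] = np.inf
        b = np.min(dmat_other, axis=1) if k > 1 else np.full(n, np.inf)
        with np.errstate(invalid="ignore"):
            sil = (b - a) / np.maximum(a, b)
        scores["silhouette"][k] = float(np.nanmean(np.where(np.isfinite(sil), sil, 0.0)))
        scores["gev"][k] = gev[k]
        scores["dispersion"][k] = Wk
    # Krzanowski-Lai needs W at k-1 and k+1 (extended fits supplied by caller)
    for k in ks:
        Wm = W.get(k - 1, W1 if k - 1 == 1 else None)
        Wp = W.get(k + 1)
        if Wm is None or Wp is None:
            scores["krzanowski_lai"][k] = np.nan
            continue
        diff_k = (k - 1) ** (2 / p) * Wm - k ** (2 / p) * W[k]
        diff_k1 = k ** (2 / p) * W[k] - (k + 1) ** (2 / p) * Wp
        scores["krzanowski_lai"][k] = abs(diff_k / diff_k1) if diff_k1 != 0 else np.nan
    return scores


def _criterion_votes(scores, ks):
    votes = {}
    for name, direction in CRITERIA.items():
        per_k = np.array([scores[name].get(k, np.nan) for k in ks], dtype=float)
        if np.all(np.isnan(per_k)):
            continue
        if direction == "max":
            votes[name] = ks[int(np.nanargmax(per_k))]
        elif direction == "min":
            votes[name] = ks[int(np.nanargmin(per_k))]
        elif direction == "elbow_up":
            votes[name] = _elbow_vote(per_k, ks)
        elif direction == "elbow_down":
            votes[name] = _elbow_vote(per_k, ks, decreasing=True)
    return votes


#: Criterion bank: name -> how its per-K curve is turned into a vote.
CRITERIA = {
    "gev": "elbow_up",
    "dispersion": "elbow_down",
    "cv": "min",
    "krzanowski_lai": "max",
    "calinski_harabasz": "max",
    "davies_bouldin": "min",
    "silhouette": "max",
}


def choose_k_meta_criterion(
    peak_maps,
    candidate_ks,
    seed=None,
    n_restarts: int = 20,
    criteria: dict | None = None,
) -> KSelection:
    """Choose the number of microstate classes by a median vote over validity criteria.

    Fits the modified k-means for every candidate K (plus one K on each side,
    needed by the Krzanowski-Lai index), scores the configurable criterion
    bank, lets each criterion vote for one K, and returns the lower median of
    the votes (ties resolve toward smaller K).
    """
    ks = sorted(int(k) for k in candidate_ks)
    X = _prepare_maps(peak_maps)
    n = len(X)
    if not ks:
        raise ParameterError("candidate_ks is empty")
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ParameterError(f"candidate_ks must lie within [2, {n - 1}]")
    if len(ks) == 1:
        return KSelection(candidate_ks=ks, chosen_k=ks[0])

    criteria = CRITERIA if criteria is None else criteria
    rng = np.random.default_rng(seed)
    ext_ks = sorted(set(ks) | {ks[0] - 1, ks[-1] + 1})
    ext_ks = [k for k in ext_ks if 2 <= k <= n - 1]
    models = {
        k: modified_kmeans(X, k, n_restarts=n_restarts, seed=rng.integers(2**31))
        for k in ext_ks
    }
    scores = _meta_indices(X, models, ks)
    scores = {name: scores[name] for name in criteria}
    votes = _criterion_votes(scores, ks)
    ordered = sorted(votes.values())
    chosen = ordered[(len(ordered) - 1) // 2]  # lower median -> ties favour smaller K
    logger.info("meta-criterion votes: %s -> chosen K=%d", votes, chosen)
    return KSelection(candidate_ks=ks, criterion_scores=scores, votes=votes, chosen_k=chosen)


# ---------------------------------------------------------------------------
# Multilevel clustering and canonical labelling
# ---------------------------------------------------------------------------

def load_canonical_maps():
    """Load the shipped synthetic canonical A-E topographies (10-20 montage).

    These are idealized dipolar/bump approximations of the literature's
    canonical microstate classes, constructed on the standard 19-channel
    10-20 montage; they are used only to attach A-E tags to fitted templates,
    never for fitting.  Returns (channel_names, tags, maps (5, 19)).
    """
    ref = resources.files("msdyn.data").joinpath("canonical_1020_synthetic.csv")
    with ref.open() as f:
        rows = list(csv.reader(f))
    names = tuple(rows[0][1:])
    tags = tuple(r[0] for r in rows[1:])
    maps = np.array([[float(v) for v in r[1:]] for r in rows[1:]])
    return names, tags, maps


def assign_class_tags(model: MicrostateModel, canonical_maps, tags) -> tuple:
    """Greedy |correlation| matching of fitted templates to canonical class maps."""
    canonical_maps = np.asarray(canonical_maps, dtype=float)
    if canonical_maps.shape[1] != model.n_channels:
        raise DimensionError("canonical maps and model differ in channel count")
    r = np.abs(model.maps @ (canonical_maps / np.linalg.norm(canonical_maps, axis=1, keepdims=True)).T)
    out = [None] * model.k
    r = r.copy()
    for _ in range(min(model.k, len(tags))):
        i, j = np.unravel_index(np.argmax(r), r.shape)
        out[i] = tags[j]
        r[i, :] = -1
        r[:, j] = -1
    for i in range(model.k):  # more templates than tags: ordinal fallback
        if out[i] is None:
            out[i] = f"M{i + 1}"
    return tuple(out)


def multilevel_clustering(
    subject_models,
    k: int,
    seed=None,
    level: str = "global",
    n_restarts: int = 100,
    canonical=None,
) -> MicrostateModel:
    """Cluster pooled subject-level template maps into a group- or global-level model.

    ``canonical`` may be a (maps, tags) pair used to attach A-E class tags to
    the resulting templates by greedy |correlation| matching.
    """
    models = list(subject_models)
    if not models:
        raise ParameterError("no subject models given")
    n_ch = models[0].n_channels
    if any(m.n_channels != n_ch for m in models):
        raise DimensionError("subject models differ in channel count")
    pooled = np.vstack([m.maps for m in models])
    out = modified_kmeans(pooled, k, n_restarts=n_restarts, seed=seed, level=level)
    if canonical is not None:
        maps, tags = canonical
        out = MicrostateModel(
            maps=out.maps, level=level, gev=out.gev,
            labels_meta=assign_class_tags(out, maps, tags),
        )
    return out
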