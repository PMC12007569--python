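"""Conformational-landscape analysis.

Pipeline stage over the per-model gating table: retain models whose
interface-quality score is strictly greater than a threshold, cluster the
retained models in (C_N, C_C) space with PAM k-medoids (k = 9 by default,
with a cap on the distance-matrix dimension handled by seeded
subsampling), pick the most centrally located model of each cluster as its
representative, and assign conformational-state labels (outward-open /
occluded / inward-open / intermediate) relative to endpoint reference
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .gating import GatingMetricDefinition
from .structures import GroupSpec, StructureModel, select_coords, superpose

logger = logging.getLogger("gatescape")

__all__ = [
    "QualityFilterConfig",
    "ClusteringConfig",
    "ClusteringResult",
    "StateLabel",
    "filter_by_quality",
    "kmedoids",
    "select_representatives",
    "representative_tightness",
    "classify_state",
    "references_from_endpoints",
]


@dataclass(frozen=True)
class QualityFilterConfig:
    """Strictly-greater quality retention rule (default threshold 0.4)."""

    threshold: float = 0.4

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass(frozen=True)
class ClusteringConfig:
    """k-medoids settings: k clusters, distance-matrix cap, seed, scaling."""

    k: int = 9
    max_matrix: int = 5000
    seed: int = 0
    max_iter: int = 200
    scaling: str = "none"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.max_matrix < self.k:
            raise ValueError("max_matrix must be >= k")
        if self.scaling not in ("none", "zscore"):
            raise ValueError(f"scaling must be 'none' or 'zscore', got {self.scaling!r}")


@dataclass
class ClusteringResult:
    medoid_ids: list[str]
    assignment: dict[str, int]
    representative_ids: list[str]
    cost: float
    subsample_ids: list[str]
    cost_history: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.medoid_ids)


@dataclass(frozen=True)
class StateLabel:
    """State call for one model plus the rule record that produced it."""

    label: str
    rule: dict

    def __post_init__(self) -> None:
        if self.label not in ("outward_open", "occluded", "inward_open", "intermediate"):
            raise ValueError(f"unknown state label {self.label!r}")


# ---------------------------------------------------------------------------
# Quality filter
# ---------------------------------------------------------------------------

def filter_by_quality(landscape: pd.DataFrame, scores: Mapping[str, float] | pd.Series,
                      cfg: QualityFilterConfig = QualityFilterConfig(),
                      drop_missing: bool = False) -> pd.DataFrame:
    """Rows whose model score is strictly greater than the threshold.

    Every model must have a score; with ``drop_missing`` unscored models
    are dropped (and logged) instead of raising. Row order is preserved.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_dict()
    ids = landscape["model_id"].tolist()
    missing = [i for i in ids if i not in scores]
    if missing:
        if not drop_missing:
            raise KeyError(
                f"{len(missing)} model(s) without a quality score, e.g. {missing[:3]}"
            )
        logger.warning("quality filter: dropping %d unscored model(s)", len(missing))
    keep = [i in scores and scores[i] > cfg.threshold for i in ids]
    out = landscape.loc[keep].reset_index(drop=True)
    logger.info("quality filter: retained %d / %d models (score > %g)",
                len(out), len(landscape), cfg.threshold)
    return out


# ---------------------------------------------------------------------------
# PAM k-medoids
# ---------------------------------------------------------------------------

def _as_points(points, ids: Sequence[str] | None):
    """Accept a DataFrame (model_id + metric columns) or an array + ids."""
    if isinstance(points, pd.DataFrame):
        if "model_id" in points.columns:
            ids = points["model_id"].tolist()
            X = points.drop(columns="model_id").to_numpy(dtype=float)
        else:
            ids = [str(i) for i in points.index]
            X = points.to_numpy(dtype=float)
    else:
        X = np.asarray(points, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if ids is None:
            ids = [str(i) for i in range(len(X))]
        ids = list(ids)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite coordinates in clustering input")
    if len(ids) != len(X):
        raise ValueError("ids/points length mismatch")
    return X, ids


def _plusplus_init(D: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    """k-medoids++ seeding: D^2-weighted sequential medoid choice."""
    n = D.shape[0]
    first = int(rng.integers(n))
    medoids = [first]
    closest = D[first].copy()
    for _ in range(1, k):
        w = closest ** 2
        total = w.sum()
        if total <= 0:  # fewer distinct points than k is caught upstream
            cand = [i for i in range(n) if i not in medoids]
            medoids.append(cand[0])
            continue
        nxt = int(rng.choice(n, p=w / total))
        medoids.append(nxt)
        np.minimum(closest, D[nxt], out=closest)
    return medoids


def kmedoids(points, cfg: ClusteringConfig, ids: Sequence[str] | None = None) -> ClusteringResult:
    """PAM-style k-medoids on Euclidean distances in metric space.

    Alternates nearest-medoid assignment with within-cluster medoid
    updates until the cost is stationary. If n exceeds ``cfg.max_matrix``
    the medoid search runs on a seeded uniform subsample of that size and
    the remaining points are assigned to the nearest medoid afterwards.
    Deterministic for a given seed; ties break to the smallest index /
    lexicographically smallest model id.
    """
    X, id_list = _as_points(points, ids)
    n = len(X)
    if cfg.k > n:
        raise ValueError(f"k={cfg.k} exceeds number of points n={n}")
    if len({tuple(row) for row in X}) < cfg.k:
        raise ValueError(f"fewer than k={cfg.k} distinct points")
    if cfg.scaling == "zscore":
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xs = (X - X.mean(axis=0)) / sd
    else:
        Xs = X

    rng = np.random.default_rng(cfg.seed)
    if n > cfg.max_matrix:
        sub = np.sort(rng.choice(n, size=cfg.max_matrix, replace=False))
    else:
        sub = np.arange(n)
    D = cdist(Xs[sub], Xs[sub])

    medoids = _plusplus_init(D, cfg.k, rng)
    cost_history: list[float] = []
    prev_cost = np.inf
    for _ in range(cfg.max_iter):
        dist_to_med = D[:, medoids]
        labels = np.argmin(dist_to_med, axis=1)
        cost = float(dist_to_med[np.arange(len(sub)), labels].sum())
        cost_history.append(cost)
        new_medoids = list(medoids)
        for c in range(cfg.k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                # re-seed an empty cluster with the worst-assigned point
                worst = int(np.argmax(dist_to_med[np.arange(len(sub)), labels]))
                new_medoids[c] = worst
                continue
            within = D[np.ix_(members, members)].sum(axis=0)
            new_medoids[c] = int(members[int(np.argmin(within))])
        if new_medoids == medoids and cost >= prev_cost - 1e-12:
            break
        medoids = new_medoids
        prev_cost = cost

    # PAM SWAP refinement: greedily replace a medoid with a non-medoid
    # while any single swap lowers the cost (local optimality).
    for _ in range(100):
        dist_to_med = D[:, medoids]
        order = np.argsort(dist_to_med, axis=1)
        n1 = order[:, 0]
        d1 = dist_to_med[np.arange(len(sub)), n1]
        d2 = dist_to_med[np.arange(len(sub)), order[:, 1]] if cfg.k > 1 else np.full(len(sub), np.inf)
        base_cost = float(d1.sum())
        best = (base_cost - 1e-12, None, None)
        medoid_set = set(medoids)
        for o in range(len(sub)):
            if o in medoid_set:
                continue
            do = D[:, o]
            t_all = np.minimum(d1, do)
            delta = np.minimum(d2, do) - t_all  # extra cost if x loses its medoid
            per_medoid = np.bincount(n1, weights=delta, minlength=cfg.k)
            costs = t_all.sum() + per_medoid
            i = int(np.argmin(costs))
            if costs[i] < best[0]:
                best = (float(costs[i]), i, o)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        cost_history.append(best[0])

    # final assignment of every point (subsampled or not) to nearest medoid
    medoid_global = [int(sub[m]) for m in medoids]
    # order clusters deterministically by medoid model id
    order = sorted(range(cfg.k), key=lambda c: id_list[medoid_global[c]])
    medoid_global = [medoid_global[c] for c in order]
    full_dist = cdist(Xs, Xs[medoid_global])
    full_labels = np.argmin(full_dist, axis=1)
    cost = float(full_dist[np.arange(n), full_labels].sum())

    result = ClusteringResult(
        medoid_ids=[id_list[m] for m in medoid_global],
        assignment={id_list[i]: int(full_labels[i]) for i in range(n)},
        representative_ids=[],
        cost=cost,
        subsample_ids=[id_list[i] for i in sub],
        cost_history=cost_history,
    )
    result.representative_ids = select_representatives(result, points, ids)
    logger.info("kmedoids: k=%d on n=%d (search on %d), cost=%.4f",
                cfg.k, n, len(sub), cost)
    return result


def select_representatives(result: ClusteringResult, points,
                           ids: Sequence[str] | None = None) -> list[str]:
    """Most centrally located member of each cluster.

    The representative minimizes the mean Euclidean distance to all other
    members of its cluster; ties break to the lexicographically smallest
    model id. For a fully enumerated cluster this is its medoid.
    """
    X, id_list = _as_points(points, ids)
    pos = {m: i for i, m in enumerate(id_list)}
    reps: list[str] = []
    for c in range(result.k):
        member_ids = sorted(m for m, lab in result.assignment.items() if lab == c)
        if not member_ids:
            raise ValueError(f"cluster {c} is empty")
        idx = [pos[m] for m in member_ids]
        sub = X[idx]
        mean_d = cdist(sub, sub).mean(axis=1)
        best = int(np.argmin(mean_d))  # argmin -> first = smallest id (sorted)
        reps.append(member_ids[best])
    return reps


def representative_tightness(result: ClusteringResult,
                             models: Mapping[str, StructureModel],
                             selection: Sequence[GroupSpec]) -> dict[int, float]:
    """Mean superposed RMSD (A) of each representative to its cluster members.

    The comparison runs on the supplied atom selection; singleton clusters
    report 0.
    """
    out: dict[int, float] = {}
    for c, rep_id in enumerate(result.representative_ids):
        rep_xyz = select_coords(models[rep_id], selection)
        rmsds = []
        for mid, lab in result.assignment.items():
            if lab != c or mid == rep_id:
                continue
            rmsds.append(superpose(select_coords(models[mid], selection), rep_xyz).rmsd)
        out[c] = float(np.mean(rmsds)) if rmsds else 0.0
    return out


# ---------------------------------------------------------------------------
# State classification
# ---------------------------------------------------------------------------

def references_from_endpoints(outward: Mapping[str, float],
                              inward: Mapping[str, float]) -> dict:
    """Reference record from endpoint gate coordinates.

    ``outward`` is the outward-open endpoint (N-gate open, C-gate closed);
    ``inward`` the inward-open endpoint (N-gate closed, C-gate open).
    """
    return {
        "C_N": {"open": float(outward["C_N"]), "closed": float(inward["C_N"])},
        "C_C": {"open": float(inward["C_C"]), "closed": float(outward["C_C"])},
    }


def _gate_state(value: float, refs: dict, margin: float) -> str:
    closed = value >= refs["closed"] - margin
    opened = value <= refs["open"] + margin
    if closed and not opened:
        return "closed"
    if opened and not closed:
        return "open"
    if closed and opened:
        return "ambiguous"
    return "neither"


def classify_state(coords: Mapping[str, float], references: dict,
                   margins: Mapping[str, float] | float) -> StateLabel:
    """Reference-anchored state call from (C_N, C_C).

    A gate counts as closed when its coordination number is within
    ``margin`` of the closed-endpoint reference value (or beyond it), and
    open when within ``margin`` of the open-endpoint value. N open with C
    closed is outward-open; N closed with C open is inward-open; both
    closed is occluded; anything else (including overlapping margins) is
    intermediate.
    """
    if isinstance(margins, (int, float)):
        margins = {g: float(margins) for g in references}
    for g, m in margins.items():
        if m < 0:
            raise ValueError(f"negative margin for {g}")
    n_state = _gate_state(float(coords["C_N"]), references["C_N"], margins["C_N"])
    c_state = _gate_state(float(coords["C_C"]), references["C_C"], margins["C_C"])
    if n_state == "open" and c_state == "closed":
        label = "outward_open"
    elif n_state == "closed" and c_state == "open":
        label = "inward_open"
    elif n_state == "closed" and c_state == "closed":
        label = "occluded"
    else:
        label = "intermediate"
    return StateLabel(label=label, rule={
        "references": references,
        "margins": dict(margins),
        "gate_states": {"C_N": n_state, "C_C": c_state},
        "coords": {k: float(v) for k, v in dict(coords).items()},
    })
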