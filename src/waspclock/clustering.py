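"""Fuzzy c-means expression-profile clustering and rhythm enrichment.

Time-course profiles are z-scored per transcript (so clustering groups by
shape, not level), softly partitioned into c clusters with the classic fuzzy
c-means updates (Euclidean distance, fuzzifier m; m -> 1 approaches hard
k-means, the default m = 1.25 keeps memberships fairly crisp), hardened by
maximal membership, and each hard cluster is tested for over-representation
of rhythmic transcripts with a hypergeometric upper tail, BH-corrected over
the c tests of a condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ValidationError
from .rhythm_tests import bh_adjust

log = logging.getLogger(__name__)

__all__ = ["ClusterModel", "standardize", "fuzzy_cmeans", "select_c",
           "harden", "cluster_rhythm_enrichment"]


@dataclass
class ClusterModel:
    centroids: np.ndarray          # c × n_timepoints
    membership: np.ndarray         # transcripts × c, rows sum to 1
    m: float
    objective: float
    objective_path: tuple[float, ...]
    n_iter: int


def standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score rows (mean 0, sd 1 with the n-1 convention).

    Returns (z, kept_mask); constant rows cannot be standardized and are
    excluded (mask False) and logged.
    """
    X = np.asarray(values, dtype=float)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        log.info("standardize: excluded %d constant transcripts", int((~keep).sum()))
    Xk = X[keep]
    z = (Xk - Xk.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return z, keep


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """FCM membership update u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1)).

    A point coincident with a centroid gets membership 1 there (ties split
    equally among coincident centroids)."""
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=1)
    expo = 1.0 / (m - 1.0)
    # normalize by the row minimum first to avoid overflow at small m
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        d2s = d2 / d2.min(axis=1, keepdims=True).clip(min=1e-300)
        w = d2s ** -expo
        u = w / w.sum(axis=1, keepdims=True)
    if any_zero.any():
        u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(X: np.ndarray, c: int, m: float = 1.25, seed: int = 0,
                 tol: float = 1e-6, max_iter: int = 300, n_restarts: int = 3,
                 ) -> ClusterModel:
    """Fuzzy c-means on standardized profiles.

    Centroids are initialized by sampling c distinct rows under the seed;
    the best of ``n_restarts`` runs (lowest objective) is returned. The
    objective sum_ij u_ij^m d_ij^2 is tracked and is non-increasing.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not c >= 1:
        raise ValidationError("c must be >= 1")
    if c > n:
        raise ValidationError("more clusters than transcripts")
    if m <= 1:
        raise ValidationError("fuzzifier m must exceed 1")
    rng = np.random.default_rng(seed)
    best: ClusterModel | None = None
    for _ in range(max(1, n_restarts)):
        centroids = X[rng.choice(n, size=c, replace=False)].copy()
        path = []
        u = None
        for it in range(max_iter):
            d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            u = _memberships(d2, m)
            path.append(float((u ** m * d2).sum()))
            um = u ** m
            new_centroids = (um.T @ X) / um.sum(axis=0)[:, None].clip(min=1e-300)
            shift = float(np.abs(new_centroids - centroids).max())
            centroids = new_centroids
            if shift < tol:
                break
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        u = _memberships(d2, m)
        obj = float((u ** m * d2).sum())
        path.append(obj)
        model = ClusterModel(centroids, u, m, obj, tuple(path), len(path) - 1)
        if best is None or model.objective < best.objective:
            best = model
    assert best is not None
    return best


def harden(model: ClusterModel) -> np.ndarray:
    """Hard labels by maximal membership; ties go to the lowest cluster index."""
    return np.argmax(model.membership, axis=1)


def select_c(X: np.ndarray, m: float = 1.25, c_range=range(2, 31), seed: int = 0,
             collapse_frac: float = 0.5) -> tuple[int, pd.DataFrame]:
    """Centroid-redundancy heuristic for choosing c.

    Runs FCM for each candidate c and tracks the minimum pairwise centroid
    distance; returns the largest c before that distance collapses below
    ``collapse_frac`` of its value at the first candidate (redundant
    centroids indicate more clusters than distinct profile families).
    Also returns the full diagnostic curve.
    """
    c_values = list(c_range)
    if not c_values:
        raise ValidationError("empty c range")
    rows = []
    for c in c_values:
        model = fuzzy_cmeans(X, c, m=m, seed=seed, n_restarts=1)
        if c == 1:
            dmin = np.inf
        else:
            diff = model.centroids[:, None, :] - model.centroids[None, :, :]
            d = np.sqrt((diff ** 2).sum(axis=2))
            dmin = float(d[np.triu_indices(c, k=1)].min())
        rows.append({"c": c, "min_centroid_dist": dmin, "objective": model.objective})
    curve = pd.DataFrame(rows)
    if len(c_values) == 1:
        return c_values[0], curve
    ref = curve["min_centroid_dist"].iloc[0]
    collapsed = curve["min_centroid_dist"] < collapse_frac * ref
    chosen = c_values[-1]
    for i, bad in enumerate(collapsed):
        if bad and i > 0:
            chosen = c_values[i - 1]
            break
        if bad and i == 0:
            chosen = c_values[0]
            break
    return chosen, curve


def cluster_rhythm_enrichment(model: ClusterModel, ids: np.ndarray,
                              rhythmic_ids, universe_ids=None) -> pd.DataFrame:
    """Per-cluster hypergeometric enrichment of rhythmic transcripts.

    Clusters are hardened by maximal membership; for each cluster,
    p = P(X >= k) with X ~ Hypergeom(N = universe, K = rhythmic, n = cluster
    size); BH correction across the c tests. Empty clusters get p = 1.
    """
    ids = np.asarray(ids, dtype=str)
    universe = set(map(str, universe_ids)) if universe_ids is not None else set(ids)
    rhythmic = set(map(str, rhythmic_ids))
    if not rhythmic <= universe:
        raise ValidationError("rhythmic ids must be a subset of the universe")
    labels = harden(model)
    N = len(universe)
    K = len(rhythmic)
    rows = []
    for cl in range(model.membership.shape[1]):
        members = ids[labels == cl]
        n = len(members)
        k = sum(1 for t in members if t in rhythmic)
        p = 1.0 if n == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"cluster": cl, "k": k, "K": K, "n": n, "N": N,
                     "p": min(1.0, max(p, np.finfo(float).tiny))})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
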