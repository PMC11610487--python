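"""Non-parametric rhythm detection with exact small-sample nulls.

Two tests are provided, both rank-based and therefore invariant under
monotone transforms of the expression values:

* the **umbrella test**: for every cyclic umbrella ordering of the k phase
  groups (trough -> peak rising arm, peak -> trough falling arm) a
  Jonckheere-Terpstra-type concordance statistic is computed; the per-shape
  p-value comes from the exact permutation null (a convolution derived by
  conditioning on the peak/trough rank sets), and the reported p is
  Bonferroni-corrected over the k*(k-1) shapes. Asymmetric waveforms (unequal
  rise and fall) are first-class citizens of the shape set.

* the **tau test**: Kendall concordance of the series against a cosine
  reference of the test period at each candidate acrophase on the sampling
  grid; the per-phase exact null is the Jonckheere-Terpstra null over the
  reference tie blocks, Bonferroni-corrected over phases.

Samples are folded into k = period / interval phase groups, pooling cycles
(default design: 12 samples, two 24 h cycles, k = 6 groups of 2).
Ties within a series are scored with 0.5 credit and their p-values estimated
by seeded Monte-Carlo permutation (the convolution nulls assume no ties);
constant series get p = 1 by convention.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd

from ._exact import jt_null_pmf, umbrella_null_pmf
from .core_io import ExpressionMatrix, PipelineConfig, TimeDesign, ValidationError

log = logging.getLogger(__name__)

__all__ = ["umbrella_test", "tau_test", "umbrella_batch", "tau_batch",
           "bh_adjust", "detect_rhythmic"]

_PERM_FALLBACK = 20_000
_PERM_SEED = 987_654_321  # fixed: tie fallback must be reproducible


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# shared machinery

def _comparison_tensor(values: np.ndarray) -> np.ndarray:
    """C[a, i, j] = 1 if y_i < y_j else 0.5 if tied (i != j) else 0."""
    lt = (values[:, :, None] < values[:, None, :]).astype(float)
    eq = (values[:, :, None] == values[:, None, :]).astype(float)
    eq[:, np.arange(values.shape[1]), np.arange(values.shape[1])] = 0.0
    return lt + 0.5 * eq


@lru_cache(maxsize=8)
def _umbrella_machinery(times: tuple[float, ...], condition: str, period: float):
    design = TimeDesign(condition=condition, times=times)
    k = design.n_phase_groups(period)
    if k < 3:
        raise ValidationError("need at least 3 phase groups for the umbrella test")
    grp = design.phase_groups(period)
    sizes = np.bincount(grp, minlength=k)
    if len(set(sizes)) != 1:
        raise ValidationError("phase groups must be balanced")
    g = int(sizes[0])
    Z = np.zeros((len(times), k))
    Z[np.arange(len(times)), grp] = 1.0

    shapes = [(p, t) for p in range(k) for t in range(k) if t != p]
    W = np.zeros((len(shapes), k, k))
    for s, (peak, trough) in enumerate(shapes):
        r = (peak - trough) % k
        rising = [(trough + i) % k for i in range(r + 1)]
        falling = [(peak + i) % k for i in range(k - r + 1)]
        for ai in range(len(rising)):
            for bi in range(ai + 1, len(rising)):
                W[s, rising[ai], rising[bi]] += 1.0
        for ai in range(len(falling)):
            for bi in range(ai + 1, len(falling)):
                W[s, falling[bi], falling[ai]] += 1.0

    # per-shape exact survival functions on a common support
    pmfs = [umbrella_null_pmf(k, g, (p - t) % k) for (p, t) in shapes]
    smax = max(len(x) for x in pmfs)
    SF = np.zeros((len(shapes), smax + 1))
    for s, pmf in enumerate(pmfs):
        sf = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
        SF[s, : len(sf)] = sf
    centers = design.group_centers(period)
    return k, g, grp, Z, shapes, W, SF, centers


def _umbrella_stats(C: np.ndarray, Z: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Per-series, per-shape statistics from comparison tensors."""
    M = np.einsum("aij,iu,jv->auv", C, Z, Z)
    return np.einsum("auv,suv->as", M, W)


def umbrella_batch(values: np.ndarray, design: TimeDesign, period: float = 24.0,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Umbrella test over rows of ``values``; returns (p, phase, shape_index).

    p is Bonferroni-corrected over the shape set; phase is the winning shape's
    peak-group center in CT hours mod 24.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    k, g, grp, Z, shapes, W, SF, centers = _umbrella_machinery(
        tuple(design.times), design.condition, float(period))
    C = _comparison_tensor(values)
    S = _umbrella_stats(C, Z, W)
    n_shapes = len(shapes)

    has_ties = np.array([len(np.unique(row)) < len(row) for row in values])
    constant = np.ptp(values, axis=1) == 0

    p_shape = np.ones_like(S)
    integral = np.rint(S).astype(int)
    ok = ~has_ties
    if ok.any():
        idx = np.clip(integral, 0, SF.shape[1] - 1)
        p_shape[ok] = SF[np.arange(n_shapes)[None, :], idx[ok]]
    if (has_ties & ~constant).any():
        rng = np.random.default_rng(_PERM_SEED)
        for a in np.flatnonzero(has_ties & ~constant):
            p_shape[a] = _permutation_shape_p(values[a], Z, W, S[a], rng)

    best = np.argmin(p_shape, axis=1)
    p = np.minimum(1.0, p_shape[np.arange(len(values)), best] * n_shapes)
    peak_groups = np.array([shapes[b][0] for b in best])
    phase = centers[peak_groups]
    p[constant] = 1.0
    phase[constant] = 0.0
    if constant.any():
        log.info("umbrella test: %d constant series given p = 1", int(constant.sum()))
    return p, phase, best


def _permutation_shape_p(series: np.ndarray, Z: np.ndarray, W: np.ndarray,
                         s_obs: np.ndarray, rng: np.random.Generator,
                         n_perm: int = _PERM_FALLBACK) -> np.ndarray:
    perms = np.array([rng.permutation(series) for _ in range(n_perm)])
    S = _umbrella_stats(_comparison_tensor(perms), Z, W)
    return (1.0 + (S >= s_obs[None, :] - 1e-9).sum(axis=0)) / (n_perm + 1.0)


def umbrella_test(series, design: TimeDesign, period: float = 24.0,
                  ) -> tuple[float, float, tuple[int, int]]:
    """Single-series umbrella test -> (p, phase, (peak_group, trough_group))."""
    p, phase, best = umbrella_batch(np.asarray(series, dtype=float)[None, :],
                                    design, period)
    k, g, grp, Z, shapes, W, SF, centers = _umbrella_machinery(
        tuple(design.times), design.condition, float(period))
    return float(p[0]), float(phase[0]), shapes[int(best[0])]


# ---------------------------------------------------------------------------
# tau test

@lru_cache(maxsize=8)
def _tau_machinery(times: tuple[float, ...], condition: str, period: float):
    design = TimeDesign(condition=condition, times=times)
    k = design.n_phase_groups(period)
    t = np.asarray(times, dtype=float)
    ref_phases = (t[0] + design.interval * np.arange(k)) % 24.0
    V = np.zeros((k, len(t), len(t)))
    SFs = []
    smax = 0
    pmfs = []
    for j in range(k):
        ref = np.round(np.cos(2 * np.pi * (t - ref_phases[j]) / period), 9)
        blocks, inv = np.unique(ref, return_inverse=True)  # ascending block rank
        V[j] = (inv[:, None] < inv[None, :]).astype(float)
        sizes = tuple(int(x) for x in np.bincount(inv))
        pmfs.append(jt_null_pmf(sizes))
        smax = max(smax, len(pmfs[-1]))
    SF = np.zeros((k, smax + 1))
    for j, pmf in enumerate(pmfs):
        sf = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
        SF[j, : len(sf)] = sf
    return k, ref_phases, V, SF


def tau_batch(values: np.ndarray, design: TimeDesign, period: float = 24.0,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Kendall-tau cosine-reference test over rows -> (p, phase).

    Per phase, the statistic counts concordant (series, reference) pairs over
    reference tie blocks; exact JT null, Bonferroni over the phase grid.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    k, ref_phases, V, SF = _tau_machinery(tuple(design.times), design.condition,
                                          float(period))
    C = _comparison_tensor(values)
    S = np.einsum("aij,pij->ap", C, V)

    has_ties = np.array([len(np.unique(row)) < len(row) for row in values])
    constant = np.ptp(values, axis=1) == 0
    p_phase = np.ones_like(S)
    ok = ~has_ties
    if ok.any():
        idx = np.clip(np.rint(S).astype(int), 0, SF.shape[1] - 1)
        p_phase[ok] = SF[np.arange(k)[None, :], idx[ok]]
    if (has_ties & ~constant).any():
        rng = np.random.default_rng(_PERM_SEED + 1)
        for a in np.flatnonzero(has_ties & ~constant):
            perms = np.array([rng.permutation(values[a]) for _ in range(_PERM_FALLBACK)])
            Sp = np.einsum("aij,pij->ap", _comparison_tensor(perms), V)
            p_phase[a] = (1.0 + (Sp >= S[a][None, :] - 1e-9).sum(axis=0)) / (
                _PERM_FALLBACK + 1.0)

    best = np.argmin(p_phase, axis=1)
    p = np.minimum(1.0, p_phase[np.arange(len(values)), best] * k)
    phase = ref_phases[best]
    p[constant] = 1.0
    phase[constant] = 0.0
    return p, phase


def tau_test(series, design: TimeDesign, period: float = 24.0,
             ) -> tuple[float, float]:
    p, phase = tau_batch(np.asarray(series, dtype=float)[None, :], design, period)
    return float(p[0]), float(phase[0])


# ---------------------------------------------------------------------------
# matrix-level detection

def detect_rhythmic(matrix: ExpressionMatrix, config: PipelineConfig | None = None,
                    gene_level: bool = False,
                    ) -> tuple[pd.DataFrame, dict]:
    """Run both tests on every transcript of one condition.

    Returns a tidy table (one row per transcript: p/q/phase/shape per method)
    and a summary with counts at the strict and broad FDR thresholds plus the
    umbrella->tau cross-method agreement fraction.
    """
    config = config or PipelineConfig()
    if gene_level:
        matrix = matrix.by_gene()
    design = matrix.design
    period = config.test_period

    p_u, phase_u, shape_idx = umbrella_batch(matrix.values, design, period)
    p_t, phase_t = tau_batch(matrix.values, design, period)
    q_u = bh_adjust(p_u)
    q_t = bh_adjust(p_t)

    k, g, grp, Z, shapes, W, SF, centers = _umbrella_machinery(
        tuple(design.times), design.condition, float(period))
    table = pd.DataFrame({
        "transcript_id": matrix.transcript_ids,
        "condition": design.condition,
        "p_umbrella": p_u,
        "q_umbrella": q_u,
        "phase_umbrella": phase_u,
        "peak_group": [shapes[i][0] for i in shape_idx],
        "trough_group": [shapes[i][1] for i in shape_idx],
        "p_tau": p_t,
        "q_tau": q_t,
        "phase_tau": phase_t,
    })
    strict = q_u < config.rain_q_strict
    summary = {
        "condition": design.condition,
        "n_tested": int(len(p_u)),
        "n_rhythmic_strict": int(strict.sum()),
        "n_rhythmic_broad": int((q_u < config.rain_q_broad).sum()),
        "n_tau_strict": int((q_t < config.rain_q_strict).sum()),
        "tau_agreement": float((q_t[strict] < config.jtk_q).mean()) if strict.any() else float("nan"),
    }
    return table, summary
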