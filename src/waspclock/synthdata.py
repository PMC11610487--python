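"""Synthetic DD/LL circadian expression matrices with ground truth.

The generator emulates the statistical structure of a head-transcriptome
free-running time course: ~6% rhythmic transcripts, low multiplicative
amplitudes (80% with peak/trough fold <= 2, support up to 4), a bimodal
peak-phase distribution (subjective morning ~CT2 and subjective night ~CT14),
condition-specific free-running periods (DD longer than LL), most rhythmic
transcripts shared between conditions with closely matching phase, log-normal
baselines and multiplicative log-normal noise, one sample per time point.

The two conditions are simulated as independent experiments: shared biology
(baseline, amplitude, waveform class), independent noise draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, TimeDesign, ValidationError, default_designs

__all__ = ["SimulationConfig", "simulate", "planted_de", "write_ground_truth"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Amplitude model: peak/trough fold is a two-part mixture,
    U(fold_min, fold_mid] with probability fold_low_weight and
    U(fold_mid, fold_max] otherwise, so P(fold <= 2) equals fold_low_weight
    by construction. fold_min sets the smallest oscillation treated as
    biologically meaningful (see the methods note for the power analysis
    behind the default).
    """

    n_transcripts: int = 10_000
    frac_rhythmic: float = 0.06
    period_dd: float = 25.4
    period_ll: float = 24.0
    phase_centers: tuple[float, float] = (2.0, 14.0)
    phase_sd: float = 1.5
    phase_weight: float = 0.5
    fold_min: float = 1.3
    fold_mid: float = 2.0
    fold_max: float = 4.0
    fold_low_weight: float = 0.8
    frac_shared: float = 0.87
    shared_shift_sd: float = 1.5
    asym_frac: float = 0.15
    noise_cv: float = 0.15
    baseline_meanlog: float = 3.0
    baseline_sdlog: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts != int(self.n_transcripts) or self.n_transcripts < 1:
            raise ValidationError("n_transcripts must be a positive integer")
        for name in ("frac_rhythmic", "frac_shared", "asym_frac",
                     "phase_weight", "fold_low_weight"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not (1 < self.fold_min < self.fold_mid <= self.fold_max):
            raise ValidationError("fold parameters must satisfy 1 < min < mid <= max")
        if self.period_dd <= 0 or self.period_ll <= 0:
            raise ValidationError("periods must be positive")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")


def _waveform_exponent(t: np.ndarray, phase: float, period: float,
                       kind: str, rise_frac: float) -> np.ndarray:
    """Oscillation on [-1, 1] peaking at t = phase (mod period).

    'cos' is a cosine; 'saw' is a piecewise-linear sawtooth in phase with a
    rise occupying ``rise_frac`` of the cycle (ending at the peak), then a
    fall. Exponentiating fold**(s/2) gives an exact peak/trough ratio of fold.
    """
    x = np.mod(t - phase, period) / period  # 0 at peak
    if kind == "cos":
        return np.cos(2 * np.pi * x)
    fall = 1.0 - rise_frac
    s = np.where(x < fall, 1.0 - 2.0 * x / fall, -1.0 + 2.0 * (x - fall) / rise_frac)
    return s


def _draw_folds(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    low = rng.random(n) < cfg.fold_low_weight
    folds = np.where(
        low,
        rng.uniform(cfg.fold_min, cfg.fold_mid, n),
        rng.uniform(cfg.fold_mid, cfg.fold_max, n),
    )
    return folds


def _circular_diff(a: np.ndarray, b: np.ndarray, period: float = 24.0) -> np.ndarray:
    d = np.mod(np.asarray(a) - np.asarray(b), period)
    return np.minimum(d, period - d)


def simulate(config: SimulationConfig,
             designs: dict[str, TimeDesign] | None = None,
             ) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Generate (DD matrix, LL matrix, ground-truth table).

    The ground truth has one row per transcript and condition with columns
    transcript_id, condition, rhythmic, phase, period, fold, waveform,
    rise_frac, baseline, shared, de_fold, de_direction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    designs = designs or default_designs()
    n = int(cfg.n_transcripts)

    ids = np.array([f"T{i:06d}" for i in range(n)], dtype=object)
    genes = np.array([f"G{i:06d}" for i in range(n)], dtype=object)
    baseline = np.exp(rng.normal(cfg.baseline_meanlog, cfg.baseline_sdlog, n))
    rhythmic = rng.random(n) < cfg.frac_rhythmic

    # phase: two wrapped-normal clusters on the 24 h circle
    cluster = rng.random(n) < cfg.phase_weight
    centers = np.where(cluster, cfg.phase_centers[0], cfg.phase_centers[1])
    phase_dd = np.mod(centers + rng.normal(0.0, cfg.phase_sd, n), 24.0)

    shared = rng.random(n) < cfg.frac_shared
    # shared transcripts: small phase shift (|shift| <= 4 h); the rest are
    # clearly displaced (6-12 h) so phase agreement is well separated
    small = np.clip(rng.normal(0.0, cfg.shared_shift_sd, n), -4.0, 4.0)
    big = rng.uniform(6.0, 12.0, n) * rng.choice([-1.0, 1.0], n)
    phase_ll = np.mod(phase_dd + np.where(shared, small, big), 24.0)

    folds = _draw_folds(rng, n, cfg)
    asym = rng.random(n) < cfg.asym_frac
    # asymmetric sawtooth: rise occupies a clearly unequal cycle fraction
    steep_rise = rng.random(n) < 0.5
    rise_frac = np.where(steep_rise, rng.uniform(0.2, 0.35, n), rng.uniform(0.65, 0.8, n))

    sigma = np.sqrt(np.log1p(cfg.noise_cv ** 2))
    matrices: dict[str, ExpressionMatrix] = {}
    truth_rows = []
    for cond, period, phases in (("DD", cfg.period_dd, phase_dd),
                                 ("LL", cfg.period_ll, phase_ll)):
        t = np.asarray(designs[cond].times, dtype=float)
        signal = np.ones((n, len(t)))
        for i in np.flatnonzero(rhythmic):
            kind = "saw" if asym[i] else "cos"
            s = _waveform_exponent(t, phases[i], period, kind, rise_frac[i])
            signal[i] = folds[i] ** (s / 2.0)
        noise = np.exp(rng.normal(0.0, sigma, (n, len(t))) - sigma ** 2 / 2.0)
        values = baseline[:, None] * signal * noise
        matrices[cond] = ExpressionMatrix(
            transcript_ids=ids.copy(), values=values,
            design=designs[cond], gene_ids=genes.copy(),
        )
        truth_rows.append(pd.DataFrame({
            "transcript_id": ids,
            "condition": cond,
            "rhythmic": rhythmic,
            "phase": np.where(rhythmic, phases, np.nan),
            "period": np.where(rhythmic, period, np.nan),
            "fold": np.where(rhythmic, folds, np.nan),
            "waveform": np.where(rhythmic, np.where(asym, "saw", "cos"), ""),
            "rise_frac": np.where(rhythmic & asym, rise_frac, np.nan),
            "baseline": baseline,
            "shared": rhythmic & shared,
            "de_fold": 1.0,
            "de_direction": "",
        }))
    truth = pd.concat(truth_rows, ignore_index=True)
    return matrices["DD"], matrices["LL"], truth


def planted_de(matrix_dd: ExpressionMatrix, matrix_ll: ExpressionMatrix,
               truth: pd.DataFrame, transcript_ids: np.ndarray,
               fold: float = 2.0, direction: str = "DD",
               ) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Scale the chosen transcripts by ``fold`` in one condition, uniformly
    across time points, recording direction and fold in the truth table."""
    if fold < 1:
        raise ValidationError("planted fold must be >= 1")
    if direction not in ("DD", "LL"):
        raise ValidationError("direction must be 'DD' or 'LL'")
    target = matrix_dd if direction == "DD" else matrix_ll
    sel = np.isin(target.transcript_ids.astype(str), np.asarray(transcript_ids, dtype=str))
    values = target.values.copy()
    values[sel] *= fold
    scaled = ExpressionMatrix(
        transcript_ids=target.transcript_ids, values=values,
        design=target.design, gene_ids=target.gene_ids,
    )
    truth = truth.copy()
    hit = truth["transcript_id"].isin(np.asarray(transcript_ids, dtype=str))
    truth.loc[hit, "de_fold"] = fold
    truth.loc[hit, "de_direction"] = direction if fold > 1 else ""
    if direction == "DD":
        return scaled, matrix_ll, truth
    return matrix_dd, scaled, truth


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
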