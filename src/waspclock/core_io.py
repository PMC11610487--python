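"""Data model, TSV I/O, normalization and reliability filtering.

The pipeline operates on FPKM-like transcript × time-point matrices sampled on
an evenly spaced free-running design (default: 12 samples at CT1, CT5, ...,
CT45, i.e. every 4 h over 48 h, one pooled sample per time point, separately
under constant darkness DD and constant light LL).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CONDITIONS = ("DD", "LL")


class FormatError(ValueError):
    """Input file does not match the expected layout."""


class ValidationError(ValueError):
    """Input values violate a model invariant."""


@dataclass(frozen=True)
class TimeDesign:
    """Sampling design of one free-running condition.

    times are circadian-time hours, strictly increasing and evenly spaced;
    the spacing must divide the rhythm test period (24 h) so samples can be
    folded into an integer number of phase groups.
    """

    condition: str
    times: tuple[float, ...] = tuple(1.0 + 4.0 * i for i in range(12))

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}")
        t = np.asarray(self.times, dtype=float)
        if len(t) < 2:
            raise ValidationError("need at least two time points")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
            raise ValidationError("times must be strictly increasing and evenly spaced")

    @property
    def interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0]) + self.interval

    def n_phase_groups(self, period: float = 24.0) -> int:
        k = period / self.interval
        if abs(k - round(k)) > 1e-9:
            raise ValidationError(
                f"interval {self.interval} h does not divide the test period {period} h"
            )
        return int(round(k))

    def phase_groups(self, period: float = 24.0) -> np.ndarray:
        """Fold sample indices into k cyclic phase groups of the test period."""
        k = self.n_phase_groups(period)
        t0 = self.times[0]
        return (np.round((np.asarray(self.times) - t0) / self.interval).astype(int)) % k

    def group_centers(self, period: float = 24.0) -> np.ndarray:
        """CT-hour center of each phase group, modulo 24 h."""
        k = self.n_phase_groups(period)
        return (self.times[0] + self.interval * np.arange(k)) % 24.0

    def sample_names(self) -> list[str]:
        return [f"{self.condition}_CT{int(round(t)):02d}" for t in self.times]


def default_designs() -> dict[str, TimeDesign]:
    return {c: TimeDesign(condition=c) for c in CONDITIONS}


@dataclass
class ExpressionMatrix:
    """Transcripts × samples non-negative abundance matrix with design metadata."""

    transcript_ids: np.ndarray
    values: np.ndarray
    design: TimeDesign
    gene_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transcript_ids = np.asarray(self.transcript_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (transcripts × samples)")
        if self.values.shape[0] != len(self.transcript_ids):
            raise ValidationError("row count must match transcript_ids")
        if self.values.shape[1] != len(self.design.times):
            raise FormatError(
                f"matrix has {self.values.shape[1]} sample columns, design expects "
                f"{len(self.design.times)}"
            )
        if np.isnan(self.values).any():
            raise ValidationError("values contain missing entries; filter first")
        if (self.values < 0).any():
            raise ValidationError("negative abundance values")
        if len(set(self.transcript_ids)) != len(self.transcript_ids):
            raise ValidationError("transcript ids must be unique")

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    def subset(self, mask: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            transcript_ids=self.transcript_ids[mask],
            values=self.values[mask],
            design=self.design,
            gene_ids=None if self.gene_ids is None else self.gene_ids[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.design.sample_names())
        df.insert(0, "transcript_id", self.transcript_ids)
        if self.gene_ids is not None:
            df.insert(1, "gene_id", self.gene_ids)
        return df

    def by_gene(self) -> "ExpressionMatrix":
        """Sum transcript rows per parent gene (gene-level analysis mode)."""
        if self.gene_ids is None:
            raise ValidationError("no gene_id column available")
        df = pd.DataFrame(self.values)
        df["gene"] = self.gene_ids
        summed = df.groupby("gene", sort=True).sum()
        return ExpressionMatrix(
            transcript_ids=summed.index.to_numpy(dtype=object),
            values=summed.to_numpy(dtype=float),
            design=self.design,
        )


@dataclass(frozen=True)
class PipelineConfig:
    """Printed analysis constants, gathered in one place."""

    rain_q_strict: float = 0.1
    rain_q_broad: float = 0.2
    jtk_q: float = 0.6
    reliable_fpkm_min: float = 5.0
    fc_cutoff: float = 1.5
    period_grid: tuple[float, float, float] = (20.0, 28.0, 0.2)
    n_clusters: int = 30
    fuzzifier_m: float = 1.25
    test_period: float = 24.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rain_q_strict", "rain_q_broad", "jtk_q"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must be in (0, 1]")
        if self.fc_cutoff <= 1:
            raise ValidationError("fc_cutoff must exceed 1")
        lo, hi, step = self.period_grid
        if not (lo < hi and step > 0):
            raise ValidationError("period grid bounds must be ordered with positive step")

    def grid(self) -> np.ndarray:
        lo, hi, step = self.period_grid
        n = int(round((hi - lo) / step))
        return np.round(lo + step * np.arange(n + 1), 10)


def read_expression(path: str | Path, design: TimeDesign) -> ExpressionMatrix:
    """Read a TSV expression matrix, dropping transcripts with missing values.

    Layout: header row; first column ``transcript_id``; optional second column
    ``gene_id``; remaining columns one per sample in design order.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "transcript_id":
        raise FormatError("first column must be 'transcript_id'")
    has_gene = len(df.columns) > 1 and df.columns[1] == "gene_id"
    value_cols = df.columns[2:] if has_gene else df.columns[1:]
    if len(value_cols) != len(design.times):
        raise FormatError(
            f"{len(value_cols)} sample columns, design expects {len(design.times)}"
        )
    vals = df[value_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    keep = ~np.isnan(vals).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d transcripts with missing/non-numeric values", dropped)
    if (vals[keep] < 0).any():
        raise ValidationError("negative abundance values in input")
    return ExpressionMatrix(
        transcript_ids=df["transcript_id"].to_numpy(dtype=object)[keep],
        values=vals[keep],
        design=design,
        gene_ids=df["gene_id"].to_numpy(dtype=object)[keep] if has_gene else None,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def size_factors(values: np.ndarray) -> np.ndarray:
    """Median-of-ratios (DESeq-style) per-sample scale factors.

    factor_j = median over transcripts of value_ij / geometric-mean_i, the
    geometric mean taken over samples and restricted to transcripts positive
    in every sample.
    """
    values = np.asarray(values, dtype=float)
    pos = (values > 0).all(axis=1)
    if not pos.any():
        raise ValidationError("no transcript positive in all samples")
    logv = np.log(values[pos])
    log_gm = logv.mean(axis=1, keepdims=True)
    factors = np.median(np.exp(logv - log_gm), axis=0)
    return factors


def normalize(matrix: ExpressionMatrix, joint_with: ExpressionMatrix | None = None
              ) -> ExpressionMatrix:
    """Divide columns by median-of-ratios size factors.

    If ``joint_with`` is given the factors are estimated jointly across both
    matrices' columns (all samples grouped) and applied to this matrix's
    columns; otherwise estimation is per-condition.
    """
    if joint_with is None:
        f = size_factors(matrix.values)
    else:
        # align rows on shared transcripts for joint estimation
        common, ia, ib = np.intersect1d(
            matrix.transcript_ids.astype(str),
            joint_with.transcript_ids.astype(str),
            return_indices=True,
        )
        if len(common) == 0:
            raise ValidationError("no shared transcripts for joint normalization")
        stacked = np.hstack([matrix.values[ia], joint_with.values[ib]])
        f = size_factors(stacked)[: matrix.values.shape[1]]
    return replace(matrix, values=matrix.values / f)


def reliable_mask(matrix: ExpressionMatrix, floor: float = 5.0) -> np.ndarray:
    """True where every time-point value is at or above the abundance floor."""
    return (matrix.values >= floor).all(axis=1)
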